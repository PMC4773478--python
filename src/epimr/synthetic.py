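"""Synthetic inputs with planted structure for every pipeline stage.

The generator emulates the statistical shape of the study design the
pipeline targets: two conditions (origin vs tumour, 3 replicates each) with
negative-binomial counts and planted log2 fold changes; H3K27me3 tag
densities over TSS-centred windows in three spatial classes (TSS-centred
with a sharp central dip, upstream, downstream) on a Poisson background; a
control track of pure background; promoters with planted PWM occurrences; a
planted master regulator whose motif is enriched in DEG promoters while its
own gene is repressed and de novo marked; an expression compendium with a
planted co-expression module; and survival cohorts with group-wise
exponential hazards. Every output is fully determined by the design seed
via fixed-order sub-seeding.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as eio
from .chip import ChipProfile
from .expression import CountMatrix
from .motif import BASES, PWM

CHIP_CLASSES = ("NONE", "TSS", "UP", "DOWN")

# fixed sub-seeding order: one RNG stream per output kind
_STREAMS = ("genome", "pwms", "motifs", "counts", "chip", "survival", "compendium")


class ConfigurationError(ValueError):
    """Raised when a simulation design is internally inconsistent."""


@dataclass
class SimulationDesign:
    """Complete, seed-deterministic description of one synthetic study."""

    n_genes: int = 1000
    n_samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"origin": 3, "tumour": 3}
    )
    origin_group: str = "origin"
    tumour_group: str = "tumour"
    promoter_len: int = 500
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    deg_spec: dict[str, float] = field(default_factory=dict)  # gene -> planted log2FC
    baseline_log_mean: float = np.log(100.0)
    baseline_log_sd: float = 1.0
    dispersion: float = 0.05
    chip_class_spec: dict[str, str] = field(default_factory=dict)  # tumour condition
    origin_chip_class_spec: dict[str, str] = field(default_factory=dict)
    chip_background: float = 10.0  # Poisson reads per bin
    enrichment_factor: float = 8.0
    window_half: int = 3000
    bin_size: int = 100
    motif_spec: dict[tuple[str, str], int] = field(default_factory=dict)
    master_tf: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be non-negative")
        if self.enrichment_factor < 1:
            raise ConfigurationError("enrichment_factor must be >= 1")
        if (2 * self.window_half) % self.bin_size != 0:
            raise ConfigurationError("bin size must divide the window")
        for lfc in self.deg_spec.values():
            if not np.isfinite(lfc):
                raise ConfigurationError("planted log2FC must be finite")
        for cls in list(self.chip_class_spec.values()) + list(
            self.origin_chip_class_spec.values()
        ):
            if cls not in CHIP_CLASSES:
                raise ConfigurationError(f"unknown chip class {cls!r}")

    def rng(self, stream: str) -> np.random.Generator:
        """Child RNG for one named output stream (fixed sub-seeding order)."""
        idx = _STREAMS.index(stream)
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(len(_STREAMS))[idx]
        )


@dataclass
class GenomeBundle:
    """Gene annotation plus promoter sequences."""

    genes: pd.DataFrame  # columns: gene_id, chrom, tss (0-based), strand
    promoters: dict[str, str]

    def __post_init__(self) -> None:
        ids = self.genes["gene_id"]
        if ids.duplicated().any():
            raise ConfigurationError("gene ids must be unique")
        lengths = {len(s) for s in self.promoters.values()}
        if len(lengths) > 1:
            raise ConfigurationError("promoter lengths must be identical")
        for g, s in self.promoters.items():
            if set(s) - set(BASES):
                raise ConfigurationError(f"promoter {g} contains non-ACGT characters")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes["gene_id"])

    def to_bed6(self) -> pd.DataFrame:
        rows = []
        for _, r in self.genes.iterrows():
            # unit-length feature anchored at the TSS; minus strand: tss = end-1
            if r["strand"] == "+":
                start, end = r["tss"], r["tss"] + 1
            else:
                start, end = r["tss"], r["tss"] + 1
            rows.append(
                {
                    "chrom": r["chrom"],
                    "start": start,
                    "end": end,
                    "name": r["gene_id"],
                    "score": 0,
                    "strand": r["strand"],
                }
            )
        return pd.DataFrame(rows, columns=eio.BED6_COLUMNS)


def simulate_genome(design: SimulationDesign) -> GenomeBundle:
    """Non-overlapping TSSs on one chromosome plus i.i.d. promoter sequences."""
    rng = design.rng("genome")
    spacing = 2 * design.window_half + 2 * design.bin_size
    margin = design.window_half + design.bin_size
    tss = margin + spacing * np.arange(design.n_genes)
    strands = rng.choice(["+", "-"], size=design.n_genes)
    width = len(str(design.n_genes))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(design.n_genes)]
    genes = pd.DataFrame(
        {"gene_id": gene_ids, "chrom": "chr1", "tss": tss, "strand": strands}
    )
    comp = np.asarray(design.base_composition, dtype=float)
    comp = comp / comp.sum()
    promoters = {
        g: "".join(rng.choice(list(BASES), size=design.promoter_len, p=comp))
        for g in gene_ids
    }
    return GenomeBundle(genes=genes, promoters=promoters)


def sample_site(pwm: PWM, rng: np.random.Generator) -> str:
    """One exact draw from the PWM's per-column base distribution.

    Uses the raw count frequencies (no pseudocount): a consensus-only PWM
    always yields its consensus string.
    """
    freqs = pwm.raw_frequencies
    return "".join(BASES[rng.choice(4, p=freqs[:, j])] for j in range(pwm.length))


def plant_motifs(
    bundle: GenomeBundle,
    pwm: PWM,
    targets: set[str],
    sites_per_promoter: int,
    seed: int | np.random.Generator = 0,
) -> GenomeBundle:
    """Insert PWM-sampled sites at non-overlapping offsets in target promoters."""
    missing = targets - set(bundle.promoters)
    if missing:
        raise ConfigurationError(f"targets not in bundle: {sorted(missing)[:5]}")
    if sites_per_promoter == 0:
        return bundle
    L = pwm.length
    prom_len = len(next(iter(bundle.promoters.values())))
    if sites_per_promoter * L > prom_len:
        raise ConfigurationError("requested sites do not fit in the promoter")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    new_promoters = dict(bundle.promoters)
    for g in sorted(targets):
        seq = list(new_promoters[g])
        # k non-overlapping offsets: draw gaps around k fixed-length blocks
        slack = prom_len - sites_per_promoter * L
        cuts = np.sort(rng.integers(0, slack + 1, size=sites_per_promoter))
        offsets = [int(cuts[i] + i * L) for i in range(sites_per_promoter)]
        for off in offsets:
            seq[off : off + L] = sample_site(pwm, rng)
        new_promoters[g] = "".join(seq)
    return GenomeBundle(genes=bundle.genes.copy(), promoters=new_promoters)


def random_pwms(
    n: int,
    length: int = 8,
    concentration: float = 0.85,
    rng: np.random.Generator | None = None,
) -> list[PWM]:
    """Information-rich synthetic PWMs: one dominant base per column."""
    rng = rng or np.random.default_rng(0)
    pwms = []
    for i in range(n):
        dominant = rng.integers(0, 4, size=length)
        counts = np.full((4, length), (1 - concentration) / 3 * 100)
        counts[dominant, np.arange(length)] = concentration * 100
        pwms.append(PWM(id=f"M{i + 1:03d}", name=f"motif_{i + 1}", counts=counts))
    return pwms


def simulate_counts(design: SimulationDesign, bundle: GenomeBundle | None = None) -> CountMatrix:
    """NB counts per gene and sample with planted tumour fold changes."""
    if len(design.n_samples_per_group) < 2:
        raise ConfigurationError("need at least 2 condition groups")
    for g, n in design.n_samples_per_group.items():
        if n < 2:
            raise ConfigurationError(f"group {g} needs >= 2 replicates")
    rng = design.rng("counts")
    gene_ids = (
        bundle.gene_ids
        if bundle is not None
        else [f"g{i + 1:0{len(str(design.n_genes))}d}" for i in range(design.n_genes)]
    )
    baselines = rng.lognormal(design.baseline_log_mean, design.baseline_log_sd, len(gene_ids))
    lfc = np.array([design.deg_spec.get(g, 0.0) for g in gene_ids])
    columns = {}
    groups = {}
    for group, n_rep in design.n_samples_per_group.items():
        mult = 2.0**lfc if group == design.tumour_group else np.ones(len(gene_ids))
        mean = baselines * mult
        for r in range(n_rep):
            sample = f"{group}_{r + 1}"
            if design.dispersion == 0:
                counts = rng.poisson(mean)
            else:
                size = 1.0 / design.dispersion
                counts = rng.negative_binomial(size, size / (size + mean))
            columns[sample] = counts
            groups[sample] = group
    counts = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    return CountMatrix(counts=counts, groups=pd.Series(groups))


def _class_lambda(design: SimulationDesign, cls: str) -> np.ndarray:
    """Per-bin Poisson rate layout for one spatial class."""
    n_bins = 2 * design.window_half // design.bin_size
    lam = np.full(n_bins, design.chip_background)
    f = design.enrichment_factor
    half = n_bins // 2
    if cls == "UP":
        lam[:half] *= f
    elif cls == "DOWN":
        lam[half:] *= f
    elif cls == "TSS":
        lam[:] *= f
        lam[half - 1 : half + 1] = design.chip_background  # sharp central dip
    return lam


def simulate_chip(
    design: SimulationDesign, bundle: GenomeBundle | None = None
) -> tuple[dict[str, list[ChipProfile]], ChipProfile]:
    """Per-sample signal profiles plus one pure-background control track."""
    rng = design.rng("chip")
    gene_ids = (
        bundle.gene_ids
        if bundle is not None
        else [f"g{i + 1:0{len(str(design.n_genes))}d}" for i in range(design.n_genes)]
    )
    n_bins = 2 * design.window_half // design.bin_size
    layouts = {cls: _class_lambda(design, cls) for cls in CHIP_CLASSES}

    def one_profile(sample: str, class_spec: Mapping[str, str]) -> ChipProfile:
        lam = np.stack([layouts[class_spec.get(g, "NONE")] for g in gene_ids])
        values = rng.poisson(lam).astype(float)
        return ChipProfile(
            sample=sample,
            genes=list(gene_ids),
            values=values,
            window_half=design.window_half,
            bin_size=design.bin_size,
            library_size=float(values.sum()),
        )

    profiles: dict[str, list[ChipProfile]] = {}
    for group, n_rep in design.n_samples_per_group.items():
        spec = (
            design.chip_class_spec
            if group == design.tumour_group
            else design.origin_chip_class_spec
        )
        profiles[group] = [one_profile(f"{group}_chip_{r + 1}", spec) for r in range(n_rep)]
    control = one_profile("control", {})
    return profiles, control


def chip_to_bedgraph(profile: ChipProfile, bundle: GenomeBundle) -> pd.DataFrame:
    """Genomic bedGraph of a window profile (inverse of the strand correction)."""
    rows = []
    genes = bundle.genes.set_index("gene_id")
    for i, g in enumerate(profile.genes):
        tss = int(genes.loc[g, "tss"])
        strand = genes.loc[g, "strand"]
        vals = profile.values[i]
        if strand == "-":
            vals = vals[::-1]
        starts = tss + np.arange(-profile.window_half, profile.window_half, profile.bin_size)
        for s, v in zip(starts, vals):
            if np.isnan(v):
                continue
            rows.append(
                {
                    "chrom": genes.loc[g, "chrom"],
                    "start": int(s),
                    "end": int(s) + profile.bin_size,
                    "value": float(v),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def simulate_survival(
    groups: Sequence[tuple[str, int, float]],
    censoring_rate: float = 0.2,
    seed: int = 0,
    expr_bands: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Exponential event times per group with independent uniform censoring.

    ``groups`` is a sequence of (label, n_patients, hazard). Expression
    values are drawn from per-group bands chosen so that fold-change
    stratification against the cohort median reproduces the intended groups
    (HIGH above 2x median, LOW below 0.5x, MID around it).
    """
    if not 0 <= censoring_rate < 1:
        raise ValueError("censoring_rate must be in [0, 1)")
    default_bands = {"HIGH": (2.5, 4.0), "MID": (0.8, 1.2), "LOW": (0.1, 0.4)}
    rng = np.random.default_rng(seed)
    rows = []
    for label, n, hazard in groups:
        if n < 1:
            raise ValueError(f"group {label} is empty")
        if hazard <= 0:
            raise ValueError("hazards must be positive")
        event_times = rng.exponential(1.0 / hazard, size=n)
        if censoring_rate > 0:
            # exponential censoring tuned so P(censored) = censoring_rate
            c_rate = hazard * censoring_rate / (1 - censoring_rate)
            censor_times = rng.exponential(1.0 / c_rate, size=n)
        else:
            censor_times = np.full(n, np.inf)
        observed = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)
        if expr_bands and label in expr_bands:
            lo, hi = expr_bands[label]
        elif label in default_bands:
            lo, hi = default_bands[label]
        else:
            lo, hi = (0.8, 1.2)
        expr = rng.uniform(lo, hi, size=n)
        for i in range(n):
            rows.append(
                {
                    "patient_id": f"{label}_{i + 1}",
                    "time": float(np.maximum(observed[i], 1e-9)),
                    "event": int(event[i]),
                    "expr": float(expr[i]),
                    "group": label,
                }
            )
    return pd.DataFrame(rows)


def simulate_compendium(
    gene_ids: Sequence[str],
    module: set[str],
    n_profiles: int = 106,
    module_rho: float = 0.9,
    seed: int = 0,
) -> pd.DataFrame:
    """Expression compendium with one latent-factor co-expression module."""
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal(n_profiles)
    data = {}
    load = np.sqrt(module_rho)
    noise_sd = np.sqrt(1 - module_rho)
    for g in gene_ids:
        if g in module:
            data[g] = load * latent + noise_sd * rng.standard_normal(n_profiles)
        else:
            data[g] = rng.standard_normal(n_profiles)
    return pd.DataFrame(
        data, index=[f"profile_{i + 1}" for i in range(n_profiles)]
    ).T


@dataclass
class InputBundle:
    """Everything one pipeline run consumes, plus the planted ground truth."""

    design: SimulationDesign
    genome: GenomeBundle
    pwms: list[PWM]
    tf_to_gene: dict[str, str]
    counts: CountMatrix
    chip_profiles: dict[str, list[ChipProfile]]
    control_profile: ChipProfile
    truth: dict


def planted_design(
    seed: int = 0,
    n_genes: int = 1000,
    n_deg_per_direction: int = 100,
    planted_lfc: float = 2.0,
    n_denovo: int = 150,
    master_tf: bool = True,
) -> SimulationDesign:
    """Study-condition design with a planted repressed, de novo marked TF.

    Layout (gene ranks): the first ``n_deg_per_direction`` genes are planted
    DOWN (-planted_lfc), the next block UP (+planted_lfc). De novo H3K27me3
    (tumour condition only) covers the master TF gene, half of the DOWN DEGs
    and additional unrelated genes up to ``n_denovo``. The master TF is the
    first DOWN gene; its chip class is TSS (mark covering the TSS and both
    flanks), matching the configuration whose expression consequence the
    pipeline is built to detect.
    """
    width = len(str(n_genes))
    gid = lambda i: f"g{i + 1:0{width}d}"
    deg_spec: dict[str, float] = {}
    for i in range(n_deg_per_direction):
        deg_spec[gid(i)] = -planted_lfc
    for i in range(n_deg_per_direction, 2 * n_deg_per_direction):
        deg_spec[gid(i)] = planted_lfc

    rng = np.random.default_rng(seed + 10_000)
    chip_class: dict[str, str] = {}
    master_gene = gid(0) if master_tf else None
    if master_gene:
        chip_class[master_gene] = "TSS"
    # half the DOWN DEGs become de novo marked
    for i in range(1, n_deg_per_direction // 2):
        chip_class[gid(i)] = rng.choice(["TSS", "DOWN", "UP"])
    # unrelated de novo targets beyond the DEGs
    i = 2 * n_deg_per_direction
    while len(chip_class) < n_denovo and i < n_genes:
        chip_class[gid(i)] = rng.choice(["TSS", "DOWN", "UP"])
        i += 1
    return SimulationDesign(
        n_genes=n_genes,
        deg_spec=deg_spec,
        chip_class_spec=chip_class,
        master_tf=master_gene,
        seed=seed,
    )


def null_design(seed: int = 0, n_genes: int = 1000) -> SimulationDesign:
    """Same study conditions with nothing planted."""
    return SimulationDesign(n_genes=n_genes, seed=seed)


def plant_master_regulator(
    design: SimulationDesign,
    n_pwms: int = 50,
    sites_per_promoter: int = 2,
    planted_fraction: float = 0.7,
) -> InputBundle:
    """Build the full input bundle for one end-to-end pipeline run.

    Fifty information-rich PWMs are generated; each maps to one gene. When
    the design has a master TF, its PWM's motif is planted in a majority
    (``planted_fraction``) of planted-DEG promoters, the decoy PWMs get no
    planted sites, and the master PWM maps to the master gene (itself
    repressed and de novo marked by the design).
    """
    if design.master_tf is not None and design.master_tf not in (
        f"g{i + 1:0{len(str(design.n_genes))}d}" for i in range(design.n_genes)
    ):
        raise ConfigurationError(f"master_tf {design.master_tf} not in gene list")
    genome = simulate_genome(design)
    pwm_rng = design.rng("pwms")
    pwms = random_pwms(n_pwms, rng=pwm_rng)
    if genome.promoters and pwms:
        prom_len = len(next(iter(genome.promoters.values())))
        if any(p.length > prom_len for p in pwms):
            raise ConfigurationError("promoter shorter than a PWM")

    # PWM -> gene map: decoys map to genes outside the planted DEG blocks
    gene_ids = genome.gene_ids
    deg_genes = set(design.deg_spec)
    candidates = [g for g in gene_ids if g not in deg_genes]
    map_rng = design.rng("pwms")  # same stream, after pwm draws in pwm_rng
    chosen = map_rng.choice(len(candidates), size=n_pwms, replace=False)
    tf_to_gene = {pwms[i].id: candidates[int(chosen[i])] for i in range(n_pwms)}

    motif_rng = design.rng("motifs")
    planted_targets: set[str] = set()
    master_pwm_id = None
    if design.master_tf is not None:
        master_pwm_id = pwms[0].id
        tf_to_gene[master_pwm_id] = design.master_tf
        deg_list = sorted(deg_genes)
        k = int(round(planted_fraction * len(deg_list)))
        idx = motif_rng.choice(len(deg_list), size=k, replace=False)
        planted_targets = {deg_list[int(i)] for i in idx}
        genome = plant_motifs(
            genome, pwms[0], planted_targets, sites_per_promoter, seed=motif_rng
        )
    # explicit extra plantings from the design spec
    pwm_by_id = {p.id: p for p in pwms}
    for (pwm_id, gene), n_sites in sorted(design.motif_spec.items()):
        genome = plant_motifs(genome, pwm_by_id[pwm_id], {gene}, n_sites, seed=motif_rng)

    counts = simulate_counts(design, genome)
    chip_profiles, control = simulate_chip(design, genome)
    truth = {
        "master_tf": design.master_tf,
        "master_pwm": master_pwm_id,
        "planted_down": {g for g, l in design.deg_spec.items() if l < 0},
        "planted_up": {g for g, l in design.deg_spec.items() if l > 0},
        "planted_denovo": set(design.chip_class_spec),
        "motif_targets": planted_targets,
    }
    return InputBundle(
        design=design,
        genome=genome,
        pwms=pwms,
        tf_to_gene=tf_to_gene,
        counts=counts,
        chip_profiles=chip_profiles,
        control_profile=control,
        truth=truth,
    )


def write_bundle(bundle: InputBundle, outdir: str | os.PathLike) -> dict[str, str]:
    """Write every bundle component as plain-text files; returns the paths."""
    from .motif import write_jaspar

    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    bed = bundle.genome.to_bed6()
    paths["annotation"] = os.path.join(outdir, "annotation.bed")
    eio.write_bed6(bed, paths["annotation"])

    paths["promoters"] = os.path.join(outdir, "promoters.fa")
    eio.write_fasta(bundle.genome.promoters, paths["promoters"])

    paths["counts"] = os.path.join(outdir, "counts.tsv")
    eio.write_counts(bundle.counts.counts, paths["counts"])
    paths["groups"] = os.path.join(outdir, "groups.tsv")
    eio.write_groups(bundle.counts.groups, paths["groups"])

    for group, profiles in bundle.chip_profiles.items():
        for prof in profiles:
            key = f"chip_{prof.sample}"
            paths[key] = os.path.join(outdir, f"{prof.sample}.bedgraph")
            eio.write_bedgraph(chip_to_bedgraph(prof, bundle.genome), paths[key])
    paths["chip_control"] = os.path.join(outdir, "control.bedgraph")
    eio.write_bedgraph(
        chip_to_bedgraph(bundle.control_profile, bundle.genome), paths["chip_control"]
    )

    paths["pwms"] = os.path.join(outdir, "motifs.jaspar")
    write_jaspar(bundle.pwms, paths["pwms"])

    paths["tf_map"] = os.path.join(outdir, "tf_to_gene.tsv")
    pd.Series(bundle.tf_to_gene, name="gene_id").rename_axis("pwm_id").to_csv(
        paths["tf_map"], sep="\t", header=False
    )

    paths["design"] = os.path.join(outdir, "design.txt")
    with open(paths["design"], "w") as fh:
        d = bundle.design
        for key in (
            "n_genes",
            "promoter_len",
            "dispersion",
            "chip_background",
            "enrichment_factor",
            "window_half",
            "bin_size",
            "master_tf",
            "seed",
        ):
            fh.write(f"{key}: {getattr(d, key)}\n")
        fh.write(f"n_planted_deg: {len(d.deg_spec)}\n")
        fh.write(f"n_planted_chip: {len(d.chip_class_spec)}\n")
    return paths
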