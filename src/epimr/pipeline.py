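"""End-to-end pipeline: simulate -> DEG -> ChIP -> motif -> integrate -> GSEA.

``run_pipeline`` chains the stages on one config, writes each stage's
outputs under the configured directory, and records inputs, outputs and
content hashes in a machine-readable manifest; re-running an identical
config reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import chip as echip
from . import expression as eexpr
from . import network as enet
from . import regulator as ereg
from . import synthetic as esyn
from .config import RunConfig
from .motif import motif_enrichment, score_promoters

logger = logging.getLogger(__name__)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def analyse_bundle(bundle: esyn.InputBundle, config: RunConfig) -> dict:
    """Run the analytical stages on an in-memory input bundle."""
    design = bundle.design
    results: dict = {}

    deg = eexpr.call_degs(
        bundle.counts,
        origin_group=design.origin_group,
        tumour_group=design.tumour_group,
        alpha=config.alpha,
        lfc_min=config.lfc_min,
    )
    results["deg"] = deg

    origin_calls = [
        echip.call_targets(p, bundle.control_profile, fdr=config.fdr)
        for p in bundle.chip_profiles[design.origin_group]
    ]
    tumour_calls = [
        echip.call_targets(p, bundle.control_profile, fdr=config.fdr)
        for p in bundle.chip_profiles[design.tumour_group]
    ]
    denovo = echip.de_novo_targets(origin_calls, tumour_calls)
    results["origin_calls"] = origin_calls
    results["tumour_calls"] = tumour_calls
    results["denovo"] = denovo

    deg_genes = deg.index[deg["direction"] != "NS"]
    fg = [g for g in deg_genes if g in bundle.genome.promoters]
    scores = score_promoters(bundle.genome.promoters, bundle.pwms)
    if fg:
        enrichment = motif_enrichment(fg, bundle.genome.promoters, bundle.pwms, scores=scores)
    else:
        enrichment = pd.DataFrame(
            columns=["name", "fg_mean", "bg_mean", "bg_sd", "z", "p", "p_bonferroni", "n_fg", "n_bg"]
        )
    results["enrichment"] = enrichment

    table = ereg.rank_master_regulators(
        enrichment, deg, denovo, bundle.tf_to_gene, alpha=config.alpha
    )
    results["regulators"] = table
    results["shortlist"] = ereg.shortlist(table)
    results["core_set"] = ereg.intersect_down_denovo(deg, denovo)

    # GSEA of the planted-module genes (when present) against the transition ranking
    truth = bundle.truth
    if truth.get("planted_down"):
        ranked = deg["log2fc"]
        gene_set = set(truth["planted_down"])
        results["gsea"] = enet.gsea(
            ranked,
            gene_set,
            weight=config.gsea_weight,
            n_perm=config.n_perm,
            seed=design.seed,
        )
    return results


def run_pipeline(config: RunConfig) -> dict:
    """Full run from a config: simulate, analyse, write outputs + manifest."""
    config.echo()
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)

    design = esyn.planted_design(
        seed=config.seed,
        n_genes=config.n_genes,
        n_deg_per_direction=config.n_deg_per_direction,
        planted_lfc=config.planted_lfc,
        n_denovo=config.n_denovo,
        master_tf=config.master_tf,
    )
    bundle = esyn.plant_master_regulator(
        design,
        n_pwms=config.n_pwms,
        sites_per_promoter=config.sites_per_promoter,
        planted_fraction=config.planted_fraction,
    )
    input_paths = esyn.write_bundle(bundle, os.path.join(outdir, "inputs"))

    results = analyse_bundle(bundle, config)

    out_paths: dict[str, str] = {}
    deg_path = os.path.join(outdir, "deg.tsv")
    results["deg"].rename_axis("gene_id").to_csv(deg_path, sep="\t")
    out_paths["deg"] = deg_path

    calls = pd.concat(results["origin_calls"] + results["tumour_calls"])
    calls_path = os.path.join(outdir, "chip_targets.tsv")
    calls.to_csv(calls_path, sep="\t")
    out_paths["chip_targets"] = calls_path

    denovo_path = os.path.join(outdir, "denovo_targets.txt")
    with open(denovo_path, "w") as fh:
        for g in sorted(results["denovo"]):
            fh.write(g + "\n")
    out_paths["denovo"] = denovo_path

    enr_path = os.path.join(outdir, "motif_enrichment.tsv")
    results["enrichment"].to_csv(enr_path, sep="\t")
    out_paths["enrichment"] = enr_path

    reg_path = os.path.join(outdir, "regulators.tsv")
    results["regulators"].to_csv(reg_path, sep="\t", index=False)
    out_paths["regulators"] = reg_path

    core_path = os.path.join(outdir, "core_down_denovo.tsv")
    results["core_set"].rename_axis("gene_id").to_csv(core_path, sep="\t")
    out_paths["core_set"] = core_path

    manifest = {
        "config": asdict(config),
        "inputs": {k: _sha256(p) for k, p in input_paths.items()},
        "outputs": {k: _sha256(p) for k, p in out_paths.items()},
        "shortlist": results["shortlist"],
        "n_deg": int((results["deg"]["direction"] != "NS").sum()),
        "n_denovo": len(results["denovo"]),
        "n_enriched_motifs": int(
            (results["enrichment"]["p_bonferroni"] < config.alpha).sum()
        )
        if len(results["enrichment"])
        else 0,
    }
    if "gsea" in results:
        manifest["gsea"] = {
            k: (v if not isinstance(v, np.ndarray) else None)
            for k, v in results["gsea"].items()
            if k in {"es", "nes", "nominal_p", "n_perm", "seed"}
        }
    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.info("pipeline complete; manifest at %s", manifest_path)
    results["manifest"] = manifest
    return results
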