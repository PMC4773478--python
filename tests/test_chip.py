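"""TSS-window quantification, target calling and spatial pattern logic."""

import itertools

import numpy as np
import pandas as pd
import pytest

from epimr import chip as ch
from epimr import io as eio
from epimr import synthetic as syn
from epimr.synthetic import SimulationDesign


def flat_bedgraph(value=5.0, length=200_000):
    return pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [length], "value": [value]})


def annotation(rows):
    return pd.DataFrame(rows, columns=eio.BED6_COLUMNS)


class TestTssProfile:
    def test_flat_coverage_gives_equal_bins(self):
        bed = annotation([["chr1", 50_000, 50_001, "g1", 0, "+"]])
        prof = ch.tss_profile(flat_bedgraph(5.0), bed)
        assert prof.values.shape == (1, 60)
        assert np.allclose(prof.values, 5.0)

    def test_bin_count_contract(self):
        bed = annotation([["chr1", 50_000, 50_001, "g1", 0, "+"]])
        prof = ch.tss_profile(flat_bedgraph(), bed, window_half=3000, bin_size=100)
        assert prof.n_bins == 60

    def test_bin_size_must_divide_window(self):
        bed = annotation([["chr1", 50_000, 50_001, "g1", 0, "+"]])
        with pytest.raises(ValueError):
            ch.tss_profile(flat_bedgraph(), bed, window_half=3000, bin_size=70)

    def test_minus_strand_signal_is_strand_corrected(self):
        # signal only genomically downstream (right) of the TSS at 50kb
        bg = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [0, 50_000],
                "end": [50_000, 53_000],
                "value": [1.0, 9.0],
            }
        )
        plus = annotation([["chr1", 50_000, 50_001, "g1", 0, "+"]])
        minus = annotation([["chr1", 49_999, 50_000, "g1", 0, "-"]])
        p_plus = ch.tss_profile(bg, plus)
        p_minus = ch.tss_profile(bg, minus)
        # '+': enrichment in downstream (positive) bins; '-': in upstream bins
        assert p_plus.values[0, 30:].mean() > p_plus.values[0, :30].mean()
        assert p_minus.values[0, :30].mean() > p_minus.values[0, 30:].mean()

    def test_window_exiting_chromosome_yields_nan_bins(self):
        bed = annotation([["chr1", 1000, 1001, "g1", 0, "+"]])
        prof = ch.tss_profile(flat_bedgraph(), bed)
        assert np.isnan(prof.values[0, :10]).all()
        assert np.isfinite(prof.values[0, 30:]).all()

    def test_roundtrip_through_bedgraph(self, small_bundle):
        prof = small_bundle.chip_profiles["tumour"][0]
        bg = syn.chip_to_bedgraph(prof, small_bundle.genome)
        bed = small_bundle.genome.to_bed6()
        back = ch.tss_profile(bg, bed, sample=prof.sample)
        assert np.allclose(back.values, prof.values, equal_nan=True)


class TestCallTargets:
    def test_signal_equal_to_control_calls_nothing(self):
        design = syn.null_design(seed=1, n_genes=400)
        profiles, control = syn.simulate_chip(design)
        calls = ch.call_targets(profiles["tumour"][0], control)
        assert calls["is_target"].mean() <= 0.05

    def test_planted_factor_recovery(self):
        recovered, false = [], []
        for seed in range(5):
            spec = {f"g{i + 1:04d}": "TSS" for i in range(200)}
            design = SimulationDesign(n_genes=1000, chip_class_spec=spec, seed=seed)
            profiles, control = syn.simulate_chip(design)
            calls = ch.call_targets(profiles["tumour"][0], control)
            hits = set(calls.index[calls["is_target"]])
            recovered.append(len(hits & set(spec)))
            false.append(len(hits - set(spec)))
        assert np.mean(recovered) >= 190
        assert np.mean(false) <= 60

    def test_zero_control_errors(self, small_bundle):
        prof = small_bundle.chip_profiles["tumour"][0]
        zero = ch.ChipProfile(
            sample="z",
            genes=prof.genes,
            values=np.zeros_like(prof.values),
            library_size=1.0,
        )
        with pytest.raises(ValueError):
            ch.call_targets(prof, zero)


class TestDeNovo:
    @staticmethod
    def calls_from(targets, genes):
        return pd.DataFrame(
            {"is_target": [g in targets for g in genes]},
            index=pd.Index(genes, name="gene_id"),
        )

    def test_identical_tumour_and_origin_yield_empty(self):
        genes = [f"g{i}" for i in range(10)]
        c = self.calls_from({"g1", "g2"}, genes)
        assert ch.de_novo_targets([c], [c.copy()]) == set()

    def test_intersection_minus_union_rule(self):
        genes = [f"g{i}" for i in range(6)]
        t1 = self.calls_from({"g1", "g2", "g3"}, genes)
        t2 = self.calls_from({"g2", "g3", "g4"}, genes)
        o1 = self.calls_from({"g3"}, genes)
        assert ch.de_novo_targets([o1], [t1, t2]) == {"g2"}

    def test_monotone_under_added_tumour_samples(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(200)]
        origin = [self.calls_from(set(rng.choice(genes, 20, replace=False)), genes)]
        tumours = [
            self.calls_from(set(rng.choice(genes, 120, replace=False)), genes)
            for _ in range(4)
        ]
        prev = ch.de_novo_targets(origin, tumours[:1])
        for k in range(2, 5):
            cur = ch.de_novo_targets(origin, tumours[:k])
            assert cur <= prev
            prev = cur


class TestClassifyPattern:
    def test_hand_computed_up_example(self):
        row = np.concatenate([np.full(30, 80.0), np.full(30, 15.0)])
        assert ch.classify_pattern(row) == "UP"  # log2(80/15) = 2.415 >= 1

    def test_symmetric_profile_is_tss(self):
        row = np.concatenate([np.full(30, 50.0), np.full(30, 50.0)])
        row[29] = row[30] = 5.0
        assert ch.classify_pattern(row) == "TSS"

    def test_reversal_swaps_up_down_and_fixes_tss(self, rng):
        swaps = {"UP": "DOWN", "DOWN": "UP", "TSS": "TSS"}
        for _ in range(1000):
            row = rng.gamma(2.0, 10.0, size=60) + 0.1
            assert ch.classify_pattern(row[::-1]) == swaps[ch.classify_pattern(row)]

    def test_empty_window_is_inconsistent_call(self):
        with pytest.raises(ValueError):
            ch.classify_pattern(np.zeros(60))


class TestMannWhitneyAndExpressionByPattern:
    def test_small_sample_exact_p(self):
        u, p = ch.mann_whitney(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert u == 0.0
        assert abs(p - 0.1) < 1e-12  # 2 * (1 / C(6,3))

    def test_exact_p_matches_full_enumeration(self, rng):
        from scipy.stats import rankdata

        for n1, n2 in [(3, 4), (5, 5), (4, 8)]:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2) + 0.5
            _, p = ch.mann_whitney(x, y)
            # enumeration oracle: all C(n1+n2, n1) label assignments
            pooled = np.concatenate([x, y])
            ranks = rankdata(pooled)
            obs_u = np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2
            obs_dev = abs(obs_u - n1 * n2 / 2)
            count = total = 0
            for combo in itertools.combinations(range(n1 + n2), n1):
                u = np.sum(ranks[list(combo)]) - n1 * (n1 + 1) / 2
                total += 1
                if abs(u - n1 * n2 / 2) >= obs_dev - 1e-9:
                    count += 1
            assert abs(p - count / total) < 1e-9

    def test_identical_classes_give_p_one(self):
        vals = np.array([1.0, 2, 3, 4])
        _, p = ch.mann_whitney(vals, vals.copy())
        assert p == 1.0

    def test_marked_classes_show_lower_expression(self, rng):
        rejections = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            classes = pd.Series(
                ["TSS"] * 100 + ["UP"] * 100, index=[f"g{i}" for i in range(200)]
            )
            expr = pd.Series(
                np.concatenate([r.normal(-1, 1, 100), r.normal(0, 1, 100)]),
                index=classes.index,
            )
            _, pairs = ch.expression_by_pattern(classes, expr)
            if pairs["p"].iloc[0] < 0.05:
                rejections += 1
        assert rejections >= 19

    def test_single_member_class_excluded(self):
        classes = pd.Series(["TSS"] * 5 + ["UP"], index=[f"g{i}" for i in range(6)])
        expr = pd.Series(np.arange(6.0), index=classes.index)
        with pytest.warns(UserWarning), pytest.raises(ValueError):
            ch.expression_by_pattern(classes, expr)
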