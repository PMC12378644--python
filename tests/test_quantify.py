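import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikequant import synthetic
from spikequant.quantify import (
    RecoveryWarning,
    SampleAbortedError,
    StandardRecovery,
    cells_from_haploid,
    combine_recoveries,
    detection_limit,
    estimate_recovery,
    gene_abundance,
    quantify_samples,
    recovery_ratio,
    standard_recovery,
    volumetric_abundance,
)

finite_pos = st.floats(1e-9, 1e12, allow_nan=False, allow_infinity=False)
counts_st = st.floats(0, 1e9, allow_nan=False, allow_infinity=False)


class TestScalarOps:
    def test_standard_recovery_direct(self):
        assert standard_recovery(4000, 2000) == 2.0
        assert standard_recovery(0, 100) == 0.0

    def test_standard_recovery_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            standard_recovery(10, 0)

    def test_recovery_ratio(self):
        assert recovery_ratio(1e6, 1e6) == 1.0
        assert recovery_ratio(0.5, 1e6) == 5e-7

    def test_recovery_ratio_warns_above_one(self):
        with pytest.warns(RecoveryWarning):
            assert recovery_ratio(2.0, 1.0) == 2.0

    def test_recovery_ratio_zero_added_rejected(self):
        with pytest.raises(ValueError):
            recovery_ratio(1.0, 0.0)

    def test_gene_abundance(self):
        assert gene_abundance(100, 0.01) == pytest.approx(1e4)
        assert gene_abundance(0, 0.5) == 0.0
        with pytest.raises(ValueError, match="flagged"):
            gene_abundance(10, 0.0)

    def test_volumetric(self):
        assert volumetric_abundance(1e9, 1.0) == 1e9
        assert volumetric_abundance(1e9, 0.5) == 2e9
        with pytest.raises(ValueError):
            volumetric_abundance(1.0, 0.0)

    def test_detection_limit(self):
        assert detection_limit(1e-6, 1.0) == pytest.approx(1e6)
        # deeper sequencing: R scaled by d divides the limit by d exactly
        assert detection_limit(13e-6, 1.0) == pytest.approx(1e6 / 13)

    def test_cells_from_haploid(self):
        assert cells_from_haploid(1e6, 2) == 5e5
        assert cells_from_haploid(123.0, 1) == 123.0
        with pytest.raises(ValueError):
            cells_from_haploid(1.0, 0)

    @given(s_s=counts_st, s_p=st.integers(1, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_standard_recovery_oracle(self, s_s, s_p):
        assert standard_recovery(s_s, s_p) == pytest.approx(s_s / s_p, rel=1e-12)

    @given(g_s=counts_st, r=st.floats(1e-9, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_abundance_linearity(self, g_s, r):
        assert gene_abundance(2 * g_s, r) == pytest.approx(2 * gene_abundance(g_s, r), rel=1e-12)


class TestCombineRecoveries:
    def test_identical_inputs_any_method(self):
        recs = [StandardRecovery(f"s{i}", 100.0, 100, 100.0) for i in range(3)]
        for method in ("geometric", "arithmetic", "pooled"):
            assert combine_recoveries(recs, method) == pytest.approx(0.01)

    def test_geometric_closed_form(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RecoveryWarning)  # dispersion 4 > 2
            assert combine_recoveries([0.01, 0.04], "geometric") == pytest.approx(0.02)

    @given(rs=st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=5))
    @settings(max_examples=200, deadline=None)
    def test_geometric_log_mean_oracle(self, rs):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RecoveryWarning)
            got = combine_recoveries(rs, "geometric")
        assert got == pytest.approx(float(np.exp(np.mean(np.log(rs)))), rel=1e-12)

    def test_combined_within_min_max(self):
        rs = [0.01, 0.03, 0.08]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RecoveryWarning)
            for method in ("geometric", "arithmetic"):
                r = combine_recoveries(rs, method)
                assert min(rs) <= r <= max(rs)

    def test_pooled_formula(self):
        recs = [
            StandardRecovery("a", 500.0, 100, 2e5),
            StandardRecovery("b", 300.0, 50, 1e5),
        ]
        expected = (500 + 300) / (100 * 2e5 + 50 * 1e5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RecoveryWarning)
            assert combine_recoveries(recs, "pooled") == pytest.approx(expected, rel=1e-12)

    def test_dispersion_warning(self):
        with pytest.warns(RecoveryWarning, match="dispersion"):
            combine_recoveries([0.01, 0.05], "geometric")

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero or missing"):
            combine_recoveries([0.0, 0.0], "geometric")

    def test_zero_ratio_dropped_with_warning(self):
        with pytest.warns(RecoveryWarning, match="dropping"):
            assert combine_recoveries([0.0, 0.04], "geometric") == pytest.approx(0.04)


def _toy_tables():
    counts = pd.DataFrame(
        [
            {"sample_id": "s1", "reference_class": "standard_gene", "reference_id": "stdA", "taxon_id": "", "count": 400},
            {"sample_id": "s1", "reference_class": "standard_gene", "reference_id": "stdB", "taxon_id": "", "count": 200},
            {"sample_id": "s1", "reference_class": "recA", "reference_id": "recA|t1", "taxon_id": "t1", "count": 100},
            {"sample_id": "s1", "reference_class": "psbO", "reference_id": "psbO|t2", "taxon_id": "t2", "count": 0},
        ]
    )
    samples = pd.DataFrame([{"sample_id": "s1", "volume_liters": 2.0}])
    standards = pd.DataFrame(
        [
            {"sample_id": "s1", "standard_id": "stdA", "s_p": 100, "s_a": 2e5},
            {"sample_id": "s1", "standard_id": "stdB", "s_p": 100, "s_a": 1e5},
        ]
    )
    return counts, samples, standards


class TestTablePipeline:
    def test_recovery_and_abundance(self):
        counts, samples, standards = _toy_tables()
        rec, abund = quantify_samples(counts, samples, standards, method="geometric")
        # R_a = (400/100)/2e5 = 2e-5 ; R_b = (200/100)/1e5 = 2e-5
        assert rec["r_combined"].iloc[0] == pytest.approx(2e-5)
        row = abund[abund["taxon_id"] == "t1"].iloc[0]
        assert row["g_a"] == pytest.approx(100 / 2e-5)
        assert row["haploid_equivalents_per_liter"] == pytest.approx(100 / 2e-5 / 2.0)
        assert row["detection_limit_per_liter"] == pytest.approx(1 / (2e-5 * 2.0))

    def test_zero_count_reports_zero_and_detection_limit(self):
        counts, samples, standards = _toy_tables()
        _, abund = quantify_samples(counts, samples, standards)
        row = abund[abund["taxon_id"] == "t2"].iloc[0]
        assert row["haploid_equivalents_per_liter"] == 0.0
        assert row["detection_limit_per_liter"] > 0

    def test_ploidy_adjustment(self):
        counts, samples, standards = _toy_tables()
        _, abund = quantify_samples(counts, samples, standards, ploidy={"t1": 2})
        row = abund[abund["taxon_id"] == "t1"].iloc[0]
        assert row["cells_per_liter"] == pytest.approx(row["haploid_equivalents_per_liter"] / 2)

    def test_high_recovery_aborts_sample(self):
        counts, samples, standards = _toy_tables()
        counts.loc[counts["reference_class"] == "standard_gene", "count"] = 1e9
        with pytest.warns(RecoveryWarning):
            with pytest.raises(SampleAbortedError):
                quantify_samples(counts, samples, standards)

    def test_missing_standard_metadata_rejected(self):
        counts, samples, _ = _toy_tables()
        with pytest.raises(ValueError, match="no standard metadata"):
            estimate_recovery(counts, pd.DataFrame(columns=["sample_id"]), "s1")

    def test_equation_chain_single_expression_oracle(self):
        """G_s -> per-liter output equals G_s*S_p*S_a/(S_s*volume)."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            s_s, s_p, s_a = rng.uniform(10, 1e5), rng.integers(1, 500), rng.uniform(1e3, 1e9)
            g_s, vol = rng.uniform(0, 1e5), rng.uniform(0.1, 10)
            r = recovery_ratio(standard_recovery(s_s, int(s_p)), s_a)
            got = volumetric_abundance(gene_abundance(g_s, r), vol)
            want = g_s * s_p * s_a / (s_s * vol)
            assert got == pytest.approx(want, rel=1e-12)


class TestScaleInvariance:
    def test_common_scaling_tracks_truth(self):
        """Scaling all s_a and all true abundances by c leaves the estimate/
        truth relationship unchanged: with counts fixed (expected counts are
        invariant under the joint scaling), estimates scale by exactly c,
        mirroring the scaled truth."""
        counts, samples, standards = _toy_tables()
        _, base = quantify_samples(counts, samples, standards)
        c = 7.3
        scaled_standards = standards.assign(s_a=standards["s_a"] * c)
        _, scaled = quantify_samples(counts, samples, scaled_standards)
        np.testing.assert_allclose(
            scaled["haploid_equivalents_per_liter"],
            base["haploid_equivalents_per_liter"] * c,
            rtol=1e-12,
        )

    def test_composition_invariant_to_recovery_and_volume(self):
        counts, samples, standards = _toy_tables()
        counts.loc[counts["reference_id"] == "psbO|t2", "count"] = 40
        _, abund = quantify_samples(counts, samples, standards)
        rel_est = abund["haploid_equivalents_per_liter"] / abund["haploid_equivalents_per_liter"].sum()
        rel_counts = abund["g_s"] / abund["g_s"].sum()
        np.testing.assert_allclose(rel_est, rel_counts, rtol=1e-12)


class TestParameterRecoverySmall:
    def test_ten_percent_accuracy_at_fifty_reads(self):
        """Well-covered taxa recover truth within 10% on a small simulation."""
        cfg = synthetic.default_config(n_samples=2, n_reads=400_000, seed=2, abundance_range=[1e8, 1e9])
        tr = synthetic.build_transect(cfg)
        rng = np.random.default_rng(0)
        counts = pd.concat(
            [
                synthetic.simulate_counts(truth, stds, sample, rng=rng)
                for sample, truth, stds in zip(tr.samples, tr.truths, tr.standards_by_sample)
            ],
            ignore_index=True,
        )
        _, abund = quantify_samples(counts, tr.sample_table(), tr.standard_table())
        exp = {}
        for sample, truth, stds in zip(tr.samples, tr.truths, tr.standards_by_sample):
            e = synthetic.expected_counts(truth, stds, sample)
            for row in e.itertuples():
                exp[(row.sample_id, row.reference_id)] = row.count
        merged = abund.merge(tr.truth_table(), on=["sample_id", "taxon_id"])
        ok = total = 0
        for row in merged.itertuples():
            # 500+ expected reads: counting noise CV <= ~4.5%, so the 10%
            # band holds with high probability
            if exp[(row.sample_id, f"{row.marker_name}|{row.taxon_id}")] < 500:
                continue
            total += 1
            err = abs(row.haploid_equivalents_per_liter - row.true_haploid_equivalents_per_liter)
            ok += err / row.true_haploid_equivalents_per_liter <= 0.10
        assert total >= 10
        assert ok / total >= 0.95
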