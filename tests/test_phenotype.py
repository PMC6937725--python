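"""Immunophenotyping: gMFI, the PBMC-normalization formula, positive and
co-expression fractions, and phenotype-table assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stromaflow import CohortConfig, PanelSpec, double_positive_fraction, \
    fraction_positive, geometric_mfi, normalized_expression, simulate_cohort
from stromaflow.gating import GateThreshold
from stromaflow.phenotype import build_phenotype_table
from stromaflow.pipeline import gate_cohort

finite_pos = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


class TestGeometricMfi:
    def test_log_symmetric_triple(self):
        assert geometric_mfi(np.array([1.0, 10.0, 100.0])) == pytest.approx(10.0)

    def test_constant(self):
        assert geometric_mfi(np.array([5.0, 5.0, 5.0])) == pytest.approx(5.0)

    def test_lognormal_recovers_location(self, rng):
        x = np.exp(np.log(100) + 0.5 * rng.standard_normal(10_000))
        assert geometric_mfi(x) == pytest.approx(100.0, rel=0.03)

    def test_nonpositive_excluded(self, caplog):
        assert geometric_mfi(np.array([-1.0, 10.0, 10.0])) == pytest.approx(10.0)

    def test_all_nonpositive_is_error(self):
        with pytest.raises(ValueError):
            geometric_mfi(np.array([-1.0, 0.0]))
        with pytest.raises(ValueError):
            geometric_mfi(np.array([]))

    @settings(deadline=None, max_examples=200)
    @given(st.lists(finite_pos, min_size=1, max_size=50))
    def test_never_exceeds_arithmetic_mean(self, values):
        x = np.array(values)
        assert geometric_mfi(x) <= np.mean(x) * (1 + 1e-9)


class TestNormalizedExpression:
    @pytest.mark.parametrize("triple,expected", [
        ((1100, 100, 500), 2.0),
        ((100, 100, 500), 0.0),
        ((50, 100, 500), -0.1),
    ])
    def test_formula(self, triple, expected):
        assert normalized_expression(*triple) == pytest.approx(expected)

    def test_nonpositive_reference_is_error(self):
        with pytest.raises(ValueError):
            normalized_expression(1.0, 1.0, 0.0)

    @settings(deadline=None, max_examples=200)
    @given(finite_pos, finite_pos, finite_pos,
           st.floats(min_value=0.01, max_value=100))
    def test_scale_equivariance(self, s, f, p, c):
        """Scaling sample+FMO by c scales the numerator by c; scaling the
        PBMC reference too restores invariance."""
        base = normalized_expression(s, f, p)
        scaled_num = normalized_expression(c * s, c * f, p)
        assert scaled_num == pytest.approx(c * base, rel=1e-9, abs=1e-12)
        assert normalized_expression(c * s, c * f, c * p) == \
            pytest.approx(base, rel=1e-9, abs=1e-12)


class TestFractions:
    def test_all_below_cutoff(self):
        thr = GateThreshold("x", cutoff=10.0, method="fmo_percentile")
        assert fraction_positive(np.array([1.0, 2.0]), thr) == 0.0

    def test_half_positive(self):
        thr = GateThreshold("x", cutoff=2.5, method="fmo_percentile")
        assert fraction_positive(np.array([1.0, 2, 3, 4]), thr) == 0.5

    def test_empty_population_is_error(self):
        thr = GateThreshold("x", cutoff=1.0, method="fmo_percentile")
        with pytest.raises(ValueError):
            fraction_positive(np.array([]), thr)

    def test_pd1_high_fraction_recovers_mixture_weight(self):
        cfg = CohortConfig(n_patients=4, n_events_per_sample=4000, seed=31,
                           pd1_high_cd8_weight=0.30, pd1_weight_logit_sd=0.0,
                           pd1_high_cd8_shift=0.0)
        cohort = simulate_cohort(cfg)
        labels_map = gate_cohort(cohort, PanelSpec())
        for sample, truth in zip(cohort.samples, cohort.truths):
            labels = labels_map[sample.sample_id]
            mask = labels.masks["t_cd8"]
            if mask.sum() < 100:
                continue
            frac = fraction_positive(sample.intensities("PD-1")[mask],
                                     labels.pd1_high_threshold)
            w = truth.pd1_high_weights["t_cd8"]
            se = np.sqrt(w * (1 - w) / mask.sum())
            assert frac == pytest.approx(w, abs=4 * se + 0.02)


class TestPhenotypeTable:
    def test_bookkeeping_and_determinism(self, gated_cohort):
        cohort, labels_map = gated_cohort
        t1 = build_phenotype_table(cohort.samples, cohort.fmos, labels_map,
                                   cohort.reference, cohort.reference_fmos)
        t2 = build_phenotype_table(cohort.samples, cohort.fmos, labels_map,
                                   cohort.reference, cohort.reference_fmos)
        pd.testing.assert_frame_equal(t1, t2)
        # one row per sample per defined statistic; flagged rows carry NaN
        per_sample = t1.groupby("sample_id").size().unique()
        assert len(per_sample) == 1
        assert (t1.loc[t1["flag"] != "", "value"].isna()).all()
        fracs = t1[t1["statistic"].isin(
            ["frequency_of_cd45pos", "frequency_of_t", "pd1_high_fraction",
             "positive_fraction", "double_positive_fraction"])]
        ok = fracs["value"].dropna()
        assert ((ok >= 0) & (ok <= 1)).all()

    def test_exclusive_subset_frequencies_sum_below_one(self, gated_cohort):
        cohort, labels_map = gated_cohort
        t = build_phenotype_table(cohort.samples, cohort.fmos, labels_map,
                                  cohort.reference, cohort.reference_fmos)
        freq = t[t["statistic"] == "frequency_of_cd45pos"]
        sums = freq.groupby("sample_id")["value"].sum()
        assert (sums <= 1.0 + 1e-9).all()

    def test_coexpression_below_marginal(self, gated_cohort):
        """PD-1-high ∧ TIM3 co-expression cannot exceed TIM3's marginal
        positive fraction within the same T-cell subset."""
        cohort, labels_map = gated_cohort
        from stromaflow.phenotype import _positive_threshold
        for sample in cohort.samples:
            labels = labels_map[sample.sample_id]
            thr = _positive_threshold(cohort.fmos[sample.sample_id], "TIM3",
                                      0.995)
            for pop in ("t_cd4", "t_cd8"):
                mask = labels.masks[pop]
                high = mask & (sample.intensities("PD-1")
                               > labels.pd1_high_threshold.cutoff)
                if high.sum() == 0 or mask.sum() == 0:
                    continue
                joint = np.mean(
                    (sample.intensities("TIM3") > thr.cutoff)[high])
                # joint count <= marginal count over the subset
                n_joint = joint * high.sum()
                n_marginal = np.sum(
                    (sample.intensities("TIM3") > thr.cutoff)[mask])
                assert n_joint <= n_marginal + 1e-9

    def test_cd16_shift_with_ts_class(self):
        cfg = CohortConfig(n_patients=16, n_events_per_sample=1200, seed=13,
                           tumor_fractions=[0.4] * 8 + [0.75] * 8)
        cohort = simulate_cohort(cfg)
        labels_map = gate_cohort(cohort, PanelSpec())
        t = build_phenotype_table(cohort.samples, cohort.fmos, labels_map,
                                  cohort.reference, cohort.reference_fmos)
        cd16 = t[(t["statistic"] == "normalized_gmfi")
                 & (t["population"] == "monocyte") & (t["flag"] == "")]
        means = cd16.groupby("ts_class")["value"].mean()
        assert means["high"] > means["low"]

    def test_missing_reference_is_error(self, gated_cohort):
        cohort, labels_map = gated_cohort
        with pytest.raises(ValueError, match="reference"):
            build_phenotype_table(cohort.samples, cohort.fmos, labels_map,
                                  None, {})


class TestDoublePositive:
    def test_cutoffs_below_all_data_give_one(self, gated_cohort):
        cohort, labels_map = gated_cohort
        sample = cohort.samples[0]
        labels = labels_map[sample.sample_id]
        lo = GateThreshold("x", cutoff=1e-12, method="fmo_percentile")
        assert double_positive_fraction(sample, labels, lo, lo) == 1.0

    def test_zero_cd45neg_flagged(self):
        cfg = CohortConfig(n_patients=1, n_events_per_sample=600,
                           cd45_pos_fraction=1.0, seed=2)
        cohort = simulate_cohort(cfg)
        sample = cohort.samples[0]
        from stromaflow import gate_populations
        labels = gate_populations(sample, cohort.fmos[sample.sample_id])
        thr = GateThreshold("x", cutoff=1.0, method="fmo_percentile")
        with pytest.raises(ValueError, match="CD45"):
            double_positive_fraction(sample, labels, thr, thr)
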