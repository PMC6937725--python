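"""Gating: FMO percentile thresholds, the bimodal mixture split (with an
sklearn cross-check), the population hierarchy, and T:S estimation."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from stromaflow import CohortConfig, PanelSpec, classify_ts, estimate_ts, \
    fmo_threshold, gate_populations, simulate_cohort, split_bimodal
from stromaflow.gating import CompartmentEstimate, fit_gaussian_mixture_1d
from stromaflow.pipeline import gate_cohort


class TestFmoThreshold:
    def test_constant_vector(self):
        thr = fmo_threshold(np.full(100, 100.0))
        assert thr.cutoff == pytest.approx(100.0)

    def test_uniform_quantile(self, rng):
        thr = fmo_threshold(rng.uniform(0, 1, 10_000), percentile=0.995)
        assert thr.cutoff == pytest.approx(0.995, abs=0.01)

    def test_linear_interpolation_rule(self):
        # empirical 0.9 quantile of 1..1000 under linear interpolation:
        # 1 + 0.9 * 999 = 900.1
        thr = fmo_threshold(np.arange(1.0, 1001.0), percentile=0.9)
        assert thr.cutoff == pytest.approx(900.1)

    def test_contracts(self, rng):
        with pytest.raises(ValueError, match="50"):
            fmo_threshold(np.ones(10))
        with pytest.raises(ValueError, match="finite"):
            fmo_threshold(np.r_[np.ones(60), np.nan])
        with pytest.raises(ValueError):
            fmo_threshold(np.ones(60), percentile=1.5)


class TestSplitBimodal:
    def test_symmetric_equal_mixture_cuts_at_midpoint(self, rng):
        x = np.r_[rng.normal(2, 0.1, 5000), rng.normal(4, 0.1, 5000)]
        thr = split_bimodal(x)
        assert thr.diagnostics["bimodality_ok"]
        assert np.log(thr.cutoff) == pytest.approx(3.0, abs=0.05)

    def test_unimodal_flagged(self, rng):
        thr = split_bimodal(rng.normal(3, 0.5, 2000))
        assert not thr.diagnostics["bimodality_ok"]
        assert not thr.usable

    def test_unimodal_falls_back_to_fmo(self, rng):
        fmo = np.exp(rng.normal(2, 0.4, 2000))
        thr = split_bimodal(rng.normal(3, 0.5, 2000), fmo_values=fmo,
                            fmo_percentile=0.995)
        assert thr.method == "fmo_percentile"
        assert thr.usable

    def test_unequal_weights_shift_cutoff_toward_minor_mode(self, rng):
        # oracle: solve w1 N(x|2,.1) = w2 N(x|5,.1) between the means
        w1, w2, m1, m2, s = 0.9, 0.1, 2.0, 5.0, 0.1

        def f(x):
            return (np.log(w1) + norm.logpdf(x, m1, s)
                    - np.log(w2) - norm.logpdf(x, m2, s))

        expected = brentq(f, m1, m2)
        assert expected > (m1 + m2) / 2     # toward the minor mode

        x = np.r_[rng.normal(m1, s, 18000), rng.normal(m2, s, 2000)]
        thr = split_bimodal(x)
        assert np.log(thr.cutoff) == pytest.approx(expected, abs=0.05)

    def test_matches_sklearn_mixture(self, rng):
        """Cross-check the hand-rolled EM against sklearn's GaussianMixture."""
        from sklearn.mixture import GaussianMixture
        x = np.r_[rng.normal(1.5, 0.3, 1500), rng.normal(4.0, 0.5, 1000)]
        fit = fit_gaussian_mixture_1d(x)
        gm = GaussianMixture(n_components=2, n_init=5, random_state=0,
                             tol=1e-6).fit(x[:, None])
        order = np.argsort(gm.means_.ravel())
        np.testing.assert_allclose(fit["means"],
                                   gm.means_.ravel()[order], atol=0.02)
        np.testing.assert_allclose(fit["weights"],
                                   gm.weights_[order], atol=0.01)

    def test_contracts(self, rng):
        with pytest.raises(ValueError, match="100"):
            split_bimodal(np.ones(50))
        with pytest.raises(ValueError, match="finite"):
            split_bimodal(np.r_[rng.normal(size=200), np.inf])


class TestGateTree:
    def test_compartment_recovery_with_wide_separation(self):
        cfg = CohortConfig(n_patients=2, n_events_per_sample=1000,
                           cd45_pos_fraction=0.0, composition="deterministic",
                           caf_fraction_of_stroma=0.0,
                           tumor_fractions=[0.6, 0.6], seed=21)
        cohort = simulate_cohort(cfg)
        for sample, truth in zip(cohort.samples, cohort.truths):
            labels = gate_populations(sample, cohort.fmos[sample.sample_id])
            pred = labels.labels.to_numpy()
            keep = sample.keep_mask
            truth_compartment = np.where(truth.labels == "tumor",
                                         "tumor", "stroma")
            agree = (pred[keep] == truth_compartment[keep]).mean()
            assert agree >= 0.98

    def test_no_immune_events_gives_empty_subsets(self):
        cfg = CohortConfig(n_patients=1, n_events_per_sample=1000,
                           cd45_pos_fraction=0.0, seed=3)
        cohort = simulate_cohort(cfg)
        sample = cohort.samples[0]
        labels = gate_populations(sample, cohort.fmos[sample.sample_id])
        for pop in ("t_cd4", "t_cd8", "b_cell", "monocyte", "apc"):
            assert labels.count(pop) == 0

    def test_fmo_identical_channel_positive_fraction(self, gated_cohort):
        """A channel with no signal above background gates at ~1-percentile."""
        cohort, _ = gated_cohort
        sample = cohort.samples[0]
        fmo = cohort.fmos[sample.sample_id]["CD3"]
        thr = fmo_threshold(fmo.intensities("CD3")[fmo.keep_mask],
                            percentile=0.995)
        # the FMO's own values, gated on themselves
        frac = np.mean(fmo.intensities("CD3")[fmo.keep_mask] > thr.cutoff)
        assert frac == pytest.approx(0.005, abs=0.004)

    def test_missing_channel_error_names_channel(self, small_cohort):
        sample = small_cohort.samples[0]
        broken = PanelSpec(cd45="CD45-MISSING")
        with pytest.raises(KeyError, match="CD45-MISSING"):
            gate_populations(sample, small_cohort.fmos[sample.sample_id],
                             broken)

    def test_b7h3_cutoff_monotonicity(self, gated_cohort):
        """Raising the B7-H3 cutoff never decreases the tumor count."""
        cohort, labels_map = gated_cohort
        sample = cohort.samples[0]
        labels = labels_map[sample.sample_id]
        cd45n = labels.masks["cd45_neg"]
        b7h3 = sample.intensities("B7-H3")[cd45n]
        base_cut = labels.thresholds["B7-H3"].cutoff
        counts = [(b7h3 < c).sum()
                  for c in np.linspace(base_cut * 0.5, base_cut * 2.0, 9)]
        assert all(c1 <= c2 for c1, c2 in zip(counts, counts[1:]))

    def test_compartments_partition_cd45neg(self, gated_cohort):
        _, labels_map = gated_cohort
        for labels in labels_map.values():
            n = labels.count("tumor") + labels.count("stroma")
            assert n == labels.masks["cd45_neg"].sum()


class TestTsEstimate:
    def test_arithmetic(self):
        est = CompartmentEstimate(n_tumor=60, n_stroma=40, bimodality_ok=True)
        assert est.ts_ratio == pytest.approx(1.5)
        assert est.tumor_fraction == pytest.approx(0.6)
        assert est.ts_ratio == pytest.approx(
            est.tumor_fraction / (1 - est.tumor_fraction))

    def test_zero_tumor(self):
        est = CompartmentEstimate(n_tumor=0, n_stroma=100, bimodality_ok=True)
        assert est.ts_ratio == 0.0
        assert est.tumor_fraction == 0.0

    def test_zero_stroma_flags_infinite_ratio(self):
        est = CompartmentEstimate(n_tumor=100, n_stroma=0, bimodality_ok=True)
        assert est.ts_ratio == np.inf

    def test_zero_cd45neg_is_error(self):
        cfg = CohortConfig(n_patients=1, n_events_per_sample=600,
                           cd45_pos_fraction=1.0, seed=2)
        cohort = simulate_cohort(cfg)
        sample = cohort.samples[0]
        labels = gate_populations(sample, cohort.fmos[sample.sample_id])
        with pytest.raises(ValueError, match="CD45"):
            estimate_ts(labels)

    @pytest.mark.parametrize("ratio,expected", [
        (1.49, "low"), (1.51, "high"), (1.50, "high"), (0.0, "low"),
        (np.inf, "high"),
    ])
    def test_classification_boundary(self, ratio, expected):
        if np.isinf(ratio):
            est = CompartmentEstimate(n_tumor=10, n_stroma=0,
                                      bimodality_ok=True)
        else:
            est = CompartmentEstimate(n_tumor=int(round(ratio * 100)),
                                      n_stroma=100, bimodality_ok=True)
        assert classify_ts(est) == expected

    def test_small_recovery_panel(self):
        cfg = CohortConfig(n_patients=8, n_events_per_sample=1500,
                           cd45_pos_fraction=1 / 3,
                           tumor_fractions=list(np.linspace(0.2, 0.8, 8)),
                           seed=17)
        cohort = simulate_cohort(cfg)
        labels_map = gate_cohort(cohort, PanelSpec())
        est = np.array([estimate_ts(labels_map[t.sample_id]).tumor_fraction
                        for t in cohort.truths])
        true = np.array([t.true_tumor_fraction for t in cohort.truths])
        assert np.corrcoef(true, est)[0, 1] > 0.95
        assert np.max(np.abs(true - est)) < 0.05
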