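"""Synthetic experiment generators: determinism, oracle agreement, recovery."""

import numpy as np
import pytest

from gutflow import (
    CATEGORY_ABRUPT,
    CompartmentChain,
    ValidationError,
    analyze_samples,
    egestion_time_cdf,
    egestion_time_variance,
    fraction_cv_increasing,
    generate_egestion_experiment,
    generate_fate_experiment,
    parameter_recovery_suite,
)
from gutflow.egestion import bin_times, egestion_distribution, stats_from_distribution
from gutflow.fate import partition_table
from gutflow.synth import (
    DEFAULT_BASE_M,
    ExperimentDesign,
    abrupt_chain,
    calibrate_fate_rates,
    default_design,
    design_inoculum,
    expected_fate_partition,
    gradual_chain,
)


class TestDesignValidation:
    def test_growth_chains_rejected(self):
        chain = CompartmentChain([1.0], [0.5])
        with pytest.raises(ValidationError):
            ExperimentDesign(treatments={"T": chain})

    def test_detection_fraction_bounds(self):
        chain = CompartmentChain([1.0], [0.0])
        with pytest.raises(ValidationError):
            ExperimentDesign(treatments={"T": chain}, detection_fraction=0.0)
        with pytest.raises(ValidationError):
            ExperimentDesign(treatments={"T": chain}, detection_fraction=1.5)

    def test_chain_constructors_hit_targets(self):
        from gutflow import proportion_egested

        for p in (0.2, 0.5, 0.9):
            assert proportion_egested(abrupt_chain(DEFAULT_BASE_M, p)) == pytest.approx(p)
            assert proportion_egested(gradual_chain(DEFAULT_BASE_M, p)) == pytest.approx(p)


def small_design(seed=0, **kw):
    defaults = dict(
        treatments={"LA": abrupt_chain(DEFAULT_BASE_M, 0.25)},
        n_replicate_days=2,
        vials_per_day=1,
        mean_ingested_bacteria=500.0,
        mean_ingested_spheres=500.0,
        detection_fraction=0.05,
        seed=seed,
    )
    defaults.update(kw)
    return ExperimentDesign(**defaults)


class TestEgestionGenerator:
    def test_regeneration_is_byte_identical(self, tmp_path):
        from gutflow.io import write_ground_truth, write_samples

        for i, out in enumerate(["a", "b"]):
            samples, truth = generate_egestion_experiment(small_design(seed=9))
            write_samples(samples, tmp_path / f"{out}.csv")
            write_ground_truth(truth, tmp_path / f"{out}.yaml")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
        assert (tmp_path / "a.yaml").read_bytes() == (tmp_path / "b.yaml").read_bytes()

    def test_ground_truth_accompanies_data(self):
        samples, truth = generate_egestion_experiment(small_design())
        assert set(truth["treatments"]) == {"LA"}
        rec = truth["treatments"]["LA"]
        for key in ("proportion_egested", "mean_h", "variance_h2", "m", "r"):
            assert key in rec
        assert len(samples) == 2  # days x vials

    def test_sphere_bins_match_phase_type_integrals(self):
        """With full detection, hourly microsphere proportions converge to
        the phase-type CDF increments (conditional on 5-h egestion)."""
        chain = CompartmentChain(DEFAULT_BASE_M, (0.0,) * 5)
        design = ExperimentDesign(
            treatments={"S": chain},
            n_replicate_days=1,
            vials_per_day=1,
            mean_ingested_bacteria=10.0,
            mean_ingested_spheres=8000.0,
            detection_fraction=1.0,
            seed=5,
        )
        samples, _ = generate_egestion_experiment(design)
        observed = egestion_distribution(samples[0], "spheres")
        cdf = egestion_time_cdf(chain, np.arange(0.0, 6.0))
        expected = np.diff(cdf) / cdf[-1]
        n = sum(samples[0].sphere_counts)
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(observed - expected) < 4 * se + 1e-9)

    def test_identical_chains_recover_unit_proportion(self):
        chain = abrupt_chain(DEFAULT_BASE_M, 1.0)  # r = 0 everywhere
        design = small_design(
            treatments={"CTRL": chain},
            mean_ingested_bacteria=5000.0,
            mean_ingested_spheres=5000.0,
            n_replicate_days=3,
            seed=2,
        )
        samples, _ = generate_egestion_experiment(design)
        per_sample, _ = analyze_samples(samples, design_inoculum(design))
        assert per_sample["proportion_egested"].mean() == pytest.approx(1.0, abs=0.05)

    def test_abrupt_loss_signature(self):
        """Loss confined to the fast compartment: recovered proportion near
        the design value, normalized mean near 1."""
        design = small_design(
            n_replicate_days=3,
            vials_per_day=2,
            mean_ingested_bacteria=4000.0,
            mean_ingested_spheres=4000.0,
            detection_fraction=0.05,
            seed=21,
        )
        samples, truth = generate_egestion_experiment(design)
        per_sample, results = analyze_samples(samples, design_inoculum(design))
        true_p = truth["treatments"]["LA"]["proportion_egested"]
        assert per_sample["proportion_egested"].mean() == pytest.approx(true_p, rel=0.15)
        assert per_sample["mu_norm"].mean() == pytest.approx(1.0, abs=0.05)
        res = results[0]
        assert res.prop_below_1 and not res.stats_reduced
        assert res.category == CATEGORY_ABRUPT

    def test_gradual_loss_signature(self):
        design = small_design(
            treatments={"HA": gradual_chain(DEFAULT_BASE_M, 0.4)},
            n_replicate_days=3,
            vials_per_day=2,
            mean_ingested_bacteria=4000.0,
            mean_ingested_spheres=4000.0,
            seed=22,
        )
        samples, _ = generate_egestion_experiment(design)
        per_sample, _ = analyze_samples(samples, design_inoculum(design))
        assert per_sample["mu_norm"].mean() < 1.0
        assert per_sample["sigma2_norm"].mean() < 1.0

    def test_binned_variance_within_discretization_bound(self):
        """Hourly binning (midpoint convention) perturbs the recovered
        variance by at most the single-bin bound (width²/4) plus noise."""
        chain = CompartmentChain(DEFAULT_BASE_M, (0.0,) * 5)
        design = ExperimentDesign(
            treatments={"S": chain},
            n_replicate_days=1,
            vials_per_day=1,
            mean_ingested_bacteria=10.0,
            mean_ingested_spheres=20000.0,
            detection_fraction=1.0,
            seed=6,
        )
        samples, _ = generate_egestion_experiment(design)
        p = egestion_distribution(samples[0], "spheres")
        stats = stats_from_distribution(p, bin_times("midpoint"))
        true_var = egestion_time_variance(chain)
        assert abs(stats.variance - true_var) <= 0.25 + 0.1


def fate_design(seed=0, **kw):
    rates = calibrate_fate_rates(DEFAULT_BASE_M, 0.35, 0.10)
    defaults = dict(
        treatments={"LA": abrupt_chain(DEFAULT_BASE_M, 0.25)},
        fate_rates={"axenic": rates},
        n_replicate_days=3,
        vials_per_day=2,
        mean_ingested_bacteria=1000.0,
        seed=seed,
    )
    defaults.update(kw)
    return ExperimentDesign(**defaults)


class TestFateGenerator:
    def test_calibration_hits_targets_exactly(self):
        rates = calibrate_fate_rates(DEFAULT_BASE_M, 0.35, 0.10)
        eg, ret, lys = expected_fate_partition(rates, horizon=5.0)
        assert eg == pytest.approx(0.35, abs=1e-6)
        assert ret == pytest.approx(0.10, abs=1e-6)
        assert lys == pytest.approx(0.55, abs=1e-6)

    def test_no_loss_everything_egested(self):
        from gutflow.synth import FateRates

        design = fate_design(
            fate_rates={"axenic": FateRates(DEFAULT_BASE_M, (0.0,) * 5, 0.0)},
            n_replicate_days=1,
            vials_per_day=1,
        )
        vials, flies = generate_fate_experiment(design, heterogeneity_sd=0.0)
        v = vials[0]
        # nothing lysed or retained; only late in-transit cells missing
        assert v.retained_cfu / v.ingested < 0.02
        assert v.egested / v.ingested > 0.98

    def test_designed_partition_recovered(self):
        design = fate_design(seed=4)
        vials, _ = generate_fate_experiment(design, heterogeneity_sd=0.0)
        parts = partition_table(vials)
        for frac, target in (("egested", 0.35), ("retained", 0.10), ("lysed", 0.55)):
            vals = parts[frac].to_numpy()
            sem = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - target) < 4 * sem + 0.01, frac

    def test_heterogeneity_broadens_retention_over_time(self):
        frac = fraction_cv_increasing(
            fate_design(mean_ingested_bacteria=500.0, vials_per_day=1),
            heterogeneity_sd=1.0,
            n_runs=10,
            seed=30,
        )
        assert frac >= 0.9

    def test_missing_fate_rates_rejected(self):
        design = small_design()
        with pytest.raises(ValidationError):
            generate_fate_experiment(design, heterogeneity_sd=1.0)


class TestRecoverySuite:
    def test_report_structure_and_sanity(self):
        report = parameter_recovery_suite(4, seed=11)
        assert len(report) == 4
        assert set(report["kind"]) == {"abrupt", "gradual"}
        assert np.isfinite(report["rel_error"]).all()
        assert (report["rel_error"] < 0.5).all()

    def test_default_design_roundtrip(self):
        design = default_design(seed=1)
        samples, truth = generate_egestion_experiment(design)
        assert len(samples) == 4 * design.n_replicate_days * design.vials_per_day
        assert set(truth["treatments"]) == {"LA", "LG", "HA", "HG"}
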