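"""Particle-level transit simulation: determinism, conservation, oracles."""

import numpy as np
import pytest

from gutflow import (
    CompartmentChain,
    DemographicRates,
    DegenerateDataError,
    ParticleCapError,
    ValidationError,
    absorbing_chain_moments,
    egestion_time_mean,
    egestion_time_variance,
    empirical_moments,
    proportion_egested,
    simulate_particles,
    sweep_bidirectional,
)

from conftest import random_chain


def death_only(m, d, m_back=None):
    return DemographicRates(b=(0.0,) * len(m), d=tuple(d), m=tuple(m), m_back=m_back)


def test_seed_determinism():
    rates = death_only([1.0, 0.8], [0.3, 0.0])
    a = simulate_particles(rates, 500, seed=42)
    b = simulate_particles(rates, 500, seed=42)
    assert a == b
    c = simulate_particles(rates, 500, seed=43)
    assert a != c


def test_no_loss_all_egested():
    rates = death_only([1.0], [0.0])
    records = simulate_particles(rates, 300, seed=0)
    assert all(rec.fate == "egested" for rec in records)
    assert all(rec.egestion_time > 0 for rec in records)


def test_conservation_without_branching():
    rates = death_only([1.0, 0.5], [0.7, 0.2])
    records = simulate_particles(rates, 2000, seed=7)
    n_eg = sum(rec.fate == "egested" for rec in records)
    n_lost = sum(rec.fate == "lost" for rec in records)
    assert n_eg + n_lost == 2000


def test_equal_death_and_transit_halves_survival():
    rates = death_only([1.0], [1.0])
    records = simulate_particles(rates, 100_000, seed=3)
    frac = sum(r.fate == "egested" for r in records) / len(records)
    se = np.sqrt(0.25 / 100_000)
    assert abs(frac - 0.5) < 4 * se


@pytest.mark.parametrize("seed", [11, 12, 13])
def test_oracle_agreement_random_chain(seed):
    """Monte Carlo moments agree with the closed forms within 4 SE."""
    rng = np.random.default_rng(seed)
    m, r = random_chain(rng)
    chain = CompartmentChain(m, r)
    rates = DemographicRates.from_chain(chain)
    n = 20_000
    records = simulate_particles(rates, n, seed=seed + 1000)
    stats, frac = empirical_moments(records)
    p = proportion_egested(chain)
    k = sum(rec.fate == "egested" for rec in records)
    assert abs(frac - p) < 4 * np.sqrt(p * (1 - p) / n) + 1e-12
    mean = egestion_time_mean(chain)
    var = egestion_time_variance(chain)
    assert abs(stats.mean - mean) < 4 * np.sqrt(var / k)
    times = np.array(
        [rec.egestion_time for rec in records if rec.fate == "egested"]
    )
    m4 = np.mean((times - times.mean()) ** 4)
    se_var = np.sqrt(max(m4 - stats.variance**2, 0.0) / k)
    assert abs(stats.variance - var) < 4 * se_var


@pytest.mark.parametrize("seed", [21, 22])
def test_ode_moment_cross_check_unidirectional(seed):
    """The absorbing-chain (deterministic first-moment) solution reproduces
    the closed forms exactly for unidirectional chains."""
    rng = np.random.default_rng(seed)
    m, r = random_chain(rng)
    chain = CompartmentChain(m, r)
    p, mean, var = absorbing_chain_moments(DemographicRates.from_chain(chain))
    assert p == pytest.approx(proportion_egested(chain), rel=1e-10)
    assert mean == pytest.approx(egestion_time_mean(chain), rel=1e-10)
    assert var == pytest.approx(egestion_time_variance(chain), rel=1e-10)


def test_adding_death_never_increases_statistics():
    rng = np.random.default_rng(5)
    for _ in range(20):
        m, r = random_chain(rng)
        rates = DemographicRates.from_chain(CompartmentChain(m, r))
        i = int(rng.integers(0, len(m)))
        d2 = list(rates.d)
        d2[i] += float(rng.uniform(0.1, 1.0))
        worse = DemographicRates(b=rates.b, d=tuple(d2), m=rates.m)
        p0, mu0, v0 = absorbing_chain_moments(rates)
        p1, mu1, v1 = absorbing_chain_moments(worse)
        assert p1 < p0
        assert mu1 < mu0
        assert v1 < v0


def test_mean_variance_positive_correlation_and_cv_bound():
    rng = np.random.default_rng(99)
    means, variances = [], []
    for i in range(30):
        m, r = random_chain(rng)
        rates = DemographicRates.from_chain(CompartmentChain(m, r))
        records = simulate_particles(rates, 3000, seed=1000 + i)
        stats, _ = empirical_moments(records)
        means.append(stats.mean)
        variances.append(stats.variance)
        assert stats.variance <= stats.mean**2 * 1.25  # CV <= 1 + sampling slack
    assert np.corrcoef(means, variances)[0, 1] > 0


class TestEmpiricalMoments:
    def test_constant_times(self):
        recs = [("egested", 1.0)] * 3
        from gutflow.simulator import TransitRecord

        stats, frac = empirical_moments([TransitRecord(*r) for r in recs])
        assert (stats.mean, stats.variance, frac) == (1.0, 0.0, 1.0)

    def test_unbiased_variance_convention(self):
        from gutflow.simulator import TransitRecord

        recs = [TransitRecord("egested", 1.0), TransitRecord("egested", 3.0)]
        stats, frac = empirical_moments(recs)
        assert stats.mean == 2.0
        assert stats.variance == 2.0  # n-1 denominator
        assert frac == 1.0

    def test_known_law(self):
        rates = death_only([1.0], [0.0])
        records = simulate_particles(rates, 100_000, seed=8)
        stats, _ = empirical_moments(records)
        assert abs(stats.mean - 1.0) < 4 / np.sqrt(100_000)

    def test_zero_egested_signalled(self):
        from gutflow.simulator import TransitRecord

        with pytest.raises(DegenerateDataError):
            empirical_moments([TransitRecord("lost", None)] * 5)


class TestBranching:
    def test_birth_requires_branching_flag(self):
        rates = DemographicRates(b=(0.5,), d=(0.0,), m=(1.0,))
        with pytest.raises(ValidationError):
            simulate_particles(rates, 10, seed=0)

    def test_expected_egested_count_matches_growth_formula(self):
        # net growth r = +0.5 in one compartment: expected egested per
        # founder is m/(m-r) = 2
        rates = DemographicRates(b=(0.5,), d=(0.0,), m=(1.0,))
        records = simulate_particles(rates, 3000, seed=4, branching=True)
        n_eg = sum(rec.fate == "egested" for rec in records)
        stats, frac = empirical_moments(records, n_founders=3000)
        assert frac == n_eg / 3000
        assert frac == pytest.approx(2.0, abs=0.25)

    def test_particle_cap_signalled(self):
        rates = DemographicRates(b=(50.0,), d=(0.0,), m=(0.01,))
        with pytest.raises(ParticleCapError):
            simulate_particles(
                rates, 5, seed=0, branching=True, max_particles_per_founder=50
            )


def test_horizon_censoring_preserves_conservation():
    rates = death_only([0.4], [0.0])
    records = simulate_particles(rates, 2000, seed=9, horizon=2.0)
    n_eg = sum(rec.fate == "egested" for rec in records)
    assert all(
        rec.egestion_time <= 2.0 for rec in records if rec.fate == "egested"
    )
    assert n_eg + sum(rec.fate == "lost" for rec in records) == 2000
    assert 0 < n_eg < 2000


class TestSweep:
    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            sweep_bidirectional(0.25, -0.25, "r", [], 100, seed=0)

    def test_zero_backward_reduces_to_unidirectional(self):
        k = 3
        table = sweep_bidirectional(
            0.5, -0.25, "r", [-0.25], 4000, seed=17, backward=(0.0,) * k
        )
        rates = death_only([0.5] * k, [0.25] * k)
        records = simulate_particles(rates, 4000, seed=17)  # seed + grid index 0
        stats, frac = empirical_moments(records)
        row = table.iloc[0]
        assert row["egested_fraction"] == frac
        assert row["mean_h"] == pytest.approx(stats.mean)
        assert row["variance_h2"] == pytest.approx(stats.variance)

    def test_egested_fraction_increases_with_r(self):
        table = sweep_bidirectional(
            0.25, -0.25, "r", [-0.5, -0.25, 0.0], 6000, seed=5
        )
        frac = table["egested_fraction"].to_numpy()
        assert np.all(np.diff(frac) > 0)
        assert frac[-1] == 1.0  # r = 0: every particle eventually egested

    def test_mean_decreases_with_m(self):
        table = sweep_bidirectional(
            0.25, -0.25, "m", [0.25, 0.5, 1.0], 6000, seed=6
        )
        means = table["mean_h"].to_numpy()
        assert np.all(np.diff(means) < 0)

    def test_growth_rates_rejected(self):
        with pytest.raises(ValidationError):
            sweep_bidirectional(0.25, 0.1, "r", [0.1], 100, seed=0)
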