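import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photosens.germdata import FilterReason
from photosens.psmetric import (
    Direction,
    bootstrap_psm_se,
    classify_direction,
    compute_psm,
    compute_psm_table,
    psm_gradient,
    species_seed,
    write_psm_table,
)
from photosens.shrinkfit import SpeciesFit, fit_regularized_binomial_glm
from photosens.synthgen import SpeciesScenario, simulate_germination

finite = st.floats(-50, 50, allow_nan=False).filter(
    lambda x: x == 0 or abs(x) > 1e-100  # avoid squared-term underflow
)


def make_fit(mu0, beta1, beta2, cov):
    from scipy.special import expit

    return SpeciesFit(
        species="sp",
        mu0=mu0,
        beta1=beta1,
        beta2=beta2,
        covariance=np.asarray(cov, dtype=float),
        fitted_probabilities=(
            float(expit(mu0)),
            float(expit(mu0 + beta1)),
            float(expit(mu0 + beta2)),
        ),
        converged=True,
        n_iterations=1,
    )


class TestComputePsm:
    @pytest.mark.parametrize(
        "b1,b2,expected",
        [
            (0.0, 0.0, 0.0),
            (1.0, 0.0, math.sqrt(2 / 3)),
            (2.0, 2.0, math.sqrt(8 / 3)),
        ],
    )
    def test_worked_values(self, b1, b2, expected):
        assert compute_psm(b1, b2) == pytest.approx(expected, abs=1e-10)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            compute_psm(float("nan"), 0.0)
        with pytest.raises(ValueError):
            compute_psm(1.0, float("inf"))

    @settings(max_examples=200, deadline=None)
    @given(b1=finite, b2=finite)
    def test_equals_root_sum_squared_deviations_of_treatment_means(self, b1, b2):
        """The metric² is the sum of squared deviations of {0, β1, β2} about their mean."""
        means = np.array([0.0, b1, b2])
        ssd = float(np.sum((means - means.mean()) ** 2))
        assert compute_psm(b1, b2) ** 2 == pytest.approx(ssd, rel=1e-12, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(b1=finite, b2=finite)
    def test_symmetries_and_positive_definiteness(self, b1, b2):
        assert compute_psm(b1, b2) == compute_psm(b2, b1)
        assert compute_psm(-b1, -b2) == pytest.approx(compute_psm(b1, b2), rel=1e-12)
        if (b1, b2) != (0.0, 0.0):
            assert compute_psm(b1, b2) > 0


class TestBootstrapSE:
    def test_zero_covariance_gives_zero_se(self):
        fit = make_fit(0.2, 1.0, -0.5, np.zeros((3, 3)))
        se, _ = bootstrap_psm_se(fit, n_draws=100, seed=9)
        assert se == 0.0

    def test_fixed_seed_is_bit_reproducible(self):
        fit = make_fit(0.0, 1.0, 0.2, 0.05 * np.eye(3))
        se_a, _ = bootstrap_psm_se(fit, 5000, seed=7)
        se_b, _ = bootstrap_psm_se(fit, 5000, seed=7)
        assert se_a == se_b

    def test_matches_delta_method_oracle(self):
        """Small diagonal covariance: bootstrap SE ≈ |∇psm|·σ (delta method)."""
        sigma2 = 0.01
        fit = make_fit(0.0, 3.0, 0.0, sigma2 * np.eye(3))
        n_draws = 100_000
        se, _ = bootstrap_psm_se(fit, n_draws, seed=11)
        g1, g2 = psm_gradient(3.0, 0.0)
        delta_se = math.sqrt((g1**2 + g2**2) * sigma2)
        mc_se = delta_se / math.sqrt(2 * (n_draws - 1))  # SE of a sample SD
        assert abs(se - delta_se) < 3 * mc_se + 1e-4 * delta_se

    def test_hard_negative_eigenvalue_is_fatal(self):
        bad = np.diag([1.0, 1.0, -0.5])
        fit = make_fit(0.0, 1.0, 0.0, bad)
        with pytest.raises(ValueError, match="positive semi-definite"):
            bootstrap_psm_se(fit, 100, seed=0)


class TestClassifyDirection:
    def test_strong_long_day_response(self):
        cov = np.diag([0.1, 0.25, 0.25])  # z1 = 2/0.5 = 4, z2 = 0
        fit = make_fit(0.0, 2.0, 0.0, cov)
        classification, significant, sign = classify_direction(fit)
        assert classification is Direction.LONG_DAY
        assert significant and sign == 1

    def test_no_rejection_is_insensitive(self):
        cov = np.diag([1.0, 1.0, 1.0])  # all |z| < 1.96
        fit = make_fit(0.0, 1.0, -1.0, cov)
        classification, significant, _ = classify_direction(fit)
        assert classification is Direction.INSENSITIVE
        assert not significant

    def test_intermediate_peak_with_tied_extremes(self):
        cov = np.diag([0.1, 0.25, 0.25])  # z1 = z2 = -3, beta1-beta2 = 0
        fit = make_fit(0.0, -1.5, -1.5, cov)
        classification, significant, sign = classify_direction(fit)
        assert classification is Direction.INTERMEDIATE
        assert significant
        assert sign == 1  # tie between extremes resolves to +1

    def test_short_day_response_signs_negative(self):
        cov = np.diag([0.1, 0.25, 0.25])
        fit = make_fit(0.0, 0.0, 2.0, cov)
        classification, significant, sign = classify_direction(fit)
        assert classification is Direction.SHORT_DAY
        assert sign == -1


class TestPsmTable:
    def test_composition_excludes_and_fits(self, make_records):
        records = (
            make_records(20, 15, 10, species="good")
            + make_records(0, 0, 0, species="dead")
            + make_records(18, 18, 18, species="flat")
        )
        results, decisions = compute_psm_table(records, n_draws=500, seed=1)
        assert {d.species for d in decisions} == {"good", "dead", "flat"}
        assert {r.species for r in results} == {"good", "flat"}
        dead = next(d for d in decisions if d.species == "dead")
        assert dead.reason is FilterReason.LOW_PERCENT_ALL_TREATMENTS

    def test_output_file_is_deterministic(self, make_records, tmp_path):
        records = make_records(20, 15, 10, species="a") + make_records(
            5, 9, 28, species="b"
        )
        paths = []
        for name in ("one.csv", "two.csv"):
            results, decisions = compute_psm_table(records, n_draws=400, seed=3)
            write_psm_table(results, decisions, tmp_path / name)
            paths.append((tmp_path / name).read_bytes())
        assert paths[0] == paths[1]

    def test_species_rng_streams_are_independent(self, make_records):
        recs_a = make_records(20, 15, 10, species="a")
        recs_b = make_records(5, 9, 28, species="b")
        alone, _ = compute_psm_table(recs_a, n_draws=500, seed=5)
        together, _ = compute_psm_table(recs_a + recs_b, n_draws=500, seed=5)
        a_alone = next(r for r in alone if r.species == "a")
        a_together = next(r for r in together if r.species == "a")
        assert a_alone.se == a_together.se

    def test_weight_is_inverse_squared_se(self, make_records):
        results, _ = compute_psm_table(
            make_records(20, 15, 10), n_draws=1000, seed=2
        )
        (r,) = results
        assert r.weight == pytest.approx(1 / r.se**2, rel=1e-12)
        assert abs(r.signed_psm) == pytest.approx(r.psm, rel=1e-12)


def test_estimation_error_small_at_large_n():
    """At 500 seeds/treatment the fitted metric tracks the generative truth."""
    rng = np.random.default_rng(2024)
    scenarios = []
    for i in range(20):
        p = np.clip(rng.uniform(0.05, 0.95, size=3), 0.05, 0.95)
        scenarios.append(
            SpeciesScenario(f"s{i}", float(p[0]), float(p[1]), float(p[2]), 500)
        )
    records = simulate_germination(scenarios, seed=77)
    results, _ = compute_psm_table(records, n_draws=100, seed=77)
    by_name = {r.species: r.psm for r in results}
    errors = [abs(by_name[s.species] - s.true_psm) for s in scenarios]
    assert float(np.mean(errors)) < 0.15


def test_null_calibration_significant_fraction_bounded():
    """Species with no true treatment effect are rarely declared responsive."""
    n_species, n_seeds = 500, 30
    scenarios = [
        SpeciesScenario(f"null{i:03d}", 0.5, 0.5, 0.5, n_seeds)
        for i in range(n_species)
    ]
    records = simulate_germination(scenarios, seed=13)
    from photosens.germdata import group_by_species

    n_significant = 0
    for species_records in group_by_species(records).values():
        fit = fit_regularized_binomial_glm(species_records)
        _, significant, _ = classify_direction(fit)
        n_significant += significant
    assert n_significant / n_species <= 0.15
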