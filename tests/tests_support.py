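"""Shared builders for synthetic fits and Gamma-GLM datasets used by several
test modules."""

import numpy as np
from scipy.special import expit

from photosens.psmetric import Direction, PSMResult
from photosens.shrinkfit import SpeciesFit
from photosens.synthgen import TraitEffect, simulate_trait_table


def make_synthetic_fit(mu0, beta1, beta2, cov):
    """A SpeciesFit with prescribed coefficients and covariance (no data)."""
    return SpeciesFit(
        species="synthetic",
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


def gamma_glm_dataset(n=120, slope=0.0, seed=0, shape=5.0, predictor="seed_mass"):
    """Traits plus Gamma sensitivity responses with a known log-linear slope."""
    truth = {f"g{i:03d}": 1.0 for i in range(n)}
    traits, psm = simulate_trait_table(
        truth, TraitEffect(predictor=predictor, slope=slope, shape=shape), seed=seed
    )
    if slope == 0.0:
        rng = np.random.default_rng(seed + 10_000)
        psm = {s: float(rng.gamma(shape, 1.0 / shape)) for s in truth}
    results = [
        PSMResult(s, psm[s], psm[s], 1.0, 1.0, Direction.INSENSITIVE, False, 0)
        for s in sorted(psm)
    ]
    return results, traits


def rescale_weights(results, factor):
    return [
        PSMResult(
            r.species,
            r.psm,
            r.signed_psm,
            r.se / np.sqrt(factor),
            factor * r.weight,
            r.classification,
            r.significant,
            r.n_bootstrap,
        )
        for r in results
    ]
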