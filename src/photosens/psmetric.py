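"""The photoperiod sensitivity metric, its bootstrap uncertainty and the
per-species results table.

Given the two treatment contrasts of the per-species binomial fit —
``beta1`` (long day vs equal day) and ``beta2`` (short day vs equal day), in
log-odds units — the metric is

    PSM = sqrt( (beta1^2 + beta2^2 + (beta1 - beta2)^2) / 3 )

which equals the root sum of squared deviations of the three treatment
linear predictors {0, beta1, beta2} about their mean.  It is zero exactly
when germination is identical across treatments and grows as germination
becomes more unequal between day lengths.

The metric's standard error is a parametric bootstrap: coefficient vectors
are drawn from a multivariate normal centred at the MAP estimate with the
fit's posterior covariance, the metric is evaluated on each draw, and the
sample standard deviation of the draws is reported.  Downstream association
models weight each species by 1/SE^2.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .germdata import (
    FilterDecision,
    GerminationRecord,
    group_by_species,
)
from .germdata import apply_inclusion_filter
from .shrinkfit import PriorSpec, SpeciesFit, fit_regularized_binomial_glm

__all__ = [
    "Direction",
    "PSMResult",
    "compute_psm",
    "psm_gradient",
    "bootstrap_psm_se",
    "classify_direction",
    "compute_psm_table",
    "write_psm_table",
    "read_psm_table",
    "species_seed",
]


def compute_psm(beta1: float, beta2: float) -> float:
    """Photoperiod sensitivity metric from the two treatment contrasts."""
    if not (math.isfinite(beta1) and math.isfinite(beta2)):
        raise ValueError(f"non-finite contrast: beta1={beta1}, beta2={beta2}")
    return math.sqrt((beta1**2 + beta2**2 + (beta1 - beta2) ** 2) / 3.0)


def psm_gradient(beta1: float, beta2: float) -> tuple[float, float]:
    """Gradient of :func:`compute_psm` wrt (beta1, beta2); undefined at 0."""
    psm = compute_psm(beta1, beta2)
    if psm == 0:
        raise ValueError("PSM gradient is undefined at beta1 = beta2 = 0")
    return ((2 * beta1 - beta2) / (3 * psm), (2 * beta2 - beta1) / (3 * psm))


class Direction(enum.Enum):
    LONG_DAY = "long_day"
    SHORT_DAY = "short_day"
    INTERMEDIATE = "intermediate"
    INSENSITIVE = "insensitive"


@dataclass(frozen=True)
class PSMResult:
    """Complete sensitivity summary for one retained species."""

    species: str
    psm: float
    signed_psm: float
    se: float
    weight: float  # 1/se^2; NaN when se == 0 (degenerate covariance)
    classification: Direction
    significant: bool
    n_bootstrap: int


def _repaired_covariance(covariance: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Symmetrise and clip tiny negative eigenvalues; fail on real ones."""
    cov = np.asarray(covariance, dtype=float)
    cov = (cov + cov.T) / 2
    eigval, eigvec = np.linalg.eigh(cov)
    if np.any(eigval < -tol):
        raise ValueError(
            f"covariance is not positive semi-definite (min eigenvalue {eigval.min():.3e})"
        )
    eigval = np.clip(eigval, 0.0, None)
    return (eigvec * eigval) @ eigvec.T


def bootstrap_psm_se(
    fit: SpeciesFit,
    n_draws: int = 10_000,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[float, dict[str, float]]:
    """Parametric-bootstrap standard error of the sensitivity metric.

    Draws ``n_draws`` coefficient vectors from N((mu0, beta1, beta2), cov),
    evaluates the metric on the (beta1, beta2) margins of each draw and
    returns the sample standard deviation (n−1 denominator) together with a
    summary of the draws.  Bit-reproducible for a fixed seed.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be at least 2")
    cov = _repaired_covariance(fit.covariance)
    if not np.any(cov):  # degenerate: the coefficient distribution is a point mass
        psm = compute_psm(fit.beta1, fit.beta2)
        return 0.0, {"mean": psm, "median": psm, "q025": psm, "q975": psm}
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(fit.params, cov, size=n_draws, method="eigh")
    b1, b2 = draws[:, 1], draws[:, 2]
    psm_draws = np.sqrt((b1**2 + b2**2 + (b1 - b2) ** 2) / 3.0)
    se = float(np.std(psm_draws, ddof=1))
    summary = {
        "mean": float(np.mean(psm_draws)),
        "median": float(np.median(psm_draws)),
        "q025": float(np.quantile(psm_draws, 0.025)),
        "q975": float(np.quantile(psm_draws, 0.975)),
    }
    return se, summary


def classify_direction(
    fit: SpeciesFit, alpha: float = 0.05
) -> tuple[Direction, bool, int]:
    """Classify a species' day-length response from Wald tests.

    Two-sided Wald z-tests at level ``alpha`` are applied to the three
    contrasts: long vs equal (beta1), short vs equal (beta2) and long vs
    short (beta1 − beta2).  A species is *significant* when any test
    rejects.  Among significant species, the direction follows the fitted
    germination probabilities: long-day / short-day when that treatment's
    probability is the strict maximum, intermediate when the equal-day
    probability strictly exceeds both extremes and at least one contrast is
    significantly negative.  The sign is +1 when fitted germination under
    long days is at least that under short days, −1 otherwise; intermediate
    species inherit the sign of their larger extreme.
    """
    cov = fit.covariance
    z_crit = norm.ppf(1 - alpha / 2)

    def _z(estimate: float, variance: float) -> float:
        if variance <= 0:
            return 0.0
        return estimate / math.sqrt(variance)

    z1 = _z(fit.beta1, cov[1, 1])
    z2 = _z(fit.beta2, cov[2, 2])
    z12 = _z(fit.beta1 - fit.beta2, cov[1, 1] + cov[2, 2] - 2 * cov[1, 2])

    sig1, sig2, sig12 = (abs(z) > z_crit for z in (z1, z2, z12))
    significant = sig1 or sig2 or sig12
    p_equal, p_long, p_short = fit.p_equal, fit.p_long, fit.p_short
    sign = 1 if p_long >= p_short else -1

    if not significant:
        return Direction.INSENSITIVE, False, sign
    if (
        p_equal > p_long
        and p_equal > p_short
        and ((sig1 and fit.beta1 < 0) or (sig2 and fit.beta2 < 0))
    ):
        return Direction.INTERMEDIATE, True, sign
    if p_long > p_equal and p_long > p_short:
        return Direction.LONG_DAY, True, sign
    if p_short > p_equal and p_short > p_long:
        return Direction.SHORT_DAY, True, sign
    if sig12 or sig1 or sig2:
        # Significant contrast but no strict interior/extreme pattern (ties);
        # fall back on the long-vs-short comparison.
        if p_long > p_short:
            return Direction.LONG_DAY, True, sign
        if p_short > p_long:
            return Direction.SHORT_DAY, True, sign
    return Direction.INSENSITIVE, True, sign


def species_seed(seed: int, species: str) -> np.random.SeedSequence:
    """Independent, stable RNG stream for one species.

    Keyed on (seed, species name), so adding or removing other species never
    perturbs this species' draws.
    """
    import zlib

    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(species.encode())])


def compute_psm_table(
    records: Iterable[GerminationRecord],
    prior: PriorSpec = PriorSpec(),
    n_draws: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[list[PSMResult], list[FilterDecision]]:
    """Run filter → fit → metric → bootstrap → classification for all species.

    Returns the sensitivity results for retained species and the filter
    decision for every species.  Deterministic for a fixed seed.
    """
    grouped = group_by_species(records)
    results: list[PSMResult] = []
    decisions: list[FilterDecision] = []
    for species, species_records in grouped.items():
        try:
            decision = apply_inclusion_filter(species_records)
            decisions.append(decision)
            if not decision.retained:
                continue
            fit = fit_regularized_binomial_glm(species_records, prior)
            psm = compute_psm(fit.beta1, fit.beta2)
            se, _ = bootstrap_psm_se(fit, n_draws, species_seed(seed, species))
            weight = 1.0 / se**2 if se > 0 else float("nan")
            classification, significant, sign = classify_direction(fit, alpha)
            results.append(
                PSMResult(
                    species=species,
                    psm=psm,
                    signed_psm=sign * psm,
                    se=se,
                    weight=weight,
                    classification=classification,
                    significant=significant,
                    n_bootstrap=n_draws,
                )
            )
        except Exception as exc:
            raise type(exc)(f"species {species!r}: {exc}") from exc
    return results, decisions


_PSM_COLUMNS = [
    "species",
    "psm",
    "signed_psm",
    "se",
    "weight",
    "classification",
    "significant",
    "retained",
    "exclusion_reason",
]


def write_psm_table(
    results: Sequence[PSMResult],
    decisions: Sequence[FilterDecision],
    path: str | Path,
) -> pd.DataFrame:
    """Write the combined per-species output CSV; returns the DataFrame."""
    by_species: Mapping[str, PSMResult] = {r.species: r for r in results}
    rows = []
    for decision in decisions:
        result = by_species.get(decision.species)
        rows.append(
            {
                "species": decision.species,
                "psm": result.psm if result else np.nan,
                "signed_psm": result.signed_psm if result else np.nan,
                "se": result.se if result else np.nan,
                "weight": result.weight if result else np.nan,
                "classification": result.classification.value if result else "",
                "significant": result.significant if result else False,
                "retained": decision.retained,
                "exclusion_reason": decision.reason.value,
            }
        )
    df = pd.DataFrame(rows, columns=_PSM_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")
    return df


def read_psm_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"species": str})
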