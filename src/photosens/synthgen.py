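"""Synthetic study generator: germination trials with known true sensitivity,
trait tables with configurable effects, flowering tables, and pure-birth
trees with (λ-transformed) Brownian tip traits.

Default scenario sizes mirror a realistic field study of this design:
on the order of 67 retained species, 6–50 seeds per treatment, collection
latitudes between 16° S and 36° S.  Every generator is a pure function of
its parameters and seed, and per-species RNG streams are keyed on the
species name so adding a species never perturbs the draws of the others.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.special import logit

from .germdata import GerminationRecord, SpeciesTraits, Treatment
from .phylosignal import phylo_covariance
from .psmetric import compute_psm, species_seed

__all__ = [
    "SpeciesScenario",
    "TraitEffect",
    "true_psm_from_probabilities",
    "simulate_germination",
    "simulate_trait_table",
    "simulate_flowering_table",
    "simulate_tree_bm",
    "default_scenarios",
]


def true_psm_from_probabilities(
    p_long: float, p_equal: float, p_short: float
) -> float:
    """True sensitivity metric implied by three germination probabilities.

    The metric is defined on the log-odds scale, so the probabilities are
    converted to logits and differenced against the equal-day reference.
    Boundary probabilities (0 or 1) have infinite logits and are rejected.
    """
    probs = (p_long, p_equal, p_short)
    if any(not (0.0 < p < 1.0) for p in probs):
        raise ValueError(f"probabilities must lie strictly in (0, 1); got {probs}")
    beta1 = float(logit(p_long) - logit(p_equal))
    beta2 = float(logit(p_short) - logit(p_equal))
    return compute_psm(beta1, beta2)


@dataclass(frozen=True)
class SpeciesScenario:
    """Ground truth for one simulated species."""

    species: str
    p_long: float
    p_equal: float
    p_short: float
    n_per_treatment: int

    def __post_init__(self) -> None:
        if self.n_per_treatment <= 0:
            raise ValueError("n_per_treatment must be positive")
        for p in (self.p_long, self.p_equal, self.p_short):
            if not (0.0 < p < 1.0):
                raise ValueError("probabilities must lie strictly in (0, 1)")

    @property
    def true_psm(self) -> float:
        return true_psm_from_probabilities(self.p_long, self.p_equal, self.p_short)


def default_scenarios(
    n_species: int = 67,
    seed: int = 0,
    n_range: tuple[int, int] = (6, 50),
) -> list[SpeciesScenario]:
    """A study-scale scenario grid with heterogeneous true sensitivities."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0x5CE4]))
    out = []
    for i in range(n_species):
        base = rng.uniform(-1.5, 1.5)  # logit of equal-day germination
        shift_long = rng.normal(0, 1.0)
        shift_short = rng.normal(0, 1.0)
        p = 1 / (1 + np.exp(-np.array([base + shift_long, base, base + shift_short])))
        p = np.clip(p, 0.01, 0.99)
        out.append(
            SpeciesScenario(
                species=f"sp{i+1:03d}",
                p_long=float(p[0]),
                p_equal=float(p[1]),
                p_short=float(p[2]),
                n_per_treatment=int(rng.integers(n_range[0], n_range[1] + 1)),
            )
        )
    return out


def simulate_germination(
    scenarios: Sequence[SpeciesScenario], seed: int = 0
) -> list[GerminationRecord]:
    """Draw binomial germination counts for each species × treatment."""
    records = []
    for sc in scenarios:
        rng = np.random.default_rng(species_seed(seed, sc.species))
        for treatment, p in (
            (Treatment.LONG, sc.p_long),
            (Treatment.EQUAL, sc.p_equal),
            (Treatment.SHORT, sc.p_short),
        ):
            records.append(
                GerminationRecord(
                    species=sc.species,
                    treatment=treatment,
                    n_sown=sc.n_per_treatment,
                    n_germinated=int(rng.binomial(sc.n_per_treatment, p)),
                )
            )
    return records


@dataclass(frozen=True)
class TraitEffect:
    """Log-linear dependence of the sensitivity metric on one predictor.

    When ``slope`` is nonzero the generator replaces the supplied metric
    truth with Gamma-distributed values whose log-mean is
    ``intercept + slope * predictor`` (predictor on its modelling scale:
    log10 for seed mass, absolute degrees for latitude).
    """

    predictor: str = "seed_mass"
    slope: float = 0.0
    intercept: float = 0.5
    shape: float = 5.0


def simulate_trait_table(
    psm_truth: Mapping[str, float],
    effect: TraitEffect = TraitEffect(),
    seed: int = 0,
) -> tuple[list[SpeciesTraits], dict[str, float]]:
    """Draw a trait table and (optionally) effect-linked metric values.

    Predictor distributions: log10 seed mass ~ Normal(0.5, 1) (mg); latitude
    ~ Uniform(16, 36) degrees south (stored negative); LAI ~ Uniform(0, 6);
    alpine ~ Bernoulli(0.3); growth form categorical over
    herb/shrub/tree/climber with climbers rare.  Returns the traits and the
    metric values to pair with them (the input truth unchanged when
    ``effect.slope == 0``).
    """
    if effect.predictor not in ("seed_mass", "latitude", "lai", "alpine", "growth_form"):
        raise ValueError(f"unknown predictor {effect.predictor!r}")
    if not np.isfinite(effect.slope):
        raise ValueError("slope must be finite")
    species = list(psm_truth)
    traits: list[SpeciesTraits] = []
    psm_out: dict[str, float] = {}
    forms = np.array(["herb", "shrub", "tree", "climber"])
    form_probs = np.array([0.40, 0.33, 0.24, 0.03])
    for name in species:
        rng = np.random.default_rng(species_seed(seed, "trait:" + name))
        log_mass = rng.normal(0.5, 1.0)
        lat_south = rng.uniform(16.0, 36.0)
        lai = rng.uniform(0.0, 6.0)
        alpine = bool(rng.random() < 0.3)
        form = str(rng.choice(forms, p=form_probs))
        traits.append(
            SpeciesTraits(
                species=name,
                seed_mass_mg=float(10.0**log_mass),
                growth_form=form,
                latitude_deg=float(-lat_south),
                lai=float(lai),
                alpine=alpine,
            )
        )
        if effect.slope == 0.0:
            psm_out[name] = float(psm_truth[name])
        else:
            x = {
                "seed_mass": log_mass,
                "latitude": lat_south,
                "lai": lai,
                "alpine": float(alpine),
                "growth_form": {"herb": 0.0, "shrub": 1.0, "tree": 2.0, "climber": 3.0}[form],
            }[effect.predictor]
            mean = np.exp(effect.intercept + effect.slope * x)
            psm_out[name] = float(rng.gamma(effect.shape, mean / effect.shape))
    return traits, psm_out


def simulate_flowering_table(
    n_records: int = 135,
    seed: int = 0,
    category_probs: Mapping[str, float] | None = None,
) -> "list":
    """Draw a literature-style flowering photoperiodism table.

    Category frequencies default to the observed literature mix (long day,
    short day, day neutral, other ≈ 45 : 50 : 32 : 8).
    """
    from .ecomodels import FloweringCategory, FloweringRecord

    probs = category_probs or {
        "long_day": 45 / 135,
        "short_day": 50 / 135,
        "day_neutral": 32 / 135,
        "other": 8 / 135,
    }
    cats = list(probs)
    pvec = np.array([probs[c] for c in cats])
    pvec = pvec / pvec.sum()
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xF10E]))
    out = []
    for i in range(n_records):
        cat = FloweringCategory(str(rng.choice(cats, p=pvec)))
        out.append(
            FloweringRecord(
                species=f"fl{i+1:03d}",
                category=cat,
                latitude_deg=float(rng.uniform(-60, 60)),
                lai=float(rng.uniform(0, 6)),
                seed_mass_mg=float(10.0 ** rng.normal(0.5, 1.0)),
            )
        )
    return out


def simulate_tree_bm(
    n_tips: int,
    birth_rate: float = 1.0,
    sigma2: float = 1.0,
    lambda_true: float = 1.0,
    seed: int = 0,
) -> tuple[dendropy.Tree, dict[str, float]]:
    """Pure-birth tree plus multivariate-normal tip traits.

    The tree is simulated with a Yule (birth-only) process until ``n_tips``
    extant tips exist; traits are drawn from N(0, sigma2 · C(λ)) where C is
    the tree's phylogenetic covariance with off-diagonals scaled by
    ``lambda_true``.  λ = 1 is Brownian motion; λ = 0 removes all
    phylogenetic structure while preserving tip variances.
    """
    if n_tips < 4:
        raise ValueError("need at least 4 tips")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if not (0.0 <= lambda_true <= 1.0):
        raise ValueError("lambda_true must lie in [0, 1]")
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, 0x7EE5, n_tips])
    tree_rng = _random.Random(int(ss.generate_state(1)[0]))
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=tree_rng,
    )
    # The simulator stops at the instant of the final birth, leaving two
    # zero-length terminal branches (a singular covariance).  Extend every
    # tip by one further inter-event waiting time; the common extension
    # keeps the tree ultrametric.
    extra = tree_rng.expovariate(n_tips * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    labels = sorted(t.label for t in tree.taxon_namespace)
    cov = phylo_covariance(tree, labels)
    cov_lam = lambda_true * cov
    np.fill_diagonal(cov_lam, np.diag(cov))
    rng = np.random.default_rng(ss.spawn(1)[0])
    values = rng.multivariate_normal(
        np.zeros(n_tips), sigma2 * cov_lam, method="eigh"
    )
    return tree, dict(zip(labels, values.astype(float)))
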