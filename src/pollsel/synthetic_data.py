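"""Synthetic plant populations, bee visitation, and tripping-mediated seed set.

Generates floral-trait tables, per-species flower-visit counts driven by
configurable trait preferences, and seed set linked to visits through
species-specific tripping rates, with the generative ground truth retained
for recovery tests.

All randomness flows from a single user seed.  Each stage (plants, visits,
seeds) consumes its own child of a :class:`numpy.random.SeedSequence`, so
stages are independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import AlignmentError, ConfigurationError

__all__ = [
    "TRAIT_NAMES",
    "SPECIES",
    "TraitSpec",
    "TraitModel",
    "PreferenceModel",
    "YieldModel",
    "SyntheticTruth",
    "alfalfa_trait_model",
    "alfalfa_preference_model",
    "alfalfa_yield_model",
    "generate_plants",
    "generate_visits",
    "generate_seeds",
    "simulate_dataset",
]

#: Canonical trait column order used throughout the package.
TRAIT_NAMES = (
    "stems_per_plant",
    "racemes_per_stem",
    "flowers_per_raceme",
    "hue",
    "chroma",
    "reflectivity",
)

#: Default bee species, ordered by visit share in the alfalfa calibration.
SPECIES = ("bumble", "honey", "leafcutting")


@dataclass(frozen=True)
class TraitSpec:
    """Marginal model for one floral trait.

    ``mean`` and ``sd`` are the *target* moments of the generated values:
    bounded traits are drawn from a truncated normal whose underlying
    location/scale are solved numerically so that the truncated distribution
    itself has the requested mean and SD.
    """

    name: str
    mean: float
    sd: float
    lower: float = -math.inf
    integer: bool = False

    def validate(self) -> None:
        if not self.sd > 0:
            raise ConfigurationError(f"trait {self.name!r}: scale must be > 0, got {self.sd}")
        if self.lower > self.mean:
            raise ConfigurationError(
                f"trait {self.name!r}: lower bound {self.lower} exceeds target mean {self.mean}"
            )


@dataclass(frozen=True)
class TraitModel:
    """Joint trait model: moment-matched marginals tied by a Gaussian copula."""

    traits: Sequence[TraitSpec]
    correlation: np.ndarray | None = None

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.traits)

    def validate(self) -> np.ndarray:
        """Validate and return the (possibly implicit identity) correlation matrix."""
        for t in self.traits:
            t.validate()
        p = len(self.traits)
        if p < 1:
            raise ConfigurationError("trait model must declare at least one trait")
        if self.correlation is None:
            return np.eye(p)
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (p, p):
            raise ConfigurationError(f"correlation matrix must be {p}x{p}, got {corr.shape}")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ConfigurationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ConfigurationError("correlation matrix must have unit diagonal")
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < -1e-10:
            raise ConfigurationError("correlation matrix must be positive semi-definite")
        return corr


@dataclass(frozen=True)
class PreferenceModel:
    """Per-species visitation preference on standardized traits.

    The per-plant visit intensity for species *s* is

    ``exp(intercept_s + sum_j b_sj z_j + sum_j q_sj z_j^2 + sum_{j<k} c_sjk z_j z_k)``

    where ``z`` are the sample-standardized traits of the generated plants.
    Intensities are rescaled jointly so the expected total count over all
    plants and species equals ``target_total_visits``; per-species shares are
    therefore controlled by the intercepts.
    """

    intercepts: Mapping[str, float]
    linear: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    quadratic: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    interaction: Mapping[str, Mapping[tuple[str, str], float]] = field(default_factory=dict)
    target_total_visits: float = 8727.0
    overdispersion: float | None = None  # None => Poisson; else gamma-Poisson shape

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.intercepts)

    def validate(self, trait_names: Sequence[str]) -> None:
        if not self.intercepts:
            raise ConfigurationError("preference model must declare at least one species")
        if not self.target_total_visits > 0:
            raise ConfigurationError("target total visits must be > 0")
        if self.overdispersion is not None and not self.overdispersion > 0:
            raise ConfigurationError("overdispersion must be > 0 when set")
        known = set(trait_names)
        for coefs in (self.linear, self.quadratic):
            for sp, per_trait in coefs.items():
                if sp not in self.intercepts:
                    raise ConfigurationError(f"coefficients given for unknown species {sp!r}")
                unknown = set(per_trait) - known
                if unknown:
                    raise ConfigurationError(f"unknown traits in preference model: {sorted(unknown)}")
        for sp, pairs in self.interaction.items():
            if sp not in self.intercepts:
                raise ConfigurationError(f"coefficients given for unknown species {sp!r}")
            for pair in pairs:
                if len(pair) != 2 or set(pair) - known:
                    raise ConfigurationError(f"bad interaction pair {pair!r}")


@dataclass(frozen=True)
class YieldModel:
    """Link from visits to seeds via tripping and per-flower yield.

    Expected seeds on plant *i* are ``sum_s visits_is * trip_s * kappa_s``.
    With ``noisy=False`` the realized seed set equals this expectation exactly
    (kept fractional, no rounding: field seed sets are themselves products of
    per-raceme averages and need not be integers).  With ``noisy=True`` seeds
    are drawn negative-binomially around the expectation with gamma shape
    ``dispersion`` (variance mu + mu^2/dispersion).
    """

    tripping_rates: Mapping[str, float]
    seeds_per_tripped_flower: float | Mapping[str, float] = 1.0
    dispersion: float = 1.0
    noisy: bool = True

    def validate(self) -> None:
        for sp, rate in self.tripping_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"tripping rate for {sp!r} must be in [0, 1], got {rate}")
        for sp, kappa in self._kappa_map(self.tripping_rates).items():
            if kappa < 0:
                raise ConfigurationError(f"seeds per tripped flower for {sp!r} must be >= 0")
        if not self.dispersion > 0:
            raise ConfigurationError("dispersion must be > 0")

    def _kappa_map(self, species: Mapping[str, float]) -> dict[str, float]:
        if isinstance(self.seeds_per_tripped_flower, Mapping):
            missing = set(species) - set(self.seeds_per_tripped_flower)
            if missing:
                raise ConfigurationError(f"seeds_per_tripped_flower missing species {sorted(missing)}")
            return {sp: float(self.seeds_per_tripped_flower[sp]) for sp in species}
        return {sp: float(self.seeds_per_tripped_flower) for sp in species}


@dataclass(frozen=True)
class SyntheticTruth:
    """Generative ground truth retained for recovery tests."""

    expected_tripped: pd.DataFrame  # plants x species
    expected_seeds: pd.DataFrame  # plants x species
    preference: PreferenceModel | None = None

    @property
    def expected_total_seeds(self) -> pd.Series:
        return self.expected_seeds.sum(axis=1)


# --------------------------------------------------------------------------
# Built-in alfalfa calibration (field-study moments)
# --------------------------------------------------------------------------

def alfalfa_trait_model(correlation: np.ndarray | None = None) -> TraitModel:
    """Trait model calibrated to the alfalfa field population.

    Inter-trait correlations in the source population are unknown; the
    default is uncorrelated marginals.
    """
    return TraitModel(
        traits=(
            TraitSpec("stems_per_plant", 30.65, 16.4, lower=1.0, integer=True),
            TraitSpec("racemes_per_stem", 4.93, 3.41, lower=0.0),
            TraitSpec("flowers_per_raceme", 7.53, 2.44, lower=0.0),
            TraitSpec("hue", -0.012, 0.476),
            TraitSpec("chroma", 1.29, 0.76, lower=0.0),
            TraitSpec("reflectivity", 3.76, 1.11, lower=0.0),
        ),
        correlation=correlation,
    )


def alfalfa_preference_model(
    target_total_visits: float = 8727.0,
    shares: Mapping[str, float] | None = None,
    linear: Mapping[str, Mapping[str, float]] | None = None,
    quadratic: Mapping[str, Mapping[str, float]] | None = None,
    interaction: Mapping[str, Mapping[tuple[str, str], float]] | None = None,
    overdispersion: float | None = None,
) -> PreferenceModel:
    """Preference model with intercepts tuned to the observed visit mix.

    With all trait coefficients zero the expected per-species visit shares
    equal ``shares`` (default 52.3 / 45.0 / 2.7 % for bumble / honey /
    leafcutting).  Nonzero coefficients perturb realized shares slightly.
    """
    if shares is None:
        shares = {"bumble": 0.523, "honey": 0.450, "leafcutting": 0.027}
    intercepts = {sp: math.log(frac) for sp, frac in shares.items()}
    return PreferenceModel(
        intercepts=intercepts,
        linear=linear or {},
        quadratic=quadratic or {},
        interaction=interaction or {},
        target_total_visits=target_total_visits,
        overdispersion=overdispersion,
    )


#: Species tripping rates for the alfalfa system.
ALFALFA_TRIPPING_RATES = {"bumble": 0.55, "honey": 0.25, "leafcutting": 0.80}


def alfalfa_yield_model(noisy: bool = True, dispersion: float = 0.6,
                        seeds_per_tripped_flower: float = 31.4) -> YieldModel:
    """Yield model calibrated so mean seed set lands near the field value.

    At ~57 visits/plant and the default visit mix, mean tripped flowers per
    plant is ~24; kappa = 31.4 puts mean seed set near 755.  dispersion = 0.6
    reproduces the heavy overdispersion of field seed set (SD ~ 1.3x mean).
    """
    return YieldModel(
        tripping_rates=dict(ALFALFA_TRIPPING_RATES),
        seeds_per_tripped_flower=seeds_per_tripped_flower,
        dispersion=dispersion,
        noisy=noisy,
    )


# --------------------------------------------------------------------------
# Plants
# --------------------------------------------------------------------------

def _match_truncnorm(mean: float, sd: float, lower: float) -> tuple[float, float]:
    """Underlying (loc, scale) of a lower-truncated normal with given moments."""

    def resid(params: np.ndarray) -> list[float]:
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        a = (lower - mu) / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.root(resid, x0=[mean, math.log(sd)], method="hybr")
    if not sol.success or max(abs(r) for r in sol.fun) > 1e-8 * max(1.0, sd):
        raise ConfigurationError(
            f"cannot moment-match truncated normal (mean={mean}, sd={sd}, lower={lower})"
        )
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def generate_plants(trait_model: TraitModel, n_plants: int, rng_seed) -> pd.DataFrame:
    """Draw a plant table with moment-matched, optionally correlated traits.

    Marginals are lower-truncated normals whose underlying parameters are
    solved so the *truncated* mean/SD hit the targets; correlations are
    induced by a Gaussian copula.  Integer traits are rounded to the nearest
    integer and floored at ``ceil(lower)``.

    Returns a DataFrame with a ``plant_id`` column (1..n) and one column per
    trait, in model order.
    """
    if n_plants < 2:
        raise ConfigurationError(f"n_plants must be >= 2, got {n_plants}")
    corr = trait_model.validate()
    rng = _as_rng(rng_seed)

    p = len(trait_model.traits)
    # eigh-based square root: tolerant of semi-definite correlation matrices
    eigvals, eigvecs = np.linalg.eigh(corr)
    root = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))
    z = rng.standard_normal((n_plants, p)) @ root.T

    data: dict[str, np.ndarray] = {"plant_id": np.arange(1, n_plants + 1)}
    for j, spec in enumerate(trait_model.traits):
        col = z[:, j]
        if math.isinf(spec.lower):
            values = spec.mean + spec.sd * col
        else:
            mu, sigma = _match_truncnorm(spec.mean, spec.sd, spec.lower)
            a = (spec.lower - mu) / sigma
            u = stats.norm.cdf(col)
            # clip away exact 0/1 to keep ppf finite
            u = np.clip(u, 1e-12, 1.0 - 1e-12)
            values = stats.truncnorm.ppf(u, a, np.inf, loc=mu, scale=sigma)
        if spec.integer:
            values = np.maximum(np.rint(values), math.ceil(spec.lower))
        data[spec.name] = values
    return pd.DataFrame(data)


# --------------------------------------------------------------------------
# Visits
# --------------------------------------------------------------------------

def _standardize_sample(traits: pd.DataFrame) -> pd.DataFrame:
    sds = traits.std(ddof=1)
    if (sds <= 0).any():
        bad = list(sds.index[sds <= 0])
        raise ConfigurationError(f"cannot standardize zero-variance traits: {bad}")
    return (traits - traits.mean()) / sds


def generate_visits(plants: pd.DataFrame, preference_model: PreferenceModel, rng_seed) -> pd.DataFrame:
    """Draw per-plant per-species flower-visit counts.

    Count law is Poisson on the preference intensity (gamma-Poisson when
    ``overdispersion`` is set), with intensities rescaled so the expected
    grand total equals ``target_total_visits``.

    Returns a long DataFrame (plant_id, species, flowers_visited).
    """
    if plants.empty:
        raise ConfigurationError("plants table is empty")
    trait_names = [c for c in plants.columns if c != "plant_id"]
    preference_model.validate(trait_names)
    rng = _as_rng(rng_seed)

    z = _standardize_sample(plants[trait_names])
    n = len(plants)
    species = preference_model.species
    eta = np.zeros((n, len(species)))
    for s_idx, sp in enumerate(species):
        e = np.full(n, preference_model.intercepts[sp], dtype=float)
        for trait, b in preference_model.linear.get(sp, {}).items():
            e += b * z[trait].to_numpy()
        for trait, q in preference_model.quadratic.get(sp, {}).items():
            e += q * z[trait].to_numpy() ** 2
        for (t1, t2), c in preference_model.interaction.get(sp, {}).items():
            e += c * z[t1].to_numpy() * z[t2].to_numpy()
        eta[:, s_idx] = e
    lam = np.exp(eta)
    lam *= preference_model.target_total_visits / lam.sum()

    if preference_model.overdispersion is None:
        counts = rng.poisson(lam)
    else:
        shape = preference_model.overdispersion
        counts = rng.poisson(rng.gamma(shape, lam / shape))

    out = pd.DataFrame(
        {
            "plant_id": np.repeat(plants["plant_id"].to_numpy(), len(species)),
            "species": np.tile(np.asarray(species, dtype=object), n),
            "flowers_visited": counts.reshape(-1),
        }
    )
    return out


# --------------------------------------------------------------------------
# Seeds
# --------------------------------------------------------------------------

def generate_seeds(plants: pd.DataFrame, visits: pd.DataFrame, yield_model: YieldModel,
                   rng_seed) -> tuple[pd.Series, SyntheticTruth]:
    """Draw per-plant total seed set from visits through tripping and yield.

    Returns the seed column (indexed by plant_id) and the ground truth of
    per-species expected tripped flowers and expected seed contributions.
    """
    yield_model.validate()
    rng = _as_rng(rng_seed)

    wide = visits.pivot_table(index="plant_id", columns="species",
                              values="flowers_visited", aggfunc="sum", fill_value=0)
    extra = set(wide.index) - set(plants["plant_id"])
    if extra:
        raise AlignmentError(f"visit table references unknown plant ids: {sorted(extra)[:5]}")
    wide = wide.reindex(plants["plant_id"], fill_value=0)

    missing = set(wide.columns) - set(yield_model.tripping_rates)
    if missing:
        raise ConfigurationError(f"yield model missing tripping rates for species {sorted(missing)}")

    rates = pd.Series({sp: yield_model.tripping_rates[sp] for sp in wide.columns})
    kappa = pd.Series(yield_model._kappa_map({sp: 0.0 for sp in wide.columns}))
    expected_tripped = wide * rates
    expected_seeds = expected_tripped * kappa
    mu = expected_seeds.sum(axis=1).to_numpy(dtype=float)

    if yield_model.noisy:
        shape = yield_model.dispersion
        lam = np.where(mu > 0, rng.gamma(shape, np.maximum(mu, 1e-300) / shape), 0.0)
        seeds = rng.poisson(lam).astype(float)
    else:
        seeds = mu  # exact expectation, fractional by design (no rounding)

    seed_col = pd.Series(seeds, index=wide.index, name="total_seeds")
    truth = SyntheticTruth(expected_tripped=expected_tripped, expected_seeds=expected_seeds)
    return seed_col, truth


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------

def simulate_dataset(
    trait_model: TraitModel,
    preference_model: PreferenceModel,
    yield_model: YieldModel,
    n_plants: int,
    seed: int | np.random.SeedSequence,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Run the full generative chain: plants -> visits -> seeds.

    The seed is split into three independent child streams (plants, visits,
    seeds), so e.g. switching seed noise on does not perturb the plant draw.
    Returns (plants with ``total_seeds`` column, long visit table, truth).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    plant_ss, visit_ss, seed_ss = ss.spawn(3)
    plants = generate_plants(trait_model, n_plants, np.random.default_rng(plant_ss))
    visits = generate_visits(plants, preference_model, np.random.default_rng(visit_ss))
    seeds, truth = generate_seeds(plants, visits, yield_model, np.random.default_rng(seed_ss))
    plants = plants.copy()
    plants["total_seeds"] = seeds.to_numpy()
    truth = SyntheticTruth(
        expected_tripped=truth.expected_tripped,
        expected_seeds=truth.expected_seeds,
        preference=preference_model,
    )
    return plants, visits, truth
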