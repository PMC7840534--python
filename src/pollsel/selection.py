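"""Directional, quadratic, and correlational selection estimation.

Coefficients follow the standard regression approach on variance-standardized
traits and relativized fitness:

* ``S`` — selection differential, slope of the single regression of relative
  fitness on one standardized trait (direct + indirect selection).
* ``C_ii`` — quadratic selection differential, from the one-trait
  linear+quadratic regression.
* ``beta`` — selection gradient, partial coefficient of the linear-only
  multiple regression (direct selection).
* ``gamma_ii`` / ``gamma_ij`` — quadratic and correlational gradients, partial
  coefficients of the full second-order multiple regression.

Quadratic coefficients are reported doubled by default (``gamma_ii`` always
by convention; ``C_ii`` behind a switch).  Point estimates come from
untransformed fitness; p-values come from refitting the same designs on
log-transformed fitness, which improves residual behavior without changing
the estimates.  Percentile bootstrap CIs case-resample plants and rebuild
standardization and relativization inside each replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import attribution
from .exceptions import (
    BootstrapRetryError,
    ConfigurationError,
    DegenerateDataError,
    DegenerateFitnessError,
    DegenerateTraitError,
    NumericalError,
    ValidationError,
)
from .synthetic_data import TRAIT_NAMES

__all__ = [
    "TraitMatrix",
    "BootstrapSettings",
    "COEFFICIENT_KINDS",
    "standardize",
    "selection_differentials",
    "selection_gradients",
    "estimate_coefficients",
    "pvalues_log_model",
    "bootstrap_cis",
    "selection_report",
]

COEFFICIENT_KINDS = ("S", "beta", "C_ii", "gamma_ii", "gamma_ij")

#: Coefficient key: (kind, trait_1, trait_2); trait_2 is "" except for gamma_ij.
CoefKey = tuple[str, str, str]


@dataclass(frozen=True)
class TraitMatrix:
    """Standardized traits plus the moments needed to back-transform."""

    z: pd.DataFrame
    means: pd.Series
    sds: pd.Series

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.z.columns)


@dataclass(frozen=True)
class BootstrapSettings:
    """Case-resampling bootstrap configuration."""

    replicates: int = 1000
    level: float = 0.95
    seed: int | None = None
    restandardize: bool = True
    max_retries: int = 100

    def validate(self) -> None:
        if self.replicates < 1:
            raise ConfigurationError("bootstrap replicates must be >= 1")
        if not 0.0 < self.level < 1.0:
            raise ConfigurationError("CI level must be in (0, 1)")


def standardize(traits: pd.DataFrame) -> TraitMatrix:
    """Scale each trait to mean 0 and sample variance 1 (n-1 denominator)."""
    if traits.isna().any().any():
        raise ValidationError("traits contain missing values; apply listwise deletion first")
    if len(traits) < 3:
        raise ValidationError("standardization requires n >= 3")
    means = traits.mean()
    sds = traits.std(ddof=1)
    zero = sds[~(sds > 0)]
    if len(zero):
        raise DegenerateTraitError(f"zero-variance traits: {list(zero.index)}")
    return TraitMatrix(z=(traits - means) / sds, means=means, sds=sds)


# --------------------------------------------------------------------------
# OLS internals
# --------------------------------------------------------------------------

def _ols_fit(X: np.ndarray, y: np.ndarray, colnames: Sequence[str]) -> np.ndarray:
    coefs, _res, rank, _sv = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise NumericalError(f"rank-deficient design; offending columns: {_offending(X, colnames)}")
    return coefs

def _offending(X: np.ndarray, colnames: Sequence[str]) -> list[str]:
    from scipy.linalg import qr

    _q, _r, piv = qr(X, mode="economic", pivoting=True)
    rank = np.linalg.matrix_rank(X)
    return [colnames[i] for i in sorted(piv[rank:])]


def _ols_pvalues(X: np.ndarray, y: np.ndarray, colnames: Sequence[str]) -> np.ndarray:
    """Two-sided partial t-test p-values for every OLS coefficient."""
    n, p = X.shape
    if n <= p:
        raise NumericalError("not enough rows for OLS inference")
    coefs = _ols_fit(X, y, colnames)
    resid = y - X @ coefs
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coefs / se, np.inf * np.sign(coefs))
    return 2.0 * sps.t.sf(np.abs(t), dof)


def _full_design(Z: np.ndarray, names: Sequence[str]) -> tuple[np.ndarray, list[str], list[tuple[int, int]]]:
    """Intercept + linear + quadratic + cross-product design."""
    n, p = Z.shape
    cols = [np.ones(n)] + [Z[:, j] for j in range(p)] + [Z[:, j] ** 2 for j in range(p)]
    labels = ["intercept"] + list(names) + [f"{t}^2" for t in names]
    pairs: list[tuple[int, int]] = []
    for j in range(p):
        for k in range(j + 1, p):
            cols.append(Z[:, j] * Z[:, k])
            labels.append(f"{names[j]}*{names[k]}")
            pairs.append((j, k))
    return np.column_stack(cols), labels, pairs


# --------------------------------------------------------------------------
# Point estimators
# --------------------------------------------------------------------------

def selection_differentials(z, w, double_quadratic: bool = True) -> tuple[float, float]:
    """(S, C) for a single standardized trait.

    S is the slope of w on z; C is the quadratic coefficient from the
    one-trait linear+quadratic fit, doubled when ``double_quadratic``.
    """
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    ones = np.ones_like(z)
    s = _ols_fit(np.column_stack([ones, z]), w, ["intercept", "z"])[1]
    quad = _ols_fit(np.column_stack([ones, z, z**2]), w, ["intercept", "z", "z^2"])[2]
    factor = 2.0 if double_quadratic else 1.0
    return float(s), float(factor * quad)


def selection_gradients(Z, w, trait_names: Sequence[str] | None = None,
                        double_quadratic: bool = True
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(beta, gamma_ii, gamma_ij) from the multiple-regression models.

    beta comes from the linear-only model; gamma_ii (doubled) and gamma_ij
    (not doubled) from the full second-order model.  gamma_ij is returned as
    a symmetric p x p matrix with zero diagonal.
    """
    Z = np.asarray(Z, dtype=float)
    w = np.asarray(w, dtype=float)
    n, p = Z.shape
    names = list(trait_names) if trait_names is not None else [f"z{j}" for j in range(p)]
    ones = np.ones(n)

    beta = _ols_fit(np.column_stack([ones, Z]), w, ["intercept"] + names)[1:]

    X, labels, pairs = _full_design(Z, names)
    if n <= X.shape[1]:
        raise NumericalError(
            f"n={n} does not exceed the {X.shape[1]} parameters of the full second-order model")
    coefs = _ols_fit(X, w, labels)
    factor = 2.0 if double_quadratic else 1.0
    gamma_ii = factor * coefs[1 + p: 1 + 2 * p]
    gamma_ij = np.zeros((p, p))
    for idx, (j, k) in enumerate(pairs):
        gamma_ij[j, k] = gamma_ij[k, j] = coefs[1 + 2 * p + idx]
    return beta.copy(), gamma_ii.copy(), gamma_ij


def estimate_coefficients(
    Z,
    w,
    trait_names: Sequence[str] | None = None,
    kinds: Iterable[str] = COEFFICIENT_KINDS,
    double_gamma: bool = True,
    double_c: bool = True,
) -> dict[CoefKey, float]:
    """All requested selection coefficients as a flat {key: estimate} map.

    Keys are ``(kind, trait_1, trait_2)`` with trait_2 empty except for
    correlational gradients (trait pairs ordered as in ``trait_names``).
    """
    Z = np.asarray(Z, dtype=float)
    w = np.asarray(w, dtype=float)
    kinds = set(kinds)
    bad = kinds - set(COEFFICIENT_KINDS)
    if bad:
        raise ConfigurationError(f"unknown coefficient kinds: {sorted(bad)}")
    p = Z.shape[1]
    names = list(trait_names) if trait_names is not None else [f"z{j}" for j in range(p)]

    out: dict[CoefKey, float] = {}
    if kinds & {"S", "C_ii"}:
        ones = np.ones(len(w))
        for j, name in enumerate(names):
            zj = Z[:, j]
            if "S" in kinds:
                s = _ols_fit(np.column_stack([ones, zj]), w, ["intercept", name])[1]
                out[("S", name, "")] = float(s)
            if "C_ii" in kinds:
                quad = _ols_fit(np.column_stack([ones, zj, zj**2]), w,
                                ["intercept", name, f"{name}^2"])[2]
                out[("C_ii", name, "")] = float((2.0 if double_c else 1.0) * quad)
    if kinds & {"beta", "gamma_ii", "gamma_ij"}:
        if kinds & {"gamma_ii", "gamma_ij"}:
            beta, gii, gij = selection_gradients(Z, w, names, double_quadratic=double_gamma)
        else:
            beta = _ols_fit(np.column_stack([np.ones(len(w)), Z]), w, ["intercept"] + names)[1:]
            gii = gij = None
        if "beta" in kinds:
            for j, name in enumerate(names):
                out[("beta", name, "")] = float(beta[j])
        if "gamma_ii" in kinds:
            for j, name in enumerate(names):
                out[("gamma_ii", name, "")] = float(gii[j])
        if "gamma_ij" in kinds:
            for j in range(p):
                for k in range(j + 1, p):
                    out[("gamma_ij", names[j], names[k])] = float(gij[j, k])
    return out


def pvalues_log_model(
    Z,
    w,
    offset: float = 0.0,
    trait_names: Sequence[str] | None = None,
    kinds: Iterable[str] = COEFFICIENT_KINDS,
) -> dict[CoefKey, float]:
    """Partial t-test p-values from the log-fitness refits.

    Every model behind :func:`estimate_coefficients` is refit with response
    ``log(w + offset)``; only the p-values are taken from these fits, the
    estimates always come from untransformed fitness.
    """
    Z = np.asarray(Z, dtype=float)
    w = np.asarray(w, dtype=float)
    if offset < 0:
        raise ConfigurationError("log-model offset must be >= 0")
    if offset == 0.0 and (w <= 0).any():
        raise ConfigurationError(
            "log model undefined: zero fitness present with offset 0; "
            "set a positive offset or rely on bootstrap-only significance")
    y = np.log(w + offset)
    kinds = set(kinds)
    n, p = Z.shape
    names = list(trait_names) if trait_names is not None else [f"z{j}" for j in range(p)]
    ones = np.ones(n)

    out: dict[CoefKey, float] = {}
    for j, name in enumerate(names):
        if "S" in kinds:
            pv = _ols_pvalues(np.column_stack([ones, Z[:, j]]), y, ["intercept", name])
            out[("S", name, "")] = float(pv[1])
        if "C_ii" in kinds:
            pv = _ols_pvalues(np.column_stack([ones, Z[:, j], Z[:, j] ** 2]), y,
                              ["intercept", name, f"{name}^2"])
            out[("C_ii", name, "")] = float(pv[2])
    if "beta" in kinds:
        pv = _ols_pvalues(np.column_stack([ones, Z]), y, ["intercept"] + names)
        for j, name in enumerate(names):
            out[("beta", name, "")] = float(pv[1 + j])
    if kinds & {"gamma_ii", "gamma_ij"}:
        X, labels, pairs = _full_design(Z, names)
        pv = _ols_pvalues(X, y, labels)
        if "gamma_ii" in kinds:
            for j, name in enumerate(names):
                out[("gamma_ii", name, "")] = float(pv[1 + p + j])
        if "gamma_ij" in kinds:
            for idx, (j, k) in enumerate(pairs):
                out[("gamma_ij", names[j], names[k])] = float(pv[1 + 2 * p + idx])
    return out


# --------------------------------------------------------------------------
# Bootstrap
# --------------------------------------------------------------------------

def _nrows(data) -> int:
    if isinstance(data, tuple):
        return len(data[0])
    return len(data)


def _take(data, idx: np.ndarray):
    if isinstance(data, tuple):
        return tuple(np.asarray(part)[idx] for part in data)
    if isinstance(data, pd.DataFrame):
        return data.iloc[idx]
    return np.asarray(data)[idx]


def bootstrap_cis(
    data,
    estimator: Callable[[object], Mapping],
    settings: BootstrapSettings,
) -> dict:
    """Percentile bootstrap CIs for every statistic an estimator returns.

    Rows of ``data`` (DataFrame, array, or tuple of aligned arrays) are
    case-resampled with replacement ``settings.replicates`` times; the
    estimator runs on each replicate.  Replicates on which the estimator
    raises :class:`DegenerateDataError` (collapsed trait variance, all-zero
    fitness) are redrawn, at most ``settings.max_retries`` times each.

    Returns ``{key: (lower, upper)}`` over the keys of the full-sample
    estimate.
    """
    settings.validate()
    rng = np.random.default_rng(settings.seed)
    return _bootstrap_core(data, estimator, settings, rng)


def _bootstrap_core(data, estimator, settings: BootstrapSettings,
                    rng: np.random.Generator) -> dict:
    n = _nrows(data)
    point = estimator(data)
    keys = list(point)
    draws = np.empty((settings.replicates, len(keys)))
    for b in range(settings.replicates):
        for _attempt in range(settings.max_retries + 1):
            idx = rng.integers(0, n, n)
            try:
                est = estimator(_take(data, idx))
            except (DegenerateDataError, NumericalError):
                # collapsed trait variance, all-zero fitness, or a resample
                # with too few distinct rows for the full design: redraw
                continue
            draws[b] = [est[k] for k in keys]
            break
        else:
            raise BootstrapRetryError(
                f"bootstrap replicate redraw cap ({settings.max_retries}) exceeded")
    alpha = 1.0 - settings.level
    lo = np.percentile(draws, 100 * alpha / 2, axis=0)
    hi = np.percentile(draws, 100 * (1 - alpha / 2), axis=0)
    return {k: (float(lo[i]), float(hi[i])) for i, k in enumerate(keys)}


# --------------------------------------------------------------------------
# Report orchestration
# --------------------------------------------------------------------------

def _analysis_blocks(plants, visits, rates, bases, include_total, species=None):
    """Yield (species, basis, raw fitness values) for every analysis block."""
    ft = attribution.fitness_table(
        plants, visits, rates,
        bases=tuple(b for b in bases if b != "total") + (("total",) if include_total else ()),
        species=species,
    )
    blocks = []
    if include_total:
        sub = ft[(ft["basis"] == "total")]
        blocks.append(("all", "total", sub["attributed_seeds"].to_numpy()))
    for basis in bases:
        if basis == "total":
            continue
        for sp in sorted(ft.loc[ft["basis"] == basis, "species"].unique()):
            sub = ft[(ft["basis"] == basis) & (ft["species"] == sp)]
            blocks.append((sp, basis, sub["attributed_seeds"].to_numpy()))
    return blocks


def make_block_estimator(kinds=COEFFICIENT_KINDS, trait_names=None,
                         double_gamma=True, double_c=True,
                         restandardize=True) -> Callable:
    """Estimator closure over (raw trait matrix, raw fitness values) tuples.

    With ``restandardize`` the replicate's traits are re-standardized and its
    fitness re-relativized before estimation, mirroring the full pipeline;
    otherwise inputs are assumed already on the analysis scale.
    """

    def estimator(data):
        traits_raw, values_raw = data
        traits_raw = np.asarray(traits_raw, dtype=float)
        values_raw = np.asarray(values_raw, dtype=float)
        if restandardize:
            sds = traits_raw.std(axis=0, ddof=1)
            if not (sds > 0).all():
                raise DegenerateTraitError("replicate collapsed a trait's variance")
            Z = (traits_raw - traits_raw.mean(axis=0)) / sds
            mean_v = values_raw.mean()
            if not mean_v > 0:
                raise DegenerateFitnessError("replicate has all-zero fitness")
            w = values_raw / mean_v
        else:
            Z, w = traits_raw, values_raw
        return estimate_coefficients(Z, w, trait_names=trait_names, kinds=kinds,
                                     double_gamma=double_gamma, double_c=double_c)

    return estimator


def selection_report(
    plants: pd.DataFrame,
    visits: pd.DataFrame,
    rates: Mapping[str, float],
    settings: BootstrapSettings | None = None,
    *,
    bases: Sequence[str] = ("visited", "tripped"),
    include_total: bool = True,
    kinds: Iterable[str] = COEFFICIENT_KINDS,
    trait_names: Sequence[str] = TRAIT_NAMES,
    log_offset: float | None = None,
    log_model: Mapping[str, bool] | None = None,
    double_gamma: bool = True,
    double_c: bool = True,
    species: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Full tidy selection report across species, bases, and coefficient kinds.

    One block per species x basis plus the all-bee (total seed set) block.
    Each block carries estimates from untransformed fitness, log-model
    p-values where the log model is enabled for that species (offset defaults
    to 1 when zero fitness is present, 0 otherwise), and percentile bootstrap
    CIs with per-block child seeds split off ``settings.seed``.
    """
    settings = settings or BootstrapSettings()
    settings.validate()
    kinds = tuple(k for k in COEFFICIENT_KINDS if k in set(kinds))
    trait_names = [t for t in trait_names if t in plants.columns]
    if not trait_names:
        raise ValidationError("no trait columns found in plants table")

    clean = plants.dropna(subset=list(trait_names) + ["total_seeds"]).reset_index(drop=True)
    traits_raw = clean[list(trait_names)].to_numpy(dtype=float)
    blocks = _analysis_blocks(clean, visits, rates, bases, include_total, species=species)

    ss = np.random.SeedSequence(settings.seed)
    child_seeds = ss.spawn(len(blocks))
    log_model = dict(log_model or {})

    rows: list[dict] = []
    for (sp, basis, values), child in zip(blocks, child_seeds):
        est_fn = make_block_estimator(kinds=kinds, trait_names=trait_names,
                                      double_gamma=double_gamma, double_c=double_c,
                                      restandardize=settings.restandardize)
        if settings.restandardize:
            data = (traits_raw, values)
        else:
            tm = standardize(clean[list(trait_names)])
            data = (tm.z.to_numpy(), attribution.relative_fitness(values).to_numpy())
        point = est_fn(data)

        use_log = log_model.get(sp, True)
        pvals: Mapping[CoefKey, float] = {}
        if use_log:
            offset = log_offset
            if offset is None:
                offset = 1.0 if (np.asarray(values) == 0).any() else 0.0
            tm = standardize(clean[list(trait_names)])
            w = attribution.relative_fitness(values).to_numpy()
            pvals = pvalues_log_model(tm.z.to_numpy(), w, offset=offset,
                                      trait_names=trait_names, kinds=kinds)

        cis = _bootstrap_core(data, est_fn, settings, np.random.default_rng(child))

        for key, estimate in point.items():
            kind, t1, t2 = key
            lo, hi = cis[key]
            rows.append({
                "species": sp,
                "basis": basis,
                "coefficient_kind": kind,
                "trait_1": t1,
                "trait_2": t2,
                "estimate": estimate,
                "p_log_model": pvals.get(key, np.nan),
                "ci_lower": lo,
                "ci_upper": hi,
                "significant": not (lo <= 0.0 <= hi),
                "B": settings.replicates,
                "seed": settings.seed,
            })
    return pd.DataFrame(rows)
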