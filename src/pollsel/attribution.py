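"""Partition seed set among bee species and compute relative fitness.

Each plant's total seed set is attributed to the visiting species in
proportion to either the flowers they visited ("visited" basis) or the
flowers they tripped ("tripped" basis: visits times the species tripping
rate).  Relative fitness is absolute fitness divided by the group mean, so
it has mean 1 by construction; the opportunity for selection is its sample
variance.

Plants never visited by a species stay in that species' analysis with
fitness 0 (they are real selection targets that received nothing), so
sample sizes match across the all-bee and within-species analyses.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    ConfigurationError,
    DegenerateFitnessError,
    ValidationError,
)

__all__ = [
    "pivot_visits",
    "tripped_counts",
    "species_proportions",
    "attribute_seeds",
    "relative_fitness",
    "opportunity_for_selection",
    "fitness_table",
]

BASES = ("visited", "tripped", "total")


def pivot_visits(visits: pd.DataFrame, species: Sequence[str] | None = None,
                 plant_ids: Sequence | None = None) -> pd.DataFrame:
    """Aggregate a long visit table to a plants x species count matrix.

    Duplicate plant x species rows (multiple observation bouts) are summed.
    ``species``/``plant_ids`` force the output axes, filling absent
    combinations with zero counts.
    """
    required = {"plant_id", "species", "flowers_visited"}
    missing = required - set(visits.columns)
    if missing:
        raise ValidationError(f"visit table missing columns: {sorted(missing)}")
    if (visits["flowers_visited"] < 0).any():
        raise ValidationError("flowers_visited must be nonnegative")
    wide = visits.pivot_table(index="plant_id", columns="species",
                              values="flowers_visited", aggfunc="sum", fill_value=0)
    if species is not None:
        unknown = set(wide.columns) - set(species)
        if unknown:
            raise ValidationError(f"visit table contains unknown species: {sorted(unknown)}")
        wide = wide.reindex(columns=list(species), fill_value=0)
    if plant_ids is not None:
        extra = set(wide.index) - set(plant_ids)
        if extra:
            raise AlignmentError(f"visit table references unknown plant ids: {sorted(extra)[:5]}")
        wide = wide.reindex(plant_ids, fill_value=0)
    wide.columns.name = None
    return wide


def tripped_counts(visits: pd.DataFrame, rates: Mapping[str, float]) -> pd.DataFrame:
    """Scale per-species visit counts by species-specific tripping rates.

    ``visits`` is a plants x species count matrix (see :func:`pivot_visits`).
    Output is real-valued: tripped_is = visits_is * rate_s.
    """
    missing = set(visits.columns) - set(rates)
    if missing:
        raise ConfigurationError(f"missing tripping rate for species: {sorted(missing)}")
    for sp in visits.columns:
        if not 0.0 <= rates[sp] <= 1.0:
            raise ConfigurationError(f"tripping rate for {sp!r} must be in [0, 1]")
    rate_vec = pd.Series({sp: float(rates[sp]) for sp in visits.columns})
    return visits * rate_vec


def species_proportions(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-plant species shares of a count matrix.

    Returns (shares, unvisited).  Shares sum to 1 on each row with at least
    one positive count; all-zero rows get shares of 0 and unvisited=True.
    """
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValidationError("counts must be nonnegative")
    totals = arr.sum(axis=1)
    unvisited = totals == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = np.where(unvisited[:, None], 0.0, arr / np.where(unvisited, 1.0, totals)[:, None])
    shares_df = pd.DataFrame(shares, index=counts.index, columns=counts.columns)
    return shares_df, pd.Series(unvisited, index=counts.index, name="unvisited")


def attribute_seeds(plant_seeds: pd.Series, proportions: pd.DataFrame) -> pd.DataFrame:
    """Split each plant's seed set across species by its share matrix.

    Attribution is the proportional expectation and stays fractional.
    Unvisited plants (all-zero shares) get 0 for every species; their seeds
    still count toward the all-bee basis handled elsewhere.
    """
    if not plant_seeds.index.equals(proportions.index):
        raise AlignmentError("seed column and share matrix must share the same plant index")
    if (plant_seeds < 0).any():
        raise ValidationError("seed counts must be nonnegative")
    return proportions.mul(plant_seeds, axis=0)


def relative_fitness(values) -> pd.Series:
    """Relativize fitness: w_i = value_i / mean(value); mean(w) = 1.

    Raises :class:`DegenerateFitnessError` if every value is zero (the
    species received no seeds anywhere).
    """
    series = pd.Series(values, dtype=float) if not isinstance(values, pd.Series) else values.astype(float)
    if (series < 0).any():
        raise ValidationError("fitness values must be nonnegative")
    mean = series.mean()
    if not mean > 0:
        raise DegenerateFitnessError("all fitness values are zero; cannot relativize")
    return series / mean


def opportunity_for_selection(w) -> float:
    """Sample variance (n-1 denominator) of relative fitness."""
    arr = np.asarray(w, dtype=float)
    if arr.size < 2:
        raise ValidationError("opportunity for selection requires n >= 2")
    return float(np.var(arr, ddof=1))


def fitness_table(
    plants: pd.DataFrame,
    visits: pd.DataFrame,
    rates: Mapping[str, float],
    bases: Iterable[str] = ("visited", "tripped", "total"),
    species: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tidy table of attributed seeds and relative fitness per plant/basis/species.

    The ``total`` basis carries the plant's whole seed set under species
    label ``"all"``.  Every plant with trait+seed data appears in every
    species' rows, zeros included.
    """
    bases = tuple(bases)
    bad = set(bases) - set(BASES)
    if bad:
        raise ConfigurationError(f"unknown fitness bases: {sorted(bad)}")
    if "total_seeds" not in plants.columns:
        raise ValidationError("plants table must carry a total_seeds column")
    seeds = pd.Series(plants["total_seeds"].to_numpy(dtype=float),
                      index=pd.Index(plants["plant_id"], name="plant_id"))

    if species is None:
        species = sorted(visits["species"].unique())
    wide = pivot_visits(visits, species=species, plant_ids=seeds.index)

    frames: list[pd.DataFrame] = []
    for basis in bases:
        if basis == "total":
            w = relative_fitness(seeds)
            frames.append(pd.DataFrame({
                "plant_id": seeds.index,
                "basis": "total",
                "species": "all",
                "attributed_seeds": seeds.to_numpy(),
                "relative_fitness": w.to_numpy(),
            }))
            continue
        counts = wide if basis == "visited" else tripped_counts(wide, rates)
        shares, _unvisited = species_proportions(counts)
        attributed = attribute_seeds(seeds, shares)
        for sp in species:
            w = relative_fitness(attributed[sp])
            frames.append(pd.DataFrame({
                "plant_id": seeds.index,
                "basis": basis,
                "species": sp,
                "attributed_seeds": attributed[sp].to_numpy(),
                "relative_fitness": w.to_numpy(),
            }))
    return pd.concat(frames, ignore_index=True)
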