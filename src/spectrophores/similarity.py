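"""Distances between spectrophores, database ranking, conformer variability.

Spectrophores computed with different settings (notably resolution) are not
comparable; every operation here refuses mixed settings instead of silently
rescaling. Standard deviations use the population (n-denominator) convention
throughout, consistent with the ``std`` normalization mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .chem_io import SpectrophoreRecord

__all__ = [
    "DistanceResult",
    "ConformerVariability",
    "euclidean_distance",
    "rank_database",
    "conformer_variability",
]


@dataclass(frozen=True)
class DistanceResult:
    query_title: str
    target_title: str
    distance: float


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """√Σ (aᵢ − bᵢ)² between two spectrophore vectors of equal length."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    return float(np.linalg.norm(a - b))


def rank_database(
    query: SpectrophoreRecord,
    db: Sequence[SpectrophoreRecord],
    cutoff: float | None = None,
) -> list[DistanceResult]:
    """Rank a spectrophore database by ascending distance to the query.

    Ties keep input order (stable sort); ``cutoff`` retains only results with
    distance ≤ cutoff. Settings must match across query and database.
    """
    for rec in db:
        if rec.settings != query.settings:
            raise ValueError(
                f"settings mismatch between query and database record {rec.title!r}"
            )
    results = [
        DistanceResult(query.title, rec.title, euclidean_distance(query.values, rec.values))
        for rec in db
    ]
    results.sort(key=lambda r: r.distance)  # sort() is stable
    if cutoff is not None:
        results = [r for r in results if r.distance <= cutoff]
    return results


@dataclass
class ConformerVariability:
    """Per-position and summary spread of spectrophores within vs across molecules."""

    within_std: np.ndarray  # per position, averaged over molecules
    across_std: np.ndarray  # per position, first conformer of each molecule
    mean_within: float
    mean_across: float


def conformer_variability(
    groups: Mapping[str, Sequence[SpectrophoreRecord]],
) -> ConformerVariability:
    """Compare conformational with inter-molecular spectrophore variability.

    ``groups`` maps molecule title to that molecule's conformer spectrophores
    (all computed and normalized identically). For every spectrophore
    position the population standard deviation is taken across each
    molecule's conformers (then averaged over molecules) and across molecules
    (first conformer of each); the grand averages over positions summarise
    both.
    """
    if len(groups) < 2:
        raise ValueError("need at least two molecules to compare variability")
    settings = None
    per_molecule_std = []
    firsts = []
    for title, records in groups.items():
        records = list(records)
        if not records:
            raise ValueError(f"molecule {title!r} has no conformers")
        for rec in records:
            if settings is None:
                settings = rec.settings
            elif rec.settings != settings:
                raise ValueError("all spectrophores must share identical settings")
        stack = np.array([rec.values for rec in records])
        per_molecule_std.append(stack.std(axis=0))
        firsts.append(records[0].values)
    within = np.mean(per_molecule_std, axis=0)
    across = np.array(firsts).std(axis=0)
    return ConformerVariability(
        within_std=within,
        across_std=across,
        mean_within=float(within.mean()),
        mean_across=float(across.mean()),
    )
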