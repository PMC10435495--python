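"""Protein-RNA interaction ranking and per-subfamily motif-burden summaries.

Each candidate protein-RNA pair carries three components, each on [0, 1]:

1. normalized interaction propensity -- the predictor's z-score clamped to
   [-4, 4] and mapped linearly to [0, 1];
2. RBP propensity -- 1 for proteins in the precompiled RNA-binding-protein
   library (or similar to one), otherwise a signature score; taken as given;
3. motif component -- 0 / 0.5 / 1 for zero / one / multiple occurrences of
   the protein's RNA-binding motif on the RNA.

The ranking score is the sum of the three, scaled back to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InteractionRecord",
    "RankedInteraction",
    "GroupBurden",
    "BoxStats",
    "normalize_propensity",
    "motif_component",
    "ranking_score",
    "rank_interactions",
    "score_table",
    "motif_burden",
    "box_stats",
]


@dataclass(frozen=True)
class InteractionRecord:
    protein: str
    rna: str
    propensity_z: float
    rbp_propensity: float
    motif_count: int
    subfamily: str = ""

    def __post_init__(self):
        if not (0.0 <= self.rbp_propensity <= 1.0):
            raise ValueError("rbp_propensity must lie in [0, 1]")
        if self.motif_count < 0:
            raise ValueError("motif_count must be >= 0")


@dataclass(frozen=True)
class RankedInteraction:
    record: InteractionRecord
    normalized_propensity: float
    motif_component: float
    ranking_score: float
    rank: int


def normalize_propensity(z: float) -> float:
    """Clamp a propensity z-score to [-4, 4] and map linearly onto [0, 1]."""
    z = float(z)
    if not math.isfinite(z):
        raise ValueError("propensity z-score must be finite")
    return (min(max(z, -4.0), 4.0) + 4.0) / 8.0


def motif_component(n: int) -> float:
    """0 for no motif occurrence, 0.5 for exactly one, 1 for multiple."""
    n = int(n)
    if n < 0:
        raise ValueError("motif count must be >= 0")
    if n == 0:
        return 0.0
    return 0.5 if n == 1 else 1.0


def ranking_score(norm_prop: float, rbp_prop: float, motif_comp: float) -> float:
    """Sum of the three [0,1] components, rescaled to [0, 1] by /3."""
    for name, v in (("norm_prop", norm_prop), ("rbp_prop", rbp_prop), ("motif_comp", motif_comp)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return (norm_prop + rbp_prop + motif_comp) / 3.0


def rank_interactions(
    records: Sequence[InteractionRecord], minmax_rescale: bool = False
) -> list[RankedInteraction]:
    """Score and rank candidate pairs, highest score first.

    Ties share a deterministic order: lexicographic on (protein, rna).  With
    ``minmax_rescale`` the summed score is min-max rescaled over the table
    instead of divided by 3 (the ranking order is identical; a constant table
    maps to 0.5 everywhere).
    """
    if not records:
        raise ValueError("no interaction records supplied")
    seen: set[tuple[str, str]] = set()
    for r in records:
        key = (r.protein, r.rna)
        if key in seen:
            raise ValueError(f"duplicate (protein, rna) pair: {key}")
        seen.add(key)

    norm = [normalize_propensity(r.propensity_z) for r in records]
    mot = [motif_component(r.motif_count) for r in records]
    raw = [n + r.rbp_propensity + m for n, r, m in zip(norm, records, mot)]
    if minmax_rescale:
        lo, hi = min(raw), max(raw)
        scores = [0.5 if hi == lo else (s - lo) / (hi - lo) for s in raw]
    else:
        scores = [s / 3.0 for s in raw]

    order = sorted(
        range(len(records)),
        key=lambda i: (-scores[i], records[i].protein, records[i].rna),
    )
    out: list[RankedInteraction | None] = [None] * len(records)
    for rank, i in enumerate(order, start=1):
        out[i] = RankedInteraction(records[i], norm[i], mot[i], scores[i], rank)
    ranked = [out[i] for i in order]
    return ranked  # sorted by rank


def score_table(frame: pd.DataFrame, minmax_rescale: bool = False) -> pd.DataFrame:
    """Rank a pairs table (protein, rna, subfamily, propensity_z, rbp_propensity, motif_count)."""
    need = {"protein", "rna", "propensity_z", "rbp_propensity", "motif_count"}
    missing = need - set(frame.columns)
    if missing:
        raise ValueError(f"pairs table missing column(s): {sorted(missing)}")
    records = [
        InteractionRecord(
            protein=str(row.protein),
            rna=str(row.rna),
            propensity_z=float(row.propensity_z),
            rbp_propensity=float(row.rbp_propensity),
            motif_count=int(row.motif_count),
            subfamily=str(getattr(row, "subfamily", "")),
        )
        for row in frame.itertuples(index=False)
    ]
    ranked = rank_interactions(records, minmax_rescale=minmax_rescale)
    return pd.DataFrame(
        {
            "protein": [r.record.protein for r in ranked],
            "rna": [r.record.rna for r in ranked],
            "subfamily": [r.record.subfamily for r in ranked],
            "propensity_z": [r.record.propensity_z for r in ranked],
            "rbp_propensity": [r.record.rbp_propensity for r in ranked],
            "motif_count": [r.record.motif_count for r in ranked],
            "normalized_propensity": [r.normalized_propensity for r in ranked],
            "motif_component": [r.motif_component for r in ranked],
            "ranking_score": [r.ranking_score for r in ranked],
            "rank": [r.rank for r in ranked],
        }
    )


@dataclass(frozen=True)
class BoxStats:
    """Five-number boxplot summary; whiskers are quartile +/- 1.5 IQR clipped
    to the observed data range.  Quartiles use linear interpolation between
    order statistics ("type 7")."""

    median: float
    q25: float
    q75: float
    whisker_lo: float
    whisker_hi: float


def box_stats(values: Sequence[float]) -> BoxStats:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("box_stats needs at least one value")
    q25, med, q75 = np.quantile(v, [0.25, 0.5, 0.75])  # linear / type 7
    iqr = q75 - q25
    return BoxStats(
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        whisker_lo=float(max(v.min(), q25 - 1.5 * iqr)),
        whisker_hi=float(min(v.max(), q75 + 1.5 * iqr)),
    )


@dataclass(frozen=True)
class GroupBurden:
    """Motif burden of one subfamily: how many sequences host >=1 motif and
    the distribution of per-sequence motif counts."""

    subfamily: str
    n_sequences: int
    fraction_with_motif: float
    counts: tuple[int, ...]
    box: BoxStats


def motif_burden(
    motif_counts: Mapping[str, int], groups: Mapping[str, str]
) -> list[GroupBurden]:
    """Summarise per-sequence motif counts by subfamily.

    ``motif_counts`` maps sequence id -> number of motif occurrences;
    ``groups`` maps sequence id -> subfamily label.  Every sequence must have
    a group.  Groups are reported in order of first appearance.
    """
    order: list[str] = []
    per_group: dict[str, list[int]] = {}
    for seq_id, count in motif_counts.items():
        if seq_id not in groups:
            raise ValueError(f"sequence {seq_id!r} has no subfamily label")
        g = groups[seq_id]
        if g not in per_group:
            per_group[g] = []
            order.append(g)
        per_group[g].append(int(count))
    out = []
    for g in order:
        counts = per_group[g]
        with_motif = sum(1 for c in counts if c >= 1)
        out.append(
            GroupBurden(
                subfamily=g,
                n_sequences=len(counts),
                fraction_with_motif=with_motif / len(counts),
                counts=tuple(counts),
                box=box_stats(counts),
            )
        )
    return out
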