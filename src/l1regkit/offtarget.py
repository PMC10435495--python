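"""End-to-end k-mismatch scan of shRNA guides against a transcript set.

Every window of guide length in every transcript is compared to the guide
(sense) and to its reverse complement (antisense); windows within the
mismatch budget are reported.  No indels, no seed-region model -- this is
the end-to-end Hamming scan used for shRNA off-target screening.  Hits can
be annotated with an expressed/non-expressed flag from a counts matrix
(CPM >= 2 in at least 3/4 of samples by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from math import ceil
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .g4 import revcomp

__all__ = ["ShRNA", "OfftargetHit", "ExpressionMatrix", "scan", "classify_expressed"]

_GUIDE_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class ShRNA:
    id: str
    guide: str

    def __post_init__(self):
        g = self.guide.upper()
        if not (15 <= len(g) <= 30):
            raise ValueError(f"guide {self.id!r} must be 15-30 nt, got {len(g)}")
        bad = set(g) - _GUIDE_ALPHABET
        if bad:
            raise ValueError(f"guide {self.id!r} has invalid base(s): {sorted(bad)}")
        object.__setattr__(self, "guide", g)


@dataclass(frozen=True)
class OfftargetHit:
    shrna_id: str
    transcript_id: str
    offset: int  # 0-based position of the window start on the transcript
    orientation: str  # "sense" (matches guide) or "antisense" (matches its revcomp)
    mismatches: int
    expressed: bool | None = None


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _window_mismatches(tx: np.ndarray, probe: np.ndarray) -> np.ndarray:
    windows = np.lib.stride_tricks.sliding_window_view(tx, len(probe))
    return (windows != probe).sum(axis=1)


def scan(
    shrna: ShRNA,
    transcripts: Mapping[str, str] | Sequence[tuple[str, str]],
    max_mm: int = 0,
) -> list[OfftargetHit]:
    """Find all end-to-end matches of the guide with <= ``max_mm`` mismatches.

    ``transcripts`` maps transcript id -> sequence (duplicate ids rejected).
    'N' in a transcript mismatches every base.  Hits are ordered by
    (transcript id, offset, orientation).
    """
    if max_mm not in (0, 1, 2):
        raise ValueError("max_mm must be 0, 1 or 2")
    items = list(transcripts.items()) if isinstance(transcripts, Mapping) else list(transcripts)
    if not items:
        raise ValueError("no transcripts supplied")
    ids = [t for t, _ in items]
    if len(set(ids)) != len(ids):
        dup = next(t for t in ids if ids.count(t) > 1)
        raise ValueError(f"duplicate transcript id {dup!r}")

    probes = [("sense", _encode(shrna.guide)), ("antisense", _encode(revcomp(shrna.guide)))]
    glen = len(shrna.guide)
    hits: list[OfftargetHit] = []
    any_searchable = False
    for tx_id, seq in items:
        tx = _encode(seq)
        if tx.size < glen:
            continue
        any_searchable = True
        per_tx = []
        for orientation, probe in probes:
            mm = _window_mismatches(tx, probe)
            for off in np.nonzero(mm <= max_mm)[0]:
                per_tx.append(
                    OfftargetHit(shrna.id, tx_id, int(off), orientation, int(mm[off]))
                )
        per_tx.sort(key=lambda h: (h.offset, h.orientation))
        hits.extend(per_tx)
    if not any_searchable:
        warnings.warn(
            f"guide {shrna.id!r} is longer than every transcript; nothing searched",
            stacklevel=2,
        )
    return hits


class ExpressionMatrix:
    """Gene x sample raw counts with derived counts-per-million."""

    def __init__(self, counts: pd.DataFrame):
        if counts.shape[0] == 0 or counts.shape[1] == 0:
            raise ValueError("expression matrix is empty")
        vals = counts.to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")
        self.counts = counts
        totals = vals.sum(axis=0)
        if np.any(totals == 0):
            raise ValueError("a sample has zero total counts")
        self.cpm = counts / totals * 1e6

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def expressed_genes(self, cpm_min: float = 2.0, sample_fraction: float = 0.75) -> set[str]:
        """Genes with CPM >= ``cpm_min`` in >= ceil(fraction * n_samples) samples."""
        need = ceil(sample_fraction * self.n_samples)
        ok = (self.cpm >= cpm_min).sum(axis=1) >= need
        return set(self.cpm.index[ok])


def classify_expressed(
    hits: Sequence[OfftargetHit],
    expr: ExpressionMatrix,
    cpm_min: float = 2.0,
    sample_fraction: float = 0.75,
) -> list[OfftargetHit]:
    """Annotate hits with the expressed flag (None for transcripts absent
    from the matrix)."""
    expressed = expr.expressed_genes(cpm_min=cpm_min, sample_fraction=sample_fraction)
    known = set(expr.counts.index)
    return [
        replace(h, expressed=(h.transcript_id in expressed) if h.transcript_id in known else None)
        for h in hits
    ]
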