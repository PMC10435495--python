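"""G-quadruplex motifs and positional co-occurrence with protein-binding sites.

Works on panels of LINE-1 (L1) element sequences.  Features (predicted G4s,
predicted protein-binding sites) are half-open, 0-based intervals on a named
sequence.  Positions are pooled across sequences of unequal length by binning
interval starts into fixed-width windows (default 50 bp) and expressing each
bin start as a relative position along its sequence.  Co-occurrence of two
feature sets is tested with a hypergeometric tail over occupied bins -- the
peak-overlap statistic of HOMER's mergePeaks, re-implemented on bins.

The built-in G4 finder matches the canonical pattern only (four G-tracts of
>= ``min_tract`` guanines separated by 1..``max_loop`` nt loops); it does not
reproduce any external scoring model.  Externally predicted G4 intervals with
scores can be loaded from BED instead (score threshold 45 by default).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SequenceRecord",
    "Interval",
    "BinnedProfile",
    "OverlapTestResult",
    "revcomp",
    "find_g4",
    "load_intervals",
    "write_intervals",
    "bin_profile",
    "overlap_test",
    "strand_control",
]

_VALID = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the alphabet {A, C, G, T, N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str
    subfamily: str = ""

    def __post_init__(self):
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"sequence {self.id!r} has invalid residue(s): {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Interval:
    """Half-open, 0-based interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"
    score: float = 0.0
    label: str = ""

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end}) on {self.seq_id!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def _g4_regex(min_tract: int, max_loop: int) -> re.Pattern:
    t, l = int(min_tract), int(max_loop)
    if t < 2 or l < 1:
        raise ValueError("min_tract must be >= 2 and max_loop >= 1")
    loop = f"[ACGTN]{{1,{l}}}?"
    tract = f"(G{{{t},}})"
    return re.compile(tract + (loop + tract) * 3)


def find_g4(
    seq: SequenceRecord, min_tract: int = 3, max_loop: int = 7, strand: str = "+"
) -> list[Interval]:
    """Left-greedy, non-overlapping canonical G4 matches on the given strand.

    The score is the number of guanines in the four G-tracts.  Minus-strand
    hits are found on the reverse complement and reported in plus-strand
    coordinates with ``strand='-'``.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    pattern = _g4_regex(min_tract, max_loop)
    target = seq.sequence if strand == "+" else revcomp(seq.sequence)
    n = len(seq)
    hits = []
    for m in pattern.finditer(target):
        score = float(sum(len(g) for g in m.groups()))
        s, e = m.span()
        if strand == "-":
            s, e = n - e, n - s
        hits.append(Interval(seq.id, s, e, strand=strand, score=score, label="G4"))
    if strand == "-":
        hits.reverse()
    return hits


class BedParseError(ValueError):
    """Malformed BED input, carrying the offending line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def load_intervals(
    path,
    min_score: float = 45.0,
    seq_lengths: Mapping[str, int] | None = None,
) -> list[Interval]:
    """Load BED6 intervals, keeping those with score >= ``min_score``.

    Columns: chrom, start, end, name, score, strand (strand optional,
    defaults to '+').  Coordinates are validated against ``seq_lengths``
    when given.
    """
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise BedParseError(path, lineno, f"expected >= 5 tab-separated fields, got {len(fields)}")
            chrom, start_s, end_s, name, score_s = fields[:5]
            strand = fields[5] if len(fields) > 5 else "+"
            try:
                start, end = int(start_s), int(end_s)
                score = float(score_s)
            except ValueError:
                raise BedParseError(path, lineno, "start/end must be integers and score numeric") from None
            if start < 0 or end <= start:
                raise BedParseError(path, lineno, f"invalid coordinates [{start}, {end})")
            if strand not in ("+", "-"):
                raise BedParseError(path, lineno, f"invalid strand {strand!r}")
            if seq_lengths is not None:
                if chrom not in seq_lengths:
                    raise ValueError(f"{path}:{lineno}: unknown sequence {chrom!r}")
                if end > seq_lengths[chrom]:
                    raise ValueError(
                        f"{path}:{lineno}: interval end {end} exceeds length of {chrom!r} ({seq_lengths[chrom]})"
                    )
            if score >= min_score:
                out.append(Interval(chrom, start, end, strand=strand, score=score, label=name))
    return out


def write_intervals(path, intervals: Iterable[Interval]) -> None:
    """Write intervals as BED6 (name column = interval label)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t{iv.score:g}\t{iv.strand}\n"
            )


def _n_bins(length: int, window: int) -> int:
    return -(-length // window)  # ceil


@dataclass
class BinnedProfile:
    """Feature positions binned into fixed windows, pooled across sequences.

    ``counts`` has one row per occupied (sequence, bin) with the bin start,
    its relative position (bin_start / sequence length) and the number of
    features whose start falls in the bin.  ``relative_positions`` holds one
    sorted entry per assigned feature, from which the cumulative density is
    computed.
    """

    window: int
    counts: pd.DataFrame
    relative_positions: np.ndarray
    n_assigned: int

    @property
    def empty(self) -> bool:
        return self.n_assigned == 0

    def cumulative_density(self) -> pd.DataFrame:
        """Cumulative fraction of features at or before each relative position.

        Undefined (empty frame) for an empty profile.
        """
        if self.empty:
            return pd.DataFrame(columns=["relative_position", "cumdensity"])
        pos, cnt = np.unique(self.relative_positions, return_counts=True)
        return pd.DataFrame(
            {"relative_position": pos, "cumdensity": np.cumsum(cnt) / self.n_assigned}
        )

    def to_frame(self) -> pd.DataFrame:
        """Per-bin table with pooled cumulative density, ordered by relative position."""
        f = self.counts.sort_values(["relative_position", "seq_id"], kind="stable").reset_index(drop=True)
        if self.n_assigned:
            f["cumdensity"] = f["count"].cumsum() / self.n_assigned
        else:
            f["cumdensity"] = np.nan
        return f


def _seq_map(seqs: Sequence[SequenceRecord]) -> dict[str, SequenceRecord]:
    return {s.id: s for s in seqs}


def bin_profile(
    intervals: Sequence[Interval], seqs: Sequence[SequenceRecord], window: int = 50
) -> BinnedProfile:
    """Assign each interval to the bin containing its START position.

    Bins are half-open ``[i*window, (i+1)*window)``; the last bin of a
    sequence may be short.  The relative position of a bin is its start
    divided by the sequence length, so sequences of unequal length pool on a
    common [0, 1) axis.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    by_id = _seq_map(seqs)
    rows: dict[tuple[str, int], int] = {}
    rel_all: list[float] = []
    for iv in intervals:
        if iv.seq_id not in by_id:
            raise ValueError(f"interval references unknown sequence {iv.seq_id!r}")
        length = len(by_id[iv.seq_id])
        if iv.end > length:
            raise ValueError(f"interval [{iv.start}, {iv.end}) exceeds length of {iv.seq_id!r}")
        b = iv.start // window
        rows[(iv.seq_id, b)] = rows.get((iv.seq_id, b), 0) + 1
        rel_all.append((b * window) / length)
    counts = pd.DataFrame(
        [
            {
                "seq_id": sid,
                "bin": b,
                "bin_start": b * window,
                "relative_position": (b * window) / len(by_id[sid]),
                "count": c,
            }
            for (sid, b), c in sorted(rows.items())
        ],
        columns=["seq_id", "bin", "bin_start", "relative_position", "count"],
    )
    return BinnedProfile(
        window=window,
        counts=counts,
        relative_positions=np.sort(np.asarray(rel_all, dtype=float)),
        n_assigned=len(rel_all),
    )


@dataclass(frozen=True)
class OverlapTestResult:
    """Hypergeometric co-occurrence of two feature sets over bins.

    Over all bins of all sequences: ``n_bins`` total, ``a_bins`` hold >= 1
    a-feature, ``b_bins`` >= 1 b-feature, ``both_bins`` both; ``p`` is the
    upper-tail P[X >= both_bins] for X ~ Hypergeometric(n_bins, a_bins,
    b_bins).  ``degenerate`` flags an empty feature set (p fixed at 1).
    """

    n_bins: int
    a_bins: int
    b_bins: int
    both_bins: int
    p: float
    degenerate: bool = False


def _occupied_bins(
    intervals: Sequence[Interval], by_id: Mapping[str, SequenceRecord], window: int
) -> set[tuple[str, int]]:
    out = set()
    for iv in intervals:
        if iv.seq_id not in by_id:
            raise ValueError(f"interval references unknown sequence {iv.seq_id!r}")
        out.add((iv.seq_id, iv.start // window))
    return out


def overlap_test(
    a: Sequence[Interval],
    b: Sequence[Interval],
    seqs: Sequence[SequenceRecord],
    window: int = 50,
) -> OverlapTestResult:
    """Test positional association of feature sets ``a`` and ``b`` over bins."""
    if window < 1:
        raise ValueError("window must be >= 1")
    by_id = _seq_map(seqs)
    n_total = sum(_n_bins(len(s), window) for s in seqs)
    a_occ = _occupied_bins(a, by_id, window)
    b_occ = _occupied_bins(b, by_id, window)
    k = len(a_occ & b_occ)
    if not a_occ or not b_occ:
        return OverlapTestResult(n_total, len(a_occ), len(b_occ), k, 1.0, degenerate=True)
    p = float(stats.hypergeom.sf(k - 1, n_total, len(a_occ), len(b_occ)))
    return OverlapTestResult(n_total, len(a_occ), len(b_occ), k, p)


def strand_control(
    seqs: Sequence[SequenceRecord],
    sites: Sequence[Interval],
    window: int = 50,
    min_tract: int = 3,
    max_loop: int = 7,
) -> OverlapTestResult:
    """Negative control: overlap of MINUS-strand G4 predictions with the sites.

    G4s are re-predicted on the reverse strand of every sequence; a planted
    plus-strand-only co-localization should lose significance here.
    """
    minus = [iv for s in seqs for iv in find_g4(s, min_tract=min_tract, max_loop=max_loop, strand="-")]
    return overlap_test(minus, sites, seqs, window=window)
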