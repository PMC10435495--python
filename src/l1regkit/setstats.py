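"""Gene-set concordance statistics and a resampling overlap-enrichment test.

Differential-expression results enter as tables of ``(gene, log2fc, fdr)``;
the statistics in this module compare the resulting significant gene sets
against gene sets of interest over a background universe of expressed genes.

The enrichment test follows the resampling scheme used throughout the
analysis: the observed overlap between a query set (e.g. the upregulated
genes of one knockdown) and a target set is compared against the overlaps of
``B`` random gene sets of the same size drawn uniformly (without replacement
within a draw) from the expressed-gene universe.  The z-score against the
resampled null is converted to an upper-tail normal p-value, and p-values
across the gene sets tested in one call are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

Direction = Literal["up", "down"]

__all__ = [
    "GeneUniverse",
    "GeneSet",
    "DETable",
    "OverlapSummary",
    "EnrichmentResult",
    "DirectionalConcordance",
    "jaccard",
    "fisher_overlap",
    "resample_enrichment",
    "resample_enrichment_many",
    "bh_adjust",
    "consistent_degs",
    "directional_concordance",
]


def _clean_genes(genes: Iterable[str]) -> list[str]:
    """Strip whitespace and collapse duplicates (with a warning)."""
    out: list[str] = []
    seen: set[str] = set()
    dups = 0
    for g in genes:
        g = str(g).strip()
        if not g:
            continue
        if g in seen:
            dups += 1
            continue
        seen.add(g)
        out.append(g)
    if dups:
        warnings.warn(f"collapsed {dups} duplicate gene identifier(s)", stacklevel=3)
    return out


class GeneUniverse:
    """Ordered, unique background identifiers (the expressed genes)."""

    __slots__ = ("genes", "_index")

    def __init__(self, genes: Iterable[str]):
        self.genes: tuple[str, ...] = tuple(_clean_genes(genes))
        if not self.genes:
            raise ValueError("gene universe must be non-empty")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def __iter__(self):
        return iter(self.genes)

    def indices_of(self, genes: Iterable[str]) -> np.ndarray:
        try:
            return np.fromiter((self._index[g] for g in genes), dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message formatting
            raise ValueError(f"gene {exc.args[0]!r} not in universe") from None

    def __repr__(self) -> str:
        return f"GeneUniverse(n={len(self)})"


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of gene identifiers."""

    label: str
    members: frozenset[str]

    @classmethod
    def from_iterable(cls, label: str, genes: Iterable[str]) -> "GeneSet":
        return cls(label, frozenset(_clean_genes(genes)))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


def _members(s) -> frozenset:
    if isinstance(s, GeneSet):
        return s.members
    return frozenset(s)


@dataclass
class DETable:
    """A differential-expression table: one row per gene.

    ``frame`` must have columns ``gene``, ``log2fc`` and ``fdr``; significance
    is ``fdr <= threshold`` (default 0.05) with direction given by the sign of
    ``log2fc``.
    """

    frame: pd.DataFrame
    threshold: float = 0.05
    label: str = ""

    def __post_init__(self):
        need = {"gene", "log2fc", "fdr"}
        missing = need - set(self.frame.columns)
        if missing:
            raise ValueError(f"DE table missing column(s): {sorted(missing)}")
        if self.frame["gene"].duplicated().any():
            raise ValueError("DE table has duplicated gene rows")
        fdr = self.frame["fdr"].to_numpy(dtype=float)
        if np.any((fdr < 0) | (fdr > 1)) or np.any(~np.isfinite(fdr)):
            raise ValueError("fdr values must lie in [0, 1]")

    def significant(self, direction: Direction) -> GeneSet:
        if direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
        f = self.frame
        sig = f["fdr"] <= self.threshold
        sign = f["log2fc"] > 0 if direction == "up" else f["log2fc"] < 0
        genes = f.loc[sig & sign, "gene"]
        return GeneSet.from_iterable(f"{self.label or 'de'}_{direction}", genes)


def jaccard(a, b) -> float:
    """Jaccard similarity |A∩B| / |A∪B|; 0 when both sets are empty."""
    A, B = _members(a), _members(b)
    union = A | B
    if not union:
        return 0.0
    return len(A & B) / len(union)


@dataclass(frozen=True)
class OverlapSummary:
    jaccard: float
    intersection: int
    fisher_p: float
    odds_ratio: float


def _check_subset(s: frozenset, u: GeneUniverse, name: str) -> None:
    stray = [g for g in s if g not in u]
    if stray:
        raise ValueError(f"{name} contains genes outside the universe (e.g. {stray[0]!r})")


def fisher_overlap(a, b, universe: GeneUniverse) -> OverlapSummary:
    """One-sided (enrichment) Fisher's exact test on the 2x2 membership table."""
    A, B = _members(a), _members(b)
    _check_subset(A, universe, "set a")
    _check_subset(B, universe, "set b")
    n = len(universe)
    k = len(A & B)
    table = [[k, len(A) - k], [len(B) - k, n - len(A) - len(B) + k]]
    odds, p = stats.fisher_exact(table, alternative="greater")
    return OverlapSummary(jaccard=jaccard(A, B), intersection=k, fisher_p=float(p), odds_ratio=float(odds))


@dataclass(frozen=True)
class EnrichmentResult:
    """Resampling overlap enrichment of a query set in a target set."""

    label: str
    k_obs: int
    B: int
    null_mean: float
    null_sd: float
    z: float
    p: float
    q: float | None = None
    exact_fallback: bool = False


def _overlap_null_counts(
    rng: np.random.Generator, n_universe: int, n_query: int, target_mask: np.ndarray, B: int
) -> np.ndarray:
    """Overlap counts of B uniform size-``n_query`` subsets with the target.

    Subsets are drawn without replacement within a draw, independently across
    draws.  For small subsets a vectorised rejection sampler is used; dense
    draws fall back to per-row partial selection of random keys.
    """
    if n_query * n_query <= n_universe:
        draws = rng.integers(0, n_universe, size=(B, n_query))
        while True:
            srt = np.sort(draws, axis=1)
            bad = np.nonzero((np.diff(srt, axis=1) == 0).any(axis=1))[0]
            if bad.size == 0:
                break
            draws[bad] = rng.integers(0, n_universe, size=(bad.size, n_query))
        return target_mask[draws].sum(axis=1)
    keys = rng.random((B, n_universe))
    idx = np.argpartition(keys, n_query - 1, axis=1)[:, :n_query]
    return target_mask[idx].sum(axis=1)


def resample_enrichment(
    query,
    target,
    universe: GeneUniverse,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
    alternative: Literal["greater", "less"] = "greater",
    label: str | None = None,
) -> EnrichmentResult:
    """Resampling overlap-enrichment test of ``query`` against ``target``.

    ``B`` random subsets of the universe, each of size ``|query|``, yield a
    null distribution of overlap counts with ``target``.  The observed overlap
    is standardised against that null (sample sd, ddof=1) and converted to an
    upper-tail normal p-value (lower-tail under ``alternative="less"``).  When
    the null is degenerate (sd = 0) the exact hypergeometric tail is used and
    the result is flagged via ``exact_fallback``.
    """
    Q, T = _members(query), _members(target)
    if not Q or not T:
        raise ValueError("query and target must be non-empty")
    if B < 2:
        raise ValueError("B must be >= 2")
    _check_subset(Q, universe, "query")
    _check_subset(T, universe, "target")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(universe)
    k_obs = len(Q & T)
    mask = np.zeros(n, dtype=bool)
    mask[universe.indices_of(T)] = True

    counts = _overlap_null_counts(rng, n, len(Q), mask, B)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1))
    lab = label if label is not None else getattr(target, "label", "target")

    if sd == 0.0:
        # degenerate null (e.g. |query| == |universe|): exact hypergeometric tail
        if alternative == "greater":
            p = float(stats.hypergeom.sf(k_obs - 1, n, len(T), len(Q)))
        else:
            p = float(stats.hypergeom.cdf(k_obs, n, len(T), len(Q)))
        return EnrichmentResult(lab, k_obs, B, mean, sd, math.nan, p, exact_fallback=True)

    z = (k_obs - mean) / sd
    p = float(stats.norm.sf(z)) if alternative == "greater" else float(stats.norm.cdf(z))
    return EnrichmentResult(lab, k_obs, B, mean, sd, float(z), p)


def resample_enrichment_many(
    query,
    targets: Sequence[GeneSet],
    universe: GeneUniverse,
    B: int = 1000,
    seed: int | None = None,
    alternative: Literal["greater", "less"] = "greater",
) -> list[EnrichmentResult]:
    """Run :func:`resample_enrichment` for each target and BH-adjust jointly.

    The BH family is the set of gene sets tested in this one call.
    """
    if not targets:
        raise ValueError("no target gene sets supplied")
    ss = np.random.SeedSequence(seed)
    results = [
        resample_enrichment(
            query, t, universe, B=B, seed=np.random.default_rng(child), alternative=alternative
        )
        for t, child in zip(targets, ss.spawn(len(targets)))
    ]
    qvals = bh_adjust([r.p for r in results])
    return [replace(r, q=float(q)) for r, q in zip(results, qvals)]


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def consistent_degs(comparisons: Sequence[DETable], direction: Direction) -> GeneSet:
    """Genes significant with the stated direction in every comparison."""
    if len(comparisons) == 0:
        raise ValueError("no DE tables supplied")
    if len(comparisons) < 2:
        raise ValueError("need at least two DE tables to intersect")
    sets = [t.significant(direction).members for t in comparisons]
    core = frozenset.intersection(*sets)
    return GeneSet(f"consistent_{direction}", core)


@dataclass(frozen=True)
class DirectionalConcordance:
    """Partition of genes significant in both tables, by sign pattern."""

    up_up: GeneSet
    down_down: GeneSet
    up_down: GeneSet
    down_up: GeneSet

    def counts(self) -> dict[str, int]:
        return {
            "up_up": len(self.up_up),
            "down_down": len(self.down_down),
            "up_down": len(self.up_down),
            "down_up": len(self.down_up),
        }


def directional_concordance(de_x: DETable, de_y: DETable) -> DirectionalConcordance:
    """Classify genes significant in both tables by direction pattern.

    ``up_down`` holds genes up in ``de_x`` and down in ``de_y`` -- the
    "opposite pattern" comparison between two experimental systems.
    """
    ux, dx = de_x.significant("up").members, de_x.significant("down").members
    uy, dy = de_y.significant("up").members, de_y.significant("down").members
    return DirectionalConcordance(
        up_up=GeneSet("up_up", ux & uy),
        down_down=GeneSet("down_down", dx & dy),
        up_down=GeneSet("up_down", ux & dy),
        down_up=GeneSet("down_up", dx & uy),
    )
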