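"""Small quantification formulas: ddCt knockdown, radial cell distribution,
bisulfite peak-height methylation and subcellular fraction percentages.

All operations take plain tables or scalars and return typed results; none
fit statistical models beyond mean and standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KnockdownResult",
    "RadialDistribution",
    "MethylationCall",
    "FractionProfile",
    "ddct",
    "radial_distribution",
    "methylation_percent",
    "fraction_percent",
]


@dataclass(frozen=True)
class KnockdownResult:
    """ddCt relative quantification of a target against a reference gene.

    dCt = mean(Ct_target) - mean(Ct_reference), per condition;
    ddCt = dCt_treated - dCt_control; relative expression = 2^-ddCt
    (100 % primer efficiency); knockdown % = 100 * (1 - relative expression).
    ``ddct_sem`` propagates replicate s.e.m. of the four Ct means;
    ``rel_expr_sem`` follows by the delta method.
    """

    target: str
    reference: str
    dct_control: float
    dct_treated: float
    ddct: float
    rel_expr: float
    kd_percent: float
    ddct_sem: float
    rel_expr_sem: float


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(x))
    if x.size < 2:
        return m, 0.0
    return m, float(np.std(x, ddof=1) / math.sqrt(x.size))


def ddct(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    control: str = "control",
    treated: str = "treated",
    efficiency_base: float = 2.0,
) -> KnockdownResult:
    """Compute ddCt knockdown from a long-form Ct table.

    ``ct`` needs columns ``condition``, ``gene`` and ``ct`` with one row per
    replicate measurement; replicates are aggregated by the arithmetic mean
    of Ct (geometric mean on the expression scale).
    """
    need = {"condition", "gene", "ct"}
    missing = need - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")

    stats = {}
    for cond in (control, treated):
        for gene in (target, reference):
            vals = ct.loc[(ct["condition"] == cond) & (ct["gene"] == gene), "ct"].to_numpy(float)
            if vals.size == 0:
                raise ValueError(f"no Ct replicates for gene {gene!r} in condition {cond!r}")
            stats[(cond, gene)] = _mean_sem(vals)

    dct_c = stats[(control, target)][0] - stats[(control, reference)][0]
    dct_t = stats[(treated, target)][0] - stats[(treated, reference)][0]
    dd = dct_t - dct_c
    sem = math.sqrt(sum(s**2 for _, s in stats.values()))
    rel = efficiency_base ** (-dd)
    rel_sem = rel * math.log(efficiency_base) * sem  # delta method
    return KnockdownResult(
        target=target,
        reference=reference,
        dct_control=dct_c,
        dct_treated=dct_t,
        ddct=dd,
        rel_expr=rel,
        kd_percent=100.0 * (1.0 - rel),
        ddct_sem=sem,
        rel_expr_sem=rel_sem,
    )


@dataclass(frozen=True)
class RadialDistribution:
    """Percentage of cells per radial bin; bin 1 is anchored at the pia."""

    n_bins: int
    percentages: tuple[float, ...]
    counts: tuple[int, ...]


def radial_distribution(depths, n_bins: int = 10) -> RadialDistribution:
    """Bin relative depths (0 = pia, 1 = white matter) into equal-sized bins.

    Bins are half-open ``[i/n, (i+1)/n)``; depth exactly 1 is closed into the
    last bin.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    d = np.asarray(depths, dtype=float)
    if d.size == 0:
        raise ValueError("no cell depths supplied")
    if np.any((d < 0) | (d > 1)) or np.any(~np.isfinite(d)):
        raise ValueError("depths must lie in [0, 1]")
    idx = np.minimum((d * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    pct = 100.0 * counts / d.size
    return RadialDistribution(n_bins=n_bins, percentages=tuple(pct), counts=tuple(int(c) for c in counts))


@dataclass(frozen=True)
class MethylationCall:
    cpg_position: int
    g_height: float
    a_height: float
    percent: float


def methylation_percent(g: float, a: float) -> float:
    """Percent methylation from reverse-strand chromatogram peak heights.

    After bisulfite conversion an unmethylated C reads as T (A on the reverse
    strand) while a methylated C stays C (G on the reverse strand), so
    %methylation = 100 * G / (G + A).
    """
    if g < 0 or a < 0:
        raise ValueError("peak heights must be non-negative")
    if g + a == 0:
        raise ValueError("undefined: both peak heights are zero")
    return 100.0 * g / (g + a)


@dataclass(frozen=True)
class FractionProfile:
    """Subcellular distribution of one RNA as percentages of total."""

    target: str
    cytosol: float
    nucleoplasm: float
    chromatin: float


def fraction_percent(
    cytosol: float, nucleoplasm: float, chromatin: float, target: str = ""
) -> FractionProfile:
    """Express per-compartment RNA levels as percentages of their total."""
    levels = np.array([cytosol, nucleoplasm, chromatin], dtype=float)
    if np.any(levels < 0):
        raise ValueError("compartment levels must be non-negative")
    total = levels.sum()
    if total == 0:
        raise ValueError("all compartment levels are zero")
    pct = 100.0 * levels / total
    return FractionProfile(target=target, cytosol=pct[0], nucleoplasm=pct[1], chromatin=pct[2])
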