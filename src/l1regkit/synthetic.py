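"""Synthetic inputs with machine-readable planted truth.

Every generator here emulates one class of input the analysis consumes --
differential-expression tables with exact planted intersections, L1-like
sequence panels with planted G-quadruplexes and binding-site intervals, Ct
tables with planted knockdown fractions, transcript sets with planted
off-target sites, radial cell positions, bisulfite chromatogram peak heights
and subcellular fractionation levels -- and returns, alongside the data, a
:class:`TruthRecord` stating exactly what was planted.  Under zero noise
every planted quantity is recoverable exactly by the corresponding analysis
stage, which is the backbone of the recovery tests.

Reproducibility: a single root seed expands into per-artifact child streams
through a fixed spawn-key schedule (one integer key per artifact kind, see
``ARTIFACT_KEYS``), so adding a generator never perturbs the output of an
earlier one and identical configuration + seed yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .g4 import Interval, SequenceRecord, revcomp
from .offtarget import ExpressionMatrix, ShRNA
from .setstats import DETable, GeneUniverse

__all__ = [
    "ARTIFACT_KEYS",
    "TruthRecord",
    "DESpec",
    "SubfamilySeqSpec",
    "SeqSpec",
    "CtSpec",
    "PlantedSite",
    "OfftargetSpec",
    "FractionSpec",
    "FRACTION_DEFAULTS",
    "gen_universe",
    "gen_de_tables",
    "gen_l1_sequences",
    "gen_ct_table",
    "gen_transcriptome",
    "gen_radial_cells",
    "gen_chromatogram",
    "gen_fraction_qpcr",
]

# Fixed child-seed schedule: seed -> SeedSequence(seed, spawn_key=(key,)).
ARTIFACT_KEYS = {
    "universe": 0,
    "de": 1,
    "sequences": 2,
    "ct": 3,
    "transcriptome": 4,
    "radial": 5,
    "chromatogram": 6,
    "fractions": 7,
}


def _rng(seed: int, artifact: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(ARTIFACT_KEYS[artifact],)))


@dataclass(frozen=True)
class TruthRecord:
    """What was planted into one generated artifact."""

    artifact: str
    seed: int
    truth: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(artifact=d["artifact"], seed=d["seed"], truth=d["truth"])


# --------------------------------------------------------------------------- #
# gene universe and DE tables

def gen_universe(n: int, seed: int = 0) -> GeneUniverse:
    """``n`` unique synthetic gene tokens G000001...; deterministic."""
    if n < 1:
        raise ValueError("universe size must be >= 1")
    return GeneUniverse(f"G{i:06d}" for i in range(1, n + 1))


@dataclass(frozen=True)
class DESpec:
    """Per-condition up/down set sizes with exact planted intersections.

    Following the exact-intersection construction, one common core per
    direction is sampled first and shared by ALL conditions, then disjoint
    per-condition remainders are added -- so every pairwise intersection
    equals the core size exactly.  ``opposite`` plants a block of genes
    upregulated in the first condition and downregulated in the second (the
    opposite-pattern comparison between model systems).
    """

    conditions: tuple[str, ...]
    n_up: Mapping[str, int]
    n_down: Mapping[str, int]
    common_up: int = 0
    common_down: int = 0
    opposite: int = 0
    threshold: float = 0.05

    def _unique_counts(self) -> tuple[dict[str, int], dict[str, int]]:
        if len(self.conditions) < 1:
            raise ValueError("need at least one condition")
        if self.opposite and len(self.conditions) < 2:
            raise ValueError("opposite block needs at least two conditions")
        uu, ud = {}, {}
        first, second = self.conditions[0], self.conditions[1] if len(self.conditions) > 1 else None
        for c in self.conditions:
            up = self.n_up[c] - self.common_up - (self.opposite if c == first else 0)
            down = self.n_down[c] - self.common_down - (self.opposite if c == second else 0)
            if up < 0 or down < 0:
                raise ValueError(
                    f"requested intersections exceed set sizes for condition {c!r}"
                )
            uu[c], ud[c] = up, down
        return uu, ud

    def total_genes_needed(self) -> int:
        uu, ud = self._unique_counts()
        return self.common_up + self.common_down + self.opposite + sum(uu.values()) + sum(ud.values())


def gen_de_tables(
    universe: GeneUniverse, spec: DESpec, seed: int
) -> tuple[dict[str, DETable], TruthRecord]:
    """Generate one DE table per condition with exact planted set structure.

    Members of the planted sets get fdr <= threshold and a log2FC whose sign
    matches the direction; all other genes are clearly non-significant.
    """
    need = spec.total_genes_needed()
    if need > len(universe):
        raise ValueError(f"spec needs {need} genes but universe has {len(universe)}")
    uu, ud = spec._unique_counts()
    rng = _rng(seed, "de")
    genes = np.array(universe.genes)
    perm = genes[rng.permutation(len(genes))]

    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        chunk = perm[cursor : cursor + k]
        cursor += k
        return list(chunk)

    core_up = take(spec.common_up)
    core_down = take(spec.common_down)
    opposite = take(spec.opposite)
    unique_up = {c: take(uu[c]) for c in spec.conditions}
    unique_down = {c: take(ud[c]) for c in spec.conditions}

    first = spec.conditions[0]
    second = spec.conditions[1] if len(spec.conditions) > 1 else None
    up_sets = {
        c: set(core_up) | set(unique_up[c]) | (set(opposite) if c == first else set())
        for c in spec.conditions
    }
    down_sets = {
        c: set(core_down) | set(unique_down[c]) | (set(opposite) if c == second else set())
        for c in spec.conditions
    }

    tables: dict[str, DETable] = {}
    n = len(genes)
    for c in spec.conditions:
        fdr = rng.uniform(2 * spec.threshold, 1.0, size=n)
        lfc = rng.uniform(-0.3, 0.3, size=n)
        up_idx = universe.indices_of(sorted(up_sets[c]))
        down_idx = universe.indices_of(sorted(down_sets[c]))
        fdr[up_idx] = rng.uniform(1e-8, spec.threshold, size=up_idx.size)
        fdr[down_idx] = rng.uniform(1e-8, spec.threshold, size=down_idx.size)
        lfc[up_idx] = rng.uniform(0.5, 5.0, size=up_idx.size)
        lfc[down_idx] = -rng.uniform(0.5, 5.0, size=down_idx.size)
        frame = pd.DataFrame({"gene": genes, "log2fc": lfc, "fdr": fdr})
        tables[c] = DETable(frame, threshold=spec.threshold, label=c)

    truth = TruthRecord(
        artifact="de_tables",
        seed=seed,
        truth={
            "conditions": list(spec.conditions),
            "up": {c: sorted(up_sets[c]) for c in spec.conditions},
            "down": {c: sorted(down_sets[c]) for c in spec.conditions},
            "common_up": sorted(core_up),
            "common_down": sorted(core_down),
            "opposite_up_down": sorted(opposite),
            "pairwise_intersection_up": spec.common_up,
            "pairwise_intersection_down": spec.common_down,
        },
    )
    return tables, truth


# --------------------------------------------------------------------------- #
# L1-like sequence panels

_G4_TRACT = "GGGG"
_G4_LOOP = "TTA"
G4_UNIT = _G4_TRACT + (_G4_LOOP + _G4_TRACT) * 3  # 25 bp, 16 tract guanines


@dataclass(frozen=True)
class SubfamilySeqSpec:
    """One subfamily's panel: sequence count, length and planted features."""

    n_sequences: int
    length: int
    n_g4: int = 0
    g4_zone: tuple[float, float] = (0.5, 1.0)  # fraction of length; default 3' half
    n_g4_minus: int = 0
    motif_intervals: tuple[tuple[int, int], ...] = ()

    def validate(self) -> None:
        if self.n_sequences < 0 or self.n_g4 < 0 or self.n_g4_minus < 0:
            raise ValueError("counts must be >= 0")
        if self.length < 300:
            raise ValueError("sequence length must be >= 300 bp")
        if not (0.0 <= self.g4_zone[0] < self.g4_zone[1] <= 1.0):
            raise ValueError("g4_zone must be an increasing pair of fractions in [0, 1]")
        for s, e in self.motif_intervals:
            if not (0 <= s < e <= self.length):
                raise ValueError(f"planted motif [{s}, {e}) exceeds sequence bounds")


@dataclass(frozen=True)
class SeqSpec:
    """Panel of subfamilies plus background composition.

    Background residues are uniform over A/C/T with G at frequency ``g_freq``
    outside planted tracts, so the accidental-G4 rate is controllable; with
    ``g_freq=0`` no accidental canonical G4 can occur and planted features
    are recovered exactly.
    """

    subfamilies: Mapping[str, SubfamilySeqSpec]
    g_freq: float = 0.10
    motif_label: str = "Suz12_site"
    motif_score: float = 50.0

    def validate(self) -> None:
        if not (0.0 <= self.g_freq < 1.0):
            raise ValueError("g_freq must lie in [0, 1)")
        for sub in self.subfamilies.values():
            sub.validate()


def _place_nonoverlapping(
    rng: np.random.Generator, lo: int, hi: int, unit_len: int, n: int, occupied: list[tuple[int, int]]
) -> list[int]:
    """Random non-overlapping unit starts in [lo, hi); 1 bp flank margin."""
    if n == 0:
        return []
    if hi - unit_len < lo:
        raise ValueError("planted feature does not fit in the requested zone")
    starts: list[int] = []
    for _ in range(10_000):
        if len(starts) == n:
            break
        cand = int(rng.integers(lo, hi - unit_len + 1))
        span = (cand - 1, cand + unit_len + 1)
        if all(span[1] <= s or span[0] >= e for s, e in occupied):
            occupied.append(span)
            starts.append(cand)
    if len(starts) < n:
        raise ValueError("could not place planted features without overlap")
    return sorted(starts)


def gen_l1_sequences(
    spec: SeqSpec, seed: int
) -> tuple[list[SequenceRecord], list[Interval], TruthRecord]:
    """Generate a labelled sequence panel with planted G4s and motif intervals.

    Returns the sequences, the truth intervals (plus- and minus-strand G4s
    and the motif/binding-site intervals, BED-ready) and the truth record.
    Planted G4 units are flanked by 'T' so the canonical finder recovers each
    planted interval exactly.
    """
    spec.validate()
    rng = _rng(seed, "sequences")
    p_g = spec.g_freq
    p_other = (1.0 - p_g) / 3.0
    bases = np.array(list("ACTG"))
    probs = np.array([p_other, p_other, p_other, p_g])
    unit_plus = np.array(list(G4_UNIT))
    unit_minus = np.array(list(revcomp(G4_UNIT)))
    unit_len = len(G4_UNIT)

    seqs: list[SequenceRecord] = []
    intervals: list[Interval] = []
    truth_seqs: dict[str, dict] = {}
    for sub_name, sub in spec.subfamilies.items():
        for i in range(sub.n_sequences):
            seq_id = f"{sub_name}_{i + 1:03d}"
            arr = rng.choice(bases, size=sub.length, p=probs)
            occupied: list[tuple[int, int]] = []
            lo = int(sub.g4_zone[0] * sub.length)
            hi = int(sub.g4_zone[1] * sub.length)
            plus_starts = _place_nonoverlapping(rng, lo, hi, unit_len, sub.n_g4, occupied)
            minus_starts = _place_nonoverlapping(rng, 0, sub.length, unit_len, sub.n_g4_minus, occupied)
            for s in plus_starts:
                arr[s : s + unit_len] = unit_plus
            for s in minus_starts:
                arr[s : s + unit_len] = unit_minus
            for s in plus_starts + minus_starts:
                if s > 0:
                    arr[s - 1] = "T"
                if s + unit_len < sub.length:
                    arr[s + unit_len] = "T"
            seqs.append(SequenceRecord(id=seq_id, sequence="".join(arr), subfamily=sub_name))
            for s in plus_starts:
                intervals.append(Interval(seq_id, s, s + unit_len, "+", 16.0, "G4"))
            for s in minus_starts:
                intervals.append(Interval(seq_id, s, s + unit_len, "-", 16.0, "G4"))
            for ms, me in sub.motif_intervals:
                intervals.append(Interval(seq_id, ms, me, "+", spec.motif_score, spec.motif_label))
            truth_seqs[seq_id] = {
                "subfamily": sub_name,
                "length": sub.length,
                "g4_plus": [[s, s + unit_len] for s in plus_starts],
                "g4_minus": [[s, s + unit_len] for s in minus_starts],
                "motifs": [[int(ms), int(me)] for ms, me in sub.motif_intervals],
            }

    truth = TruthRecord(
        artifact="l1_sequences",
        seed=seed,
        truth={"g_freq": spec.g_freq, "motif_label": spec.motif_label, "sequences": truth_seqs},
    )
    return seqs, intervals, truth


# --------------------------------------------------------------------------- #
# Ct tables

@dataclass(frozen=True)
class CtSpec:
    """Planted knockdown fractions per target assay.

    The treated-sample delta-Ct is shifted by -log2(1 - kd) relative to
    control, so the ddCt pipeline recovers ``kd`` exactly at zero noise.
    ``noise_sd`` is the Gaussian s.d. of the replicate-level delta-Ct: it is
    applied to the target-gene Ct while reference replicates are generated at
    their nominal value (noise on the reference would enter both conditions
    and inflate the ddCt variance beyond the replicate delta-Ct noise).
    """

    knockdown: Mapping[str, float]
    replicates: int = 3
    noise_sd: float = 0.0
    base_ct_target: float = 24.0
    base_ct_reference: float = 18.0
    reference: str = "Ref"

    def validate(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for t, kd in self.knockdown.items():
            if not (0.0 <= kd < 1.0):
                raise ValueError(f"knockdown fraction for {t!r} must lie in [0, 1)")


def gen_ct_table(spec: CtSpec, seed: int) -> tuple[pd.DataFrame, TruthRecord]:
    """Long-form Ct table: columns assay, condition, gene, replicate, ct."""
    spec.validate()
    rng = _rng(seed, "ct")
    rows = []
    for target, kd in spec.knockdown.items():
        shift = -np.log2(1.0 - kd)
        for condition in ("control", "treated"):
            for gene, base in ((target, spec.base_ct_target), (spec.reference, spec.base_ct_reference)):
                mu = base + (shift if condition == "treated" and gene == target else 0.0)
                noisy = gene == target  # noise rides on the replicate delta-Ct
                for rep in range(1, spec.replicates + 1):
                    rows.append(
                        {
                            "assay": target,
                            "condition": condition,
                            "gene": gene,
                            "replicate": rep,
                            "ct": mu + (rng.normal(0.0, spec.noise_sd) if noisy else 0.0),
                        }
                    )
    truth = TruthRecord(
        artifact="ct_table",
        seed=seed,
        truth={
            "knockdown_percent": {t: 100.0 * kd for t, kd in spec.knockdown.items()},
            "reference": spec.reference,
            "noise_sd": spec.noise_sd,
            "replicates": spec.replicates,
        },
    )
    return pd.DataFrame(rows), truth


# --------------------------------------------------------------------------- #
# transcriptomes with planted off-target sites

@dataclass(frozen=True)
class PlantedSite:
    guide_id: str
    transcript_index: int
    mismatches: int = 0
    orientation: str = "sense"
    offset: int | None = None


@dataclass(frozen=True)
class OfftargetSpec:
    guides: Mapping[str, str]
    n_transcripts: int = 20
    transcript_length: int = 1000
    planted: tuple[PlantedSite, ...] = ()
    n_samples: int = 4
    expressed_transcripts: tuple[int, ...] | None = None  # indices; default: first half

    def validate(self) -> None:
        if self.n_transcripts < 1 or self.n_samples < 1:
            raise ValueError("transcript and sample counts must be >= 1")
        for gid, g in self.guides.items():
            ShRNA(gid, g)  # validates length and alphabet
            if len(g) > self.transcript_length:
                raise ValueError("transcript length must be >= guide length")
        for site in self.planted:
            if site.guide_id not in self.guides:
                raise ValueError(f"planted site references unknown guide {site.guide_id!r}")
            if not (0 <= site.transcript_index < self.n_transcripts):
                raise ValueError("planted site transcript index out of range")
            if site.mismatches not in (0, 1, 2):
                raise ValueError("planted mismatches must be 0, 1 or 2")
            if site.orientation not in ("sense", "antisense"):
                raise ValueError("orientation must be 'sense' or 'antisense'")


def _mutate(rng: np.random.Generator, seq: str, n_mismatches: int) -> str:
    arr = list(seq)
    pos = rng.choice(len(arr), size=n_mismatches, replace=False)
    for p in pos:
        others = [b for b in "ACGT" if b != arr[p]]
        arr[p] = others[int(rng.integers(0, 3))]
    return "".join(arr)


def gen_transcriptome(
    spec: OfftargetSpec, seed: int
) -> tuple[dict[str, str], ExpressionMatrix, TruthRecord]:
    """Random transcript set with planted guide sites and an expression matrix.

    Library sizes are scaled so that transcripts flagged expressed sit far
    above the 2-CPM filter while unexpressed ones (0/1 raw counts) sit below.
    """
    spec.validate()
    rng = _rng(seed, "transcriptome")
    tx_ids = [f"T{i + 1:04d}" for i in range(spec.n_transcripts)]
    arrs = {
        tid: rng.choice(np.array(list("ACGT")), size=spec.transcript_length)
        for tid in tx_ids
    }

    occupied: dict[str, list[tuple[int, int]]] = {tid: [] for tid in tx_ids}
    planted_truth = []
    for site in spec.planted:
        tid = tx_ids[site.transcript_index]
        guide = spec.guides[site.guide_id]
        glen = len(guide)
        inserted = _mutate(rng, guide, site.mismatches) if site.mismatches else guide
        if site.orientation == "antisense":
            inserted = revcomp(inserted)
        if site.offset is None:
            offset = None
            for _ in range(1000):
                cand = int(rng.integers(0, spec.transcript_length - glen + 1))
                if all(cand + glen <= s or cand >= e for s, e in occupied[tid]):
                    offset = cand
                    break
            if offset is None:
                raise ValueError("could not place planted site without overlap")
        else:
            offset = site.offset
            if offset + glen > spec.transcript_length:
                raise ValueError("planted site exceeds transcript length")
        occupied[tid].append((offset, offset + glen))
        arrs[tid][offset : offset + glen] = np.array(list(inserted))
        planted_truth.append(
            {
                "guide_id": site.guide_id,
                "transcript_id": tid,
                "offset": int(offset),
                "orientation": site.orientation,
                "mismatches": int(site.mismatches),
            }
        )

    transcripts = {tid: "".join(a) for tid, a in arrs.items()}

    if spec.expressed_transcripts is None:
        expressed_idx = tuple(range(spec.n_transcripts // 2 or 1))
    else:
        expressed_idx = spec.expressed_transcripts
    expressed_ids = {tx_ids[i] for i in expressed_idx}
    if not expressed_ids:
        raise ValueError("at least one transcript must be expressed")
    lam = 1e6 / len(expressed_ids)
    counts = pd.DataFrame(
        {
            f"S{j + 1}": [
                int(rng.poisson(lam)) if tid in expressed_ids else int(rng.integers(0, 2))
                for tid in tx_ids
            ]
            for j in range(spec.n_samples)
        },
        index=tx_ids,
    )
    expr = ExpressionMatrix(counts)

    truth = TruthRecord(
        artifact="transcriptome",
        seed=seed,
        truth={
            "planted_sites": planted_truth,
            "expressed": {tid: (tid in expressed_ids) for tid in tx_ids},
            "n_samples": spec.n_samples,
        },
    )
    return transcripts, expr, truth


# --------------------------------------------------------------------------- #
# radial positions, chromatograms, fractionation

def gen_radial_cells(
    n: int, bin_weights: Sequence[float], seed: int
) -> tuple[np.ndarray, TruthRecord]:
    """Sample ``n`` relative depths in [0, 1) from planted per-bin weights."""
    w = np.asarray(bin_weights, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    if w.size < 1 or np.any(w < 0):
        raise ValueError("bin weights must be non-negative")
    if w.sum() == 0:
        raise ValueError("bin weights must not all be zero")
    p = w / w.sum()
    rng = _rng(seed, "radial")
    counts = rng.multinomial(n, p)
    k = w.size
    depths = np.concatenate(
        [rng.uniform(i / k, (i + 1) / k, size=c) for i, c in enumerate(counts)]
    )
    rng.shuffle(depths)
    truth = TruthRecord(
        artifact="radial_cells",
        seed=seed,
        truth={"weights_percent": (100.0 * p).tolist(), "bin_counts": counts.tolist()},
    )
    return depths, truth


def gen_chromatogram(
    methylation_percent: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    peak_scale: float = 1000.0,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Peak-height table (cpg, g_height, a_height) with planted methylation.

    ``noise_sd`` is Gaussian peak-height noise as a fraction of
    ``peak_scale``; heights are clipped at zero.
    """
    m = np.asarray(methylation_percent, dtype=float)
    if m.size == 0:
        raise ValueError("no CpG methylation values supplied")
    if np.any((m < 0) | (m > 100)):
        raise ValueError("methylation percentages must lie in [0, 100]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed, "chromatogram")
    g = np.clip(peak_scale * m / 100.0 + rng.normal(0, noise_sd * peak_scale, m.size), 0, None)
    a = np.clip(peak_scale * (1 - m / 100.0) + rng.normal(0, noise_sd * peak_scale, m.size), 0, None)
    frame = pd.DataFrame({"cpg": np.arange(1, m.size + 1), "g_height": g, "a_height": a})
    truth = TruthRecord(
        artifact="chromatogram",
        seed=seed,
        truth={"methylation_percent": m.tolist(), "noise_sd": noise_sd},
    )
    return frame, truth


def _split_remainder(chromatin: float) -> tuple[float, float, float]:
    rem = 100.0 - chromatin
    return (0.4 * rem, 0.6 * rem, chromatin)  # (cytosol, nucleoplasm, chromatin)


#: Default subcellular proportions (cytosol, nucleoplasm, chromatin) in %,
#: chromatin-dominant as in chromatin-associated L1 RNAs; the non-chromatin
#: remainder is split 60/40 nucleoplasm/cytosol.
FRACTION_DEFAULTS: dict[str, tuple[float, float, float]] = {
    "L1MdA": _split_remainder(90.64),
    "L1MdGf": _split_remainder(92.12),
    "L1MdTf": _split_remainder(94.35),
}


@dataclass(frozen=True)
class FractionSpec:
    """Planted subcellular proportions per target RNA (percent, summing 100)."""

    targets: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(FRACTION_DEFAULTS)
    )
    replicates: int = 3
    noise_sd: float = 0.02  # lognormal sd on compartment levels

    def validate(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for t, props in self.targets.items():
            p = np.asarray(props, dtype=float)
            if p.size != 3 or np.any(p < 0) or p.sum() == 0:
                raise ValueError(f"proportions for {t!r} must be three non-negative values")


def gen_fraction_qpcr(spec: FractionSpec, seed: int) -> tuple[pd.DataFrame, TruthRecord]:
    """Compartment RNA levels (target, replicate, compartment, level)."""
    spec.validate()
    rng = _rng(seed, "fractions")
    compartments = ("cytosol", "nucleoplasm", "chromatin")
    rows = []
    truth_pct = {}
    for target, props in spec.targets.items():
        p = np.asarray(props, dtype=float)
        p = 100.0 * p / p.sum()
        truth_pct[target] = p.tolist()
        for rep in range(1, spec.replicates + 1):
            noise = np.exp(rng.normal(0.0, spec.noise_sd, size=3))
            for comp, level in zip(compartments, p * noise):
                rows.append(
                    {"target": target, "replicate": rep, "compartment": comp, "level": level}
                )
    truth = TruthRecord(
        artifact="fraction_qpcr",
        seed=seed,
        truth={"percent": truth_pct, "noise_sd": spec.noise_sd, "replicates": spec.replicates},
    )
    return pd.DataFrame(rows), truth
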