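"""Config-driven orchestration of the analysis stages.

A single :class:`RunConfig` (typically loaded from YAML) selects stages and
carries their parameters plus one root seed.  Stages run in dependency
order -- synthetic data first, then the analysis stages on its outputs --
and every file a stage writes is listed in the :class:`RunReport`.  Stage
outputs are plain files with stable names under the output directory; a
re-run with the same config and seed reproduces them byte for byte.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, quant, ranking, setstats
from . import g4 as g4mod
from . import offtarget as otmod
from . import synthetic as synth
from .offtarget import ExpressionMatrix, ShRNA

STAGES = ("synthetic", "setstats", "ranking", "g4", "quant", "offtarget")

__all__ = ["STAGES", "RunConfig", "RunReport", "StageReport", "demo_config", "run"]


class ConfigError(ValueError):
    """Invalid run configuration (raised before any stage executes)."""


@dataclass
class RunConfig:
    seed: int
    stages: tuple[str, ...]
    params: dict

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        seed = int(d.get("seed", 0))
        raw = d.get("stages", "all")
        stages = tuple(STAGES) if raw in ("all", None) else tuple(raw)
        unknown = [s for s in stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stage(s): {unknown}; known: {list(STAGES)}")
        return cls(seed=seed, stages=stages, params=d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError("config must be a mapping")
        return cls.from_dict(d)

    def stage_params(self, name: str) -> dict:
        p = self.params.get(name, {})
        if p is None:
            p = {}
        if not isinstance(p, dict):
            raise ConfigError(f"parameters for stage {name!r} must be a mapping")
        return p


@dataclass
class StageReport:
    name: str
    params: dict
    outputs: list[str]
    stats: dict
    wallclock_s: float
    warnings: list[str] = field(default_factory=list)


@dataclass
class RunReport:
    seed: int
    version: str
    stages: list[StageReport]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "version": self.version,
                    "stages": [vars(s) for s in self.stages],
                },
                fh,
                indent=1,
            )


def demo_config(seed: int = 0) -> RunConfig:
    """A small end-to-end configuration exercising every stage."""
    return RunConfig.from_dict(
        {
            "seed": seed,
            "stages": "all",
            "synthetic": {
                "universe_size": 2000,
                "de": {
                    "conditions": ["shL1a", "shL1b"],
                    "n_up": {"shL1a": 200, "shL1b": 240},
                    "n_down": {"shL1a": 180, "shL1b": 150},
                    "common_up": 120,
                    "common_down": 90,
                    "opposite": 25,
                },
                "sequences": {
                    "g_freq": 0.05,
                    "subfamilies": {
                        "L1MdTf": {
                            "n_sequences": 4,
                            "length": 3000,
                            "n_g4": 3,
                            "g4_zone": [0.80, 0.86],
                            "n_g4_minus": 1,
                            "motif_intervals": [[2400, 2440], [2450, 2490], [2500, 2540]],
                        },
                        "L1MdA": {
                            "n_sequences": 4,
                            "length": 3000,
                            "n_g4": 1,
                            "motif_intervals": [[400, 440]],
                        },
                    },
                },
                "ct": {
                    "knockdown": {"L1MdA": 0.60, "L1MdGf": 0.56, "L1MdTf": 0.54},
                    "replicates": 3,
                    "noise_sd": 0.1,
                },
                "offtarget": {
                    "guides": {
                        "shL1-a": "GATTCGCGGATACCGTTAAGC",
                        "shL1-b": "CCATGGTACGTTAGCAGTCAT",
                    },
                    "n_transcripts": 16,
                    "transcript_length": 800,
                    "planted": [
                        {"guide_id": "shL1-a", "transcript_index": 2, "mismatches": 0},
                        {"guide_id": "shL1-b", "transcript_index": 9, "mismatches": 1},
                    ],
                },
                "radial": {"n": 5000, "bin_weights": [2, 3, 4, 5, 5, 4, 3, 2, 1, 1]},
                "chromatogram": {"methylation_percent": [95, 80, 60, 30, 10], "noise_sd": 0.02},
                "fractions": {},
            },
            "setstats": {"B": 1000},
            "g4": {"window": 50, "min_score": 45.0},
            "offtarget": {"max_mm": 1},
        }
    )


# --------------------------------------------------------------------------- #
# stage implementations

def _stage_synthetic(cfg: RunConfig, outdir: Path) -> tuple[list[Path], dict]:
    p = cfg.stage_params("synthetic")
    seed = cfg.seed
    d = outdir / "synthetic"
    d.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    stats: dict = {}

    universe = synth.gen_universe(int(p.get("universe_size", 2000)), seed)
    upath = d / "universe.txt"
    upath.write_text("\n".join(universe.genes) + "\n")
    outputs.append(upath)
    stats["universe_size"] = len(universe)

    de_p = p.get("de")
    if de_p:
        spec = synth.DESpec(
            conditions=tuple(de_p["conditions"]),
            n_up=de_p["n_up"],
            n_down=de_p["n_down"],
            common_up=int(de_p.get("common_up", 0)),
            common_down=int(de_p.get("common_down", 0)),
            opposite=int(de_p.get("opposite", 0)),
        )
        tables, truth = synth.gen_de_tables(universe, spec, seed)
        for cond, t in tables.items():
            path = d / f"de_{cond}.tsv"
            io.write_table(path, t.frame)
            outputs.append(path)
        truth.to_json(d / "truth_de.json")
        outputs.append(d / "truth_de.json")

    seq_p = p.get("sequences")
    if seq_p:
        spec = synth.SeqSpec(
            subfamilies={
                name: synth.SubfamilySeqSpec(
                    n_sequences=int(s["n_sequences"]),
                    length=int(s["length"]),
                    n_g4=int(s.get("n_g4", 0)),
                    g4_zone=tuple(s.get("g4_zone", (0.5, 1.0))),
                    n_g4_minus=int(s.get("n_g4_minus", 0)),
                    motif_intervals=tuple(tuple(iv) for iv in s.get("motif_intervals", [])),
                )
                for name, s in seq_p["subfamilies"].items()
            },
            g_freq=float(seq_p.get("g_freq", 0.10)),
        )
        seqs, intervals, truth = synth.gen_l1_sequences(spec, seed)
        io.write_fasta(d / "sequences.fa", seqs)
        io.write_intervals(d / "g4_truth.bed", [iv for iv in intervals if iv.label == "G4"])
        io.write_intervals(d / "sites.bed", [iv for iv in intervals if iv.label != "G4"])
        truth.to_json(d / "truth_sequences.json")
        outputs += [d / "sequences.fa", d / "g4_truth.bed", d / "sites.bed", d / "truth_sequences.json"]
        stats["n_sequences"] = len(seqs)

    ct_p = p.get("ct")
    if ct_p:
        spec = synth.CtSpec(
            knockdown=ct_p["knockdown"],
            replicates=int(ct_p.get("replicates", 3)),
            noise_sd=float(ct_p.get("noise_sd", 0.0)),
        )
        frame, truth = synth.gen_ct_table(spec, seed)
        io.write_table(d / "ct.tsv", frame)
        truth.to_json(d / "truth_ct.json")
        outputs += [d / "ct.tsv", d / "truth_ct.json"]

    ot_p = p.get("offtarget")
    if ot_p:
        spec = synth.OfftargetSpec(
            guides=ot_p["guides"],
            n_transcripts=int(ot_p.get("n_transcripts", 20)),
            transcript_length=int(ot_p.get("transcript_length", 1000)),
            planted=tuple(synth.PlantedSite(**s) for s in ot_p.get("planted", [])),
            n_samples=int(ot_p.get("n_samples", 4)),
        )
        transcripts, expr, truth = synth.gen_transcriptome(spec, seed)
        io.write_fasta(
            d / "transcripts.fa",
            [g4mod.SequenceRecord(tid, s) for tid, s in transcripts.items()],
        )
        io.write_table(d / "counts.tsv", expr.counts.rename_axis("gene").reset_index())
        io.write_table(
            d / "guides.tsv",
            pd.DataFrame({"id": list(spec.guides), "sequence": list(spec.guides.values())}),
        )
        truth.to_json(d / "truth_transcriptome.json")
        outputs += [d / "transcripts.fa", d / "counts.tsv", d / "guides.tsv", d / "truth_transcriptome.json"]

    r_p = p.get("radial")
    if r_p:
        depths, truth = synth.gen_radial_cells(int(r_p["n"]), r_p["bin_weights"], seed)
        io.write_table(d / "radial.tsv", pd.DataFrame({"depth": depths}))
        truth.to_json(d / "truth_radial.json")
        outputs += [d / "radial.tsv", d / "truth_radial.json"]

    ch_p = p.get("chromatogram")
    if ch_p:
        frame, truth = synth.gen_chromatogram(
            ch_p["methylation_percent"], noise_sd=float(ch_p.get("noise_sd", 0.0)), seed=seed
        )
        io.write_table(d / "chromatogram.tsv", frame)
        truth.to_json(d / "truth_chromatogram.json")
        outputs += [d / "chromatogram.tsv", d / "truth_chromatogram.json"]

    if "fractions" in p:
        f_p = p.get("fractions") or {}
        spec = synth.FractionSpec(
            targets=f_p.get("targets", dict(synth.FRACTION_DEFAULTS)),
            replicates=int(f_p.get("replicates", 3)),
            noise_sd=float(f_p.get("noise_sd", 0.02)),
        )
        frame, truth = synth.gen_fraction_qpcr(spec, seed)
        io.write_table(d / "fractions.tsv", frame)
        truth.to_json(d / "truth_fractions.json")
        outputs += [d / "fractions.tsv", d / "truth_fractions.json"]

    return outputs, stats


def _stage_setstats(cfg: RunConfig, outdir: Path) -> tuple[list[Path], dict]:
    p = cfg.stage_params("setstats")
    sdir = outdir / "synthetic"
    universe = io.read_universe(sdir / "universe.txt")
    de_paths = sorted(sdir.glob("de_*.tsv"))
    tables = [io.read_de_table(path, label=path.stem.removeprefix("de_")) for path in de_paths]
    if len(tables) < 2:
        raise ConfigError("setstats stage needs at least two DE tables")
    d = outdir / "setstats"
    d.mkdir(parents=True, exist_ok=True)

    a, b = tables[0], tables[1]
    rows = []
    for direction in ("up", "down"):
        sa, sb = a.significant(direction), b.significant(direction)
        summary = setstats.fisher_overlap(sa, sb, universe)
        rows.append(
            {
                "direction": direction,
                "set_a": sa.label,
                "set_b": sb.label,
                "n_a": len(sa),
                "n_b": len(sb),
                "intersection": summary.intersection,
                "jaccard": summary.jaccard,
                "fisher_p": summary.fisher_p,
                "odds_ratio": summary.odds_ratio,
            }
        )
    conc = pd.DataFrame(rows)
    io.write_table(d / "concordance.tsv", conc)

    dirc = setstats.directional_concordance(a, b)
    io.write_table(
        d / "directional.tsv",
        pd.DataFrame([dirc.counts()]),
    )

    consistent = {
        direction: setstats.consistent_degs(tables, direction) for direction in ("up", "down")
    }
    for direction, gs in consistent.items():
        io.write_gene_set(d / f"consistent_{direction}.txt", gs)

    query = a.significant("up")
    targets = [b.significant("up"), b.significant("down")]
    results = setstats.resample_enrichment_many(
        query, targets, universe, B=int(p.get("B", 1000)), seed=cfg.seed
    )
    enr = pd.DataFrame(
        [
            {
                "set": r.label,
                "k_obs": r.k_obs,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "z": r.z,
                "p": r.p,
                "q": r.q,
            }
            for r in results
        ]
    )
    io.write_table(d / "enrichment.tsv", enr)
    stats = {
        "jaccard_up": conc.loc[conc.direction == "up", "jaccard"].iloc[0],
        "jaccard_down": conc.loc[conc.direction == "down", "jaccard"].iloc[0],
        "n_consistent_up": len(consistent["up"]),
        "n_consistent_down": len(consistent["down"]),
        "opposite_up_down": dirc.counts()["up_down"],
    }
    return [d / "concordance.tsv", d / "directional.tsv", d / "consistent_up.txt",
            d / "consistent_down.txt", d / "enrichment.tsv"], stats


def demo_interaction_table(seed: int) -> pd.DataFrame:
    """A small candidate protein-RNA table with one dominant binder."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(100,)))
    proteins = ["Suz12", "Ezh2", "Eed", "Cbx5", "Pcgf1", "Rbbp7"]
    rnas = [f"L1_{i + 1:02d}" for i in range(6)]
    rows = []
    for prot in proteins:
        for rna in rnas:
            dominant = prot == "Suz12"
            rows.append(
                {
                    "protein": prot,
                    "rna": rna,
                    "subfamily": "L1MdTf" if int(rna[-2:]) % 2 else "L1MdA",
                    "propensity_z": float(rng.normal(3.0 if dominant else 0.0, 0.5)),
                    "rbp_propensity": 1.0 if dominant else round(float(rng.uniform(0.3, 0.9)), 3),
                    "motif_count": int(rng.integers(2, 5)) if dominant else int(rng.integers(0, 2)),
                }
            )
    return pd.DataFrame(rows)


def _stage_ranking(cfg: RunConfig, outdir: Path) -> tuple[list[Path], dict]:
    p = cfg.stage_params("ranking")
    pairs_path = p.get("pairs")
    frame = io.read_table(pairs_path) if pairs_path else demo_interaction_table(cfg.seed)
    ranked = ranking.score_table(frame, minmax_rescale=bool(p.get("minmax_rescale", False)))
    d = outdir / "ranking"
    d.mkdir(parents=True, exist_ok=True)
    io.write_table(d / "ranked.tsv", ranked)
    top = ranked.iloc[0]
    return [d / "ranked.tsv"], {"top_protein": top.protein, "top_score": float(top.ranking_score)}


def _stage_g4(cfg: RunConfig, outdir: Path) -> tuple[list[Path], dict]:
    p = cfg.stage_params("g4")
    window = int(p.get("window", 50))
    min_score = float(p.get("min_score", 45.0))
    sdir = outdir / "synthetic"
    seqs = io.read_fasta(sdir / "sequences.fa")
    lengths = {s.id: len(s) for s in seqs}
    sites = io.load_intervals(sdir / "sites.bed", min_score=min_score, seq_lengths=lengths)
    g4_hits = [iv for s in seqs for iv in g4mod.find_g4(s)]
    d = outdir / "g4"
    d.mkdir(parents=True, exist_ok=True)
    io.write_intervals(d / "g4_found.bed", g4_hits)
    io.write_table(d / "g4_profile.tsv", g4mod.bin_profile(g4_hits, seqs, window).to_frame())
    io.write_table(d / "sites_profile.tsv", g4mod.bin_profile(sites, seqs, window).to_frame())
    test = g4mod.overlap_test(g4_hits, sites, seqs, window=window)
    control = g4mod.strand_control(seqs, sites, window=window)
    with open(d / "overlap.json", "w") as fh:
        json.dump({"test": vars(test), "minus_strand_control": vars(control)}, fh, indent=1)
    return (
        [d / "g4_found.bed", d / "g4_profile.tsv", d / "sites_profile.tsv", d / "overlap.json"],
        {"n_g4": len(g4_hits), "overlap_p": test.p, "control_p": control.p},
    )


def _stage_quant(cfg: RunConfig, outdir: Path) -> tuple[list[Path], dict]:
    sdir = outdir / "synthetic"
    d = outdir / "quant"
    d.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    stats: dict = {}

    ct_path = sdir / "ct.tsv"
    if ct_path.exists():
        ct = io.read_table(ct_path)
        rows = []
        for assay in ct["assay"].unique():
            sub = ct[ct["assay"] == assay]
            ref = [g for g in sub["gene"].unique() if g != assay][0]
            kd = quant.ddct(sub, target=assay, reference=ref)
            rows.append(
                {
                    "target": assay,
                    "ddct": kd.ddct,
                    "rel_expr": kd.rel_expr,
                    "kd_percent": kd.kd_percent,
                    "ddct_sem": kd.ddct_sem,
                }
            )
        io.write_table(d / "knockdown.tsv", pd.DataFrame(rows))
        outputs.append(d / "knockdown.tsv")
        stats["kd_percent"] = {r["target"]: r["kd_percent"] for r in rows}

    rad_path = sdir / "radial.tsv"
    if rad_path.exists():
        depths = io.read_table(rad_path)["depth"].to_numpy()
        dist = quant.radial_distribution(depths)
        io.write_table(
            d / "radial_distribution.tsv",
            pd.DataFrame(
                {"bin": range(1, dist.n_bins + 1), "percent": dist.percentages, "count": dist.counts}
            ),
        )
        outputs.append(d / "radial_distribution.tsv")

    chrom_path = sdir / "chromatogram.tsv"
    if chrom_path.exists():
        chrom = io.read_table(chrom_path)
        chrom["methylation_percent"] = [
            quant.methylation_percent(g, a) for g, a in zip(chrom["g_height"], chrom["a_height"])
        ]
        io.write_table(d / "methylation.tsv", chrom)
        outputs.append(d / "methylation.tsv")

    frac_path = sdir / "fractions.tsv"
    if frac_path.exists():
        fr = io.read_table(frac_path)
        rows = []
        for target, sub in fr.groupby("target", sort=False):
            means = sub.groupby("compartment", sort=False)["level"].mean()
            prof = quant.fraction_percent(
                means["cytosol"], means["nucleoplasm"], means["chromatin"], target=target
            )
            rows.append(vars(prof))
        io.write_table(d / "fractions.tsv", pd.DataFrame(rows))
        outputs.append(d / "fractions.tsv")
        stats["chromatin_percent"] = {r["target"]: r["chromatin"] for r in rows}

    return outputs, stats


def _stage_offtarget(cfg: RunConfig, outdir: Path) -> tuple[list[Path], dict]:
    p = cfg.stage_params("offtarget")
    max_mm = int(p.get("max_mm", 0))
    sdir = outdir / "synthetic"
    guides = io.read_table(sdir / "guides.tsv")
    seqs = io.read_fasta(sdir / "transcripts.fa")
    transcripts = {s.id: s.sequence for s in seqs}
    counts = io.read_table(sdir / "counts.tsv").set_index("gene")
    expr = ExpressionMatrix(counts)
    rows = []
    for g in guides.itertuples(index=False):
        hits = otmod.scan(ShRNA(g.id, g.sequence), transcripts, max_mm=max_mm)
        hits = otmod.classify_expressed(hits, expr)
        rows += [vars(h) for h in hits]
    d = outdir / "offtarget"
    d.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        rows, columns=["shrna_id", "transcript_id", "offset", "orientation", "mismatches", "expressed"]
    )
    io.write_table(d / "hits.tsv", frame)
    return [d / "hits.tsv"], {"n_hits": len(frame)}


_STAGE_FUNCS = {
    "synthetic": _stage_synthetic,
    "setstats": _stage_setstats,
    "ranking": _stage_ranking,
    "g4": _stage_g4,
    "quant": _stage_quant,
    "offtarget": _stage_offtarget,
}

_STAGE_INPUTS = {
    "setstats": ("synthetic/universe.txt",),
    "g4": ("synthetic/sequences.fa", "synthetic/sites.bed"),
    "quant": (),
    "offtarget": ("synthetic/guides.tsv", "synthetic/transcripts.fa", "synthetic/counts.tsv"),
}


def _validate(cfg: RunConfig, outdir: Path) -> None:
    """Fail before any stage runs: unknown stages are caught at parse time;
    here we check that each selected stage will find its inputs."""
    will_generate = "synthetic" in cfg.stages
    for stage in cfg.stages:
        pairs_path = cfg.stage_params("ranking").get("pairs") if stage == "ranking" else None
        if pairs_path and not Path(pairs_path).exists():
            raise ConfigError(f"ranking pairs table not found: {pairs_path}")
        for rel in _STAGE_INPUTS.get(stage, ()):
            if not will_generate and not (outdir / rel).exists():
                raise ConfigError(f"stage {stage!r} needs missing input {outdir / rel}")


def run(config: RunConfig, outdir) -> RunReport:
    """Execute the selected stages in dependency order.

    Raises :class:`ConfigError` before anything runs if the configuration is
    invalid; a failure inside a stage aborts the run with the stage named.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _validate(config, outdir)
    reports: list[StageReport] = []
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                outputs, stats = _STAGE_FUNCS[stage](config, outdir)
            except ConfigError:
                raise
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        reports.append(
            StageReport(
                name=stage,
                params=config.stage_params(stage),
                outputs=[str(o) for o in outputs],
                stats=stats,
                wallclock_s=round(time.perf_counter() - t0, 4),
                warnings=[str(w.message) for w in caught],
            )
        )
    report = RunReport(seed=config.seed, version=__version__, stages=reports)
    report.to_json(outdir / "run_report.json")
    return report
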