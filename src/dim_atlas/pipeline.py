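"""Stage orchestration: design -> simulate -> quantify -> score -> analyze.

A run is driven by one structured config (YAML) whose defaults are the
assay's processing constants (20% flank mismatch budget, Phred 30, 10-read
and 1000-read input filters, FDR 0.1). Every stage writes its outputs under
the run directory and appends an entry (parameters, input/output SHA-256
hashes) to a manifest, so a run is resumable stage by stage and reruns with
the same seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atlas as atlas_mod
from .library import ABETA42, DesignParams, build_library, library_from_csv
from .quantify import TrimSettings, apply_read_filters, quantify_samples, write_qc_report
from .scoring import NucleationModel
from .simulate import SimulationConfig, emit_fastq, simulate_dataset

STAGES = ("design", "simulate", "quantify", "score", "analyze")


@dataclass
class RunConfig:
    out_dir: str = "run"
    wt: str = ABETA42
    seed: int = 0
    # design
    gap_range: tuple[int, int] | None = None
    max_del_len: int = 39
    # simulate
    depth: int = 1_000_000
    n_bio: int = 3
    n_tech: int = 5
    sigma_rep: float = 0.1
    err_rate: float = 0.0
    emit_reads: bool = False
    # quantify / filters
    max_mismatch_frac: float = 0.20
    min_phred: int = 30
    min_input_reads: int = 10
    single_nt_min_input: int = 1000
    # score
    fdr: float = 0.1
    fdr_method: str = "fdr_bh"
    error_model: str = "additive"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineError(RuntimeError):
    pass


class Manifest:
    def __init__(self, path: Path) -> None:
        self.path = path
        self.entries = (
            json.loads(path.read_text()) if path.exists() else []
        )

    def record(self, stage: str, params: dict, inputs: list[Path], outputs: list[Path]):
        self.entries = [e for e in self.entries if e["stage"] != stage]
        self.entries.append(
            {
                "stage": stage,
                "params": params,
                "inputs": {str(p): _sha256(p) for p in inputs},
                "outputs": {str(p): _sha256(p) for p in outputs},
            }
        )
        self.path.write_text(json.dumps(self.entries, indent=2, sort_keys=True))


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Execute the requested stages in order under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    manifest = Manifest(out / "manifest.json")
    for stage in STAGES:
        if stage in stages:
            _RUNNERS[stage](cfg, out, manifest)
    return out


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage '{needed_by}' needs {path.name}; run stage '{stage}' first"
        )
    return path


def _stage_design(cfg: RunConfig, out: Path, manifest: Manifest) -> None:
    lib = build_library(
        cfg.wt, DesignParams(gap_range=cfg.gap_range, max_del_len=cfg.max_del_len)
    )
    lib.to_csv(out / "library.csv")
    lib.to_fasta(out / "library.fa")
    manifest.record(
        "design",
        {"wt": cfg.wt, "gap_range": cfg.gap_range, "max_del_len": cfg.max_del_len},
        [],
        [out / "library.csv", out / "library.fa"],
    )


def _sim_config(cfg: RunConfig) -> SimulationConfig:
    return SimulationConfig(
        depth=cfg.depth,
        n_bio=cfg.n_bio,
        n_tech=cfg.n_tech,
        sigma_rep=cfg.sigma_rep,
        err_rate=cfg.err_rate,
        seed=cfg.seed,
    )


def _stage_simulate(cfg: RunConfig, out: Path, manifest: Manifest) -> None:
    lib_csv = _require(out / "library.csv", "design", "simulate")
    lib = library_from_csv(lib_csv)
    sim = _sim_config(cfg)
    effects, counts = simulate_dataset(lib, sim)
    effects.to_csv(out / "truth.csv", index=False)
    counts.to_csv(out / "counts_true.csv", index=False)
    outputs = [out / "truth.csv", out / "counts_true.csv"]
    if cfg.emit_reads:
        rng = np.random.default_rng(sim.seed + 2)
        sheet = emit_fastq(counts, lib, out / "reads", sim, rng)
        sheet.to_csv(out / "samples.csv", index=False)
        outputs.append(out / "samples.csv")
    manifest.record(
        "simulate",
        {"seed": cfg.seed, "depth": cfg.depth, "n_bio": cfg.n_bio,
         "n_tech": cfg.n_tech, "sigma_rep": cfg.sigma_rep, "err_rate": cfg.err_rate},
        [lib_csv],
        outputs,
    )


def _stage_quantify(cfg: RunConfig, out: Path, manifest: Manifest) -> None:
    lib_csv = _require(out / "library.csv", "design", "quantify")
    lib = library_from_csv(lib_csv)
    sim = _sim_config(cfg)
    sheet_csv = out / "samples.csv"
    if sheet_csv.exists():
        sheet = pd.read_csv(sheet_csv)
        settings = TrimSettings(
            flank5=sim.flank5,
            flank3=sim.flank3,
            max_mismatch_frac=cfg.max_mismatch_frac,
            min_phred=cfg.min_phred,
        )
        counts, qc = quantify_samples(sheet, lib, settings)
        write_qc_report(qc, out / "qc.json")
        inputs = [sheet_csv]
    else:
        # count-level simulation: pass the simulator's table through
        counts_csv = _require(out / "counts_true.csv", "simulate", "quantify")
        counts = pd.read_csv(counts_csv)
        inputs = [counts_csv]
    counts = apply_read_filters(
        counts, lib,
        min_input_reads=cfg.min_input_reads,
        single_nt_min_input=cfg.single_nt_min_input,
    )
    counts.to_csv(out / "counts.csv", index=False)
    manifest.record(
        "quantify",
        {"min_phred": cfg.min_phred, "max_mismatch_frac": cfg.max_mismatch_frac,
         "min_input_reads": cfg.min_input_reads,
         "single_nt_min_input": cfg.single_nt_min_input},
        [lib_csv, *inputs],
        [out / "counts.csv"],
    )


def _stage_score(cfg: RunConfig, out: Path, manifest: Manifest) -> None:
    counts_csv = _require(out / "counts.csv", "quantify", "score")
    counts = pd.read_csv(counts_csv)
    for col in ("variant_id", "bio_rep", "count_in", "count_out"):
        if col not in counts.columns:
            raise PipelineError(f"counts file {counts_csv} lacks column '{col}'")
    results = NucleationModel(counts, error_model=cfg.error_model).fit(
        fdr=cfg.fdr, fdr_method=cfg.fdr_method
    )
    results.to_csv(out / "scores.csv")
    (out / "scores_meta.json").write_text(
        json.dumps(
            {
                "log_base": "e",
                "fdr": cfg.fdr,
                "fdr_method": cfg.fdr_method,
                "error_model": cfg.error_model,
                "sigma_add": results.sigma_add,
                "phi": results.phi,
                "schema_version": 1,
            },
            indent=2,
            sort_keys=True,
        )
    )
    manifest.record(
        "score",
        {"fdr": cfg.fdr, "fdr_method": cfg.fdr_method, "error_model": cfg.error_model},
        [counts_csv],
        [out / "scores.csv", out / "scores_meta.json"],
    )


def _stage_analyze(cfg: RunConfig, out: Path, manifest: Manifest) -> None:
    lib_csv = _require(out / "library.csv", "design", "analyze")
    scores_csv = _require(out / "scores.csv", "score", "analyze")
    lib = library_from_csv(lib_csv)
    scores = pd.read_csv(scores_csv, index_col="variant_id")
    adir = out / "analysis"
    adir.mkdir(exist_ok=True)
    scheme = atlas_mod.RegionScheme() if len(lib.wt) == 42 else None

    outputs = []
    if scheme is not None:
        freq = atlas_mod.class_frequency_table(scores, lib, scheme)
        freq.to_csv(adir / "class_frequencies.csv", index=False)
        outputs.append(adir / "class_frequencies.csv")

        cores = atlas_mod.alternative_core_scan(lib, scores, scheme)
        cores.to_csv(adir / "alternative_cores.csv", index=False)
        outputs.append(adir / "alternative_cores.csv")

    matrix = atlas_mod.deletion_effect_matrix(scores, lib)
    matrix.to_csv(adir / "deletion_matrix.csv", index=False)
    outputs.append(adir / "deletion_matrix.csv")

    hotspots = {}
    for axis in ("first_del", "last_del"):
        marg = atlas_mod.marginal_frequencies(matrix, by=axis)
        marg.to_csv(adir / f"marginal_{axis}.csv", index=False)
        outputs.append(adir / f"marginal_{axis}.csv")
        pos = marg[marg["effect_class"] == "NS+"].set_index("position")["frequency"]
        hotspots[axis] = atlas_mod.detect_hotspot(pos)
    (adir / "hotspot.json").write_text(json.dumps(hotspots, indent=2))
    outputs.append(adir / "hotspot.json")

    trunc = atlas_mod.truncation_series(scores, lib)
    trunc.to_csv(adir / "truncation_series.csv", index=False)
    outputs.append(adir / "truncation_series.csv")

    manifest.record("analyze", {}, [lib_csv, scores_csv], outputs)


_RUNNERS = {
    "design": _stage_design,
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "score": _stage_score,
    "analyze": _stage_analyze,
}
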