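"""Delimited-text + JSON-manifest persistence for every pipeline stage.

Every output directory carries a ``manifest.json`` holding the configuration,
seeds and code version used to produce it, so a run can be reproduced exactly
from its outputs alone.  Matrices are stored as tab-separated text, one file
per subject per variant for cohorts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .pipelines import PipelineGrid, build_grid
from .search import LandscapeEstimate, SearchTrace
from .space import EmbeddedSpace, SimilarityTable
from .synthetic_data import SubjectDataset, SyntheticCohortConfig


def _safe_name(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]", "__", label)


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _prepare_dir(outdir: Path, force: bool) -> Path:
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()):
        if not force:
            raise FileExistsError(
                f"{outdir} is not empty; pass force=True (--force) to overwrite"
            )
        for p in sorted(outdir.rglob("*"), reverse=True):
            p.unlink() if p.is_file() else p.rmdir()
    outdir.mkdir(parents=True, exist_ok=True)
    return outdir


def manifest_hash(outdir: Path) -> str:
    """SHA-256 of the manifest, for idempotence checks."""
    return hashlib.sha256((Path(outdir) / "manifest.json").read_bytes()).hexdigest()


def write_cohort(dataset: SubjectDataset, outdir: Path, force: bool = False) -> Path:
    outdir = _prepare_dir(Path(outdir), force)
    variant_dirs = {}
    for label, block in dataset.variants.items():
        name = _safe_name(label)
        variant_dirs[label] = name
        vdir = outdir / "variants" / name
        vdir.mkdir(parents=True, exist_ok=True)
        for sid, matrix in zip(dataset.subject_ids, block):
            np.savetxt(vdir / f"{sid}.tsv", matrix, delimiter="\t")
    manifest = {
        "kind": "cohort",
        "version": __version__,
        "subject_ids": dataset.subject_ids,
        "targets": [float(t) for t in dataset.targets],
        "task": dataset.task,
        "data_kind": dataset.data_kind,
        "split": None if dataset.split is None else list(map(str, dataset.split)),
        "communities": {k: [int(c) for c in v] for k, v in dataset.communities.items()},
        "variant_dirs": variant_dirs,
        "config": None if dataset.config is None else dataclasses.asdict(dataset.config),
    }
    _write_json(outdir / "manifest.json", manifest)
    return outdir


def read_cohort(outdir: Path) -> SubjectDataset:
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    variants = {}
    for label, name in manifest["variant_dirs"].items():
        vdir = outdir / "variants" / name
        block = [
            np.loadtxt(vdir / f"{sid}.tsv", delimiter="\t", ndmin=2)
            for sid in manifest["subject_ids"]
        ]
        variants[label] = np.stack(block)
    config = manifest.get("config")
    if config is not None:
        if config.get("variant_labels") is not None:
            config["variant_labels"] = tuple(config["variant_labels"])
        config = SyntheticCohortConfig(**config)
    return SubjectDataset(
        variants=variants,
        targets=np.array(manifest["targets"]),
        task=manifest["task"],
        communities={k: np.array(v) for k, v in manifest["communities"].items()},
        subject_ids=list(manifest["subject_ids"]),
        split=None if manifest["split"] is None else np.array(manifest["split"]),
        data_kind=manifest["data_kind"],
        config=config,
    )


def write_grid(grid: PipelineGrid, outdir: Path) -> None:
    # factor order defines pipeline ids, so it is stored as an ordered list
    _write_json(
        Path(outdir) / "grid.json",
        {"factors": [[k, list(v)] for k, v in grid.factor_levels.items()]},
    )


def read_grid(outdir: Path) -> PipelineGrid:
    payload = json.loads((Path(outdir) / "grid.json").read_text())
    return build_grid(dict(payload["factors"]))


def write_space(
    table: SimilarityTable, space: EmbeddedSpace, outdir: Path, force: bool = False
) -> Path:
    outdir = _prepare_dir(Path(outdir), force)
    np.savetxt(outdir / "similarity_table.tsv", table.matrix, delimiter="\t")
    np.savetxt(outdir / "embedding.tsv", space.coords, delimiter="\t")
    manifest = {
        "kind": "space",
        "version": __version__,
        "pair_index": [[int(i), int(j)] for i, j in table.pair_index],
        "pipeline_ids": [int(p) for p in table.pipeline_ids],
        "method": space.method,
        "params": space.params,
        "stress": space.stress,
    }
    _write_json(outdir / "manifest.json", manifest)
    return outdir


def read_space(outdir: Path) -> tuple[SimilarityTable, EmbeddedSpace]:
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    matrix = np.loadtxt(outdir / "similarity_table.tsv", delimiter="\t", ndmin=2)
    coords = np.loadtxt(outdir / "embedding.tsv", delimiter="\t", ndmin=2)
    ids = np.array(manifest["pipeline_ids"])
    table = SimilarityTable(
        matrix=matrix,
        pair_index=[tuple(p) for p in manifest["pair_index"]],
        pipeline_ids=ids,
    )
    space = EmbeddedSpace(
        coords=coords,
        method=manifest["method"],
        params=manifest["params"],
        pipeline_ids=ids.copy(),
        stress=manifest["stress"],
    )
    return table, space


def trace_frame(trace: SearchTrace, grid: PipelineGrid | None = None) -> pd.DataFrame:
    rows = []
    for e in trace.entries:
        row = {
            "iteration": e.iteration,
            "pipeline_id": e.pipeline_id,
            "score": e.score.value,
            "acquisition": e.acquisition,
            "phase": e.phase,
            "flagged": e.score.flagged,
        }
        for d, c in enumerate(e.coords):
            row[f"coord_{d}"] = c
        if grid is not None:
            row.update({f"factor_{k}": v for k, v in grid[e.pipeline_id].factors})
        rows.append(row)
    return pd.DataFrame(rows)


def write_trace(
    trace: SearchTrace,
    outdir: Path,
    grid: PipelineGrid | None = None,
    landscape: LandscapeEstimate | None = None,
    force: bool = False,
) -> Path:
    outdir = _prepare_dir(Path(outdir), force)
    trace_frame(trace, grid).to_csv(outdir / "trace.tsv", sep="\t", index=False)
    if landscape is not None:
        pd.DataFrame(
            {
                "pipeline_id": landscape.pipeline_ids,
                "mu": landscape.mu,
                "sigma": landscape.sigma,
            }
        ).to_csv(outdir / "landscape.tsv", sep="\t", index=False)
    manifest = {
        "kind": "search",
        "version": __version__,
        "config": None if trace.config is None else dataclasses.asdict(trace.config),
        "final_kernel": None if trace.gp is None else str(trace.gp.gpr.kernel_),
        "n_evaluated": len(trace.entries),
    }
    _write_json(outdir / "manifest.json", manifest)
    return outdir


def read_trace_frame(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(Path(outdir) / "trace.tsv", sep="\t")


def write_report(
    rows: pd.DataFrame, summary: dict, outdir: Path, force: bool = False
) -> Path:
    outdir = _prepare_dir(Path(outdir), force)
    rows.to_csv(outdir / "report.tsv", sep="\t", index=False)
    manifest = {"kind": "report", "version": __version__, "summary": summary}
    _write_json(outdir / "manifest.json", manifest)
    return outdir
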