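"""Readers, writers and run configuration.

Matrices arrive as delimited text (CSV/TSV with an id header row and an
id first column) or MatrixMarket MTX with companion ``<path>.rows`` /
``<path>.cols`` id files.  Annotations arrive as GMT (set name, a
description field, then member ids, tab-separated) or as a two-column
TSV of (item id, class id) pairs with set-union semantics for repeated
items.  Reports are plain text and round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import AnnotationMap, CandidateKey, DataMatrix, MEASURE_SPECS, ValidationScoreTable
from .pipeline import OptClusterResult, method_ranks, score_ranks

logger = logging.getLogger("clustagg")

__all__ = [
    "RunConfig",
    "read_matrix",
    "read_annotation",
    "normalize_library_size",
    "write_report",
    "read_score_table",
]


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    input: str
    format: str = "csv"  # csv | tsv | mtx
    domain: str = "continuous"
    annotation: str | None = None
    annotation_format: str = "gmt"  # gmt | tsv2col
    methods: list[str] = field(default_factory=lambda: ["hierarchical", "kmeans", "pam"])
    k_range: list[int] = field(default_factory=lambda: [2, 3, 4])
    validation_types: list[str] = field(default_factory=lambda: ["internal"])
    weights: list[float] | None = None
    distance: str = "footrule"
    weighted_distance: bool = True
    optimizer: str = "CE"
    optimizer_params: dict = field(default_factory=dict)
    metric: str = "euclidean"
    neighb_size: int = 10
    normalize: bool = False
    transpose: bool = False
    seed: int = 0
    outdir: str = "clustagg_out"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# readers


def read_matrix(path: str | Path, format: str = "csv", domain: str = "continuous",
                transpose: bool = False) -> DataMatrix:
    """Load an items x features matrix with ids.

    CSV/TSV must carry a header row of feature ids and a first column of
    item ids.  MTX loads the triplet file plus ``<path>.rows`` and
    ``<path>.cols`` id files (one id per line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if format == "csv" else "\t", index_col=0)
        if df.isna().any().any():
            cells = [
                f"({df.index[i]}, {df.columns[j]})"
                for i, j in zip(*np.where(df.isna().to_numpy()))
            ]
            raise ValueError(f"missing value(s) at {', '.join(cells[:10])}")
        values = df.to_numpy(dtype=float)
        row_ids = [str(r) for r in df.index]
        col_ids = [str(c) for c in df.columns]
    elif format == "mtx":
        mat = scipy.io.mmread(path)
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        row_ids = Path(f"{path}.rows").read_text().split()
        col_ids = Path(f"{path}.cols").read_text().split()
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    if transpose:
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    if len(row_ids) != len(set(row_ids)):
        raise ValueError("duplicate row ids in input")
    if domain == "counts" and np.any(values != np.round(values)):
        bad = np.argwhere(values != np.round(values))[0]
        raise ValueError(
            f"domain=counts but non-integer value at row {row_ids[bad[0]]}, "
            f"column {col_ids[bad[1]]}"
        )
    return DataMatrix(values, row_ids, col_ids, domain)


def read_annotation(path: str | Path, format: str = "gmt") -> AnnotationMap:
    """Load a functional-annotation map (GMT or two-column TSV)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    classes: dict[str, set[str]] = {}
    n_classes = 0
    if format == "gmt":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                logger.warning("GMT: empty class %r dropped", parts[0] if parts else "")
                continue
            name, _desc, *members = parts
            members = [m for m in members if m]
            if not members:
                logger.warning("GMT: empty class %r dropped", name)
                continue
            n_classes += 1
            for m in members:
                classes.setdefault(m, set()).add(name)
    elif format == "tsv2col":
        seen = set()
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            item, cls = line.rstrip("\n").split("\t")[:2]
            classes.setdefault(item, set()).add(cls)
            seen.add(cls)
        n_classes = len(seen)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if n_classes == 0:
        raise ValueError(f"no usable annotation classes in {path}")
    return AnnotationMap(classes)


def normalize_library_size(matrix: DataMatrix) -> DataMatrix:
    """Scale each column (library) to the median column total.

    Returns a continuous-domain matrix suitable for the
    continuous-data clustering algorithms.
    """
    totals = matrix.values.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("cannot normalize: a column has zero total")
    scaled = matrix.values / totals[None, :] * np.median(totals)
    return DataMatrix(scaled, list(matrix.row_ids), list(matrix.col_ids), "continuous")


# ---------------------------------------------------------------------------
# report bundle


def _fmt(x: float) -> str:
    return repr(float(x))


def write_report(result: OptClusterResult, outdir: str | Path, force: bool = False,
                 config: RunConfig | None = None) -> list[Path]:
    """Emit scores.tsv, ranks.tsv, best.json, partitions.tsv, config.json
    and log.txt into ``outdir``; refuses an existing directory without
    ``force``."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists; pass force=True/--force to overwrite")
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    table = result.score_table
    cand_names = [str(key) for key in table.candidates]
    lines = ["measure\t" + "\t".join(cand_names)]
    for i, spec in enumerate(table.specs):
        lines.append(spec.name + "\t" + "\t".join(_fmt(v) for v in table.scores[i]))
    (outdir / "scores.tsv").write_text("\n".join(lines) + "\n")
    written.append(outdir / "scores.tsv")

    lines = ["measure\tposition\tcandidate\tscore"]
    for lst, ranks, scores in zip(result.ranked_lists, method_ranks(result), score_ranks(result)):
        for pos, (key, sc) in enumerate(zip(ranks, scores), start=1):
            lines.append(f"{lst.measure}\t{pos}\t{key}\t{_fmt(sc)}")
    (outdir / "ranks.tsv").write_text("\n".join(lines) + "\n")
    written.append(outdir / "ranks.tsv")

    agg = result.aggregation
    best = {
        "best": str(result.best),
        "phi": float(agg.phi),
        "optimizer": agg.method,
        "converged": agg.converged,
        "iterations": len(agg.trace),
        "initial_phi": float(agg.trace[0]) if agg.trace else None,
        "final_order": [str(key) for key in agg.best_order],
    }
    (outdir / "best.json").write_text(json.dumps(best, indent=2, sort_keys=True) + "\n")
    written.append(outdir / "best.json")

    ids = next(iter(result.partitions.values())).n_items if result.partitions else 0
    keys = list(table.candidates)
    lines = ["item\t" + "\t".join(str(key) for key in keys)]
    row_ids = result.config_echo.get("row_ids")
    for i in range(ids):
        rid = row_ids[i] if row_ids else f"item{i}"
        lines.append(rid + "\t" + "\t".join(
            str(int(result.partitions[key].labels[i])) for key in keys))
    (outdir / "partitions.tsv").write_text("\n".join(lines) + "\n")
    written.append(outdir / "partitions.tsv")

    cfg = config.to_dict() if config is not None else dict(result.config_echo)
    cfg.pop("row_ids", None)
    (outdir / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
    written.append(outdir / "config.json")

    stamp = datetime.now(timezone.utc).isoformat()
    log_lines = [f"{stamp} run complete: best={result.best} phi={_fmt(agg.phi)}"]
    log_lines += [f"{stamp} warning: {w}" for w in result.warnings]
    (outdir / "log.txt").write_text("\n".join(log_lines) + "\n")
    written.append(outdir / "log.txt")
    return written


def read_score_table(path: str | Path) -> ValidationScoreTable:
    """Round-trip reader for scores.tsv."""
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")[1:]
    candidates = [CandidateKey.parse(name) for name in header]
    specs, rows = [], []
    for line in lines[1:]:
        parts = line.split("\t")
        specs.append(MEASURE_SPECS[parts[0]])
        rows.append([float(v) for v in parts[1:]])
    return ValidationScoreTable(np.array(rows), specs, candidates)
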