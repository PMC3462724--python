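"""Delimited-text file formats: cohorts, manifests, feature tables, reports.

On disk a cohort is a directory of one TSV matrix per subject (T rows x
R columns, full float precision), a ``manifest.tsv`` mapping subject id
to group and series path (plus an optional confounds path), and a
``region_labels.txt`` with one region name per line. Feature tables get
a sidecar JSON recording the edge-ordering convention so any artifact
can be re-derived from its inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from connmvpa.connectivity import EdgeIndexMap, FeatureDataset
from connmvpa.preprocess import ConfoundSet
from connmvpa.synth import Cohort, Subject

_GROUP_TOKENS = {"patient": -1, "control": +1}
_GROUP_NAMES = {-1: "patient", +1: "control"}


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline settings, loadable from YAML or JSON."""

    k: int = 550
    d: int = 6
    C: float = 0.255
    steps: tuple[str, ...] = ("detrend", "bandpass", "regress")
    f_low: float = 0.01
    f_high: float = 0.08
    k_grid: tuple[int, ...] = tuple(range(50, 801, 50))
    d_grid: tuple[int, ...] = tuple(range(2, 21))
    c_grid: tuple[float, ...] = tuple(np.round(np.arange(0.005, 2.0, 0.05), 3))
    n_perm: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.d < 1 or self.C <= 0 or self.n_perm < 1:
            raise ValueError("k, d >= 1; C > 0; n_perm >= 1")


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    obj = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    for key in ("steps", "k_grid", "d_grid", "c_grid"):
        if key in obj:
            obj[key] = tuple(obj[key])
    return RunConfig(**obj)


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=float), delimiter="\t", fmt="%.17g")


def read_matrix(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


def write_region_labels(labels: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(labels) + "\n")


def read_region_labels(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write per-subject matrices, manifest.tsv and region_labels.txt."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        rel = f"{s.subject_id}.tsv"
        write_matrix(s.series, outdir / rel)
        rows.append({"subject_id": s.subject_id,
                     "group": _GROUP_NAMES[s.group], "series_path": rel})
    pd.DataFrame(rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    write_region_labels(cohort.region_labels, outdir / "region_labels.txt")
    meta = {"tr_seconds": cohort.tr_seconds, "n_regions": cohort.n_regions,
            "n_subjects": len(cohort.subjects)}
    (outdir / "cohort.json").write_text(json.dumps(meta, indent=2))
    return outdir


def read_cohort(cohort_dir: str | Path,
                tr_seconds: float | None = None) -> tuple[Cohort, dict[str, ConfoundSet]]:
    """Load a cohort directory; returns the cohort and any per-subject confounds."""
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.tsv", sep="\t")
    labels = read_region_labels(cohort_dir / "region_labels.txt")
    if tr_seconds is None:
        meta_path = cohort_dir / "cohort.json"
        tr_seconds = (json.loads(meta_path.read_text())["tr_seconds"]
                      if meta_path.exists() else 2.0)
    if manifest["subject_id"].duplicated().any():
        dupes = manifest.loc[manifest["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids in manifest: {dupes}")
    subjects, confounds = [], {}
    for row_i, row in manifest.iterrows():
        token = str(row["group"]).strip().lower()
        if token not in _GROUP_TOKENS:
            raise ValueError(f"manifest row {row_i} ({row['subject_id']}): "
                             f"unknown group {row['group']!r}")
        series_path = cohort_dir / row["series_path"]
        if not series_path.exists():
            raise FileNotFoundError(f"manifest row {row_i}: missing series file {series_path}")
        series = read_matrix(series_path)
        if series.shape[1] != len(labels):
            raise ValueError(f"subject {row['subject_id']}: series has "
                             f"{series.shape[1]} regions, label table has {len(labels)}")
        subjects.append(Subject(str(row["subject_id"]), _GROUP_TOKENS[token], series))
        conf_rel = row.get("confounds_path")
        if isinstance(conf_rel, str) and conf_rel:
            conf_path = cohort_dir / conf_rel
            if not conf_path.exists():
                raise FileNotFoundError(f"manifest row {row_i}: missing confounds {conf_path}")
            confounds[str(row["subject_id"])] = ConfoundSet(str(row["subject_id"]),
                                                            read_matrix(conf_path))
    return Cohort(labels, float(tr_seconds), subjects), confounds


def write_feature_dataset(dataset: FeatureDataset, path: str | Path) -> None:
    """N x D feature TSV plus a sidecar JSON with the edge convention."""
    path = Path(path)
    frame = pd.DataFrame(dataset.X)
    frame.insert(0, "group", [_GROUP_NAMES[g] for g in dataset.y])
    frame.insert(0, "subject_id", dataset.subject_ids)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = {
        "n_regions": dataset.edge_map.n_regions,
        "n_features": dataset.edge_map.n_edges,
        "edge_ordering": "row-major strictly-upper-triangle, 0-based (0,1),(0,2),...",
        "region_labels": dataset.region_labels,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_feature_dataset(path: str | Path) -> FeatureDataset:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    y = frame["group"].map(_GROUP_TOKENS).to_numpy()
    X = frame.drop(columns=["subject_id", "group"]).to_numpy(dtype=float)
    return FeatureDataset(X, y, EdgeIndexMap(sidecar["n_regions"]),
                          sidecar["region_labels"], frame["subject_id"].tolist())


def cv_report_dict(cv) -> dict:
    """JSON-ready summary of a CvResult."""
    return {
        "k": cv.k, "d": cv.d, "C": cv.C,
        "tp": cv.tp, "tn": cv.tn, "fp": cv.fp, "fn": cv.fn,
        "gr": cv.metrics.gr, "ss": cv.metrics.ss, "sc": cv.metrics.sc,
        "consensus_features": cv.consensus.tolist(),
        "union_features": cv.union.tolist(),
        "folds": [{"subject_id": f.subject_id, "score": f.score,
                   "predicted": f.predicted, "true": f.true} for f in cv.folds],
    }
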