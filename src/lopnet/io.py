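"""Reading and writing of run-directory artifacts.

All tabular artifacts are TSV with a header row; node time series are one
matrix file per participant/run with a JSON sidecar (TR, node count, event
onsets); reports and exclusion logs are JSON.  ``load_table`` validates the
schema and reports the file, missing columns and row counts on failure.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "load_table",
    "write_table",
    "write_json",
    "load_json",
    "write_timeseries",
    "load_timeseries",
    "FILES",
]

#: canonical artifact names inside a run directory
FILES = {
    "config": "config.yaml",
    "event_bank": "event_bank.tsv",
    "responses": "responses.tsv",
    "outcomes": "memory_outcomes.tsv",
    "elaboration": "elaboration_labels.tsv",
    "congruity": "congruity_labels.tsv",
    "scores": "memory_scores.tsv",
    "exclusions": "exclusions.json",
    "truth": "ground_truth.json",
    "designs": "designs.json",
    "connectivity": "connectivity.tsv",
    "centrality": "centrality.tsv",
    "report": "report.json",
}

SCHEMAS = {
    "event_bank": ["event_id", "question", "p_yes"],
    "responses": ["participant_id", "event_id", "response", "rt_ms"],
    "outcomes": ["participant_id", "item_id", "old", "q1", "q2", "q3"],
    "elaboration": ["event_id", "category", "level"],
    "congruity": ["participant_id", "event_id", "level"],
    "scores": ["participant_id", "dimension", "level", "n_trials", "source_pct"],
    "connectivity": ["participant", "condition", "i", "j", "z"],
    "centrality": ["participant", "condition", "density", "node", "measure", "value"],
}


class InputError(ValueError):
    """A malformed or incomplete input file."""


def load_table(path, kind: str | None = None, required=None) -> pd.DataFrame:
    """Read a TSV table, validating required columns.

    ``kind`` selects a known schema from :data:`SCHEMAS`; ``required``
    overrides it with an explicit column list.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as err:  # pandas raises several parse error types
        raise InputError(f"{path}: cannot parse TSV ({err})") from err
    if df.empty:
        raise InputError(f"{path}: table is empty")
    cols = required if required is not None else SCHEMAS.get(kind, [])
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)} "
            f"({len(df)} rows)"
        )
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=default)
    return path


def load_json(path):
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: file not found")
    with open(path) as fh:
        return json.load(fh)


def write_timeseries(ts, path_stem, onsets=None, event_ids=None) -> Path:
    """Write a NodeTimeSeries as matrix TSV plus a JSON sidecar."""
    path = Path(str(path_stem) + ".tsv")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, ts.data, delimiter="\t")
    sidecar = {
        "participant_id": int(ts.participant_id),
        "tr": ts.tr,
        "n_nodes": int(ts.data.shape[0]),
        "n_volumes": int(ts.data.shape[1]),
    }
    if onsets is not None:
        sidecar["onsets"] = np.asarray(onsets).tolist()
    if event_ids is not None:
        sidecar["event_ids"] = np.asarray(event_ids).tolist()
    write_json(sidecar, Path(str(path_stem) + ".json"))
    return path


def load_timeseries(path_stem):
    """Read a matrix TSV + sidecar pair written by :func:`write_timeseries`."""
    from .simulate import NodeTimeSeries

    data = np.loadtxt(Path(str(path_stem) + ".tsv"), delimiter="\t")
    sidecar = load_json(Path(str(path_stem) + ".json"))
    if data.shape[0] != sidecar["n_nodes"]:
        raise InputError(f"{path_stem}.tsv: row count differs from sidecar n_nodes")
    ts = NodeTimeSeries(
        participant_id=sidecar["participant_id"], data=data, tr=sidecar["tr"]
    )
    return ts, sidecar
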