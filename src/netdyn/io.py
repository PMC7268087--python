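"""File interchange for pipeline stages.

Subject matrices travel as delimited text (CSV, parcels x samples) or .npy;
concatenated datasets and state time-courses are written as a .npy matrix
plus a boundaries CSV (subject_id, start, end; 0-based half-open) and a JSON
metadata record, so every stage can be run, inspected and resumed from disk.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .envelope import EnvelopeDataset
from .hmm import HMMParams, StateTimeCourses

__all__ = [
    "load_subject_matrices",
    "save_dataset",
    "load_dataset",
    "save_stc",
    "load_stc",
    "save_hmm_params",
    "load_hmm_params",
]


def load_subject_matrices(data_dir: str | Path) -> tuple[list[np.ndarray], list[str]]:
    """Load per-subject matrices (``*.csv`` or ``*.npy``, excluding helper
    files) sorted by file name; returns (matrices, subject ids)."""
    data_dir = Path(data_dir)
    mats, ids = [], []
    for path in sorted(data_dir.iterdir()):
        if path.name in ("labels.csv", "expression.csv") or path.name.endswith("_true_path.csv"):
            continue
        if path.suffix == ".csv":
            mats.append(np.atleast_2d(np.loadtxt(path, delimiter=",")))
        elif path.suffix == ".npy":
            mats.append(np.atleast_2d(np.load(path)))
        else:
            continue
        ids.append(path.stem)
    if not mats:
        raise FileNotFoundError(f"no subject matrices found in {data_dir}")
    return mats, ids


def _write_boundaries(boundaries, path: Path) -> None:
    pd.DataFrame(boundaries, columns=["subject_id", "start", "end"]).to_csv(path, index=False)


def _read_boundaries(path: Path) -> list[tuple[str, int, int]]:
    df = pd.read_csv(path)
    return [(str(r.subject_id), int(r.start), int(r.end)) for r in df.itertuples()]


def save_dataset(dataset: EnvelopeDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.save(out / "dataset.npy", dataset.data)
    _write_boundaries(dataset.subject_boundaries, out / "boundaries.csv")
    meta = {"sampling_rate": dataset.sampling_rate, "parcel_labels": dataset.parcel_labels}
    (out / "dataset_meta.json").write_text(json.dumps(meta))


def load_dataset(in_dir: str | Path) -> EnvelopeDataset:
    d = Path(in_dir)
    meta = json.loads((d / "dataset_meta.json").read_text())
    return EnvelopeDataset(
        data=np.load(d / "dataset.npy"),
        subject_boundaries=_read_boundaries(d / "boundaries.csv"),
        sampling_rate=meta["sampling_rate"],
        parcel_labels=meta["parcel_labels"],
    )


def save_stc(stc: StateTimeCourses, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.save(out / "state_timecourses.npy", stc.activations.astype(np.int8))
    _write_boundaries(stc.subject_boundaries, out / "stc_boundaries.csv")


def load_stc(in_dir: str | Path) -> StateTimeCourses:
    d = Path(in_dir)
    return StateTimeCourses(
        activations=np.load(d / "state_timecourses.npy"),
        subject_boundaries=_read_boundaries(d / "stc_boundaries.csv"),
    )


def save_hmm_params(params: HMMParams, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "n_states": params.n_states,
        "means": params.means.tolist(),
        "transition_matrix": params.transition_matrix.tolist(),
        "initial_distribution": params.initial_distribution.tolist(),
        "log_likelihood_trace": np.asarray(params.log_likelihood_trace).tolist(),
    }
    (out / "hmm_params.json").write_text(json.dumps(payload))
    np.save(out / "hmm_covariances.npy", params.covariances)


def load_hmm_params(in_dir: str | Path) -> HMMParams:
    d = Path(in_dir)
    payload = json.loads((d / "hmm_params.json").read_text())
    return HMMParams(
        n_states=payload["n_states"],
        means=np.asarray(payload["means"]),
        covariances=np.load(d / "hmm_covariances.npy"),
        transition_matrix=np.asarray(payload["transition_matrix"]),
        initial_distribution=np.asarray(payload["initial_distribution"]),
        log_likelihood_trace=np.asarray(payload["log_likelihood_trace"]),
    )
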