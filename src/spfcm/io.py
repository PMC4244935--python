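"""Delimited-matrix input, result serialization and run manifests."""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .fcm import DataMatrix, FcmError
from .pipeline import SpfcmConfig, SpfcmResult

__all__ = ["RunManifest", "read_matrix", "write_result", "write_matrix"]


class DataIOError(ValueError):
    pass


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to re-run a clustering bit-identically."""

    input: str
    config: dict
    seed: int | None
    started: str
    finished: str
    version: str

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def read_matrix(
    path,
    delimiter: str = ",",
    header: bool = True,
    id_column: bool = False,
    standardize: bool = False,
) -> DataMatrix:
    """Read a delimited numeric matrix into a DataMatrix.

    ``header`` treats the first row as feature names; ``id_column`` treats
    the first column as row identifiers.  Any non-numeric or non-finite
    cell raises an error naming the offending row and column.
    ``standardize`` z-scores each feature (population sd).
    """
    path = Path(path)
    if not path.exists():
        raise DataIOError(f"no such file: {path}")
    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            header=0 if header else None,
            dtype=str,
            skipinitialspace=True,
        )
    except pd.errors.EmptyDataError:
        raise DataIOError(f"empty input file: {path}") from None
    except pd.errors.ParserError as exc:
        raise DataIOError(f"ragged or malformed rows in {path}: {exc}") from None

    row_ids = None
    feature_names = list(map(str, df.columns)) if header else None
    if id_column:
        row_ids = df.iloc[:, 0].astype(str).tolist()
        df = df.iloc[:, 1:]
        if feature_names is not None:
            feature_names = feature_names[1:]
    if df.shape[1] == 0:
        raise DataIOError(f"no feature columns in {path}")
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().values)[0]
        raise DataIOError(
            f"missing/ragged cell at row {i + 1}, column {j + 1} of {path}"
        )

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().values
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataIOError(
            f"non-numeric cell {df.values[i, j]!r} at row {i + 1}, "
            f"column {j + 1} of {path}"
        )
    # numpy's string->float conversion is correctly rounded (exact round-trip)
    values = df.to_numpy().astype(np.float64)
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise DataIOError(
            f"non-finite value at row {i + 1}, column {j + 1} of {path}"
        )
    if standardize:
        sd = values.std(axis=0)
        sd[sd == 0] = 1.0
        values = (values - values.mean(axis=0)) / sd
    try:
        return DataMatrix(values, row_ids=row_ids, feature_names=feature_names)
    except FcmError as exc:
        raise DataIOError(str(exc)) from exc


def write_matrix(X: DataMatrix, path, labels=None) -> None:
    """Write a DataMatrix (optionally with a label column) as CSV."""
    names = (
        list(X.feature_names)
        if X.feature_names is not None
        else [f"f{j + 1}" for j in range(X.n_features)]
    )
    df = pd.DataFrame(X.values, columns=names)
    if X.row_ids is not None:
        df.insert(0, "id", list(X.row_ids))
    if labels is not None:
        df["label"] = np.asarray(labels)
    df.to_csv(path, index=False)


def _shadow_status(u: float, alpha: float, u_max: float) -> str:
    if u >= u_max - alpha:
        return "core"
    if u <= alpha:
        return "excluded"
    return "shadow"


def write_result(
    result: SpfcmResult,
    out_dir,
    *,
    row_ids=None,
    manifest: RunManifest | None = None,
) -> dict[str, Path]:
    """Serialize a sweep result: memberships, prototypes, trace, manifest.

    The memberships table carries, per object, its fuzzy memberships in
    the selected partition, the hard label, and its three-way shadow
    status (core / shadow / excluded) relative to the assigned cluster's
    optimal threshold.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    best = next(r for r in result.trace if r.C == result.best_C)
    U = result.best_U.u
    N, C = U.shape
    labels = result.best_U.hard_labels()
    ids = list(row_ids) if row_ids is not None else [str(i) for i in range(N)]
    u_max = U.max(axis=0)
    status = [
        _shadow_status(U[i, labels[i]], best.alphas[labels[i]], u_max[labels[i]])
        for i in range(N)
    ]
    memberships = pd.DataFrame(U, columns=[f"u_{j + 1}" for j in range(C)])
    memberships.insert(0, "row_id", ids)
    memberships["hard_label"] = labels
    memberships["shadow_status"] = status
    paths = {"memberships": out_dir / "memberships.csv"}
    memberships.to_csv(paths["memberships"], index=False)

    prototypes = pd.DataFrame(
        result.best_B.centers,
        columns=[f"f{j + 1}" for j in range(result.best_B.n_features)],
    )
    prototypes.insert(0, "cluster", np.arange(C))
    paths["prototypes"] = out_dir / "prototypes.csv"
    prototypes.to_csv(paths["prototypes"], index=False)

    trace = pd.DataFrame(
        {
            "C": [r.C for r in result.trace],
            "xb": [r.xb for r in result.trace],
            "db": [r.db for r in result.trace],
            "dunn": [r.dunn for r in result.trace],
            "J": [r.J for r in result.trace],
            "removed": [";".join(map(str, r.removed)) for r in result.trace],
            "alphas": [";".join(f"{a:.6g}" for a in r.alphas) for r in result.trace],
            "cardinalities": [
                ";".join(map(str, r.cardinalities)) for r in result.trace
            ],
        }
    )
    paths["trace"] = out_dir / "trace.csv"
    trace.to_csv(paths["trace"], index=False)

    if manifest is not None:
        paths["manifest"] = out_dir / "manifest.yaml"
        with open(paths["manifest"], "w") as fh:
            yaml.safe_dump(manifest.to_dict(), fh, sort_keys=False)
    return paths


def make_manifest(
    input_desc: str, cfg: SpfcmConfig, started: datetime.datetime
) -> RunManifest:
    from . import __version__

    return RunManifest(
        input=input_desc,
        config={
            "c_min": cfg.c_min,
            "c_max": cfg.c_max,
            "epsilon": cfg.policy.epsilon,
            "rho": cfg.policy.rho,
            "m": cfg.fcm.m,
            "tol": cfg.fcm.tol,
            "max_iter": cfg.fcm.max_iter,
            "w": cfg.pso.w,
            "c1": cfg.pso.c1,
            "c2": cfg.pso.c2,
            "L": cfg.pso.L,
            "T": cfg.pso.T,
        },
        seed=cfg.seed,
        started=started.isoformat(),
        finished=datetime.datetime.now().isoformat(),
        version=__version__,
    )
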