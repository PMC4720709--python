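"""Serialization: path-set tables, SDE spec documents, model bundles, metadata.

Path sets travel as delimited text in long format with columns
``path_id, label, time, coordinate_index, value`` (one header line, no
missing cells). SDE specs and experiment settings are YAML documents;
trained classifier and prior bundles are JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifiers import (
    KIND_OBC,
    BinaryClassifier,
    GaussianClassParams,
    OBCClassParams,
)
from .exceptions import InvalidInputError, InvalidSpecError
from .paths import ObservationGrid, PathSet
from .priors import NIWParams
from .sde import LinearSDESpec

PATHSET_COLUMNS = ["path_id", "label", "time", "coordinate_index", "value"]


# ---------------------------------------------------------------------------
# PathSet long-format tables
# ---------------------------------------------------------------------------

def write_pathset(pathset: PathSet, path) -> None:
    """Write a PathSet as a long-format delimited table."""
    n, N, p = pathset.paths.shape
    idx = pd.MultiIndex.from_product(
        [range(n), pathset.grid.times, range(p)],
        names=["path_id", "time", "coordinate_index"],
    )
    df = pd.DataFrame(
        {"value": pathset.paths.reshape(-1)}, index=idx
    ).reset_index()
    df.insert(1, "label", pathset.label)
    df[PATHSET_COLUMNS].to_csv(path, index=False)


def pathset_from_dataframe(df: pd.DataFrame) -> PathSet:
    """Validate and assemble a PathSet from a long-format table.

    The grid is inferred from the distinct times; every path must cover the
    full grid with exactly one value per (time, coordinate). Rows may
    arrive in any order.
    """
    missing = [c for c in PATHSET_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"path table is missing columns {missing}")
    if df["value"].isna().any():
        row = int(df.index[df["value"].isna()][0])
        raise InvalidInputError(f"missing value at row {row}")
    if not np.issubdtype(df["value"].dtype, np.number):
        raise InvalidInputError("non-numeric values in path table")
    times = np.sort(df["time"].unique())
    coords = np.sort(df["coordinate_index"].unique())
    p = coords.size
    if not np.array_equal(coords, np.arange(p)):
        raise InvalidInputError(
            f"coordinate_index must cover 0..p-1, found {coords.tolist()}"
        )
    grid = ObservationGrid(times=times, p=p)
    labels = df["label"].unique()
    if labels.size != 1:
        raise InvalidInputError(
            f"one PathSet holds one label; found {sorted(labels.tolist())}"
        )
    path_ids = np.sort(df["path_id"].unique())
    pivot = df.pivot_table(
        index="path_id", columns=["time", "coordinate_index"], values="value",
        aggfunc="first",
    )
    expected = pd.MultiIndex.from_product([times, coords])
    if pivot.shape != (path_ids.size, grid.N * p) or pivot.isna().any().any():
        bad = pivot.isna().any(axis=1)
        which = pivot.index[bad][0] if bad.any() else "?"
        raise InvalidInputError(
            f"path {which!r} does not cover the full observation grid"
        )
    counts = df.groupby("path_id").size()
    if not (counts == grid.N * p).all():
        which = counts.index[counts != grid.N * p][0]
        raise InvalidInputError(f"path {which!r} has duplicate or missing cells")
    pivot = pivot.reindex(columns=expected).loc[path_ids]
    paths = pivot.to_numpy().reshape(path_ids.size, grid.N, p)
    return PathSet(grid=grid, paths=paths, label=int(labels[0]))


def read_pathset(path) -> PathSet:
    """Read a long-format path table written by :func:`write_pathset`."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise InvalidInputError(f"cannot parse path table {path}: {exc}") from exc
    return pathset_from_dataframe(df)


# ---------------------------------------------------------------------------
# SDE spec documents
# ---------------------------------------------------------------------------

class PolynomialMatrix:
    """Serializable polynomial time dependence ``C_0 + C_1 t + C_2 t^2 + ...``."""

    def __init__(self, coefficients) -> None:
        self.coefficients = [np.asarray(c, dtype=float) for c in coefficients]
        if not self.coefficients:
            raise InvalidSpecError("polynomial form needs at least one coefficient")

    def __call__(self, t: float) -> np.ndarray:
        out = np.zeros_like(self.coefficients[0])
        for k, c in enumerate(self.coefficients):
            out = out + c * t**k
        return out

    def to_dict(self) -> dict:
        return {
            "form": "polynomial",
            "coefficients": [c.tolist() for c in self.coefficients],
        }


def _coeff_from_doc(value, shape, name):
    if isinstance(value, dict):
        if value.get("form") != "polynomial":
            raise InvalidSpecError(
                f"{name}: unknown time-dependence form {value.get('form')!r}"
            )
        coeffs = [np.asarray(c, dtype=float).reshape(shape) for c in value["coefficients"]]
        return PolynomialMatrix(coeffs)
    return np.asarray(value, dtype=float).reshape(shape)


def spec_from_dict(doc: dict) -> LinearSDESpec:
    """Build a LinearSDESpec from a structured document."""
    try:
        p, q = int(doc["p"]), int(doc["q"])
        return LinearSDESpec(
            p=p,
            q=q,
            A=_coeff_from_doc(doc["A"], (p, p), "A"),
            a=_coeff_from_doc(doc["a"], (p,), "a"),
            B=_coeff_from_doc(doc["B"], (p, q), "B"),
            init_mean=np.asarray(doc["init_mean"], dtype=float).reshape(p),
            init_cov=(
                np.asarray(doc["init_cov"], dtype=float).reshape(p, p)
                if doc.get("init_cov") is not None
                else None
            ),
            t0=float(doc.get("t0", 0.0)),
        )
    except KeyError as exc:
        raise InvalidSpecError(f"spec document is missing key {exc}") from exc


def _coeff_to_doc(value, name):
    if isinstance(value, PolynomialMatrix):
        return value.to_dict()
    if callable(value):
        raise InvalidSpecError(
            f"{name} is a generic callable; only constant matrices and "
            "PolynomialMatrix forms can be serialized"
        )
    return np.asarray(value).tolist()


def spec_to_dict(spec: LinearSDESpec) -> dict:
    """Serialize a LinearSDESpec to a plain document."""
    return {
        "p": spec.p,
        "q": spec.q,
        "A": _coeff_to_doc(spec.A, "A"),
        "a": _coeff_to_doc(spec.a, "a"),
        "B": _coeff_to_doc(spec.B, "B"),
        "init_mean": spec.init_mean.tolist(),
        "init_cov": spec.init_cov.tolist(),
        "t0": spec.t0,
    }


def load_spec(path) -> LinearSDESpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))


def save_spec(spec: LinearSDESpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# NIW and classifier bundles (JSON)
# ---------------------------------------------------------------------------

def niw_to_dict(params: NIWParams) -> dict:
    return {
        "m": params.m.tolist(),
        "Psi": params.Psi.tolist(),
        "nu": params.nu,
        "kappa": params.kappa,
    }


def niw_from_dict(doc: dict) -> NIWParams:
    return NIWParams(
        m=np.asarray(doc["m"], dtype=float),
        Psi=np.asarray(doc["Psi"], dtype=float),
        nu=float(doc["nu"]),
        kappa=float(doc["kappa"]),
    )


def classifier_to_dict(model: BinaryClassifier) -> dict:
    def bundle(cp) -> dict:
        if isinstance(cp, OBCClassParams):
            return {"m_star": cp.m_star.tolist(), "Pi": cp.Pi.tolist(), "k": cp.k}
        return {"m": cp.m.tolist(), "Psi": cp.Psi.tolist()}

    return {
        "kind": model.kind,
        "alpha1": model.alpha1,
        "class0": bundle(model.class0),
        "class1": bundle(model.class1),
    }


def classifier_from_dict(doc: dict) -> BinaryClassifier:
    kind = doc["kind"]

    def bundle(d):
        if kind == KIND_OBC:
            return OBCClassParams(
                m_star=np.asarray(d["m_star"], dtype=float),
                Pi=np.asarray(d["Pi"], dtype=float),
                k=float(d["k"]),
            )
        return GaussianClassParams(
            m=np.asarray(d["m"], dtype=float), Psi=np.asarray(d["Psi"], dtype=float)
        )

    return BinaryClassifier(
        kind=kind,
        class0=bundle(doc["class0"]),
        class1=bundle(doc["class1"]),
        alpha1=float(doc["alpha1"]),
    )


def save_json(doc: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Run metadata
# ---------------------------------------------------------------------------

def config_hash(doc) -> str:
    """Stable hash of a JSON-serializable settings document."""
    blob = json.dumps(doc, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_run_metadata(out_path, settings: dict, seed) -> Path:
    """Record the machine-readable reproduction record next to an output file."""
    meta = {
        "version": __version__,
        "root_seed": seed,
        "config_hash": config_hash(settings),
        "settings": settings,
    }
    meta_path = Path(str(out_path) + ".meta.json")
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return meta_path
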