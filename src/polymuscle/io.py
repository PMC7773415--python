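"""Serialization: model files (JSON), grid datasets (TSV), Newick trees.

Model files are structured text so they can be inspected and diffed: each
polynomial is a list of ``[i1, ..., ip, coefficient]`` rows (canonical
sorted DOF indices followed by the scalar coefficient; the intercept row is
``[coefficient]`` alone).  Angles are radians, lengths and moment arms mm.
Writing is deterministic (sorted terms, fixed layout), so
write -> read -> write round trips are byte-identical and coefficients are
preserved at full double precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .fitting import MuscleModel
from .geometry import GridDataset
from .terms import PolynomialModel, canonical_term

SCHEMA_VERSION = 1


class ModelFileError(ValueError):
    """Raised when a model file is malformed or from an unknown schema."""


def _poly_rows(poly: PolynomialModel) -> List[list]:
    return [[*term, poly.coefficients[term]] for term in poly.sorted_terms()]


def _rows_to_poly(rows, dimension: int, dof_labels, where: str) -> PolynomialModel:
    coeffs = {}
    for row in rows:
        if not isinstance(row, list) or len(row) < 1:
            raise ModelFileError(f"{where}: malformed term row {row!r}")
        *idx, c = row
        if not all(isinstance(i, int) for i in idx):
            raise ModelFileError(f"{where}: non-integer DOF index in {row!r}")
        try:
            key = canonical_term(idx, dimension)
        except ValueError as err:
            raise ModelFileError(f"{where}: {err}") from err
        coeffs[key] = float(c)
    return PolynomialModel(dimension, coeffs, tuple(dof_labels))


def write_model(model: MuscleModel, path) -> None:
    """Write a fitted muscle model to a JSON model file."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "units": {"angles": "rad", "lengths": "mm", "moment_arms": "mm"},
        "muscle": model.name,
        "dof_labels": list(model.dof_labels),
        "rom": [list(r) for r in model.roms],
        "normalization": {
            "length_range_mm": model.l_range,
            "moment_arm_max_mm": list(model.m_max),
        },
        "fit": {"mode": model.mode, "rho_l": model.rho_l, "rho_m": model.rho_m},
        "length": _poly_rows(model.L),
        "moment_arms": {
            lbl: _poly_rows(p) for lbl, p in zip(model.dof_labels, model.M)
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_model(path) -> MuscleModel:
    """Read a model file back into a :class:`MuscleModel`."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ModelFileError(f"{path}: not valid JSON ({err})") from err
    if not isinstance(doc, dict):
        raise ModelFileError(f"{path}: expected a JSON object")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ModelFileError(
            f"{path}: schema_version {version!r} unsupported "
            f"(expected {SCHEMA_VERSION})"
        )
    for key in ("muscle", "dof_labels", "rom", "normalization",
                "fit", "length", "moment_arms"):
        if key not in doc:
            raise ModelFileError(f"{path}: missing field {key!r}")
    labels = tuple(doc["dof_labels"])
    d = len(labels)
    roms = tuple((float(lo), float(hi)) for lo, hi in doc["rom"])
    L = _rows_to_poly(doc["length"], d, labels, "length")
    M = []
    for lbl in labels:
        if lbl not in doc["moment_arms"]:
            raise ModelFileError(f"{path}: missing moment arm for DOF {lbl!r}")
        M.append(_rows_to_poly(doc["moment_arms"][lbl], d, labels,
                               f"moment_arms[{lbl}]"))
    norm = doc["normalization"]
    return MuscleModel(
        name=doc["muscle"],
        dof_labels=labels,
        roms=roms,
        L=L,
        M=tuple(M),
        l_range=float(norm["length_range_mm"]),
        m_max=tuple(float(v) for v in norm["moment_arm_max_mm"]),
        mode=doc["fit"]["mode"],
        rho_l=int(doc["fit"]["rho_l"]),
        rho_m=int(doc["fit"]["rho_m"]),
    )


def write_dataset(dataset: GridDataset, path) -> None:
    """Write a grid dataset as TSV: DOF angle columns (radians), then
    ``length_mm`` and one ``moment_<dof>_mm`` column per DOF."""
    cols = {lbl: dataset.postures[:, i] for i, lbl in enumerate(dataset.dof_labels)}
    cols["length_mm"] = dataset.lengths
    for i, lbl in enumerate(dataset.dof_labels):
        cols[f"moment_{lbl}_mm"] = dataset.moments[:, i]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_dataset(path, roms: Sequence | None = None) -> GridDataset:
    """Read a TSV grid dataset written by :func:`write_dataset`.

    ROMs are not stored in the TSV; when not supplied they are taken as the
    per-DOF min/max of the sampled postures.
    """
    df = pd.read_csv(path, sep="\t")
    if "length_mm" not in df.columns:
        raise ValueError(f"{path}: missing 'length_mm' column")
    dof_labels = tuple(
        c for c in df.columns
        if c != "length_mm" and not c.startswith("moment_")
    )
    moment_cols = [f"moment_{lbl}_mm" for lbl in dof_labels]
    missing = [c for c in moment_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing moment-arm columns {missing}")
    P = df[list(dof_labels)].to_numpy(dtype=float)
    if roms is None:
        roms = tuple((float(P[:, i].min()), float(P[:, i].max()))
                     for i in range(P.shape[1]))
    return GridDataset(
        P, df["length_mm"].to_numpy(dtype=float),
        df[moment_cols].to_numpy(dtype=float),
        dof_labels, tuple(tuple(r) for r in roms),
    )


def linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(linkage, list(labels))
    return str(tree)


def write_newick(linkage: np.ndarray, labels: Sequence[str], path) -> None:
    Path(path).write_text(linkage_to_newick(linkage, labels))
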