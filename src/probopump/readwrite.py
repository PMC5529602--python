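"""Readers, writers, fixtures and run configuration.

Species morphometrics travel as CSV with the header::

    species,proboscis_length_mm,food_canal_diameter_um,pump_length_um,
    pump_width_um,pump_height_um,shape

(units suffixed in the column names; ``shape`` is optional with values
``rect``/``circ`` and defaults to rectangular, which uses both measured
chamber dimensions).  Solved fields export to CSV
(``node_index,x,y,value:<units>``, full precision, bit-exact round trip) and
to legacy ASCII VTK unstructured grids for visualisation.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chamber_bvp import ScalarField, TriMesh
from .morphometrics import ProboscisGeometry, Shape, SpeciesRecord

REQUIRED_COLUMNS = [
    "species",
    "proboscis_length_mm",
    "food_canal_diameter_um",
    "pump_length_um",
    "pump_width_um",
    "pump_height_um",
]
_SHAPE_MAP = {"rect": Shape.RECTANGULAR, "circ": Shape.CIRCULAR,
              "": Shape.RECTANGULAR}

MM = 1e-3
UM = 1e-6


class SpeciesCSVError(ValueError):
    """Schema or row-level validation failure, with row numbers."""


def read_species_csv(path) -> list[SpeciesRecord]:
    """Read and validate a species morphometrics CSV.

    Row-level problems (non-numeric cells, non-positive lengths, unknown
    shape codes) are collected and reported together with their row numbers;
    a missing column fails immediately.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SpeciesCSVError(f"missing required column(s): {', '.join(missing)}")
    records: list[SpeciesRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # header is line 1
        vals = {}
        ok = True
        for col, unit in (
            ("proboscis_length_mm", MM),
            ("food_canal_diameter_um", UM),
            ("pump_length_um", UM),
            ("pump_width_um", UM),
            ("pump_height_um", UM),
        ):
            raw = str(row[col]).strip()
            try:
                v = float(raw) * unit
            except ValueError:
                errors.append(f"row {rowno}: non-numeric {col} = {raw!r}")
                ok = False
                continue
            minimum = 0.0 if col == "proboscis_length_mm" else None
            if minimum is not None and v < minimum:
                errors.append(f"row {rowno}: negative {col} = {raw}")
                ok = False
            elif minimum is None and not v > 0:
                errors.append(f"row {rowno}: non-positive {col} = {raw}")
                ok = False
            vals[col] = v
        shape_raw = str(row.get("shape", "")).strip().lower()
        shape = _SHAPE_MAP.get(shape_raw)
        if shape is None:
            errors.append(f"row {rowno}: unknown shape {shape_raw!r} "
                          "(expected 'rect' or 'circ')")
            ok = False
        if not ok:
            continue
        try:
            records.append(SpeciesRecord(
                name=str(row["species"]).strip(),
                proboscis=ProboscisGeometry(
                    l_p=vals["proboscis_length_mm"],
                    d_p=vals["food_canal_diameter_um"]),
                pump_length=vals["pump_length_um"],
                pump_width=vals["pump_width_um"],
                pump_height=vals["pump_height_um"],
                shape=shape,
                provenance=f"{Path(str(path)).name}:row {rowno}",
            ))
        except ValueError as exc:
            errors.append(f"row {rowno}: {exc}")
    if errors:
        raise SpeciesCSVError("; ".join(errors))
    return records


def load_table1() -> list[SpeciesRecord]:
    """The five packaged lepidopteran species (morphometrics in artifact
    units; proboscis length of Manduca sexta at the lower endpoint of its
    measured 50-70 mm range)."""
    with resources.as_file(resources.files("probopump.data") / "table1.csv") as p:
        return read_species_csv(p)


# ---------------------------------------------------------------------------
# field export
# ---------------------------------------------------------------------------

def field_to_csv(fld: ScalarField, path) -> None:
    """Write ``node_index,x,y,value:<units>`` at full double precision."""
    with open(path, "w", newline="\n") as fh:
        fh.write(f"node_index,x,y,value:{fld.units}\n")
        for i, ((x, y), v) in enumerate(zip(fld.mesh.nodes, fld.values)):
            fh.write(f"{i},{float(x)!r},{float(y)!r},{float(v)!r}\n")


def field_from_csv(path, mesh: TriMesh) -> ScalarField:
    """Read a field CSV back onto its mesh (coordinates must match)."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("node_index,x,y,value:"):
            raise ValueError(f"unrecognised field CSV header: {header!r}")
        units = header.split("value:", 1)[1]
        values = np.empty(mesh.n_nodes)
        n = 0
        for line in fh:
            idx, x, y, v = line.strip().split(",")
            i = int(idx)
            if not (math.isclose(float(x), mesh.nodes[i, 0], abs_tol=1e-300, rel_tol=1e-15)
                    and math.isclose(float(y), mesh.nodes[i, 1], abs_tol=1e-300, rel_tol=1e-15)):
                raise ValueError(f"node {i} coordinates do not match the mesh")
            values[i] = float(v)
            n += 1
    if n != mesh.n_nodes:
        raise ValueError("field CSV row count does not match the mesh")
    return ScalarField(mesh, values, units=units)


def field_to_vtk(fld: ScalarField, path, name: Optional[str] = None) -> None:
    """Legacy ASCII VTK unstructured grid (triangle cells, one point scalar)."""
    mesh = fld.mesh
    name = name or fld.name.replace(" ", "_")
    with open(path, "w", newline="\n") as fh:
        fh.write("# vtk DataFile Version 2.0\n")
        fh.write(f"probopump field ({fld.units})\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y in mesh.nodes:
            fh.write(f"{float(x)!r} {float(y)!r} 0.0\n")
        m = mesh.n_triangles
        fh.write(f"CELLS {m} {4 * m}\n")
        for a, b, c in mesh.triangles:
            fh.write(f"3 {a} {b} {c}\n")
        fh.write(f"CELL_TYPES {m}\n")
        fh.write("5\n" * m)
        fh.write(f"POINT_DATA {mesh.n_nodes}\n")
        fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
        for v in fld.values:
            fh.write(f"{float(v)!r}\n")


# ---------------------------------------------------------------------------
# regime reports
# ---------------------------------------------------------------------------

def _json_default(o):
    if isinstance(o, Shape):
        return o.value
    raise TypeError(f"not JSON serialisable: {o!r}")


def reports_to_json(reports: Sequence, path) -> None:
    payload = [r.to_dict() for r in reports]
    for d in payload:
        for k, v in d.items():
            if isinstance(v, float) and math.isinf(v):
                d[k] = "inf"
    with open(path, "w", newline="\n") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def reports_to_csv(reports: Sequence, path) -> None:
    df = pd.DataFrame([r.to_dict() for r in reports])
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Solver/classification knobs for one run; unknown keys are rejected."""

    shape: str = "rectangular"
    aspect: Optional[float] = None
    g: Optional[float] = None
    theta: Optional[float] = None
    tol: float = 0.005
    max_refinements: int = 30
    base_level: int = 0
    fit_range: tuple = (0.05, 0.8)
    tie_tol: float = 0.01
    out: Optional[str] = None
    format: str = "csv"
    log_level: str = "WARNING"

    def __post_init__(self) -> None:
        for label, v in (("tol", self.tol), ("tie_tol", self.tie_tol)):
            if not v > 0:
                raise ValueError(f"{label} must be positive, got {v}")
        if self.max_refinements < 1:
            raise ValueError("max_refinements must be >= 1")
        if self.format not in ("csv", "json", "vtk"):
            raise ValueError(f"unknown format {self.format!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

FIG5_ASPECTS = (1.24, 1.0, 0.4)
FIG5_OPENINGS = (0.05, 0.1, 0.3)
FIG6_THETAS = (0.05, 0.1, 0.15, 0.3, 0.6, 0.78)


def generate_fixtures(out_dir, seed: int = 0) -> dict:
    """Write the packaged species table, a synthetic morphometrics sweep and
    the dimensionless geometry grids; returns the manifest (also written as
    ``manifest.json``).

    The synthetic sweep spans f-factors from 1e-2 to 1e7 on a log grid with
    deterministic jitter from ``seed``, so it straddles every regime-boundary
    curve (boundary f values lie roughly between 0.01 and 10).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    files = {}

    table1 = (resources.files("probopump.data") / "table1.csv").read_text()
    (out / "table1.csv").write_text(table1, newline="\n")
    files["table1.csv"] = None

    # synthetic sweep: choose plausible chamber/canal scales, then set the
    # proboscis length to land each point on its target f
    n = 25
    f_targets = np.geomspace(1e-2, 1e7, n) * 10 ** (0.05 * rng.uniform(-1, 1, n))
    lines = ["species,proboscis_length_mm,food_canal_diameter_um,pump_length_um,"
             "pump_width_um,pump_height_um,shape"]
    for i in range(n):
        d_p = 10 ** rng.uniform(math.log10(15), math.log10(100)) * UM
        L = rng.uniform(300, 2500) * UM
        aspect = rng.uniform(0.5, 1.5)
        W = max(aspect * L, 1.5 * d_p)
        h = rng.uniform(0.1, 0.6) * L
        l_p = f_targets[i] * d_p**4 / h**3
        shape = "rect" if i % 2 == 0 else "circ"
        lines.append(
            f"synthetic_{i:02d},{l_p / MM:.6g},{d_p / UM:.6g},{L / UM:.6g},"
            f"{W / UM:.6g},{h / UM:.6g},{shape}")
    (out / "synthetic_sweep.csv").write_text("\n".join(lines) + "\n", newline="\n")
    files["synthetic_sweep.csv"] = None

    lines = ["shape,aspect,g,theta"]
    for a in FIG5_ASPECTS:
        for g in FIG5_OPENINGS:
            lines.append(f"rectangular,{a},{g},")
    for th in FIG6_THETAS:
        lines.append(f"circular,,,{th}")
    (out / "geometry_grid.csv").write_text("\n".join(lines) + "\n", newline="\n")
    files["geometry_grid.csv"] = None

    for fname in files:
        digest = hashlib.sha256((out / fname).read_bytes()).hexdigest()
        files[fname] = digest
    manifest = {"seed": int(seed), "files": files}
    with open(out / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
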