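"""File formats: models, RDF curves, XVG-dialect series, configurations.

All writers emit the same dialect their reader consumes and round-trip
values at 10 significant digits.  Output files are written atomically
(temp file + rename) so interrupted runs never leave corrupt records.
Internal units are nm/ps/e/kJ/mol; RDF grids are in Angstrom.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .models import WaterModel
from .observables import CoexistenceTable, ObservableSeries, RDFCurve

__all__ = [
    "Frame",
    "atomic_write",
    "read_model",
    "write_model",
    "read_rdf",
    "write_rdf",
    "read_xvg",
    "write_xvg",
    "read_coexistence_table",
    "write_coexistence_table",
    "read_configuration_frames",
    "RunConfig",
    "read_run_config",
]


def atomic_write(path: str | Path, text: str) -> None:
    """Write ``text`` to ``path`` via a temporary file and atomic rename."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# water-model files: flat key-value text

_MODEL_KEYS = ("d_OH_nm", "d_HH_nm", "q_O_e", "sigma_nm", "epsilon_kjmol")


def read_model(path: str | Path) -> WaterModel:
    """Read a flat key-value model file (keys: name, d_OH_nm, d_HH_nm,
    q_O_e, sigma_nm, epsilon_kjmol)."""
    entries: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'key value', got {raw!r}")
        entries[parts[0]] = parts[1].strip()
    missing = [k for k in ("name", *_MODEL_KEYS) if k not in entries]
    if missing:
        raise ValueError(f"{path}: missing keys {missing}")
    return WaterModel(
        name=entries["name"],
        d_OH=float(entries["d_OH_nm"]),
        d_HH=float(entries["d_HH_nm"]),
        q_O=float(entries["q_O_e"]),
        sigma=float(entries["sigma_nm"]),
        epsilon_lj=float(entries["epsilon_kjmol"]),
    )


def write_model(model: WaterModel, path: str | Path) -> None:
    lines = [f"name {model.name}"]
    for key, value in zip(
        _MODEL_KEYS, (model.d_OH, model.d_HH, model.q_O, model.sigma, model.epsilon_lj)
    ):
        lines.append(f"{key} {value:.10g}")
    atomic_write(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# RDF files: two-column text, r in Angstrom

def read_rdf(path: str | Path, pair_label: str, cutoff: float | None = None) -> RDFCurve:
    data = _read_columns(path)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: RDF file needs two columns (r, g)")
    r, g = data[:, 0], data[:, 1]
    dr = r[1] - r[0] if len(r) > 1 else 0.0
    return RDFCurve(
        bin_centers=r,
        g_values=g,
        cutoff=cutoff if cutoff is not None else float(r[-1] + dr / 2.0),
        pair_label=pair_label,
    )


def write_rdf(curve: RDFCurve, path: str | Path) -> None:
    lines = [f"# g_{curve.pair_label}(r): r [A]  g  (cutoff {curve.cutoff:.10g} A)"]
    for r, g in zip(curve.bin_centers, curve.g_values):
        lines.append(f"{r:.10g} {g:.10g}")
    atomic_write(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# XVG-dialect series

def _read_columns(path: str | Path) -> np.ndarray:
    rows = []
    width = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "@")):
            continue
        fields = line.split()
        try:
            row = [float(x) for x in fields]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric field in {raw!r}") from exc
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise ValueError(
                f"{path}:{lineno}: ragged row ({len(row)} columns, expected {width})"
            )
        rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return np.asarray(rows)


def read_xvg(path: str | Path, kind: str, units: str = "") -> ObservableSeries:
    """Read an XVG-dialect file: '#'/'@' lines skipped, first column time (ps).

    Scalar kinds take column 2; the vector kinds (dipole_vector,
    pressure_diagonal) take columns 2-4.
    """
    data = _read_columns(path)
    t = data[:, 0]
    if len(t) > 1:
        dt = float(np.mean(np.diff(t)))
        if dt <= 0:
            raise ValueError(f"{path}: time column must be increasing")
    else:
        dt = 1.0
    if kind in ("dipole_vector", "pressure_diagonal"):
        if data.shape[1] < 4:
            raise ValueError(f"{path}: vector series needs 4 columns (t, x, y, z)")
        values = data[:, 1:4]
    else:
        if data.shape[1] < 2:
            raise ValueError(f"{path}: series needs at least 2 columns")
        values = data[:, 1]
    return ObservableSeries(values=values, dt=dt, units=units, kind=kind)


def write_xvg(series: ObservableSeries, path: str | Path, comment: str = "") -> None:
    lines = [f"# {comment}" if comment else f"# {series.kind} [{series.units}]"]
    lines.append(f"@ kind {series.kind}")
    values = np.atleast_2d(series.values.T).T
    for i, row in enumerate(values):
        fields = " ".join(f"{v:.10g}" for v in np.atleast_1d(row))
        lines.append(f"{i * series.dt:.10g} {fields}")
    atomic_write(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# coexistence tables: columnar text with one header row

def read_coexistence_table(path: str | Path) -> CoexistenceTable:
    text = Path(path).read_text().splitlines()
    body = [l for l in text if l.strip() and not l.lstrip().startswith("#")]
    if not body:
        raise ValueError(f"{path}: empty table")
    header = body[0].split()
    if any(_is_float(h) for h in header):
        raise ValueError(f"{path}: first row must be a header (T rho_liq rho_vap)")
    rows = np.asarray([[float(x) for x in l.split()] for l in body[1:]])
    return CoexistenceTable(temperatures=rows[:, 0], rho_liq=rows[:, 1], rho_vap=rows[:, 2])


def write_coexistence_table(table: CoexistenceTable, path: str | Path) -> None:
    lines = ["T_K rho_liq_gcm3 rho_vap_gcm3"]
    for t, rl, rv in zip(table.temperatures, table.rho_liq, table.rho_vap):
        lines.append(f"{t:.10g} {rl:.10g} {rv:.10g}")
    atomic_write(path, "\n".join(lines) + "\n")


def _is_float(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# configuration frames

@dataclass(frozen=True)
class Frame:
    """One configuration: site names, positions (nm) and orthorhombic box (nm)."""

    names: tuple[str, ...]
    positions: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        box = np.asarray(self.box, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "box", box)
        if pos.ndim != 2 or pos.shape[1] != 3 or len(pos) != len(self.names):
            raise ValueError("positions must be (n_atoms, 3) matching names")
        if box.shape != (3,) or np.any(box <= 0):
            raise ValueError("box must be three positive edge lengths")


def read_configuration_frames(path: str | Path, fmt: str | None = None) -> list[Frame]:
    """Read XYZ or GRO configurations (format inferred from the suffix).

    XYZ coordinates are assumed to be in Angstrom and must carry the box
    in the comment line as ``box 	Lx Ly Lz`` (Angstrom); GRO files are
    native nm with the standard trailing box line (read via MDAnalysis).
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "gro":
        return _read_gro(path)
    raise ValueError(f"unsupported configuration format {fmt!r} (use xyz or gro)")


def _read_xyz(path: Path) -> list[Frame]:
    lines = path.read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        comment = lines[i + 1]
        tokens = comment.split()
        if "box" not in tokens or len(tokens) < tokens.index("box") + 4:
            raise ValueError(
                f"{path}: XYZ comment line must contain 'box Lx Ly Lz' (A); got {comment!r}"
            )
        j = tokens.index("box")
        box_a = np.array([float(x) for x in tokens[j + 1 : j + 4]])
        names, pos = [], []
        for row in lines[i + 2 : i + 2 + n]:
            parts = row.split()
            names.append(parts[0])
            pos.append([float(x) for x in parts[1:4]])
        frames.append(
            Frame(names=tuple(names), positions=np.asarray(pos) * 0.1, box=box_a * 0.1)
        )
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return frames


def _read_gro(path: Path) -> list[Frame]:
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    frames = []
    for _ in u.trajectory:
        dims = u.dimensions
        if dims is None or np.any(dims[:3] <= 0):
            raise ValueError(f"{path}: GRO file has no box line")
        frames.append(
            Frame(
                names=tuple(u.atoms.names),
                positions=u.atoms.positions * 0.1,  # MDAnalysis works in A
                box=dims[:3] * 0.1,
            )
        )
    return frames


# ---------------------------------------------------------------------------
# run configuration

@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one optimization run."""

    bounds: dict[str, tuple[float, float]]
    weights: tuple[float, float, float] = (0.5, 0.3, 0.2)
    temperatures: tuple[float, ...] = (280.0, 298.0, 343.0)
    n_particles: int = 15
    max_iter: int = 300
    collapse_radius: float = 1e-3
    seed: int = 0
    evaluator: str = "surrogate"
    reference_model: str | None = "OPC3"
    self_tuning: bool = False

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bound for {name}: lower {lo} must be < upper {hi}")
        if self.n_particles < 2:
            raise ValueError("n_particles must be at least 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be nonnegative")


def read_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "bounds" not in raw:
        raise ValueError(f"{path}: config must be a mapping with a 'bounds' section")
    bounds = {k: (float(v[0]), float(v[1])) for k, v in raw["bounds"].items()}
    kwargs = {}
    for key in (
        "weights",
        "temperatures",
        "n_particles",
        "max_iter",
        "collapse_radius",
        "seed",
        "evaluator",
        "reference_model",
        "self_tuning",
    ):
        if key in raw:
            value = raw[key]
            if key in ("weights", "temperatures"):
                value = tuple(float(x) for x in value)
            kwargs[key] = value
    return RunConfig(bounds=bounds, **kwargs)
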