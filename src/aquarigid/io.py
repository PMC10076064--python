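"""File formats, run configuration, and reproducibility manifests.

Coordinate conventions: orthorhombic boxes with the origin at a corner;
positions are stored internally in Å (GRO files are converted from nm on
read and back on write).  Trajectories are written as extended XYZ with
the lattice and energy summary in the comment line, plus a plain-text
energy log (CSV) with one row per stored frame.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import re
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import yaml

from .core import SITES_PER_MOL, SystemState, Topology, Trajectory
from .engine import RunConfig
from .errors import ConfigError, FormatError, TopologyError
from .models import WaterModel

__all__ = ["read_coords", "write_coords", "write_trajectory",
           "read_trajectory", "write_energy_log", "load_config",
           "load_preset", "RunManifest"]

_SITE_NAMES = ("OW", "HW1", "HW2", "MW")
_WATER_O = {"O", "OW", "OH2", "OW1"}
_WATER_H = {"H", "H1", "H2", "HW1", "HW2", "HW"}
_WATER_M = {"M", "MW", "MW1", "EPW"}


def _classify(name: str, override: Optional[dict] = None) -> Optional[str]:
    if override and name in override:
        return override[name]
    base = name.strip()
    if base in _WATER_O or base.rstrip("0123456789") in _WATER_O:
        return "O"
    if base in _WATER_H or base.rstrip("0123456789") in _WATER_H:
        return "H"
    if base in _WATER_M:
        return "M"
    return None


def _assemble(names, coords, override) -> Tuple[np.ndarray, int]:
    """Group a flat atom list into per-molecule (O, H, H[, M]) site blocks."""
    kinds = [_classify(n, override) for n in names]
    if any(k is None for k in kinds):
        bad = sorted({n for n, k in zip(names, kinds) if k is None})
        raise TopologyError(
            f"unrecognized atom names {bad}; supply an override map "
            "(name -> O|H|M)")
    mols = []
    i = 0
    n = len(kinds)
    while i < n:
        if kinds[i] != "O":
            raise TopologyError(
                f"expected an O atom starting molecule at index {i}, "
                f"got {names[i]!r}")
        if i + 2 >= n or kinds[i + 1] != "H" or kinds[i + 2] != "H":
            raise TopologyError(f"molecule at index {i} lacks two hydrogens")
        has_m = i + 3 < n and kinds[i + 3] == "M"
        block = np.zeros((SITES_PER_MOL, 3))
        block[0] = coords[i]
        block[1] = coords[i + 1]
        block[2] = coords[i + 2]
        block[3] = coords[i + 3] if has_m else coords[i]  # rebuilt later
        mols.append(block)
        i += 4 if has_m else 3
    return np.concatenate(mols), len(mols)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_coords(path, fmt: str = "auto",
                override: Optional[dict] = None) -> Tuple[SystemState, int]:
    """Read coordinates; returns (state, n_molecules).

    Formats: extended XYZ (with a ``Lattice="..."`` comment), GRO
    (nm → Å) and PDB.  Water molecules are detected by atom naming
    (OW/HW…, O/H…, M/MW for the virtual site) with an optional
    ``override`` map; 3-site files get their M slot filled with the O
    position — call :func:`aquarigid.engine.rebuild_msites` once a
    topology exists.  The M-site slot of each molecule is a placeholder
    until then.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = {".xyz": "xyz", ".gro": "gro", ".pdb": "pdb"}.get(
            path.suffix.lower())
        if fmt is None:
            raise FormatError(f"cannot infer format from {path.name!r}")
    if fmt == "xyz":
        return _read_xyz(path, override)
    if fmt == "gro":
        return _read_gro(path, override)
    if fmt == "pdb":
        return _read_pdb(path, override)
    raise FormatError(f"unknown format {fmt!r}")


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')


def _parse_lattice(comment: str) -> Optional[np.ndarray]:
    m = _LATTICE_RE.search(comment)
    if not m:
        return None
    v = np.array([float(x) for x in m.group(1).split()]).reshape(3, 3)
    if not np.allclose(v, np.diag(np.diag(v))):
        raise FormatError("only orthorhombic lattices are supported")
    return np.diag(v).copy()


def _read_xyz(path, override):
    with open(path) as fh:
        natoms = int(fh.readline())
        comment = fh.readline()
        names, coords = [], []
        for _ in range(natoms):
            parts = fh.readline().split()
            names.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
    box = _parse_lattice(comment)
    if box is None:
        raise FormatError("XYZ comment line lacks a Lattice specification")
    pos, nmol = _assemble(names, np.array(coords), override)
    return SystemState(pos, np.zeros_like(pos), box), nmol


def _read_gro(path, override):
    with open(path) as fh:
        fh.readline()
        natoms = int(fh.readline())
        names, coords = [], []
        for _ in range(natoms):
            line = fh.readline()
            names.append(line[10:15].strip())
            coords.append([float(line[20:28]), float(line[28:36]),
                           float(line[36:44])])
        box_fields = [float(x) for x in fh.readline().split()]
    box = np.array(box_fields[:3]) * 10.0          # nm → Å
    pos, nmol = _assemble(names, np.array(coords) * 10.0, override)
    return SystemState(pos, np.zeros_like(pos), box), nmol


def _read_pdb(path, override):
    names, coords = [], []
    box = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                box = np.array([float(line[6:15]), float(line[15:24]),
                                float(line[24:33])])
            elif line.startswith(("ATOM", "HETATM")):
                names.append(line[12:16].strip())
                coords.append([float(line[30:38]), float(line[38:46]),
                               float(line[46:54])])
    if box is None:
        raise FormatError("PDB lacks a CRYST1 record")
    pos, nmol = _assemble(names, np.array(coords), override)
    return SystemState(pos, np.zeros_like(pos), box), nmol


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _frame_lines(positions, box, comment):
    lat = (f'Lattice="{box[0]:.10g} 0 0 0 {box[1]:.10g} 0 0 0 {box[2]:.10g}" '
           'Properties=species:S:1:pos:R:3')
    lines = [str(len(positions)), lat + " " + comment]
    nm = len(positions) // SITES_PER_MOL
    for m in range(nm):
        for s in range(SITES_PER_MOL):
            p = positions[m * SITES_PER_MOL + s]
            lines.append(f"{_SITE_NAMES[s]} {p[0]:.8f} {p[1]:.8f} {p[2]:.8f}")
    return lines


def write_coords(state: SystemState, path, fmt: str = "auto") -> None:
    """Write a single configuration (XYZ or GRO)."""
    path = Path(path)
    if fmt == "auto":
        fmt = {".xyz": "xyz", ".gro": "gro"}.get(path.suffix.lower(), "xyz")
    if fmt == "xyz":
        path.write_text("\n".join(_frame_lines(
            state.positions, state.box, f"time={state.time:.6g}")) + "\n")
        return
    if fmt == "gro":
        lines = ["aquarigid configuration", str(len(state.positions))]
        nm = len(state.positions) // SITES_PER_MOL
        for m in range(nm):
            for s in range(SITES_PER_MOL):
                p = state.positions[m * SITES_PER_MOL + s] / 10.0
                idx = m * SITES_PER_MOL + s + 1
                lines.append(f"{m + 1:5d}{'SOL':<5s}{_SITE_NAMES[s]:>5s}"
                             f"{idx % 100000:5d}"
                             f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}")
        b = state.box / 10.0
        lines.append(f"{b[0]:10.5f}{b[1]:10.5f}{b[2]:10.5f}")
        path.write_text("\n".join(lines) + "\n")
        return
    raise FormatError(f"unknown format {fmt!r}")


def write_trajectory(traj: Trajectory, path) -> None:
    """Stream frames to extended XYZ (memory use independent of length)."""
    path = Path(path)
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            comment = f"time={traj.times[f]:.6g}"
            if traj.energies is not None and f < len(traj.energies):
                row = traj.energies.iloc[f]
                comment += (f" total={row['total']:.6f}"
                            f" temperature={row['temperature']:.4f}")
            for line in _frame_lines(traj.positions[f], traj.boxes[f],
                                     comment):
                fh.write(line + "\n")


def read_trajectory(path, model: Optional[WaterModel] = None) -> Trajectory:
    """Read an extended-XYZ trajectory written by :func:`write_trajectory`."""
    frames, boxes, times = [], [], []
    with open(path) as fh:
        while True:
            head = fh.readline()
            if not head.strip():
                break
            natoms = int(head)
            comment = fh.readline()
            box = _parse_lattice(comment)
            m = re.search(r"time=([-\d.eE+]+)", comment)
            times.append(float(m.group(1)) if m else len(times))
            coords = np.empty((natoms, 3))
            for i in range(natoms):
                parts = fh.readline().split()
                coords[i] = [float(x) for x in parts[1:4]]
            frames.append(coords)
            boxes.append(box)
    topo = None
    if model is not None and frames:
        topo = Topology(model, len(frames[0]) // SITES_PER_MOL)
    return Trajectory(np.array(frames), np.array(boxes),
                      np.array(times, dtype=float), topology=topo)


def write_energy_log(traj: Trajectory, path) -> None:
    """Plain-text energy log: step time, T, components, pressure tensor."""
    if traj.energies is None:
        raise FormatError("trajectory has no energy log")
    traj.energies.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_ENGINE_KEYS = set(RunConfig.__dataclass_fields__)
_SECTION_KEYS = {
    "engine": _ENGINE_KEYS,
    "coexistence": {"window", "avg_span", "tol", "t_low", "t_high",
                    "n_steps", "replicas", "t_melt", "gap",
                    "melt_time", "cool_time"},
    "builder": {"n_molecules", "stack_z", "t_equil", "t_avg"},
    "observables": {"rdf_rmax", "rdf_bin", "fit_window", "n_blocks",
                    "temperature"},
    "models": None,   # free-form: per-model timestep/flags
}


def _check_keys(section: str, mapping: dict) -> None:
    allowed = _SECTION_KEYS[section]
    if allowed is None:
        return
    for key in mapping:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(
                f"unknown key {key!r} in section {section!r}{suffix} "
                f"(allowed: {sorted(allowed)})")


def load_config(path, overrides: Optional[dict] = None) -> dict:
    """Load and validate a YAML run configuration.

    Returns a dict with an ``engine`` :class:`RunConfig` plus the other
    validated sections.  ``overrides`` (e.g. from CLI flags) take
    precedence over file values.  Unknown keys are a hard error with a
    closest-match suggestion.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file {path} does not exist")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} is not a mapping")
    unknown = set(raw) - set(_SECTION_KEYS)
    if unknown:
        raise ConfigError(f"unknown sections {sorted(unknown)}; "
                          f"expected {sorted(_SECTION_KEYS)}")
    out = {}
    for section, content in raw.items():
        content = dict(content or {})
        _check_keys(section, content)
        out[section] = content
    if overrides:
        for section, kv in overrides.items():
            _check_keys(section, kv)
            out.setdefault(section, {}).update(kv)
    engine_kwargs = out.get("engine", {})
    out["engine"] = RunConfig(**engine_kwargs)
    return out


def load_preset(name: str) -> Path:
    """Path of a shipped preset (``paper`` or ``desk``)."""
    ref = resources.files("aquarigid").joinpath(f"presets/{name}.yaml")
    if not ref.is_file():
        raise ConfigError(f"no preset named {name!r}")
    return Path(str(ref))


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-launch an identical run."""

    command: str
    seed: int
    config: dict
    model_hash: str = ""
    code_version: str = ""
    input_checksums: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    @classmethod
    def create(cls, command: str, seed: int, config: dict,
               model: Optional[WaterModel] = None,
               inputs: Optional[list] = None) -> "RunManifest":
        from . import __version__
        mhash = ""
        if model is not None:
            blob = json.dumps(
                {"name": model.name, "q_H": model.q_H, "a": model.msite_a,
                 "mode": model.mode,
                 "lj": {k: [v.epsilon, v.sigma]
                        for k, v in model.lj_sites.items()}},
                sort_keys=True)
            mhash = hashlib.sha256(blob.encode()).hexdigest()[:16]
        checks = {str(p): _sha256(p) for p in (inputs or [])}
        cfg = {k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
               for k, v in config.items()}
        return cls(command=command, seed=seed, config=cfg, model_hash=mhash,
                   code_version=__version__, input_checksums=checks)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2,
                                         default=str) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
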