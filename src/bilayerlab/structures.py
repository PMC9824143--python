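"""Labelled particle configurations and trajectories, with GRO/PDB IO.

Internal units are nm for coordinates and box lengths (PDB input in Å is
converted on load).  Site roles are drawn from a closed vocabulary so the
analysis stages can select phosphorus planes, carbonyl/methyl markers and
hydrogen-bond donor/H/acceptor triplets without knowing force-field atom
names; the atom-name→role mapping is user configuration.

PDB files (single- and multi-frame) are parsed through MDAnalysis.  The GRO
dialect — including concatenated multi-frame files — is parsed here with the
fixed-column layout, because frame-indexed error reporting on concatenated
frames is part of the contract.  Only orthorhombic boxes are accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ROLES",
    "KINDS",
    "Configuration",
    "Trajectory",
    "StructureParseError",
    "read_structure",
    "read_trajectory",
    "write_gro",
    "write_pdb",
]

ROLES = frozenset(
    {"phosphorus", "carbonyl", "terminal_methyl", "donor", "hydrogen",
     "acceptor", "other"}
)
KINDS = frozenset({"lipid", "solute", "water"})

#: residue names that default to molecule kind "water" when no kind map is given
_WATER_RESNAMES = {"SOL", "WAT", "HOH", "TIP3", "TIP", "SPC", "W"}

#: fallback element masses (amu) guessed from the leading letter of atom names
_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "F": 18.998, "K": 39.098,
}


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


@dataclass
class Configuration:
    """A single labelled configuration in an orthorhombic box.

    positions are (N, 3) in nm; ``box`` holds the three box lengths in nm.
    ``mol_ids`` groups atoms into molecules; ``mol_kinds`` ∈ {lipid, solute,
    water}; ``roles`` ∈ :data:`ROLES`; masses are in amu.
    """

    positions: np.ndarray
    box: np.ndarray
    mol_ids: np.ndarray
    mol_kinds: np.ndarray
    roles: np.ndarray
    masses: np.ndarray
    names: np.ndarray | None = None
    resnames: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        n = self.positions.shape[0]
        self.mol_ids = np.asarray(self.mol_ids, dtype=int)
        self.mol_kinds = np.asarray(self.mol_kinds, dtype=object)
        self.roles = np.asarray(self.roles, dtype=object)
        self.masses = np.asarray(self.masses, dtype=float)
        for arr, what in [
            (self.mol_ids, "mol_ids"), (self.mol_kinds, "mol_kinds"),
            (self.roles, "roles"), (self.masses, "masses"),
        ]:
            if arr.shape != (n,):
                raise ValueError(f"{what} must have length {n}")
        if not np.isfinite(self.positions).all():
            raise ValueError("positions must be finite")
        if not np.all(self.box > 0):
            raise ValueError("box lengths must be positive")
        bad = set(self.roles) - ROLES
        if bad:
            raise ValueError(f"unknown site roles: {sorted(bad)}")
        bad = set(self.mol_kinds) - KINDS
        if bad:
            raise ValueError(f"unknown molecule kinds: {sorted(bad)}")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def indices(self, *, role: str | None = None,
                kind: str | None = None) -> np.ndarray:
        """Atom indices matching the given site role and/or molecule kind."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if role is not None:
            mask &= self.roles == role
        if kind is not None:
            mask &= self.mol_kinds == kind
        return np.flatnonzero(mask)

    def molecules(self, kind: str | None = None) -> dict[int, np.ndarray]:
        """Map molecule id → atom indices, optionally restricted by kind."""
        sel = self.indices(kind=kind)
        out: dict[int, list[int]] = {}
        for i in sel:
            out.setdefault(int(self.mol_ids[i]), []).append(int(i))
        return {m: np.asarray(v) for m, v in out.items()}


@dataclass
class Trajectory:
    """An ordered sequence of configurations sharing atom count and labels."""

    frames: list[Configuration]
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory has no frames")
        first = self.frames[0]
        for k, fr in enumerate(self.frames):
            if fr.n_atoms != first.n_atoms:
                raise ValueError(
                    f"frame {k} has {fr.n_atoms} atoms, expected {first.n_atoms}"
                )
        if self.times is None:
            self.times = np.arange(len(self.frames), dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (len(self.frames),):
            raise ValueError("times must have one entry per frame")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("frame times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


# ---------------------------------------------------------------------------
# labelling helpers

def _guess_mass(name: str) -> float:
    stripped = name.lstrip("0123456789")
    key = stripped[:1].upper()
    return _ELEMENT_MASSES.get(key, 12.011)


def _label(names, resnames, resids, role_map, kind_map, mass_map):
    role_map = role_map or {}
    roles = np.array([role_map.get(n, "other") for n in names], dtype=object)
    if kind_map:
        kinds = [kind_map.get(rn, "water" if rn in _WATER_RESNAMES else "lipid")
                 for rn in resnames]
    else:
        kinds = ["water" if rn in _WATER_RESNAMES else "lipid" for rn in resnames]
    kinds = np.array(kinds, dtype=object)
    if mass_map:
        masses = np.array([mass_map.get(n, _guess_mass(n)) for n in names])
    else:
        masses = np.array([_guess_mass(n) for n in names])
    return roles, kinds, masses


# ---------------------------------------------------------------------------
# GRO dialect (fixed columns, nm)

def _parse_gro_frame(fh, path, frame_index, start_line):
    """Parse one GRO frame; returns (frame dict, lines consumed) or None at EOF."""
    title = fh.readline()
    if title == "":
        return None, 0
    count_line = fh.readline()
    try:
        natoms = int(count_line.strip())
    except ValueError:
        raise StructureParseError(
            f"{path}: bad atom count at line {start_line + 2}: "
            f"{count_line.strip()!r}"
        ) from None
    resids, resnames, names, pos = [], [], [], []
    for i in range(natoms):
        line = fh.readline()
        lineno = start_line + 3 + i
        if line == "":
            raise StructureParseError(
                f"{path}: frame {frame_index}: unexpected end of file at "
                f"line {lineno}"
            )
        try:
            resids.append(int(line[0:5]))
            resnames.append(line[5:10].strip())
            names.append(line[10:15].strip())
            pos.append([float(line[20:28]), float(line[28:36]),
                        float(line[36:44])])
        except (ValueError, IndexError):
            raise StructureParseError(
                f"{path}: malformed fixed-column atom record at line {lineno}"
            ) from None
    box_line = fh.readline()
    if box_line == "":
        raise StructureParseError(
            f"{path}: frame {frame_index}: missing box line"
        )
    try:
        box_vals = [float(v) for v in box_line.split()]
    except ValueError:
        raise StructureParseError(
            f"{path}: malformed box line at line {start_line + 3 + natoms}"
        ) from None
    if len(box_vals) < 3:
        raise StructureParseError(f"{path}: missing box in frame {frame_index}")
    if len(box_vals) > 3 and any(abs(v) > 1e-9 for v in box_vals[3:]):
        raise StructureParseError(
            f"{path}: triclinic box in frame {frame_index}; only orthorhombic "
            "boxes are supported"
        )
    frame = {
        "resids": resids, "resnames": resnames, "names": names,
        "positions": np.asarray(pos), "box": np.asarray(box_vals[:3]),
    }
    return frame, 3 + natoms


def _read_gro_frames(path):
    frames = []
    with open(path) as fh:
        line = 0
        while True:
            frame, consumed = _parse_gro_frame(fh, path, len(frames) + 1, line)
            if frame is None:
                break
            frames.append(frame)
            line += consumed
    if not frames:
        raise StructureParseError(f"{path}: no frames")
    return frames


# ---------------------------------------------------------------------------
# PDB dialect (Å, via MDAnalysis)

def _read_pdb_frames(path):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:  # noqa: BLE001 - normalise parser errors
            raise StructureParseError(f"{path}: cannot parse PDB: {exc}") from exc
        frames = []
        names = [n.strip() for n in u.atoms.names]
        resnames = [r.strip() for r in u.atoms.resnames]
        resids = list(u.atoms.resids)
        for ts in u.trajectory:
            dims = ts.dimensions
            if dims is None or not np.all(np.asarray(dims[:3]) > 0):
                raise StructureParseError(
                    f"{path}: missing CRYST1 box in frame {ts.frame}"
                )
            if not np.allclose(dims[3:6], 90.0, atol=1e-3):
                raise StructureParseError(
                    f"{path}: non-orthorhombic box in frame {ts.frame}"
                )
            frames.append({
                "resids": resids, "resnames": resnames, "names": names,
                "positions": u.atoms.positions / 10.0,  # Å → nm
                "box": np.asarray(dims[:3]) / 10.0,
            })
    if not frames:
        raise StructureParseError(f"{path}: no frames")
    return frames


def _frames_to_config(frame, role_map, kind_map, mass_map) -> Configuration:
    roles, kinds, masses = _label(
        frame["names"], frame["resnames"], frame["resids"],
        role_map, kind_map, mass_map,
    )
    return Configuration(
        positions=frame["positions"], box=frame["box"],
        mol_ids=np.asarray(frame["resids"], dtype=int),
        mol_kinds=kinds, roles=roles, masses=masses,
        names=np.asarray(frame["names"], dtype=object),
        resnames=np.asarray(frame["resnames"], dtype=object),
    )


def _infer_format(path, fmt):
    if fmt:
        return fmt.lower()
    s = str(path).lower()
    if s.endswith(".gro"):
        return "gro"
    if s.endswith(".pdb"):
        return "pdb"
    raise ValueError(f"cannot infer structure format from {path!r}")


def read_structure(path, fmt: str | None = None, *, role_map=None,
                   kind_map=None, mass_map=None) -> Configuration:
    """Read a single-frame GRO or PDB file into a :class:`Configuration`.

    ``role_map`` maps atom names to site roles (unmapped → "other");
    ``kind_map`` maps residue names to molecule kinds (unmapped → "water" for
    common water residue names, else "lipid"); ``mass_map`` overrides the
    element guess by atom name.
    """
    fmt = _infer_format(path, fmt)
    frames = _read_gro_frames(path) if fmt == "gro" else _read_pdb_frames(path)
    return _frames_to_config(frames[0], role_map, kind_map, mass_map)


def read_trajectory(path, fmt: str | None = None, *, role_map=None,
                    kind_map=None, mass_map=None,
                    times=None) -> Trajectory:
    """Read a multi-frame (concatenated GRO or MODEL-separated PDB) file.

    Labelling is taken from the first frame and shared by all frames; a frame
    with a different atom count raises an error naming the frame index.
    """
    fmt = _infer_format(path, fmt)
    frames = _read_gro_frames(path) if fmt == "gro" else _read_pdb_frames(path)
    n0 = frames[0]["positions"].shape[0]
    for k, fr in enumerate(frames):
        if fr["positions"].shape[0] != n0:
            raise StructureParseError(
                f"{path}: frame {k + 1} has {fr['positions'].shape[0]} atoms, "
                f"expected {n0}"
            )
    first = _frames_to_config(frames[0], role_map, kind_map, mass_map)
    configs = [first]
    for fr in frames[1:]:
        configs.append(Configuration(
            positions=fr["positions"], box=fr["box"],
            mol_ids=first.mol_ids, mol_kinds=first.mol_kinds,
            roles=first.roles, masses=first.masses,
            names=first.names, resnames=first.resnames,
        ))
    return Trajectory(configs, times)


# ---------------------------------------------------------------------------
# writers (used by the synthetic generator and round-trip tests)

def _default_names(conf: Configuration):
    names = conf.names if conf.names is not None else np.array(
        ["X"] * conf.n_atoms, dtype=object)
    resnames = conf.resnames if conf.resnames is not None else np.array(
        ["MOL"] * conf.n_atoms, dtype=object)
    return names, resnames


def write_gro(obj: Configuration | Trajectory, path, title: str = "bilayerlab") -> None:
    """Write a configuration or trajectory as (concatenated) GRO text."""
    frames = obj.frames if isinstance(obj, Trajectory) else [obj]
    with open(path, "w") as fh:
        for fi, conf in enumerate(frames):
            names, resnames = _default_names(conf)
            fh.write(f"{title} frame {fi}\n{conf.n_atoms}\n")
            for i in range(conf.n_atoms):
                x, y, z = conf.positions[i]
                fh.write(
                    f"{int(conf.mol_ids[i]) % 100000:5d}"
                    f"{str(resnames[i])[:5]:<5s}{str(names[i])[:5]:>5s}"
                    f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            bx, by, bz = conf.box
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


def write_pdb(obj: Configuration | Trajectory, path) -> None:
    """Write a configuration or trajectory as (multi-MODEL) PDB text (Å)."""
    frames = obj.frames if isinstance(obj, Trajectory) else [obj]
    multi = len(frames) > 1
    with open(path, "w") as fh:
        for fi, conf in enumerate(frames):
            names, resnames = _default_names(conf)
            a, b, c = conf.box * 10.0
            fh.write(
                f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}"
                f"{90.0:7.2f} P 1           1\n"
            )
            if multi:
                fh.write(f"MODEL     {fi + 1:4d}\n")
            for i in range(conf.n_atoms):
                x, y, z = conf.positions[i] * 10.0  # nm → Å
                elem = str(names[i]).lstrip("0123456789")[:1].upper() or "C"
                fh.write(
                    f"ATOM  {(i + 1) % 100000:5d} {str(names[i])[:4]:<4s} "
                    f"{str(resnames[i])[:3]:<3s}  "
                    f"{int(conf.mol_ids[i]) % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {elem:>2s}\n"
                )
            fh.write("ENDMDL\n" if multi else "TER\n")
        fh.write("END\n")
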