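"""Particle coordinate I/O for coarse-grained membrane analysis.

Reads particle frames from GRO (fixed-column, possibly concatenated into a
multi-frame trajectory) and multi-model PDB files, selects marker particles
(e.g. the phosphate bead of each lipid headgroup) by name, and writes
analysis outputs.  All positions are kept in nanometres internally: GRO is
nm-native, PDB coordinates are Angstrom and are divided by 10 on read.

Only orthorhombic simulation boxes are supported; the downstream binning and
minimum-image geometry assume axis-aligned box vectors.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ParticleFrame",
    "Trajectory",
    "ParseError",
    "StructuralError",
    "EmptySelectionError",
    "UnsupportedFormatError",
    "read_coordinates",
    "write_gro",
    "select_particles",
]

ANGSTROM_PER_NM = 10.0


class ParseError(ValueError):
    """A record in a coordinate file could not be parsed."""


class StructuralError(ValueError):
    """Frames of one trajectory disagree structurally (e.g. particle count)."""


class EmptySelectionError(ValueError):
    """A particle-name selection matched nothing."""


class UnsupportedFormatError(ValueError):
    """File uses a dialect outside the supported subset (e.g. triclinic box)."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class ParticleFrame:
    """One time point of labelled 3D particles.

    Parameters
    ----------
    frame_index
        0-based ordinal of the frame within its trajectory.
    particle_ids
        Unique integer identifiers, stable across frames of one trajectory.
    names
        Particle-type labels (e.g. the phosphate bead name ``PO4``).
    positions
        ``(n, 3)`` coordinates in nm.
    box
        Orthorhombic box lengths ``(Lx, Ly, Lz)`` in nm, or ``None``.
    resnames
        Optional residue/species labels (e.g. lipid species), same length.
    """

    frame_index: int
    particle_ids: np.ndarray
    names: np.ndarray
    positions: np.ndarray
    box: np.ndarray | None = None
    resnames: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.particle_ids = np.asarray(self.particle_ids, dtype=np.int64)
        self.names = np.asarray(self.names, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        n = len(self.particle_ids)
        if len(self.names) != n or len(self.positions) != n:
            raise ValueError(
                "particle_ids, names and positions must have equal length"
            )
        if len(np.unique(self.particle_ids)) != n:
            raise ValueError("particle_ids must be unique within a frame")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box lengths must be three strictly positive values")
        if self.resnames is not None:
            self.resnames = np.asarray(self.resnames, dtype=object)
            if len(self.resnames) != n:
                raise ValueError("resnames must match particle count")

    @property
    def n_particles(self) -> int:
        return len(self.particle_ids)


@dataclass
class Trajectory:
    """Ordered sequence of :class:`ParticleFrame` sharing one particle set."""

    frames: list[ParticleFrame]
    reference: ParticleFrame | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a Trajectory needs at least one frame")
        ids0 = self.frames[0].particle_ids
        for fr in self.frames[1:]:
            if fr.n_particles != len(ids0):
                raise StructuralError(
                    f"frame {fr.frame_index} has {fr.n_particles} particles, "
                    f"frame {self.frames[0].frame_index} has {len(ids0)}"
                )
            if not np.array_equal(fr.particle_ids, ids0):
                raise StructuralError(
                    f"frame {fr.frame_index} particle ids differ from frame 0"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_particles(self) -> int:
        return self.frames[0].n_particles


# ---------------------------------------------------------------------------
# GRO dialect (fixed column, nm native, frames may be concatenated)
# ---------------------------------------------------------------------------

def _parse_gro_frame(lines: list[str], start: int, frame_index: int) -> tuple[ParticleFrame, int]:
    """Parse one GRO frame starting at ``lines[start]``; return (frame, next)."""
    if start + 2 > len(lines):
        raise ParseError(f"line {start + 1}: truncated GRO frame (missing header)")
    try:
        natoms = int(lines[start + 1].strip())
    except ValueError as exc:
        raise ParseError(
            f"line {start + 2}: expected particle count, got {lines[start + 1]!r}"
        ) from exc
    if natoms < 1:
        raise ParseError(f"line {start + 2}: particle count must be positive")
    end_atoms = start + 2 + natoms
    if end_atoms + 1 > len(lines):
        raise ParseError(
            f"line {len(lines)}: truncated GRO frame (expected {natoms} particles)"
        )
    names, resnames, positions = [], [], np.empty((natoms, 3))
    for i, lineno in enumerate(range(start + 2, end_atoms)):
        line = lines[lineno]
        try:
            resnames.append(line[5:10].strip())
            names.append(line[10:15].strip())
            positions[i, 0] = float(line[20:28])
            positions[i, 1] = float(line[28:36])
            positions[i, 2] = float(line[36:44])
        except (ValueError, IndexError) as exc:
            raise ParseError(
                f"line {lineno + 1}: malformed GRO atom record {line!r}"
            ) from exc
    box_fields = lines[end_atoms].split()
    if len(box_fields) not in (3, 9):
        raise ParseError(
            f"line {end_atoms + 1}: box line must hold 3 or 9 values"
        )
    try:
        box_vals = [float(v) for v in box_fields]
    except ValueError as exc:
        raise ParseError(f"line {end_atoms + 1}: malformed box line") from exc
    if len(box_vals) == 9 and any(abs(v) > 1e-12 for v in box_vals[3:]):
        raise UnsupportedFormatError(
            f"line {end_atoms + 1}: triclinic box vectors are not supported"
        )
    box = np.array(box_vals[:3])
    frame = ParticleFrame(
        frame_index=frame_index,
        particle_ids=np.arange(natoms),
        names=np.array(names, dtype=object),
        positions=positions,
        box=box if np.all(box > 0) else None,
        resnames=np.array(resnames, dtype=object),
    )
    return frame, end_atoms + 1


def _read_gro(path: Path) -> Trajectory:
    lines = path.read_text().splitlines()
    frames: list[ParticleFrame] = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip() and pos == len(lines) - 1:
            break  # trailing blank line
        frame, pos = _parse_gro_frame(lines, pos, len(frames))
        frames.append(frame)
    if not frames:
        raise ParseError("line 1: file holds no GRO frames")
    return Trajectory(frames=frames, provenance=f"GRO:{path}")


def write_gro(traj: Trajectory | ParticleFrame, path: str | Path, title: str = "piezokit") -> None:
    """Write frames in GRO dialect (positions printed to 3 decimals, nm)."""
    frames = traj.frames if isinstance(traj, Trajectory) else [traj]
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(f"{title}, frame {fr.frame_index}\n")
            fh.write(f"{fr.n_particles:5d}\n")
            resnames = fr.resnames if fr.resnames is not None else fr.names
            for i in range(fr.n_particles):
                resid = (i % 99999) + 1
                atomnum = (int(fr.particle_ids[i]) % 99999) + 1
                x, y, z = fr.positions[i]
                fh.write(
                    f"{resid:5d}{str(resnames[i])[:5]:<5s}{str(fr.names[i])[:5]:>5s}"
                    f"{atomnum:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            box = fr.box if fr.box is not None else np.zeros(3)
            fh.write(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# PDB multi-model dialect (Angstrom on disk -> nm in memory)
# ---------------------------------------------------------------------------

def _read_pdb(path: Path) -> Trajectory:
    # Cheap structural pre-scan so inconsistent MODEL blocks surface as the
    # documented structural error rather than a reader-internal exception.
    counts: list[int] = []
    current: int | None = None
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                current = 0
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = 0
                current += 1
            elif rec == "ENDMDL":
                counts.append(current or 0)
                current = None
    if current is not None and current > 0:
        counts.append(current)
    if len(set(counts)) > 1:
        raise StructuralError(
            f"MODEL blocks disagree on particle count: {sorted(set(counts))}"
        )
    if not counts or counts[0] == 0:
        raise ParseError("line 1: no ATOM/HETATM records found")

    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # pragma: no cover - reader-internal failures
        raise ParseError(f"PDB parse failed for {path}: {exc}") from exc

    names = np.array([a.name for a in u.atoms], dtype=object)
    resnames = np.array([a.resname for a in u.atoms], dtype=object)
    frames: list[ParticleFrame] = []
    for i, _ts in enumerate(u.trajectory):
        dims = u.dimensions
        box = None
        if dims is not None and np.all(dims[:3] > 0):
            if not np.allclose(dims[3:], 90.0):
                raise UnsupportedFormatError(
                    "non-orthorhombic (triclinic) PDB box is not supported"
                )
            box = dims[:3] / ANGSTROM_PER_NM
        frames.append(
            ParticleFrame(
                frame_index=i,
                particle_ids=np.arange(len(u.atoms)),
                names=names,
                positions=u.atoms.positions.astype(float) / ANGSTROM_PER_NM,
                box=box,
                resnames=resnames,
            )
        )
    return Trajectory(frames=frames, provenance=f"PDB:{path}")


def read_coordinates(path: str | Path, format: str | None = None) -> Trajectory:
    """Read a particle trajectory from a GRO or multi-model PDB file.

    Positions are returned in nm regardless of the on-disk unit system
    (GRO is nm native; PDB Angstroms are converted).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "gro":
        return _read_gro(path)
    if fmt == "pdb":
        return _read_pdb(path)
    raise UnsupportedFormatError(f"unsupported coordinate format: {fmt!r}")


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def _name_matcher(pattern: str | Callable[[str], bool]) -> Callable[[str], bool]:
    if callable(pattern):
        return pattern
    rx = re.compile(pattern)
    return lambda name: rx.fullmatch(name) is not None


def select_particles(traj: Trajectory, name_pattern: str | Callable[[str], bool]) -> Trajectory:
    """Restrict a trajectory to particles whose name matches a pattern.

    ``name_pattern`` is a regular expression matched against the full particle
    name (so ``"PO4"`` selects exactly the PO4 beads), or any predicate
    ``name -> bool``.  Order, frame count and particle ids are preserved.
    """
    match = _name_matcher(name_pattern)
    mask = np.array([bool(match(str(n))) for n in traj.frames[0].names])
    if not mask.any():
        raise EmptySelectionError(f"selection {name_pattern!r} matched no particles")
    frames = [
        ParticleFrame(
            frame_index=fr.frame_index,
            particle_ids=fr.particle_ids[mask],
            names=fr.names[mask],
            positions=fr.positions[mask],
            box=fr.box,
            resnames=fr.resnames[mask] if fr.resnames is not None else None,
        )
        for fr in traj.frames
    ]
    ref = traj.reference
    if ref is not None:
        ref_mask = np.array([bool(match(str(n))) for n in ref.names])
        ref = ParticleFrame(
            frame_index=ref.frame_index,
            particle_ids=ref.particle_ids[ref_mask],
            names=ref.names[ref_mask],
            positions=ref.positions[ref_mask],
            box=ref.box,
            resnames=ref.resnames[ref_mask] if ref.resnames is not None else None,
        )
    return Trajectory(frames=frames, reference=ref, provenance=traj.provenance)
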