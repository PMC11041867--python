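"""Structure-ensemble and transition-dipole I/O, fragment centers, distance vectors.

A dyad snapshot is a :class:`MolecularFrame`; the donor and acceptor
fragment centers are defined as the midpoints of two user-supplied nitrogen
pairs (N4–N5 for the donor, N1–N2 for the acceptor), and the distance
vector connects those centers, donor → acceptor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import DEBYE_PER_AU

logger = logging.getLogger(__name__)

__all__ = [
    "MolecularFrame",
    "FragmentSpec",
    "TransitionDipole",
    "XYZParseError",
    "read_xyz_ensemble",
    "write_xyz_ensemble",
    "fragment_center",
    "distance_vector",
    "read_tdm_table",
    "write_tdm_table",
]


class XYZParseError(ValueError):
    """Malformed multi-frame XYZ input; message carries the offending line number."""


@dataclass
class MolecularFrame:
    """Labeled 3-D coordinates for one ensemble snapshot (Å)."""

    snapshot_id: int
    labels: list[str]
    coords: np.ndarray  # (n_atoms, 3), Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if len(self.labels) != self.coords.shape[0]:
            raise ValueError(
                f"labels ({len(self.labels)}) and coords ({self.coords.shape[0]}) "
                "must have the same length"
            )
        if self.coords.shape[0] < 2:
            raise ValueError("a frame needs at least 2 atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("all coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class FragmentSpec:
    """Atom-index pairs defining the donor (N4–N5) and acceptor (N1–N2) centers.

    Atom ordering in XYZ files is arbitrary, so the nitrogen pairs are
    user-supplied rather than auto-detected.
    """

    donor_center_pair: tuple[int, int]
    acceptor_center_pair: tuple[int, int]

    def __post_init__(self) -> None:
        idx = (*self.donor_center_pair, *self.acceptor_center_pair)
        if len(idx) != 4:
            raise ValueError("each center pair must contain exactly two indices")
        if self.donor_center_pair[0] == self.donor_center_pair[1]:
            raise ValueError("donor center pair indices must be distinct")
        if self.acceptor_center_pair[0] == self.acceptor_center_pair[1]:
            raise ValueError("acceptor center pair indices must be distinct")
        if any(i < 0 for i in idx):
            raise ValueError("atom indices must be non-negative")

    def validate_for(self, frame: MolecularFrame) -> None:
        for i in (*self.donor_center_pair, *self.acceptor_center_pair):
            if i >= frame.n_atoms:
                raise IndexError(
                    f"atom index {i} out of range for frame with {frame.n_atoms} atoms"
                )


@dataclass
class TransitionDipole:
    """Per-snapshot transition dipole moment vector in atomic units."""

    snapshot_id: int
    role: str  # "donor" | "acceptor"
    vector: np.ndarray  # 3-vector, a.u.

    def __post_init__(self) -> None:
        if self.role not in ("donor", "acceptor"):
            raise ValueError(f"role must be 'donor' or 'acceptor', got {self.role!r}")
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.shape != (3,):
            raise ValueError("vector must be a 3-vector")
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("vector components must be finite")
        if np.linalg.norm(self.vector) <= 0.0:
            raise ValueError("transition dipole magnitude must be strictly positive")

    @property
    def magnitude_sq(self) -> float:
        """|mu|^2 in a.u.^2"""
        return float(self.vector @ self.vector)


def read_xyz_ensemble(path: str | Path) -> list[MolecularFrame]:
    """Read a multi-frame XYZ file into an ordered list of frames.

    The plain XYZ dialect is expected: an atom-count line, one comment line,
    then one ``symbol x y z`` record per atom, blocks concatenated.  Blank
    lines and lines starting with ``#`` between blocks are skipped.
    ``snapshot_id`` is the 0-based block index.

    Raises
    ------
    XYZParseError
        On a malformed atom count, non-numeric coordinate or truncated
        block; the message names the 1-based line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[MolecularFrame] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i].strip()
        if not line or line.startswith("#"):
            i += 1
            continue
        try:
            natoms = int(line)
        except ValueError:
            raise XYZParseError(
                f"{path}:{i + 1}: expected an atom count, got {line!r}"
            ) from None
        if natoms < 1:
            raise XYZParseError(f"{path}:{i + 1}: atom count must be >= 1, got {natoms}")
        if i + 1 >= n_lines:
            raise XYZParseError(f"{path}:{i + 1}: truncated block (missing comment line)")
        labels: list[str] = []
        coords = np.empty((natoms, 3), dtype=float)
        for k in range(natoms):
            j = i + 2 + k
            if j >= n_lines:
                raise XYZParseError(
                    f"{path}:{n_lines}: truncated block starting at line {i + 1}: "
                    f"declared {natoms} atoms, found {k}"
                )
            parts = lines[j].split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"{path}:{j + 1}: expected 'symbol x y z', got {lines[j]!r}"
                )
            labels.append(parts[0])
            try:
                coords[k] = [float(p) for p in parts[1:4]]
            except ValueError:
                raise XYZParseError(
                    f"{path}:{j + 1}: non-numeric coordinate in {lines[j]!r}"
                ) from None
        frames.append(MolecularFrame(snapshot_id=len(frames), labels=labels, coords=coords))
        i += 2 + natoms
    return frames


def write_xyz_ensemble(frames: Sequence[MolecularFrame], path: str | Path) -> None:
    """Write frames as concatenated XYZ blocks (coordinates to 6 decimals)."""
    path = Path(path)
    chunks: list[str] = []
    for fr in frames:
        chunks.append(f"{fr.n_atoms}\n")
        chunks.append(f"snapshot {fr.snapshot_id}\n")
        for lab, (x, y, z) in zip(fr.labels, fr.coords):
            chunks.append(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")
    path.write_text("".join(chunks))


def fragment_center(frame: MolecularFrame, pair: tuple[int, int]) -> np.ndarray:
    """Midpoint between two atoms (Å); the fragment-center definition.

    A degenerate pair (coincident atoms) is allowed but warned about.
    """
    i, j = pair
    for idx in (i, j):
        if idx < 0 or idx >= frame.n_atoms:
            raise IndexError(
                f"atom index {idx} out of range for frame with {frame.n_atoms} atoms"
            )
    a, b = frame.coords[i], frame.coords[j]
    if np.allclose(a, b):
        warnings.warn(
            f"fragment center pair ({i}, {j}) is degenerate: atoms coincide",
            stacklevel=2,
        )
    return 0.5 * (a + b)


def distance_vector(frame: MolecularFrame, spec: FragmentSpec) -> tuple[np.ndarray, float]:
    """Donor-center → acceptor-center vector and its magnitude (Å).

    Raises
    ------
    ValueError
        If the two centers coincide (degenerate geometry, r = 0).
    """
    spec.validate_for(frame)
    d_center = fragment_center(frame, spec.donor_center_pair)
    a_center = fragment_center(frame, spec.acceptor_center_pair)
    r_vec = a_center - d_center
    r = float(np.linalg.norm(r_vec))
    if r == 0.0:
        raise ValueError(
            f"snapshot {frame.snapshot_id}: donor and acceptor centers coincide (r = 0)"
        )
    return r_vec, r


_TDM_COLUMNS = ("snapshot_id", "role", "x", "y", "z", "unit")


def read_tdm_table(path: str | Path) -> list[TransitionDipole]:
    """Read a delimited TDM table (CSV/TSV, '#' comments tolerated).

    Required columns: snapshot_id, role, x, y, z, unit.  The unit tag is
    ``au`` or ``debye`` per row; Debye vectors are converted to atomic
    units on read.  Row-level problems are collected and reported together.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in _TDM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")

    dipoles: list[TransitionDipole] = []
    errors: list[str] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        role = str(row.role).strip().lower()
        unit = str(row.unit).strip().lower().replace(".", "")
        vec = np.array([row.x, row.y, row.z], dtype=float)
        if role not in ("donor", "acceptor"):
            errors.append(f"row {row_no}: unknown role {row.role!r}")
            continue
        if unit in ("debye", "d"):
            vec = vec / DEBYE_PER_AU
        elif unit not in ("au", "a u"):
            errors.append(f"row {row_no}: unknown unit {row.unit!r}")
            continue
        if np.linalg.norm(vec) == 0.0:
            errors.append(f"row {row_no}: zero transition dipole vector")
            continue
        dipoles.append(TransitionDipole(int(row.snapshot_id), role, vec))
    if errors:
        raise ValueError(f"{path}: invalid TDM rows:\n  " + "\n  ".join(errors))
    return dipoles


def write_tdm_table(dipoles: Sequence[TransitionDipole], path: str | Path) -> None:
    """Write TDMs as a CSV table in atomic units."""
    df = pd.DataFrame(
        {
            "snapshot_id": [d.snapshot_id for d in dipoles],
            "role": [d.role for d in dipoles],
            "x": [d.vector[0] for d in dipoles],
            "y": [d.vector[1] for d in dipoles],
            "z": [d.vector[2] for d in dipoles],
            "unit": "au",
        }
    )
    df.to_csv(path, index=False)
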