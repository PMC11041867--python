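"""Diagnostic angles and the Förster orientation factor κ².

Five angles characterize each ensemble snapshot: θ_A (acceptor TDM vs the
acceptor N1–N2 axis), θ_Ar (acceptor TDM vs the distance vector), θ_D and
θ_Dr (the donor analogues) and θ_AD (between the two TDMs).  All reported
angles are folded into [0°, 90°] because the overall sign (phase) of a
transition dipole is physically meaningless; κ² is computed from the raw
vectors, so folding never affects it.

κ = μ̂_D·μ̂_A − 3(μ̂_D·r̂)(μ̂_A·r̂);  κ² ranges from 0 (orthogonal
arrangements) to 4 (both TDMs collinear with the separation vector).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import FragmentSpec, MolecularFrame, TransitionDipole, distance_vector, fragment_center

logger = logging.getLogger(__name__)

__all__ = [
    "AngleSet",
    "SnapshotRecord",
    "folded_angle",
    "compute_angles",
    "kappa",
    "kappa_squared",
    "mean_angle",
    "weighted_mean_angle",
    "angle_histogram",
    "build_records",
    "records_to_dataframe",
]


@dataclass(frozen=True)
class AngleSet:
    """The five diagnostic angles of one snapshot, degrees, folded into [0, 90]."""

    theta_A: float
    theta_Ar: float
    theta_D: float
    theta_Dr: float
    theta_AD: float

    def __post_init__(self) -> None:
        for name in ("theta_A", "theta_Ar", "theta_D", "theta_Dr", "theta_AD"):
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 <= v <= 90.0):
                raise ValueError(f"{name} = {v} outside [0, 90] degrees")


@dataclass
class SnapshotRecord:
    """All per-snapshot quantities entering the ensemble RET analysis.

    ``v_da_sq`` (J²) is filled in by the coupling module.
    """

    snapshot_id: int
    mu_D: np.ndarray  # a.u.
    mu_A: np.ndarray  # a.u.
    r_vec: np.ndarray  # Å
    r: float  # Å
    angles: AngleSet
    kappa_sq: float
    v_da_sq: float | None = None  # J²

    def __post_init__(self) -> None:
        self.mu_D = np.asarray(self.mu_D, dtype=float)
        self.mu_A = np.asarray(self.mu_A, dtype=float)
        self.r_vec = np.asarray(self.r_vec, dtype=float)
        if not (0.0 <= self.kappa_sq <= 4.0 + 1e-12):
            raise ValueError(f"kappa_sq = {self.kappa_sq} outside [0, 4]")
        if self.mu_D_sq <= 0 or self.mu_A_sq <= 0:
            raise ValueError("TDM magnitudes must be strictly positive")
        if self.r <= 0:
            raise ValueError("distance must be strictly positive")

    @property
    def mu_D_sq(self) -> float:
        """|μ_D|², a.u.²"""
        return float(self.mu_D @ self.mu_D)

    @property
    def mu_A_sq(self) -> float:
        """|μ_A|², a.u.²"""
        return float(self.mu_A @ self.mu_A)


def _check_nonzero(*vectors: np.ndarray) -> None:
    for v in vectors:
        if np.linalg.norm(np.asarray(v, dtype=float)) == 0.0:
            raise ValueError("zero vector has no direction")


def folded_angle(u: Sequence[float], v: Sequence[float]) -> float:
    """Angle between two axes in degrees, folded into [0, 90].

    Computed as arccos(|û·v̂|); the dot product is clamped to [−1, 1] to
    guard against floating-point overshoot.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    _check_nonzero(u, v)
    c = abs(float(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(min(c, 1.0))))


def compute_angles(
    mu_D: Sequence[float],
    mu_A: Sequence[float],
    r_vec: Sequence[float],
    donor_axis: Sequence[float],
    acceptor_axis: Sequence[float],
) -> AngleSet:
    """The five folded diagnostic angles of one snapshot."""
    return AngleSet(
        theta_A=folded_angle(mu_A, acceptor_axis),
        theta_Ar=folded_angle(mu_A, r_vec),
        theta_D=folded_angle(mu_D, donor_axis),
        theta_Dr=folded_angle(mu_D, r_vec),
        theta_AD=folded_angle(mu_D, mu_A),
    )


def kappa(mu_D: np.ndarray, mu_A: np.ndarray, r_vec: np.ndarray) -> np.ndarray | float:
    """Signed orientation factor κ = μ̂_D·μ̂_A − 3(μ̂_D·r̂)(μ̂_A·r̂).

    Accepts single 3-vectors or broadcastable (..., 3) arrays.
    """
    mu_D = np.asarray(mu_D, dtype=float)
    mu_A = np.asarray(mu_A, dtype=float)
    r_vec = np.asarray(r_vec, dtype=float)
    nD = np.linalg.norm(mu_D, axis=-1, keepdims=True)
    nA = np.linalg.norm(mu_A, axis=-1, keepdims=True)
    nR = np.linalg.norm(r_vec, axis=-1, keepdims=True)
    if np.any(nD == 0) or np.any(nA == 0) or np.any(nR == 0):
        raise ValueError("zero vector has no direction")
    d, a, r = mu_D / nD, mu_A / nA, r_vec / nR
    k = np.sum(d * a, axis=-1) - 3.0 * np.sum(d * r, axis=-1) * np.sum(a * r, axis=-1)
    return float(k) if k.ndim == 0 else k


def kappa_squared(mu_D, mu_A, r_vec) -> np.ndarray | float:
    """Orientation factor κ² ∈ [0, 4]; invariant under TDM sign flips and rotations."""
    k = kappa(mu_D, mu_A, r_vec)
    return k * k if not np.isscalar(k) else float(k * k)


def mean_angle(angles: Sequence[float]) -> float:
    """Arithmetic mean of folded angles, degrees."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("cannot average an empty angle collection")
    return float(angles.mean())


def weighted_mean_angle(angles: Sequence[float], weights: Sequence[float]) -> float:
    """Intensity-weighted mean angle: Σ wᵢθᵢ / Σ wᵢ.

    The intended weights are the per-snapshot TDM-strength products
    |μ_D|²·|μ_A|², so that more intense snapshots contribute more to the
    effective angle.  A linear (not circular) mean of folded angles.
    """
    angles = np.asarray(angles, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if angles.shape != weights.shape:
        raise ValueError("angles and weights must have the same length")
    if angles.size == 0:
        raise ValueError("cannot average an empty angle collection")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total == 0:
        raise ValueError("weights must not all be zero")
    return float((weights * angles).sum() / total)


def angle_histogram(
    angles: Sequence[float], bin_width: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of folded angles on [0°, 90°].

    Returns (edges, counts); counts sum to the sample size.  Bin width
    defaults to 5°; the final bin absorbs any remainder so that the edges
    always cover 90° exactly.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    angles = np.asarray(angles, dtype=float)
    edges = np.arange(0.0, 90.0 + bin_width, bin_width)
    if edges[-1] < 90.0:
        edges = np.append(edges, 90.0)
    edges[-1] = max(edges[-1], 90.0)
    counts, _ = np.histogram(angles, bins=edges)
    return edges, counts


def build_records(
    frames: Sequence[MolecularFrame],
    dipoles: Sequence[TransitionDipole],
    spec: FragmentSpec,
) -> list[SnapshotRecord]:
    """Join frames with donor/acceptor TDMs by snapshot_id into SnapshotRecords.

    A frame lacking a complete donor+acceptor TDM pair (or TDMs without a
    frame) is dropped with a logged warning, so partial ensembles remain
    usable.
    """
    by_id: dict[int, dict[str, TransitionDipole]] = {}
    for d in dipoles:
        by_id.setdefault(d.snapshot_id, {})[d.role] = d
    frame_ids = {f.snapshot_id for f in frames}
    for sid in sorted(set(by_id) - frame_ids):
        logger.warning("snapshot %d has TDMs but no structure frame; dropped", sid)

    records: list[SnapshotRecord] = []
    for frame in frames:
        pair = by_id.get(frame.snapshot_id)
        if pair is None or "donor" not in pair or "acceptor" not in pair:
            logger.warning(
                "snapshot %d lacks a complete donor/acceptor TDM pair; dropped",
                frame.snapshot_id,
            )
            continue
        r_vec, r = distance_vector(frame, spec)
        di, dj = spec.donor_center_pair
        ai, aj = spec.acceptor_center_pair
        donor_axis = frame.coords[dj] - frame.coords[di]
        acceptor_axis = frame.coords[aj] - frame.coords[ai]
        mu_D = pair["donor"].vector
        mu_A = pair["acceptor"].vector
        records.append(
            SnapshotRecord(
                snapshot_id=frame.snapshot_id,
                mu_D=mu_D,
                mu_A=mu_A,
                r_vec=r_vec,
                r=r,
                angles=compute_angles(mu_D, mu_A, r_vec, donor_axis, acceptor_axis),
                kappa_sq=kappa_squared(mu_D, mu_A, r_vec),
            )
        )
    return records


def records_to_dataframe(records: Sequence[SnapshotRecord]) -> pd.DataFrame:
    """Tabulate per-snapshot results (id, five angles, κ², intensities, r, |V_DA|²)."""
    return pd.DataFrame(
        {
            "snapshot_id": [r.snapshot_id for r in records],
            "theta_A": [r.angles.theta_A for r in records],
            "theta_Ar": [r.angles.theta_Ar for r in records],
            "theta_D": [r.angles.theta_D for r in records],
            "theta_Dr": [r.angles.theta_Dr for r in records],
            "theta_AD": [r.angles.theta_AD for r in records],
            "kappa_sq": [r.kappa_sq for r in records],
            "mu_D_sq_au2": [r.mu_D_sq for r in records],
            "mu_A_sq_au2": [r.mu_A_sq for r in records],
            "r_angstrom": [r.r for r in records],
            "v_da_sq_J2": [r.v_da_sq for r in records],
        }
    )
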