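"""Point-dipole electrostatic coupling |V_DA|² and the golden-rule RET rate.

The squared donor–acceptor coupling in the ideal-dipole approximation is

    |V_DA|² = κ² |μ_D|² |μ_A|² / ((4πε₀)² η⁴ r⁶)

with the transition dipoles in C·m and the center–center distance in m;
η is the medium refractive index.  Combined with the spectral overlap J of
the unit-area-normalized donor emission and acceptor absorption spectra
(in cm, i.e. per wavenumber), the transfer rate is the golden-rule form

    k_RET = (2π/ħ) · ⟨|V_DA|²⟩ · J/(hc),

where J/(hc) converts the per-wavenumber overlap density into a
per-Joule density of resonant states.  τ_RET = 1/k_RET.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import constants as k
from .orientation import SnapshotRecord

__all__ = [
    "CouplingConfig",
    "RETResult",
    "v_da_squared",
    "apply_coupling",
    "ensemble_average_coupling",
    "k_ret",
    "lifetime",
    "convert_energy",
    "convert_dipole_sq",
]


@dataclass(frozen=True)
class CouplingConfig:
    """Medium parameters for the dipole–dipole coupling.

    The refractive index enters the squared coupling as η⁴; the default
    η = 1 corresponds to vacuum.
    """

    refractive_index: float = 1.0

    def __post_init__(self) -> None:
        if self.refractive_index < 1.0:
            raise ValueError("refractive index must be >= 1")


def v_da_squared(
    kappa_sq,
    mu_D_sq,
    mu_A_sq,
    r: float,
    config: CouplingConfig = CouplingConfig(),
):
    """Squared coupling |V_DA|² in J².

    Parameters are the orientation factor κ² (dimensionless, in [0, 4]),
    squared TDM magnitudes in a.u.², and the center distance r in Å.
    Accepts scalars or broadcastable arrays.
    """
    kappa_sq = np.asarray(kappa_sq, dtype=float)
    mu_D_sq = np.asarray(mu_D_sq, dtype=float)
    mu_A_sq = np.asarray(mu_A_sq, dtype=float)
    r_arr = np.asarray(r, dtype=float)
    if np.any(kappa_sq < 0) or np.any(kappa_sq > 4.0 + 1e-9):
        raise ValueError("kappa_sq must lie in [0, 4]")
    if np.any(mu_D_sq < 0) or np.any(mu_A_sq < 0):
        raise ValueError("squared TDM magnitudes must be non-negative")
    if np.any(r_arr <= 0):
        raise ValueError("distance must be strictly positive")
    mu_prod_SI = mu_D_sq * mu_A_sq * k.AU_DIPOLE_CM**4  # (C m)^4
    r_m6 = (r_arr * k.ANGSTROM_M) ** 6
    eta4 = config.refractive_index**4
    out = kappa_sq * mu_prod_SI / (k.FOUR_PI_EPS0**2 * eta4 * r_m6)
    return float(out) if out.ndim == 0 else out


def apply_coupling(
    records: Sequence[SnapshotRecord], config: CouplingConfig = CouplingConfig()
) -> None:
    """Fill ``v_da_sq`` (J²) on each snapshot record in place."""
    for rec in records:
        rec.v_da_sq = v_da_squared(rec.kappa_sq, rec.mu_D_sq, rec.mu_A_sq, rec.r, config)


def ensemble_average_coupling(records: Sequence[SnapshotRecord]) -> float:
    """Unweighted arithmetic mean of |V_DA|² over the snapshot ensemble, J²."""
    if len(records) == 0:
        raise ValueError("cannot average an empty ensemble")
    vals = [rec.v_da_sq for rec in records]
    if any(v is None for v in vals):
        raise ValueError("records lack v_da_sq; run apply_coupling first")
    return float(np.mean(vals))


def k_ret(v_da_sq_mean: float, spectral_overlap: float) -> float:
    """Golden-rule RET rate in s⁻¹ from ⟨|V_DA|²⟩ (J²) and J (cm)."""
    if v_da_sq_mean < 0 or spectral_overlap < 0:
        raise ValueError("coupling and overlap must be non-negative")
    return (2.0 * np.pi / k.HBAR) * v_da_sq_mean * spectral_overlap / k.HC_J_CM


def lifetime(rate: float) -> float:
    """RET lifetime τ = 1/k in s; k = 0 signals no transfer and is an error."""
    if rate <= 0:
        raise ValueError("no transfer: rate must be strictly positive for a lifetime")
    return 1.0 / rate


_ENERGY_TO_J = {
    "J": 1.0,
    "eV": k.E_CHARGE,
    "cm-1": k.HC_J_CM,
}


def _norm_energy_unit(unit: str) -> str:
    u = unit.strip().replace("^", "").replace("⁻¹", "-1")
    table = {"j": "J", "ev": "eV", "cm-1": "cm-1", "1/cm": "cm-1", "wavenumber": "cm-1"}
    try:
        return table[u.lower()]
    except KeyError:
        raise ValueError(f"unknown energy unit {unit!r}; use J, eV or cm-1") from None


def convert_energy(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an energy between J, eV and cm⁻¹ via CODATA h, c, e."""
    f = _ENERGY_TO_J[_norm_energy_unit(from_unit)]
    t = _ENERGY_TO_J[_norm_energy_unit(to_unit)]
    return value * f / t


_DIPOLE_SQ_TO_AU2 = {
    "au2": 1.0,
    "debye2": 1.0 / k.DEBYE_PER_AU**2,
    "C2m2": 1.0 / k.AU_DIPOLE_CM**2,
}


def _norm_dipole_sq_unit(unit: str) -> str:
    u = unit.strip().lower().replace("^", "").replace(" ", "").replace(".", "")
    table = {
        "au2": "au2",
        "au²": "au2",
        "debye2": "debye2",
        "d2": "debye2",
        "c2m2": "C2m2",
        "(cm)2": "C2m2",
    }
    try:
        return table[u]
    except KeyError:
        raise ValueError(
            f"unknown squared-dipole unit {unit!r}; use au2, debye2 or C2m2"
        ) from None


def convert_dipole_sq(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a squared dipole strength between a.u.², Debye² and C²m².

    The conversion is on the squared quantity, e.g. the factor between
    a.u.² and Debye² is 2.541746² ≈ 6.46, not 2.54.
    """
    f = _DIPOLE_SQ_TO_AU2[_norm_dipole_sq_unit(from_unit)]
    t = _DIPOLE_SQ_TO_AU2[_norm_dipole_sq_unit(to_unit)]
    return value * f / t


@dataclass
class RETResult:
    """Ensemble-averaged coupling, overlap, rate and lifetime with unit variants."""

    v_da_sq_mean: float  # J²
    spectral_overlap_J: float  # cm
    k_RET: float  # s⁻¹
    tau_RET: float  # s

    def __post_init__(self) -> None:
        if self.k_RET < 0:
            raise ValueError("rate must be non-negative")

    @classmethod
    def from_inputs(cls, v_da_sq_mean: float, spectral_overlap: float) -> "RETResult":
        rate = k_ret(v_da_sq_mean, spectral_overlap)
        return cls(
            v_da_sq_mean=v_da_sq_mean,
            spectral_overlap_J=spectral_overlap,
            k_RET=rate,
            tau_RET=lifetime(rate) if rate > 0 else float("inf"),
        )

    @property
    def v_da_sq_eV2(self) -> float:
        """The squared coupling expressed in eV² (exact squared conversion)."""
        return self.v_da_sq_mean / k.E_CHARGE**2

    @property
    def v_da_sq_cm2(self) -> float:
        """The squared coupling expressed in cm⁻² (exact squared conversion)."""
        return self.v_da_sq_mean / k.HC_J_CM**2

    def to_dict(self) -> dict:
        """JSON-ready mapping with explicit unit tags on every field."""
        return {
            "v_da_sq_mean": {"value": self.v_da_sq_mean, "unit": "J^2"},
            "v_da_sq_mean_eV2": {"value": self.v_da_sq_eV2, "unit": "eV^2"},
            "v_da_sq_mean_cm2": {"value": self.v_da_sq_cm2, "unit": "cm^-2"},
            "spectral_overlap": {"value": self.spectral_overlap_J, "unit": "cm"},
            "k_RET": {"value": self.k_RET, "unit": "s^-1"},
            "tau_RET": {"value": self.tau_RET, "unit": "s"},
        }
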