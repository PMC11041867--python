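"""Orchestration: one reproducible run from inputs to a machine-readable report.

Three mutually exclusive input modes:

* **real inputs** — multi-frame XYZ ensemble + TDM table + donor-emission /
  acceptor-absorption spectra;
* **synthetic** — a :class:`~enfret.synthetic.SyntheticConfig` generates the
  ensemble and the vibronic spectra;
* **values-only** — the ensemble-averaged coupling (J²) and spectral
  overlap (cm) are supplied directly and only the rate chain runs.

The coupling is averaged over the thermal ensemble while the overlap comes
from equilibrium-structure vibronic spectra; feeding an ensemble-derived
overlap together with the ensemble-derived coupling would double-count
thermal broadening, so that combination is refused unless explicitly
overridden.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .classify import class_summary, classify_donor_states, intensity_kappa_correlation
from .coupling import (
    CouplingConfig,
    RETResult,
    apply_coupling,
    ensemble_average_coupling,
)
from .geometry import (
    FragmentSpec,
    read_tdm_table,
    read_xyz_ensemble,
    write_tdm_table,
    write_xyz_ensemble,
)
from .orientation import (
    angle_histogram,
    mean_angle,
    records_to_dataframe,
    weighted_mean_angle,
)
from .spectra import Spectrum, normalize_unit_area, read_spectrum, spectral_overlap, write_spectrum
from .synthetic import SyntheticConfig, generate_ensemble, generate_vibronic_spectra
from .orientation import build_records

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = "1"

_ANGLE_COLUMNS = ("theta_A", "theta_Ar", "theta_D", "theta_Dr", "theta_AD")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one pipeline run."""

    # real-input mode
    xyz_path: str | None = None
    tdm_path: str | None = None
    emission_path: str | None = None
    absorption_path: str | None = None
    fragment: FragmentSpec | None = None
    # synthetic mode
    synthetic: SyntheticConfig | None = None
    # values-only mode
    v_da_sq_mean: float | None = None
    spectral_overlap: float | None = None
    # shared knobs
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    classifier_threshold: float = 45.0
    hist_bin_width: float = 5.0
    output_dir: str | None = None
    spectra_from_ensemble: bool = False
    allow_double_counting: bool = False

    def __post_init__(self) -> None:
        real = self.xyz_path is not None or self.tdm_path is not None
        values = self.v_da_sq_mean is not None or self.spectral_overlap is not None
        modes = sum([real, self.synthetic is not None, values])
        if modes != 1:
            raise ValueError(
                "exactly one input mode must be active: real paths, synthetic "
                f"config, or values-only ({modes} active)"
            )
        if real:
            for name in ("xyz_path", "tdm_path"):
                if getattr(self, name) is None:
                    raise ValueError(f"real-input mode requires {name}")
            if self.fragment is None:
                raise ValueError("real-input mode requires a FragmentSpec")
            for name in ("xyz_path", "tdm_path", "emission_path", "absorption_path"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")
        if values and (self.v_da_sq_mean is None or self.spectral_overlap is None):
            raise ValueError(
                "values-only mode requires both v_da_sq_mean and spectral_overlap"
            )
        if self.hist_bin_width <= 0:
            raise ValueError("hist_bin_width must be positive")


def _round_sig(x: float, sig: int = 12) -> float:
    if x == 0 or not np.isfinite(x):
        return x
    return float(f"{x:.{sig}g}")


def _json_ready(obj: Any) -> Any:
    """Recursively round floats to 12 significant digits for serialization."""
    if isinstance(obj, dict):
        return {k: _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return _round_sig(float(obj))
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def _config_hash(config: RunConfig) -> str:
    def enc(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        return str(o)

    d = asdict(config)
    d.pop("output_dir", None)  # where outputs go does not change what is computed
    blob = json.dumps(d, default=enc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML (or JSON) mapping."""
    raw = yaml.safe_load(Path(path).read_text())
    kwargs: dict[str, Any] = dict(raw)
    if "fragment" in kwargs and kwargs["fragment"] is not None:
        f = kwargs["fragment"]
        kwargs["fragment"] = FragmentSpec(
            donor_center_pair=tuple(f["donor_center_pair"]),
            acceptor_center_pair=tuple(f["acceptor_center_pair"]),
        )
    if "synthetic" in kwargs and kwargs["synthetic"] is not None:
        s = dict(kwargs["synthetic"])
        if "spectra" in s and s["spectra"] is not None:
            from .synthetic import VibronicConfig

            s["spectra"] = VibronicConfig(**s["spectra"])
        for key in ("r_range", "mu_A_sq_range", "ct_mixing"):
            if key in s and isinstance(s[key], list):
                s[key] = tuple(s[key])
        kwargs["synthetic"] = SyntheticConfig(**s)
    if "coupling" in kwargs and kwargs["coupling"] is not None:
        kwargs["coupling"] = CouplingConfig(**kwargs["coupling"])
    return RunConfig(**kwargs)


def _analysis_stage(config: RunConfig):
    """Geometry + orientation stage: produce snapshot records and spectra."""
    if config.synthetic is not None:
        records = generate_ensemble(config.synthetic)
        emission, absorption = generate_vibronic_spectra(config.synthetic)
        return records, emission, absorption
    frames = read_xyz_ensemble(config.xyz_path)
    dipoles = read_tdm_table(config.tdm_path)
    records = build_records(frames, dipoles, config.fragment)
    emission = absorption = None
    if config.emission_path and config.absorption_path:
        emission = read_spectrum(config.emission_path)
        absorption = read_spectrum(config.absorption_path)
    return records, emission, absorption


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full chain and return (and optionally write) the report.

    Stages: geometry → orientation → coupling → overlap → rate →
    classification.  Stage failures are re-raised with the stage name.
    Outputs (when ``output_dir`` is set): per-snapshot CSV, per-angle
    histogram CSVs, class-summary CSV and ``report.json``.
    """
    cfg_hash = _config_hash(config)
    seed = config.synthetic.seed if config.synthetic is not None else None
    logger.info("pipeline run: config hash %s, seed %s", cfg_hash, seed)

    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config_hash": cfg_hash,
        "seed": seed,
    }

    if config.v_da_sq_mean is not None:
        # values-only mode: skip straight to the rate chain
        result = RETResult.from_inputs(config.v_da_sq_mean, config.spectral_overlap)
        report["ret"] = result.to_dict()
        report["mode"] = "values_only"
        _maybe_write(config, report)
        return report

    try:
        records, emission, absorption = _analysis_stage(config)
    except Exception as exc:
        raise RuntimeError(f"analysis stage failed: {exc}") from exc
    if not records:
        raise RuntimeError("analysis stage produced no usable snapshots")

    try:
        apply_coupling(records, config.coupling)
        v_mean = ensemble_average_coupling(records)
    except Exception as exc:
        raise RuntimeError(f"coupling stage failed: {exc}") from exc

    overlap = None
    if emission is not None and absorption is not None:
        if config.spectra_from_ensemble and not config.allow_double_counting:
            raise RuntimeError(
                "rate stage refused: combining an ensemble-derived spectral overlap "
                "with the ensemble-averaged coupling double-counts thermal effects; "
                "set allow_double_counting to override"
            )
        try:
            overlap = spectral_overlap(emission, absorption)
        except Exception as exc:
            raise RuntimeError(f"overlap stage failed: {exc}") from exc

    theta_AD = [r.angles.theta_AD for r in records]
    weights = [r.mu_D_sq * r.mu_A_sq for r in records]
    try:
        labels = classify_donor_states(records, config.classifier_threshold)
        summary = class_summary(records, labels)
        correlation = (
            intensity_kappa_correlation(records) if len(records) >= 3 else float("nan")
        )
    except Exception as exc:
        raise RuntimeError(f"classification stage failed: {exc}") from exc

    report["mode"] = "synthetic" if config.synthetic is not None else "real"
    report["n_snapshots"] = len(records)
    report["angles"] = {
        "mean_theta_AD_deg": mean_angle(theta_AD),
        "weighted_mean_theta_AD_deg": weighted_mean_angle(theta_AD, weights),
    }
    report["classification"] = {
        "spearman_muD2_kappa2": correlation,
        "classes": {
            str(lab): {
                "count": int(row["count"]),
                "mean_theta_D_deg": float(row["mean_theta_D"]),
                "mean_mu_D_sq_au2": float(row["mean_mu_D_sq"]),
            }
            for lab, row in summary.iterrows()
        },
        "frac_mu_D_sq_below_2_given_kappa_sq_above_1": summary.attrs[
            "frac_low_intensity_high_kappa"
        ],
    }
    if overlap is not None:
        result = RETResult.from_inputs(v_mean, overlap)
        report["ret"] = result.to_dict()
    else:
        report["ret"] = {"v_da_sq_mean": {"value": v_mean, "unit": "J^2"}}
        report["incomplete"] = "no spectra supplied; overlap and rate not computed"

    _maybe_write(config, report, records=records, labels=labels, summary=summary)
    return report


def _maybe_write(config: RunConfig, report: dict, records=None, labels=None, summary=None):
    if config.output_dir is None:
        return
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if records is not None:
        df = records_to_dataframe(records)
        if labels is not None:
            df["state_label"] = [l.label for l in labels]
        df.to_csv(out / "snapshots.csv", index=False)
        for col in _ANGLE_COLUMNS:
            edges, counts = angle_histogram(df[col].to_numpy(), config.hist_bin_width)
            pd.DataFrame(
                {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
            ).to_csv(out / f"hist_{col}.csv", index=False)
    if summary is not None:
        summary.to_csv(out / "class_summary.csv")
    (out / "report.json").write_text(
        json.dumps(_json_ready(report), indent=2, sort_keys=True) + "\n"
    )
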