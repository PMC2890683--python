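"""File formats and the end-to-end study runner.

ROI-level CSV is the primary exchange format — the quantification consumes
ROI-mean values, never images.  The dialect is strict: comma-separated, dot
decimals, mandatory header.  Signal series use columns ``te_ms,intensity``;
first-pass curves use ``time_s,tissue,aif``.  Results are emitted as
schema-versioned JSON with a provenance block.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import DataError, MyooefError
from .fitting import (
    calibrate_rest,
    fit_apparent_t2,
    fit_cs_oef,
    fit_stress_oef,
)
from .metrics import (
    SubjectPhysiology,
    mvo2,
    mvo2_to_ml,
    percent_change,
    rate_pressure_product,
    t2_sensitivity,
)
from .perfusion import DEFAULT_N_BASIS, DEFAULT_RIDGE, DynamicCurve, quantify_perfusion
from .relaxometry import AcquisitionProtocol, AlphaTable, SignalSeries

__all__ = [
    "read_signal_csv",
    "write_signal_csv",
    "read_perfusion_csv",
    "write_perfusion_csv",
    "write_result_json",
    "StudyConfig",
    "run_study",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1.0"

_FLOAT_RE = r"^[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?$"


def _read_strict_csv(path, columns: tuple[str, ...]) -> pd.DataFrame:
    """Read a CSV enforcing the strict dialect; all cells must parse as floats.

    Rejects locale decimal commas and any other non-numeric cell, reporting
    the offending data row number (1-based, excluding the header).
    """
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except Exception as exc:
        raise DataError(f"cannot parse CSV {path}: {exc}") from exc
    missing = set(columns) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing required column(s) {sorted(missing)}")
    out = {}
    for col in columns:
        series = df[col].astype(str).str.strip()
        bad = ~series.str.match(_FLOAT_RE, na=True)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise DataError(
                f"{path}: non-numeric value {series.iloc[row - 1]!r} in column "
                f"{col!r} at data row {row} (strict dialect: dot decimals only)"
            )
        out[col] = series.astype(float).to_numpy()
    return pd.DataFrame(out)


def read_signal_csv(path, *, label="myocardium", condition="rest") -> SignalSeries:
    """Load a multi-echo series from a ``te_ms,intensity`` CSV."""
    df = _read_strict_csv(path, ("te_ms", "intensity"))
    te = df["te_ms"].to_numpy()
    dup = pd.Series(te).duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 1
        raise DataError(f"{path}: duplicate TE value {te[row-1]} at data row {row}")
    order = np.argsort(te, kind="stable")
    if not np.array_equal(order, np.arange(te.size)):
        raise DataError(f"{path}: te_ms must be strictly increasing")
    try:
        return SignalSeries(
            te_ms=te, intensity=df["intensity"].to_numpy(),
            label=label, condition=condition,
        )
    except DataError as exc:
        raise DataError(f"{path}: {exc}") from exc


def write_signal_csv(series: SignalSeries, path) -> None:
    pd.DataFrame({"te_ms": series.te_ms, "intensity": series.intensity}).to_csv(
        path, index=False
    )


def read_perfusion_csv(path) -> tuple[DynamicCurve, DynamicCurve]:
    """Load a first-pass pair from a ``time_s,tissue,aif`` CSV -> (tissue, aif)."""
    df = _read_strict_csv(path, ("time_s", "tissue", "aif"))
    t = df["time_s"].to_numpy()
    try:
        return (
            DynamicCurve(time=t, value=df["tissue"].to_numpy(), roi="tissue"),
            DynamicCurve(time=t, value=df["aif"].to_numpy(), roi="lv_blood_pool"),
        )
    except DataError as exc:
        raise DataError(f"{path}: {exc}") from exc


def write_perfusion_csv(tissue: DynamicCurve, aif: DynamicCurve, path) -> None:
    pd.DataFrame(
        {"time_s": tissue.time, "tissue": tissue.value, "aif": aif.value}
    ).to_csv(path, index=False)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_result_json(result: Any, path, *, extra: dict | None = None) -> None:
    """Serialize a result object (dataclass or dict) with schema + provenance."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "result": _jsonable(result),
    }
    if extra:
        payload.update(_jsonable(extra))
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# study configuration and runner
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """Paths and parameters for one full rest/stress study."""

    cs_rest_csv: str
    myo_rest_csv: str
    myo_stress_csv: str
    perfusion_rest_csv: str
    perfusion_stress_csv: str
    output_dir: str = "."
    protocol: AcquisitionProtocol = field(
        default_factory=AcquisitionProtocol.t2prep_default
    )
    alpha_table_csv: str | None = None
    n_basis: int = DEFAULT_N_BASIS
    ridge: float = DEFAULT_RIDGE
    baseline_frames: int = 5
    physiology_rest: dict | None = None  # {'heart_rate':…, 'systolic_bp':…}
    physiology_stress: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise DataError(f"{path}: study config must be a mapping")
        proto = raw.pop("protocol", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if proto is not None:
            cfg.protocol = AcquisitionProtocol(
                family=proto.get("family", "t2prep"),
                te_list=tuple(proto["te_list"]),
                n_refocus=proto.get("n_refocus", 3),
                tau_ms=proto.get("tau_ms"),
            )
        base = Path(path).parent
        for name in (
            "cs_rest_csv", "myo_rest_csv", "myo_stress_csv",
            "perfusion_rest_csv", "perfusion_stress_csv",
        ):
            p = base / getattr(cfg, name)
            setattr(cfg, name, str(p))
        if cfg.alpha_table_csv:
            cfg.alpha_table_csv = str(base / cfg.alpha_table_csv)
        return cfg

    def validate_paths(self) -> None:
        for name in (
            "cs_rest_csv", "myo_rest_csv", "myo_stress_csv",
            "perfusion_rest_csv", "perfusion_stress_csv",
        ):
            p = Path(getattr(self, name))
            if not p.is_file():
                raise DataError(f"input file for {name} not found: {p}")

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_study(config: StudyConfig, *, write_outputs: bool = True) -> dict:
    """Execute the full quantification chain on one study's CSV inputs.

    Stages: perfusion deconvolution (rest, stress) -> coronary-sinus OEF ->
    rest calibration (R20t, R21t) -> hyperemic myocardial OEF -> MVO2 and
    derived metrics.  Returns a nested dict shaped like a per-subject row of
    a perfusion/oxygenation summary table and, when ``write_outputs``, also
    writes ``study_result.json`` and ``study_report.md`` to the output
    directory.  Stage failures raise with the stage name attached.
    """
    config.validate_paths()
    table = (
        AlphaTable.from_csv(config.alpha_table_csv)
        if config.alpha_table_csv
        else AlphaTable.default()
    )

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except MyooefError as exc:
            raise type(exc)(f"[stage: {name}] {exc}") from exc

    tis_r, aif_r = stage("load perfusion rest", read_perfusion_csv, config.perfusion_rest_csv)
    tis_s, aif_s = stage("load perfusion stress", read_perfusion_csv, config.perfusion_stress_csv)
    perf_rest = stage(
        "perfusion rest", quantify_perfusion, tis_r, aif_r,
        n_basis=config.n_basis, ridge=config.ridge, baseline_frames=config.baseline_frames,
    )
    perf_stress = stage(
        "perfusion stress", quantify_perfusion, tis_s, aif_s,
        n_basis=config.n_basis, ridge=config.ridge, baseline_frames=config.baseline_frames,
    )

    cs_rest = stage("load cs rest", read_signal_csv, config.cs_rest_csv,
                    label="cs", condition="rest")
    myo_rest = stage("load myo rest", read_signal_csv, config.myo_rest_csv,
                     label="myocardium", condition="rest")
    myo_stress = stage("load myo stress", read_signal_csv, config.myo_stress_csv,
                       label="myocardium", condition="stress")

    oef_rest = stage("cs oef", fit_cs_oef, cs_rest, config.protocol, table)
    calib = stage(
        "rest calibration", calibrate_rest, myo_rest, oef_rest.oef_hat,
        perf_rest.mbv, config.protocol, table,
    )
    oef_stress = stage(
        "stress oef", fit_stress_oef, myo_stress, calib, perf_stress.mbv,
        config.protocol, table,
    )

    t2_rest = fit_apparent_t2(myo_rest).t2_apparent
    t2_stress = fit_apparent_t2(myo_stress).t2_apparent
    mvo2_rest = mvo2(oef_rest.oef_hat, perf_rest.mbf)
    mvo2_stress = mvo2(oef_stress.oef_hat, perf_stress.mbf)

    report: dict[str, Any] = {
        "rest": {
            "t2_apparent_ms": t2_rest,
            "mbf_ml_g_min": perf_rest.mbf,
            "mbv_ml_g": perf_rest.mbv,
            "mtt_s": perf_rest.mtt,
            "oef": oef_rest.oef_hat,
            "mvo2_umol_g_min": mvo2_rest,
            "mvo2_ml_g_min": mvo2_to_ml(mvo2_rest),
        },
        "stress": {
            "t2_apparent_ms": t2_stress,
            "mbf_ml_g_min": perf_stress.mbf,
            "mbv_ml_g": perf_stress.mbv,
            "mtt_s": perf_stress.mtt,
            "oef": oef_stress.oef_hat,
            "mvo2_umol_g_min": mvo2_stress,
            "mvo2_ml_g_min": mvo2_to_ml(mvo2_stress),
        },
        "calibration": {
            "r20t_per_s": calib.r20t_hat,
            "r21t_per_s3": calib.r21t_hat,
            "fit_r_squared": calib.fit_r_squared,
            "warnings": list(calib.warnings),
        },
        "derived": {
            "t2_sensitivity": t2_sensitivity(
                t2_rest, t2_stress, perf_rest.mbf, perf_stress.mbf
            ),
            "mbf_percent_change": percent_change(perf_rest.mbf, perf_stress.mbf),
            "oef_percent_change": percent_change(oef_rest.oef_hat, oef_stress.oef_hat),
            "mvo2_percent_change": percent_change(mvo2_rest, mvo2_stress),
        },
        "units_note": (
            "TE/tau in ms at interfaces, seconds inside exponents; R2 in 1/s; "
            "R21t in 1/s^3; MBV as mL/g with unit tissue density"
        ),
    }
    for cond, phys in (("rest", config.physiology_rest), ("stress", config.physiology_stress)):
        if phys and "heart_rate" in phys and "systolic_bp" in phys:
            report[cond]["rate_pressure_product"] = rate_pressure_product(
                phys["heart_rate"], phys["systolic_bp"]
            )
    if "rate_pressure_product" in report["rest"] and "rate_pressure_product" in report["stress"]:
        report["derived"]["rpp_percent_change"] = percent_change(
            report["rest"]["rate_pressure_product"],
            report["stress"]["rate_pressure_product"],
        )

    if write_outputs:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_result_json(
            report, out / "study_result.json",
            extra={"provenance": {
                "package_version": __version__,
                "config_hash": config.config_hash(),
            }},
        )
        (out / "study_report.md").write_text(_markdown_report(report))
    return report


def _markdown_report(report: dict) -> str:
    rows = []
    for cond in ("rest", "stress"):
        r = report[cond]
        rows.append(
            f"| {cond} | {r['t2_apparent_ms']:.1f} | {r['mbf_ml_g_min']:.2f} | "
            f"{r['mbv_ml_g']:.3f} | {r['oef']:.3f} | {r['mvo2_umol_g_min']:.2f} |"
        )
    calib = report["calibration"]
    lines = [
        "# Myocardial oxygenation study report",
        "",
        "| condition | T2app (ms) | MBF (mL/g/min) | MBV (mL/g) | OEF | MVO2 (umol/g/min) |",
        "|---|---|---|---|---|---|",
        *rows,
        "",
        f"Calibration: R20t = {calib['r20t_per_s']:.2f} 1/s, "
        f"R21t = {calib['r21t_per_s3']:.3g} 1/s^3 (R^2 = {calib['fit_r_squared']:.4f})",
        f"T2 sensitivity (%T2 per 100% MBF increase): "
        f"{report['derived']['t2_sensitivity']:.2f}",
        "",
    ]
    return "\n".join(lines)
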