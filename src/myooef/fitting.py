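"""Estimation chain: apparent T2, coronary-sinus OEF, rest calibration,
hyperemic myocardial OEF.

The measurement protocol supplies three multi-echo series per session
(coronary sinus at rest, myocardium at rest, myocardium during hyperemia)
plus blood-volume fractions from first-pass perfusion.  The chain is:

1. :func:`fit_apparent_t2` — monoexponential T2 of any series (also used for
   phantoms).
2. :func:`fit_cs_oef` — resting global OEF from the coronary-sinus decay via
   the blood R2(OEF) calibration (the sinus drains ~90% of left-ventricular
   myocardial blood, so its oxygenation indexes global OEF).
3. :func:`calibrate_rest` — with resting OEF and MBV known, invert the
   two-compartment equation per TE for the tissue rate R2t, then regress
   R2t on (OEF*MBV*tau)^2 to obtain the subject-specific intercept R20t and
   slope R21t.
4. :func:`fit_stress_oef` — during hyperemia R20t/R21t are unchanged and MBV
   is measured, so apparent T2 is a monotone decreasing function of OEF
   alone; solve for OEF by bracketed root finding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import bisect, least_squares, minimize_scalar

from .exceptions import (
    CalibrationError,
    FitError,
    ModelViolationError,
    NoSolutionError,
)
from .relaxometry import (
    AcquisitionProtocol,
    AlphaTable,
    SignalSeries,
    TissueState,
    blood_r2,
    cs_signal,
    voxel_signal,
)

__all__ = [
    "ApparentT2Fit",
    "RestCalibration",
    "OefEstimate",
    "fit_apparent_t2",
    "fit_cs_oef",
    "calibrate_rest",
    "fit_stress_oef",
    "stress_forward_t2",
]

# deterministic solver policy shared by all fits
_LSQ_KW = dict(method="trf", ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=2000)
_T2_INIT_MS = 50.0
_T2_MAX_S = 10.0  # beyond any tissue T2; hitting it means "no decay"


@dataclass(frozen=True)
class ApparentT2Fit:
    """Monoexponential fit S(TE) = S0 * exp(-TE / T2)."""

    t2_apparent: float  # ms
    s0_hat: float
    residual_norm: float
    n_points: int

    def __post_init__(self):
        if self.t2_apparent <= 0:
            raise FitError(f"apparent T2 must be positive, got {self.t2_apparent}")
        if self.n_points < 2:
            raise FitError("apparent-T2 fit needs at least two echoes")


@dataclass(frozen=True)
class RestCalibration:
    """Subject-specific tissue relaxation parameters from the resting scan."""

    r20t_hat: float  # 1/s, intercept
    r21t_hat: float  # 1/s^3, slope
    per_te_r2t: tuple[tuple[float, float], ...]  # (te_ms, r2t 1/s)
    fit_r_squared: float
    oef_rest: float
    mbv_rest: float
    s0_hat: float
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        if self.r20t_hat <= 0:
            raise CalibrationError(f"fitted R20t must be positive, got {self.r20t_hat}")
        if len(self.per_te_r2t) < 2:
            raise CalibrationError("calibration needs at least two usable echoes")


@dataclass(frozen=True)
class OefEstimate:
    oef_hat: float
    condition: Literal["rest", "stress"]
    source: Literal["coronary_sinus", "myocardium"]
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.oef_hat <= 1.0:
            raise FitError(f"OEF estimate outside [0, 1]: {self.oef_hat}")


# ---------------------------------------------------------------------------
# (a) apparent T2
# ---------------------------------------------------------------------------


def fit_apparent_t2(series: SignalSeries) -> ApparentT2Fit:
    """Joint (S0, T2) least-squares monoexponential fit of a multi-echo series.

    For exactly two echoes the interpolating closed form is returned
    (T2 = dTE / ln(S1/S2)); for more echoes a trust-region least-squares
    solve initialized at S0 = max intensity, T2 = 50 ms.  A series that does
    not decay (best-fit T2 non-positive or unbounded) raises :class:`FitError`.
    """
    te = series.te_s
    y = series.intensity
    if len(series) == 2:
        if y[1] >= y[0]:
            raise FitError(
                "series does not decay between its two echoes; apparent T2 undefined"
            )
        t2 = (te[1] - te[0]) / np.log(y[0] / y[1])
        s0 = y[0] * np.exp(te[0] / t2)
        return ApparentT2Fit(
            t2_apparent=t2 * 1000.0, s0_hat=float(s0), residual_norm=0.0, n_points=2
        )

    def resid(x):
        s0, t2 = x
        return s0 * np.exp(-te / t2) - y

    x0 = np.array([float(y.max()), _T2_INIT_MS / 1000.0])
    sol = least_squares(
        resid, x0, bounds=([0.0, 1e-6], [np.inf, _T2_MAX_S]), **_LSQ_KW
    )
    s0, t2 = sol.x
    if not sol.success:
        raise FitError(f"apparent-T2 fit did not converge: {sol.message}")
    if t2 >= 0.99 * _T2_MAX_S or s0 <= 0:
        raise FitError(
            "apparent-T2 fit unbounded (series does not decay over the TE range)"
        )
    return ApparentT2Fit(
        t2_apparent=float(t2) * 1000.0,
        s0_hat=float(s0),
        residual_norm=float(np.linalg.norm(sol.fun)),
        n_points=len(series),
    )


# ---------------------------------------------------------------------------
# (CS) resting OEF from the coronary sinus
# ---------------------------------------------------------------------------


def fit_cs_oef(
    series: SignalSeries,
    protocol: AcquisitionProtocol,
    table: AlphaTable | None = None,
) -> OefEstimate:
    """Resting global OEF from the coronary-sinus multi-echo decay.

    Two free parameters (S0, OEF); OEF box-constrained to [0, 1].  The model
    is the pure blood-pool decay ``S0 * exp(-TE * R2b(OEF, TE))`` with the
    coronary-sinus alpha coefficients.  A solution pinned at either OEF
    boundary is flagged in ``diagnostics['at_boundary']``.
    """
    table = table if table is not None else AlphaTable.default()
    te_s = np.asarray(series.te_s)
    y = series.intensity
    # precompute per-echo coefficient rows once
    coefs = np.array(
        [table.coefficients(te, "coronary_sinus") for te in series.te_ms]
    )

    def model(s0, oef):
        r2b = coefs[:, 0] + coefs[:, 1] * oef + coefs[:, 2] * oef * oef
        return s0 * np.exp(-te_s * r2b)

    def resid(x):
        return model(x[0], x[1]) - y

    x0 = np.array([float(y.max()), 0.5])
    sol = least_squares(resid, x0, bounds=([0.0, 0.0], [np.inf, 1.0]), **_LSQ_KW)
    if not sol.success:
        raise FitError(f"coronary-sinus OEF fit did not converge: {sol.message}")
    s0_hat, oef_hat = sol.x
    at_boundary = bool(oef_hat <= 1e-12 or oef_hat >= 1.0 - 1e-12)
    return OefEstimate(
        oef_hat=float(np.clip(oef_hat, 0.0, 1.0)),
        condition=series.condition,
        source="coronary_sinus",
        diagnostics={
            "s0_hat": float(s0_hat),
            "cost": float(sol.cost),
            "nfev": int(sol.nfev),
            "at_boundary": at_boundary,
        },
    )


# ---------------------------------------------------------------------------
# (b)+(c) rest calibration
# ---------------------------------------------------------------------------


def _invert_r2t(
    srel: np.ndarray,
    te_ms: np.ndarray,
    te_s: np.ndarray,
    r2b: np.ndarray,
    mbv: float,
):
    """Per-TE tissue rate from the two-compartment identity.

    ``srel`` is the signal normalized to S0.  Echoes where the blood term
    meets or exceeds the total signal (inversion argument <= 0) are returned
    as NaN for the caller to drop.
    """
    arg = (srel - mbv * np.exp(-te_s * r2b)) / (1.0 - mbv)
    r2t = np.full_like(arg, np.nan)
    ok = arg > 0
    r2t[ok] = -np.log(arg[ok]) / te_s[ok]
    return r2t, ok


def calibrate_rest(
    myo_rest: SignalSeries,
    oef_rest: float,
    mbv_rest: float,
    protocol: AcquisitionProtocol,
    table: AlphaTable | None = None,
    *,
    s0_mode: Literal["joint", "apparent"] = "joint",
) -> RestCalibration:
    """Estimate R20t (intercept) and R21t (slope) from the resting myocardium.

    Per echo, the blood rate R2b follows from the resting OEF (coronary-sinus
    measurement) via the myocardial alpha coefficients; subtracting the blood
    term from the normalized signal and taking the log yields the tissue rate
    R2t(TE).  R2t is then linear in the single regressor
    ``x = (OEF * MBV * tau)**2`` with tau = TE/n inside the T2-prep module,
    and ordinary least squares gives the calibration pair.

    ``s0_mode`` controls how the unknown proton-density scale S0 is removed:

    * ``"joint"`` (default) — S0 is a third unknown, chosen to minimize the
      residual of the linear R2t-vs-x fit (a one-dimensional inner search).
      On model-consistent data this is exact: the inversion then reproduces
      the generating R2t at every echo.
    * ``"apparent"`` — the monoexponential fit of the series supplies both S0
      and the decay, i.e. the inversion consumes the smoothed representation
      ``exp(-TE/T2_apparent)`` rather than the raw intensities.  Slightly
      more noise-robust but biased, because the biexponential signal is not
      exactly monoexponential.

    A negative fitted slope is allowed (it can happen under noise) but is
    reported in ``warnings``; healthy myocardium has R21t > 0.
    """
    if not 0.0 <= oef_rest <= 1.0:
        raise ValueError("oef_rest must lie in [0, 1]")
    if not 0.0 <= mbv_rest < 1.0:
        raise ValueError("mbv_rest must lie in [0, 1)")
    table = table if table is not None else AlphaTable.default()

    te_ms = myo_rest.te_ms
    te_s = myo_rest.te_s
    tau_s = np.array([protocol.tau_for(t) for t in te_ms]) / 1000.0
    r2b = np.array([blood_r2(oef_rest, te, "myocardium", table) for te in te_ms])
    x = (oef_rest * mbv_rest * tau_s) ** 2

    app = fit_apparent_t2(myo_rest)
    notes: list[str] = []

    def linfit(r2t_vals, xs):
        A = np.column_stack([np.ones_like(xs), xs])
        coef, res, *_ = np.linalg.lstsq(A, r2t_vals, rcond=None)
        pred = A @ coef
        ss_res = float(np.sum((r2t_vals - pred) ** 2))
        ss_tot = float(np.sum((r2t_vals - r2t_vals.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return coef[0], coef[1], ss_res, r2

    def invert_for_s0(s0):
        srel = myo_rest.intensity / s0
        return _invert_r2t(srel, te_ms, te_s, r2b, mbv_rest)

    if s0_mode == "apparent":
        s0_hat = app.s0_hat
        srel = np.exp(-te_s / (app.t2_apparent / 1000.0))
        r2t, ok = _invert_r2t(srel, te_ms, te_s, r2b, mbv_rest)
    elif s0_mode == "joint":

        def objective(log_s0):
            r2t_v, ok_v = invert_for_s0(np.exp(log_s0))
            if ok_v.sum() < 2:
                return 1e12
            _, _, ss_res, _ = linfit(r2t_v[ok_v], x[ok_v])
            return ss_res

        c = np.log(app.s0_hat)
        sol = minimize_scalar(
            objective,
            bounds=(c - 0.35, c + 0.35),
            method="bounded",
            options={"xatol": 1e-14},
        )
        s0_hat = float(np.exp(sol.x))
        r2t, ok = invert_for_s0(s0_hat)
    else:
        raise ValueError(f"unknown s0_mode {s0_mode!r}")

    if ok.sum() < len(te_ms):
        bad = te_ms[~ok]
        if ok.sum() >= 2:
            notes.append(
                f"dropped echo(es) at TE={list(bad)} ms: blood term exceeded total signal"
            )
            warnings.warn(notes[-1], RuntimeWarning, stacklevel=2)
        else:
            raise CalibrationError(
                f"inversion argument non-positive at TE={list(bad)} ms; "
                "fewer than two usable echoes remain"
            )
    r2t_ok = r2t[ok]
    x_ok = x[ok]
    intercept, slope, ss_res, r2 = linfit(r2t_ok, x_ok)
    if slope < 0:
        notes.append(f"fitted R21t is negative ({slope:.3g} 1/s^3)")

    return RestCalibration(
        r20t_hat=float(intercept),
        r21t_hat=float(slope),
        per_te_r2t=tuple(zip(te_ms[ok].tolist(), r2t_ok.tolist())),
        fit_r_squared=float(r2),
        oef_rest=float(oef_rest),
        mbv_rest=float(mbv_rest),
        s0_hat=float(s0_hat),
        warnings=tuple(notes),
    )


# ---------------------------------------------------------------------------
# (d) hyperemic OEF
# ---------------------------------------------------------------------------


def stress_forward_t2(
    oef: float,
    calib: RestCalibration,
    mbv_stress: float,
    protocol: AcquisitionProtocol,
    table: AlphaTable | None = None,
) -> float:
    """Predicted apparent T2 (ms) at a candidate hyperemic OEF.

    Builds the noise-free two-compartment signal with the calibrated
    (R20t, R21t), the hyperemic MBV and the candidate OEF, then reduces it to
    an apparent T2 exactly the way a measured series is reduced.
    """
    r21t = max(calib.r21t_hat, 0.0)  # a noise-driven negative slope is clipped here
    state = TissueState(oef=oef, mbv=mbv_stress, r20t=calib.r20t_hat, r21t=r21t)
    sig = voxel_signal(state, protocol, s0=1.0, table=table, condition="stress")
    return fit_apparent_t2(sig).t2_apparent


def fit_stress_oef(
    myo_stress: SignalSeries,
    calib: RestCalibration,
    mbv_stress: float,
    protocol: AcquisitionProtocol,
    table: AlphaTable | None = None,
    *,
    n_scan: int = 21,
    xtol: float = 1e-6,
) -> OefEstimate:
    """Hyperemic myocardial OEF by inverting the apparent-T2 forward map.

    The forward map OEF -> predicted apparent T2 is scanned on ``n_scan``
    equispaced points of [0, 1] and must be strictly decreasing (higher
    extraction means more deoxyhemoglobin, faster decay); violation raises
    :class:`ModelViolationError`.  A measured apparent T2 outside the
    attainable interval raises :class:`NoSolutionError` carrying that
    interval.  Otherwise bisection on [0, 1] with ``xtol`` returns the unique
    root.
    """
    if not 0.0 <= mbv_stress < 1.0:
        raise ValueError("mbv_stress must lie in [0, 1)")
    table = table if table is not None else AlphaTable.default()
    measured = fit_apparent_t2(myo_stress).t2_apparent

    grid = np.linspace(0.0, 1.0, n_scan)
    t2_grid = np.array(
        [stress_forward_t2(g, calib, mbv_stress, protocol, table) for g in grid]
    )
    if not np.all(np.diff(t2_grid) < 0):
        raise ModelViolationError(
            "forward map T2(OEF) is not strictly decreasing on [0, 1]; "
            "check the calibration and alpha table"
        )
    t2_lo, t2_hi = float(t2_grid[-1]), float(t2_grid[0])  # at OEF=1 and OEF=0

    def g(oef):
        return stress_forward_t2(oef, calib, mbv_stress, protocol, table) - measured

    tol_ms = 1e-9
    if measured > t2_hi + tol_ms or measured < t2_lo - tol_ms:
        raise NoSolutionError(
            f"measured apparent T2 {measured:.3f} ms outside attainable "
            f"interval [{t2_lo:.3f}, {t2_hi:.3f}] ms for OEF in [0, 1]",
            attainable=(t2_lo, t2_hi),
        )
    if measured >= t2_hi - tol_ms:
        oef_hat, iters = 0.0, 0
    elif measured <= t2_lo + tol_ms:
        oef_hat, iters = 1.0, 0
    else:
        oef_hat = bisect(g, 0.0, 1.0, xtol=xtol)
        iters = int(np.ceil(np.log2(1.0 / xtol)))
    return OefEstimate(
        oef_hat=float(np.clip(oef_hat, 0.0, 1.0)),
        condition="stress",
        source="myocardium",
        diagnostics={
            "t2_measured_ms": float(measured),
            "t2_attainable_ms": (t2_lo, t2_hi),
            "bisection_iterations": iters,
            "monotone_scan_points": n_scan,
        },
    )
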