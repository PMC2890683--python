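"""Two-compartment transverse-relaxation forward models for cardiac oximetry.

The myocardial voxel is treated as two water pools in slow exchange on the T2
time scale: intravascular blood (volume fraction MBV) and extravascular tissue.
At echo time TE the ROI-mean signal is the volume-weighted biexponential

    S(TE) = S0 * [ MBV * exp(-TE * R2b) + (1 - MBV) * exp(-TE * R2t) ]

with TE in seconds inside the exponents.  Blood relaxation depends on the
oxygen extraction fraction (OEF) through a quadratic calibration

    R2b(OEF, TE) = alpha1 + alpha2 * OEF + alpha3 * OEF**2

whose coefficients (per TE, per compartment hematocrit) come from a van Zijl
style exchange model evaluated at 1.5 T; they are shipped here as a data table.
Extravascular tissue relaxation carries a diffusion-weighting term driven by
local field gradients around deoxygenated vessels,

    R2t = R20t + R21t * (OEF * MBV * tau)**2

where tau is the interecho (refocusing) spacing in seconds, R20t (1/s) is the
intrinsic tissue rate and R21t (1/s^3) lumps diffusion constant, susceptibility
difference and vessel geometry into one subject-specific coefficient.

Coronary-sinus blood is imaged as a pure blood pool: only the first term of
the biexponential applies there.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError

__all__ = [
    "AlphaTable",
    "AcquisitionProtocol",
    "TissueState",
    "SignalSeries",
    "blood_r2",
    "tissue_r2",
    "voxel_signal",
    "cs_signal",
    "COMPARTMENTS",
]

COMPARTMENTS = ("coronary_sinus", "myocardium")

Compartment = Literal["coronary_sinus", "myocardium"]

#: default systemic (coronary sinus) hematocrit, fraction
HCT_CS_DEFAULT = 0.40
#: default capillary hematocrit, conventionally half the systemic value
HCT_MYO_DEFAULT = 0.20


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise DataError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise DataError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class AlphaTable:
    """Blood R2-vs-OEF polynomial coefficients, indexed by TE and compartment.

    Parameters
    ----------
    entries : pandas.DataFrame
        Columns ``te_ms, compartment, alpha1, alpha2, alpha3``.  All alphas in
        1/s.  Coefficients differ between coronary sinus and myocardium only
        through the assumed hematocrit.
    hematocrit_cs, hematocrit_myo : float
        Hematocrit fractions the two coefficient sets were derived for.
        Capillary hematocrit defaults to half the systemic (coronary sinus)
        value.

    The default table (:meth:`default`) is valid for a T2-preparation scheme
    whose interecho spacing is tau = TE / 3; longer tau at fixed OEF raises
    every alpha, so a table is only meaningful for the TE->tau schedule it was
    derived for.  Turbo-spin-echo acquisitions (fixed tau of e.g. 8 or 12 ms)
    need their own table supplied by the user.
    """

    entries: pd.DataFrame
    hematocrit_cs: float = HCT_CS_DEFAULT
    hematocrit_myo: float = HCT_MYO_DEFAULT

    def __post_init__(self):
        df = self.entries
        required = {"te_ms", "compartment", "alpha1", "alpha2", "alpha3"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"alpha table missing columns: {sorted(missing)}")
        for comp, grp in df.groupby("compartment"):
            if comp not in COMPARTMENTS:
                raise DataError(f"unknown compartment {comp!r}")
            te = grp["te_ms"].to_numpy(dtype=float)
            if not np.all(np.diff(te) > 0):
                raise DataError(f"TE values must be strictly increasing ({comp})")
            alphas = grp[["alpha1", "alpha2", "alpha3"]].to_numpy(dtype=float)
            if not np.all(alphas > 0):
                raise DataError(f"alpha coefficients must be positive ({comp})")
            if not np.all(np.diff(alphas, axis=0) >= 0):
                raise DataError(f"alpha coefficients must be non-decreasing in TE ({comp})")
        if not (0 < self.hematocrit_cs < 1 and 0 < self.hematocrit_myo < 1):
            raise DataError("hematocrit fractions must lie in (0, 1)")

    # -- construction -----------------------------------------------------

    @classmethod
    def default(cls) -> "AlphaTable":
        """The shipped 1.5 T coefficient table (five TEs, tau = TE/3)."""
        text = resources.files("myooef.data").joinpath("alpha_table.csv").read_text()
        return cls.from_csv(io.StringIO(text))

    @classmethod
    def from_csv(cls, path_or_buf, **kwargs) -> "AlphaTable":
        df = pd.read_csv(path_or_buf)
        return cls(entries=df, **kwargs)

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)

    # -- lookup ------------------------------------------------------------

    def te_values(self, compartment: Compartment) -> np.ndarray:
        grp = self.entries[self.entries["compartment"] == compartment]
        return grp["te_ms"].to_numpy(dtype=float)

    def coefficients(
        self, te_ms: float, compartment: Compartment, *, extrapolate: bool = False
    ) -> tuple[float, float, float]:
        """(alpha1, alpha2, alpha3) at ``te_ms``, linearly interpolated in TE.

        Extrapolation beyond the tabulated TE range is refused unless
        ``extrapolate=True`` (linear continuation of the end segments).
        """
        if compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {compartment!r}")
        grp = self.entries[self.entries["compartment"] == compartment]
        if grp.empty:
            raise ValueError(f"alpha table has no rows for compartment {compartment!r}")
        te = grp["te_ms"].to_numpy(dtype=float)
        if not extrapolate and not (te[0] <= te_ms <= te[-1]):
            raise ValueError(
                f"TE={te_ms} ms outside tabulated range [{te[0]}, {te[-1]}] ms "
                f"for {compartment}; pass extrapolate=True to override"
            )
        out = []
        for col in ("alpha1", "alpha2", "alpha3"):
            y = grp[col].to_numpy(dtype=float)
            if te_ms <= te[0]:
                a = y[0] + (y[1] - y[0]) / (te[1] - te[0]) * (te_ms - te[0])
            elif te_ms >= te[-1]:
                a = y[-1] + (y[-1] - y[-2]) / (te[-1] - te[-2]) * (te_ms - te[-1])
            else:
                a = float(np.interp(te_ms, te, y))
            out.append(float(a))
        return tuple(out)  # type: ignore[return-value]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """T2-weighting acquisition descriptor.

    ``family`` selects how the interecho spacing tau is obtained:

    * ``t2prep`` — a T2-preparation module with ``n_refocus`` refocusing
      pulses; tau = TE / n_refocus (three pulses by default).
    * ``tse`` / ``spin_echo`` — fixed interecho spacing ``tau_ms`` shared by
      all echoes (e.g. 8 or 12 ms for a turbo-spin-echo readout).
    """

    family: Literal["t2prep", "tse", "spin_echo"]
    te_list: tuple[float, ...]
    n_refocus: int = 3
    tau_ms: float | None = None

    def __post_init__(self):
        if self.family not in ("t2prep", "tse", "spin_echo"):
            raise DataError(f"unknown sequence family {self.family!r}")
        te = np.asarray(self.te_list, dtype=float)
        if te.size == 0:
            raise DataError("te_list must be non-empty")
        if not np.all(te > 0):
            raise DataError("all TE values must be positive")
        if not np.all(np.diff(te) > 0):
            raise DataError("te_list must be strictly increasing")
        object.__setattr__(self, "te_list", tuple(float(t) for t in te))
        if self.family == "t2prep":
            if self.n_refocus < 1:
                raise DataError("n_refocus must be >= 1")
        else:
            if self.tau_ms is None or self.tau_ms <= 0:
                raise DataError(f"{self.family} protocol requires explicit tau_ms > 0")

    @classmethod
    def t2prep_default(cls) -> "AcquisitionProtocol":
        """The five-echo breath-hold scheme: TE = 24..72 ms, three 180s."""
        return cls(family="t2prep", te_list=(24.0, 36.0, 48.0, 60.0, 72.0))

    def tau_for(self, te_ms: float) -> float:
        """Interecho spacing in ms at echo time ``te_ms``."""
        if self.family == "t2prep":
            return te_ms / self.n_refocus
        return float(self.tau_ms)  # type: ignore[arg-type]

    @property
    def te_s(self) -> np.ndarray:
        return np.asarray(self.te_list, dtype=float) / 1000.0

    @property
    def tau_s(self) -> np.ndarray:
        return np.array([self.tau_for(t) for t in self.te_list]) / 1000.0


@dataclass(frozen=True)
class TissueState:
    """Physiological state of a myocardial ROI under one condition.

    oef : oxygen extraction fraction, in [0, 1]
    mbv : blood volume fraction (mL blood per mL tissue), in [0, 1)
    r20t : intrinsic tissue transverse rate, 1/s
    r21t : diffusion/susceptibility coefficient, 1/s^3
    """

    oef: float
    mbv: float
    r20t: float
    r21t: float
    hematocrit: float = HCT_MYO_DEFAULT
    arterial_saturation: float = 0.95

    def __post_init__(self):
        if not 0.0 <= self.oef <= 1.0:
            raise ValueError(f"oef must lie in [0, 1], got {self.oef}")
        if not 0.0 <= self.mbv < 1.0:
            raise ValueError(f"mbv must lie in [0, 1), got {self.mbv}")
        if self.r20t <= 0:
            raise ValueError("r20t must be positive")
        if self.r21t < 0:
            raise ValueError("r21t must be non-negative")


@dataclass(frozen=True)
class SignalSeries:
    """ROI-mean signal intensity versus echo time.

    Intensities are in arbitrary scanner units; ``s0`` is known only for
    simulated series and is None for measured data.
    """

    te_ms: np.ndarray
    intensity: np.ndarray
    label: Literal["cs", "myocardium", "phantom"] = "myocardium"
    condition: Literal["rest", "stress"] = "rest"
    s0: float | None = None

    def __post_init__(self):
        te = _as_float_array(self.te_ms, "te_ms")
        sig = _as_float_array(self.intensity, "intensity")
        if te.size != sig.size:
            raise DataError("te_ms and intensity must have the same length")
        if te.size < 2:
            raise DataError("a signal series needs at least two echoes")
        if not np.all(np.diff(te) > 0):
            raise DataError("te_ms must be strictly increasing")
        if not np.all(sig > 0):
            raise DataError("intensities must be positive")
        object.__setattr__(self, "te_ms", te)
        object.__setattr__(self, "intensity", sig)

    def __len__(self) -> int:
        return int(self.te_ms.size)

    @property
    def te_s(self) -> np.ndarray:
        return self.te_ms / 1000.0


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------


def blood_r2(
    oef: float,
    te_ms: float,
    compartment: Compartment,
    table: AlphaTable | None = None,
    *,
    extrapolate: bool = False,
) -> float:
    """Blood transverse relaxation rate R2b (1/s) at a given OEF and TE.

    Evaluates the quadratic oxygenation calibration
    ``alpha1 + alpha2*OEF + alpha3*OEF**2`` with coefficients interpolated
    from ``table`` at ``te_ms`` for the requested compartment.  Strictly
    increasing in OEF (all alphas are positive), i.e. more deoxyhemoglobin
    always shortens blood T2.
    """
    if not 0.0 <= oef <= 1.0:
        raise ValueError(f"oef must lie in [0, 1], got {oef}")
    table = table if table is not None else AlphaTable.default()
    a1, a2, a3 = table.coefficients(te_ms, compartment, extrapolate=extrapolate)
    return a1 + a2 * oef + a3 * oef * oef


def tissue_r2(state: TissueState, tau_s: float) -> float:
    """Extravascular tissue relaxation rate R2t (1/s) at interecho spacing tau.

    ``R2t = R20t + R21t * (OEF * MBV * tau)**2`` with tau in seconds.  The
    diffusion term vanishes when either OEF or MBV is zero and grows
    quadratically with tau, which is why longer interecho spacing buys
    oxygenation sensitivity.
    """
    if tau_s < 0:
        raise ValueError(f"tau must be non-negative, got {tau_s}")
    x = state.oef * state.mbv * tau_s
    return state.r20t + state.r21t * x * x


def voxel_signal(
    state: TissueState,
    protocol: AcquisitionProtocol,
    s0: float,
    table: AlphaTable | None = None,
    *,
    condition: Literal["rest", "stress"] = "rest",
) -> SignalSeries:
    """Noise-free two-compartment myocardial signal over the protocol's TEs.

    The blood compartment uses the myocardium (capillary hematocrit) alpha
    coefficients; the tissue compartment uses the diffusion model at the
    protocol's interecho spacing.
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    table = table if table is not None else AlphaTable.default()
    te_s = protocol.te_s
    tau_s = protocol.tau_s
    sig = np.empty_like(te_s)
    for i, (te, tau) in enumerate(zip(protocol.te_list, tau_s)):
        r2b = blood_r2(state.oef, te, "myocardium", table)
        r2t = tissue_r2(state, tau)
        sig[i] = s0 * (
            state.mbv * np.exp(-te_s[i] * r2b) + (1.0 - state.mbv) * np.exp(-te_s[i] * r2t)
        )
    return SignalSeries(
        te_ms=np.asarray(protocol.te_list), intensity=sig, label="myocardium",
        condition=condition, s0=s0,
    )


def cs_signal(
    oef: float,
    protocol: AcquisitionProtocol,
    s0: float,
    table: AlphaTable | None = None,
    *,
    condition: Literal["rest", "stress"] = "rest",
) -> SignalSeries:
    """Noise-free coronary-sinus (pure blood pool) signal over the protocol's TEs.

    Only the blood term of the voxel model applies.  Because the alpha
    coefficients themselves depend on TE, the decay is not globally
    monoexponential even though each echo sees a single compartment.
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    table = table if table is not None else AlphaTable.default()
    te_s = protocol.te_s
    sig = np.empty_like(te_s)
    for i, te in enumerate(protocol.te_list):
        r2b = blood_r2(oef, te, "coronary_sinus", table)
        sig[i] = s0 * np.exp(-te_s[i] * r2b)
    return SignalSeries(
        te_ms=np.asarray(protocol.te_list), intensity=sig, label="cs",
        condition=condition, s0=s0,
    )
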