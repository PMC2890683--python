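"""Derived physiological quantities.

Scalar, unit-explicit helpers layered on top of the estimation chain:
myocardial oxygen consumption (Fick principle on the coronary circulation),
its unit conversion, the T2-per-flow sensitivity index used to compare pulse
sequences, the rate-pressure product workload surrogate, and percent change.

All functions are pure and operate per subject; aggregation order matters
(the product of group means is not the mean of per-subject products, which
is exactly why group-mean inputs only approximately reproduce group-mean
outputs), so averaging across subjects is left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SubjectPhysiology",
    "mvo2",
    "mvo2_to_ml",
    "t2_sensitivity",
    "rate_pressure_product",
    "percent_change",
]


@dataclass(frozen=True)
class SubjectPhysiology:
    """Per-subject constants entering MVO2 and workload calculations.

    Defaults are the standard values of the Fick oxygen-content calculation:
    1.39 mL O2 bound per gram hemoglobin, 0.14 g hemoglobin per mL blood,
    44.658 umol O2 per mL O2 (ideal gas at body conditions), and 95%
    arterial oxygen saturation.
    """

    heart_rate: float = float("nan")  # bpm
    systolic_bp: float = float("nan")  # mmHg
    hematocrit: float = 0.40
    hemoglobin_density: float = 0.14  # g Hb / mL blood
    o2_capacity: float = 1.39  # mL O2 / g Hb
    o2_molar: float = 44.658  # umol / mL O2
    arterial_saturation: float = 0.95

    def __post_init__(self):
        for name in ("hemoglobin_density", "o2_capacity", "o2_molar", "arterial_saturation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.hematocrit < 1:
            raise ValueError("hematocrit must lie in (0, 1)")


def mvo2(oef: float, mbf: float, phys: SubjectPhysiology | None = None) -> float:
    """Myocardial oxygen consumption rate in umol O2 / g / min.

    Fick principle: arterial O2 content (capacity x Hb density x saturation,
    converted to moles) times the extracted fraction times flow::

        MVO2 = 1.39 * 0.14 * 44.658 * 0.95 * OEF * MBF

    Linear in each of OEF and MBF.
    """
    if not 0.0 <= oef <= 1.0:
        raise ValueError(f"oef must lie in [0, 1], got {oef}")
    if mbf < 0:
        raise ValueError("mbf must be non-negative")
    p = phys if phys is not None else SubjectPhysiology()
    return (
        p.o2_capacity * p.hemoglobin_density * p.o2_molar * p.arterial_saturation
        * oef * mbf
    )


def mvo2_to_ml(mvo2_umol: float, phys: SubjectPhysiology | None = None) -> float:
    """Convert MVO2 from umol/g/min to mL O2/g/min (divide by 44.658 umol/mL)."""
    if mvo2_umol < 0:
        raise ValueError("mvo2 must be non-negative")
    p = phys if phys is not None else SubjectPhysiology()
    return mvo2_umol / p.o2_molar


def t2_sensitivity(
    t2_rest: float, t2_stress: float, mbf_rest: float, mbf_stress: float
) -> float:
    """Percent change in myocardial T2 per 100% (i.e. per doubling-equivalent)
    increase in MBF.

    ``100 * (T2_s - T2_r)/T2_r`` divided by the fractional flow increase
    ``(MBF_s - MBF_r)/MBF_r``.  Intended per subject, then averaged.
    """
    for name, v in (("t2_rest", t2_rest), ("t2_stress", t2_stress),
                    ("mbf_rest", mbf_rest), ("mbf_stress", mbf_stress)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    dmbf = (mbf_stress - mbf_rest) / mbf_rest
    if dmbf == 0:
        raise ZeroDivisionError("MBF unchanged between conditions; sensitivity undefined")
    return 100.0 * (t2_stress - t2_rest) / t2_rest / dmbf


def rate_pressure_product(heart_rate: float, systolic_bp: float) -> float:
    """Heart rate (bpm) x systolic pressure (mmHg): the cardiac workload surrogate."""
    if heart_rate <= 0 or systolic_bp <= 0:
        raise ValueError("heart rate and systolic pressure must be positive")
    return heart_rate * systolic_bp


def percent_change(baseline: float, follow: float) -> float:
    """100 * (follow - baseline) / baseline."""
    if baseline == 0:
        raise ValueError("baseline must be non-zero")
    return 100.0 * (follow - baseline) / baseline
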