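"""The full oximetry chain on a simulated rest/adenosine session.

Generates noise-free multi-echo series at the default operating point
(resting OEF 0.73, hyperemic OEF 0.37), then runs:
coronary-sinus OEF fit -> rest calibration (R20t, R21t) -> hyperemic OEF
inversion, and prints recovered values against the generating truth.
"""

from myooef import (
    AcquisitionProtocol,
    AlphaTable,
    SimulationConfig,
    calibrate_rest,
    fit_cs_oef,
    fit_stress_oef,
    mvo2,
    simulate_session,
)

protocol = AcquisitionProtocol.t2prep_default()
table = AlphaTable.default()

bundle = simulate_session(SimulationConfig())
truth = bundle.truth

oef_rest = fit_cs_oef(bundle.cs_rest, protocol, table)
print(f"1. coronary-sinus OEF at rest: {oef_rest.oef_hat:.4f} "
      f"(truth {truth['oef_rest']})")

calib = calibrate_rest(
    bundle.myo_rest, oef_rest.oef_hat, truth["mbv_rest"], protocol, table
)
print(f"2. rest calibration: R20t = {calib.r20t_hat:.3f} 1/s "
      f"(truth {truth['r20t']}), R21t = {calib.r21t_hat:.4g} 1/s^3 "
      f"(truth {truth['r21t']:.4g})")

oef_stress = fit_stress_oef(
    bundle.myo_stress, calib, truth["mbv_stress"], protocol, table
)
print(f"3. hyperemic myocardial OEF: {oef_stress.oef_hat:.4f} "
      f"(truth {truth['oef_stress']})")

m_rest = mvo2(oef_rest.oef_hat, truth["mbf_rest"])
m_stress = mvo2(oef_stress.oef_hat, truth["mbf_stress"])
print(f"4. MVO2 rest -> stress: {m_rest:.2f} -> {m_stress:.2f} umol/g/min")
print("\nExtraction halves while flow triples: consumption rises ~70-90%, "
      "mirroring the workload increase under adenosine.")
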