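"""First-pass perfusion: regularized deconvolution of a simulated bolus.

Simulates a gamma-variate arterial input and its tissue response at known
MBF/MTT, recovers the impulse response by non-negative exponential-basis
deconvolution, and prints the central-volume summary.
"""

from myooef import AifParams, quantify_perfusion, simulate_first_pass

for label, mbf, mtt in (("rest", 0.89, 4.045), ("adenosine", 2.97, 2.020)):
    tissue, aif = simulate_first_pass(AifParams(), mbf, mtt)
    res = quantify_perfusion(tissue, aif)
    print(f"{label:9s}: MBF = {res.mbf:.3f} mL/g/min (truth {mbf}), "
          f"MTT = {res.mtt:.2f} s (truth {mtt}), MBV = {res.mbv:.4f} mL/g")
print("\nMBV = MBF x MTT / 60 by construction; hyperemia raises flow ~3x "
      "while the transit time halves, so blood volume rises ~65%.")
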