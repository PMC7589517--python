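"""Two-density ELISA: Hill fits, Beatty affinity estimate, capacity readout.

Simulates kinetic plates at single and double bacterial coating for
antibodies of known affinity, fits the per-dilution kinetic slopes with a
Hill curve, and applies the two-density estimator.  Both the verbatim
printed form (an association constant, 1/nM) and its reciprocal reading
as K_D app in nM are shown; the plateau ratio reads out relative epitope
capacity.
"""

from bactoline import plate_ec50, beatty_kd, epitope_capacity
from bactoline.simulate import simulate_elisa

for kd in (0.2, 1.5, 24.0):
    plate_1x, plate_2x = simulate_elisa(kd)
    fit_1x, fit_2x = plate_ec50(plate_1x), plate_ec50(plate_2x)
    est = beatty_kd(fit_1x.ec50, fit_2x.ec50)
    cap = epitope_capacity(fit_1x, fit_2x)
    print(f"true K_D = {kd:5.1f} nM:")
    print(f"  EC50(1x) = {fit_1x.ec50:7.3f} nM, EC50(2x) = {fit_2x.ec50:7.3f} nM")
    print(f"  formula value = {est['formula_value_per_nM']:.4f} /nM  "
          f"->  K_D app = {est['kd_app_nM']:.3f} nM "
          f"({100 * abs(est['kd_app_nM'] - kd) / kd:.1f}% off)")
    print(f"  plateau ratio 2x/1x = {cap['ratio']:.3f} (doubled coating, "
          "doubled capacity)\n")
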