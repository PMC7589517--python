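"""Refit the affinity calibration and classify example antibodies.

Builds the default log-linear map alpha = beta0 + beta1*ln(K_D) from
titrations of the forward model at known affinities, then inverts it for
a few alpha values and assigns the three-class affinity and
epitope-availability labels the screen reports.
"""

from bactoline import kd_from_alpha, alpha_from_kd, classify_kd, classify_epitope
from bactoline.simulate import build_default_calibration, STUDY_CONSTANTS

cal = build_default_calibration(STUDY_CONSTANTS)
print(f"refit map: beta0 = {cal.beta0:.4f}, beta1 = {cal.beta1:.5f} per ln(nM), "
      f"R^2 = {cal.rsquared:.3f}")
print(f"capacity slope: {cal.ymax_slope:.3f} relocation units per nM epitope\n")

for kd in (2.0, 20.0, 100.0):
    alpha = float(alpha_from_kd(kd, cal))
    back = float(kd_from_alpha(alpha, cal))
    print(f"K_D app {kd:6.1f} nM -> alpha {alpha:.5f} -> back {back:6.1f} nM "
          f"({str(classify_kd(back, cal))} affinity)")
print()
for y_max in (1.6, 2.5, 3.4):
    print(f"y_max {y_max:.1f} -> epitope availability class: "
          f"{str(classify_epitope(y_max, cal))}")
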