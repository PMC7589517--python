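"""A full synthetic droplet screen: simulate, analyze, compare with truth.

Generates a population with known per-cell secretion rates, affinities and
epitope densities; processes every trace through feature extraction,
alpha, the affinity map and the 3x3 classification; and prints the
exclusion breakdown, the heat map, and how often the assigned bins match
the generator's ground truth (in median-rate mode, the realistic setting
where the individual cell's secretion rate is unknown).
"""

import numpy as np

from bactoline import analyze_traces, heatmap
from bactoline.pipeline import IGG_SECRETION, SecretionSummary
from bactoline.simulate import (SynthConfig, simulate_population,
                                build_default_calibration, offboundary_mask,
                                STUDY_CONSTANTS)

cal = build_default_calibration(STUDY_CONSTANTS)
cfg = SynthConfig(seed=42, n_droplets=5000)
traces, truth = simulate_population(cfg)
records = analyze_traces(traces, {"IgG": IGG_SECRETION,
                                  "IgM": SecretionSummary(300.0, 117.0)},
                         STUDY_CONSTANTS, cal, noise_sd=cfg.noise_cv)

print(f"droplets: {len(records)}, secreting cells: {int(truth.isotype.notna().sum())}")
print("exclusion breakdown:")
print(records.excluded_reason.fillna("(processed)").value_counts().to_string(), "\n")

included = records[records.excluded_reason.isna()]
print("affinity x epitope-density heat map (fractions of processed cells):")
print(heatmap(included).round(3).to_string(), "\n")

merged = records.merge(truth, on="droplet_id")
inc = merged[merged.kd_class.notna()]
offb = inc[offboundary_mask(inc.rename(columns={"isotype_y": "isotype"}))]
kd_ok = (offb.kd_class == offb.kd_class_true).mean()
ep_ok = (offb.epitope_class == offb.epitope_class_true).mean()
print(f"off-boundary cells scored: {len(offb)}")
print(f"affinity class agreement (median-rate mode): {100 * kd_ok:.1f}%")
print(f"epitope class agreement: {100 * ep_ok:.1f}%")
print("-> affinity errors are dominated by the unknown per-cell secretion rate;")
print("   the epitope readout (y_max) does not depend on the rate and is exact.")
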