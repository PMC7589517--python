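"""Cohort-level repertoire statistics.

Converts per-screen counts into frequencies of antibody-secreting cells
(Ig-SCs), using the Poisson occupancy rule: the number of screened cells is
the number of droplets times the mean occupancy lambda.  Builds the derived
quantities reported for immunisation cohorts — class-switch ratios,
specific and cross-reactive fractions, 3x3 affinity x epitope-density heat
maps with marginals, heat-map differences between cohorts — and the
two-tailed Student's t-test used for between-cohort comparisons.

Frequencies are averaged as mean +/- SD over mice; secretion rates as
median +/- SD, matching the reporting convention of droplet screens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import KD_CLASSES, EPITOPE_CLASSES

__all__ = [
    "round_half_up",
    "ScreenCounts",
    "frequencies",
    "cohort_summary",
    "switch_ratio",
    "specific_fraction",
    "crossreactivity",
    "heatmap",
    "heatmap_difference",
    "ttest_two_tailed",
]


def round_half_up(x, ndigits=0):
    """Round with ties away from zero, for printed-precision report tables.

    Internal computations are never rounded; this is applied only when a
    value is compared with, or reported at, a publication's printed
    precision (where 1.75% is printed as 1.8%).
    """
    import decimal
    d = decimal.Decimal(repr(float(x))).quantize(
        decimal.Decimal(1).scaleb(-ndigits), rounding=decimal.ROUND_HALF_UP)
    return float(d)


@dataclass
class ScreenCounts:
    """Raw outcome of one mouse's droplet screen."""

    n_droplets: int
    lambda_occupancy: float
    n_igg_sc: int = 0
    n_igm_sc: int = 0
    n_specific_igg_sc: int = 0
    mouse_id: str = ""
    immunogen: str = ""
    assay_target: str = ""

    def __post_init__(self):
        if self.n_droplets <= 0 or self.lambda_occupancy <= 0:
            raise ValueError("n_droplets and lambda_occupancy must be > 0")
        for n in (self.n_igg_sc, self.n_igm_sc, self.n_specific_igg_sc):
            if n < 0:
                raise ValueError("counts must be >= 0")

    @property
    def cells_screened(self) -> float:
        return self.n_droplets * self.lambda_occupancy


def frequencies(counts: ScreenCounts) -> dict:
    """Per-mouse Ig-SC frequencies in % of screened cells.

    Total screened cells = droplets x lambda; each frequency is the count
    over that total, in percent.  The switch ratio is flagged undefined
    (NaN) when no IgM-SCs were seen.
    """
    total = counts.cells_screened
    f_igg = 100.0 * counts.n_igg_sc / total
    f_igm = 100.0 * counts.n_igm_sc / total
    f_spec = 100.0 * counts.n_specific_igg_sc / total
    return {
        "mouse_id": counts.mouse_id,
        "cells_screened": total,
        "freq_igg": f_igg,
        "freq_igm": f_igm,
        "freq_ig_total": f_igg + f_igm,
        "freq_specific_igg": f_spec,
        "switch_ratio": switch_ratio(f_igg, f_igm),
    }


def switch_ratio(freq_igg, freq_igm):
    """Class-switch ratio: IgG-SC frequency over IgM-SC frequency.

    NaN (undefined) when the IgM frequency is zero.
    """
    if freq_igm == 0:
        return float("nan")
    return freq_igg / freq_igm


def specific_fraction(freq_specific_igg, freq_total_igg):
    """Fraction of all IgG-SCs whose IgG binds the assayed surface."""
    if freq_total_igg == 0:
        return float("nan")
    return freq_specific_igg / freq_total_igg


def crossreactivity(freq_vs_target, freq_vs_immunogen):
    """Cross-reactive frequency relative to the anti-immunogen frequency."""
    if freq_vs_immunogen == 0:
        return float("nan")
    return freq_vs_target / freq_vs_immunogen


def cohort_summary(per_mouse: pd.DataFrame, freq_cols=None, rate_cols=()) -> pd.DataFrame:
    """Cohort summary over mice: mean +/- SD for frequencies, median +/- SD for rates.

    ``per_mouse`` has one row per mouse.  Columns named in ``rate_cols``
    are summarised by median, all other numeric columns (or those named in
    ``freq_cols``) by mean; the spread column is the sample SD (ddof=1) in
    both cases, NaN for a single mouse.
    """
    if freq_cols is None:
        freq_cols = [c for c in per_mouse.select_dtypes("number").columns
                     if c not in rate_cols]
    rows = []
    for col in list(freq_cols) + list(rate_cols):
        v = per_mouse[col].to_numpy(dtype=float)
        center = float(np.median(v)) if col in rate_cols else float(np.mean(v))
        sd = float(np.std(v, ddof=1)) if v.size > 1 else float("nan")
        rows.append({"quantity": col,
                     "center": center,
                     "center_kind": "median" if col in rate_cols else "mean",
                     "sd": sd, "n_mice": v.size})
    return pd.DataFrame(rows)


def heatmap(records: pd.DataFrame) -> pd.DataFrame:
    """3x3 relative-frequency heat map of included cell records.

    Rows are affinity classes (high, intermediate, low), columns epitope
    classes (low, intermediate, high).  Entries are fractions of all
    included records and sum to 1; a ``sum`` row/column holds the
    marginals.  With no included records the matrix is all zero (flagged
    by the zero total).
    """
    included = records[records["excluded_reason"].isna()] if "excluded_reason" in records else records
    mat = pd.DataFrame(0.0, index=list(KD_CLASSES), columns=list(EPITOPE_CLASSES))
    n = len(included)
    if n > 0:
        counts = included.groupby(["kd_class", "epitope_class"]).size()
        for (kd_c, ep_c), c in counts.items():
            mat.loc[kd_c, ep_c] = c / n
    mat["sum"] = mat.sum(axis=1)
    mat.loc["sum"] = mat.sum(axis=0)
    return mat


def heatmap_difference(map_a: pd.DataFrame, map_b: pd.DataFrame) -> pd.DataFrame:
    """Signed per-bin difference of two heat maps (entries sum to ~0)."""
    return map_a - map_b


def ttest_two_tailed(group_a, group_b):
    """Classic two-sample Student's t-test with pooled variance, two-tailed.

    Implemented from the closed form: t = (mean_a - mean_b) / (s_p *
    sqrt(1/n_a + 1/n_b)) with the pooled variance s_p^2, p from the t
    distribution with n_a + n_b - 2 degrees of freedom.  Welch's unequal-
    variance variant is available via ``scipy.stats.ttest_ind(equal_var=
    False)`` if needed.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    na, nb = a.size, b.size
    dof = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / dof
    if sp2 == 0:
        t = 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    else:
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = float(2.0 * stats.t.sf(abs(t), dof)) if np.isfinite(t) else 0.0
    if t == 0.0:
        p = 1.0
    return float(t), p
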