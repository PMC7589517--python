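"""Plate-level affinity and capacity estimation from two-density ELISA.

Wells are coated with whole heat-killed bacteria at two densities (the
second twice the first), a dilution series of antibody is applied, and the
enzymatic readout is recorded kinetically.  Because product accumulation is
linear over the observation window, the per-well signal is the fitted
slope.  Slopes versus antibody concentration are fitted with a Hill curve
per coating density; the two EC50 values feed the two-density affinity
estimator of Beatty et al., and the Hill plateaus (maximal turnover rates)
measure relative epitope capacity.

The printed two-density formula

    K_D app = 1 / (2 * (2 * EC50_1x - EC50_2x))

is dimensionally an *association* constant (reciprocal concentration);
:func:`beatty_kd` therefore reports both the verbatim value and its
reciprocal read as a dissociation constant in nM, so either convention of
the estimator is reproducible.  For a bivalent antibody titrated against
antigen in the dilute-coating regime, EC50 equals K_D/2 at single coating
and approaches K_D at double coating, which is exactly what makes the
reciprocal reading ``2*(2*EC50_1x - EC50_2x)`` recover K_D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["ElisaPlate", "HillFit", "kinetic_slope", "fit_hill",
           "beatty_kd", "epitope_capacity", "plate_ec50"]


class EstimationError(ValueError):
    """Raised when the two-density estimator's precondition fails."""


@dataclass
class ElisaPlate:
    """Kinetic reads of one coating density.

    ``kinetic_reads`` has one row per dilution, one column per read time.
    """

    coating_level: str  # "1x" or "2x"
    dilution_concentrations: np.ndarray  # nM, increasing
    read_times: np.ndarray  # minutes
    kinetic_reads: np.ndarray

    def __post_init__(self):
        self.dilution_concentrations = np.asarray(self.dilution_concentrations, dtype=float)
        self.read_times = np.asarray(self.read_times, dtype=float)
        self.kinetic_reads = np.asarray(self.kinetic_reads, dtype=float)
        if self.dilution_concentrations.size < 4:
            raise ValueError("need >= 4 dilutions")
        if self.read_times.size < 2:
            raise ValueError("need >= 2 kinetic time points per well")
        if self.kinetic_reads.shape != (self.dilution_concentrations.size, self.read_times.size):
            raise ValueError("kinetic_reads must be (n_dilutions, n_times)")


@dataclass
class HillFit:
    ec50: float       # nM
    plateau: float    # maximal turnover rate, signal/min
    hill_n: float
    rss: float

    def __post_init__(self):
        if self.ec50 <= 0 or self.plateau <= 0:
            raise ValueError("ec50 and plateau must be positive")


def kinetic_slope(times, reads):
    """Ordinary least-squares slope of signal versus time (signal/min)."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(reads, dtype=float)
    return float(np.polyfit(t, y, 1)[0])


def _hill(c, plateau, ec50, n):
    return plateau * c ** n / (ec50 ** n + c ** n)


def fit_hill(concentrations, responses) -> HillFit:
    """Three-parameter Hill fit (baseline fixed at zero, blocked wells).

    ``r = plateau * c^n / (EC50^n + c^n)``, least squares.  Requires at
    least four points; initial values come from the data (half-maximal
    crossing for EC50).
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.size < 4:
        raise ValueError("need >= 4 points for a Hill fit")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    top = float(r.max())
    if top <= 0:
        raise RuntimeError("no positive response; Hill fit impossible")
    half = top / 2.0
    above = np.flatnonzero(r >= half)
    ec50_init = c[above[0]] if above.size else np.median(c[c > 0])
    ec50_init = max(ec50_init, c[c > 0].min())
    try:
        popt, _ = curve_fit(_hill, c, r, p0=[top, ec50_init, 1.0],
                            bounds=([0, 1e-12, 0.1], [np.inf, np.inf, 10.0]),
                            maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"Hill fit did not converge: {exc}") from exc
    resid = r - _hill(c, *popt)
    return HillFit(ec50=float(popt[1]), plateau=float(popt[0]),
                   hill_n=float(popt[2]), rss=float(resid @ resid))


def plate_ec50(plate: ElisaPlate) -> HillFit:
    """Kinetic slopes per dilution, then the Hill fit of slope vs concentration."""
    slopes = np.array([kinetic_slope(plate.read_times, row) for row in plate.kinetic_reads])
    return fit_hill(plate.dilution_concentrations, slopes)


def beatty_kd(ec50_1x, ec50_2x):
    """Two-density affinity estimate from EC50 at single and double coating.

    Returns a dict with the verbatim printed-formula value
    ``1 / (2*(2*EC50_1x - EC50_2x))`` (units 1/nM, an association constant)
    and its reciprocal ``kd_app_nM = 2*(2*EC50_1x - EC50_2x)`` interpreted
    as a dissociation constant in nM.

    Raises
    ------
    EstimationError
        if ``2*EC50_1x <= EC50_2x`` — coating densities too similar or
        inverted; the estimator is undefined (non-positive).
    """
    if ec50_1x <= 0 or ec50_2x <= 0:
        raise ValueError("EC50 values must be positive")
    diff = 2.0 * ec50_1x - ec50_2x
    if diff <= 0:
        raise EstimationError(
            f"2*EC50_1x - EC50_2x = {diff:.4g} <= 0: coating densities too "
            "similar or inverted; two-density estimate undefined"
        )
    return {"formula_value_per_nM": 1.0 / (2.0 * diff), "kd_app_nM": 2.0 * diff}


def epitope_capacity(fit_low: HillFit, fit_high: HillFit):
    """Relative epitope capacity from the two Hill plateaus.

    The plateau (maximal turnover rate) measures the amount of antibody
    bound at saturation, i.e. the number of binding sites in the well;
    doubling the coating should double it.
    """
    return {"plateau_low": fit_low.plateau, "plateau_high": fit_high.plateau,
            "ratio": fit_high.plateau / fit_low.plateau}
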