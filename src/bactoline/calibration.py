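"""Calibration maps linking curve features to affinity and epitope density.

Two maps are maintained:

* the affinity map, a log-linear relation ``alpha = beta0 + beta1 * ln(kd)``
  between the corrected curve feature alpha (maximal relocation divided by
  the concentration at which it occurs) and the apparent dissociation
  constant K_D app, inverted as ``kd = exp((alpha - beta0) / beta1)``;
* the capacity map, a linear relation through the origin between
  baseline-subtracted maximal relocation (y_max - 1) and the in-droplet
  concentration of available epitopes in reference-antigen equivalents.

The constants 0.969 / -0.014 published for the original instrument are
shipped as the named preset :data:`PAPER_PRESET`; because the absolute
scale of alpha depends on unit conventions and an undocumented volume
correction, the default analysis refits both maps from titrations of the
forward model in this package's own convention (nM, minutes) — see
:func:`bactoline.simulate.build_default_calibration`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

__all__ = [
    "CalibrationMap",
    "PAPER_PRESET",
    "kd_from_alpha",
    "alpha_from_kd",
    "fit_alpha_map",
    "epitope_from_ymax",
    "classify_kd",
    "classify_epitope",
    "KD_CLASSES",
    "EPITOPE_CLASSES",
]

#: affinity classes, strongest binding first
KD_CLASSES = ("high", "intermediate", "low")
#: epitope-availability classes, sparsest first
EPITOPE_CLASSES = ("low", "intermediate", "high")


class CalibrationError(ValueError):
    """Raised when a calibration cannot be fitted from the given data."""


@dataclass
class CalibrationMap:
    """Fitted or preset calibration of curve features to (K_D app, epitopes).

    Attributes
    ----------
    beta0, beta1 : float
        Intercept and slope (per ln nM) of the log-linear alpha–affinity
        relation.  ``beta1`` must be negative: stronger binders (smaller
        kd) reach their maximum at lower concentration and hence have
        larger alpha.
    ymax_slope : float
        Increase of (y_max - 1) per unit of reference signal (nM
        reference-antigen equivalent in the refit convention; ELISA
        turnover units for the published presets 0.46 / 0.67).
    kd_thresholds : (float, float)
        Class boundaries on K_D app in nM: high < t0 <= intermediate <= t1
        < low.
    ymax_thresholds : (float, float)
        Class boundaries on y_max: low < t0 <= intermediate <= t1 < high.
    provenance : str
        "paper_preset" or "refit".
    rsquared, beta_se : optional fit diagnostics.
    """

    beta0: float
    beta1: float
    ymax_slope: float = 0.1
    kd_thresholds: tuple = (10.0, 50.0)
    ymax_thresholds: tuple = (2.0, 3.0)
    provenance: str = "refit"
    rsquared: float | None = None
    beta_se: tuple | None = None

    def __post_init__(self):
        if self.beta1 >= 0:
            raise CalibrationError("beta1 must be negative (alpha decreases with kd)")
        if self.ymax_slope <= 0:
            raise CalibrationError("ymax_slope must be positive")
        for pair, name in ((self.kd_thresholds, "kd_thresholds"),
                           (self.ymax_thresholds, "ymax_thresholds")):
            if not (len(pair) == 2 and pair[0] < pair[1]):
                raise CalibrationError(f"{name} must be two strictly increasing values")

    def to_json(self, path):
        d = asdict(self)
        d["kd_thresholds"] = list(d["kd_thresholds"])
        d["ymax_thresholds"] = list(d["ymax_thresholds"])
        if d["beta_se"] is not None:
            d["beta_se"] = list(d["beta_se"])
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        d["kd_thresholds"] = tuple(d["kd_thresholds"])
        d["ymax_thresholds"] = tuple(d["ymax_thresholds"])
        if d.get("beta_se") is not None:
            d["beta_se"] = tuple(d["beta_se"])
        return cls(**d)


#: Calibration constants of the original publication's instrument, on its
#: own (non-reconstructable) alpha scale.  Usable for unit arithmetic and
#: round-trips but not interchangeable with maps refit in this package's
#: nM/minute convention.
PAPER_PRESET = CalibrationMap(
    beta0=0.969, beta1=-0.014, ymax_slope=0.46, provenance="paper_preset"
)


def kd_from_alpha(alpha, cal: CalibrationMap):
    """Apparent dissociation constant (nM) from the corrected feature alpha.

    ``kd = exp((alpha - beta0) / beta1)``; strictly decreasing in alpha.
    """
    return np.exp((np.asarray(alpha, dtype=float) - cal.beta0) / cal.beta1)


def alpha_from_kd(kd_app, cal: CalibrationMap):
    """Inverse of :func:`kd_from_alpha`: alpha = beta0 + beta1 * ln(kd)."""
    kd = np.asarray(kd_app, dtype=float)
    if np.any(kd <= 0):
        raise ValueError("kd_app must be > 0")
    return cal.beta0 + cal.beta1 * np.log(kd)


def fit_alpha_map(calibrants, **map_kwargs) -> CalibrationMap:
    """Least-squares fit of the log-linear alpha–affinity map.

    Parameters
    ----------
    calibrants : sequence of (kd_app_nM, alpha)
        Measured alpha for antibodies of known affinity; >= 3 distinct
        affinities required.
    map_kwargs : passed through to :class:`CalibrationMap` (thresholds,
        ymax_slope...).

    Returns
    -------
    CalibrationMap with ``provenance="refit"`` and fit diagnostics
    (R^2, standard errors of the coefficients).
    """
    pts = np.asarray(list(calibrants), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise CalibrationError("need >= 3 (kd, alpha) calibrants")
    kd, alpha = pts[:, 0], pts[:, 1]
    if np.unique(kd).size < 3:
        raise CalibrationError("need >= 3 distinct kd values")
    if np.any(kd <= 0):
        raise CalibrationError("kd calibrants must be > 0")
    x = np.log(kd)
    design = np.column_stack([np.ones_like(x), x])
    coef, rss, *_ = np.linalg.lstsq(design, alpha, rcond=None)
    beta0, beta1 = float(coef[0]), float(coef[1])
    if beta1 >= 0:
        raise CalibrationError(
            f"fitted beta1={beta1:.4g} is non-negative; calibrants do not show "
            "the expected decrease of alpha with kd"
        )
    resid = alpha - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((alpha - alpha.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = len(alpha) - 2
    if dof > 0 and ss_res > 0:
        sigma2 = ss_res / dof
        cov = sigma2 * np.linalg.inv(design.T @ design)
        se = (float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1])))
    else:
        se = (0.0, 0.0)
    return CalibrationMap(beta0=beta0, beta1=beta1, provenance="refit",
                          rsquared=r2, beta_se=se, **map_kwargs)


def epitope_from_ymax(y_max, cal: CalibrationMap):
    """Available-epitope concentration (reference equivalents) from y_max.

    Inverts the linear through-origin capacity map
    ``y_max - 1 = ymax_slope * q``; monotone increasing, 0 at baseline.
    """
    y = np.asarray(y_max, dtype=float)
    if np.any(y < 1):
        raise ValueError("y_max must be >= 1 (relocation baseline)")
    return (y - 1.0) / cal.ymax_slope


def classify_kd(kd_app, cal: CalibrationMap | None = None):
    """Affinity class from K_D app (nM): high < t0 <= intermediate <= t1 < low.

    Boundary values belong to the intermediate class (closed middle
    interval); the published intervals leave the boundaries unassigned.
    """
    t0, t1 = (cal.kd_thresholds if cal is not None else (10.0, 50.0))
    kd = np.asarray(kd_app, dtype=float)
    out = np.where(kd < t0, "high", np.where(kd <= t1, "intermediate", "low"))
    return out if out.shape else str(out)


def classify_epitope(y_max, cal: CalibrationMap | None = None):
    """Epitope-availability class from y_max: low < t0 <= intermediate <= t1 < high.

    Boundary closure matches :func:`classify_kd` (closed middle interval).
    """
    t0, t1 = (cal.ymax_thresholds if cal is not None else (2.0, 3.0))
    y = np.asarray(y_max, dtype=float)
    out = np.where(y < t0, "low", np.where(y <= t1, "intermediate", "high"))
    return out if out.shape else str(out)
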