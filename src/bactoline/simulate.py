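"""Ground-truth generators for every input the analysis consumes.

The population generator emulates the statistical structure of a droplet
screen: Poisson cell encapsulation, log-normal single-cell secretion rates
(parameterised by the cohort median), a 3x3 ground-truth mixture over
(affinity, epitope-density) classes, bactoline-to-bactoline variation in
the number of immobilised bacteria (which scales the available epitope
concentration), the five-point 15-minute imaging schedule, and
multiplicative measurement noise on the relocation signal above baseline.
Every latent variable is recorded in a truth table keyed by droplet id, so
parameter-recovery tests can compare pipeline output to ground truth.

Also provided: calibration titrations of the forward model (to refit the
affinity map in this package's unit convention), two-density ELISA plates,
per-droplet bacteria-count estimates by three methods, and small rendered
pixel grids to exercise the segmentation operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (AssayConstants, BindingParams, solve_relocation,
                    trace_from_secretion, concentration_at_time, langmuir_bound)
from .calibration import CalibrationMap, fit_alpha_map, classify_kd, classify_epitope
from .pipeline import DropletTrace
from .elisa import ElisaPlate

__all__ = [
    "SynthConfig",
    "STUDY_CONSTANTS",
    "simulate_population",
    "simulate_calibration_titrations",
    "simulate_elisa",
    "bacteria_per_droplet_estimates",
    "render_droplet_image",
    "build_default_calibration",
    "lognormal_sigma_from_median_sd",
]

#: Assay constants of the default synthetic study.  The volume-correction
#: factor reconciles the concentration scale at which the titration curves
#: peak with the concentrations a secreting cell reaches within the one-hour
#: imaging window, so that traces can show the interior maximum the pipeline
#: requires (the published analysis relies on the same undocumented scalar).
STUDY_CONSTANTS = AssayConstants(corr=5.0)

#: Default ground-truth mixture weights, rows = affinity class
#: (high, intermediate, low), columns = epitope class (low, intermediate,
#: high).  Emulates an immunised-cohort profile: roughly half of the
#: bacteria-binding cells are high-affinity against dense epitopes, most of
#: the rest are high-affinity against sparse/intermediate epitopes, and low
#: affinities are rare.
DEFAULT_TRUTH_WEIGHTS = (
    (0.13, 0.15, 0.45),
    (0.08, 0.10, 0.05),
    (0.01, 0.02, 0.01),
)

#: Per-class sampling ranges: K_D app (nM) per affinity class and epitope
#: concentration (nM, before bacteria-count scaling) per epitope class.
#: Ranges sample the cores of the classes (kd boundaries 10/50 nM; epitope
#: boundaries ~10/20 nM equivalent at the default capacity slope of ~0.1
#: per nM), reflecting that the assay reports affinity only at three-class
#: resolution.
DEFAULT_KD_RANGES = ((1.2, 4.0), (15.0, 33.0), (70.0, 140.0))
DEFAULT_EPITOPE_RANGES = ((5.0, 7.0), (13.0, 16.0), (28.0, 38.0))


def lognormal_sigma_from_median_sd(median, sd):
    """Log-scale sigma of a log-normal with the given median and SD.

    With median m = e^mu, SD s:  (s/m)^2 = x(x-1) where x = e^(sigma^2),
    giving the closed form x = (1 + sqrt(1 + 4 (s/m)^2)) / 2.
    """
    ratio2 = (sd / median) ** 2
    x = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * ratio2))
    return math.sqrt(math.log(x))


@dataclass
class SynthConfig:
    """Configuration of one synthetic droplet screen."""

    seed: int
    n_droplets: int = 2000
    lambda_occupancy: float = 0.25
    # probability that an encapsulated cell secretes the given isotype
    isotype_probs: dict = field(default_factory=lambda: {"IgG": 0.2, "IgM": 0.2, "none": 0.6})
    sr_median: dict = field(default_factory=lambda: {"IgG": 250.0, "IgM": 300.0})
    sr_sd: dict = field(default_factory=lambda: {"IgG": 150.0, "IgM": 117.0})
    truth_weights: tuple = DEFAULT_TRUTH_WEIGHTS
    kd_ranges: tuple = DEFAULT_KD_RANGES
    epitope_ranges: tuple = DEFAULT_EPITOPE_RANGES
    bacteria_mean: float = 164.0
    bacteria_sd: float = 30.0
    noise_cv: float = 0.05
    kd_detect: float = 2500.0
    gain: float = 267.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_droplets <= 0 or self.lambda_occupancy < 0:
            raise ValueError("n_droplets must be > 0 and lambda_occupancy >= 0")
        p = sum(self.isotype_probs.values())
        if not math.isclose(p, 1.0, rel_tol=1e-9):
            raise ValueError("isotype_probs must sum to 1")
        w = np.asarray(self.truth_weights, dtype=float)
        if w.shape != (3, 3) or not math.isclose(float(w.sum()), 1.0, rel_tol=1e-9):
            raise ValueError("truth_weights must be a 3x3 mixture summing to 1")
        if np.any(w < 0):
            raise ValueError("truth_weights must be non-negative")


def _dense_peak(params: BindingParams, constants: AssayConstants):
    """Continuous-curve (y_max, x_max) on a fine concentration grid."""
    grid = np.geomspace(0.05, 2e4, 900)
    y = solve_relocation(params, constants, grid)
    i = int(np.argmax(y))
    return float(y[i]), float(grid[i])


def simulate_population(config: SynthConfig, constants: AssayConstants | None = None):
    """Generate one droplet screen with full ground truth.

    Returns ``(traces, truth)``: a list of :class:`DropletTrace` (both
    detection channels per droplet; non-secretors and empty droplets give
    flat noisy baselines) and a DataFrame of per-droplet latents —
    occupancy, isotype, secretion rate, true kd and epitope concentration,
    bacteria count, the noiseless continuous-curve peak (y, x) and the true
    affinity/epitope classes derived from them.
    """
    constants = constants or STUDY_CONSTANTS
    rng = np.random.default_rng(config.seed)
    times = np.asarray(constants.imaging_times)
    iso_names = list(config.isotype_probs)
    iso_p = np.array([config.isotype_probs[k] for k in iso_names])
    weights = np.asarray(config.truth_weights, dtype=float).ravel()
    sigma = {iso: lognormal_sigma_from_median_sd(config.sr_median[iso], config.sr_sd[iso])
             for iso in config.sr_median}

    traces, rows = [], []
    for i in range(config.n_droplets):
        did = f"d{i:06d}"
        n_cells = int(rng.poisson(config.lambda_occupancy))
        channels = {ch: np.ones_like(times) for ch in ("IgG", "IgM")}
        row = dict(droplet_id=did, n_cells=n_cells, isotype=None, secretion_rate=np.nan,
                   kd_true=np.nan, epitope_true=np.nan, bacteria=np.nan,
                   y_max_true=np.nan, x_max_true=np.nan,
                   kd_class_true=None, epitope_class_true=None)
        if n_cells > 0:
            # doublets are indistinguishable from singlets in the assay and
            # are counted as one secreting event
            iso = iso_names[rng.choice(len(iso_names), p=iso_p)]
            if iso != "none":
                sr = float(rng.lognormal(math.log(config.sr_median[iso]), sigma[iso]))
                bin_idx = int(rng.choice(9, p=weights))
                kd_lo, kd_hi = config.kd_ranges[bin_idx // 3]
                ep_lo, ep_hi = config.epitope_ranges[bin_idx % 3]
                kd = float(np.exp(rng.uniform(math.log(kd_lo), math.log(kd_hi))))
                ep_base = float(rng.uniform(ep_lo, ep_hi))
                bact = 0.0
                while bact <= 0:
                    bact = float(rng.normal(config.bacteria_mean, config.bacteria_sd))
                epitope = ep_base * bact / config.bacteria_mean
                params = BindingParams(kd, epitope, config.kd_detect, config.gain)
                trace = trace_from_secretion(params, constants, sr)
                channels[iso] = trace.y.copy()
                y_pk, x_pk = _dense_peak(params, constants)
                row.update(isotype=iso, secretion_rate=sr, kd_true=kd,
                           epitope_true=epitope, bacteria=bact,
                           y_max_true=y_pk, x_max_true=x_pk,
                           kd_class_true=str(classify_kd(kd)),
                           epitope_class_true=str(classify_epitope(y_pk)))
        if config.noise_cv > 0:
            for ch in channels:
                noise = 1.0 + config.noise_cv * rng.standard_normal(times.size)
                channels[ch] = np.clip(1.0 + (channels[ch] - 1.0) * noise, 0.0, None)
        traces.append(DropletTrace(did, times, channels, cell_present=n_cells > 0))
        rows.append(row)
    return traces, pd.DataFrame(rows)


def offboundary_mask(truth: pd.DataFrame, margin: float = 0.2) -> pd.Series:
    """Cells whose latents sit farther than ``margin`` from every class boundary.

    Affinity: true kd outside [10/(1+m), 10*(1+m)] and [50/(1+m), 50*(1+m)].
    Epitope: the noiseless baseline-subtracted peak (y_max_true - 1) outside
    the corresponding bands around the class thresholds (y = 2 and 3, i.e.
    1 and 2 above baseline).  Cells near a boundary are ambiguous by
    construction and are not scored in recovery tests.
    """
    kd = truth["kd_true"]
    ym1 = truth["y_max_true"] - 1.0
    ok = pd.Series(True, index=truth.index)
    for b in (10.0, 50.0):
        ok &= ~kd.between(b / (1 + margin), b * (1 + margin))
    for b in (1.0, 2.0):
        ok &= ~ym1.between(b / (1 + margin), b * (1 + margin))
    return ok & truth["isotype"].notna()


def simulate_calibration_titrations(kds, epitope_total=10.0,
                                    constants: AssayConstants | None = None,
                                    kd_detect=2500.0, gain=267.0,
                                    concentrations=None):
    """Titrate the forward model at known affinities; extract (kd, alpha).

    alpha is the curve feature y_max / x_max on a dense concentration grid,
    in nM units — the same convention the droplet pipeline produces after
    converting peak time to concentration.  Feeds
    :func:`bactoline.calibration.fit_alpha_map`.
    """
    constants = constants or STUDY_CONSTANTS
    kds = np.atleast_1d(np.asarray(kds, dtype=float))
    grid = (np.geomspace(0.05, 2e4, 1200) if concentrations is None
            else np.asarray(concentrations, dtype=float))
    out = []
    for kd in kds:
        params = BindingParams(kd, epitope_total, kd_detect, gain)
        y = solve_relocation(params, constants, grid)
        i = int(np.argmax(y))
        out.append((float(kd), float(y[i] / grid[i])))
    return pd.DataFrame(out, columns=["kd_nM", "alpha"])


def build_default_calibration(constants: AssayConstants | None = None,
                              epitope_ref=10.0, kd_grid=None,
                              kd_detect=2500.0, gain=267.0) -> CalibrationMap:
    """Refit the affinity and capacity maps in this package's convention.

    The affinity map is fitted log-linearly to titrations at a reference
    capacity over a grid of affinities spanning the class boundaries; the
    capacity slope is measured directly as (y_max - 1) / epitope at the
    reference point.
    """
    constants = constants or STUDY_CONSTANTS
    if kd_grid is None:
        kd_grid = np.geomspace(1.0, 150.0, 9)
    cal_pts = simulate_calibration_titrations(kd_grid, epitope_ref, constants,
                                              kd_detect, gain)
    params = BindingParams(2.0, epitope_ref, kd_detect, gain)
    y_ref, _ = _dense_peak(params, constants)
    slope = (y_ref - 1.0) / epitope_ref
    return fit_alpha_map(cal_pts.to_numpy(), ymax_slope=slope)


def simulate_elisa(kd, antigen_1x=0.5, dilutions=None, read_times=None,
                   noise_cv=0.0, seed=None, sites_per_antibody=2.0,
                   turnover_per_bound=1.0):
    """Two-density ELISA plate pair for an antibody of known affinity.

    The per-well signal accumulates linearly in time with a rate
    proportional to the amount of antibody bound at equilibrium; binding is
    mass-action with ligand depletion, with ``sites_per_antibody`` epitope-
    binding sites per IgG (bivalent by default — the regime in which the
    two-density estimator's reciprocal reading recovers K_D).  Doubling the
    coating doubles the saturating signal.  Returns ``(plate_1x, plate_2x)``.
    """
    if dilutions is None:
        dilutions = np.geomspace(0.003, 300.0, 12)
    if read_times is None:
        read_times = np.arange(0.0, 61.0, 10.0)
    dilutions = np.asarray(dilutions, dtype=float)
    read_times = np.asarray(read_times, dtype=float)
    rng = np.random.default_rng(seed)
    plates = []
    for label, antigen in (("1x", antigen_1x), ("2x", 2.0 * antigen_1x)):
        bound = langmuir_bound(sites_per_antibody * dilutions, antigen, kd)
        rates = turnover_per_bound * bound
        reads = np.outer(rates, read_times)
        if noise_cv > 0:
            reads = reads * (1.0 + noise_cv * rng.standard_normal(reads.shape))
        plates.append(ElisaPlate(label, dilutions, read_times, reads))
    return tuple(plates)


def bacteria_per_droplet_estimates(two_d_mean=164.0, two_d_sd=30.0,
                                   bactoline_volume_um3=2000.0,
                                   hkb_volume_um3=2.0,
                                   od_fold_drop=50.0, od_to_count=16.0):
    """Bacteria-per-droplet estimates by the three independent methods.

    * ``two_d``: direct 2-D fluorescence-area count (mean, SD, CV) — a lower
      bound since the bactoline is a 3-D object;
    * ``volume``: bactoline volume divided by the volume of one bacterium —
      an upper bound;
    * ``od``: optical-density depletion before/after immobilisation times a
      per-fold droplet-count conversion.
    """
    return {
        "two_d": {"mean": two_d_mean, "sd": two_d_sd, "cv": two_d_sd / two_d_mean},
        "volume": bactoline_volume_um3 / hkb_volume_um3,
        "od": od_fold_drop * od_to_count,
    }


def render_droplet_image(relocation, shape=(64, 64), radius=26,
                         bar_halfwidth=2, bar_halflength=12,
                         fragment=False, fragment_size=8,
                         background=100.0, noise_cv=0.0, seed=None):
    """Render a synthetic droplet image pair for the segmentation pipeline.

    The droplet is a disk; the bactoline a horizontal bar through its
    centre, bright in the autofluorescence channel and carrying
    ``relocation`` times the background intensity in the signal channel.
    With ``fragment=True`` a detached blob smaller than half the bactoline
    area is added to exercise the fragment-removal rule.  Returns a dict
    with ``fitc`` (segmentation channel), ``signal``, ``droplet_mask`` and
    the ground-truth ``bactoline_mask``.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h // 2, w // 2
    droplet = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
    bar = (np.abs(yy - cy) <= bar_halfwidth) & (np.abs(xx - cx) <= bar_halflength)
    bar &= droplet
    frag = np.zeros_like(bar)
    if fragment:
        fy, fx = cy - radius // 2, cx + radius // 2
        fh = max(1, int(np.sqrt(fragment_size)))
        frag[fy:fy + fh, fx:fx + max(1, fragment_size // fh)] = True
        frag &= droplet & ~bar
    fitc = np.where(droplet, 10.0, 0.0)
    fitc[bar] = 1000.0
    fitc[frag] = 900.0
    signal = np.where(droplet, background, 0.0)
    signal[bar | frag] = background * relocation
    if noise_cv > 0:
        fitc *= 1.0 + noise_cv * rng.standard_normal(shape)
        signal *= 1.0 + noise_cv * rng.standard_normal(shape)
    return {"fitc": np.clip(fitc, 0, None), "signal": np.clip(signal, 0, None),
            "droplet_mask": droplet, "bactoline_mask": bar}
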