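"""Population receptive field (pRF) modeling.

Each cortical site is modeled as a single isotropic 2D Gaussian receptive
field with center ``(x0, y0)`` and spread ``sigma`` in degrees of visual
angle.  The neural drive at volume ``t`` is the overlap between the binary
stimulus aperture and the Gaussian; the BOLD prediction is this drive
convolved with a double-gamma hemodynamic response function (HRF) and
z-scored.  Fitting is two-stage: an exhaustive lattice search maximizing
Pearson correlation on spatially smoothed data, followed by Nelder-Mead
refinement of ``(x0, y0, log sigma)`` on the unsmoothed series.

The HRF is estimated per subject from a sparse photic-burst run by fitting
the event-locked average response with a difference of two gamma densities
(peak delay, undershoot delay and peak:undershoot ratio free; both
dispersions fixed at 1 s to keep the fit well-posed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .exceptions import DegenerateFitError, InvalidArgumentError
from .stimulus import ApertureSequence, RunSchedule

__all__ = [
    "HRFParams",
    "HRFFit",
    "PRFParams",
    "VertexTimeSeries",
    "double_gamma_kernel",
    "fit_hrf",
    "predict_timeseries",
    "default_lattice",
    "PRFGrid",
    "grid_fit",
    "refine_fit",
    "fit_vertex",
    "smooth_sheet",
    "fit_prf_sheet",
]

#: vertices whose best correlation falls below this floor are treated as
#: unmapped and excluded from delineation
R_FLOOR = 0.1


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF parameters (seconds; ratio dimensionless)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    peak_undershoot_ratio: float = 6.0
    duration_s: float = 32.0

    def __post_init__(self) -> None:
        if min(self.peak_delay_s, self.undershoot_delay_s,
               self.peak_dispersion_s, self.undershoot_dispersion_s) <= 0:
            raise InvalidArgumentError("HRF delays and dispersions must be > 0")
        if self.peak_undershoot_ratio <= 0:
            raise InvalidArgumentError("peak_undershoot_ratio must be > 0")


@dataclass
class HRFFit:
    """Result of subject-level HRF estimation."""

    params: HRFParams
    r_squared: float
    residual: float
    degenerate: bool = False


@dataclass
class PRFParams:
    """Gaussian pRF parameters for one vertex.

    ``r`` is the Pearson correlation between the model prediction and the
    data; ``beta`` the response amplitude recovered post hoc by least
    squares.  ``converged`` is cleared when Nelder-Mead refinement hit its
    iteration budget without converging (the grid-stage values are kept).
    """

    x0_deg: float
    y0_deg: float
    sigma_deg: float
    beta: float = np.nan
    r: float = np.nan
    converged: bool = True

    def __post_init__(self) -> None:
        if self.sigma_deg <= 0:
            raise InvalidArgumentError("sigma_deg must be > 0")

    @property
    def polar_angle_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.y0_deg, self.x0_deg)))

    @property
    def eccentricity_deg(self) -> float:
        return float(np.hypot(self.x0_deg, self.y0_deg))


@dataclass
class VertexTimeSeries:
    """BOLD samples (arbitrary units) for one vertex."""

    values: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidArgumentError("values must be 1-D")

    def __len__(self) -> int:
        return self.values.shape[0]


# ----------------------------------------------------------------------
# HRF
# ----------------------------------------------------------------------

def double_gamma_kernel(h: HRFParams, tr_s: float,
                        duration_s: float | None = None) -> np.ndarray:
    """Sampled double-gamma kernel, normalized to unit peak.

    kernel(t) = Gamma(shape=peak_delay/peak_disp, scale=peak_disp).pdf(t)
              - (1/ratio) * Gamma(undershoot_delay/u_disp, u_disp).pdf(t)
    """
    duration_s = h.duration_s if duration_s is None else duration_s
    if duration_s < h.peak_delay_s:
        raise InvalidArgumentError("duration_s must cover the response peak")
    t = np.arange(0.0, duration_s + 1e-9, tr_s)
    pos = stats.gamma.pdf(t, a=h.peak_delay_s / h.peak_dispersion_s,
                          scale=h.peak_dispersion_s)
    neg = stats.gamma.pdf(t, a=h.undershoot_delay_s / h.undershoot_dispersion_s,
                          scale=h.undershoot_dispersion_s)
    k = pos - neg / h.peak_undershoot_ratio
    peak = np.max(np.abs(k))
    if peak == 0:
        raise InvalidArgumentError("kernel is identically zero")
    return k / peak


def _event_average(series: VertexTimeSeries, sched: RunSchedule) -> np.ndarray:
    """Average response epoch following each stimulation volume."""
    onsets = sched.stim_onsets
    if onsets.size == 0:
        raise InvalidArgumentError("schedule contains no stimulation volumes")
    T = len(series)
    gaps = np.diff(np.append(onsets, T))
    ep_len = int(gaps.min())
    if ep_len < 2:
        raise InvalidArgumentError("epochs too short for HRF estimation")
    epochs = np.stack([series.values[o:o + ep_len] for o in onsets
                       if o + ep_len <= T])
    return epochs.mean(axis=0)


def fit_hrf(series: VertexTimeSeries, sched: RunSchedule,
            init: HRFParams = HRFParams(), r2_floor: float = 0.2) -> HRFFit:
    """Estimate HRF timing from a photic-burst run.

    The event-locked average epoch is fitted by least squares over
    ``(peak_delay, undershoot_delay, peak:undershoot ratio)`` with the two
    dispersions held at their defaults; amplitude and offset are profiled
    out linearly at every objective evaluation.
    """
    if len(series) != len(sched):
        raise InvalidArgumentError("series and schedule length mismatch")
    if np.std(series.values) == 0:
        raise DegenerateFitError("all-constant series")
    m = _event_average(series, sched)
    t_var = float(np.sum((m - m.mean()) ** 2))
    if t_var == 0:
        raise DegenerateFitError("event average has no variance")
    duration = len(m) * series.tr_s

    def sse(theta: np.ndarray) -> float:
        pd, ud, ratio = theta
        if pd <= 0 or ud <= 0 or ratio <= 0 or duration < pd:
            return np.inf
        h = replace(init, peak_delay_s=pd, undershoot_delay_s=ud,
                    peak_undershoot_ratio=ratio)
        k = double_gamma_kernel(h, series.tr_s, duration)[:len(m)]
        X = np.column_stack([k, np.ones_like(k)])
        coef, *_ = np.linalg.lstsq(X, m, rcond=None)
        return float(np.sum((m - X @ coef) ** 2))

    x0 = np.array([init.peak_delay_s, init.undershoot_delay_s,
                   init.peak_undershoot_ratio])
    res = optimize.minimize(sse, x0, method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-10,
                                     "maxiter": 2000})
    pd, ud, ratio = res.x
    params = replace(init, peak_delay_s=float(pd),
                     undershoot_delay_s=float(ud),
                     peak_undershoot_ratio=float(ratio))
    r2 = 1.0 - res.fun / t_var
    return HRFFit(params, float(r2), float(res.fun),
                  degenerate=bool(r2 < r2_floor))


# ----------------------------------------------------------------------
# Forward model
# ----------------------------------------------------------------------

def _masks_flat(ap: ApertureSequence) -> np.ndarray:
    """Cached (T, n_pixels) float view of the aperture masks."""
    flat = getattr(ap, "_flat_cache", None)
    if flat is None:
        flat = ap.masks.reshape(len(ap), -1).astype(float)
        ap._flat_cache = flat
    return flat


def _pixel_grid(ap: ApertureSequence) -> tuple[np.ndarray, np.ndarray]:
    grid = getattr(ap, "_grid_cache", None)
    if grid is None:
        n = ap.masks.shape[1]
        c = np.linspace(-ap.field_radius_deg, ap.field_radius_deg, n)
        x, y = np.meshgrid(c, c, indexing="xy")
        grid = (x.ravel(), y.ravel())
        ap._grid_cache = grid
    return grid


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd < 1e-12 * (1.0 + np.abs(v).max()):
        raise DegenerateFitError("prediction has no variance (pRF outside field?)")
    return (v - v.mean()) / sd


def _drive(x0: float, y0: float, sigma: float,
           ap: ApertureSequence) -> np.ndarray:
    px, py = _pixel_grid(ap)
    g = np.exp(-((px - x0) ** 2 + (py - y0) ** 2) / (2.0 * sigma ** 2))
    return _masks_flat(ap) @ g


def predict_timeseries(p: PRFParams, ap: ApertureSequence,
                       h: HRFParams) -> VertexTimeSeries:
    """Z-scored BOLD prediction for one pRF: aperture-Gaussian overlap
    convolved with the HRF kernel and truncated to the run length."""
    if len(ap) == 0:
        raise InvalidArgumentError("empty aperture sequence")
    tr = float(ap.times[1] - ap.times[0]) if len(ap) > 1 else 1.0
    drive = _drive(p.x0_deg, p.y0_deg, p.sigma_deg, ap)
    kernel = double_gamma_kernel(h, tr)
    pred = np.convolve(drive, kernel)[:len(ap)]
    return VertexTimeSeries(_zscore(pred), tr)


# ----------------------------------------------------------------------
# Grid stage
# ----------------------------------------------------------------------

def default_lattice(field_radius_deg: float = 10.40,
                    n_angles: int = 12, n_ecc: int = 8,
                    n_sigma: int = 6,
                    sigma_range: tuple[float, float] = (0.2, 5.0),
                    ) -> np.ndarray:
    """Coarse search lattice: polar grid of centers x log-spaced sigmas.

    Returns an (m, 3) array of (x0, y0, sigma) rows.
    """
    angles = np.arange(n_angles) * (2 * np.pi / n_angles)
    eccs = np.geomspace(field_radius_deg / 40.0, field_radius_deg, n_ecc)
    sigmas = np.geomspace(*sigma_range, n_sigma)
    rows = [(e * np.cos(a), e * np.sin(a), s)
            for e in eccs for a in angles for s in sigmas]
    return np.array(rows)


class PRFGrid:
    """Precomputed z-scored predictions for every lattice point."""

    def __init__(self, ap: ApertureSequence, h: HRFParams,
                 lattice: np.ndarray):
        lattice = np.asarray(lattice, dtype=float)
        if lattice.size == 0:
            raise InvalidArgumentError("empty lattice")
        self.lattice = lattice
        tr = float(ap.times[1] - ap.times[0]) if len(ap) > 1 else 1.0
        px, py = _pixel_grid(ap)
        # Gaussians for all lattice points: (n_pixels, m)
        d2 = ((px[:, None] - lattice[None, :, 0]) ** 2
              + (py[:, None] - lattice[None, :, 1]) ** 2)
        gauss = np.exp(-d2 / (2.0 * lattice[None, :, 2] ** 2))
        drives = _masks_flat(ap) @ gauss                      # (T, m)
        kernel = double_gamma_kernel(h, tr)
        T = len(ap)
        preds = np.empty_like(drives)
        for j in range(drives.shape[1]):
            preds[:, j] = np.convolve(drives[:, j], kernel)[:T]
        sd = preds.std(axis=0)
        self.valid = sd > 1e-12
        preds = preds - preds.mean(axis=0)
        preds[:, self.valid] /= sd[self.valid] * np.sqrt(T)
        preds[:, ~self.valid] = 0.0
        self.zpred = preds   # columns have unit L2 norm where valid

    def correlate(self, series: np.ndarray) -> np.ndarray:
        """Pearson r of each lattice prediction with a 1-D series."""
        z = series - series.mean()
        nrm = np.linalg.norm(z)
        if nrm == 0:
            raise DegenerateFitError("zero-variance series")
        r = self.zpred.T @ (z / nrm)
        r[~self.valid] = -np.inf
        return r


def grid_fit(series: VertexTimeSeries, ap: ApertureSequence, h: HRFParams,
             grid: PRFGrid | np.ndarray) -> PRFParams:
    """Exhaustive lattice search maximizing Pearson correlation.

    Ties are broken toward the lowest lattice index.
    """
    if not isinstance(grid, PRFGrid):
        grid = PRFGrid(ap, h, np.asarray(grid))
    r = grid.correlate(series.values)
    j = int(np.argmax(r))       # argmax returns the first maximal index
    x0, y0, sigma = grid.lattice[j]
    p = PRFParams(float(x0), float(y0), float(sigma), r=float(r[j]))
    p.beta = _beta_lsq(p, series, ap, h)
    return p


def _beta_lsq(p: PRFParams, series: VertexTimeSeries,
              ap: ApertureSequence, h: HRFParams) -> float:
    pred = predict_timeseries(p, ap, h).values
    X = np.column_stack([pred, np.ones_like(pred)])
    coef, *_ = np.linalg.lstsq(X, series.values, rcond=None)
    return float(coef[0])


# ----------------------------------------------------------------------
# Refinement stage
# ----------------------------------------------------------------------

def refine_fit(series: VertexTimeSeries, ap: ApertureSequence, h: HRFParams,
               init: PRFParams, max_iter: int = 400) -> PRFParams:
    """Nelder-Mead refinement of ``(x0, y0, log sigma)`` minimizing
    ``1 - Pearson r``; never returns a worse correlation than ``init``."""
    z = series.values - series.values.mean()
    nrm = np.linalg.norm(z)
    if nrm == 0:
        raise DegenerateFitError("zero-variance series")
    z = z / nrm
    tr = float(ap.times[1] - ap.times[0]) if len(ap) > 1 else 1.0
    kernel = double_gamma_kernel(h, tr)
    T = len(ap)

    def neg_r(theta: np.ndarray) -> float:
        x0, y0, logs = theta
        drive = _drive(x0, y0, np.exp(logs), ap)
        pred = np.convolve(drive, kernel)[:T]
        pred = pred - pred.mean()
        sd = np.linalg.norm(pred)
        if sd < 1e-30:
            return 1.0
        return 1.0 - float(pred @ z) / sd

    x0 = np.array([init.x0_deg, init.y0_deg, np.log(init.sigma_deg)])
    # explicit initial simplex with degree-scale edges: the default
    # per-coordinate perturbation collapses when a coordinate starts at 0
    simplex = np.vstack([x0, x0 + [0.5, 0, 0], x0 + [0, 0.5, 0],
                         x0 + [0, 0, 0.25]])
    res = optimize.minimize(neg_r, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-10,
                                     "maxiter": max_iter,
                                     "initial_simplex": simplex})
    init_r = 1.0 - neg_r(x0)
    if (not res.success and res.fun > neg_r(x0)) or (1.0 - res.fun) < init_r:
        out = replace(init, r=float(init_r), converged=bool(res.success))
        out.beta = _beta_lsq(out, series, ap, h)
        return out
    p = PRFParams(float(res.x[0]), float(res.x[1]), float(np.exp(res.x[2])),
                  r=float(1.0 - res.fun), converged=bool(res.success))
    p.beta = _beta_lsq(p, series, ap, h)
    return p


def fit_vertex(series: VertexTimeSeries, ap: ApertureSequence, h: HRFParams,
               grid: PRFGrid, n_starts: int = 3, good_r: float = 0.999,
               grid_series: np.ndarray | None = None) -> PRFParams:
    """Grid search plus Nelder-Mead refinement with multi-start.

    The simplex search can fall into a local optimum when the coarse
    lattice winner sits in the wrong basin, so refinement is restarted
    from the next-best lattice points (up to ``n_starts``) unless the
    refined correlation already exceeds ``good_r``.  ``grid_series``
    optionally supplies a (smoothed) series for the lattice stage while
    refinement runs on ``series`` itself.
    """
    r = grid.correlate(series.values if grid_series is None else
                       np.asarray(grid_series, dtype=float))
    order = np.argsort(-r)[:max(1, n_starts)]
    best: PRFParams | None = None
    for j in order:
        x0, y0, sigma = grid.lattice[j]
        init = PRFParams(float(x0), float(y0), float(sigma), r=float(r[j]))
        p = refine_fit(series, ap, h, init)
        if best is None or p.r > best.r:
            best = p
        if best.r >= good_r:
            break
    best.beta = _beta_lsq(best, series, ap, h)
    return best


# ----------------------------------------------------------------------
# Surface smoothing and sheet-level fitting
# ----------------------------------------------------------------------

def smooth_sheet(values: np.ndarray, positions: np.ndarray,
                 fwhm_mm: float) -> np.ndarray:
    """Gaussian smoothing of per-vertex data over 2-D sheet coordinates.

    ``values`` may be (n,) or (n, k); rows with NaN are excluded from the
    kernel support and left NaN.  ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise InvalidArgumentError("fwhm_mm must be >= 0")
    values = np.asarray(values, dtype=float)
    if fwhm_mm == 0:
        return values.copy()
    positions = np.asarray(positions, dtype=float)
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    d2 = ((positions[:, None, 0] - positions[None, :, 0]) ** 2
          + (positions[:, None, 1] - positions[None, :, 1]) ** 2)
    W = np.exp(-d2 / (2.0 * sigma ** 2))
    flat = values if values.ndim > 1 else values[:, None]
    ok = ~np.isnan(flat).any(axis=1)
    out = np.full_like(flat, np.nan)
    Wv = W[:, ok]
    out[ok] = (Wv[ok] @ flat[ok]) / Wv[ok].sum(axis=1, keepdims=True)
    return out if values.ndim > 1 else out[:, 0]


def fit_prf_sheet(series_matrix: np.ndarray, tr_s: float,
                  ap: ApertureSequence, h: HRFParams,
                  positions: np.ndarray,
                  lattice: np.ndarray | None = None,
                  smooth_fwhm_mm: float = 8.3) -> list[PRFParams]:
    """Two-stage pRF fit for a whole sheet.

    The lattice search runs on data smoothed across the sheet
    (default FWHM 8.3 mm); refinement runs on the unsmoothed series.
    ``series_matrix`` is (n_vertices, T).
    """
    series_matrix = np.asarray(series_matrix, dtype=float)
    if lattice is None:
        lattice = default_lattice(ap.field_radius_deg)
    grid = PRFGrid(ap, h, lattice)
    smoothed = smooth_sheet(series_matrix, positions, smooth_fwhm_mm)
    out: list[PRFParams] = []
    for i in range(series_matrix.shape[0]):
        try:
            p = fit_vertex(VertexTimeSeries(series_matrix[i], tr_s), ap, h,
                           grid, grid_series=smoothed[i])
        except DegenerateFitError:
            p = PRFParams(0.0, 0.0, 1.0, r=np.nan, converged=False)
        out.append(p)
    return out
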