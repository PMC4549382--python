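"""Retinotopic mapping stimuli on a discretized visual field.

Three stimulus protocols drive the pRF forward model:

* a rotating **wedge** aperture stepping around the visual field,
* an expanding/contracting **ring** whose width scales logarithmically with
  eccentricity,
* a sparse **photic burst** schedule (single stimulation volume followed by
  a rest block) used for subject-level HRF estimation.

The visual field is rasterized on a square pixel grid spanning
``[-R, +R]^2`` degrees of visual angle with the origin at fixation.  Only
the binary aperture matters to the pRF model; the carrier pattern is not
rendered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidArgumentError

__all__ = [
    "StimulusConfig",
    "ApertureSequence",
    "RunSchedule",
    "STIM",
    "BLANK",
    "make_wedge_apertures",
    "make_ring_apertures",
    "make_burst_schedule",
    "make_mapping_run",
]

#: condition labels used in :class:`RunSchedule`
STIM = "stimulus"
BLANK = "blank"


@dataclass(frozen=True)
class StimulusConfig:
    """Geometry and timing of the mapping stimuli.

    Defaults reproduce a wide-field retinotopy protocol: a 10.40 deg radius
    display, a 17.14 deg wedge stepping 21 times per revolution, and a ring
    whose width scales logarithmically between 0.11 and 4.62 deg over 15
    steps, with one aperture position per 2.376 s volume.
    """

    field_radius_deg: float = 10.40
    wedge_width_deg: float = 17.14
    wedge_vols_per_rev: int = 21
    ring_min_width_deg: float = 0.11
    ring_max_width_deg: float = 4.62
    ring_vols_per_rev: int = 15
    tr_s: float = 2.376
    grid_n: int = 101

    def __post_init__(self) -> None:
        if self.field_radius_deg <= 0:
            raise InvalidArgumentError("field_radius_deg must be > 0")
        if not (0 < self.wedge_width_deg <= 360):
            raise InvalidArgumentError("wedge_width_deg must lie in (0, 360]")
        if not (0 < self.ring_min_width_deg < self.ring_max_width_deg
                <= 2 * self.field_radius_deg):
            raise InvalidArgumentError(
                "ring widths must satisfy 0 < min < max <= field diameter")
        if self.wedge_vols_per_rev < 1 or self.ring_vols_per_rev < 1:
            raise InvalidArgumentError("vols_per_rev must be >= 1")
        if self.grid_n < 16:
            raise InvalidArgumentError("grid_n must be >= 16")

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinate grids (x, y) in degrees."""
        c = np.linspace(-self.field_radius_deg, self.field_radius_deg,
                        self.grid_n)
        return np.meshgrid(c, c, indexing="xy")


@dataclass
class ApertureSequence:
    """Time series of binary visual-field masks, one per acquired volume."""

    masks: np.ndarray        # (T, grid_n, grid_n) uint8 in {0, 1}
    times: np.ndarray        # (T,) volume onsets, seconds
    field_radius_deg: float

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks)
        self.times = np.asarray(self.times, dtype=float)
        if self.masks.shape[0] != self.times.shape[0]:
            raise InvalidArgumentError("masks and times length mismatch")

    def __len__(self) -> int:
        return self.masks.shape[0]

    def concat(self, other: "ApertureSequence") -> "ApertureSequence":
        dt = self.times[-1] + (self.times[1] - self.times[0]) if len(self) > 1 else 0.0
        return ApertureSequence(
            np.concatenate([self.masks, other.masks]),
            np.concatenate([self.times, other.times + dt]),
            self.field_radius_deg,
        )


@dataclass
class RunSchedule:
    """Per-volume condition labels plus run boundaries (start offsets)."""

    labels: np.ndarray                 # (T,) of {STIM, BLANK}
    run_starts: list[int] = field(default_factory=lambda: [0])

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels.tolist()) - {STIM, BLANK}
        if bad:
            raise InvalidArgumentError(f"unknown condition labels: {bad}")

    def __len__(self) -> int:
        return self.labels.shape[0]

    @property
    def stim_onsets(self) -> np.ndarray:
        """Volume indices labeled as stimulation."""
        return np.flatnonzero(self.labels == STIM)


def _disk(cfg: StimulusConfig) -> np.ndarray:
    x, y = cfg.pixel_coords()
    return x * x + y * y <= cfg.field_radius_deg ** 2


def make_wedge_apertures(cfg: StimulusConfig, n_rev: int,
                         direction: str = "ccw") -> ApertureSequence:
    """Rotating-wedge apertures, one mask per volume.

    At volume ``k`` the wedge occupies polar angles
    ``[k*360/vols_per_rev, k*360/vols_per_rev + wedge_width_deg)`` (mod 360),
    measured counter-clockwise from the positive x axis, negated for
    clockwise rotation, clipped to the field disk.
    """
    if n_rev < 1:
        raise InvalidArgumentError("n_rev must be >= 1")
    if direction not in ("cw", "ccw"):
        raise InvalidArgumentError("direction must be 'cw' or 'ccw'")
    x, y = cfg.pixel_coords()
    disk = _disk(cfg)
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    step = 360.0 / cfg.wedge_vols_per_rev
    sign = 1.0 if direction == "ccw" else -1.0
    n_vol = n_rev * cfg.wedge_vols_per_rev
    masks = np.empty((n_vol, cfg.grid_n, cfg.grid_n), dtype=np.uint8)
    for k in range(n_vol):
        start = (sign * k * step) % 360.0
        rel = (theta - start) % 360.0
        masks[k] = (disk & (rel < cfg.wedge_width_deg)).astype(np.uint8)
    times = np.arange(n_vol) * cfg.tr_s
    return ApertureSequence(masks, times, cfg.field_radius_deg)


def ring_widths(cfg: StimulusConfig) -> np.ndarray:
    """Log-spaced ring widths across one expanding revolution (degrees)."""
    return np.geomspace(cfg.ring_min_width_deg, cfg.ring_max_width_deg,
                        cfg.ring_vols_per_rev)


def ring_inner_radii(cfg: StimulusConfig) -> np.ndarray:
    """Inner-edge radii across one expanding revolution.

    Chosen so the ring sweeps from fixation (inner radius 0) to the field
    edge (outer radius = field radius at the last step), advancing on the
    same logarithmic scale as the width progression.
    """
    n = cfg.ring_vols_per_rev
    alpha = np.log(cfg.ring_max_width_deg / cfg.ring_min_width_deg)
    k = np.arange(n) / max(n - 1, 1)
    frac = (np.exp(alpha * k) - 1.0) / (np.exp(alpha) - 1.0)
    return (cfg.field_radius_deg - cfg.ring_max_width_deg) * frac


def make_ring_apertures(cfg: StimulusConfig, n_rev: int,
                        direction: str = "expand") -> ApertureSequence:
    """Expanding/contracting ring apertures with log-scaled width."""
    if n_rev < 1:
        raise InvalidArgumentError("n_rev must be >= 1")
    if direction not in ("expand", "contract"):
        raise InvalidArgumentError("direction must be 'expand' or 'contract'")
    x, y = cfg.pixel_coords()
    r = np.hypot(x, y)
    disk = _disk(cfg)
    widths = ring_widths(cfg)
    inner = ring_inner_radii(cfg)
    one_rev = np.empty((cfg.ring_vols_per_rev, cfg.grid_n, cfg.grid_n),
                       dtype=np.uint8)
    for k in range(cfg.ring_vols_per_rev):
        one_rev[k] = (disk & (r >= inner[k])
                      & (r < inner[k] + widths[k])).astype(np.uint8)
    if direction == "contract":
        one_rev = one_rev[::-1]
    masks = np.concatenate([one_rev] * n_rev, axis=0)
    times = np.arange(masks.shape[0]) * cfg.tr_s
    return ApertureSequence(masks, times, cfg.field_radius_deg)


def make_burst_schedule(n_runs: int, stim_vols: int,
                        rest_vols: int) -> RunSchedule:
    """Photic-burst schedule: per run, ``stim_vols`` stimulation volumes then
    ``rest_vols`` blanks; e.g. 10 runs of 1 + 14 give 150 volumes total."""
    if min(n_runs, stim_vols, rest_vols) < 0:
        raise InvalidArgumentError("counts must be >= 0")
    per_run = [STIM] * stim_vols + [BLANK] * rest_vols
    labels = np.array(per_run * n_runs, dtype=object)
    run_starts = [i * len(per_run) for i in range(n_runs)]
    return RunSchedule(labels, run_starts or [0])


def make_mapping_run(cfg: StimulusConfig, wedge_revs: int, ring_revs: int,
                     blank_vols: int = 24,
                     wedge_direction: str = "ccw",
                     ring_direction: str = "expand",
                     ) -> tuple[ApertureSequence, RunSchedule]:
    """Simultaneous wedge + ring mapping run followed by blank volumes.

    The wedge and ring cycle at independent frequencies but must cover the
    same number of volumes (e.g. 10 wedge revolutions x 21 = 14 ring
    revolutions x 15 = 210); the per-volume aperture is the union of the two
    masks, and ``blank_vols`` all-zero masks are appended.
    """
    n_wedge = wedge_revs * cfg.wedge_vols_per_rev
    n_ring = ring_revs * cfg.ring_vols_per_rev
    if n_wedge != n_ring:
        raise InvalidArgumentError(
            f"wedge ({n_wedge}) and ring ({n_ring}) stimulation lengths differ")
    wedge = make_wedge_apertures(cfg, wedge_revs, wedge_direction)
    ring = make_ring_apertures(cfg, ring_revs, ring_direction)
    union = np.maximum(wedge.masks, ring.masks)
    blanks = np.zeros((blank_vols, cfg.grid_n, cfg.grid_n), dtype=np.uint8)
    masks = np.concatenate([union, blanks], axis=0)
    times = np.arange(masks.shape[0]) * cfg.tr_s
    labels = np.array([STIM] * n_wedge + [BLANK] * blank_vols, dtype=object)
    return (ApertureSequence(masks, times, cfg.field_radius_deg),
            RunSchedule(labels))
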