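"""Ground-truth phantoms for every pipeline stage.

Three generator families provide synthetic inputs with known answers:

* :func:`make_retinotopic_phantom` — a flat cortical sheet carrying
  mirror-reversed polar-angle bands for V1/V2/V3 (dorsal and ventral) plus
  a V3A control band, with eccentricity running along the orthogonal axis
  and pRF size growing linearly with eccentricity.  Paired with
  :func:`simulate_bold` it yields noisy vertex time series whose true pRF
  parameters are known.

* :func:`make_or_phantom` — a tensor volume holding six gently curved,
  C-shaped fiber bundles from an LGN-analogue sphere to cortical target
  blocks, nested medio-laterally (V1 medial, then V2, then V3) and split
  superior/inferior into dorsal and ventral groups.  A CSF-analogue
  ventricle block with a high mean diffusivity lies along the ventral
  route (partial-volume blended into adjacent bundle voxels), and a V3A
  target block receives no bundle.

* :func:`make_labeled_tractogram` — hand-constructed streamlines with
  known termination label sets and planted violations of each rejection
  rule, for exact validation of the segmentation logic.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dwi import ScalarMap, TensorField, Tractogram, world_to_voxel
from .exceptions import InvalidArgumentError
from .prf import HRFParams, PRFGrid
from .retinotopy import (NONE_LABEL, SheetGeometry, VisualAreaLabels,
                         grid_sheet)
from .segmentation import AnatomyModel, StreamlineLabel
from .stimulus import ApertureSequence

__all__ = [
    "RetinotopicPhantomConfig",
    "RetinotopicPhantom",
    "make_retinotopic_phantom",
    "simulate_bold",
    "ORPhantomConfig",
    "ORPhantom",
    "make_or_phantom",
    "seed_bundles",
    "LabeledTractogramConfig",
    "make_labeled_tractogram",
    "resample_fixed_step",
]


# ----------------------------------------------------------------------
# Retinotopic sheet phantom
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class RetinotopicPhantomConfig:
    """Flat-sheet retinotopy phantom.

    Band widths are in sheet rows (the band axis); eccentricity runs along
    the columns.  ``noise_sd`` is the BOLD noise standard deviation as a
    fraction of the (z-scored, hence unit) signal amplitude.
    """

    n_cols: int = 40
    spacing_mm: float = 1.0
    band_rows: tuple[int, int, int, int, int, int] = (9, 9, 16, 9, 9, 8)
    #                 V3v V2v  V1 V2d V3d V3A
    ecc_range_deg: tuple[float, float] = (0.5, 10.0)
    sigma0_deg: float = 0.25
    sigma_slope: float = 0.15
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.band_rows):
            raise InvalidArgumentError("band widths must be > 0")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")

    @property
    def n_rows(self) -> int:
        return int(sum(self.band_rows))


@dataclass
class RetinotopicPhantom:
    """Ground truth for one hemisphere's flat sheet (left visual hemifield)."""

    sheet: SheetGeometry
    x0: np.ndarray            # (n,) pRF centers, deg
    y0: np.ndarray
    sigma: np.ndarray
    polar: np.ndarray         # signed hemifield elevation, deg
    ecc: np.ndarray
    labels: VisualAreaLabels
    config: RetinotopicPhantomConfig


def _band_profile(cfg: RetinotopicPhantomConfig) -> np.ndarray:
    """Signed elevation per row: mirror-reversing across the band stack."""
    e = np.concatenate([[0], np.cumsum(cfg.band_rows)])  # band edges
    # anchor rows and elevations; extremum rows sit on the outer band of
    # each boundary (the band farther from V1)
    anchor_rows = [0, e[1] - 1, e[2] - 1, e[2], e[3] - 1, e[3],
                   e[4], e[5], e[6] - 1]
    anchor_vals = [88.0, 0.0, 90.0, 84.0, -84.0, -90.0, 0.0, -90.0, -20.0]
    rows = np.arange(cfg.n_rows)
    return np.interp(rows, anchor_rows, anchor_vals)


def make_retinotopic_phantom(cfg: RetinotopicPhantomConfig = RetinotopicPhantomConfig()
                             ) -> RetinotopicPhantom:
    """Build the sheet, true pRF parameters and true area labels."""
    n_rows, n_cols = cfg.n_rows, cfg.n_cols
    sheet = grid_sheet(n_rows, n_cols, cfg.spacing_mm)
    theta = _band_profile(cfg)                         # per row, deg
    ecc_cols = np.linspace(*cfg.ecc_range_deg, n_cols)
    theta2 = np.tile(theta[:, None], (1, n_cols))
    ecc2 = np.tile(ecc_cols[None, :], (n_rows, 1))
    # left visual hemifield: x0 <= 0
    x0 = -ecc2 * np.cos(np.radians(theta2))
    y0 = ecc2 * np.sin(np.radians(theta2))
    sigma = cfg.sigma0_deg + cfg.sigma_slope * ecc2

    e = np.concatenate([[0], np.cumsum(cfg.band_rows)])
    names = ["V3v", "V2v", "V1", "V2d", "V3d", "V3A"]
    row_labels = np.full(n_rows, NONE_LABEL, dtype=object)
    for k, name in enumerate(names):
        row_labels[e[k]:e[k + 1]] = name
    lab2 = np.tile(row_labels[:, None], (1, n_cols))
    v1 = lab2 == "V1"
    lab2[v1] = np.where(theta2[v1] < 0, "V1d", "V1v")
    return RetinotopicPhantom(sheet, x0.ravel(), y0.ravel(), sigma.ravel(),
                              theta2.ravel(), ecc2.ravel(),
                              VisualAreaLabels(lab2.ravel()), cfg)


def simulate_bold(phantom: RetinotopicPhantom, ap: ApertureSequence,
                  h: HRFParams, noise_sd: float | None = None,
                  seed: int = 0,
                  vertices: np.ndarray | None = None) -> np.ndarray:
    """Noisy BOLD series for each sheet vertex, (n_vertices, T).

    The noiseless series is the z-scored pRF prediction (unit sd), so the
    added Gaussian noise has sd ``noise_sd`` in units of the signal sd.
    """
    if noise_sd is None:
        noise_sd = phantom.config.noise_sd
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    idx = (np.arange(phantom.x0.size) if vertices is None
           else np.asarray(vertices))
    lattice = np.column_stack([phantom.x0[idx], phantom.y0[idx],
                               phantom.sigma[idx]])
    grid = PRFGrid(ap, h, lattice)
    T = len(ap)
    clean = grid.zpred.T * np.sqrt(T)       # rows: unit-sd predictions
    rng = np.random.default_rng(seed)
    return clean + noise_sd * rng.standard_normal(clean.shape)


# ----------------------------------------------------------------------
# Optic-radiation tensor phantom
# ----------------------------------------------------------------------

BUNDLES = ("V1d", "V1v", "V2d", "V2v", "V3d", "V3v")


@dataclass(frozen=True)
class ORPhantomConfig:
    """Tensor-volume phantom of one optic radiation (right hemisphere).

    Six prolate-tensor bundles run from an LGN-analogue sphere (anterior)
    to posterior cortical target blocks, nested medio-laterally by area
    and split dorsally/ventrally, each bowing superiorly (dorsal) or
    inferiorly (ventral) along a C-shaped course.  Eigenvalues are typical
    literature magnitudes (units mm^2/s).
    """

    shape: tuple[int, int, int] = (40, 50, 40)
    voxel_mm: float = 1.0
    origin: tuple[float, float, float] = (2.0, 0.0, 0.0)
    lgn_center: tuple[float, float, float] = (22.0, 40.0, 20.0)
    seed_radius_mm: float = 6.0
    bundle_radius_mm: tuple[float, float, float] = (2.0, 1.4, 1.4)  # V1, V2, V3
    z_bulge_mm: float = 4.0
    x_bulge_mm: float = 2.0
    bundle_evals: tuple[float, float, float] = (1.7e-3, 0.2e-3, 0.2e-3)
    background_evals: tuple[float, float, float] = (0.8e-3, 0.7e-3, 0.7e-3)
    gm_evals: tuple[float, float, float] = (0.9e-3, 0.8e-3, 0.8e-3)
    csf_evals: tuple[float, float, float] = (3.0e-3, 3.0e-3, 3.0e-3)
    csf_blend: float = 0.35
    csf_blend_dist_mm: float = 2.0
    with_ventricle: bool = True


@dataclass
class ORPhantom:
    """Generated phantom: tensors, maps, masks, labels and anatomy."""

    field: TensorField
    fa_map: ScalarMap
    md_map: ScalarMap
    seed_mask: np.ndarray
    target_labels: np.ndarray          # object volume of area names / "none"
    target_masks: dict[str, np.ndarray]
    target_areas_mm2: dict[str, float]
    bundle_labels: np.ndarray          # object volume: bundle name / "none"
    ventricle_mask: np.ndarray
    anatomy: AnatomyModel
    config: ORPhantomConfig


def _centerline(cfg: ORPhantomConfig, bundle: str,
                n_samples: int = 400) -> np.ndarray:
    area = bundle[:2]                   # V1 | V2 | V3
    dv = bundle[2]                      # d | v
    sx = {"V1": 18.0, "V2": 22.0, "V3": 26.0}[area]
    ex = {"V1": 10.0, "V2": 20.0, "V3": 30.0}[area]
    sz = 23.0 if dv == "d" else 17.0
    ez = 30.0 if dv == "d" else 10.0
    zb = cfg.z_bulge_mm if dv == "d" else -cfg.z_bulge_mm
    t = np.linspace(0.0, 1.0, n_samples)
    x = sx + (ex - sx) * t + cfg.x_bulge_mm * np.sin(np.pi * t)
    y = 40.0 - 32.0 * t
    z = sz + (ez - sz) * t + zb * np.sin(np.pi * t)
    return np.column_stack([x, y, z])


def _block_mask(shape, affine_origin, voxel, xlim, ylim, zlim) -> np.ndarray:
    """Boolean mask of voxels whose centers fall inside a world-space box."""
    ax = [np.arange(shape[i]) * voxel + affine_origin[i] + voxel / 2
          for i in range(3)]
    gx = (ax[0] >= xlim[0]) & (ax[0] < xlim[1])
    gy = (ax[1] >= ylim[0]) & (ax[1] < ylim[1])
    gz = (ax[2] >= zlim[0]) & (ax[2] < zlim[1])
    return gx[:, None, None] & gy[None, :, None] & gz[None, None, :]


#: world-space target blocks (xlim, zlim); all share ylim (3, 8)
_TARGET_BLOCKS = {
    "V1d": ((6.0, 14.0), (27.0, 33.0)),
    "V1v": ((6.0, 14.0), (7.0, 13.0)),
    "V2d": ((18.0, 22.0), (28.0, 32.0)),
    "V2v": ((18.0, 22.0), (8.0, 12.0)),
    "V3d": ((28.0, 32.0), (28.0, 32.0)),
    "V3v": ((28.0, 32.0), (8.0, 12.0)),
    "V3A": ((35.0, 39.0), (28.0, 32.0)),
}
_TARGET_Y = (3.0, 8.0)


def _prolate(tangent: np.ndarray, evals: tuple[float, float, float]) -> np.ndarray:
    l1, l2, _ = evals
    t = tangent / np.linalg.norm(tangent, axis=-1, keepdims=True)
    outer = t[..., :, None] * t[..., None, :]
    return (l1 - l2) * outer + l2 * np.eye(3)


def make_or_phantom(cfg: ORPhantomConfig = ORPhantomConfig()) -> ORPhantom:
    """Rasterize the bundle tubes and assemble the full phantom."""
    from scipy.spatial import cKDTree

    shape = cfg.shape
    h = cfg.voxel_mm
    affine = np.eye(4)
    affine[:3, :3] *= h
    affine[:3, 3] = cfg.origin

    centers = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                                   indexing="ij"), axis=-1).reshape(-1, 3)
    world = (centers + 0.5) * h + np.asarray(cfg.origin)

    radii = dict(zip(("V1", "V2", "V3"), cfg.bundle_radius_mm))
    bundle_lab = np.full(np.prod(shape), NONE_LABEL, dtype=object)
    tangents = np.zeros((np.prod(shape), 3))
    for b in BUNDLES:
        cl = _centerline(cfg, b)
        tree = cKDTree(cl)
        dist, nearest = tree.query(world)
        inside = dist <= radii[b[:2]]
        clash = inside & (bundle_lab != NONE_LABEL)
        if np.any(clash):
            raise InvalidArgumentError(
                f"bundle {b} overlaps {set(bundle_lab[clash])}")
        bundle_lab[inside] = b
        tg = np.gradient(cl, axis=0)
        tangents[inside] = tg[nearest[inside]]

    # base tensors
    D = np.empty((np.prod(shape), 3, 3))
    D[:] = np.diag(cfg.background_evals)
    in_bundle = bundle_lab != NONE_LABEL
    D[in_bundle] = _prolate(tangents[in_bundle], cfg.bundle_evals)

    # cortical targets (gray-matter-like, low FA so tracking terminates)
    target_lab = np.full(np.prod(shape), NONE_LABEL, dtype=object)
    target_masks = {}
    target_areas = {}
    for name, (xlim, zlim) in _TARGET_BLOCKS.items():
        m = _block_mask(shape, cfg.origin, h, xlim, _TARGET_Y, zlim).ravel()
        target_lab[m] = name
        target_masks[name] = m.reshape(shape)
        target_areas[name] = (xlim[1] - xlim[0]) * (zlim[1] - zlim[0])
        D[m] = np.diag(cfg.gm_evals)
        bundle_lab[m] = NONE_LABEL      # cortex supersedes the tube end

    # ventricle (CSF analogue) along the ventral route + medial wall sheet
    vent = np.zeros(shape, dtype=bool)
    wall = np.zeros(shape, dtype=bool)
    if cfg.with_ventricle:
        vent = _block_mask(shape, cfg.origin, h, (10.0, 26.0), (16.0, 32.0),
                           (3.0, 7.0))
        wall = _block_mask(shape, cfg.origin, h, (10.0, 11.0), (16.0, 32.0),
                           (3.0, 7.0))
        D[vent.ravel()] = np.diag(cfg.csf_evals)
        # partial-volume blend: ventral-bundle voxels near CSF take on
        # elevated diffusivity, mimicking periventricular contamination
        from scipy import ndimage
        dist_vox = ndimage.distance_transform_edt(~vent) * h
        ventral = np.isin(bundle_lab, ["V1v", "V2v", "V3v"])
        near = ventral & (dist_vox.ravel() <= cfg.csf_blend_dist_mm)
        w = cfg.csf_blend
        D[near] = (1 - w) * D[near] + w * np.diag(cfg.csf_evals)

    field = TensorField(D.reshape(*shape, 3, 3), affine)
    fa_map = field.fa_map()
    md_map = field.md_map()

    seed_mask = (np.linalg.norm(world - np.asarray(cfg.lgn_center), axis=1)
                 <= cfg.seed_radius_mm).reshape(shape)
    anatomy = AnatomyModel(
        hemisphere="R",
        lgn_centroid=np.asarray(cfg.lgn_center),
        temporal_pole_y=47.0,
        ventricle_wall_mask=wall,
        wall_normal=np.array([1.0, 0.0, 0.0]),
        affine=affine,
    )
    return ORPhantom(field, fa_map, md_map, seed_mask,
                     target_lab.reshape(shape), target_masks, target_areas,
                     bundle_lab.reshape(shape), vent, anatomy, cfg)


def seed_bundles(phantom: ORPhantom, t: Tractogram) -> np.ndarray:
    """Bundle name at each streamline's seed point ('none' outside tubes)."""
    if t.seed_points is None:
        raise InvalidArgumentError("tractogram carries no seed points")
    idx = world_to_voxel(t.seed_points, phantom.field.affine)
    shape = np.array(phantom.field.shape)
    idx = np.clip(idx, 0, shape - 1)
    return phantom.bundle_labels[idx[:, 0], idx[:, 1], idx[:, 2]]


# ----------------------------------------------------------------------
# Labeled tractogram with planted rule violations
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class LabeledTractogramConfig:
    """Construction plan: termination label sets and planted violations.

    ``label_counts`` maps a termination label set (tuple of area names) to
    the number of valid streamlines terminating there; multi-label sets
    must name grid-adjacent target blocks.  ``violation_counts`` maps a
    rejection code to the number of planted violators.
    """

    label_counts: tuple = ((("V1d",), 10), (("V1v",), 8), (("V2d",), 6),
                           (("V2v",), 6), (("V3d",), 4), (("V3v",), 4),
                           (("V1d", "V1v"), 3), (("V1d", "V2d"), 3))
    violation_counts: tuple = (("a", 5), ("b", 5), ("c", 5), ("d", 5))
    jitter_mm: float = 0.5
    step_mm: float = 0.2
    seed: int = 0


# adjacent world-space label blocks for the labeled tractogram:
# x bands per area, z bands for dorsal/ventral, all touching
_LT_XBANDS = {"V1": (5.0, 13.0), "V2": (13.0, 21.0), "V3": (21.0, 29.0),
              "V3A": (29.0, 37.0)}
_LT_ZBANDS = {"d": (22.0, 28.0), "v": (16.0, 22.0)}
_LT_Y = (3.0, 8.0)
_LT_LGN = np.array([20.0, 35.0, 24.0])


def _lt_block(name: str) -> tuple[tuple[float, float], tuple[float, float]]:
    if name == "V3A":
        return _LT_XBANDS["V3A"], _LT_ZBANDS["d"]
    return _LT_XBANDS[name[:2]], _LT_ZBANDS[name[2]]


def _lt_endpoint(labels: tuple[str, ...]) -> np.ndarray:
    """Endpoint inside (or on the shared face of) the requested blocks."""
    boxes = [_lt_block(n) for n in labels]
    ymid = sum(_LT_Y) / 2.0
    if len(labels) == 1:
        (x0, x1), (z0, z1) = boxes[0]
        return np.array([(x0 + x1) / 2, ymid, (z0 + z1) / 2])
    if len(labels) != 2:
        raise InvalidArgumentError("label sets of size > 2 are not constructible")
    (ax, az), (bx, bz) = boxes
    # shared face: identical z-bands -> vertical boundary in x, or identical
    # x-bands -> horizontal boundary in z
    if az == bz and (ax[1] == bx[0] or bx[1] == ax[0]):
        xb = ax[1] if ax[1] == bx[0] else bx[1]
        return np.array([xb, ymid, (az[0] + az[1]) / 2])
    if ax == bx and (az[1] == bz[0] or bz[1] == az[0]):
        zb = az[1] if az[1] == bz[0] else bz[1]
        return np.array([(ax[0] + ax[1]) / 2, ymid, zb])
    raise InvalidArgumentError(f"label blocks {labels} are not adjacent")


def resample_fixed_step(waypoints: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline so consecutive points are exactly ``step`` apart
    (Euclidean), walking the path with sphere-polyline intersections."""
    pts = [np.asarray(waypoints[0], dtype=float)]
    seg = 0
    pos = pts[0]
    wp = np.asarray(waypoints, dtype=float)
    while seg < len(wp) - 1:
        a, b = pos, wp[seg + 1]
        d = b - a
        L = np.linalg.norm(d)
        if L >= step:
            pos = a + d * (step / L)
            pts.append(pos)
        else:
            # advance through vertices until the sphere of radius `step`
            # around the last emitted point intersects a later segment
            carried = seg + 1
            placed = False
            while carried < len(wp) - 1:
                u, v = wp[carried], wp[carried + 1]
                dv = v - u
                # |u + t dv - pos| = step
                aa = dv @ dv
                bb = 2 * dv @ (u - pos)
                cc = (u - pos) @ (u - pos) - step ** 2
                disc = bb * bb - 4 * aa * cc
                if aa > 0 and disc >= 0:
                    t = (-bb + np.sqrt(disc)) / (2 * aa)
                    if 0 <= t <= 1:
                        pos = u + t * dv
                        pts.append(pos)
                        seg = carried
                        placed = True
                        break
                carried += 1
            if not placed:
                break
    return np.array(pts)


def _valid_waypoints(endpoint: np.ndarray, rng: np.random.Generator,
                     jitter: float) -> np.ndarray:
    mid1 = np.array([_LT_LGN[0], 24.0, (_LT_LGN[2] + endpoint[2]) / 2])
    mid2 = np.array([endpoint[0], 14.0, endpoint[2]])
    wp = np.vstack([_LT_LGN, mid1, mid2, endpoint])
    if jitter > 0:
        wp[1:-1] += rng.normal(0.0, jitter, size=(wp.shape[0] - 2, 3))
    return wp


def _violation_waypoints(code: str, rng: np.random.Generator,
                         jitter: float) -> np.ndarray:
    end = _lt_endpoint(("V1d",))
    if code == "a":
        wp = np.vstack([_LT_LGN, [10.0, 25.0, 20.0], [-1.0, 20.0, 20.0],
                        [10.0, 12.0, 22.0], end])
    elif code == "b":
        wp = np.vstack([_LT_LGN, _LT_LGN + [0.0, 0.0, 8.0],
                        [20.0, 20.0, 30.0], [12.0, 10.0, 26.0], end])
    elif code == "c":
        wp = np.vstack([_LT_LGN, [20.0, 38.5, 10.0], [16.0, 20.0, 12.0], end])
    elif code == "d":
        wp = np.vstack([[4.7, 27.5, 14.0], [4.7, 12.5, 14.0]])
    else:
        raise InvalidArgumentError(f"unknown violation code {code!r}")
    if jitter > 0 and code != "d":
        wp[1:-1] += rng.normal(0.0, 0.2 * jitter, size=(wp.shape[0] - 2, 3))
    return wp


def make_labeled_tractogram(cfg: LabeledTractogramConfig = LabeledTractogramConfig()
                            ) -> tuple[Tractogram, list[StreamlineLabel],
                                       np.ndarray, AnatomyModel]:
    """Streamlines with known labels and planted rejections.

    Returns (tractogram, truth labels, area label volume, anatomy model).
    Truth segment assignments follow directly from the planted label sets.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = (40, 40, 40)
    h = 1.0
    affine = np.eye(4)
    affine[:3, 3] = (2.0, 0.0, 0.0)

    label_volume = np.full(shape, NONE_LABEL, dtype=object)
    for area, xlim in _LT_XBANDS.items():
        for dv, zlim in _LT_ZBANDS.items():
            name = "V3A" if area == "V3A" else area + dv
            if area == "V3A" and dv == "v":
                continue
            m = _block_mask(shape, (2.0, 0.0, 0.0), h, xlim, _LT_Y, zlim)
            label_volume[m] = name

    wall = _block_mask(shape, (2.0, 0.0, 0.0), h, (4.0, 5.0), (12.0, 28.0),
                       (8.0, 20.0))
    anatomy = AnatomyModel(hemisphere="R", lgn_centroid=_LT_LGN,
                           temporal_pole_y=36.0, ventricle_wall_mask=wall,
                           wall_normal=np.array([1.0, 0.0, 0.0]),
                           affine=affine)

    streamlines: list[np.ndarray] = []
    truth: list[StreamlineLabel] = []
    dorsal = {"V1d", "V2d", "V3d"}
    ventral = {"V1v", "V2v", "V3v"}
    groups = {"V1": {"V1d", "V1v"}, "V2": {"V2d", "V2v"},
              "V3": {"V3d", "V3v"}}
    for labels, count in cfg.label_counts:
        for _ in range(count):
            wp = _valid_waypoints(_lt_endpoint(tuple(labels)), rng,
                                  cfg.jitter_mm)
            streamlines.append(resample_fixed_step(wp, cfg.step_mm))
            ls = frozenset(labels)
            vf = ("dorsal" if ls <= dorsal else
                  "ventral" if ls <= ventral else "excluded")
            hier = next((g for g, mem in groups.items() if ls <= mem),
                        "excluded")
            truth.append(StreamlineLabel(ls, "none", vf, hier))
    for code, count in cfg.violation_counts:
        for _ in range(count):
            wp = _violation_waypoints(code, rng, cfg.jitter_mm)
            streamlines.append(resample_fixed_step(wp, cfg.step_mm))
            truth.append(StreamlineLabel(frozenset(), code, None, None))

    t = Tractogram(streamlines, affine,
                   seed_points=np.array([s[0] for s in streamlines]),
                   seed_ids=np.arange(len(streamlines)),
                   meta={"seed": cfg.seed})
    return t, truth, label_volume, anatomy
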