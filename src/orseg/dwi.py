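"""Diffusion tensor fitting and seed-to-target streamline tractography.

The tensor is estimated per voxel by weighted log-linear least squares of
``ln S = ln S0 - b g^T D g``; fractional anisotropy (FA) and mean
diffusivity (MD) follow from its eigenvalues.  Tracking propagates
streamlines bidirectionally from seed points in fixed 0.2 mm steps along
directions sampled from an axially symmetric dispersion about the local
principal eigenvector (concentration scaled by local FA), terminating on
low FA, leaving the volume, exceeding the curvature constraint, or
reaching the maximum length.  The curvature constraint is expressed as a
minimum radius of curvature (default 1 mm), giving a maximum turning angle
per step of ``2*asin(step/(2*radius))``.

Coordinate convention: world coordinates are RAS millimetres; the affine
maps a voxel index to the voxel's minimum corner, so the voxel containing
a world point is ``floor(world -> index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .exceptions import InvalidArgumentError

__all__ = [
    "GradientTable",
    "TensorField",
    "ScalarMap",
    "TrackingParams",
    "Tractogram",
    "fit_tensor",
    "fa",
    "md",
    "wm_skeleton",
    "track",
    "retain_target_terminating",
    "world_to_voxel",
    "voxel_center_world",
]


# ----------------------------------------------------------------------
# Containers
# ----------------------------------------------------------------------

@dataclass
class GradientTable:
    """Diffusion gradient scheme: b-values (s/mm^2) and unit directions."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.shape[0], 3):
            raise InvalidArgumentError("bvecs must be (n, 3) matching bvals")
        if not np.any(self.bvals == 0):
            raise InvalidArgumentError("need at least one b=0 entry")
        nz = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[nz], axis=1)
        if np.any(np.abs(norms - 1) > 1e-6):
            raise InvalidArgumentError("nonzero-b directions must be unit length")
        if np.linalg.matrix_rank(_design_matrix(self)[nz, :6]) < 6:
            raise InvalidArgumentError(
                "need >= 6 non-collinear nonzero-b directions")

    @property
    def n(self) -> int:
        return self.bvals.shape[0]


@dataclass
class ScalarMap:
    """Per-voxel scalar on a regular grid (FA dimensionless, MD mm^2/s)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors (mm^2/s) with a voxel->world map."""

    tensors: np.ndarray            # (X, Y, Z, 3, 3)
    affine: np.ndarray             # (4, 4), index -> voxel min corner, mm

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.tensors.ndim != 5 or self.tensors.shape[3:] != (3, 3):
            raise InvalidArgumentError("tensors must be (X, Y, Z, 3, 3)")
        if not np.allclose(self.tensors, np.swapaxes(self.tensors, 3, 4),
                           atol=1e-12):
            raise InvalidArgumentError("tensors must be symmetric")
        self._evals: np.ndarray | None = None
        self._evecs: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (descending) and eigenvectors per voxel (cached)."""
        if self._evals is None:
            w, v = np.linalg.eigh(self.tensors)
            self._evals = w[..., ::-1]
            self._evecs = v[..., ::-1]
        return self._evals, self._evecs

    def principal_direction(self) -> np.ndarray:
        """Unit principal eigenvector field, (X, Y, Z, 3), sign-canonical."""
        _, v = self.eigensystem()
        e1 = v[..., :, 0].copy()
        # canonical sign: largest-magnitude component positive
        flat = e1.reshape(-1, 3)
        lead = np.take_along_axis(flat, np.abs(flat).argmax(axis=1)[:, None],
                                  axis=1)[:, 0]
        flat[lead < 0] *= -1
        return e1

    def fa_map(self) -> ScalarMap:
        w, _ = self.eigensystem()
        return ScalarMap(fa(w[..., 0], w[..., 1], w[..., 2]), self.affine)

    def md_map(self) -> ScalarMap:
        w, _ = self.eigensystem()
        return ScalarMap(md(w[..., 0], w[..., 1], w[..., 2]), self.affine)


@dataclass
class TrackingParams:
    """Probabilistic tracking parameters."""

    step_mm: float = 0.2
    fa_threshold: float = 0.1
    curvature_radius_mm: float = 1.0
    n_streamlines: int = 10_000
    max_length_mm: float = 200.0
    kappa0: float = 40.0        # dispersion concentration per unit FA; inf = deterministic

    def __post_init__(self) -> None:
        if self.step_mm <= 0:
            raise InvalidArgumentError("step_mm must be > 0")
        if not (0 <= self.fa_threshold < 1):
            raise InvalidArgumentError("fa_threshold must lie in [0, 1)")
        if self.n_streamlines < 1:
            raise InvalidArgumentError("n_streamlines must be >= 1")
        if self.curvature_radius_mm <= 0 or self.max_length_mm <= 0:
            raise InvalidArgumentError("lengths must be > 0")

    @property
    def max_angle_rad(self) -> float:
        s = min(1.0, self.step_mm / (2.0 * self.curvature_radius_mm))
        return 2.0 * np.arcsin(s)


@dataclass
class Tractogram:
    """Collection of streamlines (world mm) with provenance."""

    streamlines: list[np.ndarray]
    affine: np.ndarray
    seed_points: np.ndarray | None = None
    seed_ids: np.ndarray | None = None
    meta: dict = dc_field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def subset(self, idx: np.ndarray) -> "Tractogram":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return Tractogram(
            [self.streamlines[i] for i in idx], self.affine,
            None if self.seed_points is None else self.seed_points[idx],
            None if self.seed_ids is None else self.seed_ids[idx],
            dict(self.meta))

    def endpoints(self) -> np.ndarray:
        """(n, 2, 3) first and last point of each streamline."""
        return np.array([[s[0], s[-1]] for s in self.streamlines])


# ----------------------------------------------------------------------
# Coordinate helpers
# ----------------------------------------------------------------------

def world_to_voxel(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Containing voxel indices: floor of the continuous index."""
    inv = np.linalg.inv(affine)
    pts = np.atleast_2d(points)
    idx = pts @ inv[:3, :3].T + inv[:3, 3]
    return np.floor(idx).astype(np.int64).reshape(np.shape(points))


def voxel_center_world(idx: np.ndarray, affine: np.ndarray) -> np.ndarray:
    idx = np.atleast_2d(idx).astype(float) + 0.5
    return (idx @ np.asarray(affine)[:3, :3].T
            + np.asarray(affine)[:3, 3]).reshape(np.shape(idx))


# ----------------------------------------------------------------------
# Tensor fit and derived scalars
# ----------------------------------------------------------------------

def _design_matrix(g: GradientTable) -> np.ndarray:
    b, v = g.bvals, g.bvecs
    return np.column_stack([
        -b * v[:, 0] ** 2, -b * v[:, 1] ** 2, -b * v[:, 2] ** 2,
        -2 * b * v[:, 0] * v[:, 1],
        -2 * b * v[:, 0] * v[:, 2],
        -2 * b * v[:, 1] * v[:, 2],
        np.ones_like(b),
    ])


def fit_tensor(dwi: np.ndarray, g: GradientTable,
               affine: np.ndarray | None = None) -> TensorField:
    """Weighted log-linear least-squares tensor fit.

    ``dwi`` is (X, Y, Z, n) signal; voxels with any non-positive signal are
    masked out (zero tensor).  Weights are the squared signals, the usual
    first-order propagation of log-domain noise.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4 or dwi.shape[3] != g.n:
        raise InvalidArgumentError("dwi must be (X, Y, Z, n) matching the table")
    if affine is None:
        affine = np.eye(4)
    X = _design_matrix(g)                            # (n, 7)
    S = dwi.reshape(-1, g.n)
    ok = np.all(S > 0, axis=1)
    D = np.zeros((S.shape[0], 3, 3))
    if np.any(ok):
        y = np.log(S[ok])                            # (m, n)
        w = S[ok] ** 2                               # (m, n)
        # per-voxel weighted normal equations, batched
        Xw = X[None, :, :] * w[:, :, None]           # (m, n, 7)
        A = np.einsum("mnp,nq->mpq", Xw, X)          # (m, 7, 7)
        rhs = np.einsum("mnp,mn->mp", Xw, y)         # (m, 7)
        beta = np.linalg.solve(A, rhs[:, :, None])[:, :, 0]   # (m, 7)
        dxx, dyy, dzz, dxy, dxz, dyz = beta[:, :6].T
        Dm = np.empty((beta.shape[0], 3, 3))
        Dm[:, 0, 0], Dm[:, 1, 1], Dm[:, 2, 2] = dxx, dyy, dzz
        Dm[:, 0, 1] = Dm[:, 1, 0] = dxy
        Dm[:, 0, 2] = Dm[:, 2, 0] = dxz
        Dm[:, 1, 2] = Dm[:, 2, 1] = dyz
        D[ok] = Dm
    return TensorField(D.reshape(*dwi.shape[:3], 3, 3), np.asarray(affine))


def md(l1, l2, l3):
    """Mean diffusivity (l1 + l2 + l3) / 3."""
    return (np.asarray(l1) + np.asarray(l2) + np.asarray(l3)) / 3.0


def fa(l1, l2, l3):
    """Fractional anisotropy; defined as 0 for the zero tensor."""
    l1, l2, l3 = (np.asarray(x, dtype=float) for x in (l1, l2, l3))
    m = (l1 + l2 + l3) / 3.0
    num = (l1 - m) ** 2 + (l2 - m) ** 2 + (l3 - m) ** 2
    den = l1 ** 2 + l2 ** 2 + l3 ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(1.5) * np.sqrt(num / den)
    return np.where(den > 0, out, 0.0)


def wm_skeleton(fa_map: ScalarMap, threshold: float = 0.7,
                erosion_iters: int = 1) -> np.ndarray:
    """High-FA white-matter skeleton: threshold then 6-connected erosion."""
    if not (0 <= threshold <= 1):
        raise InvalidArgumentError("threshold must lie in [0, 1]")
    mask = np.isfinite(fa_map.data) & (fa_map.data >= threshold)
    if erosion_iters > 0:
        struct = ndimage.generate_binary_structure(3, 1)
        mask = ndimage.binary_erosion(mask, structure=struct,
                                      iterations=erosion_iters)
    return mask


# ----------------------------------------------------------------------
# Tracking
# ----------------------------------------------------------------------

def _normalize_rows(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    n[n == 0] = 1.0
    return v / n


def _half_tracks(cur: np.ndarray, sign: float, e1: np.ndarray,
                 fa_vol: np.ndarray, params: TrackingParams,
                 inv3: np.ndarray, invt: np.ndarray,
                 shape: tuple[int, int, int],
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Propagate one directed half of every streamline in lockstep.

    Returns (points, lengths): points is (n, max_steps + 1, 3) with the
    seed at index 0; lengths counts valid points per streamline.
    """
    n = cur.shape[0]
    max_steps = int(np.floor((params.max_length_mm / 2.0) / params.step_mm))
    pts = np.zeros((n, max_steps + 1, 3))
    pts[:, 0] = cur
    lengths = np.ones(n, dtype=np.int64)

    def vox_of(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.floor(p @ inv3.T + invt).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
        idx_c = np.clip(idx, 0, np.array(shape) - 1)
        return idx_c, inside

    idx, inside = vox_of(cur)
    fa_here = fa_vol[idx[:, 0], idx[:, 1], idx[:, 2]]
    alive = inside & (fa_here >= params.fa_threshold)
    prev_dir = np.zeros((n, 3))
    cos_max = np.cos(params.max_angle_rad)
    finite_kappa = np.isfinite(params.kappa0)

    for t in range(max_steps):
        eta = rng.standard_normal((n, 3)) if finite_kappa else None
        if not np.any(alive):
            continue  # keep consuming rng draws for reproducibility
        v = e1[idx[:, 0], idx[:, 1], idx[:, 2]]
        ref = sign * v if t == 0 else prev_dir
        # sign-align the eigenvector with the direction of travel
        flip = np.sum(v * ref, axis=1) < 0
        v = np.where(flip[:, None], -v, v)
        if finite_kappa:
            kappa = params.kappa0 * np.maximum(
                fa_vol[idx[:, 0], idx[:, 1], idx[:, 2]], 1e-3)
            d = _normalize_rows(kappa[:, None] * v + eta)
            # dispersion is axial: re-align with the travel direction
            flip = np.sum(d * v, axis=1) < 0
            d = np.where(flip[:, None], -d, d)
        else:
            d = v
        if t > 0:
            turning = np.sum(d * prev_dir, axis=1) < cos_max
            alive &= ~turning
        nxt = cur + params.step_mm * d
        idx_n, inside_n = vox_of(nxt)
        stepped = alive & inside_n
        cur = np.where(stepped[:, None], nxt, cur)
        pts[stepped, lengths[stepped]] = nxt[stepped]
        lengths[stepped] += 1
        fa_next = fa_vol[idx_n[:, 0], idx_n[:, 1], idx_n[:, 2]]
        # the sub-threshold terminal point is kept, then the line stops
        alive = stepped & (fa_next >= params.fa_threshold)
        prev_dir = np.where(stepped[:, None], d, prev_dir)
        idx = np.where(stepped[:, None], idx_n, idx)
    return pts, lengths


def track(field: TensorField, fa_map: ScalarMap, seed_roi: np.ndarray,
          params: TrackingParams, seed: int) -> Tractogram:
    """Probabilistic bidirectional tracking from a seed ROI.

    Every streamline starts at a point drawn uniformly from the seed-ROI
    volume; both directed halves are propagated and concatenated.  All
    randomness comes from one Generator seeded with ``seed``; identical
    inputs give bit-identical tractograms.
    """
    seed_roi = np.asarray(seed_roi, dtype=bool)
    if seed_roi.shape != field.shape:
        raise InvalidArgumentError("seed ROI grid mismatch")
    if not np.any(seed_roi):
        raise InvalidArgumentError("empty seed ROI")
    rng = np.random.default_rng(seed)
    n = params.n_streamlines
    vox = np.argwhere(seed_roi)
    pick = vox[rng.integers(0, vox.shape[0], size=n)]
    frac = rng.random((n, 3))
    A = field.affine
    seeds = (pick + frac) @ A[:3, :3].T + A[:3, 3]

    e1 = field.principal_direction()
    inv = np.linalg.inv(A)
    inv3, invt = inv[:3, :3], inv[:3, 3]
    fwd_pts, fwd_len = _half_tracks(seeds, +1.0, e1, fa_map.data, params,
                                    inv3, invt, field.shape, rng)
    bwd_pts, bwd_len = _half_tracks(seeds, -1.0, e1, fa_map.data, params,
                                    inv3, invt, field.shape, rng)
    streamlines = []
    for i in range(n):
        back = bwd_pts[i, 1:bwd_len[i]][::-1]
        fwd = fwd_pts[i, :fwd_len[i]]
        streamlines.append(np.vstack([back, fwd]))
    return Tractogram(streamlines, A, seed_points=seeds,
                      seed_ids=np.arange(n),
                      meta={"seed": seed, "params": params})


def retain_target_terminating(t: Tractogram,
                              target: np.ndarray) -> Tractogram:
    """Keep streamlines with at least one endpoint inside the target mask
    (membership by containing voxel)."""
    target = np.asarray(target, dtype=bool)
    if len(t) == 0:
        return t
    ends = t.endpoints().reshape(-1, 3)
    idx = world_to_voxel(ends, t.affine)
    shape = np.array(target.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    hit = np.zeros(len(inside), dtype=bool)
    ic = np.clip(idx, 0, shape - 1)
    hit[inside] = target[ic[inside, 0], ic[inside, 1], ic[inside, 2]]
    keep = hit.reshape(-1, 2).any(axis=1)
    return t.subset(keep)
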