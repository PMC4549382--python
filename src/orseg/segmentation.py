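"""Streamline rejection heuristics and Boolean tract segmentation.

Anatomically implausible optic-radiation streamlines are rejected by four
geometric rules, applied in fixed precedence a > b > c > d:

a. crossing the midsagittal plane into the contralateral hemisphere;
b. projecting superiorly from the LGN (mean elevation of the initial 5 mm
   above 45 degrees);
c. projecting antero-inferiorly into the temporal pole (any point both
   anterior to the temporal-pole coronal plane and inferior to the LGN);
d. running parallel to the medial wall of the posterior horn of the
   lateral ventricle (at least half of the points within one voxel of the
   wall with the local tangent within 20 degrees of the wall plane).

Surviving streamlines are labeled by the visual areas within a small
radius of their cortical endpoint (the endpoint farther from the LGN) and
segmented with two Boolean AND/NOT schemes: by represented visual field
(dorsal = lower field V1d/V2d/V3d, ventral = upper field V1v/V2v/V3v;
mixed terminations excluded) and by cortical hierarchy (exclusive V1, V2
or V3 projections, dorsal and ventral combined).  Together the two schemes
yield five segments: dorsal, ventral, V1, V2 and V3.  Streamlines reaching
the V3A control region feed a false-positive-rate estimate.

The rule thresholds (5 mm, 45 deg, 50 %, 20 deg, 1 voxel, 2 mm assignment
radius) are package defaults collected in :class:`RejectionConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .dwi import Tractogram, world_to_voxel
from .exceptions import InvalidArgumentError, UndefinedPercentageError
from .retinotopy import AREA_NAMES, DORSAL_AREAS, NONE_LABEL, VENTRAL_AREAS

__all__ = [
    "AnatomyModel",
    "RejectionConfig",
    "StreamlineLabel",
    "apply_rejection_rules",
    "label_termination",
    "label_tractogram",
    "segment_visual_field",
    "segment_hierarchy",
    "classify_tractogram",
    "count_segments",
    "normalize_by_area",
    "false_positive_rate",
    "FIELD_SEGMENTS",
    "HIERARCHY_SEGMENTS",
    "EXCLUDED",
]

FIELD_SEGMENTS = ("dorsal", "ventral")
HIERARCHY_SEGMENTS = ("V1", "V2", "V3")
EXCLUDED = "excluded"

_HIER_GROUPS = {"V1": {"V1d", "V1v"}, "V2": {"V2d", "V2v"},
                "V3": {"V3d", "V3v"}}


@dataclass
class AnatomyModel:
    """Anatomical referents for the rejection rules, world RAS mm."""

    hemisphere: str                     # "L" or "R"
    lgn_centroid: np.ndarray            # (3,)
    temporal_pole_y: float              # coronal plane; anterior = larger y
    ventricle_wall_mask: np.ndarray     # boolean volume on the field grid
    wall_normal: np.ndarray             # unit normal of the wall plane
    affine: np.ndarray                  # voxel -> world, min-corner convention
    midsagittal_x: float = 0.0

    def __post_init__(self) -> None:
        if self.hemisphere not in ("L", "R"):
            raise InvalidArgumentError("hemisphere must be 'L' or 'R'")
        self.lgn_centroid = np.asarray(self.lgn_centroid, dtype=float)
        self.wall_normal = np.asarray(self.wall_normal, dtype=float)
        n = np.linalg.norm(self.wall_normal)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise InvalidArgumentError("wall_normal must be unit length")


@dataclass(frozen=True)
class RejectionConfig:
    """Thresholds for the four rejection rules and endpoint labeling."""

    initial_mm: float = 5.0
    elevation_deg: float = 45.0
    wall_frac: float = 0.5
    parallel_deg: float = 20.0
    wall_dist_vox: float = 1.0
    r_assign_mm: float = 2.0


@dataclass
class StreamlineLabel:
    """Classification record for one streamline."""

    labels: frozenset
    code: str = "none"                      # none | a | b | c | d
    visual_field: str | None = None         # dorsal | ventral | excluded
    hierarchy: str | None = None            # V1 | V2 | V3 | excluded


def _tangents(points: np.ndarray) -> np.ndarray:
    d = np.gradient(points, axis=0)
    n = np.linalg.norm(d, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return d / n


def apply_rejection_rules(t: Tractogram, anat: AnatomyModel,
                          cfg: RejectionConfig = RejectionConfig()
                          ) -> np.ndarray:
    """Per-streamline rejection codes ('none', 'a', 'b', 'c' or 'd')."""
    wall_dist = ndimage.distance_transform_edt(~np.asarray(
        anat.ventricle_wall_mask, dtype=bool))
    shape = np.array(anat.ventricle_wall_mask.shape)
    contra_sign = -1.0 if anat.hemisphere == "R" else 1.0
    codes = np.full(len(t), "none", dtype=object)

    for i, s in enumerate(t.streamlines):
        if s.shape[0] == 0:
            continue
        # (a) contralateral crossing
        if np.any(contra_sign * (s[:, 0] - anat.midsagittal_x) > 0):
            codes[i] = "a"
            continue
        # (b) superior projection from the LGN
        if s.shape[0] >= 2:
            d0 = np.linalg.norm(s[0] - anat.lgn_centroid)
            d1 = np.linalg.norm(s[-1] - anat.lgn_centroid)
            p = s if d0 <= d1 else s[::-1]
            step = float(np.median(np.linalg.norm(np.diff(p, axis=0), axis=1)))
            k = min(p.shape[0] - 1, max(1, int(np.ceil(cfg.initial_mm / step))))
            v = p[k] - p[0]
            nv = np.linalg.norm(v)
            if nv > 0:
                elev = np.degrees(np.arcsin(np.clip(v[2] / nv, -1, 1)))
                if elev > cfg.elevation_deg:
                    codes[i] = "b"
                    continue
        # (c) antero-inferior projection into the temporal pole
        if np.any((s[:, 1] > anat.temporal_pole_y)
                  & (s[:, 2] < anat.lgn_centroid[2])):
            codes[i] = "c"
            continue
        # (d) running parallel to the ventricle medial wall
        idx = world_to_voxel(s, anat.affine)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        ic = np.clip(idx, 0, shape - 1)
        near = np.zeros(s.shape[0], dtype=bool)
        near[inside] = wall_dist[ic[inside, 0], ic[inside, 1],
                                 ic[inside, 2]] <= cfg.wall_dist_vox
        if near.any() and s.shape[0] >= 2:
            tang = _tangents(s)
            off_plane = np.degrees(np.arcsin(
                np.clip(np.abs(tang @ anat.wall_normal), 0, 1)))
            frac = np.mean(near & (off_plane <= cfg.parallel_deg))
            if frac >= cfg.wall_frac:
                codes[i] = "d"
    return codes


def label_termination(s: np.ndarray, label_volume: np.ndarray,
                      affine: np.ndarray, lgn_centroid: np.ndarray,
                      r_assign_mm: float = 2.0) -> frozenset:
    """Area labels within ``r_assign_mm`` of the cortical endpoint.

    The cortical endpoint is the streamline end farther from the LGN;
    membership is tested against labeled-voxel centers, with the containing
    voxel always included.  Returns an empty set if no labeled voxel is in
    range.
    """
    label_volume = np.asarray(label_volume)
    shape = np.array(label_volume.shape)
    d0 = np.linalg.norm(s[0] - np.asarray(lgn_centroid))
    d1 = np.linalg.norm(s[-1] - np.asarray(lgn_centroid))
    end = s[-1] if d1 >= d0 else s[0]
    A = np.asarray(affine)
    inv = np.linalg.inv(A)
    cidx = end @ inv[:3, :3].T + inv[:3, 3]
    vsize = np.linalg.norm(A[:3, :3], axis=0)
    pad = np.ceil(r_assign_mm / vsize).astype(int) + 1
    lo = np.maximum(np.floor(cidx).astype(int) - pad, 0)
    hi = np.minimum(np.floor(cidx).astype(int) + pad + 1, shape)
    out: set = set()
    if np.any(lo >= hi):
        return frozenset()
    sub = label_volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    gx, gy, gz = np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)],
                             indexing="ij")
    centers = (np.stack([gx, gy, gz], axis=-1).reshape(-1, 3) + 0.5
               ) @ A[:3, :3].T + A[:3, 3]
    dist = np.linalg.norm(centers - end, axis=1).reshape(sub.shape)
    within = (dist <= r_assign_mm) & (sub != NONE_LABEL)
    out.update(np.unique(sub[within]).tolist())
    own = np.floor(cidx).astype(int)
    if np.all((own >= 0) & (own < shape)):
        lab = label_volume[own[0], own[1], own[2]]
        if lab != NONE_LABEL:
            out.add(lab)
    bad = out - set(AREA_NAMES)
    if bad:
        raise InvalidArgumentError(f"unknown area labels in volume: {bad}")
    return frozenset(out)


def label_tractogram(t: Tractogram, label_volume: np.ndarray,
                     lgn_centroid: np.ndarray,
                     r_assign_mm: float = 2.0) -> list[frozenset]:
    return [label_termination(s, label_volume, t.affine, lgn_centroid,
                              r_assign_mm) for s in t.streamlines]


def segment_visual_field(label_sets: list[frozenset]) -> np.ndarray:
    """dorsal / ventral / excluded per streamline (AND/NOT Boolean scheme)."""
    out = np.full(len(label_sets), EXCLUDED, dtype=object)
    dorsal, ventral = set(DORSAL_AREAS), set(VENTRAL_AREAS)
    for i, labs in enumerate(label_sets):
        if labs and labs <= dorsal:
            out[i] = "dorsal"
        elif labs and labs <= ventral:
            out[i] = "ventral"
    return out


def segment_hierarchy(label_sets: list[frozenset]) -> np.ndarray:
    """V1 / V2 / V3 / excluded per streamline (exclusive projections)."""
    out = np.full(len(label_sets), EXCLUDED, dtype=object)
    for i, labs in enumerate(label_sets):
        for name, group in _HIER_GROUPS.items():
            if labs and labs <= group:
                out[i] = name
                break
    return out


def classify_tractogram(t: Tractogram, anat: AnatomyModel,
                        label_volume: np.ndarray,
                        cfg: RejectionConfig = RejectionConfig()
                        ) -> pd.DataFrame:
    """Rejection + termination labeling + both segmentation schemes.

    Returns one row per streamline with columns ``code`` (rejection),
    ``labels``, ``visual_field`` and ``hierarchy``; rejected streamlines
    carry no segment assignment (None).
    """
    codes = apply_rejection_rules(t, anat, cfg)
    labels = label_tractogram(t, label_volume, anat.lgn_centroid,
                              cfg.r_assign_mm)
    accepted = codes == "none"
    vf = np.full(len(t), None, dtype=object)
    hi = np.full(len(t), None, dtype=object)
    acc_labels = [labels[i] for i in np.flatnonzero(accepted)]
    vf[accepted] = segment_visual_field(acc_labels)
    hi[accepted] = segment_hierarchy(acc_labels)
    return pd.DataFrame({
        "streamline": np.arange(len(t)),
        "code": codes,
        "labels": labels,
        "visual_field": vf,
        "hierarchy": hi,
    })


def count_segments(assignments: np.ndarray, scheme: str) -> pd.DataFrame:
    """Counts and percentages per segment for one hemisphere.

    Percentages are taken over the scheme's non-excluded streamlines and
    sum to 100.
    """
    segs = {"field": FIELD_SEGMENTS, "hierarchy": HIERARCHY_SEGMENTS}.get(scheme)
    if segs is None:
        raise InvalidArgumentError("scheme must be 'field' or 'hierarchy'")
    assignments = np.asarray(assignments, dtype=object)
    counts = {s: int(np.sum(assignments == s)) for s in segs}
    total = sum(counts.values())
    if total == 0:
        raise UndefinedPercentageError(
            "all streamlines excluded: percentages undefined")
    return pd.DataFrame({
        "segment": list(segs),
        "count": [counts[s] for s in segs],
        "percent": [100.0 * counts[s] / total for s in segs],
    })


def normalize_by_area(counts: dict[str, float],
                      areas: dict[str, float]) -> dict[str, float]:
    """Streamline counts per mm^2 of target surface area."""
    out = {}
    for k, c in counts.items():
        a = areas.get(k)
        if a is None or a <= 0:
            raise InvalidArgumentError(f"area for {k!r} must be > 0")
        out[k] = c / a
    return out


def false_positive_rate(counts: dict[str, float],
                        control: str = "V3A",
                        areas: dict[str, float] | None = None) -> float:
    """Control-region streamline ratio: control / (V1 + V2 + V3).

    With ``areas`` given, the same ratio is formed from area-normalized
    counts (streamlines per mm^2).
    """
    vals = dict(counts)
    if areas is not None:
        vals = normalize_by_area(
            {k: counts[k] for k in list(HIERARCHY_SEGMENTS) + [control]
             if k in counts}, areas)
    denom = sum(vals.get(k, 0.0) for k in HIERARCHY_SEGMENTS)
    if denom <= 0:
        raise InvalidArgumentError("V1+V2+V3 count must be > 0")
    return float(vals.get(control, 0.0)) / denom
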