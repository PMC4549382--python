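"""File I/O for the pipeline's standard formats.

Scalar maps and aperture sequences are written as NIfTI, gradient tables
as FSL-style ``bvals``/``bvecs`` text, tractograms as TrackVis TRK or
MRtrix TCK (world RAS mm), and label/measurement tables as delimited text.

Note on affines: internally the package maps a voxel *index* to the
voxel's minimum corner (so the containing voxel of a world point is the
floor of its continuous index).  NIfTI affines map an index to the voxel
*center*; the half-voxel shift is applied on save and removed on load.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .dwi import GradientTable, ScalarMap, Tractogram
from .exceptions import InvalidArgumentError
from .retinotopy import VisualAreaLabels
from .stimulus import ApertureSequence

__all__ = [
    "save_scalar_map", "load_scalar_map",
    "save_apertures", "load_apertures",
    "save_gradient_table", "load_gradient_table",
    "save_tractogram", "load_tractogram",
    "save_labels", "load_labels",
]


def _corner_to_center(affine: np.ndarray) -> np.ndarray:
    out = np.array(affine, dtype=float)
    out[:3, 3] += out[:3, :3] @ np.full(3, 0.5)
    return out


def _center_to_corner(affine: np.ndarray) -> np.ndarray:
    out = np.array(affine, dtype=float)
    out[:3, 3] -= out[:3, :3] @ np.full(3, 0.5)
    return out


def save_scalar_map(path: str | Path, m: ScalarMap) -> None:
    nib.save(nib.Nifti1Image(m.data.astype(np.float64),
                             _corner_to_center(m.affine)), str(path))


def load_scalar_map(path: str | Path) -> ScalarMap:
    img = nib.load(str(path))
    return ScalarMap(np.asarray(img.dataobj, dtype=float),
                     _center_to_corner(img.affine))


def save_apertures(path: str | Path, ap: ApertureSequence) -> None:
    """Aperture masks as a T x X x Y NIfTI; TR stored in the first zoom."""
    img = nib.Nifti1Image(ap.masks.astype(np.uint8), np.eye(4))
    tr = float(ap.times[1] - ap.times[0]) if len(ap) > 1 else 1.0
    img.header.set_zooms((tr, 1.0, 1.0))
    img.header["descrip"] = f"field_radius_deg={ap.field_radius_deg}".encode()
    nib.save(img, str(path))


def load_apertures(path: str | Path) -> ApertureSequence:
    img = nib.load(str(path))
    masks = np.asarray(img.dataobj, dtype=np.uint8)
    tr = float(img.header.get_zooms()[0])
    desc = bytes(img.header["descrip"]).decode(errors="ignore")
    try:
        radius = float(desc.split("=")[1].rstrip("\x00"))
    except (IndexError, ValueError) as e:
        raise InvalidArgumentError("missing field radius in header") from e
    return ApertureSequence(masks, np.arange(masks.shape[0]) * tr, radius)


def save_gradient_table(prefix: str | Path, g: GradientTable) -> None:
    """FSL convention: one row of b-values, three rows of components."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".bval"), g.bvals[None], fmt="%.6g")
    np.savetxt(prefix.with_suffix(".bvec"), g.bvecs.T, fmt="%.8f")


def load_gradient_table(prefix: str | Path) -> GradientTable:
    prefix = Path(prefix)
    bvals = np.loadtxt(prefix.with_suffix(".bval")).ravel()
    bvecs = np.loadtxt(prefix.with_suffix(".bvec")).T
    return GradientTable(bvals, bvecs)


def save_tractogram(path: str | Path, t: Tractogram,
                    grid_shape: tuple[int, int, int]) -> None:
    """Write TRK or TCK (by extension); streamline points are world RAS mm."""
    path = str(path)
    sl = nib.streamlines.Tractogram(t.streamlines,
                                    affine_to_rasmm=np.eye(4))
    if path.endswith(".trk"):
        header = {
            "voxel_to_rasmm": _corner_to_center(t.affine).astype(np.float32),
            "voxel_sizes": np.linalg.norm(t.affine[:3, :3], axis=0),
            "dimensions": np.asarray(grid_shape, dtype=np.int16),
            "voxel_order": "RAS",
        }
        nib.streamlines.save(sl, path, header=header)
    elif path.endswith(".tck"):
        nib.streamlines.save(sl, path)
    else:
        raise InvalidArgumentError("tractogram path must end in .trk or .tck")


def load_tractogram(path: str | Path,
                    affine: np.ndarray | None = None) -> Tractogram:
    f = nib.streamlines.load(str(path))
    streamlines = [np.asarray(s, dtype=float) for s in f.tractogram.streamlines]
    if affine is None:
        if hasattr(f, "header") and "voxel_to_rasmm" in getattr(f, "header", {}):
            affine = _center_to_corner(np.asarray(f.header["voxel_to_rasmm"],
                                                  dtype=float))
        else:
            affine = np.eye(4)
    return Tractogram(streamlines, np.asarray(affine, dtype=float))


def save_labels(path: str | Path, labels: VisualAreaLabels) -> None:
    pd.DataFrame({"vertex": np.arange(labels.labels.size),
                  "label": labels.labels}).to_csv(path, sep="\t", index=False)


def load_labels(path: str | Path) -> VisualAreaLabels:
    df = pd.read_csv(path, sep="\t")
    return VisualAreaLabels(df["label"].to_numpy(dtype=object))
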