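"""Tract-segment microstructure sampling and within-subject statistics.

Segment microstructure is sampled through *visitation maps*: the per-voxel
count of streamlines traversing each voxel (each streamline increments a
voxel at most once).  Mean FA and MD over the support of a segment's
visitation map summarize that segment's microstructure.  Group comparisons
use classical paired t tests with Bonferroni correction and a two-way
repeated-measures ANOVA (segment x hemisphere, subject as blocking
factor) computed from the explicit sums-of-squares partition; each
within-subject effect is tested against its own effect-by-subject error
stratum.  No sphericity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dwi import ScalarMap, Tractogram, world_to_voxel
from .exceptions import (DegenerateFitError, IncompleteDesignError,
                         InvalidArgumentError)

__all__ = [
    "VisitationMap",
    "visitation_map",
    "segment_mean_scalars",
    "paired_t",
    "bonferroni",
    "rm_anova",
]


@dataclass
class VisitationMap:
    """Per-voxel streamline visit counts for one tract segment."""

    counts: np.ndarray
    affine: np.ndarray

    @property
    def support(self) -> np.ndarray:
        return self.counts >= 1


def visitation_map(streamlines: Tractogram | list[np.ndarray],
                   grid_shape: tuple[int, int, int],
                   affine: np.ndarray | None = None) -> VisitationMap:
    """Count, per voxel, the streamlines that traverse it.

    A voxel is traversed if any streamline point falls inside it; with the
    0.2 mm tracking step far below the voxel size this approximates exact
    segment-voxel intersection.  Duplicate visits by the same streamline
    count once.
    """
    if isinstance(streamlines, Tractogram):
        affine = streamlines.affine if affine is None else affine
        lines = streamlines.streamlines
    else:
        if affine is None:
            raise InvalidArgumentError("affine required with a bare list")
        lines = streamlines
    counts = np.zeros(grid_shape, dtype=np.int64)
    shape = np.array(grid_shape)
    if lines:
        pts = np.concatenate([s for s in lines if len(s)])
        sid = np.concatenate([np.full(len(s), i) for i, s in enumerate(lines)
                              if len(s)])
        idx = world_to_voxel(pts, affine)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        rows = np.column_stack([sid[ok], idx[ok]])
        rows = np.unique(rows, axis=0)
        np.add.at(counts, (rows[:, 1], rows[:, 2], rows[:, 3]), 1)
    return VisitationMap(counts, np.asarray(affine))


def segment_mean_scalars(vmap: VisitationMap, fa_map: ScalarMap,
                         md_map: ScalarMap) -> tuple[float, float]:
    """Unweighted mean FA and MD over the visitation-map support."""
    sup = vmap.support
    if not np.any(sup):
        raise InvalidArgumentError("empty visitation support")
    return float(fa_map.data[sup].mean()), float(md_map.data[sup].mean())


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Classical paired t test on the differences; two-sided p, df = n-1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise InvalidArgumentError("paired samples must be equal-length, n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        raise DegenerateFitError("zero-variance nonzero differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def bonferroni(p: np.ndarray, m: int) -> np.ndarray:
    """Bonferroni-corrected p values, min(1, p*m) elementwise."""
    p = np.asarray(p, dtype=float)
    if m < 1:
        raise InvalidArgumentError("m must be >= 1")
    if np.any((p < 0) | (p > 1)):
        raise InvalidArgumentError("p values must lie in [0, 1]")
    return np.minimum(1.0, p * m)


def rm_anova(table: pd.DataFrame, dv: str,
             within: tuple[str, str] = ("segment", "hemisphere"),
             subject: str = "subject") -> pd.DataFrame:
    """Two-way repeated-measures ANOVA by sums-of-squares partition.

    ``table`` is long-format with one row per (subject, factor-A level,
    factor-B level) cell; the design must be complete and balanced with
    one observation per cell.  Each effect's F uses the matching
    effect-by-subject interaction as its error term.  Returns a DataFrame
    with one row per effect (A, B, A:B) holding SS, df pairs, F and p.
    """
    fa_name, fb_name = within
    need = {subject, fa_name, fb_name, dv}
    if not need <= set(table.columns):
        raise InvalidArgumentError(f"table must have columns {sorted(need)}")
    subs = np.sort(table[subject].unique())
    la = np.sort(table[fa_name].unique())
    lb = np.sort(table[fb_name].unique())
    n, a, b = len(subs), len(la), len(lb)
    if len(table) != n * a * b:
        raise IncompleteDesignError(
            f"expected {n * a * b} rows for a complete design, got {len(table)}")
    piv = table.pivot_table(index=subject, columns=[fa_name, fb_name],
                            values=dv, aggfunc="first")
    if piv.isna().any().any():
        raise IncompleteDesignError("missing cells in the design")
    Y = piv.to_numpy().reshape(n, a, b)

    gm = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_ab = Y.mean(axis=0)
    m_as = Y.mean(axis=2)
    m_bs = Y.mean(axis=1)

    ss_s = a * b * np.sum((m_s - gm) ** 2)
    ss_a = n * b * np.sum((m_a - gm) ** 2)
    ss_b = n * a * np.sum((m_b - gm) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
    ss_as = b * np.sum((m_as - m_a[None, :] - m_s[:, None] + gm) ** 2)
    ss_bs = a * np.sum((m_bs - m_b[None, :] - m_s[:, None] + gm) ** 2)
    ss_tot = np.sum((Y - gm) ** 2)
    ss_abs = ss_tot - (ss_s + ss_a + ss_b + ss_ab + ss_as + ss_bs)

    rows = []
    for name, ss_eff, df_eff, ss_err, df_err in [
        (fa_name, ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        (fb_name, ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        (f"{fa_name}:{fb_name}", ss_ab, (a - 1) * (b - 1),
         ss_abs, (a - 1) * (b - 1) * (n - 1)),
    ]:
        if df_eff == 0 or df_err == 0 or ss_err <= 0:
            F, p = (0.0, 1.0) if ss_eff == 0 else (np.inf, 0.0)
        else:
            F = (ss_eff / df_eff) / (ss_err / df_err)
            p = float(sps.f.sf(F, df_eff, df_err))
        rows.append({"effect": name, "ss": ss_eff, "df_effect": df_eff,
                     "ss_error": ss_err, "df_error": df_err,
                     "F": float(F), "p": p})
    out = pd.DataFrame(rows)
    out.attrs["ss_subject"] = float(ss_s)
    out.attrs["ss_total"] = float(ss_tot)
    return out
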