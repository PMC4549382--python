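"""End-to-end convenience: track, reject, label, segment, summarize.

Glues the module stages together for one hemisphere of the optic-radiation
phantom: seed-to-target tracking, target-terminating retention, rejection
heuristics, termination labeling, both Boolean segmentation schemes,
counts/percentages/area-normalized counts, the V3A false-positive ratio,
and visitation-map FA/MD means per segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dwi import TrackingParams, Tractogram, retain_target_terminating, track
from .retinotopy import AREA_NAMES
from .segmentation import (FIELD_SEGMENTS, HIERARCHY_SEGMENTS,
                           RejectionConfig, classify_tractogram,
                           count_segments, false_positive_rate,
                           normalize_by_area)
from .stats import segment_mean_scalars, visitation_map
from .synthetic import ORPhantom

__all__ = ["ORRunResult", "run_or_pipeline"]


@dataclass
class ORRunResult:
    """Everything one phantom run produces."""

    tractogram: Tractogram            # retained, target-terminating
    classification: pd.DataFrame      # per-streamline codes/labels/segments
    field_counts: pd.DataFrame        # dorsal/ventral counts + percent
    hierarchy_counts: pd.DataFrame    # V1/V2/V3 counts + percent
    area_counts: dict[str, int]       # per single-area termination (+V3A)
    normalized_counts: dict[str, float]
    fp_ratio: float
    fp_ratio_normalized: float
    segment_scalars: dict[str, tuple[float, float]]  # segment -> (FA, MD)
    n_seeded: int = 0
    n_retained: int = 0
    n_rejected: int = 0


def run_or_pipeline(phantom: ORPhantom, params: TrackingParams,
                    seed: int,
                    rejection: RejectionConfig = RejectionConfig()
                    ) -> ORRunResult:
    """Run the whole tractography analysis on an OR phantom."""
    target_union = np.isin(phantom.target_labels, list(AREA_NAMES))
    raw = track(phantom.field, phantom.fa_map, phantom.seed_mask, params,
                seed)
    kept = retain_target_terminating(raw, target_union)
    cls = classify_tractogram(kept, phantom.anatomy, phantom.target_labels,
                              rejection)
    accepted = cls["code"] == "none"

    vf = cls.loc[accepted, "visual_field"].to_numpy(dtype=object)
    hi = cls.loc[accepted, "hierarchy"].to_numpy(dtype=object)
    field_counts = count_segments(vf, "field")
    hierarchy_counts = count_segments(hi, "hierarchy")

    # per-area counts for the control comparison: exclusive terminations
    area_counts: dict[str, int] = {}
    labels = cls.loc[accepted, "labels"]
    for name in ("V1", "V2", "V3"):
        grp = {name + "d", name + "v"}
        area_counts[name] = int(sum(bool(s) and s <= grp for s in labels))
    area_counts["V3A"] = int(sum(s == frozenset({"V3A"}) for s in labels))

    areas = {
        "V1": phantom.target_areas_mm2["V1d"] + phantom.target_areas_mm2["V1v"],
        "V2": phantom.target_areas_mm2["V2d"] + phantom.target_areas_mm2["V2v"],
        "V3": phantom.target_areas_mm2["V3d"] + phantom.target_areas_mm2["V3v"],
        "V3A": phantom.target_areas_mm2["V3A"],
    }
    normalized = normalize_by_area(area_counts, areas)
    fp = false_positive_rate(area_counts)
    fp_norm = false_positive_rate(area_counts, areas=areas)

    seg_scalars: dict[str, tuple[float, float]] = {}
    shape = phantom.field.shape
    for scheme, names in (("visual_field", FIELD_SEGMENTS),
                          ("hierarchy", HIERARCHY_SEGMENTS)):
        col = cls[scheme].to_numpy(dtype=object)
        for s in names:
            idx = np.flatnonzero(accepted.to_numpy() & (col == s))
            if idx.size == 0:
                continue
            vmap = visitation_map(kept.subset(idx), shape)
            seg_scalars[s] = segment_mean_scalars(vmap, phantom.fa_map,
                                                  phantom.md_map)

    return ORRunResult(
        tractogram=kept, classification=cls,
        field_counts=field_counts, hierarchy_counts=hierarchy_counts,
        area_counts=area_counts, normalized_counts=normalized,
        fp_ratio=fp, fp_ratio_normalized=fp_norm,
        segment_scalars=seg_scalars,
        n_seeded=params.n_streamlines, n_retained=len(kept),
        n_rejected=int((cls["code"] != "none").sum()),
    )
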