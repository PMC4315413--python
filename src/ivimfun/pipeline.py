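"""End-to-end analysis of a block-design study: traces, fits, group table.

Per subject and block the three directional images are combined into the
trace signal; each ROI is fitted on its block-averaged signal; a subject's
condition value is the arithmetic mean of its block fits; the group table
then summarizes across subjects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fitting import DSTAR_MAX, B_THRESHOLD, ParameterMaps, fit_maps, fit_roi
from .model import AcquisitionScheme
from .phantom import SyntheticStudy
from .roi import GroupResult, ROISet, build_roi_set, summarize_group

__all__ = [
    "trace_stack",
    "study_roi_set",
    "subject_condition_table",
    "analyze_study",
    "fit_block_maps",
]

_PARAMS = ("f", "D", "Dstar", "fDstar")


def trace_stack(block_data: np.ndarray) -> np.ndarray:
    """Direction-averaged (trace) stack from (rows, cols, dirs, n_b) data.

    Geometric mean over the direction axis, computed in log space; requires
    strictly positive intensities.
    """
    if block_data.ndim != 4:
        raise ValueError("block data must be (rows, cols, dirs, n_b)")
    if np.any(block_data <= 0):
        raise ValueError("directional intensities must be positive")
    return np.exp(np.log(block_data).mean(axis=2))


def study_roi_set(study: SyntheticStudy, t_threshold: float = 5.0,
                  prob_floor: float = 0.5) -> ROISet:
    """Analysis ROIs from the study's activation t-map and tissue maps."""
    return build_roi_set(
        study.t_map, t_threshold, study.gm_prob, study.wm_prob,
        prob_floor=prob_floor,
    )


def subject_condition_table(
    study: SyntheticStudy,
    rois: ROISet | None = None,
    b_threshold: float = B_THRESHOLD,
    dstar_max: float = DSTAR_MAX,
) -> pd.DataFrame:
    """Per-subject, per-condition, per-ROI fitted parameters (storage units).

    Each block is fitted on the ROI-averaged trace signal; a subject's value
    for a condition is the arithmetic mean over that subject's blocks of the
    condition.
    """
    rois = rois or study_roi_set(study)
    scheme = study.spec.scheme
    rows = []
    for s, blocks in enumerate(study.blocks):
        per_block = []
        for block in blocks:
            stack = trace_stack(block.data)
            for roi_name, mask in rois.masks.items():
                res = fit_roi(stack, scheme, mask, b_threshold, dstar_max)
                p = res.params
                per_block.append(
                    dict(subject=s, condition=block.condition, roi=roi_name,
                         f=p.f, D=p.D, Dstar=p.Dstar, fDstar=p.fDstar)
                )
        df = pd.DataFrame(per_block)
        agg = df.groupby(["condition", "roi"], as_index=False)[list(_PARAMS)].mean()
        agg.insert(0, "subject", s)
        rows.append(agg)
    return pd.concat(rows, ignore_index=True)


def analyze_study(
    study: SyntheticStudy,
    t_threshold: float = 5.0,
    prob_floor: float = 0.5,
    direction: str = "increase",
) -> GroupResult:
    """Full group analysis of a study (ROI fits -> group statistics)."""
    rois = study_roi_set(study, t_threshold, prob_floor)
    table = subject_condition_table(study, rois)
    return summarize_group(table, direction=direction)


def fit_block_maps(
    block_data: np.ndarray,
    scheme: AcquisitionScheme,
    mask: np.ndarray,
    b_threshold: float = B_THRESHOLD,
    dstar_max: float = DSTAR_MAX,
) -> ParameterMaps:
    """Voxel-wise parameter maps of one block's trace signal."""
    return fit_maps(trace_stack(block_data), scheme, mask, b_threshold, dstar_max)
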