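"""ROI construction, map averaging/subtraction, and group statistics.

The analysis splits the slice into four regions — gray and white matter in
the activated ("visual") and non-activated ("non-visual") brain — by
thresholding an activation t-map and assigning tissue from probability maps.
Per subject and condition, parameters come from ROI-averaged fits (one per
block, averaged across blocks); the group table reports baseline and
stimulation means ± SD across subjects, the percent variation of the group
means, and one-tailed paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import ParameterMaps
from .perfusion import PerfusionConstants, DEFAULT_CONSTANTS, convert_summary

__all__ = [
    "ROI_NAMES",
    "ROISet",
    "GroupResult",
    "build_roi_set",
    "average_maps",
    "subtraction_map",
    "percent_variation",
    "paired_one_tailed_t",
    "summarize_group",
]

ROI_NAMES = ("visual_gm", "visual_wm", "nonvisual_gm", "nonvisual_wm")

#: Parameters summarized per ROI, in table display units.
_SUMMARY_PARAMS = ("fDstar", "Dstar", "f", "D")
#: Scale from storage units (mm²/s, fraction) to display units
#: (1e-3 mm² s⁻¹, percent).
_DISPLAY_SCALE = {"fDstar": 1e3, "Dstar": 1e3, "f": 100.0, "D": 1e3}


@dataclass
class ROISet:
    """Four pairwise-disjoint analysis masks on the slice grid."""

    masks: dict[str, np.ndarray]
    exclusion: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = set(ROI_NAMES) - set(self.masks)
        if missing:
            raise ValueError(f"missing ROIs: {sorted(missing)}")
        total = None
        for name in ROI_NAMES:
            m = np.asarray(self.masks[name], dtype=bool)
            self.masks[name] = m
            total = m.astype(int) if total is None else total + m.astype(int)
        if np.any(total > 1):
            raise ValueError("ROI masks must be pairwise disjoint")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]


def build_roi_set(
    t_map: np.ndarray,
    t_threshold: float,
    gm_prob: np.ndarray,
    wm_prob: np.ndarray,
    exclusion_mask: np.ndarray | None = None,
    prob_floor: float = 0.5,
) -> ROISet:
    """Split the slice into visual/non-visual gray and white matter.

    The activated ("visual") region is where the t-map reaches the threshold;
    the remainder is non-visual.  Each region is assigned to the tissue with
    the larger probability, provided that probability reaches ``prob_floor``
    (ties or sub-floor voxels are dropped rather than guessed).  Excluded
    voxels (artifact regions) are removed everywhere.
    """
    t_map = np.asarray(t_map, dtype=float)
    gm = np.asarray(gm_prob, dtype=float)
    wm = np.asarray(wm_prob, dtype=float)
    if not (t_map.shape == gm.shape == wm.shape):
        raise ValueError("t-map and probability maps must share one shape")
    keep = np.ones(t_map.shape, dtype=bool)
    if exclusion_mask is not None:
        keep &= ~np.asarray(exclusion_mask, dtype=bool)
    visual = (t_map >= t_threshold) & keep
    nonvisual = ~(t_map >= t_threshold) & keep
    is_gm = (gm > wm) & (gm >= prob_floor)
    is_wm = (wm > gm) & (wm >= prob_floor)
    masks = {
        "visual_gm": visual & is_gm,
        "visual_wm": visual & is_wm,
        "nonvisual_gm": nonvisual & is_gm,
        "nonvisual_wm": nonvisual & is_wm,
    }
    for name, m in masks.items():
        if not m.any():
            raise ValueError(f"ROI {name!r} is empty")
    return ROISet(masks, exclusion=exclusion_mask)


def average_maps(maps: Iterable[ParameterMaps]) -> ParameterMaps:
    """Voxel-wise mean of parameter maps (pixel-wise averaging after fitting).

    A voxel of the average is valid if it is valid in at least one input;
    the mean is taken over the maps in which it is valid.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("need at least one map to average")
    shape = maps[0].shape
    for m in maps[1:]:
        if m.shape != shape:
            raise ValueError("maps must share one shape")
    out = {}
    for name in ("f", "D", "Dstar", "fDstar"):
        stack = np.stack([getattr(m, name) for m in maps])
        count = np.sum(~np.isnan(stack), axis=0)
        with np.errstate(invalid="ignore"):
            out[name] = np.nansum(stack, axis=0) / np.where(count == 0, np.nan, count)
    valid = np.stack([m.valid for m in maps]).any(axis=0)
    for g in out.values():
        g[~valid] = np.nan
    return ParameterMaps(valid=valid, **out)


def subtraction_map(stim_avg: ParameterMaps, base_avg: ParameterMaps) -> ParameterMaps:
    """Stimulation-minus-baseline difference map, valid where both are."""
    if stim_avg.shape != base_avg.shape:
        raise ValueError("maps must share one shape")
    valid = stim_avg.valid & base_avg.valid
    out = {}
    for name in ("f", "D", "Dstar", "fDstar"):
        diff = getattr(stim_avg, name) - getattr(base_avg, name)
        diff[~valid] = np.nan
        out[name] = diff
    return ParameterMaps(valid=valid, **out)


def percent_variation(baseline_mean: float, stimulation_mean: float) -> float:
    """Relative change of the group mean, in percent of baseline."""
    if baseline_mean <= 0:
        raise ValueError("baseline mean must be positive")
    return 100.0 * (stimulation_mean - baseline_mean) / baseline_mean


def paired_one_tailed_t(baseline, stimulation, direction: str = "increase") -> float:
    """One-tailed paired Student t-test on per-subject condition values.

    ``direction='increase'`` tests whether stimulation exceeds baseline;
    ``'decrease'`` the opposite.  Identically zero differences give the
    t -> 0 limit p = 0.5; a nonzero but constant difference (zero variance)
    is degenerate and raises.
    """
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    base = np.asarray(baseline, dtype=float)
    stim = np.asarray(stimulation, dtype=float)
    if base.shape != stim.shape or base.ndim != 1:
        raise ValueError("baseline and stimulation must be equal-length 1-D arrays")
    n = base.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 subjects")
    diff = stim - base
    if np.all(diff == 0):
        return 0.5
    if np.std(diff, ddof=1) == 0:
        raise ValueError("zero variance of paired differences")
    alternative = "greater" if direction == "increase" else "less"
    result = stats.ttest_rel(stim, base, alternative=alternative)
    return float(result.pvalue)


@dataclass
class GroupResult:
    """Group statistics in the printed-table layout.

    ``summary``: one row per (roi, parameter) with across-subject baseline
    and stimulation mean/SD (display units: 1e-3 mm² s⁻¹, f in percent),
    percent variation of the group means, and the one-tailed paired p-value.
    ``tissue_contrast``: per condition and parameter, gray- vs white-matter
    paired p-values within the visual and non-visual regions.
    ``perfusion_summary``: the CBF/CBV twin of ``summary``.
    """

    summary: pd.DataFrame
    tissue_contrast: pd.DataFrame
    perfusion_summary: pd.DataFrame


def _subject_condition_values(
    table: pd.DataFrame, roi: str, parameter: str
) -> tuple[np.ndarray, np.ndarray, list]:
    sub = table[table["roi"] == roi]
    subjects = sorted(sub["subject"].unique())
    base, stim = [], []
    for s in subjects:
        rows = sub[sub["subject"] == s]
        for cond, store in (("baseline", base), ("stimulation", stim)):
            sel = rows[rows["condition"] == cond]
            if sel.empty:
                raise ValueError(
                    f"subject {s!r} has no {cond} value for ROI {roi!r}"
                )
            store.append(float(sel[parameter].iloc[0]))
    return np.asarray(base), np.asarray(stim), subjects


def summarize_group(
    per_subject: pd.DataFrame,
    direction: str = "increase",
    constants: PerfusionConstants = DEFAULT_CONSTANTS,
) -> GroupResult:
    """Group table from per-subject, per-condition, per-ROI parameter values.

    ``per_subject`` is tidy with columns ``subject``, ``condition``
    (baseline/stimulation), ``roi`` and the parameters ``f``, ``D``,
    ``Dstar``, ``fDstar`` in storage units (fractions and mm²/s); one row per
    subject x condition x ROI, values already averaged over a subject's
    blocks.  ``direction`` fixes the tested alternative for every
    condition contrast ('increase' or 'decrease'); ``'observed'`` instead
    tests in the direction of each observed group-mean change, matching the
    convention of reporting one-tailed p-values for decreases as well.
    """
    required = {"subject", "condition", "roi", *_SUMMARY_PARAMS}
    missing = required - set(per_subject.columns)
    if missing:
        raise KeyError(f"per-subject table missing columns: {sorted(missing)}")
    if per_subject["subject"].nunique() < 2:
        raise ValueError("group summary needs at least 2 subjects")

    rows = []
    for roi in ROI_NAMES:
        for param in _SUMMARY_PARAMS:
            base, stim, _ = _subject_condition_values(per_subject, roi, param)
            scale = _DISPLAY_SCALE[param]
            base_d, stim_d = base * scale, stim * scale
            if direction == "observed":
                test_dir = "increase" if stim_d.mean() >= base_d.mean() else "decrease"
            else:
                test_dir = direction
            rows.append(
                dict(
                    roi=roi,
                    parameter=param,
                    baseline_mean=base_d.mean(),
                    baseline_sd=base_d.std(ddof=1),
                    stimulation_mean=stim_d.mean(),
                    stimulation_sd=stim_d.std(ddof=1),
                    variation_pct=percent_variation(base_d.mean(), stim_d.mean()),
                    p_value=paired_one_tailed_t(base_d, stim_d, test_dir),
                )
            )
    summary = pd.DataFrame(rows)

    contrast_rows = []
    for region in ("visual", "nonvisual"):
        for param in _SUMMARY_PARAMS:
            for cond in ("baseline", "stimulation"):
                gm = per_subject[
                    (per_subject["roi"] == f"{region}_gm")
                    & (per_subject["condition"] == cond)
                ].sort_values("subject")[param].to_numpy()
                wm = per_subject[
                    (per_subject["roi"] == f"{region}_wm")
                    & (per_subject["condition"] == cond)
                ].sort_values("subject")[param].to_numpy()
                test_dir = "increase" if gm.mean() >= wm.mean() else "decrease"
                contrast_rows.append(
                    dict(
                        region=region,
                        parameter=param,
                        condition=cond,
                        p_value=paired_one_tailed_t(wm, gm, test_dir),
                    )
                )
    tissue_contrast = pd.DataFrame(contrast_rows)

    perfusion_summary = convert_summary(summary, constants)
    return GroupResult(summary, tissue_contrast, perfusion_summary)
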