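"""Conversion of IVIM parameters to standard perfusion units (CBV, CBF).

For a capillary network of total length L, mean segment length <l> and
MRI-visible water content lambda_H2O, the IVIM quantities map to

    CBV [ml/100ml]     = lambda_H2O * f[%]
    CBF [ml/100ml/min] = 60 * 6 * lambda_H2O * 100 / (L * <l>) * f * D*
                       = (approx. 130) * fD* [1e-3 mm² s⁻¹]

The CBF factor is always derived from the three physical constants, never
hard-coded.  The conversion is a rough estimate: it assumes one capillary
topology for the whole brain, while the real microvascular geometry differs
between tissues and cortical layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "PerfusionConstants",
    "DEFAULT_CONSTANTS",
    "cbv_from_f",
    "cbf_from_fDstar",
    "convert_summary",
]


@dataclass(frozen=True)
class PerfusionConstants:
    """Capillary-topology constants behind the unit conversion.

    lambda_h2o : MRI-visible water content (dimensionless, default 0.78)
    L_total    : total capillary length, mm (default 2)
    l_segment  : mean capillary segment length, mm (default 0.108)
    """

    lambda_h2o: float = 0.78
    L_total: float = 2.0
    l_segment: float = 0.108

    def __post_init__(self) -> None:
        if min(self.lambda_h2o, self.L_total, self.l_segment) <= 0:
            raise ValueError("all perfusion constants must be positive")

    @property
    def cbf_factor(self) -> float:
        """CBF per unit fD* expressed in 1e-3 mm²/s (≈ 130 for the defaults).

        60 converts per-second to per-minute, 6 is the capillary-network
        geometry factor, 100 scales to ml/100ml, and 1e-3 moves fD* from
        mm²/s to the display unit.
        """
        return 60.0 * 6.0 * self.lambda_h2o * 100.0 / (self.L_total * self.l_segment) * 1e-3


DEFAULT_CONSTANTS = PerfusionConstants()


def cbv_from_f(f_percent, constants: PerfusionConstants = DEFAULT_CONSTANTS):
    """Cerebral blood volume [ml/100ml] from the perfusion fraction in percent."""
    if _any_negative(f_percent):
        raise ValueError("perfusion fraction must be non-negative")
    return constants.lambda_h2o * f_percent


def cbf_from_fDstar(fdstar_e3, constants: PerfusionConstants = DEFAULT_CONSTANTS):
    """Cerebral blood flow [ml/100ml/min] from fD* in 1e-3 mm²/s."""
    if _any_negative(fdstar_e3):
        raise ValueError("fD* must be non-negative")
    return constants.cbf_factor * fdstar_e3


def _any_negative(x) -> bool:
    try:
        return bool((pd.Series(x) < 0).any())
    except (TypeError, ValueError):
        return x < 0


#: Columns of a group-summary table that scale under unit conversion.
_SCALED_COLUMNS = ("baseline_mean", "baseline_sd", "stimulation_mean", "stimulation_sd")
#: Columns carried over unchanged (percent variations and p-values are
#: invariant under a linear rescaling of the parameter).
_CARRIED_COLUMNS = ("variation_pct", "p_value")


def convert_summary(
    summary: pd.DataFrame, constants: PerfusionConstants = DEFAULT_CONSTANTS
) -> pd.DataFrame:
    """Convert a group-summary table of IVIM statistics to CBF/CBV rows.

    Expects a tidy table with columns ``roi``, ``parameter`` (containing at
    least ``f`` in percent and ``fDstar`` in 1e-3 mm²/s) and the mean/SD
    columns listed above.  Rows with parameter ``f`` become ``CBV`` rows and
    rows with ``fDstar`` become ``CBF`` rows; means and SDs are scaled by the
    same linear factor (linear maps commute with mean and SD), percent
    variations and p-values carry over unchanged.
    """
    required = {"roi", "parameter", *_SCALED_COLUMNS}
    missing = required - set(summary.columns)
    if missing:
        raise KeyError(f"summary table missing columns: {sorted(missing)}")
    out_rows = []
    for _, row in summary.iterrows():
        if row["parameter"] == "f":
            new_name, factor = "CBV", constants.lambda_h2o
        elif row["parameter"] == "fDstar":
            new_name, factor = "CBF", constants.cbf_factor
        else:
            continue
        new = row.copy()
        new["parameter"] = new_name
        for col in _SCALED_COLUMNS:
            new[col] = row[col] * factor
        for col in _CARRIED_COLUMNS:
            if col in summary.columns:
                new[col] = row[col]
        out_rows.append(new)
    if not out_rows:
        raise KeyError("summary table contains no 'f' or 'fDstar' rows to convert")
    return pd.DataFrame(out_rows).reset_index(drop=True)
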