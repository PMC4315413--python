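"""Segmented two-step IVIM fitting: single curves, voxel maps, ROI averages.

The fit proceeds in two steps, mirroring the classical segmented approach:

1. ``fit_diffusion`` — for b above a threshold (default 200 s/mm²) the
   vascular compartment is essentially fully attenuated, so the log-signal is
   fitted by ordinary least squares with a free intercept.  The slope gives
   the tissue diffusion coefficient D; the intercept gives the tissue
   amplitude (≈ 1 − f), which seeds the second step.
2. ``fit_perfusion`` — with D held fixed, the perfusion fraction f and the
   pseudo-diffusion coefficient D* are fitted over *all* b-values by bounded
   trust-region nonlinear least squares (a Levenberg–Marquardt-class
   algorithm).

The free intercept in step 1 matters: forcing the intercept to 1 would bias
D upward by the perfusion fraction.  Even with it, the residual vascular
signal just above the threshold leaves a small deterministic bias that
scales as exp(-b_threshold·(D*−D)); see the methods note for its magnitude.

A fit is flagged non-physical (``valid=False``) when f sits at a bound,
D* sits at its upper bound, the stage-1 D is non-positive, or the optimizer
did not converge — never by an ad-hoc value cut-off.  A separate
``weakly_identified`` diagnostic is raised when D*/D < 2, where the two
compartments are barely separable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .model import AcquisitionScheme, IVIMParameters, SignalCurve

__all__ = [
    "DSTAR_MAX",
    "B_THRESHOLD",
    "FitResult",
    "ParameterMaps",
    "fit_diffusion",
    "fit_perfusion",
    "fit_ivim",
    "fit_maps",
    "fit_roi",
]

#: Default b-value threshold separating the two fitting stages, s/mm².
B_THRESHOLD: float = 200.0

#: Upper bound for the pseudo-diffusion coefficient, mm²/s.  1/b1 = 0.1 for
#: the default scheme (first nonzero b = 10 s/mm²) is the identifiability
#: limit: beyond it the vascular signal has decayed almost completely before
#: the first diffusion-weighted sample, so larger values carry no signal
#: information and only fit noise.
DSTAR_MAX: float = 0.1

_XTOL = 1e-8
_MAX_NFEV = 500


@dataclass
class FitResult:
    """Outcome of a (partial or full) IVIM fit of one signal curve."""

    params: IVIMParameters
    residual_ss: float
    converged: bool
    n_iterations: int
    tissue_amplitude: float
    valid: bool = True
    weakly_identified: bool = False


@dataclass
class ParameterMaps:
    """Per-voxel fitted parameter grids with a validity mask.

    Invalid voxels (outside the mask, failed or non-physical fits) carry NaN
    in every parameter grid and False in ``valid``.
    """

    f: np.ndarray
    D: np.ndarray
    Dstar: np.ndarray
    fDstar: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        shape = self.f.shape
        for name in ("D", "Dstar", "fDstar", "valid"):
            if getattr(self, name).shape != shape:
                raise ValueError("all parameter grids must share one shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.f.shape


def fit_diffusion(
    curve: SignalCurve, b_threshold: float = B_THRESHOLD
) -> tuple[float, float]:
    """Stage 1: tissue diffusion coefficient from the high-b log-signal.

    Ordinary least squares of ln S(b) on b over b > ``b_threshold`` with a
    free intercept.  Returns ``(D, tissue_amplitude)`` where the amplitude is
    the back-transformed intercept (the mono-exponential extrapolation to
    b=0, ≈ 1 − f for a well-separated IVIM curve).

    Raises
    ------
    ValueError
        If fewer than 3 b-values exceed the threshold.
    """
    b = curve.scheme.b_values
    hi = b > b_threshold
    if hi.sum() < 3:
        raise ValueError(
            f"need >= 3 b-values above threshold {b_threshold}, got {int(hi.sum())}"
        )
    y = np.log(curve.values[hi])
    design = np.column_stack([np.ones(int(hi.sum())), -b[hi]])
    (intercept, D), *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(D), float(np.exp(intercept))


def _perfusion_residuals(x, b, y, D_fixed):
    f, dstar = x
    return f * np.exp(-b * dstar) + (1.0 - f) * np.exp(-b * D_fixed) - y


def _perfusion_jacobian(x, b, y, D_fixed):
    f, dstar = x
    ev = np.exp(-b * dstar)
    return np.column_stack([ev - np.exp(-b * D_fixed), -b * f * ev])


def fit_perfusion(
    curve: SignalCurve,
    D_fixed: float,
    tissue_amplitude: float | None = None,
    dstar_max: float = DSTAR_MAX,
) -> FitResult:
    """Stage 2: fit f and D* over all b with the tissue D held fixed.

    Minimizes sum_b [S(b) − f·e^(−b·D*) − (1−f)·e^(−b·D_fixed)]² subject to
    f in [0, 1] and D* in [D_fixed, dstar_max] (the lower bound keeps the
    compartments ordered and identifiable).  Initialization follows the
    segmented-fit convention: f0 = clip(1 − tissue_amplitude, 0.01, 0.3) and
    D*0 = 10·D_fixed.
    """
    if D_fixed <= 0:
        raise ValueError("D_fixed must be positive")
    b = curve.scheme.b_values
    y = curve.values
    if tissue_amplitude is None:
        # neutral seed when the caller has no stage-1 amplitude
        tissue_amplitude = 0.95
    f0 = float(np.clip(1.0 - tissue_amplitude, 0.01, 0.3))
    dstar0 = min(10.0 * D_fixed, 0.9 * dstar_max)
    dstar0 = max(dstar0, D_fixed * (1.0 + 1e-9))
    result = least_squares(
        _perfusion_residuals,
        x0=[f0, dstar0],
        jac=_perfusion_jacobian,
        bounds=([0.0, D_fixed], [1.0, dstar_max]),
        args=(b, y, D_fixed),
        xtol=_XTOL,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=_MAX_NFEV,
    )
    f_hat, dstar_hat = result.x
    converged = bool(result.status > 0)
    at_bound = (
        f_hat <= 1e-9
        or f_hat >= 1.0 - 1e-9
        or dstar_hat >= dstar_max * (1.0 - 1e-9)
    )
    params = IVIMParameters(f=float(f_hat), D=float(D_fixed), Dstar=float(dstar_hat))
    return FitResult(
        params=params,
        residual_ss=float(np.sum(result.fun**2)),
        converged=converged,
        n_iterations=int(result.nfev),
        tissue_amplitude=float(tissue_amplitude),
        valid=converged and not at_bound,
        weakly_identified=bool(dstar_hat < 2.0 * D_fixed),
    )


def fit_ivim(
    curve: SignalCurve,
    b_threshold: float = B_THRESHOLD,
    dstar_max: float = DSTAR_MAX,
) -> FitResult:
    """Full two-step segmented fit of a normalized signal curve."""
    D, amplitude = fit_diffusion(curve, b_threshold)
    if D <= 0:
        # Flat or rising high-b signal: no measurable diffusion. Fit the
        # perfusion stage against a vanishing D and flag the result.
        res = fit_perfusion(curve, 1e-12, amplitude, dstar_max)
        res.valid = False
        return res
    res = fit_perfusion(curve, D, amplitude, dstar_max)
    return res


def _normalize_stack(stack: np.ndarray, scheme: AcquisitionScheme) -> None:
    if stack.ndim != 3:
        raise ValueError("stack must be 3-D: (rows, cols, n_b)")
    if stack.shape[-1] != scheme.n_b:
        raise ValueError(
            f"stack has {stack.shape[-1]} b-volumes for a {scheme.n_b}-point scheme"
        )
    if scheme.b_values[0] != 0:
        raise ValueError("scheme must include a b=0 volume")


def fit_maps(
    stack: np.ndarray,
    scheme: AcquisitionScheme,
    mask: np.ndarray | None = None,
    b_threshold: float = B_THRESHOLD,
    dstar_max: float = DSTAR_MAX,
) -> ParameterMaps:
    """Voxel-by-voxel two-step fit of a (rows, cols, n_b) image stack.

    Each voxel is normalized by its own b=0 value before fitting, so the
    result is invariant to a global intensity scaling.  Voxels outside the
    mask, with non-positive signal, or with failed/non-physical fits are NaN
    with ``valid=False``; the evaluation order of voxels has no effect.
    """
    _normalize_stack(stack, scheme)
    ny, nx, _ = stack.shape
    if mask is None:
        mask = np.ones((ny, nx), dtype=bool)
    if mask.shape != (ny, nx):
        raise ValueError("mask shape must match the image grid")
    grids = {k: np.full((ny, nx), np.nan) for k in ("f", "D", "Dstar", "fDstar")}
    valid = np.zeros((ny, nx), dtype=bool)
    for iy, ix in zip(*np.nonzero(mask)):
        voxel = stack[iy, ix, :]
        if voxel[0] <= 0 or np.any(voxel <= 0):
            continue
        try:
            res = fit_ivim(
                SignalCurve(scheme, voxel / voxel[0]), b_threshold, dstar_max
            )
        except ValueError:
            continue
        p = res.params
        grids["f"][iy, ix] = p.f
        grids["D"][iy, ix] = p.D
        grids["Dstar"][iy, ix] = p.Dstar
        grids["fDstar"][iy, ix] = p.fDstar
        valid[iy, ix] = res.valid
    for g in grids.values():
        g[~valid] = np.nan
    return ParameterMaps(
        f=grids["f"], D=grids["D"], Dstar=grids["Dstar"],
        fDstar=grids["fDstar"], valid=valid,
    )


def fit_roi(
    stack: np.ndarray,
    scheme: AcquisitionScheme,
    roi_mask: np.ndarray,
    b_threshold: float = B_THRESHOLD,
    dstar_max: float = DSTAR_MAX,
) -> FitResult:
    """ROI-averaged fit: mean signal over the ROI per b-value, then one fit.

    Averaging before fitting avoids any arbitrary cut-off for misfitted
    voxels and lifts the effective SNR by roughly the square root of the ROI
    size.  The averaged curve is normalized by its mean b=0 signal.
    """
    _normalize_stack(stack, scheme)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != stack.shape[:2]:
        raise ValueError("ROI mask shape must match the image grid")
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    mean_signal = stack[roi_mask, :].mean(axis=0)
    if np.any(mean_signal <= 0):
        raise ValueError("ROI-averaged signal must be positive at every b")
    curve = SignalCurve(scheme, mean_signal / mean_signal[0])
    return fit_ivim(curve, b_threshold, dstar_max)
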