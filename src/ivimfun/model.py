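"""Bi-exponential IVIM signal model, acquisition schemes and trace signals.

The intravoxel incoherent motion (IVIM) model treats the diffusion-weighted
MR signal of a voxel as the sum of two compartments: a vascular compartment
in which blood traversing a quasi-random capillary network behaves as a fast
pseudo-diffusion process (pseudo-diffusion coefficient ``D*``), and a tissue
compartment undergoing ordinary thermal diffusion (``D``)::

    S(b) / S0 = f * exp(-b * D*) + (1 - f) * exp(-b * D)

where ``f`` is the perfusion (vascular signal) fraction and ``b`` the
diffusion weighting in s/mm².  The flow-related parameter ``f*D*`` is the
product of the two vascular quantities.

Units
-----
Diffusivities are stored in mm²/s and ``f`` as a fraction throughout the
package; report layers convert to the conventional display units
(10⁻³ mm²·s⁻¹ and percent).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_B_VALUES",
    "IVIMParameters",
    "AcquisitionScheme",
    "SignalCurve",
    "ivim_signal",
    "predict_curve",
    "compute_trace",
    "read_bval",
    "write_bval",
]

#: Default diffusion weightings of the single-slice protocol, s/mm².
DEFAULT_B_VALUES: tuple[float, ...] = (
    0, 10, 20, 40, 80, 110, 140, 170, 200, 300, 400, 500, 600, 700, 800, 900,
)


@dataclass(frozen=True)
class IVIMParameters:
    """IVIM model state.

    Parameters
    ----------
    f : float
        Perfusion fraction, dimensionless, in [0, 1].
    D : float
        Tissue diffusion coefficient, mm²/s, >= 0.
    Dstar : float
        Pseudo-diffusion coefficient of the vascular compartment, mm²/s, >= 0.
    """

    f: float
    D: float
    Dstar: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise ValueError(f"perfusion fraction f={self.f} outside [0, 1]")
        if self.D < 0.0:
            raise ValueError(f"diffusion coefficient D={self.D} is negative")
        if self.Dstar < 0.0:
            raise ValueError(f"pseudo-diffusion Dstar={self.Dstar} is negative")

    @property
    def fDstar(self) -> float:
        """Flow-related parameter f·D*, mm²/s (always derived, never set)."""
        return self.f * self.Dstar


@dataclass(frozen=True)
class AcquisitionScheme:
    """Multi-b-value acquisition: sorted b-values plus gradient directions.

    b-values must be ascending, unique, non-negative and start at 0 (the
    unweighted reference image every normalization relies on).
    """

    b_values: np.ndarray
    n_directions: int = 3

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        object.__setattr__(self, "b_values", b)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("b_values must be a 1-D array with >= 2 entries")
        if b[0] != 0.0:
            raise ValueError("first b-value must be 0")
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b-values must be strictly ascending (no duplicates)")
        if self.n_directions < 1:
            raise ValueError("n_directions must be >= 1")

    @classmethod
    def default(cls) -> "AcquisitionScheme":
        return cls(np.asarray(DEFAULT_B_VALUES, dtype=float), n_directions=3)

    @property
    def n_b(self) -> int:
        return int(self.b_values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AcquisitionScheme):
            return NotImplemented
        return (
            self.n_directions == other.n_directions
            and self.b_values.shape == other.b_values.shape
            and bool(np.all(self.b_values == other.b_values))
        )


@dataclass
class SignalCurve:
    """Relative signal S(b)/S0 sampled on an acquisition scheme."""

    scheme: AcquisitionScheme
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.scheme.n_b,):
            raise ValueError(
                f"curve has {v.shape} values for a {self.scheme.n_b}-point scheme"
            )
        if np.any(v <= 0):
            raise ValueError("signal values must be strictly positive")
        self.values = v

    def normalized(self) -> "SignalCurve":
        """Divide by the b=0 value so the curve starts at exactly 1."""
        return SignalCurve(self.scheme, self.values / self.values[0])


def ivim_signal(params: IVIMParameters, b) -> np.ndarray | float:
    """Evaluate the bi-exponential IVIM signal S(b)/S0.

    Accepts a scalar b or an array of b-values (s/mm²); returns the relative
    signal, which is 1 at b=0 and decays monotonically for positive
    diffusivities.
    """
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr < 0):
        raise ValueError("b-values must be non-negative")
    s = params.f * np.exp(-b_arr * params.Dstar) + (1.0 - params.f) * np.exp(
        -b_arr * params.D
    )
    return float(s) if np.isscalar(b) or b_arr.ndim == 0 else s


def predict_curve(params: IVIMParameters, scheme: AcquisitionScheme) -> SignalCurve:
    """Noiseless forward prediction of the model on a whole scheme."""
    return SignalCurve(scheme, ivim_signal(params, scheme.b_values))


def compute_trace(curves) -> SignalCurve:
    """Trace (direction-averaged) signal from directional acquisitions.

    The trace is the geometric mean of the directional signals at each b,
    i.e. the arithmetic mean of the log-signals.  For mono-exponential
    directional decays with diffusivities d1..dn this yields exactly the
    mono-exponential decay with the arithmetic mean diffusivity, which is the
    standard trace-weighted convention.
    """
    curves = list(curves)
    if len(curves) < 2:
        raise ValueError("trace computation needs at least 2 directional curves")
    scheme = curves[0].scheme
    for c in curves[1:]:
        if c.scheme != scheme:
            raise ValueError("directional curves must share one acquisition scheme")
    logs = np.stack([np.log(c.values) for c in curves])
    return SignalCurve(scheme, np.exp(logs.mean(axis=0)))


def read_bval(path: str | os.PathLike) -> np.ndarray:
    """Read an FSL-dialect bval file (one line, whitespace-separated, s/mm²)."""
    with open(path) as fh:
        content = fh.read()
    return np.asarray([float(tok) for tok in content.split()], dtype=float)


def write_bval(path: str | os.PathLike, b_values) -> None:
    """Write b-values as a single whitespace-separated FSL-dialect line."""
    b = np.asarray(b_values, dtype=float)
    with open(path, "w") as fh:
        fh.write(" ".join(f"{v:g}" for v in b) + "\n")
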