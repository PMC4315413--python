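"""Digital phantom of the block-design visual-stimulation IVIM experiment.

The phantom is a single axial slice containing four tissue regions — an
activated posterior gray-matter ribbon with its underlying white matter, and
non-activated gray/white matter elsewhere — inside a circular head.  Each
synthetic subject draws per-tissue, per-condition IVIM parameters from
truncated normal distributions whose means and SDs default to published
adult gray-/white-matter values under baseline and visual stimulation.  The
study alternates stimulation and baseline blocks (starting with
stimulation); every block renders the three orthogonal directional images at
all b-values with independent Gaussian noise following the measured
b-dependent SNR profile.

The slice contains no CSF compartment: the emulated acquisition suppresses
CSF with an inversion-recovery preparation, and the phantom simply omits it.
Directional signals are isotropic (identical parameters in all directions).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .model import AcquisitionScheme, IVIMParameters, write_bval, read_bval
from .simulation import SNR_AT_B0, SNR_AT_BMAX, experimental_snr_profile

__all__ = [
    "TissueTruth",
    "DEFAULT_TISSUE_TRUTHS",
    "PhantomSpec",
    "Block",
    "SyntheticStudy",
    "make_tissue_phantom",
    "draw_subject_parameters",
    "simulate_study",
    "write_study",
    "read_study",
]

TISSUES = ("visual_gm", "visual_wm", "nonvisual_gm", "nonvisual_wm")
CONDITIONS = ("baseline", "stimulation")

#: Integer labels of the phantom label map (0 = background).
LABEL_CODES = {name: i + 1 for i, name in enumerate(TISSUES)}


@dataclass(frozen=True)
class TissueTruth:
    """Mean IVIM parameters of a tissue/condition plus between-subject SDs."""

    mean: IVIMParameters
    sd_f: float
    sd_D: float
    sd_Dstar: float

    def __post_init__(self) -> None:
        if min(self.sd_f, self.sd_D, self.sd_Dstar) < 0:
            raise ValueError("between-subject SDs must be non-negative")
        if not (0 < self.mean.f < 0.25):
            raise ValueError("tissue mean f must lie in (0, 0.25)")


def _truth(f, f_sd, d, d_sd, ds, ds_sd) -> TissueTruth:
    # arguments in display units: f in percent, diffusivities in 1e-3 mm²/s
    return TissueTruth(
        mean=IVIMParameters(f=f / 100.0, D=d * 1e-3, Dstar=ds * 1e-3),
        sd_f=f_sd / 100.0,
        sd_D=d_sd * 1e-3,
        sd_Dstar=ds_sd * 1e-3,
    )


#: Group means ± across-subject SDs measured in adult gray/white matter of
#: the activated (visual) and non-activated brain, used as generative truth.
DEFAULT_TISSUE_TRUTHS: dict[str, dict[str, TissueTruth]] = {
    "visual_gm": {
        "baseline": _truth(3.55, 0.59, 0.713, 0.017, 17.27, 10.17),
        "stimulation": _truth(5.34, 0.81, 0.711, 0.005, 30.50, 18.35),
    },
    "visual_wm": {
        "baseline": _truth(4.17, 0.98, 0.723, 0.019, 9.58, 4.82),
        "stimulation": _truth(4.69, 0.45, 0.719, 0.017, 13.40, 6.18),
    },
    "nonvisual_gm": {
        "baseline": _truth(4.67, 3.01, 0.724, 0.049, 16.97, 11.29),
        "stimulation": _truth(3.66, 1.27, 0.739, 0.016, 17.91, 9.45),
    },
    "nonvisual_wm": {
        "baseline": _truth(4.54, 1.57, 0.714, 0.049, 15.13, 20.81),
        "stimulation": _truth(4.39, 0.82, 0.713, 0.020, 9.65, 4.54),
    },
}

#: Truncation ranges keeping drawn subject parameters physical and
#: identifiable (D* capped below the fitting identifiability limit).
_TRUNCATION = {
    "f": (1e-3, 0.25),
    "D": (0.1e-3, 3e-3),
    "Dstar": (2e-3, 90e-3),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Full specification of a synthetic study (geometry, truths, noise)."""

    shape: tuple[int, int] = (64, 64)
    brain_radius: float = 28.0
    gm_ribbon_width: float = 7.0
    visual_extent: float = 12.0  # posterior rows forming the activated sector
    n_subjects: int = 8
    blocks_per_condition: int = 5
    scheme: AcquisitionScheme = field(default_factory=AcquisitionScheme.default)
    tissue_truths: dict = field(
        default_factory=lambda: DEFAULT_TISSUE_TRUTHS
    )
    sd_scale: float = 1.0
    snr_b0: float = SNR_AT_B0
    snr_bmax: float = SNR_AT_BMAX
    t_value_active: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.blocks_per_condition < 1:
            raise ValueError("need at least 1 subject and 1 block per condition")
        if self.sd_scale < 0:
            raise ValueError("sd_scale must be non-negative")
        if min(self.snr_b0, self.snr_bmax) <= 0:
            raise ValueError("SNR endpoints must be positive")


@dataclass
class Block:
    """One acquisition block: condition label plus (rows, cols, dirs, n_b) data."""

    condition: str
    data: np.ndarray


@dataclass
class SyntheticStudy:
    """A complete synthetic multi-subject block-design study."""

    spec: PhantomSpec
    label_map: np.ndarray
    t_map: np.ndarray
    gm_prob: np.ndarray
    wm_prob: np.ndarray
    subject_params: list  # per subject: {tissue: {condition: IVIMParameters}}
    blocks: list  # per subject: [Block, ...] alternating, stimulation first

    def tissue_mask(self, tissue: str) -> np.ndarray:
        return self.label_map == LABEL_CODES[tissue]


def make_tissue_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic label map and activation indicator for a spec.

    Geometry: a circular head; the posterior sector (last ``visual_extent``
    rows intersecting the head) is the activated region; within each sector,
    an outer gray-matter ribbon of width ``gm_ribbon_width`` surrounds the
    white-matter core.  Raises if any of the four regions is empty.
    """
    ny, nx = spec.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    head = r <= spec.brain_radius
    if spec.gm_ribbon_width <= 0:
        raise ValueError("gm_ribbon_width must be positive")
    if spec.visual_extent <= 0:
        raise ValueError("visual_extent must be positive")
    gm_shell = head & (r > spec.brain_radius - spec.gm_ribbon_width)
    wm_core = head & ~gm_shell
    posterior_start = cy + spec.brain_radius - spec.visual_extent
    visual = head & (yy >= posterior_start)
    label = np.zeros(spec.shape, dtype=np.int16)
    label[visual & gm_shell] = LABEL_CODES["visual_gm"]
    label[visual & wm_core] = LABEL_CODES["visual_wm"]
    label[~visual & gm_shell] = LABEL_CODES["nonvisual_gm"]
    label[~visual & wm_core] = LABEL_CODES["nonvisual_wm"]
    for name, code in LABEL_CODES.items():
        if not np.any(label == code):
            raise ValueError(f"phantom geometry leaves region {name!r} empty")
    activation = visual
    return label, activation


def _draw_truncated(rng, mean, sd, lo, hi, max_tries=1000):
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(max_tries):
        v = rng.normal(mean, sd)
        if lo < v < hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def draw_subject_parameters(
    spec: PhantomSpec, subject_index: int, rng: np.random.Generator
) -> dict:
    """Per-tissue, per-condition parameters of one subject.

    Each of f, D and D* is drawn independently from a normal distribution
    (mean and SD from the spec's truth table, SDs scaled by ``sd_scale``)
    truncated to physical, identifiable ranges.
    """
    del subject_index  # the caller's rng stream already distinguishes subjects
    out: dict = {}
    for tissue, by_cond in spec.tissue_truths.items():
        out[tissue] = {}
        for cond, truth in by_cond.items():
            f = _draw_truncated(
                rng, truth.mean.f, truth.sd_f * spec.sd_scale, *_TRUNCATION["f"]
            )
            d = _draw_truncated(
                rng, truth.mean.D, truth.sd_D * spec.sd_scale, *_TRUNCATION["D"]
            )
            ds = _draw_truncated(
                rng,
                truth.mean.Dstar,
                truth.sd_Dstar * spec.sd_scale,
                *_TRUNCATION["Dstar"],
            )
            out[tissue][cond] = IVIMParameters(f=f, D=d, Dstar=ds)
    return out


def _block_conditions(blocks_per_condition: int) -> list[str]:
    # alternating, always starting with the stimulus block
    return ["stimulation", "baseline"] * blocks_per_condition


def simulate_study(spec: PhantomSpec) -> SyntheticStudy:
    """Render a fully reproducible synthetic study from its spec.

    Every voxel's three directional signals follow the forward model of its
    tissue's condition parameters (isotropic, hence trace-consistent);
    independent Gaussian noise with sigma = 1/SNR(b) is added per direction,
    block and voxel.  Background voxels hold a small constant intensity.
    """
    label, activation = make_tissue_phantom(spec)
    snr = experimental_snr_profile(spec.scheme, spec.snr_b0, spec.snr_bmax)
    sigma = 1.0 / snr
    ny, nx = spec.shape
    n_b = spec.scheme.n_b
    n_dirs = spec.scheme.n_directions
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects)

    subject_params = []
    subject_blocks = []
    for s in range(spec.n_subjects):
        rng = np.random.default_rng(subject_seeds[s])
        params = draw_subject_parameters(spec, s, rng)
        # clean signal per condition, per voxel (background decays nothing)
        clean = {}
        for cond in CONDITIONS:
            img = np.full((ny, nx, n_b), 0.05)
            for tissue, code in LABEL_CODES.items():
                p = params[tissue][cond]
                curve = p.f * np.exp(-spec.scheme.b_values * p.Dstar) + (
                    1 - p.f
                ) * np.exp(-spec.scheme.b_values * p.D)
                img[label == code] = curve
            clean[cond] = img
        blocks = []
        for cond in _block_conditions(spec.blocks_per_condition):
            noise = rng.normal(0.0, 1.0, size=(ny, nx, n_dirs, n_b)) * sigma
            data = clean[cond][:, :, None, :] + noise
            blocks.append(Block(cond, np.clip(data, 1e-6, None)))
        subject_params.append(params)
        subject_blocks.append(blocks)

    t_map = spec.t_value_active * activation.astype(float)
    gm_prob = np.isin(
        label, [LABEL_CODES["visual_gm"], LABEL_CODES["nonvisual_gm"]]
    ).astype(float)
    wm_prob = np.isin(
        label, [LABEL_CODES["visual_wm"], LABEL_CODES["nonvisual_wm"]]
    ).astype(float)
    return SyntheticStudy(
        spec=spec,
        label_map=label,
        t_map=t_map,
        gm_prob=gm_prob,
        wm_prob=wm_prob,
        subject_params=subject_params,
        blocks=subject_blocks,
    )


def _nifti(data: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine=np.eye(4))


def write_study(study: SyntheticStudy, directory: str | os.PathLike) -> list[str]:
    """Write a study as a NIfTI/bval/CSV file tree; returns written names.

    Layout: one 4D NIfTI per subject and block (rows x cols x directions x
    b-values), shared ``bvals`` file, mask/t-map NIfTIs, a manifest CSV
    listing every file, a CSV of the ground-truth subject parameters, and a
    YAML echo of the scalar spec fields.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"output directory {directory} does not exist")
    spec = study.spec
    written: list[str] = []

    def save(name, img):
        nib.save(_nifti(img), directory / name)
        written.append(name)

    for s, blocks in enumerate(study.blocks):
        for k, block in enumerate(blocks):
            save(f"sub-{s:02d}_block-{k:02d}_{block.condition}.nii", block.data)
    save("label_map.nii", study.label_map)
    save("t_map.nii", study.t_map)
    save("gm_prob.nii", study.gm_prob)
    save("wm_prob.nii", study.wm_prob)
    write_bval(directory / "bvals", spec.scheme.b_values)
    written.append("bvals")

    truth_rows = []
    for s, params in enumerate(study.subject_params):
        for tissue, by_cond in params.items():
            for cond, p in by_cond.items():
                truth_rows.append(
                    dict(subject=s, tissue=tissue, condition=cond,
                         f=p.f, D=p.D, Dstar=p.Dstar)
                )
    pd.DataFrame(truth_rows).to_csv(
        directory / "subject_truth.csv", index=False, float_format="%.17g"
    )
    written.append("subject_truth.csv")

    echo = dict(
        shape=list(spec.shape),
        brain_radius=spec.brain_radius,
        gm_ribbon_width=spec.gm_ribbon_width,
        visual_extent=spec.visual_extent,
        n_subjects=spec.n_subjects,
        blocks_per_condition=spec.blocks_per_condition,
        n_directions=spec.scheme.n_directions,
        sd_scale=spec.sd_scale,
        snr_b0=spec.snr_b0,
        snr_bmax=spec.snr_bmax,
        t_value_active=spec.t_value_active,
        seed=spec.seed,
    )
    with open(directory / "spec.yaml", "w") as fh:
        yaml.safe_dump(echo, fh)
    written.append("spec.yaml")

    manifest = pd.DataFrame({"file": sorted(written + ["manifest.csv"])})
    manifest.to_csv(directory / "manifest.csv", index=False)
    return sorted(written + ["manifest.csv"])


def read_study(directory: str | os.PathLike) -> SyntheticStudy:
    """Round-trip reader for :func:`write_study` output."""
    directory = Path(directory)
    with open(directory / "spec.yaml") as fh:
        echo = yaml.safe_load(fh)
    b_values = read_bval(directory / "bvals")
    spec = PhantomSpec(
        shape=tuple(echo["shape"]),
        brain_radius=echo["brain_radius"],
        gm_ribbon_width=echo["gm_ribbon_width"],
        visual_extent=echo["visual_extent"],
        n_subjects=echo["n_subjects"],
        blocks_per_condition=echo["blocks_per_condition"],
        scheme=AcquisitionScheme(b_values, n_directions=echo["n_directions"]),
        sd_scale=echo["sd_scale"],
        snr_b0=echo["snr_b0"],
        snr_bmax=echo["snr_bmax"],
        t_value_active=echo["t_value_active"],
        seed=echo["seed"],
    )

    def load(name):
        return np.asarray(nib.load(directory / name).dataobj)

    truth = pd.read_csv(directory / "subject_truth.csv", float_precision="round_trip")
    subject_params = []
    for s in range(spec.n_subjects):
        params: dict = {}
        for _, row in truth[truth["subject"] == s].iterrows():
            params.setdefault(row["tissue"], {})[row["condition"]] = IVIMParameters(
                f=row["f"], D=row["D"], Dstar=row["Dstar"]
            )
        subject_params.append(params)

    conditions = _block_conditions(spec.blocks_per_condition)
    blocks = []
    for s in range(spec.n_subjects):
        subject = []
        for k, cond in enumerate(conditions):
            data = load(f"sub-{s:02d}_block-{k:02d}_{cond}.nii")
            subject.append(Block(cond, data))
        blocks.append(subject)

    return SyntheticStudy(
        spec=spec,
        label_map=load("label_map.nii").astype(np.int16),
        t_map=load("t_map.nii"),
        gm_prob=load("gm_prob.nii"),
        wm_prob=load("wm_prob.nii"),
        subject_params=subject_params,
        blocks=blocks,
    )
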