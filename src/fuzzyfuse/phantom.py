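"""Synthetic multimodal brain-like phantoms with known ground truth.

Every downstream stage (clustering, fusion, decision, classification) is
validated on phantoms generated here, so no external image database is
needed.  The geometry is a nested set of concentric regions — a CSF core,
a GM ring and a WM exterior — anatomically evocative and trivially
parameterised.  Partial-volume voxels arise from linear mixing across a
boundary band; a smooth additive bias field emulates scanner intensity
inhomogeneity; additive white Gaussian noise is injected at a stated
fraction of the intensity dynamic range.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .volume import ImageVolume, save_nifti

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "OneClassDataset",
    "generate_phantom",
    "generate_oneclass",
    "TISSUES",
]

#: canonical tissue order; fixes integer label ids everywhere downstream
TISSUES = ("CSF", "GM", "WM")

# T1-like anatomical contrast: CSF dark, WM bright.
DEFAULT_MEANS_ANAT = (0.10, 0.50, 0.90)
# FDG-PET-like functional contrast: GM metabolically bright, CSF dark.
DEFAULT_MEANS_FUNC = (0.05, 0.90, 0.40)


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of one synthetic image pair.

    ``snr_noise`` is the additive Gaussian noise standard deviation as a
    fraction of the intensity dynamic range (the paper-style "SNR x%"
    levels span 0.01–0.20); ``bias_amplitude`` scales a smooth additive
    intensity-inhomogeneity field the same way (0.20 emulates 20% RF
    non-uniformity).
    """

    shape: tuple[int, ...] = (64, 64)
    n_tissues: int = 3
    tissue_means_anat: tuple[float, ...] = DEFAULT_MEANS_ANAT
    tissue_means_func: tuple[float, ...] = DEFAULT_MEANS_FUNC
    pv_width: float = 2.0
    bias_amplitude: float = 0.20
    snr_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) not in (2, 3):
            raise ValueError("phantom shape must be 2D or 3D")
        if min(self.shape) < 4 * self.n_tissues:
            raise ValueError(
                f"shape {self.shape} too small to host {self.n_tissues} "
                "nested regions"
            )
        if self.n_tissues != len(self.tissue_means_anat) or \
                self.n_tissues != len(self.tissue_means_func):
            raise ValueError("one mean per tissue per modality required")
        for means in (self.tissue_means_anat, self.tissue_means_func):
            if len(set(means)) != len(means):
                raise ValueError("tissue means must be distinct per modality")
            if not all(0.0 <= m <= 1.0 for m in means):
                raise ValueError("tissue means must lie in [0, 1]")
        if not 0.0 <= self.snr_noise < 1.0:
            raise ValueError("snr_noise must lie in [0, 1)")
        if self.pv_width < 0:
            raise ValueError("pv_width must be non-negative")
        if self.bias_amplitude < 0:
            raise ValueError("bias_amplitude must be non-negative")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclasses.dataclass
class PhantomSample:
    """Generated image pair plus ground truth."""

    anat: ImageVolume
    func: ImageVolume
    truth_labels: np.ndarray          # integer tissue id per voxel
    truth_fractions: np.ndarray       # (n_tissues, *shape) mixing fractions
    bias_field: np.ndarray            # the additive inhomogeneity field
    spec: PhantomSpec

    def pure_mask(self, tissue: int, tol: float = 1e-12) -> np.ndarray:
        """Voxels entirely composed of one tissue."""
        return self.truth_fractions[tissue] >= 1.0 - tol

    def save(self, outdir: str | Path) -> None:
        """Write NIfTI volumes plus a JSON sidecar with the spec."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_nifti(self.anat, outdir / "anat.nii")
        save_nifti(self.func, outdir / "func.nii")
        save_nifti(self.truth_labels.astype(float), outdir / "truth_labels.nii")
        save_nifti(np.moveaxis(self.truth_fractions, 0, -1),
                   outdir / "truth_fractions.nii")
        (outdir / "spec.json").write_text(self.spec.to_json() + "\n")


@dataclasses.dataclass
class OneClassDataset:
    """Feature-vector fixture for one-class classification."""

    target: np.ndarray        # (n_target, dim)
    outliers: np.ndarray      # (n_outlier, dim)

    @property
    def labels(self) -> np.ndarray:
        """+1 for target vectors, -1 for outliers, in stacked order."""
        return np.concatenate([
            np.ones(len(self.target), dtype=int),
            -np.ones(len(self.outliers), dtype=int),
        ])

    @property
    def X(self) -> np.ndarray:
        return np.vstack([self.target, self.outliers]) if len(self.outliers) \
            else self.target.copy()


def _radial_distance(shape: tuple[int, ...]) -> np.ndarray:
    """Distance of each voxel centre from the grid centre, normalised so
    the shortest half-axis has length 1."""
    axes = [np.arange(s, dtype=float) - (s - 1) / 2.0 for s in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    half = (min(shape) - 1) / 2.0
    return np.sqrt(sum(g ** 2 for g in grids)) / half


def _ramp(signed_dist: np.ndarray, width: float) -> np.ndarray:
    """Linear 0→1 transition of the given width centred on the boundary;
    a hard step when width is zero."""
    if width <= 0:
        return (signed_dist >= 0).astype(float)
    return np.clip(signed_dist / width + 0.5, 0.0, 1.0)


def tissue_fractions(spec: PhantomSpec) -> np.ndarray:
    """Ground-truth mixing fractions, shape (n_tissues, *spec.shape).

    Nested-sphere geometry: tissue 0 occupies the core, the last tissue
    the exterior, with linear partial-volume bands of ``pv_width`` voxels
    at each interface.
    """
    rho = _radial_distance(spec.shape)
    half = (min(spec.shape) - 1) / 2.0
    width = spec.pv_width / half                    # band width in rho units
    # interface radii evenly spaced inside the unit ball
    radii = [(i + 1) / (spec.n_tissues) for i in range(spec.n_tissues - 1)]

    # cumulative "inside interface i" memberships, forced nested even when
    # wide partial-volume bands overlap
    inside = np.stack([_ramp(r - rho, width) for r in radii])
    inside = np.maximum.accumulate(inside, axis=0)

    fractions = np.empty((spec.n_tissues,) + spec.shape)
    fractions[0] = inside[0]
    for i in range(1, spec.n_tissues - 1):
        fractions[i] = inside[i] - inside[i - 1]
    fractions[-1] = 1.0 - inside[-1]
    return fractions


def bias_field(spec: PhantomSpec) -> np.ndarray:
    """Smooth additive inhomogeneity surrogate: a low-order polynomial
    ramp across the grid, scaled so max|field| = bias_amplitude x
    dynamic range of the anatomical tissue means.

    A tilted plane is deliberately chosen over a radial profile: the
    phantom's anatomy is concentric, so an affine field is the smooth
    inhomogeneity that remains identifiable from the anatomy itself.
    """
    if spec.bias_amplitude == 0:
        return np.zeros(spec.shape)
    axes = [np.linspace(-1, 1, s) for s in spec.shape]
    grids = np.meshgrid(*axes, indexing="ij")
    # diagonal ramp with unequal axis weights so no axis is degenerate
    weights = [1.0 / (1 + i) for i in range(len(spec.shape))]
    ramp = sum(w * g for w, g in zip(weights, grids))
    dyn = max(spec.tissue_means_anat) - min(spec.tissue_means_anat)
    return spec.bias_amplitude * dyn * ramp / np.abs(ramp).max()


def noiseless_image(spec: PhantomSpec, modality: str) -> np.ndarray:
    """Partial-volume mixed intensities with no bias and no noise."""
    means = spec.tissue_means_anat if modality == "anatomical" \
        else spec.tissue_means_func
    frac = tissue_fractions(spec)
    return np.tensordot(np.asarray(means), frac, axes=(0, 0))


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate one co-registered anatomical/functional pair.

    Deterministic for a fixed ``spec.seed``; the two modalities receive
    independent noise draws but share geometry, ground truth and the
    bias field (applied to the anatomical image only, where the
    bias-corrected clustering stage is expected to remove it).
    """
    frac = tissue_fractions(spec)
    labels = np.argmax(frac, axis=0)
    bias = bias_field(spec)
    rng = np.random.default_rng(spec.seed)

    volumes = {}
    for modality in ("anatomical", "functional"):
        means = spec.tissue_means_anat if modality == "anatomical" \
            else spec.tissue_means_func
        clean = np.tensordot(np.asarray(means), frac, axes=(0, 0))
        img = clean + (bias if modality == "anatomical" else 0.0)
        dyn = max(means) - min(means)
        if spec.snr_noise > 0:
            img = img + rng.normal(0.0, spec.snr_noise * dyn, size=spec.shape)
        volumes[modality] = ImageVolume(data=img, modality=modality)

    return PhantomSample(
        anat=volumes["anatomical"],
        func=volumes["functional"],
        truth_labels=labels,
        truth_fractions=frac,
        bias_field=bias,
        spec=spec,
    )


def generate_oneclass(n_target: int, n_outlier: int, dim: int,
                      separation: float, seed: int = 0,
                      blob_std: float = 1.0) -> OneClassDataset:
    """Gaussian target blob plus outliers displaced by ``separation``.

    The target class is an isotropic Gaussian with standard deviation
    ``blob_std``; outliers are drawn from an identical Gaussian whose
    mean is shifted by ``separation`` along the first feature axis.
    """
    if n_target < 1:
        raise ValueError("need at least one target vector")
    if n_outlier < 0:
        raise ValueError("n_outlier must be non-negative")
    if dim < 1:
        raise ValueError("dim must be at least 1")
    rng = np.random.default_rng(seed)
    target = rng.normal(0.0, blob_std, size=(n_target, dim))
    shift = np.zeros(dim)
    shift[0] = separation
    outliers = rng.normal(0.0, blob_std, size=(max(n_outlier, 0), dim)) + shift
    return OneClassDataset(target=target, outliers=outliers)
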