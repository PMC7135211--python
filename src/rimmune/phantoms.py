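"""Synthetic tumor phantoms with a controllable rim/margin phenotype.

The generator emulates, at desk scale, the kind of CT volumes the
radiomic catalog is designed for: one quasi-ellipsoidal lesion embedded
in a parenchyma-like background, with

* a core whose intensity carries a spatially correlated, optionally
  skew-warped texture field,
* a peritumoral rim (bright ring) whose contrast against the core can be
  coupled to a latent per-sample immune activity (``th2_level``), and
* a sigmoid intensity ramp of controllable width at the outer margin,
  whose sharpness is likewise coupled to the latent state.

The background mean equals the core mean, so the step seen by an
outward margin profile equals the rim-core contrast.  Everything is
driven by a single integer seed; identical (config, state) pairs give
bit-identical volumes.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from rimmune.volume import VolumeROI

__all__ = [
    "PhantomConfig",
    "LatentImmuneState",
    "draw_latent_states",
    "generate_phantom",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Generative parameters for a phantom cohort.

    ``coupling_beta`` is the effect size linking the latent ``th2_level``
    to the image phenotype: the rim-core contrast shifts by
    ``coupling_beta`` HU per latent unit, and the margin width shrinks by
    the factor ``exp(-0.01 * coupling_beta * th2_level)``, bounded to [1/2, 2].
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radius_mm: float = 8.0
    core_mean_hu: float = 20.0
    rim_mean_hu: float = 60.0
    noise_sd_hu: float = 15.0
    texture_corr_len_mm: float = 2.0
    margin_width_mm: float = 1.0
    histogram_skew_param: float = 0.0
    coupling_beta: float = 0.0
    n_samples: int = 60
    seed: int = 0
    # rim ring thickness and the width of its inner (rim-to-core) ramp
    rim_thickness_mm: float = 3.25
    rim_inner_width_mm: float = 0.25
    # relative axis-length jitter of the quasi-ellipsoid
    axis_jitter: float = 0.10

    def __post_init__(self) -> None:
        for name in (
            "tumor_radius_mm",
            "texture_corr_len_mm",
            "margin_width_mm",
            "rim_thickness_mm",
            "rim_inner_width_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")
        if len(self.grid_shape) != 3 or any(int(n) < 4 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be three axes of >= 4 voxels, got {self.grid_shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        # the tumor plus twice the margin must fit inside the grid
        need = self.tumor_radius_mm * (1.0 + self.axis_jitter) + 2.0 * self.margin_width_mm
        for axis, (n, s) in enumerate(zip(self.grid_shape, self.spacing_mm)):
            half_extent = n * s / 2.0
            if need > half_extent:
                raise ValueError(
                    f"tumor (radius+2*margin = {need:.1f} mm) does not fit axis {axis} "
                    f"(half-extent {half_extent:.1f} mm); enlarge grid_shape[{axis}] "
                    f"or shrink tumor_radius_mm/margin_width_mm"
                )


@dataclass(frozen=True)
class LatentImmuneState:
    """Continuous latent immune activities of one sample (arbitrary scale)."""

    sample_id: str
    th1_level: float = 0.0
    th2_level: float = 0.0
    ctl_level: float = 0.0


def draw_latent_states(n_samples: int, seed: int, prefix: str = "S") -> list[LatentImmuneState]:
    """Draw i.i.d. standard-normal latent states for a cohort."""
    rng = np.random.default_rng(seed)
    levels = rng.standard_normal((n_samples, 3))
    return [
        LatentImmuneState(f"{prefix}{i:03d}", *map(float, levels[i])) for i in range(n_samples)
    ]


def _logistic(t: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(t, -60, 60)))


def _texture_field(shape, spacing, corr_len_mm, skew_param, rng) -> np.ndarray:
    """Gaussian-correlated unit-SD noise field, optionally skew-warped.

    The warp ``(exp(s*z) - 1)/s`` is re-standardized so ``skew_param``
    moves only the asymmetry of the marginal, not its scale.
    """
    white = rng.standard_normal(shape)
    sigma_vox = [corr_len_mm / s for s in spacing]
    f = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = f.std()
    if sd > 0:
        f = f / sd
    if skew_param != 0.0:
        f = (np.exp(skew_param * f) - 1.0) / skew_param
        f = (f - f.mean()) / max(f.std(), 1e-12)
    return f


def generate_phantom(config: PhantomConfig, state: LatentImmuneState) -> VolumeROI:
    """Render one phantom volume for a given latent immune state.

    The per-sample RNG stream is derived from ``(config.seed, sample_id)``
    so a cohort can be generated in any order, or one sample in isolation,
    with identical results.
    """
    digest = hashlib.sha256(f"{config.seed}:{state.sample_id}".encode()).digest()
    key = int.from_bytes(digest[:4], "little") % (2**31)
    rng = np.random.default_rng([config.seed % (2**31), key])

    shape = tuple(int(n) for n in config.grid_shape)
    spacing = config.spacing_mm
    center = [(n - 1) / 2.0 for n in shape]

    # quasi-ellipsoid: seeded per-sample jitter of the three axis lengths
    jit = 1.0 + config.axis_jitter * rng.uniform(-1.0, 1.0, size=3)
    radii = config.tumor_radius_mm * jit

    axes = [
        (np.arange(n) - c) * s for n, c, s in zip(shape, center, spacing)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    rho = np.sqrt(
        (zz / radii[0]) ** 2 + (yy / radii[1]) ** 2 + (xx / radii[2]) ** 2
    )
    mask = rho <= 1.0
    # signed distance from the tumor boundary in mm (>0 outside)
    u = (rho - 1.0) * config.tumor_radius_mm

    # latent coupling: rim contrast in HU and margin width in mm
    contrast = (config.rim_mean_hu - config.core_mean_hu) + config.coupling_beta * state.th2_level
    # width factor bounded to [1/2, 2] so extreme latents sharpen/smear the
    # margin without destroying the rim ring itself
    width = config.margin_width_mm * float(
        np.clip(np.exp(-0.01 * config.coupling_beta * state.th2_level), 0.5, 2.0)
    )

    # rim ring: rises from core level at depth rim_thickness, falls to the
    # background (== core level) across the outer margin of width `width`
    ring = _logistic((u + config.rim_thickness_mm) / config.rim_inner_width_mm) * (
        1.0 - _logistic(u / width)
    )
    intensities = config.core_mean_hu + contrast * ring

    if config.noise_sd_hu > 0:
        intensities = intensities + config.noise_sd_hu * _texture_field(
            shape, spacing, config.texture_corr_len_mm, config.histogram_skew_param, rng
        )

    return VolumeROI(intensities=intensities, mask=mask, spacing_mm=spacing)


def generate_cohort(
    config: PhantomConfig, states: list[LatentImmuneState] | None = None
) -> tuple[list[LatentImmuneState], list[VolumeROI]]:
    """Draw latent states (unless given) and render the whole cohort."""
    if states is None:
        states = draw_latent_states(config.n_samples, config.seed)
    rois = [generate_phantom(config, s) for s in states]
    return states, rois


def write_cohort(
    out_dir: str | Path,
    states: list[LatentImmuneState],
    rois: list[VolumeROI],
) -> Path:
    """Write NIfTI image/mask pairs plus a cohort manifest CSV.

    Returns the manifest path.  Columns: sample_id, image, mask and the
    three latent levels.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = out / "cohort.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "image", "mask", "th1_level", "th2_level", "ctl_level"])
        for st, roi in zip(states, rois):
            img = out / "images" / f"{st.sample_id}.nii"
            msk = out / "masks" / f"{st.sample_id}.nii"
            roi.save(img, msk)
            w.writerow(
                [st.sample_id, str(img), str(msk), st.th1_level, st.th2_level, st.ctl_level]
            )
    return manifest
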