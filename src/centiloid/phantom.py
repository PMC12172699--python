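"""Seeded synthetic amyloid-PET phantoms with known ground truth.

The generator emulates the statistical structure the MRI-less pipeline
assumes: brain-like volumes with cortical, white-matter and cerebellar
compartments, a cortical signal that interpolates linearly between the
young-control anchor (PiB SUVr 1.014) and the AD anchor (2.088), tracer
SUVr linked to PiB SUVr through the published calibration slopes, smooth
random deformations, PET-like Gaussian blur and voxelwise noise.  Every
output is a deterministic function of the spec and its seed.

Compartment label conventions (``make_anatomy``): 0 background, 1 non-brain
soft tissue, 2 cortical ribbon, 3 white matter, 4 cerebellum, and, when the
skull option is on, 5 for a skull/scalp shell (used to emulate the
high-skull-uptake failure mode of some ^18F tracers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .quantification import DEFAULT_ANCHORS, VOISet, get_calibration
from .registration import AffineTransform, FFDTransform, apply_transform
from .volume_io import MaskVolume, Volume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "default_grid",
    "full_scale_grid",
    "make_anatomy",
    "make_voi_set",
    "render_pet",
    "make_random_ffd",
    "make_cohort",
    "BACKGROUND", "SOFT_TISSUE", "CORTEX", "WHITE_MATTER", "CEREBELLUM", "SKULL",
]

BACKGROUND, SOFT_TISSUE, CORTEX, WHITE_MATTER, CEREBELLUM, SKULL = range(6)

# tracers with high nonspecific white-matter binding vs the PiB/NAV class
_HIGH_WM_TRACERS = frozenset({"FBP", "FMM", "FBB"})
_WM_INTENSITY = {"high": 1.6, "low": 1.1}
_SOFT_TISSUE_INTENSITY = 0.25
_SKULL_INTENSITY = 1.5


def default_grid() -> tuple[tuple[int, int, int], np.ndarray]:
    """Test-scale grid: 64 x 64 x 48 voxels of 3 mm."""
    return _centered_grid((64, 64, 48), 3.0)


def full_scale_grid() -> tuple[tuple[int, int, int], np.ndarray]:
    """Template-scale grid: 160 x 160 x 96 voxels of 1.5 mm."""
    return _centered_grid((160, 160, 96), 1.5)


def _centered_grid(shape, vox: float):
    affine = np.diag([vox, vox, vox, 1.0])
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * vox
    return tuple(shape), affine


@dataclass
class PhantomSpec:
    grid: tuple = field(default_factory=default_grid)
    burden: float = 0.0
    tracer: str = "PiB"
    psf_fwhm: float = 8.0
    noise_sd: float = 0.02
    deformation: object = None
    skull: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.burden <= 1.0:
            raise ValueError("burden must lie in [0, 1]")
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PhantomTruth:
    true_suvr: float
    pib_suvr: float
    true_weight_proxy: float
    deformation_field: object
    masks: VOISet


def _ellipsoid(world: np.ndarray, center, semi) -> np.ndarray:
    c = np.asarray(center, dtype=np.float64)
    s = np.asarray(semi, dtype=np.float64)
    d = (world - c[:, None]) / s[:, None]
    return (d ** 2).sum(axis=0) <= 1.0


def make_anatomy(grid=None, skull: bool = False) -> Volume:
    """Deterministic compartment-label volume (see module docstring)."""
    shape, affine = grid if grid is not None else default_grid()
    if int(np.prod(shape)) < 32 ** 3:
        raise ValueError(f"grid {shape} too small; need at least 32^3 voxels")
    idx = np.indices(shape, dtype=np.float64).reshape(3, -1)
    world = affine[:3, :3] @ idx + affine[:3, 3:4]

    head = _ellipsoid(world, (0, 5, 0), (80, 92, 60))
    cerebrum = _ellipsoid(world, (0, 12, 10), (62, 72, 44))
    wm = _ellipsoid(world, (0, 12, 10), (62 * 0.88, 72 * 0.88, 44 * 0.88))
    cerebellum = _ellipsoid(world, (0, -52, -36), (32, 24, 19)) & head & ~cerebrum

    labels = np.zeros(int(np.prod(shape)), dtype=np.int16)
    labels[head] = SOFT_TISSUE
    if skull:
        inner = _ellipsoid(world, (0, 5, 0), (80 * 0.93, 92 * 0.93, 60 * 0.93))
        labels[head & ~inner] = SKULL
    labels[cerebrum & ~wm] = CORTEX
    labels[wm] = WHITE_MATTER
    labels[cerebellum] = CEREBELLUM
    return Volume(labels.reshape(shape), affine, meta={"kind": "anatomy-labels"})


def make_voi_set(grid=None) -> VOISet:
    """Binary cortical-target and cerebellar-reference masks in template space."""
    anat = make_anatomy(grid)
    target = MaskVolume((anat.data == CORTEX).astype(np.float32), anat.affine,
                        kind="binary")
    reference = MaskVolume((anat.data == CEREBELLUM).astype(np.float32), anat.affine,
                           kind="binary")
    return VOISet(target=target, reference=reference, space_label="phantom template space")


def make_random_ffd(grid, spacing_mm: float, amplitude_mm: float,
                    seed: int) -> FFDTransform:
    """Smooth random FFD with control displacements of the given amplitude.

    Control displacements are drawn uniformly in [-amplitude, amplitude] per
    component and tapered to zero at the lattice border so the warp vanishes
    toward the volume edge.
    """
    shape, affine = grid
    extent = np.asarray(shape) * np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    if amplitude_mm > extent.min() / 10:
        raise ValueError("deformation amplitude exceeds a tenth of the grid extent")
    corners = np.array(np.meshgrid(*[[0, s - 1] for s in shape], indexing="ij")
                       ).reshape(3, -1)
    wc = affine[:3, :3] @ corners + affine[:3, 3:4]
    box_min, box_max = wc.min(axis=1), wc.max(axis=1)
    spacing = np.full(3, float(spacing_mm))
    origin = box_min - 2 * spacing
    n_cp = np.ceil((box_max - origin) / spacing).astype(int) + 3
    rng = np.random.default_rng(seed)
    cp = rng.uniform(-amplitude_mm, amplitude_mm, size=(*n_cp, 3))
    for ax in range(3):
        taper = np.ones(n_cp[ax])
        taper[:3] = (0.0, 0.25, 0.7)
        taper[-3:] = (0.7, 0.25, 0.0)
        sl = [None, None, None, None]
        sl[ax] = slice(None)
        cp *= taper[tuple(sl)]
    return FFDTransform(cp, origin, spacing)


def render_pet(spec: PhantomSpec, true_suvr: Optional[float] = None
               ) -> tuple[Volume, PhantomTruth]:
    """Render one phantom PET volume plus its ground truth.

    Compartment intensities (cerebellum = 1 by construction): cortex carries
    the tracer SUVr — by default the burden-interpolated anchor value mapped
    through the tracer's published calibration line; ``true_suvr`` overrides
    it directly.  The intensity volume is warped by the ground-truth
    deformation, blurred with a Gaussian PSF, then degraded with voxelwise
    Gaussian noise.  The recorded ``true_suvr`` is the analytic pre-blur
    compartment ratio.
    """
    shape, affine = spec.grid
    anat = make_anatomy(spec.grid, skull=spec.skull)
    pib_suvr = DEFAULT_ANCHORS.yc0_mean + spec.burden * (
        DEFAULT_ANCHORS.ad100_mean - DEFAULT_ANCHORS.yc0_mean
    )
    if true_suvr is None:
        if spec.tracer == "PiB":
            suvr = pib_suvr
        else:
            calib = get_calibration(spec.tracer, "standard")
            suvr = calib.slope * pib_suvr + calib.intercept
    else:
        suvr = float(true_suvr)
    wm_level = _WM_INTENSITY["high" if spec.tracer in _HIGH_WM_TRACERS else "low"]
    lut = np.array([0.0, _SOFT_TISSUE_INTENSITY, suvr, wm_level, 1.0,
                    _SKULL_INTENSITY])
    data = lut[np.asarray(anat.data, dtype=np.intp)]
    vol = Volume(data, affine, meta={"tracer": spec.tracer, "seed": spec.seed,
                                     "rng": "numpy.random.default_rng(PCG64)"})

    deformation = spec.deformation
    if isinstance(deformation, tuple) and deformation and deformation[0] == "ffd":
        _, d_spacing, d_amp = deformation
        deformation = make_random_ffd(spec.grid, d_spacing, d_amp, spec.seed + 7)
    if deformation is not None:
        if not isinstance(deformation, (AffineTransform, FFDTransform)):
            raise ValueError(f"unsupported deformation spec: {deformation!r}")
        vol = apply_transform(vol, deformation, spec.grid)
        vol.meta.pop("support_mask", None)

    if spec.psf_fwhm > 0:
        vox = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
        sigma = spec.psf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vox
        vol.data = ndimage.gaussian_filter(vol.data, sigma=sigma)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol.data = vol.data + rng.normal(0.0, spec.noise_sd, size=shape)

    truth = PhantomTruth(
        true_suvr=suvr,
        pib_suvr=pib_suvr,
        true_weight_proxy=float(np.clip(1.0 - spec.burden, 0.0, 1.0)),
        deformation_field=deformation,
        masks=make_voi_set(spec.grid),
    )
    return vol, truth


def make_cohort(n_neg: int, n_pos: int, tracer: str = "PiB", seed: int = 0,
                grid=None, psf_fwhm: float = 8.0, noise_sd: float = 0.02,
                deformation: object = None, tracer_residual_sd: float = 0.06,
                ) -> list[tuple[Volume, PhantomTruth]]:
    """Two-class cohort with anchor-matched SUVr distributions.

    Pre-blur PiB SUVr is drawn from Normal(1.014, 0.047²) for the
    amyloid-negative class and Normal(2.088, 0.209²) for the positive class.
    For ^18F tracers the rendered SUVr follows the published calibration
    line plus Normal(0, tracer_residual_sd²) residuals.  Fully reproducible:
    the cohort is a pure function of its arguments.
    """
    if n_neg < 0 or n_pos < 0:
        raise ValueError("cohort sizes must be non-negative")
    grid = grid if grid is not None else default_grid()
    rng = np.random.default_rng(seed)
    pib = np.concatenate([
        rng.normal(DEFAULT_ANCHORS.yc0_mean, 0.047, size=n_neg),
        rng.normal(DEFAULT_ANCHORS.ad100_mean, 0.209, size=n_pos),
    ])
    pib = np.clip(pib, 0.1, None)  # floor far below the negative anchor
    if tracer == "PiB":
        rendered = pib
    else:
        calib = get_calibration(tracer, "standard")
        rendered = (calib.slope * pib + calib.intercept
                    + rng.normal(0.0, tracer_residual_sd, size=pib.size))
    seeds = rng.integers(0, 2 ** 31 - 1, size=pib.size)
    cohort = []
    for i, (p, s_val) in enumerate(zip(pib, rendered)):
        burden = float(np.clip(
            (p - DEFAULT_ANCHORS.yc0_mean)
            / (DEFAULT_ANCHORS.ad100_mean - DEFAULT_ANCHORS.yc0_mean), 0.0, 1.0))
        spec = PhantomSpec(grid=grid, burden=burden, tracer=tracer,
                           psf_fwhm=psf_fwhm, noise_sd=noise_sd,
                           deformation=deformation, seed=int(seeds[i]))
        vol, truth = render_pet(spec, true_suvr=float(s_val))
        truth.pib_suvr = float(p)
        vol.meta["class"] = "negative" if i < n_neg else "positive"
        cohort.append((vol, truth))
    return cohort
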