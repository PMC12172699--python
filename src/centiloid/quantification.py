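"""SUVr quantification and the Centiloid calibration algebra.

The Centiloid (CL) scale linearly rescales PiB SUVr so that the mean of a
young-control anchor cohort (YC-0) maps to 0 and the mean of a typical
AD-dementia anchor cohort (AD-100) maps to 100:

    CL = 100 * (SUVr - SUVr_YC0) / (SUVr_AD100 - SUVr_YC0)

An ^18F tracer (or an alternative, MRI-less "non-standard" pipeline) is
calibrated by ordinary least squares of its SUVr on standard-pipeline PiB
SUVr, SUVr_tracer = m * SUVr_PiB + b; inverting the fit yields the
PiB-equivalent SUVr (SUVr_tracer - b) / m, which then feeds the anchor
equation.  Composing the two steps gives the direct conversion

    CL = 100 * (SUVr_tracer - offset) / divisor,
    offset = b + m * SUVr_YC0,   divisor = m * (SUVr_AD100 - SUVr_YC0).

The bundled registry holds published slope/intercept pairs for PiB,
florbetapir (FBP), flutemetamol (FMM), florbetaben (FBB) and NAV4694 (NAV)
under both the MRI-based standard pipeline and the MRI-less non-standard
pipeline, together with the anchor means (1.014 and 2.088).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .volume_io import MaskVolume, Volume

__all__ = [
    "VOISet",
    "SUVrResult",
    "CentiloidAnchors",
    "TracerCalibration",
    "CentiloidEquation",
    "QCVerdict",
    "DEFAULT_ANCHORS",
    "TRACERS",
    "PIPELINES",
    "compute_suvr",
    "centiloid_from_pib",
    "pib_equivalent_suvr",
    "centiloid_from_tracer",
    "compose_equation",
    "fit_calibration",
    "level1_qc",
    "coefficient_registry",
    "get_calibration",
]

Tracer = Literal["PiB", "FBP", "FMM", "FBB", "NAV"]
Pipeline = Literal["standard", "nonstandard"]
TRACERS = ("PiB", "FBP", "FMM", "FBB", "NAV")
PIPELINES = ("standard", "nonstandard")


@dataclass
class VOISet:
    """Cortical target and whole-cerebellum reference masks on one grid."""

    target: MaskVolume
    reference: MaskVolume
    space_label: str = "template space"

    def __post_init__(self) -> None:
        if self.target.shape != self.reference.shape or not np.allclose(
            self.target.affine, self.reference.affine, atol=1e-3
        ):
            raise ValueError("target and reference VOIs must share one grid")
        overlap = float((self.target.data * self.reference.data).sum())
        if overlap > 0.01 * float(self.target.data.sum()):
            raise ValueError(
                "target and reference VOIs overlap by more than 1% of the target weight"
            )


@dataclass
class SUVrResult:
    suvr: float
    target_mean: float
    reference_mean: float
    n_target_voxels: int
    n_reference_voxels: int


@dataclass(frozen=True)
class CentiloidAnchors:
    """Level-1 anchor means of PiB SUVr: YC-0 maps to CL 0, AD-100 to CL 100."""

    yc0_mean: float = 1.014
    ad100_mean: float = 2.088

    def __post_init__(self) -> None:
        if not self.ad100_mean > self.yc0_mean > 0:
            raise ValueError("anchors must satisfy ad100_mean > yc0_mean > 0")


DEFAULT_ANCHORS = CentiloidAnchors()


@dataclass(frozen=True)
class TracerCalibration:
    """Slope/intercept of tracer SUVr regressed on standard-pipeline PiB SUVr."""

    tracer: str
    pipeline: str
    slope: float
    intercept: float
    r2: float | None = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")


@dataclass(frozen=True)
class CentiloidEquation:
    """Direct conversion CL(s) = 100 * (s - offset) / divisor for one tracer."""

    offset: float
    divisor: float
    tracer: str
    pipeline: str

    def __post_init__(self) -> None:
        if self.divisor <= 0:
            raise ValueError("divisor must be positive")

    def __call__(self, suvr):
        return 100.0 * (np.asarray(suvr, dtype=np.float64) - self.offset) / self.divisor


# Published calibration coefficients: {(tracer, pipeline): (m, b, r2)}.
# PiB/standard is the identity by definition (PiB on the standard pipeline
# IS the reference quantity of the scale).
_REGISTRY: dict[tuple[str, str], tuple[float, float, float | None]] = {
    ("PiB", "standard"): (1.0, 0.0, None),
    ("PiB", "nonstandard"): (0.924, 0.097, 0.993),
    ("FBP", "standard"): (0.523, 0.511, 0.905),
    ("FBP", "nonstandard"): (0.462, 0.641, 0.879),
    ("FMM", "standard"): (0.770, 0.218, 0.963),
    ("FMM", "nonstandard"): (0.703, 0.347, 0.965),
    ("FBB", "standard"): (0.608, 0.390, 0.954),
    ("FBB", "nonstandard"): (0.557, 0.490, 0.957),
    ("NAV", "standard"): (1.046, -0.035, 0.991),
    ("NAV", "nonstandard"): (0.899, 0.145, 0.990),
}


def coefficient_registry() -> tuple[list[TracerCalibration], CentiloidAnchors]:
    """All bundled tracer calibrations plus the default anchors."""
    calibs = [
        TracerCalibration(tracer=t, pipeline=p, slope=m, intercept=b, r2=r2)
        for (t, p), (m, b, r2) in _REGISTRY.items()
    ]
    return calibs, DEFAULT_ANCHORS


def get_calibration(tracer: str, pipeline: str) -> TracerCalibration:
    key = (tracer, pipeline)
    if key not in _REGISTRY:
        raise KeyError(
            f"no calibration for tracer={tracer!r}, pipeline={pipeline!r}; "
            f"tracers: {TRACERS}, pipelines: {PIPELINES}"
        )
    m, b, r2 = _REGISTRY[key]
    return TracerCalibration(tracer=tracer, pipeline=pipeline, slope=m, intercept=b, r2=r2)


def compute_suvr(vol: Volume, vois: VOISet) -> SUVrResult:
    """Weighted-mean SUVr: cortical target mean over cerebellar reference mean.

    Mask values act as weights, so binary masks reduce to plain means and
    probabilistic masks to weighted means.  Voxels flagged out-of-support
    by a prior resampling (``meta["support_mask"]``) are excluded.
    """
    if vol.shape != vois.target.shape or not np.allclose(
        vol.affine, vois.target.affine, atol=1e-3
    ):
        raise ValueError("volume is not on the VOI grid; resample it first")
    data = np.asarray(vol.data, dtype=np.float64)
    support = vol.meta.get("support_mask")
    means, counts = [], []
    for mask in (vois.target, vois.reference):
        w = np.asarray(mask.data, dtype=np.float64)
        if support is not None:
            w = w * support
        sel = w > 0
        n_nan = int(np.isnan(data[sel]).sum())
        if n_nan:
            raise ValueError(f"{n_nan} NaN voxels inside the VOI")
        wsum = w.sum()
        if wsum <= 0:
            raise ValueError("VOI is empty after support masking")
        means.append(float((w * data).sum() / wsum))
        counts.append(int(sel.sum()))
    target_mean, reference_mean = means
    if reference_mean <= 0:
        raise ValueError(
            f"reference-region mean is non-positive ({reference_mean:g}); SUVr undefined"
        )
    return SUVrResult(
        suvr=target_mean / reference_mean,
        target_mean=target_mean,
        reference_mean=reference_mean,
        n_target_voxels=counts[0],
        n_reference_voxels=counts[1],
    )


def centiloid_from_pib(suvr, anchors: CentiloidAnchors = DEFAULT_ANCHORS):
    """Anchor equation: CL = 100 * (SUVr - YC0) / (AD100 - YC0)."""
    s = np.asarray(suvr, dtype=np.float64)
    out = 100.0 * (s - anchors.yc0_mean) / (anchors.ad100_mean - anchors.yc0_mean)
    return float(out) if out.ndim == 0 else out


def pib_equivalent_suvr(tracer_suvr, calib: TracerCalibration):
    """Invert the tracer-on-PiB regression: (SUVr - b) / m."""
    s = np.asarray(tracer_suvr, dtype=np.float64)
    out = (s - calib.intercept) / calib.slope
    return float(out) if out.ndim == 0 else out


def centiloid_from_tracer(tracer_suvr, calib: TracerCalibration,
                          anchors: CentiloidAnchors = DEFAULT_ANCHORS):
    """Tracer SUVr -> PiB-equivalent SUVr -> Centiloid."""
    return centiloid_from_pib(pib_equivalent_suvr(tracer_suvr, calib), anchors)


def compose_equation(calib: TracerCalibration,
                     anchors: CentiloidAnchors = DEFAULT_ANCHORS) -> CentiloidEquation:
    """Collapse the two-step conversion into CL(s) = 100 (s - offset)/divisor."""
    offset = calib.intercept + calib.slope * anchors.yc0_mean
    divisor = calib.slope * (anchors.ad100_mean - anchors.yc0_mean)
    return CentiloidEquation(offset=offset, divisor=divisor,
                             tracer=calib.tracer, pipeline=calib.pipeline)


def fit_calibration(pib_suvrs, tracer_suvrs, tracer: str,
                    pipeline: str) -> TracerCalibration:
    """OLS of tracer SUVr on PiB SUVr (PiB is the independent variable)."""
    x = np.asarray(pib_suvrs, dtype=np.float64)
    y = np.asarray(tracer_suvrs, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pib_suvrs and tracer_suvrs must be 1-D and paired")
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs, got {x.size}")
    if np.var(x) <= 0:
        raise ValueError("PiB SUVr values have zero variance")
    fit = stats.linregress(x, y)
    return TracerCalibration(tracer=tracer, pipeline=pipeline,
                             slope=float(fit.slope), intercept=float(fit.intercept),
                             r2=float(fit.rvalue ** 2))


@dataclass(frozen=True)
class QCVerdict:
    slope_ok: bool
    intercept_ok: bool
    r2_ok: bool

    @property
    def passed(self) -> bool:
        return self.slope_ok and self.intercept_ok and self.r2_ok


def level1_qc(slope: float, intercept: float, r2: float) -> QCVerdict:
    """Level-1 replication acceptance ranges.

    The regression of locally computed Centiloid values against the
    published ones must have slope in [0.98, 1.02], intercept in [-2, 2]
    and R² strictly above 0.98.
    """
    if not all(np.isfinite([slope, intercept, r2])):
        raise ValueError("QC inputs must be finite")
    return QCVerdict(
        slope_ok=bool(0.98 <= slope <= 1.02),
        intercept_ok=bool(-2.0 <= intercept <= 2.0),
        r2_ok=bool(r2 > 0.98),
    )
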