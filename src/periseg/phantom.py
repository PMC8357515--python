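"""Synthetic pelvic CT slices with perianal-abscess lesions and ground truth.

The phantom is an idealized concentric construction: an air background, a
circular body cross-section wrapped in a skin (epidermis + dermis) band and
a subcutaneous-fascia layer, an anal canal at the centre and — in the
lesion group — a U-shaped high-attenuation abscess wall around a
low-attenuation core adjacent to the canal. Per-tissue Hounsfield values
are drawn from configurable (mean, sd) pairs; additive scanner noise and a
Gaussian edge blur follow, so lesion edges come out blurred.

All randomness flows from the config seed: identical configs give
bit-identical slices.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .types import BinaryMask, CTSlice

__all__ = [
    "TISSUE_CLASSES",
    "SKIN_THICKNESS_RANGE_MM",
    "FASCIA_HU",
    "GeometryError",
    "LesionGeometry",
    "PhantomConfig",
    "PhantomGroundTruth",
    "default_tissue_hu",
    "generate_phantom",
    "generate_cohort",
]

#: Integer labels of the tissue-class map.
TISSUE_CLASSES = {
    "background": 0,
    "epidermis_dermis": 1,
    "subcutaneous_fascia": 2,
    "soft_tissue": 3,
    "abscess_wall": 4,
    "abscess_core": 5,
    "anal_canal": 6,
}

#: Reported skin (epidermis + dermis) thickness ranges per group, mm.
SKIN_THICKNESS_RANGE_MM = {"lesion": (4.1, 4.9), "control": (1.8, 3.6)}

#: Reported subcutaneous-fascia CT value (mean, sd) per group, HU.
FASCIA_HU = {"lesion": (-95.45, 8.26), "control": (-76.34, 7.69)}


class GeometryError(ValueError):
    """The requested anatomy does not fit into the image."""


def default_tissue_hu(group: str) -> dict[str, tuple[float, float]]:
    """Per-tissue (mean, sd) HU defaults for a group.

    Only the fascia values are reported measurements; the rest are
    plausible CT defaults recorded here so analysis code never hard-codes
    them.
    """
    return {
        "background": (-1000.0, 0.0),
        "epidermis_dermis": (60.0, 15.0),
        "subcutaneous_fascia": FASCIA_HU[group],
        "soft_tissue": (30.0, 10.0),
        "abscess_wall": (40.0, 10.0),
        "abscess_core": (15.0, 8.0),
        "anal_canal": (-300.0, 20.0),
    }


@dataclass(frozen=True)
class LesionGeometry:
    """Abscess geometry in millimetres relative to the image centre.

    ``center_mm`` is ``(row, col)``; ``None`` places the lesion adjacent
    to the anal canal (touching its posterior edge).
    """

    center_mm: tuple[float, float] | None = None
    outer_radius_mm: float = 8.0
    core_radius_mm: float = 4.0
    u_gap_deg: float = 60.0

    def __post_init__(self) -> None:
        if not 0 < self.core_radius_mm < self.outer_radius_mm:
            raise ValueError("need 0 < core radius < outer radius")
        if not 0 <= self.u_gap_deg < 360:
            raise ValueError("u_gap_deg must lie in [0, 360)")


@dataclass
class PhantomConfig:
    image_size: int = 128
    pixel_spacing_mm: float = 0.5
    group: str = "lesion"
    skin_thickness_mm: float | None = None  # default: midpoint of group range
    tissue_hu: dict[str, tuple[float, float]] | None = None
    lesion_geometry: LesionGeometry = field(default_factory=LesionGeometry)
    noise_sd_hu: float = 5.0
    blur_sigma_px: float = 1.0
    seed: int = 0
    body_radius_mm: float | None = None  # default: 44 % of the field of view
    fascia_thickness_mm: float = 4.0
    anal_canal_radius_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.group not in SKIN_THICKNESS_RANGE_MM:
            raise ValueError(f"group must be 'lesion' or 'control', got {self.group!r}")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.skin_thickness_mm is None:
            lo, hi = SKIN_THICKNESS_RANGE_MM[self.group]
            self.skin_thickness_mm = (lo + hi) / 2.0
        if self.tissue_hu is None:
            self.tissue_hu = default_tissue_hu(self.group)
        missing = set(TISSUE_CLASSES) - set(self.tissue_hu)
        if missing:
            raise ValueError(f"tissue_hu missing classes: {sorted(missing)}")


@dataclass
class PhantomGroundTruth:
    """Everything the generator knows about a phantom."""

    tissue_map: np.ndarray
    lesion_mask: BinaryMask
    skin_thickness_mm: float
    hu_params: dict[str, tuple[float, float]]
    group: str
    body_radius_mm: float
    fascia_thickness_mm: float


def _lesion_center(config: PhantomConfig) -> tuple[float, float]:
    geo = config.lesion_geometry
    if geo.center_mm is not None:
        return geo.center_mm
    return (config.anal_canal_radius_mm + geo.outer_radius_mm, 0.0)


def _validate_geometry(config: PhantomConfig, body_r: float) -> None:
    half_field = config.image_size * config.pixel_spacing_mm / 2.0
    if body_r + config.pixel_spacing_mm > half_field:
        raise GeometryError(
            f"body radius {body_r:.1f} mm does not fit a "
            f"{config.image_size} px image at {config.pixel_spacing_mm} mm/px"
        )
    inner_r = body_r - config.skin_thickness_mm - config.fascia_thickness_mm
    if inner_r <= config.anal_canal_radius_mm:
        raise GeometryError("no soft-tissue space left inside skin and fascia")
    if config.group == "lesion":
        cy, cx = _lesion_center(config)
        reach = float(np.hypot(cy, cx)) + config.lesion_geometry.outer_radius_mm
        if reach > inner_r:
            raise GeometryError(
                f"lesion (reach {reach:.1f} mm) exceeds the soft-tissue "
                f"compartment (radius {inner_r:.1f} mm)"
            )


def _tissue_map(config: PhantomConfig, body_r: float) -> np.ndarray:
    n = config.image_size
    sp = config.pixel_spacing_mm
    coord = (np.arange(n) - (n - 1) / 2.0) * sp
    yy, xx = np.meshgrid(coord, coord, indexing="ij")
    r = np.hypot(yy, xx)
    t = np.zeros((n, n), dtype=np.uint8)
    inner_r = body_r - config.skin_thickness_mm - config.fascia_thickness_mm
    t[r <= body_r] = TISSUE_CLASSES["epidermis_dermis"]
    t[r <= body_r - config.skin_thickness_mm] = TISSUE_CLASSES["subcutaneous_fascia"]
    t[r <= inner_r] = TISSUE_CLASSES["soft_tissue"]
    t[r <= config.anal_canal_radius_mm] = TISSUE_CLASSES["anal_canal"]
    if config.group == "lesion":
        geo = config.lesion_geometry
        cy, cx = _lesion_center(config)
        d = np.hypot(yy - cy, xx - cx)
        wall = (d <= geo.outer_radius_mm) & (d > geo.core_radius_mm)
        if geo.u_gap_deg > 0:
            # wedge opening faces the anal canal, giving the U shape
            phi = np.arctan2(yy - cy, xx - cx)
            phi_gap = np.arctan2(-cy, -cx)
            dphi = np.angle(np.exp(1j * (phi - phi_gap)))
            wall &= np.abs(np.degrees(dphi)) > geo.u_gap_deg / 2.0
        t[wall] = TISSUE_CLASSES["abscess_wall"]
        t[d <= geo.core_radius_mm] = TISSUE_CLASSES["abscess_core"]
    return t


def generate_phantom(config: PhantomConfig) -> tuple[CTSlice, PhantomGroundTruth]:
    """Generate one synthetic CT slice plus its full ground truth.

    Raises :class:`GeometryError` when the configured anatomy cannot fit
    into the image.
    """
    body_r = config.body_radius_mm
    if body_r is None:
        body_r = 0.44 * config.image_size * config.pixel_spacing_mm
    _validate_geometry(config, body_r)
    tissue = _tissue_map(config, body_r)
    rng = np.random.default_rng(config.seed)
    means = np.zeros(len(TISSUE_CLASSES))
    sds = np.zeros(len(TISSUE_CLASSES))
    for name, label in TISSUE_CLASSES.items():
        means[label], sds[label] = config.tissue_hu[name]
    img = means[tissue] + sds[tissue] * rng.standard_normal(tissue.shape)
    if config.noise_sd_hu > 0:
        img += config.noise_sd_hu * rng.standard_normal(tissue.shape)
    if config.blur_sigma_px > 0:
        img = gaussian_filter(img, config.blur_sigma_px)
    lesion_mask = (tissue == TISSUE_CLASSES["abscess_wall"]) | (
        tissue == TISSUE_CLASSES["abscess_core"]
    )
    ct = CTSlice(img, (config.pixel_spacing_mm, config.pixel_spacing_mm))
    gt = PhantomGroundTruth(
        tissue_map=tissue,
        lesion_mask=lesion_mask,
        skin_thickness_mm=float(config.skin_thickness_mm),
        hu_params=dict(config.tissue_hu),
        group=config.group,
        body_radius_mm=float(body_r),
        fascia_thickness_mm=float(config.fascia_thickness_mm),
    )
    return ct, gt


def _cohort_config(
    base: PhantomConfig, group: str, rng: np.random.Generator
) -> PhantomConfig:
    lo, hi = SKIN_THICKNESS_RANGE_MM[group]
    outer = rng.uniform(5.5, 7.5)
    geo = LesionGeometry(
        center_mm=None,
        outer_radius_mm=outer,
        core_radius_mm=outer * rng.uniform(0.4, 0.6),
        u_gap_deg=rng.uniform(50.0, 80.0),
    )
    hu = dict(default_tissue_hu(group))
    # fascia mean varies between subjects by the reported group sd,
    # so cohort-level statistics reproduce the printed mean +/- sd
    f_mean, f_sd = hu["subcutaneous_fascia"]
    hu["subcutaneous_fascia"] = (f_mean + rng.normal(0.0, f_sd), f_sd)
    return dataclasses.replace(
        base,
        group=group,
        skin_thickness_mm=float(rng.uniform(lo, hi)),
        lesion_geometry=geo,
        tissue_hu=hu,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(
    n_lesion: int,
    n_control: int,
    base_config: PhantomConfig | None = None,
    seed: int = 0,
) -> list[tuple[CTSlice, PhantomGroundTruth]]:
    """Generate a two-group cohort with per-sample anatomy variation.

    Skin thickness is drawn uniformly within the group's reported range;
    lesion geometry varies mildly; the fascia mean varies between samples
    by the reported group sd. Fully reproducible from ``seed``.
    """
    if n_lesion < 0 or n_control < 0:
        raise ValueError("cohort counts must be non-negative")
    if base_config is None:
        base_config = PhantomConfig()
    rng = np.random.default_rng(seed)
    samples = []
    for group, count in (("lesion", n_lesion), ("control", n_control)):
        for _ in range(count):
            cfg = _cohort_config(base_config, group, rng)
            samples.append(generate_phantom(cfg))
    return samples
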