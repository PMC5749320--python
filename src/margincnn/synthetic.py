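"""Speckle phantom generator for margin-focused nodule classification.

Real follicular-neoplasm ultrasound cohorts are not publicly available, so
every downstream stage is exercised on synthetic B-mode-like phantoms:

* a piecewise-constant template — brighter background, hypoechoic (darker)
  elliptical nodule, and a rim band along the nodule boundary — multiplied
  by Rayleigh speckle noise and blurred (sigma = 1 px) to mimic
  resolution-cell correlation;
* the class-discriminative signal lives ONLY in the rim band: adenoma
  phantoms get a smooth, regular, bright rim; carcinoma phantoms get an
  irregular rim (larger radial boundary perturbation, angular intensity
  modulation, and randomized rim interruptions). Interiors and backgrounds
  share statistics across classes, so a classifier that beats chance on
  margin patches — but not on interior patches — is evidencing
  margin-localized features;
* each image is affinely rescaled toward its cohort's target mean intensity
  (defaults 63.819 for cohort "A", 82.07 for cohort "B", emulating two
  clinics with different acquisition settings), then rounded
  half-away-from-zero and clipped to 8 bits.

Everything is deterministic given the seed; per-case seeds are spawned from
a master seed via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .case import ADENOMA, CARCINOMA, LABELS, NoduleCase
from .patches import Contour, densify_polygon

N_BOUNDARY_SAMPLES = 720


class ConfigurationError(ValueError):
    """Synthetic configuration violates its invariants."""


@dataclass(frozen=True)
class RimRegularity:
    """Class-specific rim/boundary roughness parameters.

    ``amplitude`` scales the radial perturbation of the boundary (relative
    to the local radius); ``frequency`` is the dominant angular frequency of
    that perturbation; ``intensity_modulation`` is the relative amplitude of
    angular brightness variation along the rim; ``n_interruptions`` rim
    segments are blanked to interior intensity (carcinoma margins are
    discontinuous where invasion disrupts the capsule).
    """

    amplitude: float
    frequency: int
    intensity_modulation: float = 0.0
    n_interruptions: int = 0
    interruption_width_deg: float = 18.0


@dataclass(frozen=True)
class SyntheticConfig:
    image_size: int = 370
    nodule_radius_range: tuple[float, float] = (80.0, 105.0)
    axis_ratio_range: tuple[float, float] = (0.78, 0.98)
    rim_width: float = 8.0
    rim_regularity: dict = field(
        default_factory=lambda: {
            ADENOMA: RimRegularity(amplitude=0.02, frequency=5),
            CARCINOMA: RimRegularity(
                amplitude=0.10,
                frequency=9,
                intensity_modulation=0.30,
                n_interruptions=3,
            ),
        }
    )
    interior_mean: float = 45.0
    background_mean: float = 95.0
    rim_mean: dict = field(
        default_factory=lambda: {ADENOMA: 135.0, CARCINOMA: 85.0}
    )
    cohort_intensity_targets: dict = field(
        default_factory=lambda: {"A": 63.819, "B": 82.07}
    )
    speckle_shape: float = 1.0
    contour_jitter: float = 0.0
    patch_size: int = 50

    def validate(self) -> "SyntheticConfig":
        rmin, rmax = self.nodule_radius_range
        if not (0 < rmin <= rmax):
            raise ConfigurationError("nodule_radius_range must satisfy 0 < min <= max")
        qmin, qmax = self.axis_ratio_range
        if not (0 < qmin <= qmax <= 1):
            raise ConfigurationError("axis_ratio_range must satisfy 0 < min <= max <= 1")
        if 2 * (rmax + self.rim_width) + self.patch_size >= self.image_size:
            raise ConfigurationError(
                "image too small: 2*(max radius + rim_width) + patch_size must be "
                f"< image_size ({self.image_size})"
            )
        for v in (self.interior_mean, self.background_mean, *self.rim_mean.values()):
            if not 0 <= v <= 255:
                raise ConfigurationError("intensity targets must lie in [0, 255]")
        for t in self.cohort_intensity_targets.values():
            if not 0 <= t <= 255:
                raise ConfigurationError("cohort intensity targets must lie in [0, 255]")
        if self.speckle_shape <= 0:
            raise ConfigurationError("speckle_shape must be positive")
        return self


def _boundary_radius(theta, base_a, base_b, phi, reg: RimRegularity, rng):
    """Radius profile of a perturbed, rotated ellipse at angles ``theta``."""
    t = theta - phi
    ellipse = (base_a * base_b) / np.sqrt(
        (base_b * np.cos(t)) ** 2 + (base_a * np.sin(t)) ** 2
    )
    phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
    pert = np.sin(reg.frequency * theta + phase1) + 0.5 * np.sin(
        (2 * reg.frequency + 1) * theta + phase2
    )
    return ellipse * (1.0 + reg.amplitude * pert / 1.5)


def generate_case(
    label: str, cohort: str, config: SyntheticConfig | None = None, seed: int = 0
) -> NoduleCase:
    """Generate one phantom nodule case; bit-identical for identical inputs."""
    config = (config or SyntheticConfig()).validate()
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    if cohort not in config.cohort_intensity_targets:
        raise ConfigurationError(f"no intensity target for cohort {cohort!r}")
    rng = np.random.default_rng(seed)
    size = config.image_size
    reg: RimRegularity = config.rim_regularity[label]

    # nodule geometry
    rmin, rmax = config.nodule_radius_range
    a = rng.uniform(rmin, rmax)
    b = a * rng.uniform(*config.axis_ratio_range)
    phi = rng.uniform(0, np.pi)
    jitter_max = size / 2 - (rmax + config.rim_width) - config.patch_size / 2
    jitter = rng.uniform(-1, 1, size=2) * max(0.0, min(6.0, jitter_max))
    cy, cx = size / 2 + jitter[0], size / 2 + jitter[1]

    theta = np.linspace(0.0, 2 * np.pi, N_BOUNDARY_SAMPLES, endpoint=False)
    radius = _boundary_radius(theta, a, b, phi, reg, rng)

    # per-pixel polar coordinates, boundary radius by angular interpolation
    rows = np.arange(size)[:, None] - cy
    cols = np.arange(size)[None, :] - cx
    pix_theta = np.mod(np.arctan2(rows, cols), 2 * np.pi)
    pix_dist = np.hypot(rows, cols)
    r_at = np.interp(pix_theta, theta, radius, period=2 * np.pi)

    template = np.full((size, size), config.background_mean, dtype=np.float64)
    inside = pix_dist < r_at
    template[inside] = config.interior_mean
    rim = inside & (pix_dist >= r_at - config.rim_width)
    rim_val = np.full((size, size), config.rim_mean[label])
    if reg.intensity_modulation:
        mod_phase = rng.uniform(0, 2 * np.pi)
        rim_val *= 1.0 + reg.intensity_modulation * np.sin(
            reg.frequency * pix_theta + mod_phase
        )
    template[rim] = rim_val[rim]
    if reg.n_interruptions:
        width = np.deg2rad(reg.interruption_width_deg)
        gap_centers = rng.uniform(0, 2 * np.pi, size=reg.n_interruptions)
        for g in gap_centers:
            d = np.abs(np.mod(pix_theta - g + np.pi, 2 * np.pi) - np.pi)
            template[rim & (d < width / 2)] = config.interior_mean

    # multiplicative Rayleigh speckle (normalized to unit mean), then blur
    speckle = rng.rayleigh(scale=config.speckle_shape, size=(size, size))
    speckle /= config.speckle_shape * np.sqrt(np.pi / 2.0)
    image = ndimage.gaussian_filter(template * speckle, sigma=1.0)

    # affine rescale toward the cohort's target mean, then 8-bit quantize
    target = config.cohort_intensity_targets[cohort]
    image = image * (target / image.mean())
    image = np.clip(np.floor(image + 0.5), 0, 255).astype(np.uint8)

    # ground-truth contour: the perturbed boundary traced to a closed path
    vr = cy + radius * np.sin(theta)
    vc = cx + radius * np.cos(theta)
    if config.contour_jitter > 0:
        vr = vr + rng.normal(0, config.contour_jitter, size=vr.shape)
        vc = vc + rng.normal(0, config.contour_jitter, size=vc.shape)
    vertices = np.column_stack([np.rint(vr), np.rint(vc)]).astype(np.int64)
    keep = np.any(vertices != np.roll(vertices, 1, axis=0), axis=1)
    contour = densify_polygon(vertices[keep]).points

    case = NoduleCase(
        case_id=f"{cohort}-{label[:3]}-{seed}",
        image=image,
        contour=contour,
        label=label,
        cohort=cohort,
        meta={"seed": seed, "axes": (a, b), "center": (cy, cx)},
    )
    return case.validate()


def generate_cohort(
    n_adenoma: int,
    n_carcinoma: int,
    cohort: str,
    config: SyntheticConfig | None = None,
    seed: int = 0,
) -> list[NoduleCase]:
    """Generate a labeled cohort; per-case seeds spawn from the master seed."""
    if n_adenoma < 0 or n_carcinoma < 0:
        raise ValueError("case counts must be nonnegative")
    config = (config or SyntheticConfig()).validate()
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_adenoma + n_carcinoma)]
    cases = []
    for i in range(n_adenoma):
        c = generate_case(ADENOMA, cohort, config, child_seeds[i])
        c.case_id = f"{cohort}-ade-{i:03d}"
        cases.append(c)
    for i in range(n_carcinoma):
        c = generate_case(CARCINOMA, cohort, config, child_seeds[n_adenoma + i])
        c.case_id = f"{cohort}-car-{i:03d}"
        cases.append(c)
    return cases


def rim_roughness(contour) -> float:
    """Scale-free roughness: std of the centroid-distance profile over its mean.

    0 for a perfect circle (up to pixel discretization); grows with the
    radial perturbation amplitude of the boundary.
    """
    pts = contour.points if isinstance(contour, Contour) else np.asarray(contour)
    if len(pts) < 16:
        raise ValueError("contour must have at least 16 points")
    pts = pts.astype(np.float64)
    ctr = pts.mean(axis=0)
    dist = np.hypot(*(pts - ctr).T)
    mean = dist.mean()
    if mean == 0:
        raise ValueError("degenerate contour: zero mean radius")
    return float(dist.std() / mean)


def with_interior_contours(cases, inset: float | None = None) -> list[NoduleCase]:
    """Copies of ``cases`` whose contours are moved inside the nodule.

    The interior-control condition: a square patch of side ``s`` centered on
    the inset path reaches at most ``s/sqrt(2)`` px from its center (the
    corners), so keeping every patch pixel clear of the rim band needs
    ``inset >= rim_width + s/sqrt(2)``. The default of 50 px covers the
    default geometry (rim 8 px, patches 50 px -> corners at 35.4 px) with
    several pixels to spare; the default nodule radii are sized so the inset
    path stays a valid closed contour.
    """
    from .patches import inset_contour

    if inset is None:
        inset = 50.0
    out = []
    for case in cases:
        inner = inset_contour(case.contour, inset)
        c = NoduleCase(case.case_id, case.image, inner, case.label, case.cohort, dict(case.meta))
        out.append(c.validate())
    return out
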