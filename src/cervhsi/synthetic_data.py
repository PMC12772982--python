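"""Seeded synthetic phantom scenes with known ground truth.

A phantom is a dark background holding a bright "cervix" disc; lesion
polygons inside the disc carry elevated chromophore concentrations, and the
reflectance follows a single-layer Beer-Lambert model

    R(x, y, l) = R_base(l) * exp(-sum_i c_i(x, y) * eps_i(l)) + noise

clipped to [0, 1].  The generator also fabricates a higher-resolution
perspective-distorted second view with noisy landmark pairs, and imperfect
multi-examiner annotations, so the full registration/consensus/index/stats
chain can be exercised without any external data.

All randomness flows from integer seeds through fixed ``SeedSequence``
splitting, so identical seeds give bit-identical scenes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .consensus import AnnotationSet, CIN_CLASSES
from .registration import Homography, LandmarkSet, project_points, warp_mask
from .spectral import Hypercube, WavelengthGrid, build_grid

__all__ = [
    "ChromophoreModel",
    "DEFAULT_CHROMOPHORES",
    "LesionRegion",
    "PhantomSpec",
    "ExaminerNoiseSpec",
    "SubjectScene",
    "CohortSpec",
    "generate_phantom_cube",
    "simulate_examiner_annotations",
    "generate_second_view",
    "generate_subject_scene",
    "generate_cohort",
    "rasterize_polygon",
    "random_perspective",
]

# stream ids for SeedSequence splitting (fixed so streams are independent
# and stable across versions)
_STREAM_CUBE = 11
_STREAM_ANNOT = 23
_STREAM_VIEW = 37
_STREAM_SCENE = 53


@dataclass(frozen=True)
class ChromophoreModel:
    """Absorption curve built as a sum of Gaussian peaks (center, width, amplitude)."""

    name: str
    peaks: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        for c, w, a in self.peaks:
            if w <= 0:
                raise ValueError("peak width must be positive")
            if a < 0:
                raise ValueError("peak amplitude must be >= 0")

    def absorption(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        lam = np.asarray(wavelengths_nm, dtype=np.float64)
        out = np.zeros_like(lam)
        for center, width, amp in self.peaks:
            out += amp * np.exp(-0.5 * ((lam - center) / width) ** 2)
        return out


# Peak placement puts signal exactly in the wavelength windows the band-ratio
# indices read; amplitudes are arbitrary units, not physical coefficients.
DEFAULT_CHROMOPHORES: dict[str, ChromophoreModel] = {
    "hbo2": ChromophoreModel("hbo2", ((542.0, 12.0, 1.0), (577.0, 10.0, 1.0))),
    "hb": ChromophoreModel("hb", ((555.0, 15.0, 1.0), (760.0, 30.0, 0.35))),
    "water": ChromophoreModel("water", ((970.0, 35.0, 1.0),)),
}


def _default_baseline(wavelengths_nm: np.ndarray) -> np.ndarray:
    lam = np.asarray(wavelengths_nm, dtype=np.float64)
    return 0.55 + 0.25 * (lam - 500.0) / 495.0


def rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd rasterization: pixel (row, col) set iff center (col, row) inside.

    Vertices are (N, 2) as (x, y).  Vectorized ray casting along +x.
    """
    v = np.asarray(vertices, dtype=np.float64)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
        raise ValueError("polygon needs >= 3 (x, y) vertices")
    h, w = shape
    xs, ys = np.meshgrid(np.arange(w, dtype=np.float64), np.arange(h, dtype=np.float64))
    inside = np.zeros(shape, dtype=bool)
    x0, y0 = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    for i in range(v.shape[0]):
        crosses = (y0[i] > ys) != (y1[i] > ys)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x0[i] + (ys - y0[i]) * (x1[i] - x0[i]) / (y1[i] - y0[i])
        inside ^= crosses & (xs < xint)
    return inside


@dataclass
class LesionRegion:
    """Labeled lesion polygon with per-chromophore concentration multipliers."""

    label: str
    polygon: np.ndarray
    multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=np.float64)
        if self.label not in CIN_CLASSES:
            raise ValueError(f"lesion label must be one of {CIN_CLASSES}, got {self.label!r}")
        for k, v in self.multipliers.items():
            if v < 0:
                raise ValueError(f"multiplier for {k!r} must be >= 0")


@dataclass
class PhantomSpec:
    image_height: int
    image_width: int
    wavelength_grid: WavelengthGrid
    disc_center: tuple[float, float]  # (x, y)
    disc_radius: float
    lesion_regions: list[LesionRegion] = field(default_factory=list)
    baseline_concentrations: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0
    background_reflectance: float = 0.05
    healthy_margin_px: int = 3
    baseline_reflectance: Callable[[np.ndarray], np.ndarray] = _default_baseline
    pixel_pitch_mm: float = 0.45

    def validate(self) -> None:
        if self.image_height < 1 or self.image_width < 1:
            raise ValueError("image dimensions must be positive")
        if self.wavelength_grid.n_bands < 1:
            raise ValueError("wavelength grid is empty")
        if self.disc_radius <= 0:
            raise ValueError("disc radius must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for k, v in self.baseline_concentrations.items():
            if v < 0:
                raise ValueError(f"concentration for {k!r} must be >= 0")
        cx, cy = self.disc_center
        for region in self.lesion_regions:
            d = np.hypot(region.polygon[:, 0] - cx, region.polygon[:, 1] - cy)
            if np.any(d > self.disc_radius + 1e-9):
                raise ValueError(
                    f"lesion {region.label!r} polygon extends outside the cervix disc"
                )


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    h, w = shape
    xs, ys = np.meshgrid(np.arange(w, dtype=np.float64), np.arange(h, dtype=np.float64))
    return (xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= radius**2


def generate_phantom_cube(
    spec: PhantomSpec,
    chromophores: Mapping[str, ChromophoreModel] | None = None,
) -> tuple[Hypercube, AnnotationSet]:
    """Render the Beer-Lambert phantom and return it with exact ground truth.

    The ground-truth annotation set holds the lesion masks per class plus a
    ``healthy`` reference mask: the disc minus a safety margin around every
    lesion, so lesion and healthy classes are strictly disjoint.
    """
    spec.validate()
    chrom = DEFAULT_CHROMOPHORES if chromophores is None else dict(chromophores)
    h, w = spec.image_height, spec.image_width
    lam = spec.wavelength_grid.centers
    shape = (h, w)

    disc = _disc_mask(shape, spec.disc_center, spec.disc_radius)
    lesion_masks: dict[str, np.ndarray] = {}
    for region in spec.lesion_regions:
        m = rasterize_polygon(region.polygon, shape) & disc
        lesion_masks[region.label] = lesion_masks.get(region.label, np.zeros(shape, bool)) | m

    # concentration maps: baseline inside disc, multiplied inside lesions
    names = sorted(set(spec.baseline_concentrations) & set(chrom))
    conc = {name: np.where(disc, spec.baseline_concentrations[name], 0.0) for name in names}
    for region in spec.lesion_regions:
        m = rasterize_polygon(region.polygon, shape) & disc
        for name in names:
            mult = region.multipliers.get(name, 1.0)
            conc[name][m] = spec.baseline_concentrations[name] * mult

    att = np.zeros((h, w, lam.size))
    for name in names:
        att += conc[name][:, :, None] * chrom[name].absorption(lam)[None, None, :]
    base = np.asarray(spec.baseline_reflectance(lam), dtype=np.float64)
    refl = np.where(
        disc[:, :, None],
        base[None, None, :] * np.exp(-att),
        spec.background_reflectance,
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, _STREAM_CUBE]))
        refl = refl + rng.normal(0.0, spec.noise_sd, size=refl.shape)
    refl = np.clip(refl, 0.0, 1.0)

    any_lesion = np.zeros(shape, dtype=bool)
    for m in lesion_masks.values():
        any_lesion |= m
    margin = ndimage.binary_dilation(any_lesion, iterations=spec.healthy_margin_px)
    healthy = disc & ~margin

    truth = AnnotationSet(
        subject_id=f"phantom-{spec.seed}",
        examiner_id="truth",
        masks={**lesion_masks, "healthy": healthy},
        frame="hsi",
    )
    cube = Hypercube(refl, spec.wavelength_grid, pixel_pitch_mm=spec.pixel_pitch_mm)
    return cube, truth


@dataclass
class ExaminerNoiseSpec:
    n_examiners: int = 5
    boundary_jitter_sd: float = 5.0
    dilation_bias_range: tuple[float, float] = (-3.0, 3.0)
    omission_probability: float = 0.0
    healthy_fraction: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.n_examiners < 1:
            raise ValueError("n_examiners must be >= 1")
        if not 0 <= self.omission_probability <= 1:
            raise ValueError("omission_probability must be in [0, 1]")
        if self.boundary_jitter_sd < 0:
            raise ValueError("boundary_jitter_sd must be >= 0")
        if self.dilation_bias_range[0] > self.dilation_bias_range[1]:
            raise ValueError("dilation_bias_range must be (lo, hi) with lo <= hi")

    @property
    def is_noise_free(self) -> bool:
        return (
            self.boundary_jitter_sd == 0
            and self.dilation_bias_range == (0.0, 0.0)
            and self.omission_probability == 0
        )


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    # positive inside, negative outside, in pixels
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return inside - outside


def _smooth_periodic_jitter(rng: np.random.Generator, sd: float, n_bins: int = 90) -> np.ndarray:
    """Angular displacement profile: circularly smoothed white noise, scaled to sd."""
    raw = rng.normal(0.0, 1.0, size=n_bins)
    k = np.exp(-0.5 * (np.arange(-10, 11) / 3.0) ** 2)
    k /= k.sum()
    smooth = np.convolve(np.tile(raw, 3), k, mode="same")[n_bins : 2 * n_bins]
    s = smooth.std()
    if s == 0:
        return np.zeros(n_bins)
    return smooth * (sd / s)


def _perturb_mask(
    mask: np.ndarray, rng: np.random.Generator, jitter_sd: float, bias: float
) -> np.ndarray:
    """Displace the boundary radially: smooth periodic jitter + uniform bias.

    A pixel is kept iff signed_distance + bias + jitter(theta) > 0, where theta
    is the angle around the region centroid — contiguous over/under-segmentation
    rather than salt-and-pepper flips.
    """
    if not mask.any():
        return mask.copy()
    if jitter_sd == 0 and bias == 0:
        return mask.copy()
    sdist = _signed_distance(mask)
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    yy, xx = np.meshgrid(
        np.arange(mask.shape[0], dtype=np.float64),
        np.arange(mask.shape[1], dtype=np.float64),
        indexing="ij",
    )
    theta = np.arctan2(yy - cy, xx - cx)  # [-pi, pi)
    profile = _smooth_periodic_jitter(rng, jitter_sd)
    n_bins = profile.size
    bins = ((theta + np.pi) / (2 * np.pi) * n_bins).astype(np.int64) % n_bins
    return (sdist + bias + profile[bins]) > 0


def _healthy_subregion(
    healthy: np.ndarray, rng: np.random.Generator, fraction: float
) -> np.ndarray:
    """A contiguous disc-shaped sample of the true healthy area (~`fraction` of it)."""
    ys, xs = np.nonzero(healthy)
    if ys.size == 0:
        return healthy.copy()
    i = rng.integers(0, ys.size)
    cy, cx = float(ys[i]), float(xs[i])
    target = max(1, int(round(fraction * ys.size)))
    r = np.sqrt(target / np.pi) * 1.5  # oversize: the intersection trims it
    yy, xx = np.meshgrid(
        np.arange(healthy.shape[0], dtype=np.float64),
        np.arange(healthy.shape[1], dtype=np.float64),
        indexing="ij",
    )
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    out = healthy & disc
    return out if out.any() else healthy.copy()


def simulate_examiner_annotations(
    truth: AnnotationSet, noise: ExaminerNoiseSpec
) -> list[AnnotationSet]:
    """Imperfect annotations from ``n_examiners`` simulated examiners.

    Lesion boundaries get smoothed radial jitter plus a per-examiner
    dilation/erosion bias, and are omitted entirely with
    ``omission_probability``; healthy references become independent
    sub-regions of the true healthy area.  With all noise terms zero every
    examiner reproduces the truth exactly.
    """
    noise.validate()
    if truth.shape is None or not any(m.any() for m in truth.masks.values()):
        raise ValueError("truth annotation set has no nonempty masks")
    out: list[AnnotationSet] = []
    for e in range(noise.n_examiners):
        rng = np.random.default_rng(np.random.SeedSequence([noise.seed, _STREAM_ANNOT, e]))
        masks: dict[str, np.ndarray] = {}
        if noise.is_noise_free:
            masks = {cls: m.copy() for cls, m in truth.masks.items()}
        else:
            bias = rng.uniform(*noise.dilation_bias_range)
            for cls in CIN_CLASSES:
                if cls not in truth.masks:
                    continue
                if rng.uniform() < noise.omission_probability:
                    continue
                masks[cls] = _perturb_mask(
                    truth.masks[cls], rng, noise.boundary_jitter_sd, bias
                )
            if "healthy" in truth.masks:
                masks["healthy"] = _healthy_subregion(
                    truth.masks["healthy"], rng, noise.healthy_fraction
                )
        out.append(
            AnnotationSet(
                subject_id=truth.subject_id,
                examiner_id=f"examiner-{e + 1}",
                masks=masks,
                frame=truth.frame,
            )
        )
    return out


def _pseudo_rgb(cube: Hypercube) -> np.ndarray:
    """Three fixed bands (closest to 620/540/500 nm) as an (H, W, 3) image."""
    centers = cube.grid.centers
    idx = [int(np.argmin(np.abs(centers - nm))) for nm in (620.0, 540.0, 500.0)]
    return cube.reflectance[:, :, idx]


def generate_second_view(
    cube: Hypercube,
    H_true: Homography,
    scale: float = 1.5,
    noise_sd: float = 0.0,
    n_landmarks: int = 6,
    seed: int = 0,
) -> tuple[np.ndarray, LandmarkSet]:
    """Higher-resolution perspective-distorted pseudo-RGB view plus landmarks.

    ``H_true`` maps second-view (source) coordinates to cube (destination)
    coordinates; the view is rendered by sampling the cube's pseudo-RGB
    projection through ``H_true`` at each output pixel.  Landmark pairs obey
    ``dst = H_true(src)`` up to i.i.d. Gaussian coordinate noise on both sides.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if n_landmarks < 4:
        raise ValueError("need at least 4 landmarks")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _STREAM_VIEW]))
    h, w = cube.spatial_shape
    out_h, out_w = int(round(h * scale)), int(round(w * scale))
    rgb_small = _pseudo_rgb(cube)

    xs, ys = np.meshgrid(np.arange(out_w, dtype=np.float64), np.arange(out_h, dtype=np.float64))
    pts = np.stack([xs.ravel(), ys.ravel()], axis=1)
    mapped = project_points(H_true, pts)
    coords = [mapped[:, 1].reshape(out_h, out_w), mapped[:, 0].reshape(out_h, out_w)]
    rgb = np.stack(
        [
            ndimage.map_coordinates(rgb_small[:, :, c], coords, order=1, cval=0.0)
            for c in range(3)
        ],
        axis=-1,
    )

    hinv = H_true.inverse()
    center = np.array([w / 2.0, h / 2.0])
    radius = 0.35 * min(h, w)
    for _attempt in range(100):
        ang = np.sort(rng.uniform(0, 2 * np.pi, size=n_landmarks))
        rad = radius * rng.uniform(0.6, 1.0, size=n_landmarks)
        dst = center[None, :] + np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1)
        src = project_points(hinv, dst)
        if noise_sd > 0:
            src = src + rng.normal(0.0, noise_sd, size=src.shape)
            dst = dst + rng.normal(0.0, noise_sd, size=dst.shape)
        if _non_collinear(src) and _non_collinear(dst):
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("failed to draw a non-collinear landmark configuration")
    landmarks = LandmarkSet(src=src, dst=dst, source_frame="colposcope", destination_frame="hsi")
    return rgb, landmarks


def _non_collinear(pts: np.ndarray, tol: float = 1e-6) -> bool:
    n = pts.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                a2 = abs(
                    (pts[j, 0] - pts[i, 0]) * (pts[k, 1] - pts[i, 1])
                    - (pts[j, 1] - pts[i, 1]) * (pts[k, 0] - pts[i, 0])
                )
                if a2 <= tol:
                    return False
    return True


def random_perspective(
    rng: np.random.Generator,
    scale: float,
    max_rotation_deg: float = 5.0,
    max_translation: float = 3.0,
    perspective_sd: float = 1e-4,
) -> Homography:
    """Mild random colposcope->HSI homography: shrink by ``scale`` plus a small
    rotation, translation and perspective term."""
    ang = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg))
    c, s = math.cos(ang), math.sin(ang)
    tx, ty = rng.uniform(-max_translation, max_translation, size=2)
    h = np.array(
        [
            [c / scale, -s / scale, tx],
            [s / scale, c / scale, ty],
            [
                rng.normal(0.0, perspective_sd),
                rng.normal(0.0, perspective_sd),
                1.0,
            ],
        ]
    )
    return Homography(h)


def _star_polygon(
    rng: np.random.Generator,
    center: tuple[float, float],
    mean_radius: float,
    irregularity: float = 0.3,
    n_vertices: int = 12,
) -> np.ndarray:
    ang = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    ang = ang + rng.uniform(0, 2 * np.pi / n_vertices)
    rad = mean_radius * (1.0 + irregularity * rng.uniform(-1, 1, size=n_vertices))
    # light smoothing keeps the outline lesion-like rather than spiky
    rad = np.convolve(np.concatenate([rad[-1:], rad, rad[:1]]), [0.25, 0.5, 0.25], "valid")
    return np.stack(
        [center[0] + rad * np.cos(ang), center[1] + rad * np.sin(ang)], axis=1
    )


@dataclass
class SubjectScene:
    """Everything the pipeline needs for one synthetic subject."""

    subject_id: str
    cube: Hypercube
    truth: AnnotationSet  # HSI frame
    examiner_annotations: list[AnnotationSet]  # colposcope frame
    landmarks: LandmarkSet
    H_true: Homography
    colposcope_rgb: np.ndarray
    spec: PhantomSpec


@dataclass
class CohortSpec:
    """Parameters for a reproducible multi-subject phantom cohort."""

    n_subjects: int = 11
    image_height: int = 72
    image_width: int = 72
    grid_start_nm: float = 500.0
    grid_step_nm: float = 5.0
    grid_end_nm: float = 995.0
    view_scale: float = 1.5
    n_examiners: int = 5
    boundary_jitter_sd: float = 5.0
    dilation_bias_range: tuple[float, float] = (-3.0, 3.0)
    omission_probability: float = 0.0
    landmark_noise_sd: float = 0.3
    noise_sd: float = 0.004
    hemoglobin_multiplier: tuple[float, float] = (1.6, 2.4)
    water_multiplier: tuple[float, float] = (1.5, 2.1)
    seed: int = 0

    @property
    def grid(self) -> WavelengthGrid:
        return build_grid(self.grid_start_nm, self.grid_step_nm, self.grid_end_nm)


def generate_subject_scene(cohort: CohortSpec, subject_index: int) -> SubjectScene:
    """One phantom subject: cube + truth, distorted second view, landmarks and
    noisy examiner annotations drawn in the second-view (colposcope) frame."""
    rng = np.random.default_rng(
        np.random.SeedSequence([cohort.seed, _STREAM_SCENE, subject_index])
    )
    h, w = cohort.image_height, cohort.image_width
    cx = w / 2.0 + rng.uniform(-2, 2)
    cy = h / 2.0 + rng.uniform(-2, 2)
    radius = 0.42 * min(h, w) * rng.uniform(0.95, 1.05)

    hb_mult = rng.uniform(*cohort.hemoglobin_multiplier)
    water_mult = rng.uniform(*cohort.water_multiplier)
    lesions = []
    # one major lesion, one minor satellite, both safely inside the disc
    for label, frac, dist in (("major", 0.38, 0.35), ("minor", 0.22, 0.62)):
        ang = rng.uniform(0, 2 * np.pi)
        lcx = cx + dist * radius * np.cos(ang)
        lcy = cy + dist * radius * np.sin(ang)
        mean_r = frac * radius
        # clip the polygon radius so every vertex stays inside the disc
        max_r = radius - np.hypot(lcx - cx, lcy - cy) - 1.0
        poly = _star_polygon(rng, (lcx, lcy), min(mean_r, 0.9 * max_r))
        lesions.append(
            LesionRegion(
                label,
                poly,
                multipliers={"hbo2": hb_mult, "hb": hb_mult, "water": water_mult},
            )
        )

    spec = PhantomSpec(
        image_height=h,
        image_width=w,
        wavelength_grid=cohort.grid,
        disc_center=(cx, cy),
        disc_radius=radius,
        lesion_regions=lesions,
        baseline_concentrations={
            "hbo2": rng.uniform(0.25, 0.35),
            "hb": rng.uniform(0.2, 0.3),
            "water": rng.uniform(0.3, 0.4),
        },
        noise_sd=cohort.noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    cube, truth = generate_phantom_cube(spec)
    truth.subject_id = f"subject-{subject_index + 1:02d}"

    H_true = random_perspective(rng, cohort.view_scale)
    rgb, landmarks = generate_second_view(
        cube,
        H_true,
        scale=cohort.view_scale,
        noise_sd=cohort.landmark_noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    # examiners annotate in the colposcope frame: transfer truth there first
    colpo_shape = rgb.shape[:2]
    hinv = H_true.inverse()
    truth_colpo = AnnotationSet(
        subject_id=truth.subject_id,
        examiner_id="truth",
        masks={
            cls: warp_mask(hinv, m, colpo_shape) for cls, m in truth.masks.items()
        },
        frame="colposcope",
    )
    noise = ExaminerNoiseSpec(
        n_examiners=cohort.n_examiners,
        boundary_jitter_sd=cohort.boundary_jitter_sd,
        dilation_bias_range=cohort.dilation_bias_range,
        omission_probability=cohort.omission_probability,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    examiners = simulate_examiner_annotations(truth_colpo, noise)
    return SubjectScene(
        subject_id=truth.subject_id,
        cube=cube,
        truth=truth,
        examiner_annotations=examiners,
        landmarks=landmarks,
        H_true=H_true,
        colposcope_rgb=rgb,
        spec=spec,
    )


def generate_cohort(cohort: CohortSpec) -> list[SubjectScene]:
    """All subjects of a phantom cohort, reproducible from ``cohort.seed``."""
    return [generate_subject_scene(cohort, i) for i in range(cohort.n_subjects)]
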