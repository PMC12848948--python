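"""Synthetic microscopy scenes with exact ground truth.

Every pipeline stage in condensekit has a matching generator here:

* brightfield fields of view containing in-focus droplets (dark interior,
  bright 2-px rim — the typical slightly-defocused brightfield appearance
  of a refractile condensate), out-of-focus blurred droplets, a fixed
  optical speckle background shared between sample and reference, and
  camera noise;
* fluorescence condensate images with a known client enrichment factor E;
* localization point clouds of circular / linear / curved nucleoprotein
  filaments, filament bundles, and end-to-end tethered multimers carrying
  junction puncta in a second channel;
* blinking movies rendered from emitter positions (memoryless per-frame
  Bernoulli ON events, pixel-integrated Gaussian PSF, Poisson photons);
* tilted, noisy AFM height-map frame stacks with outlier frames.

Determinism contract: every generated object is a pure function of
``(spec, seed)``.  All randomness for one call flows from a single
``numpy.random.SeedSequence(seed)``; independent named child streams are
spawned for placement, sampling and noise so that changing one stage does
not perturb the others.  The brightfield speckle pattern is drawn from a
separate ``speckle_seed`` so a sample and its non-phase-separating
reference can share identical optics.

Coordinates are 0-based array indices with ``x`` = column and ``y`` = row;
pixel centers sit at integer coordinates; physical positions are in nm via
``pixel_size_nm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from condensekit.imageset import ImageSet
from condensekit.loctable import LocalizationTable

__all__ = [
    "BrightfieldSceneSpec",
    "CondensateSceneSpec",
    "FilamentSceneSpec",
    "BlinkMovieSpec",
    "SceneGroundTruth",
    "make_brightfield_set",
    "make_condensate_image",
    "make_filament_localizations",
    "make_emitter_field",
    "make_blink_movie",
    "make_afm_stack",
]


# ---------------------------------------------------------------------------
# ground truth container


@dataclass
class SceneGroundTruth:
    """Generator-side truth for a synthetic scene.

    Only the fields relevant to the generating call are populated.  Tests
    must read truth from here, never re-derive it from rendered images.
    """

    # brightfield / condensates
    droplets: pd.DataFrame | None = None  # columns: field, y, x, radius_px, in_focus
    label_mask: np.ndarray | None = None  # full condensate disks, labels 1..n
    interior_mask: np.ndarray | None = None  # labels with the 1-px edge band eroded
    background_mask: np.ndarray | None = None  # pixels ≥ 1 px outside every disk
    enrichment: float | None = None
    background_level: float | None = None

    # filaments
    filaments: list[dict] = field(default_factory=list)
    # each: {points: (n,2) nm [x, y], closed: bool, arc_length_nm: float,
    #        n_units: int, junction_arc_nm: list, bundle_id: int}
    junction_puncta_nm: np.ndarray | None = None  # (m, 2) punctum centers
    emitters_px: np.ndarray | None = None  # (n, 2) emitter [x, y] in px
    pixel_size_nm: float | None = None

    # blink movies
    on_events: pd.DataFrame | None = None  # frame, emitter, x, y, photons

    # AFM
    outlier_frames: list[int] = field(default_factory=list)
    tilt: tuple[float, float] | None = None

    def total_contour_length_nm(self) -> float:
        return float(sum(f["arc_length_nm"] for f in self.filaments))

    def to_dict(self) -> dict:
        """Scalar/tabular summary suitable for a YAML sidecar (masks omitted)."""
        out: dict = {}
        if self.droplets is not None:
            out["droplets"] = self.droplets.to_dict("records")
        if self.enrichment is not None:
            out["enrichment"] = float(self.enrichment)
        if self.background_level is not None:
            out["background_level"] = float(self.background_level)
        if self.filaments:
            out["filaments"] = [
                {
                    "closed": bool(f["closed"]),
                    "arc_length_nm": float(f["arc_length_nm"]),
                    "n_units": int(f["n_units"]),
                    "junction_arc_nm": [float(v) for v in f["junction_arc_nm"]],
                    "bundle_id": int(f["bundle_id"]),
                }
                for f in self.filaments
            ]
        if self.junction_puncta_nm is not None:
            out["junction_puncta_nm"] = self.junction_puncta_nm.tolist()
        if self.emitters_px is not None:
            out["emitters_px"] = self.emitters_px.tolist()
        if self.pixel_size_nm is not None:
            out["pixel_size_nm"] = float(self.pixel_size_nm)
        if self.on_events is not None:
            out["n_on_events"] = int(len(self.on_events))
        if self.outlier_frames:
            out["outlier_frames"] = [int(i) for i in self.outlier_frames]
        if self.tilt is not None:
            out["tilt"] = [float(self.tilt[0]), float(self.tilt[1])]
        return out

    def save_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    """Spawn n independent child generators from one root seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _check_shape(shape) -> tuple[int, int]:
    rows, cols = int(shape[0]), int(shape[1])
    if rows <= 0 or cols <= 0:
        raise ValueError(f"field_shape must be positive, got {shape!r}")
    return rows, cols


# ---------------------------------------------------------------------------
# brightfield


@dataclass(frozen=True)
class BrightfieldSceneSpec:
    """Defocused-brightfield droplet fields.

    ``rim_contrast`` and ``interior_contrast`` are fractions of the
    background level; the speckle pattern (smooth multiplicative texture of
    the optics) is a deterministic function of ``speckle_seed`` only, so a
    sample and its droplet-free reference can share it.
    """

    field_shape: tuple[int, int] = (768, 768)
    n_fields: int = 5
    n_droplets_in_focus: int = 20
    n_droplets_defocus: int = 0
    droplet_radius_px: tuple[float, float] = (3.0, 6.0)
    rim_contrast: float = 0.5
    interior_contrast: float = 0.15
    rim_width_px: float = 2.0
    defocus_sigma_px: float = 4.0
    speckle_amplitude: float = 0.05
    speckle_sigma_px: float = 3.0
    n_speckle_dots: int = 40
    speckle_dot_contrast: float = 0.4
    noise_sd: float = 10.0
    background_level: float = 1000.0
    seed: int = 0
    speckle_seed: int = 7_071

    def __post_init__(self):
        _check_shape(self.field_shape)
        if self.n_fields < 1:
            raise ValueError("n_fields must be >= 1")
        if self.n_droplets_in_focus < 0 or self.n_droplets_defocus < 0:
            raise ValueError("droplet counts must be >= 0")
        lo, hi = self.droplet_radius_px
        if lo <= 0 or hi < lo:
            raise ValueError("droplet_radius_px must be a positive (lo, hi) range")


def speckle_background(spec: BrightfieldSceneSpec) -> np.ndarray:
    """Fixed speckle texture of the optics, identical across all fields.

    Two components, both deterministic functions of ``speckle_seed`` only:
    a smooth Gaussian-filtered mottle and a sparse set of small sharp dots
    (dust and interference speckle carry sharp edges in real optics).  The
    sharp dots give a droplet-free field a positive edge fraction, which is
    what the reference normalization divides out.
    """
    rng = np.random.default_rng(spec.speckle_seed)
    rows, cols = spec.field_shape
    raw = ndimage.gaussian_filter(rng.standard_normal((rows, cols)), spec.speckle_sigma_px)
    sd = raw.std()
    if sd > 0:
        raw /= sd
    out = spec.background_level * spec.speckle_amplitude * raw
    yy, xx = np.mgrid[0:5, 0:5] - 2.0
    for _ in range(spec.n_speckle_dots):
        y = rng.uniform(3, rows - 4)
        x = rng.uniform(3, cols - 4)
        r = rng.uniform(0.8, 1.6)
        sign = rng.choice([-1.0, 1.0])
        dot = np.clip(r + 0.5 - np.hypot(yy - (y % 1), xx - (x % 1)), 0.0, 1.0)
        out[int(y) - 2 : int(y) + 3, int(x) - 2 : int(x) + 3] += (
            sign * spec.speckle_dot_contrast * spec.background_level * dot
        )
    return out


def _droplet_delta(spec: BrightfieldSceneSpec, r: float) -> np.ndarray:
    """Additive template of one droplet: dark interior, bright antialiased rim."""
    w = spec.rim_width_px
    half = int(np.ceil(r + 2))
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    d = np.hypot(yy, xx)
    total_cov = np.clip(r + 0.5 - d, 0.0, 1.0)
    inner_cov = np.clip(r - w + 0.5 - d, 0.0, 1.0)
    rim_cov = total_cov - inner_cov
    b = spec.background_level
    return spec.rim_contrast * b * rim_cov - spec.interior_contrast * b * inner_cov


def noise_free_brightfield_field(
    spec: BrightfieldSceneSpec, droplets: pd.DataFrame, field_index: int
) -> np.ndarray:
    """Render one field without camera noise (speckle included)."""
    rows, cols = spec.field_shape
    img = np.full((rows, cols), float(spec.background_level))
    img += speckle_background(spec)
    blur_canvas = np.zeros((rows, cols))
    sub = droplets[droplets["field"] == field_index]
    for _, drop in sub.iterrows():
        delta = _droplet_delta(spec, drop["radius_px"])
        half = delta.shape[0] // 2
        y, x = int(round(drop["y"])), int(round(drop["x"]))
        ys, xs = slice(y - half, y + half + 1), slice(x - half, x + half + 1)
        if drop["in_focus"]:
            img[ys, xs] += delta
        else:
            blur_canvas[ys, xs] += delta
    if spec.n_droplets_defocus:
        img += ndimage.gaussian_filter(blur_canvas, spec.defocus_sigma_px)
    return img


def make_brightfield_set(spec: BrightfieldSceneSpec) -> tuple[ImageSet, SceneGroundTruth]:
    """Generate ``spec.n_fields`` brightfield fields plus ground truth.

    In-focus droplets carry sharp rims whose gradients dominate the smooth
    speckle background; out-of-focus droplets are the same additive
    template convolved with a Gaussian of ``defocus_sigma_px``.
    """
    place_rng, noise_rng = _streams(spec.seed, 2)
    rows, cols = spec.field_shape
    r_lo, r_hi = spec.droplet_radius_px
    records = []
    for fi in range(spec.n_fields):
        for kind, n in (("focus", spec.n_droplets_in_focus), ("defocus", spec.n_droplets_defocus)):
            for _ in range(n):
                r = place_rng.uniform(r_lo, r_hi)
                margin = r + spec.rim_width_px + 4
                y = place_rng.uniform(margin, rows - margin)
                x = place_rng.uniform(margin, cols - margin)
                records.append(
                    {"field": fi, "y": y, "x": x, "radius_px": r, "in_focus": kind == "focus"}
                )
    droplets = pd.DataFrame(
        records, columns=["field", "y", "x", "radius_px", "in_focus"]
    )
    frames = np.empty((spec.n_fields, rows, cols))
    for fi in range(spec.n_fields):
        img = noise_free_brightfield_field(spec, droplets, fi)
        img += noise_rng.normal(0.0, spec.noise_sd, size=(rows, cols))
        frames[fi] = img
    truth = SceneGroundTruth(droplets=droplets, background_level=spec.background_level)
    return ImageSet(frames), truth


# ---------------------------------------------------------------------------
# fluorescence condensates


@dataclass(frozen=True)
class CondensateSceneSpec:
    """Fluorescent condensate field with known client enrichment E.

    ``enrichment`` is the ground-truth partition coefficient: interior mean
    intensity = E × background_level.  E = 1 means no enrichment.  A 1-px
    antialiasing band at each condensate edge is excluded from the
    ground-truth interior mask so noise-free intensity ratios are exact.
    """

    field_shape: tuple[int, int] = (256, 256)
    n_condensates: int = 10
    radius_px: tuple[float, float] = (5.0, 10.0)
    enrichment: float = 3.0
    background_level: float = 100.0
    noise_model: str = "none"  # none | gaussian | poisson
    noise_sd: float = 5.0  # gaussian model only
    seed: int = 0

    def __post_init__(self):
        _check_shape(self.field_shape)
        if self.enrichment < 0:
            raise ValueError("enrichment must be >= 0")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.n_condensates < 0:
            raise ValueError("n_condensates must be >= 0")


def make_condensate_image(spec: CondensateSceneSpec) -> tuple[np.ndarray, SceneGroundTruth]:
    """Render one condensate field and its label / interior / background masks.

    With ``noise_model='none'`` the mean intensity strictly inside each
    condensate equals ``enrichment × background_level`` exactly; only the
    declared 1-px edge-smoothing band deviates, and that band is excluded
    from ``truth.interior_mask``.
    """
    place_rng, noise_rng = _streams(spec.seed, 2)
    rows, cols = spec.field_shape
    r_lo, r_hi = spec.radius_px
    centers: list[tuple[float, float, float]] = []
    attempts = 0
    while len(centers) < spec.n_condensates and attempts < 50_000:
        attempts += 1
        r = place_rng.uniform(r_lo, r_hi)
        y = place_rng.uniform(r + 2, rows - r - 2)
        x = place_rng.uniform(r + 2, cols - r - 2)
        # non-overlapping with a 3-px moat so masks stay disjoint
        if all(np.hypot(y - cy, x - cx) > r + cr + 3 for cy, cx, cr in centers):
            centers.append((y, x, r))
    if len(centers) < spec.n_condensates:
        raise ValueError("could not place all condensates without overlap; "
                         "reduce n_condensates or radius range")

    yy, xx = np.mgrid[0:rows, 0:cols]
    cov = np.zeros((rows, cols))
    label = np.zeros((rows, cols), dtype=np.int32)
    interior = np.zeros((rows, cols), dtype=np.int32)
    outside = np.ones((rows, cols), dtype=bool)
    for i, (cy, cx, r) in enumerate(centers, start=1):
        d = np.hypot(yy - cy, xx - cx)
        cov = np.maximum(cov, np.clip(r + 0.5 - d, 0.0, 1.0))
        label[d <= r] = i
        interior[d <= r - 1.0] = i
        outside &= d >= r + 1.0

    b = spec.background_level
    image = b * (1.0 + (spec.enrichment - 1.0) * cov)
    if spec.noise_model == "gaussian":
        image = image + noise_rng.normal(0.0, spec.noise_sd, image.shape)
    elif spec.noise_model == "poisson":
        image = noise_rng.poisson(image).astype(float)

    truth = SceneGroundTruth(
        droplets=pd.DataFrame(centers, columns=["y", "x", "radius_px"]),
        label_mask=label,
        interior_mask=interior,
        background_mask=outside,
        enrichment=spec.enrichment,
        background_level=b,
    )
    return image, truth


# ---------------------------------------------------------------------------
# filament localizations


@dataclass(frozen=True)
class FilamentSceneSpec:
    """Localization point clouds of nucleoprotein filaments.

    A filament of ``n_units_tethered = k`` units is a single curve of total
    contour length ``k × unit`` carrying ``k − 1`` junctions; with
    ``puncta_at_junctions`` each junction contributes ``puncta_n_locs``
    events in a second channel.  ``bundle_multiplicity = m > 1`` renders m
    filaments crossing at a shared anchor point.  Localizations are
    arc-length-uniform with isotropic Gaussian jitter; the expected count
    per filament is ``localization_density × arc length``.

    Default unit preset: 2100 nm contour length (the length scale of a
    single RAD51-type nucleoprotein filament); ``unit_length_sd_nm`` adds
    filament-to-filament variability for population studies.
    """

    geometry: str = "line"  # circle | line | curve
    unit_contour_length_nm: float = 2100.0
    unit_length_sd_nm: float = 0.0
    n_units_tethered: int = 1
    bundle_multiplicity: int = 1
    localization_density: float = 0.1  # events per nm
    localization_sigma_nm: float = 15.0
    puncta_at_junctions: bool = False
    puncta_n_locs: int = 50
    puncta_sigma_nm: float = 20.0
    n_filaments: int = 1
    field_extent_nm: float = 20_000.0
    curve_amplitude_nm: float = 300.0
    pixel_size_nm: float = 130.0
    mean_photons: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if self.geometry not in ("circle", "line", "curve"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.localization_density <= 0:
            raise ValueError("localization_density must be > 0")
        if self.n_units_tethered < 1:
            raise ValueError("n_units_tethered must be >= 1")
        if self.bundle_multiplicity < 1:
            raise ValueError("bundle_multiplicity must be >= 1")
        if self.unit_contour_length_nm <= 0:
            raise ValueError("unit_contour_length_nm must be > 0")


def _dense_curve(spec: FilamentSceneSpec, length_nm: float, anchor, theta, rng,
                 step_nm: float = 2.0) -> np.ndarray:
    """Dense (n, 2) polyline [x, y] of exact arc length ``length_nm``.

    Curves are built in a local frame then resampled uniformly in arc
    length, so the ground-truth contour length is exact by construction.
    """
    if spec.geometry == "circle":
        radius = length_nm / (2.0 * np.pi)
        t = np.linspace(0.0, 2.0 * np.pi, max(int(length_nm / step_nm), 64) + 1)
        pts = np.column_stack([radius * np.cos(t), radius * np.sin(t)])
    else:
        n = max(int(length_nm / step_nm), 16) + 1
        # centered on the anchor so bundle members cross at their midpoints
        s = np.linspace(-0.5 * length_nm, 0.5 * length_nm, n)
        if spec.geometry == "line":
            pts = np.column_stack([s, np.zeros_like(s)])
        else:  # smooth curve: sinusoidal perpendicular displacement
            wavelength = max(length_nm / rng.uniform(1.5, 3.0), 1.0)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            disp = spec.curve_amplitude_nm * np.sin(2.0 * np.pi * s / wavelength + phase)
            pts = np.column_stack([s, disp])
            # resample to the requested arc length
            seg = np.hypot(*np.diff(pts, axis=0).T)
            cum = np.concatenate([[0.0], np.cumsum(seg)])
            target = np.linspace(0.0, length_nm, n)
            # walk the curve until the cumulative arc length reaches length_nm
            pts = np.column_stack(
                [np.interp(target, cum, pts[:, 0]), np.interp(target, cum, pts[:, 1])]
            )
    c, s_ = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s_], [s_, c]])
    return pts @ rot.T + np.asarray(anchor)


def _arc_positions(points: np.ndarray) -> np.ndarray:
    seg = np.hypot(*np.diff(points, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _point_at_arc(points: np.ndarray, cum: np.ndarray, s) -> np.ndarray:
    s = np.atleast_1d(np.asarray(s, dtype=float))
    return np.column_stack(
        [np.interp(s, cum, points[:, 0]), np.interp(s, cum, points[:, 1])]
    )


def make_filament_localizations(
    spec: FilamentSceneSpec,
) -> tuple[LocalizationTable, LocalizationTable, SceneGroundTruth]:
    """Generate filament and junction-puncta localization tables plus truth.

    Returns ``(filament_table, puncta_table, truth)``; the puncta table is
    empty unless ``puncta_at_junctions`` is set and k > 1.
    """
    geom_rng, samp_rng, punct_rng = _streams(spec.seed, 3)
    ext = spec.field_extent_nm
    truth = SceneGroundTruth(pixel_size_nm=spec.pixel_size_nm)
    filament_xy: list[np.ndarray] = []
    puncta_xy: list[np.ndarray] = []
    junction_centers: list[np.ndarray] = []

    for fi in range(spec.n_filaments):
        unit = spec.unit_contour_length_nm
        if spec.unit_length_sd_nm > 0:
            unit = max(geom_rng.normal(unit, spec.unit_length_sd_nm), 10.0)
        length = spec.n_units_tethered * unit
        margin = min(0.25 * ext, 2000.0)
        anchor = geom_rng.uniform(margin, ext - margin, size=2)
        for bi in range(spec.bundle_multiplicity):
            theta = geom_rng.uniform(0.0, 2.0 * np.pi)
            pts = _dense_curve(spec, length, anchor, theta, geom_rng)
            cum = _arc_positions(pts)
            junction_arc = [j * unit for j in range(1, spec.n_units_tethered)]
            truth.filaments.append(
                {
                    "points": pts,
                    "closed": spec.geometry == "circle",
                    "arc_length_nm": float(cum[-1]),
                    "n_units": spec.n_units_tethered,
                    "junction_arc_nm": junction_arc,
                    "bundle_id": fi,
                }
            )
            n_locs = samp_rng.poisson(spec.localization_density * cum[-1])
            s = samp_rng.uniform(0.0, cum[-1], size=n_locs)
            xy = _point_at_arc(pts, cum, s)
            xy += samp_rng.normal(0.0, spec.localization_sigma_nm, size=xy.shape)
            filament_xy.append(xy)
            if spec.puncta_at_junctions and junction_arc:
                centers = _point_at_arc(pts, cum, junction_arc)
                junction_centers.append(centers)
                for c in centers:
                    p = c + punct_rng.normal(
                        0.0, spec.puncta_sigma_nm, size=(spec.puncta_n_locs, 2)
                    )
                    puncta_xy.append(p)

    def _as_table(chunks: list[np.ndarray], rng) -> LocalizationTable:
        if chunks:
            xy = np.concatenate(chunks)
        else:
            xy = np.empty((0, 2))
        n = len(xy)
        photons = rng.poisson(spec.mean_photons, size=n).astype(float)
        photons = np.maximum(photons, 1.0)
        return LocalizationTable.from_arrays(
            frame=np.arange(n, dtype=np.int64),
            x=xy[:, 0] / spec.pixel_size_nm,
            y=xy[:, 1] / spec.pixel_size_nm,
            photons=photons,
            sx=np.full(n, 1.2),
            sy=np.full(n, 1.2),
            precision_nm=np.full(n, spec.localization_sigma_nm),
            pixel_size_nm=spec.pixel_size_nm,
        )

    table = _as_table(filament_xy, samp_rng)
    puncta = _as_table(puncta_xy, punct_rng)
    if junction_centers:
        truth.junction_puncta_nm = np.concatenate(junction_centers)
    truth.emitters_px = table.df[["x", "y"]].to_numpy()
    return table, puncta, truth


# ---------------------------------------------------------------------------
# blinking movies


@dataclass(frozen=True)
class BlinkMovieSpec:
    """Blinking-movie camera model.

    Binding-site blinking is memoryless: each emitter is ON in each frame
    with independent probability ``p_on``.  An ON event draws a Poisson
    photon count with mean ``mean_photons`` and distributes the photons
    multinomially over pixels according to a pixel-integrated 2-D Gaussian
    PSF, so the in-field frame sum conserves the drawn photon count exactly
    while per-pixel counts remain Poisson.  Read noise is additive Gaussian
    on top of a constant camera baseline.
    """

    field_shape: tuple[int, int] = (64, 64)
    n_frames: int = 100
    p_on: float = 0.05
    mean_photons: float = 1000.0
    psf_sigma_px: float = 1.2
    camera_baseline: float = 100.0
    read_noise_sd: float = 2.0
    pixel_size_nm: float = 130.0
    seed: int = 0

    def __post_init__(self):
        _check_shape(self.field_shape)
        if not 0.0 <= self.p_on <= 1.0:
            raise ValueError("p_on must be in [0, 1]")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def make_emitter_field(
    n_emitters: int,
    field_shape: tuple[int, int] = (64, 64),
    min_sep_px: float = 12.0,
    margin_px: float = 6.0,
    seed: int = 0,
    pixel_size_nm: float = 130.0,
) -> SceneGroundTruth:
    """Random emitter positions with a minimum pairwise separation."""
    rng = np.random.default_rng(seed)
    rows, cols = _check_shape(field_shape)
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n_emitters and attempts < 200_000:
        attempts += 1
        p = rng.uniform(
            [margin_px, margin_px], [cols - 1 - margin_px, rows - 1 - margin_px]
        )
        if all(np.hypot(*(p - q)) >= min_sep_px for q in pts):
            pts.append(p)
    if len(pts) < n_emitters:
        raise ValueError("field too crowded for requested min_sep_px")
    return SceneGroundTruth(
        emitters_px=np.array(pts).reshape(-1, 2), pixel_size_nm=pixel_size_nm
    )


def psf_pixel_probabilities(
    x0: float, y0: float, sigma: float, shape: tuple[int, int]
) -> np.ndarray:
    """Pixel-integrated 2-D Gaussian over an image of ``shape`` (sums to the
    in-field mass, ≤ 1 near borders)."""
    from scipy.special import erf

    rows, cols = shape
    xe = np.arange(cols + 1) - 0.5  # pixel i spans [i - 0.5, i + 0.5)
    ye = np.arange(rows + 1) - 0.5
    denom = sigma * np.sqrt(2.0)
    fx = 0.5 * (erf((xe[1:] - x0) / denom) - erf((xe[:-1] - x0) / denom))
    fy = 0.5 * (erf((ye[1:] - y0) / denom) - erf((ye[:-1] - y0) / denom))
    return np.outer(fy, fx)


def make_blink_movie(
    emitters: SceneGroundTruth | np.ndarray, spec: BlinkMovieSpec
) -> tuple[np.ndarray, SceneGroundTruth]:
    """Render a blinking movie from emitter positions.

    Returns the (n_frames, rows, cols) float stack plus a ground-truth
    record of every ON event (frame, emitter index, position, drawn
    photons).
    """
    xy = emitters.emitters_px if isinstance(emitters, SceneGroundTruth) else np.asarray(emitters)
    xy = xy.reshape(-1, 2)
    rows, cols = spec.field_shape
    if len(xy) and (
        xy[:, 0].min() < 0 or xy[:, 0].max() > cols - 1
        or xy[:, 1].min() < 0 or xy[:, 1].max() > rows - 1
    ):
        raise ValueError("emitter positions must lie within the field")
    blink_rng, photon_rng, noise_rng = _streams(spec.seed, 3)
    movie = np.full((spec.n_frames, rows, cols), float(spec.camera_baseline))
    events = []
    # precompute each emitter's in-field PSF probability map
    probs = [
        psf_pixel_probabilities(x, y, spec.psf_sigma_px, (rows, cols)) for x, y in xy
    ]
    flat_probs = []
    for p in probs:
        mass = p.sum()
        # append an off-field bin so truncated photons are genuinely lost
        flat_probs.append(np.concatenate([p.ravel(), [max(1.0 - mass, 0.0)]]))
    on = blink_rng.random((spec.n_frames, len(xy))) < spec.p_on
    for t in range(spec.n_frames):
        for e in np.flatnonzero(on[t]):
            n_ph = int(photon_rng.poisson(spec.mean_photons))
            if n_ph > 0:
                counts = photon_rng.multinomial(n_ph, flat_probs[e] / flat_probs[e].sum())
                movie[t] += counts[:-1].reshape(rows, cols)
            events.append(
                {"frame": t, "emitter": int(e), "x": xy[e, 0], "y": xy[e, 1], "photons": n_ph}
            )
    if spec.read_noise_sd > 0:
        movie += noise_rng.normal(0.0, spec.read_noise_sd, movie.shape)
    truth = SceneGroundTruth(
        emitters_px=xy,
        pixel_size_nm=spec.pixel_size_nm,
        on_events=pd.DataFrame(events, columns=["frame", "emitter", "x", "y", "photons"]),
    )
    return movie, truth


# ---------------------------------------------------------------------------
# AFM


def make_afm_stack(
    base_map: np.ndarray,
    tilt: tuple[float, float] = (0.0, 0.0),
    n_frames: int = 7,
    outlier_frames: int = 0,
    noise_sd: float = 0.0,
    outlier_amplitude: float = 50.0,
    seed: int = 0,
) -> tuple[np.ndarray, SceneGroundTruth]:
    """Tilted, noisy AFM frame stack with optional outlier frames.

    Each frame is ``base_map + a·x + b·y + noise``; outlier frames carry an
    additional large blob artifact.  ``outlier_frames`` must stay below
    half the stack so a median projection can reject them.
    """
    base_map = np.asarray(base_map, dtype=float)
    if base_map.ndim != 2:
        raise ValueError("base_map must be 2-D")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if outlier_frames >= n_frames / 2.0:
        raise ValueError(
            "outlier_frames must be < n_frames / 2 (median rejection contract)"
        )
    rng = np.random.default_rng(seed)
    rows, cols = base_map.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    a, b = tilt
    plane = a * xx + b * yy
    stack = np.empty((n_frames, rows, cols))
    which = sorted(rng.choice(n_frames, size=outlier_frames, replace=False).tolist())
    for t in range(n_frames):
        frame = base_map + plane
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, frame.shape)
        if t in which:
            cy, cx = rng.uniform(0, rows), rng.uniform(0, cols)
            blob = outlier_amplitude * np.exp(
                -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * (0.15 * min(rows, cols)) ** 2)
            )
            frame = frame + blob
        stack[t] = frame
    truth = SceneGroundTruth(outlier_frames=[int(i) for i in which], tilt=(float(a), float(b)))
    return stack, truth
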