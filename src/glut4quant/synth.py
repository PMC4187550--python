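"""Synthetic muscle-fibre image generator with machine-readable ground truth.

Emulates single-fibre confocal fields of skeletal muscle cross-sections:
one dominant fibre bounded by a bright dystrophin ring (the plasma-membrane,
PM, midline), a GLUT4 channel composed of large (>1 μm) and small (<1 μm)
clusters enriched at the fibre periphery and around nuclei on top of a
diffuse interior background, a bimodal MHCI channel separating type I from
type II fibres, and a DAPI channel of peripheral nuclei.

Every operation is deterministic given its seed; a full synthetic study is
derived from one master seed by stable spawn keys, so pre/post sections of
a subject share subject-level random factors (the within-subject design).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import polygon2mask

from .errors import InvalidParameterError, SpotPlacementError
from .imageio import CalibratedImage, write_image

LARGE, SMALL = "large", "small"
#: sampled diameters within this margin of the 1 μm class boundary are resampled
CLASS_GAP_UM = 0.05
#: smallest planted diameter; structures below ~2.5 px are left to the diffuse
#: background (sub-resolution clusters are not individually detectable)
MIN_DIAMETER_UM = 0.5


@dataclass
class TrueSpot:
    x: float
    y: float
    diameter_um: float
    size_class: str
    radial_depth_um: float


@dataclass
class Nucleus:
    x: float
    y: float
    radius_um: float


@dataclass
class NoiseModel:
    gaussian_sd: float = 2.0
    poisson: bool = False


@dataclass
class GroundTruth:
    """Geometry, content and rendering parameters of one synthetic fibre."""

    contour: np.ndarray            # (N, 2) float (x, y) px, implicitly closed
    shape: tuple[int, int]
    pixel_size: float              # μm/pixel
    fibre_type: str = "I"
    seed: int = 0
    nuclei: list[Nucleus] = field(default_factory=list)
    spots: list[TrueSpot] = field(default_factory=list)
    background_level: float = 20.0
    bg_peripheral_gain: float = 1.0   # background factor 1+g·exp(-depth/decay)
    bg_decay_um: float = 3.0
    spot_amplitude: float = 60.0
    intensity_scale: float = 1.0
    peripheral_boost: float = 0.0     # extra gain applied at depth <= zone
    peripheral_zone_um: float = 1.5

    _interior: np.ndarray | None = field(default=None, repr=False, compare=False)
    _depth_um: np.ndarray | None = field(default=None, repr=False, compare=False)

    def interior_mask(self) -> np.ndarray:
        """Boolean mask of pixels inside the contour (cached)."""
        if self._interior is None:
            poly = np.column_stack([self.contour[:, 1], self.contour[:, 0]])  # row, col
            self._interior = polygon2mask(self.shape, poly)
        return self._interior

    def depth_map_um(self) -> np.ndarray:
        """Distance (μm) of every pixel to the PM midline polyline (cached).

        Computed from a densely resampled rasterisation of the contour; the
        discretisation error is below ~0.3 px.
        """
        if self._depth_um is None:
            dense = resample_closed(self.contour, spacing_px=0.5)
            marker = np.zeros(self.shape, dtype=bool)
            rr = np.clip(np.round(dense[:, 1]).astype(int), 0, self.shape[0] - 1)
            cc = np.clip(np.round(dense[:, 0]).astype(int), 0, self.shape[1] - 1)
            marker[rr, cc] = True
            self._depth_um = distance_transform_edt(~marker) * self.pixel_size
        return self._depth_um

    def drop_caches(self):
        self._interior = None
        self._depth_um = None

    def to_dict(self) -> dict:
        return {
            "contour": self.contour.tolist(),
            "shape": list(self.shape),
            "pixel_size": self.pixel_size,
            "fibre_type": self.fibre_type,
            "seed": int(self.seed),
            "nuclei": [asdict(n) for n in self.nuclei],
            "spots": [asdict(s) for s in self.spots],
            "background_level": self.background_level,
            "bg_peripheral_gain": self.bg_peripheral_gain,
            "bg_decay_um": self.bg_decay_um,
            "spot_amplitude": self.spot_amplitude,
            "intensity_scale": self.intensity_scale,
            "peripheral_boost": self.peripheral_boost,
            "peripheral_zone_um": self.peripheral_zone_um,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["contour"] = np.asarray(d["contour"], dtype=float)
        d["shape"] = tuple(d["shape"])
        d["nuclei"] = [Nucleus(**n) for n in d["nuclei"]]
        d["spots"] = [TrueSpot(**s) for s in d["spots"]]
        return cls(**d)


def resample_closed(vertices: np.ndarray, *, n: int | None = None,
                    spacing_px: float | None = None) -> np.ndarray:
    """Resample a closed polyline to uniform arc-length spacing."""
    v = np.asarray(vertices, dtype=float)
    closed = np.vstack([v, v[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if n is None:
        n = max(8, int(np.ceil(total / spacing_px)))
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, s, closed[:, 0])
    y = np.interp(t, s, closed[:, 1])
    return np.column_stack([x, y])


def _rng(seed, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(key)))


# ---------------------------------------------------------------------------
# geometry


def generate_fibre_geometry(radius_um: float, irregularity: float,
                            pixel_size: float, seed: int, *,
                            fibre_type: str = "I", margin_um: float = 4.0,
                            n_nuclei: int | None = None,
                            **truth_kwargs) -> GroundTruth:
    """Generate a fibre contour, interior mask and peripheral nuclei.

    The contour's radial distance from its centroid is ``radius_um``
    modulated by a smooth random angular perturbation whose relative
    amplitude is at most ``irregularity``.
    """
    if not np.isfinite(radius_um) or radius_um < 5.0:
        raise InvalidParameterError(f"radius_um must be >= 5 μm, got {radius_um}")
    if pixel_size <= 0:
        raise InvalidParameterError(f"pixel_size must be > 0, got {pixel_size}")
    if not (0.0 <= irregularity < 1.0):
        raise InvalidParameterError(f"irregularity must be in [0,1), got {irregularity}")

    rng = _rng(seed, 1)
    r_px = radius_um / pixel_size
    margin_px = int(np.ceil(margin_um / pixel_size))
    half = int(np.ceil(r_px * (1.0 + irregularity))) + margin_px
    side = 2 * half
    cx = cy = half - 0.5

    n_theta = max(256, int(np.ceil(2 * np.pi * r_px / 1.5)))
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    if irregularity > 0:
        s = np.zeros_like(theta)
        for k in range(2, 9):
            a, b = rng.normal(0.0, 1.0 / k, size=2)
            s += a * np.cos(k * theta) + b * np.sin(k * theta)
        peak = np.max(np.abs(s))
        if peak > 0:
            s *= irregularity / peak
    else:
        s = np.zeros_like(theta)
        rng.normal(size=14)  # keep the stream aligned with the irregular case
    rho = r_px * (1.0 + s)
    contour = np.column_stack([cx + rho * np.cos(theta), cy + rho * np.sin(theta)])

    truth = GroundTruth(contour=contour, shape=(side, side), pixel_size=pixel_size,
                        fibre_type=fibre_type, seed=int(seed), **truth_kwargs)

    # peripheral nuclei, a few μm in from the membrane
    count = int(rng.integers(3, 9)) if n_nuclei is None else int(n_nuclei)
    angles = rng.uniform(0, 2 * np.pi, size=count)
    for ang in np.sort(angles):
        i = int(np.round(ang / (2 * np.pi) * n_theta)) % n_theta
        nucleus_r = rng.uniform(2.0, 3.5)
        depth = nucleus_r + rng.uniform(1.0, 3.0)
        pos = _inward_point(contour, i, depth / pixel_size)
        truth.nuclei.append(Nucleus(float(pos[0]), float(pos[1]), float(nucleus_r)))
    return truth


def _inward_point(contour: np.ndarray, i: int, depth_px: float) -> np.ndarray:
    n = len(contour)
    t = contour[(i + 1) % n] - contour[(i - 1) % n]
    norm = np.linalg.norm(t)
    if norm == 0:
        norm = 1.0
    nvec = np.array([t[1], -t[0]]) / norm
    centroid = contour.mean(axis=0)
    if np.dot(centroid - contour[i], nvec) < 0:
        nvec = -nvec
    return contour[i] + depth_px * nvec


# ---------------------------------------------------------------------------
# spots


def _sample_diameter(rng, mean, sd, size_class):
    """Sample a diameter consistent with its class, away from the boundary."""
    for _ in range(1000):
        d = rng.normal(mean, sd)
        if abs(d - 1.0) <= CLASS_GAP_UM or d < MIN_DIAMETER_UM:
            continue
        if size_class == LARGE and d > 1.0:
            return float(d)
        if size_class == SMALL and 0.0 < d < 1.0:
            return float(d)
    raise InvalidParameterError(
        f"diameter distribution ({mean}, {sd}) incompatible with class {size_class!r}")


def plant_spots(geometry: GroundTruth, n_large: int, n_small: int,
                large_diam_dist=(1.6, 0.25), small_diam_dist=(0.60, 0.08),
                peripheral_fraction: float = 0.3,
                perinuclear_fraction: float = 0.2,
                seed: int = 0, *, overlap_margin_um: float = 0.5,
                max_tries: int = 400) -> GroundTruth:
    """Populate a fibre with GLUT4 clusters of known position, size and class.

    ``peripheral_fraction`` of spots are placed within 1 μm radial depth of
    the PM midline, ``perinuclear_fraction`` within 2 μm of a nucleus, the
    remainder uniformly in the interior.  Spots are rejected and resampled
    when centres come closer than the sum of radii plus a safety margin, so
    the planted count equals the detectable count.
    """
    if n_large < 0 or n_small < 0:
        raise InvalidParameterError("spot counts must be >= 0")
    if not (0 <= peripheral_fraction <= 1 and 0 <= perinuclear_fraction <= 1):
        raise InvalidParameterError("placement fractions must lie in [0, 1]")
    if peripheral_fraction + perinuclear_fraction > 1 + 1e-12:
        raise InvalidParameterError("peripheral + perinuclear fraction must be <= 1")

    rng = _rng(geometry.seed, 2, seed)
    ps = geometry.pixel_size
    depth = geometry.depth_map_um()
    interior = geometry.interior_mask()
    inner = interior & (depth > 0.0)
    rows, cols = np.nonzero(inner)
    if rows.size == 0:
        raise InvalidParameterError("fibre interior is empty")

    placed: list[TrueSpot] = []
    classes = [LARGE] * n_large + [SMALL] * n_small
    dists = {LARGE: large_diam_dist, SMALL: small_diam_dist}

    def ok(x, y, d_um):
        for s in placed:
            min_sep = (d_um + s.diameter_um) / 2.0 + overlap_margin_um
            if (x - s.x) ** 2 + (y - s.y) ** 2 < (min_sep / ps) ** 2:
                return False
        return True

    n_contour = len(geometry.contour)
    for size_class in classes:
        mean, sd = dists[size_class]
        d_um = _sample_diameter(rng, mean, sd, size_class)
        placement = rng.random()
        success = False
        for _ in range(max_tries):
            if placement < peripheral_fraction:
                i = int(rng.integers(0, n_contour))
                target = rng.uniform(0.2, 1.0)
                pos = _inward_point(geometry.contour, i, target / ps)
            elif placement < peripheral_fraction + perinuclear_fraction and geometry.nuclei:
                nuc = geometry.nuclei[int(rng.integers(0, len(geometry.nuclei)))]
                ang = rng.uniform(0, 2 * np.pi)
                rad = nuc.radius_um + rng.uniform(0.0, 2.0)
                pos = np.array([nuc.x + rad / ps * np.cos(ang),
                                nuc.y + rad / ps * np.sin(ang)])
            else:
                j = int(rng.integers(0, rows.size))
                pos = np.array([cols[j] + rng.uniform(-0.5, 0.5),
                                rows[j] + rng.uniform(-0.5, 0.5)])
            r_i = int(np.clip(np.round(pos[1]), 0, geometry.shape[0] - 1))
            c_i = int(np.clip(np.round(pos[0]), 0, geometry.shape[1] - 1))
            if not inner[r_i, c_i]:
                continue
            pdepth = float(depth[r_i, c_i])
            if placement < peripheral_fraction and pdepth > 1.0:
                continue
            if placement >= peripheral_fraction + perinuclear_fraction and \
                    pdepth < d_um / 2.0 + 0.2:
                continue  # keep wholly interior spots clear of the membrane
            if ok(pos[0], pos[1], d_um):
                placed.append(TrueSpot(float(pos[0]), float(pos[1]),
                                       d_um, size_class, pdepth))
                success = True
                break
        if not success:
            raise SpotPlacementError(
                f"could not place a {size_class} spot after {max_tries} tries")

    return dataclasses.replace(geometry, spots=placed)


# ---------------------------------------------------------------------------
# rendering


def render_image(truth: GroundTruth, psf_sigma_um: float = 0.2,
                 noise: NoiseModel | None = None,
                 channel_gains: dict[str, float] | None = None,
                 band_width_px: float = 5.0,
                 image_id: str | None = None) -> CalibratedImage:
    """Render the four channels of a ground-truth fibre.

    GLUT4 = diffuse interior background (with a peripheral gradient) plus
    uniform disks for every planted spot, convolved with a Gaussian PSF;
    dystrophin = bright band of ``band_width_px`` centred on the contour;
    MHCI = high interior mean for type I, low for type II; DAPI = nuclear
    disks.  Noise (optional) is Gaussian and/or Poisson, seeded from the
    truth's seed, so noise-free renders are bit-reproducible.
    """
    if psf_sigma_um < 0:
        raise InvalidParameterError("psf_sigma_um must be >= 0")
    ps = truth.pixel_size
    shape = truth.shape
    interior = truth.interior_mask()
    depth = truth.depth_map_um()
    psf_px = psf_sigma_um / ps

    glut4 = np.zeros(shape, dtype=float)
    bg = truth.background_level * (1.0 + truth.bg_peripheral_gain *
                                   np.exp(-depth / truth.bg_decay_um))
    if truth.peripheral_boost:
        # diffuse-pool increase concentrated at the periphery: amplifies the
        # existing peripheral gradient, keeping its natural decay profile
        bg = truth.background_level * (
            1.0 + truth.bg_peripheral_gain * (1.0 + truth.peripheral_boost) *
            np.exp(-depth / truth.bg_decay_um))
    glut4[interior] = bg[interior]
    for s in truth.spots:
        rr, cc = draw_disk((s.y, s.x), max(s.diameter_um / 2.0 / ps, 0.6), shape=shape)
        glut4[rr, cc] += truth.spot_amplitude
    glut4 *= truth.intensity_scale

    dyst = np.zeros(shape, dtype=float)
    dyst[depth <= band_width_px / 2.0 * ps] = 100.0

    mhc1 = np.zeros(shape, dtype=float)
    mhc1[interior] = 150.0 if truth.fibre_type == "I" else 30.0

    dapi = np.zeros(shape, dtype=float)
    for n in truth.nuclei:
        rr, cc = draw_disk((n.y, n.x), n.radius_um / ps, shape=shape)
        dapi[rr, cc] = 120.0

    channels = {"glut4": glut4, "dystrophin": dyst, "mhc1": mhc1, "dapi": dapi}
    if psf_px > 0:
        for role in channels:
            channels[role] = gaussian_filter(channels[role], psf_px)
    if channel_gains:
        for role, gain in channel_gains.items():
            if role in channels:
                channels[role] = channels[role] * gain
    if noise is not None:
        for ci, role in enumerate(sorted(channels)):
            rng = _rng(truth.seed, 3, ci)
            img = channels[role]
            if noise.poisson:
                img = rng.poisson(np.clip(img, 0, None)).astype(float)
            if noise.gaussian_sd > 0:
                img = img + rng.normal(0.0, noise.gaussian_sd, size=shape)
            channels[role] = np.clip(img, 0.0, None)
    channels = {r: c.astype(np.float32) for r, c in channels.items()}
    return CalibratedImage(channels=channels, pixel_size=ps,
                           image_id=image_id or f"fibre-{truth.seed}")


# ---------------------------------------------------------------------------
# study generation


@dataclass
class EffectSizes:
    """Fractional pre→post changes planted for one training mode."""

    #: whole-fibre mean-intensity change; None = emergent (no global gain
    #: calibration, the change is whatever the other effects imply)
    intensity: float | None = 0.0
    large_count: float = 0.0
    large_size: float = 0.0         # mean large-spot area
    small_count: float = 0.0
    small_size: float = 0.0
    peripheral_intensity: float = 0.0    # diffuse-background gain at the PM
    peripheral_count_shift: float = 0.0  # added peripheral placement fraction


def default_effect_sizes() -> dict[str, EffectSizes]:
    """Planted training responses: endurance (ET) and sprint-interval (SIT).

    Magnitudes follow the type I fibre responses the method is meant to
    resolve: ET +15% whole-fibre intensity, +24% large-spot count, +10%
    mean large-spot size, +17% mean small-spot size; SIT +14%, +46%, +21%,
    +36%; no change in small-spot count for either mode.  ET additionally
    concentrates its intensity gain at the periphery; SIT's rise is more
    uniform across depth.
    """
    return {
        "ET": EffectSizes(intensity=0.15, large_count=0.24, large_size=0.10,
                          small_size=0.17, peripheral_intensity=0.35,
                          peripheral_count_shift=0.15),
        "SIT": EffectSizes(intensity=0.14, large_count=0.46, large_size=0.21,
                           small_size=0.36, peripheral_intensity=0.10,
                           peripheral_count_shift=0.05),
    }


@dataclass
class SynthStudyConfig:
    """Study design and imaging conditions for a synthetic training study."""

    n_subjects_per_mode: int = 8
    modes: tuple[str, ...] = ("ET", "SIT")
    fibres_per_section_per_type: int = 5
    replicates: int = 3
    effect_sizes: dict[str, EffectSizes] = field(default_factory=default_effect_sizes)
    seed: int = 0

    pixel_size: float = 0.2            # μm/pixel
    radius_um_mean: float = 32.0
    radius_um_sd: float = 2.0
    radius_um_range: tuple[float, float] = (28.0, 38.0)
    irregularity: float = 0.12
    mean_large_spots: float = 18.0
    mean_small_spots: float = 90.0
    large_diam_dist: tuple[float, float] = (1.6, 0.25)
    small_diam_dist: tuple[float, float] = (0.60, 0.08)
    peripheral_fraction: float = 0.3
    perinuclear_fraction: float = 0.2
    background_level: float = 20.0
    bg_peripheral_gain: float = 1.0
    bg_decay_um: float = 3.0
    spot_amplitude: float = 60.0
    peripheral_zone_um: float = 1.5
    psf_sigma_um: float = 0.2
    noise: NoiseModel | None = field(default_factory=NoiseModel)
    subject_sd: float = 0.10           # log-scale subject intensity factor
    section_sd: float = 0.05           # log-scale replicate(section) factor
    subject_count_sd: float = 0.10     # log-scale subject spot-abundance factor

    def validate(self):
        v = []
        if self.n_subjects_per_mode < 1:
            v.append("n_subjects_per_mode must be >= 1")
        if self.fibres_per_section_per_type < 1:
            v.append("fibres_per_section_per_type must be >= 1")
        if self.replicates < 1:
            v.append("replicates must be >= 1")
        for mode, eff in self.effect_sizes.items():
            for name, val in asdict(eff).items():
                if val is None:
                    continue
                if not np.isfinite(val) or val <= -1:
                    v.append(f"effect {mode}.{name} must be a finite fraction > -1")
        if v:
            raise InvalidParameterError("; ".join(v))


def _clipped_normal_area_um2(mean, sd):
    # E[pi/4 d^2] for d ~ N(mean, sd), ignoring the class clipping
    return np.pi / 4.0 * (mean ** 2 + sd ** 2)


def expected_flux_ratio(cfg: SynthStudyConfig, eff: EffectSizes) -> float:
    """Approximate post/pre ratio of whole-fibre mean intensity implied by
    the planted count/size/peripheral effects alone (before any global gain).

    Used to calibrate the post-training gain so the *measured* whole-fibre
    intensity change matches the configured ``intensity`` effect.
    """
    ps = cfg.pixel_size
    area_px = np.pi * (cfg.radius_um_mean / ps) ** 2
    bg_factor = 1.0 + cfg.bg_peripheral_gain * 2.0 * cfg.bg_decay_um / cfg.radius_um_mean
    bg_flux = cfg.background_level * bg_factor * area_px
    a_l = _clipped_normal_area_um2(*cfg.large_diam_dist) / ps ** 2
    a_s = _clipped_normal_area_um2(*cfg.small_diam_dist) / ps ** 2
    spot_pre = cfg.spot_amplitude * (cfg.mean_large_spots * a_l + cfg.mean_small_spots * a_s)
    spot_post = cfg.spot_amplitude * (
        cfg.mean_large_spots * (1 + eff.large_count) * a_l * (1 + eff.large_size)
        + cfg.mean_small_spots * (1 + eff.small_count) * a_s * (1 + eff.small_size))
    pre = bg_flux + spot_pre
    post = bg_flux + spot_post
    if eff.peripheral_intensity:
        # the boost amplifies the peripheral background gradient in place
        post_factor = 1.0 + cfg.bg_peripheral_gain * \
            (1.0 + eff.peripheral_intensity) * 2.0 * cfg.bg_decay_um / cfg.radius_um_mean
        post = post + cfg.background_level * area_px * (post_factor - bg_factor)
    return post / pre


@dataclass
class StudySet:
    """A generated study: manifest plus per-image ground truths.

    Images are rendered on demand (:meth:`render`) so arbitrarily large
    studies fit in memory; rendering is deterministic per image.
    """

    config: SynthStudyConfig
    manifest: pd.DataFrame
    truths: dict[str, GroundTruth]

    def render(self, image_id: str) -> CalibratedImage:
        truth = self.truths[image_id]
        img = render_image(truth, psf_sigma_um=self.config.psf_sigma_um,
                           noise=self.config.noise, image_id=image_id)
        truth.drop_caches()
        return img

    def truth_table(self) -> pd.DataFrame:
        """Per-image ground-truth summary for validation against pipeline output."""
        rows = []
        for _, m in self.manifest.iterrows():
            t = self.truths[m.image_id]
            large = [s for s in t.spots if s.size_class == LARGE]
            small = [s for s in t.spots if s.size_class == SMALL]
            rows.append({
                **m.to_dict(),
                "true_n_large": len(large),
                "true_n_small": len(small),
                "true_mean_large_area_um2": float(np.mean(
                    [np.pi / 4 * s.diameter_um ** 2 for s in large])) if large else np.nan,
                "true_mean_small_area_um2": float(np.mean(
                    [np.pi / 4 * s.diameter_um ** 2 for s in small])) if small else np.nan,
                "true_intensity_scale": t.intensity_scale,
                "true_peripheral_boost": t.peripheral_boost,
            })
        return pd.DataFrame(rows)

    def write(self, out_dir) -> Path:
        """Write TIFFs, JSON sidecars, ground-truth sidecars and manifest.csv."""
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "truth").mkdir(parents=True, exist_ok=True)
        manifest = self.manifest.copy()
        paths = []
        for image_id in manifest.image_id:
            img = self.render(image_id)
            path = out / "images" / f"{image_id}.tif"
            write_image(path, img)
            (out / "truth" / f"{image_id}.json").write_text(
                json.dumps(self.truths[image_id].to_dict()))
            paths.append(str(path.relative_to(out)))
        manifest["image_path"] = paths
        manifest.to_csv(out / "manifest.csv", index=False)
        return out / "manifest.csv"


def generate_study(config: SynthStudyConfig) -> StudySet:
    """Generate ground truths and a manifest for a full pre/post training study.

    For each subject × timepoint the design yields ``replicates ×
    fibres_per_section_per_type × 2`` fibre images (the default 3 × 5 × 2 =
    30, i.e. 15 type I and 15 type II fibres).  Post-training truths carry
    the configured effect sizes; subject- and section-level random factors
    are shared appropriately so the within-subject design is realistic.
    """
    config.validate()
    rows = []
    truths: dict[str, GroundTruth] = {}
    timepoints = ("pre", "post")
    for mode_i, mode in enumerate(config.modes):
        eff = config.effect_sizes.get(mode, EffectSizes())
        if eff.intensity is None:
            gain_post = 1.0
        else:
            gain_post = (1.0 + eff.intensity) / expected_flux_ratio(config, eff)
        for subj in range(config.n_subjects_per_mode):
            subject_id = f"{mode}{subj + 1:02d}"
            srng = _rng(config.seed, 10, mode_i, subj)
            subj_factor = float(np.exp(srng.normal(0.0, config.subject_sd)))
            subj_count = float(np.exp(srng.normal(0.0, config.subject_count_sd)))
            for tp_i, tp in enumerate(timepoints):
                post = tp == "post"
                for rep in range(config.replicates):
                    sec_rng = _rng(config.seed, 11, mode_i, subj, tp_i, rep)
                    sec_factor = float(np.exp(sec_rng.normal(0.0, config.section_sd)))
                    for type_i, ftype in enumerate(("I", "II")):
                        for fib in range(config.fibres_per_section_per_type):
                            key = (mode_i, subj, tp_i, rep, type_i, fib)
                            ss = np.random.SeedSequence(config.seed, spawn_key=key)
                            fseed = int(ss.generate_state(1)[0])
                            frng = _rng(config.seed, 12, *key)
                            radius = float(np.clip(
                                frng.normal(config.radius_um_mean, config.radius_um_sd),
                                *config.radius_um_range))
                            geo = generate_fibre_geometry(
                                radius, config.irregularity, config.pixel_size,
                                fseed, fibre_type=ftype,
                                background_level=config.background_level,
                                bg_peripheral_gain=config.bg_peripheral_gain,
                                bg_decay_um=config.bg_decay_um,
                                spot_amplitude=config.spot_amplitude,
                                peripheral_zone_um=config.peripheral_zone_um)
                            lam_l = config.mean_large_spots * subj_count * \
                                ((1 + eff.large_count) if post else 1.0)
                            lam_s = config.mean_small_spots * subj_count * \
                                ((1 + eff.small_count) if post else 1.0)
                            n_large = int(frng.poisson(lam_l))
                            n_small = int(frng.poisson(lam_s))
                            size_l = np.sqrt(1 + eff.large_size) if post else 1.0
                            size_s = np.sqrt(1 + eff.small_size) if post else 1.0
                            ld = (config.large_diam_dist[0] * size_l,
                                  config.large_diam_dist[1] * size_l)
                            sd_ = (config.small_diam_dist[0] * size_s,
                                   config.small_diam_dist[1] * size_s)
                            peri = config.peripheral_fraction + \
                                (eff.peripheral_count_shift if post else 0.0)
                            peri = min(peri, 1.0 - config.perinuclear_fraction)
                            truth = plant_spots(
                                geo, n_large, n_small, ld, sd_,
                                peri, config.perinuclear_fraction, seed=0)
                            truth.intensity_scale = subj_factor * sec_factor * \
                                (gain_post if post else 1.0)
                            truth.peripheral_boost = eff.peripheral_intensity if post else 0.0
                            truth.drop_caches()
                            image_id = (f"{subject_id}_{tp}_r{rep + 1}"
                                        f"_{ftype}_{fib + 1}")
                            truths[image_id] = truth
                            rows.append({
                                "subject_id": subject_id, "mode": mode,
                                "timepoint": tp, "replicate": rep + 1,
                                "fibre_index": fib + 1, "fibre_type": ftype,
                                "image_id": image_id,
                            })
    return StudySet(config=config, manifest=pd.DataFrame(rows), truths=truths)
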