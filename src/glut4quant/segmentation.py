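"""Active-contour segmentation of the dystrophin ring and fibre typing.

The dystrophin stain marks the sarcolemma as a bright closed band; a
classical parametric snake (internal tension/rigidity energy plus an
external image energy) is evolved from a polygon just outside the band
until it locks onto the band's midline, the approximate plasma-membrane
(PM) midline.  The external energy combines a line term (negative smoothed
intensity — a ridge attractor, required because the midline of a band is a
gradient-magnitude *minimum*) with the classical squared-gradient edge
term.  The update uses the standard semi-implicit scheme with cyclic
pentadiagonal internal-energy matrix, and vertices are resampled to
uniform arc length every iteration.

Fibre type is classified from the MHCI channel: mean intensity within the
intracellular mask, thresholded by Otsu's method over the per-fibre means
of a batch (type I above, type II below).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import (binary_dilation, binary_fill_holes,
                           distance_transform_edt, gaussian_filter,
                           map_coordinates)
from shapely.geometry import LineString
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label, regionprops

from .config import SnakeParams
from .errors import (DegenerateFibreError, InsufficientDataError,
                     SegmentationError)
from .synth import resample_closed


@dataclass
class ConvergenceReport:
    iterations: int = 0
    final_delta_px: float = np.inf
    converged: bool = False
    energy: list = field(default_factory=list)


@dataclass
class FibreContour:
    """Closed sub-pixel contour of one fibre (PM midline candidate)."""

    vertices: np.ndarray                 # (N, 2) float (x, y), implicitly closed
    convergence: ConvergenceReport = field(default_factory=ConvergenceReport)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if len(self.vertices) < 32:
            raise SegmentationError(
                f"contour needs >= 32 vertices, got {len(self.vertices)}")
        if self.enclosed_area() <= 0:
            raise SegmentationError("contour encloses no area")

    def enclosed_area(self) -> float:
        """Shoelace area in px² (orientation-independent)."""
        v = self.vertices
        x, y = v[:, 0], v[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)

    def is_simple(self) -> bool:
        ring = np.vstack([self.vertices, self.vertices[:1]])
        return LineString(ring).is_simple


@dataclass
class FibreROI:
    """Contour plus PM-band and intracellular masks for one fibre."""

    contour: FibreContour
    pm_band_mask: np.ndarray
    intracellular_mask: np.ndarray
    pixel_size: float
    fibre_type: str | None = None


def initial_contour(dystrophin: np.ndarray, *, min_area_px: int = 200,
                    dilate_px: int = 3, n_vertices: int | None = None) -> FibreContour:
    """Initial snake polygon: Otsu-threshold the dystrophin channel, keep the
    largest object, fill it, and take its boundary dilated outward by 3 px."""
    img = np.asarray(dystrophin, dtype=float)
    if img.max() <= img.min():
        raise SegmentationError("blank dystrophin channel")
    binary = img > threshold_otsu(img)
    lab = label(binary)
    props = regionprops(lab)
    props = [p for p in props if p.area >= min_area_px]
    if not props:
        raise SegmentationError(
            f"no dystrophin object with area >= {min_area_px} px")
    largest = max(props, key=lambda p: p.area)
    filled = binary_fill_holes(lab == largest.label)
    dilated = binary_dilation(filled, iterations=dilate_px)
    contours = find_contours(dilated.astype(float), 0.5)
    boundary = max(contours, key=len)          # (row, col)
    verts = np.column_stack([boundary[:, 1], boundary[:, 0]])
    if n_vertices is None:
        n_vertices = max(64, int(len(verts) / 3))
    verts = resample_closed(verts, n=n_vertices)
    return FibreContour(vertices=verts)


def _internal_matrix(n: int, alpha: float, beta: float) -> np.ndarray:
    """Cyclic pentadiagonal matrix of the membrane/thin-plate internal energy."""
    a = np.zeros(n)
    a[0] = 2 * alpha + 6 * beta
    a[1] = a[-1] = -alpha - 4 * beta
    a[2] = a[-2] = beta
    A = np.empty((n, n))
    for i in range(n):
        A[i] = np.roll(a, i)
    return A


def evolve_snake(dystrophin: np.ndarray, init: FibreContour,
                 params: SnakeParams | None = None) -> FibreContour:
    """Evolve a snake to the dystrophin ridge (PM midline).

    Minimises E = ∫ (α|v'|² + β|v''|²)/2 ds + ∫ E_ext(v) ds with
    E_ext = −(w_line·G_σ∗I + w_edge·|∇(G_σ∗I)|²), both image terms
    normalised to [0, 1].  Stops when the maximum vertex displacement per
    iteration drops below ``tol_px`` or at the iteration cap (the best
    contour is then returned with a warning and ``converged=False``).
    """
    p = params or SnakeParams()
    img = np.asarray(dystrophin, dtype=float)
    smooth = gaussian_filter(img, p.sigma_px)
    rng_span = smooth.max() - smooth.min()
    line = (smooth - smooth.min()) / rng_span if rng_span > 0 else smooth * 0.0
    gy, gx = np.gradient(line)
    edge = gx ** 2 + gy ** 2
    if edge.max() > 0:
        edge = edge / edge.max()
    ext = p.line_weight * line + p.edge_weight * edge    # to be maximised
    fy, fx = np.gradient(ext)

    v = np.array(init.vertices, dtype=float)
    n = len(v)
    A = _internal_matrix(n, p.alpha, p.beta)
    inv = np.linalg.inv(np.eye(n) + p.step * A)

    def external_force(verts):
        coords = [verts[:, 1], verts[:, 0]]                 # row, col
        fxv = map_coordinates(fx, coords, order=1, mode="nearest")
        fyv = map_coordinates(fy, coords, order=1, mode="nearest")
        return np.column_stack([fxv, fyv])

    def energy(verts):
        d1 = np.roll(verts, -1, axis=0) - verts
        d2 = np.roll(verts, -1, axis=0) - 2 * verts + np.roll(verts, 1, axis=0)
        e_int = 0.5 * (p.alpha * (d1 ** 2).sum() + p.beta * (d2 ** 2).sum())
        vals = map_coordinates(ext, [verts[:, 1], verts[:, 0]], order=1,
                               mode="nearest")
        return float(e_int - p.ext_weight * vals.sum())

    report = ConvergenceReport()
    report.energy.append(energy(v))
    for it in range(1, p.max_iter + 1):
        f = p.ext_weight * external_force(v)
        new = inv @ (v + p.step * f)
        delta = float(np.max(np.linalg.norm(new - v, axis=1)))
        v = resample_closed(new, n=n)
        report.iterations = it
        report.final_delta_px = delta
        report.energy.append(energy(v))
        if delta < p.tol_px:
            report.converged = True
            break
    if not report.converged:
        warnings.warn(f"snake did not converge in {p.max_iter} iterations "
                      f"(last displacement {report.final_delta_px:.3f} px)",
                      stacklevel=2)
    contour = FibreContour(vertices=v, convergence=report)
    if not contour.is_simple():
        repaired = resample_closed(gaussian_smooth_closed(v, 2.0), n=n)
        contour = FibreContour(vertices=repaired, convergence=report)
        if not contour.is_simple():
            raise SegmentationError("snake produced an unrepairable "
                                    "self-intersecting contour")
    return contour


def gaussian_smooth_closed(vertices: np.ndarray, sigma: float) -> np.ndarray:
    """Periodic Gaussian smoothing of a closed polyline (repair step)."""
    from scipy.ndimage import gaussian_filter1d
    return np.column_stack([
        gaussian_filter1d(vertices[:, 0], sigma, mode="wrap"),
        gaussian_filter1d(vertices[:, 1], sigma, mode="wrap"),
    ])


def contour_distance_px(contour: FibreContour, shape: tuple[int, int],
                        exact_below: float | None = None) -> np.ndarray:
    """Per-pixel distance (px) to the contour polyline.

    A dense rasterised marker plus an exact Euclidean distance transform
    gives ~0.3 px accuracy everywhere; when ``exact_below`` is set, pixels
    closer than that are refined by nearest-neighbour distance to a very
    finely resampled polyline (error < 0.05 px), which matters for thin
    sub-pixel band masks.
    """
    dense = resample_closed(contour.vertices, spacing_px=0.5)
    marker = np.zeros(shape, dtype=bool)
    rr = np.clip(np.round(dense[:, 1]).astype(int), 0, shape[0] - 1)
    cc = np.clip(np.round(dense[:, 0]).astype(int), 0, shape[1] - 1)
    marker[rr, cc] = True
    dist = distance_transform_edt(~marker)
    if exact_below is not None:
        from scipy.spatial import cKDTree

        fine = resample_closed(contour.vertices, spacing_px=0.1)
        sel_r, sel_c = np.nonzero(dist <= exact_below + 1.5)
        if sel_r.size:
            exact = cKDTree(fine).query(
                np.column_stack([sel_c, sel_r]), workers=1)[0]
            dist[sel_r, sel_c] = exact
    return dist


def make_masks(contour: FibreContour, band_halfwidth_px: float,
               shape: tuple[int, int], pixel_size: float) -> FibreROI:
    """Build the PM-band and intracellular masks from a converged contour.

    PM band = pixels whose centre lies within ``band_halfwidth_px`` of the
    contour polyline (total band thickness twice the half-width);
    intracellular = pixels inside the contour beyond the band.
    """
    dist = contour_distance_px(contour, shape, exact_below=band_halfwidth_px)
    interior = polygon2mask(shape, np.column_stack([contour.vertices[:, 1],
                                                    contour.vertices[:, 0]]))
    pm_band = dist <= band_halfwidth_px
    intracellular = interior & ~pm_band
    if not intracellular.any():
        raise DegenerateFibreError(
            "PM band covers the whole fibre; fibre too small for "
            f"band half-width {band_halfwidth_px} px")
    return FibreROI(contour=contour, pm_band_mask=pm_band,
                    intracellular_mask=intracellular, pixel_size=pixel_size)


def segment_fibre(dystrophin: np.ndarray, band_halfwidth_px: float,
                  pixel_size: float, params: SnakeParams | None = None) -> FibreROI:
    """Initialise, evolve and mask in one call (largest object only)."""
    init = initial_contour(dystrophin)
    contour = evolve_snake(dystrophin, init, params)
    return make_masks(contour, band_halfwidth_px, dystrophin.shape, pixel_size)


def mhc1_mean(mhc1: np.ndarray, roi: FibreROI) -> float:
    """Mean MHCI intensity over the intracellular mask of one fibre."""
    if not roi.intracellular_mask.any():
        raise DegenerateFibreError("empty intracellular mask")
    return float(np.asarray(mhc1, dtype=float)[roi.intracellular_mask].mean())


def classify_fibre_types(means, threshold: float | None = None) -> list[str]:
    """Classify a batch of fibres as type I/II from mean MHCI intensities.

    Default strategy: Otsu's threshold over the batch of per-fibre means
    (bimodal assumption); a fixed ``threshold`` may be supplied instead, in
    which case a single fibre is acceptable.
    """
    means = np.asarray(list(means), dtype=float)
    if threshold is None:
        if means.size < 2:
            raise InsufficientDataError(
                "batch Otsu fibre typing needs >= 2 fibres; supply a fixed threshold")
        threshold = threshold_otsu(means, nbins=128)
    return ["I" if m > threshold else "II" for m in means]
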