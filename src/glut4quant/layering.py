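"""Concentric 1 μm layers from a Euclidean distance map of the fibre.

Distances are measured from the inner edge of the PM band (not the contour
midline), so layer 1 is the first intracellular 1 μm shell immediately
adjacent to the PM layer.  Layer k collects intracellular pixels with
(k−1)·t < d ≤ k·t; pixels deeper than n·t form the residual core.  Layers
that do not close into a full annulus (irregular or small fibres) are
emitted with ``complete=False`` rather than dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt, label

from .errors import DegenerateFibreError
from .segmentation import FibreROI

CORE_INDEX = -1  # sentinel layer index for the residual core


@dataclass
class LayerSet:
    """PM band plus ordered concentric intracellular layer masks."""

    pm_layer: np.ndarray                       # mask, layer index 0
    intracellular_layers: list[np.ndarray]     # index 1..n, 1 adjacent to PM
    core_mask: np.ndarray
    pixel_size: float
    thickness_um: float
    complete_flags: list[bool] = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        return len(self.intracellular_layers)

    def layer(self, index: int) -> np.ndarray:
        """Mask by layer index: 0 = PM band, 1..n = shells, CORE_INDEX = core."""
        if index == 0:
            return self.pm_layer
        if index == CORE_INDEX:
            return self.core_mask
        return self.intracellular_layers[index - 1]

    def indices(self):
        return [0] + list(range(1, self.n_layers + 1))

    @property
    def layer_areas_um2(self) -> list[float]:
        """Areas (μm²) of the PM layer followed by layers 1..n."""
        return [layer_area(self.layer(i), self.pixel_size) for i in self.indices()]

    def label_image(self) -> np.ndarray:
        """Labelled mask: 0 exterior, 1 PM band, 2..n+1 layers, n+2 core."""
        lab = np.zeros(self.pm_layer.shape, dtype=np.uint8)
        lab[self.pm_layer] = 1
        for k, mask in enumerate(self.intracellular_layers, start=2):
            lab[mask] = k
        lab[self.core_mask] = self.n_layers + 2
        return lab


def distance_map(roi: FibreROI) -> np.ndarray:
    """Euclidean distance (μm) of every intracellular pixel from the inner
    edge of the PM band; NaN outside the intracellular mask."""
    if not roi.intracellular_mask.any():
        raise DegenerateFibreError("empty intracellular mask")
    d = distance_transform_edt(roi.intracellular_mask) * roi.pixel_size
    out = np.full(roi.intracellular_mask.shape, np.nan)
    out[roi.intracellular_mask] = d[roi.intracellular_mask]
    return out


def _is_complete_annulus(layer_mask: np.ndarray, deeper_mask: np.ndarray) -> bool:
    """A layer is a complete annulus iff removing it disconnects all deeper
    pixels from the image border (flood-fill test)."""
    if not layer_mask.any():
        return False
    if not deeper_mask.any():
        return True
    open_space = ~layer_mask
    lab, _ = label(open_space)
    border_labels = np.unique(np.concatenate([
        lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]]))
    border_labels = border_labels[border_labels > 0]
    deeper_labels = np.unique(lab[deeper_mask])
    return not np.any(np.isin(deeper_labels, border_labels))


def build_layers(roi: FibreROI, n_layers: int = 20,
                 thickness_um: float = 1.0) -> LayerSet:
    """Build the PM layer plus ``n_layers`` concentric shells of
    ``thickness_um`` from the distance map; small fibres simply yield empty
    trailing layers, flagged incomplete."""
    if n_layers < 1:
        raise DegenerateFibreError("n_layers must be >= 1")
    dmap = distance_map(roi)
    d = np.where(np.isnan(dmap), -1.0, dmap)
    layers = []
    flags = []
    for k in range(1, n_layers + 1):
        mask = (d > (k - 1) * thickness_um) & (d <= k * thickness_um)
        layers.append(mask)
    core = d > n_layers * thickness_um
    for k, mask in enumerate(layers, start=1):
        deeper = d > k * thickness_um
        flags.append(_is_complete_annulus(mask, deeper))
    return LayerSet(pm_layer=roi.pm_band_mask, intracellular_layers=layers,
                    core_mask=core, pixel_size=roi.pixel_size,
                    thickness_um=thickness_um, complete_flags=flags)


def layer_area(mask: np.ndarray, pixel_size: float) -> float:
    """Mask area in μm² (pixel count × pixel_size²); warns on empty masks
    because densities over a zero area are undefined."""
    count = int(np.count_nonzero(mask))
    if count == 0:
        warnings.warn("empty layer mask: area is 0, densities undefined",
                      stacklevel=2)
    return count * pixel_size ** 2
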