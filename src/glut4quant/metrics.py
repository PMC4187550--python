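"""Per-fibre and per-layer GLUT4 quantities.

Whole-fibre fluorescence intensity is measured on the *raw* GLUT4 channel
within the intracellular region of the dystrophin mask — no preprocessing
is applied before intensity analysis, and the detection-only
:class:`~glut4quant.spots.FilteredChannel` type is rejected by these
functions so the two data paths cannot be confused.  Mean spot size is
total spot staining area divided by spot count (reported missing, not
zero, for an empty class).  Layered metrics report, for the PM layer and
each concentric shell, the mean raw intensity and the large-spot count
per layer area.  Tables can be normalised to a reference group (the
pre-training type I mean for whole-fibre metrics, the pre-training PM
layer for layered metrics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateFibreError, InvalidParameterError
from .layering import CORE_INDEX, LayerSet, layer_area
from .segmentation import FibreROI
from .spots import FilteredChannel, SpotSet


def _require_raw(channel):
    if isinstance(channel, FilteredChannel):
        raise InvalidParameterError(
            "intensity metrics must be computed on the raw channel, "
            "not the detection-filtered one")
    return np.asarray(channel, dtype=float)


@dataclass
class FibreMetrics:
    """Whole-fibre quantities for one fibre image."""

    fibre_id: str
    mean_intensity: float
    fibre_area_um2: float
    large_count: int
    small_count: int
    large_density_per_um2: float
    small_density_per_um2: float
    large_total_area_um2: float
    small_total_area_um2: float
    mean_large_size_um2: float      # NaN when large_count == 0
    mean_small_size_um2: float      # NaN when small_count == 0

    def to_dict(self) -> dict:
        return dict(vars(self))


def fibre_mean_intensity(glut4_raw, roi: FibreROI) -> float:
    """Arithmetic mean of raw GLUT4 intensity over the intracellular mask."""
    img = _require_raw(glut4_raw)
    if not roi.intracellular_mask.any():
        raise DegenerateFibreError("empty intracellular mask")
    return float(img[roi.intracellular_mask].mean())


def fibre_spot_metrics(spots: SpotSet, fibre_area_um2: float,
                       mean_intensity: float = np.nan,
                       fibre_id: str | None = None) -> FibreMetrics:
    """Per-class spot count, density, total area, and mean size
    (= total area / count, the study's definition)."""
    if fibre_area_um2 <= 0:
        raise DegenerateFibreError("fibre area must be > 0")
    out = {}
    for cls in ("large", "small"):
        group = spots.by_class(cls)
        count = len(group)
        total = float(sum(s.area_um2 for s in group))
        out[cls] = (count, total, total / count if count else np.nan)
    return FibreMetrics(
        fibre_id=fibre_id if fibre_id is not None else spots.fibre_id,
        mean_intensity=mean_intensity,
        fibre_area_um2=fibre_area_um2,
        large_count=out["large"][0], small_count=out["small"][0],
        large_density_per_um2=out["large"][0] / fibre_area_um2,
        small_density_per_um2=out["small"][0] / fibre_area_um2,
        large_total_area_um2=out["large"][1],
        small_total_area_um2=out["small"][1],
        mean_large_size_um2=out["large"][2],
        mean_small_size_um2=out["small"][2],
    )


def layer_metrics(glut4_raw, spots: SpotSet, layers: LayerSet,
                  fibre_id: str = "") -> pd.DataFrame:
    """One row per emitted layer (PM = index 0, shells 1..n): mean raw
    intensity, large-spot count and large-spot count per layer area."""
    img = _require_raw(glut4_raw)
    assigned = [s.layer_index for s in spots.spots]
    if any(a is None for a in assigned):
        raise InvalidParameterError("spots must be layer-assigned first")
    rows = []
    for idx in layers.indices():
        mask = layers.layer(idx)
        area = layer_area(mask, layers.pixel_size) if mask.any() else 0.0
        n_large = sum(1 for s in spots.spots
                      if s.layer_index == idx and s.size_class == "large")
        rows.append({
            "image_id": fibre_id or spots.fibre_id,
            "layer_index": idx,
            "layer_area_um2": area,
            "mean_intensity": float(img[mask].mean()) if mask.any() else np.nan,
            "large_count": n_large,
            "large_count_per_um2": n_large / area if area > 0 else np.nan,
            "complete": True if idx == 0 else layers.complete_flags[idx - 1],
        })
    return pd.DataFrame(rows)


def core_large_count(spots: SpotSet) -> int:
    """Large spots assigned beyond the last concentric layer."""
    return sum(1 for s in spots.spots
               if s.layer_index == CORE_INDEX and s.size_class == "large")


def normalize_to_reference(table: pd.DataFrame, value_cols,
                           reference: pd.Series | np.ndarray,
                           percent: bool = False) -> pd.DataFrame:
    """Divide value columns by the mean of the reference rows.

    ``reference`` is a boolean row selector; each value column is divided
    by the mean of that column over the reference rows (×100 when
    ``percent``).  The reference group thereby normalises itself to mean
    1.0 (or 100) exactly.
    """
    ref = np.asarray(reference, dtype=bool)
    if ref.sum() == 0:
        raise InvalidParameterError("empty reference group")
    out = table.copy()
    scale = 100.0 if percent else 1.0
    for col in np.atleast_1d(value_cols):
        denom = table.loc[ref, col].mean()
        if not np.isfinite(denom) or denom == 0:
            raise InvalidParameterError(
                f"reference mean of {col!r} is zero or undefined")
        out[col] = table[col] / denom * scale
    return out
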