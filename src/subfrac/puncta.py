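"""Thresholding, pixel colocalization and neuropil-level quantification.

This is the first of the two measurement macros: binarize both channels
plane by plane with thresholds derived from negative-control tissue, count
receptor pixels (the "total" pool over the whole imaged field, i.e. the
neuropil), count receptor∧marker pixels (the synaptic pool), and optionally
count connected components as a punctum-level measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import measure as skmeasure

from .errors import ConfigurationError, ValidationError
from .io import ConfocalStack


@dataclass
class ThresholdSpec:
    """Per-channel binarization thresholds.

    ``method`` records how the cutoffs were obtained (``fixed`` or
    ``control_mean_plus_k_sd``); ``min_component_px`` is the size floor for
    connected-component (punctum) counts.
    """

    receptor_threshold: float
    marker_threshold: float
    method: str = "fixed"
    k: float = 3.0
    min_component_px: int = 4

    def __post_init__(self) -> None:
        if self.receptor_threshold < 0 or self.marker_threshold < 0:
            raise ValidationError("thresholds must be >= 0")
        if self.method not in ("fixed", "control_mean_plus_k_sd"):
            raise ValidationError(f"unknown threshold method {self.method!r}")
        if self.method == "control_mean_plus_k_sd" and self.k <= 0:
            raise ValidationError("k must be positive")
        if self.min_component_px < 1:
            raise ValidationError("min_component_px must be >= 1")


@dataclass
class PunctaMeasurement:
    """Per-plane and aggregate pixel/component counts for one stack."""

    per_plane: pd.DataFrame  # columns: z, receptor_px, marker_px, coloc_px
    totals: dict             # receptor_px_total, marker_px_total, coloc_px_total
    components: dict | None = None  # receptor_component_count, coloc_component_count


def derive_threshold(control_stacks: Sequence[ConfocalStack], channel: str,
                     k: float) -> float:
    """Intensity cutoff from negative-control stacks: mean + k·sd.

    Pools every voxel of the named channel across all controls and returns
    ``mean + k * population_sd``.  Deterministic; duplicating a control
    leaves the threshold unchanged.
    """
    if len(control_stacks) == 0:
        raise ValidationError("need at least one control stack")
    if k <= 0:
        raise ValidationError("k must be positive")
    values = np.concatenate([
        np.asarray(s.channel(channel), dtype=np.float64).ravel()
        for s in control_stacks
    ])
    return float(values.mean() + k * values.std(ddof=0))


def binarize(plane: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask of pixels strictly exceeding the cutoff."""
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    return np.asarray(plane) > threshold


def colocalize(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Pixel-wise AND of two equal-shape boolean masks."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValidationError(
            f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}"
        )
    return mask_a & mask_b


def count_components(mask: np.ndarray, min_component_px: int = 1) -> int:
    """Number of 8-connected in-plane components of at least the floor size."""
    labels, n = skmeasure.label(mask, connectivity=2, return_num=True)
    if min_component_px <= 1:
        return int(n)
    sizes = np.bincount(labels.ravel())[1:]
    return int(np.count_nonzero(sizes >= min_component_px))


def neuropil_measures(stack: ConfocalStack, thresholds: ThresholdSpec,
                      with_components: bool = False) -> PunctaMeasurement:
    """Quantify total and colocalized receptor signal over every z-plane.

    Each plane ("field of the z-stack") is binarized independently; totals
    are the column sums over planes.  With ``with_components=True`` the
    receptor and colocalized masks are additionally reduced to 8-connected
    component counts (summed over planes) with the configured size floor.
    """
    receptor = stack.channel("receptor")
    marker = stack.channel("marker")
    rows = []
    receptor_components = 0
    coloc_components = 0
    for z in range(stack.n_planes):
        r_mask = binarize(receptor[z], thresholds.receptor_threshold)
        m_mask = binarize(marker[z], thresholds.marker_threshold)
        c_mask = colocalize(r_mask, m_mask)
        rows.append({
            "z": z,
            "receptor_px": int(r_mask.sum()),
            "marker_px": int(m_mask.sum()),
            "coloc_px": int(c_mask.sum()),
        })
        if with_components:
            receptor_components += count_components(
                r_mask, thresholds.min_component_px)
            coloc_components += count_components(
                c_mask, thresholds.min_component_px)
    per_plane = pd.DataFrame(rows, columns=["z", "receptor_px", "marker_px",
                                            "coloc_px"])
    totals = {
        "receptor_px_total": int(per_plane["receptor_px"].sum()),
        "marker_px_total": int(per_plane["marker_px"].sum()),
        "coloc_px_total": int(per_plane["coloc_px"].sum()),
    }
    components = None
    if with_components:
        components = {
            "receptor_component_count": receptor_components,
            "coloc_component_count": coloc_components,
        }
    return PunctaMeasurement(per_plane=per_plane, totals=totals,
                             components=components)
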