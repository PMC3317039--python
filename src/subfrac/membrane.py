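"""The image-based subcellular fraction: membrane band extraction and counts.

This is the second measurement macro.  It selects the z-plane with the
highest receptor/marker colocalization, obtains the somatic contour (a
manually traced polygon takes priority; otherwise the marker ring is traced
automatically), rasterizes a band of fixed physical thickness (default 2 μm)
centered on the contour — the "image-based subcellular fraction" — and
splits receptor pixels inside the band into synaptic (marker-colocalized)
and extrasynaptic (marker-free) pools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage as ndi
from skimage import measure as skmeasure
from skimage.morphology import convex_hull_image

from .errors import TraceFailureError, ValidationError
from .io import ConfocalStack
from .puncta import ThresholdSpec, binarize, colocalize


@dataclass
class Contour:
    """Closed somatic membrane polygon in pixel coordinates (y, x)."""

    vertices: np.ndarray  # (N, 2) float, ordered
    source: str = "manual"  # or "auto_traced"
    closed: bool = True

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValidationError("contour vertices must be an (N, 2) array")
        if len(self.vertices) < 3:
            raise ValidationError("contour needs at least 3 vertices")
        ring = shapely.LinearRing(self.vertices[:, ::-1])  # shapely wants (x, y)
        if not ring.is_valid:
            raise ValidationError("contour polygon is self-intersecting")

    @property
    def centroid(self) -> tuple[float, float]:
        c = shapely.LinearRing(self.vertices[:, ::-1]).centroid
        return float(c.y), float(c.x)


@dataclass
class MembraneFraction:
    """Band mask of stated physical thickness plus the two membrane pools."""

    plane_index: int
    contour: Contour
    band_mask: np.ndarray
    band_thickness_um: float
    synaptic_px: int
    extrasynaptic_px: int
    synaptic_mask: np.ndarray | None = None
    extrasynaptic_mask: np.ndarray | None = None


def select_max_coloc_plane(stack: ConfocalStack,
                           thresholds: ThresholdSpec) -> int:
    """z index with the most receptor∧marker pixels; ties → lowest index."""
    receptor = stack.channel("receptor")
    marker = stack.channel("marker")
    counts = [
        int(colocalize(binarize(receptor[z], thresholds.receptor_threshold),
                       binarize(marker[z], thresholds.marker_threshold)).sum())
        for z in range(stack.n_planes)
    ]
    return int(np.argmax(counts))


def trace_membrane(marker_plane: np.ndarray, threshold: float,
                   min_component_px: int = 64,
                   max_vertices: int = 256) -> Contour:
    """Trace the somatic outline from the marker ring in one plane.

    Thresholds the plane, keeps every connected component above the size
    floor (the ring may be interrupted at synapse-free stretches of
    membrane, so it need not be one component), fills their union to its
    convex hull (the soma is convex; ring gaps would otherwise leak through
    ``binary_fill_holes``), and returns the outer boundary polygon
    simplified to at most ``max_vertices`` vertices.  Raises
    :class:`TraceFailureError` when no component reaches
    ``min_component_px`` — callers with a manual contour should fall back
    to it.
    """
    mask = binarize(marker_plane, threshold)
    labels, n = skmeasure.label(mask, connectivity=2, return_num=True)
    if n == 0:
        raise TraceFailureError("no signal above threshold; trace manually")
    sizes = np.bincount(labels.ravel())[1:]
    if sizes.max() < min_component_px:
        raise TraceFailureError(
            f"largest component has {sizes.max()} px "
            f"(< {min_component_px}); trace manually"
        )
    keep = np.flatnonzero(sizes >= min_component_px) + 1
    hull = convex_hull_image(np.isin(labels, keep))
    contours = skmeasure.find_contours(hull.astype(float), 0.5)
    boundary = max(contours, key=len)
    tolerance = 0.0
    simplified = boundary
    while len(simplified) > max_vertices:
        tolerance = tolerance + 0.25
        simplified = skmeasure.approximate_polygon(boundary, tolerance)
    # find_contours repeats the first vertex at the end of a closed loop.
    if np.allclose(simplified[0], simplified[-1]):
        simplified = simplified[:-1]
    return Contour(vertices=simplified, source="auto_traced")


def band_from_contour(contour: Contour, thickness_um: float,
                      pixel_size_um: float,
                      image_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize the membrane band: pixels within ``thickness/2`` of the trace.

    Distances from pixel centers to the closed polyline are exact (shapely),
    in physical units, so the band is centered on the traced membrane with
    half its thickness on either side.
    """
    if thickness_um <= 0:
        raise ValidationError("thickness_um must be positive")
    if pixel_size_um <= 0:
        raise ValidationError("pixel_size_um must be positive")
    if thickness_um < pixel_size_um:
        raise ValidationError(
            f"band thickness {thickness_um} μm is below one pixel "
            f"({pixel_size_um} μm)"
        )
    ny, nx = image_shape
    ring = shapely.LinearRing(contour.vertices[:, ::-1])
    yy, xx = np.mgrid[0:ny, 0:nx]
    points = shapely.points(np.stack([xx.ravel(), yy.ravel()], axis=1))
    dist_px = shapely.distance(points, ring).reshape(ny, nx)
    return dist_px * pixel_size_um <= thickness_um / 2


def membrane_measures(
    stack: ConfocalStack,
    thresholds: ThresholdSpec,
    contour: Contour | None = None,
    thickness_um: float = 2.0,
    plane_override: int | None = None,
    keep_masks: bool = True,
) -> MembraneFraction:
    """Run the full membrane macro on one stack.

    A supplied (manual) contour takes priority over automated tracing; the
    optional ``plane_override`` mirrors the supervised plane-selection step
    and replaces the automatic max-colocalization choice when given.
    """
    if plane_override is not None:
        if not 0 <= plane_override < stack.n_planes:
            raise ValidationError("plane_override out of range")
        plane = int(plane_override)
    else:
        plane = select_max_coloc_plane(stack, thresholds)
    marker_plane = stack.channel("marker")[plane]
    if contour is None:
        try:
            contour = trace_membrane(marker_plane, thresholds.marker_threshold)
        except TraceFailureError as err:
            raise TraceFailureError(
                f"automatic trace failed on plane {plane} ({err}); supply a "
                "manually traced contour"
            ) from err
    band = band_from_contour(contour, thickness_um, stack.pixel_size_um,
                             stack.plane_shape)
    r_mask = binarize(stack.channel("receptor")[plane],
                      thresholds.receptor_threshold)
    m_mask = binarize(marker_plane, thresholds.marker_threshold)
    synaptic = r_mask & m_mask & band
    extrasynaptic = r_mask & ~m_mask & band
    return MembraneFraction(
        plane_index=plane,
        contour=contour,
        band_mask=band,
        band_thickness_um=thickness_um,
        synaptic_px=int(synaptic.sum()),
        extrasynaptic_px=int(extrasynaptic.sum()),
        synaptic_mask=synaptic if keep_masks else None,
        extrasynaptic_mask=extrasynaptic if keep_masks else None,
    )


def recover_scene_counts(
    stack: ConfocalStack,
    thresholds: ThresholdSpec,
    ring_thickness_um: float = 2.0,
    membrane_tol_um: float = 1.5,
    thickness_um: float = 2.0,
) -> dict:
    """Punctum-level per-class counts for validating synthetic scenes.

    Labels the thresholded receptor channel in 3D (26-connectivity, size
    floor from ``thresholds``) and classifies each component: overlapping
    thresholded marker signal → synaptic; otherwise, in-plane radial distance
    of its centroid from the traced membrane centerline within
    ``membrane_tol_um`` → extrasynaptic; else intracellular.  This validation
    view complements the per-plane pixel macros; it is how the generator's
    planted counts are checked against what the imaging model lets through.
    """
    plane = select_max_coloc_plane(stack, thresholds)
    contour = trace_membrane(stack.channel("marker")[plane],
                             thresholds.marker_threshold)
    cy, cx = contour.centroid
    radii = np.hypot(contour.vertices[:, 0] - cy, contour.vertices[:, 1] - cx)
    # the trace follows the ring's outer edge; step back half a ring thickness
    centerline_px = float(radii.mean()) - (ring_thickness_um / 2) / stack.pixel_size_um

    r_mask = stack.channel("receptor") > thresholds.receptor_threshold
    m_mask = stack.channel("marker") > thresholds.marker_threshold
    labels, n = skmeasure.label(r_mask, connectivity=3, return_num=True)
    counts = {"synaptic": 0, "extrasynaptic": 0, "intracellular": 0}
    if n == 0:
        return counts
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    overlaps = ndi.sum_labels(m_mask.astype(np.float64), labels,
                              index=np.arange(1, n + 1))
    centroids = ndi.center_of_mass(r_mask, labels, index=np.arange(1, n + 1))
    tol_px = membrane_tol_um / stack.pixel_size_um
    for size, overlap, (zc, yc, xc) in zip(sizes, overlaps, centroids):
        if size < thresholds.min_component_px:
            continue
        if overlap > 0.25 * size:
            counts["synaptic"] += 1
        elif abs(np.hypot(yc - cy, xc - cx) - centerline_px) <= tol_px:
            counts["extrasynaptic"] += 1
        else:
            counts["intracellular"] += 1
    return counts
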