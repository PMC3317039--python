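"""Ground-truthed synthetic confocal scenes and dose-response cohorts.

A scene emulates a single large ventral motor neuron (soma diameter > 40 μm)
outlined by a presynaptic-marker ring, with receptor puncta planted in three
pools:

``synaptic``
    receptor blob centered on the marker-ring centerline where marker signal
    is present (receptor and marker colocalize there);
``extrasynaptic``
    receptor blob centered on the ring centerline inside a planted gap of the
    marker ring (membrane receptor with no presynaptic terminal);
``intracellular``
    receptor blob in the soma interior, away from the membrane.

All on-ring puncta sit in a single "equator" plane so that the plane of
maximal receptor/marker colocalization is known by construction.  Channels
are optionally blurred with a Gaussian PSF and corrupted with Poisson and/or
Gaussian read noise.  The pre-PSF, pre-noise per-class receptor contributions
are retained in the ground truth so tests can compare measured pixel sets
against planted footprints exactly.

Cohorts assign per-neuron planted counts from a dose model with a U-shaped
dose effect, an injected/contralateral side factor whose contralateral spread
grows with dose, and negative-binomial between-neuron overdispersion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ConfocalStack, SceneMetadata

PUNCTUM_CLASSES = ("synaptic", "extrasynaptic", "intracellular")


@dataclass
class SceneParams:
    """Parameters of one synthetic scene.

    ``punctum_radius_um`` is the Gaussian σ of a planted blob.  With the
    default amplitude and integer quantization a blob's above-background
    footprint has radius σ·sqrt(2·ln(2·amplitude)) ≈ 0.85 μm, which is kept
    strictly inside the 2 μm marker ring so membrane pools are exactly
    recoverable (see docs/methods.md).
    """

    image_shape: tuple[int, int, int] = (9, 192, 192)  # (z, y, x)
    pixel_size_um: float = 0.25
    z_step_um: float = 0.5
    soma_diameter_um: float = 42.0
    ring_thickness_um: float = 2.0
    ring_amplitude: float = 150.0
    n_synaptic: int = 12
    n_extrasynaptic: int = 8
    n_intracellular: int = 15
    n_marker_only: int = 4
    punctum_radius_um: float = 0.25
    punctum_amplitude: float = 150.0
    psf_sigma_um: tuple[float, float] = (0.2, 0.4)  # (lateral, axial)
    apply_psf: bool = True
    background_level: float = 20.0
    noise_model: str = "poisson"  # poisson | gaussian | poisson+gaussian | none
    gaussian_sd: float = 3.0
    gap_halfwidth_um: float = 2.0
    min_arc_um: float = 4.5
    interior_margin_um: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.soma_diameter_um <= 40:
            raise ValidationError("soma_diameter_um must exceed 40 μm")
        if min(self.n_synaptic, self.n_extrasynaptic, self.n_intracellular,
               self.n_marker_only) < 0:
            raise ValidationError("puncta counts must be >= 0")
        if min(self.psf_sigma_um) <= 0:
            raise ValidationError("psf sigmas must be positive")
        if self.noise_model not in ("poisson", "gaussian", "poisson+gaussian", "none"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        ny, nx = self.image_shape[1], self.image_shape[2]
        extent_um = min(ny, nx) * self.pixel_size_um
        if self.soma_diameter_um + 2 * 2.0 > extent_um:
            raise ValidationError(
                f"soma ({self.soma_diameter_um} μm + 2 μm clearance) does not fit "
                f"into a {extent_um:.1f} μm field"
            )

    @property
    def ring_radius_px(self) -> float:
        """Ring centerline radius in pixels (the soma membrane)."""
        return (self.soma_diameter_um / 2) / self.pixel_size_um


@dataclass
class GroundTruth:
    """Everything a scene's generator knows that the pipeline must recover."""

    punctum_table: pd.DataFrame  # columns: class, z, y, x, radius_um
    contour_true: np.ndarray     # (N, 2) float (y, x) membrane polygon, peak plane
    counts_true: dict            # class -> planted count
    peak_plane_true: int
    center_px: tuple[float, float]          # (y, x) soma center
    ring_radius_px: float                    # centerline radius
    ring_outer_radius_px: float
    class_fields: dict = field(default_factory=dict)  # class -> (z,y,x) float32
    background_level: float = 0.0

    def class_footprint(self, cls: str, threshold: float) -> np.ndarray:
        """Planted boolean footprint of one class at a given intensity cutoff.

        Reproduces the renderer's quantization (background + contribution,
        rounded) so the comparison with measured masks is exact on noiseless,
        unblurred scenes.
        """
        total = self.background_level + self.class_fields[cls]
        return np.round(total).astype(np.int64) > threshold


def _add_blob(canvas: np.ndarray, yc: float, xc: float, sigma_px: float,
              amplitude: float, truncate: float = 4.5) -> None:
    """Accumulate a truncated 2D Gaussian blob onto a plane, in place."""
    ny, nx = canvas.shape
    r = int(math.ceil(truncate * sigma_px))
    y0, y1 = max(0, int(yc) - r), min(ny, int(yc) + r + 1)
    x0, x1 = max(0, int(xc) - r), min(nx, int(xc) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (yy - yc) ** 2 + (xx - xc) ** 2
    blob = amplitude * np.exp(-d2 / (2 * sigma_px ** 2))
    blob[d2 > (truncate * sigma_px) ** 2] = 0.0
    canvas[y0:y1, x0:x1] += blob


def _ring_angles(params: SceneParams, rng: np.random.Generator) -> dict:
    """Assign angular slots on the ring to the three on-ring roles.

    Slots are equally spaced with a random global rotation and a per-slot
    jitter bounded so that the minimum arc separation is respected; classes
    are assigned by random permutation.
    """
    n = params.n_synaptic + params.n_extrasynaptic + params.n_marker_only
    out = {"synaptic": [], "extrasynaptic": [], "marker_only": []}
    if n == 0:
        return out
    circumference = 2 * math.pi * params.ring_radius_px * params.pixel_size_um
    spacing = circumference / n
    if spacing < params.min_arc_um:
        raise ValidationError(
            f"{n} on-ring puncta need {n * params.min_arc_um:.0f} μm of ring; "
            f"only {circumference:.0f} μm available"
        )
    jitter_um = max(0.0, (spacing - params.min_arc_um) / 2)
    rotation = rng.uniform(0, 2 * math.pi)
    angles = []
    for i in range(n):
        arc = i * spacing + rng.uniform(-jitter_um, jitter_um)
        angles.append(rotation + 2 * math.pi * arc / circumference)
    labels = (["synaptic"] * params.n_synaptic
              + ["extrasynaptic"] * params.n_extrasynaptic
              + ["marker_only"] * params.n_marker_only)
    rng.shuffle(labels)
    for angle, label in zip(angles, labels):
        out[label].append(angle)
    return out


def _sample_interior(params: SceneParams, rng: np.random.Generator,
                     n: int) -> list[tuple[int, float, float]]:
    """Rejection-sample well-separated interior punctum positions (z, y, x)."""
    nz = params.image_shape[0]
    cy = params.image_shape[1] / 2
    cx = params.image_shape[2] / 2
    max_r_px = params.ring_radius_px - (
        params.ring_thickness_um / 2 + params.interior_margin_um
    ) / params.pixel_size_um
    if n > 0 and max_r_px <= 0:
        raise ValidationError("soma interior too small for intracellular puncta")
    min_sep_um = 2.5
    placed: list[tuple[int, float, float]] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > 20000:
            raise ValidationError("could not place intracellular puncta; too crowded")
        z = int(rng.integers(0, nz))
        rho = max_r_px * math.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * math.pi)
        y, x = cy + rho * math.sin(theta), cx + rho * math.cos(theta)
        ok = True
        for (z2, y2, x2) in placed:
            dz_um = (z - z2) * params.z_step_um
            dr_um = math.hypot(y - y2, x - x2) * params.pixel_size_um
            if math.hypot(dz_um, dr_um) < min_sep_um:
                ok = False
                break
        if ok:
            placed.append((z, y, x))
    return placed


def generate_scene(params: SceneParams) -> tuple[ConfocalStack, GroundTruth]:
    """Render one two-channel scene and its ground truth.

    Identical ``params`` (including ``seed``) give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = params.image_shape
    cy, cx = ny / 2, nx / 2
    R = params.ring_radius_px
    half_ring_px = (params.ring_thickness_um / 2) / params.pixel_size_um
    sigma_px = params.punctum_radius_um / params.pixel_size_um
    peak_plane = nz // 2

    receptor = np.zeros((nz, ny, nx), dtype=np.float64)
    marker = np.zeros((nz, ny, nx), dtype=np.float64)
    class_fields = {cls: np.zeros((nz, ny, nx), dtype=np.float32)
                    for cls in PUNCTUM_CLASSES}

    # Marker ring: hard-edged annulus on every plane (somatic cylinder),
    # with full-thickness angular gaps carved at extrasynaptic sites.
    yy, xx = np.mgrid[0:ny, 0:nx]
    rho = np.hypot(yy - cy, xx - cx)
    theta = np.arctan2(yy - cy, xx - cx)
    annulus = np.abs(rho - R) <= half_ring_px

    slots = _ring_angles(params, rng)
    gap_half_rad = params.gap_halfwidth_um / (R * params.pixel_size_um)
    ring_mask = annulus.copy()
    for angle in slots["extrasynaptic"]:
        delta = np.angle(np.exp(1j * (theta - angle)))
        ring_mask &= np.abs(delta) > gap_half_rad
    marker += params.ring_amplitude * ring_mask[None, :, :]

    rows = []

    def on_ring_xy(angle: float) -> tuple[float, float]:
        return cy + R * math.sin(angle), cx + R * math.cos(angle)

    for angle in slots["synaptic"]:
        y, x = on_ring_xy(angle)
        _add_blob(class_fields["synaptic"][peak_plane], y, x, sigma_px,
                  params.punctum_amplitude)
        _add_blob(marker[peak_plane], y, x, sigma_px, params.punctum_amplitude)
        rows.append(("synaptic", peak_plane, y, x, params.punctum_radius_um))
    for angle in slots["extrasynaptic"]:
        y, x = on_ring_xy(angle)
        _add_blob(class_fields["extrasynaptic"][peak_plane], y, x, sigma_px,
                  params.punctum_amplitude)
        rows.append(("extrasynaptic", peak_plane, y, x, params.punctum_radius_um))
    for angle in slots["marker_only"]:
        y, x = on_ring_xy(angle)
        _add_blob(marker[peak_plane], y, x, sigma_px, params.punctum_amplitude)
    for (z, y, x) in _sample_interior(params, rng, params.n_intracellular):
        _add_blob(class_fields["intracellular"][z], y, x, sigma_px,
                  params.punctum_amplitude)
        rows.append(("intracellular", z, y, x, params.punctum_radius_um))

    for cls in PUNCTUM_CLASSES:
        receptor += class_fields[cls]
    receptor += params.background_level
    marker += params.background_level

    if params.apply_psf:
        from scipy.ndimage import gaussian_filter
        sig_lat, sig_ax = params.psf_sigma_um
        sigmas = (sig_ax / params.z_step_um,
                  sig_lat / params.pixel_size_um,
                  sig_lat / params.pixel_size_um)
        receptor = gaussian_filter(receptor, sigmas, mode="reflect")
        marker = gaussian_filter(marker, sigmas, mode="reflect")

    def corrupt(channel: np.ndarray) -> np.ndarray:
        out = channel
        if params.noise_model in ("poisson", "poisson+gaussian"):
            out = rng.poisson(np.clip(out, 0, None)).astype(np.float64)
        if params.noise_model in ("gaussian", "poisson+gaussian"):
            out = out + rng.normal(0.0, params.gaussian_sd, size=out.shape)
        return out

    receptor = corrupt(receptor)
    marker = corrupt(marker)
    voxels = np.stack([
        np.clip(np.round(receptor), 0, 65535).astype(np.uint16),
        np.clip(np.round(marker), 0, 65535).astype(np.uint16),
    ])

    punctum_table = pd.DataFrame(
        rows, columns=["class", "z", "y", "x", "radius_um"]
    )
    counts = {cls: int((punctum_table["class"] == cls).sum())
              for cls in PUNCTUM_CLASSES}
    contour_angles = np.linspace(0, 2 * math.pi, 256, endpoint=False)
    contour_true = np.stack([
        cy + R * np.sin(contour_angles), cx + R * np.cos(contour_angles)
    ], axis=1)

    stack = ConfocalStack(voxels, ["receptor", "marker"],
                          params.pixel_size_um, params.z_step_um)
    truth = GroundTruth(
        punctum_table=punctum_table,
        contour_true=contour_true,
        counts_true=counts,
        peak_plane_true=peak_plane,
        center_px=(cy, cx),
        ring_radius_px=R,
        ring_outer_radius_px=R + half_ring_px,
        class_fields=class_fields,
        background_level=params.background_level,
    )
    return stack, truth


# -- dose model and cohorts ----------------------------------------------------

#: Default multiplicative dose effects (relative to vehicle) per pool for the
#: low/mid/high doses.  The total and extrasynaptic pools are U-shaped
#: (mid < baseline < low < high); the synaptic pool rises mainly at the high
#: dose.  These are simulation parameters, not measured biology.
DEFAULT_EFFECTS = {
    0.01: {"total": 1.3, "synaptic": 1.1, "extrasynaptic": 1.3},
    0.1:  {"total": 0.8, "synaptic": 1.0, "extrasynaptic": 0.8},
    1.0:  {"total": 1.8, "synaptic": 2.0, "extrasynaptic": 1.8},
}

#: Fraction of the injected-side effect reaching the contralateral hemicord.
#: Near-total spread at the high dose, little at the low dose.
DEFAULT_SPREAD = {0.01: 0.1, 0.1: 0.3, 1.0: 1.0}


@dataclass
class DoseModel:
    """Per-neuron planted-count model across doses and hemicord sides.

    ``dispersion`` is the negative-binomial overdispersion ``a`` in
    ``var = μ·(1 + a·μ)``; ``a = 0`` is the deterministic limit (counts equal
    ``round(μ)`` exactly).
    """

    doses_um: tuple[float, ...] = (0.01, 0.1, 1.0)
    baseline_counts: dict = field(default_factory=lambda: {
        "synaptic": 12, "extrasynaptic": 8, "intracellular": 15})
    effects: dict = field(default_factory=lambda: {
        d: dict(v) for d, v in DEFAULT_EFFECTS.items()})
    spread: dict = field(default_factory=lambda: dict(DEFAULT_SPREAD))
    dispersion: float = 0.05

    def __post_init__(self) -> None:
        if len(self.doses_um) == 0:
            raise ValidationError("dose set must not be empty")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")

    @property
    def baseline_total(self) -> float:
        return float(sum(self.baseline_counts.values()))

    def _factors(self, dose_um: float) -> dict:
        """Per-pool multiplicative factors at one dose (1.0 for vehicle)."""
        eff = self.effects.get(dose_um, {"total": 1.0, "synaptic": 1.0,
                                         "extrasynaptic": 1.0})
        base = self.baseline_counts
        # The intracellular factor is derived so the configured *total*
        # factor is honored given the synaptic/extrasynaptic factors.
        intra = (eff["total"] * self.baseline_total
                 - eff["synaptic"] * base["synaptic"]
                 - eff["extrasynaptic"] * base["extrasynaptic"]
                 ) / base["intracellular"]
        if intra < 0:
            raise ValidationError("inconsistent dose factors: negative "
                                  "intracellular pool")
        return {"synaptic": eff["synaptic"],
                "extrasynaptic": eff["extrasynaptic"],
                "intracellular": intra}

    def pool_means(self, dose_um: float, side: str) -> dict:
        """Expected planted counts per pool for one neuron."""
        factors = self._factors(dose_um)
        if side == "contralateral":
            s = self.spread.get(dose_um, 0.0)
            factors = {k: 1.0 + s * (v - 1.0) for k, v in factors.items()}
        return {k: self.baseline_counts[k] * v for k, v in factors.items()}

    def sample_pool_counts(self, dose_um: float, side: str,
                           rng: np.random.Generator) -> dict:
        means = self.pool_means(dose_um, side)
        out = {}
        for pool, mu in means.items():
            if self.dispersion == 0 or mu == 0:
                out[pool] = int(round(mu))
            else:
                r = 1.0 / self.dispersion  # NB size parameter
                p = r / (r + mu)
                out[pool] = int(rng.negative_binomial(r, p))
        return out


def distance_grid(neurons_per_side: int) -> np.ndarray:
    """Rostrocaudal sampling offsets on the 100 μm grid spanning ±600 μm.

    13 neurons per side give the full −600…600 grid; fewer give an evenly
    spaced, grid-aligned subset.
    """
    if neurons_per_side < 1:
        raise ValidationError("neurons_per_side must be >= 1")
    if neurons_per_side > 13:
        raise ValidationError("at most 13 sites fit on the ±600 μm, 100 μm grid")
    if neurons_per_side == 1:
        return np.array([0.0])
    raw = np.linspace(-600, 600, neurons_per_side)
    return np.round(raw / 100) * 100


def sample_cohort_counts(
    dose_model: DoseModel,
    n_subjects_per_dose: int,
    neurons_per_side: int,
    seed: int,
) -> pd.DataFrame:
    """Draw planted per-neuron counts for a full cohort, without imaging.

    Returns one row per neuron with design columns (``subject_id``,
    ``dose_um``, ``side``, ``distance_um``) and planted counts per pool plus
    ``total_count``.  This is the sampling layer used for statistical
    calibration work, where rendering images would add nothing.
    """
    if n_subjects_per_dose < 1:
        raise ValidationError("n_subjects_per_dose must be >= 1")
    rng = np.random.default_rng(seed)
    distances = distance_grid(neurons_per_side)
    rows = []
    subject_counter = 0
    for dose in dose_model.doses_um:
        for _ in range(n_subjects_per_dose):
            subject_counter += 1
            sid = f"s{subject_counter:03d}"
            for side in ("injected", "contralateral"):
                for dist in distances:
                    counts = dose_model.sample_pool_counts(dose, side, rng)
                    rows.append({
                        "subject_id": sid,
                        "dose_um": dose,
                        "side": side,
                        "distance_um": float(dist),
                        "synaptic_count": counts["synaptic"],
                        "extrasynaptic_count": counts["extrasynaptic"],
                        "intracellular_count": counts["intracellular"],
                        "total_count": sum(counts.values()),
                    })
    return pd.DataFrame(rows)


def generate_cohort(
    dose_model: DoseModel,
    n_subjects_per_dose: int,
    neurons_per_side: int,
    scene_params: SceneParams,
    seed: int,
) -> list[tuple[ConfocalStack, GroundTruth, SceneMetadata]]:
    """Generate a full imaged cohort: one scene per neuron.

    Per-neuron planted counts come from the dose model; sides and distances
    follow the within-subject sampling design (every subject contributes both
    hemicords, one neuron per 100 μm grid site).  Reproducible under ``seed``.
    """
    counts = sample_cohort_counts(dose_model, n_subjects_per_dose,
                                  neurons_per_side, seed)
    scene_seeds = np.random.SeedSequence(seed).generate_state(len(counts))
    # The ring holds a bounded number of well-separated on-ring puncta;
    # extreme negative-binomial draws are clipped to that capacity (the
    # planted ground truth records the clipped values).
    circumference_um = math.pi * scene_params.soma_diameter_um
    capacity = int(circumference_um // scene_params.min_arc_um)
    capacity -= scene_params.n_marker_only
    out = []
    for i, row in counts.iterrows():
        n_syn = int(row["synaptic_count"])
        n_ex = int(row["extrasynaptic_count"])
        if n_syn + n_ex > capacity:
            scale = capacity / (n_syn + n_ex)
            n_syn = int(math.floor(n_syn * scale))
            n_ex = int(math.floor(n_ex * scale))
        params = replace(
            scene_params,
            n_synaptic=n_syn,
            n_extrasynaptic=n_ex,
            n_intracellular=int(row["intracellular_count"]),
            seed=int(scene_seeds[i] % (2 ** 31)),
        )
        stack, truth = generate_scene(params)
        meta = SceneMetadata(
            subject_id=row["subject_id"],
            neuron_id=f"{row['subject_id']}_n{i:04d}",
            dose_um=float(row["dose_um"]),
            side=row["side"],
            distance_um=float(row["distance_um"]),
            pixel_size_um=scene_params.pixel_size_um,
            z_step_um=scene_params.z_step_um,
        )
        out.append((stack, truth, meta))
    return out
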