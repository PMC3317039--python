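"""Calibrated multi-channel stack I/O and the coordinate conventions.

Every in-memory stack is a :class:`ConfocalStack` whose voxel array is indexed
``(channel, z, y, x)``.  Pixel coordinates are 0-based, ``y`` increases
downward, and ``z`` index 0 is the first acquired plane; all crops use
half-open ranges.  No other module re-infers axes.

Stacks are stored as OME-TIFF with physical calibration and channel names in
the OME metadata.  Per-scene experimental metadata (dose, hemicord side,
rostrocaudal distance, ...) travels in a flat key=value sidecar next to the
image, for when OME annotations are not available.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .errors import ConfigurationError, ValidationError

#: Channel labels every analysis stack must carry.
REQUIRED_CHANNELS = ("receptor", "marker")

#: Default lateral sampling (μm/pixel) used when a file carries no calibration.
#: High-NA oil objectives at the magnifications typical for single-soma fields
#: sample below 0.2 μm laterally; the value is configuration, not a constant.
DEFAULT_PIXEL_SIZE_UM = 0.14


@dataclass
class ConfocalStack:
    """A calibrated multi-channel 3D fluorescence stack.

    Parameters
    ----------
    voxels
        Non-negative intensities, indexed ``(channel, z, y, x)``.
    channel_names
        One label per channel; must include ``"receptor"`` and ``"marker"``
        for the quantification modules to apply.
    pixel_size_um
        Lateral sampling, μm per pixel (x and y are assumed isotropic).
    z_step_um
        Axial distance between consecutive planes, μm.
    """

    voxels: np.ndarray
    channel_names: Sequence[str]
    pixel_size_um: float
    z_step_um: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValidationError(
                f"voxels must be 4-D (channel, z, y, x); got {self.voxels.ndim}-D"
            )
        if self.voxels.shape[1] < 1:
            raise ValidationError("stack needs at least one z-plane")
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.voxels.shape[0]} channels"
            )
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValidationError("pixel_size_um and z_step_um must be positive")
        if np.issubdtype(self.voxels.dtype, np.floating) and np.min(self.voxels) < 0:
            raise ValidationError("intensities must be non-negative")
        self.channel_names = list(self.channel_names)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[1]

    @property
    def plane_shape(self) -> tuple[int, int]:
        return self.voxels.shape[2], self.voxels.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """Return the 3D (z, y, x) array for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise ConfigurationError(
                f"channel {name!r} not present; have {self.channel_names}"
            ) from None
        return self.voxels[idx]

    def with_channel(self, name: str, data: np.ndarray) -> "ConfocalStack":
        """Return a copy with one channel's voxels replaced."""
        idx = self.channel_names.index(name)
        voxels = self.voxels.astype(np.result_type(self.voxels.dtype, data.dtype))
        voxels = voxels.copy()
        voxels[idx] = data
        return replace(self, voxels=voxels)


@dataclass
class SceneMetadata:
    """Experimental design factors attached to one imaged neuron.

    ``dose_um`` is the cytokine dose in μM (0.0 denotes the albumin vehicle);
    ``side`` is the hemicord relative to the injection; ``distance_um`` is the
    signed rostrocaudal offset from the injection center.
    """

    subject_id: str
    neuron_id: str
    dose_um: float
    side: str
    distance_um: float
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float = 0.5

    VALID_SIDES = ("injected", "contralateral")

    def __post_init__(self) -> None:
        if self.dose_um < 0:
            raise ValidationError("dose_um must be >= 0")
        if self.side not in self.VALID_SIDES:
            raise ValidationError(f"side must be one of {self.VALID_SIDES}")
        if abs(self.distance_um) > 600:
            raise ValidationError("distance_um must lie within ±600 μm")


# -- OME-TIFF read/write -------------------------------------------------------


def write_stack(stack: ConfocalStack, path: str | Path) -> None:
    """Write a stack to OME-TIFF with lossless integer encoding.

    Calibration and channel names are stored in the OME metadata so that
    ``read_stack(write_stack(s)) == s``.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if not np.issubdtype(stack.voxels.dtype, np.integer):
        raise ValidationError(
            "write_stack stores integer data losslessly; cast explicitly first"
        )
    tifffile.imwrite(
        path,
        stack.voxels,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": stack.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.z_step_um,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )


def _parse_ome(ome_xml: str) -> tuple[dict, list[str]]:
    """Extract physical sizes and channel names from OME XML."""
    root = ET.fromstring(ome_xml)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    cal: dict = {}
    names: list[str] = []
    if pixels is not None:
        for key, attr in (("pixel_size_um", "PhysicalSizeX"),
                          ("z_step_um", "PhysicalSizeZ")):
            val = pixels.get(attr)
            if val is not None:
                cal[key] = float(val)
        for ch in pixels.findall("ome:Channel", ns):
            name = ch.get("Name")
            if name is not None:
                names.append(name)
    return cal, names


def read_stack(
    path: str | Path,
    channel_map: Mapping[str, int] | None = None,
    *,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
) -> ConfocalStack:
    """Read a multi-page TIFF / OME-TIFF into a :class:`ConfocalStack`.

    Parameters
    ----------
    channel_map
        Optional mapping from channel label to channel index.  When omitted,
        channel names are taken from the OME metadata.  The resulting stack
        must expose both required labels (``receptor``, ``marker``).
    pixel_size_um, z_step_um
        Explicit calibration overriding whatever the file carries.  Required
        when the file has none.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes  # e.g. 'CZYX', 'ZYX', 'YX'
        ome_cal: dict = {}
        ome_names: list[str] = []
        if tif.ome_metadata:
            ome_cal, ome_names = _parse_ome(tif.ome_metadata)

    # Normalize axes to (C, Z, Y, X).
    axes = axes.replace("S", "C")  # sample axis treated as channel
    for missing in "CZ":
        if missing not in axes:
            data = np.expand_dims(data, axis=0)
            axes = missing + axes
    if set(axes) != set("CZYX"):
        raise ValidationError(f"unsupported axis layout {axes!r} in {path}")
    data = np.transpose(data, [axes.index(a) for a in "CZYX"])

    n_channels = data.shape[0]
    if channel_map is not None:
        names = [""] * n_channels
        for label, idx in channel_map.items():
            if not 0 <= idx < n_channels:
                raise ConfigurationError(
                    f"channel_map index {idx} out of range for {n_channels} channels"
                )
            names[idx] = label
    elif len(ome_names) == n_channels:
        names = ome_names
    else:
        raise ConfigurationError(
            "no channel_map given and file carries no usable channel names"
        )
    for required in REQUIRED_CHANNELS:
        if required not in names:
            raise ConfigurationError(
                f"channel map must include {required!r}; got {names}"
            )

    px = pixel_size_um if pixel_size_um is not None else ome_cal.get("pixel_size_um")
    zs = z_step_um if z_step_um is not None else ome_cal.get("z_step_um")
    if px is None or zs is None:
        raise ValidationError(
            f"no calibration in {path}; pass pixel_size_um / z_step_um explicitly"
        )
    if px <= 0 or zs <= 0:
        raise ValidationError("calibration values must be positive")
    return ConfocalStack(data, names, float(px), float(zs))


# -- metadata sidecar ----------------------------------------------------------

_SIDECAR_FIELDS = (
    "subject_id", "neuron_id", "dose_um", "side", "distance_um",
    "pixel_size_um", "z_step_um",
)


def sidecar_path(image_path: str | Path) -> Path:
    image_path = Path(image_path)
    return image_path.with_name(image_path.stem + ".meta.txt")


def write_metadata_sidecar(meta: SceneMetadata, image_path: str | Path) -> Path:
    """Write a flat key=value sidecar next to an image file."""
    out = sidecar_path(image_path)
    lines = [f"{k}={getattr(meta, k)}" for k in _SIDECAR_FIELDS]
    out.write_text("\n".join(lines) + "\n")
    return out


def read_metadata_sidecar(image_path: str | Path) -> SceneMetadata:
    """Read the key=value sidecar written by :func:`write_metadata_sidecar`."""
    src = sidecar_path(image_path)
    if not src.exists():
        raise IOError(f"no metadata sidecar at {src}")
    fields: dict = {}
    for line in src.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        fields[key.strip()] = value.strip()
    kwargs = {
        "subject_id": fields["subject_id"],
        "neuron_id": fields["neuron_id"],
        "dose_um": float(fields["dose_um"]),
        "side": fields["side"],
        "distance_um": float(fields["distance_um"]),
    }
    if "pixel_size_um" in fields:
        kwargs["pixel_size_um"] = float(fields["pixel_size_um"])
    if "z_step_um" in fields:
        kwargs["z_step_um"] = float(fields["z_step_um"])
    return SceneMetadata(**kwargs)
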