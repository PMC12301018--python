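"""I/O for multi-channel confocal z-stacks, binary masks and surface meshes.

The canonical in-memory layout is ``(channel, z, y, x)``; every reader
normalizes to it. Stacks are stored as OME-TIFF with physical voxel sizes in
micrometres; masks as single-channel 8-bit TIFFs with a JSON sidecar recording
threshold provenance; meshes in any triangle format trimesh can write
(STL/OBJ/PLY).
"""

from __future__ import annotations

import json
import logging
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import trimesh
from skimage import measure

from .errors import ConfigError, EmptyInputError, FormatError, MetadataError, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "DepthOrigin",
    "ImageStack",
    "MeshSurface",
    "read_stack",
    "write_stack",
    "write_masks",
    "read_mask",
    "export_mesh",
]


class DepthOrigin(str, Enum):
    """Orientation of the z axis relative to the biofilm.

    ``substrate_at_z0`` means z=0 is the substrate-adjacent face (the face
    attached to the concrete); ``free_surface_at_z0`` means z=0 is the bulk
    liquid side. Depth is always reported as distance from the substrate.
    """

    substrate_at_z0 = "substrate_at_z0"
    free_surface_at_z0 = "free_surface_at_z0"


@dataclass
class ImageStack:
    """A multi-channel 3D fluorescence acquisition.

    Parameters
    ----------
    voxels
        Non-negative intensity array indexed ``(channel, z, y, x)``.
    voxel_size
        Physical voxel edge lengths ``(dz, dy, dx)`` in micrometres.
    channel_labels
        One name per channel, in channel order.
    depth_origin
        Which stack face sits at z=0; see :class:`DepthOrigin`.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_labels: list[str]
    depth_origin: DepthOrigin = DepthOrigin.substrate_at_z0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValidationError(
                f"stack must be 4D (channel, z, y, x); got ndim={self.voxels.ndim}"
            )
        if any(s < 1 for s in self.voxels.shape):
            raise ValidationError(f"all stack dimensions must be >= 1; got {self.voxels.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)  # type: ignore[assignment]
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValidationError(f"voxel_size must be 3 positive floats; got {self.voxel_size}")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.voxels.shape[0]:
            raise ConfigError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.voxels.shape[0]} channels"
            )
        self.depth_origin = DepthOrigin(self.depth_origin)

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def channel(self, label: str) -> np.ndarray:
        """Return the 3D volume for the channel named ``label``."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise ConfigError(f"no channel labelled {label!r}; have {self.channel_labels}")
        return self.voxels[idx]


@dataclass
class MeshSurface:
    """A triangulated iso-surface with its enclosed volume in cubic micrometres."""

    vertices: np.ndarray
    faces: np.ndarray
    enclosed_volume: float

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValidationError("face index out of vertex range")
        if self.enclosed_volume < 0:
            raise ValidationError("enclosed_volume must be >= 0")


_OME_NS = "{http://www.openmicroscopy.org/Schemas/OME/2016-06}"


def _parse_ome(ome_xml: str):
    """Extract (dz, dy, dx) and channel names from OME-XML, missing -> None."""
    root = ET.fromstring(ome_xml)
    pixels = root.find(f"{_OME_NS}Image/{_OME_NS}Pixels")
    if pixels is None:
        return None, None
    sizes = tuple(pixels.get(f"PhysicalSize{ax}") for ax in ("Z", "Y", "X"))
    voxel_size = None
    if all(s is not None for s in sizes):
        voxel_size = tuple(float(s) for s in sizes)  # type: ignore[arg-type]
    names = [c.get("Name") for c in pixels.findall(f"{_OME_NS}Channel")]
    labels = [n for n in names if n] or None
    return voxel_size, labels


def read_stack(
    path: str | Path,
    channel_labels: Sequence[str] | None = None,
    voxel_size: tuple[float, float, float] | None = None,
    depth_origin: DepthOrigin = DepthOrigin.substrate_at_z0,
) -> ImageStack:
    """Read a TIFF / OME-TIFF stack and normalize axes to (channel, z, y, x).

    Voxel size comes from OME metadata unless ``voxel_size`` is given, in
    which case the override wins (with a warning if it disagrees with the
    file). Missing axes of length 1 (single channel or single slice) are
    restored.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes
            ome_xml = tf.ome_metadata
    except FormatError:
        raise
    except Exception as exc:  # pragma: no cover - tifffile raises various types
        raise FormatError(f"could not read {path} as TIFF: {exc}") from exc

    data, axes = _normalize_axes(data, axes)

    meta_voxel, meta_labels = (None, None)
    if ome_xml:
        try:
            meta_voxel, meta_labels = _parse_ome(ome_xml)
        except ET.ParseError:
            log.warning("unparseable OME metadata in %s", path)

    if voxel_size is not None:
        if meta_voxel is not None and not np.allclose(voxel_size, meta_voxel):
            log.warning(
                "voxel size override %s differs from file metadata %s; using override",
                voxel_size,
                meta_voxel,
            )
        vs = tuple(voxel_size)
    elif meta_voxel is not None:
        vs = meta_voxel
    else:
        raise MetadataError(f"{path} carries no voxel-size metadata and no override was given")

    n_chan = data.shape[0]
    if channel_labels is not None:
        if len(channel_labels) != n_chan:
            raise ConfigError(
                f"file has {n_chan} channels but {len(channel_labels)} labels provided"
            )
        labels = list(channel_labels)
    elif meta_labels is not None and len(meta_labels) == n_chan:
        labels = meta_labels
    else:
        labels = [f"channel_{i}" for i in range(n_chan)]

    return ImageStack(data, vs, labels, depth_origin)


def _normalize_axes(data: np.ndarray, axes: str) -> tuple[np.ndarray, str]:
    """Reorder/expand a tifffile series to the canonical CZYX layout."""
    axes = axes.replace("S", "C")  # treat samples-per-pixel as channels
    for ax in [a for a in axes if a not in "CZYX"]:
        i = axes.index(ax)
        if data.shape[i] == 1:  # singleton extras (T, Q, I ...) are dropped
            data = np.squeeze(data, axis=i)
            axes = axes.replace(ax, "", 1)
        elif ax in "QI" and "Z" not in axes:
            # plain multi-page TIFF without declared axes: pages are z-slices
            axes = axes.replace(ax, "Z", 1)
        else:
            raise FormatError(f"unsupported non-singleton axis {ax!r} in TIFF (axes={axes})")
    for ax in "CZYX":
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in "CZYX"]
    return np.transpose(data, order), "CZYX"


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as OME-TIFF with voxel size and channel names embedded."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dz, dy, dx = stack.voxel_size
    tifffile.imwrite(
        path,
        stack.voxels,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeY": dy,
            "PhysicalSizeZ": dz,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(stack.channel_labels)},
        },
    )
    return path


def write_masks(masks: Sequence, path: str | Path) -> list[Path]:
    """Write one binary TIFF per component mask plus a JSON provenance sidecar.

    All masks must share a spatial shape. An empty list is accepted (warning
    logged, no files written).
    """
    path = Path(path)
    if not masks:
        log.warning("write_masks called with no masks; nothing written")
        return []
    shapes = {tuple(m.occupancy.shape) for m in masks}
    if len(shapes) > 1:
        raise ValidationError(f"masks have differing shapes: {sorted(shapes)}")
    path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    provenance = {}
    for m in masks:
        comp = getattr(m.component, "value", m.component)
        f = path / f"mask_{comp}.tif"
        tifffile.imwrite(f, m.occupancy.astype(np.uint8))
        provenance[comp] = {
            "file": f.name,
            "threshold_used": None if m.threshold_used is None else float(m.threshold_used),
            "method": m.method,
        }
        written.append(f)
    sidecar = path / "masks_provenance.json"
    sidecar.write_text(json.dumps(provenance, indent=2))
    return written


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask TIFF back as a boolean 3D array."""
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    return arr.astype(bool)


def export_mesh(
    mask,
    voxel_size: tuple[float, float, float],
    path: str | Path | None = None,
) -> MeshSurface:
    """Triangulate the 0.5 iso-surface of a binary mask and write it out.

    The occupancy volume is zero-padded by one voxel so marching cubes closes
    the surface at the stack boundary; coordinates are scaled to micrometres
    using ``voxel_size`` (dz, dy, dx). The enclosed volume is computed from
    the watertight mesh.
    """
    occ = np.asarray(getattr(mask, "occupancy", mask)).astype(float)
    if occ.ndim != 3:
        raise ValidationError(f"mask must be 3D; got ndim={occ.ndim}")
    if not occ.any():
        raise EmptyInputError("cannot mesh an empty mask")
    padded = np.pad(occ, 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(voxel_size))
    # shift so coordinates refer to the unpadded volume origin
    verts = verts - np.asarray(voxel_size)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    volume = float(abs(mesh.volume))
    if path is not None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        if path.suffix.lower() not in {".stl", ".obj", ".ply"}:
            raise ConfigError(f"unsupported mesh format {path.suffix!r}; use .stl/.obj/.ply")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mesh.export(path)
    return MeshSurface(verts, faces, volume)
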