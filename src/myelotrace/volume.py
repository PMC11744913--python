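"""3D image stacks with voxel-spacing metadata.

A :class:`VolumeStack` is the common currency of the image pipeline: a
single- or multi-channel 3D intensity array plus the physical voxel size.
Axis order is channel-first ``(c, z, y, x)`` for multi-channel data and
``(z, y, x)`` for single-channel data; in-plane analysis operates on
``(y, x)`` planes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

#: Default light-sheet voxel size in micrometres (x, y, z).
DEFAULT_VOXEL_SIZE_UM = (0.54, 0.54, 4.0)


@dataclass
class VolumeStack:
    """A 3D (or channel-first 4D) intensity volume with physical metadata.

    Parameters
    ----------
    data:
        ``(z, y, x)`` or ``(c, z, y, x)`` array of finite, non-negative
        intensities.
    voxel_size_um:
        Physical voxel edge lengths ``(x, y, z)`` in micrometres.
    channel_names:
        One name per channel; a single unnamed channel by default.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"expected 3D or 4D data, got {self.data.ndim}D")
        if any(s < 1 for s in self.data.shape):
            raise ValueError("all dimensions must be >= 1")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be strictly positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        if not self.channel_names:
            if self.data.ndim == 4:
                self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
            else:
                self.channel_names = ["ch0"]
        n_ch = self.data.shape[0] if self.data.ndim == 4 else 1
        if len(self.channel_names) != n_ch:
            raise ValueError("one channel name per channel required")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0] if self.data.ndim == 4 else 1

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[-3:])

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return one channel as a ``(z, y, x)`` array."""
        if isinstance(name_or_index, str):
            idx = self.channel_names.index(name_or_index)
        else:
            idx = int(name_or_index)
        if self.data.ndim == 3:
            if idx != 0:
                raise IndexError("single-channel stack")
            return self.data
        return self.data[idx]

    def save(self, path) -> None:
        """Write as a multi-page TIFF with voxel metadata in the description."""
        meta = {
            "voxel_size_um": list(self.voxel_size_um),
            "channel_names": self.channel_names,
            "axes": "CZYX" if self.data.ndim == 4 else "ZYX",
        }
        tifffile.imwrite(path, self.data, metadata=meta,
                         photometric="minisblack")

    @classmethod
    def load(cls, path) -> "VolumeStack":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        voxel = tuple(meta.get("voxel_size_um", DEFAULT_VOXEL_SIZE_UM))
        names = list(meta.get("channel_names", []))
        return cls(data=data, voxel_size_um=voxel, channel_names=names)


def convert_stacks(planes, channel_names=None,
                   voxel_size_um=DEFAULT_VOXEL_SIZE_UM) -> VolumeStack:
    """Assemble a 2D-plane series into a channel-first 3D stack.

    Parameters
    ----------
    planes:
        Either a sequence of 2D planes (single channel) or a sequence of
        per-channel sequences (``planes[c][z]`` is a 2D plane).

    Raises
    ------
    ValueError
        If any plane is missing (``None``) or its shape disagrees with the
        first plane; the error names the offending indices.
    """
    planes = list(planes)
    if not planes:
        raise ValueError("empty plane series")
    multi = not hasattr(planes[0], "ndim") or getattr(planes[0], "ndim", None) != 2
    series = [list(ch) for ch in planes] if multi else [list(planes)]

    ref_shape = None
    bad = []
    for c, ch in enumerate(series):
        for z, p in enumerate(ch):
            if p is None:
                raise ValueError(f"missing plane at channel {c}, index {z}")
            p = np.asarray(p)
            if ref_shape is None:
                ref_shape = p.shape
            elif p.shape != ref_shape:
                bad.append((c, z, p.shape))
    if bad:
        raise ValueError(f"ragged plane series, offending (channel, plane, shape): {bad}")
    data = np.stack([np.stack([np.asarray(p) for p in ch]) for ch in series])
    if not multi:
        names = channel_names or ["ch0"]
        return VolumeStack(data=data[0], voxel_size_um=voxel_size_um,
                           channel_names=list(names))
    names = channel_names or [f"ch{i}" for i in range(len(series))]
    return VolumeStack(data=data, voxel_size_um=voxel_size_um,
                       channel_names=list(names))
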