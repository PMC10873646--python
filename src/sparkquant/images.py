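"""In-memory image container and OME-TIFF round-trip.

``ImageStack`` is the single image type exchanged between modules: a numpy
array in a fixed axis order with the physical metadata the measurements
need (pixel size, frame interval). Axes follow the convention

    (t,) (c,) (z,) y, x

i.e. time first when present, then channel, then the spatial axes. 2D
single-channel snapshots are plain (y, x) arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """An intensity stack plus the physical metadata needed for analysis.

    Parameters
    ----------
    data
        Intensity array; axis order given by ``axes`` (subset of "TCZYX"
        in that order).
    axes
        Axis string, e.g. ``"YX"``, ``"CYX"``, ``"TYX"``, ``"TCYX"``.
    pixel_size_um
        Lateral pixel size in micrometres. For 3D stacks the z spacing is
        ``z_step_um`` (defaults to the lateral size).
    frame_interval_s
        Time between frames in seconds (None for single-frame data).
    """

    data: np.ndarray
    axes: str = "YX"
    pixel_size_um: float = 0.1
    z_step_um: float | None = None
    frame_interval_s: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != len(self.axes):
            raise ValueError(
                f"data has {self.data.ndim} axes but axes string is {self.axes!r}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    # -- axis helpers -----------------------------------------------------
    def axis(self, name: str) -> int:
        i = self.axes.find(name.upper())
        if i < 0:
            raise KeyError(f"stack has no {name!r} axis (axes={self.axes!r})")
        return i

    @property
    def n_frames(self) -> int:
        return self.data.shape[self.axis("T")] if "T" in self.axes else 1

    @property
    def n_channels(self) -> int:
        return self.data.shape[self.axis("C")] if "C" in self.axes else 1

    def frame(self, t: int) -> "ImageStack":
        """Extract one time point (drops the T axis)."""
        if "T" not in self.axes:
            raise KeyError("stack has no time axis")
        sl = [slice(None)] * self.data.ndim
        sl[self.axis("T")] = t
        return replace(self, data=self.data[tuple(sl)], axes=self.axes.replace("T", ""))

    def channel(self, c: int) -> "ImageStack":
        """Extract one channel (drops the C axis)."""
        if "C" not in self.axes:
            if c == 0:
                return self
            raise KeyError("stack has no channel axis")
        sl = [slice(None)] * self.data.ndim
        sl[self.axis("C")] = c
        return replace(self, data=self.data[tuple(sl)], axes=self.axes.replace("C", ""))

    @property
    def spacing(self) -> tuple[float, ...]:
        """Physical spacing of the spatial axes, (z,)y,x order, in µm."""
        z = self.z_step_um if self.z_step_um is not None else self.pixel_size_um
        if "Z" in self.axes:
            return (z, self.pixel_size_um, self.pixel_size_um)
        return (self.pixel_size_um, self.pixel_size_um)

    @property
    def voxel_volume_um(self) -> float:
        """Pixel area (µm^2) in 2D or voxel volume (µm^3) in 3D."""
        return float(np.prod(self.spacing))

    def times_s(self) -> np.ndarray:
        """Frame acquisition times in seconds (0-based)."""
        if self.frame_interval_s is None:
            raise ValueError("stack has no frame interval")
        return np.arange(self.n_frames) * float(self.frame_interval_s)

    # -- I/O ---------------------------------------------------------------
    def save(self, path) -> None:
        """Write the stack as OME-TIFF with pixel-size / interval metadata."""
        md = {
            "axes": self.axes,
            "PhysicalSizeX": self.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": self.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
        }
        if "Z" in self.axes:
            md["PhysicalSizeZ"] = self.z_step_um or self.pixel_size_um
            md["PhysicalSizeZUnit"] = "µm"
        if self.frame_interval_s is not None:
            md["TimeIncrement"] = self.frame_interval_s
            md["TimeIncrementUnit"] = "s"
        tifffile.imwrite(path, self.data, ome=True, metadata=md)

    @classmethod
    def load(cls, path) -> "ImageStack":
        """Read an OME-TIFF written by :meth:`save` (or compatible)."""
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes.replace("S", "C")
            px, z, dt = 0.1, None, None
            if tf.ome_metadata:
                import re

                m = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', tf.ome_metadata)
                if m:
                    px = float(m.group(1))
                m = re.search(r'PhysicalSizeZ="([\d.eE+-]+)"', tf.ome_metadata)
                if m:
                    z = float(m.group(1))
                m = re.search(r'TimeIncrement="([\d.eE+-]+)"', tf.ome_metadata)
                if m:
                    dt = float(m.group(1))
        # tifffile may report singleton axes explicitly; squeeze them out
        keep = [i for i, (a, n) in enumerate(zip(axes, data.shape))
                if n > 1 or a in "YX"]
        data = data.reshape([data.shape[i] for i in keep])
        axes = "".join(axes[i] for i in keep)
        return cls(data=data, axes=axes, pixel_size_um=px, z_step_um=z,
                   frame_interval_s=dt)
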