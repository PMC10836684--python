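"""Multi-channel micrograph container with multi-page TIFF I/O.

A :class:`MicrographStack` holds one 2D intensity array per fluorescence
channel (all the same shape) plus the pixel size and acquisition time.
On disk it is a multi-page TIFF, one page per channel, with channel
labels, pixel size and time stored as JSON in the image description.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import InvalidInputError, UnknownChannelError

__all__ = ["MicrographStack"]


@dataclass
class MicrographStack:
    channels: dict[str, np.ndarray]
    pixel_size_um: float = 1.0
    time_h: float = 0.0
    field_origin_um: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise InvalidInputError(f"channel shapes differ: {shapes}")
        for ch, a in self.channels.items():
            if a.ndim != 2:
                raise InvalidInputError(f"channel {ch!r} is not a 2D array")
            if np.any(a < 0):
                raise InvalidInputError(f"channel {ch!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_labels(self) -> list[str]:
        return list(self.channels)

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.channels[label]
        except KeyError:
            raise UnknownChannelError(
                f"channel {label!r}; available: {self.channel_labels}"
            ) from None

    def save_tiff(self, path: str | Path) -> None:
        arr = np.stack([self.channels[ch] for ch in self.channels]).astype(np.float32)
        desc = json.dumps(
            {
                "channels": self.channel_labels,
                "pixel_size_um": self.pixel_size_um,
                "time_h": self.time_h,
                "field_origin_um": list(self.field_origin_um),
                **self.meta,
            }
        )
        tifffile.imwrite(path, arr, description=desc, photometric="minisblack")

    @classmethod
    def load_tiff(cls, path: str | Path) -> "MicrographStack":
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            desc = tf.pages[0].description
        try:
            meta = json.loads(desc)
        except (TypeError, json.JSONDecodeError):
            meta = {}
        if arr.ndim == 2:
            arr = arr[None]
        labels = meta.pop("channels", None) or [f"ch{i}" for i in range(arr.shape[0])]
        return cls(
            channels={ch: arr[i].astype(np.float64) for i, ch in enumerate(labels)},
            pixel_size_um=float(meta.pop("pixel_size_um", 1.0)),
            time_h=float(meta.pop("time_h", 0.0)),
            field_origin_um=tuple(meta.pop("field_origin_um", (0.0, 0.0))),
            meta=meta,
        )
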