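"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class MosaicImage:
    """Assembled multichannel whole-slide raster.

    Pixel convention throughout the package: origin at top-left, axes
    (row=y, col=x), 0-based, half-open windows.
    """

    data: np.ndarray  # (n_channels, H, W)
    channel_names: list[str]
    pixel_size: float = 1.0  # micrometres per pixel

    def __post_init__(self) -> None:
        if self.data.ndim == 2:
            self.data = self.data[None]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in mosaic (has {self.channel_names})"
            ) from None

    def save(self, path: str | Path) -> None:
        """Write as multi-page TIFF with a JSON channel-map sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.data.astype(np.float32), photometric="minisblack")
        sidecar = path.with_suffix(path.suffix + ".json")
        with open(sidecar, "w") as fh:
            json.dump(
                {"channel_names": self.channel_names, "pixel_size_um": self.pixel_size},
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, path: str | Path) -> "MosaicImage":
        path = Path(path)
        data = tifffile.imread(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = json.load(fh)
            names = meta["channel_names"]
            px = meta.get("pixel_size_um", 1.0)
        else:
            n = data.shape[0] if data.ndim == 3 else 1
            names = [f"ch{i}" for i in range(n)]
            px = 1.0
        return cls(data=np.atleast_3d(data) if data.ndim == 2 else data,
                   channel_names=names, pixel_size=px)


@dataclass
class LabelMask:
    """Integer-labelled segmentation raster; 0 is background."""

    labels: np.ndarray  # (H, W) non-negative integers
    role: str  # nucleus | cytoplasm | cell
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_labels(self) -> int:
        return int(len(np.unique(self.labels[self.labels > 0])))

    def label_set(self) -> set[int]:
        return set(np.unique(self.labels[self.labels > 0]).tolist())
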