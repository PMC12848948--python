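"""Container for a set of 2-D grayscale fields of view from one sample."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class ImageSet:
    """A stack of 2-D grayscale fields of view imaged under one condition.

    Parameters
    ----------
    frames
        Array of shape ``(n_fields, rows, cols)``.
    pixel_size_nm
        Physical pixel size, if known.
    meta
        Free-form metadata (sample name, axis coordinates, ...).
    """

    frames: np.ndarray
    pixel_size_nm: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (n_fields, rows, cols); got shape {self.frames.shape}"
            )

    @property
    def n_fields(self) -> int:
        return self.frames.shape[0]

    @property
    def field_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def __len__(self) -> int:
        return self.n_fields

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i) -> np.ndarray:
        return self.frames[i]

    def save(self, path) -> None:
        """Write as a multi-page 32-bit float TIFF."""
        tifffile.imwrite(path, self.frames.astype(np.float32), photometric="minisblack")

    @classmethod
    def load(cls, path, pixel_size_nm: float | None = None) -> "ImageSet":
        return cls(tifffile.imread(path), pixel_size_nm=pixel_size_nm)
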