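"""Pixel-lattice container shared by all segmentation stages.

Images are stored channel-last as ``(height, width, D)`` float arrays.
Grayscale inputs get a singleton channel axis so every downstream
computation can treat the multichannel case uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ImageGrid:
    """A 2-D image on a pixel lattice.

    Parameters
    ----------
    data
        Intensities, shape ``(height, width)`` or ``(height, width, D)``.
    integer_levels
        True when the source data was integer-valued (e.g. an 8-bit PNG);
        controls how many candidate intensity levels the adaptive
        thresholding enumerates.
    """

    data: np.ndarray
    integer_levels: bool = False

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        if arr.ndim != 3:
            raise ValueError(f"expected 2-D image, got array of ndim {arr.ndim}")
        object.__setattr__(self, "data", arr)

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    @property
    def intensity_min(self) -> float:
        """Minimum intensity over all pixels and channels (J_min)."""
        return float(self.data.min())

    @property
    def intensity_max(self) -> float:
        """Maximum intensity over all pixels and channels (J_max)."""
        return float(self.data.max())

    @property
    def intensity_range(self) -> float:
        return self.intensity_max - self.intensity_min

    def pixels(self) -> np.ndarray:
        """Flattened view, shape ``(N, D)`` in row-major pixel order."""
        return self.data.reshape(-1, self.n_channels)
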