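"""Small shared container for binned relative-frequency distributions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError


@dataclass
class Histogram1D:
    """Relative-frequency histogram: edges, frequencies summing to 1, sample count."""

    bin_edges: np.ndarray
    frequencies: np.ndarray
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.bin_edges) != len(self.frequencies) + 1:
            raise DataError("bin_edges must have one more entry than frequencies")
        if np.any(self.frequencies < 0):
            raise DataError("histogram frequencies must be >= 0")

    @property
    def centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    def density(self) -> np.ndarray:
        """Frequencies divided by bin width (probability density estimate)."""
        return self.frequencies / self.widths

    @classmethod
    def from_samples(
        cls, samples, *, bin_width: float | None = None, bin_edges=None
    ) -> "Histogram1D":
        s = np.asarray(samples, dtype=float)
        if s.size == 0:
            raise DataError("cannot histogram an empty sample")
        if bin_edges is None:
            if bin_width is None or bin_width <= 0:
                raise DataError("either bin_edges or a positive bin_width is required")
            hi = np.ceil(s.max() / bin_width) * bin_width
            hi = max(hi, bin_width)
            bin_edges = np.arange(0.0, hi + bin_width / 2, bin_width)
        counts, edges = np.histogram(s, bins=np.asarray(bin_edges, dtype=float))
        total = counts.sum()
        freq = counts / total if total else counts.astype(float)
        return cls(bin_edges=edges, frequencies=freq, n_samples=int(s.size))
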