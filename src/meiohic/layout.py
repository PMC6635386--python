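"""Genome binning model.

A :class:`GenomeLayout` tiles an ordered set of chromosomes into fixed-width
bins (the last bin of each chromosome may be short) and provides the global
bin index used by every contact matrix in the package.  Coordinates are
0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

__all__ = ["GenomeLayout"]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes, their lengths and a fixed bin size.

    Parameters
    ----------
    chrom_names:
        Chromosome names, in the order that defines the global bin index.
    lengths:
        Chromosome lengths in bp, same order.
    bin_size:
        Bin width in bp (default 50 kbp, the resolution used throughout
        the analysis).
    """

    chrom_names: tuple[str, ...]
    lengths: tuple[int, ...]
    bin_size: int = 50_000

    # derived, filled in __post_init__
    _offsets: tuple[int, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.lengths):
            raise ValueError("chrom_names and lengths must have equal length")
        if len(self.chrom_names) == 0:
            raise ValueError("layout needs at least one chromosome")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for name, length in zip(self.chrom_names, self.lengths):
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            if length < self.bin_size:
                raise ValueError(
                    f"chromosome {name!r} ({length} bp) is shorter than one bin "
                    f"({self.bin_size} bp)"
                )
        object.__setattr__(
            self,
            "chrom_names",
            tuple(str(n) for n in self.chrom_names),
        )
        object.__setattr__(self, "lengths", tuple(int(x) for x in self.lengths))
        nbins = [ceil(l / self.bin_size) for l in self.lengths]
        offsets = np.concatenate([[0], np.cumsum(nbins)])
        object.__setattr__(self, "_offsets", tuple(int(x) for x in offsets))

    # ------------------------------------------------------------------ #
    @property
    def n_chroms(self) -> int:
        return len(self.chrom_names)

    @property
    def n_bins(self) -> int:
        """Total number of bins over all chromosomes."""
        return self._offsets[-1]

    @property
    def offsets(self) -> tuple[int, ...]:
        """Global bin offset of each chromosome (length ``n_chroms + 1``)."""
        return self._offsets

    def bins_per_chrom(self) -> np.ndarray:
        return np.diff(self._offsets)

    def chrom_index(self, name: str) -> int:
        try:
            return self.chrom_names.index(name)
        except ValueError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def chrom_slice(self, chrom: int | str) -> slice:
        """Global-bin slice covering one chromosome."""
        c = chrom if isinstance(chrom, int) else self.chrom_index(chrom)
        return slice(self._offsets[c], self._offsets[c + 1])

    def chrom_of_bins(self) -> np.ndarray:
        """Per-bin chromosome index, shape ``(n_bins,)``."""
        out = np.empty(self.n_bins, dtype=np.int32)
        for c in range(self.n_chroms):
            out[self.chrom_slice(c)] = c
        return out

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin containing genomic position ``pos`` (0-based)."""
        c = self.chrom_index(chrom)
        if not 0 <= pos < self.lengths[c]:
            raise ValueError(f"position {pos} outside {chrom} (len {self.lengths[c]})")
        return self._offsets[c] + pos // self.bin_size

    def bin_span(self, global_bin: int) -> tuple[str, int, int]:
        """``(chrom, start, end)`` of a global bin; end clipped to chromosome."""
        if not 0 <= global_bin < self.n_bins:
            raise IndexError(f"bin {global_bin} out of range")
        c = int(np.searchsorted(self._offsets, global_bin, side="right") - 1)
        local = global_bin - self._offsets[c]
        start = local * self.bin_size
        end = min(start + self.bin_size, self.lengths[c])
        return self.chrom_names[c], start, end

    def bin_starts(self) -> np.ndarray:
        """Per-bin start coordinate within its chromosome."""
        out = np.empty(self.n_bins, dtype=np.int64)
        for c in range(self.n_chroms):
            n = self._offsets[c + 1] - self._offsets[c]
            out[self.chrom_slice(c)] = np.arange(n, dtype=np.int64) * self.bin_size
        return out

    def bin_midpoints(self) -> np.ndarray:
        """Per-bin midpoint coordinate within its chromosome (clipped bins too)."""
        mids = np.empty(self.n_bins, dtype=np.float64)
        for c in range(self.n_chroms):
            sl = self.chrom_slice(c)
            n = sl.stop - sl.start
            starts = np.arange(n, dtype=np.float64) * self.bin_size
            ends = np.minimum(starts + self.bin_size, self.lengths[c])
            mids[sl] = (starts + ends) / 2.0
        return mids

    def same_chrom_matrix(self) -> np.ndarray:
        """Boolean ``(n_bins, n_bins)`` matrix, True where bins share a chromosome."""
        c = self.chrom_of_bins()
        return c[:, None] == c[None, :]

    def __eq__(self, other: object) -> bool:  # frozen dataclass default compares _offsets too
        if not isinstance(other, GenomeLayout):
            return NotImplemented
        return (
            self.chrom_names == other.chrom_names
            and self.lengths == other.lengths
            and self.bin_size == other.bin_size
        )

    def __hash__(self) -> int:
        return hash((self.chrom_names, self.lengths, self.bin_size))
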