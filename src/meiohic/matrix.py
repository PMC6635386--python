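"""Contact-matrix container and text I/O.

Contacts are stored dense and symmetric over the global bins of a
:class:`~meiohic.layout.GenomeLayout`.  The interchange format is the
7-column interaction table (``chrom1 start1 end1 chrom2 start2 end2 count``)
with bin-edge coordinates; each unordered bin pair appears once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .layout import GenomeLayout

__all__ = ["ContactMatrix", "read_contacts", "write_contacts", "contacts_to_matrix"]


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts with a filtered-bin mask and biases.

    Attributes
    ----------
    layout:
        The genome binning the matrix is defined over.
    counts:
        ``(n_bins, n_bins)`` symmetric non-negative float array.  Off-diagonal
        contacts appear at both ``[i, j]`` and ``[j, i]``; the number of
        read-level contacts is the upper-triangle (diagonal included) sum.
    mask:
        Boolean per-bin array; ``True`` marks a filtered (unusable) bin.
    biases:
        Per-bin positive multiplicative visibility factors (1.0 when raw).
    normalization:
        One of ``raw``, ``ICE``, ``scaled``, ``obs/exp``.
    meta:
        Free-form provenance (e.g. ICE convergence flag).
    """

    layout: GenomeLayout
    counts: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    biases: np.ndarray = None  # type: ignore[assignment]
    normalization: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.layout.n_bins
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape != (n, n):
            raise ValueError(f"counts must be ({n}, {n}), got {self.counts.shape}")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool).copy()
        if self.biases is None:
            self.biases = np.ones(n, dtype=np.float64)
        else:
            self.biases = np.asarray(self.biases, dtype=np.float64).copy()

    # ------------------------------------------------------------------ #
    @property
    def n_bins(self) -> int:
        return self.layout.n_bins

    @property
    def unmasked(self) -> np.ndarray:
        return ~self.mask

    def total(self) -> float:
        """Full matrix sum (off-diagonal entries counted twice)."""
        return float(self.counts.sum())

    def total_contacts(self) -> float:
        """Upper-triangle-plus-diagonal sum: the number of contacts."""
        return float((self.counts.sum() + np.trace(self.counts)) / 2.0)

    def is_symmetric(self, tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.counts, self.counts.T, atol=tol, rtol=0))

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            layout=self.layout,
            counts=self.counts.copy(),
            mask=self.mask.copy(),
            biases=self.biases.copy(),
            normalization=self.normalization,
            meta=dict(self.meta),
        )

    def marginals(self) -> np.ndarray:
        """Per-bin row sums (symmetric matrix, so row == column sums)."""
        return self.counts.sum(axis=1)

    def intra_block(self, chrom: int | str) -> np.ndarray:
        sl = self.layout.chrom_slice(chrom)
        return self.counts[sl, sl]


# ---------------------------------------------------------------------- #
# 7-column interaction-table I/O


def contacts_to_matrix(
    pairs: np.ndarray, layout: GenomeLayout, mask: np.ndarray | None = None
) -> ContactMatrix:
    """Accumulate a ``(n, 2)`` array of global bin-pair contacts into a matrix."""
    n = layout.n_bins
    counts = np.zeros((n, n), dtype=np.float64)
    pairs = np.asarray(pairs)
    if pairs.size:
        np.add.at(counts, (pairs[:, 0], pairs[:, 1]), 1.0)
        off = pairs[:, 0] != pairs[:, 1]
        np.add.at(counts, (pairs[off, 1], pairs[off, 0]), 1.0)
    return ContactMatrix(layout=layout, counts=counts, mask=mask)


def read_contacts(path: str | Path, layout: GenomeLayout) -> ContactMatrix:
    """Read a 7-column interaction table into a :class:`ContactMatrix`.

    Pairs are accumulated symmetrically; malformed rows raise a ``ValueError``
    carrying the 1-based line number.
    """
    n = layout.n_bins
    counts = np.zeros((n, n), dtype=np.float64)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ValueError(
                    f"{path}: line {lineno}: expected 7 tab-separated columns, "
                    f"got {len(fields)}"
                )
            c1, s1, _e1, c2, s2, _e2, v = fields
            try:
                i = layout.bin_index(c1, int(s1))
                j = layout.bin_index(c2, int(s2))
                val = float(v)
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            counts[i, j] += val
            if i != j:
                counts[j, i] += val
    return ContactMatrix(layout=layout, counts=counts)


def write_contacts(matrix: ContactMatrix, path: str | Path) -> None:
    """Write the unmasked upper triangle as a 7-column interaction table."""
    layout = matrix.layout
    keep = matrix.unmasked
    iu, ju = np.triu_indices(matrix.n_bins)
    vals = matrix.counts[iu, ju]
    sel = (vals != 0) & keep[iu] & keep[ju]
    with open(path, "w") as fh:
        for i, j, v in zip(iu[sel], ju[sel], vals[sel]):
            c1, s1, e1 = layout.bin_span(int(i))
            c2, s2, e2 = layout.bin_span(int(j))
            fh.write(f"{c1}\t{s1}\t{e1}\t{c2}\t{s2}\t{e2}\t{v:.10g}\n")


def write_dense(matrix: ContactMatrix, path: str | Path, chrom: str | int | None = None) -> None:
    """Dense TSV dump (whole genome or one chromosome) for inspection."""
    block = matrix.counts if chrom is None else matrix.intra_block(chrom)
    np.savetxt(path, block, delimiter="\t", fmt="%.10g")
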