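"""Whole-genome architectural statistics.

Distance-decay curves P(s), per-chromosome inter/intra interaction ratios,
sub-telomeric (bouquet) interaction scores, and a stratum-adjusted
correlation coefficient (SCC) for replicate reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import scale_matrix
from .matrix import ContactMatrix
from .stats import rank_sum_test

__all__ = [
    "DecayCurve",
    "contact_probability_curve",
    "RatioTable",
    "inter_intra_ratio",
    "SubtelomereScore",
    "subtelomeric_interactions",
    "compare_subtelomere_scores",
    "ReproducibilityScore",
    "scc_reproducibility",
]


# ---------------------------------------------------------------------- #
# P(s)


@dataclass
class DecayCurve:
    """Mean contact probability per distance stratum."""

    s: np.ndarray  # genomic separation, bp (strictly increasing)
    p: np.ndarray  # mean probability per stratum
    n_pairs: np.ndarray  # unmasked pairs per stratum

    def fit_slope(self, s_min: float | None = None, s_max: float | None = None
                  ) -> tuple[float, float]:
        """Least-squares slope of log10 P vs log10 s over [s_min, s_max].

        Returns ``(slope, intercept)``; strata with zero probability are
        dropped from the fit.
        """
        sel = (self.p > 0) & (self.n_pairs > 0)
        if s_min is not None:
            sel &= self.s >= s_min
        if s_max is not None:
            sel &= self.s <= s_max
        if sel.sum() < 2:
            raise ValueError("fewer than 2 usable strata in the fit range")
        slope, intercept = np.polyfit(np.log10(self.s[sel]), np.log10(self.p[sel]), 1)
        return float(slope), float(intercept)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"s": self.s, "p": self.p, "n_pairs": self.n_pairs})


def contact_probability_curve(
    matrix: ContactMatrix, chroms: list[str] | None = None
) -> DecayCurve:
    """P(s): mean contact value over unmasked intra pairs per bin-distance.

    Intended for matrices scaled to total 1 (probability normalization), but
    works on any scale; only the intercept changes.
    """
    layout = matrix.layout
    names = list(layout.chrom_names) if chroms is None else list(chroms)
    keep = matrix.unmasked
    max_bins = max(
        layout.chrom_slice(c).stop - layout.chrom_slice(c).start for c in names
    )
    sums = np.zeros(max_bins)
    npairs = np.zeros(max_bins)
    for c in names:
        sl = layout.chrom_slice(c)
        block = matrix.counts[sl, sl]
        k = keep[sl]
        nb = block.shape[0]
        for d in range(1, nb):
            dk = k[: nb - d] & k[d:]
            if dk.any():
                sums[d] += np.diagonal(block, offset=d)[dk].sum()
                npairs[d] += dk.sum()
    ds = np.arange(1, max_bins)
    valid = npairs[1:] > 0
    if not valid.any():
        raise ValueError("no unmasked intra-chromosomal pairs")
    p = np.zeros(max_bins - 1)
    p[valid] = sums[1:][valid] / npairs[1:][valid]
    return DecayCurve(
        s=(ds[valid] * layout.bin_size).astype(float),
        p=p[valid],
        n_pairs=npairs[1:][valid],
    )


# ---------------------------------------------------------------------- #
# inter/intra ratio


@dataclass
class RatioTable:
    """Per-chromosome inter/intra ratios and their correlation with length."""

    table: pd.DataFrame  # chrom, length, inter, intra, ratio
    spearman_rho: float
    spearman_p: float


def inter_intra_ratio(matrix: ContactMatrix) -> RatioTable:
    """R_c = (inter-chromosomal sum of c) / (intra sum of c, diagonal included).

    Sums are over the full symmetric matrix (both triangles), so an all-ones
    matrix with chromosomes of 10 and 30 bins gives R = 300/100 and 300/900.
    A Spearman correlation of R_c with chromosome length is attached
    (NaN ratios excluded).
    """
    layout = matrix.layout
    rows = []
    for c, name in enumerate(layout.chrom_names):
        sl = layout.chrom_slice(c)
        row_sum = matrix.counts[sl, :].sum()
        intra = matrix.counts[sl, sl].sum()
        inter = row_sum - intra
        if intra == 0:
            warnings.warn(f"{name}: zero intra-chromosomal sum, ratio undefined",
                          stacklevel=2)
            ratio = np.nan
        else:
            ratio = inter / intra
        rows.append((name, layout.lengths[c], inter, intra, ratio))
    table = pd.DataFrame(rows, columns=["chrom", "length", "inter", "intra", "ratio"])
    ok = table["ratio"].notna()
    if (ok.sum() >= 3 and table.loc[ok, "ratio"].nunique() > 1
            and table.loc[ok, "length"].nunique() > 1):
        rho, pval = sps.spearmanr(table.loc[ok, "length"], table.loc[ok, "ratio"])
    else:
        rho, pval = np.nan, np.nan
    return RatioTable(table=table, spearman_rho=float(rho), spearman_p=float(pval))


# ---------------------------------------------------------------------- #
# sub-telomeric (bouquet) interactions


@dataclass
class SubtelomereScore:
    """Per chromosome pair: summed per-million inter counts inside the window."""

    table: pd.DataFrame  # chrom1, chrom2, score
    window: tuple[float, float]

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy()


def subtelomeric_interactions(
    matrix: ContactMatrix,
    window: tuple[float, float] = (3_000_000.0, 3_500_000.0),
) -> SubtelomereScore:
    """Sum per-million inter-chromosomal counts between chromosome-start windows.

    Counts are expressed per million *contacts* (upper-triangle sum), making
    the scores invariant to global rescaling.  Normalizing by the contact
    count rather than the raw matrix sum matters for discrete data: two
    libraries of identical depth get the identical factor, so tied counts
    stay tied and rank comparisons between cell types remain calibrated.
    A bin belongs to the window when its midpoint falls in the half-open
    interval measured from the chromosome start (the default [3.0, 3.5) Mbp
    skips the masked centromeric starts of real mouse maps).  Chromosomes
    the window does not fit in are skipped with a warning.
    """
    w0, w1 = window
    if not 0 <= w0 < w1:
        raise ValueError("window must satisfy 0 <= start < end")
    layout = matrix.layout
    total = matrix.total_contacts()
    if total <= 0:
        raise ValueError("cannot score a zero-total matrix")
    scaled = matrix.copy()
    scaled.counts = scaled.counts * (1e6 / total)
    mids = layout.bin_midpoints()
    win_bins: dict[int, np.ndarray] = {}
    for c in range(layout.n_chroms):
        if w1 > layout.lengths[c]:
            warnings.warn(
                f"{layout.chrom_names[c]}: window [{w0}, {w1}) exceeds chromosome, "
                "skipped", stacklevel=2,
            )
            continue
        sl = layout.chrom_slice(c)
        local = mids[sl]
        sel = (local >= w0) & (local < w1)
        win_bins[c] = np.flatnonzero(sel) + sl.start
    if not win_bins:
        raise ValueError("window fits no chromosome")
    rows = []
    chroms = sorted(win_bins)
    for ai in range(len(chroms)):
        for bi in range(ai + 1, len(chroms)):
            a, b = chroms[ai], chroms[bi]
            score = scaled.counts[np.ix_(win_bins[a], win_bins[b])].sum()
            rows.append((layout.chrom_names[a], layout.chrom_names[b], float(score)))
    return SubtelomereScore(
        table=pd.DataFrame(rows, columns=["chrom1", "chrom2", "score"]),
        window=(float(w0), float(w1)),
    )


def compare_subtelomere_scores(
    a: SubtelomereScore, b: SubtelomereScore
) -> tuple[float, float, int]:
    """Two-sided rank-sum comparison of two score sets (e.g. two cell types)."""
    return rank_sum_test(a.scores, b.scores)


# ---------------------------------------------------------------------- #
# stratum-adjusted correlation (SCC)


@dataclass
class ReproducibilityScore:
    """Per-chromosome SCC and their unweighted genome mean."""

    per_chrom: pd.DataFrame  # chrom, scc
    genome_score: float
    h: int
    max_distance: float


def _box_smooth(mat: np.ndarray, h: int) -> np.ndarray:
    """2D mean filter of half-width h with edge-corrected normalization."""
    if h == 0:
        return mat
    from scipy.ndimage import uniform_filter

    size = 2 * h + 1
    num = uniform_filter(mat, size=size, mode="constant", cval=0.0)
    den = uniform_filter(np.ones_like(mat), size=size, mode="constant", cval=0.0)
    return num / den


def scc_reproducibility(
    matrix_a: ContactMatrix,
    matrix_b: ContactMatrix,
    h: int = 5,
    max_distance: float = 10_000_000.0,
    min_distance: float = 0.0,
) -> ReproducibilityScore:
    """Stratum-adjusted correlation between two raw intra-chromosomal maps.

    Both matrices are smoothed with a (2h+1)-wide 2D mean filter; per
    distance stratum up to ``max_distance`` the Pearson correlation of the
    smoothed entries is combined with weights proportional to the stratum
    pair count times the variance-stabilized (rank) spread of each vector.
    Entries within ``h`` bins of the matrix boundary are dropped from each
    stratum: their truncated smoothing windows carry a deterministic
    distance-decay bump shared by any two maps, which would fabricate
    correlation between unrelated samples.  The genome score is the
    unweighted mean over chromosomes.  Setting ``min_distance`` instead
    restricts to strata *beyond* that separation.
    """
    if matrix_a.layout != matrix_b.layout:
        raise ValueError("matrices must share a layout")
    layout = matrix_a.layout
    keep = matrix_a.unmasked & matrix_b.unmasked
    rows = []
    for c, name in enumerate(layout.chrom_names):
        sl = layout.chrom_slice(c)
        a = _box_smooth(matrix_a.counts[sl, sl], h)
        b = _box_smooth(matrix_b.counts[sl, sl], h)
        k = keep[sl]
        nb = a.shape[0]
        d_max = min(int(max_distance // layout.bin_size), nb - 1)
        d_min = int(min_distance // layout.bin_size)
        num = 0.0
        den = 0.0
        for d in range(d_min, d_max + 1):
            dk = k[: nb - d] & k[d:]
            # trim positions whose smoothing window leaves the matrix
            if h > 0:
                dk = dk.copy()
                dk[:h] = False
                dk[len(dk) - h :] = False
            if dk.sum() < 2:
                continue
            x = np.diagonal(a, offset=d)[dk]
            y = np.diagonal(b, offset=d)[dk]
            if x.std() == 0 or y.std() == 0:
                continue  # degenerate stratum, weight 0
            rho = np.corrcoef(x, y)[0, 1]
            rx = sps.rankdata(x)
            ry = sps.rankdata(y)
            w = x.size * rx.std() * ry.std()
            num += w * rho
            den += w
        rows.append((name, num / den if den > 0 else np.nan))
    per_chrom = pd.DataFrame(rows, columns=["chrom", "scc"])
    return ReproducibilityScore(
        per_chrom=per_chrom,
        genome_score=float(per_chrom["scc"].mean()),
        h=h,
        max_distance=float(max_distance),
    )
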