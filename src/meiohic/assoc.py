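"""Peak annotation, permutation association, and expression statistics.

Covers the functional half of the analysis: assigning ChIP peaks to
promoters / gene bodies / intergenic space, Venn-style peak-set overlaps,
permutation Z-scores relating peaks to per-bin value tracks (insulation or
expression), compartment-occupancy enrichment, rank-sum expression
comparisons, CPM conversion, and flat hypergeometric GO enrichment with
Benjamini-Hochberg correction.

Peaks and genes are plain DataFrames (BED-like: ``chrom, start, end`` and
``gene_id, chrom, tss, strand, start, end``), 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .layout import GenomeLayout
from .stats import bh_adjust, rank_sum_test

__all__ = [
    "read_bed",
    "write_bed",
    "annotate_peaks_to_features",
    "peak_set_overlap",
    "PermutationResult",
    "permutation_mean_zscore",
    "compartment_occupancy_enrichment",
    "expression_group_comparison",
    "counts_to_cpm",
    "hypergeometric_enrichment_bh",
]

PROMOTER_WINDOW = 2_000  # bp upstream of the TSS


# ---------------------------------------------------------------------- #
# BED helpers


def read_bed(path) -> pd.DataFrame:
    """Minimal BED reader: chrom, start, end (+ name if present)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else ""))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name") if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def _validate_peaks(peaks: pd.DataFrame) -> None:
    if (peaks["start"] >= peaks["end"]).any():
        raise ValueError("peak starts must be < ends")


# ---------------------------------------------------------------------- #
# annotation


def _promoter_interval(tss: int, strand: str, window: int) -> tuple[int, int]:
    """Strand-aware window strictly upstream of the TSS, half-open."""
    if strand == "+":
        return tss - window, tss
    return tss + 1, tss + 1 + window


def annotate_peaks_to_features(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_window: int = PROMOTER_WINDOW,
    promoter_mode: str = "upstream",
) -> tuple[pd.Series, np.ndarray]:
    """Assign each peak the highest-priority overlapping category.

    Priority: promoter > gene body > intergenic.  The promoter is the
    strand-aware window strictly upstream of the TSS (``promoter_mode=
    "symmetric"`` uses +/- ``promoter_window`` around the TSS instead).
    Returns the per-peak category Series and the signed distance from each
    peak midpoint to its nearest TSS (strand-oriented: negative = upstream).
    """
    if promoter_mode not in ("upstream", "symmetric"):
        raise ValueError("promoter_mode must be 'upstream' or 'symmetric'")
    _validate_peaks(peaks)
    prom_trees: dict[str, IntervalTree] = {}
    body_trees: dict[str, IntervalTree] = {}
    tss_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in genes.groupby("chrom"):
        pt, bt = IntervalTree(), IntervalTree()
        for _, g in sub.iterrows():
            if promoter_mode == "upstream":
                ps, pe = _promoter_interval(int(g.tss), g.strand, promoter_window)
            else:
                ps, pe = int(g.tss) - promoter_window, int(g.tss) + promoter_window + 1
            if pe > ps:
                pt.addi(max(ps, 0), pe)
            if g.end > g.start:
                bt.addi(int(g.start), int(g.end))
        prom_trees[chrom], body_trees[chrom] = pt, bt
        tss_by_chrom[chrom] = (
            sub["tss"].to_numpy(),
            np.where(sub["strand"].to_numpy() == "+", 1, -1),
        )
    cats = []
    dists = []
    for _, p in peaks.iterrows():
        if p.chrom in prom_trees and prom_trees[p.chrom].overlap(p.start, p.end):
            cats.append("promoter")
        elif p.chrom in body_trees and body_trees[p.chrom].overlap(p.start, p.end):
            cats.append("gene_body")
        else:
            cats.append("intergenic")
        if p.chrom in tss_by_chrom:
            tss, sign = tss_by_chrom[p.chrom]
            mid = (p.start + p.end) // 2
            i = int(np.argmin(np.abs(tss - mid)))
            dists.append((mid - tss[i]) * sign[i])
        else:
            dists.append(np.nan)
    return pd.Series(cats, index=peaks.index, name="category"), np.asarray(dists, float)


def peak_set_overlap(
    sets: dict[str, pd.DataFrame], min_overlap: int = 1
) -> pd.DataFrame:
    """Venn-region counts for 2-3 peak sets, reported per set.

    A peak of set S belongs to the region labelled by the subset of *other*
    sets it overlaps by at least ``min_overlap`` bp.  Counts are reported
    per set, so asymmetric totals (one peak spanning two partners) stay
    visible.  Columns: ``set, overlaps_with, count``.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("need 2 or 3 peak sets")
    trees: dict[str, dict[str, IntervalTree]] = {}
    for name, df in sets.items():
        _validate_peaks(df)
        by_chrom: dict[str, IntervalTree] = {}
        for chrom, sub in df.groupby("chrom"):
            t = IntervalTree()
            for _, p in sub.iterrows():
                t.addi(int(p.start), int(p.end))
            by_chrom[chrom] = t
        trees[name] = by_chrom
    rows = []
    names = list(sets)
    for name in names:
        patterns: dict[tuple[str, ...], int] = {}
        for _, p in sets[name].iterrows():
            hit = []
            for other in names:
                if other == name:
                    continue
                t = trees[other].get(p.chrom)
                if t is None:
                    continue
                if any(
                    min(iv.end, p.end) - max(iv.begin, p.start) >= min_overlap
                    for iv in t.overlap(p.start, p.end)
                ):
                    hit.append(other)
            key = tuple(sorted(hit))
            patterns[key] = patterns.get(key, 0) + 1
        for key, count in sorted(patterns.items()):
            rows.append((name, "+".join(key) if key else "none", count))
    return pd.DataFrame(rows, columns=["set", "overlaps_with", "count"])


# ---------------------------------------------------------------------- #
# permutation association


@dataclass
class PermutationResult:
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    flank_shifts: np.ndarray  # bp offsets of the local profile
    flank_z: np.ndarray
    n_perm: int
    seed: int


def _peaks_to_bins(peaks: pd.DataFrame, layout: GenomeLayout) -> list[np.ndarray]:
    """Per peak: global bins its interval overlaps."""
    out = []
    for _, p in peaks.iterrows():
        c = layout.chrom_index(p.chrom)
        sl = layout.chrom_slice(c)
        b0 = int(p.start) // layout.bin_size
        b1 = (int(p.end) - 1) // layout.bin_size
        b1 = min(b1, sl.stop - sl.start - 1)
        out.append(np.arange(sl.start + b0, sl.start + b1 + 1))
    return out


def _mean_over_peaks(track: np.ndarray, peak_bins: list[np.ndarray]) -> float:
    vals = [np.nanmean(track[b]) for b in peak_bins]
    vals = [v for v in vals if np.isfinite(v)]
    return float(np.mean(vals)) if vals else np.nan


def permutation_mean_zscore(
    track: np.ndarray,
    peaks: pd.DataFrame,
    layout: GenomeLayout,
    n_perm: int = 10_000,
    flank: int = 250_000,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> PermutationResult:
    """Z-score of the mean track value over peaks vs random relocations.

    The observed statistic is the mean of the per-bin track over the query
    peaks.  The null relocates every peak uniformly within its own
    chromosome (length preserved; placements covering masked bins are
    redrawn), ``n_perm`` times.  The empirical p uses the add-one estimator
    and is two-sided by doubling the smaller tail.  The flank profile
    re-evaluates Z at the peaks shifted by +/- ``flank`` bp in bin-size
    steps against the same null distribution.
    """
    track = np.asarray(track, dtype=float).copy()
    if track.shape != (layout.n_bins,):
        raise ValueError("track must have one value per bin")
    if mask is None:
        mask = np.zeros(layout.n_bins, dtype=bool)
    # masked bins are outside the analysis universe for the observed
    # statistic and the null alike
    track[mask] = np.nan
    rng = np.random.default_rng(seed)
    peak_bins = _peaks_to_bins(peaks, layout)
    observed = _mean_over_peaks(track, peak_bins)

    # per-peak chromosome and length in bins, for relocation
    chrom_idx = [layout.chrom_index(c) for c in peaks["chrom"]]
    len_bins = [b.size for b in peak_bins]
    if not mask.any() and all(lb == 1 for lb in len_bins):
        # vectorized fast path: single-bin peaks, nothing masked
        cols = np.empty((len(peak_bins), n_perm), dtype=np.int64)
        for pi, ci in enumerate(chrom_idx):
            sl = layout.chrom_slice(ci)
            cols[pi] = rng.integers(sl.start, sl.stop, size=n_perm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            null = np.nanmean(track[cols], axis=0)
        return _finalize_permutation(track, peak_bins, layout, observed, null,
                                     flank, n_perm, seed)
    null = np.empty(n_perm)
    for t in range(n_perm):
        vals = []
        for ci, lb in zip(chrom_idx, len_bins):
            sl = layout.chrom_slice(ci)
            hi = sl.stop - sl.start - lb
            for _ in range(100):
                s = int(rng.integers(0, hi + 1))
                bins = np.arange(sl.start + s, sl.start + s + lb)
                if not mask[bins].any():
                    break
            v = np.nanmean(track[bins])
            if np.isfinite(v):
                vals.append(v)
        null[t] = np.mean(vals) if vals else np.nan
    return _finalize_permutation(track, peak_bins, layout, observed, null,
                                 flank, n_perm, seed)


def _finalize_permutation(
    track: np.ndarray,
    peak_bins: list[np.ndarray],
    layout: GenomeLayout,
    observed: float,
    null: np.ndarray,
    flank: int,
    n_perm: int,
    seed: int,
) -> PermutationResult:
    null = null[np.isfinite(null)]
    null_mean = float(null.mean())
    null_sd = float(null.std())
    if null_sd == 0:
        warnings.warn("degenerate permutation null (sd = 0); Z defined as 0",
                      stacklevel=2)
        z = 0.0
    else:
        z = (observed - null_mean) / null_sd
    n = null.size
    p_hi = (1 + np.sum(null >= observed)) / (n + 1)
    p_lo = (1 + np.sum(null <= observed)) / (n + 1)
    p = min(1.0, 2.0 * min(p_hi, p_lo))

    step = layout.bin_size
    shifts = np.arange(-flank, flank + 1, step)
    flank_z = np.empty(shifts.size)
    for si, sh in enumerate(shifts):
        db = int(round(sh / step))
        vals = []
        for b in peak_bins:
            nb = b + db
            chrom, _, _ = layout.bin_span(int(b[0]))
            sl = layout.chrom_slice(chrom)
            nb = nb[(nb >= sl.start) & (nb < sl.stop)]
            if nb.size:
                v = np.nanmean(track[nb])
                if np.isfinite(v):
                    vals.append(v)
        obs_s = np.mean(vals) if vals else np.nan
        flank_z[si] = 0.0 if null_sd == 0 else (obs_s - null_mean) / null_sd
    return PermutationResult(
        observed=observed, null_mean=null_mean, null_sd=null_sd, z=float(z),
        p=float(p), flank_shifts=shifts, flank_z=flank_z, n_perm=n_perm, seed=seed,
    )


def compartment_occupancy_enrichment(
    peaks: pd.DataFrame,
    profile,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Fraction of peak midpoints in A-compartment bins + permutation p.

    The null relocates midpoints uniformly over the assigned (non-NA) bins;
    p is one-sided for enrichment, with the add-one estimator.
    """
    labels = profile.labels
    layout = profile.layout
    assigned = np.flatnonzero(labels != "NA")
    if assigned.size == 0:
        raise ValueError("no assigned bins")
    mids = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    bins = np.array(
        [layout.bin_index(c, int(m)) for c, m in zip(peaks["chrom"], mids)]
    )
    bins = bins[labels[bins] != "NA"]
    if bins.size == 0:
        raise ValueError("no peaks on assigned bins")
    observed = float((labels[bins] == "A").mean())
    frac_a = float((labels[assigned] == "A").mean())
    if frac_a == 1.0:
        warnings.warn("every assigned bin is A; null degenerate, p = 1",
                      stacklevel=2)
        return observed, 1.0
    rng = np.random.default_rng(seed)
    draws = rng.choice(assigned, size=(n_perm, bins.size), replace=True)
    null = (labels[draws] == "A").mean(axis=1)
    p = float((1 + np.sum(null >= observed)) / (n_perm + 1))
    return observed, p


# ---------------------------------------------------------------------- #
# expression statistics


def expression_group_comparison(
    expr: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    value_col: str = "fpkm",
) -> tuple[float, float, int]:
    """Two-sided rank-sum comparison of expression between two gene groups.

    Returns ``(statistic, p, direction)``; direction +1 means group A tends
    higher.  Exact null for small groups, normal approximation with
    continuity correction otherwise.
    """
    idx = expr.set_index("gene_id")[value_col]
    a = idx.reindex(group_a).dropna().to_numpy()
    b = idx.reindex(group_b).dropna().to_numpy()
    return rank_sum_test(a, b)


def counts_to_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: each column scaled so it sums to 1e6.

    ``counts`` is genes x cell types (gene ids as index or a ``gene_id``
    column, which is preserved).
    """
    out = counts.copy()
    value_cols = [c for c in out.columns if c != "gene_id"]
    for c in value_cols:
        total = out[c].sum()
        if total <= 0:
            raise ValueError(f"library {c!r} has zero total")
        out[c] = out[c] * 1e6 / total
    return out


def hypergeometric_enrichment_bh(
    term_map: dict[str, set[str]],
    selected: set[str],
    universe: set[str],
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per term, BH-corrected.

    For each term with K genes in the universe and k in the selected set of
    size n drawn from N universe genes, p = P[X >= k] with
    X ~ Hypergeom(N, K, n).  Columns: ``term, k, K, n, N, p, q,
    significant`` (q <= ``q_threshold``).
    """
    if not universe:
        raise ValueError("empty universe")
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    N = len(universe)
    n = len(selected)
    rows = []
    for term, genes in term_map.items():
        tg = genes & universe
        K = len(tg)
        if K == 0:
            continue
        k = len(tg & selected)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    df["significant"] = df["q"] <= q_threshold
    return df.sort_values("p").reset_index(drop=True)
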