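"""Synthetic genomes, contact maps, peak tracks and expression tables.

Every architectural signal the analysis modules measure is planted here with
a known, parameterized ground truth: a power-law distance decay (optionally
piecewise), an alternating A/B checkerboard, TAD blocks with elevated
within-domain contact, a flat inter-chromosomal background with optional
telomere-bouquet and centromere-cluster enrichment, gene placement biased
toward A compartments, and expression tables with additive log2 effects for
A-compartment and promoter-peak genes.

The generative model is a declared stand-in: the real study mixes and
re-processes sequencing reads, it does not simulate them.  Validation is by
parameter recovery — the analysis modules must recover what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import GenomeLayout
from .matrix import ContactMatrix, contacts_to_matrix

__all__ = [
    "GenomeSpec",
    "ArchitectureSpec",
    "EffectSpec",
    "planted_compartment_labels",
    "planted_tad_ids",
    "planted_tad_borders",
    "build_genome_layout",
    "simulate_expected_matrix",
    "beta_for_inter_intra_ratio",
    "sample_contact_reads",
    "simulate_mixture",
    "simulate_peak_tracks",
    "simulate_expression_table",
]

PROMOTER_WINDOW = 2_000  # bp upstream of the TSS, strand-aware


@dataclass(frozen=True)
class GenomeSpec:
    """Synthetic genome shape.

    Defaults give the toy scale used throughout the test-bed: 3 chromosomes
    of 10 Mbp at 50-kbp bins (600 bins total), small enough that every
    analysis runs in seconds yet large enough for eigenvector and insulation
    signals to be well conditioned.
    """

    chrom_lengths: tuple[int, ...] = (10_000_000, 10_000_000, 10_000_000)
    bin_size: int = 50_000
    telomere_window: int = 500_000  # bp at each chromosome end
    n_genes: int = 1_000
    density_ratio: float = 2.0  # A:B gene-density ratio

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.bin_size <= 0:
            raise ValueError("bin size must be positive")
        if self.n_genes < 0:
            raise ValueError("gene count must be >= 0")
        if self.density_ratio <= 0:
            raise ValueError("density ratio must be > 0")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Planted contact-map architecture.

    ``decay_alphas``/``decay_breakpoints`` define a (piecewise) power law
    P(s) ~ s^-alpha, continuous at the breakpoints.  ``amplitude`` is the
    checkerboard modulation a in (1 + a e_i e_j), ``tau`` the within-TAD
    enrichment, ``beta`` the inter-chromosomal background weight relative to
    the intra kernel, ``gamma`` the telomere-bouquet factor, and
    ``centromere_factor`` the chromocenter factor (both applied to inter
    contacts whose bins fall in the respective end windows).
    """

    decay_alphas: tuple[float, ...] = (1.0,)
    decay_breakpoints: tuple[float, ...] = ()  # bp, len == len(alphas) - 1
    compartment_block_bins: int = 50
    amplitude: float = 0.6
    tad_segment_bins: tuple[int, ...] = (50,)
    tau: float = 5.0
    beta: float = 0.005
    gamma: float = 1.0
    centromere_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude < 1.0:
            raise ValueError("checkerboard amplitude must be in [0, 1)")
        if len(self.decay_breakpoints) != len(self.decay_alphas) - 1:
            raise ValueError("need one breakpoint fewer than decay exponents")
        for name, v in [
            ("tau", self.tau),
            ("gamma", self.gamma),
            ("centromere_factor", self.centromere_factor),
        ]:
            if v < 1.0:
                raise ValueError(f"{name} must be >= 1 (1 = off)")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.compartment_block_bins < 1 or any(t < 1 for t in self.tad_segment_bins):
            raise ValueError("block and TAD segment lengths must be >= 1 bin")


@dataclass(frozen=True)
class EffectSpec:
    """Planted functional effects for peaks and expression.

    Expression is log-normal on the log2 scale: ``log2 FPKM ~ N(mean, sd)``
    plus additive effects for A-compartment genes and genes with a promoter
    peak.  ``promoter_fraction`` of the ``n_peaks`` peaks land in promoter
    windows of distinct genes, the rest uniformly in non-promoter space.
    """

    log2_mean: float = 3.0
    log2_sd: float = 2.0
    compartment_a_log2_effect: float = 1.0
    promoter_peak_log2_effect: float = 1.0
    promoter_fraction: float = 0.8
    n_peaks: int = 500
    peak_width: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.promoter_fraction <= 1.0:
            raise ValueError("promoter fraction must be in [0, 1]")
        if self.log2_sd <= 0:
            raise ValueError("log2 sd must be > 0")
        if self.n_peaks < 0 or self.peak_width <= 0:
            raise ValueError("invalid peak count or width")


# ---------------------------------------------------------------------- #
# planted truth helpers


def planted_compartment_labels(layout: GenomeLayout, block_bins: int = 50) -> np.ndarray:
    """Deterministic alternating A/B blocks per chromosome (A first)."""
    labels = np.empty(layout.n_bins, dtype="<U1")
    for c in range(layout.n_chroms):
        sl = layout.chrom_slice(c)
        n = sl.stop - sl.start
        block = (np.arange(n) // block_bins) % 2
        labels[sl] = np.where(block == 0, "A", "B")
    return labels


def planted_tad_ids(layout: GenomeLayout, segment_bins: tuple[int, ...]) -> np.ndarray:
    """Per-bin TAD id; segments tile each chromosome cyclically."""
    ids = np.empty(layout.n_bins, dtype=np.int64)
    next_id = 0
    for c in range(layout.n_chroms):
        sl = layout.chrom_slice(c)
        n = sl.stop - sl.start
        pos = 0
        k = 0
        chrom_ids = np.empty(n, dtype=np.int64)
        while pos < n:
            seg = segment_bins[k % len(segment_bins)]
            chrom_ids[pos : pos + seg] = next_id
            pos += seg
            k += 1
            next_id += 1
        ids[sl] = chrom_ids
    return ids


def planted_tad_borders(layout: GenomeLayout, segment_bins: tuple[int, ...]) -> np.ndarray:
    """Global bin indices of internal TAD borders (first bin of each new TAD)."""
    ids = planted_tad_ids(layout, segment_bins)
    chrom = layout.chrom_of_bins()
    change = (np.diff(ids) != 0) & (np.diff(chrom) == 0)
    return np.flatnonzero(change) + 1


# ---------------------------------------------------------------------- #
# genome + genes


def build_genome_layout(
    spec: GenomeSpec,
    labels: np.ndarray | None = None,
    compartment_block_bins: int = 50,
    seed: int = 0,
) -> tuple[GenomeLayout, pd.DataFrame]:
    """Build the binned layout and an A-biased random gene table.

    Genes pick an A bin with probability ``r / (1 + r)`` (``r`` the A:B
    density ratio) and a B bin otherwise; the TSS is uniform within the bin
    and the strand is a fair coin.  Returns ``(layout, genes)`` where
    ``genes`` has columns ``gene_id, chrom, tss, strand, start, end``
    (0-based half-open gene body of fixed 10-kbp length, clipped).
    """
    names = tuple(f"chr{i + 1}" for i in range(len(spec.chrom_lengths)))
    layout = GenomeLayout(names, tuple(spec.chrom_lengths), spec.bin_size)
    if labels is None:
        labels = planted_compartment_labels(layout, compartment_block_bins)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    a_bins = np.flatnonzero(labels == "A")
    b_bins = np.flatnonzero(labels == "B")
    p_a = spec.density_ratio / (1.0 + spec.density_ratio)
    gene_len = 10_000
    rows = []
    for g in range(spec.n_genes):
        if (rng.random() < p_a and a_bins.size) or not b_bins.size:
            b = int(rng.choice(a_bins))
        else:
            b = int(rng.choice(b_bins))
        chrom, bstart, bend = layout.bin_span(b)
        tss = int(rng.integers(bstart, bend))
        strand = "+" if rng.random() < 0.5 else "-"
        clen = layout.lengths[layout.chrom_index(chrom)]
        if strand == "+":
            start, end = tss, min(tss + gene_len, clen)
        else:
            start, end = max(tss - gene_len + 1, 0), tss + 1
        rows.append((f"gene{g:05d}", chrom, tss, strand, start, end))
    genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "tss", "strand", "start", "end"]
    )
    return layout, genes


# ---------------------------------------------------------------------- #
# expected contact matrix


def _distance_kernel(s: np.ndarray, arch: ArchitectureSpec, bin_size: int) -> np.ndarray:
    """Piecewise power law in bin units, continuous at the breakpoints.

    Working in bin units keeps the kernel O(1) near the diagonal so the
    inter-chromosomal background weight ``beta`` is directly comparable to
    long-range intra contact values; the log-log slope is unit-invariant.
    """
    alphas = arch.decay_alphas
    bps = tuple(b / bin_size for b in arch.decay_breakpoints)
    out = np.empty_like(s, dtype=float)
    scale = 1.0
    lo = 0.0
    for k, alpha in enumerate(alphas):
        hi = bps[k] if k < len(bps) else np.inf
        sel = (s >= lo) & (s < hi)
        out[sel] = scale * s[sel] ** (-alpha)
        if np.isfinite(hi):
            # continuity: match value at the breakpoint
            scale = scale * hi ** (-alpha) / hi ** (-alphas[k + 1])
        lo = hi
    return out


def _end_window_flags(
    layout: GenomeLayout, window_bp: int, which: str
) -> np.ndarray:
    """Per-bin flag for bins whose midpoint lies in chromosome-end windows.

    ``which`` is ``"both"`` (telomeres: first and last window of each
    chromosome) or ``"start"`` (centromeres: chromosome start only, mouse
    acrocentric convention).
    """
    mids = layout.bin_midpoints()
    chrom = layout.chrom_of_bins()
    lengths = np.asarray(layout.lengths)[chrom]
    start_w = mids < window_bp
    if which == "start":
        return start_w
    return start_w | (mids >= lengths - window_bp)


def simulate_expected_matrix(
    layout: GenomeLayout,
    arch: ArchitectureSpec,
    labels: np.ndarray,
    telomere_window: int = 500_000,
    centromere_window: int | None = None,
) -> ContactMatrix:
    """Real-valued expected contact matrix with all signals planted.

    Intra-chromosomal pair (i, j): ``K(s) * (1 + a e_i e_j) * tau^[same TAD]``
    with ``s = max(|i-j|, 1)`` in bin units so the diagonal stays finite.
    Inter-chromosomal pair: ``beta * gamma^[both telomeric] * c^[both
    centromeric]``.  The result is symmetric and strictly positive.
    """
    labels = np.asarray(labels)
    if labels.shape != (layout.n_bins,):
        raise ValueError("labels must cover every bin")
    n = layout.n_bins
    chrom = layout.chrom_of_bins()
    same_chrom = chrom[:, None] == chrom[None, :]

    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :]).astype(float)
    s = np.maximum(d, 1.0)
    expected = _distance_kernel(s, arch, layout.bin_size)

    e = np.where(labels == "A", 1.0, -1.0)
    expected *= 1.0 + arch.amplitude * np.outer(e, e)

    tads = planted_tad_ids(layout, arch.tad_segment_bins)
    same_tad = tads[:, None] == tads[None, :]
    expected = np.where(same_tad, expected * arch.tau, expected)

    tel = _end_window_flags(layout, telomere_window, "both")
    cen = _end_window_flags(
        layout, telomere_window if centromere_window is None else centromere_window,
        "start",
    )
    inter = arch.beta * np.ones((n, n))
    inter *= np.where(np.outer(tel, tel), arch.gamma, 1.0)
    inter *= np.where(np.outer(cen, cen), arch.centromere_factor, 1.0)

    counts = np.where(same_chrom, expected, inter)
    counts = (counts + counts.T) / 2.0  # exact symmetry
    return ContactMatrix(layout=layout, counts=counts, normalization="raw",
                         meta={"expected": True})


def beta_for_inter_intra_ratio(
    layout: GenomeLayout,
    arch: ArchitectureSpec,
    labels: np.ndarray,
    target_ratio: float,
    chrom: int | str = 0,
    **kwargs,
) -> float:
    """Closed-form beta giving a target inter/intra ratio on one chromosome.

    The inter sum of a chromosome is linear in beta, so
    ``beta = target * intra_sum / inter_sum(beta=1)``.
    """
    probe = ArchitectureSpec(
        decay_alphas=arch.decay_alphas,
        decay_breakpoints=arch.decay_breakpoints,
        compartment_block_bins=arch.compartment_block_bins,
        amplitude=arch.amplitude,
        tad_segment_bins=arch.tad_segment_bins,
        tau=arch.tau,
        beta=1.0,
        gamma=arch.gamma,
        centromere_factor=arch.centromere_factor,
        seed=arch.seed,
    )
    m = simulate_expected_matrix(layout, probe, labels, **kwargs)
    sl = layout.chrom_slice(chrom)
    intra = m.counts[sl, sl].sum()
    inter = m.counts[sl, :].sum() - intra
    if inter <= 0:
        raise ValueError("chromosome has no inter-chromosomal pairs")
    return float(target_ratio * intra / inter)


# ---------------------------------------------------------------------- #
# read sampling and mixtures


def sample_contact_reads(
    expected: ContactMatrix, n_reads: int, seed: int = 0
) -> tuple[np.ndarray, ContactMatrix]:
    """Draw ``n_reads`` contacts multinomially from an expected matrix.

    Sampling is over unordered bin pairs (diagonal allowed, its mass
    down-weighted by 1/2 so the symmetric-matrix algebra stays simple).
    Returns the contact list as an ``(n_reads, 2)`` array with ``i <= j``
    and the accumulated raw count matrix.  Bit-reproducible given the seed.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    layout = expected.layout
    n = layout.n_bins
    iu, ju = np.triu_indices(n)
    w = expected.counts[iu, ju].astype(float).copy()
    w[iu == ju] *= 0.5
    total = w.sum()
    if n_reads == 0:
        return np.empty((0, 2), dtype=np.int32), contacts_to_matrix(
            np.empty((0, 2), int), layout
        )
    if total <= 0:
        raise ValueError("expected matrix has zero total mass")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_reads, w / total)
    nz = np.flatnonzero(draws)
    pairs = np.empty((n_reads, 2), dtype=np.int32)
    pairs[:, 0] = np.repeat(iu[nz], draws[nz])
    pairs[:, 1] = np.repeat(ju[nz], draws[nz])
    return pairs, contacts_to_matrix(pairs, layout)


def simulate_mixture(
    reads_a: np.ndarray,
    reads_b: np.ndarray,
    n_reads: int,
    proportions: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    seed: int = 0,
) -> list[np.ndarray]:
    """Contamination series: resample ``round(p n)`` contacts from pool B and
    the remainder from pool A, one dataset per proportion.

    The default six proportions (0 to 100% in steps of 20%) reproduce the
    standard purity-validation design.  Exact split, deterministic per seed.
    """
    reads_a = np.asarray(reads_a)
    reads_b = np.asarray(reads_b)
    datasets: list[np.ndarray] = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(proportions))
    for p, child in zip(proportions, children):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion {p} outside [0, 1]")
        n_b = int(round(p * n_reads))
        n_a = n_reads - n_b
        if n_a > 0 and reads_a.shape[0] == 0:
            raise ValueError("pool A empty but its share is positive")
        if n_b > 0 and reads_b.shape[0] == 0:
            raise ValueError("pool B empty but its share is positive")
        rng = np.random.default_rng(child)
        parts = []
        if n_a:
            parts.append(reads_a[rng.integers(0, reads_a.shape[0], n_a)])
        if n_b:
            parts.append(reads_b[rng.integers(0, reads_b.shape[0], n_b)])
        mixed = (
            np.concatenate(parts)
            if parts
            else np.empty((0, 2), dtype=reads_a.dtype if reads_a.size else np.int32)
        )
        datasets.append(mixed)
    return datasets


# ---------------------------------------------------------------------- #
# peaks and expression


def _promoter_interval(tss: int, strand: str, chrom_len: int,
                       window: int = PROMOTER_WINDOW) -> tuple[int, int]:
    """Strand-aware promoter window, 0-based half-open, clipped."""
    if strand == "+":
        return max(tss - window, 0), tss
    return tss + 1, min(tss + 1 + window, chrom_len)


def simulate_peak_tracks(
    layout: GenomeLayout,
    genes: pd.DataFrame,
    effect: EffectSpec,
    factor: str = "peak",
) -> pd.DataFrame:
    """Place peaks in promoter windows of distinct genes plus uniform background.

    Returns a sorted, non-self-overlapping BED-like frame with columns
    ``chrom, start, end, name`` plus a boolean ``promoter`` column and the
    id of the targeted gene (empty for background peaks).
    """
    rng = np.random.default_rng(effect.seed)
    n_prom = int(round(effect.promoter_fraction * effect.n_peaks))
    if n_prom > len(genes):
        raise ValueError(
            f"{n_prom} promoter peaks requested but only {len(genes)} genes"
        )
    if effect.n_peaks == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "name", "promoter", "gene_id"]
        )
    width = effect.peak_width
    lengths = dict(zip(layout.chrom_names, layout.lengths))

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.chrom_names}
    rows = []

    def overlaps(chrom: str, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in placed[chrom])

    prom_intervals: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.chrom_names}
    for _, g in genes.iterrows():
        s, e = _promoter_interval(int(g.tss), g.strand, lengths[g.chrom])
        prom_intervals[g.chrom].append((s, e))

    if n_prom > 0:
        chosen = rng.choice(len(genes), size=n_prom, replace=False)
        for gi in chosen:
            g = genes.iloc[int(gi)]
            ps, pe = _promoter_interval(int(g.tss), g.strand, lengths[g.chrom])
            if pe - ps < width:
                start = ps
            else:
                start = int(rng.integers(ps, pe - width + 1))
            end = start + width
            for _ in range(50):
                if not overlaps(g.chrom, start, end):
                    break
                start = ps if pe - ps < width else int(rng.integers(ps, pe - width + 1))
                end = start + width
            placed[g.chrom].append((start, end))
            rows.append((g.chrom, start, end, True, g.gene_id))

    n_bg = effect.n_peaks - n_prom
    clens = np.asarray(layout.lengths, dtype=float)
    p_chrom = clens / clens.sum()
    tries = 0
    while n_bg > 0:
        tries += 1
        if tries > 100_000:
            raise RuntimeError("could not place background peaks without overlap")
        c = int(rng.choice(layout.n_chroms, p=p_chrom))
        chrom = layout.chrom_names[c]
        start = int(rng.integers(0, layout.lengths[c] - width))
        end = start + width
        in_prom = any(s < end and start < e for s, e in prom_intervals[chrom])
        if in_prom or overlaps(chrom, start, end):
            continue
        placed[chrom].append((start, end))
        rows.append((chrom, start, end, False, ""))
        n_bg -= 1

    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "promoter", "gene_id"])
    order = {c: i for i, c in enumerate(layout.chrom_names)}
    peaks = peaks.sort_values(
        ["chrom", "start"], key=lambda s: s.map(order) if s.name == "chrom" else s
    ).reset_index(drop=True)
    peaks.insert(3, "name", [f"{factor}_{i:05d}" for i in range(len(peaks))])
    return peaks


def simulate_expression_table(
    genes: pd.DataFrame,
    gene_labels: np.ndarray,
    promoter_peak: np.ndarray,
    effect: EffectSpec,
    count_scale: float = 20.0,
) -> pd.DataFrame:
    """Log-normal expression with planted compartment and promoter-peak effects.

    ``log2 FPKM = N(mean, sd) + a_eff [label == A] + p_eff [promoter peak]``;
    counts are FPKM scaled by ``count_scale`` and rounded.  Columns:
    ``gene_id, fpkm, counts`` (indexed like ``genes``).
    """
    gene_labels = np.asarray(gene_labels)
    promoter_peak = np.asarray(promoter_peak, dtype=bool)
    if len(gene_labels) != len(genes) or len(promoter_peak) != len(genes):
        raise ValueError("per-gene annotations must match the gene table")
    rng = np.random.default_rng(effect.seed)
    log2 = rng.normal(effect.log2_mean, effect.log2_sd, size=len(genes))
    log2 = log2 + effect.compartment_a_log2_effect * (gene_labels == "A")
    log2 = log2 + effect.promoter_peak_log2_effect * promoter_peak
    fpkm = np.exp2(log2)
    counts = np.rint(fpkm * count_scale).astype(np.int64)
    return pd.DataFrame(
        {"gene_id": genes["gene_id"].to_numpy(), "fpkm": fpkm, "counts": counts}
    )
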