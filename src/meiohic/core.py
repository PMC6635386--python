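"""Matrix conditioning: low-count filtering, ICE balancing, scaling, obs/exp.

The processing order mirrors standard Hi-C practice: raw binned counts are
first cleaned of low-visibility bins (columns whose marginal falls below the
first antimode of the marginal distribution, floored at ``min_count``), then
balanced by iterative correction (ICE) so every usable bin has the same
total visibility, then optionally depth-scaled and distance-normalized.
"""

from __future__ import annotations

import warnings

import numpy as np

from .matrix import ContactMatrix

__all__ = [
    "filter_low_count_bins",
    "marginal_antimode_threshold",
    "ice_normalize",
    "scale_matrix",
    "observed_over_expected",
]


def marginal_antimode_threshold(marginals: np.ndarray, min_count: float = 10) -> float:
    """Low-count threshold from the first antimode of the marginal distribution.

    A Freedman-Diaconis histogram of ``log1p`` marginals is smoothed with a
    3-bin moving average; the first local minimum of the smoothed counts
    (an antimode separating the dead-bin mode from the main mass) defines
    the threshold.  To count as an antimode the trough must genuinely
    separate two modes — its smoothed height must fall below a quarter of
    the tallest mode — otherwise the distribution is treated as unimodal
    and the plain ``min_count`` cutoff applies.  The result is always
    floored at ``min_count``.
    """
    m = np.asarray(marginals, dtype=float)
    m = m[np.isfinite(m)]
    if m.size == 0:
        return float(min_count)
    x = np.log1p(m)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr <= 0:
        return float(min_count)
    width = 2.0 * iqr / np.cbrt(x.size)
    nbins = max(int(np.ceil((x.max() - x.min()) / width)), 1)
    hist, edges = np.histogram(x, bins=nbins)
    if hist.size < 3:
        return float(min_count)
    smooth = np.convolve(hist, np.ones(3) / 3.0, mode="same")
    centers = (edges[:-1] + edges[1:]) / 2.0
    antimode = None
    depth_cap = 0.25 * smooth.max()
    for i in range(1, smooth.size - 1):
        if (
            smooth[i] < smooth[i - 1]
            and smooth[i] <= smooth[i + 1]
            and smooth[i] < depth_cap
            and smooth[: i].max() > smooth[i]
        ):
            antimode = float(np.expm1(centers[i]))
            break
    if antimode is None:
        return float(min_count)
    return max(antimode, float(min_count))


def filter_low_count_bins(matrix: ContactMatrix, min_count: float = 10) -> ContactMatrix:
    """Mask bins whose marginal total falls below the antimode threshold.

    Operates on raw (unbalanced) matrices.  Masked bins are zeroed so they
    carry no counts downstream; the mask only ever grows.
    """
    if matrix.normalization != "raw":
        warnings.warn("low-count filtering is intended for raw matrices", stacklevel=2)
    out = matrix.copy()
    marg = out.marginals()
    threshold = marginal_antimode_threshold(marg[out.unmasked], min_count=min_count)
    newly = (marg < threshold) & out.unmasked
    out.mask |= newly
    if out.mask.all():
        raise ValueError("no usable bins: every bin fell below the low-count threshold")
    out.counts[out.mask, :] = 0.0
    out.counts[:, out.mask] = 0.0
    out.meta["low_count_threshold"] = float(threshold)
    return out


def _row_sum_cv(counts: np.ndarray, keep: np.ndarray) -> float:
    s = counts[np.ix_(keep, keep)].sum(axis=1)
    mu = s.mean()
    if mu == 0:
        return 0.0
    return float(s.std() / mu)


def ice_normalize(
    matrix: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> ContactMatrix:
    """Iterative correction (ICE) over the unmasked bins.

    Each pass divides the matrix by the outer product of normalized row
    sums until the coefficient of variation of the unmasked row sums drops
    below ``tol`` (or ``max_iter`` passes have run; ``max_iter=1`` gives the
    single-pass variant used on the compartment pathway).  The result is
    rescaled so the mean unmasked row sum of the input is preserved, and the
    accumulated per-bin biases are stored: ``balanced = raw / (b_i b_j)``
    up to that global rescale.

    Non-convergence is flagged in ``meta['ice_converged']``, not fatal.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    out = matrix.copy()
    keep = out.unmasked
    if not keep.any():
        raise ValueError("no usable bins")
    counts = out.counts
    target_mean = counts[np.ix_(keep, keep)].sum(axis=1).mean()
    biases = np.ones(out.n_bins)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        s = counts[np.ix_(keep, keep)].sum(axis=1)
        mu = s.mean()
        if mu == 0:
            break
        f = np.ones(out.n_bins)
        f[keep] = s / mu
        # guard dead rows inside the unmasked set
        f[f == 0] = 1.0
        counts = counts / np.outer(f, f)
        biases *= f
        if _row_sum_cv(counts, keep) < tol:
            converged = True
            break
    # preserve the mean unmasked row sum of the input
    cur_mean = counts[np.ix_(keep, keep)].sum(axis=1).mean()
    if cur_mean > 0:
        counts = counts * (target_mean / cur_mean)
    counts[~keep, :] = 0.0
    counts[:, ~keep] = 0.0
    out.counts = counts
    out.biases = biases
    out.normalization = "ICE"
    out.meta["ice_converged"] = bool(converged)
    out.meta["ice_iterations"] = int(iterations)
    out.meta["ice_row_sum_cv"] = _row_sum_cv(counts, keep)
    if not converged and max_iter > 1:
        warnings.warn(
            f"ICE did not reach row-sum CV < {tol} in {max_iter} iterations",
            stacklevel=2,
        )
    return out


def scale_matrix(matrix: ContactMatrix, target_total: float) -> ContactMatrix:
    """Multiply every entry by ``target_total / total`` (full-matrix sum).

    ``target_total=1`` gives the probability normalization used for contact
    probability curves; ``1e6`` gives per-million counts; ``2e8`` emulates a
    fixed 100M-contact sequencing depth.
    """
    total = matrix.total()
    if total <= 0:
        raise ValueError("cannot scale a zero-total matrix")
    out = matrix.copy()
    out.counts = out.counts * (float(target_total) / total)
    out.normalization = "scaled"
    out.meta["scaled_to"] = float(target_total)
    return out


def observed_over_expected(matrix: ContactMatrix) -> ContactMatrix:
    """Distance-normalize each chromosome: entry / mean of its diagonal.

    The expected value at separation ``d`` is the mean over unmasked intra
    pairs of that chromosome at distance ``d`` bins.  Strata with zero mean
    and all inter-chromosomal entries become NaN.
    """
    out = matrix.copy()
    n = out.n_bins
    res = np.full((n, n), np.nan)
    keep = out.unmasked
    for c in range(out.layout.n_chroms):
        sl = out.layout.chrom_slice(c)
        block = out.counts[sl, sl]
        k = keep[sl]
        nb = block.shape[0]
        oe = np.full_like(block, np.nan)
        for d in range(nb):
            diag = np.diagonal(block, offset=d)
            dk = k[: nb - d] & k[d:]
            if not dk.any():
                continue
            mu = diag[dk].mean()
            if mu == 0:
                continue
            vals = np.full(nb - d, np.nan)
            vals[dk] = diag[dk] / mu
            idx = np.arange(nb - d)
            oe[idx, idx + d] = vals
            oe[idx + d, idx] = vals
        res[sl, sl] = oe
    out.counts = res
    out.normalization = "obs/exp"
    return out
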