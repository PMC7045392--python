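"""Copy-number profiling by marker-frequency analysis (MFA).

In an unsynchronized replicating population, sequencing depth decreases
from active replication origins toward the terminus, so the binned,
normalized read depth is a proxy for relative copy number. This module
turns a per-base depth stream into that profile: fixed-width binning,
normalization by the mode of the bin-count distribution, log2 transform,
recentering of coordinates on *oriC*, and LOESS smoothing with optional
exclusion (deletions) and reversal (inversions) of intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import ChromosomeMap

__all__ = [
    "BinnedCoverage",
    "SmoothedProfile",
    "bin_coverage",
    "normalize_by_mode",
    "recenter_on_oriC",
    "loess_fit",
]


@dataclass
class BinnedCoverage:
    """Fixed-width window counts and their normalized log2 values.

    ``norm_log2`` is NaN for masked bins (zero counts, MAD outliers, the
    partial last bin is additionally excluded from mode estimation).
    """

    chrom: ChromosomeMap
    bin_size: int
    starts: np.ndarray           # 1-based first position of each bin
    counts: np.ndarray           # summed per-base depth per bin
    norm_log2: np.ndarray | None = None
    masked: np.ndarray | None = None
    mode: float | None = None

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    @property
    def widths(self) -> np.ndarray:
        w = np.full(self.n_bins, self.bin_size, dtype=int)
        w[-1] = self.chrom.length - self.starts[-1] + 1
        return w

    @property
    def has_partial_last(self) -> bool:
        return self.chrom.length % self.bin_size != 0

    @property
    def midpoints(self) -> np.ndarray:
        """Bin midpoint genome coordinates (float)."""
        return self.starts + (self.widths - 1) / 2.0


def bin_coverage(depth: np.ndarray, bin_size: int, chrom: ChromosomeMap) -> BinnedCoverage:
    """Sum per-base depth into non-overlapping ``bin_size``-bp windows.

    The number of bins is ``ceil(L / bin_size)``; on lengths that are
    not multiples of the bin size the last bin is shorter and is flagged
    (excluded from mode estimation downstream).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if bin_size > chrom.length:
        raise ValueError(f"bin_size {bin_size} exceeds chromosome length {chrom.length}")
    if len(depth) != chrom.length:
        raise ValueError("depth stream must cover the whole chromosome")
    n = math.ceil(chrom.length / bin_size)
    edges = np.arange(n) * bin_size
    counts = np.add.reduceat(np.asarray(depth, dtype=float), edges)
    if np.any(counts < 0):
        raise ValueError("negative depth")
    return BinnedCoverage(chrom=chrom, bin_size=bin_size, starts=edges + 1, counts=counts)


def _estimate_mode(counts: np.ndarray) -> float:
    """Histogram mode of positive bin counts.

    Histogram cells are ``median/50`` wide (so the estimate scales with
    overall depth and normalization is invariant to rescaling all
    counts); ties broken toward the smaller count; the estimate is the
    mean of the member counts, so a constant profile normalizes to
    exactly 0 log2.
    """
    pos = counts[counts > 0]
    if len(pos) == 0:
        raise ValueError("all-zero profile: mode undefined")
    width = float(np.median(pos)) / 50.0
    keys = np.floor(pos / width).astype(np.int64)
    uniq, freq = np.unique(keys, return_counts=True)
    best = uniq[freq == freq.max()].min()  # tie -> smaller count
    return float(pos[keys == best].mean())


def normalize_by_mode(binned: BinnedCoverage, outlier_mad: float = 4.0) -> BinnedCoverage:
    """Fill ``norm_log2 = log2(count / mode)`` and the bin mask.

    The mode is estimated from full-width nonzero bins. Zero-count bins
    are masked (log2 undefined), as are bins whose ``norm_log2`` lies
    beyond ``outlier_mad`` median-absolute-deviations — a deterministic
    stand-in for removing visually obvious outliers before fitting.
    Pass ``outlier_mad=None`` to disable outlier masking.
    """
    counts = binned.counts
    full = np.ones(binned.n_bins, dtype=bool)
    if binned.has_partial_last:
        full[-1] = False
    mode = _estimate_mode(counts[full])
    with np.errstate(divide="ignore"):
        norm = np.where(counts > 0, np.log2(np.maximum(counts, 1e-300) / mode), np.nan)
    masked = ~np.isfinite(norm)
    if outlier_mad is not None:
        valid = norm[~masked]
        med = np.median(valid)
        mad = np.median(np.abs(valid - med))
        if mad > 0:
            masked |= np.where(np.isfinite(norm), np.abs(norm - med) > outlier_mad * 1.4826 * mad, True)
    return replace(binned, norm_log2=norm, masked=masked, mode=mode)


def recenter_on_oriC(positions, chrom: ChromosomeMap):
    """Signed bp offsets from oriC in ``(-L/2, +L/2]`` (clockwise positive)."""
    return chrom.recenter(positions)


@dataclass
class SmoothedProfile:
    """A LOESS-fitted copy-number curve on the bin grid.

    ``offsets`` are oriC-recentered signed positions, sorted ascending;
    ``fitted_log2`` is the smoothed normalized log2 copy number at each
    grid point. The curve is circular: evaluation wraps with period L.
    """

    chrom: ChromosomeMap
    offsets: np.ndarray
    fitted_log2: np.ndarray
    span: float
    masked_intervals: tuple = ()

    @property
    def genome_positions(self) -> np.ndarray:
        return self.chrom.uncenter(self.offsets)

    def value_at(self, genome_positions):
        """Fitted log2 value at arbitrary genome coordinates (circular interp)."""
        x = self.chrom.recenter(genome_positions)
        out = np.interp(np.atleast_1d(x), self.offsets, self.fitted_log2,
                        period=self.chrom.length)
        return float(out[0]) if np.ndim(genome_positions) == 0 else out

    def roughness(self) -> float:
        """Mean squared second difference of the fitted curve (wrapped)."""
        f = self.fitted_log2
        f3 = np.concatenate([f[-1:], f, f[:1]])
        d2 = np.diff(f3, n=2)
        return float(np.mean(d2**2))


def _check_intervals(intervals, chrom: ChromosomeMap, label: str):
    ivs = [(int(a), int(b)) for a, b in intervals]
    for a, b in ivs:
        if not (1 <= a <= b <= chrom.length):
            raise ValueError(f"{label} interval ({a}, {b}) outside chromosome (wrapping intervals unsupported)")
    ivs.sort()
    for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
        if a2 <= b1:
            raise ValueError(f"overlapping {label} intervals ({a1},{b1}) and ({a2},{b2})")
    return ivs


def _in_any(positions: np.ndarray, intervals) -> np.ndarray:
    hit = np.zeros(len(positions), dtype=bool)
    for a, b in intervals:
        hit |= (positions >= a) & (positions <= b)
    return hit


def loess_fit(
    binned: BinnedCoverage,
    span: float = 0.1,
    exclusions=(),
    inversions=(),
    pad_frac: float = 0.02,
    iterations: int = 2,
) -> SmoothedProfile:
    """LOESS-smooth the normalized profile against recentered position.

    Local degree-1 regression with tricube weights (statsmodels
    ``lowess``); ``span`` is the fraction of bins in each local window.
    Bins inside ``exclusions`` (known deletions) are dropped before the
    fit; bins inside each ``inversions`` interval have their positions
    reflected about the interval midpoint, which undoes a copy-number
    flip so the fit recovers the sample's own gradient. To avoid edge
    artifacts on the circular axis, each end of the recentered axis is
    padded with the wrapped ``pad_frac`` of bins from the opposite end;
    the padding is discarded after fitting. Fitted values are returned
    on the full bin grid.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if binned.norm_log2 is None or binned.masked is None:
        binned = normalize_by_mode(binned)
    excl = _check_intervals(exclusions, binned.chrom, "exclusion")
    invs = _check_intervals(inversions, binned.chrom, "inversion")

    mid = binned.midpoints.copy()
    keep = ~binned.masked & ~_in_any(mid, excl)
    for a, b in invs:
        inside = (mid >= a) & (mid <= b)
        mid[inside] = a + b - mid[inside]
    x = binned.chrom.recenter(mid[keep])
    y = binned.norm_log2[keep]
    if len(x) < 10:
        raise ValueError(f"only {len(x)} unmasked bins; need at least 10 to fit")

    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    L = binned.chrom.length
    npad = max(2, int(round(pad_frac * len(x))))
    xp = np.concatenate([x[-npad:] - L, x, x[:npad] + L])
    yp = np.concatenate([y[-npad:], y, y[:npad]])
    # keep the local window at span * n original bins despite padding
    frac = min(1.0, span * len(x) / len(xp))
    delta = max(binned.bin_size, 1e-3 * L)
    fit = lowess(yp, xp, frac=frac, it=iterations, delta=delta, return_sorted=True)
    fx, fy = fit[:, 0], fit[:, 1]
    core = (fx > -L / 2) & (fx <= L / 2)
    fx, fy = fx[core], fy[core]
    # deduplicate x (lowess merges ties); interp requires increasing xp
    fx, idx = np.unique(fx, return_index=True)
    fy = fy[idx]

    grid = np.sort(binned.chrom.recenter(binned.midpoints))
    fitted = np.interp(grid, fx, fy, period=L)
    return SmoothedProfile(
        chrom=binned.chrom,
        offsets=grid,
        fitted_log2=fitted,
        span=span,
        masked_intervals=tuple(excl),
    )
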