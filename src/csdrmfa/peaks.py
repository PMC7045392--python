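"""oriK peak calling, origin localization and replication-activity ratios.

A position is called an oriK peak when the LOESS-smoothed copy-number
curve is a local maximum whose fitted values are non-increasing moving
outward from the peak, sampled at 10-kbp steps up to ±100 kbp in both
directions on the circle. The ori-to-ter ratio is the linear fold
between the fitted maximum outside the terminus region and the fitted
value at *dif*; the max/min ratio is the fold between the fitted
extremes. Peak ranges aggregate called positions across strains by
single-linkage clustering on circular distance.

Smoothed-curve maxima localize a shared or asymmetric origin poorly:
smoothing displaces the apex of a shallow, one-sidedly steep peak by up
to the smoothing window. :func:`locate_origins` therefore refines origin
positions by weighted least squares on the binned log2 profile under the
exponential gradient-mixture model (each origin contributes
``w * 2^(A (1 - d/D))`` in fork-travel distance ``d``), multi-started
from the called peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .genome import ChromosomeMap, circular_distance
from .mfa import BinnedCoverage, SmoothedProfile, loess_fit

__all__ = [
    "OriKPeak",
    "PeakRange",
    "call_orik_peaks",
    "locate_origins",
    "ori_ter_ratio",
    "max_min_ratio",
    "peak_ranges",
]


@dataclass
class OriKPeak:
    position: int            # genome coordinate of the fitted maximum
    fitted_log2: float
    ratio_to_minimum: float  # linear fold over the profile's LOESS minimum
    in_ter: bool


@dataclass
class PeakRange:
    label: str
    start: int
    end: int
    members: dict[str, list[int]]  # strain -> member peak positions


def call_orik_peaks(
    profile: SmoothedProfile,
    window: int = 100_000,
    step: int = 10_000,
    eps: float = 1e-4,
    min_prominence_log2: float = 0.1,
) -> list[OriKPeak]:
    """Call oriK peaks on a smoothed profile.

    A grid point qualifies if it is a circular local maximum of the
    fitted curve and the curve, sampled outward at ``step`` intervals to
    ``±window``, never increases by more than ``eps`` log2 between
    consecutive samples on either side. Peaks closer than ``window``
    (circular distance) are merged keeping the higher one. Candidates
    rising less than ``min_prominence_log2`` above the profile minimum
    are dropped, so an essentially flat profile yields no calls.
    """
    chrom = profile.chrom
    L = chrom.length
    if window >= L / 2:
        raise ValueError("window must be smaller than half the chromosome")
    grid_spacing = float(np.median(np.diff(profile.offsets)))
    if grid_spacing > window / 10:
        raise ValueError("profile grid too coarse for the peak window")

    f = profile.fitted_log2
    n = len(f)
    left = np.roll(f, 1)
    right = np.roll(f, -1)
    is_max = (f >= left) & (f >= right) & ((f > left) | (f > right))

    fit_min = float(f.min())
    genome_pos = profile.genome_positions
    offs = np.arange(step, window + 1, step, dtype=float)

    candidates: list[OriKPeak] = []
    for i in np.flatnonzero(is_max):
        if f[i] - fit_min < min_prominence_log2:
            continue
        p = genome_pos[i]
        ok = True
        for sign in (+1.0, -1.0):
            samples = profile.value_at((p - 1 + sign * offs) % L + 1)
            path = np.concatenate([[f[i]], samples])
            if np.any(np.diff(path) > eps):
                ok = False
                break
        if ok:
            candidates.append(
                OriKPeak(
                    position=int(round(p)),
                    fitted_log2=float(f[i]),
                    ratio_to_minimum=float(2.0 ** (f[i] - fit_min)),
                    in_ter=chrom.contains_ter(int(round(p))),
                )
            )

    # merge peaks closer than the window, keeping the higher fitted value
    candidates.sort(key=lambda pk: -pk.fitted_log2)
    kept: list[OriKPeak] = []
    for pk in candidates:
        if all(circular_distance(pk.position, q.position, L) >= window for q in kept):
            kept.append(pk)
    kept.sort(key=lambda pk: pk.position)
    return kept


def _mixture_residuals(theta, x, y, k, L):
    D = L / 2
    pos = theta[:k]
    amps = theta[k:2 * k]
    wl = theta[2 * k:3 * k]
    w = np.exp(wl - wl.max())
    w = w / w.sum()
    c = np.zeros_like(x)
    for i in range(k):
        d = np.abs((x - pos[i] + D) % L - D)
        c += w[i] * 2.0 ** (amps[i] * (1 - d / D))
    return np.log2(c) + theta[-1] - y


def locate_origins(
    binned: BinnedCoverage,
    n_origins: int = 2,
    span: float = 0.1,
    window: int = 400_000,
    max_starts: int = 6,
) -> np.ndarray:
    """Estimate origin positions by fitting the gradient-mixture model.

    Least-squares fit of ``log2(sum_i w_i 2^(A_i (1 - d_i/D))) + c`` to
    the normalized log2 bin values, with origin positions, amplitudes,
    mixture weights and the offset free. Starts are taken from the
    called peaks, augmented with coarse alternatives when fewer than
    ``n_origins`` peaks exist or starts may sit on one flank; the best
    final cost wins. Positions are searched within ``±window`` of each
    start. Returns sorted genome coordinates.
    """
    if binned.norm_log2 is None or binned.masked is None:
        raise ValueError("normalize the binned coverage first")
    chrom = binned.chrom
    L = chrom.length
    sel = ~binned.masked
    x = binned.midpoints[sel]
    y = binned.norm_log2[sel]
    k = n_origins

    peaks = sorted(call_orik_peaks(loess_fit(binned, span=span)),
                   key=lambda p: -p.fitted_log2)
    starts: list[list[float]] = []
    if len(peaks) >= k:
        starts.append([float(p.position) for p in peaks[:k]])
    if peaks and k == 2:
        top = float(peaks[0].position)
        for alt in np.arange(8) * L / 8 + 1:
            if circular_distance(top, alt, L) > 600_000:
                starts.append([top, float(alt)])
    if not starts:
        starts.append([L * (i + 1) / (k + 1) for i in range(k)])

    best = None
    for init in starts[:max_starts]:
        init = np.asarray(init, dtype=float)
        theta0 = np.concatenate([init, [1.0] * k, [0.0] * k, [0.0]])
        lb = np.concatenate([init - window, [0.01] * k, [-4.0] * k, [-2.0]])
        ub = np.concatenate([init + window, [3.0] * k, [4.0] * k, [2.0]])
        res = least_squares(
            _mixture_residuals, theta0, args=(x, y, k, L), bounds=(lb, ub),
            method="trf", max_nfev=300,
            x_scale=np.concatenate([[1e4] * k, [0.5] * k, [0.5] * k, [0.2]]),
        )
        if best is None or res.cost < best.cost:
            best = res
    return np.sort(best.x[:k] % L)


def _nonter_mask(profile: SmoothedProfile) -> np.ndarray:
    pos = profile.genome_positions
    return ~np.array([profile.chrom.contains_ter(int(round(p))) for p in pos])


def ori_ter_ratio(profile: SmoothedProfile, chrom: ChromosomeMap | None = None) -> float:
    """Linear fold of the fitted maximum (ter excluded) over the fit at *dif*.

    Values below 1 are legal: in a strain whose only strong peak is the
    terminus fork trap, the *dif* fit can exceed every non-ter value.
    """
    chrom = chrom or profile.chrom
    outside = _nonter_mask(profile)
    if not outside.any():
        raise ValueError("entire non-ter region masked")
    max_fit = float(profile.fitted_log2[outside].max())
    dif_fit = profile.value_at(chrom.dif_position)
    return float(2.0 ** (max_fit - dif_fit))


def max_min_ratio(profile: SmoothedProfile, exclude_ter: bool = True) -> float:
    """Linear fold between the fitted maximum and minimum of the profile."""
    f = profile.fitted_log2
    if exclude_ter:
        outside = _nonter_mask(profile)
        if not outside.any():
            raise ValueError("entire non-ter region masked")
        max_fit = float(f[outside].max())
    else:
        max_fit = float(f.max())
    return float(2.0 ** (max_fit - f.min()))


def peak_ranges(
    peaks_by_strain: dict[str, list[int]],
    cluster_radius: int = 150_000,
    chrom: ChromosomeMap | None = None,
    length: int | None = None,
) -> list[PeakRange]:
    """Cluster per-strain peak positions into cross-strain peak ranges.

    Single-linkage at ``cluster_radius`` circular distance; each cluster
    is reported as [min member position, max member position].
    """
    if chrom is not None:
        length = chrom.length
    if length is None:
        raise ValueError("supply chrom or length")
    items = [(pos, strain) for strain, plist in peaks_by_strain.items() for pos in plist]
    if not items:
        return []
    items.sort()
    positions = np.array([p for p, _ in items], dtype=float)
    # chain-merge along the sorted circle
    breaks = np.flatnonzero(np.diff(positions) > cluster_radius)
    clusters = np.split(np.arange(len(items)), breaks + 1)
    # wrap: merge first and last cluster if they touch across the origin
    if len(clusters) > 1:
        wrap_gap = length - positions[-1] + positions[0]
        if wrap_gap <= cluster_radius:
            clusters[0] = np.concatenate([clusters[-1], clusters[0]])
            clusters.pop()
    ranges = []
    for k, idx in enumerate(clusters):
        members: dict[str, list[int]] = {}
        for i in idx:
            pos, strain = items[i]
            members.setdefault(strain, []).append(pos)
        pos_all = [items[i][0] for i in idx]
        ranges.append(
            PeakRange(label=f"range{k + 1}", start=min(pos_all), end=max(pos_all), members=members)
        )
    ranges.sort(key=lambda r: r.start)
    for k, r in enumerate(ranges):
        r.label = f"range{k + 1}"
    return ranges
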