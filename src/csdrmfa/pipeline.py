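"""End-to-end orchestration of the MFA stages.

One call takes binned coverage to the corrected profile and its derived
statistics: normalize, detect deletions/amplifications and inversions,
re-fit the curve with deletions excluded and inversions reversed, call
oriK peaks and compute the replication-activity ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .mfa import BinnedCoverage, SmoothedProfile, loess_fit, normalize_by_mode
from .peaks import OriKPeak, call_orik_peaks, max_min_ratio, ori_ter_ratio
from .variants import CopyStepCall, InversionCall, detect_copy_steps, detect_inversions

__all__ = ["MFAResult", "analyze_binned"]


@dataclass
class MFAResult:
    binned: BinnedCoverage
    profile: SmoothedProfile          # corrected fit (deletions excluded, inversions reversed)
    uncorrected_profile: SmoothedProfile
    peaks: list[OriKPeak]
    inversions: list[InversionCall]
    copy_steps: list[CopyStepCall]
    ori_ter: float
    max_min: float


def analyze_binned(
    binned: BinnedCoverage,
    span: float = 0.1,
    peak_window: int = 100_000,
    scan_variants: bool = True,
    known_deletions=(),
    known_inversions=(),
) -> MFAResult:
    """Run the full copy-number analysis on binned coverage.

    Structural variants are detected from the normalized profile unless
    supplied as known intervals; the LOESS fit used for peak calling and
    ratios excludes deletions and reverses inversions.
    """
    if binned.norm_log2 is None:
        binned = normalize_by_mode(binned)
    uncorrected = loess_fit(binned, span=span)
    steps = list(detect_copy_steps(binned)) if scan_variants else []
    invs = list(detect_inversions(binned, span=span)) if scan_variants else []
    deletions = list(known_deletions) + [
        (c.start, c.end) for c in steps if c.direction == "deletion"
    ]
    inversions = list(known_inversions) + [(c.start, c.end) for c in invs]
    profile = (
        loess_fit(binned, span=span, exclusions=deletions, inversions=inversions)
        if (deletions or inversions)
        else uncorrected
    )
    return MFAResult(
        binned=binned,
        profile=profile,
        uncorrected_profile=uncorrected,
        peaks=call_orik_peaks(profile, window=peak_window),
        inversions=invs,
        copy_steps=steps,
        ori_ter=ori_ter_ratio(profile),
        max_min=max_min_ratio(profile),
    )
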