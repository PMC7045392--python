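"""Copy-number profiles and replication-activity ratios per strain class.

Reproduces the exponential- vs stationary-phase MFA contrast: a steep
symmetric gradient for the wild type (ori:ter ~2.5), a flat curve with a
terminus peak for the cSDR parent, a dominant 4.5-Mb origin for the
suppressor, and a flat stationary profile. Writes per-strain profiles
and a summary table under results/.
"""

from pathlib import Path

import pandas as pd

from csdrmfa.mfa import loess_fit, normalize_by_mode
from csdrmfa.peaks import max_min_ratio, ori_ter_ratio
from csdrmfa.simulate import scenario_presets, simulate_coverage

BIN_SIZE = 1000
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, scen in scenario_presets().items():
        binned = normalize_by_mode(simulate_coverage(scen, bin_size=BIN_SIZE))
        # fit the sample's own curve: reverse the planted inversion so the
        # gradient is read in the sample's coordinates
        profile = loess_fit(binned, inversions=scen.inversions)
        pd.DataFrame({
            "bin_start": binned.starts,
            "recentered_pos": binned.chrom.recenter(binned.midpoints),
            "raw_count": binned.counts,
            "norm_log2": binned.norm_log2,
        }).to_csv(OUT / f"profile_{name}.tsv", sep="\t", index=False,
                  float_format="%.5g")
        rows.append({
            "strain": name,
            "ori_ter_ratio": round(ori_ter_ratio(profile), 3),
            "max_min_ratio": round(max_min_ratio(profile), 3),
            "fitted_range_log2": round(float(profile.fitted_log2.max()
                                             - profile.fitted_log2.min()), 3),
        })
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "copy_number_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print("\nThe wild-type gradient is ~2.5-fold ori over ter; the cSDR parent "
          "is flat with its strongest feature in ter; stationary is flat.")


if __name__ == "__main__":
    main()
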