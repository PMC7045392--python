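"""Head-on collision scores and expression/copy-number correlation.

Scores P(HO) = lagging-strand RNA coverage / total over the 3.3-4.25 Mb
region for each strain class against its predominant origin (oriC for
the wild type, oriK45 for the cSDR parent and the inverted suppressor).
The inversion moves the rRNA operons between oriC and oriK45 back to the
leading strand of oriK45-initiated forks, cutting the rRNA head-on
burden. Also demonstrates that LOESS smoothing of per-gene log2 fold
changes against position exposes the copy-number-driven component of
expression differences.
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from csdrmfa.collision import (
    head_on_fraction,
    logfc_per_gene,
    positional_smooth_and_correlate,
)
from csdrmfa.genome import ECOLI_K12
from csdrmfa.simulate import (
    expression_presets,
    expected_copy_number,
    scenario_presets,
    simulate_expression,
)

REGION = (3_300_000, 4_250_000)
OUT = Path(__file__).resolve().parent.parent / "results"


def collision_table() -> pd.DataFrame:
    rows = []
    for name, cfg in expression_presets(seed=0).items():
        expr = simulate_expression(cfg["expr"])
        for cls in ("all", "rRNA", "mRNA"):
            sc = head_on_fraction(expr, list(cfg["genes"]), REGION, cfg["origin"],
                                  ECOLI_K12, gene_class_filter=cls)
            rows.append({"strain": name, "origin": cfg["origin"],
                         "gene_class": cls, "p_ho": round(sc.p_ho, 3),
                         "n_genes": sc.n_genes})
    return pd.DataFrame(rows)


def expression_correlation() -> pd.DataFrame:
    """Dosage-driven expression: genes near an active origin are amplified."""
    eps = expression_presets(seed=0)
    genes = list(eps["wild-type-like"]["genes"])
    presets = scenario_presets()
    rng = np.random.default_rng(90)
    mids = np.array([g.midpoint for g in genes])
    out = []
    for name in ("wild-type-like", "suppressor-like"):
        dosage = expected_copy_number(
            dataclasses.replace(presets[name], inversions=()), mids,
        )
        parent_dosage = expected_copy_number(presets["csdr-parent-like"], mids)
        base = {g.gene_id: 200.0 for g in genes}
        # RNA counts follow dosage with strong gene-level noise
        rna_a = {g.gene_id: base[g.gene_id] * d * rng.lognormal(0, 0.6)
                 for g, d in zip(genes, dosage)}
        rna_b = {g.gene_id: base[g.gene_id] * d * rng.lognormal(0, 0.6)
                 for g, d in zip(genes, parent_dosage)}
        dna_a = {g.gene_id: 100.0 * d for g, d in zip(genes, dosage)}
        dna_b = {g.gene_id: 100.0 * d for g, d in zip(genes, parent_dosage)}
        lfc_rna = logfc_per_gene(rna_a, rna_b)
        lfc_dna = logfc_per_gene(dna_a, dna_b)
        raw, smooth = positional_smooth_and_correlate(lfc_rna, lfc_dna, genes,
                                                      ECOLI_K12)
        out.append({"comparison": f"{name} vs csdr-parent-like",
                    "pearson_raw": round(raw, 3),
                    "pearson_smoothed": round(smooth, 3)})
    return pd.DataFrame(out)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pho = collision_table()
    pho.to_csv(OUT / "collision_scores.tsv", sep="\t", index=False)
    print(pho.to_string(index=False))
    print("\nrRNA head-on burden: parent (oriK45, no inversion) is highest; the "
          "inversion restores co-directionality; wild type (oriC) is lowest.")

    corr = expression_correlation()
    corr.to_csv(OUT / "expression_correlation.tsv", sep="\t", index=False)
    print("\n" + corr.to_string(index=False))
    print("\nSmoothing against position lifts the RNA/DNA fold-change "
          "correlation well above the raw per-gene value.")


if __name__ == "__main__":
    main()
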