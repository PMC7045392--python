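"""Generate the four synthetic strain classes used throughout the analysis.

Writes binned coverage (bedGraph), the genome landmark map, a toy gene
table and stranded expression counts for each preset under
results/sim/<preset>/, plus the planted ground truth.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np

from csdrmfa.io import write_coverage, write_genome_map
from csdrmfa.simulate import (
    expression_presets,
    scenario_presets,
    simulate_coverage,
    simulate_expression,
)

BIN_SIZE = 1000
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    eps = expression_presets(seed=0)
    for name, scen in scenario_presets().items():
        d = OUT / name
        d.mkdir(exist_ok=True)
        binned = simulate_coverage(scen, bin_size=BIN_SIZE)
        depth = np.repeat(binned.counts / binned.widths, binned.widths)
        write_coverage(d / "coverage.bedGraph", depth, scen.chrom)
        write_genome_map(d / "genome_map.yaml", scen.chrom)
        cfg = eps.get(name)
        if cfg is not None:
            expr = simulate_expression(cfg["expr"])
            with open(d / "expression.tsv", "w") as fh:
                fh.write("gene_id\tcoverage\n")
                for gid, v in expr.items():
                    fh.write(f"{gid}\t{v:g}\n")
            with open(d / "genes.tsv", "w") as fh:
                fh.write("gene_id\tstart\tend\tstrand\tgene_class\n")
                for g in cfg["genes"]:
                    fh.write(f"{g.gene_id}\t{g.start}\t{g.end}\t{g.strand}\t{g.gene_class}\n")
        with open(d / "truth.json", "w") as fh:
            json.dump(dataclasses.asdict(scen), fh, indent=2, default=str)
        print(f"{name}: mean depth/bin {binned.counts.mean():.0f}, "
              f"origins {[o for o, _ in scen.origins]}")


if __name__ == "__main__":
    main()
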