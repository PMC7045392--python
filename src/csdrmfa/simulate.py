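"""Synthetic MFA data with known ground truth.

Every input the pipeline consumes can be generated here from explicit
parameters and a seed: binned sequencing coverage with planted origins,
terminus fork trap, inversions and deletions; stranded per-gene RNA
counts with rRNA-dominated expression; and genome sequences with planted
R-loop-forming cassettes.

The copy-number model is phenomenological: each origin contributes an
exponential-of-linear gradient 2^(A * (1 - d/D)) in fork-travel distance
d (bidirectional forks stopping at the origin's antipode, or at the
terminus-region edges when the fork trap is on), mixed by origin weight;
the trap adds a log2 plateau over the terminus region. Read noise is
negative binomial. No cell-cycle mechanics are simulated — downstream
statistics depend only on the gradient shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import ChromosomeMap, GeneRecord, ECOLI_K12, RRN_OPERONS
from .mfa import BinnedCoverage, bin_coverage
from .rlfs import reverse_complement

__all__ = [
    "ReplicationScenario",
    "ExpressionScenario",
    "expected_copy_number",
    "simulate_coverage",
    "simulate_expression",
    "synthesize_genome_with_rlfs",
    "scenario_presets",
    "expression_presets",
    "make_gene_table",
    "apply_inversion_to_genes",
    "ORIK45_POSITION",
]

ORIK45_POSITION = 4_510_000


@dataclass(frozen=True)
class ReplicationScenario:
    """Full parameterization of a synthetic MFA experiment."""

    chrom: ChromosomeMap
    origins: tuple  # ((position, weight), ...); weights sum to 1
    amplitudes: tuple  # peak-to-terminus gradient height, log2, per origin
    ter_trap: bool = False
    trap_peak_log2: float = 0.0
    inversions: tuple = ()
    deletions: tuple = ()
    depth_per_bin: float = 200.0
    dispersion: float = 50.0  # negative-binomial size parameter
    seed: int = 0

    def __post_init__(self) -> None:
        w = sum(w for _, w in self.origins)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"origin weights sum to {w}, expected 1")
        if len(self.amplitudes) != len(self.origins):
            raise ValueError("need one amplitude per origin")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be >= 0")
        ivs = sorted(list(self.inversions) + list(self.deletions))
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if a2 <= b1:
                raise ValueError("scenario intervals overlap")


def _sample_to_reference(scenario: ReplicationScenario, positions: np.ndarray) -> np.ndarray:
    """Map reference coordinates to the sample's own coordinates.

    Reads from an inverted segment map back to reflected positions; the
    returned array is NaN where the reference position is deleted in
    the sample.
    """
    x = positions.astype(float).copy()
    for a, b in scenario.inversions:
        inside = (x >= a) & (x <= b)
        x[inside] = a + b - x[inside]
    for a, b in scenario.deletions:
        inside = (x >= a) & (x <= b)
        x[inside] = np.nan
    return x


def expected_copy_number(scenario: ReplicationScenario, positions) -> np.ndarray:
    """Relative (linear) expected copy number at reference coordinates.

    c(x) = sum_i w_i * 2^(A_i * (1 - d_i(x)/D_i)) with fork-travel
    distance d and per-direction maximal travel D; deleted positions are
    0; the fork-trap plateau multiplies the terminus region by
    2^trap_peak_log2.
    """
    pos = np.atleast_1d(np.asarray(positions, dtype=float))
    if np.any((pos < 1) | (pos > scenario.chrom.length)):
        raise ValueError("position outside chromosome")
    chrom = scenario.chrom
    L = chrom.length
    x = _sample_to_reference(scenario, pos)
    deleted = np.isnan(x)
    x = np.where(deleted, 1.0, x)

    tstart, tend = chrom.ter_region
    in_ter = np.array([chrom.contains_ter(int(round(p))) for p in x])
    c = np.zeros_like(x)
    for (origin, weight), amp in zip(scenario.origins, scenario.amplitudes):
        if scenario.ter_trap:
            d_cw = np.mod(x - origin, L)
            d_ccw = np.mod(origin - x, L)
            D_cw = (tstart - origin) % L
            D_ccw = (origin - tend) % L
            expo = np.where(
                in_ter, 0.0,
                np.where(d_cw <= D_cw, amp * (1 - d_cw / D_cw), amp * (1 - d_ccw / D_ccw)),
            )
        else:
            d = np.minimum(np.mod(x - origin, L), np.mod(origin - x, L))
            expo = amp * (1 - d / (L / 2))
        c += weight * 2.0 ** expo
    if scenario.ter_trap:
        c = np.where(in_ter, c * 2.0 ** scenario.trap_peak_log2, c)
    c[deleted] = 0.0
    if np.ndim(positions) == 0:
        return float(c[0])
    return c


def simulate_coverage(scenario: ReplicationScenario, bin_size: int = 200) -> BinnedCoverage:
    """Draw per-bin negative-binomial counts around the expected gradient.

    Bin means are ``depth_per_bin * c(midpoint) / mean(c)`` (the partial
    last bin scaled by its width); the NB size parameter is the
    scenario's dispersion. Identical scenario and seed give identical
    output.
    """
    if scenario.depth_per_bin <= 0:
        raise ValueError("depth_per_bin must be positive")
    chrom = scenario.chrom
    template = bin_coverage(np.zeros(chrom.length), bin_size, chrom)
    c = expected_copy_number(scenario, template.midpoints)
    mean_c = c.mean()
    mu = scenario.depth_per_bin * c / mean_c
    mu = mu * template.widths / bin_size
    rng = np.random.default_rng(scenario.seed)
    r = scenario.dispersion
    p = r / (r + np.maximum(mu, 1e-12))
    counts = np.where(mu > 0, rng.negative_binomial(r, p), 0).astype(float)
    return replace(template, counts=counts)


@dataclass(frozen=True)
class ExpressionScenario:
    """Stranded per-gene expression with rRNA-dominated levels."""

    genes: tuple  # GeneRecord, ...
    base_level: float = 200.0
    rrna_ratio: float = 20.0  # expected rRNA level / mRNA level, > 1
    dispersion: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rrna_ratio <= 1:
            raise ValueError("rrna_ratio must exceed 1")

    def expected_level(self, gene: GeneRecord) -> float:
        if gene.gene_class == "rRNA":
            return self.base_level * self.rrna_ratio
        return self.base_level


def simulate_expression(scenario: ExpressionScenario) -> dict[str, float]:
    """Negative-binomial per-gene counts around class-dependent levels."""
    rng = np.random.default_rng(scenario.seed)
    out: dict[str, float] = {}
    r = scenario.dispersion
    for gene in scenario.genes:
        mu = scenario.expected_level(gene)
        if scenario.dispersion == np.inf:
            out[gene.gene_id] = float(mu)
        else:
            out[gene.gene_id] = float(rng.negative_binomial(r, r / (r + mu)))
    return out


# -- genome sequences with planted RLFS cassettes ---------------------------


def _rlfs_cassette(model: str, rng: np.random.Generator) -> str:
    """A cassette guaranteed to satisfy the given model's definition."""
    tract = "GGGG" if model == "m2" else "GGG"
    riz = tract + ("AT" + tract) * 4  # 5 tracts, 2-nt linkers, G-density > 0.5
    linker = "".join(rng.choice(list("ACT"), size=20))
    rez_len = 150
    n_g = int(round(0.45 * rez_len))
    rez = np.array(list("".join(rng.choice(list("ACT"), size=rez_len))))
    g_pos = rng.choice(rez_len, size=n_g, replace=False)
    rez[g_pos] = "G"
    return riz + linker + "".join(rez)


def synthesize_genome_with_rlfs(
    length: int,
    placements=(),
    gc: float = 0.25,
    seed: int = 0,
) -> tuple[str, list[dict]]:
    """i.i.d. background sequence with planted RIZ+linker+REZ cassettes.

    ``placements`` is a list of ``(position, model, strand)``; cassettes
    are written at the stated 1-based positions (reverse-complemented
    for '-'). Returns the sequence and a truth table of planted sites.
    Colliding placements raise.
    """
    rng = np.random.default_rng(seed)
    p_g = gc / 2
    p_a = (1 - gc) / 2
    seq = rng.choice(list("ACGT"), size=length, p=[p_a, p_g, p_g, p_a])
    truth: list[dict] = []
    occupied: list[tuple[int, int]] = []
    for pos, model, strand in placements:
        cassette = _rlfs_cassette(model, rng)
        if strand == "-":
            cassette = reverse_complement(cassette)
        start, end = pos, pos + len(cassette) - 1  # 1-based inclusive
        if end > length:
            raise ValueError(f"placement at {pos} runs past the sequence end")
        for s, e in occupied:
            if start <= e and s <= end:
                raise ValueError(f"placement at {pos} collides with ({s}, {e})")
        occupied.append((start, end))
        seq[start - 1:end] = list(cassette)
        truth.append({"start": start, "end": end, "model": model, "strand": strand})
    return "".join(seq), truth


# -- gene tables and named presets ------------------------------------------


def make_gene_table(
    chrom: ChromosomeMap = ECOLI_K12,
    n_mrna: int = 300,
    rrn_operons: dict | None = None,
    mrna_length: int = 1200,
    rrna_length: int = 5000,
    leading_bias: float = 0.7,
    seed: int = 0,
) -> tuple:
    """A toy gene table: evenly spaced mRNA genes plus rRNA operons.

    mRNA strands are drawn leading-strand biased with respect to
    replication from oriC (fraction ``leading_bias`` co-directional),
    mirroring the real genome's strand bias. rRNA operons default to the
    package's K-12 anchor positions and transcription directions.
    """
    rng = np.random.default_rng(seed)
    if rrn_operons is None:
        rrn_operons = RRN_OPERONS
    genes: list[GeneRecord] = []
    spacing = chrom.length // n_mrna
    for i in range(n_mrna):
        start = 1 + i * spacing
        end = min(start + mrna_length - 1, chrom.length)
        mid = (start + end) / 2
        d = (mid - chrom.oriC_position) % chrom.length
        fork_clockwise = d < chrom.length / 2
        leading_strand = "+" if fork_clockwise else "-"
        lagging_strand = "-" if fork_clockwise else "+"
        strand = leading_strand if rng.random() < leading_bias else lagging_strand
        genes.append(GeneRecord(f"g{i:04d}", start, end, strand, "mRNA",
                                essential=bool(rng.random() < 0.1)))
    for name, (pos, strand) in rrn_operons.items():
        genes.append(GeneRecord(name, pos, pos + rrna_length - 1, strand, "rRNA",
                                product="ribosomal RNA operon (16S-23S-5S)"))
    genes.sort(key=lambda g: g.start)
    return tuple(genes)


def apply_inversion_to_genes(genes, a: int, b: int) -> tuple:
    """Reflect genes whose midpoints lie in [a, b] and flip their strands."""
    out = []
    for g in genes:
        if a <= g.midpoint <= b:
            out.append(
                GeneRecord(g.gene_id, int(a + b - g.end), int(a + b - g.start),
                           "-" if g.strand == "+" else "+", g.gene_class,
                           essential=g.essential, product=g.product)
            )
        else:
            out.append(g)
    return tuple(sorted(out, key=lambda g: g.start))


# The suppressor inversion spans rrnD (3.42 Mb) to rrnE (4.2 Mb).
SUPPRESSOR_INVERSION = (3_420_000, 4_200_000)

# Wild-type amplitude from the closed form: with a single origin at oriC
# the fitted value at dif sits at fork-travel fraction ~0.993 of the
# maximum, so amplitude 1.32 log2 gives an ori:ter ratio of ~2.48.
_WT_AMPLITUDE = 1.32


def scenario_presets(chrom: ChromosomeMap = ECOLI_K12) -> dict[str, ReplicationScenario]:
    """Named scenarios mirroring the canonical cSDR strain classes.

    - ``wild-type-like``: single origin at oriC, steep symmetric
      gradient (ori:ter ~ 2.5), no trap.
    - ``csdr-parent-like``: weak multi-origin initiation dominated by
      the 4.5-Mb site, with a strong terminus fork-trap peak.
    - ``suppressor-like``: one dominant origin at 4,510,000 carrying
      the 3.42-4.2 Mb inversion.
    - ``stationary-like``: zero-amplitude (non-replicating) profile.
    """
    return {
        "wild-type-like": ReplicationScenario(
            chrom=chrom, origins=((chrom.oriC_position, 1.0),),
            amplitudes=(_WT_AMPLITUDE,), seed=101,
        ),
        "csdr-parent-like": ReplicationScenario(
            chrom=chrom,
            origins=((ORIK45_POSITION, 0.5), (531_400, 0.25), (2_988_600, 0.25)),
            amplitudes=(0.35, 0.2, 0.2),
            ter_trap=True, trap_peak_log2=0.7, seed=102,
        ),
        "suppressor-like": ReplicationScenario(
            chrom=chrom, origins=((ORIK45_POSITION, 1.0),), amplitudes=(1.2,),
            inversions=(SUPPRESSOR_INVERSION,), seed=103,
        ),
        "stationary-like": ReplicationScenario(
            chrom=chrom, origins=((chrom.oriC_position, 1.0),), amplitudes=(0.0,),
            seed=104,
        ),
    }


def expression_presets(chrom: ChromosomeMap = ECOLI_K12, seed: int = 0) -> dict[str, dict]:
    """Expression scenarios for collision scoring, per strain class.

    Each entry carries the gene table (inversion applied for the
    suppressor), the predominant origin to score against, and the
    :class:`ExpressionScenario`.
    """
    genes = make_gene_table(chrom, seed=seed)
    inv_genes = apply_inversion_to_genes(genes, *SUPPRESSOR_INVERSION)
    mk = lambda g, s: ExpressionScenario(genes=g, seed=s)
    return {
        "wild-type-like": {"genes": genes, "origin": chrom.oriC_position,
                           "expr": mk(genes, seed + 1)},
        "csdr-parent-like": {"genes": genes, "origin": ORIK45_POSITION,
                             "expr": mk(genes, seed + 2)},
        "suppressor-like": {"genes": inv_genes, "origin": ORIK45_POSITION,
                            "expr": mk(inv_genes, seed + 3)},
    }
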