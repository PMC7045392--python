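"""Readers and writers for the formats the pipeline touches.

Supported inputs: single-record FASTA genomes, per-base coverage as
bedGraph / BED4 / two-column TSV, and gene tables in PTT/RNT, BED6 or
GFF3 dialects. All readers convert to the package's internal 1-based
inclusive circular coordinates (bedGraph/BED are 0-based half-open).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO

from .genome import ChromosomeMap, GeneRecord

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_fasta",
    "read_coverage",
    "write_coverage",
    "read_gene_table",
    "read_expression_table",
    "load_genome_map",
    "write_genome_map",
]

_IUPAC = set("ACGTRYSWKMBDHVN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def read_fasta(path) -> tuple[str, str]:
    """Read a single-chromosome FASTA file.

    Returns ``(name, sequence)`` with the sequence upper-cased and RNA
    ``U`` mapped to ``T``. Multi-record files are rejected: the pipeline
    models exactly one circular chromosome.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise FormatError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise FormatError(f"{path}: multiple sequences; supply a single chromosome")
    rec = records[0]
    seq = str(rec.seq).upper().replace("U", "T")
    if len(seq) == 0:
        raise FormatError(f"{path}: empty sequence")
    bad = set(seq) - _IUPAC
    if bad:
        raise FormatError(f"{path}: illegal characters outside IUPAC codes: {sorted(bad)}")
    return rec.id, seq


def read_coverage(path, chrom: ChromosomeMap, wrap: bool = False) -> np.ndarray:
    """Read per-base depth into a length-L array (index 0 = position 1).

    Accepts bedGraph / BED4 (``chrom start end depth``, 0-based
    half-open) or two-column TSV (``position depth``, 1-based). Gaps are
    depth 0. Overlapping bedGraph intervals and negative depths are
    errors. Intervals running past the chromosome end are wrapped onto
    the start when ``wrap=True``, otherwise rejected.
    """
    depth = np.zeros(chrom.length, dtype=float)
    covered_any = False
    last_end = {}  # per-chrom running end for overlap detection
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) >= 4:
                name, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                if value < 0:
                    raise FormatError(f"{path}:{lineno}: negative depth {value}")
                if start < 0 or end <= start:
                    raise FormatError(f"{path}:{lineno}: bad interval {start}-{end}")
                if name in last_end and start < last_end[name]:
                    raise FormatError(f"{path}:{lineno}: overlapping bedGraph intervals")
                last_end[name] = end
                if end > chrom.length:
                    if not wrap:
                        raise FormatError(
                            f"{path}:{lineno}: interval end {end} beyond chromosome "
                            f"length {chrom.length} (pass wrap=True for circular wrap)"
                        )
                    depth[start:] += value
                    depth[: end - chrom.length] += value
                else:
                    depth[start:end] += value
                covered_any = True
            elif len(fields) == 2:
                pos, value = int(fields[0]), float(fields[1])
                if value < 0:
                    raise FormatError(f"{path}:{lineno}: negative depth {value}")
                if not 1 <= pos <= chrom.length:
                    raise FormatError(f"{path}:{lineno}: position {pos} outside chromosome")
                depth[pos - 1] = value
                covered_any = True
            else:
                raise FormatError(f"{path}:{lineno}: expected 2 or >=4 columns")
    if not covered_any:
        log.warning("%s: empty coverage file; returning all-zero depth", path)
    return depth


def write_coverage(path, depth: np.ndarray, chrom: ChromosomeMap) -> None:
    """Write per-base depth as bedGraph, run-length collapsing equal values."""
    with open(path, "w") as fh:
        i = 0
        n = len(depth)
        while i < n:
            j = i + 1
            while j < n and depth[j] == depth[i]:
                j += 1
            if depth[i] != 0:
                fh.write(f"{chrom.name}\t{i}\t{j}\t{depth[i]:g}\n")
            i = j


_PTT_LOC = re.compile(r"^(\d+)\.\.(\d+)$")


def _classify_product(product: str) -> str:
    text = product.lower()
    if "rrna" in text or "ribosomal rna" in text:
        return "rRNA"
    if "trna" in text or re.search(r"\btRNA\b", product):
        return "tRNA"
    return "other"


def read_gene_table(path, dialect: str | None = None) -> list[GeneRecord]:
    """Read a gene table in PTT/RNT, BED6 or GFF3 dialect.

    PTT rows (``location strand length PID gene synonym code COG
    product``) become mRNA records; RNT rows (same layout, structural
    RNAs) are classed rRNA/tRNA from the product text. The dialect is
    sniffed from the filename/content unless given explicitly.
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = {".ptt": "ptt", ".rnt": "rnt", ".bed": "bed", ".gff": "gff",
                   ".gff3": "gff"}.get(suffix, "ptt")
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if dialect in ("ptt", "rnt"):
                fields = line.split("\t")
                m = _PTT_LOC.match(fields[0].strip())
                if m is None:
                    # PTT files carry a 2-line header; skip non-location rows
                    if lineno <= 3 or fields[0].lower().startswith("location"):
                        continue
                    raise FormatError(f"{path}:{lineno}: unparseable location {fields[0]!r}")
                start, end = int(m.group(1)), int(m.group(2))
                strand = fields[1].strip() if len(fields) > 1 else ""
                if strand not in ("+", "-"):
                    raise FormatError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
                gene = fields[4].strip() if len(fields) > 4 else f"g{lineno}"
                product = fields[8].strip() if len(fields) > 8 else ""
                if dialect == "rnt":
                    gene_class = _classify_product(product)
                    if gene_class == "other":
                        gene_class = "rRNA" if "5s" in product.lower() else "other"
                else:
                    gene_class = "mRNA"
                genes.append(GeneRecord(gene, start, end, strand, gene_class, product=product))
            elif dialect == "bed":
                fields = line.split("\t")
                if len(fields) < 6:
                    raise FormatError(f"{path}:{lineno}: BED6 requires 6 columns")
                strand = fields[5]
                if strand not in ("+", "-"):
                    raise FormatError(
                        f"{path}:{lineno}: strand required for collision scoring (got {strand!r})"
                    )
                genes.append(
                    GeneRecord(fields[3], int(fields[1]) + 1, int(fields[2]), strand)
                )
            elif dialect == "gff":
                fields = line.split("\t")
                if len(fields) < 9:
                    raise FormatError(f"{path}:{lineno}: GFF3 requires 9 columns")
                strand = fields[6]
                if strand not in ("+", "-"):
                    raise FormatError(
                        f"{path}:{lineno}: strand required for collision scoring (got {strand!r})"
                    )
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                ftype = fields[2]
                gene_class = {"rRNA": "rRNA", "tRNA": "tRNA", "CDS": "mRNA", "gene": "mRNA"}.get(
                    ftype, "other"
                )
                genes.append(
                    GeneRecord(
                        attrs.get("ID", attrs.get("Name", f"g{lineno}")),
                        int(fields[3]),
                        int(fields[4]),
                        strand,
                        gene_class,
                    )
                )
            else:
                raise ValueError(f"unknown gene-table dialect {dialect!r}")
    return genes


def read_expression_table(path) -> dict[str, float]:
    """Read a two-column ``gene_id<TAB>coverage`` table."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("gene"):
                continue
            gene_id, value = line.split("\t")[:2]
            out[gene_id] = float(value)
    return out


def load_genome_map(path) -> ChromosomeMap:
    """Load a :class:`ChromosomeMap` from a YAML landmark file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return ChromosomeMap(
        name=cfg["name"],
        length=int(cfg["length"]),
        oriC_position=int(cfg["oriC_position"]),
        dif_position=int(cfg["dif_position"]),
        ter_region=tuple(int(v) for v in cfg["ter_region"]),
        circular=bool(cfg.get("circular", True)),
    )


def write_genome_map(path, chrom: ChromosomeMap) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "name": chrom.name,
                "length": chrom.length,
                "oriC_position": chrom.oriC_position,
                "dif_position": chrom.dif_position,
                "ter_region": list(chrom.ter_region),
                "circular": chrom.circular,
            },
            fh,
        )
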