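"""SNP-to-gene annotation via position and chromatin loops (MAGMA format).

Exonic and promoter SNPs are assigned directly to the genes whose exon or
promoter contains them. Remaining (intronic/intergenic) SNPs are assigned
through loops: if the SNP's bin overlaps a loop anchor whose partner anchor
overlaps a gene's promoter or any exon, the SNP is assigned to that gene. A
SNP may map to several genes; SNPs matching no rule are reported separately.
The result serializes to the MAGMA gene-annotation format: one line per gene,

    GENE_ID  chrom:start:stop  rsid rsid ...

with the gene location 1-based inclusive and genes sorted by (chrom, start).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .errors import FormatError, ParameterError
from .genome import (
    BinGrid,
    GeneModel,
    interval_0based_to_1based_inclusive,
    pos_1based_to_0based,
)
from .loops import Loop

import logging

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SnpRecord:
    rsid: str
    chrom: str
    pos: int  # 1-based

    def __post_init__(self):
        if self.pos < 1:
            raise ParameterError(f"{self.rsid}: 1-based position must be >= 1")


@dataclass(frozen=True)
class GeneAnnot:
    chrom: str
    start: int  # 1-based inclusive
    stop: int
    rsids: tuple[str, ...]


@dataclass
class SnpGeneAnnot:
    genes: dict[str, GeneAnnot] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict, compare=False)  # (gene, rsid) -> category
    unassigned: tuple[str, ...] = field(default=(), compare=False)

    def __eq__(self, other):
        return isinstance(other, SnpGeneAnnot) and self.genes == other.genes


def snps_from_table(table: pd.DataFrame) -> list[SnpRecord]:
    recs = [SnpRecord(str(r.rsid), str(r.chrom), int(r.pos)) for r in table.itertuples()]
    if len({r.rsid for r in recs}) != len(recs):
        raise ParameterError("duplicate rsids in SNP table")
    return recs


def _gene_trees(genes: list[GeneModel]):
    """Interval trees of (promoter union exons) per chromosome -> gene ids."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        ivs = [g.promoter] + list(g.exons)
        for a, b in ivs:
            if b > a:
                trees.setdefault(g.chrom, IntervalTree()).addi(max(0, a), b, g.gene_id)
    return trees


def assign_snps(
    snps: list[SnpRecord],
    genes: list[GeneModel],
    loops: list[Loop],
    grid: BinGrid,
) -> SnpGeneAnnot:
    """Assign SNPs to genes positionally, then by loop mediation.

    Direct rule: a SNP inside any exon or promoter of gene g is assigned to g
    (category 'exonic' or 'promoter'). Loop rule, applied only to SNPs with no
    direct assignment: the SNP's bin must overlap a loop anchor whose partner
    anchor overlaps g's promoter or an exon (category 'loop'). SNPs on
    chromosomes unknown to the grid are logged and skipped.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    prom_trees: dict[str, IntervalTree] = {}
    exon_trees: dict[str, IntervalTree] = {}
    for g in genes:
        a, b = g.promoter
        prom_trees.setdefault(g.chrom, IntervalTree()).addi(max(0, a), b, g.gene_id)
        for ea, eb in g.exons:
            exon_trees.setdefault(g.chrom, IntervalTree()).addi(ea, eb, g.gene_id)

    # loop anchors indexed by bin: bin -> set of partner bins
    partners: dict[tuple[str, int], set[int]] = {}
    for lp in loops:
        partners.setdefault((lp.chrom, lp.promoter_bin), set()).add(lp.target_bin)
        partners.setdefault((lp.chrom, lp.target_bin), set()).add(lp.promoter_bin)

    assigned: dict[str, set[str]] = {}
    provenance: dict = {}
    unassigned: list[str] = []
    for snp in snps:
        if snp.chrom not in grid.chrom_sizes:
            logger.warning("SNP %s on unknown chromosome %s: skipped", snp.rsid, snp.chrom)
            continue
        pos0 = pos_1based_to_0based(snp.pos)
        if pos0 >= grid.chrom_sizes[snp.chrom]:
            logger.warning("SNP %s beyond end of %s: skipped", snp.rsid, snp.chrom)
            continue
        hits: dict[str, str] = {}
        for iv in exon_trees.get(snp.chrom, IntervalTree()).at(pos0):
            hits[iv.data] = "exonic"
        for iv in prom_trees.get(snp.chrom, IntervalTree()).at(pos0):
            hits.setdefault(iv.data, "promoter")
        if not hits:
            b = grid.bin_index(snp.chrom, pos0)
            for pb in partners.get((snp.chrom, b), ()):
                s, e = grid.bin_interval(snp.chrom, pb)
                for tree in (prom_trees, exon_trees):
                    t = tree.get(snp.chrom)
                    if t is None:
                        continue
                    for iv in t.overlap(s, e):
                        hits.setdefault(iv.data, "loop")
        if not hits:
            unassigned.append(snp.rsid)
            continue
        for gid, cat in hits.items():
            assigned.setdefault(gid, set()).add(snp.rsid)
            provenance[(gid, snp.rsid)] = cat

    pos_of = {s.rsid: (s.chrom, s.pos) for s in snps}
    genes_out: dict[str, GeneAnnot] = {}
    for gid, rsids in assigned.items():
        g = gene_by_id[gid]
        span = g.span
        start, stop = interval_0based_to_1based_inclusive(max(0, span[0]), span[1])
        ordered = tuple(sorted(rsids, key=lambda r: (pos_of[r][1], r)))
        genes_out[gid] = GeneAnnot(g.chrom, start, stop, ordered)
    return SnpGeneAnnot(genes=genes_out, provenance=provenance, unassigned=tuple(unassigned))


def write_magma_annot(annot: SnpGeneAnnot, path) -> None:
    """Write MAGMA gene-annotation text; genes with no SNPs are omitted.

    Output is deterministic: genes sorted by (chrom, start, gene_id).
    """
    items = sorted(annot.genes.items(), key=lambda kv: (kv[1].chrom, kv[1].start, kv[0]))
    with open(path, "w") as fh:
        for gid, ga in items:
            if not ga.rsids:
                continue
            fh.write(f"{gid}\t{ga.chrom}:{ga.start}:{ga.stop}\t" + "\t".join(ga.rsids) + "\n")


def read_magma_annot(path) -> SnpGeneAnnot:
    genes: dict[str, GeneAnnot] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError("expected gene id and location", line=ln)
            gid, loc, rsids = parts[0], parts[1], tuple(parts[2:])
            if gid in genes:
                raise FormatError(f"duplicate gene id {gid!r}", line=ln)
            loc_parts = loc.split(":")
            if len(loc_parts) != 3:
                raise FormatError(f"malformed location {loc!r}", line=ln)
            chrom = loc_parts[0]
            try:
                start, stop = int(loc_parts[1]), int(loc_parts[2])
            except ValueError as exc:
                raise FormatError(f"malformed location {loc!r}", line=ln) from exc
            if start < 1 or stop < start:
                raise FormatError(f"invalid location bounds {loc!r}", line=ln)
            genes[gid] = GeneAnnot(chrom, start, stop, rsids)
    return SnpGeneAnnot(genes=genes)
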