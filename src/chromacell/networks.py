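"""Peak-to-gene networks, enhancer-count/expression summaries, enrichment.

Peaks are linked to genes either directly (peak overlaps the gene's promoter)
or through a significant loop (peak overlaps one anchor, gene promoter
overlaps the partner anchor). Enhancer counting and the enhancer-count vs
expression summary treat a peak as an enhancer only when it overlaps no
promoter, so promoter-proximal peaks are never double-counted. Gene-set module
enrichment uses Fisher's exact test on the 2x2 overlap table with BH
correction across modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import ParameterError
from .genome import BinGrid, GeneModel
from .loops import Loop

ENHANCER_COUNT_CAP = 10


@dataclass(frozen=True)
class PeakGeneLink:
    peak_id: str
    gene_id: str
    cell_type: str
    evidence: str                 # 'promoter-overlap' | 'loop'
    loop_id: str | None = None


def _promoter_trees(genes: list[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        a, b = g.promoter
        if b > a:
            trees.setdefault(g.chrom, IntervalTree()).addi(a, b, g.gene_id)
    return trees


def link_peaks_to_genes(
    peaks,
    loops: list[Loop],
    genes: list[GeneModel],
    grid: BinGrid,
    cell_type: str = "",
) -> list[PeakGeneLink]:
    """Link peaks to genes by promoter overlap or loop mediation.

    ``peaks`` are (chrom, start, end, name) tuples; ``loops`` should already
    be the significant set. A peak may link to many genes and vice versa;
    links are deduplicated per (peak, gene, evidence) and sorted.
    """
    prom_trees = _promoter_trees(genes)

    # anchor trees: anchor bin interval -> (partner bin, loop index)
    anchor_trees: dict[str, IntervalTree] = {}
    for k, lp in enumerate(loops):
        for a_bin, partner in ((lp.promoter_bin, lp.target_bin), (lp.target_bin, lp.promoter_bin)):
            s, e = grid.bin_interval(lp.chrom, a_bin)
            anchor_trees.setdefault(lp.chrom, IntervalTree()).addi(s, e, (partner, k))

    links: set[PeakGeneLink] = set()
    for chrom, s, e, name in peaks:
        tree = prom_trees.get(chrom)
        if tree is not None:
            for iv in tree.overlap(s, e):
                links.add(PeakGeneLink(name, iv.data, cell_type, "promoter-overlap"))
        atree = anchor_trees.get(chrom)
        if atree is None or tree is None:
            continue
        for iv in atree.overlap(s, e):
            partner_bin, loop_idx = iv.data
            ps, pe = grid.bin_interval(chrom, partner_bin)
            for piv in tree.overlap(ps, pe):
                links.add(
                    PeakGeneLink(name, piv.data, cell_type, "loop", loop_id=f"loop{loop_idx + 1}")
                )
    return sorted(links, key=lambda l: (l.peak_id, l.gene_id, l.evidence, l.loop_id or ""))


def enhancer_counts(
    links: list[PeakGeneLink], peaks, genes: list[GeneModel]
) -> dict[str, int]:
    """Distinct linked enhancer peaks per gene (all genes present, zeros kept).

    A peak counts as an enhancer when it overlaps no promoter; each distinct
    enhancer peak id counts once per gene regardless of how many loops carry it.
    """
    prom_trees = _promoter_trees(genes)
    enhancer_ids = set()
    for chrom, s, e, name in peaks:
        tree = prom_trees.get(chrom)
        if tree is None or not tree.overlap(s, e):
            enhancer_ids.add(name)
    per_gene: dict[str, set] = {g.gene_id: set() for g in genes}
    for l in links:
        if l.peak_id in enhancer_ids and l.gene_id in per_gene:
            per_gene[l.gene_id].add(l.peak_id)
    return {g: len(s) for g, s in per_gene.items()}


def enhancer_count_vs_expression(
    links: list[PeakGeneLink],
    expression: pd.Series,
    peaks,
    genes: list[GeneModel],
) -> pd.DataFrame:
    """Mean expression by number of linked enhancers (0..9, pooled '10+').

    ``expression`` maps gene_id to an expression value and must cover every
    linked gene.
    """
    counts = enhancer_counts(links, peaks, genes)
    missing = [g for g in counts if g not in expression.index]
    if missing:
        raise ParameterError(f"expression missing for {len(missing)} genes (e.g. {missing[0]})")
    groups: dict[str, list[float]] = {}
    for gene_id, k in counts.items():
        label = str(k) if k < ENHANCER_COUNT_CAP else f"{ENHANCER_COUNT_CAP}+"
        groups.setdefault(label, []).append(float(expression[gene_id]))
    order = [str(i) for i in range(ENHANCER_COUNT_CAP)] + [f"{ENHANCER_COUNT_CAP}+"]
    rows = [
        {"enhancers": lab, "n_genes": len(groups[lab]), "mean_expression": float(np.mean(groups[lab]))}
        for lab in order
        if lab in groups
    ]
    return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    module_id: str
    table: tuple[int, int, int, int]   # (overlap, query-only, module-only, neither)
    odds_ratio: float
    p: float
    q: float


def gene_set_enrichment(
    query,
    modules: dict[str, set],
    universe,
    alternative: str = "two-sided",
) -> list[EnrichmentResult]:
    """Fisher's exact test of a query gene set against named modules.

    The 2x2 table per module is (overlap, query-only, module-only, neither)
    over the universe; the odds ratio is (a*d)/(b*c) with a 0.5 continuity
    correction applied to every cell when any cell is zero. BH correction is
    applied across modules.
    """
    universe = set(universe)
    if not universe:
        raise ParameterError("empty universe")
    query = set(query) & universe
    if set(query) - universe:
        raise ParameterError("query genes outside the universe")
    results = []
    pvals = []
    for module_id in sorted(modules):
        mod = set(modules[module_id]) & universe
        a = len(query & mod)
        b = len(query - mod)
        c = len(mod - query)
        d = len(universe) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        results.append(EnrichmentResult(module_id, (a, b, c, d), float(orr), float(p), np.nan))
        pvals.append(p)
    if pvals:
        qvals = stats.false_discovery_control(pvals, method="bh")
        for r, q in zip(results, qvals):
            r.q = float(q)
    return results
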