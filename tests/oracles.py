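"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (double/triple loops, exhaustive
enumeration) and shares no code with the package internals.
"""

from math import comb


def intervals_overlap(a_start, a_end, b_start, b_end):
    return a_start < b_end and b_start < a_end


def brute_force_links(peaks, loops, genes, grid):
    """All (peak, gene, evidence) triples by exhaustive pairwise overlap."""
    out = set()
    for chrom, ps, pe, name in peaks:
        for g in genes:
            if g.chrom != chrom:
                continue
            pa, pb = g.promoter
            if intervals_overlap(ps, pe, pa, pb):
                out.add((name, g.gene_id, "promoter-overlap"))
        for lp in loops:
            if lp.chrom != chrom:
                continue
            for a_bin, partner in (
                (lp.promoter_bin, lp.target_bin),
                (lp.target_bin, lp.promoter_bin),
            ):
                s, e = grid.bin_interval(chrom, a_bin)
                if not intervals_overlap(ps, pe, s, e):
                    continue
                s2, e2 = grid.bin_interval(chrom, partner)
                for g in genes:
                    if g.chrom != chrom:
                        continue
                    pa, pb = g.promoter
                    if intervals_overlap(s2, e2, pa, pb):
                        out.add((name, g.gene_id, "loop"))
    return out


def brute_force_snp_assignment(snps, genes, loops, grid):
    """gene_id -> set of rsids, by the direct-then-loop rules, naively."""
    out = {}
    for snp in snps:
        pos0 = snp.pos - 1
        if snp.chrom not in grid.chrom_sizes or pos0 >= grid.chrom_sizes[snp.chrom]:
            continue
        direct = set()
        for g in genes:
            if g.chrom != snp.chrom:
                continue
            pa, pb = g.promoter
            hit = pa <= pos0 < pb or any(a <= pos0 < b for a, b in g.exons)
            if hit:
                direct.add(g.gene_id)
        hits = set(direct)
        if not direct:
            b = pos0 // grid.resolution
            for lp in loops:
                if lp.chrom != snp.chrom:
                    continue
                for a_bin, partner in (
                    (lp.promoter_bin, lp.target_bin),
                    (lp.target_bin, lp.promoter_bin),
                ):
                    if a_bin != b:
                        continue
                    s, e = grid.bin_interval(snp.chrom, partner)
                    for g in genes:
                        if g.chrom != snp.chrom:
                            continue
                        pa, pb = g.promoter
                        if intervals_overlap(s, e, pa, pb) or any(
                            intervals_overlap(s, e, ea, eb) for ea, eb in g.exons
                        ):
                            hits.add(g.gene_id)
        for gid in hits:
            out.setdefault(gid, set()).add(snp.rsid)
    return out


def fisher_two_sided_exhaustive(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with the same margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(1.0, total)
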