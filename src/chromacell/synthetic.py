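"""Synthetic Hi-C datasets with planted ground truth.

The generator emulates the statistical structure that the analysis stages
assume, at bin resolution and with known ("planted") answers:

* power-law distance decay with Poisson (optionally negative-binomial) counts;
* a two-compartment checkerboard modulating contacts between same-sign bins;
* TAD blocks whose within-domain contacts are uniformly boosted;
* local-interaction-hotspot (FIRE) bins whose cis contacts are boosted;
* promoter-anchored loops as boosted single bin pairs;
* cell-type-specific peaks at planted enhancer bins, and gene expression whose
  mean increases with the number of planted enhancers per gene, saturating at 10;
* SNPs stratified into exonic / promoter / intronic / intergenic placements with
  recorded true target genes.

The expected count for a bin pair (i, j), i != j, is

    E[c_ij] = L * |i-j|**(-alpha)
              * (1 + beta * s_i * s_j)
              * tad_boost ** [i, j in the same planted domain]
              * fire_boost ** [i or j is a planted FIRE bin]
              * loop_boost ** [(i, j) is a planted loop]
              * b_i * b_j

where s is the planted compartment sign and b an optional per-bin coverage
bias (lognormal; off by default). The diagonal is excluded everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .contacts import ContactMatrix
from .errors import ParameterError
from .genome import BinGrid, BinTrack, GeneModel

CELL_TYPES = ("neuron", "glia")
EXPRESSION_SATURATION = 10  # enhancer count beyond which mean expression is flat


@dataclass(frozen=True)
class GeneratorParams:
    """Dials of the synthetic contact model (see module docstring)."""

    L: float = 300.0            # mean count at offset 1 bin
    alpha: float = 1.0          # distance-decay exponent
    beta: float = 0.4           # compartment checkerboard amplitude
    tad_boost: float = 2.0      # within-domain contact multiplier
    fire_boost: float = 1.4    # contact multiplier for planted hotspot bins
    loop_boost: float = 3.0     # multiplier for planted loop pixels
    bias_sd: float = 0.0        # lognormal sigma of per-bin coverage bias
    dispersion: float | None = None  # NB size parameter; None = Poisson
    # pixel-level rate variability: each pair's rate is E[c_ij] times a
    # mean-one Weibull multiplier with this shape (None = no mixing). This is
    # the distributional form the loop caller's background model assumes for
    # interaction frequencies at fixed distance.
    pixel_weibull_shape: float | None = None
    mu0: float = 5.0            # baseline expression mean
    gamma: float = 2.0          # expression increment per linked enhancer
    expr_noise_sd: float = 1.0

    def __post_init__(self):
        if self.alpha <= 0 or self.L <= 0:
            raise ParameterError("decay parameters L and alpha must be positive")
        for name in ("tad_boost", "fire_boost", "loop_boost"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if not 0 <= self.beta < 1:
            raise ParameterError("beta must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Planted structure, per cell type and chromosome, on one grid."""

    grid: BinGrid
    cell_types: tuple[str, ...]
    params: GeneratorParams
    compartment_sign: dict = field(default_factory=dict)  # ct -> chrom -> ±1 array
    tad_domains: dict = field(default_factory=dict)       # ct -> chrom -> [(s, e)], half-open bins
    fire_bins: dict = field(default_factory=dict)         # ct -> chrom -> sorted bin list
    loops: dict = field(default_factory=dict)             # ct -> chrom -> [(promoter_bin, target_bin)]
    enhancer_bins: dict = field(default_factory=dict)     # ct -> chrom -> sorted bin list
    bias: dict = field(default_factory=dict)              # chrom -> per-bin bias array
    snp_truth: dict = field(default_factory=dict)         # rsid -> {category, genes per ct}

    def tad_boundaries(self, cell_type: str, chrom: str) -> list[int]:
        """Interior boundaries: bin indices where one planted domain ends and the next starts."""
        doms = self.tad_domains.get(cell_type, {}).get(chrom, [])
        return [e for (s, e) in doms[:-1]]

    def to_json(self) -> str:
        def conv(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))

        payload = {
            "resolution": self.grid.resolution,
            "chrom_sizes": dict(self.grid.chrom_sizes),
            "cell_types": list(self.cell_types),
            "params": asdict(self.params),
            "compartment_sign": self.compartment_sign,
            "tad_domains": self.tad_domains,
            "fire_bins": self.fire_bins,
            "loops": self.loops,
            "enhancer_bins": self.enhancer_bins,
            "snp_truth": self.snp_truth,
        }
        return json.dumps(payload, default=conv, sort_keys=True)


def generate_genome(
    n_chrom: int,
    chrom_length: int,
    resolution: int,
    n_genes: int,
    seed: int,
) -> tuple[BinGrid, list[GeneModel]]:
    """Generate a bin grid and a deterministic random gene complement.

    Genes are laid out roughly evenly along each chromosome with random jitter,
    so consecutive TSSs stay well separated; strand is random; each gene has
    2-6 exons extending downstream of the TSS.
    """
    if n_chrom < 1 or n_genes < 1:
        raise ParameterError("need at least one chromosome and one gene")
    if chrom_length < 100 * resolution:
        raise ParameterError(
            f"chrom_length {chrom_length} must be >= 100 * resolution ({100 * resolution})"
        )
    rng = np.random.default_rng(seed)
    chroms = {f"chr{i + 1}": chrom_length for i in range(n_chrom)}
    grid = BinGrid(chroms, resolution)

    genes: list[GeneModel] = []
    per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0) for i in range(n_chrom)]
    gid = 0
    margin = 25_000
    for ci, chrom in enumerate(chroms):
        k = per_chrom[ci]
        if k == 0:
            continue
        usable = chrom_length - 2 * margin
        spacing = usable / k
        jitter = spacing / 5.0
        for slot in range(k):
            tss = int(margin + (slot + 0.5) * spacing + rng.uniform(-jitter, jitter))
            strand = "+" if rng.random() < 0.5 else "-"
            max_span = int(min(0.7 * spacing, 15_000))
            n_ex = int(rng.integers(2, 7))
            exons = []
            cursor = 0
            for _ in range(n_ex):
                elen = int(rng.integers(100, 400))
                if cursor + elen > max_span:
                    break
                exons.append((cursor, cursor + elen))
                cursor += elen + int(rng.integers(300, 2000))
            if not exons:
                exons = [(0, 200)]
            if strand == "+":
                abs_exons = [(tss + a, tss + b) for a, b in exons]
            else:
                abs_exons = [(tss - b, tss - a) for a, b in exons]
            abs_exons = [
                (max(0, a), min(chrom_length, b)) for a, b in abs_exons if a < chrom_length and b > 0
            ]
            gid += 1
            genes.append(GeneModel(f"GENE{gid:05d}", chrom, strand, tss, tuple(abs_exons)))
    tss_seen = {(g.chrom, g.tss) for g in genes}
    assert len(tss_seen) == len(genes), "TSS collision in genome generation"
    return grid, genes


def plant_truth(
    grid: BinGrid,
    genes: list[GeneModel] | None = None,
    cell_types: tuple[str, ...] = CELL_TYPES,
    params: GeneratorParams = GeneratorParams(),
    seed: int = 0,
    *,
    compartment_block_bins: tuple[int, int] = (10, 30),
    compartment_switch_frac: float = 0.1,
    n_tads: int | None = None,
    tad_len_bins: tuple[int, int] = (8, 20),
    n_fires_specific: int = 20,
    n_fires_common: int = 10,
    frac_looped_promoters: float = 0.6,
    loop_dist_range: tuple[int, int] = (30_000, 200_000),
    max_loops_per_promoter: int = 3,
) -> SyntheticTruth:
    """Plant compartments, TADs, FIRE bins, loops and enhancers on a grid.

    Loops and enhancers require gene models (promoter bins anchor the loops);
    without genes those fields stay empty. Compartment signs of the first cell
    type define the "reference" pattern; other cell types flip a fraction of
    blocks (the planted switch regions). TAD domains are shared across cell
    types; FIRE bins comprise per-cell-type specific sets plus a common set.
    """
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(grid=grid, cell_types=tuple(cell_types), params=params)
    for ct in cell_types:
        truth.compartment_sign[ct] = {}
        truth.tad_domains[ct] = {}
        truth.fire_bins[ct] = {}
        truth.loops[ct] = {}
        truth.enhancer_bins[ct] = {}

    res = grid.resolution
    d_lo = max(1, -(-loop_dist_range[0] // res))
    d_hi = max(d_lo, loop_dist_range[1] // res)

    for chrom in grid.chroms:
        n = grid.n_bins(chrom)

        # compartments: alternating-sign blocks; other cell types flip some blocks
        edges = [0]
        while edges[-1] < n:
            edges.append(edges[-1] + int(rng.integers(*compartment_block_bins)))
        edges[-1] = n
        base = np.empty(n, dtype=int)
        sign = 1
        blocks = []
        for a, b in zip(edges[:-1], edges[1:]):
            base[a:b] = sign
            blocks.append((a, b))
            sign = -sign
        truth.compartment_sign[cell_types[0]][chrom] = base
        for ct in cell_types[1:]:
            s = base.copy()
            for a, b in blocks:
                if rng.random() < compartment_switch_frac:
                    s[a:b] = -s[a:b]
            truth.compartment_sign[ct][chrom] = s

        # TADs: contiguous domains tiling the chromosome, shared across cell types
        if n_tads is not None:
            cuts = np.linspace(0, n, n_tads + 1)
            cuts[1:-1] += rng.uniform(-0.15, 0.15, n_tads - 1) * (n / n_tads)
            cuts = np.unique(np.round(cuts).astype(int))
            cuts[0], cuts[-1] = 0, n
        else:
            cuts = [0]
            while cuts[-1] < n:
                cuts.append(cuts[-1] + int(rng.integers(*tad_len_bins)))
            cuts[-1] = n
            cuts = np.unique(cuts)
        domains = [(int(a), int(b)) for a, b in zip(cuts[:-1], cuts[1:]) if b > a]
        for ct in cell_types:
            truth.tad_domains[ct][chrom] = list(domains)

        # FIRE bins: disjoint specific sets per cell type plus a common set;
        # the outermost bins are avoided (the 200-kb local window of the FIRE
        # score is truncated there and those bins are masked by the caller)
        margin = min(-(-200_000 // res), max(0, n // 2 - 1))
        eligible = np.arange(margin, n - margin)
        need = n_fires_specific * len(cell_types) + n_fires_common
        pool = rng.choice(eligible, size=min(need, len(eligible)), replace=False)
        idx = 0
        specific = {}
        for ct in cell_types:
            specific[ct] = sorted(int(b) for b in pool[idx : idx + n_fires_specific])
            idx += n_fires_specific
        common = sorted(int(b) for b in pool[idx : idx + n_fires_common])
        for ct in cell_types:
            truth.fire_bins[ct][chrom] = sorted(specific[ct] + common)

        # per-bin coverage bias (shared across cell types)
        if params.bias_sd > 0:
            truth.bias[chrom] = rng.lognormal(mean=0.0, sigma=params.bias_sd, size=n)
        else:
            truth.bias[chrom] = np.ones(n)

        # loops: planted promoter-bin -> distal-bin pairs, per cell type
        if genes is not None:
            chrom_genes = [g for g in genes if g.chrom == chrom]
            prom_bins = sorted({grid.bin_index(chrom, g.tss) for g in chrom_genes})
            prom_set = set(prom_bins)
            for ct in cell_types:
                loops = []
                enh = set()
                chosen = [
                    b for b in prom_bins if rng.random() < frac_looped_promoters
                ]
                for p in chosen:
                    k = int(rng.integers(1, max_loops_per_promoter + 1))
                    tried = set()
                    for _ in range(k):
                        for _attempt in range(20):
                            d = int(rng.integers(d_lo, d_hi + 1))
                            t = p + d if rng.random() < 0.5 else p - d
                            if 0 <= t < n and t not in prom_set and t not in tried:
                                tried.add(t)
                                loops.append((p, t))
                                enh.add(t)
                                break
                truth.loops[ct][chrom] = sorted(loops)
                truth.enhancer_bins[ct][chrom] = sorted(enh)
        else:
            for ct in cell_types:
                truth.loops[ct][chrom] = []
                truth.enhancer_bins[ct][chrom] = []
    return truth


def expected_matrix(truth: SyntheticTruth, cell_type: str, chrom: str) -> np.ndarray:
    """Noise-free expected contact matrix for one cell type and chromosome."""
    p = truth.params
    n = truth.grid.n_bins(chrom)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    with np.errstate(divide="ignore"):
        E = p.L * d ** (-p.alpha)
    np.fill_diagonal(E, 0.0)

    s = truth.compartment_sign.get(cell_type, {}).get(chrom)
    if s is not None and p.beta > 0:
        E *= 1.0 + p.beta * np.outer(s, s)

    doms = truth.tad_domains.get(cell_type, {}).get(chrom, [])
    if doms and p.tad_boost > 1:
        dom_id = np.full(n, -1)
        for k, (a, b) in enumerate(doms):
            dom_id[a:b] = k
        same = (dom_id[:, None] == dom_id[None, :]) & (dom_id[:, None] >= 0)
        E[same] *= p.tad_boost

    fire = truth.fire_bins.get(cell_type, {}).get(chrom, [])
    if fire and p.fire_boost > 1:
        f = np.zeros(n, dtype=bool)
        f[list(fire)] = True
        E[f[:, None] | f[None, :]] *= p.fire_boost

    for (a, b) in truth.loops.get(cell_type, {}).get(chrom, []):
        E[a, b] *= p.loop_boost
        E[b, a] *= p.loop_boost

    bias = truth.bias.get(chrom)
    if bias is not None and not np.all(bias == 1.0):
        E *= np.outer(bias, bias)
    np.fill_diagonal(E, 0.0)
    return E


def simulate_contact_map(
    grid: BinGrid,
    truth: SyntheticTruth,
    cell_type: str,
    seed: int,
    chrom: str | None = None,
) -> ContactMatrix:
    """Sample a symmetric integer contact matrix from the planted model."""
    if truth.grid.resolution != grid.resolution or dict(truth.grid.chrom_sizes) != dict(
        grid.chrom_sizes
    ):
        raise ParameterError("truth was planted on a different grid")
    if chrom is None:
        if len(grid.chroms) != 1:
            raise ParameterError("multi-chromosome grid: pass chrom=")
        chrom = grid.chroms[0]
    rng = np.random.default_rng(seed)
    E = expected_matrix(truth, cell_type, chrom)
    n = E.shape[0]
    iu = np.triu_indices(n, k=1)
    mu = E[iu]
    k0 = truth.params.pixel_weibull_shape
    if k0 is not None:
        from scipy.special import gamma as _gamma

        w = rng.weibull(k0, size=mu.shape) / _gamma(1 + 1 / k0)
        # planted loop pixels keep their exact boosted rate: the loop boost is
        # defined relative to the distance expectation, not to pixel noise
        loop_pairs = truth.loops.get(cell_type, {}).get(chrom, [])
        if loop_pairs:
            keep = np.zeros((n, n), dtype=bool)
            for a, b in loop_pairs:
                keep[a, b] = keep[b, a] = True
            w = np.where(keep[iu], 1.0, w)
        mu = mu * w
    disp = truth.params.dispersion
    if disp is None:
        vals = rng.poisson(mu)
    else:
        # negative binomial with mean mu and size (dispersion) r: var = mu + mu^2 / r
        r = float(disp)
        vals = rng.negative_binomial(r, r / (r + mu))
    counts = np.zeros((n, n))
    counts[iu] = vals
    counts += counts.T
    return ContactMatrix(chrom, grid, counts)


def simulate_bin_tracks(
    truth: SyntheticTruth, chrom: str, seed: int
) -> tuple[BinTrack, BinTrack]:
    """Per-bin gene-density and GC tracks.

    Gene density is Poisson with a rate that rises with the fraction of cell
    types whose planted compartment is A (+1) in the bin — gene-dense regions
    sit in the active compartment of most cell types; GC is an independent
    clipped Gaussian around 0.45.
    """
    rng = np.random.default_rng(seed)
    signs = [np.asarray(truth.compartment_sign[ct][chrom]) for ct in truth.cell_types]
    frac_a = np.mean([s > 0 for s in signs], axis=0)
    n = len(signs[0])
    density = rng.poisson(1.0 + 3.0 * frac_a, size=n).astype(float)
    gc = np.clip(rng.normal(0.45, 0.05, size=n), 0.30, 0.60)
    return (
        BinTrack(chrom, truth.grid, density),
        BinTrack(chrom, truth.grid, gc),
    )


PEAK_WIDTH = 600


def planted_enhancer_counts(
    truth: SyntheticTruth, genes: list[GeneModel], cell_type: str
) -> dict[str, int]:
    """Number of distinct planted enhancer bins looped to each gene's promoter bin."""
    counts: dict[str, int] = {}
    for g in genes:
        pb = truth.grid.bin_index(g.chrom, g.tss)
        loops = truth.loops.get(cell_type, {}).get(g.chrom, [])
        counts[g.gene_id] = len({t for (p, t) in loops if p == pb})
    return counts


def simulate_peaks_expression(
    truth: SyntheticTruth,
    genes: list[GeneModel],
    seed: int,
) -> tuple[dict[str, list[tuple[str, int, int, str]]], pd.DataFrame]:
    """Peaks at planted enhancer bins and expression rising with enhancer count.

    Each planted enhancer bin yields one peak of width 600 bp centered in the
    bin, labeled with its cell type. Expression of a gene with k planted
    enhancers is Gaussian with mean ``mu0 + gamma * min(k, 10)``.
    """
    rng = np.random.default_rng(seed)
    p = truth.params
    res = truth.grid.resolution
    width = min(PEAK_WIDTH, res)
    peaks: dict[str, list[tuple[str, int, int, str]]] = {}
    for ct in truth.cell_types:
        rows = []
        k = 0
        for chrom in truth.grid.chroms:
            for b in truth.enhancer_bins.get(ct, {}).get(chrom, []):
                start, end = truth.grid.bin_interval(chrom, b)
                mid = (start + end) // 2
                k += 1
                rows.append((chrom, mid - width // 2, mid + width // 2, f"{ct}_peak{k}"))
        peaks[ct] = rows

    expr = {}
    for ct in truth.cell_types:
        counts = planted_enhancer_counts(truth, genes, ct)
        mean = np.array(
            [p.mu0 + p.gamma * min(counts[g.gene_id], EXPRESSION_SATURATION) for g in genes]
        )
        expr[ct] = mean + rng.normal(0.0, p.expr_noise_sd, size=len(genes))
    table = pd.DataFrame(expr, index=[g.gene_id for g in genes])
    table.index.name = "gene_id"
    return peaks, table


def _positional_genes(genes: list[GeneModel], chrom: str, pos0: int) -> list[str]:
    out = []
    for g in genes:
        if g.chrom != chrom:
            continue
        a, b = g.promoter
        if a <= pos0 < b or any(ea <= pos0 < eb for ea, eb in g.exons):
            out.append(g.gene_id)
    return out


def _loop_genes(
    truth: SyntheticTruth, genes: list[GeneModel], cell_type: str, chrom: str, pos0: int
) -> list[str]:
    grid = truth.grid
    b = grid.bin_index(chrom, pos0)
    partners = set()
    for (p, t) in truth.loops.get(cell_type, {}).get(chrom, []):
        if t == b:
            partners.add(p)
        elif p == b:
            partners.add(t)
    out = set()
    for pb in partners:
        s, e = grid.bin_interval(chrom, pb)
        for g in genes:
            if g.chrom != chrom:
                continue
            pa, pe = g.promoter
            if pa < e and s < pe:
                out.add(g.gene_id)
            elif any(ea < e and s < eb for ea, eb in g.exons):
                out.add(g.gene_id)
    return sorted(out)


def simulate_snps(
    truth: SyntheticTruth,
    genes: list[GeneModel],
    n_snps: int,
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Place SNPs in exonic/promoter/intronic/intergenic strata with known targets.

    Returns a SNP table (rsid, chrom, 1-based pos) and per-SNP truth: the
    placement category and, per cell type, the true target gene set (positional
    for exonic/promoter SNPs; planted-loop-derived for the distal strata).
    """
    if n_snps < 1:
        raise ParameterError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    grid = truth.grid
    rows = []
    snp_truth: dict[str, dict] = {}
    categories = ["exonic", "promoter", "intronic", "intergenic"]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    for i in range(n_snps):
        cat = categories[i % 4]
        chrom = grid.chroms[int(rng.integers(len(grid.chroms)))]
        cg = by_chrom.get(chrom, [])
        pos0 = None
        for _attempt in range(200):
            if cat == "exonic" and cg:
                g = cg[int(rng.integers(len(cg)))]
                ea, eb = g.exons[int(rng.integers(len(g.exons)))]
                cand = int(rng.integers(ea, eb))
            elif cat == "promoter" and cg:
                g = cg[int(rng.integers(len(cg)))]
                pa, pb = g.promoter
                cand = int(rng.integers(max(0, pa), min(pb, grid.chrom_sizes[chrom])))
                # promoter placement must not also hit an exon of another stratum
            elif cat == "intronic" and cg:
                g = cg[int(rng.integers(len(cg)))]
                s, e = g.span
                cand = int(rng.integers(s, e))
                if _positional_genes(genes, chrom, cand):
                    continue
            else:
                cand = int(rng.integers(0, grid.chrom_sizes[chrom]))
                if cat == "intergenic":
                    inside = any(
                        gg.span[0] <= cand < gg.span[1] for gg in cg
                    ) or bool(_positional_genes(genes, chrom, cand))
                    if inside:
                        continue
            pos0 = cand
            break
        if pos0 is None:
            continue
        rsid = f"rs{i + 1}"
        rows.append((rsid, chrom, pos0 + 1))
        positional = _positional_genes(genes, chrom, pos0)
        entry = {"category": cat, "genes": {}}
        for ct in truth.cell_types:
            if positional:
                entry["genes"][ct] = sorted(positional)
            else:
                entry["genes"][ct] = _loop_genes(truth, genes, ct, chrom, pos0)
        snp_truth[rsid] = entry
    table = pd.DataFrame(rows, columns=["rsid", "chrom", "pos"])
    truth.snp_truth.update(snp_truth)
    return table, snp_truth


def write_peaks_bed(peaks: list[tuple[str, int, int, str]], path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        for chrom, s, e, name in peaks:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def read_peaks_bed(path) -> list[tuple[str, int, int, str]]:
    from .errors import FormatError

    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError("expected at least 3 BED fields", line=ln)
            name = parts[3] if len(parts) > 3 else f"peak{ln}"
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out


def write_snp_table(table: pd.DataFrame, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_snp_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
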