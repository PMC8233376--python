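"""End-to-end orchestration: simulate -> balance -> compartments -> TADs ->
FIREs -> loops -> networks -> snp2gene, with a machine-readable report.

A single master seed deterministically derives per-stage seeds (hash of the
stage name), so any stage can be rerun in isolation and a rerun with the same
config reproduces every output byte for byte. Each output file starts with a
header comment carrying the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as _stats

from . import compartments as comp_mod
from . import fires as fire_mod
from . import loops as loop_mod
from . import networks as net_mod
from . import snp2gene as s2g_mod
from . import synthetic as syn
from . import tads as tad_mod
from .contacts import ice_normalize, write_bias, write_contacts
from .errors import ParameterError
from .genome import BinGrid, write_bedgraph, write_gene_table
from .synthetic import GeneratorParams

logger = logging.getLogger(__name__)

RESOLUTIONS = {"compartments": 100_000, "tads": 40_000, "loops": 10_000}


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    chrom_length: int = 20_000_000
    n_genes: int = 300
    n_snps: int = 200
    cell_types: tuple[str, ...] = syn.CELL_TYPES
    resolutions: dict = field(default_factory=lambda: dict(RESOLUTIONS))
    # per-analysis depth (mean count at offset 1); deeper near the diagonal at
    # coarser bins, as in real libraries
    depth: dict = field(default_factory=lambda: {"compartments": 1000.0, "tads": 300.0, "loops": 1000.0})
    alpha: float = 1.0
    beta: float = 0.4
    tad_boost: float = 2.0
    fire_boost: float = 1.4
    loop_boost: float = 3.0
    # pixel-level rate variability at loop resolution: the Weibull form the
    # loop caller's background model assumes; None elsewhere
    pixel_weibull_shape_loops: float | None = 3.5
    n_tads: int | None = None
    n_fires_specific: int = 20
    n_fires_common: int = 10
    di_window: int = 2_000_000
    loop_min_dist: int = 20_000
    loop_max_dist: int = 2_000_000
    loop_fdr: float = 0.01

    def params_for(self, analysis: str) -> GeneratorParams:
        """Generator parameters per analysis resolution.

        Each resolution carries the structure its stage analyzes (the three
        matrices are simulated from independent planted truths): the
        checkerboard at 100 kb, TAD blocks and FIRE bins at 40 kb, loops at
        10 kb.
        """
        return GeneratorParams(
            L=self.depth[analysis],
            alpha=self.alpha,
            beta=self.beta if analysis == "compartments" else 0.0,
            tad_boost=self.tad_boost if analysis == "tads" else 1.0,
            fire_boost=self.fire_boost if analysis == "tads" else 1.0,
            loop_boost=self.loop_boost if analysis == "loops" else 1.0,
            pixel_weibull_shape=(
                self.pixel_weibull_shape_loops if analysis == "loops" else None
            ),
        )

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # where results land does not change what they are
        payload["cell_types"] = list(payload["cell_types"])
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def derive_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).hexdigest()
    return int(h[:8], 16) % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on synthetic data; returns (and writes) the report."""
    os.makedirs(config.out_dir, exist_ok=True)
    chash = config.config_hash()
    header = f"config_hash={chash} seed={config.seed}"
    out = lambda name: os.path.join(config.out_dir, name)
    report: dict = {"config_hash": chash, "seed": config.seed, "stages": {}}
    cts = tuple(config.cell_types)
    if len(cts) < 2:
        raise ParameterError("pipeline needs at least two cell types")
    ct_a, ct_b = cts[0], cts[1]

    # ---- simulate --------------------------------------------------------
    grid10, genes = syn.generate_genome(
        1, config.chrom_length, config.resolutions["loops"], config.n_genes,
        derive_seed(config.seed, "genome"),
    )
    chrom = grid10.chroms[0]
    write_gene_table(genes, out("genes.tsv"), header=header)
    grids = {k: BinGrid(dict(grid10.chrom_sizes), r) for k, r in config.resolutions.items()}
    truths, matrices = {}, {}
    for analysis in ("compartments", "tads", "loops"):
        truths[analysis] = syn.plant_truth(
            grids[analysis],
            genes=genes if analysis == "loops" else None,
            cell_types=cts,
            params=config.params_for(analysis),
            seed=derive_seed(config.seed, f"truth:{analysis}"),
            n_tads=config.n_tads,
            n_fires_specific=config.n_fires_specific,
            n_fires_common=config.n_fires_common,
        )
        for ct in cts:
            cm = syn.simulate_contact_map(
                grids[analysis], truths[analysis], ct,
                derive_seed(config.seed, f"map:{analysis}:{ct}"), chrom=chrom,
            )
            matrices[(analysis, ct)] = cm
            write_contacts(cm, out(f"contacts_{analysis}_{ct}.txt"), header=header)
    with open(out("truth.json"), "w") as fh:
        fh.write(truths["loops"].to_json())
        fh.write("\n")
    peaks, expression = syn.simulate_peaks_expression(
        truths["loops"], genes, derive_seed(config.seed, "peaks")
    )
    for ct in cts:
        syn.write_peaks_bed(peaks[ct], out(f"peaks_{ct}.bed"), header=header)
    expression.to_csv(out("expression.tsv"), sep="\t")
    snp_table, snp_truth = syn.simulate_snps(
        truths["loops"], genes, config.n_snps, derive_seed(config.seed, "snps")
    )
    syn.write_snp_table(snp_table, out("snps.tsv"), header=header)
    report["stages"]["simulate"] = {
        "n_genes": len(genes),
        "n_snps": int(len(snp_table)),
        "chrom_length": config.chrom_length,
    }

    # ---- balance ---------------------------------------------------------
    balanced = {}
    for key, cm in matrices.items():
        bal = ice_normalize(cm)
        balanced[key] = bal
        write_bias(bal, out(f"bias_{key[0]}_{key[1]}.txt"))
    report["stages"]["balance"] = {
        f"{a}_{ct}": {"converged": bool(balanced[(a, ct)].converged),
                      "n_masked": int((~balanced[(a, ct)].mask).sum())}
        for (a, ct) in balanced
    }

    # ---- compartments ----------------------------------------------------
    comp_tracks = {}
    comp_metrics = {}
    t100 = truths["compartments"]
    gd, _gc100 = syn.simulate_bin_tracks(t100, chrom, derive_seed(config.seed, "tracks100"))
    for ct in cts:
        track = comp_mod.compartment_track(balanced[("compartments", ct)], gd)
        comp_tracks[ct] = track
        write_bedgraph(track.pc, out(f"compartment_pc_{ct}.bedgraph"), header=header)
        truth_sign = np.asarray(t100.compartment_sign[ct][chrom])
        called = track.sign()
        m = track.pc.mask
        agree = float((called[m] == truth_sign[m]).mean())
        comp_metrics[ct] = {
            "label_agreement_with_truth": agree,
            "chosen_pc_index": track.chosen_pc_index,
            "gene_density_corr": track.gene_density_corr,
        }
    switches = comp_mod.call_switches(comp_tracks[ct_a], comp_tracks[ct_b])
    with open(out("compartment_switches.bed"), "w") as fh:
        fh.write(f"# {header}\n")
        for sw in switches:
            s, e = sw.interval(grids["compartments"], chrom)
            fh.write(f"{chrom}\t{s}\t{e}\t{sw.direction}\n")
    comp_metrics["n_switch_regions"] = len(switches)
    report["stages"]["compartments"] = comp_metrics

    # ---- TADs ------------------------------------------------------------
    tad_metrics = {}
    tad_calls = {}
    t40 = truths["tads"]
    for ct in cts:
        di = tad_mod.directionality_index(balanced[("tads", ct)], window=config.di_window)
        write_bedgraph(di, out(f"di_{ct}.bedgraph"), header=header)
        call = tad_mod.segment_tads(di, seed=derive_seed(config.seed, f"hmm:{ct}"))
        tad_calls[ct] = call
        with open(out(f"tads_{ct}.bed"), "w") as fh:
            fh.write(f"# {header}\n")
            for s, e in call.domains:
                gs, _ = grids["tads"].bin_interval(chrom, s)
                _, ge = grids["tads"].bin_interval(chrom, e - 1)
                fh.write(f"{chrom}\t{gs}\t{ge}\n")
        recall = tad_mod.boundary_recall(t40.tad_boundaries(ct, chrom), call.boundaries)
        tad_metrics[ct] = {"n_domains": len(call.domains), "boundary_recall": recall}
    report["stages"]["tads"] = tad_metrics

    # ---- FIREs -----------------------------------------------------------
    fire_tracks = {}
    for ct in cts:
        ft = fire_mod.fire_scores(matrices[("tads", ct)])
        fire_tracks[ct] = ft
        write_bedgraph(ft.z, out(f"fire_z_{ct}.bedgraph"), header=header)
    calls = fire_mod.classify_fires(fire_tracks[ct_a], fire_tracks[ct_b])
    with open(out("fire_calls.tsv"), "w") as fh:
        fh.write(f"# {header}\nbin\tz_{ct_a}\tz_{ct_b}\tcategory\n")
        for c in calls:
            fh.write(f"{c.bin}\t{c.z_a:.4f}\t{c.z_b:.4f}\t{c.category}\n")
    common40 = set(t40.fire_bins[ct_a][chrom]) & set(t40.fire_bins[ct_b][chrom])
    truth_spec = {
        "A-specific": set(t40.fire_bins[ct_a][chrom]) - common40,
        "B-specific": set(t40.fire_bins[ct_b][chrom]) - common40,
    }
    fire_metrics = {}
    for cat, truth_bins in truth_spec.items():
        called_bins = {c.bin for c in calls if c.category == cat}
        tp = len(called_bins & truth_bins)
        fire_metrics[cat] = {
            "precision": tp / len(called_bins) if called_bins else float("nan"),
            "recall": tp / len(truth_bins) if truth_bins else float("nan"),
        }
    sfs = fire_mod.super_fires(fire_tracks[ct_a])
    with open(out(f"super_fires_{ct_a}.bed"), "w") as fh:
        fh.write(f"# {header}\n")
        for sf in sfs:
            gs, _ = grids["tads"].bin_interval(chrom, sf.start_bin)
            _, ge = grids["tads"].bin_interval(chrom, sf.end_bin - 1)
            fh.write(f"{chrom}\t{gs}\t{ge}\tSF{sf.rank}\t{sf.cumulative_score:.3f}\n")
    fire_metrics["n_super_fires_A"] = len(sfs)
    report["stages"]["fires"] = fire_metrics

    # ---- loops -----------------------------------------------------------
    t10 = truths["loops"]
    _gd10, gc10 = syn.simulate_bin_tracks(t10, chrom, derive_seed(config.seed, "tracks10"))
    prom_bins = sorted({grid10.bin_index(chrom, g.tss) for g in genes})
    loop_metrics = {}
    called_loops = {}
    for ct in cts:
        bg = loop_mod.sample_background_anchors(
            prom_bins, grid10, gc10, seed=derive_seed(config.seed, f"bg:{ct}")
        )
        loops = loop_mod.call_promoter_loops(
            matrices[("loops", ct)], prom_bins, bg,
            min_dist=config.loop_min_dist, max_dist=config.loop_max_dist,
            fdr=config.loop_fdr,
        )
        called_loops[ct] = loops
        loop_mod.write_bedpe(loops, grid10, out(f"loops_{ct}.bedpe"), header=header)
        truth_pairs = {
            frozenset(pair) for pair in t10.loops[ct][chrom]
        }
        called_pairs = {frozenset((l.promoter_bin, l.target_bin)) for l in loops}
        tp = len(called_pairs & truth_pairs)
        loop_metrics[ct] = {
            "n_called": len(loops),
            "sensitivity": tp / len(truth_pairs) if truth_pairs else float("nan"),
            "empirical_fdr": 1 - tp / len(called_pairs) if called_pairs else 0.0,
        }
        # TAD domains were called on the 40-kb grid; rescale to 10-kb bin units
        ratio = config.resolutions["tads"] // config.resolutions["loops"]
        tads10 = tad_mod.TadCall(
            chrom, [(s * ratio, e * ratio) for s, e in tad_calls[ct].domains]
        )
        summary = loop_mod.classify_interactions(loops, peaks[ct], genes, tads10, grid10)
        loop_metrics[ct]["frac_within_tad"] = summary["frac_within_tad"]
        loop_metrics[ct]["frac_EP"] = summary["frac_EP"]
        loop_metrics[ct]["frac_PP"] = summary["frac_PP"]
    report["stages"]["loops"] = loop_metrics

    # ---- networks --------------------------------------------------------
    links = net_mod.link_peaks_to_genes(peaks[ct_a], called_loops[ct_a], genes, grid10, cell_type=ct_a)
    with open(out(f"links_{ct_a}.tsv"), "w") as fh:
        fh.write(f"# {header}\npeak_id\tgene_id\tcell_type\tevidence\tloop_id\n")
        for l in links:
            fh.write(f"{l.peak_id}\t{l.gene_id}\t{l.cell_type}\t{l.evidence}\t{l.loop_id or '.'}\n")
    enh_table = net_mod.enhancer_count_vs_expression(
        links, expression[ct_a], peaks[ct_a], genes
    )
    enh_table.to_csv(out(f"expression_by_enhancers_{ct_a}.tsv"), sep="\t", index=False)
    if len(enh_table) >= 3:
        rho = float(_stats.spearmanr(np.arange(len(enh_table)), enh_table["mean_expression"]).statistic)
    else:
        rho = float("nan")
    report["stages"]["networks"] = {
        "n_links": len(links),
        "expression_spearman_over_enhancer_groups": rho,
    }

    # ---- snp2gene --------------------------------------------------------
    snps = s2g_mod.snps_from_table(snp_table)
    annot = s2g_mod.assign_snps(snps, genes, called_loops[ct_a], grid10)
    s2g_mod.write_magma_annot(annot, out(f"snp2gene_{ct_a}.genes.annot"))
    truth_map = {
        rsid: set(entry["genes"][ct_a]) for rsid, entry in snp_truth.items()
    }
    called_map: dict[str, set] = {rsid: set() for rsid in truth_map}
    for gid, ga in annot.genes.items():
        for rsid in ga.rsids:
            called_map.setdefault(rsid, set()).add(gid)
    jac = []
    exact = 0
    for rsid, tset in truth_map.items():
        cset = called_map.get(rsid, set())
        if not tset and not cset:
            jac.append(1.0)
            exact += 1
            continue
        jac.append(len(tset & cset) / len(tset | cset))
        exact += tset == cset
    report["stages"]["snp2gene"] = {
        "n_assigned_genes": len(annot.genes),
        "n_unassigned_snps": len(annot.unassigned),
        "truth_mean_jaccard": float(np.mean(jac)) if jac else float("nan"),
        "truth_exact_fraction": exact / len(truth_map) if truth_map else float("nan"),
    }

    with open(out("report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
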