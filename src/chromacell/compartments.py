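"""A/B compartment calling at 100 kb and compartment-switch detection.

The compartment signal is taken from the eigenvectors of the Pearson
correlation matrix of the observed/expected contact map. Among the first four
eigenvectors, the one most correlated (in absolute value) with a per-bin
gene-density track is selected per chromosome, and its sign is oriented so the
correlation with gene density is non-negative; bins with positive values are
labeled A, negative B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import ContactMatrix, expected_by_distance
from .errors import DegenerateInputError, ParameterError
from .genome import BinTrack

N_EIGENVECTORS = 4


@dataclass
class CompartmentTrack:
    chrom: str
    pc: BinTrack                 # oriented eigenvector values; masked where no call
    labels: np.ndarray           # 'A', 'B', or '.' for masked
    chosen_pc_index: int         # 1-based rank of the selected eigenvector
    gene_density_corr: float     # Pearson r after orientation (>= 0)

    def sign(self) -> np.ndarray:
        """+1 for A, -1 for B, 0 for masked."""
        out = np.zeros(len(self.labels), dtype=int)
        out[self.labels == "A"] = 1
        out[self.labels == "B"] = -1
        return out


@dataclass
class SwitchRegion:
    chrom: str
    start_bin: int
    end_bin: int                 # half-open
    direction: str               # "A->B" or "B->A", cellA relative to cellB

    def interval(self, grid, chrom):
        s, _ = grid.bin_interval(chrom, self.start_bin)
        _, e = grid.bin_interval(chrom, self.end_bin - 1)
        return s, e


def observed_over_expected(cm: ContactMatrix) -> np.ndarray:
    """O/E matrix: each off-diagonal divided by the mean at its offset."""
    profile = expected_by_distance(cm)
    n = cm.n_bins
    oe = np.zeros((n, n))
    for d in range(1, n):
        e = profile.e_d[d - 1]
        if not np.isfinite(e) or e <= 0:
            continue
        idx = np.arange(n - d)
        oe[idx, idx + d] = cm.counts[idx, idx + d] / e
        oe[idx + d, idx] = oe[idx, idx + d]
    return oe


def compartment_track(cm100: ContactMatrix, gene_density: BinTrack) -> CompartmentTrack:
    """Call A/B compartments on a balanced 100-kb matrix.

    Uses the first four eigenvectors of the O/E correlation matrix; selects the
    one with the largest |Pearson r| against gene density and orients it so
    that r >= 0.
    """
    if gene_density.values.shape[0] != cm100.n_bins:
        raise ParameterError("gene-density track does not match matrix bins")
    mask = cm100.mask & gene_density.mask
    if mask.sum() < N_EIGENVECTORS + 1:
        raise DegenerateInputError("too few unmasked bins for compartment analysis")
    oe = observed_over_expected(cm100)
    np.fill_diagonal(oe, 1.0)  # neutral self-pair; O/E fluctuates around 1
    oe = oe[np.ix_(mask, mask)]
    sd = oe.std(axis=0)
    if np.count_nonzero(sd > 0) < 2:
        raise DegenerateInputError("observed/expected matrix is constant")
    keep = sd > 0
    if keep.sum() < mask.sum():
        # bins with constant O/E carry no correlation signal; mask them too
        mi = np.flatnonzero(mask)
        mask = mask.copy()
        mask[mi[~keep]] = False
        oe = oe[np.ix_(keep, keep)]
    corr = np.corrcoef(oe)
    corr = np.nan_to_num(corr, nan=0.0)
    if np.linalg.matrix_rank(corr) < 2:
        raise DegenerateInputError("correlation matrix has rank < 2")
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    top = evecs[:, order[:N_EIGENVECTORS]]

    gd = gene_density.values[mask]
    best_r, best_k = 0.0, 0
    for k in range(top.shape[1]):
        v = top[:, k]
        if v.std() == 0 or gd.std() == 0:
            continue
        r = float(np.corrcoef(v, gd)[0, 1])
        if abs(r) > abs(best_r):
            best_r, best_k = r, k
    vec = top[:, best_k]
    if best_r < 0:
        vec = -vec
        best_r = -best_r

    n = cm100.n_bins
    values = np.zeros(n)
    values[mask] = vec
    labels = np.full(n, ".", dtype="<U1")
    labels[mask & (values > 0)] = "A"
    labels[mask & (values <= 0)] = "B"
    pc = BinTrack(cm100.chrom, cm100.grid, values, mask=mask)
    return CompartmentTrack(cm100.chrom, pc, labels, best_k + 1, best_r)


def call_switches(trackA: CompartmentTrack, trackB: CompartmentTrack) -> list[SwitchRegion]:
    """Maximal runs of bins whose A/B label differs between two cell types."""
    if trackA.chrom != trackB.chrom or len(trackA.labels) != len(trackB.labels):
        raise ParameterError("compartment tracks are on different grids")
    sa, sb = trackA.sign(), trackB.sign()
    out: list[SwitchRegion] = []
    cur_dir, cur_start = None, None
    for i in range(len(sa) + 1):
        if i < len(sa) and sa[i] != 0 and sb[i] != 0 and sa[i] != sb[i]:
            direction = "A->B" if sa[i] > 0 else "B->A"
        else:
            direction = None
        if direction != cur_dir:
            if cur_dir is not None:
                out.append(SwitchRegion(trackA.chrom, cur_start, i, cur_dir))
            cur_dir, cur_start = direction, i
    return out
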