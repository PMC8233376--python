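"""Binned cis contact matrices: I/O, ICE balancing, distance decay, and SCC.

All matrices are per-chromosome and symmetric; trans contacts are outside the
scope of this package. Raw matrices hold non-negative integer counts; balancing
divides entry ``(i, j)`` by ``bias_i * bias_j`` so that unmasked row sums are
equal (iterative correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, FormatError, InsufficientDataError, ParameterError
from .genome import BinGrid

LOW_COVERAGE_QUANTILE = 0.02  # nonzero bins in the lowest 2% of coverage are masked


@dataclass
class ContactMatrix:
    """Symmetric binned contact matrix for one chromosome."""

    chrom: str
    grid: BinGrid
    counts: np.ndarray
    balanced: bool = False
    bias: np.ndarray | None = None
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    converged: bool = True

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.grid.n_bins(self.chrom)
        if self.counts.shape != (n, n):
            raise ParameterError(f"counts shape {self.counts.shape} != ({n}, {n})")
        if not np.allclose(self.counts, self.counts.T):
            raise ParameterError("contact matrix must be symmetric")
        if (self.counts < 0).any():
            raise ParameterError("contact counts must be non-negative")
        if self.mask is None:
            self.mask = self.counts.sum(axis=0) > 0
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def same_grid(self, other: "ContactMatrix") -> bool:
        return (
            self.chrom == other.chrom
            and self.grid.resolution == other.grid.resolution
            and self.counts.shape == other.counts.shape
        )


@dataclass
class DecayProfile:
    """Mean contact per distance offset ``d`` (in bins), d = 1..n_bins-1."""

    e_d: np.ndarray

    def __post_init__(self):
        self.e_d = np.asarray(self.e_d, dtype=float)

    def __getitem__(self, d: int) -> float:
        return float(self.e_d[d - 1])


def read_contacts(path, grid: BinGrid, chrom: str | None = None) -> ContactMatrix:
    """Read a sparse triplet file (chrom, bin1_start, bin2_start, count).

    Duplicate and mirrored entries are summed into both triangles. Coordinates
    must be multiples of the grid resolution and inside the chromosome.
    """
    res = grid.resolution
    mats: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"expected 4 fields, got {len(parts)}", line=ln)
            c, s1, s2, cnt = parts
            try:
                s1, s2, cnt = int(s1), int(s2), float(cnt)
            except ValueError as exc:
                raise FormatError(str(exc), line=ln) from exc
            if c not in grid.chrom_sizes:
                raise FormatError(f"unknown chromosome {c!r}", line=ln)
            if s1 % res or s2 % res:
                raise FormatError(f"coordinate not a multiple of resolution {res}", line=ln)
            n = grid.n_bins(c)
            i, j = s1 // res, s2 // res
            if i >= n or j >= n or s1 < 0 or s2 < 0:
                raise FormatError(f"bin start outside chromosome {c}", line=ln)
            if cnt < 0:
                raise FormatError("negative count", line=ln)
            if c not in mats:
                mats[c] = np.zeros((n, n))
            mats[c][i, j] += cnt
            if i != j:
                mats[c][j, i] += cnt
    if chrom is None:
        if len(mats) > 1:
            raise ParameterError(f"file contains {len(mats)} chromosomes; pass chrom=")
        chrom = next(iter(mats)) if mats else next(iter(grid.chrom_sizes))
    n = grid.n_bins(chrom)
    counts = mats.get(chrom, np.zeros((n, n)))
    return ContactMatrix(chrom, grid, counts)


def write_contacts(cm: ContactMatrix, path, header: str | None = None) -> None:
    """Write the upper triangle (including diagonal) as triplets."""
    res = cm.grid.resolution
    iu, ju = np.nonzero(np.triu(cm.counts))
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        for i, j in zip(iu, ju):
            v = cm.counts[i, j]
            v_s = f"{v:.6g}" if cm.balanced else str(int(round(v)))
            fh.write(f"{cm.chrom}\t{i * res}\t{j * res}\t{v_s}\n")


def write_bias(cm: ContactMatrix, path) -> None:
    if cm.bias is None:
        raise ParameterError("matrix carries no bias vector")
    res = cm.grid.resolution
    with open(path, "w") as fh:
        for i, (b, ok) in enumerate(zip(cm.bias, cm.mask)):
            fh.write(f"{cm.chrom}\t{i * res}\t{b:.8g}\t{int(ok)}\n")


def ice_normalize(cm: ContactMatrix, tol: float = 1e-6, max_iter: int = 200) -> ContactMatrix:
    """Iteratively correct a raw matrix so unmasked row sums are equal.

    Bins with zero marginal, or with coverage below the lowest 2% of covered
    bins (capped at half the median marginal, so already-even matrices lose
    nothing), are masked and excluded. The bias update is
    ``b_i <- b_i * (rowsum_i / mean rowsum)``; iteration stops when the
    coefficient of variation of unmasked row sums falls below ``tol``.
    """
    if cm.balanced:
        raise ParameterError("matrix already balanced")
    counts = cm.counts
    marg = counts.sum(axis=0)
    if marg.sum() == 0:
        raise DegenerateInputError("all-zero contact matrix")
    mask = marg > 0
    nz = marg[mask]
    if mask.sum() >= 2 and LOW_COVERAGE_QUANTILE > 0:
        # low-coverage cut: lowest 2% of covered bins, but never above half the
        # median marginal — keeps the mask stable when marginals are already
        # (near-)equal, so balancing is idempotent
        cut = min(np.quantile(nz, LOW_COVERAGE_QUANTILE), 0.5 * np.median(nz))
        mask &= marg >= cut
    if mask.sum() < 2:
        raise DegenerateInputError("fewer than 2 bins with usable coverage")

    w = counts.copy()
    w[~mask, :] = 0.0
    w[:, ~mask] = 0.0
    bias = np.ones(cm.n_bins)
    converged = False
    for _ in range(max_iter):
        s = w.sum(axis=0)
        sm = s[mask]
        mean = sm.mean()
        cv = sm.std() / mean if mean > 0 else np.inf
        if cv < tol:
            converged = True
            break
        upd = np.ones_like(bias)
        upd[mask] = sm / mean
        bias *= upd
        w = counts / np.outer(bias, bias)
        w[~mask, :] = 0.0
        w[:, ~mask] = 0.0
    bias[~mask] = np.nan
    return ContactMatrix(
        cm.chrom, cm.grid, w, balanced=True, bias=bias, mask=mask, converged=converged
    )


def expected_by_distance(cm: ContactMatrix) -> DecayProfile:
    """Mean contact over unmasked bin pairs at each offset d >= 1."""
    n = cm.n_bins
    mask = cm.mask.astype(float)
    e = np.empty(n - 1)
    for d in range(1, n):
        vals = np.diagonal(cm.counts, offset=d)
        w = mask[:-d] * mask[d:]
        tot = w.sum()
        e[d - 1] = (vals * w).sum() / tot if tot > 0 else np.nan
    return DecayProfile(e)


def fit_decay_exponent(profile: DecayProfile, d_min: int = 1, d_max: int | None = None) -> tuple[float, float]:
    """Log-log least-squares fit of e_d = L * d**(-alpha); returns (L, alpha)."""
    e = profile.e_d
    d = np.arange(1, len(e) + 1)
    if d_max is None:
        d_max = len(e)
    sel = (d >= d_min) & (d <= d_max) & np.isfinite(e) & (e > 0)
    if sel.sum() < 3:
        raise InsufficientDataError("fewer than 3 usable offsets for decay fit")
    slope, intercept = np.polyfit(np.log(d[sel]), np.log(e[sel]), 1)
    return float(np.exp(intercept)), float(-slope)


def scc(
    cmA: ContactMatrix,
    cmB: ContactMatrix,
    h: int = 1,
    max_dist: int = 5_000_000,
) -> float:
    """Stratum-adjusted correlation coefficient between two contact maps.

    Both matrices are smoothed with a (2h+1)^2 mean filter; bin pairs are
    stratified by distance offset up to ``max_dist``; per-stratum Pearson
    correlations are combined with weights proportional to stratum size times
    the geometric mean of the two stratum standard deviations.
    """
    if not cmA.same_grid(cmB):
        raise ParameterError("matrices must share a grid")
    if h < 0:
        raise ParameterError("smoothing half-width must be >= 0")
    res = cmA.grid.resolution
    n = cmA.n_bins
    d_max = min(n - 1, max_dist // res)

    def smooth(m):
        return ndimage.uniform_filter(np.asarray(m, dtype=float), size=2 * h + 1, mode="constant")

    a = smooth(cmA.counts)
    b = smooth(cmB.counts)
    mask = cmA.mask & cmB.mask

    num = den = 0.0
    n_strata = 0
    for d in range(1, d_max + 1):
        ok = mask[:-d] & mask[d:]
        if ok.sum() < 3:
            continue
        x = np.diagonal(a, offset=d)[ok]
        y = np.diagonal(b, offset=d)[ok]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        w = len(x) * sx * sy
        num += w * r
        den += w
        n_strata += 1
    if n_strata < 2:
        raise InsufficientDataError("fewer than 2 distance strata with >= 3 pairs")
    return float(np.clip(num / den, -1.0, 1.0))
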