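"""FIRE calling: local cis-interaction hotspots, differential and super-FIREs.

A bin's local cis count C is the sum of its raw contacts to bins 15-200 kb
away (offsets 1..5 at 40 kb). Scores are z-standardized log counts,
``z = (log(C + 1) - mean) / sd`` over unmasked bins, so a one-sided normal
p-value applies directly and the quantile thresholds of the differential
rules are on the standard normal scale. Differential classification between
two cell types follows quantile rules (A-specific: z_A > qnorm(0.975) and
z_B < qnorm(0.9)); common FIREs are significant in both cell types with
|z_A - z_B| < 0.5. Super-FIREs are clusters of adjacent FIRE bins ranked by
cumulative score, cut at the point where the slope of the scaled
rank/cumulative-score curve equals 1 (the hockey-stick rule used for
super-enhancers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .contacts import ContactMatrix
from .errors import InsufficientDataError, ParameterError
from .genome import BinTrack

FIRE_P_THRESHOLD = 0.05
Q_HIGH = stats.norm.ppf(0.975)
Q_LOW = stats.norm.ppf(0.9)
Q_HIGH_LITERAL = stats.norm.ppf(0.95)
COMMON_MAX_DELTA = 0.5


@dataclass
class FireTrack:
    chrom: str
    local_counts: np.ndarray
    z: BinTrack
    p: np.ndarray
    is_fire: np.ndarray

    @property
    def mask(self) -> np.ndarray:
        return self.z.mask


def fire_scores(
    cm40_raw: ContactMatrix,
    min_dist: int = 15_000,
    max_dist: int = 200_000,
) -> FireTrack:
    """Score local cis interaction frequency per bin on a raw matrix.

    C_i sums contacts of bin i to bins whose center distance lies within
    [min_dist, max_dist]; offsets run from ceil(min_dist/res) to
    floor(max_dist/res). Bins with zero marginal are masked.
    """
    if cm40_raw.balanced:
        raise ParameterError("FIRE scores are computed on raw matrices")
    res = cm40_raw.grid.resolution
    if not (max_dist > min_dist > 0):
        raise ParameterError("need max_dist > min_dist > 0")
    d_lo = max(1, -(-min_dist // res))
    d_hi = max_dist // res
    if d_hi < d_lo:
        raise ParameterError("distance window contains no bin offsets")
    n = cm40_raw.n_bins
    counts = cm40_raw.counts
    C = np.zeros(n)
    for d in range(d_lo, d_hi + 1):
        diag = np.diagonal(counts, offset=d)
        C[:-d] += diag
        C[d:] += diag
    mask = cm40_raw.counts.sum(axis=0) > 0
    # bins whose local window is truncated by a chromosome end are not
    # comparable to interior bins and are masked
    mask[:d_hi] = False
    mask[n - d_hi:] = False
    if mask.sum() < 2:
        raise InsufficientDataError("all bins masked")
    logc = np.log(C + 1.0)
    mu, sd = logc[mask].mean(), logc[mask].std()
    if sd <= 1e-12 * max(1.0, abs(mu)):  # constant local counts
        z = np.zeros(n)
    else:
        z = (logc - mu) / sd
    z[~mask] = 0.0
    p = stats.norm.sf(z)
    is_fire = mask & (p < FIRE_P_THRESHOLD)
    return FireTrack(
        cm40_raw.chrom,
        C,
        BinTrack(cm40_raw.chrom, cm40_raw.grid, z, mask=mask),
        p,
        is_fire,
    )


@dataclass
class FireCall:
    bin: int
    z_a: float
    z_b: float
    category: str  # 'A-specific' | 'B-specific' | 'common' | 'none'


def classify_fires(
    trackA: FireTrack, trackB: FireTrack, mode: str = "mirrored"
) -> list[FireCall]:
    """Classify bins as A-specific, B-specific, common, or none.

    ``mirrored`` (default) applies the A-specific quantile rule symmetrically
    to both cell types; ``literal`` keeps the original asymmetric variant of
    the rule (B-specific uses qnorm(0.95) on z_A). Bins matching a
    differential rule are excluded from the common set.
    """
    if mode not in ("mirrored", "literal"):
        raise ParameterError(f"unknown mode {mode!r}")
    if trackA.z.values.shape != trackB.z.values.shape or trackA.chrom != trackB.chrom:
        raise ParameterError("FIRE tracks are on different grids")
    out: list[FireCall] = []
    mask = trackA.mask & trackB.mask
    for i in np.flatnonzero(mask):
        za, zb = float(trackA.z.values[i]), float(trackB.z.values[i])
        a_specific = za > Q_HIGH and zb < Q_LOW
        if mode == "mirrored":
            b_specific = zb > Q_HIGH and za < Q_LOW
        else:
            b_specific = zb < Q_LOW and za > Q_HIGH_LITERAL
        if a_specific:
            cat = "A-specific"
        elif b_specific:
            cat = "B-specific"
        elif trackA.is_fire[i] and trackB.is_fire[i] and abs(za - zb) < COMMON_MAX_DELTA:
            cat = "common"
        else:
            cat = "none"
        if cat != "none":
            out.append(FireCall(int(i), za, zb, cat))
    return out


@dataclass
class SuperFire:
    start_bin: int
    end_bin: int           # half-open
    cumulative_score: float
    rank: int              # 1 = highest cumulative score
    low_confidence: bool = False


def _clusters(track: FireTrack) -> list[tuple[int, int, float]]:
    bins = np.flatnonzero(track.is_fire)
    clusters = []
    if bins.size == 0:
        return clusters
    start = prev = bins[0]
    for b in bins[1:]:
        if b == prev + 1:
            prev = b
            continue
        clusters.append((int(start), int(prev) + 1))
        start = prev = b
    clusters.append((int(start), int(prev) + 1))
    return [
        (s, e, float(track.z.values[s:e].sum())) for (s, e) in clusters
    ]


def super_fires(track: FireTrack) -> list[SuperFire]:
    """Top-ranked clusters of adjacent FIRE bins by cumulative score.

    Clusters are sorted by cumulative z; rank and score are both scaled to
    [0, 1] and the cutoff placed where the tangent slope of the scaled curve
    equals 1 (the point of the ascending curve furthest below the diagonal).
    With fewer than 3 clusters all are returned flagged low-confidence; with
    all scores tied there is no elbow and the list is empty.
    """
    clusters = _clusters(track)
    if not clusters:
        return []
    clusters.sort(key=lambda c: c[2])
    scores = np.array([c[2] for c in clusters])
    m = len(clusters)
    if m < 3:
        return [
            SuperFire(s, e, sc, rank=r + 1, low_confidence=True)
            for r, (s, e, sc) in enumerate(sorted(clusters, key=lambda c: -c[2]))
        ]
    if np.isclose(scores.max(), scores.min()):
        return []
    xs = np.arange(m) / (m - 1)
    ys = (scores - scores.min()) / (scores.max() - scores.min())
    cut_idx = int(np.argmin(ys - xs))
    cut_score = ys[cut_idx]
    chosen = [c for c, y in zip(clusters, ys) if y > cut_score]
    chosen.sort(key=lambda c: -c[2])
    return [
        SuperFire(s, e, sc, rank=r + 1) for r, (s, e, sc) in enumerate(chosen)
    ]
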