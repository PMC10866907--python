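"""Two-locus linkage disequilibrium from haplotype frequencies.

Follows the classical parameterisation: haplotype frequencies g11, g10,
g01, g00 (1 = alt allele at the nonsyn/first and syn/second locus), allele
frequencies p1, q1, p2, q2, and the LD parameters D = g11 - p1*p2,
r2 = D^2 / (p1 q1 p2 q2) and X2 = n * r2.  The primary path counts
haplotypes from phased genotypes; an EM estimator over the
double-heterozygote ambiguity covers unphased input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HaplotypeCounts:
    """Counts of the four two-locus haplotypes AB, Ab, aB, ab."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self):
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("haplotype counts must be non-negative")
        if self.n == 0:
            raise ValueError("haplotype counts sum to zero")

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass
class LDStats:
    g11: float
    g10: float
    g01: float
    g00: float
    p1: float
    p2: float
    D: float
    X2: float
    r2: float
    n: float
    defined: bool = True
    converged: bool = True
    loglik_trace: list = field(default_factory=list)

    @property
    def q1(self) -> float:
        return 1.0 - self.p1

    @property
    def q2(self) -> float:
        return 1.0 - self.p2


def _ld_from_freqs(g11, g10, g01, g00, n) -> LDStats:
    p1 = g11 + g10
    p2 = g11 + g01
    D = g11 - p1 * p2
    denom = p1 * (1 - p1) * p2 * (1 - p2)
    if denom <= 0:
        return LDStats(g11, g10, g01, g00, p1, p2, D, np.nan, np.nan, n, defined=False)
    r2 = D * D / denom
    return LDStats(g11, g10, g01, g00, p1, p2, D, n * r2, r2, n)


def ld_from_haplotype_counts(h: HaplotypeCounts) -> LDStats:
    """LD parameters from a table of observed haplotype counts.

    A locus monomorphic in the table makes D/r2 undefined; the result is
    flagged (``defined=False``), never coerced to zero.
    """
    n = h.n
    return _ld_from_freqs(h.n11 / n, h.n10 / n, h.n01 / n, h.n00 / n, n)


def extract_haplotype_counts(
    gm: GenotypeMatrix, site_a: int, site_b: int, sample_idx=None
) -> HaplotypeCounts:
    """Count the four haplotypes between two sites from phased genotypes.

    Each individual contributes two haplotypes; a haplotype missing at
    either site is dropped.
    """
    if not gm.phased:
        raise ValueError("genotypes are unphased; use em_haplotype_freqs")
    if sample_idx is None:
        cols = slice(None)
    else:
        sample_idx = np.asarray(sample_idx, dtype=np.intp)
        cols = np.sort(np.concatenate([2 * sample_idx, 2 * sample_idx + 1]))
    a = gm.haplotypes[site_a, cols]
    b = gm.haplotypes[site_b, cols]
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    return HaplotypeCounts(
        n11=int(((a == 1) & (b == 1)).sum()),
        n10=int(((a == 1) & (b == 0)).sum()),
        n01=int(((a == 0) & (b == 1)).sum()),
        n00=int(((a == 0) & (b == 0)).sum()),
    )


# genotype-pair cell (i, j) -> definite haplotype contributions
# (counts of AB, Ab, aB, ab per individual); the (1, 1) cell is ambiguous
_CELL_HAPS = {
    (0, 0): (0, 0, 0, 2), (0, 1): (0, 0, 1, 1), (0, 2): (0, 0, 2, 0),
    (1, 0): (0, 1, 0, 1), (1, 2): (1, 0, 1, 0),
    (2, 0): (0, 2, 0, 0), (2, 1): (1, 1, 0, 0), (2, 2): (2, 0, 0, 0),
}


def _pair_table_loglik(table, g):
    g11, g10, g01, g00 = g
    probs = {
        (0, 0): g00**2, (0, 1): 2 * g01 * g00, (0, 2): g01**2,
        (1, 0): 2 * g10 * g00, (1, 1): 2 * (g11 * g00 + g10 * g01),
        (1, 2): 2 * g11 * g01,
        (2, 0): g10**2, (2, 1): 2 * g11 * g10, (2, 2): g11**2,
    }
    ll = 0.0
    for (i, j), cnt in np.ndenumerate(table):
        if cnt > 0:
            ll += cnt * np.log(max(probs[(i, j)], 1e-300))
    return ll


def em_haplotype_freqs(pair_table, tol: float = 1e-10, max_iter: int = 1000) -> LDStats:
    """EM estimate of haplotype frequencies from unphased genotype pairs.

    ``pair_table`` is the 3x3 matrix of genotype-dosage pair counts
    (rows: dosage at locus 1; columns: dosage at locus 2).  Only the
    double-heterozygote cell is latent; the EM iterates the standard
    coupling-fraction update from a deterministic linkage-equilibrium
    initialisation (g = product of allele frequencies) until the haplotype
    frequencies move by less than ``tol``.
    """
    table = np.asarray(pair_table, dtype=float)
    if table.shape != (3, 3) or (table < 0).any():
        raise ValueError("pair_table must be a non-negative 3x3 matrix")
    n_ind = table.sum()
    if n_ind == 0:
        raise ValueError("empty pair table")
    n_hap = 2 * n_ind

    dosage1 = np.array([[i for _ in range(3)] for i in range(3)], float)
    dosage2 = np.array([[j for j in range(3)] for _ in range(3)], float)
    p1 = (table * dosage1).sum() / n_hap
    p2 = (table * dosage2).sum() / n_hap
    g = np.array([p1 * p2, p1 * (1 - p2), (1 - p1) * p2, (1 - p1) * (1 - p2)])

    base = np.zeros(4)
    for cell, contrib in _CELL_HAPS.items():
        base += table[cell] * np.asarray(contrib, float)
    n_dh = table[1, 1]

    trace = [_pair_table_loglik(table, g)]
    converged = False
    for _ in range(max_iter):
        coupling = g[0] * g[3]
        repulsion = g[1] * g[2]
        tot = coupling + repulsion
        w = coupling / tot if tot > 0 else 0.5
        counts = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        g_new = counts / n_hap
        trace.append(_pair_table_loglik(table, g_new))
        delta = np.abs(g_new - g).max()
        g = g_new
        if delta < tol:
            converged = True
            break
    if not converged:
        log.warning("EM did not converge within %d iterations", max_iter)
    out = _ld_from_freqs(*g, n_hap)
    out.converged = converged
    out.loglik_trace = trace
    return out


def pair_table_from_codes(codes_a, codes_b) -> np.ndarray:
    """3x3 genotype-pair count table from two dosage vectors (missing at
    either locus drops the individual)."""
    a = np.asarray(codes_a)
    b = np.asarray(codes_b)
    ok = (a != MISSING) & (b != MISSING)
    table = np.zeros((3, 3))
    np.add.at(table, (a[ok], b[ok]), 1)
    return table


def pair_ld(gm: GenotypeMatrix, site_a: int, site_b: int, sample_idx=None) -> LDStats:
    """LD between two sites: haplotype counting when phased, EM otherwise."""
    if gm.phased:
        return ld_from_haplotype_counts(
            extract_haplotype_counts(gm, site_a, site_b, sample_idx)
        )
    log.warning("unphased genotypes: estimating haplotype frequencies by EM")
    cols = slice(None) if sample_idx is None else np.asarray(sample_idx, dtype=np.intp)
    return em_haplotype_freqs(
        pair_table_from_codes(gm.codes[site_a, cols], gm.codes[site_b, cols])
    )


def nearest_syn_pairs(sites) -> pd.DataFrame:
    """Pair each nonsynonymous site with its nearest synonymous site on the
    same chromosome (ties broken toward the smaller position).

    Returns columns nonsyn_idx, syn_idx, distance; nonsyn sites with no
    synonymous partner on their chromosome are omitted.
    """
    rows = []
    by_chrom: dict[str, list] = {}
    for i, s in enumerate(sites):
        by_chrom.setdefault(s.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        syn = [i for i in idxs if sites[i].func_class == "synonymous"]
        if not syn:
            continue
        syn_pos = np.array([sites[i].pos for i in syn])
        for i in idxs:
            if sites[i].func_class != "nonsynonymous":
                continue
            d = np.abs(syn_pos - sites[i].pos)
            best = d.min()
            cand = [syn[k] for k in np.flatnonzero(d == best)]
            j = min(cand, key=lambda k: sites[k].pos)
            rows.append({"nonsyn_idx": i, "syn_idx": j, "distance": int(best)})
    return pd.DataFrame(rows, columns=["nonsyn_idx", "syn_idx", "distance"])


@dataclass
class DecayCurve:
    midpoints: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    half_max_distance: float  # np.inf when the curve never falls to half max
    max_dist: int


def _pairwise_r2(mat: np.ndarray, pairs_i, pairs_j, chunk=4096) -> np.ndarray:
    """r^2 between allele rows of ``mat`` for the given index pairs,
    pairwise-complete over missing entries."""
    out = np.empty(len(pairs_i))
    for lo in range(0, len(pairs_i), chunk):
        ii = pairs_i[lo : lo + chunk]
        jj = pairs_j[lo : lo + chunk]
        A = mat[ii].astype(float)
        B = mat[jj].astype(float)
        ok = (A != MISSING) & (B != MISSING)
        A[~ok] = 0.0
        B[~ok] = 0.0
        n = ok.sum(axis=1)
        sa, sb = A.sum(axis=1), B.sum(axis=1)
        sab = (A * B).sum(axis=1)
        saa, sbb = (A * A).sum(axis=1), (B * B).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = sab - sa * sb / n
            va = saa - sa * sa / n
            vb = sbb - sb * sb / n
            r2 = np.where((va > 0) & (vb > 0), cov**2 / (va * vb), np.nan)
        out[lo : lo + chunk] = r2
    return out


def ld_decay(
    gm: GenotypeMatrix,
    sample_idx=None,
    max_dist: int = 100_000,
    bin_width: int = 1_000,
    pair_budget: int = 200_000,
    seed: int = 0,
) -> DecayCurve:
    """Mean r^2 per distance bin and the half-maximum decay distance.

    All intra-chromosomal pairs within ``max_dist`` are used (subsampled to
    ``pair_budget`` with a fixed seed when more exist).  The decay distance
    is where the binned mean r^2 first falls to half its maximum, linearly
    interpolated between bin midpoints; a curve that never crosses reports
    ``inf`` (read: beyond ``max_dist``).
    """
    if sample_idx is None:
        sample_idx = np.arange(gm.n_samples)
    sample_idx = np.asarray(sample_idx, dtype=np.intp)
    if gm.phased:
        cols = np.sort(np.concatenate([2 * sample_idx, 2 * sample_idx + 1]))
        mat = gm.haplotypes[:, cols]
    else:
        mat = gm.codes[:, sample_idx]

    chroms = gm.chroms()
    pos = gm.positions()
    pi, pj = [], []
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        p = pos[idx]
        hi = np.searchsorted(p, p + max_dist, side="right")
        for k, i in enumerate(idx):
            js = idx[k + 1 : hi[k]]
            pi.append(np.full(js.size, i))
            pj.append(js)
    pi = np.concatenate(pi) if pi else np.empty(0, dtype=np.intp)
    pj = np.concatenate(pj) if pj else np.empty(0, dtype=np.intp)
    if pi.size == 0:
        raise ValueError("need at least two sites within max_dist on one chromosome")
    if pi.size > pair_budget:
        keep = np.random.default_rng(seed).choice(pi.size, pair_budget, replace=False)
        keep.sort()
        pi, pj = pi[keep], pj[keep]

    r2 = _pairwise_r2(mat, pi, pj)
    dist = pos[pj] - pos[pi]
    ok = ~np.isnan(r2)
    r2, dist = r2[ok], dist[ok]

    edges = np.arange(0, max_dist + bin_width, bin_width)
    which = np.clip(np.digitize(dist, edges) - 1, 0, len(edges) - 2)
    sums = np.bincount(which, weights=r2, minlength=len(edges) - 1)
    counts = np.bincount(which, minlength=len(edges) - 1)
    nonempty = counts > 0
    mid = (edges[:-1] + edges[1:]) / 2.0
    mids = mid[nonempty]
    means = sums[nonempty] / counts[nonempty]

    target = means.max() / 2.0 if means.size else np.nan
    half = np.inf
    for k in range(means.size):
        if means[k] <= target + 1e-15:
            if k == 0:
                half = float(mids[0])
            else:
                m0, m1 = means[k - 1], means[k]
                half = float(mids[k - 1] + (mids[k] - mids[k - 1]) * (m0 - target) / (m0 - m1))
            break
    return DecayCurve(mids, means, counts[nonempty], half, max_dist)
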