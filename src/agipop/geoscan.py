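"""Genotype-environment association scan.

Per-site Spearman correlation (Rho) between city-level allele frequencies
and geographic or bioclimatic features, Benjamini-Hochberg FDR control,
Nonsyn/Syn stratification by |Rho| and merging of high-|Rho| genome regions.

P-values are permutation-based throughout: the exact permutation
distribution when the number of cities used is at most ``exact_max_n``
(default 8), and a Monte-Carlo permutation null otherwise.  The
t-approximation is deliberately not used — with a few dozen rank-tied
populations it is anti-conservative in the tails, which breaks the FDR
guarantee of the downstream Benjamini-Hochberg step.
"""

from __future__ import annotations

import functools
import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values.

    NaN entries are excluded from the number of tests and propagated as NaN.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if (p[ok] < 0).any() or (p[ok] > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


@functools.lru_cache(maxsize=4)
def _perm_indices(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _exact_perm_pvals(rx: np.ndarray, ry: np.ndarray) -> np.ndarray:
    """Exact two-sided permutation p-values for Spearman rho.

    ``rx``: (n_sites, n) site AF ranks; ``ry``: (n,) feature ranks.  With the
    tie structures fixed, rho is affine in S = sum(rx * perm(ry)), so the
    permutation distribution of |rho| is obtained by counting the
    sum-product statistic over all n! permutations of the feature ranks.
    """
    n = ry.size
    perms = ry[_perm_indices(n)]  # (n!, n)
    obs = rx @ ry  # (n_sites,)
    # average ranks always sum to n(n+1)/2, so the centring constant is
    # shared by every site and the null distribution of S depends on the
    # site's ranks only through their multiset (relabelling the permutation
    # index): one null per tie pattern suffices.
    center = n * ((n + 1) / 2) * ry.mean()
    obs_dev = np.abs(obs - center)
    patterns, inverse = np.unique(np.sort(rx, axis=1), axis=0, return_inverse=True)
    pvals = np.empty(rx.shape[0])
    n_perm = perms.shape[0]
    for k in range(patterns.shape[0]):
        null_dev = np.sort(np.abs(perms @ patterns[k] - center))
        rows = inverse == k
        ge = n_perm - np.searchsorted(null_dev, obs_dev[rows] - 1e-9, side="left")
        pvals[rows] = ge / n_perm
    return pvals


def _mc_perm_pvals(rx: np.ndarray, ry: np.ndarray, n_perms: int, seed: int) -> np.ndarray:
    """Monte-Carlo permutation p-values for Spearman rho, two-sided, with
    the (k+1)/(B+1) estimator (valid by construction, so downstream BH
    control holds).  As in the exact path, the null of the sum-product
    statistic depends on a site's ranks only through their multiset, so one
    sampled null per tie pattern serves all its sites."""
    n = ry.size
    rng = np.random.default_rng(seed)
    perms = np.tile(ry, (n_perms, 1))
    perms = rng.permuted(perms, axis=1)
    obs = rx @ ry
    center = n * ((n + 1) / 2) * ry.mean()
    obs_dev = np.abs(obs - center)
    patterns, inverse = np.unique(np.sort(rx, axis=1), axis=0, return_inverse=True)
    pvals = np.empty(rx.shape[0])
    for k in range(patterns.shape[0]):
        null_dev = np.sort(np.abs(perms @ patterns[k] - center))
        rows = inverse == k
        ge = n_perms - np.searchsorted(null_dev, obs_dev[rows] - 1e-9, side="left")
        pvals[rows] = (ge + 1) / (n_perms + 1)
    return pvals


def _spearman_block(af: np.ndarray, y: np.ndarray, exact_max_n: int,
                    mc_perms: int = 20_000, mc_seed: int = 0):
    """Vectorised Spearman rho and two-sided p for sites sharing a complete
    city subset.  ``af``: (n_sites, n) with no NaN; ``y``: (n,)."""
    n = y.size
    rx = stats.rankdata(af, axis=1)
    ry = stats.rankdata(y)
    sx = rx.std(axis=1)
    sy = ry.std()
    valid = (sx > 0) & (sy > 0)
    rho = np.full(af.shape[0], np.nan)
    if sy > 0:
        cov = ((rx - rx.mean(axis=1, keepdims=True)) * (ry - ry.mean())).mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(valid, cov / np.where(valid, sx * sy, 1), np.nan)
        rho = np.clip(rho, -1, 1)
    p = np.full(af.shape[0], np.nan)
    if valid.any():
        if n <= exact_max_n:
            p[valid] = _exact_perm_pvals(rx[valid], ry)
        else:
            p[valid] = _mc_perm_pvals(rx[valid], ry, mc_perms, mc_seed)
    return rho, p, valid


def spearman_scan(
    pop_daf: pd.DataFrame,
    features: pd.DataFrame,
    feature_names=("Long", "Lati"),
    min_pops: int = 5,
    exact_max_n: int = 8,
    mc_perms: int = 20_000,
    mc_seed: int = 0,
) -> pd.DataFrame:
    """Correlation scan of per-city allele frequencies against features.

    Parameters
    ----------
    pop_daf : DataFrame
        Sites x cities allele frequencies (NaN = no calls in that city).
        Rows index sites in genome order.
    features : DataFrame
        City-indexed feature table (e.g. Long, Lati, Bio1..Bio19); only the
        cities appearing as ``pop_daf`` columns are used.
    feature_names : sequence of str
        Features to scan.
    min_pops : int
        Minimum cities with non-missing AF for a site to be tested.
    exact_max_n : int
        Use the exact permutation null when the city count is <= this;
        above it, a Monte-Carlo permutation null with ``mc_perms`` draws
        (fixed ``mc_seed`` for reproducibility).

    Returns a tidy DataFrame (site, feature, rho, p, q, n_pops) with BH
    q-values computed within each feature.
    """
    if min_pops < 4:
        raise ValueError("min_pops < 4: correlation would be meaningless")
    cities = [c for c in pop_daf.columns if c in features.index]
    if len(cities) < len(pop_daf.columns):
        missing = set(pop_daf.columns) - set(cities)
        raise KeyError(f"cities absent from feature table: {sorted(missing)}")
    af = pop_daf[cities].to_numpy(dtype=float)
    n_sites = af.shape[0]
    site_idx = np.arange(n_sites)

    frames = []
    # sites sharing a missingness pattern form one vectorised block
    miss = np.isnan(af)
    pattern_ids = np.unique(miss, axis=0, return_inverse=True)[1]
    for feat in feature_names:
        y_all = features.loc[cities, feat].to_numpy(dtype=float)
        rho = np.full(n_sites, np.nan)
        p = np.full(n_sites, np.nan)
        n_used = np.full(n_sites, 0)
        for pid in np.unique(pattern_ids):
            rows = site_idx[pattern_ids == pid]
            use = ~miss[rows[0]]
            if use.sum() < min_pops:
                continue
            r_blk, p_blk, _ = _spearman_block(af[np.ix_(rows, np.flatnonzero(use))],
                                              y_all[use], exact_max_n,
                                              mc_perms, mc_seed)
            rho[rows], p[rows] = r_blk, p_blk
            n_used[rows] = int(use.sum())
        q = bh_fdr(p)
        frames.append(pd.DataFrame({
            "site": site_idx, "feature": feat, "rho": rho,
            "p": p, "q": q, "n_pops": n_used,
        }))
    return pd.concat(frames, ignore_index=True)


def site_max_abs_rho(results: pd.DataFrame, n_sites: int) -> np.ndarray:
    """Per-site maximum |rho| across scanned features (NaN if never tested)."""
    out = np.full(n_sites, np.nan)
    ok = results.dropna(subset=["rho"])
    if len(ok):
        grp = ok.assign(a=ok["rho"].abs()).groupby("site")["a"].max()
        out[grp.index.to_numpy()] = grp.to_numpy()
    return out


def ns_ratio_by_rho(
    results: pd.DataFrame,
    func_class: np.ndarray,
    bins=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
) -> pd.DataFrame:
    """Nonsyn/Syn count ratio within |rho| bins.

    ``results`` should be the scan output restricted to one feature (or
    pre-aggregated with one row per site); ``func_class`` indexes sites.
    Bins are left-closed, with the last bin closed on both ends.  Bins with
    zero synonymous sites report a NaN ratio alongside the raw counts.
    """
    bins = np.asarray(bins, dtype=float)
    ok = results.dropna(subset=["rho"])
    a = ok["rho"].abs().to_numpy()
    fc = np.asarray(func_class, dtype=object)[ok["site"].to_numpy()]
    which = np.digitize(a, bins[1:-1], right=False)
    rows = []
    for b in range(len(bins) - 1):
        in_bin = which == b
        n_non = int(((fc == "nonsynonymous") & in_bin).sum())
        n_syn = int(((fc == "synonymous") & in_bin).sum())
        rows.append({
            "lo": bins[b], "hi": bins[b + 1],
            "n_nonsyn": n_non, "n_syn": n_syn,
            "ratio": (n_non / n_syn) if n_syn else np.nan,
        })
    return pd.DataFrame(rows)


def rho_profile_and_merge(
    results: pd.DataFrame,
    sites,
    threshold: float = 0.8,
    merge_gap: int = 1_000_000,
) -> pd.DataFrame:
    """Merge sites with high |rho| into genome regions.

    Seeds are sites whose |rho| reaches ``threshold`` for at least one
    feature; seeds on the same chromosome closer than ``merge_gap`` bp merge
    into one region.  Returns BED-style 0-based half-open regions with seed
    counts and the features implicated.
    """
    n_sites = len(sites)
    maxrho = site_max_abs_rho(results, n_sites)
    ok = results.dropna(subset=["rho"])
    feat_hits = (
        ok[ok["rho"].abs() >= threshold].groupby("site")["feature"].agg(set)
        if len(ok) else pd.Series(dtype=object)
    )
    seeds = np.flatnonzero(maxrho >= threshold)
    regions = []
    cur = None
    for i in seeds:
        s = sites[i]
        feats = feat_hits.get(i, set())
        if cur is not None and s.chrom == cur["chrom"] and (s.pos - 1) - cur["end"] < merge_gap:
            cur["end"] = s.pos
            cur["n_sites"] += 1
            cur["features"] |= feats
        else:
            if cur is not None:
                regions.append(cur)
            cur = {"chrom": s.chrom, "start": s.pos - 1, "end": s.pos,
                   "n_sites": 1, "features": set(feats)}
    if cur is not None:
        regions.append(cur)
    df = pd.DataFrame(regions, columns=["chrom", "start", "end", "n_sites", "features"])
    if len(df):
        df["features"] = df["features"].map(lambda s: ",".join(sorted(s)))
    return df
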