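"""Diversity, differentiation, windowed sweep scans and runs of homozygosity.

Per-site nucleotide diversity / heterozygosity, the Weir & Cockerham (1984)
F_ST variance-component estimator, the island-model gene-flow proxy
Nm = (1 - F_ST) / (4 F_ST), 10 kb / 5 kb sliding-window scans with top-5%
intersection of F_ST and the log2 diversity ratio, and a PLINK-style
windowed ROH scanner with the inbreeding coefficient F_ROH.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


def diversity_stats(gm: GenotypeMatrix, sample_idx=None) -> pd.DataFrame:
    """Per-site nucleotide diversity (unbiased pi), expected and observed
    heterozygosity for one population.

    With k called alleles and alt count c: pi = 2*(c/k)*(1-c/k)*k/(k-1)
    (the unbiased per-site estimator), He = 2*p*q, Ho = fraction of called
    individuals that are heterozygous.  Sites with fewer than 2 called
    individuals are NaN.
    """
    if sample_idx is None:
        sample_idx = np.arange(gm.n_samples)
    codes = gm.codes[:, np.asarray(sample_idx, dtype=np.intp)]
    miss = codes == MISSING
    n_ind = (~miss).sum(axis=1)
    k = 2.0 * n_ind
    k[n_ind < 2] = 0  # at least two called individuals required
    c = np.where(miss, 0, codes).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(k > 0, c / np.maximum(k, 1), np.nan)
        pi = np.where(k >= 2, 2 * p * (1 - p) * k / np.maximum(k - 1, 1), np.nan)
        he = np.where(k >= 2, 2 * p * (1 - p), np.nan)
        ho = np.where(n_ind > 0, (codes == 1).sum(axis=1) / np.maximum(n_ind, 1), np.nan)
    ho[k < 2] = np.nan
    return pd.DataFrame({
        "chrom": [s.chrom for s in gm.sites],
        "pos": [s.pos for s in gm.sites],
        "pi": pi, "he": he, "ho": ho,
    })


def wc_fst(gm: GenotypeMatrix, partitions) -> dict:
    """Weir & Cockerham (1984) F_ST from the two-level a/b/c decomposition.

    ``partitions`` maps population label -> sample index array.  Per site,
    with r populations of n_i called individuals, alt frequency p_i and
    heterozygote proportion h_i:

        nbar = sum n_i / r                 nc = (r*nbar - sum n_i^2/(r*nbar)) / (r-1)
        pbar = sum n_i p_i / (r*nbar)      s2 = sum n_i (p_i-pbar)^2 / ((r-1)*nbar)
        hbar = sum n_i h_i / (r*nbar)

        a = nbar/nc * (s2 - (pbar*(1-pbar) - (r-1)/r*s2 - hbar/4) / (nbar-1))
        b = nbar/(nbar-1) * (pbar*(1-pbar) - (r-1)/r*s2 - (2*nbar-1)/(4*nbar)*hbar)
        c = hbar/2

    Per-site theta = a/(a+b+c) (negative values retained); the multi-site
    estimate is the ratio of sums sum(a)/sum(a+b+c).  Sites monomorphic
    across all populations, or with fewer than two populations carrying at
    least one called individual, are NaN.
    """
    labels = list(partitions)
    if len(labels) < 2:
        raise ValueError("need at least two populations")
    n_sites = gm.n_sites
    n_i = np.zeros((len(labels), n_sites))
    p_i = np.zeros_like(n_i)
    h_i = np.zeros_like(n_i)
    for k, lab in enumerate(labels):
        codes = gm.codes[:, np.asarray(partitions[lab], dtype=np.intp)]
        miss = codes == MISSING
        ni = (~miss).sum(axis=1).astype(float)
        n_i[k] = ni
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(ni > 0, np.where(miss, 0, codes).sum(axis=1) / (2 * np.maximum(ni, 1)), 0.0)
            h_i[k] = np.where(ni > 0, (codes == 1).sum(axis=1) / np.maximum(ni, 1), 0.0)

    valid_pop = n_i > 0
    r = valid_pop.sum(axis=0).astype(float)
    sum_n = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = sum_n / r
        nc = (sum_n - (n_i**2).sum(axis=0) / sum_n) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / sum_n
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / sum_n
        inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4
        a = nbar / nc * (s2 - inner / (nbar - 1))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2

    poly = (pbar > 0) & (pbar < 1)
    ok = (r >= 2) & (nbar > 1) & poly
    for arr in (a, b, c):
        arr[~ok] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    num = np.nansum(a[ok])
    den = np.nansum((a + b + c)[ok])
    overall = num / den if den > 0 else np.nan
    return {"a": a, "b": b, "c": c, "theta": theta, "overall": overall}


def nm_from_fst(fst: float) -> float:
    """Island-model gene-flow proxy Nm = (1 - F_ST) / (4 F_ST).

    Non-positive F_ST means no detectable differentiation; reported as
    infinite flow (``inf``) rather than a number.
    """
    if not np.isfinite(fst) or fst > 1:
        raise ValueError(f"F_ST {fst} outside (0, 1]")
    if fst <= 0:
        return np.inf
    return (1.0 - fst) / (4.0 * fst)


def make_windows(chrom_spans: dict, window: int = 10_000, step: int = 5_000) -> pd.DataFrame:
    """Sliding half-open windows per chromosome.

    ``chrom_spans`` maps chrom -> length (bp); windows start at 0 every
    ``step`` and are ``window`` long (the trailing window is truncated).
    """
    rows = []
    for chrom, length in chrom_spans.items():
        start = 0
        while start < length:
            rows.append((chrom, start, min(start + window, int(length))))
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def window_scan(
    chroms,
    positions,
    values,
    denom=None,
    window: int = 10_000,
    step: int = 5_000,
    clip_negative: bool = False,
    chrom_spans: dict | None = None,
) -> pd.DataFrame:
    """Aggregate per-site values into sliding windows.

    Sites are assigned to every half-open window [start, start + window)
    containing pos - 1.  With ``denom`` the window value is the ratio of
    sums sum(values)/sum(denom) (the weighted F_ST convention); otherwise
    the plain mean.  ``clip_negative`` applies max(0, value), the standard
    treatment of negative window F_ST.  Empty windows report NaN.
    """
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    if chrom_spans is None:
        chrom_spans = {
            str(ch): int(positions[chroms == ch].max())
            for ch in dict.fromkeys(chroms)
        }
    wins = make_windows(chrom_spans, window, step)
    out_vals = np.full(len(wins), np.nan)
    n_snps = np.zeros(len(wins), dtype=int)
    for ch in dict.fromkeys(chroms):
        site_sel = chroms == ch
        pos0 = positions[site_sel] - 1  # to 0-based
        v = values[site_sel]
        d = None if denom is None else np.asarray(denom, float)[site_sel]
        widx = np.flatnonzero((wins["chrom"] == ch).to_numpy())
        starts = wins["start"].to_numpy()[widx]
        ends = wins["end"].to_numpy()[widx]
        order = np.argsort(pos0)
        pos0, v = pos0[order], v[order]
        if d is not None:
            d = d[order]
        lo = np.searchsorted(pos0, starts, side="left")
        hi = np.searchsorted(pos0, ends, side="left")
        for k, w in enumerate(widx):
            sl = slice(lo[k], hi[k])
            vv = v[sl]
            use = ~np.isnan(vv)
            if d is not None:
                dd = d[sl]
                use &= ~np.isnan(dd)
            n_snps[w] = int(use.sum())
            if not use.any():
                continue
            if d is not None:
                dsum = dd[use].sum()
                out_vals[w] = vv[use].sum() / dsum if dsum != 0 else np.nan
            else:
                out_vals[w] = vv[use].mean()
    if clip_negative:
        out_vals = np.where(np.isnan(out_vals), np.nan, np.maximum(out_vals, 0.0))
    wins["n_snps"] = n_snps
    wins["value"] = out_vals
    return wins


def log2_pi_ratio(windows_num: pd.DataFrame, windows_den: pd.DataFrame) -> pd.DataFrame:
    """log2(pi_numerator / pi_denominator) on an aligned window grid;
    undefined (NaN) when either window diversity is 0 or missing."""
    _check_aligned(windows_num, windows_den)
    out = windows_num[["chrom", "start", "end"]].copy()
    a = windows_num["value"].to_numpy(float)
    b = windows_den["value"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        val = np.where((a > 0) & (b > 0), np.log2(np.where(b > 0, a / np.where(b > 0, b, 1), np.nan)), np.nan)
    out["n_snps"] = np.minimum(windows_num["n_snps"], windows_den["n_snps"])
    out["value"] = val
    return out


def _check_aligned(*window_dfs):
    ref = window_dfs[0][["chrom", "start", "end"]]
    for other in window_dfs[1:]:
        if not ref.reset_index(drop=True).equals(
            other[["chrom", "start", "end"]].reset_index(drop=True)
        ):
            raise ValueError("window grids are not aligned")


def sweep_intersect(stat_windows: dict, quantile: float = 0.05):
    """Windows in the top ``quantile`` of every supplied statistic.

    ``stat_windows`` maps statistic name -> window DataFrame (aligned
    grids); typically F_ST and the log2 diversity ratio, plus externally
    computed XP-CLR scores when available (when absent the intersection is
    over the statistics supplied, which is logged).  Adjacent or
    overlapping selected windows merge into regions.

    Returns ``(selected_windows, regions)``.
    """
    names = list(stat_windows)
    if len(names) < 2:
        raise ValueError("need at least two statistics to intersect")
    if "xpclr" not in names:
        log.info("sweep intersection over %s (no XP-CLR supplied)", names)
    _check_aligned(*stat_windows.values())
    base = stat_windows[names[0]][["chrom", "start", "end"]].copy()
    keep = np.ones(len(base), dtype=bool)
    for name in names:
        v = stat_windows[name]["value"].to_numpy(float)
        thresh = np.nanquantile(v, 1 - quantile)
        keep &= ~np.isnan(v) & (v >= thresh)
        base[name] = v
    selected = base[keep].reset_index(drop=True)

    regions = []
    cur = None
    for row in selected.itertuples(index=False):
        if cur is not None and row.chrom == cur["chrom"] and row.start <= cur["end"]:
            cur["end"] = max(cur["end"], row.end)
            cur["n_windows"] += 1
        else:
            if cur is not None:
                regions.append(cur)
            cur = {"chrom": row.chrom, "start": row.start, "end": row.end, "n_windows": 1}
    if cur is not None:
        regions.append(cur)
    return selected, pd.DataFrame(regions, columns=["chrom", "start", "end", "n_windows"])


@dataclass
class ROHParams:
    """PLINK-style windowed ROH parameters (defaults match the standard
    --homozyg settings: 50-SNP windows with at most 1 het and 5 missing,
    per-SNP hit proportion 0.05, minimum 50 SNPs / 20 kb per run, at least
    1 SNP per 50 kb, internal gaps at most 100 kb)."""

    window_snp: int = 50
    window_het: int = 1
    window_missing: int = 5
    hit_threshold: float = 0.05
    min_snp: int = 50
    min_kb: float = 20.0
    density_kb: float = 50.0
    gap_kb: float = 100.0


def _window_sums(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0], np.cumsum(x)])
    return c[w:] - c[:-w]


def _eligible_snps(codes: np.ndarray, params: ROHParams) -> np.ndarray:
    """Per-SNP eligibility via the sliding homozygous-window vote."""
    n = codes.size
    w = params.window_snp
    if n < w:
        return np.zeros(n, dtype=bool)
    het = (codes == 1).astype(np.int64)
    mis = (codes == MISSING).astype(np.int64)
    win_ok = (_window_sums(het, w) <= params.window_het) & (
        _window_sums(mis, w) <= params.window_missing
    )
    ok = win_ok.astype(np.int64)
    hits = np.zeros(n, dtype=np.int64)
    cover = np.zeros(n, dtype=np.int64)
    csum = np.concatenate([[0], np.cumsum(ok)])
    for i in range(n):
        first = max(0, i - w + 1)
        last = min(i, n - w)
        if last < first:
            continue
        cover[i] = last - first + 1
        hits[i] = csum[last + 1] - csum[first]
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(cover > 0, hits / np.maximum(cover, 1), 0.0)
    return (cover > 0) & (prop >= params.hit_threshold)


def detect_roh(
    gm: GenotypeMatrix,
    sample: str | int,
    params: ROHParams | None = None,
    genome_length: float | None = None,
):
    """Runs of homozygosity for one sample, plus F_ROH.

    The scanner flags SNPs covered by a sufficient proportion of homozygous
    sliding windows, splits candidate runs at large gaps, and keeps maximal
    runs satisfying the SNP-count, length and density thresholds.
    F_ROH = sum of ROH lengths / genome length.

    Returns ``(segments DataFrame, f_roh)``; f_roh is None when no genome
    length is given.
    """
    params = params or ROHParams()
    if genome_length is not None and genome_length <= 0:
        raise ValueError("genome length must be positive")
    j = sample if isinstance(sample, (int, np.integer)) else gm.samples.index(sample)
    sample_id = gm.samples[j]
    chroms = gm.chroms()
    pos_all = gm.positions()
    segs = []
    for ch in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == ch)
        codes = gm.codes[idx, j]
        pos = pos_all[idx]
        elig = _eligible_snps(codes, params)
        # maximal runs of consecutive eligible SNPs, split at large gaps
        run_start = None
        boundaries = []
        for k in range(len(idx) + 1):
            end_run = k == len(idx) or not elig[k]
            split = (
                not end_run
                and run_start is not None
                and k > run_start
                and pos[k] - pos[k - 1] > params.gap_kb * 1000
            )
            if run_start is not None and (end_run or split):
                boundaries.append((run_start, k))
                run_start = k if split else None
            elif run_start is None and not end_run:
                run_start = k
        for lo, hi in boundaries:
            n_snps = hi - lo
            start0 = int(pos[lo] - 1)
            end0 = int(pos[hi - 1])
            length = end0 - start0
            if n_snps < params.min_snp:
                continue
            if length < params.min_kb * 1000:
                continue
            if length / n_snps > params.density_kb * 1000:
                continue
            segs.append({"sample": sample_id, "chrom": ch, "start": start0,
                         "end": end0, "n_snps": n_snps, "length": length})
    seg_df = pd.DataFrame(segs, columns=["sample", "chrom", "start", "end", "n_snps", "length"])
    f_roh = None
    if genome_length is not None:
        f_roh = float(seg_df["length"].sum()) / float(genome_length)
    return seg_df, f_roh


def roh_summary(gm: GenotypeMatrix, sample_idx, params=None, genome_length=None) -> pd.DataFrame:
    """Per-sample total ROH length, segment count and F_ROH."""
    rows = []
    for j in np.asarray(sample_idx, dtype=np.intp):
        seg, f = detect_roh(gm, int(j), params, genome_length)
        rows.append({
            "sample": gm.samples[j],
            "n_segments": len(seg),
            "total_length": int(seg["length"].sum()) if len(seg) else 0,
            "f_roh": f,
        })
    return pd.DataFrame(rows)
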