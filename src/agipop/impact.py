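"""Release-impact classification and introgression tests.

For sites absent from the ancestral gene pool (derived AF_A = 0, inferred
from the designated ancestral wild population plus the outgroup), the change
in wild allele frequency dAF_N = AF_N - AF_A classifies sites into not
affected (dAF_N < 0.05), weakly affected, and strongly affected (Fisher
exact test on derived/ancestral allele counts, BH-adjusted q < 0.05 among
affected sites).  The Nonsyn/Syn ratio of each class is compared against a
randomization null in which site records are shuffled against the fixed
functional annotations.  Patterson's D (ABBA-BABA) with a block jackknife
tests for gene flow per functional SNP class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geoscan import bh_fdr

log = logging.getLogger(__name__)

NOT_AFFECTED = "not_affected"
WEAK = "weak"
STRONG = "strong"


def select_provinces(meta: pd.DataFrame, min_n: int = 9) -> list:
    """Provinces with at least ``min_n`` individuals in each of the wild
    (N), artificially bred (B) and post-release (T) groups — enough
    wild/released interaction for the dAF analysis.  Kin-excluded samples
    do not count."""
    use = meta[~meta["kin_excluded"]] if "kin_excluded" in meta.columns else meta
    counts = use.groupby(["province", "group"]).size().unstack(fill_value=0)
    for g in "NBT":
        if g not in counts.columns:
            counts[g] = 0
    ok = counts[(counts["N"] >= min_n) & (counts["B"] >= min_n) & (counts["T"] >= min_n)]
    return sorted(ok.index)


def fisher_two_sided(tables) -> np.ndarray:
    """Two-sided Fisher exact p for an iterable of 2x2 tables
    [[a, b], [c, d]]."""
    out = np.empty(len(tables))
    for i, t in enumerate(tables):
        out[i] = stats.fisher_exact(t, alternative="two-sided")[1]
    return out


def classify_affected(
    derived_n,
    called_n,
    derived_a,
    called_a,
    delta: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify candidate sites by the magnitude and significance of dAF_N.

    Inputs are aligned arrays of derived/total allele counts in the focal
    wild population (N) and the ancestral pool (A), for sites pre-filtered
    to AF_A = 0 and AF_N > 0.  A site is affected iff
    dAF_N = AF_N - AF_A >= ``delta``; among affected sites a two-sided
    Fisher exact test on [derived, ancestral] counts is BH-adjusted, and
    q < ``alpha`` splits strong from weak.  Sites with zero called alleles
    in either pool are dropped (count logged).
    """
    derived_n = np.asarray(derived_n, dtype=np.int64)
    called_n = np.asarray(called_n, dtype=np.int64)
    derived_a = np.asarray(derived_a, dtype=np.int64)
    called_a = np.asarray(called_a, dtype=np.int64)
    ok = (called_n > 0) & (called_a > 0)
    if (~ok).any():
        log.info("classify_affected: dropped %d sites with empty pools", int((~ok).sum()))
    df = pd.DataFrame({
        "site": np.flatnonzero(ok),
        "derived_n": derived_n[ok], "called_n": called_n[ok],
        "derived_a": derived_a[ok], "called_a": called_a[ok],
    })
    df["af_a"] = df["derived_a"] / df["called_a"]
    df["af_n"] = df["derived_n"] / df["called_n"]
    df["delta_af"] = df["af_n"] - df["af_a"]
    df["class"] = NOT_AFFECTED
    df["fisher_p"] = np.nan
    df["q"] = np.nan
    aff = df["delta_af"] >= delta
    if aff.any():
        tables = [
            [[int(r.derived_n), int(r.called_n - r.derived_n)],
             [int(r.derived_a), int(r.called_a - r.derived_a)]]
            for r in df[aff].itertuples(index=False)
        ]
        p = fisher_two_sided(tables)
        q = bh_fdr(p)
        df.loc[aff, "fisher_p"] = p
        df.loc[aff, "q"] = q
        df.loc[aff, "class"] = np.where(q < alpha, STRONG, WEAK)
    return df


def ns_ratio(func_class) -> float:
    """Nonsyn/Syn count ratio of a site set (NaN when no synonymous sites)."""
    fc = np.asarray(func_class, dtype=object)
    n_non = int((fc == "nonsynonymous").sum())
    n_syn = int((fc == "synonymous").sum())
    return n_non / n_syn if n_syn else np.nan


@dataclass
class NSRatioTest:
    observed: dict
    null: dict  # class -> array of B null ratios
    p: dict  # one-sided randomization p per class
    p_label: dict  # "<1/(B+1)" style label when no trial is as extreme
    B: int
    seed: int


def randomization_null(
    classified: pd.DataFrame,
    func_class,
    B: int = 1000,
    seed: int = 0,
    mode: str = "tuple",
    delta: float = 0.05,
    alpha: float = 0.05,
) -> NSRatioTest:
    """Randomization null for the per-class Nonsyn/Syn ratios.

    ``mode="tuple"`` (default): each trial permutes the (AF_A, AF_N,
    counts) records across site positions while annotations stay fixed.
    Because each record keeps its own counts, its affected/weak/strong
    class is unchanged by the shuffle, so the trial reduces to permuting
    the class labels against the annotations.  ``mode="independent"``
    permutes the ancestral and focal count pairs separately and re-runs the
    classification (including Fisher tests) per trial.

    One-sided p-values use the (k+1)/(B+1) estimator: "strong" tests for a
    ratio lower than the null, "weak" for higher.  When no trial is as
    extreme the label reports the resolution bound (the "P < 0.001"
    convention at B = 1000).
    """
    if B < 100:
        log.warning("B=%d randomization trials gives unstable p-values", B)
    rng = np.random.default_rng(seed)
    fc = np.asarray(func_class, dtype=object)[classified["site"].to_numpy()]
    classes = classified["class"].to_numpy()
    observed = {cls: ns_ratio(fc[classes == cls]) for cls in (STRONG, WEAK)}

    null = {STRONG: np.empty(B), WEAK: np.empty(B)}
    if mode == "tuple":
        for b in range(B):
            perm_classes = classes[rng.permutation(classes.size)]
            for cls in (STRONG, WEAK):
                null[cls][b] = ns_ratio(fc[perm_classes == cls])
    elif mode == "independent":
        dn = classified["derived_n"].to_numpy()
        cn = classified["called_n"].to_numpy()
        da = classified["derived_a"].to_numpy()
        ca = classified["called_a"].to_numpy()
        n = len(classified)
        for b in range(B):
            pa = rng.permutation(n)
            pn = rng.permutation(n)
            re = classify_affected(dn[pn], cn[pn], da[pa], ca[pa], delta, alpha)
            cl = np.full(n, NOT_AFFECTED, dtype=object)
            cl[re["site"].to_numpy()] = re["class"].to_numpy()
            for cls in (STRONG, WEAK):
                null[cls][b] = ns_ratio(fc[cl == cls])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    p, label = {}, {}
    for cls, side in ((STRONG, "le"), (WEAK, "ge")):
        obs = observed[cls]
        vals = null[cls]
        if np.isnan(obs):
            p[cls] = np.nan
            label[cls] = "undefined"
            continue
        with np.errstate(invalid="ignore"):
            k = int(np.nansum(vals <= obs) if side == "le" else np.nansum(vals >= obs))
        p[cls] = (k + 1) / (B + 1)
        label[cls] = f"< {1 / (B + 1):.3g}" if k == 0 else f"{p[cls]:.4g}"
    return NSRatioTest(observed=observed, null=null, p=p, p_label=label, B=B, seed=seed)


@dataclass
class DStatResult:
    D: float
    se: float
    z: float
    n_blocks: int
    n_sites: int
    abba: float
    baba: float
    snp_class: str = "all"


def patterson_d(p1, p2, p3, p_out=None, func_class=None, snp_class: str = "all",
                n_blocks: int = 20) -> DStatResult:
    """Patterson's D (ABBA-BABA) from population allele frequencies.

    On the four-taxon tree (((P1, P2), P3), O) with derived-allele
    frequencies p1, p2, p3 and outgroup state pO (0 or 1):

        D = sum[(1-p1) p2 p3 (1-pO) - p1 (1-p2) p3 (1-pO)] /
            sum[(1-p1) p2 p3 (1-pO) + p1 (1-p2) p3 (1-pO)]

    D > 0 indicates excess sharing between P2 and P3, D < 0 between P1 and
    P3.  The standard error comes from a delete-one jackknife over
    ``n_blocks`` contiguous equal-SNP blocks; Z = D / SE.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    p3 = np.asarray(p3, float)
    pO = np.zeros_like(p1) if p_out is None else np.asarray(p_out, float)
    keep = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3) | np.isnan(pO))
    if func_class is not None and snp_class != "all":
        want = {"missense": "nonsynonymous", "synonymous": "synonymous"}.get(
            snp_class, snp_class
        )
        keep &= np.asarray(func_class, dtype=object) == want
    p1, p2, p3, pO = p1[keep], p2[keep], p3[keep], pO[keep]

    abba = (1 - p1) * p2 * p3 * (1 - pO) + p1 * (1 - p2) * (1 - p3) * pO
    baba = p1 * (1 - p2) * p3 * (1 - pO) + (1 - p1) * p2 * (1 - p3) * pO
    num = abba.sum() - baba.sum()
    den = abba.sum() + baba.sum()
    if den == 0:
        return DStatResult(np.nan, np.nan, np.nan, 0, int(keep.sum()),
                           float(abba.sum()), float(baba.sum()), snp_class)
    D = num / den

    n = p1.size
    blocks = np.array_split(np.arange(n), min(n_blocks, n))
    blocks = [b for b in blocks if b.size and (abba[b].sum() + baba[b].sum()) > 0]
    if len(blocks) < 3:
        return DStatResult(float(D), np.nan, np.nan, len(blocks), n,
                           float(abba.sum()), float(baba.sum()), snp_class)
    d_minus = []
    for b in blocks:
        a = abba.sum() - abba[b].sum()
        bb = baba.sum() - baba[b].sum()
        d_minus.append((a - bb) / (a + bb) if (a + bb) > 0 else np.nan)
    d_minus = np.asarray(d_minus, float)
    ok = ~np.isnan(d_minus)
    nb = int(ok.sum())
    if nb < 3:
        return DStatResult(float(D), np.nan, np.nan, nb, n,
                           float(abba.sum()), float(baba.sum()), snp_class)
    dm = d_minus[ok]
    se = np.sqrt((nb - 1) / nb * ((dm - dm.mean()) ** 2).sum())
    z = D / se if se > 0 else np.nan
    return DStatResult(float(D), float(se), float(z), nb, n,
                       float(abba.sum()), float(baba.sum()), snp_class)
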