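"""Ground-truth validation scenarios.

Each function builds a purpose-built synthetic study, runs the relevant
analysis stage, and measures how well the implanted signal is recovered (or
how well the null is respected).  These are the package's end-to-end checks
on known truth; the test suite and the reproduction script both run them.

Scenario sizes are fixed, documented choices: large enough for the measured
rates to be stable, small enough to run on a laptop in seconds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import diversity, geoscan, impact, polarize
from .synthetic import ScenarioConfig, simulate_arrays


def _wild_city_daf(ds):
    paf = polarize.population_af(ds.gm, ds.meta, "city", group="N")
    pol = polarize.polarize(paf, ds.gm.sites, ds.outgroup)
    return pd.DataFrame(pol.daf)


def clinal_recovery(seeds=range(10, 20)) -> dict:
    """Power/precision of the correlation scan for implanted clines.

    Each replicate study: 20 cities x 15 wild diploids, logistic slope 0.3,
    200 clinal sites among 5000 (no release-impact structure, so every
    non-clinal site is null).  Power and precision are pooled over the
    replicates: with BH at q < 0.05 the expected false-discovery proportion
    is ~alpha times the null fraction, so a single replicate's precision
    hovers at the 95% boundary and only the pooled rate is stable.
    """
    if isinstance(seeds, (int, np.integer)):
        seeds = [seeds]
    n_true_hit = n_true = n_disc = n_disc_true = 0
    for seed in seeds:
        cfg = ScenarioConfig(seed=seed, n_cities=20, cities_per_province=4,
                             n_sites=5000, n_clinal_sites=200, n_impact_sites=0,
                             introgression_m=0.0, n_wild_per_city=15)
        ds = simulate_arrays(cfg)
        scan = geoscan.spearman_scan(_wild_city_daf(ds), ds.climate,
                                     ("Long", "Lati"), min_pops=5)
        sig = scan.loc[scan["q"] < 0.05, "site"].unique()
        clinal = np.flatnonzero(ds.truth.is_clinal)
        n_true += clinal.size
        n_true_hit += int(np.isin(clinal, sig).sum())
        n_disc += sig.size
        n_disc_true += int(np.isin(sig, clinal).sum())
    return {"power": n_true_hit / n_true if n_true else np.nan,
            "precision": n_disc_true / n_disc if n_disc else np.nan,
            "n_discoveries": n_disc, "n_clinal": n_true,
            "n_replicates": len(list(seeds))}


def geoscan_type1(seeds=range(20)) -> dict:
    """False-discovery calibration on fully neutral scans (8 cities, 2000
    sites, exact-permutation p-values): fraction of tests with q < 0.05."""
    n_sig = 0
    n_tests = 0
    for seed in seeds:
        cfg = ScenarioConfig(seed=seed, n_cities=8, n_sites=2000,
                             n_clinal_sites=0, n_impact_sites=0,
                             introgression_m=0.0)
        ds = simulate_arrays(cfg)
        scan = geoscan.spearman_scan(_wild_city_daf(ds), ds.climate,
                                     ("Long", "Lati"), min_pops=5)
        ok = scan.dropna(subset=["q"])
        n_sig += int((ok["q"] < 0.05).sum())
        n_tests += len(ok)
    rate = n_sig / n_tests if n_tests else np.nan
    se = np.sqrt(0.05 * 0.95 / n_tests) if n_tests else np.nan
    return {"rate": rate, "n_tests": n_tests, "bound": 0.05 + 3 * se}


def _impact_cfg(seed, nonsyn_sel, nonsyn_beta):
    return ScenarioConfig(seed=seed, n_sites=5000, n_impact_sites=800,
                          n_clinal_sites=0, n_cities=6, cities_per_province=2,
                          n_wild_per_city=30, ancestral_n_wild_per_city=15,
                          introgression_m=0.1, nonsyn_sel=nonsyn_sel,
                          nonsyn_beta=nonsyn_beta)


def impact_analysis(seed: int = 0, nonsyn_sel: float = 0.3,
                    nonsyn_beta: float | None = 9.0, B: int = 1000,
                    province: str = "prov1") -> dict:
    """Classify release-affected sites in one focal province and run the
    annotation-randomization null.

    ``nonsyn_sel < 1`` simulates purifying selection against introgressed
    nonsynonymous alleles in the wild; ``nonsyn_sel=1, nonsyn_beta=None``
    is the fully neutral control (annotations independent of frequencies).
    """
    ds = simulate_arrays(_impact_cfg(seed, nonsyn_sel, nonsyn_beta))
    gm, meta, og = ds.gm, ds.meta, ds.outgroup
    anc = polarize.ancestral_af(gm, meta, og, ds.config.ancestral_label)
    flip = anc["status"].to_numpy() == polarize.ALT_ANCESTRAL

    paf = polarize.population_af(gm, meta[meta["province"] == province],
                                 "province", group="N")
    alt_n = paf.alt_count[province]
    tot_n = paf.called_total[province]
    der_n = np.where(flip, tot_n - alt_n, alt_n)
    cand = anc["af_a_zero"].to_numpy() & (tot_n > 0) & (der_n > 0)
    idx = np.flatnonzero(cand)
    cls = impact.classify_affected(
        der_n[idx], tot_n[idx],
        anc["derived_count"].to_numpy()[idx], anc["called_total"].to_numpy()[idx],
    )
    cls["site"] = idx[cls["site"].to_numpy()]
    test = impact.randomization_null(cls, gm.func_classes(), B=B, seed=seed)
    counts = cls["class"].value_counts().to_dict()
    return {"counts": counts, "observed": test.observed, "p": test.p,
            "p_label": test.p_label, "classified": cls, "test": test}


def impact_neutral_pvalues(seeds=range(20), B: int = 1000) -> list:
    """Strong-class randomization p-values over neutral replicate studies."""
    return [impact_analysis(seed, nonsyn_sel=1.0, nonsyn_beta=None, B=B)["p"]["strong"]
            for seed in seeds]


def sweep_recovery(seed: int = 7, region=(400_000, 450_000)) -> dict:
    """Recovery of one implanted 50 kb divergent region as the unique
    top-5% F_ST x top-5% log2 diversity-ratio intersection."""
    cfg = ScenarioConfig(seed=seed, n_sites=5000, n_impact_sites=0,
                         n_clinal_sites=0, introgression_m=0.0,
                         sweep_region=region)
    ds = simulate_arrays(cfg)
    gm, meta = ds.gm, ds.meta
    groups = {g: gm.sample_indices(meta[meta["group"] == g].index) for g in "NB"}
    fst = diversity.wc_fst(gm, groups)
    chroms, pos = gm.chroms(), gm.positions()
    w_fst = diversity.window_scan(chroms, pos, fst["a"],
                                  denom=fst["a"] + fst["b"] + fst["c"],
                                  clip_negative=True)
    pi = {g: diversity.diversity_stats(gm, idx)["pi"].to_numpy()
          for g, idx in groups.items()}
    w_b = diversity.window_scan(chroms, pos, pi["B"])
    w_n = diversity.window_scan(chroms, pos, pi["N"])
    ratio = diversity.log2_pi_ratio(w_b, w_n)
    _, regions = diversity.sweep_intersect({"fst": w_fst, "log2_pi_ratio": ratio},
                                           quantile=0.05)
    overlaps = [
        r for r in regions.itertuples(index=False)
        if r.start < region[1] and r.end > region[0]
    ]
    return {"regions": regions, "n_regions": len(regions),
            "n_overlapping": len(overlaps)}


def dstat_trio(seed: int, m: float, province: str = "prov1") -> impact.DStatResult:
    """Patterson's D on the trio (bred, post-release, wild) of one province.

    The scenario releases a drifted descendant of the bred pool; with
    introgression ``m`` the wild population shares its private drift,
    producing D > 0 (post-release/wild excess).  ``post_admix=0`` keeps the
    m = 0 control a true null.
    """
    cfg = ScenarioConfig(seed=seed, n_sites=8000, n_impact_sites=800,
                         n_clinal_sites=0, introgression_m=m,
                         post_admix=0.0, nonsyn_sel=1.0)
    ds = simulate_arrays(cfg)
    gm, meta, og = ds.gm, ds.meta, ds.outgroup
    status = polarize.polarization_status(gm.sites, og)[0]
    flip = status == polarize.ALT_ANCESTRAL
    ok = status != polarize.UNRESOLVED

    def daf(group):
        sub = meta[(meta["province"] == province) & (meta["group"] == group)]
        p = polarize.population_af(gm, sub, "province", group=group).af(province)
        return np.where(flip, 1 - p, p)

    return impact.patterson_d(daf("B")[ok], daf("T")[ok], daf("N")[ok])


def dstat_contrast(n_reps: int = 20, seed0: int = 0) -> dict:
    """|Z| under introgression (m = 0.1) vs the m = 0 control, paired over
    seed replicates."""
    z_m, z_0 = [], []
    for k in range(n_reps):
        z_m.append(dstat_trio(seed0 + k, 0.1).z)
        z_0.append(dstat_trio(seed0 + 1000 + k, 0.0).z)
    wins = sum(abs(a) > abs(b) for a, b in zip(z_m, z_0))
    return {"z_introgression": z_m, "z_control": z_0, "wins": int(wins),
            "n_reps": n_reps}


def group_orderings(seed: int = 7, n_roh_samples: int = 10) -> dict:
    """Diversity and inbreeding orderings across wild / post-release / bred
    under the rearing-history scenario (no release-impact structure)."""
    cfg = ScenarioConfig(seed=seed, n_sites=3000, n_impact_sites=0,
                         n_clinal_sites=100, introgression_m=0.0)
    ds = simulate_arrays(cfg)
    gm, meta = ds.gm, ds.meta
    L = ds.config.chrom_length
    pi, roh_total, froh = {}, {}, {}
    for g in "NTB":
        idx = gm.sample_indices(meta[meta["group"] == g].index)
        pi[g] = float(np.nanmean(diversity.diversity_stats(gm, idx)["pi"]))
        summ = diversity.roh_summary(gm, idx[:n_roh_samples], genome_length=L)
        roh_total[g] = float(summ["total_length"].mean())
        froh[g] = float(summ["f_roh"].mean())
    return {"pi": pi, "roh_total": roh_total, "f_roh": froh}
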