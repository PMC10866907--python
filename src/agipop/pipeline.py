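"""End-to-end orchestration of the analysis stages.

Stage order: io -> polarize -> {geoscan, ld, diversity, impact, dstat}.
Each run writes its tables into a fresh output directory together with a
manifest (config echo, seed, input checksums, per-stage row counts) so a
rerun with the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core_io, diversity, geoscan, impact, ld, polarize

log = logging.getLogger(__name__)

STAGE_ORDER = ["io", "polarize", "geoscan", "ld", "diversity", "impact", "dstat"]
STAGE_DEPS = {
    "io": [],
    "polarize": ["io"],
    "geoscan": ["io", "polarize"],
    "ld": ["io"],
    "diversity": ["io"],
    "impact": ["io", "polarize"],
    "dstat": ["io", "polarize"],
}


@dataclass
class PipelineConfig:
    """Paths, thresholds and sizes for a pipeline run.

    Threshold defaults are the analysis standards used throughout:
    affected-site dAF >= 0.05, FDR alpha 0.05, |rho| region threshold 0.8,
    sweep quantile 0.05 (top 5%), province minimum 9 per group, B = 1000
    randomization trials, 10 kb windows with 5 kb step.
    """

    vcf: str = ""
    samples: str = ""
    climate: str = ""
    outgroup: str = ""
    out_dir: str = "agipop_out"
    func_class_source: str = "ANN-field"
    ancestral_label: str = "prov0"
    features: list = field(default_factory=lambda: ["Long", "Lati"])
    max_missing_rate: float = 0.15
    min_maf: float = 0.05
    delta: float = 0.05
    alpha: float = 0.05
    rho_threshold: float = 0.8
    rho_merge_gap: int = 1_000_000
    sweep_quantile: float = 0.05
    min_n: int = 9
    min_pops: int = 5
    window: int = 10_000
    step: int = 5_000
    B: int = 1000
    seed: int = 0
    genome_length: float | None = None
    xpclr_windows: str | None = None  # optional externally computed scores TSV

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _resolve_stages(stages):
    if stages is None:
        wanted = set(STAGE_ORDER)
    else:
        wanted = set(stages)
        unknown = wanted - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for s in list(wanted):
            missing = [dep for dep in STAGE_DEPS[s] if dep not in wanted]
            if missing:
                raise ValueError(
                    f"stage {s!r} requires upstream stage(s) {missing} which are not selected"
                )
    return [s for s in STAGE_ORDER if s in wanted]


def run_pipeline(cfg: PipelineConfig, stages=None) -> dict:
    """Run the selected stages and write outputs plus a manifest.

    Returns a dict of in-memory stage results keyed by stage name.
    """
    order = _resolve_stages(stages)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    manifest = {
        "seed": cfg.seed,
        "stages": order,
        "inputs": {},
        "row_counts": {},
    }
    for key in ("vcf", "samples", "climate", "outgroup"):
        p = getattr(cfg, key)
        if p:
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}
    results: dict = {}

    # ---- io -------------------------------------------------------------
    gm = core_io.read_vcf(cfg.vcf, cfg.func_class_source)
    meta, climate, outgroup = core_io.read_metadata(cfg.samples, cfg.climate, cfg.outgroup)
    core_io.check_samples_covered(gm, meta)
    gm = core_io.apply_site_filters(gm, cfg.max_missing_rate, cfg.min_maf)
    results["io"] = {"gm": gm, "meta": meta, "climate": climate, "outgroup": outgroup}
    manifest["row_counts"]["io"] = {"sites": gm.n_sites, "samples": gm.n_samples,
                                    "filter_report": gm.filter_report}

    if "polarize" in order:
        city_af = polarize.population_af(gm, meta, "city", group="N")
        pol = polarize.polarize(city_af, gm.sites, outgroup)
        anc = polarize.ancestral_af(gm, meta, outgroup, cfg.ancestral_label)
        pol.to_frame().to_csv(out / "polarized_af.tsv", sep="\t", index=False)
        results["polarize"] = {"city_af": city_af, "polarized": pol, "ancestral": anc}
        manifest["row_counts"]["polarize"] = {
            "sites": len(pol.site_keys),
            "resolved": int(pol.resolved.sum()),
        }

    if "geoscan" in order:
        pol = results["polarize"]["polarized"]
        daf = pd.DataFrame(pol.daf)
        scan = geoscan.spearman_scan(daf, climate, cfg.features, cfg.min_pops)
        scan.to_csv(out / "geoscan.tsv", sep="\t", index=False)
        regions = geoscan.rho_profile_and_merge(scan, gm.sites, cfg.rho_threshold,
                                                cfg.rho_merge_gap)
        regions.to_csv(out / "rho_regions.bed", sep="\t", index=False, header=False)
        ratios = geoscan.ns_ratio_by_rho(
            scan[scan["feature"] == cfg.features[0]], gm.func_classes()
        )
        ratios.to_csv(out / "ns_ratio_by_rho.tsv", sep="\t", index=False)
        results["geoscan"] = {"scan": scan, "regions": regions, "ns_by_rho": ratios}
        manifest["row_counts"]["geoscan"] = {
            "tests": len(scan),
            "significant": int((scan["q"] < cfg.alpha).sum()),
            "regions": len(regions),
        }

    wild_idx = gm.sample_indices([s for s in gm.samples if meta.loc[s, "group"] == "N"])

    if "ld" in order:
        pairs = ld.nearest_syn_pairs(gm.sites)
        r2 = []
        for row in pairs.itertuples(index=False):
            st = ld.pair_ld(gm, int(row.nonsyn_idx), int(row.syn_idx), wild_idx)
            r2.append(st.r2 if st.defined else np.nan)
        pairs = pairs.assign(r2=r2) if len(pairs) else pairs.assign(r2=pd.Series(dtype=float))
        pairs.to_csv(out / "nearest_syn_ld.tsv", sep="\t", index=False)
        decay = {}
        for grp in "NBT":
            idx = gm.sample_indices([s for s in gm.samples if meta.loc[s, "group"] == grp])
            if idx.size >= 2:
                decay[grp] = ld.ld_decay(gm, idx, seed=cfg.seed)
        results["ld"] = {"pairs": pairs, "decay": decay}
        manifest["row_counts"]["ld"] = {
            "pairs": len(pairs),
            "half_max": {g: d.half_max_distance for g, d in decay.items()},
        }

    if "diversity" in order:
        groups = {}
        for grp in "NBT":
            idx = gm.sample_indices([s for s in gm.samples if meta.loc[s, "group"] == grp])
            if idx.size >= 2:
                groups[grp] = idx
        div = {g: diversity.diversity_stats(gm, idx) for g, idx in groups.items()}
        pair_fst = {}
        for a in groups:
            for b in groups:
                if a < b:
                    res = diversity.wc_fst(gm, {a: groups[a], b: groups[b]})
                    pair_fst[f"{a}-{b}"] = res["overall"]
        sweep = None
        if "N" in groups and "B" in groups:
            fst = diversity.wc_fst(gm, {"N": groups["N"], "B": groups["B"]})
            chroms, pos = gm.chroms(), gm.positions()
            w_fst = diversity.window_scan(chroms, pos, fst["a"],
                                          denom=fst["a"] + fst["b"] + fst["c"],
                                          window=cfg.window, step=cfg.step,
                                          clip_negative=True)
            w_pi_b = diversity.window_scan(chroms, pos, div["B"]["pi"].to_numpy(),
                                           window=cfg.window, step=cfg.step)
            w_pi_n = diversity.window_scan(chroms, pos, div["N"]["pi"].to_numpy(),
                                           window=cfg.window, step=cfg.step)
            w_ratio = diversity.log2_pi_ratio(w_pi_b, w_pi_n)
            stat_windows = {"fst": w_fst, "log2_pi_ratio": w_ratio}
            if cfg.xpclr_windows:
                xp = pd.read_csv(cfg.xpclr_windows, sep="\t")
                stat_windows["xpclr"] = xp
            selected, regions = diversity.sweep_intersect(stat_windows, cfg.sweep_quantile)
            w_fst.to_csv(out / "windows_fst.tsv", sep="\t", index=False)
            w_ratio.to_csv(out / "windows_log2_pi_ratio.tsv", sep="\t", index=False)
            regions.to_csv(out / "sweep_regions.bed", sep="\t", index=False, header=False)
            sweep = {"selected": selected, "regions": regions}
        roh = diversity.roh_summary(gm, np.arange(gm.n_samples),
                                    genome_length=cfg.genome_length)
        roh.to_csv(out / "roh_summary.tsv", sep="\t", index=False)
        results["diversity"] = {"pi": div, "pairwise_fst": pair_fst,
                                "sweep": sweep, "roh": roh}
        manifest["row_counts"]["diversity"] = {
            "pairwise_fst": pair_fst,
            "sweep_regions": 0 if sweep is None else len(sweep["regions"]),
            "roh_samples": len(roh),
        }

    if "impact" in order or "dstat" in order:
        anc = results["polarize"]["ancestral"]
        provinces = impact.select_provinces(meta, cfg.min_n)
        provinces = [p for p in provinces if p != cfg.ancestral_label]
        results["impact"] = {"provinces": provinces, "per_province": {}}
        results["dstat"] = {"per_province": {}}
        status = results["polarize"]["polarized"].status
        flip = status == polarize.ALT_ANCESTRAL
        func = gm.func_classes()
        for prov in provinces:
            prov_af = polarize.population_af(gm, meta[meta["province"] == prov],
                                             "province", group="N")
            if prov not in prov_af.alt_count:
                continue
            alt_n = prov_af.alt_count[prov]
            tot_n = prov_af.called_total[prov]
            der_n = np.where(flip, tot_n - alt_n, alt_n)
            cand = (
                anc["af_a_zero"].to_numpy()
                & (tot_n > 0)
                & (der_n > 0)
            )
            idx = np.flatnonzero(cand)
            if "impact" in order:
                cls = impact.classify_affected(
                    der_n[idx], tot_n[idx],
                    anc["derived_count"].to_numpy()[idx],
                    anc["called_total"].to_numpy()[idx],
                    cfg.delta, cfg.alpha,
                )
                cls["site"] = idx[cls["site"].to_numpy()]
                test = impact.randomization_null(cls, func, cfg.B, cfg.seed)
                cls.to_csv(out / f"affected_sites_{prov}.tsv", sep="\t", index=False)
                results["impact"]["per_province"][prov] = {"classified": cls, "test": test}
            if "dstat" in order:
                pol = results["polarize"]["polarized"]
                sub = meta[meta["province"] == prov]
                daf_parts = {}
                for grp, lbl in (("B", "p1"), ("T", "p2"), ("N", "p3")):
                    gaf = polarize.population_af(gm, sub[sub["group"] == grp],
                                                 "province", group=grp)
                    pafv = gaf.af(prov) if prov in gaf.alt_count else None
                    if pafv is None:
                        break
                    daf_parts[lbl] = np.where(flip, 1 - pafv, pafv)
                else:
                    dres = {}
                    for snp_class in ("missense", "synonymous", "all"):
                        dres[snp_class] = impact.patterson_d(
                            daf_parts["p1"], daf_parts["p2"], daf_parts["p3"],
                            func_class=func, snp_class=snp_class,
                        )
                    results["dstat"]["per_province"][prov] = dres
        if "impact" in order:
            summary = []
            for prov, r in results["impact"]["per_province"].items():
                for cls in (impact.STRONG, impact.WEAK):
                    summary.append({
                        "province": prov, "class": cls,
                        "observed_ratio": r["test"].observed[cls],
                        "null_mean": float(np.nanmean(r["test"].null[cls])),
                        "p": r["test"].p[cls], "p_label": r["test"].p_label[cls],
                        "B": cfg.B, "seed": cfg.seed,
                    })
            pd.DataFrame(summary).to_csv(out / "impact_summary.tsv", sep="\t", index=False)
            manifest["row_counts"]["impact"] = {"provinces": provinces}
        if "dstat" in order:
            rows = []
            for prov, dres in results["dstat"]["per_province"].items():
                for snp_class, d in dres.items():
                    rows.append({"province": prov, "snp_class": snp_class,
                                 "D": d.D, "se": d.se, "z": d.z,
                                 "n_blocks": d.n_blocks})
            pd.DataFrame(rows).to_csv(out / "dstat.tsv", sep="\t", index=False)
            manifest["row_counts"]["dstat"] = {"trios": len(rows)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    results["manifest"] = manifest
    return results
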