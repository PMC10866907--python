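"""Synthetic genotype/metadata generator with known ground truth.

Emulates the sampling design the analyses assume: multiple cities with
coordinates, three groups per province (wild N, captive-bred B, post-release
T), synonymous/nonsynonymous site labels, clinal allele-frequency structure
along geography, a low-frequency skew at nonsynonymous sites, an ancestral
wild province whose alleles agree with the outgroup, and bred-to-wild
admixture.  Sites are independent (binomial sampling from population allele
frequencies); a dedicated two-locus haplotype sampler covers linkage
statistics, and explicit autozygous tracts in bred/post-release individuals
produce detectable runs of homozygosity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import GenotypeMatrix, SiteRecord, write_vcf

_BASES = np.array(list("ACGT"))


def cline_af(x, s: float, x0: float):
    """Logistic allele-frequency cline along a coordinate.

    ``1 / (1 + exp(-s * (x - x0)))``: 0.5 at the cline centre ``x0``,
    approaching 0/1 away from it at rate ``s`` (per degree).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("slope must be finite")
    out = 1.0 / (1.0 + np.exp(-s * (x - x0)))
    return float(out) if out.ndim == 0 else out


@dataclass
class ScenarioConfig:
    """Full parameterisation of a synthetic study.

    Defaults describe a desk-scale analogue of the field design: wild
    populations sampled across a longitude/latitude gradient, with bred and
    post-release groups in every non-ancestral province, drifted bred pools,
    clinal sites, purifying constraint on nonsynonymous sites, and
    bred-to-wild introgression at sites absent from the ancestral province.
    """

    seed: int = 0
    n_cities: int = 8
    cities_per_province: int = 2
    # longitude/latitude sampling window (degrees); roughly the natural range
    lon_range: tuple = (97.0, 127.0)
    lat_range: tuple = (21.0, 47.0)
    city_coords: list | None = None  # optional [(lon, lat), ...]
    n_wild_per_city: int = 15
    # wild sample size in ancestral-province cities (None = n_wild_per_city)
    ancestral_n_wild_per_city: int | None = None
    n_bred_per_province: int = 10
    n_post_per_province: int = 10
    n_sites: int = 5000
    frac_nonsyn: float = 0.3
    n_clinal_sites: int = 200
    cline_slope: float = 0.3
    cline_center: float = 112.0
    cline_center_jitter: float = 10.0  # per-site centre ~ U(x0 +- jitter)
    # derived AF at constrained sites ~ Beta(1, beta); None disables the
    # low-frequency skew (annotations then independent of AF)
    nonsyn_beta: float | None = 9.0
    n_impact_sites: int = 800  # sites absent from the ancestral province
    ancestral_label: str = "prov0"
    introgression_m: float = 0.1
    nonsyn_sel: float = 0.3  # nonsyn introgressed AF multiplier (1 = neutral)
    wild_drift: float = 0.02  # Balding-Nichols F of city pools around baseline
    bred_drift: float = 0.2
    post_drift: float = 0.3  # extra drift of the released pool beyond bred
    post_admix: float = 0.4  # wild fraction in the post-release pool
    sweep_region: tuple | None = None  # (start_bp, end_bp) swept in the wild
    roh_fraction: dict = field(
        default_factory=lambda: {"N": 0.02, "T": 0.15, "B": 0.30}
    )
    roh_mean_len: int = 100_000
    chrom: str = "LG01"
    snp_spacing: int = 200
    outgroup_alt_frac: float = 0.3  # non-impact sites where ALT is ancestral
    outgroup_mismatch_frac: float = 0.02  # outgroup matches neither allele
    outgroup_missing_frac: float = 0.02

    def __post_init__(self):
        if self.n_clinal_sites + self.n_impact_sites > self.n_sites:
            raise ValueError("n_clinal_sites + n_impact_sites exceeds n_sites")
        for name in ("introgression_m", "frac_nonsyn", "post_admix"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.n_wild_per_city, self.n_bred_per_province,
               self.n_post_per_province) < 0:
            raise ValueError("sample counts must be >= 0")

    @property
    def chrom_length(self) -> int:
        return self.n_sites * self.snp_spacing + self.snp_spacing

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Per-site truth flags and the population AFs genotypes were drawn from."""

    is_clinal: np.ndarray
    is_constrained: np.ndarray
    is_introgressed: np.ndarray
    func_class: np.ndarray
    pop_af: dict  # population id -> per-site AF actually sampled from
    city_province: dict  # city -> province
    autozygous_spans: dict  # sample id -> list of (start0, end0) bp spans


def _balding_nichols(rng, p, F):
    """Population AF drawn around baseline ``p`` with drift intensity ``F``."""
    if F <= 0:
        return p.copy()
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    out = np.where((p <= 0) | (p >= 1), p, rng.beta(np.maximum(a, 1e-9), np.maximum(b, 1e-9)))
    return out


def _draw_autozygous_spans(rng, target_frac, chrom_length, mean_len):
    """Autozygous tracts totalling ~``target_frac`` of the chromosome; the
    last tract is truncated so the total does not overshoot."""
    target = target_frac * chrom_length
    spans = []
    covered = 0.0
    while covered < target:
        length = min(int(rng.exponential(mean_len)) + 1, int(target - covered) + 1)
        start = int(rng.integers(0, max(chrom_length - length, 1)))
        spans.append((start, start + length))
        covered += length
    return spans


class SyntheticDataset:
    """In-memory result of :func:`simulate_arrays`."""

    def __init__(self, gm, meta, climate, outgroup, truth, config):
        self.gm: GenotypeMatrix = gm
        self.meta: pd.DataFrame = meta
        self.climate: pd.DataFrame = climate
        self.outgroup: dict = outgroup
        self.truth: GroundTruth = truth
        self.config: ScenarioConfig = config


def simulate_arrays(cfg: ScenarioConfig) -> SyntheticDataset:
    """Simulate one study in memory (no files written).

    Genotypes are drawn as two Bernoulli haplotypes per individual from the
    individual's population AF, so the resulting matrix is phased.  Bred and
    post-release individuals additionally carry autozygous tracts in which
    the second haplotype copies the first.
    """
    rng = np.random.default_rng(cfg.seed)
    n_sites = cfg.n_sites

    # --- geography -------------------------------------------------------
    if cfg.city_coords is not None:
        coords = np.asarray(cfg.city_coords, dtype=float)
        if len(coords) != cfg.n_cities:
            raise ValueError("city_coords length != n_cities")
    else:
        lon = rng.uniform(*cfg.lon_range, cfg.n_cities)
        lat = rng.uniform(*cfg.lat_range, cfg.n_cities)
        coords = np.column_stack([lon, lat])
    cities = [f"city{i:02d}" for i in range(cfg.n_cities)]
    n_prov = int(np.ceil(cfg.n_cities / cfg.cities_per_province))
    provinces = [f"prov{i}" for i in range(n_prov)]
    city_province = {
        cities[i]: provinces[i // cfg.cities_per_province] for i in range(cfg.n_cities)
    }
    if cfg.ancestral_label not in provinces:
        raise ValueError(f"ancestral label {cfg.ancestral_label} not among {provinces}")

    # --- site classes and truth flags ------------------------------------
    func = np.where(rng.random(n_sites) < cfg.frac_nonsyn, "nonsynonymous", "synonymous")
    func = func.astype(object)
    other = rng.random(n_sites) < 0.05
    func[other] = "other"
    perm = rng.permutation(n_sites)
    impact_idx = perm[: cfg.n_impact_sites]
    clinal_idx = perm[cfg.n_impact_sites : cfg.n_impact_sites + cfg.n_clinal_sites]
    is_impact = np.zeros(n_sites, bool)
    is_impact[impact_idx] = True
    is_clinal = np.zeros(n_sites, bool)
    is_clinal[clinal_idx] = True
    is_constrained = (func == "nonsynonymous") & ~is_clinal
    if cfg.nonsyn_beta is None:
        is_constrained[:] = False

    # --- baseline derived AFs --------------------------------------------
    baseline = rng.uniform(0.05, 0.95, n_sites)
    con = is_constrained
    if cfg.nonsyn_beta is not None:
        baseline[con] = rng.beta(1.0, cfg.nonsyn_beta, int(con.sum()))
    baseline[is_impact] = 0.0

    # per-city wild AFs
    wild_af = np.empty((n_sites, cfg.n_cities))
    for c in range(cfg.n_cities):
        wild_af[:, c] = _balding_nichols(rng, baseline, cfg.wild_drift)
    # clinal override: logistic in longitude with per-site centre and sign
    x0 = rng.uniform(
        cfg.cline_center - cfg.cline_center_jitter,
        cfg.cline_center + cfg.cline_center_jitter,
        cfg.n_clinal_sites,
    )
    sgn = rng.choice([-1.0, 1.0], cfg.n_clinal_sites)
    for k, i in enumerate(clinal_idx):
        wild_af[i] = cline_af(coords[:, 0], sgn[k] * cfg.cline_slope, x0[k])

    positions = (np.arange(n_sites) + 1) * cfg.snp_spacing

    # implanted selective sweep in the wild: derived allele nearly lost in
    # every wild population inside the region (low wild diversity there,
    # strong wild-vs-bred differentiation)
    if cfg.sweep_region is not None:
        lo, hi = cfg.sweep_region
        in_sweep = (positions >= lo) & (positions < hi)
        wild_af[in_sweep] = 0.02

    # bred pool: drifted from baseline; carries derived alleles at impact
    # sites.  The released pool descends from it with extra drift.
    bred_af = _balding_nichols(rng, baseline, cfg.bred_drift)
    bred_af[impact_idx] = rng.uniform(0.05, 0.8, cfg.n_impact_sites)
    release_af = _balding_nichols(rng, bred_af, cfg.post_drift)

    # introgression released -> wild in non-ancestral provinces; purifying
    # selection damps the nonsynonymous share of the introgressed alleles
    sel = np.where(func == "nonsynonymous", cfg.nonsyn_sel, 1.0)
    ancestral_cities = [c for c in range(cfg.n_cities)
                        if city_province[cities[c]] == cfg.ancestral_label]
    m = cfg.introgression_m
    eff_m = m * sel
    for c in range(cfg.n_cities):
        if c in ancestral_cities:
            continue
        wild_af[:, c] = (1 - eff_m) * wild_af[:, c] + eff_m * release_af
    is_introgressed = is_impact & (m > 0)

    # post-release group per city: the released pool admixed with local wild
    post_af = (1 - cfg.post_admix) * release_af[:, None] + cfg.post_admix * wild_af

    # --- alleles and outgroup --------------------------------------------
    ref = rng.choice(_BASES, n_sites)
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    # at a fraction of non-impact sites the ALT allele is ancestral: the VCF
    # alt-AF there is 1 - derived AF and the outgroup carries ALT
    alt_ancestral = (rng.random(n_sites) < cfg.outgroup_alt_frac) & ~is_impact
    out_allele = np.where(alt_ancestral, alt, ref).astype(object)
    mism = rng.random(n_sites) < cfg.outgroup_mismatch_frac
    mism &= ~is_impact
    for i in np.flatnonzero(mism):
        out_allele[i] = rng.choice([b for b in "ACGT" if b not in (ref[i], alt[i])])
    og_missing = (rng.random(n_sites) < cfg.outgroup_missing_frac) & ~is_impact

    def to_alt_scale(daf):
        return np.where(alt_ancestral, 1.0 - daf, daf)

    # --- samples ----------------------------------------------------------
    sample_rows = []
    pop_af_cols = []  # per-sample AF column (alt-allele scale)
    pop_af = {}
    for c, city in enumerate(cities):
        af_alt = to_alt_scale(wild_af[:, c])
        pop_af[f"N:{city}"] = af_alt
        n_wild = cfg.n_wild_per_city
        if (cfg.ancestral_n_wild_per_city is not None
                and city_province[city] == cfg.ancestral_label):
            n_wild = cfg.ancestral_n_wild_per_city
        for j in range(n_wild):
            sample_rows.append((f"N_{city}_{j:02d}", "N", city_province[city], city,
                                coords[c, 0], coords[c, 1]))
            pop_af_cols.append(af_alt)
    bred_alt = to_alt_scale(bred_af)
    pop_af["B:pool"] = bred_alt
    for p, prov in enumerate(provinces):
        if prov == cfg.ancestral_label:
            continue
        prov_cities = [i for i in range(cfg.n_cities) if city_province[cities[i]] == prov]
        home = prov_cities[0]
        city = cities[home]
        for j in range(cfg.n_bred_per_province):
            sample_rows.append((f"B_{prov}_{j:02d}", "B", prov, city,
                                coords[home, 0], coords[home, 1]))
            pop_af_cols.append(bred_alt)
        post_alt = to_alt_scale(post_af[:, home])
        pop_af[f"T:{prov}"] = post_alt
        for j in range(cfg.n_post_per_province):
            sample_rows.append((f"T_{prov}_{j:02d}", "T", prov, city,
                                coords[home, 0], coords[home, 1]))
            pop_af_cols.append(post_alt)

    meta = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "group", "province", "city", "longitude", "latitude"],
    )
    meta["host_plant"] = "Nicotiana"
    meta["kin_excluded"] = False
    n_samples = len(meta)

    # --- genotypes: two Bernoulli haplotypes per individual ---------------
    af_matrix = np.column_stack(pop_af_cols)  # sites x samples
    hap1 = (rng.random((n_sites, n_samples)) < af_matrix).astype(np.int8)
    hap2 = (rng.random((n_sites, n_samples)) < af_matrix).astype(np.int8)

    # autozygous tracts: second haplotype copies the first inside the spans
    autozygous_spans = {}
    for s_idx, row in enumerate(meta.itertuples(index=False)):
        frac = cfg.roh_fraction.get(row.group, 0.0)
        if frac <= 0:
            autozygous_spans[row.sample_id] = []
            continue
        spans = _draw_autozygous_spans(rng, frac, cfg.chrom_length, cfg.roh_mean_len)
        autozygous_spans[row.sample_id] = spans
        for start, end in spans:
            in_span = (positions >= start) & (positions < end)
            hap2[in_span, s_idx] = hap1[in_span, s_idx]

    haplotypes = np.empty((n_sites, 2 * n_samples), dtype=np.int8)
    haplotypes[:, 0::2] = hap1
    haplotypes[:, 1::2] = hap2
    codes = (hap1 + hap2).astype(np.int8)

    sites = [
        SiteRecord(cfg.chrom, int(positions[i]), str(ref[i]), str(alt[i]), str(func[i]))
        for i in range(n_sites)
    ]
    gm = GenotypeMatrix(sites=sites, samples=list(meta["sample_id"]),
                        codes=codes, haplotypes=haplotypes)

    # --- climate: affine in coordinates plus noise ------------------------
    clim = {"city": cities, "Long": coords[:, 0], "Lati": coords[:, 1]}
    for k in range(1, 20):
        a, b = rng.normal(0, 1, 2)
        noise = rng.normal(0, 0.5, cfg.n_cities)
        clim[f"Bio{k}"] = a * coords[:, 0] + b * coords[:, 1] + noise
    climate = pd.DataFrame(clim).set_index("city")

    outgroup = {
        (cfg.chrom, int(positions[i])): str(out_allele[i])
        for i in range(n_sites)
        if not og_missing[i]
    }

    truth = GroundTruth(
        is_clinal=is_clinal,
        is_constrained=is_constrained,
        is_introgressed=is_introgressed,
        func_class=np.asarray(func, dtype=object),
        pop_af=pop_af,
        city_province=city_province,
        autozygous_spans=autozygous_spans,
    )
    return SyntheticDataset(gm, meta.set_index("sample_id"), climate, outgroup, truth, cfg)


def simulate_dataset(cfg: ScenarioConfig, out_dir):
    """Simulate a study and write the four input files core_io reads.

    Returns ``(paths, truth)`` where paths is a dict with keys
    ``vcf``, ``samples``, ``climate``, ``outgroup``.
    """
    ds = simulate_arrays(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "variants.vcf",
        "samples": out / "samples.tsv",
        "climate": out / "climate.tsv",
        "outgroup": out / "outgroup.tsv",
    }
    write_vcf(ds.gm, paths["vcf"])
    ds.meta.reset_index().to_csv(paths["samples"], sep="\t", index=False)
    ds.climate.reset_index().to_csv(paths["climate"], sep="\t", index=False)
    og = pd.DataFrame(
        [(c, p, a) for (c, p), a in sorted(ds.outgroup.items())],
        columns=["chrom", "pos", "allele"],
    )
    og.to_csv(paths["outgroup"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}, ds.truth


def sample_two_locus_haplotypes(g, n_diploids, seed=0, positions=(1000, 2000),
                                chrom="LG01"):
    """Draw phased diploids from explicit two-locus haplotype frequencies.

    ``g = (g11, g10, g01, g00)`` are the frequencies of haplotypes AB, Ab,
    aB, ab (1 = alt allele).  ``2 * n_diploids`` haplotypes are drawn
    multinomially and paired at random into individuals; returns a phased
    two-site :class:`GenotypeMatrix`.
    """
    g = np.asarray(g, dtype=float)
    if g.shape != (4,) or abs(g.sum() - 1) > 1e-9 or (g < 0).any():
        raise ValueError("g must be 4 non-negative frequencies summing to 1")
    rng = np.random.default_rng(seed)
    # haplotype alleles at (site_a, site_b): AB=(1,1), Ab=(1,0), aB=(0,1), ab=(0,0)
    alleles = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.int8)
    draws = rng.choice(4, size=2 * n_diploids, p=g)
    rng.shuffle(draws)
    haps = alleles[draws]  # (2n, 2 sites)
    haplotypes = haps.T.copy()  # (2 sites, 2n)
    codes = haplotypes[:, 0::2] + haplotypes[:, 1::2]
    sites = [
        SiteRecord(chrom, positions[0], "A", "G", "nonsynonymous"),
        SiteRecord(chrom, positions[1], "C", "T", "synonymous"),
    ]
    samples = [f"s{i:03d}" for i in range(n_diploids)]
    return GenotypeMatrix(sites=sites, samples=samples,
                         codes=codes.astype(np.int8), haplotypes=haplotypes)
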