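"""Domain types and readers/writers shared by every analysis stage.

The in-memory data model is deliberately small: a :class:`GenotypeMatrix`
(sites x samples alt-allele dosage codes, with optional phased haplotypes),
pandas tables for sample metadata and per-city climate features, and a dict
for outgroup alleles.  VCF coordinates are 1-based; all internal window
arithmetic is half-open 0-based and converted only at I/O boundaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

MISSING = -1  # genotype code for uncalled

FUNC_CLASSES = ("synonymous", "nonsynonymous", "other")

#: SnpEff effect terms mapped onto the site classes used throughout.
_ANN_EFFECT_MAP = {
    "missense_variant": "nonsynonymous",
    "synonymous_variant": "synonymous",
}

VALID_GROUPS = ("N", "B", "T")


@dataclass(frozen=True)
class SiteRecord:
    """A biallelic SNP with its functional class.

    ``func_class`` is one of ``synonymous``, ``nonsynonymous`` or ``other``
    (the default when no annotation is available).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    func_class: str = "other"
    gene_id: str | None = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"not a SNP at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.func_class not in FUNC_CLASSES:
            raise ValueError(f"unknown func_class {self.func_class!r}")


@dataclass
class GenotypeMatrix:
    """Sites x samples diploid alt-allele dosages.

    ``codes[i, j]`` counts alt alleles of sample ``j`` at site ``i``
    (0, 1, 2, or :data:`MISSING`).  When the source VCF was phased,
    ``haplotypes`` holds the per-haplotype alleles as a
    ``(n_sites, 2 * n_samples)`` array (columns ``2j`` and ``2j+1`` are the
    two haplotypes of sample ``j``), again with :data:`MISSING` for uncalled.
    """

    sites: list[SiteRecord]
    samples: list[str]
    codes: np.ndarray
    haplotypes: np.ndarray | None = None
    filter_report: dict = field(default_factory=dict)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, missing}")
        keys = [(s.chrom, s.pos) for s in self.sites]
        if keys != sorted(keys):
            raise ValueError("sites must be sorted by (chrom, pos)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def phased(self) -> bool:
        return self.haplotypes is not None

    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.sites])

    def func_classes(self) -> np.ndarray:
        return np.array([s.func_class for s in self.sites])

    def sample_indices(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in sample_ids], dtype=np.intp)

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sites=[self.sites[i] for i in idx],
            samples=list(self.samples),
            codes=self.codes[idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[idx],
        )


def _parse_ann_class(ann: str | None) -> str:
    """Functional class from the FIRST ANN effect only (multi-transcript
    annotations are not collapsed; the first entry wins)."""
    if not ann:
        return "other"
    first = ann.split(",")[0]
    fields = first.split("|")
    effect = fields[1] if len(fields) > 1 else ""
    for eff in effect.split("&"):
        if eff in _ANN_EFFECT_MAP:
            return _ANN_EFFECT_MAP[eff]
    return "other"


def read_sites_tsv(path) -> dict[tuple[str, int], tuple[str, str | None]]:
    """Read a sites TSV (chrom, pos, func_class, gene_id) into a lookup."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = {}
    for row in df.itertuples(index=False):
        fc = str(row.func_class)
        if fc not in FUNC_CLASSES:
            warnings.warn(f"unknown func_class {fc!r} at {row.chrom}:{row.pos}; using 'other'")
            fc = "other"
        gene = getattr(row, "gene_id", None)
        gene = None if gene is None or pd.isna(gene) else str(gene)
        out[(str(row.chrom), int(row.pos))] = (fc, gene)
    return out


def read_vcf(path, func_class_source: str = "ANN-field") -> GenotypeMatrix:
    """Read a VCF 4.x into a :class:`GenotypeMatrix`.

    Only biallelic SNP rows are kept; multiallelic and indel rows are skipped
    and counted in ``filter_report["skipped_non_biallelic_snp"]``.

    Parameters
    ----------
    path : str
        VCF path (plain or bgzipped).
    func_class_source : str
        ``"ANN-field"`` to parse the first SnpEff ANN effect, otherwise a
        path to a sites TSV with columns chrom, pos, func_class, gene_id.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path} contains no samples")

    tsv_lookup = None
    if func_class_source != "ANN-field":
        tsv_lookup = read_sites_tsv(func_class_source)

    sites: list[SiteRecord] = []
    codes_rows = []
    hap_rows = []
    skipped = 0
    all_phased = True
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped += 1
            continue
        if v.ALT[0] not in "ACGT" or v.REF not in "ACGT":
            skipped += 1
            continue
        if tsv_lookup is not None:
            fc, gene = tsv_lookup.get((v.CHROM, v.POS), ("other", None))
        else:
            fc = _parse_ann_class(v.INFO.get("ANN"))
            gene = None
        sites.append(SiteRecord(v.CHROM, v.POS, v.REF, v.ALT[0], fc, gene))
        g = v.genotype.array()  # (n_samples, 3): allele1, allele2, phased
        a1, a2, ph = g[:, 0], g[:, 1], g[:, 2]
        miss = (a1 < 0) | (a2 < 0)
        row = np.where(miss, MISSING, a1 + a2).astype(np.int8)
        codes_rows.append(row)
        if all_phased and not np.all((ph == 1) | miss):
            all_phased = False
        hap = np.empty(2 * len(samples), dtype=np.int8)
        hap[0::2] = np.where(a1 < 0, MISSING, a1)
        hap[1::2] = np.where(a2 < 0, MISSING, a2)
        hap_rows.append(hap)

    if skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNP rows", skipped)
    codes = (
        np.array(codes_rows, dtype=np.int8)
        if codes_rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    haps = np.array(hap_rows, dtype=np.int8) if (all_phased and hap_rows) else None
    order = sorted(range(len(sites)), key=lambda i: (sites[i].chrom, sites[i].pos))
    gm = GenotypeMatrix(
        sites=[sites[i] for i in order],
        samples=samples,
        codes=codes[order] if len(sites) else codes,
        haplotypes=haps[order] if haps is not None and len(sites) else haps,
    )
    gm.filter_report["skipped_non_biallelic_snp"] = skipped
    return gm


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as a plain-text VCF 4.2 with ANN functional
    annotations, phased if haplotypes are present."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chrom for s in gm.sites):
            maxpos = max(s.pos for s in gm.sites if s.chrom == chrom)
            fh.write(f"##contig=<ID={chrom},length={maxpos + 1000}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        eff_rev = {"nonsynonymous": "missense_variant", "synonymous": "synonymous_variant"}
        sep = "|" if gm.phased else "/"
        for i, s in enumerate(gm.sites):
            if s.func_class in eff_rev:
                gene = s.gene_id or "."
                info = f"ANN={s.alt}|{eff_rev[s.func_class]}|MODERATE|{gene}"
            else:
                info = "."
            if gm.phased:
                h = gm.haplotypes[i]
                gts = [
                    "./."
                    if h[2 * j] == MISSING or h[2 * j + 1] == MISSING
                    else f"{h[2 * j]}{sep}{h[2 * j + 1]}"
                    for j in range(gm.n_samples)
                ]
            else:
                conv = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                gts = [conv[int(c)] for c in gm.codes[i]]
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def apply_site_filters(
    gm: GenotypeMatrix,
    max_missing_rate: float = 0.15,
    min_maf: float = 0.05,
    depth_table: pd.DataFrame | None = None,
    min_mean_depth: float = 10.0,
) -> GenotypeMatrix:
    """Restrict to sites passing missingness, minor-allele-frequency and
    (optionally) mean-depth thresholds.

    The standard resequencing filter set: per-site missing rate <=
    ``max_missing_rate``, MAF >= ``min_maf``, and mean depth >=
    ``min_mean_depth`` when a depth table (columns chrom, pos, mean_depth)
    is supplied.  A report of per-rule removal counts is attached to the
    returned matrix.
    """
    if min_maf >= 0.5:
        raise ValueError("min_maf >= 0.5 is ill-posed")
    if not (0 <= max_missing_rate <= 1):
        raise ValueError("max_missing_rate must be in [0, 1]")

    codes = gm.codes
    miss = codes == MISSING
    miss_rate = miss.mean(axis=1)
    called = (~miss).sum(axis=1) * 2
    alt = np.where(miss, 0, codes).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
    maf = np.minimum(af, 1 - af)

    pass_miss = miss_rate <= max_missing_rate
    pass_maf = ~np.isnan(maf) & (maf >= min_maf)
    report = {
        "fail_missing": int((~pass_miss).sum()),
        "fail_maf": int((pass_miss & ~pass_maf).sum()),
    }
    keep = pass_miss & pass_maf
    if depth_table is not None:
        dt = depth_table.set_index(["chrom", "pos"])["mean_depth"]
        depths = np.array(
            [dt.get((s.chrom, s.pos), np.nan) for s in gm.sites], dtype=float
        )
        pass_depth = ~np.isnan(depths) & (depths >= min_mean_depth)
        report["fail_depth"] = int((keep & ~pass_depth).sum())
        keep &= pass_depth
    else:
        log.warning("no depth table supplied; depth filter skipped")

    out = gm.take_sites(keep)
    report["input_sites"] = gm.n_sites
    report["output_sites"] = out.n_sites
    out.filter_report = report
    return out


def read_metadata(samples_path, climate_path, outgroup_path):
    """Read the three metadata tables and cross-validate them.

    Returns ``(sample_meta, climate, outgroup)``:
    sample_meta — DataFrame indexed by sample_id with group/province/city/
    coordinates/host_plant/kin_excluded; climate — DataFrame indexed by city
    (columns Long, Lati, Bio1..Bio19); outgroup — dict mapping (chrom, pos)
    to the outgroup allele (missing sites and 'N' alleles are absent).
    """
    meta = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "group", "province", "city", "longitude", "latitude"}
    if not required.issubset(meta.columns):
        raise ValueError(f"samples TSV missing columns {required - set(meta.columns)}")
    bad_groups = set(meta["group"]) - set(VALID_GROUPS)
    if bad_groups:
        raise ValueError(f"unknown groups {bad_groups}; expected one of {VALID_GROUPS}")
    if not np.isfinite(meta[["longitude", "latitude"]].to_numpy()).all():
        raise ValueError("non-finite sample coordinates")
    if "host_plant" not in meta.columns:
        meta["host_plant"] = None
    if "kin_excluded" not in meta.columns:
        meta["kin_excluded"] = False
    meta["kin_excluded"] = meta["kin_excluded"].astype(bool)
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    meta = meta.set_index("sample_id")

    climate = pd.read_csv(climate_path, sep="\t", dtype={"city": str}).set_index("city")
    if climate.columns.duplicated().any():
        raise ValueError("duplicate climate feature columns")
    missing_cities = set(meta["city"]) - set(climate.index)
    if missing_cities:
        warnings.warn(f"cities absent from climate table: {sorted(missing_cities)}")

    og_df = pd.read_csv(outgroup_path, sep="\t", dtype={"chrom": str})
    outgroup: dict[tuple[str, int], str] = {}
    for row in og_df.itertuples(index=False):
        allele = str(row.allele).upper()
        if allele in "ACGT" and len(allele) == 1:
            key = (str(row.chrom), int(row.pos))
            if key in outgroup:
                raise ValueError(f"duplicate outgroup allele for {key}")
            outgroup[key] = allele
    return meta, climate, outgroup


def check_samples_covered(gm: GenotypeMatrix, meta: pd.DataFrame) -> None:
    """Fatal if a VCF sample lacks a metadata row (prevents silent group
    misassignment)."""
    missing = set(gm.samples) - set(meta.index)
    if missing:
        raise ValueError(f"samples missing from metadata: {sorted(missing)}")
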