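"""Per-population allele frequencies and derived-allele polarization.

Alt-allele frequencies are computed per population (city, province or
group), then polarized into derived-allele frequencies (DAF) against a
single outgroup sequence: if the outgroup carries the reference allele the
alt allele is derived (DAF = AF); if it carries the alternative allele the
reference allele is derived (DAF = 1 - AF); if it matches neither, or is
missing, the ancestral state is unresolved and the site is excluded from
polarized analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

REF_ANCESTRAL = "ref_ancestral"
ALT_ANCESTRAL = "alt_ancestral"
UNRESOLVED = "unresolved"


@dataclass
class PopulationAF:
    """Per-population alt-allele counts and frequencies, aligned to sites.

    ``alt_count[pop]`` and ``called_total[pop]`` are integer arrays over
    sites; ``af`` is their ratio with NaN where no alleles were called.
    """

    site_keys: list  # [(chrom, pos), ...]
    alt_count: dict = field(default_factory=dict)
    called_total: dict = field(default_factory=dict)

    @property
    def populations(self) -> list:
        return list(self.alt_count)

    def af(self, pop) -> np.ndarray:
        alt = self.alt_count[pop].astype(float)
        tot = self.called_total[pop].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / np.where(tot > 0, tot, 1), np.nan)

    def af_table(self) -> pd.DataFrame:
        return pd.DataFrame({p: self.af(p) for p in self.populations})


def population_af(
    gm: GenotypeMatrix,
    meta: pd.DataFrame,
    grouping: str = "city",
    group: str | None = None,
) -> PopulationAF:
    """Alt-allele counts per population.

    ``grouping`` is a metadata column (``city``, ``province`` or ``group``);
    ``group`` optionally restricts samples first (e.g. ``"N"`` for wild
    only, matching the per-city AF definition of the correlation scan).
    """
    if grouping not in meta.columns and grouping != meta.index.name:
        raise KeyError(f"grouping column {grouping!r} absent from metadata")
    sub = meta.loc[[s for s in gm.samples if s in meta.index]]
    if group is not None:
        sub = sub[sub["group"] == group]
    out = PopulationAF(site_keys=[(s.chrom, s.pos) for s in gm.sites])
    for pop, members in sub.groupby(grouping, sort=True).groups.items():
        idx = gm.sample_indices(members)
        if idx.size == 0:
            log.warning("population %s has no samples; omitted", pop)
            continue
        codes = gm.codes[:, idx]
        miss = codes == MISSING
        out.alt_count[pop] = np.where(miss, 0, codes).sum(axis=1).astype(np.int64)
        out.called_total[pop] = (2 * (~miss).sum(axis=1)).astype(np.int64)
    return out


@dataclass
class PolarizedAF:
    """Derived-allele frequencies per population plus polarization status."""

    site_keys: list
    status: np.ndarray  # REF_ANCESTRAL / ALT_ANCESTRAL / UNRESOLVED per site
    ancestral: np.ndarray
    derived: np.ndarray
    daf: dict  # population -> derived AF array (NaN where unresolved/missing)

    @property
    def resolved(self) -> np.ndarray:
        return self.status != UNRESOLVED

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.site_keys, columns=["chrom", "pos"])
        df["ancestral"] = self.ancestral
        df["derived"] = self.derived
        df["status"] = self.status
        for pop, v in self.daf.items():
            df[f"daf_{pop}"] = v
        return df


def polarization_status(sites, outgroup: dict):
    """Per-site polarization status and ancestral/derived alleles."""
    n = len(sites)
    status = np.full(n, UNRESOLVED, dtype=object)
    anc = np.full(n, "N", dtype=object)
    der = np.full(n, "N", dtype=object)
    for i, s in enumerate(sites):
        og = outgroup.get((s.chrom, s.pos))
        if og == s.ref:
            status[i], anc[i], der[i] = REF_ANCESTRAL, s.ref, s.alt
        elif og == s.alt:
            status[i], anc[i], der[i] = ALT_ANCESTRAL, s.alt, s.ref
    return status, anc, der


def polarize(paf: PopulationAF, sites, outgroup: dict) -> PolarizedAF:
    """Polarize alt-allele frequencies into derived-allele frequencies."""
    if len(sites) != len(paf.site_keys):
        raise ValueError("sites and PopulationAF are not aligned")
    status, anc, der = polarization_status(sites, outgroup)
    flip = status == ALT_ANCESTRAL
    unresolved = status == UNRESOLVED
    daf = {}
    for pop in paf.populations:
        af = paf.af(pop)
        d = np.where(flip, 1.0 - af, af)
        d[unresolved] = np.nan
        daf[pop] = d
    return PolarizedAF(site_keys=list(paf.site_keys), status=status,
                       ancestral=anc, derived=der, daf=daf)


def ancestral_af(
    gm: GenotypeMatrix,
    meta: pd.DataFrame,
    outgroup: dict,
    ancestral_label: str,
    level: str = "province",
) -> pd.DataFrame:
    """Ancestral-population derived-allele frequency AF_A with counts.

    Pools the wild (group N) individuals of the designated ancestral
    population(s) and counts derived vs ancestral alleles on the polarized
    scale.  ``af_a_zero`` is true iff the site is polarizable, at least one
    ancestral allele was called, and every called allele plus the outgroup
    equal the ancestral state — the site-selection condition of the
    release-impact analysis.

    Returns a DataFrame aligned to ``gm.sites`` with columns chrom, pos,
    status, derived_count, called_total, af_a, af_a_zero.
    """
    labels = [ancestral_label] if isinstance(ancestral_label, str) else list(ancestral_label)
    sel = meta[(meta["group"] == "N") & meta[level].isin(labels)]
    if sel.empty:
        raise ValueError(f"no wild samples in ancestral population(s) {labels}")
    idx = gm.sample_indices([s for s in sel.index if s in gm.samples])
    codes = gm.codes[:, idx]
    miss = codes == MISSING
    alt_count = np.where(miss, 0, codes).sum(axis=1)
    called = 2 * (~miss).sum(axis=1)

    status, anc, der = polarization_status(gm.sites, outgroup)
    flip = status == ALT_ANCESTRAL
    derived_count = np.where(flip, called - alt_count, alt_count)
    resolved = status != UNRESOLVED
    with np.errstate(invalid="ignore", divide="ignore"):
        af_a = np.where(called > 0, derived_count / np.maximum(called, 1), np.nan)
    af_a[~resolved] = np.nan
    af_a_zero = resolved & (called > 0) & (derived_count == 0)

    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in gm.sites],
            "pos": [s.pos for s in gm.sites],
            "status": status,
            "derived_count": derived_count.astype(np.int64),
            "called_total": called.astype(np.int64),
            "af_a": af_a,
            "af_a_zero": af_a_zero,
        }
    )
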