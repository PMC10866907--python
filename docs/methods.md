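# Methods

This note documents the statistical procedures, the synthetic data model that
validates them, the numerical choices, and the limits of what the tests show.

## Data model

Genotypes are biallelic diploid SNP dosages (0/1/2, plus missing) in a
sites × samples matrix; phased VCF input additionally yields a per-haplotype
matrix. Sample metadata assigns each individual a group (wild N, artificially
bred B, post-release T), a province, a city with coordinates, and a
kinship-exclusion flag (kinship itself is not computed here; the flag is
consumed as metadata). Climate is a city × feature table (Long, Lati,
Bio1–Bio19). VCF coordinates are 1-based; all window arithmetic is half-open
0-based and converted only at I/O. Functional classes come from the first
SnpEff-style ANN effect only (`missense_variant` → nonsynonymous,
`synonymous_variant` → synonymous, anything else → other); multi-transcript
collapsing rules beyond "first entry wins" are deliberately out of scope.

Site filters follow the standard resequencing defaults: per-site missing rate
≤ 0.15, minor allele frequency ≥ 0.05, and mean depth ≥ 10 when a depth table
is provided (GT-only VCFs skip the depth rule with a warning).

## Polarization and the ancestral pool

A single outgroup sequence polarizes each site: outgroup = REF ⇒ derived
allele = ALT and DAF = AF; outgroup = ALT ⇒ DAF = 1 − AF; outgroup matching
neither allele, or missing, leaves the site unresolved and excluded from all
polarized analyses — with one sequence there is no further evidence to
adjudicate. The ancestral-population frequency AF_A pools *individual allele
counts* of the designated ancestral wild province (not city-level AF means),
because the downstream Fisher test needs counts; the outgroup contributes
polarization only, never counts, since a single haploid sequence would distort
the exact-test margins.

## Correlation scan

For each site and feature, Spearman's ρ between city-level DAF and the feature
across cities with non-missing AF (minimum 5 cities). P-values are
permutation-based throughout:

- ≤ 8 cities: the exact permutation distribution. Because average ranks sum
  to n(n+1)/2, the centring constant is shared and the null of the
  sum-product statistic depends on a site's ranks only through their
  multiset, so one enumerated null per tie pattern serves all its sites.
- > 8 cities: a Monte-Carlo permutation null (default 20 000 draws, fixed
  internal seed) with the (k+1)/(B+1) estimator, using the same
  tie-pattern sharing.

The t-approximation was evaluated and rejected: on ground-truth simulations
with 20 cities and rank-tied frequencies it is anti-conservative in the far
tail (realized false-discovery proportion ≈ 6.6% at a nominal 5% BH level),
which silently breaks FDR control. The permutation p-values restore it
(≈ 4.9% realized). Note that BH at q < 0.05 *targets* a 5% false-discovery
rate, so ~95% precision is the structural expectation, not a conservative
bound; single-replicate precision hovers at that boundary and only pooled
rates are stable.

Multiple testing uses Benjamini–Hochberg within each feature (the field's
default reading of "FDR"); NaN p-values are excluded from the test count and
propagated. High-|ρ| genome regions take each site's maximum |ρ| across
features, seed at |ρ| ≥ 0.8, and merge seeds closer than a configurable gap
(default 1 Mb).

## Linkage disequilibrium

Haplotype frequencies g11, g10, g01, g00 give p1 = g11 + g10, p2 = g11 + g01,
D = g11 − p1 p2, r² = D²/(p1 q1 p2 q2), X² = n r². A locus monomorphic in the
count table flags the result undefined rather than coercing r² to 0. Phased
input is the primary path (each individual contributes two haplotypes; a
haplotype missing at either site is dropped). Unphased input goes through an
EM estimator over the double-heterozygote ambiguity, initialized at linkage
equilibrium, iterated until the frequencies move < 1e-10; the log-likelihood
is tracked and non-decrease is asserted in tests. Nearest-synonymous pairing
ties break toward the smaller position. Decay curves average r² in distance
bins (all intra-chromosomal pairs within 100 kb by default, subsampled to a
fixed-seed pair budget); the half-maximum distance interpolates linearly
between bin midpoints and reports infinity when the curve never crosses.

## Diversity, F_ST, windows, sweeps, ROH

Per-site π uses the unbiased estimator 2 p̂ q̂ k/(k−1) over k called alleles
(≥ 2 called individuals required); He = 2 p̂ q̂; Ho is the heterozygote
fraction. F_ST is the Weir–Cockerham (1984) two-level a/b/c decomposition
(formulas in the `wc_fst` docstring), per-site values retained even when
negative, multi-site estimates as ratio of sums Σa/Σ(a+b+c) — the windowed
convention; whether the original analyses used ratio-of-sums or site means in
windows is not stated anywhere authoritative, so the weighted form was chosen
and recorded. Windows are 10 kb with a 5 kb step; window F_ST clips negatives
to 0; diversity-ratio windows report log2(θπ,bred/θπ,wild), undefined when
either side is 0. Sweep candidates are windows in the top 5% of *every*
supplied statistic (F_ST and the log2 ratio internally; XP-CLR is consumed
from an external file when present, never computed), merged when adjacent.

The ROH scanner reimplements the PLINK windowed heuristic deterministically:
50-SNP sliding windows are homozygous if they contain ≤ 1 heterozygote and
≤ 5 missing calls; a SNP is eligible when ≥ 5% of the windows covering it are
homozygous; maximal runs of eligible SNPs are split at gaps > 100 kb and kept
at ≥ 50 SNPs, ≥ 20 kb, and ≥ 1 SNP per 50 kb. Exact PLINK output equivalence
is not promised (PLINK has undocumented edge behaviours); the scanner is
validated against hand-traced fixtures instead. F_ROH = Σ L_ROH / L with L the
genome length supplied by the caller.

## Release impact

Candidate sites satisfy AF_A = 0 < AF_N: polarizable, at least one called
ancestral allele, every called ancestral allele equal to the ancestral state,
and derived alleles present in the focal wild province. ΔAF_N ≥ 0.05 defines
*affected*; among affected sites a two-sided Fisher exact test on
[derived, ancestral] counts (focal vs ancestral pool) is BH-adjusted *within
the province's affected set*, and q < 0.05 defines *strongly affected*; the
rest are *weakly affected*.

The randomization null permutes the per-site (AF_A, AF_N, counts) records
across positions while annotations stay fixed. Since each record keeps its own
counts, its class is invariant under the shuffle, so the implementation
classifies once and permutes the annotation labels — mathematically identical
and ~1000× cheaper than re-testing. The alternative reading (permute the
ancestral and focal count pairs independently, re-running classification and
Fisher tests each trial) is available via `mode="independent"`. One-sided
p-values use (k+1)/(B+1); when no trial is as extreme the report carries the
resolution bound (the "P < 0.001" convention at B = 1000).

Patterson's D uses the frequency form on (((P1, P2), P3), O) with
P1 = bred, P2 = post-release, P3 = wild and the outgroup defining the
ancestral state (pO = 0 after polarization); the standard error is a
delete-one jackknife over contiguous equal-SNP blocks (default 20; equal-bp
blocks would be an equally defensible choice), Z = D/SE, requiring ≥ 3
non-empty blocks.

## Synthetic data model

Sites are independent; genotypes are two Bernoulli haplotype draws from the
individual's population AF (hence phased output). The generator emulates:

- **Geography**: cities uniform on a longitude/latitude window
  (97–127°E, 21–47°N), grouped into provinces; the first province is the
  ancestral one. Climate features are affine in coordinates plus noise.
- **Clines**: logistic DAF = 1/(1 + exp(−s(x − x0))) in longitude with
  per-site centre jitter and random sign; default slope 0.3/degree.
- **Constraint**: nonsynonymous (non-clinal) sites draw baseline derived AF
  from Beta(1, 9) (mean 0.1) instead of Uniform(0.05, 0.95) — the
  low-frequency skew purifying selection leaves in standing variation.
  Setting `nonsyn_beta=None` disables it (used by calibration nulls, where
  annotations must be independent of frequency).
- **Rearing history**: city pools drift from the baseline by Balding–Nichols
  sampling with F = 0.02 (wild); the bred pool with F = 0.2; the released
  pool descends from the bred pool with additional F = 0.3 (long rearing
  programs are many generations removed from their founders); post-release
  samples draw from a released/local-wild mixture (wild fraction 0.4).
  These drift levels put expected heterozygosity in the order
  wild > post-release > bred with comfortable margins.
- **Inbreeding**: bred and post-release individuals carry explicit autozygous
  tracts (second haplotype copies the first) covering 30% / 15% of the
  genome (wild: 2%), exponential tract lengths with 100 kb mean. Independent
  per-site sampling alone cannot produce *localized* homozygous runs, so the
  tracts are what make the ROH scanner testable against ground truth.
- **Release impact**: a set of sites has baseline wild AF = 0, outgroup = REF
  and bred-pool AF ~ Uniform(0.05, 0.8); non-ancestral wild pools receive the
  released pool's alleles at admixture fraction m (default 0.1), scaled by
  `nonsyn_sel` (default 0.3) at nonsynonymous sites — purifying selection
  against introgressed nonsynonymous variants.
- **Outgroup realism**: at 30% of non-impact sites ALT is the ancestral
  allele; 2% of outgroup alleles match neither allele (unresolvable) and 2%
  are missing.

Defaults (8 cities × 15 wild diploids, 10 B and 10 T per non-ancestral
province, 5000 sites at 200 bp spacing on one chromosome) are a desk-scale
analogue of a multi-province field design.

What the generator does *not* emulate: linkage between sites (no
recombination map — LD exists only within autozygous tracts and in the
dedicated two-locus sampler), demographic history (bottlenecks, expansions),
sequencing error, and annotation error. Passing tests therefore demonstrate
the estimators and the pipeline logic, not robustness to LD-induced
correlation between tests or to misannotation.

## Validation scenarios

`agipop.validation` freezes one scenario per claim; sizes are chosen so each
runs in seconds and the measured rates are stable:

- *Clinal recovery*: 20 cities × 15 diploids, 200/5000 clinal sites, slope
  0.3; power and precision pooled over 10 replicate studies (see the FDR
  boundary note above).
- *Type-I calibration*: 20 neutral studies, 8 cities × 2000 sites, exact
  permutation p-values.
- *Release impact*: 6 cities in 3 provinces, 30 wild/city in focal provinces
  and 15/city in the ancestral province, 800 impact sites, m = 0.1. The
  asymmetric pool sizes place the Fisher significance boundary inside the
  affected-ΔAF range so both weak and strong classes are populated; with
  equal pools the BH step makes every affected site significant. Selection
  runs use `nonsyn_sel = 0.3`; neutral calibration uses `nonsyn_sel = 1`,
  `nonsyn_beta = None`.
- *Sweep recovery*: one 50 kb region with the derived allele nearly lost in
  every wild population (wild-swept: high F_ST, high log2 θπ,B/θπ,N).
- *Gene flow*: 8000 sites, released-pool drift 0.3, `post_admix = 0` so the
  m = 0 control is a true null (any wild admixture in the post-release group
  itself produces D > 0); paired m = 0.1 vs m = 0 replicates.
- *Orderings*: the rearing-history scenario without impact sites —
  impact sites are absent from wild pools by construction and would
  mechanically inflate bred/post-release diversity relative to wild, which is
  a composition effect, not the rearing signal under test.

## Numerical choices and degenerate inputs

Monomorphic sites: skipped by the scan (ρ undefined), NaN in F_ST, flagged in
LD. Empty windows report NaN; zero-diversity windows make the log2 ratio
undefined rather than ±inf. Fisher tables with an empty pool are dropped with
a logged count. Non-positive F_ST maps to infinite Nm (flagged, not a
number). EM non-convergence is flagged, never silently accepted. All
stochastic components take explicit seeds; equal inputs give byte-identical
outputs (asserted for the simulator and the pipeline).

## Known limitations

Independent sites mean the block jackknife's blocks are more independent than
in real genomes, so D-statistic standard errors on synthetic data are, if
anything, optimistic. The EM LD estimator assumes Hardy–Weinberg pairing
within the sample; under strong inbreeding its haplotype frequencies are
biased. The ROH scanner's per-SNP voting threshold (5%) reproduces the
standard heuristic but, like the original, has no optimality guarantee. The
correlation scan treats cities as independent replicates; spatial
autocorrelation among nearby cities is not modelled.
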