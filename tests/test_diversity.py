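import numpy as np
import pandas as pd
import pytest

from agipop.core_io import MISSING, GenotypeMatrix, SiteRecord
from agipop.diversity import (
    detect_roh,
    diversity_stats,
    log2_pi_ratio,
    make_windows,
    nm_from_fst,
    roh_summary,
    sweep_intersect,
    wc_fst,
    window_scan,
)


def _gm(codes, positions=None, chrom="c1"):
    codes = np.asarray(codes, dtype=np.int8)
    positions = positions or [100 * (i + 1) for i in range(codes.shape[0])]
    sites = [SiteRecord(chrom, int(p), "A", "G") for p in positions]
    return GenotypeMatrix(sites=sites, samples=[f"s{i}" for i in range(codes.shape[1])],
                          codes=codes)


class TestDiversityStats:
    def test_fixed_site_zero_pi(self):
        out = diversity_stats(_gm([[0, 0, 0]]))
        assert out.loc[0, "pi"] == 0.0

    def test_two_individuals_opposite_homozygotes(self):
        out = diversity_stats(_gm([[0, 2]]))
        assert out.loc[0, "pi"] == pytest.approx(2 / 3)
        assert out.loc[0, "he"] == pytest.approx(0.5)
        assert out.loc[0, "ho"] == 0.0

    def test_all_heterozygous(self):
        out = diversity_stats(_gm([[1] * 10]))
        assert out.loc[0, "ho"] == 1.0
        assert out.loc[0, "he"] == pytest.approx(0.5)

    def test_single_called_individual_skipped(self):
        out = diversity_stats(_gm([[1, MISSING, MISSING]]))
        assert np.isnan(out.loc[0, "pi"])

    def test_bounds(self, small_dataset):
        out = diversity_stats(small_dataset.gm)
        ok = out.dropna()
        assert ((ok["pi"] >= 0) & (ok["pi"] <= 2 / 3 + 1e-12)).all()
        assert ((ok["he"] >= 0) & (ok["he"] <= 0.5 + 1e-12)).all()
        assert ((ok["ho"] >= 0) & (ok["ho"] <= 1)).all()


def _wc_oracle(codes_by_pop):
    """Independent Weir-Cockerham oracle via the ANOVA mean squares of the
    allele indicator (between pops / between individuals / within
    individuals)."""
    n_i, p_i, h_i = [], [], []
    for codes in codes_by_pop:
        codes = np.asarray(codes, dtype=float)
        called = codes[codes != MISSING]
        n_i.append(len(called))
        p_i.append(called.sum() / (2 * len(called)))
        h_i.append((called == 1).mean())
    n_i = np.array(n_i, float)
    p_i = np.array(p_i)
    h_i = np.array(h_i)
    r = len(n_i)
    S1 = n_i.sum()
    pbar = (n_i * p_i).sum() / S1
    nc = (S1 - (n_i**2).sum() / S1) / (r - 1)
    MSP = (2 * n_i * (p_i - pbar) ** 2).sum() / (r - 1)
    # between individuals within pops: individual means are dosage/2
    ssi = 0.0
    for codes, p in zip(codes_by_pop, p_i):
        codes = np.asarray(codes, dtype=float)
        called = codes[codes != MISSING]
        ssi += (2 * (called / 2 - p) ** 2).sum()
    MSI = ssi / (S1 - r)
    MSG = (n_i * h_i).sum() / (2 * S1)
    denom = MSP + (nc - 1) * MSI + nc * MSG
    return (MSP - MSI) / denom if denom != 0 else np.nan


class TestWCFst:
    def test_no_differentiation_near_zero(self, rng):
        codes = rng.binomial(2, 0.5, (1, 40)).astype(np.int8)
        gm = _gm(codes)
        res = wc_fst(gm, {"a": np.arange(20), "b": np.arange(20, 40)})
        assert res["theta"][0] < 0.15

    def test_fixation_approaches_one(self):
        codes = np.array([[2] * 30 + [0] * 30], dtype=np.int8)
        gm = _gm(codes)
        res = wc_fst(gm, {"a": np.arange(30), "b": np.arange(30, 60)})
        assert res["theta"][0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_anova_oracle(self, rng):
        """Per-site estimates agree with the mean-squares formulation to
        1e-12 over random 2- and 3-population configurations."""
        for trial in range(60):
            n_pops = 2 if trial % 2 == 0 else 3
            sizes = rng.integers(5, 25, n_pops)
            ps = rng.uniform(0.05, 0.95, n_pops)
            pops = [rng.binomial(2, p, s).astype(np.int8) for p, s in zip(ps, sizes)]
            codes = np.concatenate(pops)[None, :]
            gm = _gm(codes)
            parts, start = {}, 0
            for k, s in enumerate(sizes):
                parts[f"p{k}"] = np.arange(start, start + s)
                start += s
            res = wc_fst(gm, parts)
            oracle = _wc_oracle(pops)
            if np.isnan(oracle):
                assert np.isnan(res["theta"][0])
            else:
                assert res["theta"][0] == pytest.approx(oracle, abs=1e-12)

    def test_monomorphic_site_skipped(self):
        gm = _gm([[0, 0, 0, 0]])
        res = wc_fst(gm, {"a": [0, 1], "b": [2, 3]})
        assert np.isnan(res["theta"][0])

    def test_ratio_of_sums_equals_single_site(self, rng):
        codes = rng.binomial(2, [0.8] * 10 + [0.2] * 10, 20).astype(np.int8)[None, :]
        gm = _gm(codes)
        res = wc_fst(gm, {"a": np.arange(10), "b": np.arange(10, 20)})
        assert res["overall"] == pytest.approx(res["theta"][0])


class TestNm:
    def test_worked_values(self):
        assert nm_from_fst(0.2) == pytest.approx(1.0)
        assert nm_from_fst(1.0) == pytest.approx(0.0)
        assert nm_from_fst(0.0121) == pytest.approx(20.41, abs=0.005)

    def test_non_positive_fst_is_infinite_flow(self):
        assert np.isinf(nm_from_fst(-0.01))

    def test_invalid_fst_rejected(self):
        with pytest.raises(ValueError):
            nm_from_fst(1.5)


class TestWindowScan:
    def test_interval_containment(self):
        wins = window_scan(["c1", "c1"], [1000, 9000], [1.0, 3.0],
                           window=10_000, step=5_000,
                           chrom_spans={"c1": 10_000})
        first = wins.iloc[0]
        assert first["n_snps"] == 2
        assert first["value"] == pytest.approx(2.0)

    def test_negative_clip(self):
        wins = window_scan(["c1"], [1000], [-0.01], window=10_000, step=5_000,
                           clip_negative=True, chrom_spans={"c1": 10_000})
        assert wins.iloc[0]["value"] == 0.0

    def test_three_window_hand_oracle(self):
        chroms = ["c1"] * 4
        pos = [1000, 6000, 11000, 14000]
        vals = [1.0, 2.0, 3.0, 5.0]
        wins = window_scan(chroms, pos, vals, window=10_000, step=5_000,
                           chrom_spans={"c1": 15_000})
        # windows [0,10000): sites 1,2 mean 1.5; [5000,15000): 2,3,4 mean 10/3;
        # [10000,15000): 3,4 mean 4
        np.testing.assert_allclose(wins["value"], [1.5, 10 / 3, 4.0])
        np.testing.assert_array_equal(wins["n_snps"], [2, 3, 2])

    def test_ratio_of_sums_mode(self):
        wins = window_scan(["c1", "c1"], [1000, 2000], [1.0, 2.0],
                           denom=[2.0, 6.0], window=10_000, step=10_000,
                           chrom_spans={"c1": 10_000})
        assert wins.iloc[0]["value"] == pytest.approx(3.0 / 8.0)

    def test_empty_window_missing(self):
        wins = window_scan(["c1"], [1000], [1.0], window=5_000, step=5_000,
                           chrom_spans={"c1": 15_000})
        assert np.isnan(wins.iloc[2]["value"])


class TestSweepIntersect:
    N = len(make_windows({"c1": 50_000}, 10_000, 5_000))  # 10 windows

    def _wins(self, peaks):
        base = make_windows({"c1": 50_000}, 10_000, 5_000)
        base["n_snps"] = 5
        values = np.arange(self.N) * 0.01  # distinct sub-threshold background
        for idx, v in peaks.items():
            values[idx] = v
        base["value"] = values
        return base

    def test_set_intersection(self):
        sel, _ = sweep_intersect(
            {"A": self._wins({1: 5.0, 2: 4.0}), "B": self._wins({2: 5.0, 3: 4.0})},
            quantile=0.2,
        )
        assert len(sel) == 1
        assert sel.iloc[0]["start"] == 10_000

    def test_disjoint_tops_empty(self):
        sel, regions = sweep_intersect(
            {"A": self._wins({0: 5.0, 1: 4.0}), "B": self._wins({8: 5.0, 9: 4.0})},
            quantile=0.2,
        )
        assert len(sel) == 0 and len(regions) == 0

    def test_misaligned_grids_fatal(self):
        a = self._wins({})
        b = self._wins({}).iloc[1:].reset_index(drop=True)
        with pytest.raises(ValueError, match="aligned"):
            sweep_intersect({"A": a, "B": b})

    def test_adjacent_windows_merge(self):
        _, regions = sweep_intersect(
            {"A": self._wins({2: 5.0, 3: 4.0}), "B": self._wins({2: 4.0, 3: 5.0})},
            quantile=0.2,
        )
        assert len(regions) == 1
        assert regions.iloc[0]["n_windows"] == 2


def _roh_gm(het_at=(), positions=None, n=100, spacing=400):
    positions = positions or [spacing * i + 1 for i in range(n)]
    codes = np.zeros((len(positions), 1), dtype=np.int8)
    for i in het_at:
        codes[i, 0] = 1
    return _gm(codes, positions=positions)


class TestROH:
    def test_clean_run_detected(self):
        """100 consecutive homozygous SNPs spanning ~40 kb form one ROH."""
        gm = _roh_gm()
        seg, f = detect_roh(gm, 0, genome_length=400_000)
        assert len(seg) == 1
        assert seg.iloc[0]["n_snps"] == 100
        # positions 1..39601 -> 0-based half-open [0, 39601)
        assert seg.iloc[0]["length"] == 39_601
        assert f == pytest.approx(39_601 / 400_000)

    def test_clustered_hets_destroy_all_windows(self):
        """Five clustered heterozygotes in the middle of a 100-SNP
        chromosome leave no homozygous 50-SNP window, hence no ROH."""
        gm = _roh_gm(het_at=(47, 48, 49, 50, 51))
        seg, _ = detect_roh(gm, 0)
        assert len(seg) == 0

    def test_f_roh_ratio(self):
        gm = _roh_gm(n=100, positions=[400 * i + 1 for i in range(100)])
        _, f = detect_roh(gm, 0, genome_length=396_010)
        assert f == pytest.approx(0.1, abs=0.002)

    def test_gap_splits_run(self):
        """A 150 kb gap splits the run; both halves pass the thresholds."""
        pos = [400 * i + 1 for i in range(60)]
        pos += [pos[-1] + 150_000 + 400 * i for i in range(60)]
        gm = _roh_gm(n=120, positions=pos)
        seg, _ = detect_roh(gm, 0)
        assert len(seg) == 2
        assert (seg["n_snps"] == 60).all()

    def test_short_chromosome_no_windows(self):
        gm = _roh_gm(n=30, positions=[400 * i + 1 for i in range(30)])
        seg, _ = detect_roh(gm, 0)
        assert len(seg) == 0

    def test_invariant_to_sites_outside_runs(self):
        gm1 = _roh_gm()
        seg1, _ = detect_roh(gm1, 0)
        # append a distant block on another chromosome (all het, no ROH)
        extra = np.ones((60, 1), dtype=np.int8)
        sites2 = gm1.sites + [SiteRecord("c2", 400 * i + 1, "A", "G")
                              for i in range(60)]
        codes2 = np.vstack([gm1.codes, extra])
        gm2 = GenotypeMatrix(sites=sites2, samples=gm1.samples, codes=codes2)
        seg2, _ = detect_roh(gm2, 0)
        pd.testing.assert_frame_equal(seg1, seg2[seg2["chrom"] == "c1"].reset_index(drop=True))

    def test_deterministic(self):
        gm = _roh_gm(het_at=(10,))
        a, _ = detect_roh(gm, 0)
        b, _ = detect_roh(gm, 0)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_genome_length(self):
        with pytest.raises(ValueError):
            detect_roh(_roh_gm(), 0, genome_length=0)


class TestGroupOrdering:
    def test_pi_ordering_wild_post_bred(self, rearing_dataset):
        """Nucleotide diversity ranks wild > post-release > bred under the
        rearing-history scenario (drifted pools, autozygous tracts)."""
        ds = rearing_dataset
        gm, meta = ds.gm, ds.meta
        pis = {}
        for g in "NTB":
            idx = gm.sample_indices(meta[meta["group"] == g].index)
            pis[g] = np.nanmean(diversity_stats(gm, idx)["pi"])
        assert pis["N"] > pis["T"] > pis["B"]

    def test_roh_ordering_bred_exceeds_wild(self, rearing_dataset):
        ds = rearing_dataset
        gm, meta = ds.gm, ds.meta
        L = ds.config.chrom_length
        totals = {}
        for g in "NB":
            idx = gm.sample_indices(meta[meta["group"] == g].index)[:10]
            summ = roh_summary(gm, idx, genome_length=L)
            totals[g] = (summ["total_length"].mean(), summ["f_roh"].mean())
        assert totals["B"][0] > totals["N"][0]
        assert totals["B"][1] > totals["N"][1]


class TestLog2PiRatio:
    def test_undefined_when_zero(self):
        a = make_windows({"c1": 10_000}, 10_000, 10_000)
        a["n_snps"] = 1
        b = a.copy()
        a["value"] = [0.0]
        b["value"] = [0.2]
        out = log2_pi_ratio(a, b)
        assert np.isnan(out.iloc[0]["value"])

    def test_ratio_value(self):
        a = make_windows({"c1": 10_000}, 10_000, 10_000)
        a["n_snps"] = 1
        b = a.copy()
        a["value"] = [0.1]
        b["value"] = [0.4]
        out = log2_pi_ratio(a, b)
        assert out.iloc[0]["value"] == pytest.approx(-2.0)
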