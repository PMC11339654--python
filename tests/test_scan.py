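import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from feralpop import scan
from feralpop.panels import HaplotypePanel


def make_hap_panel(hap, cm=None, chrom=None, pops=None):
    hap = np.asarray(hap, dtype=np.int8)
    n_sites, n_hap = hap.shape
    assert n_hap % 2 == 0
    n_ind = n_hap // 2
    if cm is None:
        cm = np.arange(n_sites) * 0.1
    if chrom is None:
        chrom = np.array(["1"] * n_sites, dtype=object)
    if pops is None:
        pops = ["P"] * n_ind
    return HaplotypePanel(
        chrom=chrom,
        pos=(np.asarray(cm) * 1e6 + 1).astype(int),
        cm=np.asarray(cm, dtype=float),
        hap=hap,
        samples=[f"S{i}" for i in range(n_ind)],
        pops=np.asarray(pops),
    )


def brute_force_ehh(hap, carriers, focal, j):
    """O(n^2) pairwise identity over the interval [min(focal,j), max(focal,j)]."""
    lo, hi = min(focal, j), max(focal, j)
    rows = [hap[lo : hi + 1, c] for c in carriers]
    n = len(rows)
    ident = sum(
        np.array_equal(rows[a], rows[b])
        for a, b in itertools.combinations(range(n), 2)
    )
    return ident / (n * (n - 1) / 2)


class TestEhh:
    def test_degenerate_identical_panel(self):
        hap = np.zeros((11, 6), dtype=int)
        hap[5] = [1, 1, 1, 0, 0, 0]  # focal SNP polymorphic
        panel = make_hap_panel(hap)
        res = scan.ehh_and_ihh(panel, 5)
        for allele in (0, 1):
            curve = res[allele]["ehh_right"]
            assert np.allclose(curve[:, 1], 1.0)
        # iHH = full integration span on both sides (EHH = 1 throughout)
        assert res[0]["ihh"] == pytest.approx(1.0)  # 0.5 cM each side

    def test_focal_ehh_is_one(self):
        rng = np.random.default_rng(0)
        panel = make_hap_panel(rng.integers(0, 2, size=(21, 8)))
        res = scan.ehh_and_ihh(panel, 10)
        for allele in (0, 1):
            if res[allele]["ehh_left"] is not None:
                assert res[allele]["ehh_left"][0, 1] == 1.0

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(1)
        hap = rng.integers(0, 2, size=(15, 10))
        panel = make_hap_panel(hap)
        focal = 7
        res = scan.ehh_and_ihh(panel, focal)
        for allele in (0, 1):
            carriers = np.flatnonzero(hap[focal] == allele)
            if len(carriers) < 2:
                continue
            for curve, step in ((res[allele]["ehh_right"], 1),
                                (res[allele]["ehh_left"], -1)):
                for k in range(1, len(curve)):
                    j = focal + step * k
                    expected = brute_force_ehh(hap, carriers, focal, j)
                    assert curve[k, 1] == pytest.approx(expected)

    def test_monotone_nonincreasing(self):
        rng = np.random.default_rng(2)
        panel = make_hap_panel(rng.integers(0, 2, size=(31, 12)))
        res = scan.ehh_and_ihh(panel, 15)
        for allele in (0, 1):
            for side in ("ehh_left", "ehh_right"):
                curve = res[allele][side]
                if curve is not None:
                    assert np.all(np.diff(curve[:, 1]) <= 1e-12)

    def test_single_carrier_undefined(self):
        hap = np.zeros((5, 6), dtype=int)
        hap[2, 0] = 1
        panel = make_hap_panel(hap)
        res = scan.ehh_and_ihh(panel, 2)
        assert np.isnan(res[1]["ihh"])


class TestIhs:
    def test_maf_filter(self):
        rng = np.random.default_rng(3)
        hap = rng.integers(0, 2, size=(50, 100))
        hap[10] = 0
        hap[10, 0] = 1  # MAF = 0.005 < 0.01
        df = scan.ihs(make_hap_panel(hap), maf_min=0.01)
        assert np.isnan(df["ihs_uns"].iloc[10])
        assert df.attrs["n_excluded_maf"] >= 1

    def test_allele_relabeling_flips_sign(self):
        rng = np.random.default_rng(4)
        hap = rng.integers(0, 2, size=(41, 12))
        panel = make_hap_panel(hap)
        df1 = scan.ihs(panel, standardize=False)
        hap2 = hap.copy()
        hap2[20] = 1 - hap2[20]
        df2 = scan.ihs(make_hap_panel(hap2), standardize=False)
        a, b = df1["ihs_uns"].iloc[20], df2["ihs_uns"].iloc[20]
        if np.isfinite(a) and np.isfinite(b):
            assert a == pytest.approx(-b)

    def test_neutral_standardization(self, cohort):
        hap, _, _ = cohort
        df = scan.ihs(hap.for_population("SRC1"))
        vals = df["ihs"].dropna()
        assert abs(vals.mean()) < 0.05
        assert 0.9 <= vals.std() <= 1.1


class TestRsb:
    def test_self_comparison_near_zero(self, cohort):
        hap, _, _ = cohort
        p = hap.for_population("SRC1")
        sub = p.take_sites(np.arange(200))
        df = scan.rsb(sub, sub, standardize=False)
        vals = df["rsb_uns"].dropna()
        assert np.allclose(vals, 0.0, atol=1e-12)

    def test_sweep_localizes_top_rsb(self):
        """A haplotype sweep present in X and absent in Y puts the top
        standardized Rsb within 500 kb of the swept site in >= 80% of
        replicates."""
        import feralpop as fp

        cfg = fp.SimConfig(n_sites=1200, n_chromosomes=1, chrom_length=5e6,
                           source_size=1500, t_divergence=300, seed=5)
        hap, _, _ = fp.simulate_cohort(cfg)
        x0 = hap.for_population("SRC1")
        y = hap.for_population("SRC2")
        hits, n_rep = 0, 5
        for rep in range(n_rep):
            center = 1_000_000 + rep * 700_000
            mid = x0.pos.searchsorted(center)
            window = np.arange(max(0, mid - 80), min(x0.n_sites, mid + 80))
            swept = x0.hap.copy()
            swept[np.ix_(window, np.arange(14))] = swept[window][:, [14]]
            px = HaplotypePanel(chrom=x0.chrom, pos=x0.pos, cm=x0.cm,
                                hap=swept, samples=x0.samples, pops=x0.pops)
            df = scan.rsb(px, y)
            top = df.loc[df["rsb"].idxmax()]
            hits += abs(top["pos"] - center) <= 500_000
        assert hits / n_rep >= 0.8

    def test_swap_flips_sign(self, cohort):
        hap, _, _ = cohort
        x = hap.for_population("SRC1").take_sites(np.arange(150))
        y = hap.for_population("SRC2").take_sites(np.arange(150))
        d1 = scan.rsb(x, y, standardize=False)["rsb_uns"]
        d2 = scan.rsb(y, x, standardize=False)["rsb_uns"]
        ok = d1.notna() & d2.notna()
        np.testing.assert_allclose(d1[ok], -d2[ok], atol=1e-12)


class TestPTransform:
    def test_ihs_zero(self):
        assert scan.p_transform(np.array([0.0]), "ihs")[0] == pytest.approx(0.0)

    def test_rsb_zero(self):
        # p = 1 - Phi(0) = 0.5 -> -log10(0.5)
        assert scan.p_transform(np.array([0.0]), "rsb")[0] == pytest.approx(
            0.3010299957
        )

    def test_matches_direct_cdf(self):
        from scipy.stats import norm

        x = np.array([0.5, 1.5, -2.3])
        got = scan.p_transform(x, "ihs")
        direct = -np.log10(1 - 2 * np.abs(norm.cdf(x) - 0.5))
        np.testing.assert_allclose(got, direct, rtol=1e-9)

    @given(st.floats(min_value=-8, max_value=8, allow_nan=False))
    @settings(deadline=None)
    def test_ihs_symmetry(self, x):
        a = scan.p_transform(np.array([x]), "ihs")[0]
        b = scan.p_transform(np.array([-x]), "ihs")[0]
        assert a == pytest.approx(b, rel=1e-12)


def brute_force_max_interval(scores):
    best = 0.0
    for i in range(len(scores)):
        for j in range(i, len(scores)):
            best = max(best, float(np.sum(scores[i : j + 1])))
    return best


class TestLocalScore:
    def test_documented_toy(self):
        scores = np.array([1.0, -0.5, 2.0])
        np.testing.assert_allclose(scan.lindley(scores), [1.0, 0.5, 2.5])
        assert scan.max_excursion_height(scores) == pytest.approx(2.5)
        assert brute_force_max_interval(scores) == pytest.approx(2.5)

    def test_matches_brute_force_on_random_chromosomes(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            scores = rng.normal(-0.5, 1.0, size=200)
            assert scan.max_excursion_height(scores) == pytest.approx(
                brute_force_max_interval(scores)
            )

    def test_subthreshold_scores_give_no_excursions(self):
        # all p >= 1e-2 with xi = 2 -> all SNP scores <= 0
        pscores = np.full(50, 1.5)
        windows = scan.local_score(
            pscores, np.arange(50) * 1000 + 1, "1", xi=2.0, n_perm=50
        )
        assert len(windows) == 0

    def test_leftmost_peak_on_ties(self):
        scores = np.array([2.0, -2.0, 2.0])
        exc = scan.excursions(scores)
        assert len(exc) >= 1
        assert exc[0].peak_idx == 0  # L = (2, 0, 2): tie broken leftmost?
        # explicit tie inside one excursion
        exc2 = scan.excursions(np.array([1.0, 0.0, 0.0]))
        assert exc2[0].peak_idx == 0

    def test_significant_sweep_window_found(self):
        rng = np.random.default_rng(6)
        pscores = rng.uniform(0.0, 1.0, 400)
        pscores[200:210] = 8.0  # strong localized signal
        windows = scan.local_score(
            pscores, np.arange(400) * 500 + 1, "1", xi=2.0, n_perm=200, seed=1
        )
        assert len(windows) == 1
        w = windows.iloc[0]
        assert w["start"] <= 200 * 500 + 1 <= w["end"]
        assert w["start"] <= w["peak_pos"] <= w["end"]

    def test_analytic_threshold_conservative_upper_bound(self):
        """The Gumbel bound with K = 1 sits above the Monte-Carlo
        threshold (it ignores the <1 ladder-height constant) but stays on
        the same scale."""
        rng = np.random.default_rng(7)
        pscores = rng.exponential(1 / np.log(10), size=2000)  # -log10(U(0,1))
        scores = pscores - 2.0
        mc = scan.mc_threshold(scores, n_perm=400, seed=2)
        ana = scan.analytic_threshold(scores)
        assert mc <= ana <= mc + 1.0


class TestAnnotateRegions:
    def _genes(self):
        return pd.DataFrame(
            {
                "chrom": ["1", "1", "2"],
                "start": [10_000, 50_000, 10_000],
                "end": [20_000, 60_000, 20_000],
                "name": ["G1", "G2", "G3"],
            }
        )

    def _window(self, peak, chrom="1"):
        return pd.DataFrame(
            [
                {
                    "chrom": chrom, "start": peak - 100, "end": peak + 100,
                    "n_snps": 3, "peak_pos": peak, "peak_score": 5.0,
                    "threshold": 2.0,
                }
            ]
        )

    def test_peak_inside_gene_distance_zero(self):
        res = scan.annotate_regions(self._window(15_000), self._genes())
        assert res["nearest_gene"].iloc[0] == "G1"
        assert res["gene_distance_kb"].iloc[0] == 0.0

    def test_peak_8kb_from_gene(self):
        res = scan.annotate_regions(self._window(42_001), self._genes())
        assert res["nearest_gene"].iloc[0] == "G2"
        assert res["gene_distance_kb"].iloc[0] == pytest.approx(8.0)

    def test_equidistant_genes_flagged(self):
        genes = pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "start": [10_000, 30_000],
                "end": [20_001, 40_000],
                "name": ["GA", "GB"],
            }
        )
        # peak0 = 25000: 5000 bp beyond GA's last base, 5000 bp before GB
        res = scan.annotate_regions(self._window(25_001), genes)
        assert res["ambiguous"].iloc[0]
        assert set(res["nearest_gene"].iloc[0].split(";")) == {"GA", "GB"}

    def test_empty_gene_set_blank(self):
        res = scan.annotate_regions(
            self._window(15_000, chrom="9"), self._genes()
        )
        assert res["nearest_gene"].iloc[0] == ""
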