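import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from feralpop import popstruct
from feralpop.popstruct import (
    BlockScheme,
    asd_matrix,
    block_jackknife_ratio,
    classify_degree,
    f4_ratio,
    f_statistics,
    kinship,
    wc_f_statistics,
)

from conftest import certain_panel


def _drift_panel(p_anc, pops_spec, rng, n_gen=2, n_pop_size=50):
    """Certain-genotype panel: each population drifts independently from
    shared ancestral frequencies (binomial Wright-Fisher)."""
    gts, labels, samples = [], [], []
    for label, n_ind in pops_spec:
        p = p_anc.copy()
        for _ in range(n_gen):
            p = rng.binomial(2 * n_pop_size, p) / (2 * n_pop_size)
        gts.append(rng.binomial(2, p[:, None], size=(len(p), n_ind)))
        labels += [label] * n_ind
    return certain_panel(np.concatenate(gts, axis=1), labels)


class TestBlockScheme:
    def test_contiguous_sizes(self):
        bs = BlockScheme.contiguous(1010, 250)
        sizes = np.bincount(bs.block_id)
        assert list(sizes) == [250, 250, 250, 250, 10]

    def test_equal_count_remainder_to_last(self):
        bs = BlockScheme.equal_count(103, 10)
        sizes = np.bincount(bs.block_id)
        assert list(sizes[:-1]) == [10] * 9 and sizes[-1] == 13


class TestJackknife:
    def test_se_zero_for_constant_blocks(self):
        num = np.ones(100)
        den = np.full(100, 2.0)
        est, se = block_jackknife_ratio(num, den, np.arange(100) // 10)
        assert est == pytest.approx(0.5)
        assert se == pytest.approx(0.0, abs=1e-12)


class TestWeirCockerham:
    def test_fixed_difference_gives_fst_one(self):
        gt = np.zeros((500, 8), dtype=int)
        gt[:, 4:] = 2
        panel = certain_panel(gt, ["A"] * 4 + ["B"] * 4)
        res = wc_f_statistics(panel, blocks=BlockScheme.contiguous(500, 100))
        assert res["FST:A:B"].estimate == pytest.approx(1.0)

    def test_single_locus_fis_formula_oracle(self):
        # genotype counts (AA, Aa, aa) = (4, 2, 4): n=10, p=0.5, h=0.2
        gt = np.array([[0] * 4 + [1] * 2 + [2] * 4])
        n, p, h = 10, 0.5, 0.2
        b = (n / (n - 1)) * (p * (1 - p) - h * (2 * n - 1) / (4 * n))
        c = h / 2
        expected = 1 - c / (b + c)
        comp_b, comp_bc = popstruct._single_pop_fis_components(
            np.array([n]), np.array([p]), np.array([h])
        )
        assert comp_b[0] / comp_bc[0] == pytest.approx(expected)

    def test_random_split_fst_centered_near_zero(self):
        rng = np.random.default_rng(10)
        ests = []
        for _ in range(60):
            p = rng.uniform(0.1, 0.9, size=400)
            gt = rng.binomial(2, p[:, None], size=(400, 20))
            perm = rng.permutation(20)
            labels = np.empty(20, dtype=object)
            labels[perm[:10]], labels[perm[10:]] = "A", "B"
            panel = certain_panel(gt, labels)
            res = wc_f_statistics(panel, pops=["A", "B"],
                                  blocks=BlockScheme.contiguous(400, 100))
            ests.append(res["FST:A:B"].estimate)
        assert abs(np.mean(ests)) < 0.005


class TestFStatistics:
    def test_f4_antisymmetry(self):
        rng = np.random.default_rng(11)
        panel = _drift_panel(
            rng.uniform(0.2, 0.8, 600),
            [("A", 5), ("B", 5), ("C", 5), ("D", 5)],
            rng,
        )
        blocks = BlockScheme.contiguous(600, 100)
        r1 = f_statistics(panel, [("f4", "A", "B", "C", "D")], blocks)[0]
        r2 = f_statistics(panel, [("f4", "A", "B", "D", "C")], blocks)[0]
        assert r1.estimate == pytest.approx(-r2.estimate)

    def test_f2_of_same_population_near_zero(self):
        """Two disjoint samples from one panmictic pool: the unbiased f2
        estimator is centered on the true value 0."""
        rng = np.random.default_rng(12)
        ests = []
        for _ in range(30):
            p = rng.uniform(0.2, 0.8, 800)
            gt = rng.binomial(2, p[:, None], size=(800, 16))
            panel = certain_panel(gt, ["A"] * 8 + ["B"] * 8)
            r = f_statistics(panel, [("f2", "A", "B")],
                             BlockScheme.contiguous(800, 100))[0]
            ests.append(r.estimate)
        assert abs(np.mean(ests)) < 0.002

    def test_f3_negative_for_recent_even_admixture(self):
        rng = np.random.default_rng(13)
        n_sites, n_ind = 3000, 12
        p_anc = rng.uniform(0.2, 0.8, n_sites)
        # sources diverge appreciably before the admixture event
        pb, pc = p_anc.copy(), p_anc.copy()
        for _ in range(5):
            pb = rng.binomial(100, pb) / 100
            pc = rng.binomial(100, pc) / 100
        # A: one allele from the B pool, one from the C pool (one-generation
        # 50/50 admixture, minimal drift)
        ga = (
            rng.binomial(1, pb[:, None], size=(n_sites, n_ind))
            + rng.binomial(1, pc[:, None], size=(n_sites, n_ind))
        )
        gb = rng.binomial(2, pb[:, None], size=(n_sites, n_ind))
        gc = rng.binomial(2, pc[:, None], size=(n_sites, n_ind))
        panel = certain_panel(
            np.concatenate([ga, gb, gc], axis=1),
            ["A"] * n_ind + ["B"] * n_ind + ["C"] * n_ind,
        )
        r = f_statistics(panel, [("f3", "A", "B", "C")],
                         BlockScheme.contiguous(n_sites, 250))[0]
        assert r.estimate < 0
        assert r.z < -1.65
        assert r.extra["admixed"]

    def test_f3_nonnegative_for_drift_only_target(self):
        rng = np.random.default_rng(14)
        p_anc = rng.uniform(0.2, 0.8, 2000)
        panel = _drift_panel(
            p_anc, [("A", 8), ("B", 8), ("C", 8)], rng, n_gen=4
        )
        r = f_statistics(panel, [("f3", "A", "B", "C")],
                         BlockScheme.contiguous(2000, 250))[0]
        assert r.estimate > -2 * r.se

    def test_overlapping_labels_rejected(self, gpanel):
        with pytest.raises(ValueError):
            f_statistics(gpanel, [("f3", "TARGET", "TARGET", "SRC1")])


class TestF4Ratio:
    def _alpha_panel(self, alpha, rng, n_sites=4000):
        """X admixed from S1/S2 with proportion alpha; the reference I is
        a sister of S1 so the denominator f4 measures the shared internal
        branch: ratio f4(O,I;X,S2)/f4(O,I;S1,S2)."""
        p_anc = rng.uniform(0.2, 0.8, n_sites)
        drift = lambda p, n: rng.binomial(n, p) / n
        po = drift(p_anc, 100)
        b1 = drift(drift(p_anc, 100), 100)  # internal branch toward S1 and I
        pi = drift(b1, 100)
        p1 = drift(b1, 150)
        p2 = drift(drift(p_anc, 150), 150)
        px = alpha * p1 + (1 - alpha) * p2
        gts, labels = [], []
        for lab, p in (("O", po), ("I", pi), ("X", px), ("S1", p1), ("S2", p2)):
            gts.append(rng.binomial(2, p[:, None], size=(n_sites, 8)))
            labels += [lab] * 8
        return certain_panel(np.concatenate(gts, axis=1), labels)

    def test_pure_source_alpha_one(self):
        rng = np.random.default_rng(15)
        panel = self._alpha_panel(1.0, rng)
        r = f4_ratio(panel, ("O", "I", "X", "S2"), ("O", "I", "S1", "S2"),
                     BlockScheme.contiguous(4000, 250))
        assert r.ci_low < 1.0 < r.ci_high

    def test_alpha_zero_ci_covers_zero(self):
        rng = np.random.default_rng(16)
        panel = self._alpha_panel(0.0, rng)
        r = f4_ratio(panel, ("O", "I", "X", "S2"), ("O", "I", "S1", "S2"),
                     BlockScheme.contiguous(4000, 250))
        assert r.ci_low < 0.0 < r.ci_high

    def test_recovers_intermediate_alpha(self):
        rng = np.random.default_rng(17)
        panel = self._alpha_panel(0.75, rng)
        r = f4_ratio(panel, ("O", "I", "X", "S2"), ("O", "I", "S1", "S2"),
                     BlockScheme.contiguous(4000, 250))
        assert r.estimate == pytest.approx(0.75, abs=0.1)


class TestASD:
    def test_identical_homozygotes_and_opposite(self):
        gt = np.array([[0, 0], [2, 2]])  # identical homozygous genotypes
        panel = certain_panel(gt, ["P", "P"])
        assert asd_matrix(panel).iloc[0, 1] == pytest.approx(0.0)
        gt = np.array([[0, 2], [2, 0]])  # opposite homozygotes everywhere
        panel = certain_panel(gt, ["P", "P"])
        assert asd_matrix(panel).iloc[0, 1] == pytest.approx(1.0)

    def test_documented_toy(self):
        # AA/AA, AA/Aa, AA/aa, Aa/Aa -> (0 + 0.5 + 1 + 0.5)/4 = 0.5
        gt = np.array([[0, 0], [0, 1], [0, 2], [1, 1]])
        panel = certain_panel(gt, ["P", "P"])
        assert asd_matrix(panel).iloc[0, 1] == pytest.approx(0.5)


class TestKinship:
    def test_duplicated_individual(self):
        rng = np.random.default_rng(18)
        p = rng.uniform(0.1, 0.9, 2000)
        g = rng.binomial(2, p)
        gt = np.column_stack([g, g])
        panel = certain_panel(gt, ["P", "P"])
        assert kinship(panel, (0, 1)) == pytest.approx(0.5)

    def test_parent_offspring(self):
        rng = np.random.default_rng(19)
        p = rng.uniform(0.2, 0.8, 5000)
        mat = rng.binomial(1, p) + rng.binomial(1, p)
        pat = rng.binomial(1, p) + rng.binomial(1, p)
        # child: one transmitted allele from each parent
        child = rng.binomial(1, mat / 2) + rng.binomial(1, pat / 2)
        panel = certain_panel(np.column_stack([mat, child]), ["P", "P"])
        phi = kinship(panel, (0, 1))
        assert 0.177 <= phi <= 0.354

    def test_unrelated_near_zero(self):
        rng = np.random.default_rng(20)
        p = rng.uniform(0.2, 0.8, 5000)
        gt = rng.binomial(2, p[:, None], size=(5000, 2))
        panel = certain_panel(gt, ["P", "P"])
        assert abs(kinship(panel, (0, 1))) < 0.03

    def test_few_sites_warns(self):
        gt = np.tile([1, 1], (50, 1))
        panel = certain_panel(gt, ["P", "P"])
        with pytest.warns(UserWarning, match="co-called"):
            kinship(panel, (0, 1))


class TestDegreeClassification:
    @pytest.mark.parametrize(
        "phi, expected",
        [
            (0.144, "second"),   # within [0.0884, 0.177)
            (0.25, "first"),
            (0.01, "unrelated"),
            (0.5, "duplicate"),
            (0.06, "third"),
            (0.0884, "second"),  # lower bounds closed
            (0.177, "first"),
        ],
    )
    def test_examples(self, phi, expected):
        assert classify_degree(phi) == expected

    @given(st.floats(min_value=-0.5, max_value=0.6,
                     allow_nan=False, allow_infinity=False))
    @settings(deadline=None)
    def test_partition(self, phi):
        assert classify_degree(phi) in {
            "duplicate", "first", "second", "third", "unrelated"
        }
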