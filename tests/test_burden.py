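"""Gene-based burden testing: QC, collapsing, CMC, Madsen-Browning, SKAT-O."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from famrare.burden import (
    BurdenQCConfig,
    WeightScheme,
    cmc_test,
    collapse_carriers,
    gene_burden_report,
    madsen_browning_test,
    qc_filter,
    skat_o_test,
)
from famrare.io import CohortDesign, GenotypeMatrix, VariantRecord
from famrare.simulate import (
    CohortSimConfig,
    GeneModel,
    default_gene_models,
    simulate_case_control,
)


def _gm(dosages, gq=None, ids=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    ids = ids or [f"s{i}" for i in range(n)]
    keys = [f"1:{100 + j}:A:G" for j in range(m)]
    return GenotypeMatrix(ids, keys, dosages, gq)


class TestQC:
    def _variant(self, j, afs=None):
        return VariantRecord(
            "1", 100 + j, "A", "G", gene="G", functional_class="nonsynonymous",
            af_by_source=afs or {},
        )

    def test_common_in_any_database_excluded(self):
        gm = _gm(np.zeros((4, 1)))
        v = self._variant(0, {"dbA": 0.001, "dbB": 0.006})
        retained, _, log = qc_filter([v], gm)
        assert retained == [] and list(log.reason) == ["af"]

    def test_common_in_inhouse_panel_excluded(self):
        gm = _gm(np.zeros((4, 1)))
        v = self._variant(0)
        retained, _, log = qc_filter([v], gm, inhouse_af={v.key: 0.01})
        assert retained == [] and list(log.reason) == ["af"]

    def test_low_call_rate_after_gq_masking_excluded(self):
        # 4 of 10 genotypes fall below the GQ floor -> 60% call rate
        dosages = np.ones((10, 1))
        gq = np.full((10, 1), 99.0)
        gq[:4, 0] = 50.0
        gm = _gm(dosages, gq)
        retained, masked, log = qc_filter([self._variant(0)], gm)
        assert retained == [] and list(log.reason) == ["call_rate"]
        assert (masked.dosages[:4, 0] == -1).all()

    def test_passing_variant_retained(self):
        gm = _gm(np.ones((10, 1)), np.full((10, 1), 99.0))
        v = self._variant(0, {"dbA": 0.005})  # boundary: excluded only above
        retained, _, log = qc_filter([v], gm)
        assert retained == [v] and log.empty


class TestCollapse:
    def _design(self, n_cases=285, n_controls=445):
        return CohortDesign(
            [f"case{i}" for i in range(n_cases)],
            [f"ctrl{i}" for i in range(n_controls)],
        )

    def _setup(self, case_carriers, control_carriers, design):
        n = design.n_cases + design.n_controls
        dosages = np.zeros((n, 1), dtype=np.int8)
        dosages[:case_carriers, 0] = 1
        dosages[design.n_cases : design.n_cases + control_carriers, 0] = 1
        ids = design.case_ids + design.control_ids
        gm = _gm(dosages, ids=ids)
        v = VariantRecord("1", 100, "A", "G", gene="G")
        return [v], gm

    @pytest.mark.parametrize(
        "cases,controls,case_pct,control_pct",
        [
            (21, 14, 7.37, 3.15),
            (35, 37, 12.28, 8.31),
            (6, 8, 2.11, 1.80),
            (9, 7, 3.16, 1.57),
            (13, 18, 4.56, 4.04),
            (0, 0, 0.0, 0.0),
        ],
    )
    def test_carrier_frequencies(self, cases, controls, case_pct, control_pct):
        design = self._design()
        variants, gm = self._setup(cases, controls, design)
        cc, nc, cf, nf = collapse_carriers("G", variants, gm, design)
        assert (cc, nc) == (cases, controls)
        assert (cf, nf) == (case_pct, control_pct)

    def test_multi_variant_carrier_counted_once(self):
        design = self._design(4, 4)
        dosages = np.zeros((8, 2), dtype=np.int8)
        dosages[0] = [1, 1]  # carries two rare alleles -> one carrier
        gm = _gm(dosages, ids=design.case_ids + design.control_ids)
        variants = [
            VariantRecord("1", 100, "A", "G", gene="G"),
            VariantRecord("1", 101, "A", "G", gene="G"),
        ]
        cc, nc, _, _ = collapse_carriers("G", variants, gm, design)
        assert (cc, nc) == (1, 0)

    def test_empty_gene_warns(self):
        design = self._design(2, 2)
        gm = _gm(np.zeros((4, 1)), ids=design.case_ids + design.control_ids)
        with pytest.warns(UserWarning, match="no retained variants"):
            assert collapse_carriers("G", [], gm, design) == (0, 0, 0.0, 0.0)


class TestCMC:
    def test_equal_proportions_near_one(self):
        design = CohortDesign([f"a{i}" for i in range(100)], [f"b{i}" for i in range(100)])
        assert cmc_test(10, 10, design) > 0.9

    def test_matches_fisher_enumeration(self):
        design = CohortDesign(
            [f"a{i}" for i in range(285)], [f"b{i}" for i in range(445)]
        )
        p = cmc_test(21, 14, design)
        expected = stats.fisher_exact(
            [[21, 264], [14, 431]], alternative="two-sided"
        )[1]
        assert p == pytest.approx(expected, rel=1e-7)


class TestMadsenBrowning:
    def test_all_zero_dosages_give_one(self):
        ids = [f"s{i}" for i in range(8)]
        gm = _gm(np.zeros((8, 2)), ids=ids)
        design = CohortDesign(ids[:4], ids[4:])
        assert madsen_browning_test(gm, design, n_permutations=100) == 1.0

    def test_exhaustive_matches_independent_enumeration(self, small_cohort):
        """On 4 cases / 4 controls the exhaustive permutation p equals a
        brute-force enumeration over all C(8,4)=70 label assignments."""
        gm, design = small_cohort
        p = madsen_browning_test(gm, design, exhaustive=True)

        # independent oracle: recompute weights, scores and rank-sum by hand
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        g = gm.dosages.astype(float)
        ctrl = g[y == 0]
        q = (ctrl.sum(axis=0) + 1) / (2 * ctrl.shape[0] + 2)
        w = 1 / np.sqrt(g.shape[0] * q * (1 - q))
        scores = g @ w
        order = np.argsort(scores, kind="stable")
        ranks = np.empty(8)
        sorted_scores = scores[order]
        i = 0
        while i < 8:  # average ranks for ties
            j = i
            while j < 8 and sorted_scores[j] == sorted_scores[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0
            i = j
        observed = ranks[:4].sum()
        hits = sum(
            1
            for subset in combinations(range(8), 4)
            if ranks[list(subset)].sum() >= observed
        )
        assert p == pytest.approx(hits / 70, abs=1e-12)

    def test_permutation_converges_to_exhaustive(self, small_cohort):
        gm, design = small_cohort
        exact = madsen_browning_test(gm, design, exhaustive=True)
        p = madsen_browning_test(gm, design, n_permutations=20_000, seed=1)
        se = np.sqrt(exact * (1 - exact) / 20_000)
        assert abs(p - exact) < 4 * se

    def test_deterministic_given_seed(self, small_cohort):
        gm, design = small_cohort
        p1 = madsen_browning_test(gm, design, n_permutations=500, seed=7)
        p2 = madsen_browning_test(gm, design, n_permutations=500, seed=7)
        assert p1 == p2

    def test_too_few_permutations_rejected(self, small_cohort):
        gm, design = small_cohort
        with pytest.raises(ValueError, match="permutations"):
            madsen_browning_test(gm, design, n_permutations=10)


class TestSkatO:
    def _toy(self, seed=0, n=60, m=5, maf=(0.35, 0.4, 0.45, 0.5, 0.4)):
        rng = np.random.default_rng(seed)
        dosages = rng.binomial(2, list(maf), size=(n, m)).astype(np.int8)
        ids = [f"s{i}" for i in range(n)]
        gm = _gm(dosages, ids=ids)
        design = CohortDesign(ids[: n // 2], ids[n // 2 :])
        return gm, design

    def test_single_variant_p_identical_across_rho(self):
        gm, design = self._toy(m=1, maf=(0.3,))
        res = skat_o_test(gm, design)
        ps = list(res.p_by_rho.values())
        assert max(ps) - min(ps) < 1e-10
        assert res.p_value == pytest.approx(ps[0], abs=1e-10)

    def test_rho_one_with_uniform_weights_is_burden_score_test(self):
        """At rho = 1 the statistic is the squared weighted burden score; its
        p equals a one-df chi-square test on the summed dosage."""
        gm, design = self._toy(seed=3)
        res = skat_o_test(gm, design, weights=WeightScheme("uniform"), rho_grid=(1.0,))
        y = design.phenotype_vector(gm.sample_ids).astype(float)
        burden = gm.dosages.sum(axis=1).astype(float)
        score = float(burden @ (y - y.mean()))
        n = len(y)
        var = (
            y.mean() * (1 - y.mean())
            * float(((burden - burden.mean()) ** 2).sum())
            * n / (n - 1.0)
        )
        expected = stats.chi2.sf(score**2 / var, 1)
        assert res.p_value == pytest.approx(expected, rel=1e-6)

    def test_moment_matching_agrees_with_permutation(self):
        """Permutation oracle on a common-variant toy where the Gaussian
        score approximation is accurate."""
        gm, design = self._toy(seed=0)
        mm = skat_o_test(gm, design)
        perm = skat_o_test(
            gm, design, p_method="permutation", n_permutations=20_000, seed=5
        )
        se = np.sqrt(perm.p_value * (1 - perm.p_value) / 20_000)
        assert abs(mm.p_value - perm.p_value) < 3 * se

    def test_p_at_least_min_per_rho_and_at_most_bonferroni(self):
        for seed in range(4):
            gm, design = self._toy(seed=seed)
            res = skat_o_test(gm, design)
            t_min = min(res.p_by_rho.values())
            assert res.p_value >= t_min - 1e-12
            assert res.p_value <= min(1.0, t_min * len(res.p_by_rho)) + 1e-12

    def test_monomorphic_gene_gives_one(self):
        ids = [f"s{i}" for i in range(10)]
        gm = _gm(np.zeros((10, 2)), ids=ids)
        design = CohortDesign(ids[:5], ids[5:])
        res = skat_o_test(gm, design)
        assert res.p_value == 1.0

    def test_deterministic(self):
        gm, design = self._toy(seed=1)
        assert skat_o_test(gm, design).p_value == skat_o_test(gm, design).p_value


def test_unidirectional_effects_favor_burden_over_variance_component():
    """When all causal variants act in the same direction with equal
    effects, burden-style statistics (CMC, MB, SKAT-O at rho = 1) out-rank
    the pure variance-component test (rho = 0) in most replicates."""
    n_rep = 120
    gene = GeneModel("G", (0.004,) * 8, odds_ratio=2.0)
    burden_wins = {"cmc": 0, "mb": 0, "rho1": 0}
    for rep in range(n_rep):
        res = simulate_case_control(
            CohortSimConfig(genes=[gene], seed=50_000 + rep)
        )
        p_rho0 = skat_o_test(res.genotypes, res.design, rho_grid=(0.0,)).p_value
        p_rho1 = skat_o_test(res.genotypes, res.design, rho_grid=(1.0,)).p_value
        cc, nc, _, _ = collapse_carriers("G", res.variants, res.genotypes, res.design)
        p_cmc = cmc_test(cc, nc, res.design)
        # enough permutations that the p resolution is below the analytic
        # p-values being compared against
        p_mb = madsen_browning_test(
            res.genotypes, res.design, n_permutations=9_999, seed=rep
        )
        burden_wins["cmc"] += p_cmc <= p_rho0
        burden_wins["mb"] += p_mb <= p_rho0
        burden_wins["rho1"] += p_rho1 <= p_rho0
    for name, wins in burden_wins.items():
        assert wins / n_rep >= 0.60, f"{name}: {wins}/{n_rep}"


class TestGeneReport:
    def test_report_shape_and_threshold(self):
        res = simulate_case_control(
            CohortSimConfig(genes=default_gene_models(1.0), seed=0)
        )
        rows, table = gene_burden_report(
            res.variants,
            res.genotypes,
            res.design,
            mb_permutations=199,
            seed=0,
        )
        assert len(rows) == 5
        assert set(table.gene) == {"EP400", "HDAC4", "KMT2D", "KDM6A", "NSD1"}
        assert np.allclose(table.threshold, 0.01)
        for col in ("p_cmc", "p_mb", "p_skato"):
            assert ((table[col] > 0) & (table[col] <= 1)).all()
        assert (table.case_freq_pct <= 100).all()

    def test_empty_gene_row(self):
        res = simulate_case_control(
            CohortSimConfig(genes=[GeneModel("G", (0.003,) * 3)], seed=1)
        )
        rows, table = gene_burden_report(
            res.variants,
            res.genotypes,
            res.design,
            genes=["G", "ABSENT"],
            mb_permutations=199,
        )
        absent = table.set_index("gene").loc["ABSENT"]
        assert absent.n_variants_tested == 0
        assert absent.p_cmc == 1.0 and absent.p_mb == 1.0 and absent.p_skato == 1.0
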