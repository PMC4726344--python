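"""VAF filtering, the convolution smg test, Fisher enrichment, BH behaviour."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from platsig import (
    DriverSpec,
    SimulationConfig,
    cohort_comparison,
    convolution_test,
    filter_variants,
    fisher_two_sided,
    group_enrichment,
    simulate_cohort,
    smg_scan,
    subgroup_discovery,
)
from platsig.catalog import MutationRecord, MutationTable
from platsig.recurrence import (
    GeneModel,
    background_rates,
    load_toy_gene_model,
)
from platsig.simulate import default_gene_model


def fisher_enumeration(table, tol=1e-7):
    """Independent oracle: sum hypergeometric point probabilities <= observed."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    pmf = stats.hypergeom.pmf(np.arange(0, col1 + 1), n, row1, col1)
    support = (np.arange(0, col1 + 1) <= row1) & (col1 - np.arange(0, col1 + 1) <= n - row1)
    pmf = pmf[support]
    observed = stats.hypergeom.pmf(a, n, row1, col1)
    return float(pmf[pmf <= observed * (1 + tol)].sum())


def make_table(gene_hits, groups=None, vaf=0.5):
    """gene_hits: list of (sample, gene) pairs; every record passes the filter."""
    recs = [
        MutationRecord(s, "chr1", 100 + i, "C", "A", vaf=vaf, gene=g, context="ACA")
        for i, (s, g) in enumerate(gene_hits)
    ]
    return MutationTable.from_records(recs, group_of=groups)


class TestFilterVariants:
    def test_strictly_greater_than_threshold(self):
        recs = [
            MutationRecord("S1", "chr1", 10, "C", "A", vaf=v, context="ACA")
            for v in (0.19, 0.20, 0.21)
        ]
        out = filter_variants(MutationTable.from_records(recs))
        assert list(out.df["vaf"]) == [0.21]

    def test_empty_table_stays_empty(self):
        table = MutationTable(
            pd.DataFrame(
                columns=["sample", "chrom", "pos", "ref", "alt", "vaf", "gene",
                         "context", "variant_class"]
            )
        )
        assert filter_variants(table).n_records == 0

    def test_missing_vaf_dropped_and_counted(self):
        recs = [
            MutationRecord("S1", "chr1", 10, "C", "A", vaf=0.5, context="ACA"),
            MutationRecord("S1", "chr1", 20, "C", "A", context="ACA"),
        ]
        out = filter_variants(MutationTable.from_records(recs))
        assert out.n_records == 1
        assert out.parse_report["n_dropped_missing_vaf"] == 1

    def test_retained_fraction_matches_generator_design(self, default_cohort):
        table, truth = default_cohort
        kept = filter_variants(table)
        frac = kept.n_records / table.n_records
        # complement of the origin-weighted sub-0.2 beta mass
        origins = np.array(truth.origins)
        vm = truth.vaf_model
        plat = float((origins == "Platinum").mean())
        low = plat * stats.beta.cdf(0.2, *vm.platinum_beta) + (1 - plat) * (
            (1 - vm.clonal_weight) * stats.beta.cdf(0.2, *vm.subclonal_beta)
            + vm.clonal_weight * stats.beta.cdf(0.2, *vm.clonal_beta)
        )
        assert frac == pytest.approx(1 - low, abs=0.03)


class TestBackgroundRates:
    def test_per_base_rate_arithmetic(self):
        table = make_table([("S1", "G1")] * 300)
        assert background_rates(table, exome_mb=30)["S1"] == pytest.approx(1e-5)

    def test_consistent_with_mutation_rate(self, default_cohort):
        from platsig import mutation_rate

        table, _ = default_cohort
        per_mb, _ = mutation_rate(table)
        per_base = background_rates(table)
        assert np.allclose(per_base.to_numpy(), per_mb.to_numpy() / 1e6)


class TestConvolutionTest:
    def test_zero_observed_gives_p_one(self):
        assert convolution_test(0, 1000, [0.001, 0.002]) == 1.0

    def test_matches_product_of_binomials_enumeration(self):
        L, rates = 10, [0.1, 0.2]
        pmf1 = stats.binom.pmf(np.arange(L + 1), L, rates[0])
        pmf2 = stats.binom.pmf(np.arange(L + 1), L, rates[1])
        total = np.outer(pmf1, pmf2)
        for obs in range(0, 8):
            expected = sum(
                total[i, j] for i in range(L + 1) for j in range(L + 1) if i + j >= obs
            )
            assert convolution_test(obs, L, rates) == pytest.approx(expected, rel=1e-10)

    def test_within_monte_carlo_error(self):
        rng = np.random.default_rng(123)
        L = 500
        rates = rng.uniform(1e-4, 2e-3, size=5)
        obs = 4
        draws = rng.binomial(L, rates, size=(100_000, 5)).sum(axis=1)
        mc = (draws >= obs).mean()
        p = convolution_test(obs, L, rates)
        se = math.sqrt(mc * (1 - mc) / 100_000)
        assert abs(p - mc) < 3 * se + 1e-12

    def test_poisson_limit_for_small_rates(self):
        L = 1000
        rates = [1e-6, 2e-6, 5e-6, 1e-5]
        lam = L * sum(rates)
        for obs in (1, 2, 3):
            exact = convolution_test(obs, L, rates)
            poisson = stats.poisson.sf(obs - 1, lam)
            assert exact == pytest.approx(poisson, rel=0.01)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            convolution_test(1, 10, [1.5])
        with pytest.raises(ValueError):
            convolution_test(-1, 10, [0.1])


class TestFisher:
    def test_sensitive_vs_resistant_table_reproduces_known_p(self):
        p = fisher_two_sided([[3, 4], [0, 11]])
        assert p == pytest.approx(35 / 816, rel=1e-10)  # exact hypergeometric tail
        assert round(p, 2) == 0.04

    def test_cohort_vs_external_table(self):
        p = fisher_two_sided([[3, 15], [8, 271]])
        assert p == pytest.approx(fisher_enumeration([[3, 15], [8, 271]]), rel=1e-7)
        assert round(p, 2) == 0.02

    def test_degenerate_and_invalid_tables(self):
        assert fisher_two_sided([[0, 7], [0, 11]]) == 1.0
        with pytest.raises(ValueError):
            fisher_two_sided([[1, -1], [0, 2]])
        with pytest.raises(ValueError):
            fisher_two_sided([[0, 0], [0, 0]])

    def test_agrees_with_enumeration_on_small_tables(self):
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if a + b + c + d == 0:
                continue
            table = [[a, b], [c, d]]
            assert fisher_two_sided(table) == pytest.approx(
                fisher_enumeration(table), rel=1e-6, abs=1e-12
            )


@pytest.fixture(scope="module")
def driver_cohort():
    """Cohort with one strong planted driver mutated in 6 resistant patients."""
    cfg = SimulationConfig(
        seed=404,
        drivers=(
            DriverSpec(
                "REV3L", "resistant", n_patients=6,
                mutations_per_patient=(2, 1, 2, 1, 1, 1),
            ),
        ),
    )
    table, truth = simulate_cohort(cfg)
    return filter_variants(table), cfg.gene_model, truth


class TestSmgScan:
    def test_planted_driver_is_flagged(self, driver_cohort):
        filtered, genes, _ = driver_cohort
        results = smg_scan(filtered, genes)
        hits = {r.gene: r for r in results}
        assert "REV3L" in hits
        assert hits["REV3L"].q_value < 0.2
        assert hits["REV3L"].n_mutated_patients >= 6

    def test_min_patients_gate(self):
        table = make_table([("S1", "G1"), ("S2", "G2"), ("S3", "G3")])
        genes = GeneModel({"G1": 1000, "G2": 1000, "G3": 1000})
        assert smg_scan(table, genes) == []

    def test_bh_equal_p_values_collapse_to_p(self):
        # three genes with identical counts and lengths share one p; BH keeps q == p
        hits = [(f"S{i}", g) for g in ("G1", "G2", "G3") for i in range(1, 3)]
        table = make_table(hits)
        genes = GeneModel({"G1": 500, "G2": 500, "G3": 500})
        results = smg_scan(table, genes, return_all=True)
        ps = {r.p_value for r in results}
        assert len(ps) == 1
        for r in results:
            assert r.q_value == pytest.approx(r.p_value)

    def test_q_monotone_in_p_and_never_smaller(self, driver_cohort):
        filtered, genes, _ = driver_cohort
        results = smg_scan(filtered, genes, return_all=True)
        by_p = sorted(results, key=lambda r: r.p_value)
        qs = [r.q_value for r in by_p]
        assert all(q2 >= q1 - 1e-12 for q1, q2 in zip(qs, qs[1:]))
        assert all(r.q_value >= r.p_value - 1e-12 for r in results)

    def test_unknown_genes_excluded_with_warning(self):
        table = make_table([("S1", "MYSTERY"), ("S2", "MYSTERY")])
        with pytest.warns(UserWarning, match="absent"):
            assert smg_scan(table, GeneModel({"G1": 100})) == []


class TestSubgroupDiscovery:
    def test_requires_group_labels(self):
        with pytest.raises(ValueError, match="group"):
            subgroup_discovery(make_table([("S1", "G1")]), GeneModel({"G1": 100}))

    def test_subgroup_only_gene_detected(self, fixture_suite):
        from platsig import read_maf
        from platsig.catalog import read_groups

        d = fixture_suite["rev3l"]
        table = read_maf(d / "mutations.tsv", groups=read_groups(d / "groups.tsv"))
        genes = GeneModel.read_tsv(d / "gene_model.tsv")
        disc = subgroup_discovery(filter_variants(table), genes)
        assert "REV3L" in disc.subgroup_only["sensitive"]
        assert "REV3L" not in {r.gene for r in disc.overall}

    def test_gene_significant_everywhere_not_in_difference(self, driver_cohort):
        filtered, genes, _ = driver_cohort
        disc = subgroup_discovery(filtered, genes)
        overall = {r.gene for r in disc.overall}
        for grp, only in disc.subgroup_only.items():
            assert not set(only) & overall


class TestGroupEnrichment:
    GROUPS = {f"A{i}": "sensitive" for i in range(1, 8)} | {
        f"B{i}": "resistant" for i in range(1, 12)
    }

    def _cohort(self, extra=()):
        hits = [(f"A{i}", "REV3L") for i in (1, 2, 3)] + [
            (s, "FILLER") for s in self.GROUPS
        ]
        return make_table(list(hits) + list(extra), groups=self.GROUPS)

    def test_rev3l_pattern(self):
        res = group_enrichment(self._cohort(), "REV3L", "sensitive", "resistant")
        assert res.table == ((3, 4), (0, 11))
        assert res.p_two_sided == pytest.approx(35 / 816, rel=1e-9)
        assert res.odds_direction == "group_a"

    def test_patient_level_counting_ignores_multiplicity(self):
        res = group_enrichment(
            self._cohort(extra=[("A1", "REV3L")] * 5),
            "REV3L", "sensitive", "resistant",
        )
        assert res.table == ((3, 4), (0, 11))

    def test_group_swap_leaves_p_unchanged(self):
        a = group_enrichment(self._cohort(), "REV3L", "sensitive", "resistant")
        b = group_enrichment(self._cohort(), "REV3L", "resistant", "sensitive")
        assert a.p_two_sided == b.p_two_sided

    def test_everyone_mutated_gives_p_one(self):
        res = group_enrichment(self._cohort(), "FILLER", "sensitive", "resistant")
        assert res.p_two_sided == 1.0

    def test_absent_gene_gives_empty_row_and_p_one(self):
        res = group_enrichment(self._cohort(), "NONE", "sensitive", "resistant")
        assert res.table == ((0, 7), (0, 11))
        assert res.p_two_sided == 1.0


class TestCohortComparison:
    def test_rev3l_against_external_counts(self):
        res = cohort_comparison({"REV3L": (3, 18)}, {"REV3L": (8, 279)})
        assert res[0].table == ((3, 15), (8, 271))
        assert round(res[0].p_two_sided, 2) == 0.02

    def test_symmetric_counts_give_p_one(self):
        res = cohort_comparison({"G": (4, 20)}, {"G": (4, 20)})
        assert res[0].p_two_sided == 1.0
        res0 = cohort_comparison({"G": (0, 18)}, {"G": (0, 279)})
        assert res0[0].p_two_sided == 1.0

    def test_missing_gene_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="missing"):
            res = cohort_comparison({"A": (1, 5), "B": (1, 5)}, {"A": (1, 5)})
        assert [r.gene for r in res] == ["A"]


def test_bundled_gene_model_loads_and_validates():
    model = load_toy_gene_model()
    assert "REV3L" in model and model["REV3L"] > 5000
    with pytest.raises(ValueError):
        GeneModel({"G1": 0})


def test_default_gene_model_tiles_exome():
    model = default_gene_model(exome_mb=30, seed=0)
    assert sum(model.lengths.values()) == 30_000_000
    assert "REV3L" in model
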