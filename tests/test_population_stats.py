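"""Category summaries, Monte-Carlo subsampling, U-tests, ratios."""

import numpy as np
import pytest

from mitosurvey import population_stats as ps
from mitosurvey import variant_catalog as vc
from mitosurvey.io_formats import AlignedGenomeSet
from mitosurvey.variant_catalog import category_predicate_map

from oracles import exact_mw_two_sided_p, normal_mw_two_sided_p


def catalog_from_columns(cols, pops):
    ids = [f"g{i}" for i in range(len(cols[0]))]
    seqs = ["".join(c[i] for c in cols) for i in range(len(ids))]
    ags = AlignedGenomeSet.from_sequences(ids, seqs, dict(zip(ids, pops)))
    return ags, vc.build_catalog(ags, [])


class TestMeanMinorAlleleFrequency:
    def test_mean_and_se(self):
        # two noncoding minors in one population at 0.1 and 0.3
        cols = [tuple("GAAAAAAAAA"), tuple("CCCAAAAAAA")]
        ags, cat = catalog_from_columns(cols, ["P"] * 10)
        stat = ps.mean_minor_allele_frequency(cat, "other_noncoding", "P")
        assert stat.mean == pytest.approx(0.2)
        assert stat.se == pytest.approx(0.1)
        assert stat.k == 2

    def test_single_allele_has_zero_se(self):
        cols = [tuple("GAAA")]
        ags, cat = catalog_from_columns(cols, ["P"] * 4)
        stat = ps.mean_minor_allele_frequency(cat, "other_noncoding", "P")
        assert stat.mean == 0.25 and stat.se == 0.0 and stat.k == 1

    def test_empty_category_flagged_absent(self):
        cols = [tuple("GAAA")]
        ags, cat = catalog_from_columns(cols, ["P"] * 4)
        stat = ps.mean_minor_allele_frequency(cat, "tRNA", "P")
        assert not stat.defined and stat.k == 0

    def test_population_without_the_allele_flagged(self):
        cols = [("G", "A", "A", "A")]
        ags, cat = catalog_from_columns(cols, ["X", "X", "Y", "Y"])
        assert ps.mean_minor_allele_frequency(cat, "other_noncoding", "X").defined
        assert not ps.mean_minor_allele_frequency(cat, "other_noncoding", "Y").defined


class TestPerGenomeBurden:
    def test_counts_and_mean(self):
        cols = [("G", "G", "A", "A")]
        ags, cat = catalog_from_columns(cols, ["P"] * 4)
        b = ps.per_genome_burden(cat, ags, "other_noncoding", "P")
        assert b.counts.tolist() == [1, 1, 0, 0]
        assert b.mean == 0.5

    def test_missing_base_not_a_carrier(self):
        cols = [("G", "-", "A", "A")]
        ags, cat = catalog_from_columns(cols, ["P"] * 4)
        b = ps.per_genome_burden(cat, ags, "other_noncoding", "P")
        assert b.counts.tolist() == [1, 0, 0, 0]

    def test_burden_conservation(self, small_bundle, small_catalog):
        """Sum of per-genome burdens equals summed allele counts, for
        every category and population."""
        for cat_name in vc.CATEGORY_ORDER:
            for pop in ("African", "non-African"):
                b = ps.per_genome_burden(small_catalog, small_bundle.genomes,
                                         cat_name, pop)
                expected = ps.count_allele_observations(small_catalog, cat_name, pop)
                assert b.counts.sum() == expected


class TestMonteCarloSubsample:
    def test_full_size_subsample_equals_full_statistic(self, small_bundle, small_catalog):
        g = small_bundle.genomes
        n_pop = len(g.population_indices("African"))
        res = ps.monte_carlo_subsample(
            g, "African", n_pop, 5, seed=1,
            statistic=lambda s: float(vc.major_background(s).sum()),
        )
        full = float(vc.major_background(g.subset(g.population_indices("African"))).sum())
        assert np.allclose(res.replicates, full)

    def test_fixed_seed_reproduces_replicates(self, small_bundle, small_catalog):
        g = small_bundle.genomes
        r1 = ps.monte_carlo_category_maf(g, "non-African", small_catalog, 40, 20, seed=7)
        r2 = ps.monte_carlo_category_maf(g, "non-African", small_catalog, 40, 20, seed=7)
        for c in vc.CATEGORY_ORDER:
            assert np.array_equal(r1[c].replicates, r2[c].replicates, equal_nan=True)

    def test_oversized_subsample_is_an_error(self, small_bundle, small_catalog):
        with pytest.raises(ValueError, match="exceeds"):
            ps.monte_carlo_category_maf(small_bundle.genomes, "African",
                                        small_catalog, 1000, 2, seed=0)

    def test_fast_path_equals_generic_recomputation(self, small_bundle, small_catalog):
        """The vectorised Monte-Carlo path gives exactly the per-replicate
        values of the generic subsample-and-recompute path."""
        g = small_bundle.genomes
        lutmap = category_predicate_map(small_catalog)

        def statistic_for(category):
            def stat(sub):
                vals = [
                    m.pooled_freq
                    for site in vc.find_polymorphic_sites(sub)
                    for m in vc.call_minor_alleles(site)
                    if category in lutmap.get((m.position, m.base), ())
                ]
                return float(np.mean(vals)) if vals else float("nan")
            return stat

        fast = ps.monte_carlo_category_maf(g, "non-African", small_catalog,
                                           30, 10, seed=3)
        for category in ("synonymous", "nonsyn_damaging", "pathogenic_total"):
            generic = ps.monte_carlo_subsample(
                g, "non-African", 30, 10, seed=3, statistic=statistic_for(category)
            )
            assert np.allclose(fast[category].replicates, generic.replicates,
                               equal_nan=True, atol=1e-12)

    def test_monomorphic_sites_drop_out_of_subsamples(self):
        # allele carried by exactly one genome: subsamples without the
        # carrier see a monomorphic column and report no frequency
        cols = [("G", "A", "A", "A", "A", "A")]
        ags, cat = catalog_from_columns(cols, ["P"] * 6)
        res = ps.monte_carlo_category_maf(ags, "P", cat, 3, 200, seed=0)
        reps = res["other_noncoding"].replicates
        observed = reps[np.isfinite(reps)]
        assert np.all(observed == pytest.approx(1 / 3))
        assert np.isnan(reps).any()  # some subsamples miss the carrier


class TestMannWhitney:
    def test_fully_separated_exact(self):
        r = ps.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.U == 0
        assert r.p_value == pytest.approx(0.1, abs=1e-12)
        assert r.method == "exact"

    def test_complete_tie(self):
        r = ps.mann_whitney_u([1.0], [1.0])
        assert r.p_value == 1.0

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            ps.mann_whitney_u([], [1.0])

    def test_u_bounds_and_p_range(self, rng):
        for _ in range(10):
            x, y = rng.normal(size=20), rng.normal(size=35)
            r = ps.mann_whitney_u(x, y)
            assert 0 <= r.U <= len(x) * len(y)
            assert 0 < r.p_value <= 1

    def test_normal_approximation_accuracy_envelope(self):
        """True accuracy of the tie/continuity-corrected normal
        approximation at n1=n2=6: within 0.0062 of exact enumeration
        wherever the exact p <= 0.2, and within 0.016 everywhere."""
        for u in range(0, 19):
            pe = exact_mw_two_sided_p(u, 6, 6)
            pa = normal_mw_two_sided_p(u, 6, 6)
            assert abs(pe - pa) <= 0.016
            if pe <= 0.2:
                assert abs(pe - pa) <= 0.0062

    def test_asymptotic_matches_reference_formula(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6) + 0.5
        r = ps.mann_whitney_u(np.round(x, 6), np.round(y, 6))
        assert r.p_value == pytest.approx(normal_mw_two_sided_p(r.U, 6, 6), abs=1e-9) or \
            r.method == "exact"


class TestCategoryRatio:
    def test_equal_summaries_give_unity(self):
        r = ps.category_ratio((0.4, 0.01), (0.4, 0.01))
        assert r.ratio == 1.0

    def test_zero_error_limit(self):
        r = ps.category_ratio((2.0, 0.0), (1.0, 0.0))
        assert (r.ratio, r.se) == (2.0, 0.0)

    def test_error_propagation(self):
        r = ps.category_ratio((2.0, 0.2), (1.0, 0.1))
        expected = np.sqrt((0.2 / 1.0) ** 2 + (2.0 * 0.1 / 1.0) ** 2)
        assert r.se == pytest.approx(expected)

    def test_zero_denominator_flagged(self):
        r = ps.category_ratio((1.0, 0.1), (0.0, 0.0))
        assert not r.defined
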