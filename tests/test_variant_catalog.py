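"""Polymorphic sites, minor alleles, classification, annotation."""

import numpy as np
import pytest

from mitosurvey import variant_catalog as vc
from mitosurvey.io_formats import (
    AlignedGenomeSet,
    EffectAnnotation,
    GeneModel,
    PathogenicCatalogue,
)


def column_set(*cols, pops=None):
    """Build an alignment from per-column tuples (transposed)."""
    n = len(cols[0])
    seqs = ["".join(col[i] for col in cols) for i in range(n)]
    ids = [f"g{i}" for i in range(n)]
    pops = pops or {g: ("African" if i < n // 2 else "non-African")
                    for i, g in enumerate(ids)}
    return AlignedGenomeSet.from_sequences(ids, seqs, pops)


class TestFindPolymorphicSites:
    def test_basic_minor_call(self):
        ags = column_set(("A", "A", "A", "G"))
        (site,) = vc.find_polymorphic_sites(ags)
        assert site.major == "A" and site.minor_bases == ["G"]
        (minor,) = vc.call_minor_alleles(site)
        assert minor.pooled_freq == 0.25

    def test_missing_data_excluded_from_denominator(self):
        ags = column_set(("A", "A", "-", "G"))
        (site,) = vc.find_polymorphic_sites(ags)
        assert site.n_missing == 1
        (minor,) = vc.call_minor_alleles(site)
        assert minor.pooled_total == 3
        assert minor.pooled_freq == pytest.approx(1 / 3)

    def test_n_treated_like_gap(self):
        ags = column_set(("A", "A", "N", "G"))
        (site,) = vc.find_polymorphic_sites(ags)
        assert site.n_missing == 1

    def test_monomorphic_column_skipped(self):
        assert vc.find_polymorphic_sites(column_set(("A", "A", "A", "A"))) == []

    def test_tie_breaks_alphabetically(self):
        ags = column_set(("A", "A", "G", "G"))
        (site,) = vc.find_polymorphic_sites(ags)
        assert site.major == "A"
        (minor,) = vc.call_minor_alleles(site)
        assert minor.base == "G" and minor.pooled_freq == 0.5

    def test_multiallelic_yields_several_minors(self):
        ags = column_set(tuple("AAAAACCT"))
        (site,) = vc.find_polymorphic_sites(ags)
        minors = vc.call_minor_alleles(site)
        assert [(m.base, m.pooled_freq) for m in minors] == [("C", 0.25), ("T", 0.125)]

    def test_minor_freq_never_exceeds_major(self):
        rng = np.random.default_rng(1)
        M = rng.integers(0, 4, size=(12, 30)).astype(np.uint8)
        ags = AlignedGenomeSet([f"g{i}" for i in range(12)], M,
                               {f"g{i}": "A" if i < 6 else "B" for i in range(12)})
        for site in vc.find_polymorphic_sites(ags):
            major_count = site.counts.max()
            for m in vc.call_minor_alleles(site):
                assert m.pooled_count <= major_count


class TestClassifyEffect:
    def test_synonymous_third_position(self, tiny_alignment, tiny_genes):
        bg = vc.major_background(tiny_alignment)
        cmap = vc.CodingMap(tiny_genes, bg)
        assert cmap.classify(2, "C") == ("synonymous", False)

    def test_stop_gain_is_nonsynonymous(self, tiny_alignment, tiny_genes):
        # GGG -> AGG is a stop under the vertebrate mitochondrial code
        bg = vc.major_background(tiny_alignment)
        cmap = vc.CodingMap(tiny_genes, bg)
        assert cmap.classify(6, "A") == ("nonsynonymous", False)

    def test_trna_category(self, tiny_alignment, tiny_genes):
        bg = vc.major_background(tiny_alignment)
        cmap = vc.CodingMap(tiny_genes, bg)
        assert cmap.classify(10, "T") == ("tRNA", False)

    def test_fourfold_flag(self, tiny_alignment, tiny_genes):
        bg = vc.major_background(tiny_alignment)
        cmap = vc.CodingMap(tiny_genes, bg)
        # GGG third position is four-fold (GGN all Gly)
        assert cmap.classify(8, "A") == ("synonymous", True)

    def test_minus_strand_uses_complement(self):
        ags = column_set(*[(b, b, b, b) for b in "TTTAAA"])
        genes = [GeneModel("M", 0, 6, "-", "protein")]
        cmap = vc.CodingMap(genes, vc.major_background(ags))
        # '-' CDS = revcomp(TTTAAA) = TTTAAA; column 2 sits in codon AAA
        cat, _ = cmap.classify(2, "C")
        assert cat == "nonsynonymous"  # AAA(K) -> GAA(E) after complementing

    def test_gap_in_background_codon_is_unknown(self):
        ags = column_set(("A", "A", "A", "A"), ("-", "-", "-", "-"), ("A", "A", "A", "G"))
        genes = [GeneModel("G", 0, 3, "+", "protein")]
        cmap = vc.CodingMap(genes, vc.major_background(ags))
        assert cmap.classify(2, "G") == ("unknown-codon", False)

    def test_overlapping_genes_nonsynonymous_if_any(self):
        ags = column_set(*[(b, b, b, b) for b in "GGGGGG"])
        genes = [
            GeneModel("G1", 0, 6, "+", "protein"),
            GeneModel("G2", 3, 6, "+", "protein"),
        ]
        cmap = vc.CodingMap(genes, vc.major_background(ags))
        # GGG third position is four-fold in G1, but column 5 is also
        # third position of G2's GGG codon; both synonymous+fourfold
        assert cmap.classify(5, "A") == ("synonymous", True)
        # column 3: position 1 of G2's codon (nonsyn there) overrides
        assert cmap.classify(3, "A") == ("nonsynonymous", False)


class TestAttachAnnotations:
    def test_unlabelled_nonsynonymous_is_unknown(self, tiny_alignment, tiny_genes):
        cat = vc.build_catalog(tiny_alignment, tiny_genes)
        (ns,) = [m for m in cat.alleles if m.category == "nonsynonymous"]
        assert ns.effect == "unknown"

    def test_pathogenic_flag_and_compartment(self, tiny_alignment, tiny_genes):
        patho = PathogenicCatalogue(entries={(9, "T")})
        cat = vc.build_catalog(tiny_alignment, tiny_genes, pathogenic_catalogue=patho)
        (m,) = [a for a in cat.alleles if a.position == 9]
        assert m.pathogenic and m.pathogenic_compartment == "tRNA"
        assert m.category == "tRNA"

    def test_pathogenic_flag_is_cross_cutting(self, tiny_alignment, tiny_genes):
        patho = PathogenicCatalogue(entries={(2, "C")})
        cat = vc.build_catalog(tiny_alignment, tiny_genes, pathogenic_catalogue=patho)
        (m,) = [a for a in cat.alleles if a.position == 2]
        assert m.category == "synonymous" and m.pathogenic

    def test_orphan_annotations_ignored(self, tiny_alignment, tiny_genes):
        eff = EffectAnnotation({(0, "G"): "damaging"})  # not a detected minor
        patho = PathogenicCatalogue(entries={(0, "G")})
        cat = vc.build_catalog(tiny_alignment, tiny_genes, eff, patho)
        assert all(not m.pathogenic for m in cat.alleles)

    def test_effect_lookup(self, tiny_alignment, tiny_genes):
        eff = EffectAnnotation({(6, "A"): "damaging"})
        cat = vc.build_catalog(tiny_alignment, tiny_genes, eff)
        (m,) = [a for a in cat.alleles if a.position == 6]
        assert m.effect == "damaging"


class TestCatalogInvariants:
    def test_observation_conservation(self, small_bundle, small_catalog):
        """Summed per-population counts equal the planted realized counts."""
        man = small_bundle.manifest
        for pop in ("African", "non-African"):
            total_catalog = sum(m.pop_count[pop] for m in small_catalog.alleles)
            assert total_catalog == man[f"count_{pop}"].sum()

    def test_classification_invariant_under_reordering(self, small_bundle):
        b = small_bundle
        rng = np.random.default_rng(4)
        perm = rng.permutation(b.genomes.n_samples)
        shuffled = b.genomes.subset(perm)
        cat1 = vc.build_catalog(b.genomes, b.gene_models, b.effects, b.catalogue)
        cat2 = vc.build_catalog(shuffled, b.gene_models, b.effects, b.catalogue)
        key = lambda c: sorted(
            (m.position, m.base, m.category, m.fourfold, m.effect, m.pathogenic,
             m.pooled_count, tuple(sorted(m.pop_count.items())))
            for m in c.alleles
        )
        assert key(cat1) == key(cat2)

    def test_catalog_tsv_round_trip(self, small_catalog, tmp_path):
        p = tmp_path / "catalog.tsv"
        small_catalog.write_tsv(p)
        back = vc.VariantCatalog.from_tsv(
            p, small_catalog.populations, small_catalog.pop_sizes
        )
        orig = small_catalog.to_dataframe()
        assert back.to_dataframe().equals(orig)
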