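"""Polymorphic-site discovery, minor-allele calling and classification.

Minor alleles are defined on the pooled dataset (both populations
together) and then counted within each population, so the per-population
columns of the survey tables always refer to the same alleles. At each
polymorphic column the single major allele is the most frequent base
(ties broken alphabetically A<C<G<T); every other observed base is a
minor allele. Gaps and N are missing data: excluded from allele sets and
from frequency denominators.

Functional classification substitutes the minor base into the
major-allele background codon (strand-aware) and compares translations.
Synonymous changes at four-fold degenerate positions carry an extra
flag. A site inside overlapping protein genes is classified against
each gene and counted once, nonsynonymous-if-any.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import codon_engine as ce
from .io_formats import (
    AlignedGenomeSet,
    EffectAnnotation,
    GeneModel,
    PathogenicCatalogue,
    COMPLEMENT,
    N_BASES,
)

logger = logging.getLogger(__name__)

BASES = "ACGT"

#: categories a minor allele can fall into
CATEGORIES = (
    "synonymous",
    "nonsynonymous",
    "tRNA",
    "rRNA",
    "other-noncoding",
    "unknown-codon",
)


@dataclass
class SiteVariant:
    """One polymorphic alignment column."""

    position: int
    counts: np.ndarray                      # pooled counts over ACGT
    pop_counts: dict[str, np.ndarray]       # per-population counts over ACGT
    n_missing: int
    pop_missing: dict[str, int]
    major: str
    minor_bases: list[str]

    @property
    def n_called(self) -> int:
        return int(self.counts.sum())


@dataclass
class MinorAllele:
    """One (site, base) minor-allele observation with its annotations."""

    position: int
    base: str
    category: str = "other-noncoding"
    fourfold: bool = False
    effect: str = "n/a"                     # benign/damaging/unknown/n/a
    pathogenic: bool = False
    pathogenic_compartment: str | None = None  # coding/tRNA/rRNA/noncoding
    pooled_count: int = 0
    pooled_total: int = 0
    pop_count: dict[str, int] = field(default_factory=dict)
    pop_total: dict[str, int] = field(default_factory=dict)

    @property
    def pooled_freq(self) -> float:
        return self.pooled_count / self.pooled_total if self.pooled_total else float("nan")

    def pop_freq(self, population: str) -> float:
        tot = self.pop_total.get(population, 0)
        return self.pop_count.get(population, 0) / tot if tot else float("nan")


def allele_counts(genomes: AlignedGenomeSet) -> tuple[np.ndarray, np.ndarray]:
    """(4, L) pooled base counts and (L,) missing counts."""
    counts = np.stack([(genomes.matrix == b).sum(axis=0) for b in range(N_BASES)])
    missing = genomes.n_samples - counts.sum(axis=0)
    return counts, missing


def major_background(genomes: AlignedGenomeSet) -> np.ndarray:
    """Pooled major allele code per column (N where all genomes missing).

    argmax over the fixed A<C<G<T order implements the alphabetical
    tie-break.
    """
    counts, _ = allele_counts(genomes)
    major = counts.argmax(axis=0).astype(np.uint8)
    major[counts.sum(axis=0) == 0] = 4  # code for N
    return major


def find_polymorphic_sites(genomes: AlignedGenomeSet) -> list[SiteVariant]:
    """All alignment columns with >=2 distinct non-missing bases."""
    counts, missing = allele_counts(genomes)
    poly = np.flatnonzero((counts > 0).sum(axis=0) >= 2)
    pop_counts_all: dict[str, np.ndarray] = {}
    pop_n: dict[str, int] = {}
    for label in genomes.populations:
        idx = genomes.population_indices(label)
        sub = genomes.matrix[idx][:, poly]
        pop_counts_all[label] = np.stack([(sub == b).sum(axis=0) for b in range(N_BASES)])
        pop_n[label] = len(idx)
    sites: list[SiteVariant] = []
    for k, pos in enumerate(poly):
        c = counts[:, pos]
        major_idx = int(c.argmax())
        minors = [BASES[b] for b in range(N_BASES) if c[b] > 0 and b != major_idx]
        pcounts = {lab: pop_counts_all[lab][:, k].copy() for lab in pop_counts_all}
        pmissing = {lab: pop_n[lab] - int(pcounts[lab].sum()) for lab in pcounts}
        sites.append(
            SiteVariant(
                position=int(pos),
                counts=c.copy(),
                pop_counts=pcounts,
                n_missing=int(missing[pos]),
                pop_missing=pmissing,
                major=BASES[major_idx],
                minor_bases=minors,
            )
        )
    return sites


def call_minor_alleles(site: SiteVariant) -> list[MinorAllele]:
    """Every observed allele except the single major one, with counts."""
    total = site.n_called
    out = []
    for base in site.minor_bases:
        b = BASES.index(base)
        out.append(
            MinorAllele(
                position=site.position,
                base=base,
                pooled_count=int(site.counts[b]),
                pooled_total=total,
                pop_count={lab: int(c[b]) for lab, c in site.pop_counts.items()},
                pop_total={lab: int(c.sum()) for lab, c in site.pop_counts.items()},
            )
        )
    return out


class CodingMap:
    """Per-position functional context against a fixed background sequence.

    The background is the pooled major allele at every column (the
    standard convention for evaluating degeneracy and coding effect).
    """

    def __init__(self, gene_models: list[GeneModel], background: np.ndarray,
                 code: ce.GeneticCode | None = None):
        self.background = np.asarray(background, dtype=np.uint8)
        self.code = code or ce.default_code()
        L = len(self.background)
        self.protein_at: list[list[GeneModel]] = [[] for _ in range(L)]
        self.feature_at = np.zeros(L, dtype=np.uint8)  # 0 none, 1 protein, 2 tRNA, 3 rRNA
        for g in gene_models:
            if g.end > L:
                raise ValueError(f"gene {g.name} extends past alignment length {L}")
            if g.feature == "protein":
                for p in range(g.start, g.end):
                    self.protein_at[p].append(g)
                self.feature_at[g.start:g.end] = np.maximum(self.feature_at[g.start:g.end], 1)
            else:
                fcode = 2 if g.feature == "tRNA" else 3
                sl = self.feature_at[g.start:g.end]
                sl[sl == 0] = fcode
        self._overlap_logged: set[int] = set()

    # -- codon extraction -------------------------------------------------
    def codon_at(self, gene: GeneModel, position: int) -> tuple[str, int]:
        """Background codon containing `position` in `gene`, plus the
        0-based position of `position` within that codon (strand-aware)."""
        if gene.strand == "+":
            off = position - gene.start
            ci, cp = divmod(off, 3)
            cols = [gene.start + 3 * ci + k for k in range(3)]
            codes = [self.background[c] if c < gene.end else 4 for c in cols]
        else:
            off = gene.end - 1 - position
            ci, cp = divmod(off, 3)
            cols = [gene.end - 1 - 3 * ci - k for k in range(3)]
            codes = [
                COMPLEMENT[self.background[c]] if c >= gene.start else 4 for c in cols
            ]
        codon = "".join("ACGTN-"[b] for b in codes)
        return codon, cp

    def _classify_in_gene(self, gene: GeneModel, position: int, base: str):
        codon, cp = self.codon_at(gene, position)
        sub = base if gene.strand == "+" else "ACGTN-"[COMPLEMENT["ACGT".index(base)]]
        if not ce.is_resolved(codon):
            return "unknown-codon", False
        mutant = codon[:cp] + sub + codon[cp + 1:]
        aa0 = ce.translate_codon(codon, self.code)
        aa1 = ce.translate_codon(mutant, self.code)
        if aa0 == aa1:
            if self.code.is_stop(codon):
                # stop-to-stop background: no degeneracy class defined
                return "synonymous", False
            deg = ce.degeneracy_class(codon, cp + 1, self.code)
            return "synonymous", deg == 4
        return "nonsynonymous", False

    def classify(self, position: int, base: str) -> tuple[str, bool]:
        """Category and four-fold flag for a minor allele at a column.

        Overlapping protein genes: classified against each, counted once,
        nonsynonymous-if-any; four-fold only if four-fold in every frame.
        """
        genes = self.protein_at[position]
        if genes:
            if len(genes) > 1 and position not in self._overlap_logged:
                logger.info(
                    "position %d lies in overlapping protein genes %s (nonsynonymous-if-any)",
                    position + 1, [g.name for g in genes],
                )
                self._overlap_logged.add(position)
            results = [self._classify_in_gene(g, position, base) for g in genes]
            if any(cat == "nonsynonymous" for cat, _ in results):
                return "nonsynonymous", False
            if all(cat == "unknown-codon" for cat, _ in results):
                return "unknown-codon", False
            known = [r for r in results if r[0] == "synonymous"]
            return "synonymous", all(ff for _, ff in known)
        f = self.feature_at[position]
        if f == 2:
            return "tRNA", False
        if f == 3:
            return "rRNA", False
        return "other-noncoding", False

    def compartment(self, position: int) -> str:
        if self.protein_at[position]:
            return "coding"
        f = self.feature_at[position]
        return {2: "tRNA", 3: "rRNA"}.get(int(f), "noncoding")

    def fourfold_positions(self) -> np.ndarray:
        """Alignment columns that are four-fold degenerate on the background."""
        out = []
        for pos in range(len(self.background)):
            genes = self.protein_at[pos]
            if not genes:
                continue
            degs = []
            for g in genes:
                codon, cp = self.codon_at(g, pos)
                if not ce.is_resolved(codon) or self.code.is_stop(codon):
                    degs.append(0)
                else:
                    degs.append(ce.degeneracy_class(codon, cp + 1, self.code))
            if degs and all(d == 4 for d in degs):
                out.append(pos)
        return np.asarray(out, dtype=np.intp)


def classify_effect(
    position: int,
    base: str,
    gene_models: list[GeneModel],
    background: np.ndarray,
    code: ce.GeneticCode | None = None,
) -> tuple[str, bool]:
    """Convenience one-shot classification (builds a CodingMap)."""
    return CodingMap(gene_models, background, code).classify(position, base)


def attach_annotations(
    minors: list[MinorAllele],
    effect_annotation: EffectAnnotation,
    pathogenic_catalogue: PathogenicCatalogue,
    coding_map: CodingMap,
) -> list[MinorAllele]:
    """Attach effect labels and the cross-cutting pathogenic flag.

    Nonsynonymous minors missing from the annotation are 'unknown'.
    The pathogenic flag is independent of category (a synonymous minor
    in the catalogue stays synonymous but is flagged).
    """
    called = {(m.position, m.base) for m in minors}
    for m in minors:
        if m.category == "nonsynonymous":
            m.effect = effect_annotation.lookup(m.position, m.base)
        else:
            m.effect = "n/a"
        if pathogenic_catalogue.contains(m.position, m.base):
            m.pathogenic = True
            m.pathogenic_compartment = coding_map.compartment(m.position)
    orphans = [e for e in effect_annotation.entries if e not in called]
    if orphans:
        logger.info("effect annotation: %d entries are not detected minor alleles (ignored)",
                    len(orphans))
    orphans_p = [e for e in pathogenic_catalogue.entries if e not in called]
    if orphans_p:
        logger.info("pathogenic catalogue: %d entries are not detected minor alleles (ignored)",
                    len(orphans_p))
    return minors


@dataclass
class VariantCatalog:
    """All minor alleles of a survey plus the context used to build them."""

    alleles: list[MinorAllele]
    populations: list[str]
    pop_sizes: dict[str, int]
    n_polymorphic_sites: int
    n_unknown_codon: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for m in self.alleles:
            row = {
                "position": m.position + 1,
                "base": m.base,
                "category": m.category,
                "fourfold": int(m.fourfold),
                "effect": m.effect,
                "pathogenic": int(m.pathogenic),
                "compartment": m.pathogenic_compartment or "",
                "pooled_count": m.pooled_count,
                "pooled_total": m.pooled_total,
            }
            for lab in self.populations:
                row[f"count_{lab}"] = m.pop_count.get(lab, 0)
                row[f"total_{lab}"] = m.pop_total.get(lab, 0)
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, populations: list[str], pop_sizes: dict[str, int]) -> "VariantCatalog":
        # keep_default_na: the 'n/a' effect label must survive round-trips
        df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
        alleles = []
        for _, r in df.iterrows():
            alleles.append(
                MinorAllele(
                    position=int(r["position"]) - 1,
                    base=str(r["base"]),
                    category=str(r["category"]),
                    fourfold=bool(r["fourfold"]),
                    effect=str(r["effect"]),
                    pathogenic=bool(r["pathogenic"]),
                    pathogenic_compartment=(str(r["compartment"]) or None)
                    if isinstance(r["compartment"], str) and r["compartment"] else None,
                    pooled_count=int(r["pooled_count"]),
                    pooled_total=int(r["pooled_total"]),
                    pop_count={lab: int(r[f"count_{lab}"]) for lab in populations},
                    pop_total={lab: int(r[f"total_{lab}"]) for lab in populations},
                )
            )
        n_sites = len({m.position for m in alleles})
        n_unk = sum(m.category == "unknown-codon" for m in alleles)
        return cls(alleles, populations, pop_sizes, n_sites, n_unk)


def build_catalog(
    genomes: AlignedGenomeSet,
    gene_models: list[GeneModel],
    effect_annotation: EffectAnnotation | None = None,
    pathogenic_catalogue: PathogenicCatalogue | None = None,
    code: ce.GeneticCode | None = None,
) -> VariantCatalog:
    """Run the full catalogue construction on a labelled alignment."""
    effect_annotation = effect_annotation or EffectAnnotation()
    pathogenic_catalogue = pathogenic_catalogue or PathogenicCatalogue()
    background = major_background(genomes)
    cmap = CodingMap(gene_models, background, code)
    sites = find_polymorphic_sites(genomes)
    minors: list[MinorAllele] = []
    for site in sites:
        for m in call_minor_alleles(site):
            m.category, m.fourfold = cmap.classify(m.position, m.base)
            minors.append(m)
    attach_annotations(minors, effect_annotation, pathogenic_catalogue, cmap)
    n_unknown = sum(m.category == "unknown-codon" for m in minors)
    if n_unknown:
        logger.info("%d minor alleles fall in unresolved background codons "
                    "(excluded from syn/nonsyn tallies)", n_unknown)
    return VariantCatalog(
        alleles=minors,
        populations=genomes.populations,
        pop_sizes={lab: len(genomes.population_indices(lab)) for lab in genomes.populations},
        n_polymorphic_sites=len(sites),
        n_unknown_codon=n_unknown,
    )


# ---------------------------------------------------------------------------
# category predicates shared by the reporting layers
# ---------------------------------------------------------------------------

CATEGORY_PREDICATES = {
    "synonymous": lambda m: m.category == "synonymous",
    "fourfold": lambda m: m.category == "synonymous" and m.fourfold,
    "nonsynonymous": lambda m: m.category == "nonsynonymous",
    "nonsyn_unknown": lambda m: m.category == "nonsynonymous" and m.effect == "unknown",
    "nonsyn_benign": lambda m: m.category == "nonsynonymous" and m.effect == "benign",
    "nonsyn_damaging": lambda m: m.category == "nonsynonymous" and m.effect == "damaging",
    "tRNA": lambda m: m.category == "tRNA",
    "rRNA": lambda m: m.category == "rRNA",
    "other_noncoding": lambda m: m.category == "other-noncoding",
    "pathogenic_total": lambda m: m.pathogenic,
    "pathogenic_coding": lambda m: m.pathogenic and m.pathogenic_compartment == "coding",
    "pathogenic_tRNA": lambda m: m.pathogenic and m.pathogenic_compartment == "tRNA",
    "pathogenic_rRNA": lambda m: m.pathogenic and m.pathogenic_compartment == "rRNA",
}

CATEGORY_ORDER = list(CATEGORY_PREDICATES)


def category_predicate_map(catalog: VariantCatalog) -> dict[tuple[int, str], tuple[str, ...]]:
    """(position, base) -> categories the pooled catalogue assigns it."""
    out: dict[tuple[int, str], tuple[str, ...]] = {}
    for m in catalog.alleles:
        cats = tuple(c for c in CATEGORY_ORDER if CATEGORY_PREDICATES[c](m))
        out[(m.position, m.base)] = cats
    return out


def select_alleles(catalog: VariantCatalog, category: str) -> list[MinorAllele]:
    try:
        pred = CATEGORY_PREDICATES[category]
    except KeyError:
        raise KeyError(f"unknown category {category!r}; known: {CATEGORY_ORDER}") from None
    return [m for m in catalog.alleles if pred(m)]
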