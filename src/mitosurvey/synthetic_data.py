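"""Synthetic input bundles with a known planted truth.

The generator emulates the statistical structure of a two-population
survey of complete mtDNA genomes: an African-like population with
higher minor-allele frequencies across neutral-ish categories, a much
larger non-African-like population with lower frequencies, and a
pathogenic-variant catalogue whose composition is governed by an
ascertainment knob.

Ascertainment knob
------------------
Real pathogenic catalogues are built from disease studies performed
mostly in non-African cohorts, so they over-represent variants that are
(a) segregating in the non-African population and (b) common enough
there to be seen in patients. Under the default
``non_african_biased`` rule the planted pathogenic category therefore
puts zero mass on African-private variants and draws its non-African
frequencies from a strongly right-skewed distribution (a few common
"founder" pathogenic variants dominate, most entries are rare reports).
Under ``unbiased`` the pathogenic category behaves like any damaging
variant. Everything planted is recorded in a truth manifest, including
the realized per-population carrier counts, so tests compare estimates
against realized truth rather than target parameters.

Variants are planted independently (no linkage or haplogroup
structure), at most one per alignment column, and never as stop-gain
changes; carriers are drawn by binomial sampling at the target
frequency.
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
    write_alignment,
    write_effect_annotation,
    write_gene_models,
    write_pathogenic_catalogue,
    write_sample_metadata,
)
from .variant_catalog import CodingMap, major_background

logger = logging.getLogger(__name__)

AFRICAN = "African"
NON_AFRICAN = "non-African"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class FrequencySpec:
    """Parametric minor-allele frequency distribution for one category
    in one population: a point mass, uniform(low, high), or a Beta with
    given mean and shape alpha (beta = alpha*(1-mean)/mean). Draws are
    truncated to (0, 0.4] so the planted allele always stays minor."""

    kind: str = "beta"          # beta | point | uniform
    mean: float = 0.01
    alpha: float = 0.8
    low: float = 0.0
    high: float = 0.0

    MAX_FREQ = 0.4

    def sample(self, rng: np.random.Generator) -> float:
        for _ in range(200):
            if self.kind == "point":
                f = self.mean
            elif self.kind == "uniform":
                f = rng.uniform(self.low, self.high)
            elif self.kind == "beta":
                b = self.alpha * (1.0 - self.mean) / self.mean
                f = rng.beta(self.alpha, b)
            else:
                raise SimulationError(f"unknown frequency kind {self.kind!r}")
            if 0.0 < f <= self.MAX_FREQ:
                return float(f)
            if self.kind == "point":
                raise SimulationError(f"point frequency {self.mean} outside (0, {self.MAX_FREQ}]")
        return self.MAX_FREQ


@dataclass(frozen=True)
class CategoryPlan:
    """How many variants of one category to plant and how they are
    distributed across populations.

    ``presence`` = probabilities of (shared, African-private,
    non-African-private). ``effect_label`` writes rows into the effect
    annotation; ``compartments`` (pathogenic only) splits the category
    across coding/tRNA/rRNA contexts.
    """

    name: str
    count: int
    freq_african: FrequencySpec
    freq_non_african: FrequencySpec
    presence: tuple[float, float, float] = (0.5, 0.25, 0.25)
    effect_label: str | None = None
    pathogenic: bool = False
    compartments: tuple[tuple[str, float], ...] = ()


@dataclass
class SimulationSpec:
    """Complete description of one synthetic study."""

    genome_length: int = 16569
    n_african: int = 401
    n_non_african: int = 4057
    gene_models: list[GeneModel] | None = None
    categories: list[CategoryPlan] = field(default_factory=list)
    pathogenic_rule: str = "non_african_biased"   # or "unbiased"
    seed: int = 0

    @property
    def n_total(self) -> int:
        return self.n_african + self.n_non_african


def _beta(mean: float, alpha: float) -> FrequencySpec:
    return FrequencySpec("beta", mean=mean, alpha=alpha)


#: frequency contrasts used by default: African-like means a few-fold
#: above non-African-like means for every category except pathogenic.
_DEFAULT_PLANS = [
    ("synonymous", 250, _beta(0.027, 0.8), _beta(0.0040, 0.8), None),
    ("fourfold", 250, _beta(0.029, 0.8), _beta(0.0039, 0.8), None),
    ("benign", 250, _beta(0.026, 0.8), _beta(0.0042, 0.8), "benign"),
    ("damaging", 250, _beta(0.0089, 0.8), _beta(0.00082, 0.8), "damaging"),
    ("nonsyn_unknown", 12, _beta(0.026, 0.8), _beta(0.0042, 0.8), None),
    ("trna", 200, _beta(0.027, 0.8), _beta(0.0040, 0.8), None),
    ("rrna", 200, _beta(0.027, 0.8), _beta(0.0040, 0.8), None),
    ("noncoding", 200, _beta(0.027, 0.8), _beta(0.0040, 0.8), None),
]

_PATHOGENIC_COMPARTMENTS = (("coding", 0.6), ("tRNA", 0.3), ("rRNA", 0.1))


def default_category_plans(pathogenic_rule: str = "non_african_biased",
                           scale: float = 1.0) -> list[CategoryPlan]:
    plans = [
        CategoryPlan(
            name=name,
            count=max(1, int(round(count * scale))),
            freq_african=fa,
            freq_non_african=fn,
            effect_label=eff,
        )
        for name, count, fa, fn, eff in _DEFAULT_PLANS
    ]
    if pathogenic_rule == "non_african_biased":
        plans.append(
            CategoryPlan(
                name="pathogenic",
                count=max(1, int(round(200 * scale))),
                freq_african=_beta(0.0077, 1.0),
                freq_non_african=_beta(0.0037, 0.08),
                presence=(0.3, 0.0, 0.7),
                effect_label="damaging",
                pathogenic=True,
                compartments=_PATHOGENIC_COMPARTMENTS,
            )
        )
    elif pathogenic_rule == "unbiased":
        plans.append(
            CategoryPlan(
                name="pathogenic",
                count=max(1, int(round(200 * scale))),
                freq_african=_beta(0.0089, 0.8),
                freq_non_african=_beta(0.00082, 0.8),
                presence=(0.5, 0.25, 0.25),
                effect_label="damaging",
                pathogenic=True,
                compartments=_PATHOGENIC_COMPARTMENTS,
            )
        )
    else:
        raise SimulationError(f"unknown pathogenic rule {pathogenic_rule!r}")
    return plans


# mtDNA-like default gene layout ---------------------------------------------

_PROTEIN_LENGTHS = [957, 1041, 1542, 684, 207, 681, 783, 345, 297, 1377, 1812, 525, 1140]
_TRNA_LEN = 69


def build_default_gene_models(genome_length: int = 16569) -> list[GeneModel]:
    """A simplified mtDNA-like layout: a control region, two rRNAs, 22
    tRNAs and 13 protein genes (one protein gene and three tRNAs on the
    minus strand), with trailing non-coding sequence."""
    models: list[GeneModel] = []
    cur = 576  # control region
    def place(name, length, feature, strand="+"):
        nonlocal cur
        models.append(GeneModel(name, cur, cur + length, strand, feature))
        cur += length
    place("RNR1", 954, "rRNA")
    place("TRN1", _TRNA_LEN, "tRNA")
    place("RNR2", 1558, "rRNA")
    minus_trnas = {5, 11, 17}
    t = 2
    for i, plen in enumerate(_PROTEIN_LENGTHS):
        strand = "-" if i == 11 else "+"
        place(f"PG{i + 1:02d}", plen, "protein", strand)
        # distribute the remaining 21 tRNAs after protein genes
        n_t = 2 if i < 8 else 1
        for _ in range(n_t):
            if t <= 22:
                place(f"TRN{t}", _TRNA_LEN, "tRNA", "-" if t in minus_trnas else "+")
                t += 1
    if cur > genome_length:
        raise SimulationError(
            f"gene layout needs {cur} bp but genome_length is {genome_length}"
        )
    return models


def build_toy_gene_models(genome_length: int = 3000) -> list[GeneModel]:
    """Compact layout for small test genomes: one rRNA, two tRNAs and
    two protein genes (the second on the minus strand)."""
    if genome_length < 1200:
        raise SimulationError("toy layout needs >= 1200 bp")
    return [
        GeneModel("RNR1", 100, 400, "+", "rRNA"),
        GeneModel("TRN1", 400, 469, "+", "tRNA"),
        GeneModel("PG1", 470, 470 + 450, "+", "protein"),
        GeneModel("TRN2", 930, 999, "-", "tRNA"),
        GeneModel("PG2", 1000, 1000 + 150, "-", "protein"),
    ]


def default_simulation_spec(
    n_african: int = 401,
    n_non_african: int = 4057,
    genome_length: int = 16569,
    pathogenic_rule: str = "non_african_biased",
    seed: int = 0,
    variant_scale: float = 1.0,
) -> SimulationSpec:
    """The standard study conditions: 401 vs 4057 genomes, mtDNA-sized
    alignment, per-category frequency contrasts a few-fold higher in the
    African-like population."""
    return SimulationSpec(
        genome_length=genome_length,
        n_african=n_african,
        n_non_african=n_non_african,
        gene_models=build_default_gene_models(genome_length),
        categories=default_category_plans(pathogenic_rule, variant_scale),
        pathogenic_rule=pathogenic_rule,
        seed=seed,
    )


def small_simulation_spec(seed: int = 0, pathogenic_rule: str = "non_african_biased",
                          n_african: int = 40, n_non_african: int = 120) -> SimulationSpec:
    """A fast, small-genome variant of the default study for tests and
    demos (frequencies scaled up so variants segregate in tiny samples)."""
    plans = [
        CategoryPlan("synonymous", 10, _beta(0.15, 2), _beta(0.05, 2)),
        CategoryPlan("fourfold", 10, _beta(0.15, 2), _beta(0.05, 2)),
        CategoryPlan("benign", 8, _beta(0.15, 2), _beta(0.05, 2), effect_label="benign"),
        CategoryPlan("damaging", 8, _beta(0.08, 2), _beta(0.02, 2), effect_label="damaging"),
        CategoryPlan("trna", 6, _beta(0.15, 2), _beta(0.05, 2)),
        CategoryPlan("rrna", 6, _beta(0.15, 2), _beta(0.05, 2)),
        CategoryPlan("noncoding", 6, _beta(0.15, 2), _beta(0.05, 2)),
        CategoryPlan(
            "pathogenic", 8, _beta(0.08, 2), _beta(0.08, 0.5),
            presence=(0.4, 0.0, 0.6) if pathogenic_rule == "non_african_biased" else (0.5, 0.25, 0.25),
            effect_label="damaging", pathogenic=True,
            compartments=_PATHOGENIC_COMPARTMENTS,
        ),
    ]
    return SimulationSpec(
        genome_length=3000,
        n_african=n_african,
        n_non_african=n_non_african,
        gene_models=build_toy_gene_models(3000),
        categories=plans,
        pathogenic_rule=pathogenic_rule,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_reference(spec: SimulationSpec, rng: np.random.Generator | None = None):
    """Random reference with stop-free protein genes on their own strand."""
    rng = rng or np.random.default_rng(spec.seed)
    code = ce.default_code()
    gene_models = spec.gene_models or build_default_gene_models(spec.genome_length)
    for g in gene_models:
        if g.end > spec.genome_length:
            raise SimulationError(f"gene {g.name} overflows genome length {spec.genome_length}")
    ref = rng.integers(0, 4, size=spec.genome_length).astype(np.uint8)
    _, _, usable = code.site_arrays()
    sense_ids = np.flatnonzero(usable)
    for g in gene_models:
        if g.feature != "protein":
            continue
        n_codons = g.length // 3
        ids = rng.choice(sense_ids, size=n_codons)
        bases = np.stack([ids // 16, (ids // 4) % 4, ids % 4], axis=1).reshape(-1).astype(np.uint8)
        if g.strand == "-":
            bases = (3 - bases)[::-1]  # reverse complement
        ref[g.start:g.start + 3 * n_codons] = bases
    return ref, gene_models


@dataclass
class PlantedVariant:
    position: int
    base: str
    category: str
    fourfold: bool
    effect: str | None
    pathogenic: bool
    compartment: str | None
    presence: str                 # shared | african_private | non_african_private
    target_freq: dict[str, float]
    count: dict[str, int] = field(default_factory=dict)


@dataclass
class SyntheticBundle:
    spec: SimulationSpec
    genomes: AlignedGenomeSet
    gene_models: list[GeneModel]
    effects: EffectAnnotation
    catalogue: PathogenicCatalogue
    variants: list[PlantedVariant]
    reference: np.ndarray

    @property
    def manifest(self) -> pd.DataFrame:
        rows = []
        for v in self.variants:
            rows.append(
                {
                    "position": v.position + 1,
                    "base": v.base,
                    "category": v.category,
                    "fourfold": int(v.fourfold),
                    "effect": v.effect or "",
                    "pathogenic": int(v.pathogenic),
                    "compartment": v.compartment or "",
                    "presence": v.presence,
                    f"target_freq_{AFRICAN}": v.target_freq[AFRICAN],
                    f"target_freq_{NON_AFRICAN}": v.target_freq[NON_AFRICAN],
                    f"count_{AFRICAN}": v.count[AFRICAN],
                    f"count_{NON_AFRICAN}": v.count[NON_AFRICAN],
                }
            )
        return pd.DataFrame(rows)


_EXPECTED_CLASS = {
    "synonymous": ("synonymous", False),
    "fourfold": ("synonymous", True),
    "benign": ("nonsynonymous", False),
    "damaging": ("nonsynonymous", False),
    "nonsyn_unknown": ("nonsynonymous", False),
    "trna": ("tRNA", False),
    "rrna": ("rRNA", False),
    "noncoding": ("other-noncoding", False),
}


def _eligibility_pools(ref: np.ndarray, gene_models: list[GeneModel], code) -> dict:
    """position -> eligible alternate bases, per planting category."""
    cmap = CodingMap(gene_models, ref, code)
    pools: dict[str, dict[int, list[str]]] = {
        "synonymous": {}, "fourfold": {}, "nonsynonymous": {},
        "trna": {}, "rrna": {}, "noncoding": {},
    }
    L = len(ref)
    for pos in range(L):
        refbase = "ACGTN-"[ref[pos]]
        alts = [b for b in "ACGT" if b != refbase]
        if cmap.protein_at[pos]:
            for alt in alts:
                cat, ff = cmap.classify(pos, alt)
                if cat == "synonymous":
                    pools["fourfold" if ff else "synonymous"].setdefault(pos, []).append(alt)
                elif cat == "nonsynonymous" and not _is_stop_gain(cmap, pos, alt):
                    pools["nonsynonymous"].setdefault(pos, []).append(alt)
        else:
            key = {"tRNA": "trna", "rRNA": "rrna", "noncoding": "noncoding"}[
                cmap.compartment(pos)
            ]
            pools[key][pos] = alts
    return pools


def _is_stop_gain(cmap: CodingMap, pos: int, alt: str) -> bool:
    from .io_formats import COMPLEMENT
    for g in cmap.protein_at[pos]:
        codon, cp = cmap.codon_at(g, pos)
        sub = alt if g.strand == "+" else "ACGTN-"[COMPLEMENT["ACGT".index(alt)]]
        mutant = codon[:cp] + sub + codon[cp + 1:]
        if ce.is_resolved(mutant) and cmap.code.is_stop(mutant):
            return True
    return False


_POOL_OF = {
    "synonymous": "synonymous",
    "fourfold": "fourfold",
    "benign": "nonsynonymous",
    "damaging": "nonsynonymous",
    "nonsyn_unknown": "nonsynonymous",
    "trna": "trna",
    "rrna": "rrna",
    "noncoding": "noncoding",
}

_PRESENCE = ("shared", "african_private", "non_african_private")


def plant_variants(spec: SimulationSpec, reference=None, gene_models=None):
    """Generate the aligned genomes, annotations and truth manifest.

    Returns a :class:`SyntheticBundle`. Every planted variant's category
    is re-verified with the production classifier against the pooled
    major-allele background; a mismatch raises (it would mean the
    planted truth and the analysis disagree).
    """
    rng = np.random.default_rng(spec.seed)
    code = ce.default_code()
    if reference is None:
        reference, gene_models = generate_reference(spec, rng)
    pools = _eligibility_pools(reference, gene_models, code)

    used: set[int] = set()
    variants: list[PlantedVariant] = []
    for plan in spec.categories:
        sub_plans: list[tuple[str, int, str | None]]
        if plan.compartments:
            counts = _split_count(plan.count, [f for _, f in plan.compartments])
            comp_pool = {"coding": "nonsynonymous", "tRNA": "trna", "rRNA": "rrna"}
            sub_plans = [
                (comp_pool[comp], k, comp)
                for (comp, _), k in zip(plan.compartments, counts)
            ]
        else:
            sub_plans = [(_POOL_OF[plan.name], plan.count, None)]
        for pool_name, count, compartment in sub_plans:
            pool = pools[pool_name]
            avail = sorted(p for p in pool if p not in used)
            if len(avail) < count:
                raise SimulationError(
                    f"category {plan.name!r}: need {count} positions in pool "
                    f"{pool_name!r} but only {len(avail)} eligible remain"
                )
            chosen = rng.choice(len(avail), size=count, replace=False)
            for ci in np.sort(chosen):
                pos = avail[int(ci)]
                used.add(pos)
                alts = pool[pos]
                base = alts[int(rng.integers(len(alts)))]
                presence = _PRESENCE[int(rng.choice(3, p=plan.presence))]
                fa = plan.freq_african.sample(rng) if presence != "non_african_private" else 0.0
                fn = plan.freq_non_african.sample(rng) if presence != "african_private" else 0.0
                # effect labels only make sense for amino-acid-changing variants
                in_coding = compartment == "coding" or (
                    compartment is None and _POOL_OF[plan.name] == "nonsynonymous"
                )
                variants.append(
                    PlantedVariant(
                        position=pos,
                        base=base,
                        category=plan.name,
                        fourfold=plan.name == "fourfold",
                        effect=plan.effect_label if in_coding else None,
                        pathogenic=plan.pathogenic,
                        compartment=compartment,
                        presence=presence,
                        target_freq={AFRICAN: fa, NON_AFRICAN: fn},
                    )
                )

    # realize carriers
    nA, nN = spec.n_african, spec.n_non_african
    matrix = np.tile(reference, (spec.n_total, 1))
    pop_slices = {AFRICAN: (0, nA), NON_AFRICAN: (nA, nA + nN)}
    for v in variants:
        bcode = "ACGT".index(v.base)
        for label, (lo, hi) in pop_slices.items():
            f = v.target_freq[label]
            n_pop = hi - lo
            count = int(rng.binomial(n_pop, f)) if f > 0 else 0
            count = min(count, int(0.45 * n_pop))  # keep the allele minor
            if count:
                rows = lo + rng.choice(n_pop, size=count, replace=False)
                matrix[rows, v.position] = bcode
            v.count[label] = count

    ids = [f"AFR{i + 1:05d}" for i in range(nA)] + [f"NAF{i + 1:05d}" for i in range(nN)]
    pop_of = {s: (AFRICAN if s.startswith("AFR") else NON_AFRICAN) for s in ids}
    genomes = AlignedGenomeSet(ids, matrix, pop_of)

    # annotations
    effects = EffectAnnotation()
    for v in variants:
        if v.effect in ("benign", "damaging"):
            effects.entries[(v.position, v.base)] = v.effect
    catalogue = PathogenicCatalogue()
    statuses = ("Reported", "Confirmed")
    k = 0
    for v in variants:
        if v.pathogenic:
            catalogue.entries.add((v.position, v.base))
            catalogue.status_of[(v.position, v.base)] = statuses[k % 2]
            k += 1

    _verify_planted_categories(variants, genomes, gene_models, code)
    return SyntheticBundle(spec, genomes, gene_models, effects, catalogue, variants, reference)


def _split_count(total: int, fractions: list[float]) -> list[int]:
    counts = [int(round(total * f)) for f in fractions]
    counts[0] += total - sum(counts)
    return counts


def _verify_planted_categories(variants, genomes, gene_models, code) -> None:
    background = major_background(genomes)
    cmap = CodingMap(gene_models, background, code)
    for v in variants:
        if v.compartment is not None:
            expected = {"coding": ("nonsynonymous", False), "tRNA": ("tRNA", False),
                        "rRNA": ("rRNA", False)}[v.compartment]
        else:
            expected = _EXPECTED_CLASS[v.category]
        got = cmap.classify(v.position, v.base)
        if got != expected:
            raise SimulationError(
                f"planted variant at {v.position + 1}{v.base} classifies as {got}, "
                f"expected {expected} ({v.category})"
            )


def generate_bundle(spec: SimulationSpec) -> SyntheticBundle:
    """Reference + planted variants in one call (deterministic per seed)."""
    return plant_variants(spec)


# ---------------------------------------------------------------------------
# on-disk bundle
# ---------------------------------------------------------------------------

BUNDLE_FILES = {
    "alignment": "alignment.fasta",
    "metadata": "samples.tsv",
    "genes": "genes.gff3",
    "effects": "effects.tsv",
    "pathogenic": "pathogenic.tsv",
    "manifest": "truth_manifest.tsv",
}


def write_bundle(bundle: SyntheticBundle, outdir, decoys: bool = True) -> dict[str, str]:
    """Write all pipeline input files (plus the truth manifest).

    ``decoys`` adds two catalogue rows with non-usable statuses so the
    reader's Reported/Confirmed filter is exercised on every bundle;
    they do not change the parsed catalogue.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {k: os.path.join(outdir, v) for k, v in BUNDLE_FILES.items()}
    write_alignment(paths["alignment"], bundle.genomes)
    write_sample_metadata(paths["metadata"], bundle.genomes.population_of)
    write_gene_models(paths["genes"], bundle.gene_models)
    write_effect_annotation(paths["effects"], bundle.effects)
    extra = None
    if decoys:
        nonvariant = next(
            p for p in range(bundle.spec.genome_length)
            if all(v.position != p for v in bundle.variants)
        )
        refbase = "ACGTN-"[bundle.reference[nonvariant]]
        alt = next(b for b in "ACGT" if b != refbase)
        extra = [
            {"position": nonvariant + 1, "alt_base": alt, "status": "Unclear"},
            {"position": nonvariant + 1, "alt_base": alt, "status": "Provisional"},
        ]
    write_pathogenic_catalogue(paths["pathogenic"], bundle.catalogue, extra_rows=extra)
    bundle.manifest.to_csv(paths["manifest"], sep="\t", index=False)
    return paths
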