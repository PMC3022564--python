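"""End-to-end survey orchestration from a single config.

One config (YAML or a :class:`SurveyConfig`) drives the whole survey:
inputs, the survey's silent conventions exposed as named switches, the
seed, the subsample size and replicate count. Outputs are five TSV
tables plus a run log recording every switch setting and audit message:

* ``table1_sites.tsv``  - variable-site and minor-allele counts per
  category and population, with structural percentages;
* ``table2_pi.tsv``     - nucleotide diversity by site class;
* ``table3_maf.tsv``    - mean minor-allele frequencies, including the
  Monte-Carlo sample-size-corrected column and U-test p-values;
* ``table4_burden.tsv`` - mean minor alleles per genome with U-tests;
* ``ratios.tsv``        - between-population ratios per category.

Runs are deterministic for a fixed config and seed (byte-identical
outputs; the log carries no timestamps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
import yaml

from . import io_formats as io
from . import population_stats as ps
from .diversity import nucleotide_diversity
from .variant_catalog import (
    CATEGORY_ORDER,
    VariantCatalog,
    build_catalog,
    call_minor_alleles,
    category_predicate_map,
    find_polymorphic_sites,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SurveyConfig:
    alignment: str = ""
    metadata: str = ""
    genes: str = ""
    effects: str | None = None
    pathogenic: str | None = None
    out_dir: str | None = None
    seed: int = 0
    subsample_size: int | None = None       # default: size of the smaller population
    n_reps: int = 1000
    n_boot: int = 1000
    diversity_max_genomes: int = 200
    site_count_definition: str = "pooled"   # pooled | population
    recall_in_subsample: bool = True
    reference_population: str | None = None  # denominator population; default: smaller
    catalog_tsv: str | None = None           # reuse a dumped catalogue


def load_config(path) -> SurveyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(SurveyConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise io.InputError(f"unknown config keys: {sorted(unknown)}")
    return SurveyConfig(**raw)


@dataclass
class SurveyReport:
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    ratios: pd.DataFrame
    catalog: VariantCatalog
    config: SurveyConfig
    log_lines: list[str] = field(default_factory=list)

    def write(self, out_dir) -> dict[str, str]:
        import os

        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        for name, df in [
            ("table1_sites", self.table1),
            ("table2_pi", self.table2),
            ("table3_maf", self.table3),
            ("table4_burden", self.table4),
            ("ratios", self.ratios),
        ]:
            p = os.path.join(out_dir, f"{name}.tsv")
            df.to_csv(p, sep="\t", index=False, float_format="%.6g")
            paths[name] = p
        p = os.path.join(out_dir, "variant_catalog.tsv")
        self.catalog.write_tsv(p)
        paths["variant_catalog"] = p
        p = os.path.join(out_dir, "run_log.txt")
        with open(p, "w") as fh:
            fh.write("\n".join(self.log_lines) + "\n")
        paths["run_log"] = p
        return paths


# ---------------------------------------------------------------------------
# percentages (structure of the site-count table)
# ---------------------------------------------------------------------------

#: denominator structure: syn and nonsyn are percentages of their sum,
#: four-fold of synonymous, effect classes of nonsynonymous.
PERCENT_STRUCTURE = {
    "synonymous": ("synonymous", "nonsynonymous"),
    "nonsynonymous": ("synonymous", "nonsynonymous"),
    "fourfold": ("synonymous",),
    "nonsyn_unknown": ("nonsynonymous",),
    "nonsyn_benign": ("nonsynonymous",),
    "nonsyn_damaging": ("nonsynonymous",),
}


def category_percentages(counts: dict[str, float]) -> dict[str, float]:
    """Structural percentages (100*part/whole) for the categories with a
    defined denominator. A zero denominator yields NaN (flagged)."""
    out: dict[str, float] = {}
    for cat, denom_keys in PERCENT_STRUCTURE.items():
        if cat not in counts:
            continue
        whole = sum(counts.get(k, 0) for k in denom_keys)
        if whole == 0:
            logger.warning("percentage undefined for %r (zero denominator)", cat)
            out[cat] = float("nan")
        else:
            out[cat] = 100.0 * counts[cat] / whole
    return out


# ---------------------------------------------------------------------------
# survey
# ---------------------------------------------------------------------------

class _LogCapture(logging.Handler):
    def __init__(self):
        super().__init__()
        self.lines: list[str] = []

    def emit(self, record):
        self.lines.append(f"{record.levelname} {record.name}: {record.getMessage()}")


def _derive_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_survey(config: SurveyConfig) -> SurveyReport:
    """Run the full survey; deterministic for a fixed config."""
    capture = _LogCapture()
    root = logging.getLogger("mitosurvey")
    old_level = root.level
    root.addHandler(capture)
    root.setLevel(logging.INFO)
    try:
        return _run_survey(config, capture)
    finally:
        root.removeHandler(capture)
        root.setLevel(old_level)


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - rewrapped with the stage name
        raise PipelineError(name, exc) from exc


def _run_survey(config: SurveyConfig, capture: _LogCapture) -> SurveyReport:
    for key, value in sorted(asdict(config).items()):
        logger.info("config %s = %r", key, value)

    genomes = _stage("read_alignment", io.read_alignment, config.alignment)
    pops = _stage("read_sample_metadata", io.read_sample_metadata, config.metadata)
    genomes = _stage("attach_metadata", io.attach_metadata, genomes, pops)
    genes = _stage("read_gene_models", io.read_gene_models, config.genes)
    effects = (
        _stage("read_effect_annotation", io.read_effect_annotation,
               config.effects, genomes.length)
        if config.effects else io.EffectAnnotation()
    )
    patho = (
        _stage("read_pathogenic_catalogue", io.read_pathogenic_catalogue,
               config.pathogenic, genomes.length)
        if config.pathogenic else io.PathogenicCatalogue()
    )
    if len(genomes.populations) != 2:
        raise PipelineError(
            "attach_metadata",
            io.InputError(f"need exactly 2 populations, got {genomes.populations}"),
        )
    sizes = {p: len(genomes.population_indices(p)) for p in genomes.populations}
    ref_pop = config.reference_population or min(sizes, key=lambda p: (sizes[p], p))
    if ref_pop not in sizes:
        raise PipelineError("config", io.InputError(f"unknown population {ref_pop!r}"))
    other_pop = next(p for p in genomes.populations if p != ref_pop)
    sub_size = config.subsample_size or sizes[ref_pop]
    logger.info("populations: reference=%s (n=%d), comparison=%s (n=%d), subsample=%d",
                ref_pop, sizes[ref_pop], other_pop, sizes[other_pop], sub_size)

    if config.catalog_tsv:
        catalog = _stage(
            "load_catalog", VariantCatalog.from_tsv,
            config.catalog_tsv, genomes.populations, sizes,
        )
    else:
        catalog = _stage("build_catalog", build_catalog, genomes, genes, effects, patho)
    logger.info("catalogue: %d polymorphic sites, %d minor alleles",
                catalog.n_polymorphic_sites, len(catalog.alleles))

    seeds = _derive_seeds(config.seed, 10)
    table1 = _stage("table1", _build_table1, catalog, genomes, config)
    table2 = _stage("table2", _build_table2, genomes, genes, config, seeds)
    mc = _stage(
        "monte_carlo",
        ps.monte_carlo_category_maf,
        genomes, other_pop, catalog, sub_size, config.n_reps, seeds[0],
        config.recall_in_subsample,
    )
    table3 = _stage("table3", _build_table3, catalog, mc, ref_pop, other_pop)
    table4 = _stage("table4", _build_table4, catalog, genomes, ref_pop, other_pop)
    ratios = _stage("ratios", _build_ratios, catalog, genomes, mc, ref_pop, other_pop)

    report = SurveyReport(table1, table2, table3, table4, ratios, catalog, config,
                          capture.lines)
    if config.out_dir:
        report.write(config.out_dir)
    return report


# -- table builders ----------------------------------------------------------

def _population_site_counts(catalog: VariantCatalog, genomes, population: str) -> dict[str, int]:
    """Per-category variable-site counts with minors re-called within the
    population alone (the 'population' switch); annotations still come
    from the pooled catalogue."""
    lut = category_predicate_map(catalog)
    sub = genomes.subset(genomes.population_indices(population))
    positions: dict[str, set[int]] = {c: set() for c in CATEGORY_ORDER}
    for site in find_polymorphic_sites(sub):
        for m in call_minor_alleles(site):
            for cat in lut.get((m.position, m.base), ()):
                positions[cat].add(m.position)
    return {c: len(v) for c, v in positions.items()}


def _build_table1(catalog: VariantCatalog, genomes, config: SurveyConfig) -> pd.DataFrame:
    pops = catalog.populations
    counts_total = {c: ps.count_variable_sites(catalog, c) for c in CATEGORY_ORDER}
    if config.site_count_definition == "population":
        counts_pop = {p: _population_site_counts(catalog, genomes, p) for p in pops}
    else:
        counts_pop = {
            p: {c: ps.count_variable_sites(catalog, c, p) for c in CATEGORY_ORDER}
            for p in pops
        }
    pct_total = category_percentages(counts_total)
    pct_pop = {p: category_percentages(counts_pop[p]) for p in pops}
    rows = []
    for c in CATEGORY_ORDER:
        row = {
            "category": c,
            "sites_total": counts_total[c],
            "pct_total": round(pct_total[c], 1) if c in pct_total else float("nan"),
        }
        for p in pops:
            row[f"sites_{p}"] = counts_pop[p][c]
            row[f"pct_{p}"] = round(pct_pop[p][c], 1) if c in pct_pop[p] else float("nan")
            row[f"alleles_{p}"] = ps.count_allele_observations(catalog, c, p)
        rows.append(row)
    return pd.DataFrame(rows)


def _build_table2(genomes, genes, config: SurveyConfig, seeds) -> pd.DataFrame:
    rows = []
    for i, site_class in enumerate(("all", "syn", "fourfold", "nonsyn")):
        row = {"site_class": site_class}
        for j, pop in enumerate(genomes.populations):
            est = nucleotide_diversity(
                genomes, genes, site_class, pop,
                n_boot=config.n_boot,
                seed=seeds[1 + 2 * i + j],
                max_genomes=config.diversity_max_genomes,
            )
            row[f"pi_{pop}"] = est.pi
            row[f"se_{pop}"] = est.se
            row[f"n_genomes_{pop}"] = est.n_sequences
        rows.append(row)
    return pd.DataFrame(rows)


def _build_table3(catalog, mc, ref_pop: str, other_pop: str) -> pd.DataFrame:
    rows = []
    for c in CATEGORY_ORDER:
        a = ps.mean_minor_allele_frequency(catalog, c, ref_pop)
        b = ps.mean_minor_allele_frequency(catalog, c, other_pop)
        r = mc[c]
        freqs_a = _allele_freqs(catalog, c, ref_pop)
        freqs_b = _allele_freqs(catalog, c, other_pop)
        p_alleles = p_mc = float("nan")
        if len(freqs_a) and len(freqs_b):
            p_alleles = ps.mann_whitney_u(freqs_a, freqs_b).p_value
        reps = r.replicates[np.isfinite(r.replicates)]
        if len(freqs_a) and len(reps):
            p_mc = ps.mann_whitney_u(freqs_a, reps).p_value
        rows.append(
            {
                "category": c,
                f"maf_{ref_pop}": a.mean, f"se_{ref_pop}": a.se, f"k_{ref_pop}": a.k,
                f"maf_{other_pop}": b.mean, f"se_{other_pop}": b.se, f"k_{other_pop}": b.k,
                "maf_mc": r.mean,
                "se_mc_replicates": r.se,
                "se_mc_alleles": r.se_alleles,
                "p_alleles": p_alleles,
                "p_vs_mc": p_mc,
            }
        )
    return pd.DataFrame(rows)


def _allele_freqs(catalog, category, population):
    from .variant_catalog import select_alleles

    return [
        m.pop_freq(population)
        for m in select_alleles(catalog, category)
        if m.pop_count.get(population, 0) >= 1
    ]


def _build_table4(catalog, genomes, ref_pop: str, other_pop: str) -> pd.DataFrame:
    rows = []
    for c in CATEGORY_ORDER:
        a = ps.per_genome_burden(catalog, genomes, c, ref_pop)
        b = ps.per_genome_burden(catalog, genomes, c, other_pop)
        p = ps.mann_whitney_u(a.counts, b.counts).p_value
        rows.append(
            {
                "category": c,
                f"burden_{ref_pop}": a.mean, f"sem_{ref_pop}": a.sem,
                f"burden_{other_pop}": b.mean, f"sem_{other_pop}": b.sem,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def _build_ratios(catalog, genomes, mc, ref_pop: str, other_pop: str) -> pd.DataFrame:
    """Between-population ratios per category: burden ratio from the full
    samples, frequency ratio from the Monte-Carlo-corrected mean of the
    larger population over the reference population's mean."""
    rows = []
    for c in CATEGORY_ORDER:
        a_b = ps.per_genome_burden(catalog, genomes, c, ref_pop)
        b_b = ps.per_genome_burden(catalog, genomes, c, other_pop)
        rb = ps.category_ratio((b_b.mean, b_b.sem), (a_b.mean, a_b.sem))
        a_f = ps.mean_minor_allele_frequency(catalog, c, ref_pop)
        r = mc[c]
        rf = ps.category_ratio((r.mean, r.se), (a_f.mean, a_f.se))
        rows.append(
            {
                "category": c,
                "burden_ratio": rb.ratio, "burden_ratio_se": rb.se,
                "burden_ratio_defined": rb.defined,
                "freq_ratio": rf.ratio, "freq_ratio_se": rf.se,
                "freq_ratio_defined": rf.defined,
            }
        )
    return pd.DataFrame(rows)
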