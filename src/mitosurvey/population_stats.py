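"""Per-category population summaries and two-population comparisons.

Covers: mean minor-allele frequency per category, per-genome burden
(how many catalogued minor alleles of a category a genome carries),
Monte-Carlo subsampling to equalise unequal sample sizes (statistics
are recomputed from scratch within each subsample, so sites that are
monomorphic inside a subsample drop out), Mann-Whitney U-tests, and the
between-population ratio summaries.

RNG policy: every stochastic routine takes one integer seed; replicate
subsamples are drawn sequentially from a single numpy Generator, so a
fixed seed reproduces the replicate vector exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .io_formats import AlignedGenomeSet, N_BASES
from .variant_catalog import (
    BASES,
    CATEGORY_ORDER,
    CATEGORY_PREDICATES,
    VariantCatalog,
    select_alleles,
)

logger = logging.getLogger(__name__)


@dataclass
class CategoryStat:
    """Mean +/- SE of a per-allele quantity within one category."""

    mean: float
    se: float
    k: int              # number of alleles contributing
    defined: bool = True


@dataclass
class BurdenResult:
    counts: np.ndarray  # per-genome counts, order = population genomes
    mean: float
    sem: float


@dataclass
class ResamplingResult:
    """Monte-Carlo subsampling distribution of one statistic."""

    statistic: str
    replicates: np.ndarray
    subsample_size: int
    n_reps: int
    seed: int
    mean: float = field(init=False)
    se: float = field(init=False)          # SE of the mean across replicates
    se_alleles: float = float("nan")       # mean across replicates of per-replicate allele SE

    def __post_init__(self):
        vals = self.replicates[np.isfinite(self.replicates)]
        self.mean = float(vals.mean()) if len(vals) else float("nan")
        self.se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0


@dataclass
class UTestResult:
    U: float
    p_value: float
    method: str                 # exact | normal-approximation-with-tie-correction
    n1: int
    n2: int


@dataclass
class RatioResult:
    ratio: float
    se: float
    defined: bool = True


# ---------------------------------------------------------------------------
# per-category summaries
# ---------------------------------------------------------------------------

def mean_minor_allele_frequency(
    catalog: VariantCatalog, category: str, population: str
) -> CategoryStat:
    """Unweighted mean within-population frequency over the category's
    minor alleles segregating (count >= 1) in the population.

    SE is the sample SD over alleles / sqrt(k); 0 for a single allele.
    An empty category is flagged absent, not zero.
    """
    freqs = [
        m.pop_freq(population)
        for m in select_alleles(catalog, category)
        if m.pop_count.get(population, 0) >= 1
    ]
    k = len(freqs)
    if k == 0:
        return CategoryStat(float("nan"), float("nan"), 0, defined=False)
    arr = np.asarray(freqs)
    se = float(arr.std(ddof=1) / np.sqrt(k)) if k > 1 else 0.0
    return CategoryStat(float(arr.mean()), se, k)


def per_genome_burden(
    catalog: VariantCatalog,
    genomes: AlignedGenomeSet,
    category: str,
    population: str,
) -> BurdenResult:
    """Count of the category's minor alleles carried by each genome.

    A genome with missing data at a site is not a carrier there. The
    counts conserve the catalogue: sum over genomes equals the summed
    per-population allele counts.
    """
    idx = genomes.population_indices(population)
    alleles = select_alleles(catalog, category)
    if not alleles:
        counts = np.zeros(len(idx), dtype=int)
        return BurdenResult(counts, 0.0, 0.0)
    pos = np.array([m.position for m in alleles])
    codes = np.array([BASES.index(m.base) for m in alleles], dtype=np.uint8)
    carriers = genomes.matrix[np.ix_(idx, pos)] == codes[None, :]
    counts = carriers.sum(axis=1)
    mean = float(counts.mean())
    sem = float(counts.std(ddof=1) / np.sqrt(len(counts))) if len(counts) > 1 else 0.0
    return BurdenResult(counts, mean, sem)


# ---------------------------------------------------------------------------
# Monte-Carlo subsampling
# ---------------------------------------------------------------------------

def _subsample_indices(rng: np.random.Generator, n: int, size: int) -> np.ndarray:
    return rng.choice(n, size=size, replace=False)


def monte_carlo_subsample(
    genomes: AlignedGenomeSet,
    population: str,
    subsample_size: int,
    n_reps: int,
    seed: int,
    statistic,
    name: str = "statistic",
) -> ResamplingResult:
    """Subsample the population without replacement and recompute
    ``statistic`` (a callable on an AlignedGenomeSet) from scratch in
    each replicate. Deterministic for a fixed seed."""
    idx = genomes.population_indices(population)
    if subsample_size > len(idx):
        raise ValueError(
            f"subsample size {subsample_size} exceeds population size {len(idx)}"
        )
    rng = np.random.default_rng(seed)
    values = np.empty(n_reps)
    for r in range(n_reps):
        local = _subsample_indices(rng, len(idx), subsample_size)
        values[r] = statistic(genomes.subset(idx[local]))
    return ResamplingResult(name, values, subsample_size, n_reps, seed)


def category_maf_lut(catalog: VariantCatalog, positions: np.ndarray) -> np.ndarray:
    """(n_categories, len(positions), 4) bool lookup: does (position,
    base) belong to the category, according to the pooled catalogue."""
    pos_index = {int(p): i for i, p in enumerate(positions)}
    lut = np.zeros((len(CATEGORY_ORDER), len(positions), N_BASES), dtype=bool)
    for m in catalog.alleles:
        col = pos_index.get(m.position)
        if col is None:
            continue
        b = BASES.index(m.base)
        for k, cat in enumerate(CATEGORY_ORDER):
            if CATEGORY_PREDICATES[cat](m):
                lut[k, col, b] = True
    return lut


def subsample_category_maf(
    matrix_subset: np.ndarray, lut: np.ndarray, recall: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Category mean/SD/count of minor-allele frequencies in one subsample.

    ``matrix_subset``: (genomes, columns) codes restricted to pooled
    polymorphic columns; ``lut`` from :func:`category_maf_lut`.
    With ``recall`` the minor alleles are re-called within the subsample
    (pooled-catalogue annotations, so a pooled-major allele that becomes
    minor inside the subsample carries no annotation and is skipped);
    without it the allele set is frozen and only frequencies recomputed.
    """
    cnt = np.stack([(matrix_subset == b).sum(axis=0) for b in range(N_BASES)]).astype(float)
    called = cnt.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(called > 0, cnt / np.maximum(called, 1), 0.0)
    if recall:
        poly = (cnt > 0).sum(axis=0) >= 2
        major = cnt.argmax(axis=0)
        minor = (cnt > 0) & poly[None, :] & (np.arange(N_BASES)[:, None] != major[None, :])
    else:
        minor = cnt > 0
    sel = minor.T.reshape(-1)                      # (P*4,) base-fastest
    f = freq.T.reshape(-1)
    K = lut.shape[0]
    lutf = lut.reshape(K, -1)
    m = (lutf & sel).astype(float)
    den = m.sum(axis=1)
    num = m @ f
    num2 = m @ (f * f)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = np.where(den > 0, num / np.maximum(den, 1), np.nan)
        var = np.where(den > 1, (num2 - den * mean**2) / np.maximum(den - 1, 1), np.nan)
    return mean, np.sqrt(np.maximum(var, 0.0)), den


def monte_carlo_category_maf(
    genomes: AlignedGenomeSet,
    population: str,
    catalog: VariantCatalog,
    subsample_size: int,
    n_reps: int,
    seed: int,
    recall: bool = True,
) -> dict[str, ResamplingResult]:
    """Monte-Carlo per-category mean minor-allele frequency.

    Each replicate subsamples the population without replacement,
    re-calls minor alleles within the subsample and takes the category
    mean frequency; the subsampling distribution of those means is
    returned per category. Algebraically the same computation as the
    generic :func:`monte_carlo_subsample` path, vectorised over the
    pooled polymorphic columns (verified by test).
    """
    idx = genomes.population_indices(population)
    if subsample_size > len(idx):
        raise ValueError(
            f"subsample size {subsample_size} exceeds population size {len(idx)}"
        )
    positions = np.unique([m.position for m in catalog.alleles]).astype(np.intp)
    lut = category_maf_lut(catalog, positions)
    Mpop = genomes.matrix[np.ix_(idx, positions)]
    rng = np.random.default_rng(seed)
    K = len(CATEGORY_ORDER)
    means = np.empty((K, n_reps))
    sds = np.empty((K, n_reps))
    ks = np.empty((K, n_reps))
    for r in range(n_reps):
        local = _subsample_indices(rng, len(idx), subsample_size)
        means[:, r], sds[:, r], ks[:, r] = subsample_category_maf(Mpop[local], lut, recall)
    out: dict[str, ResamplingResult] = {}
    for k, cat in enumerate(CATEGORY_ORDER):
        res = ResamplingResult(f"maf_{cat}", means[k], subsample_size, n_reps, seed)
        with np.errstate(invalid="ignore"):
            allele_se = sds[k] / np.sqrt(np.maximum(ks[k], 1))
        ok = np.isfinite(allele_se) & (ks[k] > 1)
        res.se_alleles = float(allele_se[ok].mean()) if ok.any() else float("nan")
        out[cat] = res
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def mann_whitney_u(x, y) -> UTestResult:
    """Two-sided Mann-Whitney U-test.

    Exact p by enumeration for small tie-free samples (n1+n2 <= 12);
    otherwise the normal approximation with tie correction and
    continuity correction. Complete ties give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("mann_whitney_u requires two non-empty samples")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return UTestResult(len(x) * len(y) / 2.0, 1.0, "degenerate-all-tied", len(x), len(y))
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(pooled) <= 12 and no_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "normal-approximation-with-tie-correction"
    return UTestResult(float(res.statistic), float(res.pvalue), method, len(x), len(y))


# ---------------------------------------------------------------------------
# ratios
# ---------------------------------------------------------------------------

def category_ratio(
    numerator: tuple[float, float], denominator: tuple[float, float]
) -> RatioResult:
    """Ratio of two means with first-order SE propagation.

    se(r)^2 = (se_num/den)^2 + (num*se_den/den^2)^2. A non-positive or
    undefined denominator flags the ratio undefined.
    """
    num, se_num = numerator
    den, se_den = denominator
    if not np.isfinite(den) or den <= 0 or not np.isfinite(num):
        return RatioResult(float("nan"), float("nan"), defined=False)
    r = num / den
    se = float(np.sqrt((se_num / den) ** 2 + (num * se_den / den**2) ** 2))
    return RatioResult(float(r), se)


# ---------------------------------------------------------------------------
# combined per-category summary (Tables 1/3/4 core)
# ---------------------------------------------------------------------------

@dataclass
class CategorySummary:
    category: str
    population: str
    n_variable_sites: int
    n_minor_allele_observations: int
    maf: CategoryStat
    burden_mean: float
    burden_sem: float


def count_variable_sites(catalog: VariantCatalog, category: str,
                         population: str | None = None) -> int:
    """Distinct positions where >=1 minor allele of the category
    segregates (pooled minors; population column = pooled minors with
    count >= 1 in that population)."""
    alleles = select_alleles(catalog, category)
    if population is None:
        return len({m.position for m in alleles})
    return len({m.position for m in alleles if m.pop_count.get(population, 0) >= 1})


def count_allele_observations(catalog: VariantCatalog, category: str,
                              population: str) -> int:
    return sum(m.pop_count.get(population, 0) for m in select_alleles(catalog, category))


def build_category_summaries(
    catalog: VariantCatalog, genomes: AlignedGenomeSet
) -> list[CategorySummary]:
    out = []
    for cat in CATEGORY_ORDER:
        for pop in catalog.populations:
            burden = per_genome_burden(catalog, genomes, cat, pop)
            out.append(
                CategorySummary(
                    category=cat,
                    population=pop,
                    n_variable_sites=count_variable_sites(catalog, cat, pop),
                    n_minor_allele_observations=count_allele_observations(catalog, cat, pop),
                    maf=mean_minor_allele_frequency(catalog, cat, pop),
                    burden_mean=burden.mean,
                    burden_sem=burden.sem,
                )
            )
    return out
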