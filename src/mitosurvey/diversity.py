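"""Nucleotide diversity overall and partitioned by NG86 site class.

Nucleotide diversity pi is the average, over all n(n-1)/2 sequence
pairs within a population, of the per-pair per-site proportion of
differing alleles.

* class ``all``: the site-wise estimator pi = sum_s h_s / L_used with
  h_s = 1 - sum_a C(c_a,2)/C(m_s,2) (m_s = non-missing genomes at the
  column, L_used = columns with m_s >= 2). With complete data this is
  algebraically identical to the mean pairwise p-distance; with missing
  data it is the standard per-site estimator.
* class ``fourfold``: the same estimator restricted to columns that are
  four-fold degenerate on the pooled major-allele background.
* classes ``syn``/``nonsyn``: exact all-pairs NG86 with pairwise
  deletion at codon granularity (codons with gap/N or a stop codon in
  either sequence of a pair are skipped for that pair). pS = sd/S and
  pN = nd/N per pair, averaged over pairs. Computed by grouping
  identical codons per column, which is algebraically the naive double
  loop (tested against it) but scales to thousands of genomes.

Standard errors come from a seeded bootstrap over alignment (or codon)
columns. Populations larger than ``max_genomes`` are represented by a
seeded random subsample of genomes: pairs of a random subset are a
random subset of pairs, so the estimator stays unbiased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import codon_engine as ce
from .codon_engine import PairwiseCodonCounts
from .io_formats import AlignedGenomeSet, GeneModel, COMPLEMENT, N_BASES
from .variant_catalog import CodingMap, major_background

logger = logging.getLogger(__name__)

SITE_CLASSES = ("all", "syn", "fourfold", "nonsyn")

_UNUSABLE = 64  # codon-id sentinel for gap/N-containing or stop codons


@dataclass
class DiversityEstimate:
    population: str
    site_class: str
    pi: float
    se: float
    n_sequences: int
    n_pairs: int
    n_pairs_excluded: int = 0

    def __post_init__(self):
        if np.isfinite(self.pi) and self.pi > 1:
            logger.warning(
                "pi=%g > 1 for %s/%s: degenerate input?", self.pi, self.population,
                self.site_class,
            )


def ng_pair(cds1: str, cds2: str, code: ce.GeneticCode | None = None) -> PairwiseCodonCounts:
    """NG86 counts for one pair of equal-length coding sequences.

    Codons where either sequence has a gap/N, or either codon is a stop,
    are skipped entirely (pairwise deletion at codon granularity).
    S and N are averaged across the two sequences, sd and nd summed
    over codons.
    """
    code = code or ce.default_code()
    if len(cds1) != len(cds2):
        raise ValueError("coding sequences must have equal length")
    if len(cds1) % 3:
        raise ValueError("coding sequence length must be divisible by 3")
    out = PairwiseCodonCounts()
    for k in range(0, len(cds1), 3):
        a, b = cds1[k:k + 3], cds2[k:k + 3]
        if not (ce.is_resolved(a) and ce.is_resolved(b)):
            continue
        if code.is_stop(a) or code.is_stop(b):
            continue
        s1, n1 = ce.count_syn_sites(a, code)
        s2, n2 = ce.count_syn_sites(b, code)
        sd, nd = ce.pairwise_codon_diffs(a, b, code)
        out.S += (s1 + s2) / 2
        out.N += (n1 + n2) / 2
        out.sd += sd
        out.nd += nd
        out.n_codons += 1
    if out.n_codons == 0:
        logger.warning("ng_pair: zero usable codons; estimate undefined")
    return out


# ---------------------------------------------------------------------------
# codon-matrix machinery
# ---------------------------------------------------------------------------

def coding_codon_matrix(
    matrix: np.ndarray, gene_models: list[GeneModel], code: ce.GeneticCode | None = None
) -> np.ndarray:
    """(n, C) codon-id matrix over the concatenated protein genes.

    Strand-aware; codons containing gap/N and stop codons are the
    _UNUSABLE sentinel. Trailing partial codons of a gene are dropped.
    """
    code = code or ce.default_code()
    blocks = []
    for g in gene_models:
        if g.feature != "protein":
            continue
        sub = matrix[:, g.start:g.end]
        if g.strand == "-":
            sub = COMPLEMENT[sub[:, ::-1]]
        n_codons = sub.shape[1] // 3
        if n_codons == 0:
            continue
        sub = sub[:, : 3 * n_codons]
        b0 = sub[:, 0::3].astype(np.int16)
        b1 = sub[:, 1::3].astype(np.int16)
        b2 = sub[:, 2::3].astype(np.int16)
        ids = 16 * b0 + 4 * b1 + b2
        bad = (b0 >= N_BASES) | (b1 >= N_BASES) | (b2 >= N_BASES)
        ids[bad] = _UNUSABLE
        blocks.append(ids)
    if not blocks:
        raise ValueError("no protein genes: NG86 classes undefined")
    cod = np.concatenate(blocks, axis=1)
    _, _, usable = (code or ce.default_code()).site_arrays()
    stop_ids = np.flatnonzero(~usable)
    cod[np.isin(cod, stop_ids)] = _UNUSABLE
    return cod


def _ng_pair_arrays(codmat: np.ndarray, code: ce.GeneticCode):
    """Exact per-pair (S, N, sd, nd) matrices for all pairs of rows."""
    n = codmat.shape[0]
    S64, N64, usable = code.site_arrays()
    sval = np.zeros(65)
    nval = np.zeros(65)
    sval[:64] = np.where(usable, S64, 0.0)
    nval[:64] = np.where(usable, N64, 0.0)
    use = np.zeros(65)
    use[:64] = usable.astype(float)

    R = use[codmat]                       # 1 where codon usable
    As = sval[codmat]
    An = nval[codmat]
    Smat = (As @ R.T + R @ As.T) / 2.0
    Nmat = (An @ R.T + R @ An.T) / 2.0

    SD, ND = code.pair_diff_arrays()
    sdmat = np.zeros((n, n))
    ndmat = np.zeros((n, n))
    for c in range(codmat.shape[1]):
        col = codmat[:, c]
        ids = np.unique(col)
        ids = ids[ids != _UNUSABLE]
        if len(ids) < 2:
            continue
        members = {int(i): np.flatnonzero(col == i) for i in ids}
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                u, v = int(ids[a]), int(ids[b])
                sd, nd = SD[u, v], ND[u, v]
                iu, iv = members[u], members[v]
                sdmat[np.ix_(iu, iv)] += sd
                sdmat[np.ix_(iv, iu)] += sd
                ndmat[np.ix_(iu, iv)] += nd
                ndmat[np.ix_(iv, iu)] += nd
    return Smat, Nmat, sdmat, ndmat


def _sitewise_pi(sub: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column heterozygosity h_s and usability u_s for a code matrix."""
    counts = np.stack([(sub == b).sum(axis=0) for b in range(N_BASES)]).astype(float)
    m = counts.sum(axis=0)
    pairs_tot = m * (m - 1) / 2.0
    pairs_same = (counts * (counts - 1) / 2.0).sum(axis=0)
    u = (m >= 2).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(pairs_tot > 0, 1.0 - pairs_same / pairs_tot, 0.0)
    return h, u


def _bootstrap_ratio(num: np.ndarray, den: np.ndarray, n_boot: int, rng) -> float:
    """SE of sum(num)/sum(den) under column resampling (vectorised)."""
    L = len(num)
    if L == 0 or n_boot <= 1:
        return 0.0
    W = rng.multinomial(L, np.full(L, 1.0 / L), size=n_boot).T.astype(float)  # (L, B)
    nb = num @ W
    db = den @ W
    ok = db > 0
    vals = np.divide(nb, db, out=np.zeros_like(nb), where=ok)
    return float(np.std(vals[ok], ddof=1)) if ok.sum() > 1 else 0.0


def nucleotide_diversity(
    genomes: AlignedGenomeSet,
    gene_models: list[GeneModel],
    site_class: str,
    population: str | None = None,
    *,
    code: ce.GeneticCode | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    max_genomes: int | None = None,
    boot_pair_cap: int = 500,
) -> DiversityEstimate:
    """Estimate pi for one site class within one population.

    ``population=None`` uses all genomes. ``max_genomes`` caps the
    number of genomes by a seeded random subsample (unbiased).
    """
    if site_class not in SITE_CLASSES:
        raise ValueError(f"site_class must be one of {SITE_CLASSES}")
    code = code or ce.default_code()
    rng = np.random.default_rng(seed)

    if population is not None:
        idx = genomes.population_indices(population)
    else:
        idx = np.arange(genomes.n_samples)
    if len(idx) < 2:
        raise ValueError(f"population {population!r} has fewer than 2 genomes")
    if max_genomes is not None and len(idx) > max_genomes:
        idx = np.sort(rng.choice(idx, size=max_genomes, replace=False))
    sub = genomes.matrix[idx]
    n = len(idx)
    n_pairs = n * (n - 1) // 2

    if site_class in ("all", "fourfold"):
        if site_class == "fourfold":
            background = major_background(genomes)
            cols = CodingMap(gene_models, background, code).fourfold_positions()
            sub = sub[:, cols]
        h, u = _sitewise_pi(sub)
        used = u.sum()
        pi = float(h.sum() / used) if used else float("nan")
        se = _bootstrap_ratio(h, u, n_boot, rng)
        return DiversityEstimate(population or "all", site_class, pi, se, n, n_pairs)

    codmat = coding_codon_matrix(sub, gene_models, code)
    Smat, Nmat, sdmat, ndmat = _ng_pair_arrays(codmat, code)
    iu = np.triu_indices(n, 1)
    if site_class == "syn":
        den_p, num_p = Smat[iu], sdmat[iu]
    else:
        den_p, num_p = Nmat[iu], ndmat[iu]
    ok = den_p > 0
    n_excl = int((~ok).sum())
    if n_excl:
        logger.warning("%d pairs have zero usable %s sites (excluded)", n_excl, site_class)
    pi = float(np.mean(num_p[ok] / den_p[ok])) if ok.any() else float("nan")
    se = _ng_bootstrap_se(codmat, code, site_class, n_boot, boot_pair_cap, rng)
    return DiversityEstimate(population or "all", site_class, pi, se, n, n_pairs, n_excl)


def _ng_bootstrap_se(
    codmat: np.ndarray,
    code: ce.GeneticCode,
    site_class: str,
    n_boot: int,
    pair_cap: int,
    rng,
) -> float:
    """Bootstrap-over-codon-columns SE of mean per-pair pS (or pN),
    evaluated on a random subset of pairs when there are many."""
    n, C = codmat.shape
    if n_boot <= 1 or C == 0:
        return 0.0
    iu = np.transpose(np.triu_indices(n, 1))
    if len(iu) > pair_cap:
        sel = rng.choice(len(iu), size=pair_cap, replace=False)
        iu = iu[np.sort(sel)]
    I, J = iu[:, 0], iu[:, 1]

    S64, N64, usable = code.site_arrays()
    vals = S64 if site_class == "syn" else N64
    sval = np.zeros(65)
    sval[:64] = np.where(usable, vals, 0.0)
    use = np.zeros(65)
    use[:64] = usable.astype(float)
    SD, ND = code.pair_diff_arrays()
    D = SD if site_class == "syn" else ND
    Dext = np.zeros((65, 65))
    Dext[:64, :64] = np.nan_to_num(D)

    ci, cj = codmat[I], codmat[J]                     # (K, C)
    den = (sval[ci] * use[cj] + sval[cj] * use[ci]) / 2.0
    num = Dext[ci, cj]

    W = rng.multinomial(C, np.full(C, 1.0 / C), size=n_boot).T.astype(float)  # (C, B)
    nb = num @ W                                     # (K, B)
    db = den @ W
    ok = db > 0
    ratios = np.divide(nb, db, out=np.full_like(nb, np.nan), where=ok)
    with np.errstate(invalid="ignore"):
        pis = np.nanmean(ratios, axis=0)
    pis = pis[np.isfinite(pis)]
    return float(np.std(pis, ddof=1)) if len(pis) > 1 else 0.0
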