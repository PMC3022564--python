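"""Independent brute-force oracles used by the tests.

Everything here is written against first principles (and Biopython's
translation tables), independently of the package's implementation
paths, so oracle/implementation agreement is a meaningful check.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations, permutations

import numpy as np
from Bio.Data import CodonTable
from scipy import stats as sps

BASES = "ACGT"


def make_table(code_id: int = 2) -> dict[str, str]:
    bio = CodonTable.unambiguous_dna_by_id[code_id]
    table = dict(bio.forward_table)
    for c in bio.stop_codons:
        table[c] = "*"
    return table


def brute_syn_sites(codon: str, table: dict[str, str]) -> tuple[Fraction, Fraction]:
    """NG86 (S, N) by enumerating all nine single-nucleotide mutants."""
    aa = table[codon]
    s = Fraction(0)
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if table[mut] == aa and aa != "*":
                syn += 1
        s += Fraction(syn, 3)
    return s, 3 - s


def brute_pathway_diffs(c1: str, c2: str, table: dict[str, str]) -> tuple[Fraction, Fraction]:
    """Pathway-averaged (sd, nd) by enumerating every ordering of the
    differing positions; stop-passing pathways excluded, with the
    all-pathways fallback (stop steps nonsynonymous)."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return Fraction(0), Fraction(0)
    clean, dirty = [], []
    for order in permutations(diffs):
        cur, sd, nd, hit_stop = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if table[cur] == "*" or table[nxt] == "*":
                hit_stop = True
                nd += 1
            elif table[cur] == table[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (dirty if hit_stop else clean).append((sd, nd))
    paths = clean if clean else dirty
    return (
        Fraction(sum(p[0] for p in paths), len(paths)),
        Fraction(sum(p[1] for p in paths), len(paths)),
    )


def brute_pi_allpairs(matrix: np.ndarray, n_bases: int = 4) -> float:
    """Mean pairwise p-distance with pairwise deletion (double loop)."""
    n = matrix.shape[0]
    vals = []
    for i, j in combinations(range(n), 2):
        ok = (matrix[i] < n_bases) & (matrix[j] < n_bases)
        if ok.sum() == 0:
            continue
        vals.append((matrix[i][ok] != matrix[j][ok]).mean())
    return float(np.mean(vals))


def exact_mw_two_sided_p(u_obs: float, n1: int, n2: int) -> float:
    """Exact two-sided Mann-Whitney p for tie-free data by enumerating
    all C(n1+n2, n1) rank assignments."""
    N = n1 + n2
    us = []
    for comb in combinations(range(1, N + 1), n1):
        us.append(sum(comb) - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    u_min = min(u_obs, n1 * n2 - u_obs)
    return min(1.0, float(2 * np.mean(us <= u_min)))


def normal_mw_two_sided_p(u_obs: float, n1: int, n2: int) -> float:
    """Continuity-corrected normal approximation (no ties)."""
    mu = n1 * n2 / 2.0
    sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (abs(u_obs - mu) - 0.5) / sd
    return min(1.0, float(2 * sps.norm.sf(z)))


def hypergeom_subsample_mean(
    carrier_counts, pop_size: int, subsample_size: int, n_sim: int = 40000, seed: int = 7
) -> tuple[float, float]:
    """Expectation (and SE) of the per-subsample mean frequency over the
    alleles present in a without-replacement subsample.

    Treats alleles independently: each allele's subsample carrier count
    is hypergeometric given its realized population count. Returns the
    mean and Monte-Carlo SE over n_sim independent simulated subsamples.
    """
    rng = np.random.default_rng(seed)
    c = np.asarray([x for x in carrier_counts if x >= 1], dtype=np.int64)
    K = rng.hypergeometric(c[:, None], pop_size - c[:, None], subsample_size,
                           size=(len(c), n_sim))
    num = (K / subsample_size).sum(axis=0)
    den = (K >= 1).sum(axis=0)
    ok = den > 0
    x = num[ok] / den[ok]
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(ok.sum()))
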