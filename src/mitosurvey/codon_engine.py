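"""Genetic-code logic and Nei-Gojobori (NG86) codon arithmetic.

This module owns everything that depends on a genetic code: codon
translation, site-degeneracy classification, and the NG86 partition of
codon sites and pairwise codon differences into synonymous and
nonsynonymous fractions with mutational-pathway averaging.

Conventions (the MEGA-style NG86 variant):

* a single-nucleotide change that creates a stop codon counts as
  nonsynonymous in *site* counting;
* mutational pathways that pass through a stop codon are excluded from
  the pathway average of *difference* counting; if every pathway is
  excluded, all pathways are used with stop-passing steps counted as
  nonsynonymous.

All fractional quantities are computed with exact rational arithmetic
internally and returned as floats, so S + N == 3.0 holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import permutations

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
STOP = "*"
#: sentinel returned for codons containing gaps, N or other ambiguity
UNRESOLVED = None

VERTEBRATE_MITOCHONDRIAL = 2

#: codon -> integer id in lexicographic A<C<G<T order (AAA=0 ... TTT=63)
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def codon_id(codon: str) -> int:
    return 16 * _BASE_INDEX[codon[0]] + 4 * _BASE_INDEX[codon[1]] + _BASE_INDEX[codon[2]]


def codon_from_id(cid: int) -> str:
    return BASES[cid // 16] + BASES[(cid // 4) % 4] + BASES[cid % 4]


class GeneticCode:
    """A 64-codon translation table identified by its NCBI id.

    The vertebrate mitochondrial table (id 2) is the package default:
    ATA=Met, TGA=Trp, AGA/AGG=stop.
    """

    def __init__(self, table: dict[str, str], code_id: int):
        if len(table) != 64:
            raise ValueError(f"genetic code must define all 64 codons, got {len(table)}")
        bad = [c for c in table if len(c) != 3 or any(b not in BASES for b in c)]
        if bad:
            raise ValueError(f"invalid codons in table: {bad[:3]}")
        self.table = dict(table)
        self.code_id = code_id
        self.stop_codons = frozenset(c for c, aa in table.items() if aa == STOP)
        # caches for the heavier computations
        self._syn_sites: dict[str, tuple[Fraction, Fraction]] = {}
        self._pair_diffs: dict[tuple[str, str], tuple[Fraction, Fraction]] = {}
        self._arrays: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
        self._pair_arrays: tuple[np.ndarray, np.ndarray] | None = None

    @classmethod
    def from_ncbi_id(cls, code_id: int = VERTEBRATE_MITOCHONDRIAL) -> "GeneticCode":
        bio = CodonTable.unambiguous_dna_by_id[code_id]
        table = dict(bio.forward_table)
        for c in bio.stop_codons:
            table[c] = STOP
        return cls(table, code_id)

    def translate(self, codon: str) -> str:
        return self.table[codon]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    # -- vectorised views used by the diversity module ------------------
    def site_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-codon-id arrays: (S, N, usable) with NaN/False at stops."""
        if self._arrays is None:
            S = np.full(64, np.nan)
            N = np.full(64, np.nan)
            usable = np.zeros(64, dtype=bool)
            for cid in range(64):
                codon = codon_from_id(cid)
                if self.is_stop(codon):
                    continue
                s, n = count_syn_sites(codon, self)
                S[cid], N[cid] = s, n
                usable[cid] = True
            self._arrays = (S, N, usable)
        return self._arrays

    def pair_diff_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """64x64 arrays of pathway-averaged (sd, nd); NaN where a stop is involved."""
        if self._pair_arrays is None:
            SD = np.full((64, 64), np.nan)
            ND = np.full((64, 64), np.nan)
            for i in range(64):
                ci = codon_from_id(i)
                if self.is_stop(ci):
                    continue
                for j in range(i, 64):
                    cj = codon_from_id(j)
                    if self.is_stop(cj):
                        continue
                    sd, nd = pairwise_codon_diffs(ci, cj, self)
                    SD[i, j] = SD[j, i] = sd
                    ND[i, j] = ND[j, i] = nd
            self._pair_arrays = (SD, ND)
        return self._pair_arrays


_DEFAULT_CODE: GeneticCode | None = None


def default_code() -> GeneticCode:
    """The vertebrate mitochondrial code (NCBI translation table 2)."""
    global _DEFAULT_CODE
    if _DEFAULT_CODE is None:
        _DEFAULT_CODE = GeneticCode.from_ncbi_id(VERTEBRATE_MITOCHONDRIAL)
    return _DEFAULT_CODE


@dataclass
class PairwiseCodonCounts:
    """NG86 per-pair quantities aggregated over codons.

    S, N are fractional synonymous/nonsynonymous site counts (averaged
    between the two sequences); sd, nd are pathway-averaged difference
    counts summed over codons. n_codons counts codons actually compared
    (both resolved, neither a stop).
    """

    S: float = 0.0
    N: float = 0.0
    sd: float = 0.0
    nd: float = 0.0
    n_codons: int = 0

    @property
    def pS(self) -> float:
        return self.sd / self.S if self.S > 0 else float("nan")

    @property
    def pN(self) -> float:
        return self.nd / self.N if self.N > 0 else float("nan")


def is_resolved(codon: str) -> bool:
    return len(codon) == 3 and all(b in BASES for b in codon)


def translate_codon(codon: str, code: GeneticCode | None = None):
    """Translate a codon; returns the amino acid, '*' for stop, or the
    UNRESOLVED sentinel (None) if the codon contains gap/N/ambiguity."""
    code = code or default_code()
    if not is_resolved(codon):
        return UNRESOLVED
    return code.translate(codon)


def count_syn_sites(codon: str, code: GeneticCode | None = None) -> tuple[float, float]:
    """NG86 synonymous/nonsynonymous site counts (S, N) for one codon.

    Each position contributes (number of synonymous single-nucleotide
    changes)/3 to S; changes to stop codons are nonsynonymous. S+N = 3.
    """
    code = code or default_code()
    if not is_resolved(codon):
        raise ValueError(f"unresolved codon {codon!r}")
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon!r} has no NG86 site decomposition")
    cached = code._syn_sites.get(codon)
    if cached is None:
        aa = code.translate(codon)
        s = Fraction(0)
        for pos in range(3):
            syn = sum(
                1
                for b in BASES
                if b != codon[pos] and code.translate(codon[:pos] + b + codon[pos + 1:]) == aa
            )
            s += Fraction(syn, 3)
        cached = (s, 3 - s)
        code._syn_sites[codon] = cached
    return float(cached[0]), float(cached[1])


def pairwise_codon_diffs(c1: str, c2: str, code: GeneticCode | None = None):
    """Pathway-averaged synonymous/nonsynonymous differences (sd, nd).

    Averages over all orderings of the differing positions; pathways
    through stop codons are excluded, with the all-pathways fallback
    when none survive. Returns the UNRESOLVED sentinel if either codon
    is unresolved. sd + nd equals the Hamming distance of the codons.
    """
    code = code or default_code()
    if not (is_resolved(c1) and is_resolved(c2)):
        return UNRESOLVED
    if code.is_stop(c1) or code.is_stop(c2):
        raise ValueError("pairwise_codon_diffs requires non-stop codons")
    key = (c1, c2) if c1 <= c2 else (c2, c1)
    cached = code._pair_diffs.get(key)
    if cached is None:
        cached = _pathway_average(key[0], key[1], code)
        code._pair_diffs[key] = cached
    return float(cached[0]), float(cached[1])


def _pathway_average(c1: str, c2: str, code: GeneticCode) -> tuple[Fraction, Fraction]:
    diff_positions = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_positions:
        return Fraction(0), Fraction(0)
    valid: list[tuple[int, int]] = []
    fallback: list[tuple[int, int]] = []
    for order in permutations(diff_positions):
        sd = nd = 0
        through_stop = False
        current = c1
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1:]
            aa_a, aa_b = code.translate(current), code.translate(nxt)
            if aa_b == STOP or aa_a == STOP:
                through_stop = True
            if aa_a == aa_b and aa_a != STOP:
                sd += 1
            else:
                nd += 1
            current = nxt
        fallback.append((sd, nd))
        if not through_stop:
            valid.append((sd, nd))
    paths = valid if valid else fallback
    k = len(paths)
    sd = Fraction(sum(p[0] for p in paths), k)
    nd = Fraction(sum(p[1] for p in paths), k)
    return sd, nd


def degeneracy_class(codon: str, position: int, code: GeneticCode | None = None):
    """Degeneracy (1/2/3/4-fold) of a codon position (1-based 1..3).

    The number of nucleotides at that position, including the current
    one, that yield the same amino acid. Unresolved codons return the
    sentinel; stop codons are an error (callers skip them).
    """
    code = code or default_code()
    if position not in (1, 2, 3):
        raise ValueError("position must be 1, 2 or 3")
    if not is_resolved(codon):
        return UNRESOLVED
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon!r} has no degeneracy class")
    i = position - 1
    aa = code.translate(codon)
    return sum(1 for b in BASES if code.translate(codon[:i] + b + codon[i + 1:]) == aa)
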