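"""Readers and writers for every external file the survey touches.

Coordinate conventions
----------------------
Alignment columns are THE coordinate system: every annotation refers to
a column of the curated multiple alignment, not to a reference genome.
On disk all positions are 1-based (inclusive for gene spans, GFF3
style); internally everything is 0-based with half-open gene spans.

Alphabet: A/C/G/T plus N and '-' (gap). Input is case-folded to upper
case and U is mapped to T. N is treated as missing data, exactly like a
gap, in every downstream count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

# integer codes for alignment characters
ALPHABET = "ACGTN-"
A, C, G, T, MISSING_N, GAP = range(6)
N_BASES = 4  # codes < N_BASES are real nucleotides

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _ch in enumerate(ALPHABET):
    _ENCODE[ord(_ch)] = _i
    _ENCODE[ord(_ch.lower())] = _i
_ENCODE[ord("U")] = T
_ENCODE[ord("u")] = T
_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

COMPLEMENT = np.array([T, G, C, A, MISSING_N, GAP], dtype=np.uint8)


class InputError(ValueError):
    """Malformed or inconsistent input data."""


class AlignmentError(InputError):
    """Structural problem with the multiple alignment."""


def encode_sequence(seq: str, record_id: str = "<seq>") -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _ENCODE[raw]
    if (codes == 255).any():
        col = int(np.argmax(codes == 255))
        raise InputError(
            f"illegal character {seq[col]!r} in record {record_id!r} at column {col + 1}"
        )
    return codes


def decode_row(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


class AlignedGenomeSet:
    """Equal-length aligned genomes with sample ids and population labels.

    Sequences are held as a (n_samples, length) uint8 matrix using the
    codes of :data:`ALPHABET`; ``sequences`` decodes back to strings.
    """

    def __init__(
        self,
        sample_ids: list[str],
        matrix: np.ndarray,
        population_of: dict[str, str] | None = None,
    ):
        sample_ids = list(sample_ids)
        if len(set(sample_ids)) != len(sample_ids):
            dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise InputError(f"duplicate sample ids: {dupes[:5]}")
        matrix = np.asarray(matrix, dtype=np.uint8)
        if matrix.ndim != 2 or matrix.shape[0] != len(sample_ids):
            raise AlignmentError("matrix shape does not match sample ids")
        self.sample_ids = sample_ids
        self.matrix = matrix
        self.population_of = dict(population_of) if population_of else {}
        if self.population_of:
            missing = [s for s in sample_ids if s not in self.population_of]
            if missing:
                raise InputError(f"samples without population label: {missing[:5]}")

    # -- construction ----------------------------------------------------
    @classmethod
    def from_sequences(
        cls,
        sample_ids: list[str],
        sequences: list[str],
        population_of: dict[str, str] | None = None,
    ) -> "AlignedGenomeSet":
        if len(sequences) != len(sample_ids):
            raise AlignmentError("ids and sequences differ in number")
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        rows = [encode_sequence(s, rid) for rid, s in zip(sample_ids, sequences)]
        matrix = np.vstack(rows) if rows else np.zeros((0, 0), dtype=np.uint8)
        return cls(sample_ids, matrix, population_of)

    def with_populations(self, population_of: dict[str, str]) -> "AlignedGenomeSet":
        return AlignedGenomeSet(self.sample_ids, self.matrix, population_of)

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def sequences(self) -> list[str]:
        return [decode_row(self.matrix[i]) for i in range(self.n_samples)]

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.population_of.values()))

    def population_indices(self, label: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.sample_ids) if self.population_of.get(s) == label]
        if not idx:
            raise InputError(f"no samples in population {label!r}")
        return np.asarray(idx, dtype=np.intp)

    def subset(self, indices: np.ndarray) -> "AlignedGenomeSet":
        indices = np.asarray(indices, dtype=np.intp)
        ids = [self.sample_ids[i] for i in indices]
        pops = {s: self.population_of[s] for s in ids} if self.population_of else None
        return AlignedGenomeSet(ids, self.matrix[indices], pops)


@dataclass
class GeneModel:
    """A gene span on the alignment; start/end are 0-based half-open."""

    name: str
    start: int
    end: int
    strand: str
    feature: str  # protein | tRNA | rRNA
    code_id: int = 2

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise InputError(f"gene {self.name!r}: invalid span [{self.start},{self.end})")
        if self.strand not in "+-":
            raise InputError(f"gene {self.name!r}: strand must be + or -")
        if self.feature not in ("protein", "tRNA", "rRNA"):
            raise InputError(f"gene {self.name!r}: unknown feature {self.feature!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class EffectAnnotation:
    """Map (0-based position, alternate base) -> benign/damaging/unknown."""

    LABELS = ("benign", "damaging", "unknown")

    def __init__(self, entries: dict[tuple[int, str], str] | None = None):
        self.entries = dict(entries or {})

    def lookup(self, position: int, base: str) -> str:
        return self.entries.get((position, base), "unknown")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class PathogenicCatalogue:
    """Reported/Confirmed pathogenic variants as (0-based position, base)."""

    entries: set[tuple[int, str]] = field(default_factory=set)
    status_of: dict[tuple[int, str], str] = field(default_factory=dict)
    n_discarded: int = 0

    def contains(self, position: int, base: str) -> bool:
        return (position, base) in self.entries

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_alignment(path) -> AlignedGenomeSet:
    """Read an aligned multi-FASTA into an AlignedGenomeSet.

    Lower case is folded to upper, U maps to T; any character outside
    A/C/G/T/N/- is an error naming the record and column. Requires at
    least two records of identical length and unique ids.
    """
    ids: list[str] = []
    rows: list[np.ndarray] = []
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise AlignmentError(
                f"ragged alignment: record {rec.id!r} has length {len(seq)}, expected {length}"
            )
        ids.append(rec.id)
        rows.append(encode_sequence(seq, rec.id))
    if len(rows) < 2:
        raise InputError(f"alignment {path} has {len(rows)} records; need at least 2")
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise InputError(f"duplicate record ids in {path}: {dupes[:5]}")
    return AlignedGenomeSet(ids, np.vstack(rows))


def write_alignment(path, genomes: AlignedGenomeSet) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(genomes.sample_ids, genomes.matrix):
            fh.write(f">{sid}\n{decode_row(row)}\n")


def read_sample_metadata(path) -> dict[str, str]:
    """Read the sample_id/population TSV; exactly two population labels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "population"}
    if not required.issubset(df.columns):
        raise InputError(f"metadata must have columns {sorted(required)}, got {list(df.columns)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise InputError(f"duplicate sample ids in metadata: {dupes[:5]}")
    labels = sorted(df["population"].unique())
    if len(labels) > 2:
        raise InputError(
            f"the survey is a two-population contrast; metadata has {len(labels)} labels: {labels}"
        )
    return dict(zip(df["sample_id"], df["population"]))


def write_sample_metadata(path, population_of: dict[str, str]) -> None:
    pd.DataFrame(
        {"sample_id": list(population_of), "population": list(population_of.values())}
    ).to_csv(path, sep="\t", index=False)


def attach_metadata(genomes: AlignedGenomeSet, population_of: dict[str, str]) -> AlignedGenomeSet:
    """Join alignment and metadata, requiring exact id agreement."""
    missing = [s for s in genomes.sample_ids if s not in population_of]
    if missing:
        raise InputError(f"metadata missing {len(missing)} alignment samples: {missing[:5]}")
    extra = sorted(set(population_of) - set(genomes.sample_ids))
    if extra:
        logger.warning("metadata has %d samples absent from alignment (ignored)", len(extra))
    return genomes.with_populations({s: population_of[s] for s in genomes.sample_ids})


_GFF_FEATURES = {"CDS": "protein", "protein": "protein", "tRNA": "tRNA", "rRNA": "rRNA"}
_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "frame", "attributes",
]


def _gff_name(attributes: str, default: str) -> str:
    for part in str(attributes).split(";"):
        part = part.strip()
        for key in ("Name=", "ID=", "gene="):
            if part.startswith(key):
                return part[len(key):]
    return default


def read_gene_models(path) -> list[GeneModel]:
    """Read a GFF3-style gene-model file (1-based inclusive coordinates).

    Feature types CDS/protein, tRNA and rRNA are kept; others ignored.
    Returns models sorted by start, converted to 0-based half-open.
    Overlapping protein genes are legal (mtDNA reality) but logged.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=_GFF_COLUMNS, dtype=str)
    models: list[GeneModel] = []
    for i, row in df.iterrows():
        if row["type"] not in _GFF_FEATURES:
            logger.info("gene models: ignoring feature type %r", row["type"])
            continue
        start1, end1 = int(row["start"]), int(row["end"])
        if start1 > end1:
            raise InputError(f"gene model line {i + 1}: start {start1} > end {end1}")
        code_id = 2
        for part in str(row["attributes"]).split(";"):
            if part.strip().startswith("transl_table="):
                code_id = int(part.split("=", 1)[1])
        models.append(
            GeneModel(
                name=_gff_name(row["attributes"], f"gene{i + 1}"),
                start=start1 - 1,
                end=end1,
                strand=row["strand"],
                feature=_GFF_FEATURES[row["type"]],
                code_id=code_id,
            )
        )
    models.sort(key=lambda g: (g.start, g.end, g.name))
    proteins = [g for g in models if g.feature == "protein"]
    for g in proteins:
        if g.length % 3:
            logger.warning("protein gene %s has length %d not divisible by 3", g.name, g.length)
    for a, b in zip(proteins, proteins[1:]):
        if b.start < a.end:
            logger.info("overlapping protein genes: %s and %s", a.name, b.name)
    return models


def write_gene_models(path, models: list[GeneModel]) -> None:
    type_of = {"protein": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            attrs = f"Name={g.name};transl_table={g.code_id}"
            fh.write(
                "\t".join(
                    [
                        "alignment", "mitosurvey", type_of[g.feature],
                        str(g.start + 1), str(g.end), ".", g.strand, ".", attrs,
                    ]
                )
                + "\n"
            )


_EFFECT_ALIASES = {
    "benign": "benign",
    "damaging": "damaging",
    "possibly damaging": "damaging",
    "probably damaging": "damaging",
    "possibly_damaging": "damaging",
    "probably_damaging": "damaging",
    "unknown": "unknown",
}


def read_effect_annotation(path, alignment_length: int | None = None) -> EffectAnnotation:
    """Read a position/alt_base/label TSV of variant-effect predictions.

    The two 'damaging' sub-grades are pooled into one damaging class.
    Positions are 1-based on disk.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["position", "alt_base", "label"], path)
    entries: dict[tuple[int, str], str] = {}
    for _, row in df.iterrows():
        label = str(row["label"]).strip().lower()
        if label not in _EFFECT_ALIASES:
            raise InputError(f"unknown effect label {row['label']!r} in {path}")
        pos = int(row["position"]) - 1
        base = str(row["alt_base"]).strip().upper()
        _check_pos_base(pos, base, alignment_length, path)
        entries[(pos, base)] = _EFFECT_ALIASES[label]
    return EffectAnnotation(entries)


def write_effect_annotation(path, annotation: EffectAnnotation) -> None:
    rows = [
        {"position": pos + 1, "alt_base": base, "label": label}
        for (pos, base), label in sorted(annotation.entries.items())
    ]
    pd.DataFrame(rows, columns=["position", "alt_base", "label"]).to_csv(
        path, sep="\t", index=False
    )


USABLE_STATUSES = ("Reported", "Confirmed")


def read_pathogenic_catalogue(path, alignment_length: int | None = None) -> PathogenicCatalogue:
    """Read the pathogenic-variant TSV, keeping only Reported/Confirmed.

    Other statuses are discarded (count logged). An empty file is a
    valid, empty catalogue.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["position", "alt_base", "status"], path)
    cat = PathogenicCatalogue()
    for _, row in df.iterrows():
        status = str(row["status"]).strip()
        pos = int(row["position"]) - 1
        base = str(row["alt_base"]).strip().upper()
        _check_pos_base(pos, base, alignment_length, path)
        if status not in USABLE_STATUSES:
            cat.n_discarded += 1
            continue
        cat.entries.add((pos, base))
        cat.status_of[(pos, base)] = status
    if cat.n_discarded:
        logger.info(
            "pathogenic catalogue: discarded %d entries with status outside %s",
            cat.n_discarded, USABLE_STATUSES,
        )
    return cat


def write_pathogenic_catalogue(path, cat: PathogenicCatalogue, extra_rows=None) -> None:
    rows = [
        {"position": pos + 1, "alt_base": base, "status": cat.status_of.get((pos, base), "Reported")}
        for (pos, base) in sorted(cat.entries)
    ]
    rows += list(extra_rows or [])
    rows.sort(key=lambda r: (r["position"], r["alt_base"]))
    pd.DataFrame(rows, columns=["position", "alt_base", "status"]).to_csv(
        path, sep="\t", index=False
    )


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    if not set(cols).issubset(df.columns):
        raise InputError(f"{path}: expected columns {cols}, got {list(df.columns)}")


def _check_pos_base(pos: int, base: str, alignment_length: int | None, path) -> None:
    if base not in "ACGT":
        raise InputError(f"{path}: alternate base must be A/C/G/T, got {base!r}")
    if pos < 0 or (alignment_length is not None and pos >= alignment_length):
        raise InputError(f"{path}: position {pos + 1} outside alignment")
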