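"""Domain types and file I/O for protease cleavage-site data.

Coordinate convention
---------------------
Residue positions are 1-based.  A cleavage site is named by the index of its
P1 residue: the scissile bond lies between residues ``p1`` and ``p1 + 1``,
so valid sites for a protein of length ``L`` are ``1 <= p1 <= L - 1``.
This matches the P1/P1' nomenclature used in degradomics, where P4..P1 are
the residues N-terminal of the bond and P1'..P4' the residues C-terminal.

File formats
------------
Sequences are plain FASTA (read/written with Biopython).  Tabular inputs are
tab-separated UTF-8 files with a header row:

* cleavage annotations: ``protease``, ``protein_id``, ``p1``
* disulfide bonds:      ``protein_id``, ``cys_a``, ``cys_b``
* peptide hits:         ``protein_id``, ``peptide``
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids, alphabetical by one-letter code.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Letters that may legally appear in a sequence but are not standard
#: residues (ambiguity codes and rare residues).
NONSTANDARD_AA = set("BJOUXZ")

SS_CLASSES = ("coil", "strand", "helix")
EXPOSURE_CLASSES = ("exposed", "buried")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed at all."""


class AnnotationSource(enum.Enum):
    DATABASE = "database"
    EXPERIMENT = "experiment"
    PREDICTION = "prediction"


@dataclass(frozen=True)
class StructuralFeatures:
    """Per-residue structural annotation for one protein.

    ``ss_class`` holds one of :data:`SS_CLASSES` per residue, ``exposure``
    one of :data:`EXPOSURE_CLASSES`, ``disorder`` a boolean flag, and
    ``coords`` an ``(L, 3)`` array of (x, y, z) positions in arbitrary
    units (they are standardized per protein before encoding).
    """

    ss_class: tuple[str, ...]
    exposure: tuple[str, ...]
    disorder: tuple[bool, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        L = len(self.ss_class)
        if not (len(self.exposure) == len(self.disorder) == L):
            raise ValidationError("structural feature tracks differ in length")
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (L, 3):
            raise ValidationError(f"coords must have shape ({L}, 3), got {coords.shape}")
        object.__setattr__(self, "coords", coords)
        bad_ss = set(self.ss_class) - set(SS_CLASSES)
        if bad_ss:
            raise ValidationError(f"unknown secondary-structure classes: {sorted(bad_ss)}")
        bad_exp = set(self.exposure) - set(EXPOSURE_CLASSES)
        if bad_exp:
            raise ValidationError(f"unknown exposure classes: {sorted(bad_exp)}")

    def __len__(self) -> int:
        return len(self.ss_class)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with optional disulfide pairs and structure.

    ``disulfide_pairs`` is a frozenset of 1-based ``(i, j)`` index pairs
    (stored with ``i < j``); both members must be cysteines and no residue
    may participate in two bonds.
    """

    id: str
    sequence: str
    disulfide_pairs: frozenset[tuple[int, int]] = frozenset()
    features: StructuralFeatures | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein id must be non-empty")
        seq = self.sequence.upper()
        if len(seq) < 1:
            raise ValidationError(f"{self.id}: sequence must be non-empty")
        object.__setattr__(self, "sequence", seq)
        pairs = frozenset(tuple(sorted(p)) for p in self.disulfide_pairs)
        seen: set[int] = set()
        for i, j in pairs:
            for k in (i, j):
                if not (1 <= k <= len(seq)):
                    raise ValidationError(
                        f"{self.id}: disulfide index {k} outside [1, {len(seq)}]"
                    )
                if seq[k - 1] != "C":
                    raise ValidationError(
                        f"{self.id}: disulfide index {k} points at "
                        f"'{seq[k - 1]}', not Cys"
                    )
                if k in seen:
                    raise ValidationError(f"{self.id}: residue {k} in two disulfide pairs")
                seen.add(k)
            if i == j:
                raise ValidationError(f"{self.id}: degenerate disulfide pair ({i}, {j})")
        object.__setattr__(self, "disulfide_pairs", pairs)
        if self.features is not None and len(self.features) != len(seq):
            raise ValidationError(
                f"{self.id}: features cover {len(self.features)} residues, "
                f"sequence has {len(seq)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def nonstandard_positions(self) -> tuple[int, ...]:
        """1-based positions holding non-standard residue letters."""
        return tuple(
            i + 1 for i, aa in enumerate(self.sequence) if aa not in STANDARD_AA
        )


@dataclass(frozen=True, order=True)
class CleavageAnnotation:
    """One (protease, protein, P1) cleavage site, observed or predicted."""

    protease: str
    protein_id: str
    p1: int
    source: AnnotationSource = AnnotationSource.DATABASE
    score: float | None = None

    def __post_init__(self) -> None:
        if self.p1 < 1:
            raise ValidationError(f"p1 must be >= 1, got {self.p1}")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"score must lie in [0, 1], got {self.score}")


@dataclass(frozen=True)
class PeptideHit:
    """An identified peptide attributed to a protein."""

    protein_id: str
    peptide: str

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValidationError("peptide must be non-empty")
        object.__setattr__(self, "peptide", self.peptide.upper())


# The 14 tissue proteases modelled by the original study: eight matrix
# metalloproteinases and six other (serine/cysteine/aspartyl) proteases.
_DEFAULT_REGISTRY: tuple[tuple[str, str], ...] = (
    ("MMP1", "MMP"),
    ("MMP2", "MMP"),
    ("MMP3", "MMP"),
    ("MMP7", "MMP"),
    ("MMP8", "MMP"),
    ("MMP9", "MMP"),
    ("MMP12", "MMP"),
    ("MMP13", "MMP"),
    ("cathepsin K", "other"),
    ("cathepsin G", "other"),
    ("cathepsin B", "other"),
    ("cathepsin D", "other"),
    ("elastase-2", "other"),
    ("granzyme B", "other"),
)


@dataclass(frozen=True)
class ProteaseRegistry:
    """Known protease identifiers, each tagged with a group (MMP / other)."""

    entries: tuple[tuple[str, str], ...] = _DEFAULT_REGISTRY

    def __post_init__(self) -> None:
        ids = [pid for pid, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate protease ids in registry")

    @classmethod
    def default(cls) -> "ProteaseRegistry":
        return cls()

    @classmethod
    def from_ids(cls, ids: Iterable[str], group: str = "other") -> "ProteaseRegistry":
        return cls(tuple((pid, group) for pid in ids))

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(pid for pid, _ in self.entries)

    def __contains__(self, protease: str) -> bool:
        return protease in self.ids

    def __len__(self) -> int:
        return len(self.entries)

    def group(self, protease: str) -> str:
        for pid, grp in self.entries:
            if pid == protease:
                return grp
        raise KeyError(protease)

    def members(self, group: str) -> tuple[str, ...]:
        return tuple(pid for pid, grp in self.entries if grp == group)


class CleavageTableReport(NamedTuple):
    """Result of loading an annotation table: kept rows plus a reject log."""

    annotations: list[CleavageAnnotation]
    n_rejected: int
    rejected: pd.DataFrame


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    The record id is the first whitespace-delimited token of the header and
    sequences are uppercased; input order is preserved.  A header with no
    sequence raises :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            lineno = _find_header_line(path, rec.id)
            raise ParseError(
                f"{path}:{lineno}: FASTA header '{rec.id}' has no sequence"
            )
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


def _find_header_line(path: Path, rec_id: str) -> int:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].split()[0:1] == [rec_id]:
                return lineno
    return 0


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Tabular formats
# ---------------------------------------------------------------------------

def read_cleavage_table(
    path: str | Path,
    registry: ProteaseRegistry,
    proteins: Mapping[str, ProteinRecord] | None = None,
    source: AnnotationSource = AnnotationSource.DATABASE,
) -> CleavageTableReport:
    """Load a cleavage-annotation TSV (columns protease, protein_id, p1).

    Rows whose protease is absent from ``registry`` are rejected and
    returned in the report; duplicate (protease, protein_id, p1) rows are
    deduplicated.  When ``proteins`` is given, every ``p1`` is validated
    against ``1 <= p1 <= L - 1``; violations raise :class:`ValidationError`
    listing the offending rows.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"protease": str, "protein_id": str})
    required = {"protease", "protein_id", "p1"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    known = df["protease"].isin(registry.ids)
    rejected = df.loc[~known]
    df = df.loc[known].drop_duplicates(subset=["protease", "protein_id", "p1"])

    if proteins is not None:
        bad_rows = []
        for row in df.itertuples(index=True):
            prot = proteins.get(row.protein_id)
            if prot is None:
                bad_rows.append((row.Index, row.protein_id, int(row.p1), "unknown protein"))
            elif not (1 <= int(row.p1) <= prot.length - 1):
                bad_rows.append(
                    (row.Index, row.protein_id, int(row.p1), f"p1 outside [1, {prot.length - 1}]")
                )
        if bad_rows:
            detail = "; ".join(f"row {i}: {pid} p1={p1} ({why})" for i, pid, p1, why in bad_rows)
            raise ValidationError(f"{path}: invalid cleavage positions: {detail}")

    annotations = [
        CleavageAnnotation(
            protease=row.protease,
            protein_id=row.protein_id,
            p1=int(row.p1),
            source=source,
        )
        for row in df.itertuples(index=False)
    ]
    return CleavageTableReport(annotations, len(rejected), rejected.reset_index(drop=True))


def write_cleavage_table(
    annotations: Iterable[CleavageAnnotation], path: str | Path, scores: bool = False
) -> None:
    rows = [
        {
            "protease": a.protease,
            "protein_id": a.protein_id,
            "p1": a.p1,
            **({"score": a.score} if scores else {}),
        }
        for a in annotations
    ]
    cols = ["protease", "protein_id", "p1"] + (["score"] if scores else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_disulfide_table(path: str | Path) -> dict[str, frozenset[tuple[int, int]]]:
    """Load disulfide bonds (columns protein_id, cys_a, cys_b) per protein."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    out: dict[str, set[tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        pair = tuple(sorted((int(row.cys_a), int(row.cys_b))))
        out.setdefault(row.protein_id, set()).add(pair)
    return {pid: frozenset(pairs) for pid, pairs in out.items()}


def write_disulfide_table(
    pairs_by_protein: Mapping[str, Iterable[tuple[int, int]]], path: str | Path
) -> None:
    rows = [
        {"protein_id": pid, "cys_a": a, "cys_b": b}
        for pid, pairs in pairs_by_protein.items()
        for a, b in sorted(pairs)
    ]
    pd.DataFrame(rows, columns=["protein_id", "cys_a", "cys_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_peptide_table(path: str | Path) -> list[PeptideHit]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"protein_id", "peptide"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns protein_id, peptide")
    return [PeptideHit(row.protein_id, row.peptide) for row in df.itertuples(index=False)]


def write_peptide_table(hits: Iterable[PeptideHit], path: str | Path) -> None:
    pd.DataFrame(
        [{"protein_id": h.protein_id, "peptide": h.peptide} for h in hits],
        columns=["protein_id", "peptide"],
    ).to_csv(path, sep="\t", index=False)


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Load a prediction-score TSV (protein_id, p1, score)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    if not {"protein_id", "p1", "score"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns protein_id, p1, score")
    return df


def write_score_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Candidate sites
# ---------------------------------------------------------------------------

def candidate_sites(protein: ProteinRecord) -> list[int]:
    """All possible P1 positions of a protein: ``[1, L - 1]``.

    The negative class for a protease is this universe minus its annotated
    positives.  A single-residue protein has no inter-residue bond and
    yields the empty list.
    """
    return list(range(1, protein.length))
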