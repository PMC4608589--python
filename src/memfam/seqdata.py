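"""Sequence and family containers, FASTA I/O, and redundancy reduction.

A *family* is a named collection of homologous protein sequences, one
record per non-redundant homologue.  Family sets are the unit every other
stage consumes: topology calling, pairwise comparison screens, repeat
surveys and motif scans all take :class:`FamilySet` inputs.

Redundancy reduction follows the convention used when assembling homolog
lists for comparison-score work: of any group of proteins more than 80%
identical, only one representative (the longest) is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import SequenceLoadError

#: The canonical residue alphabet; X stands for any/unknown residue.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
#: Ambiguity codes folded into X at load time.
AMBIGUOUS_RESIDUES = frozenset("BZUJO")
#: Records shorter than this are rejected for pipeline use.
MIN_RECORD_LENGTH = 30


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence keyed by its database accession."""

    accession: str
    description: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        """Residues with alignment gaps removed."""
        return self.residues.replace("-", "")


@dataclass
class FamilySet:
    """An ordered, accession-unique collection of family members.

    ``tc_number`` optionally carries the family's transporter
    classification number (e.g. ``2.A.75`` for LysE).
    """

    family_id: str
    members: list[ProteinRecord]
    tc_number: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"family {self.family_id!r} has no members")
        seen: set[str] = set()
        for rec in self.members:
            if rec.accession in seen:
                raise ValueError(
                    f"duplicate accession {rec.accession!r} in family {self.family_id!r}"
                )
            seen.add(rec.accession)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.members)

    def __getitem__(self, accession: str) -> ProteinRecord:
        for rec in self.members:
            if rec.accession == accession:
                return rec
        raise KeyError(accession)

    @property
    def accessions(self) -> list[str]:
        return [rec.accession for rec in self.members]


@dataclass(frozen=True)
class RedundancyParams:
    """Identity threshold above which a candidate is considered redundant."""

    identity_threshold: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_threshold <= 1.0:
            raise ValueError("identity_threshold must lie in (0, 1]")


def _clean_residues(accession: str, raw: str, allow_gaps: bool) -> str:
    residues = raw.upper().replace("*", "")
    folded = []
    n_ambiguous = 0
    for ch in residues:
        if ch in AMBIGUOUS_RESIDUES:
            folded.append("X")
            n_ambiguous += 1
        elif ch in VALID_RESIDUES or (allow_gaps and ch in "-."):
            folded.append("-" if ch == "." else ch)
        else:
            raise SequenceLoadError(
                f"record {accession!r} contains illegal residue character {ch!r}"
            )
    if n_ambiguous:
        warnings.warn(
            f"record {accession!r}: {n_ambiguous} ambiguous residue(s) mapped to X",
            stacklevel=3,
        )
    return "".join(folded)


def read_fasta(
    path: str | Path,
    family_id: str | None = None,
    tc_number: str | None = None,
    aligned: bool = False,
) -> FamilySet:
    """Read a (possibly aligned) FASTA file into a :class:`FamilySet`.

    The accession is the first whitespace-delimited token of the header.
    Records shorter than :data:`MIN_RECORD_LENGTH` (ungapped) are dropped
    with a warning.  With ``aligned=True``, gap characters are preserved
    and all rows must have equal aligned length.
    """
    path = Path(path)
    if family_id is None:
        family_id = path.stem
    members: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        if not accession:
            raise SequenceLoadError(f"{path}: record with empty header")
        residues = _clean_residues(accession, str(rec.seq), allow_gaps=aligned)
        ungapped = residues.replace("-", "")
        if not ungapped:
            raise SequenceLoadError(f"record {accession!r} has an empty sequence")
        if len(ungapped) < MIN_RECORD_LENGTH:
            warnings.warn(
                f"record {accession!r} shorter than {MIN_RECORD_LENGTH} residues; skipped",
                stacklevel=2,
            )
            continue
        members.append(ProteinRecord(accession, rec.description, residues))
    if aligned and members:
        lengths = {len(m.residues) for m in members}
        if len(lengths) > 1:
            raise SequenceLoadError(f"{path}: ragged alignment, row lengths {sorted(lengths)}")
    return FamilySet(family_id=family_id, members=members, tc_number=tc_number)


def write_fasta(family: FamilySet, path: str | Path, width: int = 60) -> None:
    """Write a family to FASTA, preserving accession and description."""
    records = [
        SeqRecord(Seq(rec.residues), id=rec.accession, description=rec.description)
        for rec in family.members
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def read_manifest(path: str | Path, aligned: bool = False) -> dict[str, FamilySet]:
    """Read a TSV manifest of ``family_id<TAB>fasta_path[<TAB>tc_number]``.

    Relative paths resolve against the manifest's directory.
    """
    path = Path(path)
    families: dict[str, FamilySet] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise SequenceLoadError(f"{path}: malformed manifest line {line!r}")
        family_id, fasta = parts[0], parts[1]
        tc_number = parts[2] if len(parts) > 2 else None
        fasta_path = Path(fasta)
        if not fasta_path.is_absolute():
            fasta_path = path.parent / fasta_path
        families[family_id] = read_fasta(
            fasta_path, family_id=family_id, tc_number=tc_number, aligned=aligned
        )
    return families


def pairwise_identity(a: str, b: str, align_params=None) -> float:
    """Global-alignment identity: matches / aligned columns.

    Columns with a gap in both rows cannot occur in a pairwise global
    alignment, so the denominator is simply the alignment length.  The
    aligner and its scoring parameters are shared with the comparison
    engine so one scoring configuration governs the whole suite.
    """
    from .paircompare import AlignParams, align  # deferred: avoids module cycle

    if align_params is None:
        align_params = AlignParams()
    result = align(a, b, align_params)
    n_cols = 0
    matches = 0
    for i, j in result.path_with_gaps():
        n_cols += 1
        if i is not None and j is not None and a[i] == b[j]:
            matches += 1
    return matches / n_cols if n_cols else 0.0


def reduce_redundancy(family: FamilySet, params: RedundancyParams | None = None) -> FamilySet:
    """Greedy longest-first redundancy reduction.

    Candidates are visited from longest to shortest; a candidate is dropped
    iff its global identity to any already-retained record exceeds the
    threshold.  The returned set preserves the retained members' input
    order.  Idempotent by construction: the retained set contains no pair
    above the threshold.
    """
    if params is None:
        params = RedundancyParams()
    order = sorted(
        range(len(family.members)),
        key=lambda i: (-len(family.members[i].ungapped), i),
    )
    retained_idx: list[int] = []
    for i in order:
        cand = family.members[i]
        redundant = False
        for j in retained_idx:
            kept = family.members[j]
            if pairwise_identity(cand.ungapped, kept.ungapped) > params.identity_threshold:
                redundant = True
                break
        if not redundant:
            retained_idx.append(i)
    retained_idx.sort()
    return FamilySet(
        family_id=family.family_id,
        members=[family.members[i] for i in retained_idx],
        tc_number=family.tc_number,
    )
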