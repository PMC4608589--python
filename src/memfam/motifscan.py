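"""Degenerate-motif scanning with TMS localization and family prevalence.

Patterns use the compact notation of conserved-motif tables: plain
letters for fixed residues, ``X`` for any residue, and parenthesized
alternatives such as ``(K/R)``.  ``FGX(K/R)XL`` therefore matches a
six-residue window with F, G, anything, K or R, anything, L.  Hits are
ungapped; each is labeled with the TMS index containing its midpoint
(1-based, or ``loop``), since motif claims in the field are tied to TMS
numbers ("the GXXXL motif in TMS 3").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import MemfamError
from .seqdata import AMINO_ACIDS, FamilySet, ProteinRecord
from .topology import TmsAnnotation


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate pattern as an ordered list of allowed-residue sets.

    ``None`` marks a wildcard position (X).
    """

    name: str
    positions: tuple[frozenset[str] | None, ...]
    source: str = ""

    def __len__(self) -> int:
        return len(self.positions)

    def matches_at(self, residues: str, offset: int) -> bool:
        if offset < 0 or offset + len(self.positions) > len(residues):
            return False
        for k, allowed in enumerate(self.positions):
            if allowed is not None and residues[offset + k] not in allowed:
                return False
        return True


@dataclass(frozen=True)
class MotifHit:
    accession: str
    start: int  # 0-based
    end: int  # half-open
    matched: str
    tms_index: int | None  # 1-based TMS number, None for loop


@dataclass
class MotifSurvey:
    """Prevalence of one motif over one or more families."""

    pattern: MotifPattern
    families: list[str]
    best_hits: dict[str, MotifHit]  # accession -> best (first) qualifying hit
    n_displaying: int
    n_total: int
    per_family: dict[str, tuple[int, int]] = field(default_factory=dict)


def parse_pattern(text: str, name: str | None = None, source: str = "") -> MotifPattern:
    """Parse motif notation: letters, ``X`` wildcards, ``(K/R)`` alternatives."""
    positions: list[frozenset[str] | None] = []
    i = 0
    text = text.strip()
    while i < len(text):
        ch = text[i]
        if ch == "(":
            j = text.find(")", i)
            if j < 0:
                raise MemfamError(f"unclosed alternative in pattern {text!r}")
            alternatives = text[i + 1 : j].split("/")
            residues = frozenset(a.strip().upper() for a in alternatives)
            if not residues or any(len(r) != 1 or r not in AMINO_ACIDS for r in residues):
                raise MemfamError(f"malformed alternative {text[i:j + 1]!r} in {text!r}")
            positions.append(residues)
            i = j + 1
        elif ch.upper() == "X":
            positions.append(None)
            i += 1
        elif ch.upper() in AMINO_ACIDS:
            positions.append(frozenset(ch.upper()))
            i += 1
        else:
            raise MemfamError(f"illegal character {ch!r} in pattern {text!r}")
    if len(positions) < 3:
        raise MemfamError(f"pattern {text!r} must have at least 3 positions")
    return MotifPattern(name=name or text, positions=tuple(positions), source=source)


def scan(
    record: ProteinRecord,
    pattern: MotifPattern,
    tms: TmsAnnotation | None = None,
) -> list[MotifHit]:
    """All ungapped matches in left-to-right order, TMS-localized."""
    residues = record.ungapped
    hits: list[MotifHit] = []
    span = len(pattern)
    for offset in range(len(residues) - span + 1):
        if pattern.matches_at(residues, offset):
            tms_index = None
            if tms is not None:
                idx = tms.segment_index(offset + span // 2)
                tms_index = idx + 1 if idx is not None else None
            hits.append(
                MotifHit(
                    accession=record.accession,
                    start=offset,
                    end=offset + span,
                    matched=residues[offset : offset + span],
                    tms_index=tms_index,
                )
            )
    return hits


def survey(
    families: Sequence[FamilySet],
    pattern: MotifPattern,
    annotations: dict[str, TmsAnnotation] | None = None,
    expected_tms: int | None = None,
) -> MotifSurvey:
    """Count proteins displaying the motif, per family and combined.

    A protein displays the motif iff it has at least one hit — restricted
    to hits localized in TMS ``expected_tms`` when given (prevalence
    claims are usually tied to a stated TMS number).
    """
    best_hits: dict[str, MotifHit] = {}
    per_family: dict[str, tuple[int, int]] = {}
    n_displaying = 0
    n_total = 0
    for fam in families:
        fam_hits = 0
        for rec in fam.members:
            n_total += 1
            tms = annotations.get(rec.accession) if annotations else None
            hits = scan(rec, pattern, tms)
            if expected_tms is not None:
                hits = [h for h in hits if h.tms_index == expected_tms]
            if hits:
                best_hits[rec.accession] = hits[0]
                fam_hits += 1
                n_displaying += 1
        per_family[fam.family_id] = (fam_hits, len(fam.members))
    return MotifSurvey(
        pattern=pattern,
        families=[fam.family_id for fam in families],
        best_hits=best_hits,
        n_displaying=n_displaying,
        n_total=n_total,
        per_family=per_family,
    )


def position_frequencies(msa: FamilySet) -> "np.ndarray":
    """Per-column residue frequency table over an aligned family.

    Returns an array of shape (n_columns, 20) over the canonical
    alphabet, with each row summing to 1 where the column has residues
    (gap-only columns are all zero).  Conservation claims can be checked
    as thresholds on these frequencies: fully conserved = 1.00, strongly
    conserved >= 0.90, well conserved >= 0.70.
    """
    lengths = {len(rec.residues) for rec in msa.members}
    if len(lengths) != 1:
        raise MemfamError(f"ragged alignment in family {msa.family_id!r}")
    n_cols = lengths.pop()
    index = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    counts = np.zeros((n_cols, len(AMINO_ACIDS)))
    for rec in msa.members:
        for col, ch in enumerate(rec.residues):
            if ch in index:
                counts[col, index[ch]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
    return freqs


def write_hits_tsv(hits: Sequence[MotifHit], path: str | Path) -> None:
    """Hit table (1-based inclusive coordinates)."""
    with open(path, "w") as handle:
        handle.write("accession\tstart\tend\tmatched\ttms_index\n")
        for h in hits:
            loc = h.tms_index if h.tms_index is not None else "loop"
            handle.write(f"{h.accession}\t{h.start + 1}\t{h.end}\t{h.matched}\t{loc}\n")


def write_survey_tsv(surveys: Sequence[MotifSurvey], path: str | Path) -> None:
    """Prevalence table: families, motif, displaying/total, per-family split."""
    with open(path, "w") as handle:
        handle.write("families\tmotif\tn_displaying\tn_total\tper_family\n")
        for s in surveys:
            per = ", ".join(f"{k}:{v[0]}/{v[1]}" for k, v in sorted(s.per_family.items()))
            handle.write(
                f"{' & '.join(s.families)}\t{s.pattern.name}\t{s.n_displaying}"
                f"\t{s.n_total}\t{per}\n"
            )
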