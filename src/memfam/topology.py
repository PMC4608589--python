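"""Hydropathy/amphipathicity profiles, TMS calling, and averaged (AveHAS-style) plots.

Transmembrane α-helical segments (TMSs) are the structural currency of
the superfamily analyses: homology verdicts require aligned TMSs, repeat
detection compares TMS-defined halves, and motifs are localized to TMS
indices.  Segments are represented as 0-based half-open intervals
internally; TSV import/export uses the 1-based inclusive convention usual
in annotation tables.

The TMS caller is a transparent sliding-window hydropathy thresholder
(Kyte–Doolittle scale), not a hidden Markov model: maximal runs of
window-averaged hydropathy above a cutoff are merged across short dips,
length-filtered, and trimmed.  Externally produced annotations (e.g. from
an HMM-based predictor) can be imported and used everywhere a predicted
annotation is accepted.

Amphipathicity is the Eisenberg hydrophobic moment with 100° per residue,
the canonical α-helix periodicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .seqdata import FamilySet, ProteinRecord

#: Kyte–Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}


@dataclass(frozen=True)
class TopologyParams:
    """Windowing and threshold parameters for profile and TMS computation.

    ``tms_threshold`` is on the Kyte–Doolittle scale: mean window
    hydropathy of 1.6 is the classic cutoff for a membrane-spanning
    stretch.  TMS length bounds bracket the 15–25 residues an α-helix
    needs to cross the bilayer.
    """

    hydropathy_window: int = 19
    amphipathicity_window: int = 11
    helix_angle_deg: float = 100.0
    tms_threshold: float = 1.6
    tms_min_len: int = 15
    tms_max_len: int = 25
    merge_gap: int = 3

    def __post_init__(self) -> None:
        for w in (self.hydropathy_window, self.amphipathicity_window):
            if w < 5 or w % 2 == 0:
                raise ValueError("windows must be odd integers >= 5")
        if not 0 < self.tms_min_len <= self.tms_max_len:
            raise ValueError("require 0 < tms_min_len <= tms_max_len")


@dataclass
class TmsAnnotation:
    """Ordered, non-overlapping TMS intervals on one protein (0-based half-open)."""

    accession: str
    segments: list[tuple[int, int]]
    source: Literal["predicted", "imported"] = "predicted"

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.segments:
            if start < 0 or end <= start:
                raise ValueError(f"{self.accession}: bad segment ({start}, {end})")
            if start < prev_end:
                raise ValueError(f"{self.accession}: segments overlap or are unsorted")
            prev_end = end

    @property
    def n_tms(self) -> int:
        return len(self.segments)

    def segment_index(self, pos: int) -> int | None:
        """0-based index of the segment containing ``pos``, or None."""
        for idx, (start, end) in enumerate(self.segments):
            if start <= pos < end:
                return idx
        return None


@dataclass
class AvehasProfile:
    """Per-alignment-column averaged hydropathy, amphipathicity and similarity."""

    n_columns: int
    avg_hydropathy: np.ndarray
    avg_amphipathicity: np.ndarray
    similarity: np.ndarray
    contributing_counts: np.ndarray


def _kd_values(residues: str) -> np.ndarray:
    return np.array([KYTE_DOOLITTLE[ch] for ch in residues])


def hydropathy_profile(record: ProteinRecord | str, params: TopologyParams | None = None) -> np.ndarray:
    """Mean Kyte–Doolittle hydropathy over a centered window at each position.

    Windows are truncated at the termini, so every position has a value.
    """
    params = params or TopologyParams()
    residues = record.ungapped if isinstance(record, ProteinRecord) else record
    if len(residues) < params.hydropathy_window:
        raise ValueError("sequence shorter than the hydropathy window")
    values = _kd_values(residues)
    half = params.hydropathy_window // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    n = len(values)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def amphipathicity_profile(record: ProteinRecord | str, params: TopologyParams | None = None) -> np.ndarray:
    """Hydrophobic moment magnitude over a centered window at each position.

    ``|Σ_j H(a_j)·(cos jδ, sin jδ)| / w`` with δ the per-residue helix
    angle and ``w`` the (truncated) window size.
    """
    params = params or TopologyParams()
    residues = record.ungapped if isinstance(record, ProteinRecord) else record
    if len(residues) < params.amphipathicity_window:
        raise ValueError("sequence shorter than the amphipathicity window")
    values = _kd_values(residues)
    n = len(values)
    delta = math.radians(params.helix_angle_deg)
    angles = np.arange(n) * delta
    cos_part = values * np.cos(angles)
    sin_part = values * np.sin(angles)
    half = params.amphipathicity_window // 2
    ccos = np.concatenate(([0.0], np.cumsum(cos_part)))
    csin = np.concatenate(([0.0], np.cumsum(sin_part)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    moment = np.hypot(ccos[hi] - ccos[lo], csin[hi] - csin[lo])
    return moment / (hi - lo)


def predict_tms(record: ProteinRecord | str, params: TopologyParams | None = None) -> TmsAnnotation:
    """Call TMSs as thresholded hydropathy runs.

    Maximal runs with windowed hydropathy >= ``tms_threshold`` are found;
    runs separated by at most ``merge_gap`` residues are merged; runs
    shorter than ``tms_min_len`` are discarded; runs longer than
    ``tms_max_len`` are trimmed symmetrically.
    """
    params = params or TopologyParams()
    accession = record.accession if isinstance(record, ProteinRecord) else "query"
    profile = hydropathy_profile(record, params)
    above = profile >= params.tms_threshold
    runs: list[list[int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append([start, i])
            start = None
    if start is not None:
        runs.append([start, len(above)])
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= params.merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    segments: list[tuple[int, int]] = []
    for start, end in merged:
        length = end - start
        if length < params.tms_min_len:
            continue
        if length > params.tms_max_len:
            excess = length - params.tms_max_len
            start += excess // 2
            end = start + params.tms_max_len
        segments.append((start, end))
    return TmsAnnotation(accession=accession, segments=segments, source="predicted")


@dataclass(frozen=True)
class _MatrixNorm:
    matrix: object
    lo: float
    hi: float


def _similarity_matrix(name: str) -> _MatrixNorm:
    m = substitution_matrices.load(name)
    values = np.array(m).ravel()
    return _MatrixNorm(matrix=m, lo=float(values.min()), hi=float(values.max()))


def column_similarity(column: Sequence[str], norm: _MatrixNorm) -> float:
    """Mean normalized pairwise substitution score of column residues.

    Each residue pair (a, b) contributes
    ``(s(a,b) − s_min) / (max(s(a,a), s(b,b)) − s_min)`` with ``s_min``
    the matrix minimum, so an identical pair scores exactly 1 and the
    worst mismatch 0.  Gap pairs are excluded; a column with fewer than
    two residues has no pair and scores 0 by convention.
    """
    residues = [ch for ch in column if ch != "-"]
    if len(residues) < 2:
        return 0.0
    total = 0.0
    n_pairs = 0
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            a, b = residues[i], residues[j]
            try:
                s = norm.matrix[a, b]
                hi = max(norm.matrix[a, a], norm.matrix[b, b])
            except (KeyError, IndexError):
                s, hi = norm.lo, norm.hi
            total += max((s - norm.lo) / (hi - norm.lo), 0.0)
            n_pairs += 1
    return total / n_pairs


def avehas(
    msa: FamilySet,
    params: TopologyParams | None = None,
    matrix: str = "BLOSUM62",
) -> AvehasProfile:
    """AveHAS-style averaged profiles over an aligned family.

    Per-sequence hydropathy/amphipathicity profiles are computed on the
    ungapped sequences and scattered back onto alignment columns; column
    averages run over the sequences contributing a residue to that
    column.  Similarity is the normalized mean pairwise substitution
    score of the column's residues, in [0, 1].
    """
    params = params or TopologyParams()
    lengths = {len(rec.residues) for rec in msa.members}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment in family {msa.family_id!r}")
    n_columns = lengths.pop()
    hyd_sum = np.zeros(n_columns)
    amp_sum = np.zeros(n_columns)
    counts = np.zeros(n_columns, dtype=int)
    columns: list[list[str]] = [[] for _ in range(n_columns)]
    for rec in msa.members:
        ungapped = rec.ungapped
        hyd = hydropathy_profile(ungapped, params)
        amp = amphipathicity_profile(ungapped, params)
        pos = 0
        for col, ch in enumerate(rec.residues):
            columns[col].append(ch)
            if ch != "-":
                hyd_sum[col] += hyd[pos]
                amp_sum[col] += amp[pos]
                counts[col] += 1
                pos += 1
    norm = _similarity_matrix(matrix)
    similarity = np.array([column_similarity(col, norm) for col in columns])
    with np.errstate(invalid="ignore", divide="ignore"):
        avg_h = np.where(counts > 0, hyd_sum / np.maximum(counts, 1), 0.0)
        avg_a = np.where(counts > 0, amp_sum / np.maximum(counts, 1), 0.0)
    return AvehasProfile(
        n_columns=n_columns,
        avg_hydropathy=avg_h,
        avg_amphipathicity=avg_a,
        similarity=similarity,
        contributing_counts=counts,
    )


def read_tms_tsv(path: str | Path) -> dict[str, TmsAnnotation]:
    """Import TMS annotations from TSV (accession, start, end, source), 1-based inclusive."""
    annotations: dict[str, list[tuple[int, int]]] = {}
    sources: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("accession\t"):
            continue
        fields = line.split("\t")
        accession, start, end = fields[0], int(fields[1]), int(fields[2])
        source = fields[3] if len(fields) > 3 else "imported"
        annotations.setdefault(accession, []).append((start - 1, end))
        sources[accession] = source
    return {
        acc: TmsAnnotation(accession=acc, segments=sorted(segs), source=sources[acc])  # type: ignore[arg-type]
        for acc, segs in annotations.items()
    }


def write_tms_tsv(annotations: dict[str, TmsAnnotation] | Sequence[TmsAnnotation], path: str | Path) -> None:
    """Export annotations as TSV (accession, start, end, source), 1-based inclusive."""
    if isinstance(annotations, dict):
        annotations = list(annotations.values())
    with open(path, "w") as handle:
        handle.write("accession\tstart\tend\tsource\n")
        for ann in annotations:
            for start, end in ann.segments:
                handle.write(f"{ann.accession}\t{start + 1}\t{end}\t{ann.source}\n")


def write_avehas_tsv(profile: AvehasProfile, path: str | Path) -> None:
    """Plot-ready per-column AveHAS table."""
    with open(path, "w") as handle:
        handle.write("column\tavg_hydropathy\tavg_amphipathicity\tsimilarity\tn_contributing\n")
        for i in range(profile.n_columns):
            handle.write(
                f"{i + 1}\t{profile.avg_hydropathy[i]:.4f}\t{profile.avg_amphipathicity[i]:.4f}"
                f"\t{profile.similarity[i]:.4f}\t{profile.contributing_counts[i]}\n"
            )
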