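"""Internal 3-TMS repeat detection within single proteins.

A 6-TMS protein that arose by tandem duplication of a 3-TMS precursor
carries the duplication as residual sequence similarity between its two
halves: TMSs 1–3 versus TMSs 4–6.  The detector excises the two
TMS-defined regions (with a short flank), scores them against each other
with the shuffle-null z statistic, and grades the outcome:

* ``repeat_supported``  — z >= 13.0 S.D., the full homology standard;
* ``suggestive``        — 5.0 <= z < 13.0; ancient duplications commonly
  land here, and such scores support a repeat once superfamily-level
  homology is established on other grounds;
* ``not_supported``     — below 5.0.

Proteins with more than six TMSs are handled by taking the first six
(the extra C-terminal TMS of a 3+3+1 topology is ignored); a leading
extra TMS (1+3+3) can be skipped with ``tms_offset``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .errors import MemfamError
from .paircompare import AlignParams, shuffle_zscore
from .seqdata import FamilySet, ProteinRecord
from .topology import TmsAnnotation, predict_tms

Verdict = Literal["repeat_supported", "suggestive", "not_supported"]


@dataclass(frozen=True)
class RepeatParams:
    """Thresholds and geometry for half-vs-half comparison."""

    flank: int = 5
    supported_z: float = 13.0
    suggestive_z: float = 5.0
    n_shuffles: int = 2000

    def __post_init__(self) -> None:
        if self.suggestive_z > self.supported_z:
            raise ValueError("suggestive_z must not exceed supported_z")


@dataclass
class RepeatResult:
    """Half-vs-half comparison for one protein."""

    accession: str
    n_tms: int
    region_first: tuple[int, int]
    region_second: tuple[int, int]
    z_sd: float
    n_shuffles: int
    seed: int
    verdict: Verdict


class FewTmsSkip(MemfamError):
    """Raised when a protein has fewer than six usable TMSs."""


def repeat_regions(
    tms: TmsAnnotation,
    sequence_length: int,
    flank: int = 5,
    tms_offset: int = 0,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """The two non-overlapping 3-TMS unit regions defined by the annotation.

    The first region spans TMS(1+offset) start − flank to TMS(3+offset)
    end + flank; the second spans TMS(4+offset) start − flank to
    TMS(6+offset) end + flank, clipped so the regions do not overlap.
    """
    segs = tms.segments[tms_offset:]
    if len(segs) < 6:
        raise FewTmsSkip(f"{tms.accession}: {len(segs)} TMS(s) after offset, need 6")
    first_start = max(segs[0][0] - flank, 0)
    first_end = segs[2][1] + flank
    second_start = max(segs[3][0] - flank, 0)
    second_end = min(segs[5][1] + flank, sequence_length)
    if first_end > second_start:  # clip at the midpoint of the central loop
        mid = (segs[2][1] + segs[3][0]) // 2
        first_end = mid
        second_start = mid
    return (first_start, first_end), (second_start, second_end)


def detect_internal_repeat(
    record: ProteinRecord,
    tms: TmsAnnotation | None = None,
    params: RepeatParams | None = None,
    align_params: AlignParams | None = None,
    tms_offset: int = 0,
    seed: int = 0,
) -> RepeatResult:
    """Score the two 3-TMS halves of one protein against each other."""
    params = params or RepeatParams()
    tms = tms or predict_tms(record)
    (f0, f1), (s0, s1) = repeat_regions(tms, len(record.residues), params.flank, tms_offset)
    first = record.residues[f0:f1]
    second = record.residues[s0:s1]
    comp = shuffle_zscore(
        first, second, align_params, n_shuffles=params.n_shuffles, seed=seed,
        keep_alignment=False,
    )
    z = comp.z_sd
    if z >= params.supported_z:
        verdict: Verdict = "repeat_supported"
    elif z >= params.suggestive_z:
        verdict = "suggestive"
    else:
        verdict = "not_supported"
    return RepeatResult(
        accession=record.accession,
        n_tms=tms.n_tms,
        region_first=(f0, f1),
        region_second=(s0, s1),
        z_sd=z,
        n_shuffles=params.n_shuffles,
        seed=seed,
        verdict=verdict,
    )


def family_repeat_survey(
    family: FamilySet,
    annotations: dict[str, TmsAnnotation] | None = None,
    params: RepeatParams | None = None,
    align_params: AlignParams | None = None,
    seed: int = 0,
) -> list[RepeatResult]:
    """Half-vs-half comparison for every eligible family member.

    Members with fewer than six TMSs are skipped with a warning; the
    caller can compute the supported/suggestive fraction from the
    returned list.
    """
    params = params or RepeatParams()
    results: list[RepeatResult] = []
    for k, rec in enumerate(family.members):
        tms = annotations.get(rec.accession) if annotations else None
        member_seed = int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))
        try:
            results.append(
                detect_internal_repeat(rec, tms, params, align_params, seed=member_seed)
            )
        except FewTmsSkip as exc:
            warnings.warn(str(exc), stacklevel=2)
    return results


def survey_fraction(results: Sequence[RepeatResult]) -> float:
    """Fraction of surveyed members with a suggestive-or-better verdict."""
    if not results:
        return 0.0
    hits = sum(r.verdict in ("repeat_supported", "suggestive") for r in results)
    return hits / len(results)


def write_repeats_tsv(results: Sequence[RepeatResult], path: str | Path) -> None:
    """Survey table: accession, TMS count, the two regions (1-based), z, verdict."""
    with open(path, "w") as handle:
        handle.write("accession\tn_tms\tregion_first\tregion_second\tz_sd\tn_shuffles\tverdict\n")
        for r in results:
            handle.write(
                f"{r.accession}\t{r.n_tms}\t{r.region_first[0] + 1}-{r.region_first[1]}"
                f"\t{r.region_second[0] + 1}-{r.region_second[1]}\t{r.z_sd:.1f}"
                f"\t{r.n_shuffles}\t{r.verdict}\n"
            )
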