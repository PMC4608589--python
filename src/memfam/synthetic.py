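"""Ground-truth generator for duplication-derived membrane-protein families.

The generator emulates the evolutionary model under study: a ~200-residue
6-TMS protein arising from tandem duplication of a 3-TMS precursor unit
(two 3-TMS halves, "3+3"), with optional extra N- or C-terminal TMSs
(3+3+1, 1+3+3, 3+3+2), families of homologues at controlled pairwise
divergence, planted TMS-localized motifs, and a negative-control decoy
lineage built by triplication of a 2-TMS unit whose copies have diverged
beyond mutual recognition — the hallmark of the mitochondrial-carrier-style
control family.

Sequences are built from two residue classes: a strongly hydrophobic
TMS alphabet (I/L/V/F-dominated, mean Kyte–Doolittle ≈ +3.8) and a
polar/charged loop alphabet (mean ≈ −1.8).  Substitutions are drawn
within the residue class, biased by exp(BLOSUM62/2), so TMSs stay
hydrophobic and callable while loops diverge freely — the conservation
pattern averaged-hydropathy plots show in real homolog sets.  Indels are
realized as rare short loop deletions only, which keeps every family's
true alignment defined on a single shared column frame (the root frame)
and TMS counts stable.

Everything is reproducible from the config seed; independent streams are
derived per family/member with ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .seqdata import FamilySet, ProteinRecord, write_fasta
from .topology import TmsAnnotation, write_tms_tsv

Topology = Literal["3+3", "3+3+1", "1+3+3", "3+3+2", "2x3_decoy"]

#: TMS residue class: transmembrane-helix composition (mean Kyte–Doolittle
#: ≈ +3.3, ~78% I/L/V/F with a diverse hydrophobic remainder so that
#: unrelated helices are not trivially mutually similar).
HYDROPHOBIC_WEIGHTS = {
    "I": 0.34, "L": 0.31, "V": 0.08, "F": 0.08, "A": 0.05, "M": 0.08,
    "G": 0.02, "T": 0.02, "S": 0.02,
}
#: Helix-edge composition: the membrane-interface ends of a TMS block are
#: sampled pure-hydrophobic so windowed-hydropathy runs have crisp edges.
EDGE_WEIGHTS = {"I": 0.40, "L": 0.50, "V": 0.05, "F": 0.05}
#: Decoy (control-lineage) classes: a carrier-style family whose helices
#: carry more small/aromatic dilution and whose loops are charged-rich.
#: Unrelated superfamilies differ in composition, not just in sequence.
DECOY_TMS_WEIGHTS = {
    "F": 0.28, "M": 0.13, "C": 0.12, "V": 0.15, "A": 0.09, "I": 0.06,
    "L": 0.06, "G": 0.04, "T": 0.04, "S": 0.03,
}
#: Decoy helix-edge palette, hydrophobic but disjoint in emphasis from
#: the study families' I/L-dominant edges (F/C score <= 0 against I/L/V
#: under BLOSUM62, so unrelated helix ends do not look alike).
DECOY_EDGE_WEIGHTS = {"F": 0.55, "C": 0.20, "V": 0.15, "M": 0.10}
DECOY_LOOP_WEIGHTS = {
    "D": 0.05, "E": 0.05, "K": 0.06, "R": 0.03, "S": 0.13, "G": 0.13,
    "N": 0.05, "Q": 0.04, "T": 0.12, "P": 0.06, "A": 0.13, "H": 0.03,
    "Y": 0.03, "L": 0.04, "I": 0.02, "V": 0.03,
}
#: Residues at each end of a TMS drawn from EDGE_WEIGHTS.
TMS_EDGE = 4
#: Loop residue class (mean ≈ −1.1): a broad polar/charged/small mix with
#: the minority hydrophobics real inter-TMS loops carry.  Breadth matters:
#: a loop alphabet concentrated in a few small residues would make even
#: unrelated loops mutually similar under BLOSUM62's high diagonals.
LOOP_WEIGHTS = {
    "S": 0.12, "G": 0.11, "T": 0.10, "A": 0.13, "N": 0.06, "Q": 0.04,
    "P": 0.07, "D": 0.06, "E": 0.05, "K": 0.05, "R": 0.03, "H": 0.03,
    "Y": 0.03, "L": 0.05, "I": 0.04, "V": 0.03,
}
#: Background composition for architecture-free random proteins
#: (approximate natural frequencies; used for null calibration).
BACKGROUND_WEIGHTS = {
    "A": 0.078, "R": 0.051, "N": 0.045, "D": 0.054, "C": 0.019,
    "Q": 0.043, "E": 0.063, "G": 0.074, "H": 0.022, "I": 0.051,
    "L": 0.091, "K": 0.057, "M": 0.022, "F": 0.039, "P": 0.052,
    "S": 0.071, "T": 0.058, "W": 0.013, "Y": 0.032, "V": 0.065,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic superfamily.

    Divergences are target *pairwise* fractions of differing aligned
    positions: ``within_family_divergence`` between members of one
    family, ``between_family_divergence`` between members of different
    families, ``half_divergence`` between the two 3-TMS halves of the
    root (the age of the duplication), and ``decoy_copy_divergence``
    between the three 2-TMS copies of the decoy root.
    """

    seed: int = 0
    n_families: int = 4
    members_per_family: int = 8
    tms_len: int = 21
    loop_len: int = 15
    tail_len: int = 12
    topology: Topology = "3+3"
    within_family_divergence: float = 0.30
    between_family_divergence: float = 0.45
    half_divergence: float = 0.30
    decoy_copy_divergence: float = 0.75
    include_decoy: bool = True
    # the decoy lineage has its own geometry, as the real
    # mitochondrial-carrier-style control does: same helix length but the
    # long inter-helix loops of a ~300-residue carrier, so its TMS
    # spacing is out of register with the 3+3 families
    decoy_loop_len: int = 25
    decoy_tail_len: int = 20
    loop_del_prob: float = 0.05
    max_del_len: int = 3
    divergence_ladder: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)

    def __post_init__(self) -> None:
        for d in (
            self.within_family_divergence,
            self.between_family_divergence,
            self.half_divergence,
            self.decoy_copy_divergence,
            *self.divergence_ladder,
        ):
            if not 0.0 <= d <= 0.9:
                raise ValueError("divergences must lie in [0, 0.9]")
        if self.between_family_divergence < self.within_family_divergence:
            raise ValueError("between-family divergence must be >= within-family")
        if min(self.tms_len, self.loop_len) <= 0 or self.tail_len < 0:
            raise ValueError("lengths must be positive")


@dataclass
class PlantedMotif:
    """Bookkeeping for one motif plant."""

    pattern_text: str
    tms_index: int  # 1-based TMS number
    fraction: float
    placements: dict[str, tuple[int, int]] = field(default_factory=dict)  # acc -> interval


@dataclass
class SyntheticFamily:
    """One generated family with its ground truth."""

    family: FamilySet
    msa: FamilySet  # true alignment, root-frame columns
    tms: dict[str, TmsAnnotation]  # true TMS intervals, member coordinates
    is_decoy: bool = False


@dataclass
class SyntheticTruth:
    """Everything a test needs to verify downstream inference."""

    config: GeneratorConfig
    root_sequence: str
    root_classes: str  # 'T'/'L' per root position
    root_tms: list[tuple[int, int]]
    families: list[SyntheticFamily]
    decoy: SyntheticFamily | None
    motif_plants: list[PlantedMotif] = field(default_factory=list)

    def all_families(self) -> list[SyntheticFamily]:
        return self.families + ([self.decoy] if self.decoy else [])


# ---------------------------------------------------------------------------
# residue sampling and the class-restricted substitution kernel

def _weighted(rng: np.random.Generator, letters: Sequence[str], probs: np.ndarray, n: int) -> str:
    idx = rng.choice(len(letters), size=n, p=probs)
    return "".join(letters[i] for i in idx)


def _jittered_weights(
    rng: np.random.Generator,
    weights: dict[str, float],
    concentration: float = 20.0,
    mean_tolerance: float = 0.06,
) -> dict[str, float]:
    """A lineage-specific composition: Dirichlet jitter around the class weights.

    Unrelated lineages thereby differ in composition, as unrelated protein
    superfamilies do; the draw is rejected until its Kyte–Doolittle mean
    stays within ``mean_tolerance`` of the class mean so hydropathy-based
    TMS calling is unaffected.
    """
    from .topology import KYTE_DOOLITTLE

    letters, base = _normalized(weights)
    kd = np.array([KYTE_DOOLITTLE[a] for a in letters])
    target = float(base @ kd)
    for _ in range(200):
        draw = rng.dirichlet(base * concentration * len(letters))
        if abs(float(draw @ kd) - target) <= mean_tolerance:
            return dict(zip(letters, draw))
    return dict(zip(letters, base))


def _stratified(rng: np.random.Generator, weights: dict[str, float], n: int) -> str:
    """Sample ``n`` residues with near-exact composition, randomly arranged.

    Letter counts are the largest-remainder rounding of ``n * weight``;
    only the arrangement is random.  This keeps the windowed hydropathy of
    every sampled segment close to the class mean, as real TMSs and loops
    are compositionally much more uniform than an i.i.d. draw.
    """
    letters, probs = _normalized(weights)
    exact = probs * n
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    short = n - counts.sum()
    for i in np.argsort(-remainder)[:short]:
        counts[i] += 1
    pool = [ch for ch, k in zip(letters, counts) for _ in range(k)]
    return "".join(np.array(pool)[rng.permutation(n)])


def _normalized(weights: dict[str, float]) -> tuple[list[str], np.ndarray]:
    letters = list(weights)
    probs = np.array([weights[a] for a in letters])
    return letters, probs / probs.sum()


@dataclass(frozen=True)
class _Kernel:
    """Substitution kernel restricted to one residue class.

    P(new | old) ∝ class_weight(new) * exp(BLOSUM62[old, new] / 2), new ≠ old.
    """

    letters: tuple[str, ...]
    rows: dict[str, np.ndarray]
    collision: float  # E[P(two independent substitutions agree)]

    @classmethod
    def build(cls, weights: dict[str, float]) -> "_Kernel":
        blosum = substitution_matrices.load("BLOSUM62")
        letters = tuple(weights)
        base = np.array([weights[a] for a in letters])
        base = base / base.sum()
        rows: dict[str, np.ndarray] = {}
        for i, old in enumerate(letters):
            row = np.array(
                [weights[new] * math.exp(blosum[old, new] / 2.0) for new in letters]
            )
            row[i] = 0.0
            rows[old] = row / row.sum()
        collision = float(sum(base[i] * np.sum(rows[old] ** 2) for i, old in enumerate(letters)))
        return cls(letters=letters, rows=rows, collision=collision)

    def substitute(self, old: str, rng: np.random.Generator) -> str:
        row = self.rows.get(old)
        if row is None:
            # residue outside the class support (e.g. a planted motif residue):
            # resample from the class at large
            row = np.ones(len(self.letters)) / len(self.letters)
        return self.letters[rng.choice(len(self.letters), p=row)]


_TMS_KERNEL = _Kernel.build(HYDROPHOBIC_WEIGHTS)
_LOOP_KERNEL = _Kernel.build(LOOP_WEIGHTS)
_DECOY_TMS_KERNEL = _Kernel.build(DECOY_TMS_WEIGHTS)
_DECOY_LOOP_KERNEL = _Kernel.build(DECOY_LOOP_WEIGHTS)


def solve_site_rate(pairwise_divergence: float, collision: float) -> float:
    """Per-lineage site substitution probability for a target pairwise divergence.

    Two lineages mutate independently at rate ``p``; an aligned site then
    differs with probability ``2p(1-p) + p²(1-c)`` where ``c`` is the
    chance that two independent substitutions land on the same residue.
    """
    d = pairwise_divergence
    if d <= 0:
        return 0.0
    c = collision
    # Expected divergence 2p - (1+c)p² peaks at p = 1/(1+c) with value
    # 1/(1+c): in-class substitution saturates there, the
    # "diverged beyond recognition" regime.  Cap rather than fail.
    if (1.0 + c) * d >= 1.0:
        return 1.0 / (1.0 + c)
    return (1.0 - math.sqrt(1.0 - (1.0 + c) * d)) / (1.0 + c)


def _mutate(
    seq: str,
    classes: str,
    p: float,
    rng: np.random.Generator,
    decoy: bool = False,
) -> str:
    """Substitute each site with probability ``p`` within its residue class."""
    if p <= 0:
        return seq
    if decoy:
        tms_kernel, loop_kernel = _DECOY_TMS_KERNEL, _DECOY_LOOP_KERNEL
    else:
        tms_kernel, loop_kernel = _TMS_KERNEL, _LOOP_KERNEL
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < p)[0]
    for i in hits:
        kernel = tms_kernel if classes[i] == "T" else loop_kernel
        out[i] = kernel.substitute(out[i], rng)
    return "".join(out)


# ---------------------------------------------------------------------------
# architecture

def _build_root(config: GeneratorConfig, rng: np.random.Generator) -> tuple[str, str, list[tuple[int, int]]]:
    """Sample the root (ancestral) sequence, its class string, and TMS intervals."""
    t, l = config.tms_len, config.loop_len
    decoy = config.topology == "2x3_decoy"
    edge_w = _jittered_weights(
        rng, DECOY_EDGE_WEIGHTS if decoy else EDGE_WEIGHTS, mean_tolerance=0.3
    )
    tms_w = _jittered_weights(rng, DECOY_TMS_WEIGHTS if decoy else HYDROPHOBIC_WEIGHTS)
    loop_w = _jittered_weights(
        rng, DECOY_LOOP_WEIGHTS if decoy else LOOP_WEIGHTS, mean_tolerance=0.08
    )

    def tms() -> str:
        core = max(t - 2 * TMS_EDGE, 0)
        return (
            _stratified(rng, edge_w, TMS_EDGE)
            + _stratified(rng, tms_w, core)
            + _stratified(rng, edge_w, TMS_EDGE)
        )

    def loop(n: int | None = None) -> str:
        return _stratified(rng, loop_w, l if n is None else n)

    if config.topology == "2x3_decoy":
        # 2-TMS unit triplicated; copies diverged from each other
        unit = tms() + loop() + tms() + loop()
        unit_classes = "T" * t + "L" * l + "T" * t + "L" * l
        q = solve_site_rate(config.decoy_copy_divergence, _DECOY_TMS_KERNEL.collision)
        copies = [_mutate(unit, unit_classes, q, rng, decoy=True) for _ in range(3)]
        body = "".join(copies)
        body_classes = unit_classes * 3
    else:
        unit = tms() + loop() + tms() + loop() + tms() + loop()
        unit_classes = ("T" * t + "L" * l) * 3
        # ancient duplication: second half diverged from the first
        second = _mutate(unit, unit_classes, config.half_divergence, rng)
        body = unit + second
        body_classes = unit_classes * 2
        if config.topology == "3+3+1":
            body += tms() + loop()
            body_classes += "T" * t + "L" * l
        elif config.topology == "3+3+2":
            body += (tms() + loop()) * 2
            body_classes += ("T" * t + "L" * l) * 2
        elif config.topology == "1+3+3":
            body = tms() + loop() + body
            body_classes = "T" * t + "L" * l + body_classes

    root = loop(config.tail_len) + body + loop(config.tail_len)
    classes = "L" * config.tail_len + body_classes + "L" * config.tail_len
    segments = []
    i = 0
    while i < len(classes):
        if classes[i] == "T":
            j = i
            while j < len(classes) and classes[j] == "T":
                j += 1
            segments.append((i, j))
            i = j
        else:
            i += 1
    return root, classes, segments


def _loop_regions(classes: str) -> list[tuple[int, int]]:
    regions = []
    i = 0
    while i < len(classes):
        if classes[i] == "L":
            j = i
            while j < len(classes) and classes[j] == "L":
                j += 1
            regions.append((i, j))
            i = j
        else:
            i += 1
    return regions


def _apply_deletions(
    config: GeneratorConfig, classes: str, rng: np.random.Generator
) -> np.ndarray:
    """Boolean mask of root-frame positions deleted in one member."""
    deleted = np.zeros(len(classes), dtype=bool)
    if config.loop_del_prob <= 0:
        return deleted
    for start, end in _loop_regions(classes):
        if end - start < config.max_del_len + 2:
            continue
        if rng.random() < config.loop_del_prob:
            del_len = int(rng.integers(1, config.max_del_len + 1))
            offset = int(rng.integers(start + 1, end - del_len))
            deleted[offset : offset + del_len] = True
    return deleted


def _member_from_ancestor(
    ancestor: str,
    classes: str,
    root_tms: list[tuple[int, int]],
    p_member: float,
    config: GeneratorConfig,
    accession: str,
    rng: np.random.Generator,
    decoy: bool = False,
) -> tuple[ProteinRecord, str, TmsAnnotation]:
    mutated = _mutate(ancestor, classes, p_member, rng, decoy=decoy)
    deleted = _apply_deletions(config, classes, rng)
    row = "".join("-" if deleted[i] else ch for i, ch in enumerate(mutated))
    residues = row.replace("-", "")
    offsets = np.cumsum(deleted)  # deletions at or before each root position
    segments = []
    for start, end in root_tms:
        # loop-only deletions never hit TMS interiors
        segments.append((start - int(offsets[start]), end - int(offsets[end - 1]) ))
    record = ProteinRecord(accession=accession, description="synthetic", residues=residues)
    annotation = TmsAnnotation(accession=accession, segments=segments, source="imported")
    return record, row, annotation


def generate_superfamily(config: GeneratorConfig) -> SyntheticTruth:
    """Generate a planted superfamily (plus optional decoy) with full truth.

    All families descend from one root built per ``config.topology``;
    family ancestors diverge from the root and members from their family
    ancestor at site rates solved from the target pairwise divergences.
    The decoy lineage is sampled independently (unrelated by
    construction) with the triplicated-2-TMS architecture.
    """
    master = np.random.SeedSequence(config.seed)
    ss_root, ss_families, ss_decoy = master.spawn(3)
    rng_root = np.random.default_rng(ss_root)
    root, classes, root_tms = _build_root(config, rng_root)

    collision = _TMS_KERNEL.collision  # conservative: loop collision is lower
    p_member = solve_site_rate(config.within_family_divergence, collision)
    q_total = solve_site_rate(config.between_family_divergence, collision)
    if q_total < p_member:
        raise ValueError("between-family divergence unreachable: below within-family")
    p_family = 1.0 - (1.0 - q_total) / (1.0 - p_member) if p_member < 1 else 0.0

    families: list[SyntheticFamily] = []
    fam_streams = ss_families.spawn(config.n_families)
    for f in range(config.n_families):
        rng_f = np.random.default_rng(fam_streams[f])
        ancestor = _mutate(root, classes, p_family, rng_f)
        members, rows, annotations = [], [], {}
        for m in range(config.members_per_family):
            accession = f"FAM{f + 1}_{m:02d}"
            rec, row, ann = _member_from_ancestor(
                ancestor, classes, root_tms, p_member, config, accession, rng_f
            )
            members.append(rec)
            rows.append(row)
            annotations[accession] = ann
        fam_id = f"FAM{f + 1}"
        families.append(
            SyntheticFamily(
                family=FamilySet(family_id=fam_id, members=members),
                msa=FamilySet(
                    family_id=fam_id,
                    members=[
                        ProteinRecord(rec.accession, rec.description, row)
                        for rec, row in zip(members, rows)
                    ],
                ),
                tms=annotations,
            )
        )

    decoy = None
    if config.include_decoy:
        decoy_config = replace(
            config,
            topology="2x3_decoy",
            loop_len=config.decoy_loop_len,
            tail_len=config.decoy_tail_len,
        )
        rng_d = np.random.default_rng(ss_decoy)
        d_root, d_classes, d_tms = _build_root(decoy_config, rng_d)
        members, rows, annotations = [], [], {}
        for m in range(config.members_per_family):
            accession = f"DECOY_{m:02d}"
            rec, row, ann = _member_from_ancestor(
                d_root, d_classes, d_tms, p_member, config, accession, rng_d, decoy=True
            )
            members.append(rec)
            rows.append(row)
            annotations[accession] = ann
        decoy = SyntheticFamily(
            family=FamilySet(family_id="DECOY", members=members),
            msa=FamilySet(
                family_id="DECOY",
                members=[
                    ProteinRecord(rec.accession, rec.description, row)
                    for rec, row in zip(members, rows)
                ],
            ),
            tms=annotations,
            is_decoy=True,
        )

    return SyntheticTruth(
        config=config,
        root_sequence=root,
        root_classes=classes,
        root_tms=root_tms,
        families=families,
        decoy=decoy,
    )


def plant_motif(
    truth: SyntheticTruth,
    pattern_text: str,
    tms_index: int,
    fraction: float = 1.0,
    seed: int = 0,
) -> PlantedMotif:
    """Write a motif instance inside the stated TMS of a fraction of members.

    ``tms_index`` is 1-based.  At each chosen member the pattern is placed
    at a fixed offset (centered) inside the true TMS; wildcard positions
    keep the member's existing residues, alternative sets pick one allowed
    residue per member.  Records, alignment rows and truth are updated in
    place.
    """
    from .motifscan import parse_pattern  # local import: motifscan is downstream

    pattern = parse_pattern(pattern_text)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    plant = PlantedMotif(pattern_text=pattern_text, tms_index=tms_index, fraction=fraction)
    for fam in truth.all_families():
        n_plant = int(round(fraction * len(fam.family.members)))
        chosen = list(range(len(fam.family.members)))[:n_plant]
        for idx in chosen:
            rec = fam.family.members[idx]
            ann = fam.tms[rec.accession]
            if tms_index > ann.n_tms:
                raise ValueError(f"{rec.accession}: no TMS #{tms_index}")
            start, end = ann.segments[tms_index - 1]
            if len(pattern.positions) > end - start:
                raise ValueError("pattern longer than the TMS")
            offset = start + (end - start - len(pattern.positions)) // 2
            residues = list(rec.residues)
            for k, allowed in enumerate(pattern.positions):
                if allowed is None:  # wildcard: keep existing residue
                    continue
                options = sorted(allowed)
                residues[offset + k] = options[int(rng.integers(len(options)))]
            new_res = "".join(residues)
            fam.family.members[idx] = ProteinRecord(rec.accession, rec.description, new_res)
            # patch the aligned row consistently
            row = fam.msa.members[idx].residues
            new_row = []
            pos = 0
            for ch in row:
                if ch == "-":
                    new_row.append("-")
                else:
                    new_row.append(new_res[pos])
                    pos += 1
            fam.msa.members[idx] = ProteinRecord(rec.accession, rec.description, "".join(new_row))
            plant.placements[rec.accession] = (offset, offset + len(pattern.positions))
    truth.motif_plants.append(plant)
    return plant


# ---------------------------------------------------------------------------
# simple sequence sources for calibration work

def random_protein(length: int, seed: int, accession: str = "RND") -> ProteinRecord:
    """An architecture-free random protein at near-natural composition."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    letters, probs = _normalized(BACKGROUND_WEIGHTS)
    return ProteinRecord(accession, "random", _weighted(rng, letters, probs, length))


def related_pair(
    divergence: float, seed: int, config: GeneratorConfig | None = None
) -> tuple[ProteinRecord, ProteinRecord]:
    """Two 6-TMS proteins descended from one root at a target pairwise divergence."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    root, classes, _ = _build_root(config, rng)
    p = solve_site_rate(divergence, _TMS_KERNEL.collision)
    a = _mutate(root, classes, p, rng)
    b = _mutate(root, classes, p, rng)
    return (
        ProteinRecord("PAIR_A", "synthetic", a),
        ProteinRecord("PAIR_B", "synthetic", b),
    )


def write_outputs(truth: SyntheticTruth, outdir: str | Path) -> None:
    """Emit FASTA, aligned FASTA, TMS TSV and a truth JSON for one run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_lines = []
    for fam in truth.all_families():
        fid = fam.family.family_id
        write_fasta(fam.family, outdir / f"{fid}.faa")
        write_fasta(fam.msa, outdir / f"{fid}.aln.faa")
        write_tms_tsv(fam.tms, outdir / f"{fid}.tms.tsv")
        manifest_lines.append(f"{fid}\t{fid}.faa")
    (outdir / "families.tsv").write_text("\n".join(manifest_lines) + "\n")
    summary = {
        "seed": truth.config.seed,
        "topology": truth.config.topology,
        "n_families": truth.config.n_families,
        "members_per_family": truth.config.members_per_family,
        "root_tms": truth.root_tms,
        "decoy": truth.decoy.family.family_id if truth.decoy else None,
        "motif_plants": [
            {
                "pattern": p.pattern_text,
                "tms_index": p.tms_index,
                "fraction": p.fraction,
                "placements": p.placements,
            }
            for p in truth.motif_plants
        ],
    }
    (outdir / "truth.json").write_text(json.dumps(summary, indent=2) + "\n")
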