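"""The transitivity ("superfamily principle") engine.

Pairwise comparison scores rarely connect every family of a superfamily
directly: two distantly related families X and Y may show no significant
direct signal, yet X's homologue B and Y's homologue C may align with a
comparison score well above threshold.  The superfamily principle makes
the inference transitive: if A (an established member of X) is homologous
to B, B to C, and C to D (an established member of Y), then A is
homologous to D even when the direct A-vs-D score is insignificant.

A chain is *established* when the bridge comparison B–C meets both
evidence criteria (z >= 13.0 S.D. and >= 3 aligned TMSs) and the anchor
comparisons A–B and C–D each meet the z criterion.  The direct A–D score
is reported for reference but never used in the verdict — the method's
point is precisely that it can be low.

Family-level verdicts assemble into a graph whose connected components
are the inferred superfamilies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import networkx as nx
import numpy as np

from .paircompare import (
    AlignParams,
    HomologyCriteria,
    count_aligned_tms,
    shuffle_zscore,
)
from .seqdata import FamilySet, ProteinRecord
from .topology import TmsAnnotation, predict_tms


@dataclass
class HomologyChain:
    """One A–B–C–D transitivity chain with its four scores and verdict."""

    family_x: str
    family_y: str
    protein_a: str
    protein_b: str
    protein_c: str
    protein_d: str
    score_ab: float
    score_bc: float
    score_cd: float
    score_ad: float
    aligned_tms_bc: int
    verdict: Literal["established", "not_established"] = "not_established"
    #: whether both bridge proteins show the full 6-TMS (3+3) body plan —
    #: the "unified evolutionary pathway" condition; recorded as a flag,
    #: never used in the verdict (the condition is applied qualitatively,
    #: and an established 3-TMS internal repeat can substitute for it)
    unified_pathway: bool | None = None

    @staticmethod
    def decide(
        score_ab: float,
        score_bc: float,
        score_cd: float,
        aligned_tms_bc: int,
        criteria: HomologyCriteria,
    ) -> Literal["established", "not_established"]:
        ok = (
            score_bc >= criteria.z_threshold
            and aligned_tms_bc >= criteria.min_aligned_tms
            and score_ab >= criteria.z_threshold
            and score_cd >= criteria.z_threshold
        )
        return "established" if ok else "not_established"


@dataclass
class HomologyGraph:
    """Family-level homology graph and its transitive closure."""

    nodes: list[str]
    edges: dict[tuple[str, str], HomologyChain]
    components: list[set[str]]

    def component_of(self, family_id: str) -> set[str]:
        for comp in self.components:
            if family_id in comp:
                return comp
        raise KeyError(family_id)


def evaluate_chain(
    a: ProteinRecord,
    b: ProteinRecord,
    c: ProteinRecord,
    d: ProteinRecord,
    family_x: str,
    family_y: str,
    criteria: HomologyCriteria | None = None,
    align_params: AlignParams | None = None,
    tms_b: TmsAnnotation | None = None,
    tms_c: TmsAnnotation | None = None,
    n_shuffles: int = 2000,
    seed: int = 0,
) -> HomologyChain:
    """Score a full A–B–C–D chain and apply the evidence criteria.

    Four shuffle-null comparisons are run (A–B, B–C, C–D and the direct
    A–D, the last reported only).  TMS annotations for the bridge pair
    default to hydropathy predictions.
    """
    criteria = criteria or HomologyCriteria()
    accessions = {a.accession, b.accession, c.accession, d.accession}
    if len(accessions) < 4:
        raise ValueError("chain requires four distinct records")
    seeds = [int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31)) for k in range(4)]
    comp_ab = shuffle_zscore(a, b, align_params, n_shuffles, seeds[0], keep_alignment=False)
    comp_bc = shuffle_zscore(b, c, align_params, n_shuffles, seeds[1])
    comp_cd = shuffle_zscore(c, d, align_params, n_shuffles, seeds[2], keep_alignment=False)
    comp_ad = shuffle_zscore(a, d, align_params, n_shuffles, seeds[3], keep_alignment=False)
    tms_b = tms_b or predict_tms(b)
    tms_c = tms_c or predict_tms(c)
    aligned = count_aligned_tms(comp_bc, tms_b, tms_c)
    chain = HomologyChain(
        family_x=family_x,
        family_y=family_y,
        protein_a=a.accession,
        protein_b=b.accession,
        protein_c=c.accession,
        protein_d=d.accession,
        score_ab=comp_ab.z_sd,
        score_bc=comp_bc.z_sd,
        score_cd=comp_cd.z_sd,
        score_ad=comp_ad.z_sd,
        aligned_tms_bc=aligned,
        unified_pathway=(tms_b.n_tms >= 6 and tms_c.n_tms >= 6),
    )
    chain.verdict = HomologyChain.decide(
        chain.score_ab, chain.score_bc, chain.score_cd, chain.aligned_tms_bc, criteria
    )
    return chain


def build_graph(
    chains: Sequence[HomologyChain],
    criteria: HomologyCriteria | None = None,
    extra_families: Sequence[str] = (),
) -> HomologyGraph:
    """Assemble family-level verdicts into components.

    An edge (X, Y) is present iff at least one chain linking X and Y is
    established under ``criteria``; when several qualify, the one with
    the highest bridge score is kept as the edge evidence.  Components
    are the connected components of the resulting graph — the transitive
    closure of pairwise establishment.
    """
    criteria = criteria or HomologyCriteria()
    graph = nx.Graph()
    for fid in extra_families:
        graph.add_node(fid)
    edges: dict[tuple[str, str], HomologyChain] = {}
    for chain in chains:
        graph.add_node(chain.family_x)
        graph.add_node(chain.family_y)
        verdict = HomologyChain.decide(
            chain.score_ab, chain.score_bc, chain.score_cd, chain.aligned_tms_bc, criteria
        )
        if verdict != "established" or chain.family_x == chain.family_y:
            continue
        key = tuple(sorted((chain.family_x, chain.family_y)))
        if key not in edges or chain.score_bc > edges[key].score_bc:
            edges[key] = chain
        graph.add_edge(*key)
    components = [set(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), min(c)))
    return HomologyGraph(nodes=sorted(graph.nodes), edges=edges, components=components)


@dataclass
class NegativeControlReport:
    """Best chance scores between a candidate superfamily and a control family."""

    control_id: str
    best_z: dict[str, float]  # family id -> best z vs control
    top_five_mean: float
    max_z: float
    control_isolated: bool
    flags: list[str] = field(default_factory=list)


def negative_control_summary(best_z: dict[str, float]) -> tuple[float, float]:
    """Max and mean-of-top-five of the per-family best control scores."""
    values = sorted(best_z.values(), reverse=True)
    top5 = values[:5]
    return (max(values), float(np.mean(top5)))


def negative_control_report(
    families: Sequence[FamilySet],
    control: FamilySet,
    graph: HomologyGraph | None = None,
    best_z: dict[str, float] | None = None,
    criteria: HomologyCriteria | None = None,
    align_params: AlignParams | None = None,
    n_shuffles: int = 2000,
    seed: int = 0,
    top_k: int = 1,
) -> NegativeControlReport:
    """Summarize how hot the control family runs against each member family.

    ``best_z`` may be supplied directly (e.g. from a published score
    table); otherwise each family is screened against the control.  The
    control is flagged if it shares members with any family (a broken
    control design) and reported as isolated iff no best score reaches
    the homology threshold.
    """
    from .paircompare import screen_families  # local: keeps import surface flat

    criteria = criteria or HomologyCriteria()
    flags: list[str] = []
    control_accs = set(control.accessions)
    for fam in families:
        if control_accs & set(fam.accessions):
            flags.append(
                f"control {control.family_id!r} shares members with {fam.family_id!r}"
            )
    if best_z is None:
        best_z = {}
        for k, fam in enumerate(families):
            results = screen_families(
                fam, control, align_params, top_k=top_k, n_shuffles=n_shuffles,
                seed=int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31)),
            )
            best_z[fam.family_id] = max(r.z_sd for r in results)
    max_z, top5 = negative_control_summary(best_z)
    isolated = max_z < criteria.z_threshold
    if graph is not None and control.family_id in graph.nodes:
        isolated = isolated and len(graph.component_of(control.family_id)) == 1
    return NegativeControlReport(
        control_id=control.family_id,
        best_z=dict(best_z),
        top_five_mean=top5,
        max_z=max_z,
        control_isolated=isolated,
        flags=flags,
    )


def write_chains_tsv(chains: Sequence[HomologyChain], path: str | Path) -> None:
    """Chain table: four accessions, four scores, bridge TMS count, verdict."""
    with open(path, "w") as handle:
        handle.write(
            "family_x\tfamily_y\tprotein_a\tprotein_b\tprotein_c\tprotein_d"
            "\tscore_ab\tscore_bc\tscore_cd\tscore_ad\taligned_tms_bc\tverdict\n"
        )
        for ch in chains:
            handle.write(
                f"{ch.family_x}\t{ch.family_y}\t{ch.protein_a}\t{ch.protein_b}"
                f"\t{ch.protein_c}\t{ch.protein_d}\t{ch.score_ab:.1f}\t{ch.score_bc:.1f}"
                f"\t{ch.score_cd:.1f}\t{ch.score_ad:.1f}\t{ch.aligned_tms_bc}\t{ch.verdict}\n"
            )


def graph_to_json(graph: HomologyGraph) -> str:
    payload = {
        "nodes": graph.nodes,
        "edges": [
            {
                "family_x": x,
                "family_y": y,
                "bridge": f"{ch.protein_b}-{ch.protein_c}",
                "score_bc": round(ch.score_bc, 2),
                "aligned_tms_bc": ch.aligned_tms_bc,
            }
            for (x, y), ch in sorted(graph.edges.items())
        ],
        "components": [sorted(c) for c in graph.components],
    }
    return json.dumps(payload, indent=2)


def graph_to_dot(graph: HomologyGraph) -> str:
    lines = ["graph homology {"]
    for node in graph.nodes:
        lines.append(f'  "{node}";')
    for (x, y), ch in sorted(graph.edges.items()):
        lines.append(f'  "{x}" -- "{y}" [label="{ch.score_bc:.1f}"];')
    lines.append("}")
    return "\n".join(lines)
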