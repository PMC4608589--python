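"""End-to-end orchestration: from family FASTA sets to a superfamily verdict bundle.

``run_pipeline`` chains the stages of the analysis — redundancy
reduction, TMS calling, family-vs-family screening, transitivity chains,
the homology graph, the negative-control report, internal-repeat
surveys, motif surveys, averaged-profile tables and the consensus tree —
and writes their tables to an output directory.  Every stage draws its
randomness from a stream derived from the single master seed, so a rerun
with the same config is reproducible, and the summary records the seed
and parameters each number came from.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import StageError
from .motifscan import parse_pattern, survey, write_survey_tsv
from .paircompare import (
    AlignParams,
    HomologyCriteria,
    PairComparison,
    count_aligned_tms,
    screen_families,
)
from .repeats import RepeatParams, family_repeat_survey, survey_fraction, write_repeats_tsv
from .seqdata import FamilySet, RedundancyParams, read_manifest, reduce_redundancy
from .superfamily import (
    HomologyChain,
    HomologyGraph,
    build_graph,
    evaluate_chain,
    graph_to_dot,
    graph_to_json,
    negative_control_report,
    write_chains_tsv,
)
from .sfttree import ensemble_consensus, score_matrix, to_distances, nj_tree
from .topology import (
    TmsAnnotation,
    TopologyParams,
    avehas,
    predict_tms,
    write_avehas_tsv,
    write_tms_tsv,
)

ALL_STAGES = (
    "reduce", "topology", "screen", "chain", "graph", "control",
    "repeats", "motifs", "avehas", "tree",
)


@dataclass
class RunConfig:
    """Declarative run description.

    ``stages`` toggles individual steps; ``motifs`` is a list of
    ``(pattern_text, expected_tms_or_None)`` pairs; ``control_id`` names
    the family treated as the negative control (excluded from linkage).
    """

    seed: int = 0
    outdir: str | Path = "results/run"
    stages: tuple[str, ...] = ALL_STAGES
    align: AlignParams = field(default_factory=AlignParams)
    criteria: HomologyCriteria = field(default_factory=HomologyCriteria)
    topology: TopologyParams = field(default_factory=TopologyParams)
    redundancy: RedundancyParams = field(default_factory=RedundancyParams)
    repeat: RepeatParams = field(default_factory=RepeatParams)
    screen_top_k: int = 1
    screen_shuffles: int = 2000
    chain_shuffles: int = 2000
    n_trees: int = 100
    tree_members_per_family: int = 4
    motifs: tuple[tuple[str, int | None], ...] = ()
    control_id: str | None = None
    manifest: str | Path | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(payload)
        for key, klass in (
            ("align", AlignParams),
            ("criteria", HomologyCriteria),
            ("topology", TopologyParams),
            ("redundancy", RedundancyParams),
            ("repeat", RepeatParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        if "motifs" in kwargs:
            kwargs["motifs"] = tuple(
                (m["pattern"], m.get("tms")) for m in kwargs["motifs"]
            )
        return cls(**kwargs)


@dataclass
class PipelineReport:
    """In-memory results of one run; files live under ``config.outdir``."""

    config: RunConfig
    families: dict[str, FamilySet] = field(default_factory=dict)
    annotations: dict[str, TmsAnnotation] = field(default_factory=dict)
    comparisons: list[PairComparison] = field(default_factory=list)
    chains: list[HomologyChain] = field(default_factory=list)
    graph: HomologyGraph | None = None
    control_report: object | None = None
    repeat_results: dict[str, list] = field(default_factory=dict)
    motif_surveys: list = field(default_factory=list)
    consensus: str | None = None
    summary: dict = field(default_factory=dict)


def _stage_seed(master: int, stage: str) -> int:
    tag = sum(ord(c) for c in stage)
    return int(np.random.SeedSequence([master, tag]).generate_state(1)[0] % (2**31))


def run_pipeline(
    config: RunConfig,
    families: dict[str, FamilySet] | None = None,
    annotations: dict[str, TmsAnnotation] | None = None,
    msas: dict[str, FamilySet] | None = None,
) -> PipelineReport:
    """Execute the configured stages and write the report bundle.

    Families come from ``families`` or from the TSV manifest in the
    config.  Imported ``annotations`` override hydropathy predictions
    for the accessions they cover.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(config=config)
    stages = set(config.stages)
    summary: dict = {"seed": config.seed, "stages": sorted(stages)}

    if families is None:
        if config.manifest is None:
            if stages:
                raise StageError("input", "no families and no manifest given")
            families = {}
        else:
            families = read_manifest(config.manifest)
    report.families = dict(families)

    linkable = {
        fid: fam for fid, fam in report.families.items() if fid != config.control_id
    }
    control = report.families.get(config.control_id) if config.control_id else None

    try:
        if "reduce" in stages:
            report.families = {
                fid: reduce_redundancy(fam, config.redundancy)
                for fid, fam in report.families.items()
            }
            linkable = {
                fid: fam for fid, fam in report.families.items() if fid != config.control_id
            }
            control = report.families.get(config.control_id) if config.control_id else None
            summary["reduce"] = {fid: len(fam) for fid, fam in report.families.items()}
    except Exception as exc:  # noqa: BLE001
        raise StageError("reduce", str(exc)) from exc

    try:
        if "topology" in stages:
            for fam in report.families.values():
                for rec in fam.members:
                    if annotations and rec.accession in annotations:
                        report.annotations[rec.accession] = annotations[rec.accession]
                    else:
                        report.annotations[rec.accession] = predict_tms(rec, config.topology)
            write_tms_tsv(report.annotations, outdir / "tms.tsv")
            summary["topology"] = {
                fid: [report.annotations[a].n_tms for a in fam.accessions]
                for fid, fam in report.families.items()
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError("topology", str(exc)) from exc

    pair_best: dict[tuple[str, str], PairComparison] = {}
    try:
        if "screen" in stages:
            fids = sorted(report.families)
            for a_idx in range(len(fids)):
                for b_idx in range(a_idx + 1, len(fids)):
                    fx, fy = fids[a_idx], fids[b_idx]
                    results = screen_families(
                        report.families[fx],
                        report.families[fy],
                        config.align,
                        top_k=config.screen_top_k,
                        n_shuffles=config.screen_shuffles,
                        seed=_stage_seed(config.seed, f"screen:{fx}:{fy}"),
                    )
                    top = results[0]
                    if report.annotations:
                        top.aligned_tms = count_aligned_tms(
                            top,
                            report.annotations[top.accession_a],
                            report.annotations[top.accession_b],
                        )
                    pair_best[(fx, fy)] = top
                    report.comparisons.extend(results)
            with open(outdir / "comparisons.tsv", "w") as handle:
                handle.write(
                    "family_a\tfamily_b\tacc_a\tacc_b\traw_score\tz_sd"
                    "\tn_shuffles\tseed\taligned_tms\n"
                )
                for (fx, fy), comp in sorted(pair_best.items()):
                    handle.write(
                        f"{fx}\t{fy}\t{comp.accession_a}\t{comp.accession_b}"
                        f"\t{comp.raw_score:.1f}\t{comp.z_sd:.1f}\t{comp.null.n_shuffles}"
                        f"\t{comp.null.seed}\t{comp.aligned_tms}\n"
                    )
            summary["screen"] = {
                f"{fx}|{fy}": round(comp.z_sd, 1) for (fx, fy), comp in sorted(pair_best.items())
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError("screen", str(exc)) from exc

    try:
        if "chain" in stages and pair_best:
            for (fx, fy), top in sorted(pair_best.items()):
                if config.control_id in (fx, fy):
                    continue
                fam_x, fam_y = report.families[fx], report.families[fy]
                b = fam_x[top.accession_a]
                c = fam_y[top.accession_b]
                a = next((m for m in fam_x.members if m.accession != b.accession), None)
                d = next((m for m in fam_y.members if m.accession != c.accession), None)
                if a is None or d is None:
                    warnings.warn(
                        f"chain {fx}-{fy} skipped: a family has a single member",
                        stacklevel=2,
                    )
                    continue
                chain = evaluate_chain(
                    a, b, c, d, fx, fy,
                    criteria=config.criteria,
                    align_params=config.align,
                    tms_b=report.annotations.get(b.accession),
                    tms_c=report.annotations.get(c.accession),
                    n_shuffles=config.chain_shuffles,
                    seed=_stage_seed(config.seed, f"chain:{fx}:{fy}"),
                )
                report.chains.append(chain)
            write_chains_tsv(report.chains, outdir / "chains.tsv")
            summary["chains_established"] = sum(
                ch.verdict == "established" for ch in report.chains
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError("chain", str(exc)) from exc

    try:
        if "graph" in stages:
            report.graph = build_graph(
                report.chains, config.criteria, extra_families=sorted(linkable)
            )
            (outdir / "graph.json").write_text(graph_to_json(report.graph) + "\n")
            (outdir / "graph.dot").write_text(graph_to_dot(report.graph) + "\n")
            summary["components"] = [sorted(c) for c in report.graph.components]
    except Exception as exc:  # noqa: BLE001
        raise StageError("graph", str(exc)) from exc

    try:
        if "control" in stages and control is not None:
            best_z = {
                fid: max(
                    (c.z_sd for (fx, fy), c in pair_best.items()
                     if {fx, fy} == {fid, config.control_id}),
                    default=float("nan"),
                )
                for fid in linkable
            }
            if all(np.isfinite(v) for v in best_z.values()):
                report.control_report = negative_control_report(
                    list(linkable.values()), control,
                    graph=report.graph, best_z=best_z, criteria=config.criteria,
                )
            else:
                report.control_report = negative_control_report(
                    list(linkable.values()), control,
                    graph=report.graph, criteria=config.criteria,
                    align_params=config.align,
                    n_shuffles=config.screen_shuffles,
                    seed=_stage_seed(config.seed, "control"),
                )
            summary["control"] = {
                "max_z": round(report.control_report.max_z, 2),
                "top_five_mean": round(report.control_report.top_five_mean, 2),
                "isolated": report.control_report.control_isolated,
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError("control", str(exc)) from exc

    try:
        if "repeats" in stages:
            all_results = []
            for fid, fam in report.families.items():
                results = family_repeat_survey(
                    fam, report.annotations or None, config.repeat, config.align,
                    seed=_stage_seed(config.seed, f"repeats:{fid}"),
                )
                report.repeat_results[fid] = results
                all_results.extend(results)
            write_repeats_tsv(all_results, outdir / "repeats.tsv")
            summary["repeats"] = {
                fid: round(survey_fraction(res), 3)
                for fid, res in report.repeat_results.items()
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError("repeats", str(exc)) from exc

    try:
        if "motifs" in stages and config.motifs:
            fams = list(linkable.values())
            for pattern_text, expected in config.motifs:
                pattern = parse_pattern(pattern_text)
                report.motif_surveys.append(
                    survey(fams, pattern, report.annotations or None, expected)
                )
            write_survey_tsv(report.motif_surveys, outdir / "motifs.tsv")
            summary["motifs"] = {
                s.pattern.name: f"{s.n_displaying}/{s.n_total}" for s in report.motif_surveys
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError("motifs", str(exc)) from exc

    try:
        if "avehas" in stages and msas:
            for fid, msa in msas.items():
                profile = avehas(msa, config.topology, config.align.matrix)
                write_avehas_tsv(profile, outdir / f"avehas_{fid}.tsv")
            summary["avehas"] = sorted(msas)
    except Exception as exc:  # noqa: BLE001
        raise StageError("avehas", str(exc)) from exc

    try:
        if "tree" in stages:
            proteins, tags = [], []
            for fid, fam in report.families.items():
                for rec in fam.members[: config.tree_members_per_family]:
                    proteins.append(rec)
                    tags.append(fid)
            if len(proteins) >= 4:
                m = score_matrix(proteins, tags, config.align)
                ensemble = ensemble_consensus(
                    m, n_trees=config.n_trees, seed=_stage_seed(config.seed, "tree")
                )
                report.consensus = ensemble.consensus
                (outdir / "ensemble.nwk").write_text("\n".join(ensemble.trees) + "\n")
                (outdir / "consensus.nwk").write_text(ensemble.consensus + "\n")
                (outdir / "single.nwk").write_text(
                    nj_tree(to_distances(m), m.labels) + "\n"
                )
                summary["tree"] = {"n_leaves": len(proteins), "n_trees": config.n_trees}
    except Exception as exc:  # noqa: BLE001
        raise StageError("tree", str(exc)) from exc

    report.summary = summary
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return report


def recompute_reported_pairs(
    sequence_dir: str | Path,
    n_shuffles: int = 20000,
    align_params: AlignParams | None = None,
    seed: int = 0,
):
    """Recompute published bridge scores from user-supplied sequences.

    ``sequence_dir`` must contain one FASTA per accession named
    ``<accession>.fasta`` for the bridge pairs of the published chain
    table.  Returns a DataFrame with recomputed and published z side by
    side.  This is the accession-gated reproduction path: the study
    deposits no sequences, so the user must fetch them first.
    """
    from .reported import load_chains
    from .paircompare import shuffle_zscore
    from .seqdata import read_fasta
    import pandas as pd

    sequence_dir = Path(sequence_dir)
    rows = []
    for chain in load_chains():
        pair_files = [
            sequence_dir / f"{chain.protein_b}.fasta",
            sequence_dir / f"{chain.protein_c}.fasta",
        ]
        if not all(p.exists() for p in pair_files):
            continue
        b = read_fasta(pair_files[0]).members[0]
        c = read_fasta(pair_files[1]).members[0]
        comp = shuffle_zscore(b, c, align_params, n_shuffles=n_shuffles, seed=seed)
        rows.append(
            {
                "families": f"{chain.family_x} v {chain.family_y}",
                "protein_b": chain.protein_b,
                "protein_c": chain.protein_c,
                "published_z": chain.score_bc,
                "recomputed_z": round(comp.z_sd, 1),
            }
        )
    return pd.DataFrame(rows)
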