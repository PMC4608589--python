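"""Published comparison-score tables for the LysE superfamily expansion.

The original study reports, for eleven candidate families (LysE, RhtB,
CadD, CaCA2, MntP, ILT, TerC, NAAT, NicO, GAP, DsbD) plus the
mitochondrial-carrier (MC) negative control: the best pairwise
comparison scores between families with aligned-TMS counts, the full
A–B–C–D transitivity chains with accessions and all four scores, the
internal-repeat comparisons, and the shared-motif prevalence counts.
The underlying sequences are referenced by accession but not deposited,
so these printed values are the desk-scale inputs for re-running the
family-level inference: chain verdicts, the homology graph, and the
negative-control arithmetic are all recomputable from them.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .superfamily import HomologyChain

#: The eleven candidate families, in the published order.
FAMILY_ORDER = [
    "LysE", "RhtB", "CadD", "CaCA2", "MntP", "ILT",
    "TerC", "NAAT", "NicO", "GAP", "DsbD",
]
CONTROL_FAMILY = "MC"


def _data_path(name: str) -> Path:
    return Path(str(resources.files("memfam").joinpath("data", "reported", name)))


def load_pairwise_scores() -> pd.DataFrame:
    """Best between-family comparison scores (S.D.) with aligned-TMS counts."""
    return pd.read_csv(_data_path("pairwise_top_scores.tsv"), sep="\t")


def load_chains() -> list[HomologyChain]:
    """The published transitivity chains as :class:`HomologyChain` records.

    Verdicts are left ``not_established``; re-derive them with
    :func:`memfam.superfamily.build_graph` under chosen criteria.
    """
    df = pd.read_csv(_data_path("transitivity_chains.tsv"), sep="\t")
    chains = []
    for row in df.itertuples(index=False):
        chains.append(
            HomologyChain(
                family_x=row.family_x,
                family_y=row.family_y,
                protein_a=row.protein_a,
                protein_b=row.protein_b,
                protein_c=row.protein_c,
                protein_d=row.protein_d,
                score_ab=float(row.score_ab),
                score_bc=float(row.score_bc),
                score_cd=float(row.score_cd),
                score_ad=float(row.score_ad),
                aligned_tms_bc=int(row.aligned_tms_bc),
            )
        )
    return chains


def load_repeats() -> pd.DataFrame:
    """Published half-vs-half internal-repeat comparison scores."""
    return pd.read_csv(_data_path("internal_repeats.tsv"), sep="\t")


def load_motif_surveys() -> pd.DataFrame:
    """Published shared-motif prevalence counts with TMS locations."""
    return pd.read_csv(_data_path("motif_surveys.tsv"), sep="\t")


def control_best_scores() -> dict[str, float]:
    """Best score of each candidate family against the MC control."""
    df = load_pairwise_scores()
    mask = (df["family_a"] == CONTROL_FAMILY) | (df["family_b"] == CONTROL_FAMILY)
    out: dict[str, float] = {}
    for row in df[mask].itertuples(index=False):
        family = row.family_b if row.family_a == CONTROL_FAMILY else row.family_a
        out[family] = float(row.z_sd)
    return out
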