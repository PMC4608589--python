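"""Calibration and validation experiments over the synthetic generator.

These are the standard experiments the package runs to validate its own
statistics: the null calibration of the shuffle z-score on unrelated
random pairs, planted-superfamily recovery through the full linkage
pipeline, and the internal-repeat discrimination between tandem 3-TMS
duplications and the triplicated-2-TMS decoy lineage.  The acceptance
script and the analysis drivers both run them; tests assert on their
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .paircompare import HomologyCriteria, shuffle_zscore
from .pipeline import RunConfig, run_pipeline
from .repeats import RepeatParams, detect_internal_repeat
from .synthetic import GeneratorConfig, generate_superfamily, random_protein


@dataclass
class NullCalibration:
    z: np.ndarray
    mean: float
    sd: float
    frac_ge_5: float
    frac_ge_13: float


def null_calibration(
    n_pairs: int = 1000,
    n_shuffles: int = 200,
    length: int = 200,
    seed: int = 0,
) -> NullCalibration:
    """Shuffle z over unrelated random protein pairs.

    If the statistic is calibrated, z is approximately standard normal:
    the aligned pair is itself a draw from the composition null.
    """
    zs = np.empty(n_pairs)
    base = int(np.random.SeedSequence([seed, 101]).generate_state(1)[0] % (2**30))
    for i in range(n_pairs):
        a = random_protein(length, seed=base + 2 * i, accession=f"A{i}")
        b = random_protein(length, seed=base + 2 * i + 1, accession=f"B{i}")
        zs[i] = shuffle_zscore(
            a, b, n_shuffles=n_shuffles, seed=base + i, keep_alignment=False
        ).z_sd
    return NullCalibration(
        z=zs,
        mean=float(zs.mean()),
        sd=float(zs.std(ddof=1)),
        frac_ge_5=float((zs >= 5.0).mean()),
        frac_ge_13=float((zs >= 13.0).mean()),
    )


@dataclass
class LinkageReplicate:
    linked: bool
    decoy_isolated: bool
    decoy_max_z: float
    components: list[list[str]]


def planted_linkage_replicate(
    seed: int,
    outdir,
    divergence: float = 0.35,
    members_per_family: int = 8,
    n_families: int = 4,
    screen_shuffles: int = 2000,
) -> LinkageReplicate:
    """One full linkage run on a planted superfamily plus decoy.

    Families of 6-TMS proteins at the stated pairwise divergence are
    generated, TMSs are predicted from hydropathy, families are screened
    pairwise, chains evaluated, and the component structure compared to
    truth: success means the planted families form one component and the
    decoy joins none of them.
    """
    truth = generate_superfamily(
        GeneratorConfig(
            seed=seed,
            n_families=n_families,
            members_per_family=members_per_family,
            within_family_divergence=divergence,
            between_family_divergence=divergence,
        )
    )
    families = {f.family.family_id: f.family for f in truth.all_families()}
    config = RunConfig(
        seed=seed,
        outdir=outdir,
        stages=("topology", "screen", "chain", "graph", "control"),
        control_id="DECOY",
        screen_shuffles=screen_shuffles,
        chain_shuffles=screen_shuffles,
    )
    report = run_pipeline(config, families)
    planted = {f.family.family_id for f in truth.families}
    components = [sorted(c) for c in report.graph.components]
    linked = any(set(c) == planted for c in components)
    control = report.control_report
    return LinkageReplicate(
        linked=linked,
        decoy_isolated=control.control_isolated,
        decoy_max_z=control.max_z,
        components=components,
    )


@dataclass
class RepeatDiscrimination:
    tandem_z: np.ndarray
    decoy_z: np.ndarray
    tandem_frac_ge_13: float
    decoy_frac_lt_13: float


def repeat_discrimination(
    n_tandem: int = 20,
    n_decoy: int = 100,
    seed: int = 0,
    n_shuffles: int = 2000,
) -> RepeatDiscrimination:
    """Half-vs-half z for exact tandem duplications vs decoy triplications.

    Exact tandem proteins (identical 3-TMS halves) should always exceed
    the 13.0 S.D. homology standard; decoy proteins, whose halves share
    only frame-shifted, saturation-diverged 2-TMS material, should stay
    below it.
    """
    params = RepeatParams(n_shuffles=n_shuffles)
    tandem_z = []
    for k in range(n_tandem):
        truth = generate_superfamily(
            GeneratorConfig(
                seed=seed * 1000 + k, n_families=1, members_per_family=1,
                within_family_divergence=0.0, between_family_divergence=0.0,
                half_divergence=0.0, include_decoy=False, loop_del_prob=0.0,
            )
        )
        fam = truth.families[0]
        rec = fam.family.members[0]
        tandem_z.append(
            detect_internal_repeat(rec, fam.tms[rec.accession], params, seed=k).z_sd
        )
    decoy_z = []
    world = 0
    while len(decoy_z) < n_decoy:
        truth = generate_superfamily(
            GeneratorConfig(seed=seed * 1000 + 500 + world, members_per_family=8,
                            n_families=1)
        )
        decoy = truth.decoy
        for rec in decoy.family.members:
            if len(decoy_z) >= n_decoy:
                break
            decoy_z.append(
                detect_internal_repeat(
                    rec, decoy.tms[rec.accession], params, seed=len(decoy_z)
                ).z_sd
            )
        world += 1
    tandem_z = np.asarray(tandem_z)
    decoy_z = np.asarray(decoy_z)
    return RepeatDiscrimination(
        tandem_z=tandem_z,
        decoy_z=decoy_z,
        tandem_frac_ge_13=float((tandem_z >= 13.0).mean()),
        decoy_frac_lt_13=float((decoy_z < 13.0).mean()),
    )
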