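#!/usr/bin/env python
"""Survey the planted FGX(K/R)XL motif and per-column conservation.

The simulation plants FGX(K/R)XL inside TMS 3 of every member of the
related families (the decoy gets it too, by the same mechanism — its
prevalence there is what a motif shared by descent would *not* look
like, since the decoy TMS-3 position differs).  This driver scans all
families, tabulates prevalence with TMS localization, and writes the
per-column frequency tables of each family's true alignment.  Outputs
under results/motifs/.
"""

from pathlib import Path

import numpy as np

from memfam.motifscan import parse_pattern, position_frequencies, scan, survey, write_survey_tsv
from memfam.seqdata import read_manifest, read_fasta
from memfam.topology import read_tms_tsv

SIM = Path("results/synthetic")
OUT = Path("results/motifs")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    families = read_manifest(SIM / "families.tsv")
    annotations = {}
    for fid in families:
        annotations.update(read_tms_tsv(SIM / f"{fid}.tms.tsv"))
    pattern = parse_pattern("FGX(K/R)XL")
    related = [fam for fid, fam in sorted(families.items()) if fid != "DECOY"]
    result = survey(related, pattern, annotations, expected_tms=3)
    write_survey_tsv([result], OUT / "survey.tsv")
    print(f"{pattern.name} in TMS 3: {result.n_displaying}/{result.n_total} "
          f"({', '.join(f'{k} {v[0]}/{v[1]}' for k, v in sorted(result.per_family.items()))})")

    for fid in sorted(families):
        if fid == "DECOY":
            continue
        msa = read_fasta(SIM / f"{fid}.aln.faa", family_id=fid, aligned=True)
        freqs = position_frequencies(msa)
        np.savetxt(OUT / f"freqs_{fid}.tsv", freqs, fmt="%.3f", delimiter="\t")
        fully = int((freqs == 1.0).any(axis=1).sum())
        strongly = int((freqs.max(axis=1) >= 0.9).sum())
        print(f"{fid}: {fully} fully conserved columns, {strongly} at >= 90%")


if __name__ == "__main__":
    main()
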