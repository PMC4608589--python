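# Sequence drop-in for reproducing published comparison scores

The published analysis references its proteins by UniProt/GenBank
accession (e.g. P94633, H3RH39, Q2SUV5, P76249) but deposits no
sequences. To run the accession-gated reproduction (the corresponding
acceptance test and `memfam.pipeline.recompute_reported_pairs`), fetch
each accession and save it here as `<accession>.fasta`, e.g.

    https://rest.uniprot.org/uniprotkb/H3RH39.fasta  ->  data/uniprot/H3RH39.fasta

Bridge-pair scores (the B-C column of the published chain table) are
then recomputed with 20,000-shuffle nulls and compared within ±2 S.D.
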