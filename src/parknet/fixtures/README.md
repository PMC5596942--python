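# Bundled reference tables

Small curated tab-separated tables for a Parkinson's-disease brain
microarray analysis: hub-gene/miRNA regulation, an lncRNA-mediated
regulatory network, and a screened SNP set. They serve as worked-example
inputs for the test suite and `scripts/acceptance.py`; none of them is
required for running the pipeline on your own data.

- `table5.tsv` — regulatory non-coding RNAs per hub gene: one row per
  (hub gene, miRNA) pair, `pd_specific` = 1 for miRNAs already known in
  Parkinson's disease, `lncrnas` a `;`-joined list of lncRNAs curated for
  that miRNA row (empty when none are known). The lncRNA grouping of some
  rows is ambiguous in the upstream curation; the hub→miRNA membership and
  the PD flags are unambiguous and are the only fields the checks rely on.
- `table6.tsv` — the lncRNA-mediated regulatory network in long form: one
  row per (miRNA, partner) with `layer` ∈ {tf, lncrna, gene} and the
  activation/repression mode for TF→miRNA rows (`unknown` when no mode is
  recorded). The table carries 44 distinct TF strings when `TLX`, `TLX1`
  and `TLX3` are kept distinct; merging them would change that count, so
  downstream checks avoid relying on the TF-layer total.
- `table9.tsv` — the 20 most significant 3′UTR binding-site SNPs with their
  PD-specific miRNAs, HapMap population, eQTL p-value, locus and gene
  (28 rows; SNPs and genes repeat across miRNAs).
- `table10.tsv` — functional categories per SNP (`;`-joined; literal
  `none` when uncategorised), allele and region.
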