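# File formats

All files are whitespace-delimited plain text; lines beginning with `#`
are comments.  Floats are written with 17 significant digits so tables
round-trip float64 exactly.  Chromosomes are 1-based; positions are in
centimorgans.

## Inputs

* **Genotype table** — one row per individual: `ID g1 g2 ... gm`, each
  code in {0, 1, 2} counting copies of the reference allele.  Missing
  codes are not supported (a non-{0,1,2} token is a parse error).
* **Phenotype table** — `ID phenotype [generation]`, trait units; the
  optional integer generation labels per-generation evaluation.
* **Map** — `snp_id chromosome position_cM`, one row per SNP, in genotype
  column order; positions must be non-decreasing within a chromosome.

## Outputs

* **Effects table** (`effects.txt`) —
  `snp_id chromosome position_cM g_hat [gamma_post]`; the posterior
  probability column is present for the mixture-prior methods and absent
  for GS-BLUP.
* **Scaling table** (`scaling.txt`) — `snp_id center scale`, the
  training-derived standardization applied by `embayesb predict`.
* **GEBV table** — `ID gebv`.
* **TBV table** (simulator) — `ID tbv [generation]`.
* **QTL truth table** (`qtl_truth.txt`) — header plus
  `qtl_id chromosome position_cM effect variance_share_pct`.
* **Reports** — `report.json` / `accuracy.json` / `summary.json` (JSON);
  `accuracy.txt` / `localization.txt` (flat key/value text);
  `provenance.json` records the command, resolved configuration, seed and
  package version of every run.
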