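# shufflon

Quantitative toolkit for characterizing multi-module DNA inversion
("shufflon") reporter systems:

- **design** — model a reporter construct (invertible modules, one 31-nt
  recombination site repeated at junctions in alternating orientation, two
  flanking anchors) and render any module arrangement to DNA.
- **combinatorics** — enumerate/count parity-constrained signed
  permutations (384 for five modules; 176,947,200 for eleven), model
  inversion events between opposite-orientation sites, and compute the
  induced Markov chain's predictions.
- **simulate** — synthetic shuffled libraries under the inversion-event
  model, nanopore-like noisy long reads (i.i.d. substitutions, insertions,
  deletions, random strand), and planted-repeat fixtures for the miner.
- **classify** — decode each read to a configuration: a fast exact-k-mer
  *marker* decoder, plus an exhaustive edit-distance *oracle* decoder
  against all rendered references (bit-parallel Myers alignment, numba).
- **stats** — shuffling rate, per-position module occupancy, diversity
  under subsampling with rarefaction, minimal-inversion-count histograms,
  per-module inversion frequency, and an OLS regression of inversion
  frequency on module length and library.
- **mine** — 13-mer direct/inverted repeat screen of flanking DNA,
  31-nt candidate-site reconstruction, novelty and palindromy filters.

## CLI

```sh
shufflon design --seed 0 --out out/design
shufflon enumerate -n 5 --count-only
shufflon simulate --design-fasta out/design/design.fasta \
    --design-config out/design/design.json \
    --members 2000 --event-rate 3 --seed 0 --out out/sim
shufflon classify out/sim/reads.fastq \
    --design-fasta out/design/design.fasta \
    --design-config out/design/design.json --out out/cls
shufflon stats out/cls/library_summary.json \
    --design-fasta out/design/design.fasta \
    --design-config out/design/design.json --out out/stats
shufflon mine flanks.fasta --known known_kmers.txt --out out/mine
shufflon run --seed 0 --out out/run        # end-to-end pipeline
```

`shufflon run` accepts a JSON config (`--config run.json`) overriding any
subset of the defaults (design parameters, library size and event rate,
read error rates, classifier and statistics options); the exact config,
package version and all intermediate artifacts (FASTA/FASTQ/TSV/JSON) are
written to the output directory, and identical configs and seeds give
byte-identical outputs.

## File formats

Designs are a FASTA (`M1..Mn`, `anchor_L`, `anchor_R`) plus a JSON config
holding the site arms; reference sets are multi-FASTA keyed by
configuration strings such as `+1-4+3-2+5`; reads are plain 4-line FASTQ
with the true source configuration embedded in the read id
(`r000012|+1-4+3-2+5`) and mirrored in a truth TSV; statistics are tidy
TSV tables plus a JSON report.
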