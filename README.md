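# amylcons

Consensus prediction of aggregation-prone ("amyloidogenic") peptide
segments in protein sequences, from sequence alone.

Eleven component methods vote per residue:

* **Five native methods**, computed from packaged, checksummed data tables:
  * `pattern` — six-position amyloidogenic sequence pattern (hexapeptide
    windows; all-or-none per window)
  * `apd` — average packing density, 5-residue sliding window, window mean
    strictly above 21.4 is a hit
  * `bsc` — beta-strand contiguity: sliding averages of beta-strand
    propensity over windows of length 4–20; windows with mean ≥ 1.2 add
    their mean to each covered residue's cumulative score *y* (top 400
    windows); residues with *y* > 20 are hits
  * `aggrescan` — sliding average of an in-vivo aggregation-propensity
    scale; window length depends on sequence length (5/7/9/11); window
    mean strictly above −0.02 is a hit
  * `waltz` — hexapeptide position-specific scoring matrix; window score
    ≥ 79.0 is a hit
* **Six adapter methods** (`tango`, `netcssp`, `pafig`, `secstr`, `hce`,
  `amylmut`) whose models are *not* reimplemented: their per-residue scores
  are consumed from TSV files exported from the original tools, and only
  the published decision thresholds are applied (e.g. tango: beta
  aggregation strictly above 5.00 %; hce: energy strictly below −27.00;
  netcssp: P(beta)/P(helix) > 1 and P(beta) > 6; pafig: reliability
  index ≥ 7).

A residue is a **consensus hit** when at least `floor(n/2)` of the `n`
methods that actually produced output flag it (clamped to 1 when `n` = 1;
e.g. 5 of 11). Methods skipped for minimum-length reasons or missing
external scores do not count as "no" votes.

The evaluation module implements the per-residue benchmark protocol:
TP/TN/FP/FN counted per residue against annotated regions, sensitivity
`TP/(TP+FN)`, specificity `TN/(TN+FP)`, `Q = (sens+spec)/2`, Matthews
correlation coefficient, pooled and equal-weight per-protein (macro)
aggregation, and surface-exposure classification of predicted peptides
from DSSP accessibility (mean ≥ 20 Å² surface, 10–20 Å² semi-surface,
else buried).

## CLI

```sh
# consensus prediction (5 native methods; add adapters via --scores DIR
# holding <method>.tsv score tables)
amylcons predict --input proteins.fasta --methods native --out out/ \
    --format txt --format tsv --format gff3

# all 11 methods with external score files
amylcons predict --input proteins.fasta --methods all --scores scores/ --out out/

# per-residue benchmark against annotated regions (TSV: id, start, end)
amylcons benchmark --input proteins.fasta --regions regions.tsv --out bench/

# before/after consensus for point substitutions
amylcons mutate --input antibody.fasta --mutations T28G,I201E --out delta/
```

Coordinates are 1-based inclusive everywhere. Synthetic test inputs can be
generated with `amylcons.fixtures` (seeded, deterministic; planted motifs
with exactly matching annotations).

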