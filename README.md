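# duoqtl

Joint allelic and dosage QTL analysis for interspecific F1 hybrid
populations.

Many plant traits respond both to sequence variation (which haplotype an
offspring inherited) and to copy-number variation (how many copies of a
segment it carries). `duoqtl` implements the full analysis for a design
that observes both at once: an F1 cross between two outbred parents in
which the pollen was irradiated, so every line carries a recombinant
mosaic of the maternal haplotypes (D1/D2), a mosaic of the paternal
haplotypes (N1/N2), and possibly large paternal-only indels that set the
paternal dosage to 0 (deletion) or 2 (duplication). The package is aimed
at quantitative geneticists working with low-coverage sequenced progeny:
it phases the parents from a deep-coverage progeny subset, genotypes
every line at ~0.5x on 50-SNP binned markers, calls dosage from binned
coverage, and maps QTLs per channel and jointly.

## Models

Single-channel scans fit, at every marker and for each genotype channel
(maternal haplotype, paternal haplotype, dosage),

    Y_i = β₀ + β₁·gt_i + ε_i,

with genome-wide significance from the permutation null of max |t| over
markers (95%/1% thresholds from 1,000 trait shuffles; adjacent significant
markers merge into one QTL; variance explained is the adjusted R² of a
joint OLS fit). The combined model assigns each line x marker one of 10
joint states Pd.Pn.dose (e.g. `D1.N1.1`; deletions are `D•.NA.0`), runs
two-group permutation tests on all present state pairs (up to C(10,2)=45
per marker), applies Benjamini-Hochberg control per comparison family
across the genome, and classifies each QTL into one of six groups —
deletion, insertion, deletion+insertion, Pd, Pn, Pd+Pn — from which
genotype components differ between its significant pairs.

A first-class synthetic-data generator (read-level and marker-level)
produces whole experiments with a truth ledger, so every stage is
verifiable without external data; see `docs/methods.md`.

## Worked example

`examples/single_channel_scan.py` plants a dosage QTL at standardized
effect 0.4 in a 343-line population (24 deletion and 12 insertion
carriers at the locus) and scans the dosage channel:

```
planted dosage effect at marker Chr02_1000001_1100000 (beta = 1.25 trait units per copy)
thresholds: |t| > 3.30 significant, > 3.89 confirmed
chrom          start_marker            end_marker           peak_marker  peak_stat  variance_explained significance
Chr02 Chr02_1000001_1100000 Chr02_1200001_1300000 Chr02_1100001_1200000      6.532               0.113    confirmed
```

The called QTL covers the planted marker; its peak |t| of 6.5 clears the
1% genome-wide threshold ("confirmed"), and the locus explains 11% of the
trait variance (adjusted R²). `examples/combined_model.py` runs the same
kind of planted experiment through the 10-state model and prints the
significant state pairs — for a pure deletion effect the deleted lines
(`D*.NA.0`) separate from carriers of both paternal haplotypes and the
QTL classifies as `deletion`.

The other examples cover simulation (`simulate_population.py`), phasing
and low-coverage genotyping (`phase_and_genotype.py`) and dosage calling
(`dosage_calling.py`). A command-line pipeline wraps the library for
file-based use:

```bash
duoqtl simulate --out sim/ --seed 1
duoqtl select-snps --pd sim/parent_Pd_counts.tsv --pn sim/parent_Pn_counts.tsv \
    --focal Pd --out pd_informative.tsv
duoqtl phase --counts sim/deep_counts --snps pd_informative.tsv --out pd_haplotypes.tsv
duoqtl run-all --out results/ --seed 1   # the whole thing in one command
```

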