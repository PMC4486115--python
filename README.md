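# mbhsig

Identification of oxygen-tolerant NiFe membrane-bound hydrogenases (MBH,
group 1) from protein sequence alone, for people mining genome databases and
metagenome assemblies for biotechnologically useful hydrogenases.

## The problem and the method

Hydrogenases catalyse the H₂ half-cell reaction 2H⁺ + 2e⁻ ⇌ H₂ but most are
inactivated by O₂. In group 1 NiFe MBHs, O₂ tolerance is carried by the
proximal Fe–S cluster of the small subunit (α): tolerant enzymes coordinate
it with **six** conserved cysteines (the *6C group*), while standard,
O₂-sensitive enzymes have glycine in place of cysteine at the two
supernumerary positions (the *4C group*, with four cysteines). A supporting
histidine in the large subunit (β, position 229 in the scheme's reference
frame) further stabilises the cluster. These residues form a phylogenetic
signature readable from sequence alone.

`mbhsig` implements that signature as a classifier and embeds it in a small
pipeline:

1. **mining filters** — eliminate search hits with query coverage < 80% and
   keep CDS annotated with EC numbers under the hydrogenase class
   (field-wise match on the EC 1.12 prefix);
2. **signature classification** — globally align each query (affine
   Needleman–Wunsch, BLOSUM62, end gaps penalized) to a designated reference,
   map the six 1-based signature positions through the alignment, and call
   `TOLERANT_6C` / `STANDARD_4C` / `AMBIGUOUS` / `INDETERMINATE`. Only the
   two discriminating positions (nominally α62/α163) decide the label; a
   metagenomic fragment whose aligned span covers neither is
   `INDETERMINATE`, and a single covered discriminating position yields a
   provisional (1-of-2) call;
3. **placement** — neighbor-joining trees over classified references
   (Poisson-corrected alignment distances, d = −ln(1−p)) and k-nearest-
   reference group assignment for fragments, with distances computed only
   over mutually covered columns;
4. **ecology** — contingency tables of group × {taxon, oxygen class,
   environment terms}, within-group percentages, and directional fold
   differences (fold = larger/smaller percentage; one-group-only categories
   are flagged *exclusive* instead of given infinite folds).

A synthetic-data generator produces signature-planted protein families,
fragments, hit/CDS tables and group-conditional metadata with recorded
ground truth, so the entire pipeline is testable end to end.

## Worked example

```bash
mbhsig simulate --seed 1 --out demo
# wrote dataset (133 database, 44 metagenome sequences) to demo
mbhsig run --input demo --out demo_out --seed 1
# database_AMBIGUOUS      0
# database_INDETERMINATE  0
# database_STANDARD_4C    85
# database_TOLERANT_6C    48
# placed_fragments        44
```

The simulated study contains 177 sequences (the generator's default family
sizes), of which 44 were emitted as metagenome-style fragments; the 133
full-length database sequences all classify to their planted groups (48 6C,
85 4C — zero ambiguous or indeterminate calls at 10% background divergence
with conserved signatures). `demo_out/ecology.tsv` then holds the
comparative statistics, e.g.:

```text
axis          category   pct_6C  pct_4C  direction  fold   exclusive
oxygen_class  aerobe     60.42   2.35    6C         25.68  none
oxygen_class  anaerobe   25.00   69.41   4C         2.78   none
taxon_group   Euryarchaeota  0.00  8.24  4C                only_4C
```

Read: aerobes make up 60.4% of the 6C group but 2.4% of the 4C group — a
25.7-fold enrichment toward the tolerant enzymes at this sample size —
while anaerobes are 2.8-fold enriched among the standard enzymes, and
Euryarchaeota occur exclusively in the 4C group. Per-sequence calls with
position-by-position evidence and fragment placements are in
`demo_out/classification_report.tsv`.

The same steps are available as a library (`mbhsig.classify_collection`,
`mbhsig.place_fragment`, `mbhsig.enrichment_report`, ...); see
`docs/methods.md` for the model details and parameter defaults.

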