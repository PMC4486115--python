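# Methods

## The signature model

Group 1 NiFe membrane-bound hydrogenases split into two classes by the
coordination of the proximal Fe–S cluster in the small subunit: O₂-tolerant
enzymes carry cysteine at six conserved positions (6C), standard enzymes
carry glycine at the two supernumerary positions and cysteine at the other
four (4C). The classifier therefore reads residues at six 1-based positions
of a designated reference frame. Only the two *discriminating*
(supernumerary) positions decide the label — the other four are conserved in
both classes and are recorded as evidence but never flip a call. The large
subunit's supporting histidine (position 229 in its own reference frame) is
checked separately and reported as `present/absent/uncovered`; it supports
but never decides a tolerance call.

Decision rule over the covered discriminating positions:

| covered discriminating evidence                | label          |
|------------------------------------------------|----------------|
| all Cys (≥1 covered)                            | `TOLERANT_6C`  |
| all Gly (≥1 covered)                            | `STANDARD_4C`  |
| disagreement, or any residue other than C/G (X included) | `AMBIGUOUS` |
| neither position covered                        | `INDETERMINATE`|

One covered position suffices for a provisional label; the `confidence`
field distinguishes `1-of-2` from `2-of-2`. Residues other than C/G map to
`AMBIGUOUS` rather than being forced into a binary call, because signature
and phylogeny are known to disagree occasionally and the classifier should
not overcommit.

The scheme (reference sequences, the six positions, the discriminating
pair, expected residues) is **data, not code**: a flat `key = value` config
file. The shipped synthetic frame uses positions (17, 62, 120, 163, 219,
268) with discriminating pair (62, 163) in a 350-residue reference; users
analysing real sequences must supply a scheme whose positions come from a
curated reference in their own numbering frame (published α-numbering does
not pin down a frame — signal-peptide conventions differ — so the frame is
always explicit here).

## Alignment geometry

Signature reading requires knowing, for each reference position, what the
query shows there. Queries are globally aligned to the reference with affine
Needleman–Wunsch: a length-L gap costs `gap_open + (L−1)·gap_extend`
(defaults −11/−1 with BLOSUM62), end gaps are penalized, and the traceback
precedence is fixed (diagonal > up > left) so outputs are bit-reproducible.
Reference positions then map through alignment columns to one of three
statuses: `covered` (query residue present), `deleted` (query gap inside its
aligned span), `uncovered` (outside the query's first..last residue
columns — fragment truncation). Keeping a single, strict global mode and
pushing all fragment tolerance into the covered/uncovered/deleted
distinction (rather than score leniency) keeps the semantics deterministic;
a correctly placed fragment pays the same total end-gap cost wherever it
sits, so placement is driven by the substitution scores alone. The DP kernel
is numba-compiled; the first call in a session pays the JIT cost.

## Mining filters

* Coverage: hits with query coverage below 80% are eliminated; the bound is
  strict, so exactly 80.0 survives.
* EC selection: matching is field-wise on the dotted EC hierarchy ("1.12"
  matches `1.12.99.6` and `1.12.-.-`, not `1.1.1.1`); a `-` placeholder
  inside the prefix region does not match.
* Subunit assignment: best exemplar identity with thresholds ≥30% identity
  over ≥50 aligned residues (our defaults — no published values exist for
  this step), ties broken by exemplar id.

## Placement instead of Bayesian trees

The question the reference tree answers downstream is *which group a
fragment segregates with*. This package answers it deterministically at desk
scale: canonical Saitou–Nei neighbor joining over Poisson-corrected
distances (p = 1 − identity/100 over residue–residue columns;
d = −ln(1−p), capped at 10 as p→1) builds the reference tree, and fragments
are assigned by majority group among their k = 3 nearest classified
references. Fragment–reference distances use only mutually covered columns,
so short fragments are not drowned by end gaps; references with fewer than
25 aligned residue pairs are ignored, and a fragment with none left is
`unplaced`. An equal split is reported as `tie` (support 0.5) rather than
resolved arbitrarily; `support` is the fraction of the k neighbours sharing
the assigned group. Q-matrix ties break on the smallest index pair and
negative NJ branch lengths are clamped to zero with the deficit logged, so
the tree is reproducible. Bayesian MCMC tree inference would add posterior
support values but no additional information for the group-membership
question, at orders of magnitude more compute.

## Comparative ecology

Because the two groups have unequal sizes, all comparisons are on
within-group percentages. For each axis (taxon group, oxygen class,
environment terms) the contingency table counts observations per (group,
category); environment terms are frequency-weighted (each record contributes
its term counts; a presence/absence mode is available since term-frequency
semantics vary across annotation pipelines). The fold difference for a
category is max(pct)/min(pct) with the direction pointing at the enriched
group. Zero cells yield an `exclusive` flag and a null fold — no
pseudocounts, matching how one-group-only phyla are described verbally.
No hypothesis testing is attached: the statistics are descriptive.

## The synthetic generator

The generator emulates the study system so that every stage has planted
truth:

* **References**: a random 350-residue background with Cys planted at the six
  scheme positions (6C), Gly at the discriminating pair (4C), His at the
  large-subunit position. 350 residues is chosen near the length of a
  full small subunit (~362 aa).
* **Families**: star phylogenies — n descendants with i.i.d. substitutions
  (default rate 0.10, uniform over the 19 alternatives) and optional
  geometric-length indels (default rate 0.0; indels are exercised explicitly
  in tests rather than by default, keeping the default conditions exactly
  the ones under which recovery is provably exact). Signature positions are
  protected (never substituted or deleted) by default: the biological claim
  being modelled is conservation of the signature, not its decay.
* **Fragments**: a fraction (default 0.2) of sequences become uniformly
  positioned substrings with length uniform on [35, 350] — from full
  proteins down to 35-residue fragments, the range observed in real
  metagenome screens. The probability that a random span misses both
  discriminating positions has a closed form (`span_miss_probability`),
  which the tests compare against the empirical `INDETERMINATE` rate.
* **Metadata**: per-group categorical draws for taxon and oxygen class and
  Poisson term frequencies for environments. The default distributions plant
  the contrasts the comparative stage is designed to detect: aerobes at
  0.57 (6C) vs 0.02 (4C) (a 28.5-fold structure), anaerobes at 0.26 vs 0.66
  (2.54-fold), delta/alpha/beta-proteobacteria folds near 8.0/17.8/16.8, and
  one-group-exclusive taxa (CFB and GSB only 6C; Euryarchaeota, GNS and
  ε-proteobacteria only 4C).
* **Tables**: hit coverage equals the true covered fraction of the
  generating reference (so the 80% filter's behaviour is analytic), and CDS
  records carry EC `1.12.-.-` for true hydrogenases plus decoys with
  unrelated ECs.
* Default family sizes are 63 (6C) and 114 (4C) — the scale of a realistic
  mined database — with seeds fanned out per stage via
  `SeedSequence([seed, crc32(stage_name)])` so adding a stage never perturbs
  earlier ones; all outputs are byte-identical under a fixed seed.

What the generator does **not** emulate: tree-structured evolution (families
are stars, so placement tests exercise nearest-reference logic, not deep
phylogenetic structure), rate heterogeneity or realistic substitution
matrices, assembly/sequencing artifacts, chimeric fragments, and real
taxon–environment covariance. Passing tests therefore demonstrate that the
machinery is correct under its stated model, not that real metagenome calls
are error-free — on real data, accuracy rests on the curated scheme and the
alignability of the family.

## Numerical and degenerate-input choices

* Percentages and distances are float64 throughout; identity is undefined
  (and raises) when an alignment has zero residue–residue columns, and any
  reference pair with zero aligned residues aborts distance-matrix
  construction with the pair named.
* `X` is accepted as a residue and never matches an expected signature
  residue (it can only produce `AMBIGUOUS`, never a group call).
* Coordinates are 1-based inclusive everywhere, matching residue
  nomenclature (α62, H229).
* Problem sizes in the validation suite — exhaustive alignment oracle pairs
  up to length 5 over a 3-letter alphabet plus hundreds of random length-8
  pairs, 100 random additive trees with n ≤ 8, families of 100–1000
  sequences — are chosen so every check runs comfortably on a laptop while
  keeping the statistical comparisons (3σ binomial bands) meaningful.

## Known limitations

* The shipped scheme frame is synthetic; real-data use requires supplying a
  curated reference and positions.
* Placement support is a k-NN vote fraction, not a posterior probability;
  with k = 3 it takes only the values {2/3, 1, 0.5 (tie)}.
* The fold-difference estimator is a ratio of binomial proportions; when the
  rarer proportion is small (e.g. 2%), its sampling CV is large (~10% at
  n = 5000), so recovered folds scatter accordingly.
* EC-based hydrogenase selection cannot separate group 1 MBHs from other
  EC 1.12 enzymes on its own; exemplar-identity subunit assignment
  (`assign_subunit`) is the in-package discriminator for that step.
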