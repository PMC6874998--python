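# Methods

`neocohort` implements a cohort-scale neoantigen-discovery analysis for
tumor exome studies: somatic mutations and patient HLA class I genotypes
are turned into mutant/wild-type peptide pairs, scored by a panel of
matrix-based binding predictors, reduced to consensus neoantigen calls, and
summarized into the cohort statistics that motivate shared ("public")
neoantigen panels. Because patient sequencing data cannot ship with a
package, a first-class synthetic-cohort generator produces every input with
the statistical structure the analysis assumes; all validation runs against
that generator and against enumeration oracles.

## Neoantigen calling model

**Candidate peptides.** Only missense SNVs define candidates: a mutation at
protein position *p* in a protein of length *n* yields, for each length
L ∈ {8, 9, 10, 11}, every window `[s, s+L-1]` with
`max(1, p−L+1) ≤ s ≤ min(p, n−L+1)`. The mutant (MT) peptide carries the
alternate residue, the wild-type (WT) peptide the reference residue, and
the two differ at exactly one offset. Nonsense, nonstop and splice-site
variants are nonsilent (they count toward burden and the gene×sample
matrix) but have no well-defined single-residue window; they are skipped
with per-class counts surfaced in the enumeration report. Windows
containing non-canonical residues (U, X) are dropped and counted, since the
scoring matrices are 20-letter.

**Binding predictors.** Every predictor is a position-specific scoring
matrix (PSSM): a 20×L table of weights in [0, 1], with a peptide's score
the arithmetic mean of its per-position weights. Scores map to affinity
through the NetMHC-family convention

    IC50 [nM] = 50000^(1 − score),

so score 1 ↔ 1 nM and score 0 ↔ 50 µM; the conventional binder threshold of
500 nM corresponds to score ≈ 0.426. Alleles without a native matrix are
covered by pocket-similarity extrapolation (the PickPocket idea): the
available matrices of the requested length are averaged with weights
proportional to pseudo-sequence identity between the target and each
source allele (equal weights if all identities are zero). Pseudo-sequences
are deterministic 34-residue fixtures keyed on the allele name, not
biologically sourced — they give the synthesis rule something stable to
operate on, nothing more.

**Consensus rule.** A (sample, mutation, window, allele) candidate is
called a neoantigen iff

1. peptide length is 8–11 (guaranteed upstream, re-checked);
2. MT IC50 < 500 nM (strict) in at least 2 of the configured tools;
3. the consensus MT IC50 is strictly below the consensus WT IC50, i.e. the
   mutant binds more strongly than its wild-type counterpart.

The consensus summary is the median over tools, taking the lower of the two
middle values for even tool counts so the result is always an observed
value and deterministic. Criterion 3 is deliberately evaluated on the IC50
scale (score and IC50 run in opposite directions; the IC50 reading encodes
mutant-selective binding and is applied consistently). Ties — IC50 exactly
at threshold, or MT = WT — fail. Criterion 2 constrains MT peptides only.
Raising the threshold or lowering the tool quorum can only add calls
(verified by sweep).

**Counting conventions.** Per-sample neoantigen load counts distinct MT
peptide strings (windows and alleles sharing a peptide count once).
Recurrence defaults to peptide-string identity across samples regardless of
presenting allele — the convention for public neoantigens across cohorts
with differing HLA — with a stricter peptide+allele mode available.

## Cohort statistics

* **Load vs burden:** Spearman rank correlation (t-approximation for the
  p-value, flagged approximate).
* **Subgroup comparisons:** two-sided Wilcoxon rank-sum across the levels
  of age group (<60 vs ≥60, the conventional dichotomy), sex, Lauren type,
  stage and tumor location; ≥3 levels produce all pairwise tests; NA-level
  samples are excluded and counted. The exact null distribution is used
  when n ≤ 20 without ties, otherwise the normal approximation with tie and
  continuity corrections.
* **Mutual exclusivity:** per gene pair, the 2×2 co-mutation table (both /
  A-only / B-only / neither) under Fisher's exact test (two-sided, sum of
  hypergeometric probabilities ≤ observed). Direction is exclusive when the
  sample odds ratio ad/bc < 1. Degenerate tables (a gene mutated in no or
  all samples) report p = 1 and direction "undetermined". p-values are
  uncorrected by default — matching how such screens are usually reported —
  with Benjamini–Hochberg q-values available as an option.
* **Panel selection:** greedy maximum coverage. At each step the identity
  adding the most uncovered samples is picked; ties break by larger total
  carrier count, then lexicographic identity; selection stops at k or at
  zero marginal gain. Coverage is measured against the full cohort,
  including samples with no calls. Greedy selection is the explicit,
  documented stand-in for "top" panels whose selection rule is otherwise
  ambiguous.

The exact tests are computed through scipy.stats (`fisher_exact`,
`mannwhitneyu`, `spearmanr`); the test suite validates them against
independent full-enumeration oracles (all 2×2 tables with total ≤ 12; all
rank-sum splits with n ≤ 8).

## The synthetic-cohort generator

The generator emulates a gastric-cancer exome cohort and is the package's
study-condition definition, not a tuning knob.

* **Burden.** Per-sample nonsilent burden is negative binomial with size
  (dispersion) r = 2.0 and mean calibrated so the NB median equals the
  configured target (default 66). The calibration inverts the step-function
  median by bisection and takes the midpoint of the achieving interval.
  r = 2.0 balances the heavy right tail real cohorts show (a 74-sample
  draw typically peaks near 5× the median) against degenerate
  near-Poisson behavior; published cohorts report only medians and ranges,
  so the dispersion is a package choice. Samples aged ≥60 have their draw
  multiplied by `age_effect` (default 1.5) and rounded — so the realized
  cohort median sits above the configured base median whenever the effect
  is active, by design.
* **Composition.** The nonsilent background is missense-dominated
  (90.9% missense, 6.1% nonsense, 0.2% nonstop, 2.8% splice-site), placed
  uniformly over proteome residues; silent passengers arrive at a Poisson
  rate of 0.4 per nonsilent mutation. No indels are simulated (peptides are
  only defined for substitutions here); the MAF reader still accepts indel
  classes from external files.
* **Spectrum.** Each variant's nucleotide-level identity (six-class
  substitution with C>T weight `ct_fraction` = 0.45, strand orientation,
  codon offset) is a deterministic hash of its protein-space identity, so
  recurrent events share one genomic variant across samples and runs.
  Amino-acid changes are generated directly in protein space (one
  transcript per gene, no codon model): genomic coordinates exist to key
  the population-AF filter, not to be biologically consistent with the
  residue change.
* **Hotspots and drivers.** Hotspot mutations (gene, position, ref→alt,
  prevalence) are inserted per sample as independent Bernoulli events. The
  default list combines recurrent-neoantigen hotspots (TP53 R175H/R273H/
  R282W, PIK3CA H1047R, KRAS G12D/G13D, PGM5 I98V, ERBB3 V104M, C6 K817T,
  TRIM49C S327R, OR4C16 S135R) at meta-cohort-shaped prevalences with
  additional per-gene driver events that raise TP53 to ~45% prevalence and
  its exclusivity partners above 10%.
* **Exclusivity.** For each configured pair (A, B, target OR), co-mutated
  samples have all gene-B mutations removed with probability
  p = (ad − t·bc) / (a(d + t·c)) (clamped to [0, 1]), the solution of the
  expected post-thinning odds ratio equal to the target; already-exclusive
  pairs are left alone. Defaults pair TP53 against CDH1, KMT2D, RYR1,
  PIK3CA and ARID1A at target OR 0.2.
* **HLA genotypes.** Loci A, B and C are sampled independently, two
  alleles per locus with replacement from the configured population
  frequencies (each locus must sum to 1); homozygous draws collapse, giving
  3–6 alleles per patient. The default frequency set is loosely shaped on
  common East-Asian class I alleles (A11:01, A24:02, A02:01, C07:02 ...).
* **Clinical metadata.** Age, sex, Lauren type, stage and location are
  drawn from the marginal frequencies of a 74-patient gastric-cancer
  cohort (62% aged ≥60, 70% male, stage III-dominated).
* **Binding truth.** The generative model is one PSSM per (allele, length):
  cells are a 0.30 baseline plus uniform dispersion scaled by
  `motif_strength` (default 0.9), with anchor positions 2 and the
  C-terminus given elevated dispersion. At these defaults a random peptide
  sits near 600 nM and only motif-matching peptides cross 500 nM, giving a
  neoantigen-per-mutation yield of order one — the selectivity regime real
  predictor stacks operate in. Simulated tools observe truth scores plus
  Gaussian noise (SD `noise_sd`, default 0.05) clipped to [0, 1]. Noise is
  a pure hash of (peptide content, allele, tool seed), which makes
  predictions deterministic and invariant to candidate order and set. A
  separate *designed* truth (all cells high except one penalized residue
  row) guarantees every window of a chosen mutation class is called; it
  exists for calibration experiments where recurrence recovery must be
  exact, and is labelled as designed, not generative.
* **Population AFs.** A configurable fraction of distinct variants
  (default 5%) receives AF > 0.5% in at least one of four database columns
  (1000 Genomes / ESP6500 / dbSNP / ExAC analogues); the rest are absent or
  ≤ 0.5%, so the common-variant filter's effect is exactly known.
* **Seeding.** One master seed feeds fixed-offset child streams per
  component (metadata, burden, hotspots, background, HLA, exclusivity,
  silent, variant details), so the whole fixture is byte-reproducible and
  components can be varied independently.

### What the generator does and does not emulate

It reproduces the marginal structures the analysis consumes: burden
distribution and its age dependence, substitution spectrum, hotspot
recurrence, gene-level exclusivity, HLA population structure, and a
predictor panel with known truth. It does not emulate sequencing error,
subclonality, expression, proteasomal processing, real HLA binding motifs,
linkage between loci, or indel/fusion neoepitopes. Passing tests therefore
demonstrate that the pipeline's logic and statistics behave correctly under
a known generative model — not that any particular biological cohort would
yield the same numbers.

## Numerical and design choices

* AF filter comparison is strict (> 0.005); a variant at exactly 0.5% is
  kept. Absent variants are kept. The filter is idempotent.
* Gene ranking in landscape summaries is by number of mutated samples with
  lexicographic tie-break (no significance model; ranking is labelled as
  frequency-based).
* All TSV floats serialize with 9 significant digits; manifests record
  content digests, not paths, so identical runs are byte-identical.
* IC50s are floored at 1 nM (score 1.0), the transform's natural range.
* Sample universes reconcile against the metadata table: mutation or call
  records for unknown samples raise; metadata samples with no mutations or
  calls are legitimate and zero-filled.
* The exclusivity screen defaults to the 25 most-mutated genes in the
  orchestrated `stats` stage to keep pair counts interpretable; the library
  function screens any requested pairs.

## Problem sizes used in validation

The acceptance checks run at sizes chosen to exercise cohort-scale behavior
while staying desk-runnable: enumeration oracles at 1,000 random proteins
(≤ 50 aa) plus exhaustive sweeps (n ≤ 30); exact-test oracles exhaustively
at table total ≤ 12 and rank-sum n ≤ 8; type-I-error calibration at 1,000
null replicates (500-sample gene screens, 100-per-group load comparisons);
hotspot recovery on a 200-sample cohort at prevalence 0.2 under the
designed binder truth; the age-effect power check over 100 replicates of a
200-sample pipeline run with a reduced configuration (base burden median
20, two alleles per locus, two tools) — the detection rate depends on the
effect ratio and sample count, not the base median, and the reduced
configuration keeps 100 full pipeline replicates fast; and the load–burden
correlation on one full-default 200-sample run.

## Known limitations

* Only missense-derived neoantigens; the skip counts for nonsense/nonstop/
  splice variants are reported so the narrowing is visible.
* PSSM predictors with a shared generative truth cannot model systematic
  disagreement between real tools (scale differences, training-set bias);
  the consensus logic, not predictor fidelity, is what this package tests.
* The t-approximation for the Spearman p-value is inaccurate below n ≈ 10;
  the result is flagged approximate.
* Fisher's exact test is conservative for sparse tables; null calibration
  is demonstrated at cell counts where the discrete effect is negligible.
* Greedy maximum coverage is a (1 − 1/e)-approximation; for the panel sizes
  used here it is effectively exact, but optimality is not guaranteed.
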