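# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical corner cases the implementation pins down.

## Reference anchoring and fingerprinting

All functional-residue reads are anchored to the packaged mature
bacteriorhodopsin sequence (248 aa). Reference numbering is precursor
numbering — mature index + `numbering_offset` (default 13, the signal
peptide length) — so the literature's Asp98/Asp109 (acceptor/donor) and
K229 (Schiff-base lysine) apply literally while inputs remain
mature-sequence FASTA.

Queries are aligned to the reference by global Needleman–Wunsch with affine
gaps (Gotoh, via Biopython's `PairwiseAligner`): BLOSUM62, gap open −10,
gap extend −1, a length-L gap costing `open + (L−1)·extend`, end gaps
penalized. These parameters are the field's standard defaults; nothing in
the classification depends delicately on them, and all are configurable
through `ScoringScheme`. The traceback is deterministic for fixed inputs.
Scores are verified against two independent oracles in the test suite (a
top-down memoized affine DP and full alignment enumeration at tiny lengths).

Percent identity is `100 × identical columns / residue–residue columns`;
gap columns, terminal or internal, are excluded from the denominator. This
is the most common convention for "percent amino acid identity", stated
here because conventions differ by up to a point or two.

The class rules, in order of precedence (first match wins):

1. Schiff-base lysine absent, pocket match `< pocket_min_fraction`
   (default 0.8), or anchoring covering `< 0.5` of the reference →
   `UNCLASSIFIED` (retinal binding not supported).
2. acceptor D and donor D → `PROTON_PUMP`. Donor Glu is deliberately *not*
   accepted: the canonical hallmark is aspartate, and widening it is left
   to an explicit config edit.
3. acceptor T and donor A → `CHLORIDE_PUMP`.
4. donor ≠ D and Helix-G diagnostic = P → `XENORHODOPSIN`.
5. donor ≠ D otherwise → `SENSORY`.
6. anything else → `UNCLASSIFIED`.

The Helix-G diagnostic column defaults to precursor 225 (mature 212), the
single aspartate in Helix G of the reference; xenorhodopsins carry proline
where every other class keeps aspartate. Because that column doubles as a
retinal-pocket residue in the textbook pocket set, it is excluded from the
pocket list in the shipped config so the two rules cannot conflict. The
retinal-binding pocket set itself (11 positions, each with a small allowed
residue set) is taken from the bacteriorhodopsin literature and shipped as
editable YAML; `pocket_min_fraction = 0.8` tolerates divergence without
letting non-retinal proteins through. The ASR position associated with
engineered inward proton pumping (precursor 230) is reported in every
fingerprint as an annotation but never used for classification — it is
engineering context, not a class rule.

Sensory sublabels (SR-I/II/III) are not attempted: no residue rule
separating them is established enough to encode.

## Distance phylogenetics

Pairwise distances on an alignment use only columns where both sequences
have residues. `p_distance` is the mismatch fraction;
`poisson_corrected` is −ln(1−p), which diverges near the 20-state
saturation ceiling, so pairs at p ≥ 0.95 are capped at −ln(0.05) and
reported as saturated. The cap matters: deep rhodopsin-class comparisons
sit near saturation, and pretending the correction is reliable there would
silently fabricate branch length.

Neighbor joining is the Saitou–Nei Q-criterion agglomeration, exact on
additive matrices (verified on random trees in the tests). Two numerical
choices are pinned down because they affect reproducibility:

* **Tie-breaking.** Ties in Q are broken on the lexicographically lowest
  label pair, with internal nodes named from their children, so the tree is
  invariant to input taxon order. (One subtlety: Q[i,j] and Q[j,i] can
  differ by one ulp from float subtraction order, so tie candidates are
  canonicalized rather than read from the upper triangle.)
* **Negative branches.** NJ can produce negative lengths on non-additive
  input; they are clamped to zero with the deficit moved to the sibling
  branch. This never changes topology.

Bootstrap supports resample alignment columns with replacement, rebuild the
NJ tree per replicate, and report the percentage of replicates containing
each internal bipartition of the full-data tree. Monophyly of a taxon set
is an exact bipartition query (is there an edge separating exactly this set
from the rest?) returning that edge's support when available.

This distance machinery is a desk-scale method: it answers the topological
question (is the candidate set a clade, and how stable is that split under
resampling?) but makes no attempt at Bayesian posteriors or
maximum-likelihood optimization, and its supports are not comparable to
posterior probabilities.

When no multiple alignment is supplied, the pipeline builds a
reference-anchored pseudo-alignment: one column per reference position,
each query contributing the residue its pairwise position map assigns
there. Insertions relative to the reference are dropped, so this is a
projection, not a true MSA — adequate for anchorable homologs, and wrong
for sequences with large insertions carrying signal.

## Compositional HGT screening

Three per-gene signatures against the host genome:

* **G+C**: (G+C)/(A+C+G+T) with ambiguous N excluded from numerator and
  denominator; reported as `gc_delta` against the genome.
* **RSCU distance**: RSCU(c) = count(c) × family degeneracy / family
  total, over the 59 informative codons (stops and nondegenerate Met/Trp
  excluded). The distance to the pooled-gene background is the mean
  |ΔRSCU| over codons whose families are observed in both profiles; genes
  under 100 codons are flagged low-power.
* **Markov log-odds**: interpolated variable-order Markov models of orders
  0..k_max (default 5, hexamer contexts), additive pseudocount 1,
  interpolation weight w(c) = n(c)/(n(c)+400) blending each order with the
  ones below — the classic damping used by interpolated-model gene
  finders. The genome background pools both strands. The score is
  (log L(gene | self-model) − log L(gene | genome model)) / length; higher
  means more foreign-looking.

**Flagging.** Both screening metrics shrink systematically with gene
length under the null — RSCU sampling noise roughly as 1/√(codons), the
self-model's overfitting gain roughly as 1/length — and both are
right-skewed, so z-scoring the raw values would mostly flag short genes.
Each metric is therefore log-transformed, its length trend removed by a
Theil–Sen fit against log gene length (robust, because the gene population
contains true outliers by hypothesis), and the residuals standardized by
median and MAD × 1.4826. A gene is atypical when either residual z-score
reaches the cutoff (default 2.0). With this construction the null flag
rate tracks the nominal normal tail (≈2.3% per metric, ≈3–5% combined),
verified by simulation in the acceptance tests. Robust center/scale rather
than mean/SD is essential: a genuinely foreign gene would otherwise
inflate its own background.

Flags are suppressed (with a warning) below 20 genes or when the
background is degenerate (MAD = 0): no stable null distribution exists in
either case.

A native-looking gene does not rule out transfer — amelioration erodes
composition signals over time — so the screen separates *recent* transfers
from ancient ones; it does not detect HGT in general.

## Synthetic data

`evolve_family` starts every taxon's ancestry from the packaged reference
with its class-diagnostic residues planted, holds all anchored positions
(the four named sites plus the pocket) invariant, and evolves the rest
along a known tree: per-branch Poisson substitutions with uniform
replacement among the 19 alternatives, plus occasional indels (rate 0.01
events/site per substitution/site, geometric lengths of mean 2). Indels
additionally keep a 2-residue buffer away from anchored sites: a gap
abutting an anchor can slide by a column at no alignment cost, which would
make the recorded residue correspondence unrecoverable by realignment and
turn the planted-truth tests into tests of gap-placement convention.

Each class occupies its own Yule subtree (mean root-to-tip scaled to
`divergence`, default 0.25 substitutions/site) hung off the family root on
a stem of `class_separation` (default 0.5), emulating a multi-class family
with clean clades. The default family has 34 taxa (10 xenorhodopsin-like,
8 each of the three classical classes). Truth records the label, tree,
exact residue correspondence, and a reference-projected true alignment for
every taxon.

The substitution process is deliberately crude — no empirical
exchangeabilities, no rate heterogeneity, no structural constraint — since
the tests concern anchoring and rule recovery, not evolutionary realism.
Consequently, passing planted-truth tests shows the machinery reads what
was planted; it does not certify performance on real families, where
conservation patterns are gentler but alignment ambiguity is structured.
Anchored reads are reliable to a total divergence of ≈0.45 from the
reference; beyond that, gaps can slide across anchors through heavily
substituted stretches, which is why the recovery guarantee is stated at
divergence ≤ 0.3.

`generate_genome` draws intergenic background iid at `background_gc`
(default 0.45), native genes codon-by-codon from the stop-free codon
distribution implied by that base composition, and foreign genes from a
shifted composition (`delta_gc`, default +0.15) with within-family codon
probabilities sharpened by an exponent (default 2.0) and renormalized —
a one-parameter codon-bias knob that leaves amino-acid frequencies
untouched. Genes (default 200 per genome, uniform 100–400 codons, random
strand) are placed without overlap; truth records which genes are foreign.
Note the sharpening itself shifts realized gene G+C slightly beyond
`delta_gc` (favored codons are the GC-richer ones at high GC); the tests
compare against the closed-form expectation of the generating
distributions, not the raw parameter.

Everything is reproducible: identical spec + seed gives byte-identical
FASTA/BED output.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen to
exercise every claim with tight statistics while staying quick: 500
oracle-checked alignments, 100 additive NJ recoveries, 200 classified
proteins across all five labels, one 34-taxon family with 100 bootstrap
replicates, one 1000-gene null genome for calibration, and 100 seeded
genomes (200 genes, 1 planted foreign) for detection power. The whole
suite runs in well under a minute of compute per stage.

## Known limitations

* The anchored pseudo-alignment discards insertions relative to the
  reference; trees built from it ignore any signal there.
* NJ supports are not posterior probabilities; deep, near-saturated splits
  get capped distances and should be treated as qualitative.
* The IMM screen trains the self-model on the gene itself; for very short
  genes the score is dominated by shrinkage and carries little signal
  (hence the length adjustment and the low-power flag).
* The classifier is rule-based by design: a protein with an unusual but
  functional acceptor/donor pair will be called by the letter of the rules,
  and the evidence trail in the output is the intended recourse.
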