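# Methods

## The procedure

For each protein the pipeline receives one or two predicted structure
models with per-residue confidence (pLDDT), an alignment, a mutation table
and per-model predictor tables, and runs six stages:

1. **Structure.** Parse single-chain PDB ATOM records; hydrogens and
   HETATM records are dropped, residue confidence is taken from the
   B-factor of the first atom of each residue, RoseTTAFold-style 0–1
   confidences are multiplied by 100 so one 0–100 scale is used throughout.
2. **Quality.** A domain is a *good model* when the mean residue confidence
   over its segment is ≥ 70; a residue is reliable when its own confidence
   is ≥ 70. Both gates are inclusive: the sources that define the 70/0.7
   convention state the boundary as "a score of 70 is good" in one place
   and "> 70" in another, so one inclusive rule is used and both thresholds
   are configurable. Disorder is summarized per domain (probability > 0.5,
   strictly; a domain is high-disorder above 40%).
3. **Conservation.** A scorecons-style weighted sum-of-pairs score per
   alignment column (below). Diversity metrics: Neff (clusters at ≥ 80%
   pairwise identity, single linkage — equivalently connected components of
   the identity graph; identity = matches over the shorter ungapped
   length), DOPs (percentage of distinct column scores at 2-decimal
   precision), percent scorecons (columns ≥ 0.9 by default; no published
   threshold exists, so it is a config knob), and the number of distinct
   taxon identifiers.
4. **Sites.** Ligand-binding residues: predictor probability ≥ 0.5
   (inclusive, as published). Interface residues: score ≥ 0.34 — the
   interface predictor's published operating point; the cutoff the original
   survey used is not printed anywhere, so this default is explicitly a
   package choice and interface predictions may instead be supplied as a
   residue set. Conserved sites: columns scoring ≥ 0.8, plus columns
   > 0.65 with a tier-1 neighbor within 5 Å (strict <, following the
   published wording; the functional-site "within 5 Å" is inclusive ≤).
   Residue adjacency is computed at heavy-atom resolution with a cell list
   (grid edge = cutoff, 27-cell scan), so neighbor search is linear-ish in
   atoms rather than quadratic.
5. **Explain.** For each mutation at a gated residue: evidence tags from
   {ligand, interface, conserved} proximity, FoldX-convention ΔΔG > 1
   (strict) and pathogenicity > 0.611 (strict). *Explained* = any tag.
   DynaMut2-convention ΔΔG < 0 is recorded as an agreement check only, and
   burial (RSA < 20, strict) is descriptive — neither enters the verdict,
   mirroring how the original accounting separates these channels. Missing
   table entries leave a flag False with a logged note rather than failing
   the run. Counts are reported at both mutation and residue-position
   granularity since the two differ whenever positions carry several
   mutations. Two-model consensus: evidence is unioned over models whose
   residue passed the gate; a mutation explained in the merge but not by
   the first model is an "additional" explanation contributed by the
   second predictor; "overlap" counts mutations explained by both.
6. **Cohort.** Disease vs polymorphism percentages (near functional site /
   destabilizing / buried / pathogenic), two-sided Mann–Whitney U on the
   pathogenicity, RSA and ΔΔG distributions, and mutant-residue composition
   enrichment against Swiss-Prot background frequencies.

## Conservation scoring

The per-column score is a Valdar-style weighted sum of pairs,

    score(c) = Σ_{i<j} w_i w_j m(a_i, a_j) / Σ_{i<j} w_i w_j,

with `m` = BLOSUM62 normalized to unit diagonal
(`B(a,b)/√(B(a,a)B(b,b))`, clipped at 0). The exact published scorecons
formula is not reproduced anywhere accessible, so the scorer sits behind a
single function and can be swapped. Unit-diagonal normalization was chosen
over a min–max rescale deliberately: it makes a perfectly conserved column
score exactly 1 for every residue type, which anchors the two-tier rule's
0.8/0.65 thresholds on an interpretable scale. Pairs involving a gap (or
unknown residue) contribute 0 similarity but stay in the denominator — a
linear gap penalty; an all-gap column scores 0; a depth-1 alignment scores
1 on residue columns. Sequence weights are mean distances (1 − identity) to
the other sequences, normalized; uniform when all sequences are identical,
and explicit weights can be passed (the tests force uniform weights to
compare against hand-computed sums).

## Solvent accessibility

Shrake–Rupley with a deterministic Fibonacci sphere: each heavy atom gets
960 test points at radius r_atom + 1.4 Å (water probe); a point survives if
it lies outside every other atom's probe-expanded sphere, and the atom
contributes the surviving fraction of 4π(r+1.4)². Van der Waals radii:
C 1.70, N 1.55, O 1.52, S 1.80 Å; unknown elements fall back to carbon with
a warning. RSA normalizes the per-residue sum by the theoretical maximum
areas of Tien et al. (2013); the original survey used NACCESS, whose
Gly-X-Gly empirical normalization shifts RSA a few percent near the 20%
burial boundary — the table is therefore swappable in config, and burial
comparisons across normalizations should be read with that caveat.
960 points keep the one-percent self-consistency the tests require while
staying fast; the point count is a config knob.

## Superposition

Models of the same domain share residue numbering, so inter-model RMSD uses
CA atoms paired by residue number and closed-form Kabsch least squares
(SVD with reflection correction; rank-deficient point sets are allowed).
A sequence-independent structural aligner is unnecessary here because no
correspondence search is needed; this replaces the external aligner the
original workflow called.

## Statistics

Mann–Whitney U is exact — full enumeration over C(n, n1) assignments,
two-sided p = 2·min(P(U≤u), P(U≥u)) capped at 1 — when n1+n2 ≤ 14 and the
pooled sample is tie-free; otherwise the normal approximation with tie and
continuity corrections. Composition enrichment reports
(f_sample − f_bg)/f_bg per amino acid with a seeded Monte-Carlo null:
size-matched multinomial draws from the background, two-sided on
|f − f_bg|, with the (1 + hits)/(1 + draws) small-sample correction.
No multiple-testing correction is applied to the 20 per-amino-acid tests by
default (matching how such tables are usually reported); a
Benjamini–Hochberg helper exists.

## The synthetic cohort

`synthetic.make_cohort` generates the complete study input offline, with
ground truth stored alongside. Defaults (the study conditions): 20 proteins
of 60 residues, 200 disease + 200 polymorphism mutations, two models per
protein.

* **Structures.** CA + CB pseudo-atom models. Cohort proteins are compact
  globules — a self-avoiding walk (step 3.8 Å, min separation 3.4 Å)
  confined to a sphere of radius 3.7·n^(1/3) Å; the coefficient was set so the whole-domain buried fraction (RSA < 20) sits near the
  ~21% baseline reported for real domains. Ideal straight helices
  (CA–CA exactly 3.8 Å, rise 1.5 Å, twist 100°) and antiparallel
  sheet pairs are available for geometric tests but have essentially no
  buried core, so they are not used for cohort statistics. Confidence is
  two-regime: core ~N(85, 5²), termini ~N(55, 8²), clipped to [0, 100] —
  so a realistic minority of residues fails the 70 gate.
* **Second model.** Coordinates perturbed by isotropic noise rescaled to a
  target CA RMSD (1.7 Å by default, the inter-predictor RMSD scale reported
  for real model pairs), then hit with a random rigid motion; confidences
  redrawn, so some residues are gated in only one model. A small number of
  extra ligand-site residues is planted only in the second model's table,
  which is what makes "additional" explanations non-empty by construction.
* **Alignments.** Query = structure sequence; planted conserved columns are
  invariant across the alignment (scoring exactly 1); other columns mutate
  per sequence with a replacement probability solved analytically so the
  realized mean pairwise identity matches the target (0.55 by default,
  depth 30).
* **Predictors.** Planted ligand/interface residues draw probabilities above
  their cutoffs, everything else below; disorder is high on the termini.
  Per-mutation ΔΔG ~ N(0.2 + 1.5·[disease], 1.2²) — baseline location and
  scale chosen so the polymorphism class lands near the ~26% destabilizing
  rate real surveys tabulate, with the +1.5 disease shift a fixed effect
  size; pathogenicity ~ Beta(5, 2) for disease vs Beta(2, 6) for
  polymorphisms; the DynaMut2 stand-in mirrors FoldX about the 1 kcal/mol
  point with noise, giving high but imperfect agreement.
* **Mutations.** Disease mutations are placed within 5 Å of a planted site
  with probability 0.6 and at buried residues with probability 0.6;
  polymorphisms are uniform. Requesting site-proximal placement with no
  planted sites raises an explicit infeasibility error. ~80% of proteins
  carry a single disease label, the rest two.
* **Ground truth.** `should_be_explained` per mutation, per model and
  merged, computed generator-side with direct pairwise distances and set
  comprehensions — no cell list, no NeighborMap and no explanation-engine
  code — and written to a sidecar JSON. The conservation profile feeding the
  ground-truth conserved set is the package scorer (the planted-MSA →
  score map *is* the generator's definition of conservation truth); the
  two-tier rule and every proximity decision are recomputed independently.
* **Determinism.** One global seed fans out per protein through
  `numpy.random.SeedSequence(seed, spawn_key=(index,))`; bundles, verdict
  tables and manifests are byte-identical across reruns, and generated
  floats are rounded to the precision of the file formats so in-memory and
  reloaded bundles agree exactly.

What the generator does *not* emulate: real side-chain packing (SASA is
computed on CA/CB pseudo-atoms), predictor error (planted evidence is
noiseless around its thresholds, so the pipeline's explained set equals
ground truth exactly — the tests verify rule fidelity, not robustness to
noisy predictors), correlated evidence channels, alignment gaps in the
query, and the sparsity of real functional annotations. That last point
matters when reading the outputs: planted evidence is dense, so nearly all
gated disease mutations are explainable by construction, whereas on real
cohorts a substantial minority of disease mutations has no structural
rationale. Passing tests therefore demonstrate that the gating, geometry
and rule algebra are correct and deterministic, not that the pipeline's
verdicts would reach any particular accuracy on real proteins.

## Numerical choices and degenerate inputs

Distances are closed-ball (≤) for functional-site proximity and open (<)
for the tier-2 conservation rule, both switchable. Boundary cases follow
the printed inequalities exactly: ΔΔG 1.0 is not destabilizing, score 0.611
is not pathogenic, RSA 20.0 is not buried, disorder 0.5 is not disordered,
pLDDT 70.0 passes. Kabsch handles collinear inputs via SVD with reflection
fix. Correlation on zero-variance vectors raises rather than returning a
silent NaN. Empty verdict classes skip the cohort contrast with a warning
instead of emitting undefined percentages. A confidence gate above 100
yields zero verdicts and a warning (useful as a null pipeline check).

## Problem sizes

Default test and acceptance runs use the 20-protein × 60-residue cohort
(400 mutations), 100 random structures of 30–200 residues for the
neighbor-search equivalence check, and 20 cohort seeds for the
planted-effect recovery check; these sizes give stable statistics for every
assertion while keeping a full run in the minutes range on one CPU.

## Known limitations

Single-chain models only; no mmCIF; no multi-chain assemblies. The
interface cutoff default (0.34) is a stand-in for an unpublished choice.
DOPs as implemented (distinct-score fraction) mirrors the intent of the
original diversity-of-positions metric but is not guaranteed to match its
unpublished formula. The scorecons variant is one member of the family of
sum-of-pairs scorers; absolute score values (and hence the 0.8/0.65 tier
thresholds) are matrix-dependent. lDDT between models is never computed —
only predicted lDDT is consumed.
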