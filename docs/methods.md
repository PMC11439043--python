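# Methods

`mitosel` implements a positive-selection inference chain for
mitochondrial OXPHOS genes: branch-site codon-model likelihood-ratio
tests, clade-level fixed-derived-nonsynonymous-substitution (FdNs)
scanning with chemical-change classification, structural proximity
mapping of substituted residues to proton-translocation channels,
extracellular-flux (OCR) derived metrics, and genome composition
statistics.  This note records the models, the numerical choices, and
what the synthetic-data suite does and does not establish.

## Codon substitution model

The rate generator is the Goldman–Yang form over the sense codons of the
bound genetic code (default: NCBI translation table 5, the invertebrate
mitochondrial code, with 62 sense codons).  For codons differing at one
nucleotide, `q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]`;
multi-nucleotide changes have rate zero.  The chain is reversible with
stationary distribution `pi`, estimated from the data by the F3x4
position-specific nucleotide scheme by default (F1x4, F61 and uniform are
available).  A floor of 1e-9 is added to each codon frequency before
normalization so that codons unobserved in small alignments cannot
acquire exactly zero stationary probability.

Transition matrices `exp(Qt)` are computed from the eigendecomposition of
the pi-symmetrized generator and cached per `(kappa, omega)`, so a fit
re-uses one decomposition across all branches and site classes.

## Branch-site mixture (Model A) and its likelihood

Four site classes with proportions `(p0, p1, p2a, p2b)`,
`p2a/p2b = p0/p1`: class 0 evolves with `omega0 < 1` everywhere; class 1
with `omega = 1` everywhere; classes 2a/2b switch to `omega2 >= 1` on the
foreground branch (the single branch marked `#1` in the Newick input —
the stem of the marked clade, not its internal branches).  The null model
fixes `omega2 = 1`.

Likelihoods use Felsenstein pruning over compressed site patterns, with
per-node rescaling of partial likelihoods against underflow (the
log-scale is accumulated per pattern; the result is exact to better than
1e-8 relative, which the test suite verifies against exhaustive
enumeration of internal-node states on 3–4-taxon instances).  Ambiguous
codons are marginalized over their compatible sense codons; gap codons
are treated as missing data, though the intended workflow excises gap
columns before fitting.

During optimization, branch lengths are expressed in expected
substitutions per codon site at `omega = 1` (a parameterization choice
that decouples the length scale from the mixture weights); reported
branch lengths are converted to expected substitutions per site under the
fitted background mixture.

## Fitting

Bounded L-BFGS-B over `kappa` [0.01, 100], `omega0` [1e-4, 0.999],
`omega2` [1, 999] (alternative only), the class proportions on a softmax
transform, and all branch lengths [1e-7, 20], re-optimized under each
model.  Branch-length gradients are analytic (inside/outside passes);
the gradient for the proportions re-mixes cached per-class site
likelihoods; `kappa`, `omega0`, `omega2` use forward differences that
recompute only the site classes each parameter touches.  Three
deterministic starts are the default; the seed only jitters starts beyond
the third, so refits with different seeds agree (to ~1e-4 lnL).  When the
alternative is fitted after the null it is warm-started from the null
solution, which both accelerates convergence and keeps the LRT statistic
non-negative.  `omega2` estimates on a single foreground branch are
right-skewed and can run to the bound when little information is present;
this is a property of the model, not clipped away.

## LRT, multiple testing, NEB

The test statistic is `2(lnL_alt - lnL_null)`, referred by default to
chi-square with df = 2 (critical values 5.991 at 5% and 9.210 at 1%;
the survival function at df 2 is `exp(-x/2)`).  The canonical branch-site
reference — df = 1, or the 50:50 mixture of a point mass at zero and
chi-square(1) — is exposed as an option; the df = 2 default is
deliberately conservative and the null-calibration test verifies its
empirical size is below nominal.  Bonferroni adjustment multiplies the
raw p-value by the number of branches tested on the tree, capped at 1.

Selected sites are identified by Naive Empirical Bayes: per-site
posterior class probabilities computed at the maximum-likelihood
estimates, thresholding `P(2a or 2b) >= 0.95`.  BEB is out of scope.

## Pairwise dN/dS

The ML route maximizes the two-sequence GY94 likelihood
`sum log(pi_i P_ij(t))` over `t, kappa, omega` and converts to per-site
rates: with the generator scaled to one expected substitution per codon,
`dS = t * rhoS / (3 * S)` and `dN = t * rhoN / (3 * (1 - S))`, where
`rhoS` is the synonymous share of flux at the fitted `omega` and `S` the
synonymous site proportion evaluated at `omega = 1`.  The NG86 counting
estimator (equal-weight pathway averaging, changes through stop codons
excluded, Jukes–Cantor correction) is implemented independently and used
as a cross-check; the two agree to ~15% on simulated pairs at moderate
divergence.  When no synonymous divergence is observed, `omega` is
reported as undefined rather than divided by zero.

## FdNs scanning

A site is reported for a clade when (i) all clade members share one amino
acid `a_f`, (ii) `a_f` differs from every candidate ancestral state, and
(iii) at codon level a single nucleotide change can account for it
(`single_snp`); `syn_variation` flags foreground synonymous codon
variation preserving the fixed amino acid.  Ancestral states come from
Fitch parsimony over the outgroup part of the tree evaluated at the
clade's attachment point.  Ambiguous Fitch sets are intersected with the
sister lineage's set, then resolved by frequency among observed outgroup
states (alphabetical as the last resort); the candidate set and an
ambiguity flag stay on the record, so downstream users can see every
call that required a tie-break.

Convergent recurrence of the derived state in a distant outgroup does
not disqualify a site under the default rule — fixation within the clade
plus derivedness relative to the reconstructed ancestor is the defining
property, and homoplasy in a far outgroup is evidence about that outgroup,
not about the clade.  A strict mode (`require_absent_in_outgroups`)
additionally demands the derived state be absent from all outgroups.
Foreground gaps disqualify a column (fixation cannot be asserted);
outgroup gaps are treated as missing characters.  Chemical classes use
the fixed partition nonpolar {G,A,V,L,I,P,F,M,W}, polar {S,T,C,Y,N,Q},
positive {K,R,H}, negative {D,E}; a substitution "crosses polarity" iff
exactly one side is nonpolar.  No severity score is assigned — the class
pair and crossing flag are reported and scoring is left to the user.

## Structural proximity

Distances are minimum heavy-atom distances (not C-alpha or centroid)
between the query residue and any member of an annotated channel residue
set; the contact-scale 4 Å threshold only makes sense at atomic
resolution.  Proximity classes use inclusive thresholds: within 4 Å,
within 13 Å, else distal (both configurable).  Channel annotations can be
given in a template structure's numbering and are projected through a
global pairwise protein alignment (BLOSUM62, gap open −11, extend −1;
parameters recorded so mappings are reproducible).  The bundled channel
file is a small synthetic example subset and must be replaced with a
curated list for real analyses.  Superposition RMSD uses the
least-squares optimal proper rotation (Kabsch/SVD; reflections
disallowed).

## OCR metrics

Plate runs are 32 measurement cycles: 8 untreated, injection 1 (FCCP or
1% DMSO vehicle), 20 response cycles, injection 2 (sodium azide), 4
terminal cycles.  For each cycle the mean background-well OCR is
subtracted, then values are normalized per worm (subtraction first; the
order is a documented choice).  With window means over wells:

    basal   = mean(DMSO window)  - non-mitochondrial
    maximal = mean(FCCP window)  - non-mitochondrial
    spare   = mean(FCCP window)  - mean(DMSO window)

The non-mitochondrial term is the azide-phase mean pooled across all
sample wells — azide abolishes mitochondrial respiration everywhere, and
pooling makes `spare = maximal - basal` an exact algebraic identity,
asserted on every computed plate.  Response-window presets: cycles 10–13
("mephisto") and 13–16 ("elegans"); the untreated mean uses cycles 5–8;
the azide window is the final four cycles.  Negative metrics are reported
with a warning, never clipped, since clipping hides assay failure.

## Synthetic data: what it emulates and what it does not

The simulator draws root codons from `pi` and evolves them along each
branch by `exp(Qt)` with the class-specific omega on the foreground
branch, using the same generator code as inference.  Tree branch lengths
are interpreted as expected substitutions per site under the background
mixture.  Outputs are deterministic given seed and config.  Planted FdNs
columns overwrite foreground taxa with a derived codon one nucleotide
from the ancestral codon (optionally with synonymous scatter).  Toy
structures are ideal helices or random coils with CA/CB pseudo-atoms and
designated channel members, with ground-truth distances from an
exhaustive loop.  OCR plates are three-plateau traces with i.i.d.
Gaussian noise.

None of these reproduce alignment error, indels, codon-frequency
heterogeneity across genes, saturation at deep divergences, structure
coordinate error, or plate drift; passing tests demonstrate correctness
of the implemented computations under the stated models, not robustness
of the biology to those violations.

## Study conditions used by the heavier simulation tests

- Null calibration: 200 alignments of 300 codons on a 6-taxon tree
  (foreground stem 0.15 subs/site) simulated with `omega2 = 1`,
  `omega0 = 0.1`, `p0 = 0.7`, `p1 = 0.2`; the df = 2 rejection rate at
  raw p < 0.05 must stay below 0.07 (the reference is conservative for
  this mixture null).  Single-start fits with warm-started alternatives
  keep each replicate near a second.
- `omega2` recovery: 3000-codon alignments on an 8-taxon tree with a
  foreground stem of 0.3 subs/site, `omega2 = 4`, `p2 = 0.3` — a regime
  with enough foreground substitutions for the estimate to concentrate;
  the median relative error over replicates must be within 30%.  Shorter
  foreground branches or smaller `p2` leave `omega2` only weakly
  identified (the estimate is then strongly right-skewed), which is a
  property of the branch-site design worth knowing before applying it.
- NEB recall: strongly selected sites are planted as class-2a columns
  (conserved background, `omega2 = 10` foreground) on a long foreground
  stem; detection at posterior 0.95 requires the site to carry clear
  foreground change while the fitted `p2` prior is non-negligible, so the
  planted fraction is set high enough that single-substitution sites can
  clear the threshold.  Sites planted in class 2b (neutral background)
  are near-undetectable at this threshold — a real and documented
  limitation of NEB on a single short branch.

## Known limitations

- Only one foreground branch per analysis (the marked clade's stem); no
  clade-wide foreground sets, no covarion models, no tree search.
- NEB posteriors at 0.95 have low per-site power for single-substitution
  evidence; expect high precision, modest recall.
- The df = 2 LRT reference is conservative; power comparisons against
  df = 1 should use the exposed option.
- Pairwise ML on near-degenerate data (few distinct codons) can drive
  `t` to its bound; the NG86 cross-check catches such cases.
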