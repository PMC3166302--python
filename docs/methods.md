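# Methods

## The model

A position weight matrix (PWM) models a fixed-width DNA motif as independent
multinomials over {A, C, G, T}, one per position.  Binding sites frequently
violate positional independence — both between neighbours and between
distant positions brought together by the 3-D geometry of the protein–DNA
complex, and also when the observed motif is really a mixture of binding
subclasses.  The tree-based PWM (TPWM) captures such structure by recursive
maximal-dependence subdivision of a set of aligned sites:

1. For every pair of positions (i, j) the empirical joint dinucleotide
   distribution p̂ᵢⱼ is compared with the product of the empirical marginals,

       D(i, j) = Σₐ Σᵦ | p̂ᵢⱼ(a, b) − p̂ᵢ(a) · p̂ⱼ(b) |,

   the plain L1 distance (not halved; the halved total-variation variant only
   rescales the threshold, which is configurable).  D ranges over [0, 3/2];
   the maximum is attained by a uniform, perfectly correlated pair.
   No pseudocount enters these estimates: a zero cell is observed absence
   and should count as such in the split logic.  (The classical
   maximal-dependence decomposition used a chi-square statistic, which
   breaks down when the contingency table contains zeros; the L1 distance
   does not.)

2. The dependency sum Sᵢ = Σⱼ≠ᵢ D(i, j) measures how strongly position i
   interacts with the rest of the motif.  The **maximal dependent position**
   is the position with the largest Sᵢ among those whose largest single
   D(i, j) strictly exceeds the dependency threshold; if no position passes
   the gate the node becomes a leaf.

3. The site set is partitioned by the nucleotide at that position.  Subsets
   with at least `min_leaf` sites become children (so a node has between 1
   and 4 children); the procedure recurses with the split position held
   fixed.  Dependencies at deeper nodes are computed over the not-yet-fixed
   positions only — fixed positions are constants and would contribute
   D = 0 anyway.

Leaves store conditional PWMs (over all width positions; the fixed ones are
degenerate), internal nodes store the raw nucleotide fractions at their split
position.  The **composite probability** of a word multiplies branch
probabilities down the routing path and the leaf PWM over the unfixed
positions.  Words routed to a nucleotide whose subset fell below `min_leaf`
at build time use the node's *fallback PWM*, fitted on exactly those residual
sites, with the residual raw mass and the fallback's split-position column
renormalized over the absent letters.  With this construction the composite
distribution sums to 1 over all 4^W words *exactly*, for any pseudocount,
and when the pseudocount is zero the position-wise marginals of the tree
reproduce the alignment's raw column frequencies (law of total probability
over the empirical branches).  Both identities are verified by enumeration
in the test suite.

## Discriminative training (TPD)

Training refines a TPWM from a positive sequence set (enriched in sites), a
negative set (expected site-free) and an initial PWM — typically a database
matrix or an IUPAC consensus.  For each false-positive rate r in a grid:

1. scan the negative set with the current model; the cutoff is the
   ⌊r·m⌋-th largest of the m negative best-hit scores (classification is
   `score ≥ cutoff`; at ⌊r·m⌋ = 0 the cutoff sits just above the maximum);
2. scan the positives — each sequence contributes at most one site, its
   best-scoring window over all offsets and both strands — and collect the
   words scoring at least the cutoff into an alignment;
3. rebuild the TPWM from that alignment;
4. stop when the symmetrized Kullback–Leibler divergence, averaged over
   positions, between the *marginal* PWMs of consecutive models falls below
   0.001.  Marginals are compared because tree topologies may differ
   between iterations.

The model maximizing the Matthews correlation coefficient over the grid is
returned (ties go to the lowest FPR).  Scores are log-odds in bits against
an order-0 background (uniform by default, configurable): the composite
model defines P(word), so

    score(w) = log2 P(w | model) − Σᵢ log2 bg(wᵢ).

Training contains no randomness; identical inputs give bit-identical models.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `dep_threshold` | 0.1 | gate on D(i, j), L1 scale.  Null calibration: in best-hit alignments of ≥ ~500 sites from column-independent motifs the maximum pairwise D stays around 0.04–0.06, while genuinely correlated pairs in the shipped models score 0.54–0.83.  For small alignments (≈100–300 sites) the null level rises toward ~0.2 (it scales like √(1/n)); raise the gate accordingly when working with few sites. |
| `min_leaf` | 100 | smallest subset that may become a branch; guards the conditional estimates at deeper nodes. |
| `pseudocount` | 0.5 | added per cell of leaf and fallback PWMs only; branch probabilities and dependency statistics use raw frequencies. |
| `fpr_grid` | 0.005…0.3 | seven points spanning stringent to permissive cutoffs. |
| `kld_tol` | 0.001 | inner-loop convergence threshold (nats, position-averaged symmetrized KL). |
| `max_inner_iter` | 50 | safety bound; hitting it logs a warning and keeps the last model. |
| consensus `match_prob` | 0.8 | probability mass on the letters an IUPAC code denotes when building an initial PWM from a consensus. |

## The synthetic benchmark

`tpwm.simulate` emulates the standard benchmark for discriminative motif
learning: n (default 3000) background sequences of 200 bp from an order-3
Markov chain; one motif site implanted per sequence with probability equal
to the *abundance* (0.8 "abundant", 0.5 "weak") at a uniform offset,
overwriting the background so lengths stay fixed; negatives by an
independent per-sequence Fisher–Yates shuffle, which preserves each
sequence's exact base composition while destroying positional signal.  The
background transition table is a user input (TSV, 4^k rows × 4 columns);
the shipped default is uniform, since no published promoter-estimated table
is redistributable here.

The shipped motif models are synthetic surrogates (the benchmark design's
published probability tables are not available):

* independent models of widths 10 and 20 in two conservation tiers — strong
  puts 0.97 on the consensus base of each column (≈1.76 bits/position),
  weak 0.7 (≈0.64 bits/position).  The strong tier was fixed by a
  design-time calibration so that sites are separable from shuffled
  negatives at 200 bp, which is what makes abundance recovery meaningful;
* dependent models with 2, 4 and 6 correlated positions (the 6-correlated
  set is {3, 4, 12, 13, 19, 20} at width 20), built from a two-class latent
  mixture.  For such a mixture D(i, j) = δᵢδⱼ/4 in closed form, where δₚ is
  the L1 distance between the two class-conditional columns at p, so the
  dependency structure is known exactly.  The 6-correlated model couples
  position 20 most strongly (exact S₂₀ = 3.90 vs ≤ 3.61 elsewhere), making
  20 the expected first split.

What the generator does **not** emulate: realistic promoter composition
(unless a transition table is supplied), multiple or overlapping sites per
sequence, variable-length/gapped motifs, peak-height or peak-shape covariates
of real ChIP-Seq data, and sequencing artefacts.  Passing tests therefore
demonstrate correctness of the algorithms under the stated generative model,
not performance on real ChIP-Seq data.

A consequence of the one-site/abundance design worth knowing: at abundance
a the sequence-level ROC of even a perfect model is capped *in expectation*
at AUC = a + (1 − a)/2, because site-free positives are score-exchangeable
with shuffled negatives (0.9 at a = 0.8; the strong model reaches ≈ 0.88–0.90,
with single-run values fluctuating around the cap by sampling noise).

## Numerical choices and edge cases

* Ties: the maximal dependent position breaks ties by the lowest position
  index; best-hit ties by smaller start, then the forward strand; MCC ties
  across the FPR grid by the lowest FPR.  Branch children are created in
  A < C < G < T order.
* Positions are 1-based in every report and serialized tree.
* Words containing non-ACGT letters invalidate only the windows containing
  them; a sequence whose windows are all invalid scans to "no hit" and can
  never be a false positive.
* A model may assign probability 0 to a word (raw branch fractions); its
  log-odds score is −∞, which orders correctly in every comparison used.
* The convergence KLD floors marginal cells at 1e-9 (then renormalizes)
  before calling the strict `pwm_kld`, because raw branch fractions can put
  exact zeros in a marginal column.  `pwm_kld` itself refuses zero cells.
* An FPR at which no positive sequence clears the cutoff yields a failed
  trace entry (MCC = −∞, excluded from selection) rather than an abort;
  training fails only if every grid entry fails.
* Degenerate inputs rejected with located errors: empty alignments/FASTA,
  non-ACGT sites, ragged matrices, malformed transition rows, schema or
  version violations in TPWM JSON.

## Design decisions that were genuinely open

* **Fallback for absent branches.**  Fitted on the residual sites (the ones
  routed to below-`min_leaf` letters), not on all of the node's sites: this
  is the unique choice that keeps the composite distribution exactly
  normalized *and* makes the zero-pseudocount marginals reproduce the raw
  column frequencies.
* **Negative-set rescanning.**  The cutoff is recomputed from the negative
  set at every inner iteration, so it tracks the evolving model rather than
  the initial PWM.
* **Sequence-level FPR.**  A negative counts as a false positive if its
  single best hit clears the cutoff, mirroring the one-site-per-sequence
  assumption on the positive side.
* **Both-strand scanning by default** (`--single-strand` to disable), since
  peak sequences are unstranded.
* **Orientation handling in pattern accuracy.**  Δ is computed for the
  estimate and its reverse complement and the minimum reported with the
  orientation used, so a correct but strand-flipped recovery is not
  penalized.  Column-shift alignment is *not* searched: widths are fixed by
  the initial PWM, so columns correspond 1:1.

## Problem sizes used by the shipped checks

The test suite trains at the benchmark sizes (n = 1000 for the independent
and abundance checks, n = 3000 for dependent-structure recovery and the
n = 500 vs n = 3000 consistency comparison, 10 seeds each).
`scripts/acceptance.py` reports the same quantities from 5 seeds at
n = 1000 and 3 seeds at n = 3000, plus enumeration-based normalization and
scanning checks; with the vectorized scanner a full n = 3000 training run
(7 FPRs, a handful of inner iterations each) takes on the order of 15 s on
one core.

## Known limitations

* Leaf PWMs ignore any residual dependency *within* a leaf; structure below
  `min_leaf` resolution or below the dependency threshold is absorbed into
  independent columns.
* The dependency gate is a fixed threshold, not a calibrated test; its null
  level grows like √(1/n), so very small site sets need a higher gate (or
  they will show spurious splits) and very large ones could support a lower
  one.
* Scoring uses an order-0 background even when the simulator background is
  order-3; this is the standard PWM-scanning convention and is configurable,
  but scores are not p-value calibrated.
* Motif width is fixed by the initial PWM: no width search, shifting, or
  gapped/variable-spacer models.
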