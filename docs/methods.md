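# Methods

## Genotype space

The unit genotype is the specificity triplet at promoter positions
−11..−9, a length-3 string over {A,C,G,T}; the space is the 64-vertex
Hamming graph. Between a source motif `s` and target `t` at distance
`d = H(s,t)`, the *direct intermediates* are the 2^d − 2 genotypes whose
every position matches `s` or `t` (equivalently, `H(s,g)+H(g,t)=d`), and
the *direct paths* are the d! orderings in which the differing sites can
be switched one at a time. Insertions/deletions and sequence outside the
triplet are out of scope; IUPAC ambiguity codes are rejected rather than
expanded. For L ≤ 3 every set-valued operation is cross-checked in the
test suite against brute-force enumeration of the full 4^L space, and
path enumeration against depth-first search over one-step non-repeating
walks. Paths are emitted in lexicographic order so outputs are
byte-reproducible.

## Activity landscape and prediction objects

Replicate endpoint readouts (fluorescence of a transcribed aptamer at a
fixed time, default 60 min) are summarised by their mean and normalised
to percent of a reference polymerase/promoter pair:
`mean_pct = 100·mean/mean_ref`, with the replicate SEM propagated on the
same scale. The landscape is deliberately partial — only assayed motifs
exist in it — and any operation touching an unmeasured motif raises an
error listing the gaps. This is a design position, not a convenience:
silently imputing activities is precisely the failure mode the
prediction/test comparison is designed to expose (triplets off the
direct paths were not assayed up front, and that is where the prediction
broke down).

Prediction objects derived from a landscape:

* **Prediction matrix** — nodes are `s`, `t` and the direct
  intermediates, arranged in layers by distance from `s`; activities are
  attached to every node.
* **Greedy DAG** — starting from `s`, each reachable node gets edges to
  every *adjacent* next-layer candidate whose activity is at least
  `(1 − tie_tol)` times the best adjacent candidate. `tie_tol` defaults
  to 0.15: the experimental record keeps two double mutants as jointly
  most likely without stating a numeric criterion, so the tolerance is a
  configurable stand-in, recorded in output metadata. `tie_tol = 0`
  retains exact ties only. The target is always terminal.
* **Accessible paths** — the subset of the d! direct paths along which
  activity increases strictly at every step; the count is checked
  against a per-path monotonicity oracle on 1,000 random landscapes in
  the tests.
* **SSWM step probabilities** — under strong-selection weak-mutation the
  population is monomorphic and each beneficial mutation fixes or is
  lost before the next arises; the step distribution over candidates `h`
  from genotype `g` is taken proportional to the selection coefficient
  proxy `s_h = max(0, a(h)/a(g) − 1)`. If no candidate is beneficial the
  distribution falls back to uniform and is flagged. Candidates default
  to the adjacent next-layer intermediates; an option widens to all nine
  one-step neighbours for exploratory use.
* **Classification** — any observed triplet is labelled ancestral,
  target, predicted_single, predicted_double (direct intermediate one or
  two steps from the background) or unanticipated; for the 3-cube these
  partition the 64 triplets 1/1/3/3/56.

Replicate SEMs are reported but do not gate DAG construction by default;
the activity mean is the predictor, as in the original analysis.

## Serial-passage simulator

A phage genotype is the per-locus (triplet, copy number) state over the
annotated promoter network. Fitness is
`w = Σ_l weight_l · x_l/(K + x_l)` with
`x_l = copy_l · expression · a(triplet_l)`; the saturating form gives
diminishing returns per locus (rescuing a dead promoter matters more
than boosting a strong one) and `K` (default 50, in percent-activity
units) sets the half-saturation point. Locus weights are free parameters
defaulting to 1: no measured per-promoter weights exist, and *why* most
promoters never evolved is an open question the weights let a user
explore. The expression scalar models the induced → uninduced regime
switch: level 1.0 through passage 50, then 0.2 (both fixture choices;
only the switch passage is an experimental fact).

Each passage runs `generations_per_passage` (default 5; a lysis cycle
amplifies ~10²–10³-fold and no per-passage generation count is stated)
replication rounds: deterministic fitness reweighting, then multinomial
resampling at the effective sample size, then mutation. Mutation is
applied in count space — each individual suffers a single event with the
linearised hazard (per-base substitution rate × 3 positions × loci,
uniform over the three alternative bases, no transition/transversion
bias, plus a per-locus duplication rate 1→2 copies) — which is
stochastically equivalent to the expectation-vector formulation at these
rates but avoids materialising ~150 mutant categories per genotype per
generation. The passage ends with a multinomial bottleneck at
`min(bottleneck_size, effective_sample_size)` draws.

The population is tracked in genotype-frequency space at an effective
sample size of 10^5 (default) rather than as 10^7–10^8 virions; this
preserves selection exactly and represents drift at the scale of the
transferred aliquot without per-virion simulation. A 4-line × 100-passage
run over the full 16-promoter network takes ~25 s on one CPU at the
default effective size; tests use smaller effective sizes (10³–10⁴) and
fewer loci, which strengthens drift but leaves every tested invariant
(conservation, zero-rate identity, fixation under strong selection)
unchanged. All randomness descends from one master seed through
`numpy.random.SeedSequence` spawning, one stream per line, so runs are
pure functions of (config, inputs).

Default rates (mutation 10⁻⁶ per base per replication, duplication 10⁻⁷
per locus) are free parameters with no measured counterpart; every
acceptance-grade simulation result in the tests sets its rates
explicitly. Mutation rate independent of copy number and copies
collapsing onto a single locus allele are simplifications: the observed
duplication events are modelled as copy-number state, not as independent
sequence evolution of each copy.

Sequencing is emulated by re-drawing each locus's allele counts
multinomially at a fixed read depth (default 360,000, the stated minimum
per-sample depth) and duplication presence binomially.

### Fixation and summaries

An allele is *fixed* in a line when its frequency at the final sampled
passage reaches the fixation threshold (default 0.95, i.e. 95%); the
experimental record uses "fixed" qualitatively and calls 25.6%
"did not fix", which any threshold in a wide band reproduces. Loci
without a fixed allele report their allele set above a reporting floor
(default 2%, a stand-in for the variant caller's unreported floor).

## Observed-data layer

Promoter annotations use a 23-nt promoter convention with transcription
start at +1 (positions −17..+6); the specificity triplet occupies
offsets 6..8 from the promoter start, so a plus-strand promoter starting
at genome position `p` has motif window `[p+6, p+8]`, 1-based and
closed at both ends (minus-strand windows mirror from the promoter's 3'
end, though the bundled fixtures are all co-oriented). Positional
variants are assigned to the unique window containing them; overlapping
windows are an error, positions in no window are "non-promoter" and are
counted but not interpreted.

Observations at loci whose ancestral triplet differs from the main
background are classified against their own ancestral motif (their own
sub-cube toward the target) and, when a landscape is supplied, carry an
explicit caveat if that background's neighbourhood was never assayed —
for those promoters no prediction existed.

## Synthetic data: what it emulates and what it does not

The activity generator draws replicates as `truth·(1 + N(0, cv))`
(multiplicative gaussian, cv default 5%, triplicates), floored at zero.
The default truth table encodes only the qualitatively reported ordering
(best single mutant GAG; near-tied double mutants CAG/GGG above
everything else except the target; target maximal; ancestral minimal;
the three off-path triplets observed during passaging at least as active
as the predicted single mutants); the numeric levels are fixture values,
and a validator rejects any truth table violating the orderings, naming
the violated constraint. Consequently tests passing on this generator
show that the machinery recovers the *structure* of the measured
landscape under realistic replicate noise — not that any particular
percentage is right, since no numeric activities are on record.

The observation fixture encodes the reported outcome of the passaging
experiment; the four printed frequencies (46.6/25.6% and 39/3.2%) are
used verbatim, everything reported only as present or fixed is encoded
at sentinel frequencies (20% flagged "unquantified", 100% flagged
"fixed") so that count-based results never depend on placeholder
numbers. Annotation fixtures carry two genuine coordinates; the rest are
flagged placeholders spaced so motif windows never overlap. The second
AAC-background promoter is not identified in the record and is assigned
arbitrarily.

OD curves are logistic growth times a logistic decline centred at the
ground-truth lysis midpoint, sampled at 1-min resolution over 120 min.
Both lysis-time extractors (OD falling below half its maximum; steepest
decline after the maximum) recover the midpoint within the sampling
interval on these idealised curves; real curves with slow partial lysis
or regrowth may separate the two methods, which is why reports name the
method used.

What the generators do not emulate: raw reads or alignment artefacts,
non-promoter mutations, host physiology, transcript-length effects,
recombination, and any correlation between replicate noise and activity
level.

## Numerical and degenerate-input choices

* Frequencies must sum to 1 within 1e-9; exported percentages are
  clamped to [0, 100] against float spillover.
* `src == dst` yields the single zero-step path, a single-node matrix
  and an empty DAG; empty observation tables yield zero counts; an empty
  annotation warns rather than errors.
* SEM of a single replicate is 0; a zero-activity source genotype makes
  SSWM probabilities undefined (error, not NaN).
* Ties in the greedy DAG at `tie_tol = 0` are kept (≥, not >), so exact
  ties never silently drop a branch.
* Lexicographic ordering everywhere a set is serialised.

## Known limitations

* Fitness is a static per-locus sum; epistasis between promoters (e.g.
  timing interactions) is not modelled, and the saturation constant K is
  a guess exposed as a parameter.
* The linearised single-event mutation model is inaccurate for rates
  approaching 1/(3·loci); the simulator rejects configurations where the
  total hazard exceeds 1.
* Duplication state is binary by default (`max_copy_number = 2`) and
  copies do not diverge.
* The greedy DAG is a heuristic for "most likely steps"; the SSWM chain
  is the probabilistic counterpart, but neither models clonal
  interference, which the observed within-line heterogeneity suggests
  was present.
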