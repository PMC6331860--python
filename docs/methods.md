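# Methods

## Model

A compound library is a collection of sparse count fingerprints: maps
`fragment_id → count` with positive integer counts (an ECFC_4-style folded
circular fingerprint is the archetype; fragment identifiers are opaque
non-negative integers and folding is treated as upstream preprocessing).
The similarity model places each molecule in a Hilbert space whose
orthonormal basis is indexed by the fragments of the collection.

**Embedding.** Fragment *i* of compound *j* receives the complex weight
`w = re + im·i` with

* `re = log((m + 0.5)/cf_i) / log(m + 1)` — the global
  (inverse-collection-frequency) weight; `m` is the number of compounds and
  `cf_i` the number containing fragment *i*.  It is strictly decreasing in
  `cf_i` and still positive at `cf_i = m`.  The printed form of this weight
  is ambiguous about precedence; we use the standard Okapi
  inverse-frequency reading `log((m+0.5)/cf)` — the alternative
  `log(m + 0.5/cf)` is nearly constant in `cf` and has no
  inverse-frequency semantics.  The log base cancels in the ratio; natural
  logs are used.
* `im` = one of three technique weights (all non-negative, all zero when
  the fragment is absent):
  * Tech. 1, local only: `ff_ij / (ff_ij + 0.5 + 1.5·|c_j|/|c_avg|)` — a
    saturating term-frequency weight damped by compound length, always
    `< 1`;
  * Tech. 2: Tech. 1 × global;
  * Tech. 3 (modified Okapi): Tech. 2 × `min(ff_ij, ff_ir)/max(ff_ij, ff_ir)`,
    a count-agreement factor against the reference `r` with the
    `0/0 → 0` convention (a fragment absent from both contributes
    nothing).  A compound fragment absent from the reference gets zero
    imaginary weight, so Tech. 3 embeddings are reference-specific.
  * The real special case (`REAL`) sets `im ≡ 0`; the state lives in a real
    Hilbert space spanned by the compound's fragment support.  A documented
    consequence: two compounds with the same support get identical REAL
    embeddings regardless of counts.  The source work never prints the
    real-case formula; we take "special case of the complex embedding"
    literally (global weight only), and note the alternative — a real
    local×global scalar — remains untested.

The constants 0.5 and 1.5 are fixed, not fitted.  Compound length `|c_j|`
defaults to the **total** fragment-occurrence count (the Okapi
document-length convention on which the local weight is modelled);
`size_mode="distinct"` exposes the number-of-distinct-fragments
alternative, since the source description ("size in terms of the number of
fragments") supports either reading.

**Similarity.** The probability that compound `c` is relevant to reference
`r` is the Gleason-rule projection probability `tr(d Ŝ)` of the
reference's pure density `d = |r̂⟩⟨r̂|` onto the compound's one-dimensional
subspace projector `Ŝ`.  This is computed in the algebraically reduced
closed form `|⟨r|c⟩|²/(⟨r|r⟩⟨c|c⟩)` on sparse vectors — matrices are never
materialised in the screening path; the dense density/projector route
exists as an independent test oracle, and the two agree to 1e-12 on random
complex instances of dimension ≤ 8.  The value lies in [0, 1] by
Cauchy–Schwarz, is symmetric, and is invariant to rescaling either vector
by a non-zero complex scalar.  Normalising the compound projector is the
only reading that keeps the probability in [0, 1]; an unnormalised
projector would not be idempotent.  Conjugation is placed on the reference
side; the modulus makes the choice immaterial.

**Benchmark similarity.** The continuous Tanimoto coefficient
`Σab/(Σa² + Σb² − Σab)` is computed on **raw counts** — the standard
benchmark usage; which weights fed the original benchmark is not
recoverable, so a `weighted_tan` switch exposes the weighted alternative.
On 0/1 vectors it coincides with the set Tanimoto `|A∩B|/|A∪B|`.

## Screening protocol

* Ten references per activity class (configurable), drawn once from the
  sorted member list with a seeded PCG64 generator and reused for every
  method — our reading of a "unified" reference panel.  Per-class recall is
  the arithmetic mean over the ten single-reference searches; no MAX/SUM
  group fusion.
* The reference is excluded from both the ranked candidates and the recall
  denominator, so a trivial self-hit can never inflate recall.
* Cutoff arithmetic: `round(fraction × N)` positions, half away from zero,
  floor 1.  Rounding direction is not documented in the source; half-away
  is the convention chosen here.
* Ties in a ranking are broken by ascending compound id, making rankings
  machine-independent.  Zero-norm vectors (empty fingerprints) score 0
  with a logged warning rather than aborting a screen.
* Table summaries: column means, and per-row maxima counted per method with
  all ties counted ("shaded cells").  Strict tie counting reproduces the
  published DS1/DS2/DS3 top-1% shaded rows; a few published shaded rows
  (DS1 top-5%, MUV top-1%, DUD) are internally inconsistent with their own
  recall values under any tie policy we tried, and are not asserted.

## Concordance

Kendall's coefficient of concordance treats each activity class as a rater
ranking the methods (rank 1 = highest recall; midranks for ties) and uses
the tie-corrected form

    W = (12 ΣR_j² − 3 m² n (n+1)²) / (m² (n³ − n) − m ΣT_i),
    T_i = Σ (t³ − t) over tie groups of rater i,

with `X² = m(n−1)W` referred to a chi-square distribution on `n−1` degrees
of freedom (midranks and this correction reproduce the internally
consistent published rows exactly: DS2 top-1% W = 0.452, X² = 18.08; DS2
top-5% W = 0.738; MUV top-1% W = 0.272).  A fully tied matrix has no
expressible dispersion and is defined as W = 0.  The overall method
ranking orders methods by ascending rank sum; exactly tied rank sums are
joined with "=" and displayed best-mean-recall first, which matches the
published tie strings (alphabetical display is the fallback when no scores
accompany the sums).  The p-value uses the chi-square approximation, not
the exact permutation distribution; the 0.05 significance convention is
reported, never enforced.

## Synthetic benchmark

The generator emulates the *statistical* shape of the public screening
benchmarks, nothing chemical:

* each activity class owns a disjoint block of `core_size` fragments from
  a `fragment_universe` (default 512); an active includes each core
  fragment with probability `core_prob`;
* every compound (active or decoy) additionally includes each universe
  fragment with probability `background_rate` (default 0.02, ≈10
  background fragments per compound); decoys carry background only;
* counts are `1 + Poisson(count_dispersion)` (default 0.7), so fingerprints
  are genuinely count-valued and exercise the `ff > 1` branches of the
  technique weights;
* inclusion uniforms and count noise are pre-drawn for all candidate
  fragments before the inclusion threshold is applied, so for a fixed seed
  the class diversity is exactly monotone in `core_prob` and the
  calibration bisection (≤ 30 iterations, ±0.02 target band on the mean
  pairwise Tanimoto) is safe.

The default benchmark is four classes of 12 actives — two calibrated to
diversity ≈ 0.30 (homogeneous) and two to ≈ 0.10 (heterogeneous), spanning
the published class-diversity scale — against 1920 decoys (1:40
active:decoy ratio), 1968 compounds in total.  These sizes keep a full
five-method, two-cutoff evaluation in the low seconds on one CPU while
leaving recall well away from both floor and ceiling.

What the generator does **not** emulate: real substructure statistics
(fragment co-occurrence, folding collisions, scaffold families), class
overlap, property-matched decoys, or the published class compositions.
Passing tests on this benchmark therefore demonstrate correctness of the
pipeline and sane ordering behaviour (every method beats the 1%
random-retrieval baseline by a wide margin), not the published
method-versus-method ordering, which depends on real chemistry and is
asserted only from the published recall tables themselves.

## Numerical conventions

* Density operators: trace-1 within 1e-6 at construction, Hermiticity and
  PSD probes at 1e-9; projector idempotence at 1e-8 (after unit
  normalisation these are loose).
* Closed-form vs dense-trace oracle equivalence asserted at 1e-12.
* Zero-vector conventions: similarity 0 for any zero-norm operand (both
  Tanimoto and projection probability), each occurrence logged.
* Duplicate fragment keys in an input record are a parse error, never
  silently summed (whether the original folding summed collisions is
  unknowable, so ambiguous inputs are rejected).
* Reference panels, rankings, and generated libraries are bit-reproducible
  given a seed.

## Limitations

* Only pure states and one-dimensional reference subspaces are used by the
  screening path; the distribution-density operations exist for the
  framework's completeness and testing.
* The published DS1/DS3/DUD concordance rows differ in the third decimal
  from `X²/(m(n−1))` internal consistency, so the original software's
  rounding/tie policy cannot be recovered; only the internally consistent
  rows are asserted.
* Recall on classes of ~11 non-reference actives is granular (steps of
  ~9%); the synthetic benchmark trades resolution for runtime.
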