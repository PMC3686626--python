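# Methods

This note records the models, formulas, numerical choices and known
limitations behind `fpbench`. Symbols: `n` actives among `N` test
molecules, `rᵢ` the 1-based rank of the *i*-th active, `χ` a top fraction,
`α` an exponential weight.

## Evaluation metrics

**AUC.** Implemented as the Mann–Whitney form: the fraction of
(active, inactive) pairs ranked correctly, i.e. the pair count normalised
by `n(N−n)`. This normalisation is the one under which the documented
properties hold exactly — a perfect ranking scores 1, the worst scores 0,
and the expectation under a uniformly random ordering is 0.5. (A
normalisation by `nN` would cap the perfect score at `(N−n)/N` and is
therefore not used.)

**EF.** `EF(χ) = Σᵢ δ(rᵢ ≤ χN) / (χn)`. The threshold compares the
integer rank with the real-valued product `χN`, which is equivalent to
counting the top `⌊χN⌋` positions. Maximum `1/χ` when `χ ≥ n/N`, else
`N/n`; minimum 0.

**RIE.** `RIE(α) = Σᵢ e^(−αrᵢ/N) / [(n/N)(1−e^(−α))/(e^(α/N)−1)]`; the
denominator is the exact expectation of the numerator under a random
ordering, so the random mean is 1 (verified by Monte-Carlo in the test
suite). The closed-form extremes are
`RIE_min = (N/n)(1−e^(αn/N))/(1−e^(α))` and
`RIE_max = (N/n)(1−e^(−αn/N))/(1−e^(−α))`. RIE values are only
comparable across data sets when `αn/N ≪ 1`; the implementation warns
when `αn/N > 0.1`.

**BEDROC.** `(RIE − RIE_min)/(RIE_max − RIE_min)`, clamped to [0, 1] to
absorb float-epsilon overshoot at the extremes (a perfect ranking can
evaluate to `1 + 2·10⁻¹⁶` in IEEE arithmetic; the metric's contract is a
bounded score).

Degenerate compositions (`n = 0` or `n = N`) raise rather than return a
conventional value: every metric above is undefined there, and silently
returning something would corrupt downstream rank statistics.

## Similarity measures

With `a`, `b` the feature counts of the two fingerprints, `c` the common
count, `d` the common off-bits and `m` the bit-string length:
Dice `2c/(a+b)`; Tanimoto `c/(a+b−c)`; Cosine `c/√(ab)`; Russel `c/m`;
Kulczynski `(c/2)(1/a+1/b)`; McConnaughey `(c(a+b)−ab)/(ab)`; Manhattan
`1−(a+b−2c)/m`; Rogot–Goldberg `c/(a+b) + d/(2m−a−b)`. The exact
McConnaughey and Rogot–Goldberg variants differ slightly across the
literature; the forms above are pinned by unit tests so a future
correction is a one-line change.

Count vectors use the multiset generalisation `c = Σ min(aᵢ, bᵢ)`,
`a = Σaᵢ`, `b = Σbᵢ` — the standard extension that makes ECFC/FCFC
scoring well defined. Russel, Manhattan and Rogot–Goldberg all need a
finite bit universe (`m` or `d`) and are rejected for unbounded count
vectors. A molecule with no features at all would hit 0/0 in every
measure; such comparisons return 0 with a warning (including nominal
self-comparison).

Dice and Tanimoto are kept as separate measures although they induce
provably identical rankings (both order B before C exactly when
`N_{A∧B}(N_A+N_C) > N_{A∧C}(N_A+N_B)`); the equivalence is enforced as a
property test over 10⁴ random triples rather than exploited.

## Scoring stage

The test set of a repetition is `(actives \ queries) ∪ (decoys \ training
decoys)` — a partition, never an overlap. Each test molecule's score is
its maximum similarity over the query actives (MAX fusion); no other
fusion rule is supported.

**Tie-breaking.** Similarity ties are common (many decoys share a value,
especially for short bit strings), and breaking them by file order would
bias early-recognition metrics systematically. Ties are instead broken by
a pseudo-random key per molecule derived (CRC-32) from
`(master seed, target, repetition, internal ID)`. The key is shared
across fingerprints of the same repetition — so two fingerprints that
produce identical scores produce identical lists — and is independent of
the order in which test molecules are enumerated, which makes the whole
pipeline invariant to permutations of the input lists. Whether tie-breaks
should be shared across fingerprints is a genuinely open choice; sharing
was chosen because it removes a spurious source of between-fingerprint
variance, and it is isolated in one function.

Unparsable SMILES are retained in the compound lists as flagged records
and excluded from scoring with a logged count; silently dropping them
would change `n` and `N` and with them every metric.

## Rank statistics

Per (target, method, repetition) the fingerprints are ranked by score,
rank 1 best, ties averaged (so each slice sums to `k(k+1)/2`). Per-target
mean ranks over repetitions feed a **tie-corrected Friedman test** with
targets as blocks (Conover's tie-robust form
`(k−1)·Σⱼ(Rⱼ−b(k+1)/2)² / (Σᵢⱼ Rᵢⱼ² − bk(k+1)²/4)`, χ² with `k−1` df);
`scipy.stats.friedmanchisquare` is used as an independent oracle in the
tests, never as the implementation.

**Post-hoc pairwise comparisons.** The pairwise test is the `k = 2`
Friedman reduction (a sign-test-like statistic on per-target rank
differences). The bootstrap/maxT procedure, per replicate (default 100):

1. resample the repetition indices with replacement per target — jointly
   across fingerprints, preserving within-repetition correlation — and
   recompute per-target mean ranks;
2. the statistic of pair (i, j) is `|Σ_t (R̄_ti − R̄_tj)|`;
3. the joint null is generated by sign-flipping the per-target difference
   vectors (a random ±1 per target, applied to all pairs at once; 1000
   flips by default); the maxT-adjusted p-value of a pair is the fraction
   of flips whose *maximum* statistic over all pairs reaches the observed
   one, with the `(1+count)/(1+resamples)` convention so p is never 0;
4. adjusted p-values are successively maximised in raw-p order (the
   standard maxT monotonicity enforcement), which guarantees
   adjusted ≥ raw and order preservation by construction.

The 100 adjusted p-values per pair are reduced to a three-class call:
`-` all below α = 0.05, `X` all above, `o` mixed. Under a simulated
exchangeable null the rate of `-` calls stays at or below α plus
Monte-Carlo tolerance (tested). When the global test is not significant
the post-hocs are still computable but flagged as exploratory. The exact
null-generation scheme inside the original maxT machinery is a design
point with several defensible answers; the sign-flip scheme was chosen
because it is exact for the symmetric null, joint across pairs, and
seeded.

Correlation summaries between methods or fingerprints are ordinary least
squares per pair (slope, intercept, r, r², RMSE). A constant response is
reported as slope 0 with r = 0 (documented degenerate case); a constant
predictor raises.

## Scaffold analysis

Bemis–Murcko scaffolds are the canonical SMILES of the molecular
framework (ring systems plus linkers, side chains removed). Acyclic
molecules have no framework and share the single sentinel key `ACYCLIC`,
counted as one scaffold. The scaffold EF at fraction χ is
(distinct active scaffolds in the top `⌊χN⌋` entries) / (χ · S_total),
where **S_total counts distinct scaffolds among the test-set actives of
that repetition** — not the full active list — matching the analogy with
EF, whose denominator also refers to the test set. When every active has
its own scaffold the two metrics coincide term by term.

## Synthetic fixtures

Molecules are assembled by string substitution on 20 ring-system
templates (benzene through benzimidazole, plus saturated N/O
heterocycles), each with an optional ring attachment (10 choices, giving
~170 framework-distinct scaffolds) and an acyclic side chain drawn from a
pool of ~280 substituent combinations. Every assembled SMILES is
canonicalised and validated with RDKit; duplicates are rejected, and
actives and decoys never share a structure.

Style presets mirror the collection shapes they emulate: 30 actives (one
per scaffold) among 15000 decoys; 60 actives in 12 analog series with
2500 heavy-atom-matched decoys (within ±2 heavy atoms of some active);
100 diversity-picked actives with 2 decoys each selected by ECFC0 Dice
similarity > 0.5. All presets use 50 repetitions, 5 query actives and 20%
training decoys. The `difficulty` knob is the probability that a decoy is
drawn from an active scaffold rather than a framework-disjoint one
(defaults 0.9 / 0.3 / 0.5 for the three styles, reflecting their intended
hardness). `n_series` controls the scaffold-to-active ratio and active
scaffolds are guaranteed framework-distinct, so a one-active-per-series
recipe has BMS/actives = 1 by construction.

What the generator does **not** emulate: real physicochemical property
matching beyond heavy-atom count, the spread-embedding optimisation of
assay-derived decoy sets, stereochemistry, charge states, and the sheer
structural breadth of vendor libraries. Passing tests on these fixtures
therefore demonstrates that the pipeline's machinery is correct and that
it discriminates easy from hard compositions — not that any particular
fingerprint would win on real screening data.

Curation operators: MaxMin diversity picking (seeded first pick, then
greedily maximise the minimum 1−similarity distance to the picked set);
decoy selection samples without replacement among pool members passing
the ECFC0 Dice threshold, failing loudly (naming the active) when the
pool is too small; the compound filter removes MW > 700 g/mol and any
molecule with an atom outside {H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I}.

## Problem sizes and determinism

The test suite and the demo run on deliberately small compositions
(tens of actives, tens to low hundreds of decoys, 3–50 repetitions,
4–20 targets); the statistical machinery is size-agnostic and the
defaults reproduce the full-scale study conditions. Every stochastic
component — training-list sampling, tie-breaking, fixture generation,
bootstrap and sign-flip resampling — is driven by explicit seeds
(numpy `default_rng`), and identical seeds give byte-identical outputs
across the file interfaces.

## Known limitations

- 0-based compound numbering is a convention choice (the internal-ID
  scheme does not fix it); it is isolated behind the compound-list reader.
- MACCS key definitions vary slightly between toolkits; RDKit's public
  166-key set is used as-is (bit vector of length 167 with bit 0 unused).
- Avalon fingerprints require RDKit's optional Avalon extension; without
  it the two Avalon descriptors raise a capability error at call time
  while everything else works.
- Pharmacophore (4-point) fingerprints, Tversky similarity, fusion rules
  other than MAX, and SDF/MOL2 ingestion are out of scope.
- The recipe config is JSON rather than YAML; all other configs are flat
  text (one token or `NAME parameter` per line).
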