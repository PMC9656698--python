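# Methods

## Model

`ppmadl` treats a resident's day as a sequence of activity instances, each
reduced to a triplet of symbols ⟨time-bin, location, activity⟩. A
prediction-by-partial-matching model (PPM, escape method C) maintains exact
frequency counts at three context orders: activity given (time, location)
(order 2), location given time and activity given location (order 1, two
role-scoped tables), and pooled symbol frequencies (order 0). Below order 0
sits the uniform order −1 model over the training alphabet `A`. Counts are
integers and probabilities exact `Fraction`s; in a context with `n`
occurrences over `d` distinct successors, a stored successor with count `c`
has probability `c/(n+d)` and the escape event `d/(n+d)` (PPM-C), so every
context's probabilities sum to exactly 1. The order-0 "context" total is
(symbol occurrences) + (distinct symbols).

Because counts are additive and escape counts are derived, training is
path-independent: any split of a stream across `fit`/`partial_fit` calls
produces the identical model. This is what makes incremental learning exact
rather than approximate.

## Code length and the escape cascade

A query triplet (x, y, z) is coded highest-order-first with a symbol-cover
rule:

1. If context (x, y) exists and z is among its successors, contribute
   P(z|x,y) and mark z covered; otherwise descend at no cost.
2. Evaluate the order-1 transitions x→y (time table) and y→z (location
   table), skipping a transition only if all its symbols are already
   covered; a stored transition contributes its probability and covers both
   symbols; a missing one contributes nothing.
3. Every still-uncovered symbol contributes its order-0 probability, or the
   order-0 escape probability if never seen.
4. Code length = −log2 of the product of contributed factors.

Two deliberate departures from textbook PPM coding: **escape events cost
zero bits**, and each symbol's probability is counted at most once. These
choices make the worked example come out exactly — (a,c,k) costs
−log2(2/3 · 1/5) ≈ 2.91 bits with no escape factor, and the asymmetric
order-0 attributions of the other scenarios ((a,v,e) charges P(a), (i,c,n)
charges P(n)) follow from coverage. A full order-2 match is not exercised by
the worked scenarios; the cover rule extends to it naturally ((a,c,t) →
P(t|a,c)·P(a→c) ≈ 1.17 bits), which we adopt as the one consistent
extension. Exclusion-based probability rescaling (as in arithmetic-coding
PPM) is intentionally absent; only code lengths, not bitstreams, are needed.

## Novelty score and learning loop

CF(S) = 3·log2|A| / L(S); a triplet is novel iff CF strictly exceeds the
threshold `t` (default 2.0, exposed everywhere as a parameter). A detection
run scores the whole validation sequence against the *frozen* base model,
collects the novel set N in order (duplicates kept — each occurrence
reinforces counts once), then retrains once: batch refit on the stored
training triplets plus N, or an equivalent in-place count update
(`incremental=True`; a tested identity). Retraining never decreases any
existing count, so previously learned behaviour is preserved.

A consequence worth stating plainly: CF rewards *compressibility*, so fully
familiar triplets carry the highest CF of all (the worked example's exact
match scores ≈ 8.1), and a triplet is only detectably novel if it
compresses *well enough* — in practice, if it reuses known order-1
transitions or, in small models, cheap order-0 escapes. Novelty composed of
several never-seen symbols needs multiple small order-0 factors and falls
below `t` as training grows; it is invisible to this score. The literal rule
also re-flags familiar triplets, which merely reinforces their counts; a
`skip_known` flag exempts triplets whose activity is already a successor of
their order-2 context, for users who want novelty ≠ familiarity. Default
behaviour follows the literal rule.

## Prediction tasks and evaluation protocol

The three tasks are argmax queries: time→location and location→activity on
the order-1 tables, (time, location)→activity on order 2, with escape-style
backoff (order 2 → order 1 → role-restricted order 0) for unseen contexts.
Ties break by higher count, then lexicographically smallest symbol — an
arbitrary but deterministic choice. Accuracy is percent correct over *all*
test triplets; fallback predictions count as attempts.

Evaluation splits by calendar day into contiguous training / validation /
test blocks (presets mirror 15/15/28×6-fold, 5/5/6, 7/7/10 layouts and their
reduced 8-fold variants). The fold enumerator slides the test block across
the period at evenly spaced positions; when training and validation blocks
are the same size, each position yields a pair of folds with those blocks
swapped, so fold pairs share a test set (and the train-on-everything variant
is identical within a pair). With a single fold the split is chronological —
train on the earliest days, test on the latest — matching how such a system
would deploy. Whether real day-based protocols rotate test blocks or
train/validation blocks is ambiguous; the enumerator's behaviour here is the
package's fixed, documented choice.

## Synthetic residents

The generator emulates what the model assumes: per day, each scheduled
activity fires a fixed number of times at a time drawn from a categorical
distribution over bins (default: 80% peak bin, 10% each adjacent — day-to-day
jitter without losing the slot), novel activities start only at their onset
day, and with probability `noise_rate` per day one uniformly-timed random
(location, activity) pairing occurs. One seeded generator per call; identical
spec + seed gives byte-identical streams. Presets provide a 4-location/
4-activity small home and a larger 7-room/6-plus-activity layout.

What the generator does *not* emulate — raw binary-sensor segmentation,
multi-resident interleaving, annotation errors, gradual (rather than
step-change) drift — bounds what green tests mean: they validate the
machinery and its directional claims under the stated assumptions, not
field performance on real homes.

For the directional comparisons (incremental variant beats the frozen
baseline when novelty is confined to validation days; matches the
train-on-everything variant when there is none), the injected novelty is a
known (location, activity) routine at a new time bin. That is the novelty
shape the CF score can actually detect at realistic training sizes (one
strong order-1 factor plus one order-0/escape factor); see the score
discussion above. Streams are 30 days × 4–5 activities with a day-10 onset
and a 10/10/10 chronological split, sizes chosen to keep the whole suite in
seconds while leaving the effects far above sampling noise; the baseline
comparison uses 20 seeds and a sign test.

## Numerical choices and edge cases

* Exact rational arithmetic everywhere until a log is taken; float only in
  bits and CF. Reported values round to 2 d.p.
* Time bins are half-open `[start, start+width)`, labelled by start;
  `width` must divide 1440. Default 30 min keeps 8:00 and 9:30 distinct
  while pooling small jitter; real deployments should treat it as a tuning
  parameter, since no principled value exists a priori.
* Symbols come from three disjoint printable-ASCII pools assigned in
  first-seen order; an explicit (role, label) → symbol map may be supplied
  (used by the packaged worked example); pool exhaustion is a hard error
  naming the role.
* A zero code length (only possible for degenerate alphabets) reports an
  infinite CF with a `degenerate` flag rather than raising.
* Scoring is strictly read-only; `prob` returns distinct "context absent" /
  "symbol absent" signals instead of 0, because absence means escape.
* Serialization stores integer counts in versioned JSON; probabilities are
  recomputed on load, so round-trips are exact.

## Known limitations

* The CF-above-threshold rule conflates "novel but compressible" with
  "extremely familiar"; see the learning-loop section. This is inherent to
  the score as defined and is surfaced, not patched, by default.
* Context orders above 2, arithmetic-coding output, multi-resident homes,
  dynamic threshold selection and abnormality alarming on *low* CF are out
  of scope.
* Accuracy on real corpora depends on annotation quality and the time-bin
  width; nothing here claims the benchmark-scale numbers of any external
  dataset.
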