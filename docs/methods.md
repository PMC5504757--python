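# Methods

## Model

`pprlink` performs de-duplication linkage under the Fellegi-Sunter
two-class mixture: every candidate record pair is either a true match or
a non-match, and conditional on the class the per-field comparison
outcomes are independent. Each field comparison takes one of three
states — agree, disagree, missing — with class-conditional probabilities

| state | among matches | among non-matches |
|---|---|---|
| agree | m | u |
| missing | m_m | u_m |
| disagree | 1 − m − m_m | 1 − u − u_m |

For a field-state combination *j* (a pattern over all n fields), the
product of these per-field probabilities gives `recall_j` (match class)
and `fpr_j` (non-match class); both sum to 1 over the full 3^n space.
The posterior match probability of a combination is
`p_j = p·recall_j / (p·recall_j + (1−p)·fpr_j)` with p the overall match
proportion among tabulated pairs.

**EM fit.** The expectation step computes `p_j` for every observed
combination; the maximisation step re-estimates each parameter as a
ratio of posterior mass (e.g. m = posterior match mass on combinations
where the field agrees / total posterior match mass). Starting values
are m = 0.8, u = 0.1, m_m = u_m = 0.1 (the fit is insensitive to these
as long as m starts above u) and p = 0.01. Iteration stops when the
largest absolute parameter change falls below 1e−6 (max 1000
iterations); each maximisation clips probabilities to
[1e−6, 1 − 1e−6] so separable data cannot produce infinite weights. The
observed-data log-likelihood is tracked every iteration and is
non-decreasing (asserted in tests).

**Adopted parameters.** The state table is built from *blocked* pairs,
which over-represent agreement among non-matches and bias EM's u
upwards. The adopted parameter set therefore keeps EM's m and m_m but
replaces u with Jaro's frequency-based estimate on the unblocked file:
`u = Σ_v c_v(c_v−1) / (N_f(N_f−1))` over the value counts of the field's
N_f non-missing records, and `u_m = 1 − N_f(N_f−1)/(N(N−1))`, the
probability a random unordered pair has at least one missing value.
Since u (conditional on both present) and u_m are estimated
independently, u is capped at 1 − u_m to keep the trinary distribution
valid; the cap binds only for near-constant, mostly-missing fields. For
Bloom fields the value counts use exact filter equality — identical
plaintext gives identical filters — which understates chance agreement
slightly because near-matches above the agreement cutoff are not
counted. Weights use log base 2: `w_a = log2(m/u)`,
`w_d = log2((1−m)/(1−u))`; base 2 matches the entropy convention of the
profiler (a balanced binary field carries 1.00 bit).

**Threshold estimation.** The observed table is expanded to all 3^n
combinations (count 0 for unseen ones; n ≤ 12 guards the 3^n blow-up).
Combination weights sum w_a / w_d / 0 over agree / disagree / missing
states under the *adopted* parameters, for consistency with the linkage
that will actually run. True Matches = Σ p_j·c_j from the final EM
iteration; False Matches = N(N−1)/2 − True Matches. Apportioning
TP_j = TM·recall_j and FP_j = FM·fpr_j and sweeping the threshold over
the distinct combination weights yields the predicted quality curve
(an `integer_thresholds` option reproduces whole-number sweeps). The
selected threshold is the smallest one attaining the maximal predicted
F-measure — ties break low, favouring recall. Above the top weight the
empty selection is reported as precision 1, recall 0, F 0 to avoid 0/0.

**Scoring.** Pair scores are not the discretised combination weights:
exact fields contribute w_a or w_d, missing fields 0, and Dice fields a
Winkler-style partial weight — full disagreement weight below similarity
0.8, rising linearly from 0 at 0.8 to w_a at 1.0. The 0.8 cutoff is also
where Dice discretises to agree/disagree for the EM tabulation; the
anchors are configurable. A pair matches when its score is ≥ the
threshold (a `strict_gt` flag flips to >, making the selected optimum
attainable by default).

## Encoding parameters

Bloom filters default to 1000 bits, 30 hash functions per q-gram,
padded bigrams (q = 2), with keyed double hashing
(`position_i = (g1 + i·g2) mod 1000`, g1/g2 from HMAC-SHA1 of the gram
under the secret key). All values are normalised (uppercase, punctuation
stripped, whitespace collapsed, leading zeros dropped from integers)
before encoding. With these defaults a typical name sets ~200–250 of
1000 bits, so two q-gram-disjoint values still overlap by chance: the
Dice noise floor for unrelated surnames is ≈ 0.18 on average (observed
range up to ≈ 0.30). This floor is far below the 0.8 agreement cutoff
and therefore never flips a comparison state; reducing `num_hashes`
lowers the floor at some cost in similarity resolution. Exact fields and
blocking keys are 128-bit truncations of HMAC-SHA256; the encoded file
contains no plaintext, phonetic code or entity identifier.

## Synthetic data generator

The generator emulates an administrative person-record collection:
individuals appear in multiple records (duplicate counts follow a
truncated geometric distribution, p = 0.4, max 10, mean ≈ 2.4 records —
the shape of repeat-admission hospital data), field values are drawn
from skewed frequency tables, and all records of an individual are
exact copies in the error-free master. Bundled tables use a shifted
power law (weight ∝ 1/(rank + offset)) so the most common surname holds
~1–2% of the population, matching realistic name-frequency shapes
rather than a pure Zipf head; addresses are templated
"number street-name street-type" strings; birth years span 1915–2004
with mild recency weighting, months and days are uniform within valid
calendar ranges. Corruption applies two independent Bernoulli draws per
(record, field) cell at the configured error rate — one sets the value
missing (taking precedence), the other applies an operator drawn
equally from: keyboard-adjacent substitution (typo), single random
insert/delete/substitute (misspelling), dropping 1–3 trailing
characters (truncation; a length-1 value falls back to misspelling
since it has no strict non-empty prefix), and a redraw from the field's
frequency table (replacement). Date components and postcodes corrupt by
digit substitution within valid ranges; sex flips.

What the generator does **not** emulate: real name/address frequency
tables (so absolute linkage quality at a given error rate is not
comparable to collections built from population registries), field
dependence (e.g. suburb–postcode correlation), twins/households sharing
surname + address + DOB, temporal drift (name changes, moves), or
structured missingness (middle name missing-at-random only). Passing
tests therefore demonstrate the *estimation machinery* — parameter
recovery, threshold near-optimality, quality degradation with error —
not absolute quality levels on any real collection.

## Problem sizes and numerical choices

The test suite exercises the full pipeline at 50,000 records error-free
(~1M candidate pairs) and 4,000–20,000 records across 1–20% error
rates; EM recovery uses simulated 6-field tables of 100,000 pairs at a
5% match proportion, recovering m and m_m within ±0.02 and p within
±0.01 on average over 10 seeds. `scripts/acceptance.py` repeats these
computations from a single seed. Comparison is vectorised (packed-bit
Bloom matrices, chunked popcounts), so these sizes run in seconds;
blocks larger than 10,000 records warn rather than fail. All
randomness flows through `numpy.random.default_rng` seeds; identical
configurations are byte-identical.

## Known limitations

- One-to-one assignment and transitive closure of matches into entity
  clusters are out of scope; the output is a scored pair list.
- Frequency-based u for Bloom fields ignores near-match agreement mass
  (slight underestimate, slightly inflated agreement weights).
- The EM fit assumes field independence and many matches among
  candidate pairs; collections with few duplicates will fit poorly.
- Bloom-filter encodings are keyed but no claims are made about
  resistance to cryptanalytic attack; composite/record-level filters
  are not implemented.
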