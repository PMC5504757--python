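# pprlink

Probabilistic **privacy-preserving record linkage** (PPRL) for person-based
datasets. When identifying fields (names, date of birth, address) may not
leave the data custodian, linkage must run on irreversibly encoded
identifiers — but then the usual way of choosing match weights and a
decision threshold, manual inspection of record pairs, is impossible.
`pprlink` implements a complete estimation pipeline that works entirely on
the encoded data:

- **Encoding** — each similarity field (names, address, suburb) becomes a
  field-level Bloom filter: the value's character bigrams are inserted by
  keyed double hashing, so encodings of similar values share bits. Exact
  fields (sex, date-of-birth components, postcode) become keyed HMAC
  tokens. Blocking keys (surname Soundex + first initial; date of birth +
  sex) are emitted as keyed tokens at the same time.
- **Comparison** — candidate pairs are the union of within-block pairs;
  Bloom fields compare with the Sørensen-Dice coefficient
  `D(a,b) = 2|a∧b| / (|a|+|b|)`, and Dice values map to Winkler-style
  piecewise-linear partial agreement weights.
- **Estimation** — under the Fellegi-Sunter model each field has an
  m-probability (agreement among true matches) and u-probability
  (agreement among non-matches), giving weights `w_a = log2(m/u)` and
  `w_d = log2((1−m)/(1−u))`. An EM algorithm extended with *missing*
  m-/u-probabilities (`m_m`, `u_m`) fits `m, u, m_m, u_m` and the match
  proportion `p` from the table of agree/disagree/missing field-state
  combinations observed on blocked pairs. Because blocking biases the EM
  u estimates, the adopted parameter set combines EM `m`/`m_m` with
  Jaro's frequency-based `u`/`u_m` computed on the unblocked file.
- **Threshold selection** — the full `3^n` field-state space (unseen
  combinations enter with count zero) is weighted, the estimated True
  Matches (posterior mass of the final EM iteration) and False Matches
  (comparison space minus True Matches) are apportioned as
  `TP_j = TM·recall_j`, `FP_j = FM·fpr_j`, and sweeping the threshold
  over combination weights yields a predicted precision / recall /
  F-measure curve; the threshold with the highest predicted F-measure is
  selected.
- **Evaluation** — precision, recall, F-measure against a truth set
  (all unordered same-entity pairs, so blocking misses count as false
  negatives), RMSE summaries, and per-field profiling (unique values,
  missing %, discriminating power in bits).
- **Synthetic data** — a generator produces master datasets with a known
  duplicate-count distribution and frequency-weighted field values, plus
  controlled per-cell error injection (missingness and typographical
  corruption), so the entire pipeline is testable without access to real
  administrative data.

## Worked example

```python
import pprlink as pl

config = pl.GeneratorConfig(n_records=10_000, seed=7)
records, truth = pl.generate_master(config)
noisy = pl.corrupt_dataset(records, pl.CorruptionConfig(error_rate=0.05, seed=8))

result = pl.deduplicate(noisy, secret_key=b"example-key")
report = pl.evaluate_linkage(result.matches, truth)
```

prints (via the accompanying format calls):

```
candidate pairs: 38,810
EM converged in 20 iterations; match proportion p = 0.3003
  last_name  m = 0.8992  u = 8.44e-03  w_agree = +6.73
  sex        m = 0.8424  u = 5.00e-01  w_agree = +0.75
  address    m = 0.8815  u = 2.50e-04  w_agree = +11.78
selected threshold: 15.93 (predicted F = 0.9993)
actual precision = 0.9994, recall = 0.8484, F-measure = 0.9177
```

Reading this: at a 5% per-cell error rate the EM fit says ~90% of true
matching pairs still agree on surname, while two random people agree on
surname 0.8% of the time — so a surname agreement is worth +6.7 bits of
evidence, against +0.75 for sex (u = 0.5) and +11.8 for full address.
The threshold picked purely from the predicted curve (no truth used)
gives precision 0.9994; recall is bounded by pairs whose corrupted
blocking fields kept them from ever being compared.

The same flow is available from the shell:

```sh
pprlink generate --n-records 10000 --seed 7 --out master.csv --truth-out truth.csv
pprlink corrupt  --error-rate 0.05 --seed 8 --in master.csv --out noisy.csv
pprlink encode   --key example-key --in noisy.csv --out enc.csv
pprlink estimate --in enc.csv --out params.json --table-out table.csv
pprlink threshold --params params.json --table table.csv --n-records 10001 --out curve.csv
pprlink link     --params params.json --threshold 15.93 --in enc.csv --out matches.csv
pprlink evaluate --matches matches.csv --truth truth.csv --out report.json
```

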