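# File formats

All artifacts are UTF-8 plain text. Readers validate and reject malformed
input citing the offending line; writers emit stable field and record
orders so identical inputs produce byte-identical files.

## Comments — JSON lines (`*.jsonl`)

One JSON object per line, keys sorted:

| field          | type   | notes                                             |
|----------------|--------|---------------------------------------------------|
| `comment_id`   | string | unique within a corpus                            |
| `case_id`      | string | media case the comment belongs to (C1, C2, …)     |
| `media_source` | string | outlet name                                       |
| `date`         | string | ISO-8601 calendar date                            |
| `text`         | string | raw comment text (synthetic: whitespace tokens)   |
| `flags`        | array  | subset of `["duplicate", "meaningless"]`; synthetic ground truth only |

## Codings — JSON lines

| field        | type          | notes                                        |
|--------------|---------------|----------------------------------------------|
| `comment_id` | string        | reference into a comment file                |
| `labels`     | array(string) | non-empty subset of the 9 categories; `N/A` must be sole |
| `rater_id`   | string/null   | rater name, `"model"` for classifier output, null for consensus |

Valid category names: Blame Big System, Blame Medical System, Blame Doctor,
Blame Patient, Blame Other, Support Doctor, Support Patient, Support Other,
N/A.

## Policies — CSV

Columns: `policy_id, promulgation_date, lag_days, title`. Dates ISO-8601;
`lag_days ≥ 0`. Rows may be unordered on disk; readers return policies
sorted by date and require the dates to be distinct.

## Rate series — CSV

Columns: `t, date, support_rate, blame_rate, n_comments, framed`. `t` is
the 0-based analysis time index; `date` is the representative date (a
frame's second date when `framed` is true); rates are written at full
float precision.

## Segmented fits — CSV

Leading columns follow the published table layout: `policy, policy_date,
beta1, p_beta1, beta2, p_beta2, beta3, p_beta3`, followed by `beta0,
p_beta0`, the four standard errors, `outcome`, `error_model` (`iid`,
`ARMA(p,q)` or `ols_hac`), `arma_p, arma_q`, `n_points`, and the fitted
window `window_start, window_end` (in series t units). Numbers are written
at full precision.

## Sentiment dictionary — CSV with metadata header

Two comment lines (`# alpha=…`, `# stopwords=…`) followed by
`word,category,count` rows; zero counts are omitted.

## Pipeline manifest — JSON

`{"seed": …, "config_hash": …, "artifacts": {path: sha256, …}}`, written
after every pipeline run; rerunning with the same config must reproduce
identical hashes.
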