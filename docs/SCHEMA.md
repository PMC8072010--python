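# Session bundle schema

Two interchangeable formats carry session data; `foragerow.io.read_sessions`
and `write_sessions` round-trip both losslessly.

## Conventions

- **Timestamps** are integer milliseconds from session start.
- **Delays** are seconds (floats).
- **Trial indices** are 0-based and contiguous per session.
- **Zones** are numbered 0–3 clockwise around the track; each zone hosts one
  reward category.
- **Entry position** is the lateral position on entering the offer zone as a
  signed fraction of the hallway width in [-0.5, +0.5]; negative is toward
  the participant's left and the reward location, positive toward the skip
  exit.
- **Headings** are degrees in [0, 360).
- Missing optional values are empty cells (CSV) or `null` (JSONL).

## csv_bundle (a directory)

### sessions.csv — one row per session
| column | type | notes |
|---|---|---|
| participant_id | str | unique per session |
| task_variant | str | `movie` or `candy` |
| version | int | task version 1–4; 3–4 log first movement (`t_move_ms`) |
| setting | str | `in_person` or `online` |
| gender, age, bmi_group, smoker | optional | covariates; `bmi_group` is `<25` / `>=25` / empty |

### trials.csv — one row per offer
| column | type | notes |
|---|---|---|
| participant_id | str | |
| trial_index | int | 0-based |
| zone_id | int | 0–3 |
| category | str | reward category label |
| offered_delay_s | float | seconds |
| decision | str | `stay`, `skip`, or `quit` |
| t_offer_ms | int | offer presentation / offer-zone entry |
| t_move_ms | int? | first movement (versions 3–4 only) |
| t_exit_ms | int | first offer-zone exit |
| t_delay_start_ms | int? | delay countdown start (stay/quit only) |
| t_quit_or_complete_ms | int? | quit moment or delay completion |
| entry_position | float | signed width fraction, [-0.5, 0.5] |

Invariants enforced on read: `t_offer <= t_move <= t_exit`; a `quit` has a
delay start and waited time < offered delay; a `stay` completed the full
delay.

### trajectories.csv — offer-zone position samples
`participant_id, trial_index, t_ms, x, y, heading_deg` — strictly increasing
`t_ms` within a trial, all within `[t_offer_ms, t_exit_ms]`. Samples after
the first exit (re-entries) are dropped on read. Positions are arbitrary
track units; the sampling rate is whatever the logger used (the analyses are
sample-wise and rate-agnostic).

### magazine.csv — candy-variant beam breaks
`participant_id, zone_id, t_start_ms, duration_ms` with `duration_ms > 0`.

## jsonl

One JSON object per line per session, embedding `trials` (with an optional
`trajectory` object of `t`/`x`/`y`/`heading` arrays), `covariates` and
`magazine_events`. Field names match the dataclasses in
`foragerow.session`.

## Result tables

All pipeline outputs are TSV with a first line
`# foragerow <version> config=<hash>` recording the package version and a
hash of the run configuration (excluding the output directory).
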