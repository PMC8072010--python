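"""One-command orchestration: simulate -> thresholds -> metrics -> context ->
sunk-cost -> discounting -> report.

Every stage writes its tables as TSV with a provenance header (package
version + config hash); a JSON report collects the headline numbers. All
randomness flows from the master seed, so identical config + seed produce
byte-identical numeric outputs. Exclusion tallies are logged per session so
the 15-s latency and 360-degree rotation filters are auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import context as ctx
from . import discounting as disc
from . import io as fio
from . import offer_zone as oz
from . import sunk_cost as sc
from . import thresholds as th
from .session import Session, Trajectory, TrialRecord
from .simulate import AgentConfig, TaskConfig, generate_cohort, generate_survey_responses

__all__ = ["RunConfig", "run_pipeline", "make_fixtures", "analyze_sessions"]

logger = logging.getLogger("foragerow.pipeline")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "foragerow_out"
    seed: int = 0
    # either read an existing bundle ...
    input_path: Optional[str] = None
    input_format: str = "csv_bundle"
    # ... or simulate a cohort
    n_participants: int = 50
    agent: dict = field(default_factory=dict)       # AgentConfig overrides
    task: dict = field(default_factory=dict)        # TaskConfig overrides
    agent_prior: dict = field(default_factory=dict)
    # analysis parameters
    bin_width: float = 2.0
    jitter_deg: float = 1.0
    move_eps: float = 1e-6
    investments: tuple = (0.0, 5.0, 10.0)
    n_bootstrap: int = 500
    discounting_bank: str = "mcq21"
    quits_in_sequences: str = "skip"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "investments" in raw:
            raw["investments"] = tuple(raw["investments"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _setup_logging(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    root = logging.getLogger("foragerow")
    root.setLevel(logging.INFO)
    if not any(isinstance(h, logging.FileHandler)
               and getattr(h, "_foragerow_run", None) == str(out_dir) for h in root.handlers):
        fh = logging.FileHandler(out_dir / "run.log", mode="a")
        fh._foragerow_run = str(out_dir)
        fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        root.addHandler(fh)


def analyze_sessions(sessions, config: RunConfig):
    """Run the analysis stages on in-memory sessions.

    Returns a dict of DataFrames/objects: per-participant threshold fits,
    per-trial table with metrics + labels, value-tuning slopes, context
    contrasts, completion curves, the entry-bias model, and exclusion
    tallies.
    """
    # --- thresholds -------------------------------------------------------
    fit_rows, trial_tables = [], []
    for s in sessions:
        fits, table = th.fit_session_thresholds(s)
        table.insert(0, "participant_id", s.participant_id)
        table["decision"] = [t.decision for t in sorted(s.trials, key=lambda t: t.trial_index)]
        trial_tables.append(table)
        for cat, f in fits.items():
            fit_rows.append((s.participant_id, cat, f.overall_threshold,
                             f.forward_error, f.inverse_error, f.pattern, f.prop_accepted))
    fits_df = pd.DataFrame(fit_rows, columns=[
        "participant_id", "category", "threshold", "forward_error",
        "inverse_error", "pattern", "prop_accepted"])

    # --- offer-zone metrics ----------------------------------------------
    metric_tables = []
    tallies = {"n_trials": 0, "excluded_latency": 0, "excluded_rotation": 0,
               "excluded_reaction": 0}
    for s in sessions:
        m = oz.compute_session_metrics(s, jitter_deg=config.jitter_deg, move_eps=config.move_eps)
        m, t = oz.apply_exclusions(m)
        m = oz.normalize_within_session(m)
        m.insert(0, "participant_id", s.participant_id)
        metric_tables.append(m)
        for k in tallies:
            tallies[k] += t[k]
    metrics_df = pd.concat(metric_tables, ignore_index=True)
    logger.info("cohort exclusion tallies: %s", tallies)

    trials_df = pd.concat(trial_tables, ignore_index=True)
    merged = trials_df.merge(metrics_df, on=["participant_id", "trial_index"], how="left")
    merged["entry_bias"] = merged["entry_bias_pct"] / 100.0

    # --- context labels ---------------------------------------------------
    labeled = []
    for pid, g in merged.groupby("participant_id", sort=False):
        labeled.append(ctx.label_trials(g, quits=config.quits_in_sequences))
    merged = pd.concat(labeled, ignore_index=True)

    # --- value tuning -----------------------------------------------------
    tuning_rows = []
    for pid, g in merged.groupby("participant_id", sort=False):
        ok = g[~g["excluded_latency"].fillna(True).astype(bool)]
        try:
            _, _, slope_lat = oz.value_tuning(ok["z_latency"], ok["value"], config.bin_width)
        except ValueError:
            slope_lat = float("nan")
        try:
            _, _, slope_rot = oz.value_tuning(ok["z_rotation"], ok["value"], config.bin_width)
        except ValueError:
            slope_rot = float("nan")
        tuning_rows.append((pid, slope_lat, slope_rot))
    tuning_df = pd.DataFrame(tuning_rows, columns=["participant_id", "slope_z_latency", "slope_z_rotation"])

    # --- context contrasts ------------------------------------------------
    contrasts = {}
    for cell_b in ("control1", "control2"):
        for metric in ("z_latency", "z_pause", "choice"):
            try:
                r = ctx.compare_contexts(merged, metric, "regret_class", "regret", cell_b)
                contrasts[f"regret_vs_{cell_b}:{metric}"] = r
            except ValueError as e:
                logger.info("contrast regret/%s on %s skipped: %s", cell_b, metric, e)
    try:
        r = ctx.compare_contexts(merged, "z_latency", "sequence_cell", "stay_skip", "skip_skip")
        contrasts["stay_skip_vs_skip_skip:z_latency"] = r
    except ValueError as e:
        logger.info("sequence contrast skipped: %s", e)

    # --- sunk cost --------------------------------------------------------
    comp_trials = sc.completion_trials(sessions)
    curves = sc.completion_curves(comp_trials, config.investments,
                                  n_bootstrap=config.n_bootstrap, seed=config.seed)
    try:
        bias_model = sc.fit_entry_bias_model(merged)
    except ValueError as e:
        logger.info("entry-bias model skipped: %s", e)
        bias_model = None

    return {
        "fits": fits_df, "trials": merged, "tuning": tuning_df,
        "contrasts": contrasts, "curves": curves, "bias_model": bias_model,
        "tallies": tallies,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline per the config; returns the report dict."""
    out = Path(config.out_dir)
    _setup_logging(out)
    # provenance hash covers the analysis settings, not where they are written
    cfg = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    stage = "setup"
    try:
        # --- input --------------------------------------------------------
        stage = "input"
        if config.input_path is not None:
            p = Path(config.input_path)
            if not p.exists():
                raise FileNotFoundError(f"input path not found: {p}")
            sessions = fio.read_sessions(p, format=config.input_format)
            logger.info("read %d sessions from %s", len(sessions), p)
        else:
            stage = "simulate"
            task = TaskConfig(**config.task)
            base = AgentConfig(**config.agent)
            prior = {k: tuple(v) if isinstance(v, list) else v
                     for k, v in config.agent_prior.items()}
            sessions = generate_cohort(config.n_participants, agent_prior=prior,
                                       seed=config.seed, task=task, base_agent=base)
            bundle = out / "bundle"
            clean = []
            for s in sessions:
                s2 = Session(s.participant_id, s.task_variant, s.version, s.setting,
                             s.trials, {k: v for k, v in s.covariates.items()
                                        if not k.startswith("_")}, s.magazine_events)
                clean.append(s2)
            fio.write_sessions(clean, bundle, format="csv_bundle")
            logger.info("simulated %d sessions -> %s", len(sessions), bundle)

        # --- analysis -----------------------------------------------------
        stage = "analysis"
        res = analyze_sessions(sessions, config)

        stage = "write"
        fio.write_tsv(res["fits"], out / "thresholds_participant.tsv", cfg)
        fio.write_tsv(res["trials"].drop(columns=["override"], errors="ignore"),
                      out / "trials.tsv", cfg)
        fio.write_tsv(res["tuning"], out / "value_tuning.tsv", cfg)

        crows = []
        for name, r in res["contrasts"].items():
            crows.append((name, r.cell_a, r.cell_b, r.mean_a, r.mean_b,
                          r.n_participants, r.wilcoxon_p))
        fio.write_tsv(pd.DataFrame(crows, columns=[
            "contrast", "cell_a", "cell_b", "mean_a", "mean_b", "n", "wilcoxon_p"]),
            out / "context_contrasts.tsv", cfg)

        curve_rows = []
        for T, c in res["curves"].items():
            for _, r in c.table.iterrows():
                curve_rows.append((T, r["remaining"], r["n_trials"], r["p_complete"],
                                   c.slope, c.slope_ci[0], c.slope_ci[1]))
        fio.write_tsv(pd.DataFrame(curve_rows, columns=[
            "invested_s", "remaining_s", "n_trials", "p_complete",
            "slope", "slope_lo", "slope_hi"]), out / "completion_curves.tsv", cfg)

        if res["bias_model"] is not None:
            bm = res["bias_model"]
            fio.write_tsv(pd.DataFrame({
                "term": bm.params.index, "coef": bm.params.values, "se": bm.se.values}),
                out / "entry_bias_model.tsv", cfg)

        # --- discounting (simulated responders when no survey data given) --
        stage = "discounting"
        bank = disc.load_item_bank(config.discounting_bank)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 77]))
        drows = []
        for s in sessions:
            k_true = float(rng.lognormal(math.log(0.0046), 2.0))
            resp = generate_survey_responses(k_true, bank, noise=0.05,
                                             seed=rng.integers(2**31 - 1))
            r = disc.score_survey(resp, bank)
            drows.append((s.participant_id, k_true, r.k_overall, r.log10_k, r.consistency))
        disc_df = pd.DataFrame(drows, columns=[
            "participant_id", "k_true", "k_fit", "log10_k", "consistency"])
        fio.write_tsv(disc_df, out / "discounting.tsv", cfg)

        # --- report -------------------------------------------------------
        stage = "report"
        normal_frac = float((res["fits"]["pattern"] == "normal").mean())
        slopes = res["tuning"]["slope_z_latency"]
        report = {
            "n_sessions": len(sessions),
            "n_trials": int(res["tallies"]["n_trials"]),
            "exclusions": res["tallies"],
            "pattern_counts": res["fits"]["pattern"].value_counts().to_dict(),
            "frac_normal_pattern": normal_frac,
            "mean_threshold_s": float(res["fits"].loc[
                res["fits"]["pattern"] == "normal", "threshold"].mean()),
            "mean_slope_z_latency": float(np.nanmean(slopes)),
            "completion_slopes": {str(T): c.slope for T, c in res["curves"].items()},
            "entry_bias_coef": (float(res["bias_model"].params["entry_bias"])
                                if res["bias_model"] is not None else None),
            "mean_log10_k": float(disc_df["log10_k"].mean()),
            "config_hash": fio.config_hash(cfg),
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        logger.info("pipeline complete: %s", out / "report.json")
        return report
    except Exception as e:
        logger.error("pipeline failed at stage %r: %s", stage, e)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e


# ---------------------------------------------------------------------------
# Test fixtures


def _flat_trajectory(t0, n, heading=90.0, dt=50, speed=0.02):
    t = t0 + np.arange(n) * dt
    x = np.arange(n) * speed
    return Trajectory(t.astype(float), x, np.zeros(n), np.full(n, heading))


def make_fixtures(seed: int = 0, out_dir="fixtures") -> dict:
    """Write the small deterministic datasets used by the test suite.

    * ``cohort/`` — a 3-participant simulated bundle.
    * ``context_fixture.jsonl`` — an 8-trial session covering every
      (previous decision x previous value x current value) combination for
      regret/sequence labeling.
    * ``exclusion_fixture.jsonl`` — known counts of over-limit latencies and
      rotations.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    cohort = generate_cohort(3, seed=seed, task=TaskConfig(max_offers=24))
    for s in cohort:
        s.covariates.pop("_true_agent", None)
    paths["cohort"] = str(fio.write_sessions(cohort, out / "cohort", format="csv_bundle"))

    # Context fixture: a step agent with threshold 10 s for every category.
    # Sequence of (delay, decision): values are 10 - delay under a LOO fit on
    # perfectly consistent side choices; delays chosen so every trial's value
    # sign and decision are unambiguous.
    spec = [(3, "stay"), (15, "skip"), (20, "skip"), (5, "stay"),
            (25, "skip"), (18, "quit"), (22, "skip"), (4, "stay")]
    trials = []
    clock = 0
    for i, (delay, decision) in enumerate(spec):
        t_offer = clock
        t_exit = t_offer + 2000
        tds = t_exit + 500 if decision in ("stay", "quit") else None
        if decision == "stay":
            tqc = tds + delay * 1000
        elif decision == "quit":
            tqc = tds + 1000
        else:
            tqc = None
        trials.append(TrialRecord(
            trial_index=i, zone_id=i % 4, category=f"cat{i % 4}",
            offered_delay=float(delay), decision=decision,
            t_offer=t_offer, t_exit=t_exit, t_delay_start=tds,
            t_quit_or_complete=tqc, entry_position=0.0,
            trajectory=_flat_trajectory(t_offer, 10)))
        clock = (tqc or t_exit) + 4000
    ctx_sess = Session("ctxfix", version=2, trials=trials)
    paths["context"] = str(fio.write_sessions([ctx_sess], out / "context_fixture.jsonl",
                                              format="jsonl"))

    # Exclusion fixture: 10 trials; 2 with latency > 15 s, 3 with rotation
    # > 360 deg (one trial has both).
    trials = []
    clock = 0
    slow = {3, 7}
    spinny = {1, 5, 7}
    for i in range(10):
        latency = 16_000 if i in slow else 3_000
        n = latency // 50
        t = clock + np.arange(n) * 50.0
        x = np.arange(n) * 0.01
        if i in spinny:
            heading = (90.0 + np.arange(n) * (500.0 / (n - 1))) % 360.0
        else:
            heading = np.full(n, 90.0)
        trials.append(TrialRecord(
            trial_index=i, zone_id=i % 4, category=f"cat{i % 4}",
            offered_delay=10.0, decision="skip",
            t_offer=clock, t_exit=int(t[-1]),
            trajectory=Trajectory(t, x, np.zeros(n), heading)))
        clock = int(t[-1]) + 4000
    exc_sess = Session("excfix", version=2, trials=trials)
    paths["exclusion"] = str(fio.write_sessions([exc_sess], out / "exclusion_fixture.jsonl",
                                                format="jsonl"))
    return paths
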