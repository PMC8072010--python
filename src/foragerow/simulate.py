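"""Synthetic foraging agents with known ground truth.

The generator emulates the statistical structure the analyses assume, so
every estimator in the pipeline can be checked by parameter recovery:

* Stay/skip choices follow a logistic rule on (threshold - delay) with
  temperature tau (tau = 0 gives a deterministic step agent). Response
  styles per category: ``normal``, ``reversed`` (stays for long delays),
  ``full_stay`` and ``full_skip`` (delay-ignoring, deterministic).
* Entry position is drawn Normal(0, entry_bias_sd) as a fraction of hallway
  width (clipped to [-0.5, 0.5]); it shifts the stay log-odds by
  -bias_choice_coef * entry_position, so rightward (exit-side) entries make
  acceptance less likely.
* Offer-zone trajectories are a straight pass from the entry point to the
  chosen exit at constant speed (1.25 s to cross the full hallway width),
  sampled at 20 Hz, with Poisson(g(|value|)) inserted reorientation
  episodes, where g(v) = deliberation_gain * exp(-v / deliberation_width)
  and value uses the agent's *true* threshold. Each episode is an
  out-and-back heading excursion of 60-120 deg, optionally followed by a
  200-800 ms stationary pause — the VTE signature, intensifying near
  threshold.
* Quits follow a per-second hazard h(t) = quit_hazard_base /
  (1 + sunk_cost_strength * t_invested): sunk_cost_strength = 0 gives a
  memoryless (geometric-survival) quitter, larger values give hazard that
  decays with time already invested.

Defaults describe a realistic participant: heterogeneous per-category
thresholds spanning the 3-29 s delay range, moderate choice noise (1 s),
a near-threshold VTE boost, and a quit hazard putting quits near 0.7%
of started delays, the rarity observed in human cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .session import Session, Trajectory, TrialRecord

__all__ = [
    "AgentConfig",
    "TaskConfig",
    "ConfigError",
    "generate_session",
    "generate_cohort",
    "generate_survey_responses",
    "CATEGORIES",
]

CATEGORIES = ("kittens", "accidents", "dancing", "landscapes")
STYLES = ("normal", "reversed", "full_stay", "full_skip")


class ConfigError(ValueError):
    """Impossible simulator configuration."""


@dataclass
class AgentConfig:
    """Ground-truth parameters of one simulated participant.

    thresholds : per-category stay/skip threshold theta_c, seconds.
    choice_temperature : tau, s; softness of the choice rule (0 = step agent).
    response_style : per-category style, see module docstring.
    entry_bias_sd : SD of entry position, fraction of hallway width.
    bias_choice_coef : effect of entry position on stay log-odds (beta_bias).
    deliberation_gain / deliberation_width : near-threshold VTE boost
        g(|value|) = gain * exp(-|value| / width); episodes per trial.
    base_latency : ms of forward travel through the offer zone.
    quit_hazard_base : per-second quit hazard once the delay has started.
    sunk_cost_strength : >= 0; hazard decays as 1/(1 + strength * t_invested).
    """

    thresholds: tuple = (9.0, 14.0, 19.0, 24.0)
    choice_temperature: float = 1.0
    response_style: tuple = ("normal",) * 4
    entry_bias_sd: float = 0.15
    bias_choice_coef: float = 1.0
    deliberation_gain: float = 1.5
    deliberation_width: float = 3.0
    base_latency: float = 2000.0
    quit_hazard_base: float = 0.0015  # ~0.7% of started delays end in a quit
    sunk_cost_strength: float = 0.5
    rng_seed: Optional[int] = None

    def validate(self, task: "TaskConfig") -> None:
        if len(self.thresholds) != 4 or len(self.response_style) != 4:
            raise ConfigError("thresholds and response_style must have 4 entries")
        for s in self.response_style:
            if s not in STYLES:
                raise ConfigError(f"unknown response style {s!r}")
        for name in ("choice_temperature", "entry_bias_sd", "deliberation_gain",
                     "deliberation_width", "base_latency", "quit_hazard_base",
                     "sunk_cost_strength"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        lo, hi = min(task.delay_set), max(task.delay_set)
        for th, style in zip(self.thresholds, self.response_style):
            if style in ("normal", "reversed") and not (lo <= th <= hi):
                raise ConfigError(
                    f"threshold {th} outside offered delay range [{lo}, {hi}] for style {style}")


@dataclass
class TaskConfig:
    """Task-side parameters (shared across a cohort)."""

    delay_set: tuple = tuple(range(3, 30))  # 3-29 s
    draws_without_replacement: bool = True
    n_circuits: Optional[int] = None
    max_offers: Optional[int] = None
    version: int = 4
    hallway_width: float = 1.0
    crossing_time: float = 1.25  # s to cross the full hallway width
    sample_hz: float = 20.0
    include_trajectories: bool = True
    travel_ms: int = 4000  # between-zone travel
    reward_ms: int = 4000  # video / candy consumption after a completed delay

    def validate(self) -> None:
        if not self.delay_set:
            raise ConfigError("delay_set is empty")
        if self.crossing_time <= 0 or self.hallway_width <= 0:
            raise ConfigError("crossing_time and hallway_width must be positive")
        if not 1 <= self.version <= 4:
            raise ConfigError("version must be 1-4")
        if self.sample_hz <= 0:
            raise ConfigError("sample_hz must be positive")


def _vte_gain(abs_value: float, agent: AgentConfig) -> float:
    if agent.deliberation_width == 0:
        return agent.deliberation_gain if abs_value == 0 else 0.0
    return agent.deliberation_gain * math.exp(-abs_value / agent.deliberation_width)


def _episode_blocks(rng, n_ep: int, base_heading: float, dt_ms: float):
    """Heading/pause blocks for VTE episodes. Returns (headings, pause_flags)."""
    heads = []
    for _ in range(n_ep):
        amp = rng.uniform(60.0, 120.0)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        # out-and-back excursion over 8 samples, ending on the base heading
        frac = np.array([0.25, 0.5, 0.75, 1.0, 0.75, 0.5, 0.25, 0.0])
        h = base_heading + sign * amp * frac
        if rng.random() < 0.5:
            n_pause = int(rng.integers(4, 17))  # 200-800 ms at 20 Hz
            h = np.concatenate([h, np.full(n_pause, base_heading)])
        heads.append(h)
    return heads


def _make_trajectory(rng, agent, task, entry_frac, stay, abs_value, t_start):
    """Straight entry->exit pass with inserted reorientation episodes.

    Returns (Trajectory or None, latency_ms, n_episodes).
    """
    dt = 1000.0 / task.sample_hz
    W = task.hallway_width
    y0 = entry_frac * W
    y1 = (-0.5 if stay else 0.5) * W
    lateral_ms = abs(y1 - y0) / W * task.crossing_time * 1000.0
    move_ms = agent.base_latency + lateral_ms
    n_move = max(2, int(round(move_ms / dt)))

    n_ep = int(rng.poisson(_vte_gain(abs_value, agent)))
    ep_heads = _episode_blocks(rng, n_ep, 0.0, dt) if n_ep else []

    if not task.include_trajectories:
        ep_samples = sum(len(h) for h in ep_heads)
        latency = (n_move + ep_samples) * dt
        return None, latency, n_ep

    # Base pass: x runs the zone length (1 track unit), y drifts to the exit.
    xs = np.linspace(0.0, 1.0, n_move + 1)
    ys = np.linspace(y0, y1, n_move + 1)
    base_heading = math.degrees(math.atan2(ys[-1] - ys[0], 1.0)) % 360.0
    heads = np.full(n_move + 1, base_heading)

    if n_ep:
        cuts = np.sort(rng.integers(1, n_move, size=n_ep))
        seg_x, seg_y, seg_h = [], [], []
        prev = 0
        for cut, eh in zip(cuts, ep_heads):
            seg_x.append(xs[prev:cut]); seg_y.append(ys[prev:cut]); seg_h.append(heads[prev:cut])
            seg_x.append(np.full(len(eh), xs[cut])); seg_y.append(np.full(len(eh), ys[cut]))
            seg_h.append((base_heading + (eh - 0.0)) % 360.0)
            prev = cut
        seg_x.append(xs[prev:]); seg_y.append(ys[prev:]); seg_h.append(heads[prev:])
        xs = np.concatenate(seg_x); ys = np.concatenate(seg_y); hs = np.concatenate(seg_h)
    else:
        hs = heads

    n = len(xs)
    t = t_start + np.arange(n) * dt
    t = np.round(t).astype(float)
    latency = (n - 1) * dt
    return Trajectory(t, xs, ys, hs % 360.0), latency, n_ep


def _simulate_quit(rng, agent: AgentConfig, delay_s: float):
    """Per-second hazard walk. Returns waited seconds, or None if completed."""
    q0 = agent.quit_hazard_base
    if q0 <= 0:
        return None
    s = agent.sunk_cost_strength
    for t in range(int(delay_s)):
        if rng.random() < q0 / (1.0 + s * t):
            return float(t)
    return None


def generate_session(
    agent: AgentConfig,
    task: TaskConfig,
    seed=None,
    participant_id: str = "sim",
    covariates: Optional[dict] = None,
) -> Session:
    """Simulate one session. Deterministic given (configs, seed)."""
    task.validate()
    agent.validate(task)
    rng = np.random.default_rng(agent.rng_seed if seed is None else seed)

    n_delays = len(task.delay_set)
    if task.draws_without_replacement:
        stacks = [rng.permutation(task.delay_set) for _ in range(4)]
        n_offers = 4 * n_delays
    else:
        n_offers = 4 * n_delays
        stacks = [rng.choice(task.delay_set, size=n_delays, replace=True) for _ in range(4)]
    if task.n_circuits is not None:
        n_offers = min(n_offers, 4 * task.n_circuits)
    if task.max_offers is not None:
        n_offers = min(n_offers, task.max_offers)

    sess = Session(
        participant_id=participant_id,
        task_variant="movie",
        version=task.version,
        setting="in_person",
        covariates=dict(covariates or {}),
    )
    clock = 0
    tau = agent.choice_temperature
    for i in range(n_offers):
        zone = i % 4
        circuit = i // 4
        if circuit >= n_delays:
            break
        delay = float(stacks[zone][circuit])
        theta = agent.thresholds[zone]
        style = agent.response_style[zone]

        entry = float(np.clip(rng.normal(0.0, agent.entry_bias_sd), -0.5, 0.5))
        if style == "full_stay":
            stay = True
        elif style == "full_skip":
            stay = False
        else:
            drive = (theta - delay) if style == "normal" else (delay - theta)
            if tau == 0:
                stay = drive > 0
            else:
                logit = drive / tau - agent.bias_choice_coef * entry
                stay = rng.random() < expit(logit)

        abs_value = abs(theta - delay)
        t_offer = clock
        if task.version >= 3:
            reaction = int(round(rng.lognormal(math.log(500.0), 0.3)))
            t_move = t_offer + reaction
        else:
            t_move = None
        move_start = t_move if t_move is not None else t_offer
        traj, latency, _ = _make_trajectory(rng, agent, task, entry, stay, abs_value, move_start)
        t_exit = int(move_start + round(latency))

        decision = "stay" if stay else "skip"
        t_delay_start = None
        t_quit_or_complete = None
        if stay:
            t_delay_start = t_exit + 500
            waited = _simulate_quit(rng, agent, delay)
            if waited is not None:
                decision = "quit"
                t_quit_or_complete = int(t_delay_start + waited * 1000)
                clock = t_quit_or_complete + task.travel_ms
            else:
                t_quit_or_complete = int(t_delay_start + delay * 1000)
                clock = t_quit_or_complete + task.reward_ms + task.travel_ms
        else:
            clock = t_exit + task.travel_ms

        sess.trials.append(TrialRecord(
            trial_index=i, zone_id=zone, category=CATEGORIES[zone],
            offered_delay=delay, decision=decision,
            t_offer=t_offer, t_exit=t_exit, t_move=t_move,
            t_delay_start=t_delay_start, t_quit_or_complete=t_quit_or_complete,
            entry_position=entry, trajectory=traj,
        ))
    return sess


# ---------------------------------------------------------------------------
# Cohorts


def _draw_field(rng, spec):
    """Draw a value from a prior spec: constant, ("uniform", lo, hi),
    ("normal", m, sd), ("lognormal", mu, sigma), ("choice", [options]) or a
    callable rng -> value."""
    if callable(spec):
        return spec(rng)
    if isinstance(spec, tuple) and spec and isinstance(spec[0], str):
        kind = spec[0]
        if kind == "uniform":
            return float(rng.uniform(spec[1], spec[2]))
        if kind == "normal":
            return float(rng.normal(spec[1], spec[2]))
        if kind == "lognormal":
            return float(rng.lognormal(spec[1], spec[2]))
        if kind == "choice":
            return spec[1][rng.integers(len(spec[1]))]
        raise ConfigError(f"unknown prior kind {kind!r}")
    return spec


def generate_cohort(
    n_participants: int,
    agent_prior: Optional[dict] = None,
    covariate_effects: Optional[Sequence[tuple]] = None,
    seed=None,
    task: Optional[TaskConfig] = None,
    base_agent: Optional[AgentConfig] = None,
) -> list[Session]:
    """Simulate a cohort with participant-level parameters drawn from a prior.

    ``agent_prior`` maps :class:`AgentConfig` field names to prior specs (see
    ``_draw_field``); a field named ``threshold`` (singular) draws one value
    per category independently. ``covariate_effects`` is a sequence of
    ``(covariate, level, field, delta)`` tuples adding ``delta`` to an agent
    field for participants with that covariate level — e.g. a subgroup with
    reduced entry-bias sensitivity. Randomness is split per participant with
    a spawning scheme, so adding participants never perturbs earlier ones.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    task = task or TaskConfig()
    base = base_agent or AgentConfig()
    prior = dict(agent_prior or {})
    children = np.random.SeedSequence(seed).spawn(n_participants)

    import warnings as _warnings
    for name, spec in prior.items():
        if not callable(spec) and not (isinstance(spec, tuple) and spec and isinstance(spec[0], str)):
            _warnings.warn(f"prior for {name!r} is a constant; recovery tests on it are degenerate")

    sessions = []
    for p, child in enumerate(children):
        rng = np.random.default_rng(child)
        fields = {}
        for name, spec in prior.items():
            if name == "threshold":
                fields["thresholds"] = tuple(_draw_field(rng, spec) for _ in range(4))
            else:
                fields[name] = _draw_field(rng, spec)
        cov = {
            "gender": "female" if rng.random() < 0.5 else "male",
            "bmi_group": "<25" if rng.random() < 0.5 else ">=25",
            "smoker": "yes" if rng.random() < 0.25 else "no",
            "age": int(rng.integers(18, 65)),
        }
        agent = replace(base, **fields)
        for (cname, level, fname, delta) in covariate_effects or []:
            if cov.get(cname) == level:
                agent = replace(agent, **{fname: getattr(agent, fname) + delta})
        sess = generate_session(agent, task, seed=rng.integers(2**31 - 1),
                                participant_id=f"sim{p:04d}", covariates=cov)
        sess.covariates["_true_agent"] = agent
        sessions.append(sess)
    return sessions


# ---------------------------------------------------------------------------
# Survey responders


def generate_survey_responses(k_true: float, items: pd.DataFrame, noise: float = 0.0, seed=None) -> np.ndarray:
    """Binary responses of a hyperbolic discounter (1 = delayed, 0 = immediate).

    The responder chooses the delayed option iff
    delayed / (1 + k_true * delay) > immediate, i.e. iff the item's implied k
    exceeds k_true; each response is then flipped with probability ``noise``.
    """
    required = {"immediate_amount", "delayed_amount", "delay_days"}
    if not required.issubset(items.columns):
        raise ValueError(f"item bank missing columns {sorted(required - set(items.columns))}")
    imm = items["immediate_amount"].to_numpy(float)
    dly = items["delayed_amount"].to_numpy(float)
    days = items["delay_days"].to_numpy(float)
    if np.isinf(k_true):
        resp = np.zeros(len(items), int)
    else:
        resp = (dly / (1.0 + k_true * days) > imm).astype(int)
    if noise > 0:
        rng = np.random.default_rng(seed)
        flip = rng.random(len(resp)) < noise
        resp = np.where(flip, 1 - resp, resp)
    return resp
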