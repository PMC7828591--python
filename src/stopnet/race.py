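"""Independent horse-race simulation of the stop-signal task (SST).

The SST presents a choice ("go") stimulus on every trial; on a minority of
trials a stop signal follows after a stop-signal delay (SSD) and the
participant must withhold the response.  Under the independent horse-race
model the go process and the stop process race: the response is emitted iff
the go process finishes before the stop process (stop-signal onset + stop
latency).  A staircase adjusts the SSD after every stop trial — up by one
step after a successful stop (harder), down after a failed stop (easier) —
so that the probability of responding on a stop trial converges to 0.5.

Go finishing times follow an ex-Gaussian law (Gaussian mu/sigma convolved
with an exponential tau), the standard empirical RT distribution.  The stop
latency may be constant or ex-Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "RaceModelParams",
    "TrialLog",
    "sample_ex_gaussian",
    "simulate_session",
]


class ParameterError(ValueError):
    """Invalid task or race-model parameter."""


@dataclass(frozen=True)
class TaskConfig:
    """Stop-signal task design.

    Defaults mirror a three-block tracking SST: 3 test blocks of 80 trials
    (30% stop trials, i.e. 24 per block), initial SSD 500 ms, 50 ms
    staircase step, and a 1000 ms go-stimulus display duration.
    ``iti_range`` and ``practice_trials`` are design metadata; practice
    trials are simulated and flagged but excluded from all estimators.
    """

    n_test_blocks: int = 3
    trials_per_block: int = 80
    stop_proportion: float = 0.30
    ssd_initial: float = 500.0
    ssd_step: float = 50.0
    go_max_duration: float = 1000.0
    iti_range: tuple[float, float] = (1100.0, 1900.0)
    practice_trials: int = 40

    def __post_init__(self) -> None:
        if not 0.0 < self.stop_proportion < 1.0:
            raise ParameterError("stop_proportion must lie in (0, 1)")
        if self.ssd_step <= 0:
            raise ParameterError("ssd_step must be positive")
        if self.ssd_initial < 0:
            raise ParameterError("ssd_initial must be nonnegative")
        if self.n_test_blocks < 1 or self.trials_per_block < 1:
            raise ParameterError("need at least one test block and one trial")

    @property
    def stop_trials_per_block(self) -> int:
        return round(self.trials_per_block * self.stop_proportion)

    @property
    def response_window(self) -> float:
        # The go stimulus disappears after go_max_duration, but responses
        # landing in the inter-trial blank are still collected (observed
        # go-RT ranges exceed the display duration); later finishes are
        # omissions.
        return self.go_max_duration + self.iti_range[1]

    @property
    def ssd_max(self) -> float:
        # Clamp bound for the staircase; prevents unbounded drift when the
        # go law is degenerate (e.g. all omissions).
        return self.go_max_duration + 1000.0


@dataclass(frozen=True)
class RaceModelParams:
    """Generative parameters of the racing processes.

    Go RTs are ex-Gaussian(go_mu, go_sigma, go_tau); the ex-Gaussian mean is
    mu + tau.  The stop latency is constant when stop_sigma == stop_tau == 0.
    Defaults give a go-RT mean of 680 ms with heavy right skew and a 160 ms
    stop latency — adolescent-typical tracking-SST performance.
    """

    go_mu: float = 480.0
    go_sigma: float = 90.0
    go_tau: float = 200.0
    stop_mu: float = 160.0
    stop_sigma: float = 0.0
    stop_tau: float = 0.0
    p_go_omission: float = 0.005
    p_choice_error: float = 0.05
    trigger_failure_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("go_sigma", "go_tau", "stop_sigma", "stop_tau"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        for name in ("p_go_omission", "p_choice_error", "trigger_failure_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")

    @property
    def mean_go_rt(self) -> float:
        return self.go_mu + self.go_tau


#: Column order used for CSV round-trips.
TRIAL_COLUMNS = [
    "block",
    "trial_type",
    "ssd_ms",
    "responded",
    "rt_ms",
    "correct",
    "is_practice",
    "go_finish_ms",
    "stop_finish_ms",
]


@dataclass
class TrialLog:
    """Trial-level record of one simulated (or recorded) SST session.

    ``trials`` holds one row per trial with columns: block (practice block
    is -1), trial_type ('go' | 'stop'), ssd_ms (NaN on go trials),
    responded, rt_ms (NaN when no response), correct, is_practice, and the
    latent finishing times go_finish_ms / stop_finish_ms retained so that
    race outcomes can be re-derived independently of the simulator.
    """

    trials: pd.DataFrame
    seed: int | None = None
    task: TaskConfig | None = None
    params: RaceModelParams | None = None

    @property
    def test_trials(self) -> pd.DataFrame:
        return self.trials.loc[~self.trials["is_practice"]]

    def to_csv(self, path) -> None:
        header = f"# stopnet trial log; seed={self.seed}\n"
        with open(path, "w") as fh:
            fh.write(header)
            self.trials.to_csv(fh, index=False, columns=TRIAL_COLUMNS)

    @classmethod
    def from_csv(cls, path) -> "TrialLog":
        df = pd.read_csv(path, comment="#")
        df["trial_type"] = df["trial_type"].astype(str)
        return cls(trials=df)


def sample_ex_gaussian(mu, sigma, tau, n, seed):
    """Draw ``n`` ex-Gaussian variates, truncated below at zero.

    The ex-Gaussian is a Gaussian(mu, sigma) plus an independent
    Exponential(tau); its mean is mu + tau and its variance sigma^2 + tau^2.
    Negative draws (possible for small mu) are clipped to 0.

    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    if sigma < 0 or tau < 0:
        raise ParameterError("sigma and tau must be nonnegative")
    if n < 1:
        raise ParameterError("n must be at least 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    draws = rng.normal(mu, sigma, size=n) if sigma > 0 else np.full(n, float(mu))
    if tau > 0:
        draws = draws + rng.exponential(tau, size=n)
    return np.maximum(draws, 0.0)


def _stop_trial_layout(task: TaskConfig, n_trials: int, rng: np.random.Generator) -> np.ndarray:
    n_stop = round(n_trials * task.stop_proportion)
    is_stop = np.zeros(n_trials, dtype=bool)
    is_stop[:n_stop] = True
    rng.shuffle(is_stop)
    return is_stop


def simulate_session(params: RaceModelParams, task: TaskConfig, seed: int) -> TrialLog:
    """Simulate one full SST session under the horse-race model.

    Per stop trial the response is inhibited iff the stop process finishes
    strictly before the go process (SSD + stop latency < go finishing time;
    ties go to the response) and no trigger failure occurred.  After a
    successful stop the SSD increases by one step, after a failed stop it
    decreases by one step; the SSD is clamped to [0, go_max_duration + 1000]
    and carries across blocks (including the practice block).

    Go omissions occur spontaneously at ``p_go_omission`` and additionally
    whenever the go process finishes after the response window (stimulus
    display plus the inter-trial blank).  Choice
    errors flip the correctness label of responded trials at
    ``p_choice_error``, independently of the race.
    """
    rng = np.random.default_rng(seed)
    blocks: list[tuple[int, int, bool]] = []
    if task.practice_trials > 0:
        blocks.append((-1, task.practice_trials, True))
    for b in range(task.n_test_blocks):
        blocks.append((b, task.trials_per_block, False))

    ssd = float(task.ssd_initial)
    rows: list[dict] = []
    for block_idx, n_trials, is_practice in blocks:
        is_stop = _stop_trial_layout(task, n_trials, rng)
        go_finish = sample_ex_gaussian(params.go_mu, params.go_sigma, params.go_tau, n_trials, rng)
        stop_latency = sample_ex_gaussian(
            params.stop_mu, params.stop_sigma, params.stop_tau, n_trials, rng
        )
        spont_omit = rng.random(n_trials) < params.p_go_omission
        trig_fail = rng.random(n_trials) < params.trigger_failure_rate
        choice_err = rng.random(n_trials) < params.p_choice_error

        for t in range(n_trials):
            go_responds = (not spont_omit[t]) and go_finish[t] <= task.response_window
            if is_stop[t]:
                finish_stop = ssd + stop_latency[t]
                stop_wins = (not trig_fail[t]) and finish_stop < go_finish[t]
                responded = go_responds and not stop_wins
                rows.append(
                    {
                        "block": block_idx,
                        "trial_type": "stop",
                        "ssd_ms": ssd,
                        "responded": responded,
                        "rt_ms": go_finish[t] if responded else np.nan,
                        "correct": (not choice_err[t]) if responded else False,
                        "is_practice": is_practice,
                        "go_finish_ms": go_finish[t],
                        "stop_finish_ms": finish_stop,
                    }
                )
                ssd = ssd + task.ssd_step if not responded else ssd - task.ssd_step
                ssd = min(max(ssd, 0.0), task.ssd_max)
            else:
                rows.append(
                    {
                        "block": block_idx,
                        "trial_type": "go",
                        "ssd_ms": np.nan,
                        "responded": go_responds,
                        "rt_ms": go_finish[t] if go_responds else np.nan,
                        "correct": go_responds and not choice_err[t],
                        "is_practice": is_practice,
                        "go_finish_ms": go_finish[t],
                        "stop_finish_ms": np.nan,
                    }
                )

    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return TrialLog(trials=trials, seed=seed, task=task, params=params)
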