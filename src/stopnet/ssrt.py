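"""SSRT estimation and race-model validity screening for SST trial logs.

The stop-signal reaction time (SSRT) is the latent latency of the stop
process.  The integration method estimates the finishing time of the stop
process as the nth RT of the go-RT distribution, where
n = round(N * p(respond|stop)); go omissions are replaced by the
participant's maximum RT before taking the nth value, and all responded go
trials (choice errors and premature responses included) enter the
distribution.  SSRT = nth RT - mean SSD.  The cruder mean method uses
SSRT = mean go RT - mean SSD and is positively biased for right-skewed
go-RT distributions under SSD tracking.

Estimates are only meaningful when the horse-race assumptions hold;
``check_race_assumptions`` screens sessions the way methodological
guidelines recommend: p(respond|stop) must lie in [0.25, 0.75] and the mean
signal-respond RT must be strictly below the mean go RT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .race import TrialLog

__all__ = [
    "BehavioralSummary",
    "SSRTEstimate",
    "ValidityReport",
    "InsufficientTrialsError",
    "RaceModelViolationError",
    "summarize_behavior",
    "check_race_assumptions",
    "estimate_ssrt_integration",
    "estimate_ssrt_mean",
]


class InsufficientTrialsError(ValueError):
    """The log lacks the trials required for a summary or estimate."""


class RaceModelViolationError(ValueError):
    """SSRT requested on a session that fails the validity screening."""

    def __init__(self, report: "ValidityReport"):
        self.report = report
        super().__init__(f"race-model assumptions violated: {'; '.join(report.reasons)}")


@dataclass(frozen=True)
class BehavioralSummary:
    p_go_omission: float
    p_choice_error: float
    mean_go_rt: float
    sd_go_rt: float
    nth_rt: float
    p_respond_stop: float
    mean_ssd: float
    mean_signal_respond_rt: float
    n_go: int
    n_stop: int


@dataclass(frozen=True)
class SSRTEstimate:
    method: str  # 'integration' | 'mean'
    ssrt: float
    finishing_time: float  # nth RT (integration) or mean go RT (mean)
    mean_ssd: float
    n_index: int | None = None  # integration only


@dataclass(frozen=True)
class ValidityReport:
    p_respond_stop: float
    signal_respond_vs_go_ok: bool | None  # None when indeterminate
    p_in_bounds: bool
    valid: bool
    reasons: tuple[str, ...] = ()


def _test_frames(log: TrialLog | pd.DataFrame):
    trials = log.test_trials if isinstance(log, TrialLog) else log
    go = trials[trials["trial_type"] == "go"]
    stop = trials[trials["trial_type"] == "stop"]
    return go, stop


def _require(go: pd.DataFrame, stop: pd.DataFrame) -> None:
    if len(go) == 0:
        raise InsufficientTrialsError("no go test trials in log")
    if len(stop) == 0:
        raise InsufficientTrialsError("no stop test trials in log")


def _augmented_go_rts(go: pd.DataFrame, min_rt: float) -> np.ndarray:
    """All responded-go RTs plus one max-RT entry per go omission, sorted."""
    rts = go.loc[go["responded"], "rt_ms"].to_numpy(dtype=float)
    rts = rts[rts > min_rt] if min_rt > 0 else rts
    if rts.size == 0:
        raise InsufficientTrialsError("no responded go trials")
    n_omissions = int((~go["responded"]).sum())
    augmented = np.concatenate([rts, np.full(n_omissions, rts.max())])
    return np.sort(augmented)


def summarize_behavior(log: TrialLog | pd.DataFrame) -> BehavioralSummary:
    """Behavioral summary of a session's test trials.

    Probabilities are computed over test trials only; go-RT moments over
    responded go trials; the signal-respond RT over responded stop trials
    (NaN when no stop trial drew a response).
    """
    go, stop = _test_frames(log)
    _require(go, stop)
    responded_go = go[go["responded"]]
    if len(responded_go) == 0:
        raise InsufficientTrialsError("no responded go trials")
    go_rts = responded_go["rt_ms"].to_numpy(dtype=float)
    p_respond_stop = float(stop["responded"].mean())
    signal_rts = stop.loc[stop["responded"], "rt_ms"].to_numpy(dtype=float)

    augmented = _augmented_go_rts(go, 0.0)
    n_index = _nth_index(len(augmented), p_respond_stop)

    return BehavioralSummary(
        p_go_omission=float((~go["responded"]).mean()),
        p_choice_error=float((~responded_go["correct"]).mean()),
        mean_go_rt=float(go_rts.mean()),
        sd_go_rt=float(go_rts.std(ddof=1)) if len(go_rts) > 1 else 0.0,
        nth_rt=float(augmented[n_index - 1]),
        p_respond_stop=p_respond_stop,
        mean_ssd=float(stop["ssd_ms"].mean()),
        mean_signal_respond_rt=float(signal_rts.mean()) if signal_rts.size else float("nan"),
        n_go=len(go),
        n_stop=len(stop),
    )


def check_race_assumptions(
    log: TrialLog | pd.DataFrame,
    p_low: float = 0.25,
    p_high: float = 0.75,
) -> ValidityReport:
    """Screen a session for horse-race validity.

    Valid iff p_low <= p(respond|stop) <= p_high and the mean RT on
    unsuccessful stop trials is strictly below the mean go RT.  With no
    responded stop trials the latter check is indeterminate and the session
    is flagged invalid.
    """
    go, stop = _test_frames(log)
    _require(go, stop)
    p = float(stop["responded"].mean())
    reasons: list[str] = []
    p_ok = p_low <= p <= p_high
    if not p_ok:
        reasons.append(f"p(respond|stop)={p:.3f} outside [{p_low}, {p_high}]")

    signal_rts = stop.loc[stop["responded"], "rt_ms"]
    go_rts = go.loc[go["responded"], "rt_ms"]
    if len(signal_rts) == 0 or len(go_rts) == 0:
        sr_ok: bool | None = None
        reasons.append("signal-respond vs go RT check indeterminate (no responded trials)")
    else:
        sr_ok = float(signal_rts.mean()) < float(go_rts.mean())
        if not sr_ok:
            reasons.append(
                f"mean signal-respond RT {signal_rts.mean():.1f} not below "
                f"mean go RT {go_rts.mean():.1f}"
            )

    valid = p_ok and sr_ok is True
    return ValidityReport(
        p_respond_stop=p,
        signal_respond_vs_go_ok=sr_ok,
        p_in_bounds=p_ok,
        valid=valid,
        reasons=tuple(reasons),
    )


def _nth_index(n_augmented: int, p_respond_stop: float) -> int:
    """n = round(N * p), half away from zero, clamped to [1, N]."""
    raw = n_augmented * p_respond_stop
    n = int(np.floor(raw + 0.5))
    return min(max(n, 1), n_augmented)


def _validated(log, override_validity):
    go, stop = _test_frames(log)
    _require(go, stop)
    if not override_validity:
        report = check_race_assumptions(log)
        if not report.valid:
            raise RaceModelViolationError(report)
    return go, stop


def estimate_ssrt_integration(
    log: TrialLog | pd.DataFrame,
    override_validity: bool = False,
    min_rt: float = 0.0,
) -> SSRTEstimate:
    """Integration-method SSRT with go-omission replacement.

    The go-RT distribution is augmented with one maximum-RT entry per go
    omission; n = round(N_augmented * p(respond|stop)) (half away from
    zero, clamped to [1, N]); SSRT = nth smallest augmented RT minus the
    mean SSD over all stop test trials.

    ``min_rt`` optionally drops implausibly fast responses; by default every
    responded RT counts, premature and erroneous responses included.
    """
    go, stop = _validated(log, override_validity)
    augmented = _augmented_go_rts(go, min_rt)
    p = float(stop["responded"].mean())
    n = _nth_index(len(augmented), p)
    nth_rt = float(augmented[n - 1])
    mean_ssd = float(stop["ssd_ms"].mean())
    return SSRTEstimate(
        method="integration",
        ssrt=nth_rt - mean_ssd,
        finishing_time=nth_rt,
        mean_ssd=mean_ssd,
        n_index=n,
    )


def estimate_ssrt_mean(
    log: TrialLog | pd.DataFrame,
    override_validity: bool = False,
) -> SSRTEstimate:
    """Mean-method SSRT: mean responded-go RT minus mean SSD."""
    go, stop = _validated(log, override_validity)
    go_rts = go.loc[go["responded"], "rt_ms"]
    if len(go_rts) == 0:
        raise InsufficientTrialsError("no responded go trials")
    mean_go = float(go_rts.mean())
    mean_ssd = float(stop["ssd_ms"].mean())
    return SSRTEstimate(
        method="mean",
        ssrt=mean_go - mean_ssd,
        finishing_time=mean_go,
        mean_ssd=mean_ssd,
        n_index=None,
    )
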