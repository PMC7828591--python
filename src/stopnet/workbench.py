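"""End-to-end synthetic study orchestration.

``run_full_pipeline`` composes every stage: draw a latent cohort with the
study's correlation structure; map each subject's latent SSRT trait to a
stop-process latency and simulate a stop-signal session; screen sessions
against the horse-race validity rules and estimate SSRT for the survivors;
map each subject's latent N2 trait to an injected microvolt amplitude,
generate ERP epochs and derive the stop-minus-slow-go N2; then run the
analysis plan (correlations and the hierarchical regression) on the derived
measures.  All stage seeds are spawned deterministically from one master
seed, so identical configs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import erp, presets, ssrt, stats
from .cohort import (
    DEFAULT_ROI_CHANNELS,
    CohortTable,
    generate_epoch_set,
    generate_from_correlation,
)
from .race import RaceModelParams, TaskConfig, simulate_session

__all__ = ["StudyConfig", "PipelineResult", "run_full_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyConfig:
    """Full synthetic-study configuration.

    The latent SSRT column (z-scored) maps to a constant stop latency
    ``ssrt_link_mean + ssrt_link_sd * z`` ms (clipped below at 50 ms); the
    latent N2 column maps to an injected bump amplitude
    ``n2_link_mean + n2_link_sd * z`` µV.
    """

    n_subjects: int = 60
    master_seed: int = 0
    task: TaskConfig = field(default_factory=TaskConfig)
    race_base: RaceModelParams = field(default_factory=RaceModelParams)
    ssrt_link_mean: float = 160.0
    ssrt_link_sd: float = 40.0
    n2_link_mean: float = -0.12
    n2_link_sd: float = 2.06
    epoch_counts: tuple[int, int] = (35, 144)
    epoch_noise_sd: float = 20.0
    run_erp: bool = True
    run_mi: bool = False
    mi_m: int = 20


@dataclass
class PipelineResult:
    cohort: CohortTable
    behavior: pd.DataFrame      # per-subject SST summaries + SSRT + validity
    n2: pd.DataFrame | None     # per-subject derived N2
    analysis: dict
    exclusions: list[dict]
    manifest: dict


def _config_dict(config: StudyConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=list))


def _manifest_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def run_full_pipeline(config: StudyConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full synthetic study; optionally write artifacts to ``out_dir``."""
    seeds = np.random.SeedSequence(config.master_seed).spawn(4)
    cohort_seed = int(seeds[0].generate_state(1)[0] % 2**31)
    subject_entropy = seeds[1]
    epoch_entropy = seeds[2]

    corr = presets.study_correlation_matrix(include_education=True)
    cohort = generate_from_correlation(corr, config.n_subjects, seed=cohort_seed)

    z_ssrt = cohort.data["ssrt"].to_numpy()
    z_n2 = cohort.data["n2"].to_numpy()
    sst_seeds = [int(s.generate_state(1)[0] % 2**31) for s in subject_entropy.spawn(config.n_subjects)]
    ep_seeds = [int(s.generate_state(1)[0] % 2**31) for s in epoch_entropy.spawn(config.n_subjects)]

    rows = []
    exclusions: list[dict] = []
    for i in range(config.n_subjects):
        latency = max(50.0, config.ssrt_link_mean + config.ssrt_link_sd * z_ssrt[i])
        params = dataclasses.replace(config.race_base, stop_mu=latency)
        log = simulate_session(params, config.task, seed=sst_seeds[i])
        summary = ssrt.summarize_behavior(log)
        report = ssrt.check_race_assumptions(log)
        row = {
            "subject": i,
            "true_stop_latency": latency,
            "p_go_omission": summary.p_go_omission,
            "p_choice_error": summary.p_choice_error,
            "mean_go_rt": summary.mean_go_rt,
            "sd_go_rt": summary.sd_go_rt,
            "nth_rt": summary.nth_rt,
            "p_respond_stop": summary.p_respond_stop,
            "mean_ssd": summary.mean_ssd,
            "mean_signal_respond_rt": summary.mean_signal_respond_rt,
            "valid": report.valid,
            "ssrt_integration": np.nan,
            "ssrt_mean": np.nan,
        }
        if report.valid:
            row["ssrt_integration"] = ssrt.estimate_ssrt_integration(log).ssrt
            row["ssrt_mean"] = ssrt.estimate_ssrt_mean(log).ssrt
        else:
            exclusions.append({"subject": i, "reasons": list(report.reasons)})
        rows.append(row)
    behavior = pd.DataFrame(rows).set_index("subject")
    logger.info(
        "SSRT estimated for %d/%d subjects (%d excluded by race-model screening)",
        int(behavior["valid"].sum()), config.n_subjects, len(exclusions),
    )

    n2_table = None
    if config.run_erp:
        roi = erp.RoiSpec(channels=DEFAULT_ROI_CHANNELS)
        amp = config.n2_link_mean + config.n2_link_sd * z_n2
        derived = [
            erp.derive_n2(
                generate_epoch_set(
                    true_n2_amplitude=amp[i],
                    counts=config.epoch_counts,
                    noise_sd=config.epoch_noise_sd,
                    seed=ep_seeds[i],
                ),
                roi,
            )
            for i in range(config.n_subjects)
        ]
        n2_table = pd.DataFrame(
            {"true_n2": amp, "derived_n2": derived},
            index=behavior.index,
        )

    analysis_table = cohort.data.copy()
    analysis_table["ssrt_hat"] = behavior["ssrt_integration"].to_numpy()
    if n2_table is not None:
        analysis_table["n2_hat"] = n2_table["derived_n2"].to_numpy()

    analysis: dict = {
        "n_subjects": config.n_subjects,
        "n_ssrt_estimated": int(behavior["valid"].sum()),
        "n_excluded": len(exclusions),
        "r_ssrt_recovery": _safe_corr(behavior["ssrt_integration"], behavior["true_stop_latency"]),
    }
    if n2_table is not None:
        analysis["r_n2_recovery"] = _safe_corr(n2_table["derived_n2"], n2_table["true_n2"])

    def regression_estimates(df: pd.DataFrame) -> dict[str, tuple[float, float]]:
        import statsmodels.api as sm

        z = (df - df.mean()) / df.std(ddof=1)
        predictors = ["mother_education", "inattention_child", "hyperactivity_child"]
        fit = sm.OLS(z["n2_hat"], sm.add_constant(z[predictors])).fit()
        return {
            f"beta_{name}": (float(fit.params[name]), float(fit.bse[name] ** 2))
            for name in predictors
        }

    outcome = "n2_hat" if n2_table is not None else "n2"
    if config.run_mi and analysis_table.isna().any().any():
        pooled = stats.impute_and_pool(
            analysis_table[[outcome, "inattention_child", "hyperactivity_child", "mother_education"]]
            .rename(columns={outcome: "n2_hat"}),
            analysis=regression_estimates,
            m=config.mi_m,
            seed=int(seeds[3].generate_state(1)[0] % 2**31),
        )
        analysis["regression"] = {
            name: {"estimate": p.estimate, "total_variance": p.total, "p": p.p}
            for name, p in pooled.items()
        }
    else:
        reg = stats.hierarchical_regression(
            analysis_table.dropna(subset=[outcome]),
            outcome=outcome,
            blocks=[["inattention_child", "hyperactivity_child"]],
            covariates=["mother_education"],
        )
        step2 = reg.steps[-1]
        analysis["regression"] = {
            name: {
                "beta": float(step2.beta[name]),
                "p_one_tailed": float(step2.p_one_tailed[name]),
            }
            for name in step2.beta.index
        }
        analysis["regression_r2"] = step2.r_squared

    manifest = {
        "config": _config_dict(config),
        "stage_seeds": {"cohort": cohort_seed, "sst": sst_seeds, "epochs": ep_seeds},
        "exclusions": exclusions,
    }
    manifest["hash"] = _manifest_hash(manifest)

    result = PipelineResult(
        cohort=cohort,
        behavior=behavior,
        n2=n2_table,
        analysis=analysis,
        exclusions=exclusions,
        manifest=manifest,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out / "cohort.csv")
        behavior.to_csv(out / "behavior.csv")
        if n2_table is not None:
            n2_table.to_csv(out / "n2.csv")
        (out / "analysis.json").write_text(json.dumps(analysis, indent=1, default=float))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=float))
    return result


def _safe_corr(a: pd.Series, b: pd.Series) -> float:
    df = pd.concat([a, b], axis=1).dropna()
    if len(df) < 3:
        return float("nan")
    return float(df.corr().iloc[0, 1])
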