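"""Synthetic longitudinal cohorts and ERP epoch sets.

Everything downstream of data collection — SSRT screening, N2 derivation,
correlation/regression/path inference — is tested against cohorts generated
here.  Two generation modes exist: ``generate_from_correlation`` draws a
multivariate normal with a prescribed correlation matrix (repaired to the
nearest positive-definite matrix if necessary); ``generate_from_path_model``
builds variables in topological order from a recursive path model so that
the population path coefficients equal the specified values.
``inject_missingness`` masks cells completely at random (MCAR).

``generate_epoch_set`` emits one subject's worth of baseline-ready ERP
epochs: go epochs carry a go-locked template, successful-stop epochs carry
the same template plus a stop-locked negative N2 deflection (a Gaussian
bump over the ROI channels), and white Gaussian sensor noise is added.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .erp import EpochSet
from .pathmodel import PathModelSpec
from .race import sample_ex_gaussian

__all__ = [
    "CohortTable",
    "generate_from_correlation",
    "generate_from_path_model",
    "inject_missingness",
    "generate_epoch_set",
    "nearest_positive_definite",
    "n2_template",
    "DEFAULT_CHANNELS",
    "DEFAULT_ROI_CHANNELS",
]

logger = logging.getLogger(__name__)

#: Synthetic montage: six right anterior-frontal ROI channels plus two
#: non-ROI channels.  Real electrode numbers depend on the net layout, so
#: placeholder labels are used throughout.
DEFAULT_ROI_CHANNELS = tuple(f"ROI{i}" for i in range(1, 7))
DEFAULT_CHANNELS = DEFAULT_ROI_CHANNELS + ("CTL1", "CTL2")


@dataclass
class CohortTable:
    """Subjects x variables table plus missingness mask and provenance."""

    data: pd.DataFrame
    mask: pd.DataFrame | None = None  # True where a cell was masked out
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="subject")

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        df = pd.read_csv(path, index_col="subject")
        return cls(data=df, mask=df.isna())


def nearest_positive_definite(
    corr: np.ndarray, eps: float = 1e-6, max_shift: float = 0.05
) -> tuple[np.ndarray, float]:
    """Repair a symmetric matrix to the nearest PD correlation matrix.

    Eigenvalues below ``eps`` are clipped to ``eps`` and the result is
    rescaled to unit diagonal.  Returns the repaired matrix and the largest
    absolute eigenvalue shift; raises if the shift exceeds ``max_shift``.
    """
    vals, vecs = np.linalg.eigh(corr)
    shift = float(np.max(np.maximum(eps - vals, 0.0)))
    if shift == 0.0:
        return corr.copy(), 0.0
    if shift > max_shift:
        raise ValueError(
            f"matrix too far from positive definite (eigenvalue shift {shift:.4f} "
            f"> {max_shift})"
        )
    clipped = (vecs * np.maximum(vals, eps)) @ vecs.T
    d = np.sqrt(np.diag(clipped))
    repaired = clipped / np.outer(d, d)
    logger.warning(
        "correlation matrix repaired to nearest PD (eigenvalue shift %.2e)", shift
    )
    return repaired, shift


def _as_corr_frame(corr, variables=None) -> pd.DataFrame:
    if isinstance(corr, pd.DataFrame):
        return corr.astype(float)
    corr = np.asarray(corr, dtype=float)
    if variables is None:
        variables = [f"v{i}" for i in range(corr.shape[0])]
    return pd.DataFrame(corr, index=variables, columns=variables)


def generate_from_correlation(
    corr,
    n: int,
    seed: int,
    variables=None,
    means: dict[str, float] | None = None,
    sds: dict[str, float] | None = None,
) -> CohortTable:
    """Draw an MVN cohort with the given correlation structure.

    ``corr`` is a symmetric unit-diagonal matrix (DataFrame or array);
    non-PD inputs are repaired by eigenvalue clipping (logged).  Columns
    default to standard-normal marginals; ``means``/``sds`` rescale
    individual columns.
    """
    R = _as_corr_frame(corr, variables)
    mat = R.to_numpy()
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-12):
        raise ValueError("correlation matrix must have a unit diagonal")
    repaired, shift = nearest_positive_definite(mat)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(repaired)
    draws = rng.standard_normal((n, len(R))) @ L.T
    df = pd.DataFrame(draws, columns=list(R.columns))
    for col, sd in (sds or {}).items():
        df[col] *= sd
    for col, mean in (means or {}).items():
        df[col] += mean
    return CohortTable(
        data=df,
        mask=None,
        metadata={"mode": "correlation", "seed": seed, "n": n, "pd_shift": shift},
    )


def generate_from_path_model(
    path: PathModelSpec,
    exog_corr: pd.DataFrame | None,
    n: int,
    seed: int,
    means: dict[str, float] | None = None,
    sds: dict[str, float] | None = None,
) -> CohortTable:
    """Build a cohort whose population path coefficients equal the spec.

    Exogenous variables are MVN with ``exog_corr``; each endogenous
    variable is the coefficient-weighted sum of its (standardized) parents
    plus a Gaussian disturbance scaled so the variable has unit population
    variance.  Raises if the coefficients imply a non-positive disturbance
    variance.
    """
    if path.coefficients is None:
        raise ValueError("path model carries no coefficients to generate from")
    order = path.topological_order()
    exog = list(path.exogenous)
    rng = np.random.default_rng(seed)

    if exog_corr is None:
        exog_corr = pd.DataFrame(np.eye(len(exog)), index=exog, columns=exog)
    exog_tab = generate_from_correlation(
        exog_corr.loc[exog, exog], n, seed=rng.integers(2**31)
    )
    cols: dict[str, np.ndarray] = {v: exog_tab.data[v].to_numpy() for v in exog}

    implied = path.implied_correlation(exog_corr)  # validates disturbances > 0
    for v in order:
        if v in cols:
            continue
        parents = list(path.parents(v))
        beta = np.array([path.coefficients[(p_, v)] for p_ in parents])
        explained = float(
            beta @ implied.loc[parents, parents].to_numpy(dtype=float) @ beta
        )
        psi = 1.0 - explained
        systematic = sum(b * cols[p_] for b, p_ in zip(beta, parents))
        cols[v] = systematic + np.sqrt(psi) * rng.standard_normal(n)

    df = pd.DataFrame({v: cols[v] for v in order})
    for col, sd in (sds or {}).items():
        df[col] *= sd
    for col, mean in (means or {}).items():
        df[col] += mean
    return CohortTable(
        data=df,
        mask=None,
        metadata={"mode": "path", "seed": seed, "n": n},
    )


def inject_missingness(
    table: CohortTable, rates: dict[str, float], seed: int
) -> CohortTable:
    """Mask cells MCAR: each cell of a listed variable independently."""
    for var, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {var} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    data = table.data.copy()
    mask = pd.DataFrame(False, index=data.index, columns=data.columns)
    for var, rate in rates.items():
        hit = rng.random(len(data)) < rate
        data.loc[hit, var] = np.nan
        mask[var] = hit
    meta = dict(table.metadata, missingness=dict(rates))
    return CohortTable(data=data, mask=mask, metadata=meta)


def n2_template(
    times_ms: np.ndarray,
    amplitude: float,
    center: float = 215.0,
    sd: float = 20.0,
) -> np.ndarray:
    """Stop-locked N2 deflection: Gaussian bump, peak = ``amplitude`` (µV)."""
    return amplitude * np.exp(-0.5 * ((times_ms - center) / sd) ** 2)


def _go_template(times_ms: np.ndarray) -> np.ndarray:
    # Generic go-locked evoked activity shared by go and stop epochs; the
    # stop-minus-slow-go difference wave cancels it by construction.
    return 4.0 * np.exp(-0.5 * ((times_ms - 120.0) / 35.0) ** 2) - 2.0 * np.exp(
        -0.5 * ((times_ms - 320.0) / 60.0) ** 2
    )


def generate_epoch_set(
    true_n2_amplitude: float,
    counts: tuple[int, int] = (35, 144),
    noise_sd: float = 20.0,
    rt_law: tuple[float, float, float] = (480.0, 90.0, 200.0),
    seed: int = 0,
    sampling_rate: float = 250.0,
    epoch_window: tuple[float, float] = (-200.0, 800.0),
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    roi_channels: tuple[str, ...] = DEFAULT_ROI_CHANNELS,
    n2_center: float = 215.0,
    n2_sd: float = 20.0,
) -> EpochSet:
    """One subject's synthetic epochs: ``counts`` = (successful stop, go).

    Both conditions carry a shared go-locked template; successful-stop
    epochs additionally carry the stop-locked N2 bump (peak
    ``true_n2_amplitude`` µV at ``n2_center`` ms) on the ROI channels.
    White Gaussian noise of ``noise_sd`` µV is added per sample.  Go RTs
    come from an ex-Gaussian ``rt_law`` = (mu, sigma, tau).
    """
    n_stop, n_go = counts
    if n_stop < 1 or n_go < 1:
        raise ValueError("need at least one trial per condition")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    n_samples = round((epoch_window[1] - epoch_window[0]) / 1000.0 * sampling_rate) + 1
    times = epoch_window[0] + 1000.0 / sampling_rate * np.arange(n_samples)

    base = _go_template(times)
    bump = n2_template(times, true_n2_amplitude, n2_center, n2_sd)
    roi_mask = np.array([ch in roi_channels for ch in channels])

    n_trials = n_stop + n_go
    data = np.tile(base, (n_trials, len(channels), 1))
    data[:n_stop, roi_mask, :] += bump
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)

    conditions = np.array(
        ["successful_stop"] * n_stop + ["go"] * n_go, dtype=object
    )
    go_rt = np.full(n_trials, np.nan)
    go_rt[n_stop:] = sample_ex_gaussian(*rt_law, n_go, rng)
    return EpochSet(
        data=data,
        sampling_rate=sampling_rate,
        epoch_window=epoch_window,
        channels=channels,
        conditions=conditions,
        go_rt=go_rt,
    )
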