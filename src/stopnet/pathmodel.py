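"""Recursive (acyclic) path-model specification shared by the synthetic
cohort generator and the path-analysis fitter.

A model is a set of directed arrows among named observed variables.
Variables with no incoming arrow are exogenous; their mutual correlations
are free.  Every variable is standardized (unit variance), so arrow
coefficients are standardized path coefficients and each endogenous
variable's disturbance variance is 1 minus the variance its parents
explain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter

import numpy as np
import pandas as pd

__all__ = ["PathModelSpec", "CyclicModelError", "OverDeterminedError"]


class CyclicModelError(ValueError):
    """The arrow set contains a directed cycle."""


class OverDeterminedError(ValueError):
    """Coefficients imply a non-positive disturbance variance."""


@dataclass(frozen=True)
class PathModelSpec:
    """Directed acyclic path model over named variables.

    ``arrows`` maps nothing by itself; ``coefficients`` (optional) assigns a
    standardized coefficient to each arrow for data generation or implied-
    correlation computation.  Fitting ignores ``coefficients``.
    """

    arrows: tuple[tuple[str, str], ...]
    coefficients: dict[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "arrows", tuple((str(a), str(b)) for a, b in self.arrows))
        self.topological_order()  # raises on cycles
        if self.coefficients is not None:
            missing = set(self.arrows) - set(self.coefficients)
            if missing:
                raise ValueError(f"coefficients missing for arrows: {sorted(missing)}")

    @property
    def variables(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for src, dst in self.arrows:
            seen.setdefault(src)
            seen.setdefault(dst)
        return tuple(seen)

    @property
    def endogenous(self) -> tuple[str, ...]:
        targets = {dst for _, dst in self.arrows}
        return tuple(v for v in self.variables if v in targets)

    @property
    def exogenous(self) -> tuple[str, ...]:
        targets = {dst for _, dst in self.arrows}
        return tuple(v for v in self.variables if v not in targets)

    def parents(self, variable: str) -> tuple[str, ...]:
        return tuple(src for src, dst in self.arrows if dst == variable)

    def topological_order(self) -> tuple[str, ...]:
        ts = TopologicalSorter({v: set(self.parents(v)) for v in self.variables})
        try:
            return tuple(ts.static_order())
        except CycleError as err:
            raise CyclicModelError(f"path model contains a cycle: {err.args}") from err

    def n_free_parameters(self) -> int:
        """Arrow coefficients + free exogenous correlations + p variances."""
        p = len(self.variables)
        k = len(self.exogenous)
        return len(self.arrows) + k * (k - 1) // 2 + p

    def degrees_of_freedom(self) -> int:
        p = len(self.variables)
        return p * (p + 1) // 2 - self.n_free_parameters()

    def implied_correlation(
        self,
        exog_corr: pd.DataFrame | None = None,
        coefficients: dict[tuple[str, str], float] | None = None,
        disturbances: dict[str, float] | None = None,
    ) -> pd.DataFrame:
        """Model-implied correlation matrix by recursive path tracing.

        Endogenous variances are forced to 1 by scaling the disturbance,
        unless explicit ``disturbances`` (residual variances) are supplied —
        the fitter passes its residual-variance estimates so a saturated
        model reproduces the sample matrix exactly.
        """
        coefs = coefficients if coefficients is not None else self.coefficients
        if coefs is None:
            raise ValueError("no coefficients supplied")
        order = self.topological_order()
        exog = list(self.exogenous)
        R = pd.DataFrame(np.eye(len(order)), index=order, columns=order)
        if exog_corr is not None:
            for i, a in enumerate(exog):
                for b in exog[i + 1 :]:
                    R.loc[a, b] = R.loc[b, a] = float(exog_corr.loc[a, b])
        placed = set(exog)
        for v in order:
            if v in placed:
                continue
            parents = list(self.parents(v))
            beta = np.array([coefs[(p_, v)] for p_ in parents])
            for u in placed:
                R.loc[v, u] = R.loc[u, v] = float(
                    beta @ R.loc[parents, u].to_numpy(dtype=float)
                )
            explained = float(beta @ R.loc[parents, parents].to_numpy(dtype=float) @ beta)
            if disturbances is None:
                psi = 1.0 - explained
                if psi <= 0:
                    raise OverDeterminedError(
                        f"coefficients over-determined: {v} would need disturbance "
                        f"variance {psi:.4f}"
                    )
            else:
                psi = float(disturbances[v])
            R.loc[v, v] = explained + psi
            placed.add(v)
        return R
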