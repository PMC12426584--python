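"""Shared domain types: tracks, kill sites, incidents, truth parameters,
and the fit-result container used by every model family."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AGE_SEX_CLASSES = ("AF", "AM", "DF", "DM")


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth generative parameters for the synthetic cohort.

    ``beta_move`` and ``beta_feed`` map covariate column names (as produced
    by covariate extraction, e.g. ``"forest_edge_density"`` or
    ``"development_cover@150"``) to exponential selection weights.
    ``conflict_coefs`` is ``(intercept, a_feed, b_move)`` on the SD-rescaled
    suitability surfaces.
    """

    beta_move: dict[str, float]
    beta_feed: dict[str, float]
    gamma_shape: float = 2.0
    gamma_scale: float = 300.0
    vm_kappa: float = 0.5
    conflict_coefs: tuple[float, float, float] = (-6.0, 1.0, -1.0)
    fix_interval: float = 2.0

    def __post_init__(self) -> None:
        if min(self.gamma_shape, self.gamma_scale, self.vm_kappa) <= 0:
            raise ValueError("movement-kernel parameters must be positive")
        if self.fix_interval <= 0:
            raise ValueError("fix interval must be positive")


@dataclass
class Track:
    """A GPS track: ordered fixes at a fixed sampling interval."""

    animal_id: str
    age_sex_class: str
    t: np.ndarray          # hours since track start
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "animal_id": self.animal_id, "class": self.age_sex_class,
            "t": self.t, "x": self.x, "y": self.y,
        })


@dataclass
class KillSiteSet:
    """Feeding (kill) locations per animal; prey class is bookkeeping only."""

    points: pd.DataFrame   # columns: animal_id, x, y, prey_class

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class IncidentSet:
    """Reported human–carnivore incident points with a type label."""

    points: pd.DataFrame   # columns: x, y, type


@dataclass
class FitResult:
    """Coefficients and inference for any of the model families."""

    params: pd.Series
    bse: pd.Series
    llf: float
    nobs_units: int        # strata for conditional fits, points otherwise
    model_family: str      # conditional_logit | poisson_trick | logistic_rsf | binomial_glm
    converged: bool
    vcov: pd.DataFrame | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.params)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm
        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame({
            "lower": self.params - z * self.bse,
            "upper": self.params + z * self.bse,
        })

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.bse}).join(
            self.conf_int())
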