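"""Model selection and validation.

Scale-of-effect choice by single-covariate AICc, two-stage (human /
nonhuman) AICc model selection, animal-blocked k-fold cross-validation
with binned Spearman rank correlation, and out-of-sample suitability
validation against held-out tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .core import FitResult, Track
from .issa import StepDesign, fit_conditional_logit
from .rsf import RsfDesign, fit_rsf

MOVEMENT_ADJUSTMENT_TERMS = ("log_sl", "cos_ta")
AICC_TIE_TOL = 1e-6

__all__ = ["ModelSpec", "ValidationResult", "aicc", "select_scale",
           "two_stage_selection", "kfold_cv", "oos_surface_validation",
           "fit_design", "binned_spearman"]


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: behavior, covariate columns, and selection stage."""

    behavior: str                      # "movement" | "feeding"
    covariates: tuple[str, ...]
    stage: str = "stage2_combination"  # or stage1_human / stage1_nonhuman


@dataclass
class ValidationResult:
    """Per-fold binned Spearman correlations from k-fold cross-validation."""

    rs: list[float]
    k: int
    n_bins: int
    skipped_folds: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.rs))

    @property
    def sd(self) -> float:
        return float(np.std(self.rs, ddof=1)) if len(self.rs) > 1 else 0.0


def aicc(fit: FitResult) -> float:
    """Small-sample-corrected AIC: -2l + 2k + 2k(k+1)/(n-k-1).

    The effective sample size n is the number of strata for conditional
    fits and the number of points otherwise (``fit.nobs_units``).
    """
    n, k = fit.nobs_units, fit.k
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * fit.llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_design(design: StepDesign | RsfDesign,
               formula: list[str]) -> FitResult:
    """Fit the family matching the design type; movement adjustment terms
    are appended automatically for step designs."""
    if isinstance(design, StepDesign):
        cols = list(formula) + [t for t in MOVEMENT_ADJUSTMENT_TERMS
                                if t in design.rows.columns
                                and t not in formula]
        return fit_conditional_logit(design, cols)
    return fit_rsf(design, list(formula))


def select_scale(design: StepDesign | RsfDesign, covariate: str,
                 candidate_scales: list[int]) -> int:
    """Choose a covariate's scale of effect: lowest single-covariate AICc.

    Ties (ΔAICc below 1e-6) break toward the smaller radius.
    """
    scores = []
    errors = []
    for scale in sorted(candidate_scales):
        col = f"{covariate}@{scale}"
        try:
            fit = fit_design(design, [col])
            scores.append((scale, aicc(fit)))
        except Exception as exc:   # noqa: BLE001 - candidate excluded, logged
            errors.append((scale, str(exc)))
    if not scores:
        raise RuntimeError(
            f"no scale fit converged for {covariate!r}: {errors}")
    best_scale, best = scores[0]
    for scale, a in scores[1:]:
        if a < best - AICC_TIE_TOL:
            best_scale, best = scale, a
    return best_scale


def _enumerate_stage2(human: tuple[str, ...],
                      nonhuman: tuple[str, ...]) -> list[tuple[str, ...]]:
    union = tuple(nonhuman) + tuple(h for h in human if h not in nonhuman)
    lattice = [tuple(nonhuman), tuple(human), union]
    for h in human:
        lattice.append(tuple(c for c in union if c != h))
    return lattice


def two_stage_selection(design: StepDesign | RsfDesign,
                        human_candidates: list[list[str]],
                        nonhuman_candidates: list[list[str]],
                        behavior: str = "movement",
                        ) -> tuple[ModelSpec, FitResult, pd.DataFrame]:
    """Two-stage AICc selection.

    Stage 1 finds the lowest-AICc model within the human candidate set and
    within the nonhuman candidate set separately.  Stage 2 fits the
    combination lattice {nonhuman, human, union, union minus each single
    human term} and returns the lowest-AICc spec, its fit, and the full
    selection table.  AICc ties break toward fewer parameters.
    """
    if not human_candidates or not nonhuman_candidates:
        raise ValueError("candidate sets must be non-empty")

    def stage1(cands, label):
        rows = []
        for cov in cands:
            try:
                fit = fit_design(design, cov)
                if fit.converged:
                    rows.append((tuple(cov), fit, aicc(fit)))
            except Exception as exc:   # noqa: BLE001
                warnings.warn(f"{label} candidate {cov} excluded: {exc}",
                              stacklevel=3)
        if not rows:
            raise RuntimeError(f"no converged model in {label}")
        rows.sort(key=lambda r: (r[2], len(r[0])))
        return rows[0]

    human_best, _, _ = stage1(human_candidates, "stage1_human")
    nonhuman_best, _, _ = stage1(nonhuman_candidates, "stage1_nonhuman")

    table = []
    best = None
    for cov in _enumerate_stage2(human_best, nonhuman_best):
        try:
            fit = fit_design(design, list(cov))
            a = aicc(fit)
        except Exception as exc:   # noqa: BLE001
            warnings.warn(f"stage2 candidate {cov} excluded: {exc}",
                          stacklevel=2)
            continue
        table.append(dict(model=",".join(cov), k=fit.k, loglik=fit.llf,
                          aicc=a))
        if (best is None or a < best[1] - AICC_TIE_TOL
                or (abs(a - best[1]) <= AICC_TIE_TOL
                    and len(cov) < len(best[0]))):
            best = (cov, a, fit)
    if best is None:
        raise RuntimeError("no converged model in stage 2")
    tab = pd.DataFrame(table)
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].min()
    spec = ModelSpec(behavior, best[0], "stage2_combination")
    return spec, best[2], tab


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _habitat_columns(spec_cols, design) -> list[str]:
    return [c for c in spec_cols if c not in MOVEMENT_ADJUSTMENT_TERMS]


def binned_spearman(score: np.ndarray, case: np.ndarray,
                    n_bins: int = 10) -> float:
    """Spearman correlation of bin rank vs. area-adjusted used frequency.

    Scores are cut into equal-count quantile bins; per occupied bin the
    used:available count ratio is formed, and its Spearman correlation with
    the bin rank returned.  A perfectly monotone score gives 1; random
    scores hover around 0.
    """
    score = np.asarray(score, dtype=float)
    case = np.asarray(case)
    edges = np.quantile(score, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges[1:-1], score, side="right"),
                   0, n_bins - 1)
    used = np.bincount(bins[case == 1], minlength=n_bins)
    avail = np.bincount(bins[case == 0], minlength=n_bins)
    occupied = avail > 0
    if occupied.sum() < 2:
        raise ValueError("fewer than 2 occupied bins")
    ratio = used[occupied] / avail[occupied]
    if np.ptp(ratio) == 0:
        return 0.0
    return float(spearmanr(np.arange(n_bins)[occupied], ratio).statistic)


def kfold_cv(design: StepDesign | RsfDesign, covariates: list[str],
             k: int = 5, n_bins: int = 10, seed: int = 0) -> ValidationResult:
    """Animal-blocked k-fold cross-validation with binned Spearman scoring.

    All rows of an animal stay in one fold.  Per fold the model is fitted
    on the training animals, held-out rows are scored by the habitat part
    of the linear predictor, scores are cut into ``n_bins`` equal-count
    (quantile) bins of predicted suitability — the binning convention of
    the standard used:expected habitat-validation family, which keeps every
    bin populated regardless of how skewed w(x) is — and the Spearman
    correlation between bin rank and the area-adjusted used frequency
    (used count over available count per occupied bin) is recorded.  Folds
    without used points are skipped with a warning.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    animals = np.array(sorted(design.rows["animal_id"].unique()))
    if len(animals) < k:
        raise ValueError(f"only {len(animals)} animals for {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(animals))
    fold_of = {a: i % k for i, a in enumerate(animals[perm])}
    folds = design.rows["animal_id"].map(fold_of).to_numpy()

    habitat = _habitat_columns(covariates, design)
    rs_list = []
    skipped = 0
    for f in range(k):
        test = design.rows[folds == f]
        train = design.rows[folds != f].reset_index(drop=True)
        if test["case"].sum() == 0 or train["case"].sum() == 0:
            warnings.warn(f"fold {f} lacks used points; skipped", stacklevel=2)
            skipped += 1
            continue
        if isinstance(design, StepDesign):
            sub = StepDesign(train, design.J, design.formula)
        else:
            sub = RsfDesign(train, design.formula)
        fit = fit_design(sub, covariates)
        beta = fit.params.reindex(habitat).to_numpy()
        score = test[habitat].to_numpy(float) @ beta
        try:
            rs = binned_spearman(score, test["case"].to_numpy(), n_bins)
        except ValueError:
            warnings.warn(f"fold {f}: fewer than 2 occupied bins; skipped",
                          stacklevel=2)
            skipped += 1
            continue
        rs_list.append(rs)
    return ValidationResult(rs_list, k - skipped, n_bins, skipped)


def oos_surface_validation(surface_w, held_out_tracks: list[Track],
                           n_quantile_bins: int = 10) -> pd.DataFrame:
    """Bin-occupancy of held-out used locations on a suitability surface.

    Bin edges are study-area-wide quantiles of the surface, so a uniform
    point process occupies each bin with probability ~1/n_bins; used
    locations from animals held out of the fit falling mostly in the top
    bins indicate the surface generalises.  Returns a table of counts and
    fractions per bin (bin n_quantile_bins-1 is the highest-suitability
    bin).
    """
    vals = surface_w.values.ravel()
    qs = np.quantile(vals, np.linspace(0, 1, n_quantile_bins + 1))
    fixes_x = np.concatenate([t.x for t in held_out_tracks])
    fixes_y = np.concatenate([t.y for t in held_out_tracks])
    v = surface_w.value_at(fixes_x, fixes_y)   # raises if off-surface
    bins = np.clip(np.searchsorted(qs[1:-1], v, side="right"), 0,
                   n_quantile_bins - 1)
    counts = np.bincount(bins, minlength=n_quantile_bins)
    return pd.DataFrame({
        "bin": np.arange(n_quantile_bins),
        "count": counts,
        "fraction": counts / counts.sum(),
    })
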