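"""End-to-end orchestration: synthesize → fit → select → validate → map →
conflict, with deterministic seeding and a hashed artifact manifest."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .agents import simulate_cohort, simulate_incidents
from .core import AGE_SEX_CLASSES, FitResult, KillSiteSet, Track, TruthParams
from .issa import (StepDesign, clean_and_build_steps, extract_step_covariates,
                   fit_conditional_logit, fit_movement_kernel,
                   sample_available)
from .landscape import (CovariateStack, LandscapeConfig, generate_landscape,
                        standardize_stack)
from .mapping import (bivariate_overlap, fit_conflict_glm, predict_surface,
                      rescale_sd, sample_background, summarize_classes,
                      tercile_classify)
from .rsf import build_rsf_design, fit_rsf
from .selection import (ModelSpec, kfold_cv, select_scale,
                        two_stage_selection)

log = logging.getLogger("habsel")

DEFAULT_TRUTH = TruthParams(
    beta_move={"forest_edge_density": 1.0, "development_cover@150": -1.0},
    beta_feed={"forest_cover@500": 2.0, "development_cover@500": -1.0},
)

# percent-cover covariates and the candidate window radii per behavior
MOVEMENT_SCALES = (150, 1000)
FEEDING_SCALES = (100, 500, 1000)
COVER_COVARIATES = ("forest_cover", "shrub_cover", "development_cover",
                    "agriculture_cover")
NONHUMAN_PLAIN = ("forest_edge_density", "slope", "ruggedness", "tpi",
                  "dist_riparian")
HUMAN_PLAIN = ("dist_development", "dist_agriculture", "dist_road")


@dataclass
class RunConfig:
    """Full configuration of a synthetic end-to-end run."""

    landscape: LandscapeConfig = field(default_factory=lambda: LandscapeConfig())
    truth_by_class: dict[str, TruthParams] = field(
        default_factory=lambda: {c: DEFAULT_TRUTH for c in AGE_SEX_CLASSES})
    n_animals: dict[str, int] = field(
        default_factory=lambda: {"AF": 2, "AM": 1, "DF": 1, "DM": 1})
    n_steps: int = 300
    n_kills: int = 30
    J: int = 10                      # available steps per used step
    per_kill: int = 10               # available points per kill
    k_folds: int = 5
    n_bins: int = 10
    background_ratio: int = 10
    n_incidents: int = 200
    seed: int = 0
    outdir: str = "habsel_run"

    def validate(self) -> None:
        self.landscape.validate()
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        if self.J < 1 or self.per_kill < 1:
            raise ValueError("J and per_kill must be positive")
        if min(self.n_steps, self.n_kills) < 1:
            raise ValueError("n_steps and n_kills must be positive")
        for cls in self.n_animals:
            if cls not in self.truth_by_class:
                raise ValueError(f"no truth parameters for class {cls!r}")

    def to_text(self) -> str:
        def enc(o):
            if isinstance(o, (TruthParams, LandscapeConfig)):
                return asdict(o)
            if hasattr(o, "item"):
                return o.item()
            return str(o)
        return json.dumps(asdict(self), default=enc, indent=1, sort_keys=True)


def movement_covariate_spec() -> list[tuple[str, int | None]]:
    spec: list[tuple[str, int | None]] = [(n, None) for n in NONHUMAN_PLAIN]
    spec += [(n, None) for n in HUMAN_PLAIN]
    spec += [(c, s) for c in COVER_COVARIATES for s in MOVEMENT_SCALES]
    return spec


def feeding_covariate_spec() -> list[tuple[str, int | None]]:
    spec: list[tuple[str, int | None]] = [(n, None) for n in NONHUMAN_PLAIN]
    spec += [(n, None) for n in HUMAN_PLAIN]
    spec += [(c, s) for c in COVER_COVARIATES for s in FEEDING_SCALES]
    return spec


def build_movement_design(tracks: list[Track], stack: CovariateStack,
                          J: int = 10, seed: int = 0,
                          covariate_spec=None) -> StepDesign:
    """Steps → kernel → availability → covariates, pooled across tracks.

    The gamma / von Mises kernel is fitted to the pooled retained used
    steps of the dataset, then J available steps are simulated per used
    step and covariates extracted at all candidate scales.
    """
    used = []
    for t in tracks:
        used.extend(clean_and_build_steps(t))
    kernel = fit_movement_kernel(used)
    design = sample_available(used, kernel, stack.extent, J=J, seed=seed)
    spec = covariate_spec if covariate_spec is not None \
        else movement_covariate_spec()
    design = extract_step_covariates(design, stack, spec)
    design.rows.attrs["kernel"] = (kernel.gamma_shape, kernel.gamma_scale,
                                   kernel.vm_kappa)
    return design


def resolve_scales(design, candidates=COVER_COVARIATES,
                   scales=MOVEMENT_SCALES) -> dict[str, int]:
    """Scale of effect per percent-cover covariate by single-model AICc."""
    return {c: select_scale(design, c, list(scales)) for c in candidates}


def candidate_models(chosen_scales: dict[str, int],
                     human_plain=HUMAN_PLAIN, nonhuman_plain=NONHUMAN_PLAIN):
    """Default Stage-1 candidate sets: singletons plus the full set."""
    human = [f"development_cover@{chosen_scales['development_cover']}",
             f"agriculture_cover@{chosen_scales['agriculture_cover']}",
             *human_plain]
    nonhuman = [f"forest_cover@{chosen_scales['forest_cover']}",
                f"shrub_cover@{chosen_scales['shrub_cover']}",
                *nonhuman_plain]
    human_cands = [[h] for h in human] + [human]
    nonhuman_cands = [[n] for n in nonhuman] + [nonhuman]
    return human_cands, nonhuman_cands


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full synthetic analysis and write all artifacts.

    Stages: landscape synthesis, cohort simulation, movement iSSA (scale
    of effect, two-stage selection, k-fold validation), feeding RSF (same),
    suitability surfaces with tercile bivariate classification and class
    summaries, and the incident-vs-background conflict GLM.  Identical
    config (seeds included) reproduces identical artifact hashes.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]

    def stage(name):
        log.info("stage=%s", name)

    stage("landscape")
    stack = generate_landscape(config.landscape, seed=seeds[0])
    zstack = standardize_stack(stack)
    artifacts.append(io.write_stack(stack, out / "landscape"))
    artifacts += sorted((out / "landscape").glob("*.asc"))

    stage("cohort")
    tracks, kills = simulate_cohort(zstack, config.truth_by_class,
                                    config.n_animals, config.n_steps,
                                    config.n_kills, seed=seeds[1])
    tracks_df = pd.concat([t.to_frame() for t in tracks], ignore_index=True)
    artifacts.append(_save_csv(tracks_df, out / "tracks.csv"))
    artifacts.append(_save_csv(kills.points, out / "kills.csv"))
    artifacts.append(io.points_to_geojson(kills.points, out / "kills.geojson"))

    stage("movement_design")
    mdesign = build_movement_design(tracks, zstack, J=config.J, seed=seeds[2])
    artifacts.append(_save_csv(mdesign.rows, out / "movement_design.csv"))

    stage("movement_selection")
    mscales = resolve_scales(mdesign, scales=MOVEMENT_SCALES)
    h_c, n_c = candidate_models(mscales)
    mspec, mfit, mtable = two_stage_selection(mdesign, h_c, n_c, "movement")
    artifacts.append(_save_csv(mtable, out / "movement_selection.csv"))
    artifacts.append(_save_fit(mfit, out / "movement_fit.json"))

    stage("movement_validation")
    mcv = kfold_cv(mdesign, list(mspec.covariates), k=config.k_folds,
                   n_bins=config.n_bins, seed=seeds[3])
    artifacts.append(_save_csv(pd.DataFrame(
        {"fold": range(len(mcv.rs)), "rs": mcv.rs}), out / "movement_cv.csv"))

    stage("feeding_design")
    fdesign = build_rsf_design(kills, tracks, zstack,
                               feeding_covariate_spec(),
                               per_kill=config.per_kill, seed=seeds[4])
    artifacts.append(_save_csv(fdesign.rows, out / "feeding_design.csv"))

    stage("feeding_selection")
    fscales = resolve_scales(fdesign, scales=FEEDING_SCALES)
    h_c, n_c = candidate_models(fscales)
    fspec, ffit, ftable = two_stage_selection(fdesign, h_c, n_c, "feeding")
    artifacts.append(_save_csv(ftable, out / "feeding_selection.csv"))
    artifacts.append(_save_fit(ffit, out / "feeding_fit.json"))

    stage("feeding_validation")
    fcv = kfold_cv(fdesign, list(fspec.covariates), k=config.k_folds,
                   n_bins=config.n_bins, seed=seeds[5])
    artifacts.append(_save_csv(pd.DataFrame(
        {"fold": range(len(fcv.rs)), "rs": fcv.rs}), out / "feeding_cv.csv"))

    stage("mapping")
    msurf = rescale_sd(predict_surface(zstack, mfit, mspec))
    fsurf = rescale_sd(predict_surface(zstack, ffit, fspec))
    mclass = tercile_classify(msurf.w)
    fclass = tercile_classify(fsurf.w)
    biv = bivariate_overlap(mclass, fclass)
    for grid, name in [(msurf.w, "movement_w"), (fsurf.w, "feeding_w"),
                       (msurf.rescaled, "movement_rescaled"),
                       (fsurf.rescaled, "feeding_rescaled"),
                       (biv.codes, "bivariate_class")]:
        artifacts.append(io.write_ascii_grid(grid, out / f"{name}.asc"))
    artifacts.append(_save_csv(biv.table, out / "bivariate_classes.csv"))
    summary = summarize_classes(
        biv, stack, [("high", "high"), ("low", "high"), ("high", "low")],
        ["development_cover@150", "agriculture_cover@150",
         "forest_cover@150", "shrub_cover@150", "slope"],
        n_points=1000, seed=seeds[6])
    artifacts.append(_save_csv(summary, out / "class_summaries.csv"))

    stage("conflict")
    truth0 = next(iter(config.truth_by_class.values()))
    incidents = simulate_incidents(msurf.rescaled, fsurf.rescaled,
                                   truth0.conflict_coefs,
                                   config.n_incidents, seed=seeds[7])
    background = sample_background(zstack.extent,
                                   config.background_ratio * config.n_incidents,
                                   seed=seeds[7] + 1)
    cfit = fit_conflict_glm(incidents, background, msurf, fsurf)
    artifacts.append(_save_csv(incidents.points, out / "incidents.csv"))
    artifacts.append(_save_fit(cfit, out / "conflict_fit.json"))

    stage("manifest")
    cv_summary = pd.DataFrame([
        {"model": "movement", "rs_mean": mcv.mean, "rs_sd": mcv.sd,
         "k": mcv.k},
        {"model": "feeding", "rs_mean": fcv.mean, "rs_sd": fcv.sd,
         "k": fcv.k}])
    artifacts.append(_save_csv(cv_summary, out / "cv_summary.csv"))
    manifest = io.write_run_manifest(out, config.to_text(), artifacts)
    return manifest


def cohort_runner(config: RunConfig,
                  classes: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Fit class-specific and pooled movement/feeding models.

    The cohort is simulated once; per age-sex class (and pooled) the two
    designs are rebuilt from that class's animals and the generative
    covariate formulas are refitted, yielding a per-class coefficient
    comparison table.  Classes with fewer than 2 animals are skipped with
    a warning.
    """
    config.validate()
    classes = classes or tuple(sorted(config.n_animals))
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    stack = generate_landscape(config.landscape, seed=seeds[0])
    zstack = standardize_stack(stack)
    tracks, kills = simulate_cohort(zstack, config.truth_by_class,
                                    config.n_animals, config.n_steps,
                                    config.n_kills, seed=seeds[1])
    truth0 = next(iter(config.truth_by_class.values()))
    move_cols = list(truth0.beta_move)
    feed_cols = list(truth0.beta_feed)

    rows = []
    subsets = [("pooled", tracks)]
    for cls in classes:
        sub = [t for t in tracks if t.age_sex_class == cls]
        if len(sub) < 2:
            warnings.warn(f"class {cls} has {len(sub)} animals; skipped",
                          stacklevel=2)
            continue
        subsets.append((cls, sub))
    for label, sub_tracks in subsets:
        ids = {t.animal_id for t in sub_tracks}
        mdesign = build_movement_design(
            sub_tracks, zstack, J=config.J, seed=seeds[2],
            covariate_spec=_cols_to_spec(move_cols))
        mfit = fit_conditional_logit(mdesign, move_cols + ["log_sl", "cos_ta"])
        sub_kills = KillSiteSet(
            kills.points[kills.points["animal_id"].isin(ids)]
            .reset_index(drop=True))
        fdesign = build_rsf_design(sub_kills, sub_tracks, zstack,
                                   _cols_to_spec(feed_cols),
                                   per_kill=config.per_kill, seed=seeds[3])
        ffit = fit_rsf(fdesign, feed_cols)
        for term in move_cols:
            rows.append(dict(dataset=label, behavior="movement", term=term,
                             coef=mfit.params[term], se=mfit.bse[term]))
        for term in feed_cols:
            rows.append(dict(dataset=label, behavior="feeding", term=term,
                             coef=ffit.params[term], se=ffit.bse[term]))
    return pd.DataFrame(rows)


def _cols_to_spec(cols: list[str]) -> list[tuple[str, int | None]]:
    out = []
    for c in cols:
        if "@" in c:
            base, radius = c.rsplit("@", 1)
            out.append((base, int(radius)))
        else:
            out.append((c, None))
    return out


def _save_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False)
    return path


def _save_fit(fit: FitResult, path: Path) -> Path:
    payload = {
        "model_family": fit.model_family,
        "converged": bool(fit.converged),
        "loglik": float(fit.llf),
        "n_units": int(fit.nobs_units),
        "coefficients": {k: {"estimate": float(fit.params[k]),
                             "se": float(fit.bse[k])}
                         for k in fit.params.index},
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path
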