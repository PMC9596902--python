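"""End-to-end pipeline: QC → calibration search → contact screening.

For each reference property the full workflow is:

1. reference QC (normality check, median ± 3 MAD exclusion);
2. preprocessing-pipeline search with nested leave-one-cadaver-out
   validation of the PCA-LME calibration on in vitro spectra;
3. prediction of the held-out cadaver's ex vivo arthroscopic spectra
   before any exclusion;
4. search over poor-contact classifier combinations
   (algorithm × label rule × classifier preprocessing), constrained to
   flag 10–90% of ex vivo spectra and ranked by the in vitro / ex vivo
   agreement over the same retained locations (SRL);
5. re-evaluation of ex vivo predictions after excluding flagged spectra.

The result is a manifest holding a Table-shaped report per property
(Train/Test/SRL blocks for in vitro, All-Test/Classifier/SRL blocks for
ex vivo, OutlierS/OutlierN percentages), all summarized as
median (IQR) across the leave-one-cadaver-out iterations.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .contact_outlier import (
    ALGORITHMS,
    DEFAULT_RULES,
    CandidateResult,
    LabelRule,
    LabelRuleError,
    classify_spectra,
    generate_labels,
    select_combo,
    train_classifier,
)
from .evaluation import classification_metrics, median_iqr, rmse, spearman
from .pca_lme import CalibratedModel, fit_pca, leave_one_cadaver_out, project
from .preprocess import (
    CLASSIFIER_PRESETS,
    RANGE_SETS,
    REGRESSION_PRESETS,
    PreprocessConfig,
    apply_config_matrix,
)
from .reference_qc import qc_property
from .spectral_data import LOCATION_COLUMNS, SpectralDataset
from .synthetic_cohort import SynthParams, simulate_cohort

logger = logging.getLogger(__name__)

PROPERTIES = ("pg_od", "icrs", "oarsi", "mankin")


def default_reduced_grid() -> list[PreprocessConfig]:
    """Eight-config search grid for routine runs.

    The full 2112-config research grid is hours-scale; this reduced grid
    covers the published optimal pipelines plus representative corners
    of the option space (no scatter correction, plain SNV, each
    derivative order, both split-band range sets).
    """
    extra = [
        PreprocessConfig(scatter="none", sg_deriv=0, sg_window=11, ranges=RANGE_SETS[0]),
        PreprocessConfig(scatter="snv", sg_deriv=1, sg_window=15, ranges=RANGE_SETS[0]),
        PreprocessConfig(scatter="snv", sg_deriv=2, sg_window=15, ranges=RANGE_SETS[2]),
        PreprocessConfig(scatter="lsnv", lsnv_window=4, sg_deriv=0, sg_window=11,
                         ranges=RANGE_SETS[3]),
    ]
    grid: list[PreprocessConfig] = []
    for cfg in list(REGRESSION_PRESETS.values()) + extra:
        if cfg not in grid:
            grid.append(cfg)
    return grid


@dataclass
class PipelineSettings:
    """Problem-size and search-space knobs for one pipeline run."""

    properties: tuple[str, ...] = PROPERTIES
    regression_grid: list[PreprocessConfig] | None = None
    classifier_algorithms: tuple[str, ...] = ALGORITHMS
    classifier_rules: tuple[LabelRule, ...] = DEFAULT_RULES
    classifier_configs: dict[str, list[PreprocessConfig]] | None = None
    n_folds: int = 10
    max_components: int = 12
    qc_k: float = 3.0
    seed: int = 0

    def grid_for(self) -> list[PreprocessConfig]:
        return list(self.regression_grid) if self.regression_grid else default_reduced_grid()

    def clf_configs_for(self, property: str) -> list[PreprocessConfig]:
        if self.classifier_configs and property in self.classifier_configs:
            return list(self.classifier_configs[property])
        return [CLASSIFIER_PRESETS[property]]


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    seed: int
    version: str
    settings: PipelineSettings
    reports: dict[str, dict] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    exclusion_log: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "version": self.version,
            "properties": list(self.reports),
            "reports": self.reports,
            "timings_s": self.timings,
            "exclusion_log": self.exclusion_log,
        }


def _median_iqr_block(rows: pd.DataFrame, cols: dict[str, str]) -> dict:
    out = {}
    for key, col in cols.items():
        values = rows[col].dropna()
        if len(values):
            med, iqr = median_iqr(values)
            out[key] = {"median": med, "iqr": iqr}
        else:
            out[key] = {"median": float("nan"), "iqr": float("nan")}
    return out


def _location_tuples(meta: pd.DataFrame) -> list[tuple]:
    return list(map(tuple, meta[LOCATION_COLUMNS].itertuples(index=False)))


def _per_location_median(meta: pd.DataFrame, values: np.ndarray) -> pd.DataFrame:
    df = meta[LOCATION_COLUMNS].copy()
    df["value"] = values
    return df.groupby(LOCATION_COLUMNS, sort=True, as_index=False)["value"].median()


def _safe_spearman(pred, ref) -> tuple[float, float]:
    try:
        return spearman(pred, ref)
    except Exception:
        return float("nan"), float("nan")


@dataclass
class _IterationContext:
    """Shared per-iteration artifacts reused across classifier candidates."""

    holdout: str
    model: CalibratedModel
    # in vitro, held-out cadaver, per location
    iv_meta: pd.DataFrame
    iv_pred: np.ndarray
    iv_y: np.ndarray
    # ex vivo training cadavers, per spectrum
    ex_train_meta: pd.DataFrame
    ex_train_raw: np.ndarray
    ex_train_pred: np.ndarray
    ex_train_refs: np.ndarray
    ex_train_rmsecv: float
    # ex vivo held-out cadaver, per spectrum
    ex_test_meta: pd.DataFrame
    ex_test_raw: np.ndarray
    ex_test_pred: np.ndarray
    ex_test_refs: np.ndarray
    ex_test_rows: np.ndarray  # row indices into the ex-vivo subset of the dataset


def _reference_lookup(dataset: SpectralDataset, property: str,
                      excluded: set) -> dict[tuple, float]:
    refs = dataset.references
    out = {}
    for _, row in refs.iterrows():
        key = tuple(row[c] for c in LOCATION_COLUMNS)
        value = row[property]
        if key in excluded or not np.isfinite(value):
            continue
        out[key] = float(value)
    return out


def _subset_with_refs(ds: SpectralDataset, ref_map: dict[tuple, float]):
    keys = _location_tuples(ds.meta)
    keep = np.array([k in ref_map for k in keys])
    sub = ds.subset(keep)
    refs = np.array([ref_map[k] for k, kept in zip(keys, keep) if kept])
    return sub, refs, np.flatnonzero(keep)


def run_property(dataset: SpectralDataset, property: str,
                 settings: PipelineSettings, return_detail: bool = False):
    """Full workflow for one reference property; returns its report block.

    With ``return_detail=True`` also returns the winning classifier
    candidate (with its per-iteration payload) for downstream analysis.
    """
    t0 = time.perf_counter()
    log: list[str] = []

    # ---- stage 1: reference QC -------------------------------------------
    from .spectral_data import LocationKey

    refs = dataset.references
    values = refs[property].to_numpy(dtype=float)
    locations = [LocationKey(str(r.cadaver_id), r.knee_side, r.surface, int(r.site_index))
                 for r in refs.itertuples()]
    qc = qc_property(values, locations, property, k=settings.qc_k)
    excluded = {(loc.cadaver_id, loc.knee_side, loc.surface, loc.site_index)
                for loc in qc.outlier_locations}
    for loc in qc.outlier_locations:
        log.append(f"{property}: reference outlier excluded at {loc.label()}")

    ref_map = _reference_lookup(dataset, property, excluded)

    # ---- stage 2: calibration search (in vitro) --------------------------
    search, models = leave_one_cadaver_out(
        dataset, settings.grid_for(), property,
        n_folds=settings.n_folds, max_components=settings.max_components,
        seed=settings.seed, exclude_locations=excluded, return_models=True,
    )
    selected_cv = search.result_for(search.selected)

    # ---- stage 3: per-iteration contexts ---------------------------------
    iv = dataset.select_setting("in_vitro").average_replicates()
    ex = dataset.select_setting("ex_vivo")
    contexts: list[_IterationContext] = []
    for holdout, model in models:
        iv_hold, iv_y, _ = _subset_with_refs(
            iv.subset((iv.meta["cadaver_id"].astype(str) == holdout).to_numpy()), ref_map)
        iv_pred = model.predict_matrix(iv_hold.absorbance, iv_hold.grid)

        ex_train, ex_train_refs, _ = _subset_with_refs(
            ex.subset((ex.meta["cadaver_id"].astype(str) != holdout).to_numpy()), ref_map)
        ex_train_pred = model.predict_matrix(ex_train.absorbance, ex_train.grid)

        hold_mask = (ex.meta["cadaver_id"].astype(str) == holdout).to_numpy()
        hold_rows = np.flatnonzero(hold_mask)
        ex_test, ex_test_refs, kept = _subset_with_refs(ex.subset(hold_mask), ref_map)
        ex_test_pred = model.predict_matrix(ex_test.absorbance, ex_test.grid)

        contexts.append(_IterationContext(
            holdout=holdout, model=model,
            iv_meta=iv_hold.meta, iv_pred=iv_pred, iv_y=iv_y,
            ex_train_meta=ex_train.meta, ex_train_raw=ex_train.absorbance,
            ex_train_pred=ex_train_pred,
            ex_train_refs=ex_train_refs, ex_train_rmsecv=model.rmsecv,
            ex_test_meta=ex_test.meta, ex_test_raw=ex_test.absorbance,
            ex_test_pred=ex_test_pred, ex_test_refs=ex_test_refs,
            ex_test_rows=hold_rows[kept],
        ))

    # before-exclusion ex vivo metrics, per iteration
    before_rows = []
    for ctx in contexts:
        loc_pred = _per_location_median(ctx.ex_test_meta, ctx.ex_test_pred)
        loc_keys = _location_tuples(loc_pred)
        y = np.array([ref_map[k] for k in loc_keys])
        rho, p = _safe_spearman(loc_pred["value"], y)
        before_rows.append({"cadaver": ctx.holdout, "rho": rho, "p": p,
                            "rmse": rmse(loc_pred["value"], y)})
    before = pd.DataFrame(before_rows)

    # ---- stage 4: classifier search --------------------------------------
    candidates = _evaluate_classifier_candidates(dataset, property, settings,
                                                 contexts, ref_map, log)
    winner, ranking = select_combo(candidates)
    after = winner.payload  # per-iteration DataFrame

    for _, row in after.iterrows():
        log.append(
            f"{property}: iteration {row['cadaver']}: flagged {row['outlier_s']:.1f}% "
            f"of ex vivo spectra, excluded {row['outlier_n']:.1f}% of locations "
            f"({winner.describe()})"
        )

    # ---- stage 5: report --------------------------------------------------
    report = {
        "qc": qc.to_dict(),
        "selected_preprocessing": search.selected.describe(),
        "selected_combo": winner.describe(),
        "in_vitro": {
            "train": _median_iqr_block(selected_cv.per_iteration,
                                       {"rho": "train_rho", "rmsecv": "rmsecv",
                                        "n": "n_components"}),
            "test": _median_iqr_block(selected_cv.per_iteration,
                                      {"rho": "rho", "rmse": "rmse", "p": "p"}),
            "srl": _median_iqr_block(after, {"rho": "srl_iv_rho", "rmse": "srl_iv_rmse"}),
        },
        "ex_vivo": {
            "all_test": _median_iqr_block(before, {"rho": "rho", "rmse": "rmse", "p": "p"}),
            "classifier": {
                "train": _median_iqr_block(after, {"accuracy": "accuracy", "f1": "f1"}),
                "test": _median_iqr_block(after, {"accuracy": "test_accuracy",
                                                  "f1": "test_f1"}),
                "outlier_s": _median_iqr_block(after, {"pct": "outlier_s"})["pct"],
                "outlier_n": _median_iqr_block(after, {"pct": "outlier_n"})["pct"],
                **_median_iqr_block(after, {"rho": "after_rho", "rmse": "after_rmse"}),
            },
            "srl": _median_iqr_block(after, {"rho": "srl_ev_rho", "rmse": "srl_ev_rmse"}),
        },
        "spectral_sd_reduction_pct": float(np.median(after["sd_reduction_pct"])),
        "ranking": ranking.to_dict(orient="records"),
        "per_iteration": {
            "in_vitro_test": selected_cv.per_iteration.to_dict(orient="records"),
            "ex_vivo_before": before.to_dict(orient="records"),
            "ex_vivo_after": after.drop(columns=["ex_rows", "flags"]).to_dict(orient="records"),
        },
        "elapsed_s": time.perf_counter() - t0,
        "exclusion_log": log,
    }
    if return_detail:
        return report, winner
    return report


def _evaluate_classifier_candidates(dataset, property, settings, contexts,
                                    ref_map, log) -> list[CandidateResult]:
    """Evaluate every algorithm × rule × preprocessing combination."""
    iv = dataset.select_setting("in_vitro").average_replicates()
    candidates: list[CandidateResult] = []

    for clf_config in settings.clf_configs_for(property):
        # per-iteration feature caches for this preprocessing config
        feature_cache = []
        for ctx in contexts:
            train_iv = iv.subset(
                (iv.meta["cadaver_id"].astype(str) != ctx.holdout).to_numpy())
            iv_matrix, _ = apply_config_matrix(train_iv.absorbance, train_iv.grid, clf_config)
            pca = fit_pca(iv_matrix, max_components=12)
            ex_train_matrix, _ = apply_config_matrix(ctx.ex_train_raw, dataset.grid, clf_config)
            ex_test_matrix, _ = apply_config_matrix(ctx.ex_test_raw, dataset.grid, clf_config)
            feature_cache.append((pca, project(pca, ex_train_matrix),
                                  project(pca, ex_test_matrix)))

        for rule in settings.classifier_rules:
            for algorithm in settings.classifier_algorithms:
                rows = []
                failed = False
                for ctx, (pca, train_scores, test_scores) in zip(contexts, feature_cache):
                    labels = generate_labels(ctx.ex_train_pred, ctx.ex_train_refs,
                                             ctx.ex_train_rmsecv, rule)
                    try:
                        clf = train_classifier(
                            train_scores, labels, algorithm, clf_config, rule, pca,
                            n_folds=min(10, settings.n_folds), seed=settings.seed)
                        flags, summary = classify_spectra(clf, test_scores, ctx.ex_test_meta)
                    except LabelRuleError as exc:
                        log.append(f"{property}: candidate {algorithm}/"
                                   f"{rule.describe()}/{clf_config.describe()} "
                                   f"failed on iteration {ctx.holdout}: {exc}")
                        failed = True
                        break
                    rows.append(_iteration_candidate_row(ctx, clf, flags, summary,
                                                         rule, ref_map))
                if failed or not rows:
                    continue
                frame = pd.DataFrame(rows)
                candidates.append(CandidateResult(
                    algorithm=algorithm, rule=rule, preprocess=clf_config,
                    outlier_s=float(np.median(frame["outlier_s"])),
                    srl_gap=float(np.nanmedian(frame["srl_gap"])),
                    accuracy=float(np.median(frame["accuracy"])),
                    f1=float(np.median(frame["f1"])),
                    payload=frame,
                ))
    return candidates


def _iteration_candidate_row(ctx: _IterationContext, clf, flags, summary, rule,
                             ref_map) -> dict:
    """After-exclusion metrics for one iteration of one candidate."""
    meta = ctx.ex_test_meta
    keep = flags == 0

    # after-exclusion per-location prediction: median over retained replicates
    loc_pred_after = _per_location_median(meta.loc[keep].reset_index(drop=True),
                                          ctx.ex_test_pred[keep])
    keys_after = _location_tuples(loc_pred_after)
    y_after = np.array([ref_map[k] for k in keys_after])
    after_rho, after_p = _safe_spearman(loc_pred_after["value"], y_after)
    after_rmse = rmse(loc_pred_after["value"], y_after) if len(y_after) else float("nan")

    # SRL: same retained locations, in vitro vs ex vivo
    iv_keys = _location_tuples(ctx.iv_meta)
    retained = set(keys_after)
    iv_mask = np.array([k in retained for k in iv_keys])
    srl_iv_rho, _ = _safe_spearman(ctx.iv_pred[iv_mask], ctx.iv_y[iv_mask])
    srl_iv_rmse = rmse(ctx.iv_pred[iv_mask], ctx.iv_y[iv_mask]) if iv_mask.any() else float("nan")
    srl_gap = abs(srl_iv_rho - after_rho) if np.isfinite(srl_iv_rho + after_rho) else float("nan")

    # classifier test metrics against rule-generated labels on the held-out cadaver
    test_truth = generate_labels(ctx.ex_test_pred, ctx.ex_test_refs,
                                 ctx.ex_train_rmsecv, rule)
    test_accuracy, test_f1 = classification_metrics(test_truth, flags)

    # pointwise spectral SD before vs after exclusion
    sd_before = float(np.mean(ctx.ex_test_raw.std(axis=0, ddof=1)))
    if keep.sum() >= 2:
        sd_after = float(np.mean(ctx.ex_test_raw[keep].std(axis=0, ddof=1)))
        sd_reduction = 100.0 * (1.0 - sd_after / sd_before)
    else:
        sd_reduction = float("nan")

    return {
        "cadaver": ctx.holdout,
        "accuracy": clf.train_accuracy, "f1": clf.train_f1,
        "test_accuracy": test_accuracy, "test_f1": test_f1,
        "outlier_s": summary.outlier_s, "outlier_n": summary.outlier_n,
        "after_rho": after_rho, "after_p": after_p, "after_rmse": after_rmse,
        "srl_iv_rho": srl_iv_rho, "srl_iv_rmse": srl_iv_rmse,
        "srl_ev_rho": after_rho if iv_mask.any() else float("nan"),
        "srl_ev_rmse": after_rmse,
        "srl_gap": srl_gap,
        "sd_reduction_pct": sd_reduction,
        "n_retained_locations": len(keys_after),
        # ex-vivo-subset row indices, for comparison with external truth
        "ex_rows": ctx.ex_test_rows.tolist(),
        "flags": np.asarray(flags, dtype=int).tolist(),
    }


def run_full_pipeline(source: SpectralDataset | SynthParams,
                      settings: PipelineSettings | None = None) -> RunManifest:
    """Run the whole workflow on a dataset or a synthetic-cohort spec."""
    settings = settings or PipelineSettings()
    if isinstance(source, SynthParams):
        dataset, _ = simulate_cohort(source)
    else:
        dataset = source
    manifest = RunManifest(seed=settings.seed, version=__version__, settings=settings)
    for property in settings.properties:
        t0 = time.perf_counter()
        logger.info("pipeline: property %s", property)
        report = run_property(dataset, property, settings)
        manifest.reports[property] = report
        manifest.timings[property] = time.perf_counter() - t0
        manifest.exclusion_log.extend(report["exclusion_log"])
    return manifest
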