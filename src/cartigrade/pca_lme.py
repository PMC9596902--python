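"""PCA–linear-mixed-effects calibration with nested validation.

Spectra from the same cadaver (and knee, and joint surface) are not
independent, so ordinary regression on spectral features understates
uncertainty and overfits subject idiosyncrasies.  The calibration model
here compresses preprocessed absorbance spectra to at most 12 principal
component scores and regresses the reference property on those scores
with a linear mixed-effects (LME) model carrying nested random
intercepts: cadaver, knee-within-cadaver and surface-within-knee.  The
measurement site is the observational unit and is absorbed by the
residual.

Model selection and validation are nested:

* the number of PCA components (1..12) is chosen by grouped 10-fold
  cross-validation on the training cadavers, minimising RMSECV;
* each cadaver in turn is held out entirely (leave-one-cadaver-out);
  predictions for the held-out cadaver use fixed effects only, because
  its random intercepts are unknown by construction;
* the preprocessing pipeline is chosen by the highest median Spearman ρ
  across the held-out cadavers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from statsmodels.regression.mixed_linear_model import MixedLM

from .evaluation import median_iqr, spearman, rmse
from .preprocess import PipelineGrid, PreprocessConfig, apply_config_matrix
from .spectral_data import (
    LOCATION_COLUMNS,
    CartigradeError,
    SpectralDataset,
    WavelengthGrid,
)

logger = logging.getLogger(__name__)

MAX_COMPONENTS = 12
LME_MAXITER = 500
LME_TOL = 1e-8


class LeakageError(CartigradeError):
    """A training-cadaver observation reached an independent-test path."""


class ConvergenceError(CartigradeError):
    """The LME optimizer failed to converge."""


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaModel:
    """Mean-centred orthonormal basis for spectral compression."""

    mean_spectrum: np.ndarray
    loadings: np.ndarray  # (n_components, n_wavelengths), rows orthonormal
    explained_variance: np.ndarray  # fraction per component, non-increasing
    grid: WavelengthGrid | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def fit_pca(training_matrix: np.ndarray, max_components: int = MAX_COMPONENTS,
            grid: WavelengthGrid | None = None) -> PcaModel:
    """Fit a mean-centred PCA, truncated to the matrix rank."""
    x = np.asarray(training_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("training matrix must be 2-D with ≥ 2 rows")
    centered = x - x.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if rank < 1:
        raise ValueError("training matrix has rank 0 after centering")
    k = min(max_components, rank, x.shape[0] - 1, x.shape[1])
    if k < max_components:
        logger.info("PCA components truncated from %d to rank %d", max_components, k)
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(x)
    return PcaModel(
        mean_spectrum=pca.mean_,
        loadings=pca.components_,
        explained_variance=pca.explained_variance_ratio_,
        grid=grid,
    )


def project(pca: PcaModel, spectra: np.ndarray) -> np.ndarray:
    """Scores of (centred) spectra on the stored loadings."""
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    if x.shape[-1] != pca.mean_spectrum.shape[0]:
        raise ValueError(
            f"spectra have {x.shape[-1]} wavelengths, PCA expects {pca.mean_spectrum.shape[0]}"
        )
    return (x - pca.mean_spectrum) @ pca.loadings.T


# ---------------------------------------------------------------------------
# linear mixed-effects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LmeSpec:
    """Random-intercept structure: cadaver ⊃ knee ⊃ surface."""

    cadaver: bool = True
    knee: bool = True
    surface: bool = True


@dataclass
class LmeFit:
    """REML estimates for the score-on-reference mixed model."""

    fe_params: np.ndarray  # intercept first, then one coefficient per score
    fe_cov: np.ndarray
    conf_int: np.ndarray  # (n_fe, 2) 95% intervals
    variance_components: dict[str, float]
    residual_var: float
    converged: bool
    n_obs: int
    spec: LmeSpec = field(default_factory=LmeSpec)

    def predict_fixed(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        k = len(self.fe_params) - 1
        if scores.shape[1] < k:
            raise ValueError(f"need at least {k} score columns")
        return self.fe_params[0] + scores[:, :k] @ self.fe_params[1:]


def _vc_formula(spec: LmeSpec, groups: pd.DataFrame) -> dict[str, str]:
    vcf = {}
    if spec.knee and groups["knee_side"].nunique() > 1:
        vcf["knee"] = "0 + C(knee_side)"
    if spec.surface and groups["surface"].nunique() > 1:
        vcf["surface"] = "0 + C(knee_side):C(surface)"
    return vcf


def fit_lme(scores: np.ndarray, groups: pd.DataFrame, y: np.ndarray,
            spec: LmeSpec = LmeSpec()) -> LmeFit:
    """REML fit of y on PCA scores with nested random intercepts.

    ``groups`` must carry ``cadaver_id``, ``knee_side`` and ``surface``
    columns aligned row-wise with ``scores`` and ``y``.  With a single
    cadaver in the data the cadaver variance is inestimable: a warning is
    emitted and the fit degrades to the remaining structure (ultimately
    ordinary least squares).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(groups) != scores.shape[0] or len(y) != scores.shape[0]:
        raise ValueError("scores, groups and y must align row-wise")
    k = scores.shape[1]
    df = pd.DataFrame({f"s{i + 1}": scores[:, i] for i in range(k)})
    df["y"] = y
    df["cadaver_id"] = groups["cadaver_id"].astype(str).to_numpy()
    df["knee_side"] = groups["knee_side"].astype(str).to_numpy()
    df["surface"] = groups["surface"].astype(str).to_numpy()

    single_cadaver = df["cadaver_id"].nunique() < 2
    use_spec = spec
    if spec.cadaver and single_cadaver:
        warnings.warn("single cadaver in training data: cadaver variance inestimable",
                      UserWarning, stacklevel=2)
        use_spec = LmeSpec(cadaver=False, knee=spec.knee, surface=spec.surface)

    fe_terms = " + ".join([f"s{i + 1}" for i in range(k)]) or "1"
    formula = f"y ~ {fe_terms}"

    no_random = not (use_spec.cadaver or use_spec.knee or use_spec.surface)
    if no_random or (single_cadaver and not _vc_formula(use_spec, df)):
        # all random terms structurally zero: exact reduction to OLS
        import statsmodels.formula.api as smf

        ols = smf.ols(formula, data=df).fit()
        return LmeFit(fe_params=np.asarray(ols.params),
                      fe_cov=np.asarray(ols.cov_params()),
                      conf_int=np.asarray(ols.conf_int()),
                      variance_components={}, residual_var=float(ols.mse_resid),
                      converged=True, n_obs=len(df), spec=use_spec)
    if single_cadaver:
        # cadaver grouping collapsed; promote knee to the top grouping factor
        group_col = "knee_side" if use_spec.knee and df["knee_side"].nunique() > 1 else "cadaver_id"
        model = MixedLM.from_formula(
            formula, data=df, groups=group_col, re_formula="1",
            vc_formula=_vc_formula(LmeSpec(knee=False, surface=use_spec.surface), df) or None,
        )
    else:
        groups_arg = "cadaver_id" if use_spec.cadaver else "cadaver_id"
        vcf = _vc_formula(use_spec, df)
        model = MixedLM.from_formula(
            formula, data=df, groups=groups_arg,
            re_formula="1" if use_spec.cadaver else "0",
            vc_formula=vcf or None,
        )

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        # Optimizer ladder: the statsmodels default sequence first, then
        # derivative-free methods (robust on the flat variance scale), then
        # lbfgs.  The REML surface is flat near the optimum, so an
        # optimizer-reported non-convergence with finite estimates is
        # accepted with a warning (the convention of mixed-model software);
        # only an unusable fit raises.
        result = None
        best = None
        for method in (None, ["nm", "powell"], ["lbfgs"]):
            try:
                candidate = (model.fit(reml=True, maxiter=LME_MAXITER, disp=False)
                             if method is None else
                             model.fit(reml=True, method=method, maxiter=LME_MAXITER,
                                       disp=False))
            except np.linalg.LinAlgError:
                continue
            if not np.all(np.isfinite(np.asarray(candidate.params))):
                continue
            if best is None or candidate.llf > best.llf:
                best = candidate
            if getattr(candidate, "converged", True):
                result = candidate
                break
        if result is None:
            if best is None:
                raise ConvergenceError(
                    "LME fit failed: singular covariance or non-finite estimates "
                    f"(n={len(df)}, k={k})")
            logger.info(
                "LME optimizer reported non-convergence (n=%d, k=%d); accepting the "
                "best finite fit (llf=%.4f)", len(df), k, best.llf)
            result = best
    converged = bool(getattr(result, "converged", True))
    for w in caught:
        msg = str(w.message)
        if "singular" in msg.lower() or "boundary" in msg.lower():
            logger.debug("LME variance component at/near boundary: %s", msg)

    n_fe = k + 1
    fe = np.asarray(result.params[:n_fe])
    fe_cov = np.asarray(result.cov_params())[:n_fe, :n_fe]
    ci = np.asarray(result.conf_int())[:n_fe]
    vc: dict[str, float] = {}
    if use_spec.cadaver and not single_cadaver:
        vc["cadaver"] = float(np.asarray(result.cov_re).ravel()[0])
    if result.vcomp is not None and len(result.vcomp):
        for name, value in zip(model.exog_vc.names, np.asarray(result.vcomp)):
            vc[name] = float(value)
    return LmeFit(fe_params=fe, fe_cov=fe_cov, conf_int=ci, variance_components=vc,
                  residual_var=float(result.scale), converged=converged,
                  n_obs=len(df), spec=use_spec)


# ---------------------------------------------------------------------------
# calibrated model and prediction
# ---------------------------------------------------------------------------


@dataclass
class CalibratedModel:
    """A fully fitted calibration for one reference property."""

    property: str
    preprocess: PreprocessConfig
    pca: PcaModel
    lme: LmeFit
    rmsecv: float
    n_components_selected: int
    training_cadavers: frozenset[str]
    rmsecv_curve: np.ndarray | None = None
    train_rho: float | None = None

    def predict_matrix(self, absorbance: np.ndarray, grid: WavelengthGrid) -> np.ndarray:
        """Preprocess raw spectra with the stored config and predict (fixed only)."""
        x, _ = apply_config_matrix(absorbance, grid, self.preprocess)
        scores = project(self.pca, x)
        return self.lme.predict_fixed(scores[:, : self.n_components_selected])

    def to_dict(self) -> dict:
        """Versioned JSON-serializable snapshot of the calibrated model."""
        cfg = self.preprocess
        return {
            "schema_version": 1,
            "property": self.property,
            "preprocess": {
                "scatter": cfg.scatter, "lsnv_window": cfg.lsnv_window,
                "sg_deriv": cfg.sg_deriv, "sg_window": cfg.sg_window,
                "sg_degree": cfg.sg_degree, "ranges": [list(r) for r in cfg.ranges],
            },
            "pca": {
                "mean_spectrum": self.pca.mean_spectrum.tolist(),
                "loadings": self.pca.loadings.tolist(),
                "explained_variance": self.pca.explained_variance.tolist(),
            },
            "lme": {
                "fe_params": self.lme.fe_params.tolist(),
                "variance_components": self.lme.variance_components,
                "residual_var": self.lme.residual_var,
                "converged": self.lme.converged,
            },
            "rmsecv": self.rmsecv,
            "n_components_selected": self.n_components_selected,
            "training_cadavers": sorted(self.training_cadavers),
            "rmsecv_curve": (self.rmsecv_curve.tolist()
                             if self.rmsecv_curve is not None else None),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "CalibratedModel":
        if doc.get("schema_version") != 1:
            raise ValueError(f"unsupported model schema {doc.get('schema_version')!r}")
        from .preprocess import PreprocessConfig

        cfg = PreprocessConfig(
            scatter=doc["preprocess"]["scatter"],
            lsnv_window=doc["preprocess"]["lsnv_window"],
            sg_deriv=doc["preprocess"]["sg_deriv"],
            sg_window=doc["preprocess"]["sg_window"],
            sg_degree=doc["preprocess"]["sg_degree"],
            ranges=tuple(tuple(r) for r in doc["preprocess"]["ranges"]),
        )
        pca = PcaModel(
            mean_spectrum=np.asarray(doc["pca"]["mean_spectrum"]),
            loadings=np.asarray(doc["pca"]["loadings"]),
            explained_variance=np.asarray(doc["pca"]["explained_variance"]),
        )
        fe = np.asarray(doc["lme"]["fe_params"])
        lme = LmeFit(
            fe_params=fe, fe_cov=np.full((len(fe), len(fe)), np.nan),
            conf_int=np.full((len(fe), 2), np.nan),
            variance_components=dict(doc["lme"]["variance_components"]),
            residual_var=float(doc["lme"]["residual_var"]),
            converged=bool(doc["lme"]["converged"]), n_obs=0,
        )
        curve = doc.get("rmsecv_curve")
        return cls(
            property=doc["property"], preprocess=cfg, pca=pca, lme=lme,
            rmsecv=float(doc["rmsecv"]),
            n_components_selected=int(doc["n_components_selected"]),
            training_cadavers=frozenset(doc["training_cadavers"]),
            rmsecv_curve=np.asarray(curve) if curve is not None else None,
        )


def predict_fixed(model: CalibratedModel, dataset: SpectralDataset,
                  allow_training: bool = False) -> pd.DataFrame:
    """Fixed-effects predictions for every spectrum of a dataset.

    Random intercepts are unknown for unseen cadavers and set to their
    zero mean.  By default, passing spectra from a training cadaver
    raises :class:`LeakageError`; internal label-generation paths opt out
    explicitly.
    """
    cadavers = set(dataset.meta["cadaver_id"].astype(str))
    overlap = cadavers & set(model.training_cadavers)
    if overlap and not allow_training:
        raise LeakageError(f"spectra from training cadaver(s) {sorted(overlap)} "
                           "passed to independent-test prediction")
    pred = model.predict_matrix(dataset.absorbance, dataset.grid)
    out = dataset.meta.copy()
    out["prediction"] = pred
    return out


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def _location_design(dataset: SpectralDataset, property: str,
                     exclude_locations: set | None = None):
    """Per-location rows: metadata, raw spectra matrix and reference values.

    Expects a replicate-averaged dataset (one row per location); rows
    with a missing or excluded reference are dropped.
    """
    refs = dataset.reference_frame()
    y = refs[property].to_numpy(dtype=float)
    keep = np.isfinite(y)
    if exclude_locations:
        loc_tuples = list(map(tuple, dataset.meta[LOCATION_COLUMNS].itertuples(index=False)))
        keep &= np.array([t not in exclude_locations for t in loc_tuples])
    meta = dataset.meta.loc[keep].reset_index(drop=True)
    return meta, dataset.absorbance[np.flatnonzero(keep)], y[keep]


def _grouped_folds(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffled partition of location rows into ``n_folds`` folds."""
    order = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(order, n_folds)]


@dataclass
class RmsecvResult:
    """RMSECV per candidate component count, and the selected count."""

    component_counts: np.ndarray
    rmsecv: np.ndarray
    selected: int

    @property
    def selected_rmsecv(self) -> float:
        return float(self.rmsecv[self.selected - int(self.component_counts[0])])


def kfold_rmsecv_scores(meta: pd.DataFrame, matrix: np.ndarray, y: np.ndarray,
                        n_folds: int = 10, max_components: int = MAX_COMPONENTS,
                        seed: int = 0, spec: LmeSpec = LmeSpec()) -> RmsecvResult:
    """Grouped k-fold RMSECV over candidate PCA component counts.

    Operates on a per-location design (one row per measurement location).
    PCA is refit inside every fold; held-out predictions use fixed
    effects only.  The selected count attains the minimum RMSECV; ties go
    to the smaller count.
    """
    n = len(y)
    if n < n_folds:
        raise ValueError(f"{n} locations < {n_folds} folds")
    rng = np.random.default_rng(seed)
    folds = _grouped_folds(n, n_folds, rng)
    sse = None
    counts = None
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        pca = fit_pca(matrix[train_mask], max_components)
        k_max = min(max_components, pca.n_components)
        if counts is None:
            counts = np.arange(1, k_max + 1)
            sse = np.zeros(k_max)
        elif k_max < len(counts):
            counts = counts[:k_max]
            sse = sse[:k_max]
        scores_train = project(pca, matrix[train_mask])
        scores_test = project(pca, matrix[test_idx])
        groups_train = meta.loc[train_mask].reset_index(drop=True)
        for j, k in enumerate(counts):
            fit = fit_lme(scores_train[:, :k], groups_train, y[train_mask], spec)
            pred = fit.predict_fixed(scores_test[:, :k])
            sse[j] += float(np.sum((pred - y[test_idx]) ** 2))
    curve = np.sqrt(sse / n)
    selected = int(counts[int(np.argmin(curve))])  # argmin → first = smallest count
    return RmsecvResult(component_counts=counts, rmsecv=curve, selected=selected)


def kfold_rmsecv(dataset: SpectralDataset, config: PreprocessConfig, property: str,
                 n_folds: int = 10, max_components: int = MAX_COMPONENTS, seed: int = 0,
                 exclude_locations: set | None = None) -> RmsecvResult:
    """Preprocess an in-vitro dataset and run grouped k-fold RMSECV."""
    avg = dataset.average_replicates("in_vitro")
    meta, matrix_raw, y = _location_design(avg, property, exclude_locations)
    matrix, _ = apply_config_matrix(matrix_raw, avg.grid, config)
    return kfold_rmsecv_scores(meta, matrix, y, n_folds, max_components, seed)


def fit_calibrated_model(meta: pd.DataFrame, matrix_raw: np.ndarray, grid: WavelengthGrid,
                         y: np.ndarray, property: str, config: PreprocessConfig,
                         n_folds: int = 10, max_components: int = MAX_COMPONENTS,
                         seed: int = 0) -> CalibratedModel:
    """Select the component count by RMSECV, then fit on all rows."""
    matrix, out_grid = apply_config_matrix(matrix_raw, grid, config)
    cv = kfold_rmsecv_scores(meta, matrix, y, n_folds, max_components, seed)
    pca = fit_pca(matrix, max_components, grid=out_grid)
    scores = project(pca, matrix)
    k = min(cv.selected, pca.n_components)
    fit = fit_lme(scores[:, :k], meta, y)
    train_pred = fit.predict_fixed(scores[:, :k])
    train_rho, _ = spearman(train_pred, y)
    return CalibratedModel(
        property=property, preprocess=config, pca=pca, lme=fit,
        rmsecv=cv.selected_rmsecv, n_components_selected=k,
        training_cadavers=frozenset(meta["cadaver_id"].astype(str)),
        rmsecv_curve=cv.rmsecv, train_rho=train_rho,
    )


@dataclass
class CvResult:
    """Leave-one-cadaver-out outcome for one preprocessing config."""

    config: PreprocessConfig
    per_iteration: pd.DataFrame  # cadaver, rho, p, rmse, n_components, rmsecv
    failed: bool = False
    failure_reason: str | None = None

    def median_test_rho(self) -> float:
        return float(np.median(self.per_iteration["rho"]))

    def summary(self) -> dict:
        out = {}
        for col in ("rho", "p", "rmse", "n_components", "rmsecv"):
            med, iqr = median_iqr(self.per_iteration[col])
            out[col] = {"median": med, "iqr": iqr}
        return out


@dataclass
class SearchResult:
    """Grid-search outcome: per-config CV results and the winner."""

    results: list[CvResult]
    selected: PreprocessConfig

    def result_for(self, config: PreprocessConfig) -> CvResult:
        for r in self.results:
            if r.config == config:
                return r
        raise KeyError(config)


def loco_iteration_models(
    dataset: SpectralDataset, config: PreprocessConfig, property: str,
    n_folds: int = 10, max_components: int = MAX_COMPONENTS, seed: int = 0,
    exclude_locations: set | None = None,
) -> list[tuple[str, CalibratedModel]]:
    """One calibrated model per leave-one-cadaver-out iteration.

    Each model is trained on the in-vitro (replicate-averaged) spectra of
    every cadaver except the held-out one.
    """
    avg = dataset.average_replicates("in_vitro")
    meta_all, matrix_all, y_all = _location_design(avg, property, exclude_locations)
    cadavers = sorted(meta_all["cadaver_id"].astype(str).unique())
    if len(cadavers) < 3:
        raise ValueError("leave-one-cadaver-out requires ≥ 3 cadavers")
    models = []
    for i, holdout in enumerate(cadavers):
        train_mask = (meta_all["cadaver_id"].astype(str) != holdout).to_numpy()
        model = fit_calibrated_model(
            meta_all.loc[train_mask].reset_index(drop=True), matrix_all[train_mask],
            avg.grid, y_all[train_mask], property, config,
            n_folds=n_folds, max_components=max_components, seed=seed + i,
        )
        models.append((holdout, model))
    return models


def leave_one_cadaver_out(
    dataset: SpectralDataset, grid: PipelineGrid | list[PreprocessConfig], property: str,
    n_folds: int = 10, max_components: int = MAX_COMPONENTS, seed: int = 0,
    exclude_locations: set | None = None, return_models: bool = False,
):
    """Pipeline search by nested leave-one-cadaver-out validation.

    For every candidate config, each cadaver is held out once; component
    count is selected by grouped k-fold RMSECV inside the training
    cadavers; the held-out cadaver is predicted with fixed effects only.
    The config with the highest median held-out Spearman ρ wins.
    Configs whose preprocessing fails on any spectrum are marked failed
    and excluded from selection.
    """
    avg = dataset.average_replicates("in_vitro")
    meta_all, matrix_all, y_all = _location_design(avg, property, exclude_locations)
    cadavers = sorted(meta_all["cadaver_id"].astype(str).unique())
    if len(cadavers) < 3:
        raise ValueError("leave-one-cadaver-out requires ≥ 3 cadavers")
    results: list[CvResult] = []
    kept_models: dict[PreprocessConfig, list[tuple[str, CalibratedModel]]] = {}
    for config in grid:
        rows = []
        models = []
        try:
            for i, holdout in enumerate(cadavers):
                train_mask = (meta_all["cadaver_id"].astype(str) != holdout).to_numpy()
                test_mask = ~train_mask
                model = fit_calibrated_model(
                    meta_all.loc[train_mask].reset_index(drop=True), matrix_all[train_mask],
                    avg.grid, y_all[train_mask], property, config,
                    n_folds=n_folds, max_components=max_components, seed=seed + i,
                )
                pred = model.predict_matrix(matrix_all[test_mask], avg.grid)
                rho, p = spearman(pred, y_all[test_mask])
                rows.append({
                    "cadaver": holdout, "rho": rho, "p": p,
                    "rmse": rmse(pred, y_all[test_mask]),
                    "n_components": model.n_components_selected,
                    "rmsecv": model.rmsecv, "train_rho": model.train_rho,
                })
                models.append((holdout, model))
        except CartigradeError as exc:
            logger.warning("config %s failed: %s", config.describe(), exc)
            results.append(CvResult(config=config, per_iteration=pd.DataFrame(),
                                    failed=True, failure_reason=str(exc)))
            continue
        results.append(CvResult(config=config, per_iteration=pd.DataFrame(rows)))
        kept_models[config] = models
    survivors = [r for r in results if not r.failed]
    if not survivors:
        raise CartigradeError("every candidate preprocessing config failed")
    best = max(survivors, key=lambda r: r.median_test_rho())
    search = SearchResult(results=results, selected=best.config)
    if return_models:
        return search, kept_models[best.config]
    return search
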