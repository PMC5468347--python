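"""Automated model selection with bias-corrected performance estimation.

The training pipeline mirrors standard automated-ML practice for omics-scale
tabular data:

1. a *configuration grid* — combinations of feature-selection
   hyper-parameters (significance level alpha, max signature size) with
   classifier families (ridge logistic regression; linear / polynomial /
   Gaussian SVMs; random forests) and their hyper-parameter values;
2. stratified K-fold cross-validation scoring every configuration on
   out-of-fold samples (N x K model fits);
3. selection of the best configuration by mean cross-validated AUC and a
   final fit on all data (the +1 fit, so N*K + 1 in total);
4. bootstrap bias correction (BBC): because the best of N configurations
   was *selected*, its cross-validated AUC is optimistic.  For each of B
   bootstrap resamples of the pooled out-of-fold score matrix the winning
   configuration is re-chosen on the in-bag samples and scored on the
   out-of-bag samples; the mean of those B out-of-bag AUCs is the corrected
   estimate, with percentile confidence intervals.

Feature selection ("SES-lite") is forward-backward selection driven by
Fisher-z conditional-independence tests: at each step the candidate with
the strongest partial correlation with the class given the currently
selected set enters if significant at alpha, until nothing passes or the
max-features cut-off is reached; a backward sweep then re-tests each
selected feature given the others.  Statistically equivalent substitutes
(near-collinear with a selected feature) are recorded as alternate
signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .encoders import FeatureMatrix, build_feature_matrix
from .metrics import auc, auc_columns, equal_error_threshold
from .models import TrainedModel, encode_payload
from .seqio import (
    DEFAULT_W_MAT,
    DEFAULT_W_PRE,
    SequenceRecord,
    Window,
    extract_window,
    window_from_position,
)

# ---------------------------------------------------------------------------
# configuration grid


@dataclass(frozen=True)
class SelectorSpec:
    """Feature-selection hyper-parameters."""

    alpha: float = 0.05
    max_features: int = 50
    max_cond: Optional[int] = None  # None = condition on the full selected set

    def key(self):
        return (self.alpha, self.max_features, self.max_cond)


@dataclass(frozen=True)
class Configuration:
    selector: SelectorSpec
    family: str
    params: tuple  # sorted (name, value) pairs

    @property
    def id(self) -> str:
        pstr = ",".join(f"{k}={v}" for k, v in self.params)
        sel = self.selector
        return f"ses(a={sel.alpha},f={sel.max_features})|{self.family}({pstr})"


LINEAR_ONLY_FAMILIES = ("ridge-logistic", "linear-svm")


def make_config_grid(spec: dict, linear_only: bool = False) -> list[Configuration]:
    """Cartesian product of selector settings and classifier settings.

    ``spec`` either lists explicit ``selectors`` (dicts with alpha /
    max_features / max_cond) or gives ``alphas`` and ``max_features`` value
    lists which are crossed.  ``classifiers`` is a list of dicts with a
    ``family`` key plus hyper-parameter values.  Order is deterministic:
    selectors outer, classifiers inner, as given.
    """
    if "selectors" in spec:
        selectors = [SelectorSpec(**s) for s in spec["selectors"]]
    else:
        selectors = [
            SelectorSpec(alpha=a, max_features=m)
            for a, m in product(spec["alphas"], spec["max_features"])
        ]
    classifiers = spec.get("classifiers", [])
    if linear_only:
        classifiers = [c for c in classifiers if c["family"] in LINEAR_ONLY_FAMILIES]
    grid = [
        Configuration(
            selector=sel,
            family=clf["family"],
            params=tuple(sorted((k, v) for k, v in clf.items() if k != "family")),
        )
        for sel in selectors
        for clf in classifiers
    ]
    if not grid:
        raise ValueError("empty configuration grid")
    return grid


def default_grid(linear_only: bool = False) -> list[Configuration]:
    """The default grid: 2 selector settings x 14 classifier settings (N=28);
    with ``linear_only`` only ridge-logistic and linear-SVM remain (N=12)."""
    classifiers = (
        [{"family": "ridge-logistic", "penalty": lam} for lam in (0.1, 1.0, 10.0)]
        + [{"family": "linear-svm", "C": c} for c in (0.1, 1.0, 10.0)]
        + [{"family": "polynomial-svm", "C": c, "degree": 3} for c in (0.1, 1.0, 10.0)]
        + [{"family": "gaussian-svm", "C": c} for c in (0.1, 1.0, 10.0)]
        + [
            {"family": "random-forest", "n_estimators": 500, "max_depth": d}
            for d in (None, 8)
        ]
    )
    spec = {
        "selectors": [
            {"alpha": 0.01, "max_features": 25},
            {"alpha": 0.05, "max_features": 50},
        ],
        "classifiers": classifiers,
    }
    return make_config_grid(spec, linear_only=linear_only)


# ---------------------------------------------------------------------------
# SES-lite feature selection


@dataclass
class SelectionResult:
    primary: list  # column indices, in selection order
    alternates: list = field(default_factory=list)  # alternate signatures
    substitutes: dict = field(default_factory=dict)  # selected idx -> equivalents


def _standardize_columns(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / safe, mu, sd


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    selector: SelectorSpec = SelectorSpec(),
    record_equivalents: bool = False,
    equiv_corr: float = 0.95,
) -> SelectionResult:
    """Forward-backward conditional-independence feature selection.

    Forward phase: repeatedly add the candidate with the largest partial
    correlation with ``y`` given the selected set (computed by
    orthogonalising all columns against the selected ones), provided its
    Fisher-z p-value is below ``selector.alpha``; stop at
    ``selector.max_features``.  Backward phase: one sweep re-testing each
    selected feature conditional on the others; non-significant features
    are dropped.  With ``record_equivalents`` candidates nearly collinear
    with a chosen feature (|r| >= ``equiv_corr``) are reported as
    statistically equivalent substitutes and expanded into alternate
    signatures.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    Xs, _, sd = _standardize_columns(X)
    valid = sd > 0
    ys = y - y.mean()
    ynorm = np.linalg.norm(ys)
    if ynorm == 0:
        return SelectionResult(primary=[])
    ys = ys / ynorm

    R = Xs.copy()
    ry = ys.copy()
    selected: list[int] = []
    substitutes: dict[int, list[int]] = {}
    alpha = selector.alpha
    tol = 1e-9

    while len(selected) < selector.max_features:
        cond = len(selected)
        if selector.max_cond is not None:
            cond = min(cond, selector.max_cond)
        df = n - cond - 3
        if df <= 0:
            break
        rnorm = np.linalg.norm(R, axis=0)
        rynorm = np.linalg.norm(ry)
        if rynorm < tol:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (R.T @ ry) / (rnorm * rynorm)
        r[~np.isfinite(r)] = 0.0
        r[rnorm < tol] = 0.0
        r[~valid] = 0.0
        if selected:
            r[selected] = 0.0
        best = int(np.argmax(np.abs(r)))
        rb = min(abs(r[best]), 1.0 - 1e-12)
        z = np.arctanh(rb) * np.sqrt(df)
        pval = 2.0 * norm.sf(z)
        if pval > alpha:
            break
        if record_equivalents:
            c = Xs.T @ Xs[:, best] / n
            eq = [
                int(j)
                for j in np.flatnonzero(np.abs(c) >= equiv_corr)
                if j != best and j not in selected and valid[j]
            ]
            if eq:
                substitutes[best] = eq
        q = R[:, best] / rnorm[best]
        R -= np.outer(q, q @ R)
        ry = ry - q * float(q @ ry)
        R[:, best] = 0.0
        selected.append(best)

    # backward sweep: drop features that lost significance given the others
    if len(selected) > 1:
        keep = list(selected)
        for f in list(selected):
            others = [g for g in keep if g != f]
            if not others:
                continue
            B = Xs[:, others]
            coef_f, _, _, _ = np.linalg.lstsq(B, Xs[:, f], rcond=None)
            coef_y, _, _, _ = np.linalg.lstsq(B, ys, rcond=None)
            res_f = Xs[:, f] - B @ coef_f
            res_y = ys - B @ coef_y
            nf, ny = np.linalg.norm(res_f), np.linalg.norm(res_y)
            if nf < tol or ny < tol:
                continue
            rpart = float(res_f @ res_y) / (nf * ny)
            df = n - len(others) - 3
            if df <= 0:
                continue
            z = np.arctanh(min(abs(rpart), 1.0 - 1e-12)) * np.sqrt(df)
            if 2.0 * norm.sf(z) > alpha:
                keep.remove(f)
        selected = keep
        substitutes = {f: s for f, s in substitutes.items() if f in selected}

    alternates = []
    for f, subs in substitutes.items():
        for s in subs[:5]:
            alternates.append([s if g == f else g for g in selected])
    return SelectionResult(primary=selected, alternates=alternates, substitutes=substitutes)


# ---------------------------------------------------------------------------
# classifier fitting


def _calibrated(svc: SVC) -> CalibratedClassifierCV:
    # SVMs have no native probability; Platt-scale the decision values
    return CalibratedClassifierCV(svc, method="sigmoid", ensemble=False, cv=5)


def _make_estimator(cfg: Configuration, seed: int):
    params = dict(cfg.params)
    if cfg.family == "ridge-logistic":
        lam = params.get("penalty", 1.0)
        # l2-regularised logistic regression; C is the inverse ridge penalty
        return LogisticRegression(C=1.0 / lam, solver="lbfgs", max_iter=5000)
    if cfg.family == "linear-svm":
        return _calibrated(SVC(kernel="linear", C=params.get("C", 1.0),
                               random_state=seed))
    if cfg.family == "polynomial-svm":
        return _calibrated(SVC(kernel="poly", degree=params.get("degree", 3),
                               C=params.get("C", 1.0), random_state=seed))
    if cfg.family == "gaussian-svm":
        return _calibrated(SVC(kernel="rbf", C=params.get("C", 1.0),
                               random_state=seed))
    if cfg.family == "random-forest":
        return RandomForestClassifier(
            n_estimators=params.get("n_estimators", 500),
            max_depth=params.get("max_depth", None),
            random_state=seed,
        )
    raise ValueError(f"unknown family {cfg.family!r}")


def _fit_and_score(cfg, Xtr, ytr, Xte, seed):
    """Fit one configuration's classifier; return (probabilities, estimator).

    Empty feature sets fall back to an intercept-only model (constant class
    prior)."""
    if Xtr.shape[1] == 0:
        prior = float(np.clip(ytr.mean(), 1e-6, 1 - 1e-6))
        return np.full(Xte.shape[0], prior), None
    est = _make_estimator(cfg, seed)
    est.fit(Xtr, ytr.astype(int))
    proba = est.predict_proba(Xte)
    positive = list(est.classes_).index(1)
    return proba[:, positive], est


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    oof: np.ndarray  # (n_samples, n_configs) out-of-fold probabilities
    fold_of: np.ndarray  # (n_samples,) fold index of each sample
    mean_fold_auc: np.ndarray  # (n_configs,) mean per-fold AUC
    pooled_auc: np.ndarray  # (n_configs,) AUC of pooled out-of-fold scores
    grid: list
    n_fits: int
    selections: dict  # (fold, selector key) -> list of column indices
    K: int = 10
    seed: int = 0

    def best_index(self) -> int:
        return int(np.argmax(self.mean_fold_auc))  # ties -> earlier config


def cross_validate(
    X,
    y,
    grid: Sequence[Configuration],
    K: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified K-fold CV of every configuration.

    Standardisation and feature selection are fit on the training folds
    only; selection runs once per (fold, selector setting) and is shared by
    the configurations using that selector.  Every sample is scored exactly
    once per configuration.
    """
    if isinstance(X, FeatureMatrix):
        X = X.values
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=bool)
    n = y.size
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if min(n_pos, n_neg) < K:
        raise ValueError(
            f"smallest class has {min(n_pos, n_neg)} members < K={K}; use a smaller K"
        )
    grid = list(grid)
    N = len(grid)
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    oof = np.empty((n, N), dtype=np.float64)
    fold_of = np.empty(n, dtype=int)
    selections: dict = {}
    n_fits = 0

    by_selector: dict = {}
    for ci, cfg in enumerate(grid):
        by_selector.setdefault(cfg.selector, []).append(ci)

    for fold, (tr, te) in enumerate(skf.split(X, y.astype(int))):
        fold_of[te] = fold
        Xtr_raw, Xte_raw = X[tr], X[te]
        mu = Xtr_raw.mean(axis=0)
        sd = Xtr_raw.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        for selector, cfg_indices in by_selector.items():
            sel = select_features(Xtr_raw, y[tr], selector).primary
            selections[(fold, selector.key())] = list(sel)
            Xtr = (Xtr_raw[:, sel] - mu[sel]) / sd_safe[sel]
            Xte = (Xte_raw[:, sel] - mu[sel]) / sd_safe[sel]
            for ci in cfg_indices:
                scores, _ = _fit_and_score(
                    grid[ci], Xtr, y[tr], Xte, seed=seed * 1000 + fold
                )
                oof[te, ci] = scores
                n_fits += 1

    mean_fold = np.zeros(N)
    for fold in range(len(np.unique(fold_of))):
        mask = fold_of == fold
        mean_fold += auc_columns(oof[mask], y[mask])
    mean_fold /= K
    pooled = auc_columns(oof, y)
    return CVResult(
        oof=oof,
        fold_of=fold_of,
        mean_fold_auc=mean_fold,
        pooled_auc=pooled,
        grid=grid,
        n_fits=n_fits,
        selections=selections,
        K=K,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# finalisation and bootstrap bias correction


@dataclass
class FinalFit:
    config: Configuration
    selected: list  # column indices
    mu: np.ndarray
    sd: np.ndarray
    estimator: object
    threshold: float
    selection: SelectionResult
    n_fits_total: int


def select_and_finalize(X, y, cv: CVResult, seed: int = 0) -> FinalFit:
    """Pick the best configuration, refit on all data, set the decision
    threshold for equal sensitivity/specificity on its out-of-fold scores."""
    if isinstance(X, FeatureMatrix):
        X = X.values
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=bool)
    best = cv.best_index()
    cfg = cv.grid[best]
    selres = select_features(X, y, cfg.selector, record_equivalents=True)
    sel = selres.primary
    mu = X[:, sel].mean(axis=0)
    sd = X[:, sel].std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xz = (X[:, sel] - mu) / sd_safe
    _, est = _fit_and_score(cfg, Xz, y, Xz, seed=seed)
    threshold = equal_error_threshold(cv.oof[:, best], y)
    return FinalFit(
        config=cfg,
        selected=list(sel),
        mu=mu,
        sd=sd,
        estimator=est,
        threshold=threshold,
        selection=selres,
        n_fits_total=cv.n_fits + 1,
    )


def bbc_correct(
    oof,
    y,
    B: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
    max_retries: int = 10,
):
    """Bootstrap bias correction of the selected configuration's AUC.

    For each bootstrap resample of sample indices, the best configuration on
    the in-bag rows of the pooled out-of-fold score matrix is chosen and
    evaluated on the out-of-bag rows; the corrected estimate is the mean of
    those out-of-bag AUCs, with a percentile confidence interval.  Replicates
    whose in-bag or out-of-bag part lacks a class are redrawn (bounded
    retries), then skipped.

    Returns (corrected_auc, (lo, hi), n_skipped).
    """
    if isinstance(oof, CVResult):
        oof = oof.oof
    S = np.asarray(oof, dtype=np.float64)
    y = np.asarray(y, dtype=bool)
    n = y.size
    rng = np.random.default_rng(seed)
    out = []
    skipped = 0
    for _ in range(B):
        for _ in range(max_retries):
            idx = rng.integers(0, n, size=n)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            if 0 < y[idx].sum() < n and y[oob].any() and (~y[oob]).any():
                break
        else:
            skipped += 1
            continue
        best = int(np.argmax(auc_columns(S[idx], y[idx])))
        out.append(auc(S[oob, best], y[oob]))
    out = np.asarray(out)
    lo, hi = np.percentile(out, [(1 - ci) / 2 * 100, (1 + ci) / 2 * 100])
    return float(out.mean()), (float(lo), float(hi)), skipped


# ---------------------------------------------------------------------------
# high-level training entry point


def training_windows(
    records: Sequence[SequenceRecord], view: str, W: Optional[int] = None
) -> tuple[list[Window], np.ndarray]:
    """Windows + binary labels (secretory=True) for a training run.

    Preprotein view: everything windowed from position 1.  Mature view:
    secretory records windowed from cleavage_pos+3; cytoplasmic records,
    which have no signal peptide, from position 1 (their whole chain is
    "mature").  Records labelled neither secretory nor cytoplasmic are
    excluded.
    """
    if view not in ("preprotein", "mature"):
        raise ValueError(f"unknown view {view!r}")
    W = W or (DEFAULT_W_PRE if view == "preprotein" else DEFAULT_W_MAT)
    windows, labels = [], []
    for rec in records:
        if rec.label == "secretory":
            if view == "mature":
                windows.append(extract_window(rec, "mature", W))
            else:
                windows.append(extract_window(rec, "preprotein", W))
            labels.append(True)
        elif rec.label == "cytoplasmic":
            windows.append(window_from_position(rec, view, W, 1))
            labels.append(False)
    if not windows:
        raise ValueError("no labelled records to train on")
    return windows, np.asarray(labels, dtype=bool)


def train_view(
    records: Sequence[SequenceRecord],
    view: str,
    groups: Optional[Sequence[str]] = None,
    grid: Optional[Sequence[Configuration]] = None,
    K: int = 10,
    seed: int = 0,
    W: Optional[int] = None,
    bbc_B: int = 1000,
    linear_only: bool = False,
    energy_model=None,
    cpseaac_scale: str = "K/D",
    cpseaac_lam: int = 5,
    cpseaac_w: float = 0.05,
) -> TrainedModel:
    """Full pipeline: windows -> features -> CV -> finalise -> BBC -> model."""
    windows, y = training_windows(records, view, W)
    fm = build_feature_matrix(
        windows,
        groups=groups,
        energy_model=energy_model,
        cpseaac_scale=cpseaac_scale,
        cpseaac_lam=cpseaac_lam,
        cpseaac_w=cpseaac_w,
    )
    grid = list(grid) if grid is not None else default_grid(linear_only=linear_only)
    cv = cross_validate(fm.values, y, grid, K=K, seed=seed)
    fit = select_and_finalize(fm.values, y, cv, seed=seed)

    corrected, ci_bounds, _ = (None, None, 0)
    if bbc_B > 0:
        corrected, ci_bounds, _ = bbc_correct(cv.oof, y, B=bbc_B, seed=seed)

    names = [fm.feature_names[i] for i in fit.selected]
    alt_names = [
        [fm.feature_names[i] for i in sig] for sig in fit.selection.alternates
    ]
    cfg = fit.config
    coefficients = intercept = payload = None
    if fit.estimator is None:
        family = "intercept"
        prior = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
        intercept = float(np.log(prior / (1 - prior)))
    elif cfg.family == "ridge-logistic":
        family = cfg.family
        coefficients = fit.estimator.coef_.ravel().tolist()
        intercept = float(fit.estimator.intercept_[0])
    elif cfg.family == "linear-svm":
        # linear SVM decisions are a hyperplane too, but probabilities come
        # from Platt scaling, so keep the fitted payload alongside the plane
        family = cfg.family
        svc = fit.estimator.calibrated_classifiers_[0].estimator
        coefficients = svc.coef_.ravel().tolist()
        intercept = float(svc.intercept_[0])
        payload = encode_payload(fit.estimator)
    else:
        family = cfg.family
        payload = encode_payload(fit.estimator)

    best = cv.best_index()
    return TrainedModel(
        view=view,
        window_length=windows[0].length,
        groups=list(fm.manifest.keys()),
        selected_features=names,
        means=fit.mu.tolist(),
        sds=fit.sd.tolist(),
        family=family,
        params=dict(cfg.params),
        threshold=fit.threshold,
        coefficients=coefficients,
        intercept=intercept,
        payload_b64=payload,
        cv_auc=float(cv.pooled_auc[best]),
        corrected_auc=corrected,
        auc_ci=list(ci_bounds) if ci_bounds else None,
        alternate_signatures=alt_names,
        cpseaac={"scale": cpseaac_scale, "lam": cpseaac_lam, "w": cpseaac_w},
        provenance={
            "config_id": cfg.id,
            "seed": seed,
            "K": K,
            "n_configs": len(grid),
            "n_fits": fit.n_fits_total,
            "mean_fold_auc": float(cv.mean_fold_auc[best]),
        },
    )


def split_holdout(records, fraction: float = 0.2, seed: int = 0):
    """Stratified train/holdout split of records (convenience utility)."""
    rng = np.random.default_rng(seed)
    by_label: dict = {}
    for i, rec in enumerate(records):
        by_label.setdefault(rec.label, []).append(i)
    hold = set()
    for idxs in by_label.values():
        idxs = np.array(idxs)
        take = int(round(len(idxs) * fraction))
        hold.update(rng.permutation(idxs)[:take].tolist())
    train = [r for i, r in enumerate(records) if i not in hold]
    test = [r for i, r in enumerate(records) if i in hold]
    return train, test
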