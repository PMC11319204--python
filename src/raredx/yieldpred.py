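"""Diagnostic-yield prediction from phenotype groups.

The solved/unsolved status of each exome-sequenced case is regressed on
the 49 phenotype-subcategory indicators with an L1 (lasso) penalty while
the confounders -- age class, sex, sequencing site and the image-analysis
consent flag -- enter unpenalized.  Variable selection therefore acts on
the phenotype groups only.  The model minimizes

    -(1/n) loglik(beta) + lambda * sum_j w_j |beta_j|

with penalty factors w_j = 1 for the subcategory indicators and w_j = 0
for the intercept and confounders.  The path is fitted by iteratively
reweighted least squares with cyclic coordinate descent, warm-started
along a descending log-spaced lambda grid; the penalty parameter is tuned
by stratified k-fold cross-validation on the out-of-fold binomial
deviance (minimum-deviance rule by default, one-standard-error rule by
flag).  Binary indicator columns are not standardized so coefficients
remain interpretable on the log-odds scale.

Prediction for a new case imputes any unsupplied confounder with its
training-cohort mean, evaluation uses the ROC AUC (Mann-Whitney with tie
correction, percentile-bootstrap CI), and the per-term discriminatory AUC
of a single binary phenotype indicator has the closed form
(sensitivity + specificity) / 2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

__all__ = [
    "DesignMatrix",
    "PenalizedLogisticModel",
    "build_design",
    "fit_path",
    "cv_select",
    "predict_yield",
    "roc_auc",
    "per_term_auc",
    "export_paths",
    "plot_paths",
    "kkt_max_violation",
    "split_cohort",
    "SeparationWarning",
]

DEFAULT_N_LAMBDA = 100
DEFAULT_LAMBDA_MIN_RATIO = 1e-3
DEFAULT_TRAIN_FRACTION = 1256 / 1577  # reference cohort split


class SeparationWarning(UserWarning):
    """Raised when the unpenalized end of the path shows complete
    separation (coefficients diverging)."""


@dataclass
class DesignMatrix:
    """Encoded design: penalized indicator block + unpenalized confounders."""

    X: pd.DataFrame
    y: np.ndarray
    penalty_factors: np.ndarray
    penalized: list[str]
    confounders: list[str]
    site_levels: list[str] = field(default_factory=list)

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)


def build_design(
    cohort: pd.DataFrame,
    indicators: pd.DataFrame,
    solved_col: str = "solved",
) -> DesignMatrix:
    """Build the design matrix from the case table and the subcategory
    indicator matrix (indexed by patient id).

    Column order is deterministic: sorted indicator columns (penalized),
    then age_child, sex_m, site one-hots (sorted levels, first level is
    the dropped reference) and the image-analysis flag.  Cases with
    all-zero indicators are retained.
    """
    df = cohort.set_index("patient_id") if "patient_id" in cohort.columns else cohort
    ind = indicators.reindex(df.index)
    if ind.isna().any().any():
        raise ValueError("missing group indicators for some cases")
    penalized = sorted(ind.columns)
    X = ind[penalized].astype(float).copy()

    X["age_child"] = (df["age_class"].astype(str) == "child").astype(float)
    X["sex_m"] = (df["sex"].astype(str).str.lower().str.startswith("m")).astype(float)
    site_levels = sorted(df["site"].astype(str).unique())
    for level in site_levels[1:]:  # first level = reference, dropped
        X[f"site_{level}"] = (df["site"].astype(str) == level).astype(float)
    if "image_flag" in df.columns:
        X["image_flag"] = df["image_flag"].astype(float)
    if X.isna().any().any():
        raise ValueError("design matrix contains missing values")

    confounders = [c for c in X.columns if c not in penalized]
    w = np.array([1.0 if c in penalized else 0.0 for c in X.columns])
    y = df[solved_col].astype(int).to_numpy()
    return DesignMatrix(
        X=X, y=y, penalty_factors=w, penalized=penalized,
        confounders=confounders, site_levels=site_levels,
    )


# ---------------------------------------------------------------------------
# solver

def _objective(eta, y, beta, lam, w, n):
    # -(1/n) loglik + lam * sum w|beta|; log1p(exp) stabilized
    ll = np.sum(y * eta - np.logaddexp(0.0, eta))
    return -ll / n + lam * np.sum(w * np.abs(beta))


def _soft(z, t):
    return np.sign(z) * max(abs(z) - t, 0.0)


def _irls_cd(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    lam: float,
    beta: np.ndarray,
    b0: float,
    tol_obj: float = 1e-9,
    max_outer: int = 60,
    max_inner: int = 100,
    tol_cd: float = 1e-8,
):
    """Proximal-Newton lasso logistic fit: IRLS outer loop, cyclic
    coordinate descent on the weighted least-squares inner problem.
    Returns (beta, b0, converged, separated)."""
    n, p = X.shape
    beta = beta.copy()
    eta = b0 + X @ beta
    obj = _objective(eta, y, beta, lam, w, n)
    separated = False
    converged = False
    for _ in range(max_outer):
        pr = expit(eta)
        wt = np.clip(pr * (1.0 - pr), 1e-5, None)
        z = eta + (y - pr) / wt
        r = z - eta  # residual of working response
        wx = X * wt[:, None]
        denom = np.einsum("ij,ij->j", wx, X) / n
        sw = wt.sum()

        def _pass(idx) -> float:
            nonlocal b0, r
            max_step = 0.0
            d0 = float(wt @ r) / sw
            if d0 != 0.0:
                b0 += d0
                r -= d0
                max_step = abs(d0)
            for j in idx:
                if denom[j] <= 0.0:  # constant column in this fold
                    continue
                bj = beta[j]
                rho = float(wx[:, j] @ r) / n + denom[j] * bj
                if w[j] > 0.0:
                    new = _soft(rho, lam * w[j]) / denom[j]
                else:
                    new = rho / denom[j]
                d = new - bj
                if d != 0.0:
                    beta[j] = new
                    r -= d * X[:, j]
                    max_step = max(max_step, abs(d))
            return max_step

        # active-set cycling: full sweeps only to admit new coordinates
        all_idx = range(p)
        inner = 0
        while inner < max_inner:
            step = _pass(all_idx)
            inner += 1
            if step < tol_cd:
                break
            active = [j for j in all_idx if beta[j] != 0.0 or w[j] == 0.0]
            while inner < max_inner:
                step = _pass(active)
                inner += 1
                if step < tol_cd:
                    break
        eta = z - r
        new_obj = _objective(eta, y, beta, lam, w, n)
        if np.abs(beta).max(initial=0.0) > 1e3 or np.abs(b0) > 1e3:
            separated = True
            break
        if abs(obj - new_obj) < tol_obj * max(1.0, abs(obj)):
            converged = True
            obj = new_obj
            break
        obj = new_obj
    return beta, float(b0), converged, separated


@dataclass
class PenalizedLogisticModel:
    """Fitted lasso-logistic coefficient path with metadata."""

    columns: list[str]
    penalty_factors: np.ndarray
    lambdas: np.ndarray  # descending
    intercepts: np.ndarray  # (n_lambda,)
    coefs: np.ndarray  # (n_lambda, p)
    n_nonzero: np.ndarray  # nonzero penalized coefficients per lambda
    confounder_means: dict[str, float]
    train_prevalence: dict[str, float]  # penalized-column training prevalence
    site_levels: list[str] = field(default_factory=list)
    separation_flagged: bool = False
    selected_index: int | None = None
    cv_mean_deviance: np.ndarray | None = None
    cv_se_deviance: np.ndarray | None = None
    cv_folds: int | None = None
    cv_seed: int | None = None

    @property
    def penalized(self) -> list[str]:
        return [c for c, w in zip(self.columns, self.penalty_factors) if w > 0]

    @property
    def confounders(self) -> list[str]:
        return [c for c, w in zip(self.columns, self.penalty_factors) if w == 0]

    @property
    def lambda_selected(self) -> float:
        if self.selected_index is None:
            raise RuntimeError("no lambda selected; run cv_select first")
        return float(self.lambdas[self.selected_index])

    def coef_at(self, index: int) -> pd.Series:
        return pd.Series(self.coefs[index], index=self.columns)

    @property
    def coef_selected(self) -> pd.Series:
        if self.selected_index is None:
            raise RuntimeError("no lambda selected; run cv_select first")
        return self.coef_at(self.selected_index)

    def linear_predictor(self, X: np.ndarray, index: int) -> np.ndarray:
        return self.intercepts[index] + X @ self.coefs[index]

    def predict_proba(self, X, index: int | None = None) -> np.ndarray:
        if index is None:
            if self.selected_index is None:
                raise RuntimeError("no lambda selected; run cv_select first")
            index = self.selected_index
        X = np.asarray(X, dtype=float)
        return expit(self.linear_predictor(X, index))

    # -- serialization -----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "columns": self.columns,
            "penalty_factors": self.penalty_factors.tolist(),
            "lambdas": self.lambdas.tolist(),
            "intercepts": self.intercepts.tolist(),
            "coefs": self.coefs.tolist(),
            "n_nonzero": self.n_nonzero.tolist(),
            "confounder_means": self.confounder_means,
            "train_prevalence": self.train_prevalence,
            "site_levels": self.site_levels,
            "separation_flagged": self.separation_flagged,
            "selected_index": self.selected_index,
            "cv_mean_deviance": None
            if self.cv_mean_deviance is None
            else self.cv_mean_deviance.tolist(),
            "cv_se_deviance": None
            if self.cv_se_deviance is None
            else self.cv_se_deviance.tolist(),
            "cv_folds": self.cv_folds,
            "cv_seed": self.cv_seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PenalizedLogisticModel":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            columns=d["columns"],
            penalty_factors=np.array(d["penalty_factors"]),
            lambdas=np.array(d["lambdas"]),
            intercepts=np.array(d["intercepts"]),
            coefs=np.array(d["coefs"]),
            n_nonzero=np.array(d["n_nonzero"], dtype=int),
            confounder_means=d["confounder_means"],
            train_prevalence=d["train_prevalence"],
            site_levels=d.get("site_levels", []),
            separation_flagged=d["separation_flagged"],
            selected_index=d["selected_index"],
            cv_mean_deviance=None
            if d["cv_mean_deviance"] is None
            else np.array(d["cv_mean_deviance"]),
            cv_se_deviance=None
            if d["cv_se_deviance"] is None
            else np.array(d["cv_se_deviance"]),
            cv_folds=d["cv_folds"],
            cv_seed=d["cv_seed"],
        )


def _as_arrays(design_or_X, y=None, penalty_factors=None):
    if isinstance(design_or_X, DesignMatrix):
        d = design_or_X
        return (
            d.X.to_numpy(dtype=float),
            d.y.astype(float),
            d.penalty_factors,
            d.columns,
            d.site_levels,
        )
    X = np.asarray(design_or_X, dtype=float)
    cols = [f"x{j}" for j in range(X.shape[1])]
    if isinstance(design_or_X, pd.DataFrame):
        cols = list(design_or_X.columns)
    return X, np.asarray(y, dtype=float), np.asarray(penalty_factors, float), cols, []


def fit_path(
    design_or_X,
    y: np.ndarray | None = None,
    penalty_factors: np.ndarray | None = None,
    lambdas: Sequence[float] | None = None,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
) -> PenalizedLogisticModel:
    """Fit the lasso-logistic coefficient path.

    The grid runs from lambda_max (the smallest penalty at which every
    penalized coefficient is exactly zero, from the KKT conditions of the
    confounder-only fit) down to ``lambda_min_ratio * lambda_max`` in
    ``n_lambda`` log-spaced steps, warm-starting each fit from the
    previous one.  Complete separation near the unpenalized end truncates
    the path with a :class:`SeparationWarning`.
    """
    X, yv, w, cols, site_levels = _as_arrays(design_or_X, y, penalty_factors)
    n, p = X.shape
    if n < 20:
        raise ValueError("need at least 20 cases to fit the path")
    if len(np.unique(yv)) < 2:
        raise ValueError("outcome must contain both classes")

    # confounder-only fit (all penalized coefficients pinned at zero)
    beta0 = np.zeros(p)
    conf_mask = w == 0
    b0 = float(np.log(yv.mean() / (1 - yv.mean())))
    if conf_mask.any():
        sub = X[:, conf_mask]
        bsub, b0, _, _ = _irls_cd(
            sub, yv, np.zeros(sub.shape[1]), 0.0,
            np.zeros(sub.shape[1]), b0,
        )
        beta0[conf_mask] = bsub
    pr = expit(b0 + X @ beta0)
    grad = X.T @ (yv - pr) / n
    pen = w > 0
    # tiny inflation keeps the first grid point strictly at the all-zero
    # penalized solution despite the finite solver tolerance
    lam_max = float(np.max(np.abs(grad[pen]) / w[pen])) * (1.0 + 1e-6)
    if lambdas is None:
        lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    else:
        lambdas = np.asarray(sorted(lambdas, reverse=True), dtype=float)

    intercepts = np.zeros(len(lambdas))
    coefs = np.zeros((len(lambdas), p))
    nnz = np.zeros(len(lambdas), dtype=int)
    beta, b = beta0, b0
    separated = False
    n_fitted = len(lambdas)
    for i, lam in enumerate(lambdas):
        beta, b, _, sep = _irls_cd(X, yv, w, float(lam), beta, b)
        if not sep:
            # complete separation: every case on the correct side with an
            # enormous margin (fitted probabilities saturated)
            margin = (2.0 * yv - 1.0) * (b + X @ beta)
            sep = bool(margin.min() > 10.0)
        if sep:
            separated = True
            n_fitted = i
            warnings.warn(
                f"complete separation at lambda={lam:.3e}; path truncated",
                SeparationWarning,
                stacklevel=2,
            )
            break
        intercepts[i] = b
        coefs[i] = beta
        nnz[i] = int(np.count_nonzero(beta[pen]))

    lambdas = np.asarray(lambdas[:n_fitted])
    Xf = X
    means = {c: float(Xf[:, j].mean()) for j, c in enumerate(cols)}
    prevalence = {
        c: float(Xf[:, j].mean()) for j, c in enumerate(cols) if w[j] > 0
    }
    return PenalizedLogisticModel(
        columns=cols,
        penalty_factors=w,
        lambdas=lambdas,
        intercepts=intercepts[:n_fitted],
        coefs=coefs[:n_fitted],
        n_nonzero=nnz[:n_fitted],
        confounder_means=means,
        train_prevalence=prevalence,
        site_levels=site_levels,
        separation_flagged=separated,
    )


def binomial_deviance(y: np.ndarray, prob: np.ndarray) -> float:
    prob = np.clip(prob, 1e-10, 1 - 1e-10)
    return float(-2.0 * np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


def cv_select(
    design_or_X,
    y: np.ndarray | None = None,
    penalty_factors: np.ndarray | None = None,
    k: int = 10,
    seed: int = 1,
    rule: str = "min",
    model: PenalizedLogisticModel | None = None,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
) -> PenalizedLogisticModel:
    """Tune lambda by k-fold cross-validation on out-of-fold binomial
    deviance and record the selection on the full-data path model.

    Folds are stratified by outcome (plain k-fold when k equals n, i.e.
    leave-one-out); every training fold must contain both classes.
    ``rule='min'`` picks the minimum-deviance lambda, ``rule='1se'`` the
    largest lambda within one standard error of the minimum.
    """
    X, yv, w, cols, _ = _as_arrays(design_or_X, y, penalty_factors)
    n = len(yv)
    if model is None:
        model = fit_path(
            design_or_X, y, penalty_factors,
            n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio,
        )
    lambdas = model.lambdas
    if k > n:
        raise ValueError("k cannot exceed n")
    if k == n:
        splitter = KFold(n_splits=k)
        splits = splitter.split(X)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(X, yv)

    fold_dev = np.full((k, len(lambdas)), np.nan)
    for f, (tr, va) in enumerate(splits):
        if len(np.unique(yv[tr])) < 2:
            raise ValueError(f"training fold {f} contains a single class")
        sub = fit_path(X[tr], yv[tr], w, lambdas=lambdas)
        n_l = len(sub.lambdas)
        for i in range(len(lambdas)):
            j = min(i, n_l - 1)  # truncated fold path: reuse last fitted
            prob = expit(sub.intercepts[j] + X[va] @ sub.coefs[j])
            fold_dev[f, i] = binomial_deviance(yv[va], prob)

    mean_dev = fold_dev.mean(axis=0)
    se_dev = fold_dev.std(axis=0, ddof=1) / np.sqrt(k)
    i_min = int(np.argmin(mean_dev))
    if rule == "min":
        selected = i_min
    elif rule == "1se":
        limit = mean_dev[i_min] + se_dev[i_min]
        within = np.where(mean_dev <= limit)[0]
        selected = int(within[0])  # largest lambda within one SE
    else:
        raise ValueError(f"unknown rule {rule!r}")
    model.selected_index = selected
    model.cv_mean_deviance = mean_dev
    model.cv_se_deviance = se_dev
    model.cv_folds = k
    model.cv_seed = seed
    return model


def kkt_max_violation(
    model: PenalizedLogisticModel, design_or_X, y=None
) -> np.ndarray:
    """Maximum KKT violation of the penalized block per lambda.

    At a solution, |(1/n) X_j'(y - p)| <= lambda w_j whenever beta_j = 0
    and equals lambda w_j sign(beta_j) otherwise; returns the largest
    excess per lambda (should be ~0 up to the solver tolerance).
    """
    X, yv, w, _, _ = _as_arrays(design_or_X, y, model.penalty_factors)
    n = len(yv)
    pen = w > 0
    out = np.zeros(len(model.lambdas))
    for i, lam in enumerate(model.lambdas):
        pr = expit(model.linear_predictor(X, i))
        grad = X.T @ (yv - pr) / n
        beta = model.coefs[i]
        viol = 0.0
        for j in np.where(pen)[0]:
            if beta[j] == 0.0:
                viol = max(viol, abs(grad[j]) - lam * w[j])
            else:
                viol = max(viol, abs(grad[j] - lam * w[j] * np.sign(beta[j])))
        out[i] = viol
    return out


def predict_yield(
    model: PenalizedLogisticModel,
    indicators: Mapping[str, float] | pd.Series | None = None,
    age_class: str | None = None,
    sex: str | None = None,
    site: str | None = None,
    image_flag: bool | None = None,
) -> float:
    """Predicted probability of a molecular diagnosis for one case.

    Subcategory indicators default to 0 (absent); any unsupplied
    confounder -- and any site level unseen in training -- is imputed with
    the training-cohort mean of the corresponding design column.
    """
    if indicators is None and age_class is None and sex is None:
        warnings.warn(
            "no terms and no covariates supplied; returning the "
            "intercept-plus-means baseline probability",
            stacklevel=2,
        )
    x = {}
    ind = dict(indicators) if indicators is not None else {}
    for col in model.columns:
        if col in model.penalized:
            x[col] = float(ind.get(col, 0.0))
        elif col == "age_child":
            x[col] = (
                model.confounder_means[col]
                if age_class is None
                else float(age_class == "child")
            )
        elif col == "sex_m":
            x[col] = (
                model.confounder_means[col]
                if sex is None
                else float(str(sex).lower().startswith("m"))
            )
        elif col.startswith("site_"):
            level = col[len("site_"):]
            if site is None or str(site) not in model.site_levels:
                x[col] = model.confounder_means[col]
            else:
                x[col] = float(str(site) == level)
        elif col == "image_flag":
            x[col] = (
                model.confounder_means[col]
                if image_flag is None
                else float(image_flag)
            )
        else:  # unknown confounder column: training mean
            x[col] = model.confounder_means[col]
    vec = np.array([x[c] for c in model.columns])
    return float(model.predict_proba(vec[None, :])[0])


# ---------------------------------------------------------------------------
# evaluation

def roc_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    seed: int = 1,
) -> tuple[float, tuple[float, float]]:
    """ROC AUC as the tie-corrected Mann-Whitney statistic, with a
    case-level percentile-bootstrap 95% CI."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for the AUC")

    def _auc(sv, yv):
        from scipy.stats import rankdata

        n1 = int(yv.sum())
        n0 = len(yv) - n1
        ranks = rankdata(sv)
        return (ranks[yv == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    auc = float(_auc(s, y))
    rng = np.random.default_rng(seed)
    boots = []
    n = len(y)
    attempts = 0
    while len(boots) < n_boot and attempts < 10 * n_boot:
        idx = rng.integers(0, n, n)
        attempts += 1
        if len(np.unique(y[idx])) < 2:
            continue
        boots.append(_auc(s[idx], y[idx]))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return auc, (float(lo), float(hi))


def per_term_auc(
    term_sets: Sequence[Iterable[str]], labels: Sequence[int]
) -> pd.Series:
    """Discriminatory AUC of each term's binary presence indicator.

    For a binary marker with sensitivity a and specificity b the
    tie-corrected AUC is (a + b) / 2.
    """
    y = np.asarray(labels, dtype=int)
    if len(term_sets) != len(y):
        raise ValueError("term_sets and labels length mismatch")
    universe = sorted(set().union(*[set(t) for t in term_sets]))
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required")
    out = {}
    for term in universe:
        present = np.array([term in t for t in term_sets], dtype=float)
        sens = present[y == 1].mean()
        spec = 1.0 - present[y == 0].mean()
        out[term] = 0.5 * (sens + spec)
    return pd.Series(out, name="auc")


# ---------------------------------------------------------------------------
# reporting

def export_paths(
    model: PenalizedLogisticModel, min_prevalence: float = 0.05
) -> pd.DataFrame:
    """Coefficient paths of the penalized features that are nonzero in the
    selected model and were present in at least ``min_prevalence`` of the
    training cases.  Long format: feature, lambda, log_lambda, coefficient.
    """
    if model.selected_index is None:
        raise RuntimeError("run cv_select before exporting paths")
    sel = model.coef_selected
    keep = [
        c
        for c in model.penalized
        if model.train_prevalence.get(c, 0.0) >= min_prevalence
        and sel[c] != 0.0
    ]
    rows = []
    col_idx = {c: j for j, c in enumerate(model.columns)}
    for c in keep:
        j = col_idx[c]
        for i, lam in enumerate(model.lambdas):
            rows.append(
                {
                    "feature": c,
                    "lambda": float(lam),
                    "log_lambda": float(np.log(lam)),
                    "coefficient": float(model.coefs[i, j]),
                }
            )
    return pd.DataFrame(rows, columns=["feature", "lambda", "log_lambda", "coefficient"])


def plot_paths(model: PenalizedLogisticModel, path, min_prevalence: float = 0.05) -> None:
    """Coefficient-path plot (x axis ln(lambda), one line per feature)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = export_paths(model, min_prevalence=min_prevalence)
    fig, ax = plt.subplots(figsize=(7, 5))
    for feat, sub in table.groupby("feature"):
        ax.plot(sub["log_lambda"], sub["coefficient"], label=feat, lw=1)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("ln(lambda)")
    ax.set_ylabel("coefficient")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def split_cohort(
    y: Sequence[int],
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test index split at the reference cohort ratio
    (1,256 train / 321 test out of 1,577)."""
    y = np.asarray(y, dtype=int)
    n = len(y)
    n_train = int(round(train_fraction * n))
    idx = np.arange(n)
    train, test = train_test_split(
        idx, train_size=n_train, stratify=y, random_state=seed
    )
    return np.sort(train), np.sort(test)
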