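"""OLS model fitting and the full QSAR validation battery.

Internal metrics (R2, adjusted R2, RMSE, MAE, Lin's concordance),
leave-one-out and leave-many-out cross-validation, external-set predictive
squared correlations (Q2_F1/F2/F3), Y-scrambling, and a leverage-based
applicability domain (Williams plot data).

Conventions, chosen once and used consistently:

* RMSE uses denominator n (common QSAR practice), not n - p - 1.
* Q2_LOO is computed by the exact hat-matrix shortcut
  e_loo,i = e_i / (1 - h_ii); a brute-force n-refit oracle in the test
  suite pins this to 1e-10.
* Lin's CCC = 2*S_xy / (S_xx + S_yy + n*(x_bar - y_bar)^2) with raw sums of
  squared deviations (no ddof choice to make).
* Q2_LMO pools PRESS and TSS over rounds, so it degenerates to Q2_LOO when
  the rounds enumerate the single-element folds.
* Standardized residuals use s = sqrt(RSS / (n - p - 1)); the applicability
  domain flags |std. residual| > 2.5 or leverage > h* = 3(p+1)/n.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SingularityError(ValueError):
    """Design matrix is rank deficient."""


class IncompleteReportError(ValueError):
    """A metric required by the criteria check is missing."""


# ---------------------------------------------------------------------------
# model


@dataclass
class MLRModel:
    """A fitted ordinary-least-squares multilinear regression."""

    intercept: float
    coefficients: dict[str, float]
    coefficient_std_errors: dict[str, float]
    intercept_std_error: float
    n_train: int
    training_mean_y: float
    training_variance: float    # population variance of training y
    descriptor_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.descriptor_names:
            self.descriptor_names = tuple(self.coefficients)
        assert all(se >= 0 for se in self.coefficient_std_errors.values())

    @property
    def p(self) -> int:
        return len(self.coefficients)

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X, self.descriptor_names)
        beta = np.array([self.coefficients[n] for n in self.descriptor_names])
        return self.intercept + X @ beta


def _as_matrix(X, names=None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if names is not None:
            X = X.loc[:, list(names)]
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def fit_mlr(X, y) -> MLRModel:
    """Least-squares fit with residual-based coefficient standard errors."""
    import statsmodels.api as sm

    names = (list(X.columns) if isinstance(X, pd.DataFrame)
             else [f"x{i}" for i in range(np.asarray(X).shape[1])])
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n <= p + 1:
        raise SingularityError(f"need n > p + 1, got n={n}, p={p}")
    if np.linalg.matrix_rank(_design(Xm)) < p + 1:
        raise SingularityError("design matrix is rank deficient")
    res = sm.OLS(y, sm.add_constant(Xm)).fit()
    return MLRModel(
        intercept=float(res.params[0]),
        coefficients=dict(zip(names, map(float, res.params[1:]))),
        coefficient_std_errors=dict(zip(names, map(float, res.bse[1:]))),
        intercept_std_error=float(res.bse[0]),
        n_train=n,
        training_mean_y=float(y.mean()),
        training_variance=float(((y - y.mean()) ** 2).mean()),
        descriptor_names=tuple(names),
    )


# ---------------------------------------------------------------------------
# scalar metrics


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (agreement about y = x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    sxx = ((x - x.mean()) ** 2).sum()
    syy = ((y - y.mean()) ** 2).sum()
    return float(2 * sxy / (sxx + syy + len(x) * (x.mean() - y.mean()) ** 2))


def _basic(y, yhat) -> tuple[float, float]:
    e = np.asarray(y, float) - np.asarray(yhat, float)
    return float(np.sqrt((e ** 2).mean())), float(np.abs(e).mean())


def internal_metrics(model: MLRModel, X, y) -> dict[str, float]:
    """Training-set statistics: R2, adjusted R2, RMSE (over n), MAE, CCC."""
    y = np.asarray(y, dtype=float)
    if np.allclose(y.var(), 0):
        raise ValueError("zero-variance response: R2 undefined")
    yhat = model.predict(X)
    rss = ((y - yhat) ** 2).sum()
    tss = ((y - y.mean()) ** 2).sum()
    n, p = len(y), model.p
    r2 = 1 - rss / tss
    rmse, mae = _basic(y, yhat)
    return {
        "r2_tr": float(r2),
        "r2_adj": float(1 - (1 - r2) * (n - 1) / (n - p - 1)),
        "rmse_tr": rmse,
        "mae_tr": mae,
        "ccc_tr": ccc(y, yhat),
    }


# ---------------------------------------------------------------------------
# cross-validation


def loo_predictions(X, y) -> np.ndarray:
    """Leave-one-out predictions via the hat-matrix shortcut.

    For OLS the deleted residual is e_i / (1 - h_ii) exactly, so no refits
    are needed.  Folds with h_ii ~ 1 (a point its own sole support) are
    flagged and excluded by the callers.
    """
    Xd = _design(_as_matrix(X))
    y = np.asarray(y, dtype=float)
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise SingularityError("design matrix is rank deficient")
    q, _ = np.linalg.qr(Xd)
    h = (q ** 2).sum(axis=1)
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        e_loo = resid / (1 - h)
    return y - e_loo


def q2_loo(X, y) -> dict[str, float]:
    """Q2_LOO = 1 - PRESS/TSS plus the cross-validated RMSE/MAE/CCC."""
    y = np.asarray(y, dtype=float)
    yhat = loo_predictions(X, y)
    ok = np.isfinite(yhat)
    if not ok.all():
        import warnings
        warnings.warn(f"{(~ok).sum()} leave-one-out fold(s) singular; "
                      "metric computed from the remaining folds", stacklevel=2)
    press = ((y[ok] - yhat[ok]) ** 2).sum()
    tss = ((y[ok] - y[ok].mean()) ** 2).sum()
    rmse, mae = _basic(y[ok], yhat[ok])
    return {"q2_loo": float(1 - press / tss), "rmse_cv": rmse, "mae_cv": mae,
            "ccc_cv": ccc(y[ok], yhat[ok])}


def q2_loo_fitness(Xm: np.ndarray, y: np.ndarray) -> float:
    """Bare Q2_LOO for subset-search fitness: -inf on any numerical trouble."""
    Xd = _design(Xm)
    q, r = np.linalg.qr(Xd)
    if abs(np.diag(r)).min() < 1e-10 * max(abs(np.diag(r)).max(), 1.0):
        return -np.inf
    h = (q ** 2).sum(axis=1)
    if np.any(h > 1 - 1e-10):
        return -np.inf
    beta = np.linalg.solve(r, q.T @ y)
    e_loo = (y - Xd @ beta) / (1 - h)
    tss = ((y - y.mean()) ** 2).sum()
    return float(1 - (e_loo ** 2).sum() / tss)


def q2_lmo(X, y, leave_fraction: float = 0.2, repeats: int = 500,
           seed: int = 0, groups=None) -> float:
    """Leave-many-out Q2: PRESS and TSS pooled over seeded random rounds.

    ``groups`` (a list of index arrays) overrides the random rounds — with
    the single-element folds it reproduces Q2_LOO exactly.
    """
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if groups is None:
        m = max(2, int(round(n * leave_fraction)))
        rng = np.random.default_rng(seed)
        groups = [rng.choice(n, size=m, replace=False) for _ in range(repeats)]
    press = tss = 0.0
    ybar = y.mean()
    for out in groups:
        out = np.asarray(out)
        mask = np.ones(n, dtype=bool)
        mask[out] = False
        Xd = _design(Xm[mask])
        beta, *_ = np.linalg.lstsq(Xd, y[mask], rcond=None)
        pred = _design(Xm[out]) @ beta
        press += ((y[out] - pred) ** 2).sum()
        tss += ((y[out] - ybar) ** 2).sum()
    return float(1 - press / tss)


def y_scrambling(X, y, n_permutations: int = 500, seed: int = 0,
                 permuter=None) -> float:
    """Mean R2 of models refitted on permuted responses.

    Near zero means the original fit is not a chance correlation.
    ``permuter(rng, y) -> y_perm`` is a test hook; default is a uniform
    random permutation.
    """
    Xd = _design(_as_matrix(X))
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    r2s = np.empty(n_permutations)
    for i in range(n_permutations):
        yp = permuter(rng, y) if permuter is not None else rng.permutation(y)
        beta, *_ = np.linalg.lstsq(Xd, yp, rcond=None)
        rss = ((yp - Xd @ beta) ** 2).sum()
        tss = ((yp - yp.mean()) ** 2).sum()
        r2s[i] = 1 - rss / tss
    return float(r2s.mean())


# ---------------------------------------------------------------------------
# external validation


def external_metrics(model: MLRModel, X_ext, y_ext,
                     training_mean_y: float | None = None,
                     training_variance: float | None = None) -> dict[str, float]:
    """External-set battery: R2_ex, Q2_F1/F2/F3, CCC, RMSE, MAE.

    Q2_F1 references the training mean, Q2_F2 the external mean, Q2_F3 the
    per-sample training variance; R2_ex is the squared Pearson correlation
    of predicted vs observed.
    """
    y = np.asarray(y_ext, dtype=float)
    if len(y) == 0:
        raise ValueError("external set is empty")
    ybar_tr = model.training_mean_y if training_mean_y is None else training_mean_y
    var_tr = model.training_variance if training_variance is None else training_variance
    yhat = model.predict(X_ext)
    rss = ((yhat - y) ** 2).sum()
    rmse, mae = _basic(y, yhat)
    r = np.corrcoef(yhat, y)[0, 1]
    return {
        "r2_ex": float(r ** 2),
        "q2_f1": float(1 - rss / ((y - ybar_tr) ** 2).sum()),
        "q2_f2": float(1 - rss / ((y - y.mean()) ** 2).sum()),
        "q2_f3": float(1 - (rss / len(y)) / var_tr),
        "ccc_ex": ccc(y, yhat),
        "rmse_ex": rmse,
        "mae_ex": mae,
    }


# ---------------------------------------------------------------------------
# applicability domain


@dataclass
class ADReport:
    """Williams-plot data: leverage and standardized residual per molecule."""

    ids: list[str]
    leverages: np.ndarray
    standardized_residuals: np.ndarray
    h_star: float
    outside_domain_ids: list[str]
    residual_cutoff: float = 2.5
    is_training: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mol_id": self.ids,
            "leverage": self.leverages,
            "std_residual": self.standardized_residuals,
            "set": np.where(self.is_training, "train", "external")
            if self.is_training is not None else "train",
        })


def applicability_domain(model: MLRModel, X_train, X_all=None, residuals=None,
                         ids=None, residual_cutoff: float = 2.5) -> ADReport:
    """Leverage / standardized-residual applicability domain.

    h_i = x_i' (X'X)^-1 x_i over the training design (intercept included);
    the warning leverage is h* = 3(p+1)/n_train.  A molecule is outside the
    domain if leverage > h* or |standardized residual| > ``residual_cutoff``.
    """
    Xtr = _design(_as_matrix(X_train, model.descriptor_names))
    n, pp1 = Xtr.shape
    Xall = Xtr if X_all is None else _design(_as_matrix(X_all, model.descriptor_names))
    xtx = Xtr.T @ Xtr
    if np.linalg.matrix_rank(xtx) < pp1:
        raise SingularityError("X'X is singular")
    xtx_inv = np.linalg.inv(xtx)
    lev = np.einsum("ij,jk,ik->i", Xall, xtx_inv, Xall)
    h_star = 3.0 * pp1 / n
    residuals = np.asarray(residuals, dtype=float)
    s = np.sqrt((np.asarray(residuals[:n]) ** 2).sum() / (n - pp1))
    std_resid = residuals / s
    if ids is None:
        ids = [str(i) for i in range(len(Xall))]
    outside = [i for i, (h, r) in enumerate(zip(lev, std_resid))
               if h > h_star or abs(r) > residual_cutoff]
    is_training = np.arange(len(Xall)) < n if X_all is not None else None
    return ADReport(
        ids=list(ids),
        leverages=lev,
        standardized_residuals=std_resid,
        h_star=h_star,
        outside_domain_ids=[ids[i] for i in outside],
        residual_cutoff=residual_cutoff,
        is_training=is_training,
    )


def leverage_cutoff(p: int, n_train: int) -> float:
    """Warning leverage h* = 3(p+1)/n for a p-descriptor model."""
    return 3.0 * (p + 1) / n_train


# ---------------------------------------------------------------------------
# splitting, report, criteria


@dataclass(frozen=True)
class SplitAssignment:
    train_ids: tuple
    test_ids: tuple
    seed: int


def random_split(ids, train_fraction: float = 0.8, seed: int = 0,
                 sizes: tuple[int, int] | None = None) -> SplitAssignment:
    """Seeded random train/external split.

    ``sizes`` overrides the rounded-fraction sizes (the study's own split
    reports 1024/254 of 1278, which rounding cannot produce).
    """
    ids = list(ids)
    n = len(ids)
    if n < 10:
        raise ValueError("need at least 10 ids to split")
    if sizes is None:
        n_train = int(round(train_fraction * n))
    else:
        if sum(sizes) != n:
            raise ValueError(f"sizes {sizes} do not sum to {n}")
        n_train = sizes[0]
    perm = np.random.default_rng(seed).permutation(n)
    train = tuple(ids[i] for i in sorted(perm[:n_train]))
    test = tuple(ids[i] for i in sorted(perm[n_train:]))
    return SplitAssignment(train_ids=train, test_ids=test, seed=seed)


REPORT_FIELDS = (
    "r2_tr", "r2_adj", "rmse_tr", "mae_tr", "ccc_tr",
    "q2_loo", "rmse_cv", "mae_cv", "ccc_cv", "q2_lmo", "r2_yscr",
    "r2_ex", "q2_f1", "q2_f2", "q2_f3", "ccc_ex", "rmse_ex", "mae_ex",
)

_TABLE_LABELS = {
    "r2_tr": "R2_tr", "r2_adj": "R2_adj", "rmse_tr": "RMSE_tr",
    "mae_tr": "MAE_tr", "ccc_tr": "CCC_tr", "q2_loo": "Q2_LOO",
    "rmse_cv": "RMSE_cv", "mae_cv": "MAE_cv", "ccc_cv": "CCC_cv",
    "q2_lmo": "Q2_LMO", "r2_yscr": "R2_Yscr", "r2_ex": "R2_ex",
    "q2_f1": "Q2_F1", "q2_f2": "Q2_F2", "q2_f3": "Q2_F3",
    "ccc_ex": "CCC_ex", "rmse_ex": "RMSE_ex", "mae_ex": "MAE_ex",
}


@dataclass
class ValidationReport:
    """The full internal/cross-validated/external metric battery."""

    metrics: dict[str, float]
    criteria_pass: dict[str, bool] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    def __getattr__(self, name):
        metrics = object.__getattribute__(self, "metrics")
        if name in metrics:
            return metrics[name]
        raise AttributeError(name)

    def to_json(self) -> str:
        return json.dumps({"metrics": self.metrics, "criteria_pass": self.criteria_pass,
                           "notes": self.notes}, indent=2, sort_keys=True)

    def to_table(self) -> str:
        lines = ["Parameter    Value", "-" * 19]
        for key in REPORT_FIELDS:
            if key in self.metrics:
                lines.append(f"{_TABLE_LABELS[key]:<11}  {self.metrics[key]:.3f}")
        return "\n".join(lines)


#: Acceptance thresholds for a usable model.  R2_Yscr has no published
#: numeric bound ("low"); 0.2 is the conventional chance-correlation guard.
CRITERIA = {
    "r2_tr >= 0.6": lambda m: m["r2_tr"] >= 0.6,
    "q2_loo >= 0.5": lambda m: m["q2_loo"] >= 0.5,
    "q2_lmo >= 0.6": lambda m: m["q2_lmo"] >= 0.6,
    "r2_tr > q2_loo": lambda m: m["r2_tr"] > m["q2_loo"],
    "r2_ex >= 0.6": lambda m: m["r2_ex"] >= 0.6,
    "ccc_ex >= 0.80": lambda m: m["ccc_ex"] >= 0.80,
    "q2_f1 >= 0.60": lambda m: m["q2_f1"] >= 0.60,
    "q2_f2 >= 0.60": lambda m: m["q2_f2"] >= 0.60,
    "q2_f3 >= 0.60": lambda m: m["q2_f3"] >= 0.60,
    "rmse_tr < rmse_cv": lambda m: m["rmse_tr"] < m["rmse_cv"],
    "r2_yscr <= 0.2": lambda m: m["r2_yscr"] <= 0.2,
}


def criteria_check(report: ValidationReport | dict) -> dict[str, bool]:
    """Evaluate every acceptance criterion; adds an ``overall`` conjunction."""
    metrics = report.metrics if isinstance(report, ValidationReport) else dict(report)
    needed = {"r2_tr", "q2_loo", "q2_lmo", "r2_ex", "ccc_ex", "q2_f1", "q2_f2",
              "q2_f3", "rmse_tr", "rmse_cv", "r2_yscr"}
    missing = needed - set(k for k, v in metrics.items() if v is not None)
    if missing:
        raise IncompleteReportError(f"missing metrics: {sorted(missing)}")
    out = {name: bool(fn(metrics)) for name, fn in CRITERIA.items()}
    out["overall"] = all(out.values())
    return out


def validate_model(X_tr, y_tr, X_ex, y_ex, seed: int = 0,
                   lmo_fraction: float = 0.2, lmo_repeats: int = 500,
                   n_scrambles: int = 500
                   ) -> tuple[MLRModel, ValidationReport, ADReport]:
    """Fit on the training set and assemble the complete battery."""
    model = fit_mlr(X_tr, y_tr)
    metrics = internal_metrics(model, X_tr, y_tr)
    metrics.update(q2_loo(X_tr, y_tr))
    metrics["q2_lmo"] = q2_lmo(X_tr, y_tr, leave_fraction=lmo_fraction,
                               repeats=lmo_repeats, seed=seed)
    metrics["r2_yscr"] = y_scrambling(X_tr, y_tr, n_permutations=n_scrambles, seed=seed)
    metrics.update(external_metrics(model, X_ex, y_ex))
    report = ValidationReport(metrics=metrics)
    report.criteria_pass = criteria_check(report)
    y_all = np.concatenate([np.asarray(y_tr, float), np.asarray(y_ex, float)])
    X_all = pd.concat([pd.DataFrame(X_tr), pd.DataFrame(X_ex)])
    residuals = y_all - model.predict(X_all)
    ids = list(getattr(X_tr, "index", range(len(y_tr)))) + \
        list(getattr(X_ex, "index", range(len(y_ex))))
    ad = applicability_domain(model, X_tr, X_all, residuals, ids=[str(i) for i in ids])
    return model, report, ad
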