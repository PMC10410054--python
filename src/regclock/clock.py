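"""Training, applying and evaluating linear epigenetic age clocks.

The clock is an L1-penalised (LASSO) linear regression of chronological age
in months on regional mean methylation. The penalty is chosen by K-fold
cross-validation, taking the penalty that minimises mean cross-validated
error (the ``lambda.min`` convention of cv.glmnet); the one-standard-error
rule is available as an option. Features are standardised internally for
the fit and coefficients are reported back on the original beta scale, so a
serialised clock applies directly to raw regional methylation values.

At prediction time any clock region that is absent or unmeasured in a
sample contributes zero — the zero-imputation rule that makes a clock
applicable to external datasets with different CpG capture. Training never
imputes: regions with any missing value in the training matrix are dropped
before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .covio import ClockModel
from .errors import ValidationError
from .quantitation import RegionMatrix

__all__ = [
    "TrainConfig",
    "EvalResult",
    "PredictionResult",
    "GroupComparison",
    "split_train_cv",
    "train_lasso_clock",
    "predict_age",
    "evaluate_predictions",
    "compare_groups",
]


@dataclass
class TrainConfig:
    """Hyperparameters of clock training.

    cv_folds of 100 is the conventional choice; with fewer than 100 training
    samples it degrades gracefully to leave-one-out. train_fraction governs
    the holdout split (90% train / 10% holdout by default).
    """

    cv_folds: int = 100
    train_fraction: float = 0.9
    seed: int = 0
    lambda_rule: str = "min"  # "min" (lowest mean CV error) or "1se"

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValidationError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}"
            )
        if self.cv_folds < 2:
            raise ValidationError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.lambda_rule not in ("min", "1se"):
            raise ValidationError(f"unknown lambda_rule {self.lambda_rule!r}")


def split_train_cv(
    matrix: RegionMatrix, cfg: TrainConfig
) -> tuple[RegionMatrix, RegionMatrix]:
    """Randomly partition samples into training and holdout sets.

    The holdout receives ``floor(n * (1 - train_fraction))`` samples (at
    least one); the split is a uniform random permutation, reproducible
    under ``cfg.seed``.
    """
    n = matrix.n_samples
    if n < 10:
        raise ValidationError(f"need >= 10 samples to split, got {n}")
    # round before flooring so 60 * 0.1 does not floor to 5
    n_holdout = int(np.floor(round(n * (1.0 - cfg.train_fraction), 9)))
    if n_holdout < 1:
        raise ValidationError(
            f"train_fraction {cfg.train_fraction} leaves an empty holdout "
            f"for n={n}"
        )
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    ids = np.array(matrix.sample_ids)
    holdout_ids = sorted(ids[perm[:n_holdout]])
    train_ids = sorted(ids[perm[n_holdout:]])
    return matrix.subset_rows(train_ids), matrix.subset_rows(holdout_ids)


def train_lasso_clock(
    train: RegionMatrix,
    cfg: TrainConfig,
    alpha: float | None = None,
    feature_kind: str = "region",
) -> ClockModel:
    """Fit a LASSO age clock on a training matrix.

    Region columns containing any missing value are removed before fitting.
    When ``alpha`` is given the cross-validation search is skipped and that
    penalty used directly; ``alpha=0`` fits ordinary least squares.
    """
    clean = train.drop_missing_regions()
    if clean.n_regions == 0:
        raise ValidationError("no fully observed regions to train on")
    y = clean.ages.to_numpy(dtype=float)
    if np.unique(y).size < 2:
        raise ValidationError("constant age response; nothing to fit")
    X = clean.values.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd_safe

    if alpha is not None and alpha == 0.0:
        coef_s, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(y)), Xs]), y, rcond=None
        )
        b0, coefs = coef_s[0], coef_s[1:]
    elif alpha is not None:
        fit = Lasso(alpha=alpha, max_iter=100_000).fit(Xs, y)
        b0, coefs = fit.intercept_, fit.coef_
    else:
        n_folds = min(cfg.cv_folds, len(y))
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=cfg.seed)
        cv = LassoCV(cv=kf, alphas=100, max_iter=100_000,
                     random_state=cfg.seed).fit(Xs, y)
        chosen = cv.alpha_
        if cfg.lambda_rule == "1se":
            mean_mse = cv.mse_path_.mean(axis=1)
            se = cv.mse_path_.std(axis=1, ddof=1) / np.sqrt(cv.mse_path_.shape[1])
            i_min = int(np.argmin(mean_mse))
            ok = mean_mse <= mean_mse[i_min] + se[i_min]
            chosen = float(cv.alphas_[ok].max())
        fit = Lasso(alpha=chosen, max_iter=100_000).fit(Xs, y)
        b0, coefs = fit.intercept_, fit.coef_
        alpha = chosen

    # back-transform to the original beta scale
    w = coefs / sd_safe
    intercept = float(b0 - np.sum(coefs * mu / sd_safe))
    terms = {
        rid: float(wj)
        for rid, wj in zip(clean.region_ids, w)
        if wj != 0.0
    }
    return ClockModel(
        intercept=intercept,
        terms=terms,
        feature_kind=feature_kind,
        provenance=(
            f"lasso alpha={alpha:.6g} folds<= {cfg.cv_folds} "
            f"rule={cfg.lambda_rule} seed={cfg.seed} "
            f"n_train={len(y)} n_features={clean.n_regions}"
        ),
    )


@dataclass
class PredictionResult:
    sample_ids: list[str]
    e_age: np.ndarray
    n_imputed: np.ndarray  # clock terms zero-imputed per sample

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"e_age": self.e_age, "n_imputed": self.n_imputed},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


def predict_age(model: ClockModel, matrix: RegionMatrix) -> PredictionResult:
    """Predicted age = intercept + sum of weight x regional methylation.

    Clock regions absent from the matrix, or missing in a given sample,
    contribute zero; the per-sample count of such imputed terms is returned
    so saturation can be monitored. A fully missing sample predicts exactly
    the intercept.
    """
    term_ids = list(model.terms)
    weights = np.array([model.terms[t] for t in term_ids], dtype=float)
    X = matrix.values.reindex(columns=term_ids).to_numpy(dtype=float)
    missing = ~np.isfinite(X)
    X = np.where(missing, 0.0, X)
    e_age = model.intercept + X @ weights
    return PredictionResult(
        sample_ids=matrix.sample_ids,
        e_age=e_age,
        n_imputed=missing.sum(axis=1),
    )


@dataclass
class EvalResult:
    """Age-prediction accuracy summary.

    adj_r2 is the adjusted coefficient of determination of the least-squares
    fit of predicted on chronological age, 1 - (1 - R^2)(N - 1)/(N - k - 1);
    mae_months is the *median* absolute error; residuals (predicted minus
    chronological age) are the per-sample age accelerations.
    """

    adj_r2: float
    mae_months: float
    residuals: np.ndarray = field(repr=False)
    n: int = 0
    k: int = 1


def evaluate_predictions(
    predicted: np.ndarray, chronological: np.ndarray, k: int = 1
) -> EvalResult:
    """Adjusted R^2 and median absolute error of predicted vs true age."""
    pred = np.asarray(predicted, dtype=float)
    chron = np.asarray(chronological, dtype=float)
    if pred.shape != chron.shape or pred.ndim != 1:
        raise ValidationError("predicted and chronological lengths differ")
    n = pred.size
    if n < 3 or n - k - 1 <= 0:
        raise ValidationError(f"need n > k + 1 and n >= 3, got n={n}, k={k}")
    if np.allclose(pred, chron):
        r2 = 1.0
    elif np.ptp(chron) == 0 or np.ptp(pred) == 0:
        r2 = 0.0
    else:
        r2 = stats.linregress(chron, pred).rvalue ** 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    residuals = pred - chron
    return EvalResult(
        adj_r2=float(adj),
        mae_months=float(np.median(np.abs(residuals))),
        residuals=residuals,
        n=n,
        k=k,
    )


@dataclass
class GroupComparison:
    median_error: float
    p_value: float
    n_treated: int
    n_control: int


def compare_groups(treated, control) -> GroupComparison:
    """Compare age acceleration between two independent groups.

    Reports the treated group's median age acceleration ("median error")
    and the two-sided Wilcoxon rank-sum p-value (tie-corrected normal
    approximation for larger groups, exact otherwise) of treated vs control.
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValidationError("both groups must be non-empty")
    res = stats.mannwhitneyu(t, c, alternative="two-sided", method="auto")
    return GroupComparison(
        median_error=float(np.median(t)),
        p_value=float(res.pvalue),
        n_treated=t.size,
        n_control=c.size,
    )
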