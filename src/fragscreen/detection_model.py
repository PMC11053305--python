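"""L1-penalized logistic fragmentation model.

Features are the per-bin short-fragment proportions (raw, uncentered by
default); they are standardized to zero mean / unit variance internally.
The penalty is chosen by repeated stratified k-fold cross-validation,
minimizing mean held-out binomial deviance over a logarithmic lambda grid;
ties go to the larger (sparser) lambda.  The sample score is the model's
predicted case probability, thresholded at a configurable cutoff
(reference default 0.494).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold

from .fragmentation_profile import ProfileMatrix

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.494
_EPS = 1e-12


@dataclass
class FragModel:
    """Trained penalized logistic model over bin proportions.

    ``coefficients`` are on the standardized-feature scale and align with
    ``bin_labels`` (the full feature set used at training); standardization
    parameters are stored so scoring reproduces the training transform.
    """

    bin_labels: list[str]
    coefficients: np.ndarray
    intercept: float
    lambda_: float
    cutoff: float = DEFAULT_CUTOFF
    feature_means: np.ndarray = field(default=None)  # type: ignore[assignment]
    feature_scales: np.ndarray = field(default=None)  # type: ignore[assignment]
    seed: int | None = None
    cv_table: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.feature_means is None:
            self.feature_means = np.zeros_like(self.coefficients)
        if self.feature_scales is None:
            self.feature_scales = np.ones_like(self.coefficients)
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        self.feature_scales = np.asarray(self.feature_scales, dtype=float)

    @property
    def selected_labels(self) -> list[str]:
        """Features with nonzero coefficient (the model's bins)."""
        return [l for l, c in zip(self.bin_labels, self.coefficients) if c != 0.0]

    # -- persistence ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "bin_labels": self.bin_labels,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "lambda": self.lambda_,
            "cutoff": self.cutoff,
            "feature_means": self.feature_means.tolist(),
            "feature_scales": self.feature_scales.tolist(),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FragModel":
        d = json.loads(Path(path).read_text())
        return cls(
            bin_labels=list(d["bin_labels"]),
            coefficients=np.array(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            lambda_=float(d["lambda"]),
            cutoff=float(d["cutoff"]),
            feature_means=np.array(d["feature_means"], dtype=float),
            feature_scales=np.array(d["feature_scales"], dtype=float),
            seed=d.get("seed"),
        )


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1 - _EPS)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=0)
    scales = np.where(scales <= 0, 1.0, scales)
    return (X - means) / scales, means, scales


def _fit_l1(Xs: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # liblinear minimizes C * sum(logloss) + ||w||_1; glmnet-style per-sample
    # penalty lambda corresponds to C = 1 / (n * lambda)
    n = Xs.shape[0]
    clf = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear", max_iter=2000, tol=1e-8,
        random_state=0,
    )
    clf.fit(Xs, y)
    return clf


def train(
    matrix: ProfileMatrix,
    labels: Sequence[int | bool],
    n_folds: int = 5,
    n_repeats: int = 5,
    seed: int = 0,
    lambdas: np.ndarray | None = None,
    cutoff: float | str = DEFAULT_CUTOFF,
) -> FragModel:
    """Train the L1-penalized logistic model with CV-selected penalty.

    Parameters
    ----------
    matrix
        Samples x bins proportion matrix (no missing values).
    labels
        Case (1) / control (0) indicator per sample.
    n_folds, n_repeats
        Repeated stratified k-fold CV; the CV deviance curve is averaged
        over repeats before selecting lambda.
    lambdas
        Penalty grid; default is 60 log-spaced values spanning the
        data-driven maximal lambda down by 4 decades.
    cutoff
        Score threshold stored on the model; the string ``"youden"``
        selects the training-set threshold maximizing sensitivity +
        specificity - 1.
    """
    y = np.asarray(labels, dtype=int)
    X = np.asarray(matrix.values, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("matrix / labels shape mismatch")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; impute first")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present to train")
    if X.shape[0] < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} samples")

    # canonical sample order so fold assignment is permutation-invariant
    order = np.lexsort((matrix.sample_ids,))
    X, y = X[order], y[order]

    Xs, means, scales = _standardize(X)
    n = Xs.shape[0]
    if lambdas is None:
        # smallest lambda that zeroes all coefficients: max |X'(y - ybar)| / n
        ybar = y.mean()
        lam_max = np.abs(Xs.T @ (y - ybar)).max() / n
        lambdas = np.geomspace(lam_max, lam_max * 1e-4, 60)
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]  # large -> small

    cv = RepeatedStratifiedKFold(n_splits=n_folds, n_repeats=n_repeats, random_state=seed)
    dev = np.zeros((len(lambdas), cv.get_n_splits()))
    for k, (tr, te) in enumerate(cv.split(Xs, y)):
        Xtr, mtr, str_ = _standardize(X[tr])
        Xte = (X[te] - mtr) / str_
        for i, lam in enumerate(lambdas):
            clf = _fit_l1(Xtr, y[tr], lam)
            p = clf.predict_proba(Xte)[:, 1]
            dev[i, k] = _deviance(y[te], p)
    mean_dev = dev.mean(axis=1)
    # ties -> first index in the large-to-small grid, i.e. the sparser model
    best = int(np.argmin(mean_dev))
    lam = float(lambdas[best])

    clf = _fit_l1(Xs, y, lam)
    coefs = clf.coef_.ravel().astype(float)
    intercept = float(clf.intercept_[0])
    logger.info(
        "lambda=%.5g selected by CV (mean deviance %.4f); %d of %d features retained",
        lam, mean_dev[best], int((coefs != 0).sum()), len(coefs),
    )

    model = FragModel(
        bin_labels=list(matrix.bin_labels),
        coefficients=coefs,
        intercept=intercept,
        lambda_=lam,
        feature_means=means,
        feature_scales=scales,
        seed=seed,
        cv_table=pd.DataFrame({"lambda": lambdas, "mean_cv_deviance": mean_dev}),
    )
    if cutoff == "youden":
        s = score(model, matrix)
        model.cutoff = youden_cutoff(s[order], y)
    else:
        model.cutoff = float(cutoff)
    return model


def youden_cutoff(scores: np.ndarray, y: np.ndarray) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1,
    evaluated at midpoints between adjacent distinct scores."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    uniq = np.unique(scores)
    cands = np.concatenate(([0.0], (uniq[:-1] + uniq[1:]) / 2, [1.0]))
    best_t, best_j = 0.5, -np.inf
    for t in cands:
        pred = scores >= t
        sens = (pred & (y == 1)).sum() / max((y == 1).sum(), 1)
        spec = (~pred & (y == 0)).sum() / max((y == 0).sum(), 1)
        j = sens + spec - 1
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


def score(model: FragModel, matrix: ProfileMatrix | pd.DataFrame | pd.Series) -> np.ndarray:
    """Model probability in [0, 1] for each sample row.

    Rows must cover every feature label the model was trained on; a
    missing feature raises, naming the bin.
    """
    if isinstance(matrix, ProfileMatrix):
        df = matrix.to_frame()
    elif isinstance(matrix, pd.Series):
        df = matrix.to_frame().T
    else:
        df = matrix
    missing = [l for l in model.bin_labels if l not in df.columns]
    if missing:
        raise KeyError(f"missing model features: {missing[:5]}")
    X = df[model.bin_labels].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("NaN in features to score; impute first")
    Xs = (X - model.feature_means) / model.feature_scales
    eta = Xs @ model.coefficients + model.intercept
    return 1.0 / (1.0 + np.exp(-eta))


def importance(model: FragModel) -> pd.Series:
    """Relative importance (%) of each selected bin.

    Defined as the absolute standardized coefficient over the sum of
    absolute standardized coefficients, times 100; sums to 100 over the
    nonzero features.
    """
    nz = model.coefficients != 0
    if not nz.any():
        raise ValueError("model has no nonzero coefficients")
    mags = np.abs(model.coefficients[nz])
    pct = 100.0 * mags / mags.sum()
    labels = [l for l, keep in zip(model.bin_labels, nz) if keep]
    return pd.Series(pct, index=labels, name="importance_pct").sort_values(ascending=False)


def classify(scores: np.ndarray | float, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray | bool:
    """Positive iff score >= cutoff."""
    arr = np.asarray(scores, dtype=float)
    result = arr >= cutoff
    return bool(result) if np.isscalar(scores) or arr.ndim == 0 else result


def aggregate_subject_window(scored: pd.DataFrame) -> pd.DataFrame:
    """Mean score per (subject, time window).

    ``scored`` needs columns ``subject_id``, ``window`` and ``score``;
    classification is applied after averaging, so the caller thresholds the
    returned mean scores.
    """
    required = {"subject_id", "window", "score"}
    missing = required - set(scored.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = (
        scored.groupby(["subject_id", "window"], sort=True, observed=True)["score"]
        .mean()
        .reset_index()
    )
    return out
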