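"""Two-class quadratic discriminant in explicit polynomial form.

The classifier is Gaussian QDA with class-specific covariances and equal
priors by default.  Rather than scoring through the log-densities, the
score is expanded once into the polynomial

    score(x) = a0 + a'x + x'Cx

with
    a0 = 1/2 ln(|S_ctrl| / |S_pos|)
         + 1/2 (mu_ctrl' S_ctrl^-1 mu_ctrl - mu_pos' S_pos^-1 mu_pos)
         + ln(pi_pos / pi_ctrl)
    a  = S_pos^-1 mu_pos - S_ctrl^-1 mu_ctrl
    C  = 1/2 (S_ctrl^-1 - S_pos^-1)

so the fitted rule can be printed, audited and applied cell-by-cell the
way spreadsheet discriminant reports present it.  Positive scores
indicate the case (MDD/agoraphobia) class; the boundary score 0 is
judged positive; any missing feature yields the judgement "unknown"
(never imputation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import stats_core
from .exceptions import DimensionError, SingularFitError
from .peak_model import PeakTable

__all__ = [
    "QDAModel",
    "DiscriminantCoefficients",
    "DiscriminantReport",
    "fit_qda",
    "expand_polynomial",
    "score",
    "judge",
    "evaluate_training",
]

_COND_LIMIT = 1e12


@dataclass(frozen=True)
class QDAModel:
    feature_ids: tuple[str, ...]
    mu_pos: np.ndarray
    mu_ctrl: np.ndarray
    sigma_pos: np.ndarray
    sigma_ctrl: np.ndarray
    priors: tuple[float, float] = (0.5, 0.5)  # (positive, control)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


@dataclass(frozen=True)
class DiscriminantCoefficients:
    a0: float
    a: np.ndarray  # linear coefficients, one per feature
    C: np.ndarray  # symmetric quadratic coefficient matrix
    feature_ids: tuple[str, ...] = ()

    def quadratic_block(self) -> np.ndarray:
        """The C matrix as the pairwise-product block a spreadsheet report
        prints (b_i * b_j entries)."""
        return np.asarray(self.C, dtype=float)


@dataclass(frozen=True)
class DiscriminantReport:
    subject_ids: tuple[str, ...]
    groups: tuple[str, ...]
    scores: tuple[float, ...]
    judgements: tuple[str, ...]
    probability_positive: float  # % of positive subjects judged positive
    probability_control: float  # % of control subjects judged negative
    error_positive: float
    error_control: float
    box_m: stats_core.BoxMResult

    def as_dict(self) -> dict:
        return {
            "subject_ids": list(self.subject_ids),
            "groups": list(self.groups),
            "scores": list(self.scores),
            "judgements": list(self.judgements),
            "discriminant_probability_percent": {
                "positive": self.probability_positive,
                "control": self.probability_control,
            },
            "error_percent": {
                "positive": self.error_positive,
                "control": self.error_control,
            },
            "box_m": self.box_m.as_dict(),
        }


def _feature_matrix(table: PeakTable, features: Sequence[str]) -> np.ndarray:
    cols = [table.quantifier_areas(f).to_numpy(dtype=float) for f in features]
    return np.column_stack(cols)


def _class_matrices(table: PeakTable, features: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    x = _feature_matrix(table, features)
    groups = np.asarray(table.subjects["group"])
    return x[groups == "positive"], x[groups == "control"]


def fit_qda(
    table: PeakTable,
    features: Sequence[str],
    priors: tuple[float, float] = (0.5, 0.5),
    shrinkage: float = 0.0,
) -> QDAModel:
    """Fit class means and covariances (denominator n-1) on the features'
    quantifier-ion areas.

    Requires more subjects than features per class and well-conditioned
    covariances; optional ``shrinkage`` blends each covariance toward its
    diagonal.
    """
    features = tuple(features)
    xp, xc = _class_matrices(table, features)
    p = len(features)
    for name, x in (("positive", xp), ("control", xc)):
        if x.shape[0] <= p:
            raise SingularFitError(
                f"{name} class has n={x.shape[0]} <= {p} features; "
                "reduce the feature set"
            )
    covs = []
    for name, x in (("positive", xp), ("control", xc)):
        s = np.cov(x, rowvar=False, ddof=1)
        s = np.atleast_2d(s)
        if shrinkage > 0:
            s = (1.0 - shrinkage) * s + shrinkage * np.diag(np.diag(s))
        if np.linalg.cond(s) > _COND_LIMIT:
            raise SingularFitError(
                f"{name} class covariance is ill-conditioned "
                f"(cond > {_COND_LIMIT:.0e}); use fewer features or shrinkage"
            )
        covs.append(s)
    return QDAModel(
        feature_ids=features,
        mu_pos=xp.mean(axis=0),
        mu_ctrl=xc.mean(axis=0),
        sigma_pos=covs[0],
        sigma_ctrl=covs[1],
        priors=priors,
    )


def expand_polynomial(model: QDAModel) -> DiscriminantCoefficients:
    """Expand the QDA log-density difference into constant, linear and
    quadratic coefficients (positive class minus control class)."""
    sp_inv = np.linalg.inv(model.sigma_pos)
    sc_inv = np.linalg.inv(model.sigma_ctrl)
    sign_p, logdet_p = np.linalg.slogdet(model.sigma_pos)
    sign_c, logdet_c = np.linalg.slogdet(model.sigma_ctrl)
    if sign_p <= 0 or sign_c <= 0:
        raise SingularFitError("non-positive-definite class covariance")
    a0 = (
        0.5 * (logdet_c - logdet_p)
        + 0.5 * (model.mu_ctrl @ sc_inv @ model.mu_ctrl - model.mu_pos @ sp_inv @ model.mu_pos)
        + np.log(model.priors[0] / model.priors[1])
    )
    a = sp_inv @ model.mu_pos - sc_inv @ model.mu_ctrl
    c = 0.5 * (sc_inv - sp_inv)
    c = 0.5 * (c + c.T)  # enforce exact symmetry
    return DiscriminantCoefficients(
        a0=float(a0), a=a, C=c, feature_ids=model.feature_ids
    )


def score(coeffs: DiscriminantCoefficients, x: Sequence[float]) -> float:
    """Evaluate a0 + a'x + x'Cx for a complete feature vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != coeffs.a.shape:
        raise DimensionError(
            f"feature vector has length {x.size}, expected {coeffs.a.size}"
        )
    if np.isnan(x).any():
        raise ValueError("score() needs a complete vector; use judge() for missing data")
    return float(coeffs.a0 + coeffs.a @ x + x @ coeffs.C @ x)


def judge(x: Sequence[float], coeffs: DiscriminantCoefficients) -> str:
    """Spreadsheet judgement rule: 'unknown' when any feature is missing
    (NaN), else 'positive' iff score >= 0 (boundary inclusive)."""
    x = np.asarray(x, dtype=float)
    if x.shape != coeffs.a.shape:
        raise DimensionError(
            f"feature vector has length {x.size}, expected {coeffs.a.size}"
        )
    if np.isnan(x).any():
        return "unknown"
    return "positive" if score(coeffs, x) >= 0 else "negative"


def evaluate_training(model: QDAModel, table: PeakTable) -> DiscriminantReport:
    """Score and judge every training subject; report per-class
    discriminant probability (% correct) and Box's M on the class samples."""
    coeffs = expand_polynomial(model)
    x = _feature_matrix(table, model.feature_ids)
    subject_ids = tuple(table.subject_ids)
    groups = tuple(table.subjects["group"])
    scores = tuple(score(coeffs, row) for row in x)
    judgements = tuple(judge(row, coeffs) for row in x)
    n_pos = sum(1 for g in groups if g == "positive")
    n_ctrl = len(groups) - n_pos
    correct_pos = sum(
        1 for g, j in zip(groups, judgements) if g == "positive" and j == "positive"
    )
    correct_ctrl = sum(
        1 for g, j in zip(groups, judgements) if g == "control" and j == "negative"
    )
    prob_pos = 100.0 * correct_pos / n_pos
    prob_ctrl = 100.0 * correct_ctrl / n_ctrl
    xp, xc = _class_matrices(table, model.feature_ids)
    box = stats_core.boxs_m([xp, xc])
    return DiscriminantReport(
        subject_ids=subject_ids,
        groups=groups,
        scores=scores,
        judgements=judgements,
        probability_positive=prob_pos,
        probability_control=prob_ctrl,
        error_positive=100.0 - prob_pos,
        error_control=100.0 - prob_ctrl,
        box_m=box,
    )
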