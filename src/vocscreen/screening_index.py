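"""Combined-VOC screening indices and ROC evaluation.

A combined index is the vector of unstandardized predicted values (often
called PRE-1) from an ordinary least-squares regression of the binary
diagnosis indicator (control = 0, positive = 1) on the member VOCs'
quantifier-ion areas.  Single markers and combined indices are evaluated
by rank-based ROC analysis: AUC = (concordant + 0.5 tied) / (n1 * n2),
which equals the probability that a random positive outranks a random
control, with optional auto-orientation for markers that decrease in
cases.  Indices are correlated against cohort frailty/depression scores
(Pearson and Spearman) and summarised with quadratic and cubic
polynomial curve fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats_core
from .exceptions import InsufficientDataError, SingularFitError
from .peak_model import CohortTable, PeakTable

__all__ = ["CombinedIndex", "ROCResult", "combined_index", "roc", "correlate_index"]


@dataclass(frozen=True)
class CombinedIndex:
    member_ids: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray  # one per member
    values: pd.Series  # per-subject index (PRE-1), subject order preserved
    higher_indicates_positive: bool = True

    def as_dict(self) -> dict:
        return {
            "member_ids": list(self.member_ids),
            "intercept": self.intercept,
            "coefficients": list(map(float, self.coefficients)),
            "values": {k: float(v) for k, v in self.values.items()},
            "higher_indicates_positive": self.higher_indicates_positive,
        }


@dataclass(frozen=True)
class ROCResult:
    thresholds: tuple[float, ...]
    sensitivities: tuple[float, ...]
    specificities: tuple[float, ...]
    auc: float
    youden_cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    orientation_flipped: bool

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "youden_cutoff": self.youden_cutoff,
            "sensitivity_at_cutoff": self.sensitivity_at_cutoff,
            "specificity_at_cutoff": self.specificity_at_cutoff,
            "orientation_flipped": self.orientation_flipped,
            "thresholds": list(self.thresholds),
            "sensitivities": list(self.sensitivities),
            "specificities": list(self.specificities),
        }


def combined_index(table: PeakTable, members: Sequence[str]) -> CombinedIndex:
    """OLS of the diagnosis indicator on the members' quantifier areas;
    the fitted values are the per-subject combined index."""
    members = tuple(members)
    if not members:
        raise ValueError("need at least one member VOC")
    cols = [table.quantifier_areas(m).to_numpy(dtype=float) for m in members]
    x = np.column_stack(cols)
    y = np.asarray(
        [1.0 if g == "positive" else 0.0 for g in table.subjects["group"]]
    )
    design = np.column_stack([np.ones(len(y)), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularFitError("collinear member columns; drop a member")
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    values = pd.Series(fitted, index=pd.Index(table.subject_ids, name="subject_id"))
    return CombinedIndex(
        member_ids=members,
        intercept=float(beta[0]),
        coefficients=beta[1:],
        values=values,
    )


def roc(
    values: Sequence[float],
    labels: Sequence[str],
    auto_orient: bool = True,
) -> ROCResult:
    """Rank-based ROC analysis of a marker or index.

    ``labels`` are 'positive'/'control'.  If the raw AUC is < 0.5 and
    ``auto_orient`` is on, values are negated (decreasing markers).  The
    Youden cutoff maximizes sensitivity + specificity - 1, ties broken
    toward higher sensitivity; the reported cutoff classifies
    ``value >= cutoff`` as positive.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    pos = v[lab == "positive"]
    neg = v[lab == "control"]
    if pos.size == 0 or neg.size == 0:
        raise InsufficientDataError("need both positive and control labels")

    def _auc(p: np.ndarray, c: np.ndarray) -> float:
        greater = (p[:, None] > c[None, :]).sum()
        equal = (p[:, None] == c[None, :]).sum()
        return (greater + 0.5 * equal) / (p.size * c.size)

    flipped = False
    raw = _auc(pos, neg)
    if auto_orient and raw < 0.5:
        v = -v
        pos, neg = -pos, -neg
        raw = _auc(pos, neg)
        flipped = True

    # threshold sweep: "positive if value >= t", from +inf down
    uniq = np.unique(v)[::-1]
    thresholds = [np.inf, *uniq]
    sens, spec = [], []
    for t in thresholds:
        sens.append(float((pos >= t).mean()))
        spec.append(float((neg < t).mean()))
    best = 0
    best_j = -np.inf
    for i, (se, sp) in enumerate(zip(sens, spec)):
        j = se + sp - 1.0
        if j > best_j or (j == best_j and se > sens[best]):
            best, best_j = i, j
    return ROCResult(
        thresholds=tuple(float(t) for t in thresholds),
        sensitivities=tuple(sens),
        specificities=tuple(spec),
        auc=float(raw),
        youden_cutoff=float(thresholds[best]),
        sensitivity_at_cutoff=sens[best],
        specificity_at_cutoff=spec[best],
        orientation_flipped=flipped,
    )


def correlate_index(
    index: CombinedIndex,
    cohort: CohortTable,
    score_name: str,
    exclude_subjects: Sequence[str] = (),
) -> dict:
    """Correlate a combined index with a cohort score.

    Subjects with a missing score are dropped (e.g. the clinician-rated
    depression score exists only for cases); ``exclude_subjects`` removes
    designated subjects.  Returns Pearson and Spearman results plus
    quadratic and cubic polynomial fits of score on index.
    """
    scores = cohort.scores(score_name)
    joined = pd.DataFrame({"index": index.values, "score": scores}).dropna()
    if exclude_subjects:
        joined = joined.drop(index=list(exclude_subjects), errors="ignore")
    if len(joined) < 4:
        raise InsufficientDataError(
            f"only {len(joined)} subjects with non-missing {score_name}"
        )
    x = joined["index"].to_numpy()
    y = joined["score"].to_numpy()
    out = {
        "score_name": score_name,
        "n": int(len(joined)),
        "pearson": stats_core.pearson(x, y),
        "spearman": stats_core.spearman(x, y),
        "quadratic": stats_core.polyfit_f(x, y, degree=2),
        "cubic": stats_core.polyfit_f(x, y, degree=3),
    }
    return out
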