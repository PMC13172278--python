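"""Presence/background model evaluation: rank AUC, TSS, maxSSS threshold.

The classification rule is ``score >= threshold -> presence``.  The
binarization threshold is the candidate score (over all unique observed
scores) that maximizes sensitivity + specificity, taking the smallest
candidate on ties; TSS is sensitivity + specificity - 1 at that threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["ModelEvaluation", "evaluate_predictions"]


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ModelEvaluation:
    auc: float
    tss: float
    threshold: float
    sensitivity: float
    specificity: float


def evaluate_predictions(presence_scores, background_scores) -> ModelEvaluation:
    """Evaluate continuous scores against presence/background labels.

    AUC is the Mann-Whitney rank statistic (ties count one half); the
    threshold is the maxSSS candidate described in the module docstring.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise EvaluationError("presence and background score lists must be nonempty")

    ranks = rankdata(np.concatenate([p, b]))
    auc = (ranks[: p.size].sum() - p.size * (p.size + 1) / 2) / (p.size * b.size)

    candidates = np.unique(np.concatenate([p, b]))
    # sensitivity: fraction of presences >= theta; specificity: backgrounds
    # < theta.  The scan works on integer counts so that exact ties in
    # sensitivity + specificity are broken by the smallest candidate rather
    # than by floating-point summation order.
    sens_count = p.size - np.searchsorted(np.sort(p), candidates, side="left")
    spec_count = np.searchsorted(np.sort(b), candidates, side="left")
    score = sens_count * b.size + spec_count * p.size  # SSS * (n_p * n_b), exactly
    best = int(np.argmax(score))  # argmax returns the first (smallest) candidate on ties
    sens = sens_count[best] / p.size
    spec = spec_count[best] / b.size
    return ModelEvaluation(
        auc=float(auc),
        tss=float(sens + spec - 1.0),
        threshold=float(candidates[best]),
        sensitivity=float(sens),
        specificity=float(spec),
    )
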