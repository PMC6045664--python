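"""Responsiveness threshold from response vs blank-trial distributions.

A single global threshold separates "responsive" glomerulus-odor pairs from
noise. Candidate thresholds are the pooled unique amplitudes; the selection
rule picks the lowest candidate at which responses outnumber blank-trial
responses by at least ``target_ratio`` to one (counting strictly above the
candidate). The full ROC curve and its area are computed alongside but play
no role in the selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ThresholdResult:
    threshold: float
    achieved_ratio: float  # np.inf when no blanks remain above threshold
    roc_points: pd.DataFrame
    auroc: float
    status: str = "ok"  # or "no_threshold"
    target_ratio: float = 10.0


def roc_curve(responses: np.ndarray, blanks: np.ndarray) -> tuple[pd.DataFrame, float]:
    """ROC over the pooled unique candidate thresholds, strict greater-than.

    Returns a table with columns (threshold, n_response_above, n_blank_above,
    tpr, fpr) sorted by ascending threshold, and the trapezoidal area under
    the (FPR, TPR) curve including the (0,0) and (1,1) endpoints.
    """
    responses = np.asarray(responses, dtype=float).ravel()
    blanks = np.asarray(blanks, dtype=float).ravel()
    if responses.size == 0 or blanks.size == 0:
        raise ValueError("both response and blank sets must be non-empty")

    cand = np.unique(np.concatenate([responses, blanks]))
    n_resp_above = (responses[None, :] > cand[:, None]).sum(axis=1)
    n_blank_above = (blanks[None, :] > cand[:, None]).sum(axis=1)
    tpr = n_resp_above / responses.size
    fpr = n_blank_above / blanks.size
    points = pd.DataFrame(
        {
            "threshold": cand,
            "n_response_above": n_resp_above,
            "n_blank_above": n_blank_above,
            "tpr": tpr,
            "fpr": fpr,
        }
    )
    # ascending FPR with the all-positive and all-negative endpoints
    fpr_full = np.concatenate([[0.0], fpr[::-1], [1.0]])
    tpr_full = np.concatenate([[0.0], tpr[::-1], [1.0]])
    auroc = float(np.trapezoid(tpr_full, fpr_full))
    return points, auroc


def select_threshold(
    responses: np.ndarray, blanks: np.ndarray, target_ratio: float = 10.0
) -> ThresholdResult:
    """Lowest candidate threshold achieving the response:blank count ratio.

    Scans candidates in ascending order; a candidate satisfies the criterion
    when (#responses above) / (#blanks above) >= target_ratio, with zero
    blanks above counting as satisfied whenever at least one response
    remains. If no candidate qualifies the result carries status
    "no_threshold" and a NaN threshold.
    """
    if target_ratio <= 0:
        raise ValueError("target_ratio must be positive")
    points, auroc = roc_curve(responses, blanks)
    n_resp = points["n_response_above"].to_numpy()
    n_blank = points["n_blank_above"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(n_blank > 0, n_resp / np.maximum(n_blank, 1), np.inf)
    ok = np.where(n_blank > 0, ratio >= target_ratio, n_resp >= 1)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return ThresholdResult(
            threshold=np.nan, achieved_ratio=np.nan, roc_points=points,
            auroc=auroc, status="no_threshold", target_ratio=target_ratio,
        )
    i = int(idx[0])
    achieved = float(ratio[i]) if n_blank[i] > 0 else np.inf
    return ThresholdResult(
        threshold=float(points["threshold"].iloc[i]),
        achieved_ratio=achieved,
        roc_points=points,
        auroc=auroc,
        status="ok",
        target_ratio=target_ratio,
    )
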