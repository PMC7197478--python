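"""Adapters that make other tools' cell-cycle outputs comparable with ours.

Unsupervised tools produce a cyclic *ordering* of cells; discrete
classifiers produce per-phase scores or G1/S/G2M labels. These are
translated into angles (so the continuous circular-error metric applies)
or into per-class misclassification rates against a reference labeling,
and candidate orderings are judged by how much variance they explain in
the FUCCI scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cyclephase.trend import fit_cyclic_trend
from cyclephase.phase import PHASE_LABELS

__all__ = [
    "ordering_to_angles",
    "scores_to_angles",
    "misclassification_rates",
    "pve_of_scores_given_phase",
]


def ordering_to_angles(ordering: list) -> np.ndarray:
    """Place an inferred cyclic ordering on equidistant unit-circle angles.

    The i-th cell in the order (0-based) receives theta = 2*pi*i/n.
    """
    n = len(ordering)
    if n < 1:
        raise ValueError("empty ordering")
    if len(set(ordering)) != n:
        raise ValueError("ordering contains duplicate cell ids")
    return 2.0 * np.pi * np.arange(n) / n


def scores_to_angles(score_matrix: np.ndarray) -> np.ndarray:
    """Turn per-cell phase scores (2 or 3 columns) into circular angles.

    Mirrors the FUCCI-phase construction: with two scores, each column is
    centered and the angle is atan2(col2, col1). Constant columns are
    dropped first; three (or more) varying columns are projected onto their
    first two principal axes before the same atan2. A cell sitting exactly
    at the column means has no defined angle and raises.
    """
    X = np.atleast_2d(np.asarray(score_matrix, dtype=float))
    if X.shape[1] not in (2, 3):
        raise ValueError("score matrix must have 2 or 3 columns")
    # tolerance absorbs float jitter in numerically constant columns
    keep = X.std(axis=0) > 1e-12 * (1.0 + np.abs(X).max(axis=0))
    X = X[:, keep]
    if X.shape[1] < 2:
        raise ValueError("angle undefined: fewer than 2 varying score columns")
    Xc = X - X.mean(axis=0)
    if Xc.shape[1] > 2:
        # first two principal axes of the centered scores
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        Xc = Xc @ vt[:2].T
    degenerate = np.all(Xc == 0.0, axis=1)
    if degenerate.any():
        raise ValueError(
            f"angle undefined for {int(degenerate.sum())} cell(s) at the "
            "column means"
        )
    return np.mod(np.arctan2(Xc[:, 1], Xc[:, 0]), 2.0 * np.pi)


def misclassification_rates(pred_labels, ref_labels) -> dict[str, float]:
    """Per-reference-class misclassification rate of discrete phase calls.

    For each reference class c, the fraction of cells with reference c whose
    prediction differs. Classes absent from the reference get NaN.
    """
    pred = np.asarray(pred_labels)
    ref = np.asarray(ref_labels)
    if pred.size != ref.size:
        raise ValueError("label vectors must align")
    valid = set(PHASE_LABELS)
    unknown = (set(pred) | set(ref)) - valid
    if unknown:
        raise ValueError(f"unknown label(s) {sorted(unknown)}; expected {PHASE_LABELS}")
    rates = {}
    for c in PHASE_LABELS:
        mask = ref == c
        rates[c] = float((pred[mask] != c).mean()) if mask.any() else float("nan")
    return rates


def pve_of_scores_given_phase(
    fucci_scores: pd.DataFrame | np.ndarray,
    candidate_phase: np.ndarray,
    **fit_kwargs,
) -> tuple[float, float]:
    """Variance in the FUCCI scores explained by a candidate phase.

    Orders the (EGFP, mCherry) scores by the candidate phase, fits a cyclic
    trend to each score column, and returns the two PVEs. An ordering that
    genuinely tracks the cell cycle should explain most of the reporter
    oscillation; an arbitrary ordering should explain almost none.
    """
    if isinstance(fucci_scores, pd.DataFrame):
        eg = fucci_scores["egfp_score"].to_numpy(dtype=float)
        mc = fucci_scores["mcherry_score"].to_numpy(dtype=float)
    else:
        arr = np.atleast_2d(np.asarray(fucci_scores, dtype=float))
        eg, mc = arr[:, 0], arr[:, 1]
    candidate_phase = np.asarray(candidate_phase, dtype=float)
    pve_eg = fit_cyclic_trend(eg, candidate_phase, **fit_kwargs).pve
    pve_mc = fit_cyclic_trend(mc, candidate_phase, **fit_kwargs).pve
    return pve_eg, pve_mc
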