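"""FUCCI-score batch correction, circular phase inference, and PAM labels.

The two FUCCI reporters degrade in antiphase over the cell cycle:
EGFP-geminin accumulates through S/G2/M, mCherry-CDT1 through G1. Plotting
the two log-intensity scores against each other therefore traces a loop, and
each cell's position on that loop — its "FUCCI phase" — is the angle of its
centered score pair. Because images are captured one plate at a time, plate
effects are removed first with an additive two-factor linear model
(score ~ plate + individual) that deliberately retains individual effects.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "correct_batch",
    "infer_fucci_phase",
    "classify_pam",
    "pam",
]

SCORE_COLUMNS = ("egfp_score", "mcherry_score", "dapi_score")
PHASE_LABELS = ("G1", "S", "G2M")


def _check_confounding(scores: pd.DataFrame) -> None:
    tab = pd.crosstab(scores["plate_id"], scores["individual_id"]) > 0
    plates_single = (tab.sum(axis=1) == 1).all()
    indivs_single = (tab.sum(axis=0) == 1).all()
    if plates_single and indivs_single:
        raise ValueError(
            "plate is completely confounded with individual: every plate "
            "contains a single individual and vice versa, so plate and "
            "individual effects cannot be separated"
        )


def correct_batch(scores: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Remove plate effects from FUCCI/DAPI scores, keeping individual effects.

    For each score column independently, fits the additive model
    ``score ~ plate + individual`` with sum-to-zero contrasts and subtracts
    each cell's estimated plate effect. Returns the corrected table (with
    ``corrected = True``) and a diagnostics dict with two tidy frames:
    ``"ftests"`` (Type-III F-test p-values for the plate and individual
    factors, before correction) and ``"plate_effects"`` (per score and plate,
    the estimated sum-to-zero plate effect and its standard error; the
    implied last level has no SE of its own).

    A single-plate table is returned unchanged with a warning; a design in
    which plate and individual are completely aliased raises.
    """
    required = {"plate_id", "individual_id"}
    if not required <= set(scores.columns):
        raise KeyError(f"scores table needs columns {sorted(required)}")
    present = [c for c in SCORE_COLUMNS if c in scores.columns]
    if not present:
        raise KeyError(f"no score columns found (expected any of {SCORE_COLUMNS})")
    out = scores.copy()

    if scores["plate_id"].nunique() < 2:
        warnings.warn("single plate: nothing to correct", UserWarning)
        out["corrected"] = True
        empty = pd.DataFrame(columns=["score", "factor", "F", "p_value"])
        return out, {"ftests": empty, "plate_effects": pd.DataFrame()}
    _check_confounding(scores)

    plates_per_indiv = pd.crosstab(scores["plate_id"], scores["individual_id"]) > 0
    if (plates_per_indiv.sum(axis=1) < 2).any():
        warnings.warn(
            "some plate contains fewer than 2 individuals; plate and "
            "individual effects may be poorly separated",
            UserWarning,
        )

    df = scores.copy()
    df["plate_id"] = df["plate_id"].astype(str)
    df["individual_id"] = df["individual_id"].astype(str)
    rows = []
    effect_rows = []
    for col in present:
        model = smf.ols(
            f"{col} ~ C(plate_id, Sum) + C(individual_id, Sum)", data=df
        ).fit()
        anova = sm.stats.anova_lm(model, typ=3)
        for factor, label in (
            ("C(plate_id, Sum)", "plate"),
            ("C(individual_id, Sum)", "individual"),
        ):
            rows.append(
                {
                    "score": col,
                    "factor": label,
                    "F": float(anova.loc[factor, "F"]),
                    "p_value": float(anova.loc[factor, "PR(>F)"]),
                }
            )
        # per-cell plate effect: sum-to-zero coefficients, last level implied
        plates = sorted(df["plate_id"].unique())
        coefs = {}
        for p in plates[:-1]:
            term = f"C(plate_id, Sum)[S.{p}]"
            coefs[p] = float(model.params.get(term, 0.0))
            effect_rows.append(
                {
                    "score": col,
                    "plate_id": p,
                    "effect": coefs[p],
                    "se": float(model.bse.get(term, np.nan)),
                }
            )
        coefs[plates[-1]] = -sum(coefs.values())
        effect_rows.append(
            {
                "score": col,
                "plate_id": plates[-1],
                "effect": coefs[plates[-1]],
                "se": np.nan,
            }
        )
        out[col] = scores[col].to_numpy() - df["plate_id"].map(coefs).to_numpy()
    out["corrected"] = True
    return out, {
        "ftests": pd.DataFrame(rows),
        "plate_effects": pd.DataFrame(effect_rows),
    }


def infer_fucci_phase(
    scores: pd.DataFrame, rotation: float = 0.0
) -> np.ndarray:
    """Map corrected FUCCI scores to angles on [0, 2pi).

    Each score column is centered at its mean; the phase is the quadrant-aware
    inverse tangent ``atan2(egfp_centered, mcherry_centered)`` (mCherry on the
    x-axis, EGFP on the y-axis), optionally rotated by a fixed offset. Cells
    with both centered scores exactly zero have no defined angle and raise.
    """
    if "corrected" in scores.columns and not scores["corrected"].all():
        raise ValueError("scores must be batch-corrected before phase inference")
    eg = scores["egfp_score"].to_numpy(dtype=float)
    mc = scores["mcherry_score"].to_numpy(dtype=float)
    egc = eg - eg.mean()
    mcc = mc - mc.mean()
    degenerate = (egc == 0.0) & (mcc == 0.0)
    if degenerate.any():
        raise ValueError(
            f"angle undefined for {int(degenerate.sum())} cell(s) whose "
            "centered scores are both exactly zero"
        )
    theta = np.arctan2(egc, mcc) + rotation
    return np.mod(theta, 2.0 * np.pi)


def pam(points: np.ndarray, k: int, seed: int = 0, max_swaps: int = 200) -> np.ndarray:
    """Partition around medoids (build + swap), Euclidean distance.

    Deterministic given the input order: BUILD greedily seeds medoids by
    total-cost reduction, then SWAP accepts the best medoid/non-medoid
    exchange while the objective (sum of distances to the nearest medoid)
    strictly decreases. Returns the medoid indices' assignment per point.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if np.unique(points, axis=0).shape[0] < k:
        raise ValueError(f"need at least {k} distinct points")
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))

    # BUILD
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        cur = d[:, medoids].min(axis=1)
        gains = np.maximum(cur[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    # SWAP
    def cost(meds):
        return d[:, meds].min(axis=1).sum()

    best = cost(medoids)
    for _ in range(max_swaps):
        improved = False
        for mi in range(k):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                c = cost(trial)
                if c < best - 1e-12:
                    best, medoids, improved = c, trial, True
        if not improved:
            break
    return np.argmin(d[:, medoids], axis=1), np.array(medoids)


def classify_pam(
    scores: pd.DataFrame, seed: int = 0
) -> tuple[np.ndarray, dict[str, int]]:
    """Assign discrete G1/S/G2M labels by k-medoids on (EGFP, mCherry) scores.

    k is fixed at 3. Clusters are mapped to phases by medoid position in
    score space: the medoid with the largest (mCherry - EGFP) is G1 (CDT1
    high), the largest (EGFP - mCherry) is G2/M (geminin high), and the
    remaining cluster is S. Returns per-cell labels and per-class counts.
    """
    pts = scores[["egfp_score", "mcherry_score"]].to_numpy(dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 cells for 3-phase classification")
    assign, medoids = pam(pts, 3, seed=seed)
    med_pts = pts[medoids]
    g1 = int(np.argmax(med_pts[:, 1] - med_pts[:, 0]))
    g2m = int(np.argmax(med_pts[:, 0] - med_pts[:, 1]))
    if g1 == g2m:  # degenerate geometry; fall back to deterministic order
        g1, g2m = 0, 2 if g1 != 2 else 1
    s = ({0, 1, 2} - {g1, g2m}).pop()
    mapping = {g1: "G1", s: "S", g2m: "G2M"}
    labels = np.array([mapping[a] for a in assign])
    counts = {lab: int((labels == lab).sum()) for lab in PHASE_LABELS}
    return labels, counts
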