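"""Supervised continuous cell-cycle phase prediction (naive-Bayes on a grid).

Training learns, for each marker gene g, a cyclic trend f_g(theta) and a
residual scale sigma_g from cells with known FUCCI phase. Prediction
evaluates, for a new cell's quantile-normalized expression vector y, the
log-likelihood

    log L(k) = sum_g log Normal(y_g | f_g(theta_k), sigma_g)

on a grid of K equally spaced candidate phases (uniform prior) and returns
the maximizing grid angle. Genes are treated as independent given phase —
the "naive" assumption — which works well because the few strongly cyclic
marker genes carry nearly orthogonal phase information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from cyclephase.trend import CyclicTrend, fit_cyclic_trend

__all__ = [
    "PhaseGrid",
    "TrainedPredictor",
    "PredictionResult",
    "DEFAULT_PREDICTOR_GENES",
    "train_predictor",
    "evaluate_trend_at",
    "predict_phase",
    "circular_error",
    "cross_validate_by_individual",
]

#: The five most significantly cyclic genes in the training study, used as
#: the default marker panel: CDK1 (mitotic entry), UBE2C (mitotic cyclin
#: degradation), TOP2A (DNA topology during division), and the
#: replication-dependent histones H4C5 and H4C3 (S phase).
DEFAULT_PREDICTOR_GENES = ("CDK1", "UBE2C", "TOP2A", "H4C5", "H4C3")


@dataclass
class PhaseGrid:
    """K equally spaced candidate phases {2*pi*k/K : k = 0..K-1}."""

    K: int = 100

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("grid needs at least 2 angles")
        self.angles = 2.0 * np.pi * np.arange(self.K) / self.K


@dataclass
class TrainedPredictor:
    """Ranked cyclic trends plus the phase grid; the serializable model."""

    trends: list[CyclicTrend]
    grid: PhaseGrid
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.trends) < 2:
            raise ValueError(
                "phase is unidentifiable from a single gene; need >= 2 trends"
            )

    @property
    def gene_ids(self) -> list[str]:
        return [t.gene_id for t in self.trends]


@dataclass
class PredictionResult:
    theta_hat: float
    loglik_profile: np.ndarray

    @property
    def max_loglik(self) -> float:
        return float(self.loglik_profile.max())


def train_predictor(
    normalized: np.ndarray,
    thetas: np.ndarray,
    gene_ids: list[str],
    K: int = 100,
    provenance: dict | None = None,
    **fit_kwargs,
) -> TrainedPredictor:
    """Fit per-gene cyclic trends on labeled training cells.

    ``normalized`` is genes x cells on the quantile-normalized scale, rows
    aligned with ``gene_ids`` (typically the ranked top cyclic genes);
    ``thetas`` are the cells' FUCCI phases in [0, 2pi).
    """
    normalized = np.atleast_2d(np.asarray(normalized, dtype=float))
    if len(gene_ids) != normalized.shape[0]:
        raise ValueError("one gene id per matrix row required")
    if len(gene_ids) < 2:
        raise ValueError("phase is unidentifiable from a single gene")
    if normalized.shape[1] < 10:
        raise ValueError("need at least 10 training cells")
    trends = [
        fit_cyclic_trend(normalized[g], thetas, gene_id=gene_ids[g], **fit_kwargs)
        for g in range(len(gene_ids))
    ]
    return TrainedPredictor(
        trends=trends, grid=PhaseGrid(K), provenance=provenance or {}
    )


def evaluate_trend_at(trend: CyclicTrend, theta: float | np.ndarray) -> np.ndarray:
    """Evaluate a fitted cyclic trend at arbitrary angles.

    Circular linear interpolation between the two flanking training angles,
    wrapping across the 0/2pi seam (an angle beyond the last training angle
    interpolates toward the first one, one period up).
    """
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    xs = trend.train_thetas
    ys = trend.fitted_values
    if xs.size == 0:
        raise ValueError("empty trend")
    period = 2.0 * np.pi
    xp = np.concatenate([xs, [xs[0] + period]])
    fp = np.concatenate([ys, [ys[0]]])
    thw = np.mod(th, period)
    # angles below the first training angle wrap to the top interval
    thw = np.where(thw < xs[0], thw + period, thw)
    out = np.interp(thw, xp, fp)
    return out if np.ndim(theta) else float(out[0])


def predict_phase(
    cell_expression: np.ndarray, model: TrainedPredictor
) -> PredictionResult | list[PredictionResult]:
    """Predict continuous phase for one cell (1-D) or a batch (cells x genes).

    The expression vector must be aligned with ``model.gene_ids`` and on the
    model's normalized scale. Cells are predicted independently; ties at the
    likelihood maximum resolve to the smallest grid index.
    """
    y = np.asarray(cell_expression, dtype=float)
    single = y.ndim == 1
    y = np.atleast_2d(y)
    G = len(model.trends)
    if y.shape[1] != G:
        raise ValueError(
            f"expression has {y.shape[1]} genes; model expects {G} "
            f"({model.gene_ids}); missing genes are not imputed"
        )
    if np.isnan(y).any():
        bad = [model.gene_ids[g] for g in np.nonzero(np.isnan(y).any(axis=0))[0]]
        raise ValueError(f"missing expression values for gene(s): {bad}")
    angles = model.grid.angles
    fgrid = np.stack([evaluate_trend_at(t, angles) for t in model.trends])  # G x K
    sigmas = np.array([t.sigma for t in model.trends])
    # log L[m, k] = sum_g log phi((y_mg - f_gk) / sigma_g) - log sigma_g
    z = (y[:, :, None] - fgrid[None, :, :]) / sigmas[None, :, None]
    loglik = norm.logpdf(z).sum(axis=1) - np.log(sigmas).sum()
    kmax = np.argmax(loglik, axis=1)
    results = [
        PredictionResult(theta_hat=float(angles[k]), loglik_profile=loglik[m])
        for m, k in enumerate(kmax)
    ]
    return results[0] if single else results


def circular_error(theta_pred, theta_true) -> np.ndarray | float:
    """Circular distance as a fraction of the full cycle, in [0, 0.5]."""
    a = np.asarray(theta_pred, dtype=float)
    b = np.asarray(theta_true, dtype=float)
    delta = np.abs(a - b) % (2.0 * np.pi)
    delta = np.minimum(delta, 2.0 * np.pi - delta)
    err = delta / (2.0 * np.pi)
    return float(err) if err.ndim == 0 else err


def cross_validate_by_individual(
    normalized: np.ndarray,
    thetas: np.ndarray,
    individuals: np.ndarray,
    gene_ids: list[str],
    n_top_genes_list: tuple[int, ...] = (5,),
    K: int = 100,
    **fit_kwargs,
) -> pd.DataFrame:
    """Leave-one-individual-out evaluation of the phase predictor.

    One fold per individual: its cells are held out entirely, trends are fit
    and the cyclic-gene ranking recomputed on the remaining cells, and the
    held-out cells' phases are predicted with the top-``n`` genes for each
    ``n`` in ``n_top_genes_list``. Reports the mean circular error (fraction
    of cycle) and its standard error per fold and gene count.
    """
    normalized = np.atleast_2d(np.asarray(normalized, dtype=float))
    thetas = np.asarray(thetas, dtype=float)
    individuals = np.asarray(individuals)
    uniq = pd.unique(individuals)
    if uniq.size < 2:
        raise ValueError("leave-one-individual-out needs >= 2 individuals")
    rows = []
    for indiv in uniq:
        test_mask = individuals == indiv
        if test_mask.sum() < 5:
            warnings.warn(
                f"individual {indiv!r} has fewer than 5 cells; "
                "fold evaluated anyway",
                UserWarning,
            )
        train_mask = ~test_mask
        trends = [
            fit_cyclic_trend(
                normalized[g, train_mask],
                thetas[train_mask],
                gene_id=gene_ids[g],
                **fit_kwargs,
            )
            for g in range(len(gene_ids))
        ]
        ranking = np.argsort([-t.pve for t in trends], kind="stable")
        for n_top in n_top_genes_list:
            chosen = ranking[:n_top]
            model = TrainedPredictor(
                trends=[trends[g] for g in chosen], grid=PhaseGrid(K)
            )
            preds = predict_phase(normalized[np.ix_(chosen, np.nonzero(test_mask)[0])].T, model)
            errs = circular_error(
                np.array([p.theta_hat for p in preds]), thetas[test_mask]
            )
            rows.append(
                {
                    "individual": indiv,
                    "n_genes": int(n_top),
                    "n_cells": int(test_mask.sum()),
                    "mean_error": float(np.mean(errs)),
                    "se_error": float(np.std(errs, ddof=1) / np.sqrt(errs.size))
                    if errs.size > 1
                    else float("nan"),
                }
            )
    return pd.DataFrame(rows)
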