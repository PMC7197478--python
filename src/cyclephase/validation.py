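"""Self-contained validation experiments on synthetic ground truth.

Each function builds its own inputs with the synthetic generator, runs one
pipeline capability, and returns the measured quantities. They serve as the
package's reproducible benchmark suite: the analytic baselines (random-guess
error, error-metric bound), the solver cross-check against an independent
convex-programming route, permutation-test calibration, end-to-end phase
recovery with leave-one-individual-out folds and binomial thinning, planted
plate-offset recovery, and the imaging closed form.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear
from scipy.stats import kstest

from cyclephase import simulate as sim
from cyclephase.imaging import detect_nuclei, score_channel
from cyclephase.phase import correct_batch
from cyclephase.predictor import (
    PhaseGrid,
    circular_error,
    predict_phase,
    train_predictor,
)
from cyclephase.qc import CountMatrix, normalize_counts
from cyclephase.trend import (
    _diff_stencil,
    fit_cyclic_trend,
    permutation_test,
    trendfilter_solve,
)

__all__ = [
    "random_guess_error",
    "max_circular_error_on_grid",
    "grid_contract",
    "solver_vs_oracle",
    "seam_continuity",
    "permutation_calibration",
    "loio_recovery",
    "batch_recovery",
    "imaging_closed_form",
]


def random_guess_error(n: int = 1_000_000, seed: int = 0) -> float:
    """Mean circular error of uniform-random predictions vs truths (~0.25)."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 2 * np.pi, n)
    b = rng.uniform(0, 2 * np.pi, n)
    return float(circular_error(a, b).mean())


def max_circular_error_on_grid(resolution: int = 360) -> float:
    """Largest circular error over a dense angle-pair grid (= 0.5)."""
    grid = np.linspace(0, 2 * np.pi, resolution, endpoint=False)
    return float(circular_error(grid[:, None], grid[None, :]).max())


def grid_contract(seed: int = 0) -> dict:
    """Default grid size and whether predictions land on grid members."""
    rng = np.random.default_rng(seed)
    theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
    Y = np.array([np.cos(theta), np.sin(theta)]) + rng.normal(0, 0.2, (2, 200))
    model = train_predictor(Y, theta, ["a", "b"], n_lambda=10)
    obs = rng.normal(size=(25, 2))
    preds = predict_phase(obs, model)
    grid = set(model.grid.angles.tolist())
    return {
        "K": model.grid.K,
        "profile_lengths": {p.loglik_profile.size for p in preds},
        "all_on_grid": all(p.theta_hat in grid for p in preds),
        "default_K": PhaseGrid().K,
    }


def _oracle_solve(y: np.ndarray, lam: float, order: int = 2) -> np.ndarray:
    """Independent route: dense box-constrained least squares on the dual."""
    c = _diff_stencil(order)
    n = y.size
    m = n - (order + 1)
    D = np.zeros((m, n))
    for r in range(m):
        D[r, r : r + order + 2] = c
    res = lsq_linear(D.T, y, bounds=(-lam, lam), tol=1e-14, max_iter=2000)
    return y - D.T @ res.x


def solver_vs_oracle(n_instances: int = 50, seed: int = 0) -> float:
    """Max per-coordinate deviation from the convex oracle over instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for trial in range(n_instances):
        n = int(rng.integers(8, 61))
        y = rng.normal(size=n) * rng.uniform(0.5, 3.0)
        lam = (0.1, 1.0, 10.0)[trial % 3]
        dev = np.max(np.abs(trendfilter_solve(y, lam) - _oracle_solve(y, lam)))
        worst = max(worst, float(dev))
    return worst


def seam_continuity(n: int = 200) -> dict:
    """Noiseless-cosine recovery: max deviation and 0/2pi seam gap."""
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ct = fit_cyclic_trend(np.cos(theta), theta)
    return {
        "max_dev": float(np.max(np.abs(ct.fitted_values - np.cos(ct.train_thetas)))),
        "seam_gap": float(abs(ct.fitted_values[0] - ct.fitted_values[-1])),
    }


def permutation_calibration(
    n_genes: int = 200, n_cells: int = 80, B: int = 200, seed: int = 0
) -> dict:
    """KS test of null-gene permutation p-values against uniform."""
    rng = np.random.default_rng(seed)
    theta = sim.simulate_phases(n_cells, seed=seed)
    values = rng.normal(size=(n_genes, n_cells))
    report = permutation_test(values, theta, B=B, seed=seed)
    ks = kstest(report["empirical_p"].to_numpy(), "uniform")
    return {"ks_p": float(ks.pvalue), "ks_stat": float(ks.statistic)}


def loio_recovery(
    seed: int = 1,
    sizes: dict | None = None,
    noise_sd: float = 0.3,
    thin_factor: float = 2.2,
) -> dict:
    """Leave-one-individual-out phase recovery through the count pipeline.

    Five quadrature marker genes (amplitude 1, noise sigma on the normalized
    scale) plus 100 null genes are simulated at the count level; counts are
    CPM-standardized and quantile-normalized per cohort; the predictor is
    trained on each fold's training individuals and evaluated on the held-out
    individual, with and without binomial thinning of the held-out counts.
    """
    sizes = sizes or {"A": 100, "B": 250, "C": 250}
    n = sum(sizes.values())
    rng = np.random.default_rng(seed)
    theta = sim.simulate_phases(n, seed=seed)
    indiv = np.concatenate([[k] * v for k, v in sizes.items()])
    G = 105
    amp = np.zeros(G)
    amp[:5] = 1.0
    off = np.concatenate(
        [np.linspace(0, 2 * np.pi, 5, endpoint=False), rng.uniform(0, 2 * np.pi, 100)]
    )
    base = np.concatenate([np.full(5, 3.0), rng.normal(1.0, 1.0, 100)])
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(G)],
            "amplitude": amp,
            "phase_offset": off,
            "baseline": base,
            "noise_sd": np.full(G, noise_sd),
            "is_cyclic": amp > 0,
        }
    )
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "theta_true": theta,
            "individual_id": indiv,
            "plate_id": "p0",
            "library_size": rng.lognormal(np.log(5e4), 0.25, n),
        }
    )
    truth = sim.SyntheticTruth(cells=cells, genes=genes, seed=seed)
    _, cm = sim.simulate_cyclic_expression(truth)

    marker_ids = [f"g{i}" for i in range(5)]
    errors, errors_thinned = [], []
    for held in sizes:
        te = indiv == held
        tr = ~te
        cm_tr = CountMatrix(
            cm.counts[:, tr], cm.gene_ids,
            [c for c, m in zip(cm.cell_ids, tr) if m],
        )
        cm_te = CountMatrix(
            cm.counts[:, te], cm.gene_ids,
            [c for c, m in zip(cm.cell_ids, te) if m],
        )
        Ztr = normalize_counts(cm_tr, seed=seed)
        model = train_predictor(Ztr[:5], theta[tr], marker_ids)

        def fold_error(cmat):
            Zte = normalize_counts(cmat, seed=seed)
            preds = predict_phase(Zte[:5].T, model)
            return float(
                circular_error(
                    np.array([p.theta_hat for p in preds]), theta[te]
                ).mean()
            )

        errors.append(fold_error(cm_te))
        errors_thinned.append(
            fold_error(sim.thin_counts(cm_te, thin_factor, seed=seed + 9))
        )
    return {
        "mean_error": float(np.mean(errors)),
        "mean_error_thinned": float(np.mean(errors_thinned)),
        "fold_errors": errors,
        "fold_errors_thinned": errors_thinned,
        "n_cells": n,
    }


def batch_recovery(seed: int = 2) -> dict:
    """Planted plate-offset recovery and post-correction plate F-test."""
    n = 240
    theta = sim.simulate_phases(n, seed=seed)
    plates = np.repeat([f"p{i}" for i in range(4)], n // 4)
    indivs = np.tile(np.repeat(["a", "b", "c"], n // 12), 4)
    plate_offsets = {"p0": 0.3, "p1": -0.2, "p2": 0.0, "p3": 0.5}
    indiv_offsets = {"a": 0.1, "b": -0.3, "c": 0.2}
    scores = sim.simulate_fucci_scores(
        theta, plates, indivs, noise_sd=0.1,
        plate_offsets=plate_offsets, individual_offsets=indiv_offsets,
        seed=seed + 1,
    )
    corrected, diag = correct_batch(scores)
    mean_off = np.mean(list(plate_offsets.values()))
    zs = []
    for col in ("egfp_score", "mcherry_score"):
        est = diag["plate_effects"]
        est = est[(est.score == col) & est.se.notna()]
        for _, row in est.iterrows():
            truth_val = plate_offsets[row.plate_id] - mean_off
            zs.append(abs(row.effect - truth_val) / row.se)
    _, diag2 = correct_batch(corrected.drop(columns="corrected"))
    post = diag2["ftests"]
    post_p = post[
        (post.factor == "plate") & post.score.isin(["egfp_score", "mcherry_score"])
    ].p_value.min()
    return {"max_offset_z": float(max(zs)), "post_correction_plate_p": float(post_p)}


def imaging_closed_form(seed: int = 3) -> dict:
    """Noiseless-disk scoring vs log10(area x intensity); nucleus counts."""
    images, truth = sim.simulate_channel_images(
        [(60.0, 80.0, 12.0)],
        {"DAPI": [50.0], "EGFP": [20.0], "MCHERRY": [5.0]},
        background=10.0, noise_sd=0.0, size=(256, 256), seed=seed,
    )
    area = truth[0]["area_px"]
    score = score_channel(images["EGFP"], truth[0]["centroid"])
    dev = abs(score - np.log10(area * 20.0))

    spots = [(60, 60, 10), (60, 160, 10), (160, 60, 10), (160, 160, 10),
             (110, 110, 10)]
    detected = []
    for k in range(1, 6):
        imgs, _ = sim.simulate_channel_images(
            spots[:k], {"DAPI": [40.0] * k}, background=10.0, noise_sd=2.0,
            size=(256, 256), seed=seed + k,
        )
        detected.append(detect_nuclei(imgs["DAPI"]).count)
    return {
        "score_abs_dev": float(dev),
        "detected_counts": detected,
        "planted_counts": list(range(1, 6)),
    }
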