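"""Synthetic paired FUCCI + scRNA-seq data with known ground truth.

Every stage of the pipeline can be exercised without downloads: the
generator plants circular cell phases, per-gene smooth cyclic expression
trends (cosines with configurable amplitude, offset and Gaussian noise on
the normalized scale), count-level data with cyclic log-means, library-size
variation and dropout via Poisson sampling, FUCCI reporter scores
oscillating in quadrature with additive plate and individual effects, and
simple two-channel disk images on a noisy background.

Defaults emulate the training study at reduced size: 300 cells from 6
individuals spread over 8 plates in an incomplete block design, 250 genes of
which 20 are cyclic, library sizes around 5e4 molecules, and unit-amplitude
reporter oscillation with plate offsets a few tenths of a log10 unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cyclephase.qc import CountMatrix
from cyclephase.imaging import ChannelImage

__all__ = [
    "SyntheticTruth",
    "make_truth",
    "simulate_phases",
    "simulate_cyclic_expression",
    "simulate_fucci_scores",
    "thin_counts",
    "simulate_channel_images",
]


@dataclass
class SyntheticTruth:
    """Ground-truth cell and gene tables plus the seeds that made them."""

    cells: pd.DataFrame  # cell_id, theta_true, individual_id, plate_id, library_size
    genes: pd.DataFrame  # gene_id, amplitude, phase_offset, baseline, noise_sd, is_cyclic
    seed: int


def simulate_phases(
    n: int, seed: int = 0, distribution: str = "uniform", kappa: float = 2.0
) -> np.ndarray:
    """Draw i.i.d. cell phases on [0, 2pi); uniform or a von Mises mixture."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    if distribution == "uniform":
        return rng.uniform(0.0, 2.0 * np.pi, n)
    if distribution == "vonmises":
        centers = rng.choice([0.5 * np.pi, 1.5 * np.pi], size=n)
        return np.mod(rng.vonmises(centers, kappa), 2.0 * np.pi)
    raise ValueError(f"unknown phase distribution {distribution!r}")


def make_truth(
    n_cells: int = 300,
    n_genes: int = 250,
    n_cyclic: int = 20,
    n_individuals: int = 6,
    n_plates: int = 8,
    amplitude: float = 1.0,
    noise_sd: float = 0.3,
    mean_library_size: float = 5e4,
    library_size_cv: float = 0.25,
    seed: int = 0,
) -> SyntheticTruth:
    """Build a ground-truth design emulating the study at reduced size."""
    rng = np.random.default_rng(seed)
    theta = simulate_phases(n_cells, seed=seed)
    individuals = np.array([f"NA{18850 + i}" for i in range(n_individuals)])
    indiv = rng.choice(individuals, size=n_cells)
    # plates hold cells from a pair of individuals, emulating the block design
    plate_of_cell = np.empty(n_cells, dtype=object)
    plate_pairs = [
        tuple(rng.choice(n_individuals, size=2, replace=False))
        for _ in range(n_plates)
    ]
    for i in range(n_cells):
        gi = np.nonzero(individuals == indiv[i])[0][0]
        eligible = [p for p, pair in enumerate(plate_pairs) if gi in pair]
        if not eligible:
            eligible = list(range(n_plates))
        plate_of_cell[i] = f"plate{rng.choice(eligible):02d}"
    lib = rng.lognormal(
        np.log(mean_library_size) - 0.5 * np.log1p(library_size_cv**2),
        np.sqrt(np.log1p(library_size_cv**2)),
        n_cells,
    )
    cells = pd.DataFrame(
        {
            "cell_id": [f"cell{i:04d}" for i in range(n_cells)],
            "theta_true": theta,
            "individual_id": indiv,
            "plate_id": plate_of_cell,
            "library_size": lib,
        }
    )
    is_cyclic = np.zeros(n_genes, dtype=bool)
    is_cyclic[:n_cyclic] = True
    genes = pd.DataFrame(
        {
            "gene_id": [f"gene{g:04d}" for g in range(n_genes)],
            "amplitude": np.where(is_cyclic, amplitude, 0.0),
            "phase_offset": rng.uniform(0.0, 2.0 * np.pi, n_genes),
            "baseline": rng.normal(1.0, 1.0, n_genes),
            "noise_sd": np.full(n_genes, noise_sd),
            "is_cyclic": is_cyclic,
        }
    )
    return SyntheticTruth(cells=cells, genes=genes, seed=seed)


def simulate_cyclic_expression(
    truth: SyntheticTruth,
) -> tuple[np.ndarray, CountMatrix]:
    """Generate normalized-scale values and molecule counts from the truth.

    Normalized scale: y_gc = amplitude_g * cos(theta_c + offset_g) + eps,
    eps ~ N(0, noise_sd_g^2); non-cyclic genes have amplitude 0. Count
    scale: counts_gc ~ Poisson(library_size_c * p_gc) with gene proportions
    p_gc the softmax over genes of baseline_g + amplitude_g *
    cos(theta_c + offset_g), which yields realistic dropout at small
    library sizes.
    """
    rng = np.random.default_rng(truth.seed + 1)
    theta = truth.cells["theta_true"].to_numpy()
    amp = truth.genes["amplitude"].to_numpy()[:, None]
    off = truth.genes["phase_offset"].to_numpy()[:, None]
    base = truth.genes["baseline"].to_numpy()[:, None]
    sd = truth.genes["noise_sd"].to_numpy()[:, None]
    signal = amp * np.cos(theta[None, :] + off)
    normalized = signal + rng.normal(0.0, 1.0, signal.shape) * sd

    logits = base + signal
    logits -= logits.max(axis=0, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=0, keepdims=True)
    lam = truth.cells["library_size"].to_numpy()[None, :] * p
    counts = rng.poisson(lam)
    cm = CountMatrix(
        counts,
        truth.genes["gene_id"].tolist(),
        truth.cells["cell_id"].tolist(),
    )
    return normalized, cm


def simulate_fucci_scores(
    thetas: np.ndarray,
    plates: np.ndarray,
    individuals: np.ndarray,
    noise_sd: float = 0.05,
    plate_offsets: dict | None = None,
    individual_offsets: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Reporter scores in quadrature with additive batch structure.

    egfp = sin(theta) + plate + individual + eps and
    mcherry = cos(theta) + plate + individual + eps, so the pair traces the
    unit circle as the cell progresses; a DAPI score with plate structure
    but no phase dependence is included for completeness.
    """
    thetas = np.asarray(thetas, dtype=float)
    plates = np.asarray(plates)
    individuals = np.asarray(individuals)
    rng = np.random.default_rng(seed)
    p_off = np.array([(plate_offsets or {}).get(p, 0.0) for p in plates])
    i_off = np.array([(individual_offsets or {}).get(i, 0.0) for i in individuals])
    n = thetas.size
    egfp = np.sin(thetas) + p_off + i_off + rng.normal(0, noise_sd, n)
    mcherry = np.cos(thetas) + p_off + i_off + rng.normal(0, noise_sd, n)
    dapi = 3.0 + p_off + rng.normal(0, noise_sd, n)
    return pd.DataFrame(
        {
            "cell_id": [f"cell{i:04d}" for i in range(n)],
            "egfp_score": egfp,
            "mcherry_score": mcherry,
            "dapi_score": dapi,
            "plate_id": plates,
            "individual_id": individuals,
            "corrected": False,
        }
    )


def thin_counts(counts: CountMatrix, factor: float, seed: int = 0) -> CountMatrix:
    """Binomially downsample counts by ``factor``, emulating lower depth.

    Each molecule survives independently with probability 1/factor, so
    E[thinned] = counts / factor and zeros stay zero.
    """
    if factor < 1:
        raise ValueError("thinning factor must be >= 1")
    if factor == 1:
        return CountMatrix(counts.counts.copy(), counts.gene_ids, counts.cell_ids)
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(counts.counts.astype(np.int64), 1.0 / factor)
    return CountMatrix(thinned, counts.gene_ids, counts.cell_ids)


def simulate_channel_images(
    nuclei: list[tuple[float, float, float]],
    intensities: dict[str, list[float]],
    background: float = 10.0,
    noise_sd: float = 0.0,
    size: tuple[int, int] = (512, 512),
    well_id: str = "well00",
    seed: int = 0,
) -> tuple[dict[str, ChannelImage], list[dict]]:
    """Render disk 'nuclei' on a flat background, one image per channel.

    ``nuclei`` is a list of (row, col, radius); ``intensities`` maps channel
    name to the per-disk added intensity above background. Gaussian pixel
    noise is added and clipped at zero. Returns the channel images and a
    per-disk truth record (centroid, radius and exact pixel area from the
    rendered mask). Overlapping disks are allowed but warned about.
    """
    rng = np.random.default_rng(seed)
    nr, nc = size
    rr, cc = np.mgrid[0:nr, 0:nc]
    masks = []
    for r, c, rad in nuclei:
        if not (rad <= r <= nr - 1 - rad and rad <= c <= nc - 1 - rad):
            raise ValueError("disk extends outside the image bounds")
        masks.append((rr - r) ** 2 + (cc - c) ** 2 <= rad**2)
    if len(masks) > 1:
        union = np.zeros(size, dtype=int)
        for m in masks:
            union += m
        if (union > 1).any():
            warnings.warn("overlapping disks in simulated image", UserWarning)
    images = {}
    for ch, vals in intensities.items():
        if len(vals) != len(nuclei):
            raise ValueError(f"one intensity per disk required for {ch}")
        img = np.full(size, float(background))
        for m, v in zip(masks, vals):
            img[m] += v
        if noise_sd > 0:
            img = np.clip(img + rng.normal(0, noise_sd, size), 0.0, None)
        images[ch.upper()] = ChannelImage(img, ch, well_id)
    truth = [
        {
            "centroid": (r, c),
            "radius": rad,
            "area_px": int(m.sum()),
        }
        for (r, c, rad), m in zip(nuclei, masks)
    ]
    return images, truth
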