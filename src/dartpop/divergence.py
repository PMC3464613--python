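"""Per-locus divergence between two line groups and its sliding-window scan.

The default per-locus metric is the single-locus modified Rogers' distance
``sqrt(((p1-p2)^2 + (q1-q2)^2) / 2)`` which for biallelic loci equals
``|p1 - p2|``.  Windowed means along each linkage group are compared with a
label-permutation null to flag regions of elevated divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import windowed_profile
from .marker_io import AlignedDataset

logger = logging.getLogger(__name__)

METRICS = ("mrd", "delta_p_squared")


def locus_divergence(p1, p2, metric: str = "mrd"):
    """Divergence of one locus given the two group allele frequencies.

    ``mrd`` (default): single-locus modified Rogers' distance, equal to
    ``|p1 - p2|`` for biallelic loci.  ``delta_p_squared``: (p1 - p2)^2, an
    FST-numerator-like alternative.  Missing frequencies propagate to NaN.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if metric == "mrd":
        out = np.abs(p1 - p2)
    elif metric == "delta_p_squared":
        out = (p1 - p2) ** 2
    else:
        raise ValueError(f"unknown divergence metric {metric!r}; choose from {METRICS}")
    return float(out) if out.ndim == 0 else out


@dataclass
class Region:
    linkage_group: str
    start_cM: float
    end_cM: float
    peak: float


@dataclass
class DivergenceScan:
    """Per-marker divergence plus windowed means and flagged regions."""

    markers: pd.DataFrame  # marker, linkage_group, position_cM, p1, p2, d
    profiles: dict[str, tuple[np.ndarray, np.ndarray]]  # group -> (grid, windowed mean)
    group_a: str
    group_b: str
    cutoff: float | None = None
    regions: list[Region] = field(default_factory=list)


def _group_frequencies(calls: np.ndarray, mask: np.ndarray) -> np.ndarray:
    sub = calls[mask]
    with np.errstate(invalid="ignore"):
        p = np.full(calls.shape[1], np.nan)
        any_obs = ~np.all(np.isnan(sub), axis=0)
        p[any_obs] = np.nanmean(sub[:, any_obs], axis=0)
    return p


def divergence_scan(
    dataset: AlignedDataset,
    group_a: str = "winter",
    group_b: str = "spring",
    window_cM: float = 5.0,
    n_positions: int = 500,
    metric: str = "mrd",
    cutoff: float | None = None,
    n_permutations: int = 200,
    seed: int | None = 0,
) -> DivergenceScan:
    """Scan per-locus divergence between two labelled groups along the map.

    When ``cutoff`` is None it defaults to the 95th percentile of the
    per-permutation maximum windowed mean under random relabelling of the
    pooled lines (``n_permutations`` draws, seeded); regions where the
    observed windowed mean reaches the cutoff are flagged.
    """
    habit = np.asarray(dataset.habit, dtype=object)
    mask_a = habit == group_a
    mask_b = habit == group_b
    if not mask_a.any():
        raise ValueError(f"group {group_a!r} is empty")
    if not mask_b.any():
        raise ValueError(f"group {group_b!r} is empty")
    p1 = _group_frequencies(dataset.calls, mask_a)
    p2 = _group_frequencies(dataset.calls, mask_b)
    d = locus_divergence(p1, p2, metric)
    markers = pd.DataFrame(
        {
            "marker": dataset.marker_ids,
            "linkage_group": dataset.linkage_group,
            "position_cM": dataset.position_cM,
            "p1": p1,
            "p2": p2,
            "d": d,
        }
    )
    profiles = windowed_profile(dataset.position_cM, d, dataset.linkage_group,
                                window_cM, n_positions, "mean")
    if cutoff is None:
        cutoff = permutation_cutoff(
            dataset, mask_a, mask_b, window_cM=window_cM, n_positions=n_positions,
            metric=metric, n_permutations=n_permutations, seed=seed,
        )
    scan = DivergenceScan(markers, profiles, group_a, group_b, cutoff)
    scan.regions = flag_regions(scan, cutoff)
    return scan


def permutation_cutoff(
    dataset: AlignedDataset,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    window_cM: float = 5.0,
    n_positions: int = 500,
    metric: str = "mrd",
    n_permutations: int = 200,
    seed: int | None = 0,
    quantile: float = 0.95,
) -> float:
    """Family-wise permutation null for the windowed divergence mean.

    Labels of the pooled a+b lines are permuted; for each permutation the
    maximum windowed mean over all linkage groups and grid points is
    recorded, and the given quantile of these maxima is returned.  Using the
    per-permutation maximum controls the genome-wide false-positive rate, so
    null panels are flagged in about ``1 - quantile`` of seeds.
    """
    rng = np.random.default_rng(seed)
    pool = np.flatnonzero(mask_a | mask_b)
    n_a = int(mask_a.sum())
    calls = dataset.calls[pool]
    valid = (~np.isnan(calls)).astype(float)
    ones = np.where(np.isnan(calls), 0.0, calls)

    # permutation label matrix: n_permutations x len(pool), 1 = group a
    labels = np.zeros((n_permutations, len(pool)))
    for k in range(n_permutations):
        labels[k, rng.permutation(len(pool))[:n_a]] = 1.0

    with np.errstate(invalid="ignore", divide="ignore"):
        num_a, den_a = labels @ ones, labels @ valid
        num_b, den_b = (1 - labels) @ ones, (1 - labels) @ valid
        pa = np.where(den_a > 0, num_a / np.maximum(den_a, 1), np.nan)
        pb = np.where(den_b > 0, num_b / np.maximum(den_b, 1), np.nan)
    d = locus_divergence(pa, pb, metric)  # n_permutations x n_markers

    maxima = np.full(n_permutations, -np.inf)
    half = window_cM / 2.0
    lg = np.asarray(dataset.linkage_group, dtype=object)
    for g in pd.unique(lg):
        sel = np.flatnonzero(lg == g)
        pos = dataset.position_cM[sel]
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        vals = d[:, sel][:, order]
        grid = np.linspace(pos.min(), pos.max(), n_positions) if pos.max() > pos.min() \
            else np.full(n_positions, pos.min())
        lo = np.searchsorted(pos, grid - half, side="left")
        hi = np.searchsorted(pos, grid + half, side="right")
        nan = np.isnan(vals)
        cs = np.concatenate([np.zeros((n_permutations, 1)),
                             np.cumsum(np.where(nan, 0.0, vals), axis=1)], axis=1)
        cn = np.concatenate([np.zeros((n_permutations, 1), dtype=int),
                             np.cumsum((~nan).astype(int), axis=1)], axis=1)
        counts = cn[:, hi] - cn[:, lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(counts > 0, (cs[:, hi] - cs[:, lo]) / np.maximum(counts, 1), -np.inf)
        maxima = np.maximum(maxima, means.max(axis=1))
    return float(np.quantile(maxima, quantile))


def flag_regions(scan: DivergenceScan, cutoff: float) -> list[Region]:
    """Maximal runs of consecutive grid points with windowed mean >= cutoff.

    Runs separated by a single below-cutoff grid point are merged; longer
    gaps split regions.  A single-point run spans one grid step.
    """
    regions: list[Region] = []
    for g, (grid, vals) in scan.profiles.items():
        above = np.flatnonzero(~np.isnan(vals) & (vals >= cutoff))
        if above.size == 0:
            continue
        step = grid[1] - grid[0] if len(grid) > 1 else 0.0
        runs: list[list[int]] = [[above[0], above[0]]]
        for i in above[1:]:
            if i - runs[-1][1] <= 2:  # merge across at most one below-cutoff point
                runs[-1][1] = i
            else:
                runs.append([i, i])
        for i0, i1 in runs:
            peak = float(np.nanmax(vals[i0:i1 + 1]))
            end = grid[i1] + step if i1 + 1 < len(grid) else grid[i1]
            regions.append(Region(str(g), float(grid[i0]), float(end), peak))
    return regions
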