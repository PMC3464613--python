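"""Line-by-line similarity/distance matrices, PCoA and relatedness summaries.

All pairwise statistics use pairwise-complete loci: for each pair of lines
only the loci where both calls are non-missing enter the computation, so
denominators vary per pair.  For fully homozygous biallelic data the
modified Rogers' distance satisfies ``MRD**2 = 1 - simple_matching`` exactly
on complete-data pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .marker_io import AlignedDataset

logger = logging.getLogger(__name__)


@dataclass
class PairwiseMatrix:
    """Symmetric line x line matrix; NaN marks pairs with no shared loci."""

    line_ids: list[str]
    values: np.ndarray
    kind: str  # "simple-matching" | "MRD" | "one-minus-simple-matching"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.line_ids), len(self.line_ids)):
            raise ValueError("matrix shape does not match line ids")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.line_ids)


@dataclass
class PCoAResult:
    """Classical-scaling result: coordinates scaled so that the sum of
    squares of axis j equals eigenvalue j."""

    line_ids: list[str]
    coordinates: np.ndarray  # lines x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (incl. negatives)
    pct_variance: np.ndarray  # per returned axis, % of positive-eigenvalue sum


def _pair_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(shared, matches): per line pair, counts of pairwise-complete loci and
    of loci with identical calls, via three matrix products."""
    valid = (~np.isnan(calls)).astype(float)
    ones = np.where(np.isnan(calls), 0.0, calls)
    zeros = valid - ones
    shared = valid @ valid.T
    matches = ones @ ones.T + zeros @ zeros.T
    return shared, matches


def simple_matching(dataset: AlignedDataset | np.ndarray) -> PairwiseMatrix:
    """Simple matching similarity: fraction of agreeing calls among the
    pairwise-complete loci of each line pair."""
    calls, ids = _calls_ids(dataset)
    if calls.shape[0] < 2:
        raise ValueError("need at least 2 lines")
    shared, matches = _pair_counts(calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(shared > 0, matches / np.maximum(shared, 1), np.nan)
    np.fill_diagonal(s, 1.0)
    if np.isnan(s).any():
        logger.warning("some line pairs share no non-missing loci; similarity set to NaN")
    return PairwiseMatrix(ids, s, "simple-matching")


def modified_rogers(dataset: AlignedDataset | np.ndarray) -> PairwiseMatrix:
    """Modified Rogers' distance between fully homozygous biallelic lines.

    Over the m pairwise-complete loci of a pair this is
    ``sqrt(sum_loci sum_alleles (x_i - x_j)^2 / (2 m))`` which reduces to
    ``sqrt(H / m)`` with H the count of disagreeing loci.
    """
    calls, ids = _calls_ids(dataset)
    if calls.shape[0] < 2:
        raise ValueError("need at least 2 lines")
    shared, matches = _pair_counts(calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(shared > 0, np.sqrt((shared - matches) / np.maximum(shared, 1)), np.nan)
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        logger.warning("some line pairs share no non-missing loci; distance set to NaN")
    return PairwiseMatrix(ids, d, "MRD")


def _calls_ids(dataset) -> tuple[np.ndarray, list[str]]:
    if isinstance(dataset, AlignedDataset):
        return dataset.calls, list(dataset.genotypes.line_ids)
    calls = np.asarray(dataset, dtype=float)
    return calls, [f"line{i}" for i in range(calls.shape[0])]


def pcoa(dist: PairwiseMatrix, n_axes: int = 10) -> PCoAResult:
    """Classical (metric) scaling of a distance matrix.

    Double-centres -D**2/2, eigendecomposes, and returns the top ``n_axes``
    axes.  Percent variance per axis is 100 * lambda_j over the sum of the
    positive eigenvalues (negative eigenvalues, possible for non-Euclidean
    distances, are excluded from the denominator).  Each axis is oriented so
    that its largest-magnitude loading is positive.
    """
    d = np.asarray(dist.values, dtype=float)
    if np.isnan(d).any():
        raise ValueError(
            "distance matrix has missing entries; impute or drop lines "
            "with no shared loci before ordination"
        )
    n = d.shape[0]
    b = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ b @ j
    b = (b + b.T) / 2.0
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos_sum = evals[evals > 0].sum()
    n_axes = min(n_axes, n)
    coords = np.zeros((n, n_axes))
    pct = np.zeros(n_axes)
    for k in range(n_axes):
        lam = evals[k]
        if lam > 0:
            axis = evecs[:, k] * np.sqrt(lam)
            if axis[np.argmax(np.abs(axis))] < 0:
                axis = -axis
            coords[:, k] = axis
            pct[k] = 100.0 * lam / pos_sum if pos_sum > 0 else 0.0
    return PCoAResult(list(dist.line_ids), coords, evals, pct)


@dataclass
class AxisDensity:
    axis: int
    grid: np.ndarray
    density: np.ndarray
    bimodal: bool
    degenerate: bool


def axis_density_summary(
    result: PCoAResult, n_axes: int = 10, n_grid: int = 256, bw_method="silverman"
) -> list[AxisDensity]:
    """Gaussian KDE of line coordinates per principal coordinate axis.

    The bimodality flag is true when the density has more than one local
    maximum (detected by sign changes of the numerical slope).  Axes with
    (near) zero spread are flagged degenerate.
    """
    if n_axes > result.coordinates.shape[1]:
        raise ValueError("n_axes exceeds available axes")
    out = []
    for k in range(n_axes):
        x = result.coordinates[:, k]
        span = x.max() - x.min()
        if span <= 1e-12 * max(1.0, np.abs(x).max()) or len(x) < 3:
            grid = np.linspace(x.min() - 1, x.max() + 1, n_grid)
            out.append(AxisDensity(k, grid, np.zeros(n_grid), False, True))
            continue
        kde = gaussian_kde(x, bw_method=bw_method)
        pad = 3.0 * kde.factor * x.std(ddof=1)
        grid = np.linspace(x.min() - pad, x.max() + pad, n_grid)
        dens = kde(grid)
        slope_sign = np.sign(np.diff(dens))
        nz = slope_sign[slope_sign != 0]
        n_maxima = int(np.sum((nz[:-1] > 0) & (nz[1:] < 0))) if nz.size else 0
        out.append(AxisDensity(k, grid, dens, n_maxima >= 2, False))
    return out


def group_similarity_summary(
    sim: PairwiseMatrix, habit: list[str], n_bins: int = 20
) -> dict[str, dict]:
    """Mean and histogram of off-diagonal similarities, overall and per group.

    Means are over unordered within-group pairs (i < j) with a defined
    similarity.  Groups with fewer than two lines are skipped with a warning.
    """
    habit = list(habit)
    if len(habit) != sim.n:
        raise ValueError("habit labels do not match similarity matrix")
    iu = np.triu_indices(sim.n, k=1)
    out: dict[str, dict] = {}

    def summarise(mask_pairs: np.ndarray) -> dict:
        vals = sim.values[iu][mask_pairs]
        vals = vals[~np.isnan(vals)]
        hist, edges = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
        return {"n_pairs": int(vals.size),
                "mean": float(vals.mean()) if vals.size else float("nan"),
                "hist": hist, "bin_edges": edges}

    out["all"] = summarise(np.ones(len(iu[0]), dtype=bool))
    labels = np.asarray(habit, dtype=object)
    for g in dict.fromkeys(habit):
        members = labels == g
        if members.sum() < 2:
            logger.warning("group %r has fewer than 2 lines; skipped", g)
            continue
        pair_mask = members[iu[0]] & members[iu[1]]
        out[g] = summarise(pair_mask)
    return out
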