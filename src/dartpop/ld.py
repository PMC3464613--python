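"""Pairwise linkage disequilibrium, decay curves, thresholds and profiles.

Lines are treated as haplotypes (fully homozygous inbreds, dominant
presence/absence markers), so r-squared is the squared allele-frequency
correlation computed directly from the 0/1 calls of the pairwise-complete
lines of each marker pair.  Marker pairs on different linkage groups are
"unlinked" and their r-squared distribution provides the population-specific
threshold for LD due to linkage; same-group pairs carry a cM distance and
feed the loess decay curve whose intersection with the threshold estimates
the range of LD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.nonparametric.smoothers_lowess import lowess

from .diversity import windowed_profile
from .marker_io import AlignedDataset

logger = logging.getLogger(__name__)

DEFAULT_SPAN = 0.33
DEFAULT_QUANTILE = 0.95


# ---------------------------------------------------------------------------
# pairwise r-squared


def pairwise_r2(x: np.ndarray, y: np.ndarray, min_lines_per_allele: int = 1) -> float:
    """Squared allele-frequency correlation r^2 of two binary markers.

    Computed on the lines where both calls are non-missing as
    ``D^2 / (p_x (1-p_x) p_y (1-p_y))`` with ``D = p_xy - p_x p_y``; this
    equals the squared Pearson correlation of the two binary vectors.
    Returns NaN when fewer than two shared lines remain, either marker is
    monomorphic on the shared lines, or a marker's minor allele is carried by
    fewer than ``min_lines_per_allele`` shared lines.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    n = int(ok.sum())
    if n < 2:
        return float("nan")
    xs, ys = x[ok], y[ok]
    sx, sy = xs.sum(), ys.sum()
    if min(sx, n - sx) < min_lines_per_allele or min(sy, n - sy) < min_lines_per_allele:
        return float("nan")
    px, py = sx / n, sy / n
    vx, vy = px * (1 - px), py * (1 - py)
    if vx == 0 or vy == 0:
        return float("nan")
    d = (xs * ys).sum() / n - px * py
    return float(d * d / (vx * vy))


def r2_matrix(calls: np.ndarray, min_lines_per_allele: int = 1) -> np.ndarray:
    """All-pairs r^2 for a lines x markers matrix, pairwise-complete.

    Uses three matrix products over the validity mask, so it scales to
    thousands of markers.  Entries that fail the :func:`pairwise_r2`
    preconditions are NaN; the diagonal is NaN as well.
    """
    calls = np.asarray(calls, dtype=float)
    valid = (~np.isnan(calls)).astype(float)
    ones = np.where(np.isnan(calls), 0.0, calls)
    n = valid.T @ valid  # shared line counts
    sx = ones.T @ valid  # sum of x over shared lines (binary: sum == sum of squares)
    sy = sx.T
    sxy = ones.T @ ones
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sx - sx**2
        vary = n * sy - sy**2
        r2 = cov**2 / (varx * vary)
        minor_x = np.minimum(sx, n - sx)
        bad = (n < 2) | (varx <= 0) | (vary <= 0) \
            | (minor_x < min_lines_per_allele) | (minor_x.T < min_lines_per_allele)
        r2[bad] = np.nan
    np.fill_diagonal(r2, np.nan)
    return r2


# ---------------------------------------------------------------------------
# Fisher's exact test


def contingency_table(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """2x2 joint call counts [[n00, n01], [n10, n11]] over shared lines."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    xs, ys = x[ok], y[ok]
    return np.array(
        [[np.sum((xs == 0) & (ys == 0)), np.sum((xs == 0) & (ys == 1))],
         [np.sum((xs == 1) & (ys == 0)), np.sum((xs == 1) & (ys == 1))]],
        dtype=int,
    )


def fisher_exact(x: np.ndarray, y: np.ndarray, return_flag: bool = False):
    """Two-sided Fisher's exact p-value for the 2x2 joint call table.

    A degenerate table (any zero margin) yields p = 1; with
    ``return_flag=True`` the second element marks that case.
    """
    table = contingency_table(x, y)
    p, degenerate = _fisher_table(table)
    return (p, degenerate) if return_flag else p


def _fisher_table(table: np.ndarray) -> tuple[float, bool]:
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    n, r, s = a + b + c + d, a + b, a + c
    if n == 0 or r == 0 or r == n or s == 0 or s == n:
        return 1.0, True
    kmin, kmax = max(0, r + s - n), min(r, s)
    k = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(k, n, r, s)
    p_obs = pmf[a - kmin]
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    return min(p, 1.0), False


def fisher_exact_many(tables: np.ndarray) -> np.ndarray:
    """Vectorised two-sided Fisher p-values for an (N, 4) array of tables.

    Columns are (n00, n01, n10, n11).  Tables sharing margins reuse one
    hypergeometric pmf evaluation, which makes genome-scale pair lists
    feasible.
    """
    tables = np.asarray(tables, dtype=int)
    a = tables[:, 0]
    n = tables.sum(axis=1)
    r = tables[:, 0] + tables[:, 1]
    s = tables[:, 0] + tables[:, 2]
    out = np.ones(len(tables))
    ok = (n > 0) & (r > 0) & (r < n) & (s > 0) & (s < n)
    if not ok.any():
        return out
    triples = np.stack([n[ok], r[ok], s[ok]], axis=1)
    uniq, inverse = np.unique(triples, axis=0, return_inverse=True)
    kmin = np.maximum(0, uniq[:, 1] + uniq[:, 2] - uniq[:, 0])
    kmax = np.minimum(uniq[:, 1], uniq[:, 2])
    lengths = kmax - kmin + 1
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    k_all = np.concatenate([np.arange(lo, hi + 1) for lo, hi in zip(kmin, kmax)])
    rep = np.repeat(np.arange(len(uniq)), lengths)
    pmf_all = hypergeom.pmf(k_all, uniq[rep, 0], uniq[rep, 1], uniq[rep, 2])
    a_ok = a[ok]
    p_ok = np.empty(len(a_ok))
    for t in range(len(uniq)):
        seg = pmf_all[offsets[t]:offsets[t + 1]]
        srt = np.sort(seg)
        cum = np.cumsum(srt)
        members = np.flatnonzero(inverse == t)
        p_obs = seg[a_ok[members] - kmin[t]]
        idx = np.searchsorted(srt, p_obs * (1 + 1e-9), side="right")
        p_ok[members] = cum[np.maximum(idx, 1) - 1]
    out[ok] = np.minimum(p_ok, 1.0)
    return out


# ---------------------------------------------------------------------------
# pair partition and threshold


@dataclass
class PairPartition:
    """Unordered marker pairs split into same-group (linked, with distance)
    and different-group (unlinked) sets."""

    marker_ids: list[str]
    linked_i: np.ndarray
    linked_j: np.ndarray
    linked_distance: np.ndarray
    linked_group: np.ndarray  # linkage-group name per linked pair
    linked_genome: np.ndarray  # genome letter per linked pair
    n_unlinked: int

    @property
    def n_linked(self) -> int:
        return len(self.linked_i)


def partition_pairs(dataset: AlignedDataset) -> PairPartition:
    """Partition all unordered marker pairs by shared linkage group.

    Linked pairs (same linkage group) get ``|pos_i - pos_j|`` distances;
    co-located markers are kept at distance 0.  The unlinked count is exact:
    C(m, 2) minus the sum of within-group pair counts.
    """
    m = len(dataset.marker_ids)
    lg = np.asarray(dataset.linkage_group, dtype=object)
    li, lj, dist, grp, gen = [], [], [], [], []
    n_same = 0
    for g in pd.unique(lg):
        idx = np.flatnonzero(lg == g)
        k = len(idx)
        n_same += k * (k - 1) // 2
        if k < 2:
            continue
        a, b = np.triu_indices(k, k=1)
        li.append(idx[a])
        lj.append(idx[b])
        dist.append(np.abs(dataset.position_cM[idx[a]] - dataset.position_cM[idx[b]]))
        grp.append(np.full(len(a), g, dtype=object))
        gen.append(np.full(len(a), dataset.genome[idx[0]], dtype=object))
    n_unlinked = m * (m - 1) // 2 - n_same
    part = PairPartition(
        list(dataset.marker_ids),
        np.concatenate(li) if li else np.empty(0, dtype=int),
        np.concatenate(lj) if lj else np.empty(0, dtype=int),
        np.concatenate(dist) if dist else np.empty(0),
        np.concatenate(grp) if grp else np.empty(0, dtype=object),
        np.concatenate(gen) if gen else np.empty(0, dtype=object),
        n_unlinked,
    )
    logger.info("partitioned %d markers into %d linked and %d unlinked pairs",
                m, part.n_linked, part.n_unlinked)
    return part


def unlinked_r2_values(r2: np.ndarray, linkage_group: np.ndarray) -> np.ndarray:
    """r^2 values of all different-linkage-group pairs (NaN pairs dropped)."""
    lg = np.asarray(linkage_group, dtype=object)
    iu, ju = np.triu_indices(len(lg), k=1)
    vals = r2[iu, ju]
    diff = lg[iu] != lg[ju]
    vals = vals[diff]
    return vals[~np.isnan(vals)]


def ld_threshold(unlinked_r2: np.ndarray, quantile: float = DEFAULT_QUANTILE) -> float:
    """Population-specific critical r^2: empirical quantile of unlinked-pair
    r^2 values (type-7 linear-interpolation quantile)."""
    vals = np.asarray(unlinked_r2, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 20:
        raise ValueError(f"need >=20 unlinked r^2 values, got {vals.size}")
    return float(np.quantile(vals, quantile))


# ---------------------------------------------------------------------------
# decay curve


@dataclass
class DecayCurve:
    """Loess-smoothed r^2 as a function of cM distance on a 0..max grid."""

    grid: np.ndarray
    values: np.ndarray
    span: float
    min_distance: float  # smallest observed linked distance
    close_ld: float  # fitted curve at the smallest observed distance
    bin0_mean: float  # mean raw r^2 of pairs at distance <= 1 cM (NaN if none)
    threshold: float | None = None
    extent_cM: float | None = None
    censored: bool = False


def fit_decay(
    distances: np.ndarray,
    r2: np.ndarray,
    span: float = DEFAULT_SPAN,
    n_grid: int = 512,
    delta: float | None = None,
) -> DecayCurve:
    """Locally weighted linear regression of r^2 against cM distance.

    Tricube weights, local degree 1 (Cleveland's lowess with robustness
    iterations); fitted values are linearly interpolated onto an evenly
    spaced grid from 0 to the maximum observed distance and clipped to
    [0, 1].  ``delta`` (default 1% of the distance range) lets lowess skip
    nearby points, keeping genome-scale fits fast.
    """
    d = np.asarray(distances, dtype=float)
    y = np.asarray(r2, dtype=float)
    ok = ~np.isnan(d) & ~np.isnan(y)
    d, y = d[ok], y[ok]
    if d.size < 10:
        raise ValueError(f"need >=10 linked pairs with defined r^2, got {d.size}")
    if d.max() <= d.min():
        raise ValueError("linked pairs must span a positive distance range")
    if span * d.size < 2:
        raise ValueError(
            f"span {span} leaves local neighbourhoods of <2 points for n={d.size}; "
            "increase the span"
        )
    if delta is None:
        delta = 0.01 * (d.max() - d.min())
    fit = lowess(y, d, frac=span, it=3, delta=delta, return_sorted=True)
    grid = np.linspace(0.0, d.max(), n_grid)
    values = np.interp(grid, fit[:, 0], fit[:, 1])
    values = np.clip(values, 0.0, 1.0)
    min_dist = float(d.min())
    close_ld = float(np.interp(min_dist, fit[:, 0], np.clip(fit[:, 1], 0.0, 1.0)))
    near = y[d <= 1.0]
    bin0 = float(near.mean()) if near.size else float("nan")
    return DecayCurve(grid, values, span, min_dist, close_ld, bin0)


def ld_extent(curve: DecayCurve, threshold: float) -> tuple[float, bool]:
    """Distance at which the decay curve first falls below the threshold.

    Linearly interpolated between the bracketing grid points; 0 if the curve
    starts below the threshold; censored at the maximum grid distance if the
    curve never falls below.  The curve object is annotated in place.
    """
    v = curve.values
    g = curve.grid
    curve.threshold = threshold
    if v[0] < threshold:
        curve.extent_cM, curve.censored = 0.0, False
        return 0.0, False
    below = np.flatnonzero(v < threshold)
    if below.size == 0:
        curve.extent_cM, curve.censored = float(g[-1]), True
        return float(g[-1]), True
    k = below[0]
    x = g[k - 1] + (v[k - 1] - threshold) / (v[k - 1] - v[k]) * (g[k] - g[k - 1])
    curve.extent_cM, curve.censored = float(x), False
    return float(x), False


# ---------------------------------------------------------------------------
# adjacent-marker LD


def adjacent_pairs(dataset: AlignedDataset) -> pd.DataFrame:
    """Map-adjacent marker pairs per linkage group, with midpoints."""
    lg = np.asarray(dataset.linkage_group, dtype=object)
    rows = []
    for g in pd.unique(lg):
        idx = np.flatnonzero(lg == g)
        for a, b in zip(idx[:-1], idx[1:]):
            rows.append((int(a), int(b), str(g),
                         (dataset.position_cM[a] + dataset.position_cM[b]) / 2.0))
    return pd.DataFrame(rows, columns=["i", "j", "linkage_group", "midpoint_cM"])


def adjacent_ld(
    dataset: AlignedDataset,
    lines_mask: np.ndarray | None = None,
    min_lines_per_allele: int = 1,
) -> tuple[float, pd.DataFrame]:
    """Mean r^2 over map-adjacent marker pairs (undefined r^2 excluded).

    Returns the mean and the per-pair table (with an ``r2`` column).
    """
    pairs = adjacent_pairs(dataset)
    if pairs.empty:
        raise ValueError("no linkage group has two or more markers")
    calls = dataset.calls if lines_mask is None else dataset.calls[lines_mask]
    r2 = np.array([
        pairwise_r2(calls[:, i], calls[:, j], min_lines_per_allele)
        for i, j in zip(pairs["i"], pairs["j"])
    ])
    pairs = pairs.assign(r2=r2)
    valid = r2[~np.isnan(r2)]
    mean = float(valid.mean()) if valid.size else float("nan")
    return mean, pairs


def ld_window_profile(
    dataset: AlignedDataset,
    window_cM: float = 5.0,
    n_positions: int = 500,
    lines_mask: np.ndarray | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Windowed median of adjacent-pair r^2 along each linkage group.

    Each adjacent pair is located at its midpoint position.
    """
    _, pairs = adjacent_ld(dataset, lines_mask)
    return windowed_profile(
        pairs["midpoint_cM"].to_numpy(), pairs["r2"].to_numpy(),
        pairs["linkage_group"].to_numpy(dtype=object),
        window_cM, n_positions, "median",
    )


# ---------------------------------------------------------------------------
# genome-level decay analysis


@dataclass
class DecayAnalysis:
    """Threshold + per-genome (and pooled) decay curves for one line set."""

    label: str
    threshold: float
    n_unlinked: int
    curves: dict[str, DecayCurve] = field(default_factory=dict)


def decay_by_genome(
    dataset: AlignedDataset,
    lines_mask: np.ndarray | None = None,
    label: str = "all",
    span: float = DEFAULT_SPAN,
    quantile: float = DEFAULT_QUANTILE,
    genomes: tuple[str, ...] = ("A", "B", "R"),
    pooled_key: str = "ABR",
    min_lines_per_allele: int = 1,
) -> DecayAnalysis:
    """Full LD-decay characterisation of one line set.

    Computes the all-pairs r^2 matrix on the (optionally masked) lines, the
    population-specific threshold from unlinked pairs, and loess decay
    curves per genome plus the pooled curve, each intersected with the
    threshold to yield the LD extent.
    """
    calls = dataset.calls if lines_mask is None else dataset.calls[lines_mask]
    r2 = r2_matrix(calls, min_lines_per_allele)
    part = partition_pairs(dataset)
    if part.n_unlinked == 0:
        raise ValueError(
            "no unlinked marker pairs (single linkage group?); the "
            "population-specific threshold cannot be computed"
        )
    unlinked = unlinked_r2_values(r2, dataset.linkage_group)
    threshold = ld_threshold(unlinked, quantile)
    analysis = DecayAnalysis(label, threshold, int(unlinked.size))
    linked_r2 = r2[part.linked_i, part.linked_j]
    for key in (*genomes, pooled_key):
        sel = np.ones(part.n_linked, dtype=bool) if key == pooled_key \
            else part.linked_genome == key
        d, v = part.linked_distance[sel], linked_r2[sel]
        ok = ~np.isnan(v)
        if ok.sum() < 10:
            logger.warning("genome %s: too few linked pairs for a decay curve; skipped", key)
            continue
        curve = fit_decay(d[ok], v[ok], span=span)
        ld_extent(curve, threshold)
        analysis.curves[key] = curve
    return analysis
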