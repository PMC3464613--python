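"""Allele frequencies, polymorphic information content and windowed profiles."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .marker_io import AlignedDataset

logger = logging.getLogger(__name__)


def allele_frequency(calls: np.ndarray) -> float | np.ndarray:
    """Frequency of the presence allele: mean of non-missing binary calls.

    Accepts one marker column (1-D) or a lines x markers matrix (2-D, one
    frequency per marker).  All-missing markers yield NaN.
    """
    calls = np.asarray(calls, dtype=float)
    with np.errstate(invalid="ignore"):
        if calls.ndim == 1:
            if np.all(np.isnan(calls)):
                logger.warning("marker with no non-missing calls; frequency undefined")
                return float("nan")
            return float(np.nanmean(calls))
        p = np.full(calls.shape[1], np.nan)
        any_obs = ~np.all(np.isnan(calls), axis=0)
        p[any_obs] = np.nanmean(calls[:, any_obs], axis=0)
        if (~any_obs).any():
            logger.warning("%d marker(s) with no non-missing calls flagged", int((~any_obs).sum()))
        return p


def pic(p: float | np.ndarray) -> float | np.ndarray:
    """Polymorphic information content of a biallelic locus: 1 - (p^2 + q^2).

    Ranges from 0 (fixation) to 0.5 (equal allele frequencies).
    """
    p_arr = np.asarray(p, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((p_arr < 0) | (p_arr > 1)):
            raise ValueError("allele frequency outside [0, 1]")
    out = 1.0 - (p_arr**2 + (1.0 - p_arr) ** 2)
    return float(out) if np.isscalar(p) or out.ndim == 0 else out


def pic_table(dataset: AlignedDataset, include_monomorphic: bool = False) -> pd.DataFrame:
    """Per-marker table: linkage group, position, frequency and PIC on all lines."""
    p = allele_frequency(dataset.calls)
    df = pd.DataFrame(
        {
            "marker": dataset.marker_ids,
            "linkage_group": dataset.linkage_group,
            "genome": dataset.genome,
            "position_cM": dataset.position_cM,
            "p": p,
            "pic": pic(np.where(np.isnan(p), 0.0, p)),
            "monomorphic": dataset.monomorphic,
        }
    )
    df.loc[np.isnan(p), "pic"] = np.nan
    if not include_monomorphic:
        df.loc[df["monomorphic"], "pic"] = np.nan
    return df


def pic_summary(
    dataset: AlignedDataset,
    groups: list[str] | None = None,
    include_monomorphic: bool = False,
) -> pd.DataFrame:
    """Mean PIC by (line group x linkage group), plus genome and overall means.

    Each group's allele frequencies are recomputed within the group, so
    subgroup rows reflect subgroup diversity.  Markers flagged monomorphic on
    the full dataset are excluded from means unless ``include_monomorphic``.
    """
    habit = np.asarray(dataset.habit, dtype=object)
    if groups is None:
        groups = ["all"] + [g for g in dict.fromkeys(dataset.habit) if g != "unknown"]
    keep = np.ones(len(dataset.marker_ids), dtype=bool)
    if not include_monomorphic:
        keep = ~dataset.monomorphic
    lg = np.asarray(dataset.linkage_group, dtype=object)
    rows = {}
    for g in groups:
        mask = np.ones(len(habit), dtype=bool) if g == "all" else habit == g
        if not mask.any():
            logger.warning("line group %r is empty; skipped", g)
            continue
        p = allele_frequency(dataset.calls[mask])
        vals = pic(np.where(np.isnan(p), 0.0, p))
        vals = np.where(np.isnan(p) | ~keep, np.nan, vals)
        row = {}
        for group_name in pd.unique(lg):
            row[str(group_name)] = np.nanmean(vals[lg == group_name]) if np.any(
                ~np.isnan(vals[lg == group_name])) else np.nan
        for genome in ("A", "B", "R"):
            sel = dataset.genome == genome
            if sel.any():
                row[f"genome_{genome}"] = np.nanmean(vals[sel])
        row["overall"] = np.nanmean(vals)
        row["n_lines"] = int(mask.sum())
        rows[g] = row
    return pd.DataFrame(rows).T


def windowed_profile(
    positions: np.ndarray,
    values: np.ndarray,
    linkage_group: np.ndarray,
    window_cM: float = 5.0,
    n_positions: int = 500,
    statistic: str = "mean",
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Sliding-window statistic of per-marker values along each linkage group.

    For each linkage group an evaluation grid of ``n_positions`` equally
    spaced points spans the [min, max] observed marker positions.  At grid
    point g the statistic pools all values with ``|pos - g| <= window_cM/2``
    (window read as total width); empty windows yield NaN.

    Returns ``{linkage_group: (grid, stat_values)}``.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    linkage_group = np.asarray(linkage_group, dtype=object)
    half = window_cM / 2.0
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for g in pd.unique(linkage_group):
        sel = linkage_group == g
        pos = positions[sel]
        val = values[sel]
        ok = ~np.isnan(val)
        pos, val = pos[ok], val[ok]
        if pos.size == 0:
            continue
        order = np.argsort(pos, kind="stable")
        pos, val = pos[order], val[order]
        grid = np.linspace(pos.min(), pos.max(), n_positions) if pos.max() > pos.min() \
            else np.full(n_positions, pos.min())
        lo = np.searchsorted(pos, grid - half, side="left")
        hi = np.searchsorted(pos, grid + half, side="right")
        stat = np.full(n_positions, np.nan)
        if statistic == "mean":
            cs = np.concatenate([[0.0], np.cumsum(val)])
            counts = hi - lo
            nz = counts > 0
            stat[nz] = (cs[hi[nz]] - cs[lo[nz]]) / counts[nz]
        else:
            for i in range(n_positions):
                if hi[i] > lo[i]:
                    stat[i] = np.median(val[lo[i]:hi[i]])
        out[str(g)] = (grid, stat)
    return out


def pic_profile(
    dataset: AlignedDataset,
    group: str = "all",
    window_cM: float = 5.0,
    n_positions: int = 500,
    include_monomorphic: bool = False,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Windowed mean PIC along each linkage group for one line group."""
    habit = np.asarray(dataset.habit, dtype=object)
    mask = np.ones(len(habit), dtype=bool) if group == "all" else habit == group
    if not mask.any():
        raise ValueError(f"line group {group!r} is empty")
    p = allele_frequency(dataset.calls[mask])
    vals = pic(np.where(np.isnan(p), 0.0, p))
    vals = np.where(np.isnan(p), np.nan, vals)
    if not include_monomorphic:
        vals = np.where(dataset.monomorphic, np.nan, vals)
    return windowed_profile(dataset.position_cM, vals, dataset.linkage_group,
                            window_cM, n_positions, "mean")
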