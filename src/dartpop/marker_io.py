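"""Readers, writers and alignment for genotype matrices and genetic maps.

Genotype matrices are lines x markers tables of binary presence/absence
calls with missing values allowed.  Genetic maps assign each marker to a
linkage group and a centimorgan position.  :func:`align` joins the two into
an :class:`AlignedDataset` with markers ordered along the map, which is the
input type of every downstream analysis stage.
"""

from __future__ import annotations

import logging
import re
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HABITS = ("winter", "spring", "facultative", "unknown")

#: tokens interpreted as a missing genotype call by default
DEFAULT_MISSING_TOKENS = ("", "NA", "N/A", "-", "NaN", "nan", ".")

GENOMES = ("A", "B", "R")

_SPLIT_GROUP_RE = re.compile(r"^(?P<base>.*?)(?:-\d+)?$")


class MarkerIOError(ValueError):
    """Raised on malformed genotype/map input."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen[i] = 1
    if dups:
        raise MarkerIOError(f"duplicate {what} id(s): {sorted(set(dups))}")


@dataclass
class GenotypeMatrix:
    """Lines x markers binary calls with a missingness mask and line labels.

    ``calls`` is a float array with values in {0.0, 1.0, NaN}; NaN encodes a
    missing call.  ``habit`` holds one growth-habit label per line.
    """

    line_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray
    habit: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.line_ids = [str(x) for x in self.line_ids]
        self.marker_ids = [str(x) for x in self.marker_ids]
        _check_unique(self.line_ids, "line")
        _check_unique(self.marker_ids, "marker")
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.line_ids), len(self.marker_ids)):
            raise MarkerIOError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        finite = self.calls[~np.isnan(self.calls)]
        bad = finite[(finite != 0.0) & (finite != 1.0)]
        if bad.size:
            r, c = np.argwhere(~np.isnan(self.calls) & (self.calls != 0) & (self.calls != 1))[0]
            raise MarkerIOError(
                f"non-binary call {self.calls[r, c]!r} at line "
                f"{self.line_ids[r]!r}, marker {self.marker_ids[c]!r}"
            )
        if not self.habit:
            self.habit = ["unknown"] * len(self.line_ids)
        if len(self.habit) != len(self.line_ids):
            raise MarkerIOError("habit labels do not match number of lines")
        for h in self.habit:
            if h not in HABITS:
                raise MarkerIOError(f"unknown growth habit label {h!r}; expected one of {HABITS}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def missing_rate(self) -> float:
        return float(np.isnan(self.calls).mean()) if self.calls.size else 0.0

    def subset_lines(self, keep: Sequence[str] | np.ndarray) -> "GenotypeMatrix":
        """Restrict to the given line ids (or a boolean mask over lines)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {l: i for i, l in enumerate(self.line_ids)}
            idx = np.array([pos[l] for l in keep], dtype=int)
        return GenotypeMatrix(
            [self.line_ids[i] for i in idx],
            list(self.marker_ids),
            self.calls[idx, :],
            [self.habit[i] for i in idx],
        )

    def subset_markers(self, keep: Sequence[str]) -> "GenotypeMatrix":
        pos = {m: i for i, m in enumerate(self.marker_ids)}
        idx = np.array([pos[m] for m in keep], dtype=int)
        return GenotypeMatrix(
            list(self.line_ids), [self.marker_ids[i] for i in idx],
            self.calls[:, idx], list(self.habit),
        )


@dataclass
class GeneticMap:
    """Marker -> (linkage group, position in cM) lookup."""

    table: pd.DataFrame  # index marker_id, columns linkage_group, position_cM

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns) != ["linkage_group", "position_cM"]:
            raise MarkerIOError("map table must have columns linkage_group, position_cM")
        _check_unique(list(t.index.astype(str)), "marker")
        pos = pd.to_numeric(t["position_cM"], errors="coerce")
        if pos.isna().any():
            bad = t.index[pos.isna()][0]
            raise MarkerIOError(f"non-numeric map position for marker {bad!r}")
        if not np.isfinite(pos).all() or (pos < 0).any():
            bad = t.index[(~np.isfinite(pos)) | (pos < 0)][0]
            raise MarkerIOError(f"negative or non-finite map position for marker {bad!r}")
        if (t["linkage_group"].astype(str).str.len() == 0).any():
            raise MarkerIOError("empty linkage-group name in map")
        # numpy's parser round-trips repr'd floats; pandas' to_numeric does not
        exact = t["position_cM"].to_numpy()
        if exact.dtype != np.float64:
            exact = np.array([float(v) for v in exact])
        self.table = pd.DataFrame(
            {"linkage_group": t["linkage_group"].astype(str), "position_cM": exact},
            index=t.index.astype(str),
        )

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def linkage_groups(self) -> list[str]:
        return sorted(self.table["linkage_group"].unique())

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, marker: str) -> bool:
        return marker in self.table.index

    def position(self, marker: str) -> tuple[str, float]:
        row = self.table.loc[marker]
        return str(row["linkage_group"]), float(row["position_cM"])


def genome_of(linkage_group: str, strict: bool = False) -> str:
    """Genome letter derived from a linkage-group name.

    Split groups such as ``2R-1`` count as their base chromosome, so the
    trailing ``-<n>`` suffix is stripped before taking the last letter.
    """
    base = _SPLIT_GROUP_RE.match(linkage_group).group("base")
    letters = [c for c in base if c.isalpha()]
    g = letters[-1].upper() if letters else ""
    if g not in GENOMES:
        if strict:
            raise MarkerIOError(f"cannot derive genome from linkage group {linkage_group!r}")
        logger.warning("unknown genome suffix for linkage group %r; set to 'unknown'", linkage_group)
        return "unknown"
    return g


@dataclass
class AlignedDataset:
    """Genotypes restricted to mapped markers, ordered along the map.

    Marker order is (linkage_group, position_cM, marker_id).  ``genome``
    holds the genome letter per marker; ``monomorphic`` flags markers with
    at most one distinct non-missing call.
    """

    genotypes: GenotypeMatrix
    linkage_group: np.ndarray  # str per marker
    position_cM: np.ndarray  # float per marker
    genome: np.ndarray  # str per marker
    monomorphic: np.ndarray  # bool per marker

    def __post_init__(self) -> None:
        m = self.genotypes.n_markers
        for name in ("linkage_group", "position_cM", "genome", "monomorphic"):
            if len(getattr(self, name)) != m:
                raise MarkerIOError(f"{name} length does not match marker count")
        for g in np.unique(self.linkage_group):
            pos = self.position_cM[self.linkage_group == g]
            if np.any(np.diff(pos) < 0):
                raise MarkerIOError(f"positions not sorted within linkage group {g!r}")

    @property
    def marker_ids(self) -> list[str]:
        return self.genotypes.marker_ids

    @property
    def calls(self) -> np.ndarray:
        return self.genotypes.calls

    @property
    def habit(self) -> list[str]:
        return self.genotypes.habit

    def group_slices(self) -> dict[str, np.ndarray]:
        """Indices of markers per linkage group, in map order."""
        out: dict[str, np.ndarray] = {}
        for g in pd.unique(self.linkage_group):
            out[str(g)] = np.flatnonzero(self.linkage_group == g)
        return out

    def subset_lines(self, keep) -> "AlignedDataset":
        gm = self.genotypes.subset_lines(keep)
        return AlignedDataset(gm, self.linkage_group, self.position_cM, self.genome,
                              _monomorphic_mask(gm.calls))


def _monomorphic_mask(calls: np.ndarray) -> np.ndarray:
    obs = ~np.isnan(calls)
    n_obs = obs.sum(axis=0)
    s = np.where(obs, calls, 0.0).sum(axis=0)
    return (n_obs == 0) | (s == 0) | (s == n_obs)


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    # header=None + manual promotion keeps duplicate column ids detectable
    # (pandas would silently mangle them to m1.1, m1.2, ...)
    path = Path(path)
    if not path.exists():
        raise MarkerIOError(f"input file not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path, header=None, dtype=object)
    else:
        if sep is None:
            sep = "," if path.suffix.lower() == ".csv" else "\t"
        raw = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#",
                          keep_default_na=False)
    df = raw.iloc[1:, 1:]
    df.columns = [str(c) for c in raw.iloc[0, 1:]]
    df.index = [str(i) for i in raw.iloc[1:, 0]]
    return df


def read_genotypes(
    path: str | Path,
    *,
    orientation: str = "lines-in-rows",
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    sep: str | None = None,
    groups: str | Path | Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from delimited text or a spreadsheet.

    Parameters
    ----------
    orientation:
        ``"lines-in-rows"`` (default) or ``"markers-in-rows"``.
    missing_tokens:
        Cell values interpreted as missing calls.
    groups:
        Optional growth-habit labels: a two-column file (line id, habit) or a
        mapping.  Lines without a label get habit ``"unknown"``.
    """
    df = _read_table(path, sep=sep)
    if orientation == "markers-in-rows":
        df = df.T
    elif orientation != "lines-in-rows":
        raise MarkerIOError(f"unknown orientation {orientation!r}")
    line_ids = [str(x) for x in df.index]
    marker_ids = [str(x) for x in df.columns]
    missing = {str(t) for t in missing_tokens}
    raw = df.to_numpy(dtype=object)
    calls = np.empty(raw.shape, dtype=float)
    for (r, c), v in np.ndenumerate(raw):
        s = "" if v is None else str(v).strip()
        if s in missing or (isinstance(v, float) and np.isnan(v)):
            calls[r, c] = np.nan
        elif s in ("0", "0.0"):
            calls[r, c] = 0.0
        elif s in ("1", "1.0"):
            calls[r, c] = 1.0
        else:
            raise MarkerIOError(
                f"non-binary call token {s!r} at line {line_ids[r]!r}, marker {marker_ids[c]!r}"
            )
    habit: list[str] = []
    if groups is not None:
        mapping = groups if isinstance(groups, Mapping) else read_line_groups(groups)
        habit = [mapping.get(l, "unknown") for l in line_ids]
    gm = GenotypeMatrix(line_ids, marker_ids, calls, habit)
    logger.info(
        "read %d lines x %d markers from %s (missing rate %.4f)",
        gm.n_lines, gm.n_markers, path, gm.missing_rate,
    )
    return gm


def read_line_groups(path: str | Path, sep: str | None = None) -> dict[str, str]:
    """Read a line -> growth habit table (two columns, header optional)."""
    path = Path(path)
    if not path.exists():
        raise MarkerIOError(f"groups file not found: {path}")
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#", header=None)
    header_words = {"habit", "group", "growth_habit", "type", "growth habit"}
    if len(df) and str(df.iloc[0, 1]).strip().lower() in header_words:
        df = df.iloc[1:]
    out = {}
    for _, row in df.iterrows():
        h = str(row.iloc[1]).strip().lower()
        if h not in HABITS:
            raise MarkerIOError(f"unknown growth habit {h!r} for line {row.iloc[0]!r}")
        out[str(row.iloc[0]).strip()] = h
    return out


def read_genetic_map(path: str | Path, sep: str | None = None) -> GeneticMap:
    """Read a genetic map with columns marker, chrom, pos_cM (any header names)."""
    path = Path(path)
    if not path.exists():
        raise MarkerIOError(f"map file not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, header=0, dtype=str)
    else:
        if sep is None:
            sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, header=0, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise MarkerIOError("map needs >=3 columns: marker, linkage group, position cM")
    table = pd.DataFrame(
        {"linkage_group": df.iloc[:, 1].astype(str).to_numpy(),
         "position_cM": df.iloc[:, 2].to_numpy()},
        index=df.iloc[:, 0].astype(str).to_numpy(),
    )
    gmap = GeneticMap(table)
    logger.info("read genetic map with %d markers, %d linkage groups from %s",
                len(gmap), len(gmap.linkage_groups), path)
    return gmap


def write_genotypes(gm: GenotypeMatrix, path: str | Path, missing_token: str = "NA") -> None:
    vals = np.where(np.isnan(gm.calls), None, gm.calls)
    df = pd.DataFrame(vals, index=gm.line_ids, columns=gm.marker_ids)
    df = df.map(lambda v: missing_token if v is None else str(int(v)))
    df.index.name = "line"
    df.to_csv(path, sep="\t")


def write_line_groups(gm: GenotypeMatrix, path: str | Path) -> None:
    pd.DataFrame({"line": gm.line_ids, "habit": gm.habit}).to_csv(path, sep="\t", index=False)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    df = gmap.table.reset_index()
    df.columns = ["marker", "chrom", "pos_cM"]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# alignment


def align(genotypes: GenotypeMatrix, gmap: GeneticMap) -> AlignedDataset:
    """Join genotypes with the map and order markers along the genome.

    Unmapped markers are dropped (count logged).  Markers are sorted by
    (linkage group, position, marker id); ties in position keep a stable
    order by marker id.
    """
    mapped = [m for m in genotypes.marker_ids if m in gmap]
    dropped = genotypes.n_markers - len(mapped)
    if not mapped:
        raise MarkerIOError("no genotyped marker has a map entry")
    if dropped:
        logger.info("dropped %d unmapped marker(s)", dropped)
    sub = gmap.table.loc[mapped]
    order = sorted(
        range(len(mapped)),
        key=lambda i: (sub["linkage_group"].iloc[i], sub["position_cM"].iloc[i], mapped[i]),
    )
    marker_order = [mapped[i] for i in order]
    gm = genotypes.subset_markers(marker_order)
    sub = sub.iloc[order]
    genome = np.array([genome_of(g) for g in sub["linkage_group"]], dtype=object)
    ds = AlignedDataset(
        gm,
        sub["linkage_group"].to_numpy(dtype=object),
        sub["position_cM"].to_numpy(dtype=float),
        genome,
        _monomorphic_mask(gm.calls),
    )
    counts = pd.Series(ds.genome).value_counts()
    logger.info("aligned %d markers; per-genome counts: %s", gm.n_markers, counts.to_dict())
    return ds


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(stream=sys.stderr, level=getattr(logging, level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
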