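"""Pooled cluster statistics across stochastic trials.

Final clusters from all trials are pooled into one combined dataset (each
species-file entry expanded by its count) and characterized by:

* the occupancy distribution — for each cluster size s, the fraction of all
  pooled molecules residing in clusters of size s, i.e. the probability that
  a randomly chosen molecule sits in a size-s cluster; its mean is the
  average cluster occupancy (ACO);
* a binned version of the same distribution for wide size ranges;
* bond-count histograms over molecules (all molecules or one type), with the
  mean number of bonds per molecule;
* the bound-fraction (BF) matrix — the conditional distribution of
  cluster-level BF within each cluster-size bin;
* the per-size molecular composition (type fractions summing to 1 per size);
* mean and sample standard-deviation (n-1 divisor) time courses of the
  observables across trials.

Default size bins are monomer-resolved up to size 10, then doubling
(logarithmic) ranges, with a final open-ended bin.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model_io import ModelSpec, TimecourseTable
from .species_graph import ClusterSummary, summaries_from_species
from .simulator import EnsembleResult, TrialResult

__all__ = [
    "OccupancyDistribution",
    "BinnedDistribution",
    "BondHistogram",
    "BFMatrix",
    "CompositionTable",
    "TimecourseStats",
    "pool",
    "occupancy_distribution",
    "default_size_bins",
    "bin_distribution",
    "bond_histogram",
    "bf_matrix",
    "composition_table",
    "timecourse_stats",
    "write_stat_tables",
    "STAT_FILES",
]

SizeBin = tuple[int, Optional[int]]  # inclusive (lo, hi); hi=None means open-ended


@dataclass
class OccupancyDistribution:
    """Molecule-weighted cluster-size distribution and its mean (ACO)."""

    fractions: dict[int, float]
    aco: float

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"occupancy fractions sum to {total}, not 1")


@dataclass
class BinnedDistribution:
    bins: list[SizeBin]
    fractions: list[float]


@dataclass
class BondHistogram:
    scope: str  # "all" or a molecule type name
    fractions: dict[int, float]
    mean_bonds: float


@dataclass
class BFMatrix:
    """Relative frequency of cluster bound fraction, conditional on size bin.

    ``freq[i, j]`` is the frequency of BF bin i among clusters in size bin j;
    every nonempty column sums to 1.  BF bins have width ``bf_bin_width`` on
    [0, 1]; a BF of exactly 1 falls in the last bin.
    """

    size_bins: list[SizeBin]
    bf_edges: np.ndarray
    freq: np.ndarray


@dataclass
class CompositionTable:
    """Per size bin, the fraction of member molecules of each type (rows sum to 1)."""

    size_bins: list[SizeBin]
    types: list[str]
    fractions: np.ndarray  # shape (n_size_bins, n_types)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.fractions, index=[format_bin(b) for b in self.size_bins], columns=self.types
        )


@dataclass
class TimecourseStats:
    times: np.ndarray
    mean: dict[str, np.ndarray]
    std: dict[str, np.ndarray]
    n_trials: int


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------


def pool(
    source: Union[EnsembleResult, Sequence[TrialResult], Iterable[tuple[str, int]]],
    model: Optional[ModelSpec] = None,
) -> list[ClusterSummary]:
    """Pool final clusters across trials into one combined dataset.

    Accepts an :class:`EnsembleResult`, a sequence of :class:`TrialResult`,
    or an iterable of ``(complex string, count)`` species-file entries (the
    latter requires ``model``); species entries are expanded by their counts.
    """
    if isinstance(source, EnsembleResult):
        out = source.pooled_clusters()
    else:
        items = list(source)
        if items and isinstance(items[0], TrialResult):
            out = [c for tr in items for c in tr.final_clusters]
        else:
            if model is None:
                raise ValueError("pooling species entries requires the model")
            out = summaries_from_species(items, model)
    if not out:
        raise ValueError("no clusters to pool")
    return out


# ---------------------------------------------------------------------------
# size distribution
# ---------------------------------------------------------------------------


def occupancy_distribution(pooled: Sequence[ClusterSummary]) -> OccupancyDistribution:
    """fraction(s) = s * (# clusters of size s) / total molecules; ACO = mean."""
    if not pooled:
        raise ValueError("empty cluster pool")
    total = sum(c.size for c in pooled)
    mol_counts: dict[int, int] = {}
    for c in pooled:
        mol_counts[c.size] = mol_counts.get(c.size, 0) + c.size
    fractions = {s: mol_counts[s] / total for s in sorted(mol_counts)}
    aco = sum(s * f for s, f in fractions.items())
    return OccupancyDistribution(fractions=fractions, aco=aco)


def default_size_bins(max_size: int) -> list[SizeBin]:
    """Monomer-resolved bins up to 10, then doubling ranges, final bin open."""
    bins: list[SizeBin] = [(s, s) for s in range(1, min(max_size, 10) + 1)]
    if max_size <= 10:
        return bins[:-1] + [(bins[-1][0], None)]
    lo, width = 11, 10
    while lo + width - 1 < max_size:
        bins.append((lo, lo + width - 1))
        lo += width
        width *= 2
    bins.append((lo, None))
    return bins


def _check_bins(bins: Sequence[SizeBin]) -> None:
    prev_hi = 0
    for i, (lo, hi) in enumerate(bins):
        if lo != prev_hi + 1:
            raise ValueError(f"size bins must be disjoint and cover [1, inf); gap before {lo}")
        if hi is None:
            if i != len(bins) - 1:
                raise ValueError("only the last size bin may be open-ended")
            return
        if hi < lo:
            raise ValueError(f"empty size bin ({lo}, {hi})")
        prev_hi = hi
    raise ValueError("last size bin must be open-ended")


def _bin_index(bins: Sequence[SizeBin], size: int) -> int:
    for i, (lo, hi) in enumerate(bins):
        if size >= lo and (hi is None or size <= hi):
            return i
    raise ValueError(f"size {size} not covered by bins")


def bin_distribution(
    dist: OccupancyDistribution, bins: Optional[Sequence[SizeBin]] = None
) -> BinnedDistribution:
    """Aggregate occupancy fractions into size-range bins (fractions conserved)."""
    if bins is None:
        bins = default_size_bins(max(dist.fractions))
    _check_bins(bins)
    out = [0.0] * len(bins)
    for size, frac in dist.fractions.items():
        out[_bin_index(bins, size)] += frac
    return BinnedDistribution(bins=list(bins), fractions=out)


def format_bin(b: SizeBin) -> str:
    lo, hi = b
    if hi is None:
        return f">={lo}"
    if lo == hi:
        return str(lo)
    return f"{lo}-{hi}"


# ---------------------------------------------------------------------------
# bonds
# ---------------------------------------------------------------------------


def bond_histogram(
    pooled: Sequence[ClusterSummary],
    scope: str = "all",
    model: Optional[ModelSpec] = None,
) -> BondHistogram:
    """Distribution of bonds per molecule over in-scope pooled molecules."""
    if not pooled:
        raise ValueError("empty cluster pool")
    if scope != "all":
        declared = (
            {mt.name for mt in model.molecule_types}
            if model is not None
            else {t for c in pooled for t in c.type_counts}
        )
        if scope not in declared:
            raise ValueError(f"unknown molecule type {scope!r}")
    counts: dict[int, int] = {}
    n = 0
    total_bonds = 0
    for c in pooled:
        for nid, deg in c.degree_by_node.items():
            if scope != "all" and c.node_types[nid] != scope:
                continue
            counts[deg] = counts.get(deg, 0) + 1
            n += 1
            total_bonds += deg
    if n == 0:
        raise ValueError(f"no molecules of type {scope!r} in the pool")
    return BondHistogram(
        scope=scope,
        fractions={d: counts[d] / n for d in sorted(counts)},
        mean_bonds=total_bonds / n,
    )


# ---------------------------------------------------------------------------
# bound-fraction matrix
# ---------------------------------------------------------------------------


def bf_matrix(
    pooled: Sequence[ClusterSummary],
    size_bins: Optional[Sequence[SizeBin]] = None,
    bf_bin_width: float = 0.05,
) -> BFMatrix:
    """Histogram per-cluster (size, BF) pairs; normalize within each size bin."""
    if not pooled:
        raise ValueError("empty cluster pool")
    if not 0 < bf_bin_width <= 1:
        raise ValueError("bf_bin_width must be in (0, 1]")
    if size_bins is None:
        size_bins = default_size_bins(max(c.size for c in pooled))
    _check_bins(size_bins)
    n_bf = int(np.ceil(round(1.0 / bf_bin_width, 9)))
    edges = np.minimum(np.arange(n_bf + 1) * bf_bin_width, 1.0)
    counts = np.zeros((n_bf, len(size_bins)))
    for c in pooled:
        j = _bin_index(size_bins, c.size)
        i = min(int(c.bound_fraction / bf_bin_width), n_bf - 1)
        counts[i, j] += 1
    col_tot = counts.sum(axis=0)
    freq = np.divide(counts, col_tot, out=np.zeros_like(counts), where=col_tot > 0)
    return BFMatrix(size_bins=list(size_bins), bf_edges=edges, freq=freq)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


def composition_table(
    pooled: Sequence[ClusterSummary],
    size_bins: Optional[Sequence[SizeBin]] = None,
    types: Optional[Sequence[str]] = None,
) -> CompositionTable:
    """Per size bin, the fraction of member molecules belonging to each type."""
    if not pooled:
        raise ValueError("empty cluster pool")
    if size_bins is None:
        # default: one bin per observed size (exact, not ranged)
        sizes = sorted({c.size for c in pooled})
        size_bins = [(s, s) for s in sizes]
        occupied_only = True
    else:
        _check_bins(size_bins)
        occupied_only = False
    if types is None:
        types = sorted({t for c in pooled for t in c.type_counts})
    counts = np.zeros((len(size_bins), len(types)))
    tindex = {t: i for i, t in enumerate(types)}
    for c in pooled:
        if occupied_only:
            j = [lo for lo, _ in size_bins].index(c.size)
        else:
            j = _bin_index(size_bins, c.size)
        for t, k in c.type_counts.items():
            counts[j, tindex[t]] += k
    row_tot = counts.sum(axis=1, keepdims=True)
    fractions = np.divide(counts, row_tot, out=np.zeros_like(counts), where=row_tot > 0)
    return CompositionTable(size_bins=list(size_bins), types=list(types), fractions=fractions)


# ---------------------------------------------------------------------------
# time courses
# ---------------------------------------------------------------------------


def timecourse_stats(tables: Sequence[TimecourseTable]) -> TimecourseStats:
    """Pointwise mean and sample std (n-1 divisor; 0 for one trial) per observable."""
    if not tables:
        raise ValueError("need at least one trial time course")
    t0 = tables[0]
    for t in tables[1:]:
        if not np.array_equal(t.times, t0.times):
            raise ValueError("trial time grids differ")
        if t.names != t0.names:
            raise ValueError("trial observable sets differ")
    n = len(tables)
    mean: dict[str, np.ndarray] = {}
    std: dict[str, np.ndarray] = {}
    for name in t0.names:
        stacked = np.vstack([t.columns[name] for t in tables])
        mean[name] = stacked.mean(axis=0)
        std[name] = stacked.std(axis=0, ddof=1) if n > 1 else np.zeros(stacked.shape[1])
    return TimecourseStats(times=t0.times.copy(), mean=mean, std=std, n_trials=n)


# ---------------------------------------------------------------------------
# table export
# ---------------------------------------------------------------------------

STAT_FILES = (
    "occupancy.tsv",
    "aco.txt",
    "bonds_all.tsv",
    "bf_matrix.tsv",
    "composition.tsv",
    "timecourse_stats.tsv",
)


def write_stat_tables(
    directory: Union[str, os.PathLike],
    pooled: Sequence[ClusterSummary],
    timecourses: Optional[Sequence[TimecourseTable]] = None,
    size_bins: Optional[Sequence[SizeBin]] = None,
    bf_bin_width: float = 0.05,
    scopes: Optional[Sequence[str]] = None,
) -> list[Path]:
    """Export every statistic as tab-separated tables with fixed names.

    Writes occupancy.tsv, aco.txt, bonds_all.tsv (plus bonds_<type>.tsv per
    requested scope), bf_matrix.tsv, composition.tsv and, when time courses
    are supplied, timecourse_stats.tsv.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    dist = occupancy_distribution(pooled)
    occ = pd.DataFrame(
        {"size": list(dist.fractions), "fraction": list(dist.fractions.values())}
    )
    path = directory / "occupancy.tsv"
    occ.to_csv(path, sep="\t", index=False, float_format="%.10g")
    written.append(path)

    path = directory / "aco.txt"
    path.write_text(f"aco\n{dist.aco:.10g}\n", encoding="utf-8")
    written.append(path)

    for scope in ["all", *(scopes or [])]:
        hist = bond_histogram(pooled, scope=scope)
        df = pd.DataFrame(
            {"bonds": list(hist.fractions), "fraction": list(hist.fractions.values())}
        )
        path = directory / f"bonds_{scope}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)

    mat = bf_matrix(pooled, size_bins=size_bins, bf_bin_width=bf_bin_width)
    df = pd.DataFrame(
        mat.freq,
        index=[f"{lo:.6g}-{hi:.6g}" for lo, hi in zip(mat.bf_edges[:-1], mat.bf_edges[1:])],
        columns=[format_bin(b) for b in mat.size_bins],
    )
    df.index.name = "bf_bin"
    path = directory / "bf_matrix.tsv"
    df.to_csv(path, sep="\t", float_format="%.10g")
    written.append(path)

    comp = composition_table(pooled, size_bins=size_bins)
    cdf = comp.to_frame()
    cdf.index.name = "size"
    path = directory / "composition.tsv"
    cdf.to_csv(path, sep="\t", float_format="%.10g")
    written.append(path)

    if timecourses:
        ts = timecourse_stats(timecourses)
        cols: dict[str, np.ndarray] = {"time": ts.times}
        for name in ts.mean:
            cols[f"{name}_mean"] = ts.mean[name]
            cols[f"{name}_std"] = ts.std[name]
        path = directory / "timecourse_stats.tsv"
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)
    return written
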