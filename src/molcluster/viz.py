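"""Figure generation from exported stat tables.

Figures are drawn strictly from the tab-separated tables written by
:func:`molcluster.stats.write_stat_tables`; they never recompute statistics,
so a figure always shows exactly the exported numbers.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "SUPPORTED_FORMATS",
    "plot_timecourse",
    "plot_occupancy",
    "plot_bonds",
    "plot_bf_matrix",
    "plot_composition",
    "make_all_figures",
]

SUPPORTED_FORMATS = ("png", "svg", "pdf")


def _save(fig, stem: Path, formats: Sequence[str]) -> list[Path]:
    paths = []
    for fmt in formats:
        p = stem.with_suffix(f".{fmt}")
        fig.savefig(p, bbox_inches="tight")
        paths.append(p)
    plt.close(fig)
    return paths


def plot_timecourse(table_dir: Path, out_stem: Path, formats) -> list[Path]:
    """Mean observable trajectories with +/- one-standard-deviation envelopes."""
    df = pd.read_csv(table_dir / "timecourse_stats.tsv", sep="\t")
    names = [c[:-5] for c in df.columns if c.endswith("_mean")]
    fig, ax = plt.subplots(figsize=(6, 4))
    for name in names:
        m, s = df[f"{name}_mean"], df[f"{name}_std"]
        (line,) = ax.plot(df["time"], m, label=name)
        ax.fill_between(df["time"], m - s, m + s, alpha=0.25, color=line.get_color())
    ax.set_xlabel("time")
    ax.set_ylabel("copy number")
    if names:
        ax.legend(fontsize=8)
    ax.set_title("observable time courses (mean ± std)")
    return _save(fig, out_stem, formats)


def plot_occupancy(table_dir: Path, out_stem: Path, formats) -> list[Path]:
    """Occupancy distribution bars, ACO marker, and binned inset."""
    occ = pd.read_csv(table_dir / "occupancy.tsv", sep="\t")
    aco = float(pd.read_csv(table_dir / "aco.txt", sep="\t")["aco"].iloc[0])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(occ["size"], occ["fraction"], width=0.8)
    ax.axvline(aco, color="k", linestyle="--", label=f"ACO = {aco:.3g}")
    ax.set_xlabel("cluster size (molecules)")
    ax.set_ylabel("fraction of molecules")
    ax.set_title("cluster occupancy distribution")
    ax.legend(fontsize=8)
    # binned inset from the bf_matrix column layout is not used; rebin from occupancy
    comp = pd.read_csv(table_dir / "bf_matrix.tsv", sep="\t", index_col=0)
    labels = list(comp.columns)
    if len(occ) > 1:
        inset = ax.inset_axes([0.55, 0.55, 0.4, 0.35])
        binned = _rebin(occ, labels)
        inset.bar(range(len(labels)), binned)
        inset.set_xticks(range(len(labels)))
        inset.set_xticklabels(labels, rotation=90, fontsize=5)
        inset.tick_params(labelsize=5)
    return _save(fig, out_stem, formats)


def _rebin(occ: pd.DataFrame, labels: list[str]) -> np.ndarray:
    """Aggregate occupancy fractions into the labelled size ranges."""
    out = np.zeros(len(labels))
    bounds = []
    for lab in labels:
        lab = str(lab)
        if lab.startswith(">="):
            bounds.append((int(lab[2:]), None))
        elif "-" in lab:
            lo, hi = lab.split("-")
            bounds.append((int(lo), int(hi)))
        else:
            bounds.append((int(lab), int(lab)))
    for size, frac in zip(occ["size"], occ["fraction"]):
        for i, (lo, hi) in enumerate(bounds):
            if size >= lo and (hi is None or size <= hi):
                out[i] += frac
                break
    return out


def plot_bonds(table_dir: Path, out_stem: Path, formats) -> list[Path]:
    """Bonds-per-molecule histograms: all molecules plus any per-type tables."""
    files = sorted(table_dir.glob("bonds_*.tsv"))
    fig, axes = plt.subplots(1, len(files), figsize=(3 * len(files), 3), squeeze=False)
    for ax, path in zip(axes[0], files):
        df = pd.read_csv(path, sep="\t")
        ax.bar(df["bonds"], df["fraction"])
        ax.set_title(path.stem.replace("bonds_", ""), fontsize=9)
        ax.set_xlabel("bonds per molecule")
        ax.set_ylabel("fraction")
    fig.tight_layout()
    return _save(fig, out_stem, formats)


def plot_bf_matrix(table_dir: Path, out_stem: Path, formats) -> list[Path]:
    """Bound fraction by cluster size, as a heat map with a color bar."""
    df = pd.read_csv(table_dir / "bf_matrix.tsv", sep="\t", index_col=0)
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(df.values, aspect="auto", origin="lower", cmap="viridis")
    ax.set_xticks(range(len(df.columns)))
    ax.set_xticklabels(df.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(df.index)))
    ax.set_yticklabels(df.index, fontsize=6)
    ax.set_xlabel("cluster size bin")
    ax.set_ylabel("bound fraction bin")
    fig.colorbar(im, ax=ax, label="relative frequency (per size bin)")
    ax.set_title("bound fraction across cluster sizes")
    return _save(fig, out_stem, formats)


def plot_composition(table_dir: Path, out_stem: Path, formats) -> list[Path]:
    """Stacked per-size composition bars (type fractions sum to 1 per bar)."""
    df = pd.read_csv(table_dir / "composition.tsv", sep="\t", index_col=0)
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(df.index))
    bottom = np.zeros(len(df.index))
    for col in df.columns:
        ax.bar(x, df[col].values, bottom=bottom, label=col)
        bottom += df[col].values
    ax.set_xticks(x)
    ax.set_xticklabels(df.index, rotation=90, fontsize=6)
    ax.set_xlabel("cluster size")
    ax.set_ylabel("fraction of molecules")
    ax.legend(fontsize=8)
    ax.set_title("cluster composition by size")
    return _save(fig, out_stem, formats)


def make_all_figures(
    table_dir: Union[str, os.PathLike],
    out_dir: Union[str, os.PathLike, None] = None,
    formats: Sequence[str] = ("png",),
) -> list[Path]:
    """Render the five standard figures from a directory of stat tables."""
    table_dir = Path(table_dir)
    out_dir = Path(out_dir) if out_dir is not None else table_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    for fmt in formats:
        if fmt not in SUPPORTED_FORMATS:
            raise ValueError(
                f"unsupported format {fmt!r}; supported: {', '.join(SUPPORTED_FORMATS)}"
            )
    written: list[Path] = []
    if (table_dir / "timecourse_stats.tsv").exists():
        written += plot_timecourse(table_dir, out_dir / "timecourse", formats)
    written += plot_occupancy(table_dir, out_dir / "occupancy", formats)
    written += plot_bonds(table_dir, out_dir / "bonds", formats)
    written += plot_bf_matrix(table_dir, out_dir / "bf_matrix", formats)
    written += plot_composition(table_dir, out_dir / "composition", formats)
    return written
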