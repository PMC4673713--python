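"""Library QC statistics: length distribution, coverage, and cloning success.

Summarizes a 3'UTR clone library the way a release report would: the length
distribution of cloned inserts against the annotated reference, the fraction
of each contig's genes captured, overlap with an ORF clone collection, and
cloning success stratified by insert length (libraries of this kind lose
efficiency for long inserts because recombinational cloning is size-biased).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LibraryStats",
    "length_stats",
    "coverage_and_overlap",
    "success_by_length_bins",
    "count_panel_genes",
    "median_lower",
    "DEFAULT_LENGTH_BINS",
    "plot_length_histogram",
    "plot_contig_coverage",
]

#: Length-bin edges for success-by-length reporting (last bin open-ended).
DEFAULT_LENGTH_BINS = (0, 500, 1000, 1500, 2000, math.inf)


@dataclass
class LibraryStats:
    n_targeted: int = 0
    n_cloned: int = 0
    median_length_cloned: float = float("nan")
    median_length_reference: float | None = None
    histogram_edges: list[float] = field(default_factory=list)
    histogram_counts: list[int] = field(default_factory=list)
    per_contig_coverage: dict[str, float] = field(default_factory=dict)
    orf_overlap: tuple[int, int] = (0, 0)
    unknown_genes: list[str] = field(default_factory=list)


def median_lower(values) -> float:
    """Median using the lower of the two middle values for even counts.

    Fixed convention so reported medians are always observed lengths.
    """
    ordered = sorted(values)
    if not ordered:
        raise ValueError("median of empty set")
    return float(ordered[(len(ordered) - 1) // 2])


def length_stats(
    cloned_lengths,
    reference_lengths=None,
    bin_width: int = 250,
) -> LibraryStats:
    """Medians and a fixed-edge histogram (edges start at 0) of insert lengths."""
    cloned = list(cloned_lengths)
    if not cloned:
        raise ValueError("empty cloned length set")
    if any(x <= 0 for x in cloned):
        raise ValueError("lengths must be positive")
    top = (max(cloned) // bin_width + 1) * bin_width
    edges = np.arange(0, top + bin_width, bin_width)
    counts, _ = np.histogram(cloned, bins=edges)
    stats = LibraryStats(
        n_cloned=len(cloned),
        median_length_cloned=median_lower(cloned),
        histogram_edges=[float(e) for e in edges],
        histogram_counts=[int(c) for c in counts],
    )
    if reference_lengths is not None:
        ref = list(reference_lengths)
        if ref:
            stats.median_length_reference = median_lower(ref)
    return stats


def coverage_and_overlap(
    targeted_genes,
    cloned_genes,
    contig_gene_sets: dict[str, set],
    orf_genes=None,
) -> LibraryStats:
    """Per-contig capture fraction and overlap with an ORF collection.

    Coverage of a contig = |cloned library ∩ contig genes| / |contig genes|.
    Library genes absent from the annotation are flagged, not dropped.
    """
    if not contig_gene_sets or all(not s for s in contig_gene_sets.values()):
        raise ValueError("empty annotation gene sets")
    targeted = set(targeted_genes)
    cloned = set(cloned_genes)
    annotated = set().union(*contig_gene_sets.values())
    coverage = {
        contig: (len(cloned & genes) / len(genes)) if genes else float("nan")
        for contig, genes in sorted(contig_gene_sets.items())
    }
    orf = set(orf_genes) if orf_genes is not None else set()
    return LibraryStats(
        n_targeted=len(targeted),
        n_cloned=len(cloned),
        per_contig_coverage=coverage,
        orf_overlap=(len(targeted & orf), len(cloned & orf)),
        unknown_genes=sorted(cloned - annotated),
    )


def success_by_length_bins(
    targeted_lengths: dict[str, int],
    cloned_genes,
    bin_edges=DEFAULT_LENGTH_BINS,
) -> pd.DataFrame:
    """Cloning success percentage per insert-length bin.

    Returns one row per bin with targeted/cloned counts and
    pct = 100 * cloned / targeted; bins with no targeted genes report NaN
    (undefined, deliberately distinct from 0 %).
    """
    cloned = set(cloned_genes)
    missing = cloned - set(targeted_lengths)
    if missing:
        raise ValueError(f"cloned genes missing from targeted set: {sorted(missing)}")
    edges = list(bin_edges)
    rows = []
    for lo, hi in zip(edges, edges[1:]):
        genes = [g for g, ln in targeted_lengths.items() if lo <= ln < hi]
        n_t = len(genes)
        n_c = sum(1 for g in genes if g in cloned)
        label = f"{int(lo)}-{int(hi) - 1}" if math.isfinite(hi) else f">={int(lo)}"
        rows.append(
            {
                "bin": label,
                "n_targeted": n_t,
                "n_cloned": n_c,
                "pct_cloned": 100.0 * n_c / n_t if n_t else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def count_panel_genes(path, gene_column: str | None = None) -> int:
    """Number of unique genes in a panel sheet (TSV/CSV, or XLSX).

    Accepts the package's own primer sheets as well as externally published
    panel tables; the gene column is auto-detected unless named.
    """
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    if gene_column is None:
        candidates = [
            c for c in df.columns if "gene" in str(c).lower() or "symbol" in str(c).lower()
        ]
        if not candidates:
            gene_column = df.columns[0]
        else:
            gene_column = candidates[0]
    return int(df[gene_column].dropna().nunique())


def plot_length_histogram(stats: LibraryStats, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    edges = stats.histogram_edges
    ax.bar(edges[:-1], stats.histogram_counts,
           width=[b - a for a, b in zip(edges, edges[1:])], align="edge",
           color="#7b5aa6", edgecolor="white")
    ax.axvline(stats.median_length_cloned, color="purple", ls="--",
               label=f"median {stats.median_length_cloned:.0f} nt")
    if stats.median_length_reference is not None:
        ax.axvline(stats.median_length_reference, color="red", ls="--",
                   label=f"reference median {stats.median_length_reference:.0f} nt")
    ax.set_xlabel("insert length (nt)")
    ax.set_ylabel("clones")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_contig_coverage(stats: LibraryStats, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    contigs = list(stats.per_contig_coverage)
    ax.bar(contigs, [100 * stats.per_contig_coverage[c] for c in contigs],
           color="#4878a8")
    ax.set_ylabel("% of annotated genes in library")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
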