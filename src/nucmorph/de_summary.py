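"""Differential-expression significance filtering and recovery summaries.

Consumes gene-level DE result tables (gene_id, log2fc, padj) produced
upstream (e.g. by DESeq2) and applies the study's significance rule —
adjusted p < 0.05 and absolute fold change > 2, i.e. |log2fc| > 1, both
strict — then summarizes recovery across conditions as Venn-style set
overlaps and matched fold-change correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DeSets",
    "DeOverlap",
    "FcCorrelation",
    "load_de_table",
    "validate_de_table",
    "filter_de",
    "overlap_sets",
    "fc_correlation",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("gene_id", "log2fc", "padj")

#: column aliases accepted when loading tables written by common DE tools
COLUMN_ALIASES = {
    "gene_id": ("gene_id", "gene", "ensembl_id", "row.names", "id"),
    "log2fc": ("log2fc", "log2foldchange", "logfc"),
    "padj": ("padj", "p_adj", "fdr", "qvalue", "adj.p.val"),
}


@dataclass
class DeSets:
    """Result of the significance filter: up- and down-regulated gene ids."""

    up: set[str]
    down: set[str]
    n_dropped_nan: int = 0

    @property
    def all(self) -> set[str]:
        return self.up | self.down


@dataclass
class DeOverlap:
    """Venn-style counts over named gene sets."""

    set_sizes: dict[str, int]
    unique: dict[str, int]
    pairwise: dict[tuple[str, str], int]
    threeway: int | None
    #: count of genes in every membership pattern, keyed by the frozenset
    #: of set names containing them
    pattern_counts: dict[frozenset, int]


@dataclass
class FcCorrelation:
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    n_matched: int


def validate_de_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema and invariants; drop NaN-padj rows with a logged count."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DE table missing required columns: {missing}")
    n0 = len(table)
    table = table.dropna(subset=["padj"])
    if len(table) < n0:
        logger.info("dropped %d rows with NaN padj", n0 - len(table))
    if table["gene_id"].duplicated().any():
        raise ValueError("gene_id values must be unique per table")
    pv = table["padj"].to_numpy()
    if pv.size and (pv.min() < 0 or pv.max() > 1):
        raise ValueError("padj values must lie in [0, 1]")
    return table


def load_de_table(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a TSV DE table, mapping common DESeq2-style headers.

    ``column_map`` overrides the automatic alias lookup, mapping required
    names to the file's column names.
    """
    df = pd.read_csv(path, sep="\t")
    lower = {c.lower(): c for c in df.columns}
    rename: dict[str, str] = {}
    for want in REQUIRED_COLUMNS:
        if column_map and want in column_map:
            rename[column_map[want]] = want
            continue
        for alias in COLUMN_ALIASES[want]:
            if alias in lower:
                rename[lower[alias]] = want
                break
    df = df.rename(columns=rename)
    return validate_de_table(df)


def filter_de(
    table: pd.DataFrame, padj_cut: float = 0.05, fc_cut: float = 2.0
) -> DeSets:
    """Apply the DE significance rule: padj < cut and |FC| > fc_cut.

    Both inequalities are strict; the fold-change cut acts on the linear
    scale, i.e. ``log2fc > log2(fc_cut)`` for up-regulated genes and
    ``log2fc < -log2(fc_cut)`` for down-regulated ones.
    """
    n0 = len(table)
    table = validate_de_table(table)
    lfc_cut = np.log2(fc_cut)
    sig = table["padj"] < padj_cut
    up = set(table.loc[sig & (table["log2fc"] > lfc_cut), "gene_id"])
    down = set(table.loc[sig & (table["log2fc"] < -lfc_cut), "gene_id"])
    return DeSets(up=up, down=down, n_dropped_nan=n0 - len(table))


def overlap_sets(named_sets: dict[str, set[str]]) -> DeOverlap:
    """Exact Venn counts (unique / pairwise / three-way) over gene sets."""
    if len(named_sets) < 2:
        raise ValueError("need at least 2 sets to overlap")
    names = list(named_sets)
    universe: set[str] = set().union(*named_sets.values())
    pattern_counts: dict[frozenset, int] = {}
    for g in universe:
        key = frozenset(n for n in names if g in named_sets[n])
        pattern_counts[key] = pattern_counts.get(key, 0) + 1
    unique = {
        n: pattern_counts.get(frozenset([n]), 0) for n in names
    }
    pairwise = {
        (a, b): len(named_sets[a] & named_sets[b]) for a, b in combinations(names, 2)
    }
    threeway = (
        len(set.intersection(*named_sets.values())) if len(names) == 3 else None
    )
    return DeOverlap(
        set_sizes={n: len(named_sets[n]) for n in names},
        unique=unique,
        pairwise=pairwise,
        threeway=threeway,
        pattern_counts=pattern_counts,
    )


def fc_correlation(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    gene_filter: set[str] | None = None,
) -> FcCorrelation:
    """Pearson correlation and OLS fit of matched log2 fold changes.

    Genes are matched by ``gene_id`` across the two tables, optionally
    restricted to ``gene_filter`` (callers typically pass the union of
    each table's DE genes).  Genes present in only one table are excluded;
    at least 3 matched genes are required.
    """
    a = validate_de_table(table_a).set_index("gene_id")["log2fc"]
    b = validate_de_table(table_b).set_index("gene_id")["log2fc"]
    genes = a.index.intersection(b.index)
    if gene_filter is not None:
        genes = genes.intersection(sorted(gene_filter))
    if len(genes) < 3:
        raise ValueError(f"only {len(genes)} matched genes; need >= 3")
    x = a.loc[genes].to_numpy(dtype=np.float64)
    y = b.loc[genes].to_numpy(dtype=np.float64)
    r, p = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return FcCorrelation(
        pearson_r=float(r),
        p_value=float(p),
        slope=float(slope),
        intercept=float(intercept),
        n_matched=int(len(genes)),
    )
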