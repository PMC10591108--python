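"""Gene-set characterization of driver-pair target genes.

Two flavors, matching the two figure panels they feed:

* dependency bins — genes bucketed by median CERES score into half-open
  bins of width 0.4 on [−2, 0), then 2×2 Fisher fold enrichment of the
  target genes against each bin;
* pathway enrichment — upper-tail hypergeometric p of the target genes
  against each set of a GMT collection, BH-adjusted across the collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .ols import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")


@dataclass
class EnrichmentRow:
    name: str
    overlap: int
    target_size: int
    set_size: int
    universe_size: int
    fold_enrichment: float
    odds_ratio: float
    p_value: float
    fdr: float = float("nan")
    zero_cell: bool = False


def read_gmt(path: str | Path) -> GeneSetCollection:
    """GMT: one set per line — name <tab> description <tab> genes...; the
    universe defaults to the union of all sets."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = {g for g in fields[2:] if g}
    universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets=sets, universe=universe)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\tsynthetic\t{genes}\n")


def bin_genes_by_ceres(
    ceres: pd.DataFrame,
    width: float = 0.4,
    lower: float = -2.0,
    upper: float = 0.0,
) -> dict[str, set[str]]:
    """Bucket genes by median CERES across cell lines into half-open,
    lower-inclusive bins of the given width on [lower, upper); genes falling
    outside go to an ``"other"`` bucket, all-NaN genes are dropped with a
    warning."""
    n_bins = int(round((upper - lower) / width))
    edges = [round(lower + i * width, 10) for i in range(n_bins + 1)]
    labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(n_bins)]
    bins: dict[str, set[str]] = {lab: set() for lab in labels}
    bins["other"] = set()
    medians = ceres.median(axis=1, skipna=True)
    n_nan = int(medians.isna().sum())
    if n_nan:
        logger.warning("bin_genes_by_ceres: dropping %d all-NaN genes", n_nan)
    for gene, med in medians.dropna().items():
        if lower <= med < upper:
            # epsilon guards float edges: a median exactly on an edge belongs
            # to the bin whose lower bound it is
            idx = min(int(np.floor((med - lower) / width + 1e-9)), len(labels) - 1)
            bins[labels[idx]].add(gene)
        else:
            bins["other"].add(gene)
    return bins


def fisher_enrichment(
    target: set[str],
    annotated: set[str],
    universe: set[str],
    continuity_correction: bool = False,
) -> EnrichmentRow:
    """Two-sided Fisher's exact test of target × annotated membership over
    the universe (minimum-likelihood two-sided convention), with fold
    enrichment (overlap/target)/(annotated/universe).

    Zero-cell odds ratios are reported as 0/inf and flagged unless
    ``continuity_correction`` adds 0.5 to every cell (for the ratio only).
    """
    if not target or not universe:
        raise ValueError("target and universe must be non-empty")
    if not target <= universe or not annotated <= universe:
        raise ValueError("target and annotated must be subsets of the universe")
    a = len(target & annotated)
    b = len(target - annotated)
    c = len(annotated - target)
    d = len(universe) - a - b - c
    _odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    zero_cell = 0 in (a, b, c, d)
    if continuity_correction and zero_cell:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    elif b * c == 0:
        odds = float("inf") if a * d > 0 else (0.0 if a == 0 else float("inf"))
    else:
        odds = (a * d) / (b * c)
    fold = (
        (a / len(target)) / (len(annotated) / len(universe)) if annotated else float("nan")
    )
    return EnrichmentRow(
        name="",
        overlap=a,
        target_size=len(target),
        set_size=len(annotated),
        universe_size=len(universe),
        fold_enrichment=fold,
        odds_ratio=float(odds),
        p_value=float(p),
        zero_cell=zero_cell,
    )


def hypergeom_enrichment(
    target: set[str], collection: GeneSetCollection
) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric enrichment of ``target`` against every set
    in the collection, BH across the collection."""
    if not target:
        raise ValueError("target gene set is empty")
    universe = collection.universe
    drawn = target & universe
    if not drawn:
        raise ValueError("target is disjoint from the collection universe")
    N, n = len(universe), len(drawn)
    rows: list[EnrichmentRow] = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe
        K = len(members)
        k = len(drawn & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if K else float("nan")
        if (n - k) * (K - k) == 0:
            odds = float("inf") if k * (N - K - n + k) > 0 else 0.0
        else:
            odds = (k * (N - K - n + k)) / ((n - k) * (K - k))
        rows.append(
            EnrichmentRow(
                name=name,
                overlap=k,
                target_size=n,
                set_size=K,
                universe_size=N,
                fold_enrichment=fold,
                odds_ratio=float(odds),
                p_value=p,
            )
        )
    fdr = bh_adjust([r.p_value for r in rows])
    for row, q in zip(rows, fdr):
        row.fdr = float(q)
    return rows


def enrichment_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "overlap": r.overlap,
                "target_size": r.target_size,
                "set_size": r.set_size,
                "universe_size": r.universe_size,
                "fold_enrichment": r.fold_enrichment,
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "zero_cell": r.zero_cell,
            }
            for r in rows
        ]
    )
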