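"""Peak files → binding-activity matrices and co-bound loci.

A sample's binding activity for a factor is the mean of log2(1+signalValue)
over its peaks, z-scored per factor across cell lines so that activities are
comparable pan-cancer. Co-bound loci are the maximal overlaps between a TF
peak set and an HM peak set of the same cell line; their signals feed the
per-cancer correlation analysis, and genes whose TSS windows they hit are
the pair's target genes.

Coordinates are BED-style throughout: 0-based, half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .exceptions import PeakFormatError, ValidationError

logger = logging.getLogger(__name__)

#: Expected column counts per dialect (signalValue is column 7 in both).
DIALECT_COLUMNS = {"narrowPeak": 10, "broadPeak": 9}

#: Marks read as promoter marks by target-gene assignment; every other mark
#: (H3K4me1, H3K27ac, ...) is treated as an enhancer mark.
PROMOTER_MARKS = frozenset({"H3K4me3", "H3K9ac"})


class GenomicInterval(NamedTuple):
    chrom: str
    start: int
    end: int
    signal: float


@dataclass
class PeakSet:
    """One sample's peaks for one factor, sorted by (chrom, start)."""

    sample_id: str
    factor_id: str
    factor_class: str                 # "TF" or "HM"
    intervals: list[GenomicInterval]
    dialect: str = "narrowPeak"

    def __post_init__(self):
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))

    def __len__(self) -> int:
        return len(self.intervals)

    def total_length(self) -> int:
        return sum(iv.end - iv.start for iv in self.intervals)


class CoboundLocus(NamedTuple):
    chrom: str
    start: int
    end: int
    tf_signal: float
    hm_signal: float
    cell_line: str


def read_peak_file(
    path: str | Path,
    dialect: str,
    sample_id: str | None = None,
    factor_id: str | None = None,
    factor_class: str | None = None,
) -> PeakSet:
    """Parse a narrowPeak (BED6+4) or broadPeak (BED6+3) file.

    Signal is taken from the signalValue column (column 7). Raises
    :class:`PeakFormatError` with the line number on a wrong column count,
    and :class:`ValidationError` on start >= end.
    """
    if dialect not in DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECT_COLUMNS)}")
    expected = DIALECT_COLUMNS[dialect]
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != expected:
                raise PeakFormatError(
                    f"{dialect} requires {expected} columns, found {len(fields)}", lineno
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                signal = float(fields[6])
            except ValueError as exc:
                raise PeakFormatError(f"unparseable numeric field ({exc})", lineno) from None
            if start >= end:
                raise ValidationError(f"line {lineno}: start {start} >= end {end}")
            if signal < 0:
                raise ValidationError(f"line {lineno}: negative signal {signal}")
            intervals.append(GenomicInterval(fields[0], start, end, signal))
    if sample_id is None or factor_id is None:
        # Generator convention: "<sample>__<factor>.<dialect>".
        stem = path.name.rsplit(".", 1)[0]
        parts = stem.split("__")
        if sample_id is None:
            sample_id = parts[0]
        if factor_id is None:
            factor_id = parts[1] if len(parts) > 1 else stem
    if factor_class is None:
        factor_class = "TF" if dialect == "narrowPeak" else "HM"
    return PeakSet(sample_id, factor_id, factor_class, intervals, dialect)


def write_peak_file(peaks: PeakSet, path: str | Path) -> None:
    """Inverse of :func:`read_peak_file` (name/score/strand filled neutrally)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks.intervals):
            row = (
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{peaks.sample_id}_{peaks.factor_id}_{i}"
                f"\t0\t.\t{iv.signal:.12f}\t-1\t-1"
            )
            if peaks.dialect == "narrowPeak":
                row += f"\t{(iv.end - iv.start) // 2}"
            fh.write(row + "\n")


def activity_score(peaks: PeakSet) -> float:
    """Mean log2(1+signal) over the sample's peaks; NaN when the set is empty
    (an explicit missing value — never coerced to zero)."""
    if len(peaks) == 0:
        return float("nan")
    signals = np.array([iv.signal for iv in peaks.intervals])
    return float(np.mean(np.log2(1.0 + signals)))


@dataclass
class ActivityMatrix:
    """Cell-line × factor activity table.

    ``values`` holds per-factor z-scores (or raw scores for columns flagged
    in ``unnormalized``); ``factor_class`` maps each column to TF/HM.
    """

    values: pd.DataFrame
    factor_class: dict[str, str]
    unnormalized: set[str] = field(default_factory=set)

    def by_class(self, factor_class: str) -> pd.DataFrame:
        cols = [c for c in self.values.columns if self.factor_class.get(c) == factor_class]
        return self.values[cols]


def build_activity_matrix(peak_sets: Iterable[PeakSet]) -> ActivityMatrix:
    """Score every peak set, average replicates of the same (cell line,
    factor), and z-score each factor across cell lines (sample sd).

    Factors observed in a single cell line are left raw and flagged;
    constant columns become all-zero with a warning. Missing combinations
    stay NaN.
    """
    scores: dict[tuple[str, str], list[float]] = {}
    classes: dict[str, str] = {}
    for ps in peak_sets:
        classes[ps.factor_id] = ps.factor_class
        scores.setdefault((ps.sample_id, ps.factor_id), []).append(activity_score(ps))
    records = [
        {"sample": s, "factor": f, "score": float(np.nanmean(vals)) if vals else np.nan}
        for (s, f), vals in scores.items()
    ]
    raw = pd.DataFrame(records).pivot(index="sample", columns="factor", values="score")
    raw = raw.sort_index().sort_index(axis=1)

    values = raw.copy()
    unnormalized: set[str] = set()
    for col in raw.columns:
        observed = raw[col].dropna()
        if len(observed) < 2:
            unnormalized.add(col)
            logger.warning("factor %s observed in <2 cell lines; column left un-normalized", col)
            continue
        sd = observed.std(ddof=1)
        if sd == 0:
            logger.warning("factor %s has zero variance across cell lines; z-scores set to 0", col)
            values[col] = raw[col] * 0.0
        else:
            values[col] = (raw[col] - observed.mean()) / sd
    return ActivityMatrix(values=values, factor_class=classes, unnormalized=unnormalized)


def intersect_peaks(tf: PeakSet, hm: PeakSet) -> list[CoboundLocus]:
    """All maximal nonempty TF∩HM overlaps for one cell line, by linear sweep.

    Output is sorted by (chrom, start); complexity O(n + m + k) given the
    sorted PeakSet invariant.
    """
    if tf.sample_id != hm.sample_id:
        raise ValidationError(
            f"cell line mismatch: {tf.sample_id!r} vs {hm.sample_id!r}"
        )
    loci: list[CoboundLocus] = []
    a, b = tf.intervals, hm.intervals
    i = j = 0
    # Merge the two sorted streams by (chrom, start); keep the still-open
    # intervals of the opposite side and intersect each newly opened interval
    # against them. Intervals may overlap within a set, so a plain two-pointer
    # walk would drop pairs.
    active_tf: list[GenomicInterval] = []
    active_hm: list[GenomicInterval] = []
    current_chrom: str | None = None
    while i < len(a) or j < len(b):
        take_tf = j >= len(b) or (
            i < len(a) and (a[i].chrom, a[i].start) <= (b[j].chrom, b[j].start)
        )
        iv = a[i] if take_tf else b[j]
        if take_tf:
            i += 1
        else:
            j += 1
        if iv.chrom != current_chrom:
            active_tf.clear()
            active_hm.clear()
            current_chrom = iv.chrom
        other = active_hm if take_tf else active_tf
        other[:] = [o for o in other if o.end > iv.start]
        for o in other:
            start = max(iv.start, o.start)
            end = min(iv.end, o.end)
            if start < end:
                tf_iv, hm_iv = (iv, o) if take_tf else (o, iv)
                loci.append(
                    CoboundLocus(iv.chrom, start, end, tf_iv.signal, hm_iv.signal, tf.sample_id)
                )
        (active_tf if take_tf else active_hm).append(iv)
    loci.sort(key=lambda lc: (lc.chrom, lc.start, lc.end))
    return loci


def loci_to_frame(loci: Iterable[CoboundLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        list(loci), columns=["chrom", "start", "end", "tf_signal", "hm_signal", "cell_line"]
    )


def assign_target_genes(
    loci: Iterable[CoboundLocus],
    annotation: pd.DataFrame,
    hm_id: str,
    promoter_window: int = 1000,
    enhancer_window: int = 2000,
) -> set[str]:
    """Genes whose TSS window overlaps any co-bound locus.

    The window is ``promoter_window`` for promoter marks (H3K4me3, H3K9ac)
    and ``enhancer_window`` otherwise; strand only places the TSS. The
    annotation needs columns (gene_id, chrom, tss) with unique gene ids.
    """
    if promoter_window < 0 or enhancer_window < 0:
        raise ValueError("windows must be non-negative")
    loci = list(loci)
    if annotation.empty:
        logger.warning("empty gene annotation: no target genes assignable")
        return set()
    if annotation["gene_id"].duplicated().any():
        raise ValidationError("gene annotation has duplicated gene ids")
    if not loci:
        return set()
    window = promoter_window if hm_id in PROMOTER_MARKS else enhancer_window
    targets: set[str] = set()
    by_chrom: dict[str, list[CoboundLocus]] = {}
    for lc in loci:
        by_chrom.setdefault(lc.chrom, []).append(lc)
    for chrom, group in annotation.groupby("chrom"):
        chrom_loci = by_chrom.get(chrom)
        if not chrom_loci:
            continue
        starts = np.array([lc.start for lc in chrom_loci])
        ends = np.array([lc.end for lc in chrom_loci])
        for gene_id, tss in zip(group["gene_id"], group["tss"]):
            lo, hi = tss - window, tss + window
            if np.any((starts < hi) & (ends > lo)):
                targets.add(gene_id)
    return targets


def covered_bases(loci: Iterable[CoboundLocus | GenomicInterval]) -> int:
    """Total number of genome bases covered by the (possibly overlapping) loci."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for lc in loci:
        by_chrom.setdefault(lc.chrom, []).append((lc.start, lc.end))
    total = 0
    for spans in by_chrom.values():
        spans.sort()
        cur_s, cur_e = None, None
        for s, e in spans:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
    return total
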