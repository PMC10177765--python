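"""Cross-cohort mutation-burden statistics.

Per-window mutation frequencies are per-sample normalized (captured mutations
divided by cohort size) before correlation, because cohort sizes can differ
severalfold and raw capture counts would confound cohort size with burden.
Cohort comparisons use the unpaired Wilcoxon rank-sum (Mann–Whitney) test;
the paired signed-rank variant is available for window-wise paired vectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .discovery import Window, WindowPanel
from .io import MutationCatalog, RegionSet, normalize_chrom
from .refinement import BurdenMatrix

__all__ = [
    "WindowFrequencyVector",
    "CorrelationResult",
    "FoldChangeResult",
    "window_frequency",
    "pearson",
    "wilcoxon_compare",
    "fold_changes",
    "coldspot_panel",
]

logger = logging.getLogger(__name__)


@dataclass
class WindowFrequencyVector:
    """Mutations captured per window, normalized per sample of the cohort."""

    panel_name: str
    cohort_name: str
    window_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.window_ids):
            raise ValueError("values and window_ids lengths differ")
        if (self.values < 0).any():
            raise ValueError("frequencies must be non-negative")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class FoldChangeResult:
    window_id: str
    gene: str
    mean_a: float
    mean_b: float
    fold: float  # inf when mean_b == 0 and mean_a > 0
    p: float

    @property
    def is_infinite(self) -> bool:
        return np.isinf(self.fold)


def window_frequency(
    catalog: MutationCatalog, panel: WindowPanel, normalized: bool = True
) -> WindowFrequencyVector:
    """Per-window capture count divided by the cohort's sample count
    (mutations per sample per window); ``normalized=False`` returns raw
    capture counts."""
    n = catalog.n_samples
    if n == 0:
        raise ValueError("catalog has zero samples; frequencies are undefined")
    counts = np.zeros(len(panel.windows), dtype=float)
    for rec in catalog.records:
        for j, w in enumerate(panel.windows):
            if w.contains_pos(rec.chrom, rec.pos):
                counts[j] += 1
                break  # windows are capture-disjoint; attribute once
    values = counts / n if normalized else counts
    return WindowFrequencyVector(
        panel_name=panel.name,
        cohort_name=catalog.cohort_name,
        window_ids=[w.window_id for w in panel.windows],
        values=values,
    )


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided p-value from the
    t-transform with n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ValueError("need >= 3 observations for a correlation p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=len(x))


def wilcoxon_compare(a, b, paired: bool = False) -> float:
    """Two-sided Wilcoxon comparison of two samples.

    ``paired=True``: signed-rank test on the differences (zero differences
    dropped; all-zero differences give p = 1 with a warning).
    ``paired=False``: rank-sum (Mann–Whitney) test, exact when both samples
    have <= 25 observations and the pooled data is tie-free, otherwise the
    tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired comparison needs equal-length vectors")
        d = a - b
        if np.all(d == 0):
            warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
            return 1.0
        res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
        return float(res.pvalue)
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    small = max(len(a), len(b)) <= 25
    method = "exact" if (tie_free and small) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def fold_changes(
    m_a: BurdenMatrix, m_b: BurdenMatrix, panel: WindowPanel
) -> list[FoldChangeResult]:
    """Per-window fold change in mean per-sample mutation count, cohort a
    over cohort b, with an unpaired Wilcoxon p-value per window.

    Windows where cohort b captures nothing are reported with an infinite
    fold rather than dropped.
    """
    ids_a, ids_b = m_a.window_ids, m_b.window_ids
    want = [w.window_id for w in panel.windows]
    if ids_a != want or ids_b != want:
        raise ValueError("both burden matrices must be computed on the given panel")
    out = []
    for j, w in enumerate(panel.windows):
        col_a = m_a.counts[:, j]
        col_b = m_b.counts[:, j]
        mean_a = float(col_a.mean())
        mean_b = float(col_b.mean())
        if mean_b == 0:
            fold = np.inf if mean_a > 0 else np.nan
        else:
            fold = mean_a / mean_b
        p = wilcoxon_compare(col_a, col_b, paired=False)
        out.append(
            FoldChangeResult(
                window_id=w.window_id, gene=w.gene,
                mean_a=mean_a, mean_b=mean_b, fold=fold, p=p,
            )
        )
    return out


def coldspot_panel(
    catalog: MutationCatalog,
    footprint: RegionSet,
    size: int,
    width: int = 100,
    exclude: WindowPanel | None = None,
) -> WindowPanel:
    """Equal-width control panel of minimally mutated windows.

    Candidate windows tile each footprint region left to right at the given
    width; tiles intersecting ``exclude`` (typically the hotspot panel) are
    discarded, the rest are sorted by ascending capture count (zero-capture
    first; ties by chromosome then start) and the first ``size`` are kept.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    tiles: list[Window] = []
    for region in footprint:
        chrom = normalize_chrom(region.chrom)
        # region is BED half-open; first 1-based position is start + 1
        s = region.start + 1
        while s + width - 1 <= region.end:
            tiles.append(Window(chrom=chrom, start=s, end=s + width - 1, gene=region.gene))
            s += width
    if exclude is not None:
        tiles = [t for t in tiles if not any(t.intersects(w) for w in exclude.windows)]
    if len(tiles) < size:
        raise ValueError(
            f"footprint yields only {len(tiles)} candidate windows (< {size}); "
            "footprint too small for the requested cold-spot panel"
        )
    # capture counts per tile
    by_chrom: dict[str, np.ndarray] = {}
    for rec in catalog.records:
        by_chrom.setdefault(normalize_chrom(rec.chrom), [])
    for rec in catalog.records:
        by_chrom[normalize_chrom(rec.chrom)].append(rec.pos)  # type: ignore[union-attr]
    pos_arrays = {c: np.sort(np.asarray(p)) for c, p in by_chrom.items()}
    counted = []
    for t in tiles:
        arr = pos_arrays.get(t.chrom)
        if arr is None:
            n = 0
        else:
            n = int(
                np.searchsorted(arr, t.end, side="right")
                - np.searchsorted(arr, t.start, side="left")
            )
        counted.append((n, t.chrom, t.start, t))
    counted.sort(key=lambda x: (x[0], x[1], x[2]))
    chosen = [
        Window(chrom=t.chrom, start=t.start, end=t.end, gene=t.gene,
               capture_count=n, rank=i + 1)
        for i, (n, _, _, t) in enumerate(counted[:size])
    ]
    return WindowPanel(name="coldspot", windows=chosen, source_cohort=catalog.cohort_name)
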