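"""Fixed-width mutation-capture window placement, ranking and panel algebra.

The placement procedure is a greedy maximal-capture search: candidate windows
of width ``w`` are anchored at each distinct position of a not-yet-captured
mutation record (the window ``[p, p + w - 1]`` in 1-based inclusive
coordinates), and at every step the candidate capturing the most remaining
records is selected (ties broken by chromosome name, then leftmost start).
Each record is captured exactly once, so capture counts over the returned
windows sum to the catalog size.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .io import MutationCatalog, RegionSet, normalize_chrom

__all__ = [
    "Window",
    "WindowPanel",
    "PanelOverlap",
    "place_windows",
    "rank_windows",
    "top_fraction_panel",
    "panel_overlap",
]


@dataclass(frozen=True)
class Window:
    """A fixed-width genomic window, 1-based inclusive on both ends."""

    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    gene: str = ""
    capture_count: int = 0
    rank: int = 0

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def contains_pos(self, chrom: str, pos: int) -> bool:
        return normalize_chrom(chrom) == normalize_chrom(self.chrom) and (
            self.start <= pos <= self.end
        )

    def intersects(self, other: "Window") -> bool:
        return normalize_chrom(self.chrom) == normalize_chrom(other.chrom) and (
            self.start <= other.end and other.start <= self.end
        )

    @property
    def window_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class WindowPanel:
    """An ordered (rank-order) collection of windows forming a panel.

    Windows are capture-disjoint: each mutation record of the source catalog
    is attributed to exactly one window.
    """

    name: str
    windows: list[Window] = field(default_factory=list)
    source_cohort: str = ""

    @property
    def total_width(self) -> int:
        return sum(w.width for w in self.windows)

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def contains_pos(self, chrom: str, pos: int) -> bool:
        return any(w.contains_pos(chrom, pos) for w in self.windows)


def place_windows(
    catalog: MutationCatalog,
    footprint: RegionSet | None = None,
    width: int = 100,
) -> list[Window]:
    """Greedy maximal-capture placement of fixed-width windows.

    ``footprint`` is optional and used only to annotate windows whose captured
    records carry no gene label; the catalog is expected to be pre-restricted
    to the footprint.
    """
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    if not catalog.records:
        return []

    # per-chrom sorted position arrays with record indices
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for idx, rec in enumerate(catalog.records):
        by_chrom.setdefault(normalize_chrom(rec.chrom), []).append((rec.pos, idx))

    chrom_pos: dict[str, np.ndarray] = {}
    chrom_idx: dict[str, np.ndarray] = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        chrom_pos[chrom] = np.array([p for p, _ in pairs], dtype=np.int64)
        chrom_idx[chrom] = np.array([i for _, i in pairs], dtype=np.int64)

    captured = np.zeros(len(catalog.records), dtype=bool)
    windows: list[Window] = []

    while True:
        best: tuple[int, str, int] | None = None  # (-count, chrom, anchor)
        for chrom in sorted(chrom_pos):
            pos = chrom_pos[chrom]
            alive = ~captured[chrom_idx[chrom]]
            live_pos = pos[alive]
            if live_pos.size == 0:
                continue
            anchors = np.unique(live_pos)
            lo = np.searchsorted(live_pos, anchors, side="left")
            hi = np.searchsorted(live_pos, anchors + width, side="left")
            counts = hi - lo
            k = int(np.argmax(counts))  # np.argmax: first (leftmost) maximum
            cand = (-int(counts[k]), chrom, int(anchors[k]))
            if best is None or cand < best:
                best = cand
        if best is None or best[0] == 0:
            break
        count, chrom, anchor = -best[0], best[1], best[2]
        pos = chrom_pos[chrom]
        in_window = (pos >= anchor) & (pos < anchor + width)
        hit_idx = chrom_idx[chrom][in_window & ~captured[chrom_idx[chrom]]]
        captured[hit_idx] = True

        gene = _modal_gene(catalog, hit_idx)
        if not gene and footprint is not None:
            regions = footprint.regions_at(chrom, anchor)
            if regions:
                gene = regions[0].gene
        windows.append(
            Window(
                chrom=chrom,
                start=anchor,
                end=anchor + width - 1,
                gene=gene,
                capture_count=int(count),
            )
        )
    return windows


def _modal_gene(catalog: MutationCatalog, indices: np.ndarray) -> str:
    genes = [catalog.records[i].gene for i in indices if catalog.records[i].gene]
    if not genes:
        return ""
    return Counter(genes).most_common(1)[0][0]


def rank_windows(windows: Iterable[Window]) -> list[Window]:
    """Sort by capture count descending (ties by chrom then start) and assign
    ranks 1..N."""
    ordered = sorted(
        windows, key=lambda w: (-w.capture_count, normalize_chrom(w.chrom), w.start)
    )
    return [replace(w, rank=i + 1) for i, w in enumerate(ordered)]


def top_fraction_panel(
    ranked: Sequence[Window],
    q: float = 0.10,
    name: str = "top",
    source_cohort: str = "",
) -> WindowPanel:
    """Panel of the top ``ceil(q * N)`` ranked windows."""
    if not ranked:
        raise ValueError("cannot build a panel from an empty ranked list")
    if not (0 < q <= 1):
        raise ValueError(f"q must be in (0, 1], got {q}")
    n = math.ceil(q * len(ranked))
    return WindowPanel(name=name, windows=list(ranked[:n]), source_cohort=source_cohort)


@dataclass
class PanelOverlap:
    """Set algebra between two panels under >=1 bp intersection.

    ``shared_in_a`` / ``shared_in_b`` count windows of each panel intersecting
    the other (they can differ when overlap is not one-to-one). The union
    keeps every window of ``a`` plus the windows of ``b`` that intersect no
    window of ``a`` (overlapping cross-panel windows are represented once,
    by the ``a`` member).
    """

    shared_pairs: list[tuple[Window, Window]]
    shared_in_a: int
    shared_in_b: int
    unique_a: int
    unique_b: int
    union_panel: WindowPanel


def panel_overlap(a: WindowPanel, b: WindowPanel) -> PanelOverlap:
    pairs = [(wa, wb) for wa in a.windows for wb in b.windows if wa.intersects(wb)]
    shared_a = {id(wa) for wa, _ in pairs}
    shared_b = {id(wb) for _, wb in pairs}
    unique_b_windows = [wb for wb in b.windows if id(wb) not in shared_b]
    union = WindowPanel(
        name=f"{a.name}+{b.name}",
        windows=list(a.windows) + unique_b_windows,
        source_cohort=f"{a.source_cohort}+{b.source_cohort}",
    )
    return PanelOverlap(
        shared_pairs=pairs,
        shared_in_a=len(shared_a),
        shared_in_b=len(shared_b),
        unique_a=len(a) - len(shared_a),
        unique_b=len(b) - len(shared_b),
        union_panel=union,
    )
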