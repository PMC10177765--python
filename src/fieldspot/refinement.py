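"""Hotspot refinement: per-sample window counts, one-way ANOVA across windows,
and Tukey HSD selection of windows that capture significantly more mutations
than the majority of lower-ranked windows.

The statistical layout treats each window of the candidate panel as a group
and each sample's mutation count in that window as one observation of the
group. A single one-way ANOVA (window as factor) gates the analysis; all-pairs
Tukey–Kramer HSD (pooled mean-square error, studentized-range distribution
with k groups and N - k error degrees of freedom) then yields adjusted
p-values for every window pair. A window is a hotspot when it beats — higher
mean and adjusted p below alpha — more than a majority (default > 50%) of the
windows ranked below it. The lowest-ranked window has no lower-ranked
comparators and is never a hotspot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .discovery import Window, WindowPanel
from .io import MutationCatalog, normalize_chrom

__all__ = [
    "BurdenMatrix",
    "HotspotDecision",
    "DegenerateDataError",
    "per_sample_window_counts",
    "anova_across_windows",
    "tukey_pairwise_p",
    "tukey_select",
    "refine_panel",
]


class DegenerateDataError(ValueError):
    """Raised when counts carry no within-group variance, so the pooled
    error term of the Tukey HSD is zero and adjusted p-values are undefined."""


@dataclass
class BurdenMatrix:
    """Samples x windows mutation-count matrix for one cohort.

    Columns follow the panel's rank order; rows cover the catalog's full
    sample roster, so zero-mutation samples appear as zero rows.
    """

    sample_ids: list[str]
    windows: list[Window]
    counts: np.ndarray  # shape (n_samples, n_windows), integer
    cohort_name: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.windows)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.windows)} windows"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def window_ids(self) -> list[str]:
        return [w.window_id for w in self.windows]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_windows(self) -> int:
        return len(self.windows)


@dataclass(frozen=True)
class HotspotDecision:
    """Per-window outcome of the Tukey selection step."""

    window: Window
    frac_lower_ranked_beaten: float
    is_hotspot: bool
    anova_F: float = float("nan")
    anova_p: float = float("nan")


def per_sample_window_counts(catalog: MutationCatalog, panel: WindowPanel) -> BurdenMatrix:
    """Count, per sample and per panel window, the catalog records falling
    inside the window (1-based inclusive bounds)."""
    roster = list(catalog.roster)
    row = {s: i for i, s in enumerate(roster)}
    counts = np.zeros((len(roster), len(panel.windows)), dtype=np.int64)
    by_chrom: dict[str, list[tuple[int, int]]] = {}  # chrom -> [(pos, row)]
    for rec in catalog.records:
        by_chrom.setdefault(normalize_chrom(rec.chrom), []).append(
            (rec.pos, row[rec.sample_id])
        )
    for j, w in enumerate(panel.windows):
        for pos, i in by_chrom.get(normalize_chrom(w.chrom), ()):
            if w.start <= pos <= w.end:
                counts[i, j] += 1
    return BurdenMatrix(
        sample_ids=roster,
        windows=list(panel.windows),
        counts=counts,
        cohort_name=catalog.cohort_name,
    )


def anova_across_windows(m: BurdenMatrix) -> tuple[float, float]:
    """One-way fixed-effects ANOVA with window as the factor.

    Returns ``(F, p)``; all-equal data returns the ``F = 0, p = 1``
    convention instead of the 0/0 indeterminate form.
    """
    if m.n_windows < 2:
        raise ValueError("ANOVA needs >= 2 windows (no between-group contrast)")
    if m.n_samples < 2:
        raise ValueError("ANOVA needs >= 2 samples")
    x = m.counts
    if np.all(x == x.flat[0]):
        return 0.0, 1.0
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.f_oneway(*(x[:, j] for j in range(m.n_windows)))
    f = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(f):  # zero between- and within-group variance handled above
        return 0.0, 1.0
    return f, p


def tukey_pairwise_p(m: BurdenMatrix) -> np.ndarray:
    """All-pairs Tukey–Kramer adjusted p-values for the window groups.

    Balanced by construction (every window has one observation per sample).
    Entry ``[i, j]`` is the adjusted p-value for windows i vs j; the diagonal
    is 1.
    """
    x = m.counts.astype(float)
    n, k = x.shape
    if k < 2:
        raise ValueError("need >= 2 windows")
    means = x.mean(axis=0)
    sse = float(((x - means) ** 2).sum())
    df_err = n * k - k
    if df_err <= 0:
        raise DegenerateDataError("not enough observations for a pooled error term")
    mse = sse / df_err
    if mse == 0:
        raise DegenerateDataError(
            "zero pooled within-window variance: counts are degenerate "
            "(every sample identical within each window); Tukey HSD is undefined"
        )
    # Tukey-Kramer standard error; groups are balanced with n obs each
    se = np.sqrt(mse / 2.0 * (1.0 / n + 1.0 / n))
    diff = np.abs(means[:, None] - means[None, :])
    q = diff / se
    p = stats.studentized_range.sf(q, k, df_err)
    p = np.asarray(p, dtype=float)
    np.fill_diagonal(p, 1.0)
    return np.clip(p, 0.0, 1.0)


_QCRIT_CACHE: dict[tuple[float, int, int], float] = {}


def _tukey_critical_q(alpha: float, k: int, df_err: int) -> float:
    """Studentized-range critical value; cached because the ppf is costly and
    simulation reuses the same (alpha, k, df) many times."""
    key = (alpha, k, df_err)
    if key not in _QCRIT_CACHE:
        _QCRIT_CACHE[key] = float(stats.studentized_range.ppf(1.0 - alpha, k, df_err))
    return _QCRIT_CACHE[key]


def _permutation_pairwise_p(
    m: BurdenMatrix, n_perm: int = 999, seed: int = 0
) -> np.ndarray:
    """Family-wise max-statistic permutation alternative to the studentized
    range (not the default): observations are permuted across windows within
    the pooled sample, and each pair's |mean difference| is referred to the
    null distribution of the maximum pairwise difference."""
    rng = np.random.default_rng(seed)
    x = m.counts.astype(float)
    n, k = x.shape
    means = x.mean(axis=0)
    obs = np.abs(means[:, None] - means[None, :])
    pooled = x.ravel()
    max_null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(pooled).reshape(n, k)
        pm = perm.mean(axis=0)
        d = np.abs(pm[:, None] - pm[None, :])
        max_null[b] = d.max()
    # p = (1 + #{null >= obs}) / (1 + B)
    p = (1.0 + (max_null[None, None, :] >= obs[:, :, None]).sum(axis=2)) / (1.0 + n_perm)
    np.fill_diagonal(p, 1.0)
    return p


def tukey_select(
    m: BurdenMatrix,
    alpha: float = 0.05,
    majority: float = 0.5,
    method: str = "tukey",
    anova_F: float = float("nan"),
    anova_p: float = float("nan"),
    n_perm: int = 999,
    seed: int = 0,
) -> list[HotspotDecision]:
    """Flag windows beating more than ``majority`` of lower-ranked windows.

    A window "beats" a lower-ranked window when its mean per-sample count is
    greater and the adjusted pairwise p-value is below ``alpha``.
    ``method`` is ``"tukey"`` (studentized-range, default) or
    ``"permutation"`` (max-statistic permutation).
    """
    if m.n_windows < 2:
        raise ValueError("tukey_select needs >= 2 windows")
    ranks = [w.rank for w in m.windows]
    if len(set(ranks)) != len(ranks) or any(r <= 0 for r in ranks):
        raise ValueError("windows must carry distinct positive ranks")
    x = m.counts.astype(float)
    n, k = x.shape
    means = x.mean(axis=0)
    if method == "tukey":
        # significance at alpha is decided on the q scale against the cached
        # critical value: q > q_crit  <=>  adjusted p < alpha (sf is monotone),
        # which avoids one slow tail integral per window pair
        sse = float(((x - means) ** 2).sum())
        df_err = n * k - k
        if df_err <= 0:
            raise DegenerateDataError("not enough observations for a pooled error term")
        mse = sse / df_err
        if mse == 0:
            raise DegenerateDataError(
                "zero pooled within-window variance: counts are degenerate "
                "(every sample identical within each window); Tukey HSD is undefined"
            )
        se = np.sqrt(mse / n)
        q = np.abs(means[:, None] - means[None, :]) / se
        significant = q > _tukey_critical_q(alpha, k, df_err)
    elif method == "permutation":
        significant = _permutation_pairwise_p(m, n_perm=n_perm, seed=seed) < alpha
    else:
        raise ValueError(f"unknown method: {method!r}")
    decisions = []
    for i, w in enumerate(m.windows):
        lower = [j for j in range(m.n_windows) if m.windows[j].rank > w.rank]
        if not lower:
            frac = 0.0
        else:
            beaten = sum(
                1 for j in lower if significant[i, j] and means[i] > means[j]
            )
            frac = beaten / len(lower)
        decisions.append(
            HotspotDecision(
                window=w,
                frac_lower_ranked_beaten=frac,
                is_hotspot=frac > majority,
                anova_F=anova_F,
                anova_p=anova_p,
            )
        )
    return decisions


def refine_panel(
    catalog: MutationCatalog,
    panel: WindowPanel,
    alpha: float = 0.05,
    majority: float = 0.5,
    method: str = "tukey",
    return_decisions: bool = False,
):
    """Refine a candidate panel to its final hotspots.

    Pipeline: per-sample window counts -> one-way ANOVA gate (proceed only
    when the window factor is significant at ``alpha``) -> Tukey HSD
    selection. Returns the hotspot panel in rank order (and the per-window
    decisions when ``return_decisions``).
    """
    m = per_sample_window_counts(catalog, panel)
    f, p = anova_across_windows(m)
    if p >= alpha:
        hot = WindowPanel(
            name=f"{panel.name}_hotspots", windows=[], source_cohort=panel.source_cohort
        )
        decisions = [
            HotspotDecision(window=w, frac_lower_ranked_beaten=0.0, is_hotspot=False,
                            anova_F=f, anova_p=p)
            for w in panel.windows
        ]
        return (hot, decisions) if return_decisions else hot
    decisions = tukey_select(
        m, alpha=alpha, majority=majority, method=method, anova_F=f, anova_p=p
    )
    hot_windows = [d.window for d in decisions if d.is_hotspot]
    hot_windows.sort(key=lambda w: w.rank)
    hot = WindowPanel(
        name=f"{panel.name}_hotspots",
        windows=hot_windows,
        source_cohort=panel.source_cohort,
    )
    return (hot, decisions) if return_decisions else hot
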