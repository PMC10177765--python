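"""Synthetic cohort generation with planted hotspot windows.

The generator emulates the statistical structure the hotspot analysis
assumes: a targeted-sequencing footprint of gene exons; per-sample mutation
totals drawn from a negative binomial (real cohorts mix targeted-panel and
exome burdens with heavy overdispersion, so Poisson totals would be too
tight); a planted minority of mutations concentrated in short fixed-width
hotspot windows inside exons, with per-hotspot weights drawn from a
Dirichlet; cohort-level multipliers acting on both the hotspot weight and
the mean burden; and clinical covariates (age, sex, smoking) whose
distributions depend on the risk label. Every draw flows from a single seed,
and ground truth (hotspot coordinates, weights, per-sample totals) is
returned so recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from .discovery import Window
from .io import ClinicalTable, MutationCatalog, MutationRecord, Region, RegionSet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_footprint",
    "plant_hotspots",
    "generate_cohort",
    "generate_clinical",
    "risk_scenario_config",
]

_BASES = np.array(list("ACGT"))


def _subseed(seed: int, tag: str) -> list[int]:
    return [seed, zlib.crc32(tag.encode()) & 0x7FFFFFFF]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generator.

    Defaults give a ~40 kb footprint (25 genes x 4 exons x 400 bp, i.e. a few
    hundred background candidate windows) with 10 planted 100-bp hotspots
    jointly receiving 30% of each sample's mutations, and negative-binomial
    per-sample totals with mean 20 and dispersion 2.
    """

    seed: int = 0
    n_genes: int = 25
    exons_per_gene: int = 4
    exon_width_bp: int = 400
    n_chroms: int = 5
    n_hotspots: int = 10
    hotspot_width_bp: int = 100
    hotspot_weight: float = 0.3  # fraction of a sample's mutations in hotspots
    hotspot_dirichlet_alpha: float = 5.0
    burden_mean: float = 20.0  # negative-binomial mean mutations per sample
    burden_dispersion: float = 2.0  # NB shape; variance = mean + mean^2 / shape
    cohort_multipliers: dict[str, float] = field(default_factory=dict)
    age_means: dict[str, float] = field(default_factory=lambda: {"high": 70.0, "low": 60.0})
    age_sd: float = 8.0
    smoking_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "high": {"never": 0.3, "former": 0.4, "current": 0.3},
            "low": {"never": 0.6, "former": 0.3, "current": 0.1},
        }
    )

    def __post_init__(self) -> None:
        if not (0 <= self.hotspot_weight < 1):
            raise ValueError("hotspot_weight must be in [0, 1)")
        if self.burden_mean <= 0:
            raise ValueError("burden_mean must be > 0")
        if self.exon_width_bp < self.hotspot_width_bp:
            raise ValueError("exons must be at least one hotspot wide")

    def multiplier(self, cohort_name: str) -> float:
        return float(self.cohort_multipliers.get(cohort_name, 1.0))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.md5(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class GroundTruth:
    """Everything needed to score recovery exactly."""

    cohort_name: str
    hotspot_windows: list[Window]
    hotspot_weights: np.ndarray
    sample_totals: dict[str, int]
    effective_hotspot_weight: float
    effective_burden_mean: float

    def to_dict(self) -> dict:
        return {
            "cohort_name": self.cohort_name,
            "hotspot_windows": [
                {"chrom": w.chrom, "start": w.start, "end": w.end, "gene": w.gene}
                for w in self.hotspot_windows
            ],
            "hotspot_weights": [float(x) for x in self.hotspot_weights],
            "sample_totals": self.sample_totals,
            "effective_hotspot_weight": self.effective_hotspot_weight,
            "effective_burden_mean": self.effective_burden_mean,
        }


def generate_footprint(config: SimulationConfig) -> RegionSet:
    """Lay out n_genes x exons_per_gene disjoint exons on synthetic
    chromosomes (genes round-robin across chromosomes, exons separated by
    short introns). Purely arithmetic, hence identical for any seed."""
    regions: list[Region] = []
    cursors = {str(c + 1): 10_000 for c in range(config.n_chroms)}
    intron, intergenic = 500, 10_000
    for g in range(config.n_genes):
        chrom = str(g % config.n_chroms + 1)
        gene = f"GENE{g + 1:03d}"
        pos = cursors[chrom]
        for _ in range(config.exons_per_gene):
            regions.append(Region(chrom=chrom, start=pos, end=pos + config.exon_width_bp,
                                  gene=gene, label=gene))
            pos += config.exon_width_bp + intron
        cursors[chrom] = pos + intergenic
    return RegionSet(regions, name="synthetic_footprint")


def plant_hotspots(config: SimulationConfig) -> list[Window]:
    """Choose hotspot windows: distinct exons, window placed uniformly inside
    the exon. One window per chosen exon, so hotspots are pairwise disjoint."""
    footprint = generate_footprint(config)
    rng = np.random.default_rng(_subseed(config.seed, "hotspots"))
    if config.n_hotspots > len(footprint):
        raise ValueError("more hotspots requested than exons available")
    exon_idx = rng.choice(len(footprint), size=config.n_hotspots, replace=False)
    hotspots = []
    for i in sorted(exon_idx):
        r = footprint.regions[i]
        max_start = r.end - config.hotspot_width_bp + 1  # 1-based start bound
        start = int(rng.integers(r.start + 1, max_start + 1))
        hotspots.append(
            Window(chrom=r.chrom, start=start, end=start + config.hotspot_width_bp - 1,
                   gene=r.gene)
        )
    return hotspots


def _footprint_position_arrays(footprint: RegionSet):
    chroms, poss, genes = [], [], []
    for r in footprint:
        n = r.width
        chroms.append(np.full(n, r.chrom))
        poss.append(np.arange(r.start + 1, r.end + 1))
        genes.append(np.full(n, r.gene))
    return np.concatenate(chroms), np.concatenate(poss), np.concatenate(genes)


def generate_cohort(
    config: SimulationConfig,
    cohort_name: str,
    n_samples: int,
    hotspot_weights: np.ndarray | None = None,
    hotspots: Sequence[Window] | None = None,
) -> tuple[MutationCatalog, GroundTruth]:
    """Draw a cohort's mutation catalog.

    Per sample: total mutations ~ NB(mean = burden_mean x multiplier,
    shape = burden_dispersion); each mutation lands in a planted hotspot with
    probability hotspot_weight x multiplier (hotspot picked by its Dirichlet
    weight, position uniform inside the window), otherwise uniformly over the
    whole footprint — hotspot windows also receive their width-share of
    background, so hotspot_weight = 0 reduces to a uniform catalog. Pass
    ``hotspot_weights`` to share the per-hotspot
    weight vector between cohorts (correlated cohorts); leave None to draw a
    fresh vector. ``hotspots`` overrides the planted windows (e.g. windows
    planted under a different seed, for cohorts whose hotspot structure is
    fully independent of another cohort's).
    """
    mult = config.multiplier(cohort_name)
    w_eff = config.hotspot_weight * mult
    if not (0 <= w_eff < 1):
        raise ValueError(
            f"effective hotspot weight {w_eff:.3f} for cohort {cohort_name!r} "
            "is outside [0, 1); lower the multiplier or the base weight"
        )
    mean_eff = config.burden_mean * mult

    footprint = generate_footprint(config)
    if hotspots is None:
        hotspots = plant_hotspots(config)
    else:
        hotspots = list(hotspots)
        if len(hotspots) != config.n_hotspots:
            raise ValueError("hotspots length must equal n_hotspots")
    rng = np.random.default_rng(_subseed(config.seed, f"cohort:{cohort_name}"))

    if hotspot_weights is None:
        weights = rng.dirichlet(np.full(config.n_hotspots, config.hotspot_dirichlet_alpha))
    else:
        weights = np.asarray(hotspot_weights, dtype=float)
        if weights.shape != (config.n_hotspots,):
            raise ValueError("hotspot_weights length must equal n_hotspots")
        weights = weights / weights.sum()

    chrom_all, pos_all, gene_all = _footprint_position_arrays(footprint)

    shape = config.burden_dispersion
    p_nb = shape / (shape + mean_eff)
    totals = rng.negative_binomial(shape, p_nb, size=n_samples)

    records: list[MutationRecord] = []
    sample_ids = [f"{cohort_name}_s{i + 1:04d}" for i in range(n_samples)]
    for sid, total in zip(sample_ids, totals):
        total = int(total)
        if total == 0:
            continue
        n_hot = int(rng.binomial(total, w_eff))
        hot_idx = rng.choice(config.n_hotspots, size=n_hot, p=weights)
        for k in hot_idx:
            h = hotspots[k]
            pos = int(rng.integers(h.start, h.end + 1))
            ref, alt = _draw_substitution(rng)
            records.append(MutationRecord(sid, h.chrom, pos, ref, alt, h.gene))
        bg_pick = rng.integers(0, len(pos_all), size=total - n_hot)
        for j in bg_pick:
            ref, alt = _draw_substitution(rng)
            records.append(
                MutationRecord(sid, str(chrom_all[j]), int(pos_all[j]), ref, alt,
                               str(gene_all[j]))
            )
    catalog = MutationCatalog(
        records=records, cohort_name=cohort_name, sample_ids=tuple(sample_ids)
    )
    truth = GroundTruth(
        cohort_name=cohort_name,
        hotspot_windows=hotspots,
        hotspot_weights=weights,
        sample_totals={sid: int(t) for sid, t in zip(sample_ids, totals)},
        effective_hotspot_weight=w_eff,
        effective_burden_mean=mean_eff,
    )
    return catalog, truth


def _draw_substitution(rng) -> tuple[str, str]:
    i = int(rng.integers(4))
    j = (i + 1 + int(rng.integers(3))) % 4
    return str(_BASES[i]), str(_BASES[j])


def generate_clinical(
    config: SimulationConfig, labels: Mapping[str, str]
) -> ClinicalTable:
    """Draw clinical covariates per sample given risk labels.

    Age ~ Normal(age_means[label], age_sd) truncated to [30, 95]; sex is a
    fair coin; smoking category follows the per-label probabilities.
    """
    import pandas as pd

    rng = np.random.default_rng(_subseed(config.seed, "clinical"))
    rows = []
    for sid, label in labels.items():
        mu = config.age_means[label]
        a, b = (30.0 - mu) / config.age_sd, (95.0 - mu) / config.age_sd
        age = float(stats.truncnorm.rvs(a, b, loc=mu, scale=config.age_sd,
                                        random_state=rng))
        sex = "male" if rng.random() < 0.5 else "female"
        probs = config.smoking_probs[label]
        cats = sorted(probs)
        smoking = str(rng.choice(cats, p=np.array([probs[c] for c in cats])
                                 / sum(probs.values())))
        rows.append({"sample_id": sid, "risk_label": label, "age": round(age, 1),
                     "sex": sex, "smoking": smoking})
    return ClinicalTable(pd.DataFrame(rows))


def risk_scenario_config(seed: int = 1) -> SimulationConfig:
    """The default high- vs low-risk normal-tissue scenario.

    Low-risk normal tissue carries a low mutation burden (~4 SNVs per sample
    over the footprint) of which only a small fraction (3%) falls inside
    tumor hotspots; high-risk tissue carries a 3x multiplier on both the
    burden and the hotspot fraction, and its donors are on average 10 years
    older (70 +/- 5 vs 60 +/- 5 years) and more often smokers.
    """
    return SimulationConfig(
        seed=seed,
        hotspot_weight=0.03,
        burden_mean=4.0,
        age_sd=5.0,
        cohort_multipliers={"high": 3.0, "low": 1.0},
        age_means={"high": 70.0, "low": 60.0},
    )


def generate_risk_cohorts(
    config: SimulationConfig, n_high: int = 233, n_low: int = 483
):
    """Draw the full high- vs low-risk study: two cohorts named ``high`` and
    ``low`` sharing hotspot structure and weights (the same tissue), plus a
    clinical table whose risk labels match the cohorts.

    Default cohort sizes (233 high, 483 low) mirror the normal-urothelium
    cohorts the analysis is designed around. Returns
    ``(catalogs, clinical, truths)`` where ``catalogs`` and ``truths`` are
    dicts keyed by label.
    """
    cat_high, truth_high = generate_cohort(config, "high", n_high)
    cat_low, truth_low = generate_cohort(
        config, "low", n_low, hotspot_weights=truth_high.hotspot_weights
    )
    labels = {s: "high" for s in cat_high.roster}
    labels.update({s: "low" for s in cat_low.roster})
    clinical = generate_clinical(config, labels)
    return (
        {"high": cat_high, "low": cat_low},
        clinical,
        {"high": truth_high, "low": truth_low},
    )
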