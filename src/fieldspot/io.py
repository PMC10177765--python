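"""Readers, writers and containers for mutation catalogs, genomic regions and
clinical covariates.

Coordinate conventions (all conversion is isolated here):

* mutation positions are 1-based genomic coordinates (mutation-table convention);
* regions are 0-based half-open intervals (BED convention);
* a 1-based position ``p`` lies inside BED interval ``[start, end)`` iff
  ``start < p <= end``.

Chromosome names are normalized at ingest by stripping a leading ``chr``
prefix, so catalogs and region sets using either convention interoperate.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "FormatError",
    "MutationRecord",
    "MutationCatalog",
    "Region",
    "RegionSet",
    "ClinicalTable",
    "normalize_chrom",
    "read_mutations",
    "write_mutations",
    "read_regions",
    "write_regions",
    "restrict_to_regions",
    "write_panel",
    "read_clinical",
]

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

#: column mapping for MAF-style mutation tables
MAF_COLUMNS = {
    "sample_id": "Tumor_Sample_Barcode",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "gene": "Hugo_Symbol",
}

SIMPLE_COLUMNS = {
    "sample_id": "sample",
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "gene": "gene",
}


class FormatError(ValueError):
    """An input file does not conform to its declared dialect."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix so naming conventions match."""
    if chrom[:3].lower() == "chr":
        return chrom[3:]
    return chrom


@dataclass(frozen=True)
class MutationRecord:
    """A single somatic single-nucleotide variant call."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ (both {self.ref!r})")


@dataclass
class MutationCatalog:
    """A cohort's somatic SNV records plus the cohort's sample roster.

    ``sample_ids`` may be set explicitly (e.g. from a clinical table) so that
    samples carrying zero mutations still count toward per-sample averages;
    when unset the roster is the distinct sample ids observed in ``records``
    in order of first appearance.
    """

    records: list[MutationRecord] = field(default_factory=list)
    cohort_name: str = ""
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.sample_ids is not None:
            roster = set(self.sample_ids)
            observed = {r.sample_id for r in self.records}
            missing = observed - roster
            if missing:
                raise ValueError(
                    f"{len(missing)} record sample ids missing from roster, "
                    f"e.g. {sorted(missing)[:3]}"
                )

    @property
    def observed_sample_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.sample_id, None)
        return tuple(seen)

    @property
    def roster(self) -> tuple[str, ...]:
        return self.sample_ids if self.sample_ids is not None else self.observed_sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.roster)

    def with_samples(self, sample_ids: Iterable[str]) -> "MutationCatalog":
        """Return a copy carrying an explicit sample roster."""
        return replace(self, sample_ids=tuple(sample_ids))

    def deduplicated(self) -> "MutationCatalog":
        """Drop exact duplicate records (same sample, site and alleles).

        Duplicates are retained at ingest; merged multi-source cohorts can
        opt in to deduplication explicitly.
        """
        seen: set[tuple] = set()
        out = []
        for r in self.records:
            key = (r.sample_id, r.chrom, r.pos, r.ref, r.alt)
            if key not in seen:
                seen.add(key)
                out.append(r)
        return replace(self, records=out)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Region:
    """A target interval (e.g. an exon) in BED coordinates, 0-based half-open."""

    chrom: str
    start: int
    end: int
    gene: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos: int) -> bool:
        """Whether 1-based position ``pos`` lies inside this region."""
        return self.start < pos <= self.end


class RegionSet:
    """A collection of target regions (a sequencing footprint), point-queryable."""

    def __init__(self, regions: Iterable[Region], name: str = ""):
        self.regions: list[Region] = list(regions)
        self.name = name
        self._trees: dict[str, IntervalTree] | None = None

    def _build(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for r in self.regions:
                trees.setdefault(normalize_chrom(r.chrom), IntervalTree()).addi(
                    r.start, r.end, r
                )
            self._trees = trees
        return self._trees

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether 1-based ``pos`` falls inside any region on ``chrom``."""
        tree = self._build().get(normalize_chrom(chrom))
        return bool(tree is not None and tree[pos - 1])

    def regions_at(self, chrom: str, pos: int) -> list[Region]:
        tree = self._build().get(normalize_chrom(chrom))
        if tree is None:
            return []
        return [iv.data for iv in sorted(tree[pos - 1])]

    def merged(self) -> "RegionSet":
        """Merge overlapping/adjacent intervals per chromosome."""
        out: list[Region] = []
        for chrom, tree in sorted(self._build().items()):
            t = tree.copy()
            t.merge_overlaps(strict=False)
            for iv in sorted(t):
                out.append(Region(chrom, iv.begin, iv.end))
        return RegionSet(out, name=self.name)

    @property
    def total_width(self) -> int:
        """Total merged width in bp."""
        return sum(r.width for r in self.merged())


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates keyed by sample id.

    Columns: ``risk_label`` in {high, low}, ``age`` (years), ``sex`` in
    {male, female}, ``smoking`` in {never, former, current, unknown}.
    """

    data: pd.DataFrame

    VALID_LABELS = frozenset({"high", "low"})
    VALID_SEX = frozenset({"male", "female"})
    VALID_SMOKING = frozenset({"never", "former", "current", "unknown"})

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "sample_id":
            if "sample_id" not in df.columns:
                raise FormatError("clinical table needs a sample_id column")
            df = df.set_index("sample_id")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample_id in clinical table: {dupes[:3]}")
        for col in ("risk_label", "age", "sex", "smoking"):
            if col not in df.columns:
                raise FormatError(f"clinical table missing required column: {col}")
        bad = set(df["risk_label"].dropna()) - self.VALID_LABELS
        if bad:
            raise FormatError(f"invalid risk_label values: {sorted(bad)}")
        ages = df["age"].dropna()
        if (ages <= 0).any():
            raise FormatError("age must be > 0 when present")
        self.data = df

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    def labels(self) -> pd.Series:
        return self.data["risk_label"]

    def write(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.data.reset_index().to_csv(fh, index=False)


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, comment="#")
    return ClinicalTable(df)


# ---------------------------------------------------------------------------
# mutation tables


def read_mutations(
    path: str | Path,
    dialect: str = "simple-tsv",
    cohort_name: str | None = None,
) -> MutationCatalog:
    """Read a tab-delimited mutation table into a :class:`MutationCatalog`.

    Non-SNV rows (indels, multi-base substitutions, identical ref/alt) are
    dropped with a logged count. ``dialect`` is ``"simple-tsv"``
    (sample, chrom, pos, ref, alt[, gene]) or ``"maf-like"`` (MAF column names).
    """
    path = Path(path)
    if dialect == "maf-like":
        colmap = MAF_COLUMNS
    elif dialect == "simple-tsv":
        colmap = SIMPLE_COLUMNS
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    name = cohort_name if cohort_name is not None else path.stem
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        logger.warning("empty mutation table: %s", path)
        return MutationCatalog(records=[], cohort_name=name)

    required = [colmap[k] for k in ("sample_id", "chrom", "pos", "ref", "alt")]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    gene_col = colmap["gene"] if colmap["gene"] in df.columns else None

    records: list[MutationRecord] = []
    dropped = 0
    for row in df.itertuples(index=False):
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        ref = str(r[colmap["ref"]]).upper()
        alt = str(r[colmap["alt"]]).upper()
        if ref not in _BASES or alt not in _BASES or ref == alt:
            dropped += 1
            continue
        gene = str(r[gene_col]) if gene_col and pd.notna(r[gene_col]) else ""
        records.append(
            MutationRecord(
                sample_id=str(r[colmap["sample_id"]]),
                chrom=normalize_chrom(str(r[colmap["chrom"]])),
                pos=int(r[colmap["pos"]]),
                ref=ref,
                alt=alt,
                gene=gene,
            )
        )
    if dropped:
        logger.info("dropped %d non-SNV rows from %s", dropped, path)
    return MutationCatalog(records=records, cohort_name=name)


def write_mutations(
    catalog: MutationCatalog, path: str | Path, header_comment: str | None = None
) -> None:
    """Write a catalog in the simple-tsv dialect (round-trips with read_mutations)."""
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample", "chrom", "pos", "ref", "alt", "gene"])
        for r in catalog.records:
            w.writerow([r.sample_id, r.chrom, r.pos, r.ref, r.alt, r.gene])


# ---------------------------------------------------------------------------
# BED regions


def read_regions(path: str | Path, name: str | None = None) -> RegionSet:
    """Read a BED file (0-based half-open; >=3 columns, optional 4th = gene)."""
    path = Path(path)
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line needs >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start ({start}) must be < end ({end})"
                )
            gene = fields[3] if len(fields) > 3 else ""
            regions.append(Region(chrom=chrom, start=start, end=end, gene=gene, label=gene))
    return RegionSet(regions, name=name if name is not None else path.stem)


def write_regions(
    regions: RegionSet, path: str | Path, header_comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\n")


def restrict_to_regions(catalog: MutationCatalog, footprint: RegionSet) -> MutationCatalog:
    """Keep only records whose position falls inside the footprint.

    The sample roster is preserved: samples whose mutations all fall outside
    the footprint drop to zero records but still count toward ``n_samples``.
    """
    roster = catalog.roster
    kept = [r for r in catalog.records if footprint.contains(r.chrom, r.pos)]
    n_dropped = len(catalog.records) - len(kept)
    if n_dropped:
        logger.info(
            "restrict_to_regions: dropped %d/%d records outside footprint %s",
            n_dropped, len(catalog.records), footprint.name,
        )
    return MutationCatalog(records=kept, cohort_name=catalog.cohort_name, sample_ids=roster)


def write_panel(panel, path: str | Path, header_comment: str | None = None) -> None:
    """Write a window panel as BED: chrom, 0-based start, exclusive end,
    name ``gene:rank``, score = capture count.

    Windows use 1-based inclusive coordinates internally, so a window
    ``[s, e]`` becomes the BED interval ``[s-1, e)``.
    """
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for w in panel.windows:
            name = f"{w.gene or 'NA'}:{w.rank}"
            fh.write(f"{w.chrom}\t{w.start - 1}\t{w.end}\t{name}\t{w.capture_count}\n")
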