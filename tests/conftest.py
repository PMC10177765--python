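import dataclasses

import numpy as np
import pytest

import fieldspot as fs


@pytest.fixture
def toy_catalog():
    """Four mutations on one chromosome at positions 1, 50, 120, 500."""
    recs = [
        fs.MutationRecord("s1", "1", 1, "A", "T", "GENEA"),
        fs.MutationRecord("s1", "1", 50, "C", "G", "GENEA"),
        fs.MutationRecord("s2", "1", 120, "G", "A", "GENEA"),
        fs.MutationRecord("s2", "1", 500, "T", "C", "GENEB"),
    ]
    return fs.MutationCatalog(records=recs, cohort_name="toy")


@pytest.fixture
def small_footprint():
    return fs.RegionSet(
        [
            fs.Region("1", 0, 1000, gene="GENEA"),
            fs.Region("1", 2000, 3000, gene="GENEB"),
            fs.Region("2", 0, 500, gene="GENEC"),
        ],
        name="small",
    )


def random_catalog(rng, n_records, span=2000, n_samples=4, chroms=("1",)):
    """A random catalog for property tests."""
    recs = []
    for _ in range(n_records):
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        recs.append(
            fs.MutationRecord(
                sample_id=f"s{rng.integers(n_samples) + 1}",
                chrom=str(rng.choice(chroms)),
                pos=int(rng.integers(1, span + 1)),
                ref=str(ref),
                alt=str(alt),
            )
        )
    return fs.MutationCatalog(records=recs, cohort_name="random")


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter synthetic cohort (200 samples) with ground truth,
    shared across tests to keep the suite fast."""
    cfg = fs.SimulationConfig(seed=0)
    catalog, truth = fs.generate_cohort(cfg, "tumor", 200)
    return cfg, catalog, truth


def panel_from_windows(windows, name="panel"):
    ranked = [dataclasses.replace(w, rank=i + 1) for i, w in enumerate(windows)]
    return fs.WindowPanel(name=name, windows=ranked)
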