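import numpy as np
import pandas as pd
import pytest

from circaging import phenotype, quantify, synthetic


def make_junction_table(rows):
    """rows: (circ_id, host_gene, library_id, j, c)."""
    return pd.DataFrame(
        [
            {
                "circ_id": circ,
                "host_gene": gene,
                "chrom": "chr1",
                "junction_start": 100,
                "junction_end": 500,
                "library_id": lib,
                "bsj_reads": j,
                "canonical_reads": c,
            }
            for circ, gene, lib, j, c in rows
        ]
    )


@pytest.fixture
def two_circ_table():
    return make_junction_table(
        [("circA", "G1", "lib1", 5, 80), ("circB", "G2", "lib1", 15, 100)]
    )


@pytest.fixture(scope="session")
def small_pool():
    cfg = synthetic.PoolSimConfig(
        n_circ_total=60,
        n_shared=20,
        n_young_only=20,
        n_old_only=20,
        mean_bsj_reads=100.0,
        rnase_r_circ_enrichment=5.0,
        seed=11,
    )
    table, truth = synthetic.simulate_pool_counts(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def small_pool_profiles(small_pool):
    _, table, _ = small_pool
    return quantify.compute_bpm_all(table)


def make_cohort(rows):
    """rows: dicts overriding a complete default record."""
    default = {
        "participant_id": None,
        "age": 70.0,
        "sex": "female",
        "bmi": 27.0,
        "education": "elementary",
        "site": "Greve",
        "smoking": "none",
        "neutrophil_pct": 55.0,
        "lymphocyte_pct": 30.0,
        "monocyte_pct": 8.0,
        "eosinophil_pct": 3.0,
        "mother_death_age": np.nan,
        "father_death_age": np.nan,
        "grip_fu3": 30.0,
        "grip_fu4": 29.0,
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(default)
        rec["participant_id"] = f"P{i:03d}"
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out, columns=phenotype.COHORT_COLUMNS)
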