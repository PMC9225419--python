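import numpy as np
import pandas as pd
import pytest

from microsev.io import (
    HLA_COLUMNS,
    RANKS,
    TITER_COLUMNS,
    CountTable,
    SampleMetadata,
    TaxonomyTable,
)
from microsev.synthetic import SyntheticCohortSpec, default_paper_like_spec, generate


def make_metadata(groups, batches=None, seed=0):
    """Metadata frame with filled-in HLA flags and titers for anti-Ro rows."""
    rng = np.random.default_rng(seed)
    n = len(groups)
    sids = [f"s{i + 1:03d}" for i in range(n)]
    if batches is None:
        batches = [f"b{(i % 2) + 1}" for i in range(n)]
    df = pd.DataFrame({"group": list(groups), "batch": list(batches)}, index=sids)
    is_ro = df["group"] != "HC"
    for c in HLA_COLUMNS:
        df[c] = np.where(is_ro, (rng.random(n) < 0.4).astype(float), np.nan)
    for c in TITER_COLUMNS:
        df[c] = np.where(is_ro, rng.gamma(5.0, 2.0, n), np.nan)
    return SampleMetadata(df)


@pytest.fixture
def tiny_counts():
    return CountTable(
        pd.DataFrame(
            [[5, 0, 3, 2], [1, 2, 0, 7], [0, 7, 4, 1]],
            index=["s1", "s2", "s3"],
            columns=["t1", "t2", "t3", "t4"],
        )
    )


@pytest.fixture
def tiny_taxonomy():
    rows = {
        "t1": ["Bacteria", "P1", "C1", "O1", "F1", "G1", "S1"],
        "t2": ["Bacteria", "P1", "C1", "O1", "F1", "G1", "S2"],
        "t3": ["Bacteria", "P2", "C2", "O2", "F2", "G2", "S3"],
        "t4": ["Bacteria", "P2", "C2", "O2", "F2", "", ""],
    }
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)))


@pytest.fixture(scope="session")
def paper_cohort():
    """One realization of the study-scale synthetic cohort."""
    return generate(default_paper_like_spec(seed=7))


def random_count_table(rng, n_samples=None, n_taxa=None, max_count=50):
    ns = n_samples or int(rng.integers(2, 12))
    nt = n_taxa or int(rng.integers(2, 15))
    m = rng.integers(0, max_count, size=(ns, nt))
    # guarantee no all-zero sample
    m[:, 0] = np.maximum(m[:, 0], 1)
    return CountTable(
        pd.DataFrame(
            m,
            index=[f"s{i}" for i in range(ns)],
            columns=[f"t{j}" for j in range(nt)],
        )
    )


def interaction_spec(seed, log_or=0.5, titer_slopes=None):
    """Small, well-specified cohort for interaction-estimator checks: 20
    single-species genera of comparable abundance, 125 anti-Ro mothers."""
    tm = {}
    if titer_slopes is not None:
        tm["ro52_iga"] = {
            "intercept": 10.0, "group_effect": 0.0, "noise_sd": 1.0,
            "interactions": [("G001", *titer_slopes)],
        }
    return SyntheticCohortSpec(
        n_per_group=(2, 43, 82),
        n_taxa_species=20,
        taxonomy_shape={"phylum": 2, "class": 3, "order": 4, "family": 8,
                        "genus": 20},
        base_logsd=0.5,
        hla_carrier_freq={"hla_drb1_0301": 0.5, "hla_drb1_1501": 0.5,
                          "hla_dqb1_0201": 0.5, "hla_dqb1_0602": 0.5},
        planted_hla_interaction=(
            [("G001", "hla_drb1_0301", log_or)] if log_or is not None else []
        ),
        titer_model=tm,
        seed=seed,
    )
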