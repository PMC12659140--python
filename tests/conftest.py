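import numpy as np
import pandas as pd
import pytest

import regiscan as rs
from regiscan.cohort import add_followup


@pytest.fixture(scope="session")
def icd_tree():
    return rs.load_toy_tree("ICD10")


@pytest.fixture(scope="session")
def atc_tree():
    return rs.load_toy_tree("ATC")


@pytest.fixture(scope="session")
def small_cohort():
    """A matched 100:500 cohort with follow-up columns, fixed seed."""
    pool = rs.simulate_cohort(100, 5, rs.HazardConfig(), seed=41)
    matched = rs.match_children(
        pool[pool["exposure"]], pool[~pool["exposure"]], ratio=5, seed=42
    )
    return add_followup(matched.children)


@pytest.fixture(scope="session")
def small_events(small_cohort, icd_tree):
    return rs.simulate_events(small_cohort, icd_tree, rs.HazardConfig(), seed=43)


def toy_chain_table():
    """root -> A -> A0 dictionary table."""
    return pd.DataFrame(
        {
            "code": ["root", "A", "A0"],
            "parent": ["", "root", "A"],
            "label": ["r", "a", "a0"],
            "level": ["root", "chapter", "block"],
        }
    )


def balanced_icd_table():
    """2 chapters x 2 blocks x 2 categories: 15 nodes, 14 non-root."""
    rows = [("root", "", "root")]
    for ch in ("C1", "C2"):
        rows.append((ch, "root", "chapter"))
        for b in ("a", "b"):
            block = f"{ch}{b}"
            rows.append((block, ch, "block"))
            for c in ("1", "2"):
                rows.append((f"{block}{c}", block, "category"))
    return pd.DataFrame(
        [(c, p, "", lvl) for c, p, lvl in rows],
        columns=["code", "parent", "label", "level"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
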