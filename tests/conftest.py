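"""Shared fixtures: a cascade fixture cohort built by construction.

The ``table8_fixture`` reproduces, by construction, the margins of the
study-style cascade evaluation on 114 fibrosis-evaluable subjects:
51 stage-1 rule-outs (44 with a non-severe elastography reference),
21 stage-1 rule-ins (17 severe), 42 grey-zone subjects of whom stage 2
classifies 12 (5 ruled in / 7 ruled out, 9 correct in total).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


def build_table8_cohort() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (panels, reference) for the 114-subject cascade fixture."""
    rows = []
    refs = []

    def add(n, nfs, fib4, tyg, vai, severe):
        for _ in range(n):
            i = len(rows)
            rows.append(
                dict(subject_id=f"P{i:03d}", nfs=nfs, fib4=fib4, tyg=tyg, vai=vai)
            )
            refs.append(dict(subject_id=f"P{i:03d}", severe_fibrosis=severe))

    # stage-1 rule-out: NFS <= -1.455 and FIB-4 <= 1.3 (44 correct, 7 not)
    add(44, -2.0, 1.0, 4.0, 3.0, False)
    add(7, -2.0, 1.0, 4.0, 3.0, True)
    # stage-1 rule-in: NFS > 0.676 and FIB-4 > 2.67 (17 correct, 4 not)
    add(17, 1.0, 3.0, 4.0, 3.0, True)
    add(4, 1.0, 3.0, 4.0, 3.0, False)
    # grey zone, stage-2 ruled in via TyG > 5.61 and VAI > 6.21 (4 correct)
    add(4, 0.0, 2.0, 6.0, 7.0, True)
    add(1, 0.0, 2.0, 6.0, 7.0, False)
    # grey zone, stage-2 ruled out via TyG <= 2.65 and VAI <= 1.67 (5 correct)
    add(5, 0.0, 2.0, 2.0, 1.0, False)
    add(2, 0.0, 2.0, 2.0, 1.0, True)
    # grey zone, still unclassified after stage 2
    add(18, 0.0, 2.0, 4.0, 3.0, False)
    add(12, 0.0, 2.0, 4.0, 3.0, True)

    panels = pd.DataFrame(rows)
    reference = pd.DataFrame(refs)
    assert len(panels) == 114
    return panels, reference


@pytest.fixture(scope="session")
def table8_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    return build_table8_cohort()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250926)
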