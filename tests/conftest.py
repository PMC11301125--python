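"""Shared fixtures: small deterministic datasets and the replicated study fits.

The session-scoped fixtures at the bottom run the expensive simulation
study (12 fixed-seed replicates at the published group sizes) once and
share the fits between the recovery and DIF-detection tests.
"""

import numpy as np
import pandas as pd
import pytest

from audcheck import (DIFDetector, ItemBank, MultigroupTwoPL, ResponseMatrix,
                      TwoParameterLogistic, simulate, study)


def toy_matrix(rows, item_ids=("i1", "i2", "i3"), patients=None, groups=None):
    """Build a small ResponseMatrix from a list of response tuples (None = missing)."""
    n = len(rows)
    patients = patients or [f"p{i}" for i in range(n)]
    groups = groups or ["clinic"] * n
    frame = pd.DataFrame(
        [[pd.NA if v is None else v for v in row] for row in rows],
        columns=list(item_ids),
    ).astype("Int8")
    return ResponseMatrix(np.array(patients, object), np.array(groups, object), frame)


@pytest.fixture
def three_item_bank():
    return ItemBank.from_reference(
        ["i1", "i2", "i3"], [1.2, 2.0, 2.8], [-0.5, 0.3, 1.1],
        anchors=["i1"], reference_group="clinic", focal_group="online",
    )


@pytest.fixture(scope="session")
def study_bank():
    return study.checklist_item_bank()


def simulate_clean_study(seed):
    cfg = simulate.study_config(seed=seed, missing_rate=0.0, duplicate_rate=0.0)
    data, theta = simulate.simulate_study(cfg)
    return data, theta


@pytest.fixture(scope="session")
def study_draw():
    """One clean draw at the published group sizes."""
    data, theta = simulate_clean_study(seed=1)
    return data, theta


@pytest.fixture(scope="session")
def multigroup_replicates():
    """12 fixed-seed draws with the published-pattern multigroup fit on each."""
    reps = []
    for seed in study.REPLICATION_SEEDS:
        data, _ = simulate_clean_study(seed)
        fit = MultigroupTwoPL(
            reference_group=study.REFERENCE_GROUP,
            anchors=study.ANCHOR_ITEMS,
            free_a=list(study.FOCAL_A_OVERRIDES),
            free_b=list(study.FOCAL_B_OVERRIDES),
        ).fit(data).result_
        reps.append({"seed": seed, "data": data, "fit": fit})
    return reps


@pytest.fixture(scope="session")
def detection_replicates(multigroup_replicates):
    """Full anchored DIF detection on each of the 12 replicate draws."""
    out = []
    for rep in multigroup_replicates:
        det = DIFDetector(
            anchors=study.ANCHOR_ITEMS, reference_group=study.REFERENCE_GROUP
        ).fit(rep["data"])
        out.append({"seed": rep["seed"], "report": det.report_})
    return out


NULL_BANK = ItemBank.from_reference(
    ["i1", "i2", "i3", "i4", "i5"],
    [1.5, 2.2, 1.8, 2.6, 1.2],
    [-0.8, 0.0, 0.5, 1.0, 1.5],
    reference_group="clinic", focal_group="online",
)


def null_draw(n_per_group, seed, bank=NULL_BANK):
    """Two groups simulated from one shared bank: no DIF anywhere."""
    rng = np.random.default_rng(seed)
    theta = rng.normal(0, 1, 2 * n_per_group)
    groups = np.array(["clinic"] * n_per_group + ["online"] * n_per_group, object)
    return simulate.simulate_responses(theta, groups, bank, seed + 1)


#: moderate discriminations keep the small-sample MLE away from the a -> inf
#: boundary, where the chi-square asymptotics of the LR test would not apply
CALIBRATION_BANK = ItemBank.from_reference(
    ["i1", "i2", "i3", "i4", "i5"],
    [1.3, 1.8, 1.5, 2.0, 1.1],
    [-0.8, 0.0, 0.5, 1.0, 1.4],
    reference_group="clinic", focal_group="online",
)


@pytest.fixture(scope="session")
def null_joint_tests():
    """200 no-DIF replicates: joint 2-df LR test of one item at reduced n."""
    from audcheck import lr_test_item

    out = []
    for rep in range(200):
        data = null_draw(200, seed=5_000 + 2 * rep, bank=CALIBRATION_BANK)
        out.append(
            lr_test_item(data, "i3", anchors=("i1", "i2"),
                         reference_group="clinic", localize=False)
        )
    return out


@pytest.fixture(scope="session")
def single_group_replicates():
    """12 reference-group-only draws with a single-group fit on each."""
    bank = study.checklist_item_bank()
    reps = []
    for seed in study.REPLICATION_SEEDS:
        rng_seed = 10_000 + seed
        rng = np.random.default_rng(rng_seed)
        n = study.N_PER_GROUP[study.REFERENCE_GROUP]
        theta = rng.normal(0.0, 1.0, n)
        groups = np.full(n, study.REFERENCE_GROUP, object)
        data = simulate.simulate_responses(theta, groups, bank, seed=20_000 + seed)
        model = TwoParameterLogistic().fit(data)
        reps.append({"seed": seed, "model": model})
    return reps
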