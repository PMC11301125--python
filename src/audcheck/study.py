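"""Published configuration of the two-modality Alcohol Symptom Checklist study.

The checklist asks patients eleven yes/no questions mirroring the DSM-5
alcohol use disorder criteria.  The study compared its measurement behaviour
between in-clinic (paper) and online patient-portal administration using a
multiple-group two-parameter logistic IRT model.  This module embeds the
published final item parameters, anchor set, latent moments of the online
group, and the analysed group sizes, so that the whole analysis can be
replayed on synthetic data with one call.

Parameter conventions: logistic metric without the 1.7 scaling constant,
reference group (in clinic) latent trait fixed at N(0, 1).  Items whose
parameters did not differ significantly between modalities are shared
(equality-constrained); items 1, 3 and 4 have an online-specific severity b,
and item 9 has both an online-specific discrimination a and severity b.
Items 5, 6 and 7 were the anchors.
"""

from __future__ import annotations

from .io import ItemBank, LatentDistribution

#: canonical item order of the 11-item checklist
ITEM_IDS: tuple[str, ...] = (
    "tolerance",
    "withdrawal",
    "larger_longer",
    "quit_control",
    "time_spent",
    "physical_psychological",
    "neglect_roles",
    "hazardous_use",
    "social_interpersonal",
    "craving",
    "activities_given_up",
)

#: display labels in checklist order
ITEM_LABELS: dict[str, str] = {
    "tolerance": "1. Tolerance",
    "withdrawal": "2. Withdrawal",
    "larger_longer": "3. Larger/longer",
    "quit_control": "4. Quit/control",
    "time_spent": "5. Time spent",
    "physical_psychological": "6. Physical/psychological problems",
    "neglect_roles": "7. Neglect roles",
    "hazardous_use": "8. Hazardous use",
    "social_interpersonal": "9. Social/interpersonal problems",
    "craving": "10. Craving",
    "activities_given_up": "11. Activities given up",
}

REFERENCE_GROUP = "in_clinic"
FOCAL_GROUP = "online"

#: analysed sample sizes after exclusions
N_PER_GROUP: dict[str, int] = {REFERENCE_GROUP: 1603, FOCAL_GROUP: 1640}

#: anchor items (assumed DIF-free, identify the common latent metric)
ANCHOR_ITEMS: tuple[str, ...] = (
    "time_spent",
    "physical_psychological",
    "neglect_roles",
)

#: reference-group (in clinic) discrimination and severity, checklist order
A_REFERENCE: tuple[float, ...] = (1.46, 2.19, 2.18, 2.68, 2.8, 2.74, 3.26, 1.54, 3.08, 2.51, 3.51)
B_REFERENCE: tuple[float, ...] = (0.99, 1.25, 0.52, 0.73, 0.84, 0.44, 1.29, 1.86, 0.81, 0.68, 1.0)

#: online-group overrides for the parameters that showed DIF
FOCAL_A_OVERRIDES: dict[str, float] = {"social_interpersonal": 2.65}
FOCAL_B_OVERRIDES: dict[str, float] = {
    "tolerance": 0.81,
    "larger_longer": 0.28,
    "quit_control": 0.87,
    "social_interpersonal": 1.07,
}

#: estimated latent moments of the online group (reference fixed at 0, 1)
FOCAL_MEAN = -0.05
FOCAL_VARIANCE = 0.90

#: per-item family-wise error rate convention: 0.05 Bonferroni-split over 11 items
FAMILYWISE_ALPHA = 0.05

#: fixed seeds for the 12-replicate simulation study
REPLICATION_SEEDS: tuple[int, ...] = tuple(range(1, 13))


def checklist_item_bank() -> ItemBank:
    """The published final item bank (both groups, constraints, anchors)."""
    return ItemBank.from_reference(
        ITEM_IDS,
        A_REFERENCE,
        B_REFERENCE,
        focal_a=FOCAL_A_OVERRIDES,
        focal_b=FOCAL_B_OVERRIDES,
        anchors=ANCHOR_ITEMS,
        reference_group=REFERENCE_GROUP,
        focal_group=FOCAL_GROUP,
    )


def checklist_latent() -> LatentDistribution:
    """The published latent moments: in clinic N(0, 1), online N(-0.05, 0.90)."""
    return LatentDistribution(
        means={REFERENCE_GROUP: 0.0, FOCAL_GROUP: FOCAL_MEAN},
        variances={REFERENCE_GROUP: 1.0, FOCAL_GROUP: FOCAL_VARIANCE},
        reference_group=REFERENCE_GROUP,
    )
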