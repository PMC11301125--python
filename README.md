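# audcheck

Measurement-equivalence analysis for the 11-item Alcohol Symptom Checklist —
the yes/no questionnaire mirroring the DSM-5 alcohol use disorder (AUD)
criteria that primary-care patients complete either **online** (through a
patient portal) or **in clinic** (on paper). The package asks the
psychometric question behind that workflow choice: *does the checklist
measure the same thing in both modalities?* It is written for biostatisticians
and health-services researchers who want a tested, reproducible pipeline for
two-group item response theory (IRT) analyses of short dichotomous symptom
checklists.

## What it computes

**Model.** Responses follow a two-parameter logistic (2PL) IRT model: a
respondent with latent AUD severity θ endorses item *j* in group *g* with
probability

    P(y_ij = 1 | θ) = 1 / (1 + exp(−a_jg (θ − b_jg)))

where *a* is the item's discrimination and *b* its severity location
(logistic metric, no 1.7 constant). The latent trait is standard normal in
the reference (in-clinic) group; the focal (online) group's latent mean and
variance are estimated. Item parameters are estimated by marginal maximum
likelihood via Bock–Aitkin EM with equally spaced quadrature.

**Differential item functioning (DIF).** Anchor items pin the common latent
metric; every other item is tested by likelihood-ratio against the current
constrained model, parameters of the most significant item are freed, and
remaining items are re-tested until nothing reaches the Bonferroni-corrected
per-item level α = 0.05/11 ≈ .0045. The default scheme tests each parameter
with separate 1-df tests; a joint 2-df scheme is also available.

**DIF impact.** Expected test score per group, T_g(θ) = Σ_j P_jg(θ), the
model-implied number of criteria endorsed. The maximum over θ of
|T_focal − T_reference| summarises how much DIF can move the total score
clinicians act on.

**Severity scoring.** Criteria counts and DSM-5 grades (0–1 no AUD, 2–3
mild, 4–5 moderate, 6–11 severe) with unadjusted per-group tabulations.

**Synthetic data.** Because the motivating study used protected EHR data,
`audcheck.simulate` draws realistic two-group response matrices from the
published configuration (1603 in-clinic and 1640 online respondents, focal
latent N(−0.05, 0.90), published item bank), with optional missing-item and
duplicate-checklist contamination to exercise the filtering rules.

## Worked example

The deterministic headline — how much can DIF move a total score — straight
from the embedded published item bank:

```python
import audcheck as ac
from audcheck import study

curve = ac.impact_curve(study.checklist_item_bank())
print(round(curve.max_abs_difference, 4), round(curve.argmax_theta, 2))
# 0.1287 1.11
print(round(curve.weighted_mean_abs_difference(study.checklist_latent()), 4))
# 0.0632
```

A patient at the same latent severity is expected to endorse at most **0.13
criteria** more (or fewer) out of 11 depending on modality, with the largest
gap at θ ≈ 1.11; averaged over where online respondents actually sit on the
latent scale the gap is only 0.06 criteria. On the 0–11 scale used for
diagnosis this is negligible.

The full simulate-and-detect loop (about 20 s):

```python
data, _ = ac.simulate_study(ac.study_config(seed=1, missing_rate=0, duplicate_rate=0))
det = ac.DIFDetector(anchors=study.ANCHOR_ITEMS,
                     reference_group=study.REFERENCE_GROUP).fit(data)
print(det.flagged_items_)
# ('tolerance', 'larger_longer', 'quit_control', 'social_interpersonal')
```

On this draw the procedure recovers exactly the four items that carried DIF
in the generating bank. Re-detection is stochastic: items whose generating
effects sit near the significance boundary are flagged in only some
replicates (see `docs/methods.md`).

The same stages are available from the shell:

```bash
audcheck simulate --out sim.csv --seed 1
audcheck dif --responses sim.csv --reference in_clinic \
    --anchors time_spent,physical_psychological,neglect_roles --out-dir reports/
audcheck replicate-paper --out-dir replica/ --skip-simulations
# max |difference| = 0.1287 criteria
```

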