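# syncopedx

Likelihood-ratio Bayesian differential diagnosis and risk stratification
for transient loss of consciousness (TLOC), built for emergency-department
decision support.

Syncope is common, usually benign, and routinely over-tested: most
patients are asymptomatic at presentation, and the fear of missing a
cardiac cause drives unnecessary admissions. `syncopedx` implements the
evidence-based pipeline a bedside tool needs: a ranked differential over
four etiologies — vasovagal, orthostatic, cardiogenic, and neurogenic
loss of consciousness (e.g. seizure, the highest-risk non-syncopal
mimic) — followed by Canadian Syncope Score (CSS) risk stratification and
a structured recommendation bundle.

## The model

Each etiology *E* is an independent binary model. Evidence from the
twenty yes/no assessment questions accumulates on the log-odds scale via
published likelihood ratios:

```
logit(p_post) = logit(p_pre) + Σ_q ln(LHR_q)
```

where `LHR_q` is the question's positive likelihood ratio
(sensitivity / (1 − specificity)) if answered yes, its negative
likelihood ratio ((1 − sensitivity) / specificity) if answered no, and 1
(no contribution) if unanswered or if the (question, etiology) cell has
no published ratio. `p_pre` is the etiology's population prevalence. The
four posteriors are ranked raw — never renormalized — because the models
are independent.

Two etiologies (orthostatic, neurogenic LOC) lack usable literature
ratios; each has two flagged questions, and a unanimous *yes* promotes
that etiology to the top of the differential without altering any
probability. A partial *yes* instead emits a question-specific
recommendation (e.g. volume loading for positive orthostatic vitals even
when the leading differential is cardiogenic).

The CSS is an additive point score over seven answer-derived items (ECG
findings, troponin, blood pressure, cardiac history, vasovagal
predisposition) plus two diagnosis-derived items; the total maps to low
(<1), intermediate (1–3), or high (>3) risk, each with a disposition:
discharge with outpatient workup, observation of 6 hours or less, or
longer observation and admission.

All content — questions, LHR pairs, priors, CSS weights, cut points, and
recommendation prose — lives in a declarative JSON knowledge base
(`kb.schema.json`); the packaged default ships the curated
twenty-question table.

## Worked example

```python
from syncopedx import (AnswerSet, AnswerValue, Etiology,
                       assess_case, load_knowledge_base)

kb = load_knowledge_base()
answers = AnswerSet(
    {"heart_disease_history": AnswerValue.YES,
     "chest_pain": AnswerValue.YES,
     "exertion": AnswerValue.YES,
     "trigger_context": AnswerValue.NO,
     "troponin_elevated": AnswerValue.YES},
    user_selected_ddx=Etiology.CARDIOGENIC,
)
a = assess_case(answers, kb)
for p in a.differential:
    print(f"{p.etiology.value:<14} {p.probability:.4f}")
print(a.css.total, a.css.risk_class.value)
```

prints

```
cardiogenic    0.9583
orthostatic    0.1000
neurogenic_loc 0.0500
vasovagal      0.0185
5 high
```

Cardiac history (LHR+ 2.93), chest pain (4.25), exertion (4.36) and
elevated troponin (1.98) multiply the cardiogenic pretest odds
(0.13/0.87) up to a posterior of 0.958, while the absent vasovagal
trigger context (LHR− 0.498) and the cardiac history (vasovagal LHR+
0.072) collapse the vasovagal posterior to 0.019; orthostatic and
neurogenic carry no ratios and stay at their priors. The CSS tallies
cardiac history (+1), troponin (+2), vasovagal predisposition not
triggered (trigger context answered no), and the cardiac diagnosis (+2):
total 5, high risk, i.e. longer-term observation and admission.

The same pipeline is available from the shell:

```bash
syncopedx assess --case case.json --explain
syncopedx simulate --n 100 --seed 7 --out cohort/
syncopedx batch cohort/
syncopedx report evaluations.jsonl --restrict cardiogenic,vasovagal
syncopedx validate-kb my_kb.json
```

## Scope

`syncopedx` is a library and CLI, not a medical device: the packaged
priors and CSS weights are configurable surrogates documented in
`docs/methods.md`, the synthetic cohort generator makes a conditional
independence assumption real findings violate, and nothing here replaces
clinical judgment.
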