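# Methods

## The diagnostic model

`syncopedx` treats each of the four etiologies of transient loss of
consciousness — vasovagal, orthostatic, cardiogenic, neurogenic LOC — as
an *independent* binary model. For etiology *E* with pretest probability
*p₀*, the posttest log-odds after an assessment is

    logit(p) = logit(p₀) + Σ_q x_q ln(LHR⁺_{q,E}) + (1 − x_q) ln(LHR⁻_{q,E})

where the sum runs over answered questions with a defined
(question, etiology) likelihood-ratio cell and *x_q* ∈ {0, 1} encodes
no/yes. This is the standard sequential-testing identity: posttest odds =
pretest odds × ∏ LHR. Three kinds of input contribute a neutral factor
of 1: a question answered `unknown`, a prompt-only question (which by
construction carries no ratios), and an absent cell. The same quantity is
implemented a second time in the regression parameterization — intercept
β₀′ = logit(p₀) + Σ ln(LHR⁻) over answered cells, slope
β_q = ln(LHR⁺/LHR⁻) per yes — purely as an internal cross-check; the test
suite asserts the two forms agree to 1e-10 on random knowledge bases.

Assumptions worth stating plainly:

- **Naive-Bayes evidence combination.** Multiplying LHRs assumes the
  findings are conditionally independent given the etiology. The curated
  question list mitigates this by consolidating collinear variables
  (e.g. the several cardiac-history conditions share one question), but
  residual correlation biases posteriors toward over-confidence.
- **No cross-etiology normalization.** The four posteriors are ranked
  raw and deliberately do not sum to 1; a test asserts the engine never
  renormalizes. The ranking, not the absolute probability, is the
  clinical output.
- **`unknown` is a first-class state.** Clinical data entry is
  progressive; an unanswered question must not silently count as "no".
  With every answer unknown the differential equals the priors exactly
  (pinned to 1e-12).

### Overrides

Orthostatic syncope and neurogenic LOC have no reliable published
likelihood ratios, so their posteriors would otherwise never move off
the prior. Each has two flagged questions; when *all* of an etiology's
flagged questions are answered yes, the etiology is promoted above every
non-promoted one. Promotion changes rank only — probabilities are left
untouched so the display stays honest about what was computed versus
asserted. When several promotions fire simultaneously the fixed risk
precedence applies (neurogenic LOC > cardiogenic > orthostatic >
vasovagal; riskier first). The same precedence breaks exact probability
ties. It is configurable via the knowledge base's `tie_break_order` but
the default should rarely be changed.

A *partial* positive (≥1 but not all flagged questions yes) does not
promote; it emits the question-specific recommendation instead. "At
least one but not all" was chosen over "exactly one" so the rule
composes cleanly with the all-yes override: every positive pattern
triggers exactly one of {promotion, question-specific advice}.

### Numerical choices

- Log-space accumulation in knowledge-base question order gives a
  deterministic summation; permuting the answer map changes nothing
  beyond 1e-12 (and in practice nothing at all, since only KB order is
  iterated).
- The inverse logit is evaluated in its two algebraic forms on either
  side of 0 to avoid overflow; inputs must be finite. Beyond |logit| ≈ 15
  probabilities saturate in double precision, which is far outside the
  clinically reachable range (all twenty LHRs combined move the log-odds
  by at most ~12).
- Priors are validated to the open interval (0, 1); likelihood ratios
  must be finite and strictly positive.

## Knowledge-base content and its provenance

The packaged default transcribes the curated twenty-question assessment:
five vasovagal and eleven cardiogenic LHR cells, seven CSS-input flags,
three prompt-only questions, and the two override pairs, along with the
documented numeric cutoffs (age 35 y, SBP 90/180 mmHg, orthostatic drop
20 mmHg / rise 30 bpm, QRS axis −30/100°, QRS 120 ms, QTc 480 ms,
troponin 14 ng/L). Two content decisions are surrogates and are marked
as such:

- **Priors.** The deployed pretest odds were never published. Defaults
  are the midpoints of the published prevalence ranges for the two
  dominant causes — vasovagal (21–48%) → 0.345, cardiac (5–21%) → 0.13 —
  plus implementer-chosen 0.10 (orthostatic) and 0.05 (neurogenic LOC).
  All four are opaque, overridable inputs to the engine.
- **CSS weights.** The point values come from the CSS derivation study
  (vasovagal predisposition −1, heart-disease history +1, SBP <90/>180
  +2, elevated troponin +2, abnormal QRS axis +1, QRS >120 ms +1,
  QTc >480 ms +2, diagnosis-vasovagal −2, diagnosis-cardiac +2), fully
  overridable. The vasovagal-predisposition item is sourced from the
  trigger-context question, the closest available match; the mapping is
  config-level, not code-level. The single packaged QRS question uses
  the 120 ms cutoff and feeds both the differential display and the CSS
  item, even though the original score used a different cutoff — one
  question, one answer, no hidden second threshold.
- The SBP <90/>180 question is flagged as a CSS input: it is a scored
  item of the original score and the default CSS config requires it,
  giving seven question-sourced items in total.

Risk classes follow the printed cut points: low (<1), intermediate (1–3
inclusive), high (>3); with integer totals "low" is total ≤ 0. Unknown
answers never trigger a CSS item (conservative, fewer points), but the
itemized result keeps untriggered items visible so the clinician can see
what went untallied.

## Recommendations

Primary text follows the working diagnosis — the clinician's selection
when present, else the engine's top etiology (the resolve rule is
user-first by design: the tool is an adjunct, not an arbiter). Secondary
text appears only when the engine's top pick is discordant with the
clinician's selection, keyed by the ordered pair; validation requires
all 12 discordant pairs to have text at load time, so a reachable key
can never be missing at run time. The shipped prose paraphrases the
standard dispositions and routing advice (volume loading for orthostatic
findings, neurologic workup for neurologic red flags); prose is content,
not logic, and is fully overridable.

## Evaluation log and congruence

Completed assessments persist as JSON Lines (`record.schema.json`): the
answers, the engine's top etiology, the user's selection, the CSS total
and class, and the recommendation keys. Anonymity is enforced by schema —
no field exists that could carry an identifier; the record id is a random
token. `append_record` re-runs the engine on the stored answers and
refuses records whose stored results disagree (integrity check). The
congruence report is the fraction of records, among those with a user
selection (optionally restricted by user-selected etiology, and
excluding records flagged hypothetical), whose engine top pick matched
the user. An empty eligible set yields an explicit empty report, never a
division error. A local file store replaces any server backend: the
logged fields are the contract, the hosting is not.

## Synthetic cases

The generator makes end-to-end behaviour testable without clinical data.
For a case with true etiology *E*, each question with an informative,
orientation-consistent cell (LHR⁺ > 1 > LHR⁻) is answered yes with
probability equal to the sensitivity obtained by inverting the pair:

    specificity = (LHR⁺ − 1) / (LHR⁺ − LHR⁻),  sensitivity = LHR⁺ (1 − specificity)

(the unique solution of the two defining ratio equations; the test suite
verifies reconstruction to 1e-9). Cells that are absent or not
invertible — including reversed-orientation pairs such as the vasovagal
heart-disease cell (0.072, 1.82), which encodes a *negative* predictor —
fall back to a neutral yes-rate of 0.2, a deliberate constant chosen as
a plausible background endorsement rate rather than an estimate of any
clinical truth. Each answer is then independently blanked to `unknown`
at a configurable rate (default 0). A single seeded NumPy generator
drives label draws and answers, so cohorts are fully reproducible.

What the generator does *not* emulate: correlated findings, real ED
case-mix, informative missingness, or clinician answer noise. Passing
the generator/engine consistency test therefore shows the engine
recovers the structure the generator encodes — that the pipeline is
self-consistent and the LHRs separating — not that it attains any
particular accuracy on real patients. On the seed-fixed 50/50
vasovagal-vs-cardiogenic cohort (n = 1000, no unknowns) the restricted
top-1 recovery is 0.755, well above the 0.70 bar (0.5 majority baseline
+ 0.2 margin); the ceiling sits near 0.75 because the neutral 0.2
yes-rate injects off-etiology positives and the unequal priors pull the
comparison toward vasovagal. Problem sizes used throughout (1000-case
cohorts, 10 000-draw rate checks, 1000 random-KB oracle trials) were
chosen to make sampling error negligible relative to the asserted
margins.

## Known limitations

- The engine's probabilities inherit every limitation of the published
  LHRs (heterogeneous source populations, consolidation of collinear
  variables) and of the naive independence assumption.
- The two low-evidence etiologies are handled by rule, not inference;
  their displayed probabilities are priors unless promoted.
- The congruence metric measures agreement with clinicians, not
  correctness; it is a feedback-loop statistic, not a validation study.
- The CLI's interactive mode is a flat question list; no attempt is made
  to re-create any mobile user experience.
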