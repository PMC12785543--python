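# Methods

## Model

The simulator represents the non-resuscitation consultation pathway of an
emergency department. Level I/II (critical) patients bypass the consultation
queues in the modeled hospital and are out of scope; Level III and IV
patients are the populations that compete for physicians.

**Arrivals.** A piecewise-constant non-homogeneous Poisson process with a
weekly cycle: for hour *h* of day *d* the number of arrivals is
Poisson(scale · λ_{d,h}), and, conditional on the count, the arrival instants
are i.i.d. uniform within the hour — exactly the conditional law of a Poisson
process given its hourly count, so the construction is a genuine NHPP with
the stated intensity. The simulation clock starts Monday 00:00 with an empty
system; the default horizon is one week (10,080 min). Each arrival is
Level III with probability 0.25, else Level IV.

**Consultations.** Initial and follow-up consultations draw from a base
family — exponential with mean 9 min (initial) or 15 min (follow-up), or
lognormal with σ = 0.3 and log-mean ln(mean) − σ²/2 so the untruncated mean
is preserved — hard-truncated to [5, 15] and [5, 25] min respectively. The
stated means are the *untruncated* base means: the truncated-exponential
effective service means are then 9.092 and 12.841 min (closed form
a + m − (b−a)e^{−(b−a)/m}/(1 − e^{−(b−a)/m})), which reproduces the
case-study's ≈85% physician utilization; forcing the truncated means to 9/15
would overload the system (and a truncated mean of 15 on [5, 25] is not even
attainable for an exponential base). The exponential sampler inverts the
truncated CDF; the lognormal sampler uses rejection. Services are never
preempted.

**Examinations.** After the initial consult a patient needs at least one
exam with probability 0.6; conditional on that gate, the four modalities are
independent Bernoulli draws (lab 0.92, ultrasound 0.22, X-ray 0.29, CT 0.55),
resampled until at least one indicator is set. A patient's exams run in
descending order of report delay (δ: X-ray 30 = CT 30 > lab 20 > US 0; ties
break by processing time descending, then by a fixed modality order), so the
slowest-reporting results are in flight first. Exam *k* becomes ready the
moment exam *k−1* finishes *processing* — report delays overlap later exams.
Each modality has one device with a FIFO queue; the extra delay ρ when a
device is busy is emergent from contention, not sampled. All results are
available at t_exam = max_k (start_k + τ_k + δ_k), when the patient joins
the follow-up queue.

**Staffing.** A three-shift daily roster (07–15 and 15–22 with 5 physicians,
22–07 with 3 by default; the sensitivity ladder S0–S6 raises it to 7/7/5).
At a downward shift boundary, physicians mid-consult finish their current
patient and then withdraw ("lame duck"); idle surplus withdraws immediately.
An upward boundary triggers an allocation epoch.

**Decision epochs.** The engine is event-driven (not time-stepped): a policy
decision is made whenever a physician frees (consultation end, upward shift
change) and whenever an arrival or a newly exam-complete patient meets idle
capacity. All policies are work-conserving and FIFO within a class. Event
ties at equal times resolve consultation-end < exam-end < results-ready <
shift-change < arrival, then insertion order, so a freed physician is
visible to a same-instant arrival and runs are bit-reproducible. Scheduling
a dedicated event at the instant a patient *becomes* urgent under SBP would
change nothing: if any physician were idle while anyone waited, a decision
would already have fired, so urgency flips can only matter at the next epoch
anyway.

**ALT with one free physician.** The batch quota ⌊R/2⌋ is zero at R = 1,
which taken literally would permanently starve initial patients whenever
physicians free one at a time (the common case). A per-replication toggle
serves the two categories alternately at single-physician epochs, which is
what a 1:1 capacity split means in that regime; with R ≥ 2 the quota form
applies and unused quota is redistributed to the other category.

## Key performance indicators

Stage waits are: initial wait = initial-consult start − arrival; follow-up
wait = follow-up-consult start − t_exam. From these the package reports two
layers:

* **Patient-cumulative waits** (`w_level3`, `w_level4`, `w_overall`): each
  fully completed patient contributes initial wait + (follow-up wait if they
  had exams); per-level means average over that level's patients and the
  overall mean over all patients. These are the headline waiting-time
  statistics and the grid-search objective. They are the only reading under
  which a policy's per-level and overall waits cohere with its delay rates:
  under strict initial priority, Level III *initial* waits are necessarily
  minutes-scale (top priority at ~86% utilization) while a Level III
  patient's total waiting is dominated by the follow-up stage — reporting
  Eq.-style initial-only waits per level would contradict a 0% share of
  initial waits above 30 min whenever the per-level mean exceeds 30.
* **Stage-wait statistics** (`w_init3`, `w_init4`, `w_follow`,
  `w_total_records`): class means of the individual wait records, plus the
  record-pooled mean in which an examined patient contributes two records.

Delay rates Δ_l are the share of *initial* waits strictly above the clinical
target (30/120 min); a wait exactly at the target is on time; SL_l = 1 − Δ_l
identically. Physician utilization is busy time over scheduled time
(42,840 physician-min per baseline week); device utilization is processing
time over capacity × horizon. Patients still in the system at the horizon
are censored from wait statistics but their accrued busy time counts.
Across replications each KPI is summarized by mean, sample SD, min, median,
max and a normal-approximation 95% CI (mean ± 1.96·SD/√n).

## Randomness and common random numbers

Replication *r* of an experiment uses seed base_seed + r, expanded into four
named substreams (arrival counts/instants, triage levels, service durations,
exam requirements). All patient material is pre-generated from these streams
before the event loop runs, so it is policy-independent: two policies run at
the same seed see identical patients, which makes paired comparisons exact
common random numbers. Paired *t*-tests use the per-replication overall-wait
differences, significance is Bonferroni-adjusted to 0.05/3 over the three
pairs, and the paired effect size is Cohen's d = mean(diff)/SD(diff) = t/√n.
Grid-search cells all reuse the identical seed set, making the ranking
CRN-paired across cells and invariant to evaluation order; exact objective
ties (possible when thresholds never bind) break by (k1, k2) ascending.

## Optimization

`two_stage_optimize` scans (k1, k2) ∈ [0, 40]² at step 1.0 with 50
replications per cell, then rescans the ±1 neighborhood of the coarse argmin
at step 0.1 with 100 replications, returning the cell with the lowest mean
overall wait among those meeting the service-level floors (default
SL_3, SL_4 ≥ 0.95); if no cell is feasible it returns the unconstrained
optimum with a warning. In this implementation's dynamics the objective
surface is nearly flat over a broad (k1, k2) region (see Limitations), so
the argmin location is noise-dominated even under CRN.

## What the generator emulates — and what it does not

The synthetic scenario reproduces the case-study's operating conditions:
the 168-hour empirical rate table, the 25/75 triage mix, truncated service
laws, the exam-requirement mix, and the 5/5/3 roster. It does not model
patient abandonment or reneging, physician breaks or heterogeneity, bed or
room constraints, level-dependent service or exam distributions, batch or
correlated arrivals, or calendar effects (holidays). Passing tests therefore
certify the scheduling dynamics under these stylized conditions, not
forecasts for a particular hospital; the published source for the baseline
likewise could not validate absolute waits against patient records.

## Problem sizes and numerical choices

Tests and the acceptance script use 100 replications of the one-week
baseline per policy (≈2,200 arrivals each, seconds of CPU per policy);
the engine-validation suite checks the M/M/c limit against Erlang-C at
three (λ, μ, c) points with 20 one-week replications each, and policy rules
against a brute-force priority-sort oracle on 10⁴ random queue states.
The acceptance-style grid search uses the reduced window [8, 18] × [0, 6]
at step 1 with 20 replications per cell to keep the full suite in minutes.
Truncation windows carrying less than 1e−12 of base-distribution mass are
rejected as configuration errors. Seeds derived from a user seed stay below
2³¹.

## Limitations

* **Near-critical load sensitivity.** The baseline runs at ≈86% weekly
  physician utilization with peak hours offered ≈1.2× capacity; mean waits
  in this regime are extremely sensitive to small load changes (a 3%
  arrival-rate reduction roughly halves some policy means). Comparisons
  between policies (CRN-paired) are robust; absolute wait levels are not,
  and small implementation details of the original case study that its
  description does not pin down can shift absolute levels by tens of
  percent.
* **SBP delay floor.** With k2 = 2.1, an urgent Level-IV patient must reach
  a physician within 2.1 min of being flagged to avoid breaching the
  120-min target, while the mean completion gap at peak with all physicians
  busy is ≈2.4 min. A work-conserving, non-preemptive engine therefore
  cannot drive the Level-IV delay rate to exactly zero at this load; the
  published 0.00 ± 0.00% is not reachable under the documented mechanism.
* **Flat tuning surface.** Because the two dynamic policies (ALT, SBP) are
  near-tied here, the grid-search argmin is identified only up to a broad
  plateau; reported optima should be read as "a good region", not a point.
* The engine is validated against closed-form queueing results in the
  Markovian limit; no empirical patient-level dataset is bundled.
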