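# edsim — discrete-event simulation of emergency-department patient flow

`edsim` models the consultation pathway of triage Level III (moderate, 30-min
wait target) and Level IV (low urgency, 120-min target) patients in a
hospital emergency department, and evaluates how the rule used to hand free
physicians to waiting patients changes waiting times, service-level
compliance, and resource utilization.

Patients arrive by a weekly-cyclic non-homogeneous Poisson process
(hour-of-day × day-of-week rate table λ_{d,h}), receive an initial
consultation, then with probability `p_exam` undergo one or more diagnostic
examinations (laboratory, B-ultrasound, X-ray, CT — each with a processing
time τ_j, a report delay δ_j, and unit device capacity) before queueing
again for a follow-up consultation. Consultation durations follow truncated
exponential (or, for robustness analyses, truncated lognormal)
distributions. Physician capacity R_t follows a three-shift roster.

Three allocation policies are implemented. At each decision epoch, with
D_init,3, D_init,4, D_follow the waiting demands and R the free physicians:

* **IFP** (Initial-First): N_init,3 = min(D_init,3, R), then Level IV, then
  follow-ups — initial consultations always outrank follow-ups.
* **ALT** (Alternating 1:1): at most ⌊R/2⌋ physicians go to initials
  (Level III first), the rest to follow-ups, unused quota redistributed;
  a toggle alternates the two categories when a single physician frees.
* **SBP** (Slack-Based): a Level-l patient is *urgent* once its wait w_i(t)
  satisfies w_i(t) ≥ T_l − k_l; priority order is urgent III > urgent IV >
  follow-ups > non-urgent initials. The slack tolerances (k_1, k_2) are
  tuned by a two-stage grid search minimizing the overall mean wait subject
  to service-level floors SL_3, SL_4.

The package ships the full case-study baseline (168-hour arrival-rate
table, 25%/75% triage mix, service and exam parameters, 5/5/3 staffing) as
`edsim.default_baseline()`; scenarios serialize to YAML and arrival tables
to CSV. Paired policy comparisons run under common random numbers with
paired *t*-tests, Bonferroni-corrected significance, and Cohen's d.

## Worked example

```python
import edsim

cfg = edsim.default_baseline()                      # embedded case-study ED
report = edsim.compare_policies(
    cfg,
    [edsim.PolicySpec("IFP"), edsim.PolicySpec("ALT"), edsim.PolicySpec("SBP", 13.1, 2.1)],
    n_reps=20, base_seed=7,
)
for name in report.policies:
    s = report.summaries[name].loc["w_overall"]
    print(f"{name}: overall wait {s['mean']:.2f} min (95% CI {s['ci_lo']:.2f}-{s['ci_hi']:.2f})")
print(report.pairwise[["pair", "mean_diff", "t", "p", "cohens_d"]].round(4).to_string(index=False))
```

prints

```
IFP: overall wait 59.59 min (95% CI 52.91-66.26)
ALT: overall wait 48.24 min (95% CI 43.07-53.41)
SBP: overall wait 49.97 min (95% CI 44.15-55.78)
       pair  mean_diff       t      p  cohens_d
IFP vs. ALT    11.3487 14.2888 0.0000    3.1951
IFP vs. SBP     9.6206 19.2313 0.0000    4.3002
ALT vs. SBP    -1.7282 -4.5334 0.0002   -1.0137
```

Each replication simulates one operational week (~2,200 arrivals). The
overall wait is the per-patient cumulative waiting time (initial wait plus,
for examined patients, the wait between results availability and the
follow-up consultation), averaged over all completed patients. Strict
initial-priority (IFP) starves the follow-up queue and is clearly worst;
the paired *t*-statistics show the differences are systematic, not noise
(all |d| > 1, i.e. very large paired effects). With 20 replications the
ALT-vs-SBP gap is small compared to its confidence band — the two dynamic
policies are close at this load; see `docs/methods.md` for why.

The same studies are available from the shell:

```bash
edsim run --policy IFP --reps 20 --seed 7 --out out/ifp
edsim compare --reps 100 --seed 1 --out out/cmp
edsim optimize --stage coarse --k1-max 18 --k1-min 8 --k2-max 6 --reps 20 --out out/grid
edsim sensitivity --mode staffing --reps 20 --out out/staffing
```

Every command writes CSV tables plus a `manifest.json` (command, scenario
hash, seeds, outputs) from which the run can be reproduced bit-for-bit.

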