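# kbplan — knowledge-based VMAT planning toolkit

`kbplan` is a Python toolkit for *knowledge-based planning* (KBP) research
in radiotherapy: predicting achievable dose-volume histograms (DVHs) from
patient anatomy, scoring treatment-plan quality, and studying how a
prediction model improves when its training database is refined in a
closed loop. It targets medical physicists and planning researchers who
want an open, end-to-end testbed for KBP methodology without a commercial
treatment-planning system.

The setting is pelvic volumetric modulated arc therapy (VMAT) for
cervical cancer: two planning targets — PGTVnd (60 Gy / 25 fractions) and
PCTV (45 Gy / 25 fractions) — and seven organs at risk (spinal cord,
bladder, rectum, kidneys, femoral heads).

## What's inside

* **DVH metrics** (`kbplan.dvh`) — cumulative DVH curves with strict
  validation; D_x%, V_xGy, D_mean, D_min, D_xcc endpoints; conformity
  index CI = (V_Tref/V_T)·(V_Tref/V_ref) at a configurable reference
  isodose (default 95%); homogeneity index HI = (D_2% − D_98%)/D_50%.
* **Plan Quality Metric** (`kbplan.pqm`) — a 19-criterion, 100-point
  scoring scheme over target coverage/hot-spot/minimum-dose rows, CI, HI
  and OAR dose constraints. Threshold rows score 0 below the *acceptable*
  level, 60% of their points at exactly acceptable, rising linearly to
  full points at the *excellent* level; CI and HI rows score
  `max_points·CI` and `max_points·(1 − HI)`.
* **DVH prediction model** (`kbplan.model`) — per-OAR principal-component
  regression: DVH shapes on a common dose grid are compressed into k
  modes (default 3) and a ridge regression maps anatomy features (overlap
  fraction, log falloff scale, log organ/target volume) to mode scores.
  Predictions come with an estimate band; the band's lower bound supplies
  the OAR optimization objectives.
* **Closed-loop model evolution** (`kbplan.evolution`) — flag relatively
  suboptimal database plans against the model's predictions, re-optimize
  them under the estimated DVHs, admit only new plans whose endpoints
  beat the prediction (self-checking gate), retrain, repeat: models
  C_0 … C_6 with the database growing 25 → 100 plans.
* **Rank-based model comparison** (`kbplan.ranking`) — per patient and
  OAR, models are ranked by ascending absolute prediction error; with M
  models the best earns M points down to 1 (ties share averaged points),
  then points are averaged over the cohort.
* **Synthetic cohort** (`kbplan.cohort`) — generates pelvic anatomies and
  plans with a single planner-skill parameter ε that inflates OAR doses
  above the achievable optimum, so flagging, re-optimization and gating
  have exact semantics.
* **Interchange + CLI** (`kbplan.io`, `kbplan.cli`) — JSON plan bundles,
  per-structure CSV curves, YAML/JSON criteria sets, JSON model files,
  and a `kbplan` command with `simulate / score / train / predict /
  evolve / rank` subcommands.

## Worked example

Simulate a small cohort and score one plan:

```bash
kbplan simulate --n 3 --seed 7 --out demo
kbplan score demo/SYN-0000.json
```

```
      criterion      structure   metric  value  points  max_points
     pgtvnd_v60         pgtvnd   V_60Gy 100.00    8.00        8.00
     pgtvnd_v66         pgtvnd   V_66Gy   0.00    8.00        8.00
    pgtvnd_dmin         pgtvnd    D_min  60.00    5.00        5.00
      pgtvnd_ci         pgtvnd       CI   0.67    1.33        2.00
      pgtvnd_hi         pgtvnd       HI   0.06    1.89        2.00
       pctv_v45           pctv   V_45Gy 100.00    8.00        8.00
     pctv_v49.5           pctv V_49.5Gy   0.00    8.00        8.00
      pctv_dmin           pctv    D_min  45.00    5.00        5.00
        pctv_ci           pctv       CI   0.70    1.41        2.00
        pctv_hi           pctv       HI   0.06    1.89        2.00
   cord_d0.03cc    spinal_cord D_0.03cc  17.21   10.00       10.00
    bladder_d35        bladder    D_35%  15.68   10.00       10.00
     rectum_d60         rectum    D_60%   7.28   10.00       10.00
   kidney_l_v18       kidney_l   V_18Gy   1.57    5.00        5.00
   kidney_r_v18       kidney_r   V_18Gy   0.16    5.00        5.00
    femur_l_v35 femoral_head_l   V_35Gy   7.74    3.00        3.00
femur_l_d0.03cc femoral_head_l D_0.03cc  48.13    2.00        2.00
    femur_r_v35 femoral_head_r   V_35Gy   5.88    3.00        3.00
femur_r_d0.03cc femoral_head_r D_0.03cc  48.11    2.00        2.00
Total: 98.52 / 100
```

Each row shows the measured endpoint (doses in Gy, volumes in percent of
the structure), the points it earns, and the criterion's maximum; the
total out of 100 is the plan-quality score. This synthetic plan meets
every excellent dose level, so only the continuous CI/HI rows hold it
below 100.

Run the full closed-loop evolution experiment (seven model files
C_0.json … C_6.json plus a trace of database size, per-OAR prediction
error and mean plan quality per round):

```bash
kbplan evolve --seed 1 --out evo
kbplan rank evo/C_1.json evo/C_6.json --eval-dir demo --out ranks.csv
```

In the default seeded experiment the evaluation error of C_6 is lower
than C_1 for every OAR endpoint — the later model, trained on the larger
and cleaner database, predicts closer to the best-effort dose.

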