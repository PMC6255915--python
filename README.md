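# vefkit

Behavioural analysis for **virtual-environment foraging** sessions in
head-fixed mice.  In this task a mouse runs on a treadmill through a
projected corridor; crossing a trigger line displaces the target wall to
the left (40 % of trials), centre (20 %) or right (40 %), where it shows a
grating while a distractor wall with a competing grating moves to the
opposite side.  The orientation difference ΔOri between the gratings
(90° … 5°) sets the difficulty.  A session is recorded as two text
streams: a per-trial event log and a continuous 60 Hz readout of position
and licking.

`vefkit` turns those two files into:

* **seven primary single-trial metrics** — hit index (+1/0/−1), target
  distance `TD = |X_T − X_M|/ΔX_T`, path-reliability score (the maximum
  over longitudinal positions of the pooled-SD Cohen's D between left- and
  right-target running paths, also as a 15-trial sliding "local PR"),
  path surplus `PS = L_R/L_i − 1`, reaction time (the time at which the
  slope regressing a 20-sample lateral path segment onto its 5-sample
  forward shift deviates most from 1), lick position, and running speed;
* **visual discrimination thresholds** — logistic fits
  `f(ΔOri) = L/(1+e^{−s(ΔOri−o)})` of the hit-index, target-distance and
  PR psychometric curves, crossed with bootstrap-calibrated criteria and
  averaged;
* **alertness states and the sATT score** — high/low-alert trial labels
  from the bimodal local-PR distribution (bimodality coefficient
  `BC = (skew²+1)/(kurt−3+3(n−1)²/((n−2)(n−3))) > 0.55`, cut by
  variance-ratio maximisation), with sustained attention quantified as the
  fraction of session time spent high-alert;
* **cognitive-load and attention scores** — per-trial
  `CL = 0.5·NR + 0.25·NT + 0.25·NP` (percentile-normalised reaction time,
  target distance, path surplus), the cued-attention score
  `cATT = (CL_noncued − CL_cued)/CL_all`, the error-prediction index
  `EP = (ΔRT + ΔPS + ΔLL)/3`, and Dunn–Šidák-corrected paired contrasts;
* a **synthetic-session generator** that produces both session files plus
  full ground truth (per-trial choices, true reaction times, alertness
  segments), so every stage is verified by parameter recovery.

It is aimed at behavioural/systems neuroscientists who want single-trial,
non-binary performance readouts compatible with trial-by-trial neuronal
analyses.  See `docs/methods.md` for definitions, conventions and known
limitations.

## Worked example

```python
import numpy as np
from vefkit.config import SimConfig
from vefkit.synthetic import generate_session
from vefkit.metrics import compute_metric_table
from vefkit.session_io import segment_trials
from vefkit.psychometrics import threshold_by_condition
from vefkit.benchmarks import SIM_COHORT_CRITERIA
from vefkit.states import classify_states
from vefkit.scores import normalization_bounds, cl_index, catt_score, ep_index

cfg = SimConfig(n_trials=400, seed=42)          # high-state threshold 10 deg, low 16 deg
session, truth = generate_session(cfg)
table = compute_metric_table(session)
slices = segment_trials(session)

inc = table[table.include_flag]
print(f"included choice trials: {len(inc)} / {len(table)}")
print(f"mean hit index: {inc.hit_index.mean():.3f}")
print(f"median reaction time: {inc.reaction_time.median()*1000:.0f} ms")

est = threshold_by_condition(table, {"all": np.ones(len(table), bool)},
                             criteria=SIM_COHORT_CRITERIA,
                             slices=slices, geometry=cfg.geometry)["all"]
print(f"averaged discrimination threshold: {est.averaged:.1f} deg")

cls = classify_states(inc.local_pr.to_numpy(), inc.duration.to_numpy())
print(f"BC = {cls.bimodality.bc:.2f}, cut = {cls.cut:.2f}, sATT = {cls.satt:.2f}")

cl = cl_index(table, normalization_bounds(table))
print(f"mean CL index: {catt_score(cl, table.cue_flag.to_numpy()).cl_all:.3f}, "
      f"cATT = {catt_score(cl, table.cue_flag.to_numpy()).catt:.3f}")
print(f"EP index: {ep_index(table).ep:.3f}")
```

prints

```
included choice trials: 320 / 400
mean hit index: 0.659
median reaction time: 400 ms
averaged discrimination threshold: 11.5 deg
BC = 0.84, cut = 7.93, sATT = 0.17
mean CL index: 0.364, cATT = 0.155
EP index: 0.072
```

The 400 trials contain 80 excluded centre (instruction) trials.  The
averaged threshold of 11.5° lies between the configured high-alert (10°)
and low-alert (16°) truths, weighted by the time spent in each state.  The
local-PR distribution is clearly bimodal (BC 0.84 ≫ 0.55); sATT 0.17 means
17 % of analysed session time was spent above the alertness cut (this
default session alternates states every ~5 minutes, so many 15-trial
windows straddle state boundaries and read as low — see the limitations
section of the methods note).  The positive cATT (cued trials lower the
cognitive-load index by ~15 % of its grand mean) reflects the default
speed-incentive cue, and the positive EP index shows slower, less direct,
less reward-anticipating behaviour on trials that end in a miss.

The same pipeline runs from the shell:

```bash
vef simulate --seed 42 --out session/        # events.tsv, trace.tsv, truth
vef validate session/
vef metrics session/ --out metrics.tsv
vef states metrics.tsv --out states.tsv
vef scores metrics.tsv --out report.json
vef run --seed 42 --out run_out/             # everything, with a manifest
```

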