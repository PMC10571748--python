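# pigwalk

Activity monitoring for group-housed fattening pigs from UHF-RFID proximity
logs.

Pigs in a fattening pen wear RFID ear tags; fixed antennas at the feeding
trough, the nipple drinkers and a playing device register any tag inside
their reading area, at most once per second.  `pigwalk` turns those raw
detection streams into a per-animal, per-day activity measure — the
**virtual walking distance (VWD)** — and the cohort summaries an animal
scientist or herd manager would look at: fattening-stage means, per-pig
profiles, hour-of-day activity curves, and daily series overlaid with
locomotion (lameness) scores.

## The measure

Let an animal's readings on one calendar day, ordered in time, visit
antenna locations $\ell_1, \ell_2, \dots, \ell_k$ (consecutive readings at
the same antenna collapsed into one visit).  With $d(\cdot,\cdot)$ the
center-to-center Euclidean distance between antenna locations,

$$\mathrm{VWD} = \sum_{i=1}^{k-1} d(\ell_i, \ell_{i+1}).$$

VWD is a *lower bound* on the distance actually walked: a detection cannot
happen unless the pig is near the antenna, but the pig also moves where no
antenna sees it, and per-second detection is imperfect (roughly 90%
sensitivity at the trough down to 60% at the drinkers).  Because the
distance matrix satisfies the triangle inequality, missed detections can
only shorten the computed path — a property the test suite verifies against
simulated ground truth.

The package ships the five-location reference pen (trough, three drinkers,
playing device) with its published distance matrix, and accepts arbitrary
pens via 2-D antenna coordinates or an explicit matrix.

A semi-Markov barn simulator (`pigwalk.simulate`) generates reading streams
with the structure the analysis assumes — feeding-driven diurnal rhythm,
nocturnal rest, declining activity across the fattening period, per-pig
activity levels, per-location detection dropout, optional lameness
episodes — together with the true center-path length per pig-day, so every
pipeline stage is testable without animal data.

## Worked example

The least active day the measure can register in the reference pen is a pig
detected only at the trough, at the playing device and at the trough again:
two transitions of 5.2 m each, so VWD = 10.4 m — regardless of how many
1 Hz readings each visit produced.

```python
>>> import pandas as pd, pigwalk as pw
>>> layout = pw.bundled_layout()
>>> readings = pd.DataFrame({
...     "timestamp": pd.to_datetime(["2023-01-02 07:12:00",
...                                  "2023-01-02 12:40:30",
...                                  "2023-01-02 18:05:10"]),
...     "animal_id": "pig001",
...     "location_id": ["trough", "playing_device", "trough"],
...     "pen_id": "pen1"})
>>> pw.daily_vwd(readings, layout.distance_matrix())
DailyVWD(animal_id='pig001', date=datetime.date(2023, 1, 2), vwd_m=10.4,
         n_readings=3, n_transitions=2, fattening_day=None)
```

An end-to-end run on a simulated cohort, via the CLI:

```sh
$ pigwalk simulate --out-dir demo --seed 1 --n-pigs 5 --n-days 100
$ pigwalk compute  --readings demo/readings.csv --out-dir demo
$ pigwalk aggregate --out-dir demo --health demo/health.csv
$ pigwalk report   --out-dir demo
pigs: 5   pig-days: 500
overall mean daily VWD: 223.6 m
stage means [all_days]: d1_30 289.5 m (n=150); d31_60 231.0 m (n=150); d61_90 175.9 m (n=150); d_gt90 146.8 m (n=50)
stage means [per_pig_means]: d1_30 289.5 m (n=5); d31_60 231.0 m (n=5); d61_90 175.9 m (n=5); d_gt90 146.8 m (n=5)
per-pig daily means range 155.3 m (pig004) to 357.2 m (pig005)
peak hourly activity: 24.9 m in bin h18 (18:00-19:00)
```

Reading the output: activity falls monotonically across the four fattening
stages (days 1–30, 31–60, 61–90, >90) because the simulated cohort ages;
the two stage-mean variants coincide here because every pig contributes
every day (a balanced design); the activity peak sits in the early evening,
between the late-afternoon feedings, and the night hours (22:00–06:00) are
nearly flat — the rest phase.

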