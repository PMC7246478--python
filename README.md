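# noisecross

Individual aircraft-noise exposure assessment for case-crossover studies of
acute mortality.

Epidemiologists investigating whether nighttime aircraft noise can trigger
cardiovascular death need, for every death in a cohort, the noise exposure at
the person's residence during the night before death — and during comparable
*control* nights, so that each person serves as their own control. This
package builds that exposure database. From three inputs — an airport
movement list, per-event noise footprint grids, and geocoded death records —
it produces, for every person × (case or control) date × exposure window, the
three standard nighttime noise metrics:

* **L_Aeq** — equivalent continuous sound level over the window:
  `L_Aeq = max(0, L_AE − 10·log₁₀(T/t₀))`, `t₀ = 1 s`, where
  `L_AE = 10·log₁₀(Σᵢ 10^(L_AE,i/10))` energetically sums the per-flight
  sound exposure levels of the n flights in the window;
* **L_Amax** — the highest per-flight maximum level in the window;
* **NAT₅₅** — the number of flights whose L_Amax exceeds 55 dB.

Per-flight levels come from footprint grids (250 m receiver spacing, one
grid per year × aircraft group × route × procedure) by inverse-distance
weighting over the four nearest receivers, `L = (Σ Lᵢ/dᵢ)/(Σ 1/dᵢ)`.
Control nights are time-stratified: the 3–4 other dates in the same calendar
month sharing the case's weekday. Daytime deaths (07:00–23:00) get five
windows over the preceding night (evening, early night, core night, early
morning, overall night); nighttime deaths get the two hours preceding the
death clock time. See `docs/methods.md` for the full model and conventions.

Because real movement lists, acoustic footprints and mortality records are
restricted, the package ships a seeded synthetic generator (`synth` module /
`noisecross simulate`) that emulates all three inputs — flight ban, delayed
flights, day-to-day route variability, monotone footprint decay — so the
whole pipeline runs and is testable without external data.

## Worked example

```python
from noisecross import build_events, classify_death
from noisecross.synth import SynthConfig, make_footprints, make_movements, make_deaths
from noisecross.movements import recover_types, filter_flights, assign_groups
from noisecross.metrics import MovementIndex, compute_exposure

cfg = SynthConfig(seed=7, study_span=(2010, 2010), n_deaths=1)
store = make_footprints(cfg)
movements, registry = make_movements(cfg)
movements = recover_types(movements, registry)          # fill types via tail numbers
movements, excluded = filter_flights(movements, drop_missing_type=True)
movements = assign_groups(movements)

death = make_deaths(cfg)[0]
print(death.person_id, death.death_dt, death.icd10, classify_death(death.death_dt))
index = MovementIndex(movements)
for e in build_events(death):
    r = compute_exposure(e, index, store)
    print(f"{e.event_kind:7s} {e.event_date} {e.window.window_id:13s} "
          f"laeq={r.laeq:6.2f} lamax={r.lamax_max:6.2f} nat55={r.nat55:3d} n={r.n_flights}")
```

prints

```
P00001 2010-09-23 00:51:20 I97 nighttime
case    2010-09-23 last2h        laeq= 32.17 lamax= 60.21 nat55=  1 n=5
control 2010-09-02 last2h        laeq= 28.79 lamax= 54.19 nat55=  0 n=4
control 2010-09-09 last2h        laeq= 28.14 lamax= 58.71 nat55=  1 n=1
control 2010-09-16 last2h        laeq= 25.20 lamax= 52.76 nat55=  0 n=2
control 2010-09-30 last2h        laeq= 37.20 lamax= 66.73 nat55=  1 n=6
```

This person died during the night (00:51), so each event is the 2-hour
window 22:51–00:51 on the case night and on the four same-weekday September
control nights. On the case night 5 flights were audible at the residence,
giving an equivalent level of 32.2 dB and one flight louder than 55 dB; the
control nights bracket that exposure (25.2–37.2 dB), which is exactly the
within-person contrast a conditional logistic regression would analyse.

The same pipeline is available from the shell:

```sh
noisecross simulate --seed 7 --out study/ --start-year 2010 --end-year 2010
noisecross sample  --deaths study/deaths.csv --out study/events.csv
noisecross compute --events study/events.csv --deaths study/deaths.csv \
    --movements study/movements.csv --registry study/registry.csv \
    --footprints study/footprints --out study/exposures.csv
```

`exposures.csv` holds one row per event:
`person_id,event_kind,event_date,window_id,laeq_db,lamax_db,nat55,n_flights`.

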