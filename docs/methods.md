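# Methods

`noisecross` computes individual nighttime aircraft-noise exposure for a
case-crossover study of acute mortality: for each death it quantifies the
noise at the person's residence during defined windows of the night before
(or, for nighttime deaths, the two hours before) death, and during the same
windows on time-stratified control nights. The output is one row of
(L_Aeq, max L_Amax, NAT_55) per person × date × window, ready for a
conditional-logistic-regression analysis that is deliberately out of scope
here.

## Study design

The case-crossover design compares a subject's exposure at the event time
with the same subject's exposure at nearby reference times, so stable
personal characteristics cannot confound. Control nights are sampled
*time-stratified*: every other date in the same calendar month that shares
the case's day of week. Any calendar month contains each weekday 4 or 5
times, so every case receives exactly 3 or 4 controls, lying both before and
after the case whenever the case is not the first or last occurrence of its
weekday in the month. Matching on weekday absorbs the weekly periodicity of
airport operations; sampling within the month bounds seasonal trend leakage.

Deaths are classified by clock time, with half-open conventions throughout:
daytime deaths in [07:00, 23:00), nighttime deaths in [23:00, 07:00).
Daytime deaths get five windows anchored to the single night block preceding
the death day — evening 19:00–23:00, early night 23:00–23:30 (the slot
reserved for delayed flights), core night 23:30–06:00 (flight ban), early
morning 06:00–07:00, and overall night 23:00–07:00. The three sub-windows
partition the overall night exactly (1800 + 23400 + 3600 = 28800 s).
Nighttime deaths get one 2-hour window ending at the death clock time;
control events reuse the case's clock time on the control date so that case
and control windows have identical duration T. Windows are nominal clock
intervals; daylight-saving transition nights keep their nominal T and flight
timestamps (also local clock times) are compared directly. This is a known
approximation affecting two nights per year.

## Flight selection

Movement lists carry one timestamped record per departure (brake release)
or arrival (touch down). Because an aircraft is audible away from the
airport before touch down and after brake release, each movement maps to a
10-minute audible interval: [t−10 min, t] for arrivals, [t, t+10 min] for
departures. A flight belongs to a window iff its audible interval overlaps
the half-open window with positive measure; under this rule the 19:00–07:00
night envelope expands to an 18:50–07:10 selection band. A flight straddling
an internal boundary (e.g. 23:00) contributes its full event levels to every
window it overlaps — footprints are per-event, not time-resolved, so no
energy splitting is attempted. A `membership="point"` switch (raw timestamp
in window) is provided as the alternative reading.

Cleaning: missing aircraft types are recovered from a tail-number registry
keyed by validity date ranges (a present type is never overwritten); flights
are then restricted to large aircraft, maximum take-off weight strictly
greater than 8618 kg, with a known air route. The command-line pipeline also
drops flights whose type remains unknown after recovery, since such flights
cannot be matched to any footprint; every exclusion is counted by reason.

## Footprints and interpolation

A footprint is a regular receiver grid (250 m spacing) of per-event levels
L_AE (sound exposure level) and L_Amax, keyed by year, aircraft group, air
route, procedure, and optionally time of day. The level at a residence is
taken from the four nearest receivers by inverse-distance weighting with
exponent 1,

    L = (Σᵢ Lᵢ/dᵢ) / (Σᵢ 1/dᵢ),  i = 1..4,

with a point on a receiver (distance < 1 µm, the floating-point
geocode-on-receiver case) returning the stored value exactly. Distances are
Euclidean in the projected metric CRS; no geodesy is performed.
Interpolation is an arithmetic weighted mean of dB values, not of energies —
that is what the weighting formula states, and for the sub-decibel spreads
between neighboring receivers 250 m apart the difference to an energetic
mean is far below other error sources. "Four nearest" means the four
receivers with smallest distance (with ties broken in row-major receiver
order for determinism), which coincides with the enclosing cell corners for
interior points and differs only near grid edges. Points outside the
receiver lattice's bounding rectangle raise an error rather than
extrapolate; study-area selection is expected to prevent them.

When the exact footprint key is absent, a similar footprint substitutes: the
same (group, route, procedure, time of day) in the nearest other year, ties
toward the earlier year (fleet and procedures drift slowly, so the nearest
year is the best proxy; the earlier-year tie-break is an arbitrary but fixed
convention); failing that, the same (group, route, procedure) ignoring time
of day. Every substitution is logged with both keys. If no year of the
(group, route, procedure) combination exists, a missing-footprint error
names the key and the flight.

## Exposure metrics

For the n flights selected into a window, with per-flight interpolated
levels L_AE,i and L_Amax,i:

* total energy:  L_AE = 10·log₁₀( Σᵢ 10^(L_AE,i/10) )  (energetic sum);
* equivalent level:  L_Aeq = max(0, L_AE − 10·log₁₀(T/t₀)),  t₀ = 1 s, with
  T the nominal window duration in seconds;
* maximum level: max L_Amax,i over the window;
* NAT_55: the number of flights with L_Amax,i strictly above 55 dB (an
  `nat_strict=False` switch makes the comparison ≥, since exact-55.0 values
  are not disambiguated by the definition).

Windows with no flight, or whose raw L_Aeq is negative, are set to 0 dB; by
the same convention the empty-window maximum level is 0 dB and NAT is 0. The
flight count n is recorded alongside so analysts can distinguish true
silence from floored values. Accumulation happens in the linear energy
domain in double precision; nothing is rounded until CSV output (3
decimals). The empty energetic sum is represented internally as −∞ dB,
which the zero rule maps to 0.

## Synthetic study data

Real inputs (airport movement lists, acoustic footprints, geocoded mortality
records) are restricted, so the `synth` module generates structurally
faithful stand-ins; all are deterministic given the master seed, with
independent per-generator substreams.

* **Footprints** follow a toy line-source decay,
  `L_AE(x, y) = max(0, S − k·log₁₀(1 + d/d₀))`, with d the distance to the
  route axis segment, source level S per aircraft group (99/93/78 dB),
  slope k = 22 dB per decade, d₀ = 200 m, and L_Amax = L_AE − 8 dB, plus a
  small per-year level drift (σ = 0.5 dB). These values were chosen once so
  that nightly L_Aeq at residences spans roughly 20–75 dB, the range typical
  of an exposed population around a major airport; the model reproduces
  monotone distance decay, not acoustics — no directivity, topography or
  meteorology.
* **Movements**: nightly counts are Poisson (default mean 60 in the
  19:00–07:00 band, plus 40 daytime flights) over a default 2000–2015 span;
  each night draws one of two "wind regimes" that concentrate traffic on a
  different half of the 6 routes (4 departure, 2 approach axes), giving the
  day-to-day route variability the design needs. No flight falls inside the
  23:30–06:00 ban; each night flight spills into the delayed 23:00–23:30
  slot with probability 0.05, otherwise lands in the evening (~75%) or
  early-morning (20%) slots. 5% of rows lose their aircraft type (the tail
  registry covers 75% of tails, so most but not all are recoverable) and 1%
  lose their route, exercising the cleaning paths.
* **Deaths** are uniform over the 20 × 20 km study region and the span, with
  a 0.7 daytime fraction and ICD-10 codes drawn from I00–I99. One aircraft
  group sits below the 8618 kg cutoff to exercise the large-aircraft filter.

What passing tests on these data show: the calendar logic, window
construction, dB arithmetic, interpolation and aggregation are correct, and
the pipeline is deterministic end to end. What they do not show: anything
about real acoustic propagation, real fleet mixes, or the magnitude of real
exposure contrasts — the synthetic generator is a test harness, not a noise
model.

## Numerical and design choices

* Boundary conventions are half-open everywhere ([start, end) windows,
  [07:00, 23:00) day); touching a window endpoint is not membership.
* The within-window L_Amax statistic is the *maximum* event level; the word
  "mean" in the metric's long name refers to the footprint averaging over
  flights of a type, not to a within-window mean.
* IDW uses exponent 1, as the weighting formula is written, not the more
  common exponent 2.
* Grid files are plain text with the northernmost row first; a long-format
  `x,y,lae,lamax` CSV reader infers the lattice and rejects irregular ones.
* Fallback order and tie-breaks (earlier year; bare time-of-day before
  `day` before `night`) are fixed conventions chosen for determinism.
* The pipeline's problem sizes in the acceptance script — a two-year span,
  150 deaths, ~73 000 movements, ~2 300 events — are the package's default
  demonstration scale; every operation is linear in the number of events
  and flights, so larger spans only cost time.

## Known limitations

* No acoustic propagation model; synthetic footprints are a geometric toy.
* No CRS handling: all coordinates must share one projected metric CRS.
* Flights straddling window boundaries are counted whole in each window they
  touch, so adjacent-window energies can double-count boundary flights (the
  energy-additivity invariant therefore holds exactly only for flights that
  do not straddle).
* DST transition nights use nominal clock durations.
* The downstream health analysis (conditional logistic regression) is out of
  scope; the package stops at the exposure database.
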