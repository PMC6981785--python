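# dynagra

Dynamic spatio-temporal correlation analysis for air-quality monitoring
networks: an information-entropy **adaptive sliding window** feeding
**grey relational analysis** (ASW-GRA), recomputed hour by hour for
variable–variable, station–station and cross-dimension pairs, with static,
fixed-window and partial-correlation contrast methods and a
fluctuation-entropy evaluation of how dynamic each method's output is.

It is written for analysts of dense urban / industrial-park sensor grids —
the setting where the "most relevant influence factor" on a pollutant such
as PM2.5 changes with the hour and a single whole-archive correlation
number misleads.

## The method

At each hour *t*, the L0 = 10 most recent values of the object series form
a decision segment. Its mean-normalised absolute changes
z_i = |d_{i+1} − d_i|/|m| are converted to probabilities p_i = z_i/Σz, whose
Shannon entropy H = −Σ p_i log₂ p_i sets the adjustment proportion
s = H / log₂ L0. With stability thresholds s_min = min p_i,
s_max = max p_i, the window length becomes

    L = L0            if s_min < s < s_max
    L = round(L0 / s) if s ≥ s_max      (smooth, even change → lengthen)
    L = round(s · L0) if s ≤ s_min      (concentrated change → shorten)

clamped into [Lmin, Lmax]. On the trailing L values the grey relational
degree is computed: after per-sequence min–max scaling, with deviations
Δ_k(i) = |y(i) − x_k(i)| and two-level extrema Δmin, Δmax over all
candidates,

    ξ_k(i) = (Δmin + ρ·Δmax) / (Δ_k(i) + ρ·Δmax),    r_k = (1/L) Σ_i ξ_k(i)

with resolution ratio ρ = 0.5. The degree r_k ∈ (0, 1] is emitted as one
record per candidate per hour; ranking the candidates at each hour names
the currently dominant factor or source direction. See `docs/methods.md`
for conventions, degenerate cases and the pairwise-vs-joint scoring
discussion.

## Worked example

```python
import collections
import numpy as np
import dynagra as dg

# synthetic 9-station hourly grid, 240 h, known couplings to PM2.5
panel = dg.generate_scenario(dg.default_scenario(seed=42))

records = dg.variable_correlation_series(
    panel, "HS", "PM2.5", ["PM10", "CO", "TVOC", "temperature"])
by = collections.defaultdict(list)
for r in records:
    by[r.associated_variable].append(r.degree)
for v, ds in sorted(by.items(), key=lambda kv: -np.mean(kv[1])):
    print(f"{v:12s} mean degree {np.mean(ds):.3f}")
```

prints

```
PM10         mean degree 0.867
CO           mean degree 0.690
temperature  mean degree 0.611
TVOC         mean degree 0.588
```

— the time-averaged dynamic degrees recover the generator's coupling order
(PM10 strongest at β = 0.9, CO next at β = 0.6, the nuisance and the
meteorological driver trailing). The per-hour ranking shifts with the
moment, which is the point of the dynamic method: at hour 120 of the same
run, `dg.ranking_at_time(records, panel.timestamps[120])` puts PM10 first
(0.867) but temperature second (0.697) and CO last (0.530), while the
whole-period static degree of the PM2.5–PM10 pair is a single 0.683 that
can say nothing about any particular hour. Each record also carries the
window length the entropy rule chose (here between 11 h and 15 h as the
series alternates between calm and fluctuating spells).

The same analysis is available from the shell:

```bash
dynagra simulate --seed 42 --hours 240 --out run/
dynagra analyze variables --panel run/panel.csv --station HS \
    --object-variable PM2.5 --candidates PM10,CO,TVOC,temperature \
    --out run/variables.csv
dynagra evaluate --records run/variables.csv --panel run/panel.csv \
    --out run/summary.csv
```

plus `analyze points` (station–station), `analyze cross`
(station,variable pairs) and `matrix` (full station×station degree matrix
at one time point, with the strongest off-diagonal interaction reported).

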