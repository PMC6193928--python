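# driftwatch

Diel timing of drifting fish eggs versus their egg predator, reconstructed
from PIT telemetry.

## The problem

Asp (*Leuciscus aspius*), a large rheophilic cyprinid, releases free-drifting
eggs over gravel spawning grounds in early spring. Bleak (*Alburnus
alburnus*), a small visually foraging cyprinid, eats those eggs — but only
while it can see them. Whether spawning is timed to *avoid* the predator's
activity window is a question about the 24-hour mismatch between when eggs
enter the water column and when the predator is on the ground.

`driftwatch` implements the full inference chain from raw passive-telemetry
detection logs to that mismatch, for ecologists working with PIT (RFID)
antenna arrays:

1. **Ingest** — parse and validate detection logs (timestamp, antenna,
   12-digit tag code), a tagging registry, and an hourly water-temperature
   series; collapse the reader's 10 Hz re-detection bursts.
2. **Presence bouts** — a fish is present while successive detections are
   ≤ 2 h apart; a longer silence is departure. Asp are analysed from one
   year after tagging, bleak from one day; male asp are excluded.
3. **Egg availability** — each female's length is back-projected to the
   spawning year with an individual-anchored von Bertalanffy curve
   L(t) = L∞(1 − e^(−K(t−t₀))), converted to weight by W = a·TLᵇ
   (a = 0.00744, b = 3.046; TL in cm, W in g), to eggs through a
   gonadosomatic index, and the eggs are spread uniformly over her time on
   the spawning ground into hourly bins.
4. **Diel labelling** — sunrise/sunset from the NOAA solar-position
   algorithm at the study coordinates (49.578497° N, 15.251671° E); every
   hourly bin gets an exact day fraction.
5. **Models** — two Gaussian linear mixed models (REML, Satterthwaite
   degrees of freedom, Nakagawa marginal/conditional R², backward stepwise
   selection by ML-AIC): hourly eggs ~ period + day-of-year + predator
   presence + temperature with a year random intercept, and per-individual
   predator presence ~ period + day-of-year + eggs with a random intercept
   and date slope by individual. Kendall's τ-b tests the daily
   egg–predator association.

Because no raw telemetry from the original study system is publicly
deposited, the package includes a first-class synthetic-study generator
(`driftwatch.synthdata`) that emulates it with known ground truth — tagged
females making short night-biased visits, a diurnal predator that leaves
before sunset, three 10 Hz antennas, hourly temperature — so every stage of
the chain is testable against planted parameters.

## Worked example

Generate a synthetic two-season study at the default conditions (230 tagged
females and 23 bleak per 14-day season, 63% nocturnal visit probability,
diurnal predator with an 8% nocturnal leak) and run the full pipeline:

```bash
driftwatch synth --seed 7 --out data
cat > run.yaml <<'YAML'
detections: data/detections.csv
registry: data/registry.csv
temperature: data/temperature.csv
season_windows:
  - ["2016-04-01", "2016-04-15"]
  - ["2017-04-01", "2017-04-15"]
outdir: out
YAML
driftwatch run --config run.yaml
```

Selected lines of the printed `summary.json` for this seed:

```
egg_night_share_pct        61.68   ± 11.47 (SD over 28 season days)
bleak_night_share_pct       1.21   ± 0.81  (SD over 46 individuals)
egg model r²  marginal 0.28, conditional 0.28
egg model period-of-day term: estimate 0.808, SE 0.065, df 666.4, p ≈ 2e-32
```

Reading: roughly 62% of the modelled eggs entered the water at night
(the generator planted 63%), while the predator was present at night only
~1% of its time — the diel mismatch the pipeline is built to expose. The
period-of-day coefficient (night = 1, all covariates z-scored) is the
corresponding model-based contrast. The egg model's random year intercept
fits at zero variance here (marginal = conditional R²) because the default
generator plants no inter-annual effect; the fit is flagged singular rather
than hidden. `out/` also contains per-stage CSVs (bouts, biomass,
hourly egg bins, 24-h diel profile with a plot, both model tables) and a
reproducibility manifest.

Every stage is also callable as a library function
(`driftwatch.presence.segment_bouts`, `driftwatch.biomass.project_length`,
`driftwatch.mixedstats.fit_lmm`, ...) on pandas objects.

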