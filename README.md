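# petrelpop

Population assessment toolkit for burrow-nesting seabirds, built around the
long-term mist-net study of the Cape Verde petrel (*Pterodroma feae*) on
Fogo Island. It bundles the study's published data tables and implements the
full analysis chain on top of them:

* **Open-population capture–mark–recapture.** The POPAN parameterization of
  the Jolly–Seber model: a super-population of *N* birds enters the sampled
  population with entry probabilities *b*, survives between annual sessions
  with apparent survival *φ* and is detected with capture probability *p*.
  The package fits all constant/time-dependent structures of (*φ, p, b*) by
  maximum likelihood from m-array sufficient statistics, ranks them by AICc,
  and model-averages *N* with unconditional standard errors. RELEASE-style
  goodness-of-fit tests (TEST2/TEST3 contingency decomposition) screen the
  underlying Cormack–Jolly–Seber assumptions.
* **Brood-patch breeder enumeration.** Three graded counting rules (minimum /
  most probable / maximum) translate brood-patch scores of mist-netted birds,
  benchmarked against same-year nest captures, into bounds on the breeder
  fraction, and scale it to the population estimate.
* **Biometric sexing.** Sexual size dimorphism index
  (SDI = 100·(male − female)/male per trait), pooled and Welch two-sample
  tests (from raw values or published summaries), Bonferroni control, a
  linear discriminant sexing function with a stratified train/test split,
  and one-way intra-class correlation for measurement repeatability.
* **Breeding phenology.** Geolocator immersion/light traces (both logger
  dialects) are normalized to 10-minute wet fractions; colony visits are
  long nocturnal dry spells (> 4 h) and burrow days are dark, dry daylight;
  first arrival dates and incubation bout lengths follow. Nest visit logs
  reduce to a season-outcome taxonomy and annual breeding success.
* **Synthetic data.** Generators for every input stream (encounter
  histories, biometrics, activity traces, nest logs, two-group samples)
  with known latent truth, defaulting to the study's published parameter
  estimates.

## Worked example

```
python examples/population_size.py
```

fits the shipped ten-year capture table (145 birds, 73 first-recapture
events) and prints, among other lines:

```
model: phi(.) p(t) b(.)
N: 275.2 (SE 27.5, 95% CI 231-341)
phi: 0.753±0.043, ...
b:   0.350±0.105, 0.072±0.012, ...
p:   0.207±0.081, ..., 0.109±0.041, ...

model-averaged N = 273 ± 29 (unconditional SE), 95% CI [217, 330]; 1.95% of
the variance comes from model uncertainty
```

Read: under the best-supported structure (constant survival and entry,
year-specific capture probability), about three quarters of the birds
survive and remain in the sampled population from one year to the next
(φ ≈ 0.75 — low for a petrel, consistent with many immatures in the
mist-netted sample), roughly 7% of the super-population enters per
interval, and yearly capture probabilities range from ≈ 0.11 to ≈ 0.39.
Averaging the eight candidate models weights structure uncertainty into a
super-population estimate of ≈ 273 birds. The other scripts in `examples/`
walk through the dimorphism/sexing analysis, the brood-patch breeder
bounds, geolocator phenology and nest outcomes, each printing the numbers
it computes and a line on what they mean.

A thin CLI mirrors the library:

```
petrelpop simulate popan --seed 1 --out sim/
petrelpop marray --inp sim/histories.inp
petrelpop fit --marray m.tsv --model "phi(.) p(t) b(.)" --seed 1
petrelpop breeders --scores scores.csv --mode probable --popsize 293 --ci 232,354
```

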