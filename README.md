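# dispersalkit

Social versus spatial natal-dispersal inference for fission–fusion animal
societies, from photographic mark–resight data.

## The problem

In species that form multi-level societies — stable social *communities* of
tens of individuals whose day-to-day *groups* merge and split constantly, and
whose communities overlap in space — the classical spatial definition of
natal dispersal (moving far from the birth site) misses half the picture. A
juvenile can disperse **socially**, by permanently switching its association
to a different community while staying near its natal range; **spatially**,
by moving beyond the scale of an adult home range while keeping its natal
associations; **both**; or not at all. Giraffes are the motivating system:
adult females form discrete communities of roughly 60–90 members that
overlap in space, and calves resighted photographically over many years can
be classified into these four dispersal types.

`dispersalkit` implements that entire inference chain for anyone with tidy
resight records (one row per individual per sighting, with group membership
and coordinates):

1. **Ageing** (`growth`): measured heights are converted to ages by
   inverting a von Bertalanffy growth curve
   h(a) = H∞ − (H∞ − h0)·e^(−k·a), with a per-individual least-squares
   birth-date fit across repeated measurements.
2. **Association network** (`network`): gambit-of-the-group detections →
   group-by-individual matrix → simple ratio index
   SRI(a,b) = x / (x + y_ab + y_a + y_b) → weighted modularity
   maximisation (Leiden) → adult-female community partition, with a
   temporal-stability report.
3. **Social dispersal** (`social`): each calf detection is assigned to the
   community holding the majority of adult females in its group; the natal
   community is the modal assignment before weaning (≤ 18 months); a
   permanent post-weaning switch of association is social dispersal, while
   non-natal spells followed by a return count as exploratory visits.
4. **Spatial dispersal** (`spatial`): net displacement from first detection
   is compared with a per-community threshold radius r = sqrt(Ā/π), where
   Ā is the community's mean adult-female 95% kernel home-range area; a
   final position beyond the threshold is confirmed with a local-linear
   smoother (more than half of the detections after the smoothed line's
   final crossing must lie beyond), and single-occasion exceedances with
   return are recorded as sorties.
5. **Statistics** (`models`): sex differences as logistic regressions with
   a natal-community random intercept (adaptive Gauss–Hermite quadrature);
   dispersal type as a multinomial logit with "none" as the reference
   level (exponentiated coefficients are relative risk ratios); distance
   and age as Gaussian linear models; all ranked by
   AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with Akaike weights.
6. **Synthetic society** (`simulate`): a generative model of the whole
   study — overlapping communities, Chinese-restaurant fission–fusion
   groups, robust-design survey calendar, Bernoulli detection, planted
   dispersal fates and ages, sorties, and noisy heights — so every stage is
   testable against known truth.

## Worked example

```python
import dispersalkit as dk

cfg = dk.SimConfig(n_communities=4, members_per_community=(20, 25),
                   n_calves=60, seed=1)
society = dk.simulate_society(cfg)
result = dk.run_pipeline(society.detections, seed=0)

print("communities:", result.partition.n_communities,
      " modularity Q = %.3f" % result.partition.modularity)
print(result.thresholds.round(2))
ok = result.records.dropna(subset=["dispersal_class"])
print(dk.summarize_types(ok).summary())
ev = dk.evaluate_against_truth(result.records, society.truth)
print("agreement with planted fates: %.1f%%" % (100 * ev["agreement"]))
```

prints

```
communities: 4  modularity Q = 0.724
           mean_area_km2  radius_km  n_members
community
0                 105.78       5.80         25
1                 111.39       5.95         22
2                 102.78       5.72         22
3                  98.33       5.59         20
Counts (proportion within sex):
  F  none: 23 (0.74)  social: 1 (0.03)  spatial: 5 (0.16)  social-and-spatial: 2 (0.06)
  M  none: 7 (0.24)  social: 7 (0.24)  spatial: 4 (0.14)  social-and-spatial: 11 (0.38)
Dispersed:
  F  8/31 (26%)
  M  22/29 (76%)
agreement with planted fates: 100.0%
```

Four communities are recovered from the association network with threshold
radii near 5.8 km (the generating adult movement scatter of 2.5 km implies a
true 95% home-range radius of sqrt(5.991)·2.5 ≈ 6.1 km); dispersal is
strongly male-biased, as planted; and the four-way classification matches
every planted fate in this small society.

The same stages are available from the shell:

```bash
dispersalkit simulate --seed 1 --out sim/
dispersalkit network  --detections sim/detections.csv --out net/ --periods 3
dispersalkit pipeline --detections sim/detections.csv --out run/
dispersalkit models   --records run/records.csv --covariates sim/covariates.csv --out fits/
```

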