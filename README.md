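# heatfish

Growth, mortality and size-structure analysis for a whole-ecosystem
warming comparison: Eurasian perch (*Perca fluviatilis*) from an
artificially heated, enclosed coastal bay versus its reference area in the
adjacent archipelago.  The package is aimed at fisheries and global-change
ecologists who want a tested, reusable implementation of this analysis
chain, runnable end-to-end on synthetic data with the same statistical
structure as the field data.

The chain quantifies four things, heated vs reference:

1. **Size-at-age** — a hierarchical Bayesian von Bertalanffy growth model
   on log length at catch,
   `log L ~ Student-t(ν, log[L∞_j (1 − e^{−K_j (t − t0)})], σ)`,
   with cohort-varying `L∞` and `K` (independent normal deviations around
   area hyper-means) and shared-vs-area-specific variants compared by
   PSIS-LOO.
2. **Growth-at-size** — the allometric model `G = α L^θ` for annual
   specific growth `G = 100 (log L_{t+1} − log L_t)` (%/yr) against
   geometric mean length, with `α` varying across individuals nested in
   cohorts; lengths-at-age are back-calculated from operculum annuli via
   `L_a = L_s (r_a / R)^s`, s = 0.861.
3. **Mortality** — catch-curve regression: binned catch is expanded to
   CPUE-at-age through age-length keys, the descending limb (modal age and
   older) is kept, and the negative age slope of log CPUE estimates the
   instantaneous mortality `Z` (annual mortality `1 − e^{−Z}`), with
   cohort-varying coefficients under a correlated MVN prior.
4. **Size structure** — the bounded power-law size-spectrum exponent fitted
   to binned body masses by exact bin probabilities (MLEbin) with
   profile-likelihood CIs, plus lognormal models of the size- and
   age-resolved catch giving mean size and mean age differences between
   areas.

Inference runs on a purpose-built blocked adaptive Metropolis-within-Gibbs
sampler (3 chains, split-R̂ < 1.1 enforced, PSIS-LOO via `arviz`); see
`docs/methods.md` for the models, priors, sampler moves, and the synthetic
data's assumptions.

## Worked example

Run the full chain on a simulated pair of populations (cohorts 1981–1997,
catch years 1987–2003, generative parameters at the published posterior
medians; about two minutes):

```sh
heatfish run-all --seed 0 --outdir demo
```

prints (numbers from this exact command):

```
heatfish synthetic analysis report
seed 0  config 2ad5f6468dcb

Growth (VBGE hyper-means, posterior medians):
  L_inf heated 45.4 cm vs reference 40.3 cm (+12%)
  K heated 0.181 /yr vs reference 0.152 /yr (+20%)
  alpha heated 464 vs reference 491 (-5%)
  specific growth at 15 cm: heated 24.5 vs reference 17.9 %/yr
Mortality (catch curve):
  Z heated 0.82, reference 0.57 (annual 56% vs 44%)
Size spectrum exponent gamma:
  heated: -1.10 [-1.12, -1.08]
  reference: -1.13 [-1.15, -1.11]
Mean length difference (heated - reference): +2.56 cm
Mean age difference (heated - reference): -0.58 yr

Directional contrasts (heated vs reference):
  heated_faster_growth: yes
  heated_larger_size_at_age: yes
  heated_higher_mortality: yes
  heated_larger_mean_size: yes
  heated_younger_mean_age: yes
```

Reading this: the heated population grows faster (higher `K`, higher
specific growth at a common 15 cm length), suffers higher total mortality
(`Z` 0.82 vs 0.57, i.e. 56% vs 44% of a cohort dying per year), and ends up
on average 2.6 cm longer yet 0.6 years younger — faster growth outpacing
the extra mortality.  The size-spectrum exponents barely differ.  At this
demo scale the `α` contrast is wide (its posterior inherits the `α`–`θ`
ridge); the growth contrast at an in-range length is the stable summary.
The generating truth behind this run is `Z` 0.73/0.62 and growth parameters
at the medians listed in `docs/methods.md`, so the magnitudes above are
single-realization estimates, not tuning targets.

Every stage is also exposed as a library function
(`heatfish.growth_models.fit_vbge`, `heatfish.mortality.expand_catch`,
`heatfish.size_spectrum.mlebin_fit`, ...) and as individual subcommands
(`simulate`, `backcalc`, `fit-vbge`, `fit-growth`, `alk`, `expand`,
`catch-curve`, `spectrum`, `mean-size-age`, `compare`, `validate`),
reading and writing plain CSV/YAML/JSON (posterior draws as netCDF).

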