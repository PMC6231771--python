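# phenosync

Tools for studying **within-population phenological synchrony under
climate warming**: does spring warming make the individuals of a plant
population leaf out (or flower) more asynchronously, and if so, is that
driven by between-individual differences in day-length and chilling
sensitivity rather than by the shape of the spring temperature curve?

The package is aimed at phenology and climate-change ecologists who want
to run this analysis chain on PEP725-style observation tables — or, as
here, on synthetic data with the same statistical structure, so every
stage is testable without restricted-access downloads.

## What it computes

**Synchrony.** For a 1°×1° pixel, species and year, leaf-out synchrony
LOS is the sample standard deviation of event dates across individuals;
LOS-DD is the SD of the degree-day sums individuals accumulated by their
event (base 5 °C, from 1 January):

    DD_sum = Σ_{t0..t_LO} max(T_t − 5, 0)

**Drivers.** Chilling hours count the time between 0 and 5 °C from
1 November of the preceding year; day length follows the CBM model
(a function of latitude and day-of-year with a 0.8333° horizon term);
preseason temperature is the mean over the 60 days before the pixel's
mean event date.

**Cleaning.** PEP-style rules, in fixed order: drop series with
across-year SD > 25 days; drop observations more than 3×MAD from the
series median; pixelize by flooring coordinates; keep ≥ 3 individuals
sharing ≥ 15 years; drop individuals > 200 m from the pixel's mean
altitude; drop years with < 90 % coverage.

**Inference.** Per-pixel OLS of LOS on preseason temperature with
cross-pixel correlation summaries; a hierarchical Bayesian
random-intercept regression (species and pixel intercepts, N(0, 1000)
coefficient priors, Uniform(0, 100) random-intercept-variance priors,
own Gibbs sampler with Gelman–Rubin diagnostics):

    y_i ~ N(α + β·x_i + u_species(i) + v_pixel(i), σ²)

**Nulls and experiments.** A degree-day-only simulation quantifies how
much synchrony loss the spring temperature-curve shape alone produces;
twig-experiment analytics estimate per-individual forcing, day-length
and chilling requirements and decompose leaf-out variation into
treatment / between-individual / within-individual components.

## Worked example

```sh
python examples/03_synchrony_and_regression.py
```

```
per-year synchrony series (first 5 years):
       los  los_dd  mean_doy  preseason_temp  mean_chilling  dl_at_forcing
year
2001  1.68   10.82    123.53            5.33         1760.0          14.71
2002  2.17   14.48    115.00            6.93         1622.0          14.18
2003  2.16   10.77    124.40            5.45         1837.2          14.81
2004  2.46   10.39    120.07            6.14         1594.0          14.45
2005  2.02   11.06    122.93            5.27         1712.0          14.66

LOS vs preseason temperature: slope +0.278 days/degC, r = +0.51, p = 0.021 over 20 years
```

Each row is one pixel-year: `los` is the spread of leaf-out dates in
days (synchrony; larger = less synchronous), `los_dd` the same spread in
degree-days, `mean_doy` the mean event date, and the last three columns
the candidate drivers. The regression line at the bottom is the pixel's
answer to the headline question: here a year that is 1 °C warmer in the
preseason shows a 0.28-day wider spread of leaf-out dates (p = 0.02) —
the population loses synchrony as springs warm.

The other scripts in `examples/` walk through climate generation,
cleaning, the Bayesian driver models, the degree-day-only null, the twig
experiment, and the end-to-end pipeline (`RunConfig` + `run_all`).

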