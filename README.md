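# mixedcodes

Tools for studying **conjunctive ("nonlinear mixed selectivity") population
codes**: how neural populations that respond to combinations of stimulus
features trade reliability against metabolic cost.

Stimuli have `K` discrete features with `n` values each (`M = n^K` stimuli).
A code of **order `O`** dedicates one binary unit to every combination of
`O` features and every joint value assignment — `O = 1` is pure
single-feature tuning, `O = K` a one-hot code over stimuli. The package
constructs these codebooks, derives their closed-form properties,

- population size `D_O = C(K,O) n^O`,
- representation energy `P_O = C(K,O)` (squared codeword norm),
- minimum distance `Δ_O = sqrt(2 C(K−1,O−1))`,
- and the exact ratio `Δ_O²/P_O = 2O/K`, strictly increasing with order,

simulates transmission through Gaussian or Poisson channels with
maximum-likelihood decoding, estimates error rates by the union bound
`PE ≤ Σ_v N_all(v) Q(d(K,O,v)·sqrt(SNR/P_O)/2)`, optimizes code order under
neuron-count or total-energy budgets (`E = εV + D_O`), generalizes the codes
to receptive fields of width `σ_rf` (discrete and continuous stimuli), and
evaluates codes against the rate-distortion bound of the uniform source.
It is aimed at computational neuroscientists and anyone modelling discrete
channel codes with population-coding constraints.

## Worked example

The order-2 code for `K = 3` features with `n = 5` values:

```python
>>> from mixedcodes import analytic_report
>>> rep = analytic_report(3, 5, 2, snr_grid=[9.0, 25.0])
>>> rep.population, rep.representation_energy, rep.min_distance
(75, 3.0, 2.0)
>>> rep.neighbor_counts["min_distance"]
12
>>> list(rep.ube_nearest)
[0.49958709998130246, 0.023354502736671768]
```

75 units (three feature-pair subpopulations of 25), energy 3 (one active
unit per subpopulation), minimum codeword distance 2, and 12 nearest
neighbors (the `K(n−1)` one-feature-away stimuli). The union-bound estimate
predicts a 2.3% error rate at SNR 25. Simulating the channel:

```sh
$ mixedcodes simulate -K 3 -n 5 -O 2 --snr 25 --trials 10000 --seed 1
{
  "pe": 0.0232,
  "pe_se": 0.0015053823434596275,
  "mse": 0.168,
  ...
}
```

The Monte-Carlo error rate (2.32% ± 0.15%) matches the estimate, and the
MSE of 0.168 says the average error, when one occurs, lands about
`sqrt(0.168/0.0232) ≈ 2.7` squared-feature-units away. Repeating with
`-O 1` at the same SNR gives `pe ≈ 0.111`: the pure code makes almost five times
as many errors with the same energy.

Other entry points: `mixedcodes analyze | sweep | energy-map | rf-sweep |
rd-curve | fixtures` (see `--help`; `sweep` takes YAML configs or the named
presets `fig2a`, `fig2c-right`, `fig3`, `s4`), and the library API in
`mixedcodes` (`build_codebook`, `simulate`, `ube_error`, `allocate_energy`,
`optimal_order`, `rf_sweep`, `continuous_simulate`,
`rate_distortion_bound`, ...). `docs/methods.md` documents the model,
numerical choices, and limitations.

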