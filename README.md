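# spectraldcm

Spectral dynamic causal modelling of regional calcium-imaging time series.

The package implements a complete modelling chain for slow (seizure-like)
state transitions in multichannel fluorescence recordings:

1. **`neural_mass`** — three-population neural mass sources (projection,
   excitatory and inhibitory interneuron populations; five intrinsic
   couplings H1–H5 plus time constants T_E/T_I as log-scalings of fixed
   prior means), with a stochastic time-domain simulator and a linearised
   steady-state cross-spectral predictor that agree with each other.
2. **`observation_model`** — the calcium-indicator kernel (inverted
   quadratic rise, exponential decay, both branches normalised to 1 at the
   end of the rise), convolution and anti-aliased decimation to the
   imaging rate, and the observation power transfer used during inversion.
3. **`spectral_features`** — sliding-window Fourier summaries, the k×k
   window-by-window band-power correlation ("delay–delay") matrix, and
   windowed multivariate-autoregressive complex cross-spectral densities
   with an eigenmode summary.
4. **`variational_inversion`** — variational-Laplace (Gauss–Newton ascent
   on a free-energy objective) fitting of a network model to an observed
   cross-spectrum; Gaussian posteriors, free energy, predicted spectra,
   variance explained; independent per-window inversions.
5. **`model_space`** — the factorial baseline architecture space (6 hub
   levels × neighbouring × homotopic = 24 models over 5 bilateral region
   pairs), closed-form Bayesian model reduction, and family-wise
   comparison.
6. **`peb_hierarchy`** — parametric empirical Bayes over windows: a
   temporal basis (tonic step, monophasic pharmacokinetic bump, ramp,
   slow cosine drifts, per-fish effects), group-level coefficient
   posteriors, BMR over which parameter sets fluctuate, and the
   construct-validity experiment (recovering a known single-parameter
   ramp from synthetic fluorescence segments).
7. **`forward_mapping`** — PCA of intrinsic-parameter trajectories
   (gains and time constants separately) and generative maps from the
   two-component score plane to predicted delta/gamma log band power.
8. **`synthetic_data`** — generation of every input the pipeline needs:
   construct-validity segments and full multi-fish, 10-region, 150-minute
   experiments with known ground-truth parameter trajectories.
9. **`workbench_cli`** — TSV/YAML/HDF5 formats, the staged pipeline and
   the `spectraldcm` command-line interface.

All defaults (prior means and variances, window schemes, bands, grids)
live in `src/spectraldcm/defaults.yaml`; user YAML files override them
(unknown keys are rejected).

## Command line

```sh
spectraldcm run                      # full pipeline on a synthetic miniature
spectraldcm run --config my.yaml     # override any defaults
spectraldcm synth|features|baseline|invert|peb|map
spectraldcm validate-fig1 --seed 1   # construct-validity check
```

The pipeline stages (synth → features → baseline → invert → peb → map)
write their artefacts — recordings as TSV, ground truth and summaries as
YAML, window posteriors as HDF5, maps as delimited grids — under the
configured output directory. The packaged pipeline defaults describe a
one-fish, 10-minute miniature so a full run completes quickly; override
`pipeline.duration_s`, `pipeline.n_fish`, etc. for paper-scale runs.

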