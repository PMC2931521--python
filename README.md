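# autoassoc

A spiking-network model of autoassociative memory storage and recall, with
an analysis pipeline for simulated synaptic pathologies and personalized
in-silico therapeutics.

The model is a 100-neuron recurrent excitatory network with a single
feedback interneuron. Each neuron is an isopotential Hodgkin–Huxley sphere
(leak + fast Na⁺ + delayed-rectifier K⁺, reduced Traub–Miles kinetics)
driven by peak-normalized double-exponential AMPA/GABA_A conductances with
1 ms synaptic delays. Random 10-neuron stimulus patterns are stored through
a Hebbian rule

```
W_ij = g_max_ampa · n11 / (n11 + (n10 + n01) · gamma_ltd)
```

where `n11` counts patterns in which both neurons of a connected pair are
co-active and `n10`/`n01` count independent activations (never co-active
pairs stay silent). Feedback inhibition scales as
`gGABA = g_max_ampa · pattern_size · connectivity · relative_inhibition`,
with each excitatory→interneuron synapse at 90% of `g_max_ampa`.

Two assays score each stored pattern within one gamma cycle (25 ms
default): **pattern separation** fails if any non-member neuron spikes when
the full pattern is stimulated; **pattern completion** fails if a held-out
member does not spike when the other nine are stimulated. The *max error*
(the larger of the two rates) is the scalar minimized to define optimal
"wild-type" networks.

Large parameter sweeps (20 values each of connectivity, LTP strength, LTD
strength and relative inhibition = 160,000 combinations; × 6 storage loads
= 960,000 conditions; 3 connectivity profiles × 10 memory sets each) are
made tractable by a precomputed **spike-threshold table**: the minimal
excitatory conductance that fires a neuron as a function of concurrent
inhibitory conductance, validated against explicit simulation. On top of
the sweep sit single- and dual-parameter pathology analyses, bias
classification against the optimal ensemble's tolerable error limits, and
per-individual therapy line searches over a heterogeneous synthetic cohort.

## Command-line pipeline

One command with one subcommand per stage; stages read each other's
artifacts from the `--out` directory and write a JSON manifest per run:

```bash
autoassoc threshold-table --out results --seed 1
autoassoc sweep           --out results --seed 1 --scale small
autoassoc select-optimal  --out results --seed 1 --scale small
autoassoc single-pathology --out results --seed 1
autoassoc interaction     --out results --seed 1
autoassoc cohort          --out results --seed 1
autoassoc treat           --out results --seed 1
```

`--scale small` (default) runs a 5-values-per-axis grid with storage loads
{5, 30} and a top-10 optimal ensemble — minutes on one CPU. `--scale full`
runs the full 20⁴ grid with loads {5, 10, 15, 20, 25, 30} and top-100
selection (long-running). A YAML file passed with `--config` overrides any
default (see `DEFAULT_CONFIG` in `autoassoc/cli.py` for the schema);
`--resume` reuses per-connectivity-level sweep checkpoints.

Outputs are plain CSV/JSON: the threshold table, the sweep database
(one row per parameter combination × load, with mean ± SEM error rates
over 3 connectivity profiles), the selected optima, error-vs-perturbation
curves, interaction surfaces, and untreated/treated cohort error tables.

## Notes

- Conductance densities are interpreted in mS/cm² (τ_m = 10 ms); see the
  `biophysics` module docstring.
- The threshold table's default excitatory→inhibitory event lag is 1.3 ms,
  the emergent disynaptic latency measured in full network simulations
  (configurable via the table's `offset` parameter).
- The fast sweep path evaluates one synchronous recruitment round per
  gamma cycle; explicit simulation includes higher-order recruitment, and
  their agreement is bounded by tests in `tests/test_assays.py`.
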