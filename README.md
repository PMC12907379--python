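# neurocosim

Multi-scale neural co-simulation in a single process: a biophysical
spiking network that generates seizure-like events is embedded as a
*proxy node* inside a delayed whole-brain mean-field network, with a
bidirectional spike-to-rate translation layer, an epoch-synchronised
exchange protocol, and tools to map how seizures propagate from the seed
region across the connectome.

It is intended for computational neuroscientists who want a compact,
fully inspectable testbed for cross-scale experiments — seizure onset at
the cellular level, recruitment at the whole-brain level — without
distributed-simulator plumbing.

## The models

**Micro scale.** Single-compartment neurons with slow ion-concentration
dynamics: reduced Hodgkin-Huxley currents `i_X = g_X (V - E_X)`, Nernst
reversals `E_X = C log(X_o/X_i)/z`, a saturating Na/K pump, and two slow
variables (intracellular potassium deviation ΔK_i and bath-buffered gain
K_g) from which all six ion concentrations follow by mass conservation.
The bath potassium concentration `K_bath` is the single control
parameter: raising it moves the cell through resting state (RS), spike
train (ST), tonic spiking (TS), bursting, seizure-like events (SLE),
sustained ictal activity (SIA) and depolarization block (DB). Cells are
wired all-to-all with exponential conductance synapses (w = 0.5).

**Macro scale.** A reduced Wong-Wang network over a connectome:

    dS_I/dt = -S_I/τ_s + (1 - S_I) γ H(x_I)
    H(x)    = (ax - b)/(1 - exp(-d(ax - b)))
    x_I     = ω J_N S_I + G J_N Σ_K c_IK S_K(t - τ_IK) + I_0

with conduction delays τ_IK = tract length / speed held in a ring
buffer.

**Coupling.** Both sides advance in *epochs* no longer than the smallest
conduction delay, which makes the exchange exact: results are
bit-identical when the exchange interval is halved. Micro spikes become
the proxy activity ν_P through a calcium-like exponential kernel (or
plain binning), scaled by a gain G_A = 100 and fed into the proxy's
gating equation; macro rates of regions connected to the proxy are
converted back into synthetic events dispatched to every cell.

## Worked example

Classify one cell's firing pattern at a seizure-prone bath level:

```
$ neurocosim neuron -O sim.kbath=17.0 -O sim.duration=60000 --out out
K_bath=17.0 mM -> SLE
```

The cell at 17 mM bath potassium produces recurrent seizure-like
events — multi-second depolarized spiking episodes separated by quiescent
gaps — and the classifier labels the 60 s trace accordingly (the trace
itself is written to `out/trace.csv`).

Sweep the default bath grid:

```
$ neurocosim sweep -O sim.duration=60000 --out out
 kbath_mM pattern_label
      4.0            RS
      7.5            TS
      9.5            TS
     12.5         BURST
     17.0           SLE
     17.5           SLE
     22.5            DB
```

Read bottom to top: at 4 mM the cell rests; at 7.5–9.5 mM it spikes
tonically; at 12.5 mM it bursts; at 17–17.5 mM it produces seizure-like
events; at 22.5 mM spiking collapses onto a depolarized plateau
(depolarization block). See `docs/methods.md` for the two labels that
deviate from the canonical taxonomy and why.

Run a full co-simulation on a synthetic 10-region connectome with a
100-cell all-seizure proxy, then map propagation:

```
$ neurocosim cosim -O micro.N=100 -O micro.f=1.0 \
      -O micro.kbath_sle=17.5 -O sim.duration=16000 --out run
$ neurocosim analyze --rates run/region_rates.csv --out run
```

`run/propagation_map.csv` lists, per region, the baseline rate, the
seizure onset time (first sustained rise exceeding baseline by 10% for at
least 100 ms) and the delay relative to the seed region; regions without
a qualifying excursion are marked NA.

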