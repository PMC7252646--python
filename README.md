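# eigenlock

Leading-eigenvector dynamics of phase-locking functional connectivity.

## The problem

Multichannel oscillatory recordings — EEG above all — carry a time-varying
web of synchrony: groups of channels transiently lock their phases,
rearrange, and lock again. Static functional connectivity averages this
structure away. `eigenlock` is for researchers who want the *dynamics*: it
turns raw multichannel signals into a time series of binary phase-locking
networks and compresses each network snapshot into a single tracked
object, the **prime eigenvector**, whose trajectory exposes meta-stable
states and the transitions between them.

## The method

For channels *m, n* and a sliding window of width *t_w* samples, the
phase-locking value is a Euclidean distance between windowed angular-speed
phasor vectors. With φ̇<sub>m,t</sub> the first difference of the
unwrapped Hilbert phase,

```
v_m  = ( e^{iφ̇_{m,t_1}}, …, e^{iφ̇_{m,t_w}} )
d_mn = ‖ v_m − v_n ‖₂ = sqrt( Σ_t 4 sin²( (φ̇_{m,t} − φ̇_{n,t}) / 2 ) )
```

Small *d* means the pair held a constant phase difference across the
window. Thresholding *d* (default 4×10⁻⁴; strict `<`) yields a symmetric
binary adjacency matrix **A**(t) per window.

The prime eigenvector **Φ**(t) is the unit-norm, entrywise-nonnegative
eigenvector of the largest eigenvalue of **A**(t); its support is the
dominant synchronized cluster (for a union of cliques it is exactly the
uniform vector on the largest clique). The successive inner product
⟨**Φ**(t), **Φ**(t+1)⟩ then sits near 1 while the dominant cluster is
stable and dips when it changes — for uniform cluster vectors the dip
equals the analytic overlap |A∩B| / √(|A||B|) of the old and new clusters,
reaching 0 for disjoint supports. Counting values < 0.01 ("Event 0",
transition) and > 0.99 ("Event 1", persistence) gives a one-number summary
of how restless the network is; all-pairs inner products give a recurrence
matrix whose blocks are the meta-stable states.

The package also ships a scripted phase-oscillator simulator (three
built-in validation scenarios with staged cluster merges and splits, plus
noisy EEG-like signal synthesis), classical graph-topology summaries with
a matched-density G(n, m) null, baseline dynamical clustering methods
(single-linkage cut, greedy modularity, Jaccard cluster tracking), and
paired Wilcoxon condition comparisons.

## Worked example

Run the first validation scenario — 8 oscillators in clusters of 3 (3 Hz)
and 5 (5 Hz) that merge at step 500 and separate at step 1500 — through
the full pipeline:

```python
import eigenlock as el

script = el.build_scenario("scenario1")
traj = el.simulate_phase_network(script, seed=1)

window = el.WindowSpec(width=40, step=1, fs=1000.0)
distances = el.windowed_plv_distance(traj.speeds.T, window)
networks = el.binarize(distances, threshold=4e-4)

led = el.LeadingEigenvectorDynamics()
events = led.events(networks)
print(f"Event-1 frequency: {events.freq_event1:.4f}")
print(f"Event-0 frequency: {events.freq_event0:.4f}")
for s in led.spikes(networks):
    print(f"spike at step {s.window_start}: inner product {s.minimum:.4f}")
print("state durations (windows):", led.segmentation(networks).durations().tolist())
```

prints

```
Event-1 frequency: 0.9990
Event-0 frequency: 0.0000
spike at step 500: inner product 0.7906
spike at step 1461: inner product 0.7906
state durations (windows): [500, 961, 500]
```

Exactly two spikes appear, one per staged cluster change, and their depth
is the analytic overlap √(5/8) ≈ 0.7906 of the 5-clique with the merged
8-clique. The trajectory segments into three meta-stable states whose
boundaries recover the scripted change points.

The same analysis is available from the shell:

```sh
eigenlock simulate --scenario scenario1 --outdir out/sim
eigenlock connect out/sim/scenario1_speeds.tsv --input-kind speed \
    --window-ms 40 --step-ms 1 --threshold 4e-4 --outdir out/conn
eigenlock eigdyn out/conn/networks.tsv --outdir out/eig
```

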