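# Methods

## Phase-locking model and the distance-based PLV

Two oscillators are phase-locked over an interval when their phase
difference is constant there, equivalently when their angular speeds —
first differences of unwrapped instantaneous phase, in rad/sample — are
equal. The pipeline therefore measures synchrony on angular speeds, not
on phases: per sliding window, each channel contributes a row vector of
unit phasors `exp(i*phi_dot)`, and the phase-locking value of a pair is
the Euclidean distance between its rows,

    d_mn^2 = sum_t |e^{i phi_dot_m,t} - e^{i phi_dot_n,t}|^2
           = sum_t 4 sin^2((phi_dot_m,t - phi_dot_n,t)/2).

Unlike the classical phase-coherence PLV (modulus of the mean
phase-difference phasor, also provided), this accumulates every sample's
disagreement and cannot be fooled by trajectories that cross: positive
and negative speed differences do not cancel. Because the squared
distance is a plain sum over samples, any split of a window into disjoint
sub-windows satisfies `d^2 = d_a^2 + d_b^2` exactly. This identity is
what turns a window that straddles an instantaneous network change into a
brief intermediate regime in which rearranging groups are unlocked from
both their old and their new partners — so a simultaneous split-and-merge
is resolved as two consecutive transitions.

The distance is not normalized, so an absolute threshold defines an edge:
`d < threshold` (strict; a tie is a non-edge — deterministic, and
measure-zero in practice). The default threshold is 4e-4, appropriate for
near-noiseless angular speeds such as the scripted simulations. For noisy
signals the same decision must be made the way it is made on real
recordings — by inspecting the clearly bimodal distribution of locked and
unlocked distances — which `suggest_threshold` automates with an Otsu
split of the log-distance histogram.

## Signal front end

Narrow-band analysis uses a linear-phase FIR band-pass (Hamming design,
taps from the `3.3 / (transition_width / fs)` rule, default transition
4 Hz) applied by centered convolution, which is exactly zero-phase. The
conventional bands are 8-12, 18-22, 26-30 and 38-42 Hz at fs = 1 kHz.
Phase comes from the analytic signal (Hilbert transform), unwrapped along
time; a guard warns if any speed magnitude exceeds pi rad/sample, which
can only happen on unwrap failure. The first and last
`(taps-1)/2 + ceil(fs/low_edge)` samples are treated as edge-contaminated
and excluded from sliding windows by default (the filter's group delay
plus one period of the slowest in-band component); a flag includes them.
The sliding window defaults to 40 ms width and 5 ms step, converted to
samples at fs; the scripted-scenario analyses use step 1 for maximal
temporal resolution.

## Prime-eigenvector dynamics

The prime eigenvector of a window's binary adjacency is computed per
connected component: each component contributes its Perron eigenvalue,
and the winner's Perron vector (entrywise nonnegative, unit norm) is
embedded in the full channel set. Numerical choices:

* **Degeneracy.** Components tying within a relative gap of 1e-8 (equal
  size cliques, typically) are resolved toward maximal overlap with the
  previous window's vector, or — with no previous vector — toward the
  component containing the lowest channel index. This makes the series
  continuous: identical consecutive adjacencies give an inner product of
  exactly 1 even under eigenvalue multiplicity, where a raw eigensolver
  would return an arbitrary basis of the degenerate space.
* **Edgeless windows** are flagged invalid rather than given a zero
  vector; pairs touching them are excluded from all event denominators,
  so missing data cannot fabricate transitions.
* Since all valid vectors are nonnegative, successive inner products lie
  in [0, 1] and need no absolute value; values are clipped to [0, 1]
  against round-off.

Event counting uses the bimodality of the inner-product series: values
below 0.01 are transitions (Event 0), values above 0.99 persistence
(Event 1), with frequencies normalized by valid pairs. The accumulated
(running-ratio) variants support online monitoring.

**Spike detection** formalizes "sharp dips": a spike is a maximal run of
consecutive values below the plateau level (0.99) containing at least one
value at or below the spike level, reported at its minimum; two spikes
are distinct only if separated by a return to plateau. The spike level
defaults to 0.95. The rationale: the dips that matter are cross-plateau
overlaps of dominant clusters, `|A∩B|/sqrt(|A||B|)`, and the shallowest
overlap realized in the built-in scenarios is sqrt(14/17) ≈ 0.908 (the
17-cluster shedding 3 members in the benchmark's step-1500 event), while
genuine plateaus sit at 1 up to round-off — so 0.95 separates the two
regimes with a wide margin on both sides. The level is configurable for
data with noisier plateaus.

**State segmentation** is greedy: extend the current state while the next
vector's inner product with the running centroid (renormalized mean)
stays at or above the similarity level (default 0.99); valid windows are
partitioned exactly, so durations sum to the valid-window count.

## The simulator and the built-in scenarios

The simulator realizes the angular-speed autoregression: uncoupled
oscillators keep their speed; a symmetric pair coupling of strength `a`
moves each partner toward the other, decaying the speed gap with ratio
`1 - 2a` per step. The printed form of the coupling (difference term
added with a plus sign) amplifies gaps; it is kept as
`coupling_sign="as_printed"` for fidelity experiments, while the default
`"attract"` produces locking. The uniform coupling strength convention is
0.1. Initial phases are uniform on [0, 2*pi); they do not affect any
angular-speed quantity but the seed is recorded for bit reproducibility.

Scenario scripts pin angular speeds exactly (scripted segments override
coupling to machine precision), and cluster rearrangements are
instantaneous step changes. Frequencies in Hz convert to rad/step via
`2*pi*f/fs` with fs = 1 kHz (1 ms steps). The three builders stage:

1. **scenario1** — 8 oscillators, clusters of 3 (3 Hz) and 5 (5 Hz);
   merge at step 500 (common 4 Hz), split at 1500; duration 2000. The
   merged-cluster frequency is arbitrary for the binary analysis and was
   set between the two cluster frequencies.
2. **scenario2** — 15 oscillators; a 12-oscillator cluster (5 Hz) sheds a
   5-subset at step 1000, which joins the 3-cluster (3 Hz); duration
   2000. Expected dips: sqrt(7/12) then 0.
3. **benchmark** — 27 oscillators in four indivisible clusters
   3/5/9/10 at 3/4/5/7 Hz with changes at 500, 1000 and 1500; duration
   2500 so the final arrangement is well represented, and the post-1500
   configuration is held to the end (the narrative of the comparison
   figure hints at one more drift at step 2000, but the scenario's own
   description lists exactly three change points, which is what the
   builder implements). Expected dips: sqrt(10/19) at 500; sqrt(10/19)
   and 0 at 1000; sqrt(14/17) and sqrt(14/24) at 1500 — five spikes.

`synth_multichannel_signal` turns trajectories into EEG-like channels,
`cos(phase) + N(0, noise_sd)`. What it emulates: band-limited oscillatory
channels with genuinely phase-locked groups, scheduled rearrangements and
observation noise. What it does not: 1/f background spectra, volume
conduction and shared sources, non-stationary amplitudes, artifacts
(blinks, EMG), or inter-subject variability. Passing tests on these
fixtures therefore validate the measurement chain — filtering, phase
estimation, distance, thresholding, eigen-tracking — not robustness to
every property of scalp recordings; on real EEG the threshold choice and
artifact handling remain the user's responsibility (the pipeline accepts
pre-cleaned signals; no ICA or surface-Laplacian step is included).

## Parameter-recovery experiment

The switching-rate fixtures (`experiments.py`) plant a known number of
dominant-cluster swaps: a 3-channel anchor cluster locked at 20 Hz
throughout keeps every window valid, while a 6-channel and a 4-channel
group alternate between locked (19 / 21 Hz) and free (distinct per-channel
frequencies, pairwise gaps >= 0.4 Hz, all inside the 18-22 Hz band).
Every swap drives the dominant cluster through two disjoint-support
transitions, so the Event-0 frequency is proportional to the planted
rate. Defaults: 13 channels, 5000 samples, noise_sd 0.03 (about 3% of
the unit carrier amplitude — enough to perturb every distance, small
enough that the locked/unlocked modes stay separable, as they must be
for any threshold-based method), switching rates 2/5/8 per trial, 100
replicates, per-trial Otsu threshold. Recovery is the fraction of
replicates whose Event-0 frequencies are strictly increasing in the
planted rate; 12 replicates double as paired synthetic subjects for the
Wilcoxon check.

## Topology metrics and the random null

Density is edges over possible pairs; mean efficiency averages reciprocal
shortest-path lengths over unordered pairs with disconnected pairs
contributing 0 (well defined on fragmented graphs, unlike mean path
length); the global clustering coefficient is the mean of local
clustering coefficients with degree-<2 nodes contributing 0
(transitivity available behind a flag, since "cluster coefficient" is
ambiguous in common usage). The random null matches the exact edge count
— uniform G(n, m), not G(n, p) — because the comparison of interest is
at fixed density. Recurrence-probability networks average per-trial edge
probabilities first, then across trials, weighting trials equally.

A known limitation worth stating: the folk identity "Erdős–Rényi
clustering equals density" is asymptotic. At n = 32 the expectation of
mean local clustering in G(n, m) sits measurably below m/C(n,2) (the
conditional closure probability is (m-k)/(C(n,2)-k) given degree k, and
degree-<2 nodes pull the mean down further); at m = 50 the gap is about
0.016, an order of magnitude beyond the Monte-Carlo standard error of a
2000-rep estimate. The null sampler itself is verified against an
independent G(n, m) sampler; the asymptotic identity should not be used
as a finite-n test.

## Baselines

Hierarchical clustering uses single linkage so the depth-threshold cut
equals connected components under `d < threshold` — the same edge rule as
the eigenvector pipeline, making the two methods comparable. Modularity
clustering is the deterministic greedy (Clauset–Newman–Moore) scheme; in
weighted mode, distances map to similarities `1/(1e-6 + d)` (no standard
convention exists; this one is monotone, positive and saturates at the
regularizer for exact ties). Temporal tracking matches clusters across
windows by greedy maximal Jaccard overlap, ties toward the lower previous
label, fresh labels for unmatched clusters.

## Statistics

Condition comparisons are two-sided paired Wilcoxon signed-rank tests at
alpha = 0.05, exact null for up to 25 nonzero differences, zeros dropped;
all-zero difference vectors are flagged degenerate instead of tested. No
multiple-testing correction is applied by default (per-pair tests are
reported as such); Holm adjustment is available. Event frequencies are
computed per trial and averaged per subject before testing.

## Problem sizes

The scripted scenarios run at their native sizes (8/15/27 oscillators,
2000-2500 steps, window 40, step 1). Oracle sweeps cover all 33,866
graphs on 2-6 nodes plus 500 random graphs on up to 12 nodes. The
parameter-recovery study uses 100 replicates of 3 conditions, 13 channels
x 5000 samples each; the random null uses 2000 repetitions at n = 32,
m = 50. Everything runs in a few minutes on a single CPU.
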