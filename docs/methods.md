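# Methods

## Scope and data model

`mfnet` analyses multichannel extracellular voltage recordings from planar
MEAs (default: 8×8 grid, 200 µm pitch, four corner sites absent, 60
electrodes) whose surface is partitioned by a dual-compartment microfluidic
chip. The default compartment map assigns, column by column: somatic
chamber (1–2), short microchannels (3), synaptic chamber (4–5), long
microchannels (6–7), empty output chamber (8). The layout is entirely
configuration-driven (JSON), so other chips are a config file away; the
default was chosen to give every compartment at least one electrode column
in the canonical left-to-right order of the dual-compartment design.
Columns 1–4 are re-referenced against reference channel R1, columns 5–8
against R2; reference channels are separate channels in the recording
container and never part of the analysis set.

## Preprocessing

Re-referencing subtracts the assigned reference channel sample-wise and
drops reference channels. Filtering uses a digital 4th-order Bessel
bandpass (200–3500 Hz), designed by bilinear transform with frequency
pre-warping (`scipy.signal.bessel`, phase-normalized). The default pass is
single and causal: zero-phase (forward–backward) filtering would smear
energy acausally and could corrupt the lead/lag relations that the delayed
correlation analysis interprets as propagation direction. A `zero_phase`
option exists for waveform-shape work. Filter onset transients are handled
by excluding an initial settling window (default 100 ms) from both
threshold estimation and detection. Re-referencing precedes filtering; the
two operations do not commute exactly, and this order removes the shared
artifact before it can ring through the filter.

## Spike detection

Per electrode, the threshold is ±k·MAD with k = 5, computed over the whole
(post-settle) trace. **MAD here is the normal-consistent median absolute
deviation**, median(|x − median(x)|)/0.6745, i.e. a robust estimator of
the noise standard deviation — the convention of standard extracellular
thresholding, where the median's insensitivity to the spikes themselves is
the point. The unscaled deviation (`mad_scale="raw"`) and the mean
absolute deviation (`mad_statistic="mean"`) are available as options.
The scaled default is a deliberate design choice: 5× the *unscaled* median
deviation is only ≈3.4 σ on Gaussian noise, which on a 200–3500 Hz band at
10 kHz yields several threshold crossings per second per channel (Rice's
formula; confirmed empirically), so pure-noise channels would exceed the
0.1 Hz activity criterion. At 5 σ the false-event rate is ≈0.008 s⁻¹ and
noise-only recordings are correctly silent.

Threshold polarity per electrode is the sign of the first threshold
crossing encountered (the first phase of the waveform); if no crossing
occurs the electrode is silent (negative polarity recorded by convention).
Timestamps are the crossing samples — not the extremum — and after each
accepted event further crossings are suppressed for a 3 ms dead time.
All-zero traces have zero MAD and are flagged degenerate rather than
raising. An electrode is *active* when count/duration ≥ 0.1 Hz
(boundary inclusive).

Waveform cutouts (default 1 ms pre / 2 ms post) support the per-compartment
waveform phenomenology: the amplitude coefficient of variation is low at
axonal (long-microchannel) sites where one unit dominates, and high at
proximal sites where several units of different amplitudes superpose.
Windows crossing the trace boundary are flagged and excluded from
statistics.

## Bursts

A burst is a maximal run of consecutive spikes whose interspike intervals
are all ≤ 100 ms. The bound is read inclusively, and ISI comparisons carry
a 1e-9 relative slack so that spikes exactly 100 ms apart (after float
subtraction) stay in one burst. The minimum spike count per burst is 2 —
the weakest reading of a "succession" of spikes — and configurable.
Because "burst rate" in Hz is ambiguous between bursts-per-second and the
spike rate inside bursts, `burst_stats` reports both: bursts/s per
electrode (averaged over active electrodes, burst-less electrodes
contributing zero) and the intra-burst spike rate (spikes in bursts per
total burst time). Mean burst duration averages over electrodes that have
bursts; burst-less electrodes are logged and excluded from that average.

## Cross-correlation

Spike trains are binned at 5 ms into half-open bins [k·b, (k+1)·b); the
bin index carries a 1e-9 relative slack so spikes at exact bin edges land
in the later bin, and a spike at exactly t = duration is kept in the last
bin so counts always sum to the spike count. For each pair the Pearson
correlation of the binned counts is computed for every lag within ±5 bins
(±25 ms, spanning both analysis windows) with overlapping-region
normalization. Zero-variance slices yield coefficient 0 with a validity
flag. From the lag profile the central-bin coefficient c₀ and the maximum
c_max with its lag are extracted; ties in the maximum break toward the
smallest |lag|, then toward the negative lag. Delays are signed, positive
when the first electrode leads; swapping the pair negates the delay and
preserves the coefficients. The correlation matrix orders electrodes by
compartment (somatic chamber, microchannels and synaptic chamber, empty
chamber) so compartment structure is visible as blocks.

Significance: the null hypothesis is generated by jittering every spike of
the second train uniformly within ±50 ms (wrapping at the recording
boundary, which maps a homogeneous Poisson train to another one of the
same rate), re-binning, and recomputing c_max. With n surrogates,
p = (1 + #{c_max,surr ≥ c_max,obs})/(n + 1); pairs with fewer than two
spikes on either train are flagged undefined. This replaces by a
reproducible procedure what would otherwise be a visual judgement of the
correlogram. The test is calibrated: on independent Poisson pairs the
empirical type-I error at α = 0.05 is within [0.03, 0.07] (the acceptance
suite measures it over 1000 pairs). No multiple-testing correction is
applied by default; when a whole array (~1.7k pairs) is screened for graph
construction, the graph-level α is set to 1e-3 — an order of magnitude
below the per-pair default of 0.01 — as a pragmatic Bonferroni-flavoured
guard that the scenario analyses and acceptance script use.

## Connectivity graphs

With 5 ms bins the two analysis windows coincide with bin boundaries: a
maximum in the central bin means |delay| ≤ 2.5 ms (short-term window,
undirected, stored with endpoints in canonical order); a maximum at lag
1–5 bins means a 5–25 ms delay (delayed window, directed from the leading
electrode under the assumption that a positive delay marks propagation
direction, possibly through hidden nodes). The windows partition the
significant pairs by construction — no pair can appear in both graphs.
Edges are classed by geometry with soma–neurite taking precedence whenever
an endpoint is somatic; neurite–neurite pairs are same-line (same row:
same or aligned microchannels), same-column (parallel microchannels), or
misaligned. Edge "length" is reported in electrode pitches
(max of row and column distance, the k of "n + k"). Node roles are
computed on somatic electrodes only — efferent (out-degree > 0, in-degree
0), afferent (the converse), mixed, isolated — with bare degrees reported
for non-somatic sites. Bidirectionally significant pairs keep both
orientations.

## Synthetic recordings

The generator emulates exactly the statistical structure the analysis
assumes, with known ground truth, and deliberately nothing more. Each
spike source is homed at an electrode and fires as a homogeneous Poisson
background superposed with burst trains (Poisson burst onsets; each burst
carries 2 + Poisson(mean − 2) spikes at a fixed intra-burst ISI with
relative jitter). Defaults — 35 ms intra-burst ISI, 7 spikes/burst —
give bursts of ~200 ms and an intra-burst spike rate of ~29 Hz, typical
for hippocampal cultures on MEAs. Waveforms are biphasic negative-leading
difference-of-Gaussians templates (1 ms width) with per-event amplitude
jitter; default peaks are −35 µV at somatic sites and −100 µV inside
microchannels, reflecting the sealing-resistance amplification of
high-impedance channels. Propagation edges deposit delayed, thinned
(transmission probability), rescaled copies of a source's events at target
electrodes. Noise is i.i.d. Gaussian per channel (default 2 µV raw);
no 50 Hz interference or drift is modelled since the bandpass removes
both by design. The sampling rate defaults to 10 kHz — typical for the
commercial amplifier class and ample for 200–3500 Hz content.

Randomness is keyed per channel, per source, and per edge from the
top-level seed (`SeedSequence([seed, namespace, crc32(id)])`), which makes
simulations reproducible and exactly linear: with zero noise, the sum of
single-source simulations is bit-identical to the joint simulation.

The canned dual-compartment scenario places a somatic chain source
(delays 6/12/18 ms into short microchannel, synaptic chamber, long
microchannel — one efferent node), three long-microchannel feeders onto
somatic sites (8/11/14 ms — three afferent nodes), a ~1 ms common drive in
the synaptic chamber (short-term synchrony), and six unconnected controls;
somatic rates sit in the 0.9–2.5 Hz range typical of hippocampal somas.
All true delays are resolvable by 5 ms binning.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: overlapping spikes from many units per
electrode, electrode drift, non-stationary rates, network-wide bursting
across electrodes, inhibition, stimulation artifacts, and spike-waveform
propagation shape changes. Results on real recordings depend on those
factors; the synthetic validation establishes correctness of the
computations, not field performance.

## Problem sizes and tolerances

Validation runs use the study-scale recording unit: 50 s, 60 channels,
10 kHz. The detection oracle check runs 100 random 10⁴-sample traces
against an exhaustive per-sample reference (exact match required); the
correlation oracle 500 random pairs against per-lag Pearson slices at
1e-12 relative tolerance; burst grouping 1000 random trains against a
quadratic reference; calibration 1000 independent pairs with 199
surrogates; graph recovery uses 2000 surrogates at graph α = 1e-3. The
noise-only control uses 20 seeds of the full 60-channel recording.
Reports are serialized with sorted keys and no timestamps so identical
inputs give byte-identical files.

## Known limitations

- Threshold crossings are multi-unit events; no spike sorting into single
  units is attempted, so per-electrode statistics conflate co-located
  units (by design, matching the analysis the package implements).
- The delayed-correlation direction rule cannot distinguish direct
  propagation from shared drive with unequal latencies; edges are
  "functional propagation", not synapses.
- Collective (network-wide) burst detection across electrodes is out of
  scope; no published rule exists for the highlighting convention it
  would replicate, so per-electrode bursts are the only burst statistic.
- With a common reference per column group, reference-channel noise is
  injected into all channels of the group; at realistic noise levels this
  is far below threshold but it does raise the effective noise floor by
  √2 versus an ideal reference.
- Vendor acquisition formats are not parsed; any channels × samples array
  with a sampling rate can be converted to the HDF5 container.
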