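# mfnet

Spike-train analysis for microelectrode-array (MEA) recordings of neural
cultures grown in microfluidic chips — and for the random cultures they are
compared against.

In a dual-compartment microfluidic design, somas are confined to large
somatic chambers while neurites explore narrow microchannels and a middle
"synaptic" chamber overlaid on an 8×8, 200 µm-pitch, 60-electrode array.
Because every electrode sits in a known compartment, functional connectivity
inferred from spike timing can be read back onto the circuit geometry:
which somas drive which microchannels, where signals mix, and which somatic
sites act as input (afferent) or output (efferent) nodes. `mfnet`
implements that analysis chain as a tested, reusable library with a CLI,
plus a synthetic-recording generator with full ground truth for validating
every stage.

## Analysis chain

1. **Re-referencing** — each electrode minus its column group's reference
   channel (columns 1–4 → R1, columns 5–8 → R2) to remove shared artifacts.
2. **Bandpass** — 4th-order Bessel, 200–3500 Hz (single causal pass by
   default so inter-electrode delays are preserved).
3. **Spike detection** — per-electrode threshold at ±5·MAD of the whole
   trace (MAD = normal-consistent median absolute deviation, a robust σ̂ of
   the noise); threshold polarity from the first crossing; 3 ms post-spike
   dead time. Electrodes with mean rate ≥ 0.1 Hz are *active*.
4. **Bursts** — maximal runs of spikes with interspike intervals ≤ 100 ms
   (inclusive), ≥ 2 spikes; burst rate and duration statistics.
5. **Cross-correlation** — spike trains binned at 5 ms; Pearson correlation
   of each electrode pair at lags within ±5 bins. The central bin c₀ and
   the maximum bin c_max with its delay are extracted; significance comes
   from spike-time jittering surrogates (±50 ms, rate-preserving).
6. **Connectivity graphs** — significant pairs maximal in the central bin
   (|delay| ≤ 2.5 ms) form the undirected *short-term* map; pairs maximal
   at 5–25 ms form the *delayed* map, directed from the leading electrode.
   Edges are classed by geometry (soma–neurite / same column / same line /
   misaligned) and somatic nodes by role (efferent / afferent / mixed /
   isolated).

## Worked example

The canned dual-compartment scenario simulates a somatic source feeding a
short microchannel, the synaptic chamber and a long microchannel with
6/12/18 ms cumulative delays, three long-microchannel sources feeding back
onto somatic electrodes, a zero-delay common drive in the synaptic chamber,
and six unconnected controls — all on top of 2 µV Gaussian noise.

```python
from mfnet import AnalysisConfig, build_default_layout, run_pipeline, scenario_dual_compartment

layout = build_default_layout()
rec, truth = scenario_dual_compartment(seed=1)
report = run_pipeline(rec, layout, AnalysisConfig(n_surrogates=1000, alpha=0.001, seed=1))

print("active electrodes :", report["n_active"])
print("delayed edges     :", report["delayed_graph"]["n_edges"])
for e in report["delayed_graph"]["edges"]:
    print(f"  {e['from']} -> {e['to']}  delay {e['delay_ms']:.0f} ms  ({e['class']})")
```

prints

```
active electrodes : 19
delayed edges     : 9
  14 -> 34  delay 5 ms  (soma_neurite)
  14 -> 44  delay 10 ms  (soma_neurite)
  14 -> 64  delay 20 ms  (soma_neurite)
  62 -> 22  delay 10 ms  (soma_neurite)
  75 -> 25  delay 10 ms  (soma_neurite)
  67 -> 27  delay 15 ms  (soma_neurite)
  34 -> 44  delay 5 ms  (same_line)
  34 -> 64  delay 10 ms  (same_line)
  44 -> 64  delay 5 ms  (same_line)
```

Exactly the 19 electrodes carrying programmed activity are active; every
true propagation pair is recovered with the correct orientation and a delay
matching the programmed one to the 5 ms bin; electrode 14 is the single
efferent somatic node and 22/25/27 are the afferent ones
(`report["node_roles"]`). The three ~1 ms common-drive pairs appear only in
the short-term map.

The same stages are available from a shell:

```sh
mfnet layout --default > layout.json
mfnet simulate --scenario dual --seed 1 --out rec.h5
mfnet run rec.h5 --layout layout.json --out results/
```

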