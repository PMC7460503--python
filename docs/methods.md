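# Methods

This note records the model, the synthetic-data design, the numerical
choices and the limitations of `gaitphase`, in the package's own terms.

## Classification task

Four gait phases — heel strike (HS, code 0), flat foot (FF, 1), heel off
(HO, 2), swing (SW, 3) — are decoded from triaxial calf acceleration
sampled at 200 Hz. An example is a sliding window of `S·L = 8·25 = 200`
samples (1 s) advanced by 5 samples, labeled with the phase of its final
sample: the label a real-time controller needs *now*. Windows never cross
recording boundaries. The 70/30 train/test split is window-level random by
default; a subject-level mode is provided because window-level splitting
lets a model exploit subject identity (windows from one subject appear on
both sides), which inflates absolute scores — the comparisons between
variants are unaffected since all variants share the split.

## Network

The full model runs a three-layer valid CNN over each 5×5×3 sub-window map
(4×4/20 → 2×2×20, 2×2/5 → 1×1×5, 1×1/1 → 1×1×1, ReLU), feeds the
concatenated flattened codes of the last two layers (6 features per
sub-window) to an LSTM with 36 units, and classifies from the
concatenation of the LSTM output with the raw flattened window (600
values) through FC(160) → FC(60) → FC(4) → softmax. Design points that
were genuinely open:

* **Window geometry.** The architecture table fixes the conv shapes
  (a 4×4 valid kernel producing 2×2 implies a 5×5 input map) but not how a
  1-D triaxial stream becomes 2-D. We reshape each 25-sample block
  row-major to 5×5 with the axes as channels and use 8 blocks (1 s of
  context). All of this is configurable (`WindowingSpec`).
* **Middle conv layer.** A 1×1 kernel cannot map 2×2 → 1×1 at stride 1;
  the layer uses a 2×2 kernel, honoring the published feature-map column.
* **CNN↔LSTM wiring.** Serial: conv codes are the LSTM's inputs, and only
  the raw window rides the skip path into FC1. A parallel CNN/LSTM fusion
  would contradict the skip definition `concat(o_lstm, x)`.
* **LSTM input width.** Concatenating the flattened outputs of conv
  layers 2 and 3 (5 + 1 = 6 features) uses all three layers and avoids a
  one-scalar bottleneck.
* **Batch-norm placement.** On every conv and FC pre-activation (never on
  the raw skip path), ε = 1e-5, population (1/m) batch variance, running
  statistics with momentum 0.9 for inference.
* **Head activations.** FC(160) and FC(60) use leaky ReLU (slope 0.01);
  the final 4-unit layer is linear into the softmax.
* **Initialization.** Fan-in-scaled uniform, seed-controlled. Batch size
  64. Plain SGD at lr 0.05; the full protocol is 10 000 iterations and the
  scaled runs below use 2 000.
* **LSTM activation.** The cell activation is ReLU by default (applied to
  the candidate and the cell output; gates stay sigmoid, with the 0.7
  forget-bias offset added to the forget-gate pre-activation).
  Empirically the 200-step raw-sequence baseline diverges with ReLU at
  lr 0.05 — a known failure mode of unbounded recurrences — so the `lstm`
  baseline uses the standard tanh cell
  (`ExperimentConfig.lstm_baseline_activation`); the hybrid variants keep
  ReLU over their stable 8-step code sequence. Training aborts with a
  diagnostic if the loss turns non-finite.

Ablations: `no_skip` removes the skip concatenation (FC1 input dim 36),
`lstm_cnn` removes skip and batch norm, `lstm` is the raw-sequence
recurrent baseline (LSTM(36) → FC(60) → FC(4)).

All layers are NumPy with hand-written backward passes. Gradient
correctness is established by central finite differences per layer and
through every parameter tensor of every full variant (tanh configurations,
so the difference quotient is valid). Replicate runs (several seeds ×
speeds) can execute as one *stacked* model whose parameters carry a
leading member axis; members are initialized, batched and updated exactly
as individual runs and the test suite asserts bit-identical results, so
stacking is purely an execution strategy for single-CPU throughput.

## Synthetic data

The generator emulates steady treadmill walking as the study protocol
describes it; acquisition transients, rests and ramp-ups are out of scope
(the protocol discarded them).

* **Phase schedule.** Cycle length `round(fs / cadence)` samples; default
  phase fractions (0.08, 0.32, 0.20, 0.40) — the stance/swing 60/40 split
  is documented, the within-stance split is a design choice that makes HS
  the short, hard class, matching the published confusion structure. HS,
  FF and HO get `round(fraction × cycle)` samples, SW the remainder (equal
  to its own rounded share under the defaults).
* **Cadence.** 0.9 cycles/s per m/s of speed (≈0.7–1.1 Hz over the study
  speeds); the study reports no cadence, so this is a configurable choice
  in the normal-walking range.
* **Waveforms.** Per (phase, axis): a Gaussian bump plus one sinusoid over
  within-phase progress τ ∈ [0, 1), with fixed constants shaped like calf
  accelerometry (impact spike at HS, quiet FF plateau, push-off ramp at
  HO, smooth pendular SW). τ is defined against the nominal phase duration
  so truncated trailing phases keep the same waveform. With zero noise the
  signal is exactly cycle-periodic (tested to 1e-9).
* **Noise.** Additive AR(1), coefficient 0.9; `noise_sd` = 0.05 g is the
  *stationary* standard deviation (innovations scaled by √(1−0.81)). The
  high AR coefficient mimics the smoothness of Kalman-filtered sensor
  output.
* **Envelope.** Samples are clipped to −1…2 g, the range the original
  sensors observed, not their ±16 g span.
* **Subjects.** Per-axis amplitude multipliers ~ U(0.8, 1.2) and ±5%
  cadence jitter per subject; repeats share the subject's morphology but
  have independent noise and are separate recordings.

What the generator does **not** emulate: aperiodic events (turns,
stumbles), sensor-placement drift, inter-cycle waveform variability beyond
noise, gyroscope channels, pathological gaits. Phase boundaries here
coincide with template changes, which makes the classification easier than
on real data: passing the end-to-end thresholds demonstrates that the
pipeline learns and that the variant *ordering* (full model > ablations >
plain LSTM) reproduces, not that real-data accuracies would be attained.

## Evaluation calculus

Confusion matrices have true classes on rows, predictions on columns,
order HS, FF, HO, SW. Per class, one-vs-rest P, R and F1 = 2PR/(P+R) in
percent; 0/0 → 0 (the convention that reproduces the published zero rows
for baselines that never predict HS). Accuracy = 100·trace/total. Macro-P
and macro-R are unweighted class means; macro-F1 is their harmonic mean —
deliberately *not* the mean of per-class F1, following the published
definition. ROC curves enumerate every distinct score threshold
(descending, trapezoidal area); macro-AUC is the unweighted mean of the
four one-vs-rest AUCs, with absent classes excluded under a warning.
Reports round percentages to one decimal.

The published-results checker recomputes every derivable table value:
F1 cells named in the study's text (the FMS-Net HS rows 63.7/76.6/54.9 and
the cross-speed averages 65.1/89.5/72.4/71.4) must match exactly at the
printed precision; the remaining F1 cells are recomputed from *rounded*
published P/R and may differ from the printed value by up to one unit in
the last digit (±0.05 input rounding propagates to ~±0.05 in F1), so they
are checked with tolerance 0.1. Seven of 36 cells in fact differ by
exactly 0.1, confirming the original values were computed from unrounded
internals.

## Scaled protocols and determinism

The full protocol (16 subjects, three 120 s walks per speed, 10 000
iterations) is the `ExperimentConfig` default. Routine verification uses
two scaled presets chosen to keep a complete run on one CPU in the
minutes range while leaving thousands of windows per speed: `acceptance`
(4 subjects, one 60 s walk per speed, 2 000 iterations, batch 64) and
`smoke` (one speed, 2 subjects, 20 s, 500 iterations). Every stage —
simulation, windowing, split, initialization, batching — draws from seeds
derived from one master seed via a hash, so a repeated run emits
byte-identical reports; all derived seeds stay below 2³¹.

Numerics: float32 parameters and activations for training (float64
available, used by the finite-difference tests); softmax is stabilized by
max subtraction; cross-entropy clamps probabilities at 1e-12; argmax ties
break to the lowest class index; BN in training mode requires m ≥ 2.

## Known limitations

* Synthetic difficulty is below real data; absolute scores near 100% on
  the synthetic cohorts are expected and only orderings and learning
  behavior transfer.
* The exact CNN↔LSTM wiring of the original implementation is not
  recoverable from its description; the serial topology here is the one
  consistent with the skip definition.
* The raw-skip vector is unnormalized by design (BN inside the network
  handles scale); extremely different sensor scales would require input
  standardization.
* Plain SGD without clipping is faithful to the description but fragile at
  high learning rates; the divergence diagnostic names the remedies.
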