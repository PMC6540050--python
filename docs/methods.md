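# Methods

## Signal model and generator

Skin conductance (μS) is modelled as tonic level plus phasic
skin-conductance responses (SCRs) plus sensor noise. The generator does
not model the physiology beyond what the extraction needs: it consumes any
single-channel conductance series with a known sampling rate.

The extraction pipeline is deterministic in the input samples:

1. **Resampling.** Rational polyphase resampling (`scipy.signal.
   resample_poly`, Kaiser-windowed FIR) to the 128 Hz working rate, with
   `padtype="line"` so boundary transients do not corrupt short records
   and DC maps to DC exactly. Output length is ⌈n·up/down⌉ for the reduced
   ratio up/down. Up-sampling is refused — acquisition rates at or above
   128 Hz are assumed.
2. **Low-pass filter.** Zero-phase (forward–backward) Butterworth,
   order 4, cutoff 60 Hz. Zero phase matters because the Hilbert step is
   phase-sensitive. At the 128 Hz working rate the 60 Hz cutoff sits just
   below the 64 Hz Nyquist frequency, so the filter is nearly all-pass;
   it is implemented as specified, and both cutoff and order are
   configurable for users who want a meaningful band limit.
3. **Windowing.** Non-overlapping windows of `window_seconds × fs`
   samples (default 4 s × 128 Hz = 512); the trailing partial window is
   discarded and reported. Each window is processed independently.
4. **Hilbert transform.** FFT-based discrete analytic signal per window,
   no tapering; the edge distortion of the FFT method is accepted as part
   of the construction. The imaginary part is the −90°-shifted signal.
5. **Digitisation.** Per value v: u = ⌊|v|·s⌋ (C-style truncation;
   `nearest` selectable), reduced modulo 2³² (unsigned-cast semantics),
   then byte = u mod 256 (`lsb`, default) or u ≫ 24 (`shift24`).
   Truncation adds a 10⁻⁶-count tolerance so decimal values such as
   1.234567 scale to exactly 1234567 despite binary float representation.

### Digitiser constants

The scale factor defaults to 10⁶: the digitiser's purpose is to promote
the sixth decimal place of a μS-scale value — where sensor/ADC noise
lives — above the byte boundary. With a small scale (10²) the shift24 mode
maps every μS-scale value to byte 0 (u < 2²⁴), which is why `lsb` + 10⁶ is
the default and the literal `shift24` + 10² combination is kept only to
demonstrate that degeneracy (see the mode-sensitivity regression test).

## Synthetic EDA simulator

`synthetic.SimConfig` defaults define the simulated cohort:

| parameter | default | why |
|---|---|---|
| native_fs_hz | 512 Hz | typical research-grade acquisition rate, ≥ 128 Hz |
| baseline_us | 2 μS | mid-range resting skin conductance |
| drift_amplitude_us / drift_period_s | 0.3 μS / 60 s | slow tonic wander |
| scr_rate_per_min | 3 | spontaneous SCR rate of an awake subject |
| scr_rise_s / scr_decay_s | 0.75 s / 3 s | canonical bi-exponential SCR shape |
| scr_amp_mean_us | 0.4 μS | exponential amplitude distribution |
| noise_sd_us | 0.01 μS | sensor noise floor |
| adc_bits / adc_range_us | 10 bits / 25 μS | low-cost acquisition ADC |

SCRs arrive as a Poisson process; each adds an amplitude-scaled
bi-exponential kernel k(t) = exp(−t/decay) − exp(−t/rise), normalised to
unit peak (the peak location has the closed form
t\* = ln(decay/rise)·rise·decay/(decay−rise)). The drift phase is random
per subject, and the drift period is drawn uniformly in [0.5, 1.5]× the
nominal period: tonic drift has no fixed clock, and a period shared
coherently across subjects would make cohort records mutually correlated,
violating the simulator's contract of statistically independent subjects.
The ADC stage clips to [0, adc_range] and rounds to the
adc_range/2^bits grid; quantised sensor noise is the physical entropy
carrier the LSB digitiser harvests. Per-subject seeds derive from the
master seed through `numpy.random.SeedSequence((master, index))`.

What the simulator does **not** model: emotional/stimulus structure,
motion artifacts, electrode drift and detachment, inter-subject
physiological diversity beyond seed-driven variation, and any coupling
between subjects. Tests passing on simulated cohorts therefore establish
that the pipeline and battery behave correctly on signals with the stated
statistical structure — not that any particular real recording yields
full-entropy output. With the default 0.01 μS noise floor (below half a
quantisation step) the digitiser output is *not* guaranteed near-uniform;
the documented operating condition for full-entropy output is sensor
noise ≥ 4 quantisation steps (≈ 0.1 μS at the 10-bit/25 μS defaults),
under which pooled cohort output reaches ≥ 7.9 bits/byte over ≥ 1 MB.

## Evaluation battery

**ENT-style statistics.** Entropy is the Shannon entropy of the empirical
byte distribution; optimum compression = (8 − H)/8 × 100 by definition.
The χ² exceed percentage uses the exact χ²₂₅₅ survival function, not a
lookup table. Serial correlation is circular (last byte pairs with
first) and flagged undefined for zero-variance streams. Monte-Carlo π
maps 6-byte groups to 24-bit coordinates and tests
x² + y² ≤ (2²⁴−1)² in integer arithmetic, making the boundary exact.

**Min-entropy.** Estimated on the bit serialisation (MSB-first).
Probability upper bounds use the 99% normal bound
p̂ + 2.576√(p̂(1−p̂)/(n−1)). For a binary source the mean
time-to-first-collision over disjoint scans is exactly 2 + 2p(1−p), so
the collision estimate inverts that closed form at the lower confidence
bound of the observed mean; when the bound exceeds the curve's maximum
2.5 (e.g. a strictly alternating input, where every scan takes three
symbols) no solution exists and the estimator returns the conservative
fallback of 1 bit/bit — alternation is instead caught by the Markov
estimate, which upper-bounds the probability of the most likely 128-step
path of a first-order chain (dynamic programme; verified against
exhaustive path enumeration at short lengths). The overall assessment is
the minimum of the three estimates. Below 10⁴ bits a warning is raised.

**Restart check.** The matrix (row i = first c outputs after restart i) is
assessed in row-major and column-major order with the full three-estimator
minimum; the check fails when either order falls below half the row-major
baseline, or the baseline itself is below 0.01. The order-sensitive Markov
estimate is what makes the column reading collapse when restarts replay
the same sequence; a frequency-only statistic would be permutation
invariant and blind to this failure mode. The half-the-baseline threshold
is this package's own simplification of the full SP 800-90B restart
procedure.

**SP 800-22 subset.** Frequency, block-frequency (default block length
128) and runs tests in their standard closed forms. The multi-sequence
rule floors K·((1−α) − 3√(α(1−α)/K)) to a count — 96 at α = 0.01, K = 100
(the un-floored value is 96.015). P-value uniformity per test uses the
one-sample KS test against Uniform(0, 1).

**Cross-subject.** Hamming distances pair words positionally (word i vs
word i) after truncating to the shortest whole-word length; goodness of
fit to Binomial(m, ½) pools bins from both tails until each expected
count is ≥ 5 (standard χ² validity rule).

**Cipher demo.** NPCR/UACI thresholds come from the normal approximation
to the two-independent-uniform-images null: NPCR critical value
100·(F − z_α√(F/MN))/(F+1); UACI mean (F+2)/(3F+3) and variance
(F+2)(F²+2F+3)/(18(F+1)²F·MN), bounds at z_{α/2}. A plain XOR stream
cipher has no diffusion — one flipped plaintext bit changes exactly one
ciphertext pixel — so the diffusion experiment offers both the literal
shared-keystream mode (which fails NPCR by construction, and is reported
as such) and an independent-keystream-per-plaintext mode, which realises
the two-independent-uniform-ciphertext regime the thresholds describe.

## Numerical and scale choices

- All statistics are deterministic functions of their input stream; all
  simulation randomness flows from one integer seed.
- Statistical tests in the suite run at desk scale chosen so each check's
  Monte-Carlo error is well inside its tolerance: 1 MiB byte streams for
  ENT/min-entropy regimes, 100 × 10⁵-bit sequences for the pass-rate
  rule, 10 × 800 KB streams (4.5 × 10⁶ word pairs) for the Hamming null,
  200 seeds for simulator moment recovery.
- Estimates are clipped to their domains ([0, 1] bits/bit, [0, 8]
  bits/byte); degenerate inputs (constant streams, unreachable Markov
  states, empty transition rows) take the conservative branch rather
  than raising.

## Known limitations

- Only three of the ten SP 800-90B estimators and three of the fifteen
  SP 800-22 tests are implemented in-package; the bitstream export is the
  supported path to the official external suites for the rest.
- The 60 Hz/128 Hz cutoff/rate combination makes the low-pass nearly
  inert; it is kept for fidelity to the generator's definition.
- The simulator is a testing instrument, not a fitted model of any real
  EDA dataset; absolute entropy figures on real recordings depend on the
  real sensor's noise floor and ADC, which only hardware can supply.
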