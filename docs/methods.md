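# Methods

## Scope

`pspwedge` is a synthetic re-creation of a bench experiment on
ambient-light fading of photostimulable phosphor (PSP) plates: step-wedge
radiographs whose lateral halves received different light exposure before
read-out, compared through image-quality metrics, paired-half
discrepancies, and a two-way ANOVA/Tukey analysis. Everything is
simulation: no scanner hardware, photometry, or diagnostic-task evaluation
is modelled, and the published table values from physical plates are not
reproduction targets — the package reproduces the *structure* and the
*qualitative* findings (direction and significance of effects, saturation
counts) at desk scale.

## Forward model

For a pixel under `d` mm of aluminium, acquired at exposure time `t` with
light duration `t_L` on the exposed half:

    S = DAP_rate · t · e^(−μ d) · e^(−t_L/τ)      (fading term on the exposed half only)
    GV = clip(round(b₀ − g·log₁₀(S + s₀)) , 0, 255)

with optional additive zero-mean Gaussian noise (σ, gray values) added to
the analog response before quantization.

Assumptions and their motivation:

- **Mono-exponential fading** `e^(−t_L/τ)`. Latent-signal loss in storage
  phosphors is exponential in time; a bi-exponential (fast+slow trap
  populations) would add parameters nothing in the analysis can
  constrain.
- **Logarithmic inverted response.** Two observed facts force the shape:
  dark saturation (MGV ≤ 1) occurs at the *longest* exposures, and light
  exposure *raises* MGVs. The simplest response with both properties is
  an affine function of log-signal with negative slope. Real read-out
  electronics are proprietary; this is an effective model, not a claim
  about hardware.
- **Additive Gaussian gray-scale noise.** The analysis needs nonzero ROI
  SDs and replicate scatter; a full signal-dependent (quantum + structure)
  noise model is out of scope. One consequence is directional: because
  fading raises MGV while σ stays fixed, simulated SNR *rises* with light
  duration, whereas physical plates show SNR falling. No packaged
  analysis target depends on this direction; treat simulated CNR/SNR
  trends as placeholders, not physics.
- **Quantization** is round-half-away-from-zero then clip, stated so that
  renders are bit-reproducible across platforms.
- **No** scatter, blur/MTF, plate wear, scan-direction artifacts, or
  delayed-scan (dark) fading.

## Geometry

Default plate: 300 × 540 px, nine steps of 1..9 mm as 30-row horizontal
bands (rows 15–285) spanning columns 30–510; pixels outside the wedge are
bare plate (0 mm). Columns split at 270 into the covered (left) and
light-exposed (right) halves, so each step crosses both halves. One ROI
per step × half — 18 per image — is the step∩half rectangle inset by a
4 px margin (the source experiment does not report ROI dimensions; the
margin is config-pinned and results at desk scale are insensitive to it).
ROI statistics use the sample SD (n−1), the ImageJ convention.

## Parameters and calibration

All constants live in `src/pspwedge/data/default_config.yaml`; none are
observable from published summary data, so they are calibration choices,
made once by constraint analysis on the log response and then frozen:

| parameter | vistascan_like | express_like | meaning |
|---|---|---|---|
| μ (1/mm) | 0.28 | 0.28 | effective Al attenuation |
| DAP rate (mGy·cm²/s) | 219.3 | 219.3 | implied by 21.93 mGy·cm² at 0.10 s |
| g (gv/decade) | 95 | 148 | inverse dynamic range |
| b₀ (gv) | 212 | 264 | response intercept |
| s₀ | 0.5 | 0.5 | signal floor (low-dose roll-off) |
| σ (gv) | 2.0 | 2.0 | read-out noise |
| τ (s) | 300 | 480 | light-fading time constant |

The express-like profile is calibrated so that, noise-free, the two
thinnest steps dark-saturate (MGV ≤ 1) at 0.50 s with ≥3 gray values of
margin at every threshold, and 90 s of light un-saturates exactly one of
them; one step also dark-saturates at 0.40 s, and no condition produces
bright saturation (MGV ≥ 254). The vistascan-like profile encodes a wider
dynamic range (smaller g): no saturation at any design condition. The
exact proportionality `DAP = 219.3 · t` is treated as ground truth; the
physically printed per-exposure DAP readings scatter ≤ 0.03 mGy·cm² from
it (dose-meter rounding) and are carried as documentation only.

Seeding: each factorial cell derives a 31-bit seed from
SHA-256 of `"{root_seed}|{system}|{exposure:.6g}|{light:.6g}|{repeat}"`,
so any cell re-renders identically in isolation and full reruns are
byte-identical.

## What the generator does and does not emulate

It emulates: the graded attenuation series, system-dependent dynamic
range and dark saturation, monotone light-induced brightening, replicate
scatter, and the balanced 2 × 5 × 6 × 10 design. It does not emulate:
absolute discrepancy magnitudes of physical plates (τ and the signal
units are unidentifiable from published summaries), the decrease of
CNR/SNR under light, exposure-dependent brightness-discrepancy profiles
beyond the saturation mechanism, or plate-to-plate variability (repeats
are i.i.d. noise realizations). Passing tests therefore demonstrate
correctness of the measurement/statistics machinery and qualitative
fidelity of the saturation and fading mechanisms — not quantitative
agreement with any physical system.

## Statistical procedure

Per system × metric (brightness and contrast by default, the metrics the
source analysis transformed): per-repeat discrepancies are Box-Cox
transformed at fixed λ (0.5 / 0.5 for brightness; 0.5 VistaScan-like,
0.35 Express-like for contrast). λ is deliberately *not* re-estimated per
dataset — the analysis treats it as part of the protocol. The balanced
two-way fixed-effects ANOVA (light × exposure + interaction) is fitted via
statsmodels OLS; repeats are independent observations. Tukey HSD uses
`q = |m_i − m_j| / √(MS_res/n)` against the studentized-range distribution
with the *pooled* residual (df = N − ab) of the full model, sliced two
ways: light levels within each exposure (uppercase letters) and exposure
levels within each light duration (lowercase). The slicing convention is
a design choice — the source tables do not state theirs — and reproduces
their two letter families. Compact letter displays use insert-and-absorb;
letters are assigned in ascending order of means ('A' = smallest,
matching the tables, where the no-light control reads 'A'), ties broken
by factor-level order. p-values below 10⁻⁴ print as "<0.0001".

Degenerate inputs: noise-free ROIs have SD = 0, so CNR/SNR are undefined
there; they propagate as missing values and a condition needs ≥ 2 defined
repeats to aggregate (under default noise this occurs only for SNR in the
express-like 0.50 s arm, whose dark-saturated ROIs are exactly constant;
those conditions report NaN with a warning). Box-Cox inputs must be
positive — with noise enabled, discrepancies are almost surely positive.

## Numerical choices

- ROI means/SDs in float64; saturation thresholds applied to un-rounded
  ROI means (steps, not pixels, are counted as saturated).
- Contrast and the CNR aggregate use *absolute* adjacent differences:
  signed differences would telescope contrast to (step9 − step1)/8 and
  defeat its use as a nine-step metric; for monotone step MGVs the two
  conventions coincide.
- The absolute value in the discrepancy is taken per repeat, before
  averaging.
- The fading time constant is recoverable from rendered images: invert
  the response on every exposed-half step that stays inside (1, 254)
  across a 0–90 s duration grid (3 s steps), regress log-signal on
  duration per step, average slopes. With 8-bit quantization as the only
  error source both default profiles recover τ to ~0.1% (tested bound:
  1%).
- ANOVA requires a complete, balanced layout with ≥ 2 replicates per
  cell and raises otherwise; the manifest guarantees balance.

## Problem sizes

The default study (600 images of 300 × 540 px plus the full analysis)
runs in well under a minute on one CPU; the test suite uses the full
design for end-to-end checks and a 2 × 2 × 3 × 2 scaled design for
determinism and CLI checks. These sizes are the package's chosen desk
scale for a fully synthetic factorial.

## Known limitations

Beyond the generator gaps above: the letter-display slicing uses one
pooled error term for both families (a simple-effects convention; a
cell-means model with per-slice errors would differ); fading is applied
uniformly across the exposed half (no penumbra at the paperboard edge);
and the 8-bit PGM export discards nothing from the simulation but is
narrower than the 16-bit RAW of real scanners.
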