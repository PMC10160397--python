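# Methods

This note documents the model as implemented: the numerical scheme, the
parameter choices, the places where the design was genuinely open and
what was decided there, what the synthetic stimuli do and do not
emulate, and the known limitations.

## Fractional membrane dynamics

Every dynamic layer has the affine conductance form

    D^α x = A(t) − B(t)·x,     A = g_leak·V_rest + Σᵢ inputᵢ·batteryᵢ·gainᵢ,
                               B = g_leak + Σᵢ inputᵢ·gainᵢ,

with a common order α (default 0.4; α = 1 recovers ordinary membrane
dynamics). The operator is discretized by the Grünwald–Letnikov sum
applied to the deviation from the initial state x₀ (the Caputo reading,
under which constants have zero derivative and a displaced state relaxes
along the Mittag-Leffler curve E_α(−t^α)):

    x_n = (x₀ + h^α·A − Σ_{k≥1} c_k (x_{n−k} − x₀)) / (1 + h^α·B),
    c_k = (−1)^k·binom(α, k)   (c₀ = 1, c_k < 0 for k ≥ 1).

The right-hand side is treated semi-implicitly: the state enters
linearly, so the implicit solve is a division. This is unconditionally
stable for B ≥ 0 — which matters, because the summing layer's inhibitory
conductance reaches ε_in·Ī ≈ 300. At α = 1 the scheme is exactly the
backward-Euler step and the initial-condition correction cancels.

Numerical accuracy: against a truncated Mittag-Leffler power series the
scheme is within 10⁻² for t ≥ 1 at h ≤ 0.1 on the unit relaxation
problem; the first-order product formula cannot resolve the t^α
singular layer at t < 1 at any practical step, and fractional
relaxation approaches its fixed point only as t^{−α}/Γ(1−α), so
slow-conductance fixed points are approached to a few percent over a
few hundred frames while the network's own layers (B ≈ 30) settle to
well under 1% within tens of frames.

Choices: h = 1 frame (the reference constants are unitless; the 33.3 ms
sampling interval is the unit of time); all membranes seeded at V_rest
with the history buffer initialized accordingly; full history retained
by default (runs are a few hundred frames — `memory_window` enables the
short-memory truncation for longer inputs, at an error that is
negligible for B ≈ 30 conductances but substantial for slow unit-scale
relaxations).

## Parameters

Defaults follow the reference table: α₁ = 0.4, V_th1 = V_th2 = 5·10⁻⁴,
E_ex = 1, λ_ex = λ_in = 1.2, γ₁ = γ₂ = 150, ε_ex = 1, ε_in = 100,
δ_ex = 1.5, m = 1, F₁ = 5, σ₁ = 0.3, F₂ = 1, σ₂ = 0.4,
ξ_ex = 5·128²/n², μ = {1, 1, 0}. Ranged parameters are pinned mid-range
(g_leak = 30, V_rest = 0, E_in = −0.5, β_on = β_off = 1.1) and values
outside their reference range raise a warning, not an error. Luminance
is normalized to [0, 1] on load (thresholds of order 10⁻⁴ are consistent
with O(1) inputs through gains of order 1).

The Gaussian kernels are evaluated literally as
G(x, y) = F/(2πσ²)·exp(−(x²+y²)/(2σ)) on a 3×3 (G₁) and 5×5 (G₂)
integer grid; `kernel_exponent_variant="sigma_squared"` switches to the
conventional 2σ² denominator. Convolution uses replicate padding so a
uniform field stays uniform at the borders.

## Design decisions where the literal equations are ambiguous or unstable

Four switches control departures from the most literal reading; their
defaults are the configuration in which the network actually exhibits
the documented behaviors, and each can be flipped back.

**ON-channel summing battery (`on_inhibition_excitatory`, default True).** The
literal ON summing equation gives its second synaptic term the
excitatory battery E_ex. The "corrected" symmetric alternative (E_in in
both channels) turns out to silence the entire network: the inhibitory
path is fast (g_leak = 30 settles within a frame) and un-delayed in its
nearest-neighbor term, and with kernel mass ≈ 16.8 and ε_in = 100 it
outweighs the excitatory conductance ≈ 20–40-fold for *any* input, so
both summing channels are pinned below zero and rectified away. As
formulated, the ON channel saturates toward E_ex and carries a compressed
copy of local activity, the OFF channel stays competitive, and the
correlation layer receives usable structure. The literal equation is
therefore the default.

**LGMD input rectification (`rectify_lgmd_input`, default True).** The
grid sum R1 is signed. Fed literally into the conductance term, a
negative R1 with |ξ_ex·R1| > g_leak makes the total membrane
conductance negative; the continuous equation is then unstable and the
discrete solve lands on its spurious positive equilibrium — channels
with strongly *anti*-preferred drive would report the largest rectified
output. A synaptic conductance cannot be negative, so the drive is
clamped at zero by default; the preferred channel (positive R1) is
unaffected.

**Correlator orientation (`offset_sign`, default −1).** The direction
layer correlates S at (i, j) and time t with S at the displaced pixel
two frames earlier. For motion along θ, the two-frame-old matching
signal lies *upstream* (at −m along θ), so the default displaces
against θ; the literal orientation (+1) responds to motion
opposite to its label.

**Diagonal sampling (`interpolate_diagonals`, default True).** Rounding
the diagonal displacement to the integer 8-neighborhood gives those
channels a √2-times longer baseline; under strong noise they then
outgrow the true cardinal channel. Bilinear sampling at the exact
distance m equalizes all 8 channels.

## Velocity tuning of the direction layer

The correlation `S(t)·S_up(t−2) − S(t−1)·S_up(t−1)` with displacement m
is a matched filter for patterns that travel m pixels per 2 frames:
the detector's preferred speed is **m/2 = 0.5 px/frame** with the
reference m = 1. At exactly 1 px/frame the two products cancel
identically on the pixel lattice (the pattern repeats every frame up to
an integer shift), and above it the delayed product finds no match, so
cardinal channels go silent. Direction experiments in the tests and the
acceptance script therefore translate objects at the matched speed.
Objects are rasterized with exact area coverage (anti-aliasing), so
sub-pixel positions are meaningful — as they are for a camera
integrating over pixel footprints.

Why looming peaks at the collision frame: an expanding dark square
drives edge transients everywhere, and once it fills the field the
membrane fields settle along power-law curves. A log-convex relaxation
a(t) satisfies a(t)a(t−2) > a(t−1)², so during settling *every*
direction channel receives positive drive at once — the collision
spike. Exponential settling (α = 1) makes this term vanish, which is
why the fractional network's peak dominates the integer-order one on
the same input.

## Motion-direction estimate

The local angle field is the two-argument arctangent of the θ = π/2 and
θ = 0 correlation outputs, folded to [0, 2π); the global estimate MD(t)
is the mode of the masked angles quantized to the 8 canonical
directions (ties toward the smaller angle; undefined when no pixel
passes the mask). The mask keeps pixels whose correlation energy
exceeds max(energy_floor, 10% of the frame's peak) — with a purely
absolute floor, the sea of near-zero background drift swamps the mode.

Limitation: this two-channel readout is the network's weakest output.
For cardinal motion it lands on the true octant on roughly half of the
frames (the anti-aliased rasterization alternates the correlation
field's fine structure with sub-pixel phase), and for diagonal motion
the two channels' lobes misalign and the mode is unreliable. The robust
direction readout is the per-θ tuning curve (time-integrated rectified
LGMD output), which recovers all 8 directions cleanly down to SNR 5 dB.

## Synthetic stimuli

The generator reproduces the simulated test conditions: 128×128 frames
at a 33.3 ms nominal interval; a centered dark square growing linearly
until it fills the field at a known frame (the ground-truth collision
time, after which frames are constant); its exact time reverse
(receding); and fixed-size blocks or bars translating at constant speed
along one of the 8 canonical angles, with additive zero-mean Gaussian
noise calibrated in dB against the temporal-variance signal power and
clipped to [0, 1]. Problem sizes used by the tests: 128×128×60 for the
system-level checks, 32–64 px grids for unit-level properties.

What the generator does not emulate: perspective, texture, cluttered or
moving backgrounds, luminance adaptation, camera noise other than
additive Gaussian, or objects that change speed. Passing the suite
shows the network's selectivity on clean geometric stimuli with known
ground truth; it does not certify performance on natural video.

The receding omnidirectionality check shrinks the square at ~1 px/frame
edge change (0.5 px/frame per side — the matched speed); a fast shrink
leaves the correlator unmatched and the network silent, which is itself
the expected velocity-tuning behavior.

## Other numerical choices

- First frame: L(t−1) is defined as L(1), so runs start from a
  motionless view rather than a spurious full-field transient.
- Off-grid correlation partners contribute 0; test objects stay ≥ 5 px
  from borders.
- Collision report: peak frame is the earliest argmax of
  C(t) = Σ_θ L̂1(t, θ) (the single-trace aggregation is a documented
  choice; expansion drives all channels, so the sum is the natural
  collapse); prominence is peak over run median, median floored at
  10⁻¹² — for looming traces that are silent before the collision the
  prominence is accordingly enormous, and only its ordering against
  translation is meaningful.
- Tuning-curve ties break toward the smaller angle; an all-zero curve
  is flagged `no_motion`.

## Known limitations

- Single fractional order for all layers, as reference.
- The direction layer resolves only the 8 canonical angles and one
  speed octave around m/2 px/frame; speed estimation and collision
  location are out of scope.
- The MD estimator's per-frame reliability (above).
- No feed-forward inhibition, no spike generation: outputs are
  continuous membrane potentials.
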