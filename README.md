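# dflgmd

A directionally selective, fractional-order LGMD collision-sensing
visual neural network, with a synthetic stimulus generator and a CLI.

## The problem

The lobula giant movement detector (LGMD) is an insect visual neuron
that fires strongly to objects approaching on a collision course and
weakly to receding or translating objects; directionally selective
neurons in the same optic lobe respond maximally to motion along a
preferred angle. `dflgmd` implements a five-layer retinotopic network
that combines both: it consumes a grayscale image sequence and emits,
per frame, a directional LGMD response for each of the 8 canonical
directions θ ∈ {0, π/4, …, 7π/4}, an aggregate collision trace whose
peak marks the collision time, and a global motion-direction estimate.
It is aimed at researchers in bio-inspired vision and robot collision
avoidance who want a tested, reproducible reference implementation that
runs on synthetic stimuli out of the box.

## The model

Every dynamic layer follows a conductance-based membrane equation under
a fractional-order time derivative of order α (default 0.4), discretized
with a semi-implicit Grünwald–Letnikov scheme (see `docs/methods.md`):

- **Photoreceptors**
  `D^α P = g_leak(V_rest − P) + λ_ex L(t)(E_ex − P) + λ_in L(t−1)(E_in − P)`,
  followed by the half-wave rectified ON/OFF split
  `P_ON = γ₁[P − V_th1]⁺`, `P_OFF = −γ₂[P − V_th2]⁻`.
- **Excitation / inhibition**: excitatory units relay each channel;
  inhibitory units low-pass it (`D^α I = g_leak(V_rest − I) + δ_ex P(E_ex − I)`),
  are rectified and spread laterally through two Gaussian kernels, the
  next-nearest one delayed by a frame:
  `Ī(t) = Î(t) ⊛ G₁ + β Î(t−1) ⊛ G₂`.
- **Summing units** stage the excitation/inhibition competition per
  channel and combine superlinearly:
  `S = μ₁Ŝ_ON + μ₂Ŝ_OFF + μ₃Ŝ_ON Ŝ_OFF`.
- **Direction layer** (correlation-type elementary motion detection):
  `D_ij(t, θ) = S_ij(t)·S_xy(t−2) − S_ij(t−1)·S_xy(t−1)`, where (x, y)
  is displaced by distance m along θ; a static scene cancels exactly.
- **LGMD layer**: each direction channel integrates its D field,
  `R1(t, θ) = Σ_ij D_ij`, and drives a single fractional membrane
  `D^α L1 = g_leak(V_rest − L1) + ξ_ex R1(E_ex − L1)`; the rectified
  `L̂1(t, θ)` is the directional LGMD response and
  `C(t) = Σ_θ L̂1(t, θ)` the collision trace.

All constants default to the reference parameter table (γ = 150,
ε_in = 100, ξ_ex = 5·128²/n², …). The fractional memory is what makes
the collision peak: after the looming object fills the field, the
membrane fields settle along power-law (log-convex) curves, and the
correlation `a(t)a(t−2) − a(t−1)²` of a log-convex relaxation is
positive in every channel — a transient the memoryless α = 1 network
almost entirely lacks.

## Worked example

Generate a dark block (11 px) translating leftward across a 128×128
field at the correlator's matched speed (0.5 px/frame), then run the
network:

```sh
dflgmd synth --kind translate --direction 1.0 --speed 0.5 \
             --frames 60 --object-size 11 --seed 1 --out demo/stim
dflgmd run --input demo/stim --out demo/out
```

`demo/out/summary.json` contains (abridged):

```
preferred_theta_deg = 180.0
theta_scores = {0: 0.0, 45: 0.0, 90: 0.0, 135: 8.52, 180: 15.85,
                225: 8.52, 270: 0.0, 315: 0.0}
peak_frame = 28, peak_prominence = 5.63
```

The per-direction integrated response peaks at θ = 180° — the network
reads the leftward motion correctly — with smaller flanks at the
neighboring diagonals and silence in the null half. The flat, weakly
prominent collision trace says "no collision threat".

A looming square that fills the field at frame 40
(`dflgmd synth --kind looming --fill-frame 40 --frames 60 --out demo/loom`)
instead yields

```
peak_frame = 42, peak_value = 6.07
theta_scores ≈ 1.03 – 1.06 in all 8 directions
```

an aggregate peak within 2 frames of the collision time and a nearly
isotropic tuning curve (expansion drives every direction channel alike)
— the two signatures that separate an approaching object from a passing
one. The same run with `alpha1: 1.0` in a config file collapses the
peak to ~0: the response is carried by the fractional memory.

The same pipeline is available in Python:

```python
from dflgmd import StimulusSpec, gen_translating, run_network
spec = StimulusSpec(kind="translate", direction=0.0, speed=0.5, size=11)
out = run_network(gen_translating(spec))
print(out.tuning.preferred, out.collision.peak_frame)
```

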