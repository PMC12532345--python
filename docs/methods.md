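# Methods

`octfocus` stabilizes OCT retinal B-scans against the two dominant axial
disturbances of in-vivo imaging: rigid axial motion of the retina (head
movement) and defocus (accommodative drift of the eye's optics).  Both are
inferred from the axial intensity distribution of the B-scan alone — no
wavefront sensor, no iterative sharpness search — so a correction can be
issued per frame.  Motion is corrected first with a deterministic
edge-map similarity search; the remaining brightness redistribution between
retinal layers is then mapped to a diopter correction by a single-step
deep deterministic policy gradient (DDPG) agent.  Everything is trainable
and testable against a physics simulator; no imaging data is required.

## Forward model

A rendered A-scan is

    I(z; zf) = R(z − s) · T(z − zf) · A(z) · H(z) + N(z)

with depth `z` in µm inside the imaging window:

- `R(z)` — axial reflectivity of the retina (the phantom), rigidly shifted
  by the axial motion `s`;
- `T(u) = 1 / ((u / 2 n zR,eff)² + 1)` — confocal point-spread function of
  a Gaussian beam with diffuse reflection; `zR,eff = M² zR` incorporates a
  beam-quality factor emulating residual ocular aberration.  `T` peaks at
  the focal depth `zf` and halves at `|u| = 2 n zR,eff`;
- `A(z) = μB exp(−2 μOCT z)` — attenuation by absorption and scattering;
- `H(z) = sinc²(z / 2 zRD) · exp(−π²ω²/(8 ln 2) (z/zRD)²)` — spectrometer
  sensitivity roll-off of a spectral-domain system, with maximum ranging
  depth `zRD = λ0²/(4Δλ)` and `ω = δλ/Δλ`;
- `N(z)` — additive zero-mean Gaussian noise with a nonnegativity clamp
  (the simplest stationary choice consistent with an additive noise term).

Depth-independent gain factors are deliberately omitted: only the relative
intensity distribution carries focus information, and the preprocessing
normalizes scale away.

A B-scan replicates `I(z)` across lateral positions with a small per-column
gain jitter (default 2%) and per-pixel noise.  Lens diopters convert to
focal-depth shift linearly via a reduced-eye constant (370 µm/D from
f_eye²/n_eye with f = 22.2 mm, n = 1.336); only the linearity of this
conversion matters to the agent.

### Default optics (configurable in `SystemParams`)

| parameter | default | note |
|---|---|---|
| center wavelength λ0 | 810 nm | SLD source |
| spectrometer pixel spacing Δλ | 0.08 nm | gives zRD ≈ 2.05 mm |
| spectral resolution δλ (FWHM) | 0.06 nm | ω = 0.75 |
| Rayleigh length zR | 30 µm | ~0.1 NA beam at the retina |
| beam quality M² | 1.5 | "reasonable" aberration penalty |
| refractive index n | 1.38 | retinal tissue |
| attenuation μOCT | 3·10⁻⁴ µm⁻¹ | ~0.5 over the window |
| axial pixel pitch | 3 µm | 400-pixel window (1.2 mm) |
| noise floor σ | 0.02 | relative to peak reflectivity ~1 |
| diopter→depth | 370 µm/D | reduced-eye model |

With these values the confocal half-width `2 n zR,eff` is 124 µm, so the
two retinal bands (300 µm apart) see a ~7× brightness swing as the focus
moves between them — the signal the agent learns.

## Retina phantom

The phantom emulates a two-band retina: a shallower inner-retina band and a
deeper, brighter outer-retina band over a low background, 300 µm apart
(healthy retinal thickness), with widths 90/75 µm.  Bands are flat-topped
with sharp error-function edges (σ = 0.7 px ≈ 2 µm): retinal layer
complexes are bounded by refractive-index interfaces at the system's
coherence-limited axial resolution (~3 µm here), and edge sharpness is
load-bearing — a smooth Gaussian bump's apparent edge position drifts
toward the focal plane under the multiplicative confocal tilt
(≈ σ² · d log T/dz), which would make even an ideal registration
focus-dependent.  A single-band "foveal" variant omits the inner band.  A
randomized variant jitters positions, widths, and amplitudes for
generalization and transfer tests.

What the phantom does **not** emulate: speckle statistics, intra-layer
texture, vessel shadows, curvature/tilt of the retina, and pathology.
Passing tests therefore demonstrate that the pipeline recovers motion and
focus when layer structure is the dominant signal; they do not certify
performance on real B-scans, which the fine-tuning stage exists to address.

## Motion correction

Both frames are reduced to lateral-mean A-scans and converted to edge
detection maps (EDM): Gaussian smoothing (σ = 1.5 px), first derivative,
normalized absolute value.  Defocus alternates which retinal band
dominates, so raw-intensity similarity between cross-focused frames has two
competing optima (inner↔outer alignment); masking everything shallower than
the valley between the two strongest edge-peak clusters leaves only the
outer-retina edges, whose similarity metric

    Rm(p) = −RMS(Er(z) − Et(z − p))   (over the overlap)

has a single optimum.  The shift estimate is the exhaustive integer argmax
over p ∈ [−Np, Np] (Np defaults to the ±200 µm motion range), ties broken
toward the smallest |p|.  Positive shift means the target sits deeper; the
correction is its negation.

Numerical choices:

- Peak detection uses height ≥ 0.08 and prominence ≥ 0.04 on the
  max-normalized EDM.  The threshold must sit below the confocal contrast
  of a fully defocused band (~0.14 with the default optics) and above the
  noise-edge level (~0.01); 0.08 splits the two decades.  Peaks within
  30 px belong to one band cluster.
- The mask is applied only when **both** frames produce ≥ 2 clusters;
  masking exactly one frame reintroduces the inner/outer ambiguity the mask
  removes.  Foveal (single-cluster) profiles pass through unmasked.
- The masked EDM is renormalized to max 1 so the comparison is a shape
  comparison of the outer-retina edge pattern.
- ED is normalized by the overlap length at each candidate shift, which
  keeps large shifts from being penalized by zero padding.
- Featureless (flat) frames yield a degenerate EDM; a pair of degenerate
  frames raises instead of returning a spurious shift.

Registration is integer-pixel by design, so the residual motion after a
correct registration is the quantization error, std ≈ pitch/√12 = 0.87 µm
at 3 µm pixels.

## Preprocessing and observation

For the agent, each B-scan is split into M = 4 contiguous lateral blocks
(remainder columns to the last block), each averaged laterally and
Gaussian-smoothed along depth (σ = 2 px) — enough channels to express
lateral structure variation, few enough for a lightweight CNN.  The
observation stacks reference and target channels as [ref₁..ref_M,
tgt₁..tgt_M].  Each (ref_m, tgt_m) pair is standardized **jointly** — by
the mean and std of the concatenated pair — which removes acquisition scale
while preserving the brightness contrast *between* the frames.  Per-array
standardization would erase exactly the defocus signal.

## Reward

After a correction is applied and a fresh frame rendered, the reward is the
sliding-window negative Euclidean distance between the jointly standardized
reference and post-correction average A-scans:

    Rf = −min_b { ED(Arⁿ(z), Atⁿ(z − b)) },  b ∈ [−Nb, Nb],  Nb = 15 px

The window forgives up to ±45 µm of residual axial displacement so the
agent is graded on the intensity *distribution*, not on pixel-to-pixel
alignment; `Rf ≤ 0` with equality only for a perfect match.

## Agent

- **Actor** (focus policy): two 1D conv/max-pool blocks (8→16→32 channels,
  kernel 3, pool 2) over the (2M × 400) observation, flattened into a
  128-64-32 ReLU chain and a tanh-bounded scalar.  The physical correction
  is `action × action_scale` with `action_scale` = 1 D, containing the
  ±0.6 D training range with headroom.
- **Critic**: an independent, critic-owned copy of the actor architecture
  embeds the observation into a single value, which is concatenated with
  the action and regressed through a deep feed-forward head.  The published
  head (500-1000-1000-1000-1000-500-200) is the default; the desk-scale
  configuration substitutes 128-128-64, which trains in minutes on one CPU
  at no measurable accuracy cost in this environment.  The embedding is
  deliberately *not* weight-shared with the live actor: sharing would
  entangle the actor and critic losses.
- **Single-step episodes**: the critic target is the immediate reward (no
  bootstrapping; the discount never enters).  Target networks with Polyak
  averaging (τ = 0.005) are kept for regression stability even though
  single-step returns make them nearly optional.
- **Exploration**: Gaussian action noise annealed linearly from σ = 0.3 to
  0.015 over the first half of training; 8 noise profiles are applied per
  episode, each rendered and rewarded, which samples the local reward
  curvature around the policy at the cost of renders, not episodes.
- **Schedule** (desk defaults): 8000 episodes, minibatch 32, two updates
  per episode, Adam at 5·10⁻⁴ (actor) / 10⁻³ (critic) dropping to
  10⁻⁴ / 3·10⁻⁴ at episode 5000.  The low-noise, low-rate tail lets the
  policy settle against a locally well-resolved critic; without it the
  policy jitters around a ~0.03 D plateau.  Late-phase exploration below
  σ ≈ 0.015 destabilizes the policy (measured), so the anneal floor is a
  stability limit, not a free knob.
- **Deployment policy**: evaluation and closed-loop correction use the
  Polyak-averaged target actor.  The slow average smooths the residual
  step-to-step jitter of the live actor around the optimum and measurably
  lowers the prediction error; exploration still perturbs the live
  actor.

### Training environment (study conditions)

Per episode: reference focus varied uniformly over a 0.5 D span about the
inter-band midpoint; initial retina position uniform over ±100 µm (shared
by both frames); target defocus uniform on (−0.6, 0.6) D; target motion
uniform on (−200, 200) µm.  Motion is corrected first, and the
motion-corrected target forms the observation.  The post-correction reward
frame carries a fresh ~10 µm axial jitter — corrections and re-acquisition
are not instantaneous in reality — which the reward window absorbs.
Episodes use 32 lateral columns; every downstream stage consumes lateral
means, so this trades rendering time only.  Sessions and evaluation-grade
imaging use the default 128-column geometry (more columns average down the
observation noise, as a full-width B-scan would).

Evaluation: mean |predicted − applied| defocus over 100 fresh episodes from
the same distribution.  The no-skill reference is 0.3 D (the best constant
policy against U(−0.6, 0.6)); the desk-scale run lands at ~0.013–0.017 D.

## Sessions

A simulated imaging session drives motion (µm) and defocus (D) with
stationary Ornstein-Uhlenbeck processes (exact discretization,
`stationary_sigma` parameterizes the stationary std directly; θ = 2 s⁻¹,
dt = 40 ms by default, i.e. a ~0.5 s relaxation time consistent with slow
head drift and accommodative micro-fluctuation).  Each of the 100 frames
(4 s) is corrected independently: register → remove shift → predict →
apply diopters → re-render → record applied/corrected/residual values plus
the reward.  Metrics are plain sample statistics (ddof = 1).  A kymograph
(depth × time array of lateral means) visualizes stabilization.

Under the headline conditions (motion std ≈ 53 µm, defocus std ≈ 0.27 D)
the residual motion std sits at the integer-pixel quantization floor
(≈ 0.87 µm; individual 100-frame sessions scatter by roughly ±0.1 µm
around it) and the residual defocus std collapses to well below 0.01 D
for a converged agent.

## Focus-map fine-tuning

To adapt the agent to a new retina without continuous acquisition, a sparse
focus sweep (21 frames, 0.1 D spacing over ±1 D; non-uniform spacing is
supported) is registered to its first frame, reduced to averaged channels,
and interpolated per depth pixel along the focus axis (linear by default —
it cannot invert the monotone defocus signature between knots; cubic
optional).  Interpolation is exact at knots and rejects extrapolation; the
fine-tuning environment clamps corrections to the calibrated range, as a
physical lens would.  Because a registered sweep pins the retina to one
axial position and averages away most noise, fine-tuning episodes
re-inject the variability live acquisition has — a shared per-episode
axial roll of both frames (±100 µm) and small additive channel noise —
without which the policy overfits the sweep's fixed geometry and loses
accuracy on live frames.  The same DDPG loop then runs against map
lookups instead of renders at fine-phase learning rates with moderate
exploration noise (0.1 annealing to 0.02).  At 0.1 D knots the interpolated channels agree with
direct renders to well under 5% relative RMS, and a few hundred
fine-tuning steps on a new phantom's map measurably reduce that phantom's
evaluation error.

## Determinism and precision

All randomness flows through seeded numpy generators: a seeded environment,
agent, and session replay bit-identically.  Network arithmetic is
single-precision (the layers accept float64 for gradient checking, which
verifies the hand-written backpropagation against central differences).

## Known limitations

- The phantom's realism bounds what in-silico training can claim; transfer
  to real data is only emulated (new-phantom fine-tuning), not measured.
- Registration is integer-pixel; sub-pixel refinement is out of scope.
- The critic compresses the observation to one scalar before the head (the
  published design); tasks where reward depends on more than one latent
  degree of freedom would need a wider embedding.
- Cross-focus registration retains a small (< 0.5 px) focus-dependent bias
  from the confocal tilt across band interiors; with sharp-edged phantoms
  it is negligible against the quantization floor.
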