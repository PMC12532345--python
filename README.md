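# octfocus

Axial-motion and defocus stabilization for OCT retinal B-scans.

In-vivo retinal OCT suffers from two axial disturbances: the subject's head
motion shifts the retina within the imaging window, and accommodative
fluctuation of the eye's optics moves the focal plane, redistributing
brightness between the inner and outer retinal layers.  `octfocus`
implements a per-frame, non-iterative correction pipeline that needs only
the B-scan images themselves:

1. **Motion correction** — reference and target frames are reduced to
   lateral-mean A-scans and to edge detection maps (EDM, the normalized
   absolute derivative of the smoothed profile).  Because defocus can make
   the inner band of one frame resemble the outer band of the other, the
   inner-retina portion of both maps is masked away; the axial shift is
   then the integer pixel offset maximizing

       Rm = −√( (1/N) Σ (Erⁿ − Etⁿ)² ),   p ∈ [−Np, Np].

2. **Focus correction** — a single-step deep deterministic policy gradient
   (DDPG) agent maps the stacked, jointly standardized reference/target
   A-scan channels (2M × depth) to a diopter correction through a
   lightweight 1D CNN actor with a tanh output.  Its critic regresses the
   immediate reward

       Rf = −min_b ED(Arⁿ(z), Atⁿ(z − b)),   b ∈ [−Nb, Nb],

   a sliding-window similarity that tolerates residual axial motion.

3. **Physics simulator** — renders defocused retinal A-scans as
   `I(z; zf) = R(z)·T(z−zf)·A(z)·H(z) + N(z)` (confocal PSF, attenuation,
   spectral-domain sensitivity roll-off) over synthetic two-band retina
   phantoms, with Ornstein-Uhlenbeck motion/defocus trajectories, so the
   whole closed loop trains and validates without hardware or patient
   data.

4. **Focus-map fine-tuning** — a sparse focus sweep (21 frames at 0.1 D
   over ±1 D) is registered, reduced, and interpolated per depth pixel
   into a dense focus → A-scan map, letting the agent fine-tune against
   table lookups instead of live acquisition.

See `docs/methods.md` for the model, parameter defaults, and design
rationale.

## Worked example

Train a desk-scale agent in the simulated environment, evaluate it, and
run a closed-loop session (about 15 minutes on one CPU):

```python
from dataclasses import replace
from octfocus import SystemParams, OUParams, make_phantom, run_session, session_metrics
from octfocus.agent import AgentConfig, DDPGAgent, train, evaluate
from octfocus.environment import SimulatedOCTEnv

params = replace(SystemParams(), n_lateral_ascans=32)   # training geometry
phantom = make_phantom()

agent = DDPGAgent(AgentConfig.desk(rng_seed=1), params.n_depth_pixels)
train(agent, SimulatedOCTEnv(phantom, params, rng=2))

res = evaluate(agent, SimulatedOCTEnv(phantom, params, rng=3), n_episodes=100)
print(f"mean |focus error| = {res['mean_abs_error_D']:.4f} D")

trace, stacks = run_session(
    agent, phantom, SystemParams(),                     # full-width imaging
    ou_motion=OUParams(mean_reversion_theta=2.0, stationary_sigma=53.2, dt=0.04),
    ou_defocus=OUParams(mean_reversion_theta=2.0, stationary_sigma=0.27, dt=0.04),
    n_frames=100, rng=4,
)
m = session_metrics(trace)
print(f"motion std  {m['std_applied_shift_um']:.1f} -> {m['std_residual_shift_um']:.2f} um")
print(f"defocus std {m['std_applied_defocus_D']:.3f} -> {m['std_residual_defocus_D']:.4f} D")
```

Output of this exact run:

```
mean |focus error| = 0.0109 D
motion std  33.7 -> 0.87 um
defocus std 0.204 -> 0.0079 D
```

The agent predicts the applied defocus of held-out episodes (drawn uniform
on ±0.6 D) to about a hundredth of a diopter.  In the closed loop the OU
head motion (stationary std 53 µm; a 100-frame session samples a
correlated stretch of it, here 33.7 µm) collapses to the 3 µm-pixel
quantization floor (3/√12 ≈ 0.87 µm), and the accommodative fluctuation
(stationary std 0.27 D) to below a hundredth of a diopter.

The same pipeline is scriptable from the shell:

```
octfocus simulate --n-frames 100 --seed 1 --out stack.tiff --trace trace.csv
octfocus register --ref ref.tiff --tgt tgt.tiff --np 67 --out result.json
octfocus train    --steps 8000 --seed 0 --out agent.npz --curve curve.csv
octfocus evaluate --agent agent.npz --n 100
octfocus session  --agent agent.npz --frames 100 --seed 2 --out-trace trace.csv
```

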