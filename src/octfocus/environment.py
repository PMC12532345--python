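"""Single-step simulated environment for the focus-correction agent.

One episode emulates one correction attempt during retinal imaging:

1. a reference B-scan is rendered at a randomly varied reference focus,
2. a target B-scan is rendered with random defocus and random axial motion
   relative to the reference,
3. the axial motion is corrected first by the masked-EDM registration, and
   the motion-corrected target together with the reference forms the
   agent's (2M, depth) observation,
4. the agent's diopter correction is applied, a fresh post-correction frame
   is rendered (with a small residual inter-frame jitter), and the
   sliding-window similarity to the reference A-scan is the immediate
   reward.

Episodes are independent (single-step); there is no bootstrapping.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import preprocess, registration
from .simulator import BScan, FocusState, RetinaPhantom, SystemParams, render_bscan

__all__ = ["EnvConfig", "SimulatedOCTEnv"]


@dataclass
class EnvConfig:
    """Study conditions of the in-silico training protocol.

    Defocus is uniform on ``defocus_range`` (D), axial motion uniform on
    ``motion_range`` (µm), the reference focus varies uniformly over a
    ``ref_focus_variation`` D span to cover the retina, and the initial
    retina position varies by ``initial_position_range`` µm (shared by
    reference and target).  ``reacquire_jitter_um`` is the small axial
    motion accrued between applying a correction and acquiring the
    post-correction frame; the sliding-window reward absorbs it.
    """

    defocus_range: tuple = (-0.6, 0.6)
    motion_range: tuple = (-200.0, 200.0)
    ref_focus_variation: float = 0.5
    initial_position_range: tuple = (-100.0, 100.0)
    reacquire_jitter_um: float = 10.0
    M: int = 4
    smoothing_sigma: float = 2.0
    edm_sigma: float = 1.5
    Np: int | None = None  # default: motion range / pixel pitch, rounded up
    lateral_variation: float = 0.02


class SimulatedOCTEnv:
    """Renders episodes and applies diopter corrections in simulation.

    The environment owns a phantom and the system parameters; randomness
    comes from the generator passed at construction (or a seed), so a
    seeded environment replays identically.
    """

    def __init__(
        self,
        phantom: RetinaPhantom,
        params: SystemParams,
        config: EnvConfig | None = None,
        rng: np.random.Generator | int | None = None,
    ):
        self.phantom = phantom
        self.params = params
        self.config = config or EnvConfig()
        self.rng = np.random.default_rng(rng)
        if self.config.Np is None:
            span = max(abs(m) for m in self.config.motion_range)
            self.config = replace(
                self.config, Np=int(np.ceil(span / params.axial_pixel_pitch))
            )
        # reference focus is centred between the retinal bands
        inner = phantom.inner_band_center
        outer = phantom.outer_band_center
        mid_px = outer if inner is None else 0.5 * (inner + outer)
        self.base_focus_um = mid_px * params.axial_pixel_pitch
        self._episode = None

    # -- episode control ----------------------------------------------------

    def reset(self) -> np.ndarray:
        """Start a new episode; returns the agent's observation."""
        cfg, p = self.config, self.params
        rng = self.rng
        conv = p.diopter_to_depth

        ref_defocus = rng.uniform(-0.5, 0.5) * cfg.ref_focus_variation
        ref_zf = self.base_focus_um + ref_defocus * conv
        base_shift = rng.uniform(*cfg.initial_position_range)
        applied_defocus = rng.uniform(*cfg.defocus_range)
        motion = rng.uniform(*cfg.motion_range)

        ref_state = FocusState(focal_depth_zf=ref_zf, axial_shift=base_shift)
        tgt_state = FocusState(
            focal_depth_zf=ref_zf + applied_defocus * conv,
            axial_shift=base_shift + motion,
            defocus_diopters=applied_defocus,
        )
        ref = self._render(ref_state)
        tgt = self._render(tgt_state)

        reg = registration.register_axial(
            ref, tgt, Np=cfg.Np, edm_sigma=cfg.edm_sigma,
            pixel_pitch=p.axial_pixel_pitch,
        )
        corrected_state = replace(
            tgt_state, axial_shift=tgt_state.axial_shift - reg.shift_um
        )
        tgt_corrected = self._render(corrected_state)

        obs = preprocess.build_observation(
            preprocess.subregion_channels(ref, cfg.M, cfg.smoothing_sigma),
            preprocess.subregion_channels(tgt_corrected, cfg.M, cfg.smoothing_sigma),
        )
        self._episode = {
            "ref": ref,
            "ref_ascan": preprocess.average_ascan(ref),
            "tgt_state": corrected_state,
            "applied_defocus": applied_defocus,
            "registration": reg,
        }
        return obs

    @property
    def applied_defocus(self) -> float:
        """Ground-truth defocus (D) of the current episode's target."""
        self._require_episode()
        return self._episode["applied_defocus"]

    def apply_correction(self, diopters: float) -> BScan:
        """Apply a lens correction of ``diopters`` and acquire the
        post-correction frame (the episode's target focus minus the
        correction, with fresh inter-frame jitter and noise)."""
        self._require_episode()
        cfg, p = self.config, self.params
        state = self._episode["tgt_state"]
        jitter = (
            self.rng.normal(0.0, cfg.reacquire_jitter_um)
            if cfg.reacquire_jitter_um > 0
            else 0.0
        )
        new_state = FocusState(
            focal_depth_zf=state.focal_depth_zf - diopters * p.diopter_to_depth,
            axial_shift=state.axial_shift + jitter,
            defocus_diopters=state.defocus_diopters - diopters,
        )
        return self._render(new_state)

    def reference_ascan(self) -> np.ndarray:
        self._require_episode()
        return self._episode["ref_ascan"]

    # -- helpers ------------------------------------------------------------

    def _render(self, state: FocusState) -> BScan:
        return render_bscan(
            self.phantom,
            state,
            self.params,
            lateral_variation=self.config.lateral_variation,
            rng=self.rng,
        )

    def _require_episode(self):
        if self._episode is None:
            raise RuntimeError("call reset() before interacting with the environment")
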