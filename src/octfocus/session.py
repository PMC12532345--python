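"""Closed-loop simulated correction sessions and their metrics.

A session emulates a few seconds of imaging: axial motion (µm) and
accommodative micro-fluctuation (D) both follow Ornstein-Uhlenbeck
trajectories sampled at the frame interval.  Each frame is corrected
independently — motion first (masked-EDM integer-pixel registration), then
focus (single-step agent prediction) — and the applied/corrected/residual
values are recorded per frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import preprocess, registration
from .agent import DDPGAgent, reward_focus
from .simulator import (
    BScan,
    FocusState,
    OUParams,
    RetinaPhantom,
    SystemParams,
    ou_trajectory,
    render_bscan,
)

__all__ = ["SessionTrace", "run_session", "kymograph", "session_metrics"]

logger = logging.getLogger(__name__)

TRACE_COLUMNS = [
    "frame",
    "t",
    "applied_shift_um",
    "applied_defocus_D",
    "corrected_shift_um",
    "corrected_defocus_D",
    "residual_shift_um",
    "residual_defocus_D",
    "reward",
]


@dataclass
class SessionTrace:
    """Per-frame record of a correction session (times s, shifts µm,
    defocus D).  Residuals are applied minus corrected."""

    frame: pd.DataFrame

    def __len__(self):
        return len(self.frame)

    def to_csv(self, path):
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SessionTrace":
        return cls(frame=pd.read_csv(path))


def run_session(
    agent: DDPGAgent,
    phantom: RetinaPhantom,
    params: SystemParams,
    ou_motion: OUParams,
    ou_defocus: OUParams,
    n_frames: int = 100,
    frame_dt: float = 0.04,
    rng: np.random.Generator | int | None = None,
    reference_focus_um: float | None = None,
    lateral_variation: float = 0.02,
    Np: int | None = None,
    correct_focus: bool = True,
    order: str = "motion_first",
):
    """Simulate a closed-loop imaging session with per-frame correction.

    The reference frame is rendered at ``reference_focus_um`` (default:
    midway between the retinal bands) with zero motion; each subsequent
    frame applies the OU motion/defocus state, is registered to the
    reference, has the estimated shift removed, is passed to the agent for
    a focus correction, and is re-rendered with both corrections applied.
    Frames whose edge maps are degenerate are logged and skipped.

    ``order`` controls the pipeline: ``"motion_first"`` (the default; the
    agent sees the motion-corrected frame) or ``"focus_first"`` (the agent
    predicts from the raw, unregistered frame — the configuration motion
    correction exists to avoid).

    Returns ``(trace, stacks)`` where ``stacks`` holds the raw,
    motion-corrected, and fully corrected B-scan stacks (lists of BScan).
    """
    gen = np.random.default_rng(rng)
    pitch = params.axial_pixel_pitch
    conv = params.diopter_to_depth
    if Np is None:
        Np = int(np.ceil(4.0 * ou_motion.stationary_sigma / pitch)) or 1
    if reference_focus_um is None:
        inner = phantom.inner_band_center
        mid = (
            phantom.outer_band_center
            if inner is None
            else 0.5 * (inner + phantom.outer_band_center)
        )
        reference_focus_um = mid * pitch

    motion = ou_trajectory(ou_motion, n_frames, gen)
    defocus = ou_trajectory(ou_defocus, n_frames, gen)

    ref_state = FocusState(focal_depth_zf=reference_focus_um)
    reference = render_bscan(phantom, ref_state, params, lateral_variation, gen)
    ref_ascan = preprocess.average_ascan(reference)

    rows = []
    raw_stack, motion_stack, corrected_stack = [], [], []
    for i in range(n_frames):
        shift, d = float(motion[i]), float(defocus[i])
        state = FocusState(
            focal_depth_zf=reference_focus_um + d * conv,
            axial_shift=shift,
            defocus_diopters=d,
        )
        frame = render_bscan(phantom, state, params, lateral_variation, gen)
        raw_stack.append(frame)
        try:
            reg = registration.register_axial(
                reference, frame, Np=Np, edm_sigma=1.5, pixel_pitch=pitch
            )
        except registration.RegistrationError:
            logger.warning("frame %d: un-registrable (degenerate edge maps); skipped", i)
            continue
        corrected_shift_um = reg.shift_um
        motion_state = replace(state, axial_shift=shift - corrected_shift_um)
        motion_frame = render_bscan(phantom, motion_state, params, lateral_variation, gen)
        motion_stack.append(motion_frame)

        if not correct_focus:
            correction_D = 0.0
        elif order == "motion_first":
            correction_D = agent.predict_correction(reference, motion_frame)
        elif order == "focus_first":
            correction_D = agent.predict_correction(reference, frame)
        else:
            raise ValueError(f"unknown pipeline order: {order!r}")
        final_state = FocusState(
            focal_depth_zf=motion_state.focal_depth_zf - correction_D * conv,
            axial_shift=motion_state.axial_shift,
            defocus_diopters=d - correction_D,
        )
        final = render_bscan(phantom, final_state, params, lateral_variation, gen)
        corrected_stack.append(final)

        reward = reward_focus(ref_ascan, preprocess.average_ascan(final), agent.config.Nb)
        logger.info(
            "frame %d: shift %+.1f um (corrected %+.1f), defocus %+.3f D "
            "(corrected %+.3f), reward %.4f",
            i, shift, corrected_shift_um, d, correction_D, reward,
        )
        rows.append(
            {
                "frame": i,
                "t": i * frame_dt,
                "applied_shift_um": shift,
                "applied_defocus_D": d,
                "corrected_shift_um": corrected_shift_um,
                "corrected_defocus_D": correction_D,
                "residual_shift_um": shift - corrected_shift_um,
                "residual_defocus_D": d - correction_D,
                "reward": reward,
            }
        )

    trace = SessionTrace(frame=pd.DataFrame(rows, columns=TRACE_COLUMNS))
    stacks = {"raw": raw_stack, "motion_corrected": motion_stack, "corrected": corrected_stack}
    return trace, stacks


def kymograph(stack) -> np.ndarray:
    """Project each B-scan laterally and arrange the average A-scans as
    time-ordered columns: output shape (n_depth, n_frames)."""
    if len(stack) == 0:
        raise ValueError("empty stack")
    columns = [preprocess.average_ascan(frame) for frame in stack]
    return np.stack(columns, axis=1)


def session_metrics(trace: SessionTrace) -> dict:
    """Sample statistics of a session trace (stds use ddof=1)."""
    df = trace.frame
    def _std(col):
        return float(df[col].std(ddof=1)) if len(df) > 1 else 0.0

    return {
        "std_applied_shift_um": _std("applied_shift_um"),
        "std_residual_shift_um": _std("residual_shift_um"),
        "std_applied_defocus_D": _std("applied_defocus_D"),
        "std_residual_defocus_D": _std("residual_defocus_D"),
        "mean_abs_residual_shift_um": float(df["residual_shift_um"].abs().mean()),
        "mean_abs_residual_defocus_D": float(df["residual_defocus_D"].abs().mean()),
        "n_frames": int(len(df)),
    }
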