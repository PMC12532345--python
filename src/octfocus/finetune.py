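"""Fast fine-tuning against an interpolated A-scan focus map.

Training an agent directly against live acquisition is expensive: every
reward needs a freshly acquired frame.  Instead, a sparse focus sweep
(e.g. 21 frames at 0.1 D spacing over (-1, 1) D) is registered, reduced to
averaged A-scan channels, and interpolated per depth pixel along the focus
axis.  The resulting focus map answers "what would the A-scan look like at
focus f" by table lookup, so the same single-step DDPG loop can run
against it with no further acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import interp1d

from . import preprocess, registration
from .agent import DDPGAgent, train
from .preprocess import AScanChannels
from .simulator import FocusState, RetinaPhantom, SystemParams, render_bscan

__all__ = [
    "FocusSweep",
    "FocusMap",
    "SimulatedSweepSource",
    "acquire_sweep",
    "build_focus_map",
    "FocusMapEnv",
    "finetune_agent",
]


@dataclass
class FocusSweep:
    """Registered, preprocessed frames of a sparse focus sweep.

    ``channels`` is (n_focus, M, depth); ``ascans`` the corresponding
    full-width average A-scans (n_focus, depth).  Focus values are relative
    to the sweep's reference lens setting, in diopters, strictly
    increasing but not necessarily equally spaced.
    """

    focus_values: np.ndarray
    channels: np.ndarray
    ascans: np.ndarray
    registered: bool = True

    def __post_init__(self):
        self.focus_values = np.asarray(self.focus_values, dtype=float)
        if np.any(np.diff(self.focus_values) <= 0):
            raise ValueError("focus_values must be strictly increasing")
        if self.channels.shape[0] != self.focus_values.size:
            raise ValueError("one channel frame per focus value required")


@dataclass
class FocusMap:
    """Continuous focus -> A-scan lookup built from a sweep.

    Interpolation is per depth pixel along the focus axis (linear by
    default) and exact at the sweep's knots.  Queries outside the sweep
    range are rejected.
    """

    focus_values: np.ndarray
    _channels_interp: interp1d
    _ascan_interp: interp1d
    M: int
    smoothing_sigma: float

    @property
    def focus_range(self) -> tuple:
        return float(self.focus_values[0]), float(self.focus_values[-1])

    def lookup_channels(self, focus: float) -> AScanChannels:
        self._check(focus)
        return AScanChannels(
            channels=self._channels_interp(focus), smoothing_sigma=self.smoothing_sigma
        )

    def lookup_ascan(self, focus: float) -> np.ndarray:
        self._check(focus)
        return self._ascan_interp(focus)

    def _check(self, focus: float):
        lo, hi = self.focus_range
        if not (lo - 1e-9 <= focus <= hi + 1e-9):
            raise ValueError(
                f"focus {focus:+.3f} D outside the sweep range ({lo:+.2f}, {hi:+.2f}) D"
            )


class SimulatedSweepSource:
    """Renders sweep frames from the simulator (stands in for hardware).

    ``focus`` is in diopters relative to ``ref_focus_um``; each call may
    inject a per-frame axial shift (µm) from ``shift_for`` to exercise the
    registration step of sweep acquisition.
    """

    def __init__(
        self,
        phantom: RetinaPhantom,
        params: SystemParams,
        ref_focus_um: float | None = None,
        shift_for=None,
        lateral_variation: float = 0.02,
        rng=None,
    ):
        self.phantom = phantom
        self.params = params
        if ref_focus_um is None:
            inner = phantom.inner_band_center
            mid = (
                phantom.outer_band_center
                if inner is None
                else 0.5 * (inner + phantom.outer_band_center)
            )
            ref_focus_um = mid * params.axial_pixel_pitch
        self.ref_focus_um = ref_focus_um
        self.shift_for = shift_for or (lambda i, f: 0.0)
        self.lateral_variation = lateral_variation
        self.rng = np.random.default_rng(rng)
        self._index = 0

    def __call__(self, focus_diopters: float):
        state = FocusState(
            focal_depth_zf=self.ref_focus_um + focus_diopters * self.params.diopter_to_depth,
            axial_shift=float(self.shift_for(self._index, focus_diopters)),
            defocus_diopters=focus_diopters,
        )
        self._index += 1
        return render_bscan(
            self.phantom, state, self.params,
            lateral_variation=self.lateral_variation, rng=self.rng,
        )


def acquire_sweep(
    source,
    focus_values,
    M: int = 4,
    smoothing_sigma: float = 2.0,
    Np: int = 67,
    edm_sigma: float = 1.5,
    pixel_pitch: float = 3.0,
) -> FocusSweep:
    """Acquire one frame per focus value, register each to the first frame,
    and reduce to averaged A-scan channels.

    Registration corrections are applied digitally (integer-pixel roll with
    background fill from the frame edge) before preprocessing, mirroring
    the motion-correction-first pipeline.
    """
    focus_values = np.asarray(focus_values, dtype=float)
    frames = [source(f) for f in focus_values]
    reference = frames[0]
    channels, ascans = [], []
    for frame in frames:
        reg = registration.register_axial(
            reference, frame, Np=Np, edm_sigma=edm_sigma, pixel_pitch=pixel_pitch
        )
        img = frame.intensity
        if reg.shift_pixels != 0:
            img = np.roll(img, -reg.shift_pixels, axis=0)
            if reg.shift_pixels > 0:
                img[-reg.shift_pixels:, :] = img[-reg.shift_pixels - 1 : -reg.shift_pixels, :]
            else:
                img[: -reg.shift_pixels, :] = img[-reg.shift_pixels : -reg.shift_pixels + 1, :]
        ch = preprocess.subregion_channels(img, M, smoothing_sigma)
        channels.append(ch.channels)
        ascans.append(preprocess.average_ascan(img))
    return FocusSweep(
        focus_values=focus_values,
        channels=np.stack(channels),
        ascans=np.stack(ascans),
    )


def build_focus_map(sweep: FocusSweep, kind: str = "linear") -> FocusMap:
    """Interpolate the sweep per depth pixel along the focus axis.

    Linear interpolation (default) cannot invert the monotone defocus
    signature between knots; ``kind='cubic'`` is available when the sweep
    is dense and smooth.
    """
    if sweep.focus_values.size < 2:
        raise ValueError("need at least two sweep points to interpolate")
    ch = interp1d(sweep.focus_values, sweep.channels, axis=0, kind=kind, bounds_error=True)
    asc = interp1d(sweep.focus_values, sweep.ascans, axis=0, kind=kind, bounds_error=True)
    return FocusMap(
        focus_values=sweep.focus_values,
        _channels_interp=ch,
        _ascan_interp=asc,
        M=sweep.channels.shape[1],
        smoothing_sigma=0.0,
    )


def _roll_fill(arr: np.ndarray, k: int) -> np.ndarray:
    """Roll along the last (depth) axis with edge-value fill."""
    if k == 0:
        return arr
    out = np.roll(arr, k, axis=-1)
    if k > 0:
        out[..., :k] = arr[..., :1]
    else:
        out[..., k:] = arr[..., -1:]
    return out


class FocusMapEnv:
    """Single-step environment backed by focus-map lookups.

    Episodes mirror the simulated environment — random reference focus,
    random target defocus, agent correction, immediate sliding-window
    reward — but every frame is an interpolated lookup instead of a fresh
    render, which is what makes fine-tuning fast.  Corrections that would
    leave the calibrated sweep range are clamped to its edge (the physical
    lens has the same hard range).

    A registered sweep pins the retina to one axial position and averages
    away most noise, which a policy can overfit; episodes therefore
    re-inject the variability the live environment has — a per-episode
    axial roll of both frames (``position_range`` µm, the retina's varying
    start position) and additive channel noise (``noise_sigma``, scaled to
    a sub-region average of a typical acquisition).
    """

    def __init__(
        self,
        focus_map: FocusMap,
        defocus_range=(-0.6, 0.6),
        ref_focus_variation: float = 0.5,
        Nb: int = 15,
        noise_sigma: float = 0.003,
        position_range: float = 100.0,
        pixel_pitch: float = 3.0,
        rng=None,
    ):
        self.map = focus_map
        self.defocus_range = defocus_range
        self.ref_focus_variation = ref_focus_variation
        self.Nb = Nb
        self.noise_sigma = noise_sigma
        self.position_range = position_range
        self.pixel_pitch = pixel_pitch
        self.rng = np.random.default_rng(rng)
        self._episode = None

    def reset(self) -> np.ndarray:
        rng = self.rng
        ref_f = rng.uniform(-0.5, 0.5) * self.ref_focus_variation
        d = rng.uniform(*self.defocus_range)
        lo, hi = self.map.focus_range
        tgt_f = float(np.clip(ref_f + d, lo, hi))
        applied = tgt_f - ref_f
        roll = 0
        if self.position_range > 0:
            roll = int(rng.integers(
                -round(self.position_range / self.pixel_pitch),
                round(self.position_range / self.pixel_pitch) + 1,
            ))
        ref_ch = self._augment(self.map.lookup_channels(ref_f), roll)
        tgt_ch = self._augment(self.map.lookup_channels(tgt_f), roll)
        self._episode = {
            "ref_f": ref_f,
            "tgt_f": tgt_f,
            "applied_defocus": applied,
            "roll": roll,
            "ref_ascan": _roll_fill(self.map.lookup_ascan(ref_f), roll),
        }
        return preprocess.build_observation(ref_ch, tgt_ch)

    @property
    def applied_defocus(self) -> float:
        return self._episode["applied_defocus"]

    def reference_ascan(self) -> np.ndarray:
        return self._episode["ref_ascan"]

    def apply_correction(self, diopters: float):
        lo, hi = self.map.focus_range
        f = float(np.clip(self._episode["tgt_f"] - diopters, lo, hi))
        ascan = _roll_fill(self.map.lookup_ascan(f), self._episode["roll"])
        if self.noise_sigma > 0:
            ascan = ascan + self.rng.normal(0.0, self.noise_sigma, ascan.shape)
        # duck-typed single-column "B-scan" so average_ascan reduces to it
        return _AScanFrame(ascan)

    def _augment(self, ch: AScanChannels, roll: int) -> AScanChannels:
        out = _roll_fill(ch.channels, roll)
        if self.noise_sigma > 0:
            out = out + self.rng.normal(0.0, self.noise_sigma, out.shape)
        return AScanChannels(channels=out, smoothing_sigma=ch.smoothing_sigma)


class _AScanFrame:
    """Minimal frame wrapper exposing a B-scan-like intensity array."""

    def __init__(self, ascan: np.ndarray):
        self.intensity = np.asarray(ascan, dtype=float)[:, None]


def finetune_agent(agent: DDPGAgent, focus_map: FocusMap, n_steps: int = 2000, rng=None):
    """Continue DDPG training against focus-map lookups.

    The loop is the standard single-step one, but run as a fine-tuning
    phase: moderate exploration noise (0.1 annealing to 0.02 action units)
    and the config's fine learning rates, since the agent usually starts
    near a working policy.  Zero steps return immediately with the agent
    untouched.  Returns the learning curve (empty for zero steps).
    """
    import dataclasses

    import pandas as pd

    if n_steps == 0:
        return pd.DataFrame()
    env = FocusMapEnv(focus_map, Nb=agent.config.Nb, rng=rng)
    base_cfg = agent.config
    base_lrs = (agent.actor_opt.lr, agent.critic_opt.lr)
    agent.config = dataclasses.replace(
        base_cfg,
        noise_sigma_start=0.1,
        noise_sigma_end=0.02,
        noise_anneal_steps=max(1, int(0.8 * n_steps)),
        lr_decay_at=None,
    )
    agent.actor_opt.lr = base_cfg.fine_actor_lr
    agent.critic_opt.lr = base_cfg.fine_critic_lr
    try:
        return train(agent, env, n_steps=n_steps)
    finally:
        agent.config = base_cfg
        agent.actor_opt.lr, agent.critic_opt.lr = base_lrs
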