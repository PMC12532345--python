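"""Forward model of defocused OCT retinal A-scan/B-scan intensity.

The rendered axial profile is the product of four depth-dependent factors
plus additive noise::

    I(z; zf) = R(z) * T(z - zf) * A(z) * H(z) + N(z)

where ``R`` is the axial reflectivity of the retina, ``T`` the confocal
point-spread function of the (aberrated) Gaussian imaging beam, ``A`` an
exponential attenuation from absorption/scattering, and ``H`` the
spectrometer sensitivity roll-off of a spectral-domain OCT system.  Only the
*relative* intensity distribution matters for focus inference, so all
depth-independent gain factors are omitted.

Axial motion of the subject rigidly shifts ``R`` within the imaging window
while the focal plane ``zf`` stays fixed in image coordinates (head motion
moves the retina; the tunable lens sets the focus).  Stochastic motion and
accommodative micro-fluctuation are modelled by Ornstein-Uhlenbeck
processes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SystemParams",
    "RetinaPhantom",
    "FocusState",
    "OUParams",
    "BScan",
    "SimulationError",
    "cpsf",
    "attenuation",
    "sensitivity_rolloff",
    "compose_axial_intensity",
    "render_bscan",
    "ou_trajectory",
    "make_phantom",
]


class SimulationError(ValueError):
    """Raised for physically invalid simulator inputs."""


@dataclass
class SystemParams:
    """Optical and spectrometer constants of the simulated SD-OCT system.

    Attributes
    ----------
    refractive_index_n : float
        Refractive index inside the retina (~1.38).
    rayleigh_length_zR : float
        Rayleigh length of the imaging beam at the retina, in µm.
    beam_quality_M2 : float
        Beam quality factor >= 1 emulating residual ocular aberration; the
        effective Rayleigh length is ``M2 * zR``.
    center_wavelength_lambda0 : float
        Source center wavelength, in nm.
    pixel_wavelength_spacing : float
        Spectrometer wavelength spacing between pixels (Δλ), in nm.
    spectral_resolution : float
        Spectrometer spectral resolution FWHM (δλ), in nm.
    mu_backscatter : float
        Power-backscattering amplitude scale (dimensionless).
    mu_oct_attenuation : float
        OCT signal attenuation coefficient, in 1/µm.
    axial_pixel_pitch : float
        Axial sampling, µm per pixel.
    n_depth_pixels, n_lateral_ascans : int
        B-scan geometry (depth x lateral).
    diopter_to_depth : float
        Linear conversion from lens diopters to focal-depth shift at the
        retina, µm per D (reduced-eye model, f_eye^2 / n_eye).
    noise_floor_sigma : float
        Std of the additive Gaussian noise floor, in relative intensity
        units (the noiseless peak reflectivity is ~1).
    """

    refractive_index_n: float = 1.38
    rayleigh_length_zR: float = 30.0
    beam_quality_M2: float = 1.5
    center_wavelength_lambda0: float = 810.0
    pixel_wavelength_spacing: float = 0.08
    spectral_resolution: float = 0.06
    mu_backscatter: float = 1.0
    mu_oct_attenuation: float = 3.0e-4
    axial_pixel_pitch: float = 3.0
    n_depth_pixels: int = 400
    n_lateral_ascans: int = 128
    diopter_to_depth: float = 370.0
    noise_floor_sigma: float = 0.02

    def __post_init__(self) -> None:
        if not np.isfinite(
            [
                self.refractive_index_n,
                self.rayleigh_length_zR,
                self.beam_quality_M2,
                self.center_wavelength_lambda0,
                self.pixel_wavelength_spacing,
                self.spectral_resolution,
            ]
        ).all():
            raise SimulationError("system parameters must be finite")
        if self.rayleigh_length_zR <= 0:
            raise SimulationError("rayleigh_length_zR must be > 0")
        if self.beam_quality_M2 < 1:
            raise SimulationError("beam_quality_M2 must be >= 1")
        if self.mu_oct_attenuation < 0:
            raise SimulationError("mu_oct_attenuation must be >= 0")
        if self.pixel_wavelength_spacing <= 0 or self.spectral_resolution <= 0:
            raise SimulationError("spectrometer spacings must be > 0")

    @property
    def effective_rayleigh_length(self) -> float:
        """Aberration-degraded Rayleigh length ``M2 * zR`` in µm."""
        return self.beam_quality_M2 * self.rayleigh_length_zR

    @property
    def max_ranging_depth(self) -> float:
        """Maximum ranging depth ``zRD = λ0² / (4 Δλ)`` in µm."""
        zrd_nm = self.center_wavelength_lambda0**2 / (4.0 * self.pixel_wavelength_spacing)
        return zrd_nm * 1e-3

    @property
    def omega(self) -> float:
        """Spectral resolution ratio ``ω = δλ / Δλ`` (dimensionless)."""
        return self.spectral_resolution / self.pixel_wavelength_spacing

    @property
    def depth_um(self) -> np.ndarray:
        """Depth coordinate of each axial pixel, in µm."""
        return np.arange(self.n_depth_pixels) * self.axial_pixel_pitch


@dataclass
class RetinaPhantom:
    """Synthetic axial reflectivity profile R(z) with labelled bands.

    The default phantom is a two-band retina: a bright inner-retina band and
    a deeper outer-retina band separated by a darker gap, on a low
    background.  A single-band ("foveal") variant carries only the outer
    band.
    """

    reflectivity_R: np.ndarray
    inner_band_center: float | None
    outer_band_center: float
    band_widths: tuple
    background_level: float

    def __post_init__(self) -> None:
        self.reflectivity_R = np.asarray(self.reflectivity_R, dtype=float)
        if (self.reflectivity_R < 0).any():
            raise SimulationError("reflectivity must be nonnegative")
        if self.inner_band_center is not None and not (
            self.outer_band_center > self.inner_band_center
        ):
            raise SimulationError("outer band must lie deeper than the inner band")

    @property
    def is_foveal(self) -> bool:
        return self.inner_band_center is None

    @property
    def n_depth_pixels(self) -> int:
        return self.reflectivity_R.size


@dataclass
class FocusState:
    """Instantaneous focal depth and rigid axial displacement of the retina.

    ``focal_depth_zf`` is the depth of focus within the image in µm;
    ``axial_shift`` displaces R(z) toward larger depth when positive;
    ``defocus_diopters`` records the lens defocus relative to the reference
    focus (informational; ``focal_depth_zf`` is authoritative for
    rendering).
    """

    focal_depth_zf: float
    axial_shift: float = 0.0
    defocus_diopters: float = 0.0


@dataclass
class OUParams:
    """Ornstein-Uhlenbeck process parameters.

    ``stationary_sigma`` is the *stationary* standard deviation of the
    process (µm for motion, D for defocus), not the diffusion coefficient;
    the update rule is calibrated so a long trajectory's sample std
    converges to it.
    """

    mean_reversion_theta: float
    stationary_sigma: float
    equilibrium_mu: float = 0.0
    dt: float = 0.04

    def __post_init__(self) -> None:
        if self.mean_reversion_theta <= 0:
            raise SimulationError("mean_reversion_theta must be > 0")
        if self.stationary_sigma < 0:
            raise SimulationError("stationary_sigma must be >= 0")
        if self.dt <= 0:
            raise SimulationError("dt must be > 0")


@dataclass
class BScan:
    """A 2D OCT cross-section, depth x lateral, with the focus state used to
    render it (meta is None for externally loaded images)."""

    intensity: np.ndarray
    meta: FocusState | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise SimulationError("B-scan intensity must be 2D (depth x lateral)")
        if not np.isfinite(self.intensity).all():
            raise SimulationError("B-scan intensity must be finite")


# ---------------------------------------------------------------------------
# Physics factors
# ---------------------------------------------------------------------------

def cpsf(z, zf, params: SystemParams):
    """Confocal point-spread function T(z - zf) for a Gaussian beam and a
    diffusely reflecting retina.

    ``T = 1 / ( ((z - zf) / (2 n zR_eff))² + 1 )`` with
    ``zR_eff = M² zR``.  Peaks at 1 in focus and falls to 0.5 at
    ``|z - zf| = 2 n zR_eff``.
    """
    z = np.asarray(z, dtype=float)
    if not (np.isfinite(z).all() and np.isfinite(zf)):
        raise SimulationError("cpsf inputs must be finite")
    half_width = 2.0 * params.refractive_index_n * params.effective_rayleigh_length
    return 1.0 / (((z - zf) / half_width) ** 2 + 1.0)


def attenuation(z, params: SystemParams):
    """Depth attenuation ``A(z) = μB · exp(-2 μOCT z)`` from absorption and
    scattering (z in µm from the top of the imaging window)."""
    z = np.asarray(z, dtype=float)
    return params.mu_backscatter * np.exp(-2.0 * params.mu_oct_attenuation * z)


def sensitivity_rolloff(z, params: SystemParams):
    """Spectral-domain OCT sensitivity roll-off.

    ``H(z) = sinc²(z/(2 zRD)) · exp(-π²ω²/(8 ln2) (z/zRD)²)`` where the sinc
    argument is ``π z / (2 zRD)``; the z→0 limit is 1 (handled
    analytically via numpy's normalized sinc).
    """
    z = np.asarray(z, dtype=float)
    zrd = params.max_ranging_depth
    # np.sinc(x) = sin(pi x)/(pi x); here x = z / (2 zRD)
    sinc_term = np.sinc(z / (2.0 * zrd)) ** 2
    gauss_term = np.exp(
        -(np.pi**2) * params.omega**2 / (8.0 * np.log(2.0)) * (z / zrd) ** 2
    )
    return sinc_term * gauss_term


def _shift_profile(profile: np.ndarray, shift_pixels: float, fill: float) -> np.ndarray:
    """Rigidly shift a 1D profile by a (possibly fractional) number of
    pixels toward larger depth, filling exposed samples with ``fill``.

    Sub-pixel shifts use linear interpolation, which is what makes the
    integer-pixel registration residual quantization-limited downstream.
    """
    n = profile.size
    idx = np.arange(n, dtype=float) - shift_pixels
    return np.interp(idx, np.arange(n, dtype=float), profile, left=fill, right=fill)


def compose_axial_intensity(
    phantom: RetinaPhantom,
    state: FocusState,
    params: SystemParams,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Render the axial intensity profile I(z; zf) for one focus/motion
    state.

    The reflectivity is shifted by ``state.axial_shift`` (µm) before being
    weighted by the focus-dependent CPSF and the depth-dependent attenuation
    and roll-off factors; zero-mean Gaussian noise is added and the result
    clamped to be nonnegative.  Deterministic for a given rng seed.
    """
    if phantom.n_depth_pixels != params.n_depth_pixels:
        raise SimulationError("phantom length must equal n_depth_pixels")
    pitch = params.axial_pixel_pitch
    shift_px = state.axial_shift / pitch

    # flag motion that pushes the whole retina out of the imaging window
    deepest = phantom.outer_band_center + shift_px
    shallowest = (
        phantom.inner_band_center if phantom.inner_band_center is not None
        else phantom.outer_band_center
    ) + shift_px
    if deepest < 0 or shallowest >= params.n_depth_pixels:
        raise SimulationError(
            f"axial shift {state.axial_shift:+.1f} um moves the retina out of the window"
        )

    r_shifted = _shift_profile(phantom.reflectivity_R, shift_px, phantom.background_level)
    z = params.depth_um
    intensity = (
        r_shifted
        * cpsf(z, state.focal_depth_zf, params)
        * attenuation(z, params)
        * sensitivity_rolloff(z, params)
    )
    if params.noise_floor_sigma > 0:
        gen = np.random.default_rng(rng)
        intensity = intensity + gen.normal(0.0, params.noise_floor_sigma, intensity.shape)
    return np.clip(intensity, 0.0, None)


def render_bscan(
    phantom: RetinaPhantom,
    state: FocusState,
    params: SystemParams,
    lateral_variation: float = 0.02,
    rng: np.random.Generator | int | None = None,
) -> BScan:
    """Render a B-scan by replicating the axial profile across lateral
    positions with small per-column gain variation and per-pixel noise.

    All columns share the same phantom and focus state, mimicking a
    laterally homogeneous patch of retina under a fixed focal plane.
    """
    gen = np.random.default_rng(rng)
    # noiseless axial profile; noise is drawn per pixel below
    quiet = replace_noise(params, 0.0)
    profile = compose_axial_intensity(phantom, state, quiet)
    image = np.tile(profile[:, None], (1, params.n_lateral_ascans))
    if lateral_variation > 0:
        gains = 1.0 + lateral_variation * gen.standard_normal(params.n_lateral_ascans)
        image = image * gains[None, :]
    if params.noise_floor_sigma > 0:
        image = image + gen.normal(0.0, params.noise_floor_sigma, image.shape)
    return BScan(intensity=np.clip(image, 0.0, None), meta=state)


def replace_noise(params: SystemParams, sigma: float) -> SystemParams:
    """Copy of ``params`` with a different noise floor."""
    return replace(params, noise_floor_sigma=sigma)


# ---------------------------------------------------------------------------
# Stochastic trajectories and phantoms
# ---------------------------------------------------------------------------

def ou_trajectory(
    params: OUParams,
    n_steps: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sample an Ornstein-Uhlenbeck path with the exact discrete-time
    update.

    ``x_{t+1} = μ + (x_t - μ) e^{-θ dt} + σ √(1 - e^{-2θ dt}) ξ_t`` with the
    initial value drawn from the stationary distribution N(μ, σ²), so the
    whole path is stationary and its long-run sample std converges to
    ``stationary_sigma``.
    """
    if n_steps < 1:
        raise SimulationError("n_steps must be >= 1")
    gen = np.random.default_rng(rng)
    mu, sigma = params.equilibrium_mu, params.stationary_sigma
    decay = np.exp(-params.mean_reversion_theta * params.dt)
    kick = sigma * np.sqrt(1.0 - decay**2)
    x = np.empty(n_steps)
    x[0] = mu + sigma * gen.standard_normal()
    noise = gen.standard_normal(n_steps - 1) if n_steps > 1 else np.empty(0)
    for t in range(1, n_steps):
        x[t] = mu + (x[t - 1] - mu) * decay + kick * noise[t - 1]
    return x


def _band(z: np.ndarray, center: float, width: float, edge_sigma: float) -> np.ndarray:
    """Flat-topped band of the given full width with soft (erf) edges.

    Retinal layer complexes are bounded by sharp refractive-index
    interfaces; a flat-topped profile keeps the edge positions fixed under
    the multiplicative focus weighting (a smooth bump's apparent peak would
    drift toward the focal plane, which real layer boundaries do not do).
    """
    from scipy.special import erf

    half = width / 2.0
    s = edge_sigma * np.sqrt(2.0)
    return 0.5 * (erf((z - (center - half)) / s) - erf((z - (center + half)) / s))


def make_phantom(
    n_depth_pixels: int = 400,
    inner_band_center: float = 140.0,
    outer_band_center: float = 240.0,
    band_widths: tuple = (30.0, 25.0),
    band_amplitudes: tuple = (0.8, 1.0),
    edge_sigma: float = 0.7,
    background_level: float = 0.02,
    foveal: bool = False,
    randomize: bool = False,
    rng: np.random.Generator | int | None = None,
) -> RetinaPhantom:
    """Build a synthetic two-band retina reflectivity phantom.

    The phantom carries a shallower inner-retina band and a deeper,
    brighter outer-retina band (the bright inner/outer retinal complexes of
    a cross-sectional B-scan) over a low background; bands are flat-topped
    with sharp edges, whose spacing (~300 µm at 3 µm/pixel) matches a
    healthy retinal thickness.  ``foveal=True`` drops the inner band,
    emulating foveal regions with bright structure only at the outer
    retina.  ``randomize=True`` jitters band positions, widths and
    amplitudes for generalization tests.
    """
    gen = np.random.default_rng(rng)
    inner_c, outer_c = float(inner_band_center), float(outer_band_center)
    w_in, w_out = band_widths
    a_in, a_out = band_amplitudes
    if randomize:
        inner_c += gen.uniform(-15.0, 15.0)
        outer_c += gen.uniform(-15.0, 15.0)
        w_in *= gen.uniform(0.7, 1.4)
        w_out *= gen.uniform(0.7, 1.4)
        a_in *= gen.uniform(0.7, 1.2)
        a_out *= gen.uniform(0.85, 1.1)
        if outer_c - inner_c < 60.0:  # keep bands well separated
            outer_c = inner_c + 60.0

    z = np.arange(n_depth_pixels, dtype=float)
    r = np.full(n_depth_pixels, float(background_level))
    r += a_out * _band(z, outer_c, w_out, edge_sigma)
    if not foveal:
        r += a_in * _band(z, inner_c, w_in, edge_sigma)
    return RetinaPhantom(
        reflectivity_R=r,
        inner_band_center=None if foveal else inner_c,
        outer_band_center=outer_c,
        band_widths=(w_in, w_out),
        background_level=float(background_level),
    )
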