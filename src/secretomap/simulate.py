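"""Ground-truthed synthetic scenes of a plasmonic sensing/reference well pair.

The simulator emulates the physics chain of the microwell sensor closely
enough that every pipeline stage can be exercised with known truth:

* **Secretion and binding** — the cell releases analyte at a profile-driven
  rate; each time step's mass lands on the substrate as an angularly
  weighted Gaussian puff whose width grows diffusively with time since
  onset (``sigma(age) = sqrt(sigma0^2 + 4*D*age)``).  Capture follows a
  Langmuir law: deposition at a pixel scales with ``1 - b/b_max`` and bound
  mass is irreversible, so the halo both spreads and saturates.
* **Optical transduction** — bound mass redshifts the local resonance
  linearly up to ``max_shift_nm``; the camera signal is a narrowband LED
  spectrum integrated against a Lorentzian transmission line at the
  shifted resonance (a first-order linear approximation is selectable).
* **Scene rendering** — a darker motile cell disc executes a seeded random
  walk; the well border is drawn as a dark ring (so the circular Hough
  detection has a real edge); shared low-frequency multiplicative drift,
  Gaussian read noise and optional Poisson shot noise corrupt both wells.
  The reference well shares drift and noise statistics but holds no cell
  and no secretion.

Division mode elongates then splits the cell disc; burst mode deposits a
large mass within ~10 min of the trigger, emulating necroptotic release.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError
from .io import ImageStack, WellPair, WellStack

__all__ = [
    "SecretionProfile",
    "HaloConfig",
    "BindingConfig",
    "OpticsConfig",
    "NoiseConfig",
    "SceneConfig",
    "SceneGroundTruth",
    "secretion_field",
    "transduce",
    "nonlinearity_factor",
    "simulate_scene",
    "simulate_pair",
]


@dataclass(frozen=True)
class SecretionProfile:
    """Release-rate program of the simulated cell.

    ``kind`` is one of ``none``, ``constant``, ``saturating``, ``two_phase``,
    ``burst``, ``burst_plus_gradual``.  Rates are in mass units per minute;
    times in minutes from the start of the run.
    """

    kind: str = "constant"
    rate: float = 2.0
    onset_min: float = 30.0
    t_plateau_min: float = 300.0  # secretion stops here (saturating/two_phase)
    t_resume_min: float = 480.0  # second phase start (two_phase)
    rate2: float | None = None  # second-phase rate, defaults to ``rate``
    t_burst_min: float = 60.0
    burst_mass: float = 400.0
    burst_window_min: float = 10.0  # burst is spread over <= this much time
    gradual_rate: float = 0.5  # post-burst release (burst_plus_gradual)
    gradual_delay_min: float = 40.0  # rest period after the burst

    _KINDS = ("none", "constant", "saturating", "two_phase", "burst", "burst_plus_gradual")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ConfigurationError(f"unknown profile kind {self.kind!r}")

    @property
    def expected_type(self) -> str:
        """The TIC-curve class this profile should produce."""
        return {
            "none": "NS",
            "constant": "I",
            "saturating": "II",
            "two_phase": "III",
            "burst": "burst",
            "burst_plus_gradual": "burst_plus_gradual",
        }[self.kind]

    def rate_at(self, t_min: float) -> float:
        """Instantaneous gradual release rate (mass/min); bursts excluded."""
        if self.kind in ("none", "burst"):
            return 0.0
        if self.kind == "burst_plus_gradual":
            t0 = self.t_burst_min + self.burst_window_min + self.gradual_delay_min
            return self.gradual_rate if t_min >= t0 else 0.0
        if t_min < self.onset_min:
            return 0.0
        if self.kind == "constant":
            return self.rate
        if self.kind == "saturating":
            return self.rate if t_min < self.t_plateau_min else 0.0
        # two_phase
        if t_min < self.t_plateau_min:
            return self.rate
        if t_min < self.t_resume_min:
            return 0.0
        return self.rate2 if self.rate2 is not None else self.rate

    def burst_mass_at(self, t_min: float, dt_min: float) -> float:
        """Mass released by the burst during [t, t + dt), if any."""
        if self.kind not in ("burst", "burst_plus_gradual"):
            return 0.0
        n_frames = max(1, math.ceil(self.burst_window_min / dt_min))
        frame = (t_min - self.t_burst_min) / dt_min
        if 0 <= frame < n_frames:
            return self.burst_mass / n_frames
        return 0.0


@dataclass(frozen=True)
class HaloConfig:
    """Diffusive spreading of released mass before capture."""

    sigma0_um: float = 5.0  # initial puff width
    diffusion_um2_min: float = 0.5  # effective 2D diffusion coefficient
    anisotropy: float = 0.0  # 0 isotropic .. 1 full cardioid (C shape)
    anisotropy_direction_deg: float = 0.0
    burst_spread_um: float = 25.0  # puff width for burst deposits

    def sigma_um(self, age_min: float) -> float:
        return math.sqrt(self.sigma0_um**2 + 4.0 * self.diffusion_um2_min * max(age_min, 0.0))


@dataclass(frozen=True)
class BindingConfig:
    """Langmuir capture on the functionalized surface (irreversible)."""

    b_max: float = 3.0  # per-pixel surface capacity, mass units
    capture_efficiency: float = 1.0


@dataclass(frozen=True)
class OpticsConfig:
    """EOT resonance and illumination parameters (nm)."""

    resonance_nm: float = 860.7
    fwhm_nm: float = 22.6
    led_center_nm: float = 850.0
    led_fwhm_nm: float = 30.0
    max_shift_nm: float = 10.0
    linear: bool = False  # use the first-order small-shift approximation


@dataclass(frozen=True)
class NoiseConfig:
    read_sigma: float = 2.0  # additive Gaussian, counts
    shot_scale: float = 0.0  # photons per count; 0 disables shot noise
    drift_amplitude: float = 0.002  # multiplicative, shared between wells
    drift_period_min: float | None = None  # default: 4x the run length


@dataclass(frozen=True)
class SceneConfig:
    """Full description of a simulated sensing/reference pair."""

    well_diameter_um: float = 200.0
    well_height_um: float = 50.0
    object_pixel_size_um: float = 0.65
    crop_side: int = 350
    frame_interval_min: float = 10.0
    n_frames: int = 73
    cell_radius_um: float = 8.0
    cell_contrast: float = 0.3  # fractional darkening of the cell disc
    motion_msd_target_um2: float = 1.2
    baseline_counts: float = 1000.0
    profile: SecretionProfile = field(default_factory=SecretionProfile)
    halo: HaloConfig = field(default_factory=HaloConfig)
    binding: BindingConfig = field(default_factory=BindingConfig)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    division_time_min: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.well_diameter_um <= 0 or self.object_pixel_size_um <= 0:
            raise ConfigurationError("lengths must be > 0")
        if self.well_radius_px * 2 >= self.crop_side:
            raise ConfigurationError(
                f"well ({self.well_diameter_um} um = {2 * self.well_radius_px:.0f} px) "
                f"does not fit the {self.crop_side} px crop at "
                f"{self.object_pixel_size_um} um/px"
            )

    @property
    def well_radius_px(self) -> float:
        return self.well_diameter_um / 2.0 / self.object_pixel_size_um

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) * self.frame_interval_min


@dataclass
class SceneGroundTruth:
    """Simulator-side truth for every frame of a scene."""

    bound_mass: np.ndarray  # (T, H, W) float32, non-decreasing per pixel
    cumulative_secreted_mass: np.ndarray  # (T,)
    cell_masks: np.ndarray  # (T, H, W) bool
    centroids_px: np.ndarray  # (T, 2) row/col (NaN when no cell)
    events: dict
    type_label: str
    msd_um2: float
    config: SceneConfig


def _gaussian_puff(
    shape: tuple[int, int],
    center: tuple[float, float],
    sigma_px: float,
    anisotropy: float,
    direction_rad: float,
) -> np.ndarray:
    """Unit-mass spatial kernel: isotropic Gaussian times an angular cardioid."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    kernel = np.exp(-(dr**2 + dc**2) / (2.0 * sigma_px**2))
    if anisotropy > 0:
        theta = np.arctan2(dr, dc)
        kernel = kernel * (1.0 + anisotropy * np.cos(theta - direction_rad))
    total = kernel.sum()
    return kernel / total if total > 0 else kernel


def _deposit(
    bound: np.ndarray,
    mass: float,
    center: tuple[float, float],
    sigma_px: float,
    binding: BindingConfig,
    halo: HaloConfig,
) -> float:
    """Add one puff with Langmuir limiting; returns the mass actually bound."""
    if mass <= 0:
        return 0.0
    kernel = _gaussian_puff(
        bound.shape,
        center,
        sigma_px,
        halo.anisotropy,
        math.radians(halo.anisotropy_direction_deg),
    )
    increment = (
        binding.capture_efficiency
        * mass
        * kernel
        * np.clip(1.0 - bound / binding.b_max, 0.0, 1.0)
    )
    # a discrete step must not overshoot the surface capacity
    np.minimum(increment, binding.b_max - bound, out=increment)
    bound += increment
    return float(increment.sum())


def secretion_field(
    profile: SecretionProfile,
    halo: HaloConfig,
    binding: BindingConfig,
    cell_position: tuple[float, float],
    t_min: float,
    shape: tuple[int, int] = (350, 350),
    pixel_size_um: float = 0.65,
    dt_min: float = 10.0,
) -> np.ndarray:
    """Bound-density map at time ``t_min`` for a stationary cell.

    Integrates the deposition process from the start of the run in steps of
    ``dt_min``; the full simulator does the same with a moving cell.
    """
    bound = np.zeros(shape)
    t = 0.0
    while t <= t_min + 1e-9:
        mass = profile.rate_at(t) * dt_min + profile.burst_mass_at(t, dt_min)
        if mass > 0:
            age = t - profile.onset_min if profile.kind not in ("burst",) else 0.0
            sigma_um = (
                halo.burst_spread_um
                if profile.burst_mass_at(t, dt_min) > 0
                else halo.sigma_um(age)
            )
            _deposit(bound, mass, cell_position, sigma_um / pixel_size_um, binding, halo)
        t += dt_min
    return bound


def _intensity_lookup(optics: OpticsConfig, n: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Transmitted intensity vs resonance shift, LED x Lorentzian integral."""
    gamma = optics.fwhm_nm
    led_sigma = optics.led_fwhm_nm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    lam = np.linspace(
        min(optics.led_center_nm - 4 * optics.led_fwhm_nm, optics.resonance_nm - 4 * gamma),
        max(optics.led_center_nm + 4 * optics.led_fwhm_nm, optics.resonance_nm + 4 * gamma),
        1200,
    )
    led = np.exp(-((lam - optics.led_center_nm) ** 2) / (2.0 * led_sigma**2))
    shifts = np.linspace(0.0, optics.max_shift_nm, n)
    center = optics.resonance_nm + shifts[:, None]
    lorentz = 1.0 / (1.0 + ((lam[None, :] - center) / (gamma / 2.0)) ** 2)
    intensity = np.trapezoid(led[None, :] * lorentz, lam, axis=1)
    return shifts, intensity


def transduce(
    bound: np.ndarray,
    optics: OpticsConfig,
    b_max: float,
    baseline_counts: float = 1000.0,
) -> np.ndarray:
    """Map a bound-density image to transmitted-intensity counts.

    Local resonance shift is ``max_shift * b / b_max`` (clipped at
    ``max_shift``); the transmitted intensity is the LED spectrum
    integrated against the shifted Lorentzian line, normalized so zero
    binding gives ``baseline_counts``.  With ``optics.linear`` the
    first-order Taylor expansion around zero shift is used instead.
    """
    shift = np.clip(
        optics.max_shift_nm * np.asarray(bound, dtype=float) / b_max,
        0.0,
        optics.max_shift_nm,
    )
    shifts, intensity = _intensity_lookup(optics)
    if optics.linear:
        slope = (intensity[1] - intensity[0]) / (shifts[1] - shifts[0])
        raw = intensity[0] + slope * shift
    else:
        raw = np.interp(shift, shifts, intensity)
    return baseline_counts * raw / intensity[0]


def nonlinearity_factor(optics: OpticsConfig, shift_nm: float) -> float:
    """Ratio of the full spectral response to its linear extrapolation.

    1.0 means perfectly linear transduction at ``shift_nm``; the departure
    grows as the shift approaches the resonance linewidth.
    """
    shifts, intensity = _intensity_lookup(optics)
    slope = (intensity[1] - intensity[0]) / (shifts[1] - shifts[0])
    full = np.interp(min(shift_nm, optics.max_shift_nm), shifts, intensity) - intensity[0]
    linear = slope * shift_nm
    return float(full / linear) if linear != 0 else 1.0


def _base_pattern(config: SceneConfig) -> np.ndarray:
    """Static substrate image: bright interior, dark well wall, dimmer outside."""
    n = config.crop_side
    rr, cc = np.ogrid[:n, :n]
    center = (n - 1) / 2.0
    dist = np.sqrt((rr - center) ** 2 + (cc - center) ** 2)
    radius = config.well_radius_px
    pattern = np.ones((n, n))
    pattern[dist > radius] = 0.9
    pattern[np.abs(dist - radius) <= 2.0] = 0.6
    return pattern


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius_px: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def _cell_positions(
    config: SceneConfig, rng: np.random.Generator
) -> np.ndarray:
    """Seeded random walk (px) scaled so the run MSD approaches the target."""
    n = config.n_frames
    msd_px2 = config.motion_msd_target_um2 / config.object_pixel_size_um**2
    # E|x_t - x_0|^2 = 2 sigma^2 t for a 2D walk; mean over t=1..n-1 gives
    # sigma^2 * n, so sigma = sqrt(target / n).
    step_sigma = math.sqrt(msd_px2 / max(n, 1))
    center = (config.crop_side - 1) / 2.0
    start = np.array([center, center]) + rng.uniform(-3, 3, size=2)
    steps = rng.normal(0.0, step_sigma, size=(n, 2))
    steps[0] = 0.0
    positions = start + np.cumsum(steps, axis=0)
    # keep the cell well inside the well
    limit = config.well_radius_px * 0.5
    return np.clip(positions, center - limit, center + limit)


def simulate_scene(
    config: SceneConfig,
) -> tuple[WellStack, WellStack, SceneGroundTruth]:
    """Render a sensing/reference well pair with full ground truth.

    Bit-identical output for identical config and seed.  The reference well
    shares the drift realization and noise statistics with the sensing well
    but contains no cell and no secretion.
    """
    rng = np.random.default_rng(config.seed)
    n, side = config.n_frames, config.crop_side
    times = config.times_min
    dt = config.frame_interval_min
    profile = config.profile

    positions = _cell_positions(config, rng)
    cell_radius_px = config.cell_radius_um / config.object_pixel_size_um

    drift_period = config.noise.drift_period_min or 4.0 * max(times[-1], dt)
    drift_phase = rng.uniform(0, 2 * math.pi)
    drift = 1.0 + config.noise.drift_amplitude * np.sin(
        2 * math.pi * times / drift_period + drift_phase
    )

    base = _base_pattern(config) * config.baseline_counts
    bound = np.zeros((side, side))
    truth_bound = np.zeros((n, side, side), dtype=np.float32)
    cum_mass = np.zeros(n)
    cell_masks = np.zeros((n, side, side), dtype=bool)
    centroids = np.full((n, 2), np.nan)
    sensing = np.zeros((n, side, side), dtype=np.float32)
    reference = np.zeros((n, side, side), dtype=np.float32)

    division = config.division_time_min
    daughter_offsets = None
    released = 0.0

    for t_idx, t in enumerate(times):
        # --- cell geometry -------------------------------------------------
        pos = positions[t_idx]
        if division is not None and t >= division:
            frames_since = (t - division) / dt
            sep = min(frames_since + 1, 3.0) * cell_radius_px * 0.8
            if daughter_offsets is None:
                angle = rng.uniform(0, 2 * math.pi)
                daughter_offsets = np.array(
                    [[math.sin(angle), math.cos(angle)], [-math.sin(angle), -math.cos(angle)]]
                )
            centers = [tuple(pos + daughter_offsets[0] * sep), tuple(pos + daughter_offsets[1] * sep)]
            radius = cell_radius_px * 0.85
        elif division is not None and division - dt <= t < division:
            centers = [tuple(pos)]
            radius = cell_radius_px * 1.3  # elongating mother
        else:
            centers = [tuple(pos)]
            radius = cell_radius_px
        mask = np.zeros((side, side), dtype=bool)
        for c in centers:
            mask |= _disc_mask((side, side), c, radius)
        cell_masks[t_idx] = mask
        centroids[t_idx] = pos

        # --- secretion deposit ---------------------------------------------
        gradual = profile.rate_at(t) * dt
        burst = profile.burst_mass_at(t, dt)
        if gradual > 0:
            age = t - (
                profile.onset_min
                if profile.kind != "burst_plus_gradual"
                else profile.t_burst_min + profile.burst_window_min + profile.gradual_delay_min
            )
            sigma_px = config.halo.sigma_um(age) / config.object_pixel_size_um
            per_center = gradual / len(centers)
            for c in centers:
                released += per_center
                _deposit(bound, per_center, c, sigma_px, config.binding, config.halo)
        if burst > 0:
            sigma_px = config.halo.burst_spread_um / config.object_pixel_size_um
            released += burst
            _deposit(bound, burst, tuple(pos), sigma_px, config.binding, config.halo)
        truth_bound[t_idx] = bound
        cum_mass[t_idx] = released

        # --- optics + rendering --------------------------------------------
        relative = transduce(
            bound, config.optics, config.binding.b_max, baseline_counts=1.0
        )
        img = base * relative
        img[mask] = base[mask] * (1.0 - config.cell_contrast)
        img *= drift[t_idx]
        ref = base * drift[t_idx]

        if config.noise.read_sigma > 0:
            img = img + rng.normal(0, config.noise.read_sigma, size=img.shape)
            ref = ref + rng.normal(0, config.noise.read_sigma, size=ref.shape)
        if config.noise.shot_scale > 0:
            img = rng.poisson(np.clip(img, 0, None) * config.noise.shot_scale) / config.noise.shot_scale
            ref = rng.poisson(np.clip(ref, 0, None) * config.noise.shot_scale) / config.noise.shot_scale
        sensing[t_idx] = np.clip(img, 0, None)
        reference[t_idx] = np.clip(ref, 0, None)

    disp = (positions[1:] - positions[0]) * config.object_pixel_size_um
    msd = float(np.mean(np.sum(disp**2, axis=1))) if len(disp) else 0.0

    events = {
        "onset_min": profile.onset_min if profile.kind not in ("none", "burst", "burst_plus_gradual") else None,
        "plateau_start_min": profile.t_plateau_min if profile.kind in ("saturating", "two_phase") else None,
        "plateau_end_min": profile.t_resume_min if profile.kind == "two_phase" else None,
        "division_min": division,
        "burst_min": profile.t_burst_min if profile.kind in ("burst", "burst_plus_gradual") else None,
    }

    truth = SceneGroundTruth(
        bound_mass=truth_bound,
        cumulative_secreted_mass=cum_mass,
        cell_masks=cell_masks,
        centroids_px=centroids,
        events=events,
        type_label=profile.expected_type,
        msd_um2=msd,
        config=config,
    )
    sensing_well = WellStack(
        stack=ImageStack(frames=sensing, times=times.copy()),
        well_id="S1",
        role="sensing",
    )
    reference_well = WellStack(
        stack=ImageStack(frames=reference, times=times.copy()),
        well_id="R1",
        role="reference",
    )
    return sensing_well, reference_well, truth


def simulate_pair(config: SceneConfig) -> tuple[WellPair, SceneGroundTruth]:
    """Convenience wrapper returning a :class:`WellPair` directly."""
    sensing, reference, truth = simulate_scene(config)
    return WellPair(sensing=sensing, reference=reference), truth
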