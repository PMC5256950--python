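"""Synthetic-data generators with recorded ground truth.

Every analysis stage in this package has a matched generator here:

* :func:`simulate_membrane_stack` — surface-illumination images of a membrane
  carrying diffraction-limited receptor nanoclusters (spatial Poisson
  process, Gaussian PSF, Poisson shot noise, linear camera).
* :func:`simulate_decay_cube` — per-pixel TCSPC photon-arrival histograms
  of a donor / donor+acceptor lifetime mixture with a Gaussian IRF and
  wrap-around at the laser repetition period.
* :func:`simulate_frap_trace` — partial-recovery FRAP traces with scan
  bleaching applied to bleach and reference ROIs.
* :func:`simulate_bleach_trace` — stepwise photobleaching staircases.

All generators take a seed and are reproducible bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .containers import BleachTrace, DecayCube, FRAPTrace, FrameStack, GaussianIRF

__all__ = [
    "MembraneSimParams",
    "FlimSimParams",
    "FrapSimParams",
    "BleachSimParams",
    "MembraneGroundTruth",
    "FlimGroundTruth",
    "FrapGroundTruth",
    "BleachGroundTruth",
    "render_spots",
    "simulate_membrane_stack",
    "simulate_decay_cube",
    "simulate_frap_trace",
    "simulate_bleach_trace",
]

# Axelrod-style half-time relation for a circular bleach spot:
# tau_half = HALF_TIME_FACTOR * w^2 / D.
HALF_TIME_FACTOR = 0.224


# ---------------------------------------------------------------------------
# membrane / VAEM images
# ---------------------------------------------------------------------------


@dataclass
class MembraneSimParams:
    """Parameters of the clustered-membrane image generator.

    Defaults reproduce the acquisition geometry of a 100x/1.49 NA TIRF
    objective with an emCCD (130 nm pixels) imaging GFP-tagged receptors at
    near-endogenous density: 0.55 nanoclusters per µm² of 6 receptors each.
    """

    field_px: int = 256
    pixel_size_nm: float = 130.0
    cluster_density: float = 0.55  # clusters / um^2
    receptors_per_cluster: int = 6
    brightness: float = 200.0  # photons / receptor / frame
    psf_sigma_nm: float = 110.0  # ~0.21 * 510 nm / 1.49 for GFP emission
    background: float = 50.0  # photons / pixel / frame
    gain: float = 1.0
    read_noise: float = 2.0  # a.u. rms, applied after gain
    frames: int = 1
    maturation: float = 1.0  # fluorophore maturation probability
    frame_interval_ms: float = 100.0
    seed: int | None = None

    def validate(self) -> None:
        if self.cluster_density < 0:
            raise ValueError("cluster density must be >= 0")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")
        if self.brightness < 0:
            raise ValueError("brightness must be >= 0")
        if self.psf_sigma_nm <= 0:
            raise ValueError("PSF sigma must be positive")
        if self.receptors_per_cluster < 1:
            raise ValueError("receptors per cluster must be >= 1")
        if not 0.0 <= self.maturation <= 1.0:
            raise ValueError("maturation must be in [0, 1]")
        sigma_px = self.psf_sigma_nm / self.pixel_size_nm
        if self.field_px < 6 * sigma_px:
            raise ValueError("field too small to hold a single PSF")


@dataclass
class MembraneGroundTruth:
    """True cluster configuration behind a simulated membrane stack."""

    centers_px: np.ndarray  # (n, 2) as (row, col)
    receptors: np.ndarray  # receptors placed per cluster
    fluorophores: np.ndarray  # matured (emitting) fluorophores per cluster
    nominal_area_px: float  # PSF footprint pi*(2 sigma)^2 in pixels
    density: float  # true density used (clusters / um^2)
    field_area_um2: float
    expected: np.ndarray  # noiseless expected photon image (incl. background)

    @property
    def n_clusters(self) -> int:
        return len(self.centers_px)


def render_spots(
    shape: tuple[int, int],
    centers: np.ndarray,
    amplitudes: np.ndarray,
    sigma_px: float,
) -> np.ndarray:
    """Render pixel-integrated 2-D Gaussian spots.

    Each spot deposits ``amplitude`` photons integrated over the pixel grid
    (exact error-function integration over a +/-5 sigma patch, so flux is
    conserved to better than 1e-5 for spots away from the border).
    """
    img = np.zeros(shape, dtype=float)
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), (len(centers),))
    half = int(np.ceil(5 * sigma_px))
    s = sigma_px * np.sqrt(2.0)
    ny, nx = shape
    for (cy, cx), amp in zip(centers, amplitudes):
        if amp == 0:
            continue
        y0, y1 = max(int(np.floor(cy)) - half, 0), min(int(np.floor(cy)) + half + 1, ny)
        x0, x1 = max(int(np.floor(cx)) - half, 0), min(int(np.floor(cx)) + half + 1, nx)
        if y0 >= y1 or x0 >= x1:
            continue
        ys = np.arange(y0, y1)
        xs = np.arange(x0, x1)
        fy = 0.5 * (erf((ys + 0.5 - cy) / s) - erf((ys - 0.5 - cy) / s))
        fx = 0.5 * (erf((xs + 0.5 - cx) / s) - erf((xs - 0.5 - cx) / s))
        img[y0:y1, x0:x1] += amp * np.outer(fy, fx)
    return img


def simulate_membrane_stack(
    params: MembraneSimParams,
) -> tuple[FrameStack, MembraneGroundTruth]:
    """Simulate a static membrane snapshot carrying receptor nanoclusters.

    Cluster centres follow a homogeneous spatial Poisson process with the
    requested density; every cluster renders as the summed PSFs of its
    (matured) receptors.  Per-frame Poisson shot noise, linear camera gain
    and Gaussian read noise are applied independently per frame.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    px_um = params.pixel_size_nm / 1000.0
    area_um2 = (params.field_px * px_um) ** 2
    sigma_px = params.psf_sigma_nm / params.pixel_size_nm

    n_clusters = rng.poisson(params.cluster_density * area_um2)
    centers = rng.uniform(0.0, params.field_px, size=(n_clusters, 2))
    receptors = np.full(n_clusters, params.receptors_per_cluster, dtype=int)
    if params.maturation < 1.0:
        fluorophores = rng.binomial(receptors, params.maturation)
    else:
        fluorophores = receptors.copy()

    shape = (params.field_px, params.field_px)
    expected = np.full(shape, float(params.background))
    if n_clusters:
        expected += render_spots(
            shape, centers, fluorophores * params.brightness, sigma_px
        )

    frames = np.empty((params.frames,) + shape, dtype=np.float32)
    for f in range(params.frames):
        counts = rng.poisson(expected)
        frame = params.gain * counts
        if params.read_noise > 0:
            frame = frame + rng.normal(0.0, params.read_noise, size=shape)
        frames[f] = frame

    stack = FrameStack(
        frames,
        pixel_size_nm=params.pixel_size_nm,
        frame_interval_ms=params.frame_interval_ms,
        meta={"seed": params.seed, "generator": "simulate_membrane_stack"},
    )
    gt = MembraneGroundTruth(
        centers_px=centers,
        receptors=receptors,
        fluorophores=fluorophores,
        nominal_area_px=float(np.pi * (2 * sigma_px) ** 2),
        density=params.cluster_density,
        field_area_um2=area_um2,
        expected=expected,
    )
    return stack, gt


# ---------------------------------------------------------------------------
# TCSPC decay cubes
# ---------------------------------------------------------------------------


@dataclass
class FlimSimParams:
    """Parameters of the TCSPC decay-cube generator.

    A fraction ``f_interacting`` of pixels carries the FRET-shortened donor
    lifetime (given either directly as ``tau_fret_ps`` or via a FRET
    efficiency ``fret_efficiency`` so that tau_DA = tau_D (1 - E)); the rest
    decay with the unquenched donor lifetime.  Photon arrival times are
    exponential, jittered by a Gaussian IRF and wrapped at the repetition
    period before histogramming into ``n_channels`` channels.
    """

    shape: tuple[int, int] = (128, 128)
    tau_donor_ps: float = 2402.0
    tau_fret_ps: float | None = None
    fret_efficiency: float | None = 0.25
    f_interacting: float = 0.15
    photons_mean: float = 3000.0
    photons_min: int = 0
    n_channels: int = 256
    channel_width_ps: float | None = None  # default: period / n_channels
    rep_rate_mhz: float = 40.0
    irf_center_ps: float | None = None  # default: centre of channel 10
    irf_fwhm_ps: float = 300.0
    background_fraction: float = 0.02
    seed: int | None = None

    @property
    def period_ps(self) -> float:
        return 1e6 / self.rep_rate_mhz

    def resolved_channel_width(self) -> float:
        return self.channel_width_ps or self.period_ps / self.n_channels

    def resolved_tau_fret(self) -> float:
        if self.tau_fret_ps is not None:
            return float(self.tau_fret_ps)
        if self.fret_efficiency is None:
            raise ValueError("give either tau_fret_ps or fret_efficiency")
        return self.tau_donor_ps * (1.0 - self.fret_efficiency)

    def resolved_irf(self) -> GaussianIRF:
        width = self.resolved_channel_width()
        center = self.irf_center_ps if self.irf_center_ps is not None else 10 * width
        return GaussianIRF(center_ps=center, fwhm_ps=self.irf_fwhm_ps)

    def validate(self) -> None:
        if not 0.0 <= self.f_interacting <= 1.0:
            raise ValueError("f_interacting must be in [0, 1]")
        tau_da = self.resolved_tau_fret()
        if not 0 < tau_da <= self.tau_donor_ps:
            raise ValueError("need 0 < tau_DA <= tau_D")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must be in [0, 1)")
        if self.photons_mean < 0:
            raise ValueError("photons_mean must be >= 0")
        if self.tau_donor_ps >= self.period_ps / 2:
            warnings.warn(
                "donor lifetime exceeds half the repetition period; "
                "wrap-around will dominate the decay",
                stacklevel=2,
            )
        if self.n_channels * self.resolved_channel_width() < 3 * self.tau_donor_ps:
            warnings.warn(
                "TCSPC window shorter than 3 donor lifetimes", stacklevel=2
            )


@dataclass
class FlimGroundTruth:
    """True pixel labels and parameters behind a simulated decay cube."""

    interacting: np.ndarray  # boolean (ny, nx)
    tau_map_ps: np.ndarray  # true lifetime per pixel
    photons: np.ndarray  # drawn photon total per pixel
    tau_donor_ps: float
    tau_fret_ps: float
    f_interacting: float

    @property
    def f_realized(self) -> float:
        return float(self.interacting.mean())


def simulate_decay_cube(params: FlimSimParams) -> tuple[DecayCube, FlimGroundTruth]:
    """Simulate a per-pixel TCSPC histogram cube with ground-truth labels."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    ny, nx = params.shape
    n_px = ny * nx
    n_ch = params.n_channels
    width = params.resolved_channel_width()
    period = params.period_ps
    irf = params.resolved_irf()
    tau_da = params.resolved_tau_fret()

    interacting = rng.random((ny, nx)) < params.f_interacting
    tau_map = np.where(interacting, tau_da, params.tau_donor_ps)
    photons = rng.poisson(params.photons_mean, size=(ny, nx))
    photons = np.maximum(photons, params.photons_min)

    counts = np.zeros((n_px, n_ch), dtype=np.uint32)
    tau_flat = tau_map.ravel()
    n_flat = photons.ravel()

    # Chunk rows to bound memory: every photon is an (arrival time, pixel)
    # pair before histogramming.
    chunk = max(1, int(4e6 // max(params.photons_mean * nx, 1)))
    for r0 in range(0, ny, chunk):
        r1 = min(r0 + chunk, ny)
        idx0, idx1 = r0 * nx, r1 * nx
        n_pix = n_flat[idx0:idx1]
        if params.background_fraction > 0:
            n_bg = rng.binomial(n_pix, params.background_fraction)
        else:
            n_bg = np.zeros_like(n_pix)
        n_sig = n_pix - n_bg

        pix_sig = np.repeat(np.arange(idx0, idx1), n_sig)
        t_sig = rng.exponential(1.0, size=n_sig.sum()) * np.repeat(
            tau_flat[idx0:idx1], n_sig
        )
        t_sig += rng.normal(irf.center_ps, irf.sigma_ps, size=t_sig.size)

        pix_bg = np.repeat(np.arange(idx0, idx1), n_bg)
        t_bg = rng.uniform(0.0, period, size=n_bg.sum())

        t = np.concatenate([t_sig, t_bg]) % period
        pix = np.concatenate([pix_sig, pix_bg])
        ch = (t / width).astype(np.int64)
        keep = ch < n_ch  # only relevant when the window undershoots the period
        binned = np.bincount(
            pix[keep] * n_ch + ch[keep], minlength=n_px * n_ch
        )
        counts += binned.reshape(n_px, n_ch).astype(np.uint32)

    cube = DecayCube(
        counts.reshape(ny, nx, n_ch),
        channel_width_ps=width,
        rep_rate_mhz=params.rep_rate_mhz,
        irf=irf,
    )
    gt = FlimGroundTruth(
        interacting=interacting,
        tau_map_ps=tau_map,
        photons=photons,
        tau_donor_ps=params.tau_donor_ps,
        tau_fret_ps=tau_da,
        f_interacting=params.f_interacting,
    )
    return cube, gt


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------


@dataclass
class FrapSimParams:
    """Parameters of the FRAP trace generator.

    The bleach-ROI signal follows

    ``F(t) = F_pre * [(1 - depth) + depth * Mf * R(t)] * S(t)``

    with ``R(t) = 1 - exp(-t / tau_rec)`` a single-exponential recovery whose
    half time satisfies ``tau_half = 0.224 w^2 / D``, and
    ``S(t) = exp(-k_scan (t - t_start))`` the scan-bleaching factor, which
    also attenuates the reference ROI.  Defaults reproduce a largely immobile
    membrane receptor in meristem tissue (Mf = 28 %, D = 0.003 um^2/s)
    followed for 499 s after the bleach pulse.
    """

    mobile_fraction: float = 0.28
    diffusion_um2_s: float = 0.003
    spot_radius_um: float = 1.0
    bleach_depth: float = 0.7
    scan_bleach_rate: float = 0.001  # 1/s
    noise_sd: float = 0.02  # fraction of pre-bleach intensity
    times_s: np.ndarray | None = None
    pre_bleach_points: int = 5
    interval_s: float = 1.0
    recovery_s: float = 499.0
    intensity: float = 1000.0
    background_level: float = 50.0
    seed: int | None = None

    def validate(self) -> None:
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile fraction must be in [0, 1]")
        if self.diffusion_um2_s < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        if self.spot_radius_um <= 0:
            raise ValueError("bleach-spot radius must be positive")
        if not 0.0 < self.bleach_depth <= 1.0:
            raise ValueError("bleach depth must be in (0, 1]")
        if self.pre_bleach_points < 3:
            raise ValueError("need >= 3 pre-bleach points")

    def resolved_times(self) -> tuple[np.ndarray, int]:
        if self.times_s is not None:
            t = np.asarray(self.times_s, dtype=float)
            bleach_index = int(np.searchsorted(t, 0.0))
            return t, bleach_index
        pre = -self.interval_s * np.arange(self.pre_bleach_points, 0, -1)
        post = np.arange(0.0, self.recovery_s + self.interval_s / 2, self.interval_s)
        return np.concatenate([pre, post]), self.pre_bleach_points


@dataclass
class FrapGroundTruth:
    mobile_fraction: float
    diffusion_um2_s: float
    spot_radius_um: float
    tau_half_s: float
    tau_rec_s: float
    bleach_depth: float
    scan_bleach_rate: float


def simulate_frap_trace(params: FrapSimParams) -> tuple[FRAPTrace, FrapGroundTruth]:
    """Simulate bleach / reference / background ROI traces of a FRAP run."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    times, bleach_index = params.resolved_times()

    if params.diffusion_um2_s > 0:
        tau_half = HALF_TIME_FACTOR * params.spot_radius_um**2 / params.diffusion_um2_s
        tau_rec = tau_half / np.log(2.0)
    else:
        tau_half = np.inf
        tau_rec = np.inf

    scan = np.exp(-params.scan_bleach_rate * (times - times[0]))
    post = times >= times[bleach_index]
    recovery = np.zeros_like(times)
    if np.isfinite(tau_rec):
        recovery[post] = 1.0 - np.exp(-(times[post] - times[bleach_index]) / tau_rec)
    bleach_shape = np.where(
        post,
        (1.0 - params.bleach_depth)
        + params.bleach_depth * params.mobile_fraction * recovery,
        1.0,
    )
    f0 = params.intensity
    sd = params.noise_sd * f0
    bleach = f0 * bleach_shape * scan + params.background_level
    reference = f0 * scan + params.background_level
    background = np.full_like(times, params.background_level)
    if sd > 0:
        bleach = bleach + rng.normal(0.0, sd, times.size)
        reference = reference + rng.normal(0.0, sd, times.size)
        background = background + rng.normal(0.0, sd / 4, times.size)

    trace = FRAPTrace(times, bleach, reference, background, bleach_index)
    gt = FrapGroundTruth(
        mobile_fraction=params.mobile_fraction,
        diffusion_um2_s=params.diffusion_um2_s,
        spot_radius_um=params.spot_radius_um,
        tau_half_s=tau_half,
        tau_rec_s=tau_rec,
        bleach_depth=params.bleach_depth,
        scan_bleach_rate=params.scan_bleach_rate,
    )
    return trace, gt


# ---------------------------------------------------------------------------
# photobleaching staircases
# ---------------------------------------------------------------------------


@dataclass
class BleachSimParams:
    """Parameters of the stepwise-photobleaching trace generator."""

    n_fluorophores: int = 6
    step_intensity: float = 100.0
    bleach_rate: float = 0.02  # per fluorophore per frame
    noise_sd: float = 10.0
    frames: int = 400
    baseline: float = 0.0
    seed: int | None = None

    def validate(self) -> None:
        if self.n_fluorophores < 0:
            raise ValueError("n_fluorophores must be >= 0")
        if self.step_intensity <= 0:
            raise ValueError("step intensity must be positive")
        if self.bleach_rate <= 0:
            raise ValueError("bleach rate must be positive")


@dataclass
class BleachGroundTruth:
    n_fluorophores: int
    bleach_frames: np.ndarray  # sorted frame index of each bleaching event


def simulate_bleach_trace(params: BleachSimParams) -> tuple[BleachTrace, BleachGroundTruth]:
    """Simulate a photobleaching staircase with stochastic bleach times."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_fluorophores
    if n > 0:
        t = rng.exponential(1.0 / params.bleach_rate, size=n)
        bleach_frames = np.sort(np.floor(t).astype(int) + 1)
    else:
        bleach_frames = np.empty(0, dtype=int)
    frames = np.arange(params.frames)
    alive = (bleach_frames[None, :] > frames[:, None]).sum(axis=1) if n else np.zeros(
        params.frames
    )
    values = params.baseline + params.step_intensity * alive
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, params.frames)
    trace = BleachTrace(values)
    gt = BleachGroundTruth(n_fluorophores=n, bleach_frames=bleach_frames)
    return trace, gt
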