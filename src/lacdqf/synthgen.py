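"""Synthetic interleaved DQF spectral time series.

Generates single-shot complex spectra with the statistical structure the
downstream analysis assumes, so the whole pipeline is testable without any
acquired data.  The two interleaved amplitude programs are

    fixed tag        A(t)    = a * exp(-t / t_clear) + b            (wall time, s)
    incremented tag  A(tau1) = a * sin(pi J tau1) * exp(-(tau1 - tau1_fixed) / t_comb) + b

with ``t_comb`` obtained by inverting ``1/T2 = 1/t_comb - c / t_clear``
(``c = 2 TR / tau_inc``), so the generator's T2/J/clearance ground truth is
exactly what the kinetic stage is supposed to recover.  The sin argument
uses J in Hz and tau1 in ms through one unit conversion (``/1000``).

Each shot renders a lactate Voigt doublet at 1.3 ppm, a Lorentzian lipid
residue at 1.5 ppm (opposite phase by default), creatine reference singlets
at 3.03 and 3.91 ppm, complex white noise calibrated to a target
single-shot SNR, a linear frequency drift, and occasional motion outliers
(line broadening plus amplitude drop).

Two backends: ``parametric`` (default; amplitudes straight from the
equations above) and ``physics`` (amplitude modulation taken from the
density-matrix DQF simulation, for cross-validation of the sin(pi J tau1)
envelope).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .seqmodel import (
    LARMOR_MHZ_7T,
    WATER_PPM,
    AcquisitionTag,
    TimingSchedule,
    build_schedule,
    ppm_to_hz,
)

__all__ = [
    "GroundTruth",
    "SpectrumSeries",
    "VoigtDoubletShape",
    "t_comb_from_ground_truth",
    "combined_amplitude",
    "render_fid",
    "generate_series",
    "LACTATE_PPM",
    "LIPID_PPM",
    "CREATINE_CH3_PPM",
    "CREATINE_CH2_PPM",
]

LACTATE_PPM = 1.3
LIPID_PPM = 1.5
CREATINE_CH3_PPM = 3.03
CREATINE_CH2_PPM = 3.91

LN2 = math.log(2.0)


@dataclass(frozen=True)
class VoigtDoubletShape:
    """Constant lineshape of the lactate doublet, shared across a series.

    Phases are per-peak zero-order phases (deg); widths are FWHM (Hz) of the
    Gaussian and Lorentzian components of the Voigt profile; ``peak_ratio``
    is the area ratio of the low-field to the high-field component and
    ``splitting_hz`` the doublet separation (the apparent J).
    """

    phase1_deg: float = 0.0
    phase2_deg: float = 0.0
    gauss_fwhm_hz: float = 6.0
    lorentz_fwhm_hz: float = 5.0
    peak_ratio: float = 1.0
    splitting_hz: float = 16.6

    def __post_init__(self) -> None:
        if self.gauss_fwhm_hz <= 0 or self.lorentz_fwhm_hz <= 0:
            raise ValueError("Voigt widths must be > 0")
        if self.peak_ratio <= 0:
            raise ValueError("peak_ratio must be > 0")
        if self.splitting_hz < 0:
            raise ValueError("splitting_hz must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters of one synthetic interleaved dataset.

    Defaults are the post-exercise cohort means of the in vivo study the
    generator emulates: clearance half-time 162 s (t_clear = 162 / ln 2 s),
    T2 = 138 ms, apparent J = 16.6 Hz, single-shot SNR 24.  ``drift`` is a
    slow linear frequency drift; ``outlier_rate`` the per-shot probability
    of a motion-corrupted acquisition.
    """

    t_clear_s: float = 162.0 / LN2
    t2_ms: float = 138.0
    j_hz: float = 16.6
    a0: float = 1.0
    b: float = 0.05
    lipid_amp: float = 0.3
    lipid_phase_deg: float = 180.0
    lipid_fwhm_hz: float = 12.0
    snr: float = 24.0
    drift_hz_per_min: float = 1.0
    outlier_rate: float = 0.01
    seed: int = 0
    shape: VoigtDoubletShape = field(default_factory=VoigtDoubletShape)

    def __post_init__(self) -> None:
        if self.t_clear_s <= 0 or self.t2_ms <= 0:
            raise ValueError("time constants must be > 0")
        if self.j_hz <= 0:
            raise ValueError("j_hz must be > 0")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must be in [0, 1)")

    @property
    def t_half_s(self) -> float:
        return LN2 * self.t_clear_s

    def to_dict(self) -> Dict[str, float]:
        d = {
            k: getattr(self, k)
            for k in (
                "t_clear_s",
                "t2_ms",
                "j_hz",
                "a0",
                "b",
                "lipid_amp",
                "lipid_phase_deg",
                "lipid_fwhm_hz",
                "snr",
                "drift_hz_per_min",
                "outlier_rate",
                "seed",
            )
        }
        d["t_half_s"] = self.t_half_s
        d["shape"] = {
            k: getattr(self.shape, k)
            for k in (
                "phase1_deg",
                "phase2_deg",
                "gauss_fwhm_hz",
                "lorentz_fwhm_hz",
                "peak_ratio",
                "splitting_hz",
            )
        }
        return d


@dataclass
class SpectrumSeries:
    """Ordered single-shot complex signals sharing one axis.

    ``data`` is ``(n_spectra, n_points)``; ``domain`` is ``time`` (FIDs) or
    ``frequency`` (spectra stored in descending-ppm order, matching how
    in vivo spectra are printed).  Tags align one-to-one with rows.
    """

    data: np.ndarray
    dwell_s: float
    tags: List[AcquisitionTag]
    domain: str = "time"
    larmor_mhz: float = LARMOR_MHZ_7T
    carrier_ppm: float = WATER_PPM
    provenance: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_spectra, n_points)")
        if len(self.tags) != self.data.shape[0]:
            raise ValueError("tags must align 1:1 with spectra")
        if self.domain not in ("time", "frequency"):
            raise ValueError("domain must be 'time' or 'frequency'")

    @property
    def n_spectra(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_points(self) -> int:
        return int(self.data.shape[1])

    @property
    def sw_hz(self) -> float:
        return 1.0 / self.dwell_s

    @property
    def hz_axis(self) -> np.ndarray:
        """Frequency axis (Hz offset from carrier), same order as the data."""
        f = np.fft.fftshift(np.fft.fftfreq(self.n_points, d=self.dwell_s))
        return f[::-1] if self.domain == "frequency" else f

    @property
    def ppm_axis(self) -> np.ndarray:
        """ppm axis; descending for frequency-domain data."""
        return self.carrier_ppm + self.hz_axis / self.larmor_mhz

    def window_mask(self, center_ppm: float, half_width_ppm: float) -> np.ndarray:
        ax = self.ppm_axis
        return (ax >= center_ppm - half_width_ppm) & (ax <= center_ppm + half_width_ppm)

    def to_frequency(self) -> "SpectrumSeries":
        """FFT each FID; spectra are stored in descending-ppm order."""
        if self.domain == "frequency":
            return self
        spec = np.fft.fftshift(np.fft.fft(self.data, axis=1), axes=1)[:, ::-1]
        return SpectrumSeries(
            spec, self.dwell_s, list(self.tags), "frequency",
            self.larmor_mhz, self.carrier_ppm, dict(self.provenance),
        )

    def to_time(self) -> "SpectrumSeries":
        if self.domain == "time":
            return self
        fids = np.fft.ifft(np.fft.ifftshift(self.data[:, ::-1], axes=1), axis=1)
        return SpectrumSeries(
            fids, self.dwell_s, list(self.tags), "time",
            self.larmor_mhz, self.carrier_ppm, dict(self.provenance),
        )

    def copy_with(self, data: np.ndarray, domain: Optional[str] = None) -> "SpectrumSeries":
        return SpectrumSeries(
            data, self.dwell_s, list(self.tags), domain or self.domain,
            self.larmor_mhz, self.carrier_ppm, dict(self.provenance),
        )


# ---------------------------------------------------------------------------
# Amplitude programs
# ---------------------------------------------------------------------------


def t_comb_from_ground_truth(gt: GroundTruth, cfg: TimingSchedule) -> float:
    """Combined decay constant (ms) implied by T2, t_clear and the schedule.

    Inverts ``1/T2 = 1/t_comb - c / t_clear`` with ``c = 2 TR / tau_inc``.
    """
    if cfg.tau1_increment == 0:
        return gt.t2_ms  # no clearance mapping onto the tau1 axis
    c = 2.0 * cfg.tr / cfg.tau1_increment
    rate = 1.0 / gt.t2_ms + c / gt.t_clear_s
    return 1.0 / rate


def _jmod(j_hz: float, tau1_ms: float) -> float:
    """sin(pi J tau1): J in Hz, tau1 in ms, one explicit unit conversion."""
    return math.sin(math.pi * j_hz * tau1_ms / 1000.0)


def combined_amplitude(tag: AcquisitionTag, gt: GroundTruth, cfg: TimingSchedule) -> float:
    """Noise-free lactate amplitude of one shot.

    Fixed-tag shots decay mono-exponentially in wall time; pre-cap
    incremented shots follow the combined J-modulated decay in tau1.
    Post-cap incremented shots keep the J/T2 factor frozen at the capped
    tau1 while physiological clearance continues in wall time.
    """
    if gt.a0 < 0 or gt.t_clear_s <= 0:
        raise ValueError("non-positive kinetic constants")
    if tag.tag == "fixed":
        return gt.a0 * math.exp(-tag.wall_time / gt.t_clear_s) + gt.b
    t_comb = t_comb_from_ground_truth(gt, cfg)
    if not tag.post_cap:
        return (
            gt.a0
            * _jmod(gt.j_hz, tag.tau1)
            * math.exp(-(tag.tau1 - cfg.tau1_start) / t_comb)
            + gt.b
        )
    # frozen tau1: clearance keeps running in wall time beyond the cap
    c = 2.0 * cfg.tr / cfg.tau1_increment if cfg.tau1_increment else 0.0
    cap_wall_equiv = (tag.tau1 - cfg.tau1_start) * c  # s already spent "on the ladder"
    frozen = gt.a0 * _jmod(gt.j_hz, tag.tau1) * math.exp(
        -(tag.tau1 - cfg.tau1_start) / t_comb
    )
    extra_s = tag.wall_time - cap_wall_equiv - cfg.tr  # first incremented shot sits at TR
    extra_s = max(extra_s, 0.0)
    return frozen * math.exp(-extra_s / gt.t_clear_s) + gt.b


def _physics_envelope(gt: GroundTruth, cfg: TimingSchedule) -> Dict[float, float]:
    """Signed DQF amplitude factor vs tau1 from the density-matrix backend.

    Normalized so the factor at tau1_start equals sin(pi J tau1_start),
    making the physics and parametric backends agree exactly for an ideal
    IS system.
    """
    from . import spinsim

    system = spinsim.SpinSystem(topology="IS", j_hz=gt.j_hz)
    taus = sorted({t.tau1 for t in build_schedule(cfg) if t.tag == "incremented"})
    ref: Optional[complex] = None
    raw: Dict[float, complex] = {}
    for tau1 in taus:
        spec, freqs = spinsim.simulate_dqf(system, tau1_ms=tau1, tau_m_ms=cfg.tau_m,
                                           tau2_ms=cfg.tau2)
        z = spinsim.ch3_amplitude(spec, freqs, system)
        raw[tau1] = z
        if ref is None or abs(z) > abs(ref):
            ref = z
    assert ref is not None
    signed = {t: (z * np.conj(ref)).real / abs(ref) for t, z in raw.items()}
    t0 = cfg.tau1_start
    norm = _jmod(gt.j_hz, t0) / signed[t0] if signed[t0] != 0 else 1.0
    return {t: s * norm for t, s in signed.items()}


# ---------------------------------------------------------------------------
# Spectrum rendering
# ---------------------------------------------------------------------------


def _voigt_fid(
    t: np.ndarray,
    area: float,
    freq_hz: float,
    phase_deg: float,
    gauss_fwhm_hz: float,
    lorentz_fwhm_hz: float,
) -> np.ndarray:
    """Time-domain Voigt component: complex exponential with mixed decay."""
    lb = math.pi * lorentz_fwhm_hz
    gb = (math.pi * gauss_fwhm_hz) ** 2 / (4.0 * LN2)
    return (
        area
        * np.exp(1j * math.radians(phase_deg))
        * np.exp(2j * math.pi * freq_hz * t - lb * t - gb * t * t)
    )


def render_fid(
    amplitude: float,
    freq_offset_hz: float,
    shape: VoigtDoubletShape,
    gt: GroundTruth,
    n_points: int = 1024,
    dwell_s: float = 2.5e-4,
    larmor_mhz: float = LARMOR_MHZ_7T,
    carrier_ppm: float = WATER_PPM,
    broaden: float = 1.0,
) -> np.ndarray:
    """Noise-free FID of one shot: lactate doublet + lipid + creatine.

    ``amplitude`` is the summed doublet area; ``freq_offset_hz`` a global
    frequency shift (drift); ``broaden`` multiplies all linewidths (motion
    outliers).
    """
    t = np.arange(n_points) * dwell_s
    extra_lb = (broaden - 1.0) * (shape.lorentz_fwhm_hz + shape.gauss_fwhm_hz)

    def peak(area, ppm, phase_deg, g_fwhm, l_fwhm):
        f = ppm_to_hz(ppm - carrier_ppm, larmor_mhz) + freq_offset_hz
        return _voigt_fid(t, area, f, phase_deg, g_fwhm, l_fwhm + extra_lb)

    half_split_ppm = 0.5 * shape.splitting_hz / larmor_mhz
    a1 = amplitude * shape.peak_ratio / (1.0 + shape.peak_ratio)
    a2 = amplitude / (1.0 + shape.peak_ratio)
    fid = peak(a1, LACTATE_PPM + half_split_ppm, shape.phase1_deg,
               shape.gauss_fwhm_hz, shape.lorentz_fwhm_hz)
    fid += peak(a2, LACTATE_PPM - half_split_ppm, shape.phase2_deg,
                shape.gauss_fwhm_hz, shape.lorentz_fwhm_hz)
    if gt.lipid_amp:
        # Lorentzian residue: tiny Gaussian part only to reuse the kernel
        fid += peak(gt.lipid_amp * gt.a0, LIPID_PPM, gt.lipid_phase_deg,
                    1e-3, gt.lipid_fwhm_hz)
    fid += peak(1.5 * gt.a0, CREATINE_CH3_PPM, 0.0, 6.0, 5.0)
    fid += peak(1.0 * gt.a0, CREATINE_CH2_PPM, 0.0, 6.0, 5.0)
    return fid


def _noise_sigma_for_snr(
    gt: GroundTruth,
    cfg: TimingSchedule,
    n_points: int,
    dwell_s: float,
    larmor_mhz: float,
    carrier_ppm: float,
) -> float:
    """Time-domain noise SD hitting the target single-shot SNR.

    SNR follows the acquisition definition: lactate peak height in the real
    spectrum after 10 Hz apodization and 2x zero-filling, divided by the
    noise SD in the signal-free 7-9 ppm region under the same processing,
    averaged over the first ten shots (which already decay and J-modulate).
    """
    t = np.arange(n_points) * dwell_s
    w = np.exp(-math.pi * 10.0 * t)
    f = np.fft.fftshift(np.fft.fftfreq(2 * n_points, d=dwell_s))
    ppm = carrier_ppm + f / larmor_mhz
    win = (ppm >= LACTATE_PPM - 0.1) & (ppm <= LACTATE_PPM + 0.1)
    heights = []
    for tag in build_schedule(cfg)[:10]:
        amp = combined_amplitude(tag, gt, cfg)
        fid = render_fid(amp, 0.0, gt.shape, gt, n_points, dwell_s, larmor_mhz, carrier_ppm)
        wfid = fid * w
        wfid[0] *= 0.5  # first-point correction, matching the fitting stage
        spec = np.fft.fftshift(np.fft.fft(wfid, n=2 * n_points))
        heights.append(float(np.max(np.abs(spec.real[win]))))
    peak_height = float(np.mean(heights))
    # Var(Re S_k) = sigma_t^2 * sum(w^2) / 2 for complex white noise
    spec_noise_per_sigma = math.sqrt(float(np.sum(w * w)) / 2.0)
    return peak_height / (gt.snr * spec_noise_per_sigma)


def generate_series(
    gt: GroundTruth,
    cfg: Optional[TimingSchedule] = None,
    n_points: int = 1024,
    dwell_s: float = 2.5e-4,
    larmor_mhz: float = LARMOR_MHZ_7T,
    carrier_ppm: float = WATER_PPM,
    backend: str = "parametric",
) -> SpectrumSeries:
    """Generate the interleaved synthetic series (time-domain FIDs).

    Reproducible under ``gt.seed``.  The ``physics`` backend replaces the
    parametric sin(pi J tau1) modulation of incremented shots with the
    amplitude factor simulated by the density-matrix DQF model.
    """
    if backend not in ("parametric", "physics"):
        raise ValueError("backend must be 'parametric' or 'physics'")
    cfg = cfg or TimingSchedule()
    rng = np.random.default_rng(gt.seed)
    plan = build_schedule(cfg)
    sigma = _noise_sigma_for_snr(gt, cfg, n_points, dwell_s, larmor_mhz, carrier_ppm)
    envelope = _physics_envelope(gt, cfg) if backend == "physics" else None
    t_comb = t_comb_from_ground_truth(gt, cfg)

    fids = np.empty((len(plan), n_points), dtype=complex)
    outliers: List[int] = []
    for i, tag in enumerate(plan):
        if envelope is not None and tag.tag == "incremented" and not tag.post_cap:
            amp = (
                gt.a0
                * envelope[tag.tau1]
                * math.exp(-(tag.tau1 - cfg.tau1_start) / t_comb)
                + gt.b
            )
        else:
            amp = combined_amplitude(tag, gt, cfg)
        drift = gt.drift_hz_per_min * tag.wall_time / 60.0
        is_outlier = bool(rng.random() < gt.outlier_rate)
        if is_outlier:
            outliers.append(i)
        fid = render_fid(
            amp * (0.5 if is_outlier else 1.0),
            drift,
            gt.shape,
            gt,
            n_points,
            dwell_s,
            larmor_mhz,
            carrier_ppm,
            broaden=3.0 if is_outlier else 1.0,
        )
        # sigma is the SD of the complex sample; each quadrature gets sigma/sqrt(2)
        noise = rng.standard_normal(n_points) + 1j * rng.standard_normal(n_points)
        fids[i] = fid + sigma * noise / math.sqrt(2.0)
    return SpectrumSeries(
        fids,
        dwell_s,
        plan,
        "time",
        larmor_mhz,
        carrier_ppm,
        provenance={
            "ground_truth": gt.to_dict(),
            "schedule": {
                "tau1_start": cfg.tau1_start,
                "tau1_increment": cfg.tau1_increment,
                "tau1_max": cfg.tau1_max,
                "tau_m": cfg.tau_m,
                "tau2": cfg.tau2,
                "tr": cfg.tr,
                "n_measurements": cfg.n_measurements,
                "interleave_mode": cfg.interleave_mode,
            },
            "backend": backend,
            "outlier_indices": outliers,
            "noise_sigma": sigma,
        },
    )
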