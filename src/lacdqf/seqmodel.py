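"""Sequence timing model for the CH-selective DQF semi-LASER experiment.

The double-quantum-filtered (DQF) sequence has three echo delays: a
preparation spin echo ``tau1`` during which scalar coupling evolves into
antiphase, an unrefocused multiple-quantum encoding delay ``tau_m``, and a
read spin echo ``tau2``.  Post-exercise acquisitions interleave two timing
programs shot by shot: a *fixed* program (constant delays, reporting pure
lactate clearance) and an *incremented* program in which ``tau1`` grows by a
constant step each repetition, adding T2 weighting and J modulation.

This module holds the acquisition plan and the closed-form geometry and
frequency rules of the sequence: chemical-shift displacement, the
CH-selective carrier placement rule, and total echo time.  All ppm <-> Hz
conversions go through :func:`ppm_to_hz` / :func:`hz_to_ppm`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, NamedTuple

__all__ = [
    "LARMOR_MHZ_7T",
    "WATER_PPM",
    "CH_PPM",
    "CH3_PPM",
    "ppm_to_hz",
    "hz_to_ppm",
    "TimingSchedule",
    "AcquisitionTag",
    "build_schedule",
    "csd_fraction",
    "CarrierOffset",
    "selective_carrier_offset",
    "EchoTime",
    "total_echo_time",
]

#: Proton Larmor frequency at 7 T (MHz).  Used as the single default for all
#: ppm <-> Hz conversions in the package.
LARMOR_MHZ_7T = 297.22

#: Transmitter reference: water resonance position on the ppm axis.
WATER_PPM = 4.7

#: Lactate methine (CH) and methyl (CH3) chemical shifts (ppm).
CH_PPM = 4.10
CH3_PPM = 1.31


def ppm_to_hz(delta_ppm: float, larmor_mhz: float = LARMOR_MHZ_7T) -> float:
    """Convert a chemical-shift difference in ppm to Hz at the given field."""
    return delta_ppm * larmor_mhz


def hz_to_ppm(delta_hz: float, larmor_mhz: float = LARMOR_MHZ_7T) -> float:
    """Convert a frequency difference in Hz to ppm at the given field."""
    return delta_hz / larmor_mhz


_INTERLEAVE_MODES = ("fixed_only", "incremented_only", "interleaved")


@dataclass(frozen=True)
class TimingSchedule:
    """Timing program of one interleaved DQF acquisition.

    Parameters
    ----------
    tau1_start : float
        Starting preparation echo delay tau1 (ms).
    tau1_increment : float
        tau1 step between consecutive incremented shots (ms); 0 degenerates
        to a constant-tau1 sub-series.
    tau1_max : float
        Cap on tau1 (ms); once the next increment would exceed it, the
        incremented sub-series keeps the last valid tau1.
    tau_m : float
        Multiple-quantum encoding delay (ms, unrefocused).
    tau2 : float
        Read spin-echo delay (ms).
    tr : float
        Repetition time (s); same-tag shots are 2*tr apart in interleaved
        mode.
    n_measurements : int
        Total number of single-shot acquisitions.
    interleave_mode : str
        One of ``fixed_only``, ``incremented_only``, ``interleaved``.
    """

    tau1_start: float = 22.8
    tau1_increment: float = 10.0
    tau1_max: float = 500.0
    tau_m: float = 10.6
    tau2: float = 35.0
    tr: float = 4.0
    n_measurements: int = 300
    interleave_mode: str = "interleaved"

    def __post_init__(self) -> None:
        for name in ("tau1_start", "tau1_max", "tau_m", "tau2", "tr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.tau1_increment < 0:
            raise ValueError("tau1_increment must be >= 0")
        if self.tau1_start > self.tau1_max:
            raise ValueError("tau1_start must not exceed tau1_max")
        if self.n_measurements <= 0:
            raise ValueError("n_measurements must be positive")
        if self.interleave_mode not in _INTERLEAVE_MODES:
            raise ValueError(
                f"interleave_mode must be one of {_INTERLEAVE_MODES}, "
                f"got {self.interleave_mode!r}"
            )

    @property
    def n_distinct_tau1(self) -> int:
        """Number of distinct tau1 values in the incremented sub-series."""
        if self.tau1_increment == 0:
            return 1
        span = (self.tau1_max - self.tau1_start) / self.tau1_increment
        return int(math.floor(span + 1e-9)) + 1


@dataclass(frozen=True)
class AcquisitionTag:
    """One single-shot acquisition in the interleaved plan.

    ``wall_time`` is index * TR (s).  ``post_cap`` marks incremented shots
    whose tau1 has saturated at the cap; they still clear physiologically but
    carry no new T2/J information and are excluded from the Eq.-style
    combined fit.
    """

    index: int
    tag: str  # "fixed" | "incremented"
    tau1: float  # ms
    wall_time: float  # s
    post_cap: bool = False


def build_schedule(cfg: TimingSchedule) -> List[AcquisitionTag]:
    """Expand a :class:`TimingSchedule` into the deterministic shot plan.

    In interleaved mode even indices are fixed-timing shots and odd indices
    incremented shots, so consecutive shots alternate tags and same-tag
    shots are 2*TR apart.  The incremented tau1 ladder is
    ``tau1_start + k * tau1_increment`` and saturates at the last value not
    exceeding ``tau1_max``.
    """
    plan: List[AcquisitionTag] = []
    k_cap = cfg.n_distinct_tau1 - 1
    n_inc = 0
    for i in range(cfg.n_measurements):
        if cfg.interleave_mode == "fixed_only":
            tag = "fixed"
        elif cfg.interleave_mode == "incremented_only":
            tag = "incremented"
        else:
            tag = "fixed" if i % 2 == 0 else "incremented"
        if tag == "fixed":
            tau1 = cfg.tau1_start
            post_cap = False
        else:
            k = min(n_inc, k_cap)
            tau1 = cfg.tau1_start + k * cfg.tau1_increment
            post_cap = n_inc > k_cap
            n_inc += 1
        plan.append(
            AcquisitionTag(
                index=i,
                tag=tag,
                tau1=tau1,
                wall_time=i * cfg.tr,
                post_cap=post_cap,
            )
        )
    return plan


def csd_fraction(
    delta_ppm: float,
    refocus_bw_khz: float,
    larmor_mhz: float = LARMOR_MHZ_7T,
) -> float:
    """Fractional voxel-length loss from chemical-shift displacement.

    The voxel selected for a resonance ``delta_ppm`` away from the pulse
    carrier is displaced by ``delta_f / BW`` voxel lengths along the
    direction of one refocusing pulse pair; for a double-quantum filter both
    coupled resonances must be refocused at a given position, so this
    fraction is lost from the effective voxel.
    """
    if delta_ppm < 0:
        raise ValueError("delta_ppm must be >= 0")
    if refocus_bw_khz <= 0:
        raise ValueError("refocus_bw_khz must be > 0")
    if larmor_mhz <= 0:
        raise ValueError("larmor_mhz must be > 0")
    return ppm_to_hz(delta_ppm, larmor_mhz) / (refocus_bw_khz * 1e3)


class CarrierOffset(NamedTuple):
    """Carrier-frequency shift of the CH-selective pulse, in Hz and ppm."""

    hz: float
    ppm: float


def selective_carrier_offset(
    pulse_duration_ms: float,
    larmor_mhz: float = LARMOR_MHZ_7T,
) -> CarrierOffset:
    """Carrier placement rule for the CH-selective DQF pulse.

    The pulse carrier is shifted away from the CH resonance by half of
    ``(1 / duration) * 0.97 * 4`` so that the CH line sits on the edge of
    the pass-band while the CH3 / lipid region falls deep in the stop-band.
    """
    if pulse_duration_ms <= 0:
        raise ValueError("pulse_duration_ms must be > 0")
    full_width_hz = (1.0 / (pulse_duration_ms * 1e-3)) * 0.97 * 4.0
    offset_hz = 0.5 * full_width_hz
    return CarrierOffset(hz=offset_hz, ppm=hz_to_ppm(offset_hz, larmor_mhz))


class EchoTime(NamedTuple):
    """Total echo time with the unrefocused tau_m part reported separately."""

    total_ms: float
    unrefocused_ms: float


def total_echo_time(cfg: TimingSchedule) -> EchoTime:
    """Total echo time tau1 + tau_m + tau2 at the starting timings.

    tau_m is the multiple-quantum encoding delay, which is not spin-echo
    refocused; it is included in the total but flagged separately.
    """
    return EchoTime(
        total_ms=cfg.tau1_start + cfg.tau_m + cfg.tau2,
        unrefocused_ms=cfg.tau_m,
    )
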