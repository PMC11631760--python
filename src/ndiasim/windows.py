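"""Isolation-window schemes and acquisition duty-cycle arithmetic.

Narrow-window DIA tiles a precursor m/z range with small (down to 2 Th)
isolation windows and fragments each window once per cycle.  The achievable
MS/MS rate is set by the maximum ion injection time (maxIT) plus a fixed
per-scan overhead τ that lumps together isolation, fragmentation, transfer
and detection costs of the pipelined ion path::

    rate [Hz]      = 1000 / (maxIT + τ)          (both in ms)
    cycle time [s] = n_windows × (maxIT + τ) / 1000

MS1 acquisition runs in parallel on a second analyzer and adds no serial
time by default.  τ is not printed on instrument methods, so it is
calibrated from published rates: 170 Hz at 3.5-ms fills for DIA and a
~150-Hz top speed at 2.5-ms fills for DDA.

Trading window width against fill time at constant per-cycle accumulation
(``n_windows × maxIT`` constant) reproduces the standard maxIT ladder:
2 Th / 3.5 ms, 4 Th / 7 ms, 8 Th / 14 ms, 16 Th / 28 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional


class InvalidRangeError(ValueError):
    """Raised for degenerate m/z ranges (high <= low)."""


class InvalidSchemeError(ValueError):
    """Raised for impossible window geometries (e.g. width <= overlap)."""


class InfeasibleTimingError(ValueError):
    """Raised when a requested rate cannot be met by any overhead >= 0."""


#: Per-MS/MS fixed overhead for DIA, calibrated from 170 Hz at 3.5-ms maxIT.
DIA_SCAN_OVERHEAD_MS = 1000.0 / 170.0 - 3.5

#: Per-MS/MS fixed overhead for DDA, calibrated from the ~150-Hz top speed
#: at the 2.5-ms fragment-scan fill time used by fixed-cycle DDA methods.
DDA_SCAN_OVERHEAD_MS = 1000.0 / 150.0 - 2.5


@dataclass(frozen=True)
class MzRange:
    """Closed precursor m/z range in Thomson."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.high > self.low:
            raise InvalidRangeError(
                f"degenerate m/z range [{self.low}, {self.high}]"
            )

    @property
    def span(self) -> float:
        return self.high - self.low

    def contains(self, mz: float) -> bool:
        return self.low <= mz <= self.high


@dataclass(frozen=True)
class IsolationWindow:
    """A single quadrupole isolation window, half-open ``[low, high)``.

    Half-open bounds make precursor-to-window assignment unambiguous at
    shared edges of adjacent windows.
    """

    low: float
    high: float
    index: int

    def __post_init__(self) -> None:
        if not self.high > self.low:
            raise InvalidSchemeError(f"window {self.index} has width <= 0")

    @property
    def width(self) -> float:
        return self.high - self.low

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    def contains(self, mz: float) -> bool:
        return self.low <= mz < self.high


@dataclass(frozen=True)
class WindowScheme:
    """An ordered tiling of a precursor range by isolation windows.

    Consecutive windows advance by ``width - overlap``; the first window
    starts at ``range.low`` and the union of windows covers the range.  When
    the step does not divide the span, the final window extends past
    ``range.high`` and ``clipped`` is set (full coverage is preserved).
    """

    windows: tuple[IsolationWindow, ...]
    mz_range: MzRange
    width: float
    overlap: float
    clipped: bool

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def windows_containing(self, mz: float) -> list[int]:
        """Indices of every window containing ``mz`` (overlap-aware)."""
        return [w.index for w in self.windows if w.contains(mz)]


def make_fixed_windows(
    mz_range: MzRange, width: float, overlap: float = 0.0
) -> WindowScheme:
    """Tile ``mz_range`` with fixed-width windows.

    Parameters
    ----------
    mz_range : MzRange
        Precursor range to cover, e.g. 380–980 Th.
    width : float
        Isolation width in Th; must exceed ``overlap``.
    overlap : float
        Overlap between consecutive windows in Th, >= 0.

    Returns
    -------
    WindowScheme
        ``ceil((span - overlap) / (width - overlap))`` windows; e.g. 300
        windows for 2 Th over 380–980, or 56 windows for 13 Th with 1-Th
        overlap over 361–1033.
    """
    if overlap < 0 or width <= overlap:
        raise InvalidSchemeError(
            f"need width > overlap >= 0, got width={width}, overlap={overlap}"
        )
    step = width - overlap
    # absorb float representation noise at exact-divisibility boundaries
    n = max(1, math.ceil((mz_range.span - overlap) / step - 1e-12))
    windows = tuple(
        IsolationWindow(
            low=mz_range.low + i * step,
            high=mz_range.low + i * step + width,
            index=i,
        )
        for i in range(n)
    )
    clipped = windows[-1].high > mz_range.high + 1e-12
    return WindowScheme(
        windows=windows,
        mz_range=mz_range,
        width=width,
        overlap=overlap,
        clipped=clipped,
    )


@dataclass(frozen=True)
class TimingModel:
    """Per-scan timing of the serial MS/MS schedule.

    Parameters
    ----------
    max_injection_time_ms : float
        Maximum ion accumulation time per MS/MS fill (maxIT), ms.
    scan_overhead_ms : float
        Fixed per-scan cost τ, ms.  Defaults to the DIA calibration.
    ms1_resolution : int
        Full-MS resolution setting of the parallel MS1 analyzer (bookkeeping
        only; MS1 adds no serial time unless requested in `cycle_time`).
    max_parallel_packets : int
        Maximum number of ion packets allowed in flight through the
        pipelined accumulation/processing/detection stages (five on the
        modelled instrument).
    packet_residence_ms : float, optional
        Total residence time of one packet in the pipeline.  When set, the
        scan scheduler throttles the spacing to
        ``max(maxIT + τ, residence / max_parallel_packets)`` so the
        concurrency cap is never violated.  ``None`` (default) means the
        pipeline is never the bottleneck.
    """

    max_injection_time_ms: float
    scan_overhead_ms: float = DIA_SCAN_OVERHEAD_MS
    ms1_resolution: int = 180_000
    max_parallel_packets: int = 5
    packet_residence_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.max_injection_time_ms <= 0:
            raise InfeasibleTimingError("maxIT must be > 0")
        if self.scan_overhead_ms < 0:
            raise InfeasibleTimingError("scan overhead must be >= 0")
        if self.max_parallel_packets < 1:
            raise InfeasibleTimingError("max_parallel_packets must be >= 1")

    @property
    def scan_period_ms(self) -> float:
        return self.max_injection_time_ms + self.scan_overhead_ms


def scan_spacing_ms(timing: TimingModel) -> float:
    """Actual spacing between consecutive MS/MS scans, ms.

    Equals ``maxIT + τ`` unless the packet pipeline throttles the schedule.
    """
    spacing = timing.scan_period_ms
    if timing.packet_residence_ms is not None:
        spacing = max(
            spacing, timing.packet_residence_ms / timing.max_parallel_packets
        )
    return spacing


def packets_in_flight(timing: TimingModel) -> int:
    """Maximum number of ion packets simultaneously in the pipeline."""
    if timing.packet_residence_ms is None:
        return 1
    return math.ceil(timing.packet_residence_ms / scan_spacing_ms(timing))


def scan_rate(timing: TimingModel) -> float:
    """MS/MS acquisition rate in Hz: ``1000 / (maxIT + τ)``."""
    return 1000.0 / scan_spacing_ms(timing)


def calibrate_overhead(observed_rate_hz: float, maxit_ms: float) -> float:
    """Solve the per-scan overhead τ from an observed MS/MS rate.

    ``τ = 1000 / rate - maxIT``; round-trips with `scan_rate`.  Raises
    `InfeasibleTimingError` when the implied overhead would be negative
    (rate faster than pure accumulation allows).
    """
    if observed_rate_hz <= 0:
        raise InfeasibleTimingError("observed rate must be > 0")
    tau = 1000.0 / observed_rate_hz - maxit_ms
    if tau < 0:
        raise InfeasibleTimingError(
            f"{observed_rate_hz} Hz is infeasible at maxIT {maxit_ms} ms"
        )
    return tau


def cycle_time(
    scheme: WindowScheme,
    timing: TimingModel,
    serial_ms1: bool = False,
    ms1_time_ms: float = 0.0,
) -> float:
    """Duty-cycle time in seconds for one pass over all windows.

    MS1 is acquired in parallel on the second analyzer and adds no time by
    default; set ``serial_ms1`` for non-parallel instruments.
    """
    total_ms = scheme.n_windows * scan_spacing_ms(timing)
    if serial_ms1:
        total_ms += ms1_time_ms
    return total_ms / 1000.0


def scale_maxit(width: float, ref_width: float, ref_maxit_ms: float) -> float:
    """Scale maxIT proportionally to window width.

    Keeps the total per-cycle accumulation ``n_windows × maxIT`` constant,
    e.g. 2 Th / 3.5 ms anchors 16 Th at 28 ms.
    """
    if width <= 0 or ref_width <= 0 or ref_maxit_ms <= 0:
        raise InfeasibleTimingError("widths and maxIT must be > 0")
    return ref_maxit_ms * width / ref_width


def sampling_fraction(scheme: WindowScheme, timing: TimingModel) -> float:
    """Temporal ion-beam utilization per precursor: maxIT / cycle time.

    A precursor is accumulated for maxIT once per cycle, so at fixed timing
    the sampled fraction is proportional to 1/n_windows.
    """
    return (timing.max_injection_time_ms / 1000.0) / cycle_time(scheme, timing)


def ion_beam_utilization(
    scheme: WindowScheme, timing: TimingModel
) -> dict[str, float]:
    """Both common definitions of instantaneous beam utilization.

    ``temporal``: maxIT / cycle time (time-share of one precursor's beam);
    ``mz``: window width / covered span (m/z-share isolated at any instant).
    The two differ whenever τ > 0, so both are reported rather than a single
    headline number.
    """
    return {
        "temporal": sampling_fraction(scheme, timing),
        "mz": scheme.width / scheme.mz_range.span,
    }


def points_per_peak(
    peak_fwhm_s: float, scheme: WindowScheme, timing: TimingModel
) -> float:
    """Chromatographic sampling: MS/MS points across one peak FWHM.

    Values below ~3 flag under-sampled peaks (cycle longer than the peak
    gives < 1).
    """
    return peak_fwhm_s / cycle_time(scheme, timing)


@dataclass(frozen=True)
class AcquisitionMethod:
    """A complete DIA or DDA acquisition method.

    DIA methods carry a `WindowScheme`; DDA methods carry a fixed isolation
    width plus cycle-time / top-N / dynamic-exclusion settings mirroring a
    fixed-cycle top-speed method (0.5-s cycle, 10-s exclusion, 2-Th
    isolation by default).  ``faims_transmission`` models an optional FAIMS
    front end purely as a transmission-efficiency factor.
    """

    mode: str
    timing: TimingModel
    mz_range: MzRange
    scheme: Optional[WindowScheme] = None
    agc_capacity: float = 50_000.0
    dda_isolation_width: float = 2.0
    dda_cycle_time_s: float = 0.5
    dda_top_n: int = 75
    dynamic_exclusion_s: float = 10.0
    dda_min_intensity: float = 1.0
    faims_transmission: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("DIA", "DDA"):
            raise ValueError(f"mode must be DIA or DDA, got {self.mode!r}")
        if not 0.0 <= self.faims_transmission <= 1.0:
            raise ValueError("faims_transmission must be in [0, 1]")
        if self.agc_capacity <= 0:
            raise ValueError("agc_capacity must be > 0")
        if self.mode == "DIA":
            if self.scheme is None:
                raise InvalidSchemeError("DIA method requires a WindowScheme")
        else:
            if self.dda_cycle_time_s <= 0:
                raise ValueError("DDA requires dda_cycle_time_s > 0")
            if self.dynamic_exclusion_s < 0:
                raise ValueError("DDA requires dynamic_exclusion_s >= 0")
            if self.dda_isolation_width <= 0:
                raise InvalidSchemeError("DDA isolation width must be > 0")

    @classmethod
    def dia(
        cls,
        scheme: WindowScheme,
        timing: TimingModel,
        agc_capacity: float = 50_000.0,
        faims_transmission: float = 1.0,
    ) -> "AcquisitionMethod":
        return cls(
            mode="DIA",
            timing=timing,
            mz_range=scheme.mz_range,
            scheme=scheme,
            agc_capacity=agc_capacity,
            faims_transmission=faims_transmission,
        )

    @classmethod
    def dda(
        cls,
        mz_range: MzRange,
        timing: Optional[TimingModel] = None,
        isolation_width: float = 2.0,
        cycle_time_s: float = 0.5,
        top_n: int = 75,
        dynamic_exclusion_s: float = 10.0,
        min_intensity: float = 1.0,
        agc_capacity: float = 50_000.0,
        faims_transmission: float = 1.0,
    ) -> "AcquisitionMethod":
        if timing is None:
            timing = TimingModel(
                max_injection_time_ms=2.5,
                scan_overhead_ms=DDA_SCAN_OVERHEAD_MS,
            )
        return cls(
            mode="DDA",
            timing=timing,
            mz_range=mz_range,
            scheme=None,
            agc_capacity=agc_capacity,
            dda_isolation_width=isolation_width,
            dda_cycle_time_s=cycle_time_s,
            dda_top_n=top_n,
            dynamic_exclusion_s=dynamic_exclusion_s,
            dda_min_intensity=min_intensity,
            faims_transmission=faims_transmission,
        )
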