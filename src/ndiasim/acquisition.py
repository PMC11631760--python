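"""Stochastic DIA/DDA acquisition over a peptide sample.

The simulator walks the serial MS/MS schedule through the chromatographic
gradient.  Each MS/MS fill accumulates ions from every peptide whose
precursor m/z falls inside the active isolation window and whose Gaussian
elution profile overlaps the scan time; sampled ion counts are Poisson with
mean ``flux(t) × maxIT × faims_transmission``, truncated by the AGC charge
cap (which shortens the effective injection time proportionally rather than
clipping counts, keeping quantification linear below saturation).

Random streams are split per scan from the master seed, so reordering
windows or truncating the gradient never cascades into unrelated scans and
runs are byte-reproducible.

DDA mode re-ranks currently eluting precursors by instantaneous intensity
once per fixed-length cycle, sequences the top N not on the dynamic
exclusion list, and therefore inherits the classic abundance bias that DIA
avoids.  Identification is proxied downstream by `detectability`
thresholds (points across the peak, total ions) rather than spectral
matching.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace as _dc_replace
from functools import lru_cache
from typing import Sequence

import numpy as np

from .sample import PeptideIon, fragment_mzs
from .windows import (
    AcquisitionMethod,
    cycle_time,
    packets_in_flight,
    scan_spacing_ms,
)

#: Elution support half-width in units of the Gaussian sigma.
ELUTION_SPAN_SIGMAS = 4.0
_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

_EMPTY_I = np.empty(0, dtype=np.int64)
_EMPTY_F = np.empty(0, dtype=np.float64)
_EMPTY_I.setflags(write=False)
_EMPTY_F.setflags(write=False)


@dataclass
class ScanEvent:
    """One acquisition event.

    MS2 events record the isolation window, the effective injection time
    (shortened below maxIT when the AGC cap was hit), and the sampled
    precursors as parallel arrays of peptide index, ion count and observed
    m/z.  ``target_idx`` is the deliberately selected precursor for DDA
    scans (-1 for DIA/MS1).
    """

    time: float
    ms_level: int
    window_low: float
    window_high: float
    injection_time_ms: float
    peptide_idx: np.ndarray
    counts: np.ndarray
    mz_obs: np.ndarray
    target_idx: int = -1

    @property
    def n_precursors(self) -> int:
        return len(self.peptide_idx)


@dataclass
class RunRecord:
    """A full simulated acquisition: ordered scans plus provenance."""

    run_id: str
    method: AcquisitionMethod
    gradient_length_s: float
    seed: int
    peptides: list[PeptideIon]
    scans: list[ScanEvent]
    cycle_time_s: float

    def ms2_scans(self) -> list[ScanEvent]:
        return [s for s in self.scans if s.ms_level == 2]


def _empty_scan(
    time: float, low: float, high: float, inj_ms: float, ms_level: int = 2
) -> ScanEvent:
    return ScanEvent(
        time=time,
        ms_level=ms_level,
        window_low=low,
        window_high=high,
        injection_time_ms=inj_ms,
        peptide_idx=_EMPTY_I,
        counts=_EMPTY_I,
        mz_obs=_EMPTY_F,
    )


def _sample_counts(
    rng_key: list[int],
    lam: np.ndarray,
    maxit_ms: float,
    agc_capacity: float,
) -> tuple[np.ndarray, float]:
    """Poisson-sample ion counts under the AGC charge cap.

    The expected total is compared with the cap first; when it exceeds the
    cap the fill is shortened proportionally (scaling every peptide's mean)
    and any residual Poisson overshoot is thinned without replacement so
    the recorded sum never exceeds the cap.
    """
    expected = float(lam.sum())
    frac = 1.0 if expected <= agc_capacity else agc_capacity / expected
    rng = np.random.default_rng(rng_key)
    counts = rng.poisson(lam * frac)
    cap = int(agc_capacity)
    total = int(counts.sum())
    if total > cap:
        counts = rng.multivariate_hypergeometric(counts, cap)
    return counts.astype(np.int64), maxit_ms * frac


def simulate_dia(
    peptides: Sequence[PeptideIon],
    method: AcquisitionMethod,
    gradient_length_s: float,
    seed: int,
    run_id: str = "run",
) -> RunRecord:
    """Simulate a DIA run: cycle the window scheme across the gradient.

    Every MS1 event is placed at cycle start (acquired in parallel, no
    serial cost); MS2 events follow the serial schedule at the timing
    model's scan spacing.  Deterministic under ``seed``.
    """
    if method.mode != "DIA":
        raise ValueError("simulate_dia requires a DIA method")
    timing = method.timing
    if packets_in_flight(timing) > timing.max_parallel_packets:
        raise RuntimeError("scan scheduler exceeded the packet pipeline cap")
    scheme = method.scheme
    cyc_s = cycle_time(scheme, timing)
    peptides = list(peptides)
    run = RunRecord(
        run_id=run_id,
        method=method,
        gradient_length_s=gradient_length_s,
        seed=seed,
        peptides=peptides,
        scans=[],
        cycle_time_s=cyc_s,
    )
    if not peptides:
        warnings.warn("empty sample: returning a run with no sampled ions")
        return run

    mz = np.array([p.mz for p in peptides])
    rt = np.array([p.rt_apex for p in peptides])
    sig = np.array([p.peak_fwhm for p in peptides]) * _FWHM_TO_SIGMA
    amp = (
        np.array([p.abundance for p in peptides])
        * (timing.max_injection_time_ms / 1000.0)
        * method.faims_transmission
    )

    order = np.argsort(mz, kind="stable")
    mz_sorted = mz[order]
    # per-window candidate peptide arrays (overlapping windows repeat peptides)
    win_members = []
    for w in scheme.windows:
        i0 = int(np.searchsorted(mz_sorted, w.low, side="left"))
        i1 = int(np.searchsorted(mz_sorted, w.high, side="left"))
        idx = order[i0:i1]
        win_members.append((idx, rt[idx], sig[idx], amp[idx]))

    spacing_s = scan_spacing_ms(timing) / 1000.0
    maxit = timing.max_injection_time_ms
    n_cycles = max(1, math.ceil(gradient_length_s / cyc_s))
    for cyc in range(n_cycles):
        t0 = cyc * cyc_s
        run.scans.append(
            _empty_scan(
                t0,
                scheme.mz_range.low,
                scheme.mz_range.high,
                cyc_s * 1000.0,
                ms_level=1,
            )
        )
        for j, w in enumerate(scheme.windows):
            t = t0 + j * spacing_s
            idx, w_rt, w_sig, w_amp = win_members[j]
            if len(idx) == 0:
                run.scans.append(_empty_scan(t, w.low, w.high, maxit))
                continue
            d = t - w_rt
            mask = np.abs(d) <= ELUTION_SPAN_SIGMAS * w_sig
            if not mask.any():
                run.scans.append(_empty_scan(t, w.low, w.high, maxit))
                continue
            lam = w_amp[mask] * np.exp(-0.5 * (d[mask] / w_sig[mask]) ** 2)
            counts, inj = _sample_counts(
                [seed, cyc, j], lam, maxit, method.agc_capacity
            )
            nz = counts > 0
            kept = idx[mask][nz]
            run.scans.append(
                ScanEvent(
                    time=t,
                    ms_level=2,
                    window_low=w.low,
                    window_high=w.high,
                    injection_time_ms=inj,
                    peptide_idx=kept,
                    counts=counts[nz],
                    mz_obs=mz[kept].copy(),
                )
            )
    return run


def simulate_dda(
    peptides: Sequence[PeptideIon],
    method: AcquisitionMethod,
    gradient_length_s: float,
    seed: int,
    run_id: str = "run",
) -> RunRecord:
    """Simulate a fixed-cycle top-N DDA run with dynamic exclusion.

    Each cycle acquires an MS1 survey at cycle start, ranks currently
    eluting precursors by instantaneous expected ion yield, selects up to
    ``dda_top_n`` above ``dda_min_intensity`` and not on the exclusion
    list, isolates each with the DDA width (co-isolating any interfering
    neighbours) and excludes it for ``dynamic_exclusion_s``.
    """
    if method.mode != "DDA":
        raise ValueError("simulate_dda requires a DDA method")
    if method.dda_top_n <= 0:
        raise ValueError("dda_top_n must be > 0")
    timing = method.timing
    cyc_s = method.dda_cycle_time_s
    peptides = list(peptides)
    run = RunRecord(
        run_id=run_id,
        method=method,
        gradient_length_s=gradient_length_s,
        seed=seed,
        peptides=peptides,
        scans=[],
        cycle_time_s=cyc_s,
    )
    if not peptides:
        warnings.warn("empty sample: returning a run with no sampled ions")
        return run

    mz = np.array([p.mz for p in peptides])
    rt = np.array([p.rt_apex for p in peptides])
    sig = np.array([p.peak_fwhm for p in peptides]) * _FWHM_TO_SIGMA
    amp = (
        np.array([p.abundance for p in peptides])
        * (timing.max_injection_time_ms / 1000.0)
        * method.faims_transmission
    )
    in_range = (mz >= method.mz_range.low) & (mz <= method.mz_range.high)

    spacing_s = scan_spacing_ms(timing) / 1000.0
    maxit = timing.max_injection_time_ms
    max_ms2 = int(cyc_s // spacing_s)
    top_n = min(method.dda_top_n, max_ms2)
    half_w = method.dda_isolation_width / 2.0
    release = np.full(len(peptides), -np.inf)
    order_mz = np.argsort(mz, kind="stable")
    mz_sorted = mz[order_mz]

    n_cycles = max(1, math.ceil(gradient_length_s / cyc_s))
    for cyc in range(n_cycles):
        t0 = cyc * cyc_s
        run.scans.append(
            _empty_scan(
                t0,
                method.mz_range.low,
                method.mz_range.high,
                cyc_s * 1000.0,
                ms_level=1,
            )
        )
        d0 = t0 - rt
        eluting = np.abs(d0) <= ELUTION_SPAN_SIGMAS * sig
        lam0 = np.where(eluting, amp * np.exp(-0.5 * (d0 / sig) ** 2), 0.0)
        eligible = (
            in_range
            & eluting
            & (lam0 >= method.dda_min_intensity)
            & (release <= t0)
        )
        cand = np.flatnonzero(eligible)
        if len(cand) == 0:
            continue
        cand = cand[np.argsort(-lam0[cand], kind="stable")][:top_n]
        for m, pick in enumerate(cand):
            t = t0 + (m + 1) * spacing_s
            release[pick] = t0 + method.dynamic_exclusion_s
            lo, hi = mz[pick] - half_w, mz[pick] + half_w
            i0 = int(np.searchsorted(mz_sorted, lo, side="left"))
            i1 = int(np.searchsorted(mz_sorted, hi, side="left"))
            idx = order_mz[i0:i1]
            d = t - rt[idx]
            mask = np.abs(d) <= ELUTION_SPAN_SIGMAS * sig[idx]
            if not mask.any():
                run.scans.append(
                    ScanEvent(
                        time=t, ms_level=2, window_low=lo, window_high=hi,
                        injection_time_ms=maxit, peptide_idx=_EMPTY_I,
                        counts=_EMPTY_I, mz_obs=_EMPTY_F,
                        target_idx=int(pick),
                    )
                )
                continue
            lam = amp[idx][mask] * np.exp(
                -0.5 * (d[mask] / sig[idx][mask]) ** 2
            )
            counts, inj = _sample_counts(
                [seed, cyc, m], lam, maxit, method.agc_capacity
            )
            nz = counts > 0
            kept = idx[mask][nz]
            run.scans.append(
                ScanEvent(
                    time=t,
                    ms_level=2,
                    window_low=lo,
                    window_high=hi,
                    injection_time_ms=inj,
                    peptide_idx=kept,
                    counts=counts[nz],
                    mz_obs=mz[kept].copy(),
                    target_idx=int(pick),
                )
            )
    return run


def sequenced_precursors(run: RunRecord) -> set[int]:
    """Peptide indices deliberately selected for sequencing (DDA targets)."""
    return {s.target_idx for s in run.ms2_scans() if s.target_idx >= 0}


def apply_mass_error(
    run: RunRecord,
    ppm_sigma: float,
    drift_ppm_per_hour: float = 0.0,
    seed: int = 0,
) -> RunRecord:
    """Perturb every recorded m/z by N(drift(t), sigma) in ppm.

    Drift grows linearly with run time, mimicking slow analyzer calibration
    drift (~3 ppm over hours); sigma models per-ion scatter.
    """
    new_scans = []
    for k, scan in enumerate(run.scans):
        if scan.n_precursors == 0:
            new_scans.append(scan)
            continue
        true_mz = np.array([run.peptides[i].mz for i in scan.peptide_idx])
        drift = drift_ppm_per_hour * scan.time / 3600.0
        eps = np.random.default_rng([run.seed, seed, k]).normal(
            0.0, ppm_sigma, size=scan.n_precursors
        ) if ppm_sigma > 0 else np.zeros(scan.n_precursors)
        mz_obs = true_mz * (1.0 + (drift + eps) * 1e-6)
        new_scans.append(_dc_replace(scan, mz_obs=mz_obs))
    return _dc_replace(run, scans=new_scans)


def mass_error_ppm(run: RunRecord) -> tuple[np.ndarray, np.ndarray]:
    """Per sampled ion: scan time and observed-vs-true m/z error in ppm."""
    times, ppm = [], []
    for scan in run.scans:
        if scan.n_precursors == 0:
            continue
        true_mz = np.array([run.peptides[i].mz for i in scan.peptide_idx])
        times.append(np.full(scan.n_precursors, scan.time))
        ppm.append((scan.mz_obs / true_mz - 1.0) * 1e6)
    if not times:
        return _EMPTY_F, _EMPTY_F
    return np.concatenate(times), np.concatenate(ppm)


def recalibrate(run: RunRecord, bin_width_s: float = 60.0) -> RunRecord:
    """Post-acquisition recalibration via windowed median ppm correction.

    Scans are binned in time; the median ppm error per bin (estimated
    against the true m/z available in simulation) is subtracted from every
    observed m/z, removing drift and leaving sub-ppm residual medians.
    """
    times, ppm = mass_error_ppm(run)
    if len(times) == 0:
        return run
    bins = np.floor(times / bin_width_s).astype(int)
    med = {b: float(np.median(ppm[bins == b])) for b in np.unique(bins)}
    new_scans = []
    for scan in run.scans:
        if scan.n_precursors == 0:
            new_scans.append(scan)
            continue
        b = int(scan.time // bin_width_s)
        corr = med.get(b, 0.0)
        new_scans.append(
            _dc_replace(scan, mz_obs=scan.mz_obs / (1.0 + corr * 1e-6))
        )
    return _dc_replace(run, scans=new_scans)


@dataclass(frozen=True)
class ChimericitySummary:
    """Co-isolation statistics over the MS2 scans of one run."""

    counts: np.ndarray  # sampled precursors per MS2 scan
    fraction_chimeric: float  # of non-empty MS2 scans, fraction with > 1
    mean_coisolated: float  # mean precursors per non-empty MS2 scan


def chimericity(run: RunRecord) -> ChimericitySummary:
    """Count co-isolated precursors per MS2 scan.

    The chimeric fraction is computed over scans that sampled at least one
    precursor, so empty scans at the gradient edges do not dilute it.
    """
    counts = np.array([s.n_precursors for s in run.ms2_scans()], dtype=int)
    nonempty = counts[counts > 0]
    if len(nonempty) == 0:
        return ChimericitySummary(counts, 0.0, 0.0)
    return ChimericitySummary(
        counts=counts,
        fraction_chimeric=float((nonempty > 1).mean()),
        mean_coisolated=float(nonempty.mean()),
    )


@lru_cache(maxsize=65536)
def _pair_shares_fragment(
    seq_a: str, seq_b: str, frag_ppm_tol: float
) -> bool:
    fa = fragment_mzs(seq_a)
    fb = fragment_mzs(seq_b)
    pos = np.searchsorted(fb, fa)
    for x, p in zip(fa, pos):
        for q in (p - 1, p):
            if 0 <= q < len(fb) and abs(x - fb[q]) <= frag_ppm_tol * 1e-6 * x:
                return True
    return False


def interference_fraction(run: RunRecord, frag_ppm_tol: float = 10.0) -> float:
    """Fraction of sampled precursors with a fragment-level interferer.

    A precursor is interfered when some co-isolated, co-eluting precursor
    (same MS2 scan) shares a singly charged b/y fragment m/z within the
    given ppm tolerance.  Tolerance 0 counts only exact fragment matches.
    Deterministic for a given run.
    """
    if frag_ppm_tol < 0:
        raise ValueError("fragment tolerance must be >= 0")
    sampled: set[int] = set()
    interfered: set[int] = set()
    for scan in run.ms2_scans():
        idx = scan.peptide_idx
        sampled.update(int(i) for i in idx)
        if len(idx) < 2:
            continue
        for a in range(len(idx)):
            ia = int(idx[a])
            for b in range(a + 1, len(idx)):
                ib = int(idx[b])
                if ia in interfered and ib in interfered:
                    continue
                sa = run.peptides[ia].sequence
                sb = run.peptides[ib].sequence
                key = (sa, sb) if sa <= sb else (sb, sa)
                if _pair_shares_fragment(key[0], key[1], frag_ppm_tol):
                    interfered.add(ia)
                    interfered.add(ib)
    if not sampled:
        return 0.0
    return len(interfered) / len(sampled)


def detectability(
    run: RunRecord, min_points: int = 3, min_ions: int = 10
) -> set[int]:
    """Detected precursors: a proxy for confident identification.

    A precursor counts as detected when it was sampled in at least
    ``min_points`` MS2 scans across its peak with at least ``min_ions``
    total ions — a chromatographic-sampling criterion that is monotone in
    load and in points-per-peak, standing in for search-engine
    identification (out of scope here).
    """
    n_scans: dict[int, int] = {}
    n_ions: dict[int, int] = {}
    for scan in run.ms2_scans():
        for i, c in zip(scan.peptide_idx, scan.counts):
            i = int(i)
            n_scans[i] = n_scans.get(i, 0) + 1
            n_ions[i] = n_ions.get(i, 0) + int(c)
    return {
        i
        for i in n_scans
        if n_scans[i] >= min_points and n_ions[i] >= min_ions
    }
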