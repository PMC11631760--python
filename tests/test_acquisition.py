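"""Stochastic DIA/DDA acquisition: ion statistics, mass error, metrics."""

import math

import numpy as np
import pytest

from ndiasim.acquisition import (
    apply_mass_error,
    chimericity,
    detectability,
    interference_fraction,
    mass_error_ppm,
    recalibrate,
    sequenced_precursors,
    simulate_dda,
    simulate_dia,
)
from ndiasim.sample import PeptideIon, peptide_mz
from ndiasim.windows import (
    AcquisitionMethod,
    MzRange,
    TimingModel,
    make_fixed_windows,
    scan_spacing_ms,
)


def ion(seq="PEPTIDEK", charge=2, rt=50.0, fwhm=5.0, abundance=1e5,
        species="human", accession="P1"):
    return PeptideIon(
        sequence=seq,
        protein_accessions=(accession,),
        species=species,
        charge=charge,
        mz=peptide_mz(seq, charge),
        rt_apex=rt,
        peak_fwhm=fwhm,
        abundance=abundance,
    )


def one_window_method(maxit=3.5, tau=2.0, agc=1e9):
    scheme = make_fixed_windows(MzRange(380.0, 980.0), 600.0)
    return AcquisitionMethod.dia(scheme, TimingModel(maxit, tau), agc_capacity=agc)


def test_dia_poisson_sampling_matches_closed_form_mean():
    """Sampled counts of a flat elution profile average to flux x maxIT."""
    method = one_window_method(maxit=3.5, tau=2.0)
    p = ion(abundance=5000.0, fwhm=1e7, rt=0.0)  # effectively constant flux
    spacing = scan_spacing_ms(method.timing) / 1000.0
    n_scans = 1000
    run = simulate_dia([p], method, n_scans * spacing, seed=42)
    counts = [s.counts.sum() for s in run.ms2_scans()]
    lam = 5000.0 * 3.5e-3
    assert len(counts) >= n_scans
    mean = np.mean(counts)
    assert abs(mean - lam) < 3.0 * math.sqrt(lam / len(counts))


def test_precursor_outside_windows_never_sampled():
    scheme = make_fixed_windows(MzRange(380.0, 500.0), 2.0)
    method = AcquisitionMethod.dia(scheme, TimingModel(3.5, 2.0))
    p = ion(seq="LLLLLLLLLK", charge=2)  # m/z ~ 570, outside 380-500
    assert p.mz > 500.0
    run = simulate_dia([p], method, 60.0, seed=1)
    assert all(s.n_precursors == 0 for s in run.ms2_scans())


def test_empty_sample_warns_and_returns_empty_run():
    method = one_window_method()
    with pytest.warns(UserWarning):
        run = simulate_dia([], method, 10.0, seed=1)
    assert run.scans == []


def test_total_ion_current_linear_in_load():
    """Doubling the load doubles summed counts below the AGC cap."""
    method = one_window_method(agc=1e12)
    peptides = [
        ion(seq=s, rt=r, abundance=2e4)
        for s, r in (("PEPTIDEK", 20.0), ("LLLVVKPK", 30.0), ("AAADDDRK", 40.0))
    ]
    doubled = [
        PeptideIon(**{**p.__dict__, "abundance": p.abundance * 2})
        for p in peptides
    ]
    t1 = sum(
        s.counts.sum() for s in simulate_dia(peptides, method, 60.0, 7).ms2_scans()
    )
    t2 = sum(
        s.counts.sum() for s in simulate_dia(doubled, method, 60.0, 7).ms2_scans()
    )
    assert t2 / t1 == pytest.approx(2.0, rel=0.02)


def test_agc_cap_limits_every_scan_and_shortens_injection():
    method = one_window_method(agc=500.0)
    p = ion(abundance=1e7, fwhm=20.0, rt=30.0)  # far above the cap
    run = simulate_dia([p], method, 60.0, seed=3)
    hit = 0
    for s in run.ms2_scans():
        assert s.counts.sum() <= 500
        if s.injection_time_ms < method.timing.max_injection_time_ms:
            hit += 1
    assert hit > 0


def test_agc_saturation_decreases_with_load():
    method = one_window_method(agc=200.0)

    def frac_capped(scale):
        p = ion(abundance=scale, fwhm=20.0, rt=30.0)
        run = simulate_dia([p], method, 60.0, seed=3)
        ms2 = run.ms2_scans()
        capped = [
            s.injection_time_ms < method.timing.max_injection_time_ms
            for s in ms2
        ]
        return np.mean(capped)

    assert frac_capped(1e4) <= frac_capped(1e6)


def test_dia_samples_every_inrange_precursor():
    """DIA coverage is abundance-blind: all in-range precursors are sampled."""
    scheme = make_fixed_windows(MzRange(380.0, 980.0), 8.0)
    method = AcquisitionMethod.dia(scheme, TimingModel(14.0, 2.382))
    seqs = ["PEPTIDEK", "LLLVVKPK", "AAADDDRK", "GGGSSTTK", "MMMWWYYK"]
    peptides = [
        ion(seq=s, rt=20.0 + 5 * k, abundance=1e6) for k, s in enumerate(seqs)
    ]
    run = simulate_dia(peptides, method, 60.0, seed=5)
    sampled = set()
    for s in run.ms2_scans():
        sampled.update(int(i) for i in s.peptide_idx)
    in_range = {
        k for k, p in enumerate(peptides) if 380.0 <= p.mz < 980.0
    }
    assert in_range <= sampled


def test_dda_selection_respects_dynamic_exclusion_timeline():
    """One peptide, 20-s peak, 10-s exclusion, 0.5-s cycles -> <= 3 picks."""
    maxit = 2.5
    apex_lambda = 40.0  # expected ions per fill at the apex
    threshold = 0.49 * apex_lambda  # eligible over (a hair more than) the FWHM
    p = ion(abundance=apex_lambda / (maxit / 1000.0), rt=60.0, fwhm=20.0)
    method = AcquisitionMethod.dda(
        MzRange(380.0, 980.0),
        top_n=10,
        cycle_time_s=0.5,
        dynamic_exclusion_s=10.0,
        min_intensity=threshold,
    )
    run = simulate_dda([p], method, 120.0, seed=9)
    picks = [s.time for s in run.ms2_scans() if s.target_idx == 0]

    # independent event-timeline oracle on the cycle grid
    sigma = 20.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    expected, release = [], -np.inf
    t = 0.0
    while t < 120.0:
        lam = apex_lambda * math.exp(-0.5 * ((t - 60.0) / sigma) ** 2)
        if lam >= threshold and t >= release:
            expected.append(t)
            release = t + 10.0
        t += 0.5
    assert len(picks) == len(expected)
    assert len(picks) <= 3


def test_dda_top1_sequences_only_the_most_intense():
    shared_rt = 30.0
    weak = ion(seq="PEPTIDEK", rt=shared_rt, abundance=1e4)
    strong = ion(seq="PEPTIDER", rt=shared_rt, abundance=1e6, accession="P2")
    method = AcquisitionMethod.dda(
        MzRange(380.0, 980.0), top_n=1, dynamic_exclusion_s=0.0
    )
    run = simulate_dda([weak, strong], method, 60.0, seed=1)
    targets = {s.target_idx for s in run.ms2_scans()}
    assert targets == {1}


def test_dda_reselects_every_cycle_without_exclusion():
    p = ion(rt=30.0, fwhm=10.0, abundance=1e6)
    method = AcquisitionMethod.dda(
        MzRange(380.0, 980.0), top_n=5, dynamic_exclusion_s=0.0,
        min_intensity=1.0,
    )
    run = simulate_dda([p], method, 60.0, seed=1)
    sigma = 10.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    eligible_cycles = sum(
        1
        for c in range(120)
        if (
            abs(c * 0.5 - 30.0) <= 4.0 * sigma
            and 1e6
            * (method.timing.max_injection_time_ms / 1000.0)
            * math.exp(-0.5 * ((c * 0.5 - 30.0) / sigma) ** 2)
            >= 1.0
        )
    )
    assert len(run.ms2_scans()) == eligible_cycles


def test_dda_rejects_nonpositive_top_n():
    method = AcquisitionMethod.dda(MzRange(380.0, 980.0), top_n=0)
    with pytest.raises(ValueError):
        simulate_dda([ion()], method, 10.0, seed=1)


def test_dda_prefers_abundant_precursors(human_digest):
    method = AcquisitionMethod.dda(MzRange(380.0, 980.0), top_n=15)
    run = simulate_dda(human_digest, method, 150.0, seed=2)
    picked = sequenced_precursors(run)
    assert picked
    logs = np.log2([p.abundance for p in human_digest])
    assert np.mean([logs[i] for i in picked]) > logs.mean()


def test_mass_error_identity_without_noise(dia_run):
    unperturbed = apply_mass_error(dia_run, ppm_sigma=0.0, drift_ppm_per_hour=0.0)
    _, ppm = mass_error_ppm(unperturbed)
    assert np.allclose(ppm, 0.0)


def test_mass_error_median_matches_halfnormal(dia_run):
    noisy = apply_mass_error(dia_run, ppm_sigma=2.0, seed=4)
    _, ppm = mass_error_ppm(noisy)
    assert len(ppm) > 1000
    assert np.median(np.abs(ppm)) == pytest.approx(0.6745 * 2.0, rel=0.1)


def test_mass_drift_produces_time_trend(dia_run):
    drifted = apply_mass_error(
        dia_run, ppm_sigma=0.5, drift_ppm_per_hour=72.0, seed=4
    )
    t, ppm = mass_error_ppm(drifted)
    slope = np.polyfit(t, ppm, 1)[0]
    assert slope == pytest.approx(72.0 / 3600.0, rel=0.1)


def test_recalibration_removes_drift(dia_run):
    drifted = apply_mass_error(
        dia_run, ppm_sigma=2.0, drift_ppm_per_hour=72.0, seed=8
    )
    _, ppm_pre = mass_error_ppm(drifted)
    recal = recalibrate(drifted, bin_width_s=30.0)
    _, ppm_post = mass_error_ppm(recal)
    assert abs(np.median(ppm_post)) < 0.15
    assert np.median(np.abs(ppm_post)) < np.median(np.abs(ppm_pre))
    # pure drift is removed almost entirely
    pure = apply_mass_error(dia_run, ppm_sigma=0.0, drift_ppm_per_hour=72.0)
    _, residual = mass_error_ppm(recalibrate(pure, bin_width_s=30.0))
    assert abs(np.median(residual)) < 0.05


def test_recalibration_is_a_noop_without_error(dia_run):
    recal = recalibrate(dia_run)
    for before, after in zip(dia_run.scans, recal.scans):
        assert np.allclose(before.mz_obs, after.mz_obs)


def test_chimericity_trivial_cases():
    method = one_window_method()
    solo = simulate_dia([ion(abundance=1e6)], method, 60.0, seed=1)
    assert chimericity(solo).fraction_chimeric == 0.0
    pair = [
        ion(seq="PEPTIDEK", rt=30.0, abundance=1e8),
        ion(seq="PEPTIDER", rt=30.0, abundance=1e8, accession="P2"),
    ]
    both = simulate_dia(pair, method, 55.0, seed=1)
    assert chimericity(both).fraction_chimeric == 1.0


def test_interference_trivial_cases():
    method = one_window_method()
    solo = simulate_dia([ion(abundance=1e6)], method, 60.0, seed=1)
    assert interference_fraction(solo) == 0.0
    twins = [
        ion(seq="PEPTIDEK", rt=30.0, abundance=1e6, accession="P1"),
        ion(seq="PEPTIDEK", rt=30.0, abundance=1e6, accession="P2"),
    ]
    run = simulate_dia(twins, method, 55.0, seed=1)
    assert interference_fraction(run, frag_ppm_tol=0.0) == 1.0
    # disjoint fragment sets never interfere at zero tolerance
    distinct = [
        ion(seq="AAAAAAAK", rt=30.0, abundance=1e6, accession="P1"),
        ion(seq="GGGGGGGR", rt=30.0, abundance=1e6, accession="P2"),
    ]
    run2 = simulate_dia(distinct, method, 55.0, seed=1)
    assert interference_fraction(run2, frag_ppm_tol=0.0) == 0.0


def test_detectability_requires_points_across_the_peak():
    method = one_window_method(maxit=3.5, tau=1761.2)  # ~1.76-s cycle
    sharp = ion(abundance=1e6, fwhm=0.3, rt=30.0)  # narrower than the cycle
    run = simulate_dia([sharp], method, 60.0, seed=2)
    assert detectability(run, min_points=2, min_ions=1) == set()
    broad = ion(abundance=1e6, fwhm=20.0, rt=30.0)
    run2 = simulate_dia([broad], method, 60.0, seed=2)
    assert detectability(run2, min_points=3, min_ions=10) == {0}


def test_detected_count_monotone_in_load(human_digest, dia_method_2th):
    counts = []
    for load in (0.03, 0.3, 3.0):
        scaled = [
            PeptideIon(**{**p.__dict__, "abundance": p.abundance * load})
            for p in human_digest
        ]
        run = simulate_dia(scaled, dia_method_2th, 150.0, seed=6)
        counts.append(len(detectability(run)))
    assert counts == sorted(counts)


def test_identical_seeds_reproduce_scan_for_scan(human_digest, dia_method_2th):
    r1 = simulate_dia(human_digest, dia_method_2th, 60.0, seed=11)
    r2 = simulate_dia(human_digest, dia_method_2th, 60.0, seed=11)
    assert len(r1.scans) == len(r2.scans)
    for a, b in zip(r1.scans, r2.scans):
        assert a.time == b.time
        assert np.array_equal(a.peptide_idx, b.peptide_idx)
        assert np.array_equal(a.counts, b.counts)
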