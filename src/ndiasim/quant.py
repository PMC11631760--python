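"""Precursor and protein quantification: XICs, top-N and MaxLFQ rollups.

The precursor-by-run intensity table (`QuantMatrix`) is built either from
simulated runs (trapezoid XIC areas over the sampled ion-count trace), from
the deterministic closed-form path (`theoretical_quant_matrix`, the
noise-free Gaussian peak integral — useful for exact benchmark baselines),
or from an imported precursor report (see `ndiasim.io`).

Two protein rollups are provided:

* top-N ("top3"): per run, the sum of the protein's N most intense
  precursor groups, ranked once by mean intensity across runs so the
  peptide set is fixed per protein;
* MaxLFQ: median pairwise log-ratios between runs over shared precursors,
  reconciled by damped least squares and anchored so the summed linear
  protein intensity matches the summed observed precursor intensity.

MaxLFQ uses every precursor observed in at least two runs, which is why it
outperforms top-N whenever proteins carry more than a handful of peptides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .acquisition import RunRecord
from .sample import MixtureDesign, PeptideIon

_SQRT_2PI = math.sqrt(2.0 * math.pi)
_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

META_COLUMNS = ("sequence", "charge", "protein_group", "species")


@dataclass
class QuantMatrix:
    """Precursor-by-run intensity table plus precursor annotations.

    ``data`` is indexed by precursor id (``SEQUENCE/charge``) with one
    column per run; missing values are NaN, present values are positive.
    ``meta`` shares the index and carries sequence, charge, protein_group
    and species.
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ValueError("precursor ids must be unique")
        if not self.data.columns.is_unique:
            raise ValueError("run labels must be unique")
        if not self.data.index.equals(self.meta.index):
            raise ValueError("data and meta must share the precursor index")
        vals = self.data.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValueError("intensities must be positive where present")

    @property
    def runs(self) -> list[str]:
        return list(self.data.columns)

    def n_precursors(self) -> int:
        return len(self.data)


def extract_xic(run: RunRecord, peptide_index: int) -> float:
    """Extracted-ion chromatogram area for one precursor in one run.

    Ion counts are converted to instantaneous flux (count / effective
    injection time) and integrated over the scan times with the trapezoid
    rule, so the area is linear in true abundance below the AGC cap.  A
    peptide sampled in a single scan is integrated over one cycle; a
    peptide never sampled returns NaN (missing).
    """
    xics = extract_all_xics(run)
    return xics.get(peptide_index, math.nan)


def extract_all_xics(run: RunRecord) -> dict[int, float]:
    """XIC areas for every precursor sampled in the run."""
    traces: dict[int, list[tuple[float, float]]] = {}
    for scan in run.ms2_scans():
        if scan.n_precursors == 0:
            continue
        inj_s = scan.injection_time_ms / 1000.0
        for i, c in zip(scan.peptide_idx, scan.counts):
            traces.setdefault(int(i), []).append((scan.time, c / inj_s))
    areas: dict[int, float] = {}
    for i, pts in traces.items():
        if len(pts) == 1:
            areas[i] = pts[0][1] * run.cycle_time_s
        else:
            pts.sort()
            t = np.array([p[0] for p in pts])
            r = np.array([p[1] for p in pts])
            area = float(np.trapezoid(r, t))
            # guard against degenerate all-same-time traces
            areas[i] = area if area > 0 else float(r.sum()) * run.cycle_time_s
    return areas


def _matrix_from_values(
    values: dict[str, dict[str, float]],
    meta_rows: dict[str, tuple],
    run_order: Sequence[str],
) -> QuantMatrix:
    index = sorted(meta_rows)
    data = pd.DataFrame(
        {
            run: [values.get(run, {}).get(pid, math.nan) for pid in index]
            for run in run_order
        },
        index=pd.Index(index, name="precursor_id"),
    )
    meta = pd.DataFrame(
        [meta_rows[pid] for pid in index],
        index=data.index,
        columns=list(META_COLUMNS),
    )
    return QuantMatrix(data=data, meta=meta)


def quant_matrix_from_runs(runs: Sequence[RunRecord]) -> QuantMatrix:
    """Build the precursor-by-run table from simulated acquisitions."""
    values: dict[str, dict[str, float]] = {}
    meta_rows: dict[str, tuple] = {}
    run_order = []
    for run in runs:
        run_order.append(run.run_id)
        xics = extract_all_xics(run)
        col: dict[str, float] = {}
        for i, area in xics.items():
            p = run.peptides[i]
            pid = p.precursor_id
            col[pid] = area
            meta_rows[pid] = (
                p.sequence,
                p.charge,
                ";".join(p.protein_accessions),
                p.species,
            )
        values[run.run_id] = col
    return _matrix_from_values(values, meta_rows, run_order)


def theoretical_quant_matrix(
    samples: Mapping[str, Sequence[PeptideIon]],
    faims_transmission: float = 1.0,
) -> QuantMatrix:
    """Noise-free quant table from closed-form Gaussian peak areas.

    The XIC area of a Gaussian elution profile with apex flux ``a`` and
    width sigma is ``a × sigma × sqrt(2π)``; this is the deterministic
    limit of the stochastic simulator and serves as the exact baseline for
    ratio-recovery benchmarks.
    """
    values: dict[str, dict[str, float]] = {}
    meta_rows: dict[str, tuple] = {}
    run_order = []
    for run_id, peptides in samples.items():
        run_order.append(run_id)
        col: dict[str, float] = {}
        for p in peptides:
            sigma = p.peak_fwhm * _FWHM_TO_SIGMA
            col[p.precursor_id] = (
                p.abundance * sigma * _SQRT_2PI * faims_transmission
            )
            meta_rows[p.precursor_id] = (
                p.sequence,
                p.charge,
                ";".join(p.protein_accessions),
                p.species,
            )
        values[run_id] = col
    return _matrix_from_values(values, meta_rows, run_order)


def add_noise(
    qm: QuantMatrix,
    cv: float = 0.2,
    missing_fraction: float = 0.0,
    seed: int = 0,
) -> QuantMatrix:
    """Multiplicative log-normal noise (target CV) plus random missingness."""
    rng = np.random.default_rng([seed, 0x17])
    vals = qm.data.to_numpy(dtype=float).copy()
    if cv > 0:
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        noise = rng.lognormal(-0.5 * sigma * sigma, sigma, size=vals.shape)
        vals = vals * noise
    if missing_fraction > 0:
        drop = rng.random(vals.shape) < missing_fraction
        vals[drop] = math.nan
    data = pd.DataFrame(vals, index=qm.data.index, columns=qm.data.columns)
    return QuantMatrix(data=data, meta=qm.meta.copy())


def normalize_median(qm: QuantMatrix) -> QuantMatrix:
    """Median-center log intensities per run (off by default everywhere)."""
    logged = np.log2(qm.data)
    centered = logged.sub(logged.median(axis=0), axis=1)
    overall = float(np.nanmedian(logged.to_numpy()))
    data = np.exp2(centered + overall)
    return QuantMatrix(data=data, meta=qm.meta.copy())


@dataclass
class ProteinQuant:
    """Protein-group-by-run intensities plus rollup bookkeeping."""

    data: pd.DataFrame  # protein_group x run
    method: str  # "top3" | "maxlfq"
    n_precursors_used: pd.Series
    n_precursors_total: pd.Series
    species: pd.Series

    @property
    def fraction_used(self) -> float:
        """Fraction of available precursors the rollup actually used."""
        total = int(self.n_precursors_total.sum())
        return float(self.n_precursors_used.sum()) / total if total else 0.0

    def n_disregarded(self) -> int:
        return int((self.n_precursors_total - self.n_precursors_used).sum())


def _group_rows(qm: QuantMatrix):
    for pg, idx in qm.meta.groupby("protein_group").groups.items():
        yield pg, qm.data.loc[idx], qm.meta.loc[idx]


def topn_rollup(qm: QuantMatrix, n: int = 3) -> ProteinQuant:
    """Top-N protein rollup (the "top3" intensity-sum estimator).

    Precursors are ranked once per protein by mean intensity across runs
    (keeping the peptide set fixed so run-to-run ratios stay
    interpretable); per run the protein intensity is the sum of the top-N
    precursors present in that run.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rows, used, total, species = [], {}, {}, {}
    for pg, sub, meta in _group_rows(qm):
        avail = sub.dropna(how="all")
        total[pg] = len(sub)
        if avail.empty:
            used[pg] = 0
            rows.append(pd.Series(math.nan, index=qm.data.columns, name=pg))
            species[pg] = meta["species"].iloc[0]
            continue
        ranking = avail.mean(axis=1, skipna=True).sort_values(
            ascending=False, kind="stable"
        )
        top = avail.loc[ranking.index[:n]]
        used[pg] = len(top)
        rows.append(top.sum(axis=0, min_count=1).rename(pg))
        species[pg] = meta["species"].iloc[0]
    data = pd.DataFrame(rows)
    data.index.name = "protein_group"
    return ProteinQuant(
        data=data,
        method=f"top{n}",
        n_precursors_used=pd.Series(used, name="n_used"),
        n_precursors_total=pd.Series(total, name="n_total"),
        species=pd.Series(species, name="species"),
    )


def _solve_maxlfq_profile(
    logm: np.ndarray, damping: float = 1e-10
) -> np.ndarray:
    """Solve one protein's per-run log2 abundances from pairwise ratios.

    For each run pair (i, j) sharing >= 1 precursor, the median log2 ratio
    over shared precursors gives one equation x_i - x_j = r_ij; the damped
    normal equations are solved per connected component of the run graph.
    The returned profile has an arbitrary additive constant per component
    (callers anchor it); runs with no data are NaN.
    """
    n_prec, n_runs = logm.shape
    present = np.isfinite(logm)
    has_data = present.any(axis=0)
    diffs = logm[:, :, None] - logm[:, None, :]  # (p, r, r)
    with np.errstate(invalid="ignore"):
        ratios = np.nanmedian(diffs, axis=0)
    shared = (present[:, :, None] & present[:, None, :]).sum(axis=0)

    rows_i, rows_j, rvals = [], [], []
    for i in range(n_runs):
        for j in range(i + 1, n_runs):
            if shared[i, j] >= 1 and np.isfinite(ratios[i, j]):
                rows_i.append(i)
                rows_j.append(j)
                rvals.append(ratios[i, j])

    x = np.full(n_runs, np.nan)
    # connectivity over runs with data, via the ratio equations
    adj = np.zeros((n_runs, n_runs), dtype=bool)
    for i, j in zip(rows_i, rows_j):
        adj[i, j] = adj[j, i] = True
    n_comp, labels = connected_components(
        csr_matrix(adj), directed=False
    )
    for comp in range(n_comp):
        members = np.flatnonzero((labels == comp) & has_data)
        if len(members) == 0:
            continue
        if len(members) == 1:
            # no pairwise information: fall back to the summed precursor
            # intensity of that run (anchoring makes this exact)
            col = members[0]
            x[col] = math.log2(np.nansum(np.exp2(logm[:, col])))
            continue
        pos = {run: k for k, run in enumerate(members)}
        eqs = [
            (pos[i], pos[j], r)
            for i, j, r in zip(rows_i, rows_j, rvals)
            if labels[i] == comp and labels[j] == comp
        ]
        k = len(members)
        ata = np.eye(k) * damping
        atb = np.zeros(k)
        for i, j, r in eqs:
            ata[i, i] += 1.0
            ata[j, j] += 1.0
            ata[i, j] -= 1.0
            ata[j, i] -= 1.0
            atb[i] += r
            atb[j] -= r
        x[members] = np.linalg.solve(ata, atb)
        # anchor: summed linear protein intensity over the component equals
        # the summed observed precursor intensity there
        obs = np.nansum(np.exp2(logm[:, members]))
        model = np.exp2(x[members]).sum()
        if obs > 0 and model > 0:
            x[members] += math.log2(obs / model)
    return x


def maxlfq_rollup(qm: QuantMatrix, damping: float = 1e-10) -> ProteinQuant:
    """MaxLFQ protein rollup from median pairwise precursor ratios.

    Per-precursor response factors cancel in the pairwise ratios, so on
    complete noise-free data the rollup reproduces true protein ratios
    exactly.  Every precursor observed in >= 2 runs contributes; requires
    at least 2 runs for ratio solving (single-run tables degenerate to
    summed intensities via the anchoring rule).
    """
    rows, used, total, species = [], {}, {}, {}
    for pg, sub, meta in _group_rows(qm):
        logm = np.log2(sub.to_numpy(dtype=float))
        x = _solve_maxlfq_profile(logm, damping=damping)
        rows.append(pd.Series(np.exp2(x), index=qm.data.columns, name=pg))
        total[pg] = len(sub)
        used[pg] = int((np.isfinite(logm).sum(axis=1) >= 2).sum())
        species[pg] = meta["species"].iloc[0]
    data = pd.DataFrame(rows)
    data.index.name = "protein_group"
    return ProteinQuant(
        data=data,
        method="maxlfq",
        n_precursors_used=pd.Series(used, name="n_used"),
        n_precursors_total=pd.Series(total, name="n_total"),
        species=pd.Series(species, name="species"),
    )


@dataclass
class CvSummary:
    """Coefficient-of-variation statistics over replicate runs."""

    cvs: pd.Series  # CV% per row (rows with >= min values)
    median_cv: float
    frac_below_10: float
    frac_below_20: float


def cv_stats(values: pd.DataFrame, min_values: int = 2) -> CvSummary:
    """CV% (sd/mean × 100) per row across replicate columns.

    Rows with fewer than ``min_values`` finite entries are excluded
    (a CV of a single value is undefined).  Sample standard deviation
    (ddof=1).
    """
    arr = values.to_numpy(dtype=float)
    n_ok = np.isfinite(arr).sum(axis=1)
    keep = n_ok >= min_values
    with np.errstate(invalid="ignore"):
        cv = np.nanstd(arr[keep], axis=1, ddof=1) / np.nanmean(
            arr[keep], axis=1
        ) * 100.0
    cvs = pd.Series(cv, index=values.index[keep], name="cv_percent")
    if len(cvs) == 0:
        return CvSummary(cvs, math.nan, math.nan, math.nan)
    return CvSummary(
        cvs=cvs,
        median_cv=float(cvs.median()),
        frac_below_10=float((cvs < 10.0).mean()),
        frac_below_20=float((cvs < 20.0).mean()),
    )


@dataclass
class MixRatioResult:
    """Per-protein log2 ratios between two mixture designs plus summaries."""

    ratios: pd.DataFrame  # protein_group x [species, log2_ratio, expected_log2]
    summary: pd.DataFrame  # species x [expected_log2, median_log2, sd_log2,
    #                                   median_abs_dev, n]


def mix_ratio_eval(
    pq: ProteinQuant,
    design_a: MixtureDesign,
    design_b: MixtureDesign,
    runs_a: Sequence[str],
    runs_b: Sequence[str],
) -> MixRatioResult:
    """Observed vs expected species fold changes between two designs.

    Per protein, the observed log2 ratio is taken between the mean linear
    intensity over the replicate runs of each design; the expected line per
    species is ``log2(fraction_a / fraction_b)`` (0 for human in every pair
    of the benchmark designs).  Reports SD and median absolute deviation
    from the expected value per species.
    """
    mean_a = pq.data[list(runs_a)].mean(axis=1, skipna=True)
    mean_b = pq.data[list(runs_b)].mean(axis=1, skipna=True)
    ok = mean_a.notna() & mean_b.notna() & (mean_a > 0) & (mean_b > 0)
    ratios = pd.DataFrame(
        {
            "species": pq.species[ok],
            "log2_ratio": np.log2(mean_a[ok] / mean_b[ok]),
        }
    )
    common = [
        sp
        for sp in design_a.fractions
        if sp in design_b.fractions
    ]
    expected = {
        sp: design_a.expected_log2(design_b, sp) for sp in common
    }
    ratios = ratios[ratios["species"].isin(expected)].copy()
    ratios["expected_log2"] = ratios["species"].map(expected)
    summary_rows = []
    for sp in common:
        obs = ratios.loc[ratios["species"] == sp, "log2_ratio"]
        summary_rows.append(
            {
                "species": sp,
                "expected_log2": expected[sp],
                "median_log2": float(obs.median()) if len(obs) else math.nan,
                "sd_log2": float(obs.std(ddof=1)) if len(obs) > 1 else math.nan,
                "median_abs_dev": float((obs - expected[sp]).abs().median())
                if len(obs)
                else math.nan,
                "n": int(len(obs)),
            }
        )
    summary = pd.DataFrame(summary_rows).set_index("species")
    return MixRatioResult(ratios=ratios, summary=summary)


def ratio_rmse(result: MixRatioResult) -> float:
    """RMSE of observed vs expected log2 ratios over all proteins."""
    dev = result.ratios["log2_ratio"] - result.ratios["expected_log2"]
    return float(np.sqrt(np.mean(np.square(dev))))
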