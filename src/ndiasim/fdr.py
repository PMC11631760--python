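"""Entrapment-based empirical FDR estimation and dataset-level metrics.

Appending a database of sequences known to be absent (shuffled mimics, or a
foreign species) to the search space lets the observed entrapment hits
estimate the false-discovery rate among target hits.  Two estimators are
always reported, because the size correction convention is not universal:

* ``lower_bound`` — the raw entrapment fraction
  ``n_entrap / (n_target + n_entrap)``;
* ``corrected`` — entrapment hits scaled down by the database-size ratio r
  before forming the rate, ``(n_entrap / r) / n_target``: with an
  entrapment partition r times the target size, false hits land in the
  entrapment partition r times as often, so ``n_entrap / r`` estimates the
  number of false *target* hits.

Bootstrap intervals resample the hit list with replacement at the protein
level (the benchmark convention is a small B = 23; a warning is emitted
below B = 100 because percentile intervals are then crude).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FdrEstimate:
    """Entrapment FDR point estimate, optionally with bootstrap interval."""

    n_target_hits: int
    n_entrap_hits: int
    size_ratio: float
    lower_bound: float
    corrected: float
    corrected_defined: bool
    bootstrap_mean: Optional[float] = None
    bootstrap_ci: Optional[tuple[float, float]] = None
    n_bootstrap: Optional[int] = None


def entrapment_fdr(
    n_target_hits: int, n_entrap_hits: int, size_ratio: float
) -> FdrEstimate:
    """Point estimate of the empirical FDR from entrapment hit counts.

    ``size_ratio`` is the entrapment/target database size ratio r (e.g. 9
    for a 9× mimic database).  With zero target hits the corrected
    estimate is undefined and flagged.
    """
    if n_target_hits < 0 or n_entrap_hits < 0:
        raise ValueError("hit counts must be >= 0")
    if size_ratio <= 0:
        raise ValueError("size ratio must be > 0")
    total = n_target_hits + n_entrap_hits
    lower = n_entrap_hits / total if total else 0.0
    if n_target_hits == 0:
        corrected, defined = math.nan, False
        if n_entrap_hits == 0:
            corrected, defined = 0.0, True
    else:
        corrected = (n_entrap_hits / size_ratio) / n_target_hits
        defined = True
    return FdrEstimate(
        n_target_hits=n_target_hits,
        n_entrap_hits=n_entrap_hits,
        size_ratio=size_ratio,
        lower_bound=lower,
        corrected=corrected,
        corrected_defined=defined,
    )


def bootstrap_fdr(
    hit_table: pd.DataFrame,
    size_ratio: float,
    n_bootstrap: int = 23,
    seed: int = 0,
    entrapment_column: str = "is_entrapment",
) -> FdrEstimate:
    """Bootstrap the corrected FDR over resamples of the protein hit list.

    ``hit_table`` has one row per reported protein hit and a boolean
    ``entrapment_column``.  Returns the point estimate on the full table
    together with the mean and 2.5/97.5 percentile interval over
    ``n_bootstrap`` resamples with replacement.  Deterministic under
    ``seed``.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    if n_bootstrap < 100:
        warnings.warn(
            f"B={n_bootstrap} bootstrap repetitions give a crude percentile "
            "interval; consider B >= 100",
            stacklevel=2,
        )
    flags = hit_table[entrapment_column].to_numpy(dtype=bool)
    point = entrapment_fdr(
        int((~flags).sum()), int(flags.sum()), size_ratio
    )
    rng = np.random.default_rng([seed, 0xFD])
    n = len(flags)
    estimates = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        pick = flags[rng.integers(0, n, size=n)] if n else flags
        est = entrapment_fdr(int((~pick).sum()), int(pick.sum()), size_ratio)
        estimates[b] = est.corrected
    finite = estimates[np.isfinite(estimates)]
    if len(finite) == 0:
        mean, ci = math.nan, (math.nan, math.nan)
    else:
        mean = float(finite.mean())
        ci = (
            float(np.percentile(finite, 2.5)),
            float(np.percentile(finite, 97.5)),
        )
    return FdrEstimate(
        n_target_hits=point.n_target_hits,
        n_entrap_hits=point.n_entrap_hits,
        size_ratio=size_ratio,
        lower_bound=point.lower_bound,
        corrected=point.corrected,
        corrected_defined=point.corrected_defined,
        bootstrap_mean=mean,
        bootstrap_ci=ci,
        n_bootstrap=n_bootstrap,
    )


def completeness_curve(protein_data: pd.DataFrame) -> pd.DataFrame:
    """Data-completeness curve: proteins quantified in >= x% of runs.

    For x = 0..100 the curve counts proteins whose presence fraction
    (non-missing runs / total runs) reaches x%.  Non-increasing and
    right-continuous; the value at 0% is the total protein count.
    """
    presence = protein_data.notna().mean(axis=1).to_numpy() * 100.0
    xs = np.arange(101)
    counts = [(presence >= x - 1e-9).sum() for x in xs]
    return pd.DataFrame({"pct_of_runs": xs, "n_proteins": counts})


def dynamic_range(protein_data: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Ranked log10 mean protein abundances and their span.

    Returns the abundance-rank table (descending) and the log10 span
    (max − min) across proteins.
    """
    mean = protein_data.mean(axis=1, skipna=True)
    mean = mean[mean > 0]
    log10 = np.log10(mean).sort_values(ascending=False)
    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(log10) + 1),
            "log10_abundance": log10.to_numpy(),
        },
        index=log10.index,
    )
    span = float(log10.max() - log10.min()) if len(log10) else math.nan
    return table, span
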