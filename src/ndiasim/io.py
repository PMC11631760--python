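"""File formats, configuration and run manifests.

All tabular outputs are TSV (tab-separated, UTF-8, header row) with floats
rendered at 9 significant digits so write/read round trips are byte-stable.
Run records additionally serialize to a JSON-lines scan log.  Precursor
reports use the long format (run, precursor id, sequence, charge, protein
group, species, intensity, q-value columns) so the evaluation modules can
also consume filtered exports from real search engines.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import sys
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acquisition import RunRecord
from .quant import META_COLUMNS, QuantMatrix
from .windows import (
    AcquisitionMethod,
    DDA_SCAN_OVERHEAD_MS,
    DIA_SCAN_OVERHEAD_MS,
    MzRange,
    TimingModel,
    WindowScheme,
    make_fixed_windows,
)

logger = logging.getLogger("ndiasim")

FLOAT_FORMAT = "%.9g"

#: Standard column names of the long-format precursor report, mapped to
#: themselves by default; pass a ``column_map`` to adapt external exports
#: (e.g. {"intensity": "FG.Quantity", "eg_qvalue": "EG.Qvalue"}).
REPORT_COLUMNS = (
    "run",
    "precursor_id",
    "sequence",
    "charge",
    "protein_group",
    "species",
    "intensity",
    "pg_qvalue",
    "eg_qvalue",
)


def _round9(x: float) -> float:
    return float(f"{x:{FLOAT_FORMAT[1:]}}")


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(
        path,
        sep="\t",
        index=index,
        float_format=FLOAT_FORMAT,
        lineterminator="\n",
    )


def read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def window_table(scheme: WindowScheme) -> pd.DataFrame:
    """Window scheme as a table: index, low, high, center."""
    return pd.DataFrame(
        {
            "index": [w.index for w in scheme.windows],
            "low": [w.low for w in scheme.windows],
            "high": [w.high for w in scheme.windows],
            "center": [w.center for w in scheme.windows],
        }
    )


def run_table(run: RunRecord) -> pd.DataFrame:
    """Long-format scan table of a run (one row per sampled precursor).

    MS2 scans that sampled nothing keep one row with an empty peptide_id
    so the scan structure round-trips; MS1 scans are omitted (they carry
    no sampled ions).
    """
    rows = []
    for k, scan in enumerate(run.scans):
        if scan.ms_level != 2:
            continue
        if scan.n_precursors == 0:
            rows.append(
                (k, scan.time, scan.window_low, scan.window_high,
                 scan.injection_time_ms, "", 0, math.nan)
            )
            continue
        for i, c, mz in zip(scan.peptide_idx, scan.counts, scan.mz_obs):
            rows.append(
                (k, scan.time, scan.window_low, scan.window_high,
                 scan.injection_time_ms,
                 run.peptides[int(i)].precursor_id, int(c), mz)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "scan_id", "time", "window_low", "window_high",
            "injection_time_ms", "peptide_id", "ion_count", "mz_observed",
        ],
    )


def write_scan_log_jsonl(run: RunRecord, path) -> None:
    """JSON-lines scan log: one JSON object per scan event."""
    with open(path, "w", encoding="utf-8") as fh:
        for k, scan in enumerate(run.scans):
            obj = {
                "scan_id": k,
                "time": _round9(scan.time),
                "ms_level": scan.ms_level,
                "window": [_round9(scan.window_low), _round9(scan.window_high)],
                "injection_time_ms": _round9(scan.injection_time_ms),
                "peptides": [
                    [run.peptides[int(i)].precursor_id, int(c), _round9(mz)]
                    for i, c, mz in zip(
                        scan.peptide_idx, scan.counts, scan.mz_obs
                    )
                ],
            }
            if scan.target_idx >= 0:
                obj["target"] = run.peptides[scan.target_idx].precursor_id
            fh.write(json.dumps(obj, separators=(",", ":")) + "\n")


def quant_matrix_to_report(qm: QuantMatrix) -> pd.DataFrame:
    """Long-format precursor report from a quant matrix (q-values 0)."""
    long = (
        qm.data.reset_index()
        .melt(id_vars="precursor_id", var_name="run", value_name="intensity")
        .dropna(subset=["intensity"])
    )
    merged = long.merge(
        qm.meta.reset_index(), on="precursor_id", how="left"
    )
    merged["pg_qvalue"] = 0.0
    merged["eg_qvalue"] = 0.0
    merged = merged[list(REPORT_COLUMNS)]
    return merged.sort_values(["run", "precursor_id"], kind="stable").reset_index(
        drop=True
    )


def write_precursor_report(qm: QuantMatrix, path) -> None:
    write_tsv(quant_matrix_to_report(qm), path)


def read_precursor_report(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    pg_q_threshold: float = 0.01,
    eg_q_threshold: float = 0.01,
) -> QuantMatrix:
    """Read a long-format precursor report into a `QuantMatrix`.

    ``column_map`` maps standard names (see `REPORT_COLUMNS`) to the
    file's column names for external search-engine exports.  Rows failing
    either q-value filter are dropped (and counted in the log); q-value
    columns absent from the file disable the corresponding filter.  An
    empty file yields an empty matrix with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    colmap = {name: name for name in REPORT_COLUMNS}
    if column_map:
        colmap.update(column_map)
    rename = {v: k for k, v in colmap.items() if v in df.columns}
    df = df.rename(columns=rename)
    if df.empty:
        logger.warning("empty precursor report: %s", path)
        empty = pd.DataFrame(index=pd.Index([], name="precursor_id"))
        meta = pd.DataFrame(
            columns=list(META_COLUMNS),
            index=pd.Index([], name="precursor_id"),
        )
        return QuantMatrix(data=empty, meta=meta)
    n0 = len(df)
    if "pg_qvalue" in df.columns:
        df = df[df["pg_qvalue"] < pg_q_threshold]
    if "eg_qvalue" in df.columns:
        df = df[df["eg_qvalue"] < eg_q_threshold]
    if len(df) < n0:
        logger.info(
            "q-value filter dropped %d of %d report rows", n0 - len(df), n0
        )
    if "precursor_id" not in df.columns:
        df = df.assign(
            precursor_id=df["sequence"] + "/" + df["charge"].astype(str)
        )
    data = df.pivot_table(
        index="precursor_id", columns="run", values="intensity", aggfunc="first"
    )
    data.columns.name = None
    meta_cols = [c for c in META_COLUMNS if c in df.columns]
    meta = (
        df.drop_duplicates("precursor_id")
        .set_index("precursor_id")[meta_cols]
        .reindex(data.index)
    )
    for c in META_COLUMNS:
        if c not in meta.columns:
            meta[c] = ""
    return QuantMatrix(data=data, meta=meta[list(META_COLUMNS)])


def protein_report(pq) -> pd.DataFrame:
    """Protein-quant table with rollup bookkeeping columns."""
    df = pq.data.copy()
    df.insert(0, "species", pq.species)
    df.insert(1, "n_precursors_used", pq.n_precursors_used)
    df.insert(2, "n_precursors_total", pq.n_precursors_total)
    return df.reset_index()


# --------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG: dict = {
    "sample": {
        "n_proteins": {"human": 40},
        "mixtures": ["H100"],
        "load_factor": 1.0,
        "fasta": None,
        "missed_cleavages": 0,
        "peak_fwhm_s": 6.0,
        "seed": 1,
    },
    "method": {
        "mode": "DIA",
        "mz_low": 380.0,
        "mz_high": 980.0,
        "window_width": 2.0,
        "overlap": 0.0,
        "max_injection_time_ms": 3.5,
        "scan_overhead_ms": None,
        "agc_capacity": 50000,
        "dda_cycle_s": 0.5,
        "dda_top_n": 75,
        "dynamic_exclusion_s": 10.0,
        "faims_transmission": 1.0,
    },
    "run": {
        "gradient_length_s": 300.0,
        "replicates": 1,
        "seed": 1,
    },
}


def _deep_update(base: dict, upd: Mapping) -> dict:
    out = dict(base)
    for k, v in upd.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v if not isinstance(v, Mapping) else dict(v)
    return out


def _apply_override(cfg: dict, expr: str) -> None:
    key, _, raw = expr.partition("=")
    if not _:
        raise ValueError(f"override {expr!r} is not of the form key=value")
    value = yaml.safe_load(raw)
    node = cfg
    parts = key.split(".")
    for p in parts[:-1]:
        node = node.setdefault(p, {})
    node[parts[-1]] = value


def load_config(
    path=None, overrides: Sequence[str] = ()
) -> dict:
    """Load a pipeline config (YAML over `DEFAULT_CONFIG`) with overrides.

    ``overrides`` are dotted ``section.key=value`` strings applied last.
    """
    import copy

    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_update(cfg, user)
    for expr in overrides:
        _apply_override(cfg, expr)
    validate_config(cfg)
    return cfg


def validate_config(cfg: Mapping) -> None:
    run = cfg["run"]
    if int(run["replicates"]) < 1:
        raise ValueError("run.replicates must be >= 1")
    if not isinstance(run["seed"], int):
        raise ValueError("run.seed must be an integer")
    fasta = cfg["sample"].get("fasta")
    if fasta is not None and not Path(fasta).exists():
        raise FileNotFoundError(f"sample.fasta not found: {fasta}")
    if cfg["method"]["mode"] not in ("DIA", "DDA"):
        raise ValueError("method.mode must be DIA or DDA")


def method_from_config(cfg: Mapping) -> AcquisitionMethod:
    m = cfg["method"]
    mz_range = MzRange(float(m["mz_low"]), float(m["mz_high"]))
    overhead = m.get("scan_overhead_ms")
    if m["mode"] == "DIA":
        timing = TimingModel(
            max_injection_time_ms=float(m["max_injection_time_ms"]),
            scan_overhead_ms=(
                DIA_SCAN_OVERHEAD_MS if overhead is None else float(overhead)
            ),
        )
        scheme = make_fixed_windows(
            mz_range, float(m["window_width"]), float(m["overlap"])
        )
        return AcquisitionMethod.dia(
            scheme,
            timing,
            agc_capacity=float(m["agc_capacity"]),
            faims_transmission=float(m["faims_transmission"]),
        )
    timing = TimingModel(
        max_injection_time_ms=float(m["max_injection_time_ms"]),
        scan_overhead_ms=(
            DDA_SCAN_OVERHEAD_MS if overhead is None else float(overhead)
        ),
    )
    return AcquisitionMethod.dda(
        mz_range,
        timing=timing,
        isolation_width=float(m.get("dda_isolation_width", 2.0)),
        cycle_time_s=float(m["dda_cycle_s"]),
        top_n=int(m["dda_top_n"]),
        dynamic_exclusion_s=float(m["dynamic_exclusion_s"]),
        agc_capacity=float(m["agc_capacity"]),
        faims_transmission=float(m["faims_transmission"]),
    )


def config_hash(cfg: Mapping) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(path, cfg: Mapping, seed: int) -> None:
    """Reproducibility manifest: config hash, seed and versions."""
    manifest = {
        "config": cfg,
        "config_sha256": config_hash(cfg),
        "seed": seed,
        "versions": {
            "ndiasim": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
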