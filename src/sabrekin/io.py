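"""Table ingestion/emission and JSON fit reports.

File dialects (CSV or TSV, UTF-8, header row; delimiter inferred from the
extension, ``.tsv`` meaning tabs):

* kinetics table — ``d_mix_s, pool, integral, sigma`` with
  ``pool in {e, f, CsS2, CsS, S}``; a ``d_mix_ms`` header is accepted and
  converted to seconds on ingest;
* EXSY quartet — ``d_mix_s, I_ee, I_ff, I_cross_mean`` (one row per
  spectrum);
* rate series — ``T_K, k_d_per_s, sigma_per_s, method, substrate``
  (temperatures always Kelvin; Celsius is deliberately rejected).

Reports are JSON with deterministic key order, a full input echo and the
package version, so two runs with identical configuration are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .fitting import ExsyIntegrals, KineticsDataset
from .thermo import RateSeries

__all__ = [
    "read_kinetics_table",
    "write_kinetics_table",
    "read_exsy_table",
    "read_rate_series",
    "write_rate_series",
    "write_report",
]

VALID_POOLS = {"e", "f", "CsS2", "CsS", "S"}


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        return pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SchemaError(f"cannot parse {path}: {exc}") from exc


def read_kinetics_table(path, meta: dict | None = None) -> KineticsDataset:
    """Read a long-format kinetics table into a typed dataset.

    Accepts ``d_mix_s`` or ``d_mix_ms`` (converted to seconds).  Raises
    :class:`SchemaError` naming the offending column/row for missing
    columns, unknown pools, or a non-monotone mixing-time grid.
    """
    df = _read_table(path)
    if "d_mix_ms" in df.columns and "d_mix_s" not in df.columns:
        df = df.rename(columns={"d_mix_ms": "d_mix_s"})
        df["d_mix_s"] = df["d_mix_s"].astype(float) / 1000.0
    for col in ("d_mix_s", "pool", "integral"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    bad = set(df["pool"].unique()) - VALID_POOLS
    if bad:
        raise SchemaError(
            f"{path}: unknown pool labels {sorted(bad)}; expected {sorted(VALID_POOLS)}"
        )
    try:
        ds = KineticsDataset.from_frame(df, meta=meta)
    except Exception as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    return ds


def write_kinetics_table(ds: KineticsDataset, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    ds.to_frame().to_csv(path, sep=sep, index=False)


def read_exsy_table(path, precision: float = 0.10) -> list:
    """Read EXSY quartets (one :class:`ExsyIntegrals` per row)."""
    df = _read_table(path)
    for col in ("d_mix_s", "I_ee", "I_ff", "I_cross_mean"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                ExsyIntegrals(
                    I_ee=float(row["I_ee"]),
                    I_ff=float(row["I_ff"]),
                    I_cross=float(row["I_cross_mean"]),
                    d_mix=float(row["d_mix_s"]),
                    precision=precision,
                )
            )
        except Exception as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from exc
    return out


def read_rate_series(path) -> RateSeries:
    df = _read_table(path)
    for col in ("T_K", "k_d_per_s"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if any(c.lower() in ("t_c", "t_celsius") for c in df.columns):
        raise SchemaError(f"{path}: temperatures must be Kelvin (column T_K)")
    df = df.sort_values("T_K")
    sigma = (
        df["sigma_per_s"].to_numpy(dtype=float)
        if "sigma_per_s" in df.columns
        else None
    )
    labels = {}
    for c in ("method", "substrate"):
        if c in df.columns:
            labels[c] = str(df[c].iloc[0])
    try:
        return RateSeries(
            T=df["T_K"].to_numpy(dtype=float),
            k_d=df["k_d_per_s"].to_numpy(dtype=float),
            sigma=sigma,
            labels=labels,
        )
    except Exception as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_rate_series(series: RateSeries, path) -> None:
    df = pd.DataFrame({"T_K": series.T, "k_d_per_s": series.k_d})
    if series.sigma is not None:
        df["sigma_per_s"] = series.sigma
    for key, val in series.labels.items():
        df[key] = val
    df.to_csv(Path(path), index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def write_report(result, path, *, inputs: dict | None = None, seed: int | None = None) -> None:
    """Write a deterministic JSON report for any result object.

    ``result`` may be a FitResult, EyringResult, CombinedRate or plain
    dict; anything exposing ``to_dict`` is serialized through it.
    """
    from . import __version__

    body = result.to_dict() if hasattr(result, "to_dict") else result
    report = {
        "software": {"name": "sabrekin", "version": __version__},
        "seed": seed,
        "inputs": _jsonable(inputs or {}),
        "result": _jsonable(body),
    }
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
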