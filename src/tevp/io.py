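"""CSV/JSON/YAML exchange formats.

Time series travel as CSV with a ``#``-prefixed header comment block carrying
the schema tag, units, and run metadata (protocol, oscillation parameters),
followed by a fixed column order:

    time_s, shear_rate_1_per_s, strain, sigma_yx_Pa,
    sigma_xx_Pa, sigma_yy_Pa, sigma_zz_Pa, lambda

Numeric output uses 17 significant digits so a write → read round trip is
bit-exact.  Unknown extra columns are tolerated with a warning (forward
compatibility); missing mandatory columns, unit mismatches and non-monotone
time are schema errors naming the offending field.
"""

from __future__ import annotations

import io as _io
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .simulator import RheoTimeSeries

__all__ = ["write_timeseries_csv", "read_timeseries_csv", "SchemaError"]

SCHEMA_TAG = "tevp-timeseries-v1"

COLUMNS = [
    "time_s",
    "shear_rate_1_per_s",
    "strain",
    "sigma_yx_Pa",
    "sigma_xx_Pa",
    "sigma_yy_Pa",
    "sigma_zz_Pa",
    "lambda",
]
MANDATORY = COLUMNS[:4]

UNITS = {
    "time_s": "s",
    "shear_rate_1_per_s": "1/s",
    "strain": "-",
    "sigma_yx_Pa": "Pa",
    "sigma_xx_Pa": "Pa",
    "sigma_yy_Pa": "Pa",
    "sigma_zz_Pa": "Pa",
    "lambda": "-",
}


class SchemaError(ValueError):
    """A time-series file violating the documented CSV schema."""


def write_timeseries_csv(path, ts: RheoTimeSeries) -> None:
    """Write ``ts`` with the documented header block and column order."""
    cols = {
        "time_s": ts.time,
        "shear_rate_1_per_s": ts.shear_rate,
        "strain": ts.strain,
        "sigma_yx_Pa": ts.sigma_yx,
        "sigma_xx_Pa": ts.sigma_xx,
        "sigma_yy_Pa": ts.sigma_yy,
        "sigma_zz_Pa": ts.sigma_zz,
        "lambda": ts.lam,
    }
    df = pd.DataFrame({k: (v if v is not None else np.full(len(ts), np.nan))
                       for k, v in cols.items()})
    with open(path, "w") as fh:
        fh.write(f"# schema: {SCHEMA_TAG}\n")
        fh.write("# units: " + ", ".join(f"{c}={u}" for c, u in UNITS.items()) + "\n")
        fh.write("# metadata: " + json.dumps(ts.metadata, sort_keys=True) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def _parse_header(lines: list[str]) -> dict:
    header = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" not in body:
            continue
        key, value = body.split(":", 1)
        header[key.strip()] = value.strip()
    return header


def read_timeseries_csv(path) -> RheoTimeSeries:
    """Read and validate a time-series CSV written by this package's schema."""
    text = Path(path).read_text()
    comment_lines = [ln for ln in text.splitlines() if ln.startswith("#")]
    header = _parse_header(comment_lines)
    df = pd.read_csv(_io.StringIO(text), comment="#", float_precision="round_trip")

    for col in MANDATORY:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    extra = [c for c in df.columns if c not in COLUMNS]
    if extra:
        warnings.warn(f"ignoring unknown columns {extra}", UserWarning)

    if "units" in header:
        declared = dict(part.split("=") for part in
                        (p.strip() for p in header["units"].split(",")) if "=" in part)
        declared = {k.strip(): v.strip() for k, v in declared.items()}
        for col, unit in declared.items():
            if col in UNITS and unit != UNITS[col]:
                raise SchemaError(f"unit mismatch for column {col!r}: "
                                  f"file says {unit!r}, schema requires {UNITS[col]!r}")

    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise SchemaError("non-monotone time in column 'time_s'")

    metadata = {}
    if "metadata" in header:
        try:
            metadata = json.loads(header["metadata"])
        except json.JSONDecodeError as exc:
            raise SchemaError(f"malformed metadata header: {exc}") from exc

    def opt(col):
        if col not in df.columns:
            return None
        v = df[col].to_numpy(dtype=float)
        return None if np.all(np.isnan(v)) else v

    return RheoTimeSeries(
        time=t,
        shear_rate=df["shear_rate_1_per_s"].to_numpy(dtype=float),
        strain=df["strain"].to_numpy(dtype=float),
        sigma_yx=df["sigma_yx_Pa"].to_numpy(dtype=float),
        sigma_xx=opt("sigma_xx_Pa"),
        sigma_yy=opt("sigma_yy_Pa"),
        sigma_zz=opt("sigma_zz_Pa"),
        lam=opt("lambda"),
        metadata=metadata,
    )
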