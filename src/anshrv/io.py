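"""Plain-text I/O: RR interval files, feature CSVs, JSON configuration.

RR series travel as one interval per line in milliseconds ('.' decimal
separator, LF line endings) — the least ambiguous common dialect for
ASCII RR import; seconds are supported via ``units='s'``.  Feature CSVs
carry '#'-prefixed provenance comment lines (config hash, seeds,
package version) above the header.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, HRVFeatures
from .params import DEFAULT_PARAMS

__all__ = [
    "read_rr",
    "write_rr",
    "write_features_csv",
    "read_features_csv",
    "load_params",
    "save_params",
    "config_hash",
]


def read_rr(path, units: str = "ms") -> np.ndarray:
    """Read an RR series: one interval per line, blank lines skipped.

    ``units`` is 'ms' (default) or 's' (converted to ms).  Non-numeric
    or non-positive lines raise with the offending line number.
    """
    if units not in ("ms", "s"):
        raise ValueError("units must be 'ms' or 's'")
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            try:
                v = float(text)
            except ValueError:
                raise ValueError(f"{path}: non-numeric value on line {lineno}: {text!r}")
            if v <= 0:
                raise ValueError(f"{path}: non-positive interval on line {lineno}")
            values.append(v)
    if not values:
        raise ValueError(f"{path}: no RR intervals found")
    rr = np.asarray(values, dtype=float)
    return rr * 1000.0 if units == "s" else rr


def write_rr(rr_ms, path) -> None:
    """Write an RR series in the plain-text dialect of :func:`read_rr`."""
    rr = np.asarray(rr_ms, dtype=float)
    with open(path, "w", newline="\n") as fh:
        for v in rr:
            fh.write(f"{v:.6g}\n")


def config_hash(params: dict) -> str:
    """Short stable hash of a parameter mapping, for provenance headers."""
    blob = json.dumps(params, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance_lines(provenance: dict | None) -> str:
    from . import __version__

    lines = [f"# anshrv {__version__}"]
    for key, value in (provenance or {}).items():
        lines.append(f"# {key}: {value}")
    return "\n".join(lines) + "\n"


def write_features_csv(table, path, provenance: dict | None = None) -> None:
    """Write a feature record or table as CSV with provenance comments.

    Floats are written at 6 significant digits.  ``table`` may be a
    single :class:`HRVFeatures`, a list of them, or a DataFrame.
    """
    if isinstance(table, HRVFeatures):
        table = pd.DataFrame([table.as_dict()])
    elif isinstance(table, (list, tuple)):
        table = pd.DataFrame([f.as_dict() for f in table])
    buf = _io.StringIO()
    table.to_csv(buf, index=False, float_format="%.6g")
    with open(path, "w", newline="\n") as fh:
        fh.write(_provenance_lines(provenance))
        fh.write(buf.getvalue())


def read_features_csv(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_features_csv`."""
    return pd.read_csv(path, comment="#")


def load_params(path) -> dict[str, float]:
    """Load a flat JSON parameter mapping; unknown keys are rejected."""
    with open(path) as fh:
        params = json.load(fh)
    unknown = set(params) - set(DEFAULT_PARAMS)
    if unknown:
        raise KeyError(f"{path}: unknown parameter keys: {sorted(unknown)}")
    return {k: float(v) for k, v in params.items()}


def save_params(params: dict[str, float], path) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(params, fh, indent=2, sort_keys=True)
        fh.write("\n")
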