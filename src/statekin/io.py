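"""File formats, bundled fixtures, and the expression-fraction utility.

All interchange is plain CSV/JSON.  Vendor electrophysiology formats
(ABF/HEKA) are out of scope; export traces to CSV upstream (see README).
Bundled fixtures (the printed expression and state-fraction tables) are
integrity-checked against a sha256 manifest at load time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionRecord",
    "expression_fractions",
    "load_expression_table",
    "load_state_fraction_table",
    "read_sweeps",
    "write_sweeps",
    "read_table_fixture",
    "FixtureIntegrityError",
]


class FixtureIntegrityError(RuntimeError):
    """A bundled fixture does not match its manifest checksum."""


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's expression level and within-type fraction."""

    gene: str
    subunit_type: str
    log2_level: float
    fraction_pct: float | None = None


def expression_fractions(records) -> list[ExpressionRecord]:
    """Linear-scale fraction of each isoform within its subunit type.

    fraction(gene) = 100 * 2^L(gene) / sum over the same subunit type of 2^L.
    Rounding happens only at presentation.
    """
    records = list(records)
    if not records:
        raise ValueError("no expression records")
    recs = [
        r if isinstance(r, ExpressionRecord)
        else ExpressionRecord(gene=r[0], subunit_type=r[1], log2_level=float(r[2]))
        for r in records
    ]
    if any(not np.isfinite(r.log2_level) for r in recs):
        raise ValueError("log2 levels must be finite")
    totals: dict[str, float] = {}
    for r in recs:
        totals[r.subunit_type] = totals.get(r.subunit_type, 0.0) + 2.0 ** r.log2_level
    for typ, tot in totals.items():
        if tot <= 0:
            raise ValueError(f"empty or zero-level subunit type group {typ!r}")
    return [
        ExpressionRecord(
            gene=r.gene, subunit_type=r.subunit_type, log2_level=r.log2_level,
            fraction_pct=100.0 * 2.0 ** r.log2_level / totals[r.subunit_type],
        )
        for r in recs
    ]


def read_table_fixture(name: str) -> pd.DataFrame:
    """Load a bundled CSV fixture, verifying its sha256 checksum."""
    pkg = resources.files("statekin.data")
    with pkg.joinpath("manifest.json").open() as fh:
        manifest = json.load(fh)
    if name not in manifest:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(manifest)}")
    raw = pkg.joinpath(name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != manifest[name]:
        raise FixtureIntegrityError(
            f"checksum mismatch for {name}: {digest} != {manifest[name]}"
        )
    from io import BytesIO
    return pd.read_csv(BytesIO(raw))


def load_expression_table() -> pd.DataFrame:
    """The bundled VGSC subunit expression table (log2 levels + printed %)."""
    return read_table_fixture("subunit_expression.csv")


def load_state_fraction_table() -> pd.DataFrame:
    """The bundled state-fraction / inhibition-rate table
    (columns Vh_mV, F_R, F_FI, F_SI, rate_per_s; one row per holding
    potential)."""
    return read_table_fixture("state_fractions.csv")


_SWEEP_REQUIRED = ["sweep_id", "axis_value", "availability", "peak_norm"]


def write_sweeps(df: pd.DataFrame, path) -> None:
    """Write a tidy sweep table to CSV (full float precision)."""
    missing = [c for c in _SWEEP_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"sweep table missing column(s): {', '.join(missing)}")
    df.to_csv(path, index=False, float_format="%.17g")


def read_sweeps(path) -> pd.DataFrame:
    """Read a tidy sweep CSV, validating the schema."""
    df = pd.read_csv(path)
    missing = [c for c in _SWEEP_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"sweep table missing column(s): {', '.join(missing)}")
    return df
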