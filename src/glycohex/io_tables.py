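"""Schema-validated TSV input/output with provenance comment headers.

All interchange is plain TSV with one header line; lines starting with
``#`` are provenance/comment lines and are skipped on read. Each documented
schema lists required columns; readers reject files with missing required
columns and name the discrepancies.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .synthetic import TMT10_CHANNELS

__all__ = ["SCHEMAS", "SchemaError", "read_table", "write_table"]

logger = logging.getLogger(__name__)

#: Documented table schemas: name -> required columns.
SCHEMAS: dict[str, tuple[str, ...]] = {
    "glycome": ("species", "composition"),
    "glycopsm": ("spectrum_id", "accession", "site", "composition", "pep2d", "plex")
    + TMT10_CHANNELS,
    "samples": ("sample_id", "group", "plex", "channel"),
    "annotation": ("set", "accession"),
    "plate": ("well", "role", "sample_id", "substrate", "replicate", "concentration",
              "fluorescence"),
    "cohort": ("donor_id", "group", "age", "activity", "event", "time"),
}


class SchemaError(ValueError):
    """Raised when a table's header does not match its documented schema."""


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a TSV, skip ``#`` comment lines, validate required columns."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {missing} for schema {schema!r}"
        )
    logger.info("read %d rows from %s (schema %s)", len(df), path, schema)
    return df


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    provenance: Optional[Mapping[str, object]] = None,
    index: bool = False,
) -> None:
    """Write a TSV with ``# key: value`` provenance comment lines first."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=index)
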