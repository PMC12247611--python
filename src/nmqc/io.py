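"""Readers and writers for the tabular formats the pipeline consumes.

Everything is plain CSV/TSV with a header row, '.' decimal and UTF-8; the
delimiter is sniffed from the file extension.  ``subject_id`` and ``age``
are mandatory in an IDP table, subject ids must be unique, and IDP cells
must be numeric — violations raise with row/column context rather than
propagating silently.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "read_idp_table",
    "write_table",
    "read_table",
    "load_config",
    "write_manifest",
]

RESERVED = ("subject_id", "age", "sex", "true_category", "true_severity", "rater1", "rater2")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path))


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_idp_table(path) -> pd.DataFrame:
    """Read a cohort/IDP table and validate its contract.

    Returns the typed DataFrame; the IDP columns are every numeric column
    that is not one of the reserved metadata columns.
    """
    path = Path(path)
    df = read_table(path)
    for col in ("subject_id", "age"):
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing mandatory column {col!r}")
    dupes = df["subject_id"][df["subject_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"{path.name}: duplicate subject_id {dupes.iloc[0]!r}")
    if df["age"].isna().any():
        row = int(df.index[df["age"].isna()][0])
        raise ValueError(f"{path.name}: missing age at row {row}")
    for col in idp_columns(df):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() and not df[col].isna().any():
            row = int(df.index[vals.isna()][0])
            raise ValueError(f"{path.name}: non-numeric value in column {col!r}, row {row}")
        df[col] = vals
    return df


def idp_columns(df: pd.DataFrame) -> list:
    """The phenotype columns of a cohort table (everything non-reserved)."""
    return [c for c in df.columns if c not in RESERVED]


def load_config(path) -> dict:
    """Load a YAML or JSON pipeline configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_manifest(path, config: dict) -> None:
    """Record the exact configuration and seeds that produced a run.

    The manifest is enough to regenerate every artifact; it contains no
    volatile fields so repeated runs are byte-identical.
    """
    from . import __version__

    payload = {"nmqc_version": __version__, "config": config}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)
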