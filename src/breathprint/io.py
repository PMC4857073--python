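"""Cohort file I/O, result serialisation and run manifests.

Cohort schema (comma-separated, header row)::

    subject_id, group, cpc, aetiology, encephalopathy,
    bilirubin_mg_dl, albumin_g_dl, inr, alt_u_l, egfr_ml_min,
    s1_t50 .. s7_t50, s1_t100 .. s7_t200

``group`` is one of CTRL / NC_CLD / LC; ``cpc`` A/B/C or NA; ``aetiology``
infective / non_infective / mixed or NA; ``encephalopathy`` 0/1/NA; the
numeric covariates allow NA; the 28 sensor columns are required,
non-negative and finite.  Floats are written with Python's shortest
round-tripping representation, so read -> write -> read preserves every
numeric value bit-exactly.

Result reports are JSON with a ``schema_version`` field and fixed
sentinels for non-finite numbers ("inf", "-inf") and missing values
("NA"), keeping reports diff-able.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .bp_core import response_columns
from .errors import CohortSchemaError

__all__ = [
    "META_COLUMNS",
    "COHORT_COLUMNS",
    "GROUPS",
    "read_cohort",
    "write_cohort",
    "write_results",
    "read_results",
    "RunManifest",
    "write_manifest",
]

RESULTS_SCHEMA_VERSION = "1"

GROUPS = ("CTRL", "NC_CLD", "LC")
CPC_CLASSES = ("A", "B", "C")
AETIOLOGIES = ("infective", "non_infective", "mixed")

META_COLUMNS = [
    "subject_id",
    "group",
    "cpc",
    "aetiology",
    "encephalopathy",
    "bilirubin_mg_dl",
    "albumin_g_dl",
    "inr",
    "alt_u_l",
    "egfr_ml_min",
]
COHORT_COLUMNS = META_COLUMNS + response_columns()

_NUMERIC_META = ["bilirubin_mg_dl", "albumin_g_dl", "inr", "alt_u_l", "egfr_ml_min"]


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises :class:`CohortSchemaError` with row/column context for any
    schema violation (unknown column, bad group label, negative or
    missing sensor response, ...).  Extra columns beyond the schema
    (e.g. an appended ``aubp``) are tolerated and passed through.
    """
    path = Path(path)
    if not path.exists():
        raise CohortSchemaError(f"cohort file not found: {path}")
    df = pd.read_csv(path, dtype={"subject_id": str}, keep_default_na=False,
                     na_values=["NA", ""], float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"cohort file missing columns {missing}")

    bad_group = ~df["group"].isin(GROUPS)
    if bad_group.any():
        row = int(np.flatnonzero(bad_group)[0])
        raise CohortSchemaError(
            f"row {row}: unknown group label {df['group'].iloc[row]!r} "
            f"(expected one of {GROUPS})"
        )
    bad_cpc = ~(df["cpc"].isin(CPC_CLASSES) | df["cpc"].isna())
    if bad_cpc.any():
        row = int(np.flatnonzero(bad_cpc)[0])
        raise CohortSchemaError(f"row {row}: unknown Child-Pugh class {df['cpc'].iloc[row]!r}")
    bad_aet = ~(df["aetiology"].isin(AETIOLOGIES) | df["aetiology"].isna())
    if bad_aet.any():
        row = int(np.flatnonzero(bad_aet)[0])
        raise CohortSchemaError(f"row {row}: unknown aetiology {df['aetiology'].iloc[row]!r}")
    enc = pd.to_numeric(df["encephalopathy"], errors="coerce")
    bad_enc = ~(enc.isin([0, 1]) | df["encephalopathy"].isna())
    if bad_enc.any():
        row = int(np.flatnonzero(bad_enc)[0])
        raise CohortSchemaError(
            f"row {row}: encephalopathy must be 0, 1 or NA, "
            f"got {df['encephalopathy'].iloc[row]!r}"
        )
    df["encephalopathy"] = enc

    for col in _NUMERIC_META:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise CohortSchemaError(
                f"row {row}, column {col!r}: non-numeric value {df[col].iloc[row]!r}"
            )
        df[col] = values

    for col in response_columns():
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            row = int(np.flatnonzero(values.isna())[0])
            raise CohortSchemaError(
                f"row {row}, column {col!r}: sensor response missing or "
                f"non-numeric ({df[col].iloc[row]!r})"
            )
        if (values < 0).any():
            row = int(np.flatnonzero(values < 0)[0])
            raise CohortSchemaError(
                f"row {row}, column {col!r}: negative sensor response "
                f"{values.iloc[row]!r}"
            )
        df[col] = values.astype(float)
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table with round-tripping numeric formatting."""
    out = df.copy()
    for col in out.columns:
        if col == "encephalopathy":
            out[col] = out[col].map(
                lambda v: "NA" if (pd.isna(v) or v == "NA") else str(int(v))
            )
        elif out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else repr(float(v)))
    out = out.fillna("NA")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Result reports


def _sanitize(obj: Any) -> Any:
    """Convert a report to its canonical JSON form (sentinels applied)."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_sanitize(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        v = float(obj)
        if math.isnan(v):
            return "NA"
        if math.isinf(v):
            return "inf" if v > 0 else "-inf"
        return v
    if obj is None:
        return "NA"
    return obj


def _restore(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _restore(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_restore(v) for v in obj]
    if obj == "inf":
        return math.inf
    if obj == "-inf":
        return -math.inf
    return obj


def write_results(report: dict, path: str | Path) -> None:
    """Serialise a result report to versioned JSON with fixed sentinels."""
    body = _sanitize(report)
    body.setdefault("schema_version", RESULTS_SCHEMA_VERSION)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(body, indent=2, sort_keys=True) + "\n")


def read_results(path: str | Path) -> dict:
    """Load a result report, restoring infinity sentinels ("NA" stays "NA")."""
    return _restore(json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# Run manifests


@dataclass(frozen=True)
class RunManifest:
    """Provenance record emitted once per CLI run: rerunning with an
    identical manifest (command, config, seed, input digests) reproduces
    the numeric outputs exactly."""

    command: str
    config: dict
    seed: int | None
    input_digests: dict[str, str]
    package_version: str
    timestamp: str


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    out_path: str | Path,
    command: str,
    config: dict,
    seed: int | None,
    inputs: list[str | Path],
) -> RunManifest:
    from . import __version__

    manifest = RunManifest(
        command=command,
        config=_sanitize(config),
        seed=seed,
        input_digests={str(p): _digest(p) for p in inputs},
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    path = Path(str(out_path) + ".manifest.json")
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(asdict(manifest), indent=2, sort_keys=True) + "\n")
    return manifest
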