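"""Table reading/writing with schema validation and config-stamped headers.

All artifacts are UTF-8 CSV with an explicit header row, floats written at
10 significant digits, preceded by ``#`` comment lines carrying the
package version and a hash of the generating configuration so any table
can be traced back to its run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .arrangements import Arrangement, TerminatorSpec, parse_label

FLOAT_FORMAT = "%.10g"

SCHEMAS: dict[str, list[str]] = {
    "arrangements": ["label", "pair", "junction1_name", "junction1_rate", "junction1_mu_power",
                     "junction2_name", "junction2_rate", "junction2_mu_power"],
    "measurements": ["arrangement", "condition", "replicate", "fluorescence", "normalized"],
    "observed": ["arrangement", "label"],
    "truthtable": ["arrangement", "state", "L", "T", "C", "residual", "converged"],
    "grid": ["K", "mu", "agreement", "admissible"],
    "labels": ["arrangement", "label"],
    "dose_response": ["mu_upstream", "concentration_uM", "replicate", "fluorescence"],
}


class SchemaError(ValueError):
    """A table violates its declared schema."""


def config_hash(config: Mapping | None) -> str:
    """Short stable hash of a configuration mapping."""
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    kind: str,
    config: Mapping | None = None,
) -> Path:
    """Write a schema'd CSV with a provenance comment header."""
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table missing columns {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# grncontext {__version__} table kind={kind}\n")
        fh.write(f"# config_hash={config_hash(config)}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT)
    return path


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate a schema'd CSV (tolerates any line-ending dialect)."""
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: {kind} table missing columns {missing}")
    if kind in ("observed", "labels", "arrangements"):
        key = "label" if kind == "arrangements" else "arrangement"
        dupes = df[key][df[key].duplicated()]
        if len(dupes):
            raise SchemaError(f"{path}: duplicate arrangement keys {sorted(set(dupes))}")
        for i, lbl in enumerate(df[key]):
            base = str(lbl).split("+")[0]  # variant suffix allowed in observed keys
            try:
                parse_label(base)
            except ValueError as exc:
                raise SchemaError(f"{path} row {i}: {exc}") from exc
    return df


# -- arrangement spec files -------------------------------------------------

def arrangements_to_frame(arrangements) -> pd.DataFrame:
    from .arrangements import pair_id

    rows = []
    for a in arrangements:
        row = {"label": a.label, "pair": pair_id(a)}
        for j, spec in enumerate(a.junctions, start=1):
            row[f"junction{j}_name"] = spec.name
            row[f"junction{j}_rate"] = (
                "" if spec.readthrough_rate is None else spec.readthrough_rate
            )
            row[f"junction{j}_mu_power"] = spec.mu_power
        rows.append(row)
    return pd.DataFrame(rows, columns=SCHEMAS["arrangements"])


def frame_to_arrangements(df: pd.DataFrame) -> list[Arrangement]:
    out = []
    for _, row in df.iterrows():
        junctions = []
        for j in (1, 2):
            rate = row[f"junction{j}_rate"]
            rate = None if (pd.isna(rate) or rate == "") else float(rate)
            junctions.append(
                TerminatorSpec(
                    name=str(row[f"junction{j}_name"]),
                    readthrough_rate=rate,
                    mu_power=int(row[f"junction{j}_mu_power"]),
                )
            )
        out.append(parse_label(str(row["label"]), junctions=tuple(junctions)))
    return out


def write_arrangements(arrangements, path: str | Path, config: Mapping | None = None) -> Path:
    return write_table(arrangements_to_frame(arrangements), path, "arrangements", config)


def read_arrangements(path: str | Path) -> list[Arrangement]:
    return frame_to_arrangements(read_table(path, "arrangements"))
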