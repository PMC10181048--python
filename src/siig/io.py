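"""Reading and writing trait tables, direction configs, and bundled fixtures.

Trait tables are delimited text: a header row, a first column of genotype
IDs, and numeric trait columns. The delimiter is inferred from the file
extension (``.csv`` comma, ``.tsv``/``.txt`` tab) unless given explicitly.
Decimal points only; no locale handling.

Two fixture tables from a multi-environment barley yield trial (111
genotypes, four warm locations: Ahvaz, Gonbad, Zabol, Darab) ship with
the package:

``table3``
    per-environment grain yield (kg/ha) with per-environment SIIG values
    and ranks;
``table4``
    across-environment trait means (DHE, DMA, GFP, PLH, TKW, YLD) with
    per-trait ranks and the overall SIIG value and rank.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import DirectionSpec, SIIGResult, TraitMatrix

__all__ = [
    "read_trait_table",
    "write_trait_table",
    "write_result",
    "read_directions",
    "direction_preset",
    "load_fixture",
    "table4_trait_matrix",
    "table3_environment",
    "ENVIRONMENTS",
    "FIXTURE_NAMES",
]

ENVIRONMENTS = ("Ahvaz", "Gonbad", "Zabol", "Darab")
FIXTURE_NAMES = ("table3", "table4")

# sha256 of the bundled CSVs, guarding against silent corruption
_FIXTURE_SHA256 = {
    "table3": "d4c412ce27bf22ccd80f9b4686f4d13e43243fa3b4990b4f3249fdae5bf06304",
    "table4": "c6cb7dcec77744432a8c1633070a2b901de2b88217652e875b2712be7716c9ef",
}


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    if path.suffix.lower() in (".tsv", ".txt", ".tab"):
        return "\t"
    return ","


def read_trait_table(path: str | Path, delimiter: str | None = None) -> TraitMatrix:
    """Read a delimited genotype x trait table into a validated TraitMatrix.

    The first column holds genotype IDs (kept as strings); every other
    column must parse as a number in every row. Blank or non-numeric
    cells are reported with their genotype and trait coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a genotype-ID column plus at least one trait")
    id_col = df.columns[0]
    ids = df[id_col].astype(str)
    body = df.drop(columns=[id_col])
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | body.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        cell = body.iloc[i, j]
        what = "missing value" if pd.isna(cell) else f"non-numeric value {cell!r}"
        raise ValueError(
            f"{path}: {what} at genotype {ids.iloc[i]!r}, trait {body.columns[j]!r}"
        )
    numeric.index = pd.Index(ids, name="genotype")
    return TraitMatrix(numeric.astype(float))


def write_trait_table(
    matrix: TraitMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    """Write a TraitMatrix back to delimited text (inverse of read_trait_table)."""
    path = Path(path)
    matrix.data.to_csv(path, sep=_delimiter_for(path, delimiter))


def write_result(
    result: SIIGResult,
    path: str | Path,
    decimals: int = 3,
    delimiter: str | None = None,
) -> None:
    """Write genotype_id, d_plus, d_minus, siig, rank as delimited text.

    Values are printed to ``decimals`` places (default 3, the customary
    precision for SIIG tables); ranks stay integers.
    """
    path = Path(path)
    out = result.table.copy()
    for col in ("d_plus", "d_minus", "siig"):
        out[col] = out[col].map(lambda v: f"{v:.{decimals}f}")
    out.to_csv(path, sep=_delimiter_for(path, delimiter))


def read_directions(path: str | Path) -> DirectionSpec:
    """Read a trait-direction config: a YAML mapping trait -> orientation.

    Accepted orientation spellings: benefit/max/maximize and
    cost/min/minimize.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of trait -> direction")
    return DirectionSpec(raw)


def direction_preset(name: str) -> DirectionSpec:
    """Look up a named trait-direction preset from the bundled registry.

    Presets live in ``siig/data/presets.yaml`` so new crops can be added
    without code changes; ``warm-barley`` ships by default.
    """
    raw = yaml.safe_load(
        resources.files("siig.data").joinpath("presets.yaml").read_text()
    )
    presets = raw.get("presets", {})
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    return DirectionSpec(presets[name])


def _fixture_bytes(name: str) -> bytes:
    data = resources.files("siig.data").joinpath(f"{name}.csv").read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise RuntimeError(f"fixture {name} failed its checksum; reinstall the package")
    return data


def load_fixture(name: str) -> pd.DataFrame:
    """Load a bundled fixture table by name ('table3' or 'table4').

    Returns the full printed table as a DataFrame indexed by genotype ID
    (strings), checksum-verified and validated: 111 rows, SIIG columns in
    [0, 1], and for table4 the grain-filling period within one day of
    DMA - DHE (the printed means are rounded per trait, so the identity
    holds only to +/- 1 day).
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    from io import BytesIO

    df = pd.read_csv(BytesIO(_fixture_bytes(name)), dtype={"genotype": str})
    df = df.set_index("genotype")
    if len(df) != 111:
        raise RuntimeError(f"fixture {name}: expected 111 genotypes, got {len(df)}")
    siig_cols = [c for c in df.columns if c.startswith("SIIG") and "rank" not in c]
    for c in siig_cols:
        if not df[c].between(0, 1).all():
            raise RuntimeError(f"fixture {name}: {c} outside [0, 1]")
    if name == "table4":
        drift = (df["DMA"] - df["DHE"] - df["GFP"]).abs()
        if (drift > 1).any():
            raise RuntimeError("fixture table4: GFP deviates from DMA - DHE by > 1 day")
    return df


def table4_trait_matrix() -> TraitMatrix:
    """The six-trait means from the table4 fixture as a TraitMatrix."""
    df = load_fixture("table4")
    return TraitMatrix(df[["DHE", "DMA", "GFP", "PLH", "TKW", "YLD"]].astype(float))


def table3_environment(environment: str) -> pd.DataFrame:
    """Yield, SIIG and rank columns for one environment of the table3 fixture."""
    if environment not in ENVIRONMENTS:
        raise KeyError(f"unknown environment {environment!r}; have {ENVIRONMENTS}")
    df = load_fixture("table3")
    sub = df[[f"YLD_{environment}", f"SIIG_{environment}", f"rank_{environment}"]]
    return sub.rename(
        columns={
            f"YLD_{environment}": "YLD",
            f"SIIG_{environment}": "SIIG",
            f"rank_{environment}": "rank",
        }
    )
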