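"""Tabular input/output and small chromatography helpers.

All exchange formats are plain CSV (RFC 4180, UTF-8, ``.`` decimal
separator, header row) read and written through :mod:`pandas`. Four schemas
are understood:

``traits``
    Accession x morphological-character table. Columns ``accession_id``,
    ``group`` (one of ``rugosa``, ``hybrida``, ``species``) plus one column
    per character. Binary characters must be coded 0/1.
``panel``
    Accession x targeted-fragrance-compound table (contents in µg/g).
    Undetected compounds are explicit zeros, never missing values.
``voc``
    Long-format volatile survey: one row per (cultivar, stage, replicate,
    compound) with the compound's chemical class and headspace
    concentration in µg/L. Stages are the four flower-development phases
    (1 flower-bud, 2 early-blooming, 3 full-blooming, 4 withering); odd
    sample codes 1/3/5/7 as used on GC-MS vials are accepted as aliases
    and stored canonically as 1-4.
``annotation``
    Compound-to-pathway map with columns ``pathway_id``, ``compound`` and
    optionally ``pathway_name``.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, RangeError, SchemaError, ValidationError

VALID_GROUPS = frozenset({"rugosa", "hybrida", "species"})
VOC_COLUMNS = ["cultivar", "stage", "replicate", "compound", "compound_class", "concentration"]
_STAGE_ALIASES = {1: 1, 3: 2, 5: 3, 7: 4}

SCHEMAS = ("traits", "panel", "voc", "annotation")


def _require_columns(df: pd.DataFrame, required: list[str], schema: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{schema} table is missing required column {col!r}")


def _coerce_numeric(df: pd.DataFrame, columns: list[str], schema: str) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {out[col].iloc[row]!r} in numeric column "
                f"{col!r} of {schema} table (row {row})"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ParseError(f"missing value in numeric column {col!r} of {schema} table (row {row})")
        out[col] = coerced
    return out


def validate_traits(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an accession x trait table; returns the coerced table."""
    _require_columns(df, ["accession_id", "group"], "traits")
    if df["accession_id"].duplicated().any():
        dup = df.loc[df["accession_id"].duplicated(), "accession_id"].iloc[0]
        raise ValidationError(f"duplicate accession_id {dup!r} in traits table")
    unknown = set(df["group"]) - VALID_GROUPS
    if unknown:
        raise ValidationError(f"unknown group label(s) {sorted(unknown)}; expected one of {sorted(VALID_GROUPS)}")
    trait_cols = [c for c in df.columns if c not in ("accession_id", "group")]
    if not trait_cols:
        raise SchemaError("traits table has no trait columns")
    out = _coerce_numeric(df, trait_cols, "traits")
    # binary traits (only 0/1 values by construction) are validated by the generator
    return out.reset_index(drop=True)


def validate_panel(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an accession x compound content table (µg/g, >= 0)."""
    _require_columns(df, ["accession_id"], "panel")
    if df["accession_id"].duplicated().any():
        dup = df.loc[df["accession_id"].duplicated(), "accession_id"].iloc[0]
        raise ValidationError(f"duplicate accession_id {dup!r} in panel table")
    compound_cols = [c for c in df.columns if c != "accession_id"]
    if not compound_cols:
        raise SchemaError("panel table has no compound columns")
    out = _coerce_numeric(df, compound_cols, "panel")
    values = out[compound_cols].to_numpy(dtype=float)
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative content {values[i, j]} for compound {compound_cols[j]!r} "
            f"(accession {out['accession_id'].iloc[i]!r}); contents are µg/g >= 0"
        )
    return out.reset_index(drop=True)


def validate_voc(df: pd.DataFrame, stage_coding: str = "auto") -> pd.DataFrame:
    """Validate a long-format volatile table and canonicalize stage codes.

    Parameters
    ----------
    stage_coding:
        ``"auto"`` (default) detects odd vial codes 1/3/5/7 (used when any
        5 or 7 is present together with only odd codes) and maps them to
        1-4; ``"canonical"`` requires stages already in 1-4;
        ``"sample_code"`` requires the odd coding.
    """
    _require_columns(df, VOC_COLUMNS, "voc")
    out = _coerce_numeric(df, ["stage", "replicate", "concentration"], "voc")
    stages = out["stage"].to_numpy()
    if not np.all(stages == stages.astype(int)):
        raise ValidationError("stage codes must be integers")
    stages = stages.astype(int)
    odd = set(np.unique(stages)) <= set(_STAGE_ALIASES)
    use_alias = stage_coding == "sample_code" or (
        stage_coding == "auto" and odd and bool(np.any((stages == 5) | (stages == 7)))
    )
    if use_alias:
        if not odd:
            raise ValidationError("sample-code staging requires all stages in {1,3,5,7}")
        stages = np.vectorize(_STAGE_ALIASES.get)(stages)
    if not np.all((stages >= 1) & (stages <= 4)):
        bad = int(stages[(stages < 1) | (stages > 4)][0])
        raise ValidationError(f"stage {bad} outside the four flower-development stages 1-4")
    out["stage"] = stages
    if (out["replicate"] < 1).any():
        raise ValidationError("replicate indices must be >= 1")
    out["replicate"] = out["replicate"].astype(int)
    if (out["concentration"] < 0).any():
        bad = float(out.loc[out["concentration"] < 0, "concentration"].iloc[0])
        raise ValidationError(f"negative concentration {bad}; concentrations are µg/L >= 0")
    return out.reset_index(drop=True)


def validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a compound-to-pathway annotation map."""
    _require_columns(df, ["pathway_id", "compound"], "annotation")
    if df.duplicated(["pathway_id", "compound"]).any():
        raise ValidationError("duplicate (pathway_id, compound) pair in annotation map")
    return df.reset_index(drop=True)


_VALIDATORS = {
    "traits": validate_traits,
    "panel": validate_panel,
    "voc": validate_voc,
    "annotation": validate_annotation,
}


def read_table(path: str | os.PathLike, schema: str) -> pd.DataFrame:
    """Read and validate a CSV table of the given schema.

    Raises :class:`SchemaError` on missing columns, :class:`ParseError` on
    unparseable cells and :class:`ValidationError` on invariant violations.
    """
    if schema not in _VALIDATORS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {SCHEMAS}")
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=True, encoding="utf-8")
    # accession/cultivar identifiers stay text; numeric columns are coerced
    return _VALIDATORS[schema](df)


def write_table(df: pd.DataFrame, path: str | os.PathLike, schema: str | None = None) -> None:
    """Write a table as RFC-4180 CSV (UTF-8, header row, LF line endings)."""
    if schema is not None and schema in _VALIDATORS:
        df = _VALIDATORS[schema](df)
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def panel_summary(panel: pd.DataFrame, groups: pd.Series | None = None) -> pd.DataFrame:
    """Per-compound summary of a targeted panel table.

    Returns mean, min, max content (µg/g) and the number of accessions in
    which the compound was undetected (content 0). If ``groups`` is given
    (accession-aligned labels), one summary block per group is returned
    with a leading ``group`` column.
    """
    compound_cols = [c for c in panel.columns if c != "accession_id"]
    if not compound_cols:
        raise SchemaError("panel table has no compound columns")

    def _block(df: pd.DataFrame) -> pd.DataFrame:
        vals = df[compound_cols]
        return pd.DataFrame(
            {
                "compound": compound_cols,
                "mean": vals.mean().to_numpy(),
                "min": vals.min().to_numpy(),
                "max": vals.max().to_numpy(),
                "n_undetected": (vals == 0).sum().to_numpy(),
                "n": len(df),
            }
        )

    if groups is None:
        return _block(panel)
    out = []
    for group in pd.unique(groups):
        block = _block(panel.loc[(groups == group).to_numpy()])
        block.insert(0, "group", group)
        out.append(block)
    return pd.concat(out, ignore_index=True)


def kovats_ri(rt: float, ladder: Mapping[int, float]) -> float:
    """Linear (temperature-programmed) Kovats retention index.

    Parameters
    ----------
    rt:
        Retention time of the analyte in minutes.
    ladder:
        n-alkane calibration ladder mapping carbon number (>= 5) to
        retention time in minutes; retention times must be strictly
        increasing in carbon number and at least two alkanes are needed.

    Returns
    -------
    float
        ``RI = 100 n + 100 (n' - n) (rt - rt_n) / (rt_n' - rt_n)`` where
        ``n`` and ``n'`` are the bracketing alkane carbon numbers. With the
        usual consecutive ladder this is the textbook linear convention
        (~100 units per carbon).
    """
    if len(ladder) < 2:
        raise ValidationError("alkane ladder needs at least two entries")
    carbons = sorted(ladder)
    times = [float(ladder[c]) for c in carbons]
    if any(c < 5 for c in carbons):
        raise ValidationError("alkane carbon numbers must be >= 5")
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValidationError("ladder retention times must be strictly increasing in carbon number")
    if rt < times[0] or rt > times[-1]:
        raise RangeError(
            f"retention time {rt} min outside the ladder span [{times[0]}, {times[-1]}] min"
        )
    idx = int(np.searchsorted(times, rt, side="right")) - 1
    idx = min(idx, len(carbons) - 2)
    n_lo, n_hi = carbons[idx], carbons[idx + 1]
    t_lo, t_hi = times[idx], times[idx + 1]
    return 100.0 * n_lo + 100.0 * (n_hi - n_lo) * (rt - t_lo) / (t_hi - t_lo)
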