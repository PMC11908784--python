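"""TSV table I/O with schema validation and provenance headers.

All tables are UTF-8, tab-separated, header row required, 1-based fully
closed coordinates.  Writers prepend ``#``-comment lines carrying the tool
version, seed and config hash; readers skip them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

__all__ = ["SCHEMAS", "SchemaError", "read_table", "write_table", "config_hash"]

SCHEMAS: dict[str, dict[str, type]] = {
    "pileups": {
        "site_id": str, "chrom": str, "pos": int, "ref": str, "alt": str,
        "sample_id": str, "depth_fwd": int, "depth_rev": int,
        "alt_fwd": int, "alt_rev": int,
    },
    "metadata": {
        "sample_id": str, "donor_id": str, "cell_type": str, "region": str,
        "age": float, "sex": str, "status": str, "panel_mb": float,
    },
    "truth": {
        "donor_id": str, "sample_ids": str, "site_id": str, "chrom": str,
        "pos": int, "ref": str, "alt": str, "gene": str, "true_vaf": float,
        "category": str, "pathogenic_flag": bool, "cell_type": str,
    },
    "calls": {
        "site_id": str, "chrom": str, "pos": int, "ref": str, "alt": str,
        "sample_id": str, "vaf": float, "alt_reads": int, "depth": int,
        "alt_fwd": int, "alt_rev": int,
    },
    "sites": {
        "site_id": str, "chrom": str, "pos": int, "ref": str, "alt": str, "gene": str,
    },
    "pathogenicity": {
        "gene": str, "protein_change": str, "chrom": str, "pos": int,
        "ref": str, "alt": str, "clinvar_label": str, "oncokb_label": str,
    },
    "pop_af": {"chrom": str, "pos": int, "ref": str, "alt": str, "af": float},
    "indels": {"chrom": str, "pos": int},
}


class SchemaError(ValueError):
    pass


def read_table(path, schema: str | dict | None = None, *, allow_empty: bool = False) -> pd.DataFrame:
    """Read a TSV table, validating against a named schema.

    Raises :class:`SchemaError` naming the file, the missing column, or the
    first offending row for type violations.
    """
    path = Path(path)
    cols = SCHEMAS[schema] if isinstance(schema, str) else schema
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype="object")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty (no header)")
    if cols is None:
        return df
    for name in cols:
        if name not in df.columns:
            raise SchemaError(f"{path}: missing required column {name!r}")
    if df.empty and not allow_empty:
        raise SchemaError(f"{path}: no data rows")
    for name, typ in cols.items():
        if typ in (int, float):
            coerced = pd.to_numeric(df[name], errors="coerce")
            bad = coerced.isna() & df[name].notna()
            if bad.any():
                row = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based incl. header
                raise SchemaError(
                    f"{path}: column {name!r} row {row}: "
                    f"cannot parse {df[name][bad].iloc[0]!r} as {typ.__name__}"
                )
            df[name] = coerced.astype(typ) if typ is int and not coerced.isna().any() else coerced
        elif typ is bool:
            df[name] = df[name].astype(str).str.strip().str.lower().isin({"true", "1", "yes"})
        else:
            df[name] = df[name].astype(str)
    if "pos" in cols and len(df) and (df["pos"] < 1).any():
        row = int(np.nonzero((df["pos"] < 1).to_numpy())[0][0]) + 2
        raise SchemaError(f"{path}: column 'pos' row {row}: coordinates are 1-based")
    return df


def config_hash(config) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, *, seed=None, cfg_hash: str | None = None) -> None:
    """Write a TSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# mosaicall {__version__}")
        if seed is not None:
            fh.write(f" seed={seed}")
        if cfg_hash is not None:
            fh.write(f" config={cfg_hash}")
        fh.write("\n")
        df.to_csv(fh, sep="\t", index=False)
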