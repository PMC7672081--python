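"""Flat-file readers/writers and schema validation for the screening pipeline.

All pipeline tables are plain TSV (CSV accepted) with a configurable
column-name mapping, so synthetic panels and real exports (whose headers
vary between releases) share one reader. Validated tables are ordinary
pandas DataFrames with canonical column names.

Canonical tables
----------------
coding_variants : gene, cell_line, classification, sift, polyphen
copy_number     : gene, cell_line, category
dose_response   : drug, cell_line, ln_ic50, source
drug_meta       : drug, name, target_class, commercial
cell_line_meta  : cell_line, tissue1, tissue2
cohort_variants : patient, gene, variant_classification   (MAF-like)
clinical        : patient, age, sex, cancer_type, drugs, os_months, event
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger("scscreen")


class SchemaError(ValueError):
    """A required column is absent from an input file."""


class ValidationError(ValueError):
    """A validated invariant (uniqueness, range, vocabulary) is violated."""


#: canonical column sets, in output order
TABLE_COLUMNS: dict[str, list[str]] = {
    "coding_variants": ["gene", "cell_line", "classification", "sift", "polyphen"],
    "copy_number": ["gene", "cell_line", "category"],
    "dose_response": ["drug", "cell_line", "ln_ic50", "source"],
    "drug_meta": ["drug", "name", "target_class", "commercial"],
    "cell_line_meta": ["cell_line", "tissue1", "tissue2"],
    "cohort_variants": ["patient", "gene", "variant_classification"],
    "clinical": ["patient", "age", "sex", "cancer_type", "drugs", "os_months", "event"],
}

#: per-table unique-key constraints
TABLE_KEYS: dict[str, list[str]] = {
    "dose_response": ["drug", "cell_line", "source"],
    "drug_meta": ["drug"],
    "cell_line_meta": ["cell_line"],
    "clinical": ["patient"],
}

#: default header mapping for MAF-like cohort variant files
MAF_SCHEMA = {
    "patient": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "variant_classification": "Variant_Classification",
}

#: closed vocabulary for cell-line coding variants; raw labels outside it are
#: kept verbatim and flagged, never silently reclassified
CODING_CLASSES = {"stop-loss", "nonsense", "missense", "other"}


def _read_raw(path, sep: str | None) -> pd.DataFrame:
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)


def _apply_schema(df: pd.DataFrame, table: str, schema: Mapping[str, str] | None) -> pd.DataFrame:
    mapping = dict(schema or {})
    if table == "cohort_variants" and not mapping:
        mapping = MAF_SCHEMA
    rename = {}
    for canon in TABLE_COLUMNS[table]:
        src = mapping.get(canon, canon)
        if src not in df.columns:
            raise SchemaError(f"{table}: required column {src!r} (for field {canon!r}) not found")
        rename[src] = canon
    return df.rename(columns=rename)[TABLE_COLUMNS[table]]


def _validate(df: pd.DataFrame, table: str) -> pd.DataFrame:
    df = df.copy()
    if table == "coding_variants":
        for col in ("sift", "polyphen"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].dropna()
            if ((bad < 0) | (bad > 1)).any():
                raise ValidationError(f"coding_variants: {col} outside [0, 1]")
        unknown = set(df["classification"]) - CODING_CLASSES
        if unknown:
            log.warning("coding_variants: %d non-canonical classification labels: %s",
                        len(unknown), sorted(unknown)[:10])
    elif table == "dose_response":
        df["ln_ic50"] = pd.to_numeric(df["ln_ic50"])
        if not np.isfinite(df["ln_ic50"]).all():
            raise ValidationError("dose_response: non-finite ln_ic50")
    elif table == "drug_meta":
        df["commercial"] = df["commercial"].map(_parse_bool)
    elif table == "clinical":
        df["age"] = pd.to_numeric(df["age"])
        df["os_months"] = pd.to_numeric(df["os_months"])
        df["event"] = df["event"].map(_parse_bool)
        if (df["os_months"] < 0).any():
            raise ValidationError("clinical: negative os_months")
    key = TABLE_KEYS.get(table)
    if key:
        dup = df.duplicated(subset=key, keep=False)
        if dup.any():
            offenders = df.loc[dup, key].head(10).to_dict("records")
            raise ValidationError(f"{table}: duplicate keys on {key}: {offenders}")
    log.info("%s: %d rows validated", table, len(df))
    return df.reset_index(drop=True)


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    return str(x).strip().lower() in {"1", "true", "t", "yes", "y"}


def read_table(path, table: str, schema: Mapping[str, str] | None = None,
               sep: str | None = None) -> pd.DataFrame:
    """Read one file into a validated canonical table.

    Parameters
    ----------
    path : str or Path
        TSV (default) or CSV file.
    table : str
        One of ``TABLE_COLUMNS`` keys.
    schema : mapping, optional
        canonical-field -> file-column mapping; unmapped fields are looked
        up under their canonical name. MAF headers are the default for
        ``cohort_variants``.
    sep : str, optional
        Field delimiter; inferred from the extension when omitted.
    """
    if table not in TABLE_COLUMNS:
        raise ValueError(f"unknown table kind {table!r}")
    return _validate(_apply_schema(_read_raw(path, sep), table, schema), table)


def read_tables(paths: Mapping[str, str | Path],
                schema_config: Mapping[str, Mapping[str, str]] | None = None,
                sep: str | None = None) -> dict[str, pd.DataFrame]:
    """Read and validate a set of tables; keys of `paths` name the table kinds."""
    schema_config = schema_config or {}
    return {t: read_table(p, t, schema_config.get(t), sep) for t, p in paths.items()}


def write_results(df: pd.DataFrame, path, sep: str = "\t", allow_empty: bool = False) -> None:
    """Write any pipeline output table; the file round-trips field-for-field.

    An empty frame is written (header only) only when `allow_empty` is set,
    so an accidentally empty screen does not silently produce a blank file.
    """
    if len(df) == 0 and not allow_empty:
        raise ValueError("refusing to write empty table without allow_empty=True")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)


def read_results(path, sep: str = "\t") -> pd.DataFrame:
    """Read back a table written by :func:`write_results` (types re-inferred)."""
    return pd.read_csv(path, sep=sep)


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one symbol per line, '#' comments allowed."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
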