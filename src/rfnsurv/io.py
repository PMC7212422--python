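"""Readers and writers for the three tabular inputs.

Expression: TSV with gene symbols in the first column and one column per
sample, values being median Z-scores (cBioPortal style).  Mutations: a
MAF-like TSV needing only ``Hugo_Symbol`` and ``Tumor_Sample_Barcode``
columns (anything else is ignored).  Clinical: a TSV with a sample/patient
identifier, overall survival in months, and an event status column in any
of the common dialects ("DECEASED"/"LIVING", "1:DECEASED"/"0:LIVING",
1/0); header matching is case-insensitive.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .survival import SurvivalRecord

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "read_mutations",
    "read_clinical",
    "write_expression",
    "write_mutations",
    "write_clinical",
]

_ID_COLUMNS = ("sample_id", "patient_id")
_TIME_COLUMNS = ("os_months",)
_STATUS_COLUMNS = ("os_status",)


def read_expression(path) -> pd.DataFrame:
    """Gene x sample matrix of Z-scores; first column = gene symbol."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df.index.name = "gene"
    return df.astype(float)


def read_mutations(path) -> pd.DataFrame:
    """MAF-like records reduced to (Hugo_Symbol, Tumor_Sample_Barcode)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    try:
        sym = cols["hugo_symbol"]
        bar = cols["tumor_sample_barcode"]
    except KeyError as exc:
        raise ValueError(
            "mutation file needs Hugo_Symbol and Tumor_Sample_Barcode columns"
        ) from exc
    return df[[sym, bar]].rename(
        columns={sym: "Hugo_Symbol", bar: "Tumor_Sample_Barcode"}
    )


def _parse_status(value) -> bool:
    s = str(value).strip().lower()
    if s in {"deceased", "1:deceased", "1", "1.0", "dead", "true"}:
        return True
    if s in {"living", "0:living", "0", "0.0", "alive", "false"}:
        return False
    raise ValueError(f"unrecognized survival status value: {value!r}")


def read_clinical(path) -> list[SurvivalRecord]:
    """Parse a clinical TSV into survival records, accepting common dialects."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    id_col = next((cols[c] for c in _ID_COLUMNS if c in cols), None)
    time_col = next((cols[c] for c in _TIME_COLUMNS if c in cols), None)
    status_col = next((cols[c] for c in _STATUS_COLUMNS if c in cols), None)
    if id_col is None or time_col is None or status_col is None:
        raise ValueError(
            "clinical file needs SAMPLE_ID/PATIENT_ID, OS_MONTHS and OS_STATUS columns"
        )
    logger.info("clinical dialect: id=%s time=%s status=%s", id_col, time_col, status_col)
    records = []
    n_dropped = 0
    for _, row in df.iterrows():
        time = pd.to_numeric(row[time_col], errors="coerce")
        if pd.isna(time):
            n_dropped += 1
            continue
        records.append(
            SurvivalRecord(
                sample_id=str(row[id_col]),
                time=float(time),
                event=_parse_status(row[status_col]),
            )
        )
    if n_dropped:
        logger.warning("dropped %d clinical rows without a parseable OS_MONTHS", n_dropped)
    return records


def write_expression(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "Hugo_Symbol"
    out.to_csv(path, sep="\t", float_format="%.6g")


def write_mutations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_clinical(records: list[SurvivalRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("SAMPLE_ID\tOS_MONTHS\tOS_STATUS\n")
        for rec in records:
            status = "1:DECEASED" if rec.event else "0:LIVING"
            fh.write(f"{rec.sample_id}\t{rec.time:.6g}\t{status}\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
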