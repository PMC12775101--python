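"""Delimited-table persistence for every pipeline stage.

All artifacts are plain CSV; ZIP codes are always read back as strings
(they carry leading zeros) and service dates as datetimes, so a
write/read round trip is lossless for the columns the pipeline uses.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synthetic_claims import SyntheticStudy

_STR_COLS = {
    "zip", "billing_zip", "home_zip", "alt_zip", "to_zip", "to_zip2",
    "departure_zip", "plurality_zip",
}
_DATE_COLS = {
    "service_date", "biopsy_date", "birth_date", "move_date", "move_date2",
}


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    head = pd.read_csv(path, nrows=0)
    dtypes = {c: str for c in head.columns if c in _STR_COLS}
    dates = [c for c in head.columns if c in _DATE_COLS]
    df = pd.read_csv(path, dtype=dtypes, parse_dates=dates, keep_default_na=True)
    for col in ("dx",):
        if col in df.columns:
            df[col] = df[col].fillna("")
    for col in _STR_COLS & set(df.columns):
        df[col] = df[col].fillna("")
    return df


def write_study(study: SyntheticStudy, outdir) -> None:
    outdir = Path(outdir)
    write_table(study.claims, outdir / "claims.csv")
    write_table(study.patients, outdir / "patients.csv")
    write_table(study.physicians, outdir / "physicians.csv")
    write_table(study.crosswalk, outdir / "crosswalk.csv")
    for name, frame in study.truth.items():
        write_table(frame, outdir / f"truth_{name}.csv")
    (outdir / "seed.txt").write_text(f"{study.seed}\n")


def read_study_tables(indir) -> dict:
    indir = Path(indir)
    out = {}
    for name in ("claims", "patients", "physicians", "crosswalk"):
        out[name] = read_table(indir / f"{name}.csv")
    return out
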