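"""Reading, writing and validation of the tabular artifacts.

In-memory conventions (used throughout the package):

* **beta matrix** -- :class:`pandas.DataFrame`, rows indexed by probe id,
  columns by sample id, float values in [0, 1]; missing entries are NaN
  (written as empty cells).
* **sample sheet** -- DataFrame indexed by sample id with columns
  ``cohort, cell_fraction, age, sex, braak, diagnosis, batch`` and an
  optional ``true_neuron_prop`` (synthetic ground truth, bulk samples only).
  ``braak`` is an integer 0-6; Roman numerals 0/I-VI are accepted on read.
* **probe annotation** -- DataFrame indexed by probe id with columns
  ``chromosome, position, gene, region, autosomal``.

Files are UTF-8 text with the delimiter auto-detected from {tab, comma};
written output is always tab-separated.
"""

from __future__ import annotations

import numbers
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    CategoryError,
    ContractError,
    DuplicateIDError,
    FormatError,
    ParseError,
    ValueRangeError,
    ValidationError,
)

CELL_FRACTIONS = ("neuron", "glia", "bulk")
SEXES = ("female", "male")
DIAGNOSES = ("control", "ad")
REGION_CLASSES = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR", "intergenic")
AUTOSOMES = tuple(str(c) for c in range(1, 23))
CHROMOSOMES = AUTOSOMES + ("X", "Y")

_ROMAN_BRAAK = {"0": 0, "I": 1, "II": 2, "III": 3, "IV": 4, "V": 5, "VI": 6}

SHEET_COLUMNS = ["cohort", "cell_fraction", "age", "sex", "braak", "diagnosis", "batch"]


def _detect_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _check_unique(ids: Iterable, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise DuplicateIDError(f"duplicate {what} ids: {dups[:5]}")


# ---------------------------------------------------------------------------
# beta matrix


def validate_beta_matrix(beta: pd.DataFrame) -> pd.DataFrame:
    _check_unique(beta.index, "probe")
    _check_unique(beta.columns, "sample")
    vals = beta.to_numpy(dtype=float)
    bad = (vals < 0) | (vals > 1)
    if np.any(bad & ~np.isnan(vals)):
        i, j = np.argwhere(bad & ~np.isnan(vals))[0]
        raise ValueRangeError(
            f"beta value {vals[i, j]!r} outside [0, 1] at probe "
            f"{beta.index[i]!r}, sample {beta.columns[j]!r}"
        )
    return beta


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a probes x samples beta-value table (TSV/CSV, probe ids first)."""
    sep = _detect_sep(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    _check_unique(raw.index, "probe")
    _check_unique(raw.columns, "sample")
    out = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cells = raw[col].str.strip()
        num = pd.to_numeric(cells.replace("", np.nan), errors="coerce")
        bad = num.isna() & (cells != "") & ~cells.str.lower().isin(["nan", "na"])
        if bad.any():
            probe = raw.index[bad.to_numpy()][0]
            raise ParseError(
                f"non-numeric beta value {cells[bad].iloc[0]!r} at probe "
                f"{probe!r}, sample {col!r}"
            )
        out[col] = num.to_numpy()
    return validate_beta_matrix(out)


def write_beta_matrix(beta: pd.DataFrame, path) -> None:
    validate_beta_matrix(beta)
    beta.to_csv(path, sep="\t", na_rep="", index_label="probe_id")


# ---------------------------------------------------------------------------
# sample sheet


def parse_braak(token) -> int:
    """Map a Braak stage token (Arabic 0-6 or Roman 0/I-VI) to an integer."""
    if isinstance(token, numbers.Integral) and not isinstance(token, bool):
        value = int(token)
    elif isinstance(token, numbers.Real) and float(token).is_integer():
        value = int(token)
    else:
        s = str(token).strip().upper()
        if s in _ROMAN_BRAAK:
            value = _ROMAN_BRAAK[s]
        else:
            try:
                value = int(s)
            except ValueError:
                raise CategoryError(
                    f"unrecognised Braak stage {token!r}; accepted: 0-6 or 0/I-VI"
                ) from None
    if not 0 <= value <= 6:
        raise ValueRangeError(f"Braak stage {value} outside 0-6")
    return value


def _normalize_category(series: pd.Series, accepted: tuple, name: str) -> pd.Series:
    tokens = series.astype(str).str.strip().str.lower()
    bad = ~tokens.isin(accepted)
    if bad.any():
        raise CategoryError(
            f"unknown {name} token {series[bad].iloc[0]!r}; accepted: {list(accepted)}"
        )
    return tokens


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet missing required columns: {missing}")
    _check_unique(sheet.index, "sample")
    out = sheet.copy()
    out.index = out.index.astype(str)
    out.index.name = "sample_id"
    out["cohort"] = out["cohort"].astype(str)
    out["batch"] = out["batch"].astype(str)
    out["cell_fraction"] = _normalize_category(out["cell_fraction"], CELL_FRACTIONS, "cell_fraction")
    out["sex"] = _normalize_category(out["sex"], SEXES, "sex")
    out["diagnosis"] = _normalize_category(out["diagnosis"], DIAGNOSES, "diagnosis")
    out["age"] = pd.to_numeric(out["age"], errors="raise").astype(float)
    if (out["age"] < 0).any():
        raise ValueRangeError("negative age in sample sheet")
    out["braak"] = out["braak"].map(parse_braak).astype(int)
    if "true_neuron_prop" in out.columns:
        w = pd.to_numeric(out["true_neuron_prop"], errors="raise").astype(float)
        present = w.notna()
        if ((w < 0) | (w > 1)).fillna(False).any():
            raise ValueRangeError("true_neuron_prop outside [0, 1]")
        if (present & (out["cell_fraction"] != "bulk")).any():
            raise ValidationError("true_neuron_prop set on a non-bulk sample")
        out["true_neuron_prop"] = w
    return out


def read_sample_sheet(path) -> pd.DataFrame:
    sep = _detect_sep(path)
    sheet = pd.read_csv(path, sep=sep, index_col=0)
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sample_sheet(sheet).to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# probe annotation


def validate_probe_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    for col in ("chromosome", "position"):
        if col not in ann.columns:
            raise FormatError(f"probe annotation missing column {col!r}")
    _check_unique(ann.index, "probe")
    out = ann.copy()
    out.index = out.index.astype(str)
    out.index.name = "probe_id"
    chrom = out["chromosome"].astype(str).str.strip().str.upper().str.removeprefix("CHR")
    bad = ~chrom.isin(CHROMOSOMES)
    if bad.any():
        raise CategoryError(f"unknown chromosome {out['chromosome'][bad].iloc[0]!r}")
    out["chromosome"] = chrom
    pos = pd.to_numeric(out["position"], errors="raise").astype(int)
    if (pos <= 0).any():
        raise ValueRangeError("probe position must be a positive 1-based integer")
    out["position"] = pos
    if "gene" in out.columns:
        out["gene"] = out["gene"].fillna("").astype(str)
    else:
        out["gene"] = ""
    if "region" in out.columns:
        region = out["region"].fillna("").astype(str).str.strip()
        region = region.where(region != "", "intergenic")
        bad = ~region.isin(REGION_CLASSES)
        if bad.any():
            raise CategoryError(
                f"unknown region class {region[bad].iloc[0]!r}; accepted: {list(REGION_CLASSES)}"
            )
        out["region"] = region
    else:
        out["region"] = "intergenic"
    out["autosomal"] = out["chromosome"].isin(AUTOSOMES)
    return out[["chromosome", "position", "gene", "region", "autosomal"]]


def read_probe_annotation(path) -> pd.DataFrame:
    sep = _detect_sep(path)
    ann = pd.read_csv(path, sep=sep, index_col=0)
    return validate_probe_annotation(ann)


def write_probe_annotation(ann: pd.DataFrame, path) -> None:
    validate_probe_annotation(ann).to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# ranked result tables


_P_COLUMNS = ("p", "p_combined", "p_neuron", "p_glia", "fdr_q", "bonferroni_p", "se")


def write_results_table(results: pd.DataFrame, path, annotation: pd.DataFrame | None = None) -> None:
    """Write a ranked per-probe result table (single analysis or meta).

    Columns: rank, the p value(s), probe_id, chromosome, position, gene,
    region, fdr_q.  P values are written in scientific notation with four
    significant digits.  ``results`` must carry a ``rank`` column.
    """
    if "rank" not in results.columns:
        raise ContractError("results table must be ranked (missing 'rank' column)")
    out = results.copy()
    out.index.name = "probe_id"
    is_meta = "p_combined" in out.columns
    p_cols = ["p_combined", "p_neuron", "p_glia"] if is_meta else ["p"]
    stat_cols = [c for c in ("effect", "se", "statistic", "chi_sq") if c in out.columns]
    if annotation is not None:
        ann = annotation.reindex(out.index)
        for col in ("chromosome", "position", "gene", "region"):
            out[col] = ann[col]
    ann_cols = [c for c in ("chromosome", "position", "gene", "region") if c in out.columns]
    out = out.sort_values("rank").reset_index()
    cols = ["rank"] + p_cols + ["probe_id"] + stat_cols + ann_cols + ["fdr_q"]
    out = out[cols]
    for col in out.columns:
        if col in _P_COLUMNS or col in ("effect", "statistic", "chi_sq"):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.3e}")
    out.to_csv(path, sep="\t", index=False)


def read_results_table(path) -> pd.DataFrame:
    sep = _detect_sep(path)
    tbl = pd.read_csv(path, sep=sep)
    if "probe_id" in tbl.columns:
        tbl = tbl.set_index("probe_id")
    return tbl
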