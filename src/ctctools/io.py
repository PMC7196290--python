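"""CSV readers and writers for every exchange format.

All outputs are plain CSV with a leading schema comment line
(``# ctctools-schema: <name> v1``); readers skip comment lines, so files
written by hand without the header also parse.  Matrices are genes x cells
with gene ids in the first column and one header row of cell ids; the 999
undetected sentinel is written literally.
"""

from __future__ import annotations

import os
from typing import Sequence

import pandas as pd

from .concordance import MutationCallTable
from .kinetics import CTCTimeSeries, ResponseAssessment
from .matrix import CellAnnotation, CtMatrix
from .survival import SurvivalRecord

SCHEMA_VERSION = "v1"


def _write_with_header(df: pd.DataFrame, path, name: str, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ctctools-schema: {name} {SCHEMA_VERSION}\n")
        df.to_csv(fh, index=index)


def _read_csv(path, **kwargs) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    kwargs.setdefault("float_precision", "round_trip")
    return pd.read_csv(path, comment="#", **kwargs)


# -- Ct matrices ------------------------------------------------------------

def write_ct_matrix(m: CtMatrix, path, quality_path=None,
                    annotations_path=None) -> None:
    _write_with_header(m.ct, path, "ct_matrix", index=True)
    if quality_path is not None:
        _write_with_header(m.quality, quality_path, "quality_matrix", index=True)
    if annotations_path is not None and m.annotations:
        rows = [dataclass_row(a) for a in m.annotations.values()]
        _write_with_header(pd.DataFrame(rows), annotations_path,
                           "cell_annotations", index=False)


def dataclass_row(a: CellAnnotation) -> dict:
    return {
        "cell_id": a.cell_id, "source_group": a.source_group,
        "patient_id": a.patient_id or "", "timepoint_label": a.timepoint_label or "",
        "ck_epcam": _flag_str(a.ck_epcam), "cd45": _flag_str(a.cd45),
        "dapi": _flag_str(a.dapi),
    }


def _flag_str(v: bool | None) -> str:
    return "" if v is None else ("+" if v else "-")


def _none_if_blank(v) -> str | None:
    if v is None or (isinstance(v, float) and pd.isna(v)) or pd.isna(v) or v == "":
        return None
    return str(v)


def _flag_parse(v) -> bool | None:
    if pd.isna(v) or v == "":
        return None
    if v in ("+", "1", 1, True, "True"):
        return True
    if v in ("-", "0", 0, False, "False"):
        return False
    raise ValueError(f"unparseable stain flag {v!r}")


def read_annotations(path) -> dict[str, CellAnnotation]:
    df = _read_csv(path, dtype=str)
    out = {}
    for _, r in df.iterrows():
        out[r["cell_id"]] = CellAnnotation(
            cell_id=r["cell_id"],
            source_group=r["source_group"],
            patient_id=_none_if_blank(r.get("patient_id")),
            timepoint_label=_none_if_blank(r.get("timepoint_label")),
            ck_epcam=_flag_parse(r.get("ck_epcam")),
            cd45=_flag_parse(r.get("cd45")),
            dapi=_flag_parse(r.get("dapi")),
        )
    return out


def read_ct_matrix(path, quality_path=None, annotations_path=None) -> CtMatrix:
    """Parse a genes x cells Ct CSV (sentinel 999 preserved).

    Errors carry row/column context: duplicate ids, non-numeric entries and
    a quality sidecar of mismatched shape are all rejected.
    """
    df = _read_csv(path, index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric Ct entry ({exc})") from exc
    quality = None
    if quality_path is not None:
        quality = _read_csv(quality_path, index_col=0).astype(float)
        if quality.shape != df.shape:
            raise ValueError(
                f"quality matrix {quality_path} shape {quality.shape} does not "
                f"match Ct matrix {path} shape {df.shape}"
            )
        quality.index = df.index
        quality.columns = df.columns
    annotations = read_annotations(annotations_path) if annotations_path else None
    return CtMatrix(df, quality, annotations)


# -- counts / assessments ---------------------------------------------------

def write_counts(series_list: Sequence[CTCTimeSeries], path) -> None:
    rows = [
        {"patient_id": s.patient_id, "day": d.day, "raw_count": d.raw_count,
         "volume_mL": d.volume_ml, "count_per_7.5mL": d.count_75}
        for s in series_list for d in s.draws
    ]
    _write_with_header(pd.DataFrame(rows), path, "ctc_counts", index=False)


def read_counts(path) -> list[CTCTimeSeries]:
    df = _read_csv(path)
    out = []
    for pid, sub in df.groupby("patient_id", sort=False):
        out.append(CTCTimeSeries.from_counts(
            str(pid),
            [(int(r.day), float(r.raw_count), float(r.volume_mL))
             for r in sub.itertuples()],
        ))
    return out


def write_assessments(assessments: Sequence[ResponseAssessment], path) -> None:
    rows = [{"patient_id": a.patient_id, "day": a.day, "category": a.category}
            for a in assessments]
    _write_with_header(pd.DataFrame(rows), path, "recist_assessments", index=False)


def read_assessments(path) -> list[ResponseAssessment]:
    df = _read_csv(path)
    return [ResponseAssessment(str(r.patient_id), int(r.day), str(r.category))
            for r in df.itertuples()]


# -- survival ---------------------------------------------------------------

def write_survival(records: Sequence[SurvivalRecord], path) -> None:
    rows = [
        {"patient_id": r.patient_id, "time": r.time, "event": r.event,
         "endpoint": r.endpoint, "baseline_count_75": r.baseline_count_75}
        for r in records
    ]
    _write_with_header(pd.DataFrame(rows), path, "survival_records", index=False)


def read_survival(path) -> list[SurvivalRecord]:
    df = _read_csv(path)
    out = []
    for r in df.itertuples():
        count = getattr(r, "baseline_count_75", None)
        out.append(SurvivalRecord(
            patient_id=str(r.patient_id), time=float(r.time),
            event=int(r.event), endpoint=str(getattr(r, "endpoint", "OS")),
            baseline_count_75=None if pd.isna(count) else float(count),
        ))
    return out


# -- mutation calls ---------------------------------------------------------

def write_mutation_table(table: MutationCallTable, path) -> None:
    _write_with_header(table.df, path, "mutation_calls", index=False)


def read_mutation_table(path) -> MutationCallTable:
    return MutationCallTable(_read_csv(path, dtype=str))


# -- generic tables ---------------------------------------------------------

def write_table(df: pd.DataFrame, path, name: str, index: bool = False) -> None:
    """Write any result table with the standard schema header."""
    _write_with_header(df, path, name, index=index)
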