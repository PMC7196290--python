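"""Tissue-vs-CTC mutation concordance and emergent-resistance detection.

Calls are paired binary (+/−) detections per locus, once from a tumor tissue
biopsy and once from CTCs of the same sample.  A sample is concordant when
the CTC call equals the tissue call at *every* locus; the concordance rate
is reported over samples, with a per-locus breakdown for transparency.

Emergence scans patients with before-treatment (BT) and at-relapse (AR)
samples for loci that were negative in both modalities early and positive in
tissue and/or CTC late — the pattern of an acquired resistance mutation such
as EGFR T790M under TKI therapy.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import pandas as pd

REQUIRED_COLUMNS = ("sample_id", "patient_id", "stage", "locus",
                    "tissue_call", "ctc_call")
VALID_CALLS = {"+", "-"}


class MutationCallTable:
    """Long-format table of paired tissue/CTC calls.

    One row per (sample, locus); every sample must carry both calls for each
    of its loci.  ``stage`` orders longitudinal samples (e.g. BT before AR)
    and may be empty for single-timepoint patients.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True) -> None:
        df = pd.DataFrame(df).copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df["stage"] = df["stage"].fillna("").astype(str)
        self.df = df.reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self) -> None:
        if self.df.empty:
            raise ValueError("empty mutation call table")
        bad = ~self.df["tissue_call"].isin(VALID_CALLS) | ~self.df["ctc_call"].isin(VALID_CALLS)
        if bad.any():
            raise ValueError(
                f"calls must be '+' or '-': rows {self.df.index[bad].tolist()}"
            )
        dup = self.df.duplicated(subset=["sample_id", "locus"])
        if dup.any():
            raise ValueError(
                f"duplicate (sample, locus) rows: "
                f"{self.df.loc[dup, ['sample_id', 'locus']].to_records(index=False).tolist()}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"].unique())

    @property
    def loci(self) -> list[str]:
        return list(self.df["locus"].unique())

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __len__(self) -> int:
        return len(self.df)


@dataclasses.dataclass
class ConcordanceResult:
    n_samples: int
    n_concordant: int
    rate: float                       # percent
    per_locus: dict[str, float]       # percent agreement per locus


@dataclasses.dataclass(frozen=True)
class EmergenceEvent:
    patient_id: str
    locus: str
    modality: str                     # "tissue", "ctc" or "both"


def concordance_rate(table: MutationCallTable) -> ConcordanceResult:
    """Sample-level (all-loci) concordance, in percent, plus per-locus rates."""
    df = table.df
    agree = df["tissue_call"] == df["ctc_call"]
    by_sample = agree.groupby(df["sample_id"]).all()
    n = len(by_sample)
    k = int(by_sample.sum())
    per_locus = {
        locus: 100.0 * float(agree[df["locus"] == locus].mean())
        for locus in table.loci
    }
    return ConcordanceResult(
        n_samples=n, n_concordant=k, rate=100.0 * k / n, per_locus=per_locus
    )


def detect_emergent(
    table: MutationCallTable, stage_order: tuple[str, str] = ("BT", "AR")
) -> list[EmergenceEvent]:
    """Find loci that appear between an early and a late sample of a patient.

    A locus emerges when the ``stage_order[0]`` sample is negative in both
    tissue and CTC and the ``stage_order[1]`` sample is positive in either;
    the modality reports where it appeared.  Patients without both stages
    contribute nothing.
    """
    early_label, late_label = stage_order
    events: list[EmergenceEvent] = []
    for patient, sub in table.df.groupby("patient_id", sort=False):
        stages = set(sub["stage"])
        if early_label not in stages or late_label not in stages:
            continue
        early = sub[sub["stage"] == early_label].set_index("locus")
        late = sub[sub["stage"] == late_label].set_index("locus")
        for locus in early.index.intersection(late.index):
            e_t, e_c = early.loc[locus, ["tissue_call", "ctc_call"]]
            l_t, l_c = late.loc[locus, ["tissue_call", "ctc_call"]]
            if e_t == "-" and e_c == "-" and (l_t == "+" or l_c == "+"):
                if l_t == "+" and l_c == "+":
                    modality = "both"
                elif l_t == "+":
                    modality = "tissue"
                else:
                    modality = "ctc"
                events.append(EmergenceEvent(patient, locus, modality))
    return events


def table2_fixture() -> MutationCallTable:
    """The printed 15-sample EGFR call table bundled with the package.

    Thirteen patients; LP49 and LP2 each contribute a before-treatment (BT)
    and an at-relapse (AR) sample.  Each sample carries its activating locus
    (L858R or 19del) and T790M.
    """
    with resources.files("ctctools.data").joinpath("table2_egfr_calls.csv").open() as fh:
        df = pd.read_csv(fh, comment="#", dtype=str)
    return MutationCallTable(df)
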