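"""Core containers for single-cell qRT-PCR expression data.

The raw instrument output is a genes x cells matrix of cycle-threshold (Ct)
values.  A Ct value is the PCR cycle at which a transcript's fluorescence
crosses the detection threshold: lower Ct means higher expression.  Undetected
transcripts (single-cell dropout) carry the instrument sentinel 999.  Each
entry also has a quality score in [0, 1], higher is better.

Downstream transforms are tracked through explicit *stages*
(``imputed_ct`` -> ``delta_ct`` -> ``relative_expr`` and
``imputed_ct`` -> ``zscore``) so that operations applied out of order fail
loudly instead of silently producing nonsense.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

#: Instrument sentinel for an undetected transcript.
SENTINEL = 999.0

#: Largest physically plausible Ct value; real runs stop at 40-45 cycles.
CT_VALID_MAX = 45.0

#: Allowed transform stages, in pipeline order.
STAGES = ("imputed_ct", "delta_ct", "relative_expr", "zscore")


class StageError(ValueError):
    """An operation was applied to a matrix at the wrong pipeline stage."""


@dataclasses.dataclass(frozen=True)
class CellAnnotation:
    """Per-cell metadata: provenance plus immunostain flags.

    ``ck_epcam`` is the combined cytokeratin-or-EpCAM epithelial stain,
    ``cd45`` the leukocyte stain, ``dapi`` the nuclear stain.  Flags may be
    ``None`` when the cell was not stained (e.g. cultured cell lines).
    """

    cell_id: str
    source_group: str
    patient_id: str | None = None
    timepoint_label: str | None = None
    ck_epcam: bool | None = None
    cd45: bool | None = None
    dapi: bool | None = None

    def __post_init__(self) -> None:
        if self.timepoint_label is not None and self.patient_id is None:
            raise ValueError(
                f"cell {self.cell_id!r}: timepoint_label is only meaningful "
                "for patient-derived cells (patient_id is missing)"
            )


def _check_unique(values, what: str) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups}")


class CtMatrix:
    """Raw genes x cells Ct matrix with per-entry quality scores.

    Parameters
    ----------
    ct:
        DataFrame indexed by gene id with one column per cell.  Entries must
        lie in (0, 45] or be exactly the 999 sentinel.
    quality:
        Optional DataFrame of the same shape with quality scores in [0, 1].
        Defaults to all-ones (every entry trusted).
    annotations:
        Optional mapping of cell id to :class:`CellAnnotation`.
    """

    def __init__(
        self,
        ct: pd.DataFrame,
        quality: pd.DataFrame | None = None,
        annotations: Mapping[str, CellAnnotation] | None = None,
        validate: bool = True,
    ) -> None:
        self.ct = pd.DataFrame(ct).astype(float)
        if quality is None:
            quality = pd.DataFrame(
                1.0, index=self.ct.index, columns=self.ct.columns
            )
        self.quality = pd.DataFrame(quality).astype(float)
        self.annotations = dict(annotations) if annotations else {}
        if validate:
            self._validate()

    def _validate(self) -> None:
        _check_unique(self.ct.index, "gene ids")
        _check_unique(self.ct.columns, "cell ids")
        if self.quality.shape != self.ct.shape:
            raise ValueError(
                f"quality matrix shape {self.quality.shape} does not match "
                f"ct matrix shape {self.ct.shape}"
            )
        vals = self.ct.to_numpy()
        detected = vals != SENTINEL
        bad = detected & ~((vals > 0) & (vals <= CT_VALID_MAX))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"Ct value {vals[i, j]} at gene {self.ct.index[i]!r}, cell "
                f"{self.ct.columns[j]!r} is outside (0, {CT_VALID_MAX}] and "
                f"is not the {SENTINEL:.0f} sentinel"
            )
        q = self.quality.to_numpy()
        if ((q < 0) | (q > 1)).any() or not np.isfinite(q).all():
            raise ValueError("quality scores must lie in [0, 1]")
        for cid in self.annotations:
            if cid not in self.ct.columns:
                raise ValueError(f"annotation for unknown cell {cid!r}")

    # -- conveniences -----------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def n_genes(self) -> int:
        return self.ct.shape[0]

    @property
    def n_cells(self) -> int:
        return self.ct.shape[1]

    def detected_mask(self) -> pd.DataFrame:
        """Boolean frame, True where the transcript was detected."""
        return self.ct != SENTINEL

    def copy(self) -> "CtMatrix":
        return CtMatrix(
            self.ct.copy(), self.quality.copy(), dict(self.annotations),
            validate=False,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CtMatrix({self.n_genes} genes x {self.n_cells} cells)"


class ExpressionMatrix:
    """A staged transform of a :class:`CtMatrix`.

    ``stage`` records where the matrix sits in the pipeline; every operation
    checks it.  ``flags`` carries provenance notes (genes imputed from the
    global fallback, zero-variance genes, excluded cells, ...).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        stage: str,
        flags: dict | None = None,
        validate: bool = True,
    ) -> None:
        if stage not in STAGES:
            raise StageError(f"unknown stage {stage!r}; expected one of {STAGES}")
        self.values = pd.DataFrame(values).astype(float)
        self.stage = stage
        self.flags = dict(flags) if flags else {}
        if validate:
            self._validate()

    def _validate(self) -> None:
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "cell ids")
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError(f"non-finite values in stage={self.stage} matrix")
        if self.stage == "imputed_ct" and (vals == SENTINEL).any():
            raise ValueError("imputed_ct matrix still contains the 999 sentinel")
        if self.stage == "relative_expr" and not (vals > 0).all():
            raise ValueError("relative expression values must be strictly positive")
        if self.stage == "zscore" and self.values.shape[1] >= 2:
            sd = vals.std(axis=1, ddof=1)
            nondeg = sd > 1e-12
            mean = vals.mean(axis=1)
            if nondeg.any():
                if np.abs(mean[nondeg]).max() > 1e-9:
                    raise ValueError("z-scored genes must have mean 0")
                if np.abs(sd[nondeg] - 1).max() > 1e-9:
                    raise ValueError("z-scored genes must have SD 1")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)

    def require_stage(self, stage: str, op: str) -> None:
        if self.stage != stage:
            raise StageError(
                f"{op} requires a stage={stage!r} matrix, got stage={self.stage!r}"
            )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), self.stage, dict(self.flags), validate=False
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        r, c = self.values.shape
        return f"ExpressionMatrix({r} genes x {c} cells, stage={self.stage})"
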