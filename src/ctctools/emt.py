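"""Epithelial/mesenchymal (EMT) scoring of single cells.

Each cell's GAPDH-normalized relative expression (2^-ΔCt) is summed over an
epithelial marker panel (EpCAM plus the cytokeratins KRT7/18/19) and over a
mesenchymal panel (vimentin, CD44).  The M-score is the mesenchymal share of
the total, in percent:

    m_score = 100 * m_sum / (e_sum + m_sum),    e_score = 100 - m_score.

Cells are labelled epithelial / hybrid / mesenchymal by where the M-score
falls relative to a configurable hybrid band (default [40, 60]); cells with
zero total marker signal are flagged as undefined.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_EPITHELIAL = ("EPCAM", "KRT7", "KRT18", "KRT19")
DEFAULT_MESENCHYMAL = ("VIM", "CD44")
DEFAULT_HYBRID_BAND = (40.0, 60.0)


@dataclasses.dataclass(frozen=True)
class MarkerPanel:
    """Disjoint epithelial / mesenchymal marker sets plus the reference gene."""

    epithelial: tuple[str, ...] = DEFAULT_EPITHELIAL
    mesenchymal: tuple[str, ...] = DEFAULT_MESENCHYMAL
    reference_gene: str = "GAPDH"

    def __post_init__(self) -> None:
        e, m = set(self.epithelial), set(self.mesenchymal)
        if not e or not m:
            raise ValueError("both marker sets must be non-empty")
        if e & m:
            raise ValueError(f"marker sets overlap: {sorted(e & m)}")
        if self.reference_gene in e | m:
            raise ValueError("reference gene cannot be a panel marker")

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.epithelial) + tuple(self.mesenchymal)


def _check_band(band: Sequence[float]) -> tuple[float, float]:
    lo, hi = float(band[0]), float(band[1])
    if not (0.0 <= lo <= hi <= 100.0):
        raise ValueError(f"hybrid band must satisfy 0 <= lo <= hi <= 100, got {band}")
    return lo, hi


def classify_emt(m_score: float, hybrid_band: Sequence[float] = DEFAULT_HYBRID_BAND) -> str:
    """Map an M-score (percent) to an EMT label.

    Below the band -> ``"epithelial"``; above -> ``"mesenchymal"``; inside
    (inclusive) -> ``"hybrid"``; NaN -> ``"undefined"``.
    """
    lo, hi = _check_band(hybrid_band)
    if m_score is None or (isinstance(m_score, float) and np.isnan(m_score)):
        return "undefined"
    if not (0.0 <= m_score <= 100.0):
        raise ValueError(f"m_score must be a percentage in [0, 100], got {m_score}")
    if m_score < lo:
        return "epithelial"
    if m_score > hi:
        return "mesenchymal"
    return "hybrid"


class EMTScorer(TransformerMixin, BaseEstimator):
    """Transform relative expression (cells x genes) into EMT scores.

    ``transform`` returns a DataFrame indexed by cell with columns
    ``e_sum, m_sum, e_score, m_score, label``.
    """

    def __init__(self, panel: MarkerPanel | None = None,
                 hybrid_band: Sequence[float] = DEFAULT_HYBRID_BAND) -> None:
        self.panel = panel
        self.hybrid_band = hybrid_band

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        self.panel_ = self.panel if self.panel is not None else MarkerPanel()
        _check_band(self.hybrid_band)
        missing = [g for g in self.panel_.markers if g not in X.columns]
        if missing:
            raise ValueError(f"panel markers missing from matrix: {missing}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "panel_")
        X = pd.DataFrame(X).astype(float)
        missing = [g for g in self.panel_.markers if g not in X.columns]
        if missing:
            raise ValueError(f"panel markers missing from matrix: {missing}")
        e_sum = X[list(self.panel_.epithelial)].sum(axis=1)
        m_sum = X[list(self.panel_.mesenchymal)].sum(axis=1)
        total = e_sum + m_sum
        with np.errstate(invalid="ignore", divide="ignore"):
            m_score = 100.0 * m_sum / total
        m_score = m_score.mask(total <= 0)
        if (total <= 0).any():
            logger.warning("cells with zero total marker signal flagged undefined: %s",
                           list(total.index[total <= 0]))
        out = pd.DataFrame(
            {
                "e_sum": e_sum,
                "m_sum": m_sum,
                "e_score": 100.0 - m_score,
                "m_score": m_score,
            }
        )
        out["label"] = [classify_emt(v, self.hybrid_band) for v in out["m_score"]]
        return out


def compute_emt_scores(
    expr: ExpressionMatrix,
    panel: MarkerPanel | None = None,
    hybrid_band: Sequence[float] = DEFAULT_HYBRID_BAND,
) -> pd.DataFrame:
    """Score every cell of a stage=relative_expr matrix (genes x cells)."""
    expr.require_stage("relative_expr", "compute_emt_scores")
    scorer = EMTScorer(panel=panel, hybrid_band=hybrid_band)
    return scorer.fit(expr.values.T).transform(expr.values.T)


def summarize_group_scores(
    scores: pd.DataFrame, grouping: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-group mean +/- sample SD (ddof=1) of the M-score.

    ``grouping`` maps cell id -> group.  Groups of size 1 report SD as NaN
    (undefined).  Cells with undefined scores are dropped from their group.
    """
    if len(grouping) == 0:
        raise ValueError("empty grouping")
    grouping = pd.Series(dict(grouping) if not isinstance(grouping, pd.Series) else grouping)
    m = scores["m_score"].dropna()
    groups = grouping.reindex(m.index).dropna()
    if groups.empty:
        raise ValueError("no scored cells fall in any group")
    agg = m.loc[groups.index].groupby(groups).agg(
        mean_m_score="mean",
        sd_m_score=lambda s: s.std(ddof=1),
        n="size",
    )
    return agg.reset_index(names="group")
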