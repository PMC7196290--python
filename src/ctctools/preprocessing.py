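"""Single-cell qRT-PCR preprocessing.

The chain applied to a raw Ct matrix is fixed:

1. quality filter — entries with quality < 0.65 or Ct > 30 are treated as
   undetected (999 sentinel);
2. dropout imputation — each 999 becomes that gene's highest detected Ct + 1,
   i.e. "just below the worst observed expression";
3. either ΔCt -> 2^-ΔCt relative expression against the reference gene
   (GAPDH) for EMT scoring, or per-gene Z-scoring for clustering/embedding.

Each step exists both as an sklearn-style transformer operating on a
cells x genes DataFrame (so the chain composes with sklearn pipelines) and as
a thin module-level function over the staged domain containers, which enforce
pipeline order.

A rule-based immunostain classifier (`classify_event`) labels picked events
as CTC (cytokeratin/EpCAM+, CD45−, DAPI+), WBC (CD45+) or excluded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .matrix import SENTINEL, CellAnnotation, CtMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_QUALITY_MIN = 0.65
DEFAULT_CT_MAX = 30.0
DEFAULT_REFERENCE_GENE = "GAPDH"


def _as_frame(X) -> pd.DataFrame:
    X = pd.DataFrame(X)
    return X.astype(float)


# ---------------------------------------------------------------------------
# sklearn-style transformers (X is cells x genes)
# ---------------------------------------------------------------------------

class QualityFilter(TransformerMixin, BaseEstimator):
    """Mask low-confidence entries with the undetected sentinel.

    An entry is kept only if its quality score is >= ``quality_min`` *and*
    its Ct is <= ``ct_max``; everything else becomes 999.  Stateless, but
    exposed as a transformer so the chain composes.
    """

    def __init__(self, quality_min: float = DEFAULT_QUALITY_MIN,
                 ct_max: float = DEFAULT_CT_MAX) -> None:
        self.quality_min = quality_min
        self.ct_max = ct_max

    def _check_params(self) -> None:
        if not (0.0 <= self.quality_min <= 1.0):
            raise ValueError(f"quality_min must be in [0, 1], got {self.quality_min}")
        if not np.isfinite(self.ct_max):
            raise ValueError("ct_max must be finite")

    def fit(self, X, y=None):
        self._check_params()
        X = _as_frame(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, quality=None) -> pd.DataFrame:
        self._check_params()
        X = _as_frame(X)
        out = X.copy()
        drop = X > self.ct_max  # the sentinel itself is > ct_max and stays 999
        if quality is not None:
            quality = _as_frame(quality)
            if quality.shape != X.shape:
                raise ValueError(
                    f"quality shape {quality.shape} does not match Ct shape {X.shape}"
                )
            drop |= quality.to_numpy() < self.quality_min
        out[drop] = SENTINEL
        return out


class UndetectedImputer(TransformerMixin, BaseEstimator):
    """Replace 999 sentinels with each gene's highest detected Ct + 1.

    Genes with no detected value at all fall back to the *global* detected
    maximum + 1 (the per-gene rule is undefined there); those genes are
    recorded in ``all_undetected_features_`` and logged.
    """

    def fit(self, X, y=None):
        X = _as_frame(X)
        if X.size == 0:
            raise ValueError("cannot impute an empty matrix")
        detected = X.where(X != SENTINEL)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns)
        per_gene_max = detected.max(axis=0)
        global_max = detected.to_numpy()
        global_max = global_max[np.isfinite(global_max)]
        if global_max.size == 0:
            raise ValueError("matrix has no detected Ct values; nothing to impute from")
        self.global_detected_max_ = float(global_max.max())
        all_undetected = per_gene_max.isna()
        self.all_undetected_features_ = list(per_gene_max.index[all_undetected])
        if self.all_undetected_features_:
            logger.warning(
                "genes undetected in every cell imputed from the global "
                "detected max %.2f + 1: %s",
                self.global_detected_max_, self.all_undetected_features_,
            )
        self.impute_values_ = per_gene_max.fillna(self.global_detected_max_) + 1.0
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "impute_values_")
        X = _as_frame(X)
        out = X.copy()
        for gene, value in self.impute_values_.items():
            if gene in out.columns:
                col = out[gene]
                out.loc[col == SENTINEL, gene] = value
        if (out.to_numpy() == SENTINEL).any():
            raise ValueError("sentinels remain for genes unseen at fit time")
        return out


class DeltaCtTransformer(TransformerMixin, BaseEstimator):
    """Subtract the reference gene's Ct from every gene, per cell.

    ΔCt(g, c) = Ct(g, c) − Ct(reference, c); the reference column becomes 0.
    """

    def __init__(self, reference_gene: str = DEFAULT_REFERENCE_GENE) -> None:
        self.reference_gene = reference_gene

    def fit(self, X, y=None):
        X = _as_frame(X)
        if self.reference_gene not in X.columns:
            raise ValueError(f"reference gene {self.reference_gene!r} not in matrix")
        self.n_features_in_ = X.shape[1]
        self.reference_gene_ = self.reference_gene
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "reference_gene_")
        X = _as_frame(X)
        if self.reference_gene_ not in X.columns:
            raise ValueError(f"reference gene {self.reference_gene_!r} not in matrix")
        return X.sub(X[self.reference_gene_], axis=0)


class RelativeExpressionTransformer(TransformerMixin, BaseEstimator):
    """Map ΔCt to relative expression 2^-ΔCt (strictly positive)."""

    def fit(self, X, y=None):
        self.n_features_in_ = _as_frame(X).shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        return 2.0 ** (-_as_frame(X))


class CtZScorer(TransformerMixin, BaseEstimator):
    """Per-gene standardization: z = (x − mean) / sample SD (ddof=1).

    Zero-variance genes are mapped to 0 and listed in
    ``zero_variance_features_``.  Requires at least two cells.
    """

    def fit(self, X, y=None):
        X = _as_frame(X)
        if X.shape[0] < 2:
            raise ValueError("z-scoring needs at least 2 cells (SD undefined)")
        self.n_features_in_ = X.shape[1]
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        # relative tolerance: an SD at float-noise level of the gene's own
        # magnitude is indistinguishable from constant
        tol = 1e-8 * np.maximum(1.0, self.mean_.abs())
        degenerate = sd <= tol
        self.zero_variance_features_ = list(sd.index[degenerate])
        if self.zero_variance_features_:
            logger.info("zero-variance genes set to z=0: %s",
                        self.zero_variance_features_)
        self.scale_ = sd.mask(degenerate, 1.0)
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "scale_")
        X = _as_frame(X)
        z = (X - self.mean_) / self.scale_
        z[self.zero_variance_features_] = 0.0
        return z


# ---------------------------------------------------------------------------
# Staged operations over the domain containers
# ---------------------------------------------------------------------------

def apply_quality_filter(
    m: CtMatrix,
    quality_min: float = DEFAULT_QUALITY_MIN,
    ct_max: float = DEFAULT_CT_MAX,
) -> CtMatrix:
    """Return a new CtMatrix with low-quality / high-Ct entries set to 999."""
    f = QualityFilter(quality_min=quality_min, ct_max=ct_max)
    ct_t = f.fit(m.ct.T).transform(m.ct.T, quality=m.quality.T)
    return CtMatrix(ct_t.T, m.quality.copy(), dict(m.annotations), validate=False)


def impute_undetected(m: CtMatrix | ExpressionMatrix) -> ExpressionMatrix:
    """Impute 999 sentinels gene-wise (detected max + 1).

    Accepts a quality-filtered :class:`CtMatrix`, or an already-imputed
    matrix (in which case this is the identity — imputation is idempotent).
    """
    if isinstance(m, ExpressionMatrix):
        m.require_stage("imputed_ct", "impute_undetected")
        values = m.values
    else:
        values = m.ct
    imp = UndetectedImputer().fit(values.T)
    out = imp.transform(values.T).T
    flags = {"all_undetected_genes": imp.all_undetected_features_}
    return ExpressionMatrix(out, "imputed_ct", flags=flags)


def delta_ct(
    m: ExpressionMatrix, reference_gene: str = DEFAULT_REFERENCE_GENE
) -> ExpressionMatrix:
    """Ct minus reference-gene Ct per cell (reference row becomes zero)."""
    m.require_stage("imputed_ct", "delta_ct")
    t = DeltaCtTransformer(reference_gene=reference_gene).fit(m.values.T)
    out = t.transform(m.values.T).T
    flags = dict(m.flags)
    flags["reference_gene"] = reference_gene
    return ExpressionMatrix(out, "delta_ct", flags=flags)


def relative_expression(m: ExpressionMatrix) -> ExpressionMatrix:
    """2^-ΔCt relative expression."""
    m.require_stage("delta_ct", "relative_expression")
    out = RelativeExpressionTransformer().fit(m.values.T).transform(m.values.T).T
    return ExpressionMatrix(out, "relative_expr", flags=dict(m.flags))


def zscore_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene Z-scores of the imputed Ct matrix (clustering branch)."""
    m.require_stage("imputed_ct", "zscore_transform")
    scorer = CtZScorer().fit(m.values.T)
    out = scorer.transform(m.values.T).T
    flags = dict(m.flags)
    flags["zero_variance_genes"] = scorer.zero_variance_features_
    return ExpressionMatrix(out, "zscore", flags=flags)


# ---------------------------------------------------------------------------
# Immunostain event classification
# ---------------------------------------------------------------------------

def classify_event(
    ck_epcam: bool | None = None,
    cd45: bool | None = None,
    dapi: bool | None = None,
    *,
    annotation: CellAnnotation | None = None,
) -> str:
    """Label a stained event as ``"CTC"``, ``"WBC"`` or ``"excluded"``.

    CD45-positive events are white blood cells regardless of the other
    stains; CK/EpCAM-positive, CD45-negative, DAPI-positive events are CTCs;
    anything else is excluded.  All three flags must be present.
    """
    if annotation is not None:
        ck_epcam, cd45, dapi = annotation.ck_epcam, annotation.cd45, annotation.dapi
    if ck_epcam is None or cd45 is None or dapi is None:
        raise ValueError("classify_event requires ck_epcam, cd45 and dapi flags")
    if cd45:
        return "WBC"
    if ck_epcam and dapi:
        return "CTC"
    return "excluded"
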