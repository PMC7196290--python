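"""Quality filtering, dropout imputation, ΔCt / 2^-ΔCt, Z-scoring, staining rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctctools import (
    CellAnnotation,
    CtMatrix,
    ExpressionMatrix,
    SENTINEL,
    StageError,
    apply_quality_filter,
    classify_event,
    delta_ct,
    impute_undetected,
    relative_expression,
    zscore_transform,
)


def make_ct(data, genes, cells, quality=None):
    ct = pd.DataFrame(data, index=genes, columns=cells, dtype=float)
    q = None if quality is None else pd.DataFrame(quality, index=genes, columns=cells)
    return CtMatrix(ct, q)


class TestQualityFilter:
    def test_thresholds(self):
        # (Ct 29.5, q 0.9) passes; (Ct 31, q 0.9) fails Ct<=30; (Ct 25, q 0.5) fails quality
        m = make_ct([[29.5, 31.0, 25.0]], ["g"], ["a", "b", "c"],
                    quality=[[0.9, 0.9, 0.5]])
        out = apply_quality_filter(m)
        assert out.ct.loc["g", "a"] == 29.5
        assert out.ct.loc["g", "b"] == SENTINEL
        assert out.ct.loc["g", "c"] == SENTINEL

    def test_all_passing_is_identity(self, small_ct):
        clean = CtMatrix(small_ct.ct.copy())  # quality all 1
        out = apply_quality_filter(clean, ct_max=45.0)
        pd.testing.assert_frame_equal(out.ct, clean.ct)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            CtMatrix(pd.DataFrame([[20.0, 21.0]]),
                     quality=pd.DataFrame([[1.0]]))

    @given(q1=st.floats(0, 1), q2=st.floats(0, 1))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_quality_threshold(self, q1, q2):
        """Raising quality_min can only drop more entries, never fewer."""
        lo, hi = sorted([q1, q2])
        ct = pd.DataFrame([[20.0, 25.0, 29.0]], index=["g"], columns=list("abc"))
        quality = pd.DataFrame([[0.1, 0.5, 0.9]], index=["g"], columns=list("abc"))
        m = CtMatrix(ct, quality)
        dropped_lo = apply_quality_filter(m, quality_min=lo).ct.eq(SENTINEL)
        dropped_hi = apply_quality_filter(m, quality_min=hi).ct.eq(SENTINEL)
        assert (dropped_hi | dropped_lo).equals(dropped_hi)


class TestImputation:
    def test_stated_rule(self):
        m = make_ct([[25.0, 28.0, SENTINEL]], ["g"], list("abc"))
        out = impute_undetected(m)
        assert list(out.values.loc["g"]) == [25.0, 28.0, 29.0]
        assert out.stage == "imputed_ct"

    def test_fully_detected_row_unchanged(self):
        m = make_ct([[25.0, 28.0, 26.0]], ["g"], list("abc"))
        out = impute_undetected(m)
        assert list(out.values.loc["g"]) == [25.0, 28.0, 26.0]

    def test_all_undetected_gene_uses_global_max(self):
        # gene2 has no detected values; global detected max is 30.2
        m = make_ct([[30.2, 24.0], [SENTINEL, SENTINEL]], ["g1", "g2"], ["a", "b"])
        out = impute_undetected(m)
        assert list(out.values.loc["g2"]) == [31.2, 31.2]
        assert out.flags["all_undetected_genes"] == ["g2"]

    def test_idempotent_and_sentinel_free(self, small_ct):
        once = impute_undetected(apply_quality_filter(small_ct))
        twice = impute_undetected(once)
        pd.testing.assert_frame_equal(once.values, twice.values)
        assert not (once.values == SENTINEL).any().any()

    def test_max_imputed_is_detected_max_plus_one(self, rng):
        ct = rng.uniform(15, 30, size=(6, 20))
        drop = rng.random(ct.shape) < 0.3
        ct[drop] = SENTINEL
        m = make_ct(ct, [f"g{i}" for i in range(6)], [f"c{j}" for j in range(20)])
        out = impute_undetected(m)
        for i, g in enumerate(m.gene_ids):
            det = ct[i][ct[i] != SENTINEL]
            if det.size and drop[i].any():
                assert out.values.loc[g].max() == pytest.approx(det.max() + 1)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            impute_undetected(CtMatrix(pd.DataFrame()))


class TestDeltaCtAndRelative:
    def test_closed_forms(self):
        m = make_ct([[20.0], [25.0]], ["GAPDH", "EPCAM"], ["a"])
        d = delta_ct(impute_undetected(m), "GAPDH")
        assert d.values.loc["EPCAM", "a"] == 5.0
        assert d.values.loc["GAPDH", "a"] == 0.0
        r = relative_expression(d)
        assert r.values.loc["EPCAM", "a"] == pytest.approx(0.03125)
        assert r.values.loc["GAPDH", "a"] == 1.0

    def test_negative_delta_doubles(self):
        m = ExpressionMatrix(pd.DataFrame([[-1.0]], index=["g"], columns=["a"]),
                             "delta_ct")
        assert relative_expression(m).values.iloc[0, 0] == 2.0

    def test_matches_elementwise_subtraction_oracle(self, rng):
        vals = rng.uniform(15, 30, size=(5, 5))
        genes = ["GAPDH"] + [f"g{i}" for i in range(4)]
        m = ExpressionMatrix(pd.DataFrame(vals, index=genes,
                                          columns=[f"c{j}" for j in range(5)]),
                             "imputed_ct")
        d = delta_ct(m, "GAPDH")
        expected = vals - vals[0][None, :]
        assert np.allclose(d.values.to_numpy(), expected)

    def test_missing_reference_rejected(self):
        m = make_ct([[25.0]], ["EPCAM"], ["a"])
        with pytest.raises(ValueError, match="GAPDH"):
            delta_ct(impute_undetected(m), "GAPDH")


class TestZScore:
    def test_closed_form_and_invariant(self, rng):
        m = ExpressionMatrix(pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"],
                                          columns=list("abc")), "imputed_ct")
        z = zscore_transform(m)
        assert list(z.values.loc["g"]) == [-1.0, 0.0, 1.0]  # ddof=1 convention
        vals = rng.normal(25, 3, size=(4, 30))
        z2 = zscore_transform(ExpressionMatrix(
            pd.DataFrame(vals, index=list("wxyz"),
                         columns=[f"c{j}" for j in range(30)]), "imputed_ct"))
        assert np.allclose(z2.values.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z2.values.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_constant_gene_maps_to_zero(self):
        m = ExpressionMatrix(pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]],
                                          index=["flat", "g"], columns=list("abc")),
                             "imputed_ct")
        z = zscore_transform(m)
        assert (z.values.loc["flat"] == 0).all()
        assert z.flags["zero_variance_genes"] == ["flat"]

    def test_single_cell_rejected(self):
        m = ExpressionMatrix(pd.DataFrame([[5.0]], index=["g"], columns=["a"]),
                             "imputed_ct")
        with pytest.raises(ValueError, match="2 cells"):
            zscore_transform(m)


class TestStageGuards:
    def test_wrong_stage_errors(self):
        d = ExpressionMatrix(pd.DataFrame([[1.0, 2.0]], index=["g"],
                                          columns=["a", "b"]), "delta_ct")
        with pytest.raises(StageError):
            zscore_transform(d)
        with pytest.raises(StageError):
            delta_ct(d, "g")
        imputed = ExpressionMatrix(pd.DataFrame([[1.0, 2.0]], index=["g"],
                                                columns=["a", "b"]), "imputed_ct")
        with pytest.raises(StageError):
            relative_expression(imputed)


class TestClassifyEvent:
    @pytest.mark.parametrize(
        "ck, cd45, dapi, expected",
        [
            (True, False, True, "CTC"),
            (True, True, True, "WBC"),
            (False, True, False, "WBC"),
            (False, False, False, "excluded"),
            (True, False, False, "excluded"),   # no nucleus
            (False, False, True, "excluded"),   # no epithelial stain
        ],
    )
    def test_rule(self, ck, cd45, dapi, expected):
        assert classify_event(ck, cd45, dapi) == expected

    def test_missing_flag_rejected(self):
        with pytest.raises(ValueError):
            classify_event(True, None, True)
        ann = CellAnnotation("c", "patient CTC", patient_id="LP1",
                             ck_epcam=True, cd45=False, dapi=True)
        assert classify_event(annotation=ann) == "CTC"
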