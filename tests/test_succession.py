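"""Core-ASV filtering, block scaling, row ordering and colonizer classes."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microsucc import metrics, succession
from microsucc.errors import SchemaError


def _recol_meta(n_rep=2):
    """Polyp metadata: 3 inocula x 4 timepoints x n_rep replicates."""
    rows, ids = [], []
    for inoc in ("bL", "bJ", "bA"):
        for tp in (2, 7, 14, 28):
            for r in range(1, n_rep + 1):
                ids.append(f"{inoc}_{tp}_{r}")
                rows.append(("polyp", inoc, tp, r))
    return pd.DataFrame(
        rows, index=ids, columns=["substrate", "inoculum", "timepoint", "replicate"]
    )


def _uniform_rel(meta, values: dict[str, dict[int, float]]):
    """Relative-abundance table where ASV a has values[a][timepoint] in every
    sample of that timepoint; a filler ASV absorbs the remainder."""
    asvs = list(values)
    data = {}
    for sid in meta.index:
        tp = meta.loc[sid, "timepoint"]
        col = [values[a].get(tp, 0.0) for a in asvs]
        data[sid] = col + [1.0 - sum(col)]
    return pd.DataFrame(data, index=asvs + ["filler"]).T


class TestFilterCoreAsvs:
    def test_constant_at_one_timepoint_is_retained(self):
        meta = _recol_meta()
        rel = _uniform_rel(meta, {"a": {2: 0.01}})
        assert "a" in succession.filter_core_asvs(rel, meta)

    def test_missing_from_one_sample_is_dropped(self):
        meta = _recol_meta()
        rel = _uniform_rel(meta, {"a": {2: 0.01}})
        rel.loc[meta.index[0], "a"] = 0.0  # absent from a single 2 dpr sample
        rel.loc[meta.index[0], "filler"] += 0.01
        assert "a" not in succession.filter_core_asvs(rel, meta)

    def test_below_floor_everywhere_is_dropped(self):
        meta = _recol_meta()
        rel = _uniform_rel(meta, {"a": {2: 4e-5, 7: 4e-5, 14: 4e-5, 28: 4e-5}})
        assert "a" not in succession.filter_core_asvs(rel, meta)

    def test_missing_timepoint_is_error(self):
        meta = _recol_meta()
        keep = meta["timepoint"] != 28
        rel = _uniform_rel(meta, {"a": {2: 0.01}})
        with pytest.raises(SchemaError, match="28"):
            succession.filter_core_asvs(rel.loc[keep[keep].index], meta.loc[keep])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=0.02))
    def test_monotone_in_threshold(self, floor):
        meta = _recol_meta()
        rng = np.random.default_rng(0)
        raw = rng.random((len(meta), 6)) * 0.02
        rel = pd.DataFrame(raw, index=meta.index,
                           columns=[f"a{i}" for i in range(6)])
        low = set(succession.filter_core_asvs(rel, meta, min_abund=floor))
        high = set(succession.filter_core_asvs(rel, meta, min_abund=floor * 2))
        assert high <= low

    def test_default_experiment_retains_most_planted_taxa(self, default_exp):
        table = default_exp.table.subset_substrate("polyp", keep_inoculum=True)
        rel = metrics.relative_abundance(table)
        kept = succession.filter_core_asvs(rel, table.meta)
        assert len(kept) >= 0.8 * default_exp.truth.n_taxa


class TestScaleBlocks:
    def test_block_maximum_becomes_one(self):
        meta = _recol_meta()
        rel = _uniform_rel(meta, {"a": {2: 0.02, 7: 0.01}})
        scaled, block = succession.scale_blocks(rel, meta, ["a"])
        for b in ("bL", "bJ", "bA"):
            cols = scaled.columns[(block == b).to_numpy()]
            tp = meta.loc[cols, "timepoint"]
            sub = scaled.loc["a", cols]
            assert sub[tp[tp == 2].index].iloc[0] == pytest.approx(1.0)
            assert sub[tp[tp == 7].index].iloc[0] == pytest.approx(0.5)

    def test_all_zero_rows_stay_zero(self):
        meta = _recol_meta()
        rel = _uniform_rel(meta, {"a": {2: 0.01}, "b": {}})
        scaled, _ = succession.scale_blocks(rel, meta, ["a", "b"])
        assert (scaled.loc["b"] == 0).all()

    def test_nonzero_rows_attain_max_one_per_block(self, default_exp):
        table = default_exp.table.subset_substrate("polyp", keep_inoculum=True)
        rel = metrics.relative_abundance(table)
        scaled, block = succession.scale_blocks(rel, table.meta)
        for b in block.unique():
            cols = scaled.columns[(block == b).to_numpy()]
            mx = scaled[cols].max(axis=1)
            assert np.allclose(mx[mx > 0], 1.0)


class TestOrderRows:
    def test_identical_rows_are_adjacent(self):
        mat = pd.DataFrame(
            [[1, 0, 0], [0, 1, 1], [1, 0, 0], [0.5, 0.4, 0.3]],
            index=["x", "y", "x2", "z"],
        )
        order = succession.order_rows(mat)
        assert abs(order.index("x") - order.index("x2")) == 1

    def test_planted_blocks_stay_contiguous(self, rng):
        a = rng.normal(0, 0.05, size=(5, 6)) + np.array([1, 1, 1, 0, 0, 0])
        b = rng.normal(0, 0.05, size=(5, 6)) + np.array([0, 0, 0, 1, 1, 1])
        mat = pd.DataFrame(np.vstack([a, b]),
                           index=[f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)])
        order = succession.order_rows(mat)
        labels = [name[0] for name in order]
        assert labels == sorted(labels) or labels == sorted(labels, reverse=True)

    def test_deterministic(self, default_exp):
        table = default_exp.table.subset_substrate("polyp", keep_inoculum=True)
        rel = metrics.relative_abundance(table)
        scaled, _ = succession.scale_blocks(rel, table.meta)
        assert succession.order_rows(scaled) == succession.order_rows(scaled)


class TestClassifyColonizers:
    def _profile(self, per_tp: dict[int, float]):
        meta = _recol_meta()
        rel = _uniform_rel(meta, {"a": per_tp})
        scaled, block = succession.scale_blocks(rel, meta, ["a"])
        return scaled, meta

    def test_peak_at_two_dpr_is_early(self):
        scaled, meta = self._profile({2: 0.9, 7: 0.7, 14: 0.2, 28: 0.1})
        assert succession.classify_colonizers(scaled, meta)["a"] == "early"

    def test_rising_profile_is_late(self):
        scaled, meta = self._profile({2: 0.0, 7: 0.1, 14: 0.4, 28: 0.9})
        assert succession.classify_colonizers(scaled, meta)["a"] == "late"

    def test_tie_breaks_toward_earlier_timepoint(self):
        scaled, meta = self._profile({2: 0.5, 7: 0.5, 14: 0.5, 28: 0.5})
        assert succession.classify_colonizers(scaled, meta)["a"] == "early"

    def test_absent_asv_excluded_with_warning(self):
        meta = _recol_meta()
        rel = _uniform_rel(meta, {"a": {2: 0.01}, "gone": {}})
        scaled, _ = succession.scale_blocks(rel, meta, ["a", "gone"])
        with pytest.warns(UserWarning, match="gone"):
            classes = succession.classify_colonizers(scaled, meta)
        assert "gone" not in classes

    def test_invariant_to_positive_scaling_of_an_asv(self):
        """Block scaling removes magnitude, so multiplying one ASV's raw
        trajectory by a constant cannot change its class."""
        meta = _recol_meta()
        rel = _uniform_rel(meta, {"a": {2: 0.01, 7: 0.004, 14: 0.002, 28: 0.001}})
        rel2 = rel.copy()
        rel2["a"] *= 37.0
        s1, _ = succession.scale_blocks(rel, meta, ["a"])
        s2, _ = succession.scale_blocks(rel2, meta, ["a"])
        assert succession.classify_colonizers(s1, meta) == \
            succession.classify_colonizers(s2, meta)

    def test_recovers_planted_classes(self, default_exp):
        """>= 90 % agreement with planted early/late classes at defaults."""
        table = default_exp.table.subset_substrate("polyp", keep_inoculum=True)
        rel = metrics.relative_abundance(table)
        prof = succession.succession_profile(rel, table.meta)
        truth = default_exp.truth.class_of
        scored = [
            int(truth[a] == c)
            for a, c in prof.class_of.items()
            if truth[a] in ("early", "late")
        ]
        assert len(scored) >= 20
        assert np.mean(scored) >= 0.9

    def test_class_override_is_applied(self, default_exp):
        table = default_exp.table.subset_substrate("polyp", keep_inoculum=True)
        rel = metrics.relative_abundance(table)
        prof = succession.succession_profile(rel, table.meta)
        asv = prof.asv_ids[0]
        flipped = "late" if prof.class_of[asv] == "early" else "early"
        prof2 = succession.succession_profile(
            rel, table.meta, class_override={asv: flipped}
        )
        assert prof2.class_of[asv] == flipped
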