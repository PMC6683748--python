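"""Two-step normalization, clustering, cluster-to-pattern assignment, QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clemux.barcode import (
    apply_overrides,
    assign_cluster_identities,
    classify_cells,
    cluster_barcodes,
    normalize_channels,
    normalize_per_cell,
    qc_report,
    read_calls,
)
from clemux.synthetic import BarcodePattern, ChannelPanel, enumerate_patterns

CH = ["b", "g", "r"]


def _table(values, channels=CH):
    values = np.atleast_2d(values)
    df = pd.DataFrame(values, columns=channels[: values.shape[1]])
    df.insert(0, "id", range(len(df)))
    df.insert(1, "n_px", 100)
    return df


def _ideal_table(patterns, copies, jitter=0.0, seed=0):
    """Raw intensities proportional to bits, distinct per-cell brightness."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in patterns:
        for _ in range(copies):
            b = rng.uniform(80, 150)
            rows.append([b * bit + 10 + jitter * rng.normal() for bit in p.bits])
    return _table(np.array(rows), channels=[f"c{i}" for i in range(len(patterns[0].bits))])


class TestNormalizeChannels:
    def test_hand_computed_example(self):
        # one channel [10..50]: min 10, Q1 20, Q3 40 -> N = (I-10)/20
        df = _table(np.array([[10, 20, 30, 40, 50]]).T.repeat(3, axis=1))
        norm, meta = normalize_channels(df, CH)
        assert norm["b"].tolist() == [0.0, 0.5, 1.0, 1.5, 2.0]
        assert meta.loc["b", ["min", "q1", "q3"]].tolist() == [10.0, 20.0, 40.0]

    def test_argmin_cell_maps_to_zero(self):
        df = _table(np.random.default_rng(1).uniform(5, 50, size=(10, 3)))
        norm, _ = normalize_channels(df, CH)
        for c in CH:
            assert norm[c].min() == 0.0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        st.floats(0.1, 50.0),
        st.floats(-100.0, 100.0),
        st.integers(0, 2**31 - 1),
    )
    def test_affine_invariance(self, a, b, seed):
        raw = np.random.default_rng(seed).uniform(0, 200, size=(12, 3))
        n1, _ = normalize_channels(_table(raw), CH)
        n2, _ = normalize_channels(_table(a * raw + b), CH)
        assert np.allclose(n1[CH].to_numpy(), n2[CH].to_numpy(), atol=1e-8)

    def test_uninformative_channel_named_in_error(self):
        raw = np.random.default_rng(2).uniform(0, 50, size=(8, 3))
        raw[:, 1] = 42.0
        with pytest.raises(ValueError, match="'g'"):
            normalize_channels(_table(raw), CH)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            normalize_channels(_table(np.ones((3, 3)) * [[1], [2], [3]]), CH)


class TestNormalizePerCell:
    def test_division_by_max_channel(self):
        df = _table([[2.0, 0.5, 1.0]])
        out, bad = normalize_per_cell(df, CH)
        assert out.loc[0, CH].tolist() == [1.0, 0.25, 0.5]
        assert bad == []

    def test_all_zero_cell_unclassifiable(self):
        df = _table([[0.0, 0.0, 0.0], [1.0, 2.0, 0.5]])
        out, bad = normalize_per_cell(df, CH)
        assert bad == [0]
        assert np.isnan(out.loc[0, CH]).all()

    def test_every_row_max_is_one(self):
        raw = np.random.default_rng(3).uniform(0.1, 5, size=(20, 3))
        out, bad = normalize_per_cell(_table(raw), CH)
        assert bad == []
        assert np.allclose(out[CH].max(axis=1), 1.0)


class TestClustering:
    def test_ideal_clusters_pure(self):
        pats = enumerate_patterns(ChannelPanel(("a", "b", "c")))
        f = _table(
            np.repeat([p.vector for p in pats], 50, axis=0),
            channels=["c0", "c1", "c2"],
        )
        labels, centroids = cluster_barcodes(f, ["c0", "c1", "c2"], k=7, seed=0)
        # each of the 7 ideal positions is one pure cluster
        for i in range(0, 350, 50):
            assert len(set(labels[i : i + 50])) == 1
        assert len(set(labels[::50])) == 7

    def test_k_one_centroid_is_mean(self):
        x = np.random.default_rng(4).uniform(0, 1, size=(30, 2))
        f = _table(x, channels=["u", "v"])
        labels, centroids = cluster_barcodes(f, ["u", "v"], k=1, seed=0)
        assert set(labels) == {0}
        assert np.allclose(centroids[0], x.mean(axis=0))

    def test_k_exceeding_cells_rejected(self):
        f = _table(np.eye(3), channels=CH)
        with pytest.raises(ValueError, match="exceeds"):
            cluster_barcodes(f, CH, k=5, seed=0)


class TestAssignIdentities:
    def test_exact_centroids_identity_matching(self):
        pats = enumerate_patterns(ChannelPanel(("a", "b")))
        centroids = np.array([p.vector for p in pats])
        mapping = assign_cluster_identities(centroids, pats)
        assert [str(mapping[i]) for i in range(3)] == [str(p) for p in pats]

    def test_stable_under_small_perturbation(self):
        pats = enumerate_patterns(ChannelPanel(("a", "b", "c")))
        ideals = np.array([p.vector for p in pats])
        # minimum ideal-ideal distance is 1 (one bit flip at max 1)
        rng = np.random.default_rng(5)
        noise = rng.uniform(-0.2, 0.2, size=ideals.shape)
        mapping = assign_cluster_identities(ideals + noise, pats)
        assert [str(mapping[i]) for i in range(7)] == [str(p) for p in pats]

    def test_permutation_equivariance(self):
        pats = enumerate_patterns(ChannelPanel(("a", "b", "c")))
        centroids = np.array([p.vector for p in pats]) + 0.05
        m1 = assign_cluster_identities(centroids, pats)
        perm = np.array([3, 1, 4, 0, 6, 2, 5])
        m2 = assign_cluster_identities(centroids[perm], pats)
        for new_idx, old_idx in enumerate(perm):
            assert m2[new_idx] == m1[old_idx]

    def test_count_mismatch_rejected(self):
        pats = enumerate_patterns(ChannelPanel(("a", "b")))
        with pytest.raises(ValueError, match="bijection"):
            assign_cluster_identities(np.zeros((2, 2)), pats)


class TestClassifyCells:
    def test_noiseless_ideal_data_fully_correct(self):
        pats = enumerate_patterns(ChannelPanel(("a", "b", "c", "d")))
        table = _ideal_table(pats, copies=10, jitter=0.0, seed=6)
        truth = [str(p) for p in pats for _ in range(10)]
        calls = classify_cells(
            table, [f"c{i}" for i in range(4)], pats, seed=1,
            low_confidence_quantile=1.0,
        )
        assert (calls["pattern"] == truth).all()
        assert (calls["flags"] == "ok").all()

    def test_all_zero_cells_flagged_not_fatal(self):
        pats = enumerate_patterns(ChannelPanel(("a", "b", "c")))
        table = _ideal_table(pats, copies=8, seed=7)
        ch = ["c0", "c1", "c2"]
        zero = table.copy().iloc[:5]
        zero["id"] = range(1000, 1005)
        zero[ch] = table[ch].min().min()  # at the channel minima: N = 0
        full = pd.concat([table, zero], ignore_index=True)
        calls = classify_cells(full, ch, pats, seed=2, low_confidence_quantile=1.0)
        flagged = calls[calls["id"] >= 1000]
        assert (flagged["flags"] == "unclassifiable").all()
        rest = calls[calls["id"] < 1000]
        truth = [str(p) for p in pats for _ in range(8)]
        assert (rest["pattern"] == truth).all()

    def test_rescaling_equivariance(self):
        """Affine rescaling of any raw channel leaves every call unchanged."""
        pats = enumerate_patterns(ChannelPanel(("a", "b", "c")))
        ch = ["c0", "c1", "c2"]
        table = _ideal_table(pats, copies=20, jitter=3.0, seed=8)
        scaled = table.copy()
        scaled["c1"] = scaled["c1"] * 7.3 + 55.0
        c1 = classify_cells(table, ch, pats, seed=3)
        c2 = classify_cells(scaled, ch, pats, seed=3)
        assert (c1["pattern"] == c2["pattern"]).all()

    def test_row_order_invariance(self):
        pats = enumerate_patterns(ChannelPanel(("a", "b", "c")))
        ch = ["c0", "c1", "c2"]
        table = _ideal_table(pats, copies=15, jitter=3.0, seed=9)
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        c1 = classify_cells(table, ch, pats, seed=4).set_index("id")
        c2 = classify_cells(shuffled, ch, pats, seed=4).set_index("id")
        assert (c1["pattern"] == c2.loc[c1.index, "pattern"]).all()


class TestOverridesAndQC:
    def _calls(self):
        return pd.DataFrame(
            {
                "id": range(5),
                "cluster": [0, 1, 0, 1, 0],
                "pattern": ["10", "01", "10", "01", "10"],
                "distance": [0.1] * 5,
                "flags": ["ok"] * 5,
            }
        )

    def test_exclude_override(self):
        out = apply_overrides(
            self._calls(), pd.DataFrame({"id": [1, 3], "action": ["exclude"] * 2})
        )
        assert (out.loc[out["id"].isin([1, 3]), "flags"] == "excluded;manual_override").all()
        assert (out.loc[~out["id"].isin([1, 3]), "flags"] == "ok").all()

    def test_reassign_override(self):
        out = apply_overrides(
            self._calls(), pd.DataFrame({"id": [0], "action": ["reassign:11"]})
        )
        assert out.loc[out["id"] == 0, "pattern"].item() == "11"
        assert out.loc[out["id"] == 0, "flags"].item() == "manual_override"

    def test_unknown_id_and_action_rejected(self):
        with pytest.raises(ValueError, match="unknown cell id"):
            apply_overrides(self._calls(), pd.DataFrame({"id": [99], "action": ["exclude"]}))
        with pytest.raises(ValueError, match="unknown override action"):
            apply_overrides(self._calls(), pd.DataFrame({"id": [0], "action": ["drop"]}))

    def test_qc_report_deterministic_and_complete(self, tmp_path):
        rng = np.random.default_rng(10)
        lm = rng.uniform(0, 100, size=(2, 64, 64)).astype(np.float32)
        from clemux.segmentation import CellRecord

        cells = [
            CellRecord(id=i, centroid=(16.0 + 10 * i, 32.0), outline=np.empty((0, 2)),
                       area_px=100, area_um2=1.0, circularity=0.9)
            for i in range(4)
        ]
        calls = pd.DataFrame(
            {
                "id": range(4),
                "cluster": [0, 0, 1, 1],
                "pattern": ["01", "01", "10", "10"],
                "distance": [0.1, 0.2, 0.1, 0.2],
                "flags": ["ok"] * 4,
            }
        )
        out1 = qc_report(calls, lm, cells, tmp_path / "a")
        qc_report(calls, lm, cells, tmp_path / "b")
        assert (tmp_path / "a" / "calls.csv").read_bytes() == (
            tmp_path / "b" / "calls.csv"
        ).read_bytes()
        for name in ("gallery_01.png", "gallery_10.png"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
        assert len(out1) == 4
        back = read_calls(tmp_path / "a" / "calls.csv")
        assert back["pattern"].tolist() == ["01", "01", "10", "10"]

    def test_qc_report_applies_overrides(self, tmp_path):
        lm = np.zeros((1, 32, 32), dtype=np.float32)
        from clemux.segmentation import CellRecord

        cells = [
            CellRecord(id=i, centroid=(16.0, 16.0), outline=np.empty((0, 2)),
                       area_px=10, area_um2=1.0, circularity=0.9)
            for i in range(3)
        ]
        calls = pd.DataFrame(
            {"id": range(3), "cluster": 0, "pattern": ["1"] * 3,
             "distance": 0.1, "flags": ["ok"] * 3}
        )
        overrides = pd.DataFrame({"id": [0, 2], "action": ["exclude", "exclude"]})
        out = qc_report(calls, lm, cells, tmp_path, overrides=overrides)
        assert (out.loc[out["id"].isin([0, 2]), "flags"].str.contains("excluded")).all()
        written = read_calls(tmp_path / "calls.csv")
        assert (written.loc[written["id"].isin([0, 2]), "flags"] == "excluded;manual_override").all()
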