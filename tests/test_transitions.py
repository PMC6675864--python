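"""Transition cross-tabulation, z-statistics, masking and heatmap export."""

import numpy as np
import pandas as pd
import pytest

import sleepbouts as sb


def bout_seq(states, onsets=None):
    onsets = onsets or list(range(len(states)))
    return [sb.Bout(s, o, 1, 4.0) for s, o in zip(states, onsets)]


@pytest.fixture
def worked_table():
    """3-state table with hand-computed expectations and z-statistics."""
    O = np.array([[0, 10, 2], [8, 0, 4], [2, 4, 0]])
    return sb.TransitionTable(states=("A", "B", "C"), O=O)


def oracle_z(t, method="pearson"):
    """Cell-by-cell scalar reference for the vectorized z computation."""
    K = len(t.states)
    N = t.O.sum()
    R = [t.O[i, :].sum() for i in range(K)]
    C = [t.O[:, j].sum() for j in range(K)]
    Z = np.full((K, K), np.nan)
    for i in range(K):
        for j in range(K):
            E = R[i] * C[j] / N
            if E == 0:
                continue
            z = (t.O[i, j] - E) / np.sqrt(E)
            if method == "adjusted":
                z /= np.sqrt((1 - R[i] / N) * (1 - C[j] / N))
            Z[i, j] = z
    return Z


class TestCrossTabulate:
    def test_worked_example(self):
        t = sb.cross_tabulate({"r1": bout_seq(["AW", "PW", "AW", "S1"])},
                              states=("AW", "PW", "S1"))
        assert t.N == 3
        idx = {s: i for i, s in enumerate(t.states)}
        assert t.O[idx["AW"], idx["PW"]] == 1
        assert t.O[idx["PW"], idx["AW"]] == 1
        assert t.O[idx["AW"], idx["S1"]] == 1

    def test_no_transitions_across_subjects(self):
        t = sb.cross_tabulate(
            {"r1": bout_seq(["PW", "AW"]), "r2": bout_seq(["AW", "PW"])},
            states=("AW", "PW"),
        )
        assert t.N == 2  # only the within-subject pairs

    def test_empty_table_when_no_pairs(self):
        t = sb.cross_tabulate({"r1": bout_seq(["AW"]), "r2": []},
                              states=("AW", "PW"))
        assert t.N == 0

    def test_bin_selection_uses_successor_onset(self):
        bouts = bout_seq(["AW", "PW", "AW"], onsets=[0, 895, 905])
        t0 = sb.cross_tabulate({"r1": bouts}, states=("AW", "PW"), bin_index=0)
        t1 = sb.cross_tabulate({"r1": bouts}, states=("AW", "PW"), bin_index=1)
        assert t0.N == 1 and t0.O[0, 1] == 1  # AW->PW lands at epoch 895
        assert t1.N == 1 and t1.O[1, 0] == 1  # PW->AW lands at epoch 905

    def test_matches_naive_pair_loop(self, study):
        group = [h for h in study if h.treatment == "VEH"]
        by_subject = sb.bouts_by_subject(group)
        t = sb.cross_tabulate(by_subject)
        O = np.zeros_like(t.O)
        idx = {s: i for i, s in enumerate(t.states)}
        for bouts in by_subject.values():
            for k in range(len(bouts) - 1):
                O[idx[bouts[k].state], idx[bouts[k + 1].state]] += 1
        assert (t.O == O).all()


class TestZStatistics:
    def test_worked_pearson_values(self, worked_table):
        t = sb.z_statistics(worked_table)
        assert t.E[0, 1] == pytest.approx(5.6)
        assert t.Z[0, 1] == pytest.approx(1.859, abs=1e-3)
        assert t.Z[1, 0] == pytest.approx(2.0)

    def test_worked_adjusted_value(self, worked_table):
        t = sb.z_statistics(worked_table, method="adjusted")
        assert t.Z[0, 1] == pytest.approx(3.29, abs=0.01)

    def test_zero_when_observed_equals_expected(self, worked_table):
        # in the worked table the C->A cell has E = 6*10/30 = 2 = O, so z = 0
        t = sb.z_statistics(worked_table)
        assert t.E[2, 0] == pytest.approx(2.0)
        assert t.Z[2, 0] == pytest.approx(0.0, abs=1e-12)

    def test_probability_scale_is_count_scale_over_sqrt_n(self, worked_table):
        zc = sb.z_statistics(worked_table, on="counts")
        zp = sb.z_statistics(worked_table, on="probabilities")
        ok = np.isfinite(zc.Z)
        assert np.allclose(zp.Z[ok], zc.Z[ok] / np.sqrt(worked_table.N))

    def test_conservation(self, rng):
        for _ in range(20):
            O = rng.integers(0, 50, size=(5, 5))
            np.fill_diagonal(O, 0)
            if O.sum() == 0:
                continue
            t = sb.TransitionTable(states=tuple("ABCDE"), O=O)
            assert t.E.sum() == pytest.approx(t.N)
            assert np.allclose(t.E.sum(axis=1), t.R)
            assert np.allclose(t.E.sum(axis=0), t.C)

    def test_empty_table_rejected(self):
        t = sb.TransitionTable(states=("A", "B"), O=np.zeros((2, 2), dtype=int))
        with pytest.raises(ValueError, match="empty"):
            sb.z_statistics(t)

    @pytest.mark.parametrize("method", ["pearson", "adjusted"])
    def test_matches_scalar_oracle(self, rng, method):
        for _ in range(100):
            K = int(rng.integers(2, 8))
            O = rng.integers(0, 101, size=(K, K))
            np.fill_diagonal(O, 0)
            if O.sum() == 0:
                continue
            t = sb.TransitionTable(states=tuple(f"s{i}" for i in range(K)), O=O)
            Z = sb.z_statistics(t, method=method).Z
            Zo = oracle_z(t, method=method)
            ok = np.isfinite(Zo)
            assert (np.isfinite(Z) == ok).all()
            assert np.allclose(Z[ok], Zo[ok], atol=1e-12, rtol=0)

    def test_structural_zero_diagonal_enforced(self):
        with pytest.raises(ValueError, match="diagonal"):
            sb.TransitionTable(states=("A", "B"), O=np.array([[1, 2], [3, 0]]))


class TestMask:
    def test_worked_example_mask(self, worked_table):
        t = sb.apply_mask(sb.z_statistics(worked_table), min_count=5)
        assert (~t.mask).sum() == 2  # only A->B (10) and B->A (8) survive
        assert not t.mask[0, 1] and not t.mask[1, 0]
        assert np.isnan(t.Z[t.mask]).all()

    def test_min_count_zero_masks_only_diagonal(self, worked_table):
        t = sb.apply_mask(sb.z_statistics(worked_table), min_count=0)
        assert (t.mask == np.eye(3, dtype=bool)).all()

    def test_all_zero_offdiagonal_fully_masked(self):
        O = np.zeros((3, 3), dtype=int)
        O[0, 1] = 1  # keep the table non-empty
        t = sb.apply_mask(
            sb.z_statistics(sb.TransitionTable(states=("A", "B", "C"), O=O))
        )
        assert t.mask.all()

    def test_mask_on_expected_counts(self, worked_table):
        t = sb.apply_mask(
            sb.z_statistics(worked_table), min_count=5, on_expected=True
        )
        expected_rule = (worked_table.E < 5) | np.eye(3, dtype=bool)
        assert (t.mask == expected_rule).all()


class TestExport:
    def test_csv_round_trip_full_precision(self, worked_table, tmp_path):
        t = sb.apply_mask(sb.z_statistics(worked_table))
        p = tmp_path / "t.csv"
        sb.heatmap_export(t, csv_path=p)
        # %.17g serialization is exact; exact recovery needs the
        # round-trip float parser rather than pandas' fast default
        back = pd.read_csv(p, float_precision="round_trip")
        assert len(back) == 9
        for _, row in back.iterrows():
            i = t.states.index(row["from_state"])
            j = t.states.index(row["to_state"])
            assert row["observed"] == t.O[i, j]
            assert bool(row["masked"]) == bool(t.mask[i, j])
            if not row["masked"]:
                assert row["z"] == t.Z[i, j]  # exact serialization

    def test_images_written(self, worked_table, tmp_path):
        t = sb.apply_mask(sb.z_statistics(worked_table))
        png, svg = tmp_path / "t.png", tmp_path / "t.svg"
        sb.heatmap_export(t, image_paths=[png, svg])
        assert png.stat().st_size > 0 and svg.stat().st_size > 0

    def test_unfilled_table_rejected(self, worked_table):
        with pytest.raises(ValueError, match="fill"):
            sb.heatmap_export(worked_table)


@pytest.fixture(scope="module")
def grid(study, tmp_path_factory):
    by_tr = {
        tr: sb.bouts_by_subject([h for h in study if h.treatment == tr])
        for tr in ("VEH", "AM5", "AM10")
    }
    out = tmp_path_factory.mktemp("grid")
    return sb.heatmap_grid(by_tr, out_dir=out), out


class TestGrid:
    def test_nine_panels_and_files(self, grid):
        tables, out = grid
        assert len(tables) == 9
        assert len(list(out.glob("transitions_*.csv"))) == 9
        assert (out / "transition_grid.png").exists()
        assert (out / "transition_grid.svg").exists()

    def test_panels_share_state_ordering(self, grid):
        tables, _ = grid
        orders = {t.states for t in tables.values()}
        assert orders == {tuple(sb.SPLIT_STATES)}

    def test_missing_state_fully_masked(self):
        # a treatment whose bouts never visit IS: IS row and column masked
        seqs = {"r1": bout_seq(["AW", "PW"] * 10, onsets=range(20))}
        tables = sb.heatmap_grid({"VEH": seqs}, treatments=["VEH"], n_bins=1)
        t = tables[("VEH", 0)]
        i = t.states.index("IS")
        assert t.mask[i, :].all() and t.mask[:, i].all()
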