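import math

import numpy as np
import pandas as pd
import pytest

import siamvs as sv


def _library_with_known_actives(rng, n=60, length=32, n_active=8):
    fps = rng.integers(0, 5, size=(n, length))
    fps[:, 0] += 1
    labels = ["X"] * n_active + [sv.INACTIVE_LABEL] * (n - n_active)
    ids = [f"m{i:03d}" for i in range(n)]
    return sv.ScreeningLibrary(fps, labels, ids)


class TestRankDatabase:
    def test_exact_duplicate_ranks_first_with_tan(self, rng):
        lib = _library_with_known_actives(rng)
        lib.fingerprints[5] = lib.fingerprints[0]  # duplicate of the query
        ranked = sv.rank_database(sv.TanimotoScorer(), lib.fingerprint(0), lib)
        assert ranked.molecule_ids[0] == "m005"
        assert ranked.scores[0] == pytest.approx(1.0)

    def test_query_excluded_and_permutation(self, rng):
        lib = _library_with_known_actives(rng)
        ranked = sv.rank_database(sv.TanimotoScorer(), lib.fingerprint(3), lib)
        assert len(ranked) == lib.n_molecules - 1
        assert "m003" not in set(ranked.molecule_ids)
        assert sorted(ranked.molecule_ids) == sorted(
            str(m) for m in lib.molecule_ids if m != "m003"
        )

    def test_equal_scores_fall_back_to_id_order(self):
        fps = np.tile([1, 2, 3], (5, 1))  # all identical -> all scores 1.0
        lib = sv.ScreeningLibrary(fps, ["X"] * 5,
                                  ["q", "d", "b", "a", "c"])
        ranked = sv.rank_database(sv.TanimotoScorer(), lib.fingerprint(0), lib)
        assert list(ranked.molecule_ids) == ["a", "b", "c", "d"]

    def test_order_matches_sort_oracle(self, rng):
        lib = _library_with_known_actives(rng, n=50)
        scorer = sv.TanimotoScorer()
        q = lib.fingerprint(2)
        ranked = sv.rank_database(scorer, q, lib)
        rows = []
        for i in range(lib.n_molecules):  # brute-force oracle
            if i == 2:
                continue
            rows.append(
                (str(lib.molecule_ids[i]),
                 sv.tanimoto_score(q.values, lib.fingerprints[i]))
            )
        rows.sort(key=lambda t: (-t[1], t[0]))
        assert list(ranked.molecule_ids) == [r[0] for r in rows]


class TestRecallAt:
    def _ranked(self, labels, query_class="X"):
        n = len(labels)
        return sv.RankedList(
            query_id="q", query_class=query_class,
            molecule_ids=np.array([f"m{i}" for i in range(n)]),
            labels=np.asarray(labels, dtype=str),
            scores=np.linspace(1, 0, n),
        )

    def test_all_actives_in_top_block(self):
        ranked = self._ranked(["X"] * 5 + ["INACTIVE"] * 95)
        assert sv.recall_at(ranked, 5.0) == 100.0

    def test_full_cutoff_always_complete(self, rng):
        labels = rng.permutation(["X"] * 7 + ["INACTIVE"] * 43)
        assert sv.recall_at(self._ranked(list(labels)), 100.0) == 100.0

    def test_direct_count_oracle(self):
        # N=200, top 1% keeps ceil(2)=2 positions, 2 of 8 actives there
        labels = ["X", "X"] + ["INACTIVE"] * 100 + ["X"] * 6 + ["INACTIVE"] * 92
        assert sv.recall_at(self._ranked(labels), 1.0) == pytest.approx(25.0)

    def test_monotone_in_cutoff(self, rng):
        labels = list(rng.permutation(["X"] * 10 + ["INACTIVE"] * 190))
        ranked = self._ranked(labels)
        values = [sv.recall_at(ranked, pct) for pct in (1, 2, 5, 10, 50, 100)]
        assert all(a <= b for a, b in zip(values, values[1:]))

    def test_cutoff_count_uses_ceiling(self):
        labels = ["X"] + ["INACTIVE"] * 149 + ["X"]
        # 1% of 151 -> ceil(1.51) = 2 kept positions
        ranked = self._ranked(labels)
        assert math.ceil(0.01 * len(ranked)) == 2
        assert sv.recall_at(ranked, 1.0) == pytest.approx(50.0)

    def test_errors(self):
        ranked = self._ranked(["INACTIVE"] * 10)
        with pytest.raises(ValueError, match="no same-class active"):
            sv.recall_at(ranked, 5.0)
        with pytest.raises(ValueError, match="pct"):
            sv.recall_at(self._ranked(["X", "X"]), 0.0)


class TestRecallTable:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        df = pd.DataFrame(
            rng.uniform(0, 100, size=(4, 3)),
            index=["06233", "09249", "31420", "78331"],
            columns=["TAN", "SMLP", "Hybrid-F-Max"],
        )
        table = sv.RecallTable(df)
        path = tmp_path / "table.tsv"
        table.write(path)
        back = sv.RecallTable.read(path)
        assert back == table  # bit-exact values, labels preserved

    def test_summarize_single_column(self):
        table = sv.RecallTable(pd.DataFrame({"TAN": [10.0, 20.0, 60.0]}))
        means, shaded = sv.summarize(table)
        assert means["TAN"] == pytest.approx(30.0)
        assert shaded["TAN"] == 3  # sole column tops every row

    def test_shaded_counts_share_ties(self):
        df = pd.DataFrame({"a": [1.0, 5.0], "b": [1.0, 3.0]})
        _, shaded = sv.summarize(sv.RecallTable(df))
        assert shaded["a"] == 2 and shaded["b"] == 1
        assert shaded.sum() >= len(df)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sv.RecallTable(pd.DataFrame())


class TestPublishedTables:
    def test_all_bundled_tables_load(self):
        for name in sv.PUBLISHED_TABLES:
            table = sv.load_published_table(name)
            assert table.df.shape[1] in (9, 10)
            assert ((table.df.values >= 0) & (table.df.values <= 100)).all()

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            sv.load_published_table("nope")


@pytest.fixture(scope="module")
def protocol():
    return sv.CvProtocol(k_folds=2, queries_per_class=3,
                         cutoffs=(1.0, 5.0), seed=7, n_train_pairs=200)


class TestRunCv:

    def test_tan_cells_in_range_and_deterministic(self, easy_library, protocol):
        factory = lambda seed: sv.TanimotoScorer()  # noqa: E731
        t1 = sv.run_cv(factory, easy_library, protocol, method_name="tan")
        t2 = sv.run_cv(factory, easy_library, protocol, method_name="tan")
        for pct in (1.0, 5.0):
            vals = t1[pct].df["tan"].values
            assert ((vals >= 0) & (vals <= 100)).all()
            assert t1[pct].df.equals(t2[pct].df)
            assert set(t1[pct].df.index) == {"A", "B"}

    def test_protocol_matches_direct_fold_computation(self, easy_library,
                                                      protocol):
        """For the untrained TAN scorer the CV result must equal a direct
        recomputation over the same folds, queries and rankings."""
        from siamvs.screening_eval import _stratified_folds

        tables = sv.run_cv(lambda s: sv.TanimotoScorer(), easy_library,
                           protocol, method_name="tan")
        root = np.random.SeedSequence(protocol.seed)
        ss_folds, ss_rest = root.spawn(2)
        fold = _stratified_folds(easy_library, protocol.k_folds,
                                 np.random.default_rng(ss_folds))
        fold_seeds = ss_rest.spawn(protocol.k_folds)
        expect = {1.0: {}, 5.0: {}}
        for f in range(protocol.k_folds):
            _, ss_query = fold_seeds[f].spawn(2)
            test_lib = easy_library.subset(np.flatnonzero(fold == f))
            qrng = np.random.default_rng(ss_query)
            for lbl in ["A", "B"]:
                members = np.flatnonzero(test_lib.labels == lbl)
                queries = qrng.choice(members, size=3, replace=False)
                per = {1.0: [], 5.0: []}
                for qi in queries:
                    ranked = sv.rank_database(
                        sv.TanimotoScorer(), test_lib.fingerprint(qi), test_lib
                    )
                    for pct in (1.0, 5.0):
                        per[pct].append(sv.recall_at(ranked, pct))
                for pct in (1.0, 5.0):
                    expect[pct].setdefault(lbl, []).append(np.mean(per[pct]))
        for pct in (1.0, 5.0):
            for lbl in ["A", "B"]:
                assert tables[pct].df.loc[lbl, "tan"] == pytest.approx(
                    np.mean(expect[pct][lbl]), abs=1e-12
                )

    def test_small_class_rejected_by_stratification_check(self, rng):
        fps = rng.integers(0, 4, size=(30, 16)) + 1
        labels = ["A"] * 4 + ["B"] * 26
        lib = sv.ScreeningLibrary(fps, labels, [f"m{i}" for i in range(30)])
        protocol = sv.CvProtocol(k_folds=2, queries_per_class=5, seed=0)
        with pytest.raises(ValueError, match="'A'"):
            sv.run_cv(lambda s: sv.TanimotoScorer(), lib, protocol)
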