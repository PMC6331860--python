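import numpy as np
import pandas as pd
import pytest

from sqbscreen import (
    ActivityLabels,
    CountFingerprint,
    METHODS,
    SimilarityScreener,
    WeightScheme,
    compute_corpus_stats,
    embed_compound,
    evaluate,
    rank_library,
    recall_at,
    sqb_probability,
    summarize_table,
    tanimoto_continuous,
)
from sqbscreen.screening import RankedList, normalize_method


def _mini_library(seed=3, n=12, nf=20):
    rng = np.random.default_rng(seed)
    lib = []
    for i in range(n):
        frags = rng.choice(nf, size=rng.integers(2, 7), replace=False)
        lib.append(
            CountFingerprint(
                f"M{i:02d}", {int(f): int(rng.integers(1, 4)) for f in frags}
            )
        )
    return lib


class TestRankLibrary:
    def test_identical_candidate_ranks_first_with_score_one(self):
        ref = CountFingerprint("REF", {1: 2, 3: 1})
        lib = [
            ref,
            CountFingerprint("TWIN", {1: 2, 3: 1}),
            CountFingerprint("OTHER", {9: 1}),
            CountFingerprint("HALF", {1: 2, 8: 4}),
        ]
        for method in METHODS:
            ranked = rank_library(ref, lib, method=method)
            assert ranked.entries[0][0] == "TWIN"
            assert ranked.entries[0][1] == pytest.approx(1.0)
            assert "REF" not in ranked.ids()

    def test_all_equal_scores_ordered_by_compound_id(self):
        ref = CountFingerprint("REF", {50: 1})
        lib = [ref] + [
            CountFingerprint(cid, {1: 1}) for cid in ("Z", "A", "M")
        ]
        ranked = rank_library(ref, lib, method="tan")
        assert ranked.ids() == ["A", "M", "Z"]

    def test_tan_order_matches_brute_force_pairwise_sort(self):
        lib = _mini_library()
        ref = lib[0]
        ranked = rank_library(ref, lib, method="tan")
        brute = sorted(
            (
                (fp.compound_id, tanimoto_continuous(ref.counts, fp.counts))
                for fp in lib[1:]
            ),
            key=lambda kv: (-kv[1], kv[0]),
        )
        assert [cid for cid, _ in brute] == ranked.ids()
        for (cid, score), (bcid, bscore) in zip(ranked.entries, brute):
            assert score == pytest.approx(bscore)

    @pytest.mark.parametrize("method", METHODS)
    def test_vectorized_scores_match_embedding_route(self, method):
        """The numpy scoring path must agree with per-compound embedding calls."""
        lib = _mini_library(seed=9)
        ref = lib[1]
        stats = compute_corpus_stats(lib)
        ranked = rank_library(ref, lib, method=method)
        scores = dict(ranked.entries)
        for fp in lib:
            if fp.compound_id == ref.compound_id:
                continue
            if method == "tan":
                expected = tanimoto_continuous(ref.counts, fp.counts)
            else:
                scheme = WeightScheme(normalize_method(method).removeprefix("sqb-"))
                ref_vec = embed_compound(ref, stats, scheme, reference=ref)
                cand = embed_compound(fp, stats, scheme, reference=ref)
                expected = sqb_probability(ref_vec, cand)
            assert scores[fp.compound_id] == pytest.approx(expected, abs=1e-12)

    def test_unknown_method_rejected(self):
        lib = _mini_library()
        with pytest.raises(ValueError, match="unknown similarity method"):
            rank_library(lib[0], lib, method="cosine")

    def test_screener_param_protocol(self):
        scr = SimilarityScreener(method="tan", weighted_tan=True)
        assert scr.get_params()["weighted_tan"] is True
        scr.set_params(method="sqb-okapi")
        assert scr.method == "sqb-okapi"


class TestRecallAt:
    def _ranked(self, n):
        return RankedList("R", tuple((f"C{i:04d}", 1.0 - i / n) for i in range(n)))

    def test_all_actives_in_top_gives_100(self):
        ranked = self._ranked(200)
        actives = {f"C{i:04d}" for i in range(2)}
        assert recall_at(ranked, actives, 0.01) == 100.0

    def test_no_actives_in_top_gives_0(self):
        ranked = self._ranked(200)
        assert recall_at(ranked, {"C0199"}, 0.01) == 0.0

    def test_hand_counted_fraction(self):
        # 1000 entries, 1% cutoff = 10; 5 of 20 actives inside
        ranked = self._ranked(1000)
        actives = {f"C{i:04d}" for i in range(5)} | {
            f"C{i:04d}" for i in range(900, 915)
        }
        assert recall_at(ranked, actives, 0.01) == pytest.approx(25.0)

    def test_cutoff_floor_of_one(self):
        ranked = self._ranked(10)
        assert recall_at(ranked, {"C0000"}, 0.01) == 100.0

    def test_monotone_in_fraction(self):
        rng = np.random.default_rng(5)
        ranked = self._ranked(500)
        actives = {f"C{i:04d}" for i in rng.choice(500, 40, replace=False)}
        fractions = [0.01, 0.02, 0.05, 0.1, 0.5, 0.9]
        recalls = [recall_at(ranked, actives, f) for f in fractions]
        assert recalls == sorted(recalls)

    def test_near_full_cutoff_returns_100(self):
        ranked = self._ranked(50)
        actives = {"C0010", "C0049"}
        assert recall_at(ranked, actives, 0.999) == 100.0

    def test_errors(self):
        ranked = self._ranked(10)
        with pytest.raises(ValueError):
            recall_at(ranked, set(), 0.01)
        with pytest.raises(ValueError):
            recall_at(ranked, {"C0000"}, 1.5)


class TestSummarizeTable:
    def test_single_cell(self):
        table = pd.DataFrame({"m": [42.0]}, index=["k"])
        mean_row, shaded = summarize_table(table)
        assert mean_row["m"] == 42.0
        assert shaded["m"] == 1

    def test_constant_rows_shade_every_method(self):
        table = pd.DataFrame(
            [[10.0, 10.0, 10.0]] * 4, columns=["a", "b", "c"]
        )
        _, shaded = summarize_table(table)
        assert shaded.tolist() == [4, 4, 4]

    def test_shaded_counts_cover_at_least_all_rows(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.uniform(0, 100, size=(7, 4)))
        mean_row, shaded = summarize_table(table)
        assert shaded.sum() >= len(table)
        assert np.allclose(mean_row, table.mean(axis=0))

    def test_missing_cell_rejected(self):
        table = pd.DataFrame([[1.0, np.nan]])
        with pytest.raises(ValueError, match="missing"):
            summarize_table(table)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="0, 100"):
            summarize_table(pd.DataFrame([[101.0]]))


@pytest.fixture(scope="module")
def tiny_benchmark():
    rng = np.random.default_rng(17)
    lib = []
    classes = {}
    for cid, base in (("K1", 0), ("K2", 30)):
        members = set()
        for i in range(8):
            name = f"{cid}_{i}"
            frags = {
                int(base + f): 1 + int(rng.integers(0, 3))
                for f in rng.choice(12, 6, replace=False)
            }
            lib.append(CountFingerprint(name, frags))
            members.add(name)
        classes[cid] = members
    for i in range(60):
        frags = {int(rng.integers(0, 80)): 1 for _ in range(5)}
        lib.append(CountFingerprint(f"D{i:03d}", frags))
    return lib, ActivityLabels(classes)


class TestEvaluate:
    def test_seeded_runs_are_bit_identical(self, tiny_benchmark):
        lib, labels = tiny_benchmark
        a = evaluate(lib, labels, references_per_class=3, seed=5)
        b = evaluate(lib, labels, references_per_class=3, seed=5)
        for ra, rb in zip(a, b):
            pd.testing.assert_frame_equal(ra.table, rb.table)

    def test_different_seed_changes_reference_draw(self, tiny_benchmark):
        lib, labels = tiny_benchmark
        a = evaluate(lib, labels, references_per_class=3, seed=5, methods=["tan"])
        b = evaluate(lib, labels, references_per_class=3, seed=6, methods=["tan"])
        assert a[0].references != b[0].references

    def test_reference_panel_shared_across_methods_and_fractions(self, tiny_benchmark):
        lib, labels = tiny_benchmark
        results = evaluate(lib, labels, references_per_class=3, seed=5)
        assert results[0].references == results[1].references
        for refs in results[0].references.values():
            assert len(refs) == 3

    def test_mean_row_recomputes_from_table(self, tiny_benchmark):
        lib, labels = tiny_benchmark
        results = evaluate(lib, labels, references_per_class=3, seed=1)
        for res in results:
            assert np.allclose(res.mean_row, res.table.mean(axis=0), atol=1e-12)
            assert ((res.table.to_numpy() >= 0) & (res.table.to_numpy() <= 100)).all()

    def test_identical_methods_give_identical_columns(self, tiny_benchmark):
        lib, labels = tiny_benchmark
        res = evaluate(
            lib, labels, references_per_class=3, seed=2, methods=["tan", "tan"]
        )[0]
        col = res.table.iloc[:, 0]
        assert np.allclose(res.table.iloc[:, 1], col)

    def test_class_too_small_names_class(self, tiny_benchmark):
        lib, labels = tiny_benchmark
        with pytest.raises(ValueError, match="K1"):
            evaluate(lib, labels, references_per_class=8, seed=0)
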