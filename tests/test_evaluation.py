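import numpy as np
import pytest

from homeval.evaluation import (
    Benchmark,
    UndefinedMetricError,
    f_beta,
    f_beta_max,
    pr_curve,
    select_thresholds,
    taxonomy_match,
    top1_accuracy,
    write_threshold_table,
)
from homeval.io import DomainRecord, ScoreTable, TaxonomyId, parse_taxonomy
from oracles import brute_force_fbeta_max, brute_force_pr, brute_force_top1, random_instance


def _dom(did, tax):
    return DomainRecord(
        domain_id=did,
        pdb_id="0000",
        chain_id="A",
        release_date=None,
        n_residues=100,
        n_sse=5,
        taxonomy=tax if isinstance(tax, TaxonomyId) else parse_taxonomy(tax),
    )


class TestTaxonomyMatch:
    def test_h_level_requires_x_and_h(self):
        a = parse_taxonomy("3240.1.1.2")
        assert taxonomy_match(a, parse_taxonomy("3240.1.1.1"), "H")
        assert not taxonomy_match(a, parse_taxonomy("3240.2.1.1"), "H")
        assert taxonomy_match(a, parse_taxonomy("3240.2.1.1"), "X")

    def test_f_level_requires_all_four(self):
        a = parse_taxonomy("1.2.3.4")
        assert not taxonomy_match(a, parse_taxonomy("1.2.3.5"), "F")
        assert taxonomy_match(a, parse_taxonomy("1.2.3.4"), "F")

    @pytest.mark.parametrize("level", ["H", "X", "F"])
    def test_reflexivity(self, level):
        a = parse_taxonomy("7.3.2.9")
        assert taxonomy_match(a, a, level)

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            taxonomy_match(parse_taxonomy("1.1.1.1"), parse_taxonomy("1.1.1.1"), "T")


class TestTop1Accuracy:
    def test_worked_example_is_half(self, fig2):
        result = top1_accuracy(fig2.benchmark)
        assert result.accuracy == 0.5
        by_query = {a.query_id: a for a in result.assignments}
        assert by_query["q1"].matched
        assert not by_query["q2"].matched
        assert by_query["q2"].best_library_id == "l5"

    def test_perfect_classifier(self):
        queries = [_dom("q1", "1.1.1.1"), _dom("q2", "2.1.1.1")]
        library = [_dom("l1", "1.1.1.1"), _dom("l2", "2.1.1.1")]
        scores = ScoreTable.from_records(
            [("q1", "l1", 5.0), ("q1", "l2", 1.0), ("q2", "l1", 1.0), ("q2", "l2", 5.0)]
        )
        bench = Benchmark.from_collections(queries, library, scores, level="H")
        assert top1_accuracy(bench).accuracy == 1.0

    def test_identical_domain_excluded_from_argmax(self):
        # q1 appears in the library; its own (highest-scoring) entry must be skipped
        q1 = _dom("q1", "1.1.1.1")
        library = [q1, _dom("l1", "2.1.1.1")]
        scores = ScoreTable.from_records([("q1", "q1", 100.0), ("q1", "l1", 1.0)])
        bench = Benchmark.from_collections([q1], library, scores, level="H")
        result = top1_accuracy(bench)
        assert result.assignments[0].best_library_id == "l1"
        assert result.accuracy == 0.0

    def test_tie_breaks_to_smallest_library_id(self):
        queries = [_dom("q1", "1.1.1.1")]
        library = [_dom("lb", "1.1.1.1"), _dom("la", "2.1.1.1")]
        scores = ScoreTable.from_records([("q1", "la", 3.0), ("q1", "lb", 3.0)])
        bench = Benchmark.from_collections(queries, library, scores, level="H")
        assert top1_accuracy(bench).assignments[0].best_library_id == "la"

    def test_unassignable_query_excluded_with_warning(self, caplog):
        queries = [_dom("q1", "1.1.1.1"), _dom("q2", "2.1.1.1")]
        library = [_dom("l1", "1.1.1.1")]
        scores = ScoreTable.from_records([("q1", "l1", 1.0)])
        bench = Benchmark.from_collections(queries, library, scores, level="H")
        with caplog.at_level("WARNING"):
            result = top1_accuracy(bench)
        assert result.accuracy == 1.0
        assert result.unassigned == ["q2"]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 50:
            bench = random_instance(rng, score_fraction=0.8)
            try:
                expected, _ = brute_force_top1(bench)
            except ZeroDivisionError:
                continue
            assert top1_accuracy(bench).accuracy == pytest.approx(expected)
            checked += 1


class TestPrCurve:
    def test_worked_example_precision_recall(self, fig2):
        curve = pr_curve(fig2.benchmark)
        p, r = curve.at_threshold(fig2.threshold)
        assert p == pytest.approx(0.4)
        assert r == pytest.approx(0.5)
        assert curve.n_evaluated_pairs == 12
        assert curve.n_positive_pairs == 4

    def test_strict_comparison_excludes_pairs_at_threshold(self, fig2):
        # q1-l2 scores exactly 5.0 and must not count as above 5.0
        curve = pr_curve(fig2.benchmark)
        p_at_5, r_at_5 = curve.at_threshold(5.0)
        p_below, r_below = curve.at_threshold(4.999)
        assert r_below > r_at_5

    def test_degenerate_all_homologous(self):
        queries = [_dom("q1", "1.1.1.1")]
        library = [_dom("l1", "1.1.1.1"), _dom("l2", "1.1.1.2")]
        scores = ScoreTable.from_records([("q1", "l1", 2.0), ("q1", "l2", 1.0)])
        bench = Benchmark.from_collections(queries, library, scores, level="H")
        curve = pr_curve(bench)
        assert curve.precision[-1] == 1.0
        assert curve.recall[-1] == 1.0

    def test_no_homologous_pair_is_undefined(self):
        queries = [_dom("q1", "1.1.1.1")]
        library = [_dom("l1", "2.1.1.1")]
        scores = ScoreTable.from_records([("q1", "l1", 1.0)])
        bench = Benchmark.from_collections(queries, library, scores, level="H")
        with pytest.raises(UndefinedMetricError):
            pr_curve(bench)

    def test_unscored_pairs_lie_below_every_threshold(self):
        # l2 is an unscored homolog: recall can never reach 1 over thresholds
        queries = [_dom("q1", "1.1.1.1")]
        library = [_dom("l1", "1.1.1.1"), _dom("l2", "1.1.1.1")]
        scores = ScoreTable.from_records([("q1", "l1", 2.0)])
        bench = Benchmark.from_collections(queries, library, scores, level="H")
        curve = pr_curve(bench)
        assert curve.n_positive_pairs == 2
        assert curve.recall.max() == pytest.approx(0.5)

    def test_all_vs_all_excludes_diagonal_once(self):
        doms = [_dom(f"d{i}", f"{1 + i % 2}.1.1.1") for i in range(4)]
        rows = [
            (a.domain_id, b.domain_id, 1.0 + i)
            for i, (a, b) in enumerate(
                (a, b) for a in doms for b in doms
            )
        ]
        bench = Benchmark.from_collections(
            doms, doms, ScoreTable.from_records(rows), level="H"
        )
        curve = pr_curve(bench)
        assert curve.n_evaluated_pairs == 12  # 4*4 minus the 4 diagonal pairs

    def test_recall_monotone_and_final_precision_is_base_rate(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            bench = random_instance(rng, score_fraction=1.0)
            try:
                curve = pr_curve(bench)
            except UndefinedMetricError:
                continue
            assert np.all(np.diff(curve.recall) >= -1e-12)
            assert curve.precision[-1] == pytest.approx(
                curve.n_positive_pairs / curve.n_evaluated_pairs
            )

    def test_matches_brute_force_at_every_threshold(self):
        rng = np.random.default_rng(23)
        checked = 0
        while checked < 30:
            bench = random_instance(rng, score_fraction=0.9)
            if not len(bench.scores):
                continue
            try:
                curve = pr_curve(bench)
            except UndefinedMetricError:
                continue
            for i, thr in enumerate(curve.thresholds):
                if np.isinf(thr):
                    thr = float(min(r.score for r in bench.scores) - 1)
                p, r = brute_force_pr(bench, thr)
                assert curve.precision[i] == pytest.approx(p)
                assert curve.recall[i] == pytest.approx(r)
            checked += 1


class TestFBeta:
    def test_worked_example_f1(self):
        assert f_beta(0.4, 0.5, 1.0) == pytest.approx(4 / 9)
        assert round(f_beta(0.4, 0.5, 1.0), 2) == 0.44

    def test_equal_precision_recall_is_identity(self):
        for beta in (0.5, 1.0, 2.0):
            assert f_beta(0.7, 0.7, beta) == pytest.approx(0.7)

    def test_beta_weighting_when_precision_exceeds_recall(self):
        assert f_beta(1.0, 0.5, 0.5) == pytest.approx(5 / 6)
        assert f_beta(1.0, 0.5, 2.0) == pytest.approx(5 / 9)
        assert f_beta(1.0, 0.5, 0.5) > f_beta(1.0, 0.5, 1.0) > f_beta(1.0, 0.5, 2.0)

    def test_zero_when_either_is_zero(self):
        assert f_beta(0.0, 0.5, 1.0) == 0.0
        assert f_beta(0.5, 0.0, 2.0) == 0.0

    def test_invalid_beta(self):
        with pytest.raises(ValueError):
            f_beta(0.5, 0.5, 0.0)

    def test_f1_is_harmonic_mean(self):
        rng = np.random.default_rng(1)
        for p, r in rng.random((50, 2)):
            if p > 0 and r > 0:
                assert f_beta(p, r, 1.0) == pytest.approx(2 * p * r / (p + r))

    def test_beta_ordering_tracks_precision_recall_ordering(self, fig2):
        curve = pr_curve(fig2.benchmark)
        for p, r in zip(curve.precision, curve.recall):
            if p == 0 or r == 0:
                continue
            f05, f1, f2 = (f_beta(p, r, b) for b in (0.5, 1.0, 2.0))
            if p >= r:
                assert f05 >= f1 >= f2
            if r >= p:
                assert f2 >= f1 >= f05


class TestFBetaMax:
    def test_single_point_curve(self, fig2):
        value, thr = f_beta_max(pr_curve(fig2.benchmark), 1.0)
        # the best threshold on this toy curve reaches recall 1 at precision 4/12
        assert value == pytest.approx(max(
            f_beta(p, r, 1.0)
            for p, r in zip(pr_curve(fig2.benchmark).precision, pr_curve(fig2.benchmark).recall)
        ))

    def test_perfect_point_attains_one(self):
        queries = [_dom("q1", "1.1.1.1")]
        library = [_dom("l1", "1.1.1.1"), _dom("l2", "2.1.1.1")]
        scores = ScoreTable.from_records([("q1", "l1", 5.0), ("q1", "l2", 1.0)])
        bench = Benchmark.from_collections(queries, library, scores, level="H")
        value, thr = f_beta_max(pr_curve(bench), 1.0)
        assert value == pytest.approx(1.0)
        assert thr == pytest.approx(1.0)  # the gap threshold (strict >)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(99)
        checked = 0
        while checked < 20:
            bench = random_instance(rng)
            try:
                curve = pr_curve(bench)
            except UndefinedMetricError:
                continue
            for beta in (0.5, 1.0, 2.0):
                assert f_beta_max(curve, beta)[0] == pytest.approx(
                    brute_force_fbeta_max(bench, beta)
                )
            checked += 1


class TestSelectThresholds:
    def _bench(self):
        queries = [_dom("q1", "1.1.1.1"), _dom("q2", "2.1.1.1")]
        library = [
            _dom("l1", "1.1.1.1"),
            _dom("l2", "2.1.1.1"),
            _dom("l3", "3.1.1.1"),
        ]
        scores = ScoreTable.from_records(
            [
                ("q1", "l1", 9.0),
                ("q1", "l2", 2.0),
                ("q1", "l3", 1.0),
                ("q2", "l2", 8.0),
                ("q2", "l1", 3.0),
                ("q2", "l3", 1.5),
            ]
        )
        return Benchmark.from_collections(queries, library, scores, level="H")

    def test_perfect_separation_selects_gap_threshold_everywhere(self):
        table = select_thresholds(pr_curve(self._bench()))
        thresholds = {e.threshold for e in table.entries.values()}
        assert thresholds == {3.0}  # homologs score > 3, others <= 3

    def test_unattained_precision_marked(self):
        queries = [_dom("q1", "1.1.1.1")]
        library = [_dom("l1", "1.1.1.1"), _dom("l2", "2.1.1.1")]
        # the non-homolog always outscores the homolog: precision < 0.99 everywhere
        scores = ScoreTable.from_records([("q1", "l1", 1.0), ("q1", "l2", 5.0)])
        bench = Benchmark.from_collections(queries, library, scores, level="H")
        table = select_thresholds(pr_curve(bench))
        assert not table["precision=0.99"].attained
        assert not table["precision=0.9"].attained

    def test_precision_thresholds_are_nested(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            bench = random_instance(rng)
            try:
                table = select_thresholds(pr_curve(bench))
            except UndefinedMetricError:
                continue
            hi, lo = table["precision=0.99"], table["precision=0.9"]
            if hi.attained and lo.attained:
                assert hi.threshold >= lo.threshold

    def test_tsv_round_trip_smoke(self, tmp_path):
        table = select_thresholds(pr_curve(self._bench()))
        out = tmp_path / "thresholds.tsv"
        write_threshold_table(table, out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("criterion\t")
        assert len(lines) == 1 + len(table.entries)
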