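import math

import numpy as np
import pytest

from peptriage.score_combine import (
    SCORE_COLUMNS,
    ChainScoreRecord,
    ScoreTable,
    impute_median,
    impute_table,
    metaranker_combine,
    outlier_fractions,
    rank_table,
    read_score_table,
    write_score_table,
)
from peptriage.validation_xml import ChainOutlierCounts


def counts(n_residues=10, n_rama=0, n_rota=0, n_bond_len=0, n_bond_ang=0,
           n_rsrz_gt2=0, n_rsrz_eligible=None, rscc_values=()):
    return ChainOutlierCounts(
        n_residues=n_residues,
        n_rama=n_rama,
        n_rota=n_rota,
        n_bond_len=n_bond_len,
        n_bond_ang=n_bond_ang,
        n_rsrz_gt2=n_rsrz_gt2,
        n_rsrz_eligible=n_residues if n_rsrz_eligible is None else n_rsrz_eligible,
        rscc_values=tuple(rscc_values),
    )


def random_table(rng, n=20):
    records = []
    for i in range(n):
        records.append(
            ChainScoreRecord(
                entry_id=f"e{i:03d}",
                chain_id="B",
                n_residues=10,
                bond_len_frac=float(rng.uniform(0, 0.3)),
                bond_ang_frac=float(rng.uniform(0, 0.3)),
                rama_frac=float(rng.uniform(0, 0.5)),
                rota_frac=float(rng.uniform(0, 0.5)),
                rsrz_gt2_frac=float(rng.uniform(0, 0.5)),
                bdiff_percentile=float(rng.uniform(0, 100)),
                rscc_prob=float(rng.uniform(0, 1)),
            )
        )
    return ScoreTable(records=records)


class TestOutlierFractions:
    def test_rsrz_fraction_one_in_21(self):
        fr = outlier_fractions(counts(n_residues=21, n_rsrz_gt2=1))
        assert fr["rsrz_gt2_frac"] == pytest.approx(0.047619, abs=5e-7)

    def test_all_zero_counts(self):
        fr = outlier_fractions(counts())
        assert all(fr[c] == 0.0 for c in fr)

    def test_rama_fraction(self):
        fr = outlier_fractions(counts(n_residues=10, n_rama=3))
        assert fr["rama_frac"] == pytest.approx(0.3)

    def test_zero_rsrz_denominator_is_missing(self):
        fr = outlier_fractions(counts(n_residues=5, n_rsrz_eligible=0))
        assert fr["rsrz_gt2_frac"] is None
        assert fr["rama_frac"] == 0.0

    def test_separate_denominators(self):
        fr = outlier_fractions(
            counts(n_residues=10, n_rsrz_gt2=2, n_rsrz_eligible=8, n_bond_ang=5)
        )
        assert fr["rsrz_gt2_frac"] == pytest.approx(0.25)
        assert fr["bond_ang_frac"] == pytest.approx(0.5)


class TestImputeMedian:
    def test_zero_median_column(self):
        assert impute_median([0.0, 0.0, 0.0, None]) == [0.0, 0.0, 0.0, 0.0]

    def test_hand_median(self):
        assert impute_median([0.1, None, 0.3]) == pytest.approx([0.1, 0.2, 0.3])

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            impute_median([None, None])

    def test_median_preserved_under_imputation(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 40))
            column = [float(rng.uniform(0, 1)) for _ in range(n)]
            n_missing = int(rng.integers(1, 5))
            with_missing = column + [None] * n_missing
            before = float(np.median(column))
            after = float(np.median(impute_median(with_missing)))
            assert after == pytest.approx(before)


class TestMetaRankerCombine:
    def test_worst_in_both_columns_of_four(self):
        """A record worst in two active columns of a 4-record table scores 2·ln(1/4)."""
        records = []
        for i in range(4):
            records.append(
                ChainScoreRecord(
                    entry_id=f"e{i}",
                    chain_id="B",
                    n_residues=10,
                    bond_len_frac=0.0,
                    bond_ang_frac=0.0,
                    rama_frac=float(i) / 10,   # record 3 worst
                    rota_frac=float(i) / 10,   # record 3 worst
                    rsrz_gt2_frac=0.0,
                    bdiff_percentile=50.0,
                    rscc_prob=0.5,
                )
            )
        table = metaranker_combine(ScoreTable(records=records))
        worst = table.records[3]
        best = table.records[0]
        # constant columns contribute the same tie term to every record
        tie_term = 5 * math.log((1 + 2 + 3 + 4) / 4 / 4)
        assert worst.combined_score == pytest.approx(2 * math.log(1 / 4) + tie_term)
        assert worst.combined_score - best.combined_score == pytest.approx(
            2 * (math.log(1 / 4) - math.log(4 / 4))
        )

    def test_best_everywhere_scores_zero(self):
        rng = np.random.default_rng(3)
        table = random_table(rng, n=6)
        best = table.records[0]
        for col in SCORE_COLUMNS:
            vals = [r.column(col) for r in table.records[1:]]
            if col == "rscc_prob":
                setattr(best, col, max(vals) + 0.001)
            else:
                setattr(best, col, min(vals) - 0.001 if min(vals) > 0 else 0.0)
        # ensure strict best: other records strictly worse in every column
        for r in table.records[1:]:
            for col in SCORE_COLUMNS:
                if col == "rscc_prob":
                    setattr(r, col, min(getattr(r, col), best.column(col) - 0.001))
                else:
                    setattr(r, col, getattr(r, col) + best.column(col) + 0.001)
        metaranker_combine(table)
        assert best.combined_score == pytest.approx(0.0)
        assert all(r.combined_score < 0 for r in table.records[1:])

    def test_doubling_weights_doubles_scores(self, rng):
        table1 = random_table(rng, n=15)
        table2 = ScoreTable(records=[ChainScoreRecord(**vars(r)) for r in table1.records])
        metaranker_combine(table1)
        metaranker_combine(table2, weights={c: 2.0 for c in SCORE_COLUMNS})
        for r1, r2 in zip(table1.records, table2.records):
            assert r2.combined_score == pytest.approx(2 * r1.combined_score)

    def test_nonpositive_weight_rejected(self, rng):
        table = random_table(rng, n=5)
        with pytest.raises(ValueError):
            metaranker_combine(table, weights={"rama_frac": 0.0})

    def test_scores_nonpositive(self, rng):
        table = metaranker_combine(random_table(rng, n=30))
        assert all(r.combined_score <= 1e-12 for r in table.records)

    def test_dominance_monotonicity(self, rng):
        """Strictly worse in one column, at least as bad elsewhere => lower score."""
        for seed in range(20):
            local = np.random.default_rng(seed)
            table = random_table(local, n=12)
            a, b = table.records[0], table.records[1]
            # make a dominate b in badness: copy then worsen one column
            for col in SCORE_COLUMNS:
                setattr(a, col, b.column(col))
            a.rscc_prob = b.rscc_prob * 0.5  # strictly worse (lower is bad)
            metaranker_combine(table)
            rank_table(table)
            assert a.combined_score < b.combined_score
            assert a.rank < b.rank

    def test_order_invariant_to_log_base(self, rng):
        """Rank order is unchanged by any log base (scores scale linearly)."""
        table_e = random_table(rng, n=25)
        table_10 = ScoreTable(records=[ChainScoreRecord(**vars(r)) for r in table_e.records])
        metaranker_combine(table_e)
        metaranker_combine(table_10)
        for r in table_10.records:
            r.combined_score = r.combined_score / math.log(10)  # log10 rescaling
        order_e = [r.entry_id for r in rank_table(table_e).records]
        order_10 = [r.entry_id for r in rank_table(table_10).records]
        assert order_e == order_10

    def test_order_invariant_to_monotone_column_relabeling(self, rng):
        table1 = random_table(rng, n=18)
        table2 = ScoreTable(records=[ChainScoreRecord(**vars(r)) for r in table1.records])
        for r in table2.records:  # strictly monotone transforms per column
            r.rama_frac = math.exp(r.rama_frac)
            r.bdiff_percentile = r.bdiff_percentile**3
            r.rscc_prob = math.tan(r.rscc_prob)  # monotone on (0, 1)
        metaranker_combine(table1)
        metaranker_combine(table2)
        order1 = [r.entry_id for r in rank_table(table1).records]
        order2 = [r.entry_id for r in rank_table(table2).records]
        assert order1 == order2


class TestRankTable:
    def test_two_records(self):
        records = [
            ChainScoreRecord(entry_id="x", chain_id="B", n_residues=5, combined_score=-1.0),
            ChainScoreRecord(entry_id="y", chain_id="B", n_residues=5, combined_score=-5.0),
        ]
        table = rank_table(ScoreTable(records=records))
        assert [(r.entry_id, r.rank) for r in table.records] == [("y", 1), ("x", 2)]

    def test_ranks_are_permutation(self, rng):
        table = rank_table(metaranker_combine(random_table(rng, n=40)))
        assert sorted(r.rank for r in table.records) == list(range(1, 41))

    def test_input_order_irrelevant(self, rng):
        table = metaranker_combine(random_table(rng, n=15))
        ranked = rank_table(ScoreTable(records=list(table.records)))
        by_entry = {r.entry_id: r.rank for r in ranked.records}
        shuffled = ScoreTable(records=[table.records[i] for i in rng.permutation(15)])
        reranked = rank_table(shuffled)
        assert {r.entry_id: r.rank for r in reranked.records} == by_entry


class TestTableIO:
    def test_empty_table_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_score_table(ScoreTable(records=[]), path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert "combined_score" in lines[0]

    def test_roundtrip(self, tmp_path, rng):
        table = rank_table(metaranker_combine(random_table(rng, n=10)))
        impute_table(table)
        path = tmp_path / "scores.tsv"
        write_score_table(table, path)
        back = read_score_table(path)
        assert len(back) == 10
        for orig, rt in zip(table.records, back.records):
            assert rt.entry_id == orig.entry_id
            assert rt.rank == orig.rank
            assert rt.combined_score == pytest.approx(orig.combined_score, rel=1e-5)
            for col in SCORE_COLUMNS:
                assert rt.column(col) == pytest.approx(orig.column(col), rel=1e-5)

    def test_malformed_row_reported_with_line(self, tmp_path, rng):
        table = rank_table(metaranker_combine(random_table(rng, n=3)))
        path = tmp_path / "scores.tsv"
        write_score_table(table, path)
        lines = path.read_text().splitlines()
        lines[2] = lines[2].replace(lines[2].split("\t")[3], "not_a_number", 1)
        path.write_text("\n".join(lines))
        with pytest.raises(ValueError, match="row 2"):
            read_score_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("entry_id\tchain_id\nx\tB\n")
        with pytest.raises(ValueError, match="lacks columns"):
            read_score_table(path)
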