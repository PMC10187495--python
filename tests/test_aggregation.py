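import io
from datetime import date, datetime, timezone

import pytest

from tweetsent import (
    EmptyCellError,
    GeneratorConfig,
    generate_corpus,
    generate_incidence,
    mean_polarity,
    read_incidence,
    score_corpus,
    summarize_cells,
    top_k_words,
    weekly_series,
)
from tweetsent.aggregation import scored_table, write_top_words_csv
from tweetsent.scoring import score_tweet


def _scored(lexicon, make_tweet, *specs):
    """specs: (text, overrides) pairs -> list of ScoredTweet."""
    tweets = [make_tweet(text=text, **over) for text, over in specs]
    return score_corpus(tweets, lexicon)


WINTER = datetime(2020, 2, 10, 12, 0, tzinfo=timezone.utc)


class TestMeanPolarity:
    def test_single_tweet_mean_is_its_score(self, lexicon, scheme, make_tweet):
        scored = _scored(lexicon, make_tweet, ("Krise", {}))  # -0.5034
        cell = mean_polarity(scored, "authority", 2, scheme)
        assert cell.mean_polarity == -0.5034
        assert (cell.n_tweets, cell.n_negative) == (1, 1)

    def test_two_tweet_arithmetic_mean(self, lexicon, scheme, make_tweet):
        # positiv 0.2222 and falsch -0.4463 -> mean (0.2222 - 0.4463) / 2
        scored = _scored(lexicon, make_tweet, ("positiv", {}), ("falsch", {}))
        cell = mean_polarity(scored, "authority", 2, scheme)
        assert cell.mean_polarity == pytest.approx((0.2222 - 0.4463) / 2, rel=1e-12)

    def test_empty_cell_is_an_explicit_error_not_zero(self, lexicon, scheme, make_tweet):
        scored = _scored(lexicon, make_tweet, ("Freude", {}))
        with pytest.raises(EmptyCellError):
            mean_polarity(scored, "expert", 2, scheme)

    def test_neutral_tweets_stay_in_denominator_by_default(
        self, lexicon, scheme, make_tweet
    ):
        scored = _scored(lexicon, make_tweet, ("Freude", {}), ("und oder", {}))
        assert mean_polarity(scored, "authority", 2, scheme).mean_polarity == 0.6502 / 2
        excl = mean_polarity(scored, "authority", 2, scheme, include_neutral=False)
        assert excl.mean_polarity == 0.6502

    def test_overall_mean_decomposes_over_groups(self, lexicon, scheme):
        """All-tweets mean equals the count-weighted mean of per-group means."""
        config = GeneratorConfig(seed=3, n_per_cell={"authority": (120, 0, 0),
                                                     "expert": (80, 0, 0)},
                                 off_topic_fraction=0, non_original_fraction=0,
                                 non_german_fraction=0)
        tweets, _ = generate_corpus(config)
        scored = score_corpus(tweets, lexicon)
        overall = sum(s.score for s in scored) / len(scored)
        parts = [mean_polarity(scored, g, 1, scheme) for g in ("authority", "expert")]
        weighted = sum(p.mean_polarity * p.n_tweets for p in parts) / sum(
            p.n_tweets for p in parts
        )
        assert overall == pytest.approx(weighted, abs=1e-14)

    def test_summary_has_one_row_per_nonempty_cell(self, lexicon, scheme, make_tweet):
        scored = _scored(
            lexicon, make_tweet,
            ("Freude", {"group": "authority", "created_at": WINTER}),
            ("Gefahr", {"group": "expert"}),
        )
        frame = summarize_cells(scored, scheme)
        assert list(map(tuple, frame[["group", "phase_id"]].values)) == [
            ("authority", 1), ("expert", 2),
        ]


class TestTopKWords:
    def test_occurrence_counting_and_ranking(self, lexicon, scheme, make_tweet):
        scored = _scored(
            lexicon, make_tweet,
            ("Risiko Risiko Gefahr", {}),
            ("Risiken und Gefahren", {}),
        )
        assert top_k_words(scored, 2, -1, scheme) == [("risiko", 3), ("gefahr", 2)]

    def test_equal_counts_break_alphabetically(self, lexicon, scheme, make_tweet):
        scored = _scored(lexicon, make_tweet, ("Tod Krise Krise Tod", {}))
        assert top_k_words(scored, 2, -1, scheme) == [("krise", 2), ("tod", 2)]

    def test_truncation_to_distinct_words(self, lexicon, scheme, make_tweet):
        scored = _scored(lexicon, make_tweet, ("Freude gut", {}))
        assert len(top_k_words(scored, 2, 1, scheme, k=5)) == 2

    def test_signs_are_separated(self, lexicon, scheme, make_tweet):
        scored = _scored(lexicon, make_tweet, ("Freude Gefahr", {}))
        assert top_k_words(scored, 2, 1, scheme) == [("freude", 1)]
        assert top_k_words(scored, 2, -1, scheme) == [("gefahr", 1)]

    def test_stable_under_corpus_permutation(self, lexicon, scheme, make_tweet):
        specs = [("Risiko Gefahr", {}), ("Krise", {}), ("Gefahr", {})]
        forward = top_k_words(_scored(lexicon, make_tweet, *specs), 2, -1, scheme)
        backward = top_k_words(_scored(lexicon, make_tweet, *specs[::-1]), 2, -1, scheme)
        assert forward == backward

    def test_groups_pooled_by_default_with_optional_filter(
        self, lexicon, scheme, make_tweet
    ):
        scored = _scored(
            lexicon, make_tweet,
            ("Gefahr", {"group": "authority"}),
            ("Gefahr", {"group": "expert"}),
        )
        assert top_k_words(scored, 2, -1, scheme) == [("gefahr", 2)]
        assert top_k_words(scored, 2, -1, scheme, group="expert") == [("gefahr", 1)]

    def test_csv_writer_emits_ranked_rows(self, lexicon, scheme, make_tweet):
        scored = _scored(lexicon, make_tweet, ("Risiko Gefahr Freude", {}))
        buf = io.StringIO()
        write_top_words_csv(scored, scheme, buf, k=5)
        lines = buf.getvalue().splitlines()
        assert lines[0] == "phase,sign,rank,word,count"
        assert "2,negative,1,gefahr,1" in lines


class TestWeeklySeries:
    def test_counts_within_one_iso_week(self, lexicon, scheme, make_tweet):
        when = datetime(2020, 3, 18, 12, 0, tzinfo=timezone.utc)  # ISO week 2020-W12
        scored = _scored(
            lexicon, make_tweet,
            *[("Freude", {"created_at": when})] * 3,
            *[("Gefahr", {"created_at": when})] * 2,
        )
        frame = weekly_series(scored)
        assert len(frame) == 1
        row = frame.iloc[0]
        assert (row["iso_week"], row["n_positive"], row["n_negative"]) == (
            "2020-W12", 3, 2,
        )

    def test_incidence_sampled_on_thursday_and_divided_by_100(
        self, lexicon, make_tweet
    ):
        when = datetime(2020, 3, 18, 12, 0, tzinfo=timezone.utc)
        scored = _scored(lexicon, make_tweet, ("Freude", {"created_at": when}))
        frame = weekly_series(scored, incidence=[(date(2020, 3, 19), 1500)])
        assert frame.iloc[0]["incidence_scaled"] == 15.0

    def test_empty_corpus_gives_empty_series(self):
        assert weekly_series([]).empty

    def test_neutral_tweets_enter_neither_count(self, lexicon, make_tweet):
        scored = _scored(lexicon, make_tweet, ("nur neutrale Worte", {}))
        frame = weekly_series(scored)
        assert frame.iloc[0][["n_positive", "n_negative"]].tolist() == [0, 0]

    def test_weekly_counts_sum_to_sign_class_totals(self, lexicon):
        config = GeneratorConfig(seed=5, n_per_cell={"authority": (60, 60, 60),
                                                     "expert": (60, 60, 60)},
                                 off_topic_fraction=0, non_original_fraction=0,
                                 non_german_fraction=0)
        tweets, _ = generate_corpus(config)
        scored = score_corpus(tweets, lexicon)
        frame = weekly_series(scored)
        classes = [s.sign_class for s in scored]
        assert frame["n_positive"].sum() == classes.count("positive")
        assert frame["n_negative"].sum() == classes.count("negative")
        # weeks strictly increasing
        assert list(frame["iso_week"]) == sorted(set(frame["iso_week"]))


class TestReadIncidence:
    def test_rows_sorted_by_date(self):
        csv = "date,count\n2020-03-03,30\n2020-03-01,10\n2020-03-02,20\n"
        series = read_incidence(io.StringIO(csv))
        assert [d for d, _ in series] == [date(2020, 3, i) for i in (1, 2, 3)]

    def test_duplicate_date_rejected(self):
        csv = "date,count\n2020-03-01,10\n2020-03-01,20\n"
        with pytest.raises(ValueError, match="duplicate"):
            read_incidence(io.StringIO(csv))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            read_incidence(io.StringIO("date,count\n2020-03-01,-5\n"))

    def test_generated_curve_round_trips_with_length_preserved(self, tmp_path):
        series = generate_incidence(GeneratorConfig())
        assert len(series) == (date(2021, 1, 15) - date(2020, 1, 1)).days + 1
        path = tmp_path / "incidence.csv"
        path.write_text(
            "date,count\n" + "".join(f"{d},{c}\n" for d, c in series), encoding="utf-8"
        )
        assert read_incidence(path) == series


def test_scored_table_columns_and_phases(lexicon, scheme, make_tweet):
    st = score_tweet(make_tweet(text="Freude! #Corona"), lexicon)
    frame = scored_table([st], scheme)
    assert list(frame.columns) == [
        "id", "group", "phase", "score", "sign_class", "n_tokens", "n_matches",
    ]
    assert frame.iloc[0]["phase"] == 2 and frame.iloc[0]["score"] == 0.6502
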