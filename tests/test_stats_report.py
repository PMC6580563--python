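"""Statistics accumulation, merging and report rendering."""

import json
import random

import numpy as np
import pytest

from fqprep.adapter_align import AdapterMatch, AdapterSpec
from fqprep.stats_report import (
    MULTI_KEY,
    RunStats,
    StreamPanel,
    accumulate,
    merge,
    render,
    render_html,
    render_text,
    _quantiles_from_counts,
)
from fqprep.trim_filter import FilterCriterion, ReadVerdict

from conftest import make_record


def passing(rec):
    return ReadVerdict(record=rec)


def failing(rec, *criteria):
    return ReadVerdict(record=rec, failed_criteria=frozenset(criteria))


def random_stats(seed, n=200):
    r = random.Random(seed)
    stats = RunStats()
    for i in range(n):
        L = r.randint(0, 30)
        rec = make_record(
            "".join(r.choice("ACGTN") for _ in range(L)),
            [r.randint(0, 41) for _ in range(L)],
            rid=f"s{i}",
        )
        roll = r.random()
        if roll < 0.6:
            v = passing(rec)
        elif roll < 0.8:
            v = failing(rec, FilterCriterion.N_RATIO)
        else:
            v = failing(rec, FilterCriterion.TOO_SHORT, FilterCriterion.QUALITY)
        if r.random() < 0.3:
            L2 = max(L, 5)
            v = ReadVerdict(
                record=v.record,
                failed_criteria=v.failed_criteria,
                adapter=AdapterSpec("ACGTA"),
                adapter_match=AdapterMatch(0, 5, 0, 5, 0, 5),
            )
        accumulate(stats, v, rec)
    return stats


class TestAccumulate:
    def test_passing_read_counted_both_sides(self):
        stats = RunStats()
        rec = make_record("ACGT")
        accumulate(stats, passing(rec), rec)
        assert stats.before.length_hist[4] == 1
        assert stats.after.length_hist[4] == 1

    def test_single_criterion_counted_alone(self):
        stats = RunStats()
        rec = make_record("ANNA")
        accumulate(stats, failing(rec, FilterCriterion.N_RATIO), rec)
        assert stats.filter_counts["n_ratio"] == 1
        assert stats.filter_counts[MULTI_KEY] == 0
        assert stats.after.reads == 0

    def test_multi_criterion_counted_as_plus_only(self):
        stats = RunStats()
        rec = make_record("A")
        accumulate(
            stats, failing(rec, FilterCriterion.TOO_SHORT, FilterCriterion.QUALITY), rec
        )
        assert stats.filter_counts[MULTI_KEY] == 1
        assert stats.filter_counts["too_short"] == 0
        assert stats.filter_counts["quality_filter"] == 0

    def test_adapter_overlap_histogram_uses_aligned_length(self):
        stats = RunStats()
        rec = make_record("ACGTACGT")
        v = ReadVerdict(
            record=rec.slice(0, 3),
            adapter=AdapterSpec("ACGTA"),
            adapter_match=AdapterMatch(3, 8, 0, 5, 0, 5),
        )
        accumulate(stats, v, rec)
        assert stats.adapter_hist == {5: 1}

    def test_invariants_on_random_stream(self):
        stats = random_stats(7)
        d = stats.to_dict()
        # position-p base counts sum to reads of length > p
        depth = stats.before.base_counts.sum(axis=1)
        longer = [
            sum(v for k, v in stats.before.length_hist.items() if k > p)
            for p in range(stats.before.base_counts.shape[0])
        ]
        assert depth.tolist() == longer
        assert sum(stats.before.length_hist.values()) == stats.before.reads
        assert sum(d["filter_counts"].values()) == stats.reads_filtered
        for side in ("before", "after"):
            assert sum(d[side]["base_percent"].values()) == pytest.approx(100.0)


class TestMerge:
    def test_identity(self):
        stats = random_stats(1)
        assert merge(stats, RunStats()) == stats

    def test_commutative(self):
        a, b = random_stats(2), random_stats(3, n=120)
        assert merge(a, b) == merge(b, a)

    def test_merge_of_chunk_stats_equals_whole_file_stats(self):
        r = random.Random(11)
        recs = []
        for i in range(120):
            L = r.randint(0, 25)
            recs.append(make_record("".join(r.choice("ACGTN") for _ in range(L)),
                                    [r.randint(0, 41) for _ in range(L)], rid=f"c{i}"))
        whole = RunStats()
        for rec in recs:
            accumulate(whole, passing(rec), rec)
        chunked = RunStats()
        for k in range(4):
            part = RunStats()
            for rec in recs[k * 30 : (k + 1) * 30]:
                accumulate(part, passing(rec), rec)
            chunked = merge(chunked, part)
        assert chunked == whole

    def test_associative(self):
        recs = [random_stats(10 + i, n=50) for i in range(4)]
        total = RunStats()
        for s in recs:
            total = merge(total, s)
        alt = merge(merge(recs[0], recs[1]), merge(recs[2], recs[3]))
        assert total == alt


class TestQuantiles:
    def test_against_numpy_on_expanded_data(self, rng):
        for _ in range(50):
            counts = np.zeros(42, dtype=np.int64)
            for _ in range(rng.randint(1, 60)):
                counts[rng.randint(0, 41)] += 1
            values = np.repeat(np.arange(42), counts)
            got = _quantiles_from_counts(counts, (0.25, 0.5, 0.75))
            want = np.percentile(values, [25, 50, 75])
            assert got == pytest.approx(list(want))


class TestRender:
    def test_json_round_trip_lossless(self, tmp_path):
        stats = random_stats(5)
        path = render(stats, "json", tmp_path / "r.json")
        back = RunStats.from_dict(json.load(open(path)))
        assert back == stats

    def test_zero_stats_valid_json(self, tmp_path):
        path = render(RunStats(), "json", tmp_path / "zero.json")
        d = json.load(open(path))
        assert d["totals"]["reads_in"] == 0
        assert all(v == 0 for v in d["filter_counts"].values())

    def test_text_base_percent_sums_to_100(self):
        text = render_text(random_stats(6))
        assert "sum 100.0%" in text

    def test_html_payload_equals_json(self, tmp_path):
        stats = random_stats(8)
        html_doc = render_html(stats)
        marker = '<script type="application/json" id="report-data">'
        start = html_doc.index(marker) + len(marker)
        stop = html_doc.index("</script>", start)
        payload = json.loads(html_doc[start:stop])
        assert payload == stats.to_dict()
        assert "<svg" in html_doc

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            render(RunStats(), "pdf", tmp_path / "x")
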