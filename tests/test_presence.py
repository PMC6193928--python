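import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from driftwatch.errors import DriftwatchError
from driftwatch.presence import (
    EligibilityRules,
    apply_eligibility,
    hourly_bins,
    presence_matrix,
    segment_bouts,
)

from conftest import utc


def _events(times, tag="a"):
    return pd.DataFrame(
        {"timestamp": list(times), "antenna_id": 1, "tag_code": tag}
    )


def oracle_partition(offsets_s: np.ndarray, gap_s: float) -> list[list[int]]:
    """Independent O(n²) chaining oracle: connected components of the
    pairwise |ti - tj| <= gap graph (for sorted inputs this equals the
    bout partition)."""
    n = len(offsets_s)
    adj = np.abs(offsets_s[:, None] - offsets_s[None, :]) <= gap_s
    ncomp, labels = connected_components(csr_matrix(adj), directed=False)
    return [sorted(np.flatnonzero(labels == c)) for c in range(ncomp)]


class TestSegmentBouts:
    def test_two_hour_gap_rule_splits_at_long_silence(self):
        t0 = utc("2017-04-01T00:00:00")
        ev = _events([t0, t0 + pd.Timedelta(hours=1), t0 + pd.Timedelta(hours=4)])
        b = segment_bouts(ev)
        assert len(b) == 2
        assert b["start"].iloc[0] == t0
        assert b["end"].iloc[0] == t0 + pd.Timedelta(hours=1)
        assert b["start"].iloc[1] == b["end"].iloc[1] == t0 + pd.Timedelta(hours=4)

    def test_gap_of_exactly_two_hours_merges(self):
        t0 = utc("2017-04-01T00:00:00")
        b = segment_bouts(_events([t0, t0 + pd.Timedelta(hours=2)]))
        assert len(b) == 1 and b["n_detections"].iloc[0] == 2

    def test_unsorted_input_is_a_programming_error(self):
        t0 = utc("2017-04-01T00:00:00")
        ev = _events([t0 + pd.Timedelta(hours=1), t0])
        with pytest.raises(DriftwatchError, match="sorted"):
            segment_bouts(ev)

    def test_antennas_pooled_into_metadata(self):
        t0 = utc("2017-04-01T00:00:00")
        ev = _events([t0, t0 + pd.Timedelta(minutes=30)])
        ev["antenna_id"] = [3, 1]
        b = segment_bouts(ev)
        assert b["antennas_seen"].iloc[0] == (1, 3)

    @given(
        st.lists(
            st.floats(min_value=0, max_value=200, allow_nan=False),
            min_size=1,
            max_size=300,
        ),
        st.floats(min_value=0.5, max_value=10),
    )
    def test_matches_pairwise_chaining_oracle(self, offsets_h, gap_h):
        offsets = np.sort(np.asarray(offsets_h, dtype=float))
        t0 = utc("2017-04-01T00:00:00")
        ev = _events([t0 + pd.Timedelta(hours=h) for h in offsets])
        b = segment_bouts(ev, pd.Timedelta(hours=gap_h))
        expected = oracle_partition(offsets * 3600.0, gap_h * 3600.0)
        got = []
        i = 0
        for _, row in b.iterrows():
            got.append(list(range(i, i + row["n_detections"])))
            i += row["n_detections"]
        assert got == expected

    @given(
        st.lists(
            st.floats(min_value=0, max_value=100, allow_nan=False),
            min_size=1,
            max_size=150,
        )
    )
    def test_partition_and_gap_monotonicity(self, offsets_h):
        t0 = utc("2017-04-01T00:00:00")
        ev = _events(sorted(t0 + pd.Timedelta(hours=h) for h in offsets_h))
        small = segment_bouts(ev, pd.Timedelta(hours=1))
        large = segment_bouts(ev, pd.Timedelta(hours=3))
        assert small["n_detections"].sum() == len(ev)  # every detection in one bout
        assert len(large) <= len(small)


class TestEligibility:
    REG = pd.DataFrame(
        {
            "tag_code": ["A", "B", "M", "L"],
            "species": ["asp", "bleak", "asp", "bleak"],
            "sex": ["female", "unknown", "male", "unknown"],
            "tagging_date": [
                utc("2016-04-01"),
                utc("2017-03-30"),
                utc("2015-04-01"),
                utc("2017-04-04T12:00:00"),
            ],
        }
    )

    def _bout(self, tag, start_s, hours=1):
        s = utc(start_s)
        return dict(
            tag_code=tag,
            start=s,
            end=s + pd.Timedelta(hours=hours),
            n_detections=5,
            antennas_seen=(1,),
        )

    def test_same_season_asp_excluded_next_year_included(self):
        bouts = pd.DataFrame(
            [self._bout("A", "2016-04-05"), self._bout("A", "2017-04-05")]
        )
        kept, _ = apply_eligibility(bouts, self.REG)
        assert list(kept["start"].dt.year) == [2017]

    def test_bleak_included_from_one_day_after_tagging(self):
        bouts = pd.DataFrame(
            [self._bout("B", "2017-03-30T12:00:00"), self._bout("B", "2017-03-31")]
        )
        kept, _ = apply_eligibility(bouts, self.REG)
        assert len(kept) == 1 and kept["start"].iloc[0] == utc("2017-03-31")

    def test_male_asp_excluded_from_egg_modelling(self):
        bouts = pd.DataFrame([self._bout("M", "2017-04-05")])
        kept, _ = apply_eligibility(bouts, self.REG, for_eggs=True)
        assert kept.empty
        kept2, _ = apply_eligibility(bouts, self.REG, for_eggs=False)
        assert len(kept2) == 1

    def test_unknown_tags_reported_as_orphans(self):
        bouts = pd.DataFrame([self._bout("ZZZ", "2017-04-05")])
        kept, orphans = apply_eligibility(bouts, self.REG)
        assert kept.empty and len(orphans) == 1

    def test_bouts_clipped_to_season_window(self):
        bouts = pd.DataFrame([self._bout("A", "2017-04-01T23:00:00", hours=3)])
        windows = [(utc("2017-03-25"), utc("2017-04-02"))]
        kept, _ = apply_eligibility(bouts, self.REG, season_windows=windows)
        assert kept["end"].iloc[0] == utc("2017-04-02")


class TestPresenceMatrix:
    def test_partial_bin_overlap_geometry(self):
        bins = pd.date_range(utc("2017-04-01"), periods=24, freq="1h")
        bouts = pd.DataFrame(
            [
                dict(
                    tag_code="a",
                    start=utc("2017-04-01T10:30:00"),
                    end=utc("2017-04-01T12:30:00"),
                    n_detections=9,
                    antennas_seen=(1,),
                )
            ]
        )
        m = presence_matrix(bouts, bins)
        assert m.loc[utc("2017-04-01T10:00:00"), "a"] == 0.5
        assert m.loc[utc("2017-04-01T11:00:00"), "a"] == 1.0
        assert m.loc[utc("2017-04-01T12:00:00"), "a"] == 0.5
        assert m["a"].sum() == 2.0

    def test_zero_duration_bout_counts_as_full_bin_membership(self):
        bins = pd.date_range(utc("2017-04-01"), periods=24, freq="1h")
        t = utc("2017-04-01T10:15:00")
        bouts = pd.DataFrame(
            [dict(tag_code="a", start=t, end=t, n_detections=1, antennas_seen=(2,))]
        )
        m = presence_matrix(bouts, bins)
        assert m.loc[utc("2017-04-01T10:00:00"), "a"] == 1.0
        assert m["a"].sum() == 1.0

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0, max_value=20, allow_nan=False),
                st.floats(min_value=0.01, max_value=6, allow_nan=False),
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_row_sums_recover_total_duration_for_disjoint_bouts(self, raw):
        t0 = utc("2017-04-01T00:00:00")
        rows, cursor = [], 0.0
        for off, dur in raw:
            start = cursor + off + 0.01
            rows.append(
                dict(
                    tag_code="a",
                    start=t0 + pd.Timedelta(hours=start),
                    end=t0 + pd.Timedelta(hours=start + dur),
                    n_detections=2,
                    antennas_seen=(1,),
                )
            )
            cursor = start + dur
        bouts = pd.DataFrame(rows)
        bins = pd.date_range(t0, periods=int(cursor) + 2, freq="1h")
        m = presence_matrix(bouts, bins)
        total_h = sum(
            (b["end"] - b["start"]).total_seconds() / 3600 for _, b in bouts.iterrows()
        )
        assert np.isclose(m["a"].sum(), total_h, rtol=1e-9)
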