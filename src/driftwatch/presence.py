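"""Presence-bout reconstruction and eligibility filtering.

A fish is considered continuously present while successive detections are no
more than a gap threshold apart (2 h by default); a longer silence marks
departure, and the last detection before it closes the bout. Detections from
any of the three antennas are pooled as a proxy for presence on the spawning
ground; antenna identity is kept only as bout metadata.

Eligibility mirrors the differing lifespans of the two species: long-lived
asp are analysed only from one year after tagging (behaviour in the tagging
season is disturbed by capture and surgery), short-lived bleak from one day
after tagging. Male asp are excluded from egg modelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from driftwatch.errors import DriftwatchError, InvalidParameterError

BOUT_COLUMNS = ("tag_code", "start", "end", "n_detections", "antennas_seen")


@dataclass(frozen=True)
class EligibilityRules:
    """Species-specific minimum tag-to-detection lags and sexes kept for eggs."""

    asp_min_lag: pd.Timedelta = pd.Timedelta(days=365)
    bleak_min_lag: pd.Timedelta = pd.Timedelta(days=1)
    sexes_kept_for_eggs: tuple[str, ...] = ("female",)

    def __post_init__(self) -> None:
        if self.asp_min_lag < pd.Timedelta(0) or self.bleak_min_lag < pd.Timedelta(0):
            raise InvalidParameterError("eligibility lags must be non-negative")


def segment_bouts(
    events: pd.DataFrame,
    gap_threshold: pd.Timedelta = pd.Timedelta(hours=2),
) -> pd.DataFrame:
    """Split each individual's detection stream into presence bouts.

    Consecutive detections with an inter-detection gap <= ``gap_threshold``
    (inclusive boundary) share a bout. Bout start/end are the first/last
    detection instants, so a bout containing one detection has zero duration
    but is retained.

    Parameters
    ----------
    events
        Canonical detection events; must be sorted by time within each tag.
    gap_threshold
        Maximum silence that still counts as presence (> 0).

    Returns
    -------
    DataFrame with columns ``tag_code, start, end, n_detections,
    antennas_seen`` (sorted tuple of antenna ids), ordered by tag then start.
    """
    if gap_threshold <= pd.Timedelta(0):
        raise InvalidParameterError("gap_threshold must be positive")
    rows: list[tuple] = []
    gap_ns = gap_threshold.value
    for tag, grp in events.groupby("tag_code", sort=True):
        t = grp["timestamp"].to_numpy(dtype="datetime64[ns]").astype(np.int64)
        if np.any(np.diff(t) < 0):
            raise DriftwatchError(f"events for tag {tag} are not sorted by time")
        ants = grp["antenna_id"].to_numpy()
        # bout breaks where the silence exceeds the threshold
        breaks = np.flatnonzero(np.diff(t) > gap_ns) + 1
        for seg in np.split(np.arange(len(t)), breaks):
            rows.append(
                (
                    tag,
                    pd.Timestamp(t[seg[0]], unit="ns", tz="UTC"),
                    pd.Timestamp(t[seg[-1]], unit="ns", tz="UTC"),
                    len(seg),
                    tuple(sorted(set(ants[seg].tolist()))),
                )
            )
    return pd.DataFrame(rows, columns=list(BOUT_COLUMNS))


class EligibleBouts(NamedTuple):
    bouts: pd.DataFrame
    orphans: pd.DataFrame


def apply_eligibility(
    bouts: pd.DataFrame,
    registry: pd.DataFrame,
    rules: EligibilityRules = EligibilityRules(),
    season_windows: Iterable[tuple[pd.Timestamp, pd.Timestamp]] | None = None,
    for_eggs: bool = True,
) -> EligibleBouts:
    """Filter bouts by species-specific tagging lag, sex and season window.

    Asp bouts are kept only if ``start - tagging_date >= asp_min_lag``;
    bleak bouts only if the lag is at least ``bleak_min_lag``. With
    ``for_eggs`` true, asp are additionally restricted to the sexes in
    ``rules.sexes_kept_for_eggs`` (females by default). Bouts whose tag is
    absent from the registry go to the ``orphans`` report instead of raising.
    Bouts straddling a season boundary are clipped to the window.
    """
    reg = registry.set_index("tag_code")
    known = bouts["tag_code"].isin(reg.index)
    orphans = bouts.loc[~known].copy()
    kept = bouts.loc[known].copy()
    if kept.empty:
        return EligibleBouts(kept.reset_index(drop=True), orphans.reset_index(drop=True))

    species = kept["tag_code"].map(reg["species"]).to_numpy()
    sex = kept["tag_code"].map(reg["sex"]).to_numpy()
    tagged = pd.DatetimeIndex(kept["tag_code"].map(reg["tagging_date"]))
    if tagged.tz is not None:
        tagged = tagged.tz_convert(None)
    lag = kept["start"].to_numpy(dtype="datetime64[ns]") - tagged.to_numpy()

    is_asp = species == "asp"
    ok = np.where(
        is_asp,
        lag >= rules.asp_min_lag.to_timedelta64(),
        lag >= rules.bleak_min_lag.to_timedelta64(),
    )
    if for_eggs:
        ok &= ~is_asp | np.isin(sex, rules.sexes_kept_for_eggs)
    kept = kept.loc[ok]

    if season_windows is not None:
        clipped = []
        for _, b in kept.iterrows():
            for w0, w1 in season_windows:
                if b["end"] >= w0 and b["start"] < w1:
                    row = b.copy()
                    row["start"] = max(b["start"], w0)
                    row["end"] = min(b["end"], w1)
                    clipped.append(row)
                    break
        kept = (
            pd.DataFrame(clipped, columns=kept.columns)
            if clipped
            else kept.iloc[0:0]
        )
    return EligibleBouts(kept.reset_index(drop=True), orphans.reset_index(drop=True))


def hourly_bins(
    season_windows: Iterable[tuple[pd.Timestamp, pd.Timestamp]],
    bin_width: pd.Timedelta = pd.Timedelta(hours=1),
) -> pd.DatetimeIndex:
    """Contiguous bin-start grid (aligned to whole UTC hours) covering each window."""
    parts = []
    for w0, w1 in season_windows:
        parts.append(pd.date_range(w0.floor(bin_width), w1, freq=bin_width, inclusive="left"))
    return parts[0].append(parts[1:]) if len(parts) > 1 else parts[0]


def _overlap_per_bin(
    start: pd.Timestamp,
    end: pd.Timestamp,
    bins: np.ndarray,
    width_ns: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Overlap seconds of [start, end] with each hit bin; returns (idx, seconds)."""
    s, e = start.value, end.value
    lo = max(np.searchsorted(bins, s, side="right") - 1, 0)
    hi = np.searchsorted(bins, e, side="right")
    idx = np.arange(lo, hi)
    if len(idx) == 0:
        return idx, np.zeros(0)
    b0 = bins[idx]
    ov = np.minimum(e, b0 + width_ns) - np.maximum(s, b0)
    ov = np.clip(ov, 0, None) / 1e9
    keep = ov > 0
    return idx[keep], ov[keep]


def presence_matrix(
    bouts: pd.DataFrame,
    bins: pd.DatetimeIndex,
    bin_width: pd.Timedelta = pd.Timedelta(hours=1),
) -> pd.DataFrame:
    """Per-individual, per-bin fractional presence in [0, 1].

    The entry is the fraction of the bin covered by the individual's bouts.
    A zero-duration bout (single detection) counts as full membership of its
    containing bin — the animal was demonstrably there. Values are capped at
    1 when several bouts of one individual touch the same bin.
    """
    width_ns = bin_width.value
    bin_ns = bins.to_numpy(dtype="datetime64[ns]").astype(np.int64)
    tags = sorted(bouts["tag_code"].unique())
    mat = pd.DataFrame(0.0, index=bins, columns=tags)
    col_of = {t: i for i, t in enumerate(tags)}
    arr = mat.to_numpy()
    for _, b in bouts.iterrows():
        j = col_of[b["tag_code"]]
        if b["end"] == b["start"]:
            i = np.searchsorted(bin_ns, b["start"].value, side="right") - 1
            if 0 <= i < len(bin_ns) and bin_ns[i] <= b["start"].value < bin_ns[i] + width_ns:
                arr[i, j] = 1.0
            continue
        idx, ov = _overlap_per_bin(b["start"], b["end"], bin_ns, width_ns)
        arr[idx, j] += ov / (width_ns / 1e9)
    np.clip(arr, 0.0, 1.0, out=arr)
    mat.iloc[:, :] = arr
    return mat
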