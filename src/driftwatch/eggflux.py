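"""Uniform egg allocation over female presence time and day/night shares.

Each female's estimated egg output is spread at a single constant rate over
the union of her presence bouts within the season ("time spent on the
spawning ground"), so a bout twice as long receives twice the eggs. The
binned series conserves the total exactly: per-bin overlaps are normalized
by their sum before multiplying by fecundity.

Day/night shares are reported as a mean ± SD over groups — season days for
the egg series (dispersion across nights of the season) and individuals for
predator presence (dispersion across fish). Bins straddling sunrise/sunset
contribute fractionally via the day-fraction weights rather than a majority
label, avoiding boundary bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from driftwatch.errors import DriftwatchError, InvalidParameterError
from driftwatch.presence import _overlap_per_bin


def allocate_eggs(
    bouts: pd.DataFrame,
    fecundity_by_tag: pd.Series,
    bins: pd.DatetimeIndex,
    bin_width: pd.Timedelta = pd.Timedelta(hours=1),
) -> tuple[pd.Series, pd.DataFrame]:
    """Distribute each female's eggs evenly over her bouts into hourly bins.

    Parameters
    ----------
    bouts
        Eligible female bouts (already clipped to the season).
    fecundity_by_tag
        Egg count per tag_code; tags without bouts are skipped with a warning.

    Returns
    -------
    (total, per_female)
        ``total`` — eggs per bin summed over females, indexed by bin start;
        ``per_female`` — the same disaggregated, one column per female.
        For each female the column sums to her fecundity to within float
        round-off (normalized allocation).
    """
    width_ns = bin_width.value
    bin_ns = bins.to_numpy(dtype="datetime64[ns]").astype(np.int64)
    tags = [t for t in fecundity_by_tag.index if t in set(bouts["tag_code"])]
    missing = sorted(set(fecundity_by_tag.index) - set(tags))
    if missing:
        warnings.warn(
            f"{len(missing)} female(s) with fecundity but no bouts skipped: "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
    per = pd.DataFrame(0.0, index=bins, columns=tags)
    arr = per.to_numpy()
    col_of = {t: j for j, t in enumerate(tags)}
    # raw per-bin overlap seconds per female; zero-duration bouts count as
    # one unit of membership in their containing bin
    for _, b in bouts.iterrows():
        tag = b["tag_code"]
        if tag not in col_of:
            continue
        j = col_of[tag]
        if b["end"] == b["start"]:
            i = np.searchsorted(bin_ns, b["start"].value, side="right") - 1
            if 0 <= i < len(bin_ns) and bin_ns[i] <= b["start"].value < bin_ns[i] + width_ns:
                arr[i, j] += 1e-9  # placeholder weight, only used if total duration is 0
            continue
        idx, ov = _overlap_per_bin(b["start"], b["end"], bin_ns, width_ns)
        arr[idx, j] += ov
    col_sums = arr.sum(axis=0)
    for tag, j in col_of.items():
        total = col_sums[j]
        if total <= 0:
            raise DriftwatchError(f"female {tag} has bouts but zero allocatable time")
        arr[:, j] *= float(fecundity_by_tag[tag]) / total
    per.iloc[:, :] = arr
    return per.sum(axis=1).rename("eggs"), per


@dataclass(frozen=True)
class NightShare:
    """Mean ± SD of per-group night percentages, with bookkeeping."""

    mean_pct: float
    sd_pct: float
    n_groups: int
    n_excluded: int
    per_group: pd.Series


def night_share(
    values: pd.Series,
    night_weight: pd.Series,
    groups: pd.Series,
) -> NightShare:
    """Night percentage of a non-negative series, summarized over groups.

    For each group g: pct_g = 100·Σ(night_weight·value)/Σ(value). Groups with
    zero total are excluded (and counted) rather than producing NaN. The
    result is invariant to rescaling ``values`` by any positive constant.

    ``values``, ``night_weight`` and ``groups`` must share an index;
    ``night_weight`` is 1 − day fraction of the bin (fractional at the
    sunrise/sunset bins).
    """
    if (values < 0).any():
        raise InvalidParameterError("night_share requires non-negative values")
    df = pd.DataFrame({"v": values, "nw": night_weight, "g": groups})
    tot = df.groupby("g")["v"].sum()
    night = (df["v"] * df["nw"]).groupby(df["g"]).sum()
    nonzero = tot > 0
    n_excluded = int((~nonzero).sum())
    if not nonzero.any():
        return NightShare(float("nan"), float("nan"), 0, n_excluded, pd.Series(dtype=float))
    pct = 100.0 * night[nonzero] / tot[nonzero]
    sd = float(pct.std(ddof=1)) if len(pct) > 1 else 0.0
    return NightShare(float(pct.mean()), sd, int(len(pct)), n_excluded, pct)
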