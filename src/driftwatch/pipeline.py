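"""End-to-end orchestration: ingest → bouts → biomass → egg flux → diel → models.

:func:`run` drives the full analysis on in-memory inputs and returns a
:class:`PipelineResult`; :func:`run_pipeline` wraps it with file IO, writes
the CSV/JSON output bundle and a reproducibility manifest. Both are
deterministic given the configuration (the only stochastic step, the
permutation p-value of Kendall's tau, is seeded from the config).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd

from driftwatch import __version__, biomass, diel, eggflux, mixedstats, presence
from driftwatch.errors import DriftwatchError, InsufficientDataError
from driftwatch.telemetry_io import (
    Dialect,
    read_detections,
    read_registry,
    read_temperature,
)

EGG_MODEL_FIXED = ("date", "bleak_presence", "period_night", "temp_c")
BLEAK_MODEL_FIXED = ("date", "eggs", "period_night", "temp_c")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, YAML-serializable."""

    detections: str = "detections.csv"
    registry: str = "registry.csv"
    temperature: str = "temperature.csv"
    season_windows: list[tuple[str, str]] = field(default_factory=list)
    gap_hours: float = 2.0
    bin_minutes: int = 60
    dedupe_spacing_s: float = 1.0
    latitude: float = diel.SITE_LATITUDE
    longitude: float = diel.SITE_LONGITUDE
    zenith: float = diel.ZENITH_OFFICIAL
    asp_min_lag_days: float = 365.0
    bleak_min_lag_days: float = 1.0
    lw_a: float = 0.00744
    lw_b: float = 3.046
    gsi: float = 0.12
    egg_mass_g: float = 0.0035
    scale_response: bool = True
    stepwise: bool = True
    fit_models: bool = True
    seed: int = 0
    outdir: str = "out"

    def windows(self) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
        if not self.season_windows:
            raise DriftwatchError("season_windows must be configured")
        return [
            (pd.Timestamp(a, tz="UTC"), pd.Timestamp(b, tz="UTC"))
            for a, b in self.season_windows
        ]


@dataclass
class PipelineResult:
    bouts_asp: pd.DataFrame
    bouts_bleak: pd.DataFrame
    females: pd.DataFrame
    egg_series: pd.Series
    egg_per_female: pd.DataFrame
    bleak_matrix: pd.DataFrame
    day_frac: pd.Series
    egg_night: eggflux.NightShare
    bleak_night: eggflux.NightShare
    egg_table: pd.DataFrame
    bleak_table: pd.DataFrame
    egg_fit: mixedstats.LmmFit | None
    bleak_fit: mixedstats.LmmFit | None
    egg_trace: list
    bleak_trace: list
    kendall: tuple[float, float]
    growth: biomass.GrowthParams
    summary: dict


def _model_table(fit: mixedstats.LmmFit | None) -> dict:
    if fit is None:
        return {"skipped": True}
    return {
        "terms": {
            k: dict(estimate=v.estimate, se=v.se, df=v.df, t=v.t, p=v.p)
            for k, v in fit.terms.items()
        },
        "r2_marginal": fit.r2_marginal,
        "r2_conditional": fit.r2_conditional,
        "sigma2_f": fit.sigma2_f,
        "sigma2_r": fit.sigma2_r,
        "sigma2_e": fit.sigma2_e,
        "aic": fit.aic,
        "n_obs": fit.n_obs,
        "n_groups": fit.n_groups,
        "singular": fit.singular,
        "fixed": list(fit.fixed),
    }


def _summary_dict(
    egg_night, bleak_night, females, bleak_matrix, orphans, egg_series,
    growth, egg_fit, bleak_fit, kendall,
) -> dict:
    return {
        "egg_night_share_pct": egg_night.mean_pct,
        "egg_night_share_sd_pct": egg_night.sd_pct,
        "egg_night_share_n_days": egg_night.n_groups,
        "bleak_night_share_pct": bleak_night.mean_pct,
        "bleak_night_share_sd_pct": bleak_night.sd_pct,
        "bleak_night_share_n_individuals": bleak_night.n_groups,
        "n_eligible_females": int(len(females)),
        "n_bleak_individuals": int(bleak_matrix.shape[1]),
        "n_orphan_bouts": int(len(orphans)),
        "total_eggs_modelled": float(egg_series.sum()),
        "growth": dataclasses.asdict(growth),
        "egg_model": _model_table(egg_fit),
        "bleak_model": _model_table(bleak_fit),
        "kendall_tau_daily_eggs_vs_bleak": {"tau": kendall[0], "p": kendall[1]},
    }


def run(
    detections: pd.DataFrame,
    registry: pd.DataFrame,
    temperature: pd.DataFrame,
    config: RunConfig,
) -> PipelineResult:
    """Run the full analysis on already-loaded canonical inputs."""
    cfg = config
    windows = cfg.windows()
    bin_width = pd.Timedelta(minutes=cfg.bin_minutes)
    gap = pd.Timedelta(hours=cfg.gap_hours)
    rules = presence.EligibilityRules(
        asp_min_lag=pd.Timedelta(days=cfg.asp_min_lag_days),
        bleak_min_lag=pd.Timedelta(days=cfg.bleak_min_lag_days),
    )

    from driftwatch.telemetry_io import dedupe_detections

    events = dedupe_detections(detections, cfg.dedupe_spacing_s)
    bouts = presence.segment_bouts(events, gap)
    eligible, orphans = presence.apply_eligibility(
        bouts, registry, rules, season_windows=windows, for_eggs=True
    )
    species = registry.set_index("tag_code")["species"]
    is_asp = eligible["tag_code"].map(species) == "asp"
    bouts_asp = eligible.loc[is_asp].reset_index(drop=True)
    bouts_bleak = eligible.loc[~is_asp].reset_index(drop=True)

    # growth fit from scale-aged asp females at first capture
    fem = registry[(registry["species"] == "asp") & (registry["sex"] == "female")]
    aged = fem.dropna(subset=["age_years", "total_length_cm"])
    growth = biomass.fit_growth(aged["age_years"], aged["total_length_cm"])

    # per-female size projection to her season midpoint
    lw = biomass.LengthWeightParams(cfg.lw_a, cfg.lw_b)
    fec_params = biomass.FecundityParams(cfg.gsi, cfg.egg_mass_g)
    mids = {w0.year: w0 + (w1 - w0) / 2 for w0, w1 in windows}
    active_tags = bouts_asp["tag_code"].unique()
    target = {}
    for tag in active_tags:
        yr = bouts_asp.loc[bouts_asp["tag_code"] == tag, "start"].iloc[0].year
        target[tag] = mids.get(yr, list(mids.values())[0])
    females = biomass.project_females(
        registry, growth, pd.Series(target, dtype=object), lw, fec_params
    )

    bins = presence.hourly_bins(windows, bin_width)
    day_frac = diel.day_fraction(bins, bin_width, cfg.latitude, cfg.longitude, cfg.zenith)
    night_w = 1.0 - day_frac

    fec_by_tag = females.set_index("tag_code")["fecundity_eggs"]
    egg_series, per_female = eggflux.allocate_eggs(bouts_asp, fec_by_tag, bins, bin_width)
    bleak_matrix = presence.presence_matrix(bouts_bleak, bins, bin_width)

    dates = pd.Series(bins.date, index=bins)
    egg_night = eggflux.night_share(egg_series, night_w, dates)
    # predator share over individuals: long-format presence with the
    # individual as the grouping unit
    long_v, long_w, long_g = [], [], []
    for ind in bleak_matrix.columns:
        long_v.append(bleak_matrix[ind])
        long_w.append(night_w)
        long_g.append(pd.Series(ind, index=bins))
    if long_v:
        bleak_night = eggflux.night_share(
            pd.concat(long_v, ignore_index=True),
            pd.concat(long_w, ignore_index=True),
            pd.concat(long_g, ignore_index=True),
        )
    else:
        bleak_night = eggflux.NightShare(float("nan"), float("nan"), 0, 0, pd.Series(dtype=float))

    # ---- design matrices and mixed models -----------------------------
    if not cfg.fit_models:
        summary = _summary_dict(
            egg_night, bleak_night, females, bleak_matrix, orphans, egg_series,
            growth, None, None, (float("nan"), float("nan")),
        )
        return PipelineResult(
            bouts_asp, bouts_bleak, females, egg_series, per_female, bleak_matrix,
            day_frac, egg_night, bleak_night, pd.DataFrame(), pd.DataFrame(),
            None, None, [], [], (float("nan"), float("nan")), growth, summary,
        )

    egg_table, _flag1 = mixedstats.build_design(
        egg_series, bleak_matrix, temperature, day_frac, "eggs"
    )
    bleak_table, _flag2 = mixedstats.build_design(
        egg_series, bleak_matrix, temperature, day_frac, "bleak"
    )
    scale_cols_egg = ["date", "bleak_presence", "period_night", "temp_c"] + (
        ["eggs"] if cfg.scale_response else []
    )
    scale_cols_bleak = ["date", "eggs", "period_night", "temp_c"] + (
        ["presence"] if cfg.scale_response else []
    )
    egg_scaled, _ = mixedstats.centre_scale(egg_table, scale_cols_egg)
    bleak_scaled, _ = mixedstats.centre_scale(bleak_table, scale_cols_bleak)

    egg_fit = bleak_fit = None
    egg_trace: list = []
    bleak_trace: list = []
    egg_random = mixedstats.RandomSpec("year")
    bleak_random = mixedstats.RandomSpec("bleak_id", slopes=("date",))
    try:
        if cfg.stepwise:
            _, egg_fit, egg_trace = mixedstats.stepwise_aic(
                egg_scaled, "eggs", EGG_MODEL_FIXED, egg_random
            )
        else:
            egg_fit = mixedstats.fit_lmm(egg_scaled, "eggs", EGG_MODEL_FIXED, egg_random)
    except InsufficientDataError:
        egg_fit = None
    try:
        if cfg.stepwise:
            _, bleak_fit, bleak_trace = mixedstats.stepwise_aic(
                bleak_scaled, "presence", BLEAK_MODEL_FIXED, bleak_random
            )
        else:
            bleak_fit = mixedstats.fit_lmm(
                bleak_scaled, "presence", BLEAK_MODEL_FIXED, bleak_random
            )
    except InsufficientDataError:
        bleak_fit = None

    daily_eggs = egg_series.groupby(pd.Series(bins.date, index=bins)).sum()
    daily_bleak = bleak_matrix.sum(axis=1).groupby(pd.Series(bins.date, index=bins)).sum()
    tau, tau_p = mixedstats.kendall_tau(
        daily_eggs.to_numpy(), daily_bleak.to_numpy(), seed=cfg.seed
    )

    summary = _summary_dict(
        egg_night, bleak_night, females, bleak_matrix, orphans, egg_series,
        growth, egg_fit, bleak_fit, (tau, tau_p),
    )
    return PipelineResult(
        bouts_asp=bouts_asp,
        bouts_bleak=bouts_bleak,
        females=females,
        egg_series=egg_series,
        egg_per_female=per_female,
        bleak_matrix=bleak_matrix,
        day_frac=day_frac,
        egg_night=egg_night,
        bleak_night=bleak_night,
        egg_table=egg_scaled,
        bleak_table=bleak_scaled,
        egg_fit=egg_fit,
        bleak_fit=bleak_fit,
        egg_trace=egg_trace,
        bleak_trace=bleak_trace,
        kendall=(tau, tau_p),
        growth=growth,
        summary=summary,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_fit_csv(fit: mixedstats.LmmFit | None, path: Path) -> None:
    if fit is None:
        path.write_text("term,estimate,se,df,t,p\n")
        return
    rows = [
        f"{k},{v.estimate:.6g},{v.se:.6g},{v.df:.6g},{v.t:.6g},{v.p:.6g}"
        for k, v in fit.terms.items()
    ]
    footer = (
        f"# r2_marginal={fit.r2_marginal:.6g} r2_conditional={fit.r2_conditional:.6g}"
    )
    path.write_text("term,estimate,se,df,t,p\n" + "\n".join(rows) + "\n" + footer + "\n")


def run_pipeline(config: RunConfig, make_plots: bool = True) -> PipelineResult:
    """File-based entry point: read inputs, run, write the output bundle."""
    cfg = config
    det = read_detections(cfg.detections, Dialect())
    registry = read_registry(cfg.registry)
    temperature = read_temperature(cfg.temperature)

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if len(det.rejects):
        det.rejects.to_csv(outdir / "rejects.csv", index=False)

    result = run(det.events, registry, temperature, cfg)

    result.bouts_asp.assign(
        antennas_seen=result.bouts_asp["antennas_seen"].map(
            lambda t: "|".join(map(str, t))
        )
    ).to_csv(outdir / "bouts_asp.csv", index=False)
    result.bouts_bleak.assign(
        antennas_seen=result.bouts_bleak["antennas_seen"].map(
            lambda t: "|".join(map(str, t))
        )
    ).to_csv(outdir / "bouts_bleak.csv", index=False)
    result.females.to_csv(outdir / "biomass.csv", index=False)
    bundle = pd.DataFrame(
        {
            "bin_start": result.egg_series.index,
            "eggs": result.egg_series.to_numpy(),
            "bleak_presence": result.bleak_matrix.sum(axis=1).to_numpy(),
            "day_fraction": result.day_frac.to_numpy(),
        }
    )
    bundle.to_csv(outdir / "eggs_bins.csv", index=False)

    prof_eggs = diel.diel_profile(result.egg_series)
    prof_bleak = diel.diel_profile(result.bleak_matrix.sum(axis=1))
    pd.DataFrame(
        {"hour": range(24), "eggs_mean": prof_eggs.to_numpy(),
         "bleak_mean": prof_bleak.to_numpy()}
    ).to_csv(outdir / "diel_profile.csv", index=False)
    _write_fit_csv(result.egg_fit, outdir / "model_eggs.csv")
    _write_fit_csv(result.bleak_fit, outdir / "model_bleak.csv")

    (outdir / "summary.json").write_text(
        json.dumps(result.summary, indent=1, sort_keys=True, allow_nan=True)
    )
    manifest = {
        "driftwatch_version": __version__,
        "config": dataclasses.asdict(cfg),
        "inputs_sha256": {
            name: _sha256(Path(getattr(cfg, name)))
            for name in ("detections", "registry", "temperature")
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    if make_plots:
        plot_diel_profile(prof_eggs, prof_bleak, outdir / "diel_profile.png")
    return result


def plot_diel_profile(prof_eggs: pd.Series, prof_bleak: pd.Series, path: Path) -> None:
    """Two-series 24-h profile: egg availability and predator presence."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax1 = plt.subplots(figsize=(8, 4))
    ax1.plot(prof_eggs.index, prof_eggs.to_numpy(), "k--", label="asp eggs")
    ax1.set_xlabel("hour of day (UTC)")
    ax1.set_ylabel("mean eggs per hourly bin")
    ax2 = ax1.twinx()
    ax2.plot(prof_bleak.index, prof_bleak.to_numpy(), "b:", label="bleak presence")
    ax2.set_ylabel("mean bleak individuals present")
    fig.legend(loc="upper center", ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
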