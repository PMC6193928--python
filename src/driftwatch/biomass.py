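"""Female size back-projection and fecundity.

Egg output cannot be read off the length recorded at tagging because females
are analysed a year or more later, after another growth increment. The chain
here is:

1. fit a population von Bertalanffy curve L(t) = L∞·(1 − e^(−K·(t − t₀)))
   to the age–length pairs from scale readings at first capture;
2. individualize the curve per female by rescaling L∞ so the curve passes
   exactly through her observed tagging length at her tagging age, then
   evaluate it at the spawning date (a true re-measured length from a
   recapture in the spawning year overrides the prediction);
3. convert length to weight with the allometric relation W = a·TL^b
   (a = 0.00744, b = 3.046, TL in cm, W in g — the coefficient is only
   dimensionally consistent with centimetres);
4. convert weight to an egg count through a gonadosomatic index:
   eggs = GSI·W / egg mass.

GSI and mean egg mass are literature-derived configuration with documented
defaults, not fitted quantities; every downstream *proportion* (diel shares,
z-scored model effects) is invariant to their values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from driftwatch.errors import (
    DriftwatchError,
    InsufficientDataError,
    InvalidParameterError,
)


@dataclass(frozen=True)
class GrowthParams:
    """von Bertalanffy parameters: L∞ (cm), K (1/yr), t₀ (yr)."""

    l_inf: float
    k: float
    t0: float
    resid_sd: float = float("nan")

    def __post_init__(self) -> None:
        if self.l_inf <= 0 or self.k <= 0:
            raise InvalidParameterError("l_inf and k must be positive")


@dataclass(frozen=True)
class LengthWeightParams:
    """W = a·TL^b with TL in cm and W in g."""

    a: float = 0.00744
    b: float = 3.046

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise InvalidParameterError("length-weight coefficient a must be positive")
        if not 2.0 < self.b < 4.0:
            raise InvalidParameterError(f"allometric exponent b={self.b} outside (2, 4)")


@dataclass(frozen=True)
class FecundityParams:
    """Gonad mass fraction of body mass and mean single-egg mass (g)."""

    gsi: float = 0.12
    egg_mass_g: float = 0.0035

    def __post_init__(self) -> None:
        if not 0 < self.gsi < 1:
            raise InvalidParameterError("gsi must lie in (0, 1)")
        if self.egg_mass_g <= 0:
            raise InvalidParameterError("egg_mass_g must be positive")


def vb_length(age_years, l_inf: float, k: float, t0: float):
    """Length-at-age under the von Bertalanffy curve."""
    return l_inf * (1.0 - np.exp(-k * (np.asarray(age_years, dtype=float) - t0)))


def fit_growth(age_years, length_cm) -> GrowthParams:
    """Least-squares von Bertalanffy fit to age–length pairs.

    The initializer is fixed (L∞ = 1.05·max length, K = 0.2, t₀ = 0) so the
    fit is deterministic and order-invariant. Requires at least four distinct
    ages; fewer cannot identify three parameters plus a residual scale.
    """
    age = np.asarray(age_years, dtype=float)
    length = np.asarray(length_cm, dtype=float)
    if age.shape != length.shape:
        raise InvalidParameterError("age and length arrays must have equal shape")
    if np.unique(age).size < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct ages to fit growth, got {np.unique(age).size}"
        )
    if np.any(length <= 0):
        raise InvalidParameterError("lengths must be positive")
    order = np.argsort(age, kind="stable")  # order-invariant objective evaluation
    age, length = age[order], length[order]

    def resid(p):
        return vb_length(age, p[0], p[1], p[2]) - length

    x0 = np.array([1.05 * float(length.max()), 0.2, 0.0])
    sol = least_squares(
        resid,
        x0,
        bounds=([1e-6, 1e-6, -np.inf], [np.inf, np.inf, np.min(age) - 1e-9]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success:
        raise DriftwatchError(f"growth fit failed to converge: {sol.message}")
    dof = max(len(age) - 3, 1)
    resid_sd = float(np.sqrt(np.sum(sol.fun**2) / dof))
    return GrowthParams(*map(float, sol.x), resid_sd=resid_sd)


def project_length(
    tl_tag_cm: float,
    age_tag_years: float,
    elapsed_years: float,
    params: GrowthParams,
    recapture_length_cm: float | None = None,
) -> float:
    """Project a female's length forward along her individualized growth curve.

    The population curve is rescaled through the observed tagging length:
    L∞ᵢ = TL_tag / (1 − e^(−K·(age_tag − t₀))), then evaluated at
    age_tag + elapsed. A measured ``recapture_length_cm`` from the spawning
    year replaces the prediction outright. Zero elapsed time returns the
    tagging length exactly.
    """
    if recapture_length_cm is not None and not math.isnan(recapture_length_cm):
        return float(recapture_length_cm)
    if age_tag_years <= params.t0:
        raise InvalidParameterError(
            f"age at tagging ({age_tag_years}) must exceed t0 ({params.t0})"
        )
    denom = 1.0 - math.exp(-params.k * (age_tag_years - params.t0))
    l_inf_i = tl_tag_cm / denom
    return l_inf_i * (
        1.0 - math.exp(-params.k * (age_tag_years + elapsed_years - params.t0))
    )


def length_to_weight(tl_cm, params: LengthWeightParams = LengthWeightParams()):
    """Allometric weight (g) from total length (cm): W = a·TL^b."""
    tl = np.asarray(tl_cm, dtype=float)
    if np.any(tl <= 0):
        raise InvalidParameterError("total length must be positive")
    out = params.a * tl**params.b
    return float(out) if np.isscalar(tl_cm) else out


def fecundity(weight_g, params: FecundityParams = FecundityParams()):
    """Expected egg count from body weight: eggs = GSI·W / egg mass."""
    w = np.asarray(weight_g, dtype=float)
    if np.any(w <= 0):
        raise InvalidParameterError("weight must be positive")
    out = params.gsi * w / params.egg_mass_g
    return float(out) if np.isscalar(weight_g) else out


def project_females(
    registry: pd.DataFrame,
    params: GrowthParams,
    target_dates: pd.Series,
    lw: LengthWeightParams = LengthWeightParams(),
    fec: FecundityParams = FecundityParams(),
) -> pd.DataFrame:
    """Per-female projected length, weight and fecundity at her target date.

    ``target_dates`` maps tag_code -> spawning-season reference date (UTC).
    A recapture length is used only when the recapture falls in the target
    date's calendar year.
    """
    rows = []
    reg = registry.set_index("tag_code")
    for tag, target in target_dates.items():
        r = reg.loc[tag]
        elapsed = (target - r["tagging_date"]).days / 365.25
        recap = None
        if pd.notna(r["recapture_date"]) and r["recapture_date"].year == target.year:
            recap = float(r["recapture_length_cm"])
        tl = project_length(
            float(r["total_length_cm"]), float(r["age_years"]), elapsed, params, recap
        )
        w = length_to_weight(tl, lw)
        rows.append((tag, tl, w, fecundity(w, fec)))
    return pd.DataFrame(
        rows, columns=["tag_code", "projected_length_cm", "weight_g", "fecundity_eggs"]
    )
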