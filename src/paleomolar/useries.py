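"""Closed-form 230Th/U dating of impure carbonates.

The 230Th clock: in a closed system with no initial 230Th, the measured
(230Th/238U) activity ratio grows towards secular equilibrium as

    a230 = 1 - exp(-l0*t) + (a234 - 1) * l0/(l0 - l4) * (1 - exp(-(l0-l4)*t))

where ``a234`` is the *measured* (234U/238U) activity ratio and ``l0``,
``l4`` are the 230Th and 234U decay constants.  The age is the root of this
equation, found by bisection on (0, 10 Myr].

Detrital thorium: dirty carbonates (flowstones with silt) carry
non-radiogenic 230Th together with 232Th.  Two correction conventions are
supported:

``equilibrium`` (default)
    the detrital fraction carries uranium with its thorium daughters in
    secular equilibrium, so its (230Th/232Th) activity ratio ``r0`` is
    constant in time and the measured a230_238 is corrected by subtracting
    ``r0 * a232_238`` once.  This is the convention under which the isochron
    intercept of the *measured* ratios estimates ``r0`` directly.

``initial``
    the detrital 230Th was incorporated at formation and decays unsupported;
    the correction subtracts ``r0 * a232_238 * exp(-l0*t)`` and the age and
    correction are iterated to convergence (|dt| < 0.01 kyr).

The common detrital ratio of a set of coeval sub-samples is estimated from
the intercept of the (230Th/232Th) vs (234U/232Th) measured-ratio line.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import (AgeEstimate, DecayConstants, NonFiniteAgeError,
                   ValidationError)

__all__ = [
    "USeriesMeasurement", "DetritalAssumption", "DetritalCorrectionResult",
    "WeightedMeanResult", "forward_a230_238", "th230_age", "detrital_correct",
    "fit_detrital_intercept", "weighted_mean", "read_useries_csv",
    "useries_report",
]

_T_MAX_YR = 1.0e7       # upper bracket of the age search, years
_T_TOL_YR = 1.0         # bisection tolerance, years


@dataclass
class USeriesMeasurement:
    """Activity ratios (with 1-sigma errors) of one carbonate sub-sample.

    ``a230_232`` / ``a234_232`` may be ``inf``/``nan`` when 232Th is below
    detection (no detrital component).
    """

    a230_238: float
    a230_238_sd: float
    a234_238: float
    a234_238_sd: float
    a230_232: float = math.inf
    a230_232_sd: float = 0.0
    a234_232: float = math.inf
    a234_232_sd: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("a230_238", "a234_238"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("a230_238_sd", "a234_238_sd", "a230_232_sd", "a234_232_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def a232_238(self) -> float:
        """Measured (232Th/238U) activity ratio, inferred from the Th-normalised
        ratios; 0 when 232Th was not detected."""
        if not math.isfinite(self.a230_232) or self.a230_232 <= 0:
            return 0.0
        return self.a230_238 / self.a230_232


@dataclass(frozen=True)
class DetritalAssumption:
    """Assumed detrital (230Th/232Th) activity ratio with its 1-sigma error."""

    r0: float
    r0_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.r0 < 0 or self.r0_sigma < 0:
            raise ValidationError("r0 and r0_sigma must be >= 0")


def forward_a230_238(t_yr, a234_238, k: DecayConstants = DecayConstants()):
    """Closed-system (230Th/238U) activity ratio after ``t_yr`` years, given
    the *measured* (234U/238U) ratio.  Vectorised in both arguments."""
    l0, l4 = k.lambda_230, k.lambda_234
    t = np.asarray(t_yr, dtype=float)
    a234 = np.asarray(a234_238, dtype=float)
    return (1.0 - np.exp(-l0 * t)
            + (a234 - 1.0) * l0 / (l0 - l4) * (1.0 - np.exp(-(l0 - l4) * t)))


def _solve_age_yr(a230: float, a234: float, k: DecayConstants) -> float:
    """Bisection root of the ingrowth equation; returns years.

    Raises NonFiniteAgeError when no root exists in (0, 10 Myr].
    """
    if a230 < 0 or a234 <= 0:
        raise ValidationError("activity ratios must be positive")
    if a230 == 0.0:
        return 0.0
    lo, hi = 0.0, _T_MAX_YR
    f_lo = -a230                       # forward(0) - a230
    f_hi = float(forward_a230_238(hi, a234, k)) - a230
    if f_hi <= 0:
        raise NonFiniteAgeError(
            f"no age root in (0, {_T_MAX_YR:.0f}] yr for "
            f"a230_238={a230:.4f}, a234_238={a234:.4f} (at/beyond secular equilibrium)")
    while hi - lo > _T_TOL_YR:
        mid = 0.5 * (lo + hi)
        if (float(forward_a230_238(mid, a234, k)) - a230) * f_lo > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def th230_age(meas: USeriesMeasurement, k: DecayConstants = DecayConstants(),
              n_mc: int = 10_000, seed: int | None = None) -> AgeEstimate:
    """230Th/U age of one sub-sample, uncorrected for detrital Th.

    The central age solves the ingrowth equation for the measured ratios;
    the 1-sigma error is the standard deviation of ages recomputed over
    ``n_mc`` Gaussian draws of the two input ratios (seeded).
    """
    t0 = _solve_age_yr(meas.a230_238, meas.a234_238, k) / 1000.0
    sigma = 0.0
    if n_mc > 0 and (meas.a230_238_sd > 0 or meas.a234_238_sd > 0):
        rng = np.random.default_rng(seed)
        a230 = rng.normal(meas.a230_238, meas.a230_238_sd, n_mc)
        a234 = rng.normal(meas.a234_238, meas.a234_238_sd, n_mc)
        ages = _solve_age_vec(a230, a234, k)
        ok = np.isfinite(ages)
        if ok.sum() < 2:
            raise NonFiniteAgeError("Monte-Carlo error propagation failed: "
                                    "nearly all draws are beyond secular equilibrium")
        sigma = float(np.std(ages[ok])) / 1000.0
    return AgeEstimate(age=t0, sigma=sigma, role="direct", unit_label=meas.label)


def _solve_age_vec(a230: np.ndarray, a234: np.ndarray,
                   k: DecayConstants) -> np.ndarray:
    """Vectorised bisection of the ingrowth equation (years; nan = no root)."""
    a230 = np.asarray(a230, float)
    a234 = np.asarray(a234, float)
    bad = (a230 < 0) | (a234 <= 0)
    hi_val = forward_a230_238(_T_MAX_YR, a234, k)
    no_root = (a230 >= hi_val) | bad
    lo = np.zeros_like(a230)
    hi = np.full_like(a230, _T_MAX_YR)
    # 24 halvings reach ~0.6 yr resolution on a 10 Myr bracket
    for _ in range(24):
        mid = 0.5 * (lo + hi)
        below = forward_a230_238(mid, a234, k) < a230
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    out = 0.5 * (lo + hi)
    out[no_root] = np.nan
    return out


@dataclass
class DetritalCorrectionResult:
    """Corrected measurement and age; ``over_corrected`` flags samples whose
    corrected (230Th/238U) went negative (too much assumed detrital 230Th)."""

    measurement: USeriesMeasurement
    age: AgeEstimate
    over_corrected: bool = False
    n_rejected: int = 0

    def __iter__(self):
        return iter((self.measurement, self.age))


def _corrected_a230(a230: float, a232_238: float, r0: float, t_kyr: float,
                    k: DecayConstants, convention: str) -> float:
    if convention == "equilibrium":
        return a230 - r0 * a232_238
    if convention == "initial":
        return a230 - r0 * a232_238 * math.exp(-k.lambda_230 * t_kyr * 1000.0)
    raise ValidationError(f"unknown detrital convention {convention!r}")


def _correct_once(a230: float, a234: float, a232_238: float, r0: float,
                  k: DecayConstants, convention: str) -> float:
    """Self-consistent detritally corrected age (kyr) for one draw.

    Solves a230 = ingrowth(t) + detrital(t) where detrital(t) is the
    non-radiogenic 230Th remaining at age t under the chosen convention
    (constant under 'equilibrium', decaying under 'initial').  The age and
    the correction are mutually consistent at the root (|dt| < 0.01 kyr).
    Returns -inf when the detrital term alone exceeds the measurement at
    every age (over-correction) and nan when the corrected ratio sits
    at/beyond secular equilibrium.
    """
    def h(t_kyr):
        det = r0 * a232_238 if convention == "equilibrium" else \
            r0 * a232_238 * math.exp(-k.lambda_230 * t_kyr * 1000.0)
        return float(forward_a230_238(t_kyr * 1000.0, a234, k)) + det - a230

    t_hi = _T_MAX_YR / 1000.0
    grid = np.concatenate([[0.0], np.geomspace(0.01, t_hi, 200)])
    vals = np.array([h(t) for t in grid])
    cross = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) <= 0)
    cross = cross[np.abs(vals[cross]) + np.abs(vals[cross + 1]) > 0]
    if cross.size == 0:
        if vals.min() > 0:
            return -math.inf          # over-correction: implied age < 0
        return math.nan               # beyond secular equilibrium
    # take the largest root: the stable fixed point of iterating the age
    # and the (decaying) correction from the uncorrected age downward
    i = int(cross[-1])
    lo, hi = float(grid[i]), float(grid[i + 1])
    f_lo = h(lo)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if h(mid) * (f_lo if f_lo != 0 else -1.0) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    return 0.5 * (lo + hi)


def detrital_correct(meas: USeriesMeasurement, det: DetritalAssumption,
                     k: DecayConstants = DecayConstants(), n_mc: int = 10_000,
                     seed: int | None = None,
                     convention: str = "equilibrium") -> DetritalCorrectionResult:
    """Correct one sub-sample for non-radiogenic 230Th and date it.

    Requires a finite measured (230Th/232Th) ratio (232Th detected).  The
    1-sigma error comes from seeded Monte-Carlo draws over the measured
    ratios and over ``r0``; draws driving the corrected ratio negative or
    past secular equilibrium are rejected and counted.
    """
    if not math.isfinite(meas.a230_232):
        # no detrital Th at all: the correction is the identity
        age = th230_age(meas, k, n_mc=n_mc, seed=seed)
        return DetritalCorrectionResult(measurement=replace(meas), age=age)

    a232_238 = meas.a232_238
    t_c = _correct_once(meas.a230_238, meas.a234_238, a232_238, det.r0, k,
                        convention)
    over = t_c == -math.inf

    sigma = 0.0
    n_rej = 0
    if n_mc > 0:
        rng = np.random.default_rng(seed)
        ages = np.empty(n_mc)
        for i in range(n_mc):
            a230 = rng.normal(meas.a230_238, meas.a230_238_sd)
            a234 = rng.normal(meas.a234_238, meas.a234_238_sd)
            r0 = rng.normal(det.r0, det.r0_sigma)
            if a230 < 0 or a234 <= 0 or r0 < 0:
                ages[i] = math.nan
                continue
            ages[i] = _correct_once(a230, a234, a232_238, r0, k, convention)
        ok = np.isfinite(ages)
        n_rej = int(n_mc - ok.sum())
        if ok.sum() >= 2:
            sigma = float(np.std(ages[ok]))

    if not over and math.isnan(t_c):
        raise NonFiniteAgeError(
            f"{meas.label or 'sample'}: corrected ratio still at/beyond "
            "secular equilibrium")
    a230_c = _corrected_a230(meas.a230_238, a232_238, det.r0,
                             0.0 if over else t_c, k, convention)
    corrected = replace(meas, a230_238=max(a230_c, 0.0),
                        a230_238_sd=math.hypot(meas.a230_238_sd,
                                               a232_238 * det.r0_sigma))
    if over:
        age = AgeEstimate(age=math.nan, sigma=sigma, role="minimum",
                          unit_label=meas.label)
    else:
        age = AgeEstimate(age=t_c, sigma=sigma, role="direct",
                          unit_label=meas.label)
    return DetritalCorrectionResult(measurement=corrected, age=age,
                                    over_corrected=over, n_rejected=n_rej)


def fit_detrital_intercept(samples: Sequence[USeriesMeasurement]
                           ) -> tuple[float, float]:
    """Estimate the common detrital (230Th/232Th) ratio of coeval sub-samples.

    Ordinary least squares of the measured (230Th/232Th) (response) on the
    measured (234U/232Th) (predictor); the intercept on the 230Th/232Th axis
    and its standard error are returned.
    """
    pts = [(s.a234_232, s.a230_232) for s in samples
           if math.isfinite(s.a234_232) and math.isfinite(s.a230_232)]
    if len(pts) < 3:
        raise ValidationError("isochron intercept fit needs >= 3 sub-samples "
                              "with finite Th-normalised ratios")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) <= 1e-12 * max(1.0, float(np.abs(x).max())):
        raise ValidationError("no isochron: degenerate spread in a234_232")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return float(res.params[0]), float(res.bse[0])


@dataclass
class WeightedMeanResult:
    """Inverse-variance weighted mean of several ages.

    ``sigma_internal`` is sqrt(1/sum(1/s_i^2)); ``sigma_inflated`` multiplies
    it by sqrt(MSWD) when MSWD > 1 (over-dispersed data).
    """

    mean: float
    sigma_internal: float
    sigma_inflated: float
    mswd: float
    n: int

    @property
    def estimate(self) -> AgeEstimate:
        return AgeEstimate(age=self.mean, sigma=self.sigma_inflated)

    def __iter__(self):
        return iter((self.estimate, self.mswd))


def weighted_mean(ages: Sequence[AgeEstimate]) -> WeightedMeanResult:
    """Inverse-variance weighted mean and MSWD of >= 2 direct ages."""
    direct = [a for a in ages if a.role == "direct"]
    if len(direct) < 2:
        raise ValidationError("weighted mean needs >= 2 direct ages")
    if any(a.sigma <= 0 for a in direct):
        raise ValidationError("weighted mean needs sigma > 0 for every age")
    x = np.array([a.age for a in direct])
    w = np.array([1.0 / a.sigma**2 for a in direct])
    mean = float(np.sum(w * x) / np.sum(w))
    internal = float(1.0 / math.sqrt(np.sum(w)))
    mswd = float(np.sum(w * (x - mean) ** 2) / (len(direct) - 1))
    inflated = internal * math.sqrt(mswd) if mswd > 1 else internal
    return WeightedMeanResult(mean=mean, sigma_internal=internal,
                              sigma_inflated=inflated, mswd=mswd,
                              n=len(direct))


# ---------------------------------------------------------------------------
# I/O

_CSV_COLS = ["label", "a230_238", "a230_238_sd", "a234_238", "a234_238_sd",
             "a230_232", "a230_232_sd", "a234_232", "a234_232_sd"]


def read_useries_csv(path) -> list[USeriesMeasurement]:
    """Read sub-sample measurements from CSV.

    Expected columns: label, a230_238, a230_238_sd, a234_238, a234_238_sd,
    a230_232, a230_232_sd, a234_232, a234_232_sd and an optional
    ``sigma_level`` column (1 or 2); 2-sigma errors are halved on input.
    Empty Th-normalised ratios are read as +inf (no detrital Th).
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns in {path}: {missing}")
    out = []
    for _, row in df.iterrows():
        level = float(row.get("sigma_level", 1.0) or 1.0)
        if level not in (1.0, 2.0):
            raise ValidationError(f"sigma_level must be 1 or 2, got {level}")

        def val(col, default=math.inf):
            v = row[col]
            return default if pd.isna(v) else float(v)

        out.append(USeriesMeasurement(
            a230_238=val("a230_238", 0.0), a230_238_sd=val("a230_238_sd", 0.0) / level,
            a234_238=val("a234_238", 1.0), a234_238_sd=val("a234_238_sd", 0.0) / level,
            a230_232=val("a230_232"), a230_232_sd=val("a230_232_sd", 0.0) / level,
            a234_232=val("a234_232"), a234_232_sd=val("a234_232_sd", 0.0) / level,
            label=str(row["label"])))
    return out


def useries_report(samples: Sequence[USeriesMeasurement],
                   det: DetritalAssumption | None = None,
                   k: DecayConstants = DecayConstants(),
                   n_mc: int = 10_000, seed: int | None = None,
                   convention: str = "equilibrium") -> dict:
    """Per-sample uncorrected/corrected ages plus the weighted corrected mean."""
    if det is None:
        r0, r0_sd = fit_detrital_intercept(samples)
        det = DetritalAssumption(r0=max(r0, 0.0), r0_sigma=r0_sd)
    per_sample = []
    corrected_ages = []
    for i, s in enumerate(samples):
        sub_seed = None if seed is None else seed + i
        try:
            raw = th230_age(s, k, n_mc=n_mc, seed=sub_seed)
            raw_age, raw_sd = raw.age, raw.sigma
        except NonFiniteAgeError:
            raw_age = raw_sd = math.nan
        corr = detrital_correct(s, det, k, n_mc=n_mc, seed=sub_seed,
                                convention=convention)
        entry = {"label": s.label,
                 "age_uncorrected_kyr": raw_age, "sigma_uncorrected_kyr": raw_sd,
                 "age_corrected_kyr": corr.age.age, "sigma_corrected_kyr": corr.age.sigma,
                 "over_corrected": corr.over_corrected}
        per_sample.append(entry)
        if not corr.over_corrected:
            corrected_ages.append(corr.age)
    report = {"r0": det.r0, "r0_sigma": det.r0_sigma,
              "convention": convention, "samples": per_sample}
    if len(corrected_ages) >= 2:
        wm = weighted_mean(corrected_ages)
        report["weighted_mean_kyr"] = wm.mean
        report["weighted_mean_sigma_internal_kyr"] = wm.sigma_internal
        report["weighted_mean_sigma_inflated_kyr"] = wm.sigma_inflated
        report["mswd"] = wm.mswd
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
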