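"""Bayesian ordered-sequence age model for stratified deposits.

The deposit is a sequence of units, oldest (index 0) at the bottom, with a
boundary age between each adjacent pair.  On the kyr-before-present scale
(larger = older) boundary ages strictly decrease upward, and every event's
true age lies between its unit's bounding boundaries.

Likelihoods: each dated event has a latent true age theta.  A ``direct``
date contributes a Gaussian likelihood N(estimate | theta, sigma).  A
``minimum`` date bounds the true age from below (theta >= the dated event,
e.g. an overlying flowstone) and is implemented with a Gaussian auxiliary
variable m ~ N(estimate, sigma) constrained to m <= theta; a ``maximum``
date is the mirror image.

Priors: within a unit, true ages are uniform between the unit's
boundaries; for a unit bounded on both sides this contributes the
phase-normalisation factor (span of the unit)^-n.  The boundary prior is
flat (``uniform_span``, the default: the marginal prior of the model span
is uniform) or proportional to 1/span (``one_over_span``, which shrinks
phases).  The posterior is sampled by a
Metropolis-within-Gibbs random-walk sampler with per-parameter proposals
adapted during burn-in, vectorised over chains.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AgeEstimate, ValidationError

__all__ = [
    "StratEvent", "SequenceModel", "BoundaryPosterior", "SequencePosterior",
    "build_model", "run_mcmc", "summarize", "read_events_csv",
]

SPAN_PRIORS = ("one_over_span", "uniform_span")


@dataclass
class StratEvent:
    """A dated event assigned to an ordinal stratigraphic unit (0 = oldest)."""

    estimate: AgeEstimate
    unit: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.estimate.sigma <= 0:
            raise ValidationError("stratigraphic events need sigma > 0")
        if self.unit < 0:
            raise ValidationError("unit index must be >= 0")


@dataclass
class SequenceModel:
    """Compiled ordered-sequence model (events in canonical order)."""

    events: list[StratEvent]
    n_units: int
    span_prior: str = "uniform_span"

    # compiled arrays
    est: np.ndarray = field(init=False, repr=False)
    sigma: np.ndarray = field(init=False, repr=False)
    unit_idx: np.ndarray = field(init=False, repr=False)
    roles: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.est = np.array([e.estimate.age for e in self.events])
        self.sigma = np.array([e.estimate.sigma for e in self.events])
        self.unit_idx = np.array([e.unit for e in self.events], dtype=int)
        self.roles = [e.estimate.role for e in self.events]

    @property
    def n_boundaries(self) -> int:
        return self.n_units - 1


def build_model(events: list[StratEvent],
                span_prior: str = "uniform_span") -> SequenceModel:
    """Validate and compile an event list into a SequenceModel.

    Unit indices must be contiguous starting at 0.  Events are put in a
    canonical order so that posterior draws do not depend on input order.
    """
    if not events:
        raise ValidationError("need at least one event")
    if span_prior not in SPAN_PRIORS:
        raise ValidationError(f"span_prior must be one of {SPAN_PRIORS!r}")
    units = sorted({e.unit for e in events})
    if units != list(range(len(units))):
        raise ValidationError(
            f"unit indices must be contiguous from 0, got {units}")
    ordered = sorted(events, key=lambda e: (e.unit, e.estimate.age,
                                            e.estimate.sigma,
                                            e.estimate.role, e.label))
    return SequenceModel(events=ordered, n_units=len(units),
                         span_prior=span_prior)


# ---------------------------------------------------------------------------
# sampler

def _log_post(theta, aux, bnd, est, sigma, roles, unit_idx, n_units,
              span_prior, unit_counts):
    """Vectorised log posterior; theta (C,n), aux (C,n_aux), bnd (C,K-1);
    est/sigma broadcast against (C,n)."""
    C = theta.shape[0]
    lp = np.zeros(C)
    ok = np.ones(C, dtype=bool)

    # ordering of boundaries, positivity
    if bnd.shape[1] > 0:
        ok &= np.all(bnd > 0, axis=1)
        if bnd.shape[1] > 1:
            ok &= np.all(np.diff(bnd, axis=1) < 0, axis=1)
    ok &= np.all(theta > 0, axis=1)

    # unit intervals
    K = n_units
    for u in range(K):
        sel = unit_idx == u
        if not np.any(sel):
            continue
        th_u = theta[:, sel]
        if u > 0:
            ok &= np.all(th_u < bnd[:, u - 1][:, None], axis=1)
        if u < K - 1:
            ok &= np.all(th_u > bnd[:, u][:, None], axis=1)

    # phase normalisation for interior units
    for u in range(1, K - 1):
        n_u = unit_counts[u]
        if n_u:
            span_u = bnd[:, u - 1] - bnd[:, u]
            with np.errstate(invalid="ignore", divide="ignore"):
                lp -= n_u * np.log(np.where(span_u > 0, span_u, np.nan))

    # span prior
    if span_prior == "one_over_span" and K >= 3:
        span = bnd[:, 0] - bnd[:, -1]
        with np.errstate(invalid="ignore", divide="ignore"):
            lp -= np.log(np.where(span > 0, span, np.nan))

    # likelihoods
    i_aux = 0
    for i, role in enumerate(roles):
        e_i = est[..., i] if np.ndim(est) == 2 else est[i]
        s_i = sigma[..., i] if np.ndim(sigma) == 2 else sigma[i]
        if role == "direct":
            lp -= 0.5 * ((e_i - theta[:, i]) / s_i) ** 2
        elif role == "minimum":
            m = aux[:, i_aux]
            lp -= 0.5 * ((e_i - m) / s_i) ** 2
            ok &= m <= theta[:, i]
            i_aux += 1
        elif role == "maximum":
            m = aux[:, i_aux]
            lp -= 0.5 * ((e_i - m) / s_i) ** 2
            ok &= m >= theta[:, i]
            i_aux += 1

    lp = np.where(ok & np.isfinite(lp), lp, -np.inf)
    return lp


@dataclass
class BoundaryPosterior:
    """Posterior draws for one boundary age (pooled over chains after
    burn-in and thinning)."""

    samples: np.ndarray
    mean: float
    sd: float
    interval_68: tuple[float, float]
    rhat: float
    name: str = ""

    @property
    def converged(self) -> bool:
        return bool(self.rhat <= 1.05)


@dataclass
class SequencePosterior:
    boundaries: list[BoundaryPosterior]
    theta_samples: np.ndarray          # (draws, n_events)
    event_labels: list[str]
    n_chains: int
    n_iter: int
    seed: int | None
    acceptance: dict[str, float] = field(default_factory=dict)
    #: per-chain boundary draws, (chains, draws_per_chain, n_boundaries) —
    #: kept so batched simulation studies can summarise each chain alone
    boundary_chain_draws: np.ndarray | None = None

    @property
    def converged(self) -> bool:
        return all(b.converged for b in self.boundaries)


def _split_rhat(x: np.ndarray) -> float:
    """Split-R^ of draws with shape (chains, draws_per_chain)."""
    C, N = x.shape
    if N < 4:
        return float("nan")
    half = N // 2
    segs = np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)
    m, n = segs.shape
    means = segs.mean(axis=1)
    w = segs.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(math.sqrt(var_hat / w))


def run_mcmc(model: SequenceModel, n_iter: int = 50_000, n_chains: int = 4,
             seed: int | None = None, burn_frac: float = 0.2, thin: int = 5,
             est=None, sigma=None) -> SequencePosterior:
    """Sample the sequence posterior.

    Metropolis-within-Gibbs: each latent age, auxiliary variable and
    boundary gets a Gaussian random-walk update per iteration; proposal
    scales adapt towards ~40% acceptance during burn-in and are frozen
    afterwards.  Returns boundary posteriors (68% central intervals,
    split-R^ across chains) plus pooled latent-age draws.

    ``est``/``sigma`` may override the model's event data with per-chain
    arrays of shape (n_chains, n_events) — used for batched simulation
    studies where each chain carries its own replicate.
    """
    if n_chains < 1:
        raise ValidationError("need >= 1 chain")
    est_a = model.est if est is None else np.asarray(est, float)
    sigma_a = model.sigma if sigma is None else np.asarray(sigma, float)
    roles = model.roles
    unit_idx = model.unit_idx
    K = model.n_units
    n = len(roles)
    n_aux = sum(r != "direct" for r in roles)
    unit_counts = [int(np.sum(unit_idx == u)) for u in range(K)]

    rng = np.random.default_rng(seed)
    C = n_chains

    def event_vals(arr):
        return arr if arr.ndim == 2 else np.broadcast_to(arr, (C, n))

    ev = event_vals(est_a)
    sg = event_vals(sigma_a)

    # --- initialisation ------------------------------------------------
    theta = ev.astype(float).copy()
    for i, role in enumerate(roles):
        if role == "minimum":
            theta[:, i] = ev[:, i] + sg[:, i]
        elif role == "maximum":
            theta[:, i] = ev[:, i] - sg[:, i]
    aux = np.empty((C, n_aux))
    i_aux = 0
    for i, role in enumerate(roles):
        if role != "direct":
            aux[:, i_aux] = ev[:, i]
            i_aux += 1

    bnd = np.empty((C, K - 1))
    for j in range(K - 1):
        older = theta[:, unit_idx == j].min(axis=1) if unit_counts[j] else None
        younger = theta[:, unit_idx == j + 1].max(axis=1) \
            if unit_counts[j + 1] else None
        if older is not None and younger is not None:
            bnd[:, j] = 0.5 * (older + younger)
        elif older is not None:
            bnd[:, j] = older - 1.0
        elif younger is not None:
            bnd[:, j] = younger + 1.0
        else:
            bnd[:, j] = 100.0
    # per-chain jitter so chains start dispersed, then repair constraints
    theta += 0.1 * sg * rng.standard_normal(theta.shape)
    bnd += 0.5 * rng.standard_normal(bnd.shape)
    theta = np.maximum(theta, 1e-3)
    bnd = np.maximum(bnd, 1e-2)
    # enforce strict decrease and consistency with theta
    for j in range(K - 1):
        if j > 0:
            bnd[:, j] = np.minimum(bnd[:, j], bnd[:, j - 1] - 0.01)
    for u in range(K):
        sel = unit_idx == u
        if not np.any(sel):
            continue
        if u > 0:
            theta[:, sel] = np.minimum(theta[:, sel],
                                       (bnd[:, u - 1] - 1e-3)[:, None])
        if u < K - 1:
            theta[:, sel] = np.maximum(theta[:, sel],
                                       (bnd[:, u] + 1e-3)[:, None])
    i_aux = 0
    for i, role in enumerate(roles):
        if role == "minimum":
            aux[:, i_aux] = np.minimum(aux[:, i_aux], theta[:, i])
            i_aux += 1
        elif role == "maximum":
            aux[:, i_aux] = np.maximum(aux[:, i_aux], theta[:, i])
            i_aux += 1

    def logpost(th, ax, bd):
        return _log_post(th, ax, bd, est_a, sigma_a, roles, unit_idx, K,
                         model.span_prior, unit_counts)

    lp = logpost(theta, aux, bnd)
    if np.any(~np.isfinite(lp)):
        raise ValidationError("could not find a valid starting state; "
                              "check the stratigraphic ordering of the events")

    # proposal bookkeeping: one scale per parameter block entry
    blocks = ([("theta", i) for i in range(n)]
              + [("aux", i) for i in range(n_aux)]
              + [("bnd", j) for j in range(K - 1)])
    scales = {}
    for kind, idx in blocks:
        if kind == "theta":
            scales[(kind, idx)] = float(np.mean(sg[:, idx]))
        elif kind == "aux":
            scales[(kind, idx)] = float(np.mean(sg)) or 1.0
        else:
            scales[(kind, idx)] = max(float(np.mean(sg)), 1.0)
    acc = {b: 0 for b in blocks}
    tries = {b: 0 for b in blocks}

    n_burn = int(burn_frac * n_iter)
    keep = []
    keep_bnd = []
    adapt_interval = 100

    for it in range(n_iter):
        for kind, idx in blocks:
            if kind == "theta":
                prop = theta.copy()
                prop[:, idx] = theta[:, idx] + scales[(kind, idx)] * \
                    rng.standard_normal(C)
                lp_new = logpost(prop, aux, bnd)
                accept = np.log(rng.random(C)) < lp_new - lp
                theta[accept, idx] = prop[accept, idx]
            elif kind == "aux":
                prop = aux.copy()
                prop[:, idx] = aux[:, idx] + scales[(kind, idx)] * \
                    rng.standard_normal(C)
                lp_new = logpost(theta, prop, bnd)
                accept = np.log(rng.random(C)) < lp_new - lp
                aux[accept, idx] = prop[accept, idx]
            else:
                prop = bnd.copy()
                prop[:, idx] = bnd[:, idx] + scales[(kind, idx)] * \
                    rng.standard_normal(C)
                lp_new = logpost(theta, aux, prop)
                accept = np.log(rng.random(C)) < lp_new - lp
                bnd[accept, idx] = prop[accept, idx]
            lp = np.where(accept, lp_new, lp)
            acc[(kind, idx)] += int(accept.sum())
            tries[(kind, idx)] += C

        if it < n_burn and (it + 1) % adapt_interval == 0:
            for b in blocks:
                rate = acc[b] / max(tries[b], 1)
                scales[b] *= math.exp(1.2 * (rate - 0.4))
                scales[b] = min(max(scales[b], 1e-4), 1e4)
                acc[b] = 0
                tries[b] = 0

        if it >= n_burn and (it - n_burn) % thin == 0:
            keep.append(theta.copy())
            keep_bnd.append(bnd.copy())

    theta_draws = np.stack(keep, axis=1)      # (C, draws, n)
    bnd_draws = np.stack(keep_bnd, axis=1)    # (C, draws, K-1)

    boundaries = []
    for j in range(K - 1):
        per_chain = bnd_draws[:, :, j]
        pooled = per_chain.reshape(-1)
        lo, hi = np.quantile(pooled, [0.16, 0.84])
        boundaries.append(BoundaryPosterior(
            samples=pooled, mean=float(pooled.mean()),
            sd=float(pooled.std(ddof=1)),
            interval_68=(float(lo), float(hi)),
            rhat=_split_rhat(per_chain) if C >= 2 else float("nan"),
            name=f"boundary_{j}_{j + 1}"))

    acc_rates = {f"{k}_{i}": (acc[(k, i)] / tries[(k, i)] if tries[(k, i)]
                              else float("nan")) for (k, i) in blocks}
    return SequencePosterior(
        boundaries=boundaries,
        theta_samples=theta_draws.reshape(-1, n),
        event_labels=[e.label for e in model.events],
        n_chains=C, n_iter=n_iter, seed=seed, acceptance=acc_rates,
        boundary_chain_draws=bnd_draws)


def summarize(post: BoundaryPosterior, level: float = 0.68,
              hdi: bool = False) -> dict:
    """Mean, sd and a central (or highest-density) interval of the draws."""
    x = np.asarray(post.samples, float)
    if x.size == 0:
        raise ValidationError("empty posterior")
    if not 0.0 <= level <= 1.0:
        raise ValidationError("level must be in [0, 1]")
    if level == 1.0:
        lo, hi = float(x.min()), float(x.max())
    elif hdi:
        xs = np.sort(x)
        m = max(int(math.ceil(level * x.size)), 1)
        widths = xs[m - 1:] - xs[:x.size - m + 1]
        i = int(np.argmin(widths))
        lo, hi = float(xs[i]), float(xs[i + m - 1])
    else:
        alpha = (1.0 - level) / 2.0
        lo, hi = (float(v) for v in np.quantile(x, [alpha, 1.0 - alpha]))
    return {"name": post.name, "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
            "level": level, "interval": (lo, hi), "rhat": post.rhat}


# ---------------------------------------------------------------------------
# I/O

def read_events_csv(path) -> list[StratEvent]:
    """Event table: columns label, age_kyr, sigma_kyr, role, unit."""
    df = pd.read_csv(path, comment="#")
    required = ["label", "age_kyr", "sigma_kyr", "role", "unit"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns in {path}: {missing}")
    events = []
    for ln, row in df.iterrows():
        try:
            events.append(StratEvent(
                estimate=AgeEstimate(age=float(row["age_kyr"]),
                                     sigma=float(row["sigma_kyr"]),
                                     role=str(row["role"]).strip()),
                unit=int(row["unit"]), label=str(row["label"])))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} line {ln + 2}: {exc}") from exc
    return events


def posterior_report(post: SequencePosterior, level: float = 0.68) -> dict:
    return {
        "converged": post.converged,
        "n_chains": post.n_chains, "n_iter": post.n_iter, "seed": post.seed,
        "boundaries": [summarize(b, level) for b in post.boundaries],
    }


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
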