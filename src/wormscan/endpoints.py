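"""Assay-level endpoints: dose-response, fecundity, lifespan, habituation.

Mortality calls from scored plates feed a probit dose-response model,

    Phi^{-1}( P(dead) ) = beta0 + beta1 * dose,

fit by binomial maximum likelihood (Fisher scoring with step halving);
the LC50 is the dose at 50% mortality, ``-beta0/beta1``.  Dose enters
linearly by default -- phosphine exposures are run across a linear
concentration range -- with a log10 option for assays spanning decades.
Counting results feed per-day fecundity curves and mean-lifespan
summaries; repeated scan series feed habituation curves (the fraction
of worms still responding to the scanner light in each 90 s interval).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .movement import MORTALITY_THRESHOLD, score_pair
from .registration import ScanPair, align

__all__ = [
    "DoseGroup",
    "ProbitFit",
    "FecunditySeries",
    "SurvivalSeries",
    "HabituationSeries",
    "fit_probit",
    "lc_p",
    "simulate_dose_response",
    "fecundity_curves",
    "lifespan_summary",
    "habituation_series",
]


@dataclass(frozen=True)
class DoseGroup:
    """Mortality outcome of one plate at one toxicant concentration (ppm)."""

    concentration: float
    n_total: int
    n_dead: int
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if not 0 <= self.n_dead <= self.n_total:
            raise ValueError("need 0 <= n_dead <= n_total")


@dataclass
class ProbitFit:
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    cov: np.ndarray
    loglik: float
    converged: bool
    dose_scale: str
    n_iter: int
    penalized: bool = False

    @property
    def valid(self) -> bool:
        """A usable toxicant fit: converged with a positive slope."""
        return self.converged and self.slope > 0

    @property
    def lc50(self) -> float:
        return lc_p(self, 0.5)

    @property
    def lc50_se(self) -> float:
        """Delta-method standard error of the LC50 on the dose scale used."""
        if not self.valid:
            return float("nan")
        g = np.array([-1.0 / self.slope, self.intercept / self.slope**2])
        var = float(g @ self.cov @ g)
        se = np.sqrt(max(var, 0.0))
        if self.dose_scale == "log10":
            # SE of 10^x via delta method
            x = -self.intercept / self.slope
            se = se * np.log(10) * 10**x
        return se

    def predict(self, dose: float | np.ndarray) -> np.ndarray:
        x = np.asarray(dose, dtype=float)
        if self.dose_scale == "log10":
            x = np.log10(x)
        return norm.cdf(self.intercept + self.slope * x)


def _is_separated(x: np.ndarray, n: np.ndarray, d: np.ndarray) -> bool:
    """Complete separation: a dose threshold splits all-alive from all-dead."""
    order = np.argsort(x)
    frac = (d / n)[order]
    partial = (frac > 0) & (frac < 1)
    if partial.any():
        return False
    # all groups are 0% or 100%; separated iff the pattern is 0...0 1...1
    return bool(np.all(np.diff(frac) >= 0))


def _probit_loglik(beta, x, n, d):
    eta = beta[0] + beta[1] * x
    mu = np.clip(norm.cdf(eta), 1e-12, 1 - 1e-12)
    return float(np.sum(d * np.log(mu) + (n - d) * np.log(1 - mu)))


def fit_probit(
    groups: list[DoseGroup],
    dose_scale: str = "linear",
    max_iter: int = 100,
    tol: float = 1e-10,
    penalty: float = 1e-4,
) -> ProbitFit:
    """Binomial maximum-likelihood probit fit of mortality against dose.

    Fisher scoring with step halving so the log-likelihood never
    decreases; convergence when it changes by less than ``tol``.  Under
    complete separation the unpenalized likelihood has no maximum; a
    warning is issued and the fit is repeated with a small quadratic
    penalty on the coefficients so finite estimates are still returned.
    """
    if dose_scale not in ("linear", "log10"):
        raise ValueError("dose_scale must be 'linear' or 'log10'")
    conc = np.array([g.concentration for g in groups], dtype=float)
    n = np.array([g.n_total for g in groups], dtype=float)
    d = np.array([g.n_dead for g in groups], dtype=float)
    if len(np.unique(conc)) < 2:
        raise ValueError("need at least 2 distinct concentrations")
    if d.sum() == 0 or d.sum() == n.sum():
        raise ValueError("response is all-alive or all-dead; probit fit undefined")
    if dose_scale == "log10":
        if (conc <= 0).any():
            raise ValueError("log10 dose scale requires positive concentrations")
        x = np.log10(conc)
    else:
        x = conc

    def _fisher(lam: float):
        # crude start: linear regression of empirical probits
        p0 = np.clip((d + 0.5) / (n + 1.0), 0.01, 0.99)
        A = np.stack([np.ones_like(x), x], axis=1)
        beta, *_ = np.linalg.lstsq(A, norm.ppf(p0), rcond=None)
        ll = _probit_loglik(beta, x, n, d) - lam * float(beta @ beta)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            eta = beta[0] + beta[1] * x
            mu = np.clip(norm.cdf(eta), 1e-12, 1 - 1e-12)
            phi = norm.pdf(eta)
            resid = phi * (d - n * mu) / (mu * (1 - mu))
            w = n * phi**2 / (mu * (1 - mu))
            info = A.T @ (A * w[:, None]) + 2 * lam * np.eye(2)
            score = A.T @ resid - 2 * lam * beta
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                break
            # step halving: the (penalized) log-likelihood must not decrease
            scale_f = 1.0
            for _ in range(30):
                cand = beta + scale_f * step
                ll_new = _probit_loglik(cand, x, n, d) - lam * float(cand @ cand)
                if ll_new >= ll - 1e-14:
                    break
                scale_f *= 0.5
            else:
                break
            beta, delta, ll = cand, ll_new - ll, ll_new
            if abs(delta) < tol:
                converged = True
                break
        eta = beta[0] + beta[1] * x
        mu = np.clip(norm.cdf(eta), 1e-12, 1 - 1e-12)
        phi = norm.pdf(eta)
        w = n * phi**2 / (mu * (1 - mu))
        info = A.T @ (A * w[:, None]) + 2 * lam * np.eye(2)
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)
        return beta, cov, _probit_loglik(beta, x, n, d), converged, it

    penalized = _is_separated(x, n, d)
    if penalized:
        warnings.warn(
            "complete separation: the unpenalized probit likelihood has no "
            "maximum; fitting with a small quadratic penalty",
            stacklevel=2,
        )
        beta, cov, ll, converged, it = _fisher(penalty)
    else:
        beta, cov, ll, converged, it = _fisher(0.0)
        if not converged or not np.all(np.isfinite(cov)) or np.abs(beta).max() > 1e6:
            warnings.warn(
                "probit fit did not converge; refitting with a small quadratic penalty",
                stacklevel=2,
            )
            beta, cov, ll, converged, it = _fisher(penalty)
            penalized = True
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return ProbitFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        se_intercept=float(se[0]),
        se_slope=float(se[1]),
        cov=cov,
        loglik=ll,
        converged=converged,
        dose_scale=dose_scale,
        n_iter=it,
        penalized=penalized,
    )


def lc_p(fit: ProbitFit, p: float) -> float:
    """Dose at which predicted mortality equals ``p`` (LC50 is p=0.5)."""
    if not 0 < p < 1:
        raise ValueError("p must lie strictly between 0 and 1")
    if not fit.valid:
        raise ValueError("LC estimates require a converged fit with positive slope")
    dose = (norm.ppf(p) - fit.intercept) / fit.slope
    return float(10**dose) if fit.dose_scale == "log10" else float(dose)


def simulate_dose_response(
    intercept: float,
    slope: float,
    doses: np.ndarray,
    n_per_dose: int,
    n_replicates: int,
    rng: np.random.Generator,
    dose_scale: str = "linear",
) -> list[DoseGroup]:
    """Draw binomial mortality counts from a known probit model."""
    x = np.log10(doses) if dose_scale == "log10" else np.asarray(doses, float)
    p = norm.cdf(intercept + slope * x)
    groups = []
    for rep in range(n_replicates):
        deaths = rng.binomial(n_per_dose, p)
        groups += [
            DoseGroup(float(c), n_per_dose, int(k), replicate=rep)
            for c, k in zip(doses, deaths)
        ]
    return groups


@dataclass
class FecunditySeries:
    days: np.ndarray
    per_day: np.ndarray  # (n_plates, n_days) counts
    per_day_mean: np.ndarray
    per_day_ci: np.ndarray  # (2, n_days): lower, upper 95%
    cumulative: np.ndarray  # (n_plates, n_days)
    cumulative_mean: np.ndarray
    cumulative_ci: np.ndarray


def fecundity_curves(
    daily_counts: np.ndarray, days: np.ndarray | None = None
) -> FecunditySeries:
    """Per-day and cumulative progeny curves across replicate plates.

    ``daily_counts`` is (n_plates, n_days); means are across plates with
    normal-approximation 95% intervals (mean +/- 1.96 SE).
    """
    try:
        counts = np.asarray(daily_counts, dtype=float)
    except ValueError as exc:
        raise ValueError("ragged day grids: all plates need the same days") from exc
    if counts.ndim == 1:
        counts = counts[None, :]
    if counts.ndim != 2:
        raise ValueError("daily_counts must be (n_plates, n_days)")
    if (counts < 0).any():
        raise ValueError("progeny counts must be non-negative")
    n_plates, n_days = counts.shape
    if days is None:
        days = np.arange(1, n_days + 1)
    days = np.asarray(days)
    if len(days) != n_days:
        raise ValueError("days vector does not match count columns")
    cum = np.cumsum(counts, axis=1)

    def _ci(mat):
        mean = mat.mean(axis=0)
        if n_plates > 1:
            se = mat.std(axis=0, ddof=1) / np.sqrt(n_plates)
        else:
            se = np.zeros(n_days)
        return mean, np.stack([mean - 1.96 * se, mean + 1.96 * se])

    pd_mean, pd_ci = _ci(counts)
    cum_mean, cum_ci = _ci(cum)
    return FecunditySeries(
        days=days,
        per_day=counts,
        per_day_mean=pd_mean,
        per_day_ci=pd_ci,
        cumulative=cum,
        cumulative_mean=cum_mean,
        cumulative_ci=cum_ci,
    )


@dataclass
class SurvivalSeries:
    """Daily live counts per plate; counts must be non-increasing."""

    days: np.ndarray
    n_alive: np.ndarray  # (n_plates, n_days)

    def __post_init__(self) -> None:
        self.n_alive = np.atleast_2d(np.asarray(self.n_alive))
        self.days = np.asarray(self.days)
        if (np.diff(self.n_alive, axis=1) > 0).any():
            raise ValueError("live counts must be non-increasing over time")

    def death_days(self) -> list[np.ndarray]:
        """Per-plate death days inferred from successive count differences."""
        out = []
        for row in self.n_alive:
            deaths = -np.diff(row)
            out.append(np.repeat(self.days[1:], deaths.astype(int)))
        return out


@dataclass
class LifespanSummary:
    mean_days: float
    se_days: float
    n_deaths: int
    trial_means: np.ndarray


def lifespan_summary(
    death_days_per_trial: list[np.ndarray] | SurvivalSeries,
) -> LifespanSummary:
    """Mean lifespan with the SE taken across trial means.

    Accepts either per-trial arrays of individual death days or a
    :class:`SurvivalSeries` (death days are then inferred from the daily
    count decrements).  The error convention is the standard error of
    the per-trial mean lifespans, matching plate-replicated assays.
    """
    if isinstance(death_days_per_trial, SurvivalSeries):
        death_days_per_trial = death_days_per_trial.death_days()
    trials = [np.asarray(t, dtype=float) for t in death_days_per_trial]
    nonempty = [t for t in trials if t.size]
    all_deaths = np.concatenate(nonempty) if nonempty else np.array([])
    if all_deaths.size == 0:
        raise ValueError("no deaths observed; mean lifespan undefined")
    trial_means = np.array([t.mean() for t in trials if t.size])
    if len(trial_means) > 1:
        se = trial_means.std(ddof=1) / np.sqrt(len(trial_means))
    else:
        se = float("nan")
    return LifespanSummary(
        mean_days=float(all_deaths.mean()),
        se_days=float(se),
        n_deaths=int(all_deaths.size),
        trial_means=trial_means,
    )


@dataclass
class HabituationSeries:
    """Fraction of worms responding to the light stimulus per interval."""

    responding_fraction: np.ndarray
    n_scored: np.ndarray
    interval_s: float

    def __post_init__(self) -> None:
        f = np.asarray(self.responding_fraction)
        if ((f < 0) | (f > 1)).any():
            raise ValueError("responding fractions must lie in [0, 1]")


def habituation_series(
    scans: list,
    segmenter,
    interval_s: float = 90.0,
    response_threshold: float = MORTALITY_THRESHOLD,
    min_area_px: int = 200,
    max_area_px: int = 20000,
    low: float | None = None,
    high: float | None = None,
) -> HabituationSeries:
    """Responding fraction over each consecutive scan interval.

    A series of ``k`` scans yields ``k - 1`` intervals; each interval is
    scored like a mortality pair (segment the earlier scan, align,
    difference, hysteresis) and the responding fraction is the share of
    segmented worms whose movement reaches ``response_threshold``.
    """
    if len(scans) < 2:
        raise ValueError("need at least two scans")
    fractions, ns = [], []
    for first, second in zip(scans[:-1], scans[1:]):
        pair = align(ScanPair(first=first, second=second, interval_s=interval_s))
        records, summary, _dm = score_pair(
            pair,
            segmenter,
            low=low,
            high=high,
            mortality_threshold=response_threshold,
            min_area_px=min_area_px,
            max_area_px=max_area_px,
        )
        ns.append(summary.n_total)
        fractions.append(summary.n_alive / summary.n_total if summary.n_total else 0.0)
    return HabituationSeries(
        responding_fraction=np.asarray(fractions),
        n_scored=np.asarray(ns),
        interval_s=interval_s,
    )
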