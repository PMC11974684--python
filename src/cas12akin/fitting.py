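"""Rate-constant estimation from plasmid-topology time courses.

Each replicate of a cleavage assay yields per-time-point percentages of
supercoiled, nicked and linear plasmid quantified from a gel.  This module
fits the four rate constants of the six-pool model to one replicate at a
time by bounded nonlinear least squares on the three observable series, then
aggregates replicates as mean +/- s.d. and compares nucleases by fold change
of the mean rates.

Conventions mirroring the original analysis:

* initial conditions are read from the earliest time point of the replicate
  (observed totSC, totNICK, lin -> initSC, initNICK1, initLIN), not fitted;
* each replicate is fitted individually; replicates are never pooled into a
  global fit;
* residuals of totSC, totNICK and lin are pooled with equal weight;
* the default starting guess is ka = kb = 0.50, kini = kini2 = 0.01 s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .model import (
    InitialFractions,
    KineticParams,
    ObservedFractions,
    integrate,
    observables,
)

__all__ = [
    "DEFAULT_INITIAL_GUESS",
    "DEFAULT_BOUNDS",
    "Replicate",
    "TimeCourseDataset",
    "FitResult",
    "AggregateRates",
    "renormalize",
    "loss",
    "fit_replicate",
    "fit_dataset",
    "aggregate",
    "fold_change",
]

#: Starting guess used by the original analysis.
DEFAULT_INITIAL_GUESS = KineticParams(ka=0.50, kb=0.50, kini=0.01, kini2=0.01)

#: Lower/upper bounds on every rate constant, s^-1.
DEFAULT_BOUNDS = (0.0, 100.0)


@dataclass(frozen=True)
class Replicate:
    """One replicate's observed fractions, id attached."""

    replicate_id: str
    observed: ObservedFractions


@dataclass
class TimeCourseDataset:
    """Observed topology time courses grouped by replicate.

    ``truth`` carries the generating parameters when the dataset is
    synthetic; it is None for real data.
    """

    replicates: list[Replicate]
    tol_sum: float = 5.0
    truth: KineticParams | None = None

    def __post_init__(self):
        for rep in self.replicates:
            obs = rep.observed
            if obs.times.size > 1 and not np.all(np.diff(obs.times) > 0):
                raise ValueError(f"replicate {rep.replicate_id}: times not strictly increasing")
            stacked = obs.stacked()
            if not np.all(np.isfinite(stacked)):
                raise ValueError(f"replicate {rep.replicate_id}: non-finite fractions")
            if stacked.min() < 0 or stacked.max() > 100:
                raise ValueError(f"replicate {rep.replicate_id}: fractions outside [0, 100]")
            sums = stacked.sum(axis=1)
            bad = np.flatnonzero(np.abs(sums - 100.0) > self.tol_sum)
            if bad.size:
                raise ValueError(
                    f"replicate {rep.replicate_id}: fraction sums outside "
                    f"[{100 - self.tol_sum}, {100 + self.tol_sum}] at time indices {bad.tolist()} "
                    f"(sums {np.round(sums[bad], 3).tolist()})"
                )

    def __len__(self) -> int:
        return len(self.replicates)

    def __iter__(self):
        return iter(self.replicates)


@dataclass(frozen=True)
class FitResult:
    """Per-replicate parameter estimate with diagnostics."""

    replicate_id: str
    params: KineticParams
    loss: float
    n_points: int
    converged: bool
    n_restarts_used: int
    variant: str
    init: InitialFractions

    def __post_init__(self):
        if self.loss < 0:
            raise ValueError("loss must be >= 0")


@dataclass(frozen=True)
class AggregateRates:
    """Mean +/- sample s.d. of ka and kb across replicate fits."""

    ka_mean: float
    ka_sd: float
    kb_mean: float
    kb_sd: float
    n: int
    ka_values: tuple[float, ...]
    kb_values: tuple[float, ...]
    single_replicate: bool = False


def renormalize(obs: ObservedFractions) -> ObservedFractions:
    """Rescale each time point so the three fractions sum to exactly 100.

    Gel quantification rarely sums to exactly 100; fitting assumes closed
    compositions.
    """
    stacked = obs.stacked()
    sums = stacked.sum(axis=1)
    if np.any(sums <= 0):
        raise ValueError("cannot renormalize a time point with non-positive total")
    scaled = np.clip(stacked * (100.0 / sums)[:, None], 0.0, 100.0)
    return ObservedFractions(
        times=obs.times, totSC=scaled[:, 0], totNICK=scaled[:, 1], lin=scaled[:, 2]
    )


def _init_from_data(obs: ObservedFractions) -> InitialFractions:
    """Initial pools read off the earliest observed time point."""
    return InitialFractions(
        initSC=float(obs.totSC[0]),
        initNICK1=float(obs.totNICK[0]),
        initLIN=float(obs.lin[0]),
    )


def _residuals(
    rates: np.ndarray,
    obs: ObservedFractions,
    init: InitialFractions,
    variant: str,
    fit_observables: str,
) -> np.ndarray:
    params = KineticParams.from_array(np.clip(rates, 0.0, None))
    traj = integrate(params, init, obs.times, variant=variant)
    if fit_observables == "tot":
        pred = observables(traj).stacked()
    else:  # raw SC / NICK / LIN pools, ignoring the unproductive sums
        pred = np.column_stack([traj.pool("SC"), traj.pool("NICK"), traj.pool("LIN")])
    return (pred - obs.stacked()).ravel()


def loss(
    params: KineticParams,
    obs: ObservedFractions,
    init: InitialFractions,
    variant: str = "as_printed",
    fit_observables: str = "tot",
) -> float:
    """Unweighted sum of squared residuals pooled over totSC, totNICK, lin (%^2)."""
    r = _residuals(params.as_array(), obs, init, variant, fit_observables)
    return float(np.dot(r, r))


def fit_replicate(
    obs: ObservedFractions,
    init_guess: KineticParams = DEFAULT_INITIAL_GUESS,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    variant: str = "as_printed",
    n_restarts: int = 10,
    seed: int | None = None,
    replicate_id: str = "r1",
    fit_observables: str = "tot",
    normalize: bool = True,
    freeze_kini: bool = False,
) -> FitResult:
    """Fit the rate constants to one replicate.

    Bounded trust-region least squares from the given guess plus
    ``n_restarts - 1`` seeded multiplicative jitters of it (factors drawn
    log-uniformly in [0.1, 10]); the best restart wins.  With
    ``freeze_kini`` the two unproductive-conversion rates are held at the
    guess and only ka, kb are free.
    """
    if fit_observables not in ("tot", "raw"):
        raise ValueError("fit_observables must be 'tot' or 'raw'")
    if obs.times.size < 4:
        raise ValueError(f"need >= 4 time points to fit 4 rate constants, got {obs.times.size}")
    if bounds[0] < 0:
        raise ValueError("lower bound must be >= 0")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    if normalize:
        obs = renormalize(obs)
    init = _init_from_data(obs)

    free = np.array([True, True, not freeze_kini, not freeze_kini])
    guess_full = init_guess.as_array()
    lo, hi = bounds
    rng = np.random.default_rng(seed)

    def objective(x_free: np.ndarray) -> np.ndarray:
        full = guess_full.copy()
        full[free] = x_free
        return _residuals(full, obs, init, variant, fit_observables)

    best = None
    best_cost = np.inf
    n_used = 0
    for restart in range(n_restarts):
        factors = np.ones(4) if restart == 0 else 10.0 ** rng.uniform(-1, 1, size=4)
        x0 = np.clip(guess_full * factors, lo + 1e-12, hi)[free]
        try:
            result = least_squares(
                objective, x0, bounds=(lo, hi), method="trf",
                ftol=1e-12, xtol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        n_used += 1
        if result.cost < best_cost:
            best_cost = result.cost
            best = result
    if best is None:
        raise RuntimeError(f"all {n_restarts} fit restarts failed for replicate {replicate_id}")

    fitted = guess_full.copy()
    fitted[free] = best.x
    params = KineticParams.from_array(fitted)
    return FitResult(
        replicate_id=replicate_id,
        params=params,
        loss=float(2.0 * best.cost),  # least_squares cost is 0.5 * SSE
        n_points=int(obs.times.size),
        converged=bool(best.status > 0),
        n_restarts_used=n_used,
        variant=variant,
        init=init,
    )


def fit_dataset(dataset: TimeCourseDataset, seed: int | None = None, **kwargs) -> list[FitResult]:
    """Fit every replicate in a dataset; seeds are derived per replicate."""
    results = []
    for i, rep in enumerate(dataset):
        rep_seed = None if seed is None else seed + i
        results.append(
            fit_replicate(rep.observed, seed=rep_seed, replicate_id=rep.replicate_id, **kwargs)
        )
    return results


def aggregate(fits: list[FitResult]) -> AggregateRates:
    """Arithmetic mean and sample s.d. (n-1) of ka and kb across replicates."""
    if not fits:
        raise ValueError("need at least one fit to aggregate")
    ka = np.array([f.params.ka for f in fits])
    kb = np.array([f.params.kb for f in fits])
    single = len(fits) == 1
    # identical replicate values must report exactly zero spread
    sd = (lambda v: 0.0 if single or np.ptp(v) == 0 else float(np.std(v, ddof=1)))
    return AggregateRates(
        ka_mean=float(ka.mean()),
        ka_sd=sd(ka),
        kb_mean=float(kb.mean()),
        kb_sd=sd(kb),
        n=len(fits),
        ka_values=tuple(ka.tolist()),
        kb_values=tuple(kb.tolist()),
        single_replicate=single,
    )


def fold_change(a: AggregateRates, b: AggregateRates) -> dict[str, float]:
    """Fold difference of mean rates, a over b, for ka and kb."""
    if b.ka_mean <= 0 or b.kb_mean <= 0:
        raise ZeroDivisionError("fold change undefined: denominator mean rate is not positive")
    return {"ka": a.ka_mean / b.ka_mean, "kb": a.kb_mean / b.kb_mean}
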