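"""Synthetic inputs with known ground truth for every pipeline stage.

The cleavage assays, trajectory analyses and plate-reader assays this
package analyses have no public raw data, so each consumer is exercised on
generated data whose truth is known:

* gel-style topology time courses — the six-pool model integrated on a time
  grid, Gaussian noise per fraction, clipped at zero and renormalised to
  100% per time point;
* two-domain coordinate ensembles — rigid pseudo-REC2 / pseudo-NUC atom
  clouds whose centre-of-mass separation is drawn per frame from a seeded
  Gaussian, with residue numbers inside the requested domain ranges and a
  sprinkling of hydrogens to exercise heavy-atom filtering;
* thermal-shift melt curves — a Gaussian fluorescence peak at a prescribed
  Tm on the instrument grid (25–99 °C in 1 °C steps);
* trans-cleavage reporter curves — saturating exponential
  plateau*(1-exp(-rate*t)) plus seeded noise.

Preset truths and time grids reflect the three orthologues' observed
behaviour: FnCas12a-like kinetics complete in tens of seconds, LbCas12a-like
in hundreds, AsCas12a-like only by ~2700 s.  All generators are
bit-reproducible under a fixed integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import Replicate, TimeCourseDataset
from .geometry import DomainDefinition, FrameEnsemble
from .model import (
    InitialFractions,
    KineticParams,
    ObservedFractions,
    integrate,
    observables,
)

__all__ = [
    "NoiseSpec",
    "EnsembleSpec",
    "RATE_PRESETS",
    "GRID_PRESETS",
    "DEFAULT_INIT",
    "time_grid",
    "generate_timecourse",
    "generate_preset_timecourse",
    "generate_ensemble",
    "generate_melt_curve",
    "generate_trans_curve",
]

#: Orthologue-like rate truths (s^-1): fast/fast, medium/slow, slow/very-slow.
RATE_PRESETS = {
    "fn": KineticParams(ka=0.5, kb=0.5, kini=0.01, kini2=0.01),
    "lb": KineticParams(ka=0.18, kb=0.1, kini=0.01, kini2=0.01),
    "as": KineticParams(ka=0.12, kb=0.012, kini=0.01, kini2=0.01),
}

#: 12 log-spaced sample times (s) spanning each orthologue's plateau window.
GRID_PRESETS = {
    "fn": (1.0, 30.0, 12),
    "lb": (1.0, 300.0, 12),
    "as": (1.0, 2700.0, 12),
}

#: Mostly supercoiled prep with a small pre-nicked background.
DEFAULT_INIT = InitialFractions(initSC=95.0, initNICK1=5.0, initLIN=0.0)


def time_grid(preset: str) -> np.ndarray:
    """Log-spaced sampling times for an orthologue preset ('fn'|'lb'|'as')."""
    try:
        start, stop, n = GRID_PRESETS[preset]
    except KeyError:
        raise ValueError(
            f"unknown grid preset {preset!r}; expected one of {sorted(GRID_PRESETS)}"
        ) from None
    return np.geomspace(start, stop, n)


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian scatter applied independently to each observed fraction.

    ``fraction_sd`` is in percentage points; the default 2 matches the
    replicate-to-replicate spread typical of gel densitometry.
    """

    fraction_sd: float = 2.0
    seed: int | None = None

    def __post_init__(self):
        if self.fraction_sd < 0:
            raise ValueError("fraction_sd must be >= 0")


@dataclass(frozen=True)
class EnsembleSpec:
    """Prescription for a two-domain pseudo-trajectory."""

    n_frames: int = 100
    distance_mean: float = 43.5
    distance_sd: float = 1.0
    atoms_per_domain: int = 50
    n_hydrogens: int = 10
    domain_radius: float = 5.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.distance_sd < 0:
            raise ValueError("distance_sd must be >= 0")
        if self.atoms_per_domain < 1:
            raise ValueError("atoms_per_domain must be >= 1")


def generate_timecourse(
    truth: KineticParams,
    init: InitialFractions = DEFAULT_INIT,
    times=None,
    noise: NoiseSpec = NoiseSpec(),
    n_replicates: int = 3,
    variant: str = "as_printed",
    noise_model: str = "gaussian",
    dirichlet_concentration: float = 500.0,
) -> TimeCourseDataset:
    """Simulate replicate topology time courses from known rates.

    The model is integrated once (initial condition applied at the first
    grid time); each replicate then receives independent seeded noise, is
    clipped at zero and renormalised so every time point sums to 100.  The
    generating parameters travel with the dataset as ``dataset.truth``.

    ``noise_model="dirichlet"`` draws each time point's composition from a
    Dirichlet centred on the model fractions instead of adding Gaussian
    scatter; ``dirichlet_concentration`` sets its tightness.
    """
    if times is None:
        times = time_grid("lb")
    if noise_model not in ("gaussian", "dirichlet"):
        raise ValueError("noise_model must be 'gaussian' or 'dirichlet'")
    clean = observables(integrate(truth, init, times, variant=variant)).stacked()
    rng = np.random.default_rng(noise.seed)

    replicates = []
    for r in range(n_replicates):
        if noise.fraction_sd == 0:
            noisy = clean.copy()
        elif noise_model == "gaussian":
            noisy = clean + rng.normal(0.0, noise.fraction_sd, size=clean.shape)
            noisy = np.clip(noisy, 0.0, None)
        else:
            alpha = np.clip(clean / 100.0, 1e-6, None) * dirichlet_concentration
            noisy = np.vstack([rng.dirichlet(a) * 100.0 for a in alpha])
        sums = noisy.sum(axis=1)
        sums[sums == 0] = 1.0
        noisy = np.clip(noisy * (100.0 / sums)[:, None], 0.0, 100.0)
        obs = ObservedFractions(
            times=np.asarray(times, dtype=float),
            totSC=noisy[:, 0],
            totNICK=noisy[:, 1],
            lin=noisy[:, 2],
        )
        replicates.append(Replicate(replicate_id=f"rep{r + 1}", observed=obs))
    return TimeCourseDataset(replicates=replicates, truth=truth)


def generate_preset_timecourse(
    preset: str,
    noise: NoiseSpec = NoiseSpec(),
    n_replicates: int = 3,
    variant: str = "as_printed",
) -> TimeCourseDataset:
    """Time course for an orthologue preset: its rate truth on its grid."""
    if preset not in RATE_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected one of {sorted(RATE_PRESETS)}")
    return generate_timecourse(
        truth=RATE_PRESETS[preset],
        init=DEFAULT_INIT,
        times=time_grid(preset),
        noise=noise,
        n_replicates=n_replicates,
        variant=variant,
    )


def _rigid_cloud(rng, n_heavy: int, n_h: int, radius: float):
    """A rigid atom cloud, heavy atoms cycling C/N/O/S plus n_h hydrogens,
    centred so its mass-weighted COM is exactly at the origin."""
    from .geometry import atomic_mass

    n = n_heavy + n_h
    xyz = rng.uniform(-radius, radius, size=(n, 3))
    heavy_cycle = ["C", "N", "O", "S"]
    elements = [heavy_cycle[i % 4] for i in range(n_heavy)] + ["H"] * n_h
    names = [f"{el}{i + 1}" for i, el in enumerate(elements)]
    masses = np.array([atomic_mass(el) for el in elements])
    xyz -= (masses[:, None] * xyz).sum(axis=0) / masses.sum()
    return xyz, np.array(elements, dtype=object), np.array(names, dtype=object)


def generate_ensemble(
    spec: EnsembleSpec,
    domains: DomainDefinition,
) -> FrameEnsemble:
    """Build a pseudo-trajectory of two rigid domains at controlled separation.

    Each domain is a fixed random atom cloud whose residue numbers tile the
    corresponding range of ``domains``; per frame, the NUC cloud is placed so
    the mass-weighted COM separation equals a draw from
    Normal(distance_mean, distance_sd) along a random direction, and the
    whole frame is given a random rigid rotation and translation.  With
    ``distance_sd=0`` every frame's measured COM distance equals
    ``distance_mean`` to construction precision.
    """
    rng = np.random.default_rng(spec.seed)
    xyz_a, el_a, names_a = _rigid_cloud(rng, spec.atoms_per_domain, spec.n_hydrogens, spec.domain_radius)
    xyz_b, el_b, names_b = _rigid_cloud(rng, spec.atoms_per_domain, spec.n_hydrogens, spec.domain_radius)

    def _tile_res_ids(n, lo, hi):
        span = hi - lo + 1
        return lo + (np.arange(n) % span)

    res_a = _tile_res_ids(xyz_a.shape[0], *domains.rec2)
    res_b = _tile_res_ids(xyz_b.shape[0], *domains.nuc)

    frames = np.empty((spec.n_frames, xyz_a.shape[0] + xyz_b.shape[0], 3))
    for f in range(spec.n_frames):
        d = rng.normal(spec.distance_mean, spec.distance_sd) if spec.distance_sd > 0 else spec.distance_mean
        d = max(d, 0.0)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        frame = np.vstack([xyz_a, xyz_b + d * direction])
        # random rigid motion of the whole frame (distances are invariant)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        frames[f] = frame @ rot.T + rng.uniform(-20, 20, size=3)

    return FrameEnsemble(
        coords=frames,
        res_ids=np.concatenate([res_a, res_b]),
        atom_names=np.concatenate([names_a, names_b]),
        elements=np.concatenate([el_a, el_b]),
    )


def generate_melt_curve(
    tm: float,
    width: float = 6.0,
    amplitude: float = 1000.0,
    baseline: float = 50.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
):
    """Thermal-shift melt curve: Gaussian fluorescence peak at ``tm`` on the
    25–99 °C instrument grid (1 °C steps).  Returns a
    :class:`~cas12akin.assays.MeltCurve`."""
    from .assays import MeltCurve

    if not (25.0 <= tm <= 99.0):
        raise ValueError(f"tm must lie on the 25-99 degC grid, got {tm}")
    temps = np.arange(25.0, 100.0, 1.0)
    fluor = baseline + amplitude * np.exp(-0.5 * ((temps - tm) / width) ** 2)
    if noise_sd > 0:
        fluor = fluor + np.random.default_rng(seed).normal(0, noise_sd, temps.size)
    return MeltCurve(temperatures=temps, fluorescence=fluor)


def generate_trans_curve(
    rate: float,
    plateau: float,
    times,
    noise_sd: float = 0.0,
    seed: int | None = None,
):
    """Trans-cleavage reporter curve plateau*(1-exp(-rate*t)) + noise.
    Returns a :class:`~cas12akin.assays.TransCurve`."""
    from .assays import TransCurve

    if rate < 0:
        raise ValueError("rate must be >= 0")
    t = np.asarray(times, dtype=float)
    fluor = plateau * (1.0 - np.exp(-rate * t))
    if noise_sd > 0:
        fluor = fluor + np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return TransCurve(times=t, fluorescence=fluor)
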