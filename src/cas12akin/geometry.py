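"""Inter-domain geometry of Cas12a conformational ensembles.

The recognition-lobe REC2 domain and the nuclease-lobe NUC domain "clamp"
around the crRNA:target-strand heteroduplex; the distance between their
centres of mass, and the number of heavy-atom contacts between them,
distinguish open and closed conformations across trajectory frames.  This
module computes, per frame:

* the mass-weighted (or geometric) centre of mass of a residue range;
* the Euclidean REC2-NUC centre-of-mass distance;
* the number of heavy-atom pairs closer than a cutoff (default 3.5 A,
  strict inequality, hydrogens excluded);
* which residue pairs are in contact in what fraction of frames;

plus a 1-D Gaussian kernel density estimate for visualising the resulting
distance / contact-count distributions.

Domain presets carry the residue ranges of the three orthologues studied:
FnCas12a REC2 340-591 / NUC 1079-1254, LbCas12a 283-521 / 998-1179,
AsCas12a 321-526 / 1067-1262 (author numbering; insertion codes are not
supported and are rejected at parse time).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ATOMIC_MASSES",
    "DOMAIN_PRESETS",
    "DomainDefinition",
    "FrameEnsemble",
    "DistanceContactSeries",
    "SelectionError",
    "ElementError",
    "infer_element",
    "atomic_mass",
    "center_of_mass",
    "com_distance_series",
    "contact_count",
    "contact_series",
    "contact_residue_pairs",
    "kde_density",
]

#: Standard atomic masses (u) for elements common in protein structures.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "MN": 54.938, "NA": 22.990, "K": 39.098, "CA": 40.078, "CL": 35.45,
}


class SelectionError(ValueError):
    """A residue range selected no atoms."""


class ElementError(ValueError):
    """An atom's element could not be resolved unambiguously."""


@dataclass(frozen=True)
class DomainDefinition:
    """Named REC2 / NUC residue ranges (inclusive) for one orthologue."""

    name: str
    rec2: tuple[int, int]
    nuc: tuple[int, int]

    def __post_init__(self):
        for label, (lo, hi) in (("rec2", self.rec2), ("nuc", self.nuc)):
            if hi < lo:
                raise ValueError(f"{label} range {lo}-{hi} is empty")
        r_lo, r_hi = self.rec2
        n_lo, n_hi = self.nuc
        if max(r_lo, n_lo) <= min(r_hi, n_hi):
            raise ValueError(f"rec2 {self.rec2} and nuc {self.nuc} ranges overlap")


DOMAIN_PRESETS = {
    "FnCas12a": DomainDefinition("FnCas12a", rec2=(340, 591), nuc=(1079, 1254)),
    "LbCas12a": DomainDefinition("LbCas12a", rec2=(283, 521), nuc=(998, 1179)),
    "AsCas12a": DomainDefinition("AsCas12a", rec2=(321, 526), nuc=(1067, 1262)),
}


def infer_element(atom_name: str) -> str:
    """Element symbol from a PDB atom name: strip digits/primes, take the
    leading letter.  Raises :class:`ElementError` when nothing sensible
    remains rather than guessing.
    """
    stripped = re.sub(r"[\d'\s]", "", atom_name)
    if not stripped or not stripped[0].isalpha():
        raise ElementError(f"cannot infer element from atom name {atom_name!r}")
    return stripped[0].upper()


def atomic_mass(element: str) -> float:
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise ElementError(f"no atomic mass known for element {element!r}") from None


@dataclass
class FrameEnsemble:
    """Ordered coordinate frames sharing one atom annotation table.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom; ``res_ids``,
    ``atom_names`` and ``elements`` are per-atom.  Empty element strings are
    resolved from the atom name on demand.
    """

    coords: np.ndarray
    res_ids: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        n_atoms = self.coords.shape[1]
        for name in ("res_ids", "atom_names", "elements"):
            if getattr(self, name).size != n_atoms:
                raise ValueError(f"{name} length does not match n_atoms={n_atoms}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def resolved_elements(self) -> np.ndarray:
        """Element per atom, inferring from the atom name where blank."""
        out = np.empty(self.n_atoms, dtype=object)
        for i in range(self.n_atoms):
            el = str(self.elements[i]).strip()
            out[i] = el.upper() if el else infer_element(str(self.atom_names[i]))
        return out

    def masses(self) -> np.ndarray:
        return np.array([atomic_mass(el) for el in self.resolved_elements()])

    def select(self, residue_range: tuple[int, int]) -> np.ndarray:
        """Boolean mask of atoms whose residue number lies in the inclusive range."""
        lo, hi = residue_range
        return (self.res_ids >= lo) & (self.res_ids <= hi)

    def heavy_mask(self) -> np.ndarray:
        return np.array([el not in ("H", "D") for el in self.resolved_elements()])


@dataclass(frozen=True)
class DistanceContactSeries:
    """Per-frame COM distance (A) and heavy-atom contact count."""

    distances: np.ndarray
    contacts: np.ndarray
    cutoff: float

    def __post_init__(self):
        object.__setattr__(self, "distances", np.asarray(self.distances, dtype=float))
        object.__setattr__(self, "contacts", np.asarray(self.contacts, dtype=int))
        if self.distances.size != self.contacts.size:
            raise ValueError("distance and contact series must have equal length")
        if np.any(self.distances < 0) or np.any(self.contacts < 0):
            raise ValueError("distances and contact counts must be >= 0")


def _require_selection(ensemble: FrameEnsemble, residue_range: tuple[int, int]) -> np.ndarray:
    mask = ensemble.select(residue_range)
    if not mask.any():
        raise SelectionError(f"residue range {residue_range[0]}-{residue_range[1]} selects no atoms")
    return mask


def center_of_mass(
    ensemble: FrameEnsemble,
    residue_range: tuple[int, int],
    weighting: str = "mass",
    frame: int | None = None,
) -> np.ndarray:
    """Centre of mass of a residue range, per frame.

    ``weighting="mass"`` uses standard atomic masses (the common
    trajectory-analysis default); ``"geometric"`` weights every atom equally.
    Returns (3,) for a single ``frame`` or (n_frames, 3) for all.
    """
    if weighting not in ("mass", "geometric"):
        raise ValueError("weighting must be 'mass' or 'geometric'")
    mask = _require_selection(ensemble, residue_range)
    xyz = ensemble.coords[:, mask, :]
    if weighting == "mass":
        w = ensemble.masses()[mask]
    else:
        w = np.ones(int(mask.sum()))
    com = np.einsum("fax,a->fx", xyz, w) / w.sum()
    return com[frame] if frame is not None else com


def com_distance_series(
    ensemble: FrameEnsemble,
    domains: DomainDefinition,
    weighting: str = "mass",
) -> np.ndarray:
    """Euclidean REC2-NUC centre-of-mass distance per frame (A)."""
    com_a = center_of_mass(ensemble, domains.rec2, weighting)
    com_b = center_of_mass(ensemble, domains.nuc, weighting)
    return np.linalg.norm(com_a - com_b, axis=1)


def _heavy_coords(ensemble, residue_range, frame):
    mask = _require_selection(ensemble, residue_range) & ensemble.heavy_mask()
    return ensemble.coords[frame, mask, :]


def contact_count(
    ensemble: FrameEnsemble,
    domains: DomainDefinition,
    frame: int = 0,
    cutoff: float = 3.5,
) -> int:
    """Number of (REC2 heavy atom, NUC heavy atom) pairs strictly closer
    than ``cutoff`` in one frame.  Hydrogens are excluded on both sides.

    Candidate pairs come from a k-d tree at radius ``cutoff`` (inclusive)
    and are then filtered with the strict inequality, so pairs at exactly
    the cutoff never count.
    """
    a = _heavy_coords(ensemble, domains.rec2, frame)
    b = _heavy_coords(ensemble, domains.nuc, frame)
    if a.size == 0 or b.size == 0:
        return 0
    pairs = cKDTree(a).query_ball_tree(cKDTree(b), r=cutoff)
    cut2 = cutoff * cutoff
    count = 0
    for i, js in enumerate(pairs):
        if js:
            d2 = np.sum((b[js] - a[i]) ** 2, axis=1)
            count += int(np.count_nonzero(d2 < cut2))
    return count


def contact_series(
    ensemble: FrameEnsemble,
    domains: DomainDefinition,
    cutoff: float = 3.5,
    weighting: str = "mass",
) -> DistanceContactSeries:
    """COM distances and contact counts for every frame."""
    distances = com_distance_series(ensemble, domains, weighting)
    contacts = [contact_count(ensemble, domains, f, cutoff) for f in range(ensemble.n_frames)]
    return DistanceContactSeries(distances=distances, contacts=contacts, cutoff=cutoff)


def contact_residue_pairs(
    ensemble: FrameEnsemble,
    domains: DomainDefinition,
    cutoff: float = 3.5,
    min_frame_fraction: float = 0.1,
) -> list[tuple[int, int, float]]:
    """Residue pairs in contact, with the fraction of frames where they touch.

    A REC2 residue and a NUC residue are in contact in a frame when any
    heavy-atom pair between them is strictly closer than ``cutoff``.  Pairs
    seen in at least ``min_frame_fraction`` of frames are returned sorted by
    fraction descending (ties by residue numbers).
    """
    heavy = ensemble.heavy_mask()
    mask_a = _require_selection(ensemble, domains.rec2) & heavy
    mask_b = _require_selection(ensemble, domains.nuc) & heavy
    res_a = ensemble.res_ids[mask_a]
    res_b = ensemble.res_ids[mask_b]
    cut2 = cutoff * cutoff

    counts: dict[tuple[int, int], int] = {}
    for f in range(ensemble.n_frames):
        a = ensemble.coords[f, mask_a, :]
        b = ensemble.coords[f, mask_b, :]
        pairs = cKDTree(a).query_ball_tree(cKDTree(b), r=cutoff)
        seen: set[tuple[int, int]] = set()
        for i, js in enumerate(pairs):
            if not js:
                continue
            d2 = np.sum((b[js] - a[i]) ** 2, axis=1)
            for j, dd in zip(js, d2):
                if dd < cut2:
                    seen.add((int(res_a[i]), int(res_b[j])))
        for pair in seen:
            counts[pair] = counts.get(pair, 0) + 1

    n = ensemble.n_frames
    result = [
        (ra, rb, c / n)
        for (ra, rb), c in counts.items()
        if c / n >= min_frame_fraction
    ]
    result.sort(key=lambda t: (-t[2], t[0], t[1]))
    return result


def kde_density(
    samples,
    grid=None,
    bandwidth: float | None = None,
    n_grid: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """1-D Gaussian kernel density estimate.

    Bandwidth defaults to Scott's rule, h = sd * n^(-1/5) (sample s.d.,
    n-1 denominator); pass ``bandwidth`` in data units to override — needed
    e.g. for degenerate samples with zero spread.  When ``grid`` is omitted
    one is built spanning the data +/- 5 bandwidths.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError(f"need >= 2 samples for a KDE, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    if bandwidth is None:
        sd = float(np.std(x, ddof=1))
        if sd == 0.0:
            raise ValueError(
                "samples have zero variance; Scott's rule gives bandwidth 0 — "
                "pass an explicit bandwidth to override"
            )
        h = sd * x.size ** (-0.2)
    else:
        if bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")
        h = float(bandwidth)
    if grid is None:
        grid = np.linspace(x.min() - 5 * h, x.max() + 5 * h, n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - x[None, :]) / h
    density = np.exp(-0.5 * z * z).sum(axis=1) / (x.size * h * np.sqrt(2 * np.pi))
    return grid, density
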