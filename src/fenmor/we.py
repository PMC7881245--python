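"""Weighted-ensemble (WE) resampler with exact weight bookkeeping.

WE path sampling maintains many weighted trajectory replicas ("walkers")
binned along a progress coordinate.  After each propagation interval tau,
under-populated bins split their highest-weight walker (weight divided
equally among copies) and over-populated bins merge their two lowest-weight
walkers (the survivor, chosen with probability proportional to weight,
inherits the pair's combined weight) until every occupied bin holds exactly
the target number of walkers.  Total probability weight is conserved exactly
and the dynamics remain unbiased in expectation.

MD propagation is out of scope: the :class:`Propagator` interface is
pluggable and ships with an overdamped Brownian-dynamics toy on 1-D model
potentials so the protocol can be exercised end to end.  For a receptor-
ligand system the progress coordinate maps onto the ligand heavy-atom RMSD
from the starting pose (``geometry.superpose_rmsd`` with a receptor
C-alpha fit), binned e.g. on :data:`FENTANYL_RMSD_BIN_BOUNDARIES`.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Walker",
    "BinScheme",
    "WEConfig",
    "Propagator",
    "OverdampedBrownian",
    "DoubleWellPotential",
    "HarmonicPotential",
    "FENTANYL_RMSD_BIN_BOUNDARIES",
    "assign_bins",
    "resample",
    "run_we",
    "WELog",
    "weighted_bin_histogram",
    "boltzmann_bin_weights",
]

#: ligand-RMSD bin boundaries (Angstrom) used for the receptor-ligand WE runs;
#: the region above the last boundary is the overflow (">10") bin
FENTANYL_RMSD_BIN_BOUNDARIES = (
    0.0, 0.5, 1.0, 1.25, 1.5, 1.75, 2.0, 2.1, 2.2, 2.3, 2.4, 2.5, 2.6, 2.7,
    2.8, 2.9, 3.0, 3.1, 3.2, 3.3, 3.4, 3.5, 3.6, 3.7, 3.8, 3.9, 4.0, 4.1,
    4.2, 4.3, 4.4, 4.5, 4.6, 4.7, 4.8, 4.9, 5.0, 5.25, 5.5, 5.75, 6.0, 6.25,
    6.5, 6.75, 7.0, 7.25, 7.5, 7.75, 8.0, 8.25, 8.5, 8.75, 9.0, 9.5, 10.0,
)


@dataclass
class Walker:
    """One weighted replica: propagator-defined state plus probability mass."""

    state: np.ndarray
    weight: float
    history_id: int

    def __post_init__(self) -> None:
        if not (self.weight > 0):
            raise ValueError(f"walker {self.history_id}: weight must be > 0")
        self.state = np.atleast_1d(np.asarray(self.state, dtype=float))


@dataclass(frozen=True)
class BinScheme:
    """Strictly increasing boundaries; values >= the last boundary fall in the
    overflow bin.  Bins are half-open: [b_i, b_{i+1})."""

    boundaries: tuple[float, ...]

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries)
        if len(b) < 2 or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be strictly increasing, length >= 2")
        object.__setattr__(self, "boundaries", b)

    @property
    def n_bins(self) -> int:
        # len-1 interior bins plus the overflow bin
        return len(self.boundaries)

    def index(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        idx = np.searchsorted(self.boundaries, v, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)


@dataclass(frozen=True)
class WEConfig:
    target_per_bin: int
    tau: float
    n_iterations: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_per_bin < 1:
            raise ValueError("target_per_bin must be >= 1")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


class Propagator(ABC):
    """Stochastic dynamics interface: advance a state by tau, report a scalar
    progress coordinate.  A stochastic thermostat is required so that split
    copies decorrelate."""

    @abstractmethod
    def advance(self, state: np.ndarray, tau: float, rng: np.random.Generator) -> np.ndarray:
        ...

    @abstractmethod
    def progress_coordinate(self, state: np.ndarray) -> float:
        ...


class DoubleWellPotential:
    """U(x) = h * ((x/a)^2 - 1)^2 + tilt * x, minima near x = +-a."""

    def __init__(self, barrier_height: float = 2.0, a: float = 1.0, tilt: float = 0.0):
        self.h, self.a, self.tilt = barrier_height, a, tilt

    def energy(self, x: np.ndarray) -> np.ndarray:
        u = (np.asarray(x) / self.a) ** 2 - 1.0
        return self.h * u ** 2 + self.tilt * np.asarray(x)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        return 4.0 * self.h * x * ((x / self.a) ** 2 - 1.0) / self.a ** 2 + self.tilt


class HarmonicPotential:
    def __init__(self, k: float = 1.0, x0: float = 0.0):
        self.k, self.x0 = k, x0

    def energy(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * self.k * (np.asarray(x) - self.x0) ** 2

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.k * (np.asarray(x) - self.x0)


class OverdampedBrownian(Propagator):
    """Euler-Maruyama overdamped Langevin dynamics on a 1-D potential.

    dx = -(1/gamma) U'(x) dt + sqrt(2 kT dt / gamma) xi.  ``kT = 0`` gives the
    deterministic steepest-descent limit.
    """

    def __init__(self, potential, kT: float = 1.0, friction: float = 1.0, dt: float = 0.01):
        self.potential, self.kT, self.friction, self.dt = potential, kT, friction, dt

    def advance(self, state: np.ndarray, tau: float, rng: np.random.Generator) -> np.ndarray:
        x = float(np.atleast_1d(state)[0])
        n_steps = max(1, int(round(tau / self.dt)))
        sigma = np.sqrt(2.0 * self.kT * self.dt / self.friction)
        noise = rng.standard_normal(n_steps) if self.kT > 0 else np.zeros(n_steps)
        for k in range(n_steps):
            x += -self.potential.gradient(x) * self.dt / self.friction + sigma * noise[k]
        return np.array([x])

    def progress_coordinate(self, state: np.ndarray) -> float:
        return float(np.atleast_1d(state)[0])


def assign_bins(walkers: Sequence[Walker], scheme: BinScheme,
                propagator: Propagator | None = None) -> np.ndarray:
    """Bin index per walker.

    With a propagator the coordinate is ``propagator.progress_coordinate``;
    without one, the last component of the state vector is used (identity for
    the 1-D toys).
    """
    if propagator is not None:
        coords = np.array([propagator.progress_coordinate(w.state) for w in walkers])
    else:
        coords = np.array([w.state[-1] for w in walkers], dtype=float)
    return _assign_coords(coords, walkers, scheme)


def _assign_coords(coords: np.ndarray, walkers: Sequence[Walker], scheme: BinScheme) -> np.ndarray:
    for w, c in zip(walkers, coords):
        if not np.isfinite(c):
            raise ValueError(f"walker {w.history_id}: non-finite progress coordinate")
    return scheme.index(coords)


def resample(walkers: Sequence[Walker], bins: np.ndarray, config: WEConfig,
             rng: np.random.Generator, id_start: int | None = None) -> list[Walker]:
    """Split/merge every occupied bin to exactly ``target_per_bin`` walkers.

    Splitting halves the highest-weight walker (ties: lowest lineage id)
    until the bin is full; merging repeatedly combines the two lowest-weight
    walkers, the survivor drawn with probability proportional to weight.
    Total weight is conserved exactly.
    """
    walkers = list(walkers)
    bins = np.asarray(bins)
    if len(walkers) != len(bins):
        raise ValueError("walkers/bins length mismatch")
    next_id = (max(w.history_id for w in walkers) + 1) if id_start is None else id_start
    out: list[Walker] = []
    for b in np.unique(bins):
        group = [walkers[i] for i in np.nonzero(bins == b)[0]]
        total = sum(w.weight for w in group)
        assert total > 0, "bin with zero total weight"
        while len(group) < config.target_per_bin:
            k = max(range(len(group)), key=lambda i: (group[i].weight, -group[i].history_id))
            w = group.pop(k)
            half = w.weight / 2.0
            group.append(Walker(w.state.copy(), half, next_id)); next_id += 1
            group.append(Walker(w.state.copy(), half, next_id)); next_id += 1
        while len(group) > config.target_per_bin:
            order = sorted(range(len(group)), key=lambda i: (group[i].weight, group[i].history_id))
            i, j = order[0], order[1]
            wi, wj = group[i], group[j]
            keep = wi if rng.random() < wi.weight / (wi.weight + wj.weight) else wj
            merged = Walker(keep.state.copy(), wi.weight + wj.weight, next_id); next_id += 1
            group = [g for k2, g in enumerate(group) if k2 not in (i, j)] + [merged]
        out.extend(group)
    return out


@dataclass
class WELog:
    """Per-iteration record sufficient to rebuild weighted histograms."""

    iterations: list[dict] = field(default_factory=list)
    seed: int = 0

    def append(self, iteration: int, walkers: Sequence[Walker], coords: np.ndarray,
               bins: np.ndarray) -> None:
        self.iterations.append({
            "iteration": iteration,
            "ids": np.array([w.history_id for w in walkers]),
            "weights": np.array([w.weight for w in walkers]),
            "pcoords": np.asarray(coords, dtype=float).copy(),
            "bins": np.asarray(bins).copy(),
        })

    def total_weight(self, it: int) -> float:
        return float(self.iterations[it]["weights"].sum())


def run_we(propagator: Propagator, scheme: BinScheme, config: WEConfig,
           initial: Sequence[Walker]) -> WELog:
    """Alternate tau-propagation of every walker with split/merge resampling.

    Fully reproducible from ``config.seed``; initial weights must sum to 1.
    """
    if abs(sum(w.weight for w in initial) - 1.0) > 1e-9:
        raise ValueError("initial weights must sum to 1")
    rng = np.random.default_rng(config.seed)
    walkers = [Walker(w.state.copy(), w.weight, w.history_id) for w in initial]
    next_id = max(w.history_id for w in walkers) + 1
    log = WELog(seed=config.seed)
    for it in range(config.n_iterations):
        for k, w in enumerate(walkers):
            try:
                w.state = propagator.advance(w.state, config.tau, rng)
            except Exception as exc:
                raise RuntimeError(f"propagator failed at iteration {it}, "
                                   f"walker {w.history_id}: {exc}") from exc
        coords = np.array([propagator.progress_coordinate(w.state) for w in walkers])
        bins = _assign_coords(coords, walkers, scheme)
        log.append(it, walkers, coords, bins)
        walkers = resample(walkers, bins, config, rng, id_start=next_id)
        next_id = max(w.history_id for w in walkers) + 1
    return log


def weighted_bin_histogram(log: WELog, scheme: BinScheme, last_n: int | None = None) -> np.ndarray:
    """Mean weighted bin occupancy over the last ``last_n`` iterations."""
    its = log.iterations[-last_n:] if last_n else log.iterations
    hist = np.zeros(scheme.n_bins)
    for rec in its:
        hist += np.bincount(rec["bins"], weights=rec["weights"], minlength=scheme.n_bins)
    return hist / len(its)


def boltzmann_bin_weights(potential, scheme: BinScheme, kT: float,
                          pad: float = 5.0, n_grid: int = 20001) -> np.ndarray:
    """Analytic equilibrium bin weights ~ integral of exp(-U/kT) per bin.

    The overflow bin integrates from the last boundary out to
    ``last boundary + pad``.
    """
    b = np.array(scheme.boundaries)
    lo, hi = b[0], b[-1] + pad
    x = np.linspace(lo, hi, n_grid)
    p = np.exp(-potential.energy(x) / kT)
    edges = np.append(b, hi)
    weights = np.empty(scheme.n_bins)
    for i in range(scheme.n_bins):
        mask = (x >= edges[i]) & (x <= edges[i + 1])
        weights[i] = np.trapezoid(p[mask], x[mask])
    return weights / weights.sum()
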