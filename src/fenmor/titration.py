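"""Titration-state analysis over a pH ladder.

Consumes discrete per-frame protonation/tautomer state series (e.g. the
output of constant-pH simulations discretised per frame): histidine states
HID / HIE / HIP, or two-state PROT / DEPROT for acids and amines.  Provides
state-occupancy curves, a macroscopic pKa from a generalised
Henderson-Hasselbalch (Hill) fit of the deprotonated fraction

    f_deprot(pH) = 1 / (1 + 10^(n * (pKa - pH))),

bootstrap pKa uncertainty, interpolation of occupancies at physiological pH,
and the conditional statistics coupling the tautomer state to a paired
ligand-residue distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "HIS_STATES",
    "TWO_STATES",
    "TitrationSeries",
    "TitrationCurve",
    "PkaFit",
    "occupancy_curve",
    "deprotonated_fraction",
    "fit_pka",
    "bootstrap_pka",
    "interpolate_occupancy",
    "tautomer_distance_coupling",
    "lambda_to_state",
]

HIS_STATES = ("HID", "HIE", "HIP")   # HIP is the protonated (charged) species
TWO_STATES = ("DEPROT", "PROT")

#: which states count as deprotonated, per alphabet
_DEPROT = {HIS_STATES: ("HID", "HIE"), TWO_STATES: ("DEPROT",)}


@dataclass
class TitrationSeries:
    """Per-pH, per-frame discrete states with an optional paired distance series."""

    ph_values: tuple[float, ...]
    states: dict[float, np.ndarray]
    residue: str = ""
    alphabet: tuple[str, ...] = HIS_STATES
    distances: dict[float, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.ph_values = tuple(float(p) for p in self.ph_values)
        for ph in self.ph_values:
            if ph not in self.states:
                raise KeyError(f"missing state column for pH {ph}")
            arr = np.asarray(self.states[ph])
            if arr.size == 0:
                raise ValueError(f"pH {ph}: no frames")
            bad = set(arr.tolist()) - set(self.alphabet)
            if bad:
                raise ValueError(f"pH {ph}: states {sorted(bad)} outside alphabet {self.alphabet}")
            self.states[ph] = arr
            if self.distances is not None:
                d = np.asarray(self.distances[ph], dtype=float)
                if d.shape != arr.shape:
                    raise ValueError(f"pH {ph}: distance series length {d.shape} != "
                                     f"state series length {arr.shape}")
                self.distances[ph] = d

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for ph in self.ph_values:
            for f, s in enumerate(self.states[ph]):
                row = [ph, f, self.residue, s]
                if self.distances is not None:
                    row.append(self.distances[ph][f])
                rows.append(row)
        cols = ["ph", "frame", "residue", "state"] + (
            ["distance"] if self.distances is not None else [])
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, residue: str | None = None,
                 alphabet: tuple[str, ...] | None = None) -> "TitrationSeries":
        df = pd.read_csv(path, sep="\t")
        if residue is not None:
            df = df[df["residue"] == residue]
        if df.empty:
            raise ValueError(f"{path}: no rows" + (f" for residue {residue!r}" if residue else ""))
        phs = tuple(sorted(df["ph"].unique()))
        states = {ph: df[df["ph"] == ph].sort_values("frame")["state"].to_numpy()
                  for ph in phs}
        distances = None
        if "distance" in df.columns:
            distances = {ph: df[df["ph"] == ph].sort_values("frame")["distance"].to_numpy(float)
                         for ph in phs}
        if alphabet is None:
            observed = set(df["state"].unique())
            alphabet = HIS_STATES if observed <= set(HIS_STATES) else TWO_STATES
        return cls(phs, states, residue=residue or str(df["residue"].iloc[0]),
                   alphabet=alphabet, distances=distances)


@dataclass
class TitrationCurve:
    """State occupancies per pH (rows sum to 1) plus optional fit results."""

    occupancies: pd.DataFrame        # index = pH, columns = states
    counts: pd.Series                # frames per pH (fit weights)
    alphabet: tuple[str, ...]
    pka: float | None = None
    hill_n: float | None = None
    fit_residual: float | None = None

    def __post_init__(self) -> None:
        sums = self.occupancies.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("occupancies must sum to 1 at every pH")


@dataclass(frozen=True)
class PkaFit:
    pka: float
    hill_n: float
    residual: float
    in_window: bool


def occupancy_curve(series: TitrationSeries) -> TitrationCurve:
    """State frequencies at each pH."""
    occ = {}
    counts = {}
    for ph in series.ph_values:
        arr = series.states[ph]
        counts[ph] = arr.size
        occ[ph] = {s: float(np.mean(arr == s)) for s in series.alphabet}
    df = pd.DataFrame(occ).T.loc[list(series.ph_values), list(series.alphabet)]
    return TitrationCurve(df, pd.Series(counts), series.alphabet)


def deprotonated_fraction(curve: TitrationCurve) -> pd.Series:
    """Deprotonated population per pH (His: HID+HIE; two-state: DEPROT)."""
    deprot = _DEPROT.get(tuple(curve.alphabet))
    if deprot is None:
        raise ValueError(f"unknown state alphabet {curve.alphabet}")
    return curve.occupancies[list(deprot)].sum(axis=1)


def _hh(ph: np.ndarray, pka: float, n: float) -> np.ndarray:
    return 1.0 / (1.0 + 10.0 ** (n * (pka - ph)))


def fit_pka(curve: TitrationCurve) -> PkaFit:
    """Weighted least-squares Hill fit of the deprotonated fraction vs pH.

    Weights are the per-pH frame counts.  Raises if the fraction never leaves
    0 or 1 inside the pH window (pKa outside the window: no extrapolated
    number is reported).  ``in_window`` flags whether the fitted pKa lies
    inside the sampled pH range.
    """
    ph = np.array(curve.occupancies.index, dtype=float)
    f = deprotonated_fraction(curve).to_numpy()
    w = np.sqrt(curve.counts.loc[curve.occupancies.index].to_numpy(float))
    if np.all(f < 1e-12) or np.all(f > 1 - 1e-12):
        raise ValueError("deprotonated fraction constant at 0 or 1: pKa outside the pH window")
    order = np.argsort(ph)
    ph, f, w = ph[order], f[order], w[order]
    p0 = (float(ph[np.argmin(np.abs(f - 0.5))]), 1.0)
    res = least_squares(lambda p: w * (_hh(ph, p[0], p[1]) - f), p0,
                        bounds=((ph.min() - 10.0, 0.05), (ph.max() + 10.0, 10.0)))
    pka, n = float(res.x[0]), float(res.x[1])
    return PkaFit(pka, n, float(np.sqrt(np.mean((res.fun / w) ** 2))),
                  in_window=bool(ph.min() <= pka <= ph.max()))


def bootstrap_pka(series: TitrationSeries, n_boot: int = 200,
                  seed: int = 0) -> tuple[float, float]:
    """Bootstrap (over frames, per pH) mean and standard deviation of the pKa."""
    rng = np.random.default_rng(seed)
    pkas = []
    for _ in range(n_boot):
        states = {}
        for ph in series.ph_values:
            arr = series.states[ph]
            states[ph] = arr[rng.integers(0, arr.size, arr.size)]
        boot = TitrationSeries(series.ph_values, states, residue=series.residue,
                               alphabet=series.alphabet)
        pkas.append(fit_pka(occupancy_curve(boot)).pka)
    return float(np.mean(pkas)), float(np.std(pkas, ddof=1))


def interpolate_occupancy(curve: TitrationCurve, ph: float = 7.4,
                          method: str = "linear") -> pd.Series:
    """State occupancies at an arbitrary pH.

    ``linear`` interpolates between the bracketing replicas (default);
    ``nearest`` reads the closest replica.
    """
    grid = np.array(curve.occupancies.index, dtype=float)
    if method == "nearest":
        return curve.occupancies.iloc[int(np.argmin(np.abs(grid - ph)))]
    if method != "linear":
        raise ValueError(f"unknown interpolation method {method!r}")
    if ph <= grid.min():
        return curve.occupancies.iloc[int(np.argmin(grid))]
    if ph >= grid.max():
        return curve.occupancies.iloc[int(np.argmax(grid))]
    out = {s: float(np.interp(ph, grid, curve.occupancies[s].to_numpy(float)))
           for s in curve.alphabet}
    return pd.Series(out)


def tautomer_distance_coupling(series: TitrationSeries) -> pd.DataFrame:
    """Conditional distance statistics per (pH, state).

    Returns a table (ph, state, mean_distance, sd_distance, occupancy, n);
    (pH, state) combinations never sampled are absent rather than zero-filled.
    """
    if series.distances is None:
        raise ValueError("series carries no paired distance data")
    rows = []
    for ph in series.ph_values:
        arr, d = series.states[ph], series.distances[ph]
        for s in series.alphabet:
            mask = arr == s
            n = int(mask.sum())
            if n == 0:
                continue
            rows.append((ph, s, float(d[mask].mean()),
                         float(d[mask].std(ddof=1)) if n > 1 else 0.0,
                         n / arr.size, n))
    return pd.DataFrame(rows, columns=["ph", "state", "mean_distance",
                                       "sd_distance", "occupancy", "n"])


def lambda_to_state(lmbda: np.ndarray, x: np.ndarray | None = None,
                    low: float = 0.2, high: float = 0.8) -> np.ndarray:
    """Discretise continuous titration coordinates to PROT/DEPROT states.

    lambda < ``low`` is protonated, lambda > ``high`` deprotonated;
    intermediate (mixed) frames are discarded.  With a tautomer coordinate
    ``x`` paired to a histidine lambda, deprotonated-site bookkeeping is the
    caller's job; this adapter covers the common two-state case.
    """
    lmbda = np.asarray(lmbda, dtype=float)
    keep = (lmbda < low) | (lmbda > high)
    out = np.where(lmbda[keep] < low, "PROT", "DEPROT")
    return out
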