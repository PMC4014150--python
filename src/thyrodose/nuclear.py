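"""Radionuclide emission spectra and beta-spectrum sampling.

A :class:`NuclideSpectrum` carries the discrete photon lines and the electron
components (beta continua, conversion lines, mean-energy Auger groups) of a
nuclide together with its physical half-life.  Packaged fixtures for I-131,
I-123 and Tc-99m are compiled from ENSDF-derived decay data, keeping emissions
with yields above 0.1% per decay; they are inputs to the pipeline, not
reference values.

Beta continua are represented by their endpoint energy and sampled from the
allowed-shape Fermi spectrum ``F(Z, E) * p * W * (Emax - E)^2`` with the
nonrelativistic point-charge Coulomb factor ``F = 2*pi*eta / (1 - exp(-2*pi*eta))``,
``eta = +Z*alpha/beta`` for beta-minus decay.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ElectronComponent",
    "NuclideSpectrum",
    "YIELD_CUT",
    "load_spectrum",
    "fermi_beta_pdf",
    "beta_mean_energy",
    "sample_beta",
    "sample_emission",
    "mean_energy_per_decay",
]

log = logging.getLogger(__name__)

#: Emissions with per-decay yield at or below this value are dropped on load.
YIELD_CUT = 1e-3

_ALPHA = 1.0 / 137.035999
_MEC2 = 0.51099895  # MeV

_PACKAGED = {"I-131": "i131.csv", "I-123": "i123.csv", "Tc-99m": "tc99m.csv"}


@dataclass(frozen=True)
class ElectronComponent:
    """One electron emission: a beta continuum, conversion line or Auger group."""

    kind: str  # beta_minus | conversion | auger
    energy: float  # MeV; beta: endpoint Emax, conversion: line, auger: mean
    emission_yield: float  # per decay
    daughter_Z: int = 0  # beta components only

    def __post_init__(self) -> None:
        if self.kind not in ("beta_minus", "conversion", "auger"):
            raise ValueError(f"unknown electron component kind {self.kind!r}")
        if self.energy <= 0 or self.emission_yield <= 0:
            raise ValueError("electron component energy and yield must be positive")
        if self.kind == "beta_minus" and self.daughter_Z <= 0:
            raise ValueError("beta components need the daughter atomic number")

    @property
    def mean_energy(self) -> float:
        """Mean energy per emission (beta: Fermi-spectrum mean, else the line)."""
        if self.kind == "beta_minus":
            return beta_mean_energy(self.energy, self.daughter_Z)
        return self.energy


@dataclass(frozen=True)
class NuclideSpectrum:
    nuclide: str
    half_life_h: float
    photon_lines: tuple[tuple[float, float], ...]  # (energy MeV, yield/decay)
    electron_components: tuple[ElectronComponent, ...]
    dropped_lines: int = 0

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValueError("half-life must be positive")
        for e, y in self.photon_lines:
            if e <= 0 or y <= YIELD_CUT:
                raise ValueError("photon lines must have positive energy and yield > the 0.1% cut")
        for c in self.electron_components:
            if c.emission_yield <= YIELD_CUT:
                raise ValueError("electron components must have yield > the 0.1% cut")

    @property
    def lambda_phys_per_s(self) -> float:
        """Physical decay constant (1/s)."""
        return np.log(2.0) / (self.half_life_h * 3600.0)

    def total_yield(self, particle_kind: str) -> float:
        if particle_kind == "photon":
            return float(sum(y for _, y in self.photon_lines))
        if particle_kind == "electron":
            return float(sum(c.emission_yield for c in self.electron_components))
        raise ValueError(f"unknown particle kind {particle_kind!r}")


# ---------------------------------------------------------------------------
# Fermi beta spectrum
# ---------------------------------------------------------------------------

def _fermi_shape(E: np.ndarray, Emax: float, Z: int) -> np.ndarray:
    """Unnormalised allowed shape F(Z,E) * p * W * (Emax - E)^2 (E in MeV)."""
    E = np.asarray(E, dtype=float)
    W = 1.0 + E / _MEC2  # total energy, mec^2 units
    p = np.sqrt(np.maximum(W * W - 1.0, 0.0))
    shape = np.zeros_like(E)
    ok = (E > 0.0) & (E < Emax) & (p > 0.0)
    if Z > 0:
        beta = np.divide(p, W, out=np.ones_like(p), where=ok)
        eta = Z * _ALPHA / np.maximum(beta, 1e-12)
        two_pi_eta = 2.0 * np.pi * eta
        coulomb = two_pi_eta / (1.0 - np.exp(-two_pi_eta))
    else:
        coulomb = np.ones_like(E)
    shape[ok] = (coulomb * p * W * (Emax - E) ** 2)[ok]
    return shape


@lru_cache(maxsize=64)
def _beta_grid(Emax: float, Z: int, n: int = 2048):
    """(energy grid, pdf, cdf) for one beta branch; cdf normalised to 1."""
    if Emax <= 0:
        raise ValueError("Emax must be positive")
    E = np.linspace(0.0, Emax, n)
    f = _fermi_shape(E, Emax, Z)
    norm = np.trapezoid(f, E)
    pdf = f / norm
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2.0 * np.diff(E))])
    cdf /= cdf[-1]
    return E, pdf, cdf


def fermi_beta_pdf(E, Emax: float, Z_daughter: int):
    """Normalised beta-spectrum density at energy ``E`` (MeV^-1).

    Raises if any requested energy lies outside the open interval (0, Emax).
    """
    if Emax <= 0:
        raise ValueError("Emax must be positive")
    E_arr = np.asarray(E, dtype=float)
    if np.any((E_arr <= 0.0) | (E_arr >= Emax)):
        raise ValueError("E must lie strictly inside (0, Emax)")
    grid, pdf, _ = _beta_grid(float(Emax), int(Z_daughter))
    out = np.interp(E_arr, grid, pdf)
    return float(out) if np.isscalar(E) else out


def beta_mean_energy(Emax: float, Z_daughter: int) -> float:
    """Quadrature mean of the Fermi spectrum (MeV)."""
    grid, pdf, _ = _beta_grid(float(Emax), int(Z_daughter))
    return float(np.trapezoid(grid * pdf, grid))


def sample_beta(Emax: float, Z_daughter: int, rng: np.random.Generator, size=None) -> np.ndarray:
    """Inverse-transform sampling on the precomputed CDF grid."""
    grid, _, cdf = _beta_grid(float(Emax), int(Z_daughter))
    u = rng.random(size)
    return np.interp(u, cdf, grid)


# ---------------------------------------------------------------------------
# Spectrum I/O and sampling
# ---------------------------------------------------------------------------

def _parse_spectrum_csv(text: str, fallback_name: str) -> NuclideSpectrum:
    meta: dict[str, str] = {}
    for line in text.splitlines():
        if line.startswith("#") and ":" in line:
            k, v = line[1:].split(":", 1)
            meta[k.strip()] = v.strip()
    table = pd.read_csv(io.StringIO(text), comment="#")
    required = {"kind", "energy_MeV", "yield", "daughter_Z"}
    if not required.issubset(table.columns):
        raise ValueError(f"spectrum file lacks columns {sorted(required - set(table.columns))}")
    if "half_life_hours" not in meta:
        raise ValueError("spectrum file must carry a '# half_life_hours:' header")

    kept = table[table["yield"] > YIELD_CUT]
    dropped = len(table) - len(kept)
    if dropped:
        log.warning(
            "%s: dropped %d emission line(s) at or below the %.1f%% yield cut",
            meta.get("nuclide", fallback_name), dropped, YIELD_CUT * 100,
        )
    photons = tuple(
        (float(e), float(y))
        for e, y in kept.loc[kept.kind == "photon", ["energy_MeV", "yield"]].to_numpy()
    )
    electrons = tuple(
        ElectronComponent(
            kind=str(row["kind"]),
            energy=float(row["energy_MeV"]),
            emission_yield=float(row["yield"]),
            daughter_Z=int(row["daughter_Z"]),
        )
        for _, row in kept[kept.kind != "photon"].iterrows()
    )
    return NuclideSpectrum(
        nuclide=meta.get("nuclide", fallback_name),
        half_life_h=float(meta["half_life_hours"]),
        photon_lines=photons,
        electron_components=electrons,
        dropped_lines=dropped,
    )


def load_spectrum(nuclide_id: str | Path) -> NuclideSpectrum:
    """Load a packaged nuclide fixture (``I-131``, ``I-123``, ``Tc-99m``) or a
    user CSV in the same schema; sub-0.1%-yield lines are dropped with a log note."""
    key = str(nuclide_id)
    if key in _PACKAGED:
        text = resources.files("thyrodose").joinpath("data/spectra").joinpath(_PACKAGED[key]).read_text()
        return _parse_spectrum_csv(text, key)
    path = Path(key)
    if path.exists():
        return _parse_spectrum_csv(path.read_text(), path.stem)
    raise KeyError(f"unknown nuclide {nuclide_id!r} and no such spectrum file")


def sample_emission(
    spectrum: NuclideSpectrum,
    particle_kind: str,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray | float:
    """Draw emission energies (MeV) of one particle kind, lines weighted by yield.

    Beta components are drawn from the Fermi spectrum by inverse transform.
    """
    n = 1 if size is None else int(size)
    if particle_kind == "photon":
        if not spectrum.photon_lines:
            raise ValueError(f"{spectrum.nuclide} has no photon lines")
        energies = np.array([e for e, _ in spectrum.photon_lines])
        yields = np.array([y for _, y in spectrum.photon_lines])
        idx = rng.choice(len(energies), size=n, p=yields / yields.sum())
        out = energies[idx]
    elif particle_kind == "electron":
        comps = spectrum.electron_components
        if not comps:
            raise ValueError(f"{spectrum.nuclide} has no electron components")
        yields = np.array([c.emission_yield for c in comps])
        idx = rng.choice(len(comps), size=n, p=yields / yields.sum())
        out = np.empty(n)
        for i, comp in enumerate(comps):
            sel = idx == i
            cnt = int(sel.sum())
            if cnt == 0:
                continue
            if comp.kind == "beta_minus":
                out[sel] = sample_beta(comp.energy, comp.daughter_Z, rng, cnt)
            else:
                out[sel] = comp.energy
    else:
        raise ValueError(f"unknown particle kind {particle_kind!r}")
    return float(out[0]) if size is None else out


def mean_energy_per_decay(spectrum: NuclideSpectrum, particle_kind: str) -> float:
    """Sum of yield x energy (MeV per decay); beta branches enter with their spectrum mean."""
    if particle_kind == "photon":
        return float(sum(e * y for e, y in spectrum.photon_lines))
    if particle_kind == "electron":
        return float(sum(c.emission_yield * c.mean_energy for c in spectrum.electron_components))
    raise ValueError(f"unknown particle kind {particle_kind!r}")
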