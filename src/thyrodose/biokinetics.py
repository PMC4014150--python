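"""Compartmental biokinetics: multicomponent-exponential retention and
analytic cumulated activities.

The activity resident in a source region after administering unit activity is
modelled as a general first-order (sum-of-exponentials) retention

    A(r_S, t) = F_S * sum_i a_i * exp(-(lambda_i + lambda_p) * t)

where ``F_S`` is the fractional distribution to the region, ``a_i`` the
fraction taken up or eliminated with biological half-life ``T_i``
(``lambda_i = ln 2 / T_i``) and ``lambda_p`` the physical decay constant.
Uptake phases are encoded as paired positive/negative ``a_i`` terms.  The
cumulated activity is the closed-form time integral

    Atilde(r_S) = F_S * sum_i a_i / (lambda_i + lambda_p)      [seconds per
                                                                unit administered]

The packaged scenario coefficients for iodide (thyroid uptakes 0-55%) and
pertechnetate (IV, IV + blocking agent, oral) are *illustrative*: they follow
the structure and qualitative behaviour of the reference first-order models
(thyroid residence grows with uptake, urine residence shrinks, oral intake
shifts residence into the stomach contents) but are not transcriptions of any
published coefficient set.  Users holding a published set can supply it as a
JSON fixture in the same schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nuclear import NuclideSpectrum, load_spectrum

__all__ = [
    "SourceCompartment",
    "BiokineticScenario",
    "CumulatedActivitySet",
    "activity_at_time",
    "cumulated_activity",
    "build_scenario",
    "residence_time_table",
    "iodide_compartments",
    "pertechnetate_compartments",
    "UPTAKE_LEVELS",
]

LN2 = float(np.log(2.0))

#: Thyroid-uptake levels studied for radioiodide (0 = blocked thyroid).
UPTAKE_LEVELS = (0.0, 0.05, 0.15, 0.25, 0.35, 0.45, 0.55)


@dataclass(frozen=True)
class SourceCompartment:
    """Retention of one source region: F_S plus (a_i, T_bio_i) components."""

    region_id: str
    F_s: float
    components: tuple[tuple[float, float], ...]  # (a_i, T_bio_i hours), T_bio > 0

    def __post_init__(self) -> None:
        if self.F_s < 0:
            raise ValueError(f"{self.region_id}: F_s must be >= 0")
        for a, T in self.components:
            if T <= 0:
                raise ValueError(f"{self.region_id}: biological half-lives must be positive")
        # retention must be non-negative over time (uptake phases use negative a_i)
        if self.F_s > 0 and self.components:
            t = np.geomspace(1e-3, 24.0 * 3650.0, 400) * 3600.0  # 1e-3 h .. 10 y, in s
            if np.any(self._activity(0.0, t) < -1e-12):
                raise ValueError(f"{self.region_id}: retention goes negative; bad (a_i, T_i) set")

    def _activity(self, lambda_p: float, t: np.ndarray) -> np.ndarray:
        out = np.zeros_like(t, dtype=float)
        for a, T_h in self.components:
            lam = LN2 / (T_h * 3600.0)
            out += a * np.exp(-(lam + lambda_p) * t)
        return self.F_s * out


@dataclass(frozen=True)
class BiokineticScenario:
    nuclide: str
    agent: str  # iodide | pertechnetate
    administration: str  # iv | oral
    thyroid_uptake: float
    blocking_agent: bool
    compartments: tuple[SourceCompartment, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.thyroid_uptake <= 0.55):
            raise ValueError("thyroid uptake must lie in [0, 0.55]")
        thy = [c for c in self.compartments if c.region_id == "thyroid"]
        if self.blocking_agent or self.thyroid_uptake == 0.0:
            if any(c.F_s > 0 for c in thy):
                raise ValueError("blocked-thyroid scenario must have thyroid F_s = 0")

    def compartment(self, region_id: str) -> SourceCompartment:
        for c in self.compartments:
            if c.region_id == region_id:
                return c
        raise KeyError(f"no compartment for region {region_id!r}")

    @property
    def regions(self) -> list[str]:
        return [c.region_id for c in self.compartments]


@dataclass(frozen=True)
class CumulatedActivitySet:
    """Atilde per source region, in MBq*s per MBq administered (= seconds)."""

    nuclide: str
    scenario: BiokineticScenario | None
    atilde_s: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for region, val in self.atilde_s.items():
            if val < 0:
                raise ValueError(f"negative cumulated activity for {region}")

    def nonzero(self) -> dict[str, float]:
        return {r: v for r, v in self.atilde_s.items() if v > 0.0}

    def total(self) -> float:
        return float(sum(self.atilde_s.values()))


# ---------------------------------------------------------------------------
# Eq.-level operations
# ---------------------------------------------------------------------------

def activity_at_time(compartment: SourceCompartment, lambda_p: float, t) -> np.ndarray | float:
    """Resident activity fraction at time ``t`` seconds after administration."""
    if lambda_p <= 0:
        raise ValueError("lambda_p must be positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    out = compartment._activity(lambda_p, t_arr)
    return float(out) if np.isscalar(t) else out


def cumulated_activity(compartment: SourceCompartment, lambda_p: float) -> float:
    """Closed-form Atilde = F_S * sum_i a_i / (lambda_i + lambda_p), in seconds."""
    if lambda_p <= 0:
        raise ValueError("lambda_p must be positive")
    total = 0.0
    for a, T_h in compartment.components:
        lam = LN2 / (T_h * 3600.0)
        total += a / (lam + lambda_p)
    atilde = compartment.F_s * total
    if atilde < -1e-9:
        raise ValueError(f"{compartment.region_id}: parameter set yields negative Atilde")
    return max(atilde, 0.0)


def cumulated_activity_set(
    scenario: BiokineticScenario, spectrum: NuclideSpectrum | None = None
) -> CumulatedActivitySet:
    """Atilde for every compartment of a scenario (physical decay from the spectrum)."""
    spec = spectrum if spectrum is not None else load_spectrum(scenario.nuclide)
    lam_p = spec.lambda_phys_per_s
    return CumulatedActivitySet(
        nuclide=scenario.nuclide,
        scenario=scenario,
        atilde_s={c.region_id: cumulated_activity(c, lam_p) for c in scenario.compartments},
    )


def residence_time_table(scenario: BiokineticScenario, spectrum: NuclideSpectrum | None = None) -> pd.DataFrame:
    """Per-region Atilde in hours (residence times), as a tidy table."""
    aset = cumulated_activity_set(scenario, spectrum)
    rows = [
        {"region": r, "atilde_h": v / 3600.0, "atilde_s": v}
        for r, v in aset.atilde_s.items()
    ]
    return pd.DataFrame(rows, columns=["region", "atilde_h", "atilde_s"])


# ---------------------------------------------------------------------------
# Illustrative scenario coefficient sets
# ---------------------------------------------------------------------------

def iodide_compartments(uptake: float) -> tuple[SourceCompartment, ...]:
    """Illustrative radioiodide model parameterised by thyroid uptake ``u``.

    Thyroid: uptake from the circulating iodide pool (fast phase) and long
    organic retention.  Urine (bladder contents) carries most of the
    non-thyroidal iodide, so its residence falls as uptake rises.  Stomach,
    small intestine and kidneys see constant transit fractions.  Remaining
    tissues hold the circulating inorganic pool plus the organic iodine
    released from the thyroid.
    """
    u = float(uptake)
    if not (0.0 <= u <= 0.55):
        raise ValueError("uptake must lie in [0, 0.55]")
    comps = [
        SourceCompartment("thyroid", u, ((1.0, 1920.0), (-1.0, 6.0))),
        SourceCompartment("bladder_contents", 0.62 * (1.0 - u), ((1.0, 2.4), (-1.0, 0.4))),
        SourceCompartment("stomach", 0.10, ((1.0, 1.6), (-1.0, 0.3))),
        SourceCompartment("small_intestine", 0.07, ((1.0, 2.5), (-1.0, 0.5))),
        SourceCompartment("kidneys", 0.035, ((1.0, 3.0), (-1.0, 0.25))),
        SourceCompartment(
            "remaining_tissues",
            1.0,
            (
                (0.85 * (1.0 - u), 6.0),
                (-0.85 * (1.0 - u), 0.5),
                (0.25 * u, 288.0),
                (-0.25 * u, 48.0),
            ),
        ),
    ]
    return tuple(comps)


def pertechnetate_compartments(administration: str, blocking: bool) -> tuple[SourceCompartment, ...]:
    """Illustrative pertechnetate model for IV (with/without blocking) and oral intake."""
    if administration not in ("iv", "oral"):
        raise ValueError("administration must be 'iv' or 'oral'")
    if administration == "oral" and blocking:
        raise ValueError("the oral scenario is modelled without a blocking agent")
    thyroid_F = 0.0 if blocking else 0.02
    bladder_F = 0.40 if blocking else 0.30
    base = [
        SourceCompartment("thyroid", thyroid_F, ((1.0, 12.0), (-1.0, 1.0))),
        SourceCompartment("stomach", 0.08, ((1.0, 2.0), (-1.0, 0.4))),
        SourceCompartment("small_intestine", 0.07, ((1.0, 2.5), (-1.0, 0.6))),
        SourceCompartment("colon", 0.06, ((1.0, 8.0), (-1.0, 2.0))),
        SourceCompartment("kidneys", 0.04, ((1.0, 1.5), (-1.0, 0.3))),
        SourceCompartment("bladder_contents", bladder_F, ((1.0, 2.2), (-1.0, 0.5))),
        SourceCompartment("remaining_tissues", 1.0, ((0.75, 4.0), (-0.75, 0.5))),
    ]
    if administration == "iv":
        return tuple(base)
    # oral: gastric transit adds a strong stomach-contents source and every
    # systemic compartment sees less activity than after IV injection.
    scaled = [
        SourceCompartment(c.region_id, 0.8 * c.F_s, c.components) for c in base
    ]
    scaled.insert(1, SourceCompartment("stomach_contents", 1.0, ((1.0, 0.8), (-1.0, 0.08))))
    return tuple(scaled)


def build_scenario(
    agent: str,
    nuclide: str,
    uptake: float = 0.15,
    administration: str = "iv",
    blocking: bool = False,
    fixture_path: str | Path | None = None,
) -> BiokineticScenario:
    """Assemble a :class:`BiokineticScenario` from the built-in illustrative
    coefficients or from a JSON fixture file in the documented schema."""
    if fixture_path is not None:
        return load_scenario(fixture_path)
    if agent == "iodide":
        if blocking:
            uptake = 0.0
        comps = iodide_compartments(uptake)
        return BiokineticScenario(nuclide, "iodide", administration, uptake, uptake == 0.0, comps)
    if agent == "pertechnetate":
        comps = pertechnetate_compartments(administration, blocking)
        return BiokineticScenario(nuclide, "pertechnetate", administration, 0.0 if blocking else 0.02, blocking, comps)
    raise ValueError(f"unknown agent {agent!r}")


# ---------------------------------------------------------------------------
# JSON fixture round-trip
# ---------------------------------------------------------------------------

def scenario_to_dict(scn: BiokineticScenario) -> dict:
    return {
        "nuclide": scn.nuclide,
        "agent": scn.agent,
        "administration": scn.administration,
        "thyroid_uptake": scn.thyroid_uptake,
        "blocking_agent": scn.blocking_agent,
        "compartments": [
            {
                "region": c.region_id,
                "F_s": c.F_s,
                "a": [a for a, _ in c.components],
                "T_bio_h": [T for _, T in c.components],
            }
            for c in scn.compartments
        ],
    }


def save_scenario(scn: BiokineticScenario, path: str | Path) -> None:
    Path(path).write_text(json.dumps(scenario_to_dict(scn), indent=1))


def load_scenario(path: str | Path) -> BiokineticScenario:
    d = json.loads(Path(path).read_text())
    comps = tuple(
        SourceCompartment(
            c["region"], float(c["F_s"]), tuple(zip(map(float, c["a"]), map(float, c["T_bio_h"])))
        )
        for c in d["compartments"]
    )
    return BiokineticScenario(
        d["nuclide"], d["agent"], d["administration"],
        float(d["thyroid_uptake"]), bool(d["blocking_agent"]), comps,
    )
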