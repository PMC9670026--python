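"""Forward models for 1:1 Langmuir binding of IgG species to an immobilized ligand.

The sensor signal is the LSPR peak shift (picometers) produced by analyte
binding to Protein A on the chip surface.  Each species (monomeric IgG, or an
aggregate treated as a single analyte with its own effective rate constants) is
modelled with reaction-limited pseudo-first-order 1:1 kinetics:

    association:   dR/dt = k_on * C * (R_max - R) - k_off * R
                   R(t)  = R_eq * (1 - exp(-(k_on*C + k_off) * t)),
                   R_eq  = R_max * C / (C + K_D)
    dissociation:  R(t)  = R0 * exp(-k_off * t)

with C the molar analyte concentration, K_D = k_off / k_on.  Avidity enters
only through the per-species effective rate constants: aggregates binding
multiple ligands show a smaller effective k_off, hence a smaller apparent K_D.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "KineticParams",
    "SpeciesSpec",
    "InjectionProtocol",
    "Sensorgram",
    "molar_concentration",
    "association_response",
    "dissociation_response",
    "simulate_species_trace",
]


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of a 1:1 interaction.

    Attributes
    ----------
    k_on : float
        Association rate constant, M^-1 s^-1. Must be positive.
    k_off : float
        Dissociation rate constant, s^-1. Must be non-negative.
    """

    k_on: float
    k_off: float

    def __post_init__(self) -> None:
        if not self.k_on > 0:
            raise ValueError(f"k_on must be > 0, got {self.k_on}")
        if self.k_off < 0:
            raise ValueError(f"k_off must be >= 0, got {self.k_off}")

    @property
    def k_d(self) -> float:
        """Equilibrium dissociation constant K_D = k_off / k_on (M)."""
        return self.k_off / self.k_on


@dataclass(frozen=True)
class SpeciesSpec:
    """An analyte species with per-pH effective kinetics.

    ``molar_mass`` converts mass concentration (mg/mL) into molarity; for an
    aggregate the whole oligomer counts as one analyte, so a dimer uses twice
    the monomer mass and half the particle molarity at equal mass
    concentration.  ``r_max`` is the saturation response of the surface for
    this species, in pm.
    """

    name: str
    molar_mass: float
    kinetics_by_ph: Mapping[float, KineticParams]
    r_max: float = 1000.0

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ValueError("molar_mass must be > 0")
        if not self.r_max > 0:
            raise ValueError("r_max must be > 0")

    def kinetics_at(self, ph: float) -> KineticParams:
        try:
            return self.kinetics_by_ph[ph]
        except KeyError:
            raise KeyError(
                f"species {self.name!r} has no kinetics for pH {ph}; "
                f"available: {sorted(self.kinetics_by_ph)}"
            ) from None


@dataclass(frozen=True)
class InjectionProtocol:
    """Timing and composition of one injection cycle.

    Phases: baseline [0, t_baseline_end), association
    [t_baseline_end, t_assoc_end), dissociation [t_assoc_end, t_end].
    ``concentrations`` maps species name to mass concentration in mg/mL.
    """

    t_baseline_end: float = 10.0
    t_assoc_end: float = 110.0
    t_end: float = 300.0
    ph: float = 7.4
    concentrations: Mapping[str, float] = field(default_factory=dict)
    sample_rate: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.t_baseline_end < self.t_assoc_end < self.t_end):
            raise ValueError(
                "require 0 <= t_baseline_end < t_assoc_end < t_end, got "
                f"{self.t_baseline_end}, {self.t_assoc_end}, {self.t_end}"
            )
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError("concentrations must be >= 0")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be > 0")

    @property
    def time_grid(self) -> np.ndarray:
        n = int(round(self.t_end * self.sample_rate)) + 1
        return np.arange(n, dtype=float) / self.sample_rate


@dataclass
class Sensorgram:
    """A uniformly sampled response trace with its injection protocol."""

    time: np.ndarray
    response: np.ndarray
    protocol: InjectionProtocol
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.size < 3:
            raise ValueError("sensorgram needs at least 3 samples")
        if self.time.size != self.response.size:
            raise ValueError("time and response must have equal length")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time grid must be uniform")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("response must be finite")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


def molar_concentration(mass_conc: float, molar_mass: float) -> float:
    """Convert a mass concentration to molarity.

    mg/mL equals g/L, so dividing by the molar mass in g/mol gives mol/L.

    Parameters
    ----------
    mass_conc : float
        Mass concentration in mg/mL (>= 0).
    molar_mass : float
        Molar mass in g/mol (> 0).
    """
    if not molar_mass > 0:
        raise ValueError(f"molar_mass must be > 0, got {molar_mass}")
    if mass_conc < 0:
        raise ValueError(f"mass_conc must be >= 0, got {mass_conc}")
    return mass_conc / molar_mass


def association_response(
    params: KineticParams, conc: float, r_max: float, t: "float | np.ndarray"
) -> "float | np.ndarray":
    """Closed-form association-phase response of the 1:1 model.

    R(t) = R_max * C/(C + K_D) * (1 - exp(-(k_on*C + k_off)*t)), with t
    measured from the start of the association phase.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since association start must be >= 0")
    if conc < 0:
        raise ValueError("conc must be >= 0")
    k_obs = params.k_on * conc + params.k_off
    denom = conc + params.k_d
    r_eq = r_max * conc / denom if denom > 0 else r_max  # k_off=0, conc>0 -> r_max
    if conc == 0:
        r_eq = 0.0
    out = r_eq * -np.expm1(-k_obs * t)
    return float(out) if out.ndim == 0 else out


def dissociation_response(
    r0: float, k_off: float, t: "float | np.ndarray"
) -> "float | np.ndarray":
    """Single-exponential dissociation decay R(t) = R0 * exp(-k_off * t)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since dissociation start must be >= 0")
    if r0 < 0:
        raise ValueError("r0 must be >= 0")
    if k_off < 0:
        raise ValueError("k_off must be >= 0")
    out = r0 * np.exp(-k_off * t)
    return float(out) if out.ndim == 0 else out


def simulate_species_trace(spec: SpeciesSpec, protocol: InjectionProtocol) -> Sensorgram:
    """Simulate a noiseless single-species sensorgram over the full protocol.

    Baseline response is zero; dissociation continues continuously from the
    association endpoint.  The species' mass concentration is looked up in
    ``protocol.concentrations`` by name (missing -> 0).
    """
    params = spec.kinetics_at(protocol.ph)
    mass_conc = protocol.concentrations.get(spec.name, 0.0)
    conc = molar_concentration(mass_conc, spec.molar_mass)
    time = protocol.time_grid
    response = np.zeros_like(time)

    assoc = (time >= protocol.t_baseline_end) & (time < protocol.t_assoc_end)
    dissoc = time >= protocol.t_assoc_end
    response[assoc] = association_response(
        params, conc, spec.r_max, time[assoc] - protocol.t_baseline_end
    )
    r0 = association_response(
        params, conc, spec.r_max, protocol.t_assoc_end - protocol.t_baseline_end
    )
    response[dissoc] = dissociation_response(
        r0, params.k_off, time[dissoc] - protocol.t_assoc_end
    )
    return Sensorgram(
        time=time,
        response=response,
        protocol=protocol,
        metadata={"species": spec.name, "mass_conc_mg_per_ml": mass_conc},
    )
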