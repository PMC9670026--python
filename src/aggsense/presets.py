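"""Default species table: effective Protein A binding kinetics of human IgG1.

Rate constants are published Langmuir 1:1 fits of LSPR sensorgrams for
purified human IgG1 monomers and (predominantly dimeric) aggregates binding
Protein A sensor chips at four buffer pH values.  The avidity effect shows up
as the roughly four-fold lower effective k_off of aggregates at pH 3.8-4.0
and the correspondingly ~5x lower apparent K_D.
"""

from __future__ import annotations

from .kinetics import KineticParams, SpeciesSpec

__all__ = [
    "MONOMER_KINETICS",
    "AGGREGATE_KINETICS",
    "default_monomer",
    "default_aggregate",
    "default_species",
]

#: per-pH effective rate constants for monomeric IgG1 (k_on M^-1 s^-1, k_off s^-1)
MONOMER_KINETICS: dict[float, KineticParams] = {
    7.4: KineticParams(k_on=2.2e4, k_off=2.9e-5),
    4.0: KineticParams(k_on=3.1e4, k_off=4.0e-3),
    3.8: KineticParams(k_on=3.0e4, k_off=1.0e-2),
    3.5: KineticParams(k_on=1.7e4, k_off=1.1e-2),
}

#: per-pH effective rate constants for IgG1 aggregates (mainly dimers)
AGGREGATE_KINETICS: dict[float, KineticParams] = {
    7.4: KineticParams(k_on=2.5e4, k_off=2.9e-5),
    4.0: KineticParams(k_on=3.6e4, k_off=9.2e-4),
    3.8: KineticParams(k_on=3.6e4, k_off=2.4e-3),
    3.5: KineticParams(k_on=2.8e4, k_off=9.9e-3),
}

#: printed K_D values (M) of the same source table, per pH, per species —
#: kept for cross-checks; K_D is otherwise always recomputed as k_off/k_on.
PRINTED_KD = {
    "monomer": {7.4: 1.3e-9, 4.0: 1.3e-7, 3.8: 3.3e-7, 3.5: 6.6e-7},
    "aggregate": {7.4: 1.2e-9, 4.0: 2.6e-8, 3.8: 6.5e-8, 3.5: 3.5e-7},
}

IGG_MONOMER_MASS = 1.5e5  # g/mol
IGG_DIMER_MASS = 3.0e5  # g/mol; aggregates are counted as single analytes


def default_monomer(r_max: float = 1000.0) -> SpeciesSpec:
    return SpeciesSpec(
        name="monomer",
        molar_mass=IGG_MONOMER_MASS,
        kinetics_by_ph=dict(MONOMER_KINETICS),
        r_max=r_max,
    )


def default_aggregate(r_max: float = 1000.0) -> SpeciesSpec:
    return SpeciesSpec(
        name="aggregate",
        molar_mass=IGG_DIMER_MASS,
        kinetics_by_ph=dict(AGGREGATE_KINETICS),
        r_max=r_max,
    )


def default_species(r_max: float = 1000.0) -> list[SpeciesSpec]:
    """The two-species table used throughout the synthetic designs."""
    return [default_monomer(r_max), default_aggregate(r_max)]
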