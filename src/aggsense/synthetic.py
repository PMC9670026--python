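"""Synthetic sensorgram designs emulating the avidity-sensing experiments.

Three canned designs mirror the experimental layouts used to characterise and
quantify IgG aggregates:

``fig3_levels``
    nine aggregate levels (1-98 %) at a fixed 0.45 mg/mL total IgG.
``fig4_grid``
    the same nine levels crossed with three total concentrations
    (0.1125 / 0.25 / 0.45 mg/mL) -> 27 training samples, plus 7 control
    samples at intermediate levels, for endpoint calibration.
``fig5_lowrange``
    65 traces in the low-aggregate regime (1-20 %) over five totals,
    split 51 train / 14 validation, for the neural-network regression.

Ground truth (total concentration, aggregate mass fraction, per-species mass
concentration) is carried in a manifest, so every downstream stage can be
scored against the generating values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import (
    InjectionProtocol,
    Sensorgram,
    SpeciesSpec,
    molar_concentration,
    simulate_species_trace,
)
from .presets import default_species

__all__ = [
    "NoiseModel",
    "simulate_mixture",
    "generate_design",
    "design_rows",
    "MANIFEST_COLUMNS",
    "FIG3_FRACTIONS",
    "FIG4_TOTALS",
]

MANIFEST_COLUMNS = [
    "sample_id",
    "total_mg_per_ml",
    "aggregate_fraction",
    "ph",
    "split",
    "path",
]

# aggregate mass fractions of the nine-level series; the 1 % floor reflects
# that even purified "monomer" fractions retain ~1 % aggregate
FIG3_FRACTIONS = (0.01, 0.02, 0.05, 0.10, 0.20, 0.40, 0.60, 0.80, 0.98)
FIG4_TOTALS = (0.1125, 0.25, 0.45)  # mg/mL
FIG4_CONTROLS = (  # (fraction, total mg/mL); aggregate conc 3.4-100 ug/mL,
    # inside the method's stated 9-200 ug/mL dynamic range (plus one
    # below-detection control mirroring the real control series)
    (0.03, 0.1125),
    (0.03, 0.45),
    (0.07, 0.25),
    (0.15, 0.45),
    (0.30, 0.25),
    (0.50, 0.1125),
    (0.40, 0.25),
)
FIG5_FRACTIONS = (
    0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.08, 0.10, 0.12, 0.14, 0.16, 0.18, 0.20,
)
FIG5_TOTALS = (0.1125, 0.20, 0.25, 0.35, 0.45)  # mg/mL
FIG5_N_VALIDATION = 14


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise applied to a noiseless mixture trace.

    sigma
        additive white Gaussian noise sd, pm.
    bulk_jump
        transient offset active only during the association window, pm;
        negative by default, mimicking the refractive-index mismatch between
        sample and running buffer.
    drift
        linear baseline drift, pm/s.
    seed
        RNG seed; the same seed reproduces identical traces.
    """

    sigma: float = 2.0
    bulk_jump: float = -10.0
    drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _competitive_noiseless(
    protocol: InjectionProtocol, species: "list[SpeciesSpec]"
) -> np.ndarray:
    """Mixture response when all species compete for one shared capacity.

    The association phase solves the linear system
    dR_i/dt = k_on,i C_i (R_max - sum_j R_j) - k_off,i R_i by
    eigendecomposition; each species then dissociates independently from its
    association endpoint.  All species must share the same r_max.
    """
    r_maxes = {s.r_max for s in species}
    if len(r_maxes) != 1:
        raise ValueError("competitive mixtures require a single shared r_max")
    r_max = r_maxes.pop()
    active = [
        s for s in species
        if molar_concentration(protocol.concentrations.get(s.name, 0.0), s.molar_mass) > 0
    ]
    time = protocol.time_grid
    if not active:
        return np.zeros_like(time)
    k = np.array([
        s.kinetics_at(protocol.ph).k_on
        * molar_concentration(protocol.concentrations[s.name], s.molar_mass)
        for s in active
    ])
    koff = np.array([s.kinetics_at(protocol.ph).k_off for s in active])
    M = k[:, None] * np.ones((k.size, k.size)) + np.diag(koff)
    v = k * r_max
    r_ss = np.linalg.solve(M, v)
    w, V = np.linalg.eig(M)
    coef = np.linalg.solve(V, -r_ss)  # R(0) = 0

    response = np.zeros_like(time)
    assoc = (time >= protocol.t_baseline_end) & (time < protocol.t_assoc_end)
    dissoc = time >= protocol.t_assoc_end
    ta = time[assoc] - protocol.t_baseline_end
    r_t = r_ss[None, :] + np.real((V @ (coef[:, None] * np.exp(-np.outer(w, ta)))).T)
    response[assoc] = r_t.sum(axis=1)
    ta_end = protocol.t_assoc_end - protocol.t_baseline_end
    r_end = r_ss + np.real(V @ (coef * np.exp(-w * ta_end)))
    td = time[dissoc] - protocol.t_assoc_end
    response[dissoc] = (r_end[None, :] * np.exp(-np.outer(td, koff))).sum(axis=1)
    return response


def simulate_mixture(
    protocol: InjectionProtocol,
    species: "list[SpeciesSpec]",
    noise: "NoiseModel | None" = None,
    interaction: str = "independent",
) -> Sensorgram:
    """Simulate a mixture sensorgram from per-species 1:1 kinetics.

    With the default ``interaction="independent"`` each species binds its own
    sites and the noiseless mixture is exactly the pointwise sum of the
    single-species traces.  ``interaction="competitive"`` instead lets all
    species compete for one shared surface capacity, which caps the total
    response at r_max (the canned designs use the independent model; see the
    methods note for what each variant does and does not reproduce).  Noise,
    bulk jump and drift are applied after the mixture is formed.
    """
    names = {s.name for s in species}
    unknown = {
        k for k, v in protocol.concentrations.items() if v > 0
    } - names
    if unknown:
        raise ValueError(
            f"protocol concentrations name unknown species {sorted(unknown)}; "
            f"known: {sorted(names)}"
        )
    time = protocol.time_grid
    if interaction == "independent":
        response = np.zeros_like(time)
        for s in species:
            response += simulate_species_trace(s, protocol).response
    elif interaction == "competitive":
        response = _competitive_noiseless(protocol, species)
    else:
        raise ValueError(f"unknown interaction {interaction!r}")

    if noise is not None:
        rng = np.random.default_rng(noise.seed)
        assoc = (time >= protocol.t_baseline_end) & (time < protocol.t_assoc_end)
        response = response + noise.bulk_jump * assoc
        response = response + noise.drift * time
        if noise.sigma > 0:
            response = response + rng.normal(0.0, noise.sigma, size=time.size)

    return Sensorgram(
        time=time,
        response=response,
        protocol=protocol,
        metadata={"species": sorted(names)},
    )


def _mixture_protocol(
    total: float, fraction: float, ph: float, base: "InjectionProtocol | None" = None
) -> InjectionProtocol:
    base = base or InjectionProtocol()
    return InjectionProtocol(
        t_baseline_end=base.t_baseline_end,
        t_assoc_end=base.t_assoc_end,
        t_end=base.t_end,
        ph=ph,
        concentrations={
            "monomer": total * (1.0 - fraction),
            "aggregate": total * fraction,
        },
        sample_rate=base.sample_rate,
    )


def design_rows(design_name: str, ph: float = 3.8, seed: int = 0) -> pd.DataFrame:
    """Return the (sample_id, total, fraction, ph, split) table of a design."""
    rows: list[dict] = []
    if design_name == "fig3_levels":
        for i, frac in enumerate(FIG3_FRACTIONS):
            rows.append(
                dict(sample_id=f"L{i+1:02d}", total_mg_per_ml=0.45,
                     aggregate_fraction=frac, ph=ph, split="train")
            )
    elif design_name == "fig4_grid":
        i = 0
        for total in FIG4_TOTALS:
            for frac in FIG3_FRACTIONS:
                i += 1
                rows.append(
                    dict(sample_id=f"S{i:02d}", total_mg_per_ml=total,
                         aggregate_fraction=frac, ph=ph, split="train")
                )
        for j, (frac, total) in enumerate(FIG4_CONTROLS):
            rows.append(
                dict(sample_id=f"C{j+1}", total_mg_per_ml=total,
                     aggregate_fraction=frac, ph=ph, split="control")
            )
    elif design_name == "fig5_lowrange":
        i = 0
        for total in FIG5_TOTALS:
            for frac in FIG5_FRACTIONS:
                i += 1
                rows.append(
                    dict(sample_id=f"V{i:02d}", total_mg_per_ml=total,
                         aggregate_fraction=frac, ph=ph, split="train")
                )
        df = pd.DataFrame(rows)
        # stratified validation hold-out over aggregate level, seeded
        rng = np.random.default_rng(seed)
        order = np.argsort(df["aggregate_fraction"].to_numpy(), kind="stable")
        strata = np.array_split(order, FIG5_N_VALIDATION)
        held = [int(rng.choice(s)) for s in strata]
        df.loc[df.index[held], "split"] = "validation"
        return df
    else:
        raise ValueError(f"unknown design {design_name!r}")
    return pd.DataFrame(rows)


def generate_design(
    design_name: str,
    noise: "NoiseModel | None" = None,
    out_dir: "str | Path | None" = None,
    ph: float = 3.8,
    species: "list[SpeciesSpec] | None" = None,
    protocol: "InjectionProtocol | None" = None,
) -> pd.DataFrame:
    """Generate a design's sensorgrams and manifest.

    Returns the manifest DataFrame; when ``out_dir`` is given, one CSV per
    trace plus ``manifest.csv`` are written there and the manifest's ``path``
    column points at the trace files.  Without ``out_dir`` the traces are
    attached in-memory under ``manifest.attrs["traces"]``.

    Per-sample noise seeds are derived deterministically from
    ``noise.seed``, so the whole design is reproducible from one seed.
    """
    noise = noise or NoiseModel()
    species = species or default_species()
    manifest = design_rows(design_name, ph=ph, seed=noise.seed)
    traces: dict[str, Sensorgram] = {}
    paths = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    seed_seq = np.random.SeedSequence(noise.seed)
    child_seeds = seed_seq.spawn(len(manifest))
    for (idx, row), child in zip(manifest.iterrows(), child_seeds):
        proto = _mixture_protocol(
            row["total_mg_per_ml"], row["aggregate_fraction"], row["ph"], protocol
        )
        row_noise = NoiseModel(
            sigma=noise.sigma,
            bulk_jump=noise.bulk_jump,
            drift=noise.drift,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        trace = simulate_mixture(proto, species, row_noise)
        trace.metadata.update(row.drop("path", errors="ignore").to_dict())
        traces[row["sample_id"]] = trace
        if out is not None:
            from .io import write_sensorgram  # local import to avoid cycle

            path = out / f"{row['sample_id']}.csv"
            write_sensorgram(trace, path)
            paths.append(str(path))
        else:
            paths.append("")

    manifest = manifest.assign(path=paths)[MANIFEST_COLUMNS]
    manifest.attrs["traces"] = traces
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
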