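"""Ground-truth flux scenarios and synthetic datasets.

A scenario is a steady-state flux vector for the reference network plus the
experiment design (replicates, measurement noise).  The ``control``
scenario encodes plausible growth-rate-relative fluxes for a proliferating
cell on glucose + serine-replete medium: de novo serine synthesis is a
small fraction of serine uptake, most pyruvate enters the TCA cycle
through pyruvate dehydrogenase, and nucleotide pools are filled mostly de
novo with a minor salvage contribution.  The ``phgdh_inhibited`` scenario
scales the serine-synthesis flux by 0.5 and the PPP and TCA fluxes by 0.4
while leaving serine->glycine unchanged, then rebalances uptake, salvage
and overflow fluxes so the scaled vector still satisfies S v = 0 — the
flux-control pattern the estimation pipeline should recover.

Noise is additive Gaussian on MID fractions (clipped at 0, renormalized),
the simplest model consistent with symmetric replicate error bars; it is 0
by default (scenarios define ground truth) and set explicitly for
robustness studies (0.01 emulates typical replicate scatter).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .emu import TracerSpec, emu_decompose, simulate_mids
from .fluxes import FluxRatio, FluxVector, solve_fluxes_analytical
from .kinetics import TimeCourse
from .mid import MID, MIDSet
from .network import MetabolicNetwork, reference_network

__all__ = [
    "Scenario",
    "make_scenario",
    "simulate_mid_dataset",
    "simulate_timecourse_dataset",
    "default_tracer",
    "CONTROL_SHARES",
    "INHIBITION_FACTORS",
    "DEFAULT_POOL_SIZES",
    "DEFAULT_REPORTERS",
    "DEFAULT_TIMES",
]

#: ground-truth producer shares at the six branch points (control condition)
CONTROL_SHARES = {
    "SER": {"SSP": 0.15},     # de novo serine well below uptake
    "GLY": {"SHMT": 0.45},
    "ASP": {"ASPS": 0.70},
    "IMP": {"IMP_DN": 0.85},
    "OAA": {"PC": 0.25},      # PDH-routed flux ~3x anaplerosis
    "UMP": {"UMP_DN": 0.80},
}

#: default per-pathway flux scaling under PHGDH inhibition
INHIBITION_FACTORS = {
    "serine_synthesis": 0.5,
    "ppp": 0.4,
    "tca": 0.4,
    "serine_to_glycine": 1.0,
}

#: relative pool sizes (units: flux x minutes) for kinetic profiling
DEFAULT_POOL_SIZES = {
    "3PG": 6.0, "SER": 25.0, "GLY": 25.0, "R5P": 1.2,
    "AKG": 8.0, "OAA": 2.0, "ASP": 30.0,
}

#: reporter isotopologue per metabolite (m+k) for time courses.  For the
#: TCA pools the reporter is each pool's dominant labeled species at steady
#: state: in a closed glucose-carbon model the m+2 species of the TCA
#: intermediates vanish once labeling is complete (they arise transiently,
#: and persist in real cells only through unlabeled anaplerotic inflow such
#: as glutamine, which this network does not carry).
DEFAULT_REPORTERS = {
    "3PG": 3, "SER": 3, "GLY": 2, "R5P": 5, "AKG": 4, "OAA": 3, "ASP": 3,
}

DEFAULT_TIMES = (0.0, 2.0, 5.0, 10.0, 20.0, 40.0, 60.0, 120.0, 240.0)


def default_tracer(network: MetabolicNetwork | None = None) -> TracerSpec:
    """Pure [U-13C]glucose entering the model at G6P."""
    network = network if network is not None else reference_network()
    return TracerSpec.uniform("G6P", network.n_carbons("G6P"))


@dataclass
class Scenario:
    """Named ground truth + experiment design for synthetic datasets."""

    name: str
    fluxes: FluxVector
    scaling: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _solve_from_shares(network: MetabolicNetwork,
                       shares: dict[str, dict[str, float]],
                       condition: str) -> FluxVector:
    ratios = []
    for branch in network.branches:
        named = dict(shares[branch.pool])
        named[branch.rest] = 1.0 - sum(named.values())
        ratios.append(FluxRatio(branch.pool, named))
    return solve_fluxes_analytical(ratios, network, condition)


def _inhibited_shares(network: MetabolicNetwork, control: FluxVector,
                      factors: dict[str, float]) -> dict[str, dict[str, float]]:
    """Branch shares that realize the per-pathway scaling and rebalance the
    uptake/salvage/overflow fluxes (raises via the solver if infeasible)."""
    f_ss = factors.get("serine_synthesis", 1.0)
    f_ppp = factors.get("ppp", 1.0)
    f_tca = factors.get("tca", 1.0)
    f_sg = factors.get("serine_to_glycine", 1.0)
    b = network.biomass
    impdn = f_ppp * control["IMP_DN"]
    umpdn = f_ppp * control["UMP_DN"]
    shmt = f_sg * control["SHMT"]
    ssp = f_ss * control["SSP"]
    asps = f_tca * control["ASPS"]
    pc_share = control["PC"] / (control["PC"] + control["TCA2"])
    return {
        "IMP": {"IMP_DN": impdn / b["IMP"]},
        "UMP": {"UMP_DN": umpdn / b["UMP"]},
        "GLY": {"SHMT": shmt / (impdn + b["GLY"])},
        "SER": {"SSP": ssp / (shmt + b["SER"])},
        "ASP": {"ASPS": asps / (umpdn + b["ASP"])},
        "OAA": {"PC": pc_share},
    }


def make_scenario(name: str = "control", overrides: dict | None = None,
                  seed: int = 0, noise_sd: float = 0.0, n_replicates: int = 3,
                  network: MetabolicNetwork | None = None) -> Scenario:
    """Build a named scenario on the reference network.

    ``overrides`` may carry per-pathway scaling ``factors`` (applied on top
    of the scenario defaults) or explicit branch ``shares``; a ``custom``
    scenario requires one of the two.
    """
    network = network if network is not None else reference_network()
    overrides = dict(overrides or {})

    if name == "control":
        shares = overrides.get("shares", CONTROL_SHARES)
        factors = overrides.get("factors", {})
    elif name == "phgdh_inhibited":
        shares = CONTROL_SHARES
        factors = {**INHIBITION_FACTORS, **overrides.get("factors", {})}
    elif name == "custom":
        if "shares" in overrides:
            shares, factors = overrides["shares"], overrides.get("factors", {})
        elif "factors" in overrides:
            shares, factors = CONTROL_SHARES, overrides["factors"]
        else:
            raise ValueError("custom scenario needs 'shares' or 'factors' overrides")
    else:
        raise ValueError(f"unknown scenario {name!r}")

    fluxes = _solve_from_shares(network, shares, name)
    if any(abs(f - 1.0) > 0 for f in factors.values()):
        try:
            shares = _inhibited_shares(network, fluxes, factors)
            fluxes = _solve_from_shares(network, shares, name)
        except (ValueError, KeyError) as exc:
            raise ValueError(f"pathway scaling makes the balance infeasible: {exc}")
    return Scenario(name, fluxes, dict(factors), noise_sd, n_replicates, seed)


def _noisy_mid(rng: np.random.Generator, true: np.ndarray, sd: float,
               metabolite: str) -> MID:
    if sd == 0.0:
        frac = true
    else:
        frac = np.clip(true + rng.normal(0.0, sd, size=true.shape), 0.0, None)
        total = frac.sum()
        if total <= 0:  # pragma: no cover - sd would have to be huge
            frac = true
        else:
            frac = frac / total
    return MID(metabolite, tuple(frac), provenance="simulated")


def simulate_mid_dataset(scenario: Scenario, network: MetabolicNetwork | None = None,
                         tracer: TracerSpec | None = None,
                         metabolites: list[str] | None = None,
                         noise_sd: float | None = None,
                         n_replicates: int | None = None,
                         seed: int | None = None) -> MIDSet:
    """EMU-simulate steady-state MIDs of every balanced pool (or a chosen
    subset) and emit noisy replicates; reproducible from the seed."""
    network = network if network is not None else reference_network()
    tracer = tracer if tracer is not None else default_tracer(network)
    metabolites = metabolites if metabolites is not None else network.balanced_pools()
    sd = scenario.noise_sd if noise_sd is None else noise_sd
    n_rep = scenario.n_replicates if n_replicates is None else n_replicates
    rng = np.random.default_rng(scenario.seed if seed is None else seed)

    system = emu_decompose(network, sorted(metabolites))
    sim = simulate_mids(system, scenario.fluxes, tracer)
    true = {e.metabolite: mid for e, mid in sim.items()}

    out = MIDSet()
    for rep in range(1, n_rep + 1):
        for met in sorted(metabolites):
            out.add(met, scenario.name, str(rep),
                    _noisy_mid(rng, true[met], sd, met))
    return out


def _production_flux(network: MetabolicNetwork, fluxes: FluxVector, met: str) -> float:
    return sum(
        fluxes[rxn] * network.production_coefficient(met, rxn)
        for rxn in network.producing_reactions(met)
    )


def simulate_timecourse_dataset(
    scenario: Scenario,
    pools: dict[str, float] | None = None,
    times=DEFAULT_TIMES,
    reporters: dict[str, int] | None = None,
    network: MetabolicNetwork | None = None,
    tracer: TracerSpec | None = None,
    noise_sd: float | None = None,
    n_replicates: int | None = None,
    seed: int | None = None,
) -> list[TimeCourse]:
    """First-order labeling curves F(t) = F_inf (1 - exp(-k t)) per reporter.

    k is the scenario's turnover (total production flux / pool size) and
    F_inf the EMU-simulated steady-state reporter fraction.  The t = 0
    sample is taken at the tracer switch and is exactly unlabeled (no noise
    is added there).
    """
    network = network if network is not None else reference_network()
    tracer = tracer if tracer is not None else default_tracer(network)
    pools = pools if pools is not None else DEFAULT_POOL_SIZES
    reporters = reporters if reporters is not None else DEFAULT_REPORTERS
    sd = scenario.noise_sd if noise_sd is None else noise_sd
    n_rep = scenario.n_replicates if n_replicates is None else n_replicates
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    times = np.asarray(times, dtype=float)

    mets = [m for m in sorted(pools) if m in reporters]
    system = emu_decompose(network, mets)
    sim = simulate_mids(system, scenario.fluxes, tracer)
    plateau = {e.metabolite: mid for e, mid in sim.items()}

    out = []
    for met in mets:
        if pools[met] <= 0:
            raise ValueError(f"pool size for {met} must be > 0")
        k = _production_flux(network, scenario.fluxes, met) / pools[met]
        f_inf = float(plateau[met][reporters[met]])
        curve = f_inf * (1.0 - np.exp(-k * times))
        frac = np.tile(curve, (n_rep, 1))
        if sd > 0:
            noise = rng.normal(0.0, sd, size=frac.shape)
            noise[:, times == 0.0] = 0.0
            frac = np.clip(frac + noise, 0.0, 1.0)
        out.append(TimeCourse(met, reporters[met], times, frac, scenario.name))
    return out
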