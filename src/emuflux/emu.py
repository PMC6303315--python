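"""Elementary-metabolite-unit (EMU) decomposition and steady-state MID
simulation.

An EMU is a specific subset of a metabolite's carbon atoms.  Balancing EMUs
instead of full positional isotopomers turns steady-state label propagation
into a cascade of small linear systems, one per EMU size: every EMU of size
s is produced either by transfer from another size-s EMU or by convolution
of strictly smaller EMUs, so the systems can be solved in increasing size
order.  This is the standard reduction used by modern 13C flux analysis
software; the brute-force positional-isotopomer solver in
:mod:`emuflux.isotopomers` serves as its independent oracle on small
networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, NamedTuple

import numpy as np

from .network import MetabolicNetwork

__all__ = [
    "EMU",
    "EMUReaction",
    "EMULayeredSystem",
    "TracerSpec",
    "emu_decompose",
    "convolve_mids",
    "simulate_mids",
    "solve_emu_mids",
]

_MID_SUM_TOL = 1e-6


class EMU(NamedTuple):
    """A metabolite id plus an ordered tuple of 1-based carbon positions."""

    metabolite: str
    positions: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.positions)

    def __str__(self) -> str:  # e.g. SER[1,2]
        return f"{self.metabolite}[{','.join(map(str, self.positions))}]"


def full_emu(network: MetabolicNetwork, met: str) -> EMU:
    return EMU(met, tuple(range(1, network.n_carbons(met) + 1)))


def _validate_emu(network: MetabolicNetwork, emu: EMU) -> None:
    if emu.metabolite not in network.pools:
        raise ValueError(f"EMU references undeclared pool {emu.metabolite}")
    n = network.n_carbons(emu.metabolite)
    if not emu.positions or list(emu.positions) != sorted(set(emu.positions)):
        raise ValueError(f"EMU {emu}: positions must be strictly increasing")
    if emu.positions[0] < 1 or emu.positions[-1] > n:
        raise ValueError(f"EMU {emu}: positions outside 1..{n}")


@dataclass(frozen=True)
class EMUReaction:
    """One production channel of an EMU.

    ``sources`` holds one EMU for a plain transfer and several for a
    convolution; the channel's rate is flux(reaction) * multiplier.
    """

    product: EMU
    sources: tuple[EMU, ...]
    reaction: str
    multiplier: float

    def __post_init__(self):
        if sum(s.size for s in self.sources) != self.product.size:
            raise ValueError(
                f"EMU reaction {self.reaction}: source sizes do not add up "
                f"to {self.product}"
            )


@dataclass
class TracerSpec:
    """Isotopic state of one labeled source pool.

    ``label_probs`` gives the probability that each carbon position carries
    the label in a tracer molecule (``[U-13C]`` substrates: all ones),
    scaled by ``purity``; ``unlabeled_fraction`` is the share of the source
    pool that is ordinary unlabeled substrate.
    """

    metabolite: str
    label_probs: tuple[float, ...]
    purity: float = 1.0
    unlabeled_fraction: float = 0.0

    def __post_init__(self):
        for p in tuple(self.label_probs) + (self.purity,):
            if not 0.0 <= p <= 1.0:
                raise ValueError("tracer probabilities must lie in [0, 1]")
        if not 0.0 <= self.unlabeled_fraction <= 1.0:
            raise ValueError("unlabeled_fraction must lie in [0, 1]")

    @classmethod
    def uniform(cls, metabolite: str, n_carbons: int, purity: float = 1.0,
                unlabeled_fraction: float = 0.0) -> "TracerSpec":
        """A uniformly labeled tracer such as [U-13C]glucose."""
        return cls(metabolite, (1.0,) * n_carbons, purity, unlabeled_fraction)

    def emu_mid(self, positions: Iterable[int]) -> np.ndarray:
        """MID of the EMU covering ``positions`` of the tracer substrate."""
        mid = np.array([1.0])
        for pos in positions:
            q = self.label_probs[pos - 1] * self.purity
            mid = np.convolve(mid, [1.0 - q, q])
        if self.unlabeled_fraction > 0.0:
            e0 = np.zeros_like(mid)
            e0[0] = 1.0
            mid = self.unlabeled_fraction * e0 + (1 - self.unlabeled_fraction) * mid
        return mid


def source_emu_mid(network: MetabolicNetwork, emu: EMU,
                   tracer: TracerSpec | None) -> np.ndarray:
    """MID of a source-pool EMU: the tracer pattern for the labeled
    substrate, unlabeled for every other source (natural abundance is an
    explicit data-processing step, not baked into simulation)."""
    if tracer is not None and emu.metabolite == tracer.metabolite:
        return tracer.emu_mid(emu.positions)
    mid = np.zeros(emu.size + 1)
    mid[0] = 1.0
    return mid


def convolve_mids(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cauchy product of two MIDs: the MID of the combined fragment."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for v in (a, b):
        if abs(v.sum() - 1.0) > _MID_SUM_TOL:
            raise ValueError(f"MID does not sum to 1 (sum={v.sum():.6g})")
        if (v < -1e-12).any():
            raise ValueError("MID has negative entries")
    return np.convolve(a, b)


@dataclass
class EMULayeredSystem:
    """EMU reaction network stratified by EMU size.

    For each size the unknown EMUs obey A(v) X = B(v) Y where Y collects
    tracer EMUs and convolutions of smaller sizes; the cascade is solved in
    increasing size order.
    """

    network: MetabolicNetwork
    targets: tuple[EMU, ...]
    reactions_by_product: dict[EMU, tuple[EMUReaction, ...]]
    unknown_by_size: dict[int, tuple[EMU, ...]] = field(default_factory=dict)

    @property
    def sizes(self) -> list[int]:
        return sorted(self.unknown_by_size)

    @property
    def n_unknowns(self) -> int:
        return sum(len(v) for v in self.unknown_by_size.values())


def emu_decompose(network: MetabolicNetwork,
                  targets: Iterable[EMU | str]) -> EMULayeredSystem:
    """Trace the minimal EMU network reaching all target EMUs.

    Targets may be EMUs or bare metabolite ids (meaning the full molecule).
    Raises if a target cannot be reached from any source pool.
    """
    tgt: list[EMU] = []
    for t in targets:
        emu = full_emu(network, t) if isinstance(t, str) else t
        _validate_emu(network, emu)
        tgt.append(emu)

    reactions_by_product: dict[EMU, tuple[EMUReaction, ...]] = {}
    stack = list(tgt)
    seen: set[EMU] = set()
    while stack:
        emu = stack.pop()
        if emu in seen:
            continue
        seen.add(emu)
        if network.pools[emu.metabolite].role == "source":
            continue
        prods = []
        for rxn_id, vi, pi, mult in network.producer_channels(emu.metabolite):
            rxn = network.reaction(rxn_id)
            var = rxn.variants[vi]
            term = var.products[pi]
            wanted = [term.atoms[p - 1] for p in emu.positions]
            # group the wanted atom letters by originating substrate instance
            per_sub: list[tuple[int, list[int]]] = []
            for si, sub in enumerate(var.substrates):
                positions = sorted(
                    sub.atoms.index(letter) + 1 for letter in wanted
                    if letter in sub.atoms
                )
                if positions:
                    per_sub.append((si, positions))
            found = sum(len(p) for _, p in per_sub)
            if found != len(wanted):  # pragma: no cover - guarded by validation
                raise ValueError(
                    f"reaction {rxn_id}: product atoms of {emu} not found on "
                    "the substrate side"
                )
            sources = tuple(
                EMU(var.substrates[si].metabolite, tuple(pos)) for si, pos in per_sub
            )
            prods.append(EMUReaction(emu, sources, rxn_id, mult))
            stack.extend(sources)
        if not prods:
            raise ValueError(f"target EMU {emu} is unreachable: no reaction produces it")
        # deterministic ordering for reproducible matrices
        prods.sort(key=lambda er: (er.reaction, er.sources))
        reactions_by_product[emu] = tuple(prods)

    unknown_by_size: dict[int, list[EMU]] = {}
    for emu in reactions_by_product:
        unknown_by_size.setdefault(emu.size, []).append(emu)
    system = EMULayeredSystem(
        network,
        tuple(tgt),
        reactions_by_product,
        {s: tuple(sorted(v)) for s, v in sorted(unknown_by_size.items())},
    )
    return system


def _channel_weights_from_fluxes(system: EMULayeredSystem,
                                 fluxes: Mapping[str, float]) -> Callable[[str, str], float]:
    for rxn_id, v in fluxes.items():
        if v < 0:
            raise ValueError(f"negative flux for {rxn_id}: {v}")

    def weight(pool: str, rxn_id: str) -> float:
        try:
            return float(fluxes[rxn_id])
        except KeyError:
            raise ValueError(f"flux vector is missing reaction {rxn_id}") from None

    return weight


def _channel_weights_from_shares(system: EMULayeredSystem,
                                 shares: Mapping[str, Mapping[str, float]]) -> Callable[[str, str], float]:
    network = system.network

    def weight(pool: str, rxn_id: str) -> float:
        if pool in shares:
            s = shares[pool].get(rxn_id, 0.0)
            # a reaction share is spread over its production coefficient so
            # that multi-instance products keep the right relative weight
            coef = network.production_coefficient(pool, rxn_id)
            return s / coef if coef > 0 else 0.0
        return 1.0

    return weight


def _solve(system: EMULayeredSystem, weight: Callable[[str, str], float],
           tracer: TracerSpec | None) -> dict[EMU, np.ndarray]:
    mids: dict[EMU, np.ndarray] = {}
    network = system.network

    def known_mid(emu: EMU) -> np.ndarray:
        if network.pools[emu.metabolite].role == "source":
            return source_emu_mid(network, emu, tracer)
        return mids[emu]

    for size in system.sizes:
        unknowns = system.unknown_by_size[size]
        index = {emu: i for i, emu in enumerate(unknowns)}
        n = len(unknowns)
        A = np.zeros((n, n))
        B = np.zeros((n, size + 1))
        for i, emu in enumerate(unknowns):
            total = 0.0
            for er in system.reactions_by_product[emu]:
                w = weight(emu.metabolite, er.reaction) * er.multiplier
                total += w
                if (
                    len(er.sources) == 1
                    and er.sources[0] in index
                ):
                    A[i, index[er.sources[0]]] -= w
                else:
                    mid = known_mid(er.sources[0])
                    for src in er.sources[1:]:
                        mid = np.convolve(mid, known_mid(src))
                    B[i] += w * mid
            if total <= 0.0:
                raise ValueError(
                    f"EMU {emu} has zero total production flux; the system "
                    "requires strictly positive feeding fluxes"
                )
            A[i, i] += total
        try:
            X = np.linalg.solve(A, B)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"singular EMU balance at size {size}: some of "
                f"{[str(u) for u in unknowns]} are disconnected from any source"
            ) from exc
        for emu, row in zip(unknowns, X):
            row = np.where(row < 0.0, np.where(row < -1e-12, row, 0.0), row)
            mids[emu] = row

    out = {}
    for t in system.targets:
        mid = known_mid(t)
        s = mid.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"simulated MID of {t} sums to {s:.12g}")
        out[t] = mid
    return out


def simulate_mids(system: EMULayeredSystem, fluxes: Mapping[str, float],
                  tracer: TracerSpec | None) -> dict[EMU, np.ndarray]:
    """Steady-state MIDs of the system's target EMUs under a flux vector.

    ``fluxes`` maps reaction id to a non-negative net flux (a
    :class:`~emuflux.fluxes.FluxVector` works directly).  MIDs depend only
    on relative producer fluxes per pool, so scaling all fluxes leaves the
    result unchanged.
    """
    values = getattr(fluxes, "values_dict", None)
    mapping = values if values is not None else dict(fluxes)
    return _solve(system, _channel_weights_from_fluxes(system, mapping), tracer)


def solve_emu_mids(system: EMULayeredSystem,
                   pool_shares: Mapping[str, Mapping[str, float]],
                   tracer: TracerSpec | None) -> dict[EMU, np.ndarray]:
    """Like :func:`simulate_mids` but parameterized directly by producer
    shares per pool (reaction id -> fractional contribution).  Pools not
    listed get equal weight across their producer channels, which is exact
    whenever they have a single producing reaction.  Used by branch-ratio
    inversion, where only shares — not absolute fluxes — are known yet.
    """
    return _solve(system, _channel_weights_from_shares(system, pool_shares), tracer)
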