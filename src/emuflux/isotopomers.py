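"""Brute-force positional-isotopomer solver, the independent oracle for the
EMU engine.

Every metabolite with n carbons is represented by its full distribution
over 2**n labeling patterns (bit i set = carbon i+1 labeled).  At isotopic
steady state each balanced pool's pattern distribution is the production
flux weighted mixture of the patterns generated by its producing reactions,
with substrate pools statistically independent; the fixed point of that map
is found by damped-free Gauss-Seidel iteration.  Exponential in carbon
count, so only usable on small networks — which is the point: it shares no
code path with the EMU cascade it verifies.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from .emu import TracerSpec
from .network import MetabolicNetwork

__all__ = ["enumerate_isotopomers_bruteforce"]

_MAX_CARBONS = 12


def _source_distribution(n: int, met: str, tracer: TracerSpec | None) -> np.ndarray:
    dist = np.zeros(2 ** n)
    if tracer is None or met != tracer.metabolite:
        dist[0] = 1.0
        return dist
    probs = [p * tracer.purity for p in tracer.label_probs]
    for mask in range(2 ** n):
        p = 1.0
        for i in range(n):
            p *= probs[i] if mask >> i & 1 else 1.0 - probs[i]
        dist[mask] = p
    if tracer.unlabeled_fraction > 0:
        dist *= 1.0 - tracer.unlabeled_fraction
        dist[0] += tracer.unlabeled_fraction
    return dist


def _marginal(dist: np.ndarray, n: int, positions: list[int]) -> np.ndarray:
    """Marginal pattern distribution over a subset of carbon positions
    (1-based), in the order given."""
    k = len(positions)
    out = np.zeros(2 ** k)
    for mask in range(len(dist)):
        sub = 0
        for j, pos in enumerate(positions):
            if mask >> (pos - 1) & 1:
                sub |= 1 << j
        out[sub] += dist[mask]
    return out


def enumerate_isotopomers_bruteforce(
    network: MetabolicNetwork,
    fluxes: Mapping[str, float],
    tracer: TracerSpec | None,
    targets: Iterable[str] | None = None,
    tol: float = 1e-15,
    max_iter: int = 100_000,
) -> dict[str, np.ndarray]:
    """Steady-state MIDs of ``targets`` (metabolite ids; default: all
    balanced pools) by solving the full positional-isotopomer balance."""
    values = getattr(fluxes, "values_dict", None)
    fluxes = values if values is not None else dict(fluxes)
    for met, pool in network.pools.items():
        if pool.n_carbons > _MAX_CARBONS:
            raise ValueError(
                f"{met} has {pool.n_carbons} carbons; the 2^n isotopomer "
                "state space is too large — use the EMU path instead"
            )
    if targets is None:
        targets = network.balanced_pools()
    targets = list(targets)

    n_of = {m: p.n_carbons for m, p in network.pools.items()}
    dist: dict[str, np.ndarray] = {}
    for met, pool in network.pools.items():
        if pool.role == "source":
            dist[met] = _source_distribution(pool.n_carbons, met, tracer)
        else:
            d = np.zeros(2 ** pool.n_carbons)
            d[0] = 1.0
            dist[met] = d

    # per balanced pool: list of (weight, produced-pattern function inputs)
    computed = [m for m, pool in network.pools.items() if pool.role != "source"]
    channels: dict[str, list] = {m: [] for m in computed}
    for rxn in network.reactions:
        w_rxn = float(fluxes.get(rxn.id, 0.0))
        if w_rxn < 0:
            raise ValueError(f"negative flux for {rxn.id}")
        for var in rxn.variants:
            w = w_rxn * rxn.variant_weight
            for term in var.products:
                if term.metabolite not in channels:
                    continue
                # for each substrate instance: positions of its atoms that
                # land in this product, and the product bit positions
                pieces = []
                for sub in var.substrates:
                    sub_pos, prod_bits = [], []
                    for j, letter in enumerate(term.atoms):
                        k = sub.atoms.find(letter)
                        if k >= 0:
                            sub_pos.append(k + 1)
                            prod_bits.append(j)
                    if sub_pos:
                        pieces.append((sub.metabolite, sub_pos, prod_bits))
                channels[term.metabolite].append((w, pieces))

    computed = [m for m in computed if channels[m]]
    for it in range(max_iter):
        delta = 0.0
        for met in computed:
            total_w = sum(w for w, _ in channels[met])
            if total_w <= 0:
                raise ValueError(f"pool {met} has zero production flux")
            n = n_of[met]
            new = np.zeros(2 ** n)
            for w, pieces in channels[met]:
                margs = [
                    (_marginal(dist[sm], n_of[sm], sp), pb) for sm, sp, pb in pieces
                ]
                contrib = np.zeros(2 ** n)
                for mask in range(2 ** n):
                    p = 1.0
                    for marg, prod_bits in margs:
                        sub = 0
                        for j, bit in enumerate(prod_bits):
                            if mask >> bit & 1:
                                sub |= 1 << j
                        p *= marg[sub]
                        if p == 0.0:
                            break
                    contrib[mask] = p
                new += (w / total_w) * contrib
            delta = max(delta, float(np.abs(new - dist[met]).max()))
            dist[met] = new
        if delta < tol:
            break
    else:  # pragma: no cover
        raise RuntimeError("isotopomer fixed point did not converge")

    out = {}
    for met in targets:
        n = n_of[met]
        mid = np.zeros(n + 1)
        for mask in range(2 ** n):
            mid[bin(mask).count("1")] += dist[met][mask]
        out[met] = mid
    return out
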