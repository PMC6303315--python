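"""Atom-mapped metabolic network: parsing, validation, stoichiometry.

A network is defined in a plain-text reaction file.  Header lines declare
pool roles and biomass drains::

    SOURCE <id> <n_carbons>     # medium uptake pool, fixed isotopic state
    SINK <id>                   # excretion pool, never balanced
    BIOMASS <id> <coeff>        # drain into biomass, per unit growth rate

Reaction lines map every carbon by a lowercase letter, read left to right
as carbon 1..n of each metabolite::

    PDH: 1 PYR (abc) -> 1 ACCOA (bc) + 1 CO2 (a)

Repeating a reaction id on several lines declares mapping variants that
share one flux in equal parts; this is how symmetric intermediates
(succinate/fumarate scrambling) are expressed.  Two further line types
attach estimation metadata to the network: ``BRANCH`` lines register how
each branch point's flux ratio is read off measured mass-isotopomer
distributions, and ``LABEL`` lines give reactions their conventional
display names (e.g. ``3PG->Ser``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MetabolitePool",
    "ReactionTerm",
    "MappingVariant",
    "AtomMappedReaction",
    "BranchEntry",
    "BranchSpec",
    "MetabolicNetwork",
    "NetworkParseError",
    "parse_network_file",
    "parse_network_text",
    "write_network_file",
    "network_to_text",
    "validate_atom_balance",
    "stoichiometric_matrix",
    "reference_network",
    "load_toy_network",
    "toy_network_names",
]

BIOMASS_COL = "biomass"

_ID = r"[A-Za-z0-9_]+"
_TERM_RE = re.compile(rf"^\s*(?:(\d+)\s+)?({_ID})\s*\(([a-z]+)\)\s*$")
_RXN_RE = re.compile(rf"^({_ID})\s*:\s*(.+?)\s*->\s*(.+)$")
_BRANCH_RATIO_RE = re.compile(
    rf"^BRANCH\s+({_ID})\s+({_ID})\s*=\s*(.+?)\s*/\s*(.+?)\s+REST\s+({_ID})\s*$"
)
_BRANCH_INVERT_RE = re.compile(
    rf"^BRANCH\s+({_ID})\s+({_ID})\s*=\s*invert\s+(.+?)\s+REST\s+({_ID})\s*$"
)


class NetworkParseError(ValueError):
    """Raised for malformed reaction files; message names the line."""


@dataclass(frozen=True)
class MetabolitePool:
    """A metabolite pool with its carbon count and mass-balance role."""

    id: str
    n_carbons: int
    role: str  # 'balanced' | 'source' | 'sink'

    def __post_init__(self):
        if self.n_carbons < 1:
            raise ValueError(f"pool {self.id}: n_carbons must be >= 1")
        if self.role not in ("balanced", "source", "sink"):
            raise ValueError(f"pool {self.id}: unknown role {self.role!r}")


@dataclass(frozen=True)
class ReactionTerm:
    """One molecule instance on one side of a reaction."""

    metabolite: str
    atoms: str  # one lowercase letter per carbon, position 1..n


@dataclass(frozen=True)
class MappingVariant:
    substrates: tuple[ReactionTerm, ...]
    products: tuple[ReactionTerm, ...]


@dataclass(frozen=True)
class AtomMappedReaction:
    """A reaction with one or more equally weighted atom-mapping variants."""

    id: str
    variants: tuple[MappingVariant, ...]
    reversible: bool = False

    @property
    def substrates(self) -> tuple[ReactionTerm, ...]:
        return self.variants[0].substrates

    @property
    def products(self) -> tuple[ReactionTerm, ...]:
        return self.variants[0].products

    @property
    def variant_weight(self) -> float:
        return 1.0 / len(self.variants)


@dataclass(frozen=True)
class BranchEntry:
    """One producing reaction's share at a branch point.

    kind 'ratio'  : share = numerator / denominator, two observables over
                    measured MIDs (``MET:k`` = the m+k fraction;
                    ``L(A*B*...)`` = 1 - prod of m+0 fractions, the labeled
                    fraction of the convolved de novo precursors).
    kind 'invert' : share solved by inverting the steady-state relation
                    between the share and a single EMU-predicted observable.
    """

    reaction: str
    kind: str  # 'ratio' | 'invert'
    numerator: str | None = None
    denominator: str | None = None
    observable: str | None = None


@dataclass(frozen=True)
class BranchSpec:
    pool: str
    entries: tuple[BranchEntry, ...]
    rest: str  # reaction receiving share 1 - sum(entries)


@dataclass
class MetabolicNetwork:
    """Pools + atom-mapped reactions + biomass demand + branch registry."""

    pools: dict[str, MetabolitePool]
    reactions: list[AtomMappedReaction]
    biomass: dict[str, float] = field(default_factory=dict)
    branches: list[BranchSpec] = field(default_factory=list)
    labels: dict[str, str] = field(default_factory=dict)

    # -- basic queries ---------------------------------------------------
    def n_carbons(self, met: str) -> int:
        return self.pools[met].n_carbons

    def reaction(self, rxn_id: str) -> AtomMappedReaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def balanced_pools(self) -> list[str]:
        return [p.id for p in self.pools.values() if p.role == "balanced"]

    def source_pools(self) -> list[str]:
        return [p.id for p in self.pools.values() if p.role == "source"]

    def producer_channels(self, met: str):
        """Yield (reaction_id, variant_idx, product_idx, weight_multiplier)
        for every molecule instance of ``met`` produced anywhere.

        The channel's absolute production rate is flux * multiplier; the
        multiplier is the variant weight (mapping variants split one flux).
        """
        out = []
        for rxn in self.reactions:
            for vi, var in enumerate(rxn.variants):
                for pi, term in enumerate(var.products):
                    if term.metabolite == met:
                        out.append((rxn.id, vi, pi, rxn.variant_weight))
        return out

    def production_coefficient(self, met: str, rxn_id: str) -> float:
        """Total stoichiometric production of ``met`` by reaction ``rxn_id``."""
        rxn = self.reaction(rxn_id)
        total = 0.0
        for var in rxn.variants:
            total += rxn.variant_weight * sum(
                1 for t in var.products if t.metabolite == met
            )
        return total

    def producing_reactions(self, met: str) -> list[str]:
        seen = []
        for rxn_id, *_ in self.producer_channels(met):
            if rxn_id not in seen:
                seen.append(rxn_id)
        return seen

    # -- validation ------------------------------------------------------
    def validate(self) -> list[str]:
        """All structural violations (atom balance + pool connectivity)."""
        violations = list(validate_atom_balance(self))
        produced, consumed = set(), set()
        for rxn in self.reactions:
            for var in rxn.variants:
                consumed.update(t.metabolite for t in var.substrates)
                produced.update(t.metabolite for t in var.products)
        for pool in self.pools.values():
            if pool.role != "balanced":
                continue
            if pool.id not in produced:
                violations.append(f"balanced pool {pool.id} is never produced")
            if pool.id not in consumed and pool.id not in self.biomass:
                violations.append(f"balanced pool {pool.id} is never consumed")
        for met in self.biomass:
            if met not in self.pools:
                violations.append(f"biomass drains undeclared metabolite {met}")
        for br in self.branches:
            producers = self.producing_reactions(br.pool)
            for e in br.entries:
                if e.reaction not in producers:
                    violations.append(
                        f"branch {br.pool}: {e.reaction} does not produce it"
                    )
            if br.rest not in producers:
                violations.append(f"branch {br.pool}: REST {br.rest} does not produce it")
        return violations


def validate_atom_balance(network: MetabolicNetwork) -> list[str]:
    """Carbon-conservation violations, empty if the mapping is sound."""
    violations = []
    for rxn in network.reactions:
        for vi, var in enumerate(rxn.variants):
            tag = rxn.id if len(rxn.variants) == 1 else f"{rxn.id}[variant {vi}]"
            sub_letters, prod_letters = [], []
            for side_name, side, bag in (
                ("substrate", var.substrates, sub_letters),
                ("product", var.products, prod_letters),
            ):
                for term in side:
                    bag.extend(term.atoms)
                    n = network.n_carbons(term.metabolite)
                    if len(term.atoms) != n:
                        violations.append(
                            f"{tag}: {side_name} {term.metabolite} map "
                            f"'{term.atoms}' has {len(term.atoms)} atoms, "
                            f"pool has {n} carbons"
                        )
            for name, bag in (("substrate", sub_letters), ("product", prod_letters)):
                if len(bag) != len(set(bag)):
                    violations.append(f"{tag}: duplicate atom letter on {name} side")
            if sorted(sub_letters) != sorted(prod_letters):
                violations.append(
                    f"{tag}: substrate atoms {''.join(sorted(sub_letters))} != "
                    f"product atoms {''.join(sorted(prod_letters))}"
                )
    return violations


def stoichiometric_matrix(network: MetabolicNetwork) -> pd.DataFrame:
    """S with one row per balanced pool, one column per reaction plus a
    biomass column; steady state is S @ v = 0 with the growth flux == 1."""
    balanced = network.balanced_pools()
    if not balanced:
        raise ValueError("network has no balanced pool")
    cols = network.reaction_ids + [BIOMASS_COL]
    S = pd.DataFrame(0.0, index=balanced, columns=cols)
    for rxn in network.reactions:
        for var in rxn.variants:
            for term in var.substrates:
                if term.metabolite in S.index:
                    S.loc[term.metabolite, rxn.id] -= rxn.variant_weight
            for term in var.products:
                if term.metabolite in S.index:
                    S.loc[term.metabolite, rxn.id] += rxn.variant_weight
    for met, coeff in network.biomass.items():
        if met in S.index:
            S.loc[met, BIOMASS_COL] -= coeff
    return S


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

def _parse_terms(side: str, lineno: int) -> tuple[ReactionTerm, ...]:
    terms = []
    for chunk in side.split("+"):
        m = _TERM_RE.match(chunk)
        if not m:
            raise NetworkParseError(f"line {lineno}: malformed term {chunk.strip()!r}")
        coef = int(m.group(1)) if m.group(1) else 1
        if coef < 1:
            raise NetworkParseError(f"line {lineno}: coefficient must be >= 1")
        terms.extend([ReactionTerm(m.group(2), m.group(3))] * coef)
    return tuple(terms)


def parse_network_text(text: str, name: str = "<string>") -> MetabolicNetwork:
    sources: dict[str, int] = {}
    sinks: set[str] = set()
    biomass: dict[str, float] = {}
    labels: dict[str, str] = {}
    branch_lines: list[tuple[int, str]] = []
    rxn_order: list[str] = []
    variants: dict[str, list[MappingVariant]] = {}
    carbon_counts: dict[str, int] = dict()

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "SOURCE":
            if len(parts) != 3 or not parts[2].isdigit():
                raise NetworkParseError(f"line {lineno}: expected 'SOURCE <id> <n_carbons>'")
            sources[parts[1]] = int(parts[2])
        elif parts[0] == "SINK":
            if len(parts) != 2:
                raise NetworkParseError(f"line {lineno}: expected 'SINK <id>'")
            sinks.add(parts[1])
        elif parts[0] == "BIOMASS":
            if len(parts) != 3:
                raise NetworkParseError(f"line {lineno}: expected 'BIOMASS <id> <coeff>'")
            try:
                coeff = float(parts[2])
            except ValueError:
                raise NetworkParseError(f"line {lineno}: bad biomass coefficient") from None
            if coeff < 0:
                raise NetworkParseError(f"line {lineno}: biomass coefficient must be >= 0")
            biomass[parts[1]] = coeff
        elif parts[0] == "BRANCH":
            branch_lines.append((lineno, line))
        elif parts[0] == "LABEL":
            if len(parts) < 3:
                raise NetworkParseError(f"line {lineno}: expected 'LABEL <rxn> <name>'")
            labels[parts[1]] = " ".join(parts[2:])
        else:
            m = _RXN_RE.match(line)
            if not m:
                raise NetworkParseError(f"line {lineno}: malformed line {line!r}")
            rid, lhs, rhs = m.groups()
            var = MappingVariant(_parse_terms(lhs, lineno), _parse_terms(rhs, lineno))
            for term in var.substrates + var.products:
                prev = carbon_counts.get(term.metabolite)
                if prev is not None and prev != len(term.atoms):
                    raise NetworkParseError(
                        f"line {lineno}: {term.metabolite} used with "
                        f"{len(term.atoms)} carbons, previously {prev}"
                    )
                carbon_counts.setdefault(term.metabolite, len(term.atoms))
            if rid not in variants:
                rxn_order.append(rid)
            variants.setdefault(rid, []).append(var)

    for met, n in sources.items():
        prev = carbon_counts.get(met)
        if prev is not None and prev != n:
            raise NetworkParseError(
                f"{name}: SOURCE {met} declared with {n} carbons but mapped with {prev}"
            )
        carbon_counts[met] = n

    pools: dict[str, MetabolitePool] = {}
    for met, n in carbon_counts.items():
        role = "source" if met in sources else ("sink" if met in sinks else "balanced")
        pools[met] = MetabolitePool(met, n, role)
    for met in sorted(sinks | set(sources)):
        if met not in pools:
            raise NetworkParseError(f"{name}: declared pool {met} never appears in a reaction")

    reactions = [AtomMappedReaction(rid, tuple(variants[rid])) for rid in rxn_order]
    net = MetabolicNetwork(pools, reactions, biomass, [], labels)

    # branch lines need the reaction list, so parse them last
    for lineno, line in branch_lines:
        net.branches = list(net.branches)
        _parse_branch_line(net, line, lineno)

    for rxn_id in labels:
        if rxn_id not in net.reaction_ids:
            raise NetworkParseError(f"{name}: LABEL references unknown reaction {rxn_id}")
    for rxn in reactions:
        for var in rxn.variants:
            for term in var.substrates + var.products:
                if term.metabolite not in pools:
                    raise NetworkParseError(
                        f"{name}: reaction {rxn.id} references undeclared "
                        f"metabolite {term.metabolite}"
                    )
    return net


def _parse_branch_line(net: MetabolicNetwork, line: str, lineno: int) -> None:
    m = _BRANCH_INVERT_RE.match(line)
    if m:
        pool, rxn, obs, rest = m.groups()
        entry = BranchEntry(rxn, "invert", observable=obs.strip())
    else:
        m = _BRANCH_RATIO_RE.match(line)
        if not m:
            raise NetworkParseError(f"line {lineno}: malformed BRANCH line")
        pool, rxn, num, den, rest = m.groups()
        entry = BranchEntry(rxn, "ratio", numerator=num.strip(), denominator=den.strip())
    if pool not in net.pools:
        raise NetworkParseError(f"line {lineno}: BRANCH references unknown pool {pool}")
    for rid in (entry.reaction, rest):
        if rid not in net.reaction_ids:
            raise NetworkParseError(f"line {lineno}: BRANCH references unknown reaction {rid}")
    for existing in net.branches:
        if existing.pool == pool:
            # merge another named share onto the same branch point
            net.branches[net.branches.index(existing)] = BranchSpec(
                pool, existing.entries + (entry,), rest
            )
            return
    net.branches.append(BranchSpec(pool, (entry,), rest))


def parse_network_file(path) -> MetabolicNetwork:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return parse_network_text(path.read_text(), name=str(path))


def network_to_text(network: MetabolicNetwork) -> str:
    """Serialize in the same dialect with a stable ordering (round-trips)."""
    lines = []
    for met in sorted(network.source_pools()):
        lines.append(f"SOURCE {met} {network.n_carbons(met)}")
    for met in sorted(p.id for p in network.pools.values() if p.role == "sink"):
        lines.append(f"SINK {met}")
    for met in sorted(network.biomass):
        lines.append(f"BIOMASS {met} {network.biomass[met]:g}")
    for rxn in network.reactions:
        for var in rxn.variants:
            lhs = " + ".join(f"1 {t.metabolite} ({t.atoms})" for t in var.substrates)
            rhs = " + ".join(f"1 {t.metabolite} ({t.atoms})" for t in var.products)
            lines.append(f"{rxn.id}: {lhs} -> {rhs}")
    for br in network.branches:
        for e in br.entries:
            if e.kind == "invert":
                lines.append(
                    f"BRANCH {br.pool} {e.reaction} = invert {e.observable} REST {br.rest}"
                )
            else:
                lines.append(
                    f"BRANCH {br.pool} {e.reaction} = {e.numerator} / {e.denominator} "
                    f"REST {br.rest}"
                )
    for rxn_id in network.reaction_ids:
        if rxn_id in network.labels:
            lines.append(f"LABEL {rxn_id} {network.labels[rxn_id]}")
    return "\n".join(lines) + "\n"


def write_network_file(network: MetabolicNetwork, path) -> None:
    Path(path).write_text(network_to_text(network))


# ---------------------------------------------------------------------------
# packaged networks
# ---------------------------------------------------------------------------

def _load_packaged(relpath: str) -> MetabolicNetwork:
    text = resources.files("emuflux").joinpath(relpath).read_text()
    net = parse_network_text(text, name=relpath)
    violations = net.validate()
    if violations:  # pragma: no cover - packaged files are validated by tests
        raise ValueError(f"packaged network {relpath} invalid: {violations}")
    return net


def reference_network() -> MetabolicNetwork:
    """The packaged 19-reaction / 21-metabolite reconstruction of the
    serine-synthesis / PPP / TCA / nucleotide model used throughout.

    Glucose enters the model as G6P (the uniformly labeled tracer is applied
    there); the TCA cycle is lumped into two steps with succinate/fumarate
    scrambling written as half-weight mapping variants; surplus one-carbon
    units leave as formate.  See docs/methods.md for every reconstruction
    assumption.
    """
    return _load_packaged("data/phgdh_nucleotide.net")


def toy_network_names() -> list[str]:
    root = resources.files("emuflux").joinpath("data/toys")
    return sorted(p.name.removesuffix(".net") for p in root.iterdir() if p.name.endswith(".net"))


def load_toy_network(name: str) -> MetabolicNetwork:
    """Small packaged networks used to cross-check the EMU solver against
    brute-force isotopomer enumeration."""
    return _load_packaged(f"data/toys/{name}.net")
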