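"""Measured isotopologue data: normalization, natural-abundance correction,
replicate aggregation and delimited-table I/O.

The table dialect shared by measured and simulated data has columns
``metabolite, condition, replicate, m+0 ... m+N`` (comma- or tab-separated
by file extension); metabolites with fewer carbons leave the trailing
columns empty.  An intensity-table variant carries raw isotopologue
intensities in the same layout and is normalized on ingestion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MID",
    "MIDSet",
    "ElementalFormula",
    "normalize_isotopologue_intensities",
    "natural_abundance_matrix",
    "apply_natural_abundance",
    "natural_abundance_correction",
    "aggregate_replicates",
    "read_mid_table",
    "write_mid_table",
    "read_intensity_table",
    "C13_NATURAL_ABUNDANCE",
    "REFERENCE_FORMULAS",
]

C13_NATURAL_ABUNDANCE = 0.0107

#: ingestion tolerance on sum-to-1 (instrument rounding); internal tolerance
INGEST_SUM_TOL = 1e-3
SUM_TOL = 1e-6


@dataclass(frozen=True)
class MID:
    """A mass-isotopomer distribution: fractions m+0 .. m+n summing to 1."""

    metabolite: str
    fractions: tuple[float, ...]
    provenance: str = "raw-normalized"  # | 'corrected' | 'simulated'

    def __post_init__(self):
        fr = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", tuple(fr))
        if len(fr) < 1:
            raise ValueError("empty MID")
        if (fr < -1e-12).any():
            raise ValueError(f"{self.metabolite}: negative MID fraction")
        if abs(fr.sum() - 1.0) > SUM_TOL:
            raise ValueError(
                f"{self.metabolite}: MID sums to {fr.sum():.6g}, not 1"
            )

    @property
    def n_carbons(self) -> int:
        return len(self.fractions) - 1

    def as_array(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)

    def __getitem__(self, k: int) -> float:
        return self.fractions[k]

    @property
    def labeled_fraction(self) -> float:
        return 1.0 - self.fractions[0]


class MIDSet:
    """Measured (or simulated) MIDs keyed by (metabolite, condition,
    replicate)."""

    def __init__(self, entries: dict[tuple[str, str, str], MID] | None = None):
        self._entries: dict[tuple[str, str, str], MID] = {}
        if entries:
            for key, mid in entries.items():
                self.add(key[0], key[1], key[2], mid)

    def add(self, metabolite: str, condition: str, replicate, mid: MID) -> None:
        replicate = str(replicate)
        for (m, c, r), other in self._entries.items():
            if m == metabolite and other.n_carbons != mid.n_carbons:
                raise ValueError(
                    f"{metabolite}: replicate MIDs have different lengths "
                    f"({other.n_carbons + 1} vs {mid.n_carbons + 1})"
                )
        self._entries[(metabolite, condition, replicate)] = mid

    def get(self, metabolite: str, condition: str, replicate) -> MID:
        return self._entries[(metabolite, condition, str(replicate))]

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MIDSet):
            return NotImplemented
        if set(self._entries) != set(other._entries):
            return False
        return all(
            np.allclose(self._entries[k].as_array(), other._entries[k].as_array())
            and self._entries[k].provenance == other._entries[k].provenance
            for k in self._entries
        )

    def keys(self):
        return self._entries.keys()

    def items(self):
        return self._entries.items()

    def metabolites(self) -> list[str]:
        return sorted({m for m, _, _ in self._entries})

    def conditions(self) -> list[str]:
        return sorted({c for _, c, _ in self._entries})

    def replicates(self, condition: str) -> list[str]:
        return sorted({r for _, c, r in self._entries if c == condition})

    def for_replicate(self, condition: str, replicate) -> dict[str, MID]:
        replicate = str(replicate)
        return {
            m: mid
            for (m, c, r), mid in self._entries.items()
            if c == condition and r == replicate
        }

    def map(self, fn) -> "MIDSet":
        return MIDSet({k: fn(v) for k, v in self._entries.items()})


def normalize_isotopologue_intensities(raw, metabolite: str = "",
                                       provenance: str = "raw-normalized") -> MID:
    """Fraction-of-total normalization of raw isotopologue intensities."""
    raw = np.asarray(raw, dtype=float)
    if (raw < 0).any():
        raise ValueError("negative isotopologue intensity")
    total = raw.sum()
    if total <= 0:
        raise ValueError("all-zero intensity vector cannot be normalized")
    return MID(metabolite, tuple(raw / total), provenance)


# ---------------------------------------------------------------------------
# natural-abundance correction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElementalFormula:
    """Element counts used for natural-abundance correction."""

    C: int
    H: int = 0
    N: int = 0
    O: int = 0
    P: int = 0
    S: int = 0

    def __post_init__(self):
        if self.C < 0 or min(self.H, self.N, self.O, self.P, self.S) < 0:
            raise ValueError("element counts must be >= 0")


#: mass-shift (+0/+1/+2) natural-isotope distributions of non-carbon elements
_ELEMENT_SHIFTS = {
    "H": (1 - 0.000115, 0.000115, 0.0),
    "N": (1 - 0.00364, 0.00364, 0.0),
    "O": (1 - 0.00038 - 0.00205, 0.00038, 0.00205),
    "P": (1.0, 0.0, 0.0),
    "S": (1 - 0.0075 - 0.0425, 0.0075, 0.0425),
}


def _element_pattern(counts: ElementalFormula, length: int) -> np.ndarray:
    pat = np.zeros(length)
    pat[0] = 1.0
    for el, shifts in _ELEMENT_SHIFTS.items():
        n = getattr(counts, el)
        for _ in range(n):
            pat = np.convolve(pat, shifts)[:length]
    return pat


def natural_abundance_matrix(formula: ElementalFormula,
                             abundance: float = C13_NATURAL_ABUNDANCE,
                             full_formula: bool = False) -> np.ndarray:
    """Forward convolution matrix M with M[i, j] = P(measured m+i | j carbons
    are tracer-labeled).  Carbon-only by default; ``full_formula`` also folds
    in the +1/+2 isotopes of H, N, O, P, S."""
    n = formula.C
    M = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        col = np.zeros(n + 1)
        for k in range(n - j + 1):
            col[j + k] = math.comb(n - j, k) * abundance ** k * (1 - abundance) ** (n - j - k)
        if full_formula:
            col = np.convolve(col, _element_pattern(formula, n + 1))[: n + 1]
        M[:, j] = col
    return M


def apply_natural_abundance(mid: MID, formula: ElementalFormula,
                            abundance: float = C13_NATURAL_ABUNDANCE,
                            full_formula: bool = False) -> MID:
    """Forward operation: what an instrument would measure for a tracer MID."""
    M = natural_abundance_matrix(formula, abundance, full_formula)
    out = M @ mid.as_array()
    out = out / out.sum()
    return replace(mid, fractions=tuple(out), provenance="raw-normalized")


def natural_abundance_correction(mid: MID, formula: ElementalFormula,
                                 abundance: float = C13_NATURAL_ABUNDANCE,
                                 full_formula: bool = False) -> MID:
    """Remove natural heavy-isotope contributions from a measured MID.

    Inverts the theoretical convolution matrix, clips small negatives and
    renormalizes.  ~1.1% 13C matters at the few-percent flux level, so this
    is on by default for measured data in the pipeline (and off for
    simulated data, which is generated without natural abundance).
    """
    if formula.C != mid.n_carbons:
        raise ValueError(
            f"{mid.metabolite}: formula has {formula.C} carbons, MID has {mid.n_carbons}"
        )
    M = natural_abundance_matrix(formula, abundance, full_formula)
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("ill-conditioned natural-abundance correction matrix")
    x = np.linalg.solve(M, mid.as_array())
    x = np.clip(x, 0.0, None)
    total = x.sum()
    if total <= 0:
        raise ValueError(f"{mid.metabolite}: correction produced an empty MID")
    return replace(mid, fractions=tuple(x / total), provenance="corrected")


def aggregate_replicates(midset: MIDSet, metabolite: str,
                         condition: str) -> tuple[MID, np.ndarray]:
    """Elementwise mean MID (renormalized) and per-isotopologue s.e.m."""
    reps = midset.replicates(condition)
    arrays, missing = [], []
    for r in reps:
        try:
            arrays.append(midset.get(metabolite, condition, r).as_array())
        except KeyError:
            missing.append(r)
    if missing:
        raise ValueError(
            f"{metabolite}/{condition}: missing replicates {missing}"
        )
    if len(arrays) < 2:
        raise ValueError(f"{metabolite}/{condition}: need >= 2 replicates")
    stack = np.vstack(arrays)
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(len(arrays))
    mean = mean / mean.sum()
    prov = {m.provenance for m in (midset.get(metabolite, condition, r) for r in reps)}
    return MID(metabolite, tuple(mean), prov.pop() if len(prov) == 1 else "raw-normalized"), sem


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def _table_to_frame(midset: MIDSet) -> pd.DataFrame:
    max_n = max(mid.n_carbons for mid in dict(midset.items()).values())
    rows = []
    for (m, c, r), mid in sorted(midset.items()):
        row = {"metabolite": m, "condition": c, "replicate": r}
        for k in range(max_n + 1):
            row[f"m+{k}"] = mid.fractions[k] if k <= mid.n_carbons else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_mid_table(midset: MIDSet, path) -> None:
    df = _table_to_frame(midset)
    df.to_csv(path, sep=_sep_for(path), index=False)


def _frame_to_midset(df: pd.DataFrame, provenance: str, normalize: bool) -> MIDSet:
    required = {"metabolite", "condition", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(f"table is missing columns {sorted(required - set(df.columns))}")
    mcols = [c for c in df.columns if c.startswith("m+")]
    if not mcols:
        raise ValueError("table has no m+k columns")
    mcols.sort(key=lambda c: int(c[2:]))
    out = MIDSet()
    for i, row in df.iterrows():
        vals = row[mcols].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            raise ValueError(f"row {i}: no isotopologue values")
        if (vals < 0).any():
            raise ValueError(f"row {i}: negative fraction/intensity")
        if normalize:
            mid = normalize_isotopologue_intensities(vals, str(row["metabolite"]))
        else:
            if abs(vals.sum() - 1.0) > INGEST_SUM_TOL:
                raise ValueError(
                    f"row {i}: fractions sum to {vals.sum():.4g} "
                    f"(tolerance {INGEST_SUM_TOL})"
                )
            mid = MID(str(row["metabolite"]), tuple(vals / vals.sum()), provenance)
        out.add(str(row["metabolite"]), str(row["condition"]), str(row["replicate"]), mid)
    return out


def read_mid_table(path, provenance: str = "raw-normalized") -> MIDSet:
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    return _frame_to_midset(df, provenance, normalize=False)


def read_intensity_table(path) -> MIDSet:
    """Raw isotopologue intensity table in the same layout; rows are
    normalized to fractions on ingestion."""
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    return _frame_to_midset(df, "raw-normalized", normalize=True)


#: elemental formulas of the packaged network's measurable pools, for
#: natural-abundance correction of real data
REFERENCE_FORMULAS = {
    "G6P": ElementalFormula(C=6, H=13, O=9, P=1),
    "R5P": ElementalFormula(C=5, H=11, O=8, P=1),
    "3PG": ElementalFormula(C=3, H=7, O=7, P=1),
    "PYR": ElementalFormula(C=3, H=4, O=3),
    "SER": ElementalFormula(C=3, H=7, N=1, O=3),
    "GLY": ElementalFormula(C=2, H=5, N=1, O=2),
    "ACCOA": ElementalFormula(C=2, H=4, O=1),
    "OAA": ElementalFormula(C=4, H=4, O=5),
    "AKG": ElementalFormula(C=5, H=6, O=5),
    "ASP": ElementalFormula(C=4, H=7, N=1, O=4),
    "IMP": ElementalFormula(C=10, H=13, N=4, O=8, P=1),
    "UMP": ElementalFormula(C=9, H=13, N=2, O=9, P=1),
}
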