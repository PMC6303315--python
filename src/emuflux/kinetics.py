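"""Kinetic flux profiling: first-order approach-to-plateau fits of labeled
fraction time courses.

After switching the medium to a 13C tracer, the labeled fraction of a
well-mixed pool at isotopic quasi-steady precursor enrichment follows

    F(t) = F_inf * (1 - exp(-k t))

where k is the pool's turnover rate constant (total flux / pool size) and
F_inf the plateau enrichment.  Comparing k (or the turnover flux J = k * P
when the pool size P is known) between conditions measures relative flux
through the pathway feeding the pool — the kinetic counterpart of the
steady-state branch-ratio analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

__all__ = [
    "TimeCourse",
    "KineticFit",
    "fit_first_order_labeling",
    "relative_flux_change",
    "trajectory_table",
]

#: below this maximum observed fraction a fit is refused ("no-labeling")
NO_LABELING_FLOOR = 0.02


@dataclass
class TimeCourse:
    """Labeled fraction of one reporter isotopologue over time.

    ``fractions`` has shape (n_replicates, n_times); times are minutes.
    """

    metabolite: str
    isotopomer: int  # the m+k reporter
    times: np.ndarray
    fractions: np.ndarray
    condition: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        fr = np.atleast_2d(np.asarray(self.fractions, dtype=float))
        if fr.shape[1] != len(self.times):
            raise ValueError("fractions and times have mismatched lengths")
        if not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")
        if ((fr < -1e-9) | (fr > 1 + 1e-9)).any():
            raise ValueError("labeled fractions must lie in [0, 1]")
        self.fractions = np.clip(fr, 0.0, 1.0)

    @property
    def n_replicates(self) -> int:
        return self.fractions.shape[0]


@dataclass
class KineticFit:
    """Fitted plateau and rate constant of a first-order labeling curve."""

    metabolite: str
    condition: str
    plateau: float  # F_inf in [0, 1]
    rate: float     # k, 1/min (nan when status != 'ok')
    rss: float
    status: str  # 'ok' | 'no-labeling' | 'failed'
    pool_size: float | None = None
    n_obs: int = 0

    @property
    def turnover_flux(self) -> float | None:
        """J = k * P when a pool size is attached, else None."""
        if self.pool_size is None or self.status != "ok":
            return None
        return self.rate * self.pool_size

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.status != "ok":
            return np.zeros_like(t)
        return self.plateau * (1.0 - np.exp(-self.rate * t))


def _initial_guess(times: np.ndarray, mean_frac: np.ndarray) -> tuple[float, float]:
    f_inf0 = float(mean_frac.max())
    above = times[mean_frac >= f_inf0 / 2.0]
    above = above[above > 0]
    t_half = float(above[0]) if len(above) else float(np.median(times[times > 0]))
    return f_inf0, 1.0 / t_half


def fit_first_order_labeling(tc: TimeCourse,
                             pool_size: float | None = None) -> KineticFit:
    """Nonlinear least squares for (F_inf, k) on all replicate points.

    Requires >= 4 time points including an early one; refuses to fit when
    the maximum observed fraction is below ``NO_LABELING_FLOOR`` (returns
    status 'no-labeling' with plateau 0 and undefined k) rather than
    reporting an arbitrary rate.  Deterministic: the initialization rule is
    fixed (F_inf0 = max observed fraction, k0 = 1/t_half).
    """
    times = tc.times
    if len(times) < 4:
        raise ValueError("need at least 4 time points")
    if times.min() > 0.25 * times.max():
        raise ValueError("need an early time point (t near 0)")

    t_all = np.tile(times, tc.n_replicates)
    f_all = tc.fractions.ravel()
    if f_all.max() < NO_LABELING_FLOOR:
        return KineticFit(tc.metabolite, tc.condition, 0.0, float("nan"),
                          float(np.sum(f_all ** 2)), "no-labeling",
                          pool_size, len(f_all))

    mean_frac = tc.fractions.mean(axis=0)
    f0, k0 = _initial_guess(times, mean_frac)

    def residuals(params):
        f_inf, k = params
        return f_inf * (1.0 - np.exp(-k * t_all)) - f_all

    res = scipy.optimize.least_squares(
        residuals, x0=[min(max(f0, 1e-3), 1.0), max(k0, 1e-6)],
        bounds=([0.0, 0.0], [1.0, np.inf]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    status = "ok" if res.status > 0 else "failed"
    f_inf, k = map(float, res.x)
    return KineticFit(tc.metabolite, tc.condition, f_inf, k,
                      float(2 * res.cost), status, pool_size, len(f_all))


def relative_flux_change(control: KineticFit, treated: KineticFit,
                         pool_ratio: float | None = None) -> float:
    """Relative turnover (treated / control).

    Uses (k_t * P_t) / (k_c * P_c) when pool sizes are available (attached
    to the fits or given as ``pool_ratio`` = P_t / P_c); otherwise returns
    the bare rate-constant ratio, which equals the flux ratio only when the
    pool sizes are unchanged between conditions.
    """
    if control.status != "ok":
        raise ValueError("control fit has no labeling; relative flux undefined")
    if treated.status != "ok":
        raise ValueError("treated fit did not converge")
    if pool_ratio is None:
        if control.pool_size and treated.pool_size:
            pool_ratio = treated.pool_size / control.pool_size
        else:
            import logging
            logging.getLogger("emuflux").info(
                "%s: no pool sizes; reporting the rate-constant ratio, valid "
                "as a flux ratio only for unchanged pools", control.metabolite,
            )
            pool_ratio = 1.0
    return (treated.rate / control.rate) * pool_ratio


def trajectory_table(tcs: list[TimeCourse]) -> pd.DataFrame:
    """Tidy mean +/- s.e.m. per time point across replicates.

    With a single replicate the s.e.m. is undefined and reported as 0.
    """
    rows = []
    for tc in tcs:
        n = tc.n_replicates
        mean = tc.fractions.mean(axis=0)
        sem = (tc.fractions.std(axis=0, ddof=1) / np.sqrt(n)) if n > 1 else \
            np.zeros_like(mean)
        sem[sem <= 1e-12 * (np.abs(mean) + 1.0)] = 0.0  # rounding dust
        for t, m, s in zip(tc.times, mean, sem):
            rows.append((tc.metabolite, tc.condition, tc.isotopomer,
                         float(t), float(m), float(s), n))
    return pd.DataFrame(rows, columns=["metabolite", "condition", "isotopomer",
                                       "time_min", "mean", "sem", "n"])
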