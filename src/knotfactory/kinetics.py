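"""Knot-formation kinetics: birth-death rate equations and their fitting.

During the hold phase the number of knots on the chain evolves as a
continuous-time Markov birth-death chain on states m = 0..n_k, with forward
(knotting) rates k_{i,i+1} and backward (unknotting) rates k_{i+1,i}.  The
state probabilities obey dP/dt = Q P with tridiagonal generator Q; releasing
the chain at waiting time t_w samples the state, so observed per-time knot
counts are multinomial in P_m(t_w).  The model is fitted by multinomial
maximum likelihood, with profile-likelihood one-sigma intervals.

Backward rates are free parameters by default: observed total knotting
saturates below 1 at long times, which a pure forward chain started from the
unknotted state cannot produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm, null_space
from scipy.optimize import minimize, brentq

__all__ = [
    "RateModel",
    "KnotCountTable",
    "solve_kinetics",
    "KnotKineticsModel",
    "KineticsResults",
    "fit_kinetics",
    "saturation_summary",
    "IdentifiabilityError",
]


class IdentifiabilityError(ValueError):
    """The count data cannot constrain the requested rate parameters."""


@dataclass
class RateModel:
    """Birth-death chain on knot number m = 0..n_k.

    ``forward[i]`` is k_{i,i+1}; ``backward[i]`` is k_{i+1,i} (both s^-1).
    The initial distribution defaults to the unknotted state.
    """

    forward: np.ndarray
    backward: np.ndarray
    p0: np.ndarray | None = None

    def __post_init__(self):
        self.forward = np.atleast_1d(np.asarray(self.forward, float))
        self.backward = np.atleast_1d(np.asarray(self.backward, float))
        if self.forward.shape != self.backward.shape:
            raise ValueError("forward and backward must have equal length")
        if np.any(self.forward < 0) or np.any(self.backward < 0):
            raise ValueError("rates must be nonnegative")
        n = self.forward.size + 1
        if self.p0 is None:
            self.p0 = np.eye(n)[0]
        else:
            self.p0 = np.asarray(self.p0, float)
            if self.p0.size != n or abs(self.p0.sum() - 1) > 1e-9 or np.any(self.p0 < 0):
                raise ValueError("p0 must be a distribution over n_k + 1 states")

    @property
    def n_k(self) -> int:
        return self.forward.size

    def generator(self) -> np.ndarray:
        """Tridiagonal generator Q (column convention: dP/dt = Q P)."""
        n = self.n_k + 1
        Q = np.zeros((n, n))
        for i, k in enumerate(self.forward):
            Q[i + 1, i] += k
            Q[i, i] -= k
        for i, k in enumerate(self.backward):
            Q[i, i + 1] += k
            Q[i + 1, i + 1] -= k
        return Q

    def stationary(self) -> np.ndarray:
        """Stationary distribution from the null space of Q.

        For a chain with some zero backward rates the stationary state puts
        all mass past the last irreversible step (absorbing structure).
        """
        ns = null_space(self.generator())
        if ns.shape[1] == 0:
            raise RuntimeError("no stationary distribution found")
        # if the null space is degenerate, take the long-time limit instead
        if ns.shape[1] > 1:
            P = solve_kinetics(self, [1e6 / max(self.forward.max(), 1e-12)])
            return P[:, 0]
        v = ns[:, 0]
        v = np.abs(v)
        return v / v.sum()


def solve_kinetics(model: RateModel, times) -> np.ndarray:
    """Solve dP/dt = Q P by matrix exponential.

    Returns an array of shape (n_k + 1, len(times)); each column sums to 1.
    """
    times = np.atleast_1d(np.asarray(times, float))
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    Q = model.generator()
    cols = [expm(Q * t) @ model.p0 for t in times]
    P = np.stack(cols, axis=1)
    return np.clip(P, 0.0, None) / P.sum(axis=0, keepdims=True)


class KnotCountTable:
    """Tidy table of observed knot counts: columns R_b, t_w, m, count."""

    COLUMNS = ["R_b", "t_w", "m", "count"]

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (df["count"] < 0).any():
            raise ValueError("counts must be nonnegative")
        self.df = df.reset_index(drop=True)

    def __len__(self):
        return len(self.df)

    @property
    def n_k(self) -> int:
        return int(self.df["m"].max()) if len(self.df) else 0

    def counts_by_time(self, n_k: int | None = None):
        """(times, counts) with counts of shape (n_times, n_k + 1), pooled over R_b."""
        n_k = self.n_k if n_k is None else n_k
        times = np.sort(self.df["t_w"].unique())
        counts = np.zeros((times.size, n_k + 1), dtype=int)
        for i, t in enumerate(times):
            sub = self.df[self.df["t_w"] == t]
            for _, row in sub.iterrows():
                m = int(row["m"])
                if m <= n_k:
                    counts[i, m] += int(row["count"])
                else:
                    counts[i, n_k] += int(row["count"])
        return times, counts

    def counts_at(self, R_b: float, n_k: int | None = None) -> np.ndarray:
        """Pooled count vector over m at one compression condition."""
        n_k = self.n_k if n_k is None else n_k
        sub = self.df[np.isclose(self.df["R_b"], R_b)]
        out = np.zeros(n_k + 1, dtype=int)
        for _, row in sub.iterrows():
            out[min(int(row["m"]), n_k)] += int(row["count"])
        return out

    def to_csv(self, path):
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path))


@dataclass
class KineticsResults:
    """Fitted birth-death rates with one-sigma profile-likelihood intervals."""

    model: RateModel
    loglike: float
    intervals: dict = field(default_factory=dict)  # name -> (lo, hi)
    n_events: int = 0

    @property
    def k01(self) -> float:
        return float(self.model.forward[0])

    def rate(self, i: int, j: int) -> float:
        if j == i + 1:
            return float(self.model.forward[i])
        if j == i - 1:
            return float(self.model.backward[j])
        raise KeyError(f"no rate k_{i}{j} in a birth-death chain")

    def to_dict(self) -> dict:
        """JSON-ready rates and intervals."""
        out = {"loglike": self.loglike, "n_events": self.n_events}
        for i, k in enumerate(self.model.forward):
            out[f"k{i}{i + 1}"] = float(k)
        for i, k in enumerate(self.model.backward):
            out[f"k{i + 1}{i}"] = float(k)
        out["intervals"] = {k: list(v) for k, v in self.intervals.items()}
        return out

    def predicted_probabilities(self, times) -> pd.DataFrame:
        """Model P_m(t) at the given waiting times, tidy for CSV export."""
        P = solve_kinetics(self.model, times)
        rows = []
        for j, t in enumerate(np.atleast_1d(times)):
            for m in range(P.shape[0]):
                rows.append({"t_w": float(t), "m": m, "P": float(P[m, j])})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Birth-death knotting kinetics fit (multinomial ML)",
                 f"  events: {self.n_events}, log-likelihood: {self.loglike:.3f}"]
        for i, k in enumerate(self.model.forward):
            ci = self.intervals.get(f"k{i}{i + 1}")
            tail = f"   1-sigma [{ci[0]:.3f}, {ci[1]:.3f}]" if ci else ""
            lines.append(f"  k{i}{i + 1} = {k:8.4f} s^-1{tail}")
        for i, k in enumerate(self.model.backward):
            ci = self.intervals.get(f"k{i + 1}{i}")
            tail = f"   1-sigma [{ci[0]:.3f}, {ci[1]:.3f}]" if ci else ""
            lines.append(f"  k{i + 1}{i} = {k:8.4f} s^-1{tail}")
        return "\n".join(lines)


class KnotKineticsModel:
    """Multinomial maximum-likelihood fit of the birth-death chain to
    per-waiting-time knot counts.

    Parameters
    ----------
    table : KnotCountTable
        Observed counts versus waiting time (pooled over R_b).
    n_k : int
        Maximum knot number of the chain.
    fix_zero_backward : bool
        If True, unknotting rates are pinned at zero (pure forward chain).
    """

    def __init__(self, table: KnotCountTable, n_k: int = 2,
                 fix_zero_backward: bool = False):
        self.table = table
        self.n_k = n_k
        self.fix_zero_backward = fix_zero_backward
        self.times, self.counts = table.counts_by_time(n_k)
        if self.times.size < 3:
            raise IdentifiabilityError(
                f"need >= 3 distinct waiting times, got {self.times.size}"
            )
        if self.counts.sum() == 0:
            raise IdentifiabilityError("no events in table")

    # -- likelihood ---------------------------------------------------------

    def _unpack(self, theta: np.ndarray) -> RateModel:
        rates = np.exp(theta)
        if self.fix_zero_backward:
            return RateModel(rates, np.zeros(self.n_k))
        return RateModel(rates[: self.n_k], rates[self.n_k:])

    def loglike(self, theta: np.ndarray) -> float:
        model = self._unpack(theta)
        P = solve_kinetics(model, self.times)  # (n_k+1, n_times)
        P = np.clip(P.T, 1e-300, None)
        return float(np.sum(self.counts * np.log(P)))

    def _fit_theta(self, theta0=None, fixed: dict | None = None):
        n_par = self.n_k if self.fix_zero_backward else 2 * self.n_k
        if theta0 is None:
            theta0 = np.log(np.full(n_par, 0.1))
        fixed = fixed or {}

        free_idx = [i for i in range(n_par) if i not in fixed]

        def negll(free):
            theta = np.empty(n_par)
            for i, v in fixed.items():
                theta[i] = v
            theta[free_idx] = free
            return -self.loglike(theta)

        res = minimize(negll, np.asarray(theta0)[free_idx], method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 4000})
        theta = np.empty(n_par)
        for i, v in fixed.items():
            theta[i] = v
        theta[free_idx] = res.x
        return theta, -res.fun

    def fit(self, profile_ci: bool = True, ci_params=("k01",)) -> KineticsResults:
        theta, ll = self._fit_theta()
        model = self._unpack(theta)
        intervals = {}
        if profile_ci:
            for name in ci_params:
                idx = self._param_index(name)
                intervals[name] = self._profile_interval(theta, ll, idx)
        return KineticsResults(model=model, loglike=ll, intervals=intervals,
                               n_events=int(self.counts.sum()))

    def _param_index(self, name: str) -> int:
        i, j = int(name[1]), int(name[2])
        if j == i + 1:
            return i
        if j == i - 1 and not self.fix_zero_backward:
            return self.n_k + j
        raise KeyError(name)

    def _profile_interval(self, theta_hat, ll_hat, idx, level: float = 1.0):
        """One-sigma profile-likelihood interval: 2*(ll_hat - ll_prof) = level^2."""
        target = ll_hat - level**2 / 2.0

        def prof(v):
            _, ll = self._fit_theta(theta0=theta_hat, fixed={idx: v})
            return ll - target

        lo = hi = np.exp(theta_hat[idx])
        v0 = theta_hat[idx]
        # bracket outward in log-rate
        for sign, store in ((-1, "lo"), (1, "hi")):
            a, b = v0, v0
            fa = level**2 / 2.0
            for step in (0.1, 0.2, 0.4, 0.8, 1.6, 3.2):
                b = v0 + sign * step
                fb = prof(b)
                if fb < 0:
                    root = brentq(prof, min(a, b), max(a, b), xtol=1e-3)
                    if store == "lo":
                        lo = np.exp(root)
                    else:
                        hi = np.exp(root)
                    break
                a, fa = b, fb
            else:
                if store == "lo":
                    lo = 0.0
                else:
                    hi = np.inf
        return float(lo), float(hi)


def fit_kinetics(table: KnotCountTable, n_k: int = 2,
                 fix_zero_backward: bool = False,
                 profile_ci: bool = True) -> KineticsResults:
    """Fit the birth-death chain to a knot-count table (see KnotKineticsModel)."""
    return KnotKineticsModel(table, n_k=n_k,
                             fix_zero_backward=fix_zero_backward).fit(profile_ci=profile_ci)


def saturation_summary(model: RateModel, t_max: float = 1e4):
    """Stationary distribution and the time at which total knotting
    probability 1 - P_0(t) first reaches 95% of its asymptote."""
    pi = model.stationary()
    target = 0.95 * (1.0 - pi[0])
    if target <= 0:
        return pi, 0.0

    def knotted(t):
        return 1.0 - solve_kinetics(model, [t])[0, 0]

    lo, hi = 0.0, 1.0
    while knotted(hi) < target:
        hi *= 2.0
        if hi > t_max:
            raise RuntimeError("saturation time beyond t_max")
    t95 = brentq(lambda t: knotted(t) - target, lo, hi, xtol=1e-6)
    return pi, float(t95)
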