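"""Feature-importance weights by linear programming.

Each feature ``k`` receives a weight ``omega_k`` on the probability
simplex, chosen so that every training sample's weighted residual under
its own class undercuts its weighted residual under every wrong class by
a margin ``epsilon``, up to per-sample slacks ``xi_i``:

    min_{omega, xi, eps}   (1/N) sum_i xi_i  -  eps
    s.t.  sum_k omega_k R[i, s_i, k] - xi_i
              <= sum_k omega_k R[i, j, k] - eps     (all i, all j != s_i)
          sum_k omega_k = 1,  omega >= 0,  eps >= 0,  xi >= 0.

The printed objective admits a flat ray (raising every ``xi_i`` and
``eps`` together by the same amount leaves it unchanged), so the optimum
is non-unique; the epsilon coefficient is shrunk by ``1e-6`` to break the
tie toward the smallest slack/margin pair, making the solution
deterministic without materially changing the optimum.  ``eps`` is
bounded above by the largest total residual, which keeps the LP bounded.

The LP is always feasible (uniform weights, zero margin, large slacks),
so solver failure is reported as an error rather than as infeasibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from figcat.sparse_model import ResidualProfile

EPS_TIEBREAK = 1e-6


@dataclass
class WeightSolution:
    """Solution of the feature-weighting LP."""

    omega: np.ndarray  # K, on the probability simplex
    epsilon: float  # margin >= 0
    xi: np.ndarray  # N, slacks >= 0
    labels: np.ndarray  # N, class indices used
    objective: float  # solver-reported optimum

    def recompute_objective(self) -> float:
        return float(self.xi.mean() - (1.0 - EPS_TIEBREAK) * self.epsilon)

    def max_constraint_violation(self, R: np.ndarray) -> float:
        """Largest violation of the margin constraints (<= 0 when feasible)."""
        worst = 0.0
        N, C, _ = R.shape
        for i in range(N):
            si = int(self.labels[i])
            own = float(R[i, si] @ self.omega)
            for j in range(C):
                if j == si:
                    continue
                lhs = own - self.xi[i] - (float(R[i, j] @ self.omega) - self.epsilon)
                worst = max(worst, lhs)
        return worst


def fit_weights(
    profile: ResidualProfile | np.ndarray, labels: np.ndarray
) -> WeightSolution:
    """Solve the feature-weighting LP for a residual profile.

    Parameters
    ----------
    profile:
        ``N x C x K`` residual array (or a :class:`ResidualProfile`).
    labels:
        length-``N`` integer class indices into the profile's class axis.
    """
    R = profile.R if isinstance(profile, ResidualProfile) else np.asarray(profile)
    R = np.asarray(R, dtype=np.float64)
    if R.ndim != 3:
        raise ValueError("residual profile must be N x C x K")
    N, C, K = R.shape
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (N,):
        raise ValueError("labels length must match the number of samples")
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= C:
        raise ValueError(f"labels must lie in [0, {C})")

    # variables z = [omega (K), xi (N), eps (1)]
    n_var = K + N + 1
    cost = np.zeros(n_var)
    cost[K : K + N] = 1.0 / N
    cost[-1] = -(1.0 - EPS_TIEBREAK)

    rows, b_ub = [], []
    for i in range(N):
        si = int(labels[i])
        diff_own = R[i, si]
        for j in range(C):
            if j == si:
                continue
            row = np.zeros(n_var)
            row[:K] = diff_own - R[i, j]
            row[K + i] = -1.0
            row[-1] = 1.0
            rows.append(row)
            b_ub.append(0.0)
    A_ub = np.array(rows) if rows else None
    b_ub = np.array(b_ub) if rows else None

    A_eq = np.zeros((1, n_var))
    A_eq[0, :K] = 1.0
    b_eq = np.array([1.0])

    eps_cap = float(R.sum(axis=2).max(initial=0.0))
    bounds = [(0, None)] * (K + N) + [(0, eps_cap)]

    res = linprog(
        cost,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"LP solver failed: {res.message}")
    z = res.x
    return WeightSolution(
        omega=np.maximum(z[:K], 0.0),
        epsilon=float(max(z[-1], 0.0)),
        xi=np.maximum(z[K : K + N], 0.0),
        labels=labels,
        objective=float(res.fun),
    )
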