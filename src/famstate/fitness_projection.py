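"""Age x state projection matrices and dominant-eigenvalue fitness.

The wild-type life history is projected over 21 stages: age classes 1-7
crossed with the three living nonbreeder states (with parents, with
siblings, independent/nonbreeder). A bird in stage ``(a, s)`` contributes

* ``phi_s(a) * psi_{s->s'}(a)`` to stage ``(min(a+1, 7), s')`` for each
  living nonbreeder destination ``s'``, and
* a fecundity of ``phi_s(a) * psi_{s->breeder}(a)`` into stage
  ``(age 1, with parents)``: breeding contributes exactly one recruit, and
  breeders are lost to population growth afterwards (they appear nowhere as
  a stage), reflecting the extreme rarity of repeat breeding.

The dominant eigenvalue (spectral radius) of this matrix is a relative
fitness proxy — it assumes clutch size and fledging success are independent
of parental age — computed per posterior draw so that fitness itself gets a
posterior distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import N_AGE_CLASSES
from .multistate_model import PosteriorDraws, ProbabilityTables

__all__ = [
    "N_STAGES",
    "STAGE_STATES",
    "FitnessPosterior",
    "stage_index",
    "build_projection_matrix",
    "dominant_eigenvalue",
    "lambda_per_draw",
    "wildtype_fitness",
]

#: Living nonbreeder states that form the stage space, in storage order.
STAGE_STATES = (1, 2, 3)

N_STAGES = N_AGE_CLASSES * len(STAGE_STATES)

#: Stage receiving recruits: age 1, with parents.
_RECRUIT_STAGE = 0


def stage_index(age: int, state: int) -> int:
    """Row/column index of stage ``(age class, state)``; state in {1, 2, 3}."""
    if not 1 <= age <= N_AGE_CLASSES:
        raise ValueError(f"age class must be in 1..{N_AGE_CLASSES}")
    if state not in STAGE_STATES:
        raise ValueError("stage states are 1 (parents), 2 (siblings), 3 (independent/nonbreeder)")
    return (age - 1) * len(STAGE_STATES) + STAGE_STATES.index(state)


def build_projection_matrix(tables: ProbabilityTables, strategy=None) -> np.ndarray:
    """Projection matrix ``A`` with ``n_{t+1} = A @ n_t`` from one draw's tables.

    If ``strategy`` (a :class:`~famstate.strategy_costbenefit.StrategySpec`)
    is given, the observed transitions are replaced by the forced
    stay/leave schedule (survival and breeding-from-independence stay at
    their observed values).
    """
    if strategy is not None:
        from .strategy_costbenefit import forced_transition_tables

        tables = forced_transition_tables(tables, strategy)
    phi, psi = tables.phi, tables.psi
    rowsums = psi[:3].sum(axis=2)
    if np.any(rowsums > 1.0 + 1e-9):
        raise ValueError("transition table row sums exceed 1")
    A = np.zeros((N_STAGES, N_STAGES))
    for s in STAGE_STATES:
        for a in range(1, N_AGE_CLASSES + 1):
            if s != 1 and a == 1:
                continue  # unreachable: every bird is with parents at age 1
            col = stage_index(a, s)
            surv = phi[s - 1, a - 1]
            nxt = min(a + 1, N_AGE_CLASSES)
            for s2 in STAGE_STATES:
                w = surv * psi[s - 1, a - 1, s2 - 1]
                if w > 0.0:
                    A[stage_index(nxt, s2), col] += w
            A[_RECRUIT_STAGE, col] += surv * psi[s - 1, a - 1, 3]  # fecundity of 1 per breeder
    # Restrict to stages reachable from recruitment. Stages no bird can ever
    # occupy (e.g. the with-parents chain after a forced early departure, or
    # the age-1 sibling/independent stages) must not contribute spurious
    # cycles to the spectral radius.
    reachable = np.zeros(N_STAGES, dtype=bool)
    stack = [_RECRUIT_STAGE]
    reachable[_RECRUIT_STAGE] = True
    while stack:
        j = stack.pop()
        for i in np.nonzero(A[:, j])[0]:
            if not reachable[i]:
                reachable[i] = True
                stack.append(i)
    A[:, ~reachable] = 0.0
    return A


def dominant_eigenvalue(M: np.ndarray, tol: float = 5e-15, max_iter: int = 100_000) -> float:
    """Spectral radius of a nonnegative square matrix.

    Power iteration on the shifted matrix ``M + I`` (the shift makes the
    Perron root strictly dominant in modulus for nonnegative matrices, so
    periodic chains such as Leslie two-cycles still converge); falls back to
    a dense eigensolve in the rare non-convergent case.
    """
    M = np.asarray(M, float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"matrix must be square, got shape {M.shape}")
    if np.any(M < 0):
        raise ValueError("projection matrices must be nonnegative")
    n = M.shape[0]
    if n == 0:
        return 0.0
    v = np.full(n, 1.0 / np.sqrt(n))
    lam = 0.0
    streak = 0
    for _ in range(max_iter):
        w = M @ v + v  # (M + I) v
        nrm = np.linalg.norm(w)
        if nrm == 0.0:
            return 0.0
        w /= nrm
        new_lam = float(w @ (M @ w))
        # linear convergence: require several consecutive near-stationary
        # Rayleigh quotients so a slowly contracting ratio cannot stop early
        if abs(new_lam - lam) < tol * max(1.0, abs(new_lam)):
            streak += 1
            if streak >= 4:
                return max(new_lam, 0.0)
        else:
            streak = 0
        lam, v = new_lam, w
    return float(np.max(np.abs(np.linalg.eigvals(M))))


@dataclass(frozen=True)
class FitnessPosterior:
    """Posterior distribution of a dominant-eigenvalue fitness proxy."""

    lambdas: np.ndarray
    mean: float
    lo95: float
    hi95: float

    @classmethod
    def from_lambdas(cls, lambdas: np.ndarray) -> "FitnessPosterior":
        lam = np.asarray(lambdas, float)
        return cls(
            lambdas=lam,
            mean=float(lam.mean()),
            lo95=float(np.quantile(lam, 0.025)),
            hi95=float(np.quantile(lam, 0.975)),
        )

    @property
    def n_draws(self) -> int:
        return self.lambdas.size


def lambda_per_draw(draws: PosteriorDraws, strategy=None) -> np.ndarray:
    """Dominant eigenvalue of the projection matrix for every posterior draw."""
    out = np.empty(draws.n_draws)
    for i in range(draws.n_draws):
        out[i] = dominant_eigenvalue(build_projection_matrix(draws.tables(i), strategy))
    return out


def wildtype_fitness(draws: PosteriorDraws) -> FitnessPosterior:
    """Posterior of wild-type fitness: lambda_wt per draw, with mean and 95 % CRI."""
    return FitnessPosterior.from_lambdas(lambda_per_draw(draws))
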