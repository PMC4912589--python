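"""Stay/leave cost-benefit simulation over forced family-departure strategies.

Each strategy forces the family phase of the life history: stay with parents
through age ``p`` (departure on the transition out of age ``p``), then with
siblings for ``s`` further years, then enter independence — all with
probability 1 — while survival and the observed age-specific probability of
breeding from independence are kept at their posterior values. The fitness
of a strategy is the dominant eigenvalue ``lambda_s`` of the projection
matrix built from the forced transitions, computed per posterior draw, and
compared with wild-type fitness through the per-draw difference

    omega = lambda_wt - lambda_s.

``P`` is the proportion of omega draws strictly below zero (ties count as
not-below); a strategy is credibly different from the wild type when
P < 0.05 or P > 0.95. P near 0 means the forced strategy is credibly worse
than the wild type.

By default the forced family phases cannot breed directly (birds route
through independence first); set ``allow_sibling_breeding=True`` to retain
the observed sibling-to-breeder shortcut during the forced sibling phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import N_AGE_CLASSES, STATE_LABELS
from .fitness_projection import FitnessPosterior, build_projection_matrix, dominant_eigenvalue
from .multistate_model import PosteriorDraws, ProbabilityTables, transition_ages
from .synthetic_data import ALLOWED_MOVES

__all__ = [
    "StrategySpec",
    "OmegaResult",
    "forced_transition_tables",
    "strategy_fitness",
    "fitness_difference",
    "default_strategies",
    "strategy_grid",
    "monitor_draw_correlations",
]


@dataclass(frozen=True)
class StrategySpec:
    """Forced family schedule: leave parents after age ``leave_parents_age``,
    then spend ``sibling_years`` years with siblings before independence.

    ``sibling_years = 0`` means going straight to independent/nonbreeder.
    Sibling years that would run past age class 7 saturate there: the bird
    keeps sibling-state survival in the 7+ class and never reaches
    independence (a degenerate never-breeding strategy).
    """

    leave_parents_age: int
    sibling_years: int = 0
    allow_sibling_breeding: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.leave_parents_age <= N_AGE_CLASSES:
            raise ValueError(f"leave_parents_age must be in 1..{N_AGE_CLASSES}")
        if self.sibling_years < 0:
            raise ValueError("sibling_years must be >= 0")

    @property
    def leave_siblings_age(self) -> int:
        return self.leave_parents_age + self.sibling_years

    def label(self) -> str:
        return f"p{self.leave_parents_age}s{self.sibling_years}"


def forced_transition_tables(tables: ProbabilityTables, strategy: StrategySpec) -> ProbabilityTables:
    """Replace observed transitions with the forced stay/leave schedule.

    With-parents rows: remain with probability 1 below the departure age,
    then move (probability 1) to the sibling state if ``sibling_years > 0``,
    else directly to independent/nonbreeder. Sibling rows: remain until the
    forced sibling departure, then move to independence. The
    independent/nonbreeder rows keep the observed age-specific breeding
    probability. Survival is untouched. Every row still sums to 1
    (unreachable ages get a deterministic "remain" row).
    """
    p_age = strategy.leave_parents_age
    s_years = strategy.sibling_years
    leave_sib = strategy.leave_siblings_age
    psi = np.zeros_like(tables.psi)
    # from with-parents
    for a in range(1, N_AGE_CLASSES + 1):
        if a < p_age:
            psi[0, a - 1, 0] = 1.0
        elif a == p_age:
            psi[0, a - 1, 1 if s_years > 0 else 2] = 1.0
        else:  # unreachable
            psi[0, a - 1, 0] = 1.0
    # from with-siblings (occupied at ages p_age+1 .. p_age+s_years)
    for a in range(1, N_AGE_CLASSES + 1):
        if a < leave_sib or (leave_sib > N_AGE_CLASSES and a == N_AGE_CLASSES):
            # forced stay (saturating in class 7 when the schedule overruns it)
            if strategy.allow_sibling_breeding and a >= 2:
                to_b = tables.psi[1, a - 1, 3]
                psi[1, a - 1, 1] = 1.0 - to_b
                psi[1, a - 1, 3] = to_b
            else:
                psi[1, a - 1, 1] = 1.0
        else:
            psi[1, a - 1, 2] = 1.0
    # from independent/nonbreeder: observed breeding probability retained
    psi[2] = tables.psi[2]
    psi[3, :, 3] = 1.0
    return ProbabilityTables(phi=tables.phi.copy(), psi=psi, p=tables.p.copy())


def strategy_fitness(draws: PosteriorDraws, strategy: StrategySpec) -> FitnessPosterior:
    """Posterior of ``lambda_s`` for one forced strategy."""
    lams = np.empty(draws.n_draws)
    for i in range(draws.n_draws):
        lams[i] = dominant_eigenvalue(build_projection_matrix(draws.tables(i), strategy))
    return FitnessPosterior.from_lambdas(lams)


@dataclass(frozen=True)
class OmegaResult:
    """Fitness difference omega = lambda_wt - lambda_s for one strategy."""

    strategy: StrategySpec
    omegas: np.ndarray
    mean: float
    lo95: float
    hi95: float
    p_below_zero: float
    credible: bool


def fitness_difference(
    wildtype: FitnessPosterior, simulated: FitnessPosterior, strategy: StrategySpec
) -> OmegaResult:
    """Per-draw omega with its 95 % CRI and below-zero tail probability.

    The two posteriors must be aligned draw-for-draw (same posterior draw
    indices), so omega reflects within-draw parameter correlations.
    """
    if wildtype.n_draws != simulated.n_draws:
        raise ValueError(
            f"misaligned posteriors: {wildtype.n_draws} wild-type vs {simulated.n_draws} strategy draws"
        )
    omega = wildtype.lambdas - simulated.lambdas
    p = float(np.mean(omega < 0.0))
    return OmegaResult(
        strategy=strategy,
        omegas=omega,
        mean=float(omega.mean()),
        lo95=float(np.quantile(omega, 0.025)),
        hi95=float(np.quantile(omega, 0.975)),
        p_below_zero=p,
        credible=bool(p < 0.05 or p > 0.95),
    )


def default_strategies(allow_sibling_breeding: bool = False) -> list[StrategySpec]:
    """The full non-degenerate grid: leave parents at age p = 1..7 and spend
    s = 0..7-p years with siblings (so independence is reached by class 7)."""
    return [
        StrategySpec(p, s, allow_sibling_breeding)
        for p in range(1, N_AGE_CLASSES + 1)
        for s in range(0, N_AGE_CLASSES - p + 1)
    ]


def strategy_grid(
    draws: PosteriorDraws,
    strategies: list[StrategySpec] | None = None,
    wildtype: FitnessPosterior | None = None,
) -> pd.DataFrame:
    """Omega summaries for every strategy, ordered by (p, s).

    Returns a table with one row per strategy plus a leading ``wildtype``
    reference row (lambda summary, omega fields empty).
    """
    from .fitness_projection import wildtype_fitness

    if strategies is None:
        strategies = default_strategies()
    if wildtype is None:
        wildtype = wildtype_fitness(draws)
    rows = [
        {
            "strategy": "wildtype",
            "leave_parents_age": np.nan,
            "sibling_years": np.nan,
            "lambda_mean": wildtype.mean,
            "lambda_lo95": wildtype.lo95,
            "lambda_hi95": wildtype.hi95,
            "omega_mean": np.nan,
            "omega_lo95": np.nan,
            "omega_hi95": np.nan,
            "P": np.nan,
            "credible": pd.NA,
        }
    ]
    for spec in sorted(strategies, key=lambda t: (t.leave_parents_age, t.sibling_years)):
        fit = strategy_fitness(draws, spec)
        res = fitness_difference(wildtype, fit, spec)
        rows.append(
            {
                "strategy": spec.label(),
                "leave_parents_age": spec.leave_parents_age,
                "sibling_years": spec.sibling_years,
                "lambda_mean": fit.mean,
                "lambda_lo95": fit.lo95,
                "lambda_hi95": fit.hi95,
                "omega_mean": res.mean,
                "omega_lo95": res.lo95,
                "omega_hi95": res.hi95,
                "P": res.p_below_zero,
                "credible": res.credible,
            }
        )
    return pd.DataFrame(rows)


def monitor_draw_correlations(draws: PosteriorDraws, threshold: float = 0.9) -> pd.DataFrame:
    """Posterior correlations between transition probabilities at consecutive
    ages within each from-state, flagging |r| > ``threshold``.

    Strong negative correlations between neighbouring ages would indicate
    that the cost-benefit comparisons are driven by estimation trade-offs
    rather than data. Survival is excluded: its age-linear form makes
    consecutive ages correlated by construction.
    """
    derived = draws.derived()
    rows = []
    for s in (1, 2, 3):
        ages = transition_ages(s)
        for d in ALLOWED_MOVES[s]:
            for a1, a2 in zip(ages, ages[1:]):
                c1 = f"psi[{STATE_LABELS[s]}->{STATE_LABELS[d]},a{a1}]"
                c2 = f"psi[{STATE_LABELS[s]}->{STATE_LABELS[d]},a{a2}]"
                if c1 not in derived or c2 not in derived:
                    continue
                x, y = derived[c1].to_numpy(), derived[c2].to_numpy()
                if x.std() == 0.0 or y.std() == 0.0:
                    r = 0.0
                else:
                    r = float(np.corrcoef(x, y)[0, 1])
                rows.append(
                    {
                        "from_state": STATE_LABELS[s],
                        "destination": STATE_LABELS[d],
                        "age_pair": f"a{a1}-a{a2}",
                        "r": r,
                        "flagged": bool(abs(r) > threshold),
                    }
                )
    return pd.DataFrame(rows)
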