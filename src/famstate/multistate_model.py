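"""Bayesian multistate Cormack-Jolly-Seber model for family-association states.

Model
-----
Marked geese move among four observable states — with parents (P), with
siblings (S), independent/nonbreeder (INB), independent/breeder (IB) — plus
an absorbing latent dead state. Conditional on first capture (every bird is
seen with parents at age 1):

* survival: ``logit(phi_s(a)) = alpha_s + beta_s * a`` — a linear age trend
  per state over age classes 1..7 (7 pools all older ages);
* transitions: forward-only multinomial logits with full age specificity
  (with-parents transitions estimable from age 1, sibling and independent
  transitions from age 2; IB is absorbing). The last allowed destination is
  the reference category, recovered as one minus the sum of the others;
* detection: state-specific resighting probabilities ``p_s``.

Priors are Normal(0, prior_sd) on all logit-scale coefficients (default
sd = 31.62, i.e. variance 1000 — effectively flat) and Uniform(0, 1) on each
``p_s``.

The likelihood marginalizes the latent state sequence with the hidden-Markov
forward algorithm (numba-compiled, with identical histories pooled), and the
posterior is sampled by adaptive random-walk Metropolis in parameter blocks
(survival | transitions per from-state | detection), targeting roughly 30 %
acceptance. Sampling is deterministic given the seed.

An ``age_constant`` model variant shares each transition multinomial across
ages (survival keeps its age trend).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._likelihood import forward_one, total_loglik
from .core_io import N_AGE_CLASSES, STATE_LABELS, CaptureHistory
from .synthetic_data import ALLOWED_MOVES, FIRST_TRANSITION_AGE, TruthParams

__all__ = [
    "PriorConfig",
    "McmcConfig",
    "ParamLayout",
    "ProbabilityTables",
    "PosteriorDraws",
    "CredibleDifference",
    "transition_row",
    "survival_prob",
    "forward_loglik",
    "log_prior",
    "sample_posterior",
    "gelman_rubin",
    "psrf",
    "summarize_posterior",
    "credible_difference",
    "tables_from_truth",
]

_SQRT1000 = math.sqrt(1000.0)

#: Destination order per from-state; the last entry is the multinomial-logit
#: reference category (recovered as 1 - sum of the others).
_DEST_ORDER = {1: (1, 2, 3, 4), 2: (2, 3, 4), 3: (3, 4)}


@dataclass(frozen=True)
class PriorConfig:
    """Priors: Normal(0, prior_sd) coefficients, Uniform(0,1) detection."""

    prior_sd: float = _SQRT1000


@dataclass(frozen=True)
class McmcConfig:
    """MCMC protocol.

    Defaults follow the full analysis protocol (3 chains of 450,000
    iterations after a 90,000 burn-in, thinned by 10); pass smaller values
    for desk-scale runs.
    """

    n_chains: int = 3
    n_iterations: int = 450_000
    n_burnin: int = 90_000
    thin: int = 10
    seed: int = 0
    target_accept: float = 0.30
    init_attempts: int = 100

    def __post_init__(self) -> None:
        if self.n_iterations <= self.n_burnin:
            raise ValueError("n_iterations must exceed n_burnin")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


# ---------------------------------------------------------------------------
# Parameter layout
# ---------------------------------------------------------------------------

class ParamLayout:
    """Index bookkeeping for the unconstrained parameter vector.

    Order: survival intercepts ``alpha_s`` (4), survival slopes ``beta_s``
    (4), multinomial-logit transition coefficients ``eta`` grouped by
    from-state then age then destination, detection probabilities ``p_s``
    (4, stored on the probability scale with a uniform prior).
    """

    def __init__(self, variant: str = "age_specific"):
        if variant not in ("age_specific", "age_constant"):
            raise ValueError(f"unknown model variant {variant!r}")
        self.variant = variant
        names: list[str] = []
        for kind in ("alpha", "beta"):
            names += [f"{kind}[{STATE_LABELS[s]}]" for s in (1, 2, 3, 4)]
        self._eta_slices: dict[int, tuple[int, int]] = {}
        for s in (1, 2, 3):
            dests = _DEST_ORDER[s][:-1]  # free (non-reference) destinations
            ages = self.eta_ages(s)
            start = len(names)
            for a in ages:
                tag = f"a{a}" if variant == "age_specific" else "all"
                names += [f"eta[{STATE_LABELS[s]},{tag},{STATE_LABELS[d]}]" for d in dests]
            self._eta_slices[s] = (start, len(names))
        self._p_start = len(names)
        names += [f"p[{STATE_LABELS[s]}]" for s in (1, 2, 3, 4)]
        self.names = names
        self.n_params = len(names)

    def eta_ages(self, s: int) -> tuple[int, ...]:
        if self.variant == "age_constant":
            return (FIRST_TRANSITION_AGE[s],)
        return tuple(range(FIRST_TRANSITION_AGE[s], N_AGE_CLASSES + 1))

    @property
    def coef_indices(self) -> np.ndarray:
        """Indices with a Normal prior (everything except detection)."""
        return np.arange(0, self._p_start)

    @property
    def p_indices(self) -> np.ndarray:
        return np.arange(self._p_start, self.n_params)

    def blocks(self) -> dict[str, np.ndarray]:
        """Metropolis update blocks: survival, transitions per from-state, detection."""
        out = {"survival": np.arange(0, 8)}
        for s in (1, 2, 3):
            lo, hi = self._eta_slices[s]
            out[f"trans_{STATE_LABELS[s]}"] = np.arange(lo, hi)
        out["detection"] = self.p_indices
        return out

    def eta_matrix(self, theta: np.ndarray, s: int) -> np.ndarray:
        """``(n_ages, k-1)`` eta coefficients for from-state ``s``."""
        lo, hi = self._eta_slices[s]
        k1 = len(_DEST_ORDER[s]) - 1
        return theta[lo:hi].reshape(-1, k1)

    # -- transform to probability tables --------------------------------
    def tables(self, theta: np.ndarray) -> "ProbabilityTables":
        theta = np.asarray(theta, float)
        ages = np.arange(1, N_AGE_CLASSES + 1)
        alpha, beta = theta[0:4], theta[4:8]
        phi = expit(alpha[:, None] + beta[:, None] * ages[None, :])
        psi = np.zeros((4, N_AGE_CLASSES, 4))
        for s in (1, 2, 3):
            eta = self.eta_matrix(theta, s)
            first = FIRST_TRANSITION_AGE[s]
            n_ages = N_AGE_CLASSES - first + 1
            if self.variant == "age_constant":
                eta = np.repeat(eta, n_ages, axis=0)
            rows = _softmax_rows(eta)
            for j, d in enumerate(_DEST_ORDER[s]):
                psi[s - 1, first - 1:, d - 1] = rows[:, j]
        # unreachable age-1 rows for S and INB: park mass on "stay"
        psi[1, 0, 1] = 1.0
        psi[2, 0, 2] = 1.0
        psi[3, :, 3] = 1.0  # breeder absorbing
        p = theta[self._p_start:]
        return ProbabilityTables(phi=phi, psi=psi, p=p.copy())


def _softmax_rows(eta: np.ndarray) -> np.ndarray:
    """Row-wise back-transformation with an implicit 0 for the reference.

    Returns ``(n, k)`` probabilities where the first ``k-1`` columns are
    ``exp(eta_i) / (1 + sum_j exp(eta_j))`` and the final column is one
    minus the sum of the others.
    """
    eta = np.atleast_2d(np.asarray(eta, float))
    m = np.maximum(eta.max(axis=1, keepdims=True), 0.0)
    ex = np.exp(eta - m)
    denom = np.exp(-m) + ex.sum(axis=1, keepdims=True)
    free = ex / denom
    last = 1.0 - free.sum(axis=1, keepdims=True)
    np.clip(last, 0.0, None, out=last)
    return np.hstack([free, last])


def transition_row(eta: Sequence[float]) -> np.ndarray:
    """Back-transform ``k-1`` multinomial-logit coefficients to ``k`` probabilities.

    ``psi_i = exp(eta_i) / (1 + sum_j exp(eta_j))`` for the parameterized
    destinations; the final (reference) destination is ``1 - sum(psi_i)``.
    Guarded against overflow; never returns negative mass.
    """
    return _softmax_rows(np.asarray(eta, float))[0]


def survival_prob(alpha_s: float, beta_s: float, age: int) -> float:
    """Survival probability ``inverse-logit(alpha_s + beta_s * age)``."""
    if not 1 <= age <= N_AGE_CLASSES:
        raise ValueError(f"age class must be in 1..{N_AGE_CLASSES}, got {age}")
    return float(expit(alpha_s + beta_s * age))


# ---------------------------------------------------------------------------
# Probability tables and likelihood
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbabilityTables:
    """Per-draw probability tables: ``phi`` (4x7), ``psi`` (4x7x4), ``p`` (4,)."""

    phi: np.ndarray
    psi: np.ndarray
    p: np.ndarray

    def transition_stack(self) -> np.ndarray:
        """``(7, 5, 5)`` combined survival+transition matrices over {1..4, dead}."""
        trans = np.zeros((N_AGE_CLASSES, 5, 5))
        trans[:, :4, :4] = self.phi.T[:, :, None] * self.psi.transpose(1, 0, 2)
        trans[:, :4, 4] = 1.0 - self.phi.T
        trans[:, 4, 4] = 1.0
        return trans


def tables_from_truth(truth: TruthParams) -> ProbabilityTables:
    """Probability tables of a generating :class:`TruthParams`."""
    return ProbabilityTables(phi=truth.phi_table(), psi=truth.psi.copy(), p=truth.detection.copy())


class _PatternData:
    """Deduplicated observation patterns (from marking onward) with counts."""

    def __init__(self, histories: Iterable[CaptureHistory]):
        counts: dict[tuple[int, ...], int] = {}
        for h in histories:
            key = h.observations_from_marking()
            counts[key] = counts.get(key, 0) + 1
        if not counts:
            raise ValueError("need at least one capture history")
        keys = sorted(counts)
        max_len = max(len(k) for k in keys)
        self.patterns = np.zeros((len(keys), max_len), dtype=np.int64)
        self.lengths = np.array([len(k) for k in keys], dtype=np.int64)
        self.counts = np.array([counts[k] for k in keys], dtype=np.float64)
        for i, k in enumerate(keys):
            self.patterns[i, : len(k)] = k
        self.n_individuals = int(self.counts.sum())

    def loglik(self, tables: ProbabilityTables) -> float:
        return float(
            total_loglik(self.patterns, self.lengths, self.counts, tables.transition_stack(), tables.p)
        )


def forward_loglik(
    history: CaptureHistory,
    params: ProbabilityTables | np.ndarray,
    layout: ParamLayout | None = None,
) -> float:
    """Log-likelihood contribution of one history, conditional on first capture.

    ``params`` may be a :class:`ProbabilityTables` or an unconstrained
    parameter vector together with its :class:`ParamLayout`. Observation
    sequences inconsistent with the forward-only state graph return
    ``-inf`` with a warning naming the individual.
    """
    if isinstance(params, ProbabilityTables):
        tables = params
    else:
        if layout is None:
            raise TypeError("a ParamLayout is required when params is a raw vector")
        tables = layout.tables(np.asarray(params, float))
    obs = np.asarray(history.observations_from_marking(), dtype=np.int64)
    ll = float(forward_one(obs, len(obs), tables.transition_stack(), tables.p))
    if ll == -np.inf:
        warnings.warn(
            f"history {history.individual_id!r} has zero probability under the model "
            "(observation sequence inconsistent with the state graph or parameters)",
            stacklevel=2,
        )
    return ll


def log_prior(theta: np.ndarray, layout: ParamLayout, prior: PriorConfig | None = None) -> float:
    """Log prior density: Normal(0, prior_sd) coefficients, Uniform(0,1) detection."""
    prior = prior or PriorConfig()
    theta = np.asarray(theta, float)
    p = theta[layout.p_indices]
    if np.any(p < 0.0) or np.any(p > 1.0):
        return -np.inf
    coefs = theta[layout.coef_indices]
    sd = prior.prior_sd
    return float(-0.5 * np.sum((coefs / sd) ** 2) - coefs.size * math.log(sd * math.sqrt(2.0 * math.pi)))


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Post-burn-in, thinned MCMC draws from all chains.

    ``params`` is ``(n_draws, n_params)`` on the unconstrained scale;
    ``chain`` and ``iteration`` tag each row. Derived probability tables
    are computed on demand and cached.
    """

    params: np.ndarray
    chain: np.ndarray
    iteration: np.ndarray
    layout: ParamLayout
    _tables_cache: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_draws(self) -> int:
        return self.params.shape[0]

    @property
    def n_chains(self) -> int:
        return len(np.unique(self.chain))

    def tables_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Stacked derived tables: phi ``(n,4,7)``, psi ``(n,4,7,4)``, p ``(n,4)``."""
        if self._tables_cache is None:
            phi = np.empty((self.n_draws, 4, N_AGE_CLASSES))
            psi = np.empty((self.n_draws, 4, N_AGE_CLASSES, 4))
            p = np.empty((self.n_draws, 4))
            for i in range(self.n_draws):
                t = self.layout.tables(self.params[i])
                phi[i], psi[i], p[i] = t.phi, t.psi, t.p
            self._tables_cache = (phi, psi, p)
        return self._tables_cache

    def tables(self, i: int) -> ProbabilityTables:
        """Probability tables of draw ``i``."""
        phi, psi, p = self.tables_arrays()
        return ProbabilityTables(phi=phi[i], psi=psi[i], p=p[i])

    # -- derived scalar parameters --------------------------------------
    def derived(self) -> pd.DataFrame:
        """Draws of every estimable derived probability, one column each.

        Columns: ``phi[s,aA]`` for estimable (state, age), ``psi[s->s2,aA]``
        for every allowed move and estimable age, and ``p[s]``.
        """
        phi, psi, p = self.tables_arrays()
        cols: dict[str, np.ndarray] = {}
        for s in (1, 2, 3, 4):
            first = 1 if s == 1 else 2
            for a in range(first, N_AGE_CLASSES + 1):
                cols[f"phi[{STATE_LABELS[s]},a{a}]"] = phi[:, s - 1, a - 1]
        for s in (1, 2, 3):
            for a in transition_ages(s):
                for d in _DEST_ORDER[s]:
                    cols[f"psi[{STATE_LABELS[s]}->{STATE_LABELS[d]},a{a}]"] = psi[:, s - 1, a - 1, d - 1]
        for s in (1, 2, 3, 4):
            cols[f"p[{STATE_LABELS[s]}]"] = p[:, s - 1]
        return pd.DataFrame(cols)

    def raw_frame(self) -> pd.DataFrame:
        """Long-format raw draws (chain, iteration, parameter, value)."""
        wide = pd.DataFrame(self.params, columns=self.layout.names)
        wide.insert(0, "iteration", self.iteration)
        wide.insert(0, "chain", self.chain)
        return wide.melt(id_vars=["chain", "iteration"], var_name="parameter", value_name="value")


def transition_ages(s: int) -> tuple[int, ...]:
    """Estimable transition ages for from-state ``s`` (P from 1, others from 2)."""
    return tuple(range(FIRST_TRANSITION_AGE[s], N_AGE_CLASSES + 1))


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

def sample_posterior(
    histories: Iterable[CaptureHistory],
    mcmc: McmcConfig,
    prior: PriorConfig | None = None,
    variant: str = "age_specific",
    progress: bool = False,
) -> PosteriorDraws:
    """Sample the posterior by adaptive block random-walk Metropolis.

    Blocks (survival coefficients, transition coefficients per from-state,
    detection probabilities) are updated in turn each iteration with
    Gaussian proposals whose scales adapt toward ``target_accept`` during
    burn-in (Robbins-Monro on the log scale) and are frozen afterwards.
    Initial values are drawn Normal(0, 0.1) for coefficients and
    Uniform(0.3, 0.9) for detection, re-drawn up to ``init_attempts`` times
    if the posterior is not finite. Fully deterministic given the seed.
    """
    prior = prior or PriorConfig()
    layout = ParamLayout(variant)
    data = _PatternData(histories)
    blocks = layout.blocks()

    def log_post(theta: np.ndarray) -> float:
        lp = log_prior(theta, layout, prior)
        if lp == -np.inf:
            return -np.inf
        return lp + data.loglik(layout.tables(theta))

    n_keep = (mcmc.n_iterations - mcmc.n_burnin + mcmc.thin - 1) // mcmc.thin
    all_params = np.empty((mcmc.n_chains * n_keep, layout.n_params))
    all_chain = np.empty(mcmc.n_chains * n_keep, dtype=np.int64)
    all_iter = np.empty(mcmc.n_chains * n_keep, dtype=np.int64)

    for c in range(mcmc.n_chains):
        rng = np.random.default_rng([mcmc.seed, c])
        theta = None
        for _ in range(mcmc.init_attempts):
            cand = np.empty(layout.n_params)
            cand[layout.coef_indices] = rng.normal(0.0, 0.1, layout.coef_indices.size)
            cand[layout.p_indices] = rng.uniform(0.3, 0.9, layout.p_indices.size)
            lp = log_post(cand)
            if np.isfinite(lp):
                theta = cand
                break
        if theta is None:
            raise RuntimeError(
                f"chain {c}: could not find a finite-posterior initial value in "
                f"{mcmc.init_attempts} attempts"
            )
        scales = {name: 0.05 for name in blocks}
        row = c * n_keep
        for it in range(mcmc.n_iterations):
            for name, idx in blocks.items():
                prop = theta.copy()
                prop[idx] += rng.normal(0.0, scales[name], idx.size)
                lpp = log_post(prop)
                accept = lpp - lp > math.log(rng.random()) if np.isfinite(lpp) else False
                if accept:
                    theta, lp = prop, lpp
                if it < mcmc.n_burnin:
                    step = min(0.1, (it + 1.0) ** -0.6)
                    scales[name] = float(
                        np.clip(
                            scales[name] * math.exp(step * ((1.0 if accept else 0.0) - mcmc.target_accept)),
                            1e-4,
                            5.0,
                        )
                    )
            if it >= mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thin == 0:
                all_params[row] = theta
                all_chain[row] = c
                all_iter[row] = it
                row += 1
            if progress and (it + 1) % 5000 == 0:
                print(f"chain {c}: iteration {it + 1}/{mcmc.n_iterations}", flush=True)

    return PosteriorDraws(params=all_params, chain=all_chain, iteration=all_iter, layout=layout)


# ---------------------------------------------------------------------------
# Diagnostics and summaries
# ---------------------------------------------------------------------------

def psrf(chains: np.ndarray) -> float:
    """Classic Gelman-Rubin potential scale reduction factor.

    ``chains`` is ``(m, n)``: m chains of n retained draws. Uses the
    original (non-split) formula
    ``sqrt(((n-1)/n * W + B/n) / W)`` with B the between-chain and W the
    within-chain variance.
    """
    chains = np.asarray(chains, float)
    m, n = chains.shape
    if m < 2:
        raise ValueError("PSRF requires at least two chains")
    if n < 10:
        raise ValueError("PSRF requires at least 10 retained draws per chain")
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b_over_n = means.var(ddof=1)
    if w == 0.0:
        return 1.0 if b_over_n == 0.0 else np.inf
    var_hat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_hat / w))


def gelman_rubin(draws: PosteriorDraws, derived: bool = True, threshold: float = 1.1) -> pd.DataFrame:
    """R-hat per scalar parameter, with a flag for values above ``threshold``.

    By default diagnoses the derived probability scales (survival,
    transition and detection probabilities) — the identified quantities —
    rather than raw multinomial-logit coefficients, whose near-flat
    directions in sparse cells are not scientifically meaningful.
    """
    if draws.n_chains < 2:
        raise ValueError("Gelman-Rubin diagnostic requires at least two chains")
    frame = draws.derived() if derived else pd.DataFrame(draws.params, columns=draws.layout.names)
    chain_ids = np.unique(draws.chain)
    n = min((draws.chain == c).sum() for c in chain_ids)
    rows = []
    for col in frame.columns:
        x = np.vstack([frame[col].to_numpy()[draws.chain == c][:n] for c in chain_ids])
        r = psrf(x)
        rows.append({"parameter": col, "rhat": r, "flagged": bool(r > threshold)})
    return pd.DataFrame(rows)


def summarize_posterior(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean and central 95 % credible interval per derived probability."""
    frame = draws.derived()
    return pd.DataFrame(
        {
            "parameter": frame.columns,
            "mean": frame.mean().to_numpy(),
            "lo95": frame.quantile(0.025).to_numpy(),
            "hi95": frame.quantile(0.975).to_numpy(),
        }
    ).reset_index(drop=True)


@dataclass(frozen=True)
class CredibleDifference:
    """Posterior difference A - B with the below-zero tail probability."""

    mean: float
    lo95: float
    hi95: float
    p_below_zero: float
    credible: bool


def credible_difference(draws_a: np.ndarray, draws_b: np.ndarray) -> CredibleDifference:
    """Summary of the per-draw difference A - B.

    ``P`` is the proportion of differences strictly below zero (ties count
    as not-below); the difference is called credible when P < 0.05 or
    P > 0.95.
    """
    a = np.asarray(draws_a, float)
    b = np.asarray(draws_b, float)
    if a.shape != b.shape:
        raise ValueError(f"draw vectors must be aligned; got lengths {a.size} and {b.size}")
    d = a - b
    p = float(np.mean(d < 0.0))
    return CredibleDifference(
        mean=float(d.mean()),
        lo95=float(np.quantile(d, 0.025)),
        hi95=float(np.quantile(d, 0.975)),
        p_below_zero=p,
        credible=bool(p < 0.05 or p > 0.95),
    )
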