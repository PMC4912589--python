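"""Observational summaries of family-association durations and breeding.

Parent-association duration is the number of winters a bird is assigned the
with-parents state, from marking up to the first winter assigned a
different nonzero state. Unseen winters (code 0) flanked by two with-parents
assignments are bridged (counted as with-parents); trailing unseen winters
do not extend a duration. Sibling-association duration is computed the same
way over the with-siblings run following the parent phase. An "ever-breeder"
is any bird observed at least once in the independent/breeder state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .core_io import CaptureHistory

__all__ = ["DurationSummary", "BreedingSummary", "association_durations", "breeding_summary"]


def _durations(history: CaptureHistory) -> tuple[int, int, bool]:
    """(parent_years, sibling_years, ever_breeder) for one history."""
    obs = history.observations_from_marking()
    idx1 = [i for i, o in enumerate(obs) if o == 1]
    idx2 = [i for i, o in enumerate(obs) if o == 2]
    # bridging: 0s between two same-state sightings count as that state, so a
    # run's length is simply last index - first index + 1 (monotone states
    # guarantee no other nonzero code can appear inside the run).
    parent = idx1[-1] - idx1[0] + 1  # idx1 is non-empty: marking observation is state 1
    sibling = (idx2[-1] - idx2[0] + 1) if idx2 else 0
    ever_breeder = any(o == 4 for o in obs)
    return parent, sibling, ever_breeder


@dataclass(frozen=True)
class DurationSummary:
    """Per-individual association durations with histogram and stratified means."""

    per_individual: pd.DataFrame  # id, parent_years, sibling_years, ever_breeder
    parent_histogram: pd.Series
    sibling_histogram: pd.Series

    @property
    def n_individuals(self) -> int:
        return len(self.per_individual)

    def fraction_parent_leq(self, years: int) -> float:
        return float((self.per_individual["parent_years"] <= years).mean())

    def fraction_sibling_leq(self, years: int) -> float:
        """Fraction of sibling associations lasting <= ``years``, among birds
        that associated with a sibling at all."""
        sib = self.per_individual.loc[self.per_individual["sibling_years"] > 0, "sibling_years"]
        return float((sib <= years).mean()) if len(sib) else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_individuals": self.n_individuals,
            "parent_histogram": {int(k): int(v) for k, v in self.parent_histogram.items()},
            "sibling_histogram": {int(k): int(v) for k, v in self.sibling_histogram.items()},
            "fraction_parent_leq_3": self.fraction_parent_leq(3),
            "fraction_sibling_leq_3": self.fraction_sibling_leq(3),
        }


def association_durations(histories: Iterable[CaptureHistory]) -> DurationSummary:
    """Parent and sibling association durations for each history."""
    rows = [
        {"id": h.individual_id, **dict(zip(("parent_years", "sibling_years", "ever_breeder"), _durations(h)))}
        for h in histories
    ]
    frame = pd.DataFrame(rows, columns=["id", "parent_years", "sibling_years", "ever_breeder"])
    parent_hist = frame["parent_years"].value_counts().sort_index() if len(frame) else pd.Series(dtype=int)
    sib = frame.loc[frame["sibling_years"] > 0, "sibling_years"] if len(frame) else pd.Series(dtype=int)
    sibling_hist = sib.value_counts().sort_index()
    return DurationSummary(per_individual=frame, parent_histogram=parent_hist, sibling_histogram=sibling_hist)


def _mean_se(x: pd.Series) -> tuple[float, float]:
    n = len(x)
    if n == 0:
        return float("nan"), float("nan")
    mean = float(x.mean())
    se = float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return mean, se


@dataclass(frozen=True)
class BreedingSummary:
    """Ever-breeder counts and association durations stratified by breeding."""

    n_individuals: int
    n_breeders: int
    proportion_breeders: float
    parent_mean_breeders: float
    parent_se_breeders: float
    parent_mean_nonbreeders: float
    parent_se_nonbreeders: float
    sibling_mean_breeders: float
    sibling_se_breeders: float
    sibling_mean_nonbreeders: float
    sibling_se_nonbreeders: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def breeding_summary(histories: Iterable[CaptureHistory]) -> BreedingSummary:
    """Counts of ever-breeders and duration means (+-SE) by breeder status."""
    frame = association_durations(histories).per_individual
    n = len(frame)
    breeders = frame[frame["ever_breeder"]]
    nonbreeders = frame[~frame["ever_breeder"]]
    pm_b, ps_b = _mean_se(breeders["parent_years"])
    pm_n, ps_n = _mean_se(nonbreeders["parent_years"])
    sm_b, ss_b = _mean_se(breeders["sibling_years"])
    sm_n, ss_n = _mean_se(nonbreeders["sibling_years"])
    return BreedingSummary(
        n_individuals=n,
        n_breeders=len(breeders),
        proportion_breeders=float(len(breeders) / n) if n else float("nan"),
        parent_mean_breeders=pm_b,
        parent_se_breeders=ps_b,
        parent_mean_nonbreeders=pm_n,
        parent_se_nonbreeders=ps_n,
        sibling_mean_breeders=sm_b,
        sibling_se_breeders=ss_b,
        sibling_mean_nonbreeders=sm_n,
        sibling_se_nonbreeders=ss_n,
    )
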