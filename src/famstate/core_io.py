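"""Domain types and I/O for family-association capture histories.

A capture (encounter) history records, for one individually marked goose,
the observed family-association state in each winter of the study:

====  =========================================
code  meaning
====  =========================================
0     not seen
1     seen, with >=1 parent
2     seen, with >=1 sibling (post-parents)
3     seen, independent / nonbreeder
4     seen, independent / breeder
====  =========================================

Latent (true) states use the same codes 1-4 for living birds plus
``DEAD = 5``; the dead state is never observable (a dead bird is always
recorded 0).

Conventions used throughout the package:

* Occasions are winters indexed by integer calendar year.
* Every bird is marked in its first winter and is, by protocol, seen with at
  least one parent then: the observation at the cohort (marking) year is
  always state 1.
* Age class at year ``t`` for a bird marked (at age 1) in ``cohort_year``
  is ``min(t - cohort_year + 1, 7)``; ages of 7 and above are pooled into a
  single "7+" class.
* Observed nonzero states never decrease over time: birds do not return to
  previous association states (1 -> 2 -> 3 -> 4 ordering of the codes makes
  the "no backward transition" rule a simple monotonicity check).
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "DEAD",
    "N_AGE_CLASSES",
    "OBS_CODES",
    "STATE_LABELS",
    "MODAL_PRECEDENCE",
    "CaptureHistoryError",
    "ParseError",
    "ValidationError",
    "CaptureHistory",
    "StudyConfig",
    "age_class",
    "modal_state",
    "read_capture_histories",
    "write_capture_histories",
    "write_mark_inp",
    "wexford_like_config",
]

#: Observable state codes.
OBS_CODES = (0, 1, 2, 3, 4)

#: Latent-only absorbing death state.
DEAD = 5

#: Pooled terminal age class is 7 ("7+").
N_AGE_CLASSES = 7

#: Short labels for the four observable states, by code.
STATE_LABELS = {1: "P", 2: "S", 3: "INB", 4: "IB"}

#: Tie-break precedence for the within-winter modal state: family states
#: over independent ones, breeder over nonbreeder.
MODAL_PRECEDENCE = (1, 2, 4, 3)


class CaptureHistoryError(Exception):
    """Base class for capture-history problems."""


class ParseError(CaptureHistoryError):
    """A file cell could not be interpreted as a state code."""


class ValidationError(CaptureHistoryError):
    """A history violates a structural invariant."""


def age_class(year: int, cohort_year: int) -> int:
    """Age class (1..7) of a bird marked at age 1 in ``cohort_year``.

    Ages of 7 and above are pooled into class 7.
    """
    if year < cohort_year:
        raise ValueError(f"year {year} precedes cohort year {cohort_year}")
    return min(year - cohort_year + 1, N_AGE_CLASSES)


def modal_state(within_year_observations: Sequence[int]) -> int:
    """Modal state among repeated within-winter sightings of one bird.

    Ties are broken by the fixed precedence 1 > 2 > 4 > 3 (family states
    over independent, breeder over nonbreeder).

    Parameters
    ----------
    within_year_observations
        Non-empty sequence of seen-state codes (1-4). Callers must emit 0
        themselves for winters with no sightings.
    """
    obs = list(within_year_observations)
    if not obs:
        raise ValueError("modal_state requires at least one sighting; emit 0 for unseen winters")
    bad = [o for o in obs if o not in (1, 2, 3, 4)]
    if bad:
        raise ValueError(f"sighting codes must be in 1..4, got {bad}")
    counts = Counter(obs)
    top = max(counts.values())
    candidates = [s for s, c in counts.items() if c == top]
    return min(candidates, key=MODAL_PRECEDENCE.index)


@dataclass(frozen=True)
class CaptureHistory:
    """One individual's encounter history over the full study span.

    ``observations[i]`` is the state code observed in year
    ``start_year + i``; the vector covers every study year so that a
    collection of histories shares a common, fixed-width year axis.
    """

    individual_id: str
    cohort_year: int
    start_year: int
    observations: tuple[int, ...]

    def __post_init__(self) -> None:
        obs = tuple(int(o) for o in self.observations)
        object.__setattr__(self, "observations", obs)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        iid = self.individual_id
        if not self.observations:
            raise ValidationError(f"{iid}: empty observation vector")
        bad = [o for o in self.observations if o not in OBS_CODES]
        if bad:
            raise ValidationError(f"{iid}: observation codes {bad} outside 0..4")
        c = self.cohort_index
        if c < 0 or c >= len(self.observations):
            raise ValidationError(
                f"{iid}: cohort year {self.cohort_year} outside study span "
                f"{self.start_year}..{self.start_year + len(self.observations) - 1}"
            )
        if any(o != 0 for o in self.observations[:c]):
            raise ValidationError(f"{iid}: nonzero observation before cohort year")
        if self.observations[c] != 1:
            raise ValidationError(
                f"{iid}: first observation must be state 1 (seen with parents at age 1), "
                f"got {self.observations[c]}"
            )
        seen = [o for o in self.observations[c:] if o != 0]
        if any(b < a for a, b in zip(seen, seen[1:])):
            raise ValidationError(f"{iid}: return to an earlier state (observed states must be non-decreasing)")

    # -- conveniences --------------------------------------------------
    @property
    def cohort_index(self) -> int:
        return self.cohort_year - self.start_year

    @property
    def n_years(self) -> int:
        return len(self.observations)

    def observations_from_marking(self) -> tuple[int, ...]:
        """Observation codes from the marking year to the end of the study."""
        return self.observations[self.cohort_index:]

    def age_at(self, year: int) -> int:
        return age_class(year, self.cohort_year)


@dataclass(frozen=True)
class StudyConfig:
    """Study design: occasions (winters) and marked cohort sizes.

    ``cohorts`` maps cohort (marking) year to the number of first-winter
    birds marked that year. The span must give the earliest cohort at least
    8 occasions so that the pooled 7+ age class is reachable.
    """

    start_year: int
    n_occasions: int
    cohorts: Mapping[int, int]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_occasions < 8:
            raise ValueError("n_occasions must be >= 8 so age class 7+ is reachable")
        last = self.start_year + self.n_occasions - 1
        for year, n in self.cohorts.items():
            if n < 0:
                raise ValueError(f"cohort {year}: negative size")
            if not (self.start_year <= year <= last):
                raise ValueError(f"cohort year {year} outside study span {self.start_year}..{last}")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.start_year, self.start_year + self.n_occasions))

    @property
    def n_individuals(self) -> int:
        return sum(self.cohorts.values())


def wexford_like_config(seed: int = 0) -> StudyConfig:
    """Study design shaped like the Wexford scheme: 656 first-winter geese
    marked 1983-2003 (none in 2000), resighted through 2009.

    Cohort sizes for 1996, 1997, 1999 and 2003 are the reported ones
    (22, 13, 13, 39); the remaining 569 birds are spread near-evenly over
    the other 16 cohorts, which is a plausible fill, not a reported value.
    """
    years = [y for y in range(1983, 2004) if y != 2000]
    fixed = {1996: 22, 1997: 13, 1999: 13, 2003: 39}
    rest = [y for y in years if y not in fixed]
    remaining = 656 - sum(fixed.values())
    base, extra = divmod(remaining, len(rest))
    cohorts = dict(fixed)
    for i, y in enumerate(sorted(rest)):
        cohorts[y] = base + (1 if i < extra else 0)
    return StudyConfig(start_year=1983, n_occasions=2009 - 1983 + 1, cohorts=cohorts, seed=seed)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_capture_histories(path: str | Path) -> list[CaptureHistory]:
    """Read capture histories from delimited text.

    Expected header: ``id,cohort_year,<year>,<year>,...`` with one column
    per study year holding codes 0-4.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if len(header) < 3 or header[0] != "id" or header[1] != "cohort_year":
            raise ParseError(f"{path}: header must start with 'id,cohort_year' followed by year columns")
        try:
            years = [int(y) for y in header[2:]]
        except ValueError as exc:
            raise ParseError(f"{path}: non-integer year column in header: {exc}") from None
        if years != list(range(years[0], years[0] + len(years))):
            raise ParseError(f"{path}: year columns must be consecutive")
        histories = []
        for rownum, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2 + len(years):
                raise ParseError(f"{path}: row {rownum}: expected {2 + len(years)} fields, got {len(row)}")
            iid = row[0]
            try:
                cohort = int(row[1])
            except ValueError:
                raise ParseError(f"{path}: row {rownum}: cohort_year {row[1]!r} is not an integer") from None
            obs = []
            for colnum, cell in enumerate(row[2:], start=3):
                try:
                    code = int(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}: row {rownum}, column {colnum}: {cell!r} is not a state code"
                    ) from None
                if code not in OBS_CODES:
                    raise ParseError(
                        f"{path}: row {rownum}, column {colnum}: state code {code} outside 0..4"
                    )
                obs.append(code)
            histories.append(
                CaptureHistory(
                    individual_id=iid,
                    cohort_year=cohort,
                    start_year=years[0],
                    observations=tuple(obs),
                )
            )
    return histories


def write_capture_histories(histories: Iterable[CaptureHistory], path: str | Path) -> None:
    """Write histories to the capture-history CSV format.

    All histories are laid out on a common year axis (the union of their
    spans); observations outside an individual's own span are 0, so
    ``read(write(h)) == h`` whenever the inputs already share one span.
    """
    histories = list(histories)
    path = Path(path)
    if not histories:
        with path.open("w", newline="") as fh:
            csv.writer(fh).writerow(["id", "cohort_year"])
        return
    start = min(h.start_year for h in histories)
    end = max(h.start_year + h.n_years - 1 for h in histories)
    years = list(range(start, end + 1))
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "cohort_year", *years])
        for h in histories:
            row = [0] * len(years)
            off = h.start_year - start
            for i, o in enumerate(h.observations):
                row[off + i] = o
            writer.writerow([h.individual_id, h.cohort_year, *row])


def write_mark_inp(histories: Iterable[CaptureHistory], path: str | Path) -> None:
    """Export histories as a MARK-style ``.inp`` file for external cross-checks.

    Each line is the concatenated state codes over the common year axis
    followed by a frequency of 1, e.g. ``11304000 1;``.
    """
    histories = list(histories)
    path = Path(path)
    if not histories:
        path.write_text("")
        return
    start = min(h.start_year for h in histories)
    end = max(h.start_year + h.n_years - 1 for h in histories)
    n = end - start + 1
    lines = []
    for h in histories:
        row = ["0"] * n
        off = h.start_year - start
        for i, o in enumerate(h.observations):
            row[off + i] = str(o)
        lines.append("".join(row) + " 1;")
    path.write_text("\n".join(lines) + "\n")
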