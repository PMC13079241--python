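"""Regional wall-motion abnormality ratings: adjudication, agreement, pattern stratification.

Each wall is rated dichotomously (present/absent, with an indeterminate
escape hatch) by two primary observers; a third observer settles any
disagreement, including disagreements about image adequacy.  Adjudicated
states are classified by temporal behaviour (persistent vs dynamic across the
two timepoints) and by location relative to the monitored wall (same vs
remote), and the trending concordance rate is stratified by the four
resulting patterns.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import AdjudicationError, ConfigurationError, UndefinedStatisticError
from .trending import AnalysisConfig, ConcordanceResult, PairedChange, concordance_rate
from .vocab import PATTERNS, RATINGS, TIMEPOINTS, WALLS

#: Priority used when a pair must be assigned to exactly one pattern
#: (exclusive counting mode): same-wall beats remote, persistent beats dynamic.
_EXCLUSIVE_PRIORITY = ("same_persistent", "same_dynamic", "remote_persistent", "remote_dynamic")


@dataclass(frozen=True)
class RwmaPattern:
    """Pattern memberships of one (patient, monitored wall) pair."""

    patient_id: str
    monitored_wall: str
    memberships: frozenset[str]

    def __post_init__(self) -> None:
        unknown = self.memberships - set(PATTERNS)
        if unknown:
            raise ConfigurationError(f"unknown pattern(s): {sorted(unknown)}")


@dataclass(frozen=True)
class KappaResult:
    """Two-rater chance-corrected agreement."""

    kappa: Optional[float]
    observed_agreement: float
    expected_agreement: float
    n_items: int
    categories: tuple[str, ...]


def adjudicate(obs1: str, obs2: str, obs3: Optional[str] = None) -> str:
    """Final rating for one (patient, timepoint, wall).

    Agreement between the two primary observers stands; any disagreement —
    including one observer calling the image inadequate (indeterminate) — is
    settled verbatim by the third observer.
    """
    for name, r in (("obs1", obs1), ("obs2", obs2)):
        if r not in RATINGS:
            raise ConfigurationError(f"{name} rating {r!r} not in {RATINGS}")
    if obs1 == obs2:
        return obs1
    if obs3 is None:
        raise AdjudicationError("observers disagree and no adjudicator rating is available")
    if obs3 not in RATINGS:
        raise ConfigurationError(f"obs3 rating {obs3!r} not in {RATINGS}")
    return obs3


def adjudicate_table(ratings: pd.DataFrame) -> pd.DataFrame:
    """Adjudicate a long-format rating table to one final rating per item.

    Expects columns ``patient_id, timepoint, wall, observer, rating`` with
    observers ``obs1``/``obs2`` and, where they disagree, ``obs3``.  Returns
    columns ``patient_id, timepoint, wall, rating``.
    """
    wide = ratings.pivot_table(
        index=["patient_id", "timepoint", "wall"], columns="observer", values="rating", aggfunc="first"
    )
    out = []
    for (pid, tp, wall), row in wide.iterrows():
        o1, o2 = row.get("obs1"), row.get("obs2")
        if pd.isna(o1) or pd.isna(o2):
            raise AdjudicationError(f"missing primary-observer rating for ({pid}, {tp}, {wall})")
        o3 = row.get("obs3")
        final = adjudicate(o1, o2, None if pd.isna(o3) else o3)
        out.append({"patient_id": pid, "timepoint": tp, "wall": wall, "rating": final})
    return pd.DataFrame(out)


def cohens_kappa(
    ratings_a: Sequence[str],
    ratings_b: Sequence[str],
    categories: Optional[Sequence[str]] = None,
) -> KappaResult:
    """Cohen's kappa between two aligned rating vectors.

    By default the category set is the union of categories present in the
    data (up to all three, including indeterminate).  When the expected
    agreement is 1 (both raters constant and identical) kappa is undefined
    and reported as None.
    """
    if len(ratings_a) != len(ratings_b):
        raise UndefinedStatisticError("rating vectors must be aligned (equal length)")
    n = len(ratings_a)
    if n == 0:
        raise UndefinedStatisticError("kappa requires at least one item")
    cats = tuple(categories) if categories is not None else tuple(
        sorted(set(ratings_a) | set(ratings_b))
    )
    counts_a = Counter(ratings_a)
    counts_b = Counter(ratings_b)
    po = sum(a == b for a, b in zip(ratings_a, ratings_b)) / n
    pe = sum((counts_a[c] / n) * (counts_b[c] / n) for c in cats)
    kappa = None if pe >= 1.0 else (po - pe) / (1.0 - pe)
    return KappaResult(kappa, po, pe, n, cats)


def classify_patterns(
    adjudicated: pd.DataFrame, patient_id: str, monitored_wall: str
) -> RwmaPattern:
    """Pattern memberships for one patient relative to one monitored wall.

    For every wall with non-indeterminate adjudicated ratings at both
    timepoints: present at both timepoints makes it persistent, present at
    exactly one makes it dynamic, absent at both contributes nothing.  The
    location is ``same`` when the wall is the monitored one, ``remote``
    otherwise; memberships are the union over walls.  A wall indeterminate at
    either timepoint is left out of the temporal classification.
    """
    if monitored_wall not in WALLS:
        raise ConfigurationError(f"monitored_wall {monitored_wall!r} not in {WALLS}")
    sub = adjudicated[adjudicated["patient_id"] == patient_id]
    memberships: set[str] = set()
    for wall in WALLS:
        ratings = {
            tp: sub.loc[(sub["wall"] == wall) & (sub["timepoint"] == tp), "rating"]
            for tp in TIMEPOINTS
        }
        if any(len(r) == 0 for r in ratings.values()):
            continue
        pre, icu = ratings["pre_cpb"].iloc[0], ratings["icu"].iloc[0]
        if "indeterminate" in (pre, icu):
            continue
        n_present = (pre == "present") + (icu == "present")
        if n_present == 0:
            continue
        temporal = "persistent" if n_present == 2 else "dynamic"
        location = "same" if wall == monitored_wall else "remote"
        memberships.add(f"{location}_{temporal}")
    return RwmaPattern(patient_id, monitored_wall, frozenset(memberships))


def classify_all_patterns(adjudicated: pd.DataFrame) -> dict[tuple[str, str], RwmaPattern]:
    """Memberships for every (patient, monitored wall) combination in the table."""
    patients = sorted(adjudicated["patient_id"].unique())
    return {
        (pid, wall): classify_patterns(adjudicated, pid, wall)
        for pid, wall in itertools.product(patients, WALLS)
    }


def pattern_concordance(
    pairs: Sequence[PairedChange],
    patterns: Mapping[tuple[str, str], RwmaPattern],
    cfg: AnalysisConfig | None = None,
    mode: str = "overlapping",
) -> dict[str, Optional[ConcordanceResult]]:
    """Concordance rate stratified by RWMA pattern.

    In the default ``overlapping`` mode a pair is counted in every pattern it
    belongs to; in ``exclusive`` mode each pair is assigned to its single
    highest-priority pattern (same over remote, persistent over dynamic).
    Patterns with no retained pair report None (rate undefined).
    """
    cfg = cfg or AnalysisConfig()
    if mode not in ("overlapping", "exclusive"):
        raise ConfigurationError("mode must be 'overlapping' or 'exclusive'")
    buckets: dict[str, list[PairedChange]] = {p: [] for p in PATTERNS}
    for pair in pairs:
        pat = patterns.get((pair.patient_id, pair.wall))
        if pat is None or not pat.memberships:
            continue
        if mode == "overlapping":
            targets = pat.memberships
        else:
            targets = [next(p for p in _EXCLUSIVE_PRIORITY if p in pat.memberships)]
        for name in targets:
            buckets[name].append(pair)
    out: dict[str, Optional[ConcordanceResult]] = {}
    for name in PATTERNS:
        sub = buckets[name]
        retained = [p for p in sub if p.excluded is False]
        out[name] = concordance_rate(sub, cfg) if retained else None
    return out
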