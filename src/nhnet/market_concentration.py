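"""Herfindahl-Hirschman concentration indices per HRR and date.

The HHI of an HRR is the sum over facilities of squared certified-bed
shares.  The affiliation-accounted HHI (AHHI) first pools the beds of
facilities in the same ownership group, so each group contributes one
squared share; every single-affiliation facility contributes alone.
Pooling can only concentrate the market, hence AHHI >= HHI, and the
difference dHHI = AHHI - HHI is the concentration attributable purely to
super-organization.  Indices are on the 0-1 scale (not the 0-10,000
antitrust convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .ownership_network import OwnershipGroup

logger = logging.getLogger(__name__)


class UndefinedMarketError(ValueError):
    """An HRR with zero total certified beds has no defined concentration."""


class PartitionError(ValueError):
    """Groups plus singles must partition the HRR's facilities exactly."""


@dataclass(frozen=True)
class ConcentrationRecord:
    hrr: str
    date: int
    hhi: float
    ahhi: float
    delta: float
    total_beds: int


def hhi(beds: Sequence[float]) -> float:
    """Sum of squared bed shares over facilities in one focal area.

    Facilities with zero (or missing) beds are excluded with a warning;
    with n facilities the result lies in [1/n, 1].
    """
    arr = np.asarray([b for b in beds if b], dtype=float)
    if arr.size < len(list(beds)):
        logger.warning(
            "excluded %d zero-bed facilities from concentration index",
            len(list(beds)) - arr.size,
        )
    total = arr.sum()
    if arr.size == 0 or total <= 0:
        raise UndefinedMarketError("no certified beds in focal area")
    shares = arr / total
    return float(np.sum(shares**2))


def ahhi(
    beds_by_provider: Mapping[str, float],
    groups: Sequence[OwnershipGroup],
    singles: Sequence[str],
) -> float:
    """Affiliation-accounted HHI: one pooled share per ownership group.

    ``groups`` and ``singles`` together must cover every provider in
    ``beds_by_provider`` exactly once; a facility in two groups (or both
    grouped and single) raises :class:`PartitionError`.
    """
    seen: set[str] = set()
    unit_beds: list[float] = []
    for g in groups:
        overlap = seen & set(g.members)
        if overlap:
            raise PartitionError(f"facilities {sorted(overlap)} appear in two units")
        seen |= set(g.members)
        unit_beds.append(sum(beds_by_provider.get(p, 0.0) or 0.0 for p in g.members))
    for p in singles:
        if p in seen:
            raise PartitionError(f"facility {p} is both grouped and single")
        seen.add(p)
        unit_beds.append(beds_by_provider.get(p, 0.0) or 0.0)
    missing = set(beds_by_provider) - seen
    if missing:
        raise PartitionError(f"facilities {sorted(missing)} not covered by partition")
    return hhi(unit_beds)


def delta_hhi(
    beds_by_provider: Mapping[str, float],
    groups: Sequence[OwnershipGroup],
    singles: Sequence[str],
) -> float:
    """AHHI minus HHI of the same beds and partition; nonnegative."""
    return ahhi(beds_by_provider, groups, singles) - hhi(list(beds_by_provider.values()))


def concentration_record(
    hrr: str,
    date: int,
    beds_by_provider: Mapping[str, float],
    groups: Sequence[OwnershipGroup],
    singles: Sequence[str],
) -> ConcentrationRecord:
    h = hhi(list(beds_by_provider.values()))
    a = ahhi(beds_by_provider, groups, singles)
    return ConcentrationRecord(
        hrr=hrr,
        date=date,
        hhi=h,
        ahhi=a,
        delta=a - h,
        total_beds=int(sum(b or 0 for b in beds_by_provider.values())),
    )


def concentration_table(records: Sequence[ConcentrationRecord]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "hrr": r.hrr,
                "date": r.date,
                "hhi": r.hhi,
                "ahhi": r.ahhi,
                "delta_hhi": r.delta,
                "total_beds": r.total_beds,
            }
            for r in records
        ]
    )
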