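"""Owner-name normalization and registered-organization filtering.

Since 2013, US registered organizations (LLCs, trusts, corporations) must
use their exact legal name from the public organic record on statutory
documents, and those names are unique within a state.  Exact key matching
on a lightly normalized legal name is therefore a defensible way to link
the same owner across facility ownership records; fuzzy matching is
deliberately avoided.

The normalization rule is minimal: commas and periods are removed, runs of
whitespace are collapsed to a single space, ends are trimmed, and the
result is upper-cased.  Nothing else is canonicalized — ``"LLC"`` and
``"L L C"`` stay distinct keys on purpose, because the legal names
themselves are the identifiers.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

_PUNCT = re.compile(r"[,.]")
_WS = re.compile(r"\s+")


@dataclass(frozen=True)
class NameKey:
    """A raw owner name together with its normalized match key."""

    raw: str
    key: str


def normalize_owner_name(raw: str) -> NameKey:
    """Normalize a raw owner name into an exact match key.

    Removes commas and periods, collapses whitespace runs to one space,
    strips leading/trailing whitespace and upper-cases.  Deterministic and
    idempotent: normalizing an already-normalized key returns it unchanged.
    An empty or all-punctuation input yields an empty key; callers decide
    how to treat it (the IO layer skips such records with a warning).
    """
    key = _PUNCT.sub("", raw)
    key = _WS.sub(" ", key).strip().upper()
    return NameKey(raw=raw, key=key)


def filter_registered_organizations(records: Sequence) -> list:
    """Keep only ownership records whose owner is a registered organization.

    Facilities owned solely by individuals carry no usable exact-match key
    (personal names are not unique), so individual-kind records are dropped
    before any network construction.  The number of dropped records is
    logged.
    """
    kept = [r for r in records if getattr(r, "owner_kind", None) == "organization"]
    dropped = len(records) - len(kept)
    if dropped:
        logger.info("dropped %d individual-owner records (%d kept)", dropped, len(kept))
    return kept


def audit_table(raw_names: Iterable[str]) -> "list[tuple[str, str]]":
    """Return (raw, key) pairs for an audit listing of the normalization."""
    return [(raw, normalize_owner_name(raw).key) for raw in raw_names]
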