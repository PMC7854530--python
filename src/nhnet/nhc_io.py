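"""Reading Nursing Home Compare (NHC) style tables and panel assembly.

The public NHC open datasets ship as CSV spreadsheets keyed by "Federal
Provider Number": provider characteristics (beds, occupancy, staffing,
ownership type, the Total Weighted Health Survey Score outcome), ownership
records ("Owner Name" / owner type), and Minimum Data Set (MDS) quality
measure prevalences in long format.  This module parses those dialects,
links rows by provider number within and across semi-annual processing
dates, places each facility into a hospital referral region (HRR) through
a ZIP->HRR crosswalk, and assembles the complete-case longitudinal panel
used by every downstream stage.

Column headers changed across CMS releases, so every reader takes an
optional column mapping; the defaults match the 2016-2018 NHC headers.
Missing covariates are flagged, never imputed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .name_matching import normalize_owner_name

logger = logging.getLogger(__name__)

OWNERSHIP_TYPES = ("for-profit", "government", "non-profit")


class FormatError(ValueError):
    """A table does not conform to the expected NHC dialect."""


class LinkageError(ValueError):
    """Provider-number linkage failed (e.g. duplicate key within a date)."""


class CrosswalkError(KeyError):
    """A ZIP code cannot be placed into a hospital referral region."""


# Default 2016-2018 NHC provider-table headers, field name -> CSV column.
DEFAULT_PROVIDER_COLUMNS: dict[str, str] = {
    "provider_id": "Federal Provider Number",
    "zip": "Provider Zip Code",
    "state": "Provider State",
    "beds": "Number of Certified Beds",
    "residents": "Number of Residents in Certified Beds",
    "occupancy_pct": "Occupancy Percentage",
    "years_in_business": "Years in Business",
    "ownership_type": "Ownership Type",
    "hospital_based": "Provider Resides in Hospital",
    "sff": "Special Focus Facility",
    "ccrc": "Continuing Care Retirement Community",
    "council": "With a Resident and Family Council",
    "ownership_changed": "Changed Ownership in Last 12 Months",
    "staffing_cna_hrd": "Adjusted CNA Staffing Hours per Resident per Day",
    "staffing_lpn_hrd": "Adjusted LPN Staffing Hours per Resident per Day",
    "staffing_rn_hrd": "Adjusted RN Staffing Hours per Resident per Day",
    "five_star": "Overall Rating",
    "twhss": "Total Weighted Health Survey Score",
}

# Columns the provider reader insists on; the rest may be absent (their
# fields are then missing and the facility is incomplete for models that
# need them).  Occupancy is derived from residents/beds when its column is
# absent, as in the real datasets.
REQUIRED_PROVIDER_COLUMNS = (
    "provider_id",
    "zip",
    "state",
    "beds",
    "residents",
    "ownership_type",
    "twhss",
)

DEFAULT_OWNERSHIP_COLUMNS: dict[str, str] = {
    "provider_id": "Federal Provider Number",
    "owner_name": "Owner Name",
    "owner_kind": "Owner Type",
}

DEFAULT_MDS_COLUMNS: dict[str, str] = {
    "provider_id": "Federal Provider Number",
    "code": "Measure Code",
    "score": "Four Quarter Average Score",
}

DEFAULT_CROSSWALK_COLUMNS: dict[str, str] = {
    "zip": "ZIP Code",
    "hrr_id": "HRR ID",
    "hrr_name": "HRR Name",
}

# Model-level covariate requirements used by the completeness filter.
MODEL1_COVARIATES = (
    "staffing_cna_hrd",
    "staffing_lpn_hrd",
    "staffing_rn_hrd",
    "residents",
    "occupancy_pct",
    "years_in_business",
    "ownership_type",
    "hospital_based",
    "sff",
    "ccrc",
    "council",
    "ownership_changed",
    "five_star",
    "twhss",
)

_TRUTHY = {"yes", "y", "true", "1", "resident", "family", "both"}
_FALSY = {"no", "n", "false", "0", "none", ""}


@dataclass
class FacilitySnapshot:
    """One facility's covariates and outcome at one processing date."""

    provider_id: str
    date: int
    zip: str
    state: str
    beds: int | None = None
    residents: int | None = None
    occupancy_pct: float | None = None
    years_in_business: float | None = None
    ownership_type: str | None = None
    hospital_based: bool | None = None
    sff: bool | None = None
    ccrc: bool | None = None
    council: bool | None = None
    ownership_changed: bool | None = None
    staffing_cna_hrd: float | None = None
    staffing_lpn_hrd: float | None = None
    staffing_rn_hrd: float | None = None
    five_star: int | None = None
    twhss: float | None = None
    twhss_int: int | None = None
    mds: dict[int, float] = field(default_factory=dict)
    hrr: str | None = None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class OwnerRecord:
    """One owner-facility tie at one processing date."""

    provider_id: str
    owner_name_raw: str
    owner_key: str
    owner_kind: str  # "organization" | "individual"
    date: int


@dataclass
class ZipHrrMap:
    """Total ZIP -> (HRR id, HRR name) lookup."""

    entries: dict[str, tuple[str, str]]
    states: set[str] = field(default_factory=set)

    def lookup(self, zip_code: str) -> str:
        try:
            return self.entries[zip_code][0]
        except KeyError:
            raise CrosswalkError(f"ZIP code {zip_code!r} is not in the crosswalk")

    def hrr_name(self, hrr_id: str) -> str | None:
        for hid, name in self.entries.values():
            if hid == hrr_id:
                return name
        return None

    @property
    def n_hrrs(self) -> int:
        return len({hid for hid, _ in self.entries.values()})


@dataclass
class Panel:
    """The linked longitudinal panel across all processing dates."""

    snapshots_by_date: dict[int, list[FacilitySnapshot]]
    owners_by_date: dict[int, list[OwnerRecord]]
    dates: list[int]
    complete_providers: set[str]
    incomplete_reasons: dict[str, list[str]] = field(default_factory=dict)
    crosswalk: ZipHrrMap | None = None

    def snapshots(self, date: int) -> list[FacilitySnapshot]:
        return self.snapshots_by_date[date]

    def owners(self, date: int) -> list[OwnerRecord]:
        return self.owners_by_date[date]

    def to_frame(self, complete_only: bool = True) -> pd.DataFrame:
        """One row per facility-date; MDS prevalences as ``mds_<code>`` columns."""
        rows = []
        for date in self.dates:
            for s in self.snapshots_by_date[date]:
                if complete_only and s.provider_id not in self.complete_providers:
                    continue
                row = {
                    "provider_id": s.provider_id,
                    "date": s.date,
                    "zip": s.zip,
                    "state": s.state,
                    "hrr": s.hrr,
                    "beds": s.beds,
                    "residents": s.residents,
                    "occupancy_pct": s.occupancy_pct,
                    "years_in_business": s.years_in_business,
                    "ownership_type": s.ownership_type,
                    "hospital_based": s.hospital_based,
                    "sff": s.sff,
                    "ccrc": s.ccrc,
                    "council": s.council,
                    "ownership_changed": s.ownership_changed,
                    "staffing_cna_hrd": s.staffing_cna_hrd,
                    "staffing_lpn_hrd": s.staffing_lpn_hrd,
                    "staffing_rn_hrd": s.staffing_rn_hrd,
                    "five_star": s.five_star,
                    "twhss": s.twhss,
                    "twhss_int": s.twhss_int,
                    "complete": s.provider_id in self.complete_providers,
                }
                for code in sorted(s.mds):
                    row[f"mds_{code}"] = s.mds[code]
                rows.append(row)
        return pd.DataFrame(rows)


def round_half_away(x: float) -> int:
    """Nearest-integer discretization, halves away from zero (54.5 -> 55)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _parse_float(value) -> float | None:
    if value is None:
        return None
    s = str(value).strip()
    if s == "" or s.lower() in {"na", "nan", "null", "."}:
        return None
    try:
        return float(s)
    except ValueError:
        return None


def _parse_bool(value) -> bool | None:
    if value is None:
        return None
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False if s != "" else None
    return None


def _parse_ownership_type(value) -> str | None:
    if value is None:
        return None
    s = str(value).strip().lower()
    if not s:
        return None
    if s.startswith("for profit") or s == "for-profit":
        return "for-profit"
    if s.startswith("government"):
        return "government"
    if s.startswith("non profit") or s == "non-profit":
        return "non-profit"
    return None


def _read_csv(path) -> pd.DataFrame:
    # Everything is read as text: provider numbers and ZIPs are identifiers
    # whose leading zeros must survive.
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _resolve_columns(columns) -> Mapping[str, str] | None:
    """Accept a field->header mapping directly or as a YAML file path."""
    if columns is None or isinstance(columns, Mapping):
        return columns
    import yaml

    with open(columns) as fh:
        loaded = yaml.safe_load(fh) or {}
    if not isinstance(loaded, dict):
        raise FormatError(f"column mapping file {columns} must hold a mapping")
    return loaded


def read_provider_table(
    path,
    date: int,
    columns: Mapping[str, str] | None = None,
) -> list[FacilitySnapshot]:
    """Parse one processing date's provider-characteristics table.

    Returns one :class:`FacilitySnapshot` per row.  Numeric fields are
    parsed; unparseable or empty covariates are left ``None`` and later
    make the facility incomplete.  Invariant violations (occupancy outside
    0-100, residents exceeding beds, ratings outside 1-5) are recorded in
    ``snapshot.flags`` rather than raised, so a handful of bad rows cannot
    abort a national table.

    Raises :class:`FormatError` if a required column is absent and
    :class:`LinkageError` on a duplicated provider number within the date.
    """
    columns = _resolve_columns(columns)
    cols = dict(DEFAULT_PROVIDER_COLUMNS)
    if columns:
        cols.update(columns)
    df = _read_csv(path)
    for field_name in REQUIRED_PROVIDER_COLUMNS:
        if cols[field_name] not in df.columns:
            raise FormatError(
                f"provider table {path} lacks required column {cols[field_name]!r}"
            )

    def get(row, field_name):
        col = cols.get(field_name)
        return row[col] if col in df.columns else None

    snapshots: list[FacilitySnapshot] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        pid = str(get(row, "provider_id")).strip()
        if pid in seen:
            raise LinkageError(
                f"duplicate Federal Provider Number {pid!r} at date {date}"
            )
        seen.add(pid)
        beds = _parse_float(get(row, "beds"))
        residents = _parse_float(get(row, "residents"))
        occupancy = _parse_float(get(row, "occupancy_pct"))
        if occupancy is None and beds and residents is not None and beds > 0:
            occupancy = 100.0 * residents / beds
        twhss = _parse_float(get(row, "twhss"))
        five_star = _parse_float(get(row, "five_star"))
        snap = FacilitySnapshot(
            provider_id=pid,
            date=date,
            zip=str(get(row, "zip")).strip().zfill(5),
            state=str(get(row, "state")).strip().upper(),
            beds=None if beds is None else int(beds),
            residents=None if residents is None else int(residents),
            occupancy_pct=occupancy,
            years_in_business=_parse_float(get(row, "years_in_business")),
            ownership_type=_parse_ownership_type(get(row, "ownership_type")),
            hospital_based=_parse_bool(get(row, "hospital_based")),
            sff=_parse_bool(get(row, "sff")),
            ccrc=_parse_bool(get(row, "ccrc")),
            council=_parse_bool(get(row, "council")),
            ownership_changed=_parse_bool(get(row, "ownership_changed")),
            staffing_cna_hrd=_parse_float(get(row, "staffing_cna_hrd")),
            staffing_lpn_hrd=_parse_float(get(row, "staffing_lpn_hrd")),
            staffing_rn_hrd=_parse_float(get(row, "staffing_rn_hrd")),
            five_star=None if five_star is None else int(five_star),
            twhss=twhss,
            twhss_int=None if twhss is None else round_half_away(twhss),
        )
        snap.flags = tuple(_validate_snapshot(snap))
        snapshots.append(snap)
    return snapshots


def _validate_snapshot(s: FacilitySnapshot) -> list[str]:
    flags = []
    if s.occupancy_pct is not None and not (0.0 <= s.occupancy_pct <= 100.0):
        flags.append("occupancy_out_of_range")
    if s.beds is not None and s.beds < 0:
        flags.append("negative_beds")
    if s.residents is not None and s.residents < 0:
        flags.append("negative_residents")
    if (
        s.beds is not None
        and s.residents is not None
        and s.residents > s.beds
    ):
        flags.append("residents_exceed_beds")
    if s.five_star is not None and s.five_star not in (1, 2, 3, 4, 5):
        flags.append("five_star_out_of_range")
    if s.twhss is not None and s.twhss < 0:
        flags.append("negative_twhss")
    return flags


def read_ownership_table(
    path,
    date: int,
    columns: Mapping[str, str] | None = None,
) -> list[OwnerRecord]:
    """Parse one processing date's ownership table into owner-facility ties.

    The owner key is the normalized exact legal name; the owner kind is
    mapped to ``organization``/``individual`` from the type column.  Rows
    with an empty owner name are skipped with a logged warning.
    """
    columns = _resolve_columns(columns)
    cols = dict(DEFAULT_OWNERSHIP_COLUMNS)
    if columns:
        cols.update(columns)
    df = _read_csv(path)
    for field_name, col in cols.items():
        if col not in df.columns:
            raise FormatError(f"ownership table {path} lacks column {col!r}")
    records: list[OwnerRecord] = []
    skipped = 0
    for _, row in df.iterrows():
        raw = str(row[cols["owner_name"]])
        key = normalize_owner_name(raw).key
        if not key:
            skipped += 1
            continue
        kind_raw = str(row[cols["owner_kind"]]).strip().lower()
        kind = "individual" if "individual" in kind_raw else "organization"
        records.append(
            OwnerRecord(
                provider_id=str(row[cols["provider_id"]]).strip(),
                owner_name_raw=raw,
                owner_key=key,
                owner_kind=kind,
                date=date,
            )
        )
    if skipped:
        logger.warning("skipped %d ownership rows with empty owner name", skipped)
    return records


def read_mds_table(
    path,
    date: int,
    columns: Mapping[str, str] | None = None,
) -> dict[str, dict[int, float]]:
    """Parse a long-format MDS quality-measure table.

    Returns ``provider_id -> {measure code -> four-quarter average}``.
    Rows with a missing score are dropped (the facility is then incomplete
    for models requiring that code).
    """
    columns = _resolve_columns(columns)
    cols = dict(DEFAULT_MDS_COLUMNS)
    if columns:
        cols.update(columns)
    df = _read_csv(path)
    for field_name, col in cols.items():
        if col not in df.columns:
            raise FormatError(f"MDS table {path} lacks column {col!r}")
    out: dict[str, dict[int, float]] = {}
    for _, row in df.iterrows():
        score = _parse_float(row[cols["score"]])
        if score is None:
            continue
        pid = str(row[cols["provider_id"]]).strip()
        code = int(float(row[cols["code"]]))
        out.setdefault(pid, {})[code] = score
    return out


def read_crosswalk(
    path,
    columns: Mapping[str, str] | None = None,
) -> ZipHrrMap:
    """Read the ZIP -> hospital referral region crosswalk.

    Any Dartmouth-Atlas-style shape (zip, HRR id, HRR name, optional
    state) is accepted.  A ZIP mapped to two different HRRs is a
    :class:`FormatError`; an exact duplicate row is tolerated.
    """
    columns = _resolve_columns(columns)
    cols = dict(DEFAULT_CROSSWALK_COLUMNS)
    if columns:
        cols.update(columns)
    df = _read_csv(path)
    for field_name in ("zip", "hrr_id"):
        if cols[field_name] not in df.columns:
            raise FormatError(f"crosswalk {path} lacks column {cols[field_name]!r}")
    has_name = cols.get("hrr_name") in df.columns
    has_state = "State" in df.columns
    entries: dict[str, tuple[str, str]] = {}
    states: set[str] = set()
    for _, row in df.iterrows():
        z = str(row[cols["zip"]]).strip().zfill(5)
        hrr_id = str(row[cols["hrr_id"]]).strip()
        hrr_name = str(row[cols["hrr_name"]]).strip() if has_name else hrr_id
        if z in entries and entries[z][0] != hrr_id:
            raise FormatError(
                f"ZIP {z!r} maps to both HRR {entries[z][0]!r} and {hrr_id!r}"
            )
        entries[z] = (hrr_id, hrr_name)
        if has_state:
            states.add(str(row["State"]).strip().upper())
    return ZipHrrMap(entries=entries, states=states)


def assemble_panel(
    snapshots_by_date: Mapping[int, Sequence[FacilitySnapshot]],
    owners_by_date: Mapping[int, Sequence[OwnerRecord]],
    crosswalk: ZipHrrMap,
    required_covariates: Sequence[str] = MODEL1_COVARIATES,
    mds_by_date: Mapping[int, Mapping[str, Mapping[int, float]]] | None = None,
    required_mds_codes: Sequence[int] | None = None,
) -> Panel:
    """Link the per-date tables into the longitudinal complete-case panel.

    A provider enters ``complete_providers`` only if, at *every* processing
    date, it (a) has at least one organization-kind owner, (b) has every
    required covariate non-missing with no validation flag on a required
    field, (c) resolves to an HRR through the crosswalk, and (d) carries
    every required MDS code when codes are demanded.  All other providers
    are retained in the panel but flagged incomplete, with reasons.

    An empty intersection yields an explicit empty panel, not an error.
    """
    dates = sorted(snapshots_by_date)
    if not dates:
        raise FormatError("panel assembly needs at least one processing date")

    snaps: dict[int, list[FacilitySnapshot]] = {}
    reasons: dict[str, list[str]] = {}

    def note(pid: str, why: str) -> None:
        reasons.setdefault(pid, []).append(why)

    for date in dates:
        out = []
        mds_for_date = (mds_by_date or {}).get(date, {})
        for s in snapshots_by_date[date]:
            s = replace(s)
            if mds_for_date:
                s.mds = dict(mds_for_date.get(s.provider_id, {}))
            try:
                s.hrr = crosswalk.lookup(s.zip)
            except CrosswalkError:
                note(s.provider_id, f"unresolved ZIP {s.zip} at date {date}")
            out.append(s)
        snaps[date] = out

    presence: dict[str, set[int]] = {}
    by_key: dict[tuple[int, str], FacilitySnapshot] = {}
    for date in dates:
        for s in snaps[date]:
            presence.setdefault(s.provider_id, set()).add(date)
            by_key[(date, s.provider_id)] = s

    org_owned: dict[int, set[str]] = {}
    for date in dates:
        org_owned[date] = {
            r.provider_id
            for r in owners_by_date.get(date, [])
            if r.owner_kind == "organization"
        }

    complete: set[str] = set()
    for pid, present in presence.items():
        ok = True
        if present != set(dates):
            missing_dates = sorted(set(dates) - present)
            note(pid, f"absent at dates {missing_dates}")
            ok = False
        for date in sorted(present):
            if pid not in org_owned[date]:
                note(pid, f"no organization owner at date {date}")
                ok = False
        for date in sorted(present):
            snap = by_key[(date, pid)]
            if snap.hrr is None:
                ok = False
            for cov in required_covariates:
                if getattr(snap, cov, None) is None:
                    note(pid, f"missing {cov} at date {date}")
                    ok = False
            if snap.flags:
                note(pid, f"validation flags {list(snap.flags)} at date {date}")
                ok = False
            if required_mds_codes:
                missing_codes = [c for c in required_mds_codes if c not in snap.mds]
                if missing_codes:
                    note(pid, f"missing MDS codes {missing_codes} at date {date}")
                    ok = False
        if ok:
            complete.add(pid)

    if not complete:
        logger.warning("panel has no complete providers")
    return Panel(
        snapshots_by_date=snaps,
        owners_by_date={d: list(owners_by_date.get(d, [])) for d in dates},
        dates=dates,
        complete_providers=complete,
        incomplete_reasons=reasons,
        crosswalk=crosswalk,
    )


# ---------------------------------------------------------------------------
# Panel persistence (JSON-lines, one record per facility-date)


def write_panel(panel: Panel, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        header = {
            "kind": "header",
            "dates": panel.dates,
            "complete_providers": sorted(panel.complete_providers),
        }
        fh.write(json.dumps(header) + "\n")
        for date in panel.dates:
            for s in panel.snapshots_by_date[date]:
                rec = {
                    "kind": "snapshot",
                    **{k: v for k, v in s.__dict__.items() if k != "flags"},
                    "flags": list(s.flags),
                    "mds": {str(k): v for k, v in s.mds.items()},
                }
                fh.write(json.dumps(rec) + "\n")
            for r in panel.owners_by_date[date]:
                fh.write(json.dumps({"kind": "owner", **r.__dict__}) + "\n")


def read_panel(path) -> Panel:
    path = Path(path)
    snaps: dict[int, list[FacilitySnapshot]] = {}
    owners: dict[int, list[OwnerRecord]] = {}
    header = None
    with path.open() as fh:
        for line in fh:
            rec = json.loads(line)
            kind = rec.pop("kind")
            if kind == "header":
                header = rec
            elif kind == "snapshot":
                rec["flags"] = tuple(rec["flags"])
                rec["mds"] = {int(k): v for k, v in rec["mds"].items()}
                s = FacilitySnapshot(**rec)
                snaps.setdefault(s.date, []).append(s)
            elif kind == "owner":
                r = OwnerRecord(**rec)
                owners.setdefault(r.date, []).append(r)
    if header is None:
        raise FormatError(f"panel file {path} has no header record")
    return Panel(
        snapshots_by_date=snaps,
        owners_by_date=owners,
        dates=list(header["dates"]),
        complete_providers=set(header["complete_providers"]),
    )
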