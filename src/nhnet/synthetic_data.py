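"""NHC-like synthetic panels with planted ownership structure.

Every pipeline stage needs ground truth: this module fabricates
multi-date provider/ownership/MDS/crosswalk tables in the exact dialect
the IO layer reads, with (a) a planted partition of each HRR's facilities
into ownership groups realized as shared owner keys, (b) cross-classified
state/HRR membership (a configurable fraction of HRRs straddles two
states), and (c) outcome counts drawn from the same log-link Poisson
mixed model the inference stage fits, at known coefficients and variance
components.

Default magnitudes emulate the national picture of the 2016-2018 cohort:
~30 facilities per HRR, 56.8% of facilities in super-organization,
ownership-group sizes from a shifted geometric with mean ~3.2, ownership
type shares 74.3/6.5/19.2 (for-profit/government/non-profit), outcome
counts in the mid-50s with log-scale variance split across state, HRR,
facility and observation terms.  Owner names are decorated with commas,
periods, stray spacing and case changes so the normalization rule is
exercised; decorations always normalize back to the planted key.

The generative distributions themselves (geometric group sizes, lognormal
beds, Gaussian staffing) are this module's own modelling choices — the
real datasets prescribe none.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import glmm
from . import market_concentration as mc
from .nhc_io import (
    DEFAULT_CROSSWALK_COLUMNS,
    DEFAULT_MDS_COLUMNS,
    DEFAULT_OWNERSHIP_COLUMNS,
    DEFAULT_PROVIDER_COLUMNS,
    MODEL1_COVARIATES,
    FacilitySnapshot,
    OwnerRecord,
    Panel,
    ZipHrrMap,
    assemble_panel,
    round_half_away,
)

# The 21 MDS measure codes carried by the Model 2 design: long-stay
# prevalences 401-452 and short-stay prevalences 424-471.
MDS_CODES = (
    401, 402, 403, 404, 405, 406, 407, 408, 409, 410, 411, 415, 419, 451, 452,
    424, 425, 426, 430, 434, 471,
)


class ConfigError(ValueError):
    """The generator configuration is internally infeasible."""


# Coefficients used to simulate outcomes, keyed by design column name.
# Magnitudes echo plausible effects: strong protective RN staffing, lower
# counts for non-profits, mild occupancy effect.  The intercept targets a
# *marginal* count mean near 59: with total latent variance 0.904 the
# log-normal lift is exp(0.452), so exp(3.63 + 0.452) ~ 59.
DEFAULT_TRUE_BETA: dict[str, float] = {
    "intercept": 3.63,
    "staffing_cna_hrd": -0.034,
    "staffing_rn_hrd": -0.23,
    "occupancy_pct": -0.005,
    "ownership_government": -0.047,
    "ownership_nonprofit": -0.13,
    "mean_group_size": -0.017,
    "delta_hhi": 0.03,
    "affiliation_single": 0.022,
}

# Compact fixed-effect specification used both to simulate outcomes and in
# the parameter-recovery experiments.
RECOVERY_SPEC = glmm.ModelSpec(
    variant="model1",
    continuous=("staffing_cna_hrd", "staffing_rn_hrd", "occupancy_pct"),
    booleans=(),
    include_ownership_type=True,
    include_affiliation=True,
    include_interaction=False,
    include_quality=False,
    hrr_level=("mean_group_size", "delta_hhi"),
)


@dataclass
class GeneratorConfig:
    n_states: int = 8
    n_hrrs: int = 20
    hrr_two_state_frac: float = 0.3
    n_facilities: int = 600
    n_dates: int = 5
    # ownership structure
    target_prevalence_multiple_pct: float = 56.8
    prevalence_hrr_sd: float = 16.7  # between-HRR spread of the target
    group_size_mean: float = 3.2
    group_size_max: int = 8
    second_shared_owner_prob: float = 0.3
    solo_owners_per_facility_mean: float = 0.6  # Poisson, plus one guaranteed
    pct_individual_owners: float = 0.15
    pct_individual_only_facilities: float = 0.0
    # facility covariates
    beds_log_mean: float = math.log(90.0)
    beds_log_sd: float = 0.7
    beds_min: int = 16
    beds_max: int = 500
    occupancy_mean: float = 82.0
    occupancy_sd: float = 10.0
    ownership_type_shares: tuple[float, float, float] = (0.743, 0.065, 0.192)
    staffing_cna_mean: float = 2.3
    staffing_cna_sd: float = 0.45
    staffing_lpn_mean: float = 0.85
    staffing_lpn_sd: float = 0.25
    staffing_rn_mean: float = 0.65
    staffing_rn_sd: float = 0.3
    years_shape: float = 4.0
    years_scale: float = 7.0
    five_star_probs: tuple[float, ...] = (0.12, 0.18, 0.22, 0.24, 0.24)
    hospital_based_p: float = 0.05
    sff_p: float = 0.03
    ccrc_p: float = 0.08
    council_p: float = 0.55
    ownership_changed_p: float = 0.07
    mds_codes: tuple[int, ...] = MDS_CODES
    mds_missing_rate: float = 0.256  # fraction of facilities missing >=1 code
    # outcome model
    # Variance components: shares of the four-component total are
    # 0.175 (state) and 0.073 (HRR) with a total of 0.904, so the planted
    # intraclass correlations and the outcome's coefficient of variation
    # both sit at the observed national magnitudes.
    true_beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_BETA))
    sigma2_state: float = 0.158
    sigma2_hrr: float = 0.066
    sigma2_facility: float = 0.47
    sigma2_obs: float = 0.21

    def __post_init__(self):
        if not 0 <= self.hrr_two_state_frac <= 1:
            raise ConfigError("hrr_two_state_frac must lie in [0, 1]")
        if not 0 <= self.target_prevalence_multiple_pct <= 100:
            raise ConfigError("target prevalence must lie in [0, 100]")
        if self.group_size_mean < 2:
            raise ConfigError("mean ownership-group size must be >= 2")
        if abs(sum(self.ownership_type_shares) - 1.0) > 1e-9:
            raise ConfigError("ownership type shares must sum to 1")
        for p in (
            self.pct_individual_owners,
            self.pct_individual_only_facilities,
            self.mds_missing_rate,
        ):
            if not 0 <= p <= 1:
                raise ConfigError("probabilities must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted structure: the generator's bookkeeping for every stage."""

    affiliation: dict[str, str]                    # provider -> single|multiple
    groups_by_hrr: dict[str, list[frozenset]]      # planted partitions
    hrr_metrics: pd.DataFrame                      # per (hrr, date) truth
    owners_by_provider: dict[str, list[str]]       # org owner keys
    n_individual_records: int
    n_org_records: int
    true_beta: dict[str, float]
    sigma2: dict[str, float]
    design_colnames: list[str] = field(default_factory=list)
    beta_vector: np.ndarray | None = None          # aligned to design_colnames


@dataclass
class SyntheticData:
    """In-memory synthetic tables plus the planted truth."""

    config: GeneratorConfig
    seed: int
    snapshots_by_date: dict[int, list[FacilitySnapshot]]
    owners_by_date: dict[int, list[OwnerRecord]]
    mds_by_date: dict[int, dict[str, dict[int, float]]]
    crosswalk: ZipHrrMap
    truth: GroundTruth

    def assemble(
        self,
        required_covariates: Sequence[str] = MODEL1_COVARIATES,
        required_mds_codes: Sequence[int] | None = None,
    ) -> Panel:
        return assemble_panel(
            self.snapshots_by_date,
            self.owners_by_date,
            self.crosswalk,
            required_covariates=required_covariates,
            mds_by_date=self.mds_by_date,
            required_mds_codes=required_mds_codes,
        )

    def model_frame(self, require_outcome: bool = True) -> pd.DataFrame:
        """Panel frame joined with the *planted* affiliation and metrics.

        This is the frame the outcomes were simulated from; fitting on it
        isolates the regression stage from the network stage.  During
        generation the outcome does not exist yet, hence the switch.
        """
        required = MODEL1_COVARIATES if require_outcome else tuple(
            c for c in MODEL1_COVARIATES if c != "twhss"
        )
        panel = self.assemble(required_covariates=required)
        frame = panel.to_frame(complete_only=True)
        frame["affiliation"] = [self.truth.affiliation[p] for p in frame["provider_id"]]
        mf = self.truth.hrr_metrics[
            ["hrr", "date", "prevalence_multiple_pct", "mean_group_size", "delta_hhi"]
        ]
        return frame.merge(mf, on=["hrr", "date"], how="left")


# ---------------------------------------------------------------------------
# Geography and facilities


def _state_codes(n: int) -> list[str]:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    out = []
    for i in range(n):
        out.append(letters[i // 26] + letters[i % 26])
    return out


def _build_geography(config: GeneratorConfig, rng: np.random.Generator):
    """HRRs, their states and ZIP codes.

    HRR i has primary state i mod n_states; the first
    ``round(frac * n_hrrs)`` HRRs also reach into the next state, giving
    genuine cross-classification (states holding several HRRs and HRRs
    spanning two states).  Each HRR holds four ZIPs, split between its
    states when it has two.
    """
    states = _state_codes(config.n_states)
    hrr_ids = [f"H{i + 1:03d}" for i in range(config.n_hrrs)]
    n_two = int(round(config.hrr_two_state_frac * config.n_hrrs))
    zip_state: dict[str, str] = {}
    zip_hrr: dict[str, str] = {}
    hrr_zips: dict[str, list[str]] = {}
    for i, hrr in enumerate(hrr_ids):
        primary = states[i % config.n_states]
        secondary = states[(i + 1) % config.n_states] if i < n_two else None
        zips = [f"{90000 + i * 10 + j:05d}" for j in range(4)]
        hrr_zips[hrr] = zips
        for j, z in enumerate(zips):
            zip_hrr[z] = hrr
            zip_state[z] = secondary if (secondary and j >= 2) else primary
    entries = {z: (h, f"Region {h}") for z, h in zip_hrr.items()}
    crosswalk = ZipHrrMap(entries=entries, states=set(states))
    return hrr_ids, hrr_zips, zip_state, crosswalk


def generate_facilities(
    config: GeneratorConfig, seed: int
) -> tuple[dict[int, list[FacilitySnapshot]], ZipHrrMap, dict[str, str]]:
    """Facility snapshots for every date, without outcomes.

    Returns the per-date snapshot lists, the crosswalk, and the facility ->
    HRR assignment.  Static attributes (beds, ownership type, five-star)
    are fixed per facility; staffing and occupancy drift slightly between
    dates; years in business advances half a year per semi-annual date.
    """
    rng = np.random.default_rng(seed)
    hrr_ids, hrr_zips, zip_state, crosswalk = _build_geography(config, rng)

    n = config.n_facilities
    pids = [f"{100000 + i:06d}" for i in range(n)]
    fac_hrr = {pid: hrr_ids[i % len(hrr_ids)] for i, pid in enumerate(pids)}
    beds = np.clip(
        np.round(rng.lognormal(config.beds_log_mean, config.beds_log_sd, n)),
        config.beds_min,
        config.beds_max,
    ).astype(int)
    own_type = rng.choice(
        ["for-profit", "government", "non-profit"],
        size=n,
        p=config.ownership_type_shares,
    )
    occupancy0 = np.clip(rng.normal(config.occupancy_mean, config.occupancy_sd, n), 40, 100)
    cna0 = np.maximum(rng.normal(config.staffing_cna_mean, config.staffing_cna_sd, n), 0.3)
    lpn0 = np.maximum(rng.normal(config.staffing_lpn_mean, config.staffing_lpn_sd, n), 0.05)
    rn0 = np.maximum(rng.normal(config.staffing_rn_mean, config.staffing_rn_sd, n), 0.05)
    years0 = rng.gamma(config.years_shape, config.years_scale, n)
    five_star = rng.choice([1, 2, 3, 4, 5], size=n, p=config.five_star_probs)
    hosp = rng.uniform(size=n) < config.hospital_based_p
    sff = rng.uniform(size=n) < config.sff_p
    ccrc = rng.uniform(size=n) < config.ccrc_p
    council = rng.uniform(size=n) < config.council_p
    zips = np.array(
        [hrr_zips[fac_hrr[pid]][rng.integers(0, 4)] for pid in pids]
    )

    snapshots_by_date: dict[int, list[FacilitySnapshot]] = {}
    for date in range(1, config.n_dates + 1):
        occ = np.clip(occupancy0 + rng.normal(0, 1.5, n), 40, 100)
        cna = np.maximum(cna0 + rng.normal(0, 0.05, n), 0.3)
        lpn = np.maximum(lpn0 + rng.normal(0, 0.04, n), 0.05)
        rn = np.maximum(rn0 + rng.normal(0, 0.04, n), 0.05)
        changed = rng.uniform(size=n) < config.ownership_changed_p
        out = []
        for i, pid in enumerate(pids):
            residents = int(round(beds[i] * occ[i] / 100.0))
            # covariates are rounded here to the precision the CSV writer
            # emits, so fixtures round-trip through the IO layer exactly
            out.append(
                FacilitySnapshot(
                    provider_id=pid,
                    date=date,
                    zip=str(zips[i]),
                    state=zip_state[str(zips[i])],
                    hrr=None,  # resolved by the crosswalk at assembly
                    beds=int(beds[i]),
                    residents=residents,
                    occupancy_pct=round(100.0 * residents / beds[i], 4),
                    years_in_business=round(float(years0[i] + 0.5 * (date - 1)), 2),
                    ownership_type=str(own_type[i]),
                    hospital_based=bool(hosp[i]),
                    sff=bool(sff[i]),
                    ccrc=bool(ccrc[i]),
                    council=bool(council[i]),
                    ownership_changed=bool(changed[i]),
                    staffing_cna_hrd=round(float(cna[i]), 5),
                    staffing_lpn_hrd=round(float(lpn[i]), 5),
                    staffing_rn_hrd=round(float(rn[i]), 5),
                    five_star=int(five_star[i]),
                )
            )
        snapshots_by_date[date] = out
    return snapshots_by_date, crosswalk, fac_hrr


# ---------------------------------------------------------------------------
# Ownership planting


def _draw_group_sizes(
    rng: np.random.Generator, m: int, mean: float, max_size: int
) -> list[int]:
    """Partition m facilities into groups of >= 2 with shifted-geometric sizes."""
    if m < 2:
        return []
    p = 1.0 / (mean - 1.0) if mean > 2 else 1.0
    sizes: list[int] = []
    left = m
    while left > 0:
        s = 2 + (int(rng.geometric(p)) - 1 if p < 1.0 else 0)
        s = min(s, max_size, left)
        if left - s == 1:  # avoid stranding a singleton
            s += 1
        sizes.append(s)
        left -= s
    return sizes


def _decorate(rng: np.random.Generator, key: str) -> str:
    """Add punctuation/spacing/case noise that normalizes back to ``key``."""
    style = rng.integers(0, 5)
    if style == 0:
        return key
    if style == 1:
        return key.replace(" LLC", ", L.L.C.") if key.endswith(" LLC") else key + "."
    if style == 2:
        return key.replace(" ", "  ", 1)
    if style == 3:
        toks = key.split(" ")
        return (" ".join(toks[:-1]) + ", " + toks[-1]) if len(toks) > 1 else key
    return key.title()


def generate_ownership(
    config: GeneratorConfig,
    seed: int,
    snapshots_by_date: Mapping[int, Sequence[FacilitySnapshot]],
    fac_hrr: Mapping[str, str],
) -> tuple[dict[int, list[OwnerRecord]], dict[str, str], dict[str, list[frozenset]], dict[str, list[str]], int, int]:
    """Plant shared-owner groups and emit per-date owner tables.

    Within each HRR, a target share of facilities is partitioned into
    groups; each group is realized as one (sometimes two) owner keys held
    by every member.  Every facility additionally gets solo organization
    owners with unique keys, and individual owners are injected at the
    configured rate (they never create network ties).  Raw names are
    freshly decorated at every date.

    Raises :class:`ConfigError` when the prevalence target is unreachable
    (every HRR smaller than the minimum group size).
    """
    rng = np.random.default_rng(seed)
    pids = [s.provider_id for s in snapshots_by_date[min(snapshots_by_date)]]
    by_hrr: dict[str, list[str]] = {}
    for pid in pids:
        by_hrr.setdefault(fac_hrr[pid], []).append(pid)

    target = config.target_prevalence_multiple_pct
    if target > 0 and all(len(v) < 2 for v in by_hrr.values()):
        raise ConfigError(
            "prevalence target unreachable: no HRR holds two facilities"
        )

    affiliation = {pid: "single" for pid in pids}
    groups_by_hrr: dict[str, list[frozenset]] = {}
    shared_owner_keys: dict[str, list[tuple[frozenset, list[str]]]] = {}
    for hrr, members in sorted(by_hrr.items()):
        n_h = len(members)
        # each HRR draws its own prevalence around the national target
        # (the observed between-HRR spread is large); exact 0% and 100%
        # targets are honoured without noise
        target_h = target
        if 0.0 < target < 100.0 and config.prevalence_hrr_sd > 0:
            target_h = float(
                np.clip(rng.normal(target, config.prevalence_hrr_sd), 0.0, 100.0)
            )
        m = int(round(target_h / 100.0 * n_h))
        if m == 1:
            m = 2 if target_h >= 50 else 0
        m = min(m, n_h)
        sizes = _draw_group_sizes(rng, m, config.group_size_mean, config.group_size_max)
        chosen = [str(x) for x in rng.choice(members, size=sum(sizes), replace=False)]
        groups: list[frozenset] = []
        keyed: list[tuple[frozenset, list[str]]] = []
        pos = 0
        for gi, size in enumerate(sizes):
            grp = frozenset(chosen[pos : pos + size])
            pos += size
            groups.append(grp)
            for pid in grp:
                affiliation[pid] = "multiple"
            keys = [f"{hrr} GROUP {gi + 1} HOLDINGS LLC"]
            if rng.uniform() < config.second_shared_owner_prob:
                keys.append(f"{hrr} GROUP {gi + 1} REALTY TRUST")
            keyed.append((grp, keys))
        groups_by_hrr[hrr] = groups
        shared_owner_keys[hrr] = keyed

    individual_only = set()
    if config.pct_individual_only_facilities > 0:
        k = int(round(config.pct_individual_only_facilities * len(pids)))
        individual_only = set(
            rng.choice([p for p in pids if affiliation[p] == "single"], size=k, replace=False)
        )

    owners_by_provider: dict[str, list[str]] = {pid: [] for pid in pids}
    for hrr, keyed in shared_owner_keys.items():
        for grp, keys in keyed:
            for pid in grp:
                owners_by_provider[pid].extend(keys)
    for pid in pids:
        if pid in individual_only:
            owners_by_provider[pid] = []
            continue
        n_solo = 1 + int(rng.poisson(config.solo_owners_per_facility_mean))
        for j in range(n_solo):
            owners_by_provider[pid].append(f"PROVIDER {pid} OPERATIONS {j + 1} LLC")

    n_org = 0
    n_ind = 0
    owners_by_date: dict[int, list[OwnerRecord]] = {}
    first = " JAMES MARY ROBERT PATRICIA JOHN JENNIFER MICHAEL LINDA".split()
    last = "SMITH JOHNSON WILLIAMS BROWN JONES GARCIA MILLER DAVIS".split()
    for date in sorted(snapshots_by_date):
        recs: list[OwnerRecord] = []
        for pid in pids:
            for key in owners_by_provider[pid]:
                raw = _decorate(rng, key)
                recs.append(
                    OwnerRecord(
                        provider_id=pid,
                        owner_name_raw=raw,
                        owner_key=key,
                        owner_kind="organization",
                        date=date,
                    )
                )
                n_org += 1
            wants_individual = pid in individual_only or (
                rng.uniform() < config.pct_individual_owners
            )
            if wants_individual:
                name = f"{rng.choice(first)} {rng.choice(last)}"
                recs.append(
                    OwnerRecord(
                        provider_id=pid,
                        owner_name_raw=name,
                        owner_key=name.strip().upper(),
                        owner_kind="individual",
                        date=date,
                    )
                )
                n_ind += 1
        owners_by_date[date] = recs
    return owners_by_date, affiliation, groups_by_hrr, owners_by_provider, n_org, n_ind


# ---------------------------------------------------------------------------
# Truth metrics and outcomes


def _truth_metrics(
    config: GeneratorConfig,
    snapshots_by_date: Mapping[int, Sequence[FacilitySnapshot]],
    fac_hrr: Mapping[str, str],
    affiliation: Mapping[str, str],
    groups_by_hrr: Mapping[str, list[frozenset]],
) -> pd.DataFrame:
    """Per-HRR truth for prevalence, group size and concentration.

    Beds are static, so concentration truth is identical at every date;
    rows are replicated per date for a uniform join key.
    """
    first = snapshots_by_date[min(snapshots_by_date)]
    beds = {s.provider_id: float(s.beds) for s in first}
    rows = []
    by_hrr: dict[str, list[str]] = {}
    for pid, hrr in fac_hrr.items():
        by_hrr.setdefault(hrr, []).append(pid)
    for hrr, members in sorted(by_hrr.items()):
        groups = groups_by_hrr.get(hrr, [])
        n_multi = sum(1 for p in members if affiliation[p] == "multiple")
        h = mc.hhi([beds[p] for p in members])
        grouped = set().union(*groups) if groups else set()
        unit_beds = [sum(beds[p] for p in g) for g in groups]
        unit_beds += [beds[p] for p in members if p not in grouped]
        a = mc.hhi(unit_beds)
        sizes = [len(g) for g in groups]
        rows.append(
            {
                "hrr": hrr,
                "n_facilities": len(members),
                "n_multiple": n_multi,
                "prevalence_multiple_pct": 100.0 * n_multi / len(members),
                "mean_group_size": float(np.mean(sizes)) if sizes else 1.0,
                "n_groups": len(sizes),
                "hhi": h,
                "ahhi": a,
                "delta_hhi": a - h,
            }
        )
    per_hrr = pd.DataFrame(rows)
    dated = []
    for date in sorted(snapshots_by_date):
        d = per_hrr.copy()
        d["date"] = date
        dated.append(d)
    return pd.concat(dated, ignore_index=True)


def simulate_outcomes(
    config: GeneratorConfig,
    seed: int,
    frame: pd.DataFrame,
    spec: glmm.ModelSpec = RECOVERY_SPEC,
) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """Draw the deficiency counts from the planted mixed model.

    Builds the fixed-effect design on the supplied truth frame, aligns
    ``config.true_beta`` to its columns (absent names get 0), draws the
    state/HRR/facility intercepts and observation residuals at the
    configured variances, and samples y ~ Poisson(exp(linear predictor)).
    The raw score written to the table is the count plus sub-0.5 uniform
    jitter, so nearest-integer discretization recovers the count exactly.

    Raises :class:`ConfigError` if any linear predictor exceeds 30.
    """
    rng = np.random.default_rng(seed)
    work = frame.copy()
    work["twhss_int"] = 0  # placeholder; design needs the column present
    work["twhss"] = 0.0
    bundle = glmm.build_design(work, spec, check_rank=False)
    beta = np.array([config.true_beta.get(c, 0.0) for c in bundle.colnames])
    eta = bundle.X @ beta
    sig = {
        "state": config.sigma2_state,
        "hrr": config.sigma2_hrr,
        "facility": config.sigma2_facility,
        "obs": config.sigma2_obs,
    }
    for name, codes in bundle.factor_codes.items():
        nl = len(bundle.factor_levels[name])
        u = rng.normal(0.0, math.sqrt(sig[name]), nl)
        eta = eta + u[codes]
    if np.max(eta) > 30:
        raise ConfigError(f"linear predictor overflow (max eta {np.max(eta):.1f})")
    y = rng.poisson(np.exp(eta))
    jitter = rng.uniform(-0.3, 0.3, size=y.shape)
    twhss = np.where(y == 0, np.abs(jitter), y + jitter)

    keyed = bundle.row_index.copy()
    keyed["twhss"] = twhss
    keyed["twhss_int"] = y
    out = frame.drop(columns=["twhss", "twhss_int"], errors="ignore").merge(
        keyed, on=["provider_id", "date"], how="left"
    )
    return out, bundle.colnames, beta


def generate(config: GeneratorConfig, seed: int) -> SyntheticData:
    """Full generation pass: facilities, ownership, MDS, outcomes, truth.

    All randomness flows from ``seed`` through fixed per-stage offsets, so
    two calls with the same arguments produce identical tables.
    """
    snapshots_by_date, crosswalk, fac_hrr = generate_facilities(config, seed)
    (
        owners_by_date,
        affiliation,
        groups_by_hrr,
        owners_by_provider,
        n_org,
        n_ind,
    ) = generate_ownership(config, seed + 1, snapshots_by_date, fac_hrr)
    truth_metrics = _truth_metrics(
        config, snapshots_by_date, fac_hrr, affiliation, groups_by_hrr
    )

    # MDS prevalences: per-code national mean, facility-level spread,
    # missingness knocks single codes out of single dates.
    rng = np.random.default_rng(seed + 2)
    code_means = {c: rng.uniform(2.0, 30.0) for c in config.mds_codes}
    pids = [s.provider_id for s in snapshots_by_date[min(snapshots_by_date)]]
    base = {
        pid: {
            c: round(
                float(np.clip(rng.normal(code_means[c], code_means[c] / 3.0), 0.0, 100.0)),
                3,
            )
            for c in config.mds_codes
        }
        for pid in pids
    }
    missing_fac = set(
        rng.choice(pids, size=int(round(config.mds_missing_rate * len(pids))), replace=False)
    )
    mds_by_date: dict[int, dict[str, dict[int, float]]] = {}
    for date in sorted(snapshots_by_date):
        table: dict[str, dict[int, float]] = {}
        for pid in pids:
            vals = {
                c: round(float(np.clip(v + rng.normal(0, 0.5), 0.0, 100.0)), 3)
                for c, v in base[pid].items()
            }
            table[pid] = vals
        mds_by_date[date] = table
    for pid in missing_fac:
        date = int(rng.integers(1, config.n_dates + 1))
        code = int(rng.choice(config.mds_codes))
        mds_by_date[date][pid].pop(code, None)

    # attach MDS to snapshots and resolve HRR for the truth frame
    for date, snaps in snapshots_by_date.items():
        for s in snaps:
            s.mds = dict(mds_by_date[date][s.provider_id])

    truth = GroundTruth(
        affiliation=affiliation,
        groups_by_hrr=groups_by_hrr,
        hrr_metrics=truth_metrics,
        owners_by_provider=owners_by_provider,
        n_individual_records=n_ind,
        n_org_records=n_org,
        true_beta=dict(config.true_beta),
        sigma2={
            "state": config.sigma2_state,
            "hrr": config.sigma2_hrr,
            "facility": config.sigma2_facility,
            "obs": config.sigma2_obs,
        },
    )
    data = SyntheticData(
        config=config,
        seed=seed,
        snapshots_by_date=snapshots_by_date,
        owners_by_date=owners_by_date,
        mds_by_date=mds_by_date,
        crosswalk=crosswalk,
        truth=truth,
    )

    frame = data.model_frame(require_outcome=False)
    simulated, colnames, beta = simulate_outcomes(config, seed + 3, frame)
    truth.design_colnames = colnames
    truth.beta_vector = beta
    lookup = {
        (p, d): (t, ti)
        for p, d, t, ti in zip(
            simulated["provider_id"],
            simulated["date"],
            simulated["twhss"],
            simulated["twhss_int"],
        )
    }
    for date, snaps in snapshots_by_date.items():
        for s in snaps:
            t, ti = lookup[(s.provider_id, date)]
            s.twhss = round(float(t), 4)
            s.twhss_int = round_half_away(s.twhss)
            assert s.twhss_int == int(ti)
    return data


# ---------------------------------------------------------------------------
# Fixture emission


def emit_fixture(config: GeneratorConfig, seed: int, out_dir) -> dict[str, list[str]]:
    """Write the synthetic tables as NHC-dialect CSVs plus truth JSON.

    Emits one provider, ownership and MDS CSV per date, a single
    crosswalk, and ``ground_truth.json``; the files round-trip through
    the IO layer unchanged.  Returns the written paths by table kind.
    """
    data = generate(config, seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    c = DEFAULT_PROVIDER_COLUMNS
    paths: dict[str, list[str]] = {"provider": [], "ownership": [], "mds": []}

    for date in sorted(data.snapshots_by_date):
        rows = []
        for s in data.snapshots_by_date[date]:
            rows.append(
                {
                    c["provider_id"]: s.provider_id,
                    c["zip"]: s.zip,
                    c["state"]: s.state,
                    c["beds"]: s.beds,
                    c["residents"]: s.residents,
                    c["occupancy_pct"]: round(s.occupancy_pct, 4),
                    c["years_in_business"]: round(s.years_in_business, 2),
                    c["ownership_type"]: {
                        "for-profit": "For profit - Corporation",
                        "government": "Government - City/county",
                        "non-profit": "Non profit - Corporation",
                    }[s.ownership_type],
                    c["hospital_based"]: "YES" if s.hospital_based else "NO",
                    c["sff"]: "YES" if s.sff else "NO",
                    c["ccrc"]: "YES" if s.ccrc else "NO",
                    c["council"]: "Resident" if s.council else "None",
                    c["ownership_changed"]: "YES" if s.ownership_changed else "NO",
                    c["staffing_cna_hrd"]: round(s.staffing_cna_hrd, 5),
                    c["staffing_lpn_hrd"]: round(s.staffing_lpn_hrd, 5),
                    c["staffing_rn_hrd"]: round(s.staffing_rn_hrd, 5),
                    c["five_star"]: s.five_star,
                    c["twhss"]: round(s.twhss, 4),
                }
            )
        p = out_dir / f"provider_d{date}.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        paths["provider"].append(str(p))

        oc = DEFAULT_OWNERSHIP_COLUMNS
        orows = [
            {
                oc["provider_id"]: r.provider_id,
                oc["owner_name"]: r.owner_name_raw,
                oc["owner_kind"]: "Individual" if r.owner_kind == "individual" else "Organization",
            }
            for r in data.owners_by_date[date]
        ]
        p = out_dir / f"ownership_d{date}.csv"
        pd.DataFrame(orows).to_csv(p, index=False)
        paths["ownership"].append(str(p))

        mcols = DEFAULT_MDS_COLUMNS
        mrows = [
            {
                mcols["provider_id"]: pid,
                mcols["code"]: code,
                mcols["score"]: round(val, 3),
            }
            for pid, codes in sorted(data.mds_by_date[date].items())
            for code, val in sorted(codes.items())
        ]
        p = out_dir / f"mds_d{date}.csv"
        pd.DataFrame(mrows).to_csv(p, index=False)
        paths["mds"].append(str(p))

    xc = DEFAULT_CROSSWALK_COLUMNS
    xrows = [
        {xc["zip"]: z, xc["hrr_id"]: h, xc["hrr_name"]: name}
        for z, (h, name) in sorted(data.crosswalk.entries.items())
    ]
    xw = out_dir / "crosswalk.csv"
    pd.DataFrame(xrows).to_csv(xw, index=False)
    paths["crosswalk"] = [str(xw)]

    truth_path = out_dir / "ground_truth.json"
    truth = data.truth
    with truth_path.open("w") as fh:
        json.dump(
            {
                "affiliation": truth.affiliation,
                "groups_by_hrr": {
                    h: [sorted(g) for g in gs] for h, gs in truth.groups_by_hrr.items()
                },
                "hrr_metrics": truth.hrr_metrics.to_dict(orient="records"),
                "true_beta": truth.true_beta,
                "sigma2": truth.sigma2,
                "design_colnames": truth.design_colnames,
                "beta_vector": list(map(float, truth.beta_vector)),
                "n_individual_records": truth.n_individual_records,
                "n_org_records": truth.n_org_records,
            },
            fh,
            indent=1,
        )
    paths["ground_truth"] = [str(truth_path)]
    return paths


def load_fixture(fixture_dir) -> Panel:
    """Read an emitted fixture back through the IO layer into a Panel."""
    from . import nhc_io

    fixture_dir = Path(fixture_dir)
    crosswalk = nhc_io.read_crosswalk(fixture_dir / "crosswalk.csv")
    snapshots = {}
    owners = {}
    mds = {}
    for p in sorted(fixture_dir.glob("provider_d*.csv")):
        date = int(p.stem.split("_d")[1])
        snapshots[date] = nhc_io.read_provider_table(p, date)
        owners[date] = nhc_io.read_ownership_table(
            fixture_dir / f"ownership_d{date}.csv", date
        )
        mpath = fixture_dir / f"mds_d{date}.csv"
        if mpath.exists():
            mds[date] = nhc_io.read_mds_table(mpath, date)
    return assemble_panel(snapshots, owners, crosswalk, mds_by_date=mds)
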