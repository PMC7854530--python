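"""HRR-level explanatory variables and national summary tables.

Step one of the two-step procedure: for every hospital referral region and
processing date, derive the five super-organization covariates that enter
the regression — prevalence of multiple-affiliation facilities, mean
ownership-group size, HHI, AHHI and dHHI — plus the bookkeeping counts
(facilities, groups, co-owning organizations).  The national summary
averages those covariates *unweighted across HRRs* (the focal area, not
the facility, is the unit) with sample standard deviations, and sums the
counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import market_concentration as mc
from . import ownership_network as net
from .name_matching import filter_registered_organizations
from .nhc_io import Panel

logger = logging.getLogger(__name__)

HRR_VARIABLES = (
    "prevalence_multiple_pct",
    "mean_group_size",
    "hhi",
    "ahhi",
    "delta_hhi",
)


@dataclass
class HrrNetwork:
    """All network-stage outputs for one HRR at one date."""

    hrr: str
    date: int
    bipartite: net.BipartiteGraph
    projection: net.FacilityProjection
    classes: list[net.AffiliationClass]
    groups: list[net.OwnershipGroup]
    concentration: mc.ConcentrationRecord


@dataclass(frozen=True)
class HRRMetrics:
    hrr: str
    date: int
    n_facilities: int
    n_multiple: int
    prevalence_multiple_pct: float
    mean_group_size: float
    group_size_imputed: bool  # True when the HRR has no groups at all
    hhi: float
    ahhi: float
    delta_hhi: float
    n_groups: int
    n_coowners: int


@dataclass
class NationalSummary:
    date: int
    means: dict[str, float]
    sds: dict[str, float]
    totals: dict[str, int]
    degenerate: bool = False  # single-HRR sample, SDs reported as 0


def derive_hrr_networks(
    panel: Panel,
    seed: int = net.DEFAULT_SEED,
    resolution: float = net.DEFAULT_RESOLUTION,
    complete_only: bool = True,
) -> dict[tuple[str, int], HrrNetwork]:
    """Run the full network stage for every (HRR, date) in the panel.

    Owner records are filtered to registered organizations; facilities are
    restricted to the complete-case cohort by default.  HRRs with zero
    facilities at a date are omitted (logged).
    """
    out: dict[tuple[str, int], HrrNetwork] = {}
    for date in panel.dates:
        snaps = [
            s
            for s in panel.snapshots(date)
            if s.hrr is not None
            and (not complete_only or s.provider_id in panel.complete_providers)
        ]
        owners = filter_registered_organizations(panel.owners(date))
        pids = {s.provider_id for s in snaps}
        owners = [r for r in owners if r.provider_id in pids]
        by_hrr: dict[str, list] = {}
        for s in snaps:
            by_hrr.setdefault(s.hrr, []).append(s)
        for hrr, facs in sorted(by_hrr.items()):
            bip = net.build_bipartite(owners, facs, hrr, date)
            proj = net.project_facilities(bip)
            classes = net.classify_affiliation(proj)
            groups = net.detect_ownership_groups(proj, seed=seed, resolution=resolution)
            beds = {f.provider_id: float(f.beds or 0) for f in facs}
            grouped = set().union(*(g.members for g in groups)) if groups else set()
            singles = [p for p in beds if p not in grouped]
            try:
                conc = mc.concentration_record(hrr, date, beds, groups, singles)
            except mc.UndefinedMarketError:
                logger.warning("HRR %s date %s has no certified beds; skipped", hrr, date)
                continue
            out[(hrr, date)] = HrrNetwork(
                hrr=hrr,
                date=date,
                bipartite=bip,
                projection=proj,
                classes=classes,
                groups=groups,
                concentration=conc,
            )
    return out


def compute_hrr_metrics(
    networks: Mapping[tuple[str, int], HrrNetwork],
) -> list[HRRMetrics]:
    """One metrics record per HRR x date from the network-stage outputs.

    ``mean_group_size`` is the mean of Louvain group sizes; an HRR with no
    groups (every facility standalone) gets 1.0 with the imputation flag
    set, so the regression covariate is defined everywhere.
    """
    out = []
    for (hrr, date), nw in sorted(networks.items()):
        n_fac = len(nw.projection.nodes)
        if n_fac == 0:
            logger.warning("HRR %s date %s has zero facilities; omitted", hrr, date)
            continue
        n_multi = sum(1 for c in nw.classes if c.affiliation == "multiple")
        sizes = [g.size for g in nw.groups]
        if sizes:
            mgs, imputed = float(np.mean(sizes)), False
        else:
            mgs, imputed = 1.0, True
        out.append(
            HRRMetrics(
                hrr=hrr,
                date=date,
                n_facilities=n_fac,
                n_multiple=n_multi,
                prevalence_multiple_pct=100.0 * n_multi / n_fac,
                mean_group_size=mgs,
                group_size_imputed=imputed,
                hhi=nw.concentration.hhi,
                ahhi=nw.concentration.ahhi,
                delta_hhi=nw.concentration.delta,
                n_groups=len(nw.groups),
                n_coowners=net.count_coowning_organizations(nw.bipartite, nw.groups),
            )
        )
    return out


def metrics_frame(metrics: Sequence[HRRMetrics]) -> pd.DataFrame:
    return pd.DataFrame([m.__dict__ for m in metrics])


def national_summary(metrics: Sequence[HRRMetrics], date: int) -> NationalSummary:
    """Unweighted across-HRR means and sample SDs at one processing date."""
    rows = [m for m in metrics if m.date == date]
    if not rows:
        raise ValueError(f"no HRR metrics for date {date}")
    means, sds = {}, {}
    degenerate = len(rows) < 2
    for var in HRR_VARIABLES:
        vals = np.array([getattr(r, var) for r in rows], dtype=float)
        means[var] = float(vals.mean())
        sds[var] = 0.0 if degenerate else float(vals.std(ddof=1))
    totals = {
        "n_facilities": int(sum(r.n_facilities for r in rows)),
        "n_multiple": int(sum(r.n_multiple for r in rows)),
        "n_coowners": int(sum(r.n_coowners for r in rows)),
        "n_groups": int(sum(r.n_groups for r in rows)),
        "n_hrrs": len(rows),
    }
    return NationalSummary(date=date, means=means, sds=sds, totals=totals, degenerate=degenerate)


def summary_frame(summaries: Sequence[NationalSummary]) -> pd.DataFrame:
    """Wide national-summary table, one column pair (mean, SD) per date."""
    rows = []
    for var in HRR_VARIABLES:
        row: dict = {"variable": var}
        for s in summaries:
            row[f"mean_d{s.date}"] = s.means[var]
            row[f"sd_d{s.date}"] = s.sds[var]
        rows.append(row)
    for tot in ("n_facilities", "n_multiple", "n_coowners", "n_groups"):
        row = {"variable": tot}
        for s in summaries:
            row[f"mean_d{s.date}"] = s.totals[tot]
            row[f"sd_d{s.date}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_shares(counts: Mapping[str, float], decimals: int = 1) -> dict[str, float]:
    """Percentage shares of category counts, rounded to a fixed precision.

    Used for the ownership-type composition of the cohort (facilities or
    residents).  Shares are computed against the sum of the supplied
    counts.
    """
    total = float(sum(counts.values()))
    if total <= 0:
        raise ValueError("cohort shares need a positive total")
    return {k: round(100.0 * v / total, decimals) for k, v in counts.items()}
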