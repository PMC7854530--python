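import warnings

import pytest

warnings.filterwarnings("ignore", message=".*ArviZ.*")

from nhnet.nhc_io import FacilitySnapshot, OwnerRecord
from nhnet import synthetic_data as synth


def make_snapshot(pid, date=1, hrr="H1", **kw):
    defaults = dict(
        zip="90000",
        state="AA",
        beds=100,
        residents=80,
        occupancy_pct=80.0,
        years_in_business=20.0,
        ownership_type="for-profit",
        hospital_based=False,
        sff=False,
        ccrc=False,
        council=True,
        ownership_changed=False,
        staffing_cna_hrd=2.3,
        staffing_lpn_hrd=0.8,
        staffing_rn_hrd=0.6,
        five_star=3,
        twhss=50.0,
        twhss_int=50,
    )
    defaults.update(kw)
    return FacilitySnapshot(provider_id=pid, date=date, hrr=hrr, **defaults)


def org_owner(pid, key, date=1):
    return OwnerRecord(
        provider_id=pid,
        owner_name_raw=key,
        owner_key=key,
        owner_kind="organization",
        date=date,
    )


@pytest.fixture(scope="session")
def fig2_hrr():
    """A 14-facility HRR with two planted ownership groups.

    Eight facilities share owners (one group of five, one of three) and
    six are isolated in the projection; every facility also holds a solo
    owner so isolation comes from lack of *shared* ownership, not lack of
    owners.
    """
    facs = [make_snapshot(f"F{i:02d}") for i in range(14)]
    owners = []
    for i, f in enumerate(facs):
        owners.append(org_owner(f.provider_id, f"SOLO OPERATOR {i} LLC"))
    for pid in ["F00", "F01", "F02", "F03", "F04"]:
        owners.append(org_owner(pid, "BIG GROUP HOLDINGS LLC"))
    for pid in ["F05", "F06", "F07"]:
        owners.append(org_owner(pid, "SMALL GROUP REALTY TRUST"))
    return facs, owners


@pytest.fixture(scope="session")
def small_synth():
    """A modest synthetic panel shared across tests (deterministic)."""
    cfg = synth.GeneratorConfig(n_facilities=150, n_hrrs=6, n_states=3, n_dates=3)
    return synth.generate(cfg, 42)
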