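import copy

import pytest

from nhnet import nhc_io
from nhnet.nhc_io import (
    CrosswalkError,
    FormatError,
    LinkageError,
    assemble_panel,
    read_crosswalk,
    read_ownership_table,
    read_provider_table,
    read_panel,
    round_half_away,
    write_panel,
)
from nhnet import synthetic_data as synth

PROVIDER_HEADER = (
    "Federal Provider Number,Provider Zip Code,Provider State,"
    "Number of Certified Beds,Number of Residents in Certified Beds,"
    "Ownership Type,Total Weighted Health Survey Score,Occupancy Percentage"
)


def provider_csv(tmp_path, rows, header=PROVIDER_HEADER, name="prov.csv"):
    p = tmp_path / name
    p.write_text(header + "\n" + "\n".join(rows) + "\n")
    return p


class TestProviderTable:
    def test_row_count_preserved(self, tmp_path):
        p = provider_csv(
            tmp_path,
            [
                "015009,36301,AL,57,49,For profit - Corporation,54.48,86.0",
                "015010,36302,AL,90,70,Government - State,12.0,77.8",
                "015011,36303,AL,50,40,Non profit - Corporation,3.2,80.0",
            ],
        )
        snaps = read_provider_table(p, date=1)
        assert len(snaps) == 3
        assert snaps[0].twhss_int == 54  # 54.48 discretized to nearest integer
        assert snaps[0].ownership_type == "for-profit"
        assert snaps[1].ownership_type == "government"

    def test_occupancy_above_100_flagged(self, tmp_path):
        p = provider_csv(
            tmp_path, ["015009,36301,AL,57,49,For profit - LLC,54.48,101"]
        )
        (snap,) = read_provider_table(p, date=1)
        assert "occupancy_out_of_range" in snap.flags

    def test_residents_exceeding_beds_flagged(self, tmp_path):
        p = provider_csv(tmp_path, ["015009,36301,AL,40,49,For profit - LLC,1,90"])
        (snap,) = read_provider_table(p, date=1)
        assert "residents_exceed_beds" in snap.flags

    def test_missing_required_column_names_it(self, tmp_path):
        p = tmp_path / "bad.csv"
        header = PROVIDER_HEADER.replace("Number of Certified Beds,", "")
        p.write_text(header + "\n015009,36301,AL,49,For profit - LLC,5,86\n")
        with pytest.raises(FormatError, match="Number of Certified Beds"):
            read_provider_table(p, date=1)

    def test_duplicate_provider_is_linkage_error(self, tmp_path):
        p = provider_csv(
            tmp_path,
            [
                "015009,36301,AL,57,49,For profit - LLC,5,86",
                "015009,36301,AL,57,49,For profit - LLC,5,86",
            ],
        )
        with pytest.raises(LinkageError, match="015009"):
            read_provider_table(p, date=1)

    def test_column_mapping_from_yaml_file(self, tmp_path):
        header = PROVIDER_HEADER.replace(
            "Total Weighted Health Survey Score", "Weighted Survey Score (2019)"
        )
        p = provider_csv(
            tmp_path,
            ["015009,36301,AL,57,49,For profit - LLC,54.48,86.0"],
            header=header,
        )
        mapping = tmp_path / "columns.yaml"
        mapping.write_text("twhss: Weighted Survey Score (2019)\n")
        (snap,) = read_provider_table(p, date=1, columns=mapping)
        assert snap.twhss_int == 54

    def test_missing_covariate_left_none(self, tmp_path):
        p = provider_csv(tmp_path, ["015009,36301,AL,57,49,For profit - LLC,5,"])
        (snap,) = read_provider_table(p, date=1)
        # occupancy column empty -> derived from residents/beds instead
        assert snap.occupancy_pct == pytest.approx(100 * 49 / 57)
        assert snap.staffing_rn_hrd is None


@pytest.mark.parametrize(
    "value,expected", [(54.48, 54), (54.5, 55), (0.49, 0), (-1.5, -2), (63.55, 64)]
)
def test_round_half_away(value, expected):
    assert round_half_away(value) == expected


class TestOwnershipTable:
    HEADER = "Federal Provider Number,Owner Name,Owner Type"

    def test_key_normalized(self, tmp_path):
        p = tmp_path / "own.csv"
        p.write_text(
            self.HEADER + '\n015009,"ABC HEALTH, L.L.C.",Organization\n'
        )
        (rec,) = read_ownership_table(p, date=1)
        assert rec.owner_key == "ABC HEALTH LLC"
        assert rec.owner_kind == "organization"

    def test_individual_kind_and_shared_keys(self, tmp_path):
        p = tmp_path / "own.csv"
        p.write_text(
            self.HEADER
            + "\n015009,JOHN SMITH,Individual\n"
            + "015010,ACME TRUST,Organization\n"
            + "015011,ACME TRUST.,Organization\n"
        )
        recs = read_ownership_table(p, date=1)
        assert recs[0].owner_kind == "individual"
        assert recs[1].owner_key == recs[2].owner_key
        assert recs[1].provider_id != recs[2].provider_id

    def test_empty_owner_name_skipped(self, tmp_path):
        p = tmp_path / "own.csv"
        p.write_text(self.HEADER + "\n015009,,Organization\n015010,OK LLC,Organization\n")
        recs = read_ownership_table(p, date=1)
        assert len(recs) == 1


class TestCrosswalk:
    def test_lookup_and_missing_zip(self, tmp_path):
        p = tmp_path / "xw.csv"
        p.write_text("ZIP Code,HRR Name,HRR ID\n36301,Dothan AL,H001\n36302,Dothan AL,H001\n")
        xw = read_crosswalk(p)
        assert xw.lookup("36301") == "H001"
        with pytest.raises(CrosswalkError, match="99999"):
            xw.lookup("99999")

    def test_conflicting_duplicate_rejected(self, tmp_path):
        p = tmp_path / "xw.csv"
        p.write_text("ZIP Code,HRR Name,HRR ID\n36301,A,H001\n36301,B,H002\n")
        with pytest.raises(FormatError):
            read_crosswalk(p)

    def test_full_hrr_coverage_count(self, tmp_path):
        # the national crosswalk places ZIPs into 306 regions
        p = tmp_path / "xw.csv"
        lines = ["ZIP Code,HRR Name,HRR ID"]
        for i in range(306):
            lines.append(f"{10000 + i:05d},Region {i},H{i + 1:03d}")
        p.write_text("\n".join(lines) + "\n")
        assert read_crosswalk(p).n_hrrs == 306


class TestAssemblePanel:
    def test_provider_absent_at_one_date_excluded(self, small_synth):
        data = copy.deepcopy(small_synth)
        victim = data.snapshots_by_date[1][0].provider_id
        data.snapshots_by_date[2] = [
            s for s in data.snapshots_by_date[2] if s.provider_id != victim
        ]
        panel = data.assemble()
        assert victim not in panel.complete_providers
        assert any("absent at dates" in r for r in panel.incomplete_reasons[victim])

    def test_individual_only_owners_excluded(self, small_synth):
        data = copy.deepcopy(small_synth)
        victim = data.snapshots_by_date[1][0].provider_id
        for date, recs in data.owners_by_date.items():
            data.owners_by_date[date] = [
                r for r in recs if r.provider_id != victim
            ] + [
                nhc_io.OwnerRecord(
                    provider_id=victim,
                    owner_name_raw="JANE DOE",
                    owner_key="JANE DOE",
                    owner_kind="individual",
                    date=date,
                )
            ]
        panel = data.assemble()
        assert victim not in panel.complete_providers

    def test_missing_covariates_shrink_complete_set(self):
        cfg = synth.GeneratorConfig(n_facilities=100, n_hrrs=4, n_states=2, n_dates=2)
        data = synth.generate(cfg, 7)
        victims = sorted(s.provider_id for s in data.snapshots_by_date[1])[:10]
        for s in data.snapshots_by_date[2]:
            if s.provider_id in victims:
                s.staffing_rn_hrd = None
        panel = data.assemble()
        assert len(panel.complete_providers) == 90

    def test_completeness_filter_monotone(self, small_synth):
        data = copy.deepcopy(small_synth)
        for s in data.snapshots_by_date[1][:5]:
            s.five_star = None
        without = data.assemble(
            required_covariates=[c for c in nhc_io.MODEL1_COVARIATES if c != "five_star"]
        )
        with_fs = data.assemble(required_covariates=nhc_io.MODEL1_COVARIATES)
        assert with_fs.complete_providers <= without.complete_providers
        assert len(with_fs.complete_providers) < len(without.complete_providers)

    def test_every_complete_provider_resolves_hrr(self, small_synth):
        panel = small_synth.assemble()
        for date in panel.dates:
            for s in panel.snapshots(date):
                if s.provider_id in panel.complete_providers:
                    assert s.hrr is not None and s.state

    def test_empty_input_gives_empty_panel(self):
        xw = nhc_io.ZipHrrMap(entries={"00001": ("H1", "One")})
        panel = assemble_panel({1: []}, {1: []}, xw)
        assert panel.complete_providers == set()


def test_panel_round_trip(tmp_path, small_synth):
    panel = small_synth.assemble()
    path = tmp_path / "panel.jsonl"
    write_panel(panel, path)
    back = read_panel(path)
    assert back.dates == panel.dates
    assert back.complete_providers == panel.complete_providers
    for date in panel.dates:
        orig = {s.provider_id: s for s in panel.snapshots(date)}
        loaded = {s.provider_id: s for s in back.snapshots(date)}
        assert orig.keys() == loaded.keys()
        for pid in orig:
            assert orig[pid] == loaded[pid]
        assert panel.owners(date) == back.owners(date)
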