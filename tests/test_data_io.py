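"""Zone-table IO, subsetting rules, pipeline orchestration and CLI."""

import dataclasses
import json

import numpy as np
import pytest
from click.testing import CliRunner

import boundline as bl
from boundline.cli import main as cli_main
from boundline.data_io import PH_INTERVALS, depth_class_from_cm
from conftest import FAST_FIT, FAST_FIT_NOCOV


@pytest.fixture()
def records():
    spec = bl.GeneratorSpec(n_farms=4, zones_per_farm=9, rng_seed=8)
    return bl.generate_zones(spec)


class TestReadWrite:
    def test_round_trip_preserves_everything(self, records, tmp_path):
        p = tmp_path / "zones.csv"
        bl.write_zone_table(records, p)
        back = bl.read_zone_table(p)
        assert back == records

    def test_tab_separated_round_trip(self, records, tmp_path):
        p = tmp_path / "zones.tsv"
        bl.write_zone_table(records, p, sep="\t")
        assert bl.read_zone_table(p) == records

    def test_dialect_remapping_equals_canonical(self, records, tmp_path):
        p = tmp_path / "zones.csv"
        bl.write_zone_table(records, p)
        txt = p.read_text().replace("yield_t_ha", "Yield (t/ha)", 1)
        txt = txt.replace("mg_mgL", "Mg mg/l", 1)
        q = tmp_path / "alt.csv"
        q.write_text(txt)
        back = bl.read_zone_table(
            q, dialect={"yield_t_ha": "Yield (t/ha)", "mg_mgL": "Mg mg/l"}
        )
        assert back == records

    def test_well_formed_rows_all_kept(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "zone_id,farm_id,east,north,season,crop,yield_t_ha\n"
            "z1,f1,0,0,2016,feed,8.1\nz2,f1,10,0,2016,feed,9.2\n"
            "z3,f1,20,0,2016,milling,7.7\n"
        )
        assert len(bl.read_zone_table(p)) == 3

    def test_invalid_rows_dropped_with_log(self, tmp_path, caplog):
        p = tmp_path / "t.csv"
        p.write_text(
            "zone_id,farm_id,east,north,season,crop,yield_t_ha\n"
            "z1,f1,0,0,2016,feed,8.1\nz2,f1,10,0,2016,feed,-3.0\n"
        )
        with caplog.at_level("WARNING"):
            recs = bl.read_zone_table(p)
        assert len(recs) == 1
        assert any("dropp" in m for m in caplog.text.splitlines())

    def test_missing_mandatory_column_is_hard_error(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("zone_id,farm_id,east,north,season,crop\nz,f,0,0,2016,feed\n")
        with pytest.raises(ValueError, match="yield_t_ha"):
            bl.read_zone_table(p)

    def test_duplicate_zone_season_dropped(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "zone_id,farm_id,east,north,season,crop,yield_t_ha\n"
            "z1,f1,0,0,2016,feed,8.1\nz1,f1,5,5,2016,feed,9.0\n"
            "z1,f1,5,5,2017,feed,9.0\n"
        )
        assert len(bl.read_zone_table(p)) == 2


def _zone(zid, ph=None, depth=None, crop="feed", season=2016):
    return bl.ZoneRecord(zid, "f", 0.0, 0.0, season, crop, 8.0, ph=ph,
                         depth_class=depth)


class TestSubsetting:
    def test_ph_boundary_closed_on_the_right(self):
        at7 = _zone("a", ph=7.0)
        just_above = _zone("b", ph=7.0001)
        assert bl.subset_records([at7, just_above], "ph<=7") == [at7]
        assert bl.subset_records([at7], "7<ph<=7.5") == []
        at75 = _zone("c", ph=7.5)
        assert bl.subset_records([at75], "7<ph<=7.5") == [at75]

    def test_ph_intervals_partition_records_with_ph(self, rng):
        recs = [_zone(str(i), ph=float(p))
                for i, p in enumerate(rng.uniform(3.5, 9.5, 200))]
        recs.append(_zone("nop", ph=None))
        subsets = [bl.subset_records(recs, r) for r in PH_INTERVALS]
        ids = [r.zone_id for s in subsets for r in s]
        assert len(ids) == len(set(ids)) == 200

    def test_depth_rule_selects_exactly_that_class(self):
        recs = [_zone(str(i), depth=d)
                for i, d in enumerate(["deep", "shallow", "deep", "medium", None])]
        got = bl.subset_records(recs, "depth:deep")
        assert [r.zone_id for r in got] == ["0", "2"]

    def test_crop_and_season_rules(self):
        recs = [_zone("a", crop="milling"), _zone("b"), _zone("c", season=2017)]
        assert [r.zone_id for r in bl.subset_records(recs, "crop:milling")] == ["a"]
        assert [r.zone_id for r in bl.subset_records(recs, "season:2017")] == ["c"]

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            bl.subset_records([], "ph<42")

    def test_numeric_depth_binning(self):
        assert depth_class_from_cm(29.9) == "shallow"
        assert depth_class_from_cm(30.0) == "medium"
        assert depth_class_from_cm(50.0) == "medium"
        assert depth_class_from_cm(50.1) == "deep"


class TestRunAnalysis:
    def test_too_few_records_is_a_precondition_error(self):
        recs = bl.generate_zones(bl.GeneratorSpec(n_farms=1, zones_per_farm=10,
                                                  rng_seed=0))
        with pytest.raises(ValueError, match="usable records"):
            bl.run_analysis(recs, bl.AnalysisConfig(nutrient="Mg"))

    def test_censored_data_selects_boundary_and_infers_crit(self):
        recs = bl.generate_zones(bl.GeneratorSpec(n_farms=60, rng_seed=0))
        cfg = bl.AnalysisConfig(nutrient="Mg", n_mc_draws=20_000, rng_seed=0,
                                fit=FAST_FIT)
        rep = bl.run_analysis(recs, cfg)
        assert rep.stage_errors == {}
        assert rep.transform.applied
        assert rep.comparison.selected == "BL"
        assert rep.crit is not None
        # truth exp((13.64+21.05)/10.15) = 30.5 mg/L
        assert 20.0 < rep.crit.point_mgL < 45.0
        assert 0.3 < rep.sigma_e < 0.8

    def test_uncensored_iid_data_rejects_boundary_usually(self):
        wins = 0
        for seed in range(5):
            spec = bl.GeneratorSpec(n_farms=40, spatial=None, boundary=None,
                                    rng_seed=seed)
            recs = bl.generate_zones(spec)
            cfg = bl.AnalysisConfig(nutrient="Mg", rng_seed=seed, fit=FAST_FIT_NOCOV)
            rep = bl.run_analysis(recs, cfg)
            wins += rep.comparison.selected == "BL"
        assert wins <= 1

    def test_report_serializes_and_tables_export(self, tmp_path):
        recs = bl.generate_zones(bl.GeneratorSpec(n_farms=60, rng_seed=1))
        cfg = bl.AnalysisConfig(nutrient="Mg", n_mc_draws=20_000, fit=FAST_FIT)
        rep = bl.run_analysis(recs, cfg)
        d = json.loads(rep.to_json(tmp_path / "rep.json"))
        assert {"config", "models", "selection"} <= set(d)
        from boundline.pipeline import write_report_tables
        paths = write_report_tables(rep, tmp_path / "tables")
        assert all(p.exists() for p in paths)
        assert not rep.model_table().empty
        assert list(rep.params_table()["parameter"]) == ["beta2", "beta0", "beta1"]


class TestCli:
    def test_simulate_fit_report_round_trip(self, tmp_path):
        runner = CliRunner()
        zones = tmp_path / "zones.csv"
        rep = tmp_path / "rep.json"
        r = runner.invoke(cli_main, ["simulate", "--out", str(zones),
                                     "--seed", "0", "--n-farms", "60"])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, ["fit", "--input", str(zones), "--out",
                                     str(rep), "--nutrient", "Mg",
                                     "--draws", "20000", "--seed", "1"])
        assert r.exit_code == 0, r.output
        out_dir = tmp_path / "tables"
        r = runner.invoke(cli_main, ["report", "--report", str(rep),
                                     "--out-dir", str(out_dir)])
        assert r.exit_code == 0, r.output
        assert (out_dir / "models.csv").exists()

    def test_fit_fails_cleanly_on_tiny_input(self, tmp_path):
        runner = CliRunner()
        zones = tmp_path / "zones.csv"
        runner.invoke(cli_main, ["simulate", "--out", str(zones), "--seed", "0",
                                 "--n-farms", "1"])
        r = runner.invoke(cli_main, ["fit", "--input", str(zones), "--out",
                                     str(tmp_path / "r.json"), "--nutrient", "Mg"])
        assert r.exit_code != 0
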