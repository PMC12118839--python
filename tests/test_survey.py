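"""Survey data model: rugosity, proportions, depth handling, CV curves, I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from reefcarb.survey import (
    BenthicTransect,
    Intercept,
    SurveyValidationError,
    benthic_proportions,
    classify_urchin,
    cv_replicate_curve,
    read_survey,
    rugosity,
    standardize_depth,
    write_survey,
)
from reefcarb.synthetic import SimulationConfig, generate_survey


from helpers import make_transect


class TestRugosity:
    @pytest.mark.parametrize(
        "contour,planar,expected",
        [(2.0, 2.0, 1.0), (3.0, 2.0, 1.5), (2.5, 2.0, 1.25)],
    )
    def test_ratio(self, contour, planar, expected):
        assert rugosity(contour, planar) == pytest.approx(expected)

    def test_tape_inconsistency_rejected(self):
        with pytest.raises(ValueError, match="inconsistency"):
            rugosity(1.9, 2.0)

    @given(
        planar=st.floats(0.5, 10),
        excess=st.floats(0, 5),
    )
    def test_always_at_least_one(self, planar, excess):
        assert rugosity(planar + excess, planar) >= 1.0


class TestBenthicProportions:
    def test_single_category(self):
        t = make_transect({"sand": 200})
        props, corals = benthic_proportions(t)
        assert props["sand"] == 1.0
        assert corals == {}

    def test_equal_split(self):
        t = make_transect({"coral": 100, "sand": 100})
        props, corals = benthic_proportions(t)
        assert props["coral"] == 0.5
        assert corals["Porites lobata"] == 0.5

    def test_partition_sums_to_one(self, rng):
        # proportions from a random composition match generating counts
        for _ in range(20):
            raw = rng.dirichlet([2.0, 2.0, 2.0, 2.0])
            counts = np.round(raw * 200).astype(int)
            counts[0] += 200 - counts.sum()
            cats = ["coral", "sand", "rubble", "carbonate_substrate"]
            t = make_transect(
                {c: int(n) for c, n in zip(cats, counts) if n > 0}
            )
            props, _ = benthic_proportions(t)
            assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)
            for c, n in zip(cats, counts):
                assert props[c] == pytest.approx(n / 200.0)

    def test_incomplete_tiling_rejected(self):
        with pytest.raises(SurveyValidationError, match="tile every cm"):
            make_transect({"sand": 150}, contour_m=2.0)

    def test_unknown_category_rejected(self):
        with pytest.raises(SurveyValidationError, match="unknown benthic"):
            make_transect({"lava": 200})


class TestStandardizeDepth:
    def test_subtraction(self):
        assert standardize_depth(6.4, 0.4) == pytest.approx(6.0)

    def test_identity(self):
        assert standardize_depth(2.0, 0.0) == 2.0

    def test_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert standardize_depth(0.2, 0.4) == 0.0

    def test_missing_offset_fatal_unless_msl_assumed(self):
        with pytest.raises(ValueError, match="tide offset"):
            standardize_depth(5.0, None)
        assert standardize_depth(5.0, None, assume_msl=True) == 5.0


class TestCVReplicateCurve:
    def test_constant_counts_plateau_immediately(self):
        curve, plateau = cv_replicate_curve([5, 5, 5, 5, 5])
        assert np.allclose(curve["cv"], 0.0)
        assert plateau == 3

    def test_oscillating_counts_approach_limit(self):
        counts = [1, 9] * 20
        curve, _ = cv_replicate_curve(counts)
        # sd/mean of an even split of 1s and 9s -> 4/5 = 0.8 as n grows
        assert curve["cv"].iloc[-1] == pytest.approx(0.8, abs=0.02)
        # oracle: direct sd/mean on each prefix
        for n, cv in curve.itertuples(index=False):
            prefix = np.array(counts[: int(n)], dtype=float)
            assert cv == pytest.approx(prefix.std(ddof=1) / prefix.mean())

    def test_zero_mean_prefix_reported_missing(self):
        curve, _ = cv_replicate_curve([0, 0, 0, 1, 1])
        assert np.isnan(curve["cv"].iloc[0])

    def test_too_few_counts(self):
        with pytest.raises(ValueError):
            cv_replicate_curve([1, 2])


class TestUrchinClassification:
    @pytest.mark.parametrize(
        "species,group",
        [
            ("Echinometra mathaei", "echinometra"),
            ("Diadema paucispinum", "diadematidae"),
            ("Echinothrix calamaris", "diadematidae"),
            ("Tripneustes gratilla", "non_eroding"),
            ("Heterocentrotus mammillatus", "other_eroding"),
        ],
    )
    def test_genus_rules(self, species, group):
        assert classify_urchin(species) == group

    def test_explicit_table_overrides(self):
        assert classify_urchin("Echinometra mathaei", {"Echinometra mathaei": "other_eroding"}) == "other_eroding"


class TestReadWrite:
    def test_toy_quadrat_file(self, tmp_path):
        (tmp_path / "u.csv").write_text(
            "quadrat_id,site_id,depth_m,area_m2,species,group,test_diameter_mm\n"
            "Q1,S1,6,0.25,Echinometra mathaei,echinometra,30\n"
            "Q1,S1,6,0.25,Echinometra mathaei,echinometra,25\n"
            "Q1,S1,6,0.25,Echinothrix calamaris,diadematidae,60\n"
        )
        (tmp_path / "b.csv").write_text(
            "transect_id,site_id,depth_m,planar_length_m,contour_length_m,position_cm,category,taxon\n"
            + "\n".join(
                f"T1,S1,6,0.02,0.02,{i},sand," for i in range(2)
            )
        )
        (tmp_path / "f.csv").write_text(
            "belt_id,site_id,depth_m,length_m,width_m,species,fork_length_cm\n"
            "B1,S1,6,25,5,,\n"
        )
        ds = read_survey(tmp_path / "b.csv", tmp_path / "u.csv", tmp_path / "f.csv")
        assert len(ds.quadrats["Q1"].urchins) == 3
        assert ds.belts["B1"].fishes == []

    def test_negative_diameter_names_row(self, tmp_path):
        (tmp_path / "u.csv").write_text(
            "quadrat_id,site_id,depth_m,area_m2,species,group,test_diameter_mm\n"
            "Q1,S1,6,0.25,Echinometra mathaei,echinometra,30\n"
            "Q1,S1,6,0.25,Echinometra mathaei,echinometra,-5\n"
        )
        (tmp_path / "b.csv").write_text(
            "transect_id,site_id,depth_m,planar_length_m,contour_length_m,position_cm,category,taxon\n"
            "T1,S1,6,0.01,0.01,0,sand,\n"
        )
        (tmp_path / "f.csv").write_text(
            "belt_id,site_id,depth_m,length_m,width_m,species,fork_length_cm\n"
            "B1,S1,6,25,5,,\n"
        )
        with pytest.raises(SurveyValidationError, match="row 1"):
            read_survey(tmp_path / "b.csv", tmp_path / "u.csv", tmp_path / "f.csv")

    def test_missing_column_fatal(self, tmp_path):
        (tmp_path / "u.csv").write_text("quadrat_id,site_id\nQ1,S1\n")
        with pytest.raises(SurveyValidationError, match="missing required"):
            read_survey(tmp_path / "u.csv", tmp_path / "u.csv", tmp_path / "u.csv")

    def test_empty_file_fatal(self, tmp_path):
        (tmp_path / "u.csv").write_text(
            "quadrat_id,site_id,depth_m,area_m2,species,group,test_diameter_mm\n"
        )
        with pytest.raises(SurveyValidationError, match="empty"):
            read_survey(tmp_path / "u.csv", tmp_path / "u.csv", tmp_path / "u.csv")

    def test_excel_workbook_reader(self, tmp_path):
        pytest.importorskip("openpyxl")
        from reefcarb.survey import read_survey_excel

        cfg = SimulationConfig(seed=11, sites=("S1",), depths=(6.0,), n_replicates=3, n_belts=2)
        ds, _ = generate_survey(cfg)
        paths = [tmp_path / n for n in ("b.csv", "u.csv", "f.csv")]
        write_survey(ds, *paths)
        xlsx = tmp_path / "survey.xlsx"
        with pd.ExcelWriter(xlsx) as writer:
            for path, sheet in zip(paths, ("benthic", "urchins", "fish")):
                pd.read_csv(path).to_excel(writer, sheet_name=sheet, index=False)
        back = read_survey_excel(xlsx)
        assert back.counts() == ds.counts()
        tid = next(iter(ds.transects))
        assert back.transects[tid].intercepts == ds.transects[tid].intercepts

    def test_validation_report_station_counts(self):
        cfg = SimulationConfig(seed=4, sites=("S1", "S2"), depths=(3.0,), n_replicates=2, n_belts=1)
        ds, _ = generate_survey(cfg)
        report = ds.validation_report()
        assert report["totals"] == {"transects": 4, "quadrats": 4, "belts": 2}
        assert report["stations"]["S1@3m"] == {
            "transects": 2,
            "quadrats": 2,
            "belts": 1,
        }

    def test_round_trip_reproduces_records(self, tmp_path):
        cfg = SimulationConfig(seed=7, sites=("S1",), depths=(3.0, 6.0), n_replicates=3, n_belts=2)
        ds, _ = generate_survey(cfg)
        paths = [tmp_path / n for n in ("b.csv", "u.csv", "f.csv")]
        write_survey(ds, *paths)
        back = read_survey(*paths)
        assert back.counts() == ds.counts()
        for tid, t in ds.transects.items():
            bt = back.transects[tid]
            assert bt.intercepts == t.intercepts
            assert bt.contour_length_m == t.contour_length_m
        for qid, q in ds.quadrats.items():
            assert back.quadrats[qid].urchins == q.urchins
        for bid, b in ds.belts.items():
            assert back.belts[bid].fishes == b.fishes
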