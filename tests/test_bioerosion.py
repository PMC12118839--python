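"""Bioerosion terms: parrotfish grazing, urchin power laws, borers, totals."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from reefcarb.bioerosion import (
    ParrotfishParams,
    bite_rate,
    bite_volume,
    macroboring,
    microboring,
    parrotfish_erosion,
    parrotfish_erosion_transect,
    scar_proportion,
    site_mean_skeletal_density,
    total_bioerosion,
    urchin_erosion_individual,
    urchin_erosion_quadrat,
)
from reefcarb.survey import (
    BenthicTransect,
    FishBeltTransect,
    FishRecord,
    Intercept,
    UrchinQuadrat,
    UrchinRecord,
)

from helpers import make_transect


class TestParrotfishComponents:
    def test_bite_volume_direct(self):
        assert bite_volume(30.0) == pytest.approx(math.exp(3.1892) / 1000, abs=1e-12)

    def test_bite_volume_small_fish_floor(self):
        assert bite_volume(1e-9) == pytest.approx(math.exp(1.3172) / 1000, rel=1e-6)

    @given(l1=st.floats(1, 60), l2=st.floats(1, 60))
    def test_bite_volume_monotone(self, l1, l2):
        if l1 < l2:
            assert bite_volume(l1) < bite_volume(l2)

    def test_scar_proportion_midpoint(self):
        l50 = 2.46142 / 0.08864
        assert scar_proportion(l50) == pytest.approx(0.5, abs=1e-9)

    def test_scar_proportion_direct(self):
        assert scar_proportion(50.0) == pytest.approx(
            1 / (1 + math.exp(-(-2.46142 + 0.08864 * 50))), abs=1e-12
        )
        assert scar_proportion(50.0) == pytest.approx(0.878, abs=1e-3)

    @given(length=st.floats(0.1, 200))
    def test_scar_proportion_bounded(self, length):
        assert 0 < scar_proportion(length) < 1

    def test_bite_rate_interior_zero(self):
        l0 = 3.955 / 0.45
        assert bite_rate(l0, brc=0.0) == pytest.approx(0.0, abs=1e-9)

    def test_bite_rate_direct(self):
        assert bite_rate(20.0, brc=2.0) == pytest.approx(60 * abs(5.955 - 9.0))
        assert bite_rate(20.0, brc=2.0) == pytest.approx(182.7)

    def test_bite_rate_symmetric_about_zero(self):
        l0 = 3.955 / 0.45
        for delta in (1.0, 3.7):
            assert bite_rate(l0 + delta, 0.0) == pytest.approx(
                bite_rate(l0 - delta, 0.0), abs=1e-9
            )


class TestSkeletalDensity:
    def test_single_species(self, tables):
        t = make_transect({"coral": 100, "sand": 100})
        # only Porites lobata present -> its table density
        assert site_mean_skeletal_density([t], tables) == pytest.approx(1.32)

    def test_weighted_mean(self, tables):
        intercepts = [Intercept(i, "coral", "Porites lobata") for i in range(50)]
        intercepts += [
            Intercept(50 + i, "coral", "Pocillopora meandrina") for i in range(50)
        ]
        intercepts += [Intercept(100 + i, "sand", None) for i in range(100)]
        t = BenthicTransect("T", "S", 6.0, 2.0, 2.0, intercepts)
        assert site_mean_skeletal_density([t], tables) == pytest.approx(
            (1.32 + 1.54) / 2
        )

    def test_no_coral_falls_back_to_table_mean(self, tables):
        t = make_transect({"sand": 200})
        with pytest.warns(UserWarning, match="table-mean"):
            d = site_mean_skeletal_density([t], tables)
        assert d == pytest.approx(float(tables.all_densities().mean()))


class TestParrotfishErosion:
    def test_empty_belt_zero(self, tables):
        belt = FishBeltTransect("B", "S", 6.0, fishes=[])
        assert parrotfish_erosion_transect(belt, 1.4, tables) == 0.0

    def test_single_fish_oracle(self, tables):
        length, brc, dk = 20.0, 2.0, 1.32
        belt = FishBeltTransect(
            "B", "S", 6.0, fishes=[FishRecord("Chlorurus spilurus", length)]
        )
        vol = math.exp(1.3172 + 0.0624 * length) / 1000
        sp = 1 / (1 + math.exp(-(-2.46142 + 0.08864 * length)))
        br = 60 * abs((4.31 + brc - 0.355) - 0.045 * 10 * length)
        expected = vol * sp * br * dk * 365 * 0.001 / 125.0
        assert parrotfish_erosion_transect(belt, dk, tables) == pytest.approx(
            expected, abs=1e-12
        )

    def test_station_mean_over_belts(self, tables):
        b1 = FishBeltTransect("B1", "S", 6.0, fishes=[FishRecord("Chlorurus spilurus", 20.0)])
        b2 = FishBeltTransect("B2", "S", 6.0, fishes=[])
        with pytest.warns(UserWarning, match="belts"):
            rate = parrotfish_erosion([b1, b2], 1.32, tables)
        assert rate == pytest.approx(
            parrotfish_erosion_transect(b1, 1.32, tables) / 2
        )

    def test_no_belts_zero(self, tables):
        assert parrotfish_erosion([], 1.32, tables) == 0.0

    def test_unresolvable_species_fatal(self, tables):
        belt = FishBeltTransect(
            "B", "S", 6.0, fishes=[FishRecord("Bolbometopon muricatum", 40.0)]
        )
        with pytest.raises(KeyError):
            parrotfish_erosion_transect(belt, 1.4, tables)


class TestUrchinErosion:
    @pytest.mark.parametrize(
        "group,diameter,expected",
        [
            ("echinometra", 30.0, 3e-4 * 30**1.9671 * 0.365 * 0.57),
            ("diadematidae", 60.0, 3e-6 * 60**3.2887 * 0.365 * 0.57),
            ("other_eroding", 40.0, 3e-5 * 40**2.6414 * 0.365 * 0.57),
        ],
    )
    def test_individual_power_law(self, group, diameter, expected):
        assert urchin_erosion_individual(group, diameter) == pytest.approx(
            expected, abs=1e-12
        )

    def test_spot_values(self):
        assert urchin_erosion_individual("echinometra", 30.0) == pytest.approx(0.0502, abs=2e-4)
        assert urchin_erosion_individual("diadematidae", 60.0) == pytest.approx(0.44, abs=2e-3)

    def test_non_eroding_zero(self):
        assert urchin_erosion_individual("non_eroding", 90.0) == 0.0

    def test_unknown_group_fatal(self):
        with pytest.raises(KeyError):
            urchin_erosion_individual("asteroidea", 30.0)

    @given(d1=st.floats(5, 150), d2=st.floats(5, 150))
    def test_monotone_in_size(self, d1, d2):
        if d1 < d2:
            for g in ("echinometra", "diadematidae", "other_eroding"):
                assert urchin_erosion_individual(g, d1) < urchin_erosion_individual(g, d2)

    def test_quadrat_normalization(self):
        q = UrchinQuadrat(
            "Q", "S", 6.0, urchins=[UrchinRecord("Echinometra mathaei", "echinometra", 30.0)]
        )
        total, per = urchin_erosion_quadrat(q)
        assert total == pytest.approx(
            urchin_erosion_individual("echinometra", 30.0) / 0.25
        )
        assert total == pytest.approx(0.201, abs=1e-3)

    def test_empty_quadrat_zero(self):
        total, per = urchin_erosion_quadrat(UrchinQuadrat("Q", "S", 6.0))
        assert total == 0.0

    def test_additive_and_linear_in_density(self):
        one = UrchinQuadrat(
            "Q", "S", 6.0, urchins=[UrchinRecord("Echinometra mathaei", "echinometra", 30.0)]
        )
        three = UrchinQuadrat(
            "Q", "S", 6.0,
            urchins=[UrchinRecord("Echinometra mathaei", "echinometra", 30.0)] * 3,
        )
        assert urchin_erosion_quadrat(three)[0] == pytest.approx(
            3 * urchin_erosion_quadrat(one)[0], abs=1e-12
        )


class TestBoring:
    def test_macro_includes_cca(self):
        t = make_transect(
            {"carbonate_substrate": 50, "rubble": 30, "coralline_algae": 20, "sand": 100}
        )
        assert macroboring(t) == pytest.approx(1.0 * 0.21 * 0.5, abs=1e-12)

    def test_micro_excludes_cca(self):
        t = make_transect(
            {"carbonate_substrate": 50, "rubble": 30, "coralline_algae": 20, "sand": 100}
        )
        assert microboring(t) == pytest.approx(1.0 * 0.20 * 0.4, abs=1e-12)
        assert microboring(t) / 0.20 < macroboring(t) / 0.21

    def test_maximal_substrate(self):
        t = make_transect({"carbonate_substrate": 200})
        assert macroboring(t) == pytest.approx(0.21)
        assert microboring(t) == pytest.approx(0.20)

    def test_rugosity_scaling(self):
        t = make_transect(
            {"carbonate_substrate": 80, "rubble": 40, "sand": 180}, contour_m=3.0
        )
        assert t.rugosity == 1.5
        assert macroboring(t) == pytest.approx(1.5 * 0.21 * 0.4, abs=1e-12)

    def test_zero_available(self):
        t = make_transect({"sand": 200})
        assert macroboring(t) == 0.0 and microboring(t) == 0.0


class TestTotal:
    def test_components_sum(self):
        t = make_transect({"carbonate_substrate": 100, "sand": 100})
        q = UrchinQuadrat(
            "Q", "S", 6.0, urchins=[UrchinRecord("Echinometra mathaei", "echinometra", 30.0)]
        )
        res = total_bioerosion(t, q, parrotfish_rate_k=0.1)
        assert res.total == pytest.approx(
            res.parrotfish + res.urchin + res.macro + res.micro, abs=1e-12
        )
        assert res.parrotfish == 0.1

    def test_oracle_equivalence_random_stations(self, tables, rng):
        """Module totals equal an independent straight-line evaluation."""
        for _ in range(100):
            n_carb = int(rng.integers(0, 80))
            n_rub = int(rng.integers(0, 40))
            n_cca = int(rng.integers(0, 30))
            n_sand = 200 - n_carb - n_rub - n_cca
            r = float(rng.uniform(1.0, 2.0))
            t = make_transect(
                {
                    k: v
                    for k, v in {
                        "carbonate_substrate": n_carb,
                        "rubble": n_rub,
                        "coralline_algae": n_cca,
                        "sand": n_sand,
                    }.items()
                    if v
                },
                planar=2.0 / r,
            )
            groups = ["echinometra", "diadematidae", "other_eroding", "non_eroding"]
            laws = {
                "echinometra": (3e-4, 1.9671),
                "diadematidae": (3e-6, 3.2887),
                "other_eroding": (3e-5, 2.6414),
            }
            urchins = []
            expected_urchin = 0.0
            for _ in range(int(rng.integers(0, 12))):
                g = groups[int(rng.integers(0, 4))]
                d = float(rng.uniform(10, 120))
                urchins.append(UrchinRecord("x", g, d))
                if g in laws:
                    a, b = laws[g]
                    expected_urchin += a * d**b * 0.365 * 0.57 / 0.25
            q = UrchinQuadrat("Q", "S", 6.0, urchins=urchins)
            fish_rate = float(rng.uniform(0, 0.01))
            res = total_bioerosion(t, q, fish_rate)
            r = t.contour_length_m / t.planar_length_m
            expected = (
                fish_rate
                + expected_urchin
                + r * 0.21 * (n_carb + n_rub + n_cca) / 200.0
                + r * 0.20 * (n_carb + n_rub) / 200.0
            )
            assert res.total == pytest.approx(expected, abs=1e-9)
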