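"""Indicator computation: worked-example values, oracle equivalence, invariants."""

import math

import numpy as np
import pytest

from espdyn import (
    change_intensity,
    compute_all,
    count_changes,
    derive_change,
    esp_cum,
    espd_chi,
    espd_cum,
    espd_mean,
    espd_p,
)
from espdyn.exceptions import EmptyInputError, InsufficientDataError
from espdyn.geodata import ChangeRecord, Mosaic, Patch

from conftest import random_instance


# -- independent brute-force implementations (plain loops, no library calls) --

def oracle_esp_cum(patches, m, e):
    total = 0.0
    for p in patches:
        total += m.lookup(p.lulc, e) * p.area
    return total


def oracle_espd_cum(records, m, e):
    total = 0.0
    for r in records:
        total += (m.lookup(r.new_lulc, e) - m.lookup(r.old_lulc, e)) * r.area
    return total


def oracle_espd_mean(records, m, e):
    vals = [m.lookup(r.new_lulc, e) - m.lookup(r.old_lulc, e) for r in records]
    return sum(vals) / len(vals)


def oracle_espd_chi(records, m, e):
    num, den = 0.0, 0.0
    for r in records:
        num += (m.lookup(r.new_lulc, e) - m.lookup(r.old_lulc, e)) * r.area
        den += r.area
    return num / den


class TestWorkedExample:
    """The published three-patch mosaic reproduces all printed values."""

    def test_per_patch_potentials(self, toy, matrix):
        old, new, _ = toy
        forest_score = matrix.lookup("31000", "I1")
        p1_old = next(p for p in old.patches if p.patch_id == "P1")
        p1_new = next(p for p in new.patches if p.patch_id == "P1")
        assert forest_score * p1_old.area == 840
        assert forest_score * p1_new.area == 490

    def test_cumulative_totals(self, toy, matrix):
        old, new, _ = toy
        assert esp_cum(old, matrix, "I1", "total") == 1005
        assert esp_cum(new, matrix, "I1", "total") == 755
        assert esp_cum(old, matrix, "I1", "density") == pytest.approx(50.25)

    def test_change_indicators(self, toy, matrix):
        old, new, _ = toy
        records = derive_change(old, new)
        assert espd_cum(records, old.a_tot, matrix, "I1", "total") == -250
        assert espd_cum(records, old.a_tot, matrix, "I1", "density") == pytest.approx(-12.5)
        assert espd_mean(records, matrix, "I1") == pytest.approx(-52.5)
        assert espd_chi(records, matrix, "I1") == pytest.approx(-50.0)
        assert count_changes(records, matrix, "I1") == (2, 2)

    def test_per_record_changes(self, matrix):
        to_fabric = ChangeRecord("a", "31000", "11100", 2.0)
        to_arable = ChangeRecord("b", "31000", "21000", 3.0)
        assert espd_p(to_fabric, matrix, "I1") == -65
        assert espd_p(to_arable, matrix, "I1") == -40


class TestSingleOps:
    def test_uniform_mosaic_density_equals_class_score(self, matrix):
        m = Mosaic((Patch("a", "31000", 3.0), Patch("b", "31000", 9.0)))
        assert esp_cum(m, matrix, "I1", "density") == 70

    def test_empty_mosaic_raises(self, matrix):
        with pytest.raises(EmptyInputError):
            esp_cum(Mosaic(()), matrix, "I1")

    def test_zero_change_fixed_point(self, matrix):
        assert espd_cum([], 20.0, matrix, "I1", "total") == 0
        assert espd_cum([], 20.0, matrix, "I1", "density") == 0

    def test_empty_mean_and_chi_are_undefined(self, matrix):
        with pytest.raises(InsufficientDataError):
            espd_mean([], matrix, "I1")
        with pytest.raises(InsufficientDataError):
            espd_chi([], matrix, "I1")

    def test_equal_score_transition_is_zero_and_uncounted(self, matrix):
        # both classes sit on the drinking-water floor of 5
        rec = ChangeRecord("a", "13300", "12100", 2.0)
        assert espd_p(rec, matrix, "P1") == 0
        assert count_changes([rec], matrix, "P1") == (1, 0)

    def test_area_weighted_mean_variant(self, matrix):
        recs = [
            ChangeRecord("a", "31000", "21000", 3.0),
            ChangeRecord("b", "31000", "11100", 2.0),
        ]
        assert espd_mean(recs, matrix, "I1", area_weighted=True) == pytest.approx(-125.0)

    def test_chi_of_constant_change_is_that_value(self, matrix):
        recs = [
            ChangeRecord("a", "31000", "21000", 1.0),
            ChangeRecord("b", "31000", "21000", 7.0),
        ]
        assert espd_chi(recs, matrix, "I1") == -40


class TestChangeIntensity:
    def test_all_qualifying(self, matrix):
        recs = [ChangeRecord("a", "31000", "13300", 5.0)]
        assert change_intensity(recs, 20.0) == pytest.approx(2500.0)  # 50 000 m2 / 20 ha

    def test_non_qualifying_transitions_ignored(self, matrix):
        recs = [ChangeRecord("a", "11100", "14100", 5.0)]  # artificial -> artificial
        assert change_intensity(recs, 20.0) == 0.0

    def test_linearity_in_area(self, matrix):
        recs = [ChangeRecord("a", "23000", "12100", 2.0)]
        doubled = [ChangeRecord("a", "23000", "12100", 4.0)]
        assert change_intensity(doubled, 20.0) == 2 * change_intensity(recs, 20.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    @pytest.mark.parametrize("service", ["I1", "P1", "R1", "R2", "R3", "C1"])
    def test_all_indicators_match_bruteforce(self, seed, service, matrix):
        mosaic, records = random_instance(seed)
        a_tot = mosaic.a_tot
        assert esp_cum(mosaic, matrix, service, "total") == pytest.approx(
            oracle_esp_cum(mosaic.patches, matrix, service), abs=1e-9
        )
        assert espd_cum(records, a_tot, matrix, service, "total") == pytest.approx(
            oracle_espd_cum(records, matrix, service), abs=1e-9
        )
        assert espd_cum(records, a_tot, matrix, service, "density") == pytest.approx(
            oracle_espd_cum(records, matrix, service) / a_tot, abs=1e-9
        )
        assert espd_mean(records, matrix, service) == pytest.approx(
            oracle_espd_mean(records, matrix, service), abs=1e-9
        )
        assert espd_chi(records, matrix, service) == pytest.approx(
            oracle_espd_chi(records, matrix, service), abs=1e-9
        )
        for r in records:
            assert espd_p(r, matrix, service) == matrix.lookup(
                r.new_lulc, service
            ) - matrix.lookup(r.old_lulc, service)


class TestInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_bounds(self, seed, matrix):
        mosaic, records = random_instance(seed)
        for e in matrix.services:
            dens = esp_cum(mosaic, matrix, e, "density")
            assert 5 <= dens <= 100
            vals = [espd_p(r, matrix, e) for r in records]
            assert all(-95 <= v <= 95 for v in vals)
            assert min(vals) - 1e-12 <= espd_chi(records, matrix, e) <= max(vals) + 1e-12

    @pytest.mark.parametrize("k", [0.1, 3.0, 1e4])
    def test_scale_invariance(self, k, matrix):
        mosaic, records = random_instance(7)
        scaled_m = Mosaic(
            tuple(Patch(p.patch_id, p.lulc, p.area * k) for p in mosaic.patches)
        )
        scaled_r = [
            ChangeRecord(r.patch_id, r.old_lulc, r.new_lulc, r.area * k) for r in records
        ]
        for e in ("I1", "C1"):
            assert esp_cum(scaled_m, matrix, e, "total") == pytest.approx(
                k * esp_cum(mosaic, matrix, e, "total")
            )
            assert esp_cum(scaled_m, matrix, e, "density") == pytest.approx(
                esp_cum(mosaic, matrix, e, "density")
            )
            assert espd_chi(scaled_r, matrix, e) == pytest.approx(
                espd_chi(records, matrix, e)
            )
            assert espd_cum(
                scaled_r, mosaic.a_tot * k, matrix, e, "density"
            ) == pytest.approx(espd_cum(records, mosaic.a_tot, matrix, e, "density"))


class TestComputeAll:
    def test_worked_example_table(self, toy, matrix):
        from espdyn.geodata import scope_patches

        old, new, boundaries = toy
        old_s = scope_patches(old, boundaries)
        new_s = scope_patches(new, boundaries)
        records = scope_patches(derive_change(old_s, new_s), boundaries)
        table = compute_all("toy", old_s, new_s, records, matrix)
        assert len(table) == 12  # 2 scopes x 6 services
        row = table[(table.scope == "metropolitan") & (table.service == "I1")].iloc[0]
        assert row.espcum_old_total == 1005
        assert row.espcum_total == 755
        assert row.espdcum_total == -250
        assert row.n_changed == 2 and row.n_nonzero == 2
        assert row.a_tot == pytest.approx(20) and row.a_tot_ch == pytest.approx(5)

    def test_determinism_across_cities(self, toy, matrix):
        old, new, _ = toy
        records = derive_change(old, new)
        t1 = compute_all("a", old, new, records, matrix, scopes=("metropolitan",))
        t2 = compute_all("b", old, new, records, matrix, scopes=("metropolitan",))
        assert t1.drop(columns="city").equals(t2.drop(columns="city"))

    def test_change_layer_matches_derived(self, toy, matrix):
        old, new, _ = toy
        derived = derive_change(old, new)
        supplied = [
            ChangeRecord("x", "31000", "21000", 3.0),
            ChangeRecord("y", "31000", "11100", 2.0),
        ]
        a = compute_all("t", old, new, derived, matrix, scopes=("metropolitan",))
        b = compute_all("t", old, new, supplied, matrix, scopes=("metropolitan",))
        assert np.allclose(a["espdcum_total"], b["espdcum_total"])
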