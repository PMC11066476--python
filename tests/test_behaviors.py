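"""Growth, death, mitosis, mucus secretion and stromal proliferation."""

import numpy as np
import pytest

from conftest import single_cell_lattice
from luadmorph.behaviors import (
    BehaviorRates,
    apply_death,
    apply_growth,
    apply_mitosis,
    proliferate_stroma,
    secrete_mucus,
)
from luadmorph.lattice import (
    APICAL,
    BASAL,
    CANCER,
    CYTOSOL,
    GENERIC,
    GROWING_STROMAL,
    LATERAL,
    NORMAL,
    STROMAL,
    Lattice,
)
from luadmorph.presets import _build_columnar_cell


def _epithelium_pair(width=30, height=40):
    """Two columnar cancer cells side by side on bare medium."""
    lat = Lattice(width, height)
    a = _build_columnar_cell(lat, CANCER, 5, 5, 10, 30)
    b = _build_columnar_cell(lat, CANCER, 5, 15, 10, 30)
    lat.validate()
    return lat, a, b


class TestGrowth:
    def test_linear_increment_is_exact(self):
        lat = Lattice(20, 45)
        cid = _build_columnar_cell(lat, CANCER, 3, 5, 10, 30)
        comp = [c for c in lat.cluster_comps[cid] if lat.comp_type[c] == CYTOSOL][0]
        rates = {CANCER: BehaviorRates(growth_rate=0.03)}
        before = float(lat.comp_target[comp])
        for _ in range(100):
            apply_growth(lat, rates)
        assert float(lat.comp_target[comp]) - before == pytest.approx(3.0, abs=1e-12)
        assert lat.clus_growth_progress[cid] == pytest.approx(3.0, abs=1e-12)

    def test_contact_inhibition_multiplier(self):
        lat, a, b = _epithelium_pair()
        rates = {
            CANCER: BehaviorRates(growth_rate=0.3, contact_inhibition_factor=0.997)
        }
        cytosol_a = [
            c for c in lat.cluster_comps[a] if lat.comp_type[c] == CYTOSOL
        ][0]
        before = float(lat.comp_target[cytosol_a])
        apply_growth(lat, rates, contact_inhibition_enabled=True)
        # the two cells touch, so the increment is 0.3 * 0.997 = 0.2991
        assert float(lat.comp_target[cytosol_a]) - before == pytest.approx(
            0.2991, abs=1e-12
        )

    def test_no_inhibition_for_isolated_cell(self):
        lat = Lattice(20, 45)
        cid = _build_columnar_cell(lat, CANCER, 3, 5, 10, 30)
        comp = [c for c in lat.cluster_comps[cid] if lat.comp_type[c] == CYTOSOL][0]
        rates = {
            CANCER: BehaviorRates(growth_rate=0.3, contact_inhibition_factor=0.997)
        }
        before = float(lat.comp_target[comp])
        apply_growth(lat, rates, contact_inhibition_enabled=True)
        assert float(lat.comp_target[comp]) - before == pytest.approx(0.3)

    def test_zero_rate_changes_nothing(self):
        lat = Lattice(20, 45)
        _build_columnar_cell(lat, CANCER, 3, 5, 10, 30)
        targets = lat.comp_target.copy()
        apply_growth(lat, {CANCER: BehaviorRates(growth_rate=0.0)})
        assert np.array_equal(targets, lat.comp_target)


class TestDeath:
    def test_zero_rate_never_kills(self):
        lat, cid, comp = single_cell_lattice(cell_type=STROMAL)
        rng = np.random.default_rng(0)
        for _ in range(200):
            assert apply_death(lat, {STROMAL: BehaviorRates(death_rate=0.0)}, rng) == []

    def test_rate_one_kills_every_eligible_cell(self):
        lat, a, b = _epithelium_pair()
        rng = np.random.default_rng(0)
        dying = apply_death(lat, {CANCER: BehaviorRates(death_rate=1.0)}, rng)
        assert sorted(dying) == sorted([a, b])
        for cid in (a, b):
            assert not lat.clus_alive[cid]
            for comp in lat.cluster_comps[cid]:
                assert lat.comp_target[comp] == 0.0

    def test_survival_tracks_geometric_law(self):
        """Mean survival of independent cells follows (1 - d)^t."""
        lat = Lattice(40, 40)
        for i in range(100):
            cid = lat.new_cluster(STROMAL, reference_volume=1.0)
            lat.new_compartment(cid, GENERIC, 1.0, 0.0)
        rng = np.random.default_rng(7)
        d, t = 0.002, 1000
        rates = {STROMAL: BehaviorRates(death_rate=d)}
        for _ in range(t):
            apply_death(lat, rates, rng)
        frac = len(lat.alive_clusters(STROMAL)) / 100
        p = (1 - d) ** t
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / 100)


class TestMitosis:
    def test_below_double_volume_no_division(self):
        lat, cid, comp = single_cell_lattice(cell=10)
        lat.clus_ref_volume[cid] = 100 / 1.9  # cell sits at 1.9x reference
        assert apply_mitosis(lat, np.random.default_rng(0)) == []

    def test_columnar_cell_splits_into_two_polar_daughters(self):
        lat = Lattice(30, 70)
        cid = _build_columnar_cell(lat, CANCER, 3, 10, 10, 60)
        lat.clus_ref_volume[cid] = 300.0  # at 2x its reference volume
        events = apply_mitosis(lat, np.random.default_rng(0))
        assert len(events) == 1
        _, da, db = events[0]
        for d in (da, db):
            vol = lat.cluster_volume(d)
            assert abs(vol - 300) <= 30  # within 10% of half
            types = {
                int(lat.comp_type[c])
                for c in lat.cluster_comps[d]
                if lat.comp_volume[c] > 0
            }
            assert types == {APICAL, BASAL, LATERAL, CYTOSOL}
        lat.validate()

    def test_stromal_pseudocell_splits_generically(self):
        lat, cid, comp = single_cell_lattice(cell=10, cell_type=STROMAL)
        lat.clus_ref_volume[cid] = 50.0
        events = apply_mitosis(lat, np.random.default_rng(0))
        assert len(events) == 1
        _, da, db = events[0]
        for d in (da, db):
            comps = lat.cluster_comps[d]
            assert len(comps) == 1
            assert int(lat.comp_type[comps[0]]) == GENERIC
            assert lat.cluster_volume(d) == 50
        lat.validate()

    def test_growth_clock_trigger_with_volume_gate(self):
        lat, cid, comp = single_cell_lattice(cell=10, cell_type=STROMAL)
        lat.clus_birth_targets[cid] = {GENERIC: 100.0}
        rates = {STROMAL: BehaviorRates(growth_rate=1.0, division_gain=5.0)}
        rng = np.random.default_rng(0)
        for _ in range(4):
            apply_growth(lat, rates)
            assert apply_mitosis(lat, rng, rates) == []  # clock not yet reached
        apply_growth(lat, rates)
        events = apply_mitosis(lat, rng, rates)  # clock reached, cell at target
        assert len(events) == 1
        for d in events[0][1:]:
            assert lat.clus_growth_progress[d] == 0.0

    def test_pixel_conservation_through_division(self):
        lat, a, b = _epithelium_pair()
        total = lat.width * lat.height
        lat.clus_ref_volume[a] = 150.0
        apply_mitosis(lat, np.random.default_rng(0))
        assert lat.recount_volumes().sum() == total
        lat.validate()


class TestContactInhibitionDesynchronization:
    def test_inhibited_neighbor_divides_later(self):
        """With contact inhibition, a touching cell's division clock runs
        slower than an isolated cell's, spreading out division times."""

        def run(ci_enabled):
            lat = Lattice(60, 40)
            a = _build_columnar_cell(lat, CANCER, 3, 5, 10, 30)  # isolated
            b = _build_columnar_cell(lat, CANCER, 3, 30, 10, 30)  # touching c
            c = _build_columnar_cell(lat, NORMAL, 3, 40, 10, 30)
            rates = {
                CANCER: BehaviorRates(
                    growth_rate=1.0,
                    division_gain=50.0,
                    contact_inhibition_factor=0.5,
                ),
                NORMAL: BehaviorRates(growth_rate=0.0),
            }
            rng = np.random.default_rng(0)
            division_mcs = {}
            for mcs in range(1, 201):
                apply_growth(lat, rates, contact_inhibition_enabled=ci_enabled)
                for parent, da, db in apply_mitosis(lat, rng, rates):
                    division_mcs[parent] = mcs
                if len(division_mcs) >= 2:
                    break
            return [division_mcs.get(a), division_mcs.get(b)]

        off = run(False)
        on = run(True)
        assert off[0] == off[1]  # synchronized without inhibition
        assert on[1] > on[0]  # inhibited cell lags
        assert np.var(on) > np.var(off)


class TestMucus:
    def _apa_cell(self):
        lat = Lattice(20, 45)
        cid = _build_columnar_cell(lat, CANCER, 3, 5, 10, 30)
        return lat, cid

    def test_zero_rate_makes_no_mucus(self):
        lat, cid = self._apa_cell()
        rates = {CANCER: BehaviorRates(mucus_secretion_rate=0.0)}
        assert secrete_mucus(lat, rates, np.random.default_rng(0)) == 0

    def test_unit_rate_creates_one_pixel_per_mcs(self):
        lat, cid = self._apa_cell()
        rates = {CANCER: BehaviorRates(mucus_secretion_rate=1.0)}
        rng = np.random.default_rng(0)
        made = sum(secrete_mucus(lat, rates, rng) for _ in range(50))
        assert made == 50
        from luadmorph.lattice import MUCUS

        mucus_comps = [
            c
            for cl in lat.alive_clusters(MUCUS)
            for c in lat.cluster_comps[cl]
        ]
        assert sum(int(lat.comp_volume[c]) for c in mucus_comps) == 50
        lat.validate()

    def test_mucus_appears_only_on_the_apical_side(self):
        lat, cid = self._apa_cell()
        rates = {CANCER: BehaviorRates(mucus_secretion_rate=0.5)}
        rng = np.random.default_rng(1)
        for _ in range(40):
            secrete_mucus(lat, rates, rng)
        from luadmorph.lattice import MUCUS

        apical_top = 3 + 30  # cell spans rows [3, 33); apical at the top
        pix = [
            tuple(p)
            for cl in lat.alive_clusters(MUCUS)
            for p in lat.cluster_pixels(cl)
        ]
        assert pix, "no mucus was secreted"
        assert all(r >= 18 for r, c in pix)  # upper half: apical side only

    def test_fractional_rates_accumulate(self):
        lat, cid = self._apa_cell()
        rates = {CANCER: BehaviorRates(mucus_secretion_rate=0.25)}
        rng = np.random.default_rng(2)
        made = [secrete_mucus(lat, rates, rng) for _ in range(8)]
        assert sum(made) == 2  # one pixel per four MCS


class TestStromalGrowth:
    def _bed_with_tumor(self):
        lat = Lattice(30, 50)
        gs = lat.new_cluster(GROWING_STROMAL, reference_volume=100.0)
        gs_comp = lat.new_compartment(gs, GENERIC, 100.0, 2.0)
        lat.paint(np.arange(0, 10)[:, None], np.arange(0, 10)[None, :], gs_comp)
        far = lat.new_cluster(GROWING_STROMAL, reference_volume=100.0)
        far_comp = lat.new_compartment(far, GENERIC, 100.0, 2.0)
        lat.paint(np.arange(0, 10)[:, None], np.arange(20, 30)[None, :], far_comp)
        _build_columnar_cell(lat, CANCER, 10, 0, 10, 30)  # basal rests on gs
        lat.validate()
        return lat, gs_comp, far_comp

    def test_increment_requires_cancer_basal_contact(self):
        lat, near, far = self._bed_with_tumor()
        rates = {GROWING_STROMAL: BehaviorRates(stromal_growth_rate=0.02)}
        for _ in range(300):
            proliferate_stroma(lat, rates)
        assert float(lat.comp_target[near]) - 100.0 == pytest.approx(6.0, abs=1e-9)
        assert float(lat.comp_target[far]) == 100.0

    def test_zero_rate_is_inert(self):
        lat, near, far = self._bed_with_tumor()
        rates = {GROWING_STROMAL: BehaviorRates(stromal_growth_rate=0.0)}
        proliferate_stroma(lat, rates)
        assert float(lat.comp_target[near]) == 100.0
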