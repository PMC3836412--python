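"""Torsion-grid search: energy model, minimisation, dedup, H-bonds, shapes."""

import itertools
import math

import numpy as np
import pytest

from gluconf.geometry import bond_length, internal_coordinates, rmsd_symmetric
from gluconf.search import (
    COULOMB_CONSTANT,
    EnergyParameters,
    ScanConfig,
    TorsionEnergyModel,
    classify_shape,
    deduplicate,
    detect_hbond,
    enumerate_torsion_grid,
    minimize_torsions,
    mm_energy,
    place_ammonium_hydrogens,
    run_conformer_pipeline,
    _minimize_model,
)
from gluconf.synthetic import ideal_template, template_internal_coordinates
from gluconf.topology import DEFAULT_TOPOLOGY, canonical_key

from conftest import conformer_at, random_rotation


def zeroed_params(**overrides) -> EnergyParameters:
    """Parameters with every term switched off (for isolating single terms)."""
    p = EnergyParameters.anionic()
    p.charges = {n: 0.0 for n in p.charges}
    p.lj = {n: (1.0, 1e-30) for n in p.lj}
    p.net_charge = 0.0
    for k, v in overrides.items():
        setattr(p, k, v)
    return p


class TestMmEnergy:
    def test_zero_at_equilibrium(self, template):
        p = zeroed_params()
        assert mm_energy(template, p) == pytest.approx(0.0, abs=1e-12)

    def test_single_bond_displacement(self, template):
        """k (r-r0)^2 = 300 * 0.1^2 = 3 kcal/mol."""
        p = zeroed_params(bond_k=300.0, angle_k=1e-12)
        key = canonical_key(("CB", "CG"))
        r = bond_length(template.atoms["CB"], template.atoms["CG"])
        p.bond_r0 = dict(p.bond_r0)
        p.bond_r0[key] = r + 0.1
        # other bonds stay at their own equilibria
        for other in p.bond_r0:
            if other != key:
                a, b = other
                p.bond_r0[other] = bond_length(template.atoms[a],
                                               template.atoms[b])
        assert mm_energy(template, p) == pytest.approx(3.0, abs=1e-9)

    def test_coulomb_closed_form(self, template):
        """Only two charged atoms >= 3 bonds apart: E = 332.0637 q1 q2 / r."""
        p = zeroed_params()
        p.charges = {n: 0.0 for n in p.charges}
        p.charges["N"] = 1.0
        p.charges["OE2"] = 1.0
        p.bond_k = 1e-12
        p.angle_k = 1e-12
        r = bond_length(template.atoms["N"], template.atoms["OE2"])
        assert mm_energy(template, p) == pytest.approx(
            COULOMB_CONSTANT / r, rel=1e-9)

    def test_rigid_motion_invariance(self, template, rng):
        e0 = mm_energy(template)
        for _ in range(5):
            moved = template.transformed(random_rotation(rng),
                                         rng.normal(size=3) * 8)
            assert mm_energy(moved) == pytest.approx(e0, rel=1e-12, abs=1e-9)

    def test_model_agrees_with_direct_energy(self, template):
        model = TorsionEnergyModel(
            internal_coordinates(template, DEFAULT_TOPOLOGY))
        for tors in ((180.0, 180.0, 180.0, 180.0), (33.0, -120.0, 55.0, 170.0)):
            conf = model.conformer(tors)
            assert model.energy(tors) == pytest.approx(mm_energy(conf),
                                                       rel=1e-12)

    def test_charge_model_sums_to_species_charge(self):
        EnergyParameters.anionic().validate()
        EnergyParameters.zwitterionic().validate()
        bad = EnergyParameters.anionic()
        bad.charges = dict(bad.charges)
        bad.charges["N"] = 0.5
        with pytest.raises(ValueError):
            bad.validate()


class TestEnumerateTorsionGrid:
    def test_axis_values_step_120(self, template):
        cfg = ScanConfig(torsion_names=("chi1",), step=120.0)
        points = list(enumerate_torsion_grid(template, cfg))
        assert [p[0][0] for p in points] == [-180.0, -60.0, 60.0]

    @pytest.mark.parametrize("k,step,expected", [
        (1, 30.0, 12), (2, 60.0, 36), (3, 30.0, 1728),
    ])
    def test_cardinality(self, template, k, step, expected):
        names = ("chi1", "chi2", "chi3")[:k]
        cfg = ScanConfig(torsion_names=names, step=step)
        count = sum(1 for _ in enumerate_torsion_grid(template, cfg))
        assert count == expected

    def test_grid_torsions_measure_back(self, template, topo):
        cfg = ScanConfig(torsion_names=("chi1", "chi3"), step=90.0)
        for tors, conf in enumerate_torsion_grid(template, cfg):
            ics = internal_coordinates(conf, topo)
            for name, want in zip(cfg.torsion_names, tors):
                got = ics.get_torsion(topo.torsions[name])
                assert math.isclose((got - want) % 360.0 % 360.0, 0.0,
                                    abs_tol=1e-6) or \
                    math.isclose((got - want) % 360.0, 360.0, abs_tol=1e-6)

    def test_invalid_step_rejected(self, template):
        with pytest.raises(ValueError):
            ScanConfig(step=50.0).validate()


class TestMinimizeTorsions:
    def test_monotonic_from_random_starts(self, template, rng):
        model = TorsionEnergyModel(
            internal_coordinates(template, DEFAULT_TOPOLOGY))
        cfg = ScanConfig()
        for _ in range(50):
            x0 = rng.uniform(-180, 180, size=4)
            e0 = model.energy(x0)
            _, e, _, _ = _minimize_model(model, x0, cfg)
            assert e <= e0 + 1e-12

    def test_stationary_point_stays_put(self, template):
        model = TorsionEnergyModel(
            internal_coordinates(template, DEFAULT_TOPOLOGY))
        cfg = ScanConfig()
        x, e, _, _ = _minimize_model(model, (-90.0, 60.0, -60.0, 170.0), cfg)
        x2, e2, _, _ = _minimize_model(model, x, cfg)
        assert max(abs(a - b) for a, b in zip(x, x2)) <= 0.1
        assert e2 <= e + 1e-9

    def test_one_torsion_matches_bruteforce_oracle(self, template):
        """1-D minimisation agrees with an exhaustive fine-grid search."""
        params = zeroed_params()
        params.charges = {n: 0.0 for n in params.charges}
        params.charges["N"] = 1.0
        params.charges["OE1"] = -1.0
        params.net_charge = 0.0
        model = TorsionEnergyModel(
            internal_coordinates(template, DEFAULT_TOPOLOGY), params,
            torsion_names=("chi2",))
        grid = np.arange(-180.0, 180.0, 0.01)
        energies = np.array([model.energy((g,)) for g in grid])
        brute_x = grid[np.argmin(energies)]
        brute_e = energies.min()
        cfg = ScanConfig(torsion_names=("chi2",))
        x, e, _, _ = _minimize_model(model, (brute_x + 5.0,), cfg)
        assert e <= brute_e + 1e-9
        assert abs((x[0] - brute_x + 180) % 360 - 180) <= 0.05

    def test_public_api_round_trip(self, template):
        res = minimize_torsions(conformer_at({"chi1": -70.0, "chi2": 60.0}))
        assert res.energy <= mm_energy(conformer_at({"chi1": -70.0,
                                                     "chi2": 60.0})) + 1e-9
        assert res.conformer.atoms["N"] is not None


class TestDeduplicate:
    def test_identical_pair_keeps_lower_energy(self, template):
        a = conformer_at({}, "a")
        b = conformer_at({}, "b")
        kept = deduplicate([(a, 2.0), (b, 1.0)], dedup_rmsd=0.1)
        assert len(kept) == 1
        assert kept[0][1] == 1.0

    def test_threshold_behaviour(self):
        near = conformer_at({"chi3": 181.5}, "near")   # ~0.02 Å from trans
        far = conformer_at({"chi3": 140.0}, "far")
        base = conformer_at({}, "base")
        assert rmsd_symmetric(base, near) < 0.1
        assert rmsd_symmetric(base, far) > 0.1
        assert len(deduplicate([(base, 0.0), (near, 1.0)], 0.1)) == 1
        assert len(deduplicate([(base, 0.0), (far, 1.0)], 0.1)) == 2

    def test_idempotent(self, rng):
        items = [(conformer_at({"chi1": float(v)}, f"c{i}"), float(i))
                 for i, v in enumerate(rng.uniform(-180, 180, 12))]
        once = deduplicate(items, 0.1)
        twice = deduplicate(once, 0.1)
        assert [id(c) for c, _ in once] == [id(c) for c, _ in twice]

    def test_size_monotone_in_threshold(self, rng):
        items = [(conformer_at({"chi1": float(v), "chi2": float(w)}, f"c{i}"),
                  float(i))
                 for i, (v, w) in enumerate(
                     zip(rng.uniform(-180, 180, 15),
                         rng.uniform(-180, 180, 15)))]
        sizes = [len(deduplicate(items, t)) for t in (0.05, 0.2, 0.5, 1.0, 2.0)]
        assert sizes == sorted(sizes, reverse=True)


class TestHydrogenBonds:
    def test_extended_conformer_has_no_side_chain_contact(self):
        ext = conformer_at({})
        bonds = detect_hbond(ext)
        assert not any(b.acceptor in ("OE1", "OE2") for b in bonds)

    def test_folded_conformer_reports_contact(self):
        folded = conformer_at({"chi1": -76.7, "chi2": 65.9, "chi3": -69.6,
                               "theta": 171.9})
        bonds = detect_hbond(folded)
        assert any(b.acceptor in ("OE1", "OE2") and b.distance_ha < 2.5
                   and b.angle_dha >= 120.0 for b in bonds)

    def test_hydrogen_geometry(self, template):
        hs = place_ammonium_hydrogens(template)
        assert len(hs) == 3
        n = template.atoms["N"]
        for h in hs.values():
            assert np.linalg.norm(h - n) == pytest.approx(1.01, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        folded = conformer_at({"chi1": -76.7, "chi2": 65.9, "chi3": -69.6})
        ref = [(b.hydrogen, b.acceptor, round(b.distance_ha, 6),
                round(b.angle_dha, 4)) for b in detect_hbond(folded)]
        moved = folded.transformed(random_rotation(rng), rng.normal(size=3) * 9)
        got = [(b.hydrogen, b.acceptor, round(b.distance_ha, 6),
                round(b.angle_dha, 4)) for b in detect_hbond(moved)]
        assert got == ref


class TestClassifyShape:
    def test_all_trans_is_extended(self):
        assert classify_shape(conformer_at({})) == "extended"

    def test_hbonded_conformer_is_rounded(self):
        folded = conformer_at({"chi1": -76.7, "chi2": 65.9, "chi3": -69.6})
        assert detect_hbond(folded)
        assert classify_shape(folded) == "rounded"

    def test_infinite_threshold_rounds_everything(self):
        assert classify_shape(conformer_at({}), threshold=math.inf) == "rounded"


class TestPipeline:
    def test_one_torsion_scan_contract(self):
        cfg = ScanConfig(torsion_names=("chi3",), step=30.0)
        db = run_conformer_pipeline(cfg)
        assert len(db.records) >= 1
        energies = [r.energy for r in db.records]
        assert energies == sorted(energies)
        confs = [r.conformer for r in db.records]
        for i, j in itertools.combinations(range(len(confs)), 2):
            assert rmsd_symmetric(confs[i], confs[j]) > cfg.dedup_rmsd
        assert db.n_grid == 12
        groups = [r.group for r in db.records]
        assert min(groups) == 1
        assert set(groups) == set(range(1, max(groups) + 1))

    def test_determinism(self):
        cfg = ScanConfig(torsion_names=("chi1", "chi3"), step=60.0)
        db1 = run_conformer_pipeline(cfg)
        db2 = run_conformer_pipeline(cfg)
        assert len(db1.records) == len(db2.records)
        for r1, r2 in zip(db1.records, db2.records):
            assert r1.energy == r2.energy
            for n in r1.conformer.atoms:
                assert np.array_equal(r1.conformer.atoms[n],
                                      r2.conformer.atoms[n])

    def test_grid_minima_bounded_by_grid_energies(self, template):
        """Every 1-D minimisation lands at or below the best grid energy."""
        cfg = ScanConfig(torsion_names=("chi2",), step=30.0)
        model = TorsionEnergyModel(
            internal_coordinates(template, DEFAULT_TOPOLOGY), None,
            cfg.torsion_names)
        grid = cfg.grid_axis()
        e_grid_min = min(model.energy((g,)) for g in grid)
        for g in grid:
            _, e, _, _ = _minimize_model(model, (g,), cfg)
            assert e <= e_grid_min + 1e-9 or e <= model.energy((g,)) + 1e-12
        best = min(_minimize_model(model, (g,), cfg)[1] for g in grid)
        assert best <= e_grid_min + 1e-12
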