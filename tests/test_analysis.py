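"""Folding observables: RMSD, contacts, H-bonds, series diagnostics."""

import numpy as np
import pytest

from admdpath.analysis import (
    ContactCriteria, HBondCriteria, backbone_hbonds, distance_series,
    formation_order, fraction_formed_at_rg, local_rmsd, native_contacts,
    pearson, reduction_step, rmsd, compute_metrics,
)
from admdpath.builder import build_extended
from admdpath.structures import Conformation, Path
from admdpath.synthetic import bead_topology, make_hbond_fixture

from conftest import random_rigid_transform


def _quaternion_rmsd(a, b):
    """Independent superposition oracle via the quaternion eigenvalue method."""
    a = a - a.mean(0)
    b = b - b.mean(0)
    M = b.T @ a
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K).max()
    msd = (np.sum(a * a) + np.sum(b * b) - 2 * lam) / len(a)
    return np.sqrt(max(msd, 0.0))


def _bead_conf(xyz):
    xyz = np.asarray(xyz, float)
    return Conformation(xyz, bead_topology("A" * len(xyz)))


class TestRMSD:
    def test_identity_is_zero(self, mimic):
        assert rmsd(mimic.native, mimic.native) < 1e-8

    def test_rigid_copy_is_zero(self, mimic, rng):
        R, t = random_rigid_transform(rng)
        moved = Conformation(mimic.native.positions @ R.T + t,
                             mimic.native.topology)
        assert rmsd(mimic.native, moved) < 1e-6

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(100):
            a = rng.normal(scale=5, size=(5, 3))
            b = rng.normal(scale=5, size=(5, 3))
            got = rmsd(_bead_conf(a), _bead_conf(b))
            assert abs(got - _quaternion_rmsd(a, b)) < 1e-8

    def test_symmetry(self, rng):
        a = rng.normal(scale=5, size=(7, 3))
        b = rng.normal(scale=5, size=(7, 3))
        assert abs(rmsd(_bead_conf(a), _bead_conf(b))
                   - rmsd(_bead_conf(b), _bead_conf(a))) < 1e-10

    def test_size_mismatch_rejected(self, mimic):
        with pytest.raises(ValueError):
            rmsd(mimic.native, _bead_conf(np.zeros((5, 3))))


class TestLocalRMSD:
    def _path(self, mimic, rng):
        coords = np.stack([
            mimic.extended.positions,
            mimic.extended.positions + rng.normal(scale=0.8, size=(23, 3)),
            mimic.native.positions,
        ])
        return Path(coords, mimic.native.topology)

    def test_full_range_equals_global_rmsd(self, mimic, rng):
        path = self._path(mimic, rng)
        series = local_rmsd(path, mimic.native, (1, 23))
        expected = [rmsd(path.frame(j), mimic.native) for j in range(3)]
        np.testing.assert_allclose(series, expected, atol=1e-10)

    def test_native_frame_is_zero_for_every_range(self, mimic, rng):
        path = self._path(mimic, rng)
        for rr in ((1, 10), (11, 23), (1, 23)):
            assert local_rmsd(path, mimic.native, rr)[-1] < 1e-9

    def test_subrange_matches_extracted_substructure_oracle(self, mimic, rng):
        path = self._path(mimic, rng)
        series = local_rmsd(path, mimic.native, (11, 23))
        sub = slice(10, 23)
        expected = [_quaternion_rmsd(mimic.native.positions[sub],
                                     path.coords[j][sub]) for j in range(3)]
        np.testing.assert_allclose(series, expected, atol=1e-8)

    def test_empty_or_invalid_range_rejected(self, mimic, rng):
        path = self._path(mimic, rng)
        with pytest.raises(ValueError):
            local_rmsd(path, mimic.native, (0, 5))
        with pytest.raises(ValueError):
            local_rmsd(path, mimic.native, (8, 5))


class TestNativeContacts:
    def test_pair_just_under_cutoff_counted(self):
        # a (1, 4) pair at 6.49 Å with spacers keeping others apart
        pos = np.array([[0, 0, 0], [20, 0, 0], [40, 0, 0], [6.49, 0.4, 0]])
        pos[3] = [6.49, 0, 0]
        conf = _bead_conf(pos)
        res = native_contacts(conf, conf)
        assert (1, 4) in res.native_pairs
        assert res.count == len(res.native_pairs)

    def test_separation_two_excluded(self):
        pos = np.array([[0, 0, 0], [3.8, 3.8, 0], [4.0, 0, 0], [40, 0, 0]])
        conf = _bead_conf(pos)
        res = native_contacts(conf, conf)
        assert (1, 3) not in res.native_pairs  # |i−j| = 2, 4.0 Å

    def test_matches_double_loop_oracle(self, rng):
        crit = ContactCriteria()
        for _ in range(100):
            native = _bead_conf(rng.uniform(0, 15, size=(23, 3)))
            frame = _bead_conf(rng.uniform(0, 15, size=(23, 3)))
            res = native_contacts(frame, native, crit)
            # brute-force double loop
            npos, fpos = native.positions, frame.positions
            native_pairs = []
            for i in range(23):
                for j in range(i + 3, 23):
                    if np.linalg.norm(npos[i] - npos[j]) < 6.5:
                        native_pairs.append((i + 1, j + 1))
            count = sum(
                1 for (i, j) in native_pairs
                if np.linalg.norm(fpos[i - 1] - fpos[j - 1]) < 6.5)
            assert sorted(res.native_pairs) == native_pairs
            assert res.count == count

    def test_native_frame_recovers_all_native_pairs(self, mimic):
        res = native_contacts(mimic.native, mimic.native)
        assert res.count == len(res.native_pairs) == len(mimic.go_spec.contact_map)


class TestBackboneHbonds:
    def test_collinear_geometry_is_bond(self):
        conf, _ = make_hbond_fixture(1)
        res = backbone_hbonds(conf, conf)
        assert res.count == 1

    def test_bent_geometry_rejected_by_angle(self):
        conf, top = make_hbond_fixture(1)
        pos = conf.positions.copy()
        # move the donor H off the O···N axis: angle at H drops below 135°
        names = top.atom_names
        donor_h = np.flatnonzero((top.residue_index == 2) & (names == "H"))[0]
        pos[donor_h] += [0.0, 0.9, 0.0]
        bent = Conformation(pos, top)
        assert backbone_hbonds(bent, bent).count == 0

    def test_helix_matches_enumeration_oracle(self):
        conf, top = build_extended("A" * 12, (-57, -47, 180))
        crit = HBondCriteria(distance_dialect="O-H")
        res = backbone_hbonds(conf, conf, crit)
        # residue-by-residue enumeration oracle over all (donor, acceptor)
        sets = top.backbone_sets()
        p = conf.positions
        expected = []
        for d in range(12):
            for a in range(12):
                if d == a or sets[d]["H"] is None or sets[a]["O"] is None:
                    continue
                O, H, N = p[sets[a]["O"]], p[sets[d]["H"]], p[sets[d]["N"]]
                if np.linalg.norm(O - H) >= 2.5:
                    continue
                u, v = O - H, N - H
                ang = np.degrees(np.arccos(
                    np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v)))
                if ang > 135:
                    expected.append((d + 1, a + 1))
        assert sorted(res.native_pairs) == sorted(expected)
        assert res.count == len(expected) > 0

    def test_on_dialect_differs_for_helix(self):
        # the printed O-N < 2.5 Å criterion is stricter than helix geometry
        conf, _ = build_extended("A" * 12, (-57, -47, 180))
        on = backbone_hbonds(conf, conf, HBondCriteria(distance_dialect="O-N"))
        oh = backbone_hbonds(conf, conf, HBondCriteria(distance_dialect="O-H"))
        assert on.count == 0 and oh.count == 8

    def test_bead_model_rejected(self, mimic):
        with pytest.raises(ValueError):
            backbone_hbonds(mimic.native, mimic.native)


class TestSeriesDiagnostics:
    def test_distance_series_constant_for_identical_frames(self, mimic):
        coords = np.repeat(mimic.native.positions[None], 3, axis=0)
        path = Path(coords, mimic.native.topology)
        s = distance_series(path, (8, 14))
        assert np.ptp(s) == 0.0

    def test_distance_series_pythagorean(self):
        pos0 = np.array([[0, 0, 0], [10, 0, 0], [20, 0, 0], [30, 0, 0]])
        pos1 = pos0.copy()
        pos1[3] = [3, 4, 0]
        path = Path(np.stack([pos0, pos1, pos0]), bead_topology("AAAA"))
        assert distance_series(path, (1, 4))[1] == pytest.approx(5.0)

    def test_distance_series_matches_norm_oracle(self, mimic, rng):
        coords = rng.uniform(0, 20, size=(4, 23, 3))
        path = Path(coords, mimic.native.topology)
        s = distance_series(path, (3, 17))
        expected = [np.linalg.norm(c[2] - c[16]) for c in coords]
        np.testing.assert_allclose(s, expected, atol=1e-12)

    def test_reduction_step_linear(self):
        series = np.linspace(10, 0, 101)
        assert reduction_step(series, 0.9) == 90

    def test_reduction_step_constant_series(self):
        assert reduction_step(np.full(10, 3.0), 0.9) == 0

    def test_reduction_step_matches_scan_oracle(self, rng):
        for _ in range(100):
            s = np.sort(rng.normal(size=30))[::-1] + rng.normal(scale=0.05,
                                                                size=30)
            frac = rng.uniform(0.1, 0.95)
            level = s[-1] + (1 - frac) * (s[0] - s[-1])
            hits = [j for j in range(30) if s[j] <= level + 1e-12]
            expected = hits[0] if hits else None
            assert reduction_step(s, frac) == expected

    def test_formation_order_and_ties(self):
        n = 30
        below = 5.0
        above = 8.0
        sa = np.where(np.arange(n) >= 5, below, above)
        sb = np.where(np.arange(n) >= 9, below, above)
        sc = np.where(np.arange(n) >= 9, below, above)
        order = formation_order({(1, 4): sa, (2, 6): sb, (1, 5): sc},
                                cutoff=6.5, persistence=5)
        assert order == [((1, 4), 5), ((1, 5), 9), ((2, 6), 9)]

    def test_formation_requires_persistence(self):
        n = 40
        s = np.full(n, 8.0)
        s[10:12] = 5.0          # transient flicker: not a formation event
        s[20:] = 5.0
        order = formation_order({(1, 4): s}, cutoff=6.5, persistence=5)
        assert order == [((1, 4), 20)]

    def test_formation_order_matches_scan_oracle(self, rng):
        for _ in range(50):
            series_map = {}
            for k in range(10):
                s = rng.uniform(4, 9, size=40)
                series_map[(1, 4 + k)] = s
            got = formation_order(series_map, cutoff=6.5, persistence=5)
            expected = []
            for pair, s in series_map.items():
                step = None
                for j in range(len(s)):
                    if j + 5 <= len(s) and np.all(s[j:j + 5] < 6.5):
                        step = j
                        break
                if step is not None:
                    expected.append((pair, step))
            expected.sort(key=lambda e: (e[1], e[0]))
            assert got == expected

    def test_pearson_cases(self, rng):
        a = rng.normal(size=50)
        assert pearson(a, 2 * a + 1) == pytest.approx(1.0)
        assert pearson(a, -a) == pytest.approx(-1.0)
        b = rng.normal(size=50)
        expected = (np.mean(a * b) - a.mean() * b.mean()) / (a.std() * b.std())
        assert pearson(a, b) == pytest.approx(expected, abs=1e-10)
        with pytest.raises(ValueError):
            pearson(a, np.full(50, 2.0))


class TestCollapseDiagnostics:
    def _metrics(self, mimic):
        frac = np.linspace(0, 1, 21)[:, None, None]
        coords = (1 - frac) * mimic.extended.positions + frac * mimic.native.positions
        path = Path(coords, mimic.native.topology)
        proxy = [p for p in mimic.spec.hbond_proxy_pairs
                 if p in mimic.go_spec.contact_map]
        return compute_metrics(path, mimic.potential, mimic.native,
                               hbond_proxy_pairs=proxy, rg_weighting="uniform")

    def test_full_reduction_reaches_native_totals(self, mimic):
        m = self._metrics(mimic)
        d = fraction_formed_at_rg(m, 1.0)
        assert d.percent_contacts == pytest.approx(100.0)
        assert d.percent_hbonds == pytest.approx(100.0)
        assert d.frame_index == 20

    def test_zero_reduction_is_start_point(self, mimic):
        m = self._metrics(mimic)
        d = fraction_formed_at_rg(m, 0.0)
        assert d.frame_index == 0
        assert d.percent_hbonds == 0.0

    def test_matches_recomputation_from_raw_series(self, mimic):
        m = self._metrics(mimic)
        d = fraction_formed_at_rg(m, 0.7)
        j = reduction_step(m.rg, 0.7)
        assert d.frame_index == j
        assert d.percent_contacts == pytest.approx(
            100.0 * m.n_native_contacts[j] / m.native_contact_total)

    def test_contact_count_at_native_endpoint_is_total(self, mimic):
        m = self._metrics(mimic)
        assert m.n_native_contacts[-1] == m.native_contact_total
        assert m.n_native_hbonds[-1] == m.native_hbond_total
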