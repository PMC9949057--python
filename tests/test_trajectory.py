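"""Geometry operators versus brute-force oracles and scripted fixtures."""

import numpy as np
import pytest

from rndflux.synthetic import script_trajectory
from rndflux.trajectory import (
    ContactTable,
    CylinderSpec,
    TrajectoryEnsemble,
    contact_occupancy,
    cylinder_count,
    ion_rmsd,
    min_helix_distance,
    select,
    top_k_residues,
    water_density_grid,
    z_trace,
)


def make_ensemble(coords, names=None, resnames=None, resids=None, chains=None,
                  box=None):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    return TrajectoryEnsemble(
        names=np.array(names if names is not None else ["X"] * n),
        resnames=np.array(resnames if resnames is not None else ["UNK"] * n),
        resids=np.array(resids if resids is not None else np.arange(1, n + 1)),
        chains=np.array(chains if chains is not None else ["A"] * n),
        coords=coords,
        times=np.arange(coords.shape[0], dtype=float),
        box=box,
    )


def random_ensemble(rng, n_frames=4, n_atoms=200, box=None):
    coords = rng.uniform(0, 5, size=(n_frames, n_atoms, 3))
    names = rng.choice(["OW", "NA", "CA", "CB"], size=n_atoms).astype("U8")
    resids = rng.integers(1, 40, size=n_atoms)
    return make_ensemble(
        coords,
        names=names,
        resnames=["RES"] * n_atoms,
        resids=resids,
        box=box,
    )


def anchors_spec(**kwargs):
    return CylinderSpec(
        anchor_a={"name": "ANCA"}, anchor_b={"name": "ANCB"}, **kwargs
    )


def with_anchors(coords_fn, n_frames, za=-2.0, zb=2.0):
    """Prepend two anchor atoms on the z axis so the midpoint is the origin."""
    frames = []
    for f in range(n_frames):
        frame = [
            ("ANCA", "PRO", 900, "P", (0.0, 0.0, za)),
            ("ANCB", "PRO", 901, "P", (0.0, 0.0, zb)),
        ]
        frame.extend(coords_fn(f))
        frames.append(frame)
    return script_trajectory(frames)


class TestCylinderCount:
    def test_scripted_ec_half_count(self):
        # exactly 6 waters in the extracellular half every frame
        def waters(f):
            recs = [
                ("OW", "SOL", 10 + i, "W", (0.1 * i, 0.0, 0.5 + 0.1 * i))
                for i in range(6)
            ]
            recs.append(("OW", "SOL", 50, "W", (0.0, 0.0, -1.0)))  # IC half
            recs.append(("OW", "SOL", 51, "W", (3.0, 0.0, 0.5)))  # outside radius
            return recs

        traj = with_anchors(waters, n_frames=10)
        spec = anchors_spec(length=4.0, radius=1.3, half="extracellular")
        res = cylinder_count(traj, spec, {"name": "OW"})
        assert res.mean == pytest.approx(6.0)
        assert res.sd == pytest.approx(0.0)

    def test_boundary_conventions(self):
        def particles(f):
            return [
                ("P1", "ION", 1, "I", (0.0, 0.0, 0.0)),  # midplane point
                ("P2", "ION", 2, "I", (1.3, 0.0, 0.5)),  # radial boundary
                ("P3", "ION", 3, "I", (0.0, 0.0, 2.0)),  # axial boundary
            ]

        traj = with_anchors(particles, n_frames=1)
        whole = anchors_spec(length=4.0, radius=1.3, half="whole")
        ec = anchors_spec(length=4.0, radius=1.3, half="extracellular")
        ic = anchors_spec(length=4.0, radius=1.3, half="intracellular")
        assert cylinder_count(traj, whole, {"resname": "ION"}).mean == 3
        # boundary points (closed cylinder) all sit on the EC side
        assert cylinder_count(traj, ec, {"resname": "ION"}).mean == 3
        assert cylinder_count(traj, ic, {"resname": "ION"}).mean == 0

    def test_trailing_window(self):
        def particles(f):
            z = 0.5 if f >= 8 else 10.0  # inside only for the last 2 frames
            return [("P1", "ION", 1, "I", (0.0, 0.0, z))]

        traj = with_anchors(particles, n_frames=10)
        spec = anchors_spec()
        assert cylinder_count(traj, spec, {"resname": "ION"}).mean == pytest.approx(0.2)
        last = cylinder_count(traj, spec, {"resname": "ION"}, window=1.0)
        assert last.mean == pytest.approx(1.0)
        with pytest.raises(ValueError, match="window"):
            cylinder_count(traj, spec, {"resname": "ION"}, window=100.0)

    def test_ambiguous_anchor_rejected(self):
        frames = [[("ANCA", "P", 1, "A", (0, 0, 0)), ("ANCA", "P", 2, "A", (0, 0, 1))]]
        traj = script_trajectory(frames)
        spec = CylinderSpec(anchor_a={"name": "ANCA"}, anchor_b={"name": "ANCA"})
        with pytest.raises(ValueError, match="exactly one"):
            cylinder_count(traj, spec, {"name": "ANCA"})

    def test_brute_force_oracle_with_box(self, rng):
        traj = random_ensemble(rng, box=np.array([5.0, 5.0, 5.0]))
        # plant anchors as existing atoms
        traj.names[0], traj.names[1] = "A1", "A2"
        spec = CylinderSpec(
            anchor_a={"name": "A1"}, anchor_b={"name": "A2"},
            length=3.0, radius=1.0,
        )
        res = cylinder_count(traj, spec, {"name": "OW"})
        box = traj.box
        mask = select(traj, name="OW")
        for f in range(traj.n_frames):
            center = 0.5 * (traj.coords[f, 0] + traj.coords[f, 1])
            n = 0
            for xyz in traj.coords[f, mask]:
                d = xyz - center
                d = d - box * np.round(d / box)
                if abs(d[2]) <= 1.5 and np.hypot(d[0], d[1]) <= 1.0:
                    n += 1
            assert res.per_frame[f] == n

    def test_permutation_invariance(self, rng):
        traj = random_ensemble(rng)
        traj.names[0], traj.names[1] = "A1", "A2"
        spec = CylinderSpec(anchor_a={"name": "A1"}, anchor_b={"name": "A2"})
        base = cylinder_count(traj, spec, {"name": "OW"}).per_frame
        perm = rng.permutation(traj.n_atoms)
        shuffled = make_ensemble(
            traj.coords[:, perm, :],
            names=traj.names[perm],
            resnames=traj.resnames[perm],
            resids=traj.resids[perm],
            chains=traj.chains[perm],
        )
        again = cylinder_count(shuffled, spec, {"name": "OW"}).per_frame
        np.testing.assert_array_equal(base, again)


class TestZTrace:
    def test_empty_region_empty_table(self):
        traj = with_anchors(lambda f: [("OW", "SOL", 1, "W", (10.0, 10.0, 10.0))], 3)
        table = z_trace(traj, anchors_spec(), {"water": {"name": "OW"}})
        assert table.empty

    def test_fixed_ion_constant_trace(self):
        traj = with_anchors(lambda f: [("NA", "NA", 1, "I", (0.0, 0.0, 0.5))], 5)
        table = z_trace(traj, anchors_spec(), {"Na+": {"name": "NA"}})
        assert len(table) == 5
        assert (table["z_nm"] == 0.5).all()
        assert (table["species"] == "Na+").all()

    def test_entry_mid_trajectory(self):
        def water(f):
            z = 0.5 if f >= 5 else 30.0
            return [("OW", "SOL", 1, "W", (0.0, 0.0, z))]

        traj = with_anchors(water, 10)
        table = z_trace(traj, anchors_spec(), {"water": {"name": "OW"}})
        assert sorted(table["time_ps"]) == [5.0, 6.0, 7.0, 8.0, 9.0]


class TestContacts:
    def test_always_in_contact_is_100(self):
        def frame(f):
            return [
                ("NA", "NA", 500, "I", (0.0, 0.0, 0.0)),
                ("OD1", "ASP", 513, "A", (0.2, 0.0, 0.0)),
            ]

        traj = script_trajectory([frame(f) for f in range(10)])
        table = contact_occupancy(
            traj, {"name": "NA"}, {"resname": "ASP"}, cutoff=0.3
        )
        assert table.table.iloc[0]["occupancy_pct"] == pytest.approx(100.0)

    def test_nine_of_ten_frames_is_90(self):
        frames = []
        for f in range(10):
            dist = 0.2 if f < 9 else 1.0
            frames.append(
                [
                    ("NA", "NA", 500, "I", (0.0, 0.0, 0.0)),
                    ("OD1", "ASP", 513, "A", (dist, 0.0, 0.0)),
                ]
            )
        table = contact_occupancy(
            script_trajectory(frames), {"name": "NA"}, {"resname": "ASP"},
            cutoff=0.3, min_report=1.0,
        )
        assert table.table.iloc[0]["occupancy_pct"] == pytest.approx(90.0)

    def test_cutoff_is_strict(self):
        frames = [
            [
                ("NA", "NA", 500, "I", (0.0, 0.0, 0.0)),
                ("OD1", "ASP", 513, "A", (0.31, 0.0, 0.0)),
            ]
        ] * 4
        table = contact_occupancy(
            script_trajectory(frames), {"name": "NA"}, {"resname": "ASP"},
            cutoff=0.3,
        )
        assert table.table.empty

    def test_min_report_threshold_drops_rare_contacts(self):
        frames = []
        for f in range(200):
            dist = 0.2 if f == 0 else 1.0  # 0.5 % occupancy
            frames.append(
                [
                    ("NA", "NA", 500, "I", (0.0, 0.0, 0.0)),
                    ("OD1", "ASP", 513, "A", (dist, 0.0, 0.0)),
                ]
            )
        table = contact_occupancy(
            script_trajectory(frames), {"name": "NA"}, {"resname": "ASP"},
            cutoff=0.3, min_report=1.0,
        )
        assert table.table.empty

    def test_brute_force_oracle(self, rng):
        traj = random_ensemble(rng, n_frames=3, n_atoms=60)
        traj.names[0] = "PRB"
        table = contact_occupancy(
            traj, {"name": "PRB"}, {"name": ["CA", "CB"]}, cutoff=0.8,
            min_report=0.0,
        )
        got = {
            (row["resid"]): row["occupancy_pct"]
            for _, row in table.table.iterrows()
        }
        mask = select(traj, name=["CA", "CB"])
        by_res = {}
        for ai in np.flatnonzero(mask):
            by_res.setdefault(int(traj.resids[ai]), []).append(ai)
        for resid, atoms in by_res.items():
            hits = 0
            for f in range(traj.n_frames):
                d = min(
                    np.linalg.norm(traj.coords[f, a] - traj.coords[f, 0])
                    for a in atoms
                )
                hits += d < 0.8
            expected = 100.0 * hits / traj.n_frames
            assert got.get(resid, 0.0) == pytest.approx(expected)

    def test_subsampling_invariance_for_constant_contacts(self):
        frames = [
            [
                ("NA", "NA", 500, "I", (0.0, 0.0, 0.0)),
                ("OD1", "ASP", 513, "A", (0.2, 0.0, 0.0)),
            ]
        ] * 12
        full = contact_occupancy(
            script_trajectory(frames), {"name": "NA"}, {"resname": "ASP"}
        )
        sub = contact_occupancy(
            script_trajectory(frames[::3]), {"name": "NA"}, {"resname": "ASP"}
        )
        assert (
            full.table.iloc[0]["occupancy_pct"]
            == sub.table.iloc[0]["occupancy_pct"]
        )


class TestTopK:
    def _table(self, rows):
        import pandas as pd

        df = pd.DataFrame(
            [
                {
                    "residue": f"RES{rid}",
                    "resname": "RES",
                    "resid": rid,
                    "chain": "A",
                    "occupancy_pct": occ,
                }
                for rid, occ in rows
            ]
        ).sort_values(["occupancy_pct", "resid"], ascending=[False, True])
        return ContactTable(df.reset_index(drop=True), cutoff=0.6, min_report=1.0)

    def test_k_larger_than_table_returns_all(self):
        table = self._table([(1, 10.0), (2, 20.0)])
        assert top_k_residues(table, 5) == ["RES2", "RES1"]

    def test_tie_breaks_by_residue_number(self):
        table = self._table([(200, 50.0), (100, 50.0)])
        assert top_k_residues(table, 1) == ["RES100"]

    def test_planted_top_four(self):
        rows = [(1, 90.0), (2, 80.0), (3, 70.0), (4, 60.0), (5, 5.0), (6, 2.0)]
        table = self._table(rows)
        assert top_k_residues(table, 4) == ["RES1", "RES2", "RES3", "RES4"]


class TestIonRmsd:
    def test_static_ion_is_zero(self):
        traj = make_ensemble(np.zeros((5, 1, 3)), names=["NA"])
        res = ion_rmsd(traj, {"name": "NA"})
        assert res.mean[0] == 0.0 and res.sd[0] == 0.0

    def test_constant_displacement(self):
        coords = np.zeros((6, 1, 3))
        coords[1:, 0, 0] = 0.2
        traj = make_ensemble(coords, names=["NA"])
        res = ion_rmsd(traj, {"name": "NA"}, reference=np.zeros((1, 3)))
        assert np.allclose(res.per_frame[1:], 0.2)

    def test_alignment_removes_rigid_translation(self):
        rng = np.random.default_rng(3)
        protein = rng.uniform(0, 2, size=(10, 3))
        ion = np.array([1.0, 1.0, 1.0])
        frames = []
        for f in range(5):
            shift = np.array([0.3 * f, 0.0, 0.0])
            coords = np.vstack([protein + shift, ion + shift])
            frames.append(coords)
        coords = np.array(frames)
        names = ["CA"] * 10 + ["NA"]
        traj = make_ensemble(coords, names=names)
        raw = ion_rmsd(traj, {"name": "NA"})
        assert raw.mean[0] > 0.1
        aligned = ion_rmsd(traj, {"name": "NA"}, align={"name": "CA"})
        assert aligned.mean[0] == pytest.approx(0.0, abs=1e-9)

    def test_multi_ion_reports_per_ion(self):
        coords = np.zeros((4, 2, 3))
        coords[1:, 1, 2] = 0.5
        traj = make_ensemble(coords, names=["NA", "NA"])
        res = ion_rmsd(traj, {"name": "NA"})
        assert res.mean.shape == (2,)
        assert res.mean[0] == 0.0
        assert res.mean[1] == pytest.approx(0.375)


class TestMinHelixDistance:
    def test_fixed_single_pair(self):
        coords = np.zeros((4, 2, 3))
        coords[:, 1, 0] = 1.0
        traj = make_ensemble(coords, names=["CA", "CA"], resids=[10, 20])
        res = min_helix_distance(traj, {"resid": 10}, {"resid": 20})
        assert np.allclose(res.per_frame, 1.0)

    def test_step_increase_mid_trajectory(self):
        coords = np.zeros((10, 2, 3))
        coords[:, 1, 0] = 1.0
        coords[5:, 1, 0] = 1.4  # outward shift by 0.4 nm
        traj = make_ensemble(coords, names=["CA", "CA"], resids=[10, 20])
        res = min_helix_distance(traj, {"resid": 10}, {"resid": 20})
        assert np.allclose(res.per_frame[:5], 1.0)
        assert np.allclose(res.per_frame[5:], 1.4)

    def test_brute_force_oracle(self, rng):
        traj = random_ensemble(rng, n_frames=3, n_atoms=50)
        sel_a = {"resid": [1, 2, 3, 4, 5]}
        sel_b = {"resid": [20, 21, 22]}
        ma = select(traj, **sel_a)
        mb = select(traj, **sel_b)
        if not (ma.any() and mb.any()):
            pytest.skip("random fixture missing residues")
        res = min_helix_distance(traj, sel_a, sel_b)
        for f in range(traj.n_frames):
            brute = min(
                np.linalg.norm(a - b)
                for a in traj.coords[f, ma]
                for b in traj.coords[f, mb]
            )
            assert res.per_frame[f] == pytest.approx(brute)

    def test_empty_selection_rejected(self):
        traj = make_ensemble(np.zeros((2, 2, 3)), names=["CA", "CA"])
        with pytest.raises(ValueError):
            min_helix_distance(traj, {"name": "ZZ"}, {"name": "CA"})


class TestDensityGrid:
    def test_single_water_single_voxel(self):
        traj = make_ensemble(np.full((1, 1, 3), 1.05), names=["OW"])
        grid = water_density_grid(traj, {"name": "OW"}, voxel=0.1)
        nonzero = np.nonzero(grid.values)
        assert len(nonzero[0]) == 1
        assert grid.values[nonzero][0] == pytest.approx(1 / 0.1**3)

    def test_integrated_density_equals_mean_count(self, rng):
        traj = random_ensemble(rng, n_frames=5, n_atoms=100)
        grid = water_density_grid(traj, {"name": "OW"}, voxel=0.25)
        expected = select(traj, name="OW").sum()
        assert grid.integrated_count() == pytest.approx(expected)

    def test_uniform_scripted_waters_near_uniform(self, rng):
        # Poisson counting bound on a uniform cloud
        coords = rng.uniform(0, 2, size=(40, 500, 3))
        traj = make_ensemble(coords, names=["OW"] * 500)
        region = np.array([[0.0, 2.0], [0.0, 2.0], [0.0, 2.0]])
        grid = water_density_grid(traj, {"name": "OW"}, voxel=0.5, region=region)
        counts = grid.values * 0.5**3  # mean count per voxel
        lam = 500 / counts.size
        assert abs(counts.mean() - lam) < 0.1 * lam
        assert counts.std() < 3 * np.sqrt(lam / 40)

    def test_invalid_voxel_rejected(self):
        traj = make_ensemble(np.zeros((1, 1, 3)), names=["OW"])
        with pytest.raises(ValueError):
            water_density_grid(traj, {"name": "OW"}, voxel=0.0)
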