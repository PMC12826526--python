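import numpy as np
import pytest

from conftest import make_crosslink_set
from looplink.exceptions import ContractError
from looplink.netbuild import NetworkConfig, build_network
from looplink.structmap import (
    DistanceConstraint,
    LayoutConfig,
    RgSimConfig,
    StructureModel,
    distance_stats,
    layout3d,
    map_constraints,
    radius_of_gyration,
    read_calpha,
    rescale_to_backbone,
    simulate_rg,
)


def pdb_line(serial, resseq, x, y, z, alt=" ", occ=1.0, chain="A"):
    return (f"ATOM  {serial:5d}  CA {alt}ALA {chain}{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}           C")


@pytest.fixture
def tiny_pdb(tmp_path):
    lines = [
        pdb_line(1, 1, 0.0, 0.0, 0.0),
        pdb_line(2, 2, 3.8, 0.0, 0.0),
        pdb_line(3, 3, 7.6, 0.0, 0.0),
        "END",
    ]
    path = tmp_path / "tiny.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadCalpha:
    def test_three_residue_fixture(self, tiny_pdb):
        model = read_calpha(tiny_pdb, "A")
        assert len(model.coords) == 3
        assert model.distance(1, 3) == pytest.approx(7.6)

    def test_altloc_resolves_to_highest_occupancy(self, tmp_path):
        lines = [
            pdb_line(1, 1, 0.0, 0.0, 0.0, alt="A", occ=0.3),
            pdb_line(2, 1, 9.9, 0.0, 0.0, alt="B", occ=0.7),
            pdb_line(3, 2, 1.0, 0.0, 0.0),
            "END",
        ]
        path = tmp_path / "alt.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_calpha(path, "A")
        assert len(model.coords) == 2
        assert model.coords[("A", 1)][0] == pytest.approx(9.9)

    def test_missing_chain_raises_lookup_error(self, tiny_pdb):
        with pytest.raises(LookupError):
            read_calpha(tiny_pdb, "B")


class TestMapConstraints:
    @pytest.fixture
    def model(self):
        coords = {("A", 1): np.zeros(3), ("A", 2): np.array([30.0, 0, 0]),
                  ("A", 3): np.array([0.0, 0, 45.0])}
        return StructureModel(source_id="m", coords=coords)

    def test_distances_and_flags(self, model):
        mapping = map_constraints(model, [(1, 2), (1, 3)])
        by_pair = {c.pair: c for c in mapping.constraints}
        assert by_pair[(1, 2)].distance == pytest.approx(30.0)
        assert by_pair[(1, 2)].flag == "within"
        assert by_pair[(1, 3)].distance == pytest.approx(45.0)
        assert by_pair[(1, 3)].flag == "beyond"

    def test_unmappable_pairs_are_skipped_not_dropped_silently(self, model):
        mapping = map_constraints(model, [(1, 2), (1, 99)])
        assert len(mapping.constraints) + len(mapping.skipped) == 2
        assert mapping.skipped == ((1, 99),)

    def test_offset_shifts_numbering(self, model):
        # sequence site 0 maps to structure residue 1 with offset 1
        mapping = map_constraints(model, [(0, 1)], offset=1)
        assert mapping.constraints[0].distance == pytest.approx(30.0)


class TestDistanceStats:
    def test_mean_sd_p95(self):
        cs = [DistanceConstraint((1, k), float(d), "within")
              for k, d in enumerate([1, 2, 3], start=3)]
        stats = distance_stats(cs)
        assert stats.mean == pytest.approx(2.0)
        assert stats.sd == pytest.approx(np.std([1, 2, 3]))

    def test_constant_distances(self):
        stats = distance_stats([7.0, 7.0, 7.0])
        assert stats.sd == 0.0
        assert stats.p95 == 7.0

    def test_uniform_sample_p95(self):
        rng = np.random.default_rng(8)
        d = rng.uniform(0, 100, size=1000)
        stats = distance_stats(list(d))
        se = 100 * np.sqrt(0.95 * 0.05 / 1000) / 1.0  # order-stat SE approx
        assert abs(stats.p95 - 95.0) < 3 * se * 10  # generous; exactness not claimed

    def test_empty_rejected(self):
        with pytest.raises(ContractError):
            distance_stats([])


class TestRadiusOfGyration:
    def test_single_point_is_zero(self):
        assert radius_of_gyration([[1.0, 2.0, 3.0]]) == 0.0

    def test_two_points_half_separation(self):
        assert radius_of_gyration([[0, 0, 0], [10, 0, 0]]) == pytest.approx(5.0)

    def test_points_on_sphere_give_radius(self, rng):
        rho = 12.5
        v = rng.normal(size=(200, 3))
        pts = rho * v / np.linalg.norm(v, axis=1, keepdims=True)
        # symmetrize so the centroid is exactly at the origin
        pts = np.vstack([pts, -pts])
        assert radius_of_gyration(pts) == pytest.approx(rho, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(size=(50, 3))
        base = radius_of_gyration(pts)
        for _ in range(5):
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            moved = pts @ q.T + rng.normal(size=3) * 100
            assert abs(radius_of_gyration(moved) - base) < 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ContractError):
            radius_of_gyration(np.zeros((0, 3)))


class TestLayout3d:
    def test_seeded_determinism_is_bitwise(self):
        net = build_network(12, make_crosslink_set({(2, 10): 1}))
        c1 = layout3d(net, LayoutConfig(iterations=50, seed=3))
        c2 = layout3d(net, LayoutConfig(iterations=50, seed=3))
        for n in c1:
            assert (c1[n] == c2[n]).all()

    def test_two_node_path_rescales_to_target_length(self):
        net = build_network(2, make_crosslink_set({}),
                            NetworkConfig(backbone_weight=7.5))
        coords = layout3d(net, LayoutConfig(iterations=50, seed=1))
        d = np.linalg.norm(coords[1] - coords[2])
        assert d == pytest.approx(7.5)

    def test_long_range_links_compact_the_chain(self):
        pairs = {(2, 18): 1, (3, 15): 1, (5, 19): 1, (1, 10): 1, (8, 16): 1}
        bare = build_network(20, make_crosslink_set({}),
                             NetworkConfig.visualization())
        linked = build_network(20, make_crosslink_set(pairs),
                               NetworkConfig(backbone_weight=1.0,
                                             crosslink_weight=1.0))
        wins = 0
        for seed in range(10):
            cfg = LayoutConfig(iterations=200, seed=seed)
            rg_bare = radius_of_gyration(
                np.array(list(layout3d(bare, cfg).values())))
            rg_linked = radius_of_gyration(
                np.array(list(layout3d(linked, cfg).values())))
            wins += rg_linked < rg_bare
        assert wins >= 8


class TestSimulateRg:
    def test_degenerate_two_node_network(self, rng):
        net = build_network(2, make_crosslink_set({}))
        result = simulate_rg(net, RgSimConfig(n_sim=1,
                                              layout=LayoutConfig(iterations=50)),
                             rng)
        assert result.rg_values[0][0] == pytest.approx(1.9)

    def test_rescaling_preserves_mean_backbone_spacing(self):
        net = build_network(15, make_crosslink_set({(2, 12): 1}),
                            NetworkConfig.physical())
        coords = layout3d(net, LayoutConfig(iterations=100, seed=4),
                          rescale=False)
        coords = rescale_to_backbone(coords, net)
        spacings = [np.linalg.norm(coords[i] - coords[j])
                    for i, j in net.backbone_edges]
        assert np.mean(spacings) == pytest.approx(3.8, abs=1e-6)

    def test_crosslinks_compact_the_simulated_chain(self, rng):
        bare = build_network(40, make_crosslink_set({}), NetworkConfig.physical())
        pairs = {(int(i), int(j)): 1
                 for i, j in rng.integers(1, 41, size=(20, 2))
                 if j - i >= 2}
        linked = build_network(40, make_crosslink_set(pairs),
                               NetworkConfig.physical())
        cfg = RgSimConfig(n_sim=5, crosslink_ranges=((26.0, 30.0),),
                          layout=LayoutConfig(iterations=150))
        rg_bare = np.mean(simulate_rg(bare, cfg, np.random.default_rng(1)).rg_values[0])
        rg_linked = np.mean(simulate_rg(linked, cfg, np.random.default_rng(1)).rg_values[0])
        assert rg_linked < rg_bare

    def test_reproducible_under_fixed_seed(self):
        net = build_network(12, make_crosslink_set({(2, 10): 1}),
                            NetworkConfig.physical())
        cfg = RgSimConfig(n_sim=3, layout=LayoutConfig(iterations=50))
        r1 = simulate_rg(net, cfg, np.random.default_rng(9))
        r2 = simulate_rg(net, cfg, np.random.default_rng(9))
        assert r1.rg_values == r2.rg_values
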