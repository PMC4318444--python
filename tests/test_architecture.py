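import dataclasses
import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rhizotrace as rt
from rhizotrace.architecture import (Lateral, RootTopology, _pixel_graph,
                                     compute_lauz, compute_lateral_density,
                                     lateral_profile, measure_local_traits)
from rhizotrace.segmentation import BinaryMask
from rhizotrace.synthetic import PlantGeometry, _GtLateral

from conftest import make_noiseless_scene, recover_topology


def _mask(px, scale=0.01):
    return BinaryMask(np.asarray(px, bool), scale, "root")


def _ribbon(canvas, p, q, w=3):
    from skimage import draw
    p, q = np.asarray(p, float), np.asarray(q, float)
    d = q - p
    n = np.array([-d[1], d[0]]) / np.hypot(*d) * w / 2
    rr, cc = draw.polygon([p[0] + n[0], q[0] + n[0], q[0] - n[0], p[0] - n[0]],
                          [p[1] + n[1], q[1] + n[1], q[1] - n[1], p[1] - n[1]],
                          shape=canvas.shape)
    canvas[rr, cc] = True


class TestSkeletonize:
    def test_straight_ribbon_length(self):
        px = np.zeros((40, 450), bool)
        _ribbon(px, (20, 10), (20, 410), w=3)
        skel = rt.skeletonize_mask(_mask(px))
        assert abs(int(skel.sum()) - 400) <= 3

    def test_filled_disk_collapses(self):
        px = np.zeros((60, 60), bool)
        yy, xx = np.mgrid[:60, :60]
        px[(yy - 30) ** 2 + (xx - 30) ** 2 <= 12 ** 2] = True
        skel = rt.skeletonize_mask(_mask(px))
        assert skel.sum() <= 5

    def test_y_junction_one_branch_three_endpoints(self):
        px = np.zeros((350, 350), bool)
        _ribbon(px, (10, 100), (210, 100))            # stem, 200 px
        _ribbon(px, (208, 100), (330, 240))           # arm 1
        _ribbon(px, (208, 102), (330, 320))           # arm 2 (other angle)
        skel = rt.skeletonize_mask(_mask(px))
        g = _pixel_graph(skel)
        deg = dict(g.degree())
        endpoints = [n for n, d in deg.items() if d == 1]
        junctions = {n for n, d in deg.items() if d >= 3}
        # adjacent junction pixels form one physical branch point
        n_branch = nx.number_connected_components(g.subgraph(junctions))
        assert len(endpoints) == 3
        assert n_branch == 1

    def test_empty_mask_gives_empty_skeleton(self):
        skel = rt.skeletonize_mask(_mask(np.zeros((10, 10))))
        assert not skel.any()


def _simple_topology():
    # primary 10 cm straight; laterals inserted at 2, 4, 6 cm from the base
    primary = np.column_stack([np.zeros(11), np.linspace(0, 10, 11)])
    lats = []
    for ins, length in [(2.0, 3.0), (4.0, 2.0), (6.0, 1.0)]:
        poly = np.column_stack([np.linspace(0, length, 5),
                                np.full(5, ins)])
        lats.append(Lateral(ins, 10.0 - ins, poly, length))
    return RootTopology(primary, lats, 10.0)


class TestLocalTraits:
    def test_insertion_from_apex_arithmetic(self):
        topo = _simple_topology()
        assert [l.insertion_from_apex for l in topo.laterals] == [8.0, 6.0, 4.0]

    def test_lauz_definition(self):
        assert compute_lauz(_simple_topology()) == pytest.approx(4.0)

    def test_lauz_equals_primary_length_without_laterals(self):
        bare = RootTopology(np.array([[0.0, 0.0], [0.0, 7.0]]), [], 7.0)
        assert compute_lauz(bare) == 7.0

    def test_density_five_laterals_eight_cm_branched_zone(self):
        # 5 laterals, primary 10 cm, LAUZ 2 cm -> 5/8 per cm
        primary = np.column_stack([np.zeros(11), np.linspace(0, 10, 11)])
        lats = [Lateral(i * 2.0, 10 - i * 2.0,
                        np.array([[0.0, i * 2.0], [1.0, i * 2.0]]), 1.0)
                for i in range(5)]  # insertions 0,2,4,6,8 -> most apical 8
        topo = RootTopology(primary, lats, 10.0)
        assert compute_lateral_density(topo) == pytest.approx(0.625)

    def test_density_single_lateral(self):
        primary = np.column_stack([np.zeros(11), np.linspace(0, 10, 11)])
        lat = Lateral(6.0, 4.0, np.array([[0.0, 6.0], [1.0, 6.0]]), 1.0)
        topo = RootTopology(primary, [lat], 10.0)
        assert compute_lateral_density(topo) == pytest.approx(1.0 / 6.0)

    def test_density_undefined_without_laterals(self):
        bare = RootTopology(np.array([[0.0, 0.0], [0.0, 7.0]]), [], 7.0)
        with pytest.raises(ValueError):
            compute_lateral_density(bare)
        assert measure_local_traits(bare).lateral_density is None

    def test_profile_sorted_by_insertion_from_apex(self):
        assert lateral_profile(_simple_topology()) == [(4.0, 1.0), (6.0, 2.0),
                                                       (8.0, 3.0)]

    def test_profile_empty_without_laterals(self):
        bare = RootTopology(np.array([[0.0, 0.0], [0.0, 7.0]]), [], 7.0)
        assert lateral_profile(bare) == []


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10 ** 9))
def test_partition_identity_on_random_topologies(seed):
    """LAUZ + branched-zone length = primary length, always and exactly."""
    rng = np.random.default_rng(seed)
    length = rng.uniform(1, 30)
    primary = np.column_stack([np.zeros(5), np.linspace(0, length, 5)])
    n = rng.integers(0, 12)
    ins = np.sort(rng.uniform(0, length, n))
    lats = [Lateral(float(s), float(length - s),
                    np.array([[0.0, s], [1.0, s]]), 1.0) for s in ins]
    traits = measure_local_traits(RootTopology(primary, lats, float(length)))
    assert traits.lauz + traits.branched_zone_length == pytest.approx(
        traits.primary_length, abs=1e-12)


class TestBuildTopology:
    def test_bare_primary_length_within_two_percent(self):
        geom = PlantGeometry(
            rt.sample_plant(dataclasses.replace(rt.PlantModel(), lateral_rate=0.0),
                            3).primary, 18.0, [], 2.0, 3, 3)
        scene = rt.render_scene(geom, rng_seed=3, noise_sd=0,
                                mesh_brightness=0, glint_fraction=0, vignette=0)
        topo = recover_topology(scene)
        assert topo.laterals == []
        assert topo.primary_length == pytest.approx(18.0, rel=0.02)

    def test_seed_far_from_skeleton_raises(self):
        px = np.zeros((100, 100), bool)
        _ribbon(px, (40, 50), (90, 50))
        skel = rt.skeletonize_mask(_mask(px))
        with pytest.raises(rt.SeedNotFoundError):
            rt.build_topology(skel, (5.0, 2.0), 0.01, snap_radius_cm=0.1)

    def test_disconnected_fragments_counted_not_traced(self):
        px = np.zeros((200, 120), bool)
        _ribbon(px, (5, 60), (120, 60))
        _ribbon(px, (160, 10), (160, 110))  # far fragment
        skel = rt.skeletonize_mask(_mask(px))
        topo = rt.build_topology(skel, (60.0, 5.0), 0.01)
        assert topo.n_excluded_px > 50
        assert topo.primary_length == pytest.approx(1.15, abs=0.05)

    def test_min_lateral_threshold_counts_only_long_branches(self):
        # 8 laterals above the 0.3 cm floor, 3 short spurs below it
        rule = lambda age: 1.2 if age > 6 else 0.12
        model = dataclasses.replace(rt.PlantModel(), primary_length=14.0,
                                    lateral_length_rule=rule)
        geom = rt.sample_plant(model, 12)
        n_long = sum(l.length >= 0.3 for l in geom.laterals)
        n_short = sum(l.length < 0.3 for l in geom.laterals)
        assert n_long > 0 and n_short > 0
        scene = rt.render_scene(geom, rng_seed=12, noise_sd=0,
                                mesh_brightness=0, glint_fraction=0, vignette=0)
        topo = recover_topology(scene)
        assert topo.n_laterals == n_long

    def test_primary_is_max_arclength_geodesic_vs_enumeration_oracle(self):
        """On a small skeleton the traced primary must match exhaustive
        enumeration: for every node take the minimum-weight simple path
        from the seed (its geodesic), then the farthest node wins."""
        px = np.zeros((90, 90), bool)
        _ribbon(px, (5, 30), (80, 30))
        _ribbon(px, (40, 30), (70, 62))
        skel = rt.skeletonize_mask(_mask(px))
        assert skel.sum() <= 500
        g = _pixel_graph(skel)
        seed = min(map(tuple, np.argwhere(skel)))
        best_node, best_dist = None, -1.0
        for node in g.nodes:
            dmin = np.inf
            for path in nx.all_simple_paths(g, seed, node, cutoff=160):
                wsum = sum(g[a][b]["weight"]
                           for a, b in itertools.pairwise(path))
                dmin = min(dmin, wsum)
            if node == seed:
                dmin = 0.0
            if dmin != np.inf and (dmin > best_dist
                                   or (dmin == best_dist and node > best_node)):
                best_node, best_dist = node, dmin
        topo = rt.build_topology(skel, (seed[1], seed[0]), 0.01)
        assert topo.primary_length * 100 == pytest.approx(best_dist, rel=0.05)


class TestRecoveryAgainstGroundTruth:
    def test_lateral_count_exact_and_lauz_tight(self, noiseless_scenes):
        for scene in noiseless_scenes:
            topo = recover_topology(scene)
            truth = scene.truth_topology
            assert topo.n_laterals == truth.n_laterals
            assert abs(compute_lauz(topo) - compute_lauz(truth)) \
                <= 2 * scene.truth_mask.scale

    def test_acropetal_profile_increases_with_insertion_from_apex(
            self, noiseless_scenes):
        topo = recover_topology(noiseless_scenes[0])
        prof = lateral_profile(topo)
        lengths = [l for _, l in prof]
        # older (more basal) laterals are longer; tolerate ties and px noise
        assert all(b - a >= -0.06 for a, b in itertools.pairwise(lengths))

    def test_noise_robust_lateral_count(self):
        for seed in range(20):
            geom = rt.sample_plant(rt.PlantModel(), 40 + seed)
            scene = rt.render_scene(geom, rng_seed=700 + seed)
            mask = rt.segment_root(scene.image)
            topo = recover_topology(scene, mask=mask)
            assert topo.n_laterals == scene.truth_topology.n_laterals


def test_inhibited_regime_lowers_density_and_raises_lauz():
    """Halving lateral emergence (with the other inhibition multipliers)
    must separate 10 vs 10 plants on density and LAUZ."""
    from scipy import stats as sps
    control, treated = [], []
    for i in range(10):
        gc = rt.sample_plant(rt.PlantModel(), 100 + i)
        gt_ = rt.sample_plant(rt.cd_like(rt.PlantModel()), 200 + i)
        control.append(gc)
        treated.append(gt_)
    d_c = [compute_lateral_density(g.truth_topology()) for g in control]
    d_t = [compute_lateral_density(g.truth_topology()) for g in treated]
    l_c = [compute_lauz(g.truth_topology()) for g in control]
    l_t = [compute_lauz(g.truth_topology()) for g in treated]
    assert sps.ttest_ind(d_c, d_t, equal_var=False).pvalue < 0.05
    assert np.mean(d_t) < np.mean(d_c)
    assert sps.ttest_ind(l_c, l_t, equal_var=False).pvalue < 0.05
    assert np.mean(l_t) > np.mean(l_c)
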