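"""Candidate enumeration, qualification, expansion and ranked prediction."""

import math

import numpy as np
import pytest

from somcyp.chemio import Bond, InputError, LigandPose, Molecule
from somcyp.cndo import rank_hydrogen_classes
from somcyp.chemio import hydrogen_equivalence_classes
from somcyp.pose_features import (
    detect_hydrogen_bonds,
    detect_lipophilic_contacts,
    site_heme_distance,
)
from somcyp.predictor import (
    ALIPHATIC_HYDROXYLATION,
    N_DEALKYLATION,
    PredictorConfig,
    QualifiedSite,
    enumerate_candidate_sites,
    expand_adjacent_sites,
    predict_sites,
    qualify_sites,
)
from somcyp.fixtures import PosePlacement, make_pose_set
from somcyp.chemio import read_pose_set

from conftest import make_poses
from test_pose_features import bare_site


def benzene():
    ring = [
        1.395 * np.array([math.cos(math.radians(60 * k)),
                          math.sin(math.radians(60 * k)), 0.0])
        for k in range(6)
    ]
    coords = ring + [1.78 * np.array([math.cos(math.radians(60 * k)),
                                      math.sin(math.radians(60 * k)), 0.0])
                     for k in range(6)]
    bonds = [Bond(k, (k + 1) % 6, 1.5) for k in range(6)]
    bonds += [Bond(k, 6 + k, 1.0) for k in range(6)]
    return Molecule(["C"] * 6 + ["H"] * 6, np.array(coords), bonds, name="benzene")


def cf4():
    d = 1.32 / math.sqrt(3.0)
    coords = np.array([[0, 0, 0], [d, d, d], [d, -d, -d], [-d, d, -d], [-d, -d, d]])
    return Molecule(["C", "F", "F", "F", "F"], coords,
                    [Bond(0, k, 1.0) for k in (1, 2, 3, 4)], name="CF4")


class TestEnumerate:
    def test_propane_hydroxylation_sites(self, propane):
        sites = enumerate_candidate_sites(propane, (ALIPHATIC_HYDROXYLATION,))
        assert sorted(s.carbon_index for s in sites) == [0, 1, 2]

    def test_trimethylamine_dealkylation_sites(self, molecules):
        tma = molecules["trimethylamine"]
        sites = enumerate_candidate_sites(tma, (N_DEALKYLATION,))
        assert len(sites) == 3
        assert all(s.reaction_type == N_DEALKYLATION for s in sites)

    def test_aromatic_carbons_excluded(self):
        assert enumerate_candidate_sites(benzene(), (ALIPHATIC_HYDROXYLATION,)) == []

    def test_carbon_can_carry_both_types(self, molecules):
        tma = molecules["trimethylamine"]
        sites = enumerate_candidate_sites(tma)
        by_carbon = {}
        for s in sites:
            by_carbon.setdefault(s.carbon_index, set()).add(s.reaction_type)
        assert all(
            types == {ALIPHATIC_HYDROXYLATION, N_DEALKYLATION}
            for types in by_carbon.values()
        )


def brute_force_qualified(sites, poses, site_model, config):
    """Independent (site x pose) enumeration of the qualification rule."""
    kept = poses[: config.poses_kept]
    low, high = config.distance_window
    carbons = {s.carbon_index for s in sites}
    result = set()
    for site in sites:
        for pose in kept:
            d = site_heme_distance(pose, site.carbon_index, site_model)
            if not (low <= d <= high):
                continue
            if config.require_feature:
                has = bool(detect_hydrogen_bonds(pose, site_model,
                                                 config.hbond_criteria)) or bool(
                    detect_lipophilic_contacts(pose, site_model,
                                               config.lipophilic_criteria,
                                               heme_carbons=carbons)
                )
                if not has:
                    continue
            result.add((site.carbon_index, site.reaction_type))
            break
    return result


class TestQualify:
    def test_matches_brute_force_enumeration(self, cyclohexanone, toy_site, tmp_path):
        poses = make_poses(cyclohexanone, [4.0, 5.0, 6.0, 7.6, 9.0],
                           tmp_path, carbon_index=3)
        sites = enumerate_candidate_sites(cyclohexanone)
        for require in (True, False):
            config = PredictorConfig(require_feature=require)
            qualified = qualify_sites(sites, poses, toy_site, config)
            got = {(q.site.carbon_index, q.site.reaction_type) for q in qualified}
            assert got == brute_force_qualified(sites, poses, toy_site, config)

    def test_widening_window_never_shrinks_the_set(self, cyclohexanone, toy_site,
                                                   tmp_path):
        poses = make_poses(cyclohexanone, [2.6, 4.0, 7.4, 8.0, 11.0],
                           tmp_path, carbon_index=3)
        sites = enumerate_candidate_sites(cyclohexanone)
        narrow = qualify_sites(
            sites, poses, toy_site,
            PredictorConfig(distance_window=(3.0, 6.5), require_feature=False),
        )
        wide = qualify_sites(
            sites, poses, toy_site,
            PredictorConfig(distance_window=(2.5, 9.0), require_feature=False),
        )
        as_set = lambda qs: {(q.site.carbon_index, q.site.reaction_type) for q in qs}
        assert as_set(narrow) <= as_set(wide)

    def test_site_beyond_window_never_qualifies(self, cyclohexanone, tmp_path):
        poses = make_poses(cyclohexanone, [8.0], tmp_path, carbon_index=3)
        sites = enumerate_candidate_sites(cyclohexanone)
        qualified = qualify_sites(
            sites, poses, bare_site(), PredictorConfig(require_feature=False)
        )
        assert 3 not in {q.site.carbon_index for q in qualified}

    def test_site_at_five_with_ser119_hbond_qualifies(self, cyclohexanone, tmp_path):
        poses = make_poses(cyclohexanone, [5.0], tmp_path, carbon_index=3, seed=4)
        o_idx = cyclohexanone.symbols.index("O")
        og = poses[0].molecule.coords[o_idx] + np.array([0.0, 0.0, 2.9])
        site_model = bare_site(ser_og=og)
        qualified = qualify_sites(
            enumerate_candidate_sites(cyclohexanone), poses, site_model,
            PredictorConfig(require_feature=True),
        )
        assert 3 in {q.site.carbon_index for q in qualified}
        hit = [q for q in qualified if q.site.carbon_index == 3][0]
        assert hit.flags["hbond"]

    def test_require_feature_flag(self, methane, tmp_path):
        poses = make_poses(methane, [5.0], tmp_path, carbon_index=0)
        sites = enumerate_candidate_sites(methane)
        strict = qualify_sites(sites, poses, bare_site(),
                               PredictorConfig(require_feature=True))
        relaxed = qualify_sites(sites, poses, bare_site(),
                                PredictorConfig(require_feature=False))
        assert strict == []
        assert [q.site.carbon_index for q in relaxed] == [0]

    def test_empty_pose_set_rejected(self, methane, toy_site):
        with pytest.raises(InputError):
            qualify_sites(enumerate_candidate_sites(methane), [], toy_site)


class TestAdjacency:
    def _qualified_for(self, m, carbon, fraction=0.5):
        sites = enumerate_candidate_sites(m)
        site = next(s for s in sites if s.carbon_index == carbon
                    and s.reaction_type == ALIPHATIC_HYDROXYLATION)
        return [QualifiedSite(site, fraction,
                              dict(distance=True, hbond=True, lipophilic=False,
                                   adjacency_derived=False))], sites

    def test_ring_neighbors_added(self, cyclohexanone):
        qualified, all_sites = self._qualified_for(cyclohexanone, 3)
        expanded = expand_adjacent_sites(qualified, all_sites, cyclohexanone)
        carbons = {q.site.carbon_index for q in expanded}
        assert carbons == {2, 3, 4}
        derived = [q for q in expanded if q.flags["adjacency_derived"]]
        assert {q.site.carbon_index for q in derived} == {2, 4}
        assert all(q.pose_fraction == 0.5 for q in derived)

    def test_methane_adds_nothing(self, methane):
        qualified, all_sites = self._qualified_for(methane, 0)
        expanded = expand_adjacent_sites(qualified, all_sites, methane)
        assert len(expanded) == 1

    def test_idempotent(self, cyclohexanone):
        qualified, all_sites = self._qualified_for(cyclohexanone, 3)
        once = expand_adjacent_sites(qualified, all_sites, cyclohexanone)
        twice = expand_adjacent_sites(once, all_sites, cyclohexanone)
        key = lambda qs: sorted(
            (q.site.carbon_index, q.site.reaction_type,
             q.flags["adjacency_derived"]) for q in qs
        )
        assert key(once) == key(twice)


class TestPredict:
    def test_energy_order_matches_direct_calls(self, cyclohexanone, toy_site,
                                               tmp_path):
        poses = make_poses(cyclohexanone, [4.0, 5.0, 5.5, 6.0], tmp_path,
                           carbon_index=3)
        pred = predict_sites(cyclohexanone, poses, toy_site,
                             config=PredictorConfig(require_feature=False,
                                                    adjacency_expansion=False))
        ranked = rank_hydrogen_classes(
            cyclohexanone, hydrogen_equivalence_classes(cyclohexanone)
        )
        energy_by_carbon = {r.hydrogen_class.carbon_index: r.delta_h for r in ranked}
        deltas = [e.delta_h for e in pred.entries]
        assert deltas == sorted(deltas)
        for e in pred.entries:
            assert e.delta_h == pytest.approx(
                energy_by_carbon[e.site.carbon_index], abs=1e-12
            )

    def test_single_qualifying_site(self, methane, tmp_path):
        poses = make_poses(methane, [5.0], tmp_path, carbon_index=0)
        pred = predict_sites(methane, poses, bare_site(),
                             config=PredictorConfig(require_feature=False))
        assert len(pred.entries) == 1
        assert pred.entries[0].rank == 1
        assert pred.entries[0].in_top_k

    def test_no_candidates_gives_empty_prediction_with_warning(self, tmp_path):
        m = cf4()
        poses = make_poses(m, [5.0], tmp_path, carbon_index=0)
        pred = predict_sites(m, poses, bare_site())
        assert pred.entries == []
        assert pred.warnings

    def test_nothing_qualifies_gives_empty_prediction_with_warning(
            self, methane, tmp_path):
        poses = make_poses(methane, [12.0], tmp_path, carbon_index=0)
        pred = predict_sites(methane, poses, bare_site(),
                             config=PredictorConfig(require_feature=False))
        assert pred.entries == []
        assert any("qualified" in w for w in pred.warnings)

    def test_deterministic_output(self, cyclohexanone, toy_site, tmp_path):
        poses = make_poses(cyclohexanone, [4.0, 6.0, 9.0], tmp_path, carbon_index=3)
        config = PredictorConfig(require_feature=False)
        a = predict_sites(cyclohexanone, poses, toy_site, config=config).to_json()
        b = predict_sites(cyclohexanone, poses, toy_site, config=config).to_json()
        assert a == b

    def test_external_energy_table_drives_ranking(self, cyclohexanone, toy_site,
                                                  tmp_path):
        poses = make_poses(cyclohexanone, [4.0, 5.0, 6.0], tmp_path, carbon_index=3)
        table = {1: 0.5, 2: 0.1, 3: 0.3, 4: 0.2, 5: 0.4}
        pred = predict_sites(
            cyclohexanone, poses, toy_site,
            config=PredictorConfig(require_feature=False,
                                   adjacency_expansion=False),
            energy_table=table,
        )
        carbons = [e.site.carbon_index for e in pred.entries]
        assert carbons == sorted(carbons, key=lambda c: table[c])

    def test_top_k_traceability(self, cyclohexanone, toy_site, tmp_path):
        """Every top-k site traces to a pose in the window or to expansion."""
        poses = make_poses(cyclohexanone, [4.0, 5.5, 8.5], tmp_path, carbon_index=3)
        pred = predict_sites(cyclohexanone, poses, toy_site)
        for e in pred.top():
            assert e.flags["distance"] or e.flags["adjacency_derived"]
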