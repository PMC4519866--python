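"""Shared fixtures: reference molecules, toy active sites, file snippets."""

from __future__ import annotations

import numpy as np
import pytest

from somcyp.active_site import extract_active_site
from somcyp.fixtures import (
    FixtureSpec,
    PosePlacement,
    make_pose_set,
    make_toy_active_site,
    reference_molecules,
)


@pytest.fixture(scope="session")
def molecules():
    return reference_molecules()


@pytest.fixture()
def methane(molecules):
    return molecules["methane"]


@pytest.fixture()
def propane(molecules):
    return molecules["propane"]


@pytest.fixture()
def cyclohexanone(molecules):
    return molecules["cyclohexanone"]


@pytest.fixture()
def toy_site(tmp_path):
    """Standard toy active site: Fe at the origin, Ser119, 3 waters, Phe108."""
    spec = FixtureSpec(
        fe_position=np.zeros(3),
        residues={"Ser119": np.array([4.0, 0.0, 3.0])},
        waters={
            619: np.array([0.0, 4.0, 3.5]),
            623: np.array([0.0, -4.0, 3.5]),
            637: np.array([3.0, 3.0, 3.0]),
        },
        phe_residues={"Phe108": np.array([0.0, 0.0, 9.0])},
    )
    path = make_toy_active_site(spec, tmp_path / "site.pdb")
    return extract_active_site(path)


def make_poses(substrate, distances, tmp_path, carbon_index=0, seed=1,
               direction=(0.0, 0.0, 1.0), name="poses.sdf"):
    """Pose set placing `carbon_index` at the given Fe distances (Fe at origin)."""
    from somcyp.chemio import read_pose_set
    from somcyp.fixtures import rotation_about_axis

    rng = np.random.default_rng(seed)
    placements = []
    for d in distances:
        axis = rng.normal(size=3)
        placements.append(
            PosePlacement(
                rotation=rotation_about_axis(axis, float(rng.uniform(0, 360))),
                carbon_index=carbon_index,
                fe_distance=float(d),
                direction=np.asarray(direction, float),
            )
        )
    path = make_pose_set(substrate, placements, tmp_path / name)
    return read_pose_set(path, substrate)
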