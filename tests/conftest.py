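import numpy as np
import pytest

from star3d.geometry import random_rigid_transform
from star3d.structure_io import Residue, ResidueChain
from star3d.synthetic_fixtures import TopologySpec, build_structure, make_pair

#: the standard two-stem benchmark topology used across the suite
TWO_STEM_BRACKET = "..((((....))))..(((......))).."


def chain_from_points(points, bases=None, label="points") -> ResidueChain:
    """Chain carrying only representative points (no atoms)."""
    points = np.asarray(points, float)
    bases = bases or "A" * len(points)
    residues = [Residue(index=i + 1, base=bases[i], author_id=f"A/{i + 1}",
                        atoms={}, rep_point=points[i].copy())
                for i in range(len(points))]
    return ResidueChain(label=label, residues=residues)


@pytest.fixture(scope="session")
def two_stem_chain():
    return build_structure(TopologySpec(bracket=TWO_STEM_BRACKET))


@pytest.fixture(scope="session")
def two_stem_pair():
    """Rigid copy of the two-stem fixture under a fixed random motion."""
    spec = TopologySpec(bracket=TWO_STEM_BRACKET)
    rng = np.random.default_rng(2024)
    return make_pair(spec, spec, random_rigid_transform(rng))


@pytest.fixture(scope="session")
def hairpin_chain():
    return build_structure(TopologySpec(bracket="((((....))))"))
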