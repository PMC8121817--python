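import numpy as np
import pytest

from tmfret.forster_core import FCGModel
from tmfret.synthetic_data import (
    DEFAULT_TRUTH,
    simulate_c4_tetramer,
    solve_two_ring_geometry,
)

#: Printed reference distances (Å) between the S4 donor site and the two
#: C-linker acceptor sites in the fourfold-symmetric channel structure,
#: keyed by relation class.
REFERENCE_DISTANCES = {
    "A-helix": {"same": 41.0, "adjacent": 22.1, "diagonal": 28.1},
    "B-helix": {"same": 44.8, "adjacent": 18.8, "diagonal": 35.4},
}


@pytest.fixture(scope="session")
def default_truth():
    return DEFAULT_TRUTH


@pytest.fixture(scope="session")
def fcg_model_5A():
    return FCGModel(r0=13.0, sigma=5.0)


@pytest.fixture()
def square_ring_pdb(tmp_path):
    """C4 fixture with probe CB atoms at (±10, ±10, 0): side 20 Å exactly.

    Phase π/4 puts every coordinate on an exact multiple of 0.001 Å, so the
    PDB round trip preserves the geometry to machine precision.
    """
    radius = float(np.sqrt(200.0))
    text = simulate_c4_tetramer({6: (radius, 0.0, np.pi / 4)})
    path = tmp_path / "square_ring.pdb"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def standin_structure_pdb(tmp_path_factory):
    """Synthetic stand-in tetramer consistent with the printed distances.

    Donor ring (residue 355 stand-in, here numbered 10) at radius 23 Å;
    two acceptor rings solved from the printed same/adjacent/diagonal
    distances of the A'-helix site (residue 20) and B'-helix site
    (residue 30).  Synthetic: constructed geometry, not a deposited model.
    """
    donor_radius = 23.0
    sites = {10: (donor_radius, 0.0, 0.0)}
    for resnum, key in ((20, "A-helix"), (30, "B-helix")):
        ref = REFERENCE_DISTANCES[key]
        geo = solve_two_ring_geometry(
            ref["same"], ref["adjacent"], ref["diagonal"], donor_radius
        )
        sites[resnum] = (geo["acceptor_radius"], geo["height"], geo["phase"])
    path = tmp_path_factory.mktemp("structures") / "synthetic_standin_tetramer.pdb"
    path.write_text(simulate_c4_tetramer(sites))
    return path
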