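import numpy as np
import pytest

from pmhcnet import fixtures as fx


@pytest.fixture(scope="session")
def toy_spec():
    return fx.FixtureSpec(seed=3)


@pytest.fixture(scope="session")
def toy_complex(toy_spec):
    """One synthetic complex with its generating torsions and frames."""
    return fx.make_toy_complex(toy_spec)


@pytest.fixture(scope="session")
def toy_bundles():
    """Small labeled dataset over one shared scaffold."""
    return fx.make_toy_dataset(4, fx.FixtureSpec(seed=5))


@pytest.fixture(scope="session")
def random_nine_mer():
    """A deterministic random 9-mer built directly from torsions (no MHC)."""
    from pmhcnet import geometry as geo
    from pmhcnet import residues as rc

    rng = np.random.default_rng(17)
    seq = "LMKTEQFVW"
    r = len(seq)
    phi = rng.uniform(-150, -60, r)
    psi = rng.uniform(100, 160, r)
    omega = np.full(r, 180.0)
    frames = geo.backbone_frames_from_torsions(seq, phi, psi, omega)
    aatype = rc.seq_to_indices(seq)
    chi_def = rc.stacked_layouts()["chi_defined"][aatype]
    angles = np.zeros((r, 7))
    defined = np.zeros((r, 7), dtype=bool)
    angles[:, 0], angles[:, 1], angles[:, 2] = phi, psi, omega
    defined[:, :3] = True
    defined[0, 0] = defined[0, 2] = False
    angles[:, 3:] = np.where(chi_def, rng.uniform(-180, 180, (r, 4)), 0.0)
    defined[:, 3:] = chi_def
    tors = geo.TorsionSet(angles, defined)
    coords, mask = geo.place_atoms(frames, tors, seq)
    return seq, frames, tors, coords, mask
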