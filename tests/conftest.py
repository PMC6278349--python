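import numpy as np
import pytest

from hydrodecomp import geometry, synthetic


@pytest.fixture(scope="session")
def benzene():
    return synthetic.make_fixture_geometry("benzene")


@pytest.fixture(scope="session")
def benzene_with_radii(benzene):
    return geometry.assign_radii(benzene)


@pytest.fixture()
def benzene_xyz(tmp_path, benzene):
    """Benzene written as a count/comment/records XYZ file."""
    lines = [str(len(benzene)), "idealized benzene, distances in angstrom"]
    for atom in benzene.atoms:
        x, y, z = atom.position
        lines.append(f"{atom.element} {x:.6f} {y:.6f} {z:.6f}")
    path = tmp_path / "benzene.xyz"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def benzene_pdb(tmp_path, benzene):
    """The same geometry as a minimal PDB with ATOM records."""
    lines = []
    for i, atom in enumerate(benzene.atoms, start=1):
        x, y, z = atom.position
        lines.append(
            f"ATOM  {i:5d} {atom.element:<4s}BNZ A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {atom.element:>2s}"
        )
    lines.append("END")
    path = tmp_path / "benzene.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def mc_asa_oracle(mol, probe_radius=1.4, n_samples_per_atom=100_000, seed=1234):
    """Monte-Carlo surface-area oracle, independent of the lattice method.

    For each atom, sample uniformly random directions on its probe-expanded
    sphere and accept the fraction of points not buried inside any other
    expanded sphere; contribution = fraction x 4 pi r^2.
    """
    rng = np.random.default_rng(seed)
    coords = mol.coordinates
    radii = mol.radii + probe_radius
    total = 0.0
    for i in range(len(mol)):
        dirs = rng.normal(size=(n_samples_per_atom, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = coords[i] + radii[i] * dirs
        exposed = np.ones(n_samples_per_atom, dtype=bool)
        for j in range(len(mol)):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 >= radii[j] ** 2
        total += exposed.mean() * 4.0 * np.pi * radii[i] ** 2
    return total
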