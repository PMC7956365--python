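import numpy as np
import pytest

from probedock import (PharmacophorePoint, Sphere, SphereSet, default_registry,
                       generate_fixture, parse_ftmap_result)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def fixture_pdb(registry):
    """Synthetic probe-map result: 2 crossclusters with 3 and 2 probes."""
    pdb_text, ligand_text = generate_fixture(
        seed=42, n_crossclusters=2, probes_per_cluster=[3, 2],
        registry=registry)
    return pdb_text, ligand_text


@pytest.fixture()
def parsed(fixture_pdb, registry):
    return parse_ftmap_result(fixture_pdb[0], registry)


def random_sphere_set(rng, n=50, labels=("acceptor", "donor", "hydrophobic")):
    """Randomized sphere set with values quantized to the printed precision."""
    colors = [(lab, i + 1) for i, lab in enumerate(sorted(labels))]
    spheres = [
        Sphere(index=i + 1,
               center=np.round(rng.uniform(-50, 50, size=3), 5),
               radius=round(float(rng.uniform(0.1, 5.0)), 3),
               surface_atom=int(rng.integers(0, 9999)),
               critical=int(rng.integers(0, 10)),
               color=int(rng.integers(1, len(colors) + 1)))
        for i in range(n)
    ]
    return SphereSet(colors=colors, clusters=[(1, spheres)], provenance="random set")


def random_points(rng, n, labels=("donor", "acceptor", "hydrophobic", "aromatic")):
    return [
        PharmacophorePoint(label=labels[int(rng.integers(len(labels)))],
                           center=rng.uniform(-20, 20, size=3),
                           source_cluster=int(rng.integers(5)),
                           source_probe=int(rng.integers(5)),
                           source_atoms=tuple(int(v) for v in
                                              rng.integers(0, 9, size=2)))
        for _ in range(n)
    ]
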