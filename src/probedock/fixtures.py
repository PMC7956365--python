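"""Synthetic probe-mapping fixtures: a pseudo-protein plus crossclusters.

Real probe-mapping output requires a web service run; for testing and
demonstration this module fabricates a structurally plausible stand-in: a
rigid glycine backbone arc (the "receptor") and a configurable number of
crossclusters, each a group of probe molecules from the 16-probe library
placed by seeded random rigid transforms near a declared pocket center.

The fixtures emulate the *file shape* of probe-mapping results — delimited
probe blocks around defined hot spots — not the physics: probe placements
are random within a pocket, not energy-minimized, and the pseudo-protein has
no actual cavities.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .ftmap import Atom, ProbeMolecule, format_pdb_atom
from .mol2 import write_mol2
from .probes import ProbeRegistry, default_registry

__all__ = ["generate_fixture", "make_probe", "random_rigid_transform"]


def random_rigid_transform(rng: np.random.Generator, center, max_offset: float = 2.0):
    """A seeded random rotation plus a translation within ``max_offset`` of center."""
    rot = Rotation.random(rng=rng).as_matrix()
    # uniform direction, offset radius uniform in [0, max_offset)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    offset = direction * max_offset * rng.uniform() ** (1.0 / 3.0)
    return rot, np.asarray(center, dtype=float) + offset


def make_probe(probe_type: str, rotation, translation,
               registry: ProbeRegistry | None = None,
               serial_start: int = 1, residue_seq: int = 1,
               chain: str = "X") -> ProbeMolecule:
    """Instantiate one probe at a rigid placement of its template geometry."""
    registry = registry if registry is not None else default_registry()
    template = registry.get(probe_type)
    if template is None:
        raise ValueError(f"probe type {probe_type!r} is not registered")
    coords = template.coords @ np.asarray(rotation).T + np.asarray(translation)
    atoms = [
        Atom(serial=serial_start + i, name=template.atom_names[i],
             element=template.elements[i], residue_name=template.code,
             residue_seq=residue_seq, chain=chain, coords=coords[i], is_het=True)
        for i in range(template.n_heavy)
    ]
    mol = ProbeMolecule(probe_type=template.code, atoms=atoms,
                        bonds=list(template.bonds))
    mol.validate()
    return mol


def _backbone_arc(n_residues: int, rng: np.random.Generator) -> list[Atom]:
    """Glycine backbone (N, CA, C, O per residue) along a helical arc."""
    atoms = []
    serial = 1
    for r in range(n_residues):
        t = r * 0.6
        base = np.array([8.0 * np.cos(t), 8.0 * np.sin(t), 1.5 * t])
        offsets = {"N": np.array([0.0, 0.0, 0.0]),
                   "CA": np.array([1.2, 0.6, 0.3]),
                   "C": np.array([2.4, 0.0, 0.6]),
                   "O": np.array([3.0, 1.0, 0.9])}
        for name in ("N", "CA", "C", "O"):
            element = name[0]
            atoms.append(Atom(serial=serial, name=name, element=element,
                              residue_name="GLY", residue_seq=r + 1, chain="A",
                              coords=base + offsets[name], is_het=False))
            serial += 1
    return atoms


def generate_fixture(
    seed: int,
    n_crossclusters: int = 2,
    probes_per_cluster: list[int] | None = None,
    pocket_centers: list | None = None,
    probe_types: list[str] | None = None,
    registry: ProbeRegistry | None = None,
    n_residues: int = 10,
) -> tuple[str, str]:
    """Fabricate (probe-map PDB text, toy ligand MOL2 text).

    Each crosscluster k gets ``probes_per_cluster[k]`` probes (default 3),
    cycling through ``probe_types`` (default: the whole registered library),
    placed by seeded random rigid transforms within 2 Å of
    ``pocket_centers[k]``.  Deterministic per seed: the same arguments give
    byte-identical text.
    """
    registry = registry if registry is not None else default_registry()
    if probes_per_cluster is None:
        probes_per_cluster = [3] * n_crossclusters
    if len(probes_per_cluster) != n_crossclusters:
        raise ValueError("probes_per_cluster length must equal n_crossclusters")
    if pocket_centers is None:
        pocket_centers = [np.array([14.0 + 8.0 * k, 2.0, 3.0 * k])
                          for k in range(n_crossclusters)]
    if len(pocket_centers) != n_crossclusters:
        raise ValueError("pocket_centers length must equal n_crossclusters")
    if probe_types is None:
        probe_types = list(registry.codes)
    for code in probe_types:
        if code not in registry:
            raise ValueError(f"probe type {code!r} is not registered")

    rng = np.random.default_rng(seed)
    lines = ["HEADER    synthetic probe-mapping fixture"]
    for atom in _backbone_arc(n_residues, rng):
        lines.append(format_pdb_atom("ATOM", atom.serial, atom.name,
                                     atom.residue_name, atom.chain,
                                     atom.residue_seq, atom.coords,
                                     element=atom.element))
    lines.append("TER")

    serial = 4 * n_residues + 1
    residue_seq = 1
    type_cycle = 0
    for k in range(n_crossclusters):
        population = probes_per_cluster[k]
        lines.append(f"HEADER crosscluster.{k}.{population}")
        for _ in range(population):
            code = probe_types[type_cycle % len(probe_types)]
            type_cycle += 1
            rot, trans = random_rigid_transform(rng, pocket_centers[k])
            probe = make_probe(code, rot, trans, registry,
                               serial_start=serial, residue_seq=residue_seq)
            for atom in probe.atoms:
                lines.append(format_pdb_atom("HETATM", atom.serial, atom.name,
                                             atom.residue_name, atom.chain,
                                             atom.residue_seq, atom.coords,
                                             element=atom.element))
            serial += len(probe.atoms)
            residue_seq += 1
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    # toy candidate ligand: a phenol body placed at the first pocket
    rot, trans = random_rigid_transform(rng, pocket_centers[0], max_offset=1.0)
    ligand = make_probe("PHN", rot, trans, registry, chain="L")
    ligand_text = write_mol2([ligand], names=["toy_ligand"])
    return pdb_text, ligand_text
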