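"""Pharmacophore feature perception for probe molecules.

Each probe type carries a hand-curated feature template (see
:mod:`probedock.probes`): hydrogen-bond donors and acceptors sit on single
heavy atoms, aromatic and hydrophobic features on atom-group centroids.
Templates make perception deterministic and total over the registered probe
library; a rule-based fallback handles nonstandard probes:

* donor — N or O bearing at least one hydrogen (explicit, or implicit per
  template counts),
* acceptor — any O; any N except one bonded to three heavy atoms and no H,
* aromatic — six-membered ring whose bonds are all aromatic order,
* hydrophobic — centroid of each maximal connected carbon set with no N/O
  neighbor.

Two features may coincide at one center (hydroxyl O is donor + acceptor);
they are kept as distinct points, never merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ParseError, PerceptionError
from .ftmap import ProbeMolecule
from .probes import ProbeRegistry, default_registry

__all__ = [
    "FEATURE_LABELS", "PharmacophorePoint", "perceive_features",
    "write_pharmacophore_file", "read_pharmacophore_file",
]

#: Closed label vocabulary.  ``null`` is compatible with everything in
#: chemical matching and is used for unlabeled spheres.
FEATURE_LABELS = ("donor", "acceptor", "hydrophobic", "aromatic",
                  "positive", "negative", "null")


@dataclass
class PharmacophorePoint:
    """A labeled 3-D interaction feature with provenance.

    ``source_atoms`` index into the owning probe's atom list; for single-atom
    features the center equals that atom's position, otherwise the centroid.
    """

    label: str
    center: np.ndarray
    source_cluster: int = 0
    source_probe: int = 0
    source_atoms: tuple[int, ...] = ()

    def __post_init__(self):
        if self.label not in FEATURE_LABELS:
            raise ValueError(f"unknown feature label {self.label!r}")
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,) or not np.all(np.isfinite(self.center)):
            raise ValueError("feature center must be a finite 3-vector")
        if not self.source_atoms:
            raise ValueError("feature must record at least one source atom")


def _template_features(probe, template, cluster_id, probe_index):
    heavy = probe.heavy_indices
    coords = probe.coords
    points = []
    for label, idx in template.features:
        atom_ids = tuple(heavy[i] for i in idx)
        center = coords[list(atom_ids)].mean(axis=0)
        points.append(PharmacophorePoint(label=label, center=center,
                                         source_cluster=cluster_id,
                                         source_probe=probe_index,
                                         source_atoms=atom_ids))
    return points


def _fallback_features(probe, cluster_id, probe_index):
    coords = probe.coords
    elements = probe.elements
    n = len(elements)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    orders = {}
    for i, j, o in probe.bonds:
        g.add_edge(i, j)
        orders[frozenset((i, j))] = o
    h_count = [sum(1 for nb in g.neighbors(i) if elements[nb] == "H") for i in range(n)]
    heavy_deg = [sum(1 for nb in g.neighbors(i) if elements[nb] != "H") for i in range(n)]
    points = []
    for i in range(n):
        el = elements[i]
        if el in ("N", "O") and h_count[i] >= 1:
            points.append(PharmacophorePoint("donor", coords[i], cluster_id,
                                             probe_index, (i,)))
        if el == "O" or (el == "N" and not (heavy_deg[i] == 3 and h_count[i] == 0)):
            points.append(PharmacophorePoint("acceptor", coords[i], cluster_id,
                                             probe_index, (i,)))
    for ring in nx.cycle_basis(g):
        if len(ring) == 6 and all(
            orders.get(frozenset((ring[k], ring[(k + 1) % 6]))) == "ar" for k in range(6)
        ):
            points.append(PharmacophorePoint("aromatic", coords[ring].mean(axis=0),
                                             cluster_id, probe_index, tuple(sorted(ring))))
    plain_c = [i for i in range(n) if elements[i] == "C"
               and not any(elements[nb] in ("N", "O") for nb in g.neighbors(i))]
    sub = g.subgraph(plain_c)
    for comp in nx.connected_components(sub):
        idx = tuple(sorted(comp))
        points.append(PharmacophorePoint("hydrophobic", coords[list(idx)].mean(axis=0),
                                         cluster_id, probe_index, idx))
    if not points:
        raise PerceptionError(
            f"no features perceivable for probe {probe.probe_type!r} "
            f"(no donor/acceptor heteroatom, aromatic ring, or hydrophobic carbon set)"
        )
    return points


def perceive_features(
    probe: ProbeMolecule,
    registry: ProbeRegistry | None = None,
    cluster_id: int = 0,
    probe_index: int = 0,
) -> list[PharmacophorePoint]:
    """Assign pharmacophore points to one probe molecule.

    Registered probe types use their curated template evaluated at the
    probe's actual coordinates; unregistered ones fall back to the rules in
    the module docstring.
    """
    registry = registry if registry is not None else default_registry()
    template = registry.get(probe.probe_type)
    if template is not None:
        return _template_features(probe, template, cluster_id, probe_index)
    return _fallback_features(probe, cluster_id, probe_index)


def write_pharmacophore_file(points: list[PharmacophorePoint]) -> str:
    """Serialize points to the intermediate pharmacophore text dialect.

    One point per line: ``cluster_id probe_index label x y z n atom_idx...``
    with coordinates at 4 decimals; comment lines start with ``#``.
    """
    lines = ["# pharmacophore points",
             "# cluster probe label x y z n_source_atoms atom_indices..."]
    for p in points:
        idx = " ".join(str(i) for i in p.source_atoms)
        lines.append(f"{p.source_cluster} {p.source_probe} {p.label} "
                     f"{p.center[0]:.4f} {p.center[1]:.4f} {p.center[2]:.4f} "
                     f"{len(p.source_atoms)} {idx}")
    return "\n".join(lines) + "\n"


def read_pharmacophore_file(text: str) -> list[PharmacophorePoint]:
    """Parse the pharmacophore text dialect; inverse of the writer."""
    points = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 8:
            raise ParseError(f"expected at least 8 fields, got {len(parts)}", line=lineno)
        if parts[2] not in FEATURE_LABELS:
            raise ParseError(f"unknown feature label {parts[2]!r}", line=lineno)
        try:
            cluster, probe = int(parts[0]), int(parts[1])
            center = np.array([float(v) for v in parts[3:6]])
            n_src = int(parts[6])
            atoms = tuple(int(v) for v in parts[7:7 + n_src])
        except ValueError as exc:
            raise ParseError(str(exc), line=lineno) from exc
        if len(atoms) != n_src:
            raise ParseError(f"declared {n_src} source atoms, found {len(atoms)}",
                             line=lineno)
        points.append(PharmacophorePoint(label=parts[2], center=center,
                                         source_cluster=cluster, source_probe=probe,
                                         source_atoms=atoms))
    return points
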