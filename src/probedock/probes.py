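"""Registry of the 16 small organic probes used by solvent-mapping services.

Probe-mapping servers flood a protein surface with a fixed library of small
organic molecules (ethanol, benzene, urea, ...) and cluster the docked copies
into consensus "crossclusters" that mark candidate binding hot spots.  This
module ships one template per probe type:

* heavy-atom topology (names, elements, bonds with orders),
* idealized reference coordinates (used by the synthetic fixture generator),
* implicit-hydrogen counts per heavy atom,
* a hand-curated pharmacophore feature template (label + source atom indices).

Bonds are assigned from the template rather than guessed from distances: a
probe residue parsed out of a PDB file carries no CONECT records, and the
template, matched by atom order, makes reconstruction deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ProbeTemplate", "ProbeRegistry", "default_registry", "UNKNOWN_PROBE"]

#: Sentinel returned by classification for residue codes not in the registry.
UNKNOWN_PROBE = "unknown"


@dataclass(frozen=True)
class ProbeTemplate:
    """Heavy-atom template for one probe type.

    ``features`` maps a pharmacophore label to the heavy-atom indices that
    generate it; single-atom features (donor/acceptor) sit on that atom,
    multi-atom features (aromatic/hydrophobic) sit on the centroid.
    """

    code: str                 # residue code used in probe-map PDB output
    name: str                 # human-readable probe name
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    implicit_h: tuple[int, ...]
    coords: np.ndarray        # (n_heavy, 3) idealized geometry, Å
    bonds: tuple[tuple[int, int, str], ...]   # (i, j, order); order in {1,2,3,ar}
    features: tuple[tuple[str, tuple[int, ...]], ...] = field(default=())

    @property
    def n_heavy(self) -> int:
        return len(self.elements)

    def __post_init__(self):
        assert self.coords.shape == (len(self.elements), 3)
        assert len(self.atom_names) == len(self.elements) == len(self.implicit_h)
        for i, j, _ in self.bonds:
            assert 0 <= i < self.n_heavy and 0 <= j < self.n_heavy


class ProbeRegistry:
    """Lookup table from residue codes to probe templates.

    Lookup normalizes the code (strip + uppercase) so padded or lowercase
    residue fields in fixed-column PDB records resolve to the same template.
    """

    def __init__(self, templates: dict[str, ProbeTemplate] | None = None):
        self._templates: dict[str, ProbeTemplate] = {}
        for t in (templates or {}).values():
            self.register(t)

    def register(self, template: ProbeTemplate) -> None:
        self._templates[template.code.strip().upper()] = template

    def classify(self, residue_name: str) -> str:
        """Return the probe code for ``residue_name`` or :data:`UNKNOWN_PROBE`."""
        t = self._templates.get(residue_name.strip().upper())
        return t.code if t is not None else UNKNOWN_PROBE

    def get(self, residue_name: str) -> ProbeTemplate | None:
        return self._templates.get(residue_name.strip().upper())

    def __contains__(self, residue_name: str) -> bool:
        return residue_name.strip().upper() in self._templates

    def __iter__(self):
        return iter(self._templates.values())

    def __len__(self) -> int:
        return len(self._templates)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self._templates)


def _hexagon(radius: float) -> np.ndarray:
    """Six points of a planar hexagon in the xy plane."""
    ang = np.arange(6) * (math.pi / 3.0)
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)])


def _template(code, name, spec, bonds, features):
    """Build a ProbeTemplate from (name, element, nH, x, y, z) rows."""
    atom_names = tuple(r[0] for r in spec)
    elements = tuple(r[1] for r in spec)
    implicit_h = tuple(r[2] for r in spec)
    coords = np.array([r[3:6] for r in spec], dtype=float)
    return ProbeTemplate(
        code=code, name=name, atom_names=atom_names, elements=elements,
        implicit_h=implicit_h, coords=coords,
        bonds=tuple((i, j, str(o)) for i, j, o in bonds),
        features=tuple((lab, tuple(idx)) for lab, idx in features),
    )


def _ring_template(code, name, extra, extra_bonds, extra_features, ring_h=1):
    """Benzene-like template: aromatic 6-ring plus optional substituents."""
    hexa = _hexagon(1.39)
    spec = [(f"C{i+1}", "C", ring_h if i else (ring_h if not extra else 0),
             *hexa[i]) for i in range(6)]
    bonds = [(i, (i + 1) % 6, "ar") for i in range(6)]
    features = [("aromatic", tuple(range(6)))]
    spec += extra
    bonds += extra_bonds
    features += extra_features
    return _template(code, name, spec, bonds, features)


def default_registry() -> ProbeRegistry:
    """The standard 16-probe library used by solvent-mapping servers."""
    reg = ProbeRegistry()

    reg.register(_template(
        "ETH", "ethane",
        [("C1", "C", 3, 0.0, 0.0, 0.0), ("C2", "C", 3, 1.53, 0.0, 0.0)],
        [(0, 1, 1)],
        [("hydrophobic", (0, 1))]))

    reg.register(_template(
        "EOH", "ethanol",
        [("C1", "C", 3, 0.0, 0.0, 0.0), ("C2", "C", 2, 1.53, 0.0, 0.0),
         ("O1", "O", 1, 2.01, 1.35, 0.0)],
        [(0, 1, 1), (1, 2, 1)],
        [("donor", (2,)), ("acceptor", (2,)), ("hydrophobic", (0, 1))]))

    reg.register(_template(
        "IPA", "isopropanol",
        [("C1", "C", 3, -1.44, -0.51, 0.0), ("C2", "C", 1, 0.0, 0.0, 0.0),
         ("C3", "C", 3, 1.44, -0.51, 0.0), ("O1", "O", 1, 0.0, 1.43, 0.0)],
        [(0, 1, 1), (1, 2, 1), (1, 3, 1)],
        [("donor", (3,)), ("acceptor", (3,)), ("hydrophobic", (0, 1, 2))]))

    reg.register(_template(
        "IBU", "isobutanol",
        [("C1", "C", 2, 0.0, 0.0, 0.0), ("C2", "C", 1, 1.53, 0.0, 0.0),
         ("C3", "C", 3, 2.10, 1.40, 0.0), ("C4", "C", 3, 2.10, -0.80, 1.20),
         ("O1", "O", 1, -0.60, 1.30, 0.0)],
        [(0, 1, 1), (1, 2, 1), (1, 3, 1), (0, 4, 1)],
        [("donor", (4,)), ("acceptor", (4,)), ("hydrophobic", (1, 2, 3))]))

    reg.register(_template(
        "ACO", "acetone",
        [("C1", "C", 3, -1.29, -0.60, 0.0), ("C2", "C", 0, 0.0, 0.0, 0.0),
         ("C3", "C", 3, 1.29, -0.60, 0.0), ("O1", "O", 0, 0.0, 1.22, 0.0)],
        [(0, 1, 1), (1, 2, 1), (1, 3, 2)],
        [("acceptor", (3,)), ("hydrophobic", (0, 2))]))

    reg.register(_template(
        "ACD", "acetaldehyde",
        [("C1", "C", 3, -1.50, 0.0, 0.0), ("C2", "C", 1, 0.0, 0.0, 0.0),
         ("O1", "O", 0, 0.60, 1.06, 0.0)],
        [(0, 1, 1), (1, 2, 2)],
        [("acceptor", (2,)), ("hydrophobic", (0,))]))

    reg.register(_template(
        "DME", "dimethyl ether",
        [("C1", "C", 3, -1.17, -0.63, 0.0), ("O1", "O", 0, 0.0, 0.20, 0.0),
         ("C2", "C", 3, 1.17, -0.63, 0.0)],
        [(0, 1, 1), (1, 2, 1)],
        [("acceptor", (1,)), ("hydrophobic", (0, 2))]))

    hexa = _hexagon(1.53)
    reg.register(_template(
        "CHX", "cyclohexane",
        [(f"C{i+1}", "C", 2, *hexa[i]) for i in range(6)],
        [(i, (i + 1) % 6, 1) for i in range(6)],
        [("hydrophobic", tuple(range(6)))]))

    reg.register(_template(
        "ACT", "acetonitrile",
        [("C1", "C", 3, 0.0, 0.0, 0.0), ("C2", "C", 0, 1.47, 0.0, 0.0),
         ("N1", "N", 0, 2.63, 0.0, 0.0)],
        [(0, 1, 1), (1, 2, 3)],
        [("acceptor", (2,)), ("hydrophobic", (0,))]))

    reg.register(_template(
        "URE", "urea",
        [("C1", "C", 0, 0.0, 0.0, 0.0), ("O1", "O", 0, 0.0, 1.23, 0.0),
         ("N1", "N", 2, -1.16, -0.67, 0.0), ("N2", "N", 2, 1.16, -0.67, 0.0)],
        [(0, 1, 2), (0, 2, 1), (0, 3, 1)],
        [("donor", (2,)), ("donor", (3,)), ("acceptor", (1,))]))

    reg.register(_template(
        "MAM", "methylamine",
        [("C1", "C", 3, 0.0, 0.0, 0.0), ("N1", "N", 2, 1.47, 0.0, 0.0)],
        [(0, 1, 1)],
        [("donor", (1,)), ("acceptor", (1,)), ("hydrophobic", (0,))]))

    reg.register(_ring_template(
        "PHN", "phenol",
        [("O1", "O", 1, 2.75, 0.0, 0.0)],
        [(0, 6, "1")],
        [("donor", (6,)), ("acceptor", (6,))]))

    reg.register(_ring_template(
        "BZD", "benzaldehyde",
        [("C7", "C", 1, 2.86, 0.0, 0.0), ("O1", "O", 0, 3.52, 1.03, 0.0)],
        [(0, 6, "1"), (6, 7, "2")],
        [("acceptor", (7,))]))

    reg.register(_ring_template("BNZ", "benzene", [], [], []))

    reg.register(_template(
        "ACM", "acetamide",
        [("C1", "C", 3, -1.51, -0.02, 0.0), ("C2", "C", 0, 0.0, 0.0, 0.0),
         ("O1", "O", 0, 0.61, 1.06, 0.0), ("N1", "N", 2, 0.70, -1.15, 0.0)],
        [(0, 1, 1), (1, 2, 2), (1, 3, 1)],
        [("donor", (3,)), ("acceptor", (2,)), ("hydrophobic", (0,))]))

    reg.register(_template(
        "DMF", "N,N-dimethylformamide",
        [("C1", "C", 1, 0.0, 0.0, 0.0), ("O1", "O", 0, 0.61, 1.06, 0.0),
         ("N1", "N", 0, 0.67, -1.16, 0.0), ("C2", "C", 3, 2.12, -1.20, 0.0),
         ("C3", "C", 3, 0.0, -2.44, 0.0)],
        [(0, 1, 2), (0, 2, 1), (2, 3, 1), (2, 4, 1)],
        [("acceptor", (1,)), ("hydrophobic", (3, 4))]))

    return reg
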