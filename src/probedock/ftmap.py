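"""Reading probe-mapping results: receptor + docked probe crossclusters in PDB.

A solvent-mapping run leaves a single PDB file holding the target protein
(``ATOM`` records) followed by the docked probe crossclusters (``HETATM``
records).  The dialect accepted here marks each crosscluster with a delimiter
line of the form::

    HEADER crosscluster.<rank>.<population>

preceding its probe block.  When no delimiter is present a fallback grouping
rule applies: consecutive ``HETATM`` records sharing chain and residue number
form one probe molecule, and a jump in residue numbering starts a new
crosscluster.  Probe bond topology is reconstructed from the registry
templates (PDB carries no connectivity), matched by heavy-atom order.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import MalformedInputError, TemplateMismatchError
from .probes import UNKNOWN_PROBE, ProbeRegistry, ProbeTemplate, default_registry

__all__ = [
    "Atom", "ProbeMolecule", "CrossCluster", "FTMapResult",
    "parse_ftmap_result", "classify_probe", "format_pdb_atom",
]

_KNOWN_ELEMENTS = frozenset(
    "H C N O S P F CL BR I".split()
)

_CLUSTER_RE = re.compile(r"crosscluster\.(\d+)\.(\d+)", re.IGNORECASE)


@dataclass
class Atom:
    """One atom from a PDB record (coordinates in Å)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain: str
    coords: np.ndarray
    is_het: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if self.element.upper() not in _KNOWN_ELEMENTS:
            raise ValueError(f"atom {self.serial}: unrecognized element {self.element!r}")


@dataclass
class ProbeMolecule:
    """A docked probe copy: typed atoms plus template-derived bonds.

    ``bonds`` are (i, j, order) with indices into ``atoms`` and order one of
    ``"1" "2" "3" "ar"``.  Hydrogens, when present in the source file, follow
    the heavy atoms and are each bonded to their nearest heavy atom.
    """

    probe_type: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(a.element for a in self.atoms)

    @property
    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element != "H"]

    def validate(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) outside atom list of length {n}")
        if n > 1:
            # connectivity check via BFS over the bond graph
            adj: dict[int, set[int]] = {i: set() for i in range(n)}
            for i, j, _ in self.bonds:
                adj[i].add(j)
                adj[j].add(i)
            seen, stack = {0}, [0]
            while stack:
                for nb in adj[stack.pop()]:
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            if len(seen) != n:
                raise ValueError(f"probe {self.probe_type}: bond graph is disconnected")


@dataclass
class CrossCluster:
    """One consensus cluster of docked probes marking a candidate hot spot."""

    cluster_id: int
    probes: list[ProbeMolecule]
    label: str = ""

    @property
    def probe_atom_coords(self) -> np.ndarray:
        """All probe atom coordinates stacked, (n, 3)."""
        return np.vstack([p.coords for p in self.probes])


@dataclass
class FTMapResult:
    """Parsed probe-mapping output: receptor atoms + ordered crossclusters."""

    receptor_atoms: list[Atom]
    crossclusters: list[CrossCluster]
    source_path: str = ""
    unknown_residues: list[tuple[str, int]] = field(default_factory=list)

    @property
    def cluster_ids(self) -> list[int]:
        return [c.cluster_id for c in self.crossclusters]

    def get_cluster(self, cluster_id: int) -> CrossCluster:
        for c in self.crossclusters:
            if c.cluster_id == cluster_id:
                return c
        raise KeyError(cluster_id)

    @property
    def n_probe_atoms(self) -> int:
        return sum(len(p.atoms) for c in self.crossclusters for p in c.probes)


def classify_probe(residue_name: str, registry: ProbeRegistry) -> str:
    """Map a residue code to its probe type; total, returns ``unknown`` if absent.

    Lookup trims whitespace and uppercases, so padded fixed-column codes and
    lowercase variants resolve identically.
    """
    return registry.classify(residue_name)


def _guess_element(name: str, element_field: str) -> str:
    if element_field.strip():
        return element_field.strip().capitalize().upper() if len(element_field.strip()) > 1 \
            else element_field.strip().upper()
    stripped = name.strip()
    # two-letter elements in the probe set
    for two in ("CL", "BR"):
        if stripped.upper().startswith(two):
            return two
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


def _parse_pdb_atom(line: str, lineno: int, is_het: bool) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        residue_name = line[17:21].strip()
        chain = line[21:22]
        residue_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = _guess_element(name, line[76:78] if len(line) >= 78 else "")
    except (ValueError, IndexError) as exc:
        raise MalformedInputError(f"line {lineno}: bad PDB atom record: {exc}") from exc
    return Atom(serial=serial, name=name, element=element, residue_name=residue_name,
                residue_seq=residue_seq, chain=chain, coords=np.array([x, y, z]),
                is_het=is_het)


def _build_probe(residue_atoms: list[Atom], template: ProbeTemplate) -> ProbeMolecule:
    """Reconstruct a probe molecule from one residue's atoms using its template."""
    heavy = [a for a in residue_atoms if a.element != "H"]
    hydrogens = [a for a in residue_atoms if a.element == "H"]
    if len(heavy) != template.n_heavy:
        raise TemplateMismatchError(
            f"residue {residue_atoms[0].residue_name} {residue_atoms[0].residue_seq}: "
            f"{len(heavy)} heavy atoms, template {template.code} expects {template.n_heavy}"
        )
    for a, el in zip(heavy, template.elements):
        if a.element != el:
            raise TemplateMismatchError(
                f"residue {a.residue_name} {a.residue_seq}: atom {a.name} is {a.element}, "
                f"template {template.code} expects {el} at this position"
            )
    atoms = heavy + hydrogens
    bonds = [(i, j, o) for i, j, o in template.bonds]
    heavy_xyz = np.array([a.coords for a in heavy])
    for h_idx, h in enumerate(hydrogens, start=len(heavy)):
        nearest = int(np.argmin(np.linalg.norm(heavy_xyz - h.coords, axis=1)))
        bonds.append((nearest, h_idx, "1"))
    mol = ProbeMolecule(probe_type=template.code, atoms=atoms, bonds=bonds)
    mol.validate()
    return mol


def parse_ftmap_result(
    pdb_text: str,
    registry: ProbeRegistry | None = None,
    source_path: str = "",
) -> FTMapResult:
    """Parse a probe-mapping PDB result into receptor atoms and crossclusters.

    Raises
    ------
    MalformedInputError
        If the text contains no receptor ``ATOM`` records.
    TemplateMismatchError
        If a recognized probe residue does not match its template topology.
    """
    registry = registry if registry is not None else default_registry()
    receptor: list[Atom] = []
    unknown: list[tuple[str, int]] = []

    # raw clusters: (cluster_id or None, label, list of residues);
    # each residue is a list of HETATM Atom objects
    raw_clusters: list[dict] = []
    saw_delimiter = False
    current: dict | None = None
    prev_key: tuple[str, int] | None = None

    def new_cluster(cid, label):
        nonlocal current
        current = {"cluster_id": cid, "label": label, "residues": []}
        raw_clusters.append(current)

    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec == "HEADER":
            m = _CLUSTER_RE.search(line)
            if m:
                saw_delimiter = True
                new_cluster(int(m.group(1)), line.strip())
                prev_key = None
            continue
        if rec == "ATOM  ":
            receptor.append(_parse_pdb_atom(line, lineno, is_het=False))
            continue
        if rec == "HETATM":
            atom = _parse_pdb_atom(line, lineno, is_het=True)
            if registry.classify(atom.residue_name) == UNKNOWN_PROBE:
                unknown.append((atom.residue_name, atom.residue_seq))
                continue
            key = (atom.chain, atom.residue_seq)
            if current is None:
                new_cluster(None, "")
            elif not saw_delimiter and prev_key is not None and key != prev_key:
                # fallback grouping: a gap in residue numbering splits clusters
                if atom.residue_seq > prev_key[1] + 1 or atom.chain != prev_key[0]:
                    new_cluster(None, "")
            if key != prev_key:
                current["residues"].append([])
                prev_key = key
            current["residues"][-1].append(atom)
            continue
        # TER / END / REMARK / anything else: ignored

    if not receptor:
        raise MalformedInputError("no ATOM records: receptor is missing or input is not PDB")
    if unknown:
        codes = sorted({c for c, _ in unknown})
        warnings.warn(f"skipped {len(unknown)} HETATM residues with unregistered codes: "
                      f"{', '.join(codes)}", stacklevel=2)

    clusters: list[CrossCluster] = []
    next_id = 0
    for raw in raw_clusters:
        if not raw["residues"]:
            continue
        probes = []
        for residue_atoms in raw["residues"]:
            template = registry.get(residue_atoms[0].residue_name)
            probes.append(_build_probe(residue_atoms, template))
        cid = raw["cluster_id"]
        if cid is None:
            cid = next_id
        next_id = max(next_id, cid) + 1
        clusters.append(CrossCluster(cluster_id=cid, probes=probes, label=raw["label"]))

    ids = [c.cluster_id for c in clusters]
    if len(set(ids)) != len(ids):
        raise MalformedInputError(f"duplicate crosscluster ids: {sorted(ids)}")
    clusters.sort(key=lambda c: c.cluster_id)
    return FTMapResult(receptor_atoms=receptor, crossclusters=clusters,
                       source_path=source_path, unknown_residues=unknown)


def format_pdb_atom(
    record: str, serial: int, name: str, residue_name: str, chain: str,
    residue_seq: int, coords, occupancy: float = 1.00, bfactor: float = 0.00,
    element: str = "",
) -> str:
    """Render one fixed-column PDB ATOM/HETATM line (no trailing newline)."""
    x, y, z = (float(v) for v in coords)
    name_f = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (f"{record:<6s}{serial:>5d} {name_f}{'':1s}{residue_name:<4s}"
            f"{chain:1s}{residue_seq:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{bfactor:6.2f}"
            f"{'':10s}{element:>2s}")
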