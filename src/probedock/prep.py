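"""Docking preparation: box construction, keyword-input files with override
semantics, and chemical-matching parameter/correlation tables.

The docking box is an axis-aligned bounding box of the sphere centers grown
by a margin on every side (default 5 Å; a wider 10 Å margin is the usual
choice when large flexible ligands must fit).  Keyword files use the classic
``keyword  value`` one-per-line dialect; when the user supplies a custom
docking input, only the pipeline-managed keywords are rewritten and every
other line is preserved byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import EmptyInputError, ParseError
from .pharmacophore import FEATURE_LABELS, PharmacophorePoint
from .spheres import SphereSet

__all__ = [
    "DockingBox", "DockParams", "MatchTable",
    "compute_box", "write_box_pdb", "write_grid_input",
    "default_dock_params", "finalize_dock_input",
    "build_match_table", "write_match_files", "read_match_table", "evaluate_match",
]


@dataclass
class DockingBox:
    """Axis-aligned docking box; corners in Å."""

    min_corner: np.ndarray
    max_corner: np.ndarray
    margin: float = 0.0

    def __post_init__(self):
        self.min_corner = np.asarray(self.min_corner, dtype=float)
        self.max_corner = np.asarray(self.max_corner, dtype=float)
        if np.any(self.max_corner < self.min_corner):
            raise ValueError("max_corner must dominate min_corner componentwise")

    @property
    def center(self) -> np.ndarray:
        return (self.min_corner + self.max_corner) / 2.0

    @property
    def dimensions(self) -> np.ndarray:
        return self.max_corner - self.min_corner

    @property
    def corners(self) -> np.ndarray:
        lo, hi = self.min_corner, self.max_corner
        return np.array([[x, y, z] for x in (lo[0], hi[0])
                         for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])

    def contains(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        return np.all((pts >= self.min_corner) & (pts <= self.max_corner), axis=1)


def compute_box(sphere_set: SphereSet | np.ndarray, margin: float = 5.0) -> DockingBox:
    """Bounding box of sphere centers grown by ``margin`` on all sides.

    The box is computed over centers, not center±radius: with probe-derived
    spheres of sub-Å radius the margin dominates, and this keeps the corner
    arithmetic exactly reproducible.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    centers = sphere_set.centers if isinstance(sphere_set, SphereSet) \
        else np.asarray(sphere_set, dtype=float).reshape(-1, 3)
    if centers.size == 0:
        raise EmptyInputError("cannot build a box around an empty sphere set")
    return DockingBox(min_corner=centers.min(axis=0) - margin,
                      max_corner=centers.max(axis=0) + margin, margin=margin)


def write_box_pdb(box: DockingBox) -> str:
    """Render the box as 8 corner pseudo-atoms plus REMARK geometry lines."""
    c, d = box.center, box.dimensions
    lines = [
        "REMARK    docking box",
        f"REMARK    CENTER (X Y Z)      {c[0]:8.3f}{c[1]:8.3f}{c[2]:8.3f}",
        f"REMARK    DIMENSIONS (X Y Z)  {d[0]:8.3f}{d[1]:8.3f}{d[2]:8.3f}",
    ]
    from .ftmap import format_pdb_atom
    for i, corner in enumerate(box.corners, start=1):
        lines.append(format_pdb_atom("HETATM", i, "DU", "BOX", "B", 1, corner,
                                     element="C"))
    # box edges: corners differing in exactly one bit of their (x,y,z) index
    for i in range(8):
        for j in range(i + 1, 8):
            if bin(i ^ j).count("1") == 1:
                lines.append(f"CONECT{i + 1:>5d}{j + 1:>5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


@dataclass
class DockParams:
    """Ordered keyword/value file with comments preserved.

    ``lines`` holds (kind, keyword, separator, value, raw) tuples where kind
    is ``kv``, ``comment`` or ``blank``; rewriting a managed keyword keeps the
    original separator so untouched bytes stay untouched.
    """

    lines: list[tuple] = field(default_factory=list)

    @classmethod
    def from_pairs(cls, pairs) -> "DockParams":
        p = cls()
        for k, v in pairs:
            p.set(k, v)
        return p

    @classmethod
    def from_text(cls, text: str) -> "DockParams":
        p = cls()
        seen = set()
        for lineno, raw in enumerate(text.splitlines(), start=1):
            stripped = raw.strip()
            if not stripped:
                p.lines.append(("blank", None, None, None, raw))
                continue
            if stripped.startswith("#"):
                p.lines.append(("comment", None, None, None, raw))
                continue
            parts = raw.split(None, 1)
            if len(parts) != 2:
                raise ParseError(f"expected 'keyword value', got {stripped!r}",
                                 line=lineno)
            keyword, value = parts[0], parts[1].rstrip()
            if keyword in seen:
                raise ParseError(f"duplicate keyword {keyword!r}", line=lineno)
            seen.add(keyword)
            sep_start = len(keyword)
            sep_end = len(raw) - len(raw[sep_start:].lstrip())
            p.lines.append(("kv", keyword, raw[sep_start:sep_end], value, raw))
        return p

    def keywords(self) -> list[str]:
        return [k for kind, k, *_ in self.lines if kind == "kv"]

    def get(self, keyword: str, default=None):
        for kind, k, _, v, _ in self.lines:
            if kind == "kv" and k == keyword:
                return v
        return default

    def set(self, keyword: str, value) -> None:
        value = str(value)
        for i, (kind, k, sep, _, _) in enumerate(self.lines):
            if kind == "kv" and k == keyword:
                sep = sep or " " * max(1, 31 - len(keyword))
                self.lines[i] = ("kv", keyword, sep, value, f"{keyword}{sep}{value}")
                return
        sep = " " * max(1, 31 - len(keyword))
        self.lines.append(("kv", keyword, sep, value, f"{keyword}{sep}{value}"))

    def to_text(self) -> str:
        return "\n".join(raw for *_, raw in self.lines) + "\n"

    def copy(self) -> "DockParams":
        p = DockParams()
        p.lines = list(self.lines)
        return p


_GRID_DEFAULTS = (
    ("compute_grids", "yes"),
    ("grid_spacing", "0.3"),
    ("output_molecule", "no"),
    ("contact_score", "no"),
    ("energy_score", "yes"),
    ("energy_cutoff_distance", "9999"),
    ("atom_model", "a"),
    ("attractive_exponent", "6"),
    ("repulsive_exponent", "12"),
    ("distance_dielectric", "yes"),
    ("dielectric_factor", "4"),
    ("bump_filter", "yes"),
    ("bump_overlap", "0.75"),
    ("receptor_file", "receptor.mol2"),
    ("box_file", "box.pdb"),
    ("vdw_definition_file", "vdw_AMBER_parm99.defn"),
    ("score_grid_prefix", "grid"),
)


def write_grid_input(box_file: str, receptor_file: str,
                     overrides: dict | None = None) -> str:
    """Keyword input for the potential-grid precomputation step.

    The shipped defaults mirror the standard energy-grid setup (0.3 Å
    spacing, 6-12 van der Waals, distance-dependent dielectric); any keyword
    may be overridden.  Output ordering is fixed, so identical inputs give
    byte-identical text.
    """
    if not box_file or not receptor_file:
        raise ValueError("box_file and receptor_file paths must be non-empty")
    params = DockParams.from_pairs(_GRID_DEFAULTS)
    params.set("receptor_file", receptor_file)
    params.set("box_file", box_file)
    for k, v in (overrides or {}).items():
        params.set(k, v)
    return params.to_text()


_DOCK_DEFAULTS = (
    ("conformer_search_type", "flex"),
    ("user_specified_anchor", "no"),
    ("limit_max_anchors", "no"),
    ("min_anchor_size", "5"),
    ("pruning_use_clustering", "yes"),
    ("pruning_max_orients", "1000"),
    ("pruning_clustering_cutoff", "100"),
    ("pruning_conformer_score_cutoff", "100.0"),
    ("use_internal_energy", "yes"),
    ("internal_energy_rep_exp", "12"),
    ("ligand_atom_file", "ligand.mol2"),
    ("limit_max_ligands", "no"),
    ("skip_molecule", "no"),
    ("read_mol_solvation", "no"),
    ("calculate_rmsd", "no"),
    ("use_database_filter", "no"),
    ("orient_ligand", "yes"),
    ("automated_matching", "yes"),
    ("receptor_site_file", "spheres.sph"),
    ("max_orientations", "1000"),
    ("critical_points", "no"),
    ("chemical_matching", "no"),
    ("use_ligand_spheres", "no"),
    ("use_clash_overlap", "no"),
    ("write_growth_tree", "no"),
    ("bump_filter", "no"),
    ("score_molecules", "yes"),
    ("contact_score_primary", "no"),
    ("contact_score_secondary", "no"),
    ("grid_score_primary", "yes"),
    ("grid_score_secondary", "no"),
    ("grid_score_rep_rad_scale", "1"),
    ("grid_score_vdw_scale", "1"),
    ("grid_score_es_scale", "1"),
    ("grid_score_grid_prefix", "grid"),
    ("minimize_ligand", "yes"),
    ("simplex_max_iterations", "1000"),
    ("atom_model", "all"),
    ("vdw_defn_file", "vdw_AMBER_parm99.defn"),
    ("flex_defn_file", "flex.defn"),
    ("flex_drive_file", "flex_drive.tbl"),
    ("ligand_outfile_prefix", "docked"),
    ("write_orientations", "no"),
    ("num_scored_conformers", "1"),
    ("rank_ligands", "no"),
)


def default_dock_params() -> DockParams:
    """The shipped default docking keyword set (anchor-and-grow, grid score)."""
    return DockParams.from_pairs(_DOCK_DEFAULTS)


def finalize_dock_input(custom: DockParams | str | None,
                        managed: DockParams | dict) -> DockParams:
    """Merge managed keywords into a custom keyword file, or into defaults.

    With a custom file, only managed keywords are altered (replaced in place,
    appended when missing); every other line — unknown keywords, comments,
    blank lines — is preserved verbatim.  The operation is idempotent.
    """
    if isinstance(custom, str):
        custom = DockParams.from_text(custom)
    base = custom.copy() if custom is not None else default_dock_params()
    items = managed.items() if isinstance(managed, dict) else \
        ((k, managed.get(k)) for k in managed.keywords())
    for k, v in items:
        base.set(k, v)
    return base


@dataclass
class MatchTable:
    """Label-pair compatibility for chemical matching.

    The default policy is identity matching — a ligand feature may only
    overlap a sphere of its own label — with ``null`` compatible with
    everything; the matrix is symmetric with an all-true diagonal.
    """

    labels: tuple[str, ...]
    compatibility: np.ndarray

    def __post_init__(self):
        self.compatibility = np.asarray(self.compatibility, dtype=bool)
        n = len(self.labels)
        if self.compatibility.shape != (n, n):
            raise ValueError("compatibility matrix shape must match labels")
        if not np.array_equal(self.compatibility, self.compatibility.T):
            raise ValueError("compatibility matrix must be symmetric")
        if not np.all(np.diag(self.compatibility)):
            raise ValueError("labels must be self-compatible")
        if "null" in self.labels:
            k = self.labels.index("null")
            if not (np.all(self.compatibility[k]) and np.all(self.compatibility[:, k])):
                raise ValueError("null must be compatible with every label")

    def compatible(self, a: str, b: str) -> bool:
        return bool(self.compatibility[self.labels.index(a), self.labels.index(b)])


def build_match_table(labels) -> MatchTable:
    """Identity compatibility over the (deduplicated, sorted) labels + null."""
    for lab in labels:
        if lab not in FEATURE_LABELS:
            raise ValueError(f"unknown feature label {lab!r}")
    uniq = sorted(set(labels) - {"null"})
    uniq.append("null")
    n = len(uniq)
    mat = np.eye(n, dtype=bool)
    mat[-1, :] = True
    mat[:, -1] = True
    return MatchTable(labels=tuple(uniq), compatibility=mat)


_LABEL_RULES = {
    "donor": "hydrogen-bond donor: N or O bearing at least one hydrogen",
    "acceptor": "hydrogen-bond acceptor: O, or N with a free lone pair",
    "hydrophobic": "hydrophobic: centroid of a connected carbon set with no N/O neighbor",
    "aromatic": "aromatic: centroid of a planar six-membered aromatic ring",
    "positive": "positive: formally positively charged group",
    "negative": "negative: formally negatively charged group",
    "null": "null: unlabeled; matches any feature",
}


def write_match_files(table: MatchTable,
                      points: list[PharmacophorePoint] | None = None) -> tuple[str, str]:
    """Render (definition file, correlation table file) for chemical matching.

    The definition file states each label's perception rule; the table file
    holds the label-pair compatibility grid as 0/1.  When ``points`` are
    given, per-label feature counts are included as comments.
    """
    defn = ["# pharmacophore label definitions"]
    counts: dict[str, int] = {}
    for p in points or []:
        counts[p.label] = counts.get(p.label, 0) + 1
    for lab in table.labels:
        defn.append(f"label {lab}")
        defn.append(f"  rule {_LABEL_RULES.get(lab, 'user-defined')}")
        if lab in counts:
            defn.append(f"  # {counts[lab]} feature point(s) in this run")
    defn_text = "\n".join(defn) + "\n"

    width = max(len(lab) for lab in table.labels)
    tbl = ["# chemical matching correlation table (1 = compatible)",
           "labels " + " ".join(table.labels)]
    for i, lab in enumerate(table.labels):
        row = " ".join("1" if table.compatibility[i, j] else "0"
                       for j in range(len(table.labels)))
        tbl.append(f"{lab:<{width}s} {row}")
    return defn_text, "\n".join(tbl) + "\n"


def read_match_table(text: str) -> MatchTable:
    """Parse a correlation table file back into a :class:`MatchTable`."""
    labels: tuple[str, ...] | None = None
    rows: dict[str, list[bool]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "labels":
            labels = tuple(parts[1:])
            continue
        if labels is None:
            raise ParseError("row before 'labels' header", line=lineno)
        if len(parts) != len(labels) + 1:
            raise ParseError(f"expected {len(labels)} entries for {parts[0]!r}",
                             line=lineno)
        rows[parts[0]] = [v == "1" for v in parts[1:]]
    if labels is None:
        raise ParseError("missing 'labels' header", line=1)
    mat = np.array([rows[lab] for lab in labels], dtype=bool)
    return MatchTable(labels=labels, compatibility=mat)


def evaluate_match(
    ligand_points: list[PharmacophorePoint],
    spheres: SphereSet,
    table: MatchTable,
    overlap: float = 1.0,
) -> bool:
    """Is a ligand placement chemically favourable against labeled spheres?

    Returns False iff some ligand feature point lies within ``overlap`` Å of
    a sphere whose label is incompatible with the point's label.  A pose with
    no overlapping sphere at all is vacuously favourable.  This mirrors the
    pruning a sphere-matching engine applies during search and is provided as
    a validator.
    """
    if overlap <= 0:
        raise ValueError("overlap distance must be positive")
    all_spheres = spheres.all_spheres
    if not ligand_points or not all_spheres:
        return True
    pts = np.array([p.center for p in ligand_points])
    ctr = np.array([s.center for s in all_spheres])
    close = cdist(pts, ctr) <= overlap
    for i, point in enumerate(ligand_points):
        for j in np.nonzero(close[i])[0]:
            if not table.compatible(point.label, spheres.label_of(all_spheres[j])):
                return False
    return True
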