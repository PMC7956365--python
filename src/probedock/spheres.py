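"""Docking spheres: conversion from crossclusters, the ``.sph`` dialect,
radius-based selection, and PDB export for visualization.

Sphere-matching docking engines place ligand atoms only where spheres exist,
so converting probe crossclusters into spheres restricts the search space to
the detected cavities.  Each sphere inherits the pharmacophore label of the
feature point it came from through the file's color table, which is what
makes chemical matching possible downstream.

Sphere records use the classic fixed-width layout
``(I5, 3F10.5, F8.3, I5, I2, I3)``: index, x, y, z, radius, nearest surface
atom, critical-cluster flag, color index.  Probe-derived spheres are not
surface-derived, so their surface atom is 0 and they are never critical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyInputError, ParseError, UnknownClusterError
from .ftmap import FTMapResult, format_pdb_atom
from .pharmacophore import PharmacophorePoint, perceive_features
from .probes import ProbeRegistry

__all__ = [
    "ALL", "Sphere", "SphereSet", "points_to_spheres", "crossclusters_to_spheres",
    "write_sph", "read_sph", "select_spheres_near", "spheres_to_pdb",
]

#: Selection sentinel: convert every crosscluster (blind mode).
ALL = "ALL"

#: Default radius for probe-derived spheres, Å.  These spheres mark candidate
#: ligand-atom positions rather than cavity volumes, so they are kept small.
DEFAULT_SPHERE_RADIUS = 0.7


@dataclass
class Sphere:
    """One docking sphere; ``color`` indexes the owning set's color table."""

    index: int
    center: np.ndarray
    radius: float
    surface_atom: int = 0
    critical: int = 0
    color: int = 1

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError(f"sphere {self.index}: radius must be positive")

    def __eq__(self, other):
        if not isinstance(other, Sphere):
            return NotImplemented
        return (self.index == other.index
                and np.array_equal(self.center, other.center)
                and self.radius == other.radius
                and self.surface_atom == other.surface_atom
                and self.critical == other.critical
                and self.color == other.color)


@dataclass
class SphereSet:
    """Cluster-organized spheres plus the label color table.

    ``colors`` is an ordered list of (label, number) with numbers contiguous
    from 1.  ``clusters`` holds (cluster_number, spheres) pairs; requesting
    cluster 0 returns the union of all clusters, mirroring the convention
    that cluster 0 is the whole sphere set.
    """

    colors: list[tuple[str, int]] = field(default_factory=list)
    clusters: list[tuple[int, list[Sphere]]] = field(default_factory=list)
    provenance: str = "sphere set"

    def __post_init__(self):
        numbers = [n for _, n in self.colors]
        if numbers != list(range(1, len(numbers) + 1)):
            raise ValueError("color numbers must be unique and contiguous from 1")
        for cnum, spheres in self.clusters:
            idx = [s.index for s in spheres]
            if len(set(idx)) != len(idx):
                raise ValueError(f"cluster {cnum}: duplicate sphere indices")

    @property
    def all_spheres(self) -> list[Sphere]:
        return [s for _, spheres in self.clusters for s in spheres]

    def __len__(self) -> int:
        return len(self.all_spheres)

    def get_cluster(self, number: int) -> list[Sphere]:
        if number == 0:
            return self.all_spheres
        for cnum, spheres in self.clusters:
            if cnum == number:
                return spheres
        raise KeyError(number)

    def color_number(self, label: str) -> int:
        for name, num in self.colors:
            if name == label:
                return num
        raise KeyError(label)

    def label_of(self, sphere: Sphere) -> str:
        for name, num in self.colors:
            if num == sphere.color:
                return name
        raise KeyError(sphere.color)

    @property
    def centers(self) -> np.ndarray:
        spheres = self.all_spheres
        return np.array([s.center for s in spheres]).reshape(len(spheres), 3)


def points_to_spheres(
    points: list[PharmacophorePoint],
    radius: float = DEFAULT_SPHERE_RADIUS,
    provenance: str = "spheres from pharmacophore points",
) -> SphereSet:
    """Turn labeled feature points into one sphere cluster with a color table.

    Labels are sorted lexicographically and numbered from 1 so identical
    inputs always produce identical files.
    """
    if radius <= 0:
        raise ValueError("sphere radius must be positive")
    labels = sorted({p.label for p in points})
    colors = [(lab, i + 1) for i, lab in enumerate(labels)]
    color_of = dict(colors)
    spheres = [
        Sphere(index=i + 1, center=p.center, radius=radius,
               surface_atom=0, critical=0, color=color_of[p.label])
        for i, p in enumerate(points)
    ]
    return SphereSet(colors=colors, clusters=[(1, spheres)], provenance=provenance)


def crossclusters_to_spheres(
    result: FTMapResult,
    selection=ALL,
    radius: float = DEFAULT_SPHERE_RADIUS,
    registry: ProbeRegistry | None = None,
) -> SphereSet:
    """Convert selected crossclusters' pharmacophore points into spheres.

    ``selection`` is a list of crosscluster ids, or :data:`ALL` to take every
    cluster (blind mode).  One sphere is emitted per feature point, all in
    cluster 1.
    """
    available = set(result.cluster_ids)
    if selection is ALL or selection == ALL or selection is None:
        chosen = result.crossclusters
    else:
        missing = [cid for cid in selection if cid not in available]
        if missing:
            raise UnknownClusterError(
                f"unknown crosscluster id(s) {missing}; available: {sorted(available)}")
        wanted = set(selection)
        chosen = [c for c in result.crossclusters if c.cluster_id in wanted]
    points: list[PharmacophorePoint] = []
    for cluster in chosen:
        for p_idx, probe in enumerate(cluster.probes):
            points.extend(perceive_features(probe, registry,
                                            cluster_id=cluster.cluster_id,
                                            probe_index=p_idx))
    sel_note = "all crossclusters" if selection in (ALL, None) \
        else f"crossclusters {sorted(set(selection))}"
    return points_to_spheres(points, radius=radius,
                             provenance=f"spheres from probe features ({sel_note})")


def write_sph(sphere_set: SphereSet) -> str:
    """Serialize a sphere set to the classic ``.sph`` dialect."""
    lines = [sphere_set.provenance]
    for name, num in sphere_set.colors:
        lines.append(f"color {name} {num}")
    for cnum, spheres in sphere_set.clusters:
        lines.append(f"cluster{cnum:6d} number_of_spheres_in_cluster{len(spheres):6d}")
        for s in spheres:
            lines.append(f"{s.index:5d}{s.center[0]:10.5f}{s.center[1]:10.5f}"
                         f"{s.center[2]:10.5f}{s.radius:8.3f}{s.surface_atom:5d}"
                         f"{s.critical:2d}{s.color:3d}")
    return "\n".join(lines) + "\n"


def read_sph(text: str) -> SphereSet:
    """Parse ``.sph`` text; accepts multi-cluster files from classic sphere
    generators as well as this package's single-cluster output."""
    colors: list[tuple[str, int]] = []
    clusters: list[tuple[int, list[Sphere]]] = []
    provenance = "sphere set"
    current: list[Sphere] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("color "):
            parts = stripped.split()
            if len(parts) != 3:
                raise ParseError(f"bad color line: {stripped!r}", line=lineno)
            try:
                colors.append((parts[1], int(parts[2])))
            except ValueError as exc:
                raise ParseError(f"bad color number: {exc}", line=lineno) from exc
            continue
        if stripped.startswith("cluster"):
            parts = stripped.split()
            try:
                cnum = int(parts[1])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"bad cluster header: {stripped!r}", line=lineno) from exc
            current = []
            clusters.append((cnum, current))
            continue
        if lineno == 1:
            provenance = line
            continue
        if current is None:
            raise ParseError(f"sphere record before any cluster header: {stripped!r}",
                             line=lineno)
        try:
            sphere = Sphere(
                index=int(line[0:5]),
                center=np.array([float(line[5:15]), float(line[15:25]),
                                 float(line[25:35])]),
                radius=float(line[35:43]),
                surface_atom=int(line[43:48]) if line[43:48].strip() else 0,
                critical=int(line[48:50]) if line[48:50].strip() else 0,
                color=int(line[50:53]) if line[50:53].strip() else 1,
            )
        except (ValueError, IndexError) as exc:
            raise ParseError(f"malformed sphere record: {exc}", line=lineno) from exc
        current.append(sphere)
    return SphereSet(colors=colors, clusters=clusters, provenance=provenance)


def select_spheres_near(
    sphere_set: SphereSet,
    reference_points,
    radius: float = 3.0,
) -> SphereSet:
    """Keep spheres whose center lies within ``radius`` of any reference point.

    The boundary is inclusive (distance ≤ radius counts), mirroring the
    classic sphere-selector semantics of picking spheres "within" a radius
    around a reference; default radius is 3 Å.
    """
    refs = np.asarray(reference_points, dtype=float).reshape(-1, 3)
    if refs.size == 0:
        raise EmptyInputError("reference point list is empty")
    if radius <= 0:
        raise ValueError("selection radius must be positive")
    tree = cKDTree(refs)
    clusters = []
    for cnum, spheres in sphere_set.clusters:
        kept = []
        for s in spheres:
            dist, _ = tree.query(s.center)
            if dist <= radius:
                kept.append(replace(s, center=s.center.copy()))
        clusters.append((cnum, kept))
    return SphereSet(colors=list(sphere_set.colors), clusters=clusters,
                     provenance=sphere_set.provenance)


def spheres_to_pdb(sphere_set: SphereSet) -> str:
    """Export spheres as pseudo-atoms for visualization.

    One ``HETATM`` per sphere: element C, residue SPH, residue number = the
    sphere index, B-factor = the radius.
    """
    lines = ["REMARK   docking spheres exported for visualization",
             "REMARK   B-factor column holds the sphere radius"]
    serial = 0
    for cnum, spheres in sphere_set.clusters:
        for s in spheres:
            serial += 1
            lines.append(format_pdb_atom(
                "HETATM", serial, "C", "SPH", "S", s.index, s.center,
                occupancy=1.0, bfactor=s.radius, element="C"))
    lines.append("END")
    return "\n".join(lines) + "\n"
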