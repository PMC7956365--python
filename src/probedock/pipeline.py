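"""End-to-end orchestration: parse → perceive → spheres → box → input files.

A run consumes one probe-mapping PDB result (plus an optional ligand and an
optional custom docking input) and emits every preparation artifact a
sphere-matching docking engine needs, along with a run log and a manifest.
Runs are pure functions of (configuration, input bytes): the log records
step order and parameters, not wall-clock time, so repeated runs with the
same seed and inputs are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ProbeDockError
from .ftmap import parse_ftmap_result
from .mol2 import write_mol2
from .pharmacophore import perceive_features, write_pharmacophore_file
from .prep import (build_match_table, compute_box, default_dock_params,
                   finalize_dock_input, write_box_pdb, write_grid_input,
                   write_match_files)
from .probes import ProbeRegistry, default_registry
from .spheres import (ALL, SphereSet, crossclusters_to_spheres, read_sph,
                      select_spheres_near, spheres_to_pdb, write_sph)

__all__ = ["RunConfig", "RunLog", "run_pipeline"]


@dataclass
class RunConfig:
    """All knobs of one preparation run.

    ``selection=None`` means every crosscluster (blind mode).  In
    ``classic-sph-file`` mode an existing sphere file supplies the spheres;
    a crosscluster selection then restricts them to within
    ``selection_radius`` Å of the chosen clusters' probe atoms, emulating
    the classic sphere-selector step.
    """

    ftmap_path: str
    out_dir: str
    mode: str = "ftspheres"              # "ftspheres" | "classic-sph-file"
    selection: list[int] | None = None   # None = ALL (blind)
    chem_match: bool = True
    margin: float = 5.0                  # docking-box margin, Å
    sphere_radius: float = 0.7           # probe-derived sphere radius, Å
    selection_radius: float = 3.0        # classic sphere-selector radius, Å
    skip_grid: bool = False
    seed: int = 0
    ligand_path: str | None = None
    receptor_path: str | None = None     # pre-prepared receptor MOL2, optional
    sphere_file: str | None = None       # required in classic-sph-file mode
    sphere_cluster: int = 1              # which classic cluster (0 = all)
    custom_dock_input: str | None = None

    def __post_init__(self):
        if self.margin < 0:
            raise ValueError("margin must be non-negative")
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be positive")
        if self.mode not in ("ftspheres", "classic-sph-file"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "classic-sph-file" and not self.sphere_file:
            raise ValueError("classic-sph-file mode requires sphere_file")


@dataclass
class RunLog:
    """Ordered step records; rendered as a plain-text log artifact."""

    records: list[dict] = field(default_factory=list)

    def add(self, step: str, status: str = "done", **params) -> None:
        self.records.append({"step": len(self.records) + 1, "name": step,
                             "status": status, "params": params})

    def to_text(self) -> str:
        lines = ["# preparation run log"]
        for r in self.records:
            params = " ".join(f"{k}={v}" for k, v in sorted(r["params"].items()))
            lines.append(f"step {r['step']:2d} [{r['status']:>7s}] {r['name']}"
                         + (f" | {params}" if params else ""))
        return "\n".join(lines) + "\n"

    @property
    def executed_steps(self) -> int:
        return sum(1 for r in self.records if r["status"] == "done")


class PipelineStageError(ProbeDockError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def run_pipeline(config: RunConfig,
                 registry: ProbeRegistry | None = None) -> dict[str, str]:
    """Execute the preparation pipeline; returns {artifact name: path}.

    Artifacts written to ``config.out_dir``: probes.mol2, pharmacophores.txt,
    spheres.sph, spheres.pdb, box.pdb, grid.in (unless skipped), dock.in,
    chem.defn + chem_match.tbl (when chemical matching is on), run.log and
    manifest.json.
    """
    registry = registry if registry is not None else default_registry()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    manifest: dict[str, str] = {}

    def emit(name: str, filename: str, text: str) -> Path:
        path = out / filename
        path.write_text(text)
        manifest[name] = str(path)
        return path

    def stage(name: str, func, **params):
        try:
            value = func()
        except Exception as exc:
            log.add(name, status="error", error=str(exc), **params)
            emit("run_log", "run.log", log.to_text())
            raise PipelineStageError(name, exc) from exc
        log.add(name, **params)
        return value

    result = stage("parse_probe_map", lambda: parse_ftmap_result(
        Path(config.ftmap_path).read_text(), registry,
        source_path=config.ftmap_path), path=config.ftmap_path)

    selection = ALL if config.selection is None else list(config.selection)
    sel_note = "ALL" if selection == ALL else ",".join(map(str, selection))

    all_probes = [p for c in result.crossclusters for p in c.probes]
    if all_probes:
        stage("write_probes_mol2",
              lambda: emit("probes_mol2", "probes.mol2", write_mol2(all_probes)),
              n_probes=len(all_probes))

    def perceive():
        points = []
        for cluster in result.crossclusters:
            for p_idx, probe in enumerate(cluster.probes):
                points.extend(perceive_features(probe, registry,
                                                cluster_id=cluster.cluster_id,
                                                probe_index=p_idx))
        emit("pharmacophores", "pharmacophores.txt", write_pharmacophore_file(points))
        return points

    points = stage("perceive_pharmacophores", perceive,
                   n_clusters=len(result.crossclusters))

    def build_spheres():
        if config.mode == "ftspheres":
            return crossclusters_to_spheres(result, selection,
                                            radius=config.sphere_radius,
                                            registry=registry)
        loaded = read_sph(Path(config.sphere_file).read_text())
        spheres = loaded.get_cluster(config.sphere_cluster)
        subset = SphereSet(colors=list(loaded.colors), clusters=[(1, spheres)],
                           provenance=loaded.provenance)
        if selection != ALL:
            refs = [result.get_cluster(cid).probe_atom_coords for cid in selection]
            subset = select_spheres_near(subset, np.vstack(refs),
                                         radius=config.selection_radius)
        return subset

    sphere_set = stage("build_spheres", build_spheres, mode=config.mode,
                       selection=sel_note, radius=config.sphere_radius)

    stage("write_sphere_file",
          lambda: emit("spheres_sph", "spheres.sph", write_sph(sphere_set)),
          n_spheres=len(sphere_set))
    stage("export_sphere_pdb",
          lambda: emit("spheres_pdb", "spheres.pdb", spheres_to_pdb(sphere_set)))

    box = stage("compute_box", lambda: compute_box(sphere_set, margin=config.margin),
                margin=config.margin)
    stage("write_box_pdb", lambda: emit("box_pdb", "box.pdb", write_box_pdb(box)))

    grid_exists = (out / "grid.bmp").exists() and (out / "grid.nrg").exists()
    if config.skip_grid and grid_exists:
        log.add("write_grid_input", status="skipped", reason="grid files present")
    else:
        receptor = config.receptor_path or config.ftmap_path
        stage("write_grid_input",
              lambda: emit("grid_input", "grid.in",
                           write_grid_input(str(out / "box.pdb"), receptor)),
              skip_requested=config.skip_grid)

    def build_dock_input():
        managed = {
            "receptor_site_file": str(out / "spheres.sph"),
            "grid_score_grid_prefix": str(out / "grid"),
            "chemical_matching": "yes" if config.chem_match else "no",
        }
        if config.ligand_path:
            managed["ligand_atom_file"] = config.ligand_path
        if config.chem_match:
            managed["chem_defn_file"] = str(out / "chem.defn")
            managed["chem_match_tbl"] = str(out / "chem_match.tbl")
        custom = None
        if config.custom_dock_input:
            custom = Path(config.custom_dock_input).read_text()
        params = finalize_dock_input(custom, managed)
        emit("dock_input", "dock.in", params.to_text())
        return params

    stage("write_dock_input", build_dock_input, chem_match=config.chem_match,
          custom=bool(config.custom_dock_input))

    if config.chem_match:
        def build_match():
            table = build_match_table(sorted({p.label for p in points}))
            defn_text, table_text = write_match_files(table, points)
            emit("chem_defn", "chem.defn", defn_text)
            emit("chem_match_tbl", "chem_match.tbl", table_text)
        stage("write_match_files", build_match,
              n_labels=len({p.label for p in points}))

    emit("run_log", "run.log", log.to_text())
    emit("manifest", "manifest.json",
         json.dumps({k: Path(v).name for k, v in manifest.items()},
                    indent=2, sort_keys=True) + "\n")
    return manifest
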