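"""End-to-end workflow: YAML config → passivated structures on disk.

For every scaffold × ligand-candidate combination one *job* is run through
the four stages — scaffold anchor distribution, ligand anchor discovery,
biased conformer search, rigid attachment — and the result written out with
a JSON sidecar recording placements, clash warnings, and charge bookkeeping.
A failing job (e.g. an unparseable SMILES) is recorded and does not abort
the rest of the batch.
"""

from __future__ import annotations

import json
import re
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .anchors import LigandCandidate, apply_split, match_functional_groups
from .attach import AssemblyReport, attach_all
from .config import ConfigError, CoreSpec, JobConfig
from .conformers import biased_conformer_search, ligand_vector
from .io import molecule_from_smiles, read_structure, write_structure
from .molecule import Molecule
from .surface import (
    AnchorSet,
    build_surface_model,
    core_vectors,
    distance_matrix,
    find_anchors,
    select_anchor_subset,
)

__all__ = ["JobResult", "run_pipeline", "validate_and_report", "enumerate_jobs"]


@dataclass
class JobResult:
    job_id: str
    report: AssemblyReport | None = None
    output_paths: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)
    log_lines: list[str] = field(default_factory=list)
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def _sanitize(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9@._+-]", "_", label)[:120]


def _load_ligand(spec: str, seed: int) -> Molecule:
    p = Path(spec)
    if p.suffix.lower() in (".xyz", ".pdb") and p.exists():
        mol = read_structure(p)
        if not mol.bonds:
            _perceive_bonds(mol)
        return mol
    return molecule_from_smiles(spec, embed3d=True, seed=seed)


def _perceive_bonds(mol: Molecule, slack: float = 0.45) -> None:
    """Distance heuristic: bond when r < r_cov(i) + r_cov(j) + slack."""
    from scipy.spatial import cKDTree

    from .molecule import covalent_radius

    pos = mol.positions
    radii = np.array([covalent_radius(a.element) for a in mol.atoms])
    tree = cKDTree(pos)
    cutoff = radii.max() * 2 + slack if len(mol) else 0.0
    for i, j in tree.query_pairs(cutoff):
        d = float(np.linalg.norm(pos[i] - pos[j]))
        if 0.1 < d < radii[i] + radii[j] + slack and radii[i] > 0 and radii[j] > 0:
            mol.add_bond(i, j)


def _expand_candidates(config: JobConfig, ligand_spec: str) -> list[LigandCandidate]:
    proto = _load_ligand(ligand_spec, config.seed)
    cands = match_functional_groups(proto, config.ligand_groups)
    return [apply_split(c) if c.group.split else c for c in cands]


def enumerate_jobs(config: JobConfig) -> list[tuple[CoreSpec, str]]:
    """All (core, ligand spec) combinations the config implies.

    With ``multi_ligand`` each core yields a single combined job, labelled
    by the joined dummy→ligand map.
    """
    jobs = []
    for core in config.input_cores:
        if config.multi_ligand:
            label = "+".join(f"{d}:{l}" for d, l in config.multi_ligand)
            jobs.append((core, label))
        else:
            for lig in config.input_ligands:
                jobs.append((core, lig))
    return jobs


def _prepare_candidate(cand: LigandCandidate, config: JobConfig) -> LigandCandidate:
    cand.conformer = biased_conformer_search(cand)
    cand.ligand_vector = ligand_vector(cand.conformer, cand.edited_anchor)
    return cand


def _select_sites(core: Molecule, anchors: AnchorSet, config: JobConfig) -> AnchorSet:
    k = config.distribution.resolve_count(len(anchors))
    if k >= len(anchors):
        return anchors
    surface = None
    if config.distribution.distance == "over_surface":
        surface = build_surface_model(anchors)
    D = distance_matrix(anchors, surface, config.distribution.distance)
    return select_anchor_subset(
        anchors, D, k, mode=config.distribution.mode, seed=config.seed
    )


def _core_vectors_for(core: Molecule, anchors: AnchorSet, config: JobConfig) -> np.ndarray:
    return core_vectors(core, anchors, mode=config.alignment)


def _write_outputs(
    report: AssemblyReport, job_id: str, outdir: Path, fmt: str
) -> list[str]:
    outdir.mkdir(parents=True, exist_ok=True)
    stem = _sanitize(job_id)
    structure_path = outdir / f"{stem}.{fmt}"
    write_structure(report.structure, structure_path, fmt)
    sidecar = {
        "job": job_id,
        "n_atoms": len(report.structure),
        "net_formal_charge": report.net_formal_charge,
        "placements": [
            {
                "site_index": p.site_index,
                "azimuth_deg": round(np.degrees(p.azimuth), 3),
                "core_vector": [round(float(x), 6) for x in p.core_vector],
                "n_ligand_atoms": len(p.ligand),
            }
            for p in report.placements
        ],
        "clash_pairs": [[i, j, round(d, 4)] for i, j, d in report.clash_pairs],
        "warnings": report.warnings,
    }
    sidecar_path = outdir / f"{stem}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return [str(structure_path), str(sidecar_path)]


def _run_single(
    config: JobConfig,
    core: Molecule,
    core_spec: CoreSpec,
    cand: LigandCandidate,
    outdir: Path | None,
) -> JobResult:
    job_id = f"{core.name or 'core'}@{cand.label}"
    result = JobResult(job_id=job_id)
    t0 = time.perf_counter()
    anchors = find_anchors(core, core_spec.anchor or config.core_anchor)
    selected = _select_sites(core, anchors, config)
    result.timings["distribute"] = time.perf_counter() - t0
    result.log_lines.append(f"{job_id}: {len(selected)}/{len(anchors)} sites selected")

    t0 = time.perf_counter()
    _prepare_candidate(cand, config)
    result.timings["conformer"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    vecs = _core_vectors_for(core, selected, config)
    report = attach_all(
        core,
        selected,
        vecs,
        {site: cand for site in selected.indices},
        bond_to_scaffold=(config.alignment == "covalent"),
    )
    result.timings["attach"] = time.perf_counter() - t0
    result.report = report
    result.log_lines.extend(report.warnings)
    if outdir is not None:
        result.output_paths = _write_outputs(report, job_id, outdir, config.output_format)
    return result


def _run_multi_ligand(
    config: JobConfig, core: Molecule, core_spec: CoreSpec, outdir: Path | None
) -> JobResult:
    job_id = f"{core.name or 'core'}@" + "+".join(d for d, _ in config.multi_ligand)
    result = JobResult(job_id=job_id)
    t0 = time.perf_counter()
    assignments: dict[int, LigandCandidate] = {}
    all_sites: list[int] = []
    for dummy, lig_spec in config.multi_ligand:
        sites = find_anchors(core, dummy)
        cands = _expand_candidates(config, lig_spec)
        if not cands:
            raise ConfigError(f"ligand {lig_spec!r} matches no functional group")
        cand = _prepare_candidate(cands[0], config)
        for s in sites.indices:
            assignments[s] = cand
        all_sites.extend(sites.indices)
        result.log_lines.append(f"{job_id}: dummy {dummy} -> {lig_spec} at {len(sites)} sites")
    result.timings["conformer"] = time.perf_counter() - t0

    order = sorted(all_sites)
    anchors = AnchorSet(indices=tuple(order), positions=core.positions[order])
    t0 = time.perf_counter()
    vecs = _core_vectors_for(core, anchors, config)
    report = attach_all(
        core,
        anchors,
        vecs,
        assignments,
        bond_to_scaffold=(config.alignment == "covalent"),
    )
    result.timings["attach"] = time.perf_counter() - t0
    result.report = report
    result.log_lines.extend(report.warnings)
    if outdir is not None:
        result.output_paths = _write_outputs(report, job_id, outdir, config.output_format)
    return result


def run_pipeline(config: JobConfig, outdir: str | Path | None = None, write: bool = True) -> list[JobResult]:
    """Run every enumerated job; failures are isolated per job."""
    out = Path(outdir if outdir is not None else config.output_dir) if write else None
    results: list[JobResult] = []
    any_job = False
    for core_spec in config.input_cores:
        try:
            core = read_structure(core_spec.path)
        except Exception as exc:
            label = f"{core_spec.path}@*"
            results.append(JobResult(job_id=label, error=f"core read failed: {exc}"))
            continue
        if config.multi_ligand:
            any_job = True
            try:
                results.append(_run_multi_ligand(config, core, core_spec, out))
            except Exception as exc:
                results.append(JobResult(job_id=f"{core.name}@multi_ligand", error=str(exc)))
            continue
        for lig_spec in config.input_ligands:
            try:
                cands = _expand_candidates(config, lig_spec)
            except Exception as exc:
                any_job = True
                results.append(JobResult(job_id=f"{core.name}@{lig_spec}", error=str(exc)))
                continue
            if not cands:
                any_job = True
                results.append(
                    JobResult(
                        job_id=f"{core.name}@{lig_spec}",
                        error="no functional group matched the ligand",
                    )
                )
                continue
            for cand in cands:
                any_job = True
                try:
                    results.append(_run_single(config, core, core_spec, cand, out))
                except Exception as exc:
                    results.append(JobResult(job_id=f"{core.name}@{cand.label}", error=str(exc)))
    if not any_job:
        raise ConfigError("configuration produced zero runnable jobs")
    return results


def validate_and_report(config: JobConfig) -> list[str]:
    """Dry run: enumerate jobs and report anchor/ligand diagnostics without
    writing any structure."""
    lines: list[str] = []
    for core_spec in config.input_cores:
        p = Path(core_spec.path)
        if not p.exists():
            lines.append(f"ERROR core file missing: {core_spec.path}")
            continue
        try:
            core = read_structure(p)
        except Exception as exc:
            lines.append(f"ERROR core unreadable: {core_spec.path}: {exc}")
            continue
        if config.multi_ligand:
            for dummy, lig in config.multi_ligand:
                try:
                    n = len(find_anchors(core, dummy))
                    lines.append(f"core {core.name}: dummy {dummy} x{n} -> ligand {lig}")
                except ValueError as exc:
                    lines.append(f"ERROR core {core.name}: {exc}")
        else:
            anchor = core_spec.anchor or config.core_anchor
            try:
                n = len(find_anchors(core, anchor))
                k = config.distribution.resolve_count(n)
                lines.append(
                    f"core {core.name}: anchor {anchor!r} x{n}, selecting {k} "
                    f"({config.distribution.mode}, {config.distribution.distance})"
                )
            except (ValueError, IndexError) as exc:
                lines.append(f"ERROR core {core.name}: {exc}")
    for lig in config.input_ligands:
        p = Path(lig)
        if p.suffix.lower() in (".xyz", ".pdb") and not p.exists():
            lines.append(f"ERROR ligand file missing: {lig}")
            continue
        try:
            cands = _expand_candidates(config, lig)
            lines.append(f"ligand {lig}: {len(cands)} anchoring mode(s)")
        except Exception as exc:
            lines.append(f"ERROR ligand {lig}: {exc}")
    return lines
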