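"""End-to-end job orchestration.

``run_job`` executes read/validate -> CG build -> restraints -> REMC ->
filter -> consensus clustering -> evaluation outputs, writing a
self-describing result directory: 10 final C-alpha models, a cluster
report, per-replica trajectories with TSV sidecars, contact maps for the
final models, and a log file with everything needed to recreate the run.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .cg_model import CGChain, CGComplex, CGSnapshot, build_cg, peptide_chain, place_sc_from_trace
from .energy import (
    EnergyModel,
    default_energy_model,
    generate_restraints,
    restraints_to_tsv,
)
from .evaluate import (
    DEFAULT_CONTACT_CUTOFF,
    best_of_set,
    contact_map,
    contact_map_to_tsv,
)
from .postprocess import (
    ClusteringConfig,
    FilteredSet,
    FinalModelSet,
    cluster_report_tsv,
    consensus_cluster,
    filter_trajectory,
)
from .sampler import (
    DEFAULT_MACROCYCLES,
    MAX_MACROCYCLES,
    SimulationConfig,
    Trajectory,
    run_docking,
)
from .structures_io import (
    ReceptorStructure,
    STANDARD_RESIDUES,
    normalize_nonstandard,
    read_pdb,
    validate_peptide,
    validate_receptor,
    write_models_pdb,
)

__all__ = [
    "JobConfig",
    "JobResult",
    "JobConfigError",
    "run_job",
    "resubmit_with_exclusions",
    "evaluate_against_reference",
    "load_job_result",
    "parse_config_file",
]


class JobConfigError(ValueError):
    pass


@dataclass
class JobConfig:
    receptor_path: str
    peptide_sequence: str
    peptide_ss: str | None = None
    n_macrocycles: int = DEFAULT_MACROCYCLES
    seed: int = 0
    flexibility_marks: dict = field(default_factory=dict)   # residue ref -> moderate|full
    excluded_residues: list = field(default_factory=list)   # "unlikely to bind"
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    output_dir: str = "cgdock_out"
    project_name: str | None = None
    n_replicas: int = 10
    snapshots_per_macrocycle: int = 20
    moves_per_snapshot: int = 60
    write_trajectories: bool = True
    energy_model: EnergyModel | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.n_macrocycles <= MAX_MACROCYCLES:
            raise JobConfigError(
                f"n_macrocycles must be 1-{MAX_MACROCYCLES}, "
                f"got {self.n_macrocycles}"
            )
        for v in self.flexibility_marks.values():
            if v not in ("moderate", "full"):
                raise JobConfigError(f"invalid flexibility level {v!r}")
        if self.contact_cutoff <= 0:
            raise JobConfigError("contact_cutoff must be positive")


@dataclass
class JobResult:
    status: str  # done | failed_no_bound_states | error
    config: JobConfig
    output_dir: Path
    trajectories: list[Trajectory] | None = None
    filtered: FilteredSet | None = None
    final: FinalModelSet | None = None
    peptide_chain_id: str = "P"


def _resolve_residue(receptor: ReceptorStructure, ref) -> int:
    """Residue reference -> global index. Accepts a global int index or a
    'CHAIN:SEQID' / 'CHAIN:SEQID:ICODE' string in author numbering."""
    if isinstance(ref, (int, np.integer)):
        if not 0 <= int(ref) < receptor.n_residues:
            raise JobConfigError(f"residue index {ref} outside receptor")
        return int(ref)
    parts = str(ref).split(":")
    if len(parts) < 2:
        raise JobConfigError(f"bad residue reference {ref!r}")
    chain, seq = parts[0], int(parts[1])
    icode = parts[2] if len(parts) > 2 else ""
    try:
        return receptor.global_index(chain, seq, icode)
    except KeyError:
        raise JobConfigError(
            f"residue {ref!r} not present in the receptor"
        ) from None


def _model_contacts_excluded(snap: CGSnapshot, excluded: set[int],
                             cutoff: float) -> bool:
    cm = contact_map(snap.complex, cutoff=cutoff)
    return any(j in excluded for _, j, _ in cm.contacts)


def _write_sidecar(trajectories, dest) -> None:
    lines = ["replica\tmacrocycle\tsnapshot\ttemperature"
             "\te_total\te_binding\te_restraint\tbound"]
    for t in trajectories:
        for s in t.snapshots:
            lines.append(
                f"{s.replica_index}\t{s.macrocycle_index}\t{s.snapshot_index}"
                f"\t{s.temperature:.6f}\t{s.energy_total:.6f}"
                f"\t{s.energy_binding:.6f}\t{s.energy_restraint:.6f}"
                f"\t{int(s.bound)}"
            )
    Path(dest).write_text("\n".join(lines) + "\n")


def run_job(cfg: JobConfig) -> JobResult:
    """Execute a full docking job and write its result directory."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    receptor = normalize_nonstandard(validate_receptor(
        read_pdb(cfg.receptor_path)))
    peptide = validate_peptide(cfg.peptide_sequence, cfg.peptide_ss)
    rec_cg = build_cg(receptor)

    marks = {
        _resolve_residue(receptor, k): v
        for k, v in cfg.flexibility_marks.items()
    }
    excluded = {_resolve_residue(receptor, r) for r in cfg.excluded_residues}

    model = cfg.energy_model or default_energy_model()
    if excluded:
        model = replace(model, excluded_residues=frozenset(excluded))
    restraints = generate_restraints(rec_cg, marks, k_r=model.k_r,
                                     tolerance=model.restraint_tolerance)
    restraints_to_tsv(restraints, out / "restraints.tsv")

    sim_cfg = SimulationConfig(
        n_replicas=cfg.n_replicas,
        n_macrocycles=cfg.n_macrocycles,
        snapshots_per_macrocycle=cfg.snapshots_per_macrocycle,
        moves_per_snapshot=cfg.moves_per_snapshot,
        seed=cfg.seed,
    )
    trajectories = run_docking(rec_cg, peptide, restraints, model, sim_cfg)

    pep_chain_id = "P"
    if cfg.write_trajectories:
        traj_dir = out / "trajectories"
        traj_dir.mkdir(exist_ok=True)
        for t in trajectories:
            write_models_pdb(t.snapshots,
                             traj_dir / f"replica_{t.replica_index}.pdb")
    _write_sidecar(trajectories, out / "trajectory_energies.tsv")

    fs = FilteredSet()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for t in trajectories:
            fs.extend(filter_trajectory(t, cutoff=model.bound_cutoff))
    if excluded:
        keep = [
            i for i, m in enumerate(fs.models)
            if not _model_contacts_excluded(m, excluded, cfg.contact_cutoff)
        ]
        fs = FilteredSet([fs.models[i] for i in keep],
                         [fs.provenance[i] for i in keep])

    result = JobResult("done", cfg, out, trajectories=trajectories,
                       filtered=fs, peptide_chain_id=pep_chain_id)
    if len(fs) == 0:
        result.status = "failed_no_bound_states"
        _write_log(result, receptor, peptide, model)
        return result

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final = consensus_cluster(fs, ClusteringConfig(seed=cfg.seed))
    result.final = final

    models_dir = out / "final_models"
    models_dir.mkdir(exist_ok=True)
    for c, medoid in enumerate(final.medoids):
        write_models_pdb([medoid], models_dir / f"model_{c}.pdb")
        cm = contact_map(medoid.complex, cutoff=cfg.contact_cutoff)
        contact_map_to_tsv(cm, medoid.complex,
                           models_dir / f"model_{c}_contacts.tsv")
    cluster_report_tsv(final, out / "clusters.tsv")
    _write_log(result, receptor, peptide, model)
    return result


def _write_log(result: JobResult, receptor, peptide, model) -> None:
    cfg = result.config
    lines = [
        f"cgdock_version={__version__}",
        f"python={sys.version.split()[0]}",
        f"numpy={np.__version__}",
        f"status={result.status}",
        f"project={cfg.project_name or ''}",
        f"receptor={cfg.receptor_path}",
        f"receptor_chains={','.join(c.chain_id for c in receptor.chains)}",
        f"receptor_residues={receptor.n_residues}",
        f"peptide={peptide.sequence}",
        f"peptide_ss={peptide.ss_states}",
        f"peptide_chain_id={result.peptide_chain_id}",
        f"macrocycles={cfg.n_macrocycles}",
        f"replicas={cfg.n_replicas}",
        f"snapshots_per_macrocycle={cfg.snapshots_per_macrocycle}",
        f"moves_per_snapshot={cfg.moves_per_snapshot}",
        f"seed={cfg.seed}",
        f"contact_cutoff={cfg.contact_cutoff}",
        f"bound_cutoff={model.bound_cutoff}",
        f"k_r={model.k_r}",
        f"flexible={';'.join(f'{k}:{v}' for k, v in cfg.flexibility_marks.items())}",
        f"excluded={';'.join(str(r) for r in cfg.excluded_residues)}",
    ]
    (result.output_dir / "job.log").write_text("\n".join(lines) + "\n")


def parse_config_file(path) -> dict:
    """Flat key=value job configuration; '#' starts a comment line."""
    kv = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise JobConfigError(f"bad config line: {raw!r}")
        key, val = line.split("=", 1)
        kv[key.strip()] = val.strip()
    out = {}
    if "receptor" in kv:
        out["receptor_path"] = kv["receptor"]
    if "peptide" in kv:
        out["peptide_sequence"] = kv["peptide"]
    if kv.get("ss"):
        out["peptide_ss"] = kv["ss"]
    if "macrocycles" in kv:
        out["n_macrocycles"] = int(kv["macrocycles"])
    if "seed" in kv:
        out["seed"] = int(kv["seed"])
    if "contact_cutoff" in kv:
        out["contact_cutoff"] = float(kv["contact_cutoff"])
    if kv.get("out"):
        out["output_dir"] = kv["out"]
    if kv.get("project"):
        out["project_name"] = kv["project"]
    if kv.get("flexible"):
        marks = {}
        for item in kv["flexible"].split(";"):
            *res, level = item.split(":")
            marks[":".join(res)] = level
        out["flexibility_marks"] = marks
    if kv.get("excluded"):
        out["excluded_residues"] = kv["excluded"].split(";")
    return out


def load_job_result(jobdir) -> JobResult:
    """Reconstruct a JobResult from a written result directory.

    Coordinates come from the C-alpha model files (pseudo side chains are
    rebuilt from the trace); energies come from the cluster report.
    """
    jobdir = Path(jobdir)
    log = dict(
        line.split("=", 1)
        for line in (jobdir / "job.log").read_text().splitlines()
        if "=" in line
    )
    cfg = JobConfig(
        receptor_path=log["receptor"],
        peptide_sequence=log["peptide"],
        peptide_ss=log["peptide_ss"],
        n_macrocycles=int(log["macrocycles"]),
        seed=int(log["seed"]),
        contact_cutoff=float(log["contact_cutoff"]),
        output_dir=str(jobdir),
        project_name=log.get("project") or None,
    )
    result = JobResult(log["status"], cfg, jobdir,
                       peptide_chain_id=log["peptide_chain_id"])
    models_dir = jobdir / "final_models"
    if result.status == "done" and models_dir.is_dir():
        medoids = []
        report = (jobdir / "clusters.tsv").read_text().splitlines()[1:]
        for c, row in enumerate(report):
            cols = row.split("\t")
            cplx = _read_ca_complex(models_dir / f"model_{c}.pdb",
                                    log["peptide_chain_id"],
                                    log["peptide"], log["peptide_ss"])
            medoids.append(CGSnapshot(
                complex=cplx, replica_index=int(cols[4]),
                macrocycle_index=0, snapshot_index=int(cols[5]),
                temperature=0.0, energy_total=float(cols[6]),
                energy_binding=float(cols[6]), energy_restraint=0.0,
            ))
        result.final = FinalModelSet(
            medoids=medoids,
            medoid_indices=list(range(len(medoids))),
            assignment=np.zeros(len(medoids), dtype=int),
            cluster_members=[[c] for c in range(len(medoids))],
            density=[float(r.split("\t")[2]) for r in report],
            diversity=[float(r.split("\t")[3]) for r in report],
            provenance=[(int(r.split("\t")[4]), int(r.split("\t")[5]))
                        for r in report],
        )
    return result


def _read_ca_complex(path, peptide_chain_id: str, pep_seq: str,
                     pep_ss: str) -> CGComplex:
    s = read_pdb(Path(path).read_text())
    rec_ca, rec_seq, rec_chain_ids, rec_author, rec_chain_idx = \
        [], [], [], [], []
    pep_ca = []
    for ci, chain in enumerate(s.chains):
        for res in chain.residues:
            if chain.chain_id == peptide_chain_id:
                pep_ca.append(res.atoms["CA"])
            else:
                rec_ca.append(res.atoms["CA"])
                from .structures_io import STANDARD_RESIDUES
                rec_seq.append(STANDARD_RESIDUES.get(res.name, "X"))
                rec_chain_ids.append(chain.chain_id)
                rec_author.append(res.author_id)
                rec_chain_idx.append(ci)
    rec_ca = np.asarray(rec_ca)
    rec = CGChain(
        ca=rec_ca, sc=place_sc_from_trace(rec_ca, "".join(rec_seq)),
        sequence="".join(rec_seq), ss="C" * len(rec_seq),
        chain_index=np.asarray(rec_chain_idx),
        chain_ids=rec_chain_ids, author_ids=rec_author,
    )
    pep = peptide_chain(validate_peptide(pep_seq, pep_ss),
                        np.asarray(pep_ca))
    return CGComplex(rec, pep)


def resubmit_with_exclusions(prev: JobResult, excluded_model_ids,
                             cutoff: float | None = None) -> JobConfig:
    """Derive a resubmission config excluding the binding modes of the
    marked final models.

    Receptor residues contacting the marked models' peptides (contact map
    at the job's cutoff) are added to the unlikely-to-bind list.
    """
    if prev.final is None:
        raise ValueError("previous job has no final models")
    cutoff = cutoff if cutoff is not None else prev.config.contact_cutoff
    new_excluded = set()
    for mid in excluded_model_ids:
        cm = contact_map(prev.final.medoids[mid].complex, cutoff=cutoff)
        residues = {j for _, j, _ in cm.contacts}
        if not residues:
            warnings.warn(f"model {mid} has no receptor contacts",
                          stacklevel=2)
        new_excluded |= residues
    merged = sorted(
        {str(r) for r in prev.config.excluded_residues}
        | {str(r) for r in new_excluded}
    , key=str)
    return replace(
        prev.config,
        excluded_residues=[int(r) if r.lstrip("-").isdigit() else r
                           for r in merged],
        output_dir=str(Path(prev.config.output_dir).with_name(
            Path(prev.config.output_dir).name + "_resubmit")),
    )


def evaluate_against_reference(result: JobResult, reference) -> dict:
    """Benchmark one job against a reference complex.

    ``reference`` is a CGComplex or a PDB path containing the receptor
    plus the peptide as its own chain (matched by sequence). Reports the
    best ligand RMSD and quality class over all snapshots and over the 10
    final models, like one row of a benchmark table.
    """
    if not isinstance(reference, CGComplex):
        ref_struct = read_pdb(str(reference))
        pep_seq = result.config.peptide_sequence
        pep_chains = [
            c for c in ref_struct.chains
            if "".join(STANDARD_RESIDUES.get(r.name, "X")
                       for r in c.residues) == pep_seq
        ]
        if len(pep_chains) != 1:
            raise ValueError(
                "reference must contain exactly one chain matching the "
                "peptide sequence"
            )
        pep_ca = np.asarray([r.atoms["CA"] for r in pep_chains[0].residues])
        rec_struct = ReceptorStructure(
            [c for c in ref_struct.chains if c is not pep_chains[0]]
        )
        reference = CGComplex(
            build_cg(rec_struct),
            peptide_chain(validate_peptide(pep_seq), pep_ca),
        )

    row = {"project": result.config.project_name or "",
           "seed": result.config.seed, "status": result.status}
    if result.status != "done" or result.final is None:
        row.update(best_all=None, class_all="NA",
                   best_top10=None, class_top10="NA")
        return row
    if result.trajectories is not None:
        snaps = [s for t in result.trajectories for s in t.snapshots]
        best_all, _, qc_all = best_of_set(snaps, reference)
        row["best_all"] = best_all
        row["class_all"] = qc_all.label
    else:
        row["best_all"] = None
        row["class_all"] = "NA"
    best10, _, qc10 = best_of_set(result.final.medoids, reference)
    row["best_top10"] = best10
    row["class_top10"] = qc10.label
    return row
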