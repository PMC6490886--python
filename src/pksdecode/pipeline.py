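"""End-to-end orchestration: roles -> domains -> assembly -> product -> sugar.

Produces a single machine-readable run report (JSON) that fully determines a
rerun: input digests, config, seed and per-stage outputs.  Warnings (e.g. a
discordant AT motif pair) are reported, never fatal; stage errors abort with
a partial report carrying the failure record.
"""

from __future__ import annotations

import hashlib
import json
import platform
import sys
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

from . import __version__
from . import assembly_line as al
from . import cluster_io as cio
from . import product_builder as pb
from . import sugar_pathway as sp
from .domain_grammar import classify_protein, load_profiles

__all__ = ["RunReport", "run_all", "StageError"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunReport:
    inputs: dict
    seed: Optional[int]
    versions: dict
    stages: dict
    discrepancies: list
    warnings: list
    failure: Optional[dict] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _digest(path: Optional[Path], packaged: Optional[str] = None) -> dict:
    if path is not None:
        data = Path(path).read_bytes()
        name = str(path)
    else:
        data = resources.files("pksdecode.data").joinpath(packaged).read_bytes()
        name = f"packaged:{packaged}"
    return {"source": name, "sha256": hashlib.sha256(data).hexdigest()}


def _versions() -> dict:
    import Bio
    import numpy
    import pandas

    return {
        "pksdecode": __version__,
        "python": platform.python_version(),
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "biopython": Bio.__version__,
    }


def run_all(
    cluster: Optional[str | Path] = None,
    calls: Optional[str | Path] = None,
    fasta: Optional[str | Path] = None,
    target: Optional[str | Path] = None,
    tailoring: Optional[str | Path] = None,
    rules: Optional[str | Path] = None,
    profiles_path: Optional[str | Path] = None,
    out: Optional[str | Path] = None,
    seed: Optional[int] = None,
    branch: str = "canonical",
    cluster_format: str = "tsv",
) -> RunReport:
    """Run the full pipeline; ``None`` inputs fall back to packaged fixtures.

    Domain calls come either from a call-table JSON (``calls``, used for the
    packaged transcription of the cluster's multienzymes) or from scanning a
    protein FASTA (``fasta``).  All inputs are validated up front so a
    missing file fails cleanly before anything is written.
    """
    if calls is not None and fasta is not None:
        raise ValueError("give either a call-table JSON or a FASTA, not both")
    for p in (cluster, calls, fasta, target, tailoring, rules, profiles_path):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(p)

    inputs = {
        "cluster": _digest(cluster, "ossamycin_table1.tsv"),
        "calls": _digest(calls, "ossamycin_calls.json") if fasta is None else None,
        "fasta": _digest(fasta) if fasta is not None else None,
        "target": _digest(target, "ossamycin_target.yaml"),
        "tailoring": _digest(tailoring, "ossamycin_tailoring.yaml"),
        "profiles": _digest(profiles_path, "domain_profiles.yaml"),
        "rules": _digest(rules, "role_rules.yaml"),
    }
    report = RunReport(
        inputs=inputs, seed=seed, versions=_versions(),
        stages={}, discrepancies=[], warnings=[],
    )
    profiles = load_profiles(profiles_path)

    def _finish_error(stage: str, exc: Exception) -> StageError:
        report.failure = {"stage": stage, "error": f"{type(exc).__name__}: {exc}"}
        _write(report, out)
        return StageError(stage, exc)

    # ---- roles
    try:
        annotation = (
            cio.ossamycin_cluster() if cluster is None
            else cio.load_cluster_table(cluster, cluster_format)
        )
        role_rules = cio.load_role_rules(rules)
        assignments = cio.classify_roles(annotation, role_rules)
        census = cio.role_census(assignments)
        sugar_gene_count = sum(census.get(r, 0) for r in cio.SUGAR_ROLES)
        report.stages["roles"] = {
            "n_genes": len(annotation),
            "census": census,
            "sugar_pathway_genes": sugar_gene_count,
            "assignments": [asdict(a) for a in assignments],
        }
    except Exception as exc:
        raise _finish_error("roles", exc)

    # ---- domain calls
    try:
        if fasta is not None:
            from Bio import SeqIO

            tables = {
                rec.id: classify_protein(rec.id, str(rec.seq), profiles)
                for rec in SeqIO.parse(str(fasta), "fasta")
            }
        else:
            tables = al.load_call_tables(calls, profiles)
        domain_summary = {
            pid: [
                {
                    "type": c.domain_type,
                    "interval": c.interval,
                    "partial": c.partial,
                    "call": asdict(c.call) if c.call is not None else None,
                }
                for c in calls_
            ]
            for pid, calls_ in tables.items()
        }
        for pid, calls_ in tables.items():
            for c in calls_:
                conf = getattr(c.call, "confidence", "")
                if isinstance(conf, str) and conf.startswith("discordant"):
                    report.warnings.append(f"{pid}: discordant AT motifs ({conf})")
                for flag in getattr(c.call, "flags", ()):
                    report.warnings.append(f"{pid}: {flag}")
        report.stages["domains"] = {"proteins": domain_summary}
    except Exception as exc:
        raise _finish_error("domains", exc)

    # ---- assembly
    try:
        backbone = al.load_target(target)
        table = al.build_modules(tables)
        report.warnings.extend(table.warnings)
        ordering = al.order_multienzymes(table, backbone)
        assignment = ordering.assignment
        report.discrepancies.extend(assignment.discrepancies)
        report.stages["assembly"] = {
            "protein_order": list(ordering.order),
            "tied_orders": [list(o) for o in ordering.tied_orders],
            "n_extension_modules": len(table.extension_modules),
            "modules_per_protein": table.per_protein_counts,
            "n_cycles": backbone.n_cycles,
            "score": ordering.score,
            "iteration": {
                "iterated_modules": list(assignment.iterated_modules),
                "stutter_cycles": list(assignment.stutter_cycles),
                "cycle_to_module": {str(k): v for k, v in assignment.cycle_to_module.items()},
                "ties": [list(t) for t in assignment.ties],
            },
        }
    except Exception as exc:
        raise _finish_error("assembly", exc)

    # ---- product
    try:
        ordered_modules = [
            m for pid in ordering.order for m in table.modules_by_protein.get(pid, ())
            if not m.malformed
        ]
        chain = pb.assemble_chain(table.loading, assignment, ordered_modules, backbone)
        mac = pb.macrolactonize(chain, backbone.cyclization_carbon)
        events = pb.load_tailoring_events(tailoring)
        tailored = pb.apply_tailoring(mac, events)
        mass = pb.compute_mass(tailored)
        smiles = pb.export_structure(tailored)

        no_iter = None
        if assignment.stutter_cycles:
            shorter = al.suppress_iteration(backbone, assignment)
            ident = al.IterationAssignment(
                cycle_to_module={e.cycle: ordered_modules[e.cycle - 1].module_id
                                 for e in shorter.extensions},
                iterated_modules=(), discrepancies=assignment.discrepancies,
                score=0.0, stutter_cycles=(),
            )
            chain14 = pb.assemble_chain(table.loading, ident, ordered_modules, shorter)
            mac14 = pb.macrolactonize(chain14, shorter.cyclization_carbon)
            no_iter = {
                "ring_size": mac14.ring_size,
                "cyclization_carbon": shorter.cyclization_carbon,
                "backbone_carbons": chain14.backbone_carbon_count,
            }
        from .formulas import hill_notation

        report.stages["product"] = {
            "backbone_carbons": chain.backbone_carbon_count,
            "ring_size": mac.ring_size,
            "cyclization_carbon": mac.lactone_oxygen_carbon,
            "formula": hill_notation(mass.formula),
            "monoisotopic_mass": mass.monoisotopic_mass,
            "mh_plus": mass.mh_plus,
            "n_tailoring_events": len(tailored.tailoring),
            "smiles": smiles,
            "without_iteration": no_iter,
            "units": [
                {"cycle": u.cycle_index, "alpha": u.alpha_substituent,
                 "beta_state": u.beta_state, "alpha_stereo": u.alpha_stereo,
                 "beta_stereo": u.beta_stereo, "carbons": list(u.carbons),
                 "sidechain_carbons": list(u.sidechain_carbons),
                 "module": u.module_id}
                for u in chain.units
            ],
        }
    except Exception as exc:
        raise _finish_error("product", exc)

    # ---- sugar pathway
    try:
        graph = sp.reconstruct_pathway(assignments, branch)
        residue = sp.residue_formula(graph)
        from .formulas import hill_notation, monoisotopic_mass

        report.stages["sugar"] = {
            "branch": graph.branch,
            "missing_roles": list(graph.missing_roles),
            "steps": [asdict(s) for s in graph.steps],
            "residue_formula": hill_notation(residue),
            "residue_monoisotopic": round(monoisotopic_mass(residue), 4),
        }
    except Exception as exc:
        raise _finish_error("sugar", exc)

    _write(report, out)
    return report


def _write(report: RunReport, out: Optional[str | Path]) -> None:
    if out is None:
        return
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
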