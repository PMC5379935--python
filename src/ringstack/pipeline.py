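"""End-to-end analysis orchestration.

Runs the full quaternary-structure workflow on a double-ring assembly
(and optionally a nucleotide-bound complex): subunit RMSD matrix and
clustering, inter-ring stack geometry, buried surface area, elastic-
network modes with the counter-rotation overlap, nucleotide
conformation and contact tables, and the Matthews block when a unit
cell is present.  Results are returned as one nested dict and written
as machine-readable files (JSON summary, CSV/TSV tables, Newick tree);
every stage failure is recorded in the report rather than aborting the
rest, and a failed stage makes ``run_full_analysis`` raise at the end
unless ``allow_partial`` is set.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import anm as anm_mod
from . import crystal_calc, na_geometry, ring_geometry, sasa, superpose_cluster
from .structure_io import Selection, StructureModel, read_structure, select_atoms

__all__ = ["AnalysisConfig", "PipelineError", "run_full_analysis"]

REPORT_SCHEMA_VERSION = "1.0"


class PipelineError(RuntimeError):
    """One or more pipeline stages failed."""


@dataclass
class AnalysisConfig:
    """Declarative configuration for :func:`run_full_analysis`.

    ``structure`` may be a path to a PDB file or an in-memory
    :class:`StructureModel` holding the double ring.  ``ring_a_chains`` /
    ``ring_b_chains`` name the two rings; analyses marked optional are
    skipped when their inputs are absent.
    """

    structure: object  # path or StructureModel
    ring_a_chains: tuple = ("A", "B", "C", "D", "E", "F")
    ring_b_chains: tuple = ("G", "H", "I", "J", "K", "L")
    selection_preset: str = "main-chain"
    linkage: str = "ward"
    n_fold: int = 6
    anm_cutoff: float = 15.0
    anm_gamma: float = 1.0
    anm_modes: int = 20
    sasa_ensemble: tuple = sasa.DEFAULT_ENSEMBLE
    rna_chains: tuple = ()
    contact_cutoff: float = 3.6
    matthews_z: int | None = None
    matthews_mass: float | None = None
    seed: int = 0
    output_dir: object | None = None

    def load_structure(self) -> StructureModel:
        if isinstance(self.structure, StructureModel):
            return self.structure
        return read_structure(self.structure)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _log(msg: str) -> None:
    print(f"[ringstack] {msg}", file=sys.stderr)


def run_full_analysis(config: AnalysisConfig, allow_partial: bool = False) -> dict:
    """Execute all stages and return the structured report.

    With ``config.output_dir`` set, machine-readable files are written
    there (summary.json, rmsd_matrix.csv, tree.newick, assignments.tsv,
    anm_eigenvalues.csv, contacts.tsv, nucleotides.csv as applicable).
    """
    model = config.load_structure()
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "parameters": {
            "selection_preset": config.selection_preset,
            "linkage": config.linkage,
            "n_fold": config.n_fold,
            "anm_cutoff": config.anm_cutoff,
            "anm_gamma": config.anm_gamma,
            "anm_modes": config.anm_modes,
            "sasa_ensemble": [list(s) for s in config.sasa_ensemble],
            "contact_cutoff": config.contact_cutoff,
        },
        "stages": {},
        "errors": {},
    }
    chains_a = tuple(config.ring_a_chains)
    chains_b = tuple(config.ring_b_chains)
    all_chains = chains_a + chains_b
    sel = Selection(preset=config.selection_preset, het=False)

    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        def wrap(fn):
            _log(f"stage {name}")
            try:
                report["stages"][name] = fn()
            except Exception as exc:  # noqa: BLE001 — partial reports are the contract
                _log(f"stage {name} FAILED: {exc}")
                report["errors"][name] = f"{type(exc).__name__}: {exc}"
        return wrap

    @stage("rmsd_clustering")
    def _():
        subunits = [select_atoms(model, Selection(chains=(c,), het=False)) for c in all_chains]
        dm = superpose_cluster.rmsd_matrix(subunits, sel, labels=list(all_chains))
        tree = superpose_cluster.hierarchical_cluster(dm, config.linkage)
        groups = superpose_cluster.cut_tree(tree, 2)
        if outdir:
            pd.DataFrame(dm.d, index=dm.labels, columns=dm.labels).to_csv(outdir / "rmsd_matrix.csv",
                                                                          float_format="%.6f")
            (outdir / "tree.newick").write_text(tree.to_newick() + "\n")
            pd.DataFrame(sorted(groups.items()), columns=["chain", "cluster"]).to_csv(
                outdir / "assignments.tsv", sep="\t", index=False)
        return {
            "labels": dm.labels,
            "mean_pairwise_rmsd": dm.mean_offdiag(),
            "max_pairwise_rmsd": float(dm.d.max()),
            "linkage": config.linkage,
            "k2_assignment": groups,
        }

    @stage("stack_geometry")
    def _():
        ring_a = select_atoms(model, Selection(chains=chains_a, het=False))
        ring_b = select_atoms(model, Selection(chains=chains_b, het=False))
        geo = ring_geometry.stack_geometry(ring_a, ring_b, config.n_fold)
        return {
            "delta_deg": geo.delta_deg,
            "tilt_deg": geo.tilt_deg,
            "rise_A": geo.rise,
            "plane_rms_a": geo.plane_a.rms_residual,
            "plane_rms_b": geo.plane_b.rms_residual,
        }

    @stage("buried_surface_area")
    def _():
        res = sasa.buried_surface_area(model, Selection(chains=chains_a),
                                       Selection(chains=chains_b), config.sasa_ensemble)
        return {
            "bsa_mean_A2": res.ensemble_mean,
            "bsa_sd_A2": res.ensemble_sd,
            "ensemble_values": res.ensemble_values,
            "asa_a": res.asa_a, "asa_b": res.asa_b, "asa_ab": res.asa_ab,
        }

    @stage("anm")
    def _():
        net = anm_mod.build_anm(model, gamma=config.anm_gamma, cutoff=config.anm_cutoff)
        idx_a = [i for i, c in enumerate(net.node_chain_ids) if c in chains_a]
        idx_b = [i for i, c in enumerate(net.node_chain_ids) if c in chains_b]
        lam, _vec = net.nontrivial()
        out = {
            "n_nodes": len(net.nodes),
            "n_zero_modes": net.n_zero_modes,
            "n_nontrivial_modes": int(len(lam)),
            "softest_eigenvalues": [float(x) for x in lam[: config.anm_modes]],
        }
        if idx_a and idx_b and len(idx_a) + len(idx_b) == len(net.nodes):
            axis = ring_geometry.best_fit_plane(net.nodes[idx_a]).normal
            rows = anm_mod.ring_rotation_overlap(net, idx_a, idx_b, axis, k=config.anm_modes)
            best = max(rows, key=lambda r: r["overlap"])
            out["counter_rotation"] = {"best_mode": best["mode"], "best_overlap": best["overlap"]}
        if outdir:
            pd.DataFrame({"mode": np.arange(1, len(lam) + 1), "eigenvalue": lam}).to_csv(
                outdir / "anm_eigenvalues.csv", index=False, float_format="%.8g")
        return out

    if config.rna_chains:
        @stage("nucleotides")
        def _():
            rows = []
            for chain_id in config.rna_chains:
                nt_model = select_atoms(model, Selection(chains=(chain_id,)))
                for _, res_seq, _, res_name, _atoms in nt_model.residues():
                    view = na_geometry.residue_view(model, chain_id, res_seq)
                    try:
                        chi = na_geometry.glycosidic_chi(view)
                        pucker = na_geometry.pseudorotation(view)
                    except ValueError:
                        continue
                    rows.append({
                        "chain": chain_id, "res_seq": res_seq, "res_name": res_name,
                        "chi_deg": chi.chi, "conformer": chi.conformer,
                        "P_deg": pucker.P, "nu_max_deg": pucker.nu_max,
                        "pucker_class": pucker.pucker_class, "hemisphere": pucker.hemisphere,
                    })
            if outdir and rows:
                pd.DataFrame(rows).to_csv(outdir / "nucleotides.csv", index=False,
                                          float_format="%.3f")
            return rows

        @stage("contacts")
        def _():
            recs = na_geometry.contact_table(
                model,
                Selection(chains=all_chains, het=False),
                Selection(chains=tuple(config.rna_chains)),
                config.contact_cutoff,
            )
            rows = [{
                "chain_a": r.atom_a[0], "res_a": r.atom_a[1], "name_a": r.atom_a[3],
                "chain_b": r.atom_b[0], "res_b": r.atom_b[1], "name_b": r.atom_b[3],
                "distance_A": round(r.distance, 3), "class": r.contact_class,
            } for r in recs]
            if outdir and rows:
                pd.DataFrame(rows).to_csv(outdir / "contacts.tsv", sep="\t", index=False)
            return rows

    if model.cell is not None and config.matthews_z and config.matthews_mass:
        @stage("matthews")
        def _():
            res = crystal_calc.matthews(model.cell, config.matthews_z, config.matthews_mass)
            return {"cell_volume_A3": res.cell_volume, "v_m": res.v_m,
                    "solvent_percent": 100.0 * res.solvent_fraction}

    if outdir:
        (outdir / "summary.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=_json_default) + "\n")
    if report["errors"] and not allow_partial:
        raise PipelineError(f"stages failed: {', '.join(report['errors'])}")
    return report
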