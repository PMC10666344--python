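"""Scenario orchestration: full pipeline runs and scenario comparison.

A scenario = dataset + pedigree strategy (full or generation-truncated) +
MAF threshold + solver options.  ``run_scenario`` executes
load -> truncate -> genetic groups -> A^-1 -> MAF filter -> MME -> PCG ->
trajectory statistics and (optionally) writes a self-describing output
directory; ``compare_scenarios`` assembles cross-scenario EBV correlations,
the top-K bull ranking comparison and the condition-number report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .pedigree import (Pedigree, load_pedigree_csv, truncate_pedigree,
                       assign_genetic_groups, inbreeding_coefficients,
                       build_A_inverse, impute_marker_covariates)
from .genotypes import (GenotypeMatrix, load_genotypes_tsv, maf_filter,
                        center_genotypes, marker_scale)
from .model import (VarianceParameters, observations_from_frames, build_design,
                    build_residual_weights, build_mme, reconstruct_ebv,
                    group_solutions, load_phenotypes_csv, load_drp_csv,
                    MMESystem)
from .pcg import PCGOptions, PCGTrajectory, SpectralEstimates, pcg_solve, \
    build_preconditioners, estimate_spectrum
from .convergence_analysis import (partition_animals, trajectory_stats,
                                   scenario_correlations, top_k_comparison,
                                   condition_number_report, AnimalGroupPartition,
                                   ScenarioComparison, AnalysisError)
from .synthetic_data import SimulatedDataset

log = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ScenarioSpec:
    dataset: Union[str, Path, SimulatedDataset]
    max_generations: Optional[int] = None      # None = FULL
    maf_threshold: Optional[float] = None
    pcg: PCGOptions = field(default_factory=lambda: PCGOptions(
        second_level="deflation"))
    vp: VarianceParameters = field(default_factory=VarianceParameters)
    out_dir: Optional[Union[str, Path]] = None
    seed: int = 0
    name: str = "scenario"


@dataclass
class ScenarioRun:
    spec: ScenarioSpec
    pedigree: Pedigree
    system: MMESystem
    trajectory: PCGTrajectory
    spectral: SpectralEstimates
    ebv: pd.Series                  # indexed by animal_id
    groups_solution: np.ndarray
    partition: AnimalGroupPartition
    stats: pd.DataFrame
    n_snps_used: int
    manifest: dict


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **kw)
            except Exception as e:
                raise PipelineError(name, e) from e
            log.info("stage %s: %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def _load_dataset(dataset):
    if isinstance(dataset, SimulatedDataset):
        return (dataset.pedigree, dataset.genotypes, dataset.phenotypes,
                dataset.drp)
    d = Path(dataset)
    ped = load_pedigree_csv(d / "pedigree.csv")
    gm = load_genotypes_tsv(d / "genotypes.tsv")
    pheno = load_phenotypes_csv(d / "phenotypes.csv")
    drp = load_drp_csv(d / "drp.csv")
    return ped, gm, pheno, drp


def run_scenario(spec: ScenarioSpec) -> ScenarioRun:
    """Execute one evaluation scenario end to end (deterministic)."""
    timings = {}

    def timed(name, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kw)
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(name, e) from e
        timings[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %-12s %6.2fs", name, timings[name])
        return out

    ped, gm, pheno, drp = timed("load", _load_dataset, spec.dataset)
    if spec.max_generations is not None:
        ped = timed("truncate", truncate_pedigree, ped, spec.max_generations)
    groups = timed("groups", assign_genetic_groups, ped)
    F = timed("inbreeding", inbreeding_coefficients, ped)
    structures = timed("A_inverse", build_A_inverse, ped, groups, F)

    def prep_genotypes():
        g = gm
        if spec.maf_threshold is not None:
            g = maf_filter(g, spec.maf_threshold)
        sc = marker_scale(g.p, spec.vp.k, spec.vp.sigma_a2) if g.n_snps else None
        Z = center_genotypes(g)
        # align rows to the pedigree's genotyped block
        row = {a: i for i, a in enumerate(g.animal_ids)}
        geno_ids = ped.ids[structures.geno_idx]
        missing = [a for a in geno_ids if a not in row]
        if missing:
            raise ValueError(
                f"{len(missing)} genotype-flagged animals missing from the "
                f"genotype matrix (first: {missing[0]!r})")
        Z2 = Z[[row[a] for a in geno_ids]]
        return g, sc, Z2

    gm_used, scale, Z2 = timed("genotypes", prep_genotypes)
    T1 = timed("impute", impute_marker_covariates, structures, Z2)

    def assemble():
        obs = observations_from_frames(pheno, drp, ped)
        X, rec_anim, names = build_design(obs, ped)
        rw = build_residual_weights(obs, spec.vp)
        y = obs.records["value"].to_numpy(dtype=float)
        return build_mme(X, rec_anim, y, rw, Z2, T1, structures, spec.vp,
                         scale, fixed_names=names)

    system = timed("mme", assemble)

    def solve():
        M, basis = build_preconditioners(system, spec.pcg)
        return pcg_solve(system, M, spec.pcg, deflation_basis=basis)

    trajectory = timed("pcg", solve)
    spectral = trajectory.spectral or estimate_spectrum(trajectory)
    partition = timed("partition", partition_animals, ped)
    stats = timed("trajectory_stats", trajectory_stats, trajectory, system,
                  partition, ped)
    ebv = pd.Series(reconstruct_ebv(trajectory.x_final, system),
                    index=pd.Index(ped.ids, name="animal_id"), name="ebv")
    gsol = group_solutions(trajectory.x_final, system)

    manifest = {
        "name": spec.name,
        "version": __version__,
        "seed": spec.seed,
        "max_generations": spec.max_generations,
        "maf_threshold": spec.maf_threshold,
        "stop_cd": spec.pcg.stop_cd,
        "second_level": spec.pcg.second_level,
        "n_animals": ped.n_animals,
        "n_genotyped": int(len(structures.geno_idx)),
        "n_snps_used": gm_used.n_snps,
        "n_genetic_groups": structures.n_groups,
        "n_records": int(system.Wmat.shape[0]),
        "n_unknowns": system.n_unknowns,
        "iterations": trajectory.final_iteration,
        "converged": bool(trajectory.converged),
        "kappa": spectral.kappa,
        "timings_s": timings,
    }
    run = ScenarioRun(spec=spec, pedigree=ped, system=system,
                      trajectory=trajectory, spectral=spectral, ebv=ebv,
                      groups_solution=gsol, partition=partition, stats=stats,
                      n_snps_used=gm_used.n_snps, manifest=manifest)
    if spec.out_dir is not None:
        write_run(run, spec.out_dir)
    return run


def write_run(run: ScenarioRun, out_dir) -> None:
    """Write a self-describing scenario output directory."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    ped = run.pedigree
    sol = pd.DataFrame({
        "animal_id": ped.ids,
        "sex": ped.df["sex"],
        "genotyped": ped.df["genotyped"].astype(int),
        "phenotyped": ped.df["phenotyped"].astype(int),
        "ebv": run.ebv.to_numpy(),
    })
    sol.to_csv(d / "solutions.csv", index=False, float_format=FLOAT_FMT)
    traj = run.trajectory
    pd.DataFrame({
        "iteration": np.arange(1, traj.final_iteration + 1),
        "CK": traj.ck, "CM": traj.cm, "CD": traj.cd,
        "alpha": traj.alphas, "beta": traj.betas,
    }).to_csv(d / "trajectory.csv", index=False, float_format=FLOAT_FMT)
    run.stats.to_csv(d / "trajectory_stats.csv", index=False,
                     float_format=FLOAT_FMT)
    pd.DataFrame({"group": np.arange(len(run.groups_solution)),
                  "solution": run.groups_solution}).to_csv(
        d / "genetic_groups.csv", index=False, float_format=FLOAT_FMT)
    with open(d / "spectral.json", "w") as fh:
        json.dump({"mu1": run.spectral.mu1, "mu_max": run.spectral.mu_max,
                   "kappa": run.spectral.kappa}, fh, indent=2, sort_keys=True)
    # timings are wall-clock and would break byte-identical reruns
    manifest = {k: v for k, v in run.manifest.items() if k != "timings_s"}
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def compare_scenarios(run_a: ScenarioRun, run_b: ScenarioRun,
                      K: int = 50, out_dir=None) -> ScenarioComparison:
    """Cross-scenario report: correlations, top-K bulls, condition numbers.

    The animal-group partition of ``run_a`` (the reference, e.g. FULL)
    classifies animals; correlations are over the animals common to both.
    """
    common = run_a.ebv.index.intersection(run_b.ebv.index)
    if len(common) == 0:
        raise AnalysisError("scenarios share no animals")
    corr = scenario_correlations(run_a.ebv, run_b.ebv, run_a.partition)
    bulls = run_a.pedigree.df.loc[run_a.pedigree.df["sex"] == "M", "animal_id"]
    bulls = pd.Index(bulls).intersection(common)
    overlap, rank_corr, non_overlap = top_k_comparison(
        run_a.ebv, run_b.ebv, bulls, K=K)
    cond = condition_number_report(run_a.trajectory, run_a.spectral,
                                   run_b.trajectory, run_b.spectral)
    comp = ScenarioComparison(
        correlations=corr, top_k_overlap=overlap, rank_correlation=rank_corr,
        non_overlap_ranks=non_overlap,
        final_iterations=(run_a.trajectory.final_iteration,
                          run_b.trajectory.final_iteration),
        kappas=(run_a.spectral.kappa, run_b.spectral.kappa))
    if out_dir is not None:
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        corr.to_csv(d / "correlations.csv", float_format=FLOAT_FMT)
        with open(d / "topk.json", "w") as fh:
            json.dump({"K": K, "overlap": overlap,
                       "rank_correlation": rank_corr,
                       "non_overlap_ranks": non_overlap}, fh, indent=2,
                      sort_keys=True)
        with open(d / "spectral.json", "w") as fh:
            json.dump(cond, fh, indent=2, sort_keys=True)
    return comp
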