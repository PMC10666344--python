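"""Convergence-heterogeneity analysis of PCG trajectories.

Partitions the evaluated animals into the four information groups
(G+P+, G-P+, G+P-, G-P-), summarises per-snapshot |x_i - x_F| trajectories
per effect category (animal groups by sex, SNP effects, genetic groups),
and compares two evaluation scenarios (cross-scenario EBV correlations,
top-K bull ranking overlap, condition-number ratio).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .pcg import PCGTrajectory, SpectralEstimates

log = logging.getLogger(__name__)

GROUP_NAMES = ("GpPp", "GmPp", "GpPm", "GmPm")


class AnalysisError(ValueError):
    pass


@dataclass
class AnimalGroupPartition:
    """Disjoint id sets by (genotyped, phenotyped) status, plus sex labels."""

    GpPp: np.ndarray
    GmPp: np.ndarray
    GpPm: np.ndarray
    GmPm: np.ndarray
    sex: pd.Series          # indexed by animal_id

    def group(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def sizes(self) -> dict:
        return {g: len(self.group(g)) for g in GROUP_NAMES}


@dataclass
class ScenarioComparison:
    correlations: pd.DataFrame      # group x sex Pearson correlations
    top_k_overlap: int
    rank_correlation: float
    non_overlap_ranks: dict
    final_iterations: tuple
    kappas: tuple

    @property
    def kappa_ratio(self) -> float:
        return self.kappas[0] / self.kappas[1]


def partition_animals(ped: Pedigree) -> AnimalGroupPartition:
    """Split animals by genotype/phenotype flags (DRP counts as phenotype)."""
    df = ped.df
    g = df["genotyped"].to_numpy()
    p = df["phenotyped"].to_numpy()
    ids = df["animal_id"].to_numpy()
    return AnimalGroupPartition(
        GpPp=ids[g & p], GmPp=ids[~g & p], GpPm=ids[g & ~p], GmPm=ids[~g & ~p],
        sex=df.set_index("animal_id")["sex"],
    )


def trajectory_stats(trajectory: PCGTrajectory, system,
                     partition: AnimalGroupPartition,
                     ped: Pedigree) -> pd.DataFrame:
    """Per-snapshot mean and sample SD of |x_i - x_F| per effect category.

    Animal categories (four information groups, split by sex) are measured
    on reconstructed EBVs; the SNP category on the marker-effect entries;
    the genetic-group category on the group solutions.  Columns: iteration,
    category, mean_absdiff, sd_absdiff, n.
    """
    from .model import reconstruct_ebv, group_solutions

    if not trajectory.snapshots:
        raise AnalysisError("trajectory has no snapshots")
    ebv_final = reconstruct_ebv(trajectory.x_final, system)
    g_final = trajectory.x_final[system.layout.snp]
    grp_final = group_solutions(trajectory.x_final, system)

    pos = {a: i for i, a in enumerate(ped.df["animal_id"])}
    cat_indices = {}
    for gname in GROUP_NAMES:
        ids = partition.group(gname)
        for sex in ("M", "F"):
            sel = [pos[a] for a in ids if partition.sex[a] == sex]
            if sel:
                cat_indices[f"{gname}_{sex}"] = np.array(sel)
            else:
                log.info("category %s_%s empty; omitted", gname, sex)

    rows = []
    for it, x in trajectory.snapshots:
        ebv = reconstruct_ebv(x, system)
        for cat, idx in cat_indices.items():
            d = np.abs(ebv[idx] - ebv_final[idx])
            rows.append((it, cat, d.mean(), d.std(ddof=1) if len(d) > 1 else 0.0,
                         len(d)))
        g = x[system.layout.snp]
        if len(g):
            d = np.abs(g - g_final)
            rows.append((it, "snp", d.mean(), d.std(ddof=1) if len(d) > 1 else 0.0,
                         len(d)))
        grp = group_solutions(x, system)
        if len(grp):
            d = np.abs(grp - grp_final)
            rows.append((it, "genetic_group", d.mean(),
                         d.std(ddof=1) if len(d) > 1 else 0.0, len(d)))
    return pd.DataFrame(rows, columns=["iteration", "category", "mean_absdiff",
                                       "sd_absdiff", "n"])


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return np.nan          # undefined-signal, not a crash
    return float(np.corrcoef(a, b)[0, 1])


def scenario_correlations(ebv_a: pd.Series, ebv_b: pd.Series,
                          partition: AnimalGroupPartition) -> pd.DataFrame:
    """Pearson EBV correlations between two scenarios, per group and sex.

    ``ebv_a`` / ``ebv_b`` are Series indexed by animal_id; correlations are
    computed over the intersection of animals.  Rows: the four information
    groups plus 'All'; columns: M, F, All.
    """
    common = ebv_a.index.intersection(ebv_b.index)
    a = ebv_a.loc[common]
    b = ebv_b.loc[common]
    sex = partition.sex

    rows = {}
    for gname in GROUP_NAMES + ("All",):
        if gname == "All":
            ids = pd.Index(common)
        else:
            ids = pd.Index(partition.group(gname)).intersection(common)
        cells = {}
        for sx in ("M", "F"):
            sub = ids[sex.reindex(ids).to_numpy() == sx]
            cells[sx] = _pearson(a.loc[sub].to_numpy(), b.loc[sub].to_numpy())
        cells["All"] = _pearson(a.loc[ids].to_numpy(), b.loc[ids].to_numpy())
        rows[gname] = cells
    return pd.DataFrame(rows).T[["M", "F", "All"]]


def top_k_comparison(ebv_a: pd.Series, ebv_b: pd.Series,
                     bull_ids, K: int = 50):
    """Top-K bull overlap and rank correlation between two scenarios.

    Ranking is by EBV descending with ties broken by id ascending.  The rank
    correlation is the Pearson correlation of within-scenario ranks over the
    common top animals; the other-scenario rank of each non-overlapping
    animal is reported alongside.
    """
    bulls = pd.Index(sorted(bull_ids))
    bulls = bulls.intersection(ebv_a.index).intersection(ebv_b.index)
    if len(bulls) < K:
        raise AnalysisError(f"only {len(bulls)} bulls available for top-{K}")

    def ranking(ebv: pd.Series) -> pd.Series:
        df = pd.DataFrame({"ebv": ebv.loc[bulls]}).reset_index(names="animal_id")
        df = df.sort_values(["ebv", "animal_id"], ascending=[False, True])
        df["rank"] = np.arange(1, len(df) + 1)
        return df.set_index("animal_id")["rank"]

    rank_a = ranking(ebv_a)
    rank_b = ranking(ebv_b)
    top_a = set(rank_a.index[rank_a <= K])
    top_b = set(rank_b.index[rank_b <= K])
    common = sorted(top_a & top_b)
    overlap = len(common)
    rc = _pearson(rank_a.loc[common].to_numpy(dtype=float),
                  rank_b.loc[common].to_numpy(dtype=float))
    non_overlap = {
        a: {"rank_a": int(rank_a[a]), "rank_b": int(rank_b[a])}
        for a in sorted((top_a | top_b) - set(common))
    }
    return overlap, rc, non_overlap


def condition_number_report(traj_a: PCGTrajectory, spec_a: SpectralEstimates,
                            traj_b: PCGTrajectory, spec_b: SpectralEstimates) -> dict:
    """Side-by-side condition numbers and iteration counts for two runs."""
    return {
        "kappa_a": spec_a.kappa,
        "kappa_b": spec_b.kappa,
        "kappa_ratio": spec_a.kappa / spec_b.kappa,
        "iterations_a": traj_a.final_iteration,
        "iterations_b": traj_b.final_iteration,
        "mu1_a": spec_a.mu1, "mu_max_a": spec_a.mu_max,
        "mu1_b": spec_b.mu1, "mu_max_b": spec_b.mu_max,
    }
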