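"""Synthetic dairy-population generator.

Produces multi-generation pedigrees, gene-dropped genotypes, true marker and
polygenic effects, cow phenotypes with a herd/age/lactation fixed-effect
structure, and bull DRP pseudo-phenotypes with EDC precision weights — the
statistical structure the single-step evaluation assumes, at desk scale.

Defaults emulate a national dairy evaluation in miniature: ~5,000 animals
over 8 discrete generations, 2,000 unlinked SNPs, genotyping confined to
recent cohorts, female phenotyping from mid-pedigree cohorts on, and
unknown-parent links concentrated in the early generations so that full
vs. generation-truncated scenarios differ in their genetic-group structure.
Every stage is reproducible from the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .pedigree import (Pedigree, PedigreeRecord, sort_and_validate,
                       inbreeding_coefficients, write_pedigree_csv)
from .genotypes import GenotypeMatrix, write_genotypes_tsv
from .model import ObservationSet, observations_from_frames


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 42
    # population structure
    n_founders: int = 600
    n_generations: int = 8
    matings_per_generation: int = 275
    offspring_per_mating: int = 2
    sex_ratio: float = 0.5
    founder_birth_year: int = 1975
    country_probs: tuple = (0.8, 0.1, 0.1)        # PL, USCA, OTHER
    unknown_parent_rate_early: float = 0.15       # generations 1-2
    unknown_parent_rate_late: float = 0.02
    selection_fraction: Optional[float] = None    # sires from top fraction by a_true
    # genotyping / phenotyping
    n_snps: int = 2000
    founder_maf_low: float = 0.01
    founder_maf_high: float = 0.5
    genotyped_last_generations: int = 3
    genotyping_prob: float = 0.6
    phenotyped_from_generation: int = 6
    phenotyping_prob_female: float = 0.6
    drp_from_generation: int = 6
    drp_prob_male: float = 0.35
    edc_log_mean: float = 3.0
    edc_log_sd: float = 0.8
    # fixed effects
    mu: float = 100.0
    mu_drp: float = 100.0
    n_herds: int = 25
    herd_sd: float = 2.0
    age_class_effects: tuple = (0.0, 0.5, 1.0)
    lactation_phase_effects: tuple = (0.0, -0.3, 0.4)
    # variance parameters (national stature evaluation values)
    sigma_a2: float = 5.50
    sigma_e2: float = 4.63
    k: float = 0.2

    def __post_init__(self):
        for p in (self.sex_ratio, self.genotyping_prob,
                  self.phenotyping_prob_female, self.drp_prob_male,
                  self.unknown_parent_rate_early, self.unknown_parent_rate_late):
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"probability {p} outside [0, 1]")
        for c in (self.n_founders, self.n_generations,
                  self.matings_per_generation, self.offspring_per_mating,
                  self.n_snps, self.n_herds):
            if c <= 0:
                raise SimulationError("counts must be positive")


@dataclass
class SyntheticTruth:
    g_true: np.ndarray      # per-SNP effects
    u_true: np.ndarray      # per-animal polygenic values
    a_true: np.ndarray      # per-animal total breeding values
    founder_p: np.ndarray   # founder allele frequencies
    sum2pq: float


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix       # genotyped animals only
    truth: SyntheticTruth
    phenotypes: pd.DataFrame        # cow records
    drp: pd.DataFrame               # bull DRP records
    full_codes: np.ndarray          # all-animal genotype codes (internal)

    def observations(self) -> ObservationSet:
        return observations_from_frames(self.phenotypes, self.drp, self.pedigree)


def _stage_rngs(seed: int):
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(4)]


def simulate_pedigree(config: SimulationConfig,
                      rng: Optional[np.random.Generator] = None,
                      a_true_for_selection: Optional[dict] = None) -> Pedigree:
    """Discrete-generation random-mating pedigree with data flags.

    Parents are drawn from the previous generation; a configurable fraction
    of parent links in early generations is blanked to create unknown
    parents.  Genotyping is restricted to the last
    ``genotyped_last_generations`` cohorts; females are phenotyped from
    ``phenotyped_from_generation`` on; males get a DRP flag from
    ``drp_from_generation`` on.
    """
    if rng is None:
        rng = _stage_rngs(config.seed)[0]
    c = config
    if c.n_founders < 2:
        raise SimulationError("need at least 2 founders")
    records = []
    males: list[str] = []
    females: list[str] = []
    geno_start = c.n_generations - c.genotyped_last_generations + 1

    def flags(sex: str, gen: int):
        genotyped = gen >= geno_start and rng.random() < c.genotyping_prob
        if sex == "F":
            phenotyped = (gen >= c.phenotyped_from_generation
                          and rng.random() < c.phenotyping_prob_female)
        else:
            phenotyped = (gen >= c.drp_from_generation
                          and rng.random() < c.drp_prob_male)
        return genotyped, phenotyped

    countries = np.array(["PL", "USCA", "OTHER"])
    for i in range(c.n_founders):
        sex = "M" if rng.random() < c.sex_ratio else "F"
        g, p = flags(sex, 0)
        rec = PedigreeRecord(
            animal_id=f"A{i:06d}", sex=sex,
            birth_year=c.founder_birth_year,
            country=str(rng.choice(countries, p=c.country_probs)),
            genotyped=g, phenotyped=p)
        records.append(rec)
        (males if sex == "M" else females).append(rec.animal_id)

    next_id = c.n_founders
    for gen in range(1, c.n_generations + 1):
        if not males or not females:
            raise SimulationError(f"generation {gen - 1} lacks one sex entirely")
        blank_rate = (c.unknown_parent_rate_early if gen <= 2
                      else c.unknown_parent_rate_late)
        prev_m, prev_f = males, females
        if c.selection_fraction and a_true_for_selection:
            ranked = sorted(prev_m, key=lambda a: -a_true_for_selection.get(a, 0.0))
            prev_m = ranked[:max(2, int(len(ranked) * c.selection_fraction))]
        males, females = [], []
        for _ in range(c.matings_per_generation):
            sire = prev_m[rng.integers(len(prev_m))]
            dam = prev_f[rng.integers(len(prev_f))]
            for _ in range(c.offspring_per_mating):
                sex = "M" if rng.random() < c.sex_ratio else "F"
                g, p = flags(sex, gen)
                s = "" if rng.random() < blank_rate else sire
                d = "" if rng.random() < blank_rate else dam
                rec = PedigreeRecord(
                    animal_id=f"A{next_id:06d}", sire_id=s, dam_id=d, sex=sex,
                    birth_year=c.founder_birth_year + gen,
                    country=str(rng.choice(countries, p=c.country_probs)),
                    genotyped=g, phenotyped=p)
                records.append(rec)
                next_id += 1
                (males if sex == "M" else females).append(rec.animal_id)
    return sort_and_validate(records)


def simulate_genotypes(ped: Pedigree, config: SimulationConfig,
                       rng: Optional[np.random.Generator] = None):
    """Gene-drop genotypes down the pedigree.

    Founder codes are Binomial(2, p_j) with p_j ~ U(maf_low, maf_high);
    each parent transmits allele A with probability code/2 per SNP
    (exact for unlinked loci); an unknown parent transmits from the founder
    frequency.  Returns ``(GenotypeMatrix of flagged animals, full codes
    over all animals, founder p)``.
    """
    if rng is None:
        rng = _stage_rngs(config.seed)[1]
    m = config.n_snps
    p = rng.uniform(config.founder_maf_low, config.founder_maf_high, size=m)
    n = ped.n_animals
    codes = np.zeros((n, m), dtype=np.int8)
    sire, dam = ped.sire_idx, ped.dam_idx
    for i in range(n):
        s, d = sire[i], dam[i]
        ps = codes[s] / 2.0 if s >= 0 else p
        pd_ = codes[d] / 2.0 if d >= 0 else p
        codes[i] = (rng.random(m) < ps).astype(np.int8) + \
                   (rng.random(m) < pd_).astype(np.int8)
    flagged = ped.df["genotyped"].to_numpy()
    gm = GenotypeMatrix(
        animal_ids=ped.ids[flagged],
        snp_ids=np.array([f"snp{j}" for j in range(m)], dtype=object),
        codes=codes[flagged].copy())
    return gm, codes, p


def simulate_effects_and_phenotypes(ped: Pedigree, full_codes: np.ndarray,
                                    founder_p: np.ndarray,
                                    config: SimulationConfig,
                                    rng: Optional[np.random.Generator] = None):
    """True effects, breeding values and cow phenotype records.

    g_true ~ N(0, (1-k) sigma_a2 / sum2pq) iid; u_true follows the pedigree
    recursion with Mendelian-sampling variance k sigma_a2 (1/2 - (F_s+F_d)/4)
    (unknown parents contribute founder variance); a_true = z g_true + u_true
    with z centered at the founder frequencies.  Cow phenotype =
    mu + herd + age class + lactation phase + a_true + e, e ~ N(0, sigma_e2).
    """
    if rng is None:
        rng = _stage_rngs(config.seed)[2]
    c = config
    sum2pq = float(np.sum(2.0 * founder_p * (1.0 - founder_p)))
    sigma_g2 = (1.0 - c.k) * c.sigma_a2 / sum2pq
    m = len(founder_p)
    g_true = rng.normal(0.0, np.sqrt(sigma_g2), size=m)

    n = ped.n_animals
    F = inbreeding_coefficients(ped)
    sire, dam = ped.sire_idx, ped.dam_idx
    u = np.zeros(n)
    ksa2 = c.k * c.sigma_a2
    for i in range(n):
        s, d = sire[i], dam[i]
        mean = 0.0
        var_frac = 1.0
        if s >= 0:
            mean += 0.5 * u[s]
            var_frac -= 0.25 * (1.0 + F[s])
        if d >= 0:
            mean += 0.5 * u[d]
            var_frac -= 0.25 * (1.0 + F[d])
        u[i] = mean + rng.normal(0.0, np.sqrt(ksa2 * var_frac))
    Z = full_codes.astype(float) - 2.0 * founder_p
    a_true = Z @ g_true + u
    truth = SyntheticTruth(g_true=g_true, u_true=u, a_true=a_true,
                           founder_p=founder_p, sum2pq=sum2pq)

    herd_effects = rng.normal(0.0, c.herd_sd, size=c.n_herds)
    cows = np.flatnonzero((ped.df["sex"] == "F").to_numpy()
                          & ped.df["phenotyped"].to_numpy())
    herds = rng.integers(c.n_herds, size=len(cows))
    ages = rng.integers(len(c.age_class_effects), size=len(cows))
    lacts = rng.integers(len(c.lactation_phase_effects), size=len(cows))
    y = (c.mu + herd_effects[herds]
         + np.asarray(c.age_class_effects)[ages]
         + np.asarray(c.lactation_phase_effects)[lacts]
         + a_true[cows]
         + rng.normal(0.0, np.sqrt(c.sigma_e2), size=len(cows)))
    pheno = pd.DataFrame({
        "animal_id": ped.ids[cows],
        "value": y,
        "herd": [f"h{h}" for h in herds],
        "age_class": [f"age{a}" for a in ages],
        "lactation_phase": [f"lac{l}" for l in lacts],
    })
    return truth, pheno


def simulate_drp_edc(truth: SyntheticTruth, ped: Pedigree,
                     config: SimulationConfig,
                     rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Bull DRP records: DRP = mu_drp + a_true + N(0, sigma_e2/EDC),
    EDC ~ rounded lognormal floored at 1."""
    if rng is None:
        rng = _stage_rngs(config.seed)[3]
    c = config
    bulls = np.flatnonzero((ped.df["sex"] == "M").to_numpy()
                           & ped.df["phenotyped"].to_numpy())
    edc = np.maximum(
        1, np.round(rng.lognormal(c.edc_log_mean, c.edc_log_sd, size=len(bulls)))
    ).astype(int)
    drp = (c.mu_drp + truth.a_true[bulls]
           + rng.normal(0.0, np.sqrt(c.sigma_e2 / edc)))
    return pd.DataFrame({"animal_id": ped.ids[bulls], "drp": drp, "edc": edc})


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run all simulation stages with per-stage seed streams."""
    rngs = _stage_rngs(config.seed)
    ped = simulate_pedigree(config, rngs[0])
    gm, codes, p = simulate_genotypes(ped, config, rngs[1])
    truth, pheno = simulate_effects_and_phenotypes(ped, codes, p, config, rngs[2])
    drp = simulate_drp_edc(truth, ped, config, rngs[3])
    return SimulatedDataset(config=config, pedigree=ped, genotypes=gm,
                            truth=truth, phenotypes=pheno, drp=drp,
                            full_codes=codes)


def write_dataset(ds: SimulatedDataset, directory) -> dict:
    """Emit pedigree.csv, genotypes.tsv, phenotypes.csv, drp.csv.

    The files round-trip losslessly through the package loaders.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": d / "pedigree.csv",
        "genotypes": d / "genotypes.tsv",
        "phenotypes": d / "phenotypes.csv",
        "drp": d / "drp.csv",
    }
    try:
        write_pedigree_csv(ds.pedigree, paths["pedigree"])
        write_genotypes_tsv(ds.genotypes, paths["genotypes"])
        ds.phenotypes.to_csv(paths["phenotypes"], index=False, float_format="%.10g")
        ds.drp.to_csv(paths["drp"], index=False, float_format="%.10g")
    except OSError as e:
        raise SimulationError(f"failed writing dataset to {d}: {e}") from e
    return {k: str(v) for k, v in paths.items()}
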