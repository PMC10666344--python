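"""Single-step SNP-BLUP mixed model equations.

The observation model is

    y = X beta + W a + e,

where ``a`` is the vector of breeding values.  For genotyped animals
``a = Z g + u`` with ``g`` the random SNP effects and ``u`` the residual
polygenic effect; for non-genotyped animals the marker term is expressed
through imputed covariates ``T1 = A12 A22^-1 Z2`` plus an explicit
imputation residual ``eps`` (the hybrid parameterisation, provably
equivalent to single-step GBLUP).  Priors:

    g   ~ N(0, I (1-k) sigma_a2 / sum 2 p q)
    eps ~ N(0, (A^11)^-1 (1-k) sigma_a2)      (A^11: non-genotyped block
                                               of the animal-only A^-1)
    u   ~ N(0, A k sigma_a2)                  (grouped A^-1 when genetic
                                               groups are present)
    e   ~ N(0, diag(sigma_e2 / w_j))          (w = 1 for cow records,
                                               w = EDC for bull DRPs)

The full solution vector is x = [beta; g; eps; u; genetic groups].  The
coefficient matrix C is exposed matrix-free (an exact diagonal is extracted
analytically for the Jacobi preconditioner); a dense assembly is available
for the direct-solve oracle on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import linalg

from .pedigree import Pedigree, RelationshipStructures, tabular_relationship_matrix
from .genotypes import MarkerScale

COW = "cow_phenotype"
BULL = "bull_drp"


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class VarianceParameters:
    """Fixed variance components of the evaluation (not estimated)."""

    sigma_a2: float = 5.50
    sigma_e2: float = 4.63
    k: float = 0.2

    def __post_init__(self):
        if self.sigma_a2 <= 0 or self.sigma_e2 <= 0:
            raise ModelError("variances must be positive")
        if not 0.0 < self.k < 1.0:
            raise ModelError(f"k = {self.k} outside (0, 1)")


@dataclass
class ObservationSet:
    """Cow phenotype records and bull DRP records with EDC weights.

    ``records`` columns: animal_id, value, kind, weight, herd, age_class,
    lactation_phase, cohort.  Cow records carry the herd/age/lactation
    labels; bull records carry the artificial fixed-effect class ``cohort``
    (birth-year based).  At most one record per animal.
    """

    records: pd.DataFrame

    def __post_init__(self):
        df = self.records
        dup = df["animal_id"].duplicated()
        if dup.any():
            raise ModelError(
                f"animal {df.loc[dup, 'animal_id'].iloc[0]!r} has multiple records")
        cows = df["kind"] == COW
        bulls = df["kind"] == BULL
        if not (cows | bulls).all():
            raise ModelError("record kind must be cow_phenotype or bull_drp")
        if cows.any() and not np.allclose(df.loc[cows, "weight"], 1.0):
            raise ModelError("cow records must have weight 1")
        if bulls.any() and (df.loc[bulls, "weight"] <= 0).any():
            bad = df.loc[bulls & (df["weight"] <= 0), "animal_id"].iloc[0]
            raise ModelError(f"bull {bad!r} has EDC <= 0")

    @property
    def n_records(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class EffectLayout:
    """Index ranges of the solution vector [beta; g; eps; u; groups]."""

    beta: slice
    snp: slice
    eps: slice
    animal: slice
    group: slice

    @property
    def total(self) -> int:
        return self.group.stop

    @classmethod
    def build(cls, n_beta: int, n_snp: int, n_eps: int, n_animal: int,
              n_group: int) -> "EffectLayout":
        o = 0
        parts = []
        for n in (n_beta, n_snp, n_eps, n_animal, n_group):
            parts.append(slice(o, o + n))
            o += n
        return cls(*parts)


@dataclass
class MMESystem:
    """Matrix-free mixed model equations: operator, RHS, layout, diagonal."""

    layout: EffectLayout
    matvec: Callable[[np.ndarray], np.ndarray]
    rhs: np.ndarray
    diag: np.ndarray
    T: np.ndarray                  # n_animals x m marker covariates
    X: sp.csr_matrix
    Wmat: sp.csr_matrix            # records -> animals incidence
    rw: np.ndarray                 # per-record precision w_j / sigma_e2
    structures: RelationshipStructures
    vp: VarianceParameters
    scale: Optional[MarkerScale]
    A11: sp.csr_matrix             # non-genotyped block of animal-only A^-1
    A_inv_constrained: sp.csr_matrix
    group_kept: np.ndarray         # group codes kept after the constraint
    fixed_names: list = field(default_factory=list)

    @property
    def n_unknowns(self) -> int:
        return self.layout.total

    def to_dense(self) -> np.ndarray:
        """Densely assembled C for the direct-solve oracle (small systems)."""
        n = self.structures.n_animals
        lay = self.layout
        dim = lay.total
        n1 = lay.eps.stop - lay.eps.start
        S = sp.csr_matrix(
            (np.ones(n1), (self.structures.nongeno_idx, np.arange(n1))),
            shape=(n, n1))
        F = np.hstack([
            self.X.toarray(),
            self.Wmat @ self.T,
            (self.Wmat @ S).toarray(),
            self.Wmat.toarray(),
            np.zeros((self.Wmat.shape[0], lay.group.stop - lay.group.start)),
        ])
        C = (F * self.rw[:, None]).T @ F
        vp, sc = self.vp, self.scale
        if lay.snp.stop > lay.snp.start:
            C[lay.snp, lay.snp] += np.eye(lay.snp.stop - lay.snp.start) / sc.sigma_g2
        if n1:
            C[lay.eps, lay.eps] += self.A11.toarray() / ((1 - vp.k) * vp.sigma_a2)
        ug = slice(lay.animal.start, lay.group.stop)
        C[ug, ug] += self.A_inv_constrained.toarray() / (vp.k * vp.sigma_a2)
        return C


def observations_from_frames(pheno: Optional[pd.DataFrame],
                             drp: Optional[pd.DataFrame],
                             ped: Pedigree,
                             bull_class: str = "cohort") -> ObservationSet:
    """Assemble an ObservationSet from phenotype and DRP tables.

    ``pheno`` columns: animal_id, value, herd, age_class, lactation_phase.
    ``drp`` columns: animal_id, drp, edc.  Bull fixed-effect classes are one
    artificial class per birth-year cohort (``bull_class='cohort'``) or one
    per record (``'record'``).
    """
    frames = []
    if pheno is not None and len(pheno):
        f = pd.DataFrame({
            "animal_id": pheno["animal_id"].astype(str),
            "value": pheno["value"].astype(float),
            "kind": COW,
            "weight": 1.0,
            "herd": pheno["herd"].astype(str),
            "age_class": pheno["age_class"].astype(str),
            "lactation_phase": pheno["lactation_phase"].astype(str),
            "cohort": "",
        })
        frames.append(f)
    if drp is not None and len(drp):
        ids = drp["animal_id"].astype(str)
        if bull_class == "cohort":
            years = ped.df.set_index("animal_id")["birth_year"]
            cohort = ids.map(years).astype(str)
        else:
            cohort = pd.Series([f"rec{i}" for i in range(len(drp))], index=drp.index)
        f = pd.DataFrame({
            "animal_id": ids,
            "value": drp["drp"].astype(float),
            "kind": BULL,
            "weight": drp["edc"].astype(float),
            "herd": "", "age_class": "", "lactation_phase": "",
            "cohort": cohort,
        })
        frames.append(f)
    if not frames:
        raise ModelError("no observations")
    return ObservationSet(pd.concat(frames, ignore_index=True))


def build_design(obs: ObservationSet, ped: Pedigree):
    """Fixed-effect design X and record->animal incidence.

    X has a global intercept plus reference-coded factors (first level
    dropped, levels sorted): herd, age_class and lactation_phase for cow
    records and the artificial bull class for DRP records.  Returns
    ``(X, rec_animal_idx, column_names)``.
    """
    df = obs.records
    try:
        rec_anim = np.array([ped.position(a) for a in df["animal_id"]])
    except Exception as e:
        raise ModelError(f"observation for animal not in pedigree: {e}") from e

    n_rec = len(df)
    cols = [np.ones((n_rec, 1))]
    names = ["intercept"]
    for factor in ("herd", "age_class", "lactation_phase", "cohort"):
        labels = df[factor].to_numpy()
        levels = sorted(set(labels) - {""})
        for lev in levels[1:]:          # first level = reference
            cols.append((labels == lev).astype(float)[:, None])
            names.append(f"{factor}={lev}")
    X = sp.csr_matrix(np.hstack(cols))
    return X, rec_anim, names


def build_residual_weights(obs: ObservationSet,
                           vp: VarianceParameters) -> np.ndarray:
    """Per-record residual precision w_j / sigma_e2 (w = 1 cows, EDC bulls)."""
    w = obs.records["weight"].to_numpy(dtype=float)
    if (w <= 0).any():
        raise ModelError("non-positive residual weight")
    return w / vp.sigma_e2


def build_mme(X: sp.csr_matrix,
              rec_animal_idx: np.ndarray,
              y: np.ndarray,
              rw: np.ndarray,
              Z2: np.ndarray,
              T1: np.ndarray,
              structures: RelationshipStructures,
              vp: VarianceParameters,
              scale: Optional[MarkerScale],
              fixed_names: Optional[list] = None,
              constrain_first_group: bool = True) -> MMESystem:
    """Assemble the matrix-free MME operator, RHS and exact diagonal.

    ``Z2`` holds centered genotypes of the genotyped block, ``T1`` the
    imputed covariates of the non-genotyped block.  When genetic groups are
    present the first instantiated group is constrained to zero (its column
    dropped): with an intercept in X the grouped system is otherwise
    singular because a constant shift of all groups and animals is absorbed
    by the intercept.
    """
    n = structures.n_animals
    geno, nongeno = structures.geno_idx, structures.nongeno_idx
    m = Z2.shape[1]
    if T1.shape != (len(nongeno), m):
        raise ModelError(f"T1 shape {T1.shape} != ({len(nongeno)}, {m})")
    if m and scale is None:
        raise ModelError("marker scale required when SNPs are present")

    T = np.zeros((n, m))
    if m:
        T[geno] = Z2
        T[nongeno] = T1

    n_rec = len(y)
    Wmat = sp.csr_matrix(
        (np.ones(n_rec), (np.arange(n_rec), rec_animal_idx)), shape=(n_rec, n))

    ng_total = structures.n_groups
    if ng_total and constrain_first_group:
        group_kept = np.arange(1, ng_total)
        keep = np.concatenate([np.arange(n), n + group_kept])
        Ainv_c = structures.A_inv[np.ix_(keep, keep)].tocsr()
    else:
        group_kept = np.arange(ng_total)
        Ainv_c = structures.A_inv.tocsr()
    ng = len(group_kept)

    A11 = structures.A_inv_animal[np.ix_(nongeno, nongeno)].tocsr()
    n1 = len(nongeno)
    nb = X.shape[1]
    lay = EffectLayout.build(nb, m, n1, n, ng)

    k, sa2 = vp.k, vp.sigma_a2
    eps_prec = 1.0 / ((1.0 - k) * sa2)
    u_prec = 1.0 / (k * sa2)
    XT = X.T.tocsr()
    WT = Wmat.T.tocsr()

    def matvec(v: np.ndarray) -> np.ndarray:
        beta = v[lay.beta]
        g = v[lay.snp]
        eps = v[lay.eps]
        ug = v[lay.animal.start:lay.group.stop]
        a = T @ g if m else np.zeros(n)
        a = a + ug[:n]
        if n1:
            a[nongeno] += eps
        obs_lin = X @ beta + Wmat @ a
        r = rw * obs_lin
        out = np.empty_like(v)
        out[lay.beta] = XT @ r
        t = WT @ r
        if m:
            out[lay.snp] = T.T @ t + g / scale.sigma_g2
        if n1:
            out[lay.eps] = t[nongeno] + (A11 @ eps) * eps_prec
        prior_ug = (Ainv_c @ ug) * u_prec
        out[lay.animal.start:lay.group.stop] = prior_ug
        out[lay.animal] += t
        return out

    # exact diagonal
    t_diag = np.asarray(WT @ rw)
    diag = np.empty(lay.total)
    diag[lay.beta] = np.asarray(X.power(2).T @ rw).ravel()
    if m:
        Tobs = T[rec_animal_idx]
        diag[lay.snp] = np.einsum("r,rj,rj->j", rw, Tobs, Tobs) + 1.0 / scale.sigma_g2
        del Tobs
    if n1:
        diag[lay.eps] = t_diag[nongeno] + A11.diagonal() * eps_prec
    dA = Ainv_c.diagonal() * u_prec
    diag[lay.animal] = t_diag + dA[:n]
    diag[lay.group] = dA[n:]

    # RHS
    r = rw * y
    b = np.zeros(lay.total)
    b[lay.beta] = XT @ r
    t = WT @ r
    if m:
        b[lay.snp] = T.T @ t
    if n1:
        b[lay.eps] = t[nongeno]
    b[lay.animal] = t

    return MMESystem(
        layout=lay, matvec=matvec, rhs=b, diag=diag, T=T, X=X, Wmat=Wmat,
        rw=rw, structures=structures, vp=vp, scale=scale, A11=A11,
        A_inv_constrained=Ainv_c, group_kept=group_kept,
        fixed_names=fixed_names or [],
    )


def direct_solve_oracle(system: MMESystem) -> np.ndarray:
    """Dense symmetric solve of the constrained MME (test oracle, small n)."""
    if system.n_unknowns > 4000:
        raise ModelError(
            f"direct oracle limited to small systems, got {system.n_unknowns}")
    C = system.to_dense()
    b = system.rhs
    try:
        x = linalg.solve(C, b, assume_a="sym")
    except linalg.LinAlgError as e:
        raise ModelError(f"singular MME after constraints: {e}") from e
    resid = np.linalg.norm(C @ x - b)
    if not np.isfinite(resid) or resid > 1e-6 * max(np.linalg.norm(b), 1.0):
        raise ModelError("MME numerically singular after constraints")
    return x


def reconstruct_ebv(x: np.ndarray, system: MMESystem) -> np.ndarray:
    """Per-animal EBV = T g + S eps + u (grouped animal solutions already
    include the genetic-group contribution through the grouped A^-1)."""
    if len(x) != system.n_unknowns:
        raise ModelError(f"solution length {len(x)} != {system.n_unknowns}")
    lay = system.layout
    ebv = x[lay.animal].copy()
    m = lay.snp.stop - lay.snp.start
    if m:
        ebv += system.T @ x[lay.snp]
    nongeno = system.structures.nongeno_idx
    if len(nongeno):
        ebv[nongeno] += x[lay.eps]
    return ebv


def group_solutions(x: np.ndarray, system: MMESystem) -> np.ndarray:
    """Genetic-group solutions (constrained group re-inserted as 0)."""
    ng_total = system.structures.n_groups
    full = np.zeros(ng_total)
    full[system.group_kept] = x[system.layout.group]
    return full


def ssgblup_oracle(obs: ObservationSet, ped: Pedigree, Z2: np.ndarray,
                   vp: VarianceParameters, scale: Optional[MarkerScale]) -> np.ndarray:
    """Equivalence oracle: single-step GBLUP EBVs on a small, group-free instance.

    Builds G = (1-k) Z2 Z2'/sum2pq + k A22, H^-1 = A^-1 +
    blockdiag(0, G^-1 - A22^-1), and solves the animal-model MME
    [beta; a] directly.  Requires complete parentage (no genetic groups).
    """
    n = ped.n_animals
    if n > 2000:
        raise ModelError("ssGBLUP oracle limited to small instances")
    A = tabular_relationship_matrix(ped)
    Ainv = np.linalg.inv(A)
    geno = np.flatnonzero(ped.df["genotyped"].to_numpy())
    Hinv = Ainv.copy()
    if len(geno):
        A22 = A[np.ix_(geno, geno)]
        G = vp.k * A22
        if Z2.shape[1]:
            G = G + (1.0 - vp.k) * (Z2 @ Z2.T) / scale.sum2pq
        try:
            Ginv = np.linalg.inv(G)
        except np.linalg.LinAlgError as e:
            raise ModelError(f"singular G: {e}") from e
        Hinv[np.ix_(geno, geno)] += Ginv - np.linalg.inv(A22)

    X, rec_anim, _ = build_design(obs, ped)
    rw = build_residual_weights(obs, vp)
    y = obs.records["value"].to_numpy(dtype=float)
    n_rec = len(y)
    Wm = sp.csr_matrix((np.ones(n_rec), (np.arange(n_rec), rec_anim)),
                       shape=(n_rec, n)).toarray()
    Xd = X.toarray()
    F = np.hstack([Xd, Wm])
    C = (F * rw[:, None]).T @ F
    nb = Xd.shape[1]
    C[nb:, nb:] += Hinv / vp.sigma_a2
    b = (F * rw[:, None]).T @ y
    sol = linalg.solve(C, b, assume_a="sym")
    return sol[nb:]


def load_phenotypes_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"animal_id": str, "herd": str,
                                    "age_class": str, "lactation_phase": str})


def load_drp_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"animal_id": str})
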