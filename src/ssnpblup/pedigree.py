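"""Pedigree handling and relationship structures.

Parses and validates pedigrees, truncates them by generation, assigns
unknown-parent genetic groups (sex x country x 10-year birth window),
computes inbreeding coefficients, and builds the sparse inverse numerator
relationship matrix A^-1 (optionally with genetic-group columns appended)
together with the dense tabular A used as an oracle and as the source of
the A12 / A22 blocks needed to impute marker covariates for non-genotyped
animals.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

UNKNOWN = ""
COUNTRIES = ("PL", "USCA", "OTHER")


@dataclass(frozen=True)
class PedigreeRecord:
    """One animal: identity, parentage and cohort metadata.

    ``sire_id`` / ``dam_id`` equal to the empty string mean an unknown
    parent.  ``phenotyped`` covers both an own record (cows) and a DRP
    pseudo-phenotype (bulls).
    """

    animal_id: str
    sire_id: str = UNKNOWN
    dam_id: str = UNKNOWN
    sex: str = "F"
    birth_year: int = 0
    country: str = "PL"
    genotyped: bool = False
    phenotyped: bool = False


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    ``sire_idx`` / ``dam_idx`` hold positional parent indices (-1 =
    unknown); every known parent precedes its offspring.
    """

    df: pd.DataFrame
    n_auto_added: int = 0

    @property
    def n_animals(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> np.ndarray:
        return self.df["animal_id"].to_numpy()

    @property
    def sire_idx(self) -> np.ndarray:
        return self.df["sire_idx"].to_numpy()

    @property
    def dam_idx(self) -> np.ndarray:
        return self.df["dam_idx"].to_numpy()

    def position(self, animal_id: str) -> int:
        pos = self._index().get(animal_id)
        if pos is None:
            raise PedigreeError(f"unknown animal id {animal_id!r}")
        return pos

    def _index(self) -> dict:
        if not hasattr(self, "_pos_cache") or len(self._pos_cache) != len(self.df):
            self._pos_cache = {a: i for i, a in enumerate(self.df["animal_id"])}
        return self._pos_cache


@dataclass
class GeneticGroupMap:
    """Unknown-parent group structure.

    ``labels`` lists the instantiated (sex, country, window_start) groups in
    numbering order; ``sire_group`` / ``dam_group`` give, per animal, the
    group code of an unknown parent slot (-1 where the parent is known).
    """

    labels: list[tuple[str, str, int]]
    sire_group: np.ndarray
    dam_group: np.ndarray

    @property
    def n_groups(self) -> int:
        return len(self.labels)


@dataclass
class RelationshipStructures:
    """Inbreeding, sparse A^-1 (grouped or not) and genotype-block indices."""

    inbreeding: np.ndarray
    A_inv: sp.csr_matrix          # animals (+ appended group columns)
    n_animals: int
    n_groups: int
    nongeno_idx: np.ndarray       # block 1: non-genotyped animal positions
    geno_idx: np.ndarray          # block 2: genotyped animal positions
    A_inv_animal: sp.csr_matrix = None  # animal-only A^-1 (no groups)

    def __post_init__(self):
        if self.A_inv_animal is None:
            self.A_inv_animal = self.A_inv


def _as_record(rec) -> PedigreeRecord:
    if isinstance(rec, PedigreeRecord):
        return rec
    return PedigreeRecord(*rec)


def _normalise_parent(pid) -> str:
    if pid is None:
        return UNKNOWN
    s = str(pid).strip()
    if s in ("", "0", "nan", "NA", "."):
        return UNKNOWN
    return s


def sort_and_validate(
    raw_records: Sequence,
    founder_year_gap: int = 5,
) -> Pedigree:
    """Topologically sort a pedigree, auto-adding bare ancestors as founders.

    Parent ids that never appear as animals are added as founder records with
    sex inferred from the slot they occupy and birth year set to the earliest
    offspring's year minus ``founder_year_gap``.

    Raises
    ------
    PedigreeError
        on duplicated animal ids, sex-inconsistent parent usage, a parent
        born in or after its offspring's birth year, or a parentage cycle
        (one cycle member is named).
    """
    records = [_as_record(r) for r in raw_records]
    by_id: dict[str, PedigreeRecord] = {}
    for r in records:
        if r.animal_id in by_id:
            raise PedigreeError(f"duplicated animal_id {r.animal_id!r}")
        by_id[r.animal_id] = r

    # auto-add bare ancestors
    n_auto = 0
    for r in list(records):
        for pid, sex in ((_normalise_parent(r.sire_id), "M"), (_normalise_parent(r.dam_id), "F")):
            if pid and pid not in by_id:
                founder = PedigreeRecord(
                    animal_id=pid, sex=sex,
                    birth_year=int(r.birth_year) - founder_year_gap,
                    country=r.country,
                )
                by_id[pid] = founder
                records.append(founder)
                n_auto += 1

    # Kahn topological sort; deterministic (input order among ready animals)
    parents = {
        r.animal_id: [p for p in (_normalise_parent(r.sire_id), _normalise_parent(r.dam_id)) if p]
        for r in records
    }
    children: dict[str, list[str]] = {a: [] for a in by_id}
    indeg = {a: 0 for a in by_id}
    for a, ps in parents.items():
        for p in ps:
            children[p].append(a)
            indeg[a] += 1
    order: list[str] = []
    ready = [r.animal_id for r in records if indeg[r.animal_id] == 0]
    head = 0
    while head < len(ready):
        a = ready[head]
        head += 1
        order.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
    if len(order) != len(by_id):
        cyclic = sorted(a for a, d in indeg.items() if d > 0)
        raise PedigreeError(f"parentage cycle detected involving {cyclic[0]!r}")

    # consistency checks (after cycle detection so cycles are named as such)
    for r in records:
        for pid, sex in ((_normalise_parent(r.sire_id), "M"),
                         (_normalise_parent(r.dam_id), "F")):
            if not pid:
                continue
            parent = by_id[pid]
            if parent.sex != sex:
                role = "sire" if sex == "M" else "dam"
                raise PedigreeError(
                    f"{pid!r} used as {role} of {r.animal_id!r} but recorded "
                    f"with sex {parent.sex!r}")
            if parent.birth_year >= r.birth_year:
                raise PedigreeError(
                    f"parent {pid!r} (born {parent.birth_year}) not older than "
                    f"offspring {r.animal_id!r} (born {r.birth_year})")

    pos = {a: i for i, a in enumerate(order)}
    rows = []
    for a in order:
        r = by_id[a]
        s, d = _normalise_parent(r.sire_id), _normalise_parent(r.dam_id)
        rows.append(
            (a, s, d, pos[s] if s else -1, pos[d] if d else -1,
             r.sex, int(r.birth_year), r.country, bool(r.genotyped), bool(r.phenotyped))
        )
    df = pd.DataFrame(
        rows,
        columns=["animal_id", "sire_id", "dam_id", "sire_idx", "dam_idx",
                 "sex", "birth_year", "country", "genotyped", "phenotyped"],
    )
    return Pedigree(df=df, n_auto_added=n_auto)


def load_pedigree_csv(path) -> Pedigree:
    """Read a pedigree CSV (animal_id, sire_id, dam_id, sex, birth_year,
    country[, genotyped, phenotyped]); empty string or 0 = unknown parent."""
    df = pd.read_csv(path, dtype={"animal_id": str, "sire_id": str, "dam_id": str},
                     keep_default_na=False)
    recs = [
        PedigreeRecord(
            animal_id=row.animal_id,
            sire_id=_normalise_parent(row.sire_id),
            dam_id=_normalise_parent(row.dam_id),
            sex=row.sex,
            birth_year=int(row.birth_year),
            country=row.country,
            genotyped=bool(int(getattr(row, "genotyped", 0) or 0)),
            phenotyped=bool(int(getattr(row, "phenotyped", 0) or 0)),
        )
        for row in df.itertuples()
    ]
    return sort_and_validate(recs)


def write_pedigree_csv(ped: Pedigree, path) -> None:
    out = ped.df[["animal_id", "sire_id", "dam_id", "sex", "birth_year",
                  "country"]].copy()
    out["genotyped"] = ped.df["genotyped"].astype(int)
    out["phenotyped"] = ped.df["phenotyped"].astype(int)
    out.to_csv(path, index=False)


def truncate_pedigree(ped: Pedigree, max_generations: int) -> Pedigree:
    """Keep data animals plus ancestors within ``max_generations`` parent steps.

    Generation 0 = animals with phenotype or genotype; an ancestor's
    generation is the minimum number of parent steps to any generation-0
    animal.  Parents of retained animals that were dropped are reset to
    unknown, and the result is re-sorted.
    """
    if max_generations < 1:
        raise PedigreeError("max_generations must be >= 1")
    df = ped.df
    data_mask = (df["genotyped"] | df["phenotyped"]).to_numpy()
    if not data_mask.any():
        raise PedigreeError("no phenotyped or genotyped animal in pedigree")
    n = ped.n_animals
    gen = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    gen[data_mask] = 0
    sire, dam = ped.sire_idx, ped.dam_idx
    # propagate min parent-steps upward; reverse order suffices after one
    # sweep because parents precede offspring
    for i in range(n - 1, -1, -1):
        g = gen[i]
        if g == np.iinfo(np.int64).max:
            continue
        for p in (sire[i], dam[i]):
            if p >= 0 and gen[p] > g + 1:
                gen[p] = g + 1
    # a data animal deep in the pedigree can also pull its ancestors in via a
    # later-positioned descendant; the single reverse sweep handles all cases
    # because gen[offspring] is final before its (earlier) parents are visited
    keep = gen <= max_generations
    kept_ids = set(df.loc[keep, "animal_id"])
    recs = []
    for row in df.loc[keep].itertuples():
        recs.append(PedigreeRecord(
            animal_id=row.animal_id,
            sire_id=row.sire_id if row.sire_id in kept_ids else UNKNOWN,
            dam_id=row.dam_id if row.dam_id in kept_ids else UNKNOWN,
            sex=row.sex, birth_year=row.birth_year, country=row.country,
            genotyped=row.genotyped, phenotyped=row.phenotyped,
        ))
    return sort_and_validate(recs)


def decade_window(year: int, anchor: int = 0) -> int:
    """Start year of the 10-year window containing ``year``."""
    return ((year - anchor) // 10) * 10 + anchor


def assign_genetic_groups(ped: Pedigree, window_years: int = 10,
                          anchor: int = 0) -> GeneticGroupMap:
    """Map every unknown-parent slot to a (sex, country, birth-window) group.

    The window is taken from the OFFSPRING's birth year and country; the
    slot's sex is male for sire slots and female for dam slots.  Only
    instantiated groups are numbered, consecutively in order of first use.
    """
    df = ped.df
    n = ped.n_animals
    sire_group = np.full(n, -1, dtype=np.int64)
    dam_group = np.full(n, -1, dtype=np.int64)
    labels: list[tuple[str, str, int]] = []
    codes: dict[tuple[str, str, int], int] = {}

    years = df["birth_year"].to_numpy()
    countries = df["country"].to_numpy()
    sires = ped.sire_idx
    dams = ped.dam_idx
    for i in range(n):
        for slot_sex, parent, target in (("M", sires[i], sire_group),
                                         ("F", dams[i], dam_group)):
            if parent >= 0:
                continue
            win = ((years[i] - anchor) // window_years) * window_years + anchor
            key = (slot_sex, str(countries[i]), int(win))
            if key not in codes:
                codes[key] = len(labels)
                labels.append(key)
            target[i] = codes[key]
    return GeneticGroupMap(labels=labels, sire_group=sire_group, dam_group=dam_group)


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficient F_i = f(sire_i, dam_i).

    Recursive coancestry with memoisation; unknown parents are unrelated
    non-inbred founders, so genetic groups never create inbreeding.
    """
    n = ped.n_animals
    sire, dam = ped.sire_idx, ped.dam_idx
    F = np.zeros(n)
    memo: dict[tuple[int, int], float] = {}
    sys.setrecursionlimit(max(sys.getrecursionlimit(), 10 * n + 1000))

    def kin(a: int, b: int) -> float:
        if a < 0 or b < 0:
            return 0.0
        if a == b:
            return 0.5 * (1.0 + F[a])
        if a < b:
            a, b = b, a          # a is the younger (later position)
        key = (a, b)
        v = memo.get(key)
        if v is None:
            v = 0.5 * (kin(sire[a], b) + kin(dam[a], b))
            memo[key] = v
        return v

    for i in range(n):
        if sire[i] >= 0 and dam[i] >= 0:
            F[i] = kin(sire[i], dam[i])
    return F


def tabular_relationship_matrix(ped: Pedigree,
                                subset: Optional[Sequence[str]] = None) -> np.ndarray:
    """Dense numerator relationship matrix A by the recursive tabular method.

    Computed over the full pedigree then restricted to ``subset`` (all
    animals if None).  Intended for desk-scale instances.
    """
    n = ped.n_animals
    sire, dam = ped.sire_idx, ped.dam_idx
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    if subset is None:
        return A
    idx = np.array([ped.position(a) for a in subset], dtype=np.int64)
    return A[np.ix_(idx, idx)]


def build_A_inverse(ped: Pedigree,
                    groups: Optional[GeneticGroupMap],
                    F: np.ndarray) -> RelationshipStructures:
    """Sparse A^-1 via per-animal contribution rules (Henderson / Quaas).

    Each animal i contributes the stencil {i: 1, parent slots: -1/2,
    parent-pair: 1/4} scaled by 1/d_i, where d_i is the Mendelian sampling
    variance fraction: 0.5 - 0.25 (F_s + F_d) with both parents known, an
    unknown parent contributing F = 0 plus a founder variance of 0.25.  When
    ``groups`` is given, each unknown parent slot is replaced by its group
    column (appended after the animals) using the same stencil; groups carry
    no inbreeding.
    """
    n = ped.n_animals
    if len(F) != n:
        raise PedigreeError(f"inbreeding vector length {len(F)} != n_animals {n}")
    ng = groups.n_groups if groups is not None else 0
    dim = n + ng
    sire, dam = ped.sire_idx, ped.dam_idx

    def slot(i: int, parent: np.ndarray, group: Optional[np.ndarray]) -> int:
        if parent[i] >= 0:
            return parent[i]
        if group is not None and group[i] >= 0:
            return n + group[i]
        return -1

    rows, cols, vals = [], [], []
    rows_a, cols_a, vals_a = [], [], []   # animal-only version

    def add(buf, i, j, v):
        buf[0].append(i)
        buf[1].append(j)
        buf[2].append(v)

    sg = groups.sire_group if groups is not None else None
    dg = groups.dam_group if groups is not None else None
    for i in range(n):
        s, d = sire[i], dam[i]
        dvar = 0.5
        if s >= 0:
            dvar -= 0.25 * F[s]
        else:
            dvar += 0.25
        if d >= 0:
            dvar -= 0.25 * F[d]
        else:
            dvar += 0.25
        alpha = 1.0 / dvar

        for grouped, buf in ((True, (rows, cols, vals)),
                             (False, (rows_a, cols_a, vals_a))):
            ps = slot(i, sire, sg if grouped else None)
            pd_ = slot(i, dam, dg if grouped else None)
            parents = [p for p in (ps, pd_) if p >= 0]
            add(buf, i, i, alpha)
            for p in parents:
                add(buf, i, p, -0.5 * alpha)
                add(buf, p, i, -0.5 * alpha)
            for p in parents:
                for q in parents:
                    add(buf, p, q, 0.25 * alpha)

    A_inv = sp.csr_matrix(sp.coo_matrix((vals, (rows, cols)), shape=(dim, dim)))
    if ng:
        A_inv_animal = sp.csr_matrix(
            sp.coo_matrix((vals_a, (rows_a, cols_a)), shape=(n, n)))
    else:
        A_inv_animal = A_inv
    geno = np.flatnonzero(ped.df["genotyped"].to_numpy())
    nongeno = np.flatnonzero(~ped.df["genotyped"].to_numpy())
    return RelationshipStructures(
        inbreeding=np.asarray(F, dtype=float), A_inv=A_inv, n_animals=n,
        n_groups=ng, nongeno_idx=nongeno, geno_idx=geno,
        A_inv_animal=A_inv_animal,
    )


def impute_marker_covariates(structures: RelationshipStructures,
                             Z2: np.ndarray,
                             method: str = "sparse",
                             A_dense: Optional[np.ndarray] = None) -> np.ndarray:
    """T1 = A12 A22^-1 Z2: expected centered genotypes of non-genotyped animals.

    ``method='sparse'`` uses the identity A12 A22^-1 = -(A^11)^-1 A^12 on the
    animal-only A^-1 (sparse LU on the non-genotyped block); ``method='dense'``
    is a cross-oracle forming the relationship blocks from ``A_dense`` (the
    full tabular A over all animals).
    """
    n1 = len(structures.nongeno_idx)
    m = Z2.shape[1] if Z2.ndim == 2 else 0
    if Z2.shape[0] != len(structures.geno_idx):
        raise PedigreeError(
            f"Z2 has {Z2.shape[0]} rows but {len(structures.geno_idx)} genotyped animals")
    if n1 == 0:
        return np.zeros((0, m))
    if len(structures.geno_idx) == 0:
        return np.zeros((n1, m))
    if method == "dense":
        if A_dense is None:
            raise PedigreeError("dense route requires A_dense")
        A12b = A_dense[np.ix_(structures.nongeno_idx, structures.geno_idx)]
        A22b = A_dense[np.ix_(structures.geno_idx, structures.geno_idx)]
        try:
            return A12b @ np.linalg.solve(A22b, Z2)
        except np.linalg.LinAlgError as e:
            raise PedigreeError(f"singular A22 block: {e}") from e
    Ai = structures.A_inv_animal.tocsc()
    ng, g = structures.nongeno_idx, structures.geno_idx
    A11 = Ai[np.ix_(ng, ng)].tocsc()
    A12 = Ai[np.ix_(ng, g)].tocsc()
    rhs = -np.asarray(A12 @ Z2)
    try:
        lu = splu(A11)
    except RuntimeError as e:
        raise PedigreeError(f"singular A^11 block (duplicate animals?): {e}") from e
    return lu.solve(rhs)
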