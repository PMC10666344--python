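import numpy as np
import pandas as pd
import pytest

from ssnpblup.pedigree import (PedigreeRecord, sort_and_validate,
                               inbreeding_coefficients, build_A_inverse,
                               assign_genetic_groups, impute_marker_covariates)
from ssnpblup.genotypes import center_genotypes, marker_scale
from ssnpblup.model import (
    VarianceParameters, ObservationSet, ModelError, observations_from_frames,
    build_design, build_residual_weights, build_mme, direct_solve_oracle,
    ssgblup_oracle, reconstruct_ebv, COW, BULL,
)
from ssnpblup.synthetic_data import SimulationConfig, simulate_dataset


def assemble_system(ds, vp=None, groups=False):
    """End-to-end MME assembly for a simulated dataset."""
    vp = vp or VarianceParameters()
    ped = ds.pedigree
    gg = assign_genetic_groups(ped) if groups else None
    F = inbreeding_coefficients(ped)
    st = build_A_inverse(ped, gg, F)
    gm = ds.genotypes
    sc = marker_scale(gm.p, vp.k, vp.sigma_a2) if gm.n_snps else None
    Z = center_genotypes(gm)
    row = {a: i for i, a in enumerate(gm.animal_ids)}
    Z2 = Z[[row[a] for a in ped.ids[st.geno_idx]]]
    T1 = impute_marker_covariates(st, Z2)
    obs = ds.observations()
    X, rec, names = build_design(obs, ped)
    rw = build_residual_weights(obs, vp)
    y = obs.records["value"].to_numpy(float)
    return build_mme(X, rec, y, rw, Z2, T1, st, vp, sc, fixed_names=names), obs


class TestVarianceParameters:
    def test_defaults_are_the_evaluation_values(self):
        vp = VarianceParameters()
        assert (vp.sigma_a2, vp.sigma_e2, vp.k) == (5.50, 4.63, 0.2)

    @pytest.mark.parametrize("kw", [dict(sigma_a2=-1), dict(k=0.0), dict(k=1.0)])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ModelError):
            VarianceParameters(**kw)


class TestObservations:
    def obs_df(self):
        return pd.DataFrame({
            "animal_id": ["a", "b"], "value": [1.0, 2.0],
            "kind": [COW, BULL], "weight": [1.0, 25.0],
            "herd": ["h1", ""], "age_class": ["x", ""],
            "lactation_phase": ["y", ""], "cohort": ["", "2000"]})

    def test_valid(self):
        assert ObservationSet(self.obs_df()).n_records == 2

    def test_duplicate_record_rejected(self):
        df = self.obs_df()
        df.loc[1, "animal_id"] = "a"
        with pytest.raises(ModelError, match="multiple"):
            ObservationSet(df)

    def test_zero_edc_rejected(self):
        df = self.obs_df()
        df.loc[1, "weight"] = 0.0
        with pytest.raises(ModelError, match="EDC"):
            ObservationSet(df)

    def test_residual_weights(self):
        rw = build_residual_weights(ObservationSet(self.obs_df()),
                                    VarianceParameters())
        assert rw[0] == pytest.approx(1.0 / 4.63)      # cow: w = 1
        assert rw[1] == pytest.approx(25.0 / 4.63)     # bull: w = EDC


class TestDesign:
    def test_reference_coding(self):
        ped = sort_and_validate(
            [PedigreeRecord(f"c{i}", sex="F", birth_year=2000, phenotyped=True)
             for i in range(3)])
        pheno = pd.DataFrame({
            "animal_id": ["c0", "c1", "c2"], "value": [1.0, 2.0, 3.0],
            "herd": ["h1", "h2", "h3"], "age_class": ["a", "a", "a"],
            "lactation_phase": ["l", "l", "l"]})
        obs = observations_from_frames(pheno, None, ped)
        X, rec, names = build_design(obs, ped)
        # 3 herds -> intercept + 2 free herd columns; single-level factors
        # contribute nothing
        assert names == ["intercept", "herd=h2", "herd=h3"]
        assert np.allclose(X.toarray()[:, 0], 1.0)
        assert list(rec) == [ped.position(a) for a in ("c0", "c1", "c2")]

    def test_unknown_animal_rejected(self):
        ped = sort_and_validate([PedigreeRecord("a", sex="F", birth_year=2000)])
        pheno = pd.DataFrame({"animal_id": ["zz"], "value": [1.0], "herd": ["h"],
                              "age_class": ["a"], "lactation_phase": ["l"]})
        obs = observations_from_frames(pheno, None, ped)
        with pytest.raises(ModelError, match="not in pedigree"):
            build_design(obs, ped)


class TestMMEOperator:
    def test_unknown_count(self, small_dataset):
        system, _ = assemble_system(small_dataset)
        lay = system.layout
        n = small_dataset.pedigree.n_animals
        n2 = int(small_dataset.pedigree.df["genotyped"].sum())
        assert lay.snp.stop - lay.snp.start == small_dataset.genotypes.n_snps
        assert lay.eps.stop - lay.eps.start == n - n2
        assert lay.animal.stop - lay.animal.start == n
        assert lay.total == system.rhs.shape[0] == system.diag.shape[0]

    def test_operator_matches_dense_columns(self, small_dataset, rng):
        system, _ = assemble_system(small_dataset)
        C = system.to_dense()
        for j in rng.integers(0, system.n_unknowns, 12):
            e = np.zeros(system.n_unknowns)
            e[j] = 1.0
            assert np.abs(system.matvec(e) - C[:, j]).max() < 1e-10

    def test_operator_symmetric(self, small_dataset, rng):
        system, _ = assemble_system(small_dataset)
        for _ in range(10):
            v = rng.standard_normal(system.n_unknowns)
            w = rng.standard_normal(system.n_unknowns)
            lhs = system.matvec(v) @ w
            rhs = v @ system.matvec(w)
            assert abs(lhs - rhs) < 1e-12 * max(abs(lhs), 1.0)

    def test_diagonal_matches_operator(self, small_dataset, rng):
        system, _ = assemble_system(small_dataset)
        for j in rng.integers(0, system.n_unknowns, 15):
            e = np.zeros(system.n_unknowns)
            e[j] = 1.0
            assert system.matvec(e)[j] == pytest.approx(system.diag[j], rel=1e-10)

    def test_grouped_system_solvable(self, grouped_dataset):
        system, _ = assemble_system(grouped_dataset, groups=True)
        x = direct_solve_oracle(system)       # would raise if singular
        assert np.isfinite(x).all()
        assert len(system.group_kept) == grouped_dataset.pedigree.df.pipe(
            lambda d: assign_genetic_groups(grouped_dataset.pedigree).n_groups) - 1


class TestDirectSolve:
    def test_intercept_recovers_record_in_strong_data_limit(self):
        ped = sort_and_validate(
            [PedigreeRecord("a", sex="F", birth_year=2000, phenotyped=True)])
        pheno = pd.DataFrame({"animal_id": ["a"], "value": [10.0],
                              "herd": ["h"], "age_class": ["x"],
                              "lactation_phase": ["l"]})
        obs = observations_from_frames(pheno, None, ped)
        vp = VarianceParameters(sigma_a2=1e-6, sigma_e2=1e-6)
        F = inbreeding_coefficients(ped)
        st = build_A_inverse(ped, None, F)
        X, rec, _ = build_design(obs, ped)
        rw = build_residual_weights(obs, vp)
        system = build_mme(X, rec, np.array([10.0]), rw,
                           np.zeros((0, 0)), np.zeros((1, 0)), st, vp, None)
        x = direct_solve_oracle(system)
        assert x[0] == pytest.approx(10.0, rel=1e-3)

    def test_solve_contract_residual(self, small_dataset):
        system, _ = assemble_system(small_dataset)
        x = direct_solve_oracle(system)
        C = system.to_dense()
        r = np.linalg.norm(C @ x - system.rhs)
        assert r < 1e-8 * np.linalg.norm(system.rhs)


class TestEquivalence:
    def test_hybrid_equals_ssgblup(self, small_dataset):
        system, obs = assemble_system(small_dataset)
        x = direct_solve_oracle(system)
        ebv = reconstruct_ebv(x, system)
        ped = small_dataset.pedigree
        Z2 = system.T[system.structures.geno_idx]
        ebv2 = ssgblup_oracle(obs, ped, Z2, system.vp, system.scale)
        rel = np.linalg.norm(ebv - ebv2) / np.linalg.norm(ebv2)
        assert rel < 1e-6

    def test_no_genotypes_reduces_to_pedigree_blup(self):
        cfg = SimulationConfig(
            seed=5, n_founders=30, n_generations=3, matings_per_generation=15,
            offspring_per_mating=2, n_snps=10, genotyping_prob=0.0,
            phenotyped_from_generation=1, drp_from_generation=1,
            unknown_parent_rate_early=0.0, unknown_parent_rate_late=0.0)
        ds = simulate_dataset(cfg)
        ds.genotypes.codes = ds.genotypes.codes[:, :0]   # drop SNP columns
        ds.genotypes.snp_ids = ds.genotypes.snp_ids[:0]
        ds.genotypes.p = ds.genotypes.p[:0]
        system, obs = assemble_system(ds)
        x = direct_solve_oracle(system)
        ebv = reconstruct_ebv(x, system)
        ebv_pb = ssgblup_oracle(obs, ds.pedigree, np.zeros((0, 0)),
                                system.vp, None)
        assert np.linalg.norm(ebv - ebv_pb) / np.linalg.norm(ebv_pb) < 1e-8

    def test_k_near_one_approaches_pedigree_blup(self, small_dataset):
        vp_hi = VarianceParameters(k=0.999)
        system, obs = assemble_system(small_dataset, vp=vp_hi)
        ebv = reconstruct_ebv(direct_solve_oracle(system), system)
        ebv_pb = ssgblup_oracle(obs, small_dataset.pedigree, np.zeros((0, 0)),
                                VarianceParameters(k=0.999), None)
        rel = np.linalg.norm(ebv - ebv_pb) / np.linalg.norm(ebv_pb)
        assert rel < 0.05

    def test_larger_residual_variance_shrinks_solutions(self, small_dataset):
        sys_a, _ = assemble_system(small_dataset, vp=VarianceParameters())
        sys_b, _ = assemble_system(
            small_dataset, vp=VarianceParameters(sigma_e2=2 * 4.63))
        xa = direct_solve_oracle(sys_a)
        xb = direct_solve_oracle(sys_b)
        lay = sys_a.layout
        rand = slice(lay.snp.start, lay.group.stop)
        assert np.linalg.norm(xb[rand]) < np.linalg.norm(xa[rand])


class TestReconstruction:
    def test_zero_marker_parts_give_polygenic_only(self, small_dataset):
        system, _ = assemble_system(small_dataset)
        x = np.zeros(system.n_unknowns)
        lay = system.layout
        x[lay.animal] = np.arange(lay.animal.stop - lay.animal.start, dtype=float)
        assert np.allclose(reconstruct_ebv(x, system), x[lay.animal])

    def test_marker_term_added_for_genotyped_animal(self, small_dataset):
        system, _ = assemble_system(small_dataset)
        lay = system.layout
        x = np.zeros(system.n_unknowns)
        j = system.structures.geno_idx[0]
        x[lay.animal.start + j] = 0.5
        g = np.zeros(lay.snp.stop - lay.snp.start)
        g[0] = 1.0
        x[lay.snp] = g
        ebv = reconstruct_ebv(x, system)
        assert ebv[j] == pytest.approx(0.5 + system.T[j, 0])

    def test_layout_mismatch_rejected(self, small_dataset):
        system, _ = assemble_system(small_dataset)
        with pytest.raises(ModelError, match="length"):
            reconstruct_ebv(np.zeros(3), system)
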