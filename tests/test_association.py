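"""Kinship, GLM and MLM marker-trait association."""

import numpy as np
import pytest

from ssrkit.association import (
    AssociationScan,
    TraitVector,
    bend_psd,
    glm_scan,
    ibs_kinship,
    mlm_scan,
)
from ssrkit.errors import ValidationError
from ssrkit.simulate import (
    PhenotypeSpec,
    PopulationSpec,
    generate_phenotype,
    generate_structured_genotypes,
)

from conftest import matrix_from_codes


def random_matrix(rng, n=60, m=10, n_alleles=3):
    calls = []
    for _ in range(n):
        row = []
        for _ in range(m):
            a, b = rng.integers(0, n_alleles, size=2)
            row.append((str(100 + 2 * a), str(100 + 2 * b)))
        calls.append(row)
    return matrix_from_codes(calls)


def trait_for(matrix, values, name="t"):
    return TraitVector(list(matrix.individuals), np.asarray(values, float), name)


class TestKinship:
    def test_identical_individuals(self):
        m = matrix_from_codes([[("A", "B"), ("C", "C")], [("A", "B"), ("C", "C")]])
        K = ibs_kinship(m)
        assert K[0, 1] == pytest.approx(1.0)

    def test_opposite_homozygotes(self):
        m = matrix_from_codes([[("A", "A"), ("C", "C")], [("B", "B"), ("D", "D")]])
        assert ibs_kinship(m)[0, 1] == pytest.approx(0.0)

    def test_hand_scoring(self):
        # (A/A vs A/A) = 1 and (A/B vs A/A) = 0.5 -> mean 0.75
        m = matrix_from_codes([[("A", "A"), ("A", "B")], [("A", "A"), ("A", "A")]])
        assert ibs_kinship(m)[0, 1] == pytest.approx(0.75)

    def test_missing_skipped_pairwise(self):
        m = matrix_from_codes(
            [[("A", "A"), None, ("A", "B")], [("A", "A"), ("C", "C"), ("A", "A")]]
        )
        assert ibs_kinship(m)[0, 1] == pytest.approx((1.0 + 0.5) / 2)

    def test_bending_makes_psd(self):
        M = np.array([[1.0, 0.99, 0.0], [0.99, 1.0, 0.99], [0.0, 0.99, 1.0]])
        assert np.linalg.eigvalsh(M).min() < 0
        bent = bend_psd(M)
        assert np.linalg.eigvalsh(bent).min() >= -1e-12


class TestGLM:
    def test_perfect_predictor(self, rng):
        m = random_matrix(rng, n=50, m=3, n_alleles=2)
        # trait = dosage of one allele at marker 2 (a deterministic
        # function of genotype class)
        col = m.column(1)
        y = np.array([c.count("102") for c in col], dtype=float)
        if np.ptp(y) == 0:
            pytest.skip("degenerate draw")
        res = glm_scan(m, trait_for(m, y))
        r = [x for x in res if x.marker == "M2"][0]
        assert r.pve == pytest.approx(100.0, abs=1e-6)
        assert r.p_value < 1e-10

    def test_type_one_error_calibrated(self):
        """Null simulation: empirical rejection at 0.05 within 0.05 +- 0.02."""
        pvals = []
        for seed in range(60):
            r = np.random.default_rng(1000 + seed)
            m = random_matrix(r, n=60, m=15, n_alleles=2)
            y = r.normal(size=60)
            res = glm_scan(m, trait_for(m, y))
            pvals += [x.p_value for x in res]
        frac = np.mean(np.array(pvals) < 0.05)
        assert abs(frac - 0.05) <= 0.02

    def test_structure_covariates_attenuate_confounding(self):
        """A marker confounded with population structure loses significance
        once Q covariates absorb the stratification."""
        freqs = [np.array([[0.9, 0.1], [0.1, 0.9]]) for _ in range(20)]
        spec = PopulationSpec(
            K=2, n_individuals=60, n_loci=20, n_alleles=2, alpha=0.05,
            allele_freqs=freqs, missing_rate=0.0,
        )
        mat, Q = generate_structured_genotypes(spec, seed=4)
        rng = np.random.default_rng(4)
        # phenotype driven purely by structure
        y = Q[:, 0] * 2.0 + rng.normal(0, 0.3, size=60)
        res_no_q = glm_scan(mat, trait_for(mat, y))
        res_q = glm_scan(mat, trait_for(mat, y), Q=Q)
        pq = {r.marker: r.p_value for r in res_q}
        pn = {r.marker: r.p_value for r in res_no_q}
        common = sorted(set(pq) & set(pn))
        assert np.median([pq[m] for m in common]) > np.median([pn[m] for m in common])

    def test_rank_deficient_marker_skipped(self):
        m = matrix_from_codes([[("A", "A")], [("A", "A")], [("A", "A")], [("A", "A")]])
        with pytest.warns(UserWarning):
            res = glm_scan(m, TraitVector(m.individuals, [0.0, 1.0, 2.0, 3.0]))
        assert res == []


class TestMLM:
    def test_identity_kinship_equals_glm(self, rng):
        m = random_matrix(rng, n=40, m=8, n_alleles=2)
        y = rng.normal(size=40)
        glm = {r.marker: r for r in glm_scan(m, trait_for(m, y))}
        mlm = {
            r.marker: r
            for r in mlm_scan(m, trait_for(m, y), kinship=np.eye(40) / 2.0)
        }
        assert set(glm) == set(mlm)
        for marker in glm:
            assert mlm[marker].p_value == pytest.approx(glm[marker].p_value, rel=1e-6)
            assert mlm[marker].pve == pytest.approx(glm[marker].pve, rel=1e-6)

    def test_structured_null_calibration_beats_glm(self):
        """Phenotype = polygenic signal from kinship + noise: the MLM's
        rejection rate stays closer to nominal than the GLM's."""
        glm_p, mlm_p = [], []
        for seed in range(12):
            r = np.random.default_rng(2000 + seed)
            freqs = [np.array([[0.9, 0.1], [0.1, 0.9]]) for _ in range(25)]
            spec = PopulationSpec(
                K=2, n_individuals=50, n_loci=25, n_alleles=2, alpha=0.05,
                allele_freqs=freqs, missing_rate=0.0,
            )
            mat, _ = generate_structured_genotypes(spec, seed=seed)
            Kin = ibs_kinship(mat)
            L = np.linalg.cholesky(bend_psd(2 * Kin) + 1e-6 * np.eye(50))
            y = L @ r.normal(size=50) + 0.5 * r.normal(size=50)
            tv = trait_for(mat, y)
            glm_p += [x.p_value for x in glm_scan(mat, tv)]
            mlm_p += [x.p_value for x in mlm_scan(mat, tv, kinship=Kin)]
        glm_rate = np.mean(np.array(glm_p) < 0.05)
        mlm_rate = np.mean(np.array(mlm_p) < 0.05)
        assert abs(mlm_rate - 0.05) < abs(glm_rate - 0.05)
        assert glm_rate > 0.05  # structure inflates the naive scan

    def test_planted_effect_ranks_first_and_pve_close(self):
        """A marker explaining ~30% of variance tops the scan and its PVE
        lands within 10 points of the realised truth."""
        rng = np.random.default_rng(7)
        mat = random_matrix(rng, n=100, m=20, n_alleles=2)
        spec = PhenotypeSpec(causal_effects={"M7": 1.0}, heritability=0.30)
        trait, truth = generate_phenotype(mat, spec, seed=7)
        for scan in (
            glm_scan(mat, trait),
            mlm_scan(mat, trait, kinship=ibs_kinship(mat)),
        ):
            best = min(scan, key=lambda r: r.p_value)
            assert best.marker == "M7"
            assert abs(best.pve - truth["M7"]) <= 10.0

    def test_non_psd_kinship_rejected(self, rng):
        m = random_matrix(rng, n=5, m=3)
        bad = np.eye(5)
        bad[0, 1] = bad[1, 0] = 2.0  # not PSD, bending handles it
        res = mlm_scan(m, trait_for(m, rng.normal(size=5)), kinship=bad)
        assert isinstance(res, list)


class TestScanFrontEnd:
    def test_summary_shape_and_pve_bounds(self, rng):
        m = random_matrix(rng, n=40, m=6, n_alleles=2)
        tv = trait_for(m, rng.normal(size=40))
        res = AssociationScan(m, tv, kinship=ibs_kinship(m)).fit(model="both")
        df = res.summary()
        assert set(df["model"]) == {"GLM", "MLM"}
        assert ((df["p_value"] >= 0) & (df["p_value"] <= 1)).all()
        assert ((df["PVE_percent"] >= 0) & (df["PVE_percent"] <= 100)).all()

    def test_constant_trait_rejected(self, rng):
        m = random_matrix(rng, n=10, m=2)
        with pytest.raises(ValidationError):
            TraitVector(m.individuals, np.ones(10))
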