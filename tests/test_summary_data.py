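import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from factormr.summary_data import (
    LDMatrix,
    SummaryDataError,
    VariantRecord,
    beta_to_covariance,
    build_summary_dataset,
    build_variant_covariance,
    harmonize,
    logit_to_linear,
    nearest_psd,
    read_ld_matrix,
    read_summary_associations,
    variance_from_frequency,
)

HEADER = "variant_id\tposition\teffect_allele\tother_allele\tbeta\tse\tn\n"


def write_tsv(path, rows, header=HEADER):
    path.write_text(header + "".join(rows))


def rec(vid="rs1", pos=100, ea="A", oa="G", beta=0.1, se=0.01, n=1000):
    return VariantRecord(vid, pos, ea, oa, beta, se, n)


class TestReadSummaryAssociations:
    def test_well_formed_three_rows(self, tmp_path):
        f = tmp_path / "x.tsv"
        write_tsv(f, [
            "rs1\t100\tA\tG\t0.1\t0.01\t1000\n",
            "rs2\t200\tC\tA\t-0.2\t0.02\t1000\n",
            "rs3\t300\tG\tT\t0.0\t0.03\t1000\n",
        ])
        records = read_summary_associations(f)
        assert len(records) == 3
        assert records[0] == rec()
        assert records[1].beta == -0.2

    def test_missing_beta_dropped_and_logged(self, tmp_path, caplog):
        f = tmp_path / "x.tsv"
        write_tsv(f, [
            "rs1\t100\tA\tG\t0.1\t0.01\t1000\n",
            "rs2\t200\tC\tA\t\t0.02\t1000\n",
        ])
        with caplog.at_level("INFO", logger="factormr.summary_data"):
            records = read_summary_associations(f)
        assert len(records) == 1
        assert "dropped 1 rows" in caplog.text

    def test_column_map_equivalent_parse(self, tmp_path):
        canonical = tmp_path / "a.tsv"
        renamed = tmp_path / "b.tsv"
        rows = ["rs1\t100\tA\tG\t0.1\t0.01\t1000\n"]
        write_tsv(canonical, rows)
        write_tsv(renamed, rows,
                  header="variant_id\tposition\teffect_allele\tother_allele\tb\tse\tn\n")
        assert read_summary_associations(canonical) == read_summary_associations(
            renamed, column_map={"beta": "b"})

    def test_missing_column_raises(self, tmp_path):
        f = tmp_path / "x.tsv"
        f.write_text("variant_id\tbeta\nrs1\t0.1\n")
        with pytest.raises(SummaryDataError, match="required column"):
            read_summary_associations(f)

    def test_non_acgt_allele_raises(self, tmp_path):
        f = tmp_path / "x.tsv"
        write_tsv(f, ["rs1\t100\tA\tI\t0.1\t0.01\t1000\n"])
        with pytest.raises(SummaryDataError, match="A/C/G/T"):
            read_summary_associations(f)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_summary_associations(tmp_path / "nope.tsv")


class TestVariantRecord:
    def test_identical_alleles_rejected(self):
        with pytest.raises(SummaryDataError):
            rec(ea="A", oa="A")

    def test_negative_se_rejected(self):
        with pytest.raises(SummaryDataError):
            rec(se=-1.0)

    def test_palindromic_detection(self):
        assert rec(ea="A", oa="T").is_palindromic
        assert rec(ea="C", oa="G").is_palindromic
        assert not rec(ea="A", oa="G").is_palindromic


def _ld(ids):
    p = len(ids)
    return LDMatrix(list(ids), np.eye(p))


class TestHarmonize:
    def test_identical_alleles_unchanged(self):
        exp = [rec("rs1"), rec("rs2", ea="C", oa="A")]
        out = [rec("rs1", beta=0.5), rec("rs2", ea="C", oa="A", beta=0.6)]
        h = harmonize(exp, out, _ld(["rs1", "rs2"]))
        assert [o.beta for o in h.outcome] == [0.5, 0.6]

    def test_swapped_alleles_flip_sign(self):
        exp = [rec("rs1", ea="A", oa="G")]
        out = [rec("rs1", ea="G", oa="A", beta=0.2)]
        h = harmonize(exp, out, _ld(["rs1"]))
        assert h.outcome[0].beta == pytest.approx(-0.2)
        assert h.outcome[0].effect_allele == "A"

    def test_palindromic_dropped(self):
        ids = [f"rs{i}" for i in range(1, 6)]
        exp = [rec(v) for v in ids[:4]] + [rec("rs5", ea="A", oa="T")]
        out = [rec(v, beta=0.3) for v in ids[:4]] + [rec("rs5", ea="A", oa="T", beta=0.3)]
        h = harmonize(exp, out, _ld(ids))
        assert len(h.exposure) == 4
        assert h.n_palindromic_dropped == 1

    def test_irreconcilable_dropped_with_warning(self):
        exp = [rec("rs1", ea="A", oa="G"), rec("rs2")]
        out = [rec("rs1", ea="A", oa="C", beta=0.2), rec("rs2", beta=0.1)]
        h = harmonize(exp, out, _ld(["rs1", "rs2"]))
        assert h.variant_ids == ["rs2"]
        assert h.n_irreconcilable_dropped == 1

    def test_empty_intersection_raises(self):
        with pytest.raises(SummaryDataError, match="no variants shared"):
            harmonize([rec("rs1")], [rec("rs2")], _ld(["rs3"]))

    def test_output_in_ld_order(self):
        exp = [rec("rs2", pos=200), rec("rs1")]
        out = [rec("rs1", beta=0.4), rec("rs2", pos=200, beta=0.5)]
        h = harmonize(exp, out, _ld(["rs1", "rs2"]))
        assert h.variant_ids == ["rs1", "rs2"]

    def test_idempotent(self):
        exp = [rec("rs1", ea="A", oa="G"), rec("rs2", ea="C", oa="A")]
        out = [rec("rs1", ea="G", oa="A", beta=0.2), rec("rs2", ea="C", oa="A", beta=0.3)]
        h1 = harmonize(exp, out, _ld(["rs1", "rs2"]))
        h2 = harmonize(h1.exposure, h1.outcome, h1.ld)
        assert h1.exposure == h2.exposure
        assert h1.outcome == h2.outcome


class TestScaleConversions:
    def test_beta_to_covariance_definition(self):
        assert beta_to_covariance(np.array([0.1]), np.array([0.5]))[0] == pytest.approx(0.05)

    def test_zero_beta(self):
        assert np.all(beta_to_covariance(np.zeros(4), np.ones(4)) == 0)

    def test_nonpositive_variance_raises(self):
        with pytest.raises(SummaryDataError):
            beta_to_covariance(np.ones(2), np.array([1.0, 0.0]))

    def test_beta_to_covariance_matches_individual_level(self, rng):
        # simulate individuals with known marginal betas; compare cov(Z, X)
        n, p = 100_000, 5
        freq = rng.uniform(0.2, 0.8, p)
        z = rng.binomial(2, freq, size=(n, p)).astype(float)
        beta_true = rng.normal(0, 0.1, p)
        varz = z.var(axis=0)
        zc = z - z.mean(axis=0)
        # each variant independently drives X marginally
        x = zc @ beta_true + rng.standard_normal(n)
        cov_emp = zc.T @ (x - x.mean()) / n
        # with independent variants, cov(Z_j, X) = beta_j var(Z_j)
        expected = beta_to_covariance(beta_true, varz)
        assert np.allclose(cov_emp, expected, atol=4 * 2.0 / np.sqrt(n))

    def test_round_trip(self, rng):
        beta = rng.normal(size=10)
        var = rng.uniform(0.1, 1.0, 10)
        back = beta_to_covariance(beta, var) / var
        assert np.allclose(back, beta, rtol=1e-14)

    def test_variance_from_frequency_half(self):
        assert variance_from_frequency(np.array([0.5]))[0] == pytest.approx(0.5)

    def test_variance_from_frequency_closed_form(self):
        assert variance_from_frequency(np.array([0.1]))[0] == pytest.approx(0.18)

    @given(st.floats(min_value=0.01, max_value=0.99))
    def test_variance_frequency_symmetry(self, f):
        a = variance_from_frequency(np.array([f]))[0]
        b = variance_from_frequency(np.array([1 - f]))[0]
        assert a == pytest.approx(b)

    def test_variance_from_frequency_bounds(self):
        with pytest.raises(SummaryDataError):
            variance_from_frequency(np.array([0.0]))
        with pytest.raises(SummaryDataError):
            variance_from_frequency(np.array([1.0]))


class TestLogitToLinear:
    def test_half_prevalence(self):
        assert logit_to_linear(np.array([1.0]), 0.5)[0] == pytest.approx(0.25)

    def test_zero_beta(self):
        assert logit_to_linear(np.array([0.0]), 0.3)[0] == 0.0

    def test_boundary_raises(self):
        with pytest.raises(SummaryDataError):
            logit_to_linear(np.array([1.0]), 0.0)
        with pytest.raises(SummaryDataError):
            logit_to_linear(np.array([1.0]), 1.0)

    def test_matches_logistic_simulation(self, rng):
        # small-effect logistic model: linear OLS coefficient ~= beta * mu(1-mu)
        n = 100_000
        z = rng.binomial(2, 0.4, n).astype(float)
        beta_logit = 0.08
        intercept = -0.7  # prevalence around 0.33
        prob = 1 / (1 + np.exp(-(intercept + beta_logit * z)))
        y = rng.binomial(1, prob).astype(float)
        mu = y.mean()
        zc = z - z.mean()
        ols = float(zc @ (y - mu) / (zc @ zc))
        approx = logit_to_linear(np.array([beta_logit]), mu)[0]
        assert approx == pytest.approx(ols, rel=0.10)


class TestNearestPsd:
    def test_identity_unchanged(self):
        assert np.array_equal(nearest_psd(np.eye(3)), np.eye(3))

    def test_negative_eigenvalue_clipped(self):
        # build a symmetric matrix with eigenvalues (1, -0.1)
        q = np.array([[np.cos(0.3), -np.sin(0.3)], [np.sin(0.3), np.cos(0.3)]])
        m = q @ np.diag([1.0, -0.1]) @ q.T
        repaired = nearest_psd(m)
        w = np.sort(np.linalg.eigvalsh(repaired))
        assert w[1] == pytest.approx(1.0, abs=1e-10)
        assert w[0] == pytest.approx(1e-8, rel=1e-6)

    def test_clipping_bound(self, rng):
        for _ in range(10):
            a = rng.standard_normal((5, 5))
            m = 0.5 * (a + a.T)
            w = np.linalg.eigvalsh(m)
            repaired = nearest_psd(m)
            worst = max(0.0, -w.min())
            assert np.linalg.norm(repaired - m) <= worst * np.sqrt(5) + 1e-10

    def test_asymmetric_raises(self):
        with pytest.raises(SummaryDataError):
            nearest_psd(np.array([[1.0, 0.5], [0.0, 1.0]]))


class TestBuildVariantCovariance:
    def test_identity_unit_variance(self):
        out = build_variant_covariance(_ld(["a", "b", "c"]), np.ones(3))
        assert np.allclose(out.matrix, np.eye(3))

    def test_two_by_two_scaling(self):
        ld = LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        out = build_variant_covariance(ld, np.array([1.0, 4.0]))
        assert out.matrix[0, 1] == pytest.approx(1.0)

    def test_unit_variances_idempotent(self, rng):
        from tests.conftest import random_correlation
        rho = random_correlation(8, rng)
        ld = LDMatrix([f"v{i}" for i in range(8)], rho)
        out = build_variant_covariance(ld, np.ones(8))
        assert np.allclose(out.matrix, rho, atol=1e-9)

    def test_output_psd(self, rng):
        from tests.conftest import random_correlation
        rho = random_correlation(12, rng)
        ld = LDMatrix([f"v{i}" for i in range(12)], rho)
        out = build_variant_covariance(ld, rng.uniform(0.1, 0.9, 12))
        assert np.allclose(out.matrix, out.matrix.T)
        assert np.linalg.eigvalsh(out.matrix).min() >= -1e-10

    def test_dimension_mismatch(self):
        with pytest.raises(SummaryDataError):
            build_variant_covariance(_ld(["a", "b"]), np.ones(3))


class TestLDMatrixIO:
    def test_square_roundtrip(self, tmp_path):
        f = tmp_path / "ld.tsv"
        f.write_text("rs1\trs2\n1.0\t0.3\n0.3\t1.0\n")
        ld = read_ld_matrix(f)
        assert ld.variant_ids == ["rs1", "rs2"]
        assert ld.rho[0, 1] == pytest.approx(0.3)

    def test_long_format(self, tmp_path):
        f = tmp_path / "ld.tsv"
        f.write_text("id1\tid2\tr\nrs1\trs2\t0.4\n")
        ld = read_ld_matrix(f)
        assert ld.variant_ids == ["rs1", "rs2"]
        assert ld.rho[0, 1] == pytest.approx(0.4)
        assert ld.rho[0, 0] == 1.0

    def test_dataset_roundtrip(self, tmp_path):
        from factormr.summary_data import SummaryDataset
        ds = SummaryDataset(["a", "b"], np.array([0.1, 0.2]), np.array([0.3, 0.4]),
                            100, 200, 1.0, 2.0, np.array([0.5, 0.6]))
        ds.to_files(tmp_path / "d.tsv", tmp_path / "d.json")
        back = SummaryDataset.from_files(tmp_path / "d.tsv", tmp_path / "d.json")
        assert back.variant_ids == ds.variant_ids
        assert np.allclose(back.delta_x, ds.delta_x)
        assert back.n_y == 200 and back.var_y == 2.0


class TestBuildSummaryDataset:
    def test_from_frequencies_with_logit_outcome(self):
        exp = [rec("rs1"), rec("rs2", ea="C", oa="A", beta=0.2)]
        out = [rec("rs1", beta=0.5), rec("rs2", ea="C", oa="A", beta=0.6)]
        h = harmonize(exp, out, _ld(["rs1", "rs2"]))
        ds, varz = build_summary_dataset(
            h, None, var_x=1.0, var_y=1.0,
            allele_frequencies=np.array([0.5, 0.1]), case_fraction=0.33,
        )
        expected_var = np.array([0.5, 0.18])
        assert np.allclose(ds.variant_variances, expected_var)
        assert np.allclose(ds.delta_x, np.array([0.1, 0.2]) * expected_var)
        assert np.allclose(ds.delta_y, np.array([0.5, 0.6]) * 0.33 * 0.67 * expected_var)
        assert np.allclose(varz.matrix, np.diag(expected_var))
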