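"""Proteomics chain: parsing, filters, imputation, DE rule, PCA, ORA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from neurocult import proteomics, simulate
from neurocult.errors import (
    ConfigurationError,
    DataError,
    DomainError,
    FormatError,
    InsufficientSampleError,
    ValidationError,
)
from neurocult.proteomics import (
    ProteinTable,
    differential_expression,
    filter_contaminants,
    filter_valid,
    impute_missing,
    is_differentially_expressed,
    log2_and_normalize,
    overrepresentation,
    pca_scores,
    read_protein_table,
    volcano_data,
)

GROUPS4 = {"a_1": "A", "a_2": "A", "b_1": "B", "b_2": "B"}


def table_of(values, samples=None, groups=None, **kw) -> ProteinTable:
    samples = samples or list(GROUPS4)
    df = pd.DataFrame(values, columns=samples,
                      index=[f"P{i}" for i in range(len(values))])
    return ProteinTable(df, groups or GROUPS4, **kw)


def random_table(rng, n=30, missing=0.2) -> ProteinTable:
    vals = np.power(2.0, rng.normal(22, 2, size=(n, 4)))
    mask = rng.random((n, 4)) < missing
    vals[mask] = np.nan
    flags = rng.random(n) < 0.2
    t = table_of(vals)
    return t.replace(is_contaminant=pd.Series(flags, index=t.protein_ids))


class TestReadWrite:
    def test_minimal_round_trip(self, tmp_path):
        t = table_of([[1.0, 2.0, 3.0, 4.0], [5.0, np.nan, 7.0, 8.0]])
        path = tmp_path / "pg.tsv"
        t.to_tsv(path)
        back = read_protein_table(path, GROUPS4)
        pd.testing.assert_frame_equal(back.intensities, t.intensities)
        assert list(back.protein_ids) == list(t.protein_ids)

    def test_zero_and_na_both_missing(self, tmp_path):
        path = tmp_path / "pg.tsv"
        path.write_text(
            "Protein IDs\tIntensity s1\tIntensity s2\n"
            "P1\t0\t100\n"
            "P2\tNA\t200\n")
        t = read_protein_table(path, {"s1": "A", "s2": "B"})
        assert math.isnan(t.intensities.loc["P1", "s1"])
        assert math.isnan(t.intensities.loc["P2", "s1"])

    def test_format_errors(self, tmp_path):
        p1 = tmp_path / "noid.tsv"
        p1.write_text("X\tIntensity s1\nP1\t5\n")
        with pytest.raises(FormatError, match="id column"):
            read_protein_table(p1, {"s1": "A"})
        p2 = tmp_path / "dupe.tsv"
        p2.write_text("Protein IDs\tIntensity s1\nP1\t5\nP1\t6\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_protein_table(p2, {"s1": "A"})
        p3 = tmp_path / "text.tsv"
        p3.write_text("Protein IDs\tIntensity s1\nP1\thello\n")
        with pytest.raises(FormatError, match="non-numeric"):
            read_protein_table(p3, {"s1": "A"})


class TestFilters:
    def test_no_flags_unchanged(self):
        t = table_of([[1.0] * 4] * 5)
        assert len(filter_contaminants(t).protein_ids) == 5

    def test_flagged_rows_removed(self):
        t = table_of([[1.0] * 4] * 10)
        flags = pd.Series([True] * 3 + [False] * 7, index=t.protein_ids)
        t = t.replace(is_contaminant=flags)
        assert len(filter_contaminants(t).protein_ids) == 7

    def test_contaminant_filter_matches_row_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            t = random_table(rng)
            got = set(filter_contaminants(t).protein_ids)
            expected = {pid for pid in t.protein_ids
                        if not t.is_contaminant[pid] and not t.is_decoy[pid]}
            assert got == expected

    def test_presence_boundary_inclusive(self):
        """2-of-4 is exactly 50% and is kept; 1-of-4 is dropped."""
        t = table_of([
            [1.0, 2.0, np.nan, np.nan],   # 2/4 -> kept
            [1.0, np.nan, np.nan, np.nan],  # 1/4 -> dropped
            [1.0, 2.0, 3.0, 4.0],
        ])
        kept = filter_valid(t)
        assert list(kept.protein_ids) == ["P0", "P2"]

    def test_complete_table_unchanged(self):
        t = table_of([[1.0] * 4] * 4)
        assert len(filter_valid(t).protein_ids) == 4

    def test_min_presence_domain(self):
        t = table_of([[1.0] * 4])
        with pytest.raises(ConfigurationError):
            filter_valid(t, min_presence=0.0)

    def test_filters_commute(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            t = random_table(rng)
            ab = filter_valid(filter_contaminants(t))
            ba = filter_contaminants(filter_valid(t))
            assert list(ab.protein_ids) == list(ba.protein_ids)


class TestImputation:
    def test_complete_table_bitwise_unchanged(self):
        t = table_of(np.power(2.0, np.random.default_rng(2)
                              .normal(20, 1, (10, 4))))
        out = impute_missing(t, seed=5)
        assert out.intensities.equals(t.intensities)

    def test_determinism(self):
        rng = np.random.default_rng(3)
        t = random_table(rng, missing=0.3)
        t = filter_valid(t)
        a = impute_missing(t, seed=7).intensities
        b = impute_missing(t, seed=7).intensities
        assert a.equals(b)

    def test_observed_values_untouched(self):
        rng = np.random.default_rng(4)
        t = filter_valid(random_table(rng, missing=0.3))
        out = impute_missing(t, seed=1)
        obs = t.intensities.notna()
        assert np.array_equal(out.intensities.to_numpy()[obs.to_numpy()],
                              t.intensities.to_numpy()[obs.to_numpy()])
        assert not out.intensities.isna().any().any()

    def test_downshift_draws_below_observed(self):
        """Imputed values sit below the observed mean in every sample."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            t = filter_valid(random_table(rng, n=60, missing=0.25))
            out = impute_missing(t, seed=int(rng.integers(1 << 31)))
            for s in t.samples:
                miss = t.intensities[s].isna()
                if not miss.any():
                    continue
                imputed = np.log2(out.intensities.loc[miss, s])
                observed = np.log2(t.intensities.loc[~miss, s])
                assert imputed.mean() < observed.mean()

    def test_all_missing_row_is_an_error(self):
        t = table_of([[np.nan] * 4, [1.0] * 4])
        with pytest.raises(DataError):
            impute_missing(t)

    def test_half_minimum_method(self):
        t = table_of([[8.0, np.nan, 8.0, 8.0], [2.0, 4.0, 2.0, 4.0]])
        out = impute_missing(t, method="half_min")
        assert out.intensities.loc["P0", "a_2"] == pytest.approx(2.0)


class TestNormalization:
    def test_log2_closed_form(self):
        t = table_of([[8.0, 8.0, 8.0, 8.0]])
        out = log2_and_normalize(t)
        assert np.allclose(out.intensities.to_numpy(), 3.0)

    def test_equal_median_centering_is_noop(self):
        vals = np.power(2.0, np.array([[1.0, 1.0, 1.0, 1.0],
                                       [2.0, 2.0, 2.0, 2.0],
                                       [3.0, 3.0, 3.0, 3.0]]))
        out = log2_and_normalize(table_of(vals))
        assert np.allclose(out.intensities.to_numpy(),
                           np.log2(vals))

    def test_sample_medians_equal_after_centering(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            vals = np.power(2.0, rng.normal(20, 2, size=(31, 4))
                            + rng.normal(0, 1, size=(1, 4)))
            out = log2_and_normalize(table_of(vals))
            med = np.median(out.intensities.to_numpy(), axis=0)
            assert np.allclose(med, med[0], atol=1e-12)

    def test_quantile_normalization_equalizes_distributions(self):
        rng = np.random.default_rng(7)
        vals = np.power(2.0, rng.normal(20, 2, size=(40, 4)))
        out = log2_and_normalize(table_of(vals), method="quantile")
        cols = [np.sort(out.intensities[s].to_numpy()) for s in GROUPS4]
        for c in cols[1:]:
            assert np.allclose(c, cols[0])

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            log2_and_normalize(table_of([[0.0, 1.0, 1.0, 1.0]]))


class TestDifferentialExpression:
    @pytest.mark.parametrize("fc,p,expected", [
        (1.6, 0.05, True),
        (1.4, 0.01, False),   # fold too small
        (1.6, 0.15, False),   # p too large
        (1.5, 0.01, False),   # boundary fc excluded (strict)
        (1.6, 0.1, False),    # boundary p excluded (strict)
        (1.0 / 1.6, 0.05, True),  # symmetric downregulation
    ])
    def test_rule(self, fc, p, expected):
        assert is_differentially_expressed(fc, p) is expected

    def test_flags_match_brute_force_scan(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            vals = np.power(2.0, rng.normal(20, 1.5, size=(20, 4)))
            t = log2_and_normalize(table_of(vals))
            de = differential_expression(t, "A", "B")
            from scipy import stats as sps
            for pid in t.protein_ids:
                row = t.intensities.loc[pid]
                a = row[["a_1", "a_2"]].to_numpy()
                b = row[["b_1", "b_2"]].to_numpy()
                fc = 2.0 ** (a.mean() - b.mean())
                pval = sps.ttest_ind(a, b, equal_var=False).pvalue
                expected = max(fc, 1 / fc) > 1.5 and pval < 0.1
                assert bool(de.loc[pid, "is_de"]) == expected

    def test_sorted_by_p(self):
        rng = np.random.default_rng(9)
        t = log2_and_normalize(
            table_of(np.power(2.0, rng.normal(20, 1, size=(15, 4)))))
        de = differential_expression(t, "A", "B")
        assert list(de["p_value"]) == sorted(de["p_value"])

    def test_requires_normalized_state_and_n2(self):
        t = table_of([[1.0] * 4] * 3)
        with pytest.raises(ValidationError):
            differential_expression(t, "A", "B")
        t2 = log2_and_normalize(table_of(
            [[1.0, 2.0, 3.0]] * 3, samples=["a_1", "a_2", "b_1"],
            groups={"a_1": "A", "a_2": "A", "b_1": "B"}))
        with pytest.raises(InsufficientSampleError):
            differential_expression(t2, "A", "B")


class TestPca:
    def test_collinear_samples_are_rank_one(self):
        base = np.arange(1.0, 11.0)
        vals = np.power(2.0, np.outer([1.0, 2.0, 3.0, 4.0], base))
        t = log2_and_normalize(table_of(vals.T))
        _, var = pca_scores(t)
        assert var[0] == pytest.approx(1.0)

    def test_variance_fractions_sorted(self):
        rng = np.random.default_rng(10)
        t = log2_and_normalize(
            table_of(np.power(2.0, rng.normal(20, 1, size=(25, 4)))))
        _, var = pca_scores(t)
        assert np.all(np.diff(var) <= 1e-12)
        assert var.sum() <= 1.0 + 1e-9

    def test_scores_match_eigendecomposition(self):
        """3-sample toy matrix vs a brute-force covariance eigensolve."""
        rng = np.random.default_rng(11)
        t = log2_and_normalize(
            table_of(np.power(2.0, rng.normal(20, 1, size=(8, 3))),
                     samples=["a_1", "a_2", "b_1"],
                     groups={"a_1": "A", "a_2": "A", "b_1": "B"}))
        scores, var = pca_scores(t)
        x = t.intensities.to_numpy().T
        x = x - x.mean(axis=0)
        cov = x.T @ x
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        for i in range(2):
            got = scores.iloc[:, i].to_numpy()
            expected = x @ v[:, i]
            assert np.allclose(np.abs(got), np.abs(expected), atol=1e-8)
        assert np.allclose(var[:2], (w / w.sum())[:2], atol=1e-12)

    def test_too_few_samples(self):
        t = table_of([[1.0]], samples=["a_1"], groups={"a_1": "A"})
        with pytest.raises(InsufficientSampleError):
            pca_scores(t)


class TestVolcano:
    def test_closed_form_and_passthrough(self):
        rng = np.random.default_rng(12)
        t = log2_and_normalize(
            table_of(np.power(2.0, rng.normal(20, 1, size=(10, 4)))))
        de = differential_expression(t, "A", "B")
        v = volcano_data(de)
        assert len(v) == len(de)
        assert np.allclose(v["neg_log10_p"],
                           -np.log10(de["p_value"]))
        assert (v["is_de"] == de["is_de"]).all()
        # p = 0.01 maps to exactly 2
        de2 = de.copy()
        de2.iloc[0, de2.columns.get_loc("p_value")] = 0.01
        assert volcano_data(de2)["neg_log10_p"].iloc[0] == pytest.approx(2.0)


class TestOverrepresentation:
    def test_disjoint_set_p_one(self):
        bg = [f"g{i}" for i in range(20)]
        res = overrepresentation(bg[:5], bg, {"s": bg[10:15]})
        assert res[0].overlap == 0 and res[0].p_value == pytest.approx(1.0)

    def test_degenerate_full_overlap(self):
        bg = [f"g{i}" for i in range(5)]
        res = overrepresentation(bg, bg, {"s": bg})
        assert res[0].p_value == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        """Background 20, set 5, list 5, overlap 4: p equals the exact
        fraction of C(20,5) draws with >= 4 set members."""
        bg = [f"g{i}" for i in range(20)]
        gene_set = bg[:5]
        hits = bg[:4] + [bg[10]]
        res = overrepresentation(hits, bg, {"s": gene_set})
        count = sum(1 for draw in itertools.combinations(bg, 5)
                    if len(set(draw) & set(gene_set)) >= 4)
        expected = count / math.comb(20, 5)
        assert res[0].p_value == pytest.approx(expected, abs=1e-12)

    def test_bh_monotone_and_above_raw(self):
        rng = np.random.default_rng(13)
        bg = [f"g{i}" for i in range(50)]
        hits = list(rng.choice(bg, size=10, replace=False))
        sets = {f"s{i}": list(rng.choice(bg, size=rng.integers(3, 15),
                                         replace=False))
                for i in range(8)}
        res = overrepresentation(hits, bg, sets)
        raw = np.array([r.p_value for r in res])
        adj = np.array([r.adjusted_p for r in res])
        assert np.all(adj >= raw - 1e-15)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_stray_id_rejected(self):
        with pytest.raises(ValidationError):
            overrepresentation(["x"], ["a", "b"], {"s": ["a"]})


class TestPlantedRecoverySmall:
    def test_spiked_proteins_recovered(self):
        """A scaled-down planted matrix: the DE rule finds the spikes."""
        params = simulate.ProteinSimParams(n_proteins=200, seed=21)
        table, truth = simulate.generate_protein_matrix(params)
        t = filter_valid(filter_contaminants(table))
        t = impute_missing(t, seed=22)
        t = log2_and_normalize(t)
        de = differential_expression(t, "combo", "B12")
        spiked_kept = set(truth.spiked_ids) & set(de.index)
        called = set(de.index[de["is_de"]])
        assert len(called & spiked_kept) / len(spiked_kept) >= 0.8
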