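import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicereg.abundance import (
    DiffExprThresholds,
    compute_fpkm,
    compute_tpm,
    filter_differential_genes,
    genotype_means,
    size_factors,
    spearman_log_tpm,
)


def frame(values, genes=None, libs=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    libs = libs or [f"L{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=libs)


class TestTpm:
    def test_single_gene_gets_the_million(self):
        tpm = compute_tpm(frame([[7]]), pd.Series({"g0": 500}))
        assert tpm.iloc[0, 0] == pytest.approx(1e6)

    def test_length_normalisation_closed_form(self):
        tpm = compute_tpm(frame([[10], [10]]), pd.Series({"g0": 1000, "g1": 2000}))
        assert tpm["L0"].tolist() == pytest.approx([666666.6667, 333333.3333], rel=1e-6)

    def test_matches_two_pass_reference(self):
        """Against an independently coded per-library two-pass computation."""
        rng = np.random.default_rng(0)
        counts = frame(rng.integers(0, 500, size=(5, 3)))
        lengths = pd.Series(rng.integers(200, 5000, size=5), index=counts.index)
        tpm = compute_tpm(counts, lengths)
        for lib in counts.columns:
            rates = [counts.loc[g, lib] / lengths[g] for g in counts.index]
            expected = [r / sum(rates) * 1e6 for r in rates]
            assert tpm[lib].tolist() == pytest.approx(expected)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(1)
        counts = frame(rng.integers(1, 1000, size=(20, 4)))
        lengths = pd.Series(rng.integers(100, 3000, size=20), index=counts.index)
        sums = compute_tpm(counts, lengths).sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-9)

    def test_zero_library_names_culprit(self):
        with pytest.raises(ValueError, match="L1"):
            compute_tpm(frame([[5, 0], [5, 0]]), pd.Series({"g0": 100, "g1": 100}))


class TestFpkm:
    def test_definition(self):
        counts = frame([[100], [1e6 - 100]])
        lengths = pd.Series({"g0": 1000, "g1": 1000})
        fpkm = compute_fpkm(counts, lengths, factors=pd.Series({"L0": 1.0}))
        assert fpkm.loc["g0", "L0"] == pytest.approx(100)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        counts = frame(rng.integers(1, 500, size=(8, 3)))
        lengths = pd.Series(rng.integers(200, 2000, size=8), index=counts.index)
        a = compute_fpkm(counts, lengths)
        b = compute_fpkm(counts * 2, lengths)
        assert np.allclose(a.values, b.values)

    def test_size_factors_match_median_of_ratios_reference(self):
        """Size factors equal an independently coded median-of-ratios
        (geometric-mean) computation, and pyDESeq2's, on a toy matrix."""
        rng = np.random.default_rng(3)
        counts = frame(rng.integers(1, 2000, size=(40, 4)))
        sf = size_factors(counts)
        logc = np.log(counts.values)
        loggeo = logc.mean(axis=1)
        expected = [np.exp(np.median(logc[:, j] - loggeo)) for j in range(4)]
        assert sf.tolist() == pytest.approx(expected)

        from pydeseq2.preprocessing import deseq2_norm
        _, sf_ref = deseq2_norm(counts.T)
        assert sf.tolist() == pytest.approx(np.asarray(sf_ref).ravel().tolist())


def de_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "log2FoldChange", "padj"])


class TestDifferentialFilter:
    FPKM = pd.DataFrame(
        {"ctrl": [2.0, 2.0, 2.0, 2.0, 0.1, 2.0, 2.0, 2.0],
         "sKO": [0.1] * 8,
         "dKO": [0.1] * 8},
        index=[f"g{i}" for i in range(8)],
    )

    def test_toy_table_exhaustive_conditions(self):
        """8 genes spanning the threshold combinations; exactly 3 survive
        (hand-applied padj < 0.05, |log2FC| > 0.5, FPKM >= 1 rules)."""
        t = de_table([
            ("g0", 0.6, 0.01),    # keep, up
            ("g1", -0.8, 0.04),   # keep, down
            ("g2", 0.5, 0.01),    # |lfc| not > 0.5
            ("g3", 0.6, 0.05),    # padj not < 0.05
            ("g4", 0.9, 0.001),   # unexpressed (max FPKM 0.1)
            ("g5", 0.1, 0.2),     # fails both
            ("g6", 2.0, 0.001),   # keep, up
            ("g7", 1.5, None),    # missing padj
        ])
        res = filter_differential_genes(t, self.FPKM)
        assert list(res.up["gene_id"]) == ["g0", "g6"]
        assert list(res.down["gene_id"]) == ["g1"]
        assert res.n_missing_padj == 1
        assert "g4" in res.excluded_unexpressed

    def test_boundary_values_are_strict(self):
        t = de_table([("g0", 0.5, 0.01), ("g1", 0.51, 0.05), ("g2", 0.51, 0.049)])
        fpkm = pd.DataFrame({"ctrl": [5.0] * 3}, index=["g0", "g1", "g2"])
        res = filter_differential_genes(t, fpkm)
        assert res.gene_ids == {"g2"}

    def test_fpkm_floor_is_inclusive(self):
        t = de_table([("g0", 1.0, 0.01)])
        fpkm = pd.DataFrame({"ctrl": [1.0]}, index=["g0"])
        assert filter_differential_genes(t, fpkm).gene_ids == {"g0"}

    @given(
        floor=st.floats(min_value=0.5, max_value=4.0),
        lfc=st.floats(min_value=0.1, max_value=2.0),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_in_thresholds(self, floor, lfc):
        """Raising the FPKM floor or |log2FC| cutoff never adds genes."""
        rng = np.random.default_rng(7)
        t = de_table([
            (f"g{i}", float(rng.normal(0, 1.2)), float(rng.uniform(0, 0.2)))
            for i in range(30)
        ])
        fpkm = pd.DataFrame(
            {"ctrl": rng.uniform(0, 5, 30)}, index=[f"g{i}" for i in range(30)]
        )
        loose = filter_differential_genes(t, fpkm, DiffExprThresholds())
        tight = filter_differential_genes(
            t, fpkm, DiffExprThresholds(log2fc=0.5 + lfc, fpkm_floor=1.0 + floor)
        )
        assert tight.gene_ids <= loose.gene_ids


class TestSpearman:
    def test_identical_vectors(self):
        v = pd.Series([1.0, 5.0, 2.0], index=list("abc"))
        assert spearman_log_tpm(v, v) == pytest.approx(1.0)

    def test_reversed_ranks(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        b = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        assert spearman_log_tpm(a, b) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self):
        a = pd.Series([3.0, 1.0, 4.0, 1.5, 9.0, 2.6], index=list("abcdef"))
        b = pd.Series([2.0, 7.0, 1.0, 8.0, 2.8, 1.8], index=list("abcdef"))
        ra, rb = a.rank(), b.rank()
        expected = np.corrcoef(ra, rb)[0, 1]
        assert spearman_log_tpm(a, b) == pytest.approx(expected)

    def test_too_few_shared_genes(self):
        a = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ValueError, match="shared"):
            spearman_log_tpm(a, a)


def test_genotype_means_collapses_replicates():
    m = frame([[1, 3, 10, 30]], libs=["c1", "c2", "k1", "k2"])
    out = genotype_means(m, {"c1": "ctrl", "c2": "ctrl", "k1": "dKO", "k2": "dKO"})
    assert out.loc["g0", "ctrl"] == 2 and out.loc["g0", "dKO"] == 20
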