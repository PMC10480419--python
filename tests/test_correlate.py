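"""Spearman engine against brute-force oracles; model-to-tissue aggregation;
matched-origin specificity; PCA QC contracts."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import modelfidelity as mf
from modelfidelity.correlate import model_to_tissue, pca_qc, specificity


# ---------------------------------------------------------------------------
# independent oracle: explicit average-rank construction + covariance formula
def rank_average(v):
    n = len(v)
    order = sorted(range(n), key=lambda i: v[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson_oracle(a, b):
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = sum((x - ma) ** 2 for x in a)
    vb = sum((y - mb) ** 2 for y in b)
    return cov / (va * vb) ** 0.5


def spearman_oracle(x, y):
    return pearson_oracle(rank_average(list(x)), rank_average(list(y)))


class TestSpearman:
    def test_monotone_and_reversed(self):
        assert mf.spearman([1, 2, 3], [10, 20, 30]).rho == pytest.approx(1.0)
        assert mf.spearman([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_average_ranks_with_ties(self):
        # ranks of x are [1, 2.5, 2.5, 4]; Pearson against [1,2,3,4]
        res = mf.spearman([1, 2, 2, 3], [1, 2, 3, 4])
        assert res.rho == pytest.approx(0.9486832980505138, abs=1e-12)

    def test_constant_input_undefined(self):
        res = mf.spearman([5, 5, 5, 5], [1, 2, 3, 4])
        assert np.isnan(res.rho) and not res.defined

    def test_contract_errors(self):
        with pytest.raises(ValueError, match="length mismatch"):
            mf.spearman([1, 2, 3], [1, 2])
        with pytest.raises(ValueError, match="n >= 3"):
            mf.spearman([1, 2], [1, 2])

    def test_matches_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(3, 30))
            # coarse integer draws force ties
            x = rng.integers(0, max(2, n // 2), size=n).astype(float)
            y = rng.integers(0, max(2, n // 2), size=n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            res = mf.spearman(x, y)
            assert res.rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_invariant_under_strictly_increasing_transforms(self, data):
        n = data.draw(st.integers(4, 15))
        x = np.array(
            data.draw(st.lists(st.integers(-50, 50), min_size=n, max_size=n)),
            dtype=float,
        )
        y = np.array(
            data.draw(st.lists(st.integers(-50, 50), min_size=n, max_size=n)),
            dtype=float,
        )
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        base = mf.spearman(x, y).rho
        # TPM vs log2(TPM+1) equivalence is a special case of monotone maps
        assert mf.spearman(np.log2(x - x.min() + 1.0), y).rho == pytest.approx(base, abs=1e-12)
        assert mf.spearman(x, np.exp(y / 25.0)).rho == pytest.approx(base, abs=1e-12)


def _toy_setup():
    """3 genes x (2 models + 4 tissue samples in 2 groups)."""
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(12)]
    cols = ["m1", "m2", "ta1", "ta2", "tb1", "tb2"]
    vals = pd.DataFrame(rng.random((12, 6)) * 100, index=genes, columns=cols)
    vals["ta1"] = vals["m1"]  # model m1 exactly equals tissue sample ta1
    vals = vals / vals.sum(axis=0) * 1e6
    matrix = mf.ExpressionMatrix(vals, mf.Unit.tpm)
    rows = []
    for c in ("m1", "m2"):
        rows.append({"sample_id": c, "source": "x", "tissue_group": "alpha",
                     "disease_state": "tumor", "model_type": "cell_line"})
    for c, tg in (("ta1", "alpha"), ("ta2", "alpha"), ("tb1", "beta"), ("tb2", "beta")):
        rows.append({"sample_id": c, "source": "x", "tissue_group": tg,
                     "disease_state": "tumor", "model_type": "tissue"})
    return matrix, mf.SampleMetadata(pd.DataFrame(rows))


class TestModelToTissue:
    def test_exact_match_gives_rho_one(self):
        matrix, meta = _toy_setup()
        sub = matrix.restrict_samples(["m1", "m2", "ta1"])
        meta_sub = mf.SampleMetadata(
            meta.table[meta.table.sample_id.isin(["m1", "m2", "ta1"])]
        )
        rec = model_to_tissue(sub, meta_sub)
        row = rec[(rec.model_sample_id == "m1") & (rec.tissue_group == "alpha")]
        assert row["rho_median"].iloc[0] == pytest.approx(1.0)

    def test_median_aggregation(self):
        # group of 3 tissue samples engineered to give pairwise rhos with a
        # known middle value: median of the three pairwise rhos
        matrix, meta = _toy_setup()
        rec = model_to_tissue(matrix, meta)
        for _, r in rec.iterrows():
            group = meta.select(model_type="tissue", tissue_group=r.tissue_group)
            rhos = [
                mf.spearman(
                    matrix.values[r.model_sample_id].to_numpy(),
                    matrix.values[s].to_numpy(),
                ).rho
                for s in group["sample_id"]
            ]
            assert r.rho_median == pytest.approx(float(np.median(rhos)), abs=1e-12)

    def test_tissue_sample_order_invariance(self):
        matrix, meta = _toy_setup()
        rec1 = model_to_tissue(matrix, meta)
        shuffled = mf.SampleMetadata(meta.table.iloc[::-1])
        rec2 = model_to_tissue(matrix, shuffled)
        pd.testing.assert_frame_equal(rec1, rec2)

    def test_restriction_commutes_with_subsetting(self):
        rng = np.random.default_rng(5)
        for trial in range(50):
            matrix, meta = _toy_setup()
            genes = list(matrix.gene_ids)
            sub_genes = sorted(rng.choice(genes, size=rng.integers(3, 10), replace=False))
            via_subset = model_to_tissue(matrix, meta, subset=sub_genes)
            pre = matrix.restrict_genes(sub_genes)
            via_restrict = model_to_tissue(pre, meta)
            np.testing.assert_allclose(
                via_subset["rho_median"], via_restrict["rho_median"], atol=1e-12
            )

    def test_empty_subset_rejected(self):
        matrix, meta = _toy_setup()
        with pytest.raises(ValueError, match="only 0 genes"):
            model_to_tissue(matrix, meta, subset=["nope1", "nope2", "nope3"])

    def test_profile_median_mode_runs(self):
        matrix, meta = _toy_setup()
        rec = model_to_tissue(matrix, meta, profile="median")
        assert set(rec.columns) == set(mf.correlate.CORRELATION_COLUMNS)


class TestSpecificity:
    def test_single_model_ranking(self):
        matrix, meta = _toy_setup()
        rec = pd.DataFrame(
            {
                "model_sample_id": ["m1"] * 3,
                "tissue_group": ["alpha", "beta", "gamma"],
                "disease_state": ["tumor", "tumor", "non_diseased"],
                "gene_subset": ["full_set"] * 3,
                "rho_median": [0.9, 0.8, 0.7],
                "n_tissue_samples": [2, 2, 2],
                "n_genes_used": [12] * 3,
            }
        )
        s = specificity(rec, meta)
        assert s.percent_best_match == 100.0
        assert s.per_model["matched_rank"].iloc[0] == 1

    def test_missing_pair_errors(self):
        matrix, meta = _toy_setup()
        rec = model_to_tissue(matrix, meta)
        broken = rec.iloc[1:]
        with pytest.raises(ValueError, match="missing records"):
            specificity(broken, meta)

    def test_tie_not_counted_unless_first_by_id(self):
        _, meta = _toy_setup()
        # matched group 'alpha' ties with 'beta'; alpha sorts first -> best
        rec = pd.DataFrame(
            {
                "model_sample_id": ["m1", "m1"],
                "tissue_group": ["alpha", "beta"],
                "disease_state": ["tumor", "tumor"],
                "gene_subset": ["full_set"] * 2,
                "rho_median": [0.8, 0.8],
                "n_tissue_samples": [2, 2],
                "n_genes_used": [12] * 2,
            }
        )
        s = specificity(rec, meta)
        assert bool(s.per_model["tied_top"].iloc[0])
        assert s.percent_best_match == 100.0
        # now the matched group sorts second among tied groups
        meta2 = mf.SampleMetadata(meta.table.assign(
            tissue_group=meta.table["tissue_group"].replace({"alpha": "zeta"})
        ))
        rec2 = rec.assign(tissue_group=["zeta", "beta"])
        s2 = specificity(rec2, meta2)
        assert s2.percent_best_match == 0.0


class TestPcaQc:
    def test_explained_fractions_non_increasing(self, default_cohort):
        logm = default_cohort["log"]
        sub = logm.restrict_samples(list(logm.sample_ids[:40]))
        scores, frac = pca_qc(sub, default_cohort["meta"], n_components=5)
        assert np.all(np.diff(frac) <= 1e-12)
        assert frac.sum() <= 1.0 + 1e-9

    def test_single_varying_gene(self):
        vals = pd.DataFrame(
            {"a": [1.0, 5.0], "b": [1.0, 7.0], "c": [1.0, 9.0]},
            index=["g1", "g2"],
        )
        m = mf.ExpressionMatrix(vals, mf.Unit.log2tpm)
        _, frac = pca_qc(m, None, n_components=1)
        assert frac[0] == pytest.approx(1.0)

    def test_degenerate_and_contract_errors(self):
        vals = pd.DataFrame(
            {"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [1.0, 2.0]}, index=["g1", "g2"]
        )
        m = mf.ExpressionMatrix(vals, mf.Unit.log2tpm)
        with pytest.raises(ValueError, match="zero-variance"):
            pca_qc(m, None, n_components=1)
        with pytest.raises(ValueError, match="exceeds"):
            pca_qc(m, None, n_components=3)
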