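"""Gene-subset construction: variance ranking, purity detector, set algebra,
tissue-specific calling."""
import numpy as np
import pandas as pd
import pytest

import modelfidelity as mf


def _log_matrix(values: dict, genes):
    df = pd.DataFrame(values, index=genes)
    return mf.ExpressionMatrix(df, mf.Unit.log2tpm)


class TestTopVariableGenes:
    def test_only_varying_gene_selected(self):
        m = _log_matrix({"s1": [0, 5, 1], "s2": [10, 5, 1], "s3": [5, 5, 1]}, ["A", "B", "C"])
        sub = mf.top_variable_genes(m, 1)
        assert sub.gene_ids == ["A"]

    def test_k_equals_total_returns_all_in_variance_order(self):
        m = _log_matrix({"s1": [0, 5, 1], "s2": [10, 5, 3], "s3": [5, 5, 2]}, ["A", "B", "C"])
        sub = mf.top_variable_genes(m, 3)
        assert sub.gene_ids == ["A", "C", "B"]

    def test_tie_break_by_gene_id_ascending(self):
        # variances {4,3,3,1,0} with the variance-3 genes named g2, g9 and the
        # variance-4 gene g7; exhaustive sort oracle fixes the order (g7, g2)
        cols = {}
        base = {
            "g7": [0.0, 4.0],   # var 8 -> scaled below
            "g2": [0.0, 2.0],
            "g9": [0.0, 2.0],
            "g5": [0.0, 1.0],
            "g1": [1.0, 1.0],
        }
        df = pd.DataFrame(base, index=["s1", "s2"]).T
        df.columns = ["s1", "s2"]
        m = mf.ExpressionMatrix(df, mf.Unit.log2tpm)
        # need >= 3 samples for the operation; replicate s2
        df3 = df.copy()
        df3["s3"] = df3["s1"]
        m = mf.ExpressionMatrix(df3, mf.Unit.log2tpm)
        variances = df3.var(axis=1, ddof=1)
        oracle = sorted(df3.index, key=lambda g: (-variances[g], g))
        sub = mf.top_variable_genes(m, 2)
        assert sub.gene_ids == oracle[:2] == ["g7", "g2"]

    def test_nestedness(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n_genes = int(rng.integers(5, 25))
            df = pd.DataFrame(
                rng.integers(0, 8, size=(n_genes, 5)).astype(float),
                index=[f"g{i}" for i in range(n_genes)],
                columns=[f"s{j}" for j in range(5)],
            )
            m = mf.ExpressionMatrix(df, mf.Unit.log2tpm)
            ks = sorted(rng.choice(np.arange(1, n_genes + 1), size=3, replace=False))
            subs = [set(mf.top_variable_genes(m, int(k)).gene_ids) for k in ks]
            assert subs[0] <= subs[1] <= subs[2]

    def test_contract_errors(self):
        m = _log_matrix({"s1": [0, 1], "s2": [1, 2], "s3": [2, 0]}, ["A", "B"])
        with pytest.raises(ValueError, match="positive"):
            mf.top_variable_genes(m, 0)
        with pytest.raises(ValueError, match="exceeds"):
            mf.top_variable_genes(m, 5)
        with pytest.raises(ValueError, match=">= 3 samples"):
            mf.top_variable_genes(m, 1, sample_ids=["s1", "s2"])


class TestExcludeGenes:
    def test_difference_preserves_order(self):
        s = mf.GeneSubset("s", ["a", "b", "c"])
        out = mf.exclude_genes(s, mf.GeneSubset("x", ["b"]))
        assert out.gene_ids == ["a", "c"]
        assert out.provenance == "difference"

    def test_identity_and_self_difference(self):
        s = mf.GeneSubset("s", ["a", "b"])
        assert mf.exclude_genes(s, []).gene_ids == ["a", "b"]
        assert mf.exclude_genes(s, s).gene_ids == []

    def test_union_restores_membership(self):
        s = ["a", "b", "c", "d"]
        excl = ["b", "d", "zz"]
        out = mf.exclude_genes(s, excl)
        assert set(out.gene_ids) | (set(excl) & set(s)) == set(s)

    def test_empty_subset_rejected_downstream(self, default_cohort):
        tpm, meta = default_cohort["tpm"], default_cohort["meta"]
        all_genes = list(tpm.stripped_index())
        empty = mf.exclude_genes(all_genes, all_genes, name="empty")
        with pytest.raises(ValueError, match="only 0 genes"):
            mf.model_to_tissue(tpm, meta, subset=empty)


class TestPurityDetector:
    def test_perfect_monotone_gene_flagged(self):
        rng = np.random.default_rng(2)
        purity = np.linspace(0.3, 0.9, 12)
        genes = {"hit": purity * 100, "noise": rng.random(12)}
        df = pd.DataFrame(genes, index=[f"s{i}" for i in range(12)]).T
        m = mf.ExpressionMatrix(df, mf.Unit.tpm, validate_tpm_colsums=False)
        meta = mf.SampleMetadata(pd.DataFrame(
            [{"sample_id": f"s{i}", "source": "x", "tissue_group": "t",
              "disease_state": "tumor", "model_type": "tissue", "purity": purity[i]}
             for i in range(12)]
        ))
        res = mf.purity_correlated_genes(m, meta, min_samples=10)
        hit = res.per_cohort["t"].set_index("gene_id").loc["hit"]
        assert hit["rho"] == pytest.approx(1.0)
        assert bool(hit["flagged"])

    def test_constant_gene_undefined_never_flagged(self):
        purity = np.linspace(0.3, 0.9, 12)
        df = pd.DataFrame(
            {"flat": np.full(12, 10.0), "var": purity * 50},
            index=[f"s{i}" for i in range(12)],
        ).T
        m = mf.ExpressionMatrix(df, mf.Unit.tpm, validate_tpm_colsums=False)
        meta = mf.SampleMetadata(pd.DataFrame(
            [{"sample_id": f"s{i}", "source": "x", "tissue_group": "t",
              "disease_state": "tumor", "model_type": "tissue", "purity": purity[i]}
             for i in range(12)]
        ))
        res = mf.purity_correlated_genes(m, meta, min_samples=10)
        flat = res.per_cohort["t"].set_index("gene_id").loc["flat"]
        assert np.isnan(flat["rho"]) and not flat["flagged"]

    def test_constant_purity_errors(self):
        df = pd.DataFrame(
            np.arange(24, dtype=float).reshape(2, 12) + 1.0,
            index=["g1", "g2"], columns=[f"s{i}" for i in range(12)],
        )
        m = mf.ExpressionMatrix(df, mf.Unit.tpm, validate_tpm_colsums=False)
        meta = mf.SampleMetadata(pd.DataFrame(
            [{"sample_id": f"s{i}", "source": "x", "tissue_group": "t",
              "disease_state": "tumor", "model_type": "tissue", "purity": 0.5}
             for i in range(12)]
        ))
        with pytest.raises(ValueError, match="constant"):
            mf.purity_correlated_genes(m, meta, min_samples=10)

    def test_ground_truth_recovery(self, default_cohort):
        tpm, meta, truth = (
            default_cohort["tpm"], default_cohort["meta"], default_cohort["truth"],
        )
        res = mf.purity_correlated_genes(tpm, meta)
        flagged = set(res.union.gene_ids)
        true_set = set(truth.purity_direction.index)
        null_set = set(tpm.stripped_index()) - true_set
        assert len(flagged & true_set) / len(true_set) >= 0.90
        assert len(flagged & null_set) / len(null_set) <= 0.05


class TestTissueSpecificSets:
    def _meta(self, samples):
        return mf.SampleMetadata(pd.DataFrame(
            [{"sample_id": s, "source": "x", "tissue_group": t,
              "disease_state": "non_diseased", "model_type": "tissue"}
             for s, t in samples]
        ))

    def test_extreme_marker_called_high(self):
        # gene hot: mean 10 in tissue A, ~0 elsewhere (5 tissues)
        rng = np.random.default_rng(3)
        tissues = ["A", "B", "C", "D", "E"]
        samples = [(f"{t}{i}", t) for t in tissues for i in range(3)]
        vals = {}
        for s, t in samples:
            hot = 10.0 if t == "A" else rng.normal(0.0, 0.01)
            vals[s] = [hot, 5.0 + rng.normal(0, 0.01), rng.normal(0, 0.01)]
        df = pd.DataFrame(vals, index=["hot", "flatish", "zero"]).clip(lower=0)
        m = mf.ExpressionMatrix(df, mf.Unit.log2tpm)
        coll = mf.tissue_specific_sets(m, self._meta(samples), z_threshold=3.0)
        assert "hot" in coll["A_high"].genes
        for name in coll.names():
            assert "flatish" not in coll[name].genes

    def test_identical_means_in_no_set(self):
        tissues = ["A", "B", "C"]
        samples = [(f"{t}{i}", t) for t in tissues for i in range(3)]
        df = pd.DataFrame({s: [4.0, 2.0] for s, _ in samples}, index=["g1", "g2"])
        m = mf.ExpressionMatrix(df, mf.Unit.log2tpm)
        coll = mf.tissue_specific_sets(m, self._meta(samples))
        assert len(coll) == 0  # all-empty sets are dropped

    def test_single_tissue_errors(self):
        samples = [(f"A{i}", "A") for i in range(4)]
        df = pd.DataFrame({s: [1.0, 2.0] for s, _ in samples}, index=["g1", "g2"])
        m = mf.ExpressionMatrix(df, mf.Unit.log2tpm)
        with pytest.raises(ValueError, match=">= 2 tissue groups"):
            mf.tissue_specific_sets(m, self._meta(samples))

    def test_recovery_with_many_reference_tissues(self):
        # the z denominator is an s.d. over the other tissues' means, so the
        # caller is only well-posed with several reference tissues; at 8
        # tissues the true markers sit at ~3 s.d. while the background is
        # t-distributed with 6 d.f.
        cfg = mf.default_config(seed=1, n_tissues=8, genes_total=2000)
        counts, meta, truth = mf.simulate_cohort(cfg)
        logm = mf.log_transform(mf.counts_to_tpm(counts))
        coll = mf.tissue_specific_sets(logm, meta, z_threshold=3.0)
        recalls, precisions = [], []
        for t, genes in truth.tissue_specific_high.items():
            got = set(coll[f"{t}_high"].genes) if f"{t}_high" in coll.sets else set()
            true = set(genes)
            recalls.append(len(got & true) / len(true))
            precisions.append(len(got & true) / max(1, len(got)))
        # markers at exactly 3 s.d. give ~60% recall at z=3; precision is
        # ~30-fold enriched over the 1% marker prevalence
        assert np.mean(recalls) >= 0.5
        assert np.mean(precisions) >= 0.2
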