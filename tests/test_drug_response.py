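import numpy as np
import pandas as pd
import pytest

from codep.data_io import DrugResponseRaw, ExpressionMatrix
from codep.drug_response import (
    DrugResponseTable,
    coverage_filter,
    dedup_auc,
    drug_drug_correlations,
    rank_drugs_by_median_auc,
    sensitivity_signature,
    signature_gsea,
)
from codep.synthetic import simulate_drug_response, simulate_genesets


def _raw(rows):
    return DrugResponseRaw(table=pd.DataFrame(rows, columns=["drug", "cell_line", "auc"]))


class TestDedup:
    def test_discordant_duplicates_removed(self):
        t = dedup_auc(_raw([("d", "c", 0.50), ("d", "c", 0.75)]))
        assert np.isnan(t.auc).all()

    def test_concordant_duplicates_averaged(self):
        t = dedup_auc(_raw([("d", "c", 0.50), ("d", "c", 0.60)]))
        assert t.auc[0, 0] == pytest.approx(0.55)
        assert ("d", "c") in t.averaged

    def test_singletons_pass_through(self):
        t = dedup_auc(_raw([("d1", "c1", 0.3), ("d2", "c1", 0.9)]))
        assert t.auc[t.drug_ids.index("d1"), 0] == 0.3
        assert not t.averaged

    def test_range_exactly_at_threshold_is_kept(self):
        # strict "> 0.2": a range of exactly 0.2 still averages
        t = dedup_auc(_raw([("d", "c", 0.40), ("d", "c", 0.60)]))
        assert t.auc[0, 0] == pytest.approx(0.5)

    def test_three_replicates_use_full_range(self):
        t = dedup_auc(_raw([("d", "c", 0.40), ("d", "c", 0.50), ("d", "c", 0.65)]))
        assert np.isnan(t.auc[0, 0])  # max-min = 0.25 > 0.2

    def test_no_duplicates_identity(self):
        raw, _, _ = simulate_drug_response(n_drugs=5, n_lines=30, n_clusters=0,
                                           n_signature_genes=0, effect_size=0.0,
                                           dup_fraction=0.0, seed=1)
        t = dedup_auc(raw)
        assert np.isfinite(t.auc).all() and not t.averaged

    def test_planted_discordant_pairs_are_the_removed_ones(self):
        raw, _, truth = simulate_drug_response(n_drugs=6, n_lines=50, n_clusters=0,
                                               n_signature_genes=0, effect_size=0.0,
                                               dup_fraction=0.3, seed=2)
        t = dedup_auc(raw)
        removed = {
            (d, c)
            for i, d in enumerate(t.drug_ids)
            for j, c in enumerate(t.cell_line_ids)
            if np.isnan(t.auc[i, j])
        }
        assert removed == {tuple(p) for p in truth.extras["discordant_pairs"]}


class TestCoverage:
    def _table(self, n_measured, n_lines=100):
        auc = np.full((2, n_lines), np.nan)
        auc[0, :n_measured] = 0.5
        auc[1, :] = 0.5  # fully covered reference drug
        return DrugResponseTable(drug_ids=["probe", "ref"],
                                 cell_line_ids=[f"c{i}" for i in range(n_lines)], auc=auc)

    def test_sixty_nine_percent_dropped(self):
        t = coverage_filter(self._table(69))
        assert t.drug_ids == ["ref"]

    def test_seventy_percent_kept(self):
        t = coverage_filter(self._table(70))
        assert t.drug_ids == ["probe", "ref"]

    def test_min_frac_zero_is_identity(self):
        t = coverage_filter(self._table(1), min_frac=0.0)
        assert t.drug_ids == ["probe", "ref"]

    def test_all_dropped_errors(self):
        auc = np.full((1, 10), np.nan)
        auc[0, 0] = 0.5
        t = DrugResponseTable(["d"], [f"c{i}" for i in range(10)], auc)
        with pytest.raises(ValueError, match="every drug"):
            coverage_filter(t)

    def test_dedup_then_filter_idempotent(self):
        raw, _, _ = simulate_drug_response(n_drugs=8, n_lines=60, n_clusters=1,
                                           n_signature_genes=4, effect_size=0.5,
                                           dup_fraction=0.2, seed=3)
        t1 = coverage_filter(dedup_auc(raw))
        t2 = coverage_filter(t1)
        assert t1.drug_ids == t2.drug_ids
        assert np.array_equal(t1.auc, t2.auc, equal_nan=True)


class TestRanking:
    def test_single_drug_rank_one(self):
        t = DrugResponseTable(["d"], ["c1", "c2"], np.array([[0.4, 0.6]]))
        df = rank_drugs_by_median_auc(t)
        assert df.iloc[0]["rank"] == 1

    def test_three_drug_ordering(self):
        t = DrugResponseTable(
            ["mid", "weak", "strong"], ["c1"],
            np.array([[0.5], [0.9], [0.2]]),
        )
        df = rank_drugs_by_median_auc(t)
        assert df["drug"].tolist() == ["strong", "mid", "weak"]
        assert df["rank"].tolist() == [1, 2, 3]

    def test_matches_brute_force_sort_on_random_tables(self, rng):
        for _ in range(100):
            n_d, n_l = int(rng.integers(2, 10)), int(rng.integers(3, 12))
            auc = rng.random((n_d, n_l))
            drugs = [f"d{i}" for i in range(n_d)]
            t = DrugResponseTable(drugs, [f"c{i}" for i in range(n_l)], auc)
            df = rank_drugs_by_median_auc(t)
            med = {d: np.median(auc[i]) for i, d in enumerate(drugs)}
            expect = sorted(drugs, key=lambda d: (med[d], d))
            assert df["drug"].tolist() == expect


class TestDrugCorrelations:
    def test_duplicated_drug_mutual_top_partner(self, rng):
        auc = rng.random((3, 40))
        auc[1] = auc[0]
        t = DrugResponseTable(["a", "a2", "other"], [f"c{i}" for i in range(40)], auc)
        res = drug_drug_correlations(t)
        assert res.most_similar["a"] == ("a2", pytest.approx(1.0))
        assert res.most_similar["a2"][0] == "a"

    def test_planted_cluster_recovered_as_one_clade(self):
        raw, _, truth = simulate_drug_response(n_drugs=12, n_lines=300, n_clusters=1,
                                               n_signature_genes=0, effect_size=0.0,
                                               dup_fraction=0.0, seed=5)
        t = coverage_filter(dedup_auc(raw))
        res = drug_drug_correlations(t)
        members = truth.extras["drug_clusters"][0]
        cut = res.clustered.cut(2)
        assert len({cut[d] for d in members}) == 1
        others = [d for d in t.drug_ids if d not in members]
        assert {cut[d] for d in others} != {cut[members[0]]}

    def test_cluster_members_mutual_top3_partners(self):
        raw, _, truth = simulate_drug_response(n_drugs=12, n_lines=300, n_clusters=1,
                                               n_signature_genes=0, effect_size=0.7,
                                               dup_fraction=0.0, seed=6)
        t = coverage_filter(dedup_auc(raw))
        res = drug_drug_correlations(t)
        members = truth.extras["drug_clusters"][0]
        for d in members:
            i = t.drug_ids.index(d)
            order = np.argsort(-np.nan_to_num(res.rho[i], nan=-2))
            top3 = {t.drug_ids[j] for j in order[:4] if t.drug_ids[j] != d}
            assert set(members) - {d} <= top3

    def test_line_permutation_invariance(self, rng):
        raw, _, _ = simulate_drug_response(n_drugs=5, n_lines=60, n_clusters=1,
                                           n_signature_genes=0, effect_size=0.0,
                                           dup_fraction=0.0, seed=7)
        t = dedup_auc(raw)
        perm = rng.permutation(len(t.cell_line_ids))
        t_p = DrugResponseTable(list(t.drug_ids),
                                [t.cell_line_ids[i] for i in perm], t.auc[:, perm])
        a = drug_drug_correlations(t)
        b = drug_drug_correlations(t_p)
        assert np.allclose(a.rho, b.rho, atol=1e-12)


class TestSensitivitySignature:
    def test_planted_genes_recovered(self):
        raw, expr, truth = simulate_drug_response(n_drugs=10, n_lines=300, n_clusters=1,
                                                  n_signature_genes=20, effect_size=0.7,
                                                  dup_fraction=0.0, seed=8)
        t = coverage_filter(dedup_auc(raw))
        lead = truth.extras["drug_clusters"][0][0]
        sig = sensitivity_signature(t, lead, expr)
        assert truth.sensitivity_genes[lead] <= set(sig.genes("sensitivity"))
        assert truth.resistance_genes[lead] <= set(sig.genes("resistance"))

    def test_gene_equal_to_auc_is_resistance_with_rho_one(self):
        rng = np.random.default_rng(9)
        auc = rng.random((1, 40))
        t = DrugResponseTable(["d"], [f"c{i}" for i in range(40)], auc)
        values = np.vstack([auc[0], rng.random(40)])
        expr = ExpressionMatrix(["MIRROR", "NOISE"], [f"c{i}" for i in range(40)], values)
        sig = sensitivity_signature(t, "d", expr)
        row = sig.table.set_index("gene").loc["MIRROR"]
        assert row["rho"] == pytest.approx(1.0)
        assert row["class"] == "resistance"

    def test_null_effect_rarely_calls_genes(self):
        false_reps = 0
        for seed in range(20):
            raw, expr, truth = simulate_drug_response(
                n_drugs=6, n_lines=100, n_clusters=1, n_signature_genes=10,
                effect_size=0.0, dup_fraction=0.0, seed=100 + seed,
            )
            t = coverage_filter(dedup_auc(raw))
            lead = truth.extras["drug_clusters"][0][0]
            sig = sensitivity_signature(t, lead, expr)
            if sig.genes("sensitivity") or sig.genes("resistance"):
                false_reps += 1
        assert false_reps <= 4  # BH controls the family-wise call rate near alpha

    def test_absent_drug_errors(self):
        raw, expr, _ = simulate_drug_response(n_drugs=4, n_lines=60, n_clusters=0,
                                              n_signature_genes=0, effect_size=0.0,
                                              dup_fraction=0.0, seed=10)
        t = dedup_auc(raw)
        with pytest.raises(KeyError):
            sensitivity_signature(t, "NOT_A_DRUG", expr)


class TestSignatureGsea:
    def _signature(self, seed=11):
        raw, expr, truth = simulate_drug_response(n_drugs=8, n_lines=300, n_clusters=1,
                                                  n_signature_genes=20, effect_size=0.7,
                                                  dup_fraction=0.0, seed=seed,
                                                  n_background_genes=200)
        t = coverage_filter(dedup_auc(raw))
        lead = truth.extras["drug_clusters"][0][0]
        return sensitivity_signature(t, lead, expr), truth, lead

    def test_set_of_planted_sensitivity_genes_positively_enriched(self):
        from codep.data_io import GeneSetCollection

        sig, truth, lead = self._signature()
        rng = np.random.default_rng(12)
        sens = sorted(truth.sensitivity_genes[lead])
        background = [g for g in sig.table["gene"] if not g.startswith("SIG")]
        sets = {"PLANTED": sens}
        for i in range(10):
            sets[f"RAND{i}"] = list(rng.choice(background, size=10, replace=False))
        coll = GeneSetCollection(sets=sets, descriptions={k: "" for k in sets})
        res = signature_gsea(sig, coll, n_perm=500, seed=13)
        by = {r.set_name: r for r in res}
        assert by["PLANTED"].nes > 0 and by["PLANTED"].q < 0.1
        assert max(res, key=lambda r: r.nes).set_name == "PLANTED"

    def test_negating_rho_flips_all_nes_signs(self):
        sig, truth, lead = self._signature(seed=14)
        sets, _ = simulate_genesets(list(sig.table["gene"]), n_sets=8, set_size=10, seed=15)
        res_a = signature_gsea(sig, sets, n_perm=200, seed=16)
        flipped = sig.table.copy()
        flipped["rho"] = -flipped["rho"]
        sig_b = type(sig)(drug_id=sig.drug_id, alpha=sig.alpha, table=flipped)
        res_b = signature_gsea(sig_b, sets, n_perm=200, seed=16)
        a = {r.set_name: r.es for r in res_a}
        b = {r.set_name: r.es for r in res_b}
        for name in a:
            assert a[name] == pytest.approx(-b[name], abs=1e-12)

    def test_same_seed_identical(self):
        sig, _, _ = self._signature(seed=17)
        sets, _ = simulate_genesets(list(sig.table["gene"]), n_sets=8, set_size=10, seed=18)
        from codep.gsea import results_to_frame

        r1 = signature_gsea(sig, sets, n_perm=200, seed=19)
        r2 = signature_gsea(sig, sets, n_perm=200, seed=19)
        assert results_to_frame(r1).equals(results_to_frame(r2))
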