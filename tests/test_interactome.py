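import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirlink import de, interactome, io, simulate


def _counts_from_rows(ids, rows, samples=None):
    rows = np.asarray(rows)
    if samples is None:
        samples = [f"s{i}" for i in range(rows.shape[1])]
    return io.CountMatrix(ids, samples, rows)


def _with_anchors(feature_id, row, n_anchors=3):
    """A matrix whose size factors are exactly 1: the varying feature plus
    constant anchor features dominating the ratio median."""
    rows = [row] + [[100] * len(row)] * n_anchors
    ids = [feature_id] + [f"anchor{i}" for i in range(n_anchors)]
    return _counts_from_rows(ids, rows)


class TestCorrelatePairs:
    def test_perfect_anticorrelation(self):
        """Profiles that are exact mirror images on the log scale give
        r = -1; counts are 2^v - 1 so log2(count + 1) hits v exactly."""
        v = np.arange(1, 8)
        mirna = _with_anchors("m", (2.0**v - 1).astype(int))
        mrna = _with_anchors("g", (2.0 ** v[::-1] - 1).astype(int))
        recs = interactome.correlate_pairs(mirna, mrna, mirna_ids=["m"],
                                           gene_ids=["g"])
        assert recs["r"].iloc[0] == pytest.approx(-1.0, abs=1e-9)
        assert recs["pvalue"].iloc[0] < 1e-6

    def test_hand_computed_product_moment(self):
        """r for x=[1,2,3], y=[1,3,2] is 0.5 by the product-moment formula;
        counts are planted so the expression transform reproduces x and y."""
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 3.0, 2.0])
        r_manual = np.sum((x - 2) * (y - 2)) / np.sqrt(
            np.sum((x - 2) ** 2) * np.sum((y - 2) ** 2)
        )
        assert r_manual == pytest.approx(0.5)
        mirna = _with_anchors("m", (2.0**x - 1).astype(int))
        mrna = _with_anchors("g", (2.0**y - 1).astype(int))
        recs = interactome.correlate_pairs(mirna, mrna, mirna_ids=["m"],
                                           gene_ids=["g"])
        assert recs["r"].iloc[0] == pytest.approx(0.5, abs=1e-9)
        n = 3
        t = 0.5 * np.sqrt((n - 2) / (1 - 0.25))
        assert recs["pvalue"].iloc[0] == pytest.approx(2 * stats.t.sf(t, n - 2))

    def test_zero_variance_flagged_not_dropped(self):
        mirna = _counts_from_rows(
            ["m1", "m2", "a1", "a2"],
            [[5, 5, 5, 5], [1, 9, 3, 7], [100] * 4, [100] * 4],
        )
        mrna = _with_anchors("g", [2, 8, 4, 6])
        recs = interactome.correlate_pairs(mirna, mrna, mirna_ids=["m1", "m2"],
                                           gene_ids=["g"])
        flat = recs[recs["mirna_id"] == "m1"]
        assert flat["flagged"].all()
        assert flat["r"].isna().all()
        assert not recs[recs["mirna_id"] == "m2"]["flagged"].any()

    def test_too_few_samples_rejected(self):
        mirna = _counts_from_rows(["m"], [[1, 2]])
        mrna = _counts_from_rows(["g"], [[2, 1]])
        with pytest.raises(ValueError, match=">= 3"):
            interactome.correlate_pairs(mirna, mrna)

    def test_per_group_scope_restricts_samples(self, small_cohort):
        mrna, mirna, meta, _, _ = small_cohort
        pooled = interactome.correlate_pairs(mirna, mrna, meta,
                                             mirna_ids=[mirna.feature_ids[0]])
        vcm = interactome.correlate_pairs(mirna, mrna, meta, scope="VCM",
                                          mirna_ids=[mirna.feature_ids[0]])
        assert pooled["n"].iloc[0] == 7
        assert vcm["n"].iloc[0] == 4
        assert (vcm["scope"] == "VCM").all()

    def test_planted_pair_recovered_in_most_seeds(self):
        """Coupling at -1.5 drives the planted pair's r below -0.7 in at
        least 90% of 200 seeds (low dispersion, 4 + 3 samples)."""
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            config = simulate.SimConfig(
                seed=seed, n_genes=30, n_mirnas=10, n_de_genes=5, n_de_mirnas=1,
                n_repressive_pairs=1, dispersion=0.01,
            )
            mrna, mirna, meta, truth = simulate.generate_paired_counts(config)
            mir, gene, _ = truth.repressive_pairs[0]
            recs = interactome.correlate_pairs(mirna, mrna, meta,
                                               mirna_ids=[mir], gene_ids=[gene])
            hits += recs["r"].iloc[0] < -0.7
        assert hits / n_rep >= 0.90

    def test_matches_brute_force_on_small_input(self):
        """On <= 5 features per side the vectorized screen equals pairwise
        scipy.stats.pearsonr on the same transformed expression."""
        rng = np.random.default_rng(0)
        mirna = _counts_from_rows([f"m{i}" for i in range(4)],
                                  rng.poisson(100, size=(4, 6)))
        mrna = _counts_from_rows([f"g{i}" for i in range(5)],
                                 rng.poisson(100, size=(5, 6)))
        recs = interactome.correlate_pairs(mirna, mrna)
        expr_m = interactome.normalized_log_expression(mirna)
        expr_g = interactome.normalized_log_expression(mrna)
        for mi, gi in itertools.product(range(4), range(5)):
            r, p = stats.pearsonr(expr_m.iloc[mi], expr_g.iloc[gi])
            row = recs[(recs["mirna_id"] == f"m{mi}") & (recs["gene_id"] == f"g{gi}")]
            assert row["r"].iloc[0] == pytest.approx(r, abs=1e-9)
            assert row["pvalue"].iloc[0] == pytest.approx(p, abs=1e-9)


class TestFilterNegative:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "n", "r",
                                           "pvalue", "scope", "flagged"])

    def test_strict_boundaries(self):
        recs = self._records([
            ("m", "g1", 7, -0.69, 0.01, "pooled", False),   # r gate
            ("m", "g2", 7, -0.70, 0.01, "pooled", False),   # r exactly at bound
            ("m", "g3", 7, -0.90, 0.20, "pooled", False),   # p gate
            ("m", "g4", 7, -0.90, 0.05, "pooled", False),   # p exactly at bound
            ("m", "g5", 7, -0.90, 0.01, "pooled", False),   # passes
        ])
        kept = interactome.filter_negative(recs)
        assert list(kept["gene_id"]) == ["g5"]

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        recs = self._records([
            ("m", f"g{i}", 7, rng.uniform(-1, 1), rng.uniform(0, 1), "pooled", False)
            for i in range(50)
        ])
        once = interactome.filter_negative(recs)
        twice = interactome.filter_negative(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_flagged_records_never_pass(self):
        recs = self._records([("m", "g", 7, -0.9, 0.001, "pooled", True)])
        assert interactome.filter_negative(recs).empty

    def test_positive_threshold_warns(self):
        recs = self._records([("m", "g", 7, 0.9, 0.001, "pooled", False)])
        with pytest.warns(UserWarning, match="positive"):
            kept = interactome.filter_negative(recs, r_max=0.95)
        assert len(kept) == 1


class TestMergeEvidence:
    def _record(self, mirna, gene, r=-0.9, p=0.01):
        return pd.DataFrame(
            [{"mirna_id": mirna, "gene_id": gene, "n": 7, "r": r, "pvalue": p,
              "scope": "pooled", "flagged": False}]
        )

    def test_validated_pair_retained(self):
        evidence = io.load_table3_evidence()
        edges = interactome.merge_evidence(
            self._record("hsa-miR-218-5p", "DDX6"), evidence
        )
        assert len(edges) == 1
        assert edges[0].validated
        assert "mirtarbase" in set(edges[0].evidence["database"])

    def test_prediction_count_gate(self):
        evidence = io.load_table3_evidence()
        rec = self._record("hsa-miR-218-5p", "TTC39C")
        at_one = interactome.merge_evidence(rec, evidence, min_predicted_dbs=1)
        at_three = interactome.merge_evidence(rec, evidence, min_predicted_dbs=3)
        assert len(at_one) == 1 and at_one[0].n_predicted_dbs == 1
        assert at_three == []

    def test_pair_absent_from_evidence_gives_no_edge(self):
        evidence = io.load_table3_evidence()
        assert interactome.merge_evidence(self._record("hsa-miR-218-5p", "NOPE"),
                                          evidence) == []

    def test_matching_by_accession_and_case(self):
        evidence = io.load_table3_evidence()
        edges = interactome.merge_evidence(self._record("mimat0000275", "ddx6"),
                                           evidence)
        assert len(edges) == 1

    def test_output_independent_of_evidence_row_order(self):
        evidence = io.load_table3_evidence()
        reversed_ev = io.TargetEvidenceTable(evidence.frame.iloc[::-1].reset_index(drop=True))
        rec = pd.concat([self._record("hsa-miR-218-5p", "DDX6"),
                         self._record("hsa-miR-494-3p", "SGMS2")], ignore_index=True)
        a = interactome.merge_evidence(rec, evidence)
        b = interactome.merge_evidence(rec, reversed_ev)
        assert [(e.mirna_id, e.gene_id, e.validated, e.n_predicted_dbs) for e in a] == [
            (e.mirna_id, e.gene_id, e.validated, e.n_predicted_dbs) for e in b
        ]


class TestBuildNetwork:
    def test_published_table_summary_after_dedup(self):
        """Passing every printed evidence pair through yields 5 miRNAs,
        18 genes, 21 unique edges (one pair is listed in two databases)."""
        evidence = io.load_table3_evidence()
        pairs = evidence.unique_pairs()
        records = pd.DataFrame(
            {"mirna_id": pairs["mirna_id"], "gene_id": pairs["target_symbol"],
             "n": 7, "r": -0.8, "pvalue": 0.01, "scope": "pooled", "flagged": False}
        )
        edges = interactome.merge_evidence(records, evidence)
        with pytest.warns(UserWarning, match="direction unknown"):
            graph, summary = interactome.build_network(edges)
        assert summary == {"n_mirnas": 5, "n_genes": 18, "n_edges": 21}

    def test_empty_edge_list(self):
        graph, summary = interactome.build_network([])
        assert summary == {"n_mirnas": 0, "n_genes": 0, "n_edges": 0}
        assert graph.number_of_nodes() == 0

    def test_directions_from_de_tables(self, small_cohort):
        mrna, mirna, meta, truth, evidence = small_cohort
        gene_de = de.de_test(mrna, meta)
        mirna_de = de.de_test(mirna, meta)
        recs = interactome.correlate_pairs(mirna, mrna, meta,
                                           mirna_ids=sorted(truth.de_mirnas))
        edges = interactome.merge_evidence(interactome.filter_negative(recs), evidence)
        if edges:
            graph, _ = interactome.build_network(edges, gene_de, mirna_de)
            for node, data in graph.nodes(data=True):
                assert data["direction"] in {"up", "down"}

    def test_pipeline_recovery_monotone_in_coupling(self):
        """Recall of planted pairs through the full screen rises with
        coupling strength (weak vs strong, 30 seeds each)."""
        def recall(strength):
            found = 0
            total = 0
            for seed in range(30):
                config = simulate.SimConfig(
                    seed=seed, n_genes=200, n_mirnas=40, n_de_genes=20,
                    coupling_strength=strength, latent_sd=0.2,
                    lfc_range=(0.8, 1.0),
                )
                mrna, mirna, meta, truth = simulate.generate_paired_counts(config)
                recs = interactome.correlate_pairs(
                    mirna, mrna, meta, mirna_ids=sorted(truth.de_mirnas))
                kept = interactome.filter_negative(recs)
                kept_pairs = set(zip(kept["mirna_id"], kept["gene_id"]))
                planted = {(m, g) for m, g, _ in truth.repressive_pairs}
                found += len(planted & kept_pairs)
                total += len(planted)
            return found / total

        assert recall(-0.2) < recall(-2.0)
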