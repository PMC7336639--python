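import numpy as np
import pandas as pd
import pytest

from myocomm.de import DEGParams
from myocomm.io import LRPair
from myocomm.lr import (
    de_receptors,
    export_chord_edges,
    flag_ligand_specificity,
    rank_de_receptors,
    score_focal_population,
    score_interactions,
    zscore_rows,
)
from myocomm.simulate import LRCircuit, SynthSpec, generate_dataset
from myocomm.preprocess import log_normalize
from conftest import make_normalized


def toy_matrix():
    """Receptor REC has mean 2.0 in the focal type; ligand LIG has means
    1, 2, 3 in the three senders (values are already log-scale means)."""
    # columns: F, F, S1, S1, S2, S2, S3, S3
    vals = np.array(
        [
            [2.0, 2.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],  # REC
            [0.0, 0.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0],  # LIG
        ]
    )
    nm = make_normalized(vals, genes=["REC", "LIG"])
    labels = np.array(["F", "F", "S1", "S1", "S2", "S2", "S3", "S3"])
    return nm, labels


class TestScoreInteractions:
    def test_product_arithmetic(self):
        nm, labels = toy_matrix()
        t = score_interactions(nm, labels, "F", {"REC"}, [LRPair("LIG", "REC")])
        assert t.sender.tolist() == ["S1", "S2", "S3"]
        assert t.raw_score.tolist() == pytest.approx([2.0, 4.0, 6.0])

    def test_zero_ligand_gives_zero_score(self):
        nm, labels = toy_matrix()
        t = score_interactions(nm, labels, "F", {"LIG"}, [LRPair("REC", "LIG")])
        # focal mean of receptor LIG is 0 -> every sender scores 0
        assert (t.raw_score == 0).all()

    def test_bilinearity_in_one_sender(self):
        nm, labels = toy_matrix()
        t1 = score_interactions(nm, labels, "F", {"REC"}, [LRPair("LIG", "REC")])
        vals = nm.dense()
        vals[1, labels == "S2"] *= 3.0
        nm2 = make_normalized(vals, genes=nm.genes)
        t2 = score_interactions(nm2, labels, "F", {"REC"}, [LRPair("LIG", "REC")])
        ratio = t2.raw_score.to_numpy() / t1.raw_score.to_numpy()
        assert ratio == pytest.approx([1.0, 3.0, 1.0])

    def test_ungated_receptor_skipped_and_empty_ok(self):
        nm, labels = toy_matrix()
        t = score_interactions(nm, labels, "F", set(), [LRPair("LIG", "REC")])
        assert t.empty

    def test_autocrine_excluded_by_default(self):
        nm, labels = toy_matrix()
        t = score_interactions(nm, labels, "F", {"REC"}, [LRPair("LIG", "REC")])
        assert "F" not in set(t.sender)
        t2 = score_interactions(
            nm, labels, "F", {"REC"}, [LRPair("LIG", "REC")], include_autocrine=True
        )
        assert "F" in set(t2.sender)


class TestZscoreRows:
    def make_table(self, raws):
        return pd.DataFrame(
            {
                "pair_name": "L_R",
                "ligand": "L",
                "receptor": "R",
                "focal": "F",
                "sender": [f"S{i}" for i in range(len(raws))],
                "raw_score": raws,
                "z_score": np.nan,
                "ligand_de": False,
                "receptor_de": True,
            }
        )

    def test_hand_computed_rows(self):
        assert zscore_rows(self.make_table([2.0, 4.0, 6.0])).z_score.tolist() == pytest.approx(
            [-1.0, 0.0, 1.0]
        )
        assert zscore_rows(self.make_table([5.0, 5.0, 5.0])).z_score.tolist() == [0, 0, 0]
        assert zscore_rows(self.make_table([0.0, 2.0])).z_score.tolist() == pytest.approx(
            [-0.7071, 0.7071], abs=1e-4
        )

    def test_singleton_row_zero(self):
        assert zscore_rows(self.make_table([3.0])).z_score.tolist() == [0.0]

    def test_invariant_to_positive_row_scaling(self):
        t1 = zscore_rows(self.make_table([1.0, 3.0, 8.0]))
        t2 = zscore_rows(self.make_table([2.5, 7.5, 20.0]))
        assert np.allclose(t1.z_score, t2.z_score)

    def test_nonconstant_rows_standardized(self, rng):
        raws = rng.gamma(1, 1, size=7)
        z = zscore_rows(self.make_table(list(raws))).z_score.to_numpy()
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


def planted_dataset(seed=0):
    spec = SynthSpec(
        n_donors=2,
        cells_per_donor_mean=500,
        cells_per_donor_sd=0,
        n_populations=5,
        population_names=["Focal", "Sender", "O1", "O2", "O3"],
        n_genes=300,
        baseline_mean=2.0,
        marker_genes_per_population=4,
        donor_depth_sigma=0.0,
        lr_circuits=[LRCircuit("LIGX", "RECX", "Sender", "Focal", 8.0)],
        seed=seed,
    )
    cm, meta, truth = generate_dataset(spec)
    return log_normalize(cm), meta["population"].to_numpy()


class TestDEReceptors:
    def test_universe_disjoint_from_matrix_empty(self):
        nm, labels = toy_matrix()
        assert de_receptors(nm, labels, "F", {"NOPE1", "NOPE2"}) == set()

    def test_planted_receptor_gated_in(self):
        nm, labels = planted_dataset()
        hits = de_receptors(nm, labels, "Focal", {"RECX", "LIGX"})
        assert "RECX" in hits
        assert "LIGX" not in hits  # elevated in Sender, not Focal

    def test_pairwise_all_mode_is_stricter(self):
        nm, labels = planted_dataset()
        ovr = de_receptors(nm, labels, "Focal", {"RECX"})
        pw = de_receptors(nm, labels, "Focal", {"RECX"}, pairwise_all=True)
        assert pw <= ovr
        assert "RECX" in pw  # fold 8 wins every pairwise comparison too


class TestFlagLigand:
    def test_uniform_ligand_not_flagged(self):
        nm, labels = toy_matrix()
        vals = nm.dense()
        vals[1] = 1.5  # ligand identical everywhere
        nm2 = make_normalized(vals, genes=nm.genes)
        t = score_interactions(nm2, labels, "F", {"REC"}, [LRPair("LIG", "REC")])
        t = flag_ligand_specificity(t, nm2, labels)
        assert not t.ligand_de.any()

    def test_planted_sender_ligand_flagged_only_there(self):
        nm, labels = planted_dataset()
        t = score_focal_population(nm, labels, "Focal", [LRPair("LIGX", "RECX")])
        flagged = t[t.ligand_de]
        assert set(flagged.sender) == {"Sender"}


class TestRankReceptors:
    def test_empty_table(self):
        panel = rank_de_receptors(pd.DataFrame(columns=["gene", "avg_log2fc", "q_value"]), {"R1"})
        assert panel.empty

    def test_sort_and_significance_flags(self):
        deg = pd.DataFrame(
            {
                "gene": ["R2", "R1", "LIG"],
                "avg_log2fc": [-0.5, 1.0, 2.0],
                "q_value": [0.2, 0.01, 0.001],
            }
        )
        panel = rank_de_receptors(deg, {"R1", "R2"})
        assert panel.gene.tolist() == ["R1", "R2"]
        assert panel.significant.tolist() == [True, False]


class TestChordExport:
    def test_empty_tables_give_header_only(self):
        edges = export_chord_edges({})
        assert edges.empty
        assert "sender" in edges.columns and "significant" in edges.columns

    def test_edge_count_one_pair_two_senders(self):
        vals = np.array(
            [
                [2.0, 0.0, 0.0],  # REC in F
                [0.0, 1.0, 2.0],  # LIG in S1, S2
            ]
        )
        nm = make_normalized(vals, genes=["REC", "LIG"])
        labels = np.array(["F", "S1", "S2"])
        t = score_interactions(nm, labels, "F", {"REC"}, [LRPair("LIG", "REC")])
        edges = export_chord_edges({"F": zscore_rows(t)})
        assert len(edges) == 2
        assert set(edges.receiver) == {"F"}
        assert edges.significant.all()

    def test_significant_count_matches_brute_force(self):
        nm, labels = planted_dataset()
        pairs = [LRPair("LIGX", "RECX"), LRPair("G00001", "G00002")]
        tables = {
            f: score_focal_population(nm, labels, f, pairs, gate_receptors=False)
            for f in ["Focal", "Sender"]
        }
        edges = export_chord_edges(tables)
        # brute force: per focal, gated pairs with ligand present x senders
        expected = 0
        for f, t in tables.items():
            gated_pairs = t[t.receptor_de][["pair_name", "sender"]].drop_duplicates()
            expected += len(gated_pairs)
        assert int(edges.significant.sum()) == expected


def test_removing_sender_leaves_other_raw_scores_unchanged():
    nm, labels = toy_matrix()
    t_full = score_interactions(nm, labels, "F", {"REC"}, [LRPair("LIG", "REC")])
    keep = labels != "S3"
    import scipy.sparse as sp

    nm_sub = make_normalized(nm.dense()[:, keep], genes=nm.genes)
    t_sub = score_interactions(nm_sub, labels[keep], "F", {"REC"}, [LRPair("LIG", "REC")])
    merged = t_full.merge(t_sub, on="sender", suffixes=("_full", "_sub"))
    assert np.allclose(merged.raw_score_full, merged.raw_score_sub)
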