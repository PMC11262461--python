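"""IO round-trips, the one-hot transform and the quality filters."""

import numpy as np
import pandas as pd
import pytest
import scipy.io
import scipy.sparse as sp

from spatialccc.readwrite import (
    RESULT_COLUMNS,
    cell_type_matrix,
    load_dataset,
    qc_filter,
    read_expression,
    read_lr_database,
    read_results,
    write_results,
)
from spatialccc.simulate import SimulationConfig, simulate_dataset, write_dataset


class TestReadExpression:
    def test_all_zero_csv(self, tmp_path):
        path = tmp_path / "expr.csv"
        pd.DataFrame(
            np.zeros((2, 3)), index=["G1", "G2"], columns=["u1", "u2", "u3"]
        ).to_csv(path)
        mat, genes, units = read_expression(path)
        assert mat.shape == (2, 3)
        assert not mat.any()
        assert genes == ["G1", "G2"] and units == ["u1", "u2", "u3"]

    def test_mtx_triplet(self, tmp_path):
        coo = sp.coo_matrix(([5.0, 1.5], ([0, 1], [0, 2])), shape=(2, 3))
        path = tmp_path / "expr.mtx"
        scipy.io.mmwrite(path, coo)
        (tmp_path / "genes.txt").write_text("G1\nG2\n")
        (tmp_path / "barcodes.txt").write_text("u1\nu2\nu3\n")
        mat, genes, units = read_expression(path)
        np.testing.assert_array_equal(mat, [[5, 0, 0], [0, 0, 1.5]])
        assert genes == ["G1", "G2"] and units == ["u1", "u2", "u3"]

    def test_mtx_sidecar_mismatch(self, tmp_path):
        coo = sp.coo_matrix(np.ones((2, 3)))
        scipy.io.mmwrite(tmp_path / "expr.mtx", coo)
        (tmp_path / "genes.txt").write_text("G1\n")
        (tmp_path / "barcodes.txt").write_text("u1\nu2\nu3\n")
        with pytest.raises(ValueError, match="sidecars"):
            read_expression(tmp_path / "expr.mtx")

    def test_duplicate_genes_summed(self, tmp_path):
        path = tmp_path / "expr.csv"
        path.write_text("gene,u1,u2,u3\nGeneA,1,0,2\nGeneB,5,5,5\nGeneA,0,1,0\n")
        mat, genes, _ = read_expression(path)
        # oracle: independent read-then-groupby-sum
        raw = pd.read_csv(path, index_col=0)
        oracle = raw.groupby(raw.index, sort=False).sum()
        assert genes == list(oracle.index)
        np.testing.assert_allclose(mat, oracle.to_numpy())
        np.testing.assert_array_equal(mat[genes.index("GeneA")], [1, 1, 2])

    def test_negative_entry_named(self, tmp_path):
        path = tmp_path / "expr.csv"
        path.write_text("gene,u1,u2\nG1,1,2\nG2,3,-4\n")
        with pytest.raises(ValueError, match="G2.*u2"):
            read_expression(path)


class TestLRDatabase:
    def test_complex_parsing(self, tmp_path):
        path = tmp_path / "lr.csv"
        path.write_text("ligand,receptor,pathway\nLama1,Itga6_Itgb1,LAMININ\n")
        db = read_lr_database(path)
        pair = db.pairs[0]
        assert pair.ligand_genes == ["Lama1"]
        assert pair.receptor_genes == ["Itga6", "Itgb1"]
        assert pair.pathway == "LAMININ"

    def test_empty_pathway_defaults(self, tmp_path):
        path = tmp_path / "lr.csv"
        path.write_text("ligand,receptor,pathway\nA,B,\n")
        assert read_lr_database(path).pairs[0].pathway == "unassigned"

    def test_row_with_empty_receptor_dropped(self, tmp_path):
        path = tmp_path / "lr.csv"
        path.write_text("ligand,receptor,pathway\nA,B,p1\nC,,p2\nD,E,p3\n")
        db = read_lr_database(path)
        assert len(db) == 2
        assert [p.pair_id for p in db] == ["A→B", "D→E"]

    def test_duplicate_pair_id_rejected(self, tmp_path):
        path = tmp_path / "lr.csv"
        path.write_text("ligand,receptor\nA,B\nA,B\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_lr_database(path)


class TestCellTypeMatrix:
    def test_one_hot_definition(self):
        mat, names = cell_type_matrix(["A", "A", "B"])
        np.testing.assert_array_equal(mat, [[1, 0], [1, 0], [0, 1]])
        assert names == ["A", "B"]

    def test_single_class(self):
        mat, names = cell_type_matrix(["X"])
        np.testing.assert_array_equal(mat, [[1.0]])
        assert names == ["X"]

    def test_column_sums_match_class_counts(self, rng):
        labels = [f"c{k}" for k in rng.integers(0, 5, size=1000)]
        mat, names = cell_type_matrix(labels)
        np.testing.assert_array_equal(mat.sum(axis=1), np.ones(1000))
        tally = {n: labels.count(n) for n in names}  # independent tally
        np.testing.assert_array_equal(mat.sum(axis=0), [tally[n] for n in names])

    def test_missing_label_named(self):
        with pytest.raises(ValueError, match="index 1"):
            cell_type_matrix(["A", "", "B"])


class TestQCFilter:
    def test_cell_threshold(self, rng):
        n_genes = 300
        expr = np.zeros((n_genes, 3))
        for c, k in enumerate((150, 99, 200)):
            expr[rng.choice(n_genes, size=k, replace=False), c] = 1.0
        _, _, cells = qc_filter(expr, min_genes_per_cell=100,
                                min_frac_cells_per_gene=0.0)
        np.testing.assert_array_equal(cells, [0, 2])

    def test_rare_gene_dropped(self):
        expr = np.ones((2, 100))
        expr[1] = 0.0
        expr[1, 0] = 1.0  # expressed in 1% of cells < 2.5%
        _, genes, _ = qc_filter(expr, min_genes_per_cell=0,
                                min_frac_cells_per_gene=0.025)
        np.testing.assert_array_equal(genes, [0])

    def test_matches_two_pass_loop_oracle(self, rng):
        expr = (rng.random((50, 40)) < 0.3).astype(float)
        _, genes, cells = qc_filter(expr, min_genes_per_cell=5,
                                    min_frac_cells_per_gene=0.1)
        # brute-force oracle: explicit two-pass loop
        keep_cells = [
            c for c in range(40) if sum(expr[g, c] > 0 for g in range(50)) >= 5
        ]
        keep_genes = [
            g
            for g in range(50)
            if sum(expr[g, c] > 0 for c in keep_cells) / len(keep_cells) >= 0.1
        ]
        np.testing.assert_array_equal(cells, keep_cells)
        np.testing.assert_array_equal(genes, keep_genes)

    def test_idempotent(self, rng):
        expr = (rng.random((60, 50)) < 0.2) * rng.random((60, 50))
        once, g1, c1 = qc_filter(expr, 5, 0.1)
        twice, g2, c2 = qc_filter(once, 5, 0.1)
        np.testing.assert_array_equal(once, twice)
        np.testing.assert_array_equal(g2, np.arange(len(g1)))

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError, match="no cell"):
            qc_filter(np.zeros((5, 5)), min_genes_per_cell=1,
                      min_frac_cells_per_gene=0.0)


class TestResultsRoundTrip:
    def _random_table(self, rng, n=100):
        return pd.DataFrame(
            {
                "ligand": [f"L{i}" for i in range(n)],
                "receptor": [f"R{i}" for i in range(n)],
                "pathway": "p",
                "sender_type": "A",
                "receiver_type": "B",
                "estimate": rng.normal(size=n),
                "std_error": rng.random(n),
                "p_value": rng.random(n),
                "p_adjusted": rng.random(n),
                "rho_selected": 0.5,
                "converged": True,
            }
        )

    def test_header_and_single_row(self, tmp_path, rng):
        path = tmp_path / "res.tsv"
        write_results(self._random_table(rng, n=1), path)
        lines = path.read_text().splitlines()
        assert len(lines) == 2
        assert lines[0].split("\t") == RESULT_COLUMNS

    def test_nan_estimate_written_as_na(self, tmp_path, rng):
        table = self._random_table(rng, n=2)
        table.loc[0, ["estimate", "std_error", "p_value", "p_adjusted"]] = np.nan
        table.loc[0, "converged"] = False
        path = tmp_path / "res.tsv"
        write_results(table, path)
        first_data = path.read_text().splitlines()[1].split("\t")
        assert first_data[5] == "NA"
        assert first_data[-1] == "false"
        back = read_results(path)
        assert np.isnan(back.loc[0, "estimate"])
        assert back.loc[0, "converged"] == False  # noqa: E712

    def test_round_trip_to_1e12(self, tmp_path, rng):
        table = self._random_table(rng)
        path = tmp_path / "res.tsv"
        write_results(table, path)
        back = read_results(path)
        for col in ("estimate", "std_error", "p_value", "p_adjusted"):
            np.testing.assert_allclose(back[col], table[col], atol=1e-12, rtol=0)

    def test_empty_rejected(self, tmp_path, rng):
        with pytest.raises(ValueError, match="empty"):
            write_results(self._random_table(rng).iloc[:0], tmp_path / "x.tsv")


class TestDatasetRoundTrip:
    def test_simulated_dataset_round_trips_through_readers(self, tmp_path, small_sim):
        paths = write_dataset(small_sim, tmp_path)
        ds = load_dataset(
            paths["expression"],
            paths["coordinates"],
            cell_types_path=paths["cell_types"],
        )
        orig = small_sim.dataset
        np.testing.assert_allclose(np.asarray(ds.expr), np.asarray(orig.expr),
                                   rtol=1e-12)
        np.testing.assert_allclose(ds.coords, orig.coords, rtol=1e-12)
        np.testing.assert_array_equal(ds.composition, orig.composition)
        assert ds.type_names == orig.type_names

    def test_spot_dataset_round_trip(self, tmp_path):
        sim = simulate_dataset(
            SimulationConfig(n_units=40, G=3, resolution="spot", dmax=3.0, seed=2)
        )
        paths = write_dataset(sim, tmp_path)
        ds = load_dataset(
            paths["expression"],
            paths["coordinates"],
            proportions_path=paths["proportions"],
        )
        np.testing.assert_allclose(ds.composition, sim.dataset.composition,
                                   atol=1e-12)
        assert ds.resolution == "spot"
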