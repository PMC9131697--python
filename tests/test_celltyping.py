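import numpy as np
import pandas as pd
import pytest

import issmap as im
from issmap.celltyping import assign_spots_to_cells, compute_type_posteriors

from _oracles import all_pairs_nearest, posterior_by_enumeration


def cells_frame(coords):
    return pd.DataFrame({"cell_id": np.arange(1, len(coords) + 1),
                         "x_um": [c[0] for c in coords],
                         "y_um": [c[1] for c in coords],
                         "area_um2": 80.0, "region": "R"})


def spots_frame(rows):
    return pd.DataFrame(rows, columns=["spot_id", "gene", "x_um", "y_um"])


class TestAssignSpots:
    def test_nearest_within_radius(self):
        cells = cells_frame([(0.0, 0.0), (50.0, 0.0)])
        spots = spots_frame([(1, "g1", 1.0, 0.0)])
        assignment, counts = assign_spots_to_cells(spots, cells, 10.0,
                                                   gene_ids=("g1",))
        assert assignment.loc[1] == 1
        assert counts.loc[1, "g1"] == 1

    def test_radius_cut_sends_spot_to_background(self):
        cells = cells_frame([(0.0, 0.0)])
        spots = spots_frame([(1, "g1", 11.0, 0.0)])
        assignment, counts = assign_spots_to_cells(spots, cells, 10.0,
                                                   gene_ids=("g1",))
        assert assignment.loc[1] == 0
        assert counts.to_numpy().sum() == 0

    def test_empty_cell_table_warns_not_raises(self):
        spots = spots_frame([(1, "g1", 0.0, 0.0)])
        with pytest.warns(UserWarning):
            assignment, _ = assign_spots_to_cells(spots, cells_frame([]), 10.0,
                                                  gene_ids=("g1",))
        assert (assignment == 0).all()

    def test_matches_all_pairs_search(self, rng):
        pts = rng.uniform(0, 500, size=(40, 2))
        cells = cells_frame([tuple(p) for p in pts])
        sxy = rng.uniform(0, 500, size=(1000, 2))
        spots = pd.DataFrame({"spot_id": np.arange(1, 1001),
                              "gene": "g1", "x_um": sxy[:, 0], "y_um": sxy[:, 1]})
        assignment, _ = assign_spots_to_cells(spots, cells, 15.0,
                                              gene_ids=("g1",))
        from scipy.spatial.distance import cdist
        d = cdist(sxy, pts)
        expect = np.where(d.min(axis=1) <= 15.0,
                          cells["cell_id"].to_numpy()[d.argmin(axis=1)], 0)
        assert np.array_equal(assignment.to_numpy(), expect)

    def test_unknown_gene_rejected(self):
        spots = spots_frame([(1, "nope", 0.0, 0.0)])
        with pytest.raises(ValueError):
            assign_spots_to_cells(spots, cells_frame([(0, 0)]), 10.0,
                                  gene_ids=("g1",))


class TestPosteriors:
    @pytest.fixture(scope="class")
    def tiny_profiles(self):
        return im.make_reference_profiles(n_types=3, markers_per_type=2,
                                          n_shared_genes=1, marker_level=2.0,
                                          off_level=0.0, seed=0)

    def test_marker_counts_concentrate_on_their_type(self, tiny_profiles):
        counts = pd.DataFrame(0, index=[1],
                              columns=list(tiny_profiles.gene_ids))
        first_marker = tiny_profiles.gene_ids[0]  # dedicated to type 0
        counts.loc[1, first_marker] = 10
        post = compute_type_posteriors(counts, tiny_profiles)
        assert post.columns[post.loc[1].argmax()] == tiny_profiles.type_ids[0]
        assert post.loc[1].iloc[0] > 0.99

    def test_zero_counts_returns_prior(self, tiny_profiles):
        counts = pd.DataFrame(0, index=[1, 2],
                              columns=list(tiny_profiles.gene_ids))
        prior = np.array([0.5, 0.3, 0.2])
        post = compute_type_posteriors(counts, tiny_profiles, prior=prior)
        assert np.allclose(post.to_numpy(), np.tile(prior, (2, 1)))

    def test_rows_normalize(self, typed_demo):
        post = typed_demo["typing"].posterior.to_numpy()
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_enumeration_oracle(self, rng):
        # random small instances against the literal Poisson enumeration
        for _ in range(10):
            n_genes = int(rng.integers(3, 6))
            n_types = int(rng.integers(2, 4))
            expr = rng.uniform(0.0, 3.0, size=(n_genes, n_types))
            expr[0, :] = rng.uniform(0.5, 3.0, n_types)  # pan row positive
            prof = im.ReferenceProfiles(
                tuple(f"g{i}" for i in range(n_genes)),
                tuple(f"T{k}" for k in range(n_types)), expr, "g0")
            counts = pd.DataFrame(rng.poisson(2.0, size=(4, n_genes)),
                                  columns=list(prof.gene_ids))
            prior = rng.dirichlet(np.ones(n_types))
            post = compute_type_posteriors(counts, prof, prior=prior,
                                           pseudocount=1e-3)
            for c in range(4):
                row = counts.iloc[c].to_numpy()
                if row.sum() == 0:
                    continue
                expect = posterior_by_enumeration(row, expr, prior, 1e-3)
                assert np.allclose(post.iloc[c].to_numpy(), expect,
                                   rtol=1e-12, atol=1e-300)

    def test_gene_axis_mismatch_rejected(self, tiny_profiles):
        counts = pd.DataFrame(0, index=[1], columns=["x", "y"])
        with pytest.raises(ValueError):
            compute_type_posteriors(counts, tiny_profiles)


class TestCallCells:
    def make_typing(self, posts, pans, types=("A", "B")):
        idx = np.arange(1, len(posts) + 1)
        counts = pd.DataFrame({"Plp1": pans}, index=pd.Index(idx, name="cell_id"))
        posterior = pd.DataFrame(posts, index=idx, columns=list(types))
        return im.TypingResult(counts, posterior,
                               pd.Series(dtype=int))

    def cells(self, n):
        return pd.DataFrame({"cell_id": np.arange(1, n + 1), "x_um": 0.0,
                             "y_um": 0.0, "area_um2": 80.0, "region": "R"})

    def test_argmax_call_and_probability(self):
        typing = self.make_typing([[0.6, 0.4]], [3])
        called = im.call_cells(typing, self.cells(1), "Plp1")
        assert called.loc[0, "called_type"] == "A"
        assert called.loc[0, "max_probability"] == pytest.approx(0.6)

    def test_pan_gate_excludes_zero_count_cells(self):
        typing = self.make_typing([[0.6, 0.4], [0.9, 0.1]], [0, 2])
        called = im.call_cells(typing, self.cells(2), "Plp1")
        assert list(called["cell_id"]) == [2]

    def test_exact_tie_goes_to_earlier_type(self):
        typing = self.make_typing([[0.5, 0.5]], [1])
        called = im.call_cells(typing, self.cells(1), "Plp1")
        assert called.loc[0, "called_type"] == "A"

    def test_min_probability_filter(self):
        typing = self.make_typing([[0.7, 0.3], [0.45, 0.55]], [1, 1])
        called = im.call_cells(typing, self.cells(2), "Plp1",
                               min_probability=0.6)
        assert list(called["cell_id"]) == [1]

    def test_typing_recovery_on_default_tissue(self, typed_demo):
        called = typed_demo["called"]
        truth = typed_demo["tissue"].cells[["cell_id", "true_type"]]
        merged = called.merge(truth, on="cell_id")
        assert (merged["called_type"] == merged["true_type"]).mean() >= 0.90

    def test_accuracy_nondecreasing_in_transcript_yield(self):
        profiles = im.make_reference_profiles(seed=1)
        layout = im.make_layout("brain_coronal", 300.0)
        spec = {"CTX": dict.fromkeys(profiles.type_ids, 1 / 13),
                "CC": dict.fromkeys(profiles.type_ids, 1 / 13)}
        accs = []
        for mean_tx in (6.0, 12.0, 24.0):
            params = im.SimulationParams(cell_density=400.0,
                                         mean_transcripts=mean_tx)
            accs_seed = []
            for seed in (0, 1, 2):
                tissue = im.simulate_tissue(profiles, layout, spec, params, seed)
                _, counts = im.assign_spots_to_cells(
                    tissue.spots, tissue.cells, 15.0, gene_ids=profiles.gene_ids)
                post = im.compute_type_posteriors(counts, profiles)
                typing = im.TypingResult(counts, post, pd.Series(dtype=int))
                called = im.call_cells(typing, tissue.cells, "Plp1")
                merged = called.merge(tissue.cells[["cell_id", "true_type"]],
                                      on="cell_id")
                accs_seed.append((merged.called_type == merged.true_type).mean())
            accs.append(np.mean(accs_seed))
        assert accs[0] <= accs[1] <= accs[2]

    def test_low_certainty_fraction_is_small(self, typed_demo):
        called = typed_demo["called"]
        assert (called["max_probability"] < 0.5).mean() <= 0.05


class TestPieChartsAndConfusion:
    def make(self, posts, types=("A", "B", "C")):
        idx = np.arange(1, len(posts) + 1)
        counts = pd.DataFrame({"Plp1": np.ones(len(posts), dtype=int)},
                              index=pd.Index(idx, name="cell_id"))
        posterior = pd.DataFrame(posts, index=idx, columns=list(types))
        typing = im.TypingResult(counts, posterior, pd.Series(dtype=int))
        cells = pd.DataFrame({"cell_id": idx, "x_um": 0.0, "y_um": 0.0,
                              "area_um2": 80.0, "region": "R"})
        called = im.call_cells(typing, cells, "Plp1")
        return typing, called

    def test_one_hot_posteriors_give_identity(self):
        typing, called = self.make([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        mat = im.mean_pie_charts(typing, called)
        assert np.allclose(mat.to_numpy(), np.eye(3))

    def test_mean_is_arithmetic(self):
        typing, called = self.make([[0.8, 0.2], [0.6, 0.4]], types=("A", "B"))
        with pytest.warns(UserWarning):  # no cells called B
            mat = im.mean_pie_charts(typing, called)
        assert np.allclose(mat.loc["A"], [0.7, 0.3])
        assert mat.loc["B"].isna().all()

    def test_diagonal_dominance_on_simulated_tissue(self, typed_demo):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mat = im.mean_pie_charts(typed_demo["typing"], typed_demo["called"])
        mat = mat.dropna(how="all")
        for t in mat.index:
            row = mat.loc[t]
            assert row[t] > row.drop(t).max()

    def test_confusion_renormalizes_losers(self):
        typing, called = self.make([[0.7, 0.2, 0.1]])
        conf = im.confusion_matrix(typing, called)
        assert np.allclose(conf.loc["A"], [0.0, 2 / 3, 1 / 3])

    def test_confusion_rows_sum_to_one_where_defined(self, typed_demo):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            conf = im.confusion_matrix(typed_demo["typing"], typed_demo["called"])
        defined = conf.dropna(how="all")
        if len(defined):
            assert np.allclose(defined.sum(axis=1), 1.0, atol=1e-9)
            assert np.allclose(np.diag(defined.reindex(columns=defined.index)), 0.0)

    def test_all_one_hot_rows_flagged(self):
        typing, called = self.make([[1.0, 0.0, 0.0]])
        with pytest.warns(UserWarning):
            conf = im.confusion_matrix(typing, called)
        assert conf.loc["A"].isna().all()
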