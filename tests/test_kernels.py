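"""Kernels: marker QC, genomic G, pedigree A (vs gene-dropping Monte Carlo),
incidence maps, and interaction covariances."""

import numpy as np
import pandas as pd
import pytest

import wheatgp as wg
from wheatgp.containers import MarkerMatrix, Pedigree
from wheatgp.exceptions import (
    DegenerateKernelError,
    PedigreeCycleError,
    ValidationError,
)
from wheatgp.kernels import expand_to_records


def _matrix_from_freqs():
    """10 lines, 6 markers with MAFs {0, .05, .05, .25, .5} plus one 60%
    missing; frequencies are exact by construction (20 alleles/marker)."""
    doses = np.zeros((10, 6))
    doses[:, 1] = [1] + [0] * 9                      # MAF 0.05
    doses[:, 2] = [1] + [0] * 9                      # MAF 0.05 (boundary)
    doses[:, 3] = [2, 2, 1, 0, 0, 0, 0, 0, 0, 0]     # MAF 0.25
    doses[:, 4] = [2, 2, 2, 2, 2, 0, 0, 0, 0, 0]     # MAF 0.50
    doses[:, 5] = [0, 1, 2, 1] + [np.nan] * 6        # 60% missing
    return MarkerMatrix([f"l{i}" for i in range(10)],
                        [f"m{j}" for j in range(6)], doses)


class TestFilterMarkers:
    def test_qc_rules_enumerated(self):
        m = _matrix_from_freqs()
        kept = wg.filter_markers(m, maf_min=0.05, max_missing=0.5)
        # monomorphic m0 and 60%-missing m5 removed; boundary MAF retained
        assert list(kept.marker_ids) == ["m1", "m2", "m3", "m4"]

    def test_monomorphic_removed(self):
        m = MarkerMatrix(["a", "b"], ["m0", "m1"],
                         np.array([[0.0, 1.0], [0.0, 1.0]]))
        kept = wg.filter_markers(m, maf_min=0.0)
        assert list(kept.marker_ids) == []

    def test_clean_mapped_panel_passes_through(self, small_sim):
        m = small_sim.markers
        kept = wg.filter_markers(m, maf_min=0.0, max_missing=1.0,
                                 gmap=small_sim.gmap)
        poly = np.minimum(m.allele_freq(), 1 - m.allele_freq()) > 0
        assert kept.n_markers == int(poly.sum())

    def test_map_restriction(self):
        m = _matrix_from_freqs()
        gmap = pd.DataFrame({"marker": ["m3"], "chromosome": "1",
                             "cM": [0.0], "Mb": [0.0]})
        kept = wg.filter_markers(m, gmap=gmap)
        assert list(kept.marker_ids) == ["m3"]


class TestImpute:
    def test_no_missing_unchanged(self):
        m = MarkerMatrix(["a", "b"], ["m"], np.array([[0.0], [2.0]]))
        assert np.array_equal(wg.impute_missing(m).doses, m.doses)

    def test_mean_dose_imputation(self):
        m = MarkerMatrix(["a", "b", "c"], ["m"],
                         np.array([[0.0], [2.0], [np.nan]]))
        imp = wg.impute_missing(m)
        assert imp.doses[2, 0] == pytest.approx(1.0)

    def test_frequencies_preserved(self, small_sim):
        ped = small_sim.pedigree
        m = wg.simulate_markers(ped, 200, wg.make_genetic_map(200, 5, 150.0, 1),
                                missing_rate=0.2, seed=3)
        before = m.allele_freq()
        after = wg.impute_missing(m).allele_freq()
        assert np.allclose(before, after)

    def test_fully_missing_marker_named(self):
        m = MarkerMatrix(["a", "b"], ["mbad"],
                         np.array([[np.nan], [np.nan]]))
        with pytest.raises(ValidationError, match="mbad"):
            wg.impute_missing(m)


class TestGenomicRelationship:
    def test_two_line_hand_example(self):
        m = MarkerMatrix(["l1", "l2"], ["m"], np.array([[0.0], [2.0]]))
        G = wg.genomic_relationship(m)  # printed scaling
        assert np.allclose(G.values, [[1.0, -1.0], [-1.0, 1.0]])

    def test_printed_scale_is_half_vanraden(self, small_sim):
        m = wg.impute_missing(small_sim.markers)
        gp = wg.genomic_relationship(m, scale="printed")
        gv = wg.genomic_relationship(m, scale="vanraden")
        assert np.allclose(2.0 * gp.values, gv.values)

    def test_duplicated_lines_share_rows(self):
        rng = np.random.default_rng(0)
        doses = rng.integers(0, 3, size=(4, 60)).astype(float)
        doses[3] = doses[0]
        m = MarkerMatrix(["a", "b", "c", "a2"], [f"m{i}" for i in range(60)],
                         doses)
        G = wg.genomic_relationship(m).to_frame()
        assert np.allclose(G.loc["a"], G.loc["a2"])
        assert G.loc["a", "a"] == pytest.approx(G.loc["a2", "a2"])

    def test_random_panel_psd_and_diagonal(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.9, 500)
        doses = (rng.random((50, 500)) < p).astype(float) + (
            rng.random((50, 500)) < p)
        m = MarkerMatrix([f"l{i}" for i in range(50)],
                         [f"m{j}" for j in range(500)], doses)
        G = wg.genomic_relationship(m, scale="vanraden")
        assert G.min_eigenvalue_ratio() >= -1e-8
        assert 0.8 <= np.diag(G.values).mean() <= 1.2

    def test_marker_order_and_allele_flip_invariance(self):
        rng = np.random.default_rng(2)
        doses = rng.integers(0, 3, size=(8, 40)).astype(float)
        ids = [f"m{j}" for j in range(40)]
        m = MarkerMatrix([f"l{i}" for i in range(8)], ids, doses)
        perm = rng.permutation(40)
        m_perm = MarkerMatrix(m.line_ids, np.asarray(ids, object)[perm],
                              doses[:, perm])
        m_flip = MarkerMatrix(m.line_ids, ids, 2.0 - doses)
        G = wg.genomic_relationship(m).values
        assert np.allclose(G, wg.genomic_relationship(m_perm).values)
        assert np.allclose(G, wg.genomic_relationship(m_flip).values)

    def test_monomorphic_panel_rejected(self):
        m = MarkerMatrix(["a", "b"], ["m"], np.array([[2.0], [2.0]]))
        with pytest.raises(DegenerateKernelError):
            wg.genomic_relationship(m)


def _gene_drop_relationship(rel, n_rep=200_000, seed=0):
    """Monte-Carlo oracle: fraction of alleles identical by descent between
    two non-inbred relatives, via single-locus gene dropping."""
    rng = np.random.default_rng(seed)
    founders = np.arange(8).reshape(4, 2)  # 4 unrelated founders x 2 alleles

    def gamete(parent_alleles):
        return parent_alleles[np.arange(n_rep), rng.integers(0, 2, n_rep)]

    f = {i: np.tile(founders[i], (n_rep, 1)) for i in range(4)}
    c1 = np.column_stack([gamete(f[0]), gamete(f[1])])
    if rel == "full_sibs":
        c2 = np.column_stack([gamete(f[0]), gamete(f[1])])
    elif rel == "half_sibs":
        c2 = np.column_stack([gamete(f[0]), gamete(f[2])])
    elif rel == "parent_offspring":
        c2 = f[0]  # compare the child against its first parent
    else:
        raise ValueError(rel)
    # kinship = P(two random alleles IBD); numerator relationship = 2 x kinship
    ibd = np.zeros(n_rep)
    for i in range(2):
        for j in range(2):
            ibd += (c1[:, i] == c2[:, j]) / 4.0
    return 2.0 * ibd.mean()


class TestPedigreeAdditive:
    def test_founders_only_identity(self):
        ped = Pedigree(["a", "b", "c"], [None] * 3, [None] * 3)
        A = wg.pedigree_additive_matrix(ped)
        assert np.allclose(A.values, np.eye(3))

    def test_tabular_values_match_gene_dropping(self):
        ped = Pedigree(
            ["p1", "p2", "p3", "p4", "s1", "s2", "h1"],
            [None, None, None, None, "p1", "p1", "p1"],
            [None, None, None, None, "p2", "p2", "p3"],
        )
        A = wg.pedigree_additive_matrix(ped).to_frame()
        assert A.loc["p1", "s1"] == pytest.approx(0.5)     # parent-offspring
        assert A.loc["s1", "s2"] == pytest.approx(0.5)     # full sibs
        assert A.loc["s1", "h1"] == pytest.approx(0.25)    # half sibs
        assert A.loc["s1", "s1"] == pytest.approx(1.0)     # non-inbred
        # Monte-Carlo gene-dropping oracle
        assert _gene_drop_relationship("full_sibs") == pytest.approx(
            A.loc["s1", "s2"], abs=0.01)
        assert _gene_drop_relationship("half_sibs") == pytest.approx(
            A.loc["s1", "h1"], abs=0.01)
        assert _gene_drop_relationship("parent_offspring") == pytest.approx(
            A.loc["p1", "s1"], abs=0.01)

    def test_cycle_detected(self):
        with pytest.raises(PedigreeCycleError):
            Pedigree(["a", "b"], ["b", "a"], [None, None])

    def test_pedigree_consistent_markers_converge_g_to_a(self):
        """mean |G - A| shrinks as the marker panel grows."""
        ped = wg.simulate_pedigree(20, 100, 3, seed=5)
        A = wg.pedigree_additive_matrix(ped).values
        diffs = {}
        for n_mark in (200, 2000):
            gmap = wg.make_genetic_map(n_mark, 10, 150.0, seed=5)
            m = wg.simulate_markers(ped, n_mark, gmap, seed=5)
            G = wg.genomic_relationship(m, scale="vanraden").values
            off = ~np.eye(100, dtype=bool)
            diffs[n_mark] = np.abs(G - A)[off].mean()
        assert diffs[2000] < diffs[200]


class TestIncidenceAndInteraction:
    def test_single_environment_column_of_ones(self, toy_records):
        sub = toy_records[toy_records["environment"] == "e1"]
        inc = wg.incidence_matrices(sub)
        assert np.array_equal(inc.Z_E, np.ones((len(sub), 1)))

    def test_permutation_invariance_and_counts(self, toy_records):
        inc = wg.incidence_matrices(toy_records)
        shuffled = wg.incidence_matrices(
            toy_records.sample(frac=1, random_state=1))
        assert np.allclose(inc.Z_L.T @ inc.Z_L, shuffled.Z_L.T @ shuffled.Z_L)
        counts = toy_records.groupby("line").size()
        assert np.allclose(inc.Z_L.T @ np.ones(len(toy_records)),
                           counts[list(inc.line_ids)].to_numpy())

    def test_interaction_matches_brute_force(self):
        rec = pd.DataFrame({
            "line": ["a", "b", "c", "a", "b", "c"],
            "environment": ["e1"] * 3 + ["e2"] * 3,
            "replicate": "r1", "trait": "AC", "value": 0.0,
        })
        K = wg.Kernel(["a", "b", "c"], np.array([
            [1.0, 0.4, 0.1], [0.4, 1.0, 0.2], [0.1, 0.2, 1.0]]))
        inc = wg.incidence_matrices(rec, line_ids=K.ids)
        ik = wg.interaction_kernel(K, inc)
        Kdf = K.to_frame()
        expected = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                if rec["environment"][i] == rec["environment"][j]:
                    expected[i, j] = Kdf.loc[rec["line"][i], rec["line"][j]]
        assert np.allclose(ik.values, expected)
        assert ik.is_psd()
        # records of the same line in different environments are independent
        assert ik.values[0, 3] == 0.0

    def test_single_environment_interaction_equals_main(self, toy_records):
        sub = toy_records[toy_records["environment"] == "e1"]
        K = wg.Kernel(["l1", "l2", "l3"],
                      np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.2],
                                [0.0, 0.2, 1.0]]))
        inc = wg.incidence_matrices(sub, line_ids=K.ids)
        ik = wg.interaction_kernel(K, inc)
        assert np.allclose(ik.values, expand_to_records(K, inc))

    def test_kernels_are_psd(self, small_sim):
        G = wg.genomic_relationship(wg.impute_missing(small_sim.markers),
                                    scale="vanraden")
        A = wg.pedigree_additive_matrix(small_sim.pedigree)
        assert G.is_psd() and A.is_psd()
        inc = wg.incidence_matrices(small_sim.records, line_ids=G.ids)
        assert wg.interaction_kernel(G, inc).is_psd()
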