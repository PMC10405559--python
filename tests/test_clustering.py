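"""Spectral clustering: binned vectors, similarity, greedy partition, consensus."""

import math

import numpy as np
import pytest

import metaspectra as ms
from metaspectra.clustering import (
    ClusterParams,
    preprocess_vector,
    similarity,
    spectrum_vector,
)

from conftest import make_spectrum, random_spectra


class TestPreprocessVector:
    def test_single_peak_unit(self):
        vec = preprocess_vector(np.array([500.0]), np.array([123.0]))
        assert list(vec.values()) == [1.0]

    def test_two_equal_peaks(self):
        vec = preprocess_vector(np.array([100.0, 200.0]), np.array([4.0, 4.0]))
        assert sorted(vec.values()) == pytest.approx([1 / math.sqrt(2)] * 2)

    def test_bin_collision_sums(self):
        vec = preprocess_vector(
            np.array([100.2, 100.7]), np.array([9.0, 16.0]), bin_width=1.0
        )
        assert list(vec.keys()) == [100]
        assert list(vec.values()) == [1.0]

    def test_top_n_selection(self):
        mz = np.arange(100.0, 200.0, 1.0)
        inten = np.arange(1.0, 101.0)
        vec = preprocess_vector(mz, inten, top_n_peaks=10)
        assert len(vec) == 10
        assert min(vec.keys()) == 190  # the 10 most intense peaks

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            preprocess_vector(np.array([]), np.array([]))


class TestSimilarity:
    def test_self_similarity_is_one(self, rng):
        for sp in random_spectra(rng, 5):
            vec = spectrum_vector(sp, ClusterParams())
            assert similarity(vec, vec) == pytest.approx(1.0)

    def test_disjoint_bins_zero(self):
        assert similarity({1: 1.0}, {2: 1.0}) == 0.0

    def test_half_overlap(self):
        # A={100,200}, B={100,300}, equal intensities: (1/sqrt2)*(1/sqrt2)
        a = preprocess_vector(np.array([100.0, 200.0]), np.array([1.0, 1.0]))
        b = preprocess_vector(np.array([100.0, 300.0]), np.array([1.0, 1.0]))
        assert similarity(a, b) == pytest.approx(0.5)

    def test_symmetric_and_bounded(self, rng):
        spectra = random_spectra(rng, 20)
        params = ClusterParams()
        vecs = [spectrum_vector(sp, params) for sp in spectra]
        for i in range(len(vecs)):
            for j in range(i, len(vecs)):
                s = similarity(vecs[i], vecs[j])
                assert 0.0 <= s <= 1.0
                assert s == pytest.approx(similarity(vecs[j], vecs[i]))


class TestNeutralMass:
    def test_doubly_charged(self):
        assert ms.neutral_mass(500.25, 2) == pytest.approx(998.48544)

    def test_singly_charged_identity(self):
        m = 723.4
        assert ms.neutral_mass(m, 1) == pytest.approx(m - 1.00728)

    def test_zero_charge_errors(self):
        with pytest.raises(ValueError):
            ms.neutral_mass(500.0, 0)

    def test_absent_charge_directs_to_policy(self):
        with pytest.raises(ValueError, match="default"):
            ms.neutral_mass(500.0, None)


class TestBuildConsensus:
    def test_singleton_identity(self):
        sp = make_spectrum("a", [100.0, 200.0], [5.0, 7.0])
        cons = ms.build_consensus([sp])
        assert [(p.mz, p.intensity) for p in cons.peaks] == [(100.0, 5.0), (200.0, 7.0)]
        assert cons.replicate_count == 1
        assert cons.precursor_mz == sp.precursor_mz

    def test_two_identical_replicates(self):
        a = make_spectrum("a", [100.0, 200.0], [5.0, 7.0])
        b = make_spectrum("b", [100.0, 200.0], [5.0, 7.0])
        cons = ms.build_consensus([a, b])
        assert cons.replicate_count == 2
        assert [(p.mz, p.intensity) for p in cons.peaks] == [(100.0, 5.0), (200.0, 7.0)]

    def test_minority_peak_dropped(self):
        shared = ([100.0, 200.0], [5.0, 5.0])
        a = make_spectrum("a", *shared)
        b = make_spectrum("b", *shared)
        c = make_spectrum("c", [100.0, 200.0, 300.0], [5.0, 5.0, 9.0])
        cons = ms.build_consensus([a, b, c], ClusterParams(min_peak_fraction=0.5))
        # 300.0 occurs in 1 of 3 members; needs ceil(0.5*3)=2
        assert [p.mz for p in cons.peaks] == pytest.approx([100.0, 200.0])

    def test_absent_counts_as_zero_in_mean(self):
        a = make_spectrum("a", [100.0, 200.0], [6.0, 3.0])
        b = make_spectrum("b", [100.0], [12.0])
        cons = ms.build_consensus([a, b], ClusterParams(min_peak_fraction=0.5))
        by_bin = {round(p.mz): p.intensity for p in cons.peaks}
        assert by_bin[100] == pytest.approx(9.0)   # (6 + 12) / 2
        # 200 occurs in 1 of 2 members, which meets ceil(0.5 * 2) = 1, so it is
        # retained with the absent member contributing zero: (3 + 0) / 2
        assert by_bin[200] == pytest.approx(1.5)

    def test_member_order_invariance(self, rng):
        members = random_spectra(rng, 4)
        for m in members:
            m.precursor_mz = 500.0
            m.charge = 2
        c1 = ms.build_consensus(list(members))
        c2 = ms.build_consensus(list(reversed(members)))
        assert [(p.mz, p.intensity) for p in c1.peaks] == [
            (p.mz, p.intensity) for p in c2.peaks
        ]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ms.build_consensus([])


class TestClusterSpectra:
    def test_single_spectrum_singleton(self):
        sp = make_spectrum("only", np.linspace(100, 900, 20), np.ones(20))
        (cluster,) = ms.cluster_spectra([sp])
        assert cluster.member_ids == ["only"]
        assert cluster.consensus.replicate_count == 1

    def test_identical_spectra_merge(self):
        mz, inten = np.linspace(100, 900, 20), np.ones(20)
        a = make_spectrum("a", mz, inten)
        b = make_spectrum("b", mz, inten)
        (cluster,) = ms.cluster_spectra([a, b])
        assert sorted(cluster.member_ids) == ["a", "b"]

    def test_charge_rule_separates(self):
        mz, inten = np.linspace(100, 900, 20), np.ones(20)
        a = make_spectrum("a", mz, inten, charge=2)
        b = make_spectrum("b", mz, inten, charge=3)
        clusters = ms.cluster_spectra([a, b], ClusterParams(require_same_charge=True))
        assert len(clusters) == 2
        clusters = ms.cluster_spectra([a, b], ClusterParams(require_same_charge=False))
        assert len(clusters) == 1

    def test_empty_input(self):
        assert ms.cluster_spectra([]) == []

    def test_duplicate_ids_rejected(self):
        sp = make_spectrum("dup", [100.0], [1.0])
        with pytest.raises(ValueError):
            ms.cluster_spectra([sp, sp])

    def test_partition_invariant(self, clustered_dataset):
        _, kept, _, clusters, _ = clustered_dataset
        all_ids = [sid for c in clusters for sid in c.member_ids]
        assert len(all_ids) == len(kept)
        assert len(set(all_ids)) == len(all_ids)
        assert sum(c.consensus.replicate_count for c in clusters) == len(kept)

    def test_members_similar_to_own_consensus(self, clustered_dataset):
        """Every non-singleton member scores >= threshold vs its consensus."""
        _, kept, _, clusters, _ = clustered_dataset
        params = ClusterParams()
        by_id = {s.spectrum_id: s for s in kept}
        for c in clusters:
            if len(c.member_ids) == 1:
                continue
            cvec = preprocess_vector(
                c.consensus.mz_array,
                np.array([p.intensity for p in c.consensus.peaks]),
                params.bin_width,
                params.top_n_peaks,
            )
            for sid in c.member_ids:
                s = similarity(spectrum_vector(by_id[sid], params), cvec)
                assert s >= params.similarity_threshold

    def test_determinism(self, rng):
        spectra = random_spectra(rng, 30)
        a = ms.cluster_spectra(spectra)
        b = ms.cluster_spectra(list(reversed(spectra)))
        assert [sorted(c.member_ids) for c in a] == [sorted(c.member_ids) for c in b]


def _greedy_oracle(spectra, params):
    """Independent re-coding of the greedy rules with dense binned vectors."""

    def vec(mz, inten):
        mz, inten = np.asarray(mz, float), np.asarray(inten, float)
        if mz.size > params.top_n_peaks:
            keep = np.sort(np.argsort(inten)[-params.top_n_peaks:])
            mz, inten = mz[keep], inten[keep]
        v = np.zeros(4000)
        for m, i in zip(mz, inten):
            v[int(m // params.bin_width)] += math.sqrt(i)
        return v / np.linalg.norm(v)

    def compatible(sp, cons):
        if params.require_same_charge and sp.charge != cons.charge:
            return False
        return abs(sp.precursor_mz - cons.precursor_mz) <= (
            params.precursor_tol_ppm * 1e-6 * cons.precursor_mz
        )

    order = sorted(spectra, key=lambda s: (s.precursor_mz, s.spectrum_id))

    def assign(order, consensi, cons_vecs, grow):
        members = [[] for _ in consensi]
        extras = []
        for sp in order:
            v = vec(sp.mz_array, sp.intensity_array)
            best, best_s = None, params.similarity_threshold
            for i, cons in enumerate(consensi):
                if not compatible(sp, cons):
                    continue
                s = float(v @ cons_vecs[i])
                if s > best_s or (s == best_s and best is None):
                    best, best_s = i, s
            if best is None:
                extras.append(sp)
                if grow:
                    consensi.append(ms.build_consensus([sp], params))
                    cons_vecs.append(
                        vec(consensi[-1].mz_array,
                            [p.intensity for p in consensi[-1].peaks])
                    )
                    members.append([sp])
            else:
                members[best].append(sp)
        return members, extras

    consensi, cons_vecs = [], []
    members, _ = assign(order, consensi, cons_vecs, grow=True)
    members = [m for m in members if m]
    for _ in range(params.passes - 1):
        consensi = [ms.build_consensus(m, params) for m in members]
        cons_vecs = [
            vec(c.mz_array, [p.intensity for p in c.peaks]) for c in consensi
        ]
        members, extras = assign(order, list(consensi), list(cons_vecs), grow=False)
        members = [m for m in members if m] + [[e] for e in extras]
    return sorted(
        sorted(s.spectrum_id for s in m) for m in members
    )


class TestGreedyOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_independent_implementation(self, seed):
        rng = np.random.default_rng(seed)
        # spectra with deliberate near-duplicates to exercise merging
        base = random_spectra(rng, 4)
        spectra = []
        for i, b in enumerate(base):
            for r in range(3):
                jit = rng.normal(0, 0.002, size=len(b.peaks))
                spectra.append(
                    make_spectrum(
                        f"t{i}r{r}",
                        b.mz_array + jit,
                        b.intensity_array * rng.lognormal(0, 0.1, len(b.peaks)),
                        precursor_mz=b.precursor_mz,
                        charge=2,
                    )
                )
        params = ClusterParams()
        got = sorted(sorted(c.member_ids) for c in ms.cluster_spectra(spectra, params))
        expected = _greedy_oracle(spectra, params)
        assert got == expected


class TestRecovery:
    def test_purity_and_completeness(self, clustered_dataset):
        _, _, _, clusters, truth = clustered_dataset
        purity, completeness, ari = ms.evaluate_clustering(clusters, truth)
        assert purity >= 0.95
        assert completeness >= 0.90
        assert ari >= 0.9


class TestSummary:
    def test_reduction_percent(self):
        assert ms.reduction_percent(1000, 135) == pytest.approx(86.5)

    def test_multi_member_percent(self):
        assert ms.multi_member_percent(637, 1000) == pytest.approx(63.7)

    def test_summary_consistent(self, clustered_dataset):
        _, kept, _, clusters, _ = clustered_dataset
        s = ms.cluster_summary(clusters)
        assert s["n_spectra"] == len(kept)
        assert s["n_clusters"] == len(clusters)
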