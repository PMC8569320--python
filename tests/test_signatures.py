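"""Signature derivation, Venn partitioning, reversal and clustering."""

import numpy as np
import pandas as pd
import pytest

from acnesig.io_formats import ExpressionMatrix
from acnesig.signatures import (
    classify_reversal,
    cluster_genes,
    derive_signatures,
    venn_partition,
)
from acnesig.synthetic import REGIONS, StudyDesignConfig, simulate_study


def jaccard(a, b):
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


class TestVennPartition:
    def test_hand_enumeration(self):
        p = venn_partition({"g1", "g2", "g3"}, {"g2", "g3"}, {"g3", "g4"})
        assert p.regions["papule_only"] == {"g1"}
        assert p.regions["papule_vehicle"] == {"g2"}
        assert p.regions["all_three"] == {"g3"}
        assert p.regions["trifarotene_only"] == {"g4"}
        for r in ("vehicle_only", "papule_trifarotene", "vehicle_trifarotene"):
            assert p.regions[r] == set()

    def test_identical_sets_all_three(self):
        genes = {"a", "b", "c"}
        p = venn_partition(genes, genes, genes)
        assert p.regions["all_three"] == genes
        assert len(p.union) == 3

    def test_matches_membership_bitmask_oracle(self, rng):
        universe = [f"g{i}" for i in range(60)]
        for _ in range(20):
            a = set(rng.choice(universe, rng.integers(0, 30), replace=False))
            b = set(rng.choice(universe, rng.integers(0, 30), replace=False))
            c = set(rng.choice(universe, rng.integers(0, 30), replace=False))
            p = venn_partition(a, b, c)
            name_of = {
                (True, False, False): "papule_only",
                (False, True, False): "vehicle_only",
                (False, False, True): "trifarotene_only",
                (True, True, False): "papule_vehicle",
                (True, False, True): "papule_trifarotene",
                (False, True, True): "vehicle_trifarotene",
                (True, True, True): "all_three",
            }
            oracle = {r: set() for r in REGIONS}
            for g in a | b | c:
                oracle[name_of[(g in a, g in b, g in c)]].add(g)
            assert p.regions == oracle
            assert sum(p.sizes.values()) == len(a | b | c)


class TestDeriveSignatures:
    def test_zero_noise_single_planted_gene(self):
        cfg = StudyDesignConfig(
            n_genes=30,
            subject_sd=0.0,
            noise_sd=0.3,  # mild noise so variances exist; large planted effect
            venn_region_sizes={"papule_only": 1},
            effect_log2fc=4.0,
            seed=21,
        )
        m, samples, truth = simulate_study(cfg)
        sig = derive_signatures(m, samples)
        (planted,) = truth.region_genes("papule_only")
        assert set(sig["papule"][1]) == {planted}
        assert sig["vehicle"][1] == {}
        assert sig["trifarotene"][1] == {}

    def test_recovery_of_planted_regions(self):
        sizes = {
            "papule_only": 10,
            "vehicle_only": 10,
            "trifarotene_only": 10,
            "papule_vehicle": 5,
            "papule_trifarotene": 5,
            "vehicle_trifarotene": 5,
            "all_three": 5,
        }
        medians = {r: [] for r in REGIONS}
        for seed in range(5):
            cfg = StudyDesignConfig(
                n_genes=600,
                venn_region_sizes=sizes,
                effect_log2fc=3.0,
                noise_sd=0.3,
                seed=seed,
            )
            m, samples, truth = simulate_study(cfg)
            sig = derive_signatures(m, samples)
            p = venn_partition(sig["papule"][1], sig["vehicle"][1], sig["trifarotene"][1])
            for r in REGIONS:
                medians[r].append(jaccard(p.regions[r], truth.region_genes(r)))
        for r in REGIONS:
            assert np.median(medians[r]) >= 0.8, (r, medians[r])


class TestClassifyReversal:
    @staticmethod
    def _result(name, deltas):
        from acnesig.diffexpr import ContrastResult
        from acnesig.preprocess import signed_fold_change

        genes = list(deltas)
        vals = np.array([deltas[g] for g in genes], dtype=float)
        table = pd.DataFrame(
            {
                "gene": genes,
                "delta_log2": vals,
                "signed_fc": signed_fold_change(vals),
                "s2": 1.0,
                "t_mod": vals,
                "p_raw": 0.01,
                "q_bh": 0.01,
            }
        ).set_index("gene", drop=False)
        return ContrastResult(name, table, 4.0, 1.0, 8, 9)

    def test_sign_patterns(self):
        part = venn_partition(set(), set(), {"up_down", "up_up"})
        pap = self._result("papule", {"up_down": 3.0, "up_up": 3.0})
        tri = self._result("trifarotene", {"up_down": -3.0, "up_up": 1.0})
        got = classify_reversal(part, pap, tri)
        assert got == {
            "up_down": "up_in_papule_down_after_treatment",
            "up_up": "other",
        }

    def test_missing_gene_is_error(self):
        part = venn_partition(set(), set(), {"g1"})
        pap = self._result("papule", {"g1": 1.0})
        tri = self._result("trifarotene", {"other": 1.0})
        with pytest.raises(KeyError):
            classify_reversal(part, pap, tri)

    def test_planted_reversal_genes_recovered_at_zero_noise(self):
        # genes planted in both papule and treatment contrasts have mirrored
        # directions by construction: all must classify as reversal patterns
        cfg = StudyDesignConfig(
            n_genes=100,
            subject_sd=0.0,
            noise_sd=0.2,
            venn_region_sizes={"papule_trifarotene": 8, "all_three": 4},
            effect_log2fc=4.0,
            seed=33,
        )
        m, samples, truth = simulate_study(cfg)
        sig = derive_signatures(m, samples)
        planted = truth.region_genes("papule_trifarotene") | truth.region_genes(
            "all_three"
        )
        pap, tri = sig["papule"][0], sig["trifarotene"][0]
        expected = truth.reversal
        part = venn_partition(set(), set(), planted)  # classify the planted genes
        got = classify_reversal(part, pap, tri)
        assert got == {g: expected[g] for g in planted}
        assert set(got.values()) <= {
            "up_in_papule_down_after_treatment",
            "down_in_papule_up_after_treatment",
        }


def brute_force_upgma(dist):
    """Independent UPGMA oracle: recompute average pairwise distances per merge."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    next_id = n
    merges = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestClusterGenes:
    def _matrix(self, rows, genes, samples):
        return ExpressionMatrix(
            pd.DataFrame(rows, index=genes, columns=samples.sample_ids[: len(rows[0])])
        )

    def test_identical_profiles_merge_first(self, rng, samples9):
        base = rng.normal(0, 1, 27)
        rows = np.vstack([base, base + 5.0, rng.normal(0, 1, 27)])
        m = ExpressionMatrix(
            pd.DataFrame(
                rows,
                index=["a", "b", "c"],
                columns=[
                    s
                    for s in samples9.sample_ids
                    if not s.endswith("_L3")
                ],
            )
        )
        order, linkage = cluster_genes(m, samples9, ["a", "b", "c"])
        # first merge joins leaves 0 ('a') and 1 ('b') at distance ~0
        assert sorted(linkage[0, :2]) == [0.0, 1.0]
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_merge_last(self, rng, samples9):
        base = np.sin(np.arange(27))
        uncorr = rng.normal(0, 1, 27)
        m = ExpressionMatrix(
            pd.DataFrame(
                np.vstack([base, -base, uncorr]),
                index=["a", "b", "c"],
                columns=[s for s in samples9.sample_ids if not s.endswith("_L3")],
            )
        )
        _, linkage = cluster_genes(m, samples9, ["a", "b", "c"])
        assert linkage[-1, 2] > linkage[0, 2]
        # the gene and its negation sit at the maximal distance 2
        from acnesig.signatures import _correlation_distance

        sub = m.values.loc[["a", "b"]].to_numpy()
        z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, keepdims=True)
        assert _correlation_distance(z)[0, 1] == pytest.approx(2.0)

    def test_matches_brute_force_upgma(self, rng, samples9):
        from acnesig.signatures import _correlation_distance

        for trial in range(10):
            genes = [f"g{i}" for i in range(8)]
            cols = [s for s in samples9.sample_ids if not s.endswith("_L3")]
            m = ExpressionMatrix(
                pd.DataFrame(
                    rng.normal(0, 1, size=(8, len(cols))), index=genes, columns=cols
                )
            )
            order, linkage = cluster_genes(m, samples9, genes)
            sub = m.values.loc[genes, cols].to_numpy()
            z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(
                axis=1, keepdims=True
            )
            oracle = brute_force_upgma(_correlation_distance(z))
            for row, (a, b, d, size) in zip(linkage, oracle):
                assert sorted(row[:2]) == sorted([a, b])
                assert row[2] == pytest.approx(d, abs=1e-10)
                assert row[3] == size

    def test_input_order_invariance(self, rng, samples9):
        genes = [f"g{i}" for i in range(6)]
        cols = [s for s in samples9.sample_ids if not s.endswith("_L3")]
        m = ExpressionMatrix(
            pd.DataFrame(
                rng.normal(0, 1, size=(6, len(cols))), index=genes, columns=cols
            )
        )
        order1, _ = cluster_genes(m, samples9, genes)
        order2, _ = cluster_genes(m, samples9, genes[::-1])
        assert order1 == order2
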