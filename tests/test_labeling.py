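"""Labeling pipeline: embedding, clustering oracle, anchoring, grouping."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nefwheat import labeling
from nefwheat.labeling import (
    EfficiencyLabels,
    EmbeddingConfig,
    anchor_labels,
    combine_conditions,
    hcluster_two,
    reflectance_cluster_baseline,
    standardize,
    strategy_for,
    tsne_embed,
)
from nefwheat.containers import SpectraMatrix


class TestStandardize:
    def test_columns_zero_mean_unit_sd(self, rng):
        z = standardize(rng.normal(2.0, 5.0, size=(20, 6)))
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_idempotent_on_z_scores(self, rng):
        z = standardize(rng.normal(size=(15, 4)))
        assert np.allclose(standardize(z), z)

    def test_constant_column_maps_to_zero(self):
        x = np.column_stack([np.arange(5.0), np.full(5, 7.0)])
        z = standardize(x)
        assert np.allclose(z[:, 1], 0)


class TestTsne:
    def test_same_seed_identical_coordinates(self, rng):
        x = rng.normal(size=(12, 8))
        cfg = EmbeddingConfig(seed=9)
        assert np.array_equal(tsne_embed(x, cfg), tsne_embed(x, cfg))

    def test_duplicate_rows_stay_mutually_nearest(self, rng):
        x = rng.normal(size=(12, 6))
        x[5] = x[2]  # exact duplicate pair
        emb = tsne_embed(x, EmbeddingConfig(seed=0))
        d = np.linalg.norm(emb - emb[2], axis=1)
        d[2] = np.inf
        assert np.argmin(d) == 5

    def test_separated_blobs_stay_separated(self, rng):
        blob_a = rng.normal(0.0, 0.2, size=(6, 5))
        blob_b = rng.normal(8.0, 0.2, size=(6, 5))
        emb = tsne_embed(np.vstack([blob_a, blob_b]), EmbeddingConfig(seed=1))
        within = max(
            np.linalg.norm(emb[i] - emb[j])
            for grp in (range(6), range(6, 12))
            for i, j in itertools.combinations(grp, 2)
        )
        between = min(
            np.linalg.norm(emb[i] - emb[j]) for i in range(6) for j in range(6, 12)
        )
        assert between > within

    def test_excessive_perplexity_rejected(self, rng):
        with pytest.raises(ValueError, match="perplexity"):
            tsne_embed(rng.normal(size=(10, 4)), EmbeddingConfig(perplexity=5.0))


def brute_force_complete_linkage(points, k=2):
    """Rescan-all-pairs agglomerative clustering with complete linkage."""
    clusters = [[i] for i in range(len(points))]
    while len(clusters) > k:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(
                np.linalg.norm(points[i] - points[j])
                for i in clusters[a]
                for j in clusters[b]
            )
            if best is None or d < best[0]:
                best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(len(points), dtype=int)
    for ci, members in enumerate(clusters):
        labels[members] = ci
    return labels


def _same_partition(a, b):
    return len(set(zip(a.tolist(), b.tolist()))) == len(set(a.tolist()))


class TestHcluster:
    def test_two_points_split(self):
        assert set(hcluster_two(np.array([[0.0, 0.0], [1.0, 1.0]]))) == {0, 1}

    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_matches_brute_force_oracle(self, n, rng):
        for _ in range(20):
            pts = rng.normal(size=(n, 3))
            assert _same_partition(
                hcluster_two(pts), brute_force_complete_linkage(pts)
            )

    def test_planted_blobs_recovered(self, rng):
        pts = np.vstack(
            [rng.normal(0, 0.3, size=(5, 2)), rng.normal(10, 0.3, size=(7, 2))]
        )
        labels = hcluster_two(pts)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[-1]


class TestAnchoring:
    def test_reference_alone_makes_everyone_inefficient(self):
        out = anchor_labels([0, 1, 1, 1], ["ref", "a", "b", "c"], "ref")
        assert out.efficient == frozenset()
        assert out.inefficient == {"a", "b", "c"}

    def test_reference_excluded_from_reported_set(self):
        out = anchor_labels([0, 0, 1], ["ref", "a", "b"], "ref")
        assert "ref" not in out.varieties
        assert out.efficient == {"a"}

    def test_cluster_id_permutation_invariance(self):
        a = anchor_labels([0, 0, 1, 1], ["ref", "a", "b", "c"], "ref")
        b = anchor_labels([1, 1, 0, 0], ["ref", "a", "b", "c"], "ref")
        assert a == b

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            anchor_labels([0, 1], ["a", "b"], "ref")


class TestCombine:
    def test_disjoint_sets_partition(self):
        lo = EfficiencyLabels(frozenset("ab"), frozenset("cd"), "refL")
        hi = EfficiencyLabels(frozenset("c"), frozenset("abd"), "refH")
        groups = combine_conditions(lo, hi)
        assert groups == {
            "a": "low_N_efficient",
            "b": "low_N_efficient",
            "c": "high_N_efficient",
            "d": "inefficient",
        }

    def test_overlap_raises_conflict(self):
        lo = EfficiencyLabels(frozenset("a"), frozenset("b"), "refL")
        hi = EfficiencyLabels(frozenset("a"), frozenset("b"), "refH")
        with pytest.raises(ValueError, match="a"):
            combine_conditions(lo, hi)

    def test_field_trial_partition_sizes(self):
        """Structural example: 6 low-N-efficient, 2 high-N-efficient, 4
        inefficient out of 12 numbered varieties."""
        varieties = {str(i) for i in range(1, 13)}
        lo_eff = {"1", "2", "3", "4", "8", "12"}
        hi_eff = {"7", "10"}
        lo = EfficiencyLabels(frozenset(lo_eff), frozenset(varieties - lo_eff), "rL")
        hi = EfficiencyLabels(frozenset(hi_eff), frozenset(varieties - hi_eff), "rH")
        groups = combine_conditions(lo, hi)
        sizes = pd.Series(groups).value_counts()
        assert sizes["low_N_efficient"] == 6
        assert sizes["high_N_efficient"] == 2
        assert sizes["inefficient"] == 4
        assert {v for v, g in groups.items() if g == "inefficient"} == {"5", "6", "9", "11"}


class TestStrategies:
    def test_known_groups_have_descriptors(self):
        assert "delay" in strategy_for("high_N_efficient").lower()
        assert "maintain" in strategy_for("inefficient").lower()
        assert "phosphorus" in strategy_for("low_N_efficient").lower()

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            strategy_for("mystery")


class TestReflectanceBaseline:
    @staticmethod
    def _class_spectra(noise_rng=None):
        wl = np.linspace(400, 1000, 40)
        varieties = [f"V{i}" for i in range(8)] + ["ref"]
        eff = {"V0", "V1", "V2", "ref"}
        rows, meta = [], []
        for v in varieties:
            for rep in (1, 2):
                base = 0.3 + (0.2 if v in eff else 0.0)
                spectrum = np.full_like(wl, base)
                if noise_rng is not None:
                    spectrum = spectrum + 0.01 * noise_rng.standard_normal(len(wl))
                rows.append(np.clip(spectrum, 0, 1))
                meta.append({"sample_id": f"{v}_{rep}", "variety": v, "n_level": 0.0,
                             "replicate": rep, "region": 1})
        truth = EfficiencyLabels(
            frozenset(eff - {"ref"}), frozenset(set(varieties) - eff), "ref"
        )
        return SpectraMatrix(np.array(rows), wl, pd.DataFrame(meta)), truth

    def test_deterministic_class_function_gives_perfect_accuracy(self, rng):
        spectra, truth = self._class_spectra(noise_rng=rng)
        acc = reflectance_cluster_baseline(spectra, truth, EmbeddingConfig(seed=0))
        assert acc == 1.0

    def test_accuracy_equals_recomputed_agreement(self, rng):
        spectra, truth = self._class_spectra(noise_rng=rng)
        cfg = EmbeddingConfig(seed=2)
        acc = reflectance_cluster_baseline(spectra, truth, cfg)
        # independent recomputation of the agreement fraction
        z = labeling.standardize(spectra.reflectance)
        assign = hcluster_two(tsne_embed(z, cfg))
        vs = spectra.meta.variety.to_numpy()
        maj = {v: round(assign[vs == v].mean()) for v in dict.fromkeys(vs)}
        ref_cluster = maj["ref"]
        agree = [
            (maj[v] == ref_cluster) == (v in truth.efficient) for v in truth.varieties
        ]
        assert acc == pytest.approx(sum(agree) / len(agree))

    def test_missing_varieties_rejected(self, rng):
        spectra, truth = self._class_spectra(noise_rng=rng)
        trimmed = spectra.select_samples(
            (spectra.meta.variety != "V7").to_numpy()
        )
        with pytest.raises(ValueError, match="V7"):
            reflectance_cluster_baseline(trimmed, truth)


def test_row_order_invariance_with_skip_tsne(rng):
    """Deterministic mode: permuting variety rows permutes labels only."""
    idx = pd.DataFrame(
        rng.normal(size=(10, 8)),
        index=[f"V{i}" for i in range(9)] + ["ref"],
        columns=list("abcdefgh"),
    )
    a = labeling.label_varieties(idx, "ref", skip_tsne=True)
    b = labeling.label_varieties(idx.iloc[::-1], "ref", skip_tsne=True)
    assert a.efficient == b.efficient
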