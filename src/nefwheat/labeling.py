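"""Nitrogen-efficiency class labels via t-SNE + hierarchical clustering.

Ground-truth labels for the classifier come from the agronomic indices:
varieties are standardised, embedded with t-SNE, cut into two groups by
complete-linkage agglomerative clustering, and the group containing a known
nitrogen-efficient reference cultivar is labelled *efficient*. Run once per
stress condition (low-N contrast anchored on the low-N reference, high-N
contrast on the high-N reference) and combined into a three-group partition:
low-N-efficient, high-N-efficient, inefficient.

With only ~13 varieties the t-SNE embedding is seed-sensitive; the seed is
part of the configuration and a ``skip_tsne`` mode clusters the standardised
indices directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.manifold import TSNE

from .containers import SpectraMatrix

__all__ = [
    "EmbeddingConfig",
    "EfficiencyLabels",
    "standardize",
    "tsne_embed",
    "hcluster_two",
    "anchor_labels",
    "combine_conditions",
    "strategy_for",
    "label_varieties",
    "reflectance_cluster_baseline",
    "STRATEGIES",
]

GROUPS = ("low_N_efficient", "high_N_efficient", "inefficient")

#: fertilisation strategy per efficiency group at normal nitrogen
STRATEGIES = {
    "inefficient": (
        "Maintain the standard nitrogen application; stable supply suits "
        "these varieties best and limits environmental losses."
    ),
    "low_N_efficient": (
        "Reduce basal nitrogen before planting and supplement with small "
        "amounts of phosphorus/potassium foliar fertiliser."
    ),
    "high_N_efficient": (
        "Increase nitrogen application and delay top-dressing to the "
        "critical growth stages (heading) to raise use efficiency."
    ),
}


@dataclass
class EmbeddingConfig:
    """t-SNE settings; perplexity must stay below (n_samples − 1) / 3.

    The defaults target variety-level problems of ~a dozen points, where
    the efficient group can be as small as 3 points: perplexity must stay
    below the smallest cluster size, and the learning rate and early
    exaggeration are kept far below sklearn's large-n defaults — at this
    scale the usual settings scatter the embedding before it converges.
    """

    out_dims: int = 3
    perplexity: float = 2.5
    n_iter: int = 2000
    learning_rate: float = 5.0
    early_exaggeration: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.out_dims not in (2, 3):
            raise ValueError("out_dims must be 2 or 3")
        if self.perplexity <= 0:
            raise ValueError("perplexity must be positive")


@dataclass(frozen=True)
class EfficiencyLabels:
    """Per-variety efficient/inefficient split under one stress condition.

    The reference cultivar anchors the efficient cluster but is excluded
    from the reported variety sets (it is a control, not a candidate).
    """

    efficient: frozenset
    inefficient: frozenset
    reference: str
    condition: str = ""

    @property
    def varieties(self) -> frozenset:
        return self.efficient | self.inefficient

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"variety": v, "condition": self.condition, "class": cls, "reference": self.reference}
            for cls, vs in (("efficient", self.efficient), ("inefficient", self.inefficient))
            for v in sorted(vs)
        ]
        return pd.DataFrame(rows)


def standardize(matrix: np.ndarray) -> np.ndarray:
    """Column z-scores (sample SD); constant columns map to zeros."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    out = np.zeros_like(x)
    nonconst = sd > 0
    out[:, nonconst] = (x[:, nonconst] - mean[nonconst]) / sd[nonconst]
    return out


def tsne_embed(matrix: np.ndarray, cfg: EmbeddingConfig) -> np.ndarray:
    """Deterministic (seeded) t-SNE embedding to 2-D or 3-D."""
    x = np.asarray(matrix, dtype=float)
    n = x.shape[0]
    if cfg.perplexity >= (n - 1) / 3:
        raise ValueError(
            f"perplexity {cfg.perplexity} too large for {n} samples "
            f"(must be < (n-1)/3 = {(n - 1) / 3:.2f})"
        )
    tsne = TSNE(
        n_components=cfg.out_dims,
        perplexity=cfg.perplexity,
        max_iter=cfg.n_iter,
        learning_rate=cfg.learning_rate,
        early_exaggeration=cfg.early_exaggeration,
        random_state=cfg.seed,
        init="pca",
        method="exact",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-n convergence chatter
        return tsne.fit_transform(x)


def hcluster_two(coordinates: np.ndarray) -> np.ndarray:
    """Complete-linkage agglomerative clustering (Euclidean), cut at k=2."""
    coords = np.asarray(coordinates, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 points")
    merge = linkage(coords, method="complete", metric="euclidean")
    return fcluster(merge, t=2, criterion="maxclust") - 1


def anchor_labels(
    assignment: np.ndarray, varieties, reference_variety: str, condition: str = ""
) -> EfficiencyLabels:
    """Label the cluster containing the reference cultivar as efficient."""
    varieties = list(varieties)
    assignment = np.asarray(assignment)
    if reference_variety not in varieties:
        raise ValueError(f"reference variety {reference_variety!r} not present")
    ref_cluster = assignment[varieties.index(reference_variety)]
    efficient = {
        v
        for v, a in zip(varieties, assignment)
        if a == ref_cluster and v != reference_variety
    }
    inefficient = {v for v in varieties if v not in efficient and v != reference_variety}
    return EfficiencyLabels(
        frozenset(efficient), frozenset(inefficient), reference_variety, condition
    )


def combine_conditions(
    labels_lowN: EfficiencyLabels, labels_highN: EfficiencyLabels
) -> dict:
    """Three-group partition from the two per-condition labelings.

    Efficient under the low-N contrast → ``low_N_efficient``; under the
    high-N contrast → ``high_N_efficient``; neither → ``inefficient``. A
    variety efficient under both is a conflict (the two definitions of
    efficiency are mutually exclusive in the trial design) and raises.
    """
    if labels_lowN.varieties != labels_highN.varieties:
        raise ValueError("the two conditions cover different variety sets")
    overlap = labels_lowN.efficient & labels_highN.efficient
    if overlap:
        raise ValueError(
            f"varieties efficient under both conditions: {sorted(overlap)}"
        )
    out = {}
    for v in labels_lowN.varieties:
        if v in labels_lowN.efficient:
            out[v] = "low_N_efficient"
        elif v in labels_highN.efficient:
            out[v] = "high_N_efficient"
        else:
            out[v] = "inefficient"
    return out


def strategy_for(group: str) -> str:
    """Fertilisation-strategy descriptor for an efficiency group."""
    try:
        return STRATEGIES[group]
    except KeyError:
        raise ValueError(f"unknown efficiency group: {group!r}") from None


def label_varieties(
    indices: pd.DataFrame,
    reference_variety: str,
    cfg: EmbeddingConfig | None = None,
    condition: str = "",
    skip_tsne: bool = False,
) -> EfficiencyLabels:
    """Full labeling pipeline: standardise → embed → cluster → anchor.

    ``indices`` is the per-variety index table (varieties in the index,
    one column per agronomic index). ``skip_tsne`` clusters the
    standardised indices directly.
    """
    cfg = cfg or EmbeddingConfig()
    numeric = indices.select_dtypes(include=[np.number])
    z = standardize(numeric.to_numpy(dtype=float))
    coords = z if skip_tsne else tsne_embed(z, cfg)
    assignment = hcluster_two(coords)
    return anchor_labels(assignment, list(indices.index), reference_variety, condition)


def reflectance_cluster_baseline(
    spectra: SpectraMatrix,
    truth: EfficiencyLabels,
    cfg: EmbeddingConfig | None = None,
    skip_tsne: bool = False,
) -> float:
    """Cluster raw reflectance directly and score agreement with the labels.

    The clustering baseline the indices-based labeling is compared against:
    sample-level spectra are embedded and cut into two clusters, each
    variety votes with its majority cluster, the cluster holding the
    reference variety's majority is called efficient, and the returned
    accuracy is the fraction of (non-reference) varieties whose baseline
    class matches ``truth``.
    """
    cfg = cfg or EmbeddingConfig()
    varieties = spectra.meta["variety"].to_numpy()
    known = truth.varieties | {truth.reference}
    missing = known - set(varieties.tolist())
    if missing:
        raise ValueError(f"spectra lack samples for varieties: {sorted(missing)}")
    z = standardize(spectra.reflectance)
    coords = z if skip_tsne else tsne_embed(z, cfg)
    assignment = hcluster_two(coords)
    majority = {
        v: int(np.round(assignment[varieties == v].mean()))
        for v in dict.fromkeys(varieties.tolist())
    }
    baseline = anchor_labels(
        list(majority.values()), list(majority.keys()), truth.reference, truth.condition
    )
    agree = sum(
        1
        for v in truth.varieties
        if (v in baseline.efficient) == (v in truth.efficient)
    )
    return agree / len(truth.varieties)
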