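"""Multimodal phenotype-driven gene prioritization.

Three evidence channels are combined per patient over a fixed gene
vocabulary (816 disease genes in the reference benchmark):

* **gestalt** -- facial-image similarity.  Each imaged patient carries 12
  unit-norm 512-dimensional facial phenotype descriptors (model ensemble +
  test-time augmentation); the distance between two patients is the mean
  of the 12 index-matched cosine distances, and a gene's score is one
  minus the smallest distance to any previously solved gallery patient of
  that gene.
* **molecular** -- per-gene maximum variant deleteriousness score after
  removing common variants (allele frequency above the cutoff).
* **feature** -- semantic similarity between the patient's phenotype terms
  and each gene's phenotype annotations (best-match-average Resnik from
  the ontology module); externally computed scores can be supplied
  instead.

Channels are min-max normalized per patient, missing scores become the
neutral floor 0 after normalization, and the fused score is a weighted sum
(equal weights by default; the trained combiner of the original pipeline
is a plug point).  Genes are ranked by descending fused score with ties
assigned the worst rank, and benchmarks report top-k accuracy with
case-level bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ontology import OntologyIndex, patient_similarity

__all__ = [
    "DescriptorSet",
    "AccuracyCurve",
    "image_distance",
    "gestalt_gene_scores",
    "molecular_gene_scores",
    "feature_gene_scores",
    "fuse_scores",
    "rank_genes",
    "topk_accuracy",
    "DEFAULT_AF_CUTOFF",
    "DEFAULT_VOCABULARY_SIZE",
]

DEFAULT_AF_CUTOFF = 0.01
DEFAULT_VOCABULARY_SIZE = 816
SCORE_CHANNELS = ("gestalt", "feature", "molecular")


@dataclass
class DescriptorSet:
    """Facial phenotype descriptors of one imaged patient: exactly 12
    vectors, each of unit norm."""

    patient_id: str
    vectors: np.ndarray  # (12, d), rows unit-norm

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != 12:
            raise ValueError(
                f"descriptor set {self.patient_id}: expected 12 vectors, "
                f"got shape {self.vectors.shape}"
            )
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError(
                f"descriptor set {self.patient_id}: vectors must be unit-norm"
            )


def image_distance(a: DescriptorSet, b: DescriptorSet) -> float:
    """Mean of the 12 index-matched cosine distances; in [0, 2]."""
    if a.vectors.shape != b.vectors.shape:
        raise ValueError(
            f"descriptor dimension mismatch: {a.vectors.shape} vs "
            f"{b.vectors.shape}"
        )
    cos = np.sum(a.vectors * b.vectors, axis=1)
    return float(np.mean(1.0 - cos))


def gestalt_gene_scores(
    test: DescriptorSet,
    gallery: Sequence[tuple[DescriptorSet, str]],
    aggregation: str = "max",
    top_m: int = 3,
) -> dict[str, float]:
    """Per-gene gestalt similarity of a test patient against a gallery of
    previously solved patients labeled with their disease gene.

    ``max`` (default) scores a gene by its most similar gallery patient
    (1 - minimum distance); ``mean_top_m`` averages the ``top_m`` best
    similarities.  Genes without a gallery patient get no score.
    """
    if not gallery:
        raise ValueError("gallery must be non-empty")
    per_gene: dict[str, list[float]] = {}
    for ds, gene in gallery:
        per_gene.setdefault(gene, []).append(image_distance(test, ds))
    scores: dict[str, float] = {}
    for gene, dists in per_gene.items():
        sims = sorted((1.0 - d for d in dists), reverse=True)
        if aggregation == "max":
            scores[gene] = sims[0]
        elif aggregation == "mean_top_m":
            scores[gene] = float(np.mean(sims[:top_m]))
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
    return scores


def molecular_gene_scores(
    variants: pd.DataFrame, af_cutoff: float = DEFAULT_AF_CUTOFF
) -> dict[str, float]:
    """Per-gene maximum deleteriousness score after dropping common
    variants (allele frequency > cutoff).  Genes whose variants are all
    filtered out get no score."""
    required = {"gene", "af", "score"}
    if not required <= set(variants.columns):
        raise ValueError(f"variant table needs columns {required}")
    if (variants["af"] < 0).any():
        raise ValueError("negative allele frequency in variant table")
    kept = variants[variants["af"] <= af_cutoff]
    return kept.groupby("gene")["score"].max().to_dict()


def feature_gene_scores(
    patient_terms: Iterable[str],
    gene_annotations: Mapping[str, Iterable[str]],
    index: OntologyIndex,
) -> dict[str, float]:
    """Per-gene phenotype-match score: best-match-average similarity of the
    patient's terms against each gene's annotation set.  Genes without
    annotations get no score."""
    terms = set(patient_terms)
    scores: dict[str, float] = {}
    for gene, ann in gene_annotations.items():
        ann = set(ann)
        if not ann:
            continue
        scores[gene] = patient_similarity(index, terms, ann)
    return scores


def fuse_scores(
    table: pd.DataFrame,
    weights: Mapping[str, float] | None = None,
    channels: Sequence[str] = SCORE_CHANNELS,
) -> pd.DataFrame:
    """Fuse per-channel gene scores into one score per gene.

    Each channel is min-max normalized to [0, 1] across the patient's
    genes; missing values become 0 after normalization (absent evidence is
    a neutral floor, never a penalty); a degenerate constant channel
    normalizes to 0.  Fused = sum of weight * normalized channel, equal
    weights by default.  Raises if every channel is entirely empty.
    """
    present = [c for c in channels if c in table.columns]
    if not present or table[present].notna().sum().sum() == 0:
        raise ValueError("all score channels are empty")
    if weights is None:
        weights = {c: 1.0 for c in channels}
    out = table.copy()
    fused = np.zeros(len(out))
    for c in channels:
        if c not in out.columns:
            continue
        col = out[c].astype(float)
        lo, hi = col.min(skipna=True), col.max(skipna=True)
        if pd.isna(lo) or hi == lo:
            norm = pd.Series(0.0, index=out.index)
            norm[col.notna() & (hi != lo)] = 0.0
        else:
            norm = (col - lo) / (hi - lo)
        norm = norm.fillna(0.0)
        out[f"{c}_norm"] = norm
        fused += weights.get(c, 0.0) * norm.to_numpy()
    out["fused"] = fused
    return out


def rank_genes(scores: pd.Series | pd.DataFrame) -> pd.DataFrame:
    """Rank genes by descending score; tied genes all receive the worst
    (largest) rank of the tie group."""
    if isinstance(scores, pd.DataFrame):
        scores = scores["fused"]
    ranks = rankdata(-scores.to_numpy(), method="max")
    out = pd.DataFrame(
        {"gene": scores.index, "score": scores.to_numpy(), "rank": ranks.astype(int)}
    )
    return out.sort_values(["rank", "gene"]).reset_index(drop=True)


@dataclass
class AccuracyCurve:
    """Top-k accuracy with case-level bootstrap confidence intervals."""

    table: pd.DataFrame  # k, accuracy, ci_low, ci_high
    n_cases: int
    n_boot: int
    seed: int
    missing_causal: int  # cases whose causal gene was absent from vocabulary

    def accuracy(self, k: int) -> float:
        row = self.table[self.table["k"] == k]
        if row.empty:
            raise KeyError(f"k={k} not evaluated")
        return float(row["accuracy"].iloc[0])


def topk_accuracy(
    causal_ranks: Sequence[float],
    ks: Sequence[int] = (1, 5, 10, 30, 100),
    n_boot: int = 1000,
    seed: int = 1,
) -> AccuracyCurve:
    """Top-k accuracy over benchmark cases.

    ``causal_ranks`` holds each case's rank of its causal gene; use
    ``np.inf`` when the causal gene is missing from the vocabulary (the
    case then counts as never hit and is flagged).  Percentile bootstrap
    CIs are taken over cases.
    """
    ranks = np.asarray(causal_ranks, dtype=float)
    if ranks.size == 0:
        raise ValueError("no benchmark cases")
    missing = int(np.sum(~np.isfinite(ranks)))
    n = ranks.size
    ks = sorted(set(int(k) for k in ks))
    rng = np.random.default_rng(seed)
    boot_idx = rng.integers(0, n, size=(n_boot, n))
    rows = []
    for k in ks:
        hit = (ranks <= k).astype(float)
        acc = float(hit.mean())
        boot = hit[boot_idx].mean(axis=1)
        lo, hi = np.percentile(boot, [2.5, 97.5])
        rows.append({"k": k, "accuracy": acc, "ci_low": lo, "ci_high": hi})
    return AccuracyCurve(
        table=pd.DataFrame(rows),
        n_cases=n,
        n_boot=n_boot,
        seed=seed,
        missing_causal=missing,
    )


def score_case(
    vocabulary: Sequence[str],
    gestalt: Mapping[str, float] | None = None,
    feature: Mapping[str, float] | None = None,
    molecular: Mapping[str, float] | None = None,
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Assemble the per-gene score table for one case over a fixed gene
    vocabulary, fuse the channels and attach ranks."""
    idx = pd.Index(sorted(set(vocabulary)), name="gene")
    table = pd.DataFrame(index=idx)
    for name, channel in (
        ("gestalt", gestalt),
        ("feature", feature),
        ("molecular", molecular),
    ):
        if channel is not None:
            table[name] = pd.Series(channel).reindex(idx)
    fused = fuse_scores(table, weights=weights)
    ranked = rank_genes(fused).set_index("gene")
    fused["rank"] = ranked["rank"].reindex(idx)
    return fused


def causal_rank(score_table: pd.DataFrame, causal_gene: str) -> float:
    """Rank of the causal gene in a scored case; inf if out of vocabulary."""
    if causal_gene not in score_table.index:
        return float("inf")
    return float(score_table.loc[causal_gene, "rank"])
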