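"""Cluster assignment on the embedding and cosine-similarity summaries.

Clusters come either from a label file (hand-circled regions) or from
k-means on the 2D map.  Similarity summaries are computed on the
standardized *spectrum* columns only — the RI column is excluded — and are
reported as cosine similarity, which can be negative for standardized
vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .descriptors import DescriptorMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    labels: dict[str, int]  # compound_id -> cluster id (contiguous from 1)
    source: str  # "file" | "kmeans"
    k: int | None = None
    seed: int | None = None

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for cid, cluster in self.labels.items():
            out.setdefault(cluster, []).append(cid)
        return out


@dataclass
class SimilaritySummary:
    within: dict[int, float]  # singletons reported as NaN
    between: pd.DataFrame  # cluster × cluster; diagonal = within
    per_class_within: dict[str, float]

    @property
    def mean_within(self) -> float:
        vals = [v for v in self.within.values() if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def mean_between(self) -> float:
        b = self.between.to_numpy()
        mask = ~np.eye(b.shape[0], dtype=bool)
        vals = b[mask]
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if vals.size else float("nan")


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u·v / (||u|| ||v||); errors on zero-norm input."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors differ in length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-norm vector")
    return float(u @ v / (nu * nv))


def assign_clusters(
    embedding: pd.DataFrame,
    mode: str = "kmeans",
    k: int | None = None,
    label_file: str | Path | None = None,
    seed: int = 0,
) -> ClusterAssignment:
    """Cluster the map: pass a label CSV through, or run seeded k-means.

    ``embedding`` is indexed by compound_id with the map coordinates as
    columns.  k-means uses 10 restarts and returns the lowest-inertia
    solution; cluster ids are relabeled contiguous from 1 in order of first
    appearance.
    """
    if mode == "file":
        if label_file is None:
            raise ValueError("file mode requires a label file")
        df = pd.read_csv(label_file)
        labels = dict(zip(df["compound_id"].astype(str), df["cluster_id"].astype(int)))
        return ClusterAssignment(labels=labels, source="file")
    if mode != "kmeans":
        raise ValueError(f"unknown mode {mode!r}")
    if k is None or k < 2:
        raise ValueError("kmeans mode requires k >= 2")
    if k > len(embedding):
        raise ValueError(f"k={k} exceeds number of points {len(embedding)}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(embedding.to_numpy())
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for cid, lab in zip(embedding.index.astype(str), raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[cid] = remap[lab]
    return ClusterAssignment(labels=labels, source="kmeans", k=k, seed=seed)


def _mean_pairwise(sim: np.ndarray, idx_a: list[int], idx_b: list[int] | None) -> float:
    """Mean cosine over unordered within-pairs (idx_b None) or cross pairs."""
    if idx_b is None:
        if len(idx_a) < 2:
            return float("nan")
        sub = sim[np.ix_(idx_a, idx_a)]
        iu = np.triu_indices(len(idx_a), k=1)
        return float(sub[iu].mean())
    if not idx_a or not idx_b:
        return float("nan")
    return float(sim[np.ix_(idx_a, idx_b)].mean())


def similarity_summary(
    matrix: DescriptorMatrix | pd.DataFrame,
    assignment: ClusterAssignment,
    class_labels: Mapping[str, str] | None = None,
) -> SimilaritySummary:
    """Within/between-cluster and per-class mean pairwise cosine similarity.

    The RI column (if present) is excluded so similarity reflects the
    standardized spectrum alone.  Singleton clusters have undefined within-
    similarity and are reported as NaN.
    """
    if isinstance(matrix, DescriptorMatrix):
        matrix = matrix.drop_ri_column()
        frame = matrix.to_frame()
    else:
        frame = matrix.drop(columns=["RI"], errors="ignore")
    ids = [str(i) for i in frame.index]
    X = frame.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm spectrum row(s)")
    unit = X / norms[:, None]
    sim = unit @ unit.T

    pos = {cid: i for i, cid in enumerate(ids)}
    members = assignment.members()
    missing = [m for mem in members.values() for m in mem if m not in pos]
    if missing:
        raise ValueError(f"matrix rows missing for assigned ids: {missing[:5]}")
    clusters = sorted(members)
    idx = {c: [pos[m] for m in members[c]] for c in clusters}

    within = {c: _mean_pairwise(sim, idx[c], None) for c in clusters}
    between = pd.DataFrame(index=clusters, columns=clusters, dtype=float)
    for a in clusters:
        for b in clusters:
            between.loc[a, b] = (
                within[a] if a == b else _mean_pairwise(sim, idx[a], idx[b])
            )

    per_class_within: dict[str, float] = {}
    if class_labels:
        by_class: dict[str, list[int]] = {}
        for cid, label in class_labels.items():
            if cid in pos:
                by_class.setdefault(label, []).append(pos[cid])
        per_class_within = {
            label: _mean_pairwise(sim, rows, None) for label, rows in by_class.items()
        }
    return SimilaritySummary(
        within=within, between=between, per_class_within=per_class_within
    )


def class_composition(
    assignment: ClusterAssignment, class_labels: Mapping[str, str]
) -> pd.DataFrame:
    """Per-cluster class fractions with the dominant class flagged.

    Fractions are over labeled members only; clusters with no labeled
    members are omitted with a logged notice.  Returns a tidy frame with
    columns (cluster_id, class, fraction, dominant).
    """
    rows = []
    for cluster, members in sorted(assignment.members().items()):
        labeled = [class_labels[m] for m in members if m in class_labels]
        if not labeled:
            logger.info("cluster %d has no labeled members; omitted", cluster)
            continue
        counts = pd.Series(labeled).value_counts()
        dominant = counts.idxmax()
        for label, count in counts.items():
            rows.append(
                {
                    "cluster_id": cluster,
                    "class": label,
                    "fraction": count / len(labeled),
                    "dominant": label == dominant,
                }
            )
    return pd.DataFrame(rows)
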