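"""Expression-pattern clustering of homoeologs and expression shift.

Homoeolog profiles (per-tissue log2(TPM+1), replicate-averaged) are
clustered into k groups (default 10) by average-linkage agglomerative
clustering on correlation distance (1 - Pearson).  A homoeologous pair or
triad whose members do not all fall in the same group counts as *shifted*
in expression pattern; the shifted fraction is the headline statistic.
A seeded subsampling routine reclusters random subsets of pairs so that
tetraploid shifted fractions can be compared with hexaploids at matched
group counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .errors import InputError
from .io import ExpressionMatrix, HomoeologMap

logger = logging.getLogger(__name__)


@dataclass
class ShiftResult:
    """Group assignments and the shifted-fraction summary."""

    assignments: pd.Series  # gene id -> group id in 1..k
    shifted: pd.Series  # group id -> bool
    fraction: float


def build_profiles(
    matrix: ExpressionMatrix, hmap: HomoeologMap, tissues: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-homoeolog expression profiles over a fixed tissue order.

    ``matrix`` is the replicate-averaged TPM matrix; profiles are
    log2(TPM+1).  Groups with any member absent from the matrix are
    skipped (logged).  Returns ``(profiles, gene_info)`` where ``profiles``
    is genes × tissues and ``gene_info`` maps gene -> (group, subgenome),
    both ordered by (group, subgenome).
    """
    if matrix.unit != "tpm":
        raise InputError("build_profiles expects an averaged TPM matrix")
    if tissues is None:
        tissues = list(matrix.samples)
    missing = [t for t in tissues if t not in matrix.samples]
    if missing:
        raise InputError(f"tissues absent from matrix: {missing}")

    rows, info = [], []
    for gid in sorted(hmap.groups):
        members = hmap.groups[gid]
        if any(g not in matrix.genes for g in members.values()):
            logger.warning("group %s has members absent from the matrix; skipped", gid)
            continue
        for sub in sorted(members):
            gene = members[sub]
            rows.append(np.log2(matrix.data.loc[gene, tissues].to_numpy(dtype=float) + 1.0))
            info.append({"gene_id": gene, "group": gid, "subgenome": sub})
    gene_info = pd.DataFrame(info, columns=["gene_id", "group", "subgenome"]).set_index("gene_id")
    profiles = pd.DataFrame(rows, index=gene_info.index, columns=tissues)
    return profiles, gene_info


def _correlation_distance(x: np.ndarray) -> np.ndarray:
    """1 - Pearson matrix; constant profiles are distance 0 to identical
    rows and 1 otherwise."""
    sd = x.std(axis=1)
    const = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    if const.any():
        for i in np.flatnonzero(const):
            same = np.all(np.isclose(x, x[i]), axis=1)
            dist[i, :] = np.where(same, 0.0, 1.0)
            dist[:, i] = dist[i, :]
    # numerical guard: symmetrise and clip
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    return dist


def cluster_profiles(profiles: pd.DataFrame, k: int = 10, metric: str = "correlation") -> pd.Series:
    """Average-linkage hierarchical clustering cut to exactly k groups.

    ``metric`` is ``correlation`` (1 - Pearson, default) or ``euclidean``.
    Rows are sorted by gene id before linkage, so the result is invariant
    to input row order; group ids are 1..k in order of first appearance.
    """
    if k < 2:
        raise InputError("k must be >= 2")
    if len(profiles) < k:
        raise InputError(f"need at least k={k} profiles, got {len(profiles)}")
    prof = profiles.sort_index()
    x = prof.to_numpy(dtype=float)
    if metric == "correlation":
        dist = _correlation_distance(x)
        condensed = squareform(dist, checks=False)
        z = linkage(condensed, method="average")
    elif metric == "euclidean":
        z = linkage(x, method="average", metric="euclidean")
    else:
        raise InputError(f"unknown metric {metric!r}")
    raw = cut_tree(z, n_clusters=k).ravel()
    # relabel to 1..k by first appearance for determinism
    relabel: dict[int, int] = {}
    labels = np.empty(len(raw), dtype=int)
    for i, r in enumerate(raw):
        labels[i] = relabel.setdefault(r, len(relabel) + 1)
    return pd.Series(labels, index=prof.index, name="group")


def shifted_fraction(assignments: pd.Series, hmap: HomoeologMap) -> ShiftResult:
    """Fraction of homoeolog groups whose members span >1 cluster.

    Groups with members missing from ``assignments`` are skipped.
    """
    flags = {}
    for gid in sorted(hmap.groups):
        genes = list(hmap.groups[gid].values())
        if any(g not in assignments.index for g in genes):
            continue
        flags[gid] = assignments.loc[genes].nunique() > 1
    if not flags:
        raise InputError("no homoeolog group fully covered by the assignments")
    shifted = pd.Series(flags)
    return ShiftResult(assignments=assignments, shifted=shifted, fraction=float(shifted.mean()))


def subsample_comparison(
    profiles: pd.DataFrame,
    hmap: HomoeologMap,
    n_target: int,
    n_reps: int = 100,
    seed: int = 0,
    k: int = 10,
    metric: str = "correlation",
) -> dict:
    """Recluster random subsets of homoeolog groups (ploidy matching).

    Each replicate samples ``n_target`` groups without replacement,
    reclusters their member profiles (same k) and records the shifted
    fraction.  Returns the replicate fractions, their mean and the
    2.5/97.5 percentiles.  Seeded and deterministic.
    """
    groups = [
        gid for gid in sorted(hmap.groups)
        if all(g in profiles.index for g in hmap.groups[gid].values())
    ]
    if n_target > len(groups):
        raise InputError(f"n_target={n_target} exceeds available groups ({len(groups)})")
    rng = np.random.default_rng(seed)
    fractions = np.empty(n_reps)
    for r in range(n_reps):
        chosen = rng.choice(groups, size=n_target, replace=False)
        sub = HomoeologMap(
            {g: hmap.groups[g] for g in chosen},
            ratio_class=hmap.ratio_class,
            subgenomes=hmap.subgenomes,
        )
        genes = [g for gid in chosen for g in hmap.groups[gid].values()]
        assign = cluster_profiles(profiles.loc[sorted(genes)], k=k, metric=metric)
        fractions[r] = shifted_fraction(assign, sub).fraction
    return {
        "fractions": fractions,
        "mean": float(fractions.mean()),
        "ci": (float(np.percentile(fractions, 2.5)), float(np.percentile(fractions, 97.5))),
    }
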