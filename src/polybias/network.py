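"""Lightweight weighted co-expression network for subgenome statistics.

The pipeline mirrors the standard weighted-network recipe: biweight
midcorrelation (robust, median/MAD-based, with the per-tail outlier cap),
soft power chosen as the first exponent whose scale-free topology fit
index reaches 0.9, signed-hybrid adjacency (negative correlations zeroed),
unsigned topological overlap, average-linkage module detection with a
static tree cut, eigengene-based module merging, KME hub calls and the
top-k-neighbour intra/inter-subgenome composition.

This is a deliberately compact, deterministic re-specification — static
cut instead of dynamic tree cut, single block — sufficient for the
subgenome-level statistics (hub distribution per subgenome, neighbour
composition) that are the bespoke outputs.  Memory is O(n_genes^2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import InputError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# biweight midcorrelation
# ---------------------------------------------------------------------------


def _bicor_weights(x: np.ndarray, max_p_outliers: float) -> tuple[np.ndarray, np.ndarray]:
    """Centred values and biweight factors for one vector.

    u_i = (x_i - median) / (9 * MAD); the max_p_outliers cap rescales each
    side so that at most that fraction of observations per tail gets zero
    weight (the side-specific quantile is pulled back to |u| = 1).
    """
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise InputError("constant (zero-MAD) vector in bicor")
    u = (x - med) / (9.0 * mad)
    if 0 < max_p_outliers < 0.5:
        q_lo = np.quantile(x, max_p_outliers)
        q_hi = np.quantile(x, 1.0 - max_p_outliers)
        u_lo = (q_lo - med) / (9.0 * mad)
        u_hi = (q_hi - med) / (9.0 * mad)
        if u_lo < -1.0:
            u = np.where(u < 0, u / abs(u_lo), u)
        if u_hi > 1.0:
            u = np.where(u > 0, u / u_hi, u)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    return (x - med) * w, w


def bicor(x, y, max_p_outliers: float = 0.05, pearson_fallback: bool = False) -> float:
    """Biweight midcorrelation of two sample vectors, in [-1, 1].

    ``pearson_fallback=True`` substitutes plain Pearson when either vector
    has zero MAD (otherwise an error); useful for oracle comparisons.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise InputError("bicor needs two equal-length vectors of length >= 3")
    try:
        xt, _ = _bicor_weights(x, max_p_outliers)
        yt, _ = _bicor_weights(y, max_p_outliers)
    except InputError:
        if pearson_fallback:
            return float(np.corrcoef(x, y)[0, 1])
        raise
    denom = np.sqrt((xt**2).sum() * (yt**2).sum())
    if denom == 0:
        raise InputError("degenerate bicor denominator")
    return float(np.clip((xt * yt).sum() / denom, -1.0, 1.0))


def bicor_matrix(
    expr: np.ndarray | pd.DataFrame,
    max_p_outliers: float = 0.05,
    pearson_fallback: bool = True,
) -> np.ndarray:
    """Gene × gene bicor matrix from a genes × samples table."""
    x = np.asarray(expr, dtype=float)
    n = x.shape[0]
    rows = np.empty_like(x)
    for i in range(n):
        try:
            xt, _ = _bicor_weights(x[i], max_p_outliers)
        except InputError:
            if not pearson_fallback:
                raise
            xc = x[i] - x[i].mean()
            xt = xc
        norm = np.sqrt((xt**2).sum())
        rows[i] = xt / norm if norm > 0 else 0.0
    corr = np.clip(rows @ rows.T, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


# ---------------------------------------------------------------------------
# soft power / adjacency / TOM
# ---------------------------------------------------------------------------


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit index of a connectivity vector.

    Bins connectivity into equal-width bins, regresses log10(frequency) on
    log10(mean k per bin) and returns ``(fit, slope)`` where fit = R^2 when
    the slope is negative and -R^2 otherwise.  Returns (nan, nan) when
    fewer than 3 usable bins exist.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if len(k) < 3 or np.allclose(k, k[0]):
        return float("nan"), float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        cnt = int(mask.sum())
        if cnt == 0:
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(cnt / len(k)))
    if len(xs) < 3:
        return float("nan"), float("nan")
    res = stats.linregress(xs, ys)
    r2 = float(res.rvalue**2)
    return (r2 if res.slope < 0 else -r2), float(res.slope)


def adjacency_signed_hybrid(corr: np.ndarray, power: int) -> np.ndarray:
    """Signed-hybrid soft threshold: a_ij = corr^power if corr > 0 else 0."""
    c = np.asarray(corr, dtype=float)
    adj = np.where(c > 0, c, 0.0) ** power
    np.fill_diagonal(adj, 0.0)
    return adj


def pick_soft_power(
    corr: np.ndarray,
    powers=range(1, 31),
    target_fit: float = 0.9,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Smallest power whose scale-free fit index reaches ``target_fit``.

    Returns ``(power, table)`` with the per-power fit and slope.  When no
    power qualifies, the power of maximum fit is returned with a warning.
    """
    records = []
    chosen = None
    for p in powers:
        adj = adjacency_signed_hybrid(corr, p)
        fit, slope = scale_free_fit(adj.sum(axis=1), n_bins=n_bins)
        records.append({"power": int(p), "fit": fit, "slope": slope})
        if chosen is None and not np.isnan(fit) and fit >= target_fit:
            chosen = int(p)
    table = pd.DataFrame(records).set_index("power")
    if chosen is None:
        valid = table["fit"].dropna()
        if valid.empty:
            raise InputError("scale-free fit undefined at every power")
        chosen = int(valid.idxmax())
        warnings.warn(
            f"no power reached fit {target_fit}; using power {chosen} "
            f"(fit {valid.max():.3f})",
            stacklevel=2,
        )
    return chosen, table


def tom_unsigned(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    diagonal 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if not np.allclose(a, a.T):
        raise InputError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1:
        raise InputError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    numer = a @ a + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


# ---------------------------------------------------------------------------
# modules / eigengenes / hubs
# ---------------------------------------------------------------------------


def module_eigengene(expr: np.ndarray, member_idx=None) -> np.ndarray:
    """First principal component of the standardized module submatrix.

    Returned over samples, scaled to unit variance, with sign oriented so
    the mean correlation with member genes is nonnegative.  A one-gene
    module returns that gene's standardized profile.
    """
    x = np.asarray(expr, dtype=float)
    if member_idx is not None:
        x = x[np.asarray(member_idx)]
    if x.ndim != 2:
        raise InputError("expected a genes × samples matrix")
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd
    if z.shape[0] == 1:
        e = z[0]
    else:
        # PC1 over samples via SVD of the standardized matrix
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
    s = e.std()
    if s > 0:
        e = e / s
    corrs = [np.corrcoef(e, row)[0, 1] for row in z if row.std() > 0]
    if corrs and np.nanmean(corrs) < 0:
        e = -e
    return e


def _merge_modules(
    expr: np.ndarray, labels: np.ndarray, merge_height: float
) -> np.ndarray:
    """Iteratively merge modules whose eigengenes correlate > 1 - height."""
    labels = labels.copy()
    while True:
        mods = sorted(m for m in np.unique(labels) if m != 0)
        if len(mods) < 2:
            return labels
        eigs = {m: module_eigengene(expr, np.flatnonzero(labels == m)) for m in mods}
        best = None
        for i, m1 in enumerate(mods):
            for m2 in mods[i + 1:]:
                r = np.corrcoef(eigs[m1], eigs[m2])[0, 1]
                if r > 1.0 - merge_height and (best is None or r > best[0]):
                    best = (r, m1, m2)
        if best is None:
            return labels
        _, m1, m2 = best
        labels[labels == m2] = m1


def detect_modules(
    tom: np.ndarray,
    expr: np.ndarray | None = None,
    min_size: int = 30,
    cut_height: float = 0.99,
    merge_height: float = 0.15,
) -> np.ndarray:
    """Module labels from average-linkage clustering of 1 - TOM.

    Static cut at ``cut_height``; clusters smaller than ``min_size`` are
    unassigned (label 0).  When ``expr`` is given, modules whose eigengenes
    correlate above 1 - ``merge_height`` are merged iteratively until
    stable.  Final labels are 1..m in decreasing module size (ties by the
    smallest member index); 0 means unassigned.
    """
    t = np.asarray(tom, dtype=float)
    dist = 1.0 - t
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(np.clip((dist + dist.T) / 2, 0, None), checks=False)
    z = linkage(condensed, method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    labels = raw.astype(int)
    for m, cnt in zip(*np.unique(labels, return_counts=True)):
        if cnt < min_size:
            labels[labels == m] = 0
    if not np.any(labels):
        logger.warning("no module of size >= %d survived; all genes unassigned", min_size)
        return labels
    if expr is not None and merge_height > 0:
        labels = _merge_modules(np.asarray(expr, dtype=float), labels, merge_height)
    # deterministic relabel: by size desc, then smallest member index
    mods = [m for m in np.unique(labels) if m != 0]
    order = sorted(mods, key=lambda m: (-(labels == m).sum(), int(np.flatnonzero(labels == m)[0])))
    out = np.zeros_like(labels)
    for new, m in enumerate(order, start=1):
        out[labels == m] = new
    return out


def hub_genes(
    expr: np.ndarray, labels: np.ndarray, kme_threshold: float = 0.9
) -> tuple[np.ndarray, np.ndarray]:
    """KME-based hub calls.

    KME(g) = Pearson correlation of gene g with its own module's
    eigengene; a gene is a hub iff assigned (label > 0) and KME strictly
    exceeds ``kme_threshold``.  Returns ``(hub_flags, kme)``; unassigned
    genes get KME = nan.
    """
    x = np.asarray(expr, dtype=float)
    labels = np.asarray(labels)
    kme = np.full(len(labels), np.nan)
    hubs = np.zeros(len(labels), dtype=bool)
    for m in np.unique(labels):
        if m == 0:
            continue
        idx = np.flatnonzero(labels == m)
        e = module_eigengene(x, idx)
        for i in idx:
            if x[i].std() == 0:
                continue
            kme[i] = np.corrcoef(x[i], e)[0, 1]
            hubs[i] = kme[i] > kme_threshold
    return hubs, kme


# ---------------------------------------------------------------------------
# neighbour composition
# ---------------------------------------------------------------------------


def neighbor_composition(
    weights: np.ndarray,
    subgenomes,
    gene_ids=None,
    k: int = 100,
) -> pd.DataFrame:
    """Intra/inter-subgenome composition of each gene's top-k neighbours.

    Neighbours are ranked by descending edge weight (TOM by convention),
    ties broken by ascending gene id.  When k >= n_genes all other genes
    are used (noted in the ``k_used`` column).  Returns one row per gene:
    subgenome, intra, inter, k_used, pct_intra and per-label counts.
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    subs = np.asarray(list(subgenomes))
    if len(subs) != n:
        raise InputError("one subgenome label per gene required")
    ids = np.asarray(list(gene_ids)) if gene_ids is not None else np.arange(n).astype(str)
    labels = sorted(set(subs.tolist()))
    if k >= n:
        logger.warning("k=%d >= %d genes; using all other genes", k, n)
    rows = []
    id_rank = np.argsort(np.argsort(ids))  # lexicographic rank for tie-break
    for i in range(n):
        others = np.array([j for j in range(n) if j != i])
        order = others[np.lexsort((id_rank[others], -w[i, others]))]
        top = order[: min(k, n - 1)]
        same = subs[top] == subs[i]
        counts = {f"n_{lab}": int(np.sum(subs[top] == lab)) for lab in labels}
        rows.append(
            {"gene_id": ids[i], "subgenome": subs[i], "intra": int(same.sum()),
             "inter": int(len(top) - same.sum()), "k_used": len(top),
             "pct_intra": 100.0 * same.sum() / len(top), **counts}
        )
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# convenience pipeline
# ---------------------------------------------------------------------------


@dataclass
class CoexpressionNetwork:
    """Full network state produced by :func:`build_network`."""

    gene_ids: np.ndarray
    corr: np.ndarray
    power: int
    adjacency: np.ndarray
    tom: np.ndarray
    labels: np.ndarray  # 0 = unassigned
    kme: np.ndarray
    hubs: np.ndarray
    power_table: pd.DataFrame = field(repr=False, default=None)


def build_network(
    expr,
    gene_ids=None,
    power: int | None = None,
    target_fit: float = 0.9,
    min_size: int = 30,
    cut_height: float = 0.99,
    merge_height: float = 0.15,
    kme_threshold: float = 0.9,
    max_p_outliers: float = 0.05,
) -> CoexpressionNetwork:
    """Run the full pipeline on a genes × samples expression table."""
    x = np.asarray(expr, dtype=float)
    if gene_ids is None:
        gene_ids = (
            np.asarray(expr.index) if isinstance(expr, pd.DataFrame) else np.arange(x.shape[0])
        )
    corr = bicor_matrix(x, max_p_outliers=max_p_outliers)
    table = None
    if power is None:
        power, table = pick_soft_power(corr, target_fit=target_fit)
    adj = adjacency_signed_hybrid(corr, power)
    tom = tom_unsigned(adj)
    labels = detect_modules(
        tom, expr=x, min_size=min_size, cut_height=cut_height, merge_height=merge_height
    )
    hubs, kme = hub_genes(x, labels, kme_threshold=kme_threshold)
    return CoexpressionNetwork(
        gene_ids=np.asarray(gene_ids), corr=corr, power=power, adjacency=adj,
        tom=tom, labels=labels, kme=kme, hubs=hubs, power_table=table,
    )
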