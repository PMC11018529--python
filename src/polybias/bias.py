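"""Homoeolog expression bias between subgenomes.

For tetraploid 1:1 pairs the summary is a pseudocounted log-ratio,
log2((TPM_x + 0.01) / (TPM_y + 0.01)).  For hexaploid 1:1:1 triads each
tissue's homoeolog TPMs are normalised to relative expression on the
2-simplex (an expressed triad requires the summed TPM to exceed 0.5), and
the triad is assigned the bias category whose ideal point is nearest in
Euclidean distance:

* Balanced       — (1/3, 1/3, 1/3)
* X dominant     — all expression from X, e.g. A dominant = (1, 0, 0)
* X suppressed   — X silent, the others equal, e.g. A suppressed = (0, .5, .5)

This is the wheat triad-classification scheme.  A per-subgenome log
deviation from the balanced expectation, log2(((TPM_i + 0.01) / (sum + 0.01))
/ 0.33), is also provided for heat-map style summaries, and a replicate-level
differential-expression criterion (Welch t on log2(TPM+1), BH-adjusted
p < 0.05 and |log2FC| >= 1) counts up-regulated homoeologs per subgenome
pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .io import ExpressionMatrix, HomoeologMap

logger = logging.getLogger(__name__)

#: default pseudocount for log ratios, as printed in the source formulas
PSEUDOCOUNT = 0.01
#: default balanced expectation constant (note: 0.33, not exactly 1/3)
EXPECTATION = 0.33
#: minimum summed TPM across a triad for it to count as expressed
EXPRESSED_MIN_SUM = 0.5


@dataclass
class TriadCategoryResult:
    """Classification of one triad in one tissue."""

    group: str
    tissue: str
    relative: np.ndarray | None  # entries sum to 1 when expressed
    category: str | None
    distance: float | None
    expressed: bool
    tie: bool = False


def ideal_points(
    labels: tuple[str, ...] | list[str], include_balanced: bool = True
) -> dict[str, np.ndarray]:
    """Ideal relative-expression points, keyed by category name.

    Category names are ``Balanced``, ``{label}_dominant`` and
    ``{label}_suppressed``.  Order of coordinates follows ``labels``.
    The insertion order of the returned dict is the tie-break order:
    Balanced first, then dominants, then suppresseds, alphabetical within
    tier.
    """
    labels = tuple(labels)
    n = len(labels)
    if n < 2:
        raise InputError("need at least two subgenome labels")
    pts: dict[str, np.ndarray] = {}
    if include_balanced:
        pts["Balanced"] = np.full(n, 1.0 / n)
    for lab in sorted(labels):
        v = np.zeros(n)
        v[labels.index(lab)] = 1.0
        pts[f"{lab}_dominant"] = v
    for lab in sorted(labels):
        v = np.full(n, 1.0 / (n - 1))
        v[labels.index(lab)] = 0.0
        pts[f"{lab}_suppressed"] = v
    return pts


def pair_log_ratio(tpm_x, tpm_y, pseudocount: float = PSEUDOCOUNT):
    """log2((TPM_x + c) / (TPM_y + c)) for an ordered label pair (x, y)."""
    x = np.asarray(tpm_x, dtype=float)
    y = np.asarray(tpm_y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise InputError("negative TPM")
    return np.log2((x + pseudocount) / (y + pseudocount))


def triad_relative_expression(
    tpms, expressed_min_sum: float = EXPRESSED_MIN_SUM
) -> np.ndarray | None:
    """Normalise triad TPMs to the simplex, or None when not expressed.

    A triad is expressed when the summed TPM exceeds ``expressed_min_sum``
    (strictly greater than).
    """
    v = np.asarray(tpms, dtype=float)
    if (v < 0).any():
        raise InputError("negative TPM")
    total = v.sum()
    if total <= expressed_min_sum:
        return None
    return v / total


def hexaploid_log_deviation(
    tpms, pseudocount: float = PSEUDOCOUNT, expectation: float = EXPECTATION
) -> np.ndarray:
    """Per-subgenome log2 deviation from the balanced expectation.

    entry_i = log2(((TPM_i + c) / (sum(TPM) + c)) / expectation).
    """
    v = np.asarray(tpms, dtype=float)
    if (v < 0).any():
        raise InputError("negative TPM")
    total = v.sum()
    return np.log2(((v + pseudocount) / (total + pseudocount)) / expectation)


def classify_triad(
    relative,
    points: dict[str, np.ndarray] | None = None,
    labels: tuple[str, ...] = ("A", "B", "C"),
    tie_tol: float = 1e-12,
) -> tuple[str, float, bool]:
    """Assign the category of the nearest ideal point (Euclidean).

    Ties within ``tie_tol`` are resolved by the fixed category order of
    :func:`ideal_points` and flagged.
    """
    v = np.asarray(relative, dtype=float)
    if abs(v.sum() - 1.0) > 1e-6:
        raise InputError(f"relative vector must sum to 1, got {v.sum()!r}")
    if points is None:
        points = ideal_points(labels)
    best_cat, best_d = None, np.inf
    n_tied = 0
    for cat, p in points.items():
        d = float(np.linalg.norm(v - p))
        if d < best_d - tie_tol:
            best_cat, best_d, n_tied = cat, d, 1
        elif d <= best_d + tie_tol:
            n_tied += 1
    return best_cat, best_d, n_tied > 1


def categorize_species(
    matrix: ExpressionMatrix,
    hmap: HomoeologMap,
    tissues: list[str] | None = None,
    expressed_min_sum: float = EXPRESSED_MIN_SUM,
    include_balanced: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every expressed triad in every tissue.

    ``matrix`` must be a replicate-averaged TPM matrix (one column per
    tissue).  Returns ``(percentages, per_triad)``:

    * ``percentages`` — tissues × categories, percent of expressed triads
      (rows sum to 100; an extra ``(mean)`` row averages across tissues;
      a tissue with no expressed triads gets NaNs).
    * ``per_triad`` — one row per triad per tissue with relative
      coordinates, category, distance and flags.
    """
    if matrix.unit != "tpm":
        raise InputError("categorize_species expects an averaged TPM matrix")
    if hmap.ratio_class != "triad":
        raise InputError("categorize_species requires a triad map")
    if tissues is None:
        tissues = list(matrix.samples)
    labels = tuple(hmap.subgenomes)
    points = ideal_points(labels, include_balanced=include_balanced)
    categories = list(points)

    rows = []
    for gid in sorted(hmap.groups):
        members = hmap.groups[gid]
        genes = [members.get(lab) for lab in labels]
        if any(g is None or g not in matrix.genes for g in genes):
            logger.warning("group %s has members absent from the matrix; skipped", gid)
            continue
        sub = matrix.data.loc[genes, tissues].to_numpy()
        for j, t in enumerate(tissues):
            rel = triad_relative_expression(sub[:, j], expressed_min_sum)
            if rel is None:
                rows.append(
                    {"group": gid, "tissue": t, "expressed": False, "category": None,
                     "distance": None, "tie": False,
                     **{f"rel_{lab}": np.nan for lab in labels}}
                )
                continue
            cat, d, tie = classify_triad(rel, points)
            rows.append(
                {"group": gid, "tissue": t, "expressed": True, "category": cat,
                 "distance": d, "tie": tie,
                 **{f"rel_{lab}": rel[i] for i, lab in enumerate(labels)}}
            )
    per_triad = pd.DataFrame(rows)

    pct_rows = {}
    for t in tissues:
        sub = per_triad[(per_triad["tissue"] == t) & per_triad["expressed"]]
        if len(sub) == 0:
            logger.warning("tissue %s has no expressed triads", t)
            pct_rows[t] = pd.Series({c: np.nan for c in categories})
            continue
        counts = sub["category"].value_counts()
        pct_rows[t] = pd.Series({c: 100.0 * counts.get(c, 0) / len(sub) for c in categories})
    percentages = pd.DataFrame(pct_rows).T[categories]
    percentages.loc["(mean)"] = percentages.loc[tissues].mean(axis=0)
    percentages.index.name = "tissue"
    return percentages, per_triad


def relative_subgenome_abundance(matrix: ExpressionMatrix, hmap: HomoeologMap) -> pd.Series:
    """Percent of total homoeolog-group TPM contributed by each subgenome.

    Sums TPM over all group members and all samples; the result sums to 100.
    """
    if len(hmap) == 0:
        raise InputError("empty homoeolog map")
    labels = tuple(hmap.subgenomes)
    totals = {lab: 0.0 for lab in labels}
    for members in hmap.groups.values():
        for lab in labels:
            gene = members.get(lab)
            if gene is not None and gene in matrix.genes:
                totals[lab] += float(matrix.data.loc[gene].sum())
    grand = sum(totals.values())
    if grand == 0:
        raise InputError("no expression in any homoeolog group")
    return pd.Series({lab: 100.0 * v / grand for lab, v in totals.items()})


def _welch_t(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Welch t-test p-value; identical inputs give p = 1."""
    if np.allclose(x, y) or (np.std(x) == 0 and np.std(y) == 0 and np.mean(x) == np.mean(y)):
        return 1.0
    p = stats.ttest_ind(x, y, equal_var=False).pvalue
    return 1.0 if np.isnan(p) else float(p)


def upregulated_counts(
    matrix: ExpressionMatrix,
    hmap: HomoeologMap,
    tissue: str,
    alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
    pseudocount: float = PSEUDOCOUNT,
    test=_welch_t,
) -> pd.DataFrame:
    """Count up-regulated homoeologs per ordered subgenome pair in a tissue.

    For every group and every subgenome pair (x, y), a two-sided test
    (default Welch t) on log2(TPM+1) replicate values; BH adjustment across
    all groups tested within this tissue for that pair; x counts as "up"
    over y when adjusted p < ``alpha`` and log2 of the ratio of replicate
    TPM means (pseudocounted) is >= ``min_abs_log2fc``.

    ``matrix`` must be the replicate-level TPM matrix with >= 2 replicates
    in ``tissue``.
    """
    if matrix.unit != "tpm":
        raise InputError("upregulated_counts expects a replicate-level TPM matrix")
    samples = [s for s in matrix.samples if str(matrix.meta.loc[s, "tissue"]) == tissue]
    if len(samples) < 2:
        raise InputError(
            f"tissue {tissue!r} has {len(samples)} replicates; need >= 2 "
            "(use pair_log_ratio summaries instead)"
        )
    labels = tuple(hmap.subgenomes)
    logdata = np.log2(matrix.data[samples] + 1.0)

    out_rows = []
    for i, x in enumerate(labels):
        for y in labels[i + 1:]:
            gids, pvals, fcs = [], [], []
            for gid in sorted(hmap.groups):
                members = hmap.groups[gid]
                gx, gy = members.get(x), members.get(y)
                if gx is None or gy is None or gx not in matrix.genes or gy not in matrix.genes:
                    continue
                vx = logdata.loc[gx].to_numpy()
                vy = logdata.loc[gy].to_numpy()
                mean_x = float(matrix.data.loc[gx, samples].mean())
                mean_y = float(matrix.data.loc[gy, samples].mean())
                gids.append(gid)
                pvals.append(test(vx, vy))
                fcs.append(np.log2((mean_x + pseudocount) / (mean_y + pseudocount)))
            if not gids:
                continue
            adj = multipletests(pvals, method="fdr_bh")[1]
            fcs = np.asarray(fcs)
            sig = adj < alpha
            up_x = int(np.sum(sig & (fcs >= min_abs_log2fc)))
            up_y = int(np.sum(sig & (fcs <= -min_abs_log2fc)))
            out_rows.append({"up": x, "vs": y, "count": up_x, "n_tested": len(gids)})
            out_rows.append({"up": y, "vs": x, "count": up_y, "n_tested": len(gids)})
    return pd.DataFrame(out_rows, columns=["up", "vs", "count", "n_tested"])
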