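"""Fractionation-bias tracks: windowed gene retention per subgenome.

Given an ordered reference gene list (e.g. syntenic gene order against an
outgroup genome) and a presence flag per subgenome, sliding windows of a
fixed gene count (default 100 genes) yield retention fractions per
subgenome.  Window coordinates are 0-based half-open [start, start+window)
and never span reference chromosome boundaries.  Retention distributions
between subgenomes are compared with the two-sided Wilcoxon rank-sum test,
and homoeologous groups with arbitrary copy counts are censused by their
sorted copy-count signature (1:1, 1:1:1, 1:1:0, ...).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)


@dataclass
class RetentionTrack:
    """Ordered reference genes with per-subgenome presence flags.

    ``frame`` has columns ``ref_chrom``, ``ref_index`` (0-based within
    chromosome, contiguous), ``ref_gene_id``; ``presence`` is a boolean
    DataFrame aligned row-for-row with one column per subgenome.
    """

    frame: pd.DataFrame
    presence: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("ref_chrom", "ref_index", "ref_gene_id"):
            if col not in self.frame.columns:
                raise FormatError(f"track is missing column {col!r}")
        if len(self.frame) != len(self.presence):
            raise FormatError("frame and presence must have the same length")
        for chrom, sub in self.frame.groupby("ref_chrom"):
            idx = np.sort(sub["ref_index"].to_numpy())
            if not np.array_equal(idx, np.arange(len(idx))):
                raise FormatError(f"ref_index not contiguous from 0 on {chrom!r}")

    @property
    def subgenomes(self) -> list[str]:
        return list(self.presence.columns)

    def __len__(self) -> int:
        return len(self.frame)


def read_retention_track(path) -> RetentionTrack:
    """Read a long-format retention TSV.

    Columns: ref_chrom, ref_index (0-based within chromosome),
    ref_gene_id, subgenome, present (0/1).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"ref_chrom", "ref_index", "ref_gene_id", "subgenome", "present"}
    if not need.issubset(df.columns):
        raise FormatError(f"retention TSV must have columns {sorted(need)}")
    wide = df.pivot_table(
        index=["ref_chrom", "ref_index", "ref_gene_id"],
        columns="subgenome",
        values="present",
        aggfunc="first",
    )
    if wide.isna().any().any():
        raise FormatError("every reference gene needs a flag for every subgenome")
    wide = wide.sort_index().reset_index()
    frame = wide[["ref_chrom", "ref_index", "ref_gene_id"]]
    presence = wide.drop(columns=["ref_chrom", "ref_index", "ref_gene_id"]).astype(bool)
    presence.columns.name = None
    return RetentionTrack(frame=frame, presence=presence)


def write_retention_track(track: RetentionTrack, path) -> None:
    rows = []
    for i in range(len(track)):
        for sub in track.subgenomes:
            rows.append(
                {
                    "ref_chrom": track.frame["ref_chrom"].iat[i],
                    "ref_index": int(track.frame["ref_index"].iat[i]),
                    "ref_gene_id": track.frame["ref_gene_id"].iat[i],
                    "subgenome": sub,
                    "present": int(track.presence[sub].iat[i]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def windowed_retention(track: RetentionTrack, window: int = 100, step: int = 10) -> pd.DataFrame:
    """Sliding-window retention fractions per subgenome.

    Windows [i, i+window) at stride ``step`` within each chromosome;
    trailing partial windows are dropped.  Returns columns subgenome,
    ref_chrom, start, fraction.
    """
    if window < 1 or step < 1:
        raise InputError("window and step must be positive")
    chrom_lengths = track.frame.groupby("ref_chrom").size()
    if window > chrom_lengths.max():
        raise InputError(f"window {window} exceeds the longest chromosome ({chrom_lengths.max()})")
    rows = []
    pres_all = track.presence.to_numpy()
    chroms_all = track.frame["ref_chrom"].to_numpy()
    idx_all = track.frame["ref_index"].to_numpy()
    for chrom in chrom_lengths.index:
        mask = chroms_all == chrom
        order = idx_all[mask].argsort()
        pres = pres_all[mask][order]
        n = pres.shape[0]
        for start in range(0, n - window + 1, step):
            block = pres[start : start + window]
            for j, sub in enumerate(track.subgenomes):
                rows.append(
                    {"subgenome": sub, "ref_chrom": chrom, "start": start,
                     "fraction": float(block[:, j].sum()) / window}
                )
    return pd.DataFrame(rows, columns=["subgenome", "ref_chrom", "start", "fraction"])


def compare_retention(windows: pd.DataFrame) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests on window fractions.

    One row per subgenome pair with window counts, medians, the rank-sum
    statistic, p-value and the direction (which subgenome has the higher
    median; 'equal' when tied).  Pairs of identical constant samples are
    reported with p = 1 and a degeneracy note.
    """
    subs = sorted(windows["subgenome"].unique())
    if len(subs) < 2:
        raise InputError("need at least two subgenomes to compare")
    rows = []
    for a, b in combinations(subs, 2):
        xa = windows.loc[windows["subgenome"] == a, "fraction"].to_numpy()
        xb = windows.loc[windows["subgenome"] == b, "fraction"].to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            raise InputError("each subgenome needs >= 2 windows")
        note = ""
        if np.all(xa == xa[0]) and np.all(xb == xb[0]) and xa[0] == xb[0]:
            stat, p = 0.0, 1.0
            note = "degenerate: identical constant samples"
        else:
            stat, p = stats.ranksums(xa, xb)
        med_a, med_b = float(np.median(xa)), float(np.median(xb))
        direction = a if med_a > med_b else b if med_b > med_a else "equal"
        rows.append(
            {"subgenome_1": a, "subgenome_2": b, "n_1": len(xa), "n_2": len(xb),
             "median_1": med_a, "median_2": med_b, "statistic": float(stat),
             "pvalue": float(p), "higher": direction, "note": note}
        )
    return pd.DataFrame(rows)


def group_ratio_census(copy_counts: pd.DataFrame) -> pd.Series:
    """Percent of homoeolog groups per sorted copy-count signature.

    ``copy_counts`` is groups × subgenomes with nonnegative integer copy
    numbers.  The signature sorts counts in decreasing order, colon-joined
    (a complete triad is '1:1:1', one loss '1:1:0').  Percentages sum
    to 100 and are invariant to group order.
    """
    if copy_counts.empty:
        raise InputError("empty copy-count table")
    vals = copy_counts.to_numpy()
    if (vals < 0).any():
        raise InputError("copy counts must be nonnegative")
    sigs = [":".join(str(c) for c in sorted(row, reverse=True)) for row in vals.astype(int)]
    counts = pd.Series(sigs).value_counts()
    return (100.0 * counts / len(sigs)).sort_index()
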