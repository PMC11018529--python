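"""Expression tables, homoeolog maps and the standard preprocessing steps.

The unit of analysis is an :class:`ExpressionMatrix` — a genes × samples
table of raw counts or TPM together with per-sample metadata (species,
tissue, replicate).  Preprocessing follows the conventional bulk RNA-seq
path for homoeolog comparisons:

1. ``counts_to_tpm``       — length- and depth-normalise raw counts,
2. ``filter_expressed``    — keep genes with TPM >= 1 in at least two samples,
3. ``average_replicates``  — arithmetic mean of replicate TPMs per tissue,
4. ``log_transform``       — log2(TPM + 1) for pattern-level analyses.

The expressed-gene filter runs on the replicate-level TPM matrix, before
replicate averaging; the two operations do not commute and the pipeline
order is fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

META_COLUMNS = ("species", "tissue", "replicate")

#: Units an ExpressionMatrix may carry. "log2tpm" marks log2(TPM+1)-scale
#: data (including latent-factor simulations) and is exempt from the
#: nonnegativity check applied to counts/tpm.
VALID_UNITS = ("counts", "tpm", "log2tpm")


@dataclass
class ExpressionMatrix:
    """Genes × samples expression table with per-sample metadata.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with one column per sample id.
    meta
        DataFrame indexed by sample id with columns ``species``,
        ``tissue`` and ``replicate``.
    unit
        One of ``counts``, ``tpm``, ``log2tpm``.
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.unit not in VALID_UNITS:
            raise FormatError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        missing = [s for s in self.data.columns if s not in self.meta.index]
        if missing:
            raise FormatError(f"samples without metadata: {missing}")
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                raise FormatError(f"metadata is missing required column {col!r}")
        if self.unit in ("counts", "tpm"):
            vals = self.data.to_numpy()
            if (vals < 0).any():
                g, s = np.argwhere(vals < 0)[0]
                raise FormatError(
                    f"negative value at gene {self.data.index[g]!r}, "
                    f"sample {self.data.columns[s]!r}"
                )

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def tissues(self) -> list[str]:
        """Unique tissues in sample (column) order."""
        seen: dict[str, None] = {}
        for s in self.data.columns:
            seen.setdefault(str(self.meta.loc[s, "tissue"]), None)
        return list(seen)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), self.meta.copy(), self.unit)


@dataclass
class HomoeologMap:
    """Groups of homoeologous genes keyed by subgenome label.

    ``groups`` maps a group id to ``{subgenome label: gene id}``.  A pair
    has exactly 2 members, a triad exactly 3, and no gene id may occur in
    two groups.
    """

    groups: dict[str, dict[str, str]]
    ratio_class: str = "triad"
    subgenomes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.ratio_class not in ("pair", "triad"):
            raise FormatError(f"ratio_class must be 'pair' or 'triad', got {self.ratio_class!r}")
        expected = 2 if self.ratio_class == "pair" else 3
        seen_genes: dict[str, str] = {}
        labels: set[str] = set()
        for gid, members in self.groups.items():
            if len(members) != expected:
                raise FormatError(
                    f"group {gid!r} has {len(members)} members; "
                    f"a {self.ratio_class} requires {expected}"
                )
            for sub, gene in members.items():
                labels.add(sub)
                if gene in seen_genes:
                    raise FormatError(
                        f"gene {gene!r} occurs in groups {seen_genes[gene]!r} and {gid!r}"
                    )
                seen_genes[gene] = gid
        if not self.subgenomes:
            self.subgenomes = tuple(sorted(labels))

    def __len__(self) -> int:
        return len(self.groups)

    def gene_to_subgenome(self) -> dict[str, str]:
        return {g: sub for m in self.groups.values() for sub, g in m.items()}


# ---------------------------------------------------------------------------
# readers / writers (TSV, '#' comments ignored, UTF-8)
# ---------------------------------------------------------------------------

_TSV_KW = dict(sep="\t", comment="#", dtype=None, encoding="utf-8")


def read_expression(table_path, meta_path) -> ExpressionMatrix:
    """Read an expression TSV (first column gene id) plus a metadata TSV.

    The metadata file must carry columns ``sample_id``, ``species``,
    ``tissue``, ``replicate`` and ``unit``; the unit must be uniform across
    samples.
    """
    data = pd.read_csv(table_path, index_col=0, **_TSV_KW)
    meta = pd.read_csv(meta_path, **_TSV_KW)
    if "sample_id" not in meta.columns or "unit" not in meta.columns:
        raise FormatError("metadata must have 'sample_id' and 'unit' columns")
    meta = meta.set_index("sample_id")
    units = set(meta["unit"].astype(str))
    if len(units) != 1:
        raise FormatError(f"mixed units in metadata: {sorted(units)}")
    return ExpressionMatrix(data, meta.drop(columns=["unit"]), unit=units.pop())


def write_expression(m: ExpressionMatrix, table_path, meta_path) -> None:
    """Write the matrix and its metadata as TSV (6 significant digits)."""
    m.data.to_csv(table_path, sep="\t", index_label="gene_id", float_format="%.6g")
    meta = m.meta.copy()
    meta["unit"] = m.unit
    meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_homoeolog_map(path, ratio_class: str, strict: bool = True) -> HomoeologMap:
    """Read a homoeolog-map TSV with columns group_id, subgenome, gene_id.

    Groups with the wrong member count raise (``strict=True``) or are
    dropped with a logged warning.
    """
    df = pd.read_csv(path, **_TSV_KW)
    for col in ("group_id", "subgenome", "gene_id"):
        if col not in df.columns:
            raise FormatError(f"homoeolog map is missing column {col!r}")
    if df.empty:
        logger.warning("homoeolog map %s is empty", path)
        return HomoeologMap({}, ratio_class=ratio_class)
    expected = 2 if ratio_class == "pair" else 3
    groups: dict[str, dict[str, str]] = {}
    for gid, sub in df.groupby("group_id", sort=True):
        members = dict(zip(sub["subgenome"].astype(str), sub["gene_id"].astype(str)))
        if len(members) != len(sub):
            raise FormatError(f"group {gid!r} repeats a subgenome label")
        if len(members) != expected:
            if strict:
                raise FormatError(
                    f"group {gid!r} has {len(members)} members; "
                    f"a {ratio_class} requires {expected}"
                )
            logger.warning("dropping group %s with %d members", gid, len(members))
            continue
        groups[str(gid)] = members
    return HomoeologMap(groups, ratio_class=ratio_class)


def write_homoeolog_map(hmap: HomoeologMap, path) -> None:
    rows = [
        {"group_id": gid, "subgenome": sub, "gene_id": gene}
        for gid, members in sorted(hmap.groups.items())
        for sub, gene in sorted(members.items())
    ]
    pd.DataFrame(rows, columns=["group_id", "subgenome", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_lengths(path) -> pd.Series:
    df = pd.read_csv(path, **_TSV_KW)
    if "gene_id" not in df.columns or "length" not in df.columns:
        raise FormatError("gene-length table needs 'gene_id' and 'length' columns")
    return df.set_index("gene_id")["length"].astype(float)


def write_gene_lengths(lengths: pd.Series, path) -> None:
    lengths.rename("length").to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def counts_to_tpm(m: ExpressionMatrix, lengths: pd.Series | dict) -> ExpressionMatrix:
    """Convert raw counts to TPM (transcripts per million).

    Per sample: rate_g = count_g / length_g, TPM_g = rate_g / sum(rates) * 1e6,
    so each sample column sums to 1e6.
    """
    if m.unit != "counts":
        raise InputError(f"counts_to_tpm expects counts, got unit {m.unit!r}")
    lengths = pd.Series(lengths, dtype=float)
    missing = m.genes.difference(lengths.index)
    if len(missing):
        raise InputError(f"genes without lengths: {list(missing[:5])}")
    lens = lengths.reindex(m.genes)
    if (lens <= 0).any():
        raise InputError("all gene lengths must be positive")
    rates = m.data.div(lens, axis=0)
    totals = rates.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise InputError(f"all-zero sample column(s): {list(zero)}")
    tpm = rates.div(totals, axis=1) * 1e6
    return ExpressionMatrix(tpm, m.meta, unit="tpm")


def filter_expressed(
    m: ExpressionMatrix, min_tpm: float = 1.0, min_samples: int = 2
) -> ExpressionMatrix:
    """Keep genes with TPM >= ``min_tpm`` in at least ``min_samples`` samples."""
    if m.unit != "tpm":
        raise InputError(f"filter_expressed expects TPM, got unit {m.unit!r}")
    keep = (m.data >= min_tpm).sum(axis=1) >= min_samples
    return ExpressionMatrix(m.data.loc[keep], m.meta, unit=m.unit)


def average_replicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Arithmetic mean over replicates: one pseudo-sample per tissue.

    Tissue order follows first appearance in the sample columns.
    """
    tissues = m.tissues()
    if not tissues:
        raise InputError("matrix has no samples")
    cols = {}
    meta_rows = []
    species = m.meta["species"].iloc[0] if len(m.meta) else "NA"
    for t in tissues:
        samples = [s for s in m.samples if str(m.meta.loc[s, "tissue"]) == t]
        if not samples:
            raise InputError(f"tissue {t!r} has no samples")
        cols[t] = m.data[samples].mean(axis=1)
        meta_rows.append({"sample_id": t, "species": species, "tissue": t, "replicate": 1})
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return ExpressionMatrix(pd.DataFrame(cols), meta, unit=m.unit)


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1); zeros map to zero."""
    if m.unit != "tpm":
        raise InputError(f"log_transform expects TPM, got unit {m.unit!r}")
    return ExpressionMatrix(np.log2(m.data + 1.0), m.meta, unit="log2tpm")


def drop_outlier_replicates(m: ExpressionMatrix, min_corr: float = 0.8) -> ExpressionMatrix:
    """Drop replicates poorly correlated with their tissue-mates.

    Per tissue, the replicate with the worst Pearson correlation to the
    centroid (mean profile) of its tissue-mates is dropped while that
    correlation is below ``min_corr``, recomputing after each removal and
    keeping at least 2 replicates.  Declared stand-in for by-eye
    hierarchical-clustering outlier removal; tissues with fewer than 3
    replicates are left alone.
    """
    drop: list[str] = []
    for t in m.tissues():
        samples = [s for s in m.samples if str(m.meta.loc[s, "tissue"]) == t]
        while len(samples) > 2:
            corrs = {}
            for s in samples:
                others = [o for o in samples if o != s]
                centroid = m.data[others].mean(axis=1).to_numpy()
                x = m.data[s].to_numpy()
                if np.std(x) == 0 or np.std(centroid) == 0:
                    continue
                corrs[s] = np.corrcoef(x, centroid)[0, 1]
            if not corrs:
                break
            worst = min(corrs, key=corrs.get)
            if corrs[worst] >= min_corr:
                break
            drop.append(worst)
            samples.remove(worst)
            logger.warning(
                "dropping outlier replicate %s (r=%.3f to centroid)", worst, corrs[worst]
            )
    if not drop:
        return m
    keep = [s for s in m.samples if s not in drop]
    return ExpressionMatrix(m.data[keep], m.meta.loc[keep], unit=m.unit)
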