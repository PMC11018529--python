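"""Seeded synthetic data with the statistical structure the analysis assumes.

Three generators, each with a truth table for recovery testing:

* :func:`simulate_expression` — replicate-level RNA-seq counts for
  homoeolog pairs/triads with planted balanced/dominant/suppressed
  categories, negative-binomial noise (variance = mu + phi * mu^2),
  library-size variation and per-gene lengths, so the TPM pathway is
  exercised downstream.
* :func:`simulate_modules` — latent-factor co-expression modules with
  planted hubs whose subgenome labels follow configurable weights.
* :func:`simulate_retention` — ordered reference genes with independent
  per-subgenome loss probabilities (biased fractionation).

Each simulator draws from its own RNG stream derived from the master seed,
so adding one call never perturbs another's draws.  Identical seed and
configuration give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import ExpressionMatrix, HomoeologMap
from .retention import RetentionTrack

DEFAULT_TISSUES = ("leaf_blade", "leaf_sheath", "shoot", "root", "rhizome")

# fixed per-simulator stream offsets
_STREAM_EXPRESSION = 1
_STREAM_MODULES = 2
_STREAM_RETENTION = 3


def default_category_proportions(labels: tuple[str, ...]) -> dict[str, float]:
    """Balanced-heavy mixture: 76.9% balanced, 6% dominant and 17.1%
    suppressed split equally among subgenomes (triad field values typical
    of balanced-dominated allopolyploids)."""
    n = len(labels)
    props = {"Balanced": 0.769}
    for lab in sorted(labels):
        props[f"{lab}_dominant"] = 0.06 / n
    for lab in sorted(labels):
        props[f"{lab}_suppressed"] = 0.171 / n
    # absorb rounding into Balanced so the mixture sums to exactly 1
    props["Balanced"] = 1.0 - (sum(props.values()) - props["Balanced"])
    return props


@dataclass
class SimulationConfig:
    """Configuration of the expression simulator.

    Defaults state the emulated study design: 1,157 triad groups across
    5 tissues with 3 biological replicates, an 8-fold planted dominance
    effect and mild negative-binomial overdispersion.
    """

    n_groups: int = 1157
    ratio_class: str = "triad"
    subgenome_labels: tuple[str, ...] = ("A", "B", "C")
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    replicates_per_tissue: int = 3
    category_proportions: dict[str, float] | None = None
    dominance_fold: float = 8.0
    base_mean: float = 20.0
    base_log_sd: float = 1.0
    nb_dispersion: float = 0.05
    library_size_cv: float = 0.1
    gene_length_range: tuple[int, int] = (500, 5000)
    seed: int = 0

    def __post_init__(self) -> None:
        expected = 2 if self.ratio_class == "pair" else 3
        if self.ratio_class not in ("pair", "triad"):
            raise ConfigurationError(f"ratio_class must be 'pair' or 'triad', got {self.ratio_class!r}")
        if len(self.subgenome_labels) != expected:
            raise ConfigurationError(
                f"{self.ratio_class} needs {expected} subgenome labels, "
                f"got {len(self.subgenome_labels)}"
            )
        if self.n_groups < 1:
            raise ConfigurationError("n_groups must be >= 1")
        if self.replicates_per_tissue < 1:
            raise ConfigurationError("replicates_per_tissue must be >= 1")
        if self.dominance_fold <= 1:
            raise ConfigurationError("dominance_fold must be > 1")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if self.library_size_cv < 0:
            raise ConfigurationError("library_size_cv must be >= 0")
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("gene_length_range must satisfy 1 <= min <= max")
        if self.category_proportions is None:
            self.category_proportions = default_category_proportions(self.subgenome_labels)
        valid = {"Balanced"} | {
            f"{lab}_{kind}" for lab in self.subgenome_labels for kind in ("dominant", "suppressed")
        }
        unknown = set(self.category_proportions) - valid
        if unknown:
            raise ConfigurationError(f"unknown categories for these labels: {sorted(unknown)}")
        vals = np.array(list(self.category_proportions.values()), dtype=float)
        if (vals < 0).any():
            raise ConfigurationError("category proportions must be nonnegative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"category proportions sum to {vals.sum()!r}, expected 1")


@dataclass
class TruthTable:
    """Ground truth emitted by the simulators (fields filled as relevant).

    * categories — group id -> planted bias category (constant over tissues)
    * mean_tpm — gene id -> configured mean expression on the TPM scale
    * modules — gene id -> planted module id
    * hub_flags — gene id -> planted hub status
    * gene_subgenome — gene id -> subgenome label
    * losses — reference-gene loss flags per subgenome (True = lost)
    """

    categories: dict[str, str] | None = None
    mean_tpm: dict[str, float] | None = None
    modules: dict[str, int] | None = None
    hub_flags: dict[str, bool] | None = None
    gene_subgenome: dict[str, str] | None = None
    losses: pd.DataFrame | None = field(default=None, repr=False)

    def to_json(self, path) -> None:
        payload = {
            "categories": self.categories,
            "mean_tpm": self.mean_tpm,
            "modules": self.modules,
            "hub_flags": self.hub_flags,
            "gene_subgenome": self.gene_subgenome,
            "losses": None if self.losses is None else self.losses.astype(int).to_dict("list"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.Series, HomoeologMap, TruthTable]:
    """Replicate-level homoeolog counts with planted bias categories.

    Per group, a base TPM-scale mean is drawn log-normally around
    ``base_mean`` (median); a planted 'X_dominant' group multiplies the X
    homoeolog's mean by ``dominance_fold`` and 'X_suppressed' divides it.
    Expected counts are mean_tpm * (length/1000) * library_factor; counts
    are negative binomial with variance mu + phi * mu^2 (Poisson at
    phi = 0).  Returns (counts, gene lengths in bp, homoeolog map, truth).
    """
    cfg = config
    rng = np.random.default_rng([_STREAM_EXPRESSION, cfg.seed])
    labels = tuple(cfg.subgenome_labels)
    n, g_per = cfg.n_groups, len(labels)

    cats = sorted(cfg.category_proportions)
    probs = np.array([cfg.category_proportions[c] for c in cats])
    planted = rng.choice(cats, size=n, p=probs / probs.sum())

    group_ids = [f"grp{i:05d}" for i in range(n)]
    gene_ids = [f"g{i:05d}_{lab}" for i in range(n) for lab in labels]
    groups = {
        gid: {lab: f"g{i:05d}_{lab}" for lab in labels}
        for i, gid in enumerate(group_ids)
    }
    hmap = HomoeologMap(groups, ratio_class=cfg.ratio_class, subgenomes=labels)

    base = cfg.base_mean * np.exp(rng.normal(0.0, cfg.base_log_sd, size=n))
    mean_tpm = np.repeat(base[:, None], g_per, axis=1)  # groups × labels
    for i, cat in enumerate(planted):
        if cat == "Balanced":
            continue
        lab, kind = cat.rsplit("_", 1)
        j = labels.index(lab)
        if kind == "dominant":
            mean_tpm[i, j] *= cfg.dominance_fold
        else:
            mean_tpm[i, j] /= cfg.dominance_fold
    mean_flat = mean_tpm.reshape(-1)  # gene order matches gene_ids

    lo, hi = cfg.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n * g_per).astype(float)

    sample_ids, meta_rows = [], []
    for t in cfg.tissues:
        for r in range(1, cfg.replicates_per_tissue + 1):
            sid = f"{t}_rep{r}"
            sample_ids.append(sid)
            meta_rows.append(
                {"sample_id": sid, "species": "synthetic", "tissue": t, "replicate": r}
            )
    n_samples = len(sample_ids)

    if cfg.library_size_cv > 0:
        sigma2 = np.log1p(cfg.library_size_cv**2)
        lib = np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=n_samples))
    else:
        lib = np.ones(n_samples)

    mu = mean_flat[:, None] * (lengths[:, None] / 1000.0) * lib[None, :]
    if cfg.nb_dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r_nb = 1.0 / cfg.nb_dispersion
        p_nb = r_nb / (r_nb + mu)
        counts = rng.negative_binomial(r_nb, p_nb)

    data = pd.DataFrame(counts.astype(float), index=gene_ids, columns=sample_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    matrix = ExpressionMatrix(data, meta, unit="counts")
    truth = TruthTable(
        categories=dict(zip(group_ids, planted)),
        mean_tpm=dict(zip(gene_ids, mean_flat)),
        gene_subgenome={g: g.rsplit("_", 1)[1] for g in gene_ids},
    )
    return matrix, pd.Series(lengths, index=gene_ids, name="length"), hmap, truth


def simulate_modules(
    n_genes: int,
    n_modules: int,
    hub_subgenome_weights: dict[str, float] | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    n_samples: int = 15,
    hub_quantile: float = 0.9,
    min_module_size: int = 30,
    loading_range: tuple[float, float] = (0.5, 1.5),
    baseline: float = 8.0,
) -> tuple[ExpressionMatrix, TruthTable]:
    """Latent-factor co-expression modules with planted subgenome-labelled hubs.

    Each module has one latent sample profile; a member gene is
    baseline + loading * latent + N(0, noise_sd).  Genes whose loading is
    at or above the per-module ``hub_quantile`` are planted hubs; hub
    subgenome labels are drawn with ``hub_subgenome_weights`` (uniform for
    non-hubs).  Values are log2(TPM+1)-scale.
    """
    if n_modules < 1:
        raise ConfigurationError("n_modules must be >= 1")
    if n_genes < n_modules * min_module_size:
        raise ConfigurationError(
            f"n_genes={n_genes} < n_modules*min_module_size={n_modules * min_module_size}"
        )
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    if hub_subgenome_weights is None:
        hub_subgenome_weights = {"A": 1.0, "B": 1.0, "C": 1.0}
    wl = sorted(hub_subgenome_weights)
    wv = np.array([hub_subgenome_weights[k] for k in wl], dtype=float)
    if (wv < 0).any() or wv.sum() == 0:
        raise ConfigurationError("hub weights must be nonnegative and not all zero")
    wv = wv / wv.sum()

    rng = np.random.default_rng([_STREAM_MODULES, seed])
    module_of = np.arange(n_genes) % n_modules + 1
    latents = rng.normal(size=(n_modules, n_samples))
    loadings = rng.uniform(loading_range[0], loading_range[1], size=n_genes)
    values = np.empty((n_genes, n_samples))
    hub = np.zeros(n_genes, dtype=bool)
    for m in range(1, n_modules + 1):
        idx = np.flatnonzero(module_of == m)
        cut = np.quantile(loadings[idx], hub_quantile)
        hub[idx] = loadings[idx] >= cut
        values[idx] = baseline + loadings[idx, None] * latents[m - 1][None, :]
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=values.shape)

    subs = np.where(
        hub,
        rng.choice(wl, size=n_genes, p=wv),
        rng.choice(wl, size=n_genes),
    )
    gene_ids = [f"mg{i:05d}" for i in range(n_genes)]
    sample_ids = [f"s{j:02d}" for j in range(n_samples)]
    meta = pd.DataFrame(
        {"sample_id": sample_ids, "species": "synthetic",
         "tissue": [f"t{j // max(1, n_samples // 5)}" for j in range(n_samples)],
         "replicate": list(range(1, n_samples + 1))}
    ).set_index("sample_id")
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), meta, unit="log2tpm"
    )
    truth = TruthTable(
        modules=dict(zip(gene_ids, module_of.tolist())),
        hub_flags=dict(zip(gene_ids, hub.tolist())),
        gene_subgenome=dict(zip(gene_ids, subs.tolist())),
    )
    return matrix, truth


def simulate_retention(
    n_reference_genes: int,
    loss_prob_per_subgenome: dict[str, float],
    seed: int = 0,
    n_chromosomes: int = 1,
) -> tuple[RetentionTrack, TruthTable]:
    """Ordered reference genes with independent per-subgenome loss.

    Each reference gene is retained in subgenome s with probability
    1 - loss_prob(s), independently.  Genes are split evenly over
    ``n_chromosomes`` reference chromosomes.
    """
    if n_reference_genes < 1:
        raise ConfigurationError("n_reference_genes must be >= 1")
    for sub, p in loss_prob_per_subgenome.items():
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"loss probability for {sub!r} must be in [0, 1]")
    rng = np.random.default_rng([_STREAM_RETENTION, seed])
    subs = sorted(loss_prob_per_subgenome)
    lost = {
        sub: rng.random(n_reference_genes) < loss_prob_per_subgenome[sub] for sub in subs
    }
    per_chrom = int(np.ceil(n_reference_genes / n_chromosomes))
    chroms, idxs = [], []
    for i in range(n_reference_genes):
        chroms.append(f"chr{i // per_chrom + 1}")
        idxs.append(i % per_chrom)
    frame = pd.DataFrame(
        {"ref_chrom": chroms, "ref_index": idxs,
         "ref_gene_id": [f"ref{i:05d}" for i in range(n_reference_genes)]}
    )
    presence = pd.DataFrame({sub: ~lost[sub] for sub in subs})
    track = RetentionTrack(frame=frame, presence=presence)
    truth = TruthTable(losses=pd.DataFrame(lost))
    return track, truth
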