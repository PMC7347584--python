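"""Synthetic data generators emulating the study design.

Three generators produce the tables every downstream stage consumes:

- phenotype tables: two groups (NC/VT) x three generations with normal
  trait noise, configurable NC-minus-VT shifts and an optional body-weight
  covariate effect;
- expression matrices: negative-binomial counts with a configurable
  fraction of truly differential genes (symmetric half-fold-change applied
  to each group) and a length-1kb FPKM view;
- metabolite tables: log-normal intensities in two fractions with
  fraction-specific fold changes for true DAMs, per-sample instrument
  scale factors and constant internal-standard rows.

Every generator is deterministic given its seed; sub-streams are derived
per generation/group with stable hashing, so adding a generation never
perturbs earlier draws.  Ground-truth annotations are returned alongside
the tables (and written as TSV sidecars by the CLI) for use by tests only,
never by pipeline stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from transgen.errors import ConfigError
from transgen.metabolome import FRACTIONS, MetaboliteTable
from transgen.transcript import ExpressionMatrix
from transgen.util import subseed

GENERATIONS = ("F1", "F2", "F3")
GROUPS = ("NC", "VT")


# ---------------------------------------------------------------------------
# Phenotype
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhenoSimConfig:
    """Configuration for the phenotype generator.

    ``group_deltas`` maps ``(trait, generation)`` to the NC-minus-VT shift
    in trait units; absent keys mean no shift.  ``covariate_slope`` couples
    every trait to the body-weight covariate (organ traits), testing the
    covariance adjustment downstream.
    """

    n_per_group_per_generation: int
    trait_means: Mapping[str, float]
    trait_sds: Mapping[str, float]
    group_deltas: Mapping[Tuple[str, str], float] = field(default_factory=dict)
    covariate_slope: float = 0.0
    bodyweight_mean: float = 3700.0
    bodyweight_sd: float = 300.0
    generations: Sequence[str] = GENERATIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group_per_generation <= 0:
            raise ConfigError("n_per_group_per_generation must be positive")
        if set(self.trait_means) != set(self.trait_sds):
            raise ConfigError("trait_means and trait_sds must cover the same traits")
        for trait, sd in self.trait_sds.items():
            if not sd > 0:
                raise ConfigError(f"trait_sds[{trait!r}] must be positive")
        if self.bodyweight_sd <= 0:
            raise ConfigError("bodyweight_sd must be positive")
        unknown = [g for g in self.generations if g not in GENERATIONS]
        if unknown:
            raise ConfigError(f"unknown generations: {unknown}")
        for (trait, gen) in self.group_deltas:
            if trait not in self.trait_means:
                raise ConfigError(f"group_deltas names unknown trait {trait!r}")
            if gen not in GENERATIONS:
                raise ConfigError(f"group_deltas names unknown generation {gen!r}")


def gen_phenotype_table(config: PhenoSimConfig) -> pd.DataFrame:
    """Long-format trait table: one row per animal x trait.

    Trait value = mean - delta * 1[VT] + slope * (bodyweight - mean bw)
    + Normal(0, sd).  The drawn body weight is attached as the ``covariate``
    column.  The true simulation parameters are echoed into
    ``df.attrs["truth"]``.
    """
    rows = []
    n = config.n_per_group_per_generation
    for gen in config.generations:
        for grp in GROUPS:
            rng = np.random.default_rng(subseed(config.seed, "pheno", gen, grp))
            bw = rng.normal(config.bodyweight_mean, config.bodyweight_sd, n)
            is_vt = 1.0 if grp == "VT" else 0.0
            for trait in sorted(config.trait_means):
                mean = config.trait_means[trait]
                sd = config.trait_sds[trait]
                delta = config.group_deltas.get((trait, gen), 0.0)
                noise = rng.normal(0.0, sd, n)
                values = (
                    mean
                    - delta * is_vt
                    + config.covariate_slope * (bw - config.bodyweight_mean)
                    + noise
                )
                for i in range(n):
                    rows.append(
                        {
                            "animal_id": f"{gen}_{grp}_{i:04d}",
                            "group": grp,
                            "generation": gen,
                            "trait": trait,
                            "value": values[i],
                            "covariate": bw[i],
                        }
                    )
    df = pd.DataFrame(rows)
    df.attrs["truth"] = {
        "group_deltas": dict(config.group_deltas),
        "trait_means": dict(config.trait_means),
        "trait_sds": dict(config.trait_sds),
        "covariate_slope": config.covariate_slope,
    }
    return df


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExprSimConfig:
    n_genes: int
    n_per_group: int
    de_fraction: float
    log2fc_magnitude: float = 2.0
    nb_dispersion: float = 0.1
    library_size_range: Tuple[int, int] = (500_000, 1_000_000)
    de_up_fraction: float = 0.5
    gene_length_bp: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_per_group <= 0:
            raise ConfigError("n_genes and n_per_group must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError("de_fraction must lie in [0, 1]")
        if self.log2fc_magnitude <= 0:
            raise ConfigError("log2fc_magnitude must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigError("library_size_range must be a positive (low, high) pair")
        if not 0.0 <= self.de_up_fraction <= 1.0:
            raise ConfigError("de_up_fraction must lie in [0, 1]")


def gen_expression_matrix(config: ExprSimConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Negative-binomial count matrix plus truth sidecar.

    True DE genes get a symmetric half fold change in each group
    (2^(+lfc/2) in VT, 2^(-lfc/2) in NC for up-in-VT genes), so the total
    VT-over-NC log2 fold change equals the configured magnitude.  The FPKM
    view uses a fixed gene length (counts * 1e9 / (libsize * length)).
    """
    rng = np.random.default_rng(subseed(config.seed, "expr"))
    g = config.n_genes
    base = rng.lognormal(mean=0.0, sigma=1.5, size=g)
    rel = base / base.sum()

    n_de = int(round(config.de_fraction * g))
    de_idx = rng.choice(g, size=n_de, replace=False)
    sign = np.where(rng.random(n_de) < config.de_up_fraction, 1.0, -1.0)
    lfc = np.zeros(g)
    lfc[de_idx] = sign * config.log2fc_magnitude

    r = 1.0 / config.nb_dispersion
    lo, hi = config.library_size_range
    counts = {}
    sample_ids = []
    group_of = {}
    for grp, mult in (("NC", 2.0 ** (-lfc / 2.0)), ("VT", 2.0 ** (lfc / 2.0))):
        for j in range(config.n_per_group):
            sid = f"{grp}_{j + 1:02d}"
            libsize = int(rng.integers(lo, hi + 1))
            mean = libsize * rel * mult
            p = r / (r + mean)
            counts[sid] = rng.negative_binomial(r, p)
            sample_ids.append(sid)
            group_of[sid] = grp
    gene_ids = [f"gene_{i:05d}" for i in range(g)]
    counts_df = pd.DataFrame(counts, index=gene_ids)[sample_ids]
    realized_lib = counts_df.sum(axis=0).to_numpy(dtype=float)
    realized_lib = np.maximum(realized_lib, 1.0)
    fpkm_df = counts_df * 1e9 / (realized_lib[None, :] * config.gene_length_bp)

    truth = pd.DataFrame(
        {
            "id": gene_ids,
            "is_de": lfc != 0.0,
            "true_log2fc": lfc,
        }
    )
    return ExpressionMatrix(counts=counts_df, fpkm=fpkm_df, group_of=group_of), truth


# ---------------------------------------------------------------------------
# Metabolome
# ---------------------------------------------------------------------------

DEFAULT_STANDARDS = {
    "semi-polar": "IS_formononetin",
    "non-polar": "IS_tocopherol_acetate",
}


@dataclass(frozen=True)
class MetabSimConfig:
    """Configuration for the metabolite-intensity generator.

    Replicates are biological pools; ``fraction_log2fc_mean`` is the
    VT-over-NC log2 shift applied to true DAM metabolites of each fraction
    (per-DAM effects scatter around it with ``dam_log2fc_sd``).
    """

    n_metabolites_per_fraction: Mapping[str, int] = field(
        default_factory=lambda: {"semi-polar": 50, "non-polar": 50}
    )
    n_replicates: int = 3
    dam_fraction: float = 0.0
    fraction_log2fc_mean: Mapping[str, float] = field(
        default_factory=lambda: {"semi-polar": 0.0, "non-polar": 0.0}
    )
    dam_log2fc_sd: float = 0.1
    noise_cv: float = 0.1
    internal_standard_names: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_STANDARDS)
    )
    sample_scale_sd: float = 0.2
    generations: Sequence[str] = GENERATIONS
    seed: int = 0

    def __post_init__(self) -> None:
        for mapping, what in (
            (self.n_metabolites_per_fraction, "n_metabolites_per_fraction"),
            (self.fraction_log2fc_mean, "fraction_log2fc_mean"),
            (self.internal_standard_names, "internal_standard_names"),
        ):
            unknown = [f for f in mapping if f not in FRACTIONS]
            if unknown:
                raise ConfigError(f"{what} names unknown fraction(s) {unknown}")
        if any(n <= 0 for n in self.n_metabolites_per_fraction.values()):
            raise ConfigError("metabolite counts must be positive")
        if self.n_replicates < 2:
            raise ConfigError("need at least 2 replicates per group")
        if not 0.0 <= self.dam_fraction <= 1.0:
            raise ConfigError("dam_fraction must lie in [0, 1]")
        if self.noise_cv <= 0:
            raise ConfigError("noise_cv must be positive")
        missing = [f for f in self.n_metabolites_per_fraction
                   if f not in self.internal_standard_names]
        if missing:
            raise ConfigError(f"fractions without internal standard name: {missing}")


def gen_metabolite_table(config: MetabSimConfig) -> tuple[MetaboliteTable, pd.DataFrame]:
    """Log-normal metabolite intensities plus truth sidecar.

    Each sample carries a common multiplicative instrument scale (removed
    by internal-standard normalization); multiplicative log-normal noise
    with the configured CV is mean-preserving.  Internal-standard rows are
    constant up to noise and the sample scale.
    """
    sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))

    met_ids: list[str] = []
    fraction_of: dict[str, str] = {}
    baseline: dict[str, float] = {}
    true_lfc: dict[str, float] = {}
    standards: list[str] = []

    for frac in sorted(config.n_metabolites_per_fraction):
        n_m = config.n_metabolites_per_fraction[frac]
        rng = np.random.default_rng(subseed(config.seed, "metab", frac))
        tag = "sem" if frac == "semi-polar" else "non"
        ids = [f"{tag}_m{i:04d}" for i in range(n_m)]
        base = rng.lognormal(mean=8.0, sigma=1.0, size=n_m)
        n_dam = int(round(config.dam_fraction * n_m))
        dam_idx = rng.choice(n_m, size=n_dam, replace=False)
        lfc = np.zeros(n_m)
        lfc[dam_idx] = rng.normal(
            config.fraction_log2fc_mean.get(frac, 0.0), config.dam_log2fc_sd, n_dam
        )
        for i, mid in enumerate(ids):
            fraction_of[mid] = frac
            baseline[mid] = float(base[i])
            true_lfc[mid] = float(lfc[i])
        met_ids.extend(ids)
        std = config.internal_standard_names[frac]
        standards.append(std)
        fraction_of[std] = frac
        baseline[std] = 1000.0
        true_lfc[std] = 0.0

    all_ids = standards + met_ids
    columns: dict[str, np.ndarray] = {}
    group_of: dict[str, str] = {}
    generation_of: dict[str, str] = {}
    for gen in config.generations:
        for grp in GROUPS:
            rng = np.random.default_rng(subseed(config.seed, "metab-samples", gen, grp))
            for rep in range(1, config.n_replicates + 1):
                sid = f"{gen}_{grp}_r{rep}"
                scale = float(np.exp(rng.normal(0.0, config.sample_scale_sd)))
                vals = np.empty(len(all_ids))
                noise = np.exp(rng.normal(-sigma**2 / 2.0, sigma, len(all_ids)))
                for i, mid in enumerate(all_ids):
                    shift = 2.0 ** true_lfc[mid] if grp == "VT" else 1.0
                    vals[i] = baseline[mid] * shift * scale * noise[i]
                columns[sid] = vals
                group_of[sid] = grp
                generation_of[sid] = gen

    intensities = pd.DataFrame(columns, index=all_ids)
    truth = pd.DataFrame(
        {
            "id": met_ids,
            "fraction": [fraction_of[m] for m in met_ids],
            "is_dam": [true_lfc[m] != 0.0 for m in met_ids],
            "true_log2fc": [true_lfc[m] for m in met_ids],
        }
    )
    table = MetaboliteTable(
        intensities=intensities,
        fraction_of=fraction_of,
        group_of=group_of,
        generation_of=generation_of,
        internal_standards=standards,
    )
    return table, truth
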