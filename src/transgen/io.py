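"""Delimited-table IO with schema validation, run configuration and the
umbrella pipeline driver.

Plain TSV is the canonical interchange format; comma-delimited input is
auto-detected.  ``run_pipeline`` wires the stages together on either
synthetic or user-supplied inputs and emits per-stage TSVs plus a
machine-readable JSON summary; identical (inputs, config, seed) yield
byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from transgen import bayes, crossgen, metabolome, synthetic, transcript
from transgen.errors import ConfigError, SchemaError
from transgen.util import subseed

logger = logging.getLogger(__name__)

_DTYPE_CASTS = {"str": str, "float": float, "int": int}


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    dtype: str = "str"  # str | float | int
    required: bool = True
    allowed: Optional[frozenset] = None


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[ColumnSpec, ...]
    key: tuple[str, ...] = ()


TRAIT_TABLE_SCHEMA = TableSchema(
    name="traits",
    columns=(
        ColumnSpec("animal_id"),
        ColumnSpec("group", allowed=frozenset({"NC", "VT"})),
        ColumnSpec("generation", allowed=frozenset({"F1", "F2", "F3"})),
        ColumnSpec("trait"),
        ColumnSpec("value", dtype="float"),
        ColumnSpec("covariate", dtype="float", required=False),
    ),
    key=("animal_id", "generation", "trait"),
)

SAMPLE_GROUP_SCHEMA = TableSchema(
    name="groups",
    columns=(
        ColumnSpec("sample"),
        ColumnSpec("group", allowed=frozenset({"NC", "VT"})),
    ),
    key=("sample",),
)

METAB_META_SCHEMA = TableSchema(
    name="meta",
    columns=(
        ColumnSpec("sample"),
        ColumnSpec("group", allowed=frozenset({"NC", "VT"})),
        ColumnSpec("generation", allowed=frozenset({"F1", "F2", "F3"})),
    ),
    key=("sample",),
)

FRACTION_MAP_SCHEMA = TableSchema(
    name="fractions",
    columns=(
        ColumnSpec("metabolite"),
        ColumnSpec("fraction", allowed=frozenset(metabolome.FRACTIONS)),
    ),
    key=("metabolite",),
)


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a delimited table against ``schema``.

    Violations raise :class:`SchemaError` naming file, row (1-based data
    row) and column.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str)
    for col in schema.columns:
        if col.name not in df.columns:
            if col.required:
                raise SchemaError(f"{path}: missing required column {col.name!r}")
            continue
        raw = df[col.name]
        if col.dtype in ("float", "int"):
            converted = pd.to_numeric(raw, errors="coerce")
            bad = converted.isna() & raw.notna()
            if bad.any():
                row = int(bad.idxmax()) + 1
                raise SchemaError(
                    f"{path}: row {row}, column {col.name!r}: "
                    f"non-numeric value {raw[bad.idxmax()]!r}"
                )
            if col.required and converted.isna().any():
                row = int(converted.isna().idxmax()) + 1
                raise SchemaError(f"{path}: row {row}, column {col.name!r}: missing value")
            df[col.name] = converted.astype(float if col.dtype == "float" else "Int64")
        else:
            if col.required and raw.isna().any():
                row = int(raw.isna().idxmax()) + 1
                raise SchemaError(f"{path}: row {row}, column {col.name!r}: missing value")
            if col.allowed is not None:
                bad = raw.notna() & ~raw.isin(col.allowed)
                if bad.any():
                    row = int(bad.idxmax()) + 1
                    raise SchemaError(
                        f"{path}: row {row}, column {col.name!r}: "
                        f"value {raw[bad.idxmax()]!r} not in {sorted(col.allowed)}"
                    )
    if schema.key:
        dup = df.duplicated(subset=list(schema.key))
        if dup.any():
            row = int(dup.idxmax()) + 1
            raise SchemaError(f"{path}: row {row}: duplicate key {schema.key}")
    logger.info("read %s: %d rows, %d columns", path, len(df), df.shape[1])
    return df


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read an id x sample numeric matrix (first column = row identifier)."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str)
    df = df.set_index(df.columns[0])
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            rid = bad.idxmax()
            raise SchemaError(
                f"{path}: row {rid!r}, column {col!r}: non-numeric value "
                f"{df.loc[rid, col]!r}"
            )
        if converted.isna().any():
            rid = converted.isna().idxmax()
            raise SchemaError(f"{path}: row {rid!r}, column {col!r}: missing value")
        out[col] = converted
    mat = pd.DataFrame(out, index=df.index)
    mat.index.name = df.index.name
    logger.info("read %s: %d x %d matrix", path, *mat.shape)
    return mat


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


# ---------------------------------------------------------------------------
# Run configuration and pipeline driver
# ---------------------------------------------------------------------------

_STAGES = ("simulate", "fit-traits", "call-dets", "call-dams", "venn")

#: Inputs each stage needs when running on user files instead of simulation.
_STAGE_INPUTS = {
    "fit-traits": ("traits",),
    "call-dets": ("counts", "groups"),
    "call-dams": ("intensities", "meta", "fractions"),
}


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run."""

    outdir: str
    seed: int = 0
    stages: Sequence[str] = _STAGES
    simulate: bool = True
    inputs: Mapping[str, str] = field(default_factory=dict)
    phenotype: Mapping[str, object] = field(default_factory=dict)
    expression: Mapping[str, object] = field(default_factory=dict)
    metabolome_sim: Mapping[str, object] = field(default_factory=dict)
    gibbs: Mapping[str, object] = field(default_factory=dict)
    use_covariate: bool = False
    fdr: float = 0.05
    dam_alpha: float = 0.05
    internal_standards: Sequence[str] = ()
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            raise ConfigError(f"unknown stages: {unknown}")
        if not 0 < self.fdr <= 1 or not 0 < self.dam_alpha <= 1:
            raise ConfigError("fdr and dam_alpha must lie in (0, 1]")
        if not self.simulate:
            for stage in self.stages:
                for key in _STAGE_INPUTS.get(stage, ()):
                    if key not in self.inputs:
                        raise ConfigError(
                            f"stage {stage!r} requires input {key!r} when simulate=false"
                        )

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        return cls(**d)  # type: ignore[arg-type]


def _expression_bundle_from_files(inputs: Mapping[str, str]) -> transcript.ExpressionMatrix:
    counts = read_matrix(inputs["counts"])
    groups_df = read_table(inputs["groups"], SAMPLE_GROUP_SCHEMA)
    group_of = dict(zip(groups_df["sample"], groups_df["group"]))
    if "fpkm" in inputs:
        fpkm = read_matrix(inputs["fpkm"])
    else:
        lengths = None
        if "lengths" in inputs:
            ldf = read_matrix(inputs["lengths"])
            lengths = ldf.iloc[:, 0].reindex(counts.index)
            if lengths.isna().any():
                raise SchemaError("length table does not cover every gene")
        fpkm = fpkm_from_counts(counts, lengths)
    return transcript.ExpressionMatrix(counts=counts, fpkm=fpkm, group_of=group_of)


def fpkm_from_counts(
    counts: pd.DataFrame, lengths_bp: Optional[pd.Series] = None
) -> pd.DataFrame:
    """FPKM = counts * 1e9 / (library size * gene length); default length 1 kb."""
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    lib = np.maximum(lib, 1.0)
    if lengths_bp is None:
        lengths = np.full(counts.shape[0], 1000.0)
    else:
        lengths = lengths_bp.to_numpy(dtype=float)
    return counts * 1e9 / (lib[None, :] * lengths[:, None])


def _metabolite_table_from_files(
    inputs: Mapping[str, str], internal_standards: Sequence[str]
) -> metabolome.MetaboliteTable:
    intensities = read_matrix(inputs["intensities"])
    meta = read_table(inputs["meta"], METAB_META_SCHEMA)
    fractions = read_table(inputs["fractions"], FRACTION_MAP_SCHEMA)
    return metabolome.MetaboliteTable(
        intensities=intensities,
        fraction_of=dict(zip(fractions["metabolite"], fractions["fraction"])),
        group_of=dict(zip(meta["sample"], meta["group"])),
        generation_of=dict(zip(meta["sample"], meta["generation"])),
        internal_standards=list(internal_standards),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order.

    Returns the JSON-serialisable summary and writes it (plus per-stage
    TSVs) under ``config.outdir``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": {
            "seed": config.seed,
            "stages": list(config.stages),
            "simulate": config.simulate,
            "use_covariate": config.use_covariate,
            "fdr": config.fdr,
            "dam_alpha": config.dam_alpha,
            "gibbs": dict(config.gibbs),
        }
    }
    logger.info("effective config: %s", report["config"])

    traits_df = None
    expr_by_gen: dict[str, transcript.ExpressionMatrix] = {}
    metab_table = None

    if "simulate" in config.stages and config.simulate:
        pheno_kwargs = dict(config.phenotype)
        pheno_kwargs.setdefault("n_per_group_per_generation", 30)
        pheno_kwargs.setdefault("trait_means", {"adult_weight": 3700.0, "liver_weight": 95.0})
        pheno_kwargs.setdefault("trait_sds", {"adult_weight": 450.0, "liver_weight": 12.0})
        pheno_kwargs.setdefault("seed", subseed(config.seed, "pheno"))
        pheno_cfg = synthetic.PhenoSimConfig(**pheno_kwargs)
        traits_df = synthetic.gen_phenotype_table(pheno_cfg)
        write_table(traits_df, outdir / "phenotype.tsv")

        for gen in synthetic.GENERATIONS:
            expr_kwargs = dict(config.expression)
            expr_kwargs.setdefault("n_genes", 2000)
            expr_kwargs.setdefault("n_per_group", 6)
            expr_kwargs.setdefault("de_fraction", 0.05)
            expr_kwargs["seed"] = subseed(config.seed, "expr", gen)
            matrix, truth = synthetic.gen_expression_matrix(
                synthetic.ExprSimConfig(**expr_kwargs)
            )
            expr_by_gen[gen] = matrix
            write_table(matrix.counts, outdir / f"counts_{gen}.tsv", index=True)
            write_table(truth, outdir / f"expr_truth_{gen}.tsv")
            groups_df = pd.DataFrame(
                {"sample": matrix.sample_ids,
                 "group": [matrix.group_of[s] for s in matrix.sample_ids]}
            )
            write_table(groups_df, outdir / f"groups_{gen}.tsv")

        metab_kwargs = dict(config.metabolome_sim)
        metab_kwargs.setdefault("dam_fraction", 0.2)
        metab_kwargs["seed"] = subseed(config.seed, "metab")
        metab_table, metab_truth = synthetic.gen_metabolite_table(
            synthetic.MetabSimConfig(**metab_kwargs)
        )
        write_table(metab_table.intensities, outdir / "intensities.tsv", index=True)
        write_table(metab_truth, outdir / "metab_truth.tsv")
        cols = list(metab_table.intensities.columns)
        write_table(
            pd.DataFrame(
                {"sample": cols,
                 "group": [metab_table.group_of[s] for s in cols],
                 "generation": [metab_table.generation_of[s] for s in cols]}
            ),
            outdir / "meta.tsv",
        )
        write_table(
            pd.DataFrame(
                {"metabolite": list(metab_table.intensities.index),
                 "fraction": [metab_table.fraction_of[m]
                              for m in metab_table.intensities.index]}
            ),
            outdir / "fractions.tsv",
        )
    elif not config.simulate:
        if "fit-traits" in config.stages:
            traits_df = read_table(config.inputs["traits"], TRAIT_TABLE_SCHEMA)
        if "call-dets" in config.stages:
            matrix = _expression_bundle_from_files(config.inputs)
            for gen in ("F1",):
                expr_by_gen[gen] = matrix
        if "call-dams" in config.stages:
            metab_table = _metabolite_table_from_files(
                config.inputs, config.internal_standards
            )

    if "fit-traits" in config.stages and traits_df is not None:
        rows = []
        traits = sorted(traits_df["trait"].unique())
        generations = sorted(traits_df["generation"].unique())
        for trait in traits:
            for gen in generations:
                gcfg = bayes.GibbsConfig(
                    **{"seed": subseed(config.seed, "gibbs", trait, gen), **config.gibbs}
                )
                chain = bayes.fit_two_group_model(
                    traits_df, trait, gen, use_covariate=config.use_covariate, config=gcfg
                )
                summary = bayes.summarize_posterior(chain)
                sub = traits_df[
                    (traits_df["trait"] == trait) & (traits_df["generation"] == gen)
                ]
                r = bayes.relevant_value(sub["value"].to_numpy(dtype=float))
                decision = bayes.decide_relevance(summary, r)
                rows.append(
                    {
                        "trait": trait,
                        "generation": gen,
                        "D_mean": summary.D_mean,
                        "P0": summary.P0,
                        "hpd_low": summary.hpd_low,
                        "hpd_high": summary.hpd_high,
                        "mcse": summary.mcse,
                        "geweke_z": summary.geweke_z,
                        "R": r,
                        "relevant": decision.relevant,
                    }
                )
        summary_df = pd.DataFrame(rows)
        write_table(summary_df, outdir / "traits_summary.tsv")
        report["relevance"] = {
            f"{row['trait']}:{row['generation']}": bool(row["relevant"]) for row in rows
        }

    det_sets: dict[str, list[transcript.DEResult]] = {}
    if "call-dets" in config.stages and expr_by_gen:
        for gen, matrix in expr_by_gen.items():
            kept, traces = transcript.call_dets(
                matrix, fdr_threshold=config.fdr, return_trace=True
            )
            det_sets[gen] = kept
            det_df = pd.DataFrame(
                [
                    {
                        "gene": r.gene_id,
                        "log2fc": r.log2fc,
                        "p": r.p_value,
                        "fdr": r.fdr,
                        "direction": r.direction,
                    }
                    for r in kept
                ]
            )
            write_table(det_df, outdir / f"dets_{gen}.tsv")
        report["det_counts"] = {gen: len(v) for gen, v in sorted(det_sets.items())}

    dam_sets: dict[str, list[metabolome.DAMRecord]] = {}
    if "call-dams" in config.stages and metab_table is not None:
        normalized = metabolome.normalize_internal_standard(metab_table)
        gens = sorted(set(normalized.generation_of.values()))
        for gen in gens:
            dams = metabolome.call_dams(normalized, gen, alpha=config.dam_alpha)
            dam_sets[gen] = dams
            dam_df = pd.DataFrame(
                [
                    {
                        "metabolite": r.metabolite_id,
                        "fraction": r.fraction,
                        "log2fc": r.log2fc,
                        "p": r.p_value,
                        "is_dam": r.is_dam,
                    }
                    for r in dams
                ]
            )
            write_table(dam_df, outdir / f"dams_{gen}.tsv")
            report.setdefault("fraction_fold_change", {})[gen] = (
                metabolome.fraction_fold_change_summary(dams)
            )
        report["dam_counts"] = {
            gen: sum(r.is_dam for r in v) for gen, v in sorted(dam_sets.items())
        }

    if "venn" in config.stages and det_sets:
        ids = {
            gen: {r.gene_id for r in det_sets.get(gen, [])} for gen in ("F1", "F2", "F3")
        }
        part = crossgen.venn_partition(ids["F1"], ids["F2"], ids["F3"])
        report["venn_regions"] = {
            label: len(members) for label, members in sorted(part.region_sets.items())
        }
        report["inherited"] = {
            "F2": len(part.inherited_F2),
            "F3": len(part.inherited_F3),
        }
        region_rows = [
            {"region": label, "id": ident}
            for label, members in sorted(part.region_sets.items())
            for ident in sorted(members)
        ]
        write_table(pd.DataFrame(region_rows, columns=["region", "id"]),
                    outdir / "venn_regions.tsv")
        concordance = crossgen.direction_concordance(
            {
                gen: [(r.gene_id, r.direction) for r in det_sets.get(gen, [])]
                for gen in ("F1", "F2", "F3")
            }
        )
        conc_rows = [
            {
                "id": c.id,
                "concordant": c.concordant,
                **{f"dir_{g}": d for g, d in sorted(c.directions.items())},
            }
            for c in concordance
        ]
        write_table(pd.DataFrame(conc_rows), outdir / "concordance.tsv")
        report["n_discordant"] = sum(not c.concordant for c in concordance)

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return report
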