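"""Targeted metabolomics stage: internal-standard normalization, one-way
ANOVA + Tukey HSD metabolite calling, and per-fraction fold-change summaries.

Intensities are metabolite x sample tables split into two fractions
(semi-polar / non-polar), each carrying its own internal-standard row.
Relative quantification divides every metabolite by its fraction's standard
within each sample, after which differential accumulation between NC and VT
within a generation is tested per metabolite at raw p < 0.05 (no multiplicity
correction by default; BH available behind a flag).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from transgen.errors import DesignError

FRACTIONS = ("semi-polar", "non-polar")


@dataclass
class MetaboliteTable:
    """Metabolite x sample intensities with fraction and sample metadata."""

    intensities: pd.DataFrame
    fraction_of: Mapping[str, str]
    group_of: Mapping[str, str]
    generation_of: Mapping[str, str]
    internal_standards: Sequence[str]

    def __post_init__(self) -> None:
        idx = set(self.intensities.index)
        missing = [m for m in self.intensities.index if m not in self.fraction_of]
        if missing:
            raise ValueError(f"metabolites without fraction label: {missing[:5]}")
        bad_frac = {m: f for m, f in self.fraction_of.items() if f not in FRACTIONS}
        if bad_frac:
            raise ValueError(f"unknown fraction labels: {bad_frac}")
        stray = [s for s in self.internal_standards if s not in idx]
        if stray:
            raise ValueError(f"internal standards absent from table: {stray}")
        for s in self.intensities.columns:
            if s not in self.group_of or s not in self.generation_of:
                raise ValueError(f"sample {s!r} lacks group/generation metadata")
        if (self.intensities.to_numpy(dtype=float) <= 0).any():
            raise ValueError("intensities must be strictly positive")

    def standard_for(self, fraction: str) -> str:
        cands = [s for s in self.internal_standards if self.fraction_of[s] == fraction]
        if len(cands) != 1:
            raise ValueError(
                f"fraction {fraction!r} must have exactly one internal standard, "
                f"found {cands}"
            )
        return cands[0]


@dataclass(frozen=True)
class DAMRecord:
    metabolite_id: str
    fraction: str
    log2fc: float  # VT over NC
    p_value: float
    tukey_pairs: Mapping[tuple[str, str], float]
    is_dam: bool


def normalize_internal_standard(table: MetaboliteTable) -> MetaboliteTable:
    """Divide every metabolite by its fraction's internal standard, per sample.

    The standard rows are removed from the output.  A missing or
    non-positive standard intensity raises, naming the offending sample.
    """
    fractions = sorted({table.fraction_of[m] for m in table.intensities.index})
    std_of = {f: table.standard_for(f) for f in fractions}
    for f, std in std_of.items():
        row = table.intensities.loc[std]
        bad = row[~(row > 0)].index.tolist() + row[row.isna()].index.tolist()
        if bad:
            raise ValueError(
                f"internal standard {std!r} missing or non-positive in sample(s) {bad}"
            )
    out = table.intensities.copy()
    for m in out.index:
        if m in std_of.values():
            continue
        out.loc[m] = out.loc[m] / table.intensities.loc[std_of[table.fraction_of[m]]]
    out = out.drop(index=list(std_of.values()))
    return replace(
        table,
        intensities=out,
        fraction_of={m: f for m, f in table.fraction_of.items() if m in out.index},
        internal_standards=[],
    )


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA: returns (F, p).

    Degenerate inputs (zero between- and within-group variation) report
    F = 0, p = 1; zero within-group variation with real separation reports
    F = inf, p = 0.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs at least 2 values")
    n_total = sum(a.size for a in arrs)
    if n_total - k <= 0:
        raise ValueError("no within-group degrees of freedom")
    grand = sum(a.sum() for a in arrs) / n_total
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ssb / (k - 1)) / (ssw / (n_total - k))
    p = float(stats.f.sf(f, k - 1, n_total - k))
    return float(f), p


def tukey_hsd(groups: Sequence[Sequence[float]]) -> dict[tuple[int, int], float]:
    """Tukey HSD p-values per group pair from the studentized range.

    Keys are ``(i, j)`` index pairs with ``i < j``.  Uses the pooled
    within-group variance; at k = 2 this reduces to the two-sided pooled
    t-test (q = t * sqrt(2)).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs at least 2 values")
    n_total = sum(a.size for a in arrs)
    df_w = n_total - k
    if df_w <= 0:
        raise ValueError("no within-group degrees of freedom")
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    s2 = ssw / df_w
    out: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(k), 2):
        diff = abs(arrs[i].mean() - arrs[j].mean())
        if s2 == 0.0:
            out[(i, j)] = 1.0 if diff == 0.0 else 0.0
            continue
        se = math.sqrt(s2 / 2.0 * (1.0 / arrs[i].size + 1.0 / arrs[j].size))
        q = diff / se
        if k == 2:
            # exact identity: the k=2 studentized-range tail is the
            # two-sided t tail at q/sqrt(2); avoids the slow quadrature
            out[(i, j)] = float(2.0 * stats.t.sf(q / math.sqrt(2.0), df_w))
        else:
            out[(i, j)] = float(stats.studentized_range.sf(q, k, df_w))
    return out


def call_dams(
    table: MetaboliteTable,
    generation: str,
    alpha: float = 0.05,
    adjust: bool = False,
    technical_rep_of: Optional[Mapping[str, str]] = None,
) -> list[DAMRecord]:
    """ANOVA-based DAM calling for one generation on a normalized table.

    ``is_dam`` is raw ``p < alpha`` by default; with ``adjust=True`` the BH
    adjusted value is thresholded instead.  ``technical_rep_of`` maps sample
    id -> biological replicate id; technical replicates are averaged into
    their biological replicate before testing.
    """
    if table.internal_standards:
        raise DesignError("table still contains internal standards; normalize first")
    samples = [s for s in table.intensities.columns if table.generation_of[s] == generation]
    if not samples:
        raise DesignError(f"no samples for generation {generation!r}")
    mat = table.intensities[samples]
    group_of = dict(table.group_of)
    if technical_rep_of is not None:
        bio = {}
        for s in samples:
            bio.setdefault(technical_rep_of.get(s, s), []).append(s)
        mat = pd.DataFrame({b: mat[cols].mean(axis=1) for b, cols in bio.items()})
        group_of = {b: group_of[cols[0]] for b, cols in bio.items()}
        samples = list(mat.columns)
    nc = [s for s in samples if group_of[s] == "NC"]
    vt = [s for s in samples if group_of[s] == "VT"]
    if len(nc) < 2 or len(vt) < 2:
        raise DesignError("both NC and VT need at least 2 replicates in the generation")

    records = []
    pvals = []
    for m in mat.index:
        g_nc = mat.loc[m, nc].to_numpy(dtype=float)
        g_vt = mat.loc[m, vt].to_numpy(dtype=float)
        _, p = anova_oneway([g_nc, g_vt])
        tk = tukey_hsd([g_nc, g_vt])
        lfc = math.log2(g_vt.mean() / g_nc.mean())
        pvals.append(p)
        records.append((m, lfc, p, {("NC", "VT"): tk[(0, 1)]}))
    if adjust:
        from transgen.transcript import benjamini_hochberg

        crit = benjamini_hochberg(pvals)
    else:
        crit = np.asarray(pvals)
    return [
        DAMRecord(
            metabolite_id=m,
            fraction=table.fraction_of[m],
            log2fc=lfc,
            p_value=p,
            tukey_pairs=tk,
            is_dam=bool(c < alpha),
        )
        for (m, lfc, p, tk), c in zip(records, crit)
    ]


def fraction_fold_change_summary(dams: Iterable[DAMRecord]) -> dict[str, float]:
    """Mean log2 fold change of called DAMs, grouped by fraction.

    Fractions without any called DAM are absent from the result.
    """
    buckets: dict[str, list[float]] = {}
    for rec in dams:
        if rec.is_dam:
            buckets.setdefault(rec.fraction, []).append(rec.log2fc)
    return {f: float(np.mean(v)) for f, v in sorted(buckets.items())}
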