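"""Differential expression calling on count matrices with a variability post-filter.

The test stage is a deliberately minimal, self-contained two-group
moderated test: counts are library-size normalised to log2-CPM, per-gene
variances are shrunk toward the genewise average (a fixed prior degrees of
freedom), and a two-sample t statistic is referred to the inflated-df t
distribution.  Benjamini-Hochberg adjustment caps the FDR at the chosen
threshold.

Candidates surviving the FDR cut then pass through a variability
post-filter computed on the FPKM view: a gene whose FPKM coefficient of
variation exceeds 50% *and* whose mean-median gap exceeds 1 is kept only
if at least half of the samples of the more expressed group show FPKM at
least twice the mean of the other group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from transgen.errors import DesignError

GROUPS = ("NC", "VT")


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance table with counts and FPKM views."""

    counts: pd.DataFrame
    fpkm: pd.DataFrame
    group_of: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.fpkm.index) or not self.counts.columns.equals(
            self.fpkm.columns
        ):
            raise ValueError("counts and fpkm must share gene and sample labels")
        missing = [s for s in self.counts.columns if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        bad = {s: g for s, g in self.group_of.items() if g not in GROUPS}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        if not np.all(np.isfinite(self.fpkm.to_numpy(dtype=float))):
            raise ValueError("FPKM values must be finite")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.group_of[s] == group]


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log2fc: float  # VT over NC
    p_value: float
    fdr: float
    direction: str  # "up" | "down" in VT relative to NC


@dataclass(frozen=True)
class FilterTrace:
    gene_id: str
    cv_percent: float
    mean_median_gap: float
    triggered: bool
    kept: bool
    n_qualifying_samples: int
    required: int
    zero_expression: bool = False


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Standard BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _fpkm_pseudocount(fpkm: np.ndarray) -> float:
    """0.125 times the average per-sample minimum positive FPKM."""
    mins = []
    for j in range(fpkm.shape[1]):
        col = fpkm[:, j]
        pos = col[col > 0]
        if pos.size:
            mins.append(pos.min())
    if not mins:
        return 0.125
    return 0.125 * float(np.mean(mins))


def de_test(matrix: ExpressionMatrix, prior_df: float = 4.0) -> list[DEResult]:
    """Moderated two-group test per gene; one :class:`DEResult` per gene.

    Requires at least 3 samples per group.  p-values are two-sided from a
    t distribution with ``n1 + n2 - 2 + prior_df`` degrees of freedom.
    """
    nc = matrix.samples_in("NC")
    vt = matrix.samples_in("VT")
    if len(nc) < 3 or len(vt) < 3:
        raise DesignError("each group needs at least 3 samples for the DE test")

    counts = matrix.counts.to_numpy(dtype=float)
    cols = list(matrix.counts.columns)
    i_nc = [cols.index(s) for s in nc]
    i_vt = [cols.index(s) for s in vt]
    lib = counts.sum(axis=0)
    logcpm = np.log2((counts + 0.5) / (lib + 1.0) * 1e6)

    a = logcpm[:, i_nc]
    b = logcpm[:, i_vt]
    n1, n2 = a.shape[1], b.shape[1]
    m1 = a.mean(axis=1)
    m2 = b.mean(axis=1)
    d_resid = n1 + n2 - 2
    ss = ((a - m1[:, None]) ** 2).sum(axis=1) + ((b - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / d_resid
    s2_prior = float(s2.mean())
    s2_mod = (prior_df * s2_prior + d_resid * s2) / (prior_df + d_resid)
    scale = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(scale > 0, (m2 - m1) / np.where(scale > 0, scale, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=d_resid + prior_df)
    fdr = benjamini_hochberg(p)

    fpkm = matrix.fpkm.to_numpy(dtype=float)
    pseudo = _fpkm_pseudocount(fpkm)
    mean_nc = fpkm[:, i_nc].mean(axis=1)
    mean_vt = fpkm[:, i_vt].mean(axis=1)
    lfc = np.log2((mean_vt + pseudo) / (mean_nc + pseudo))

    results = []
    for g, gene in enumerate(matrix.gene_ids):
        direction = "up" if lfc[g] >= 0 else "down"
        results.append(
            DEResult(
                gene_id=gene,
                log2fc=float(lfc[g]),
                p_value=float(p[g]),
                fdr=float(fdr[g]),
                direction=direction,
            )
        )
    return results


def variability_postfilter(
    matrix: ExpressionMatrix,
    candidates: Iterable[DEResult],
    cv_threshold: float = 50.0,
    gap_threshold: float = 1.0,
) -> tuple[list[DEResult], list[FilterTrace]]:
    """Apply the CV / mean-median post-filter to DE candidates.

    Both statistics are computed across *all* samples of the comparison on
    the FPKM view.  Only the conjunction (CV% > 50 and |mean - median| > 1)
    triggers the filter; triggered genes survive when at least
    ``ceil(n_high / 2)`` samples of the higher-mean group have FPKM at or
    above twice the mean FPKM of the other group.  Genes with zero mean
    FPKM in both groups are dropped with a trace flag.
    """
    candidates = list(candidates)
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    unknown = [c.gene_id for c in candidates if c.gene_id not in gene_pos]
    if unknown:
        raise ValueError(f"candidate genes absent from matrix: {unknown}")
    fpkm = matrix.fpkm.to_numpy(dtype=float)
    cols = list(matrix.fpkm.columns)
    i_nc = [cols.index(s) for s in matrix.samples_in("NC")]
    i_vt = [cols.index(s) for s in matrix.samples_in("VT")]

    kept: list[DEResult] = []
    traces: list[FilterTrace] = []
    for cand in candidates:
        x = fpkm[gene_pos[cand.gene_id]]
        mean_nc = float(x[i_nc].mean())
        mean_vt = float(x[i_vt].mean())
        if mean_nc == 0.0 and mean_vt == 0.0:
            traces.append(
                FilterTrace(
                    gene_id=cand.gene_id, cv_percent=float("nan"),
                    mean_median_gap=float("nan"), triggered=True, kept=False,
                    n_qualifying_samples=0, required=1, zero_expression=True,
                )
            )
            continue
        mean_all = float(x.mean())
        sd_all = float(x.std(ddof=0))
        cv = 100.0 * sd_all / mean_all if mean_all > 0 else float("inf")
        gap = abs(mean_all - float(np.median(x)))
        triggered = cv > cv_threshold and gap > gap_threshold
        if not triggered:
            kept.append(cand)
            traces.append(
                FilterTrace(
                    gene_id=cand.gene_id, cv_percent=cv, mean_median_gap=gap,
                    triggered=False, kept=True,
                    n_qualifying_samples=0, required=0,
                )
            )
            continue
        if mean_vt > mean_nc:
            hi_idx, other_mean = i_vt, mean_nc
        elif mean_nc > mean_vt:
            hi_idx, other_mean = i_nc, mean_vt
        else:
            # Tied group means: break toward keeping the gene.
            kept.append(cand)
            traces.append(
                FilterTrace(
                    gene_id=cand.gene_id, cv_percent=cv, mean_median_gap=gap,
                    triggered=True, kept=True,
                    n_qualifying_samples=len(i_vt), required=0,
                )
            )
            continue
        required = math.ceil(len(hi_idx) / 2)
        n_qual = int(np.count_nonzero(x[hi_idx] >= 2.0 * other_mean))
        keep = n_qual >= required
        if keep:
            kept.append(cand)
        traces.append(
            FilterTrace(
                gene_id=cand.gene_id, cv_percent=cv, mean_median_gap=gap,
                triggered=True, kept=keep,
                n_qualifying_samples=n_qual, required=required,
            )
        )
    return kept, traces


def call_dets(
    matrix: ExpressionMatrix,
    fdr_threshold: float = 0.05,
    return_trace: bool = False,
):
    """Full DET calling: DE test -> FDR cut -> variability post-filter."""
    results = de_test(matrix)
    candidates = [r for r in results if r.fdr <= fdr_threshold]
    kept, traces = variability_postfilter(matrix, candidates)
    if return_trace:
        return kept, traces
    return kept
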