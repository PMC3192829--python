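"""Replicate summaries, Z scores, the significance filter, and peak-phase
dynamics.

A gene is called significantly changed under a condition when the replicate
mean |log2R| >= 1.0 and the replicate Z score |Z| >= 2.0 (both cutoffs
configurable).  Z is the one-sample standardized mean across biological
replicates, Z = mean / (sd / sqrt(n)); for a condition-vs-condition contrast
it is the Welch form on the difference of means.  Genes with fewer than two
quantifiable replicates are never called.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

DEFAULT_R_MIN = 1.0
DEFAULT_Z_MIN = 2.0

#: tie tolerance for peak-phase calls: only (numerically) exact ties are ties
DEFAULT_TIE_EPS = 1e-9


@dataclass
class DifferentialCallSet:
    """Per-gene summary for one contrast.

    ``frame`` columns: mean_log2R, sd_log2R, z, n_used, significant,
    direction; indexed by gene id.
    """

    condition: tuple[str, str]
    vs: tuple[str, str] | None
    r_min: float
    z_min: float
    frame: pd.DataFrame

    def counts(self) -> tuple[int, int]:
        return count_significant(self)

    def significant_genes(self) -> list[str]:
        return self.frame.index[self.frame["significant"]].tolist()


def _condition_stats(
    x: ExpressionMatrix, condition: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(mean, sd, n_used) per gene over unmasked replicates of a condition."""
    cols = x.design.columns_for(condition)
    if not cols:
        raise KeyError(f"condition {condition} not present in design")
    if len(cols) < 2:
        raise ValueError(f"condition {condition} has fewer than 2 replicates")
    vals = x.values[:, cols]
    m = x.mask[:, cols]
    n = m.sum(axis=1)
    vals = np.where(m, vals, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, vals.sum(axis=1) / np.maximum(n, 1), np.nan)
        ss = ((vals - np.where(m, mean[:, None], 0.0)) ** 2 * m).sum(axis=1)
        sd = np.where(n >= 2, np.sqrt(ss / np.maximum(n - 1, 1)), np.nan)
    return mean, sd, n


def summarize_contrast(
    x: ExpressionMatrix,
    condition: tuple[str, str],
    vs: tuple[str, str] | None = None,
    r_min: float = DEFAULT_R_MIN,
    z_min: float = DEFAULT_Z_MIN,
) -> DifferentialCallSet:
    """Summarize one condition (or a condition-vs-condition difference).

    Without ``vs``, mean and sd are taken across the condition's unmasked
    replicates and Z = mean / (sd/sqrt(n)).  With ``vs``, the statistic is
    the difference of condition means with a pooled Welch standard error.
    Zero-sd genes with a nonzero mean get an infinite Z (the filter then
    rests on the mean cutoff alone).
    """
    mean, sd, n = _condition_stats(x, condition)
    if vs is None:
        n_eff = n
        with np.errstate(invalid="ignore", divide="ignore"):
            se = sd / np.sqrt(np.maximum(n, 1))
            z = mean / se
        stat = mean
    else:
        mean2, sd2, n2 = _condition_stats(x, vs)
        stat = mean - mean2
        n_eff = np.minimum(n, n2)
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(sd**2 / np.maximum(n, 1) + sd2**2 / np.maximum(n2, 1))
            z = stat / se
        sd = se * np.sqrt(np.maximum(n, 1))  # report the pooled scale

    usable = n_eff >= 2
    with np.errstate(invalid="ignore"):
        significant = usable & (np.abs(stat) >= r_min) & (np.abs(z) >= z_min)
    significant = np.asarray(significant, dtype=bool)
    direction = np.where(significant & (stat > 0), "up", np.where(significant & (stat < 0), "down", "none"))
    frame = pd.DataFrame(
        {
            "mean_log2R": stat,
            "sd_log2R": sd,
            "z": z,
            "n_used": n_eff,
            "significant": significant,
            "direction": direction,
        },
        index=pd.Index(x.genes, name="gene_id"),
    )
    if not usable.any():
        import warnings

        warnings.warn(
            f"every gene has <2 quantifiable replicates for {condition}; no calls made",
            stacklevel=2,
        )
    return DifferentialCallSet(condition=condition, vs=vs, r_min=r_min, z_min=z_min, frame=frame)


def count_significant(calls: DifferentialCallSet) -> tuple[int, int]:
    """(n_up, n_down) among significant genes."""
    d = calls.frame["direction"]
    return int((d == "up").sum()), int((d == "down").sum())


@dataclass
class PhaseProfile:
    """Replicate-mean log2R per growth phase for one substrate series."""

    substrate: str
    frame: pd.DataFrame  # columns: early, mid, late (NaN = unquantifiable), peak_phase


def peak_phase(
    x: ExpressionMatrix,
    substrate: str,
    genes: list[str] | None = None,
    tie_eps: float = DEFAULT_TIE_EPS,
) -> PhaseProfile:
    """Classify each gene's expression peak along a substrate's phase series.

    A phase is quantifiable for a gene when it has at least one unmasked
    replicate.  peak_phase is the strict argmax of the quantifiable phase
    means; genes with fewer than two quantifiable phases, or whose top two
    means are within ``tie_eps``, are 'undetermined'.
    """
    phases = x.design.phases_for(substrate)
    if len(phases) < 2:
        raise ValueError(f"substrate {substrate!r} has fewer than 2 phases in the design")
    if genes is None:
        gene_rows = np.arange(x.n_genes)
        gene_ids = list(x.genes)
    else:
        gene_rows = np.array([x.gene_index(g) for g in genes])
        gene_ids = list(genes)

    cols_by_phase = {}
    for ph in phases:
        cols_by_phase[ph] = x.design.columns_for((substrate, ph))

    data = {}
    for ph in phases:
        cols = cols_by_phase[ph]
        vals = x.values[np.ix_(gene_rows, cols)]
        m = x.mask[np.ix_(gene_rows, cols)]
        n = m.sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean = np.where(n > 0, np.where(m, vals, 0.0).sum(axis=1) / np.maximum(n, 1), np.nan)
        data[ph] = mean
    frame = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))

    peaks = []
    arr = frame.to_numpy()
    for row in arr:
        finite = np.isfinite(row)
        if finite.sum() < 2:
            peaks.append("undetermined")
            continue
        vals = np.where(finite, row, -np.inf)
        order = np.argsort(vals)[::-1]
        if vals[order[0]] - vals[order[1]] <= tie_eps:
            peaks.append("undetermined")
        else:
            peaks.append(phases[order[0]])
    frame["peak_phase"] = peaks
    return PhaseProfile(substrate=substrate, frame=frame)


def write_calls(calls: DifferentialCallSet, path) -> None:
    out = calls.frame.copy()
    out["significant"] = out["significant"].astype(int)
    out.to_csv(path, sep="\t", float_format="%.6g", encoding="utf-8")
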