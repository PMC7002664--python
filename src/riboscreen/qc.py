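"""Library and sample quality control.

Three read-outs mirror the checks a screen should pass before hit calling:

* per-sample abundance summaries (CPM quantiles, zero fraction) and
  pairwise sample correlation of log-CPM;
* conservation of library complexity between two conditions (e.g. plasmid
  pool vs post-transfection cDNA): rank correlation of mean abundance plus
  per-variant coefficient of variation, flagging variants with CV above
  10%;
* GC-dependence of the abundance distribution, which catches systematic
  under-representation of GC-rich motifs introduced during oligo synthesis.

Abundances are compared on log2(CPM + 0.5); Spearman (rank) correlation is
used throughout because the abundance distribution is heavy-tailed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import LibraryDesign, SPIKE_SUBLIB, VariantId, gc_fraction

__all__ = [
    "cpm",
    "log_cpm",
    "complexity_conservation",
    "gc_dependence",
    "qc_report",
    "QCReport",
    "GCTest",
    "ComplexityResult",
]

LOG_PSEUDOCOUNT = 0.5
CV_THRESHOLD = 0.10


def cpm(counts: pd.DataFrame | pd.Series | np.ndarray) -> pd.DataFrame | pd.Series | np.ndarray:
    """Counts per million, per sample (column); columns sum to 1e6."""
    if isinstance(counts, pd.DataFrame):
        totals = counts.sum(axis=0)
        if (totals == 0).any():
            bad = list(totals.index[totals == 0])
            raise ValueError(f"zero-total sample(s): {bad}")
        return counts / totals * 1e6
    arr = np.asarray(counts, dtype=float)
    total = arr.sum(axis=0)
    if np.any(total == 0):
        raise ValueError("zero-total sample")
    out = arr / total * 1e6
    if isinstance(counts, pd.Series):
        return pd.Series(out, index=counts.index)
    return out


def log_cpm(counts: pd.DataFrame, pseudocount: float = LOG_PSEUDOCOUNT) -> pd.DataFrame:
    """log2(CPM + pseudocount); the pseudocount admits zero counts."""
    return np.log2(cpm(counts) + pseudocount)


@dataclass
class ComplexityResult:
    """Pre/post complexity conservation: rank correlation + CV flags."""

    rho: float
    rho_pvalue: float
    cv: pd.Series
    flagged: list[str]
    cv_threshold: float


def complexity_conservation(
    counts_pre: pd.DataFrame,
    counts_post: pd.DataFrame,
    *,
    cv_threshold: float = CV_THRESHOLD,
) -> ComplexityResult:
    """Compare library composition between two conditions.

    Spearman rho is computed on the mean log2-CPM over replicates of each
    condition; the per-variant CV is sd/mean of the two condition-mean CPM
    values, and variants with CV above ``cv_threshold`` are flagged.
    """
    if list(counts_pre.index) != list(counts_post.index):
        raise ValueError("variant axes differ")
    if len(counts_pre.index) < 2:
        raise ValueError("need at least 2 variants")
    mean_pre = cpm(counts_pre).mean(axis=1)
    mean_post = cpm(counts_post).mean(axis=1)
    lp = np.log2(mean_pre + LOG_PSEUDOCOUNT)
    lq = np.log2(mean_post + LOG_PSEUDOCOUNT)
    rho, pval = sps.spearmanr(lp, lq)

    both = np.stack([mean_pre.to_numpy(), mean_post.to_numpy()])
    mean = both.mean(axis=0)
    sd = both.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)
    cv = pd.Series(cv, index=counts_pre.index, name="cv")
    flagged = list(cv.index[cv > cv_threshold])
    return ComplexityResult(float(rho), float(pval), cv, flagged, cv_threshold)


@dataclass
class GCTest:
    """GC-dependence of abundance: Spearman rho, slope and bias flag."""

    rho: float
    pvalue: float
    slope: float
    flag: bool
    rho_threshold: float
    alpha: float
    n_variants: int

    def to_dict(self) -> dict:
        return asdict(self)


def motif_gc(index, design: LibraryDesign | None = None) -> pd.Series:
    """GC fraction of each variant's motif from ``sublib|motif`` keys."""
    vals = {}
    for key in index:
        v = VariantId.from_key(key)
        if v.sub_library == SPIKE_SUBLIB or not v.motif or set(v.motif) - set("ACGT"):
            vals[key] = np.nan  # spike-in and non-variant rows carry no motif
        else:
            vals[key] = gc_fraction(v.motif)
    return pd.Series(vals)


def gc_dependence(
    counts: pd.DataFrame,
    design: LibraryDesign | None = None,
    *,
    rho_threshold: float = 0.3,
    alpha: float = 0.01,
) -> GCTest:
    """Test mean log2-CPM against motif GC fraction.

    The bias flag is raised when |rho| exceeds ``rho_threshold`` and the
    associated p-value is below ``alpha``.  The least-squares slope (log2
    CPM per unit GC fraction) quantifies the direction and strength.
    """
    gc = motif_gc(counts.index, design)
    keep = gc.notna()
    gc = gc[keep]
    sub = counts.loc[keep.index[keep]]
    if gc.nunique() < 3:
        raise ValueError(
            f"need >= 3 distinct motif GC values, got {gc.nunique()}"
        )
    abundance = log_cpm(sub).mean(axis=1)
    rho, pval = sps.spearmanr(gc.to_numpy(), abundance.to_numpy())
    slope = float(np.polyfit(gc.to_numpy(), abundance.to_numpy(), 1)[0])
    flag = bool(abs(rho) > rho_threshold and pval < alpha)
    return GCTest(float(rho), float(pval), slope, flag, rho_threshold, alpha, len(gc))


@dataclass
class QCReport:
    """Bundle of per-sample summaries, sample correlations and the GC test."""

    sample_summary: pd.DataFrame
    sample_correlation: pd.DataFrame
    gc_test: GCTest

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sample_summary": self.sample_summary.to_dict(orient="index"),
            "sample_correlation": self.sample_correlation.to_dict(orient="index"),
            "gc_test": self.gc_test.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def qc_report(counts: pd.DataFrame, design: LibraryDesign | None = None) -> QCReport:
    """Full QC bundle for one count matrix (spike row may be included)."""
    c = cpm(counts)
    summary = pd.DataFrame(
        {
            "total_counts": counts.sum(axis=0),
            "fraction_zero": (counts == 0).mean(axis=0),
            "cpm_q25": c.quantile(0.25, axis=0),
            "cpm_median": c.quantile(0.5, axis=0),
            "cpm_q75": c.quantile(0.75, axis=0),
        }
    )
    lc = log_cpm(counts)
    rho = sps.spearmanr(lc.to_numpy())[0]
    if np.isscalar(rho):  # two samples: spearmanr returns a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    corr = pd.DataFrame(np.atleast_2d(rho), index=counts.columns, columns=counts.columns)
    gct = gc_dependence(counts, design)
    return QCReport(summary, corr, gct)
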