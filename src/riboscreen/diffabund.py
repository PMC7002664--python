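"""Spike-in normalization and negative-binomial differential abundance.

The screen compares each treated dose group against the dose-0 control
group across replicates.  Counts are first normalized to the spike-in
control (present at constant input in every sample), a common NB
dispersion is estimated by method of moments and shrunk per variant, and
a conditional NB exact test yields a two-sided p-value per variant and
contrast; Benjamini-Hochberg adjustment is applied within each contrast.

Model: counts are NB with variance mu + phi * mu^2.  Conditional on the
pooled total t of a variant across both groups, the group-A sum follows
the distribution

    P(Y_A = k | t) proportional to f_A(k) * f_B(t - k),

where f_A, f_B are NB pmfs whose size parameters are n_A/phi and n_B/phi
(the sum of n iid NB(mu, phi) is NB(n*mu, phi/n)).  The shared mean and
probability parameters cancel in the normalization, so the conditional
depends only on (n_A, n_B, phi, t) -- a negative hypergeometric.  The
two-sided p-value sums every split whose conditional probability does not
exceed that of the observed split, which reduces to the conditional
binomial (Poisson) exact test as phi -> 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import false_discovery_control

from .counting import CountMatrix
from .design import VariantId
from .qc import LOG_PSEUDOCOUNT

__all__ = [
    "read_samplesheet",
    "validate_samplesheet",
    "spike_size_factors",
    "normalize_counts",
    "DispersionModel",
    "estimate_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "DifferentialTable",
    "differential_table",
]

PHI_FLOOR = 1e-8
DEFAULT_N_PRIOR = 10.0
_TIE_LOG = 1e-9  # log-space slack when comparing conditional probabilities
# (covers gammaln rounding at large totals; pmf granularity is far coarser)


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def read_samplesheet(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns sample, dose_uM, replicate."""
    sheet = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "dose_uM", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"samplesheet misses column(s) {sorted(missing)}")
    sheet["sample"] = sheet["sample"].astype(str)
    sheet["dose_uM"] = sheet["dose_uM"].astype(float)
    return sheet


def validate_samplesheet(sheet: pd.DataFrame, samples: list[str] | None = None) -> None:
    if sheet["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in samplesheet")
    doses = sorted(sheet["dose_uM"].unique())
    if 0.0 not in doses:
        raise ValueError("samplesheet has no dose-0 (control) group")
    sizes = sheet.groupby("dose_uM").size()
    if (sizes < 2).any():
        small = list(sizes.index[sizes < 2])
        warnings.warn(f"dose group(s) {small} have < 2 replicates; testing degraded")
    if samples is not None:
        missing = set(sheet["sample"]) - set(samples)
        if missing:
            raise ValueError(f"samplesheet samples absent from counts: {sorted(missing)}")


# ---------------------------------------------------------------------------
# spike-in normalization
# ---------------------------------------------------------------------------

def spike_size_factors(counts: CountMatrix | pd.DataFrame, spike_key: str | None = None) -> pd.Series:
    """Per-sample size factors from the spike-in row.

    factor_s = spike_s / geometric-mean(spike); dividing each sample's
    counts by its factor equalizes the spike-in across samples, and the
    factors have geometric mean 1 by construction.
    """
    if isinstance(counts, CountMatrix):
        spike = counts.spike_counts()
    else:
        if spike_key is None:
            raise ValueError("spike_key required for a bare DataFrame")
        spike = counts.loc[spike_key]
    if (spike <= 0).any():
        bad = list(spike.index[spike <= 0])
        raise ValueError(f"zero spike-in count in sample(s) {bad}; cannot normalize")
    log = np.log(spike.astype(float))
    factors = np.exp(log - log.mean())
    return pd.Series(factors, index=spike.index, name="size_factor")


def normalize_counts(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    return counts / size_factors.reindex(counts.columns)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

@dataclass
class DispersionModel:
    """Common + per-variant shrunken NB dispersions (var = mu + phi mu^2)."""

    phi_common: float
    phi: pd.Series
    shrinkage_weight: pd.Series
    n_prior: float

    def __getitem__(self, key: str) -> float:
        return float(self.phi.loc[key])


def estimate_dispersion(
    norm_counts: pd.DataFrame,
    groups: pd.Series,
    *,
    n_prior: float = DEFAULT_N_PRIOR,
) -> DispersionModel:
    """Method-of-moments NB dispersion with shrinkage toward the common value.

    Within each group, the sample mean m and variance s^2 of each variant
    give the moment identity s^2 = m + phi m^2.  The common dispersion
    pools numerator and denominator over all variants and groups,
    phi_common = max(0, sum(s^2 - m) / sum(m^2)); each variant-wise
    estimate is shrunk toward it with weight w = n_prior / (n_prior + df),
    df being the variant's within-group degrees of freedom.
    """
    groups = groups.reindex(norm_counts.columns)
    num = np.zeros(len(norm_counts.index))
    den = np.zeros(len(norm_counts.index))
    df = 0.0
    replicated = False
    for _, cols in groups.groupby(groups).groups.items():
        sub = norm_counts[list(cols)].to_numpy(dtype=float)
        n = sub.shape[1]
        if n < 2:
            continue
        replicated = True
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        num += s2 - m
        den += m**2
        df += n - 1
    if not replicated:
        warnings.warn(
            "no replicated group: dispersion fixed to floor "
            f"{PHI_FLOOR}; p-values will be anti-conservative"
        )
        phi = pd.Series(PHI_FLOOR, index=norm_counts.index)
        w = pd.Series(1.0, index=norm_counts.index)
        return DispersionModel(PHI_FLOOR, phi, w, n_prior)

    total_den = den.sum()
    phi_common = max(0.0, float(num.sum() / total_den)) if total_den > 0 else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_v_raw = np.where(den > 0, np.maximum(0.0, num / den), phi_common)
    w = n_prior / (n_prior + df)
    phi_v = w * phi_common + (1.0 - w) * phi_v_raw
    return DispersionModel(
        phi_common,
        pd.Series(phi_v, index=norm_counts.index, name="phi"),
        pd.Series(w, index=norm_counts.index, name="weight"),
        n_prior,
    )


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def _conditional_logpmf(total: int, n_a: float, n_b: float, phi: float) -> np.ndarray:
    """log P(Y_A = k | Y_A + Y_B = total) for k = 0..total (normalized)."""
    k = np.arange(total + 1)
    if phi <= PHI_FLOOR:
        # Poisson limit: binomial with success probability n_a / (n_a + n_b)
        logw = (
            -gammaln(k + 1)
            - gammaln(total - k + 1)
            + k * np.log(n_a)
            + (total - k) * np.log(n_b)
        )
    else:
        r_a = n_a / phi
        r_b = n_b / phi
        logw = (
            gammaln(k + r_a)
            - gammaln(k + 1)
            + gammaln(total - k + r_b)
            - gammaln(total - k + 1)
        )
    return logw - logsumexp(logw)


def nb_exact_test(
    counts_a,
    counts_b,
    phi: float,
    size_factors_a=None,
    size_factors_b=None,
) -> float:
    """Two-sided conditional NB exact test between two replicate groups.

    ``counts_a``/``counts_b`` are per-replicate counts of one variant; if
    size factors are given, counts are normalized and rounded first.  The
    p-value is the total conditional probability of all splits of the
    pooled sum that are at most as probable as the observed one; identical
    per-replicate means across groups give p = 1 for the observed mode.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("negative counts")
    if size_factors_a is not None:
        a = a / np.asarray(size_factors_a, dtype=float)
    if size_factors_b is not None:
        b = b / np.asarray(size_factors_b, dtype=float)
    sum_a = int(np.rint(a.sum()))
    sum_b = int(np.rint(b.sum()))
    return _exact_test_sums(sum_a, len(a), sum_b, len(b), phi)


def _exact_test_sums(sum_a: int, n_a: int, sum_b: int, n_b: int, phi: float) -> float:
    total = sum_a + sum_b
    if total == 0:
        return 1.0
    logp = _conditional_logpmf(total, n_a, n_b, phi)
    obs = logp[sum_a]
    mask = logp <= obs + _TIE_LOG
    if mask.all():  # observed split is the conditional mode
        return 1.0
    p = float(np.exp(logsumexp(logp[mask])))
    return min(1.0, max(p, np.finfo(float).tiny))


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return false_discovery_control(p, method="bh")


# ---------------------------------------------------------------------------
# full table
# ---------------------------------------------------------------------------

@dataclass
class DifferentialTable:
    """Per-variant, per-contrast fold changes and significance.

    ``table`` columns: variant, sublib, motif, dose_uM, cpm_control,
    cpm_treated, mean_cpm, log2fc, pvalue, fdr.
    """

    table: pd.DataFrame
    doses: list[float]
    size_factors: pd.Series
    dispersion: DispersionModel

    def contrast(self, dose: float) -> pd.DataFrame:
        sub = self.table[self.table["dose_uM"] == dose]
        if sub.empty:
            raise KeyError(f"no contrast at dose {dose}")
        return sub.reset_index(drop=True)

    def wide(self) -> pd.DataFrame:
        """One row per variant, per-dose log2FC/FDR/CPM columns."""
        w = self.table.pivot(
            index=["variant", "sublib", "motif"],
            columns="dose_uM",
            values=["log2fc", "fdr", "cpm_treated"],
        )
        w.columns = [f"{a}_{g:g}uM" for a, g in w.columns]
        return w.reset_index()

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "# per-variant differential abundance; log2fc = log2 fold change of "
                "spike-normalized mean CPM (treated vs dose 0, pseudocount 0.5); "
                "fdr = Benjamini-Hochberg within contrast\n"
            )
            self.table.to_csv(fh, sep="\t", index=False)


def differential_table(
    counts: CountMatrix,
    samplesheet: pd.DataFrame,
    *,
    n_prior: float = DEFAULT_N_PRIOR,
    pseudocount: float = LOG_PSEUDOCOUNT,
    use_spike: bool = True,
) -> DifferentialTable:
    """Spike-normalize, test every variant at every dose vs the control.

    For each non-zero dose: log2FC of (mean normalized CPM + pseudocount),
    conditional NB exact test on rounded normalized counts, BH adjustment
    across variants within the contrast.  Deterministic; no RNG involved.
    Set ``use_spike=False`` to fall back to library-size (CPM) factors for
    spike-free data.
    """
    validate_samplesheet(samplesheet, counts.samples)
    sheet = samplesheet.set_index("sample")
    sample_order = [s for s in counts.samples if s in sheet.index]
    doses = sorted(sheet["dose_uM"].unique())
    if 0.0 not in doses:
        raise ValueError("missing control (dose 0) group")

    if use_spike:
        factors = spike_size_factors(counts)
    else:
        totals = counts.counts.sum(axis=0).astype(float)
        log = np.log(totals)
        factors = pd.Series(np.exp(log - log.mean()), index=counts.counts.columns)
    variants = counts.drop_spike()
    norm = normalize_counts(variants, factors)

    groups = sheet.loc[sample_order, "dose_uM"]
    disp = estimate_dispersion(norm[sample_order], groups, n_prior=n_prior)

    # per-sample CPM on normalized counts, for fold changes and reporting
    norm_cpm = norm / norm.sum(axis=0) * 1e6
    ctrl_samples = [s for s in sample_order if sheet.loc[s, "dose_uM"] == 0.0]
    rounded = np.rint(norm[sample_order].to_numpy()).astype(np.int64)
    col_of = {s: i for i, s in enumerate(sample_order)}
    ctrl_idx = [col_of[s] for s in ctrl_samples]
    ctrl_sums = rounded[:, ctrl_idx].sum(axis=1)
    cpm_ctrl = norm_cpm[ctrl_samples].mean(axis=1)

    phi = disp.phi.to_numpy()
    rows = []
    for dose in doses:
        if dose == 0.0:
            continue
        trt_samples = [s for s in sample_order if sheet.loc[s, "dose_uM"] == dose]
        trt_idx = [col_of[s] for s in trt_samples]
        trt_sums = rounded[:, trt_idx].sum(axis=1)
        cpm_trt = norm_cpm[trt_samples].mean(axis=1)
        lfc = np.log2((cpm_trt + pseudocount) / (cpm_ctrl + pseudocount))
        pvals = np.array(
            [
                _exact_test_sums(
                    int(trt_sums[i]), len(trt_idx), int(ctrl_sums[i]), len(ctrl_idx), phi[i]
                )
                for i in range(len(variants.index))
            ]
        )
        fdr = bh_adjust(pvals)
        for i, key in enumerate(variants.index):
            v = VariantId.from_key(key)
            rows.append(
                {
                    "variant": key,
                    "sublib": v.sub_library,
                    "motif": v.motif,
                    "dose_uM": dose,
                    "cpm_control": float(cpm_ctrl.iloc[i]),
                    "cpm_treated": float(cpm_trt.iloc[i]),
                    "mean_cpm": float((cpm_ctrl.iloc[i] + cpm_trt.iloc[i]) / 2),
                    "log2fc": float(lfc.iloc[i]),
                    "pvalue": float(pvals[i]),
                    "fdr": float(fdr[i]),
                }
            )
    table = pd.DataFrame(rows)
    return DifferentialTable(table, [d for d in doses if d != 0.0], factors, disp)
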