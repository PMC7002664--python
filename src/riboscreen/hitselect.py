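"""Hit selection: thresholds, dose-dependency, pi-score, ranked lists.

A hit is a variant that passes a fold-change and an FDR threshold at the
selection dose (default: the highest), in the requested direction (ON =
induced, positive log2FC; OFF = repressed, negative), and -- optionally --
behaves dose-dependently: sign-consistent log2FC across doses with a
magnitude that is non-decreasing with dose up to a small slack.  The
pi-score, log2FC * (-log10 p), combines effect size and significance into
a single ranking statistic that is more robust to low-abundance variants
with noisy fold changes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import gc_fraction
from .diffabund import DifferentialTable

__all__ = [
    "HitCriteria",
    "HitList",
    "dose_dependency",
    "pi_score",
    "select_hits",
    "select_hits_union",
    "fold_change",
    "true_positive_rate",
]

RANK_KEYS = ("log2FC", "pi_score", "FDR")
AT_ADVISORY_FRACTION = 0.7


@dataclass(frozen=True)
class HitCriteria:
    """Selection thresholds.

    direction: "on" (log2FC >= +lfc_threshold), "off" (<= -lfc_threshold)
    or "both" (|log2FC| >= lfc_threshold).
    """

    direction: str = "off"
    lfc_threshold: float = 0.6
    fdr_threshold: float = 0.01
    require_dose_dependency: bool = True
    dose_tolerance: float = 0.1

    def __post_init__(self) -> None:
        if self.direction not in ("on", "off", "both"):
            raise ValueError(f"direction must be on/off/both, got {self.direction!r}")
        if self.lfc_threshold <= 0 or not (0 < self.fdr_threshold < 1):
            raise ValueError("thresholds must be positive (FDR in (0,1))")


def dose_dependency(log2fc_by_dose, tolerance: float = 0.1) -> bool:
    """Is the response consistent and (within slack) monotone with dose?

    ``log2fc_by_dose`` is ordered by ascending non-zero dose.  True iff
    the sign of log2FC is identical wherever |log2FC| > tolerance, and
    each successive |log2FC| drops by at most ``tolerance``.
    """
    lfc = np.asarray(list(log2fc_by_dose), dtype=float)
    if lfc.size < 2:
        warnings.warn("fewer than 2 non-zero doses: dose-dependency trivially true")
        return True
    signs = {np.sign(x) for x in lfc if abs(x) > tolerance}
    if len(signs) > 1:
        return False
    mag = np.abs(lfc)
    return bool(np.all(np.diff(mag) >= -tolerance))


def pi_score(log2fc: float, p: float) -> float:
    """log2FC * (-log10 p); zero iff log2FC = 0 or p = 1."""
    if p <= 0:
        warnings.warn("p = 0 clamped to machine minimum for pi-score")
        p = np.finfo(float).tiny
    elif p > 1:
        raise ValueError(f"p-value {p} outside (0, 1]")
    return float(log2fc * -np.log10(p))


@dataclass
class HitList:
    """Ranked hits plus the complementary negative list."""

    hits: pd.DataFrame
    negatives: pd.DataFrame
    criteria: HitCriteria
    rank_by: str
    selection_dose: float

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# hits at dose {self.selection_dose:g} uM; direction="
                f"{self.criteria.direction}, |log2FC|>={self.criteria.lfc_threshold:g}, "
                f"FDR<={self.criteria.fdr_threshold:g}, dose_dependent="
                f"{self.criteria.require_dose_dependency}, ranked by {self.rank_by}\n"
            )
            self.hits.to_csv(fh, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "n_hits": int(len(self.hits)),
            "n_tested": int(len(self.hits) + len(self.negatives)),
            "selection_dose_uM": self.selection_dose,
            "direction": self.criteria.direction,
            "lfc_threshold": self.criteria.lfc_threshold,
            "fdr_threshold": self.criteria.fdr_threshold,
            "rank_by": self.rank_by,
            "n_at_rich_flagged": int(self.hits["at_rich"].sum()) if len(self.hits) else 0,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def _direction_ok(lfc: pd.Series, criteria: HitCriteria) -> pd.Series:
    if criteria.direction == "on":
        return lfc >= criteria.lfc_threshold
    if criteria.direction == "off":
        return lfc <= -criteria.lfc_threshold
    return lfc.abs() >= criteria.lfc_threshold


def select_hits(
    table: DifferentialTable,
    criteria: HitCriteria = HitCriteria(),
    rank_by: str = "log2FC",
    selection_dose: float | None = None,
) -> HitList:
    """Apply the selection criteria and rank the passing variants.

    Ranking: ``log2FC`` (|log2FC| at the selection dose, descending),
    ``pi_score`` (|pi|, descending) or ``FDR`` (ascending); ties broken by
    (FDR, |log2FC| desc, mean CPM desc, motif).  Variants failing any
    criterion go to the negative list for false-positive spot checks.
    Duplicate motifs (multi-dose selections) keep their best rank.
    """
    if rank_by not in RANK_KEYS:
        raise ValueError(f"unknown rank_by {rank_by!r}; choose from {RANK_KEYS}")
    doses = table.doses
    dose = max(doses) if selection_dose is None else selection_dose
    sel = table.contrast(dose).copy()

    # dose-dependency flag over all non-zero doses, per variant
    if criteria.require_dose_dependency and len(doses) >= 2:
        lfc_wide = table.table.pivot(index="variant", columns="dose_uM", values="log2fc")
        lfc_wide = lfc_wide[sorted(lfc_wide.columns)]
        dd = {
            v: dose_dependency(row.to_numpy(), criteria.dose_tolerance)
            for v, row in lfc_wide.iterrows()
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel["dose_dependent"] = sel["variant"].map(dd)
    else:
        sel["dose_dependent"] = True

    sel["pi_score"] = [
        pi_score(l, p) for l, p in zip(sel["log2fc"], sel["pvalue"])
    ]
    sel["at_rich"] = [
        bool(m) and not (set(m) - set("ACGT"))
        and (1.0 - gc_fraction(m)) > AT_ADVISORY_FRACTION
        for m in sel["motif"]
    ]

    passing = (
        _direction_ok(sel["log2fc"], criteria)
        & (sel["fdr"] <= criteria.fdr_threshold)
        & (sel["dose_dependent"] if criteria.require_dose_dependency else True)
    )
    hits = sel[passing].copy()
    negatives = sel[~passing].copy()

    if rank_by == "log2FC":
        hits["_key"] = -hits["log2fc"].abs()
    elif rank_by == "pi_score":
        hits["_key"] = -hits["pi_score"].abs()
    else:
        hits["_key"] = hits["fdr"]
    hits = hits.sort_values(
        by=["_key", "fdr", "log2fc", "mean_cpm", "motif"],
        ascending=[True, True, True, False, True],
        key=lambda c: c.abs().mul(-1) if c.name == "log2fc" else c,
    )
    hits = hits.drop_duplicates(subset="variant", keep="first").drop(columns="_key")
    hits.insert(0, "rank", np.arange(1, len(hits) + 1))
    return HitList(
        hits.reset_index(drop=True),
        negatives.reset_index(drop=True),
        criteria,
        rank_by,
        dose,
    )


def select_hits_union(
    table: DifferentialTable,
    criteria: HitCriteria = HitCriteria(),
    rank_by: str = "log2FC",
) -> pd.DataFrame:
    """Union of hit lists selected at every dose, deduplicated.

    Mirrors how screen hit lists are assembled in practice: top candidates
    are taken at each ligand concentration and duplicate hits (variants
    selected at several doses) are removed keeping their best rank.
    """
    frames = []
    for dose in table.doses:
        h = select_hits(table, criteria, rank_by=rank_by, selection_dose=dose)
        frames.append(h.hits)
    merged = pd.concat(frames).sort_values("rank", kind="stable")
    merged = merged.drop_duplicates(subset="variant", keep="first")
    return merged.reset_index(drop=True)


# ---------------------------------------------------------------------------
# validation-summary utilities
# ---------------------------------------------------------------------------

def fold_change(basal_percent: float, max_percent: float, ndigits: int = 1) -> float:
    """Fold change from a basal/maximal expression range (percent of control).

    ``fold_change(19.6, 84.1)`` -> 4.3; with only a basal level,
    ``fold_change(13.3, 100)`` -> 7.5 (repression release to full control
    expression).
    """
    if basal_percent <= 0:
        raise ValueError("basal expression must be positive")
    return round(max_percent / basal_percent, ndigits)


def true_positive_rate(n_functional: int, n_tested: int, ndigits: int = 1) -> float:
    """Validation true-positive rate in percent, e.g. 10/14 -> 71.4."""
    if n_tested <= 0 or n_functional < 0 or n_functional > n_tested:
        raise ValueError("need 0 <= n_functional <= n_tested, n_tested > 0")
    return round(100.0 * n_functional / n_tested, ndigits)
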