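"""Stream FASTQ reads and count self-barcoding variants per sample.

Each read is tried on the sense strand and (by default) on its reverse
complement against the compiled anchor patterns of the library design; the
first unambiguous hit increments the corresponding variant.  The spike-in
control is counted like a variant in its own row.  Base qualities are
ignored; reads shorter than the shortest amplicon are dropped as
unassigned.  Counting is deterministic and order-independent.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .design import MatcherSet, SPIKE_SUBLIB, VariantId, reverse_complement

__all__ = ["MatchStats", "CountMatrix", "count_fastq", "merge_counts"]

STAT_FIELDS = (
    "total_reads",
    "assigned",
    "unassigned",
    "ambiguous",
    "forward_strand",
    "reverse_strand",
)


@dataclass
class MatchStats:
    """Per-sample read accounting; assigned = forward + reverse strand."""

    total_reads: int = 0
    assigned: int = 0
    unassigned: int = 0
    ambiguous: int = 0
    forward_strand: int = 0
    reverse_strand: int = 0

    def validate(self) -> None:
        vals = [getattr(self, f) for f in STAT_FIELDS]
        if any(v < 0 for v in vals):
            raise ValueError(f"negative match statistics: {self}")
        if self.assigned + self.unassigned + self.ambiguous != self.total_reads:
            raise ValueError(f"read conservation violated: {self}")
        if self.forward_strand + self.reverse_strand != self.assigned:
            raise ValueError(f"strand counts do not sum to assigned: {self}")


class CountMatrix:
    """Variants x samples integer count matrix plus per-sample match stats.

    ``counts`` is a pandas DataFrame with row index ``"sublib|motif"``
    (spike-in row ``"spike|<id>"``) and one int64 column per sample.
    """

    def __init__(self, counts: pd.DataFrame, stats: pd.DataFrame | None = None):
        self.counts = counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if stats is None:
            stats = pd.DataFrame(
                0, index=counts.columns, columns=list(STAT_FIELDS), dtype=np.int64
            )
        self.stats = stats

    # -- accessors ---------------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def variant_keys(self) -> list[str]:
        return list(self.counts.index)

    def spike_rows(self) -> list[str]:
        return [k for k in self.counts.index if k.startswith(SPIKE_SUBLIB + "|")]

    def drop_spike(self) -> pd.DataFrame:
        """Counts without the spike-in row(s)."""
        return self.counts.drop(index=self.spike_rows())

    def spike_counts(self) -> pd.Series:
        rows = self.spike_rows()
        if not rows:
            raise ValueError("count matrix has no spike-in row")
        return self.counts.loc[rows].sum(axis=0)

    # -- io ----------------------------------------------------------------

    def to_tsv(self, counts_path: str | Path, stats_path: str | Path | None = None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="variant")
        if stats_path is not None:
            self.stats.to_csv(stats_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(
        cls, counts_path: str | Path, stats_path: str | Path | None = None
    ) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="variant")
        stats = None
        if stats_path is not None:
            stats = pd.read_csv(stats_path, sep="\t", index_col="sample")
        return cls(counts, stats)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<CountMatrix {self.counts.shape[0]} variants x "
            f"{self.counts.shape[1]} samples>"
        )


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(path: str | Path):
    """Yield (index, sequence) with fail-fast reporting of malformed records."""
    with _open_maybe_gzip(path) as fh:
        it = FastqGeneralIterator(fh)
        i = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"malformed FASTQ record #{i} in {path}: {exc}"
                ) from exc
            yield i, rec[1]
            i += 1


def count_fastq(
    samples: Mapping[str, Sequence[str | Path] | str | Path],
    matchers: MatcherSet,
    *,
    strand_mode: str = "both",
    min_read_length: int | None = None,
) -> CountMatrix:
    """Count variant abundance per sample from FASTQ files.

    Parameters
    ----------
    samples
        Mapping sample id -> FASTQ path(s) (plain or ``.gz``).
    matchers
        Compiled :class:`~riboscreen.design.MatcherSet`.
    strand_mode
        ``"both"`` (default: try sense, then reverse complement) or
        ``"forward"``.
    min_read_length
        Reads shorter than this are unassigned without matching; defaults
        to the shortest amplicon in the design.
    """
    if strand_mode not in ("both", "forward"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    min_len = matchers.min_length if min_read_length is None else min_read_length

    design = matchers.design
    row_keys = [v.key for v in design.iter_variants()] + [design.spike_in.key]
    row_index = {k: i for i, k in enumerate(row_keys)}
    sample_ids = list(samples)
    mat = np.zeros((len(row_keys), len(sample_ids)), dtype=np.int64)
    stats_rows = []

    for col, sample in enumerate(sample_ids):
        paths = samples[sample]
        if isinstance(paths, (str, Path)):
            paths = [paths]
        st = MatchStats()
        for path in paths:
            for _, seq in _iter_fastq(path):
                st.total_reads += 1
                read = seq.upper().replace("U", "T")
                if len(read) < min_len:
                    st.unassigned += 1
                    continue
                hit = matchers.match(read)
                strand = "+"
                if hit is None and strand_mode == "both":
                    hit = matchers.match(reverse_complement(read))
                    strand = "-"
                if hit is None:
                    st.unassigned += 1
                elif hit.sub_library == "ambiguous":
                    st.ambiguous += 1
                else:
                    mat[row_index[hit.key], col] += 1
                    st.assigned += 1
                    if strand == "+":
                        st.forward_strand += 1
                    else:
                        st.reverse_strand += 1
        if st.total_reads == 0:
            import warnings

            warnings.warn(f"sample {sample!r}: empty FASTQ input, zero column")
        st.validate()
        stats_rows.append({"sample": sample, **{f: getattr(st, f) for f in STAT_FIELDS}})

    counts = pd.DataFrame(mat, index=row_keys, columns=sample_ids)
    stats = pd.DataFrame(stats_rows).set_index("sample")
    return CountMatrix(counts, stats)


def merge_counts(matrices: Iterable[CountMatrix]) -> CountMatrix:
    """Column-wise merge of count matrices sharing an identical variant axis."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("nothing to merge")
    first = matrices[0]
    for m in matrices[1:]:
        if list(m.counts.index) != list(first.counts.index):
            raise ValueError("variant axes differ between count matrices")
    all_samples = [s for m in matrices for s in m.samples]
    if len(set(all_samples)) != len(all_samples):
        dupes = sorted({s for s in all_samples if all_samples.count(s) > 1})
        raise ValueError(f"duplicate sample id(s) in merge: {dupes}")
    counts = pd.concat([m.counts for m in matrices], axis=1)
    stats = pd.concat([m.stats for m in matrices], axis=0)
    return CountMatrix(counts, stats)
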