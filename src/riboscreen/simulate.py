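"""Synthetic screen generator for download-free end-to-end testing.

The generator models the ligand-dependent stabilization/degradation of
riboswitch-carrying mRNAs: each variant has a basal relative expression
r0 (library abundance and constitutive ribozyme activity folded into one
number), a maximal log2 response Delta (positive for ON-switches whose
cleavage is inhibited by the ligand, negative for OFF-switches), an EC50
and a Hill coefficient, giving

    log2 r(d) = log2 r0 + Delta * d^h / (d^h + EC50^h).

Per sample, expected read proportions follow r(dose) (optionally skewed
by a GC bias term 2^(-beta * GC)), counts are drawn negative-binomially
with variance mu + phi * mu^2, a spike-in row receives a fixed expected
share of reads, and each count unit can be emitted as one FASTQ read
(random strand, per-base substitution errors, constant qualities) with a
sidecar recording the exact emitted tally.

Default study conditions match the published screens: 4 dose groups x 8
replicates, 154 bp reads; depth is configurable and scaled down in tests.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .counting import CountMatrix
from .design import LibraryDesign, gc_fraction, reverse_complement

__all__ = [
    "ScreenTruth",
    "SimConfig",
    "make_truth",
    "expected_expression",
    "simulate_counts",
    "emit_fastq",
    "write_samplesheet",
]

DEFAULT_DOSES = (0.0, 30.0, 100.0, 300.0)
SPIKE_SHARE = 0.02  # expected fraction of reads from the spike-in control
ABUNDANCE_SIGMA_LOG2 = 0.75  # log-normal library-abundance spread (log2 sd)


@dataclass
class SimConfig:
    """Simulation settings; defaults mirror the screens' replicate/dose layout."""

    doses: tuple[float, ...] = DEFAULT_DOSES
    replicates: int = 8
    reads_per_sample: int = 200_000
    phi: float = 0.05
    error_rate: float = 0.0
    read_length: int = 154
    gc_bias: float = 0.0
    spike_share: float = SPIKE_SHARE
    phi_spike: float = 0.0
    depth_sigma_log2: float = 0.3
    seed: int = 0
    gzip_output: bool = False

    def __post_init__(self) -> None:
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if not (0.0 <= self.error_rate <= 0.1):
            raise ValueError("error_rate must lie in [0, 0.1]")
        if 0.0 in self.doses and list(self.doses) != sorted(self.doses):
            raise ValueError("doses must be ascending")

    def samples(self) -> pd.DataFrame:
        rows = [
            {"sample": f"d{d:g}_r{r + 1}", "dose_uM": d, "replicate": r + 1}
            for d in self.doses
            for r in range(self.replicates)
        ]
        return pd.DataFrame(rows)


@dataclass
class ScreenTruth:
    """Ground-truth dose-response parameters per variant.

    ``table`` columns: variant, sublib, motif, r0 (basal relative
    expression in (0, 1]), delta (max log2 fold response; 0 for null
    variants), ec50_uM, hill, is_switch.
    """

    table: pd.DataFrame
    design: LibraryDesign

    @property
    def switches(self) -> pd.DataFrame:
        return self.table[self.table["is_switch"]]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "# simulated ground truth: r0 = basal relative expression, "
                "delta = max log2 response (Hill saturation), ec50 in uM\n"
            )
            self.table.to_csv(fh, sep="\t", index=False)


def make_truth(
    design: LibraryDesign,
    *,
    n_switches: int = 20,
    delta_range: tuple[float, float] = (1.0, 2.5),
    direction: str = "off",
    ec50_range: tuple[float, float] = (30.0, 100.0),
    hill: float = 1.0,
    abundance_sigma_log2: float = ABUNDANCE_SIGMA_LOG2,
    seed: int = 0,
) -> ScreenTruth:
    """Plant ``n_switches`` true switches in an otherwise null library.

    Switch positions, response magnitudes (|Delta| uniform in
    ``delta_range``), EC50s (log-uniform in ``ec50_range``) and basal
    abundances (log-normal, sd ``abundance_sigma_log2`` in log2 units) are
    drawn reproducibly from ``seed``.  ``direction``: "on", "off" or
    "both" (random sign per switch).  The default EC50 range spans the
    default dose series (30-300 uM), mirroring published cellular
    riboswitch dose-responses: the response is graded across the tested
    concentrations and approaches saturation (75-91% of Delta realized)
    at the top dose.
    """
    if direction not in ("on", "off", "both"):
        raise ValueError("direction must be on/off/both")
    rng = np.random.default_rng(seed)
    variants = design.enumerate_variants()
    n = len(variants)
    if n_switches > n:
        raise ValueError(f"cannot plant {n_switches} switches among {n} variants")
    log2_r0 = rng.normal(0.0, abundance_sigma_log2, size=n)
    r0 = 2.0 ** (log2_r0 - log2_r0.max())  # scaled into (0, 1]
    delta = np.zeros(n)
    idx = rng.choice(n, size=n_switches, replace=False)
    mag = rng.uniform(*delta_range, size=n_switches)
    if direction == "on":
        sign = np.ones(n_switches)
    elif direction == "off":
        sign = -np.ones(n_switches)
    else:
        sign = rng.choice([-1.0, 1.0], size=n_switches)
    delta[idx] = sign * mag
    lo, hi = np.log(ec50_range[0]), np.log(ec50_range[1])
    ec50 = np.exp(rng.uniform(lo, hi, size=n))
    table = pd.DataFrame(
        {
            "variant": [v.key for v in variants],
            "sublib": [v.sub_library for v in variants],
            "motif": [v.motif for v in variants],
            "r0": r0,
            "delta": delta,
            "ec50_uM": ec50,
            "hill": hill,
            "is_switch": delta != 0.0,
        }
    )
    return ScreenTruth(table, design)


def expected_expression(truth: ScreenTruth | pd.DataFrame, dose: float) -> np.ndarray:
    """Relative mRNA level r(dose) per variant (Hill response on log2 scale)."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    t = truth.table if isinstance(truth, ScreenTruth) else truth
    r0 = t["r0"].to_numpy(dtype=float)
    delta = t["delta"].to_numpy(dtype=float)
    ec50 = t["ec50_uM"].to_numpy(dtype=float)
    h = t["hill"].to_numpy(dtype=float)
    if dose == 0.0:
        return r0.copy()
    occ = dose**h / (dose**h + ec50**h)
    return r0 * 2.0 ** (delta * occ)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _sample_rngs(config: SimConfig, n: int) -> list[np.random.Generator]:
    # per-sample substreams: regeneration of any one sample is stable
    seqs = np.random.SeedSequence(config.seed).spawn(n)
    return [np.random.default_rng(s) for s in seqs]


def simulate_counts(truth: ScreenTruth, config: SimConfig) -> CountMatrix:
    """Draw the variant x sample count matrix (including the spike-in row).

    Expected proportions per sample are proportional to
    r(dose) * 2^(-gc_bias * GC(motif)), scaled to (1 - spike_share) of the
    depth; counts are NB(mu, phi).  A shared per-sample depth factor
    (log-normal, sd ``depth_sigma_log2`` in log2 units) scales variants
    and spike-in alike -- emulating transfection-efficiency and sequencing
    depth fluctuations, which spike normalization is designed to remove --
    while the spike-in's residual noise is NB(phi_spike) (Poisson by
    default, befitting a high-abundance constant-input control).  Fully
    reproducible from ``config.seed``.
    """
    sheet = config.samples()
    design = truth.design
    gc = np.array([gc_fraction(m) for m in truth.table["motif"]])
    rngs = _sample_rngs(config, len(sheet))
    cols = {}
    for (row, rng) in zip(sheet.itertuples(index=False), rngs):
        rel = expected_expression(truth, row.dose_uM) * 2.0 ** (-config.gc_bias * gc)
        total = rel.sum()
        if total <= 0:
            raise ValueError("degenerate expected proportions (all zero)")
        depth_factor = 2.0 ** rng.normal(0.0, config.depth_sigma_log2)
        depth = config.reads_per_sample * depth_factor
        mean = rel / total * depth * (1.0 - config.spike_share)
        counts = _nb_draw(rng, mean, config.phi)
        spike = _nb_draw(rng, np.array([depth * config.spike_share]), config.phi_spike)
        cols[row.sample] = np.concatenate([counts, spike])
    index = list(truth.table["variant"]) + [design.spike_in.key]
    counts = pd.DataFrame(cols, index=index)
    return CountMatrix(counts)


_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate(rng: np.random.Generator, reads: np.ndarray, error_rate: float) -> np.ndarray:
    """Per-base substitution errors on a uint8 base-index array."""
    if error_rate <= 0:
        return reads
    mask = rng.random(reads.shape) < error_rate
    shift = rng.integers(1, 4, size=int(mask.sum()))
    reads[mask] = (reads[mask] + shift) % 4
    return reads


def emit_fastq(
    counts: CountMatrix,
    design: LibraryDesign,
    config: SimConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write one FASTQ per sample; each count unit becomes one read.

    Reads carry the variant amplicon (or spike-in sequence) on a random
    strand, padded with random bases to ``read_length``, with substitution
    errors at ``error_rate`` and constant Phred+33 qualities.  The emitted
    per-variant tallies are exactly ``counts`` (the sidecar).  Returns
    sample -> FASTQ path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    amplicons = {}
    for key in counts.counts.index:
        if key == design.spike_in.key:
            amplicons[key] = design.spike_in.sequence
        else:
            sub, _, motif = key.partition("|")
            amplicons[key] = design.amplicon(sub, motif)
    too_long = [k for k, a in amplicons.items() if len(a) > config.read_length]
    if too_long:
        raise ValueError(
            f"read length {config.read_length} shorter than amplicon of "
            f"{too_long[0]!r} ({len(amplicons[too_long[0]])} nt)"
        )
    enc = {
        k: np.frombuffer(a.encode(), dtype=np.uint8) for k, a in amplicons.items()
    }
    code = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    enc = {k: code[v] for k, v in enc.items()}

    rngs = _sample_rngs(
        replace(config, seed=config.seed + 1_000_003), len(counts.samples)
    )
    paths: dict[str, Path] = {}
    keys = list(counts.counts.index)
    for sample, rng in zip(counts.samples, rngs):
        col = counts.counts[sample].to_numpy()
        n_reads = int(col.sum())
        reads = np.empty((n_reads, config.read_length), dtype=np.uint8)
        row = 0
        for key, c in zip(keys, col):
            if c == 0:
                continue
            amp = enc[key]
            pad = config.read_length - len(amp)
            block = np.empty((c, config.read_length), dtype=np.uint8)
            block[:, : len(amp)] = amp
            if pad:
                block[:, len(amp):] = rng.integers(0, 4, size=(c, pad), dtype=np.uint8)
            reads[row : row + c] = block
            row += c
        # random strand per read: reverse-complement amplicon+padding jointly
        flip = rng.random(n_reads) < 0.5
        reads[flip] = (3 - reads[flip])[:, ::-1]
        _mutate(rng, reads, config.error_rate)
        order = rng.permutation(n_reads)
        reads = reads[order]

        suffix = ".fastq.gz" if config.gzip_output else ".fastq"
        path = out_dir / f"{sample}{suffix}"
        opener = gzip.open if config.gzip_output else open
        qual = "I" * config.read_length
        with opener(path, "wt") as fh:
            seqs = _BASE_ARR[reads]
            for i in range(n_reads):
                fh.write(
                    f"@{sample}:{i}\n{seqs[i].tobytes().decode()}\n+\n{qual}\n"
                )
        paths[sample] = path
    return paths


def write_samplesheet(config: SimConfig, path: str | Path) -> None:
    config.samples().to_csv(path, sep="\t", index=False)
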