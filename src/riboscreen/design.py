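"""Riboswitch library designs: variant spaces, amplicons and read matchers.

A screening library is a set of *sub-libraries* sharing common amplicon
flanks (the PCR primer binding sites) and spacers.  Each sub-library is a
nucleotide template over ``{A, C, G, T, N}`` in which ``N`` marks the
randomized positions of the communication module.  The bases observed at
those positions, read 5'->3' on the sense strand and concatenated across
disjoint N-runs, form the variant's *motif* -- the self-barcode that
identifies each construct in sequencing reads without any added barcode.

Read matching is anchor-based: the constant flanks, spacers and fixed
template bases must occur exactly (anywhere in the read; leftmost match
wins) and the randomized positions are captured.  A design whose fixed
regions cannot disambiguate two sub-libraries is rejected when the matcher
is compiled, unless ambiguous counting is explicitly requested.

Coordinates are 0-based half-open; all sequences are normalized to
uppercase DNA (``U`` is mapped to ``T``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterator, NamedTuple

import yaml

__all__ = [
    "DesignError",
    "AmbiguityError",
    "SubLibrary",
    "SpikeIn",
    "VariantId",
    "LibraryDesign",
    "MatcherSet",
    "reverse_complement",
    "normalize_sequence",
    "gc_fraction",
    "builtin_design",
    "BUILTIN_DESIGN_NAMES",
    "SPIKE_SUBLIB",
]

#: Hard guard on the total enumerable variant space of a design.
ENUMERATION_LIMIT = 10**7

#: Reserved sub-library name used for the spike-in row of count matrices.
SPIKE_SUBLIB = "spike"

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_N_RUN = re.compile("N+")


class DesignError(ValueError):
    """Invalid library design or sequence."""


class AmbiguityError(DesignError):
    """Two sub-libraries whose fixed regions cannot be told apart."""


def normalize_sequence(seq: str, *, allow_n: bool = True) -> str:
    """Uppercase ``seq``, map U->T and validate the alphabet."""
    s = seq.upper().replace("U", "T")
    allowed = _ALPHABET if allow_n else frozenset("ACGT")
    bad = set(s) - allowed
    if bad:
        raise DesignError(
            f"invalid nucleotide(s) {sorted(bad)} in sequence {seq[:40]!r}"
        )
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement over ``{A,C,G,T,N}``; an involution."""
    return normalize_sequence(seq).translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G/C bases in ``seq`` (0 for the empty string)."""
    if not seq:
        return 0.0
    s = normalize_sequence(seq)
    return (s.count("G") + s.count("C")) / len(s)


class VariantId(NamedTuple):
    """A library variant: the sub-library it belongs to plus its motif."""

    sub_library: str
    motif: str

    @property
    def key(self) -> str:
        """Row identifier used in count matrices and FASTA headers."""
        return f"{self.sub_library}|{self.motif}"

    @classmethod
    def from_key(cls, key: str) -> "VariantId":
        sub, _, motif = key.partition("|")
        return cls(sub, motif)


@dataclass(frozen=True)
class SubLibrary:
    """One randomized-motif sub-library.

    ``template`` is the construct body with ``N`` at randomized positions;
    one or more contiguous or disjoint N-runs are allowed.
    """

    name: str
    template: str

    def __post_init__(self) -> None:
        if not self.name:
            raise DesignError("sub-library name must be non-empty")
        if self.name == SPIKE_SUBLIB:
            raise DesignError(f"sub-library name {SPIKE_SUBLIB!r} is reserved")
        object.__setattr__(self, "template", normalize_sequence(self.template))

    @property
    def runs(self) -> tuple[tuple[int, int], ...]:
        """0-based half-open (start, end) spans of the N-runs, 5'->3'."""
        return tuple(m.span() for m in _N_RUN.finditer(self.template))

    @property
    def n_random(self) -> int:
        return self.template.count("N")

    @property
    def n_variants(self) -> int:
        return 4**self.n_random

    def fill(self, motif: str) -> str:
        """Substitute ``motif`` into the template's N positions, in order."""
        motif = normalize_sequence(motif, allow_n=False)
        if len(motif) != self.n_random:
            raise DesignError(
                f"motif {motif!r} has length {len(motif)}, "
                f"sub-library {self.name!r} expects {self.n_random}"
            )
        parts: list[str] = []
        prev = 0
        offset = 0
        for start, end in self.runs:
            parts.append(self.template[prev:start])
            parts.append(motif[offset : offset + (end - start)])
            offset += end - start
            prev = end
        parts.append(self.template[prev:])
        return "".join(parts)

    def motif_display(self, motif: str) -> str:
        """Motif with ``_`` separating disjoint N-runs (e.g. ``CCG_CAG``)."""
        pieces: list[str] = []
        offset = 0
        for start, end in self.runs:
            pieces.append(motif[offset : offset + (end - start)])
            offset += end - start
        return "_".join(pieces)


@dataclass(frozen=True)
class SpikeIn:
    """Spike-in control amplicon, present at constant input in all samples."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise DesignError("spike-in id must be non-empty")
        object.__setattr__(
            self, "sequence", normalize_sequence(self.sequence, allow_n=False)
        )

    @property
    def key(self) -> str:
        return f"{SPIKE_SUBLIB}|{self.id}"


@dataclass(frozen=True)
class LibraryDesign:
    """A complete screened library: sub-libraries, flanks and spike-in.

    The amplicon of a variant is::

        flank_5p + spacer + filled_template + spacer + flank_3p

    where the flanks are the PCR primer binding sites shared by every
    construct in the library.
    """

    name: str
    sub_libraries: tuple[SubLibrary, ...]
    flank_5p: str
    flank_3p: str
    spike_in: SpikeIn
    spacer: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sub_libraries", tuple(self.sub_libraries))
        if not self.sub_libraries:
            raise DesignError("design needs at least one sub-library")
        names = [s.name for s in self.sub_libraries]
        if len(set(names)) != len(names):
            raise DesignError(f"duplicate sub-library names in {names}")
        for attr in ("flank_5p", "flank_3p", "spacer"):
            object.__setattr__(
                self, attr, normalize_sequence(getattr(self, attr), allow_n=False)
            )
        if not self.flank_5p or not self.flank_3p:
            raise DesignError("flanks must be non-empty")

    # -- variant space -----------------------------------------------------

    @property
    def n_variants(self) -> int:
        return sum(s.n_variants for s in self.sub_libraries)

    def sub_library(self, name: str) -> SubLibrary:
        for s in self.sub_libraries:
            if s.name == name:
                return s
        raise KeyError(name)

    def enumerate_variants(self) -> list[VariantId]:
        """All variants, sub-libraries in design order, motifs lexicographic.

        Raises :class:`DesignError` if the total space exceeds the
        enumeration guard (10^7 variants).
        """
        total = self.n_variants
        if total > ENUMERATION_LIMIT:
            raise DesignError(
                f"variant space of {total} exceeds enumeration bound "
                f"{ENUMERATION_LIMIT}"
            )
        out: list[VariantId] = []
        for s in self.sub_libraries:
            for bases in product("ACGT", repeat=s.n_random):
                out.append(VariantId(s.name, "".join(bases)))
        return out

    def iter_variants(self) -> Iterator[VariantId]:
        for s in self.sub_libraries:
            for bases in product("ACGT", repeat=s.n_random):
                yield VariantId(s.name, "".join(bases))

    # -- amplicons ---------------------------------------------------------

    def amplicon(self, sub_library: str, motif: str) -> str:
        body = self.sub_library(sub_library).fill(motif)
        return self.flank_5p + self.spacer + body + self.spacer + self.flank_3p

    def variant_to_amplicon(self, v: VariantId) -> str:
        """Full sense-strand amplicon for variant ``v``."""
        return self.amplicon(v.sub_library, v.motif)

    def _amplicon_pattern(self, s: SubLibrary) -> str:
        """Amplicon with N wildcards still in place (for collision checks)."""
        return self.flank_5p + self.spacer + s.template + self.spacer + self.flank_3p

    def write_variants_fasta(self, path: str | Path) -> None:
        """Export every variant amplicon as FASTA (headers ``sublib|motif``)."""
        with open(path, "w") as fh:
            for v in self.iter_variants():
                fh.write(f">{v.key}\n{self.variant_to_amplicon(v)}\n")
            fh.write(f">{self.spike_in.key}\n{self.spike_in.sequence}\n")

    # -- matching ----------------------------------------------------------

    def compile_matcher(self, *, allow_ambiguous: bool = False) -> "MatcherSet":
        return MatcherSet(self, allow_ambiguous=allow_ambiguous)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "flank_5p": self.flank_5p,
            "flank_3p": self.flank_3p,
            "spacer": self.spacer,
            "spike_in": {"id": self.spike_in.id, "sequence": self.spike_in.sequence},
            "sub_libraries": [
                {"name": s.name, "template": s.template} for s in self.sub_libraries
            ],
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "LibraryDesign":
        return cls(
            name=d["name"],
            sub_libraries=tuple(
                SubLibrary(s["name"], s["template"]) for s in d["sub_libraries"]
            ),
            flank_5p=d["flank_5p"],
            flank_3p=d["flank_3p"],
            spacer=d.get("spacer", ""),
            spike_in=SpikeIn(d["spike_in"]["id"], d["spike_in"]["sequence"]),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LibraryDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _compatible(a: str, b: str) -> bool:
    """Can some concrete read satisfy both wildcard patterns position-wise?"""
    if len(a) != len(b):
        return False
    return all(x == y or "N" in (x, y) for x, y in zip(a, b))


class MatcherSet:
    """Compiled read matchers for one design.

    One pattern per sub-library (constant anchors exact, each N-run a
    ``[ACGT]`` capture) plus an exact spike-in pattern, combined into a
    single alternation searched anywhere in the read.
    """

    def __init__(self, design: LibraryDesign, *, allow_ambiguous: bool = False):
        self.design = design
        self.allow_ambiguous = allow_ambiguous
        self.ambiguous_pairs: list[tuple[str, str]] = []
        self._check_collisions()

        subs = design.sub_libraries
        self._sub_patterns = [
            re.compile(self._pattern_for(i, s)) for i, s in enumerate(subs)
        ]
        spike = re.escape(design.spike_in.sequence)
        alternation = "|".join(
            [f"(?P<v{i}>{self._pattern_for(i, s)})" for i, s in enumerate(subs)]
            + [f"(?P<spike>{spike})"]
        )
        self._regex = re.compile(alternation)
        self._wrappers = [(f"v{i}", s) for i, s in enumerate(subs)]
        self.min_length = min(
            min(len(design._amplicon_pattern(s)) for s in subs),
            len(design.spike_in.sequence),
        )

    def _pattern_for(self, i: int, s: SubLibrary) -> str:
        body: list[str] = []
        prev = 0
        for j, (start, end) in enumerate(s.runs):
            body.append(re.escape(s.template[prev:start]))
            body.append(f"(?P<v{i}r{j}>[ACGT]{{{end - start}}})")
            prev = end
        body.append(re.escape(s.template[prev:]))
        d = self.design
        return (
            re.escape(d.flank_5p + d.spacer)
            + "".join(body)
            + re.escape(d.spacer + d.flank_3p)
        )

    def _check_collisions(self) -> None:
        d = self.design
        pats = {s.name: d._amplicon_pattern(s) for s in d.sub_libraries}
        names = list(pats)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if _compatible(pats[a], pats[b]):
                    self.ambiguous_pairs.append((a, b))
        if self.ambiguous_pairs and not self.allow_ambiguous:
            raise AmbiguityError(
                "fixed regions cannot disambiguate sub-library pairs "
                f"{self.ambiguous_pairs}; reads consistent with both would be "
                "unassignable (pass allow_ambiguous=True to count them as "
                "ambiguous instead)"
            )
        spike = d.spike_in.sequence
        for s in d.sub_libraries:
            if _compatible(pats[s.name], spike):
                raise DesignError(
                    f"spike-in sequence is a valid amplicon of sub-library "
                    f"{s.name!r}; it must not collide with the variant space"
                )

    def match(self, read: str) -> VariantId | None:
        """Assign a (sense-strand) read, or return None.

        Returns ``VariantId(sub_library, motif)``; the spike-in is reported
        as ``VariantId("spike", spike_id)``.  With ``allow_ambiguous``
        compilation, a read consistent with several sub-libraries returns
        the sentinel ``VariantId("ambiguous", "")``.
        """
        if self.ambiguous_pairs:
            return self._match_checked(read)
        m = self._regex.search(read)
        if m is None:
            return None
        if m.group("spike") is not None:
            return VariantId(SPIKE_SUBLIB, self.design.spike_in.id)
        for name, s in self._wrappers:
            if m.group(name) is not None:
                i = name[1:]
                motif = "".join(m.group(f"v{i}r{j}") for j in range(len(s.runs)))
                return VariantId(s.name, motif)
        return None  # pragma: no cover

    def _match_checked(self, read: str) -> VariantId | None:
        hits: list[VariantId] = []
        for pat, (_, s) in zip(self._sub_patterns, self._wrappers):
            m = pat.search(read)
            if m is not None:
                groups = m.groups()
                hits.append(VariantId(s.name, "".join(groups)))
        if len(hits) > 1:
            return VariantId("ambiguous", "")
        if hits:
            return hits[0]
        if re.search(re.escape(self.design.spike_in.sequence), read):
            return VariantId(SPIKE_SUBLIB, self.design.spike_in.id)
        return None


# ---------------------------------------------------------------------------
# Built-in designs
# ---------------------------------------------------------------------------

# Shared amplicon context: forward primer binding site, reverse flank and
# the (CAAA)x3 spacers placed on both sides of the construct body.
_FLANK_5P = "CATTGCAGCGTATTCCCAGTCC"
_FLANK_3P = "GCCTGGTGAAATTGTTATCCGCT"
_SPACER = "CAAA" * 3

# Fixed construct bodies below are synthetic placeholders: they reproduce
# the randomized-position layout and complexity of each published library
# design, not the exact ribozyme/aptamer sequences (which are not bundled).
_TET_APTAMER_CORE = "AAAACATACCAGATTTCGATCTGGAGAGG"
_SPIKE_BODY = "TTGACGGCTAGCTCAGTCCTAGGTACAGTGCTAGCTACTGGATCC"


def _mk(name: str, sublibs: list[SubLibrary]) -> LibraryDesign:
    spike_seq = _FLANK_5P + _SPACER + _SPIKE_BODY + _SPACER + _FLANK_3P
    return LibraryDesign(
        name=name,
        sub_libraries=tuple(sublibs),
        flank_5p=_FLANK_5P,
        flank_3p=_FLANK_3P,
        spacer=_SPACER,
        spike_in=SpikeIn("spikein1", spike_seq),
    )


def _twister_sublibs() -> list[SubLibrary]:
    # Communication module connecting ribozyme P1 to the aptamer: two
    # randomized strands (2N3N / 3N2N asymmetric, 3N3N symmetric) around
    # the fixed aptamer core, with 0/1/2 optional CG closing pairs giving
    # three linker lengths.  3 lengths x {5,5,6 N} = 18,432 variants.
    rz5 = "GGCCAGCTACGGTCCCAAG"
    rz3 = "CTTGGGACC"
    out: list[SubLibrary] = []
    for stem_name, stem in [("noCG", ""), ("CG", "CG"), ("CGCG", "CGCG")]:
        for mod_name, n1, n2 in [("2N3N", 2, 3), ("3N2N", 3, 2), ("3N3N", 3, 3)]:
            template = (
                rz5
                + stem
                + "N" * n1
                + _TET_APTAMER_CORE
                + "N" * n2
                + reverse_complement(stem)
                + rz3
            )
            out.append(SubLibrary(f"{stem_name}_{mod_name}", template))
    return out


def _builtin(name: str) -> LibraryDesign:
    if name == "tet-hhr":
        # 7 randomized positions (5 on the 5' strand, 2 on the 3' strand).
        return _mk(
            "tet-hhr",
            [
                SubLibrary(
                    "tet_hhr",
                    "GCTGTCACCGGA" + "NNNNN" + "TGTCCTGGATTCCACT" + "NN" + "GAAACAGC",
                )
            ],
        )
    if name == "gua-hdv":
        # 6 contiguous randomized positions in the communication module.
        return _mk(
            "gua-hdv",
            [SubLibrary("gua_hdv", "GGGTCGGCATGGCATCTCC" + "NNNNNN" + "CCTCCTCGCGGT")],
        )
    if name == "gua-hhr":
        return _mk(
            "gua-hhr",
            [
                SubLibrary(
                    "gua_hhr",
                    "CTGATGAGTCCGTGAGGAC" + "NNNN" + "GTCCCATTCGCCAT" + "NNN" + "GAAACG",
                )
            ],
        )
    if name == "gua-u1":
        # U1-snRNP binding site (CAGGTAAGT) inside a prolonged aptamer stem,
        # 6 randomized positions split 3+3 around it.
        return _mk(
            "gua-u1",
            [SubLibrary("gua_u1", "GATCGGAC" + "NNN" + "CAGGTAAGT" + "NNN" + "GTCCGATC")],
        )
    if name == "tet-twister":
        return _mk("tet-twister", _twister_sublibs())
    if name == "toy":
        # Small single sub-library design (64 variants) for demos and tests.
        return _mk("toy", [SubLibrary("toy", "GGAC" + "NNN" + "GTCC")])
    raise KeyError(f"unknown built-in design {name!r}; choose from {BUILTIN_DESIGN_NAMES}")


BUILTIN_DESIGN_NAMES = ("tet-hhr", "gua-hdv", "gua-hhr", "gua-u1", "tet-twister", "toy")


def builtin_design(name: str) -> LibraryDesign:
    """Return a bundled library design by name.

    Available: ``tet-hhr`` (4^7 = 16,384 variants), ``gua-hdv`` (4,096),
    ``gua-hhr`` (16,384), ``gua-u1`` (4,096), ``tet-twister`` (nine
    sub-libraries, 18,432) and ``toy`` (64).  Flanks, spacers and
    randomized-position layouts follow the published screens; fixed bodies
    are synthetic placeholders (see module comments).
    """
    return _builtin(name)
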