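"""Shannon Entropy of Locus Variability (SELV).

A locus (a single genomic position on a stated build) carries zero or more
alternate alleles reported in a population frequency resource, each with a
population allele frequency ``F_i``.  The SELV of the locus is the Shannon
entropy of that frequency vector,

    SELV = - sum_i F_i * log(F_i),

with the usual conventions ``0*log 0 = 0`` and ``1*log 1 = 0``.  Frequencies
are used exactly as reported: they are not renormalized and the reference
allele contributes no term.  SELV is therefore non-negative, zero for a
position with no reported variation, and grows with the number and balance
of segregating alleles.  Low SELV marks positions under strong selective
constraint, which is what makes the score useful for flagging candidate
pathogenic variants.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

from .errors import (
    BuildMismatchError,
    DomainError,
    DuplicateRecordError,
    UnknownStratumError,
)

__all__ = [
    "COMBINED_POPULATION",
    "FrequencyRecord",
    "LocusKey",
    "LocusFrequencyVector",
    "SelvScore",
    "LocusTable",
    "normalize_contig",
    "compute_selv",
    "build_locus_table",
    "score_variants",
    "stratified_selv",
]

#: Stratum tag for frequencies pooled over the whole resource.
COMBINED_POPULATION = ""

# Mitochondrial contig spellings differ between resources; they all denote
# the same single molecule and must pool together.
_MITO_ALIASES = frozenset({"chrM", "MT", "chrMT", "M"})


def normalize_contig(contig: str, mito_name: str = "chrM") -> str:
    """Map mitochondrial contig aliases onto one canonical name.

    ``chrM``, ``chrMT``, ``MT`` and ``M`` all become *mito_name*; every
    other contig is returned unchanged.
    """
    return mito_name if contig in _MITO_ALIASES else contig


@dataclass(frozen=True)
class LocusKey:
    """A single genomic position on a stated genome build."""

    contig: str
    position: int
    build: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DomainError(f"position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class FrequencyRecord:
    """One (site, alternate allele) row of a population frequency resource.

    ``frequency`` is the reported population allele frequency of ``alt`` at
    ``contig:position`` (1-based).  ``population`` tags an ancestry stratum;
    the empty string means the combined (all-samples) frequency.
    """

    contig: str
    position: int
    ref: str
    alt: str
    frequency: float
    population: str = COMBINED_POPULATION

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DomainError(f"position must be >= 1, got {self.position}")
        if not 0.0 <= self.frequency <= 1.0:
            raise DomainError(
                f"frequency must lie in [0, 1], got {self.frequency!r} "
                f"at {self.contig}:{self.position} {self.ref}>{self.alt}"
            )

    @property
    def is_snv(self) -> bool:
        """True when ref and alt are single, distinct nucleotides."""
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref != self.alt
            and self.ref in "ACGT"
            and self.alt in "ACGT"
        )


@dataclass(frozen=True)
class LocusFrequencyVector:
    """The vector (F_1, ..., F_n) of reported frequencies at one locus.

    Zero-frequency records are never stored, so every element lies in
    (0, 1].  ``n`` is the number of reported variants at the locus.
    """

    locus: LocusKey
    frequencies: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        for f in self.frequencies:
            if not 0.0 < f <= 1.0:
                raise DomainError(
                    f"locus vector elements must lie in (0, 1], got {f!r}"
                )

    @property
    def n(self) -> int:
        return len(self.frequencies)


@dataclass(frozen=True)
class SelvScore:
    """A locus together with its SELV value and variant count."""

    locus: LocusKey
    value: float
    n_variants: int


def compute_selv(
    frequencies: Iterable[float], log_base: float = math.e
) -> float:
    """Shannon entropy of a vector of reported allele frequencies.

    Parameters
    ----------
    frequencies
        Reported population frequencies, each in ``[0, 1]``.  They are used
        as given: no renormalization, no reference-allele mass.
    log_base
        Base of the logarithm (natural log by default).  Changing base
        rescales the value by ``1/ln(base)`` and nothing else.

    Returns
    -------
    float
        ``-sum F_i log(F_i)`` over elements with ``0 < F_i < 1``; always
        non-negative.  The empty vector gives 0.
    """
    if log_base <= 0 or log_base == 1:
        raise DomainError(f"log_base must be positive and != 1, got {log_base}")
    total = 0.0
    for f in frequencies:
        if not 0.0 <= f <= 1.0:
            raise DomainError(f"frequency must lie in [0, 1], got {f!r}")
        if 0.0 < f < 1.0:  # 0*log0 = 1*log1 = 0 by convention
            total -= f * math.log(f)
    if log_base != math.e:
        total /= math.log(log_base)
    # -0.0 can arise from an empty or all-boundary vector
    return total + 0.0


class LocusTable:
    """Per-locus frequency vectors, keyed by position and population stratum.

    Built by :func:`build_locus_table`.  All alternate alleles reported at
    the same (contig, position, stratum) are pooled into one vector; the
    table remembers how many input records were kept, dropped for zero
    frequency, or rejected as non-SNV.
    """

    def __init__(self, build: str, mito_name: str = "chrM") -> None:
        self.build = build
        self.mito_name = mito_name
        self._vectors: dict[tuple[str, int, str], list[float]] = {}
        self._seen: set[tuple[str, int, str, str, str]] = set()
        self._strata: set[str] = set()
        self.n_kept = 0
        self.n_zero_dropped = 0
        self.n_non_snv = 0

    def add(self, record: FrequencyRecord) -> None:
        contig = normalize_contig(record.contig, self.mito_name)
        if not record.is_snv:
            self.n_non_snv += 1
            return
        key = (contig, record.position, record.ref, record.alt, record.population)
        if key in self._seen:
            raise DuplicateRecordError(
                f"duplicate frequency record {contig}:{record.position} "
                f"{record.ref}>{record.alt} (population={record.population!r})"
            )
        self._seen.add(key)
        self._strata.add(record.population)
        if record.frequency == 0.0:
            self.n_zero_dropped += 1
            return
        self._vectors.setdefault(
            (contig, record.position, record.population), []
        ).append(record.frequency)
        self.n_kept += 1

    @property
    def strata(self) -> tuple[str, ...]:
        """Population strata present, combined ('') first."""
        return tuple(sorted(self._strata, key=lambda s: (s != COMBINED_POPULATION, s)))

    def loci(self, population: str = COMBINED_POPULATION) -> list[LocusKey]:
        return [
            LocusKey(c, p, self.build)
            for (c, p, pop) in sorted(self._vectors)
            if pop == population
        ]

    def vector(
        self, contig: str, position: int, population: str = COMBINED_POPULATION
    ) -> LocusFrequencyVector:
        """The frequency vector at a position (empty if nothing reported)."""
        contig = normalize_contig(contig, self.mito_name)
        freqs = self._vectors.get((contig, position, population), [])
        return LocusFrequencyVector(
            LocusKey(contig, position, self.build), tuple(freqs)
        )

    def selv(
        self,
        contig: str,
        position: int,
        population: str = COMBINED_POPULATION,
        log_base: float = math.e,
    ) -> SelvScore:
        vec = self.vector(contig, position, population)
        return SelvScore(vec.locus, compute_selv(vec.frequencies, log_base), vec.n)

    def __len__(self) -> int:
        return len(self._vectors)


def build_locus_table(
    records: Iterable[FrequencyRecord],
    build: str,
    mito_name: str = "chrM",
) -> LocusTable:
    """Pool frequency records into per-locus vectors.

    Multi-allelic positions arrive as one record per alternate allele and
    pool by position.  Duplicate (contig, position, ref, alt, population)
    records raise :class:`DuplicateRecordError`; non-SNV records are
    rejected and counted; zero-frequency records are dropped and counted.
    """
    table = LocusTable(build, mito_name=mito_name)
    for record in records:
        table.add(record)
    return table


def score_variants(
    variants: Sequence,
    table: LocusTable,
    log_base: float = math.e,
    build: str | None = None,
) -> list[tuple[object, SelvScore]]:
    """SELV-score query variants against a locus table.

    Each variant receives the SELV of its locus as recorded in the
    resource; its own alternate allele is never added to the vector, so a
    novel variant cannot inflate its own score.  A position absent from the
    table scores 0 with ``n_variants = 0`` (no reported variability).

    *variants* is any sequence of objects with ``contig`` and ``position``
    attributes (e.g. :class:`selv.io.LabeledVariant`).  If *build* is given
    it must match the table's build tag.
    """
    if build is not None and build != table.build:
        raise BuildMismatchError(
            f"variant build {build!r} does not match table build {table.build!r}"
        )
    return [
        (v, table.selv(v.contig, v.position, log_base=log_base)) for v in variants
    ]


def stratified_selv(
    table: LocusTable,
    locus: LocusKey,
    populations: Sequence[str] | None = None,
    log_base: float = math.e,
) -> dict[str, SelvScore]:
    """SELV of one locus per population stratum.

    Each stratum's score uses only that stratum's reported frequencies; the
    combined stratum (key ``""``) is reported alongside.  Requesting a
    stratum the table does not contain raises :class:`UnknownStratumError`
    listing the available strata.
    """
    available = table.strata
    if populations is None:
        populations = available or (COMBINED_POPULATION,)
    else:
        unknown = [p for p in populations if p not in available]
        if unknown:
            raise UnknownStratumError(
                f"unknown strata {unknown}; available: {list(available)}"
            )
    out: dict[str, SelvScore] = {}
    for pop in dict.fromkeys((COMBINED_POPULATION, *populations)):
        out[pop] = table.selv(locus.contig, locus.position, pop, log_base)
    return out
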