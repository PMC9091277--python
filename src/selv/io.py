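"""Readers and writers for frequency resources, variant tables and scores.

Frequency resources arrive either as gnomAD-style VCFs (allele frequencies
in an INFO key, one value per alternate allele) or as plain tab-separated
tables in the style of helixMTdb exports.  Query variants are tab-separated
tables with optional pathogenicity labels, genomic-context tags and
competitor-score columns.  All readers accept gzip-compressed input; all
coordinates are 1-based throughout (VCF convention).
"""

from __future__ import annotations

import gzip
import math
import os
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .core import (
    COMBINED_POPULATION,
    FrequencyRecord,
    LocusTable,
    SelvScore,
    normalize_contig,
)
from .errors import DomainError, DuplicateRecordError, FormatError

__all__ = [
    "CONTEXTS",
    "LabeledVariant",
    "ReadCounts",
    "FrequencyReadResult",
    "VariantReadResult",
    "read_frequency_vcf",
    "read_frequency_tsv",
    "read_variant_table",
    "write_frequency_vcf",
    "write_frequency_tsv",
    "write_variant_table",
    "scored_frame",
    "write_scored_table",
    "annotate_vcf",
]

#: Recognized genomic-context tags for query variants.
CONTEXTS = (
    "splice_site",
    "nuclear_noncoding",
    "mito_noncoding",
    "protein_coding",
    "unspecified",
)

_VARIANT_COLUMNS = ("contig", "position", "ref", "alt", "label", "context")
_NA = "NA"


@dataclass
class LabeledVariant:
    """A query SNV with optional label, context and competitor scores.

    ``label`` is 1 for pathogenic, 0 for neutral, ``None`` for unlabeled
    (a VUS).  ``extra_scores`` holds competitor predictions (ada-score,
    rf-score, CDTS, HmtVar, phastCons, phyloP, ...) as plain numbers; a
    missing score is simply absent from the map, never stored as 0.
    """

    contig: str
    position: int
    ref: str
    alt: str
    label: int | None = None
    context: str = "unspecified"
    extra_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DomainError(f"position must be >= 1, got {self.position}")
        if self.label is not None and self.label not in (0, 1):
            raise DomainError(f"label must be 0, 1 or missing, got {self.label!r}")
        if self.context not in CONTEXTS:
            raise DomainError(
                f"context must be one of {CONTEXTS}, got {self.context!r}"
            )

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref != self.alt
            and self.ref in "ACGT"
            and self.alt in "ACGT"
        )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref, self.alt)


@dataclass
class ReadCounts:
    """Per-reason bookkeeping for one read pass.

    ``total`` always equals kept plus every rejection bucket, so no input
    row can vanish silently.
    """

    kept: int = 0
    missing_key: int = 0
    non_snv: int = 0
    bad_value: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.missing_key + self.non_snv + self.bad_value


@dataclass
class FrequencyReadResult:
    records: list[FrequencyRecord]
    counts: ReadCounts

    def __iter__(self) -> Iterator[FrequencyRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class VariantReadResult:
    variants: list[LabeledVariant]
    counts: ReadCounts

    def __iter__(self) -> Iterator[LabeledVariant]:
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)


def _open_text(path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _f32(value: float) -> float:
    """Shortest decimal that round-trips through single precision.

    VCF ``Type=Float`` INFO values pass through a 32-bit float inside
    htslib; mapping the parsed value to its shortest decimal representation
    recovers the number as written (0.3, not 0.30000001192...).
    """
    return float(np.format_float_positional(np.float32(value), unique=True, trim="-"))


def _open_variant_file(path) -> pysam.VariantFile:
    """Open a VCF, tolerating plain-gzip (non-BGZF) compression.

    htslib seeks on open, which plain gzip cannot do; such files are
    decompressed to a temporary file first.
    """
    try:
        return pysam.VariantFile(str(path))
    except NotImplementedError:
        import shutil
        import tempfile

        with gzip.open(path, "rb") as src, tempfile.NamedTemporaryFile(
            suffix=".vcf", delete=False
        ) as tmp:
            shutil.copyfileobj(src, tmp)
        vcf = pysam.VariantFile(tmp.name)
        os.unlink(tmp.name)  # fd stays valid on POSIX
        return vcf


def _stratum_name(key: str, af_key: str) -> str:
    prefix = af_key + "_"
    return key[len(prefix):] if key.startswith(prefix) else key


def read_frequency_vcf(
    path,
    af_key: str = "AF",
    population_keys: Sequence[str] | None = None,
) -> FrequencyReadResult:
    """Read per-allele population frequencies from a gnomAD-style VCF.

    One :class:`FrequencyRecord` is yielded per (site, alternate allele),
    with the frequency taken from the *af_key* INFO entry matched to that
    allele.  Each key in *population_keys* (e.g. ``AF_afr``) yields
    additional records tagged with the stratum name (the key with the
    ``<af_key>_`` prefix stripped).  Sites lacking a key are counted, not
    errors; a key absent from the header is a hard error.
    """
    population_keys = list(population_keys or [])
    counts = ReadCounts()
    records: list[FrequencyRecord] = []
    with _open_variant_file(path) as vcf:
        for key in [af_key, *population_keys]:
            if key not in vcf.header.info:
                raise FormatError(
                    f"INFO key {key!r} is not declared in the VCF header of {path}"
                )
        for rec in vcf:
            alts = rec.alts or ()
            for stratum_key, stratum in (
                (af_key, COMBINED_POPULATION),
                *((k, _stratum_name(k, af_key)) for k in population_keys),
            ):
                values = rec.info.get(stratum_key)
                if values is None:
                    counts.missing_key += len(alts)
                    continue
                if not isinstance(values, tuple):
                    values = (values,)
                for alt, value in zip(alts, values):
                    if value is None:
                        counts.missing_key += 1
                        continue
                    try:
                        record = FrequencyRecord(
                            rec.chrom, rec.pos, rec.ref, alt, _f32(value), stratum
                        )
                    except DomainError:
                        counts.bad_value += 1
                        continue
                    records.append(record)
                    counts.kept += 1
    return FrequencyReadResult(records, counts)


_FREQ_COLUMNS = {
    "contig": "contig",
    "position": "position",
    "ref": "ref",
    "alt": "alt",
    "frequency": "frequency",
    "population": "population",
}


def read_frequency_tsv(
    path, columns: Mapping[str, str] | None = None
) -> FrequencyReadResult:
    """Read a tab-separated frequency table (helixMTdb-style export).

    *columns* maps the canonical names (contig, position, ref, alt,
    frequency, optional population) onto the file's header names.  Rows
    with a frequency outside [0, 1] are rejected and counted.
    """
    colmap = {**_FREQ_COLUMNS, **(columns or {})}
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for canon in ("contig", "position", "ref", "alt", "frequency"):
        if colmap[canon] not in frame.columns:
            raise FormatError(
                f"required column {canon!r} (mapped to {colmap[canon]!r}) "
                f"is missing from {path}"
            )
    has_pop = colmap["population"] in frame.columns
    counts = ReadCounts()
    records: list[FrequencyRecord] = []
    for row in frame.itertuples(index=False):
        row = dict(zip(frame.columns, row))
        try:
            record = FrequencyRecord(
                row[colmap["contig"]],
                int(row[colmap["position"]]),
                row[colmap["ref"]],
                row[colmap["alt"]],
                float(row[colmap["frequency"]]),
                row[colmap["population"]] if has_pop else COMBINED_POPULATION,
            )
        except (DomainError, ValueError):
            counts.bad_value += 1
            continue
        records.append(record)
        counts.kept += 1
    return FrequencyReadResult(records, counts)


def read_variant_table(
    path,
    score_columns: Sequence[str] | None = None,
    score_prefix: str | None = None,
) -> VariantReadResult:
    """Read a tab-separated query-variant table.

    Required columns: contig, position, ref, alt.  Optional: label (0/1),
    context.  Competitor-score columns are taken from *score_columns* if
    given, else from columns starting with *score_prefix* if given, else
    every remaining column is treated as a score.  Empty cells and ``NA``
    are missing values, never zeros.  Duplicate variant keys are an error;
    non-SNV rows are rejected and counted.
    """
    frame = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    for required in ("contig", "position", "ref", "alt"):
        if required not in frame.columns:
            raise FormatError(f"required column {required!r} missing from {path}")
    if score_columns is not None:
        score_cols = list(score_columns)
    elif score_prefix is not None:
        score_cols = [c for c in frame.columns if c.startswith(score_prefix)]
    else:
        score_cols = [c for c in frame.columns if c not in _VARIANT_COLUMNS]
    counts = ReadCounts()
    variants: list[LabeledVariant] = []
    seen: set[tuple[str, int, str, str]] = set()
    for row in frame.itertuples(index=False):
        row = dict(zip(frame.columns, row))
        label_cell = row.get("label", "")
        context = row.get("context", "") or "unspecified"
        scores = {
            c: float(row[c]) for c in score_cols if row[c] not in ("", _NA)
        }
        try:
            variant = LabeledVariant(
                row["contig"],
                int(row["position"]),
                row["ref"],
                row["alt"],
                None if label_cell in ("", _NA) else int(label_cell),
                context,
                scores,
            )
        except (DomainError, ValueError):
            counts.bad_value += 1
            continue
        if not variant.is_snv:
            counts.non_snv += 1
            continue
        if variant.key in seen:
            raise DuplicateRecordError(
                f"duplicate variant {variant.contig}:{variant.position} "
                f"{variant.ref}>{variant.alt} in {path}"
            )
        seen.add(variant.key)
        variants.append(variant)
        counts.kept += 1
    return VariantReadResult(variants, counts)


def write_frequency_tsv(records: Iterable[FrequencyRecord], path) -> None:
    with _open_text(path, "wt") as out:
        out.write("contig\tposition\tref\talt\tfrequency\tpopulation\n")
        for r in records:
            out.write(
                f"{r.contig}\t{r.position}\t{r.ref}\t{r.alt}\t"
                f"{r.frequency!r}\t{r.population}\n"
            )


def write_frequency_vcf(
    records: Sequence[FrequencyRecord],
    path,
    af_key: str = "AF",
    build: str = "",
) -> None:
    """Write frequency records as a VCF the VCF reader round-trips exactly.

    Records at one (contig, position) are merged into one multi-allelic
    line per the combined stratum; per-population frequencies become
    ``<af_key>_<population>`` INFO keys aligned to the alternate alleles.
    Frequencies are canonicalized through single precision first, since VCF
    Float INFO values are 32-bit on disk.
    """
    strata = sorted(
        {r.population for r in records if r.population != COMBINED_POPULATION}
    )
    by_site: dict[tuple[str, int], dict[str, dict[str, float]]] = {}
    ref_at: dict[tuple[str, int], str] = {}
    for r in records:
        site = (r.contig, r.position)
        ref_at.setdefault(site, r.ref)
        by_site.setdefault(site, {}).setdefault(r.alt, {})[r.population] = _f32(
            r.frequency
        )
    with _open_text(path, "wt") as out:
        out.write("##fileformat=VCFv4.2\n")
        if build:
            out.write(f"##reference={build}\n")
        out.write(
            f'##INFO=<ID={af_key},Number=A,Type=Float,'
            f'Description="Alternate allele frequency">\n'
        )
        for pop in strata:
            out.write(
                f'##INFO=<ID={af_key}_{pop},Number=A,Type=Float,'
                f'Description="Alternate allele frequency in {pop}">\n'
            )
        contigs = sorted({c for c, _ in by_site})
        for contig in contigs:
            out.write(f"##contig=<ID={contig}>\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for contig, pos in sorted(by_site):
            alleles = by_site[(contig, pos)]
            alts = sorted(alleles)
            info_parts = []
            for key, pop in (
                (af_key, COMBINED_POPULATION),
                *((f"{af_key}_{p}", p) for p in strata),
            ):
                values = [alleles[a].get(pop) for a in alts]
                if all(v is None for v in values):
                    continue
                info_parts.append(
                    key
                    + "="
                    + ",".join("." if v is None else repr(v) for v in values)
                )
            out.write(
                f"{contig}\t{pos}\t.\t{ref_at[(contig, pos)]}\t{','.join(alts)}"
                f"\t.\t.\t{';'.join(info_parts) or '.'}\n"
            )


def write_variant_table(variants: Sequence[LabeledVariant], path) -> None:
    score_cols = sorted({k for v in variants for k in v.extra_scores})
    with _open_text(path, "wt") as out:
        out.write("\t".join(_VARIANT_COLUMNS + tuple(score_cols)) + "\n")
        for v in variants:
            cells = [
                v.contig,
                str(v.position),
                v.ref,
                v.alt,
                _NA if v.label is None else str(v.label),
                v.context,
            ]
            for c in score_cols:
                s = v.extra_scores.get(c)
                cells.append(_NA if s is None else repr(s))
            out.write("\t".join(cells) + "\n")


def scored_frame(
    scored: Sequence[tuple[LabeledVariant, SelvScore]],
    predicted: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble (variant, score) pairs into a flat table, order preserved."""
    score_cols = sorted({k for v, _ in scored for k in v.extra_scores})
    rows = []
    for i, (v, s) in enumerate(scored):
        row = {
            "contig": v.contig,
            "position": v.position,
            "ref": v.ref,
            "alt": v.alt,
            "label": np.nan if v.label is None else v.label,
            "context": v.context,
            "selv": s.value,
            "n_variants": s.n_variants,
        }
        for c in score_cols:
            row[c] = v.extra_scores.get(c, np.nan)
        if predicted is not None:
            row["predicted_class"] = predicted[i]
        rows.append(row)
    columns = [
        "contig", "position", "ref", "alt", "label", "context",
        "selv", "n_variants", *score_cols,
    ]
    if predicted is not None:
        columns.append("predicted_class")
    return pd.DataFrame(rows, columns=columns)


def write_scored_table(frame: pd.DataFrame, path, precision: int = 6) -> None:
    """Write a scored table as TSV with stable column order and NA blanks."""
    frame.to_csv(
        path, sep="\t", index=False, na_rep=_NA,
        float_format=f"%.{precision}f",
    )


def annotate_vcf(
    path_in,
    table: LocusTable,
    path_out,
    info_key: str = "SELV",
    log_base: float = math.e,
) -> int:
    """Add a per-record SELV INFO field to a VCF, touching nothing else.

    The annotation key is declared in the header as ``Number=1,Type=Float``
    and appended to each record's INFO column with the SELV of the record's
    position (0 for positions absent from the table).  Every other byte of
    the file is preserved, which is why this works on the text rather than
    through a VCF object model.  Returns the number of records annotated.
    """
    n_annotated = 0
    header_line = (
        f'##INFO=<ID={info_key},Number=1,Type=Float,'
        f'Description="Shannon entropy of locus variability">\n'
    )
    with _open_text(path_in, "rt") as src, _open_text(path_out, "wt") as out:
        for line in src:
            if line.startswith("#CHROM"):
                out.write(header_line)
                out.write(line)
                continue
            if line.startswith("#"):
                out.write(line)
                continue
            stripped = line.rstrip("\n")
            fields = stripped.split("\t")
            if len(fields) < 8:
                raise FormatError(
                    f"VCF record with {len(fields)} fields (need >= 8): "
                    f"{stripped[:80]!r}"
                )
            value = table.selv(fields[0], int(fields[1]), log_base=log_base).value
            entry = f"{info_key}={value:.6g}"
            fields[7] = entry if fields[7] in (".", "") else fields[7] + ";" + entry
            out.write("\t".join(fields) + "\n")
            n_annotated += 1
    return n_annotated
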