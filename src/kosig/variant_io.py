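"""Reading and writing of variant records, reference sequence, signature
catalogs and annotation tracks, plus parental subtraction.

Coordinates are 1-based inclusive at every interface (VCF convention); BED
input is converted from its native 0-based half-open form on load.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .taxonomy import BASES, ChannelTaxonomy, get_taxonomy

SV_CLASSES_VALID = {"deletion", "inversion", "tandem-duplication", "translocation"}


class VariantIOError(ValueError):
    """A file or row violates the expected record contract."""


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class SubstitutionRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self):
        if self.ref not in BASES or self.alt not in BASES:
            raise VariantIOError(
                f"substitution alleles must be single A/C/G/T bases: "
                f"{self.chrom}:{self.pos} {self.ref}>{self.alt}"
            )
        if self.ref == self.alt:
            raise VariantIOError(f"ref equals alt at {self.chrom}:{self.pos}")

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True, order=True)
class IndelRecord:
    """VCF left-anchored indel: ref = anchor+deleted, alt = anchor+inserted."""

    chrom: str
    pos: int  # 1-based anchor coordinate
    ref: str
    alt: str

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise VariantIOError(f"empty allele at {self.chrom}:{self.pos}")
        if len(self.ref) == 1 and len(self.alt) == 1:
            raise VariantIOError(
                f"{self.chrom}:{self.pos} {self.ref}>{self.alt} is a substitution, "
                "not an indel"
            )
        for allele in (self.ref, self.alt):
            if any(b not in BASES for b in allele):
                raise VariantIOError(
                    f"non-ACGT base in allele at {self.chrom}:{self.pos}"
                )

    @property
    def is_complex(self) -> bool:
        return len(self.ref) > 1 and len(self.alt) > 1

    @property
    def is_insertion(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) > 1

    @property
    def is_deletion(self) -> bool:
        return len(self.alt) == 1 and len(self.ref) > 1

    @property
    def inserted(self) -> str:
        return self.alt[1:] if self.is_insertion else ""

    @property
    def deleted(self) -> str:
        return self.ref[1:] if self.is_deletion else ""

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True, order=True)
class RearrangementRecord:
    """A breakpoint pair with a structural-variant class."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    svclass: str

    def __post_init__(self):
        if self.svclass not in SV_CLASSES_VALID:
            raise VariantIOError(f"unknown svclass {self.svclass!r}")
        inter = self.chrom1 != self.chrom2
        if inter != (self.svclass == "translocation"):
            raise VariantIOError(
                f"svclass {self.svclass!r} inconsistent with chromosomes "
                f"{self.chrom1}/{self.chrom2}"
            )
        if not inter and self.pos2 <= self.pos1:
            raise VariantIOError(
                f"intra-chromosomal record requires pos2 > pos1 "
                f"({self.chrom1}:{self.pos1}-{self.pos2})"
            )

    @property
    def span(self) -> int | None:
        return None if self.chrom1 != self.chrom2 else self.pos2 - self.pos1


RECORD_CLASS = {
    SubstitutionRecord: "substitution",
    IndelRecord: "indel",
    RearrangementRecord: "rearrangement",
}


def mutation_class_of(records: Sequence) -> str:
    """Mutation class of a homogeneous record list; raises on mixtures."""
    classes = {RECORD_CLASS.get(type(r)) for r in records}
    classes.discard(None)
    if len(classes) != 1:
        raise VariantIOError(f"expected one mutation class, found {sorted(classes, key=str)}")
    return classes.pop()


# ---------------------------------------------------------------------------
# reject reporting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reject:
    line: int | None
    reason: str
    raw: str = ""


class RecordList(list):
    """A list of records that also carries the rows rejected while reading."""

    def __init__(self, items=(), rejects: list[Reject] | None = None):
        super().__init__(items)
        self.rejects: list[Reject] = list(rejects or [])


# ---------------------------------------------------------------------------
# reference sequence
# ---------------------------------------------------------------------------


class ReferenceSequence:
    """1-based inclusive fetch over named contigs; returns uppercase bases."""

    def fetch(self, chrom: str, start: int, end: int) -> str:
        raise NotImplementedError

    def contig_length(self, chrom: str) -> int:
        raise NotImplementedError

    @property
    def contigs(self) -> tuple[str, ...]:
        raise NotImplementedError


class InMemoryReference(ReferenceSequence):
    """Reference backed by an in-memory mapping of contig name -> sequence."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seq = {name: s.upper() for name, s in sequences.items()}

    @property
    def contigs(self) -> tuple[str, ...]:
        return tuple(self._seq)

    def contig_length(self, chrom: str) -> int:
        return len(self._seq[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seq:
            raise VariantIOError(f"unknown contig {chrom!r}")
        if start < 1 or end > len(self._seq[chrom]) or end < start:
            raise VariantIOError(
                f"fetch out of bounds: {chrom}:{start}-{end} "
                f"(length {len(self._seq[chrom])})"
            )
        return self._seq[chrom][start - 1 : end]


class FastaReference(ReferenceSequence):
    """Reference backed by an indexed FASTA file (pyfaidx)."""

    def __init__(self, path: str | os.PathLike):
        import pyfaidx

        self._fa = pyfaidx.Fasta(str(path), sequence_always_upper=True)

    @property
    def contigs(self) -> tuple[str, ...]:
        return tuple(self._fa.keys())

    def contig_length(self, chrom: str) -> int:
        return len(self._fa[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fa:
            raise VariantIOError(f"unknown contig {chrom!r}")
        if start < 1 or end > len(self._fa[chrom]) or end < start:
            raise VariantIOError(f"fetch out of bounds: {chrom}:{start}-{end}")
        return str(self._fa[chrom][start - 1 : end])


def load_reference(path: str | os.PathLike) -> FastaReference:
    return FastaReference(path)


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike, width: int = 70):
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF / TSV readers and writers
# ---------------------------------------------------------------------------


def _count_vcf_header_lines(path) -> int:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    n = 0
    with opener(path, "rt") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
    return n


def _iter_vcf_rows(path):
    """Yield (line_number, chrom, pos, ref, alts) from a VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    header_lines = _count_vcf_header_lines(path)
    for i, v in enumerate(vcf):
        yield header_lines + i + 1, v.CHROM, v.POS, v.REF.upper(), [
            a.upper() for a in v.ALT
        ]
    vcf.close()


def _iter_tsv_rows(path):
    """Yield (line_number, chrom, pos, ref, [alt]) from a headered TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise VariantIOError(
            f"{path}: TSV dialect requires columns {sorted(required)}"
        )
    for i, row in enumerate(df.itertuples(index=False)):
        yield i + 2, str(row.chrom), int(row.pos), str(row.ref).upper(), [
            str(row.alt).upper()
        ]


def _read_records(path, dialect, record_factory, on_error):
    if not Path(path).exists():
        raise FileNotFoundError(path)
    if dialect not in ("vcf", "tsv"):
        raise VariantIOError(f"unknown dialect {dialect!r}")
    rows = _iter_vcf_rows(path) if dialect == "vcf" else _iter_tsv_rows(path)
    out = RecordList()
    for line, chrom, pos, ref, alts in rows:
        try:
            if len(alts) != 1:
                raise VariantIOError(f"line {line}: expected exactly one ALT allele")
            out.append(record_factory(chrom, pos, ref, alts[0]))
        except VariantIOError as exc:
            if on_error == "raise":
                raise VariantIOError(f"{path} line {line}: {exc}") from None
            out.rejects.append(Reject(line, str(exc)))
    out.sort()
    return out


def read_substitutions(path, dialect: str = "vcf", on_error: str = "raise") -> RecordList:
    """Read single-base substitution records.

    Rows whose alleles are not single bases (indel territory) are errors; with
    ``on_error="collect"`` they are reported in ``result.rejects`` with their
    line numbers instead of raising.
    """
    return _read_records(path, dialect, SubstitutionRecord, on_error)


def read_indels(path, dialect: str = "vcf", on_error: str = "raise") -> RecordList:
    """Read left-anchored indel records (simple or complex)."""
    return _read_records(path, dialect, IndelRecord, on_error)


def write_vcf(records: Sequence, path, reference: ReferenceSequence | None = None,
              contig_lengths: Mapping[str, int] | None = None):
    """Write substitution or indel records as a minimal VCF 4.2 file."""
    lengths: dict[str, int] = {}
    if reference is not None:
        lengths = {c: reference.contig_length(c) for c in reference.contigs}
    if contig_lengths:
        lengths.update(contig_lengths)
    for r in records:
        lengths.setdefault(r.chrom, 2**29)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, ln in lengths.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(records):
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t.\n")


def read_rearrangements(path, on_error: str = "raise") -> RecordList:
    """Read breakpoint pairs from a BEDPE-like TSV.

    Columns: chrom1, pos1, chrom2, pos2 and optionally svclass. Positions are
    1-based breakpoint coordinates. Inter-chromosomal rows without a class are
    labelled translocation; intra-chromosomal rows without a class are errors.
    """
    if not Path(path).exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    required = ["chrom1", "pos1", "chrom2", "pos2"]
    if not set(required).issubset(df.columns):
        raise VariantIOError(f"{path}: requires columns {required}[,svclass]")
    has_class = "svclass" in df.columns
    out = RecordList()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            c1, p1 = str(row.chrom1), int(row.pos1)
            c2, p2 = str(row.chrom2), int(row.pos2)
            svclass = str(row.svclass) if has_class and not pd.isna(row.svclass) else None
            if svclass is None:
                if c1 != c2:
                    svclass = "translocation"
                else:
                    raise VariantIOError(
                        "intra-chromosomal row without an svclass label"
                    )
            out.append(RearrangementRecord(c1, p1, c2, p2, svclass))
        except VariantIOError as exc:
            if on_error == "raise":
                raise VariantIOError(f"{path} line {line}: {exc}") from None
            out.rejects.append(Reject(line, str(exc)))
    out.sort()
    return out


def write_rearrangements(records: Sequence[RearrangementRecord], path):
    with open(path, "w") as fh:
        fh.write("chrom1\tpos1\tchrom2\tpos2\tsvclass\n")
        for r in sorted(records):
            fh.write(f"{r.chrom1}\t{r.pos1}\t{r.chrom2}\t{r.pos2}\t{r.svclass}\n")


def write_tsv(records: Sequence, path):
    """Write substitutions or indels as the headered TSV dialect."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for r in sorted(records):
            fh.write(f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\n")


# ---------------------------------------------------------------------------
# parental subtraction
# ---------------------------------------------------------------------------


def subtract_parental(subclone_records: Sequence, parental_records: Sequence,
                      match_tolerance: int = 500) -> RecordList:
    """De novo mutations: subclone records with no match in the parental set.

    Substitutions and indels match on exact (chrom, pos, ref, alt).
    Rearrangements match when svclass and chromosomes agree and both
    breakpoints lie within ``match_tolerance`` bp (default 500, reflecting the
    breakpoint imprecision of split-read callers). The same operation filters
    parental clones against the bulk population: bulk is just another
    "parental" argument.
    """
    if not subclone_records:
        return RecordList()
    cls = mutation_class_of(list(subclone_records) + list(parental_records))
    if cls in ("substitution", "indel"):
        seen = {r.key for r in parental_records}
        return RecordList(r for r in subclone_records if r.key not in seen)

    by_group: dict = {}
    for p in parental_records:
        by_group.setdefault((p.chrom1, p.chrom2, p.svclass), []).append((p.pos1, p.pos2))
    out = RecordList()
    for r in subclone_records:
        candidates = by_group.get((r.chrom1, r.chrom2, r.svclass), [])
        matched = any(
            abs(r.pos1 - p1) <= match_tolerance and abs(r.pos2 - p2) <= match_tolerance
            for p1, p2 in candidates
        )
        if not matched:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# annotation tracks
# ---------------------------------------------------------------------------

TRACK_VOCABULARIES = {
    "strand": {"+", "-"},
    "replication": {"leading", "lagging"},
    "timing": {str(d) for d in range(1, 11)},
}


class DomainTrack:
    """Labelled genomic intervals (gene strand, replication orientation, or
    replication-timing decile). Internally half-open, 0-based."""

    def __init__(self, intervals: Iterable[tuple[str, int, int, str]],
                 vocabulary: set[str] | None = None):
        from intervaltree import IntervalTree

        self._trees: dict[str, "IntervalTree"] = {}
        self._lengths: dict[str, int] = {}
        for chrom, start, end, label in intervals:
            if end <= start:
                raise VariantIOError(
                    f"non-positive interval {chrom}:{start}-{end}"
                )
            if vocabulary is not None and label not in vocabulary:
                raise VariantIOError(
                    f"label {label!r} outside vocabulary {sorted(vocabulary)}"
                )
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end, label)
            self._lengths[label] = self._lengths.get(label, 0) + (end - start)

    @property
    def labels(self) -> set[str]:
        return set(self._lengths)

    def label_lengths(self) -> dict[str, int]:
        """Total genomic length covered by each label."""
        return dict(self._lengths)

    def intervals(self):
        """Yield (chrom, start, end, label) tuples, 0-based half-open."""
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                yield chrom, iv.begin, iv.end, iv.data

    def label_at(self, chrom: str, pos: int) -> str | None:
        """Label at a 1-based position; None if unannotated or conflicting."""
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        hits = {iv.data for iv in tree.at(pos - 1)}
        if len(hits) == 1:
            return hits.pop()
        return None  # unannotated, or overlapping conflicting annotations


def read_bed_track(path, vocabulary: str | set[str] | None = None) -> DomainTrack:
    """Read a BED4 file (0-based half-open) into a DomainTrack."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "label"], dtype=str)
    vocab = TRACK_VOCABULARIES.get(vocabulary, vocabulary) if vocabulary else None
    return DomainTrack(
        ((str(r.chrom), int(r.start), int(r.end), str(r.label))
         for r in df.itertuples(index=False)),
        vocabulary=vocab,
    )


def write_bed_track(intervals: Iterable[tuple[str, int, int, str]], path):
    with open(path, "w") as fh:
        for chrom, start, end, label in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


# ---------------------------------------------------------------------------
# signature catalogs
# ---------------------------------------------------------------------------


@dataclass
class SignatureCatalog:
    """A channel × signature matrix of non-negative weights, columns unit-sum."""

    taxonomy: ChannelTaxonomy
    names: list[str]
    matrix: np.ndarray  # shape (K, n_signatures)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.taxonomy.K, len(self.names)):
            raise VariantIOError(
                f"catalog matrix shape {self.matrix.shape} does not match "
                f"{self.taxonomy.K} channels x {len(self.names)} signatures"
            )
        if (self.matrix < 0).any():
            raise VariantIOError("signature weights must be non-negative")
        sums = self.matrix.sum(axis=0)
        if (sums <= 0).any():
            raise VariantIOError("signature column sums to zero")
        self.matrix = self.matrix / sums

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.taxonomy.labels),
                            columns=self.names)


def read_signature_catalog(path, taxonomy: str | ChannelTaxonomy) -> SignatureCatalog:
    """Load a tab-delimited channel × signature matrix.

    The first column must carry channel labels; they are harmonized to the
    canonical channel order and columns are renormalized to unit sum.
    """
    if isinstance(taxonomy, str):
        taxonomy = get_taxonomy(taxonomy)
    df = pd.read_csv(path, sep="\t", index_col=0)
    have, want = set(df.index.astype(str)), set(taxonomy.labels)
    if have != want:
        missing, extra = sorted(want - have), sorted(have - want)
        raise VariantIOError(
            f"{path}: channel labels do not match the {taxonomy.name} taxonomy "
            f"(missing {missing[:5]}, unexpected {extra[:5]})"
        )
    df = df.loc[list(taxonomy.labels)]
    return SignatureCatalog(taxonomy, [str(c) for c in df.columns], df.to_numpy())


def write_signature_catalog(catalog: SignatureCatalog, path):
    catalog.to_frame().to_csv(path, sep="\t", index_label="channel",
                              float_format="%.8g")
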