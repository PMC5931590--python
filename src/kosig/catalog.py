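"""Classification of mutations into channel taxonomies and assembly of
per-sample channel-count catalogs (the matrices M_p for parental clones and
M_s for subclones).

Substitutions follow the pyrimidine convention: a purine-reference mutation
and its trinucleotide context are reverse-complemented before labelling, so
every channel has the form ``X[R>A]Y`` with R in {C, T}.

Deletions are left-aligned against the reference before junction analysis and
receive exactly one label, with repeat-mediated taking precedence over
microhomology-mediated:

* repeat-mediated — at least one full additional copy of the deleted motif
  lies immediately 3' of the deletion;
* microhomology-mediated — the 5' end of the deleted motif shares >=1 bp but
  less than its full length with the sequence immediately 3' of the deletion
  (only defined for deletions of >=2 bp);
* otherwise "other deletion".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .taxonomy import (
    ChannelTaxonomy,
    PYRIMIDINES,
    get_taxonomy,
    revcomp,
)
from .variant_io import (
    IndelRecord,
    RearrangementRecord,
    Reject,
    ReferenceSequence,
    SubstitutionRecord,
    VariantIOError,
    mutation_class_of,
)


class ClassificationError(ValueError):
    """A record cannot be placed in any channel (caller excludes and logs)."""


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------


def classify_substitution(record: SubstitutionRecord,
                          reference: ReferenceSequence) -> str:
    """96-channel label of a substitution in pyrimidine context."""
    if record.pos < 2 or record.pos > reference.contig_length(record.chrom) - 1:
        raise ClassificationError(
            f"{record.chrom}:{record.pos}: flanking bases unavailable"
        )
    trinuc = reference.fetch(record.chrom, record.pos - 1, record.pos + 1)
    if trinuc[1] != record.ref:
        raise ClassificationError(
            f"{record.chrom}:{record.pos}: reference base is {trinuc[1]}, "
            f"record says {record.ref}"
        )
    if "N" in trinuc:
        raise ClassificationError(
            f"{record.chrom}:{record.pos}: N in trinucleotide context"
        )
    ref, alt = record.ref, record.alt
    if ref not in PYRIMIDINES:
        trinuc, ref, alt = revcomp(trinuc), revcomp(ref), revcomp(alt)
    return f"{trinuc[0]}[{ref}>{alt}]{trinuc[2]}"


def left_align_deletion(chrom: str, pos: int, deleted: str,
                        reference: ReferenceSequence) -> tuple[int, str]:
    """Left-align a deletion; returns (anchor_pos, deleted_motif).

    ``pos`` is the anchor coordinate (base before the deleted bases). The
    deletion is shifted left while the base preceding it equals its last base.
    """
    L = len(deleted)
    start = pos + 1  # first deleted base, 1-based
    while start > 2 and reference.fetch(chrom, start - 1, start - 1) == deleted[-1]:
        start -= 1
        deleted = reference.fetch(chrom, start, start + L - 1)
    return start - 1, deleted


def classify_indel(record: IndelRecord, reference: ReferenceSequence,
                   scan_window: int | None = None) -> str:
    """8-channel label of an indel record."""
    if record.is_complex:
        return "complex"
    if record.is_insertion:
        return "ins_1bp" if len(record.inserted) == 1 else "ins_ge2bp"

    deleted = record.deleted
    L = len(deleted)
    if scan_window is not None and scan_window < L:
        raise ClassificationError(f"scan_window {scan_window} < deletion length {L}")
    ref_base = reference.fetch(record.chrom, record.pos + 1, record.pos + L)
    if ref_base != deleted:
        raise ClassificationError(
            f"{record.chrom}:{record.pos}: deleted bases {deleted} do not match "
            f"reference {ref_base}"
        )
    anchor, deleted = left_align_deletion(record.chrom, record.pos, deleted, reference)

    # sequence immediately 3' of the (left-aligned) deletion
    start3 = anchor + L + 1
    end3 = min(start3 + L - 1, reference.contig_length(record.chrom))
    following = reference.fetch(record.chrom, start3, end3) if end3 >= start3 else ""

    if len(following) == L and following == deleted and "N" not in deleted:
        return "del_rep_1bp" if L == 1 else "del_rep_ge2bp"
    if L >= 2:
        mh = 0
        for a, b in zip(deleted, following):
            if a != b or a == "N":
                break
            mh += 1
        if 1 <= mh < L:
            return "del_mh_2bp" if L == 2 else "del_mh_ge3bp"
    return "del_other"


SV_BIN_EDGES = (1_000, 10_000, 1_000_000)


def classify_rearrangement(record: RearrangementRecord) -> str:
    """10-channel label of a rearrangement record.

    Intra-chromosomal spans below 1 kb are below the smallest size bin and
    raise ClassificationError (the caller routes them to the reject report).
    """
    if record.svclass == "translocation":
        return "translocation"
    span = record.span
    if span < SV_BIN_EDGES[0]:
        raise ClassificationError(
            f"{record.chrom1}:{record.pos1}-{record.pos2}: span {span} bp below "
            "the 1 kb calling resolution"
        )
    if span <= SV_BIN_EDGES[1]:
        size = "1-10kb"
    elif span <= SV_BIN_EDGES[2]:
        size = "10kb-1Mb"
    else:
        size = ">1Mb"
    return f"{record.svclass}_{size}"


def classify(record, reference: ReferenceSequence | None = None,
             scan_window: int | None = None) -> str:
    """Dispatch a record to the appropriate classifier."""
    if isinstance(record, SubstitutionRecord):
        return classify_substitution(record, reference)
    if isinstance(record, IndelRecord):
        return classify_indel(record, reference, scan_window)
    if isinstance(record, RearrangementRecord):
        return classify_rearrangement(record)
    raise TypeError(f"unsupported record type {type(record).__name__}")


# ---------------------------------------------------------------------------
# catalogs
# ---------------------------------------------------------------------------


@dataclass
class SampleCatalog:
    """Per-sample channel-count vector for one mutation class."""

    sample_id: str
    counts: np.ndarray
    role: str = "subclone"  # parental | subclone
    knockout: str | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError(f"negative channel count in sample {self.sample_id}")
        if self.role not in ("parental", "subclone"):
            raise ValueError(f"role must be parental or subclone, got {self.role!r}")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


class CatalogMatrix:
    """A set of SampleCatalogs sharing one channel taxonomy."""

    def __init__(self, taxonomy: str | ChannelTaxonomy,
                 samples: Sequence[SampleCatalog]):
        self.taxonomy = get_taxonomy(taxonomy) if isinstance(taxonomy, str) else taxonomy
        for s in samples:
            if s.counts.shape != (self.taxonomy.K,):
                raise ValueError(
                    f"sample {s.sample_id} has {s.counts.shape[0]} channels, "
                    f"taxonomy has {self.taxonomy.K}"
                )
        self.samples = list(samples)
        self.rejects: list[Reject] = []

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def counts(self) -> np.ndarray:
        """(K, n_samples) integer count matrix."""
        return np.stack([s.counts for s in self.samples], axis=1)

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def proportions(self) -> np.ndarray:
        """(K, n_samples) per-sample unit-sum profiles."""
        counts = self.counts.astype(float)
        totals = counts.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("cannot normalize a sample with zero total")
        return counts / totals

    def centroid(self) -> np.ndarray:
        """Centroid profile: mean of the per-sample normalized profiles."""
        return self.proportions().mean(axis=1)

    def centroid_counts(self) -> np.ndarray:
        """Mean channel-count vector across samples."""
        return self.counts.mean(axis=1)

    def pooled_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def subset(self, sample_ids: Sequence[str]) -> "CatalogMatrix":
        wanted = set(sample_ids)
        return CatalogMatrix(self.taxonomy,
                             [s for s in self.samples if s.sample_id in wanted])

    def __len__(self) -> int:
        return len(self.samples)

    # -- I/O: TSV with channels as rows (canonical order) and samples as columns

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.taxonomy.labels),
                            columns=self.sample_ids)

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("#class\t" + self.taxonomy.name + "\n")
            fh.write("#role\t" + "\t".join(s.role for s in self.samples) + "\n")
            fh.write("#knockout\t" + "\t".join(s.knockout or "." for s in self.samples)
                     + "\n")
            self.to_frame().to_csv(fh, sep="\t", index_label="channel")

    @classmethod
    def from_tsv(cls, path) -> "CatalogMatrix":
        meta: dict[str, list[str]] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, *vals = line[1:].rstrip("\n").split("\t")
                meta[key] = vals
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t", index_col=0)
        if "class" not in meta:
            raise VariantIOError(f"{path}: missing '#class' header line")
        taxonomy = get_taxonomy(meta["class"][0])
        if list(df.index) != list(taxonomy.labels):
            raise VariantIOError(
                f"{path}: channel rows do not match the canonical "
                f"{taxonomy.name} order"
            )
        n = df.shape[1]
        roles = meta.get("role", ["subclone"] * n)
        knockouts = meta.get("knockout", ["."] * n)
        samples = [
            SampleCatalog(str(col), df[col].to_numpy(), role=roles[j],
                          knockout=None if knockouts[j] == "." else knockouts[j])
            for j, col in enumerate(df.columns)
        ]
        return cls(taxonomy, samples)


def build_catalog(records_by_sample: Mapping[str, Sequence],
                  taxonomy: str | ChannelTaxonomy,
                  reference: ReferenceSequence | None = None,
                  roles: Mapping[str, str] | None = None,
                  knockouts: Mapping[str, str] | None = None,
                  scan_window: int | None = None) -> CatalogMatrix:
    """Classify each sample's records and assemble a CatalogMatrix.

    Records that cannot be classified (N context, sub-resolution spans) are
    excluded and reported in ``result.rejects``; per sample, the channel sum
    equals the number of classifiable records. Empty samples yield zero
    vectors. When building the subclone matrix M_s the records must already be
    de novo (parental-subtracted).
    """
    taxonomy = get_taxonomy(taxonomy) if isinstance(taxonomy, str) else taxonomy
    samples, rejects = [], []
    for sample_id, records in records_by_sample.items():
        if records and mutation_class_of(records) != taxonomy.name:
            raise VariantIOError(
                f"sample {sample_id}: records are not {taxonomy.name}s"
            )
        counts = np.zeros(taxonomy.K, dtype=np.int64)
        for rec in records:
            try:
                counts[taxonomy.index(classify(rec, reference, scan_window))] += 1
            except ClassificationError as exc:
                rejects.append(Reject(None, f"{sample_id}: {exc}"))
        samples.append(SampleCatalog(
            sample_id, counts,
            role=(roles or {}).get(sample_id, "subclone"),
            knockout=(knockouts or {}).get(sample_id),
        ))
    matrix = CatalogMatrix(taxonomy, samples)
    matrix.rejects = rejects
    return matrix
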