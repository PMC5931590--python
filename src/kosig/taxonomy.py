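"""Channel taxonomies for the three mutation classes.

Every catalog, signature and simulation in this package is expressed over one
of three fixed channel vocabularies:

* substitutions: 96 channels — 6 pyrimidine substitution types (C>A, C>G,
  C>T, T>A, T>C, T>G) crossed with the 4 possible 5' and 4 possible 3'
  flanking bases;
* indels: 8 channels — insertions split at 1 bp vs >=2 bp, deletions split by
  junction character (repeat-mediated, microhomology-mediated, other) and
  length, plus complex indels;
* rearrangements: 10 channels — deletions, inversions and tandem duplications
  in three size bins (1–10 kb, 10 kb–1 Mb, >1 Mb) plus translocations.

The label strings defined here are canonical: catalog files, signature files
and reports all use them, in this order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

BASES = ("A", "C", "G", "T")
PYRIMIDINES = ("C", "T")
SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class ChannelTaxonomy:
    """A fixed, ordered channel vocabulary for one mutation class."""

    name: str
    labels: tuple[str, ...]
    _index: dict = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self):
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.labels)})

    @property
    def K(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown {self.name} channel label: {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __len__(self) -> int:
        return len(self.labels)


def _substitution_labels() -> tuple[str, ...]:
    return tuple(
        f"{five}[{sub}]{three}"
        for sub in SUBSTITUTION_TYPES
        for five in BASES
        for three in BASES
    )


SUBSTITUTION_96 = ChannelTaxonomy("substitution", _substitution_labels())

INDEL_8 = ChannelTaxonomy(
    "indel",
    (
        "ins_1bp",
        "ins_ge2bp",
        "del_mh_2bp",
        "del_mh_ge3bp",
        "del_rep_1bp",
        "del_rep_ge2bp",
        "del_other",
        "complex",
    ),
)

SV_CLASSES = ("deletion", "inversion", "tandem-duplication")
SV_SIZE_BINS = ("1-10kb", "10kb-1Mb", ">1Mb")

REARRANGEMENT_10 = ChannelTaxonomy(
    "rearrangement",
    tuple(f"{cls}_{b}" for cls in SV_CLASSES for b in SV_SIZE_BINS) + ("translocation",),
)

TAXONOMIES = {t.name: t for t in (SUBSTITUTION_96, INDEL_8, REARRANGEMENT_10)}


def get_taxonomy(name: str) -> ChannelTaxonomy:
    """Look up a taxonomy by mutation-class name."""
    try:
        return TAXONOMIES[name]
    except KeyError:
        raise KeyError(
            f"unknown mutation class {name!r}; expected one of {sorted(TAXONOMIES)}"
        ) from None


def substitution_label(five: str, ref: str, alt: str, three: str) -> str:
    """Channel label for a pyrimidine-context substitution."""
    if ref not in PYRIMIDINES:
        raise ValueError(f"reference base must be a pyrimidine, got {ref!r}")
    return f"{five}[{ref}>{alt}]{three}"
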