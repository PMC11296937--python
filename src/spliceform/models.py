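"""Core domain types shared across the pipeline stages.

Coordinate conventions: genomic coordinates are 1-based inclusive (GTF
convention); protein residue positions are 1-based. Strand is "+" or "-".
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Sentinel returned by coordinate maps for residues that have no image
#: on the other sequence (deleted / inserted positions).
GAP = -1

EVENT_TYPES = ("SE", "MXE", "A5SS", "A3SS", "RI")
FORMS = ("inclusion", "skip")
CHAMBERS = ("atrium", "ventricle")


@dataclass(frozen=True)
class Transcript:
    """One transcript of a gene model.

    ``exons`` are ordered 5'->3' in transcription order (so for "-" strand
    genes the first exon has the largest genomic coordinates). Each exon is
    a ``(start, end)`` 1-based inclusive genomic interval.
    """

    transcript_id: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int          # genomic coordinate of the first coding base
    frame_offset: int = 0   # annotated frame offset in {0, 1, 2}

    def __post_init__(self) -> None:
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"frame_offset must be 0/1/2, got {self.frame_offset}")
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"exon start {s} > end {e} in {self.transcript_id}")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing event with inclusion/skip read support.

    Interval semantics by event type (all 1-based inclusive genomic):

    * ``SE``   – ``target1`` is the cassette exon (present in the inclusion
      form, absent in the skip form).
    * ``MXE``  – ``target1`` and ``target2`` are the mutually exclusive
      exons; the inclusion form uses ``target1``, the skip form ``target2``.
    * ``A5SS`` / ``A3SS`` – ``target1`` is the long and ``target2`` the
      short version of the exon with the alternative splice site; inclusion
      uses the long form.
    * ``RI``   – ``target1`` is the retained intron (between ``upstream``
      and ``downstream``); the inclusion form retains it.
    """

    event_id: str
    gene_id: str
    event_type: str
    upstream: tuple[int, int]
    downstream: tuple[int, int]
    target1: tuple[int, int]
    target2: Optional[tuple[int, int]]
    inclusion_reads: int
    skip_reads: int

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r}")
        if self.inclusion_reads < 0 or self.skip_reads < 0:
            raise ValueError(
                f"negative read count on event {self.event_id}: "
                f"inclusion={self.inclusion_reads} skip={self.skip_reads}"
            )

    @property
    def total_reads(self) -> int:
        return self.inclusion_reads + self.skip_reads


@dataclass
class TranslatedIsoform:
    """An in-silico translated protein isoform with tier label."""

    isoform_id: str
    gene_id: str
    sequence: str
    source_event: str
    form: str
    tier: int | str = 1               # 1 or "rejected"
    rejection_reason: Optional[str] = None   # frameshift | premature_stop | no_frame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.tier == 1) != (self.rejection_reason is None):
            raise ValueError("tier 1 iff rejection_reason is absent")
        if self.tier == 1 and "*" in self.sequence:
            raise ValueError("tier-1 sequence contains internal stop")


@dataclass(frozen=True)
class VariantRegion:
    """A contiguous difference between canonical and alternative isoform.

    Intervals are 1-based inclusive residue ranges on the respective
    sequences; ``None`` marks the empty side of a pure indel. ``terminal``
    flags regions touching either sequence terminus (N/C truncations).
    """

    kind: str                                   # insertion | deletion | substitution
    canonical_interval: Optional[tuple[int, int]]
    alternative_interval: Optional[tuple[int, int]]
    terminal: bool = False

    @property
    def length(self) -> int:
        spans = []
        for iv in (self.canonical_interval, self.alternative_interval):
            spans.append(0 if iv is None else iv[1] - iv[0] + 1)
        return max(spans)


@dataclass
class IsoformPair:
    """Canonical/alternative pair with alignment and variant regions."""

    canonical_id: str
    alternative_id: str
    canonical_seq: str
    alternative_seq: str
    aligned_canonical: str = ""
    aligned_alternative: str = ""
    variant_regions: list[VariantRegion] = field(default_factory=list)
    simple_variant: Optional[bool] = None

    def validate_alignment(self) -> None:
        if len(self.aligned_canonical) != len(self.aligned_alternative):
            raise ValueError("alignment rows differ in length")
        if self.aligned_canonical.replace("-", "") != self.canonical_seq:
            raise ValueError("canonical alignment row does not de-gap to input")
        if self.aligned_alternative.replace("-", "") != self.alternative_seq:
            raise ValueError("alternative alignment row does not de-gap to input")


@dataclass
class PeptideRecord:
    sequence: str
    parent_ids: frozenset[str]
    uniqueness: str = "shared"          # unique | razor | shared
    razor_parent: Optional[str] = None
    junction_spanning: bool = False
    intensities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.uniqueness == "unique" and len(self.parent_ids) != 1:
            raise ValueError("unique peptide must have exactly one parent")
        if self.razor_parent is not None and self.razor_parent not in self.parent_ids:
            raise ValueError("razor_parent must be a member of parent_ids")


@dataclass(frozen=True)
class SampleDesign:
    sample_id: str
    chamber: str
    donor: str

    def __post_init__(self) -> None:
        if self.chamber not in CHAMBERS:
            raise ValueError(f"chamber must be one of {CHAMBERS}, got {self.chamber!r}")


@dataclass
class DifferentialResult:
    feature_id: str
    log2fc: float
    t_stat: float
    p_value: float
    adj_p: float = float("nan")
    n_peptides_used: int = 0
    quant_mode: str = "unique"


@dataclass
class ResidueTrack:
    protein_id: str
    track_name: str
    scores: "list[float]"
    idr_mask: Optional[list[bool]] = None

    def __post_init__(self) -> None:
        for s in self.scores:
            if not (0.0 <= s <= 1.0):
                raise ValueError(
                    f"track {self.track_name} on {self.protein_id}: score {s} outside [0,1]"
                )
        if self.idr_mask is not None and len(self.idr_mask) != len(self.scores):
            raise ValueError("idr_mask length differs from scores length")


@dataclass(frozen=True)
class PtmAnnotation:
    protein_id: str
    site: int                      # 1-based residue position
    ptm_type: str = "phosphorylation"
    source: str = ""
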