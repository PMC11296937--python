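"""Splice-junction collation, filtering, and in-silico translation.

This stage turns gene models plus junction read-count tables into tier-1
non-canonical protein isoforms: junctions passing a total-read filter are
spliced into event-specific transcripts, translated in the annotated
reading frame, and kept only when translation completes without a
frameshift or premature termination codon.
"""
from __future__ import annotations

import collections
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .errors import ConfigurationError, StructuralError, ValidationError
from .models import EVENT_TYPES, GeneModel, SpliceEvent, TranslatedIsoform, Transcript

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Forward codon table (standard genetic code); stops absent from the map.
_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)

REQUIRED_COLUMNS = (
    "event_id",
    "gene_id",
    "event_type",
    "upstream_start",
    "upstream_end",
    "downstream_start",
    "downstream_end",
    "target1_start",
    "target1_end",
    "inclusion_reads",
    "skip_reads",
)
OPTIONAL_COLUMNS = ("target2_start", "target2_end")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# junction table parsing & filtering
# ---------------------------------------------------------------------------

def parse_junction_table(path) -> list[SpliceEvent]:
    """Parse a junction TSV into :class:`SpliceEvent` records.

    The dialect is a flat TSV with one row per event; see
    :data:`REQUIRED_COLUMNS`. ``target2_*`` columns are required only for
    MXE/A5SS/A3SS rows and may be blank elsewhere.

    Raises
    ------
    ConfigurationError
        if a required column is missing.
    ValidationError
        naming the offending line for malformed rows (negative read
        counts, unknown event types, non-integer coordinates).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"junction table {path} missing required column(s): {missing}")

    events: list[SpliceEvent] = []
    problems: list[str] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line_no = idx + 2  # 1-based, after header
        try:
            event_type = row.event_type
            if event_type not in EVENT_TYPES:
                raise ValueError(f"unknown event_type {event_type!r}")
            inclusion_reads = int(row.inclusion_reads)
            skip_reads = int(row.skip_reads)
            if inclusion_reads < 0 or skip_reads < 0:
                raise ValueError("negative read count")
            target2 = None
            t2s = getattr(row, "target2_start", "")
            t2e = getattr(row, "target2_end", "")
            if t2s != "" and t2e != "":
                target2 = (int(t2s), int(t2e))
            elif event_type in ("MXE", "A5SS", "A3SS"):
                raise ValueError(f"{event_type} row requires target2 coordinates")
            events.append(
                SpliceEvent(
                    event_id=row.event_id,
                    gene_id=row.gene_id,
                    event_type=event_type,
                    upstream=(int(row.upstream_start), int(row.upstream_end)),
                    downstream=(int(row.downstream_start), int(row.downstream_end)),
                    target1=(int(row.target1_start), int(row.target1_end)),
                    target2=target2,
                    inclusion_reads=inclusion_reads,
                    skip_reads=skip_reads,
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"line {line_no}: {exc}")
    if problems:
        raise ValidationError("malformed junction rows: " + "; ".join(problems))
    return events


def filter_junctions(events: Sequence[SpliceEvent], min_total_reads: int = 16) -> list[SpliceEvent]:
    """Keep events whose inclusion + skip read total reaches the threshold.

    The boundary is inclusive: an event with exactly ``min_total_reads``
    total reads is retained. Order is preserved.
    """
    if min_total_reads < 0:
        raise ValueError("min_total_reads must be >= 0")
    return [e for e in events if e.total_reads >= min_total_reads]


def filter_junctions_mixture(
    events: Sequence[SpliceEvent], contaminant_quantile: float = 0.95
) -> list[SpliceEvent]:
    """Optional two-component mixture filter on log1p total read counts.

    Fits a two-component Gaussian mixture to log1p(total reads) and keeps
    events whose posterior probability of the high-read component exceeds
    the complement of ``contaminant_quantile``. Not the default path; the
    fixed-threshold :func:`filter_junctions` is.
    """
    import numpy as np
    from scipy import stats

    totals = np.array([e.total_reads for e in events], dtype=float)
    if len(totals) < 10:
        return list(events)
    x = np.log1p(totals)
    # two-component EM on 1-D Gaussians, deterministic quantile init
    mu = np.array([np.quantile(x, 0.1), np.quantile(x, 0.9)])
    sd = np.array([x.std() or 1.0, x.std() or 1.0])
    w = np.array([0.5, 0.5])
    for _ in range(200):
        dens = np.stack([w[k] * stats.norm.pdf(x, mu[k], max(sd[k], 1e-3)) for k in range(2)])
        resp = dens / np.maximum(dens.sum(axis=0), 1e-300)
        w = resp.mean(axis=1)
        mu_new = (resp * x).sum(axis=1) / np.maximum(resp.sum(axis=1), 1e-12)
        sd = np.sqrt((resp * (x - mu_new[:, None]) ** 2).sum(axis=1) / np.maximum(resp.sum(axis=1), 1e-12))
        if np.max(np.abs(mu_new - mu)) < 1e-10:
            mu = mu_new
            break
        mu = mu_new
    hi = int(np.argmax(mu))
    dens = np.stack([w[k] * stats.norm.pdf(x, mu[k], max(sd[k], 1e-3)) for k in range(2)])
    post_hi = dens[hi] / np.maximum(dens.sum(axis=0), 1e-300)
    keep = post_hi > (1.0 - contaminant_quantile)
    return [e for e, k in zip(events, keep) if k]


# ---------------------------------------------------------------------------
# transcript splicing
# ---------------------------------------------------------------------------

def _event_middle(event: SpliceEvent, form: str) -> list[tuple[int, int]]:
    if form not in ("inclusion", "skip"):
        raise ValueError(f"form must be inclusion/skip, got {form!r}")
    t = event.event_type
    if t == "SE":
        return [event.target1] if form == "inclusion" else []
    if t == "MXE":
        return [event.target1] if form == "inclusion" else [event.target2]
    if t in ("A5SS", "A3SS"):
        return [event.target1] if form == "inclusion" else [event.target2]
    if t == "RI":
        return [event.target1] if form == "inclusion" else []
    raise AssertionError(t)


def _check_topology(event: SpliceEvent) -> None:
    us, ue = event.upstream
    ds, de = event.downstream
    if not ue < ds:
        raise StructuralError(f"event {event.event_id}: upstream must precede downstream genomically")
    intervals = [event.target1] + ([event.target2] if event.target2 else [])
    for s, e in intervals:
        if not (ue < s <= e < ds):
            raise StructuralError(
                f"event {event.event_id}: target ({s},{e}) not strictly between flanks"
            )
    if event.event_type == "RI":
        if event.target1 != (ue + 1, ds - 1):
            raise StructuralError(
                f"event {event.event_id}: RI target must span the full intron "
                f"({ue + 1},{ds - 1}), got {event.target1}"
            )
    if event.event_type in ("A5SS", "A3SS"):
        l, s = event.target1, event.target2
        if not (l[0] <= s[0] and s[1] <= l[1] and l != s and (l[0] == s[0] or l[1] == s[1])):
            raise StructuralError(
                f"event {event.event_id}: {event.event_type} short form must nest in the "
                "long form sharing one boundary"
            )


def _select_transcript(model: GeneModel, event: SpliceEvent) -> Transcript:
    """First transcript whose exon set contains both flanking exons."""
    for tx in model.transcripts:
        exset = set(tx.exons)
        if event.upstream in exset and event.downstream in exset:
            return tx
    raise StructuralError(
        f"event {event.event_id}: no transcript of {model.gene_id} contains both "
        f"flanking exons {event.upstream} and {event.downstream}"
    )


def spliced_exons(model: GeneModel, event: SpliceEvent, form: str) -> list[tuple[int, int]]:
    """Genomic-ascending exon intervals of the event-specific transcript.

    Transcript exons lying strictly between the event's flanks are replaced
    by the event form's own middle exons; everything outside the flanks is
    inherited from the transcript unchanged.
    """
    _check_topology(event)
    tx = _select_transcript(model, event)
    asc = sorted(tx.exons)
    ui = asc.index(event.upstream)
    di = asc.index(event.downstream)
    if ui > di:
        raise StructuralError(f"event {event.event_id}: flank order inconsistent with transcript")
    middle = _event_middle(event, form)
    new = asc[: ui + 1] + middle + asc[di:]
    if event.event_type == "RI" and form == "inclusion":
        # upstream + intron + downstream are one contiguous exon
        new = asc[:ui] + [(event.upstream[0], event.downstream[1])] + asc[di + 1:]
    return new


def _mature_sequence(genome: Mapping[str, str], chrom: str, strand: str,
                     exons_asc: Sequence[tuple[int, int]]) -> str:
    try:
        chrom_seq = genome[chrom]
    except KeyError:
        raise StructuralError(f"chromosome {chrom!r} absent from genome") from None
    parts = [str(chrom_seq[s - 1 : e]).upper() for s, e in exons_asc]
    joined = "".join(parts)
    return reverse_complement(joined) if strand == "-" else joined


def _transcript_offset(strand: str, exons_asc: Sequence[tuple[int, int]], gpos: int) -> int:
    """0-based offset of genomic position ``gpos`` in the mature transcript."""
    order = exons_asc if strand == "+" else list(reversed(exons_asc))
    off = 0
    for s, e in order:
        if s <= gpos <= e:
            return off + (gpos - s if strand == "+" else e - gpos)
        off += e - s + 1
    raise StructuralError(f"position {gpos} not exonic in the spliced form")


def splice_transcript(
    model: GeneModel,
    event: SpliceEvent,
    form: str,
    genome: Mapping[str, str],
) -> tuple[str, int]:
    """Return the event-form coding sequence and its annotated frame offset.

    The returned nucleotide string starts at the transcript's annotated CDS
    start and runs to the 3' end of the mature (spliced) transcript,
    reverse-complemented for "-"-strand genes. For RI inclusion forms the
    retained intron sequence is part of the product.
    """
    tx = _select_transcript(model, event)
    exons = spliced_exons(model, event, form)
    mature = _mature_sequence(genome, model.chromosome, model.strand, exons)
    cds_off = _transcript_offset(model.strand, exons, tx.cds_start)
    return mature[cds_off:], tx.frame_offset


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranslationResult:
    protein: str
    stop_found: bool          # a stop codon terminated translation
    stop_codon_index: Optional[int]   # codon index (0-based) of the stop
    trailing_partial: bool    # sequence ended mid-codon (frameshift flag)


def translate_in_frame(cds: str, frame_offset: int = 0, n_policy: str = "error") -> TranslationResult:
    """Translate ``cds`` from ``frame_offset`` to the first stop codon.

    ``n_policy`` controls ambiguous bases: ``"error"`` rejects any non-ACGT
    symbol; ``"x"`` translates codons containing N as ``X`` (other symbols
    still reject).
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    seq = cds.upper()
    allowed = set("ACGTN") if n_policy == "x" else set("ACGT")
    bad = set(seq) - allowed
    if bad:
        raise ValidationError(f"invalid nucleotide symbol(s) {sorted(bad)} in sequence")
    body = seq[frame_offset:]
    if len(body) < 3:
        raise ValidationError("sequence shorter than one codon after frame offset")
    protein = []
    stop_idx: Optional[int] = None
    n_codons = len(body) // 3
    for i in range(n_codons):
        codon = body[3 * i : 3 * i + 3]
        if codon in _STOP_CODONS:
            stop_idx = i
            break
        if "N" in codon:
            protein.append("X")
        else:
            protein.append(_CODON_TABLE[codon])
    return TranslationResult(
        protein="".join(protein),
        stop_found=stop_idx is not None,
        stop_codon_index=stop_idx,
        trailing_partial=(stop_idx is None and len(body) % 3 != 0),
    )


# ---------------------------------------------------------------------------
# tier classification
# ---------------------------------------------------------------------------

def _form_delta(tx: Transcript, event: SpliceEvent, form: str) -> int:
    """Nucleotide-length change of the event form vs the reference transcript."""
    asc = sorted(tx.exons)
    ui = asc.index(event.upstream)
    di = asc.index(event.downstream)
    ref_middle = sum(e - s + 1 for s, e in asc[ui + 1 : di])
    new_middle = sum(e - s + 1 for s, e in _event_middle(event, form))
    return new_middle - ref_middle


def classify_and_emit(
    model: GeneModel,
    event: SpliceEvent,
    genome: Mapping[str, str],
    canonical_seqs: Optional[Mapping[str, str]] = None,
    n_policy: str = "error",
) -> list[TranslatedIsoform]:
    """Translate both event forms and assign tier labels.

    A form is tier 1 when the annotated-frame translation reaches the stop
    codon mapped from the reference transcript without a frameshift
    (event length change not divisible by 3) or an earlier, premature stop.
    Forms whose protein equals the gene's supplied canonical sequence are
    labelled ``canonical_redundant`` and are not tier-1 non-canonical
    output. Rejected forms carry a ``rejection_reason``.
    """
    tx = _select_transcript(model, event)
    ref_cds = splice_transcript_reference(model, tx, genome)
    ref = translate_in_frame(ref_cds, tx.frame_offset, n_policy=n_policy)
    if not ref.stop_found:
        raise StructuralError(
            f"gene {model.gene_id}: reference transcript {tx.transcript_id} has no "
            "in-frame stop codon; annotation unusable"
        )
    out: list[TranslatedIsoform] = []
    for form in ("inclusion", "skip"):
        iso = _classify_form(model, tx, event, form, genome, ref, canonical_seqs, n_policy)
        out.append(iso)
    return out


def splice_transcript_reference(model: GeneModel, tx: Transcript, genome: Mapping[str, str]) -> str:
    """Coding sequence of the unmodified transcript (annotation as-is)."""
    exons = sorted(tx.exons)
    mature = _mature_sequence(genome, model.chromosome, model.strand, exons)
    cds_off = _transcript_offset(model.strand, exons, tx.cds_start)
    return mature[cds_off:]


def _classify_form(model, tx, event, form, genome, ref: TranslationResult,
                   canonical_seqs, n_policy) -> TranslatedIsoform:
    base = dict(
        isoform_id=f"{model.gene_id}|{event.event_id}|{form}",
        gene_id=model.gene_id,
        source_event=event.event_id,
        form=form,
        provenance=[event.event_id],
    )
    try:
        cds, frame = splice_transcript(model, event, form, genome)
    except StructuralError:
        if _cds_start_lost(model, tx, event, form):
            return TranslatedIsoform(sequence="", tier="rejected",
                                     rejection_reason="no_frame", **base)
        raise
    if len(cds) - frame < 3:
        return TranslatedIsoform(sequence="", tier="rejected",
                                 rejection_reason="no_frame", **base)
    delta = _form_delta(tx, event, form)
    res = translate_in_frame(cds, frame, n_policy=n_policy)
    if delta % 3 != 0:
        return TranslatedIsoform(sequence=res.protein, tier="rejected",
                                 rejection_reason="frameshift", **base)
    expected_len = len(ref.protein) + delta // 3
    if not res.stop_found or res.trailing_partial:
        return TranslatedIsoform(sequence=res.protein, tier="rejected",
                                 rejection_reason="frameshift", **base)
    if len(res.protein) < expected_len:
        return TranslatedIsoform(sequence=res.protein, tier="rejected",
                                 rejection_reason="premature_stop", **base)
    if canonical_seqs is not None and canonical_seqs.get(model.gene_id) == res.protein:
        return TranslatedIsoform(sequence=res.protein, tier="rejected",
                                 rejection_reason="canonical_redundant", **base)
    return TranslatedIsoform(sequence=res.protein, tier=1, rejection_reason=None, **base)


def _cds_start_lost(model, tx, event, form) -> bool:
    from .errors import StructuralError as _SE
    try:
        exons = spliced_exons(model, event, form)
        _transcript_offset(model.strand, exons, tx.cds_start)
        return False
    except _SE:
        return True


# ---------------------------------------------------------------------------
# FASTA emission
# ---------------------------------------------------------------------------

def write_isoform_fasta(
    isoforms: Iterable[TranslatedIsoform],
    path,
    event_coords: Optional[Mapping[str, int]] = None,
    width: int = 60,
) -> list[TranslatedIsoform]:
    """Write tier-1 isoforms as a protein FASTA with -J numbering.

    Within each gene, isoforms are numbered ``-J1, -J2, ...`` in ascending
    genomic-coordinate order of their source events (``event_coords`` maps
    event_id to its sort coordinate; insertion order is used when absent).
    Identical sequences within a gene collapse to a single record whose
    description lists every contributing event. Headers are
    ``<gene>-J<n> <event_id(s)> <form>``.
    """
    tier1 = [iso for iso in isoforms if iso.tier == 1]
    by_gene: dict[str, list[TranslatedIsoform]] = collections.defaultdict(list)
    for iso in tier1:
        by_gene[iso.gene_id].append(iso)

    records: list[TranslatedIsoform] = []
    for gene_id in sorted(by_gene):
        group = by_gene[gene_id]
        if event_coords is not None:
            group.sort(key=lambda i: (event_coords.get(i.source_event, 0),
                                      i.source_event, i.form))
        # dedup on exact sequence, merging provenance
        seen: dict[str, TranslatedIsoform] = {}
        ordered: list[TranslatedIsoform] = []
        for iso in group:
            if iso.sequence in seen:
                keeper = seen[iso.sequence]
                for ev in iso.provenance:
                    if ev not in keeper.provenance:
                        keeper.provenance.append(ev)
            else:
                kept = replace(iso, provenance=list(iso.provenance))
                seen[iso.sequence] = kept
                ordered.append(kept)
        for n, iso in enumerate(ordered, start=1):
            iso.isoform_id = f"{gene_id}-J{n}"
            records.append(iso)

    ids = [r.isoform_id for r in records]
    if len(ids) != len(set(ids)):
        dupes = [i for i, c in collections.Counter(ids).items() if c > 1]
        raise ValidationError(f"duplicate isoform ids: {dupes}")

    with open(path, "w") as fh:
        for iso in records:
            fh.write(f">{iso.isoform_id} {','.join(iso.provenance)} {iso.form}\n")
            for i in range(0, len(iso.sequence), width):
                fh.write(iso.sequence[i : i + width] + "\n")
    return records
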