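"""Canonical-vs-alternative isoform alignment and variant-region extraction.

Pairs are aligned globally with affine gap penalties and free end gaps, so
N-/C-terminal truncations appear as terminal variant regions rather than
forcing internal gaps. Gap runs are post-normalized to their leftmost
score-neutral placement for reproducibility.
"""
from __future__ import annotations

from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ContractError
from .models import GAP, IsoformPair, VariantRegion

_AA = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")


def _make_aligner(gap_open: int = 11, gap_extend: int = 1) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # Biopython charges open_gap_score on the first gap column, so a
    # length-L gap costs open + (L-1)*extend; shift to match the
    # "existence + per-residue" convention (length-L gap = open + L*extend).
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    aligner.mode = "global"
    return aligner


_DEFAULT_ALIGNER = _make_aligner()


def _left_normalize(row_a: str, row_b: str) -> tuple[str, str]:
    """Shift every gap run to its leftmost score-neutral position.

    A gap run in one row can move one column left whenever the residue it
    would displace equals the residue at its right end on the *other* row,
    which leaves the aligned pairs, and hence the score, unchanged.
    """
    a = list(row_a)
    b = list(row_b)

    def shift(g: list[str], other: list[str]) -> bool:
        moved = False
        i = 0
        n = len(g)
        while i < n:
            if g[i] != "-":
                i += 1
                continue
            j = i
            while j < n and g[j] == "-":
                j += 1
            # run is [i, j); try moving it left while neutral
            k = i
            while k > 0 and g[k - 1] != "-" and other[k - 1] == other[j - 1] \
                    and other[j - 1] != "-":
                # move residue at k-1 to position j-1
                g[j - 1] = g[k - 1]
                g[k - 1] = "-"
                k -= 1
                j -= 1
                moved = True
            i = max(j, i + 1)
        return moved

    shift(a, b)
    shift(b, a)
    return "".join(a), "".join(b)


def align_isoform_pair(
    canonical_seq: str,
    alternative_seq: str,
    canonical_id: str = "canonical",
    alternative_id: str = "alternative",
    aligner: Optional[Align.PairwiseAligner] = None,
) -> IsoformPair:
    """Align a canonical/alternative pair and return an :class:`IsoformPair`.

    Scoring is BLOSUM62 with affine gaps (open 11, extend 1) and free end
    gaps. Ties are resolved deterministically, preferring leftmost gap
    placement.
    """
    if not canonical_seq or not alternative_seq:
        raise ContractError("both sequences must be non-empty")
    for name, seq in (("canonical", canonical_seq), ("alternative", alternative_seq)):
        bad = set(seq.upper()) - _AA
        if bad:
            raise ContractError(f"{name} sequence contains non-amino-acid symbols {sorted(bad)}")
    canonical_seq = canonical_seq.upper()
    alternative_seq = alternative_seq.upper()
    al = (aligner or _DEFAULT_ALIGNER).align(canonical_seq, alternative_seq)[0]
    row_c, row_a = str(al[0]), str(al[1])
    row_c, row_a = _left_normalize(row_c, row_a)
    pair = IsoformPair(
        canonical_id=canonical_id,
        alternative_id=alternative_id,
        canonical_seq=canonical_seq,
        alternative_seq=alternative_seq,
        aligned_canonical=row_c,
        aligned_alternative=row_a,
    )
    pair.validate_alignment()
    pair.variant_regions = extract_variant_regions(pair)
    pair.simple_variant = classify_simple_variant(pair)
    return pair


def extract_variant_regions(pair: IsoformPair, merge_gap: int = 0) -> list[VariantRegion]:
    """Turn alignment columns into maximal variant regions.

    Maximal runs of gap columns become insertions (gap in the canonical
    row) or deletions (gap in the alternative row); runs of mismatched
    residue pairs become substitutions. Adjacent regions separated by
    fewer than ``merge_gap`` matched columns merge into one substitution
    region. Regions touching either alignment end are flagged terminal.
    """
    rc, ra = pair.aligned_canonical, pair.aligned_alternative
    if not rc:
        raise ContractError("alignment not present on pair")
    n = len(rc)

    # column classes: M match, S substitution, I insertion (gap in canonical),
    # D deletion (gap in alternative)
    classes = []
    for x, y in zip(rc, ra):
        if x == "-" and y == "-":
            raise ContractError("double-gap alignment column")
        if x == "-":
            classes.append("I")
        elif y == "-":
            classes.append("D")
        elif x == y:
            classes.append("M")
        else:
            classes.append("S")

    # raw runs of non-M columns
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if classes[i] == "M":
            i += 1
            continue
        j = i
        while j < n and classes[j] != "M":
            j += 1
        runs.append((i, j))
        i = j

    # merge runs separated by < merge_gap matched columns
    if merge_gap > 0 and len(runs) > 1:
        merged = [runs[0]]
        for s, e in runs[1:]:
            ps, pe = merged[-1]
            if s - pe < merge_gap:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        runs = merged

    # cumulative residue counts for interval conversion
    def residue_interval(row: str, start: int, end: int) -> Optional[tuple[int, int]]:
        before = sum(1 for c in row[:start] if c != "-")
        inside = sum(1 for c in row[start:end] if c != "-")
        if inside == 0:
            return None
        return (before + 1, before + inside)

    regions: list[VariantRegion] = []
    for s, e in runs:
        block = classes[s:e]
        has_i = "I" in block
        has_d = "D" in block
        has_s = "S" in block
        if has_s or (has_i and has_d):
            kind = "substitution"
        elif has_i:
            kind = "insertion"
        else:
            kind = "deletion"
        regions.append(
            VariantRegion(
                kind=kind,
                canonical_interval=residue_interval(rc, s, e),
                alternative_interval=residue_interval(ra, s, e),
                terminal=(s == 0 or e == n),
            )
        )
    return regions


def classify_simple_variant(
    pair: IsoformPair,
    min_len: int = 10,
    strict: bool = False,
    ignore_termini: bool = True,
) -> bool:
    """True iff the pair differs by one internal indel of qualifying length.

    ``min_len`` is inclusive by default (length >= 10 qualifies); set
    ``strict`` for the exclusive reading (> min_len). With
    ``ignore_termini`` (default), terminal truncation regions do not count
    against the single-region requirement.
    """
    regions = pair.variant_regions
    internal = [r for r in regions if not (ignore_termini and r.terminal)]
    if len(internal) != 1:
        return False
    region = internal[0]
    if region.kind not in ("insertion", "deletion"):
        return False
    return region.length > min_len if strict else region.length >= min_len


def build_coordinate_maps(pair: IsoformPair) -> tuple[list[int], list[int]]:
    """Return (canonical->alternative, alternative->canonical) position maps.

    Maps are 1-based lists indexed by position-1; deleted/inserted residues
    map to the :data:`~spliceform.models.GAP` sentinel.
    """
    c2a = []
    a2c = []
    ci = ai = 0
    for x, y in zip(pair.aligned_canonical, pair.aligned_alternative):
        if x != "-" and y != "-":
            ci += 1
            ai += 1
            c2a.append(ai)
            a2c.append(ci)
        elif x != "-":
            ci += 1
            c2a.append(GAP)
        else:
            ai += 1
            a2c.append(GAP)
    return c2a, a2c


def map_coordinate(pair: IsoformPair, canonical_pos: int) -> int:
    """Map a canonical residue position onto the alternative sequence.

    Returns the 1-based alternative position, or :data:`GAP` when the
    canonical residue is deleted in the alternative isoform.
    """
    if not (1 <= canonical_pos <= len(pair.canonical_seq)):
        raise ContractError(
            f"canonical position {canonical_pos} outside 1..{len(pair.canonical_seq)}"
        )
    c2a, _ = build_coordinate_maps(pair)
    return c2a[canonical_pos - 1]
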