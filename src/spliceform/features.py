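"""Intersection of variant regions with disordered-region and PTM features.

Variant vs invariant residues are scored on per-residue tracks (disorder,
protein-/RNA-binding propensity), compared with two-sample
Kolmogorov-Smirnov tests, scanned for N-glycosylation motifs, and
intersected with annotated phosphosites through the canonical-alternative
coordinate map.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import build_coordinate_maps
from .errors import ContractError, ValidationError
from .models import GAP, IsoformPair, PtmAnnotation, ResidueTrack

TrackSet = Mapping[str, Mapping[str, ResidueTrack]]  # protein_id -> track_name -> track


# ---------------------------------------------------------------------------
# disorder fractions
# ---------------------------------------------------------------------------

def disorder_fraction(track: ResidueTrack, region: tuple[int, int], threshold: float = 0.5) -> float:
    """Fraction of region residues with score strictly above ``threshold``.

    ``region`` is a 1-based inclusive residue interval on the track's
    protein.
    """
    s, e = region
    if s > e:
        raise ContractError("empty region")
    if s < 1 or e > len(track.scores):
        raise ContractError(f"region ({s},{e}) outside track of length {len(track.scores)}")
    vals = track.scores[s - 1 : e]
    return sum(1 for v in vals if v > threshold) / len(vals)


def _variant_residue_scores(pair: IsoformPair, tracks: TrackSet, track_name: str) -> list[float]:
    """Scores of all variant-region residues, each read from its own side."""
    can = tracks[pair.canonical_id][track_name].scores
    alt = tracks[pair.alternative_id][track_name].scores
    _check_track_lengths(pair, tracks, track_name)
    out: list[float] = []
    for region in pair.variant_regions:
        if region.canonical_interval is not None and region.kind in ("deletion", "substitution"):
            s, e = region.canonical_interval
            out.extend(can[s - 1 : e])
        if region.alternative_interval is not None and region.kind in ("insertion", "substitution"):
            s, e = region.alternative_interval
            out.extend(alt[s - 1 : e])
    return out


def _invariant_residue_scores(pair: IsoformPair, tracks: TrackSet, track_name: str) -> list[float]:
    """Canonical-track scores of residues aligned outside variant regions."""
    can = tracks[pair.canonical_id][track_name].scores
    _check_track_lengths(pair, tracks, track_name)
    in_variant = set()
    for region in pair.variant_regions:
        if region.canonical_interval is not None:
            s, e = region.canonical_interval
            in_variant.update(range(s, e + 1))
    c2a, _ = build_coordinate_maps(pair)
    return [
        can[pos - 1]
        for pos in range(1, len(pair.canonical_seq) + 1)
        if pos not in in_variant and c2a[pos - 1] != GAP
    ]


def _check_track_lengths(pair: IsoformPair, tracks: TrackSet, track_name: str) -> None:
    for pid, seq in ((pair.canonical_id, pair.canonical_seq),
                     (pair.alternative_id, pair.alternative_seq)):
        track = tracks[pid][track_name]
        if len(track.scores) != len(seq):
            raise ValidationError(
                f"track {track_name} on {pid}: length {len(track.scores)} != sequence "
                f"length {len(seq)}"
            )


def variant_invariant_fractions(
    pair: IsoformPair,
    tracks: TrackSet,
    track_name: str = "disorder_meta",
    threshold: float = 0.5,
) -> tuple[Optional[float], float]:
    """Disordered fraction of variant vs invariant residues of a pair.

    Variant residues pool all variant regions, inserted residues scored on
    the alternative track and deleted residues on the canonical track.
    The variant fraction is ``None`` when the pair has no variant regions.
    """
    var = _variant_residue_scores(pair, tracks, track_name)
    inv = _invariant_residue_scores(pair, tracks, track_name)
    var_frac = (sum(1 for v in var if v > threshold) / len(var)) if var else None
    inv_frac = sum(1 for v in inv if v > threshold) / len(inv) if inv else float("nan")
    return var_frac, inv_frac


# ---------------------------------------------------------------------------
# two-sample Kolmogorov-Smirnov
# ---------------------------------------------------------------------------

def _ks_statistic_num(a: np.ndarray, b: np.ndarray) -> int:
    """Integer numerator of D: max over x of |m_a(x)*n - m_b(x)*m| (over m*n)."""
    m, n = len(a), len(b)
    pooled = np.concatenate([a, b])
    pooled.sort(kind="mergesort")
    ca = np.searchsorted(np.sort(a), pooled, side="right")
    cb = np.searchsorted(np.sort(b), pooled, side="right")
    return int(np.max(np.abs(ca * n - cb * m)))


def _exact_ks_pvalue(m: int, n: int, d_num: int) -> float:
    """Exact two-sided p by lattice-path counting (no-ties null).

    Counts monotone paths from (0,0) to (m,n) keeping |i*n - j*m| < d_num
    at every vertex; p = 1 - inside/total, i.e. the probability that the
    running discrepancy ever reaches the observed numerator.
    """
    if d_num == 0:
        return 1.0
    counts = [[0] * (n + 1) for _ in range(m + 1)]
    counts[0][0] = 1
    for i in range(m + 1):
        for j in range(n + 1):
            if i == 0 and j == 0:
                continue
            if abs(i * n - j * m) >= d_num:
                continue
            c = 0
            if i > 0:
                c += counts[i - 1][j]
            if j > 0:
                c += counts[i][j - 1]
            counts[i][j] = c
    from math import comb

    total = comb(m + n, m)
    return float(1 - Fraction(counts[m][n], total))


def kolmogorov_sf(x: float) -> float:
    """Survival function of the Kolmogorov distribution.

    Uses the alternating series 2 * sum (-1)^(k-1) exp(-2 k^2 x^2) for
    large x and the Jacobi-theta dual form for small x, where the
    alternating series converges too slowly.
    """
    if x <= 0:
        return 1.0
    if x < 1.18:
        # cdf = sqrt(2*pi)/x * sum_{k>=1} exp(-(2k-1)^2 pi^2 / (8 x^2))
        t = np.pi * np.pi / (8.0 * x * x)
        cdf = 0.0
        for k in range(1, 21):
            term = np.exp(-((2 * k - 1) ** 2) * t)
            cdf += term
            if term < 1e-18:
                break
        cdf *= np.sqrt(2.0 * np.pi) / x
        return float(min(max(1.0 - cdf, 0.0), 1.0))
    total = 0.0
    for k in range(1, 101):
        term = 2.0 * (-1.0) ** (k - 1) * np.exp(-2.0 * k * k * x * x)
        total += term
        if abs(term) < 1e-18:
            break
    return float(min(max(total, 0.0), 1.0))


def ks_two_sample(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    exact_limit: int = 10_000,
) -> tuple[float, float]:
    """Two-sided two-sample KS test.

    The p value is exact (lattice-path enumeration under the no-ties null)
    when ``m * n <= exact_limit`` and the pooled sample is tie-free;
    otherwise the asymptotic Kolmogorov distribution at
    ``sqrt(m n / (m + n)) * D`` is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ContractError("both samples must be non-empty")
    m, n = a.size, b.size
    d_num = _ks_statistic_num(a, b)
    d = d_num / (m * n)
    has_ties = len(np.unique(np.concatenate([a, b]))) < m + n
    if m * n <= exact_limit and not has_ties:
        p = _exact_ks_pvalue(m, n, d_num)
    else:
        en = np.sqrt(m * n / (m + n))
        p = kolmogorov_sf(en * d)
    return float(d), float(p)


# ---------------------------------------------------------------------------
# binding-function classification
# ---------------------------------------------------------------------------

def _has_qualifying_run(flags: Sequence[bool], min_run: int) -> bool:
    run = 0
    for f in flags:
        run = run + 1 if f else 0
        if run >= min_run:
            return True
    return False


def classify_idr_function(
    pair: IsoformPair,
    tracks: TrackSet,
    propensity_threshold: float = 0.5,
    min_run: int = 1,
    idr_track: str = "disorder_fldpnn",
    idr_threshold: float = 0.5,
) -> str:
    """Assign {protein_binding, rna_binding, both, none} to a pair.

    A binding function is called when some variant-region residue lies
    inside the IDR mask (``idr_track`` score > ``idr_threshold``, or the
    track's own binary mask when present) and exceeds the propensity
    threshold on the corresponding binding track, in a run of at least
    ``min_run`` consecutive qualifying residues.
    """
    calls = {}
    for fn, track_name in (("protein_binding", "protein_binding"),
                           ("rna_binding", "rna_binding")):
        flags: list[bool] = []
        for side, pid, ival_attr in (
            ("canonical", pair.canonical_id, "canonical_interval"),
            ("alternative", pair.alternative_id, "alternative_interval"),
        ):
            prop = tracks[pid][track_name]
            idr = tracks[pid].get(idr_track)
            if idr is not None and idr.idr_mask is not None:
                mask = idr.idr_mask
            elif idr is not None:
                mask = [s > idr_threshold for s in idr.scores]
            else:
                mask = [True] * len(prop.scores)
            for region in pair.variant_regions:
                want = (("deletion", "substitution") if side == "canonical"
                        else ("insertion", "substitution"))
                ival = getattr(region, ival_attr)
                if region.kind in want and ival is not None:
                    s, e = ival
                    flags.extend(
                        mask[i] and prop.scores[i] > propensity_threshold
                        for i in range(s - 1, e)
                    )
        calls[fn] = _has_qualifying_run(flags, min_run)
    if calls["protein_binding"] and calls["rna_binding"]:
        return "both"
    if calls["protein_binding"]:
        return "protein_binding"
    if calls["rna_binding"]:
        return "rna_binding"
    return "none"


# ---------------------------------------------------------------------------
# N-glycosylation motifs
# ---------------------------------------------------------------------------

def scan_nglyco_motifs(
    sequence: str,
    region: Optional[tuple[int, int]] = None,
    rule: str = "NXS_T_literal",
) -> list[int]:
    """1-based start positions of N-glycosylation motifs in a region.

    ``NXS_T_literal`` matches N at i with S or T at i+2; ``sequon_no_proline``
    additionally requires the middle residue not be proline. Overlapping
    motifs are all reported; a motif counts when its N lies inside the
    region even if the rest extends past it.
    """
    if rule not in ("NXS_T_literal", "sequon_no_proline"):
        raise ValueError(f"unknown motif rule {rule!r}")
    seq = sequence.upper()
    s, e = region if region is not None else (1, len(seq))
    if s < 1 or e > len(seq) or s > e:
        raise ContractError(f"region ({s},{e}) outside sequence of length {len(seq)}")
    hits = []
    for i in range(s, e + 1):
        if i + 2 > len(seq):
            break
        if seq[i - 1] != "N" or seq[i + 1] not in ("S", "T"):
            continue
        if rule == "sequon_no_proline" and seq[i] == "P":
            continue
        hits.append(i)
    return hits


# ---------------------------------------------------------------------------
# PTM intersection
# ---------------------------------------------------------------------------

_PHOSPHO_RESIDUES = set("STY")


def intersect_ptm_sites(
    annotations: Sequence[PtmAnnotation],
    pair: IsoformPair,
) -> list[tuple[PtmAnnotation, str, int]]:
    """Locate canonical PTM sites relative to the pair's variant regions.

    Each site is classified exhaustively and exclusively as
    ``lost_by_deletion`` (its canonical residue has no alternative image),
    ``in_variant_region`` (inside a substitution region but still mapped),
    or ``mapped_to_alternative``. The third tuple element is the mapped
    alternative position (:data:`GAP` for lost sites).
    """
    c2a, _ = build_coordinate_maps(pair)
    n = len(pair.canonical_seq)
    in_variant = set()
    for region in pair.variant_regions:
        if region.canonical_interval is not None:
            s, e = region.canonical_interval
            in_variant.update(range(s, e + 1))
    out = []
    bad_rows = []
    for ann in annotations:
        if not (1 <= ann.site <= n):
            bad_rows.append(f"{ann.protein_id}:{ann.site} beyond length {n}")
            continue
        if (ann.ptm_type == "phosphorylation"
                and pair.canonical_seq[ann.site - 1] not in _PHOSPHO_RESIDUES):
            warnings.warn(
                f"phosphosite at {ann.protein_id}:{ann.site} on residue "
                f"{pair.canonical_seq[ann.site - 1]!r} (expected S/T/Y)",
                stacklevel=2,
            )
        mapped = c2a[ann.site - 1]
        if mapped == GAP:
            out.append((ann, "lost_by_deletion", GAP))
        elif ann.site in in_variant:
            out.append((ann, "in_variant_region", mapped))
        else:
            out.append((ann, "mapped_to_alternative", mapped))
    if bad_rows:
        raise ValidationError("PTM sites beyond sequence bounds: " + "; ".join(bad_rows))
    return out


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentReport:
    fraction_table: pd.DataFrame
    ks_disorder: tuple[float, float]
    ks_protein_binding: Optional[tuple[float, float]]
    ks_rna_binding: Optional[tuple[float, float]]
    n_pairs: int
    n_variant_frac_ge_half: int
    function_classes: dict[str, int] = field(default_factory=dict)
    motif_counts: dict[str, int] = field(default_factory=dict)
    ptm_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    underpowered: bool = False


def summarize_enrichment(
    pairs: Sequence[IsoformPair],
    tracks: TrackSet,
    annotations: Mapping[str, Sequence[PtmAnnotation]] | None = None,
    disorder_track: str = "disorder_meta",
    disorder_threshold: float = 0.5,
    propensity_threshold: float = 0.5,
    min_run: int = 1,
    motif_rule: str = "NXS_T_literal",
    pooled_residues: bool = False,
) -> EnrichmentReport:
    """Full variant-region feature-enrichment summary for a set of pairs.

    Computes per-pair variant/invariant disorder fractions, the KS test
    between the two fraction distributions (or between pooled per-residue
    scores with ``pooled_residues``), KS tests of binding propensities in
    variant-region IDR residues vs invariant IDR residues, binding
    function class counts, N-glycosylation motif counts per variant
    region, and phosphosite intersection tallies.
    """
    rows = []
    var_fracs, inv_fracs = [], []
    pooled_var, pooled_inv = [], []
    func_counts = {"protein_binding": 0, "rna_binding": 0, "both": 0, "none": 0}
    motif_counts: dict[str, int] = {}
    ptm_counts: dict[str, dict[str, int]] = {}
    bind_var = {"protein_binding": [], "rna_binding": []}
    bind_inv = {"protein_binding": [], "rna_binding": []}

    for pair in pairs:
        vf, inf_ = variant_invariant_fractions(pair, tracks, disorder_track, disorder_threshold)
        rows.append({
            "pair_id": pair.alternative_id,
            "variant_fraction": np.nan if vf is None else vf,
            "invariant_fraction": inf_,
            "simple_variant": pair.simple_variant,
        })
        if vf is not None:
            var_fracs.append(vf)
        inv_fracs.append(inf_)
        pooled_var.extend(_variant_residue_scores(pair, tracks, disorder_track))
        pooled_inv.extend(_invariant_residue_scores(pair, tracks, disorder_track))

        has_any = False
        cls = classify_idr_function(pair, tracks,
                                    propensity_threshold=propensity_threshold,
                                    min_run=min_run,
                                    idr_track=disorder_track,
                                    idr_threshold=disorder_threshold)
        for tn in ("protein_binding", "rna_binding"):
            if pair.canonical_id in tracks and tn in tracks[pair.canonical_id]:
                has_any = True
        if has_any:
            func_counts[cls] += 1
            # per-residue propensities inside the IDR mask
            for tn in ("protein_binding", "rna_binding"):
                bind_var[tn].extend(
                    v for v, d in zip(_variant_residue_scores(pair, tracks, tn),
                                      _variant_residue_scores(pair, tracks, disorder_track))
                    if d > disorder_threshold
                )
                bind_inv[tn].extend(
                    v for v, d in zip(_invariant_residue_scores(pair, tracks, tn),
                                      _invariant_residue_scores(pair, tracks, disorder_track))
                    if d > disorder_threshold
                )

        n_motifs = 0
        for region in pair.variant_regions:
            if region.alternative_interval is not None:
                n_motifs += len(scan_nglyco_motifs(pair.alternative_seq,
                                                   region.alternative_interval, motif_rule))
            if region.kind == "deletion" and region.canonical_interval is not None:
                n_motifs += len(scan_nglyco_motifs(pair.canonical_seq,
                                                   region.canonical_interval, motif_rule))
        motif_counts[pair.alternative_id] = n_motifs

        if annotations and pair.canonical_id in annotations:
            classified = intersect_ptm_sites(annotations[pair.canonical_id], pair)
            tally = {"lost_by_deletion": 0, "in_variant_region": 0, "mapped_to_alternative": 0}
            for _, cat, _ in classified:
                tally[cat] += 1
            ptm_counts[pair.alternative_id] = tally

    underpowered = len(var_fracs) < 2 or len(inv_fracs) < 2
    if pooled_residues:
        ks_dis = ks_two_sample(pooled_var, pooled_inv) if pooled_var and pooled_inv else (np.nan, np.nan)
    elif not underpowered:
        ks_dis = ks_two_sample(var_fracs, inv_fracs)
    else:
        ks_dis = (float("nan"), float("nan"))

    def _bind_ks(tn: str):
        if len(bind_var[tn]) >= 2 and len(bind_inv[tn]) >= 2:
            return ks_two_sample(bind_var[tn], bind_inv[tn])
        return None

    return EnrichmentReport(
        fraction_table=pd.DataFrame(rows),
        ks_disorder=ks_dis,
        ks_protein_binding=_bind_ks("protein_binding"),
        ks_rna_binding=_bind_ks("rna_binding"),
        n_pairs=len(pairs),
        n_variant_frac_ge_half=sum(1 for v in var_fracs if v >= 0.5),
        function_classes=func_counts,
        motif_counts=motif_counts,
        ptm_counts=ptm_counts,
        underpowered=underpowered,
    )
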