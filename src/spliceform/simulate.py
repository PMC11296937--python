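"""Synthetic data with the statistical structure the pipeline assumes.

Every generator is deterministic under a fixed seed and emits a complete
ground-truth record alongside the data: gene models with stop-free ORFs
and planted splice events of all five types; isoform pairs differing by
planted indels; peptide intensity matrices with donor random effects,
chamber fixed effects and missingness; disorder/binding tracks with
elevated scores inside variant regions; and phosphosite annotations
enriched in deleted regions.

The default cohort mirrors a two-chamber cardiac design: 7 donors, each
contributing left-atrial, right-atrial and left-ventricular samples
(LA/RA pooled as "atrium", LV as "ventricle").
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError
from .models import GeneModel, SampleDesign, SpliceEvent, Transcript
from .quant import digest
from .junctions import reverse_complement

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = ("TAA", "TAG", "TGA")

# aa -> codons for back-translation (standard genetic code)
from Bio.Data.CodonTable import standard_dna_table as _tbl
_AA2CODONS: dict[str, list[str]] = {}
for _codon, _aa in _tbl.forward_table.items():
    _AA2CODONS.setdefault(_aa, []).append(_codon)
for _aa in _AA2CODONS:
    _AA2CODONS[_aa].sort()


@dataclass
class SimulationConfig:
    """All tunable knobs of the synthetic study, with field-realistic defaults."""

    seed: int = 0
    # gene / event model
    n_genes: int = 30
    exon_codons: tuple[int, int] = (15, 40)       # codons per coding exon block
    intron_len: tuple[int, int] = (60, 200)
    utr_len: int = 30
    frame_preserving_fraction: float = 0.8
    ptc_fraction: float = 0.15                    # of frame-preserving MXE/RI events
    # junction read model (two-component: expressed + low-read contaminant)
    nb_mean: float = 100.0
    nb_size: float = 10.0
    contaminant_mean: float = 3.0
    contaminant_weight: float = 0.25
    # isoform pairs
    n_isoform_pairs: int = 100
    protein_len: tuple[int, int] = (150, 400)
    indel_len: tuple[int, int] = (10, 60)
    insertion_prob: float = 0.5
    # cohort & effect model
    n_donors: int = 7
    chambers: tuple[str, ...] = ("LA", "LV", "RA")
    frac_biased: float = 0.1
    log2fc: float = 1.0
    donor_sd: float = 0.2
    residual_sd: float = 0.3
    missing_rate: float = 0.1
    baseline_log2: float = 27.0
    baseline_sd: float = 1.5
    shared_alt_weight: float = 0.2               # leakage of isoform effect into shared peptides
    # disorder / binding model
    beta_var: tuple[float, float] = (8.0, 2.0)
    beta_inv: tuple[float, float] = (2.0, 8.0)
    smooth_window: int = 3
    protein_bump_prob: float = 0.55
    rna_bump_prob: float = 0.5
    bump_width: int = 10
    bump_low: float = 0.7
    bump_high: float = 0.95
    baseline_propensity: tuple[float, float] = (1.0, 9.0)   # Beta params
    # PTMs
    ptm_density_per_100: float = 2.0
    deleted_ptm_enrichment: float = 3.0

    def validate(self) -> None:
        for name in ("frame_preserving_fraction", "ptc_fraction", "contaminant_weight",
                     "frac_biased", "missing_rate", "insertion_prob",
                     "protein_bump_prob", "rna_bump_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0,1], got {v}")
        for name in ("n_genes", "n_isoform_pairs", "n_donors"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.indel_len[0] < 1 or self.indel_len[1] < self.indel_len[0]:
            raise ConfigurationError("invalid indel_len range")
        need = self.indel_len[1] + 2 * _indel_margin(self.indel_len[1]) + 1
        if self.protein_len[0] < need:
            raise ConfigurationError(
                f"proteins too short for the configured indels (need >= {need})"
            )


@dataclass
class GroundTruth:
    """Per-object truth keyed by id; every emitted object has a record."""

    junctions: dict[str, dict] = field(default_factory=dict)      # event_id -> labels
    event_forms: dict[str, dict] = field(default_factory=dict)    # "event|form" -> expectation
    canonical_proteins: dict[str, str] = field(default_factory=dict)
    pairs: dict[str, dict] = field(default_factory=dict)          # alternative_id -> indel truth
    isoform_effects: dict[str, float] = field(default_factory=dict)
    peptide_classes: dict[str, str] = field(default_factory=dict)
    track_regimes: dict[str, dict] = field(default_factory=dict)
    ptm_sites: dict[str, list] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# gene set + splice events
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA20[i] for i in rng.integers(0, 20, size=length))

def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))

def _nonstop_codons(rng: np.random.Generator, n: int, plant_stop: bool = False) -> str:
    codons = [_AA2CODONS[aa][rng.integers(0, len(_AA2CODONS[aa]))]
              for aa in _random_protein(rng, n)]
    if plant_stop and n >= 2:
        codons[n // 2] = _STOPS[rng.integers(0, 3)]
    return "".join(codons)


@dataclass
class _Segment:
    kind: str       # exon | intron | alt_exon
    seq: str
    tag: str = ""   # role marker (target, mx_b, ri_intron, ...)


def _layout_gene(cfg: SimulationConfig, rng: np.random.Generator, gene_idx: int):
    """Build one gene with a single planted splice event.

    Returns (GeneModel, chromosome sequence, SpliceEvent skeleton dict,
    per-form truth). Internal coding exon boundaries are codon-aligned so
    frame-preserving events never create junction-spanning codons; the
    non-frame-preserving variant shifts one boundary by one nucleotide.
    """
    event_type = ("SE", "MXE", "A5SS", "A3SS", "RI")[gene_idx % 5]
    strand = "+" if rng.integers(0, 2) == 0 else "-"
    gene_id = f"G{gene_idx:04d}"
    frame_preserving = bool(rng.random() < cfg.frame_preserving_fraction)
    plant_ptc = (frame_preserving and event_type in ("MXE", "RI")
                 and rng.random() < cfg.ptc_fraction)

    nc1 = int(rng.integers(*cfg.exon_codons))
    nc2 = int(rng.integers(*cfg.exon_codons))
    nc3 = int(rng.integers(*cfg.exon_codons))
    utr5 = _random_nt(rng, cfg.utr_len)
    utr3 = _random_nt(rng, cfg.utr_len)
    stop = _STOPS[rng.integers(0, 3)]

    c1 = _nonstop_codons(rng, nc1)
    c2 = _nonstop_codons(rng, nc2)
    c3 = _nonstop_codons(rng, nc3)

    def intron() -> str:
        return _random_nt(rng, int(rng.integers(*cfg.intron_len)))

    segs: list[_Segment] = []
    if event_type == "SE":
        e1, e2, e3 = utr5 + c1, c2, c3 + stop + utr3
        if not frame_preserving:
            # shift one boundary: move first nt of e3 onto e2
            e2, e3 = e2 + e3[0], e3[1:]
        segs = [_Segment("exon", e1, "up"), _Segment("intron", intron()),
                _Segment("exon", e2, "target"), _Segment("intron", intron()),
                _Segment("exon", e3, "down")]
    elif event_type == "MXE":
        n_b = nc2 if frame_preserving else nc2 + 1
        b = _nonstop_codons(rng, n_b, plant_stop=plant_ptc)
        if not frame_preserving:
            b = b[:3 * nc2 + 1]
        segs = [_Segment("exon", utr5 + c1, "up"), _Segment("intron", intron()),
                _Segment("exon", c2, "target"), _Segment("intron", intron()),
                _Segment("alt_exon", b, "mx_b"), _Segment("intron", intron()),
                _Segment("exon", c3 + stop + utr3, "down")]
    elif event_type in ("A5SS", "A3SS"):
        k = 3 * int(rng.integers(2, max(3, nc2 - 2)))
        if not frame_preserving:
            k += 1
        k = min(k, 3 * nc2 - 3)
        segs = [_Segment("exon", utr5 + c1, "up"), _Segment("intron", intron()),
                _Segment("exon", c2, "target"), _Segment("intron", intron()),
                _Segment("exon", c3 + stop + utr3, "down")]
        # short form trims k nt from the 3' (A5SS) or 5' (A3SS) end of the
        # target exon in transcription orientation
    else:  # RI
        n_i = int(rng.integers(cfg.exon_codons[0], cfg.exon_codons[1]))
        ri = _nonstop_codons(rng, n_i, plant_stop=plant_ptc)
        if not frame_preserving:
            ri = ri[:-1]
        segs = [_Segment("exon", utr5 + c1, "up"),
                _Segment("intron", ri, ), _Segment("exon", c2 + stop + utr3, "down")]
        segs[1].tag = "ri_intron"

    # transcript-space offsets (transcription order)
    offsets = []
    off = 0
    for s in segs:
        offsets.append(off)
        off += len(s.seq)
    total = off
    pad = 50
    genomic = _random_nt(rng, pad) + "".join(s.seq for s in segs) + _random_nt(rng, pad)
    if strand == "-":
        genomic = _random_nt(rng, pad) + reverse_complement("".join(s.seq for s in segs)) + _random_nt(rng, pad)

    def ginterval(seg_i: int) -> tuple[int, int]:
        o, ln = offsets[seg_i], len(segs[seg_i].seq)
        if strand == "+":
            return (pad + o + 1, pad + o + ln)
        return (pad + total - (o + ln) + 1, pad + total - o)

    # transcript exons (transcription order): exon + (RI keeps intron out)
    tx_exon_idx = [i for i, s in enumerate(segs) if s.kind == "exon"]
    tx_exons = tuple(ginterval(i) for i in tx_exon_idx)

    # genomic coordinate of the first coding base (transcript offset = utr_len)
    cds_off = cfg.utr_len
    seg0 = 0  # always in first exon
    o, ln = offsets[seg0], len(segs[seg0].seq)
    if strand == "+":
        cds_start = pad + o + cds_off + 1
    else:
        cds_start = pad + total - o - cds_off

    tx = Transcript(transcript_id=f"{gene_id}.t1", exons=tx_exons,
                    cds_start=cds_start, frame_offset=0)
    model = GeneModel(gene_id=gene_id, chromosome=f"chr_{gene_id}", strand=strand,
                      transcripts=(tx,))

    by_tag = {s.tag: i for i, s in enumerate(segs) if s.tag}
    up_g, down_g = ginterval(by_tag["up"]), ginterval(by_tag["down"])
    if strand == "-":
        up_g, down_g = min(up_g, down_g), max(up_g, down_g)

    truth_forms: dict[str, dict] = {}
    event_id = f"{gene_id}.ev"

    def asc(ivs):
        return sorted(ivs)

    if event_type == "SE":
        t1, t2 = ginterval(by_tag["target"]), None
        delta_skip = -len(segs[by_tag["target"]].seq)
    elif event_type == "MXE":
        t1, t2 = ginterval(by_tag["target"]), ginterval(by_tag["mx_b"])
        delta_skip = len(segs[by_tag["mx_b"]].seq) - len(segs[by_tag["target"]].seq)
    elif event_type == "RI":
        t1, t2 = (up_g[1] + 1, down_g[0] - 1), None
        delta_skip = 0
    else:  # A5SS / A3SS
        # short form trims trim_nt from the transcription-3' (A5SS) or
        # transcription-5' (A3SS) end of the target exon
        seg_len = len(segs[by_tag["target"]].seq)
        trim = 3 * int(rng.integers(2, max(3, seg_len // 3 - 1)))
        if not frame_preserving:
            trim += 1
        trim = min(trim, seg_len - 3)
        ls, le = ginterval(by_tag["target"])
        trim_high_end = (event_type == "A5SS") == (strand == "+")
        short_iv = (ls, le - trim) if trim_high_end else (ls + trim, le)
        t1, t2 = (ls, le), short_iv
        delta_skip = -trim

    def form_exons(form: str) -> list[tuple[int, int]]:
        up_i, down_i = by_tag["up"], by_tag["down"]
        if event_type == "SE":
            mid = [ginterval(by_tag["target"])] if form == "inclusion" else []
        elif event_type == "MXE":
            mid = [ginterval(by_tag["target"])] if form == "inclusion" else [ginterval(by_tag["mx_b"])]
        elif event_type in ("A5SS", "A3SS"):
            mid = [t1] if form == "inclusion" else [t2]
        else:
            if form == "inclusion":
                return asc([(min(up_g[0], down_g[0]), max(up_g[1], down_g[1]))])
            mid = []
        return asc([ginterval(up_i)] + mid + [ginterval(down_i)])

    for form in ("inclusion", "skip"):
        delta = 0 if form == "inclusion" else delta_skip
        if event_type == "RI":
            delta = (t1[1] - t1[0] + 1) if form == "inclusion" else 0
        # the reference transcript realizes the inclusion form for all
        # event types except RI, where the annotation is the spliced form
        is_ref = (form == "skip") if event_type == "RI" else (form == "inclusion")
        if delta % 3 != 0:
            expect = ("rejected", "frameshift")
        elif plant_ptc and (
            (event_type == "MXE" and form == "skip")
            or (event_type == "RI" and form == "inclusion")
        ):
            expect = ("rejected", "premature_stop")
        elif is_ref:
            expect = ("rejected", "canonical_redundant")
        else:
            expect = (1, None)
        truth_forms[f"{event_id}|{form}"] = {
            "exons": form_exons(form),
            "expected_tier": expect[0],
            "expected_reason": expect[1],
            "delta": delta,
        }

    event = SpliceEvent(
        event_id=event_id, gene_id=gene_id, event_type=event_type,
        upstream=up_g, downstream=down_g, target1=t1, target2=t2,
        inclusion_reads=0, skip_reads=0,
    )

    # planted variant region of the non-reference form, in residue space
    # (valid only when that form is expected tier 1)
    nonref_form = "inclusion" if event_type == "RI" else "skip"
    pair_info = None
    if truth_forms[f"{event_id}|{nonref_form}"]["expected_tier"] == 1:
        if event_type == "SE":
            pair_info = {"kind": "deletion",
                         "canonical_interval": (nc1 + 1, nc1 + nc2),
                         "alternative_interval": None, "length": nc2}
        elif event_type == "MXE":
            pair_info = {"kind": "substitution",
                         "canonical_interval": (nc1 + 1, nc1 + nc2),
                         "alternative_interval": (nc1 + 1, nc1 + nc2), "length": nc2}
        elif event_type == "RI":
            n_i = len(segs[by_tag["ri_intron"]].seq) // 3
            pair_info = {"kind": "insertion", "canonical_interval": None,
                         "alternative_interval": (nc1 + 1, nc1 + n_i), "length": n_i}
        else:
            d = trim // 3
            if event_type == "A5SS":
                ci = (nc1 + nc2 - d + 1, nc1 + nc2)
            else:
                ci = (nc1 + 1, nc1 + d)
            pair_info = {"kind": "deletion", "canonical_interval": ci,
                         "alternative_interval": None, "length": d}
        pair_info["n_indels"] = 1
        pair_info["simple"] = (pair_info["kind"] != "substitution"
                               and pair_info["length"] >= 10)
    return model, genomic, event, truth_forms, pair_info


def _draw_reads(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[int, int, bool]:
    contaminant = bool(rng.random() < cfg.contaminant_weight)
    mean = cfg.contaminant_mean if contaminant else cfg.nb_mean
    p = cfg.nb_size / (cfg.nb_size + mean)
    total = int(rng.negative_binomial(cfg.nb_size, p))
    incl = int(rng.binomial(total, 0.5)) if total else 0
    return incl, total - incl, contaminant


def simulate_gene_set(cfg: SimulationConfig, rng: Optional[np.random.Generator] = None):
    """Gene models, genome, splice-event table and ground truth.

    Returns (models, genome dict, events, GroundTruth). Each gene carries
    one planted event; the five event types cycle across genes, both
    strands occur, and read counts follow the two-component
    negative-binomial model.
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    models, genome, events = [], {}, []
    truth = GroundTruth()
    for g in range(cfg.n_genes):
        model, chrom_seq, event, truth_forms, pair_info = _layout_gene(cfg, rng, g)
        incl, skip, contaminant = _draw_reads(cfg, rng)
        event = dataclasses.replace(event, inclusion_reads=incl, skip_reads=skip)
        models.append(model)
        genome[model.chromosome] = chrom_seq
        events.append(event)
        truth.junctions[event.event_id] = {
            "contaminant": contaminant,
            "total_reads": incl + skip,
        }
        truth.event_forms.update(truth_forms)
        if pair_info is not None:
            truth.pairs[f"{model.gene_id}-J1"] = pair_info
        # canonical protein: straight translation of the reference transcript
        from .junctions import splice_transcript_reference, translate_in_frame
        ref = translate_in_frame(
            splice_transcript_reference(model, model.transcripts[0], genome),
            model.transcripts[0].frame_offset,
        )
        truth.canonical_proteins[model.gene_id] = ref.protein
    return models, genome, events, truth


# ---------------------------------------------------------------------------
# isoform pairs with planted indels
# ---------------------------------------------------------------------------

def _indel_margin(length: int) -> int:
    """Minimum flank on each side of a planted indel.

    With free end gaps, an indel too close to a terminus can be expressed
    more cheaply as a terminal gap, so the flank's match score must exceed
    the affine gap cost it saves. BLOSUM62 diagonal scores are >= 4, so a
    flank of (gap cost)/3 residues is comfortably sufficient.
    """
    return max(12, (28 + length) // 3)


def _plant_indel(rng: np.random.Generator, canonical: str, length: int,
                 insertion: bool) -> tuple[str, dict]:
    """Insert or delete a block, redrawing until placement is unambiguous.

    Ambiguous placements (where the indel could shift one residue left or
    right with an identical alignment score) are rejected so planted
    boundaries are a well-defined recovery target; flanks respect
    :func:`_indel_margin` so terminal gaps never outscore the planted
    alignment.
    """
    n = len(canonical)
    margin = _indel_margin(length)
    for _ in range(1000):
        if insertion:
            p = int(rng.integers(margin, n - margin + 1))  # insert between p and p+1
            s = _random_protein(rng, length)
            if s[-1] == canonical[p - 1] or s[0] == canonical[p]:
                continue
            alt = canonical[:p] + s + canonical[p:]
            return alt, {
                "kind": "insertion",
                "canonical_interval": None,
                "alternative_interval": (p + 1, p + length),
                "length": length,
            }
        i = int(rng.integers(margin, n - length - margin + 1))  # delete canonical[i:i+length]
        j = i + length
        if canonical[j - 1] == canonical[i - 1] or canonical[i] == canonical[j]:
            continue
        alt = canonical[:i] + canonical[j:]
        return alt, {
            "kind": "deletion",
            "canonical_interval": (i + 1, j),
            "alternative_interval": None,
            "length": length,
        }
    raise RuntimeError("could not place an unambiguous indel")


def simulate_isoform_pairs(
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    scenario: str = "single",
    n_pairs: Optional[int] = None,
) -> tuple[list[tuple[str, str, str, str]], GroundTruth]:
    """Canonical/alternative sequence pairs with planted variant regions.

    ``scenario`` selects the planted structure: ``single`` (one indel,
    lengths from ``cfg.indel_len``), ``short`` (one indel below the
    10-residue simple-variant floor), or ``multi`` (two indels). Returns
    [(canonical_id, canonical_seq, alternative_id, alternative_seq)] and
    truth keyed by alternative_id.
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed + 1)
    n_pairs = n_pairs if n_pairs is not None else cfg.n_isoform_pairs
    pairs = []
    truth = GroundTruth()
    for k in range(n_pairs):
        can = _random_protein(rng, int(rng.integers(*cfg.protein_len)))
        cid, aid = f"P{k:04d}", f"P{k:04d}-J1"
        if scenario == "single":
            length = int(rng.integers(cfg.indel_len[0], cfg.indel_len[1] + 1))
            alt, info = _plant_indel(rng, can, length, bool(rng.random() < cfg.insertion_prob))
            info["n_indels"] = 1
            info["simple"] = length >= 10
        elif scenario == "short":
            length = int(rng.integers(1, 10))
            alt, info = _plant_indel(rng, can, length, bool(rng.random() < cfg.insertion_prob))
            info["n_indels"] = 1
            info["simple"] = False
        elif scenario == "multi":
            hi = min(30, cfg.indel_len[1])  # two indels must both fit one half
            l1 = int(rng.integers(cfg.indel_len[0], hi + 1))
            l2 = int(rng.integers(cfg.indel_len[0], hi + 1))
            half = len(can) // 2
            left, right = can[:half], can[half:]
            alt1, i1 = _plant_indel(rng, left, l1, True)
            alt2, i2 = _plant_indel(rng, right, l2, False)
            alt = alt1 + alt2
            info = {"kind": "multi", "n_indels": 2, "simple": False,
                    "canonical_interval": None, "alternative_interval": None,
                    "length": l1 + l2}
        else:
            raise ConfigurationError(f"unknown scenario {scenario!r}")
        pairs.append((cid, can, aid, alt))
        truth.pairs[aid] = info
        truth.canonical_proteins[cid] = can
    return pairs, truth


# ---------------------------------------------------------------------------
# cohort design & peptide/protein matrices
# ---------------------------------------------------------------------------

_CHAMBER_OF = {"LA": "atrium", "RA": "atrium", "LV": "ventricle", "RV": "ventricle"}


def make_design(cfg: SimulationConfig) -> list[SampleDesign]:
    """Sample sheet for the default cohort (donors x chamber sites)."""
    design = []
    for d in range(1, cfg.n_donors + 1):
        for site in cfg.chambers:
            design.append(SampleDesign(sample_id=f"D{d}_{site}",
                                       chamber=_CHAMBER_OF[site], donor=f"D{d}"))
    return design


def simulate_protein_matrix(
    cfg: SimulationConfig,
    n_proteins: int,
    rng: Optional[np.random.Generator] = None,
):
    """Protein-level log2 abundance matrix with planted chamber effects.

    A fraction ``cfg.frac_biased`` of proteins receives a ventricle-vs-
    atrium shift of ``cfg.log2fc`` (alternating sign); donors contribute
    additive random intercepts, residuals are i.i.d. Gaussian, and
    entries go missing completely at random at ``cfg.missing_rate``.
    Returns (DataFrame proteins x samples, design, truth effects dict).
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed + 2)
    design = make_design(cfg)
    n_biased = int(round(cfg.frac_biased * n_proteins))
    effects = np.zeros(n_proteins)
    biased_idx = rng.choice(n_proteins, size=n_biased, replace=False)
    signs = np.where(np.arange(n_biased) % 2 == 0, 1.0, -1.0)
    effects[biased_idx] = cfg.log2fc * signs
    donor_eff = {f"D{d}": rng.normal(0.0, cfg.donor_sd) for d in range(1, cfg.n_donors + 1)}

    import pandas as pd
    cols = [s.sample_id for s in design]
    Y = np.empty((n_proteins, len(design)))
    base = rng.normal(0.0, 1.0, size=n_proteins)
    for j, s in enumerate(design):
        mu = base + donor_eff[s.donor] + np.where(
            np.array([s.chamber == "ventricle"]), effects, 0.0
        )
        Y[:, j] = mu + rng.normal(0.0, cfg.residual_sd, size=n_proteins)
    if cfg.missing_rate > 0:
        mask = rng.random(Y.shape) < cfg.missing_rate
        Y[mask] = np.nan
    truth = {f"PR{i:05d}": float(effects[i]) for i in range(n_proteins)}
    mat = pd.DataFrame(Y, index=list(truth), columns=cols)
    return mat, design, truth


def simulate_peptide_matrix(
    pairs: Sequence[tuple[str, str, str, str]],
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
):
    """Peptide x sample intensity table for canonical/alternative pairs.

    Peptides come from tryptic digestion of both sequences. Alternative-
    only peptides carry the isoform's planted chamber effect in full,
    canonical-only peptides carry none, and shared peptides a
    ``cfg.shared_alt_weight`` fraction. Intensities are log-normal with
    donor random intercepts and MCAR missingness. Returns
    (intensity DataFrame, design, GroundTruth).
    """
    import pandas as pd
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed + 3)
    design = make_design(cfg)
    donor_eff = {f"D{d}": rng.normal(0.0, cfg.donor_sd) for d in range(1, cfg.n_donors + 1)}
    truth = GroundTruth()

    rows, row_ids = [], []
    n_biased = int(round(cfg.frac_biased * len(pairs)))
    biased = set(rng.choice(len(pairs), size=n_biased, replace=False).tolist())
    for k, (cid, can, aid, alt) in enumerate(pairs):
        effect = cfg.log2fc * (1.0 if k % 2 == 0 else -1.0) if k in biased else 0.0
        truth.isoform_effects[aid] = effect
        truth.isoform_effects[cid] = 0.0
        can_peps = set(digest(can))
        alt_peps = set(digest(alt))
        for pep in sorted(can_peps | alt_peps):
            if pep in can_peps and pep in alt_peps:
                cls, eff = "shared", effect * cfg.shared_alt_weight
            elif pep in alt_peps:
                cls, eff = "alternative_unique", effect
            else:
                cls, eff = "canonical_unique", 0.0
            truth.peptide_classes.setdefault(pep, cls)
            base = rng.normal(cfg.baseline_log2, cfg.baseline_sd)
            vals = []
            for s in design:
                mu = base + donor_eff[s.donor] + (eff if s.chamber == "ventricle" else 0.0)
                vals.append(2.0 ** (mu + rng.normal(0.0, cfg.residual_sd)))
            rows.append(vals)
            row_ids.append(pep)
    mat = pd.DataFrame(rows, index=row_ids, columns=[s.sample_id for s in design])
    mat = mat[~mat.index.duplicated(keep="first")]
    if cfg.missing_rate > 0:
        mask = rng.random(mat.shape) < cfg.missing_rate
        mat = mat.mask(pd.DataFrame(mask, index=mat.index, columns=mat.columns))
    return mat, design, truth


# ---------------------------------------------------------------------------
# tracks & PTMs
# ---------------------------------------------------------------------------

def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    padded = np.concatenate([x[:1].repeat(window // 2), x, x[-1:].repeat(window // 2)])
    return np.convolve(padded, kernel, mode="valid")[: len(x)]


def simulate_tracks_and_ptms(
    pairs: Sequence[tuple[str, str, str, str]],
    truth: GroundTruth,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
):
    """Disorder/binding tracks and phosphosite annotations for pairs.

    Disorder scores are Beta(``beta_var``) inside planted variant regions
    and Beta(``beta_inv``) elsewhere, smoothed by a short moving average.
    Binding-propensity bumps are planted inside variant regions of a
    configurable fraction of pairs; phosphosites land on S/T/Y with the
    configured density, enriched inside deleted regions. Returns
    (tracks dict, annotations dict, GroundTruth with track/PTM truth).
    """
    from .models import PtmAnnotation, ResidueTrack
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed + 4)
    a_v, b_v = cfg.beta_var
    a_i, b_i = cfg.beta_inv
    tracks: dict[str, dict[str, ResidueTrack]] = {}
    annotations: dict[str, list[PtmAnnotation]] = {}

    for cid, can, aid, alt in pairs:
        info = truth.pairs.get(aid, {})
        var_can = set()
        var_alt = set()
        if info.get("canonical_interval"):
            s, e = info["canonical_interval"]
            var_can.update(range(s - 1, e))
        if info.get("alternative_interval"):
            s, e = info["alternative_interval"]
            var_alt.update(range(s - 1, e))

        # bumps live on the side that carries the variant residues
        has_prot = bool(rng.random() < cfg.protein_bump_prob)
        has_rna = bool(rng.random() < cfg.rna_bump_prob)
        bump_host = aid if var_alt else cid
        plant_prot = {bump_host} if has_prot else set()
        plant_rna = {bump_host} if has_rna else set()

        def draw_tracks(pid: str, seq: str, var_idx: set[int]):
            n = len(seq)
            sel = np.zeros(n, dtype=bool)
            if var_idx:
                sel[list(var_idx)] = True
            per = {}
            for name in ("disorder_meta", "disorder_fldpnn"):
                scores = np.where(sel, rng.beta(a_v, b_v, size=n), rng.beta(a_i, b_i, size=n))
                scores = np.clip(_smooth(scores, cfg.smooth_window), 0.0, 1.0)
                per[name] = ResidueTrack(
                    pid, name, scores.tolist(),
                    idr_mask=(scores > 0.5).tolist() if name == "disorder_fldpnn" else None,
                )
            for name, planted in (("protein_binding", pid in plant_prot),
                                  ("rna_binding", pid in plant_rna)):
                scores = rng.beta(*cfg.baseline_propensity, size=n)
                if planted and var_idx:
                    lo = min(var_idx)
                    width = min(cfg.bump_width, len(var_idx))
                    scores[lo : lo + width] = rng.uniform(cfg.bump_low, cfg.bump_high, size=width)
                per[name] = ResidueTrack(pid, name, np.clip(scores, 0, 1).tolist())
            tracks[pid] = per

        draw_tracks(cid, can, var_can)
        draw_tracks(aid, alt, var_alt)
        truth.track_regimes[aid] = {
            "protein_bump": has_prot,
            "rna_bump": has_rna,
        }

        # phosphosites on the canonical sequence
        sites = []
        base_p = cfg.ptm_density_per_100 / 100.0
        for pos0, aa in enumerate(can):
            if aa not in "STY":
                continue
            p = base_p * (cfg.deleted_ptm_enrichment if pos0 in var_can else 1.0)
            if rng.random() < min(p, 1.0):
                sites.append(PtmAnnotation(protein_id=cid, site=pos0 + 1,
                                           ptm_type="phosphorylation", source="synthetic"))
        annotations[cid] = sites
        truth.ptm_sites[cid] = [
            {"site": s.site, "in_deleted_region": (s.site - 1) in var_can} for s in sites
        ]
    return tracks, annotations, truth


# ---------------------------------------------------------------------------
# full synthetic study on disk
# ---------------------------------------------------------------------------

def simulate_study(cfg: SimulationConfig, outdir) -> dict:
    """Write a complete, internally consistent synthetic study to ``outdir``.

    Emits gene models (GTF), genome FASTA, junction TSV, canonical protein
    FASTA, peptide-intensity and design TSVs, residue-track and PTM TSVs,
    and a ground-truth JSON. Peptides, tracks and PTMs are generated for
    the canonical/alternative pairs realized by the genes whose
    non-reference splice form translates to tier 1, under the ids the
    pipeline itself will assign, so a pipeline run on these files closes
    end to end.
    """
    from pathlib import Path

    import dataclasses as _dc

    from .io import (write_design_table, write_fasta, write_gtf, write_json,
                     write_junction_table, write_peptide_table,
                     write_ptm_table, write_track_table)
    from .junctions import splice_transcript, translate_in_frame

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    models, genome, events, truth = simulate_gene_set(cfg)
    write_gtf(models, outdir / "genes.gtf")
    write_fasta(genome, outdir / "genome.fasta")
    write_junction_table(events, outdir / "junctions.tsv")
    write_fasta(truth.canonical_proteins, outdir / "canonical.fasta")

    # realized canonical/alternative pairs (tier-1 non-reference forms of
    # events that pass the read filter, matching pipeline -J numbering)
    pairs = []
    model_by_gene = {m.gene_id: m for m in models}
    for event in events:
        aid = f"{event.gene_id}-J1"
        if aid not in truth.pairs:
            continue
        if event.total_reads < 16:
            truth.pairs.pop(aid)
            continue
        form = "inclusion" if event.event_type == "RI" else "skip"
        cds, frame = splice_transcript(model_by_gene[event.gene_id], event, form, genome)
        alt = translate_in_frame(cds, frame).protein
        pairs.append((event.gene_id, truth.canonical_proteins[event.gene_id], aid, alt))

    rng = np.random.default_rng(cfg.seed + 10)
    matrix, design, pep_truth = simulate_peptide_matrix(pairs, cfg, rng=rng)
    truth.isoform_effects = pep_truth.isoform_effects
    truth.peptide_classes = pep_truth.peptide_classes
    write_peptide_table(matrix, outdir / "peptides.tsv")
    write_design_table(design, outdir / "design.tsv")

    tracks, annotations, truth = simulate_tracks_and_ptms(pairs, truth, cfg, rng=rng)
    write_track_table(tracks, outdir / "tracks.tsv")
    write_ptm_table(annotations, outdir / "ptm.tsv")

    def _clean(obj):
        if isinstance(obj, dict):
            return {str(k): _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        return obj

    write_json(_clean(_dc.asdict(truth)), outdir / "truth.json")
    return {
        "n_genes": len(models),
        "n_events": len(events),
        "n_pairs": len(pairs),
        "n_peptides": int(matrix.shape[0]),
        "n_samples": int(matrix.shape[1]),
    }
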