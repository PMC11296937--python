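"""Readers and writers for the pipeline's file formats.

GTF gene models (via gffutils), genome and protein FASTA (via Biopython),
and the flat TSV tables: junctions, peptide intensities, sample design,
residue tracks, PTM annotations, and variant regions.
"""
from __future__ import annotations

import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError, ValidationError
from .models import (GeneModel, IsoformPair, PtmAnnotation, ResidueTrack,
                     SampleDesign, SpliceEvent, Transcript)

# ---------------------------------------------------------------------------
# genome / protein FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by record id (first whitespace-delimited token)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GTF gene models
# ---------------------------------------------------------------------------

def write_gtf(models: Sequence[GeneModel], path) -> None:
    """Emit exon and CDS features with gene_id/transcript_id attributes.

    CDS features are written from the annotated CDS start to the end of
    each transcript's coding span; only the CDS start coordinate and frame
    are read back, so a single 1-bp CDS anchor feature per transcript is
    sufficient and unambiguous.
    """
    with open(path, "w") as fh:
        for model in models:
            for tx in model.transcripts:
                attrs = f'gene_id "{model.gene_id}"; transcript_id "{tx.transcript_id}";'
                for s, e in sorted(tx.exons):
                    fh.write(
                        f"{model.chromosome}\tspliceform\texon\t{s}\t{e}\t.\t"
                        f"{model.strand}\t.\t{attrs}\n"
                    )
                fh.write(
                    f"{model.chromosome}\tspliceform\tCDS\t{tx.cds_start}\t{tx.cds_start}\t.\t"
                    f"{model.strand}\t{tx.frame_offset}\t{attrs}\n"
                )


def read_gene_models(path) -> list[GeneModel]:
    """Parse a GTF into :class:`GeneModel` objects (gffutils, in-memory db)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    per_gene: dict[str, dict] = {}
    for feat in db.all_features():
        gene_id = feat.attributes["gene_id"][0]
        tx_id = feat.attributes["transcript_id"][0]
        g = per_gene.setdefault(gene_id, {"chrom": feat.seqid, "strand": feat.strand, "tx": {}})
        t = g["tx"].setdefault(tx_id, {"exons": [], "cds_start": None, "frame": 0})
        if feat.featuretype == "exon":
            t["exons"].append((feat.start, feat.end))
        elif feat.featuretype == "CDS":
            t["cds_start"] = feat.start
            t["frame"] = int(feat.frame) if feat.frame not in (None, ".") else 0

    models = []
    for gene_id in sorted(per_gene):
        g = per_gene[gene_id]
        txs = []
        for tx_id in sorted(g["tx"]):
            t = g["tx"][tx_id]
            if t["cds_start"] is None:
                raise ValidationError(f"transcript {tx_id} has no CDS feature")
            exons = sorted(t["exons"], reverse=(g["strand"] == "-"))
            txs.append(Transcript(transcript_id=tx_id, exons=tuple(exons),
                                  cds_start=t["cds_start"], frame_offset=t["frame"]))
        models.append(GeneModel(gene_id=gene_id, chromosome=g["chrom"],
                                strand=g["strand"], transcripts=tuple(txs)))
    return models


# ---------------------------------------------------------------------------
# junction TSV
# ---------------------------------------------------------------------------

def write_junction_table(events: Sequence[SpliceEvent], path) -> None:
    rows = []
    for e in events:
        rows.append({
            "event_id": e.event_id, "gene_id": e.gene_id, "event_type": e.event_type,
            "upstream_start": e.upstream[0], "upstream_end": e.upstream[1],
            "downstream_start": e.downstream[0], "downstream_end": e.downstream[1],
            "target1_start": e.target1[0], "target1_end": e.target1[1],
            "target2_start": e.target2[0] if e.target2 else "",
            "target2_end": e.target2[1] if e.target2 else "",
            "inclusion_reads": e.inclusion_reads, "skip_reads": e.skip_reads,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# peptide / design tables
# ---------------------------------------------------------------------------

def write_peptide_table(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis("peptide").to_csv(path, sep="\t", float_format="%.6g")


def read_peptide_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="peptide")


def write_design_table(design: Sequence[SampleDesign], path) -> None:
    pd.DataFrame(
        [{"sample_id": d.sample_id, "chamber": d.chamber, "donor": d.donor} for d in design]
    ).to_csv(path, sep="\t", index=False)


def read_design_table(path) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "chamber", "donor"):
        if col not in df.columns:
            raise ConfigurationError(f"design table missing column {col!r}")
    return [SampleDesign(r.sample_id, r.chamber, r.donor) for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# residue tracks / PTMs
# ---------------------------------------------------------------------------

def write_track_table(tracks: Mapping[str, Mapping[str, ResidueTrack]], path) -> None:
    """Long-format TSV: protein_id, track, position (1-based), score, idr."""
    rows = []
    for pid in sorted(tracks):
        for name in sorted(tracks[pid]):
            tr = tracks[pid][name]
            for pos, score in enumerate(tr.scores, start=1):
                rows.append({
                    "protein_id": pid, "track": name, "position": pos,
                    "score": round(float(score), 6),
                    "idr": int(tr.idr_mask[pos - 1]) if tr.idr_mask is not None else "",
                })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_track_table(path) -> dict[str, dict[str, ResidueTrack]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, ResidueTrack]] = {}
    for (pid, name), sub in df.groupby(["protein_id", "track"], sort=True):
        sub = sub.sort_values("position")
        if list(sub["position"]) != list(range(1, len(sub) + 1)):
            raise ValidationError(f"track {name} on {pid}: positions not contiguous from 1")
        mask = None
        if "idr" in sub.columns and sub["idr"].notna().all() and (sub["idr"].astype(str) != "").all():
            try:
                mask = [bool(int(v)) for v in sub["idr"]]
            except (TypeError, ValueError):
                mask = None
        out.setdefault(pid, {})[name] = ResidueTrack(pid, name, [float(v) for v in sub["score"]],
                                                     idr_mask=mask)
    return out


def write_ptm_table(annotations: Mapping[str, Sequence[PtmAnnotation]], path) -> None:
    rows = [
        {"protein_id": pid, "site": a.site, "ptm_type": a.ptm_type, "source": a.source}
        for pid in sorted(annotations)
        for a in annotations[pid]
    ]
    pd.DataFrame(rows, columns=["protein_id", "site", "ptm_type", "source"]).to_csv(
        path, sep="\t", index=False
    )


def read_ptm_table(path) -> dict[str, list[PtmAnnotation]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[PtmAnnotation]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.protein_id, []).append(
            PtmAnnotation(protein_id=r.protein_id, site=int(r.site),
                          ptm_type=str(r.ptm_type), source=str(r.source))
        )
    return out


# ---------------------------------------------------------------------------
# variant regions
# ---------------------------------------------------------------------------

def write_variant_regions(pairs: Sequence[IsoformPair], path) -> None:
    rows = []
    for p in pairs:
        for r in p.variant_regions:
            cs, ce = r.canonical_interval or ("", "")
            as_, ae = r.alternative_interval or ("", "")
            rows.append({
                "pair_id": p.alternative_id, "canonical_id": p.canonical_id,
                "kind": r.kind, "canonical_start": cs, "canonical_end": ce,
                "alt_start": as_, "alt_end": ae, "length": r.length,
                "terminal": int(r.terminal), "simple_flag": int(bool(p.simple_variant)),
            })
    cols = ["pair_id", "canonical_id", "kind", "canonical_start", "canonical_end",
            "alt_start", "alt_end", "length", "terminal", "simple_flag"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    """Deterministic JSON (sorted keys, fixed float formatting)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
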