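"""End-to-end orchestration: translate -> align -> quantify -> intersect.

`run_pipeline` consumes the file-based inputs (GTF, genome FASTA, junction
TSV, canonical FASTA, peptide/design TSVs, track/PTM TSVs), executes every
stage, and writes the differential table, junction-peptide deviation
table, variant-region table, enrichment report and a run manifest with
per-stage record counts.
"""
from __future__ import annotations

import dataclasses
import hashlib
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import align_isoform_pair
from .errors import ConfigurationError
from .features import summarize_enrichment
from .io import (read_design_table, read_fasta, read_gene_models,
                 read_peptide_table, read_ptm_table, read_track_table,
                 write_json, write_variant_regions)
from .junctions import (classify_and_emit, filter_junctions,
                        parse_junction_table, write_isoform_fasta)
from .quant import (assign_razor, classify_uniqueness, digest,
                    fit_differential_model, flag_junction_spanning,
                    normalize_intensities, peptide_ratio_zscore,
                    rollup_protein_intensity, va_log_ratios)


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run (YAML-loadable)."""

    gtf: str
    genome: str
    junctions: str
    canonical_fasta: str
    peptides: str
    design: str
    tracks: str
    ptm: str
    outdir: str
    min_total_reads: int = 16
    min_variant_len: int = 10
    fdr_primary: float = 0.05
    fdr_secondary: float = 0.10
    disorder_threshold: float = 0.5
    intensity_floor: float = 1e8
    prob_floor: float = 0.95
    pep_ceiling: float = 0.01
    quant_mode: str = "unique"
    seed: int = 0

    def validate(self) -> None:
        if self.quant_mode not in ("unique", "unique_razor"):
            raise ConfigurationError(f"unknown quant_mode {self.quant_mode!r}")
        for name in ("fdr_primary", "fdr_secondary", "disorder_threshold",
                     "prob_floor", "pep_ceiling"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0,1], got {v}")
        if self.min_total_reads < 0 or self.min_variant_len < 0:
            raise ConfigurationError("thresholds must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = repr(sorted(dataclasses.asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def filter_confident_features(
    table: pd.DataFrame,
    prob_floor: Optional[float] = 0.95,
    pep_ceiling: Optional[float] = 0.01,
    prob_column: str = "protein_probability",
    pep_column: str = "pep",
    strict_probability: bool = True,
) -> pd.DataFrame:
    """Drop features failing the identification-confidence filters.

    The probability floor is exclusive by default ("above" the floor); the
    posterior-error-probability ceiling is inclusive. Requesting a filter
    whose column is absent is a configuration error; pass ``None`` to skip
    a filter.
    """
    keep = pd.Series(True, index=table.index)
    if prob_floor is not None:
        if prob_column not in table.columns:
            raise ConfigurationError(f"probability filter requested but column "
                                     f"{prob_column!r} absent")
        p = table[prob_column].astype(float)
        keep &= (p > prob_floor) if strict_probability else (p >= prob_floor)
    if pep_ceiling is not None:
        if pep_column not in table.columns:
            raise ConfigurationError(f"PEP filter requested but column {pep_column!r} absent")
        keep &= table[pep_column].astype(float) <= pep_ceiling
    return table.loc[keep]


def run_pipeline(config: PipelineConfig, manifest_timestamps: bool = True) -> dict:
    """Execute every stage and write outputs under ``config.outdir``.

    Numeric outputs are byte-deterministic given identical config and
    inputs; wall-clock timestamps appear only in the run manifest (and can
    be suppressed with ``manifest_timestamps=False``).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages": {},
    }
    t0 = time.time()

    # stage 1: junctions
    events = parse_junction_table(config.junctions)
    kept = filter_junctions(events, config.min_total_reads)
    manifest["stages"]["junction_filter"] = {
        "in": len(events), "out": len(kept),
        "dropped_low_reads": len(events) - len(kept),
    }

    # stage 2: translation
    models = {m.gene_id: m for m in read_gene_models(config.gtf)}
    genome = read_fasta(config.genome)
    canonical = read_fasta(config.canonical_fasta)
    isoforms = []
    rejected = {"frameshift": 0, "premature_stop": 0, "no_frame": 0,
                "canonical_redundant": 0}
    for event in kept:
        if event.gene_id not in models:
            raise ConfigurationError(f"event {event.event_id} references unknown gene "
                                     f"{event.gene_id}")
        for iso in classify_and_emit(models[event.gene_id], event, genome,
                                     canonical_seqs=canonical):
            if iso.tier == 1:
                isoforms.append(iso)
            else:
                rejected[iso.rejection_reason] += 1
    event_coords = {e.event_id: min(e.target1[0], e.upstream[0]) for e in kept}
    db_records = write_isoform_fasta(isoforms, outdir / "isoforms.fasta",
                                     event_coords=event_coords)
    manifest["stages"]["translation"] = {
        "in": 2 * len(kept), "tier1": len(db_records), "rejected": rejected,
    }

    # stage 3: alignment & variant regions
    pairs = []
    for rec in db_records:
        if rec.gene_id not in canonical:
            continue
        pair = align_isoform_pair(canonical[rec.gene_id], rec.sequence,
                                  canonical_id=rec.gene_id, alternative_id=rec.isoform_id)
        pairs.append(pair)
    write_variant_regions(pairs, outdir / "variant_regions.tsv")
    manifest["stages"]["alignment"] = {
        "in": len(db_records), "out": len(pairs),
        "simple_variants": sum(1 for p in pairs if p.simple_variant),
    }

    # stage 4: digestion, uniqueness, razor, intensities
    database = dict(sorted(canonical.items()))
    database.update({rec.isoform_id: rec.sequence for rec in db_records})
    all_peptides = sorted({pep for seq in database.values() for pep in digest(seq)})
    records = classify_uniqueness(all_peptides, database)
    records = assign_razor(records, canonical_ids=set(canonical))
    intensity = read_peptide_table(config.peptides)
    design = read_design_table(config.design)
    pair_by_alt = {p.alternative_id: p for p in pairs}
    quantified = []
    for r in records:
        if r.sequence in intensity.index:
            r.intensities = {
                s: float(v) for s, v in intensity.loc[r.sequence].items() if pd.notna(v)
            }
            alt_parents = [pid for pid in sorted(r.parent_ids) if pid in pair_by_alt]
            r.junction_spanning = any(
                flag_junction_spanning(r.sequence, pair_by_alt[pid]) for pid in alt_parents
            )
            quantified.append(r)
    manifest["stages"]["peptides"] = {
        "digested": len(records),
        "quantified": len(quantified),
        "unique": sum(1 for r in quantified if r.uniqueness == "unique"),
        "razor": sum(1 for r in quantified if r.uniqueness == "razor"),
        "junction_spanning": sum(1 for r in quantified if r.junction_spanning),
    }

    # stage 5: roll-up + differential model
    rolled, n_pep, dropped = rollup_protein_intensity(
        quantified, mode=config.quant_mode, sample_ids=[d.sample_id for d in design]
    )
    normalized, norm_meta = normalize_intensities(rolled)
    results = fit_differential_model(normalized, design, quant_mode=config.quant_mode,
                                     n_peptides=n_pep)
    diff = pd.DataFrame([
        {
            "feature_id": r.feature_id,
            "log2FC": round(r.log2fc, 6) if np.isfinite(r.log2fc) else "",
            "t": round(r.t_stat, 6) if np.isfinite(r.t_stat) else "",
            "p_value": f"{r.p_value:.6g}" if np.isfinite(r.p_value) else "",
            "adj_p": f"{r.adj_p:.6g}" if np.isfinite(r.adj_p) else "",
            "n_peptides": r.n_peptides_used,
            "quant_mode": r.quant_mode,
            f"sig_fdr_{config.fdr_primary:g}": int(bool(np.isfinite(r.adj_p)
                                                        and r.adj_p <= config.fdr_primary)),
            f"sig_fdr_{config.fdr_secondary:g}": int(bool(np.isfinite(r.adj_p)
                                                          and r.adj_p <= config.fdr_secondary)),
        }
        for r in results
    ])
    diff.to_csv(outdir / "differential.tsv", sep="\t", index=False)
    manifest["stages"]["differential"] = {
        "proteins": len(results),
        "dropped_no_peptides": len(dropped),
        f"significant_fdr_{config.fdr_primary:g}": int(
            sum(1 for r in results if np.isfinite(r.adj_p) and r.adj_p <= config.fdr_primary)
        ),
        f"significant_fdr_{config.fdr_secondary:g}": int(
            sum(1 for r in results if np.isfinite(r.adj_p) and r.adj_p <= config.fdr_secondary)
        ),
    }

    # stage 6: junction-peptide deviation z-scores
    ratios = va_log_ratios(intensity, design, min_intensity=config.intensity_floor)
    zrows = []
    for pair in pairs:
        shared = [r.sequence for r in quantified
                  if pair.canonical_id in r.parent_ids and pair.alternative_id in r.parent_ids
                  and r.sequence in ratios.index]
        junction = [r.sequence for r in quantified
                    if r.parent_ids == frozenset({pair.alternative_id})
                    and r.sequence in ratios.index]
        shared_vals = [float(ratios[s]) for s in shared]
        for pep in junction:
            try:
                z = peptide_ratio_zscore(float(ratios[pep]), shared_vals)
            except Exception:
                continue
            zrows.append({"pair_id": pair.alternative_id, "peptide": pep,
                          "log2_va": round(float(ratios[pep]), 6),
                          "z": round(z, 6), "n_shared": len(shared_vals)})
    pd.DataFrame(zrows, columns=["pair_id", "peptide", "log2_va", "z", "n_shared"]).to_csv(
        outdir / "junction_peptides.tsv", sep="\t", index=False
    )
    manifest["stages"]["junction_zscores"] = {"peptides": len(zrows)}

    # stage 7: feature intersection
    tracks = read_track_table(config.tracks)
    annotations = read_ptm_table(config.ptm)
    covered = [p for p in pairs
               if p.canonical_id in tracks and p.alternative_id in tracks]
    report = summarize_enrichment(covered, tracks, annotations,
                                  disorder_threshold=config.disorder_threshold)
    report.fraction_table.round(6).to_csv(outdir / "enrichment_fractions.tsv",
                                          sep="\t", index=False)
    write_json(
        {
            "n_pairs": report.n_pairs,
            "n_variant_frac_ge_half": report.n_variant_frac_ge_half,
            "ks_disorder_D": report.ks_disorder[0],
            "ks_disorder_p": report.ks_disorder[1],
            "ks_protein_binding": report.ks_protein_binding,
            "ks_rna_binding": report.ks_rna_binding,
            "function_classes": report.function_classes,
            "motif_counts": report.motif_counts,
            "ptm_counts": report.ptm_counts,
            "underpowered": report.underpowered,
        },
        outdir / "enrichment_report.json",
    )
    manifest["stages"]["feature_intersection"] = {
        "pairs_in": len(pairs), "pairs_with_tracks": len(covered),
    }

    if manifest_timestamps:
        manifest["started_unix"] = int(t0)
        manifest["elapsed_s"] = round(time.time() - t0, 3)
    write_json(manifest, outdir / "run_manifest.json")
    return manifest
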