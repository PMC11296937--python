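"""Peptide-level quantification and chamber-biased differential usage.

Digestion -> uniqueness/razor classification -> intensity normalization ->
protein roll-up -> donor-adjusted no-intercept linear model with
moderated variance and Benjamini-Hochberg FDR. Also the junction-peptide
ventricle/atrium deviation z-score used to corroborate isoform-specific
regulation at the peptide level.
"""
from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pyteomics import parser as _pyt_parser
from scipy import stats

from .errors import ContractError, UndefinedStatistic, ValidationError
from .models import DifferentialResult, IsoformPair, PeptideRecord, SampleDesign

TRYPSIN_RULE = _pyt_parser.expasy_rules["trypsin"]


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

def digest(
    sequence: str,
    missed_cleavages: int = 2,
    min_len: int = 7,
    max_len: int = 50,
) -> list[str]:
    """Tryptic peptides of ``sequence`` (cleave after K/R, not before P).

    Includes 0..``missed_cleavages`` variants, a protein N-terminal
    Met-cleaved variant of each peptide starting at position 1, and a
    length filter. Order is by start position, then length; duplicates
    (from repeated sequence) are kept once.
    """
    sequence = sequence.upper()
    pieces = [
        (pos, pep)
        for pos, pep in _pyt_parser.icleave(
            sequence, TRYPSIN_RULE, missed_cleavages=missed_cleavages, min_length=1
        )
    ]
    out: list[str] = []
    seen: set[str] = set()
    for pos, pep in sorted(pieces, key=lambda t: (t[0], len(t[1]))):
        variants = [pep]
        if pos == 0 and pep.startswith("M"):
            variants.append(pep[1:])
        for v in variants:
            if min_len <= len(v) <= max_len and v not in seen:
                seen.add(v)
                out.append(v)
    return out


# ---------------------------------------------------------------------------
# uniqueness & razor
# ---------------------------------------------------------------------------

def classify_uniqueness(
    peptides: Iterable[str],
    database: Mapping[str, str],
    equate_il: bool = False,
) -> list[PeptideRecord]:
    """Assign parent sets and uniqueness classes by exact substring search.

    A peptide's parents are all database entries containing it as an exact
    substring. I and L are distinct by default; ``equate_il`` folds both to
    L before matching.
    """
    if not database:
        raise ContractError("database must be non-empty")

    def fold(s: str) -> str:
        return s.replace("I", "L") if equate_il else s

    folded_db = {pid: fold(seq.upper()) for pid, seq in database.items()}
    records = []
    for pep in peptides:
        fp = fold(pep.upper())
        parents = frozenset(pid for pid, seq in folded_db.items() if fp in seq)
        uniqueness = "unique" if len(parents) == 1 else "shared"
        records.append(PeptideRecord(sequence=pep, parent_ids=parents, uniqueness=uniqueness))
    return records


def assign_razor(
    records: Sequence[PeptideRecord],
    canonical_ids: Optional[set[str]] = None,
) -> list[PeptideRecord]:
    """Assign each shared peptide to a single razor parent.

    The razor parent is the candidate with the most unique peptides; ties
    prefer the canonical isoform (reflecting that canonical forms are
    typically the more abundant), then the lexicographically smallest id.
    Shared peptides gain ``uniqueness == "razor"``; unique peptides are
    untouched. ``canonical_ids`` defaults to ids without a ``-J`` suffix.
    """
    if canonical_ids is None:
        canonical_ids = {
            pid for r in records for pid in r.parent_ids if "-J" not in pid
        }
    unique_counts: dict[str, int] = {}
    for r in records:
        if r.uniqueness == "unique":
            (pid,) = r.parent_ids
            unique_counts[pid] = unique_counts.get(pid, 0) + 1

    out = []
    for r in records:
        if r.uniqueness == "unique" or not r.parent_ids:
            out.append(r)
            continue
        best = min(
            sorted(r.parent_ids),
            key=lambda pid: (
                -unique_counts.get(pid, 0),
                0 if pid in canonical_ids else 1,
                pid,
            ),
        )
        out.append(
            PeptideRecord(
                sequence=r.sequence,
                parent_ids=r.parent_ids,
                uniqueness="razor",
                razor_parent=best,
                junction_spanning=r.junction_spanning,
                intensities=r.intensities,
            )
        )
    return out


# ---------------------------------------------------------------------------
# junction-spanning flag
# ---------------------------------------------------------------------------

def _alt_region_geometry(pair: IsoformPair):
    """Per variant region, its footprint on the alternative sequence.

    Returns a list of ("span", start, end) for regions with alternative
    residues, or ("junction", j) for pure deletions, where the deleted
    block sits between alternative residues j and j+1.
    """
    geoms = []
    ai = 0
    rc, ra = pair.aligned_canonical, pair.aligned_alternative
    col_alt_count = []
    for y in ra:
        if y != "-":
            ai += 1
        col_alt_count.append(ai)
    # map each region back to its columns by recomputing runs of non-match
    col = 0
    for region in pair.variant_regions:
        if region.alternative_interval is not None:
            geoms.append(("span", *region.alternative_interval))
        else:
            # deletion: alternative residues seen before the deleted block
            cs, _ = region.canonical_interval
            # column index where canonical residue cs sits
            cnt = 0
            for idx, x in enumerate(rc):
                if x != "-":
                    cnt += 1
                    if cnt == cs:
                        col = idx
                        break
            j = col_alt_count[col - 1] if col > 0 else 0
            geoms.append(("junction", j))
    return geoms


def flag_junction_spanning(peptide: str, pair: IsoformPair) -> bool:
    """True iff the peptide's span intersects or crosses a variant region.

    The peptide is located in the alternative sequence (all occurrences
    considered). Insertion/substitution regions count when the peptide
    interval overlaps them; deletions count when the peptide covers both
    residues flanking the deletion junction. A peptide merely abutting a
    region does not count.
    """
    pep = peptide.upper()
    alt = pair.alternative_seq
    starts = []
    k = alt.find(pep)
    while k != -1:
        starts.append(k)
        k = alt.find(pep, k + 1)
    if not starts:
        raise ContractError(f"peptide {peptide!r} not found in {pair.alternative_id}")
    geoms = _alt_region_geometry(pair)
    n_alt = len(alt)
    for s0 in starts:
        ps, pe = s0 + 1, s0 + len(pep)
        for geom in geoms:
            if geom[0] == "span":
                _, rs, re = geom
                if ps <= re and rs <= pe:
                    return True
            else:
                _, j = geom
                if 1 <= j < n_alt and ps <= j and pe >= j + 1:
                    return True
    return False


# ---------------------------------------------------------------------------
# normalization & roll-up
# ---------------------------------------------------------------------------

def normalize_intensities(matrix: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """log2 transform + per-sample median centering.

    Nonpositive and missing entries propagate as NaN. Returns the
    normalized matrix and the per-sample medians removed, for reporting.
    """
    logm = np.log2(matrix.where(matrix > 0))
    all_missing = logm.columns[logm.isna().all(axis=0)]
    if len(all_missing):
        raise ValidationError(
            f"sample(s) with no observed intensities: {list(all_missing)}"
        )
    medians = logm.median(axis=0, skipna=True)
    return logm.sub(medians, axis=1), {"sample_medians": medians.to_dict()}


def rollup_protein_intensity(
    records: Sequence[PeptideRecord],
    mode: str = "unique",
    sample_ids: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Sum admissible peptide intensities per protein per sample.

    ``mode="unique"`` admits only unique peptides (credited to their single
    parent); ``mode="unique_razor"`` additionally admits razor peptides
    (credited to their razor parent). Returns the protein x sample matrix,
    per-protein admissible peptide counts, and ids of proteins dropped for
    having no admissible peptides.
    """
    if mode not in ("unique", "unique_razor"):
        raise ValueError(f"unknown quant mode {mode!r}")
    if sample_ids is None:
        seen: dict[str, None] = {}
        for r in records:
            for s in r.intensities:
                seen.setdefault(s, None)
        sample_ids = list(seen)

    sums: dict[str, dict[str, float]] = {}
    counts: dict[str, int] = {}
    all_parents: set[str] = set()
    for r in records:
        all_parents.update(r.parent_ids)
        if r.uniqueness == "unique":
            (target,) = r.parent_ids
        elif mode == "unique_razor" and r.uniqueness == "razor" and r.razor_parent:
            target = r.razor_parent
        else:
            continue
        counts[target] = counts.get(target, 0) + 1
        row = sums.setdefault(target, {})
        for s, v in r.intensities.items():
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                row[s] = row.get(s, 0.0) + v

    proteins = sorted(counts)
    mat = pd.DataFrame(np.nan, index=proteins, columns=list(sample_ids), dtype=float)
    for pid in proteins:
        for s, v in sums.get(pid, {}).items():
            mat.loc[pid, s] = v
    dropped = sorted(all_parents - set(proteins))
    return mat, pd.Series(counts).reindex(proteins), dropped


# ---------------------------------------------------------------------------
# differential model
# ---------------------------------------------------------------------------

def _design_matrix(design: Sequence[SampleDesign]):
    donors = sorted({d.donor for d in design})
    if len(donors) < 2:
        raise ContractError("need >= 2 donors for the donor-adjusted model")
    chambers_per_donor = {}
    for d in design:
        chambers_per_donor.setdefault(d.donor, set()).add(d.chamber)
    if sum(1 for cs in chambers_per_donor.values() if len(cs) == 2) < 2:
        raise ContractError("need >= 2 donors observed in both chambers")
    cols = ["chamber_atrium", "chamber_ventricle"] + [f"donor_{d}" for d in donors[1:]]
    X = np.zeros((len(design), len(cols)))
    for i, d in enumerate(design):
        X[i, 0 if d.chamber == "atrium" else 1] = 1.0
        if d.donor != donors[0]:
            X[i, 2 + donors[1:].index(d.donor)] = 1.0
    return X, cols


def _moments_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments prior (d0, s0^2) for scaled-F variance shrinkage.

    Models s_i^2 ~ s0^2 * F(d_i, d0) with a common residual df d (mean of
    d_i). Returns (inf, mean(s2)) when the observed spread is no larger
    than sampling noise alone explains (complete pooling).
    """
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2:
        return np.inf, float(np.mean(s2)) if len(s2) else 1.0
    d = float(np.mean(df))
    m = float(np.mean(s2))
    v = float(np.var(s2, ddof=1))
    r = v / (m * m)
    if r * d <= 2.0:
        return np.inf, m
    d0 = (4.0 * r * d + 2.0 * d - 4.0) / (r * d - 2.0)
    if d0 <= 4.0:
        # heavy-tailed prior; keep but floor to keep s0 finite
        d0 = max(d0, 2.5)
    s0 = m * (d0 - 2.0) / d0 if np.isfinite(d0) else m
    return d0, max(s0, 1e-12)


def fit_differential_model(
    matrix: pd.DataFrame,
    design: Sequence[SampleDesign],
    moderate: bool = True,
    quant_mode: str = "unique",
    n_peptides: Optional[pd.Series] = None,
) -> list[DifferentialResult]:
    """Per-protein chamber contrast with donor adjustment.

    Fits, for each protein row of the normalized log2 ``matrix``, a
    no-intercept least-squares model with one mean per chamber plus donor
    indicator effects, and reports the ventricle - atrium contrast, its
    (optionally moderated) t statistic, two-sided p value and BH-adjusted
    p across all tested proteins. Proteins observed in fewer than 2
    samples per chamber are skipped (reported with NaN statistics).
    """
    sample_order = [d.sample_id for d in design]
    missing_cols = [s for s in sample_order if s not in matrix.columns]
    if missing_cols:
        raise ContractError(f"design samples absent from matrix: {missing_cols}")
    Y = matrix[sample_order].to_numpy(dtype=float)
    X_full, _ = _design_matrix(design)
    chambers = np.array([d.chamber for d in design])

    n_prot = Y.shape[0]
    log2fc = np.full(n_prot, np.nan)
    s2 = np.full(n_prot, np.nan)
    dfs = np.full(n_prot, np.nan)
    c_var_unit = np.full(n_prot, np.nan)  # c' (X'X)^-1 c
    skipped_reason: dict[int, str] = {}

    complete = ~np.isnan(Y).any(axis=1)
    contrast_len = X_full.shape[1]

    def contrast_vec(ncols: int) -> np.ndarray:
        c = np.zeros(ncols)
        c[0], c[1] = -1.0, 1.0
        return c

    # fast path: all-complete rows share one design
    if complete.any():
        XtX_inv = np.linalg.pinv(X_full.T @ X_full)
        H = XtX_inv @ X_full.T
        B = H @ Y[complete].T                     # coef x proteins
        resid = Y[complete].T - X_full @ B
        rank = np.linalg.matrix_rank(X_full)
        dof = X_full.shape[0] - rank
        if dof < 1:
            raise ContractError("design leaves no residual degrees of freedom")
        c = contrast_vec(contrast_len)
        idx = np.where(complete)[0]
        log2fc[idx] = c @ B
        s2[idx] = (resid ** 2).sum(axis=0) / dof
        dfs[idx] = dof
        c_var_unit[idx] = float(c @ XtX_inv @ c)

    for i in np.where(~complete)[0]:
        obs = ~np.isnan(Y[i])
        for ch in ("atrium", "ventricle"):
            if (obs & (chambers == ch)).sum() < 2:
                skipped_reason[i] = f"fewer than 2 observed {ch} samples"
                break
        if i in skipped_reason:
            continue
        sub_design = [d for d, o in zip(design, obs) if o]
        try:
            Xs, _ = _design_matrix(sub_design)
        except ContractError as exc:
            skipped_reason[i] = str(exc)
            continue
        ys = Y[i, obs]
        rank = np.linalg.matrix_rank(Xs)
        dof = Xs.shape[0] - rank
        if dof < 1:
            skipped_reason[i] = "no residual degrees of freedom"
            continue
        XtX_inv = np.linalg.pinv(Xs.T @ Xs)
        beta = XtX_inv @ Xs.T @ ys
        res = ys - Xs @ beta
        c = contrast_vec(Xs.shape[1])
        log2fc[i] = c @ beta
        s2[i] = (res ** 2).sum() / dof
        dfs[i] = dof
        c_var_unit[i] = float(c @ XtX_inv @ c)

    tested = np.isfinite(log2fc)
    if moderate:
        d0, s0 = _moments_prior(s2[tested], dfs[tested])
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0)
            df_total = np.full_like(dfs, np.inf)
        else:
            s2_post = (d0 * s0 + dfs * s2) / (d0 + dfs)
            df_total = dfs + d0
    else:
        s2_post = s2
        df_total = dfs

    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(np.maximum(s2_post * c_var_unit, 0.0))
        tstat = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), np.inf * np.sign(log2fc))
        tstat = np.where((se == 0) & (log2fc == 0), 0.0, tstat)
    pvals = np.full(n_prot, np.nan)
    for i in np.where(tested)[0]:
        if np.isinf(df_total[i]):
            pvals[i] = 2.0 * stats.norm.sf(abs(tstat[i]))
        else:
            pvals[i] = 2.0 * stats.t.sf(abs(tstat[i]), df_total[i])

    adj = np.full(n_prot, np.nan)
    adj[tested] = adjust_bh(pvals[tested])

    results = []
    for i, pid in enumerate(matrix.index):
        npep = int(n_peptides.get(pid, 0)) if n_peptides is not None else 0
        results.append(
            DifferentialResult(
                feature_id=str(pid),
                log2fc=float(log2fc[i]),
                t_stat=float(tstat[i]) if tested[i] else float("nan"),
                p_value=float(pvals[i]) if tested[i] else float("nan"),
                adj_p=float(adj[i]) if tested[i] else float("nan"),
                n_peptides_used=npep,
                quant_mode=quant_mode,
            )
        )
    return results


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ContractError("p values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(n)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


# ---------------------------------------------------------------------------
# junction-peptide deviation statistic
# ---------------------------------------------------------------------------

def peptide_ratio_zscore(target_ratio: float, shared_ratios: Sequence[float]) -> float:
    """z score of a target peptide's V/A log-ratio against shared peptides.

    z = (target - mean(shared)) / sample SD(shared). Requires >= 3 shared
    ratios with positive spread; otherwise the statistic is undefined.
    """
    shared = np.asarray(shared_ratios, dtype=float)
    shared = shared[np.isfinite(shared)]
    if len(shared) < 3:
        raise UndefinedStatistic("need >= 3 shared-peptide ratios")
    sd = float(np.std(shared, ddof=1))
    if sd == 0:
        raise UndefinedStatistic("shared-peptide ratios have zero spread")
    return (float(target_ratio) - float(np.mean(shared))) / sd


def va_log_ratios(
    matrix: pd.DataFrame,
    design: Sequence[SampleDesign],
    min_intensity: float = 1e8,
    per_donor: bool = False,
) -> pd.Series:
    """Per-peptide log2 ventricle/atrium ratio of mean raw intensities.

    Peptides whose mean observed intensity falls below ``min_intensity``
    are dropped (the analysis floor for the deviation statistic). With
    ``per_donor`` the ratio is the mean of within-donor log ratios over
    donors with both chambers observed; otherwise pooled chamber means.
    """
    vent = [d.sample_id for d in design if d.chamber == "ventricle"]
    atr = [d.sample_id for d in design if d.chamber == "atrium"]
    keep = matrix.mean(axis=1, skipna=True) >= min_intensity
    sub = matrix.loc[keep]
    if not per_donor:
        vm = sub[vent].mean(axis=1, skipna=True)
        am = sub[atr].mean(axis=1, skipna=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.log2(vm / am)
        return pd.Series(out, index=sub.index).replace([np.inf, -np.inf], np.nan).dropna()
    donors = sorted({d.donor for d in design})
    ratios = []
    for donor in donors:
        v = [d.sample_id for d in design if d.donor == donor and d.chamber == "ventricle"]
        a = [d.sample_id for d in design if d.donor == donor and d.chamber == "atrium"]
        if not v or not a:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios.append(np.log2(sub[v].mean(axis=1) / sub[a].mean(axis=1)))
    if not ratios:
        raise ContractError("no donor has samples in both chambers")
    return (
        pd.concat(ratios, axis=1)
        .replace([np.inf, -np.inf], np.nan)
        .mean(axis=1, skipna=True)
        .dropna()
    )
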