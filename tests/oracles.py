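"""Independent brute-force oracles used to validate pipeline operations.

These deliberately avoid the package's own code paths: transcripts are
re-derived by direct string slicing of the chromosome, translation goes
through Bio.Seq, and the single-indel locator uses prefix/suffix matching
rather than alignment.
"""
from __future__ import annotations

import re

from Bio.Seq import Seq


def oracle_spliced_protein(genome: dict, chrom: str, strand: str,
                           exons, cds_start: int) -> str:
    """Translate an exon-interval list by direct slicing + Bio.Seq."""
    seq = "".join(genome[chrom][s - 1 : e] for s, e in sorted(exons))
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    order = sorted(exons) if strand == "+" else sorted(exons, reverse=True)
    off = 0
    for s, e in order:
        if s <= cds_start <= e:
            off += (cds_start - s) if strand == "+" else (e - cds_start)
            break
        off += e - s + 1
    cds = seq[off:]
    protein = str(Seq(cds[: 3 * (len(cds) // 3)]).translate())
    return protein.split("*")[0]


def oracle_single_indel(canonical: str, alternative: str):
    """Locate a single indel by longest common prefix/suffix matching.

    Returns (kind, canonical_interval, alternative_interval) with 1-based
    inclusive intervals, preferring the leftmost placement. Assumes the
    two sequences differ by exactly one insertion or deletion.
    """
    if len(canonical) == len(alternative):
        raise ValueError("sequences differ by zero net length; not a pure indel")
    short, long_ = ((canonical, alternative) if len(canonical) < len(alternative)
                    else (alternative, canonical))
    d = len(long_) - len(short)
    pre = 0
    while pre < len(short) and short[pre] == long_[pre]:
        pre += 1
    suf = 0
    while suf < len(short) - pre and short[-1 - suf] == long_[-1 - suf]:
        suf += 1
    # leftmost placement: shrink the prefix while the indel content allows
    start = len(short) - suf
    if start < pre:
        pre = start
    interval = (pre + 1, pre + d)
    if len(canonical) < len(alternative):
        return ("insertion", None, interval)
    return ("deletion", interval, None)


def oracle_motif_regex(sequence: str, rule: str) -> list[int]:
    """Regex-based N-glycosylation motif scan over the whole sequence."""
    pattern = r"(?=N.[ST])" if rule == "NXS_T_literal" else r"(?=N[^P][ST])"
    return [m.start() + 1 for m in re.finditer(pattern, sequence)]


def oracle_parent_scan(peptide: str, database: dict) -> frozenset:
    """Regex-based substring scan (independent of str.__contains__ path)."""
    pat = re.compile(re.escape(peptide))
    return frozenset(pid for pid, seq in database.items() if pat.search(seq))


def oracle_ks_exact_p(a, b) -> float:
    """Exact two-sided two-sample KS p by full enumeration of orderings."""
    from itertools import combinations
    from math import comb

    m, n = len(a), len(b)
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == m + n, "oracle requires tie-free data"

    def d_num(idx_a):
        ca = cb = 0
        best = 0
        for i in range(m + n):
            if i in idx_a:
                ca += 1
            else:
                cb += 1
            best = max(best, abs(ca * n - cb * m))
        return best

    obs = d_num({pooled.index(x) for x in a})
    extreme = sum(1 for idx in combinations(range(m + n), m) if d_num(set(idx)) >= obs)
    return extreme / comb(m + n, m)
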