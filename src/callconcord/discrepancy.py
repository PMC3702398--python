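"""Descriptive comparisons of multi-caller call sets.

Venn-style pattern counts, agreement histograms (how many callers detect
each site), caller-unique and caller-missed sets, depth/vaf stratification
of mutation sets, raw-VCF presence checks for sites a caller missed, and a
normal-sample vaf screen.  All summaries derive from the same site→pattern
map, so their cross-totals agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .callset_io import (
    CallerRecord,
    Pattern,
    PatternCounts,
    VariantSite,
    all_patterns,
)

__all__ = [
    "AgreementSummary",
    "venn_counts",
    "agreement_summary",
    "agreement_from_counts",
    "unique_and_missed",
    "depth_vaf_strata",
    "raw_vcf_presence",
    "normal_vaf_screen",
    "DEFAULT_DEPTH_BINS",
    "DEFAULT_VAF_BINS",
]

# bin edges echoing the depth/vaf thresholds the figures emphasize
DEFAULT_DEPTH_BINS = (0, 20, 40, 100, 200, np.inf)
DEFAULT_VAF_BINS = (0.0, 0.1, 0.2, 0.5, 1.0)


@dataclass
class AgreementSummary:
    """Histograms over the number of detecting callers (1..K)."""

    union: dict[int, int]
    per_caller: dict[str, dict[int, int]]
    K: int

    @property
    def total_detected(self) -> int:
        return sum(self.union.values())


def venn_counts(patterns: Mapping[VariantSite, Pattern]) -> dict[Pattern, int]:
    """Count sites per nonzero detection pattern (all 2^K - 1 cells present)."""
    if not patterns:
        return {}
    K = len(next(iter(patterns.values())))
    counts = {p: 0 for p in all_patterns(K) if any(p)}
    for pat in patterns.values():
        counts[pat] += 1
    return counts


def _counts_by_pattern(
    source: Mapping[VariantSite, Pattern] | PatternCounts,
) -> tuple[dict[Pattern, int], int]:
    if isinstance(source, PatternCounts):
        return {p: c for p, c in source.counts.items() if any(p)}, source.K
    vc = venn_counts(source)
    K = len(next(iter(vc))) if vc else 0
    return vc, K


def agreement_from_counts(counts: PatternCounts) -> AgreementSummary:
    """Agreement histograms computed directly from a pattern-count table."""
    cells, K = _counts_by_pattern(counts)
    union = {m: 0 for m in range(1, K + 1)}
    per = {k: {m: 0 for m in range(1, K + 1)} for k in range(K)}
    for pat, c in cells.items():
        m = sum(pat)
        union[m] += c
        for k in range(K):
            if pat[k]:
                per[k][m] += c
    return AgreementSummary(
        union=union,
        per_caller={f"caller{k}": h for k, h in per.items()},
        K=K,
    )


def agreement_summary(
    patterns: Mapping[VariantSite, Pattern],
    caller_order: Sequence[str],
) -> AgreementSummary:
    """Classify each caller's sites (and the union) by number of detectors."""
    K = len(caller_order)
    if K < 2:
        raise ValueError("agreement summary needs K >= 2 callers")
    union = {m: 0 for m in range(1, K + 1)}
    per = {c: {m: 0 for m in range(1, K + 1)} for c in caller_order}
    for pat in patterns.values():
        m = sum(pat)
        union[m] += 1
        for k, caller in enumerate(caller_order):
            if pat[k]:
                per[caller][m] += 1
    return AgreementSummary(union=union, per_caller=per, K=K)


def unique_and_missed(
    patterns: Mapping[VariantSite, Pattern],
    caller_order: Sequence[str],
) -> dict[str, dict[str, set[VariantSite]]]:
    """Per caller: sites it alone called ("only"), sites it alone missed ("all_but")."""
    K = len(caller_order)
    if K < 2:
        raise ValueError("needs K >= 2 callers")
    out = {c: {"only": set(), "all_but": set()} for c in caller_order}
    for site, pat in patterns.items():
        s = sum(pat)
        if s == 1:
            out[caller_order[pat.index(1)]]["only"].add(site)
        elif s == K - 1:
            out[caller_order[pat.index(0)]]["all_but"].add(site)
    return out


def depth_vaf_strata(
    sites: Iterable[VariantSite],
    evidence: pd.DataFrame,
    depth_bins: Sequence[float] = DEFAULT_DEPTH_BINS,
    vaf_bins: Sequence[float] = DEFAULT_VAF_BINS,
    depth_col: str = "exome_tumor_depth",
    alt_col: str = "exome_tumor_alt",
) -> tuple[pd.DataFrame, int]:
    """2-D (depth x vaf) count grid for a mutation set; returns (grid, n_missing).

    Each evaluable site lands in exactly one cell; sites absent from the
    evidence table or with zero depth go to the not-evaluable margin.
    """
    ev = evidence.set_index(["patient_id", "chrom", "pos", "alt"])
    depths, vafs = [], []
    n_missing = 0
    for site in sites:
        key = (site.patient_id, site.chrom, site.pos, site.alt)
        if key not in ev.index:
            n_missing += 1
            continue
        row = ev.loc[key]
        d = float(row[depth_col])
        if d <= 0:
            n_missing += 1
            continue
        depths.append(d)
        vafs.append(float(row[alt_col]) / d)
    d_cut = pd.cut(depths, bins=list(depth_bins), right=False)
    v_cut = pd.cut(vafs, bins=list(vaf_bins), right=True, include_lowest=True)
    grid = pd.crosstab(d_cut, v_cut, dropna=False)
    grid.index.name = "depth"
    grid.columns.name = "vaf"
    return grid, n_missing


def raw_vcf_presence(
    target_sites: Iterable[VariantSite],
    raw_records: Mapping[str, Iterable[CallerRecord]],
) -> dict[str, float]:
    """Per caller, fraction of target sites present in its raw (pre-filter) VCF.

    The complement is mass the caller never scanned at all — a different
    failure mode from scanning a site and filtering it out.
    """
    targets = set(target_sites)
    out: dict[str, float] = {}
    for caller, records in raw_records.items():
        present = {r.site for r in records} & targets
        out[caller] = len(present) / len(targets) if targets else float("nan")
    return out


def normal_vaf_screen(
    sites: Iterable[VariantSite],
    evidence: pd.DataFrame,
    cutoff: float = 0.02,
) -> float:
    """Fraction of sites whose normal exome vaf exceeds the cutoff.

    A normal-sample variant allele is about the minimum requirement for a
    site to be a germline rather than somatic call, so this bounds how much
    somatic/germline confusion can explain caller disagreement.
    """
    ev = evidence.set_index(["patient_id", "chrom", "pos", "alt"])
    vals = []
    for site in sites:
        key = (site.patient_id, site.chrom, site.pos, site.alt)
        if key not in ev.index:
            continue
        row = ev.loc[key]
        d = float(row["exome_normal_depth"])
        if d > 0:
            vals.append(float(row["exome_normal_alt"]) / d)
    if not vals:
        return float("nan")
    return float(np.mean(np.asarray(vals) > cutoff))
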