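"""Per-site validation schemes and strand-bias artifact filters.

Four labeling schemes, each turning sequencing evidence into a per-site
status:

* **Gold standard** — independent deep sequencing (~3x the exome coverage)
  of the same tumor/normal pair: somatic iff deep tumor vaf > 10% and deep
  normal vaf < 2%; among non-somatic sites, wildtype iff both vafs < 2%.
* **Signed-quality (pseudo) validation** — per-sample genotyper quality
  scores with the sign flipped when no variant allele was found, so a large
  positive tumor score supports a variant and a large negative normal score
  supports homozygous reference.  Pseudo-positive iff tumor score > q_t and
  normal score < q_n.
* **RNA-seq validation** — tumor RNA vaf > f_t with normal exome vaf < f_n,
  restricted to sites with adequate RNA coverage (depth >= 10x by default).
* **Strand-bias filters** — artifactual variant alleles tend to sit almost
  entirely on one strand while the reference allele does not; two filter
  variants match the exome-only and exome+RNA settings.

All threshold comparisons are strict (>, <) so ties fall to the negative
side; a vaf at zero depth is undefined and yields ``not_evaluable``, never
a silent pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "ValidationStatus",
    "Thresholds",
    "signed_quality",
    "gs_validate",
    "gs_validate_alt",
    "reconcile_gs",
    "pseudo_validate",
    "rna_validate",
    "exome_strand_filter",
    "rna_strand_filter",
    "strand_bias_flag",
    "build_evaluation_set",
]


class ValidationStatus(str, Enum):
    SOMATIC = "somatic"
    NON_SOMATIC = "non_somatic"
    WILDTYPE = "wildtype"
    GERMLINE = "germline"
    UNKNOWN = "unknown"
    NONMAF = "nonMAF"
    NOT_ATTEMPTED = "not_attempted"
    AMBIGUOUS = "ambiguous"
    NOT_EVALUABLE = "not_evaluable"
    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass
class Thresholds:
    """All scheme thresholds, defaulting to the headline analysis values."""

    q_t: float = 200.0       # tumor signed-quality cut (pseudo scheme)
    q_n: float = -50.0       # normal signed-quality cut (pseudo scheme)
    f_t: float = 0.10        # tumor RNA vaf cut
    f_n: float = 0.02        # normal exome vaf cut
    gs_tumor_vaf: float = 0.10
    gs_normal_vaf: float = 0.02
    gs_q_tumor: float = 200.0   # alternative gold-standard criterion
    gs_q_normal: float = -100.0
    rna_min_depth: int = 10
    eval_min_deep_depth: int = 100
    eval_min_exome_depth: int = 10

    def __post_init__(self) -> None:
        if not (0 <= self.f_t <= 1 and 0 <= self.f_n <= 1):
            raise ValueError("f_t and f_n must be fractions in [0, 1]")


def signed_quality(raw_quality: float, variant_found: bool) -> float:
    """Sign a non-negative call quality: negative when no variant allele.

    A large negative value is strong support for the *non*-existence of a
    variant allele; zero is uninformative either way.
    """
    if raw_quality < 0:
        raise ValueError(f"raw quality must be non-negative, got {raw_quality}")
    return raw_quality if variant_found else -raw_quality


def gs_validate(
    tumor_deep_vaf: float | None,
    normal_deep_vaf: float | None,
    thresholds: Thresholds | None = None,
) -> ValidationStatus:
    """Gold-standard deep-seq rule: somatic iff tumor vaf > 10% and normal < 2%.

    Among non-somatic sites, wildtype iff both vafs < 2%.  An undefined vaf
    (zero deep coverage) makes the site not evaluable.
    """
    t = thresholds or Thresholds()
    if tumor_deep_vaf is None or normal_deep_vaf is None or np.isnan(tumor_deep_vaf) or np.isnan(normal_deep_vaf):
        return ValidationStatus.NOT_EVALUABLE
    if tumor_deep_vaf > t.gs_tumor_vaf and normal_deep_vaf < t.gs_normal_vaf:
        return ValidationStatus.SOMATIC
    if tumor_deep_vaf < t.gs_normal_vaf and normal_deep_vaf < t.gs_normal_vaf:
        return ValidationStatus.WILDTYPE
    return ValidationStatus.NON_SOMATIC


def gs_validate_alt(
    signed_q_tumor: float,
    signed_q_normal: float,
    thresholds: Thresholds | None = None,
) -> ValidationStatus:
    """Alternative gold-standard criterion on signed quality scores."""
    t = thresholds or Thresholds()
    if signed_q_tumor > t.gs_q_tumor and signed_q_normal < t.gs_q_normal:
        return ValidationStatus.SOMATIC
    return ValidationStatus.NON_SOMATIC


def reconcile_gs(
    status_vaf: ValidationStatus, status_q: ValidationStatus
) -> ValidationStatus:
    """Combine the two gold-standard criteria; disagreement is ambiguous.

    Sites where the vaf rule and the signed-quality rule disagree on
    somatic vs non-somatic are excluded from evaluation sets rather than
    adjudicated.  The vaf rule's wildtype refinement takes precedence when
    both agree the site is not somatic.
    """
    vaf_somatic = status_vaf is ValidationStatus.SOMATIC
    q_somatic = status_q is ValidationStatus.SOMATIC
    if vaf_somatic != q_somatic:
        return ValidationStatus.AMBIGUOUS
    return status_vaf


def pseudo_validate(
    signed_q_tumor: float,
    signed_q_normal: float,
    q_t: float = 200.0,
    q_n: float = -50.0,
) -> bool:
    """Pseudo-positive: tumor signed quality > q_t and normal < q_n (strict)."""
    return signed_q_tumor > q_t and signed_q_normal < q_n


def rna_validate(
    rna_depth: int,
    rna_vaf: float | None,
    normal_exome_vaf: float | None,
    f_t: float = 0.10,
    f_n: float = 0.02,
    min_depth: int = 10,
) -> ValidationStatus:
    """RNA-seq scheme: positive iff RNA vaf > f_t and normal exome vaf < f_n.

    Sites under ``min_depth`` RNA coverage (default 10x; roughly a third of
    sites reach it in exome data) are not evaluable.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be at least 1")
    if rna_depth < min_depth:
        return ValidationStatus.NOT_EVALUABLE
    if rna_vaf is None or normal_exome_vaf is None or np.isnan(rna_vaf) or np.isnan(normal_exome_vaf):
        return ValidationStatus.NOT_EVALUABLE
    if rna_vaf > f_t and normal_exome_vaf < f_n:
        return ValidationStatus.POSITIVE
    return ValidationStatus.NEGATIVE


def strand_bias_flag(alt_fwd_frac: float) -> bool:
    """Extreme variant-allele strand bias: > 95% or < 5% on the forward strand."""
    return alt_fwd_frac > 0.95 or alt_fwd_frac < 0.05


def exome_strand_filter(
    alt_fwd_frac: float | None,
    ref_fwd_frac: float | None,
    ref_lo: float = 0.30,
    ref_hi: float = 0.70,
) -> bool:
    """Exome strand-bias filter: variant allele strand-extreme, reference not.

    A site is filtered out when the variant allele is almost entirely on
    one strand while the reference allele shows no such extremity (its
    forward fraction lies strictly inside (ref_lo, ref_hi)).  If either
    fraction is undefined (no alt or no ref reads) the site is not
    filtered.
    """
    if alt_fwd_frac is None or ref_fwd_frac is None or np.isnan(alt_fwd_frac) or np.isnan(ref_fwd_frac):
        return False
    return strand_bias_flag(alt_fwd_frac) and (ref_lo < ref_fwd_frac < ref_hi)


def rna_strand_filter(
    alt_fwd_frac_exome: float | None, alt_fwd_frac_rna: float | None
) -> bool:
    """RNA strand-bias filter: variant allele strand-extreme in *both* assays."""
    if (
        alt_fwd_frac_exome is None
        or alt_fwd_frac_rna is None
        or np.isnan(alt_fwd_frac_exome)
        or np.isnan(alt_fwd_frac_rna)
    ):
        return False
    return strand_bias_flag(alt_fwd_frac_exome) and strand_bias_flag(alt_fwd_frac_rna)


def _vaf(alt, depth):
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)


def build_evaluation_set(
    candidates: pd.DataFrame, thresholds: Thresholds | None = None
) -> pd.DataFrame:
    """Depth-filter candidate sites and label survivors by the gold standard.

    ``candidates`` is an evidence table (one row per site) with at least
    the columns ``deep_tumor_depth``, ``deep_tumor_alt``,
    ``deep_normal_depth``, ``deep_normal_alt``, ``exome_tumor_depth``,
    ``exome_normal_depth``, ``signed_q_tumor``, ``signed_q_normal``.

    Filters, applied in order: deep tumor depth >= 100x; exome tumor and
    normal depth >= 10x; removal of sites where the two gold-standard
    criteria disagree (ambiguous).  Surviving rows gain ``gs_status`` (the
    vaf-rule label) and deep vaf columns.
    """
    t = thresholds or Thresholds()
    df = candidates.copy()
    df = df[df["deep_tumor_depth"] >= t.eval_min_deep_depth]
    df = df[
        (df["exome_tumor_depth"] >= t.eval_min_exome_depth)
        & (df["exome_normal_depth"] >= t.eval_min_exome_depth)
    ]
    df = df.copy()
    df["deep_tumor_vaf"] = _vaf(df["deep_tumor_alt"], df["deep_tumor_depth"])
    df["deep_normal_vaf"] = _vaf(df["deep_normal_alt"], df["deep_normal_depth"])
    status = []
    for tv, nv, qt, qn in zip(
        df["deep_tumor_vaf"], df["deep_normal_vaf"],
        df["signed_q_tumor"], df["signed_q_normal"],
    ):
        s_vaf = gs_validate(tv, nv, t)
        s_q = gs_validate_alt(qt, qn, t)
        status.append(reconcile_gs(s_vaf, s_q))
    df["gs_status"] = [s.value for s in status]
    df = df[df["gs_status"] != ValidationStatus.AMBIGUOUS.value]
    return df.reset_index(drop=True)
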