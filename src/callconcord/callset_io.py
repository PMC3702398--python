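"""Reading per-caller somatic call sets and building detection-pattern tables.

A "site" is a candidate single-nucleotide somatic mutation for one patient:
the identity of a site is the tuple (patient, chromosome, position, alt
allele) — the reference allele does not enter the identity, since calls from
different callers are matched by position and alternate allele.

Each caller's output is a VCF whose records carry a somatic-status code in
INFO (``SS`` by default), a FILTER column (``PASS`` vs anything else), and
TUMOR / NORMAL sample columns with ``DP`` and ``AD`` fields.  A caller's
*final* call set is the set of sites with somatic status that pass all of
the caller's filters.  Comparing K callers over the union of their final
sets yields, per site, a K-bit detection pattern — the observation vector
of the latent class model in :mod:`callconcord.latent_class`.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

__all__ = [
    "SomaticStatus",
    "VariantSite",
    "CallerRecord",
    "PatternCounts",
    "ParseResult",
    "VcfDialect",
    "FormatError",
    "parse_caller_vcf",
    "final_somatic_set",
    "detection_patterns",
    "pattern_count_table",
    "table1_fixture",
    "all_patterns",
    "write_pattern_tsv",
    "read_pattern_tsv",
]

_NUCLEOTIDES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


class SomaticStatus(str, Enum):
    SOMATIC = "somatic"
    GERMLINE = "germline"
    WILDTYPE = "wildtype"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class VariantSite:
    """A candidate SNV for one patient.

    Equality and hashing use ``(patient_id, chrom, pos, alt)``; the
    reference allele is carried along but does not define identity.
    """

    patient_id: str
    chrom: str
    pos: int  # 1-based
    ref: str = field(compare=False)
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")
        if self.ref not in _NUCLEOTIDES or self.alt not in _NUCLEOTIDES:
            raise ValueError(f"SNV-only: ref={self.ref!r} alt={self.alt!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.patient_id, self.chrom, self.pos, self.alt)


@dataclass(frozen=True)
class CallerRecord:
    """One data line of a caller's VCF, normalized."""

    caller_id: str
    site: VariantSite
    somatic_status: SomaticStatus
    filter_pass: bool
    tumor_depth: int = 0
    tumor_alt: int = 0
    normal_depth: int = 0
    normal_alt: int = 0
    caller_quality: float | None = None

    def __post_init__(self) -> None:
        if self.tumor_alt > self.tumor_depth:
            raise ValueError("tumor_alt exceeds tumor_depth")
        if self.normal_alt > self.normal_depth:
            raise ValueError("normal_alt exceeds normal_depth")


# A detection pattern is an immutable K-tuple of 0/1 ints, caller order fixed
# by configuration.
Pattern = tuple[int, ...]


def all_patterns(K: int) -> list[Pattern]:
    """All 2^K detection patterns in lexicographic order."""
    return [tuple(bits) for bits in itertools.product((0, 1), repeat=K)]


@dataclass
class PatternCounts:
    """Counts of sites by K-caller detection pattern (all 2^K cells).

    The all-false cell counts positions screened by every caller but called
    by none; it cannot be derived from the call sets and must be supplied.
    """

    counts: dict[Pattern, int]
    K: int

    def __post_init__(self) -> None:
        expected = set(all_patterns(self.K))
        if set(self.counts) != expected:
            raise ValueError(
                f"counts must cover all 2^{self.K} patterns exactly "
                f"(got {len(self.counts)} cells)"
            )
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("pattern counts must be non-negative")

    @property
    def N(self) -> int:
        return sum(self.counts.values())

    def as_arrays(self):
        """Return (patterns matrix [2^K, K], counts vector) in lexicographic order."""
        import numpy as np

        pats = all_patterns(self.K)
        mat = np.array(pats, dtype=float)
        n = np.array([self.counts[p] for p in pats], dtype=float)
        return mat, n

    def detected_total(self) -> int:
        """Number of sites detected by at least one caller."""
        zero = (0,) * self.K
        return self.N - self.counts[zero]


@dataclass
class VcfDialect:
    """Column mapping for the supported VCF flavor."""

    somatic_status_key: str = "SS"
    status_codes: Mapping[str, SomaticStatus] = field(
        default_factory=lambda: {
            "SOMATIC": SomaticStatus.SOMATIC,
            "GERMLINE": SomaticStatus.GERMLINE,
            "WILDTYPE": SomaticStatus.WILDTYPE,
        }
    )
    tumor_sample: str = "TUMOR"
    normal_sample: str = "NORMAL"


@dataclass
class ParseResult:
    """Records plus a skip/warning report from one VCF."""

    records: list[CallerRecord]
    skipped_non_snv: int = 0
    warnings: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _sample_depth_alt(sample) -> tuple[int, int]:
    dp = sample.get("DP")
    ad = sample.get("AD")
    depth = int(dp) if dp is not None else 0
    alt = int(ad[1]) if ad is not None and len(ad) > 1 and ad[1] is not None else 0
    return depth, alt


def parse_caller_vcf(
    path: str | Path,
    caller_id: str,
    patient_id: str,
    dialect: VcfDialect | None = None,
) -> ParseResult:
    """Read one caller's VCF for one patient into normalized records.

    Multi-allelic records are split into one record per alternate allele;
    non-SNV alternates are skipped and counted.  Unknown somatic-status
    codes map to :attr:`SomaticStatus.UNKNOWN` with a warning.
    """
    dialect = dialect or VcfDialect()
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: malformed VCF header or file: {exc}") from exc

    result = ParseResult(records=[])
    with vf:
        have_samples = len(vf.header.samples) > 0
        for rec in vf:
            filter_keys = list(rec.filter.keys())
            filter_pass = filter_keys == ["PASS"] or not filter_keys
            raw_status = rec.info.get(dialect.somatic_status_key)
            if isinstance(raw_status, (tuple, list)):
                raw_status = raw_status[0] if raw_status else None
            if raw_status is None:
                status = SomaticStatus.UNKNOWN
            else:
                status = dialect.status_codes.get(str(raw_status))
                if status is None:
                    msg = (
                        f"{path.name}:{rec.chrom}:{rec.pos}: unknown somatic "
                        f"status code {raw_status!r}; mapped to 'unknown'"
                    )
                    result.warnings.append(msg)
                    warnings.warn(msg, stacklevel=2)
                    status = SomaticStatus.UNKNOWN
            t_depth = t_alt = n_depth = n_alt = 0
            if have_samples:
                try:
                    t_depth, t_alt = _sample_depth_alt(rec.samples[dialect.tumor_sample])
                    n_depth, n_alt = _sample_depth_alt(rec.samples[dialect.normal_sample])
                except KeyError:
                    pass
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or not {rec.ref, alt} <= _NUCLEOTIDES:
                    result.skipped_non_snv += 1
                    continue
                site = VariantSite(patient_id, rec.chrom, rec.pos, rec.ref, alt)
                result.records.append(
                    CallerRecord(
                        caller_id=caller_id,
                        site=site,
                        somatic_status=status,
                        filter_pass=filter_pass,
                        tumor_depth=t_depth,
                        tumor_alt=min(t_alt, t_depth),
                        normal_depth=n_depth,
                        normal_alt=min(n_alt, n_depth),
                        caller_quality=rec.qual,
                    )
                )
    return result


def final_somatic_set(records: Iterable[CallerRecord]) -> set[VariantSite]:
    """Extract a caller's final call set: somatic status, all filters passed.

    Duplicate sites are collapsed; a duplicate with conflicting filter
    status is ambiguous caller output and raises ``ValueError``.
    """
    seen: dict[VariantSite, bool] = {}
    for rec in records:
        if rec.somatic_status is not SomaticStatus.SOMATIC:
            continue
        prev = seen.get(rec.site)
        if prev is not None and prev != rec.filter_pass:
            raise ValueError(
                f"conflicting filter status for duplicate site {rec.site.key}"
            )
        seen[rec.site] = rec.filter_pass
    return {site for site, ok in seen.items() if ok}


def detection_patterns(
    callsets: Mapping[str, set[VariantSite]],
    caller_order: Sequence[str],
) -> dict[VariantSite, Pattern]:
    """Map every site in the union of call sets to its K-bit pattern.

    Bit k is 1 iff caller ``caller_order[k]`` called the site.  The union
    construction guarantees no all-zero pattern appears.
    """
    missing = set(callsets) - set(caller_order)
    if missing:
        raise ValueError(f"callers missing from caller_order: {sorted(missing)}")
    union: set[VariantSite] = set()
    for s in callsets.values():
        union |= s
    return {
        site: tuple(int(site in callsets.get(c, set())) for c in caller_order)
        for site in union
    }


def pattern_count_table(
    patterns: Mapping[VariantSite, Pattern],
    K: int,
    zero_cell_count: int,
) -> PatternCounts:
    """Tabulate detection patterns into a full 2^K-cell count table.

    ``zero_cell_count`` supplies the all-negative cell (positions screened
    but called by no caller) which the union of call sets cannot contain.
    """
    if zero_cell_count < 0:
        raise ValueError("zero_cell_count must be non-negative")
    counts = {p: 0 for p in all_patterns(K)}
    for pat in patterns.values():
        if len(pat) != K:
            raise ValueError(f"pattern length {len(pat)} != K={K}")
        counts[pat] += 1
    counts[(0,) * K] = zero_cell_count
    return PatternCounts(counts=counts, K=K)


# 16-cell detection-pattern table for the four anonymized callers (A, B, C,
# D) over the deep-sequenced 76-gene target regions of the 16-patient lung
# squamous cell carcinoma benchmark: per-pattern totals of non-somatic plus
# somatic validated counts.  The A&B-only pattern was not observed (0).
_TABLE1_CELLS: dict[Pattern, int] = {
    (0, 0, 0, 0): 4292 + 9,  # called by none of the four callers
    (1, 0, 0, 0): 3 + 4,     # Caller A only
    (0, 1, 0, 0): 1 + 2,     # Caller B only
    (0, 0, 1, 0): 2 + 0,     # Caller C only
    (0, 0, 0, 1): 6 + 5,     # Caller D only
    (1, 1, 0, 0): 0,         # A and B (absent row)
    (1, 0, 1, 0): 0 + 6,     # A and C
    (1, 0, 0, 1): 2 + 3,     # A and D
    (0, 1, 1, 0): 0 + 2,     # B and C
    (0, 1, 0, 1): 0 + 2,     # B and D
    (0, 0, 1, 1): 0 + 5,     # C and D
    (1, 1, 1, 0): 0 + 3,     # all but D
    (1, 1, 0, 1): 0 + 4,     # all but C
    (1, 0, 1, 1): 3 + 15,    # all but B
    (0, 1, 1, 1): 0 + 13,    # all but A
    (1, 1, 1, 1): 0 + 57,    # all four callers
}

TABLE1_CALLER_ORDER = ("A", "B", "C", "D")


def table1_fixture() -> PatternCounts:
    """Detection-pattern counts from the 76-gene validated benchmark table."""
    return PatternCounts(counts=dict(_TABLE1_CELLS), K=4)


def write_pattern_tsv(counts: PatternCounts, path: str | Path) -> None:
    """Write a pattern-count table as TSV (bitstring, count)."""
    with open(path, "w") as fh:
        fh.write("pattern\tcount\n")
        for pat in all_patterns(counts.K):
            fh.write("".join(map(str, pat)) + f"\t{counts.counts[pat]}\n")


def read_pattern_tsv(path: str | Path) -> PatternCounts:
    """Read a pattern-count TSV written by :func:`write_pattern_tsv`."""
    counts: dict[Pattern, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("pattern"):
            raise FormatError(f"{path}: expected 'pattern\\tcount' header")
        for line in fh:
            bits, n = line.split("\t")
            counts[tuple(int(b) for b in bits.strip())] = int(n)
    if not counts:
        raise FormatError(f"{path}: empty pattern table")
    K = len(next(iter(counts)))
    return PatternCounts(counts=counts, K=K)
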