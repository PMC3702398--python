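"""Synthetic multi-caller tumor/normal cohorts with known latent truth.

The generator emulates the generative structure the downstream analysis
assumes, so every stage — call-set parsing, pattern tables, validation
schemes, latent class fits — can be exercised against known truth:

* each candidate site has a latent status D: **somatic** with prevalence
  eta, the remaining mass split among **germline**, **wildtype_artifact**
  ("germline-like" sites whose artifactual variant allele appears at
  matched low fractions in tumor and normal) and **clean_wildtype**;
* each site carries a standard-normal random effect b; caller k calls the
  site with probability Phi(a_{d,k} + sigma * b), the random-effects
  probit of the latent class model.  The intercepts are solved from the
  configured *marginal* rates via Phi(a / sqrt(1 + sigma^2)), so at
  sigma = 0 calls are independent Bernoulli draws at exactly the
  configured per-caller false-positive / false-negative rates;
* sequencing evidence is drawn per assay — tumor/normal exome, tumor/normal
  deep sequencing at ~3x the exome depth, and tumor RNA with overdispersed
  depth including zeros — with binomial allele counts at the true vaf plus
  a base-level error rate, forward-strand allele counts (balanced for real
  variants, one-sided for artifact sites), and signed per-sample quality
  scores that are monotone in the allele evidence.

Somatic tumor vafs are purity * c / 2 for a clonal fraction c ~ U(0.2, 1);
germline vafs sit near 45% in both samples (alignment bias toward the
reference pulls heterozygous sites below 50%).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special


__all__ = [
    "SimulationConfig",
    "simulate_truth",
    "simulate_caller_calls",
    "simulate_evidence",
    "simulate_cohort",
    "write_cohort",
    "signed_score_from_counts",
    "probit_intercept",
]

_BASES = np.array(list("ACGT"))

ASSAYS = ("exome_tumor", "exome_normal", "deep_tumor", "deep_normal", "rna_tumor")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the benchmark setting the analysis targets: 16
    patients, four callers, a few percent somatic prevalence among
    screened candidate sites, ~80x exome coverage with deep sequencing at
    three times that, and an RNA depth distribution under which roughly a
    third of sites reach 10x.
    """

    n_patients: int = 16
    sites_per_patient: int = 300
    eta: float = 0.03
    K: int = 4
    caller_fp: tuple[float, ...] = (0.002, 0.001, 0.001, 0.003)
    caller_fn: tuple[float, ...] = (0.20, 0.30, 0.10, 0.10)
    sigma: float = 0.0
    germline_fraction: float = 0.25
    wildtype_artifact_fraction: float = 0.12
    purity: float = 0.8
    depth_mean_exome: float = 80.0
    depth_mean_deep: float = 240.0
    depth_dispersion: float = 5.0
    rna_depth_mean: float = 12.0
    rna_depth_dispersion: float = 0.35
    strand_artifact_prob: float = 0.5
    seq_error: float = 0.001
    raw_missing_prob: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.eta <= 1:
            raise ValueError("eta must lie in [0, 1]")
        if self.germline_fraction + self.wildtype_artifact_fraction > 1:
            raise ValueError("non-somatic fractions must sum to at most 1")
        if len(self.caller_fp) != self.K or len(self.caller_fn) != self.K:
            raise ValueError("caller_fp / caller_fn must have length K")
        for r in (*self.caller_fp, *self.caller_fn):
            if not 0 <= r < 1:
                raise ValueError(f"rates must lie in [0, 1), got {r}")
        for fp, fn in zip(self.caller_fp, self.caller_fn):
            if 1 - fn <= fp:
                raise ValueError("need sensitivity 1-fn > fp for every caller")
        if self.sigma < 0 or not 0 < self.purity <= 1:
            raise ValueError("sigma must be >= 0 and purity in (0, 1]")

    @property
    def caller_ids(self) -> list[str]:
        return [chr(ord("A") + k) for k in range(self.K)]

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def probit_intercept(marginal_rate: float, sigma: float) -> float:
    """Intercept a with Phi(a / sqrt(1 + sigma^2)) equal to the marginal rate."""
    rate = np.clip(marginal_rate, 1e-12, 1 - 1e-12)
    return float(special.ndtri(rate) * np.sqrt(1.0 + sigma**2))


def simulate_truth(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw latent statuses, random effects, and true allele fractions.

    Returns one row per site with columns ``patient_id, chrom, pos, ref,
    alt, D, b, true_tumor_vaf, true_normal_vaf, strand_artifact,
    strand_fwd_bias``.
    """
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_patients * config.sites_per_patient
    if n == 0:
        return pd.DataFrame(
            columns=[
                "patient_id", "chrom", "pos", "ref", "alt", "D", "b",
                "true_tumor_vaf", "true_normal_vaf", "strand_artifact",
                "strand_fwd_bias",
            ]
        )

    patient = np.repeat(
        [f"P{i + 1:03d}" for i in range(config.n_patients)], config.sites_per_patient
    )
    # unique positions per patient on a single synthetic contig
    pos = np.concatenate(
        [
            np.sort(
                rng.choice(10_000_000, size=config.sites_per_patient, replace=False)
            )
            + 1
            for _ in range(config.n_patients)
        ]
    )
    ref_idx = rng.integers(0, 4, n)
    alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4

    p_rest = 1.0 - config.eta
    probs = np.array(
        [
            config.eta,
            p_rest * config.germline_fraction,
            p_rest * config.wildtype_artifact_fraction,
            p_rest * (1 - config.germline_fraction - config.wildtype_artifact_fraction),
        ]
    )
    classes = np.array(["somatic", "germline", "wildtype_artifact", "clean_wildtype"])
    D = classes[rng.choice(4, size=n, p=probs)]
    b = rng.standard_normal(n)

    tumor_vaf = np.zeros(n)
    normal_vaf = np.zeros(n)
    som = D == "somatic"
    clonal = rng.uniform(0.2, 1.0, som.sum())
    tumor_vaf[som] = config.purity * clonal / 2.0
    germ = D == "germline"
    # heterozygous germline variants: centred near 45% in both samples
    # (alignment bias toward the reference allele)
    tumor_vaf[germ] = np.clip(rng.normal(0.45, 0.05, germ.sum()), 0.1, 0.9)
    normal_vaf[germ] = np.clip(rng.normal(0.45, 0.05, germ.sum()), 0.1, 0.9)
    art = D == "wildtype_artifact"
    # germline-like artifacts: matched low-but-nonzero vaf in both samples
    base = rng.uniform(0.05, 0.30, art.sum())
    tumor_vaf[art] = np.clip(base + rng.normal(0, 0.03, art.sum()), 0.02, 0.5)
    normal_vaf[art] = np.clip(base + rng.normal(0, 0.03, art.sum()), 0.02, 0.5)

    strand_artifact = np.zeros(n, dtype=bool)
    strand_artifact[art] = rng.random(art.sum()) < config.strand_artifact_prob
    fwd_bias = np.full(n, 0.5)
    extreme = rng.choice([0.002, 0.998], size=int(strand_artifact.sum()))
    fwd_bias[strand_artifact] = extreme

    return pd.DataFrame(
        {
            "patient_id": patient,
            "chrom": "1",
            "pos": pos,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "D": D,
            "b": b,
            "true_tumor_vaf": tumor_vaf,
            "true_normal_vaf": normal_vaf,
            "strand_artifact": strand_artifact,
            "strand_fwd_bias": fwd_bias,
        }
    )


def simulate_caller_calls(
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Add per-caller call indicators Y_<caller> and raw-VCF presence flags.

    Calls follow the random-effects probit: P(call) = Phi(a_{d,k} + sigma*b)
    with intercepts solved so the marginal rates equal the configured
    caller_fp (non-somatic) and 1 - caller_fn (somatic).  Raw-VCF presence:
    a called site always appears in the caller's raw output; an uncalled
    site appears (as a filtered/non-somatic record) with probability
    1 - raw_missing_prob.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    out = truth.copy()
    if len(truth) == 0:
        for caller in config.caller_ids:
            out[f"Y_{caller}"] = np.array([], dtype=int)
            out[f"raw_{caller}"] = np.array([], dtype=int)
        return out
    d = (truth["D"] == "somatic").to_numpy()
    b = truth["b"].to_numpy()
    for k, caller in enumerate(config.caller_ids):
        a0 = probit_intercept(config.caller_fp[k], config.sigma)
        a1 = probit_intercept(1.0 - config.caller_fn[k], config.sigma)
        a = np.where(d, a1, a0)
        p_call = special.ndtr(a + config.sigma * b)
        y = rng.random(len(truth)) < p_call
        out[f"Y_{caller}"] = y.astype(int)
        out[f"raw_{caller}"] = (
            y | (rng.random(len(truth)) >= config.raw_missing_prob)
        ).astype(int)
    return out


def signed_score_from_counts(
    alt: np.ndarray, depth: np.ndarray, seq_error: float = 0.001
) -> np.ndarray:
    """Signed, phred-like variant quality from allele counts.

    Ten times the log10 Bayes factor of a heterozygous-variant model
    (allele fraction 1/2) against a reference model emitting the variant
    allele only as error.  Positive when variant alleles are present
    (monotone in alt at fixed depth), negative when absent (monotone in
    depth), zero at zero depth — matching the sign contract of
    :func:`callconcord.validation.signed_quality`.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    e = min(max(seq_error, 1e-6), 0.25)
    llr = alt * np.log10(0.5 / e) + (depth - alt) * np.log10(0.5 / (1 - e))
    return 10.0 * llr


def _nb_depth(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative-binomial depths with mean `mean` and shape `dispersion`."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size)


def simulate_evidence(
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw per-assay depths, allele counts, strand counts, and signed scores.

    Deep sequencing runs at ~3x the exome mean depth; RNA depth is strongly
    overdispersed (gamma-mixed Poisson) with a large mass at low or zero
    coverage.  Allele counts are Binomial(depth, vaf + error); forward-
    strand allele counts are Binomial(alt, s) with s = 1/2 for genuine
    variants and s near 0 or 1 at strand-artifact sites.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    n = len(truth)
    out = truth[["patient_id", "chrom", "pos", "ref", "alt"]].copy()
    e = config.seq_error
    if n == 0:
        for assay in ASSAYS:
            for col in ("depth", "alt", "alt_fwd", "ref_fwd"):
                out[f"{assay}_{col}"] = np.array([], dtype=int)
        out["signed_q_tumor"] = np.array([], dtype=float)
        out["signed_q_normal"] = np.array([], dtype=float)
        return out

    vaf_for = {
        "exome_tumor": truth["true_tumor_vaf"].to_numpy(),
        "exome_normal": truth["true_normal_vaf"].to_numpy(),
        "deep_tumor": truth["true_tumor_vaf"].to_numpy(),
        "deep_normal": truth["true_normal_vaf"].to_numpy(),
        "rna_tumor": truth["true_tumor_vaf"].to_numpy(),
    }
    # deep sequencing is cleaner: artifact alleles largely absent there
    artifact = (truth["D"] == "wildtype_artifact").to_numpy()
    for assay in ("deep_tumor", "deep_normal"):
        v = vaf_for[assay].copy()
        v[artifact] = 0.0
        vaf_for[assay] = v

    s_bias = truth["strand_fwd_bias"].to_numpy()
    for assay in ASSAYS:
        if assay.startswith("deep"):
            depth = _nb_depth(rng, config.depth_mean_deep, config.depth_dispersion, n)
        elif assay.startswith("exome"):
            depth = _nb_depth(rng, config.depth_mean_exome, config.depth_dispersion, n)
        else:
            depth = _nb_depth(
                rng, config.rna_depth_mean, config.rna_depth_dispersion, n
            )
        p_alt = np.clip(vaf_for[assay] * (1 - e) + e, 0.0, 1.0)
        if e == 0:
            p_alt = np.clip(vaf_for[assay], 0.0, 1.0)
        alt = rng.binomial(depth, p_alt)
        s = np.where(s_bias != 0.5, s_bias, 0.5)
        alt_fwd = rng.binomial(alt, s)
        ref_fwd = rng.binomial(depth - alt, 0.5)
        out[f"{assay}_depth"] = depth
        out[f"{assay}_alt"] = alt
        out[f"{assay}_alt_fwd"] = alt_fwd
        out[f"{assay}_ref_fwd"] = ref_fwd

    out["signed_q_tumor"] = signed_score_from_counts(
        out["exome_tumor_alt"], out["exome_tumor_depth"], e
    )
    out["signed_q_normal"] = signed_score_from_counts(
        out["exome_normal_alt"], out["exome_normal_depth"], e
    )
    return out


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pipeline: truth (with calls) and evidence tables, one seed."""
    root = np.random.SeedSequence(config.seed)
    r_truth, r_calls, r_evid = (np.random.default_rng(s) for s in root.spawn(3))
    truth = simulate_truth(config, r_truth)
    truth = simulate_caller_calls(truth, config, r_calls)
    evidence = simulate_evidence(truth, config, r_evid)
    return truth, evidence


_VCF_HEADER = """##fileformat=VCFv4.2
##source=callconcord-simulator
##contig=<ID=1,length=10000001>
##INFO=<ID=SS,Number=1,Type=String,Description="Somatic status">
##FILTER=<ID=lowconf,Description="Did not pass the caller's filters">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL
"""


def write_cohort(
    truth: pd.DataFrame,
    evidence: pd.DataFrame,
    outdir: str | Path,
    config: SimulationConfig,
) -> dict:
    """Write per-caller per-patient VCFs, evidence/truth TSVs and a manifest.

    A caller's VCF contains its called sites as PASS/SOMATIC records plus
    the raw (scanned-but-filtered) sites flagged during simulation.
    Returns the manifest (also written as JSON) listing every file, the
    seed, and a hash of the configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ev = evidence.set_index(["patient_id", "pos"])
    files: list[str] = []
    for patient, tgroup in truth.groupby("patient_id", sort=True):
        for caller in config.caller_ids:
            name = f"{patient}.caller{caller}.vcf"
            with open(outdir / name, "w") as fh:
                fh.write(_VCF_HEADER)
                for row in tgroup.itertuples():
                    called = getattr(row, f"Y_{caller}") == 1
                    in_raw = getattr(row, f"raw_{caller}") == 1
                    if not called and not in_raw:
                        continue
                    erow = ev.loc[(patient, row.pos)]
                    td, ta = int(erow["exome_tumor_depth"]), int(erow["exome_tumor_alt"])
                    nd, na = int(erow["exome_normal_depth"]), int(erow["exome_normal_alt"])
                    if called:
                        filt, ss = "PASS", "SOMATIC"
                    else:
                        filt = "lowconf"
                        ss = "GERMLINE" if row.D == "germline" else "SOMATIC"
                    qual = max(float(erow["signed_q_tumor"]), 0.0)
                    fh.write(
                        f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t"
                        f"{qual:.1f}\t{filt}\tSS={ss}\tDP:AD\t"
                        f"{td}:{td - ta},{ta}\t{nd}:{nd - na},{na}\n"
                    )
            files.append(name)

    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    evidence.to_csv(outdir / "evidence.tsv", sep="\t", index=False)
    files += ["truth.tsv", "evidence.tsv"]
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "n_sites": int(len(truth)),
        "caller_ids": config.caller_ids,
        "files": sorted(files),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
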