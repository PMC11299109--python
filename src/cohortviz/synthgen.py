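"""Deterministic synthetic cohort generator.

Emulates the data shapes of a multi-sample ovarian high-grade serous
carcinoma (HGSC) WGS cohort on a reduced toy genome, so every pipeline stage
— purification, LOH, G-score, stratification workflows — is testable without
any controlled-access download:

* patients with 1–3 tumor samples, each with its own purity and ploidy
  (a configurable fraction of patients is whole-genome duplicated,
  ploidy > 2.2);
* per sample, copy-number segments that tile each chromosome exactly; the
  *true* (pure-tumor) copy ratio and BAF are planted first and the observed
  ``log2R``/``baf`` are produced through :func:`cohortviz.cnmath.mix` at the
  sample's purity/ploidy, so purification must recover the planted values;
* chr17-wide loss of heterozygosity (true BAF 0) in every tumor except a
  configurable number of planted non-LOH outlier patients, plus a TP53-like
  SSV whose VAF follows the homozygous-mutation relation
  ``VAF = p·CN / (p·CN + 2(1 − p))`` — so the TP53 purity approximation
  recovers the planted purity exactly;
* tandem-duplicator patients with many short high-amplitude segments and a
  deleterious CDK12-like SSV;
* passenger SSVs with a long-tailed CADD score distribution; and
* a panel of normal samples' log2R matrix with planted artifact regions for
  the blacklist rule.

All randomness flows from one seeded generator and tables are emitted sorted,
so identical (config, seed) gives byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .cnmath import PurityPloidy, mix
from .genome import GenomeAssembly, write_chrom_sizes

__all__ = ["CohortConfig", "SyntheticCohort", "toy_assembly", "generate_cohort",
           "write_cohort", "generate_fig2_fixture", "TP53_LOCUS", "CCNE1_LOCUS",
           "CDK12_LOCUS"]

# Toy genome: a handful of short chromosomes; chr17 and chr19 are included by
# name because the HGSC biology the generator plants lives there (TP53/CDK12
# on chr17, a CCNE1-like amplicon on chr19).
_TOY_CHROMS = [
    ("chr1", 1_000_000),
    ("chr3", 900_000),
    ("chr8", 800_000),
    ("chr17", 700_000),
    ("chr19", 600_000),
]

TP53_LOCUS = ("chr17", 100_000)
CDK12_LOCUS = ("chr17", 400_000)
CCNE1_LOCUS = ("chr19", 300_000)


def toy_assembly() -> GenomeAssembly:
    return GenomeAssembly("toy", _TOY_CHROMS)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort; ``seed`` is mandatory."""

    seed: int
    n_patients: int = 12
    samples_per_patient: tuple[int, int] = (1, 3)
    purity_range: tuple[float, float] = (0.15, 0.95)
    wgd_fraction: float = 0.4  # fraction of patients with ploidy > 2.2
    n_non_loh_outliers: int = 2  # patients without chr17-wide LOH
    n_tandem_duplicator_patients: int = 2
    passenger_ssvs_per_sample: int = 25
    noise_sd: float = 0.0  # optional Gaussian jitter on observed log2R/BAF
    n_normal_panel: int = 114
    n_panel_regions: int = 60
    n_artifact_regions: int = 5

    def __post_init__(self) -> None:
        if self.n_non_loh_outliers + self.n_tandem_duplicator_patients > self.n_patients:
            raise ValueError("outlier + tandem-duplicator patients exceed n_patients")
        if not 1 <= self.samples_per_patient[0] <= self.samples_per_patient[1]:
            raise ValueError("invalid samples_per_patient range")
        if not 0 < self.purity_range[0] <= self.purity_range[1] <= 1:
            raise ValueError("invalid purity range")


@dataclass
class SyntheticCohort:
    assembly: GenomeAssembly
    patients: pd.DataFrame  # patient, is_loh_outlier, is_tandem_duplicator
    samples: pd.DataFrame   # sample, patient, purity, ploidy
    segments: pd.DataFrame  # sample, chrom, start, end, log2R, baf, true_r, true_baf
    ssvs: pd.DataFrame      # sample, chrom, pos, ref, alt, vaf, cadd, clinvar_pathogenic, gene
    normal_panel: pd.DataFrame  # regions × normals log2R, index region ids
    artifact_regions: list[str]


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    rng = np.random.default_rng(config.seed)
    assembly = toy_assembly()
    chrom_order = {c: i for i, (c, _) in enumerate(assembly.chromosomes)}

    n = config.n_patients
    patient_ids = [f"P{i + 1:03d}" for i in range(n)]
    # first the non-LOH outliers, then tandem duplicators, then ordinary HGSC;
    # assignment is positional so counts are exact by construction
    outliers = set(patient_ids[: config.n_non_loh_outliers])
    tandem = set(patient_ids[config.n_non_loh_outliers:
                             config.n_non_loh_outliers + config.n_tandem_duplicator_patients])
    wgd_patients = {p for p in patient_ids
                    if rng.random() < config.wgd_fraction}

    samples_rows = []
    segment_rows = []
    ssv_rows = []
    for patient in patient_ids:
        lo, hi = config.samples_per_patient
        n_samples = int(rng.integers(lo, hi + 1))
        ploidy_base = float(rng.uniform(3.1, 3.9)) if patient in wgd_patients \
            else float(rng.uniform(1.9, 2.1))
        for k in range(n_samples):
            sample = f"{patient}_s{k + 1}"
            purity = float(np.round(rng.uniform(*config.purity_range), 4))
            ploidy = float(np.round(ploidy_base + rng.normal(0, 0.03), 4))
            pp = PurityPloidy(purity, ploidy)
            samples_rows.append({"sample": sample, "patient": patient,
                                 "purity": purity, "ploidy": ploidy})
            segment_rows.extend(
                _sample_segments(rng, assembly, sample, pp,
                                 loh17=patient not in outliers,
                                 tandem=patient in tandem,
                                 noise_sd=config.noise_sd))
            ssv_rows.extend(
                _sample_ssvs(rng, assembly, sample, pp, segment_rows,
                             loh17=patient not in outliers,
                             tandem=patient in tandem,
                             n_passengers=config.passenger_ssvs_per_sample))

    patients = pd.DataFrame({
        "patient": patient_ids,
        "is_loh_outlier": [p in outliers for p in patient_ids],
        "is_tandem_duplicator": [p in tandem for p in patient_ids],
        "wgd": [p in wgd_patients for p in patient_ids],
    })
    samples = pd.DataFrame(samples_rows).sort_values(
        ["patient", "sample"]).reset_index(drop=True)
    segments = pd.DataFrame(segment_rows)
    segments["_c"] = segments["chrom"].map(chrom_order)
    segments = segments.sort_values(["sample", "_c", "start"]).drop(columns="_c") \
        .reset_index(drop=True)
    ssvs = pd.DataFrame(ssv_rows)
    ssvs["_c"] = ssvs["chrom"].map(chrom_order)
    ssvs = ssvs.sort_values(["sample", "_c", "pos"]).drop(columns="_c") \
        .reset_index(drop=True)

    panel, artifacts = _normal_panel(rng, assembly, config)
    return SyntheticCohort(assembly, patients, samples, segments, ssvs,
                           panel, artifacts)


def _sample_segments(rng, assembly, sample, pp, loh17, tandem, noise_sd):
    rows = []
    for chrom, length in assembly.chromosomes:
        if tandem and chrom in ("chr1", "chr8"):
            breaks = _tandem_breaks(rng, length)
        else:
            k = int(rng.integers(1, 4))
            cuts = sorted(rng.integers(1, length, size=k - 1).tolist()) if k > 1 else []
            breaks = [0, *cuts, length]
            breaks = sorted(set(breaks))
        for i in range(len(breaks) - 1):
            start, end = int(breaks[i]), int(breaks[i + 1])
            if tandem and chrom in ("chr1", "chr8") and i % 2 == 1:
                total_cn = int(rng.integers(6, 12))  # short tandem-dup amplicon
                minor_cn = 0
            else:
                total_cn = int(np.clip(round(pp.ploidy + rng.normal(0, 0.9)), 1, 6))
                minor_cn = int(rng.integers(0, total_cn // 2 + 1))
            if chrom == "chr17":
                if loh17:
                    minor_cn = 0
                    total_cn = max(1, total_cn)
                else:
                    # retained heterozygosity needs both alleles present
                    total_cn = max(2, total_cn)
                    minor_cn = max(1, min(minor_cn, total_cn // 2))
            rows.append(_make_segment(rng, sample, chrom, start, end,
                                      total_cn, minor_cn, pp, noise_sd))
    return rows


def _tandem_breaks(rng, length):
    """Many short segments: alternating background / amplicon."""
    breaks = [0]
    pos = 0
    while pos < length - 40_000:
        pos += int(rng.integers(20_000, 60_000))  # background stretch
        breaks.append(min(pos, length))
        pos += int(rng.integers(5_000, 15_000))  # short amplicon (~100 kb scale-down)
        breaks.append(min(pos, length))
    if breaks[-1] != length:
        breaks.append(length)
    return sorted(set(breaks))


def _make_segment(rng, sample, chrom, start, end, total_cn, minor_cn, pp, noise_sd):
    true_r = total_cn / pp.ploidy
    true_baf = (minor_cn / total_cn) if total_cn > 0 else 0.0
    obs_r, obs_baf = mix(true_r, true_baf, pp)
    log2r = float(np.log2(obs_r))
    if noise_sd > 0:
        log2r += float(rng.normal(0, noise_sd))
        obs_baf = float(np.clip(obs_baf + rng.normal(0, noise_sd / 2), 0, 1))
    return {"sample": sample, "chrom": chrom, "start": start, "end": end,
            "log2R": log2r, "baf": float(obs_baf),
            "true_total_cn": total_cn, "true_minor_cn": minor_cn,
            "true_r": true_r, "true_baf": true_baf}


def _total_cn_at(segment_rows, sample, chrom, pos):
    for row in reversed(segment_rows):
        if (row["sample"] == sample and row["chrom"] == chrom
                and row["start"] <= pos < row["end"]):
            return row["true_total_cn"]
    raise AssertionError("segments must tile the genome")  # pragma: no cover


def _homozygous_vaf(purity, cn):
    # mutation on all tumor copies diluted by 2 normal copies per normal cell
    return purity * cn / (purity * cn + 2.0 * (1.0 - purity))


def _sample_ssvs(rng, assembly, sample, pp, segment_rows, loh17, tandem,
                 n_passengers):
    rows = []
    if loh17:
        cn = _total_cn_at(segment_rows, sample, *TP53_LOCUS)
        rows.append({"sample": sample, "chrom": TP53_LOCUS[0], "pos": TP53_LOCUS[1],
                     "ref": "C", "alt": "T",
                     "vaf": _homozygous_vaf(pp.purity, cn),
                     "cadd": float(np.round(rng.uniform(25, 40), 2)),
                     "clinvar_pathogenic": True, "gene": "TP53"})
    if tandem:
        cn = _total_cn_at(segment_rows, sample, *CDK12_LOCUS)
        rows.append({"sample": sample, "chrom": CDK12_LOCUS[0], "pos": CDK12_LOCUS[1],
                     "ref": "G", "alt": "A",
                     "vaf": _homozygous_vaf(pp.purity, cn),
                     "cadd": float(np.round(rng.uniform(30, 45), 2)),
                     "clinvar_pathogenic": True, "gene": "CDK12"})
    bases = "ACGT"
    for _ in range(n_passengers):
        chrom, length = assembly.chromosomes[int(rng.integers(len(assembly.chromosomes)))]
        pos = int(rng.integers(0, length))
        ref, alt = rng.choice(list(bases), size=2, replace=False)
        # long-tailed deleteriousness scores; most passengers score low
        cadd = float(np.round(rng.exponential(6.0), 2))
        rows.append({"sample": sample, "chrom": chrom, "pos": pos,
                     "ref": str(ref), "alt": str(alt),
                     "vaf": float(np.round(rng.uniform(0.05, pp.purity / 2 + 0.05), 4)),
                     "cadd": min(cadd, 60.0),
                     "clinvar_pathogenic": False, "gene": ""})
    return rows


def _normal_panel(rng, assembly, config):
    regions = []
    for i in range(config.n_panel_regions):
        chrom, length = assembly.chromosomes[i % len(assembly.chromosomes)]
        start = int(rng.integers(0, length - 10_000))
        regions.append(f"{chrom}:{start}-{start + 10_000}")
    normals = [f"N{j + 1:03d}" for j in range(config.n_normal_panel)]
    values = rng.normal(0.0, 0.05, size=(config.n_panel_regions, config.n_normal_panel))
    artifact_idx = rng.choice(config.n_panel_regions,
                              size=config.n_artifact_regions, replace=False)
    for i in artifact_idx:
        hits = rng.choice(config.n_normal_panel,
                          size=int(rng.integers(3, 10)), replace=False)
        values[i, hits] = rng.uniform(0.3, 0.8, size=len(hits)) \
            * rng.choice([-1, 1], size=len(hits))
    panel = pd.DataFrame(np.round(values, 4), index=regions, columns=normals)
    return panel, [regions[i] for i in sorted(artifact_idx)]


def write_cohort(cohort: SyntheticCohort, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write all tables as TSV with fixed formatting (byte-reproducible)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("patients", cohort.patients), ("samples", cohort.samples),
                     ("segments", cohort.segments), ("ssvs", cohort.ssvs)):
        p = out_dir / f"{name}.tsv"
        # default float formatting is shortest-roundtrip repr: lossless and
        # deterministic, so purification recovery survives a file roundtrip
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    p = out_dir / "normal_panel.tsv"
    cohort.normal_panel.to_csv(p, sep="\t", index_label="region",
                               float_format="%.4f")
    paths["normal_panel"] = p
    p = out_dir / "toy.chrom.sizes"
    write_chrom_sizes(cohort.assembly, p)
    paths["chrom_sizes"] = p
    return paths


# ---------------------------------------------------------------------------
# Sequence-track fixture


def generate_fig2_fixture(sequence: str = "ACGTACGTACGT",
                          start: int = 0) -> tuple[list[dict], dict]:
    """A tiny sequence record plus the layered rect+text spec that renders it.

    The spec splits the sequence into per-nucleotide rows, draws a background
    rectangle per base (colored by base) and the base letter on top — one rect
    and one text primitive per nucleotide.
    """
    records = [{"sequence": sequence, "start": start}]
    spec = {
        "name": "sequence-track",
        "data": {"values": records},
        "transform": [
            {"type": "flattenSequence", "field": "sequence",
             "startField": "start", "posField": "pos", "asField": "base"},
            {"type": "formula", "expr": "pos + 1", "as": "pos2"},
        ],
        "encoding": {
            "x": {"field": "pos", "type": "quantitative"},
        },
        "layer": [
            {"name": "backgrounds", "mark": "rect",
             "encoding": {"x2": {"field": "pos2", "type": "quantitative"},
                          "color": {"field": "base", "type": "nominal"}}},
            {"name": "letters", "mark": "text",
             "encoding": {"text": {"field": "base", "type": "nominal"},
                          "color": {"value": "#000000"}}},
        ],
    }
    return records, spec
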