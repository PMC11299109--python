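"""Copy-number mathematics for tumor cohorts.

A tumor sample is a mixture of tumor cells (fraction *purity*) and normal
diploid cells.  The observed copy ratio R = 2^log2R and B-allele fraction
(BAF) are therefore diluted versions of the tumor's own values.  This module
implements:

* ``purity_from_tp53`` — approximate purity from the VAF of a truncal
  homozygous TP53 mutation and the total copy number at the locus,
  ``purity = 2 / ((CN/VAF) − (CN − 2))``.
* ``purify_r`` / ``purify_baf`` — remove the normal-cell contribution from R
  and BAF given purity and ploidy:

  .. math::

      \\mathrm{purifiedR} = \\frac{p\\,\\psi\\,R + 2(1-p)(R-1)}{p\\,\\psi}

      f(a) = p - 1 + R\\,a\\,(2(1-p) + p\\,\\psi), \\qquad
      \\mathrm{purifiedBaf} = \\frac{f(b)}{f(1-b) + f(b)}

  with purity *p* and tumor ploidy *ψ* (average tumor copy number).
* ``mix`` — the algebraic inverse: from true (purified) values to observed
  ones, used by the synthetic cohort generator and roundtrip tests.
* ``loh`` — loss of heterozygosity, ``abs(BAF − 0.5) × 2``: 0 is full
  heterozygosity, 1 total loss of one allele.
* ``gscore`` — a GISTIC-1.0-style recurrence score: amplifications and
  deletions processed separately, segments kept only when
  ``|purifiedLog2R| > 0.7`` (strict), amplitude clamped to 2.5, then an
  amplitude-weighted coverage divided by the number of samples in the group.
* ``count_breakpoints``, ``blacklist`` (normal-panel artifact regions with
  ``|log2R| > 0.2`` in ≥ 3 normals) and ``ssv_filter`` (CADD ≥ 10 or
  ClinVar-pathogenic).

Copy ratios are held as linear R internally; log2 conversion happens at the
I/O boundary (segment tables store ``log2R``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import GenomicInterval

__all__ = [
    "PurityPloidy", "GScoreParams",
    "purity_from_tp53", "purify_r", "purify_log2r", "purify_baf", "loh",
    "mix", "gscore", "count_breakpoints", "blacklist", "ssv_filter",
    "purify_segments",
]


@dataclass(frozen=True)
class PurityPloidy:
    """Per-sample purity (tumor cell fraction) and tumor ploidy."""

    purity: float
    ploidy: float

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.ploidy <= 0:
            raise ValueError(f"ploidy must be positive, got {self.ploidy}")


@dataclass(frozen=True)
class GScoreParams:
    """Inclusion threshold and clamp for the G-score summary.

    Segments whose |purified log2R| does not exceed ``inclusion_threshold``
    are ignored; the amplitude of the rest is clamped to ``cap`` before the
    weighted coverage is accumulated.
    """

    inclusion_threshold: float = 0.7
    cap: float = 2.5
    bin_size: Optional[int] = None  # optional post-binning; None = exact intervals

    def __post_init__(self) -> None:
        if not 0 < self.inclusion_threshold < self.cap:
            raise ValueError("require 0 < inclusion_threshold < cap")


# ---------------------------------------------------------------------------
# Purity and purification


def purity_from_tp53(cn_tp53: float, vaf_tp53: float) -> float:
    """Purity implied by a homozygous TP53 mutation's VAF and total CN.

    Returned even if outside (0, 1] — the caller decides how to treat
    implausible estimates.
    """
    if vaf_tp53 <= 0:
        raise ValueError("VAF must be positive")
    if cn_tp53 <= 0:
        raise ValueError("copy number must be positive")
    return 2.0 / ((cn_tp53 / vaf_tp53) - (cn_tp53 - 2.0))


def purify_r(r, pp: PurityPloidy):
    """Copy ratio as it would be observed in a pure tumor (accepts arrays)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("copy ratio R must be positive")
    p, psi = pp.purity, pp.ploidy
    out = (p * psi * r + 2.0 * (1.0 - p) * (r - 1.0)) / (p * psi)
    return float(out) if out.ndim == 0 else out


def purify_log2r(log2r, pp: PurityPloidy):
    """log2R wrapper around :func:`purify_r`.

    Purified R can be ≤ 0 for deep deletions in noisy data; its log2 is
    floored at a large negative value rather than erroring.
    """
    r = np.power(2.0, np.asarray(log2r, dtype=float))
    pure = np.asarray(purify_r(r, pp))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(pure > 0, np.log2(np.maximum(pure, 1e-300)), -10.0)
    return float(out) if out.ndim == 0 else out


def purify_baf(baf, r, pp: PurityPloidy):
    """B-allele fraction corrected for normal-cell contamination.

    Clamped to [0, 1]; a zero denominator yields a missing value (NaN).
    """
    baf = np.asarray(baf, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any((baf < 0) | (baf > 1)):
        raise ValueError("BAF must be in [0, 1]")
    p, psi = pp.purity, pp.ploidy
    coef = 2.0 * (1.0 - p) + p * psi

    def f(af):
        return p - 1.0 + r * af * coef

    num = f(baf)
    den = f(1.0 - baf) + f(baf)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)
    out = np.clip(out, 0.0, 1.0)
    out = np.where(den != 0, out, np.nan)
    return float(out) if out.ndim == 0 else out


def loh(baf):
    """Loss of heterozygosity: ``abs(BAF − 0.5) × 2`` ∈ [0, 1]."""
    baf = np.asarray(baf, dtype=float)
    if np.any((baf < 0) | (baf > 1)):
        raise ValueError("BAF must be in [0, 1]")
    out = np.abs(baf - 0.5) * 2.0
    return float(out) if out.ndim == 0 else out


def mix(true_r, true_baf, pp: PurityPloidy):
    """Observed (R, BAF) produced by diluting true tumor values with normal
    cells — the algebraic inverse of ``purify_r`` / ``purify_baf``.
    """
    true_r = np.asarray(true_r, dtype=float)
    true_baf = np.asarray(true_baf, dtype=float)
    p, psi = pp.purity, pp.ploidy
    # invert purify_r
    obs_r = (p * psi * true_r + 2.0 * (1.0 - p)) / (p * psi + 2.0 * (1.0 - p))
    # invert purify_baf at the observed R
    coef = 2.0 * (1.0 - p) + p * psi
    a = p - 1.0
    b = obs_r * coef
    obs_baf = (true_baf * (2.0 * a + b) - a) / b
    if obs_r.ndim == 0:
        return float(obs_r), float(obs_baf)
    return obs_r, obs_baf


# ---------------------------------------------------------------------------
# Segment-level helpers


def purify_segments(segments: pd.DataFrame,
                    samples: Mapping[str, PurityPloidy]) -> pd.DataFrame:
    """Add purified_log2r / purified_baf / loh columns to a segment table.

    ``segments`` needs columns sample, chrom, start, end, log2R, baf;
    ``samples`` maps sample id → :class:`PurityPloidy`.
    """
    out = segments.copy()
    plog = np.empty(len(out))
    pbaf = np.empty(len(out))
    for i, row in enumerate(out.itertuples(index=False)):
        pp = samples[row.sample]
        r_obs = 2.0 ** row.log2R
        plog[i] = purify_log2r(row.log2R, pp)
        pbaf[i] = purify_baf(row.baf, r_obs, pp) if not pd.isna(row.baf) else np.nan
    out["purified_log2r"] = plog
    out["purified_baf"] = pbaf
    out["loh"] = np.abs(out["purified_baf"] - 0.5) * 2.0
    return out


def gscore_weight(purified_log2r: float, params: GScoreParams = GScoreParams()) -> float:
    """Weight one segment contributes before division by sample count.

    Zero when |purified log2R| ≤ the inclusion threshold (strict ``>`` keeps
    a segment); otherwise the amplitude clamped to ``cap``.
    """
    amp = abs(purified_log2r)
    if amp <= params.inclusion_threshold:
        return 0.0
    return min(amp, params.cap)


def gscore(segments: pd.DataFrame, n_samples: int,
           params: GScoreParams = GScoreParams(),
           value_column: str = "purified_log2r") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Amplification and deletion recurrence profiles for one sample group.

    Returns two frames with columns chrom/start/end/gscore: piecewise-constant
    profiles partitioned at segment breakpoints (adjacent equal-valued pieces
    merged, zero stretches omitted).  Each position's score is the sum of the
    clamped amplitudes of overlapping qualifying segments divided by
    ``n_samples`` — the group size, not the number of aberrant samples.
    """
    from .dataflow import DataTable, coverage  # late import: avoid cycle

    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    seg = segments.copy()
    vals = seg[value_column].astype(float)
    seg["_weight"] = np.minimum(np.abs(vals), params.cap)
    seg = seg[np.abs(vals) > params.inclusion_threshold]
    profiles = []
    for sign in (1, -1):
        sub = seg[np.sign(seg[value_column]) == sign]
        if sub.empty:
            profiles.append(pd.DataFrame(columns=["chrom", "start", "end", "gscore"]))
            continue
        table = coverage(DataTable(sub[["chrom", "start", "end", "_weight"]]),
                         weight_field="_weight", as_="gscore", chrom_field="chrom")
        df = table.df.copy()
        df["gscore"] = df["gscore"] / float(n_samples)
        if params.bin_size:
            df = _bin_profile(df, params.bin_size)
        profiles.append(df.reset_index(drop=True))
    return profiles[0], profiles[1]


def _bin_profile(df: pd.DataFrame, bin_size: int) -> pd.DataFrame:
    """Average the exact profile over fixed-width bins (coverage-weighted)."""
    rows = []
    for chrom, group in df.groupby("chrom", sort=False):
        lo = (group["start"].min() // bin_size) * bin_size
        hi = group["end"].max()
        for b0 in range(int(lo), int(hi), bin_size):
            b1 = b0 + bin_size
            overlap = np.minimum(group["end"], b1) - np.maximum(group["start"], b0)
            mask = overlap > 0
            if not mask.any():
                continue
            total = float((group.loc[mask, "gscore"] * overlap[mask]).sum())
            rows.append({"chrom": chrom, "start": b0, "end": b1,
                         "gscore": total / bin_size})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gscore"])


def count_breakpoints(segments: pd.DataFrame) -> int:
    """Breakpoints of one sample: per chromosome, one fewer than segments.

    Segments on each chromosome must be non-overlapping.
    """
    total = 0
    for chrom, group in segments.groupby("chrom", sort=False):
        g = group.sort_values("start")
        if (g["start"].values[1:] < g["end"].values[:-1]).any():
            raise ValueError(f"overlapping segments on {chrom}")
        total += max(0, len(g) - 1)
    return total


def blacklist(panel_log2r: pd.DataFrame, threshold: float = 0.2,
              min_samples: int = 3) -> list:
    """Artifact regions from a panel of normals.

    ``panel_log2r`` is regions × samples (index = region identifiers).  A
    region is blacklisted when strictly more than ``threshold`` absolute
    log2R is seen in at least ``min_samples`` normals; missing values count
    as 0 (no evidence of artifact).
    """
    if min_samples > panel_log2r.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds panel size {panel_log2r.shape[1]}")
    values = panel_log2r.fillna(0.0).abs().to_numpy()
    exceed = (values > threshold).sum(axis=1)
    return list(panel_log2r.index[exceed >= min_samples])


def ssv_filter(ssvs: pd.DataFrame, cadd_min: float = 10.0,
               cadd_column: str = "cadd",
               pathogenic_column: str = "clinvar_pathogenic") -> pd.DataFrame:
    """Keep variants with CADD ≥ ``cadd_min`` or flagged ClinVar-pathogenic."""
    cadd = ssvs[cadd_column].fillna(-np.inf)
    pathogenic = ssvs[pathogenic_column].fillna(False).astype(bool)
    return ssvs[(cadd >= cadd_min) | pathogenic].reset_index(drop=True)
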