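"""Copy-number alteration calling and cohort-level dynamics.

Works on allele-specific segment tables (0-based half-open intervals
with major/minor tumor copy number per sample).  Gains and losses are
called against an integer baseline (default 2, i.e. no whole-genome
duplication adjustment); cohort dynamics are summarized as the change,
between two timepoints, in the fraction of patients carrying a gain or
loss in each genomic bin, and as per-gene total-copy-number
trajectories across the three timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "call_gain_loss",
    "call_segments",
    "cohort_fraction_delta",
    "gene_cn_trajectory",
    "paired_cn_test",
    "PairedTestResult",
]


def call_gain_loss(total_cn: int, baseline: int = 2) -> str:
    """Classify a total copy number as loss / neutral / gain vs baseline."""
    if total_cn < 0:
        raise ValueError("negative copy number")
    if total_cn < baseline:
        return "loss"
    if total_cn > baseline:
        return "gain"
    return "neutral"


def call_segments(segments: pd.DataFrame, baseline: int = 2) -> pd.DataFrame:
    """Vectorized gain/loss calls for a segment table.

    Requires ``n_major`` and ``n_minor`` columns; adds ``total_cn`` and
    ``state``.
    """
    total = segments["n_major"].to_numpy() + segments["n_minor"].to_numpy()
    if np.any(total < 0) or np.any(segments["n_major"] < 0) or np.any(segments["n_minor"] < 0):
        raise ValueError("negative copy number")
    out = segments.copy()
    out["total_cn"] = total
    out["state"] = np.select([total < baseline, total > baseline],
                             ["loss", "gain"], default="neutral")
    return out


def cohort_fraction_delta(
    calls_t1: pd.DataFrame, calls_t2: pd.DataFrame
) -> pd.DataFrame:
    """Per-bin change in the fraction of patients with a gain or loss.

    Inputs are call tables (columns ``patient_id``, ``bin``, ``state``)
    for two timepoints.  Only patients present at both timepoints are
    used (inner join on patients).  For each bin,
    ``delta_gain = fraction(t2 gain) - fraction(t1 gain)`` and likewise
    for losses; values lie in [-1, 1].
    """
    patients = sorted(set(calls_t1["patient_id"]) & set(calls_t2["patient_id"]))
    if not patients:
        raise ValueError("no patients shared between the two timepoints")
    bins = sorted(set(calls_t1["bin"]) | set(calls_t2["bin"]))

    def _fractions(calls: pd.DataFrame) -> pd.DataFrame:
        sub = calls[calls["patient_id"].isin(patients)]
        n = len(patients)
        tab = (
            sub.groupby("bin")["state"]
            .agg(gain=lambda s: (s == "gain").sum() / n,
                 loss=lambda s: (s == "loss").sum() / n)
            .reindex(bins, fill_value=0.0)
        )
        return tab

    f1, f2 = _fractions(calls_t1), _fractions(calls_t2)
    out = pd.DataFrame(
        {
            "bin": bins,
            "delta_gain": (f2["gain"] - f1["gain"]).to_numpy(),
            "delta_loss": (f2["loss"] - f1["loss"]).to_numpy(),
            "n_patients": len(patients),
        }
    )
    return out


def gene_cn_trajectory(
    segments: pd.DataFrame,
    gene_locus: tuple[str, int, int],
    timepoints: tuple[str, ...] = ("pre", "post_a", "post_b"),
) -> pd.DataFrame:
    """Total copy number of one gene per patient per timepoint.

    ``gene_locus`` is (chrom, start, end), 0-based half-open.  When the
    gene spans several segments in a sample, the segment covering the
    largest share of the gene (length-weighted majority) supplies the
    copy number.  Missing samples or uncovered genes are NaN, never
    imputed.
    """
    chrom, gstart, gend = gene_locus
    if gend <= gstart:
        raise ValueError("empty gene locus")
    rows = []
    for pid, patient_segs in segments.groupby("patient_id", sort=True):
        rec: dict[str, object] = {"patient_id": pid}
        for tp in timepoints:
            sub = patient_segs[
                (patient_segs["timepoint"] == tp)
                & (patient_segs["chrom"] == chrom)
                & (patient_segs["start"] < gend)
                & (patient_segs["end"] > gstart)
            ]
            if len(sub) == 0:
                rec[tp] = np.nan
                continue
            overlap = np.minimum(sub["end"], gend) - np.maximum(sub["start"], gstart)
            best = sub.iloc[int(np.argmax(overlap.to_numpy()))]
            rec[tp] = float(best["n_major"] + best["n_minor"])
        rows.append(rec)
    return pd.DataFrame(rows, columns=["patient_id", *timepoints])


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    n_pairs: int
    degenerate: bool = False


def paired_cn_test(values_t1, values_t2) -> PairedTestResult:
    """Two-tailed paired Wilcoxon signed-rank test on per-patient values.

    NaN pairs are dropped; zero differences are discarded (signed-rank
    convention).  The exact null distribution is used for n <= 25
    complete non-zero pairs, the normal approximation above.  If every
    difference is zero the comparison is degenerate and reported with
    p = 1.
    """
    a = np.asarray(values_t1, dtype=float)
    b = np.asarray(values_t2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ValueError("need >= 2 complete pairs")
    d = a - b
    nonzero = d[d != 0]
    if len(nonzero) == 0:
        return PairedTestResult(0.0, 1.0, int(len(a)), degenerate=True)
    method = "exact" if len(nonzero) <= 25 else "approx"
    try:
        res = stats.wilcoxon(nonzero, alternative="two-sided", method=method)
    except ValueError:
        res = stats.wilcoxon(nonzero, alternative="two-sided", method="approx")
    return PairedTestResult(float(res.statistic), float(res.pvalue), int(len(a)))
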