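"""Thresholded somatic calling and longitudinal trajectory classification.

A mutation is *called* in a sample when it has coverage, its observed
VAF reaches ``min_vaf`` (default 5%, the conventional exome detection
limit), and it is supported by at least ``min_alt`` reads (default 3, a
stand-in for the stringency of intersecting two independent callers).

Comparing two timepoints, each mutation is persistent (called in both),
emerging (called only later), or disappearing (called only earlier).
For emerging/disappearing mutations the raw read counts in the sample
where the call is missing are re-scanned: one or more alt reads below
the calling threshold is a *trace*, evidence that the subclone was
present below the detection limit rather than truly absent/new.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "call_variants",
    "trace_scan",
    "pair_samples",
    "classify_trajectories",
    "summarize_trace_rates",
    "DEFAULT_MIN_VAF",
    "DEFAULT_MIN_ALT",
    "DEFAULT_MIN_CELLULARITY",
]

DEFAULT_MIN_VAF = 0.05
DEFAULT_MIN_ALT = 3
#: Minimum tumor cell fraction for a sample to enter longitudinal comparison.
DEFAULT_MIN_CELLULARITY = 0.20


def call_variants(
    observations: pd.DataFrame,
    min_vaf: float = DEFAULT_MIN_VAF,
    min_alt: int = DEFAULT_MIN_ALT,
) -> pd.DataFrame:
    """Apply the VAF and alt-read gates to a table of read counts.

    Parameters
    ----------
    observations : DataFrame
        Requires ``mutation_id``, ``alt_reads``, ``ref_reads`` columns;
        other columns pass through.

    Returns
    -------
    DataFrame with added ``vaf_obs``, ``called`` and ``reason`` columns;
    ``reason`` is one of pass / no_coverage / below_vaf /
    below_alt_reads (first failing gate, in that order).
    """
    alt = observations["alt_reads"].to_numpy()
    ref = observations["ref_reads"].to_numpy()
    if np.any(alt < 0) or np.any(ref < 0):
        raise ValueError("read counts must be non-negative")
    depth = alt + ref
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    called = (depth > 0) & (vaf >= min_vaf) & (alt >= min_alt)
    reason = np.full(len(observations), "pass", dtype=object)
    reason[(depth > 0) & (alt < min_alt) & (vaf >= min_vaf)] = "below_alt_reads"
    reason[(depth > 0) & (vaf < min_vaf)] = "below_vaf"
    reason[depth == 0] = "no_coverage"
    out = observations.copy()
    out["vaf_obs"] = vaf
    out["called"] = called
    out["reason"] = reason
    return out


def trace_scan(alt_reads: int, depth: int, called: bool) -> tuple[bool, int]:
    """Re-scan raw counts at a locus that may have escaped formal calling.

    Returns ``(trace_present, trace_reads)``: a trace is one or more alt
    reads at a covered locus that was *not* called (calling and trace
    presence are mutually exclusive by construction).  Counts are
    reported uncapped.
    """
    if depth <= 0:
        return False, 0
    if called:
        return False, int(alt_reads)
    return alt_reads >= 1, int(alt_reads)


@dataclass(frozen=True)
class SamplePair:
    """One longitudinal transition between two eligible samples."""

    t1: str
    t2: str
    fallback: bool = False  # True when post_b is compared directly to pre

    @property
    def label(self) -> str:
        return f"{self.t1}->{self.t2}"


def pair_samples(
    purity: dict[str, float],
    min_cellularity: float = DEFAULT_MIN_CELLULARITY,
    timepoints: tuple[str, ...] = ("pre", "post_a", "post_b"),
) -> list[SamplePair]:
    """Decide which sample pairs are comparable for one patient.

    Consecutive timepoints are paired when both samples pass the
    cellularity gate.  When the intermediate sample fails the gate (or
    is missing) but the first and last pass, the last is compared
    directly to the first (fallback pairing).
    """
    t1, t2, t3 = timepoints
    ok = {tp: purity.get(tp, 0.0) >= min_cellularity for tp in timepoints}
    pairs = []
    if ok[t1] and ok[t2]:
        pairs.append(SamplePair(t1, t2))
    if ok[t2] and ok[t3]:
        pairs.append(SamplePair(t2, t3))
    if not ok[t2] and ok[t1] and ok[t3]:
        pairs.append(SamplePair(t1, t3, fallback=True))
    return pairs


def classify_trajectories(
    calls_t1: pd.DataFrame,
    calls_t2: pd.DataFrame,
    transition: str = "t1->t2",
    include_absent: bool = False,
) -> pd.DataFrame:
    """Classify each mutation's longitudinal status between two samples.

    Both inputs are :func:`call_variants` outputs for the same patient.
    A mutation absent from one table is treated as uncovered there.
    Mutations called in neither sample carry status ``absent`` and are
    excluded from the output unless ``include_absent`` is set, matching
    a called-variant universe.

    Returns a table with columns mutation_id, transition, status,
    trace_flag, trace_reads_prior, trace_reads_post, vaf_t1, vaf_t2.
    """
    cols = ["mutation_id", "alt_reads", "ref_reads", "vaf_obs", "called"]
    merged = calls_t1[cols].merge(
        calls_t2[cols], on="mutation_id", how="outer", suffixes=("_t1", "_t2")
    )
    rows = []
    for r in merged.itertuples(index=False):
        c1 = bool(r.called_t1) if pd.notna(r.called_t1) else False
        c2 = bool(r.called_t2) if pd.notna(r.called_t2) else False
        alt1 = int(r.alt_reads_t1) if pd.notna(r.alt_reads_t1) else 0
        alt2 = int(r.alt_reads_t2) if pd.notna(r.alt_reads_t2) else 0
        d1 = alt1 + (int(r.ref_reads_t1) if pd.notna(r.ref_reads_t1) else 0)
        d2 = alt2 + (int(r.ref_reads_t2) if pd.notna(r.ref_reads_t2) else 0)
        covered1 = pd.notna(r.called_t1) and d1 > 0
        covered2 = pd.notna(r.called_t2) and d2 > 0
        trace_prior = trace_post = 0
        if c1 and c2:
            status, flag = "persistent", "not_applicable"
        elif c2 and not c1:
            status = "emerging"
            if covered1:
                present, trace_prior = trace_scan(alt1, d1, called=False)
                flag = "pre_existing_trace" if present else "no_trace"
            else:
                flag = "not_applicable"
        elif c1 and not c2:
            status = "disappearing"
            if covered2:
                present, trace_post = trace_scan(alt2, d2, called=False)
                flag = "residual_trace" if present else "no_trace"
            else:
                flag = "not_applicable"
        else:
            status, flag = "absent", "not_applicable"
        if status == "absent" and not include_absent:
            continue
        rows.append(
            dict(mutation_id=r.mutation_id, transition=transition, status=status,
                 trace_flag=flag, trace_reads_prior=trace_prior,
                 trace_reads_post=trace_post,
                 vaf_t1=r.vaf_obs_t1, vaf_t2=r.vaf_obs_t2)
        )
    return pd.DataFrame(
        rows,
        columns=["mutation_id", "transition", "status", "trace_flag",
                 "trace_reads_prior", "trace_reads_post", "vaf_t1", "vaf_t2"],
    )


def summarize_trace_rates(
    trajectories: pd.DataFrame, grouping: str = "per-cohort"
) -> pd.DataFrame:
    """Count emerging/disappearing mutations and their trace fractions.

    ``grouping`` is ``per-patient`` (requires a ``patient_id`` column)
    or ``per-cohort``.  Trace fractions are NaN — not 0 — when the
    corresponding denominator is empty.
    """
    if grouping not in ("per-patient", "per-cohort"):
        raise ValueError("grouping must be per-patient or per-cohort")

    def _one(df: pd.DataFrame) -> dict:
        emerging = df[df["status"] == "emerging"]
        disappearing = df[df["status"] == "disappearing"]
        n_e, n_d = len(emerging), len(disappearing)
        n_et = int((emerging["trace_flag"] == "pre_existing_trace").sum())
        n_dt = int((disappearing["trace_flag"] == "residual_trace").sum())
        return dict(
            n_persistent=int((df["status"] == "persistent").sum()),
            n_emerging=n_e, n_emerging_trace=n_et,
            emerging_trace_fraction=n_et / n_e if n_e else np.nan,
            n_disappearing=n_d, n_disappearing_trace=n_dt,
            disappearing_trace_fraction=n_dt / n_d if n_d else np.nan,
        )

    if grouping == "per-patient":
        rows = [
            {"patient_id": pid, **_one(g)}
            for pid, g in trajectories.groupby("patient_id", sort=True)
        ]
        return pd.DataFrame(rows)
    return pd.DataFrame([{"patient_id": "cohort", **_one(trajectories)}])
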