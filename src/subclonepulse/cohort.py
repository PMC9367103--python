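"""Clinical response classification and cohort-level association scans.

Response is scored from tumor diameters: single-lesion RECIST-style
thresholds (complete response at diameter 0, partial response at >= 30%
shrinkage, progressive disease at >= 20% growth, stable disease
otherwise), dichotomized into responders (CR/PR) vs non-responders
(SD/PD).  A second, more sensitive progression rule (UICC-style) flags
progressive disease when the product of the largest and perpendicular
diameters grows by >= 25%.

Cohort scans: per-response-group paired comparisons of tumor mutational
burden across timepoints (Wilcoxon signed-rank) and a per-gene
mutation-vs-response association scan (two-tailed Fisher exact with
Benjamini-Hochberg correction across tested genes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cna import paired_cn_test

__all__ = [
    "classify_recist",
    "classify_uicc_pd",
    "ResponseAssessment",
    "assess_response",
    "compare_tmb_by_group",
    "mutation_response_association",
    "trend_test_proportions",
]

RESPONDER_CATEGORIES = frozenset({"CR", "PR"})


def classify_recist(d1: float, d2: float) -> str:
    """RECIST-style category from largest tumor diameters (mm) at two visits.

    CR if the lesion vanished, PR at >= 30% shrinkage, PD at >= 20%
    growth, SD otherwise.
    """
    if d1 <= 0 or d2 < 0:
        raise ValueError("diameters must be positive at baseline, non-negative after")
    if d2 == 0:
        return "CR"
    change = (d2 - d1) / d1
    if change <= -0.30:
        return "PR"
    if change >= 0.20:
        return "PD"
    return "SD"


def classify_uicc_pd(l1: float, p1: float, l2: float, p2: float) -> bool:
    """Progression by the bidimensional product rule.

    True iff the product of the largest and perpendicular diameters grew
    by at least 25% (boundary inclusive).
    """
    if min(l1, p1, l2, p2) < 0:
        raise ValueError("diameters must be non-negative")
    base = l1 * p1
    if base <= 0:
        raise ValueError("baseline product must be positive")
    return (l2 * p2 - base) / base >= 0.25


@dataclass(frozen=True)
class ResponseAssessment:
    patient_id: str
    transition: str
    recist: str
    uicc_pd: bool
    responder: bool


def assess_response(
    patient_id: str,
    l1: float,
    p1: float,
    l2: float,
    p2: float,
    transition: str = "t1->t2",
) -> ResponseAssessment:
    """Combine the RECIST dichotomy with the UICC progression override.

    UICC progression forces the final category to PD (and hence
    non-responder) regardless of the unidimensional change.
    """
    recist = classify_recist(l1, l2)
    uicc = classify_uicc_pd(l1, p1, l2, p2)
    if uicc:
        recist = "PD"
    return ResponseAssessment(patient_id, transition, recist, uicc,
                              recist in RESPONDER_CATEGORIES)


def compare_tmb_by_group(tmb: pd.DataFrame) -> pd.DataFrame:
    """Paired TMB comparison between two timepoints, per response group.

    ``tmb`` needs columns ``patient_id``, ``responder`` (bool), and
    ``tmb_t1``/``tmb_t2``.  Patients missing either timepoint are
    excluded; groups with fewer than two complete pairs are reported as
    not assessable.
    """
    rows = []
    for flag, label in ((True, "responder"), (False, "non-responder")):
        g = tmb[tmb["responder"] == flag].dropna(subset=["tmb_t1", "tmb_t2"])
        rec = {"group": label, "n_pairs": len(g)}
        if len(g) < 2:
            rec.update(mean_t1=np.nan, mean_t2=np.nan, p_value=np.nan,
                       assessable=False)
        else:
            res = paired_cn_test(g["tmb_t1"], g["tmb_t2"])
            rec.update(mean_t1=float(g["tmb_t1"].mean()),
                       mean_t2=float(g["tmb_t2"].mean()),
                       p_value=res.p_value, assessable=True)
        rows.append(rec)
    return pd.DataFrame(rows)


def mutation_response_association(
    mutation_matrix: pd.DataFrame,
    responder: pd.Series,
    min_mutated: int = 3,
) -> pd.DataFrame:
    """Per-gene Fisher exact scan of mutation status against response.

    ``mutation_matrix`` is genes x patients (boolean mutated flags);
    ``responder`` is a boolean Series indexed by patient.  Genes mutated
    in fewer than ``min_mutated`` patients are not tested; genes whose
    2x2 table has an empty response margin are skipped with a note.
    P-values are Benjamini-Hochberg adjusted across tested genes.
    """
    patients = [p for p in mutation_matrix.columns if p in responder.index]
    if not patients:
        raise ValueError("no overlapping patients between matrix and labels")
    resp = responder.loc[patients].astype(bool)
    if resp.nunique() < 2:
        raise ValueError("need both responders and non-responders")
    rows = []
    for gene, row in mutation_matrix[patients].iterrows():
        mutated = row.astype(bool)
        n_mut = int(mutated.sum())
        if n_mut < min_mutated:
            continue
        table = np.array(
            [
                [int((mutated & resp).sum()), int((mutated & ~resp).sum())],
                [int((~mutated & resp).sum()), int((~mutated & ~resp).sum())],
            ]
        )
        if table.sum(axis=1).min() == 0:
            rows.append(dict(gene=gene, n_mutated=n_mut, odds_ratio=np.nan,
                             p_value=np.nan, note="degenerate_margin"))
            continue
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(dict(gene=gene, n_mutated=n_mut, odds_ratio=float(odds),
                         p_value=float(p), note=""))
    out = pd.DataFrame(rows, columns=["gene", "n_mutated", "odds_ratio",
                                      "p_value", "note"])
    out["q_value"] = np.nan
    tested = out["p_value"].notna()
    if tested.any():
        out.loc[tested, "q_value"] = multipletests(
            out.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    return out


def trend_test_proportions(successes, totals, scores=None) -> tuple[float, float]:
    """Chi-squared test for a linear trend in proportions (1 df).

    The Cochran-Armitage-style statistic used for ordered response
    groups (equivalent to R's ``prop.trend.test`` with the same
    scores).  Returns (chi2, p).
    """
    x = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if x.shape != n.shape or np.any(n <= 0) or np.any(x < 0) or np.any(x > n):
        raise ValueError("invalid success/total vectors")
    score = np.arange(1, len(x) + 1, dtype=float) if scores is None else np.asarray(scores, dtype=float)
    p_bar = x.sum() / n.sum()
    if p_bar in (0.0, 1.0):
        return 0.0, 1.0
    w = n
    s_bar = (w * score).sum() / w.sum()
    num = ((x - n * p_bar) * score).sum() ** 2
    den = p_bar * (1 - p_bar) * (w * (score - s_bar) ** 2).sum()
    chi2 = num / den
    return float(chi2), float(stats.chi2.sf(chi2, df=1))
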