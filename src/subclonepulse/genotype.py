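"""Purity- and copy-number-aware allele-frequency algebra.

The central quantity is the *relative VAF* (rVAF): the observed variant
allele frequency divided by the VAF expected for a fully clonal mutation
given the local total copy number ``n_tot``, the number of mutated allele
copies ``n_mut`` (multiplicity), and the tumor cell fraction ``rho``
(purity).  For a clonal mutation rVAF is ~1; sub-clonal mutations sit
below 1, so the clamped rVAF serves as a cellular-prevalence estimate.

Expected VAF model::

    VAF_exp = n_mut * rho / (2 * (1 - rho) + n_tot * rho)

i.e. mutated copies contributed by tumor cells over all allele copies in
the sequenced mixture (normal cells are diploid wild type).

Also houses tumor mutational burden (TMB, coding mutations per megabase)
and the six-class pyrimidine-collapsed substitution spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VafContext",
    "TmbRecord",
    "expected_vaf",
    "rvaf",
    "cellular_prevalence",
    "estimate_multiplicity",
    "compute_tmb",
    "substitution_spectrum",
    "CODING_EFFECTS",
    "SPECTRUM_CLASSES",
]

#: Effect classes counted as amino-acid changing.
CODING_EFFECTS = frozenset({"missense", "nonsense", "frameshift", "splice"})

#: The six pyrimidine-reference substitution classes.
SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def expected_vaf(n_mut, n_tot, purity):
    """Expected VAF of a fully clonal mutation.

    Parameters
    ----------
    n_mut : int or array
        Number of mutated allele copies per tumor cell (1 <= n_mut <= n_tot).
    n_tot : int or array
        Total copy number at the locus in tumor cells (>= 1).
    purity : float or array
        Tumor cell fraction rho in (0, 1].

    Returns
    -------
    float or ndarray in (0, 1].
    """
    n_mut = np.asarray(n_mut, dtype=float)
    n_tot = np.asarray(n_tot, dtype=float)
    purity = np.asarray(purity, dtype=float)
    if np.any(purity <= 0) or np.any(purity > 1):
        raise ValueError("purity must lie in (0, 1]")
    if np.any(n_tot < 1):
        raise ValueError("n_tot must be >= 1")
    if np.any(n_mut < 1) or np.any(n_mut > n_tot):
        raise ValueError("n_mut must satisfy 1 <= n_mut <= n_tot")
    out = n_mut * purity / (2.0 * (1.0 - purity) + n_tot * purity)
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class VafContext:
    """Per-mutation genotype context needed to correct an observed VAF."""

    vaf_obs: float
    n_mut: int = 1
    n_tot: int = 2
    purity: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf_obs <= 1.0:
            raise ValueError("vaf_obs must lie in [0, 1]")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must lie in (0, 1]")
        if self.n_tot < 1 or not 1 <= self.n_mut <= self.n_tot:
            raise ValueError("require 1 <= n_mut <= n_tot")

    @property
    def expected_vaf(self) -> float:
        return expected_vaf(self.n_mut, self.n_tot, self.purity)


def rvaf(vaf_obs, n_mut=1, n_tot=2, purity=1.0):
    """Relative VAF: observed over expected-clonal VAF.

    Returned raw (uncapped); sampling noise can push truly clonal
    mutations slightly above 1.  Use :func:`cellular_prevalence` for the
    [0, 1]-clamped value used in displays and clustering input.
    """
    vaf_obs = np.asarray(vaf_obs, dtype=float)
    if np.any(vaf_obs < 0) or np.any(vaf_obs > 1):
        raise ValueError("vaf_obs must lie in [0, 1]")
    out = vaf_obs / expected_vaf(n_mut, n_tot, purity)
    return out.item() if out.ndim == 0 else out


def cellular_prevalence(vaf_obs, n_mut=1, n_tot=2, purity=1.0):
    """rVAF clamped to [0, 1]; an estimate of the cancer cell fraction."""
    return np.clip(rvaf(vaf_obs, n_mut, n_tot, purity), 0.0, 1.0)


def estimate_multiplicity(vaf_obs: float, n_tot: int, purity: float) -> int:
    """Estimate the number of mutated allele copies at a locus.

    Chooses the multiplicity ``m`` in 1..n_tot whose expected clonal VAF
    is nearest the observation; ties break toward the smaller ``m``.
    Exactly inverts :func:`expected_vaf` on noiseless input.
    """
    if n_tot < 1:
        raise ValueError("n_tot must be >= 1")
    candidates = np.arange(1, int(n_tot) + 1)
    expect = expected_vaf(candidates, int(n_tot), purity)
    return int(candidates[np.argmin(np.abs(expect - vaf_obs))])


@dataclass(frozen=True)
class TmbRecord:
    """Tumor mutational burden for one sample."""

    sample_id: str
    n_coding_mutations: int
    target_size_mb: float
    tmb: float


def compute_tmb(
    mutations: pd.DataFrame,
    target_size_mb: float = 50.0,
    coding_only: bool = True,
    sample_id: str = "",
) -> TmbRecord:
    """Mutations per megabase of sequenced target.

    Parameters
    ----------
    mutations : DataFrame
        One row per called mutation; needs an ``effect`` column when
        ``coding_only`` is set.
    target_size_mb : float
        Size of the captured target in megabases (default 50, an
        exome-capture-sized target).
    coding_only : bool
        Count only amino-acid-changing mutations (missense, nonsense,
        frameshift, splice); synonymous variants are excluded.
    """
    if target_size_mb <= 0:
        raise ValueError("target_size_mb must be positive")
    if coding_only and len(mutations):
        n = int(mutations["effect"].isin(CODING_EFFECTS).sum())
    else:
        n = int(len(mutations))
    return TmbRecord(sample_id, n, float(target_size_mb), n / float(target_size_mb))


def substitution_spectrum(mutations: pd.DataFrame) -> dict[str, int]:
    """Tally SNVs into the six pyrimidine-reference substitution classes.

    Purine-reference substitutions are collapsed onto their reverse
    complement (G>A counts as C>T).  Indels and records with non-ACGT
    alleles are skipped (the latter with a warning).  Counts sum to the
    number of admissible SNVs.
    """
    counts = {cls: 0 for cls in SPECTRUM_CLASSES}
    if not len(mutations):
        return counts
    for ref, alt in zip(mutations["ref"].astype(str), mutations["alt"].astype(str)):
        if len(ref) != 1 or len(alt) != 1:
            continue  # indel
        ref, alt = ref.upper(), alt.upper()
        if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
            warnings.warn(f"skipping non-ACGT substitution {ref}>{alt}", stacklevel=2)
            continue
        if ref in ("G", "A"):
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        counts[f"{ref}>{alt}"] += 1
    return counts
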