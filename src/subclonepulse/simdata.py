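"""Synthetic longitudinal tumor cohorts with known clonal ground truth.

Emulates the data shape of a neoadjuvant trial in which each tumor is
biopsied at three timepoints — pretreatment (``pre``), after the first
chemotherapy regimen (``post_a``), and after the second (``post_b``) —
and exome-sequenced at moderate depth.  Each simulated tumor carries a
truncal clone (prevalence 1 at every timepoint) plus a small nested
hierarchy of subclones whose cellular prevalences drift multiplicatively
between timepoints and whose small members can go extinct, so that
subclones churn across the detection limit while truncal mutations
persist.  Read counts are emitted from the purity/copy-number expected
VAF model, giving every downstream stage a scored ground truth.

Genome model: a fixed list of bins (by default the p/q arms of 22
autosomes, 50 Mb each).  Copy number starts diploid everywhere;
configurable directed events add gains/losses at a stated timepoint with
a stated probability and persist thereafter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype import expected_vaf

__all__ = [
    "TIMEPOINTS",
    "DEFAULT_BINS",
    "EFFECT_CLASSES",
    "CnaEvent",
    "SimConfig",
    "Subclone",
    "ClonalTree",
    "PatientData",
    "Cohort",
    "simulate_clonal_tree",
    "simulate_copy_number",
    "simulate_reads",
    "simulate_cohort",
    "write_cohort",
]

#: Fixed timepoint vocabulary, in temporal order.
TIMEPOINTS = ("pre", "post_a", "post_b")

#: Effect classes and their sampling weights (amino-acid-changing heavy).
EFFECT_CLASSES = ("missense", "nonsense", "frameshift", "splice", "synonymous")
_EFFECT_WEIGHTS = (0.60, 0.10, 0.08, 0.07, 0.15)

_ARM_LENGTH = 50_000_000
_BASES = ("A", "C", "G", "T")


def _default_bins() -> dict[str, tuple[str, int, int]]:
    bins: dict[str, tuple[str, int, int]] = {}
    for c in range(1, 23):
        bins[f"{c}p"] = (f"chr{c}", 0, _ARM_LENGTH)
        bins[f"{c}q"] = (f"chr{c}", _ARM_LENGTH, 2 * _ARM_LENGTH)
    return bins


#: Default genome model: chromosome arms as bins, 0-based half-open.
DEFAULT_BINS = _default_bins()


@dataclass(frozen=True)
class CnaEvent:
    """A directed copy-number event applied to one bin at one timepoint."""

    bin: str
    timepoint: str
    kind: str  # "gain" or "loss"
    probability: float = 1.0


@dataclass
class SimConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror a moderate-size neoadjuvant exome cohort: ~150x mean
    target depth, tumor purity declining under treatment, 2-6 subclones
    per tumor, and enough multiplicative prevalence drift
    (``expansion_sd``, log-scale SD) plus extinction of small clones
    that subclones regularly cross a 5% VAF detection limit.
    """

    n_patients: int = 10
    n_subclones_range: tuple[int, int] = (2, 6)
    mutations_per_clone_range: tuple[int, int] = (8, 25)
    depth_mean: float = 150.0
    purity_by_timepoint: tuple[float, float, float] = (0.7, 0.45, 0.35)
    extinction_prob_small_clone: float = 0.3
    expansion_sd: float = 0.5
    sequencing_error_rate: float = 0.0
    directed_cna_events: tuple[CnaEvent, ...] = ()
    bins: dict[str, tuple[str, int, int]] = field(default_factory=_default_bins)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for lo, hi in (self.n_subclones_range, self.mutations_per_clone_range):
            if lo > hi or lo < 1:
                raise ValueError("ranges must be ordered pairs of positive ints")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        for p in self.purity_by_timepoint:
            if not 0.0 < p <= 1.0:
                raise ValueError("purities must lie in (0, 1]")
        for p in (self.extinction_prob_small_clone, self.sequencing_error_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.expansion_sd < 0:
            raise ValueError("expansion_sd must be >= 0")
        for ev in self.directed_cna_events:
            if ev.bin not in self.bins:
                raise ValueError(f"directed CNA event references unknown bin {ev.bin!r}")
            if ev.timepoint not in TIMEPOINTS:
                raise ValueError(f"unknown timepoint {ev.timepoint!r}")
            if ev.kind not in ("gain", "loss"):
                raise ValueError(f"CNA event kind must be gain/loss, got {ev.kind!r}")
            if not 0.0 <= ev.probability <= 1.0:
                raise ValueError("event probability must lie in [0, 1]")

    @property
    def purity(self) -> dict[str, float]:
        return dict(zip(TIMEPOINTS, self.purity_by_timepoint))


@dataclass
class Subclone:
    subclone_id: int
    parent_id: int | None  # None marks the truncal root
    prevalence: dict[str, float]  # timepoint -> lineage-inclusive fraction
    mutation_ids: list[str]


@dataclass
class ClonalTree:
    """Nested subclone hierarchy with per-timepoint cellular prevalences.

    Prevalences are lineage-inclusive (a clone's value counts its
    descendants), so the truncal root is 1.0 at every timepoint and, at
    every timepoint, each node's children sum to at most its own value.
    A mutation's cancer cell fraction equals its clone's prevalence.
    """

    subclones: list[Subclone]

    def __post_init__(self) -> None:
        self._by_id = {s.subclone_id: s for s in self.subclones}

    @property
    def root(self) -> Subclone:
        return self._by_id[0]

    def children(self, subclone_id: int) -> list[Subclone]:
        return [s for s in self.subclones if s.parent_id == subclone_id]

    def prevalence(self, subclone_id: int, timepoint: str) -> float:
        return self._by_id[subclone_id].prevalence[timepoint]

    def mutation_clone(self) -> dict[str, int]:
        return {m: s.subclone_id for s in self.subclones for m in s.mutation_ids}

    def mutation_ccf(self, mutation_id: str, timepoint: str) -> float:
        return self._by_id[self.mutation_clone()[mutation_id]].prevalence[timepoint]


def simulate_clonal_tree(config: SimConfig, rng: np.random.Generator) -> ClonalTree:
    """Draw a clonal hierarchy and its prevalence trajectory.

    The pretreatment prevalences are assigned by stick-breaking within
    each parent's unallocated share.  Between consecutive timepoints each
    surviving subclone's prevalence is multiplied by a log-normal factor
    ``exp(N(0, expansion_sd))``; subclones below 0.1 prevalence
    additionally go extinct with probability
    ``extinction_prob_small_clone``.  Nesting is restored top-down by
    rescaling any children whose sum exceeds their parent.  The truncal
    root stays at prevalence 1 throughout; extinct clones stay extinct.
    """
    lo, hi = config.n_subclones_range
    k = int(rng.integers(lo, hi + 1))
    parent_of = {0: None}
    for i in range(1, k + 1):
        parent_of[i] = int(rng.integers(0, i))

    prev = {0: {tp: 1.0 for tp in TIMEPOINTS}}
    allocated = {i: 0.0 for i in range(k + 1)}
    for i in range(1, k + 1):
        p = parent_of[i]
        avail = prev[p]["pre"] - allocated[p]
        value = avail * rng.uniform(0.05, 0.8)
        allocated[p] += value
        prev[i] = {"pre": value}

    for tp_prev, tp_next in zip(TIMEPOINTS, TIMEPOINTS[1:]):
        for i in range(1, k + 1):
            v = prev[i][tp_prev]
            if v > 0:
                v = min(v * rng.lognormal(0.0, config.expansion_sd), 1.0)
                if prev[i][tp_prev] < 0.1 and rng.random() < config.extinction_prob_small_clone:
                    v = 0.0
            prev[i][tp_next] = v
        # top-down renormalization: children may not exceed their parent
        for node in range(k + 1):
            kids = [i for i in range(1, k + 1) if parent_of[i] == node]
            total = sum(prev[i][tp_next] for i in kids)
            if total > prev[node][tp_next] and total > 0:
                scale = prev[node][tp_next] / total
                for i in kids:
                    prev[i][tp_next] *= scale

    m_lo, m_hi = config.mutations_per_clone_range
    subclones, counter = [], 0
    for i in range(k + 1):
        n_mut = int(rng.integers(m_lo, m_hi + 1))
        ids = [f"m{counter + j:04d}" for j in range(n_mut)]
        counter += n_mut
        subclones.append(Subclone(i, parent_of[i], prev[i], ids))
    return ClonalTree(subclones)


def assign_mutation_loci(
    tree: ClonalTree, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Place each mutation at a random position in a random genome bin."""
    bin_names = list(config.bins)
    rows = []
    for sub in tree.subclones:
        for mid in sub.mutation_ids:
            b = bin_names[int(rng.integers(len(bin_names)))]
            chrom, start, end = config.bins[b]
            pos = int(rng.integers(start + 1, end + 1))  # 1-based
            ref = _BASES[int(rng.integers(4))]
            alt = rng.choice([x for x in _BASES if x != ref])
            effect = rng.choice(EFFECT_CLASSES, p=_EFFECT_WEIGHTS)
            gene = f"G{b}_{int(rng.integers(1, 5))}"
            rows.append(
                dict(mutation_id=mid, subclone_id=sub.subclone_id, bin=b,
                     chrom=chrom, pos=pos, ref=ref, alt=str(alt),
                     gene=gene, effect=str(effect))
            )
    return pd.DataFrame(rows)


def simulate_copy_number(
    tree: ClonalTree,
    config: SimConfig,
    rng: np.random.Generator,
    mutated_bins: set[str] | None = None,
) -> pd.DataFrame:
    """Per-timepoint allele-specific copy-number segments for one patient.

    Baseline is diploid heterozygous (major 1, minor 1) in every bin.
    Directed events fire at their stated timepoint with their stated
    probability and persist at later timepoints; a loss removes the
    minor allele first and never drives a bin carrying mutations below
    total copy number 1.
    """
    mutated_bins = mutated_bins or set()
    state = {b: [1, 1] for b in config.bins}  # [major, minor]
    rows = []
    for tp in TIMEPOINTS:
        for ev in config.directed_cna_events:
            if ev.timepoint != tp:
                continue
            if rng.random() >= ev.probability:
                continue
            major, minor = state[ev.bin]
            if ev.kind == "gain":
                state[ev.bin] = [major + 1, minor]
            else:
                total = major + minor
                floor = 1 if ev.bin in mutated_bins else 0
                if total - 1 >= floor:
                    if minor > 0:
                        state[ev.bin] = [major, minor - 1]
                    else:
                        state[ev.bin] = [major - 1, minor]
        for b, (chrom, start, end) in config.bins.items():
            major, minor = state[b]
            rows.append(dict(timepoint=tp, bin=b, chrom=chrom, start=start,
                             end=end, n_major=major, n_minor=minor))
    return pd.DataFrame(rows)


def simulate_reads(
    mutation_ccf: float,
    n_mut: int,
    n_tot: int,
    purity: float,
    depth_mean: float,
    rng: np.random.Generator,
    error_rate: float = 0.0,
) -> tuple[int, int]:
    """Draw (alt_reads, ref_reads) for one mutation in one sample.

    Total depth is Poisson(``depth_mean``); alt reads are binomial with
    success probability ``mutation_ccf * expected_vaf(n_mut, n_tot,
    purity)``.  A nonzero ``error_rate`` adds Binomial(depth, error_rate)
    false alt reads, capped at the depth.
    """
    if not 0.0 <= mutation_ccf <= 1.0:
        raise ValueError("mutation_ccf must lie in [0, 1]")
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    depth = int(rng.poisson(depth_mean))
    if depth == 0:
        return 0, 0
    p = mutation_ccf * expected_vaf(n_mut, n_tot, purity)
    alt = int(rng.binomial(depth, p))
    if error_rate > 0:
        alt = min(depth, alt + int(rng.binomial(depth, error_rate)))
    return alt, depth - alt


@dataclass
class PatientData:
    patient_id: str
    tree: ClonalTree
    mutations: pd.DataFrame  # long: one row per mutation per timepoint
    segments: pd.DataFrame
    purity: dict[str, float]


@dataclass
class Cohort:
    config: SimConfig
    patients: list[PatientData]

    def truth(self) -> dict:
        """Ground-truth clonal structure, JSON-serializable."""
        out = {"patients": []}
        for p in self.patients:
            out["patients"].append(
                {
                    "patient_id": p.patient_id,
                    "tree": [
                        {
                            "subclone_id": s.subclone_id,
                            "parent_id": s.parent_id,
                            "prevalence": {tp: s.prevalence[tp] for tp in TIMEPOINTS},
                            "mutation_ids": list(s.mutation_ids),
                        }
                        for s in p.tree.subclones
                    ],
                    "mutation_to_subclone": p.tree.mutation_clone(),
                    "purity": p.purity,
                }
            )
        return out


def simulate_cohort(config: SimConfig) -> Cohort:
    """Simulate a full cohort: trees, copy number, and read counts."""
    ss = np.random.SeedSequence(config.seed)
    patients = []
    for pi, child in enumerate(ss.spawn(config.n_patients)):
        rng = np.random.default_rng(child)
        pid = f"P{pi + 1:03d}"
        tree = simulate_clonal_tree(config, rng)
        loci = assign_mutation_loci(tree, config, rng)
        segments = simulate_copy_number(
            tree, config, rng, mutated_bins=set(loci["bin"])
        )
        seg_cn = segments.set_index(["timepoint", "bin"])
        rows = []
        for tp in TIMEPOINTS:
            rho = config.purity[tp]
            for locus in loci.itertuples(index=False):
                seg = seg_cn.loc[(tp, locus.bin)]
                n_tot = int(seg["n_major"] + seg["n_minor"])
                ccf = tree.prevalence(locus.subclone_id, tp)
                alt, ref = simulate_reads(
                    ccf, 1, n_tot, rho, config.depth_mean, rng,
                    error_rate=config.sequencing_error_rate,
                )
                rows.append(
                    dict(patient_id=pid, timepoint=tp, chrom=locus.chrom,
                         pos=locus.pos, ref=locus.ref, alt=locus.alt,
                         gene=locus.gene, effect=locus.effect,
                         alt_reads=alt, ref_reads=ref,
                         mutation_id=locus.mutation_id)
                )
        segments = segments.assign(patient_id=pid)[
            ["patient_id", "timepoint", "chrom", "start", "end", "n_major", "n_minor"]
        ]
        patients.append(
            PatientData(pid, tree, pd.DataFrame(rows), segments, dict(config.purity))
        )
    return Cohort(config, patients)


_VCF_MUT_COLS = ["patient_id", "timepoint", "chrom", "pos", "ref", "alt",
                 "gene", "effect", "alt_reads", "ref_reads", "mutation_id"]


def _write_vcf(sample: pd.DataFrame, path: Path, patient_id: str, timepoint: str) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=subclonepulse",
    ]
    lines += [
        f"##contig=<ID=chr{c},length={2 * _ARM_LENGTH}>" for c in range(1, 23)
    ]
    lines += [
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Effect class">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{patient_id}.{timepoint}",
    ]
    for r in sample.sort_values(["chrom", "pos"]).itertuples(index=False):
        lines.append(
            f"{r.chrom}\t{r.pos}\t{r.mutation_id}\t{r.ref}\t{r.alt}\t.\tPASS\t"
            f"GENE={r.gene};EFFECT={r.effect}\tAD\t{r.ref_reads},{r.alt_reads}"
        )
    path.write_text("\n".join(lines) + "\n")


def write_cohort(cohort: Cohort, out_dir: str | Path, write_vcf: bool = True) -> dict[str, list[str]]:
    """Serialize a cohort: per-sample mutation TSV/VCF, segments, purity, truth.

    Output is deterministic given the cohort (stable row order, plain
    text).  Returns a manifest of written file names by category.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str]] = {"mutations": [], "vcf": [], "segments": [],
                                      "purity": [], "truth": []}
    seg_all, purity_rows = [], []
    for p in cohort.patients:
        for tp in TIMEPOINTS:
            sample = p.mutations[p.mutations["timepoint"] == tp][_VCF_MUT_COLS]
            name = f"{p.patient_id}.{tp}.muts.tsv"
            sample.to_csv(out / name, sep="\t", index=False)
            manifest["mutations"].append(name)
            if write_vcf:
                vname = f"{p.patient_id}.{tp}.vcf"
                _write_vcf(sample, out / vname, p.patient_id, tp)
                manifest["vcf"].append(vname)
            purity_rows.append(dict(patient_id=p.patient_id, timepoint=tp,
                                    purity=p.purity[tp]))
        seg_all.append(p.segments)
    pd.concat(seg_all).to_csv(out / "segments.tsv", sep="\t", index=False)
    pd.DataFrame(purity_rows).to_csv(out / "purity.tsv", sep="\t", index=False)
    manifest["segments"].append("segments.tsv")
    manifest["purity"].append("purity.tsv")
    (out / "truth.json").write_text(json.dumps(cohort.truth(), indent=1, sort_keys=True))
    manifest["truth"].append("truth.json")
    return manifest
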