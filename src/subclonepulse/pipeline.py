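"""End-to-end orchestration: simulate or load a cohort, then run every
analysis stage and write a reproducible report bundle.

Stages, per patient: purity-based eligibility gating (tumor cell
fraction >= 20% by default, with each decision logged), rVAF tables,
thresholded calling, longitudinal trajectory classification with
trace-read re-scanning (falling back to a direct pre -> post_b
comparison when the intermediate sample is ineligible), and clonal
clustering with singleton-merge and small-cluster display pruning.
Cohort level: TMB per sample, CNA fraction deltas between timepoints,
trace-rate summaries, and — when clinical measurements are supplied —
response classification and a gene-mutation association scan.  When the
input is simulated, a truth-vs-inferred scorecard is added.  A manifest
records the configuration hash so reruns are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (ClusterModel, build_fishplot_table, cluster_mutations,
                         merge_singletons, prune_small_clusters)
from .cna import call_segments, cohort_fraction_delta
from .cohort import assess_response, mutation_response_association
from .detection import (DEFAULT_MIN_ALT, DEFAULT_MIN_CELLULARITY,
                        DEFAULT_MIN_VAF, call_variants, classify_trajectories,
                        pair_samples, summarize_trace_rates)
from .genotype import compute_tmb, estimate_multiplicity
from .io import read_measurements, read_mutation_table, read_purity, read_segments
from .simdata import TIMEPOINTS, Cohort, SimConfig, simulate_cohort, write_cohort

__all__ = ["RunConfig", "RunResult", "run_pipeline"]

logger = logging.getLogger("subclonepulse")


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``simulate`` (a :class:`SimConfig`) or the input
    paths (``mutation_tables`` + ``segments_path`` + ``purity_path``)
    must be provided.  ``seed`` drives every source of randomness,
    including the simulator when present.
    """

    simulate: SimConfig | None = None
    mutation_tables: tuple[str, ...] = ()
    segments_path: str | None = None
    purity_path: str | None = None
    measurements_path: str | None = None
    min_vaf: float = DEFAULT_MIN_VAF
    min_alt: int = DEFAULT_MIN_ALT
    min_cellularity: float = DEFAULT_MIN_CELLULARITY
    k_max: int = 10
    tmb_target_size_mb: float = 50.0
    tmb_coding_only: bool = True
    min_mutated: int = 3
    seed: int = 0
    out_dir: str = "subclonepulse_run"

    def __post_init__(self) -> None:
        has_paths = bool(self.mutation_tables)
        if self.simulate is not None and has_paths:
            raise ValueError("provide either a simulate block or input paths, not both")
        if self.simulate is None and not has_paths:
            raise ValueError("one of simulate block or input paths is required")
        if has_paths and (self.segments_path is None or self.purity_path is None):
            raise ValueError("segments_path and purity_path required with mutation_tables")
        if not 0.0 <= self.min_vaf <= 1.0 or not 0.0 <= self.min_cellularity <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
        if self.min_alt < 0 or self.k_max < 1 or self.tmb_target_size_mb <= 0:
            raise ValueError("invalid threshold configuration")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            if "directed_cna_events" in sim:
                from .simdata import CnaEvent

                sim["directed_cna_events"] = tuple(
                    CnaEvent(**ev) for ev in sim["directed_cna_events"]
                )
            for key in ("n_subclones_range", "mutations_per_clone_range",
                        "purity_by_timepoint"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimConfig(**sim)
        if "mutation_tables" in raw:
            raw["mutation_tables"] = tuple(raw["mutation_tables"])
        return cls(simulate=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"]["bins"] = {
                k: list(v) for k, v in self.simulate.bins.items()
            }
        return d

    def config_hash(self) -> str:
        # out_dir is a destination, not part of the analysis configuration
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class RunResult:
    out_dir: Path
    manifest: dict
    rvaf: pd.DataFrame
    trajectories: pd.DataFrame
    clusters: pd.DataFrame
    fishplot: pd.DataFrame
    tmb: pd.DataFrame
    cna_delta: pd.DataFrame
    trace_summary: pd.DataFrame
    eligibility: pd.DataFrame
    response: pd.DataFrame | None = None
    association: pd.DataFrame | None = None
    scorecard: dict | None = None
    cluster_models: dict[str, ClusterModel] = field(default_factory=dict)


def _load_inputs(config: RunConfig):
    """Return (mutations, segments, purity, truth-or-None)."""
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        cohort = simulate_cohort(sim)
        muts = pd.concat([p.mutations for p in cohort.patients], ignore_index=True)
        segs = pd.concat([p.segments for p in cohort.patients], ignore_index=True)
        purity = pd.DataFrame(
            [
                dict(patient_id=p.patient_id, timepoint=tp, purity=p.purity[tp])
                for p in cohort.patients
                for tp in TIMEPOINTS
            ]
        )
        return muts, segs, purity, cohort
    muts = pd.concat(
        [read_mutation_table(p) for p in config.mutation_tables], ignore_index=True
    )
    segs = read_segments(config.segments_path)
    purity = read_purity(config.purity_path)
    return muts, segs, purity, None


def _annotate_copy_number(
    sample: pd.DataFrame, segments: pd.DataFrame, purity: float
) -> pd.DataFrame:
    """Attach n_tot / n_mut / rVAF columns to one sample's mutations."""
    out = sample.copy()
    n_tot = np.full(len(out), 2, dtype=int)
    matched = np.zeros(len(out), dtype=bool)
    if len(segments):
        seg = segments.reset_index(drop=True)
        for i, (chrom, pos) in enumerate(zip(out["chrom"], out["pos"])):
            hit = seg[(seg["chrom"] == chrom) & (seg["start"] < pos) & (pos <= seg["end"])]
            if len(hit):
                n_tot[i] = max(1, int(hit.iloc[0]["n_major"] + hit.iloc[0]["n_minor"]))
                matched[i] = True
    if not matched.all():
        warnings.warn(
            f"{int((~matched).sum())} mutation(s) lack copy-number overlap; "
            "defaulting to n_tot=2, n_mut=1",
            stacklevel=2,
        )
    depth = out["alt_reads"] + out["ref_reads"]
    vaf = np.where(depth > 0, out["alt_reads"] / depth.clip(lower=1), 0.0)
    n_mut = np.where(
        matched,
        [estimate_multiplicity(v, nt, purity) for v, nt in zip(vaf, n_tot)],
        1,
    )
    out["n_tot"] = n_tot
    out["n_mut"] = n_mut
    out["vaf_obs"] = vaf
    out["rvaf"] = [
        v / _expected(vm, nt, purity) for v, vm, nt in zip(vaf, n_mut, n_tot)
    ]
    out["ccf"] = np.clip(out["rvaf"], 0.0, 1.0)
    out["purity"] = purity
    return out


def _expected(n_mut, n_tot, purity):
    from .genotype import expected_vaf

    return expected_vaf(int(n_mut), int(n_tot), purity)


def _cluster_patient(
    calls: dict[str, pd.DataFrame],
    eligible: list[str],
    k_max: int,
    seed: int,
) -> ClusterModel | None:
    called_any = set()
    for tp in eligible:
        called_any |= set(calls[tp].loc[calls[tp]["called"], "mutation_id"])
    called_any = sorted(called_any)
    if len(called_any) < 2 or len(eligible) < 1:
        return None
    X = np.zeros((len(called_any), len(eligible)))
    D = np.zeros_like(X)
    for j, tp in enumerate(eligible):
        tab = calls[tp].set_index("mutation_id")
        for i, mid in enumerate(called_any):
            if mid in tab.index:
                row = tab.loc[mid]
                X[i, j] = row["ccf"]
                D[i, j] = row["alt_reads"] + row["ref_reads"]
    model = cluster_mutations(
        pd.DataFrame(X, index=called_any, columns=eligible),
        pd.DataFrame(D, index=called_any, columns=eligible),
        k_max=k_max,
        seed=seed,
    )
    return model


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage and write the report bundle to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    muts, segs, purity, cohort = _load_inputs(config)

    purity_map: dict[str, dict[str, float]] = {}
    for r in purity.itertuples(index=False):
        purity_map.setdefault(r.patient_id, {})[r.timepoint] = float(r.purity)

    rvaf_tables, traj_tables, elig_rows = [], [], []
    cluster_models: dict[str, ClusterModel] = {}
    cluster_rows, fish_rows, tmb_rows = [], [], []

    for pi, pid in enumerate(sorted(purity_map)):
        pmut = muts[muts["patient_id"] == pid]
        psegs = segs[segs["patient_id"] == pid]
        rho = purity_map[pid]
        calls: dict[str, pd.DataFrame] = {}
        eligible: list[str] = []
        for tp in TIMEPOINTS:
            if tp not in rho:
                elig_rows.append(dict(patient_id=pid, timepoint=tp, purity=np.nan,
                                      eligible=False, reason="missing_sample"))
                logger.info("eligibility %s %s: missing sample", pid, tp)
                continue
            ok = rho[tp] >= config.min_cellularity
            elig_rows.append(dict(patient_id=pid, timepoint=tp, purity=rho[tp],
                                  eligible=ok,
                                  reason="pass" if ok else "low_cellularity"))
            logger.info("eligibility %s %s: purity=%.2f -> %s", pid, tp, rho[tp],
                        "eligible" if ok else "ineligible")
            sample = pmut[pmut["timepoint"] == tp]
            if not len(sample):
                continue
            annotated = _annotate_copy_number(
                sample, psegs[psegs["timepoint"] == tp], rho[tp]
            )
            annotated = call_variants(annotated, config.min_vaf, config.min_alt)
            calls[tp] = annotated
            rvaf_tables.append(annotated)
            if ok:
                eligible.append(tp)
            called = annotated[annotated["called"]]
            tmb_rows.append(
                dict(patient_id=pid, timepoint=tp, eligible=ok,
                     tmb=compute_tmb(called, config.tmb_target_size_mb,
                                     config.tmb_coding_only).tmb)
            )

        for pair in pair_samples(rho, config.min_cellularity):
            if pair.t1 not in calls or pair.t2 not in calls:
                continue
            traj = classify_trajectories(calls[pair.t1], calls[pair.t2],
                                         transition=pair.label)
            traj.insert(0, "patient_id", pid)
            traj["fallback_pairing"] = pair.fallback
            traj_tables.append(traj)

        if eligible and calls:
            model = _cluster_patient(calls, eligible, config.k_max,
                                     seed=(config.seed + pi) % (2**31))
            if model is not None:
                model = merge_singletons(model)
                display, _removed = prune_small_clusters(model)
                cluster_models[pid] = model
                tab = model.prevalence_table()
                tab.insert(0, "patient_id", pid)
                cluster_rows.append(tab)
                if display.n_clusters:
                    fish = build_fishplot_table(display)
                    fish.insert(0, "patient_id", pid)
                    fish_rows.append(fish)

    rvaf = pd.concat(rvaf_tables, ignore_index=True) if rvaf_tables else pd.DataFrame()
    trajectories = (
        pd.concat(traj_tables, ignore_index=True) if traj_tables else pd.DataFrame(
            columns=["patient_id", "mutation_id", "transition", "status",
                     "trace_flag", "trace_reads_prior", "trace_reads_post",
                     "vaf_t1", "vaf_t2", "fallback_pairing"])
    )
    clusters = pd.concat(cluster_rows, ignore_index=True) if cluster_rows else pd.DataFrame()
    fishplot = pd.concat(fish_rows, ignore_index=True) if fish_rows else pd.DataFrame()
    tmb = pd.DataFrame(tmb_rows)
    eligibility = pd.DataFrame(elig_rows)

    trace_summary = (
        pd.concat(
            [summarize_trace_rates(trajectories, "per-patient"),
             summarize_trace_rates(trajectories, "per-cohort")],
            ignore_index=True,
        )
        if len(trajectories)
        else pd.DataFrame()
    )

    seg_calls = call_segments(segs)
    seg_calls = seg_calls.assign(
        bin=seg_calls["chrom"].astype(str) + ":" + seg_calls["start"].astype(str)
        + "-" + seg_calls["end"].astype(str)
    )
    deltas = []
    for t1, t2 in (("pre", "post_a"), ("post_a", "post_b"), ("pre", "post_b")):
        c1 = seg_calls[seg_calls["timepoint"] == t1]
        c2 = seg_calls[seg_calls["timepoint"] == t2]
        if len(c1) and len(c2):
            d = cohort_fraction_delta(c1, c2)
            d.insert(0, "transition", f"{t1}->{t2}")
            deltas.append(d)
    cna_delta = pd.concat(deltas, ignore_index=True) if deltas else pd.DataFrame()

    response = association = None
    if config.measurements_path:
        meas = read_measurements(config.measurements_path)
        response = _assess_cohort_response(meas)
        pre_called = rvaf[(rvaf["timepoint"] == "pre") & (rvaf["called"])]
        if len(pre_called) and response is not None and len(response):
            matrix = (
                pre_called.assign(flag=True)
                .pivot_table(index="gene", columns="patient_id", values="flag",
                             aggfunc="any", fill_value=False)
                .astype(bool)
            )
            responder = response.set_index("patient_id")["responder"]
            try:
                association = mutation_response_association(
                    matrix, responder, min_mutated=config.min_mutated
                )
            except ValueError as exc:
                logger.warning("association scan skipped: %s", exc)

    scorecard = None
    if cohort is not None:
        scorecard = _score_against_truth(cohort, trajectories, cluster_models)
        sim_dir = out / "simulated_inputs"
        write_cohort(cohort, sim_dir, write_vcf=False)

    manifest = dict(
        package="subclonepulse",
        version=__version__,
        seed=config.seed,
        config_hash=config.config_hash(),
        n_patients=len(purity_map),
        stages=["load", "eligibility", "rvaf", "calling", "trajectories",
                "clustering", "tmb", "cna", "report"],
        outputs=sorted(
            ["rvaf.tsv", "trajectories.tsv", "clusters.tsv", "fishplot.tsv",
             "tmb.tsv", "cna_delta.tsv", "trace_summary.tsv",
             "eligibility.tsv", "manifest.json"]
            + (["scorecard.json"] if scorecard is not None else [])
        ),
    )

    for name, df in [
        ("rvaf.tsv", rvaf), ("trajectories.tsv", trajectories),
        ("clusters.tsv", clusters), ("fishplot.tsv", fishplot),
        ("tmb.tsv", tmb), ("cna_delta.tsv", cna_delta),
        ("trace_summary.tsv", trace_summary), ("eligibility.tsv", eligibility),
    ]:
        df.to_csv(out / name, sep="\t", index=False)
    if scorecard is not None:
        (out / "scorecard.json").write_text(
            json.dumps(scorecard, indent=1, sort_keys=True)
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return RunResult(out, manifest, rvaf, trajectories, clusters, fishplot, tmb,
                     cna_delta, trace_summary, eligibility, response, association,
                     scorecard, cluster_models)


def _assess_cohort_response(meas: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for pid, g in meas.groupby("patient_id", sort=True):
        g = g.set_index("timepoint")
        if "pre" not in g.index or "post_b" not in g.index:
            continue
        a, b = g.loc["pre"], g.loc["post_b"]
        res = assess_response(pid, a["largest_mm"], a["perpendicular_mm"],
                              b["largest_mm"], b["perpendicular_mm"],
                              transition="pre->post_b")
        rows.append(dict(patient_id=pid, transition=res.transition,
                         recist=res.recist, uicc_pd=res.uicc_pd,
                         responder=res.responder))
    return pd.DataFrame(rows)


def _score_against_truth(
    cohort: Cohort,
    trajectories: pd.DataFrame,
    cluster_models: dict[str, ClusterModel],
) -> dict:
    """Truth-vs-inferred scorecard for a simulated run."""
    per_patient = {}
    emerging_total = emerging_true_prior = emerging_trace_hit = 0
    for p in cohort.patients:
        clone_of = p.tree.mutation_clone()
        traj = trajectories[trajectories["patient_id"] == p.patient_id]
        emerging = traj[traj["status"] == "emerging"]
        hits = n_with_prior = 0
        for r in emerging.itertuples(index=False):
            t1 = r.transition.split("->")[0]
            mid = r.mutation_id
            if mid in clone_of and p.tree.prevalence(clone_of[mid], t1) > 0:
                n_with_prior += 1
                if r.trace_flag == "pre_existing_trace":
                    hits += 1
        emerging_total += len(emerging)
        emerging_true_prior += n_with_prior
        emerging_trace_hit += hits
        entry = dict(
            n_true_clones=len(p.tree.subclones),
            n_emerging=int(len(emerging)),
            n_emerging_with_true_prior=n_with_prior,
            n_emerging_trace_detected=hits,
        )
        if p.patient_id in cluster_models:
            entry["n_inferred_clusters"] = cluster_models[p.patient_id].n_clusters
        per_patient[p.patient_id] = entry
    return dict(
        per_patient=per_patient,
        cohort=dict(
            n_emerging=emerging_total,
            n_emerging_with_true_prior=emerging_true_prior,
            n_emerging_trace_detected=emerging_trace_hit,
            trace_recall=(
                emerging_trace_hit / emerging_true_prior
                if emerging_true_prior
                else None
            ),
        ),
    )
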