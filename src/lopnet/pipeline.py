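"""End-to-end orchestration: simulate -> classify -> connect -> graph -> infer.

The pipeline executes the five analysis steps in order on a synthetic cohort
(or user-supplied tables), producing a :class:`RunReport` with per-stage
provenance and the headline results: memory-performance contrasts, the
FDR-conjunction node sets per centrality measure, the centrality-change /
source-memory correlation, and the exhaustive subset permutation p.

Reproducibility: a single master seed is expanded into per-stage substreams
with :class:`numpy.random.SeedSequence` (children spawned in a fixed,
documented order), so rerunning any configuration reproduces every number
bit-exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, graphs, inference, io
from .connectivity import (
    build_task_regressor,
    make_deconvolver,
    ppi_matrix,
    remove_drift,
)
from .simulate import (
    ITISpec,
    MemoryEffects,
    NoiseSpec,
    RTModel,
    generate_design,
    generate_event_bank,
    generate_memory_outcomes,
    generate_node_timeseries,
    generate_responses,
    sample_ground_truth,
)

__all__ = ["PipelineConfig", "RunReport", "SimulatedCohort", "PipelineError",
           "run_pipeline", "simulate_cohort", "load_inputs"]

#: PPI condition names used throughout
ELAB_HIGH, ELAB_LOW = "elab_high", "elab_low"
CONGR_HIGH, CONGR_LOW = "congr_high", "congr_low"
REMEMBERED, FORGOTTEN = "remembered", "forgotten"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str, report: dict | None = None):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.report = report


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults mirror the study conditions.

    113 participants, 100 events, 42 nodes (4 of them planted hubs), two
    encoding runs of 131 volumes at TR 2.39 s, 2 s events with jittered
    1-7 s ITIs (mean 2.98 s), edge densities 20-30% in steps of 2, BH-FDR
    q = 0.05, and the >=10-trials / >=10%-source-memory exclusion rules.
    """

    seed: int = 0
    # cohort
    n_participants: int = 113
    n_events: int = 100
    agreement_profile: tuple = (0.25, 0.25, 0.5)
    # planted truth
    n_nodes: int = 42
    n_hubs: int = 4
    hub_nodes: tuple | None = None
    gain_mean: float = 0.65
    gain_sd: float = 0.2
    memory_slope: float = 2.0
    base_corr: float = 0.2
    spillover: float = 0.3
    n_affiliates: int = 0
    n_factors: int = 6
    factor_sd: float = 0.15
    neighbor_corr: float = 0.55
    neighbor_decay: float = 0.5
    # behavioral effects
    elab_effect: float = 1.18
    congr_effect: float = 0.58
    ability_sd: float = 0.25
    # scanning / noise
    tr: float = 2.39
    n_runs: int = 2
    volumes_per_run: int = 131
    microtime: int = 16
    ar1_rho: float = 0.3
    sigma: float = 0.3
    #: absolute ridge penalty for deconvolution; None = 0.05 * tr(H'H) / T
    ridge_lambda: float | None = 0.01
    # analysis
    densities: tuple = graphs.DEFAULT_DENSITIES
    q: float = 0.05
    measures: tuple = graphs.MEASURES
    contrasts: tuple = ("elaboration", "congruity", "memory")
    min_trials: int = 10
    min_source_frac: float = 0.10
    node_frac: float = 0.85
    participant_frac: float = 0.85
    restrict_to_remembered: bool = True
    #: subsample the larger condition of each contrast to equal trial
    #: counts before building PPI terms; unequal counts bias the Fisher-z
    #: estimates of strong pairs differently per condition, which the
    #: density threshold does not remove
    match_trial_counts: bool = True
    permutation_max: int = 2_000_000
    # output
    out_dir: str | None = None
    write_timeseries: bool = False

    def __post_init__(self) -> None:
        d = np.asarray(self.densities, dtype=float)
        if np.any(d <= 0) or np.any(d > 1) or np.any(np.diff(d) <= 0):
            raise ValueError("densities must be sorted and in (0, 1]")
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        if self.n_events % self.n_runs:
            raise ValueError("n_events must divide evenly over the runs")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("agreement_profile", "hub_nodes", "densities", "measures", "contrasts"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class SimulatedCohort:
    """Everything the generator produced for one cohort."""

    bank: object
    responses: pd.DataFrame
    outcomes: pd.DataFrame
    truth: object
    designs: dict                 # (participant_id, run) -> DesignSpec
    event_assignment: dict        # (participant_id, run) -> event ids in order
    participants: np.ndarray
    ts_seeds: dict                # (participant_id, run) -> SeedSequence
    match_seed: object = None     # SeedSequence for trial-count matching


@dataclass
class RunReport:
    """Provenance and headline results of one pipeline run."""

    config: dict
    behavior: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)
    density_check: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)     # measure -> findings
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "behavior": self.behavior,
            "exclusions": self.exclusions,
            "density_check": self.density_check,
            "results": self.results,
            "warnings": self.warnings,
        }

    def save(self, path) -> None:
        io.write_json(self.to_dict(), path)


def simulate_cohort(config: PipelineConfig) -> SimulatedCohort:
    """Stage 1: draw the full synthetic cohort from the master seed."""
    ss = np.random.SeedSequence(config.seed)
    # fixed spawn order: bank, responses, truth, outcomes, designs,
    # timeseries, trial matching
    s_bank, s_resp, s_truth, s_out, s_design, s_ts, s_match = ss.spawn(7)
    bank = generate_event_bank(
        config.n_events, config.agreement_profile, np.random.default_rng(s_bank)
    )
    responses = generate_responses(
        bank, config.n_participants, RTModel(), np.random.default_rng(s_resp)
    )
    truth = sample_ground_truth(
        n_nodes=config.n_nodes,
        n_participants=config.n_participants,
        n_hubs=config.n_hubs,
        hub_nodes=config.hub_nodes,
        gain_mean=config.gain_mean,
        gain_sd=config.gain_sd,
        memory_slope=config.memory_slope,
        base_corr=config.base_corr,
        spillover=config.spillover,
        n_affiliates=config.n_affiliates,
        n_factors=config.n_factors,
        factor_sd=config.factor_sd,
        neighbor_corr=config.neighbor_corr,
        neighbor_decay=config.neighbor_decay,
        seed=np.random.default_rng(s_truth),
    )
    effects = MemoryEffects(
        elab_effect=config.elab_effect,
        congr_effect=config.congr_effect,
        ability_sd=config.ability_sd,
    )
    outcomes = generate_memory_outcomes(
        responses, effects, truth, np.random.default_rng(s_out)
    )
    participants = np.sort(responses["participant_id"].unique())
    per_run = config.n_events // config.n_runs
    designs, assignment, ts_seeds = {}, {}, {}
    design_children = s_design.spawn(len(participants) * config.n_runs)
    ts_children = s_ts.spawn(len(participants) * config.n_runs)
    d_rng = np.random.default_rng(s_design.spawn(1)[0])
    idx = 0
    for pid in participants:
        order = d_rng.permutation(bank.event_id)
        for run in range(config.n_runs):
            designs[(pid, run)] = generate_design(
                n_events=per_run,
                tr=config.tr,
                iti_spec=ITISpec(),
                seed=np.random.default_rng(design_children[idx]),
                n_volumes=config.volumes_per_run,
            )
            assignment[(pid, run)] = order[run * per_run:(run + 1) * per_run]
            ts_seeds[(pid, run)] = ts_children[idx]
            idx += 1
    return SimulatedCohort(
        bank=bank,
        responses=responses,
        outcomes=outcomes,
        truth=truth,
        designs=designs,
        event_assignment=assignment,
        participants=participants,
        ts_seeds=ts_seeds,
        match_seed=s_match,
    )


def classify_and_score(cohort_or_tables) -> dict:
    """Stage 2: elaboration/congruity labels, memory scores, exclusions."""
    if isinstance(cohort_or_tables, SimulatedCohort):
        responses, outcomes = cohort_or_tables.responses, cohort_or_tables.outcomes
    else:
        responses, outcomes = cohort_or_tables
    ranked = behavior.rank_events(responses)
    elab = behavior.classify_elaboration(ranked)
    congr = behavior.classify_congruity(responses)
    scores = behavior.score_memory(outcomes, elab, congr)
    return {"ranked": ranked, "elaboration": elab, "congruity": congr, "scores": scores}


def _remembered_events(outcomes: pd.DataFrame) -> dict:
    """participant -> set of event ids remembered with full source memory."""
    old = outcomes[outcomes["old"]]
    hit = old[(old["q1"] == "yes") & (old["q2"] == "yes") & (old["q3"] == "correct")]
    return {pid: set(g["item_id"]) for pid, g in hit.groupby("participant_id")}


def _condition_labels(event_ids, elab_level, congr_level, remembered, restrict):
    """Per-event labels for each PPI condition family, for one run."""
    lab = {}
    rem = np.array([e in remembered for e in event_ids])
    eh = np.array([elab_level[e] == "high" for e in event_ids])
    ch = np.array([congr_level.get(e) == "high" for e in event_ids])
    base = rem if restrict else np.ones(len(event_ids), dtype=bool)
    lab[ELAB_HIGH] = eh & base
    lab[ELAB_LOW] = ~eh & base
    lab[CONGR_HIGH] = ch & base
    lab[CONGR_LOW] = ~ch & base
    lab[REMEMBERED] = rem
    lab[FORGOTTEN] = ~rem
    return lab


_CONTRAST_CONDITIONS = {
    "elaboration": (ELAB_HIGH, ELAB_LOW),
    "congruity": (CONGR_HIGH, CONGR_LOW),
    "memory": (REMEMBERED, FORGOTTEN),
}


def connect_participants(
    config: PipelineConfig,
    cohort: SimulatedCohort,
    labels: dict,
    included,
    report: RunReport | None = None,
    timeseries_dir=None,
) -> list:
    """Stage 3: node time series -> drift removal -> deconvolution -> cPPI.

    Returns one :class:`ConnectivityMatrix` per included participant and
    condition; PPI terms are concatenated across runs before correlation.
    """
    elab_level = dict(zip(labels["elaboration"]["event_id"],
                          labels["elaboration"]["level"]))
    congr = labels["congruity"]
    remembered = _remembered_events(cohort.outcomes)
    conditions = sorted(
        {c for name in config.contrasts for c in _CONTRAST_CONDITIONS[name]}
    )
    T = config.volumes_per_run
    M = make_deconvolver(T, config.tr, config.ridge_lambda)
    noise = NoiseSpec(ar1_rho=config.ar1_rho, sigma=config.sigma)
    matrices = []
    p_index = {pid: i for i, pid in enumerate(cohort.participants)}
    match_seed = cohort.match_seed or np.random.SeedSequence(0)
    match_rngs = [np.random.default_rng(s) for s in match_seed.spawn(len(included))]
    for pid, match_rng in zip(included, match_rngs):
        cmap = congr[congr["participant_id"] == pid]
        congr_level = dict(zip(cmap["event_id"], cmap["level"]))
        run_conds = []
        for run in range(config.n_runs):
            event_ids = cohort.event_assignment[(pid, run)]
            run_conds.append(
                _condition_labels(
                    event_ids, elab_level, congr_level,
                    remembered.get(pid, set()), config.restrict_to_remembered,
                )
            )
        if config.match_trial_counts:
            for name in config.contrasts:
                ca, cb = _CONTRAST_CONDITIONS[name]
                na = sum(int(rc[ca].sum()) for rc in run_conds)
                nb = sum(int(rc[cb].sum()) for rc in run_conds)
                if min(na, nb) == 0 or na == nb:
                    continue
                big = ca if na > nb else cb
                drop = abs(na - nb)
                slots = [(r, i) for r, rc in enumerate(run_conds)
                         for i in np.flatnonzero(rc[big])]
                for j in match_rng.choice(len(slots), size=drop, replace=False):
                    r, i = slots[j]
                    run_conds[r][big][i] = False
        terms = {c: [] for c in conditions}
        zero_psi = {c: True for c in conditions}
        for run in range(config.n_runs):
            design = cohort.designs[(pid, run)]
            event_ids = cohort.event_assignment[(pid, run)]
            # the planted coupling acts on successfully encoded deep events:
            # deep processing that centralizes the hubs is what produces the
            # durable memory, so the two labels coincide at the trial level
            rem_pid = remembered.get(pid, set())
            deep_run = np.array([
                "deep" if (elab_level[e] == "high" and e in rem_pid) else "other"
                for e in event_ids
            ])
            ts = generate_node_timeseries(
                design,
                cohort.truth,
                labels=deep_run,
                noise=noise,
                seed=np.random.default_rng(cohort.ts_seeds[(pid, run)]),
                participant=p_index[pid],
                deep_label="deep",
                microtime=config.microtime,
                participant_id=pid,
            )
            if timeseries_dir is not None:
                io.write_timeseries(
                    ts, Path(timeseries_dir) / f"sub-{pid:03d}_run-{run + 1}",
                    onsets=design.onsets, event_ids=event_ids,
                )
            clean = remove_drift(ts.data, config.tr)
            neural = (M @ clean.T).T
            cond_events = run_conds[run]
            for cond in conditions:
                sel = cond_events[cond]
                names = np.where(sel, cond, "other")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    reg = build_task_regressor(
                        design, cond, config.microtime, labels=names
                    )
                if sel.any():
                    zero_psi[cond] = False
                from .connectivity import compute_ppi_term

                terms[cond].append(
                    compute_ppi_term(neural, reg.psi_micro, config.tr,
                                     microtime=config.microtime)
                )
        for cond in conditions:
            if zero_psi[cond] and report is not None:
                report.warnings.append(
                    f"participant {pid}: no events in condition {cond!r}"
                )
            full = np.concatenate(terms[cond], axis=1)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                mat = ppi_matrix(full, participant_id=pid, condition=cond)
            for w in caught:
                if report is not None:
                    report.warnings.append(f"participant {pid}/{cond}: {w.message}")
            matrices.append(mat)
    return matrices


def graph_stage(config: PipelineConfig, matrices) -> tuple[pd.DataFrame, dict]:
    """Stage 4: density check at the most conservative threshold, centralities."""
    d_min = min(config.densities)
    check = graphs.validate_density(
        [graphs.threshold_binarize(m, d_min) for m in matrices],
        config.node_frac,
        config.participant_frac,
    )
    if not check["passed"]:
        raise PipelineError(
            "graph",
            f"density {d_min:.0%} fails the "
            f"{config.node_frac:.0%}/{config.participant_frac:.0%} rule "
            f"(fraction of participants ok: {check['frac_participants_ok']:.2f})",
            report=check,
        )
    table = graphs.centrality_profile(matrices, config.densities, config.measures)
    return table, check


def infer_stage(
    config: PipelineConfig,
    table: pd.DataFrame,
    scores: pd.DataFrame,
    included,
) -> dict:
    """Stage 5: conjunction inference, memory correlation, permutation null."""
    overall = scores[
        (scores["dimension"] == "all") & scores["participant_id"].isin(included)
    ].set_index("participant_id")["corrected_source_pct"]
    all_nodes = sorted(table["node"].unique())
    results = {}
    for measure in config.measures:
        res_m = {}
        for contrast in config.contrasts:
            ca, cb = _CONTRAST_CONDITIONS[contrast]
            tests = inference.paired_node_tests(table, ca, cb, measure)
            conj = inference.conjunction(tests, config.q, measure, contrast)
            res_m[contrast] = {
                "conjunction_nodes": conj.nodes,
                "increased": conj.increased,
                "decreased": conj.decreased,
                "directions": {str(k): v for k, v in conj.directions.items()},
            }
            if contrast == "elaboration" and conj.increased:
                change = inference.centrality_change(
                    table, conj.increased, REMEMBERED, FORGOTTEN, measure
                )
                corr = inference.memory_correlation(change, overall)
                perm = inference.exhaustive_permutation(
                    table,
                    all_nodes,
                    conj.increased,
                    overall,
                    condition_a=REMEMBERED,
                    condition_b=FORGOTTEN,
                    measure=measure,
                    max_subsets=config.permutation_max,
                )
                res_m["memory_link"] = {
                    "nodes": conj.increased,
                    "r": corr["r"],
                    "p": corr["p"],
                    "n": corr["n"],
                    "n_subsets": perm.n_subsets,
                    "count_ge": perm.count_ge,
                    "empirical_p": perm.empirical_p,
                    "empirical_p_smoothed": perm.empirical_p_smoothed,
                    "percent_ge": 100.0 * perm.empirical_p,
                }
                res_m["_null_distribution"] = perm.r_null
        results[measure] = res_m
    return results


def _behavior_summary(labels: dict, responses: pd.DataFrame, scores, included) -> dict:
    """RT and memory-performance summaries for the report."""
    inc_scores = scores[scores["participant_id"].isin(included)]
    elab_level = dict(zip(labels["elaboration"]["event_id"],
                          labels["elaboration"]["level"]))
    resp = responses.assign(elab=lambda d: d["event_id"].map(elab_level))
    rt = resp.groupby("elab")["rt_ms"].mean().to_dict()
    out = {"mean_rt_ms": rt, "n_included": len(included)}
    for name, pairing, measure in [
        ("source_elaboration", ("elaboration", "high", "low"), "corrected_source_pct"),
        ("source_congruity", ("congruity", "high", "low"), "corrected_source_pct"),
        ("dprime_elaboration", ("elaboration", "high", "low"), "d_prime"),
        ("dprime_congruity", ("congruity", "high", "low"), "d_prime"),
    ]:
        try:
            out[name] = behavior.compare_conditions(inc_scores, measure, pairing)
        except ValueError as err:
            out[name] = {"error": str(err)}
    return out


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all five stages on a synthetic cohort and report results."""
    report = RunReport(config=asdict(config))
    out = Path(config.out_dir) if config.out_dir else None

    try:
        cohort = simulate_cohort(config)
    except Exception as err:
        raise PipelineError("simulate", str(err)) from err
    if out:
        config.to_yaml(out / io.FILES["config"])
        io.write_table(cohort.bank.to_frame(), out / io.FILES["event_bank"])
        io.write_table(cohort.responses, out / io.FILES["responses"])
        io.write_table(cohort.outcomes, out / io.FILES["outcomes"])
        io.write_json(
            {
                "hub_nodes": cohort.truth.hub_nodes,
                "coupling_gain": cohort.truth.coupling_gain,
                "memory_slope": cohort.truth.memory_slope,
            },
            out / io.FILES["truth"],
        )
        io.write_json(
            {
                f"{pid}/{run}": {
                    "onsets": d.onsets,
                    "durations": d.durations,
                    "tr": d.tr,
                    "n_volumes": d.n_volumes,
                    "event_ids": cohort.event_assignment[(pid, run)],
                }
                for (pid, run), d in cohort.designs.items()
            },
            out / io.FILES["designs"],
        )

    try:
        labels = classify_and_score(cohort)
        included, excl_log = behavior.filter_participants(
            labels["scores"], config.min_trials, config.min_source_frac
        )
    except Exception as err:
        raise PipelineError("classify", str(err)) from err
    if len(included) < 3:
        raise PipelineError("classify", "fewer than 3 participants survive exclusion")
    report.exclusions = {
        "n_included": len(included),
        "n_excluded": len(cohort.participants) - len(included),
        "log": excl_log,
    }
    report.behavior = _behavior_summary(
        labels, cohort.responses, labels["scores"], included
    )
    if out:
        io.write_table(labels["elaboration"], out / io.FILES["elaboration"])
        io.write_table(labels["congruity"], out / io.FILES["congruity"])
        io.write_table(labels["scores"], out / io.FILES["scores"])
        io.write_json(excl_log, out / io.FILES["exclusions"])

    try:
        ts_dir = out / "timeseries" if (out and config.write_timeseries) else None
        matrices = connect_participants(config, cohort, labels, included, report, ts_dir)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError("connect", str(err)) from err
    if out:
        rows = []
        for m in matrices:
            iu, ju = np.triu_indices(m.n_nodes, k=1)
            rows.append(
                pd.DataFrame(
                    {
                        "participant": m.participant_id,
                        "condition": m.condition,
                        "i": iu,
                        "j": ju,
                        "z": m.z[iu, ju],
                    }
                )
            )
        io.write_table(pd.concat(rows, ignore_index=True), out / io.FILES["connectivity"])

    try:
        table, density_check = graph_stage(config, matrices)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError("graph", str(err)) from err
    report.density_check = {k: v for k, v in density_check.items() if k != "per_graph"}
    if out:
        io.write_table(table, out / io.FILES["centrality"])

    try:
        results = infer_stage(config, table, labels["scores"], included)
    except Exception as err:
        raise PipelineError("infer", str(err)) from err
    for measure, res in results.items():
        null = res.pop("_null_distribution", None)
        if out is not None and null is not None:
            io.write_table(
                pd.DataFrame({"r_null": null}),
                out / f"null_distribution_{measure}.tsv",
            )
    report.results = results
    if out:
        report.save(out / io.FILES["report"])
    return report


def load_inputs(responses_path, outcomes_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate and load user-supplied behavioral tables."""
    responses = io.load_table(responses_path, "responses")
    outcomes = io.load_table(outcomes_path, "outcomes")
    if outcomes["old"].dtype == object:
        outcomes["old"] = outcomes["old"].astype(str).str.lower().isin(["true", "1", "yes"])
    else:
        outcomes["old"] = outcomes["old"].astype(bool)
    return responses, outcomes
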