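"""End-to-end orchestration: simulate -> extract -> detect -> analyze -> report.

`run_pipeline` drives every stage on synthetic data (or on loaded
traces), producing an :class:`AnalysisReport` whose tables mirror the
figure-style groupings of the analysis: event probability per condition,
latency medians and jitter, population coactivation, pairwise joint
probabilities and extra synchrony, and event/non-CF sizes.  Statistical
tests (two-way ANOVA with Tukey HSD, Kolmogorov-Smirnov, two-sample t) are
thin wrappers over statsmodels / scipy routines.  Everything is
deterministic given the configuration seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import ks_2samp, ttest_ind

from . import amplitude, coding, synchrony
from .constants import EVOKED_WINDOW_MS, condition_order
from .events import (add_onset_latencies, classify_events, detect_events,
                     spontaneous_rate)
from .synthgen import (GeneratorConfig, GroundTruth, StimulusProtocol,
                       TraceSet, make_protocol, render_traces, simulate_events)
from .traces import compute_dff, normalize_to_spontaneous


@dataclass
class ExperimentResult:
    """All per-experiment intermediate products of the analysis."""

    index: int
    protocol: StimulusProtocol
    truth: GroundTruth | None
    traces: TraceSet
    events: pd.DataFrame                  # classified, with latencies
    norm_dff: dict[int, np.ndarray]       # spontaneous-peak normalized
    mean_spont: dict[int, np.ndarray]     # peak-aligned mean spontaneous event
    spont_peak: dict[int, float]
    spont_integral_mean: dict[int, float]


@dataclass
class AnalysisReport:
    """Figure-style tables, named test results, and reproducibility metadata."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    test_results: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.10g")
        if self.test_results is not None:
            self.test_results.to_csv(outdir / "test_results.csv", index=False,
                                     float_format="%.10g")
        (outdir / "run_metadata.json").write_text(
            json.dumps(self.metadata, indent=2, sort_keys=True, default=str))


def config_hash(config: GeneratorConfig) -> str:
    d = dataclasses.asdict(config)
    d["movie_shape"] = list(d["movie_shape"])
    return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()


# ---------------------------------------------------------------------------
# Per-experiment analysis
# ---------------------------------------------------------------------------

def analyze_experiment(traces: TraceSet, protocol: StimulusProtocol,
                       config: GeneratorConfig, index: int = 0,
                       truth: GroundTruth | None = None,
                       from_dff: bool = False) -> ExperimentResult:
    """Detection + classification + normalization for one recording.

    ``from_dff=False`` recomputes ΔF/F from the raw-fluorescence traces (the
    standard path); the baseline percentile filter runs on a subgrid when
    traces are rendered densely, since the baseline varies on second
    timescales.
    """
    stride = max(1, int(round(config.frame_period_ms / traces.dt_ms))) \
        if traces.dt_ms < config.frame_period_ms else 1
    all_events = []
    norm_dff: dict[int, np.ndarray] = {}
    mean_spont: dict[int, np.ndarray] = {}
    spont_peak: dict[int, float] = {}
    spont_int: dict[int, float] = {}
    for i in range(traces.n_dendrites):
        dff = traces.dff[i] if from_dff else compute_dff(
            traces.raw_f[i], traces.dt_ms, baseline_stride=stride)
        ev = detect_events(dff, traces.dt_ms,
                           rise_ms=config.kernel_rise_ms,
                           decay_half_ms=config.kernel_decay_half_ms,
                           refractory_ms=config.refractory_ms,
                           dendrite_id=i)
        ev = classify_events(ev, protocol)
        ev = add_onset_latencies(ev, dff, traces.dt_ms, protocol)
        spont_idx = ev.loc[ev["label"] != "evoked", "peak_index"].to_numpy(int)
        if len(spont_idx):
            ndff, peak, me = normalize_to_spontaneous(dff, traces.dt_ms, spont_idx)
            norm_dff[i], spont_peak[i], mean_spont[i] = ndff, peak, me
        all_events.append(ev)
    events = pd.concat(all_events, ignore_index=True) if all_events \
        else pd.DataFrame()

    # mean spontaneous integral per dendrite, on the normalized trace
    ints = amplitude.event_integrals(events[events["label"] != "evoked"],
                                     norm_dff, traces.dt_ms) \
        if len(events) else pd.DataFrame()
    for did in norm_dff:
        sub = ints[(ints["dendrite_id"] == did) & ~ints["excluded"]] \
            if len(ints) else ints
        if len(sub):
            spont_int[did] = float(sub["integral_raw"].mean())
    return ExperimentResult(index=index, protocol=protocol, truth=truth,
                            traces=traces, events=events, norm_dff=norm_dff,
                            mean_spont=mean_spont, spont_peak=spont_peak,
                            spont_integral_mean=spont_int)


def _amplitude_tables(exp: ExperimentResult, conditions: list[str],
                      rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    """Event sizes, enhancement vs non-CF linearity for one experiment."""
    dt = exp.traces.dt_ms
    excluded, excl_frac = amplitude.exclude_multi_event_trials(exp.events)
    sizes = amplitude.event_integrals(exp.events, exp.norm_dff, dt)
    keep = ~sizes.apply(lambda r: (r["dendrite_id"], r["trial_id"]) in excluded,
                        axis=1) if len(sizes) else slice(None)
    sizes = sizes[keep] if len(sizes) else sizes

    # per-dendrite paired sizes: each dendrite's own condition-mean traces,
    # jitter-matched reference and non-CF average, in units of its mean
    # spontaneous-event integral
    per_dendrite_rows = []
    for did in sorted(exp.norm_dff):
        scale = exp.spont_integral_mean.get(did)
        if not scale or scale <= 0:
            continue
        sub = exp.events[exp.events["dendrite_id"] == did]
        dff_map = {did: exp.norm_dff[did]}
        t_axis, cmeans = amplitude.condition_mean_traces(
            sub, dff_map, dt, exp.protocol, excluded=excluded)
        ncf_d = amplitude.extract_noncf(sub, dff_map, dt, exp.protocol,
                                        {did: scale}, rng)
        for cond in conditions:
            enh_int = np.nan
            if cond in cmeans:
                try:
                    ref = amplitude.build_sp_reference(
                        sub, {did: exp.mean_spont[did]}, dt, exp.protocol,
                        excluded=excluded, conditions=[cond])
                    enh = amplitude.enhancement_trace(cmeans[cond], ref)
                    enh_int = amplitude.peak_anchored_integral(
                        enh, dt, t_axis) / scale
                except (ValueError, KeyError):
                    pass
            ncf_int = np.nan
            tr = ncf_d["mean_traces"].get(cond)
            if tr is not None:
                ncf_int = amplitude.peak_anchored_integral(
                    tr, dt, ncf_d["t_axis_ms"]) / scale
            per_dendrite_rows.append({
                "dendrite_id": did, "condition": cond,
                "enhancement_integral": enh_int, "noncf_integral": ncf_int})
    per_dendrite = pd.DataFrame(per_dendrite_rows, columns=[
        "dendrite_id", "condition", "enhancement_integral", "noncf_integral"])

    # pooled non-CF pass: condition-mean rise times and per-trial integrals
    noncf = amplitude.extract_noncf(exp.events, exp.norm_dff, dt, exp.protocol,
                                    exp.spont_integral_mean, rng)
    linearity = amplitude.linearity_comparison(per_dendrite, conditions)
    linearity.insert(0, "experiment", exp.index)
    per_dendrite.insert(0, "experiment", exp.index)
    extras = {"exclusion_fraction": excl_frac,
              "noncf_rise_times_ms": noncf["rise_times_ms"],
              "noncf_missing": noncf["missing"],
              "noncf_integrals": noncf["integrals"],
              "linearity_per_dendrite": per_dendrite}
    return sizes, {"linearity": linearity, **extras}


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------

def stat_tests(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """The analysis' named tests, two-tailed throughout.

    Two-way ANOVA (condition x experiment, dendrites/trials/pairs as
    observations) with Tukey HSD post-hoc on probability, latency,
    coactivation, extra-synchrony and size tables; two-sample KS on
    early/late latency-interval counts (weakest vs strongest condition);
    two-sample t on measured vs independent joint probabilities.  Tests
    with insufficient groups are skipped with a log row.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rows = []

    def _anova(df: pd.DataFrame, value: str, measure: str) -> None:
        d = df.dropna(subset=[value])
        d = d[d["condition"] != "sp"]
        if d["condition"].nunique() < 2 or len(d) < 4:
            rows.append({"test": "anova2", "measure": measure,
                         "statistic": np.nan, "dof": "", "pvalue": np.nan,
                         "detail": "skipped: insufficient groups"})
            return
        formula = f"{value} ~ C(condition)"
        if d["experiment"].nunique() > 1:
            formula += " + C(experiment)"
        fit = smf.ols(formula, data=d).fit()
        an = sm.stats.anova_lm(fit, typ=2)
        f = float(an.loc["C(condition)", "F"])
        dof = (int(an.loc["C(condition)", "df"]), int(an.loc["Residual", "df"]))
        p = float(an.loc["C(condition)", "PR(>F)"])
        rows.append({"test": "anova2", "measure": measure, "statistic": f,
                     "dof": f"{dof[0]},{dof[1]}", "pvalue": p,
                     "detail": "factors: condition + experiment"})
        try:
            tk = pairwise_tukeyhsd(d[value].to_numpy(),
                                   d["condition"].to_numpy())
            for res in tk.summary().data[1:]:
                rows.append({"test": "tukey_hsd", "measure": measure,
                             "statistic": float(res[2]), "dof": "",
                             "pvalue": float(res[3]),
                             "detail": f"{res[0]} vs {res[1]}"})
        except Exception as exc:  # degenerate groups
            rows.append({"test": "tukey_hsd", "measure": measure,
                         "statistic": np.nan, "dof": "", "pvalue": np.nan,
                         "detail": f"skipped: {exc}"})

    if "probability" in tables:
        _anova(tables["probability"], "probability", "event_probability")
    if "latency" in tables:
        _anova(tables["latency"], "latency_median_ms", "latency_median")
        _anova(tables["latency"], "latency_mad_ms", "latency_mad")
    if "coactivation" in tables:
        _anova(tables["coactivation"], "fraction", "coactivation")
    if "extra_synchrony_pairs" in tables:
        d = tables["extra_synchrony_pairs"].copy()
        d["extra_pct"] = 100.0 * (d["measured_joint"] - d["independent_joint"])
        _anova(d, "extra_pct", "extra_synchrony")
    if "event_sizes" in tables:
        d = tables["event_sizes"]
        d = d[d["label"] == "evoked"]
        _anova(d, "integral_norm", "event_size")

    if "latency_window_counts" in tables:
        d = tables["latency_window_counts"]
        conds = [c for c in d["condition"].unique()]
        if len(conds) >= 2:
            weak, strong = conds[0], conds[-1]
            order = condition_order("duration" if weak.startswith("d")
                                    else "pressure")
            weak = next(c for c in order if c in conds)
            strong = next(c for c in reversed(order) if c in conds)
            for win, grp in d.groupby("window"):
                a = grp.loc[grp["condition"] == weak, "count"]
                b = grp.loc[grp["condition"] == strong, "count"]
                if len(a) and len(b):
                    ks = ks_2samp(a, b)
                    rows.append({"test": "ks", "measure": "latency_counts",
                                 "statistic": float(ks.statistic), "dof": "",
                                 "pvalue": float(ks.pvalue),
                                 "detail": f"{weak} vs {strong}, window {win}"})

    if "extra_synchrony_pairs" in tables:
        d = tables["extra_synchrony_pairs"]
        for cond, grp in d.groupby("condition", sort=False):
            if len(grp) >= 2:
                t = ttest_ind(grp["measured_joint"], grp["independent_joint"])
                rows.append({"test": "ttest", "measure": "joint_probability",
                             "statistic": float(t.statistic), "dof": "",
                             "pvalue": float(t.pvalue),
                             "detail": f"measured vs independent, {cond}"})

    return pd.DataFrame(rows, columns=["test", "measure", "statistic",
                                       "dof", "pvalue", "detail"])


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: GeneratorConfig, mode: str = "duration",
                 render_mode: str = "frame", outdir: str | Path | None = None,
                 n_shuffles: int = 100) -> AnalysisReport:
    """Simulate ``config.n_experiments`` recordings and run the full analysis.

    Deterministic given ``config.seed``.  Writes the report tables to
    ``outdir`` when given.
    """
    config.validate()
    root_ss = np.random.SeedSequence(config.seed)
    exp_seeds = root_ss.spawn(config.n_experiments + 1)
    analysis_rng = np.random.default_rng(exp_seeds[-1])

    experiments: list[ExperimentResult] = []
    for e in range(config.n_experiments):
        rng = np.random.default_rng(exp_seeds[e])
        protocol = make_protocol(config, mode, rng)
        truth = simulate_events(config, protocol, rng)
        traces = render_traces(truth, config, protocol, mode=render_mode, rng=rng)
        experiments.append(analyze_experiment(traces, protocol, config,
                                              index=e, truth=truth))

    return analyze_experiments(experiments, config, mode, analysis_rng,
                               outdir=outdir, n_shuffles=n_shuffles)


def analyze_experiments(experiments: list[ExperimentResult],
                        config: GeneratorConfig, mode: str,
                        rng: np.random.Generator,
                        outdir: str | Path | None = None,
                        n_shuffles: int = 100) -> AnalysisReport:
    """Aggregate per-experiment products into the report tables and tests."""
    conditions = list(condition_order(mode))
    tables: dict[str, list[pd.DataFrame]] = {}
    log: list[str] = []
    rise_rows = []

    def add(name: str, df: pd.DataFrame) -> None:
        tables.setdefault(name, []).append(df)

    for exp in experiments:
        e = exp.index
        ids = np.arange(exp.traces.n_dendrites)

        prob = coding.event_probability(exp.events, exp.protocol, ids)
        prob.insert(0, "experiment", e)
        add("probability", prob)

        if mode == "duration":
            cat_rows = []
            for did in ids:
                sub = prob[prob["dendrite_id"] == did].set_index("condition")
                sp = float(sub.loc["sp", "probability"])
                n_tr = int(sub.loc[conditions[0], "n_trials"])
                cat, responsive = coding.categorize_dendrite(
                    sub["probability"], sp, n_tr)
                cat_rows.append({"experiment": e, "dendrite_id": did,
                                 "category": cat, "responsive": responsive})
            add("categories", pd.DataFrame(cat_rows))

        lat = coding.latency_stats(exp.events)
        lat.insert(0, "experiment", e)
        add("latency", lat)
        cnt = coding.latency_window_counts(exp.events)
        cnt.insert(0, "experiment", e)
        add("latency_window_counts", cnt)

        resp = synchrony.responsive_dendrites(exp.events, exp.protocol, ids)
        try:
            coact = synchrony.coactivation_fraction(exp.events, exp.protocol,
                                                    resp)
            coact.insert(0, "experiment", e)
            add("coactivation", coact)
        except ValueError as exc:
            log.append(f"experiment {e}: {exc}")
        pairs = synchrony.pair_joint_probability(exp.events, exp.protocol,
                                                 resp if len(resp) >= 2 else ids)
        pairs.insert(0, "experiment", e)
        add("extra_synchrony_pairs", pairs)

        pos = {int(d): float(p) for d, p in zip(
            exp.truth.dendrites["dendrite_id"], exp.truth.dendrites["position_um"])} \
            if exp.truth is not None else {int(i): float(p) for i, p in
                                           zip(ids, exp.traces.positions_um)}
        if len(pos) >= 2:
            corr = synchrony.spont_distance_correlation(
                exp.events, pos, exp.traces.duration_ms, exp.traces.dt_ms,
                n_shuffles=n_shuffles, rng=rng)
            corr.insert(0, "experiment", e)
            add("spont_distance_correlation", corr)

        sizes, extras = _amplitude_tables(exp, conditions, rng)
        if len(sizes):
            sizes.insert(0, "experiment", e)
            add("event_sizes", sizes)
        add("linearity", extras["linearity"])
        add("linearity_per_dendrite", extras["linearity_per_dendrite"])
        ncf_int = extras["noncf_integrals"]
        if len(ncf_int):
            ncf_int.insert(0, "experiment", e)
            add("noncf_integrals", ncf_int)
        for cond, rt in extras["noncf_rise_times_ms"].items():
            rise_rows.append({"experiment": e, "condition": cond,
                              "rise_time_ms": rt})
        log.append(f"experiment {e}: multi-event exclusion fraction "
                   f"{extras['exclusion_fraction']:.4f}")
        for did, cond in extras["noncf_missing"]:
            log.append(f"experiment {e}: dendrite {did} has no qualifying "
                       f"non-CF trial for {cond}")

    out_tables = {k: pd.concat(v, ignore_index=True) for k, v in tables.items()}
    out_tables["noncf_rise_times"] = pd.DataFrame(
        rise_rows, columns=["experiment", "condition", "rise_time_ms"])
    out_tables["latency_summary"] = coding.summarize_latency(
        out_tables["latency"]) if "latency" in out_tables else pd.DataFrame()
    if "extra_synchrony_pairs" in out_tables:
        out_tables["extra_synchrony"] = synchrony.extra_synchrony(
            out_tables["extra_synchrony_pairs"])

    tests = stat_tests(out_tables)
    import cfcalcium

    report = AnalysisReport(
        tables=out_tables, test_results=tests,
        metadata={"config_hash": config_hash(config), "seed": config.seed,
                  "mode": mode, "n_experiments": len(experiments),
                  "package_version": cfcalcium.__version__,
                  "numpy_version": np.__version__,
                  "evoked_window_ms": list(EVOKED_WINDOW_MS),
                  "exclusion_log": log})
    if outdir is not None:
        report.write(outdir)
    return report


# ---------------------------------------------------------------------------
# Dataset serialization (for the CLI's simulate/analyze round trip)
# ---------------------------------------------------------------------------

def save_dataset(outdir: str | Path, config: GeneratorConfig,
                 protocol: StimulusProtocol, truth: GroundTruth,
                 traces: TraceSet) -> None:
    """Write a simulated dataset as plain-text files (config YAML + CSVs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    protocol.to_csv(outdir / "protocol.csv")
    truth.events.to_csv(outdir / "ground_truth_events.csv", index=False)
    truth.dendrites.to_csv(outdir / "ground_truth_dendrites.csv", index=False)
    truth.shared_state.to_csv(outdir / "ground_truth_shared_state.csv",
                              index=False)
    raw = pd.DataFrame(traces.raw_f.T,
                       columns=[f"dendrite_{i}" for i in
                                range(traces.n_dendrites)])
    raw.insert(0, "time_ms", np.arange(raw.shape[0]) * traces.dt_ms)
    raw.to_csv(outdir / "raw_fluorescence.csv", index=False,
               float_format="%.6g")


def load_dataset(indir: str | Path) -> tuple[GeneratorConfig, StimulusProtocol,
                                             GroundTruth | None, TraceSet]:
    """Read a dataset previously written by :func:`save_dataset`."""
    indir = Path(indir)
    config = GeneratorConfig.from_yaml(indir / "config.yaml")
    protocol = StimulusProtocol.from_csv(indir / "protocol.csv",
                                         iti_s=config.iti_s)
    raw = pd.read_csv(indir / "raw_fluorescence.csv")
    t = raw.pop("time_ms").to_numpy()
    dt = float(t[1] - t[0]) if len(t) > 1 else config.frame_period_ms
    raw_f = raw.to_numpy().T
    f0 = config.f0
    traces = TraceSet(dff=raw_f / f0 - 1.0, raw_f=raw_f, dt_ms=dt,
                      positions_um=np.arange(raw_f.shape[0])
                      * config.dendrite_spacing_um, f0=f0)
    truth = None
    gt_path = indir / "ground_truth_events.csv"
    if gt_path.exists():
        truth = GroundTruth(
            events=pd.read_csv(gt_path),
            dendrites=pd.read_csv(indir / "ground_truth_dendrites.csv"),
            shared_state=pd.read_csv(indir / "ground_truth_shared_state.csv"),
            duration_ms=float(len(t) * dt))
    return config, protocol, truth, traces
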