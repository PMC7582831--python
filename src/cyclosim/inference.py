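"""Panel statistics and model inversion: from ΔR/R0 panels back to PDE activities.

Three layers:

* cohort statistics — Welch two-sample tests (the package's reading of the
  two-group comparisons) and one-way ANOVA with Bonferroni-corrected pairwise
  comparisons, starred ``*`` 0.01 ≤ p ≤ 0.05, ``**`` 0.001 ≤ p < 0.01,
  ``***`` p < 0.001;
* panel assembly — per-cell basal ratio, stimulus ΔR/R0, post-stimulus level
  and saturation headroom extracted from a generated dataset directory;
* enzyme-activity inference — least-squares inversion of the steady-state
  model: compartment-local PDE activity scalars (fitted on the log scale to
  enforce positivity) are chosen so that model-predicted inhibitor ΔR/R0
  values match the observed panel, with bootstrap confidence intervals over
  cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (CyclosimError, IdentifiabilityError, InvalidInputError, MissingDataError)
from .kinetics import (CellModel, Compartment, TreatmentEffects, UNTREATED,
                       michaelis_menten_rate, synthesis_rate)
from .pharmacology import Treatment, apply_treatment
from .sensors import SensorSpec, ratio_from_concentration
from .synthetic import read_manifest
from .traces import (background_subtract_and_ratio, extract_plateau_delta,
                     normalize_to_baseline, plateau_level, read_trace,
                     saturation_headroom, BASELINE_FRAMES)

# ---------------------------------------------------------------------------
# Group statistics


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class StatResult:
    method: str
    statistic: float
    df: float
    p: float
    p_adjusted: float
    groups: tuple
    stars: str

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise InvalidInputError("p must lie in [0, 1]")


def welch_test(group_a: Sequence[float], group_b: Sequence[float],
               labels: tuple = ("a", "b"), pooled: bool = False) -> StatResult:
    """Two-sample t test, unequal-variance (Welch) by default."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidInputError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        # degenerate identical constants: no evidence of difference
        return StatResult("student_t" if pooled else "welch_t", 0.0,
                          len(a) + len(b) - 2, 1.0, 1.0, labels, "ns")
    res = stats.ttest_ind(a, b, equal_var=pooled)
    df = res.df if hasattr(res, "df") else len(a) + len(b) - 2
    p = float(res.pvalue)
    return StatResult("student_t" if pooled else "welch_t", float(res.statistic),
                      float(df), p, p, labels, significance_stars(p))


def anova_bonferroni(groups: Mapping[str, Sequence[float]],
                     pairs: Sequence[tuple] | None = None) -> list:
    """One-way ANOVA plus Bonferroni-corrected pairwise comparisons.

    Returns the omnibus result first, followed by one :class:`StatResult`
    per requested pair with ``p_adjusted = min(1, m * p)`` where ``m`` is the
    number of comparisons.
    """
    names = list(groups)
    if len(names) < 3:
        raise InvalidInputError("need >= 3 groups; use welch_test for two")
    arrays = [np.asarray(groups[n], float) for n in names]
    if any(len(a) < 2 for a in arrays):
        raise InvalidInputError("each group needs n >= 2")
    if all(np.allclose(a, arrays[0][0]) for a in arrays):
        omnibus = StatResult("one_way_anova", 0.0, len(names) - 1, 1.0, 1.0,
                             tuple(names), "ns")
    else:
        f, p = stats.f_oneway(*arrays)
        omnibus = StatResult("one_way_anova", float(f), float(len(names) - 1),
                             float(p), float(p), tuple(names), significance_stars(float(p)))
    results = [omnibus]
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    m = len(pairs)
    for a, b in pairs:
        base = welch_test(groups[a], groups[b], labels=(a, b))
        p_adj = min(1.0, m * base.p)
        results.append(replace(base, method="bonferroni_pair", p_adjusted=p_adj,
                               stars=significance_stars(p_adj)))
    return results


# ---------------------------------------------------------------------------
# Panel assembly from a dataset directory


def build_delta_panel(dataset_dir: str | Path, plateau_len: int = 6,
                      slope_tol: float = 1e-3) -> pd.DataFrame:
    """Per-cell quantification of every trace in a generated dataset.

    Columns: scenario, nucleotide, compartment, genotype, cell_id, basal_r
    (background-subtracted pre-stimulus 480/545 ratio), delta (stimulus
    ΔR/R0), post_r (basal_r scaled by the post-stimulus plateau) and
    headroom (response to the terminal saturating addition).
    """
    dataset_dir = Path(dataset_dir)
    manifest = read_manifest(dataset_dir)
    rows = []
    missing = []
    for entry in manifest["traces"]:
        path = dataset_dir / entry["file"]
        if not path.exists():
            missing.append(entry["file"])
            continue
        trace = read_trace(path)
        series = background_subtract_and_ratio(trace)
        stim_label = trace.meta.get("stim_label")
        sat_label = trace.meta.get("saturation_label")
        series = normalize_to_baseline(series, series.events[stim_label])
        basal_r = series.r0
        delta = extract_plateau_delta(series, stim_label, plateau_len, slope_tol)
        post_r = basal_r * plateau_level(series, stim_label, plateau_len, slope_tol)
        headroom = saturation_headroom(series, sat_label, plateau_len, slope_tol)
        rows.append({**{k: entry[k] for k in ("scenario", "nucleotide", "compartment",
                                              "genotype", "cell_id")},
                     "basal_r": basal_r, "delta": delta, "post_r": post_r,
                     "headroom": headroom})
    if missing:
        raise MissingDataError(f"missing trace files: {missing}")
    return pd.DataFrame(rows)


def summarize_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Group means ± SEM with n per (scenario × compartment × genotype)."""
    def sem(x):
        return float(np.std(x, ddof=1) / np.sqrt(len(x)))

    out = (panel.groupby(["scenario", "nucleotide", "compartment", "genotype"])
           .agg(mean_delta=("delta", "mean"), sem_delta=("delta", sem),
                mean_basal_r=("basal_r", "mean"), sem_basal_r=("basal_r", sem),
                n=("delta", "size"))
           .reset_index())
    if (out["n"] < 2).any():
        raise InvalidInputError("summaries need n >= 2 per group")
    return out


# ---------------------------------------------------------------------------
# Steady-state helpers for single-compartment inversion


def _local_net_rate(comp: Compartment, nucleotide: str, s: float,
                    effects: TreatmentEffects, activities: Mapping[str, float],
                    j_scale: float = 1.0) -> float:
    rate = j_scale * sum(synthesis_rate(src, effects) for src in comp.cyclases)
    for iso, act in comp.pdes:
        act = act * activities.get(iso.name, 1.0)
        rate -= michaelis_menten_rate(iso, s, act, effects.inhibition_of(iso.name),
                                      nucleotide=nucleotide)
    return rate


def _solve_local_steady_state(comp: Compartment, nucleotide: str,
                              effects: TreatmentEffects,
                              activities: Mapping[str, float],
                              j_scale: float = 1.0) -> float:
    f = lambda s: _local_net_rate(comp, nucleotide, s, effects, activities, j_scale)
    hi = 1.0
    while f(hi) > 0:
        hi *= 4.0
        if hi > 1e7:
            raise InvalidInputError("no finite local steady state")
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-14))


def predict_deltas(comp: Compartment, nucleotide: str, sensor: SensorSpec,
                   treatments: Sequence[Treatment], activities: Mapping[str, float],
                   j_scale: float = 1.0) -> np.ndarray:
    """Model-predicted ΔR/R0 per treatment for a single compartment."""
    model = CellModel(genotype="template", nucleotide=nucleotide,
                      compartments=(replace(comp, exchanges={}),))
    s0 = _solve_local_steady_state(comp, nucleotide, UNTREATED, activities, j_scale)
    r0 = ratio_from_concentration(sensor, s0)
    out = []
    for trt in treatments:
        eff = apply_treatment(model, trt)
        s1 = _solve_local_steady_state(comp, nucleotide, eff, activities, j_scale)
        out.append(ratio_from_concentration(sensor, s1) / r0 - 1.0)
    return np.asarray(out)


@dataclass(frozen=True)
class ActivityFit:
    """Result of inverting a delta panel for one compartment."""

    activities: Mapping[str, float]
    j_scale: float
    ci: Mapping[str, tuple]
    residual: float
    n_bootstrap: int


def estimate_pde_activity(panel: pd.DataFrame, template: CellModel,
                          sensor: SensorSpec, treatments: Mapping[str, Treatment],
                          compartment: str | None = None, fit_j: bool = False,
                          bootstrap: int = 1000, seed: int = 0) -> ActivityFit:
    """Recover compartment-local PDE activity scalars from an inhibitor panel.

    ``panel`` holds per-cell rows with columns ``treatment`` (keys of
    ``treatments``) and ``delta``.  The fit adjusts one activity scalar per
    PDE of the template compartment (and optionally a basal-synthesis scale)
    by least squares on 20%-trimmed treatment-mean deltas — trimming keeps
    the cohort summary close to the typical cell, which is what the
    homogeneous template describes, rather than the heterogeneity-skewed
    mean.  Confidence intervals are conservative: the hull of the bootstrap
    2.5/97.5 percentile and the normal (±1.96 SE) interval over resampled
    cells, widened by the spread between mean- and median-aggregated fits
    (a data-driven allowance for aggregation sensitivity under cell-to-cell
    heterogeneity).  Deterministic given ``seed``.
    """
    compartment = compartment or sensor.compartment
    comp = template.compartment(compartment)
    pde_names = [iso.name for iso, _ in comp.pdes]
    n_params = len(pde_names) + (1 if fit_j else 0)
    labels = list(treatments)
    if panel["treatment"].nunique() < n_params:
        raise IdentifiabilityError(
            pde_names + (["j_basal"] if fit_j else []),
            f"{panel['treatment'].nunique()} treatments cannot constrain {n_params} parameters")
    missing = set(labels) - set(panel["treatment"])
    if missing:
        raise MissingDataError(f"panel lacks treatments: {sorted(missing)}")
    trt_list = [treatments[k] for k in labels]

    def observed(frame: pd.DataFrame, agg="trimmed") -> np.ndarray:
        if agg == "trimmed":
            stat = lambda v: stats.trim_mean(v, 0.2)
        elif agg == "median":
            stat = np.median
        else:
            stat = np.mean
        series = frame.groupby("treatment")["delta"].agg(stat)
        return series.reindex(labels).to_numpy()

    def fit_once(y: np.ndarray, x0: np.ndarray) -> np.ndarray:
        def resid(x):
            acts = dict(zip(pde_names, np.exp(x[:len(pde_names)])))
            j = float(np.exp(x[-1])) if fit_j else 1.0
            try:
                pred = predict_deltas(comp, template.nucleotide, sensor, trt_list,
                                      acts, j)
            except CyclosimError:
                # no finite steady state in this parameter region: saturated
                # prediction, steering the optimizer back toward feasibility
                pred = np.full(len(trt_list), (sensor.r_max / sensor.r_min) - 1.0)
            return pred - y
        sol = optimize.least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14)
        return sol.x

    y_obs = observed(panel)
    x0 = np.zeros(n_params)
    x_hat = fit_once(y_obs, x0)
    est = np.exp(x_hat)

    # aggregation-sensitivity allowance: how far the answer moves between
    # mean- and median-summarised panels
    try:
        sens = np.abs(np.exp(fit_once(observed(panel, "mean"), x_hat))
                      - np.exp(fit_once(observed(panel, "median"), x_hat)))
    except Exception:
        sens = np.zeros(n_params)

    rng = np.random.default_rng(seed)
    samples = []
    groups = {k: g.reset_index(drop=True) for k, g in panel.groupby("treatment")}
    for _ in range(bootstrap):
        resampled = []
        for k, g in groups.items():
            idx = rng.integers(0, len(g), len(g))
            resampled.append(g.iloc[idx])
        try:
            samples.append(fit_once(observed(pd.concat(resampled)), x_hat))
        except Exception:
            continue
    samples = np.exp(np.array(samples)) if samples else np.empty((0, n_params))

    activities = dict(zip(pde_names, est[:len(pde_names)]))
    ci = {}
    for i, name in enumerate(pde_names + (["j_basal"] if fit_j else [])):
        if len(samples):
            lo_p, hi_p = np.percentile(samples[:, i], [2.5, 97.5])
            sd = float(samples[:, i].std(ddof=1))
            lo = min(lo_p, est[i] - 1.96 * sd) - sens[i]
            hi = max(hi_p, est[i] + 1.96 * sd) + sens[i]
        else:
            lo = hi = float("nan")
        ci[name] = (float(lo), float(hi))
    resid = predict_deltas(comp, template.nucleotide, sensor, trt_list, activities,
                           float(np.exp(x_hat[-1])) if fit_j else 1.0) - y_obs
    return ActivityFit(activities=activities,
                       j_scale=float(np.exp(x_hat[-1])) if fit_j else 1.0,
                       ci=ci, residual=float(np.sqrt(np.mean(resid ** 2))),
                       n_bootstrap=len(samples))


# ---------------------------------------------------------------------------
# Genotype comparison report


def _groups(panel: pd.DataFrame, scenario_ids, column: str):
    if isinstance(scenario_ids, str):
        scenario_ids = [scenario_ids]
    sub = panel[panel["scenario"].isin(scenario_ids)]
    ctrl = sub.loc[sub["genotype"] == "control", column].to_numpy()
    mdx = sub.loc[sub["genotype"] == "mdx", column].to_numpy()
    return ctrl, mdx


def _check(panel, scenario_ids, column, direction, alpha=0.05, description="",
           equal_margin=0.10):
    """One ordering check.

    ``lower`` / ``higher`` demand a Welch-significant difference in that
    direction.  ``equal`` accepts either a non-significant test or an
    observed difference below ``equal_margin`` of the response scale (the
    mean elevation above the sensor floor for ratio columns, the mean
    response for ΔR/R0 columns) — a pure p >= α rule would fail its own
    type-I rate even when the groups are identical by construction.
    """
    ctrl, mdx = _groups(panel, scenario_ids, column)
    res = welch_test(mdx, ctrl, labels=("mdx", "control"))
    diff = float(np.mean(mdx) - np.mean(ctrl))
    if column in ("basal_r", "post_r"):
        scale = float(np.mean(np.concatenate([ctrl, mdx]))) - 1.0  # above r_min
    else:
        scale = abs(float(np.mean(np.concatenate([ctrl, mdx]))))
    if direction == "lower":
        holds = diff < 0 and res.p < alpha
    elif direction == "higher":
        holds = diff > 0 and res.p < alpha
    elif direction == "equal":
        holds = res.p >= alpha or abs(diff) <= equal_margin * scale
    else:
        raise InvalidInputError(f"unknown direction {direction!r}")
    return {"description": description, "direction": direction, "holds": bool(holds),
            "p": res.p, "mean_control": float(np.mean(ctrl)),
            "mean_mdx": float(np.mean(mdx)), "n_control": len(ctrl), "n_mdx": len(mdx)}


def _basal_scenarios(panel, nucleotide, compartment):
    sub = panel[(panel["nucleotide"] == nucleotide) & (panel["compartment"] == compartment)]
    return sorted(sub["scenario"].unique())


def genotype_ordering_report(panel: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Which control-vs-mdx orderings hold in a quantified cohort panel.

    Basal-ratio comparisons pool every scenario of a compartment (the
    pre-stimulus baseline is treatment-independent); response comparisons use
    the matching stimulus or inhibitor scenario.
    """
    checks = {}
    comp_tag = {"CYT": "cyt", "PM": "pm", "OMM": "omm"}

    def add(key, *args, **kwargs):
        # a cohort lacking the scenarios of a check simply skips it
        try:
            checks[key] = _check(*args, **kwargs)
        except InvalidInputError:
            pass

    # cGMP basal levels: lower in mdx in cytosol and PM, unchanged at the OMM
    for comp, direction in (("CYT", "lower"), ("PM", "lower"), ("OMM", "equal")):
        add(f"cgmp_basal_{comp_tag[comp]}",
            panel, _basal_scenarios(panel, "cGMP", comp), "basal_r", direction, alpha,
            f"basal cGMP at {comp}: mdx vs control ({direction})")
    # PM cGMP-PDE inhibitor panel: larger deltas in mdx (PDE5-selective probe)
    add("cgmp_pm_pde5_delta",
        panel, "cgmp_pm_sildenafil", "delta", "higher", alpha,
        "sildenafil ΔR/R0 at the PM: larger in mdx")
    inhibitor_pm = panel[(panel["nucleotide"] == "cGMP") & (panel["compartment"] == "PM")
                         & ~panel["scenario"].str.contains("snapbay41|cinaciguat")]
    if len(inhibitor_pm):
        sums = {g: float(inhibitor_pm.loc[inhibitor_pm["genotype"] == g, "delta"].mean())
                for g in ("control", "mdx")}
        checks["cgmp_pm_total_pde_delta"] = {
            "description": "summed PM cGMP-PDE inhibitor ΔR/R0: larger in mdx",
            "direction": "higher", "holds": bool(sums["mdx"] > sums["control"]),
            "p": float("nan"), "mean_control": sums["control"], "mean_mdx": sums["mdx"],
            "n_control": 0, "n_mdx": 0}
    # NO-independent stimulation equalises cytosolic cGMP but not PM cGMP
    add("cgmp_stim_cyt_level",
        panel, "cgmp_cyt_snapbay41", "post_r", "equal", alpha,
        "post SNAP+Bay41 cGMP level in the cytosol: no genotype difference")
    add("cgmp_stim_pm_level",
        panel, "cgmp_pm_snapbay41", "post_r", "lower", alpha,
        "post SNAP+Bay41 cGMP level at the PM: still lower in mdx")
    add("cgmp_pm_cinaciguat",
        panel, "cgmp_pm_cinaciguat", "delta", "higher", alpha,
        "cinaciguat ΔR/R0 at the PM: larger in mdx (oxidised sGC pool)")
    # cAMP side
    add("camp_basal_cyt",
        panel, _basal_scenarios(panel, "cAMP", "CYT"), "basal_r", "higher", alpha,
        "basal cAMP in the cytosol: higher in mdx")
    add("camp_cyt_pde4_delta",
        panel, "camp_cyt_rolipram", "delta", "lower", alpha,
        "rolipram ΔR/R0 in the cytosol: smaller in mdx (less PDE4)")
    add("camp_iso_cyt",
        panel, "camp_cyt_iso", "delta", "lower", alpha,
        "isoprenaline ΔR/R0 in the cytosol: smaller in mdx")
    add("camp_fsk_cyt",
        panel, "camp_cyt_forskolin", "delta", "lower", alpha,
        "forskolin ΔR/R0 in the cytosol: smaller in mdx")
    add("camp_basal_pm",
        panel, _basal_scenarios(panel, "cAMP", "PM"), "basal_r", "equal", alpha,
        "basal cAMP at the PM: no genotype difference")
    add("camp_iso_pm",
        panel, "camp_pm_iso", "delta", "equal", alpha,
        "isoprenaline ΔR/R0 at the PM: no genotype difference")
    add("camp_basal_omm",
        panel, _basal_scenarios(panel, "cAMP", "OMM"), "basal_r", "lower", alpha,
        "basal cAMP at the OMM: lower in mdx")

    n_hold = sum(1 for c in checks.values() if c["holds"])
    return {"alpha": alpha, "n_checks": len(checks), "n_holding": n_hold,
            "all_hold": n_hold == len(checks), "checks": checks}


def run_genotype_comparison(dataset_dir: str | Path, out_dir: str | Path | None = None,
                            alpha: float = 0.05) -> dict:
    """Quantify a cohort, compare genotypes and emit the ordering report."""
    panel = build_delta_panel(dataset_dir)
    report = genotype_ordering_report(panel, alpha=alpha)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        panel.to_csv(out_dir / "panel.csv", index=False)
        summarize_panel(panel).to_csv(out_dir / "summary.csv", index=False)
        (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
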