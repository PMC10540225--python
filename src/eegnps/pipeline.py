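"""End-to-end orchestration: simulate (or ingest), spectra, IRT scoring,
stable sparse classification, longitudinal models and missingness
sensitivity, under one master seed, with per-stage artifacts and a plain-text
report whose sections mirror the analysis tables (item loadings, univariate
mixed model with sensitivity columns, cognition associations, classifier
AUCs, multivariate model comparison).

The master seed deterministically spawns per-stage substreams, so disabling
one stage does not perturb another's randomness and two runs with the same
seed produce byte-identical numeric artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import SimulationConfig, generate_cohort, generate_ratings, \
    apply_missingness, iter_eeg, WAVES
from .spectra import average_reference, log_power_spectra, NormativeSpectraModel, FREQ_GRID
from .irt import fit_gpcm, collapse_categories, responses_to_matrix, average_evaluators
from .stability import stability_select, crossval_auc, OneFactorScores
from .longitudinal import (fit_lme_univariate, fit_mlme, compare_models,
                           association_regression, demographics_tests)
from .isni import compute_isni
from .io import write_json

logger = logging.getLogger("eegnps")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "assemble_report"]

ALL_STAGES = ("simulate", "spectra", "irt", "longitudinal", "sensitivity",
              "classify", "mlme")

COLLAPSE_MAP = {
    "Sharp waves": {0: 0, 1: 1, 2: 1},
    "Paroxysmal activity": {0: 0, 1: 1, 2: 1, 3: 1},
}
DROP_ITEM = "Background frequency"
CSV_FLOAT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage. Partial artifacts remain."""

    def __init__(self, stage, message):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


@dataclass
class PipelineConfig:
    """All pipeline parameters; round-trips through YAML unchanged."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    data_dir: str | None = None          # ingest cohort/gte/moca CSVs instead of simulating
    stages: tuple = ALL_STAGES
    ssc_n_reps: int = 1000
    ssc_n_cv: int = 1000
    ssc_train_frac: float = 0.7
    ssc_screen_threshold: float = 2.0
    ssc_retain_threshold: float = 0.5
    ssc_l1_ratio: float = 0.5
    irt_n_quadrature: int = 61
    seed: int = 0

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["simulation"]["gte_items"] = {
            k: {"a": v["a"], "b": list(v["b"]), "waves": list(v.get("waves", WAVES))}
            for k, v in self.simulation.gte_items.items()}
        d["simulation"]["moca_items"] = {
            k: {"a": v["a"], "b": list(v["b"])}
            for k, v in self.simulation.moca_items.items()}
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        sim = d.pop("simulation", {})
        cfg = cls(simulation=SimulationConfig(**sim), **d)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _stage_seeds(master_seed):
    ss = np.random.SeedSequence(int(master_seed))
    names = ("simulate", "ssc", "final")
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(names, ss.spawn(len(names)))}


def _feature_name(channel, freq):
    return f"{channel}@{freq:g}"


def _write_csv(df, path, index=False):
    df.to_csv(path, index=index, float_format=CSV_FLOAT)


def run_pipeline(config, outdir):
    """Execute the enabled stages in dependency order; return artifact map.

    On a stage failure the partial report and manifest are still written and
    a :class:`PipelineError` naming the stage is raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    stages = set(config.stages)
    results = {}
    timings = {}
    error = None

    def run_stage(name, fn):
        t0 = time.perf_counter()
        logger.info("stage %s: start (seed=%s)", name, seeds.get(name, "-"))
        out = fn()
        timings[name] = time.perf_counter() - t0
        logger.info("stage %s: done in %.2fs", name, timings[name])
        return out

    plan = [
        ("simulate", lambda: _stage_simulate(config, seeds, outdir, results)),
        ("spectra", lambda: _stage_spectra(config, outdir, results)),
        ("irt", lambda: _stage_irt(config, outdir, results)),
        ("longitudinal", lambda: _stage_longitudinal(config, outdir, results)),
        ("sensitivity", lambda: _stage_sensitivity(config, outdir, results)),
        ("classify", lambda: _stage_classify(config, seeds, outdir, results)),
        ("mlme", lambda: _stage_mlme(config, outdir, results)),
    ]
    try:
        for name, fn in plan:
            if name in stages:
                try:
                    run_stage(name, fn)
                except PipelineError:
                    raise
                except Exception as exc:
                    raise PipelineError(name, str(exc)) from exc
    except PipelineError as exc:
        error = exc
    report_path = outdir / "report.txt"
    report_path.write_text(_render_report(results))
    manifest = {
        "package_version": __version__,
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "config": config.to_dict(),
        "timings_s": timings,
        "status": "failed" if error else "ok",
        "error": str(error) if error else None,
    }
    write_json(manifest, outdir / "manifest.json")
    if error is not None:
        raise error
    return {"outdir": outdir, "results": results, "report": report_path}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config, seeds, outdir, results):
    if config.data_dir is not None:
        ddir = Path(config.data_dir)
        cohort = pd.read_csv(ddir / "cohort.csv")
        gte = pd.read_csv(ddir / "gte_responses.csv")
        moca = pd.read_csv(ddir / "moca.csv")
        results["ingested"] = True
    else:
        sim_cfg = config.simulation.replace(seed=seeds["simulate"])
        results["sim_cfg"] = sim_cfg
        cohort = generate_cohort(sim_cfg)
        cohort = apply_missingness(cohort, config=sim_cfg)
        gte, moca = generate_ratings(cohort, sim_cfg)
        absent = set(cohort.loc[~cohort["present_adulthood"], "subject_id"])
        gte = gte[~((gte["wave"] == "adulthood") & gte["subject_id"].isin(absent))]
        moca = moca[~moca["subject_id"].isin(absent)]
    results["cohort"] = cohort
    results["gte"] = gte.reset_index(drop=True)
    results["moca"] = moca.reset_index(drop=True)
    _write_csv(cohort, outdir / "cohort.csv")
    _write_csv(results["gte"], outdir / "gte_responses.csv")
    _write_csv(results["moca"], outdir / "moca.csv")
    results["demographics"] = demographics_tests(cohort)
    _write_csv(results["demographics"], outdir / "demographics.csv")


def _present_records(cohort):
    for row in cohort.itertuples(index=False):
        for wave in WAVES:
            if getattr(row, f"present_{wave}"):
                yield row.subject_id, wave


def _stage_spectra(config, outdir, results):
    if "sim_cfg" not in results:
        raise PipelineError("spectra", "spectral stage requires simulated EEG "
                            "(ingested epoch tables are processed via eegnps.io)")
    cohort = results["cohort"]
    sim_cfg = results["sim_cfg"]
    present = {(row.subject_id, w) for row in cohort.itertuples(index=False)
               for w in WAVES if getattr(row, f"present_{w}")}
    records = []
    for eeg in iter_eeg(cohort, sim_cfg):
        if (eeg.subject_id, eeg.wave) not in present:
            continue
        spec = log_power_spectra(average_reference(eeg))
        records.append(spec)
    ages = {(r.subject_id, w): getattr(r, f"age_{w}")
            for r in cohort.itertuples(index=False) for w in WAVES}
    groups = dict(zip(cohort["subject_id"], cohort["group"]))
    ref_idx = [i for i, s in enumerate(records) if groups[s.subject_id] == "CON"]
    X = np.stack([s.values for s in records])
    ref_ages = np.array([ages[(records[i].subject_id, records[i].wave)] for i in ref_idx])
    norms = NormativeSpectraModel().fit(X[ref_idx], ref_ages)
    z_rows = {}
    gsf = {}
    zframes = []
    for i, s in enumerate(records):
        zs = norms.zscore(s, ages[(s.subject_id, s.wave)])
        z_rows[(s.subject_id, s.wave)] = zs.z.ravel()
        gsf[f"{s.subject_id}/{s.wave}"] = zs.gsf
        zframes.append(zs)
    feat_names = [_feature_name(ch, f) for ch in records[0].channel_labels
                  for f in FREQ_GRID]
    zfeat = pd.DataFrame.from_dict(z_rows, orient="index", dtype=float)
    zfeat.columns = feat_names
    zfeat.index = pd.MultiIndex.from_tuples(zfeat.index, names=["subject_id", "wave"])
    results["zfeatures"] = zfeat
    results["norms"] = norms
    long = zfeat.stack().rename("z").reset_index()
    long.columns = ["subject_id", "wave", "feature", "z"]
    _write_csv(long, outdir / "zspectra.csv")
    write_json(gsf, outdir / "gsf.json")


def _stage_irt(config, outdir, results):
    gte = results["gte"]
    common = [i for i in gte["item"].unique() if i != "Reactivity"]
    wide5 = responses_to_matrix(gte[gte["item"].isin(common)], items=sorted(common))
    initial = fit_gpcm(wide5, n_quadrature=config.irt_n_quadrature, compute_se=False)

    reduced_long = collapse_categories(
        gte[gte["item"].isin(common) & (gte["item"] != DROP_ITEM)], COLLAPSE_MAP)
    items4 = sorted(set(common) - {DROP_ITEM})
    wide4 = responses_to_matrix(reduced_long, items=items4)
    optimized = fit_gpcm(wide4, n_quadrature=config.irt_n_quadrature, compute_se=False)

    scores = pd.DataFrame(index=wide4.index)
    scores["sqnps"] = optimized.transform(wide4)
    scores = scores.reset_index()
    avg = average_evaluators(scores)

    moca = results["moca"].set_index("subject_id").drop(columns=["total"])
    moca_model = fit_gpcm(moca, n_quadrature=config.irt_n_quadrature, compute_se=False)
    mf = pd.DataFrame({"subject_id": moca.index,
                       "mf": moca_model.transform(moca)})

    results["irt_initial"] = initial
    results["irt_optimized"] = optimized
    results["moca_model"] = moca_model
    results["sqnps"] = scores
    results["sqnps_avg"] = avg
    results["mf"] = mf
    write_json(initial.to_dict(), outdir / "irt_initial.json")
    write_json(optimized.to_dict(), outdir / "irt_optimized.json")
    write_json(moca_model.to_dict(), outdir / "moca_model.json")
    loadings_df = pd.DataFrame({"item": optimized.item_names_,
                                "loading": optimized.loadings_})
    results["loadings"] = loadings_df
    _write_csv(loadings_df, outdir / "loadings.csv")
    _write_csv(scores, outdir / "sqnps.csv")
    _write_csv(avg, outdir / "sqnps_avg.csv")
    _write_csv(mf, outdir / "mf.csv")


def _lme_frame(results, include_missing=False):
    """Evaluator-level long frame for the univariate mixed model."""
    cohort = results["cohort"]
    scores = results["sqnps"]
    meta = cohort.set_index("subject_id")
    rows = scores.copy()
    rows["age"] = [meta.loc[s, f"age_{w}"] for s, w in zip(rows["subject_id"], rows["wave"])]
    for col in ("group", "sex", "ecology"):
        rows[col] = rows["subject_id"].map(meta[col])
    if include_missing:
        evaluators = sorted(scores["evaluator"].unique())
        missing = []
        for r in cohort[~cohort["present_adulthood"]].itertuples(index=False):
            for ev in evaluators:
                missing.append({
                    "subject_id": r.subject_id, "wave": "adulthood",
                    "evaluator": ev, "sqnps": np.nan, "age": r.age_adulthood,
                    "group": r.group, "sex": r.sex, "ecology": r.ecology})
        if missing:
            rows = pd.concat([rows, pd.DataFrame(missing)], ignore_index=True)
    return rows


def _stage_longitudinal(config, outdir, results):
    data = _lme_frame(results)
    fit_subj = fit_lme_univariate(data, random_spec="subject")
    fit_both = fit_lme_univariate(data, random_spec="subject+evaluator")
    cmp_eval = compare_models(fit_subj, fit_both)
    results["lme_subject"] = fit_subj
    results["lme_subject_evaluator"] = fit_both
    results["lme_evaluator_anova"] = cmp_eval
    write_json({
        "fixed_effects": fit_subj.fe_table.reset_index().to_dict("records"),
        "variance_components": fit_subj.vc,
        "loglik": fit_subj.loglik, "aic": fit_subj.aic, "bic": fit_subj.bic,
        "n_obs": fit_subj.n_obs, "n_subjects": fit_subj.n_subjects,
        "evaluator_anova": dataclasses.asdict(cmp_eval),
    }, outdir / "lme_univariate.json")

    # associations of the cognition factor with each wave's averaged score
    cohort = results["cohort"].set_index("subject_id")
    avg = results["sqnps_avg"]
    mf = results["mf"].set_index("subject_id")["mf"]
    assoc = {}
    for wave in WAVES:
        sub = avg[avg["wave"] == wave].copy()
        sub["mf"] = sub["subject_id"].map(mf)
        sub["age"] = sub["subject_id"].map(cohort[f"age_{wave}"])
        for c in ("sex", "ecology"):
            sub[c] = sub["subject_id"].map(cohort[c])
        assoc[wave] = association_regression(sub, outcome="mf", predictor="sqnps")
    results["associations"] = assoc
    write_json({w: t.reset_index().to_dict("records") for w, t in assoc.items()},
               outdir / "associations.json")


def _stage_sensitivity(config, outdir, results):
    if "lme_subject" not in results:
        raise PipelineError("sensitivity", "univariate mixed fit unavailable "
                            "(longitudinal stage disabled)")
    data = _lme_frame(results, include_missing=True)
    res = compute_isni(results["lme_subject"], data)
    results["isni"] = res
    write_json({
        "table": res.table.reset_index().to_dict("records"),
        "sigma": res.sigma, "n_dropped": res.n_dropped,
        "missing_model": res.missing_model,
    }, outdir / "isni.json")


def _stage_classify(config, seeds, outdir, results):
    if "zfeatures" not in results:
        raise PipelineError("classify", "z-spectra unavailable (spectra stage disabled)")
    cohort = results["cohort"].set_index("subject_id")
    zfeat = results["zfeatures"]
    sq = results["sqnps"].pivot_table(index=["subject_id", "wave"],
                                      columns="evaluator", values="sqnps")
    sq.columns = [f"sqnps_ev{c}" for c in sq.columns]
    ss = np.random.SeedSequence(seeds["ssc"])
    model_seeds = iter(int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(12))
    summary = {}
    samples = []
    stable_z = {}
    for wave in WAVES:
        zw = zfeat.xs(wave, level="wave")
        sw = sq.xs(wave, level="wave")
        shared = zw.index.intersection(sw.index)
        tables = {"z": zw.loc[shared], "sqnps": sw.loc[shared],
                  "both": pd.concat([sw.loc[shared], zw.loc[shared]], axis=1)}
        y = cohort.loc[shared, "group"].to_numpy()
        for model, Xf in tables.items():
            sel = stability_select(
                Xf, y, n_reps=config.ssc_n_reps, train_frac=config.ssc_train_frac,
                screen_threshold=config.ssc_screen_threshold,
                retain_threshold=config.ssc_retain_threshold,
                l1_ratio=config.ssc_l1_ratio, seed=next(model_seeds))
            ev = crossval_auc(
                Xf, y, features=sel.stable_set, n_cv=config.ssc_n_cv,
                train_frac=config.ssc_train_frac, l1_ratio=config.ssc_l1_ratio,
                seed=next(model_seeds))
            key = f"{wave}/{model}"
            summary[key] = {
                "auc_mean": ev.auc_mean, "auc_std": ev.auc_std,
                "n_stable": len(sel.stable_set),
                "stable_features": sel.stable_set,
            }
            samples.append(pd.DataFrame({
                "wave": wave, "model": model,
                "rep": np.arange(len(ev.auc_samples)), "auc": ev.auc_samples}))
            if model == "z":
                stable_z[wave] = sel.stable_set
    results["ssc"] = summary
    results["stable_z"] = stable_z
    write_json(summary, outdir / "ssc_results.json")
    _write_csv(pd.concat(samples, ignore_index=True), outdir / "auc_samples.csv")

    # qNPS: one-factor reduction of the stable spectral features (both waves)
    union = sorted(set().union(*stable_z.values()))
    if len(union) < 2:
        raise PipelineError("classify", "fewer than 2 stable spectral features; "
                            "cannot extract the qNPS factor")
    avg = results["sqnps_avg"].set_index(["subject_id", "wave"])["sqnps"]
    ref = avg.reindex(zfeat.index)
    factor = OneFactorScores().fit(zfeat[union],
                                   ref.fillna(ref.mean()) if ref.notna().any() else None)
    qnps = pd.Series(factor.transform(zfeat[union]), index=zfeat.index, name="qnps")
    results["qnps"] = qnps.reset_index()
    _write_csv(results["qnps"], outdir / "qnps.csv")


def _stage_mlme(config, outdir, results):
    if "qnps" not in results:
        raise PipelineError("mlme", "qNPS unavailable (classifier stage disabled "
                            "or did not run)")
    cohort = results["cohort"].set_index("subject_id")
    qn = results["qnps"].set_index(["subject_id", "wave"])["qnps"]
    sq = results["sqnps_avg"].set_index(["subject_id", "wave"])["sqnps"]
    idx = qn.index.union(sq.index)
    rows = []
    for sid, wave in idx:
        for modality, series in (("qnps", qn), ("sqnps", sq)):
            rows.append({
                "subject_id": sid, "wave": wave, "modality": modality,
                "y": series.get((sid, wave), np.nan),
                "group": cohort.loc[sid, "group"],
                "age": cohort.loc[sid, f"age_{wave}"],
                "sex": cohort.loc[sid, "sex"],
                "ecology": cohort.loc[sid, "ecology"]})
    long = pd.DataFrame(rows)
    fits = {c: fit_mlme(long, constraint=c)
            for c in ("qnps_only", "sqnps_only", "both")}
    comps = {
        "qnps_vs_both": compare_models(fits["qnps_only"], fits["both"]),
        "sqnps_vs_both": compare_models(fits["sqnps_only"], fits["both"]),
    }
    results["mlme"] = fits
    results["mlme_comparisons"] = comps
    write_json({
        "logliks": {c: f.loglik for c, f in fits.items()},
        "n_free_params": {c: f.n_free_params for c, f in fits.items()},
        "comparisons": {k: dataclasses.asdict(v) for k, v in comps.items()},
        "subject_corr_both": fits["both"].subject_corr,
        "resid_sd_both": fits["both"].resid_sd,
    }, outdir / "mlme_comparison.json")


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def _render_report(results):
    lines = ["eegnps analysis report", "=" * 60, ""]

    if "demographics" in results:
        lines += ["== Demographics (two-group tests) ==",
                  results["demographics"].to_string(index=False,
                                                    float_format="%.3f"), ""]
    if "loadings" in results:
        lines += ["== IRT item loadings (optimized model) =="]
        lines += [results["loadings"].to_string(index=False, float_format="%.3f")]
        init, opt = results.get("irt_initial"), results.get("irt_optimized")
        if init is not None and opt is not None:
            lines += [f"initial model:   AIC {init.aic_:.2f}  BIC {init.bic_:.2f}",
                      f"optimized model: AIC {opt.aic_:.2f}  BIC {opt.bic_:.2f}"]
        lines += [""]
    if "lme_subject" in results:
        fit = results["lme_subject"]
        tab = fit.fe_table.copy()
        if "isni" in results:
            tab = tab.join(results["isni"].table[["isni", "c"]])
        lines += ["== Univariate mixed model (ML) ==",
                  tab.to_string(float_format="%.3f"),
                  f"loglik {fit.loglik:.2f}  AIC {fit.aic:.2f}  BIC {fit.bic:.2f}",
                  f"variance components: {{{', '.join(f'{k}: {v:.3f}' for k, v in fit.vc.items())}}}"]
        cmp_eval = results.get("lme_evaluator_anova")
        if cmp_eval is not None:
            lines += [f"evaluator random effect ANOVA: L ratio {cmp_eval.l_ratio:.3f}, "
                      f"df {cmp_eval.df}, p {cmp_eval.p:.3f}"]
        lines += [""]
    if "associations" in results:
        lines += ["== Association with the cognition factor (standardized betas) =="]
        for wave, tab in results["associations"].items():
            lines += [f"-- predictor: averaged EEG score, {wave} --",
                      tab.to_string(float_format="%.3f")]
        lines += [""]
    if "ssc" in results:
        lines += ["== Classifier AUC (mean ± SD over cross-validations) =="]
        for key, d in results["ssc"].items():
            lines += [f"{key:24s} AUC {d['auc_mean']:.3f} ± {d['auc_std']:.3f} "
                      f"({d['n_stable']} stable features)"]
        lines += [""]
    if "mlme" in results:
        lines += ["== Multivariate model comparison (likelihood-ratio ANOVA) =="]
        for c, f in results["mlme"].items():
            lines += [f"{f.label:20s} loglik {f.loglik:.2f}"]
        for name, cmp in results["mlme_comparisons"].items():
            lines += [f"{name}: L ratio {cmp.l_ratio:.3f}, df {cmp.df}, p {cmp.p:.4g}"]
        lines += [""]
    return "\n".join(lines)


def assemble_report(outdir):
    """Rebuild the report from artifacts already on disk."""
    outdir = Path(outdir)
    results = {}
    if (outdir / "demographics.csv").exists():
        results["demographics"] = pd.read_csv(outdir / "demographics.csv")
    if (outdir / "loadings.csv").exists():
        results["loadings"] = pd.read_csv(outdir / "loadings.csv")
    if (outdir / "lme_univariate.json").exists():
        d = json.loads((outdir / "lme_univariate.json").read_text())
        fe = pd.DataFrame(d["fixed_effects"]).set_index("term")

        class _F:  # minimal shim with the attributes the renderer uses
            fe_table = fe
            vc = d["variance_components"]
            loglik = d["loglik"]
            aic = d["aic"]
            bic = d["bic"]
        results["lme_subject"] = _F()
    if (outdir / "ssc_results.json").exists():
        results["ssc"] = json.loads((outdir / "ssc_results.json").read_text())
    path = outdir / "report.txt"
    path.write_text(_render_report(results))
    return path
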