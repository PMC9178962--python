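"""End-to-end orchestration: simulate → ms → trajectories → deviations →
compare → brainage → pls.

Every stage draws its randomness from a named child seed of the run seed, so
a config run twice produces bit-identical result bundles (no timestamps are
written).  Outputs carry the config hash, parcellation hash, seed and
convention flags.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate as sim
from .brainage import BrainAgeRegressor, compare_gaps, compute_gaps
from .deviations import (AgeCategory, compute_deviations, summarize_deviations,
                         test_deviations)
from .io import RunConfig, save_config, write_with_meta
from .network import cohort_mean_map, cohort_regional_ms
from .parcellation import Parcellation
from .pls import (PLSBrainCognition, group_score_comparison,
                  loading_map_correlation, permutation_significance,
                  score_outcome_correlations)
from .stats import case_control_map, hub_relationship, pal_model
from .trajectories import NormativeTrajectoryModel, compare_degrees

STAGES = ("simulate", "ms", "trajectories", "deviations", "compare",
          "brainage", "pls")

_DEPS = {"ms": ("simulate",), "trajectories": ("simulate",),
         "deviations": ("trajectories",), "compare": ("simulate",),
         "brainage": ("trajectories", "simulate"), "pls": ("simulate",)}


def _stage_seeds(seed: int) -> dict:
    """Named, order-independent child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES) + 3)
    names = list(STAGES) + ["trajectory_truth", "pal", "extra"]
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(names, children)}


def run_pipeline(config: RunConfig, out_dir=None, stages=None) -> dict:
    """Execute the configured stages; returns the artifact dictionary.

    Raises before execution if a requested stage's dependency is absent.
    """
    stages = list(stages or STAGES)
    for st in stages:
        for dep in _DEPS.get(st, ()):
            if dep not in stages:
                raise ValueError(f"stage {st!r} requires {dep!r} to run first")
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    seeds = _stage_seeds(config.seed)
    parcellation = Parcellation.of_size(config.n_regions)
    meta = config.meta(parcellation)
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")
    partition = tuple(AgeCategory(lo, hi) for lo, hi in config.age_partition)
    art: dict = {"parcellation": parcellation, "seeds": seeds}

    if "simulate" in stages:
        truth = sim.default_trajectories(
            parcellation, seed=seeds["trajectory_truth"],
            n_noise=config.n_noise_regions, noise_sd=config.ms_noise_sd,
            early=config.early, late=config.late)
        art["truth"] = truth
        norm_demo = sim.sample_cohort(sim.CohortSpec(
            config.n_normative, config.normative_age_range,
            group="normative", seed=seeds["simulate"]), id_prefix="nrm")
        ctrl_demo = sim.sample_cohort(sim.CohortSpec(
            config.n_controls, config.casecontrol_age_range,
            group="control", seed=seeds["simulate"] + 1), id_prefix="ctl")
        pat_demo = sim.sample_cohort(sim.CohortSpec(
            config.n_patients, config.casecontrol_age_range,
            group="patient", seed=seeds["simulate"] + 2), id_prefix="pat")
        cc_demo = pd.concat([ctrl_demo, pat_demo], ignore_index=True)
        injection = sim.AgedInjectionSpec(
            config.injection_delta_years,
            sim.decreasing_regions(truth, config.early, config.late))
        art["injection"] = injection
        if config.feature_level:
            art["features_normative"] = sim.generate_feature_table(
                norm_demo, truth, None, seed=seeds["simulate"] + 3)
            art["features_casecontrol"] = sim.generate_feature_table(
                cc_demo, truth, injection, seed=seeds["simulate"] + 4)
        else:
            art["ms_normative"] = sim.generate_regional_ms(
                norm_demo, truth, None, seed=seeds["simulate"] + 3)
            art["ms_casecontrol"] = sim.generate_regional_ms(
                cc_demo, truth, injection, seed=seeds["simulate"] + 4)
        pal = sim.generate_pal(cc_demo, sim.PALSpec(), seed=seeds["pal"])
        art.update(demo_normative=norm_demo, demo_casecontrol=cc_demo,
                   pal=pal)
        norm_demo.to_csv(out / "demographics_normative.csv", index=False)
        cc_demo.to_csv(out / "demographics_casecontrol.csv", index=False)
        pal.to_csv(out / "pal.csv", index=False)

    if "ms" in stages:
        if config.feature_level:
            art["ms_normative"] = cohort_regional_ms(art["features_normative"])
            art["ms_casecontrol"] = cohort_regional_ms(
                art["features_casecontrol"])
        write_with_meta(art["ms_normative"].reset_index(),
                        out / "regional_ms_normative.csv", meta)
        write_with_meta(art["ms_casecontrol"].reset_index(),
                        out / "regional_ms_casecontrol.csv", meta)

    if "trajectories" in stages:
        model = NormativeTrajectoryModel(
            degree=config.degree, early=config.early, late=config.late)
        ages = art["demo_normative"]["age"].to_numpy(float)
        model.fit(ages, art["ms_normative"])
        art["model"] = model
        write_with_meta(model.to_frame(), out / "normative_model.csv", meta)
        report = compare_degrees(ages,
                                 art["ms_normative"].to_numpy(float))
        report = {"selected_degree": report["selected_degree"],
                  "shares": {k: v["share_significant"]
                             for k, v in report["tests"].items()},
                  "category_counts": model.category_counts(),
                  "n_excluded": int((~model.retained_).sum())}
        (out / "trajectory_report.json").write_text(
            json.dumps({**meta, **report}, indent=2, sort_keys=True))

    if "deviations" in stages:
        demo = art["demo_casecontrol"]
        patients = demo[demo["group"] == "patient"]
        records = compute_deviations(
            art["ms_casecontrol"].loc[patients["subject_id"]], patients,
            art["model"], partition=partition)
        tests = test_deviations(records, art["model"], fdr_q=config.fdr_q,
                                n_perm=config.n_perm_deviations,
                                fdr_method=config.fdr_method,
                                seed=seeds["deviations"],
                                partition=partition)
        summary = summarize_deviations(tests)
        art.update(deviation_records=records, deviation_tests=tests,
                   deviation_summary=summary)
        write_with_meta(records, out / "deviation_records.csv", meta)
        write_with_meta(tests, out / "deviation_tests.csv", meta)
        (out / "deviation_summary.json").write_text(
            json.dumps({**meta, **summary}, indent=2, sort_keys=True))

    if "compare" in stages:
        demo = art["demo_casecontrol"].set_index("subject_id")
        cc = case_control_map(art["ms_casecontrol"], demo["group"],
                              fdr_q=config.fdr_q,
                              n_perm=config.n_perm_groups,
                              fdr_method=config.fdr_method,
                              seed=seeds["compare"])
        t_map = cc.set_index("region")["t"]
        ctrl_ms = art["ms_casecontrol"].loc[
            demo.index[demo["group"] == "control"]]
        hub = hub_relationship(t_map, cohort_mean_map(ctrl_ms),
                               n_perm=config.n_perm_groups,
                               seed=seeds["compare"] + 1)
        pal_fit = pal_model(art["pal"], art["demo_casecontrol"],
                            partition=partition)
        art.update(case_control=cc, hub=hub, pal_fit=pal_fit)
        write_with_meta(cc, out / "case_control.csv", meta)
        (out / "group_report.json").write_text(json.dumps(
            {**meta, "hub_relationship": hub, "pal_model": pal_fit},
            indent=2, sort_keys=True, default=float))

    if "brainage" in stages:
        model = BrainAgeRegressor(cv_folds=config.cv_folds,
                                  random_state=seeds["brainage"])
        model.fit(art["ms_normative"],
                  art["demo_normative"]["age"].to_numpy(float))
        demo = art["demo_casecontrol"].set_index("subject_id")
        gaps = compute_gaps(model, art["ms_casecontrol"],
                            demo.loc[art["ms_casecontrol"].index, "age"],
                            convention=config.gap_convention)
        comparison = compare_gaps(gaps, demo["group"])
        art.update(brainage_model=model, gaps=gaps,
                   gap_comparison=comparison)
        (out / "brainage_model.json").write_text(
            json.dumps({**meta, **model.to_dict()}, indent=2,
                       sort_keys=True))
        write_with_meta(gaps, out / "brainage_gaps.csv", meta)
        (out / "brainage_compare.json").write_text(
            json.dumps({**meta, **comparison}, indent=2, sort_keys=True,
                       default=float))

    if "pls" in stages:
        demo = art["demo_casecontrol"].set_index("subject_id")
        pal = art["pal"].set_index("subject_id")
        subjects = art["ms_casecontrol"].index
        X = art["ms_casecontrol"]
        Y = pd.DataFrame({"age": demo.loc[subjects, "age"],
                          "pal_total_errors":
                              pal.loc[subjects, "pal_total_errors"]})
        pls = PLSBrainCognition(n_components=config.pls_components).fit(X, Y)
        p_perm = permutation_significance(pls, X, Y,
                                          n_perm=config.n_perm_pls,
                                          seed=seeds["pls"])
        corr = score_outcome_correlations(pls, Y)
        group_cmp = group_score_comparison(
            pls, demo.loc[subjects, "group"].to_numpy(),
            n_perm=config.n_perm_pls, seed=seeds["pls"] + 1)
        report = {"pct_var_y": pls.pct_var_y_.tolist(),
                  "cum_pct_var_y": pls.cum_pct_var_y_.tolist(),
                  "perm_p": p_perm.tolist(),
                  "score_outcome_correlations": corr.to_dict("records"),
                  "group_comparison": group_cmp.to_dict("records")}
        if "case_control" in art:
            lmc = loading_map_correlation(
                pls, art["case_control"].set_index("region")["t"],
                n_perm=config.n_perm_pls, seed=seeds["pls"] + 2)
            report["loading_map_correlation"] = lmc.to_dict("records")
        art.update(pls=pls, pls_report=report)
        write_with_meta(pls.loadings_frame(), out / "pls_loadings.csv", meta)
        scores = pd.DataFrame(pls.x_scores_, index=subjects,
                              columns=[f"component_{k+1}"
                                       for k in range(pls.n_components)])
        write_with_meta(scores.reset_index(), out / "pls_scores.csv", meta)
        (out / "pls_report.json").write_text(
            json.dumps({**meta, **report}, indent=2, sort_keys=True,
                       default=float))

    manifest = {"config_hash": config.hash, "seed": config.seed,
                "stages": stages,
                "files": sorted(p.name for p in out.iterdir()
                                if p.is_file())}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    art["out_dir"] = out
    return art
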