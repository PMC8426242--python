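"""End-to-end driver: phantom -> quantification -> detector evaluation ->
survival analysis, in one reproducible run.

Every stochastic stage (phantom rendering, simulated detector, bootstrap
resampling, cohort generation) takes its own explicit seed, so a run
configuration reproduces all outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detection import Focus, quantify_foci, suv_peak, percist_measurable, region_stats
from .evaluation import (METRICS, bootstrap_ci, label_accuracy, match_foci,
                         missed_lesion_comparison)
from .io import write_lesion_table, write_report, write_survival_table
from .phantom import (CohortConfig, DetectorProfile, PhantomConfig,
                      generate_cohort, simulate_detector)
from .survival import (compare_cpe_bootstrap, cox_fit, km_estimate,
                       logrank_test, mtv_agreement, optimal_logrank_cutoff,
                       quartile_groups, stepwise_cox)

REQUIRED_SEEDS = ("phantom", "detector", "bootstrap", "cohort")


class RunConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """One reproducible end-to-end run."""

    seeds: dict[str, int]
    n_patients_imaging: int = 10
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    detector: DetectorProfile = field(default_factory=DetectorProfile)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    bootstrap_replicates: int = 1000
    connectivity: int = 26
    min_volume_ml: float = 0.5
    ai_recovery_logit_mean: float = 0.3    # per-patient AI/manual MTV recovery
    ai_recovery_logit_sd: float = 0.9
    output_dir: str = "petmtv-run"

    def __post_init__(self) -> None:
        missing = [s for s in REQUIRED_SEEDS if s not in self.seeds]
        if missing:
            raise RunConfigError(f"missing explicit seed(s) for stage(s): {missing}")
        for k, v in self.seeds.items():
            if not isinstance(v, (int, np.integer)):
                raise RunConfigError(f"seed for stage {k!r} must be an integer")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seeds" not in raw:
            raise RunConfigError("run config must declare a 'seeds' mapping")
        kwargs = dict(raw)
        if "phantom" in kwargs and isinstance(kwargs["phantom"], dict):
            p = dict(kwargs["phantom"])
            for key in ("grid_shape", "spacing"):
                if key in p:
                    p[key] = tuple(p[key])
            kwargs["phantom"] = PhantomConfig(**p)
        if "detector" in kwargs and isinstance(kwargs["detector"], dict):
            kwargs["detector"] = DetectorProfile(**kwargs["detector"])
        if "cohort" in kwargs and isinstance(kwargs["cohort"], dict):
            kwargs["cohort"] = CohortConfig(**kwargs["cohort"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def build_reference_read(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Render phantoms and quantify them into one reference lesion table.

    Detected foci are paired with ground-truth lesions by voxel overlap
    and inherit the truth classification and anatomical labels.  Truth
    lesions missed by thresholding (below the minimum volume after
    segmentation) are appended as manually-added foci with their
    constructed volume, mirroring a reader who adds lesions the
    threshold preselection missed.
    """
    tables = []
    recovery = []
    for i in range(config.n_patients_imaging):
        pcfg = replace(config.phantom, seed=config.seeds["phantom"] + i)
        result = _generate(pcfg)
        pid = f"IM{i:03d}"
        volume = result.volume
        foci, report = quantify_foci(volume, result.masks["blood_pool"],
                                     result.masks["liver"],
                                     config.min_volume_ml, config.connectivity)
        # pair detected foci with truth lesions by voxel overlap
        focus_sets = [set(map(tuple, f.voxels)) for f in foci]
        claimed: set[int] = set()
        rows = []
        liver_stats = region_stats(volume, result.masks["liver"], "liver")
        for les in result.lesions:
            lset = set(map(tuple, les.voxels))
            best, best_j = 0, None
            for j, fset in enumerate(focus_sets):
                if j in claimed:
                    continue
                ov = len(lset & fset)
                if ov > best:
                    best, best_j = ov, j
            if best_j is not None:
                f = foci[best_j]
                claimed.add(best_j)
                mtv, suvpeak, measurable = f.mtv_ml, f.suvpeak, f.measurable
                recovery.append({"patient_id": pid, "lesion_id": les.lesion_id,
                                 "true_ml": les.volume_ml, "mtv_ml": mtv})
            else:
                # manually added: quantified from its constructed voxels
                pseudo = Focus(focus_id=les.lesion_id, voxels=les.voxels,
                               suvmax=les.suvmax)
                suvpeak = suv_peak(volume, pseudo)
                measurable = percist_measurable(suvpeak, liver_stats)
                mtv = les.volume_ml
            rows.append({
                "patient_id": pid, "focus_id": les.lesion_id,
                "classification": les.classification,
                "measurable": bool(measurable), "mtv_ml": float(mtv),
                "suvmax": les.suvmax, "suvpeak": float(suvpeak),
                "body_part": les.body_part, "region": les.region,
                "subregion": les.subregion if les.subregion else pd.NA,
            })
        tables.append(pd.DataFrame(rows))
    reference = pd.concat(tables, ignore_index=True)
    rec = pd.DataFrame(recovery)
    stage_report = {
        "n_patients": config.n_patients_imaging,
        "n_foci": int(len(reference)),
        "n_suspicious": int((reference["classification"] == "suspicious").sum()),
        "n_measurable": int(reference["measurable"].sum()),
        "mtv_recovery": {
            "n_lesions": int(len(rec)),
            "max_abs_error_ml": float((rec["mtv_ml"] - rec["true_ml"]).abs().max())
            if len(rec) else None,
            "mean_abs_error_ml": float((rec["mtv_ml"] - rec["true_ml"]).abs().mean())
            if len(rec) else None,
        },
    }
    return reference, stage_report


def _generate(pcfg: PhantomConfig):
    from .phantom import generate_phantom
    return generate_phantom(pcfg)


def evaluate_detector(reference: pd.DataFrame, config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate the candidate read and compute all accuracy metrics."""
    profile = replace(config.detector, seed=config.seeds["detector"])
    candidate = simulate_detector(reference, profile)
    matches = match_foci(reference, candidate)
    report: dict = {"n_foci": int(len(matches))}
    B = config.bootstrap_replicates
    for measurable_only, key in ((False, "all_foci"), (True, "measurable_only")):
        block = {}
        for scope in ("per-focus", "per-patient-mean"):
            for m in METRICS:
                try:
                    res = bootstrap_ci(matches, m, scope=scope,
                                       measurable_only=measurable_only,
                                       n_replicates=B,
                                       seed=config.seeds["bootstrap"])
                    block[f"{m}_{scope}"] = res.as_dict()
                except Exception as exc:  # undefined metric on this stratum
                    block[f"{m}_{scope}"] = {"error": str(exc)}
        report[key] = block
    labels = {}
    for level in ("body_part", "region", "subregion", "most_detailed"):
        res = label_accuracy(matches, level, n_replicates=B,
                             seed=config.seeds["bootstrap"])
        labels[level] = res.as_dict()
    report["label_accuracy"] = labels
    report["missed_vs_detected"] = missed_lesion_comparison(matches, reference)
    return candidate, report


def survival_analysis(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Cohort generation plus the full survival layer."""
    ccfg = replace(config.cohort, seed=config.seeds["cohort"])
    _, surv = generate_cohort(ccfg)
    report: dict = {"n_patients": int(len(surv)),
                    "event_fraction": surv.attrs.get("event_fraction")}

    # univariate whole-body model + concordance
    fit_wb = cox_fit(surv, ["log2_mtv_whole_body"])
    report["cox_whole_body"] = fit_wb.summary().to_dict(orient="records")
    from .survival import gonen_heller_cpe
    report["cpe_whole_body"] = gonen_heller_cpe(
        fit_wb.linear_predictor(surv)).value

    # organ-wise stepwise selection
    organ_covs = [c for c in surv.columns
                  if c.startswith("log2_mtv_") and c != "log2_mtv_whole_body"]
    step = stepwise_cox(surv, organ_covs)
    report["stepwise"] = {
        "selected": step.selected,
        "model": step.fit.summary().to_dict(orient="records") if step.fit else [],
        "n_trace_steps": len(step.trace),
    }

    # concordance comparison: whole-body vs best single organ covariate
    rival = step.selected[0] if step.selected else organ_covs[0]
    comp = compare_cpe_bootstrap(surv, ["log2_mtv_whole_body"], [rival],
                                 n_replicates=config.bootstrap_replicates,
                                 seed=config.seeds["bootstrap"])
    report["cpe_comparison"] = {
        "model_a": "log2_mtv_whole_body", "model_b": rival,
        "cpe_a": comp.cpe_a, "cpe_b": comp.cpe_b, "delta": comp.delta,
        "z": comp.z, "p_value": comp.p_value,
        "n_replicates": comp.n_replicates, "n_dropped": comp.n_dropped,
    }

    # Kaplan–Meier by whole-body MTV quartiles
    labels, collapsed = quartile_groups(surv["mtv_whole_body"].to_numpy())
    curves = km_estimate(surv, labels)
    chi2, df, p = logrank_test(surv, labels)
    report["km_quartiles"] = {
        "collapsed": collapsed,
        "logrank_chi2": chi2, "df": df, "p_value": p,
        "medians": {g: c.median for g, c in sorted(curves.items())},
    }

    # optimised log-rank cutoff on whole-body MTV
    cut = optimal_logrank_cutoff(surv["mtv_whole_body"].to_numpy(), surv)
    report["optimal_cutoff_whole_body"] = {
        "cutoff_ml": cut.cutoff, "chi2": cut.chi2, "p_naive": cut.p_naive,
        "n_low": cut.n_low, "n_high": cut.n_high,
    }
    low = surv["mtv_whole_body"].to_numpy() <= cut.cutoff
    cut_curves = km_estimate(surv, np.where(low, "low", "high"))
    report["optimal_cutoff_medians"] = {g: c.median for g, c in cut_curves.items()}

    # manual-vs-AI whole-body MTV agreement (simulated partial recovery)
    rng = np.random.default_rng(config.seeds["detector"] + 1)
    from scipy.special import expit
    frac = expit(rng.normal(config.ai_recovery_logit_mean,
                            config.ai_recovery_logit_sd, len(surv)))
    manual = surv["mtv_whole_body"].to_numpy()
    ai = manual * frac
    report["mtv_agreement_manual_vs_ai"] = mtv_agreement(ai, manual)
    return surv, report


def run_all(config: RunConfig, write_outputs: bool = True) -> dict:
    """Execute phantom -> detection -> evaluation -> survival.

    Returns the combined run report; with ``write_outputs`` the lesion
    tables, survival table, per-stage JSON reports and a manifest are
    written under ``config.output_dir``.  Stage errors propagate with
    the stage name attached.
    """
    out = Path(config.output_dir)
    report: dict = {"config_hash": config.config_hash(), "version": __version__}
    stage = "phantom+quantification"
    try:
        reference, stage1 = build_reference_read(config)
        report[stage] = stage1
        stage = "detector-evaluation"
        candidate, stage2 = evaluate_detector(reference, config)
        report[stage] = stage2
        stage = "survival"
        surv, stage3 = survival_analysis(config)
        report[stage] = stage3
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
        write_lesion_table(reference, out / "lesions_reference.csv")
        write_lesion_table(candidate, out / "lesions_candidate.csv")
        write_survival_table(surv, out / "survival.csv")
        write_report(report, out / "report.json")
        manifest = {"config_hash": config.config_hash(),
                    "version": __version__,
                    "outputs": ["lesions_reference.csv", "lesions_candidate.csv",
                                "survival.csv", "report.json"]}
        write_report(manifest, out / "manifest.json")
    return report
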