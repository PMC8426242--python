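"""Candidate-vs-reference read comparison.

A candidate read (e.g. a simulated automated detector) is compared to
the reference read focus by focus.  Per-focus status follows the
reference classification: TP when both reads call a focus suspicious,
TN when both call it unsuspicious, FN when the reference is suspicious
but the candidate is not (or missed the focus entirely), FP when the
candidate calls a reference-unsuspicious focus suspicious or invents
one.

Metrics are reported per focus (pooled) or per patient (metric within
each patient, then averaged over patients with a defined value).
Confidence intervals are percentile bootstrap over patients — patients
are resampled with replacement and carry all their foci with them,
because foci of one patient are not independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

METRICS = ("sensitivity", "specificity", "accuracy", "ppv", "npv")
LABEL_LEVELS = ("body_part", "region", "subregion", "most_detailed")


class UndefinedMetricError(ValueError):
    """The requested metric has an empty denominator everywhere."""


@dataclass
class MetricWithCI:
    """Point estimate with a percentile-bootstrap 95% interval."""

    name: str
    scope: str                    # "per-focus" | "per-patient-mean"
    estimate: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    n_replicates: int = 0
    n_undefined_replicates: int = 0

    def as_dict(self) -> dict:
        return {
            "name": self.name, "scope": self.scope, "estimate": self.estimate,
            "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
            "n_replicates": self.n_replicates,
            "n_undefined_replicates": self.n_undefined_replicates,
        }


def _status(ref_susp: np.ndarray, cand_susp: np.ndarray) -> np.ndarray:
    out = np.empty(ref_susp.shape, dtype=object)
    out[ref_susp & cand_susp] = "TP"
    out[ref_susp & ~cand_susp] = "FN"
    out[~ref_susp & cand_susp] = "FP"
    out[~ref_susp & ~cand_susp] = "TN"
    return out


def match_foci(reference: pd.DataFrame, candidate: pd.DataFrame) -> pd.DataFrame:
    """Pair reference and candidate foci by (patient_id, focus_id).

    Reference foci absent from the candidate read count as missed
    (suspicious ones become FN, unsuspicious ones TN); candidate foci
    absent from the reference become FP when suspicious.  Label
    agreement is recorded at every level; the subregion column is NA
    where the reference provides no subregion, and ``most_detailed``
    compares at the finest reference-provided level.
    """
    keys = ["patient_id", "focus_id"]
    for df, side in ((reference, "reference"), (candidate, "candidate")):
        if df.duplicated(subset=keys).any():
            raise ValueError(f"duplicate (patient, focus) keys in {side} read")
    merged = reference.merge(candidate, on=keys, how="outer",
                             suffixes=("_ref", "_cand"), indicator=True)
    in_ref = merged["_merge"] != "right_only"
    present = merged["_merge"] == "both"

    ref_susp = (merged["classification_ref"] == "suspicious").to_numpy()
    cand_susp = (present & (merged["classification_cand"] == "suspicious")
                 ).to_numpy()
    out = pd.DataFrame({
        "patient_id": merged["patient_id"],
        "ref_focus_id": merged["focus_id"].where(in_ref, pd.NA),
        "cand_focus_id": merged["focus_id"].where(present | ~in_ref, pd.NA),
        "ref_classification": merged["classification_ref"].where(in_ref, pd.NA),
        "cand_classification": merged.get("classification_cand",
                                          pd.Series(pd.NA)).where(
            present | ~in_ref, pd.NA),
        "status": _status(ref_susp, cand_susp),
        "measurable": (merged["measurable_ref"].fillna(True).astype(bool)
                       if "measurable_ref" in merged else True),
    })
    # candidate-only foci: suspicious ones are FP, others carry no signal
    extra = ~in_ref.to_numpy()
    if extra.any():
        out.loc[extra, "status"] = "FP"
        keep = ~extra | (merged["classification_cand"] == "suspicious").to_numpy()
        out = out[keep]
        merged = merged[keep]
        present = present[keep]
        in_ref = in_ref[keep]

    has_labels = {"body_part_ref", "region_ref", "body_part_cand",
                  "region_cand"} <= set(merged.columns)
    if has_labels:
        both = (present & in_ref).to_numpy()
        bp = pd.array(merged["body_part_ref"] == merged["body_part_cand"],
                      dtype="boolean")
        rg = pd.array(merged["region_ref"] == merged["region_cand"],
                      dtype="boolean")
        has_sub = merged["subregion_ref"].notna().to_numpy() \
            if "subregion_ref" in merged else np.zeros(len(merged), bool)
        sub = pd.array(merged.get("subregion_ref") == merged.get("subregion_cand"),
                       dtype="boolean")
        out["label_match_body_part"] = bp.to_numpy(object)
        out["label_match_region"] = rg.to_numpy(object)
        out["label_match_subregion"] = np.where(has_sub, sub.to_numpy(object),
                                                pd.NA)
        out["label_match_most_detailed"] = np.where(
            has_sub, sub.to_numpy(object), rg.to_numpy(object))
        for col in ("label_match_body_part", "label_match_region",
                    "label_match_subregion", "label_match_most_detailed"):
            out.loc[~both, col] = pd.NA
    return out.reset_index(drop=True)


def match_foci_by_overlap(reference_foci: dict, candidate_foci: dict) -> list[tuple]:
    """Pair mask-bearing foci of one patient by maximal voxel overlap.

    ``reference_foci`` / ``candidate_foci`` map focus id to a Focus with
    a ``voxels`` array.  Each candidate is assigned to the reference
    focus sharing the most voxels; equal-overlap ties are broken toward
    the reference focus with the higher SUVmax.  Returns
    ``(ref_id or None, cand_id or None)`` pairs covering all foci.
    """
    ref_sets = {k: {tuple(v) for v in f.voxels} for k, f in reference_foci.items()}
    pairs: list[tuple] = []
    matched_ref: set = set()
    for cid, cf in candidate_foci.items():
        cset = {tuple(v) for v in cf.voxels}
        best, best_key = None, None
        for rid, rset in ref_sets.items():
            if rid in matched_ref:
                continue
            ov = len(cset & rset)
            if ov == 0:
                continue
            key = (ov, reference_foci[rid].suvmax)
            if best is None or key > best:
                best, best_key = key, rid
        if best_key is None:
            pairs.append((None, cid))
        else:
            matched_ref.add(best_key)
            pairs.append((best_key, cid))
    for rid in reference_foci:
        if rid not in matched_ref:
            pairs.append((rid, None))
    return pairs


def _counts_per_patient(matches: pd.DataFrame,
                        measurable_only: bool) -> pd.DataFrame:
    df = matches
    if measurable_only:
        df = df[df["measurable"].astype(bool)]
    if df.empty:
        raise UndefinedMetricError("no foci left after measurability filter")
    tab = (df.groupby("patient_id")["status"]
             .value_counts().unstack(fill_value=0)
             .reindex(columns=["TP", "FP", "FN", "TN"], fill_value=0))
    return tab


def _metric_from_counts(tp, fp, fn, tn, name: str):
    """Vectorised metric from count arrays; NaN where undefined."""
    tp, fp, fn, tn = (np.asarray(a, dtype=float) for a in (tp, fp, fn, tn))
    with np.errstate(invalid="ignore", divide="ignore"):
        if name == "sensitivity":
            return np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        if name == "specificity":
            return np.where(tn + fp > 0, tn / (tn + fp), np.nan)
        if name == "accuracy":
            total = tp + fp + fn + tn
            return np.where(total > 0, (tp + tn) / total, np.nan)
        if name == "ppv":
            return np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        if name == "npv":
            return np.where(tn + fn > 0, tn / (tn + fn), np.nan)
    raise ValueError(f"unknown metric {name!r}")


def _point_estimate(counts: pd.DataFrame, name: str, scope: str) -> float:
    if scope == "per-focus":
        sums = counts.sum(axis=0)
        est = _metric_from_counts(sums["TP"], sums["FP"], sums["FN"], sums["TN"], name)
        est = float(est)
        if np.isnan(est):
            raise UndefinedMetricError(f"{name} undefined: empty denominator")
        return est
    if scope == "per-patient-mean":
        vals = _metric_from_counts(counts["TP"], counts["FP"], counts["FN"],
                                   counts["TN"], name)
        if np.all(np.isnan(vals)):
            raise UndefinedMetricError(f"{name} undefined for every patient")
        return float(np.nanmean(vals))
    raise ValueError("scope must be 'per-focus' or 'per-patient-mean'")


def classification_metrics(matches: pd.DataFrame, scope: str = "per-focus",
                           measurable_only: bool = False,
                           metrics: tuple[str, ...] = METRICS) -> list[MetricWithCI]:
    """Point estimates of sensitivity/specificity/accuracy/PPV/NPV.

    Raises UndefinedMetricError when a requested metric has an empty
    denominator (e.g. specificity on a table without unsuspicious foci).
    """
    counts = _counts_per_patient(matches, measurable_only)
    return [MetricWithCI(name=m, scope=scope,
                         estimate=_point_estimate(counts, m, scope))
            for m in metrics]


def bootstrap_ci(matches: pd.DataFrame, metric: str, scope: str = "per-focus",
                 measurable_only: bool = False, n_replicates: int = 1000,
                 level: float = 0.95, seed: int = 0) -> MetricWithCI:
    """Percentile bootstrap CI with patient-level resampling.

    Patients are drawn with replacement; each drawn patient contributes
    all its foci.  Replicates where the metric is undefined are dropped
    and counted.
    """
    counts = _counts_per_patient(matches, measurable_only)
    n_pat = counts.shape[0]
    if n_pat < 2:
        raise ValueError("bootstrap requires at least 2 patients")
    estimate = _point_estimate(counts, metric, scope)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_pat, size=(n_replicates, n_pat))
    arr = counts.to_numpy(dtype=float)          # (P, 4) TP FP FN TN
    picked = arr[idx]                            # (B, P, 4)
    if scope == "per-focus":
        sums = picked.sum(axis=1)                # (B, 4)
        reps = _metric_from_counts(sums[:, 0], sums[:, 1], sums[:, 2],
                                   sums[:, 3], metric)
    else:
        per_pat = _metric_from_counts(picked[..., 0], picked[..., 1],
                                      picked[..., 2], picked[..., 3], metric)
        with np.errstate(invalid="ignore"):
            reps = np.nanmean(per_pat, axis=1)
    defined = reps[~np.isnan(reps)]
    n_undef = int(n_replicates - defined.size)
    if defined.size == 0:
        raise UndefinedMetricError(f"{metric} undefined in every bootstrap replicate")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(defined, [alpha, 1.0 - alpha])
    return MetricWithCI(name=metric, scope=scope, estimate=estimate,
                        ci_lower=float(lo), ci_upper=float(hi),
                        n_replicates=int(defined.size),
                        n_undefined_replicates=n_undef)


def label_accuracy(matches: pd.DataFrame, level: str, scope: str = "per-focus",
                   n_replicates: int = 0, seed: int = 0) -> MetricWithCI:
    """Fraction of matched foci whose candidate label agrees at ``level``.

    Subregion accuracy is computed only over foci whose reference read
    provides a subregion; ``most_detailed`` compares each focus at its
    finest reference-provided level.  Optionally adds a patient-level
    percentile bootstrap CI (``n_replicates > 0``).
    """
    if level not in LABEL_LEVELS:
        raise ValueError(f"level must be one of {LABEL_LEVELS}")
    col = f"label_match_{level}"
    if col not in matches.columns:
        raise UndefinedMetricError("match table carries no label agreement")
    df = matches[matches[col].notna()]
    if df.empty:
        raise UndefinedMetricError(f"no focus carries a {level} label")
    hits = df[col].astype(bool).to_numpy()
    patients = df["patient_id"].to_numpy()

    if scope == "per-focus":
        estimate = float(hits.mean())
    elif scope == "per-patient-mean":
        estimate = float(pd.Series(hits).groupby(patients).mean().mean())
    else:
        raise ValueError("scope must be 'per-focus' or 'per-patient-mean'")

    result = MetricWithCI(name=f"label_accuracy_{level}", scope=scope,
                          estimate=estimate)
    if n_replicates > 0:
        per_pat = pd.DataFrame({"hit": hits.astype(float), "pid": patients})
        agg = per_pat.groupby("pid")["hit"].agg(["sum", "count"]).to_numpy()
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, agg.shape[0], size=(n_replicates, agg.shape[0]))
        picked = agg[idx]                        # (B, P, 2)
        if scope == "per-focus":
            reps = picked[..., 0].sum(axis=1) / picked[..., 1].sum(axis=1)
        else:
            reps = np.mean(picked[..., 0] / picked[..., 1], axis=1)
        lo, hi = np.quantile(reps, [0.025, 0.975])
        result.ci_lower, result.ci_upper = float(lo), float(hi)
        result.n_replicates = n_replicates
    return result


def missed_lesion_comparison(matches: pd.DataFrame,
                             reference: pd.DataFrame) -> dict:
    """Compare MTV and SUVmax of missed (FN) vs detected (TP) suspicious foci.

    Two-sided Mann-Whitney U per quantity (exact for small samples,
    normal approximation with tie correction otherwise, via scipy).
    """
    ref = reference.set_index(["patient_id", "focus_id"])
    keyed = matches[matches["ref_focus_id"].notna()].copy()
    keys = list(zip(keyed["patient_id"], keyed["ref_focus_id"]))
    report: dict = {}
    for quantity in ("mtv_ml", "suvmax"):
        values = ref.loc[keys, quantity].to_numpy(dtype=float)
        fn = values[(keyed["status"] == "FN").to_numpy()]
        tp = values[(keyed["status"] == "TP").to_numpy()]
        entry: dict = {
            "n_missed": int(fn.size), "n_detected": int(tp.size),
            "missed_mean": float(fn.mean()) if fn.size else None,
            "detected_mean": float(tp.mean()) if tp.size else None,
            "missed_median": float(np.median(fn)) if fn.size else None,
            "detected_median": float(np.median(tp)) if tp.size else None,
        }
        if fn.size and tp.size:
            method = "exact" if (fn.size <= 20 and tp.size <= 20
                                 and np.unique(values).size == values.size) else "asymptotic"
            res = stats.mannwhitneyu(fn, tp, alternative="two-sided", method=method)
            entry["u_statistic"] = float(res.statistic)
            entry["p_value"] = float(res.pvalue)
            entry["applicable"] = True
        else:
            entry["applicable"] = False
        report[quantity] = entry
    return report
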