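"""Evaluation metrics for diagnosis sets against injected ground truth.

For each scenario the diagnosis set is scored *before* and *after* the
probing loop:

* **set size** — number of candidate minimal diagnoses;
* **weighted FPR** — per-diagnosis false-positive rate
  ``FP/(FP+TN)`` over faultable components, averaged with the diagnosis
  probabilities as weights;
* **health-state AUC** — ROC area of the health state ``H(c)`` as a ranking
  of the truly faulty components, computed from the 11 thresholds
  0.0, 0.1, …, 1.0 (strictly-greater comparison) with trapezoidal
  integration;
* **top-K** — whether the injected fault set appears, as an exact set, among
  the K most probable diagnoses (K = 1..5);
* **wasted effort** — expected number of healthy components inspected when
  components are examined in decreasing health-state order until every true
  fault has been reached, with ties resolved by their analytic expectation.

Dermatomes are excluded from every population: they can be neither true nor
predicted positives, and counting them would deflate false-positive rates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diagnosis import DiagnosisSet, diagnose, health_state
from .errors import InconsistentAnswerError, UndefinedMetricError
from .model import AnatomyModel
from .simulate import GroundTruthScenario, oracle_from_scenario
from .troubleshoot import run_probing

__all__ = [
    "MetricsRecord",
    "MetricsReport",
    "weighted_fpr",
    "health_auc",
    "top_k_contains",
    "wasted_effort",
    "evaluate_batch",
    "compare_policies",
]

#: Metrics where smaller is better ("improvement" = before − after).
LOWER_IS_BETTER = ("set_size", "weighted_fpr", "wasted_effort")
#: Metrics where larger is better ("improvement" = after − before).
HIGHER_IS_BETTER = ("auc", "top5_hit")


def weighted_fpr(
    model: AnatomyModel, D: DiagnosisSet, faults: Iterable[str]
) -> float:
    """Probability-weighted false-positive rate of a diagnosis set.

    For each diagnosis Δ: ``FP = |Δ \\ faults|`` and
    ``TN = |faultable \\ (Δ ∪ faults)|``. A diagnosis with ``FP + TN = 0``
    (every faultable component faulty or accused) contributes 0 and is
    flagged with a warning.
    """
    faults = set(faults)
    faultable = set(model.faultable_ids)
    total = 0.0
    for d in D:
        fp = len(d.delta - faults)
        tn = len(faultable - (set(d.delta) | faults))
        if fp + tn == 0:
            warnings.warn(
                "diagnosis covers every non-faulty component; its FPR term "
                "is defined as 0",
                stacklevel=2,
            )
            continue
        total += d.probability * fp / (fp + tn)
    return total


def health_auc(
    model: AnatomyModel, H: dict[str, float], faults: Iterable[str]
) -> float:
    """ROC area of the health state as a detector of the true faults.

    Eleven thresholds t = 0.0..1.0 in steps of 0.1; a component is predicted
    faulty when ``H(c) > t`` (strict). Each threshold yields an (FPR, TPR)
    point over the faultable components; the corner points (0,0) and (1,1)
    are added, points are sorted by FPR (TPR secondary) and integrated with
    the trapezoid rule.
    """
    faults = set(faults)
    if not faults:
        raise UndefinedMetricError("AUC undefined without faulty components")
    comps = model.faultable_ids
    healthy = [c for c in comps if c not in faults]
    points = {(0.0, 0.0), (1.0, 1.0)}
    for i in range(11):
        t = i / 10.0
        predicted = {c for c in comps if H.get(c, 0.0) > t}
        tp = len(predicted & faults)
        fp = len(predicted) - tp
        tpr = tp / len(faults)
        fpr = fp / len(healthy) if healthy else 0.0
        points.add((fpr, tpr))
    pts = sorted(points)
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    return float(np.trapezoid(ys, xs))


def top_k_contains(D: DiagnosisSet, faults: Iterable[str], K: int) -> bool:
    """Is the true fault set (exact set equality) among the K most probable
    diagnoses? Ranking ties are broken by (size, lexicographic) — the
    DiagnosisSet's canonical deterministic order."""
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    target = frozenset(faults)
    return any(d.delta == target for d in D.diagnoses[:K])


def wasted_effort(
    model: AnatomyModel, H: dict[str, float], faults: Iterable[str]
) -> float:
    """Expected number of healthy components inspected before all faults.

    Components are inspected in strictly decreasing health-state order until
    every true fault has been inspected. Healthy components strictly above
    the least-suspected fault ``h* = min_f H(f)`` are always inspected; within
    the tie group at ``h*`` (m healthy, r faulty components), a uniformly
    random order inspects ``m·r/(r+1)`` healthy components before the last
    faulty one in expectation.
    """
    faults = sorted(set(faults))
    if not faults:
        raise UndefinedMetricError("wasted effort undefined without faults")
    comps = model.faultable_ids
    h_star = min(H.get(f, 0.0) for f in faults)
    above = sum(
        1 for c in comps if c not in faults and H.get(c, 0.0) > h_star + 1e-12
    )
    tied = [c for c in comps if math.isclose(H.get(c, 0.0), h_star, abs_tol=1e-12)]
    m = sum(1 for c in tied if c not in faults)
    r = sum(1 for c in tied if c in faults)
    return above + m * r / (r + 1)


@dataclass(frozen=True)
class MetricsRecord:
    """Before/after metrics for one scenario."""

    scenario_seed: int
    cardinality: int
    set_size_before: int
    set_size_after: int
    weighted_fpr_before: float
    weighted_fpr_after: float
    auc_before: float
    auc_after: float
    topk_hit_before: dict[int, bool]
    topk_hit_after: dict[int, bool]
    wasted_effort_before: float
    wasted_effort_after: float
    probes_used: int
    probe_curve: list[int]
    truth_in_before: bool
    truth_in_after: bool

    def to_row(self) -> dict:
        row = {
            "scenario_seed": self.scenario_seed,
            "cardinality": self.cardinality,
            "set_size_before": self.set_size_before,
            "set_size_after": self.set_size_after,
            "weighted_fpr_before": self.weighted_fpr_before,
            "weighted_fpr_after": self.weighted_fpr_after,
            "auc_before": self.auc_before,
            "auc_after": self.auc_after,
            "wasted_effort_before": self.wasted_effort_before,
            "wasted_effort_after": self.wasted_effort_after,
            "probes_used": self.probes_used,
            "truth_in_before": self.truth_in_before,
            "truth_in_after": self.truth_in_after,
        }
        for k in range(1, 6):
            row[f"top{k}_hit_before"] = self.topk_hit_before[k]
            row[f"top{k}_hit_after"] = self.topk_hit_after[k]
        return row


@dataclass
class MetricsReport:
    """Per-scenario records plus per-cardinality aggregates."""

    records: list[MetricsRecord]
    policy: str
    prior_fault_prob: float
    seed: int
    n_inconsistent: int = 0
    probe_curves: list[list[int]] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.records])

    def per_cardinality_means(self) -> pd.DataFrame:
        df = self.to_dataframe()
        return df.groupby("cardinality").mean(numeric_only=True)

    def improvement_table(self, relative: bool = False) -> pd.DataFrame:
        """Mean per-cardinality improvement per metric, oriented so that
        better-after is positive: before − after for set size, weighted FPR
        and wasted effort; after − before for AUC and the top-5 hit rate.
        With ``relative=True``, improvements are divided by the before value.
        """
        df = self.to_dataframe()
        df = df.assign(
            top5_hit_before=df["top5_hit_before"].astype(float),
            top5_hit_after=df["top5_hit_after"].astype(float),
        )
        rows = {}
        for metric in LOWER_IS_BETTER + HIGHER_IS_BETTER:
            before, after = df[f"{metric}_before"], df[f"{metric}_after"]
            imp = (before - after) if metric in LOWER_IS_BETTER else (after - before)
            if relative:
                with np.errstate(divide="ignore", invalid="ignore"):
                    imp = (imp / before.replace(0, np.nan)).fillna(0.0)
            rows[metric] = imp.groupby(df["cardinality"]).mean()
        return pd.DataFrame(rows).T

    def mean_probe_curve(self) -> list[float]:
        """Mean diagnosis-set size per probe index, padding finished sessions
        with their terminal size."""
        if not self.probe_curves:
            return []
        width = max(len(c) for c in self.probe_curves)
        padded = [c + [c[-1]] * (width - len(c)) for c in self.probe_curves]
        return [float(np.mean(col)) for col in zip(*padded)]

    def summary(self) -> dict:
        imp = self.improvement_table()
        return {
            "policy": self.policy,
            "prior_fault_prob": self.prior_fault_prob,
            "seed": self.seed,
            "n_scenarios": len(self.records),
            "n_inconsistent": self.n_inconsistent,
            "per_cardinality_means": self.per_cardinality_means().to_dict(),
            "improvement_table": {
                metric: {int(k): v for k, v in row.items()}
                for metric, row in imp.iterrows()
            },
            "mean_probe_curve": self.mean_probe_curve(),
        }


def _score(
    model: AnatomyModel, D: DiagnosisSet, faults: frozenset[str]
) -> tuple[float, float, dict[int, bool], float]:
    H = health_state(D, model)
    return (
        weighted_fpr(model, D, faults),
        health_auc(model, H, faults),
        {k: top_k_contains(D, faults, k) for k in range(1, 6)},
        wasted_effort(model, H, faults),
    )


def evaluate_batch(
    model: AnatomyModel,
    scenarios: Sequence[GroundTruthScenario],
    policy: str = "info_gain",
    prior_fault_prob: float = 0.1,
    seed: int = 0,
) -> MetricsReport:
    """Diagnose each scenario's initial observations, run the probing loop
    against the scenario oracle, and score the set before and after.

    Sessions aborted by an inconsistent answer are counted and excluded from
    aggregation. Deterministic given the seed (per-scenario probing seeds are
    spawned from it).
    """
    master = np.random.default_rng(seed)
    records: list[MetricsRecord] = []
    curves: list[list[int]] = []
    n_inconsistent = 0
    for sc in scenarios:
        probe_seed = int(master.integers(2**31))
        D0 = diagnose(model, sc.initial_obs, prior_fault_prob)
        try:
            Df, log = run_probing(
                model, D0, oracle_from_scenario(sc), policy=policy, seed=probe_seed
            )
        except InconsistentAnswerError:
            n_inconsistent += 1
            continue
        fpr0, auc0, topk0, we0 = _score(model, D0, sc.faults)
        fpr1, auc1, topk1, we1 = _score(model, Df, sc.faults)
        curve = [len(D0)] + [r.set_size_after for r in log]
        records.append(
            MetricsRecord(
                scenario_seed=sc.seed,
                cardinality=sc.cardinality,
                set_size_before=len(D0),
                set_size_after=len(Df),
                weighted_fpr_before=fpr0,
                weighted_fpr_after=fpr1,
                auc_before=auc0,
                auc_after=auc1,
                topk_hit_before=topk0,
                topk_hit_after=topk1,
                wasted_effort_before=we0,
                wasted_effort_after=we1,
                probes_used=len(log),
                probe_curve=curve,
                truth_in_before=D0.contains_delta(sc.faults),
                truth_in_after=Df.contains_delta(sc.faults),
            )
        )
        curves.append(curve)
    return MetricsReport(
        records,
        policy=policy,
        prior_fault_prob=prior_fault_prob,
        seed=seed,
        n_inconsistent=n_inconsistent,
        probe_curves=curves,
    )


def first_probe_reduction(curve: Sequence[int]) -> float:
    """Fractional shrink of the diagnosis set after the first probe; 0.0 for
    sessions that never probed."""
    if len(curve) < 2 or curve[0] == 0:
        return 0.0
    return (curve[0] - curve[1]) / curve[0]


def compare_policies(
    model: AnatomyModel,
    scenarios: Sequence[GroundTruthScenario],
    prior_fault_prob: float = 0.1,
    seed: int = 0,
) -> dict:
    """Paired comparison of the information-gain and random probe policies.

    Runs both policies on the same scenarios (same per-scenario seeds) and
    compares the fractional diagnosis-set reduction after the first probe
    with a one-sided paired t-test (alternative: info-gain > random).
    """
    rep_ig = evaluate_batch(model, scenarios, "info_gain", prior_fault_prob, seed)
    rep_rand = evaluate_batch(model, scenarios, "random", prior_fault_prob, seed)
    red_ig = [first_probe_reduction(c) for c in rep_ig.probe_curves]
    red_rand = [first_probe_reduction(c) for c in rep_rand.probe_curves]
    n = min(len(red_ig), len(red_rand))
    red_ig, red_rand = red_ig[:n], red_rand[:n]
    diffs = np.array(red_ig) - np.array(red_rand)
    if np.allclose(diffs, 0.0):
        tstat, pvalue = 0.0, 1.0
    else:
        tstat, pvalue = stats.ttest_rel(red_ig, red_rand, alternative="greater")
    return {
        "n": n,
        "mean_first_probe_reduction_info_gain": float(np.mean(red_ig)) if n else 0.0,
        "mean_first_probe_reduction_random": float(np.mean(red_rand)) if n else 0.0,
        "t_statistic": float(tstat),
        "p_value": float(pvalue),
        "report_info_gain": rep_ig,
        "report_random": rep_rand,
    }
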