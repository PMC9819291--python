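"""Anchor-based MCID estimation for a change score (the core computation).

Given per-patient changes of a target instrument (FACIT-FS, oriented so
positive = improvement) and of one or more anchor instruments with
previously established MCIDs, the procedure is, per direction:

1. label each patient *truly worsened* / *improved* / *unchanged* by
   comparing the oriented anchor change against the anchor's own MCID
   (thresholds inclusive);
2. dichotomize (direction-positive vs all others), sweep every observed
   integer change of the required sign (plus 0) as a candidate cutoff,
   and compute sensitivity, specificity, and the tie-adjusted AUC
   (concordance probability);
3. select the operating cutoff maximizing the Youden index
   J = sensitivity + specificity - 1, ties broken toward the smaller
   absolute cutoff (the more sensitive MCID);
4. reconcile the per-anchor cutoffs into one MCID pair (on disagreement
   the primary anchor decides, matching how the published pair -3/+4 was
   settled when VAS Fatigue and SF36-MCS disagreed on improvement);
5. classify every patient by the final pair.

All deltas entering these routines must already be oriented so that
positive = improvement; orientation happens once, at ingestion
(:func:`oriented_delta` / :func:`compute_change_scores`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnchorSpec",
    "RocCurve",
    "McidResult",
    "McidPair",
    "McidAnalysis",
    "DEFAULT_ANCHORS",
    "DIRECTIONS",
    "oriented_delta",
    "compute_change_scores",
    "classify_by_anchor",
    "roc_curve",
    "select_cutoff",
    "reconcile_anchors",
    "classify_patients_by_mcid",
    "estimate_mcid",
    "bootstrap_mcid_ci",
]

DIRECTIONS = ("worsened", "improved")


@dataclass(frozen=True)
class AnchorSpec:
    """An external criterion instrument with per-direction MCIDs.

    ``mcid_worsen``/``mcid_improve`` are expressed on the *oriented*
    anchor-change scale (positive = improvement), so the worsening
    threshold is negative.
    """

    name: str
    higher_is_better: bool
    mcid_worsen: float
    mcid_improve: float
    primary: bool = False

    def __post_init__(self) -> None:
        if not (self.mcid_worsen < 0.0 < self.mcid_improve):
            raise ValueError(
                f"anchor {self.name}: need mcid_worsen < 0 < mcid_improve "
                f"(got {self.mcid_worsen}, {self.mcid_improve})"
            )


#: The two anchors of the fatigue analyses with commonly used scleroderma
#: thresholds: VAS Fatigue +/-10 mm (primary), SF36-MCS +/-5 points.
DEFAULT_ANCHORS: tuple[AnchorSpec, ...] = (
    AnchorSpec("vas_fatigue", higher_is_better=False,
               mcid_worsen=-10.0, mcid_improve=10.0, primary=True),
    AnchorSpec("sf36_mcs", higher_is_better=True,
               mcid_worsen=-5.0, mcid_improve=5.0),
)


@dataclass
class RocCurve:
    """ROC coordinates over the candidate cutoffs of one direction."""

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    direction: str
    n_pos: int
    n_neg: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "direction": self.direction,
            "cutoff": self.cutoffs,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        })


@dataclass(frozen=True)
class McidResult:
    direction: str
    anchor_name: str
    cutoff: float
    sensitivity: float
    specificity: float
    auc: float

    def __post_init__(self) -> None:
        if self.direction == "worsened" and self.cutoff > 0:
            raise ValueError("worsening cutoff must be <= 0")
        if self.direction == "improved" and self.cutoff < 0:
            raise ValueError("improvement cutoff must be >= 0")


@dataclass(frozen=True)
class McidPair:
    mcid_worsen: float
    mcid_improve: float
    provenance: tuple[McidResult, ...] = ()

    def __post_init__(self) -> None:
        if not (self.mcid_worsen < 0.0 < self.mcid_improve):
            raise ValueError("need mcid_worsen < 0 < mcid_improve")


def oriented_delta(baseline, followup, higher_is_better: bool) -> np.ndarray:
    """Change score oriented so positive always means improvement."""
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    d = followup - baseline
    return d if higher_is_better else -d


def compute_change_scores(cohort: pd.DataFrame,
                          anchors: tuple[AnchorSpec, ...] = DEFAULT_ANCHORS,
                          target: str = "facit_fs") -> pd.DataFrame:
    """Oriented change of the target and each anchor, one row per patient.

    The target instrument (FACIT-FS: higher = better) and every anchor are
    oriented at this single point; downstream routines never re-orient.
    """
    out = pd.DataFrame({"patient_id": cohort["patient_id"]})
    out["delta_target"] = oriented_delta(
        cohort[f"{target}_base"], cohort[f"{target}_fu"], higher_is_better=True)
    for anchor in anchors:
        out[f"delta_{anchor.name}"] = oriented_delta(
            cohort[f"{anchor.name}_base"], cohort[f"{anchor.name}_fu"],
            anchor.higher_is_better)
    return out


def classify_by_anchor(delta_anchor, anchor: AnchorSpec):
    """Label ``worsened`` / ``unchanged`` / ``improved`` by the anchor MCID.

    ``improved`` iff oriented delta >= ``mcid_improve``; ``worsened`` iff
    delta <= ``mcid_worsen``; thresholds inclusive.  Missing deltas map to
    ``excluded``.  Scalar in, scalar out; vector in, numpy array out.
    """
    d = np.asarray(delta_anchor, dtype=float)
    labels = np.where(np.isnan(d), "excluded",
                      np.where(d >= anchor.mcid_improve, "improved",
                               np.where(d <= anchor.mcid_worsen, "worsened",
                                        "unchanged")))
    if labels.ndim == 0:
        return labels.item()
    return labels


def roc_curve(delta_target, positive, direction: str) -> RocCurve:
    """ROC of the target change against a direction-positive labelling.

    For ``direction="worsened"`` a patient is test-positive at cutoff
    ``c <= 0`` iff ``delta_target <= c``; for ``"improved"``, iff
    ``delta_target >= c`` with ``c >= 0``.  Candidate cutoffs are every
    observed integer delta of the required sign plus 0.  The AUC is the
    tie-adjusted concordance probability (ties counted half), computed
    via mid-ranks.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    d = np.asarray(delta_target, dtype=float)
    pos = np.asarray(positive, dtype=bool)
    if d.shape != pos.shape:
        raise ValueError("delta_target and labels must align")
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"degenerate labels for direction {direction!r}: "
                         f"{n_pos} positives, {n_neg} negatives")
    # score increases with evidence for the direction
    score = -d if direction == "worsened" else d
    ranks = stats.rankdata(score)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    rounded = np.rint(d)
    if direction == "worsened":
        cand = np.unique(np.concatenate([rounded[rounded <= 0], [0.0]]))
        sens = np.array([(d[pos] <= c).mean() for c in cand])
        spec = np.array([(d[~pos] > c).mean() for c in cand])
    else:
        cand = np.unique(np.concatenate([rounded[rounded >= 0], [0.0]]))
        sens = np.array([(d[pos] >= c).mean() for c in cand])
        spec = np.array([(d[~pos] < c).mean() for c in cand])
    return RocCurve(cand, sens, spec, float(auc), direction, n_pos, n_neg)


def select_cutoff(curve: RocCurve, rule: str = "youden",
                  anchor_name: str = "") -> McidResult:
    """Operating cutoff of one ROC curve.

    ``rule="youden"`` maximizes J = sensitivity + specificity - 1; ties
    (within 1e-12) resolve toward the smaller ``|cutoff|``.
    """
    if curve.cutoffs.size == 0:
        raise ValueError("empty ROC curve")
    if rule != "youden":
        raise ValueError(f"unknown selection rule {rule!r}")
    j = curve.sensitivity + curve.specificity - 1.0
    # a zero cutoff cannot express a *minimal important* change; the 0
    # sentinel stays on the curve but is only selectable when no nonzero
    # candidate exists
    eligible = np.flatnonzero(curve.cutoffs != 0)
    if eligible.size == 0:
        eligible = np.arange(curve.cutoffs.size)
    best = np.max(j[eligible])
    tied = eligible[j[eligible] >= best - 1e-12]
    k = tied[np.argmin(np.abs(curve.cutoffs[tied]))]
    return McidResult(curve.direction, anchor_name, float(curve.cutoffs[k]),
                      float(curve.sensitivity[k]), float(curve.specificity[k]),
                      curve.auc)


def reconcile_anchors(results: dict[str, list[McidResult]],
                      policy: str = "primary",
                      primary_anchor: str = "vas_fatigue") -> McidPair:
    """Combine per-anchor cutoffs into the final MCID pair.

    ``results`` maps each direction to its per-anchor :class:`McidResult`
    list.  Policies: ``primary`` (common value when all anchors agree,
    otherwise the primary anchor's value -- the published behaviour),
    ``max`` / ``min`` (largest / smallest absolute cutoff), ``mean``
    (mean cutoff rounded half away from zero).
    """
    final: dict[str, float] = {}
    provenance: list[McidResult] = []
    for direction in DIRECTIONS:
        entries = results.get(direction, [])
        if not entries:
            raise ValueError(f"no MCID result for direction {direction!r}")
        provenance.extend(entries)
        values = [r.cutoff for r in entries]
        if policy == "primary":
            if len(set(values)) == 1:
                final[direction] = values[0]
            else:
                prim = [r for r in entries if r.anchor_name == primary_anchor]
                if not prim:
                    raise ValueError(
                        f"anchors disagree on {direction} and primary anchor "
                        f"{primary_anchor!r} is absent")
                final[direction] = prim[0].cutoff
        elif policy == "max":
            final[direction] = max(values, key=abs)
        elif policy == "min":
            final[direction] = min(values, key=abs)
        elif policy == "mean":
            mean = float(np.mean(values))
            final[direction] = float(np.copysign(np.floor(abs(mean) + 0.5), mean))
        else:
            raise ValueError(f"unknown reconciliation policy {policy!r}")
    return McidPair(final["worsened"], final["improved"], tuple(provenance))


def classify_patients_by_mcid(change_scores: pd.DataFrame,
                              pair: McidPair) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label every patient by the final MCID pair and count the groups.

    ``worsened`` iff delta <= ``mcid_worsen``; ``improved`` iff delta >=
    ``mcid_improve``; else ``unchanged``; missing deltas are ``excluded``
    and counted separately.  Labels partition the classified patients.
    """
    d = change_scores["delta_target"].to_numpy(dtype=float)
    labels = np.where(np.isnan(d), "excluded",
                      np.where(d <= pair.mcid_worsen, "worsened",
                               np.where(d >= pair.mcid_improve, "improved",
                                        "unchanged")))
    out = pd.DataFrame({"patient_id": change_scores["patient_id"],
                        "label": labels})
    counts = {key: int((labels == key).sum())
              for key in ("worsened", "improved", "unchanged", "excluded")}
    return out, counts


@dataclass
class McidAnalysis:
    """Everything the MCID stage produces for one cohort."""

    pair: McidPair
    results: tuple[McidResult, ...]
    curves: dict[tuple[str, str], RocCurve]         # (direction, anchor)
    change_scores: pd.DataFrame
    labels: pd.DataFrame
    counts: dict[str, int]

    def results_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "direction": r.direction, "anchor": r.anchor_name,
            "cutoff": r.cutoff, "sensitivity": r.sensitivity,
            "specificity": r.specificity, "auc": r.auc,
        } for r in self.results])

    def roc_frame(self) -> pd.DataFrame:
        parts = []
        for (direction, anchor), curve in self.curves.items():
            f = curve.to_frame()
            f.insert(1, "anchor", anchor)
            parts.append(f)
        return pd.concat(parts, ignore_index=True)


def estimate_mcid(cohort: pd.DataFrame,
                  anchors: tuple[AnchorSpec, ...] = DEFAULT_ANCHORS,
                  policy: str = "primary",
                  rule: str = "youden") -> McidAnalysis:
    """Run the full anchor-based MCID procedure on one cohort table.

    Patients with a missing target or anchor delta are excluded from the
    ROC of that anchor; the negative class pools unchanged and
    opposite-direction patients.
    """
    primary = next((a.name for a in anchors if a.primary), anchors[0].name)
    scores = compute_change_scores(cohort, anchors)
    results: dict[str, list[McidResult]] = {d: [] for d in DIRECTIONS}
    curves: dict[tuple[str, str], RocCurve] = {}
    for anchor in anchors:
        delta_anchor = scores[f"delta_{anchor.name}"].to_numpy(dtype=float)
        usable = ~(np.isnan(delta_anchor)
                   | scores["delta_target"].isna().to_numpy())
        anchor_labels = classify_by_anchor(delta_anchor[usable], anchor)
        d_target = scores["delta_target"].to_numpy(dtype=float)[usable]
        for direction in DIRECTIONS:
            curve = roc_curve(d_target, anchor_labels == direction, direction)
            curves[(direction, anchor.name)] = curve
            results[direction].append(
                select_cutoff(curve, rule=rule, anchor_name=anchor.name))
    pair = reconcile_anchors(results, policy=policy, primary_anchor=primary)
    labels, counts = classify_patients_by_mcid(scores, pair)
    flat = tuple(r for direction in DIRECTIONS for r in results[direction])
    return McidAnalysis(pair, flat, curves, scores, labels, counts)


def bootstrap_mcid_ci(cohort: pd.DataFrame,
                      anchors: tuple[AnchorSpec, ...] = DEFAULT_ANCHORS,
                      policy: str = "primary",
                      n_boot: int = 2000,
                      seed: int = 0,
                      level: float = 0.95) -> pd.DataFrame:
    """Percentile bootstrap intervals for the MCID pair and per-anchor AUCs.

    Patients are resampled with replacement; replicates whose resample
    degenerates (a direction with no positives or no negatives) are
    skipped and reported.
    """
    rng = np.random.default_rng(seed)
    n = len(cohort)
    stats_rows = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            ana = estimate_mcid(cohort.iloc[idx].reset_index(drop=True),
                                anchors=anchors, policy=policy)
        except ValueError:
            skipped += 1
            continue
        row = {"mcid_worsen": ana.pair.mcid_worsen,
               "mcid_improve": ana.pair.mcid_improve}
        for r in ana.results:
            row[f"auc_{r.direction}_{r.anchor_name}"] = r.auc
        stats_rows.append(row)
    boot = pd.DataFrame(stats_rows)
    alpha = (1.0 - level) / 2.0
    out = boot.quantile([alpha, 0.5, 1.0 - alpha]).T
    out.columns = ["lower", "median", "upper"]
    out.attrs["n_boot_effective"] = len(boot)
    out.attrs["n_boot_skipped"] = skipped
    return out
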