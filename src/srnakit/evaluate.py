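"""Scoring pipeline calls against simulated ground truth.

A called miRNA is a true positive when its mature sequence equals a
planted mature exactly; a drought-category call must match the planted
class exactly; a TAS locus requires >= 50% reciprocal overlap between the
called cluster's phased-unit span and the planted phased region; a trigger
is correct when the assigned miRNA's mature equals the planted trigger
and the hit model matches. With an empty call set, precision is reported
as 1.0 (0/0 convention) and recall as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .expression import DEResult
from .mirna import MiRNAAnnotation
from .phasing import PhasedCluster, TriggerAssignment
from .simulate import GroundTruth

__all__ = ["TaskScore", "EvaluationReport", "evaluate_against_truth"]

# planted class -> expected pipeline category
CLASS_TO_CATEGORY = {
    "up_both": "up_both",
    "down_both": "down_both",
    "up_T_down_S": "up_T_down_S",
    "down_T_up_S": "down_T_up_S",
    "unchanged": "mixed_or_unchanged",
    "nd": "mixed_or_unchanged",
}


@dataclass
class TaskScore:
    task: str
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 1.0


@dataclass
class EvaluationReport:
    scores: list[TaskScore]
    details: dict[str, object]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "task": s.task, "tp": s.tp, "fp": s.fp, "fn": s.fn,
                    "precision": s.precision, "recall": s.recall,
                }
                for s in self.scores
            ]
        )


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def evaluate_against_truth(
    truth: GroundTruth,
    annotations: list[MiRNAAnnotation] | None = None,
    de_results: list[DEResult] | None = None,
    clusters: list[PhasedCluster] | None = None,
    triggers: dict[str, TriggerAssignment | None] | None = None,
    de_min_mean: float = 20.0,
) -> EvaluationReport:
    scores: list[TaskScore] = []
    details: dict[str, object] = {}

    # --- miRNA calling (by exact mature sequence)
    if annotations is not None:
        planted = {m.mature_seq for m in truth.planted_mirs}
        called = {a.mature for a in annotations}
        tp = len(called & planted)
        scores.append(
            TaskScore("mirna_calling", tp, len(called - planted), len(planted - called))
        )
        details["mirna_missed"] = sorted(planted - called)
        details["mirna_spurious"] = sorted(called - planted)

    # --- DE categorisation, restricted to directional classes with
    # control-side mean >= de_min_mean
    if de_results is not None:
        by_mature = {m.mature_seq: m for m in truth.planted_mirs}
        by_id = {r.mirna_id: r for r in de_results}
        ann_by_mature = {a.mature: a for a in (annotations or [])}
        tp = fp = fn = 0
        unchanged_total = unchanged_miscalled = 0
        for m in truth.planted_mirs:
            expected = CLASS_TO_CATEGORY[m.de_class]
            ann = ann_by_mature.get(m.mature_seq)
            res = by_id.get(ann.name or ann.locus_id) if ann else None
            if m.de_class in ("unchanged", "nd"):
                if res is not None:
                    unchanged_total += 1
                    if res.category != expected:
                        unchanged_miscalled += 1
                continue
            base_mean = max(
                m.expected_means.get("G1_ctrl", 0.0),
                m.expected_means.get("G2_ctrl", 0.0),
            )
            if base_mean < de_min_mean:
                continue
            if res is None:
                fn += 1
            elif res.category == expected:
                tp += 1
            else:
                fp += 1
                fn += 1
        scores.append(TaskScore("de_categorization", tp, fp, fn))
        details["unchanged_total"] = unchanged_total
        details["unchanged_miscalled"] = unchanged_miscalled
        details["unchanged_false_rate"] = (
            unchanged_miscalled / unchanged_total if unchanged_total else 0.0
        )

    # --- TAS detection by >= 50% reciprocal overlap of phased spans
    matched: dict[str, PhasedCluster] = {}
    if clusters is not None:
        used = set()
        fn = 0
        for t in truth.planted_tas:
            span_t = (t.cleavage, t.cleavage + 21 * t.n_units)
            hit = None
            for cl in clusters:
                if cl.chrom != t.chrom or id(cl) in used:
                    continue
                if _reciprocal_overlap(span_t, cl.unit_span) >= 0.5:
                    hit = cl
                    break
            if hit is None:
                fn += 1
            else:
                used.add(id(hit))
                matched[t.locus_id] = hit
        fp = len(clusters) - len(matched)
        scores.append(TaskScore("tas_detection", len(matched), fp, fn))

    # --- trigger assignment on matched TAS loci
    if triggers is not None and clusters is not None:
        tp = fp = fn = 0
        for t in truth.planted_tas:
            cl = matched.get(t.locus_id)
            assignment = triggers.get(cl.tas_id) if cl is not None else None
            if assignment is None:
                fn += 1
                continue
            mirna_seq = assignment.mirna_id  # resolved below if annotations given
            if annotations is not None:
                by_name = {a.name or a.locus_id: a.mature for a in annotations}
                mirna_seq = by_name.get(assignment.mirna_id, assignment.mirna_id)
            if mirna_seq == t.trigger_seq and assignment.hit_model == t.hit_model:
                tp += 1
            else:
                fp += 1
                fn += 1
        scores.append(TaskScore("trigger_assignment", tp, fp, fn))

    return EvaluationReport(scores=scores, details=details)
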