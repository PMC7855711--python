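"""Relative quantification of qPCR data by the 2^-ΔΔCt method.

ΔCt normalises each sample's target Ct against a reference gene
(technical replicates are averaged first); ΔΔCt is the difference of
group mean ΔCts and 2^-ΔΔCt the implied fold change.  Group comparison
uses Student's t-test on the ΔCts — paired on within-pair differences
for matched designs (e.g. tumor vs. adjacent normal tissue), unpaired
otherwise — with significance flagged at p <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datatypes import CtRecord
from .errors import DegenerateInputError, ValidationError
from .stats import TTestResult, compare_groups


def delta_ct(records: list[CtRecord], sample_id: str, target_id: str,
             reference_id: str) -> float:
    """ΔCt = mean(target replicate Cts) - mean(reference replicate Cts)
    for one sample."""
    target = [r.ct for r in records if r.sample_id == sample_id and r.target_id == target_id]
    reference = [r.ct for r in records
                 if r.sample_id == sample_id and r.target_id == reference_id]
    if not target:
        raise ValidationError(f"sample {sample_id!r}: no Ct for target {target_id!r}")
    if not reference:
        raise ValidationError(f"sample {sample_id!r}: no Ct for reference {reference_id!r}")
    return float(np.mean(target) - np.mean(reference))


def fold_change(group_case, group_control) -> float:
    """2^-ΔΔCt with ΔΔCt = mean(ΔCt_case) - mean(ΔCt_control)."""
    case = np.asarray(group_case, dtype=float)
    control = np.asarray(group_control, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValidationError("fold_change requires non-empty groups")
    ddct = float(case.mean() - control.mean())
    return float(2.0 ** (-ddct))


@dataclass
class QpcrResult:
    """Per-target relative-quantification report row."""

    target_id: str
    group_case: str
    group_control: str
    n_case: int
    n_control: int
    ddct: float
    fold_change: float
    t: float
    p: float
    significant: bool
    paired: bool
    per_pair_fold_changes: Optional[dict[str, float]] = None


def _safe_compare(a, b, **kwargs) -> TTestResult:
    # exactly replicate-free ΔCts (e.g. noise-free simulated plates) have
    # zero variance: the fold change is still well defined, the test is not
    try:
        return compare_groups(a, b, **kwargs)
    except DegenerateInputError:
        return TTestResult(t=float("nan"), p=float("nan"), significant=False)


def _group_delta_cts(records: list[CtRecord], target_id: str, reference_id: str,
                     group_label: str) -> dict[str, float]:
    """ΔCt per sample for every sample of the group measuring the target."""
    samples = sorted({r.sample_id for r in records
                      if r.group_label == group_label and r.target_id == target_id})
    return {s: delta_ct(records, s, target_id, reference_id) for s in samples}


def analyze_target(records: list[CtRecord], target_id: str, reference_id: str,
                   group_case: str, group_control: str, paired: bool = False,
                   welch: bool = False, alpha: float = 0.05) -> QpcrResult:
    """Full 2^-ΔΔCt analysis of one target between two groups.

    Paired designs require every sample to carry a pair_id and both
    members of each pair to be measured; unmatched pair_ids are an
    error.  Per-pair fold changes are reported whenever pair_ids exist.
    """
    dct_case = _group_delta_cts(records, target_id, reference_id, group_case)
    dct_control = _group_delta_cts(records, target_id, reference_id, group_control)
    if not dct_case or not dct_control:
        raise ValidationError(f"target {target_id!r}: empty group")

    pair_of = {r.sample_id: r.pair_id for r in records if r.pair_id is not None}
    per_pair_fc = None
    if paired:
        case_by_pair = {pair_of[s]: d for s, d in dct_case.items() if s in pair_of}
        ctrl_by_pair = {pair_of[s]: d for s, d in dct_control.items() if s in pair_of}
        unmatched = sorted(set(case_by_pair) ^ set(ctrl_by_pair))
        unpaired_samples = sorted(
            [s for s in dct_case if s not in pair_of]
            + [s for s in dct_control if s not in pair_of]
        )
        if unmatched or unpaired_samples:
            raise ValidationError(
                "incomplete pairing: unmatched pair_ids "
                f"{unmatched}, samples without pair_id {unpaired_samples}"
            )
        pairs = sorted(case_by_pair)
        a = [case_by_pair[p] for p in pairs]
        b = [ctrl_by_pair[p] for p in pairs]
        test = _safe_compare(a, b, paired=True, alpha=alpha)
        per_pair_fc = {p: float(2.0 ** (-(case_by_pair[p] - ctrl_by_pair[p]))) for p in pairs}
        case_vals, ctrl_vals = a, b
    else:
        case_vals = [dct_case[s] for s in sorted(dct_case)]
        ctrl_vals = [dct_control[s] for s in sorted(dct_control)]
        test = _safe_compare(case_vals, ctrl_vals, paired=False, welch=welch, alpha=alpha)

    ddct = float(np.mean(case_vals) - np.mean(ctrl_vals))
    return QpcrResult(
        target_id=target_id, group_case=group_case, group_control=group_control,
        n_case=len(case_vals), n_control=len(ctrl_vals),
        ddct=ddct, fold_change=float(2.0 ** (-ddct)),
        t=test.t, p=test.p, significant=test.significant, paired=paired,
        per_pair_fold_changes=per_pair_fc,
    )


def analyze_plate(records: list[CtRecord], reference_id: str, group_case: str,
                  group_control: str, paired: bool = False, welch: bool = False,
                  alpha: float = 0.05) -> list[QpcrResult]:
    """Run analyze_target for every non-reference target on the plate."""
    targets = sorted({r.target_id for r in records if r.target_id != reference_id})
    return [analyze_target(records, t, reference_id, group_case, group_control,
                           paired=paired, welch=welch, alpha=alpha)
            for t in targets]
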