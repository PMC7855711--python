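"""Stage 2: lncRNA-bait correlation screen and four-list candidate algebra.

Every lncRNA is correlated with every bait gene within each dataset
(Pearson, p < alpha); per-dataset significant associations are voted
across datasets per (lncRNA, bait, sign) triple, and retained triples
populate four signed lists:

  A: positively correlated with down-regulated baits
  B: positively correlated with up-regulated baits
  C: negatively correlated with down-regulated baits
  D: negatively correlated with up-regulated baits

Under the sponge model a tumor-suppressor lncRNA tracks the
down-regulated coding genes, so candidates arise from A∩D; oncogene
candidates from B∩C; membership in both intersections is surfaced as a
conflict rather than silently resolved.
"""

from __future__ import annotations

import logging
from fractions import Fraction

from .datatypes import (CandidateCall, ConsensusGeneList, CorrelationRecord,
                        ExpressionDataset, FourLists, SignedConsensusEntry)
from .stats import pearson_matrix

log = logging.getLogger(__name__)


def correlate_lncrnas(dataset: ExpressionDataset,
                      baits_up: ConsensusGeneList, baits_down: ConsensusGeneList,
                      alpha: float = 0.01) -> list[CorrelationRecord]:
    """Pearson correlation of every measured lncRNA against every measured
    bait gene; only pairs with p < ``alpha`` are returned."""
    lnc_ids = dataset.features_of_biotype("lncRNA")
    if not lnc_ids:
        log.warning("%s: no lncRNA features; stage contributes nothing", dataset.dataset_id)
        return []
    bait_ids = [b for b in baits_up.feature_ids + baits_down.feature_ids
                if b in dataset.values.index]
    if not bait_ids:
        return []
    L = dataset.values.loc[lnc_ids].to_numpy(dtype=float)
    B = dataset.values.loc[bait_ids].to_numpy(dtype=float)
    R, P, N = pearson_matrix(L, B)
    out = []
    for i, lnc in enumerate(lnc_ids):
        for j, bait in enumerate(bait_ids):
            p = P[i, j]
            if p == p and p < alpha and N[i, j] >= 3:  # p==p filters NaN
                out.append(CorrelationRecord(
                    dataset_id=dataset.dataset_id, feature_a=lnc, feature_b=bait,
                    r=float(R[i, j]), p=float(p), n=int(N[i, j]),
                ))
    return out


def vote_and_build_lists(records_by_dataset: dict[str, list[CorrelationRecord]],
                         baits_up: ConsensusGeneList, baits_down: ConsensusGeneList,
                         n_datasets_consulted: int,
                         min_fraction: Fraction | float = Fraction(1, 2),
                         min_bait_count: int = 1) -> FourLists:
    """Vote per (lncRNA, bait, sign) triple across datasets, then map
    retained triples to the four lists by sign x bait direction.

    A lncRNA enters a list when it has at least ``min_bait_count``
    retained bait associations of the corresponding type.
    """
    min_fraction = Fraction(min_fraction).limit_denominator(10**9)
    up_set = set(baits_up.feature_ids)
    down_set = set(baits_down.feature_ids)

    votes: dict[tuple[str, str, str], set[str]] = {}
    for ds_id, records in records_by_dataset.items():
        for rec in records:
            votes.setdefault((rec.feature_a, rec.feature_b, rec.sign), set()).add(ds_id)

    lists = FourLists()
    counts: dict[tuple[str, str], set[str]] = {}  # (lncrna, list letter) -> baits
    for (lnc, bait, sign), ds_ids in sorted(votes.items()):
        frac = Fraction(len(ds_ids), n_datasets_consulted)
        if frac < min_fraction:
            continue
        entry = SignedConsensusEntry(
            lncrna_id=lnc, bait_id=bait, sign=sign,
            support_fraction=frac, supporting_dataset_ids=tuple(sorted(ds_ids)),
        )
        lists.entries.append(entry)
        if bait in down_set:
            letter = "A" if sign == "positive" else "C"
        elif bait in up_set:
            letter = "B" if sign == "positive" else "D"
        else:
            continue
        counts.setdefault((lnc, letter), set()).add(bait)

    target = {"A": lists.list_A, "B": lists.list_B, "C": lists.list_C, "D": lists.list_D}
    for (lnc, letter), baits in counts.items():
        if len(baits) >= min_bait_count:
            target[letter].add(lnc)
    return lists


def classify_candidates(lists: FourLists) -> list[CandidateCall]:
    """Set algebra over the four lists.

    tumor_suppressor = A∩D \\ B∩C; oncogene = B∩C \\ A∩D; membership in
    both intersections yields role=conflict.  Output sorted by lncRNA id.
    """
    ts = lists.list_A & lists.list_D
    onco = lists.list_B & lists.list_C
    calls = []
    for lnc in sorted(ts | onco):
        in_ts, in_onco = lnc in ts, lnc in onco
        role = "conflict" if (in_ts and in_onco) else ("tumor_suppressor" if in_ts else "oncogene")
        source = frozenset(
            letter for letter, members in lists.as_dict().items() if lnc in members
        )
        calls.append(CandidateCall(lncrna_id=lnc, role=role, source_lists=source))
    return calls
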