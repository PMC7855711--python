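"""Stage 3: reconstruction of lncRNA-miRNA-mRNA (ceRNA) axes.

For a candidate lncRNA: (1) select miRNAs negatively correlated with it
(p <= alpha, default 0.001); (2) union those with miRNAs carrying
predicted binding sites for the lncRNA; (3) expand each miRNA to its
experimentally validated mRNA targets, dropping miRNAs with none;
(4) keep only miRNAs annotated as dysregulated in the study disease
(oncomiRs); (5) assemble one axis per (miRNA, target mRNA) pair whose
mRNA is significantly positively correlated with the lncRNA, recording
the miRNA-mRNA correlation and whether the full negative-sign pattern
of the sponge model holds (``strict_pass``).

Identifier comparison is case-insensitive after whitespace trimming; no
alias resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .datatypes import CeRNAAxis, CorrelationRecord, ExpressionDataset, InteractionTable
from .stats import pearson_matrix

log = logging.getLogger(__name__)


def _norm(identifier: str) -> str:
    return identifier.strip().lower()


@dataclass
class AnnotatedMirna:
    """A miRNA with its evidence channels and optional correlation record."""

    mirna_id: str
    correlation_selected: bool = False
    binding_predicted: bool = False
    correlation: Optional[CorrelationRecord] = None
    cancer_directions: tuple[str, ...] = ()
    targets: frozenset = frozenset()


def select_negative_mirnas(lnc_id: str, dataset: ExpressionDataset,
                           alpha: float = 0.001) -> list[CorrelationRecord]:
    """miRNAs negatively correlated with the lncRNA at p <= ``alpha``."""
    if lnc_id not in dataset.values.index:
        raise KeyError(f"{dataset.dataset_id}: lncRNA {lnc_id!r} not measured")
    mirna_ids = dataset.features_of_biotype("miRNA")
    if not mirna_ids:
        return []
    L = dataset.values.loc[[lnc_id]].to_numpy(dtype=float)
    M = dataset.values.loc[mirna_ids].to_numpy(dtype=float)
    R, P, N = pearson_matrix(L, M)
    out = []
    for j, mirna in enumerate(mirna_ids):
        r, p = R[0, j], P[0, j]
        if r == r and r < 0 and p <= alpha and N[0, j] >= 3:
            out.append(CorrelationRecord(
                dataset_id=dataset.dataset_id, feature_a=lnc_id, feature_b=mirna,
                r=float(r), p=float(p), n=int(N[0, j]),
            ))
    return out


def merge_mirna_evidence(correlation_hits: list[CorrelationRecord],
                         binding_table: InteractionTable,
                         lnc_id: str) -> dict[str, AnnotatedMirna]:
    """Union of correlation-selected and binding-predicted miRNAs.

    Binding predictions "complete" the correlation output: a miRNA from
    either channel is retained, flagged with the channel(s) that
    supplied it.  Keys are normalised (trimmed, lower-cased) ids; the
    original spelling is kept on the record.
    """
    if binding_table.kind != "lncrna_mirna_binding":
        raise ValueError("binding_table must have kind 'lncrna_mirna_binding'")
    merged: dict[str, AnnotatedMirna] = {}
    for rec in correlation_hits:
        key = _norm(rec.feature_b)
        merged[key] = AnnotatedMirna(
            mirna_id=rec.feature_b, correlation_selected=True, correlation=rec,
        )
    rows = binding_table.rows
    for _, row in rows[rows["id_a"].map(_norm) == _norm(lnc_id)].iterrows():
        key = _norm(row["id_b"])
        if key in merged:
            merged[key].binding_predicted = True
        else:
            merged[key] = AnnotatedMirna(mirna_id=row["id_b"], binding_predicted=True)
    return merged


def expand_validated_targets(mirnas: dict[str, AnnotatedMirna],
                             targets_table: InteractionTable,
                             ) -> tuple[dict[str, AnnotatedMirna], list[str]]:
    """Attach each miRNA's validated mRNA target set (deduplicated).

    miRNAs with an empty target set are dropped and returned in the
    excluded list.
    """
    if targets_table.kind != "mirna_mrna_validated":
        raise ValueError("targets_table must have kind 'mirna_mrna_validated'")
    by_mirna: dict[str, set[str]] = {}
    for _, row in targets_table.rows.iterrows():
        by_mirna.setdefault(_norm(row["id_a"]), set()).add(row["id_b"].strip())
    kept: dict[str, AnnotatedMirna] = {}
    excluded: list[str] = []
    for key, ann in mirnas.items():
        targets = by_mirna.get(key, set())
        if not targets:
            excluded.append(ann.mirna_id)
            continue
        ann.targets = frozenset(targets)
        kept[key] = ann
    if excluded:
        log.info("miRNA(s) without validated targets excluded: %s",
                 ", ".join(sorted(excluded)))
    return kept, sorted(excluded)


def filter_oncomirs(mirnas: dict[str, AnnotatedMirna], cancer_table: InteractionTable,
                    disease: str) -> dict[str, AnnotatedMirna]:
    """Keep miRNAs with >= 1 dysregulation annotation for the disease.

    All recorded dysregulation directions are attached; conflicting
    directions from different sources are both reported, never resolved.
    """
    if cancer_table.kind != "mirna_cancer":
        raise ValueError("cancer_table must have kind 'mirna_cancer'")
    rows = cancer_table.rows
    disease_rows = rows[rows["id_b"].map(_norm) == _norm(disease)]
    directions: dict[str, list[str]] = {}
    for _, row in disease_rows.iterrows():
        ds = directions.setdefault(_norm(row["id_a"]), [])
        if row["annotation"] and row["annotation"] not in ds:
            ds.append(row["annotation"])
    kept = {}
    for key, ann in mirnas.items():
        if key in directions:
            ann.cancer_directions = tuple(directions[key])
            kept[key] = ann
    return kept


@dataclass
class AxisThresholds:
    """Thresholds for axis assembly.

    alpha_lnc_mrna: significance level for the required positive
    lncRNA-mRNA correlation.  min_r_lnc_mrna: optional floor on that
    coefficient (0 keeps all significant positives).  top_k_mrnas:
    optional cap keeping only the highest-r mRNAs per lncRNA.
    """

    alpha_lnc_mrna: float = 0.01
    min_r_lnc_mrna: float = 0.0
    top_k_mrnas: Optional[int] = None


def assemble_axes(lnc_id: str, mirnas: dict[str, AnnotatedMirna],
                  corr_lnc_mrna: list[CorrelationRecord],
                  corr_mirna_mrna: list[CorrelationRecord],
                  thresholds: AxisThresholds | None = None,
                  strict: bool = False) -> list[CeRNAAxis]:
    """Assemble sign-checked axes, ranked by descending lncRNA-mRNA r.

    One axis per (miRNA, mRNA) pair where the mRNA belongs to the
    miRNA's validated target set and is positively correlated with the
    lncRNA (r > min_r, p <= alpha).  ``strict_pass`` marks axes whose
    miRNA is significantly negatively correlated with the lncRNA and
    whose miRNA-mRNA correlation is negative; with ``strict=True`` only
    those are emitted.  Pairs lacking a miRNA-mRNA correlation record
    are skipped with a log entry, never fabricated.
    """
    th = thresholds or AxisThresholds()
    lnc_mrna = {_norm(rec.feature_b): rec for rec in corr_lnc_mrna
                if _norm(rec.feature_a) == _norm(lnc_id)}
    mirna_mrna = {(_norm(rec.feature_a), _norm(rec.feature_b)): rec
                  for rec in corr_mirna_mrna}

    eligible_mrnas = {
        key: rec for key, rec in lnc_mrna.items()
        if rec.r > th.min_r_lnc_mrna and rec.r > 0 and rec.p <= th.alpha_lnc_mrna
    }
    if th.top_k_mrnas is not None:
        ranked = sorted(eligible_mrnas.items(), key=lambda kv: -kv[1].r)[: th.top_k_mrnas]
        eligible_mrnas = dict(ranked)

    axes: list[CeRNAAxis] = []
    for key in sorted(mirnas):
        ann = mirnas[key]
        for mrna in sorted(ann.targets):
            mkey = _norm(mrna)
            if mkey not in eligible_mrnas:
                continue
            lm = eligible_mrnas[mkey]
            mm = mirna_mrna.get((key, mkey))
            if mm is None:
                log.info("axis %s / %s / %s skipped: no miRNA-mRNA correlation record",
                         lnc_id, ann.mirna_id, mrna)
                continue
            corr = ann.correlation
            neg_lnc_mirna = corr is not None and corr.r < 0
            strict_pass = bool(neg_lnc_mirna and mm.r < 0)
            if strict and not strict_pass:
                continue
            axes.append(CeRNAAxis(
                lncrna_id=lnc_id, mirna_id=ann.mirna_id, mrna_id=mrna,
                r_lnc_mirna=None if corr is None else corr.r,
                p_lnc_mirna=None if corr is None else corr.p,
                r_mirna_mrna=mm.r, p_mirna_mrna=mm.p,
                r_lnc_mrna=lm.r, p_lnc_mrna=lm.p,
                evidence={
                    "binding_predicted": ann.binding_predicted,
                    "correlation_selected": ann.correlation_selected,
                    "target_validated": True,
                    "oncomir": bool(ann.cancer_directions),
                },
                mirna_cancer_direction="/".join(ann.cancer_directions) or None,
                strict_pass=strict_pass,
            ))
    axes.sort(key=lambda ax: (-ax.r_lnc_mrna, ax.mirna_id, ax.mrna_id))
    return axes


def correlate_pairs(dataset: ExpressionDataset, ids_a: list[str], ids_b: list[str],
                    ) -> list[CorrelationRecord]:
    """All-pairs correlation records (no significance filter) between two
    feature groups measured in the dataset; unmeasured ids are skipped."""
    ids_a = [i for i in ids_a if i in dataset.values.index]
    ids_b = [i for i in ids_b if i in dataset.values.index]
    if not ids_a or not ids_b:
        return []
    A = dataset.values.loc[ids_a].to_numpy(dtype=float)
    B = dataset.values.loc[ids_b].to_numpy(dtype=float)
    R, P, N = pearson_matrix(A, B)
    out = []
    for i, a in enumerate(ids_a):
        for j, b in enumerate(ids_b):
            if a == b or R[i, j] != R[i, j]:
                continue
            out.append(CorrelationRecord(
                dataset_id=dataset.dataset_id, feature_a=a, feature_b=b,
                r=float(R[i, j]), p=float(P[i, j]), n=int(N[i, j]),
            ))
    return out
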