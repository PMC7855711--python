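"""Stage 1: consensus differential screening of protein-coding genes.

Each dataset is tested per severity contrast with a one-way ANOVA
(equivalent to a pooled-variance t-test for two groups), FDR-adjusted
within (dataset x contrast), then votes are counted across datasets: a
gene becomes a "bait gene" when the same direction of dysregulation is
called in at least ``min_fraction`` (default 50%) of consulted datasets.
"""

from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np

from .datatypes import ConsensusGeneList, ContrastSpec, DifferentialResult, ExpressionDataset
from .errors import InsufficientDataError
from .stats import anova_two_group, fdr_adjust

log = logging.getLogger(__name__)


def differential_by_contrast(dataset: ExpressionDataset, contrast: ContrastSpec,
                             alpha: float = 0.01, adjust: bool = True,
                             biotype: str = "mRNA") -> list[DifferentialResult]:
    """Severe-vs-mild ANOVA for every feature of the given biotype.

    Significance is assessed on the FDR-adjusted q-value (``adjust=True``,
    the default) or on the raw p-value (``adjust=False``); only features
    passing ``alpha`` are returned, with direction = sign of
    (mean_severe - mean_mild).  A contrast with fewer than 2 samples in
    either group is skipped with a warning and contributes no calls.
    """
    ann = dataset.sample_annotations
    if contrast.clinical_feature not in ann.columns:
        log.warning("%s: clinical feature %r not annotated; contrast skipped",
                    dataset.dataset_id, contrast.clinical_feature)
        return []
    levels = ann[contrast.clinical_feature]
    severe_samples = [s for s in dataset.sample_ids
                      if str(levels.get(s)) in contrast.severe_levels]
    mild_samples = [s for s in dataset.sample_ids
                    if str(levels.get(s)) in contrast.mild_levels]
    if len(severe_samples) < 2 or len(mild_samples) < 2:
        log.warning("%s / %s: group with < 2 samples (severe=%d, mild=%d); contrast skipped",
                    dataset.dataset_id, contrast.label, len(severe_samples), len(mild_samples))
        return []

    features = dataset.features_of_biotype(biotype)
    tested: list[tuple[str, float, float, float]] = []  # fid, F, p, mean-diff
    for fid in features:
        row = dataset.values.loc[fid]
        severe = row[severe_samples].dropna().to_numpy(dtype=float)
        mild = row[mild_samples].dropna().to_numpy(dtype=float)
        if severe.size < 2 or mild.size < 2:
            continue
        if np.ptp(np.concatenate([severe, mild])) == 0:
            log.debug("%s / %s: constant feature %s excluded",
                      dataset.dataset_id, contrast.label, fid)
            continue
        try:
            F, p = anova_two_group(severe, mild)
        except InsufficientDataError:
            continue
        tested.append((fid, F, p, float(severe.mean() - mild.mean())))
    if not tested:
        return []

    pvals = np.array([t[2] for t in tested])
    qvals = fdr_adjust(pvals)
    out = []
    for (fid, F, p, diff), q in zip(tested, qvals):
        crit = q if adjust else p
        if crit <= alpha and diff != 0:
            out.append(DifferentialResult(
                dataset_id=dataset.dataset_id,
                feature_id=fid,
                contrast_label=contrast.label,
                statistic=F,
                p=p,
                q=float(q),
                direction="up_in_severe" if diff > 0 else "down_in_severe",
            ))
    return out


def screen_collection(datasets: list[ExpressionDataset], contrasts: list[ContrastSpec],
                      alpha: float = 0.01, adjust: bool = True) -> list[DifferentialResult]:
    """Run every contrast against every dataset and pool the calls."""
    calls: list[DifferentialResult] = []
    for ds in datasets:
        for contrast in contrasts:
            calls.extend(differential_by_contrast(ds, contrast, alpha=alpha, adjust=adjust))
    return calls


def consensus_genes(calls: list[DifferentialResult], n_datasets_consulted: int,
                    min_fraction: Fraction | float = Fraction(1, 2),
                    ) -> tuple[ConsensusGeneList, ConsensusGeneList]:
    """Cross-dataset vote counting into up- and down-regulated bait lists.

    A dataset supports a (feature, direction) pair if any of its
    contrasts calls it.  support_fraction = supporting datasets /
    ``n_datasets_consulted`` (all consulted datasets, including ones
    where the feature is unmeasured).  Features reaching the threshold
    in both directions are excluded from both lists and logged as
    conflicting.  Comparison against the threshold is exact rational
    arithmetic.
    """
    if n_datasets_consulted < 1:
        raise ValueError("n_datasets_consulted must be >= 1")
    min_fraction = Fraction(min_fraction).limit_denominator(10**9)
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must lie in (0, 1]")

    votes: dict[tuple[str, str], set[str]] = {}
    for call in calls:
        direction = "up" if call.direction == "up_in_severe" else "down"
        votes.setdefault((call.feature_id, direction), set()).add(call.dataset_id)

    passing: dict[str, dict[str, tuple[Fraction, tuple[str, ...]]]] = {}
    for (fid, direction), ds_ids in votes.items():
        frac = Fraction(len(ds_ids), n_datasets_consulted)
        if frac >= min_fraction:
            passing.setdefault(fid, {})[direction] = (frac, tuple(sorted(ds_ids)))

    up = ConsensusGeneList(direction="up", min_fraction=min_fraction)
    down = ConsensusGeneList(direction="down", min_fraction=min_fraction)
    for fid in sorted(passing):
        dirs = passing[fid]
        if len(dirs) == 2:
            log.warning("feature %s meets the consensus threshold in both directions; "
                        "excluded as conflicting", fid)
            continue
        (direction, (frac, ds_ids)), = dirs.items()
        (up if direction == "up" else down).entries.append((fid, frac, ds_ids))
    return up, down
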