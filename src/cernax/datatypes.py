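"""Domain data model.

The central container is :class:`ExpressionDataset`: one study's
feature x sample matrix (assumed log-scale) together with per-sample
clinical annotations and per-feature biotype labels (mRNA / lncRNA /
miRNA).  Severity contrasts (:class:`ContrastSpec`) split samples of a
clinical feature into a "severe" and a "mild" group.  The downstream
stages exchange lightweight records (:class:`CorrelationRecord`,
:class:`DifferentialResult`) and set-valued results
(:class:`ConsensusGeneList`, :class:`FourLists`, :class:`CandidateCall`,
:class:`CeRNAAxis`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError

BIOTYPES = ("mRNA", "lncRNA", "miRNA")


@dataclass
class ExpressionDataset:
    """One study's expression matrix plus clinical and biotype metadata.

    Parameters
    ----------
    dataset_id:
        Short identifier for the study.
    values:
        DataFrame of continuous (log-scale) expression, rows indexed by
        feature_id, columns by sample_id.  NaN marks a missing value.
    sample_annotations:
        DataFrame indexed by sample_id, one column per clinical feature,
        categorical string levels (NaN allowed per-sample).
    feature_biotypes:
        Series mapping feature_id -> biotype in {mRNA, lncRNA, miRNA}.
    """

    dataset_id: str
    values: pd.DataFrame
    sample_annotations: pd.DataFrame
    feature_biotypes: pd.Series

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        idx = self.values.index
        if idx.duplicated().any():
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(
                f"{self.dataset_id}: duplicate feature_id(s): {', '.join(map(str, dups))}"
            )
        missing_ann = [s for s in self.values.columns if s not in self.sample_annotations.index]
        if missing_ann:
            raise ValidationError(
                f"{self.dataset_id}: sample(s) without annotation record: "
                + ", ".join(map(str, missing_ann))
            )
        for clin in self.sample_annotations.columns:
            if self.sample_annotations[clin].dropna().empty:
                raise ValidationError(
                    f"{self.dataset_id}: clinical feature {clin!r} has no non-missing level"
                )
        vals = self.values.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValidationError(f"{self.dataset_id}: non-finite expression value")
        unknown = set(self.feature_biotypes.dropna().unique()) - set(BIOTYPES)
        if unknown:
            raise ValidationError(
                f"{self.dataset_id}: unknown biotype(s): {', '.join(sorted(map(str, unknown)))}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def features_of_biotype(self, biotype: str) -> list[str]:
        """Feature ids measured in this dataset carrying the given biotype."""
        bt = self.feature_biotypes.reindex(self.values.index)
        return list(self.values.index[(bt == biotype).to_numpy()])

    def expression(self, feature_id: str) -> pd.Series:
        if feature_id not in self.values.index:
            raise KeyError(f"{self.dataset_id}: feature {feature_id!r} not measured")
        return self.values.loc[feature_id]


@dataclass(frozen=True)
class ContrastSpec:
    """A binary severity split of one clinical feature's levels."""

    clinical_feature: str
    severe_levels: frozenset
    mild_levels: frozenset
    label: str = ""

    def __post_init__(self):
        severe = frozenset(self.severe_levels)
        mild = frozenset(self.mild_levels)
        object.__setattr__(self, "severe_levels", severe)
        object.__setattr__(self, "mild_levels", mild)
        if not severe or not mild:
            raise ValidationError("ContrastSpec: severe and mild level sets must be non-empty")
        if severe & mild:
            raise ValidationError(
                f"ContrastSpec: overlapping levels {sorted(severe & mild)}"
            )
        if not self.label:
            object.__setattr__(
                self,
                "label",
                f"{self.clinical_feature}:{'|'.join(sorted(map(str, severe)))}"
                f"_vs_{'|'.join(sorted(map(str, mild)))}",
            )


@dataclass(frozen=True)
class CorrelationRecord:
    """Pearson correlation between two features within one dataset."""

    dataset_id: str
    feature_a: str
    feature_b: str
    r: float
    p: float
    n: int

    def __post_init__(self):
        if abs(self.r) > 1 + 1e-12:
            raise ValidationError(f"|r| > 1: {self.r}")
        if not (0.0 <= self.p <= 1.0):
            raise ValidationError(f"p outside [0, 1]: {self.p}")
        if self.n < 3:
            raise ValidationError(f"correlation record with n < 3 (n={self.n})")

    @property
    def sign(self) -> str:
        return "positive" if self.r > 0 else "negative"


@dataclass(frozen=True)
class DifferentialResult:
    """One feature's severe-vs-mild ANOVA call within one dataset."""

    dataset_id: str
    feature_id: str
    contrast_label: str
    statistic: float  # one-way ANOVA F; equals t^2 for two groups
    p: float
    q: float
    direction: str  # up_in_severe | down_in_severe

    def __post_init__(self):
        if self.statistic < 0:
            raise ValidationError(f"negative F statistic: {self.statistic}")
        if self.direction not in ("up_in_severe", "down_in_severe"):
            raise ValidationError(f"bad direction: {self.direction}")


@dataclass
class ConsensusGeneList:
    """Direction-labelled genes with cross-dataset support ("bait genes")."""

    direction: str  # up | down
    entries: list[tuple[str, Fraction, tuple[str, ...]]] = field(default_factory=list)
    min_fraction: Fraction = Fraction(1, 2)

    @property
    def feature_ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    def support(self, feature_id: str) -> Optional[Fraction]:
        for fid, frac, _ in self.entries:
            if fid == feature_id:
                return frac
        return None


@dataclass(frozen=True)
class SignedConsensusEntry:
    """A retained (lncRNA, bait, sign) association with its dataset support."""

    lncrna_id: str
    bait_id: str
    sign: str  # positive | negative
    support_fraction: Fraction
    supporting_dataset_ids: tuple[str, ...]


@dataclass
class FourLists:
    """The four signed lncRNA-bait consensus lists.

    A: positive with down-baits, B: positive with up-baits,
    C: negative with down-baits, D: negative with up-baits.
    Tumor-suppressor candidates arise from A∩D, oncogene candidates from B∩C.
    """

    list_A: set[str] = field(default_factory=set)
    list_B: set[str] = field(default_factory=set)
    list_C: set[str] = field(default_factory=set)
    list_D: set[str] = field(default_factory=set)
    entries: list[SignedConsensusEntry] = field(default_factory=list)

    def as_dict(self) -> dict[str, set[str]]:
        return {"A": self.list_A, "B": self.list_B, "C": self.list_C, "D": self.list_D}


@dataclass(frozen=True)
class CandidateCall:
    """A candidate lncRNA's derived role from the four-list algebra."""

    lncrna_id: str
    role: str  # tumor_suppressor | oncogene | conflict
    source_lists: frozenset

    def __post_init__(self):
        if self.role not in ("tumor_suppressor", "oncogene", "conflict"):
            raise ValidationError(f"bad role: {self.role}")


@dataclass
class InteractionTable:
    """External interaction evidence consumed as a table.

    kind ``lncrna_mirna_binding``: (lncrna_id, mirna_id) binding predictions;
    ``mirna_mrna_validated``: experimentally validated miRNA targets;
    ``mirna_cancer``: miRNA-disease dysregulation annotations, with the
    dysregulation direction in ``annotation``.
    """

    kind: str
    rows: pd.DataFrame  # columns: id_a, id_b, source_db, annotation (optional)

    KINDS = ("lncrna_mirna_binding", "mirna_mrna_validated", "mirna_cancer")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValidationError(f"unknown interaction-table kind: {self.kind}")
        df = self.rows
        if "annotation" not in df.columns:
            df = df.assign(annotation="")
        for col in ("id_a", "id_b", "source_db"):
            if col not in df.columns:
                raise ValidationError(f"interaction table missing column {col!r}")
            if df[col].astype(str).str.strip().eq("").any():
                raise ValidationError(f"empty identifier in column {col!r}")
        dup = df.duplicated(subset=["id_a", "id_b", "source_db"])
        if dup.any():
            raise ValidationError("duplicate (id_a, id_b, source_db) interaction rows")
        self.rows = df.reset_index(drop=True)


@dataclass
class CeRNAAxis:
    """One lncRNA-miRNA-mRNA triplet with its three correlation records.

    The sponge model expects the lncRNA and mRNA to be positively
    correlated while the miRNA is negatively correlated with both.
    """

    lncrna_id: str
    mirna_id: str
    mrna_id: str
    r_lnc_mirna: Optional[float]
    p_lnc_mirna: Optional[float]
    r_mirna_mrna: Optional[float]
    p_mirna_mrna: Optional[float]
    r_lnc_mrna: float
    p_lnc_mrna: float
    evidence: dict = field(default_factory=dict)  # binding_predicted, correlation_selected, target_validated, oncomir
    mirna_cancer_direction: Optional[str] = None
    strict_pass: bool = False


@dataclass(frozen=True)
class CtRecord:
    """One qPCR cycle-threshold measurement."""

    sample_id: str
    group_label: str
    target_id: str
    ct: float
    replicate_index: int = 0
    pair_id: Optional[str] = None

    def __post_init__(self):
        if not np.isfinite(self.ct) or self.ct <= 0:
            raise ValidationError(f"Ct must be finite and > 0, got {self.ct}")
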