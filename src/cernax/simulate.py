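"""Synthetic multi-dataset cohorts with planted, serialized ground truth.

The generator emulates a heterogeneous collection of expression studies
(log-scale values, per-dataset baselines and effect jitter, features
missing from some platforms) with the statistical structure the screens
assume:

* bait mRNAs carry a severe-vs-mild group mean shift (in within-group
  SD units) with the configured sign;
* one sponge lncRNA, its axis mRNAs (positive) and axis miRNAs
  (negative) load on a shared per-sample latent factor, scaled by
  ``sponge_coupling`` — the closed-form correlation between two such
  features is ±λ²/(λ²+σ²);
* bait genes load on the same factor (down-baits +, up-baits −), and
  the whole ceRNA module is itself severity-associated (sponge and axis
  mRNAs down in severe samples, axis miRNAs up), so the module's mutual
  coupling runs through both the severity split and the factor — the
  premise under which the correlation screen discovers it;
* decoy features are independent noise, and the interaction tables mix
  true rows with decoy rows.

All randomness derives from a single master seed via named substreams,
so adding a stage never perturbs another stage's draws, and identical
seeds give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import ContrastSpec, CtRecord, ExpressionDataset, InteractionTable
from .errors import ValidationError
from .io import (write_ct_records, write_expression_dataset, write_interaction_table)

CLINICAL_FEATURE = "severity"
SEVERE_LEVEL = "severe"
MILD_LEVEL = "mild"
DISEASE = "CRC"

DEFAULT_CONTRAST = ContrastSpec(
    clinical_feature=CLINICAL_FEATURE,
    severe_levels=frozenset({SEVERE_LEVEL}),
    mild_levels=frozenset({MILD_LEVEL}),
    label="severity:severe_vs_mild",
)


def substream(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Deterministic named RNG substream: (master seed, crc32(stage), index)."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(stage.encode()), index]))


@dataclass
class GeneratorConfig:
    """Cohort-generation parameters (defaults are the study conditions)."""

    n_datasets: int = 8
    samples_per_group: int = 60
    n_bait_up: int = 5
    n_bait_down: int = 19
    bait_effect_size: float = 1.5  # group mean shift, within-group SD units
    n_decoy_mrna: int = 40
    n_decoy_lncrna: int = 10
    n_decoy_mirna: int = 10
    sponge_coupling: float = 0.8  # latent-factor loading lambda
    n_axis_mirnas: int = 4
    n_axis_mrnas: int = 6
    n_no_target_mirnas: int = 2  # binding-predicted miRNAs without target rows
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    effect_jitter: float = 0.2  # per-dataset relative jitter on the bait effect
    missing_feature_fraction: float = 0.1
    interaction_false_positive_rows: int = 10
    seed: int = 7

    def validate(self) -> None:
        counts = (self.n_datasets, self.samples_per_group, self.n_bait_up,
                  self.n_bait_down, self.n_decoy_mrna, self.n_decoy_lncrna,
                  self.n_decoy_mirna, self.n_axis_mirnas, self.n_axis_mrnas,
                  self.n_no_target_mirnas, self.interaction_false_positive_rows)
        if any(c < 0 for c in counts):
            raise ValidationError("all counts must be >= 0")
        if self.n_datasets < 1 or self.samples_per_group < 2:
            raise ValidationError("need >= 1 dataset and >= 2 samples per group")
        if not (0.0 <= self.sponge_coupling <= 1.0):
            raise ValidationError("sponge_coupling must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if not (0.0 <= self.missing_feature_fraction < 1.0):
            raise ValidationError("missing_feature_fraction must lie in [0, 1)")


@dataclass
class PlantedTruth:
    """Ground-truth ledger written alongside every generated cohort."""

    bait_up_ids: list[str]
    bait_down_ids: list[str]
    sponge_lncrna_id: str
    axis_triplets: list[tuple[str, str]]  # (mirna_id, mrna_id)
    oncomir_ids: list[str]
    no_target_mirna_ids: list[str]
    decoy_mrna_ids: list[str]
    decoy_lncrna_ids: list[str]
    decoy_mirna_ids: list[str]
    decoy_interaction_rows: dict[str, list[list[str]]] = field(default_factory=dict)
    feature_presence: dict[str, list[str]] = field(default_factory=dict)  # dataset -> features
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["axis_triplets"] = [list(t) for t in self.axis_triplets]
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        d["axis_triplets"] = [tuple(t) for t in d["axis_triplets"]]
        return cls(**d)


def _feature_plan(config: GeneratorConfig) -> tuple[dict[str, str], dict[str, float], dict[str, int], PlantedTruth]:
    """Feature ids with biotypes, latent loadings, and bait shift signs."""
    lam = config.sponge_coupling
    bait_up = [f"BGU{i:03d}" for i in range(1, config.n_bait_up + 1)]
    bait_down = [f"BGD{i:03d}" for i in range(1, config.n_bait_down + 1)]
    sponge = "LNC-SPONGE1"
    axis_mirnas = [f"miR-AX{i:02d}" for i in range(1, config.n_axis_mirnas + 1)]
    axis_mrnas = [f"AXM{i:03d}" for i in range(1, config.n_axis_mrnas + 1)]
    nt_mirnas = [f"miR-NT{i:02d}" for i in range(1, config.n_no_target_mirnas + 1)]
    decoy_mrna = [f"DCM{i:03d}" for i in range(1, config.n_decoy_mrna + 1)]
    decoy_lnc = [f"DCL{i:03d}" for i in range(1, config.n_decoy_lncrna + 1)]
    decoy_mir = [f"miR-DC{i:02d}" for i in range(1, config.n_decoy_mirna + 1)]

    biotypes: dict[str, str] = {}
    for f in bait_up + bait_down + axis_mrnas + decoy_mrna:
        biotypes[f] = "mRNA"
    biotypes[sponge] = "lncRNA"
    for f in decoy_lnc:
        biotypes[f] = "lncRNA"
    for f in axis_mirnas + nt_mirnas + decoy_mir:
        biotypes[f] = "miRNA"

    loadings: dict[str, float] = {f: 0.0 for f in biotypes}
    loadings[sponge] = lam
    for f in axis_mrnas + bait_down:
        loadings[f] = lam
    for f in axis_mirnas + bait_up:
        loadings[f] = -lam

    shift_signs: dict[str, int] = {f: 0 for f in biotypes}
    for f in bait_up:
        shift_signs[f] = +1
    for f in bait_down:
        shift_signs[f] = -1
    # the whole ceRNA module is severity-associated, the premise under
    # which the correlation screen can discover it: the sponge lncRNA
    # and its target mRNAs are down in severe samples, its miRNAs up,
    # so their mutual coupling runs through both the shared severity
    # split and the latent factor
    shift_signs[sponge] = -1
    for f in axis_mrnas:
        shift_signs[f] = -1
    for f in axis_mirnas:
        shift_signs[f] = +1

    truth = PlantedTruth(
        bait_up_ids=bait_up, bait_down_ids=bait_down, sponge_lncrna_id=sponge,
        axis_triplets=[(m, t) for m in axis_mirnas for t in axis_mrnas],
        oncomir_ids=list(axis_mirnas),
        no_target_mirna_ids=nt_mirnas,
        decoy_mrna_ids=decoy_mrna, decoy_lncrna_ids=decoy_lnc, decoy_mirna_ids=decoy_mir,
        seed=config.seed,
    )
    return biotypes, loadings, shift_signs, truth


def generate_cohort(config: GeneratorConfig) -> tuple[list[ExpressionDataset], PlantedTruth]:
    """Generate the dataset collection and its ground-truth ledger.

    Expression model per dataset d, feature f, sample j (log scale):

        x = b_{d,f} + s_f * e_d * sd_within * severe_j + load_f * g_j + sigma * eps

    with per-dataset feature baselines b, bait shift sign s_f, jittered
    effect e_d ≈ bait_effect_size, shared latent factor g_j ~ N(0,1)
    and noise eps ~ N(0,1).  Every planted (non-decoy) feature is always
    measured in the first dataset — the reference dataset used for the
    axis-stage correlations — and every feature is measured in at least
    one dataset; otherwise each feature is dropped from each dataset
    with probability ``missing_feature_fraction``.
    """
    config.validate()
    biotypes, loadings, shift_signs, truth = _feature_plan(config)
    features = list(biotypes)
    planted = set(truth.bait_up_ids + truth.bait_down_ids + [truth.sponge_lncrna_id]
                  + [m for m, _ in truth.axis_triplets] + [t for _, t in truth.axis_triplets]
                  + truth.no_target_mirna_ids)
    sd_within = float(np.sqrt(config.sponge_coupling**2 + config.noise_sd**2))

    # presence plan: one draw per (feature, dataset), independent of matrix draws
    rng_miss = substream(config.seed, "missing")
    presence = {}
    for f in features:
        drop = rng_miss.random(config.n_datasets) < config.missing_feature_fraction
        if f in planted:
            drop[0] = False
        if drop.all():
            drop[int(rng_miss.integers(config.n_datasets))] = False
        presence[f] = ~drop

    n = 2 * config.samples_per_group
    datasets = []
    for d in range(config.n_datasets):
        rng = substream(config.seed, "dataset", d)
        ds_id = f"SYN{d:02d}"
        sample_ids = [f"{ds_id}_S{j:03d}" for j in range(n)]
        severe = np.zeros(n)
        severe[: config.samples_per_group] = 1.0  # first half severe
        effect = config.bait_effect_size * (
            1.0 + config.effect_jitter * (2.0 * rng.random() - 1.0)
        )
        factor = rng.standard_normal(n)
        measured = [f for f in features if presence[f][d]]
        rows = np.empty((len(measured), n))
        for i, f in enumerate(measured):
            baseline = config.baseline_mean + config.baseline_sd * rng.standard_normal()
            rows[i] = (
                baseline
                + shift_signs[f] * effect * sd_within * severe
                + loadings[f] * factor
                + config.noise_sd * rng.standard_normal(n)
            )
        values = pd.DataFrame(rows, index=measured, columns=sample_ids)
        annotations = pd.DataFrame(
            {CLINICAL_FEATURE: np.where(severe == 1.0, SEVERE_LEVEL, MILD_LEVEL)},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        datasets.append(ExpressionDataset(
            dataset_id=ds_id, values=values, sample_annotations=annotations,
            feature_biotypes=pd.Series({f: biotypes[f] for f in measured}),
        ))
        truth.feature_presence[ds_id] = measured
    return datasets, truth


def generate_interaction_tables(truth: PlantedTruth, config: GeneratorConfig,
                                ) -> dict[str, InteractionTable]:
    """Binding, validated-target and disease tables for the planted truth.

    The binding table links the sponge lncRNA to every axis miRNA and to
    the no-target miRNAs (exercising the empty-target exclusion rule);
    the target table holds every planted (miRNA, mRNA) pair; the disease
    table marks the axis miRNAs as dysregulated oncomiRs.  Each table
    additionally receives ``interaction_false_positive_rows`` decoy rows
    drawn from the decoy feature pools.
    """
    rng = substream(config.seed, "interactions")
    k = config.interaction_false_positive_rows
    decoys: dict[str, list[list[str]]] = {"binding": [], "targets": [], "cancer": []}

    binding_rows = [
        {"id_a": truth.sponge_lncrna_id, "id_b": m, "source_db": "simbind", "annotation": ""}
        for m in sorted({m for m, _ in truth.axis_triplets}) + truth.no_target_mirna_ids
    ]
    pool_lnc = truth.decoy_lncrna_ids + [truth.sponge_lncrna_id]
    for _ in range(k):
        row = [str(rng.choice(pool_lnc)), str(rng.choice(truth.decoy_mirna_ids)), "simbind"]
        decoys["binding"].append(row)
        binding_rows.append({"id_a": row[0], "id_b": row[1], "source_db": row[2], "annotation": ""})

    target_rows = [
        {"id_a": m, "id_b": t, "source_db": "simtargets", "annotation": ""}
        for m, t in truth.axis_triplets
    ]
    for _ in range(k):
        row = [str(rng.choice(truth.decoy_mirna_ids)), str(rng.choice(truth.decoy_mrna_ids)),
               "simtargets"]
        decoys["targets"].append(row)
        target_rows.append({"id_a": row[0], "id_b": row[1], "source_db": row[2], "annotation": ""})

    cancer_rows = [
        {"id_a": m, "id_b": DISEASE, "source_db": "simcancer", "annotation": "Downregulated"}
        for m in truth.oncomir_ids
    ]
    for _ in range(k):
        row = [str(rng.choice(truth.decoy_mirna_ids)), DISEASE, "simcancer"]
        decoys["cancer"].append(row)
        cancer_rows.append({"id_a": row[0], "id_b": row[1], "source_db": row[2],
                            "annotation": "Upregulated"})
    truth.decoy_interaction_rows = decoys

    def dedup(rows):
        return (pd.DataFrame(rows)
                .drop_duplicates(subset=["id_a", "id_b", "source_db"])
                .reset_index(drop=True))

    return {
        "lncrna_mirna_binding": InteractionTable("lncrna_mirna_binding", dedup(binding_rows)),
        "mirna_mrna_validated": InteractionTable("mirna_mrna_validated", dedup(target_rows)),
        "mirna_cancer": InteractionTable("mirna_cancer", dedup(cancer_rows)),
    }


def generate_qpcr_plate(fold_changes: dict[str, float], n_per_group: int = 6,
                        ct_noise_sd: float = 0.2, seed: int = 7,
                        reference_id: str = "PPIA", reference_ct: float = 20.0,
                        control_dct: float = 5.0, paired: bool = False,
                        ) -> list[CtRecord]:
    """Simulate a two-group qPCR plate implying the given fold changes.

    The case-group ΔCt for a target with true fold change FC is
    control ΔCt − log2(FC) (true ΔΔCt = −log2(FC)); Gaussian noise of
    ``ct_noise_sd`` cycles perturbs every Ct independently.
    """
    for target, fc in fold_changes.items():
        if not (fc > 0):
            raise ValidationError(f"fold change for {target!r} must be > 0, got {fc}")
    rng = substream(seed, "qpcr")
    records: list[CtRecord] = []
    groups = [("case", 1), ("control", 0)]
    for g_idx, (group, is_case) in enumerate(groups):
        for j in range(n_per_group):
            sample = f"{group}{j:02d}"
            pair = f"P{j:02d}" if paired else None
            ref_ct = reference_ct + ct_noise_sd * rng.standard_normal()
            records.append(CtRecord(sample_id=sample, group_label=group,
                                    target_id=reference_id, ct=float(ref_ct),
                                    replicate_index=0, pair_id=pair))
            for target in sorted(fold_changes):
                dct = control_dct - is_case * np.log2(fold_changes[target])
                ct = ref_ct + dct + ct_noise_sd * rng.standard_normal()
                records.append(CtRecord(sample_id=sample, group_label=group,
                                        target_id=target, ct=float(ct),
                                        replicate_index=0, pair_id=pair))
    return records


def write_cohort(out_dir, config: GeneratorConfig,
                 qpcr_fold_changes: dict[str, float] | None = None) -> PlantedTruth:
    """Generate and write the complete input layout.

    Produces per-dataset TSV triples, ``manifest.yaml``, ``contrasts.yaml``,
    the three interaction TSVs, ``qpcr.csv`` and ``truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    datasets, truth = generate_cohort(config)
    manifest = {"datasets": []}
    for ds in datasets:
        names = {k: f"{ds.dataset_id}_{k}.tsv" for k in ("matrix", "annotations", "biotypes")}
        write_expression_dataset(ds, out / names["matrix"], out / names["annotations"],
                                 out / names["biotypes"])
        manifest["datasets"].append({"dataset_id": ds.dataset_id, **names})
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    with open(out / "contrasts.yaml", "w") as fh:
        yaml.safe_dump({"contrasts": [{
            "clinical_feature": CLINICAL_FEATURE,
            "severe_levels": [SEVERE_LEVEL],
            "mild_levels": [MILD_LEVEL],
            "label": DEFAULT_CONTRAST.label,
        }]}, fh, sort_keys=False)

    tables = generate_interaction_tables(truth, config)
    filenames = {
        "lncrna_mirna_binding": "lncrna_mirna_binding.tsv",
        "mirna_mrna_validated": "mirna_mrna_targets.tsv",
        "mirna_cancer": "mirna_cancer.tsv",
    }
    for kind, table in tables.items():
        write_interaction_table(table, out / filenames[kind])

    if qpcr_fold_changes is None:
        qpcr_fold_changes = {truth.sponge_lncrna_id: 0.5}
    records = generate_qpcr_plate(qpcr_fold_changes, seed=config.seed)
    write_ct_records(records, out / "qpcr.csv")

    with open(out / "truth.json", "w") as fh:
        fh.write(truth.to_json() + "\n")
    return truth
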