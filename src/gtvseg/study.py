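"""End-to-end transfer-learning study pipeline.

Runs the full design: generate a source-domain training cohort and a
source-domain multi-observer test cohort, plus a shifted target-domain
retraining cohort and target-domain test cohort; pretrain the generic model
(Model 1) on the source cohort; evaluate it on both test sets; fine-tune it
on the small target retraining cohort (Model 2); re-evaluate; and build the
statistical report (per-method score summaries with ANOVA/Tukey, the
consensus-level recall table, and a per-subject listing ordered by tumour
volume).  Every stage is seeded from one master seed with disjoint
sub-streams, so re-running a manifest reproduces the report byte for byte.

The default ``desk_scale_manifest`` is sized to run on one CPU in minutes:
64 x 64 slices, a depth-3 / base-8 network, cohorts of 40 (source train),
8 (source interobserver, 5 observers each), 12 (target retrain) and 16
(target test).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import FEET_FIRST, write_volume
from .metrics import (
    consensus_recall,
    consensus_regions,
    metric_record,
    model_vs_observers,
    pairwise_observer_dsc,
)
from .nn.unet import NetworkConfig
from .phantom import DomainSpec, ObserverSimConfig, Subject, attach_observers, generate_cohort
from .stats import build_report, write_report
from .training import (
    Checkpoint,
    TrainConfig,
    fine_tune,
    predict_volume,
    preprocess_subject,
    split_subjects,
    train,
)

MODEL1 = "model1"
MODEL2 = "model2"


def source_domain_spec(**overrides) -> DomainSpec:
    """The generic ('source hospital') acquisition domain."""
    spec = DomainSpec(
        name="source",
        image_size=64,
        n_slices_range=(8, 12),
        pixel_spacing_mm=1.0,
        slice_thickness_mm=3.0,
        background_hu=40.0,
        lung_hu=-800.0,
        tumour_hu_range=(10.0, 80.0),
        noise_sd_hu=10.0,
        intensity_offset_hu=0.0,
        tumour_radius_range_mm=(3.5, 6.5),
        tumour_irregularity=0.3,
    )
    return replace(spec, **overrides)


def target_domain_spec(**overrides) -> DomainSpec:
    """The local ('target hospital') domain: noisier scans with a global
    calibration shift, thicker slices, larger (later-stage) tumours, and
    feet-first patient orientation."""
    spec = DomainSpec(
        name="target",
        image_size=64,
        n_slices_range=(6, 10),
        pixel_spacing_mm=1.0,
        slice_thickness_mm=5.0,
        background_hu=40.0,
        lung_hu=-800.0,
        tumour_hu_range=(-40.0, 30.0),
        noise_sd_hu=30.0,
        intensity_offset_hu=100.0,
        tumour_radius_range_mm=(5.0, 8.0),
        tumour_irregularity=0.4,
        orientation=FEET_FIRST,
    )
    return replace(spec, **overrides)


@dataclass
class StudyManifest:
    """Cohort specs, seeds, network and training configuration for one study."""

    seed: int = 0
    n_source_train: int = 40
    n_interobserver: int = 8
    n_retrain: int = 12
    n_target_test: int = 16
    source_spec: DomainSpec = field(default_factory=source_domain_spec)
    target_spec: DomainSpec = field(default_factory=target_domain_spec)
    observer_cfg: ObserverSimConfig = field(default_factory=ObserverSimConfig)
    network: NetworkConfig = field(default_factory=lambda: NetworkConfig(input_size=64, depth=3, base_channels=8))
    pretrain: TrainConfig = field(default_factory=lambda: TrainConfig(
        epochs_max=30, batch_size=6, learning_rate=1e-3, val_fraction=0.10, max_empty_ratio=1.0))
    fine_tune: TrainConfig = field(default_factory=lambda: TrainConfig(
        epochs_max=25, batch_size=6, learning_rate=2e-4, val_fraction=0.20, early_stop_patience=10,
        max_empty_ratio=1.0, freeze_bn_stats=True))
    threshold: float = 0.5

    def validate(self) -> None:
        self.source_spec.validate()
        self.target_spec.validate()
        self.observer_cfg.validate()
        self.network.validate()
        self.pretrain.validate()
        self.fine_tune.validate()
        if self.network.input_size != self.source_spec.image_size:
            raise ValueError("network input_size must match source image_size")
        if self.network.input_size != self.target_spec.image_size:
            raise ValueError("network input_size must match target image_size")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, sort_keys=True))


def desk_scale_manifest(seed: int = 0, **overrides) -> StudyManifest:
    """The default one-CPU study manifest."""
    m = StudyManifest(seed=seed)
    return replace(m, **overrides) if overrides else m


def _derive_seeds(master: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n) % (2 ** 31)]


def _predict_subject(ckpt: Checkpoint, subject: Subject, threshold: float) -> np.ndarray:
    sub = preprocess_subject(subject)
    return predict_volume(ckpt, sub.volume, threshold=threshold)


def run_study(manifest: StudyManifest, outdir=None) -> dict:
    """Execute the full study; returns (and optionally persists) the report."""
    manifest.validate()
    (s_train, s_inter, s_retrain, s_test, s_obs, s_fit, s_ft, s_net) = _derive_seeds(manifest.seed, 8)

    # --- cohorts (disjoint seed streams) --------------------------------
    source_train = generate_cohort(manifest.source_spec, manifest.n_source_train, s_train)
    interobserver = generate_cohort(
        replace(manifest.source_spec, name="interobserver"), manifest.n_interobserver, s_inter)
    retrain = generate_cohort(
        replace(manifest.target_spec, name="retrain"), manifest.n_retrain, s_retrain)
    target_test = generate_cohort(
        replace(manifest.target_spec, name="target_test"), manifest.n_target_test, s_test)
    obs_cfg = replace(manifest.observer_cfg, seed=s_obs)
    interobserver = [attach_observers(sub, obs_cfg) for sub in interobserver]

    train_ids = sorted(s.id for s in source_train) + sorted(s.id for s in retrain)
    quarantined = {s.id for s in interobserver} | {s.id for s in target_test}
    assert not quarantined.intersection(train_ids), "test-set quarantine violated"

    # --- Model 1: pretrain on the source domain -------------------------
    pre_cfg = replace(manifest.pretrain, seed=s_fit, threshold=manifest.threshold)
    net_cfg = replace(manifest.network, seed=s_net)
    ckpt1, hist1 = train(net_cfg, source_train, pre_cfg)

    # --- Model 2: fine-tune on the target retraining cohort -------------
    _, source_val = split_subjects(source_train, pre_cfg.val_fraction, pre_cfg.seed)
    ft_cfg = replace(manifest.fine_tune, seed=s_ft, threshold=manifest.threshold)
    ckpt2, hist2 = fine_tune(ckpt1, retrain, ft_cfg, source_val_cohort=source_val)

    # --- evaluation ------------------------------------------------------
    records_rows: list[dict] = []
    consensus_rows: list[dict] = []

    def add(rec, test_set):
        row = dataclasses.asdict(rec)
        row["test_set"] = test_set
        records_rows.append(row)

    # manual arm: pairwise observer agreement on the interobserver set
    for sub in interobserver:
        for rec in pairwise_observer_dsc(sub.observer_masks, sub.id):
            add(rec, "interobserver")

    preds: dict[str, dict[str, np.ndarray]] = {MODEL1: {}, MODEL2: {}}
    for label, ckpt in ((MODEL1, ckpt1), (MODEL2, ckpt2)):
        for sub in target_test:
            pred = _predict_subject(ckpt, sub, manifest.threshold)
            sub_c = sub.canonical()
            add(metric_record(pred, sub_c.truth_mask, sub.id, label, "RO"), "target_test")
        for sub in interobserver:
            pred = _predict_subject(ckpt, sub, manifest.threshold)
            preds[label][sub.id] = pred
            for rec in model_vs_observers(pred, sub.observer_masks, sub.id, predictor=label):
                add(rec, "interobserver")
            cr = consensus_regions(sub.observer_masks)
            for level, rc in consensus_recall(pred, cr).items():
                consensus_rows.append(
                    {"predictor": label, "subject_id": sub.id, "level": level, "recall": rc})

    records = pd.DataFrame(records_rows)
    consensus = pd.DataFrame(consensus_rows)

    report = build_report(records, consensus, manifest_info=manifest.to_dict())
    report["history"] = {MODEL1: hist1.to_dict(), MODEL2: hist2.to_dict()}
    report["train_subject_ids"] = train_ids
    report["headline"] = _headline(records, consensus)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_report(report, outdir)
        ckpt1.save(outdir / "model1.npz")
        ckpt2.save(outdir / "model2.npz")
        records.to_csv(outdir / "records.csv", index=False)
        consensus.to_csv(outdir / "consensus_records.csv", index=False)
    return report


def _headline(records: pd.DataFrame, consensus: pd.DataFrame) -> dict:
    """The study's principal numbers, on the scale the tables report them."""
    out: dict = {}
    tgt = records[records["test_set"] == "target_test"]
    for label in (MODEL1, MODEL2):
        sub = tgt[tgt["predictor"] == label]
        out[f"target_median_dsc_{label}"] = float(sub["dsc"].median())
        out[f"target_median_recall_{label}"] = float(sub["recall"].median())
        prec = sub["precision"].dropna()
        out[f"target_median_precision_{label}"] = float(prec.median()) if len(prec) else float("nan")
    out["target_dsc_gain"] = out[f"target_median_dsc_{MODEL2}"] - out[f"target_median_dsc_{MODEL1}"]

    inter = records[records["test_set"] == "interobserver"]
    manual = inter[inter["predictor"].str.startswith("RO")]
    out["interobserver_manual_median_dsc"] = float(manual["dsc"].median())
    for label in (MODEL1, MODEL2):
        sub = inter[inter["predictor"] == label]
        per_subject = sub.groupby("subject_id")["dsc"].median()
        out[f"interobserver_median_dsc_{label}"] = float(per_subject.median())
    out["interobserver_dsc_shift"] = (
        out[f"interobserver_median_dsc_{MODEL2}"] - out[f"interobserver_median_dsc_{MODEL1}"])

    if len(consensus):
        for label in (MODEL1, MODEL2):
            sub = consensus[consensus["predictor"] == label]
            for level, df_l in sub.groupby("level"):
                vals = df_l["recall"].dropna()
                if len(vals):
                    out[f"consensus_recall_level{int(level)}_{label}"] = float(vals.median())
    return out


def save_cohort(subjects: list[Subject], outdir) -> str:
    """Persist a cohort as NIfTI image/mask pairs plus a TSV manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sub in subjects:
        img_path = outdir / f"{sub.id}_image.nii.gz"
        mask_path = outdir / f"{sub.id}_mask.nii.gz"
        write_volume(sub.volume, img_path)
        write_volume(replace_mask_volume(sub), mask_path, mask=True)
        row = {"id": sub.id, "domain": sub.domain, "image": img_path.name, "mask": mask_path.name,
               "orientation": sub.volume.orientation}
        for i, m in enumerate(sub.observer_masks):
            obs_path = outdir / f"{sub.id}_observer{i + 1}.nii.gz"
            write_volume(dataclasses.replace(sub.volume, data=m, intensity_state="HU"), obs_path, mask=True)
            row[f"observer{i + 1}"] = obs_path.name
        rows.append(row)
    manifest_path = outdir / "cohort_manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)
    return str(manifest_path)


def replace_mask_volume(sub: Subject):
    """The truth mask wrapped as a Volume on the subject's grid."""
    return dataclasses.replace(sub.volume, data=sub.truth_mask, intensity_state="HU")
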