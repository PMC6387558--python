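"""End-to-end pipeline driver.

Runs phantom generation (or cohort loading), preprocessing, per-subject
t-maps with FWE thresholding and cluster extent filtering, hallmark
extraction, rater classification with supermajority voting, diagnostic
performance, and metabolic subtyping — writing TSV reports and an audit
manifest (configuration hash + seed) so re-runs are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagstats, io, subtype
from .hallmarks import compute_hallmarks
from .patterns import RaterRule, classify_subject, mean_pairwise_kappa, \
    supermajority_vote
from .phantom import CohortSpec, make_atlas, make_cohort
from .preprocess import PreprocConfig, preprocess_cohort
from .tmap import DEFAULT_EXTENT_MM3, extract_clusters, fit_subject_tmap, \
    fwe_threshold

log = logging.getLogger("dlbpet")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Serializable configuration for a full pipeline run."""

    grid_shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size_mm: float = 4.0
    fwhm_mm: tuple[float, float, float] = (8.0, 8.0, 8.0)
    scale_target: float = 1.0
    mask_fraction: float = 0.8
    alpha: float = 0.05
    extent_mm3: float = DEFAULT_EXTENT_MM3
    connectivity: int = 18
    use_age_covariate: bool = True
    quorum: int = 3
    rater_min_fractions: tuple[float, ...] = (0.01, 0.02, 0.02, 0.05)
    rater_taus: tuple[float, ...] = (0.4, 0.5, 0.5, 0.6)
    subtype_k: int = 2
    pca_variance_target: float = 0.80
    seed: int = 0
    n_controls: int = 112
    n_patients: dict = field(
        default_factory=lambda: {"DLB": 72, "ADD": 55, "PCA": 5, "PD": 36})
    write_volumes: bool = False

    def raters(self) -> tuple[RaterRule, ...]:
        return tuple(RaterRule(f, t, f"r{i + 1}") for i, (f, t) in
                     enumerate(zip(self.rater_min_fractions, self.rater_taus,
                                   strict=True)))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("grid_shape", "fwhm_mm", "rater_min_fractions",
                    "rater_taus"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    hallmark_table: pd.DataFrame
    label_table: pd.DataFrame
    performance: dict
    kappa: float
    subtype_labels: np.ndarray | None
    feature_matrix: subtype.FeatureMatrix | None
    manifest: dict


def _stage(name, subject, t0, **info):
    log.info("stage=%s subject=%s wall=%.2fs %s", name, subject,
             time.perf_counter() - t0,
             " ".join(f"{k}={v}" for k, v in info.items()))


def run_pipeline(config: PipelineConfig, out_dir=None,
                 cohort=None) -> PipelineResult:
    """Run the full analysis.

    ``cohort`` may be a pre-built ``(controls, patients, meta)`` triple;
    otherwise a synthetic cohort is generated from the config.  When
    ``out_dir`` is given, TSV reports (and volumes, if requested) are
    written there together with a manifest.
    """
    cfg = config
    atlas = make_atlas(cfg.grid_shape, cfg.voxel_size_mm)
    if cohort is None:
        spec = CohortSpec(n_controls=cfg.n_controls,
                          n_patients=dict(cfg.n_patients), seed=cfg.seed)
        t0 = time.perf_counter()
        controls, patients, meta = make_cohort(spec, atlas)
        _stage("phantom", "cohort", t0, controls=len(controls),
               patients=len(patients))
    else:
        controls, patients, meta = cohort

    t0 = time.perf_counter()
    pre = PreprocConfig(fwhm_mm=cfg.fwhm_mm, scale_target=cfg.scale_target,
                        mask_fraction=cfg.mask_fraction)
    controls, patients, mask = preprocess_cohort(controls, patients, pre)
    _stage("preprocess", "cohort", t0, mask_voxels=int(mask.sum()))

    raters = cfg.raters()
    hall_rows, label_rows, tmaps, rater_matrix = [], [], [], []
    for scan in patients:
        t0 = time.perf_counter()
        tm = fit_subject_tmap(scan, controls, mask,
                              use_age=cfg.use_age_covariate)
        thr = fwe_threshold(tm, cfg.alpha)
        clusters = extract_clusters(tm, thr, connectivity=cfg.connectivity,
                                    extent_mm3=cfg.extent_mm3)
        profile = compute_hallmarks(scan, clusters, atlas)
        labels = [str(classify_subject(profile, r).value) for r in raters]
        vote = supermajority_vote(labels, cfg.quorum)
        tmaps.append(tm)
        rater_matrix.append(labels)
        hall_rows.append({
            "subject_id": scan.subject_id,
            "occipital": profile.occipital_involved,
            "dlpfc": profile.dlpfc_involved,
            "cis": profile.cis_value,
            "asymmetry_index": profile.asymmetry_index,
            "symmetric": profile.symmetric,
            **{f"frac_{k}": v for k, v in profile.roi_fractions.items()},
        })
        label_rows.append({
            "subject_id": scan.subject_id,
            "cohort": scan.cohort,
            **{f"rater_{i + 1}": lab for i, lab in enumerate(labels)},
            "label": str(vote.label.value),
            "fallback": str(vote.fallback.value),
        })
        _stage("tmap+classify", scan.subject_id, t0,
               clusters=clusters.n_clusters, label=vote.label.value)

    hallmarks_df = pd.DataFrame(hall_rows)
    labels_df = pd.DataFrame(label_rows)

    kappa = float("nan")
    if len(patients) >= 2:
        kappa = mean_pairwise_kappa(np.array(rater_matrix).T)

    perf = {}
    label_map = {"DLB": "DLB_LIKE", "ADD": "AD_LIKE", "PD": "PD_LIKE"}
    present = set(labels_df.cohort)
    for a, b in (("DLB", "ADD"), ("DLB", "PD")):
        if a in present and b in present:
            try:
                conf = diagstats.pairwise_confusion(
                    labels_df.label, labels_df.cohort, a, b,
                    label_map=label_map)
                perf[f"{a}_vs_{b}"] = diagstats.performance(conf)
            except ValueError:
                pass

    feat = sub_labels = None
    dlb_idx = [i for i, s in enumerate(patients) if s.cohort == "DLB"]
    if len(dlb_idx) >= max(3, cfg.subtype_k):
        t0 = time.perf_counter()
        feat = subtype.build_feature_matrix(
            [tmaps[i] for i in dlb_idx], atlas,
            [patients[i].subject_id for i in dlb_idx])
        scores = subtype.pca_reduce(feat.values, cfg.pca_variance_target)
        dendro = subtype.hcluster_chebyshev_ward(scores)
        sub_labels = subtype.cut(dendro, cfg.subtype_k)
        _stage("subtype", "DLB", t0, k=cfg.subtype_k,
               sizes=np.bincount(sub_labels)[1:].tolist())

    manifest = {"config_hash": cfg.config_hash, "seed": cfg.seed,
                "n_controls": len(controls), "n_patients": len(patients),
                "mask_voxels": int(mask.sum())}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for df, name in ((hallmarks_df, "hallmarks.tsv"),
                         (labels_df, "labels.tsv"), (meta, "metadata.tsv")):
            df2 = df.copy()
            df2.insert(0, "config_hash", cfg.config_hash)
            io.write_table(df2, out / name)
        if feat is not None:
            fm = feat.to_frame().reset_index(names="subject_id")
            fm.insert(0, "config_hash", cfg.config_hash)
            fm["subtype"] = sub_labels
            io.write_table(fm, out / "subtype.tsv")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
        (out / "config.json").write_text(cfg.to_json())
        if cfg.write_volumes:
            vol_dir = out / "tmaps"
            vol_dir.mkdir(exist_ok=True)
            for scan, tm in zip(patients, tmaps):
                io.write_volume(tm.t, cfg.voxel_size_mm,
                                vol_dir / f"{scan.subject_id}_t.nii.gz")

    return PipelineResult(hallmark_table=hallmarks_df, label_table=labels_df,
                          performance=perf, kappa=kappa,
                          subtype_labels=sub_labels, feature_matrix=feat,
                          manifest=manifest)
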