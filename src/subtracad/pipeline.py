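"""End-to-end orchestration: simulate → preprocess → register → subtract →
detect → featurize → select → classify → report.

A run is driven by a :class:`RunConfig` (YAML-loadable, schema-checked,
unknown keys rejected).  One global seed is fanned out deterministically
per stage and patient via ``numpy.random.SeedSequence`` so identical
config+seed reproduce a run byte-for-byte at the stored precision.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import detect, features, model, phantom, preprocess, register, subtract
from .core import Mammogram, ROUNDS
from .io import read_image, read_mask
from .select import MajorityConsensusSelector

STAGES = ("simulate", "preprocess", "register", "subtract", "detect", "featurize", "classify")


@dataclass
class RunConfig:
    seed: int = 0
    manifest: Optional[str] = None  # existing cohort; None → simulate
    out_dir: str = "runs/run0"
    stages: tuple[str, ...] = STAGES
    save_stages: bool = False
    cohort: phantom.CohortConfig = field(default_factory=phantom.CohortConfig)
    preprocess: preprocess.PreprocessParams = field(default_factory=preprocess.PreprocessParams)
    detect: detect.DetectParams = field(default_factory=detect.DetectParams)
    register_iterations: tuple[int, ...] = register.DEFAULT_ITERATIONS
    register_sigma: float = register.DEFAULT_SMOOTHING_SIGMA
    round1_spec: str = "voting"
    round2_spec: str = "ann"
    round1_k: int = 19
    round2_k: int = 17
    quorum: int = 5
    cv: str = "lopo"  # lopo | kfold
    k_folds: int = 5
    n_boot: int = 500

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        nested = {
            "cohort": phantom.CohortConfig,
            "preprocess": preprocess.PreprocessParams,
            "detect": detect.DetectParams,
        }
        kwargs = {}
        for key, value in raw.items():
            if key in nested and isinstance(value, dict):
                cls_ = nested[key]
                bad = set(value) - set(cls_.__dataclass_fields__)
                if bad:
                    raise ValueError(f"unknown {key} keys: {sorted(bad)}")
                for fname in ("image_shape", "views", "mass_radius_range", "clahe_tiles"):
                    if fname in value and isinstance(value[fname], list):
                        value[fname] = tuple(value[fname])
                kwargs[key] = cls_(**value)
            else:
                kwargs[key] = tuple(value) if isinstance(value, list) else value
        return cls(**kwargs)

    def resolved(self) -> dict:
        out = asdict(self)
        return out


def read_manifest(path) -> dict:
    """Load and validate a cohort manifest.

    Returns ``{patient_id: {view: {round: row-dict}}}``; duplicate
    (patient, view, round) triples and missing image files are errors.
    """
    path = Path(path)
    root = path.parent
    index: dict = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing_cols = set(phantom.MANIFEST_HEADER) - set(reader.fieldnames or [])
        if missing_cols:
            raise ValueError(f"manifest missing columns: {sorted(missing_cols)}")
        for row in reader:
            if row["round"] not in ROUNDS:
                raise ValueError(f"unsupported round {row['round']!r}: only prior/recent")
            img_path = root / row["image_path"]
            if not img_path.exists():
                raise FileNotFoundError(f"manifest references missing file: {img_path}")
            slot = index.setdefault(row["patient_id"], {}).setdefault(row["view"], {})
            if row["round"] in slot:
                raise ValueError(
                    f"duplicate manifest entry: {row['patient_id']}/{row['view']}/{row['round']}"
                )
            slot[row["round"]] = dict(row)
    return index


def _stage_depth(stages) -> int:
    """Index of the deepest requested stage in the canonical order."""
    return max((STAGES.index(s) for s in stages if s in STAGES), default=0)


def _process_pair(
    recent: Mammogram,
    prior: Mammogram,
    cfg: RunConfig,
    truth_masks: list,
    truth_labels: list,
    depth: int = len(STAGES) - 1,
) -> dict:
    """Preprocess both rounds, register, subtract and detect for one view.

    ``depth`` truncates the chain (index into ``STAGES``): downstream
    entries are simply absent from the result dict.
    """
    out: dict = {}
    recent_pp, recent_mask = preprocess.preprocess_pipeline(recent, cfg.preprocess)
    prior_pp, _ = preprocess.preprocess_pipeline(prior, cfg.preprocess)
    out.update({"recent_pp": recent_pp, "prior_pp": prior_pp, "breast_mask": recent_mask})
    if depth < STAGES.index("register"):
        return out
    warped, field_hat = register.demons_register(
        recent_pp.pixels,
        prior_pp.pixels,
        iterations=cfg.register_iterations,
        smoothing_sigma=cfg.register_sigma,
    )
    out["field"] = field_hat
    if depth < STAGES.index("subtract"):
        return out
    # compare only where both rounds carry tissue: zeros in the warped
    # prior (outside its breast mask, or warped out of frame) would
    # otherwise surface as spurious bright residual.  The breast mask
    # itself stays the recent one so peripheral distances are anatomical.
    residual = subtract.temporal_subtract(recent_pp, warped, recent_mask)
    residual.pixels[warped <= 0] = 0.0
    out["residual"] = residual
    if depth < STAGES.index("detect"):
        return out
    rois = detect.segment_candidates(residual, cfg.detect)
    tally = detect.match_to_truth(rois, truth_masks, truth_labels)
    out.update({"rois": rois, "tally": tally})
    if depth < STAGES.index("featurize"):
        return out
    out["vectors"] = [
        features.extract_all(roi, recent_pp.pixels, roi_id=i)
        for i, roi in enumerate(rois)
    ]
    return out


def build_feature_table(results: list[dict]) -> dict:
    """Stack per-pair feature vectors into X / labels / groups arrays."""
    X, labels, groups, views = [], [], [], []
    for res in results:
        for vec in res.get("vectors", []):
            X.append(vec.values)
            labels.append(vec.label or "normal")
            groups.append(vec.patient_id)
            views.append(vec.view)
    return {
        "X": np.asarray(X) if X else np.empty((0, features.N_FEATURES)),
        "labels": np.asarray(labels),
        "groups": np.asarray(groups),
        "views": np.asarray(views),
    }


def evaluate_two_rounds(table: dict, cfg: RunConfig, seed: int) -> dict:
    """Round 1 (normal vs. mass) then round 2 (benign vs. malignant)."""
    out: dict = {}
    y1 = (table["labels"] != "normal").astype(int)
    selector1 = MajorityConsensusSelector(
        target_size=cfg.round1_k, quorum=cfg.quorum, random_state=seed
    )
    spec1 = model.ClassifierSpec(cfg.round1_spec, round=1, seed=seed)
    cv_kwargs = dict(selection=selector1, n_boot=cfg.n_boot, seed=seed)
    if cfg.cv == "kfold":
        report1 = model.kfold_cv(
            table["X"], y1, table["groups"], cfg.k_folds, spec1, **cv_kwargs
        )
    else:
        report1 = model.lopo_cv(table["X"], y1, table["groups"], spec1, **cv_kwargs)
    out["round1"] = report1

    mass_rows = np.flatnonzero(table["labels"] != "normal")
    if len(mass_rows):
        y2 = (table["labels"][mass_rows] == "malignant").astype(int)
        groups2 = table["groups"][mass_rows]
        if len(np.unique(y2)) == 2 and len(np.unique(groups2)) >= 2:
            selector2 = MajorityConsensusSelector(
                target_size=cfg.round2_k, quorum=cfg.quorum, random_state=seed
            )
            spec2 = model.ClassifierSpec(cfg.round2_spec, round=2, seed=seed)
            cv2 = dict(selection=selector2, n_boot=cfg.n_boot, seed=seed)
            if cfg.cv == "kfold":
                out["round2"] = model.kfold_cv(
                    table["X"][mass_rows], y2, groups2, cfg.k_folds, spec2, **cv2
                )
            else:
                out["round2"] = model.lopo_cv(
                    table["X"][mass_rows], y2, groups2, spec2, **cv2
                )
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; write artifacts and a summary JSON."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text(yaml.safe_dump(cfg.resolved(), sort_keys=True))
    stage_seed = {s: int(np.random.SeedSequence([cfg.seed, i]).generate_state(1)[0] % (2**31))
                  for i, s in enumerate(STAGES)}
    depth = _stage_depth(cfg.stages)

    summary: dict = {"seed": cfg.seed, "stages": list(cfg.stages)}

    # --- data: simulate or load ------------------------------------------
    patients: list[tuple[str, list[Mammogram], dict]] = []
    if cfg.manifest:
        index = read_manifest(cfg.manifest)
        root = Path(cfg.manifest).parent
        for pid, by_view in sorted(index.items()):
            imgs: list[Mammogram] = []
            truth: dict = {"mass_masks": {}, "mass_labels": {}, "patient_label": "normal"}
            for view, rounds in by_view.items():
                if set(rounds) != set(ROUNDS):
                    continue  # incomplete pair: skip with a note
                for rnd in ROUNDS:
                    row = rounds[rnd]
                    imgs.append(Mammogram(read_image(root / row["image_path"]), pid, view, rnd))
                    if rnd == "recent":
                        truth["patient_label"] = row["label"]
                        if row["mask_path"]:
                            truth["mass_masks"][view] = [read_mask(root / row["mask_path"])]
            patients.append((pid, imgs, truth))
    else:
        cohort_cfg = cfg.cohort
        pat_seeds = np.random.SeedSequence(
            [stage_seed["simulate"], cohort_cfg.seed]
        ).spawn(cohort_cfg.n_patients)
        for i, s in enumerate(pat_seeds):
            pid = f"P{i:03d}"
            imgs, gt = phantom.generate_patient(cohort_cfg, pid, np.random.default_rng(s))
            truth = {
                "mass_masks": gt.mass_masks,
                "mass_labels": gt.mass_labels,
                "patient_label": gt.patient_label,
            }
            patients.append((pid, imgs, truth))
    summary["n_patients"] = len(patients)

    if depth < STAGES.index("preprocess"):
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        return summary

    # --- image stages per patient/view -----------------------------------
    results = []
    tallies = {"n_truth": 0, "n_detected": 0, "n_missed": 0, "n_fp": 0}
    bg_reductions = []
    for pid, imgs, truth in patients:
        by_view: dict = {}
        for img in imgs:
            by_view.setdefault(img.view, {})[img.round] = img
        for view, rounds in by_view.items():
            if set(rounds) != set(ROUNDS):
                continue
            masks = list(truth["mass_masks"].get(view, []))
            label = truth["patient_label"]
            labels = [label] * len(masks) if label in ("benign", "malignant") else []
            res = _process_pair(rounds["recent"], rounds["prior"], cfg, masks, labels, depth)
            if "tally" in res:
                for key in tallies:
                    tallies[key] += res["tally"][key]
            if "residual" in res:
                lesion = np.zeros(res["residual"].pixels.shape, dtype=bool)
                for m in masks:
                    lesion |= np.asarray(m, dtype=bool)
                background = res["breast_mask"] & ~lesion
                if background.any():
                    bg_reductions.append(
                        subtract.background_reduction(
                            res["recent_pp"].pixels, res["residual"].pixels, background
                        )
                    )
            results.append(res)

    if depth >= STAGES.index("detect"):
        summary["detection"] = tallies
        summary["retention_pct"] = (
            100.0 * tallies["n_detected"] / tallies["n_truth"] if tallies["n_truth"] else None
        )
    if depth >= STAGES.index("subtract"):
        summary["mean_background_reduction_pct"] = (
            float(np.mean(bg_reductions)) if bg_reductions else None
        )

    # --- features + classification ---------------------------------------
    if depth >= STAGES.index("featurize"):
        table = build_feature_table(results)
        summary["n_rois"] = int(len(table["labels"]))
        if depth >= STAGES.index("classify") and len(table["labels"]):
            reports = evaluate_two_rounds(table, cfg, stage_seed["classify"])
            for name, rep in reports.items():
                summary[name] = rep.as_dict()

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
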