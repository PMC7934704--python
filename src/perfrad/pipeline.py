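"""End-to-end orchestration: simulate -> segment -> features -> predict -> evaluate.

A run is driven by a :class:`RunConfig` (YAML round-trippable), writes all
artifacts under one run directory with a fixed layout, and records a manifest
with the config hash and a SHA-256 digest of every file each stage read or
wrote.  Re-running with the identical config and seed reproduces identical
digests; with ``resume=True`` stages whose recorded outputs are intact are
skipped.  Image outputs are written as uncompressed NIfTI so that digests are
a pure function of the voxel data.

Seeding: one global seed; every stochastic stage derives its own substream by
hashing (seed, stage name), so adding a stage never perturbs another stage's
draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import imaging, predict, segment, stats, synth

log = logging.getLogger("perfrad.pipeline")

LAYOUT = {
    "cohort": "cohort.csv",
    "scores": "scores.csv",
    "trace": "trace.json",
    "roc": "roc.json",
    "agreement": "agreement.json",
    "segmentation": "segmentation.csv",
    "manifest": "manifest.json",
    "report": "report.md",
    "images": "images",
    "masks": "masks",
}


@dataclasses.dataclass
class RunConfig:
    """Everything one reproducible run depends on."""

    out_dir: str = "run"
    seed: int = 0
    n_cases: int = 36
    n_nondfs: int = 10
    responder_fraction: float = 33.0 / 44.0
    # phantom geometry
    grid_shape: tuple[int, int, int] = (40, 56, 56)
    spacing: tuple[float, float, float] = (1.25, 1.0, 1.0)
    radii_range_mm: tuple[float, float] = (8.0, 13.0)
    tumor_hu: float = 80.0
    background_hu: float = -100.0
    noise_sd: float = 8.0
    # group structure on change features (log-scale shifts, nonDFS - DFS)
    bf_log_ratio_sd: float = 0.2
    bf_effect_d: float = 0.6612  # population AUC Phi(d/sqrt 2) = 0.68
    volume_effect_d: float = 0.5073  # 0.64
    case_log_sd: float = 0.5
    target_icc: float = 0.75
    laryngoscopy_icc: float = 0.55
    # predictor / evaluation options
    feature_cols: list[str] | None = None  # default: volume_pct + perfusion pct changes
    max_features: int = 2
    ci_method: str = "delta"  # or "bootstrap"
    bootstrap_resamples: int = 2000

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("grid_shape", "spacing", "radii_range_mm"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        # out_dir is where results land, not part of what they are
        payload = {k: v for k, v in dataclasses.asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=list).encode()
        ).hexdigest()


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    package_version: str
    stages: dict[str, dict]
    warnings: list[str]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _digests(paths: list[Path], root: Path) -> dict[str, str]:
    return {str(p.relative_to(root)): _sha256(p) for p in sorted(paths)}


def _stage_intact(record: dict | None, root: Path) -> bool:
    if not record:
        return False
    for rel, digest in record.get("outputs", {}).items():
        p = root / rel
        if not p.exists() or _sha256(p) != digest:
            return False
    return True


def _simulate(config: RunConfig, root: Path) -> list[Path]:
    """Generate the paired image cohort and ground truth."""
    rng = synth.rng_for(config.seed, "simulate")
    n = config.n_cases
    labels = np.array([1] * config.n_nondfs + [0] * (n - config.n_nondfs))
    rng.shuffle(labels)
    img_dir = root / LAYOUT["images"]
    img_dir.mkdir(parents=True, exist_ok=True)
    truth_rows = []
    outputs = []
    sig_r = synth.rater_log_sd_for_icc(config.target_icc, config.case_log_sd)
    sig_l = synth.rater_log_sd_for_icc(config.laryngoscopy_icc, config.case_log_sd)
    for i in range(n):
        radii = tuple(rng.uniform(*config.radii_range_mm, size=3))
        spec = synth.PhantomSpec(
            shape=config.grid_shape, spacing=config.spacing, radii_mm=radii,
            tumor_hu=config.tumor_hu, background_hu=config.background_hu,
            noise_sd=config.noise_sd, seed=int(rng.integers(0, 2**31 - 1)),
        )
        # responders concentrate at strong shrinkage; group effect on volume change
        mu_vol = math.log(0.45) + labels[i] * config.volume_effect_d * config.case_log_sd
        shrink = float(np.clip(np.exp(rng.normal(mu_vol, config.case_log_sd)), 0.05, 1.4))
        mu_bf = -0.15 + labels[i] * config.bf_effect_d * config.bf_log_ratio_sd
        perf_pre = {
            p: max(0.5, rng.normal(synth.PERFUSION_TRUTH_MEANS[p], synth.PERFUSION_TRUTH_SDS[p]))
            for p in imaging.PERFUSION_PARAMS
        }
        perf_post = {
            p: perf_pre[p] * float(np.exp(rng.normal(
                mu_bf if p == "BF" else -0.1, config.bf_log_ratio_sd)))
            for p in imaging.PERFUSION_PARAMS
        }
        try:
            case = synth.generate_case_pair(
                spec, shrink, label="nonDFS" if labels[i] else "DFS",
                case_id=f"case{i:03d}", perfusion_pre=perf_pre, perfusion_post=perf_post,
                rater_log_sd=sig_r, laryngoscopy_sd=0.0,
            )
        except synth.SpecError:
            shrink = 0.3
            case = synth.generate_case_pair(
                spec, shrink, label="nonDFS" if labels[i] else "DFS",
                case_id=f"case{i:03d}", perfusion_pre=perf_pre, perfusion_post=perf_post,
                rater_log_sd=sig_r, laryngoscopy_sd=0.0,
            )
        lar_ratio = shrink * math.exp(rng.normal(0.0, sig_l * math.sqrt(2.0)))
        for tp, vol, mask in (
            ("pre", case.pre_volume, case.pre_mask),
            ("post", case.post_volume, case.post_mask),
        ):
            imaging.write_volume(vol, img_dir / f"{case.case_id}_{tp}.nii")
            imaging.write_volume(mask, img_dir / f"{case.case_id}_{tp}_truth.nii")
            maps = synth.generate_perfusion_maps(case, tp, seed=spec.seed)
            mdir = img_dir / f"{case.case_id}_{tp}_perfusion"
            mdir.mkdir(exist_ok=True)
            for p in imaging.PERFUSION_PARAMS:
                imaging.write_volume(maps[p], mdir / f"{p}.nii")
                outputs.append(mdir / f"{p}.nii")
            outputs += [img_dir / f"{case.case_id}_{tp}.nii", img_dir / f"{case.case_id}_{tp}_truth.nii"]
        truth_rows.append({
            "case_id": case.case_id,
            "label": case.label,
            "dfs_fail": int(labels[i]),
            "true_pre_volume": case.true_pre_volume_mm3,
            "true_post_volume": case.true_post_volume_mm3,
            "true_pct_change": case.true_pct_volume_change,
            "rad1_pct_change": feat.percent_change(*case.rater_volumes["rad1"]),
            "rad2_pct_change": feat.percent_change(*case.rater_volumes["rad2"]),
            "laryngoscopy_pct_change": 100.0 * (lar_ratio - 1.0),
            **{f"true_{p}_pre": perf_pre[p] for p in imaging.PERFUSION_PARAMS},
            **{f"true_{p}_post": perf_post[p] for p in imaging.PERFUSION_PARAMS},
        })
    truth_path = root / "truth.csv"
    pd.DataFrame(truth_rows).to_csv(truth_path, index=False)
    outputs.append(truth_path)
    return outputs


def _box_from_truth(mask: imaging.BinaryMask, margin: int = 3) -> imaging.BoundingBox:
    idx = np.argwhere(mask.voxels > 0)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    box = imaging.BoundingBox(tuple(int(v) for v in lo), tuple(int(v) for v in hi))
    return box.dilate(margin, mask.shape)


def _segment_stage(config: RunConfig, root: Path) -> list[Path]:
    img_dir = root / LAYOUT["images"]
    mask_dir = root / LAYOUT["masks"]
    mask_dir.mkdir(parents=True, exist_ok=True)
    truth = pd.read_csv(root / "truth.csv")
    rows, outputs = [], []
    params = segment.SegmentationParams()
    for case_id in truth["case_id"]:
        for tp in ("pre", "post"):
            vol = imaging.read_volume(img_dir / f"{case_id}_{tp}.nii")
            gt = imaging.read_mask(img_dir / f"{case_id}_{tp}_truth.nii")
            box = _box_from_truth(gt)
            result = segment.segment_tumor(vol, box, params)
            out = mask_dir / f"{case_id}_{tp}_mask.nii"
            imaging.write_volume(result.mask, out)
            outputs.append(out)
            rows.append({
                "case_id": case_id, "timepoint": tp,
                "dice_vs_truth": stats.dice(result.mask, gt),
                "volume_mm3": result.mask.volume_mm3(),
                "truth_volume_mm3": gt.volume_mm3(),
                **{k: v for k, v in result.diagnostics.items()},
            })
    seg_path = root / LAYOUT["segmentation"]
    pd.DataFrame(rows).to_csv(seg_path, index=False)
    outputs.append(seg_path)
    return outputs


def _features_stage(config: RunConfig, root: Path) -> list[Path]:
    img_dir = root / LAYOUT["images"]
    mask_dir = root / LAYOUT["masks"]
    truth = pd.read_csv(root / "truth.csv")
    rows = []
    for _, t in truth.iterrows():
        case_id = t["case_id"]
        rads, perfs = {}, {}
        for tp in ("pre", "post"):
            vol = imaging.read_volume(img_dir / f"{case_id}_{tp}.nii")
            mask = imaging.read_mask(mask_dir / f"{case_id}_{tp}_mask.nii")
            rads[tp] = feat.extract_radiomics(vol, mask)
            maps = imaging.read_perfusion_maps(img_dir / f"{case_id}_{tp}_perfusion")
            roi = imaging.resample_mask_to_grid(mask, maps.grid)
            if not roi.voxels.any():
                # tumor too thin for the 5 mm composite at 50% coverage: use the
                # best-covered voxel so the perfusion reading is still defined
                cov = imaging.coverage_fraction(mask, maps.grid)
                best = np.unravel_index(np.argmax(cov), cov.shape)
                vox = np.zeros(cov.shape, dtype=np.uint8)
                vox[best] = 1
                roi = imaging.BinaryMask(vox, roi.spacing, roi.origin)
                warnings.warn(f"{case_id} {tp}: ROI fell below coverage threshold; "
                              "using best-covered perfusion voxel")
            perfs[tp] = feat.perfusion_roi_stats(maps, roi)
        record = feat.CaseRecord(
            case_id=case_id, pre_radiomics=rads["pre"], post_radiomics=rads["post"],
            pre_perfusion=perfs["pre"], post_perfusion=perfs["post"],
            laryngoscopy_pct_change=float(t["laryngoscopy_pct_change"]),
            dfs_label=t["label"],
        )
        chg = record.change_features()
        rows.append({
            "case_id": case_id, "label": t["label"], "dfs_fail": int(t["dfs_fail"]),
            "responder": int(record.responder),
            "laryngoscopy_pct_change": t["laryngoscopy_pct_change"],
            "rad1_pct_change": t["rad1_pct_change"],
            "rad2_pct_change": t["rad2_pct_change"],
            "true_pct_change": t["true_pct_change"],
            **{f"pre_{k}": v for k, v in rads["pre"].values.items()},
            **{f"post_{k}": v for k, v in rads["post"].values.items()},
            **{f"pre_{p}": perfs["pre"][p] for p in imaging.PERFUSION_PARAMS},
            **{f"post_{p}": perfs["post"][p] for p in imaging.PERFUSION_PARAMS},
            **chg,
        })
    cohort_path = root / LAYOUT["cohort"]
    pd.DataFrame(rows).to_csv(cohort_path, index=False)
    return [cohort_path]


def default_feature_cols(cohort: pd.DataFrame) -> list[str]:
    """Classifier inputs: percent volume change plus perfusion percent changes."""
    cols = ["volume_pct"] + [f"pct_{p}" for p in imaging.PERFUSION_PARAMS]
    return [c for c in cols if c in cohort.columns and cohort[c].notna().all()]


def _predict_stage(config: RunConfig, root: Path) -> list[Path]:
    cohort = pd.read_csv(root / LAYOUT["cohort"])
    cols = config.feature_cols or default_feature_cols(cohort)
    X = cohort[cols].to_numpy(dtype=float)
    y = cohort["dfs_fail"].to_numpy(dtype=int)
    result = predict.two_loop_loo(X, y, cols, config.max_features, list(cohort["case_id"]))
    scores = pd.DataFrame({
        "case_id": result.case_ids,
        "dfs_fail": result.labels,
        "testing_index": result.testing_index,
        "training_index": result.training_index,
    })
    scores_path = root / LAYOUT["scores"]
    scores.to_csv(scores_path, index=False)
    trace = {
        "feature_cols": cols,
        "max_features": config.max_features,
        "fold_selections": result.fold_selections,
        "selection_frequency": result.selection_frequency,
        "skipped_folds": result.skipped_folds,
        "testing_auc": result.testing_auc(),
        "training_auc_resubstitution": result.training_auc(),
        "training_auc_mean_fold": result.mean_fold_training_auc(),
    }
    trace_path = root / LAYOUT["trace"]
    trace_path.write_text(json.dumps(trace, indent=2, sort_keys=True))
    return [scores_path, trace_path]


def _evaluate_stage(config: RunConfig, root: Path) -> list[Path]:
    cohort = pd.read_csv(root / LAYOUT["cohort"])
    scores = pd.read_csv(root / LAYOUT["scores"])
    y = scores["dfs_fail"].to_numpy(dtype=int)
    out = {}
    for split in ("testing", "training"):
        s = scores[f"{split}_index"].to_numpy(dtype=float)
        ok = np.isfinite(s)
        roc = stats.fit_binormal_roc(s[ok][y[ok] == 1], s[ok][y[ok] == 0])
        entry = dataclasses.asdict(roc)
        if config.ci_method == "bootstrap":
            lo, hi = stats.bootstrap_auc_ci(
                s[ok][y[ok] == 1], s[ok][y[ok] == 0],
                config.bootstrap_resamples, seed=config.seed,
            )
            entry["bootstrap_ci"] = [lo, hi]
        out[split] = entry
    roc_path = root / LAYOUT["roc"]
    roc_path.write_text(json.dumps(out, indent=2, sort_keys=True))

    # agreement layer: percent volume change by computer vs raters vs laryngoscopy
    agree = {}
    pairs = {
        "computer_vs_rad1": ("volume_pct", "rad1_pct_change"),
        "computer_vs_rad2": ("volume_pct", "rad2_pct_change"),
        "rad1_vs_rad2": ("rad1_pct_change", "rad2_pct_change"),
        "laryngoscopy_vs_computer": ("laryngoscopy_pct_change", "volume_pct"),
    }
    for name, (ca, cb) in pairs.items():
        table = cohort[[ca, cb]].to_numpy(dtype=float)
        res = stats.icc(table)
        tt = stats.paired_ttest(table[:, 0], table[:, 1])
        agree[name] = {"icc": res.icc, "icc_model": res.icc_model,
                       "t_stat": tt.t_stat, "p_value": tt.p_value, "n": res.n}
    resp_computer = (cohort["volume_pct"] <= -50.0).astype(int)
    resp_lar = (cohort["laryngoscopy_pct_change"] <= -50.0).astype(int)
    kap = stats.cohen_kappa(resp_computer, resp_lar)
    agree["kappa_responder_computer_vs_laryngoscopy"] = {
        "kappa": kap.kappa, "n": kap.n, "degenerate": kap.degenerate}
    kap2 = stats.cohen_kappa(resp_lar, cohort["dfs_fail"].to_numpy(dtype=int))
    agree["kappa_laryngoscopy_responder_vs_dfs_fail"] = {
        "kappa": kap2.kappa, "n": kap2.n, "degenerate": kap2.degenerate}
    agree_path = root / LAYOUT["agreement"]
    agree_path.write_text(json.dumps(agree, indent=2, sort_keys=True))
    return [roc_path, agree_path]


STAGES = {
    "simulate": _simulate,
    "segment": _segment_stage,
    "features": _features_stage,
    "predict": _predict_stage,
    "evaluate": _evaluate_stage,
}
STAGE_ORDER = ["simulate", "segment", "features", "predict", "evaluate"]


def run_pipeline(config: RunConfig, resume: bool = False) -> RunManifest:
    """Execute all stages in order; returns the manifest (also written to disk)."""
    from importlib.metadata import version as _version

    root = Path(config.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    config.to_yaml(root / "config.yaml")
    try:
        pkg_version = _version("perfrad")
    except Exception:
        pkg_version = "unknown"
    manifest_path = root / LAYOUT["manifest"]
    old = None
    if resume and manifest_path.exists():
        prior = RunManifest.load(manifest_path)
        if prior.config_hash == config.config_hash():
            old = prior
    stages: dict[str, dict] = {}
    warn_log: list[str] = []
    for name in STAGE_ORDER:
        prior_rec = old.stages.get(name) if old else None
        if resume and _stage_intact(prior_rec, root):
            log.info("stage %s: outputs intact, skipping", name)
            stages[name] = prior_rec
            continue
        log.info("stage %s: running", name)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                outputs = STAGES[name](config, root)
            except Exception as err:
                raise RuntimeError(f"stage '{name}' failed: {err}") from err
        for w in caught:
            warn_log.append(f"{name}: {w.message}")
            log.warning("stage %s: %s", name, w.message)
        stages[name] = {"outputs": _digests(outputs, root)}
    manifest = RunManifest(config.config_hash(), pkg_version, stages, warn_log)
    manifest.save(manifest_path)
    report_text = report(manifest, root)
    (root / LAYOUT["report"]).write_text(report_text)
    return manifest


def report(manifest: RunManifest, root: str | Path) -> str:
    """One-page markdown summary of a completed run."""
    root = Path(root)
    if not manifest.stages:
        raise ValueError("empty manifest: nothing to report")
    lines = ["# perfrad run report", ""]
    lines.append(f"config hash: `{manifest.config_hash[:16]}`  |  package {manifest.package_version}")
    lines.append("")
    seg_path = root / LAYOUT["segmentation"]
    if seg_path.exists():
        seg = pd.read_csv(seg_path)
        dice_med = seg["dice_vs_truth"].median()
        verr = (100.0 * (seg["volume_mm3"] - seg["truth_volume_mm3"]) / seg["truth_volume_mm3"]).abs()
        lines += [
            "## Segmentation vs ground truth",
            f"- scans segmented: {len(seg)}",
            f"- median Dice: {dice_med:.3f} (IQR {seg['dice_vs_truth'].quantile(0.25):.3f}"
            f"-{seg['dice_vs_truth'].quantile(0.75):.3f})",
            f"- median |volume error|: {verr.median():.1f}%",
            "",
        ]
    else:
        lines += ["## Segmentation", "- (stage absent)", ""]
    cohort_path = root / LAYOUT["cohort"]
    if cohort_path.exists():
        cohort = pd.read_csv(cohort_path)
        n_fail = int(cohort["dfs_fail"].sum())
        lines += [
            "## Cohort",
            f"- cases: {len(cohort)}; without one-year DFS: {n_fail} "
            f"({100.0 * n_fail / len(cohort):.0f}%)",
            f"- responders (>=50% shrinkage by computer volume): {int(cohort['responder'].sum())}",
            "",
        ]
    trace_path = root / LAYOUT["trace"]
    roc_path = root / LAYOUT["roc"]
    if trace_path.exists() and roc_path.exists():
        trace = json.loads(trace_path.read_text())
        roc = json.loads(roc_path.read_text())
        sel = ", ".join(f"{k} ({v}/{len(trace['fold_selections'])})"
                        for k, v in sorted(trace["selection_frequency"].items(),
                                           key=lambda kv: -kv[1]))
        lines += [
            "## Combined response index (two-loop LOO + LDA)",
            f"- candidate features: {', '.join(trace['feature_cols'])} "
            f"(max {trace['max_features']} selected per fold)",
            f"- selection frequency: {sel}",
            "",
            "| split | empirical AUC | binormal AUC | 95% CI |",
            "|---|---|---|---|",
        ]
        for split in ("training", "testing"):
            r = roc[split]
            lines.append(
                f"| {split.capitalize()} | {r['auc_empirical']:.2f} | {r['auc_binormal']:.2f} "
                f"| ({r['ci_low']:.2f}, {r['ci_high']:.2f}) |"
            )
        lines.append("")
    else:
        lines += ["## Prediction", "- (stage absent)", ""]
    agree_path = root / LAYOUT["agreement"]
    if agree_path.exists():
        agree = json.loads(agree_path.read_text())
        lines += ["## Agreement (percent volume change)", "| pair | ICC | paired t | p |", "|---|---|---|---|"]
        for name, entry in agree.items():
            if "icc" in entry:
                lines.append(f"| {name} | {entry['icc']:.2f} | {entry['t_stat']:.2f} "
                             f"| {entry['p_value']:.3f} |")
        for name, entry in agree.items():
            if "kappa" in entry:
                lines.append("")
                lines.append(f"- {name}: kappa = {entry['kappa']:.2f}")
        lines.append("")
    else:
        lines += ["## Agreement", "- (stage absent)", ""]
    if manifest.warnings:
        lines += ["## Warnings", *[f"- {w}" for w in manifest.warnings], ""]
    return "\n".join(lines)
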