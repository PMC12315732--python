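"""End-to-end orchestration: simulate -> invert -> maps -> reliability -> report.

The pipeline is resumable per stage: each stage writes its outputs plus a
marker JSON carrying the configuration hash; a later invocation skips
completed stages and refuses to resume over outputs produced with a
different configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as io_mod
from . import maps as maps_mod
from .cohort import CohortSpec, simulate_cohort, REGION_LABELS
from .inversion import InversionConfig, invert_volume
from .maps import BinDefinition, compute_maps, majority_vote_roi, roi_reduce
from .protocol import make_default_protocol, read_protocol, write_protocol
from .reliability import bland_altman, cv_ws, gaussian_smooth_masked, icc_a1

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "invert", "maps", "reliability", "report")


@dataclass
class RunConfig:
    """Single configuration object for a pipeline run."""

    out_dir: str = "mdmri_run"
    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    inversion: InversionConfig = field(default_factory=InversionConfig)
    bins: BinDefinition = field(default_factory=BinDefinition)
    smoothing_fwhm_mm: float = 4.0
    voxel_size_mm: float = 2.0
    csf_threshold: float = 0.2

    def __post_init__(self) -> None:
        # one top-level seed flows to every stage
        self.cohort = dataclasses.replace(self.cohort, seed=self.seed)
        self.inversion = dataclasses.replace(self.inversion, seed=self.seed)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs:
            kwargs["cohort"] = CohortSpec(**{
                k: tuple(v) if k == "shape" else v
                for k, v in kwargs["cohort"].items()})
        if "inversion" in kwargs:
            kwargs["inversion"] = InversionConfig(**{
                k: tuple(v) if k.endswith("_range") else v
                for k, v in kwargs["inversion"].items()})
        if "bins" in kwargs:
            kwargs["bins"] = BinDefinition(**kwargs["bins"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _marker(out: Path, stage: str) -> Path:
    return out / f".stage_{stage}.json"


def _stage_done(out: Path, stage: str, cfg_hash: str) -> bool:
    m = _marker(out, stage)
    if not m.exists():
        return False
    info = io_mod.read_json(m)
    if info.get("config_hash") != cfg_hash:
        raise RuntimeError(
            f"stage {stage!r} in {out} was produced with a different "
            f"configuration ({info.get('config_hash')} != {cfg_hash})")
    return True


def _mark(out: Path, stage: str, cfg_hash: str, t0: float, **extra) -> None:
    io_mod.write_json({"stage": stage, "config_hash": cfg_hash,
                       "elapsed_s": time.time() - t0, **extra},
                      _marker(out, stage))


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the pipeline stages in order; returns the report dictionary.

    Every output directory carries the configuration hash; rerunning with
    the same configuration is a no-op for completed stages.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    config.to_yaml(out / "config.yaml")
    vs = config.voxel_size_mm

    # ---- simulate ----------------------------------------------------
    if "simulate" in stages and not _stage_done(out, "simulate", h):
        t0 = time.time()
        proto = make_default_protocol(config.seed)
        ds = simulate_cohort(config.cohort, proto)
        cdir = out / "cohort"
        cdir.mkdir(exist_ok=True)
        write_protocol(proto, cdir / "protocol.tsv")
        io_mod.save_nifti(ds.labels, cdir / "labels.nii.gz", vs)
        for (s, r), sig in ds.signals.items():
            io_mod.save_nifti(sig, cdir / f"sub-{s:02d}_ses-{r}_signal.nii.gz", vs)
        for s, tmap in ds.truth_maps.items():
            io_mod.save_maps(tmap, cdir / f"sub-{s:02d}_truth",
                             vs, {"config_hash": h, "kind": "truth"})
        io_mod.write_json({"config_hash": h,
                           "n_subjects": config.cohort.n_subjects,
                           "n_sessions": config.cohort.n_sessions,
                           "shape": list(config.cohort.shape),
                           "seed": config.seed}, cdir / "manifest.json")
        _mark(out, "simulate", h, t0)

    # ---- invert ------------------------------------------------------
    if "invert" in stages and not _stage_done(out, "invert", h):
        t0 = time.time()
        cdir = out / "cohort"
        proto = read_protocol(cdir / "protocol.tsv")
        labels, _ = io_mod.load_nifti(cdir / "labels.nii.gz")
        mask = labels > 0
        sdir = out / "solutions"
        sdir.mkdir(exist_ok=True)
        n_comp = 0
        for f in sorted(cdir.glob("sub-*_signal.nii.gz")):
            sig, _ = io_mod.load_nifti(f)
            res = invert_volume(sig, proto, mask, config.inversion)
            n_comp += sum(sol.n_components for r in res.values()
                          for sol in r.solutions)
            io_mod.save_solutions(
                res, sdir / f.name.replace("_signal.nii.gz", "_solutions.npz"))
        _mark(out, "invert", h, t0, total_components=n_comp)

    # ---- maps --------------------------------------------------------
    if "maps" in stages and not _stage_done(out, "maps", h):
        t0 = time.time()
        labels, _ = io_mod.load_nifti(out / "cohort" / "labels.nii.gz")
        sidecar = {"config_hash": h,
                   "omega_low_rad_s": maps_mod.OMEGA_LOW,
                   "omega_high_rad_s": maps_mod.OMEGA_HIGH,
                   "diso_split": config.bins.diso_split,
                   "ddeltasq_split": config.bins.ddeltasq_split}
        for f in sorted((out / "solutions").glob("*_solutions.npz")):
            res = io_mod.load_solutions(f)
            m = compute_maps(res, labels.shape, bins=config.bins)
            io_mod.save_maps(
                m, out / "maps" / f.name.replace("_solutions.npz", ""),
                vs, sidecar)
        _mark(out, "maps", h, t0)

    # ---- reliability -------------------------------------------------
    if "reliability" in stages and not _stage_done(out, "reliability", h):
        t0 = time.time()
        rel = _reliability_stage(config, out)
        _mark(out, "reliability", h, t0, **{"n_maps": len(rel)})

    # ---- report ------------------------------------------------------
    report = {}
    if "report" in stages:
        t0 = time.time()
        rdir = out / "reliability"
        report = {
            "config_hash": h,
            "voxelwise": io_mod.read_json(rdir / "voxelwise_summary.json"),
            "roi": io_mod.read_json(rdir / "roi_summary.json"),
            "bland_altman": io_mod.read_json(rdir / "bland_altman.json"),
        }
        io_mod.write_json(report, out / "report.json")
        _mark(out, "report", h, t0)
    return report


def _load_cohort_maps(out: Path) -> dict[tuple[int, int], dict[str, np.ndarray]]:
    maps = {}
    for d in sorted((out / "maps").glob("sub-*_ses-*")):
        sub = int(d.name.split("_")[0].split("-")[1])
        ses = int(d.name.split("ses-")[1])
        maps[(sub, ses)] = io_mod.load_maps(d)
    return maps


def _reliability_stage(config: RunConfig, out: Path) -> dict:
    import pandas as pd

    labels, _ = io_mod.load_nifti(out / "cohort" / "labels.nii.gz")
    mask = labels > 0
    all_maps = _load_cohort_maps(out)
    subjects = sorted({s for s, _ in all_maps})
    sessions = sorted({r for _, r in all_maps})
    map_names = [k for k in maps_mod.MAP_NAMES if k in next(iter(all_maps.values()))]
    rdir = out / "reliability"
    rdir.mkdir(exist_ok=True)

    # voxel-wise ICC / CVws on smoothed maps
    vox_summary = {}
    vox_rows = []
    for name in map_names:
        sm = {key: gaussian_smooth_masked(np.nan_to_num(vol[name]), mask,
                                          config.smoothing_fwhm_mm,
                                          config.voxel_size_mm)
              for key, vol in all_maps.items()}
        icc_vol = np.full(labels.shape, np.nan)
        cv_vol = np.full(labels.shape, np.nan)
        flat = np.flatnonzero(mask.ravel())
        tables = np.stack([[sm[(s, r)].ravel() for r in sessions]
                           for s in subjects])  # (n, k, vox)
        for vi in flat:
            tab = tables[:, :, vi]
            icc_vol.ravel()[vi] = icc_a1(tab, clamp=True)
            if tab.mean() != 0:
                cv_vol.ravel()[vi] = cv_ws(tab)
        io_mod.save_maps({f"icc_{name}": icc_vol, f"cvws_{name}": cv_vol},
                         rdir / "voxelwise", config.voxel_size_mm)
        vox_summary[name] = {
            "median_icc": float(np.nanmedian(icc_vol[mask])),
            "median_cvws": float(np.nanmedian(cv_vol[mask])),
        }
        for vi in flat:
            vox_rows.append({"map": name, "voxel": int(vi),
                             "icc": icc_vol.ravel()[vi],
                             "cvws": cv_vol.ravel()[vi]})
    pd.DataFrame(vox_rows).to_csv(rdir / "voxelwise.tsv", sep="\t", index=False)
    io_mod.write_json(vox_summary, rdir / "voxelwise_summary.json")

    # ROI-based: region means (CSF-fraction filtered), then ICC / CVws
    roi_summary = {}
    roi_rows = []
    for name in map_names:
        roi_summary[name] = {}
        for rname, lab in REGION_LABELS.items():
            roi = labels == lab
            tab = np.array([
                [roi_reduce(all_maps[(s, r)][name], roi,
                            all_maps[(s, r)]["fbin3"], config.csf_threshold)
                 for r in sessions] for s in subjects])
            if not np.all(np.isfinite(tab)):
                roi_summary[name][rname] = {"icc": None, "cvws": None}
                continue
            entry = {"icc": icc_a1(tab, clamp=True),
                     "cvws": cv_ws(tab) if tab.mean() != 0 else None}
            roi_summary[name][rname] = entry
            roi_rows.append({"map": name, "roi": rname, **entry})
    pd.DataFrame(roi_rows).to_csv(rdir / "roi.tsv", sep="\t", index=False)
    io_mod.write_json(roi_summary, rdir / "roi_summary.json")

    # Bland-Altman over template-ROI voxels, test vs retest, all subjects
    template = majority_vote_roi([mask] * (len(subjects) * len(sessions)))
    ba = {}
    for name in map_names:
        test = np.concatenate([all_maps[(s, sessions[0])][name][template]
                               for s in subjects])
        retest = np.concatenate([all_maps[(s, sessions[1])][name][template]
                                 for s in subjects])
        ok = np.isfinite(test) & np.isfinite(retest)
        if ok.sum() < 2:
            continue
        summ = bland_altman(test[ok], retest[ok])
        ba[name] = {"mean_difference": summ.mean_difference,
                    "ci_low": summ.ci_low, "ci_high": summ.ci_high,
                    "relative_mean_difference_pct":
                        summ.relative_mean_difference_pct}
    io_mod.write_json(ba, rdir / "bland_altman.json")
    return vox_summary
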