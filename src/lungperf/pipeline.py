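"""End-to-end pipeline: simulate/read -> preprocess -> denoise -> quantify.

Every stage writes its outputs to disk (NIfTI/CSV/PNG) so any stage can be
re-run in isolation, and a JSON manifest records seeds, configuration, output
hashes and wall times. One global seed fans out deterministically to
per-stage seeds; two runs with the same config and seed produce byte-identical
payloads.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as lio
from .bsn import BSNConfig, PDConfig, TrainConfig, BlindSpotDenoiser, DenoiserResults
from .phantom import PhantomSpec, NoiseSpec, make_phantom_bundle
from .pnp import PnPConfig
from .preprocess import (auto_baseline_frames, background_subtract, compute_mip,
                         default_mip_slab, estimate_lung_mask, select_peak_frame)
from .fractal import fd_map, fd_overlay
from .segmentation import gaussian_baseline, image_metrics, kmeans_segment

logger = logging.getLogger("lungperf")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of a full experiment run.

    ``stages`` toggles each pipeline step; ``denoise_method`` selects among
    ``apbsn`` (blind-spot network alone), ``pnp`` (PnP-ADMM around it) and
    ``gaussian`` (baseline filter). When ``input_path`` is unset, a phantom is
    simulated from ``phantom_spec``/``noise_spec``.
    """

    out_dir: str = "lungperf_run"
    input_path: str | None = None
    model_path: str | None = None
    seed: int = 0
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "preprocess": True, "train": True,
        "denoise": True, "fd": True, "kmeans": True, "metrics": True,
    })
    denoise_method: str = "pnp"
    gaussian_sigma: float = 1.0
    mip_slices: int = 20
    phantom_spec: PhantomSpec = field(default_factory=PhantomSpec)
    noise_spec: NoiseSpec | None = None
    bsn_config: BSNConfig = field(default_factory=BSNConfig)
    pd_config: PDConfig = field(default_factory=PDConfig)
    train_config: TrainConfig | None = None
    pnp_config: PnPConfig | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        plain = {"out_dir", "input_path", "model_path", "seed", "stages",
                 "denoise_method", "gaussian_sigma", "mip_slices"}
        for key, value in raw.items():
            if key in plain:
                kwargs[key] = value
        if "phantom_spec" in raw:
            spec = dict(raw["phantom_spec"])
            for tup_key in ("grid_shape", "enhancement_curve"):
                if tup_key in spec:
                    spec[tup_key] = tuple(spec[tup_key])
            kwargs["phantom_spec"] = PhantomSpec(**spec)
        if "noise_spec" in raw:
            ns = dict(raw["noise_spec"])
            if "gain_coeffs" in ns:
                ns["gain_coeffs"] = tuple(ns["gain_coeffs"])
            kwargs["noise_spec"] = NoiseSpec(**ns)
        for key, cfg_cls in (("bsn_config", BSNConfig), ("pd_config", PDConfig),
                             ("train_config", TrainConfig), ("pnp_config", PnPConfig)):
            if key in raw:
                sub = dict(raw[key])
                for tk in ("branch_kernels", "dilations"):
                    if tk in sub:
                        sub[tk] = tuple(sub[tk])
                kwargs[key] = cfg_cls(**sub)
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(seed: int, names) -> dict:
    state = np.random.SeedSequence(seed).generate_state(len(names)) % (2**31)
    return {name: int(s) for name, s in zip(names, state)}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log")
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)

    stage_names = ["simulate", "preprocess", "train", "denoise", "fd", "kmeans", "metrics"]
    seeds = _stage_seeds(cfg.seed, stage_names)
    manifest: dict = {
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "denoise_method": cfg.denoise_method,
        "stages_run": [],
        "outputs": {},
        "wall_times_s": {},
        "versions": {"numpy": np.__version__},
    }

    def record(stage: str, name: str, path: Path):
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    bundle = None
    series = None
    lung_mask = None
    enhanced = None
    peak_t = None
    model: DenoiserResults | None = None

    try:
        if cfg.stages.get("simulate") and cfg.input_path is None:
            t0 = time.time()
            noise = cfg.noise_spec or NoiseSpec(seed=seeds["simulate"])
            bundle = make_phantom_bundle(cfg.phantom_spec, noise, seed=seeds["simulate"])
            series = bundle.noisy_series
            lio.write_series(bundle.clean_series, out / "clean.nii")
            lio.write_series(series, out / "noisy.nii")
            lio.write_volume(bundle.lung_mask.astype(np.float32), out / "lung_mask.nii")
            record("simulate", "clean", out / "clean.nii")
            record("simulate", "noisy", out / "noisy.nii")
            record("simulate", "lung_mask", out / "lung_mask.nii")
            manifest["wall_times_s"]["simulate"] = round(time.time() - t0, 3)
            manifest["stages_run"].append("simulate")
        elif cfg.input_path is not None:
            series = lio.read_series(cfg.input_path)

        if cfg.stages.get("preprocess"):
            if series is None:
                raise RuntimeError("preprocess: no input series (enable simulate or set input_path)")
            t0 = time.time()
            baseline = auto_baseline_frames(series)
            enhanced_series = background_subtract(series, baseline)
            if bundle is not None:
                lung_mask = bundle.lung_mask
            else:
                peak_guess = int(np.argmax(
                    enhanced_series.data.reshape(enhanced_series.n_timepoints, -1).mean(axis=1)))
                lung_mask = estimate_lung_mask(enhanced_series.volume(peak_guess))
            peak_t = select_peak_frame(enhanced_series, lung_mask)
            enhanced = enhanced_series.volume(peak_t)
            lio.write_volume(enhanced, out / "peak_enhanced.nii", series.voxel_spacing)
            record("preprocess", "peak_enhanced", out / "peak_enhanced.nii")
            manifest["peak_timepoint"] = peak_t
            manifest["baseline_frames"] = baseline
            manifest["wall_times_s"]["preprocess"] = round(time.time() - t0, 3)
            manifest["stages_run"].append("preprocess")

        if cfg.stages.get("train"):
            if enhanced is None:
                raise RuntimeError("train: preprocess stage required")
            t0 = time.time()
            train_cfg = cfg.train_config or TrainConfig(seed=seeds["train"])
            model = BlindSpotDenoiser(list(enhanced), cfg.bsn_config, cfg.pd_config).fit(train_cfg)
            model.save(out / "model.ckpt.npz")
            record("train", "model", out / "model.ckpt.npz")
            manifest["final_train_loss"] = model.loss_history[-1]
            manifest["wall_times_s"]["train"] = round(time.time() - t0, 3)
            manifest["stages_run"].append("train")
        elif cfg.model_path is not None:
            model = DenoiserResults.load(cfg.model_path)

        slab = None
        denoised_vol = None
        if cfg.stages.get("denoise"):
            if enhanced is None:
                raise RuntimeError("denoise: preprocess stage required")
            t0 = time.time()
            slab = default_mip_slab(lung_mask, cfg.mip_slices)
            denoised = []
            for idx, z in enumerate(range(*slab)):
                y = enhanced[z]
                if cfg.denoise_method == "gaussian":
                    denoised.append(gaussian_baseline(y, cfg.gaussian_sigma))
                elif cfg.denoise_method == "apbsn":
                    if model is None:
                        raise RuntimeError("denoise: no trained model available")
                    denoised.append(model.denoise(y, seed=seeds["denoise"] + idx))
                elif cfg.denoise_method == "pnp":
                    if model is None:
                        raise RuntimeError("denoise: no trained model available")
                    pnp_cfg = cfg.pnp_config or PnPConfig(seed=seeds["denoise"] + idx)
                    denoised.append(model.pnp_denoise(y, pnp_cfg).x)
                else:
                    raise ValueError(f"unknown denoise method {cfg.denoise_method!r}")
            denoised_vol = np.stack(denoised)
            lio.write_volume(denoised_vol, out / "denoised.nii", series.voxel_spacing)
            record("denoise", "denoised", out / "denoised.nii")
            manifest["wall_times_s"]["denoise"] = round(time.time() - t0, 3)
            manifest["stages_run"].append("denoise")

        mip = None
        mask2d = None
        if denoised_vol is not None:
            mip = compute_mip(denoised_vol)
            mask2d = lung_mask[slice(*slab)].any(axis=0)
            lio.write_volume(mip, out / "mip.nii", series.voxel_spacing)
            record("denoise", "mip", out / "mip.nii")

        if cfg.stages.get("fd"):
            if mip is None:
                raise RuntimeError("fd: denoise stage required")
            t0 = time.time()
            fmap = fd_map(mip)
            lio.write_volume(fmap.values, out / "fd_map.nii", series.voxel_spacing)
            record("fd", "fd_map", out / "fd_map.nii")
            fig = fd_overlay(mip, fmap, mask2d, path=out / "fd_overlay.png")
            import matplotlib.pyplot as plt

            plt.close(fig)
            record("fd", "fd_overlay", out / "fd_overlay.png")
            manifest["mean_lung_fd"] = fmap.mean(mask2d)
            manifest["wall_times_s"]["fd"] = round(time.time() - t0, 3)
            manifest["stages_run"].append("fd")

        if cfg.stages.get("kmeans"):
            if mip is None:
                raise RuntimeError("kmeans: denoise stage required")
            t0 = time.time()
            seg = kmeans_segment(mip, mask2d, k=3, seed=seeds["kmeans"])
            lio.write_volume(seg.labels.astype(np.float32), out / "kmeans_labels.nii",
                             series.voxel_spacing)
            record("kmeans", "kmeans_labels", out / "kmeans_labels.nii")
            manifest["cluster_means"] = [float(c) for c in seg.cluster_means]
            manifest["wall_times_s"]["kmeans"] = round(time.time() - t0, 3)
            manifest["stages_run"].append("kmeans")

        if cfg.stages.get("metrics"):
            if denoised_vol is None:
                raise RuntimeError("metrics: denoise stage required")
            t0 = time.time()
            rows = []
            clean_ref = None
            if bundle is not None:
                curve = np.asarray(bundle.spec.enhancement_curve)
                clean_enh = (bundle.enhancement[None] * curve[:, None, None, None])[peak_t]
                clean_ref = clean_enh
            for i, z in enumerate(range(*slab)):
                ref = clean_ref[z] if clean_ref is not None else enhanced[z]
                m = image_metrics(denoised_vol[i], ref, mask=lung_mask[z])
                rows.append({"slice": z, "method": cfg.denoise_method,
                             "psnr": m["psnr"], "ssim": m["ssim"],
                             "sharpness": m["sharpness"]})
            with open(out / "metrics.csv", "w", newline="") as fh:
                writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
                writer.writeheader()
                writer.writerows(rows)
            record("metrics", "metrics", out / "metrics.csv")
            manifest["wall_times_s"]["metrics"] = round(time.time() - t0, 3)
            manifest["stages_run"].append("metrics")
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.removeHandler(log_handler)
        log_handler.close()
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.removeHandler(log_handler)
    log_handler.close()
    return manifest
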