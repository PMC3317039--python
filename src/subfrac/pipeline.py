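"""End-to-end orchestration: simulate → (deconvolve) → quantify → analyze.

A run is fully described by a :class:`RunConfig` (loadable from YAML).  Every
randomized stage derives its stream from the single run seed; the config is
serialized verbatim into the output directory, measurement tables carry the
originating config hash in a header comment, and the measurement stage is
cached by that hash so statistics can be re-run without re-imaging.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import membrane, puncta, stats, synth
from .deconv import PSFModel, deconvolve_stack
from .errors import ValidationError

log = logging.getLogger("subfrac")


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    out_dir: str = "subfrac_run"
    seed: int = 0
    # cohort design
    n_subjects_per_dose: int = 4
    neurons_per_side: int = 6
    n_control_scenes: int = 4
    # scene and dose model
    scene: synth.SceneParams = field(default_factory=synth.SceneParams)
    dose_model: synth.DoseModel = field(default_factory=synth.DoseModel)
    # thresholding
    threshold_k: float = 3.0
    min_component_px: int = 4
    # deconvolution
    deconvolve: bool = False
    rl_iterations: int = 3
    deconvolve_channels: tuple[str, ...] = ("receptor", "marker")
    # membrane band
    band_thickness_um: float = 2.0
    # persistence
    save_images: bool = False
    resume: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        scene_raw = dict(raw.pop("scene", {}))
        if "image_shape" in scene_raw:
            scene_raw["image_shape"] = tuple(scene_raw["image_shape"])
        if "psf_sigma_um" in scene_raw:
            scene_raw["psf_sigma_um"] = tuple(scene_raw["psf_sigma_um"])
        scene = synth.SceneParams(**scene_raw)
        dm_raw = raw.pop("dose_model", {})
        if "doses_um" in dm_raw:
            dm_raw["doses_um"] = tuple(dm_raw["doses_um"])
        if "effects" in dm_raw:
            dm_raw["effects"] = {float(k): dict(v)
                                 for k, v in dm_raw["effects"].items()}
        if "spread" in dm_raw:
            dm_raw["spread"] = {float(k): float(v)
                                for k, v in dm_raw["spread"].items()}
        dose_model = synth.DoseModel(**dm_raw)
        if "deconvolve_channels" in raw:
            raw["deconvolve_channels"] = tuple(raw["deconvolve_channels"])
        return cls(scene=scene, dose_model=dose_model, **raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def measurement_hash(self) -> str:
        """Hash of the config subsection that determines the measurements."""
        sub = self.to_dict()
        sub.pop("out_dir")
        sub.pop("resume")
        sub.pop("save_images")
        payload = json.dumps(sub, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_tsv(frame: pd.DataFrame, path: Path, config_hash: str,
               units: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n# units={units}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def derive_run_thresholds(config: RunConfig) -> puncta.ThresholdSpec:
    """Thresholds from simulated negative-control scenes (no puncta)."""
    seeds = np.random.SeedSequence([config.seed, 1]).generate_state(
        config.n_control_scenes)
    controls = []
    for s in seeds:
        params = dataclasses.replace(
            config.scene, n_synaptic=0, n_extrasynaptic=0, n_intracellular=0,
            n_marker_only=0, ring_amplitude=0.0, seed=int(s % (2 ** 31)),
        )
        stack, _ = synth.generate_scene(params)
        if config.deconvolve:
            stack = _deconvolve(stack, config)
        controls.append(stack)
    return puncta.ThresholdSpec(
        receptor_threshold=puncta.derive_threshold(controls, "receptor",
                                                   config.threshold_k),
        marker_threshold=puncta.derive_threshold(controls, "marker",
                                                 config.threshold_k),
        method="control_mean_plus_k_sd",
        k=config.threshold_k,
        min_component_px=config.min_component_px,
    )


def _deconvolve(stack, config: RunConfig):
    psf = PSFModel(sigma_lateral_um=config.scene.psf_sigma_um[0],
                   sigma_axial_um=config.scene.psf_sigma_um[1])
    return deconvolve_stack(stack, psf, config.rl_iterations,
                            channels=config.deconvolve_channels)


def measure_cohort(config: RunConfig) -> pd.DataFrame:
    """Simulate the cohort and run both macros on every neuron."""
    cohort = synth.generate_cohort(
        config.dose_model, config.n_subjects_per_dose,
        config.neurons_per_side, config.scene, seed=config.seed,
    )
    thresholds = derive_run_thresholds(config)
    log.info("thresholds: receptor=%.2f marker=%.2f (k=%g)",
             thresholds.receptor_threshold, thresholds.marker_threshold,
             thresholds.k)
    rows = []
    for stack, truth, meta in cohort:
        if config.deconvolve:
            stack = _deconvolve(stack, config)
        neuropil = puncta.neuropil_measures(stack, thresholds,
                                            with_components=True)
        try:
            mem = membrane.membrane_measures(
                stack, thresholds, thickness_um=config.band_thickness_um,
                keep_masks=False)
            plane, syn_px, ex_px = (mem.plane_index, mem.synaptic_px,
                                    mem.extrasynaptic_px)
        except membrane.TraceFailureError as err:
            raise RuntimeError(
                f"stage quantify-membrane failed for {meta.neuron_id}: {err}"
            ) from err
        rows.append({
            "subject_id": meta.subject_id,
            "neuron_id": meta.neuron_id,
            "dose_um": meta.dose_um,
            "side": meta.side,
            "distance_um": meta.distance_um,
            "neuropil_total_px": neuropil.totals["receptor_px_total"],
            "neuropil_synaptic_px": neuropil.totals["coloc_px_total"],
            "neuropil_receptor_components": neuropil.components[
                "receptor_component_count"],
            "neuropil_coloc_components": neuropil.components[
                "coloc_component_count"],
            "membrane_plane": plane,
            "membrane_synaptic_px": syn_px,
            "membrane_extrasynaptic_px": ex_px,
            "truth_synaptic": truth.counts_true["synaptic"],
            "truth_extrasynaptic": truth.counts_true["extrasynaptic"],
            "truth_intracellular": truth.counts_true["intracellular"],
        })
    return pd.DataFrame(rows)


def analyze_measurements(measurements: pd.DataFrame) -> dict:
    """The statistics battery on a measurement table."""
    out: dict = {}
    for outcome in ("neuropil_total_px", "neuropil_synaptic_px",
                    "membrane_synaptic_px", "membrane_extrasynaptic_px"):
        out[f"anova_{outcome}"] = stats.mixed_anova(measurements, outcome)
        try:
            out[f"tukey_{outcome}"] = stats.tukey_posthoc(measurements, outcome)
        except ValidationError as err:
            log.info("tukey skipped for %s: %s", outcome, err)
    for outcome, covariate in (
        ("neuropil_synaptic_px", "neuropil_total_px"),
        ("membrane_synaptic_px", "neuropil_total_px"),
    ):
        res = stats.ancova(measurements, outcome, covariate)
        out[f"ancova_{outcome}"] = res["table"].reset_index(names="term")
        out[f"ancova_{outcome}_slope"] = res["slope"]
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; deterministic given the config seed.

    Returns a dict with the measurement table, statistics tables and output
    paths.  The measurement stage is cached by config hash: re-running with
    an unchanged imaging configuration reuses ``measurements_<hash>.tsv``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        (out_dir / "config.yaml").write_text(
            yaml.safe_dump(config.to_dict(), sort_keys=True))
        chash = config.measurement_hash()
        meas_path = out_dir / f"measurements_{chash}.tsv"
        if config.resume and meas_path.exists():
            log.info("reusing cached measurements %s", meas_path.name)
            measurements = pd.read_csv(meas_path, sep="\t", comment="#")
        else:
            measurements = measure_cohort(config)
            _write_tsv(measurements, meas_path, chash, "pixels")
        results = analyze_measurements(measurements)
        for name, obj in results.items():
            if isinstance(obj, pd.DataFrame):
                _write_tsv(obj, out_dir / f"{name}.tsv", chash, "F/p")
        log.info("pipeline complete: %d neurons", len(measurements))
        return {"measurements": measurements, "stats": results,
                "out_dir": out_dir, "config_hash": chash,
                "measurements_path": meas_path}
    finally:
        log.removeHandler(handler)
        handler.close()
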