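"""Run configuration, run logging, and the stage pipeline.

A :class:`RunConfig` selects stages and carries every seed and constant;
:func:`run_pipeline` executes the selected stages in declared order.
With identical config and seeds the numerical outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import fiberimg, forcespec, io, synthgen, titration
from .constants import KBT_PNNM

__version__ = "0.1.0"

STAGES = ("simulate", "fit_titration", "analyze_fec", "analyze_kymo")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    outdir: str = "out"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    kbt_pNnm: float = KBT_PNNM
    substrate_length_nt: int = 13552
    site_size_nt: float = 65.0
    baseline_direction: str = "relaxing"
    complete_to_pN: float = 17.5
    equilibrium_drift_tolerance: float = 0.01
    image_k_sd: float = 3.0
    # simulate-stage parameters
    salts_mM: list[float] = field(default_factory=lambda: [0.0, 25.0, 100.0, 250.0])
    condensation_factors: list[float] = field(
        default_factory=lambda: [1.0, 0.8, 0.6, 0.4]
    )
    hysteresis_kBT: float = 1400.0
    n_forces: int = 60
    noise_sd_nm: float = 0.0
    titration_site_sizes_nt: list[float] = field(default_factory=lambda: [43.0, 55.0, 65.0])
    titration_plateaus: list[float] = field(default_factory=lambda: [2.0, 4.0, 6.0])
    titration_noise_sd: float = 0.02
    kymo_lengths_um: list[float] = field(
        default_factory=lambda: list(np.linspace(6.5, 0.5, 16))
    )

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}; valid: {STAGES}")
        if self.kbt_pNnm <= 0 or self.substrate_length_nt <= 0 or self.site_size_nt <= 0:
            raise ValueError("physical constants must be positive")
        if len(self.salts_mM) != len(self.condensation_factors):
            raise ValueError("salts and condensation factors must align")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls(**data)

    def canonical_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=float)

    def hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


@dataclass
class RunLog:
    """Machine-readable record of one pipeline run."""

    config_hash: str
    version: str = __version__
    records: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add(self, stage: str, outputs: list[str], elapsed_s: float) -> None:
        self.records.append(
            {
                "stage": stage,
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
                "elapsed_s": round(elapsed_s, 3),
                "outputs": outputs,
            }
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _force_schedule(cfg: RunConfig) -> np.ndarray:
    return np.linspace(0.05, cfg.complete_to_pN, cfg.n_forces)


def _stage_simulate(cfg: RunConfig, outdir: Path) -> list[str]:
    outputs: list[str] = []
    schedule = _force_schedule(cfg)
    model0 = synthgen.PolymerModel(contour_length_nt=cfg.substrate_length_nt)

    branches = []
    # bare chain at 0 mM: the ledger reference (no hysteresis at zero salt)
    p, r, truth = synthgen.gen_fec_ssdna(
        model0, synthgen.HysteresisModel(), schedule, cfg.noise_sd_nm, seed=cfg.seed
    )
    branches += [p, r]
    io.write_truth(truth, outdir / "fec_ssDNA_0mM.truth.json")
    outputs.append("fec_ssDNA_0mM.truth.json")

    for i, (salt, c) in enumerate(zip(cfg.salts_mM, cfg.condensation_factors)):
        if salt == 0 and c == 1.0:
            continue
        model = synthgen.PolymerModel(
            contour_length_nt=cfg.substrate_length_nt, salt_mM=salt
        )
        if salt > 0:
            hyst = synthgen.HysteresisModel(
                target_hysteresis_energy_kBT=cfg.hysteresis_kBT
            )
            p, r, truth = synthgen.gen_fec_ssdna(
                model, hyst, schedule, cfg.noise_sd_nm, seed=cfg.seed + 100 + i
            )
            branches += [p, r]
            io.write_truth(truth, outdir / f"fec_ssDNA_{salt:g}mM.truth.json")
            outputs.append(f"fec_ssDNA_{salt:g}mM.truth.json")
        coat = synthgen.CoatingModel(condensation_factor=c, site_size_nt=cfg.site_size_nt)
        p, r, truth = synthgen.gen_fec_coated(
            model, coat, schedule, cfg.noise_sd_nm, seed=cfg.seed + 200 + i
        )
        branches += [p, r]
        io.write_truth(truth, outdir / f"fec_SSB_{salt:g}mM.truth.json")
        outputs.append(f"fec_SSB_{salt:g}mM.truth.json")

    io.write_branch_table(branches, outdir / "branches.csv")
    outputs.append("branches.csv")

    curves = []
    for i, (site, plateau, salt) in enumerate(
        zip(cfg.titration_site_sizes_nt, cfg.titration_plateaus, cfg.salts_mM)
    ):
        curve, truth = synthgen.gen_titration(
            site,
            plateau,
            n_points=30,
            ratio_max=2.5 * site,
            noise_sd=cfg.titration_noise_sd * plateau,
            seed=cfg.seed + 300 + i,
            salt_mM=salt,
        )
        curves.append(curve)
        io.write_truth(truth, outdir / f"titration_{salt:g}mM.truth.json")
        outputs.append(f"titration_{salt:g}mM.truth.json")
    io.write_titration_table(curves, outdir / "titrations.csv")
    outputs.append("titrations.csv")

    lengths = np.asarray(cfg.kymo_lengths_um, dtype=float)
    stack, truth = synthgen.gen_kymograph(
        lengths,
        np.full(lengths.size, 1000.0),
        psf_sigma_px=1.0,
        background_mean=100.0,
        background_sd=10.0,
        seed=cfg.seed + 400,
    )
    meta = {
        "pixel_um": truth.params["pixel_um"],
        "frame_interval_s": truth.params["frame_interval_s"],
        "tether_rc": truth.params["tether_rc"],
        "flow_axis": 0,
    }
    io.write_kymograph(stack, meta, outdir / "kymo.tif")
    io.write_truth(truth, outdir / "kymo.truth.json")
    outputs += ["kymo.tif", "kymo.json", "kymo.truth.json"]
    return outputs


def _stage_fit_titration(cfg: RunConfig, outdir: Path) -> list[str]:
    curves = io.read_titration_table(outdir / "titrations.csv")
    fits = [
        titration.fit_site_size(c, n_boot=200, boot_seed=cfg.seed + 500 + i)
        for i, c in enumerate(curves)
    ]
    table = titration.amplitude_vs_salt(fits)
    table.to_csv(outdir / "amplitude_vs_salt.csv", index=False)
    records = [dataclasses.asdict(f) for f in fits]
    (outdir / "site_size_fits.json").write_text(json.dumps(records, indent=1))
    return ["site_size_fits.json", "amplitude_vs_salt.csv"]


def _stage_analyze_fec(cfg: RunConfig, outdir: Path) -> list[str]:
    branches = io.read_branch_table(outdir / "branches.csv")
    anchor_by_salt = {}
    for b in branches:
        if b.condition == "ssDNA" and b.direction == "relaxing":
            f, e = b.sorted_by_force()
            anchor_by_salt[b.salt_mM] = float(np.interp(cfg.complete_to_pN, f, e))
    completed = [
        forcespec.complete_branch(
            b,
            anchor_extension_nm=anchor_by_salt.get(b.salt_mM),
            f_target_pN=cfg.complete_to_pN,
        )
        for b in branches
    ]
    ledger = forcespec.energy_ledger(
        completed,
        reference=("ssDNA", 0.0, "pulling"),
        baseline_direction=cfg.baseline_direction,
        kbt_pNnm=cfg.kbt_pNnm,
    )
    io.write_ledger(ledger, outdir / "ledger.json")
    return ["ledger.json", "ledger.tsv"]


def _stage_analyze_kymo(cfg: RunConfig, outdir: Path) -> list[str]:
    stack, meta = io.read_kymograph(outdir / "kymo.tif")
    traces = fiberimg.analyze_stack(
        stack,
        tether_rc=tuple(meta["tether_rc"]),
        pixel_um=meta["pixel_um"],
        frame_interval_s=meta["frame_interval_s"],
        k_sd=cfg.image_k_sd,
    )
    ref = traces[0].roi_mean_intensity
    traces = fiberimg.normalize_intensity(traces, ref)
    rows = [dataclasses.asdict(t) for t in traces]
    import pandas as pd

    pd.DataFrame(rows).to_csv(outdir / "fiber_trace.csv", index=False)
    return ["fiber_trace.csv"]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "fit_titration": _stage_fit_titration,
    "analyze_fec": _stage_analyze_fec,
    "analyze_kymo": _stage_analyze_kymo,
}


def run_pipeline(cfg: RunConfig) -> RunLog:
    """Execute the configured stages in order; abort on the first failure."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = RunLog(config_hash=cfg.hash())
    for stage in cfg.stages:
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_FN[stage](cfg, outdir)
        except Exception as exc:
            log.warnings.append(f"stage '{stage}' failed: {exc}")
            log.write(outdir / "runlog.json")
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        log.add(stage, outputs, time.perf_counter() - t0)
    log.write(outdir / "runlog.json")
    return log
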