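"""File formats: tidy CSV tables, ledger JSON/TSV, TIFF stacks with JSON sidecars.

All tables are comma-separated UTF-8 with a mandatory header row; units
are encoded in the header names.  JSON is the canonical structured
output.  Image stacks are multi-page 16-bit unsigned TIFF with a JSON
sidecar carrying pixel size, frame interval, tether position and flow
axis; ground-truth records live in a ``*.truth.json`` sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import ForceExtensionBranch, SyntheticTruth, TimeTrace
from .forcespec import EnergyLedger, LedgerEntry
from .titration import TitrationCurve

BRANCH_COLUMNS = ["condition", "salt_mM", "mg_mM", "direction", "force_pN", "extension_nm"]
TITRATION_COLUMNS = ["ratio_nt_per_tet", "fold_enhancement", "salt_mM", "replicate"]
TIMETRACE_COLUMNS = ["time_s", "extension_nm", "force_pN"]


class SchemaError(ValueError):
    """A table violates its declared schema (missing column, bad cell)."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _numeric(df: pd.DataFrame, columns: list[str], path) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = converted.isna() & out[col].notna()
        if bad.any():
            # +2: header row plus 1-based numbering
            lines = [str(i + 2) for i in df.index[bad][:5]]
            raise SchemaError(
                f"{path}: non-numeric value in column '{col}' at line(s) {', '.join(lines)}"
            )
        out[col] = converted
    return out


# --------------------------------------------------------------------------
# force-extension branches
# --------------------------------------------------------------------------

def read_branch_table(path) -> list[ForceExtensionBranch]:
    """Read branches from a tidy CSV, grouped by (condition, salt, direction)."""
    df = pd.read_csv(path)
    _require_columns(df, BRANCH_COLUMNS, path)
    df = _numeric(df, ["salt_mM", "mg_mM", "force_pN", "extension_nm"], path)
    branches = []
    for (cond, salt, mg, direction), grp in df.groupby(
        ["condition", "salt_mM", "mg_mM", "direction"], sort=False
    ):
        branches.append(
            ForceExtensionBranch(
                condition=str(cond),
                salt_mM=float(salt),
                direction=str(direction),
                force_pN=grp["force_pN"].to_numpy(),
                extension_nm=grp["extension_nm"].to_numpy(),
                mg_mM=float(mg),
            )
        )
    return branches


def write_branch_table(branches: list[ForceExtensionBranch], path) -> None:
    rows = []
    for b in branches:
        for f, e in zip(b.force_pN, b.extension_nm):
            rows.append(
                dict(
                    condition=b.condition,
                    salt_mM=b.salt_mM,
                    mg_mM=b.mg_mM,
                    direction=b.direction,
                    force_pN=f,
                    extension_nm=e,
                )
            )
    pd.DataFrame(rows, columns=BRANCH_COLUMNS).to_csv(path, index=False)


# --------------------------------------------------------------------------
# titration tables
# --------------------------------------------------------------------------

def read_titration_table(path) -> list[TitrationCurve]:
    df = pd.read_csv(path)
    _require_columns(df, TITRATION_COLUMNS, path)
    df = _numeric(df, ["ratio_nt_per_tet", "fold_enhancement", "salt_mM"], path)
    curves = []
    for (salt, rep), grp in df.groupby(["salt_mM", "replicate"], sort=False):
        curves.append(
            TitrationCurve(
                ratio=grp["ratio_nt_per_tet"].to_numpy(),
                fold_enhancement=grp["fold_enhancement"].to_numpy(),
                salt_mM=float(salt),
                replicate_id=str(rep),
            )
        )
    return curves


def write_titration_table(curves: list[TitrationCurve], path) -> None:
    rows = []
    for c in curves:
        for r, y in zip(c.ratio, c.fold_enhancement):
            rows.append(
                dict(
                    ratio_nt_per_tet=r,
                    fold_enhancement=y,
                    salt_mM=c.salt_mM,
                    replicate=c.replicate_id,
                )
            )
    pd.DataFrame(rows, columns=TITRATION_COLUMNS).to_csv(path, index=False)


# --------------------------------------------------------------------------
# time traces
# --------------------------------------------------------------------------

def read_timetrace(path) -> TimeTrace:
    df = pd.read_csv(path)
    _require_columns(df, TIMETRACE_COLUMNS, path)
    df = _numeric(df, TIMETRACE_COLUMNS, path)
    return TimeTrace(
        df["time_s"].to_numpy(), df["extension_nm"].to_numpy(), df["force_pN"].to_numpy()
    )


def write_timetrace(trace: TimeTrace, path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.time_s,
            "extension_nm": trace.extension_nm,
            "force_pN": trace.force_pN,
        }
    ).to_csv(path, index=False)


# --------------------------------------------------------------------------
# energy ledger
# --------------------------------------------------------------------------

def write_ledger(ledger: EnergyLedger, path) -> tuple[Path, Path]:
    """Write the ledger as canonical JSON plus a TSV mirror (one row per branch)."""
    path = Path(path)
    json_path = path.with_suffix(".json") if path.suffix != ".json" else path
    tsv_path = json_path.with_suffix(".tsv")

    payload = {
        "reference": list(ledger.reference),
        "baseline_direction": ledger.baseline_direction,
        "kbt_pNnm": ledger.kbt_pNnm,
        "entries": [dataclasses.asdict(e) for e in ledger.entries],
        "hysteresis_kBT": [
            {"condition": c, "salt_mM": s, "hysteresis_kBT": v}
            for (c, s), v in sorted(ledger.hysteresis_kBT.items())
        ],
    }
    json_path.write_text(json.dumps(payload, indent=1, sort_keys=True))

    rows = [dataclasses.asdict(e) for e in ledger.entries]
    pd.DataFrame(
        rows,
        columns=[
            "condition",
            "salt_mM",
            "direction",
            "work_pNnm",
            "dE_kBT",
            "ddE_kBT",
            "extrapolation_error_bound_pNnm",
        ],
    ).to_csv(tsv_path, sep="\t", index=False)
    return json_path, tsv_path


def read_ledger(path) -> EnergyLedger:
    d = json.loads(Path(path).read_text())
    ledger = EnergyLedger(
        reference=tuple(d["reference"]),
        baseline_direction=d["baseline_direction"],
        kbt_pNnm=d["kbt_pNnm"],
    )
    ledger.entries = [LedgerEntry(**e) for e in d["entries"]]
    ledger.hysteresis_kBT = {
        (h["condition"], h["salt_mM"]): h["hysteresis_kBT"] for h in d["hysteresis_kBT"]
    }
    return ledger


# --------------------------------------------------------------------------
# image stacks and truth sidecars
# --------------------------------------------------------------------------

def write_kymograph(stack: np.ndarray, meta: dict, path) -> tuple[Path, Path]:
    """Write a stack as multi-page uint16 TIFF with a JSON metadata sidecar.

    ``meta`` must include pixel_um, frame_interval_s, tether_rc and
    flow_axis; a ``scale`` key records the float-to-uint16 quantization
    factor so intensities can be recovered on read.
    """
    path = Path(path)
    stack = np.asarray(stack, dtype=float)
    lo = min(0.0, float(stack.min()))
    peak = float(stack.max() - lo)
    scale = (65535.0 / peak) if peak > 0 else 1.0
    quantized = np.clip((stack - lo) * scale, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, quantized)
    sidecar = path.with_suffix(".json")
    meta_out = dict(meta) | {"scale": scale, "offset": lo}
    sidecar.write_text(json.dumps(meta_out, indent=1, sort_keys=True))
    return path, sidecar


def read_kymograph(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    raw = tifffile.imread(path).astype(float)
    stack = raw / meta["scale"] + meta["offset"]
    return stack, meta


def write_truth(truth: SyntheticTruth, path) -> Path:
    path = Path(path)
    path.write_text(truth.to_json())
    return path


def read_truth(path) -> SyntheticTruth:
    return SyntheticTruth.from_json(Path(path).read_text())
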