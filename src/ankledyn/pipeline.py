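"""Single-measurement processing chain and batch driver.

The per-folder chain is: parse the folder-name key, read and concatenate
the buffers, low-pass filter, detect the offset (level-windowed histogram
mode), detect direction, segment contractions, extract MVIC features,
assess offset stability, and validate.  The batch driver loops the chain
over every folder in a root, never aborting on a single bad measurement,
and exports a statistician-ready summary table as CSV (canonical) plus a
mirrored XLSX copy.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as ft
from . import offset_detection as od
from . import validation as vl
from .errors import (AnkledynError, EmptyWindow, IndeterminateDirection,
                     NoMeasurements)
from .filtering import FilterCoefficients, FilterSpec, apply_lowpass, design_cheby2
from .io_picoscope import (MeasurementKey, Recording, parse_folder_name,
                           read_measurement_folder)

try:  # py311+: stdlib TOML reader for the plain-text config file
    import tomllib
except ModuleNotFoundError:  # pragma: no cover
    tomllib = None


@dataclass(frozen=True)
class RunConfig:
    """All tunables of the chain, mirroring the module boundaries."""

    filter_order: int = 5
    filter_stopband_db: float = 50.0
    filter_design_cut_hz: float = 29.3935
    filter_enabled: bool = True
    offset_expected_v: float = od.DEFAULT_EXPECTED_OFFSET_V
    offset_half_width_v: float = od.DEFAULT_HALF_WIDTH_V
    offset_bin_width_v: float = od.ADC_QUANTUM_V
    offset_drift_tolerance_v: float = od.DEFAULT_DRIFT_TOLERANCE_V
    features_threshold_frac: float = ft.DEFAULT_THRESHOLD_FRAC
    features_min_hold_s: float = ft.DEFAULT_MIN_HOLD_S
    features_expected_contractions: int = 3
    calibration_gain_nm_per_v: float | None = None
    validation: vl.ValidationConfig = field(default_factory=vl.ValidationConfig)
    dpn_context: bool = False

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        """Load overrides from a TOML-style sectioned key/value file."""
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kw = {}
        for section, prefix in [("filter", "filter_"), ("offset", "offset_"),
                                ("features", "features_"),
                                ("calibration", "calibration_")]:
            for k, v in raw.get(section, {}).items():
                kw[prefix + k] = v
        vcfg = {}
        for k, v in raw.get("validation", {}).items():
            if k == "tremor_band_hz":
                v = tuple(v)
            vcfg[k] = v
        if "dpn_context" in raw:
            kw["dpn_context"] = raw["dpn_context"]
            vcfg.setdefault("dpn_context", raw["dpn_context"])
        if vcfg:
            kw["validation"] = vl.ValidationConfig(**vcfg)
        return cls(**kw)


@dataclass
class MeasurementResult:
    """Everything the chain produced for one measurement folder."""

    folder: str
    key: MeasurementKey | None
    raw: Recording | None
    filtered: Recording | None
    offset: od.OffsetEstimate | None
    features: ft.FeatureSet | None
    stability: od.OffsetStability | None
    report: vl.ValidationReport


def _design(cfg: RunConfig, fs: float) -> FilterCoefficients:
    return design_cheby2(FilterSpec(order=cfg.filter_order,
                                    stopband_atten_db=cfg.filter_stopband_db,
                                    design_cut_hz=cfg.filter_design_cut_hz,
                                    fs_hz=fs))


def process_measurement(folder: str | Path,
                        cfg: RunConfig = RunConfig()) -> MeasurementResult:
    """Run the full chain on one measurement folder.

    Upstream failures become validation codes rather than exceptions, so
    the caller always receives a result with a report.
    """
    folder = Path(folder)
    pre: dict[str, str] = {}
    key = raw = filt = offset = feats = stab = None

    try:
        key = parse_folder_name(folder.name)
    except AnkledynError as exc:
        pre[vl.TECHNICAL_SIGNAL_FAULT] = f"unparseable folder name: {exc}"

    try:
        raw = read_measurement_folder(folder)
    except AnkledynError as exc:
        pre[vl.TECHNICAL_SIGNAL_FAULT] = f"unreadable folder: {exc}"
        report = vl.ValidationReport(status="invalid", codes=frozenset(pre),
                                     notes=pre, dpn_context=cfg.dpn_context,
                                     source=folder.name)
        return MeasurementResult(str(folder), key, None, None, None, None,
                                 None, report)

    filt = apply_lowpass(raw, _design(cfg, raw.fs)) if cfg.filter_enabled else raw

    try:
        window = od.default_window(cfg.offset_expected_v, cfg.offset_half_width_v)
        offset = od.estimate_offset(filt, window=window,
                                    bin_width_v=cfg.offset_bin_width_v)
    except EmptyWindow as exc:
        pre[vl.OFFSET_UNDETECTABLE] = str(exc)

    if offset is not None:
        try:
            direction = ft.detect_direction(filt, offset)
        except IndeterminateDirection as exc:
            pre[vl.TECHNICAL_SIGNAL_FAULT] = f"direction indeterminate: {exc}"
            direction = None
        if direction is not None:
            segments = ft.segment_contractions(
                filt, offset, direction,
                threshold_frac=cfg.features_threshold_frac,
                min_hold_s=cfg.features_min_hold_s)
            cal = None
            if cfg.calibration_gain_nm_per_v:
                cal = ft.Calibration(cfg.calibration_gain_nm_per_v, "config")
            feats = ft.extract_mvic(filt, offset, direction, segments, cal=cal)
            base = ft.baseline_intervals(filt, segments)
            if base:
                try:
                    stab = od.offset_stability(
                        filt, offset, base,
                        bin_width_v=cfg.offset_bin_width_v,
                        half_width_v=cfg.offset_half_width_v,
                        drift_tolerance_v=cfg.offset_drift_tolerance_v)
                except AnkledynError:
                    stab = None

    vcfg = replace(cfg.validation,
                   expected_contractions=cfg.features_expected_contractions,
                   min_hold_s=cfg.features_min_hold_s,
                   drift_tolerance_v=cfg.offset_drift_tolerance_v,
                   dpn_context=cfg.dpn_context or cfg.validation.dpn_context)
    report = vl.validate(filt if filt is not None else raw, key, feats, stab,
                         vcfg, precomputed_codes=pre, source=folder.name)
    return MeasurementResult(str(folder), key, raw, filt, offset, feats,
                             stab, report)


def result_row(res: MeasurementResult) -> dict:
    """Flatten one measurement result into a summary-table row."""
    key, feats = res.key, res.features
    row = {
        "folder": Path(res.folder).name,
        "subject_id": key.subject_id if key else "",
        "foot": key.foot if key else "",
        "direction_keyword": key.direction_flag if key else "",
        "pedal_angle_deg": key.pedal_angle_deg if key else None,
        "offset_v": res.offset.offset_v if res.offset else np.nan,
        "direction_detected": feats.direction if feats else "",
        "n_contractions": feats.n_contractions if feats else 0,
        "mvic_amplitudes_v": ";".join(f"{a:.6f}" for a in feats.mvic_amplitudes_v)
                             if feats else "",
        "mvic_peak_v": feats.mvic_peak_v if feats else np.nan,
        "mvic_mean_v": feats.mvic_mean_v if feats else np.nan,
        "mvic_torque_nm": feats.mvic_torque_nm if feats and
                          feats.mvic_torque_nm is not None else np.nan,
        "inter_mvic_variation": feats.inter_mvic_variation if feats else np.nan,
        "inter_mvic_sd_v": feats.inter_mvic_sd_v if feats else np.nan,
        "steadiness_mean": float(np.mean(feats.intra_mvic_steadiness))
                           if feats is not None and len(feats.intra_mvic_steadiness)
                           else np.nan,
        "offset_drift_v": res.stability.drift_v if res.stability else np.nan,
        "status": res.report.status,
        "codes": ";".join(sorted(res.report.codes)),
    }
    return row


def _folder_digest(folder: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(folder.iterdir()):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def process_cohort(root: str | Path, out_dir: str | Path,
                   cfg: RunConfig = RunConfig(),
                   use_cache: bool = True) -> pd.DataFrame:
    """Process every measurement folder under ``root`` and export the
    summary as CSV and XLSX plus a per-folder outcome log.

    Per-folder rows are cached by a content hash of the folder's files, so
    reruns over an unchanged cohort only touch changed folders.  Raises
    :class:`NoMeasurements` when the root holds no folders.
    """
    root, out_dir = Path(root), Path(out_dir)
    folders = sorted(p for p in root.iterdir() if p.is_dir())
    if not folders:
        raise NoMeasurements(f"no measurement folders under {root}")
    out_dir.mkdir(parents=True, exist_ok=True)

    cache_path = out_dir / "rowcache.json"
    cache = {}
    if use_cache and cache_path.exists():
        cache = json.loads(cache_path.read_text())

    rows, log_lines = [], []
    for folder in folders:
        digest = _folder_digest(folder) if use_cache else None
        cached = cache.get(folder.name)
        if cached is not None and cached.get("digest") == digest:
            row = cached["row"]
        else:
            res = process_measurement(folder, cfg)
            row = result_row(res)
            if use_cache:
                cache[folder.name] = {"digest": digest, "row": row}
        rows.append(row)
        log_lines.append(f"{folder.name}\t{row['status']}\t{row['codes']}")

    if use_cache:
        cache_path.write_text(json.dumps(cache, indent=0, sort_keys=True))

    columns = list(result_row(MeasurementResult(
        "", None, None, None, None, None, None,
        vl.ValidationReport("valid", frozenset(), {}, False))).keys())
    table = (pd.DataFrame(rows)[columns]
             .sort_values("folder").reset_index(drop=True))
    table.to_csv(out_dir / "summary.csv", index=False, float_format="%.6f")
    table.to_excel(out_dir / "summary.xlsx", index=False)
    (out_dir / "process.log").write_text("\n".join(log_lines) + "\n")
    return table
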