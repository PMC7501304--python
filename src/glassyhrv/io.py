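"""File formats, manifest handling, configuration and the pipeline driver.

RR series are plain text, one positive interval (milliseconds) per line,
``#`` comments allowed; the manifest is a CSV with columns
``patient_id,class,path``.  Couplings are exported as CSV (tau,J,sigma_J —
tau is 1-based, matching J(tau) starting at tau = 1), everything else as
JSON.  All internal indexing is 0-based half-open; the 1-based beat/lag
convention appears only at these boundaries.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("glassyhrv")

CLASS_LABELS = ("H", "AF", "CD", "UNKNOWN")

__all__ = [
    "RRSeries",
    "ManifestRecord",
    "DatasetManifest",
    "PipelineConfig",
    "RRFormatError",
    "read_rr_series",
    "write_rr_series",
    "read_manifest",
    "write_manifest",
    "run_pipeline",
]


class RRFormatError(ValueError):
    """Malformed RR file or manifest."""


@dataclass(frozen=True)
class RRSeries:
    """One patient's raw inter-beat intervals in milliseconds."""

    patient_id: str
    class_label: str
    intervals: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", np.asarray(self.intervals, dtype=float))
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}")
        if self.intervals.ndim != 1 or self.intervals.size < 2:
            raise ValueError("an RR series needs at least 2 intervals")
        if np.any(self.intervals <= 0) or not np.all(np.isfinite(self.intervals)):
            raise ValueError("all RR intervals must be positive and finite")

    @property
    def n_beats(self) -> int:
        return self.intervals.size


@dataclass(frozen=True)
class ManifestRecord:
    patient_id: str
    class_label: str
    path: Path


@dataclass(frozen=True)
class DatasetManifest:
    """Patient records plus per-class counts."""

    records: tuple

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise RRFormatError(f"duplicate patient_id(s) in manifest: {dup}")

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.class_label] = counts.get(r.class_label, 0) + 1
        return counts

    def of_class(self, class_label: str) -> list[ManifestRecord]:
        return [r for r in self.records if r.class_label == class_label]


@dataclass
class PipelineConfig:
    """All tunables of the analysis pipeline, JSON round-trippable.

    The cutoff T bounds the coupling range (couplings are negligible beyond
    ~10^2 beats); reg_weight is the pseudo-likelihood penalty lambda; the
    resampling fields follow the minibatch uncertainty scheme (scaled-down
    defaults; the full-scale study design used 500 batches of 20).
    """

    T: int = 100
    reg_weight: float = 1e-2
    learning_rate: float = 0.05
    epsilon: float = 1e-8
    max_epochs: int = 2000
    tolerance: float = 1e-6
    n_batches: int = 50
    batch_size: int = 8
    seed: int = 0
    psd_segment_length: int = 4096
    psd_overlap: float = 0.5
    psd_band: tuple = (1e-4, 1e-2)
    tau_lo_max: int | None = None
    n_synth: int = 100
    autocorr_tau_max: int = 100

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.reg_weight < 0:
            raise ValueError("reg_weight must be nonnegative")
        if not 0 <= self.psd_overlap < 1:
            raise ValueError("psd_overlap must lie in [0, 1)")
        if not self.psd_band[0] < self.psd_band[1]:
            raise ValueError("psd_band lower edge must be below upper edge")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        if "psd_band" in data:
            data["psd_band"] = tuple(data["psd_band"])
        return cls(**data)


def read_rr_series(path, patient_id: str = "", class_label: str = "UNKNOWN") -> RRSeries:
    """Read a plain-text RR file: one interval per line, '#' comments skipped."""
    path = Path(path)
    intervals = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            try:
                value = float(text)
            except ValueError:
                raise RRFormatError(f"{path}:{lineno}: not a number: {text!r}") from None
            if value <= 0 or not np.isfinite(value):
                raise RRFormatError(f"{path}:{lineno}: nonpositive interval {value}")
            intervals.append(value)
    if not intervals:
        raise RRFormatError(f"{path}: no RR intervals found")
    if not patient_id:
        patient_id = path.stem
    return RRSeries(patient_id=patient_id, class_label=class_label, intervals=np.array(intervals))


def write_rr_series(series, path, header: str | None = None) -> None:
    """Write intervals one per line; ``header`` becomes a '#' comment."""
    path = Path(path)
    lines = []
    if header:
        lines.append(f"# {header}")
    values = series.intervals if hasattr(series, "intervals") else np.asarray(series)
    lines.extend(f"{v:.9g}" for v in values)
    path.write_text("\n".join(lines) + "\n")


def read_manifest(path) -> DatasetManifest:
    """Load a patient manifest CSV with header patient_id,class,path."""
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    required = {"patient_id", "class", "path"}
    if not required.issubset(frame.columns):
        raise RRFormatError(f"{path}: manifest must have columns {sorted(required)}")
    records = []
    for row in frame.to_dict("records"):
        label = row["class"]
        if label not in CLASS_LABELS:
            raise RRFormatError(f"{path}: unknown class token {label!r} for {row['patient_id']}")
        rr_path = Path(row["path"])
        if not rr_path.is_absolute():
            rr_path = path.parent / rr_path
        if not rr_path.exists():
            raise RRFormatError(f"{path}: missing RR file {rr_path} for {row['patient_id']}")
        records.append(ManifestRecord(patient_id=row["patient_id"], class_label=label, path=rr_path))
    return DatasetManifest(records=tuple(records))


def write_manifest(manifest: DatasetManifest, path) -> None:
    path = Path(path)
    frame = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in manifest.records],
            "class": [r.class_label for r in manifest.records],
            "path": [str(Path(r.path).name) for r in manifest.records],
        }
    )
    frame.to_csv(path, index=False)


def write_couplings_csv(model, path) -> None:
    frame = pd.DataFrame(
        {
            "tau": np.arange(1, model.T + 1),
            "J": model.J,
            "sigma_J": model.sigma_J,
        }
    )
    frame.to_csv(path, index=False, float_format="%.12g")


def run_pipeline(config: PipelineConfig, manifest: DatasetManifest, class_label: str, out_dir) -> Path:
    """Run standardize -> infer -> fit-tail -> generate -> psd -> validate.

    Writes a couplings CSV and a JSON report under ``out_dir`` and returns
    the report path.  Deterministic for a fixed (config, manifest, seed).
    """
    from glassyhrv import inference, powerlaw, preprocess, spectral, validation

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = manifest.of_class(class_label)
    if not records:
        raise ValueError(f"manifest has no series of class {class_label!r}")
    report: dict = {"class": class_label, "config": asdict(config), "stages": {}}

    def stage(name, fn):
        t0 = time.perf_counter()
        logger.info("stage %s starting (seed=%d, T=%d, lambda=%g, batches=%dx%d)",
                    name, config.seed, config.T, config.reg_weight,
                    config.n_batches, config.batch_size)
        try:
            result = fn()
        except Exception as exc:  # surface the failing stage by name
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        report["stages"][name] = round(time.perf_counter() - t0, 3)
        return result

    series = stage(
        "standardize",
        lambda: [preprocess.standardize(read_rr_series(r.path, r.patient_id, r.class_label)) for r in records],
    )
    plan = inference.ResamplingPlan(config.n_batches, min(config.batch_size, len(series)), config.seed)
    model = stage("infer", lambda: inference.resampled_inference(series, plan, config))
    write_couplings_csv(model, out_dir / f"couplings_{class_label}.csv")
    fit = stage(
        "fit-tail",
        lambda: powerlaw.fit_power_law_tail(model, powerlaw.RangeSearch(tau_lo_max=config.tau_lo_max)),
    )
    seed_series = series[0]
    band = stage(
        "generate-validate",
        lambda: validation.autocorrelation_band(
            seed_series, model, n_synth=config.n_synth, tau_max=config.autocorr_tau_max,
            seed=config.seed,
        ),
    )
    from glassyhrv.generation import convolve_generate, finalize_synthetic, perturb_couplings

    synth = finalize_synthetic(
        convolve_generate(seed_series, perturb_couplings(model, config.seed), model.h)
    )
    seg = min(config.psd_segment_length, len(seed_series) // 2, len(synth) // 2)
    psd = stage("psd", lambda: spectral.welch_psd(seed_series, segment_length=seg, overlap=config.psd_overlap))
    psd_band = spectral.resolvable_band(psd, config.psd_band)
    psd_fit = stage("psd-fit", lambda: spectral.fit_psd_power_law(psd, psd_band))
    ecdf = stage(
        "validate",
        lambda: validation.ecdf_compare(
            np.concatenate([s.values for s in series]), synth.values, p=0.95
        ),
    )
    pd.DataFrame({"frequency": psd.frequencies, "power": psd.power}).to_csv(
        out_dir / f"psd_{class_label}.csv", index=False, float_format="%.9g"
    )
    report.update(
        {
            "h": model.h,
            "sigma_h": model.sigma_h,
            "n_series": len(series),
            "powerlaw": fit.to_dict(),
            "spectral": psd_fit.to_dict(),
            "ecdf": ecdf.to_dict(),
            "autocorr": {"p": band.p, "coverage": band.coverage, "n_synth": config.n_synth},
        }
    )
    report_path = out_dir / f"report_{class_label}.json"
    report_path.write_text(json.dumps(report, indent=1))
    logger.info("pipeline report written to %s", report_path)
    return report_path
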