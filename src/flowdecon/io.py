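"""Event-table I/O, run configuration and the end-to-end pipeline.

The canonical interchange format is a tidy CSV/TSV table with one row per
flow-cytometry event: ``event_id``, one or more channel intensity columns,
optional latent columns (simulation ground truth), and ``population``,
``condition`` (pre / post / control) and ``replicate`` labels.  FCS files are
out of scope for direct ingestion; convert them to this table first.

``run_pipeline`` ties the stages together: per-population deconvolution and
re-convolution validation, per pre/post pair enrichment and gate-survival
prediction, and panel-level outlier / noise statistics.  Stage errors are
collected per population rather than aborting the run, so one
noise-dominated channel does not void a whole panel.
"""

from __future__ import annotations

import hashlib
import json
import warnings
import zlib
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import popstats
from .deconvolution import (
    deconvolve_population,
    reconvolve,
    summarize_moments,
    validate_reconvolution,
)
from .enrichment import (
    EnrichmentModel,
    enrichment_curve,
    infer_survival_function,
    predict_gate_survival,
)
from .simulate import (
    CONDITIONS,
    NoiseModel,
    PopulationSpec,
    ScenarioConfig,
    SignalParams,
    SurvivalModel,
    synthesize_scenario,
)

__all__ = [
    "SchemaError",
    "UnsupportedFormatError",
    "RunConfig",
    "read_events",
    "write_events",
    "scenario_from_dict",
    "load_scenario",
    "load_config",
    "run_pipeline",
    "write_report",
]

#: Non-channel columns of an event table.
RESERVED_COLUMNS = ("event_id", "population", "condition", "replicate")


class SchemaError(ValueError):
    """An event table or config violates the expected schema."""


class UnsupportedFormatError(ValueError):
    """Requested file format cannot be read in this build."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    ``inputs`` maps population label -> event-table path; alternatively a
    scenario can be simulated in place.  ``control`` names the non-fluorescent
    control population used for deconvolution and normalization.
    """

    inputs: Mapping[str, str] = field(default_factory=dict)
    scenario: ScenarioConfig | None = None
    channel: str = "yfp"
    control: str = "control"
    threshold: float = popstats.DEFAULT_THRESHOLD
    gates: tuple[float, float] = (4.1, 779.5)
    grid_points: int = 200
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.gates[1] <= self.gates[0]:
            raise SchemaError("gates must be ordered: low < high")
        if self.threshold <= 0:
            raise SchemaError("threshold must be positive")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    return {"tsv": "tsv", "txt": "tsv", "fcs": "fcs"}.get(suffix, "csv")


def channel_columns(table: pd.DataFrame) -> list[str]:
    """Channel intensity columns: everything not reserved or latent."""
    return [
        c
        for c in table.columns
        if c not in RESERVED_COLUMNS and not c.startswith("latent")
    ]


def validate_events(table: pd.DataFrame, channel: str | None = None) -> pd.DataFrame:
    """Validate the event-table schema; flags negative intensities, keeps them."""
    for column in RESERVED_COLUMNS:
        if column not in table.columns:
            raise SchemaError(f"event table is missing required column {column!r}")
    channels = channel_columns(table)
    if not channels:
        raise SchemaError("event table has no channel intensity column")
    if channel is not None and channel not in channels:
        raise SchemaError(f"event table is missing the channel column {channel!r}")
    for c in channels:
        if not np.issubdtype(np.asarray(table[c]).dtype, np.number):
            raise SchemaError(f"channel column {c!r} is not numeric")
    unknown = set(map(str, table["condition"].unique())) - set(CONDITIONS)
    if unknown:
        raise SchemaError(
            f"unknown condition labels {sorted(unknown)}; expected one of {CONDITIONS}"
        )
    for pop, group in table.groupby("population", observed=True):
        if group["event_id"].duplicated().any():
            raise SchemaError(f"duplicate event_id values within population {pop!r}")
    for c in channels:
        negatives = int((table[c] < 0).sum())
        if negatives:
            warnings.warn(
                f"channel {c!r} contains {negatives} negative intensities "
                "(kept: baseline-subtracted data are accepted but flagged)",
                RuntimeWarning,
                stacklevel=3,
            )
    return table


def read_events(path, fmt: str | None = None, channel: str | None = None) -> pd.DataFrame:
    """Read and validate an event table from CSV or TSV."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "fcs":
        raise UnsupportedFormatError(
            "FCS ingestion is not supported in this build; export the events to a "
            "CSV/TSV table (one row per event, one column per channel) first"
        )
    if fmt not in ("csv", "tsv"):
        raise UnsupportedFormatError(f"unknown event-table format {fmt!r}")
    table = pd.read_csv(path, sep="," if fmt == "csv" else "\t")
    return validate_events(table, channel=channel)


def write_events(table: pd.DataFrame, path, fmt: str | None = None) -> Path:
    """Write an event table as CSV or TSV."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt not in ("csv", "tsv"):
        raise UnsupportedFormatError(f"cannot write event-table format {fmt!r}")
    table.to_csv(path, sep="," if fmt == "csv" else "\t", index=False)
    return path


# ---------------------------------------------------------------------------
# configuration documents
# ---------------------------------------------------------------------------


def scenario_from_dict(doc: Mapping) -> ScenarioConfig:
    """Build a ScenarioConfig from a parsed YAML/JSON document.

    Expected layout::

        channel: yfp
        populations:
          wt:
            signal: {shape: 0.12, scale: 595.0}
            noise: {mean: 1.0, variance: 0.09, family: gamma}
            n: 30000
            survival: {p0: 0.001, beta: 0.5}   # optional
    """
    populations = {}
    for label, spec in dict(doc.get("populations", {})).items():
        signal = SignalParams(**spec["signal"])
        noise_doc = dict(spec.get("noise", {"mean": 1.0, "variance": 0.09}))
        if "pool" in noise_doc:
            noise = NoiseModel.empirical(noise_doc["pool"])
        else:
            noise = NoiseModel.parametric(
                mean=noise_doc["mean"],
                variance=noise_doc["variance"],
                family=noise_doc.get("family", "gamma"),
            )
        survival = (
            SurvivalModel(**spec["survival"]) if spec.get("survival") is not None else None
        )
        populations[label] = PopulationSpec(
            signal=signal,
            noise=noise,
            survival=survival,
            n=int(spec.get("n", 30_000)),
            replicate=int(spec.get("replicate", 1)),
        )
    return ScenarioConfig(populations=populations, channel=doc.get("channel", "yfp"))


def load_scenario(path) -> ScenarioConfig:
    """Load a scenario configuration from a YAML document."""
    with open(path) as handle:
        return scenario_from_dict(yaml.safe_load(handle))


def load_config(path) -> RunConfig:
    """Load a pipeline RunConfig from a YAML document."""
    with open(path) as handle:
        doc = yaml.safe_load(handle)
    scenario = scenario_from_dict(doc["scenario"]) if "scenario" in doc else None
    gates = doc.get("gates", (4.1, 779.5))
    return RunConfig(
        inputs=dict(doc.get("inputs", {})),
        scenario=scenario,
        channel=doc.get("channel", "yfp"),
        control=doc.get("control", "control"),
        threshold=float(doc.get("threshold", popstats.DEFAULT_THRESHOLD)),
        gates=(float(gates[0]), float(gates[1])),
        grid_points=int(doc.get("grid_points", 200)),
        seed=int(doc.get("seed", 0)),
        outdir=doc.get("outdir"),
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _jsonable(obj):
    """Recursively convert numpy / dataclass values into JSON-serializable ones."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj


def _package_version() -> str:
    try:
        return metadata.version("flowdecon")
    except metadata.PackageNotFoundError:  # pragma: no cover - editable edge case
        return "unknown"


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(_jsonable(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_tables(config: RunConfig) -> dict[str, pd.DataFrame]:
    if config.scenario is not None:
        tables = synthesize_scenario(config.scenario, seed=config.seed)
        if config.control not in tables:
            from .simulate import default_autofluorescence, synthesize_control

            tables[config.control] = synthesize_control(
                default_autofluorescence(),
                seed=np.random.SeedSequence([config.seed, 0xC0]),
                channel=config.channel,
                population=config.control,
            )
        return tables
    return {
        label: read_events(path, channel=config.channel)
        for label, path in config.inputs.items()
    }


def run_pipeline(config: RunConfig, tables: Mapping[str, pd.DataFrame] | None = None) -> dict:
    """Run deconvolution, enrichment and population statistics end to end.

    Returns a JSON-serializable report bundle.  Per-population stage failures
    are recorded under ``errors`` with the population and stage name; the
    remaining stages continue.
    """
    if tables is None:
        tables = _load_tables(config)
    if config.control not in tables:
        raise SchemaError(f"control population {config.control!r} not found among inputs")

    channel = config.channel
    control_values = np.asarray(
        tables[config.control][channel], dtype=float
    )
    control_mean = float(control_values.mean())

    bundle: dict = {
        "config": _jsonable(config),
        "config_hash": _config_hash(config),
        "version": _package_version(),
        "seed": config.seed,
        "control": {
            "label": config.control,
            "moments": _jsonable(summarize_moments(control_values, label="noise")),
            "band": popstats.control_band(control_values),
        },
        "populations": {},
        "pairs": {},
        "outliers": {},
        "errors": [],
    }

    fits: dict[tuple[str, str], object] = {}

    for label, table in tables.items():
        if label == config.control:
            continue
        for condition, group in table.groupby("condition", observed=True):
            if len(group) == 0 or condition == "control":
                continue
            key = f"{label}/{condition}"
            raw = np.asarray(group[channel], dtype=float)
            entry: dict = {"n": int(raw.size)}
            try:
                entry["moments"] = _jsonable(summarize_moments(raw, label=channel))
                fit = deconvolve_population(raw, control_values)
                fits[(label, str(condition))] = fit
                entry["gamma"] = {"shape": fit.shape, "scale": fit.scale}
                rc_seed = np.random.SeedSequence([config.seed, zlib.crc32(key.encode())])
                rc = reconvolve(fit, control_values, seed=rc_seed)
                entry["reconvolution"] = _jsonable(validate_reconvolution(raw, rc))
            except Exception as err:  # noqa: BLE001 - collected per stage
                bundle["errors"].append(
                    {"population": label, "stage": f"deconvolution[{condition}]",
                     "error": str(err)}
                )
            bundle["populations"][key] = entry

    for label in {lbl for (lbl, cond) in fits if cond == "pre"}:
        if (label, "post") not in fits:
            continue
        model = EnrichmentModel(before=fits[(label, "pre")], after=fits[(label, "post")])
        try:
            curve = enrichment_curve(model, num=config.grid_points)
            base = infer_survival_function(model)
            entry = {
                "slope": curve.slope,
                "intercept": curve.intercept,
                "fit_range": curve.fit_range,
                "curvature_flag": curve.curvature_flag,
                "beta": base.beta,
                "gates": list(config.gates),
                "survival_ratio": None,
                "shape_mismatch": base.shape_mismatch,
            }
        except Exception as err:  # noqa: BLE001
            bundle["errors"].append(
                {"population": label, "stage": "enrichment", "error": str(err)}
            )
            continue
        bundle["pairs"][label] = entry
        try:
            estimate = predict_gate_survival(model, gates=config.gates)
            entry["survival_ratio"] = estimate.ratio
        except Exception as err:  # noqa: BLE001 - e.g. gate outside support
            bundle["errors"].append(
                {"population": label, "stage": "gate_survival", "error": str(err)}
            )

    for label, table in tables.items():
        if label == config.control:
            continue
        pre = table[table["condition"] == "pre"]
        if len(pre) == 0:
            continue
        try:
            replicates = {
                int(rep): np.asarray(group[channel], dtype=float)
                for rep, group in pre.groupby("replicate", observed=True)
            }
            report = popstats.outlier_report(
                replicates, control_mean, threshold=config.threshold
            )
            bundle["outliers"][label] = _jsonable(report)
        except Exception as err:  # noqa: BLE001
            bundle["errors"].append(
                {"population": label, "stage": "outliers", "error": str(err)}
            )

    return bundle


def write_report(bundle: dict, path) -> Path:
    """Write a report bundle as deterministic (sorted-key) JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(bundle), indent=2, sort_keys=True) + "\n")
    return path
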