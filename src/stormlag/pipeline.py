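"""End-to-end orchestration: simulate -> classify -> design -> fit ->
effects -> attribution, per cause and analysis variant.

Each cause is fit independently (one model per cause).  Admission-type
stratification splits each cause's counts into emergency and
nonemergency components that sum exactly to the all-admissions counts.
A run writes tidy delimited outputs plus a manifest (config echo, file
digests, per-stage log lines) so every run is self-describing and
byte-reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import attribution as attr
from . import design as dsg
from . import exposure as expo
from . import inference as inf
from . import model as mdl
from . import simulate as sim

__all__ = ["AnalysisConfig", "RunManifest", "filter_causes", "run_analysis"]

_EXPOSURE_MODES = {"binary", "three_category"}
_TEMP_MODES = {"lag0", "lags0_7", "none"}
_ADMISSION = {"all", "emergency", "nonemergency"}


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration for a full analysis run."""

    causes: tuple[str, ...] = ("cause_a",)
    exposure_mode: str = "binary"
    temperature_mode: str = "lag0"
    admission_type: str = "all"
    emergency_fraction: float = 0.6
    cause_threshold: int = 50_000
    n_causes_alpha: int = 13
    max_lag: int = 7
    seed: int = 0
    out_dir: str = "stormlag_run"
    sim_overrides: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.exposure_mode not in _EXPOSURE_MODES:
            raise ValueError(f"exposure_mode must be one of {_EXPOSURE_MODES}")
        if self.temperature_mode not in _TEMP_MODES:
            raise ValueError(f"temperature_mode must be one of {_TEMP_MODES}")
        if self.admission_type not in _ADMISSION:
            raise ValueError(f"admission_type must be one of {_ADMISSION}")
        if self.cause_threshold < 0:
            raise ValueError("cause_threshold must be >= 0")

    def sim_config(self, cause_index: int) -> sim.SimConfig:
        overrides = dict(self.sim_overrides)
        overrides["seed"] = _derive_seed(self.seed, cause_index)
        return sim.SimConfig(**overrides)


def _derive_seed(seed: int, index: int) -> int:
    # stable sub-seed per cause, kept below 2**31
    h = hashlib.sha256(f"{seed}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunManifest:
    config: dict
    outputs: dict[str, str] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def add_output(self, path: Path) -> None:
        self.outputs[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def filter_causes(totals: dict[str, float], threshold: float = 50_000) -> list[str]:
    """Retain causes with strictly more hospitalizations than the
    threshold; output sorted by cause name for determinism."""
    if any(v < 0 for v in totals.values()):
        raise ValueError("totals must be non-negative")
    return sorted(name for name, total in totals.items() if total > threshold)


def _split_admissions(
    panel: pd.DataFrame, frac: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binomially thin counts into emergency / nonemergency components
    that sum exactly to the original counts."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 977]))
    emer = rng.binomial(panel["count"].to_numpy(), frac)
    e = panel.copy()
    e["count"] = emer
    ne = panel.copy()
    ne["count"] = panel["count"].to_numpy() - emer
    return e, ne


def _fit_one(
    panel: pd.DataFrame,
    exposure: pd.DataFrame,
    config: AnalysisConfig,
    cause: str,
    out: Path,
    manifest: RunManifest,
) -> None:
    options = dsg.DesignOptions(
        exposure_mode=config.exposure_mode,
        temperature_mode=config.temperature_mode,
        max_lag=config.max_lag,
    )
    design = dsg.build_design(panel, exposure, options)
    manifest.log.append(
        f"{cause}: design rows={design.X.shape[0]} cols={design.X.shape[1]} "
        f"strata_dropped={design.n_strata_dropped}"
    )
    fit = mdl.fit_conditional_quasipoisson(design)
    if fit.dropped_columns:
        manifest.log.append(f"{cause}: dropped columns {fit.dropped_columns}")
    manifest.log.append(
        f"{cause}: converged={fit.converged} iter={fit.iterations} "
        f"dispersion={fit.dispersion:.4f}"
    )
    fit_path = out / f"{cause}_fit.txt"
    fit_path.write_text(fit.report() + "\n")
    manifest.add_output(fit_path)

    blocks = (
        ["exposure"] if config.exposure_mode == "binary" else ["gale", "hurricane"]
    )
    tables = [
        inf.effects_table(fit, config.n_causes_alpha, block=b, cause=cause)
        for b in blocks
    ]
    eff_path = out / f"{cause}_effects.csv"
    pd.concat(tables, ignore_index=True).to_csv(
        eff_path, index=False, float_format="%.10g"
    )
    manifest.add_output(eff_path)

    baselines = attr.county_baseline_rates(panel, exposure)
    cum, _ = inf.cumulative_and_average_effects(
        fit, config.n_causes_alpha, block=blocks[0]
    )
    result = attr.excess_hospitalizations(baselines, cum, cause=cause)
    lag_df = inf.lag_effects(fit, config.n_causes_alpha, block=blocks[0])
    decomp = attr.lag_decomposition(baselines, lag_df, cause=cause)
    attr_path = out / f"{cause}_attribution.csv"
    summary = pd.DataFrame(
        [
            {
                "cause": cause,
                "lag": "cumulative",
                "excess": result.excess,
                "ci_low": result.ci_low,
                "ci_high": result.ci_high,
            }
        ]
    )
    pd.concat([summary, decomp.astype({"lag": str})], ignore_index=True).to_csv(
        attr_path, index=False, float_format="%.10g"
    )
    manifest.add_output(attr_path)


def run_analysis(config: AnalysisConfig) -> RunManifest:
    """Run the full pipeline for every configured cause.

    Simulates one panel per cause (sub-seeded from the run seed),
    classifies exposures from the simulated winds, fits the model,
    writes effect and attribution tables, and returns the manifest.
    Any stage failure propagates with the cause name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={f.name: getattr(config, f.name) for f in dataclasses.fields(config)},
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    for i, cause in enumerate(config.causes):
        try:
            panel, truth = sim.simulate_panel(config.sim_config(i))
            manifest.log.append(
                f"{cause}: simulated {len(panel)} rows, "
                f"{len(truth.exposure_calendar)} exposure days"
            )
            wind = panel[["county_id", "date", "wind_knots"]]
            exposure = expo.make_exposure_panel(wind, panel[["county_id", "date"]])
            if config.admission_type != "all":
                e_panel, ne_panel = _split_admissions(
                    panel, config.emergency_fraction, config.sim_config(i).seed
                )
                panel_used = e_panel if config.admission_type == "emergency" else ne_panel
            else:
                panel_used = panel
            _fit_one(panel_used, exposure, config, cause, out, manifest)
        except Exception as exc:
            raise RuntimeError(f"stage failure for cause {cause!r}: {exc}") from exc
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out / "manifest.json")
    return manifest


def read_config(path) -> AnalysisConfig:
    """Parse a flat key = value config file into an AnalysisConfig."""
    raw: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        raw[key.strip()] = val.strip()
    kwargs: dict = {}
    if "causes" in raw:
        kwargs["causes"] = tuple(c.strip() for c in raw.pop("causes").split(","))
    for key, cast in (
        ("exposure_mode", str),
        ("temperature_mode", str),
        ("admission_type", str),
        ("emergency_fraction", float),
        ("cause_threshold", int),
        ("n_causes_alpha", int),
        ("max_lag", int),
        ("seed", int),
        ("out_dir", str),
    ):
        if key in raw:
            kwargs[key] = cast(raw.pop(key))
    sim_fields = {f.name: f for f in dataclasses.fields(sim.SimConfig)}
    overrides = []
    for key, val in raw.items():
        if key in sim_fields:
            typ = sim_fields[key].type
            if key in ("population_range",):
                parsed = tuple(int(v) for v in val.split(","))
            elif key in ("dow_log_effects", "true_beta_lags"):
                parsed = tuple(float(v) for v in val.split(","))
            elif "int" in str(typ):
                parsed = int(val)
            else:
                parsed = float(val)
            overrides.append((key, parsed))
        else:
            raise KeyError(f"unknown config key {key!r}")
    if overrides:
        kwargs["sim_overrides"] = tuple(overrides)
    return AnalysisConfig(**kwargs)
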