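"""Configuration loading, validation, output writing, and fixtures.

Config files are YAML or JSON (auto-detected by extension) with up to four
sections — ``trial``, ``thresholds``, ``allocation``, ``population``,
``scenarios`` — of which only ``trial.arms`` is required.  Every design
default the protocol states is applied automatically: Beta(100,100) prior,
x = y = 0.95, equivalence margin 0.01, ceiling 10 000, interim analysis every
100 outcomes.  Population rates and arm effects have no defaults: whoever
runs a simulation owns those assumptions.  Validation is all-at-once: every
defect is reported with its field path in a single error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .bayes import BetaParams
from .allocation import AllocationSpec
from .engine import Arm, TrialConfig
from .errors import ConfigurationError, InvalidInputError
from .oc import Scenario
from .population import PopulationSpec, Subgroup
from .stopping import StoppingThresholds

__all__ = ["LoadedConfig", "RunManifest", "load_config", "write_outputs", "make_fixture"]

FIXTURE_NAMES = ("two_arm_null", "two_arm_d3", "extreme_effect", "equity_toy")


@dataclass
class LoadedConfig:
    trial: TrialConfig
    population: PopulationSpec | None = None
    scenarios: list[Scenario] = field(default_factory=list)
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        return hashlib.sha1(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class RunManifest:
    """Record of one run: config identity, seed, version, timing, outputs."""

    config_hash: str
    master_seed: int
    package_version: str
    started_at: float
    finished_at: float | None = None
    output_paths: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _read_structured(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    elif path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        # fall back: YAML is a JSON superset
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return data


def _get(section: Mapping, key: str, default: Any = None) -> Any:
    return section.get(key, default) if section else default


def load_config(path: str | Path) -> LoadedConfig:
    """Parse and validate a config file, applying protocol defaults.

    Raises :class:`ConfigurationError` listing *every* defect found, each
    prefixed with its field path.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw = _read_structured(path)
    defects: list[str] = []

    trial_sec = raw.get("trial") or {}
    arms_raw = _get(trial_sec, "arms")
    arms: list[Arm] = []
    if not arms_raw:
        defects.append("trial.arms: required (list of arm definitions)")
    else:
        for i, a in enumerate(arms_raw):
            if isinstance(a, str):
                arms.append(Arm(a, is_control=(i == 0)))
            elif isinstance(a, Mapping):
                arm_id = a.get("id") or a.get("arm_id")
                if not arm_id:
                    defects.append(f"trial.arms[{i}].id: required")
                    continue
                arms.append(Arm(str(arm_id), bool(a.get("control", a.get("is_control", False)))))
            else:
                defects.append(f"trial.arms[{i}]: must be a string or mapping")

    prior_sec = _get(trial_sec, "prior") or {}
    try:
        prior = BetaParams(
            float(_get(prior_sec, "alpha", 100.0)), float(_get(prior_sec, "beta", 100.0))
        )
    except (InvalidInputError, TypeError, ValueError) as e:
        defects.append(f"trial.prior: {e}")
        prior = BetaParams(100.0, 100.0)

    th_sec = raw.get("thresholds") or {}
    try:
        ceiling = _get(th_sec, "ceiling_n", 10_000)
        thresholds = StoppingThresholds(
            x_best=float(_get(th_sec, "x_best", 0.95)),
            y_equiv=float(_get(th_sec, "y_equiv", 0.95)),
            margin=float(_get(th_sec, "margin", 0.01)),
            ceiling_n=None if ceiling in (None, "none") else int(ceiling),
        )
    except (ConfigurationError, TypeError, ValueError) as e:
        defects.append(f"thresholds: {e}")
        thresholds = StoppingThresholds()

    master_seed = int(_get(trial_sec, "master_seed", 0))

    alloc_sec = raw.get("allocation") or {}
    allocation = None
    if alloc_sec and arms:
        try:
            allocation = AllocationSpec(
                arm_ids=tuple(a.arm_id for a in arms),
                ratio=tuple(_get(alloc_sec, "ratio", ()) or ()),
                block_sizes=tuple(_get(alloc_sec, "block_sizes", ()) or ()),
                strata=(
                    tuple(alloc_sec["strata"]) if _get(alloc_sec, "strata") else None
                ),
                seed=int(_get(alloc_sec, "seed", master_seed)),
            )
        except (ConfigurationError, TypeError, ValueError) as e:
            defects.append(f"allocation: {e}")

    trial = None
    if arms:
        try:
            trial = TrialConfig(
                arms=arms,
                prior=prior,
                thresholds=thresholds,
                allocation=allocation,
                interim_every_outcomes=int(
                    _get(trial_sec, "interim_every_outcomes", 100)
                ),
                comparison_draws=int(_get(trial_sec, "comparison_draws", 100_000)),
                comparison_method=str(_get(trial_sec, "comparison_method", "auto")),
                master_seed=master_seed,
            )
        except (ConfigurationError, TypeError, ValueError) as e:
            defects.append(f"trial: {e}")

    pop_sec = raw.get("population") or {}
    population = None
    if pop_sec:
        try:
            subgroups = tuple(
                Subgroup(
                    str(s["label"]),
                    float(s["prevalence"]),
                    float(s["baseline_attendance"]),
                )
                for s in _get(pop_sec, "subgroups", [])
            )
            population = PopulationSpec(
                subgroups=subgroups,
                arm_effects=dict(_get(pop_sec, "arm_effects", {})),
                referrals_per_window=int(_get(pop_sec, "referrals_per_window", 100)),
                window_hours=float(_get(pop_sec, "window_hours", 72.0)),
                seed=int(_get(pop_sec, "seed", master_seed)),
            )
        except (ConfigurationError, KeyError, TypeError, ValueError) as e:
            defects.append(f"population: {e!r}")

    scenarios: list[Scenario] = []
    for i, s in enumerate(raw.get("scenarios") or []):
        try:
            sc_th = StoppingThresholds(
                x_best=float(s.get("x_best", thresholds.x_best)),
                y_equiv=float(s.get("y_equiv", thresholds.y_equiv)),
                margin=float(s.get("margin", thresholds.margin)),
                ceiling_n=(
                    None
                    if s.get("ceiling_n", None) in (None, "none")
                    else int(s["ceiling_n"])
                ),
            )
            scenarios.append(
                Scenario(
                    effect_d=float(s.get("effect_d", 0.0)),
                    control_rate=float(s.get("control_rate", 0.50)),
                    thresholds=sc_th,
                    n_sims=int(s.get("n_sims", 1000)),
                    base_seed=int(s.get("base_seed", master_seed)),
                    interim_every_outcomes=int(s.get("interim_every_outcomes", 100)),
                    prior=prior,
                    comparison_method=str(s.get("comparison_method", "exact")),
                )
            )
        except (ConfigurationError, TypeError, ValueError) as e:
            defects.append(f"scenarios[{i}]: {e}")

    if defects:
        raise ConfigurationError(defects)
    assert trial is not None
    return LoadedConfig(trial=trial, population=population, scenarios=scenarios, raw=raw)


def serialise_config(loaded: LoadedConfig) -> dict:
    """Config dict that round-trips through :func:`load_config`."""
    trial = loaded.trial
    out: dict[str, Any] = {
        "trial": {
            "arms": [
                {"id": a.arm_id, "control": a.is_control} for a in trial.arms
            ],
            "prior": {"alpha": trial.prior.alpha, "beta": trial.prior.beta},
            "interim_every_outcomes": trial.interim_every_outcomes,
            "comparison_draws": trial.comparison_draws,
            "comparison_method": trial.comparison_method,
            "master_seed": trial.master_seed,
        },
        "thresholds": {
            "x_best": trial.thresholds.x_best,
            "y_equiv": trial.thresholds.y_equiv,
            "margin": trial.thresholds.margin,
            "ceiling_n": trial.thresholds.ceiling_n,
        },
        "allocation": {
            "ratio": list(trial.allocation.ratio),
            "block_sizes": list(trial.allocation.block_sizes),
            "strata": list(trial.allocation.strata) if trial.allocation.strata else None,
            "seed": trial.allocation.seed,
        },
    }
    if loaded.population is not None:
        pop = loaded.population
        out["population"] = {
            "subgroups": [
                {
                    "label": s.label,
                    "prevalence": s.prevalence,
                    "baseline_attendance": s.baseline_attendance,
                }
                for s in pop.subgroups
            ],
            "arm_effects": {
                k: dict(v) if isinstance(v, Mapping) else v
                for k, v in pop.arm_effects.items()
            },
            "referrals_per_window": pop.referrals_per_window,
            "window_hours": pop.window_hours,
            "seed": pop.seed,
        }
    if loaded.scenarios:
        out["scenarios"] = [
            {
                "effect_d": sc.effect_d,
                "control_rate": sc.control_rate,
                "x_best": sc.thresholds.x_best,
                "y_equiv": sc.thresholds.y_equiv,
                "margin": sc.thresholds.margin,
                "ceiling_n": sc.thresholds.ceiling_n,
                "n_sims": sc.n_sims,
                "base_seed": sc.base_seed,
                "interim_every_outcomes": sc.interim_every_outcomes,
                "comparison_method": sc.comparison_method,
            }
            for sc in loaded.scenarios
        ]
    return out


def write_outputs(
    out_dir: str | Path,
    master_seed: int,
    config_hash: str,
    **artefacts: pd.DataFrame | Mapping,
) -> RunManifest:
    """Write tabular artefacts as CSV and structured ones as JSON.

    Each keyword becomes ``<name>.csv`` (DataFrame) or ``<name>.json``
    (mapping).  Numeric formatting is locale-independent at full float
    precision.  The manifest, written last, references every emitted file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    probe = out_dir / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as e:
        raise InvalidInputError(f"output directory not writable: {out_dir}: {e}")
    manifest = RunManifest(
        config_hash=config_hash,
        master_seed=master_seed,
        package_version=__version__,
        started_at=time.time(),
    )
    for name, obj in artefacts.items():
        if isinstance(obj, pd.DataFrame):
            path = out_dir / f"{name}.csv"
            obj.to_csv(path, index=False, float_format="%.17g")
        elif isinstance(obj, Mapping):
            path = out_dir / f"{name}.json"
            path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
        else:
            raise InvalidInputError(
                f"artefact {name!r} must be a DataFrame or mapping, got {type(obj)}"
            )
        manifest.output_paths.append(str(path))
    manifest.finished_at = time.time()
    manifest_path = out_dir / "manifest.json"
    manifest.output_paths.append(str(manifest_path))
    manifest_path.write_text(json.dumps(manifest.to_dict(), indent=2, sort_keys=True))
    return manifest


def _fixture_config(name: str) -> dict:
    base = {
        "trial": {
            "arms": [
                {"id": "control", "control": True},
                {"id": "intervention", "control": False},
            ],
            "master_seed": 1,
        },
        "thresholds": {},
    }
    if name == "two_arm_null":
        base["population"] = {
            "subgroups": [
                {"label": "all", "prevalence": 1.0, "baseline_attendance": 0.50}
            ],
            "arm_effects": {"control": 0.0, "intervention": 0.0},
            "seed": 1,
        }
        base["scenarios"] = [
            {"effect_d": 0.0, "control_rate": 0.50, "n_sims": 300, "base_seed": 1,
             "ceiling_n": None}
        ]
    elif name == "two_arm_d3":
        base["population"] = {
            "subgroups": [
                {"label": "all", "prevalence": 1.0, "baseline_attendance": 0.50}
            ],
            "arm_effects": {"control": 0.0, "intervention": 0.03},
            "seed": 1,
        }
        base["scenarios"] = [
            {"effect_d": 0.03, "control_rate": 0.50, "n_sims": 1000, "base_seed": 1,
             "ceiling_n": None}
        ]
    elif name == "extreme_effect":
        base["population"] = {
            "subgroups": [
                {"label": "all", "prevalence": 1.0, "baseline_attendance": 0.50}
            ],
            "arm_effects": {"control": 0.0, "intervention": 0.40},
            "seed": 1,
        }
    elif name == "equity_toy":
        base["population"] = {
            "subgroups": [
                {"label": "A", "prevalence": 0.05, "baseline_attendance": 0.20},
                {"label": "B", "prevalence": 0.08, "baseline_attendance": 0.25},
                {"label": "C", "prevalence": 0.87, "baseline_attendance": 0.60},
            ],
            "arm_effects": {"control": 0.0, "intervention": 0.0},
            "seed": 1,
        }
    return base


def _equity_toy_participants() -> pd.DataFrame:
    """Deterministic three-group toy table: A 5%/20%, B 8%/25%, C 87%/60%."""
    rows = []
    spec = [("A", 50, 10), ("B", 80, 20), ("C", 870, 522)]
    i = 0
    for label, n_ref, n_att in spec:
        for j in range(n_ref):
            rows.append(
                {
                    "participant_id": f"P{i:07d}",
                    "subgroup": label,
                    "window": 0,
                    "arm": "control",
                    "attended": j < n_att,
                }
            )
            i += 1
    return pd.DataFrame(rows)


def make_fixture(name: str, out_dir: str | Path) -> dict[str, Path]:
    """Emit a small ready-to-run config (and deterministic companion files).

    Available fixtures: two_arm_null (null-effect simulation scenario),
    two_arm_d3 (the 3-point-effect simulation scenario), extreme_effect
    (a 0.50 vs 0.90 single trial), equity_toy (a three-group attendance table
    whose left-behind set is {A, B}).
    """
    if name not in FIXTURE_NAMES:
        raise InvalidInputError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    config_path = out_dir / f"{name}.yaml"
    config_path.write_text(yaml.safe_dump(_fixture_config(name), sort_keys=False))
    paths["config"] = config_path
    if name == "equity_toy":
        table_path = out_dir / "equity_toy_participants.csv"
        _equity_toy_participants().to_csv(table_path, index=False)
        paths["participants"] = table_path
        expected_path = out_dir / "equity_toy_expected.json"
        expected_path.write_text(
            json.dumps(
                {
                    "left_behind_groups": ["A", "B"],
                    "group_attendance": {"A": 0.20, "B": 0.25, "C": 0.60},
                },
                indent=2,
            )
        )
        paths["expected"] = expected_path
    return paths
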