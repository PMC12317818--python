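"""YAML / CSV interfaces for parameters, diets and feeding schedules."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .deb_core import DEBCoreParams
from .digestion import DigestionParams
from .feed_chemistry import (CompoundComposition, DietSpec,
                             default_library, diet_from_proximate)
from .params import ModelParams
from .simulation import FeedingSchedule, Meal, Scenario

__all__ = [
    "load_params", "save_params", "load_diet", "load_schedule",
    "load_scenario",
]


def save_params(params: ModelParams, path) -> None:
    data = {
        "core": dataclasses.asdict(params.core),
        "digestion": dataclasses.asdict(params.digestion),
        "library": {k: v.as_dict() for k, v in params.library.items()},
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_params(path) -> ModelParams:
    data = yaml.safe_load(Path(path).read_text())
    library = ({k: CompoundComposition(**v)
                for k, v in data.get("library", {}).items()}
               or default_library())
    return ModelParams(core=DEBCoreParams(**data["core"]),
                       digestion=DigestionParams(**data["digestion"]),
                       library=library)


def load_diet(path, library=None, name=None) -> DietSpec:
    """Diet YAML: {protein, fat, carb, ash, moisture, adc: {...},
    densities: {dry, wet}} on a dry-matter basis."""
    data = yaml.safe_load(Path(path).read_text())
    return diet_from_proximate(
        {k: data.get(k, 0.0) for k in ("protein", "fat", "carb", "ash")},
        data["adc"],
        library=library,
        densities=data.get("densities"),
        moisture=data.get("moisture", 0.09),
        name=name or data.get("name", Path(path).stem),
    )


def load_schedule(path) -> FeedingSchedule:
    """Feeding schedule CSV/YAML: rows of (time d, ration fraction, diet id);
    an empty file is fasting."""
    path = Path(path)
    if path.suffix in (".yml", ".yaml"):
        rows = yaml.safe_load(path.read_text()) or []
        meals = [Meal(time=float(r["time"]), ration=float(r["ration"]),
                      diet_id=str(r.get("diet", "default"))) for r in rows]
    else:
        df = pd.read_csv(path)
        meals = [Meal(time=float(r.time), ration=float(r.ration),
                      diet_id=str(getattr(r, "diet", "default")))
                 for r in df.itertuples()]
    return FeedingSchedule(meals=tuple(sorted(meals, key=lambda m: m.time)))


def load_scenario(path, library=None) -> Scenario:
    """Scenario YAML combining duration, initial weight, temperature,
    inline diets and either an inline schedule or daily-feeding shorthand."""
    data = yaml.safe_load(Path(path).read_text())
    diets = {}
    for name, d in data["diets"].items():
        diets[name] = diet_from_proximate(
            {k: d.get(k, 0.0) for k in ("protein", "fat", "carb", "ash")},
            d["adc"], library=library, densities=d.get("densities"),
            moisture=d.get("moisture", 0.09), name=name)
    if "schedule" in data:
        meals = tuple(Meal(time=float(r["time"]), ration=float(r["ration"]),
                           diet_id=str(r.get("diet", next(iter(diets)))))
                      for r in data["schedule"])
        schedule = FeedingSchedule(meals=meals)
    else:
        feeding = data["feeding"]
        schedule = FeedingSchedule.daily(
            duration=float(data["duration"]),
            daily_fraction=float(feeding["daily_fraction"]),
            meals_per_day=int(feeding.get("meals_per_day", 1)),
            diet_id=str(feeding.get("diet", next(iter(diets)))),
        )
    temp = data["temperature"]
    if isinstance(temp, list):
        temp = [(float(p["time"]), float(p["T_C"])) for p in temp]
    return Scenario(
        duration=float(data["duration"]),
        initial_weight=float(data["initial_weight"]),
        temperature=temp,
        schedule=schedule,
        diets=diets,
        n_fish=int(data.get("n_fish", 1)),
        output_resolution=data.get("output_resolution", "hourly"),
        f_initial=float(data.get("f_initial", 0.8)),
    )
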