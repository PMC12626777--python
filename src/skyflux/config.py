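"""Flat YAML configuration for simulations and the analysis pipeline.

A config file is a flat mapping whose keys mirror
:class:`~skyflux.simulate.SimulationConfig` (station and forward-model
parameters) and :class:`~skyflux.model.PipelineConfig` (analysis
knobs).  Nested structures use simple list syntax:

    station_name: SYNTH
    station_latitude: 35.333
    station_longitude: -97.278
    station_altitude: 370.0
    start_date: 2022-04-01
    end_date: 2022-04-30
    nocturnal_peak_offset: 4.0
    wind_profile: [[0, 2, 4], [1500, 8, 9], [3000, 11, 10]]
    rain_episodes: [["2022-04-03 01:00", "2022-04-03 05:00", 0.6]]
    seed: 1
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from pathlib import Path

import yaml

from .model import PipelineConfig
from .series import Station
from .simulate import RainEpisode, SimulationConfig

__all__ = ["load_config", "save_config"]

_STATION_KEYS = {
    "station_name": "name",
    "station_latitude": "latitude",
    "station_longitude": "longitude",
    "station_altitude": "altitude_m",
}
_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)} - {"station"}
_PIPE_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)}


def _as_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def load_config(path) -> tuple[SimulationConfig, PipelineConfig]:
    """Parse a flat YAML config into simulation + pipeline settings."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")

    st_kwargs = {}
    sim_kwargs = {}
    pipe_kwargs = {}
    for key, value in raw.items():
        if key in _STATION_KEYS:
            st_kwargs[_STATION_KEYS[key]] = value
        elif key in _SIM_FIELDS:
            sim_kwargs[key] = value
        elif key in _PIPE_FIELDS:
            pipe_kwargs[key] = value
        else:
            raise ValueError(f"{path}: unknown config key {key!r}")

    if "start_date" in sim_kwargs:
        sim_kwargs["start_date"] = _as_date(sim_kwargs["start_date"])
    if "end_date" in sim_kwargs:
        sim_kwargs["end_date"] = _as_date(sim_kwargs["end_date"])
    if "wind_profile" in sim_kwargs:
        sim_kwargs["wind_profile"] = tuple(tuple(map(float, node)) for node in sim_kwargs["wind_profile"])
    if "rain_episodes" in sim_kwargs:
        sim_kwargs["rain_episodes"] = tuple(
            RainEpisode(start, end, float(frac)) for start, end, frac in sim_kwargs["rain_episodes"]
        )
    if "elevations_deg" in sim_kwargs:
        sim_kwargs["elevations_deg"] = tuple(map(float, sim_kwargs["elevations_deg"]))
    if "envelope_q" in pipe_kwargs:
        pipe_kwargs["envelope_q"] = tuple(map(float, pipe_kwargs["envelope_q"]))

    if st_kwargs:
        st_kwargs.setdefault("name", "SYNTH")
        sim_kwargs["station"] = Station(**st_kwargs)
    return SimulationConfig(**sim_kwargs), PipelineConfig(**pipe_kwargs)


def save_config(sim: SimulationConfig, pipe: PipelineConfig, path) -> None:
    """Write settings back out as flat YAML."""
    flat = {
        "station_name": sim.station.name,
        "station_latitude": sim.station.latitude,
        "station_longitude": sim.station.longitude,
        "station_altitude": sim.station.altitude_m,
    }
    for f in dataclasses.fields(SimulationConfig):
        if f.name == "station":
            continue
        value = getattr(sim, f.name)
        if isinstance(value, dt.date):
            value = value.isoformat()
        elif f.name == "wind_profile":
            value = [list(node) for node in value]
        elif f.name == "rain_episodes":
            value = [[str(ep.start), str(ep.end), ep.fraction] for ep in value]
        elif isinstance(value, tuple):
            value = list(value)
        flat[f.name] = value
    for f in dataclasses.fields(PipelineConfig):
        value = getattr(pipe, f.name)
        flat[f.name] = list(value) if isinstance(value, tuple) else value
    Path(path).write_text(yaml.safe_dump(flat, sort_keys=False))
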