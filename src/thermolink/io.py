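"""File formats, unit conversions, and analysis configuration.

Conventions at the file boundary follow electrophysiology reporting habits:
temperatures in degrees Celsius, calcium in millimolar, currents in pA,
times in seconds.  Internally everything is kelvin / molar / pA / seconds;
each conversion happens exactly once, here.

Formats (all plain text):

* traces — TSV with header ``time_s<TAB>current_pA`` plus an optional
  JSON sidecar (same path + ``.meta.json``) holding recording metadata;
* idealized events — TSV ``start_s  level  duration_s``;
* dose–response tables — CSV/TSV with header
  ``temperature_C,calcium_mM,po[,sem][,n_patches]``;
* model parameters and analysis configs — JSON with explicit unit keys;
  couplings are either ``{"value": v}`` or
  ``{"dH_J_per_mol": ..., "dS_J_per_mol_K": ...}``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .linkage import DoseResponsePoint
from .models import (
    Coupling,
    FourStateModel,
    GeneralizedModel,
    SensorModel,
    VantHoffCoupling,
    celsius_to_kelvin,
)
from .single_channel import IdealizedRecord, Trace

__all__ = [
    "ParseError",
    "AnalysisConfig",
    "parse_coupling",
    "coupling_to_json",
    "load_model",
    "save_model",
    "default_mthk_model",
    "default_vant_hoff",
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "read_dose_response",
    "write_dose_response",
    "config_hash",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Input file violated the documented schema; message names the line."""


# ---------------------------------------------------------------------------
# couplings and model configs


def parse_coupling(obj) -> Coupling:
    """Parse a coupling entry: a bare number, ``{"value": v}`` or a van't Hoff pair."""
    if isinstance(obj, (int, float)):
        return float(obj)
    if not isinstance(obj, dict):
        raise ParseError(f"coupling entry must be a number or object (got {obj!r})")
    if "dH_J_per_mol" in obj or "dS_J_per_mol_K" in obj:
        try:
            return VantHoffCoupling(
                dH=float(obj["dH_J_per_mol"]), dS=float(obj["dS_J_per_mol_K"])
            )
        except KeyError as exc:
            raise ParseError(f"van't Hoff coupling needs both dH_J_per_mol and dS_J_per_mol_K: {obj}") from exc
    if "value" in obj:
        return float(obj["value"])
    raise ParseError(f"cannot interpret coupling entry {obj!r}")


def coupling_to_json(c: Coupling) -> dict:
    if isinstance(c, VantHoffCoupling):
        return {"dH_J_per_mol": c.dH, "dS_J_per_mol_K": c.dS}
    return {"value": float(c)}


_FOUR_STATE_KEYS = ("L0", "K_Ca", "theta_UC", "theta_UO", "theta_BC", "theta_BO")
_SENSOR_KEYS = ("L0", "D", "C", "E", "M0")


def load_model(source: Union[PathLike, dict]):
    """Load a model from a JSON file or an already-parsed dict.

    The ``model_type`` key selects ``four_state``, ``sensor`` or
    ``generalized``; parameters live under ``parameters``.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = json.load(fh)
    else:
        cfg = source
    mtype = cfg.get("model_type")
    params = cfg.get("parameters", {})
    if mtype == "four_state":
        missing = [k for k in _FOUR_STATE_KEYS if k not in params]
        if missing:
            raise ParseError(f"four_state model missing parameters: {missing}")
        return FourStateModel(**{k: parse_coupling(params[k]) for k in _FOUR_STATE_KEYS})
    if mtype == "sensor":
        missing = [k for k in _SENSOR_KEYS if k not in params]
        if missing:
            raise ParseError(f"sensor model missing parameters: {missing}")
        kwargs = {k: parse_coupling(params[k]) for k in _SENSOR_KEYS}
        for k in ("L0", "D", "C", "E"):
            if isinstance(kwargs[k], VantHoffCoupling):
                raise ParseError(f"sensor parameter {k} must be a fixed number")
        if "K" in params:
            kwargs["K"] = parse_coupling(params["K"])
        return SensorModel(**kwargs)
    if mtype == "generalized":
        try:
            alpha = params.get("alpha")
            return GeneralizedModel(
                L0=float(params["L0"]["value"] if isinstance(params["L0"], dict) else params["L0"]),
                K=[float(v) for v in params["K"]],
                theta_UC=[float(v) for v in params["theta_UC"]],
                theta_UO=[float(v) for v in params["theta_UO"]],
                theta_BC=[float(v) for v in params["theta_BC"]],
                theta_BO=[float(v) for v in params["theta_BO"]],
                alpha=np.asarray(alpha, dtype=float) if alpha is not None else None,
            )
        except KeyError as exc:
            raise ParseError(f"generalized model missing parameter: {exc}") from exc
    raise ParseError(f"unknown model_type {mtype!r}")


def save_model(model, path: PathLike, **extra) -> None:
    """Serialize a model to the JSON schema read by :func:`load_model`."""
    if isinstance(model, FourStateModel):
        cfg = {
            "schema_version": 1,
            "model_type": "four_state",
            "parameters": {k: coupling_to_json(getattr(model, k)) for k in _FOUR_STATE_KEYS},
        }
    elif isinstance(model, SensorModel):
        cfg = {
            "schema_version": 1,
            "model_type": "sensor",
            "parameters": {
                **{k: coupling_to_json(getattr(model, k)) for k in _SENSOR_KEYS},
                "K": coupling_to_json(model.K),
            },
        }
    elif isinstance(model, GeneralizedModel):
        cfg = {
            "schema_version": 1,
            "model_type": "generalized",
            "parameters": {
                "L0": model.L0,
                "K": list(model.K),
                "theta_UC": list(model.theta_UC),
                "theta_UO": list(model.theta_UO),
                "theta_BC": list(model.theta_BC),
                "theta_BO": list(model.theta_BO),
                **({"alpha": np.asarray(model.alpha).tolist()} if model.alpha is not None else {}),
            },
        }
    else:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    cfg.update(extra)
    Path(path).write_text(json.dumps(cfg, indent=2) + "\n")


def _default_config() -> dict:
    with resources.files("thermolink.data").joinpath("mthk_ir_default.json").open() as fh:
        return json.load(fh)


def default_vant_hoff(coupling_name: str) -> VantHoffCoupling:
    """The shipped van't Hoff (dH, dS) pair for one of the four couplings."""
    cfg = _default_config()
    try:
        vh = cfg["vant_hoff_variants"][coupling_name]
    except KeyError as exc:
        raise KeyError(
            f"no van't Hoff variant for {coupling_name!r}; "
            f"available: {sorted(cfg['vant_hoff_variants'])}"
        ) from exc
    return VantHoffCoupling(dH=vh["dH_J_per_mol"], dS=vh["dS_J_per_mol_K"])


#: Reference temperature (21 degC) at which an anchored van't Hoff coupling
#: equals its static value.
ANCHOR_T_K = 294.15


def default_mthk_model(
    vant_hoff: Sequence[str] = (),
    anchor_T_K: Optional[float] = ANCHOR_T_K,
) -> FourStateModel:
    """The shipped default MthK four-state model.

    ``vant_hoff`` names couplings (e.g. ``("theta_UC",)``) whose static
    value is replaced by the shipped van't Hoff temperature dependence —
    the standard way to make exactly one interaction term
    temperature-sensitive in simulations.

    By default the substitution is *anchored*: the shipped dH sets the
    temperature sensitivity while dS is re-derived so the coupling equals
    its static value at ``anchor_T_K`` (21 degC).  This keeps the
    temperature-dependent model consistent with the static one at the
    reference temperature, which the raw shipped (dH, dS) pairs are not.
    Pass ``anchor_T_K=None`` to use the raw pairs verbatim.
    """
    import math

    from .models import R_GAS

    cfg = _default_config()
    model = load_model(cfg)
    replacements = {}
    for name in vant_hoff:
        vh = default_vant_hoff(name)
        if anchor_T_K is not None:
            static = getattr(model, name)
            # exp(-(dH - T*dS)/(R*T)) == static at T = anchor_T_K
            dS = (vh.dH + R_GAS * anchor_T_K * math.log(static)) / anchor_T_K
            vh = VantHoffCoupling(dH=vh.dH, dS=dS)
        replacements[name] = vh
    return dataclasses.replace(model, **replacements)


# ---------------------------------------------------------------------------
# traces


def write_trace(trace: Trace, path: PathLike) -> None:
    """Write a trace as TSV (time_s, current_pA) with a JSON metadata sidecar."""
    path = Path(path)
    t = np.arange(trace.current.size) * trace.dt
    df = pd.DataFrame({"time_s": t, "current_pA": trace.current})
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps({"dt_s": trace.dt, **trace.metadata}, indent=2) + "\n")


def read_trace(path: PathLike) -> Trace:
    """Read a TSV trace; validates the header and time-column monotonicity."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("time_s", "current_pA"):
        if col not in df.columns:
            raise ParseError(f"{path}:1: missing required column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    dt_steps = np.diff(t)
    bad = np.flatnonzero(dt_steps <= 0)
    if bad.size:
        raise ParseError(
            f"{path}:{bad[0] + 3}: time column is not strictly increasing"
        )  # +3: header line + 1-based + offset into diffs
    dt = float(np.median(dt_steps)) if t.size > 1 else 1.0
    metadata: dict = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text())
        dt = float(metadata.pop("dt_s", dt))
    return Trace(dt=dt, current=df["current_pA"].to_numpy(dtype=float), metadata=metadata)


# ---------------------------------------------------------------------------
# idealized event tables


def write_events(record: IdealizedRecord, path: PathLike) -> None:
    """Write an idealized record as TSV (start_s, level, duration_s)."""
    rows = []
    t = 0.0
    for lvl, dur in record.events:
        rows.append({"start_s": t, "level": lvl, "duration_s": dur})
        t += dur
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False, float_format="%.9g")


def read_events(path: PathLike, n_channels: int = 1) -> IdealizedRecord:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("start_s", "level", "duration_s"):
        if col not in df.columns:
            raise ParseError(f"{path}:1: missing required column {col!r}")
    if (df["duration_s"] <= 0).any():
        line = int(df.index[df["duration_s"] <= 0][0]) + 2
        raise ParseError(f"{path}:{line}: non-positive event duration")
    events = [(int(l), float(d)) for l, d in zip(df["level"], df["duration_s"])]
    return IdealizedRecord(events=events, n_channels=n_channels)


# ---------------------------------------------------------------------------
# dose–response tables


def _sniff_sep(path: Path) -> str:
    header = path.read_text().splitlines()[0] if path.read_text() else ""
    return "\t" if "\t" in header else ","


def read_dose_response(path: PathLike) -> list[DoseResponsePoint]:
    """Read a dose–response table (temperature_C, calcium_mM, po[, sem, n_patches]).

    Temperatures are converted degC -> K and calcium mM -> M on read.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    for col in ("temperature_C", "calcium_mM", "po"):
        if col not in df.columns:
            raise ParseError(f"{path}:1: missing required column {col!r}")
    points = []
    for i, row in df.iterrows():
        line = int(i) + 2
        po = float(row["po"])
        if not 0.0 <= po <= 1.0:
            raise ParseError(f"{path}:{line}: po={po} outside [0, 1]")
        ca = float(row["calcium_mM"])
        if ca < 0:
            raise ParseError(f"{path}:{line}: negative calcium concentration")
        sem = None
        if "sem" in df.columns and pd.notna(row["sem"]):
            sem = float(row["sem"])
            if sem < 0:
                raise ParseError(f"{path}:{line}: negative sem")
        n_patches = (
            int(row["n_patches"])
            if "n_patches" in df.columns and pd.notna(row["n_patches"])
            else None
        )
        points.append(
            DoseResponsePoint(
                temperature=celsius_to_kelvin(float(row["temperature_C"])),
                calcium=ca * 1e-3,
                po=po,
                sem=sem,
                n_patches=n_patches,
            )
        )
    return points


def write_dose_response(points: Sequence[DoseResponsePoint], path: PathLike) -> None:
    """Write dose–response points with file-boundary units (degC, mM)."""
    rows = [
        {
            "temperature_C": p.temperature - 273.15,
            "calcium_mM": p.calcium * 1e3,
            "po": p.po,
            "sem": p.sem if p.sem is not None else "",
            "n_patches": p.n_patches if p.n_patches is not None else "",
        }
        for p in points
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# analysis configuration


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline options; every quantity carries its unit in the field name.

    Defaults follow common single-channel practice: 1.4 kHz digital
    filtering, a 0.04 ms event dead time, at most 4 dwell-mixture
    components selected at 95% confidence, and 1000 bootstrap replicates.
    """

    filter_fc_Hz: float = 1400.0
    min_event_duration_s: float = 4e-5
    k_max: int = 4
    confidence: float = 0.95
    n_boot: int = 1000
    seed: int = 0
    n_channels: int = 1
    open_current_pA: float = 10.0
    noise_sd_pA: float = 1.0
    sampling_rate_Hz: float = 25000.0

    @classmethod
    def from_json(cls, source: Union[PathLike, dict]) -> "AnalysisConfig":
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                cfg = json.load(fh)
        else:
            cfg = dict(source)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(cfg) - known - {"schema_version"}
        if unknown:
            raise ParseError(f"unknown analysis-config keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in cfg.items() if k in known})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
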