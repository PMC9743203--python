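"""File formats: FPT sample CSV, potential config files, run manifests.

Everything on disk is flat text.  First-passage ensembles are stored as CSV
with ``# key=value`` comment headers carrying provenance (protocol, rate or
period, potential form, seed, temperature, dt) followed by one row per
trajectory: ``tau_ps,censored,resets``.  Internally every time is ps and
every rate ps⁻¹; values in ns are accepted on read only with an explicit
unit suffix (``0.1 ns^-1`` → 1e-4 ps⁻¹) and converted immediately.
"""

from __future__ import annotations

import hashlib
import json
import re
import time
from dataclasses import dataclass

import numpy as np

from . import __version__
from .fpt_stats import FPTSampleSet
from .potentials import PotentialSpec, default_spec

__all__ = [
    "FormatError",
    "parse_rate",
    "parse_time",
    "read_fpt_csv",
    "write_fpt_csv",
    "read_potential_config",
    "write_potential_config",
    "RunManifest",
]


class FormatError(ValueError):
    """Malformed input file."""


_RATE_UNITS = {"ps^-1": 1.0, "1/ps": 1.0, "ps-1": 1.0,
               "ns^-1": 1e-3, "1/ns": 1e-3, "ns-1": 1e-3,
               "fs^-1": 1e3, "1/fs": 1e3}
_TIME_UNITS = {"ps": 1.0, "ns": 1e3, "fs": 1e-3, "us": 1e6}


def _parse_with_units(text, units: dict, what: str) -> float:
    if isinstance(text, (int, float)):
        return float(text)
    s = str(text).strip()
    m = re.fullmatch(r"([-+0-9.eE]+)\s*([^\s]*)", s)
    if not m:
        raise FormatError(f"cannot parse {what} {text!r}")
    value = float(m.group(1))
    unit = m.group(2)
    if not unit:
        return value
    if unit not in units:
        raise FormatError(f"unknown {what} unit {unit!r} in {text!r}")
    return value * units[unit]


def parse_rate(text) -> float:
    """Rate string → ps⁻¹ ('0.1 ns^-1' → 1e-4; bare numbers are ps⁻¹)."""
    return _parse_with_units(text, _RATE_UNITS, "rate")


def parse_time(text) -> float:
    """Time string → ps ('2 ns' → 2000; bare numbers are ps)."""
    return _parse_with_units(text, _TIME_UNITS, "time")


# ---------------------------------------------------------------------------
# FPT sample CSV
# ---------------------------------------------------------------------------

def write_fpt_csv(samples: FPTSampleSet, path) -> None:
    """Serialize an ensemble: `# key=value` headers + tau_ps,censored,resets."""
    meta = dict(samples.metadata)
    meta["protocol"] = samples.protocol_kind
    if samples.rate is not None:
        meta["rate"] = f"{samples.rate:.12g} ps^-1"
    if samples.period is not None:
        meta["period"] = f"{samples.period:.12g} ps"
    meta["n"] = samples.n
    meta["censored_count"] = samples.n_censored
    resets = (samples.resets if samples.resets is not None
              else np.zeros(samples.n, dtype=int))
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        fh.write("tau_ps,censored,resets\n")
        for tau, cen, res in zip(samples.tau, samples.censored, resets):
            fh.write(f"{tau:.12g},{int(cen)},{int(res)}\n")


def read_fpt_csv(path) -> FPTSampleSet:
    """Parse an FPT ensemble CSV written by :func:`write_fpt_csv`.

    Provenance headers are required (inference needs to know the protocol
    and its r*); negative passage times are a format error.
    """
    meta: dict = {}
    rows: list[tuple[float, int, int]] = []
    with open(path) as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                cols = [c.strip() for c in line.split(",")]
                if cols[0] != "tau_ps":
                    raise FormatError(
                        f"{path}:{lineno}: expected 'tau_ps,...' column "
                        f"header, got {line!r}")
                header_seen = True
                continue
            parts = line.split(",")
            try:
                tau = float(parts[0])
                cen = int(parts[1]) if len(parts) > 1 else 0
                res = int(parts[2]) if len(parts) > 2 else 0
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad row {line!r}") from exc
            if tau < 0:
                raise FormatError(
                    f"{path}:{lineno}: negative passage time {tau}")
            rows.append((tau, cen, res))
    if "protocol" not in meta:
        raise FormatError(
            f"{path}: missing '# protocol=...' header; inference requires "
            "the resetting protocol and its rate")
    protocol = meta.pop("protocol")
    rate = parse_rate(meta.pop("rate")) if "rate" in meta else None
    period = parse_time(meta.pop("period")) if "period" in meta else None
    if protocol == "poisson" and rate is None:
        raise FormatError(f"{path}: poisson provenance requires a "
                          "'# rate=...' header")
    meta.pop("n", None)
    meta.pop("censored_count", None)
    tau = np.array([r[0] for r in rows])
    cen = np.array([bool(r[1]) for r in rows])
    res = np.array([r[2] for r in rows], dtype=int)
    return FPTSampleSet(tau=tau, censored=cen, protocol_kind=protocol,
                        rate=rate, period=period, resets=res, metadata=meta)


# ---------------------------------------------------------------------------
# Potential configuration files (flat key = value text)
# ---------------------------------------------------------------------------

def read_potential_config(path) -> PotentialSpec:
    """Flat ``key = value`` file → PotentialSpec.

    Recognized keys: ``form`` (required), ``temperature`` (K),
    ``box_<axis> = lo hi`` per dimension; every other numeric key is a
    potential parameter.  ``form = <name>`` alone loads the shipped
    calibrated defaults; explicit parameter keys override them.
    """
    form = None
    temperature = None
    params: dict = {}
    box: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "form":
                form = value
            elif key == "temperature":
                temperature = float(value)
            elif key.startswith("box"):
                lo, hi = (float(v) for v in value.replace(",", " ").split())
                box[key] = (lo, hi)
            else:
                try:
                    params[key] = float(value)
                except ValueError:
                    params[key] = value
    if form is None:
        raise FormatError(f"{path}: missing 'form = ...'")
    temperature = temperature if temperature is not None else 300.0
    try:
        spec = default_spec(form, temperature=temperature)
        merged = dict(spec.parameters)
        merged.update(params)
        params = merged
        dim = spec.dimensionality
    except Exception:
        dim = 2 if any(k in params for k in ("box_y",)) or \
            form.endswith("2d") else 1
    box_tuple = ()
    if box:
        order = sorted(box)  # box, box_x, box_y
        box_tuple = tuple(box[k] for k in order)
    return PotentialSpec(form=form, parameters=params, dimensionality=dim,
                         box=box_tuple, temperature=temperature)


def write_potential_config(spec: PotentialSpec, path) -> None:
    axes = "xyz"
    with open(path, "w") as fh:
        fh.write(f"form = {spec.form}\n")
        fh.write(f"temperature = {spec.temperature:g}\n")
        for i, (lo, hi) in enumerate(spec.box):
            fh.write(f"box_{axes[i]} = {lo:g} {hi:g}\n")
        for key, value in spec.parameters.items():
            fh.write(f"{key} = {value!r}\n" if isinstance(value, str)
                     else f"{key} = {value:.12g}\n")


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce an output file bit-for-bit."""

    command: str
    configuration: dict
    seed: int | None
    inputs: dict
    outputs: dict
    version: str = __version__
    timestamp: str = ""

    @classmethod
    def create(cls, command: str, configuration: dict, seed: int | None,
               input_paths=(), output_paths=()) -> "RunManifest":
        return cls(
            command=command,
            configuration=configuration,
            seed=seed,
            inputs={str(p): _digest(p) for p in input_paths},
            outputs={str(p): _digest(p) for p in output_paths},
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
            fh.write("\n")
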