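"""Tiny declarative distribution specs used by the season simulator.

A spec is a plain dict, e.g. ``{"kind": "lognormal", "mu": 4.25, "sigma": 0.7,
"lo": 1, "hi": 300, "integer": True}``.  Keeping specs as data makes simulation
configs serializable to YAML/JSON without custom tags.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError

_KINDS = {"constant", "poisson", "normal", "lognormal", "uniform_int", "negbinom"}


def validate_spec(spec: dict, name: str = "distribution") -> None:
    if not isinstance(spec, dict) or "kind" not in spec:
        raise ConfigurationError(f"{name}: spec must be a dict with a 'kind' key")
    kind = spec["kind"]
    if kind not in _KINDS:
        raise ConfigurationError(f"{name}: unknown distribution kind {kind!r}")
    required = {
        "constant": ["value"],
        "poisson": ["mean"],
        "normal": ["mean", "sd"],
        "lognormal": ["mu", "sigma"],
        "uniform_int": ["lo", "hi"],
        "negbinom": ["mean", "dispersion"],
    }[kind]
    for key in required:
        if key not in spec:
            raise ConfigurationError(f"{name}: {kind} spec requires {key!r}")
    if kind == "normal" and spec["sd"] < 0:
        raise ConfigurationError(f"{name}: sd must be >= 0")
    if kind == "poisson" and spec["mean"] < 0:
        raise ConfigurationError(f"{name}: mean must be >= 0")


def spec_mean(spec: dict) -> float:
    """Approximate mean of a spec (before clipping), for config validation."""
    kind = spec["kind"]
    offset = spec.get("offset", 0.0)
    if kind == "constant":
        return spec["value"] + offset
    if kind in ("poisson", "normal", "negbinom"):
        return spec["mean"] + offset
    if kind == "lognormal":
        return float(np.exp(spec["mu"] + spec["sigma"] ** 2 / 2)) + offset
    if kind == "uniform_int":
        return (spec["lo"] + spec["hi"]) / 2 + offset
    raise ConfigurationError(f"unknown kind {kind!r}")


def draw(spec: dict, rng: np.random.Generator, size: int) -> np.ndarray:
    """Draw ``size`` values from a spec with optional offset/clip/rounding."""
    validate_spec(spec)
    kind = spec["kind"]
    if kind == "constant":
        x = np.full(size, float(spec["value"]))
    elif kind == "poisson":
        x = rng.poisson(spec["mean"], size).astype(float)
    elif kind == "normal":
        x = rng.normal(spec["mean"], spec["sd"], size)
    elif kind == "lognormal":
        x = rng.lognormal(spec["mu"], spec["sigma"], size)
    elif kind == "uniform_int":
        x = rng.integers(spec["lo"], spec["hi"] + 1, size).astype(float)
    elif kind == "negbinom":
        # mean/dispersion parameterization: var = mean + mean^2/dispersion
        m, k = float(spec["mean"]), float(spec["dispersion"])
        p = k / (k + m)
        x = rng.negative_binomial(k, p, size).astype(float)
    x = x + spec.get("offset", 0.0)
    lo, hi = spec.get("lo"), spec.get("hi")
    if lo is not None or hi is not None:
        x = np.clip(x, lo, hi)
    if spec.get("integer", False):
        x = np.rint(x)
    return x
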