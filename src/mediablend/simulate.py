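"""Synthetic phenotype landscapes for testing blending and optimization.

A ground-truth response surface assigns every medium a noise-free
phenotype (an OD600- or titer-like positive number) built multiplicatively
from per-component effect curves and pairwise synergies:

    mean(medium) = baseline * prod_c f_c(conc_c) * prod_{(c,d) present} gamma_cd

Effect shapes mirror the response classes seen in real media screens:

* ``essential`` — Monod-type saturation f = f_max * c / (K + c); zero
  without the component (trace elements, nitrogen source).
* ``boost`` — saturating benefit f = 1 + (f_max - 1) * c / (K + c); the
  phenotype is fine without the supplement (f(0) = 1) but improves up to
  f_max with it (beneficial supplements).
* ``peaked`` — unimodal f = f_max * (c / c_opt) * exp(1 - c / c_opt),
  maximal at c_opt (carbon sources: too little starves, too much
  inhibits).
* ``inhibitory`` — f = 1 / (1 + slope * c), monotone decline
  (detrimental surfactants).
* ``inert`` — f = 1 everywhere.

Replicate noise is multiplicative log-normal: each replicate is the mean
times exp(eps), eps ~ Normal(0, sigma) with sigma = sqrt(ln(1 + cv^2)), so
the coefficient of variation of the replicates equals ``noise_cv`` and
values stay positive.  Measurements are deterministic given (truth seed,
replicate seed, medium name, replicate index).
"""

from __future__ import annotations

import json
import math
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blending import MediumSpec
from .errors import InvalidShapeParameters

SHAPES = ("essential", "boost", "peaked", "inert", "inhibitory")
TRUTH_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ComponentEffect:
    """One component's effect curve on the phenotype."""

    shape: str
    f_max: float | None = None
    K: float | None = None
    c_opt: float | None = None
    slope: float | None = None

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise InvalidShapeParameters(f"unknown shape {self.shape!r}")
        if self.shape in ("essential", "boost"):
            if self.f_max is None or not self.f_max > 0:
                raise InvalidShapeParameters(f"{self.shape}: f_max must be > 0")
            if self.K is None or not self.K > 0:
                raise InvalidShapeParameters(f"{self.shape}: K must be > 0")
        elif self.shape == "peaked":
            if self.f_max is None or not self.f_max > 0:
                raise InvalidShapeParameters("peaked: f_max must be > 0")
            if self.c_opt is None or not self.c_opt > 0:
                raise InvalidShapeParameters("peaked: c_opt must be > 0")
        elif self.shape == "inhibitory":
            if self.slope is None or not self.slope > 0:
                raise InvalidShapeParameters("inhibitory: slope must be > 0")

    def multiplier(self, c: float) -> float:
        """Effect multiplier at concentration c >= 0."""
        if c < 0:
            raise ValueError("concentration must be >= 0")
        if self.shape == "inert":
            return 1.0
        if self.shape == "essential":
            return self.f_max * c / (self.K + c)
        if self.shape == "boost":
            return 1.0 + (self.f_max - 1.0) * c / (self.K + c)
        if self.shape == "peaked":
            if c == 0:
                return 0.0
            return self.f_max * (c / self.c_opt) * math.exp(1.0 - c / self.c_opt)
        # inhibitory
        return 1.0 / (1.0 + self.slope * c)


def boost_effect(screening_conc: float, effect: float, saturation: float = 0.9) -> ComponentEffect:
    """Boost shape calibrated to multiply the phenotype by ``effect`` exactly
    at the screening concentration, saturating at ``saturation`` of f_max there."""
    if not effect > 1:
        raise InvalidShapeParameters("effect must be > 1 for a beneficial boost")
    K = screening_conc * (1 - saturation) / saturation
    f_max = 1 + (effect - 1) / saturation
    return ComponentEffect(shape="boost", f_max=f_max, K=K)


@dataclass
class Measurement:
    medium_name: str
    replicate_index: int
    value: float


@dataclass
class ResponseSurfaceTruth:
    """Fully specified ground-truth landscape.

    ``interactions`` maps an unordered component pair to a synergy
    multiplier gamma > 0 applied when both components are present
    (concentration > 0) in the medium.
    """

    baseline: float
    component_effects: dict[str, ComponentEffect]
    interactions: dict[frozenset, float] = field(default_factory=dict)
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.baseline > 0:
            raise InvalidShapeParameters("baseline must be > 0")
        if self.noise_cv < 0:
            raise InvalidShapeParameters("noise_cv must be >= 0")
        self.interactions = {frozenset(k): float(v) for k, v in self.interactions.items()}
        for pair, gamma in self.interactions.items():
            if not gamma > 0:
                raise InvalidShapeParameters(f"synergy for {sorted(pair)} must be > 0")

    # -- evaluation ------------------------------------------------------

    def _lookup(self, medium: MediumSpec) -> dict[str, float]:
        """Concentration of every truth component in the medium (0 if absent)."""
        concs = {name: 0.0 for name in self.component_effects}
        lower = {name.lower(): name for name in self.component_effects}
        for item, (conc, _unit) in medium.targets.items():
            key = lower.get(item.lower())
            if key is None:
                warnings.warn(
                    f"medium item {item!r} unknown to the truth; treated as inert",
                    stacklevel=3,
                )
            else:
                concs[key] = conc
        return concs

    def true_mean(self, medium: MediumSpec) -> float:
        """Noise-free phenotype of a medium."""
        concs = self._lookup(medium)
        value = self.baseline
        for name, effect in self.component_effects.items():
            value *= effect.multiplier(concs[name])
        for pair, gamma in self.interactions.items():
            if all(concs.get(c, 0.0) > 0 for c in pair):
                value *= gamma
        return value


def evaluate(
    truth: ResponseSurfaceTruth,
    medium: MediumSpec,
    n_replicates: int,
    replicate_seed: int = 0,
) -> list[Measurement]:
    """Simulated replicate measurements of one medium.

    With ``noise_cv`` = 0 the result is exactly the noise-free mean and is
    seed-independent.  Otherwise each replicate draws its own log-normal
    factor from a stream keyed by (truth seed, replicate seed, medium
    name, replicate index), so repeated calls are reproducible.
    """
    mean = truth.true_mean(medium)
    out = []
    if truth.noise_cv == 0:
        return [Measurement(medium.name, i + 1, mean) for i in range(n_replicates)]
    sigma = math.sqrt(math.log(1.0 + truth.noise_cv**2))
    name_key = zlib.crc32(medium.name.encode())
    for i in range(n_replicates):
        rng = np.random.default_rng(
            [truth.seed % 2**31, replicate_seed % 2**31, name_key, i]
        )
        out.append(Measurement(medium.name, i + 1, mean * math.exp(rng.normal(0.0, sigma))))
    return out


# --- truth construction -------------------------------------------------


@dataclass
class TruthConfig:
    """Recipe for a randomized screening-library truth.

    ``n_supplements`` components named supplement_01.. are generated;
    ``n_beneficial`` of them (chosen reproducibly from the seed) get a
    boost effect that multiplies the phenotype by ``beneficial_effect`` at
    the screening concentration, the rest are inert.  Explicit
    ``component_effects`` and ``interactions`` are layered on top.
    """

    baseline: float = 1.0
    n_supplements: int = 0
    n_beneficial: int = 0
    beneficial_effect: float = 1.5
    screening_conc: float = 1.0
    noise_cv: float = 0.10
    component_effects: dict[str, ComponentEffect] = field(default_factory=dict)
    interactions: dict = field(default_factory=dict)
    supplement_prefix: str = "supplement"


def supplement_name(prefix: str, i: int) -> str:
    return f"{prefix}_{i + 1:02d}"


def make_truth(config: TruthConfig, seed: int) -> ResponseSurfaceTruth:
    """Build a fully specified truth from a config, reproducibly from seed."""
    if config.n_beneficial > config.n_supplements:
        raise InvalidShapeParameters("n_beneficial cannot exceed n_supplements")
    rng = np.random.default_rng(seed)
    effects = dict(config.component_effects)
    if config.n_supplements:
        beneficial = set(
            rng.choice(config.n_supplements, size=config.n_beneficial, replace=False).tolist()
        )
        for i in range(config.n_supplements):
            name = supplement_name(config.supplement_prefix, i)
            if i in beneficial:
                effects[name] = boost_effect(config.screening_conc, config.beneficial_effect)
            else:
                effects[name] = ComponentEffect(shape="inert")
    return ResponseSurfaceTruth(
        baseline=config.baseline,
        component_effects=effects,
        interactions=dict(config.interactions),
        noise_cv=config.noise_cv,
        seed=int(seed),
    )


# --- serialization ------------------------------------------------------


def truth_to_json(truth: ResponseSurfaceTruth, path=None) -> str:
    doc = {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "baseline": truth.baseline,
        "noise_cv": truth.noise_cv,
        "seed": truth.seed,
        "component_effects": {
            name: {
                k: v
                for k, v in {
                    "shape": e.shape, "f_max": e.f_max, "K": e.K,
                    "c_opt": e.c_opt, "slope": e.slope,
                }.items()
                if v is not None
            }
            for name, e in truth.component_effects.items()
        },
        "interactions": [
            {"pair": sorted(pair), "gamma": gamma}
            for pair, gamma in sorted(truth.interactions.items(), key=lambda kv: sorted(kv[0]))
        ],
    }
    text = json.dumps(doc, indent=2, sort_keys=True) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def truth_from_json(source) -> ResponseSurfaceTruth:
    if isinstance(source, str) and source.lstrip().startswith("{"):
        doc = json.loads(source)
    else:
        with open(source) as fh:
            doc = json.load(fh)
    if doc.get("schema_version") != TRUTH_SCHEMA_VERSION:
        raise ValueError(f"unsupported truth schema version {doc.get('schema_version')}")
    return ResponseSurfaceTruth(
        baseline=doc["baseline"],
        component_effects={
            name: ComponentEffect(**params)
            for name, params in doc["component_effects"].items()
        },
        interactions={frozenset(e["pair"]): e["gamma"] for e in doc["interactions"]},
        noise_cv=doc["noise_cv"],
        seed=doc["seed"],
    )


def measurements_to_frame(
    measurements: list[Measurement], plate_id: int = 1, wells: list[str] | None = None
) -> pd.DataFrame:
    """Measurements in the wet-lab import shape (plate_id, well, medium,
    replicate, value), so simulated and measured data are interchangeable."""
    rows = []
    for i, m in enumerate(measurements):
        rows.append(
            {
                "plate_id": plate_id,
                "well": wells[i] if wells else "",
                "medium_name": m.medium_name,
                "replicate": m.replicate_index,
                "value": m.value,
            }
        )
    return pd.DataFrame(rows, columns=["plate_id", "well", "medium_name", "replicate", "value"])
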