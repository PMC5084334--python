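"""Run configuration: coefficient overrides, adjustment constants, z vs rate.

A config file (YAML or JSON — YAML is a superset, so one loader serves both)
may hold:

.. code-block:: yaml

    pooled_slope: 0.032        # or "recomputed" downstream
    reference_age: 25.09
    z: 3.72                    # or false_positive_rate: 1.0e-4
    log_level: INFO
    seed: 0
    coefficients:
      male: {beta0: -6.586, beta1: 2.100, beta2: 2.905, beta3: -101.737, beta_age: 0.0}

``z`` takes precedence over ``false_positive_rate`` when both are present;
the resolved multiplier is stored once at load time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .limits import false_positive_multiplier
from .records import Sex, logger
from .scoring import ScoreCoefficients, published_coefficients

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    pooled_slope: float = 0.032
    reference_age: float = 25.09
    z: float = 3.72
    log_level: str = "WARNING"
    seed: int = 0
    coefficients: dict[Sex, ScoreCoefficients] = field(
        default_factory=lambda: {
            Sex.MALE: published_coefficients(Sex.MALE),
            Sex.FEMALE: published_coefficients(Sex.FEMALE),
        }
    )

    def configure_logging(self) -> None:
        handler = logging.StreamHandler()  # stderr
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.handlers[:] = [handler]
        logger.setLevel(self.log_level.upper())


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON run configuration; ``None`` gives the defaults."""
    cfg = RunConfig()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if "pooled_slope" in raw:
        cfg.pooled_slope = float(raw["pooled_slope"])
    if "reference_age" in raw:
        cfg.reference_age = float(raw["reference_age"])
        if cfg.reference_age <= 0:
            raise ValueError("reference_age must be positive")
    if "z" in raw:
        cfg.z = float(raw["z"])
    elif "false_positive_rate" in raw:
        cfg.z = false_positive_multiplier(float(raw["false_positive_rate"]))
    if "log_level" in raw:
        cfg.log_level = str(raw["log_level"])
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    for sex_name, coeffs in (raw.get("coefficients") or {}).items():
        sex = Sex(sex_name)
        cfg.coefficients[sex] = ScoreCoefficients(
            sex=sex,
            beta0=float(coeffs["beta0"]),
            beta1=float(coeffs["beta1"]),
            beta2=float(coeffs["beta2"]),
            beta3=float(coeffs["beta3"]),
            beta_age=float(coeffs.get("beta_age", 0.0)),
            label=str(coeffs.get("label", f"config:{sex_name}")),
        )
    return cfg
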