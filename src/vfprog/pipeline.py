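"""Cohort-level orchestration: predictor tables and standard model sets.

``compute_predictors`` runs every metric on every eye and returns one tidy
row per eye; ``STANDARD_MODELS`` maps the named diagnostic models to their
predictor columns.  Eyes too short for a metric carry NaN in that metric's
columns and are dropped listwise when that model is fitted.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .io import Cohort
from .stbound import STBoundConfig, fit_stbound, stbound_predictors
from .trend import trend_predictors

__all__ = [
    "PredictorSettings",
    "compute_predictors",
    "STANDARD_MODELS",
    "MIN_TESTS",
    "required_tests",
]

#: predictor columns per named diagnostic model
STANDARD_MODELS: dict[str, list[str]] = {
    "GI": ["gi_slope", "gi_p", "gi_interaction"],
    "MS": ["ms"],
    "P1": ["p1"],
    "P2": ["p2"],
    "P3": ["p3"],
    "P4": ["p4"],
    "PoPLR": ["poplr_p"],
    "STBound": ["cv_mean", "cv_sd", "cv_interaction"],
    "GI+STBound": ["gi_slope", "gi_p", "gi_interaction", "cv_mean", "cv_sd", "cv_interaction"],
}

#: minimum number of tests for each predictor column to be defined
MIN_TESTS: dict[str, int] = {
    "gi_slope": 3,
    "gi_p": 3,
    "gi_interaction": 3,
    "p1": 3,
    "p2": 3,
    "p3": 3,
    "p4": 3,
    "ms": 3,
    "poplr_s": 3,
    "poplr_p": 3,
    "cv_mean": 2,
    "cv_sd": 2,
    "cv_interaction": 2,
}


def required_tests(columns: list[str]) -> int:
    """Minimum visit count an eye needs for every column to be defined."""
    return max(MIN_TESTS.get(c, 3) for c in columns)


@dataclass
class PredictorSettings:
    """Knobs for the per-eye predictor computation."""

    n_perm: int = 1999
    stbound: STBoundConfig = dc_field(default_factory=STBoundConfig)
    include_stbound: bool = True
    seed: int = 0


def _eye_seed(base: int, eye_id: str) -> int:
    return (int(base) + zlib.crc32(eye_id.encode())) % (2**31)


def compute_predictors(cohort: Cohort, grid, settings: PredictorSettings | None = None) -> pd.DataFrame:
    """One row per eye with all predictor columns (NaN where undefined).

    Per-eye randomness (PoPLR permutations, MCMC) is seeded from
    ``settings.seed`` and the eye id, so results do not depend on cohort
    order or on truncation of *other* eyes.
    """
    settings = settings or PredictorSettings()
    rows = {}
    for s in cohort:
        seed = _eye_seed(settings.seed, s.eye_id)
        row: dict[str, float] = dict.fromkeys(MIN_TESTS, np.nan)
        if s.n_tests >= 3:
            tp = trend_predictors(s, n_perm=settings.n_perm, seed=seed)
            row.update(
                gi_slope=tp.gi_slope, gi_p=tp.gi_p, gi_interaction=tp.gi_interaction,
                p1=tp.p1, p2=tp.p2, p3=tp.p3, p4=tp.p4, ms=tp.ms,
                poplr_s=tp.poplr_s, poplr_p=tp.poplr_p,
            )
        if settings.include_stbound and s.n_tests >= 2:
            cfg_kwargs = {
                k: getattr(settings.stbound, k)
                for k in (
                    "rho", "delta_prior_var", "sigma_df", "sigma_scale", "phi_bounds",
                    "n_burn", "n_keep", "thin", "theta_scales", "phi_scale", "adapt",
                    "target_accept", "likelihood",
                )
            }
            cfg = type(settings.stbound)(seed=seed, **cfg_kwargs)
            samples = fit_stbound(s, grid, cfg)
            cv_mean, cv_sd, cv_inter = stbound_predictors(samples)
            row.update(cv_mean=cv_mean, cv_sd=cv_sd, cv_interaction=cv_inter)
        rows[s.eye_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "eye_id"
    return df
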