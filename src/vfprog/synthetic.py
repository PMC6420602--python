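"""Synthetic longitudinal visual-field cohorts.

Generates eyes with the statistical structure the downstream analyses
assume, under four mechanisms:

``stable``
    constant mean field, constant spatial smoothness.
``global_trend``
    the whole-field mean declines linearly in time (dB/year).
``sector_trend``
    only an anatomical sector declines; the rest stays flat.
``correlation_shift``
    the mean field is flat but the spatial-smoothness parameter of the
    conditional-autoregressive (CAR) field drifts log-linearly in time --
    progression expressed purely through changing spatial correlation, the
    signal the boundary-detection predictor targets.

Each visit's spatial field is drawn from N(m_t, tau2 * Q(alpha_t)^-1) with
Q the CAR precision built from the Garway-Heath dissimilarity grid, then
heteroscedastic measurement noise is added per location (test-retest
variability is known to rise as sensitivity falls) and the result is clamped
to the instrument range [0, 50] dB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.linalg import cho_factor, solve_triangular

from .grid import VFGrid
from .io import Cohort, VFSeries, VFTest
from .stbound import precision_matrix

__all__ = [
    "SimulationParams",
    "CohortParams",
    "noise_sd",
    "simulate_eye",
    "simulate_cohort",
    "DEFAULT_SECTOR",
]

MECHANISMS = ("stable", "global_trend", "sector_trend", "correlation_shift")

# Superior-nasal wedge of the right-eye 24-2 field: a typical site of
# localized glaucomatous loss (arcuate/nasal-step region).
DEFAULT_SECTOR = (1, 2, 5, 6, 7, 11, 12, 13, 20, 21)

#: default log-linear drift rate of alpha for correlation_shift: a 3-fold
#: change over the cohort's mean follow-up of 2.6 years.
DEFAULT_GAMMA = math.log(3.0) / 2.6


@dataclass
class SimulationParams:
    """Generative settings for a single eye.

    Defaults reflect the perimetric series the toolkit targets: baseline
    sensitivity 27 dB (the cohort median), a -1.5 dB/year decline for
    trend-progressing eyes, spatial variance tau2 = 1 dB^2 (about 3 dB of
    median between-location SD once propagated through the CAR precision at
    the default smoothness), and measurement noise of 1 dB at high
    sensitivity rising by 0.1 dB per dB below 30.

    ``alpha0 = 40`` places the spatial-smoothness parameter in the regime
    where a single 52-location field is informative about it: on the
    normalized Garway-Heath dissimilarity scale most adjacent pairs have
    z around 0.02-0.2, so alpha*z is order 1 there and the CAR weights
    respond to changes in alpha.
    """

    mechanism: str = "stable"
    baseline_mean: float = 27.0
    slope: float | None = None  # dB/year; filled per mechanism if None
    sector: tuple[int, ...] = DEFAULT_SECTOR
    alpha0: float = 40.0
    gamma: float | None = None  # d log(alpha) / d year; filled per mechanism
    tau2: float = 1.0
    noise_link: tuple[float, float] = (1.0, 0.1)
    n_tests: int = 8
    follow_up_years: float = 2.6
    rho: float = 0.99
    seed: int = 0

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if self.slope is None:
            self.slope = -1.5 if self.mechanism in ("global_trend", "sector_trend") else 0.0
        if self.gamma is None:
            self.gamma = DEFAULT_GAMMA if self.mechanism == "correlation_shift" else 0.0
        if self.mechanism in ("global_trend", "sector_trend") and not self.slope < 0:
            raise ValueError("trend mechanisms require slope < 0")
        if self.mechanism == "correlation_shift":
            if self.gamma == 0:
                raise ValueError("correlation_shift requires gamma != 0")
            if self.slope != 0:
                raise ValueError("correlation_shift requires slope = 0")
        if self.mechanism == "stable" and (self.slope != 0 or self.gamma != 0):
            raise ValueError("stable requires slope = 0 and gamma = 0")
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be positive")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        if any(s < 0 for s in self.noise_link):
            raise ValueError("noise_link components must be non-negative")
        if self.n_tests < 2:
            raise ValueError("n_tests must be >= 2")
        if self.follow_up_years <= 0:
            raise ValueError("follow_up_years must be positive")


@dataclass
class CohortParams:
    """Cohort-level generative settings.

    Defaults match the clinical descriptives the toolkit was designed
    around: 26% progressing eyes, a mean of 7.4 tests per eye clipped to
    [2, 21], and mean follow-up of 2.6 years clipped to [0.2, 9.4].
    """

    n_eyes: int = 191
    frac_progressing: float = 0.26
    mechanism_mix: dict = dc_field(
        default_factory=lambda: {
            "global_trend": 1 / 3,
            "sector_trend": 1 / 3,
            "correlation_shift": 1 / 3,
        }
    )
    mean_tests: float = 7.4
    tests_clip: tuple[int, int] = (2, 21)
    mean_follow_up: float = 2.6
    follow_up_clip: tuple[float, float] = (0.2, 9.4)
    eye_params: SimulationParams = dc_field(default_factory=SimulationParams)
    seed: int = 0

    def __post_init__(self):
        if self.n_eyes < 2:
            raise ValueError("n_eyes must be >= 2")
        if not 0 <= self.frac_progressing <= 1:
            raise ValueError("frac_progressing must be in [0, 1]")
        if set(self.mechanism_mix) - set(MECHANISMS[1:]):
            raise ValueError(f"mechanism_mix keys must be progressing mechanisms {MECHANISMS[1:]}")
        tot = sum(self.mechanism_mix.values())
        if tot <= 0:
            raise ValueError("mechanism_mix must have positive total weight")
        self.mechanism_mix = {k: v / tot for k, v in self.mechanism_mix.items()}


def noise_sd(true_db, link: tuple[float, float]):
    """Measurement-noise SD at a true sensitivity: sigma0 + sigma1*max(0, 30 - dB).

    A hinge at 30 dB: homoscedastic above, linearly increasing variability
    below, capturing the inverse sensitivity-variability relationship.
    """
    s0, s1 = link
    if s0 < 0 or s1 < 0:
        raise ValueError("noise link components must be non-negative")
    return s0 + s1 * np.maximum(0.0, 30.0 - np.asarray(true_db, dtype=float))


def _mean_field(params: SimulationParams, grid: VFGrid, t: float) -> np.ndarray:
    n = grid.n_retained
    m = np.full(n, params.baseline_mean)
    if params.mechanism == "global_trend":
        m += params.slope * t
    elif params.mechanism == "sector_trend":
        idx = [grid.index_of(l) for l in params.sector]
        m[idx] += params.slope * t
    return m


def simulate_eye(grid: VFGrid, params: SimulationParams) -> VFSeries:
    """Simulate one eye; deterministic given ``params.seed``.

    Visit times: baseline at 0, the remaining n-1 uniform over
    (0, follow_up], sorted.
    """
    bad_sector = [l for l in params.sector if l not in set(grid.retained_ids.tolist())]
    if params.mechanism == "sector_trend" and bad_sector:
        raise ValueError(f"sector ids not on the retained grid: {bad_sector}")

    rng = np.random.default_rng(params.seed)
    T, n = params.n_tests, grid.n_retained
    # baseline at 0, final visit at the configured follow-up, interior visits
    # uniform in between: realized follow-up equals the configured value
    interior = np.sort(rng.uniform(0.0, params.follow_up_years, T - 2)) if T > 2 else np.empty(0)
    times = np.concatenate([[0.0], interior, [params.follow_up_years]])
    # avoid coincident times from the uniform draw (probability ~0, but cheap)
    for k in range(1, T):
        if times[k] <= times[k - 1]:
            times[k] = np.nextafter(times[k - 1], np.inf)

    alphas = params.alpha0 * np.exp(params.gamma * times)
    if (alphas <= 0).any():
        raise ValueError("alpha path must stay positive")

    tests = []
    for t, a in zip(times, alphas):
        m = _mean_field(params, grid, t)
        y = m.copy()
        if params.tau2 > 0:
            Q = precision_matrix(a, grid, params.rho)
            L = np.linalg.cholesky(Q)
            y = y + math.sqrt(params.tau2) * solve_triangular(
                L.T, rng.standard_normal(n), lower=False
            )
        sd = noise_sd(y, params.noise_link)
        if np.any(sd > 0):
            y = y + sd * rng.standard_normal(n)
        y = np.clip(y, 0.0, 50.0)
        tests.append(VFTest(float(t), y))
    label = "stable" if params.mechanism == "stable" else "progressing"
    return VFSeries(eye_id=f"sim{params.seed}", tests=tests, label=label)


def _draw_n_tests(rng, cp: CohortParams) -> int:
    # shifted Poisson: 2 + Poisson(mean - 2), then clip
    lo, hi = cp.tests_clip
    n = lo + rng.poisson(max(cp.mean_tests - lo, 0.0))
    return int(np.clip(n, lo, hi))


def _draw_follow_up(rng, cp: CohortParams) -> float:
    # Gamma(shape 2) keeps follow-up positive and right-skewed like real
    # clinic data; clipping to the observed range barely moves the mean.
    lo, hi = cp.follow_up_clip
    f = rng.gamma(2.0, cp.mean_follow_up / 2.0)
    return float(np.clip(f, lo, hi))


def simulate_cohort(grid: VFGrid, cohort: CohortParams) -> Cohort:
    """Simulate a labelled cohort; bit-reproducible given ``cohort.seed``.

    The number of progressing eyes is ``round(frac_progressing * n_eyes)``;
    mechanisms are assigned to progressors in proportion to
    ``mechanism_mix`` and positions are shuffled.  Per-eye seeds are spawned
    from the master seed.
    """
    cp = cohort
    rng = np.random.default_rng(cp.seed)
    n_prog = int(round(cp.frac_progressing * cp.n_eyes))

    mechs = []
    names = sorted(cp.mechanism_mix)
    counts = {k: int(np.floor(cp.mechanism_mix[k] * n_prog)) for k in names}
    # distribute the remainder deterministically by largest fractional part
    rem = n_prog - sum(counts.values())
    fracs = sorted(
        names, key=lambda k: (cp.mechanism_mix[k] * n_prog) % 1.0, reverse=True
    )
    for k in fracs[:rem]:
        counts[k] += 1
    for k in names:
        mechs += [k] * counts[k]
    mechs += ["stable"] * (cp.n_eyes - n_prog)
    mechs = list(rng.permutation(np.array(mechs, dtype=object)))

    child_seeds = np.random.SeedSequence(cp.seed).generate_state(cp.n_eyes) % (2**31)
    series = []
    width = len(str(cp.n_eyes))
    for i, mech in enumerate(mechs):
        p = SimulationParams(
            mechanism=mech,
            baseline_mean=cp.eye_params.baseline_mean,
            slope=None,
            sector=cp.eye_params.sector,
            alpha0=cp.eye_params.alpha0,
            gamma=None,
            tau2=cp.eye_params.tau2,
            noise_link=cp.eye_params.noise_link,
            n_tests=_draw_n_tests(rng, cp),
            follow_up_years=_draw_follow_up(rng, cp),
            rho=cp.eye_params.rho,
            seed=int(child_seeds[i]),
        )
        s = simulate_eye(grid, p)
        s.eye_id = f"eye{i + 1:0{width}d}"
        series.append(s)
    return Cohort(series)
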