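"""Synthetic crossover data generator with known ground truth.

The generator mirrors the analysis model: for each variable, subject j and
grid time t,

    ONB:  y(t) = mu(t) + b_j + eps,
    FB:   y(t) = mu(t) + delta(t) + b_j + eps,

with ``mu`` a mono-exponential on-kinetics curve (the canonical shape of a
constant-load exercise response: rise from a baseline towards a steady
state), ``delta`` a smooth condition-effect curve signed per the variable's
hypothesized direction, ``b_j`` an optional subject intercept (default off,
matching an analysis model with no subject term) and ``eps`` iid Gaussian
noise.  All curves and the noise live on the *analysis* scale: variables
flagged for log transformation are generated on the log scale and stored
back on the measurement scale, so that applying the log transform downstream
recovers exactly Gaussian errors.

Defaults emulate the motivating trial: 18 subjects, a 1-min warm-up followed
by 10 min of constant-load walking sampled on a 5-s grid (60..660 s, 121
points), per-variable baselines, condition effects and noise scales taken
from the trial's published per-condition summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import TrialDataset
from .errors import ConfigError
from .trialref import TABLE2
from .variables import VARIABLES, VariableSpec


@dataclass(frozen=True)
class MeanCurve:
    """Mono-exponential on-kinetics mean curve on the analysis scale.

    ``mu(t) = baseline + amplitude * (1 - exp(-(t - t_start) / tau_s))``

    rising from ``baseline`` at the grid start towards the steady state
    ``baseline + amplitude`` with time constant ``tau_s`` seconds.
    """

    baseline: float
    amplitude: float
    tau_s: float = 60.0

    def __call__(self, t: np.ndarray, t_start: float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.baseline + self.amplitude * (
            1.0 - np.exp(-(t - t_start) / self.tau_s)
        )


@dataclass(frozen=True)
class EffectCurve:
    """Smooth condition-effect curve delta(t) on the analysis scale.

    Kinds:
      - ``"zero"``: no effect.
      - ``"constant"``: delta(t) = amplitude everywhere.
      - ``"bump"``: Gaussian bump ``amplitude * exp(-(t-center)^2/(2 width^2))``
        peaking at ``center_s`` (defaults to the grid midpoint).
    """

    kind: str = "constant"
    amplitude: float = 0.0
    center_s: float | None = None
    width_s: float = 90.0

    def __call__(self, t: np.ndarray, grid: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "zero":
            return np.zeros_like(t)
        if self.kind == "constant":
            return np.full_like(t, self.amplitude)
        if self.kind == "bump":
            center = (
                0.5 * (grid[0] + grid[-1]) if self.center_s is None else self.center_s
            )
            return self.amplitude * np.exp(
                -((t - center) ** 2) / (2.0 * self.width_s**2)
            )
        raise ConfigError(f"unknown effect curve kind {self.kind!r}")


@dataclass
class SimConfig:
    """Full specification of one synthetic crossover dataset.

    All per-variable maps (``mean_curves``, ``effect_curves``,
    ``sigma_noise``) are keyed by variable name and interpreted on the
    analysis scale (log scale for log-flagged variables).
    """

    variables: list[VariableSpec]
    mean_curves: dict[str, MeanCurve]
    effect_curves: dict[str, EffectCurve]
    sigma_noise: dict[str, float]
    n_subjects: int = 18
    grid_start_s: float = 60.0
    grid_end_s: float = 660.0
    grid_step_s: float = 5.0
    sigma_subject: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_step_s <= 0:
            raise ConfigError("grid_step_s must be positive")
        if self.grid_end_s <= self.grid_start_s:
            raise ConfigError("grid_end_s must exceed grid_start_s")
        if self.grid.size < 5:
            raise ConfigError("grid must have at least 5 points")
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.sigma_subject < 0:
            raise ConfigError("sigma_subject must be >= 0")
        for spec in self.variables:
            for table, label in [
                (self.mean_curves, "mean curve"),
                (self.effect_curves, "effect curve"),
                (self.sigma_noise, "noise SD"),
            ]:
                if spec.name not in table:
                    raise ConfigError(f"missing {label} for variable {spec.name!r}")
            if not self.sigma_noise[spec.name] > 0:
                raise ConfigError(f"sigma_noise for {spec.name!r} must be > 0")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_end_s - self.grid_start_s) / self.grid_step_s)) + 1
        return self.grid_start_s + self.grid_step_s * np.arange(n)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def ground_truth(config: SimConfig) -> dict[str, dict[str, np.ndarray]]:
    """Exact generative curves on the grid, per variable.

    Returns ``{name: {"mu": mu(t), "delta": delta(t)}}`` on the analysis
    scale, for parameter-recovery tests against fitted posteriors.
    """
    grid = config.grid
    out = {}
    for spec in config.variables:
        mu = config.mean_curves[spec.name](grid, config.grid_start_s)
        delta = config.effect_curves[spec.name](grid, grid)
        out[spec.name] = {"mu": mu, "delta": delta}
    return out


def generate_dataset(config: SimConfig) -> TrialDataset:
    """Draw one synthetic crossover dataset.

    Values are stored on the measurement scale (exponentiated for
    log-flagged variables); identical configs (including seed) yield
    bit-identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    n = grid.size
    truth = ground_truth(config)
    width = max(2, int(math.ceil(math.log10(config.n_subjects + 1))))
    subjects = [f"S{j + 1:0{width}d}" for j in range(config.n_subjects)]

    series: dict[tuple[str, str, str], np.ndarray] = {}
    for spec in config.variables:
        mu = truth[spec.name]["mu"]
        delta = truth[spec.name]["delta"]
        sigma = config.sigma_noise[spec.name]
        for subj in subjects:
            b = rng.normal(0.0, config.sigma_subject) if config.sigma_subject > 0 else 0.0
            onb = mu + b + rng.normal(0.0, sigma, size=n)
            fb = mu + delta + b + rng.normal(0.0, sigma, size=n)
            if spec.log_transform:
                onb, fb = np.exp(onb), np.exp(fb)
            series[(subj, "ONB", spec.name)] = onb
            series[(subj, "FB", spec.name)] = fb
    return TrialDataset(grid=grid.copy(), series=series)


def default_config(seed: int = 0, variables: list[str] | None = None) -> SimConfig:
    """Default simulation emulating the motivating trial's conditions.

    Per variable, the steady state of the on-kinetics curve equals the
    trial's ONB summary mean, the baseline sits 15% below it (warm-up), the
    constant condition effect equals the FB-minus-ONB summary difference and
    the noise SD equals the average of the two reported SDs.  Log-flagged
    variables get the log-scale analogues (log-mean curves, log-ratio
    effect, coefficient-of-variation noise).
    """
    names = variables if variables is not None else list(TABLE2)
    specs = [VARIABLES[v] for v in names]
    mean_curves: dict[str, MeanCurve] = {}
    effect_curves: dict[str, EffectCurve] = {}
    sigma_noise: dict[str, float] = {}
    for spec in specs:
        row = TABLE2[spec.name]
        sd = 0.5 * (row.fb_sd + row.onb_sd)
        if spec.log_transform:
            steady = math.log(row.onb_mean)
            amplitude = 0.15 * abs(steady)
            effect = math.log(row.fb_mean) - math.log(row.onb_mean)
            sigma = sd / row.onb_mean
        else:
            steady = row.onb_mean
            amplitude = 0.15 * abs(steady)
            effect = row.fb_mean - row.onb_mean
            sigma = sd
        mean_curves[spec.name] = MeanCurve(
            baseline=steady - amplitude, amplitude=amplitude, tau_s=60.0
        )
        effect_curves[spec.name] = EffectCurve(kind="constant", amplitude=effect)
        sigma_noise[spec.name] = sigma
    return SimConfig(
        variables=specs,
        mean_curves=mean_curves,
        effect_curves=effect_curves,
        sigma_noise=sigma_noise,
        seed=seed,
    )
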