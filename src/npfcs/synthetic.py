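"""Ground-truth-known synthetic data at every level of the analysis chain.

Three generators are provided:

* :func:`simulate_trace` — Brownian-dynamics photon traces: point-like
  fluorescent spheres random-walking through a 3D-Gaussian detection
  volume in a periodic box, Poisson photon emission, 50/50 binomial
  splitting onto two detector channels.
* :func:`simulate_curve` — fast model-based correlation curves with a
  lag-dependent Gaussian noise stand-in, for exercising the fitting layer.
* :func:`generate_scenario` — whole concentration series emulating a
  nanoparticle/biopolymer aggregation experiment: a logistic aggregate
  fraction with a sharp onset, volume-scaled aggregate brightness, an
  alginate-concentration-dependent viscosity, and replicate curves, always
  emitted together with the ground-truth table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .correlator import CorrelationCurve, PhotonTrace
from .errors import ValidationError
from .models import (
    ETA_WATER_21C,
    N_A,
    DetectionVolume,
    ModelParams,
    PhysicalConditions,
    diffusion_coefficient,
    diffusion_time,
    effective_volume,
    two_population_G,
)

__all__ = [
    "SimulationConfig",
    "ScenarioConfig",
    "default_box_half_widths",
    "simulate_trace",
    "simulate_curve",
    "viscosity_model",
    "generate_scenario",
]

#: Default stand-in viscosity coefficients (a [L/g], b [L^2/g^2]) giving
#: roughly a 30-fold increase over water at 10 g/L alginate, the low end
#: of the manufacturer-specified range for low-viscosity alginate.
DEFAULT_VISCOSITY_PARAMS = (0.9, 0.2)

SeedLike = "int | np.random.SeedSequence"


def default_box_half_widths(volume: DetectionVolume) -> tuple[float, float, float]:
    """Periodic cuboid 20 w0 x 20 w0 x 3 S w0 (full widths).

    The box must hold the slow concentration-fluctuation modes the
    correlation tail is made of: periodic boundaries quantize lateral
    modes at k = 2 pi n / L, so fluctuations slower than L^2/(4 pi^2 D)
    simply do not exist in the box.  At 10 w0 full width that cutoff sits
    near 10 diffusion times and the simulated correlation decays visibly
    too fast, biasing fitted diameters low by ~15%; at 20 w0 the cutoff
    moves past the lag range that carries fitting weight.
    """
    return (
        10.0 * volume.omega0,
        10.0 * volume.omega0,
        1.5 * volume.aspect_ratio * volume.omega0,
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Brownian-dynamics photon-trace simulation setup.

    ``populations`` lists (diameter m, particle count in the box,
    brightness counts/s at the focus centre).  The box must be at least
    5 w0 half-width laterally and 1.5 S w0 axially, and the bin width at
    most 1/50 of the fastest diffusion time so correlation decays are
    resolved without binning bias.
    """

    populations: Sequence[tuple[float, int, float]]
    volume: DetectionVolume
    conditions: PhysicalConditions = PhysicalConditions()
    box_half_widths: tuple[float, float, float] | None = None
    bin_width: float = 1e-5
    duration: float = 10.0
    background_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValidationError("at least one population is required")
        for d, count, q in self.populations:
            if d <= 0 or count < 0 or q < 0:
                raise ValidationError("invalid population entry")
        box = self.box_half_widths or default_box_half_widths(self.volume)
        hx, hy, hz = box
        if hx < 5 * self.volume.omega0 or hy < 5 * self.volume.omega0:
            raise ValidationError("lateral box half-widths must be >= 5 omega0")
        if hz < 1.5 * self.volume.aspect_ratio * self.volume.omega0:
            raise ValidationError("axial box half-width must be >= 1.5 S omega0")
        object.__setattr__(self, "box_half_widths", (hx, hy, hz))
        if not (self.bin_width > 0 and self.duration >= self.bin_width):
            raise ValidationError("need positive bin width <= duration")
        fastest = min(
            diffusion_time(d, self.volume, self.conditions)[0]
            for d, _, _ in self.populations
        )
        if self.bin_width > fastest / 50.0:
            raise ValidationError(
                f"bin width {self.bin_width}s too coarse for tau_D {fastest}s "
                "(require bin_width <= tau_D/50)"
            )
        if self.background_rate < 0:
            raise ValidationError("background rate must be non-negative")

    @property
    def box_volume(self) -> float:
        hx, hy, hz = self.box_half_widths
        return 8.0 * hx * hy * hz


def simulate_trace(config: SimulationConfig) -> PhotonTrace:
    """Simulate a two-channel photon trace from diffusing emitters.

    Each particle performs an isotropic random walk with per-axis step
    standard deviation ``sqrt(2 D dt)`` under periodic boundaries.  The
    detected rate is ``sum_j Q_j W(r_j) + background`` with the Gaussian
    profile ``W = exp(-2(x^2+y^2)/w0^2 - 2 z^2/(S w0)^2)``; per-bin counts
    are Poisson draws split binomially (p = 1/2) between the channels.
    Bit-identical under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n_bins = int(round(config.duration / config.bin_width))
    hx, hy, hz = config.box_half_widths
    half = np.array([hx, hy, hz], dtype=np.float32)
    full = 2.0 * half
    w0 = config.volume.omega0
    wz = config.volume.aspect_ratio * w0
    lat_coef = np.float32(-2.0 / w0**2)
    ax_coef = np.float32(-2.0 / wz**2)

    # Positions are kept in float32: box-wrapped coordinates stay below a
    # few microns, so the absolute resolution (~1e-13 m) is far below the
    # per-bin step size and never accumulates.
    states = []
    for d, count, q in config.populations:
        pos = rng.uniform(-half, half, size=(count, 3)).astype(np.float32)
        D = diffusion_coefficient(d, config.conditions)
        sigma = np.float32(np.sqrt(2.0 * D * config.bin_width))
        states.append([pos, sigma, q, count])

    total_particles = sum(s[3] for s in states) or 1
    chunk_bins = max(1, int(4_000_000 / total_particles))
    counts = np.empty(n_bins, dtype=np.int64)
    counts_a = np.empty(n_bins, dtype=np.int64)

    start = 0
    while start < n_bins:
        stop = min(start + chunk_bins, n_bins)
        nb = stop - start
        lam = np.full(nb, config.background_rate, dtype=float)
        for state in states:
            pos, sigma, q, count = state
            if count == 0:
                continue
            traj = rng.standard_normal((nb, count, 3), dtype=np.float32)
            traj *= sigma
            np.cumsum(traj, axis=0, out=traj)
            traj += pos
            traj += half
            np.mod(traj, full, out=traj)
            traj -= half
            state[0] = traj[-1].copy()
            if q > 0.0:
                expo = traj[:, :, 0] ** 2
                expo += traj[:, :, 1] ** 2
                expo *= lat_coef
                expo += ax_coef * traj[:, :, 2] ** 2
                lam += q * np.exp(expo, out=expo).sum(axis=1, dtype=np.float64)
        c = rng.poisson(lam * config.bin_width)
        counts[start:stop] = c
        counts_a[start:stop] = rng.binomial(c, 0.5)
        start = stop

    return PhotonTrace(counts_a, counts - counts_a, config.bin_width)


def simulate_curve(
    params: ModelParams,
    volume: DetectionVolume,
    conditions: PhysicalConditions,
    noise_scale: float = 0.02,
    n_points: int = 160,
    seed: "int | np.random.SeedSequence" = 0,
    tau_min: float = 1e-5,
    tau_max: float = 10.0,
) -> CorrelationCurve:
    """Model curve on a log lag grid with a pragmatic noise stand-in.

    Gaussian noise with standard deviation
    ``noise_scale * (G(tau) + 1/N) / sqrt(index + 1)`` mimics the generic
    shape of correlator noise (larger at short lags, amplitude-coupled);
    it is not the instrument's true noise law.  The stderr column is
    populated with the exact noise standard deviation.
    """
    if noise_scale < 0:
        raise ValidationError("noise_scale must be non-negative")
    if n_points < 2:
        raise ValidationError("need at least two lag points")
    lags = np.geomspace(tau_min, tau_max, n_points)
    g = two_population_G(lags, params, volume, conditions)
    sigma = noise_scale * (g + 1.0 / params.N) / np.sqrt(np.arange(n_points) + 1.0)
    rng = np.random.default_rng(seed)
    values = g + rng.normal(size=n_points) * sigma
    meta = {
        "estimator": "synthetic_model",
        "noise_scale": noise_scale,
        "segments": 1,
        "acquisition_time_s": float("nan"),
    }
    return CorrelationCurve(lags, values, sigma, meta)


def viscosity_model(
    c_alginate: float,
    params: tuple[float, float] = DEFAULT_VISCOSITY_PARAMS,
    eta_water: float = ETA_WATER_21C,
) -> float:
    """Stand-in polynomial for the alginate-concentration viscosity.

    ``eta = eta_water * (1 + a c + b c^2)`` with ``c`` in g/L; strictly
    increasing for non-negative coefficients and equal to water at c = 0.
    A measured viscosity table can be used in its place at the pipeline
    level.
    """
    if c_alginate < 0:
        raise ValidationError("concentration must be non-negative")
    a, b = params
    return eta_water * (1.0 + a * c_alginate + b * c_alginate**2)


@dataclass(frozen=True)
class ScenarioConfig:
    """A full concentration-series experiment with known ground truth.

    The aggregate number fraction follows a logistic onset
    ``Xa(c) = Xa_max / (1 + exp(-(c - onset_c)/onset_width))`` in the
    total biopolymer concentration ``c``; the solution viscosity follows
    :func:`viscosity_model` of the alginate share of ``c``.  The particle
    number in the detection volume derives from the nanoparticle molar
    concentration (study condition: 500 pM).
    """

    concentration_grid: Sequence[float]
    bsa_weight_fraction: float = 0.0
    ph_label: str = "7"
    onset_c: float = 3.5
    onset_width: float = 0.08
    Xa_max: float = 0.005
    d1_true: float = 110e-9
    da_true: float = 400e-9
    viscosity_params: tuple[float, float] = DEFAULT_VISCOSITY_PARAMS
    np_concentration_molar: float = 500e-12
    temperature: float = 294.15
    replicates: int = 6
    noise_scale: float = 0.02
    n_points: int = 160
    seed: int = 0

    def __post_init__(self) -> None:
        grid = tuple(float(c) for c in self.concentration_grid)
        if len(grid) == 0 or any(np.diff(grid) <= 0):
            raise ValidationError("concentration grid must be non-empty, ascending")
        if any(c < 0 for c in grid):
            raise ValidationError("concentrations must be non-negative")
        object.__setattr__(self, "concentration_grid", grid)
        if not (0.0 <= self.Xa_max <= 1.0):
            raise ValidationError("Xa_max must lie in [0, 1]")
        if not (0.0 <= self.bsa_weight_fraction <= 1.0):
            raise ValidationError("bsa_weight_fraction must lie in [0, 1]")
        if self.replicates < 3:
            raise ValidationError("need at least triplicate replicates")
        if not (self.onset_width > 0):
            raise ValidationError("onset width must be positive")

    def aggregate_fraction(self, c: float) -> float:
        """Ground-truth logistic Xa at total biopolymer concentration c."""
        if self.Xa_max == 0.0:
            return 0.0
        return self.Xa_max / (1.0 + np.exp(-(c - self.onset_c) / self.onset_width))

    def alginate_concentration(self, c: float) -> float:
        return c * (1.0 - self.bsa_weight_fraction)


def generate_scenario(
    scenario: ScenarioConfig, volume: DetectionVolume
) -> tuple[list[dict], pd.DataFrame]:
    """Generate labelled replicate curves plus the ground-truth table.

    Returns ``(records, truth)``.  Each record carries ``concentration``,
    ``replicate``, ``eta`` (Pa s) and ``curve``; the truth table has one
    row per concentration with the generating Xa, phi_a, diameters and
    viscosity, for recovery scoring.
    """
    from .models import volume_fraction  # local import avoids cycle at doc build

    grid = scenario.concentration_grid
    n_per_m3 = scenario.np_concentration_molar * 1000.0 * N_A
    n_true = n_per_m3 * effective_volume(volume)
    base = np.random.SeedSequence(scenario.seed)
    children = base.spawn(len(grid) * scenario.replicates)

    records: list[dict] = []
    truth_rows = []
    idx = 0
    for c in grid:
        xa = float(scenario.aggregate_fraction(c))
        eta = viscosity_model(
            scenario.alginate_concentration(c), scenario.viscosity_params
        )
        conditions = PhysicalConditions(scenario.temperature, eta)
        params = ModelParams(n_true, xa, scenario.d1_true, scenario.da_true)
        truth_rows.append(
            {
                "concentration_g_per_L": c,
                "Xa_true": xa,
                "phi_a_true": volume_fraction(xa, scenario.d1_true, scenario.da_true),
                "d1_true_m": scenario.d1_true,
                "da_true_m": scenario.da_true,
                "eta_Pa_s": eta,
                "N_true": n_true,
            }
        )
        for rep in range(scenario.replicates):
            curve = simulate_curve(
                params,
                volume,
                conditions,
                noise_scale=scenario.noise_scale,
                n_points=scenario.n_points,
                seed=children[idx],
            )
            records.append(
                {
                    "concentration": c,
                    "replicate": rep,
                    "eta": eta,
                    "curve": curve,
                }
            )
            idx += 1
    return records, pd.DataFrame(truth_rows)
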