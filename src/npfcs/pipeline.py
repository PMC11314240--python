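"""Series-level orchestration: calibration, fitting with model selection
and viscosity handling for every replicate of a concentration series,
replicate statistics, aggregation-onset reporting, and results I/O.

The analysis chain per concentration point is: fit both models at the
solution viscosity, pick one by the Occam rule, record the viscosity used,
and convert to the aggregate volume fraction.  Replicates are fitted
separately and their parameters averaged (standard error of the mean
across replicates), matching how triplicate measurements of independent
experiments are usually pooled, rather than fitting averaged curves.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import FitFailureError, ValidationError
from .fitting import (
    CalibrationResult,
    FitConfig,
    calibrate,
    fit_one_population,
    fit_two_population,
    select_model,
    viscosity_correct,
)
from .models import (
    DetectionVolume,
    ModelParams,
    N_A,
    PhysicalConditions,
    effective_volume,
)
from .synthetic import (
    DEFAULT_VISCOSITY_PARAMS,
    ScenarioConfig,
    generate_scenario,
    simulate_curve,
    viscosity_model,
)

__all__ = [
    "ExperimentConfig",
    "OnsetInterval",
    "SeriesResult",
    "run_series",
    "onset_interval",
    "layer_thickness",
    "layer_count",
    "write_results",
    "read_results",
]

DEFAULT_ONSET_THRESHOLD = 0.05


# ---------------------------------------------------------------------------
# Onset and layer arithmetic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OnsetInterval:
    """Concentration interval bracketing the aggregation onset.

    ``low`` is the last grid point at or below the threshold before the
    first crossing and ``high`` the first point above it; both are None
    when the threshold is never exceeded.  ``flagged`` marks series that
    are non-monotonic around the crossing or that start above threshold.
    """

    low: float | None
    high: float | None
    flagged: bool = False

    @property
    def empty(self) -> bool:
        return self.high is None


def onset_interval(
    concentrations: Sequence[float],
    phi_a: Sequence[float],
    threshold: float = DEFAULT_ONSET_THRESHOLD,
) -> OnsetInterval:
    """Bracket the first threshold crossing of the volume-fraction series."""
    c = np.asarray(concentrations, dtype=float)
    phi = np.asarray(phi_a, dtype=float)
    if c.size == 0 or c.size != phi.size:
        raise ValidationError("need equal-length, non-empty series")
    if np.any(np.diff(c) <= 0):
        raise ValidationError("concentration grid must be strictly ascending")
    above = phi > threshold
    if not above.any():
        return OnsetInterval(None, None, False)
    i = int(np.argmax(above))
    flagged = bool(np.any(~above[i:]))  # dips back below after the crossing
    if i == 0:
        return OnsetInterval(None, float(c[0]), True)
    return OnsetInterval(float(c[i - 1]), float(c[i]), flagged)


def layer_thickness(
    d_coated: float, d_plain: float, u_coated: float = 0.0, u_plain: float = 0.0
) -> tuple[float, float]:
    """Adsorbed-layer thickness from coated vs. plain particle diameters.

    ``t = (d_coated - d_plain) / 2`` with linear worst-case propagation
    ``u = (u_coated + u_plain) / 2``.
    """
    if d_coated < d_plain:
        raise ValidationError("coated diameter must be >= plain diameter")
    return (d_coated - d_plain) / 2.0, (u_coated + u_plain) / 2.0


def layer_count(
    thickness: float, uncertainty: float, monolayer_height: float
) -> tuple[int, int]:
    """Range of adsorbed monolayers consistent with thickness +- uncertainty.

    Bounds are ``(t -+ u) / h`` rounded half-up; the lower bound is
    clamped at zero when the uncertainty covers zero thickness.
    """
    if not (monolayer_height > 0):
        raise ValidationError("monolayer height must be positive")
    lo = max(0.0, (thickness - uncertainty) / monolayer_height)
    hi = max(0.0, (thickness + uncertainty) / monolayer_height)
    return int(math.floor(lo + 0.5)), int(math.floor(hi + 0.5))


# ---------------------------------------------------------------------------
# Experiment configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentConfig:
    """One concentration/pH series, from calibration through onset report.

    The composition is a BSA weight fraction applied to a total-biopolymer
    grid (g/L); the viscosity entering the fits is the stand-in polynomial
    of the alginate share.  When driven synthetically the scenario fields
    (onset, aggregate size and fraction, noise) define the ground truth.
    """

    label: str = "series"
    ph_label: str = "7"
    temperature: float = 294.15
    np_concentration_molar: float = 500e-12
    bsa_weight_fraction: float = 0.0
    concentration_grid: Sequence[float] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    viscosity_params: tuple[float, float] = DEFAULT_VISCOSITY_PARAMS
    calibration_diameter: float = 110e-9
    omega0_true: float = 350e-9
    aspect_ratio_true: float = 11.0
    onset_c: float = 3.5
    onset_width: float = 0.08
    Xa_max: float = 0.005
    d1_true: float = 110e-9
    da_true: float = 400e-9
    replicates: int = 6
    noise_scale: float = 0.02
    n_points: int = 160
    onset_threshold: float = DEFAULT_ONSET_THRESHOLD
    equivalence_tolerance: float = 0.02
    #: smallest fluorescent species the sample can contain.  The labelled
    #: nanoparticles are the only emitters, so fitted diameters below about
    #: half the stock particle size are sub-physical; without this bound a
    #: spurious fast component can absorb short-lag noise and relabel the
    #: real particles as "aggregate", inflating phi_a to ~0.5 on null data.
    fit_d_min: float = 50e-9
    seed: int = 0

    def __post_init__(self) -> None:
        grid = tuple(float(c) for c in self.concentration_grid)
        object.__setattr__(self, "concentration_grid", grid)
        object.__setattr__(self, "viscosity_params", tuple(self.viscosity_params))
        if self.replicates < 1:
            raise ValidationError("every concentration point needs >= 1 replicate")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["concentration_grid"] = list(self.concentration_grid)
        d["viscosity_params"] = list(self.viscosity_params)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: expected a mapping")
        return cls.from_dict(data)


@dataclass(frozen=True)
class SeriesResult:
    """Aggregated outcome of one series.

    ``points`` holds per-concentration replicate means and standard
    errors, ``fits`` one row per replicate fit, ``truth`` the generator's
    ground-truth table when the series was synthetic.
    """

    points: pd.DataFrame
    fits: pd.DataFrame
    onset: OnsetInterval
    calibration: CalibrationResult
    config: ExperimentConfig
    truth: pd.DataFrame | None = None
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _derive_seed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] & 0x7FFFFFFF)


def run_series(config: ExperimentConfig) -> SeriesResult:
    """Run the full chain on a synthetic series: calibrate the detection
    volume from a reference-bead curve, fit every replicate with both
    models at the solution viscosity, select per the Occam rule, and
    aggregate replicate statistics and the onset interval.

    Deterministic given the config seed.  A calibration failure aborts;
    a concentration point whose replicates all fail is flagged and the
    series continues.
    """
    root = np.random.SeedSequence(config.seed)
    cal_seq, scen_seq = root.spawn(2)
    true_volume = DetectionVolume(config.omega0_true, config.aspect_ratio_true)
    water = PhysicalConditions(config.temperature)
    fit_config = FitConfig(
        equivalence_tolerance=config.equivalence_tolerance,
        d_bounds=(config.fit_d_min, 5e-6),
    )

    # daily reference measurement on beads of known diameter
    n_ref = (
        config.np_concentration_molar * 1000.0 * N_A * effective_volume(true_volume)
    )
    ref_curve = simulate_curve(
        ModelParams(n_ref, 0.0, config.calibration_diameter, config.calibration_diameter),
        true_volume,
        water,
        noise_scale=config.noise_scale,
        n_points=config.n_points,
        seed=_derive_seed(cal_seq),
    )
    calibration = calibrate(ref_curve, config.calibration_diameter, water, fit_config)
    cal_volume = calibration.volume

    scenario = ScenarioConfig(
        concentration_grid=config.concentration_grid,
        bsa_weight_fraction=config.bsa_weight_fraction,
        ph_label=config.ph_label,
        onset_c=config.onset_c,
        onset_width=config.onset_width,
        Xa_max=config.Xa_max,
        d1_true=config.d1_true,
        da_true=config.da_true,
        viscosity_params=config.viscosity_params,
        np_concentration_molar=config.np_concentration_molar,
        temperature=config.temperature,
        replicates=config.replicates,
        noise_scale=config.noise_scale,
        n_points=config.n_points,
        seed=_derive_seed(scen_seq),
    )
    records, truth = generate_scenario(scenario, true_volume)

    fit_rows = []
    for rec in records:
        conditions = PhysicalConditions(config.temperature, rec["eta"])
        row = {
            "concentration_g_per_L": rec["concentration"],
            "replicate": rec["replicate"],
            "eta_Pa_s": rec["eta"],
        }
        try:
            fit1 = fit_one_population(rec["curve"], cal_volume, conditions, fit_config)
            fit2 = fit_two_population(rec["curve"], cal_volume, conditions, fit_config)
            chosen = select_model(fit1, fit2, fit_config)
            chosen = viscosity_correct(chosen, rec["eta"])
        except FitFailureError as exc:
            row.update({"model": "failed", "error": str(exc)})
            fit_rows.append(row)
            continue
        row.update(
            {
                "model": chosen.model,
                "N": chosen.N,
                "Xa": chosen.Xa,
                "d1_nm": chosen.d1 * 1e9,
                "da_nm": chosen.da * 1e9,
                "phi_a": chosen.phi_a,
                "chi2_red_1pop": chosen.chi2_red_1pop,
                "chi2_red_2pop": chosen.chi2_red_2pop,
                "size_valid_1": chosen.size_validity[0],
                "size_valid_a": chosen.size_validity[1],
            }
        )
        fit_rows.append(row)
    fits = pd.DataFrame(fit_rows)

    point_rows = []
    series_flags = []
    for c in config.concentration_grid:
        sub = fits[fits["concentration_g_per_L"] == c]
        ok = sub[sub["model"] != "failed"]
        two = ok[ok["model"] == "two_population"]
        row = {
            "concentration_g_per_L": c,
            "n_replicates": len(sub),
            "n_failed": int((sub["model"] == "failed").sum()),
            "n_one_population": int((ok["model"] == "one_population").sum()),
            "n_two_population": len(two),
        }
        if len(ok) == 0:
            series_flags.append(f"all_replicates_failed_at_{c:g}")
            row.update(
                {k: float("nan") for k in (
                    "phi_a_mean", "phi_a_sem", "d1_nm_mean", "d1_nm_sem",
                    "da_nm_mean", "da_nm_sem",
                )}
            )
        else:
            row.update(_mean_sem(ok["phi_a"], "phi_a"))
            row.update(_mean_sem(ok["d1_nm"], "d1_nm"))
            if len(two):
                row.update(_mean_sem(two["da_nm"], "da_nm"))
            else:
                row.update({"da_nm_mean": float("nan"), "da_nm_sem": float("nan")})
        point_rows.append(row)
    points = pd.DataFrame(point_rows)

    valid = points[points["phi_a_mean"].notna()]
    onset = onset_interval(
        valid["concentration_g_per_L"], valid["phi_a_mean"], config.onset_threshold
    )
    return SeriesResult(
        points=points,
        fits=fits,
        onset=onset,
        calibration=calibration,
        config=config,
        truth=truth,
        flags=tuple(series_flags),
    )


def _mean_sem(values: pd.Series, name: str) -> dict:
    vals = np.asarray(values, dtype=float)
    out = {f"{name}_mean": float(vals.mean())}
    out[f"{name}_sem"] = (
        float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size >= 2 else float("nan")
    )
    return out


# ---------------------------------------------------------------------------
# Results I/O
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"


def write_results(result: SeriesResult, directory: str | Path) -> None:
    """Write per-fit and per-point tables (TSV) and a structured run report."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    result.points.to_csv(
        directory / "points.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    result.fits.to_csv(
        directory / "fits.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    if result.truth is not None:
        result.truth.to_csv(
            directory / "truth.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
    report = {
        "software": {"name": "npfcs", "version": __version__},
        "config": result.config.to_dict(),
        "calibration": {
            "omega0_m": float(result.calibration.omega0),
            "aspect_ratio": float(result.calibration.aspect_ratio),
            "n_ref": float(result.calibration.n_ref),
            "chi2_red": float(result.calibration.chi2_red),
            "s_at_lower_bound": bool(result.calibration.s_at_lower_bound),
        },
        "onset": {
            "low_g_per_L": None if result.onset.low is None else float(result.onset.low),
            "high_g_per_L": None if result.onset.high is None else float(result.onset.high),
            "flagged": bool(result.onset.flagged),
            "threshold": float(result.config.onset_threshold),
        },
        "flags": list(result.flags),
    }
    with (directory / "report.yaml").open("w") as fh:
        yaml.safe_dump(report, fh, sort_keys=True)


def read_results(directory: str | Path) -> SeriesResult:
    """Read back a result directory; numeric content round-trips exactly."""
    directory = Path(directory)
    report_path = directory / "report.yaml"
    try:
        with report_path.open() as fh:
            report = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        loc = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise ValidationError(f"{report_path}: malformed report{loc}") from exc
    points = pd.read_csv(directory / "points.tsv", sep="\t")
    fits = pd.read_csv(directory / "fits.tsv", sep="\t")
    truth_path = directory / "truth.tsv"
    truth = pd.read_csv(truth_path, sep="\t") if truth_path.exists() else None
    cal = report["calibration"]
    onset = report["onset"]
    return SeriesResult(
        points=points,
        fits=fits,
        onset=OnsetInterval(onset["low_g_per_L"], onset["high_g_per_L"], onset["flagged"]),
        calibration=CalibrationResult(
            omega0=cal["omega0_m"],
            aspect_ratio=cal["aspect_ratio"],
            n_ref=cal["n_ref"],
            chi2_red=cal["chi2_red"],
            s_at_lower_bound=cal["s_at_lower_bound"],
        ),
        config=ExperimentConfig.from_dict(report["config"]),
        truth=truth,
        flags=tuple(report.get("flags", ())),
    )
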