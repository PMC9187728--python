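"""Synthetic gas-exchange data with a factorial design.

Generates net photosynthetic rate (Pn) observations over a grid of leaf
temperature, photon flux density (PPFD) and blue-light ratio, mimicking a
growth-chamber light-response campaign on cucumber seedlings.  The noiseless
response surface is phenomenological: a non-rectangular hyperbola in light,
modulated by Gaussian response curves in temperature and in blue-light
fraction, with the blue-light optimum drifting upward under temperature
stress (blue-light demand rises when the leaf is away from its thermal
optimum).  Replicate noise is homoscedastic Gaussian, and gross errors of
instrument origin can be injected for testing outlier filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GroundTruthParams",
    "ExperimentDesign",
    "MeasurementRecord",
    "true_pn",
    "generate_dataset",
    "inject_gross_errors",
    "records_to_frame",
    "frame_to_records",
    "write_csv",
    "read_csv",
    "CSV_COLUMNS",
]

#: Fixed CSV dialect: UTF-8, "." decimal separator, one observation per row.
CSV_COLUMNS = ["temperature_C", "ppfd_umol_m2_s", "blue_ratio", "replicate", "pn_umol_m2_s"]

#: PPFD levels of the light-response program, high to low (umol m-2 s-1).
DEFAULT_PPFD_LEVELS = (1600, 1400, 1200, 1000, 800, 600, 400, 200, 100, 50, 30, 20, 10, 5, 0)

#: 16-level variant: one extra level at 900 umol m-2 s-1 yields a 720-group
#: factorial (5 temperatures x 16 light levels x 9 blue ratios).
PPFD_LEVELS_16 = (1600, 1400, 1200, 1000, 900, 800, 600, 400, 200, 100, 50, 30, 20, 10, 5, 0)


@dataclass(frozen=True)
class GroundTruthParams:
    """Parameters of the noiseless Pn surface and the replicate-noise model.

    Attributes
    ----------
    pmax0 : float
        Light-saturated gross assimilation at the joint optimum, umol m-2 s-1.
    alpha0 : float
        Apparent quantum yield (initial slope of the light response).
    theta : float
        Curvature of the non-rectangular hyperbola, in (0, 1).
    rd : float
        Dark respiration, umol m-2 s-1.
    t_opt, t_width : float
        Optimum and Gaussian width of the temperature response, deg C.
    b_opt, b_width : float
        Optimum and Gaussian width of the blue-light-ratio response
        (fractions of total photon flux).
    b_tshift : float
        Upward shift of the blue-light optimum per deg C of departure from
        ``t_opt`` (temperature-stress coupling).
    noise_sd : float
        Standard deviation of the Gaussian replicate noise, umol m-2 s-1.
    seed : int
        Seed of the generator used by :func:`generate_dataset`.
    """

    pmax0: float = 25.0
    alpha0: float = 0.06
    theta: float = 0.8
    rd: float = 1.5
    t_opt: float = 24.0
    t_width: float = 8.0
    b_opt: float = 0.30
    b_width: float = 0.35
    b_tshift: float = 0.02
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < 1.0):
            raise ValueError(f"theta must lie in (0, 1), got {self.theta}")
        if self.pmax0 <= 0:
            raise ValueError("pmax0 must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0.0 < self.b_opt < 1.0):
            raise ValueError("b_opt must lie in (0, 1)")
        if self.t_width <= 0:
            raise ValueError("t_width must be positive")
        for name in ("pmax0", "alpha0", "theta", "rd", "t_opt", "t_width",
                     "b_opt", "b_width", "b_tshift", "noise_sd"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial measurement design: conditions crossed, fixed replicate count.

    Defaults reproduce the light-response campaign: five temperatures from
    18 to 30 deg C, the fifteen-level PPFD program, nine blue-light ratios
    from 10% to 90%, three replicates per condition (675 condition groups,
    2025 observations).
    """

    temperatures: tuple[float, ...] = (18.0, 21.0, 24.0, 27.0, 30.0)
    ppfd_levels: tuple[float, ...] = DEFAULT_PPFD_LEVELS
    blue_ratios: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 10))
    replicates: int = 3

    def __post_init__(self) -> None:
        if not (self.temperatures and self.ppfd_levels and self.blue_ratios):
            raise ValueError("all factor lists must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def n_groups(self) -> int:
        return len(self.temperatures) * len(self.ppfd_levels) * len(self.blue_ratios)

    def with_16_levels(self) -> "ExperimentDesign":
        """Variant with a sixteenth PPFD level (720 condition groups)."""
        return replace(self, ppfd_levels=PPFD_LEVELS_16)


@dataclass(frozen=True)
class MeasurementRecord:
    """One gas-exchange observation."""

    temperature: float  # deg C
    par: float  # photon flux density, umol m-2 s-1
    blue_ratio: float  # blue fraction of total photon flux, in [0, 1]
    replicate: int  # 1-based replicate index
    pn: float  # net photosynthetic rate, umol m-2 s-1

    def __post_init__(self) -> None:
        if self.par < 0:
            raise ValueError("par must be non-negative")
        if not (0.0 <= self.blue_ratio <= 1.0):
            raise ValueError("blue_ratio must lie in [0, 1]")


def true_pn(par, temperature, blue_ratio, params: GroundTruthParams):
    """Noiseless net photosynthetic rate at the given condition.

    The light response is the non-rectangular hyperbola

        NRH(I) = (a*I + P - sqrt((a*I + P)^2 - 4*theta*a*I*P)) / (2*theta)

    with effective plateau P reduced by Gaussian factors in temperature and
    blue-light ratio; dark respiration ``rd`` is subtracted.  Accepts scalars
    or broadcastable arrays; vectorized.
    """
    par = np.asarray(par, dtype=float)
    temperature = np.asarray(temperature, dtype=float)
    blue_ratio = np.asarray(blue_ratio, dtype=float)
    if not (np.all(np.isfinite(par)) and np.all(np.isfinite(temperature))
            and np.all(np.isfinite(blue_ratio))):
        raise ValueError("inputs must be finite")
    if np.any(par < 0):
        raise ValueError("par must be non-negative")

    t_dev = temperature - params.t_opt
    b_center = params.b_opt + params.b_tshift * np.abs(t_dev)
    p_eff = (
        params.pmax0
        * np.exp(-(t_dev**2) / (2.0 * params.t_width**2))
        * np.exp(-((blue_ratio - b_center) ** 2) / (2.0 * params.b_width**2))
    )
    a_i = params.alpha0 * par
    s = a_i + p_eff
    disc = s * s - 4.0 * params.theta * a_i * p_eff
    # disc >= (a_i - p_eff)^2 >= 0 analytically; clip guards rounding
    nrh = (s - np.sqrt(np.clip(disc, 0.0, None))) / (2.0 * params.theta)
    out = nrh - params.rd
    return out if out.ndim else float(out)


def generate_dataset(
    design: ExperimentDesign = ExperimentDesign(),
    params: GroundTruthParams = GroundTruthParams(),
) -> list[MeasurementRecord]:
    """Draw one noisy dataset: every condition crossed with every replicate.

    Records are emitted in design order (temperature, then PPFD, then blue
    ratio, then replicate); ``params.seed`` fully determines the output.
    """
    rng = np.random.default_rng(params.seed)
    records: list[MeasurementRecord] = []
    for t in design.temperatures:
        for par in design.ppfd_levels:
            for b in design.blue_ratios:
                mu = true_pn(par, t, b, params)
                for rep in range(1, design.replicates + 1):
                    noise = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
                    records.append(
                        MeasurementRecord(float(t), float(par), float(b), rep, mu + noise)
                    )
    return records


@dataclass(frozen=True)
class CorruptionManifest:
    """Which condition groups received an injected gross error."""

    groups: tuple[tuple[float, float, float], ...]  # (temperature, par, blue_ratio)
    replicate_index: tuple[int, ...]  # corrupted replicate per group (1-based)
    signs: tuple[int, ...]  # +1 or -1 applied to the magnitude


def inject_gross_errors(
    records: list[MeasurementRecord],
    group_count: int,
    magnitude: float,
    seed: int,
) -> tuple[list[MeasurementRecord], CorruptionManifest]:
    """Shift one replicate's Pn by +/- ``magnitude`` in ``group_count`` groups.

    Groups are distinct condition triples chosen uniformly by a generator
    seeded with ``seed``; the manifest records which groups, which replicate
    and which sign.  Emulates instrument faults later removed by the Dixon
    criterion.
    """
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    keys: list[tuple[float, float, float]] = []
    seen: set[tuple[float, float, float]] = set()
    for r in records:
        k = (r.temperature, r.par, r.blue_ratio)
        if k not in seen:
            seen.add(k)
            keys.append(k)
    if group_count > len(keys):
        raise ValueError(f"group_count {group_count} exceeds {len(keys)} available groups")

    rng = np.random.default_rng(seed)
    chosen_idx = rng.choice(len(keys), size=group_count, replace=False)
    chosen = [keys[i] for i in chosen_idx]

    group_reps: dict[tuple[float, float, float], list[int]] = {}
    for r in records:
        group_reps.setdefault((r.temperature, r.par, r.blue_ratio), []).append(r.replicate)

    targets: dict[tuple[float, float, float], tuple[int, int]] = {}
    reps_out: list[int] = []
    signs_out: list[int] = []
    for k in chosen:
        reps = group_reps[k]
        rep = int(reps[rng.integers(len(reps))])
        sign = 1 if rng.random() < 0.5 else -1
        targets[k] = (rep, sign)
        reps_out.append(rep)
        signs_out.append(sign)

    out: list[MeasurementRecord] = []
    for r in records:
        k = (r.temperature, r.par, r.blue_ratio)
        hit = targets.get(k)
        if hit is not None and r.replicate == hit[0]:
            out.append(replace(r, pn=r.pn + hit[1] * magnitude))
        else:
            out.append(r)
    manifest = CorruptionManifest(tuple(chosen), tuple(reps_out), tuple(signs_out))
    return out, manifest


def records_to_frame(records: list[MeasurementRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "temperature_C": [r.temperature for r in records],
            "ppfd_umol_m2_s": [r.par for r in records],
            "blue_ratio": [r.blue_ratio for r in records],
            "replicate": [r.replicate for r in records],
            "pn_umol_m2_s": [r.pn for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame) -> list[MeasurementRecord]:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    return [
        MeasurementRecord(
            float(row.temperature_C),
            float(row.ppfd_umol_m2_s),
            float(row.blue_ratio),
            int(row.replicate),
            float(row.pn_umol_m2_s),
        )
        for row in df.itertuples(index=False)
    ]


def write_csv(records: list[MeasurementRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_csv(path) -> list[MeasurementRecord]:
    return frame_to_records(pd.read_csv(path))
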