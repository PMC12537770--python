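"""Synthetic data generators emulating the experimental assays.

Produces every input class the pipeline consumes: plate-reader OD curves
(logistic + Gaussian noise, 10-min interval over 24 h), two-gate flow-
cytometry event counts (multinomial sampling, up to 100,000 events),
CFU spot counts (Poisson sampling of a 20-uL spot), and multi-day
replicate competition-frequency series observed through those assays.

Every generator is fully deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .dynamics import (
    DEFAULT_DILUTION,
    InteractionMatrix,
    SpeciesParams,
    simulate_invasion,
    simulate_serial_transfer,
)
from .growth import logistic

#: Plate-reader sampling: every 10 min over 24 h -> 145 points.
OD_TIMES_H = np.arange(0, 145) / 6.0

MAX_FLOW_EVENTS = 100_000


@dataclass(frozen=True)
class SyntheticConfig:
    """Shared settings for the generators."""

    seed: int = 0
    od_noise_sd: float = 0.01
    n_replicates: int = 5
    flow_events: int = MAX_FLOW_EVENTS
    cfu_spot_volume_ul: float = 20.0

    def __post_init__(self) -> None:
        if self.flow_events < 1 or self.flow_events > MAX_FLOW_EVENTS:
            raise ValueError(f"flow_events must be in [1, {MAX_FLOW_EVENTS}]")
        if self.od_noise_sd < 0:
            raise ValueError("od_noise_sd must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.cfu_spot_volume_ul <= 0:
            raise ValueError("cfu_spot_volume_ul must be positive")


def gen_od_curves(
    config: SyntheticConfig,
    true_params: dict[str, tuple[float, float, float]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a randomised 96-well plate of logistic growth curves.

    ``true_params`` maps strain_id -> (K, r, N0) in OD units / per hour.
    Each strain gets ``config.n_replicates`` wells assigned in randomised
    order; each well is a noiseless logistic curve at 10-min intervals over
    24 h plus i.i.d. Gaussian noise (sd ``od_noise_sd``), floored at 0.

    Returns (plate, platemap): the long-form reader table (time_h, well,
    od) and the well-to-strain map (well, strain_id, media_id, replicate).
    """
    rng = np.random.default_rng(config.seed)
    strains = sorted(true_params)
    n_wells = len(strains) * config.n_replicates
    if n_wells > 96:
        raise ValueError("layout exceeds a 96-well plate")
    wells = [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)][:n_wells]
    assignments = [
        (strain, rep)
        for strain in strains
        for rep in range(1, config.n_replicates + 1)
    ]
    rng.shuffle(assignments)

    plate_rows, map_rows = [], []
    for well, (strain, rep) in zip(wells, assignments):
        K, r, N0 = true_params[strain]
        od = logistic(OD_TIMES_H, K, r, N0)
        if config.od_noise_sd > 0:
            od = od + rng.normal(0.0, config.od_noise_sd, size=od.shape)
        od = np.maximum(od, 0.0)
        map_rows.append(
            {"well": well, "strain_id": strain, "media_id": "fresh", "replicate": rep}
        )
        plate_rows.append(
            pd.DataFrame({"time_h": OD_TIMES_H, "well": well, "od": od})
        )
    plate = pd.concat(plate_rows, ignore_index=True)
    platemap = pd.DataFrame(map_rows)
    return plate, platemap


def gen_flow_counts(
    true_freq_E: float,
    events: int = MAX_FLOW_EVENTS,
    seed: int | np.random.Generator = 0,
) -> tuple[int, int]:
    """Two-gate event counts (E. coli gate, yeast gate).

    Draws (count_E, count_Y) from a two-category multinomial over
    ``events`` trials with P(E) = ``true_freq_E``.  Counts always sum to
    ``events``; the estimated frequency is count_E / events.
    """
    if not (0.0 <= true_freq_E <= 1.0):
        raise ValueError("true_freq_E must be in [0, 1]")
    if not (1 <= events <= MAX_FLOW_EVENTS):
        raise ValueError(f"events must be in [1, {MAX_FLOW_EVENTS}]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    count_E, count_Y = rng.multinomial(events, [true_freq_E, 1.0 - true_freq_E])
    return int(count_E), int(count_Y)


def gen_cfu_counts(
    density: float,
    spot_volume_ul: float = 20.0,
    dilution: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> int:
    """Colony count from spotting a diluted culture onto a selective plate.

    Poisson draw with mean density (cells/mL) x spot volume (mL) x
    dilution.  The default 20-uL spot at 10 cells/mL has an expectation of
    0.2 colonies — the limit-of-detection regime.
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    if spot_volume_ul <= 0 or not (0 < dilution <= 1):
        raise ValueError("need spot_volume_ul > 0 and 0 < dilution <= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mean = density * (spot_volume_ul / 1000.0) * dilution
    return int(rng.poisson(mean))


def gen_competition_series(
    params: tuple[SpeciesParams, SpeciesParams, SpeciesParams],
    alphas: InteractionMatrix,
    config: SyntheticConfig,
    n_cycles: int = 7,
    model: str = "freqdep",
    dilution_factor: float = DEFAULT_DILUTION,
    invasion: bool = False,
    equilibration_cycles: int = 3,
    observation: str = "flow",
) -> pd.DataFrame:
    """Replicate daily frequency series of a competition experiment.

    Runs the serial-transfer (or delayed-invader) simulation once, then
    observes the end-of-day states through the flow-cytometry generator
    (E vs Y two-gate counts) or CFU counting, independently per replicate.
    With ``od_noise_sd``-style sampling noise only, the underlying
    trajectory is shared and replicates differ by observation noise alone.

    Returns a long table: replicate, day, plus observed columns
    (freq_E/freq_Y for flow; cfu_E/cfu_Y/cfu_B for plating) and the true
    densities N_E, N_Y, N_B.
    """
    if observation not in ("flow", "cfu"):
        raise ValueError("observation must be 'flow' or 'cfu'")
    if invasion:
        pair = tuple(p for p in params if p.role in ("E", "Y"))
        invader = next(p for p in params if p.role == "B")
        result = simulate_invasion(
            model,
            pair,
            alphas,
            invader,
            equilibration_cycles=equilibration_cycles,
            total_cycles=n_cycles,
            dilution_factor=dilution_factor,
        )
        trajectories = result.cycles
    else:
        trajectories = simulate_serial_transfer(
            model, params, alphas, n_cycles=n_cycles, dilution_factor=dilution_factor
        )

    rng = np.random.default_rng(config.seed)
    rows = []
    for rep in range(1, config.n_replicates + 1):
        for traj in trajectories:
            n_e, n_y, n_b = traj.populations[-1]
            row = {
                "replicate": rep,
                "day": traj.cycle + 1,
                "N_E": n_e,
                "N_Y": n_y,
                "N_B": n_b,
            }
            if observation == "flow":
                total_ey = n_e + n_y
                freq = n_e / total_ey if total_ey > 0 else 0.0
                count_e, count_y = gen_flow_counts(freq, config.flow_events, rng)
                row["freq_E"] = count_e / config.flow_events
                row["freq_Y"] = count_y / config.flow_events
            else:
                for label, dens in (("cfu_E", n_e), ("cfu_Y", n_y), ("cfu_B", n_b)):
                    # dilute dense cultures into a countable range
                    dil = min(1.0, 2000.0 / dens) if dens > 0 else 1.0
                    row[label] = gen_cfu_counts(
                        dens, config.cfu_spot_volume_ul, dil, rng
                    )
                    row[f"{label}_dilution"] = dil
            rows.append(row)
    return pd.DataFrame(rows)


def write_manifest(
    path: str,
    config: SyntheticConfig,
    ground_truth: dict,
    outputs: list[str],
) -> None:
    """Record seed, config and ground-truth parameters for a generated set."""
    manifest = {
        "config": asdict(config),
        "ground_truth": ground_truth,
        "outputs": outputs,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=float)
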