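"""Phase diagrams over pairs of interaction coefficients.

Sweeps two alpha coefficients over a grid (default 0-3 in steps of 0.01,
endpoints inclusive, all other alphas fixed at 0.01), integrates the
frequency-dependent three-species model for 24 h at each grid point,
classifies the endpoint against the extinction threshold, and locates
outcome boundaries along grid slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import (
    InteractionMatrix,
    SpeciesParams,
    default_community,
    integrate_batch,
)
from .outcomes import EXTINCTION_THRESHOLD, classify_simulation

ALPHA_NAMES = ("alpha_EY", "alpha_EB", "alpha_YE", "alpha_YB", "alpha_BE", "alpha_BY")

#: Fig-style colour convention for outcome categories.
CATEGORY_COLOURS = {
    "coexist": "#2ca02c",            # green
    "competitor_extinct": "#9467bd",  # purple
    "ecoli_extinct": "#1f77b4",       # blue
    "yeast_extinct": "#d62728",       # red
    "multiple_extinct": "#7f7f7f",    # grey (not part of the single-extinction legend)
}


@dataclass(frozen=True)
class SweepSpec:
    """Specification of a two-coefficient sweep."""

    axis_x: str
    axis_y: str
    lo: float = 0.0
    hi: float = 3.0
    step: float = 0.01
    fixed_alpha: float = 0.01
    params: tuple[SpeciesParams, SpeciesParams, SpeciesParams] = field(
        default_factory=default_community
    )
    model: str = "freqdep"
    t_end: float = 24.0
    threshold: float = EXTINCTION_THRESHOLD
    rtol: float = 1e-8

    def __post_init__(self) -> None:
        for ax in (self.axis_x, self.axis_y):
            if ax not in ALPHA_NAMES:
                raise ValueError(f"axis {ax!r} not one of {ALPHA_NAMES}")
        if self.axis_x == self.axis_y:
            raise ValueError("axis_x and axis_y must differ")
        if not (self.lo < self.hi and self.step > 0):
            raise ValueError("need lo < hi and step > 0")
        if self.fixed_alpha < 0:
            raise ValueError("fixed_alpha must be non-negative")

    @property
    def values(self) -> np.ndarray:
        """Grid values per axis, endpoints inclusive."""
        n = int(round((self.hi - self.lo) / self.step)) + 1
        return self.lo + self.step * np.arange(n)


@dataclass
class SweepGrid:
    """Outcome categories on the (axis_x, axis_y) grid.

    ``categories[i, j]`` is the label at x = values[j], y = values[i]
    (row = y, column = x, image convention).
    """

    spec: SweepSpec
    categories: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return self.spec.values

    def slice_along_x(self, at_y: float) -> np.ndarray:
        i = _index_of(self.values, at_y)
        return self.categories[i, :]

    def slice_along_y(self, at_x: float) -> np.ndarray:
        j = _index_of(self.values, at_x)
        return self.categories[:, j]


def _index_of(values: np.ndarray, v: float) -> int:
    i = int(np.argmin(np.abs(values - v)))
    if abs(values[i] - v) > 1e-9:
        raise ValueError(f"value {v} is not on the grid")
    return i


def classify_point(
    spec: SweepSpec, alpha_x: float, alpha_y: float
) -> str:
    """Integrate one grid point and classify its endpoint (pure function)."""
    alphas = InteractionMatrix(
        **{
            name: (
                alpha_x
                if name == spec.axis_x
                else alpha_y
                if name == spec.axis_y
                else spec.fixed_alpha
            )
            for name in ALPHA_NAMES
        }
    )
    traj = integrate_batch(
        spec.model,
        spec.params,
        alphas,
        t_end=spec.t_end,
        grid=np.array([0.0, spec.t_end]),
        rtol=spec.rtol,
    )
    return classify_simulation(traj.end_state, spec.threshold).category


def run_sweep(spec: SweepSpec) -> SweepGrid:
    """Classify every grid point; deterministic given the spec.

    Integrator failures propagate with the offending grid coordinates.
    """
    values = spec.values
    cats = np.empty((len(values), len(values)), dtype=object)
    for i, ay in enumerate(values):
        for j, ax in enumerate(values):
            try:
                cats[i, j] = classify_point(spec, float(ax), float(ay))
            except RuntimeError as exc:
                raise RuntimeError(
                    f"integration failed at ({spec.axis_x}={ax:g}, "
                    f"{spec.axis_y}={ay:g}): {exc}"
                ) from exc
    return SweepGrid(spec=spec, categories=cats)


def run_slice(spec: SweepSpec, at_y: float) -> np.ndarray:
    """Labels along axis_x with axis_y held at ``at_y`` (single grid row)."""
    values = spec.values
    _ = _index_of(values, at_y)  # validate at_y is on the grid
    out = np.empty(len(values), dtype=object)
    for j, ax in enumerate(values):
        out[j] = classify_point(spec, float(ax), float(at_y))
    return out


def find_boundary(
    labels: np.ndarray,
    values: np.ndarray,
    from_label: str,
    to_label: str,
) -> float:
    """First transition point along a slice, at grid resolution.

    Returns the smallest axis value whose label equals ``to_label``
    immediately after a run of ``from_label``.  Raises ValueError when the
    slice is uniform or the requested transition never occurs.
    """
    labels = np.asarray(labels)
    if len(labels) != len(values):
        raise ValueError("labels and values must have equal length")
    if len(set(labels.tolist())) == 1:
        raise ValueError("no transition: slice is uniform")
    for k in range(1, len(labels)):
        if labels[k - 1] == from_label and labels[k] == to_label:
            return float(values[k])
    raise ValueError(
        f"no transition: {from_label!r} -> {to_label!r} not found on slice"
    )


def find_boundary_in_grid(
    grid: SweepGrid,
    along: str,
    at: float,
    from_label: str,
    to_label: str,
) -> float:
    """``find_boundary`` on a row or column of a full 2-D grid."""
    if along == "x":
        labels = grid.slice_along_x(at_y=at)
    elif along == "y":
        labels = grid.slice_along_y(at_x=at)
    else:
        raise ValueError("along must be 'x' or 'y'")
    return find_boundary(labels, grid.values, from_label, to_label)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def grid_to_frame(grid: SweepGrid) -> pd.DataFrame:
    """Long-form table: alpha_x, alpha_y, category (one row per cell)."""
    values = grid.values
    yy, xx = np.meshgrid(values, values, indexing="ij")
    return pd.DataFrame(
        {
            "alpha_x": xx.ravel(),
            "alpha_y": yy.ravel(),
            "category": grid.categories.ravel(),
        }
    )


def frame_to_grid(frame: pd.DataFrame, spec: SweepSpec) -> SweepGrid:
    """Rebuild a SweepGrid from its long-form table."""
    values = spec.values
    n = len(values)
    frame = frame.sort_values(["alpha_y", "alpha_x"])
    cats = frame["category"].to_numpy(dtype=object).reshape(n, n)
    return SweepGrid(spec=spec, categories=cats)


def export_phase_diagram(
    grid: SweepGrid, csv_path: str, image_path: str | None = None
) -> None:
    """Write the grid as CSV and (optionally) a categorical heatmap image."""
    grid_to_frame(grid).to_csv(csv_path, index=False)
    if image_path is None:
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    order = list(CATEGORY_COLOURS)
    codes = np.vectorize(order.index)(grid.categories)
    values = grid.values
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.imshow(
        codes,
        origin="lower",
        extent=(values[0], values[-1], values[0], values[-1]),
        cmap=ListedColormap([CATEGORY_COLOURS[c] for c in order]),
        vmin=-0.5,
        vmax=len(order) - 0.5,
        aspect="auto",
        interpolation="nearest",
    )
    ax.set_xlabel(grid.spec.axis_x)
    ax.set_ylabel(grid.spec.axis_y)
    handles = [
        plt.Rectangle((0, 0), 1, 1, color=CATEGORY_COLOURS[c]) for c in order
    ]
    ax.legend(handles, order, loc="upper right", fontsize=7)
    fig.tight_layout()
    fig.savefig(image_path, dpi=150)
    plt.close(fig)
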