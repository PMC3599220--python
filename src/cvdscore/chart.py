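"""SCORE-style absolute-risk charts.

A chart is a grid over sex x smoking x age x systolic blood pressure x a
blood marker (glucose or cholesterol); each cell holds the absolute risk of
fatal CVD over the horizon, as an integer percent.  Panels follow the ESC
chart convention: within a panel, SBP runs down the rows (highest on top) and
the marker across the columns (lowest on the left).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .weibull import WeibullPHModel, predict_absolute_risk

#: Canonical axis order for cell keys, regardless of specification order.
AXIS_ORDER = ("sex", "smoking", "age", "sbp", "marker")

#: Conventional SCORE-chart tick values (the publication prints only one
#: example cell; these grids are chart convention, not study data).
DEFAULT_AXES = {
    "sex": ["male", "female"],
    "smoking": [False, True],
    "age": [40, 50, 55, 60, 65],
    "sbp": [120, 140, 160, 180],
    "glucose": [4, 5, 6, 7, 8],
    "cholesterol": [4, 5, 6, 7, 8],
}


def round_half_up_percent(risk: float) -> int:
    """100*risk rounded half-up to an integer (chart cells are integers)."""
    return int(np.floor(100.0 * risk + 0.5))


@dataclass
class ChartGrid:
    """A rendered risk chart: axes, horizon and integer-percent cells.

    ``cells`` maps ``(sex, smoking, age, sbp, marker_value)`` tuples (canonical
    axis order) to integer percents.  ``marker`` names the blood variable of
    the fifth axis.
    """

    axes: dict[str, list]
    marker: str
    horizon: float
    cells: dict[tuple, int]
    model_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = 1
        for name in AXIS_ORDER[:-1]:
            expected *= len(self.axes[name])
        expected *= len(self.axes[self.marker])
        if len(self.cells) != expected:
            raise ValueError("cells do not cover the axis product exactly")
        for v in self.cells.values():
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 99):
                raise ValueError(f"cell values must be integers in [0, 99], got {v!r}")

    def cell(self, sex, smoking, age, sbp, marker_value) -> int:
        return self.cells[(sex, bool(smoking), age, sbp, marker_value)]

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(zip(("sex", "smoking", "age", "sbp", self.marker), k),
                     risk_percent=v) for k, v in self.cells.items()]
        return pd.DataFrame(rows)


def _axis_values(axes: Mapping, marker: str) -> dict[str, list]:
    out = {}
    for name in ("sex", "smoking", "age", "sbp", marker):
        out[name] = list(axes.get(name, DEFAULT_AXES[name]))
    return out


def build_chart(
    model: WeibullPHModel,
    axes: Mapping[str, Sequence] | None = None,
    horizon: float = 10.0,
    marker: str | None = None,
    fixed: Mapping[str, float] | None = None,
) -> ChartGrid:
    """One predict_absolute_risk call per cell, rounded half-up to percent.

    ``marker`` defaults to whichever of glucose/cholesterol the model carries;
    ``fixed`` supplies values for any model covariate that is neither an axis
    nor the marker (e.g. the second marker of a joint model).
    """
    axes = dict(axes or {})
    if marker is None:
        candidates = [m for m in ("glucose", "cholesterol") if m in model.beta]
        if len(candidates) != 1:
            raise ValueError(
                "marker is ambiguous or absent; pass marker= explicitly "
                f"(model covariates: {list(model.beta)})"
            )
        marker = candidates[0]
    if marker not in model.beta:
        raise ValueError(f"model has no coefficient for marker {marker!r}")
    fixed = dict(fixed or {})
    missing = [c for c in model.beta
               if c not in ("smoking", "sbp", marker) and c not in fixed]
    if missing:
        raise ValueError(f"covariate(s) {missing} need a value via fixed=")

    vals = _axis_values(axes, marker)
    cells = {}
    for sex, smoking, age, sbp, mv in product(
        vals["sex"], vals["smoking"], vals["age"], vals["sbp"], vals[marker]
    ):
        profile = {"sex": sex, "age": float(age), "smoking": float(bool(smoking)),
                   "sbp": float(sbp), marker: float(mv), **fixed}
        r = predict_absolute_risk(model, profile, horizon)
        cells[(sex, bool(smoking), age, sbp, mv)] = round_half_up_percent(r)
    grid_axes = {"sex": vals["sex"], "smoking": vals["smoking"], "age": vals["age"],
                 "sbp": vals["sbp"], marker: vals[marker]}
    return ChartGrid(axes=grid_axes, marker=marker, horizon=horizon,
                     cells=cells,
                     metadata={"fixed": fixed,
                               "axis_source": "convention-default" if not axes else "user"})


def build_stratified_chart(
    model: WeibullPHModel,
    stratifier: str,
    low_value: float,
    high_value: float,
    axes: Mapping[str, Sequence] | None = None,
    horizon: float = 10.0,
    marker: str | None = None,
) -> tuple[ChartGrid, ChartGrid]:
    """Paired charts for a dichotomized second covariate (e.g. cholesterol
    low/high panels of a joint glucose+cholesterol model).  Each level is
    represented by a single value plugged into every cell."""
    if stratifier not in model.beta:
        raise ValueError(f"model has no coefficient for stratifier {stratifier!r}")
    if marker is None:
        candidates = [m for m in ("glucose", "cholesterol")
                      if m in model.beta and m != stratifier]
        if len(candidates) == 1:
            marker = candidates[0]
    low = build_chart(model, axes=axes, horizon=horizon, marker=marker,
                      fixed={stratifier: float(low_value)})
    high = build_chart(model, axes=axes, horizon=horizon, marker=marker,
                       fixed={stratifier: float(high_value)})
    low.metadata["stratum"] = f"{stratifier}={low_value}"
    high.metadata["stratum"] = f"{stratifier}={high_value}"
    return low, high


def grid_from_frame(df: pd.DataFrame, marker: str, horizon: float) -> ChartGrid:
    """Rebuild a ChartGrid from its long-format CSV table."""
    axes = {name: sorted(df[name].unique().tolist()) for name in
            ("sex", "smoking", "age", "sbp", marker)}
    axes["sex"] = [s for s in ("male", "female") if s in axes["sex"]]
    cells = {}
    for _, r in df.iterrows():
        key = (r["sex"], bool(r["smoking"]), r["age"], r["sbp"], r[marker])
        cells[key] = int(r["risk_percent"])
    return ChartGrid(axes=axes, marker=marker, horizon=horizon, cells=cells)


def render_chart(grid: ChartGrid, fmt: str = "csv", path=None):
    """Render a grid as long-format CSV, fixed-width text panels, or a
    colour-banded matplotlib figure.  Returns the artifact (string or Figure)
    and writes it to ``path`` when given."""
    if fmt == "csv":
        out = grid.to_frame().to_csv(index=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(out)
        return out
    if fmt == "text":
        out = _render_text(grid)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(out)
        return out
    if fmt == "figure":
        fig = _render_figure(grid)
        if path is not None:
            fig.savefig(path)
        return fig
    raise ValueError(f"unsupported format: {fmt!r}")


def _panel_matrix(grid: ChartGrid, sex, smoking, age) -> pd.DataFrame:
    """Rows: SBP descending; columns: marker ascending."""
    sbps = sorted(grid.axes["sbp"], reverse=True)
    mks = sorted(grid.axes[grid.marker])
    data = [[grid.cell(sex, smoking, age, sbp, mv) for mv in mks] for sbp in sbps]
    return pd.DataFrame(data, index=sbps, columns=mks)


def _render_text(grid: ChartGrid) -> str:
    buf = io.StringIO()
    buf.write(f"{int(grid.horizon)}-year risk of fatal CVD (%), marker: {grid.marker}\n")
    for sex in grid.axes["sex"]:
        for smoking in grid.axes["smoking"]:
            label = "smoker" if smoking else "non-smoker"
            for age in grid.axes["age"]:
                buf.write(f"\n[{sex}, {label}, age {age}] rows=SBP desc, cols={grid.marker} asc\n")
                mat = _panel_matrix(grid, sex, smoking, age)
                buf.write(mat.to_string() + "\n")
    return buf.getvalue()


#: Colour bands of the conventional chart legend: (upper bound %, colour).
RISK_BANDS = [(1, "#2e7d32"), (2, "#8bc34a"), (4, "#ffeb3b"),
              (9, "#ff9800"), (14, "#f44336"), (100, "#7b1fa2")]


def _render_figure(grid: ChartGrid):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    bounds = [0] + [b + 0.5 for b, _ in RISK_BANDS]
    cmap = ListedColormap([c for _, c in RISK_BANDS])
    norm = BoundaryNorm(bounds, cmap.N)

    sexes, smokes, ages = grid.axes["sex"], grid.axes["smoking"], grid.axes["age"]
    nrows, ncols = len(sexes) * len(smokes), len(ages)
    fig, axarr = plt.subplots(nrows, ncols, figsize=(2.2 * ncols, 1.8 * nrows),
                              squeeze=False)
    for i, (sex, smoking) in enumerate(product(sexes, smokes)):
        for j, age in enumerate(ages):
            ax = axarr[i][j]
            mat = _panel_matrix(grid, sex, smoking, age)
            ax.imshow(mat.values, cmap=cmap, norm=norm, aspect="auto")
            for (r, c), v in np.ndenumerate(mat.values):
                ax.text(c, r, str(v), ha="center", va="center", fontsize=7)
            ax.set_xticks(range(len(mat.columns)), mat.columns, fontsize=6)
            ax.set_yticks(range(len(mat.index)), mat.index, fontsize=6)
            if i == 0:
                ax.set_title(f"age {age}", fontsize=8)
            if j == 0:
                ax.set_ylabel(f"{sex}\n{'smoker' if smoking else 'non-smoker'}",
                              fontsize=7)
    fig.suptitle(f"{int(grid.horizon)}-year risk of fatal CVD (%) by SBP (rows) "
                 f"and {grid.marker} (columns)", fontsize=10)
    fig.tight_layout()
    return fig
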