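"""Age-ordered multimodal visualization of trial-level SART data.

Each participant occupies one vertical line of up to 23 spots (one per
cycle): the spot's height is the cycle's mean correct-action RT, its area
grows with the cycle error fraction, and its colour runs from light brown
(0 mistakes) to black (8 mistakes, the most a plottable cycle can have).
Cycles whose mean RT cannot be computed are not plotted.  Spots whose size
exceeds the cohort mean + 2 SD cutoff ("big spots" = bad performances) get
a white edge.  Three overlay curves add per-participant context: total
SART mistakes, and MMSE and TUG at baseline, the latter two multiplied by
3 so they are legible at the RT scale.

Participants are ordered left-to-right by increasing age (x is the rank,
not the age value, so 5-year age ticks are non-uniformly spaced) and can
additionally be stratified into sequential blocks, e.g. baseline
TUG < 12 s followed by TUG >= 12 s, age-ordered within each block.

Model building is separated from rendering so every layout rule is
testable without an image backend.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap

from . import protocol
from .features import ThresholdResult

logger = logging.getLogger(__name__)

__all__ = ["PlotModel", "build_plot_model", "render_full", "render_thresholded"]

#: colour ramp endpoints: light brown for error-free cycles, black for 8 mistakes
RAMP_LOW = "#C8A165"
RAMP_HIGH = "#000000"
MISTAKE_CMAP = LinearSegmentedColormap.from_list("sart_mistakes", [RAMP_LOW, RAMP_HIGH])

#: marker area range (points^2), linear in error fraction
SPOT_AREA_MIN = 6.0
SPOT_AREA_MAX = 120.0

#: overlay scale factor for MMSE and TUG
OVERLAY_FACTOR = 3.0

STRATUM_PALETTE = {0: "#1f3f8f", 1: "#7fb2e5"}  # dark blue / light blue


@dataclass
class PlotModel:
    """Backend-independent layout of the multimodal visualization.

    ``spots`` has one row per plottable cycle (participant rank, RT
    height, area, colour value, big-spot flag, stratum); ``participants``
    one row per kept participant with overlay values (already scaled);
    ``age_ticks`` the x rank positions where 5-year bands start.
    """

    spots: pd.DataFrame
    participants: pd.DataFrame
    age_ticks: pd.DataFrame
    ordering_var: str
    strata_var: str | None
    strata_cut: float | None
    mistake_threshold: int

    def thresholded(self) -> "PlotModel":
        """The big-spots-only variant: spots restricted to bad performances,
        overlays restricted to participants with at least one big spot."""
        big = self.spots[self.spots["big_spot"]]
        keep = self.participants["participant_id"].isin(big["participant_id"].unique())
        return PlotModel(
            spots=big.reset_index(drop=True),
            participants=self.participants[keep].reset_index(drop=True),
            age_ticks=self.age_ticks,
            ordering_var=self.ordering_var,
            strata_var=self.strata_var,
            strata_cut=self.strata_cut,
            mistake_threshold=self.mistake_threshold,
        )


def build_plot_model(
    metrics: pd.DataFrame,
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    threshold: ThresholdResult,
    ordering_var: str = "age",
    strata: tuple[str, float] | None = None,
) -> PlotModel:
    """Lay out the visualization: ranks, spot geometry, overlays, ticks.

    ``metrics`` is the pooled per-cycle table (with participant_id),
    ``features`` the per-participant features, ``cohort`` the clinical
    table providing the ordering variable, MMSE/TUG overlays and the
    optional stratification column.  Participants lacking the ordering
    variable are dropped with a warning.  Ties in the ordering variable
    break stably by participant id.
    """
    info = cohort.set_index("participant_id")
    ids = [pid for pid in features["participant_id"] if pid in info.index]
    order_vals = info.loc[ids, ordering_var]
    missing = order_vals.isna()
    if missing.any():
        warnings.warn(
            f"dropping {int(missing.sum())} participant(s) with missing {ordering_var!r}"
        )
    part = pd.DataFrame({"participant_id": order_vals.index[~missing]})
    part[ordering_var] = order_vals[~missing].to_numpy()

    strata_var = strata_cut = None
    if strata is not None:
        strata_var, strata_cut = strata
        sv = info.loc[part["participant_id"], strata_var]
        drop = sv.isna()
        if drop.any():
            warnings.warn(
                f"dropping {int(drop.sum())} participant(s) with missing {strata_var!r}"
            )
            part = part[~drop.to_numpy()].reset_index(drop=True)
            sv = sv[~drop]
        part["stratum"] = (sv.to_numpy() >= strata_cut).astype(int)  # 0: low block, 1: high
    else:
        part["stratum"] = 0

    part = part.sort_values(
        ["stratum", ordering_var, "participant_id"], kind="stable"
    ).reset_index(drop=True)
    part["rank"] = np.arange(len(part))

    feat = features.set_index("participant_id")
    part["total_mistakes"] = feat.loc[part["participant_id"], "total_mistakes"].to_numpy(float)
    part["mmse_x3"] = (
        info.loc[part["participant_id"], "mmse_w1"].to_numpy(float) * OVERLAY_FACTOR
        if "mmse_w1" in info.columns else np.nan
    )
    part["tug_x3"] = (
        info.loc[part["participant_id"], "tug_w1"].to_numpy(float) * OVERLAY_FACTOR
        if "tug_w1" in info.columns else np.nan
    )

    rank_of = dict(zip(part["participant_id"], part["rank"]))
    stratum_of = dict(zip(part["participant_id"], part["stratum"]))
    spots = metrics[
        metrics["plottable"].astype(bool) & metrics["participant_id"].isin(rank_of)
    ].copy()
    spots["rank"] = spots["participant_id"].map(rank_of)
    spots["stratum"] = spots["participant_id"].map(stratum_of)
    spots["big_spot"] = spots["n_mistakes"] >= threshold.mistake_threshold
    spots["area"] = SPOT_AREA_MIN + (SPOT_AREA_MAX - SPOT_AREA_MIN) * spots["error_fraction"]
    spots["color_value"] = np.minimum(spots["n_mistakes"], protocol.N_GO_PER_CYCLE) / protocol.N_GO_PER_CYCLE
    spots = spots[
        ["participant_id", "rank", "stratum", "cycle_index", "n_mistakes",
         "error_fraction", "mean_rt_correct_ms", "area", "color_value", "big_spot"]
    ].reset_index(drop=True)

    # 5-year age-band boundaries: first rank at or past each boundary, per stratum
    ticks = []
    if ordering_var == "age":
        for stratum, block in part.groupby("stratum"):
            ages = block[ordering_var].to_numpy(float)
            lo = 5 * np.floor(ages.min() / 5)
            for bound in np.arange(lo + 5, ages.max() + 1e-9, 5):
                idx = np.searchsorted(ages, bound)
                if 0 < idx < len(ages):
                    ticks.append(
                        {"stratum": stratum, "age": float(bound),
                         "rank": int(block["rank"].iloc[idx])}
                    )
    age_ticks = pd.DataFrame(ticks, columns=["stratum", "age", "rank"])

    return PlotModel(
        spots=spots,
        participants=part,
        age_ticks=age_ticks,
        ordering_var=ordering_var,
        strata_var=strata_var,
        strata_cut=strata_cut,
        mistake_threshold=threshold.mistake_threshold,
    )


def _render(model: PlotModel, path: str | Path, title: str) -> None:
    fig, ax = plt.subplots(figsize=(12, 6))
    sp = model.spots
    if len(sp):
        if model.strata_var is not None:
            base_color = sp["stratum"].map(STRATUM_PALETTE)
            ax.scatter(
                sp["rank"], sp["mean_rt_correct_ms"], s=sp["area"], c=base_color,
                alpha=0.85, linewidths=0,
            )
            shade = ax.scatter(
                sp["rank"], sp["mean_rt_correct_ms"], s=sp["area"], c=sp["color_value"],
                cmap=MISTAKE_CMAP, vmin=0, vmax=1, alpha=0.35, linewidths=0,
            )
        else:
            shade = ax.scatter(
                sp["rank"], sp["mean_rt_correct_ms"], s=sp["area"], c=sp["color_value"],
                cmap=MISTAKE_CMAP, vmin=0, vmax=1, alpha=0.9, linewidths=0,
            )
        big = sp[sp["big_spot"]]
        if len(big):
            ax.scatter(
                big["rank"], big["mean_rt_correct_ms"], s=big["area"],
                facecolors="none", edgecolors="white", linewidths=0.9,
            )
        fig.colorbar(shade, ax=ax, label="mistakes in cycle (0..8)")
    part = model.participants
    ax.plot(part["rank"], part["total_mistakes"], lw=0.8, color="#aa3333",
            label="total mistakes")
    ax.plot(part["rank"], part["mmse_x3"], lw=0.8, color="#2a7e2a", label="MMSE x3")
    ax.plot(part["rank"], part["tug_x3"], lw=0.8, color="#555555", label="TUG x3")
    for _, t in model.age_ticks.iterrows():
        ax.axvline(t["rank"], color="0.85", lw=0.5, zorder=0)
    if model.strata_var is not None and (part["stratum"] == 1).any():
        split = part.loc[part["stratum"] == 1, "rank"].min()
        ax.axvline(split - 0.5, color="black", lw=1.0, ls="--")
    ax.set_xlabel(f"participants ordered by {model.ordering_var} (ticks: 5-year bands)")
    ax.set_ylabel("mean correct-action RT (ms) / overlay value")
    ax.set_title(title)
    ax.legend(loc="upper left", fontsize=8)
    ax.set_xticks(model.age_ticks["rank"] if len(model.age_ticks) else [])
    ax.set_xticklabels(
        [f"{a:.0f}" for a in model.age_ticks["age"]] if len(model.age_ticks) else []
    )
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_full(model: PlotModel, path: str | Path) -> None:
    """Render the full multimodal visualization to PNG/SVG/PDF (by extension)."""
    if not len(model.participants):
        raise ValueError("cannot render an empty plot model")
    _render(model, path, "Multimodal SART visualization")


def render_thresholded(model: PlotModel, path: str | Path) -> None:
    """Render the big-spots-only variant.

    Accepts either a full model (thresholded on the fly) or the result of
    :meth:`PlotModel.thresholded`.  A model with zero big spots still
    produces a file, with a warning.
    """
    thr = model.thresholded() if model.spots["big_spot"].eq(False).any() else model
    if not len(thr.spots):
        warnings.warn("no big spots to render; writing an empty thresholded plot")
    _render(thr, path, f"Thresholded visualization (>= {model.mistake_threshold} mistakes)")
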