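"""Trial-level SART feature extraction.

This module turns raw per-presentation SART records into the per-cycle
metrics used by the multimodal visualization, pools them to derive the
"big spot" threshold (mean spot size plus two standard deviations across
all plottable cycles of all participants), and extracts the per-participant
candidate predictors: *bad performances* (cycles at or above the implied
integer mistake threshold), *total mistakes*, and *mistakes in good
performances*.

Terminology: a *presentation* is a single digit display (207 per
administration); a *cycle* is one 1..9 run (23 per administration).  Spot
sizes, thresholds and bad performances are defined per cycle.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import protocol

logger = logging.getLogger(__name__)

__all__ = [
    "SARTStream",
    "ThresholdResult",
    "ParticipantFeatures",
    "SARTFormatError",
    "SARTValidationError",
    "InsufficientDataError",
    "parse_raw_sart",
    "write_raw_sart",
    "cycle_metrics",
    "pooled_cycle_metrics",
    "compute_threshold",
    "participant_features",
    "features_table",
]


class SARTFormatError(ValueError):
    """Raised when a raw SART file does not conform to the CSV dialect."""


class SARTValidationError(ValueError):
    """Raised when a stream violates the 207-presentation protocol."""


class InsufficientDataError(ValueError):
    """Raised when too few plottable cycles exist to estimate a threshold."""


@dataclass
class SARTStream:
    """One participant's full SART administration.

    ``rt_ms`` is NaN wherever there was no press.  A press with NaN RT is a
    legal "missing RT" datum (the recording failed); the affected cycle
    cannot be plotted but its mistakes still count.
    """

    participant_id: str
    digit: np.ndarray
    pressed: np.ndarray
    rt_ms: np.ndarray

    def __post_init__(self) -> None:
        self.digit = np.asarray(self.digit, dtype=np.int8)
        self.pressed = np.asarray(self.pressed, dtype=bool)
        self.rt_ms = np.asarray(self.rt_ms, dtype=float)

    def validate(self) -> "SARTStream":
        n = protocol.N_PRESENTATIONS
        for name, arr in (("digit", self.digit), ("pressed", self.pressed), ("rt_ms", self.rt_ms)):
            if arr.shape != (n,):
                raise SARTValidationError(
                    f"participant {self.participant_id!r}: {name} has "
                    f"{arr.shape[0] if arr.ndim == 1 else arr.shape} entries, expected {n}"
                )
        expected = protocol.digit_sequence()
        bad = np.nonzero(self.digit != expected)[0]
        if bad.size:
            i = int(bad[0])
            raise SARTValidationError(
                f"participant {self.participant_id!r}: digit at presentation "
                f"{i + 1} is {int(self.digit[i])}, expected {int(expected[i])} "
                "(digits must follow the repeating 1..9 cycle)"
            )
        if np.any(~self.pressed & ~np.isnan(self.rt_ms)):
            raise SARTValidationError(
                f"participant {self.participant_id!r}: RT recorded on a presentation with no press"
            )
        with np.errstate(invalid="ignore"):
            if np.any(np.nan_to_num(self.rt_ms, nan=1.0) <= 0):
                raise SARTValidationError(
                    f"participant {self.participant_id!r}: non-positive RT"
                )
        return self


@dataclass(frozen=True)
class ThresholdResult:
    """The cohort-level big-spot threshold.

    ``cutoff = size_mean + 2 * size_sd`` in error-fraction units, estimated
    over plottable cycles only.  ``mistake_threshold`` is the smallest
    integer k in 1..9 with k/9 strictly above the cutoff; 10 encodes "no
    cycle can exceed the cutoff".
    """

    size_mean: float
    size_sd: float
    cutoff: float
    mistake_threshold: int
    n_big_spots: int
    n_participants_with_big_spots: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "size_mean": self.size_mean,
                    "size_sd": self.size_sd,
                    "cutoff": self.cutoff,
                    "mistake_threshold": self.mistake_threshold,
                    "n_big_spots": self.n_big_spots,
                    "n_participants_with_big_spots": self.n_participants_with_big_spots,
                },
                indent=2,
            )
        )

    @classmethod
    def pinned(cls, mistake_threshold: int) -> "ThresholdResult":
        """A threshold fixed a priori (e.g. 4 mistakes out of 9) rather than
        recomputed from the analysed dataset; used for cross-dataset
        comparability."""
        cutoff = (mistake_threshold - 1) / protocol.CYCLE_LENGTH
        return cls(
            size_mean=float("nan"),
            size_sd=float("nan"),
            cutoff=cutoff,
            mistake_threshold=int(mistake_threshold),
            n_big_spots=-1,
            n_participants_with_big_spots=-1,
        )


@dataclass(frozen=True)
class ParticipantFeatures:
    participant_id: str
    mean_rt_ms: float
    sd_rt_ms: float
    total_mistakes: int
    bad_performances: int
    mistakes_in_good_performances: int
    n_unplottable_cycles: int


# ---------------------------------------------------------------------------
# raw CSV I/O
# ---------------------------------------------------------------------------

def write_raw_sart(streams: Iterable[SARTStream], path: str | Path) -> None:
    """Write streams to the long-format raw SART CSV dialect.

    Columns: participant_id, presentation_index (1..207), cycle_index
    (1..23), digit (1..9), pressed (0/1), rt_ms (empty when no press or the
    RT is missing).
    """
    frames = []
    pres_idx = np.arange(1, protocol.N_PRESENTATIONS + 1)
    cyc_idx = np.repeat(np.arange(1, protocol.N_CYCLES + 1), protocol.CYCLE_LENGTH)
    for s in streams:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "presentation_index": pres_idx,
                    "cycle_index": cyc_idx,
                    "digit": s.digit,
                    "pressed": s.pressed.astype(int),
                    "rt_ms": s.rt_ms,
                }
            )
        )
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=list(protocol.RAW_SART_COLUMNS))
    out.to_csv(path, index=False)


def parse_raw_sart(path: str | Path) -> list[SARTStream]:
    """Read a raw long-format SART CSV into validated streams.

    Rows are sorted by presentation index within participant; participants
    keep file order of first appearance.  Malformed digit sequences or
    wrong row counts raise :class:`SARTValidationError`.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty raw SART file, no streams parsed")
        return []
    missing = set(protocol.RAW_SART_COLUMNS) - set(df.columns)
    if missing:
        raise SARTFormatError(f"{path}: missing required column(s) {sorted(missing)}")
    if df.empty:
        warnings.warn(f"{path}: empty raw SART file, no streams parsed")
        return []
    streams: list[SARTStream] = []
    for pid, grp in df.groupby("participant_id", sort=False):
        grp = grp.sort_values("presentation_index")
        if len(grp) != protocol.N_PRESENTATIONS:
            raise SARTValidationError(
                f"participant {pid!r}: {len(grp)} rows, expected {protocol.N_PRESENTATIONS}"
            )
        pressed = grp["pressed"].to_numpy().astype(bool)
        rt = grp["rt_ms"].to_numpy(dtype=float)
        rt[~pressed] = np.nan
        streams.append(
            SARTStream(
                participant_id=str(pid),
                digit=grp["digit"].to_numpy(),
                pressed=pressed,
                rt_ms=rt,
            ).validate()
        )
    return streams


# ---------------------------------------------------------------------------
# per-cycle metrics
# ---------------------------------------------------------------------------

_METRIC_COLUMNS = [
    "cycle_index",
    "n_omissions",
    "n_commissions",
    "n_mistakes",
    "n_correct_actions",
    "error_fraction",
    "mean_rt_correct_ms",
    "plottable",
]


def cycle_metrics(stream: SARTStream, validate: bool = True) -> pd.DataFrame:
    """Per-cycle mistake decomposition and mean correct-action RT.

    Returns a 23-row frame.  ``mean_rt_correct_ms`` averages the RTs of
    correct GO presses only (commission RTs are never used); it is NaN --
    and the cycle is not plottable -- when the cycle has no correct press
    or when any GO press in it lacks a recorded RT.
    """
    if validate:
        stream.validate()
    go = protocol.go_mask().reshape(protocol.N_CYCLES, protocol.CYCLE_LENGTH)
    pressed = stream.pressed.reshape(protocol.N_CYCLES, protocol.CYCLE_LENGTH)
    rt = stream.rt_ms.reshape(protocol.N_CYCLES, protocol.CYCLE_LENGTH)

    omissions = (go & ~pressed).sum(axis=1)
    commissions = (~go & pressed).sum(axis=1)
    go_press = go & pressed
    rt_missing = go_press & np.isnan(rt)
    n_correct = (go_press & ~np.isnan(rt)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cycles
        mean_rt = np.nanmean(np.where(go_press, rt, np.nan), axis=1)
    mean_rt = np.where(rt_missing.any(axis=1) | (n_correct == 0), np.nan, mean_rt)

    mistakes = omissions + commissions
    return pd.DataFrame(
        {
            "cycle_index": np.arange(1, protocol.N_CYCLES + 1),
            "n_omissions": omissions,
            "n_commissions": commissions,
            "n_mistakes": mistakes,
            "n_correct_actions": n_correct,
            "error_fraction": mistakes / protocol.CYCLE_LENGTH,
            "mean_rt_correct_ms": mean_rt,
            "plottable": ~np.isnan(mean_rt),
        },
        columns=_METRIC_COLUMNS,
    )


def _stacked_metric_arrays(streams: Sequence[SARTStream], validate: bool) -> dict[str, np.ndarray]:
    """Vectorised per-cycle metrics over a whole cohort: (n_streams, 23) arrays."""
    if validate:
        for s in streams:
            s.validate()
    nc, cl = protocol.N_CYCLES, protocol.CYCLE_LENGTH
    pressed = np.stack([s.pressed for s in streams]).reshape(len(streams), nc, cl)
    rt = np.stack([s.rt_ms for s in streams]).reshape(len(streams), nc, cl)
    go = protocol.go_mask().reshape(nc, cl)[None, :, :]

    omissions = (go & ~pressed).sum(axis=2)
    commissions = (~go & pressed).sum(axis=2)
    go_press = go & pressed
    rt_missing = (go_press & np.isnan(rt)).any(axis=2)
    n_correct = (go_press & ~np.isnan(rt)).sum(axis=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_rt = np.nanmean(np.where(go_press, rt, np.nan), axis=2)
    mean_rt = np.where(rt_missing | (n_correct == 0), np.nan, mean_rt)
    mistakes = omissions + commissions
    return {
        "n_omissions": omissions,
        "n_commissions": commissions,
        "n_mistakes": mistakes,
        "n_correct_actions": n_correct,
        "mean_rt_correct_ms": mean_rt,
        "plottable": ~np.isnan(mean_rt),
    }


def pooled_cycle_metrics(streams: Sequence[SARTStream], validate: bool = True) -> pd.DataFrame:
    """Cycle metrics for every stream, stacked with a participant_id column.

    Row-for-row identical to concatenating :func:`cycle_metrics` over the
    streams, but computed on stacked arrays.
    """
    if not streams:
        return pd.DataFrame(columns=["participant_id"] + _METRIC_COLUMNS)
    a = _stacked_metric_arrays(streams, validate)
    n, nc = len(streams), protocol.N_CYCLES
    return pd.DataFrame(
        {
            "participant_id": np.repeat(np.asarray([s.participant_id for s in streams], dtype=object), nc),
            "cycle_index": np.tile(np.arange(1, nc + 1), n),
            "n_omissions": a["n_omissions"].ravel(),
            "n_commissions": a["n_commissions"].ravel(),
            "n_mistakes": a["n_mistakes"].ravel(),
            "n_correct_actions": a["n_correct_actions"].ravel(),
            "error_fraction": a["n_mistakes"].ravel() / protocol.CYCLE_LENGTH,
            "mean_rt_correct_ms": a["mean_rt_correct_ms"].ravel(),
            "plottable": a["plottable"].ravel(),
        },
        columns=["participant_id"] + _METRIC_COLUMNS,
    )


# ---------------------------------------------------------------------------
# the big-spot threshold
# ---------------------------------------------------------------------------

def compute_threshold(all_metrics: pd.DataFrame) -> ThresholdResult:
    """Mean + 2 SD spot-size rule over all plottable cycles of all participants.

    Spot size is the cycle error fraction (mistakes / 9).  Cycles with no
    computable mean RT (no correct action, or a missing RT) are excluded
    from the mean/SD estimate.  The implied integer threshold is the
    smallest mistake count whose fraction strictly exceeds the cutoff.
    """
    plottable = all_metrics[all_metrics["plottable"].astype(bool)]
    if len(plottable) < 2:
        raise InsufficientDataError(
            f"need at least 2 plottable cycles to estimate a threshold, got {len(plottable)}"
        )
    sizes = plottable["error_fraction"].to_numpy(dtype=float)
    size_mean = float(sizes.mean())
    size_sd = float(sizes.std(ddof=1))
    cutoff = size_mean + 2.0 * size_sd

    mistake_threshold = protocol.CYCLE_LENGTH + 1  # 10: nothing can exceed
    for k in range(1, protocol.CYCLE_LENGTH + 1):
        if k / protocol.CYCLE_LENGTH > cutoff:
            mistake_threshold = k
            break

    big = plottable[plottable["n_mistakes"] >= mistake_threshold]
    return ThresholdResult(
        size_mean=size_mean,
        size_sd=size_sd,
        cutoff=cutoff,
        mistake_threshold=mistake_threshold,
        n_big_spots=int(len(big)),
        n_participants_with_big_spots=(
            int(big["participant_id"].nunique()) if "participant_id" in big.columns else -1
        ),
    )


# ---------------------------------------------------------------------------
# participant-level features
# ---------------------------------------------------------------------------

def participant_features(
    stream: SARTStream,
    threshold: ThresholdResult,
    bad_perf_plottable_only: bool = False,
    validate: bool = True,
) -> ParticipantFeatures:
    """The candidate predictors for one participant.

    ``mean_rt_ms`` / ``sd_rt_ms`` are taken over all recorded correct-GO
    RTs across the whole task.  A cycle counts as a bad performance when
    its mistake count reaches ``threshold.mistake_threshold``; with the
    default policy unplottable cycles are included (a cycle with no press
    at all has 8 mistakes and is plainly a bad performance), while
    ``bad_perf_plottable_only=True`` restricts bad performances to cycles
    that appear as spots in the graph.
    """
    metrics = cycle_metrics(stream, validate=validate)
    go_press_rt = stream.rt_ms[protocol.go_mask() & stream.pressed]
    go_press_rt = go_press_rt[~np.isnan(go_press_rt)]
    mean_rt = float(go_press_rt.mean()) if go_press_rt.size else float("nan")
    sd_rt = float(go_press_rt.std(ddof=1)) if go_press_rt.size > 1 else float("nan")

    eligible = metrics["plottable"] if bad_perf_plottable_only else pd.Series(True, index=metrics.index)
    is_bad = (metrics["n_mistakes"] >= threshold.mistake_threshold) & eligible
    total = int(metrics["n_mistakes"].sum())
    bad_mistakes = int(metrics.loc[is_bad, "n_mistakes"].sum())
    return ParticipantFeatures(
        participant_id=stream.participant_id,
        mean_rt_ms=mean_rt,
        sd_rt_ms=sd_rt,
        total_mistakes=total,
        bad_performances=int(is_bad.sum()),
        mistakes_in_good_performances=total - bad_mistakes,
        n_unplottable_cycles=int((~metrics["plottable"]).sum()),
    )


def features_table(
    streams: Sequence[SARTStream],
    threshold: ThresholdResult,
    bad_perf_plottable_only: bool = False,
    validate: bool = True,
) -> pd.DataFrame:
    """Per-participant features for a whole cohort, one row per stream.

    Vectorised equivalent of mapping :func:`participant_features` over the
    streams (the per-stream function is kept as the reference path).
    """
    cols = [
        "participant_id",
        "mean_rt_ms",
        "sd_rt_ms",
        "total_mistakes",
        "bad_performances",
        "mistakes_in_good_performances",
        "n_unplottable_cycles",
    ]
    if not streams:
        return pd.DataFrame(columns=cols)
    a = _stacked_metric_arrays(streams, validate)
    nc, cl = protocol.N_CYCLES, protocol.CYCLE_LENGTH
    rt = np.stack([s.rt_ms for s in streams])
    pressed = np.stack([s.pressed for s in streams])
    go = protocol.go_mask()[None, :]
    correct_rt = np.where(go & pressed, rt, np.nan)
    n_rt = (~np.isnan(correct_rt)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_rt = np.nanmean(correct_rt, axis=1)
        sd_rt = np.nanstd(correct_rt, axis=1, ddof=1)
    sd_rt = np.where(n_rt > 1, sd_rt, np.nan)
    mean_rt = np.where(n_rt > 0, mean_rt, np.nan)

    mistakes = a["n_mistakes"]
    eligible = a["plottable"] if bad_perf_plottable_only else np.ones_like(mistakes, dtype=bool)
    is_bad = (mistakes >= threshold.mistake_threshold) & eligible
    total = mistakes.sum(axis=1)
    bad_mistakes = np.where(is_bad, mistakes, 0).sum(axis=1)
    return pd.DataFrame(
        {
            "participant_id": [s.participant_id for s in streams],
            "mean_rt_ms": mean_rt,
            "sd_rt_ms": sd_rt,
            "total_mistakes": total,
            "bad_performances": is_bad.sum(axis=1),
            "mistakes_in_good_performances": total - bad_mistakes,
            "n_unplottable_cycles": (~a["plottable"]).sum(axis=1),
        },
        columns=cols,
    )
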