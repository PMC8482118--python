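"""Shared fixtures and independent oracle helpers.

The oracles here deliberately avoid the package's vectorised code paths:
mistake counting walks presentations one by one, and the threshold oracle
uses the statistics module on a plain list.
"""

from __future__ import annotations

import statistics

import numpy as np
import pandas as pd
import pytest

from sartkit import SARTStream, protocol


def make_stream(pid: str = "P1", cycles: list[dict] | None = None) -> SARTStream:
    """Build a stream from per-cycle specs.

    Each spec may set ``omit`` (list of GO digits not pressed), ``commit``
    (press on the 3), ``rt`` (base RT for presses), and ``missing_rt``
    (list of GO digits pressed but with no recorded RT).  Unspecified
    cycles are perfect (all GO pressed at 400 ms, 3 withheld).
    """
    cycles = cycles or []
    digit = protocol.digit_sequence()
    pressed = digit != protocol.NOGO_DIGIT
    rt = np.where(pressed, 400.0, np.nan)
    for c, spec in enumerate(cycles):
        base = c * protocol.CYCLE_LENGTH
        for d in spec.get("omit", []):
            i = base + d - 1
            pressed[i] = False
            rt[i] = np.nan
        if spec.get("commit", False):
            i = base + protocol.NOGO_DIGIT - 1
            pressed[i] = True
            rt[i] = spec.get("rt", 400.0)
        if "rt" in spec:
            for d in range(1, 10):
                i = base + d - 1
                if pressed[i]:
                    rt[i] = spec["rt"]
        for d in spec.get("missing_rt", []):
            i = base + d - 1
            assert pressed[i]
            rt[i] = np.nan
    return SARTStream(participant_id=pid, digit=digit, pressed=pressed, rt_ms=rt)


def random_stream(rng: np.random.Generator, pid: str = "R1") -> SARTStream:
    """A random but protocol-conforming stream (independent of simulate)."""
    digit = protocol.digit_sequence()
    go = digit != protocol.NOGO_DIGIT
    pressed = np.where(go, rng.random(digit.size) > 0.15, rng.random(digit.size) < 0.25)
    rt = np.where(pressed, rng.lognormal(5.9, 0.3, digit.size), np.nan)
    # occasional missing RTs on presses
    lost = pressed & (rng.random(digit.size) < 0.02)
    rt[lost] = np.nan
    return SARTStream(participant_id=pid, digit=digit, pressed=pressed, rt_ms=rt)


def brute_force_cycle_counts(stream: SARTStream) -> list[dict]:
    """Per-cycle mistake decomposition by walking presentations one by one."""
    out = []
    for c in range(protocol.N_CYCLES):
        om = com = n_correct = 0
        rts: list[float] = []
        missing = False
        for j in range(protocol.CYCLE_LENGTH):
            i = c * protocol.CYCLE_LENGTH + j
            d = int(stream.digit[i])
            p = bool(stream.pressed[i])
            r = float(stream.rt_ms[i])
            if d == protocol.NOGO_DIGIT:
                if p:
                    com += 1
            else:
                if not p:
                    om += 1
                else:
                    if np.isnan(r):
                        missing = True
                    else:
                        n_correct += 1
                        rts.append(r)
        mean_rt = float("nan") if (missing or n_correct == 0) else sum(rts) / len(rts)
        out.append(
            {
                "n_omissions": om,
                "n_commissions": com,
                "n_mistakes": om + com,
                "n_correct_actions": n_correct,
                "mean_rt_correct_ms": mean_rt,
                "plottable": not (missing or n_correct == 0),
            }
        )
    return out


def brute_force_threshold(error_fractions: list[float]) -> tuple[float, int]:
    """Cutoff and integer mistake threshold via the statistics module."""
    cutoff = statistics.mean(error_fractions) + 2 * statistics.stdev(error_fractions)
    for k in range(1, 10):
        if k / 9 > cutoff:
            return cutoff, k
    return cutoff, 10


def cross_ratio(a: int, b: int, c: int, d: int) -> float:
    """Closed-form 2x2 odds ratio: exposed (a events, b non) vs unexposed."""
    return (a * d) / (b * c)


@pytest.fixture(scope="session")
def small_cohort():
    """A default-config cohort shared across tests; large enough that every
    covariate level of the fully adjusted model sees events."""
    import sartkit

    cfg = sartkit.default_config()
    cfg.n_participants = 1500
    streams, cohort = sartkit.generate_cohort(cfg, seed=42)
    return cfg, streams, cohort


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    """Features + merged analysis table for the shared cohort."""
    import sartkit
    from sartkit import outcomes as outc

    _, streams, cohort = small_cohort
    metrics = sartkit.pooled_cycle_metrics(streams, validate=False)
    thr = sartkit.ThresholdResult.pinned(4)
    features = sartkit.features_table(streams, thr, validate=False)
    table = outc.merge_waves(cohort, features)
    return metrics, thr, features, table
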