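"""SART (Sustained Attention to Response Task) protocol constants.

One administration shows the digits 1..9 in order, 23 times in a row.
Every digit except 3 is a GO presentation (press as fast as possible);
the digit 3 is the NO-GO presentation (withhold the press).  Pressing on
a 3 is a commission error, failing to press on any other digit is an
omission error.
"""

from __future__ import annotations

import numpy as np

#: digits shown within one cycle, in presentation order
CYCLE_DIGITS = (1, 2, 3, 4, 5, 6, 7, 8, 9)

#: number of times the 1..9 cycle is repeated
N_CYCLES = 23

#: presentations per cycle
CYCLE_LENGTH = 9

#: total stimulus presentations per administration (23 * 9)
N_PRESENTATIONS = N_CYCLES * CYCLE_LENGTH  # 207

#: the withhold digit
NOGO_DIGIT = 3

#: GO presentations per cycle / per administration
N_GO_PER_CYCLE = CYCLE_LENGTH - 1  # 8
N_GO = N_GO_PER_CYCLE * N_CYCLES  # 184

#: stimulus duration and inter-stimulus interval, milliseconds
STIMULUS_DURATION_MS = 300
INTER_STIMULUS_INTERVAL_MS = 800

#: column names of the raw long-format SART CSV
RAW_SART_COLUMNS = (
    "participant_id",
    "presentation_index",
    "cycle_index",
    "digit",
    "pressed",
    "rt_ms",
)


def digit_sequence() -> np.ndarray:
    """The full 207-long digit sequence of one administration."""
    return np.tile(np.asarray(CYCLE_DIGITS, dtype=np.int8), N_CYCLES)


def go_mask() -> np.ndarray:
    """Boolean mask of GO presentations over the 207-long sequence."""
    return digit_sequence() != NOGO_DIGIT
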