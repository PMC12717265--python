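"""Clinical line protocol for scoring visual acuity from recognitions.

The trial mirrors chart-based testing: five letters per line, starting at
1.0 logMAR. If at least one letter on a line is recognized the test moves
one 0.1 logMAR step down; it stops when a whole line is missed or after the
floor line (-0.3 logMAR by default). The final acuity is the last attempted
line's logMAR plus 0.02 per error, errors being accumulated over all
attempted lines — the letter-by-letter penalty of ETDRS scoring, under
which a clean run down to a fully-missed line scores exactly the previous
line's value. The alternative reading (count only the terminal line's
errors) is available via ``errors="last_line"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .optotype_sim import SLOAN_LETTERS

__all__ = ["LineRecord", "TrialResult", "determine_va", "simulate_protocol"]


@dataclass(frozen=True)
class LineRecord:
    """One presented line: its level, letters, and recognition flags."""

    logmar: float
    letters: tuple
    recognized: tuple

    @property
    def n_errors(self) -> int:
        return sum(1 for r in self.recognized if not r)


@dataclass
class TrialResult:
    """Line-by-line record of a protocol run and the scored acuity."""

    lines: list = field(default_factory=list)
    total_errors: int = 0
    final_va: float = float("nan")
    completed: bool = True

    @property
    def attempted_levels(self) -> list:
        return [ln.logmar for ln in self.lines]


def _level_grid(start: float, floor: float, step: float) -> list:
    # exact two-decimal arithmetic so level labels never drift
    levels = []
    k = 0
    while True:
        lv = round(start - k * step, 2)
        if lv < round(floor, 2) - 1e-9:
            break
        levels.append(lv)
        k += 1
    return levels


def determine_va(recognize: Callable[[str, float], bool],
                 start: float = 1.0, floor: float = -0.3, step: float = 0.1,
                 letters_per_line: int = 5, seed: int = 0,
                 errors: str = "all_lines") -> TrialResult:
    """Run the line protocol against a recognition callback.

    ``recognize(letter, logmar)`` returns whether the simulated observer or
    classifier recognized that presentation. Letters on each line are drawn
    uniformly without replacement from the Sloan set (seeded). Scoring:
    final VA = last attempted line's logMAR + 0.02 x error count, where
    errors accumulate over all attempted lines (default) or only the last
    line (``errors="last_line"``).
    """
    if not start > floor:
        raise ValueError("start must be above floor")
    if not step > 0:
        raise ValueError("step must be positive")
    if errors not in ("all_lines", "last_line"):
        raise ValueError("errors must be 'all_lines' or 'last_line'")
    rng = np.random.default_rng(seed)
    result = TrialResult()
    for level in _level_grid(start, floor, step):
        letters = tuple(rng.choice(SLOAN_LETTERS, size=letters_per_line,
                                   replace=False))
        try:
            flags = tuple(bool(recognize(letter, level)) for letter in letters)
        except Exception:
            result.completed = False
            break
        line = LineRecord(logmar=level, letters=letters, recognized=flags)
        result.lines.append(line)
        if not any(flags):
            break
    if result.lines:
        if errors == "all_lines":
            n_err = sum(ln.n_errors for ln in result.lines)
        else:
            n_err = result.lines[-1].n_errors
        result.total_errors = n_err
        result.final_va = round(result.lines[-1].logmar + 0.02 * n_err, 4)
    return result


def simulate_protocol(zset, ctx, model, config=None, seed: int = 0,
                      classify_fn: Callable | None = None,
                      **protocol_kwargs) -> TrialResult:
    """Score a subject's VA by simulating optotypes and classifying them.

    Binds :func:`determine_va`'s callback to the optotype simulation
    pipeline plus the CNN classifier (or any callable via ``classify_fn``
    taking an image and returning a recognized flag). The noise seed is
    re-derived per presentation so repeated letters are independent draws,
    deterministic under ``seed``.
    """
    from dataclasses import replace

    from .optotype_sim import OptotypeSpec, SimConfig, psf_kernel_for, simulate_optotype
    from .recognition import classify

    config = config or SimConfig()
    kernel = psf_kernel_for(zset, config)
    counter = {"i": 0}

    def recognize(letter: str, logmar: float) -> bool:
        counter["i"] += 1
        cfg = replace(config, noise_seed=(seed * 100003 + counter["i"]) % (2 ** 31))
        img = simulate_optotype(zset, ctx, OptotypeSpec(letter, logmar),
                                cfg, _kernel=kernel)
        if classify_fn is not None:
            return bool(classify_fn(img))
        label, _ = classify(model, img)
        return label == "recognized"

    return determine_va(recognize, seed=seed, **protocol_kwargs)
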