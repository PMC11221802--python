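"""Cardiac cycle timing and the systole/diastole phase convention.

All phases are referenced to the *ventricle* (the convention used throughout
atrial flow analysis): ventricular systole is the interval where the mitral
valve is closed and the atrium fills (atrial reservoir phase); ventricular
diastole is the interval where the mitral valve is open and the atrium
empties. ``t_mv_open`` is the instant of maximal atrial volume, immediately
before mitral valve opening — the volume-seeding instant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, TimingError

SYSTOLE = "systole"
DIASTOLE = "diastole"


@dataclass(frozen=True)
class CardiacTiming:
    """Timing of one cardiac cycle.

    Parameters
    ----------
    cycle_length:
        RR interval in seconds.
    t_mv_open:
        Time within the cycle (s) when ventricular diastole begins.
    t_mv_close:
        Time within the cycle (s) when ventricular systole begins.
    t_pre_a:
        Optional diastasis time (s), onset of atrial contraction; must lie
        strictly inside diastole when given.
    n_frames:
        Number of sampled frames per cycle.
    """

    cycle_length: float
    t_mv_open: float
    t_mv_close: float = 0.0
    t_pre_a: float | None = None
    n_frames: int = 20

    def __post_init__(self) -> None:
        T = self.cycle_length
        if not T > 0:
            raise ConfigError(f"cycle_length must be positive, got {T}")
        for name in ("t_mv_open", "t_mv_close"):
            v = getattr(self, name)
            if not (0.0 <= v < T):
                raise ConfigError(f"{name}={v} outside [0, cycle_length)")
        if self.t_mv_open == self.t_mv_close:
            raise ConfigError("t_mv_open and t_mv_close must differ")
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if self.t_pre_a is not None:
            t = self.wrap(self.t_pre_a)
            if self.phase(t) != DIASTOLE or t == self.t_mv_open:
                raise ConfigError(
                    f"t_pre_a={self.t_pre_a} does not lie strictly inside diastole"
                )

    # -- phase arithmetic ---------------------------------------------------

    def wrap(self, t):
        """Map any time onto [0, cycle_length)."""
        return np.asarray(t) % self.cycle_length if np.ndim(t) else t % self.cycle_length

    def in_systole(self, t):
        """Vectorized predicate: does ``t`` fall in ventricular systole?

        Systole is the half-open interval from ``t_mv_close`` to
        ``t_mv_open`` (cyclically), so every time belongs to exactly one
        phase and the mapping is periodic.
        """
        T = self.cycle_length
        rel = (np.asarray(t) - self.t_mv_close) % T
        sys_len = (self.t_mv_open - self.t_mv_close) % T
        return rel < sys_len

    def phase(self, t) -> str:
        return SYSTOLE if bool(self.in_systole(t)) else DIASTOLE

    @property
    def systole_duration(self) -> float:
        return (self.t_mv_open - self.t_mv_close) % self.cycle_length

    @property
    def diastole_duration(self) -> float:
        return self.cycle_length - self.systole_duration

    def diastole_end_after(self, t: float) -> float:
        """Absolute end time of the diastolic phase of the cycle containing
        (or following) time ``t``.

        Used to resolve "leaves during the same diastolic phase": for a time
        within diastole this is the upcoming mitral-valve closure; for a time
        within systole it is the end of the *next* diastole.
        """
        T = self.cycle_length
        rel = (t - self.t_mv_open) % T
        delta = self.diastole_duration - rel
        if delta <= 0.0:  # t is in systole: end of the *next* diastole
            delta += T
        return t + delta

    @property
    def frame_times(self) -> np.ndarray:
        """Uniform frame times, frame k at ``k * cycle_length / n_frames``."""
        return np.arange(self.n_frames) * self.cycle_length / self.n_frames

    def require_frame_count(self, n: int) -> None:
        if n != self.n_frames:
            raise TimingError(
                f"series has {n} frames but timing declares n_frames={self.n_frames}"
            )
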