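"""Time-course experimental design.

The analyses in this package revolve around a stimulation time course in
which every measurement is expressed as a log10 ratio against the 0 hr
(unstimulated control) sample.  Platforms may observe different subsets of
the sampling grid — e.g. an array time point lost to QC — so the design
carries both the full grid and the RNA-usable subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class TimeDesign:
    """Sampling grid of a stimulation time course.

    Parameters
    ----------
    time_points:
        Hours after stimulation, strictly increasing, starting at 0 (the
        control sample every ratio is taken against).
    rna_time_points:
        The subset of ``time_points`` with usable RNA measurements.
    replicates:
        Technical replicates per platform sample.
    """

    time_points: tuple[float, ...]
    rna_time_points: tuple[float, ...] | None = None
    replicates: int = 3

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.time_points)
        object.__setattr__(self, "time_points", tp)
        if len(tp) < 2:
            raise ValueError("time design needs at least a control and one treated time")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError(f"time points must be strictly increasing, got {tp}")
        if tp[0] != 0.0:
            raise ValueError("first time point must be the 0 hr control")
        rna = self.rna_time_points
        rna = tp if rna is None else tuple(float(t) for t in rna)
        if not set(rna) <= set(tp):
            raise ValueError("rna_time_points must be a subset of time_points")
        object.__setattr__(self, "rna_time_points", tuple(sorted(rna)))
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def treated_times(self) -> tuple[float, ...]:
        """All non-control times (where a ratio vs 0 hr is defined)."""
        return self.time_points[1:]

    @property
    def rna_treated_times(self) -> tuple[float, ...]:
        return tuple(t for t in self.rna_time_points if t > 0)

    @property
    def shared_treated_times(self) -> tuple[float, ...]:
        """Non-control times observed by both the RNA and protein platforms.

        Protein platforms observe the full grid; RNA only its own subset, so
        the intersection is simply the RNA treated times.
        """
        return self.rna_treated_times


#: 8-point EGF-stimulation grid: 0, 0.25, 1, 4, 8, 13, 18, 24 hr, with the
#: 15 min RNA sample dropped (failed hybridization) and triplicate arrays.
DEFAULT_DESIGN = TimeDesign(
    time_points=(0.0, 0.25, 1.0, 4.0, 8.0, 13.0, 18.0, 24.0),
    rna_time_points=(0.0, 1.0, 4.0, 8.0, 13.0, 18.0, 24.0),
    replicates=3,
)


def fmt_time(t: float) -> str:
    """Canonical short label for an hour value (``0.25`` -> ``"0.25"``, ``4.0`` -> ``"4"``)."""
    return f"{float(t):g}"
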