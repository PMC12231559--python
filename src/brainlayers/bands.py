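"""Frequency-band definitions for band-limited envelope connectivity.

The default set is the five canonical resting-state bands used throughout the
package: theta (6.5–8 Hz), alpha1 (8.5–10 Hz), alpha2 (10.5–12 Hz),
beta1 (12.5–16 Hz) and beta2 (16.5–20 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with edges in Hz.

    Attributes
    ----------
    name : str
        Band label (e.g. ``"alpha1"``).
    low, high : float
        Lower / upper band edge in Hz; ``0 < low < high`` is enforced.
    """

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: require 0 < low < high, got "
                f"low={self.low}, high={self.high}"
            )

    @property
    def center(self) -> float:
        """Arithmetic band centre in Hz."""
        return 0.5 * (self.low + self.high)


#: The five default frequency layers, lowest to highest.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 6.5, 8.0),
    BandDefinition("alpha1", 8.5, 10.0),
    BandDefinition("alpha2", 10.5, 12.0),
    BandDefinition("beta1", 12.5, 16.0),
    BandDefinition("beta2", 16.5, 20.0),
)


def get_bands(spec: str | list[BandDefinition] | None = "default") -> list[BandDefinition]:
    """Resolve a band specification to a list of :class:`BandDefinition`.

    ``"default"`` / ``None`` yield the five standard bands; a list is passed
    through after validation.
    """
    if spec is None or spec == "default":
        return list(DEFAULT_BANDS)
    if isinstance(spec, str):
        raise ValueError(f"unknown band set {spec!r}")
    out = list(spec)
    if not out:
        raise ValueError("band list must be nonempty")
    for b in out:
        if not isinstance(b, BandDefinition):
            raise TypeError(f"expected BandDefinition, got {type(b)!r}")
    return out
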