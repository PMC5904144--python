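"""Channel and chain geometry.

Lengths are in micrometres (um) unless a field name says otherwise; channel
cross-section dimensions are conventionally quoted in nanometres and stored
that way (``D1``, ``D2``, ``slit_depth`` in nm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ChannelGeometry", "T4_CHANNEL", "knot_excluded_volume_ratio"]


@dataclass(frozen=True)
class ChannelGeometry:
    """Nanochannel cross-section and DNA chain constants.

    Parameters
    ----------
    D1, D2 : float
        Horizontal width and vertical depth of the nanochannel (nm).
    slit_depth : float
        Depth of the slit etched over the channel end (nm).  The slit passes
        buffer but blocks the DNA, so it must be shallower than the channel.
    persistence_P : float
        DNA persistence length (nm).
    eff_width_w : float
        DNA effective width (nm), set by ionic strength.
    contour_L : float
        Total stained contour length of the molecule (um).
    """

    D1: float = 325.0
    D2: float = 415.0
    slit_depth: float = 30.0
    persistence_P: float = 50.0
    eff_width_w: float = 12.0
    contour_L: float = 63.7

    def __post_init__(self) -> None:
        for name in ("D1", "D2", "slit_depth", "persistence_P", "eff_width_w", "contour_L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.slit_depth >= self.D2:
            raise ValueError("slit_depth must be smaller than D2 (slit blocks DNA)")

    @property
    def D_av_um(self) -> float:
        """Geometric-mean channel size sqrt(D1*D2), in um."""
        return float(np.sqrt(self.D1 * self.D2)) * 1e-3

    @property
    def persistence_um(self) -> float:
        return self.persistence_P * 1e-3


#: Default geometry: 325 x 415 nm channel, 30 nm slit, T4 DNA stained 10:1.
T4_CHANNEL = ChannelGeometry()


def knot_excluded_volume_ratio(
    g_k_um: float, r_um: float, channel: ChannelGeometry = T4_CHANNEL
) -> float:
    """Knot-knot excluded-volume fraction g_k^3 / (r * D1 * D2).

    The ratio of the volume swept by one knot (gyration radius ``g_k``) to the
    volume available to the compressed chain of extension ``r`` in a channel of
    cross-section D1 x D2.  A small value means hard-sphere knot-knot exclusion
    alone cannot explain multi-k_BT interaction free energies.

    All lengths in um except the channel dimensions, which are stored in nm.
    """
    if g_k_um <= 0 or r_um <= 0:
        raise ValueError("g_k and r must be positive")
    d1_um = channel.D1 * 1e-3
    d2_um = channel.D2 * 1e-3
    return g_k_um**3 / (r_um * d1_um * d2_um)
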