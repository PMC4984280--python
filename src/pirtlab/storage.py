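"""Storage-carbohydrate substrate accounting.

Slow-growing glucose-limited yeast cultures divert part of the consumed
glucose into the reserve carbohydrates glycogen and trehalose.  Given
cellular contents (g per g dry biomass) and the culture biomass at two
sampling times, the fraction of the glucose supplied over the interval
that ended up in reserves is

    f = [ d(glycogen * C_X * V)  +  d(trehalose * C_X * V) * c_treh ] / (S2 - S1)

where glycogen contents are already measured as glucose equivalents,
``c_treh`` converts trehalose mass to glucose equivalents by hydrolysis
stoichiometry (2 glucose per trehalose), and S2 - S1 is the glucose
supplied by the feed (complete consumption assumed).  The fraction may
be negative when stores are mobilised; it is reported, not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .feed import MixingVesselFeed, substrate_supplied
from .simulator import ReactorConfig

__all__ = ["StorageMeasurement", "TREHALOSE_GLUCOSE_FACTOR", "storage_fraction", "storage_fraction_series"]

# g glucose released per g trehalose hydrolysed: 2 * 180.16 / 342.30
TREHALOSE_GLUCOSE_FACTOR = 2 * 180.16 / 342.30


@dataclass(frozen=True)
class StorageMeasurement:
    """Storage-carbohydrate contents and biomass at one sampling time.

    Contents are weight fractions of dry biomass: glycogen in g glucose
    equivalents per g biomass, trehalose in g per g biomass.
    """

    t: float
    glycogen: float
    trehalose: float
    C_X: float

    def __post_init__(self) -> None:
        if not (0 <= self.glycogen < 1 and 0 <= self.trehalose < 1):
            raise ValueError("contents must be fractions in [0, 1)")
        if self.C_X < 0:
            raise ValueError("C_X must be >= 0")


def storage_fraction(
    m1: StorageMeasurement,
    m2: StorageMeasurement,
    feed: MixingVesselFeed,
    reactor: ReactorConfig,
    trehalose_factor: float = TREHALOSE_GLUCOSE_FACTOR,
) -> float:
    """Fraction of supplied glucose diverted to storage over [m1.t, m2.t]."""
    if m2.t <= m1.t:
        raise ValueError("require m2.t > m1.t")
    supplied = substrate_supplied(m1.t, m2.t, feed)
    if supplied <= 0:
        raise ValueError("no substrate supplied over the interval")
    d_glycogen = (m2.glycogen * m2.C_X - m1.glycogen * m1.C_X) * reactor.V
    d_trehalose = (m2.trehalose * m2.C_X - m1.trehalose * m1.C_X) * reactor.V
    return (d_glycogen + d_trehalose * trehalose_factor) / supplied


def storage_fraction_series(
    df: pd.DataFrame,
    feed: MixingVesselFeed,
    reactor: ReactorConfig,
    trehalose_factor: float = TREHALOSE_GLUCOSE_FACTOR,
) -> pd.DataFrame:
    """Storage fractions for consecutive sampling intervals.

    ``df`` needs columns t_h, C_X_gL, glycogen_g_per_g, trehalose_g_per_g.
    """
    ms = [
        StorageMeasurement(
            t=row.t_h, glycogen=row.glycogen_g_per_g,
            trehalose=row.trehalose_g_per_g, C_X=row.C_X_gL,
        )
        for row in df.itertuples()
    ]
    rows = []
    for m1, m2 in zip(ms, ms[1:]):
        rows.append(
            {
                "t1_h": m1.t,
                "t2_h": m2.t,
                "storage_fraction": storage_fraction(
                    m1, m2, feed, reactor, trehalose_factor
                ),
            }
        )
    return pd.DataFrame(rows)
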