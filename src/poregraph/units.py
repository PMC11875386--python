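"""Unit conventions shared across the package.

Physical rates are configured in the units the soil-biology literature uses
(day^-1 for biological rates, voxel^2 * day^-1 for the diffusion coefficient)
while simulation clocks run in seconds.  All day/second conversions go through
this module so the factor appears exactly once.
"""

SECONDS_PER_DAY = 86400.0


def per_second(rate_per_day: float) -> float:
    """Convert a day^-1 rate to s^-1."""
    return rate_per_day / SECONDS_PER_DAY


def coupling(d_voxel2_per_day: float, dt_seconds: float) -> float:
    """Dimensionless diffusion coupling D*dt (voxel^2) for one step.

    ``D`` is given in voxel^2/day, ``dt`` in seconds.
    """
    return d_voxel2_per_day / SECONDS_PER_DAY * dt_seconds
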