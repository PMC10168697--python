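"""Back-calculation of length-at-age from operculum annulus radii.

Perch deposit one annulus per year on the operculum bone.  Given the radius
``r_a`` of the annulus laid down at age ``a``, the radius at catch ``R`` and
the body length at catch ``L_s``, past lengths follow the power-law
body-proportionality rule

    L_a = L_s * (r_a / R) ** s

with species-specific exponent ``s`` (0.861 for perch).  The intercept kappa
of the underlying length-radius regression ``L = kappa * R**s`` cancels in
the ratio and is only needed when *simulating* radii from lengths.

Annual specific growth between consecutive ages is expressed in percent per
year, ``G = 100 * (log L_{t+1} - log L_t)`` (natural log), and attached to
the geometric mean length ``sqrt(L_t * L_{t+1})`` of the interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default length-radius exponent for perch.
DEFAULT_S = 0.861


@dataclass(frozen=True)
class BackCalcParams:
    """Constants of the length-radius power law ``L = kappa * R**s``.

    ``kappa`` is only required to invert the relationship when generating
    synthetic radii; back-calculation itself uses ``s`` alone.
    """

    s: float = DEFAULT_S
    kappa: float = 20.0

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError(f"exponent s must be > 0, got {self.s}")
        if self.kappa <= 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")


def backcalc_lengths(
    length_at_catch: float,
    radii: Sequence[float],
    s: float = DEFAULT_S,
) -> np.ndarray:
    """Back-calculate one length per annulus radius.

    Parameters
    ----------
    length_at_catch
        Body length at catch ``L_s`` (cm); the last radius corresponds to it.
    radii
        Strictly increasing annulus radii; the last entry is the radius at
        catch ``R``.
    s
        Exponent of the length-radius power law.

    Returns
    -------
    numpy.ndarray
        Monotone increasing lengths (cm), one per radius; the last equals
        ``length_at_catch`` exactly.
    """
    r = np.asarray(radii, dtype=float)
    if r.ndim != 1 or r.size == 0:
        raise ValueError("radii must be a nonempty 1-D sequence")
    if np.any(r <= 0):
        raise ValueError("radii must be strictly positive")
    if np.any(np.diff(r) <= 0):
        raise ValueError("radii must be strictly increasing")
    if length_at_catch <= 0:
        raise ValueError(f"length_at_catch must be > 0, got {length_at_catch}")
    if s <= 0:
        raise ValueError(f"s must be > 0, got {s}")
    return length_at_catch * (r / r[-1]) ** s


def specific_growth(l_start: float | np.ndarray, l_end: float | np.ndarray) -> np.ndarray:
    """Annual specific growth rate in %/yr, ``100*(log L_end - log L_start)``."""
    return 100.0 * (np.log(l_end) - np.log(l_start))


def growth_observations(
    records: Iterable,
    params: BackCalcParams | None = None,
) -> pd.DataFrame:
    """Turn aged individuals into one growth observation per age interval.

    Each fish of age ``a`` with ``a`` annulus radii yields ``a - 1``
    observations, one per consecutive pair of back-calculated lengths.
    Records with fewer than two radii are skipped with a warning.

    Returns a DataFrame with columns ``id, area, cohort, age_start, L_start,
    L_end, G, L_geo`` suitable for the allometric growth model, which needs
    the individual and cohort identifiers for its nested random effects.
    """
    params = params or BackCalcParams()
    rows = []
    n_skipped = 0
    for rec in records:
        radii = np.asarray(rec.radii, dtype=float)
        if radii.size < 2:
            n_skipped += 1
            continue
        lengths = backcalc_lengths(rec.length_at_catch, radii, params.s)
        l_start = lengths[:-1]
        l_end = lengths[1:]
        g = specific_growth(l_start, l_end)
        l_geo = np.sqrt(l_start * l_end)
        for k in range(l_start.size):
            rows.append(
                {
                    "id": rec.id,
                    "area": rec.area,
                    "cohort": rec.cohort,
                    "age_start": k + 1,
                    "L_start": l_start[k],
                    "L_end": l_end[k],
                    "G": g[k],
                    "L_geo": l_geo[k],
                }
            )
    if n_skipped:
        logger.warning("skipped %d records with < 2 radii", n_skipped)
    return pd.DataFrame(
        rows,
        columns=["id", "area", "cohort", "age_start", "L_start", "L_end", "G", "L_geo"],
    )
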