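"""Synthetic fish populations with the statistical structure the models assume.

Two reproductively isolated populations (``heated`` and ``reference``) are
simulated with cohort-varying von Bertalanffy growth, area-specific
exponential survival, Student-t observation noise on log length, dome-shaped
gillnet size selectivity, and catch recorded per net-night in 2.5 cm length
classes (1 cm classes in configured late years).  Annulus radii are produced
by exact inversion of the back-calculation power law, so that with noise and
jitter off, back-calculation round-trips to the true lengths-at-age.

Default parameter values are the posterior medians reported for the heated
bay and its reference area (asymptotic length 45.7 vs 39.4 cm, growth
coefficient 0.19 vs 0.15 /yr, t0 = -0.5 yr, total mortality 0.73 vs
0.62 /yr, allometric growth 512 vs 433 %/yr at unit length with exponents
-1.13 vs -1.18), cohorts 1981-1997 and catch years 1987-2003.

Randomness: one root seed; independent substreams are derived with
``numpy.random.SeedSequence(seed).spawn`` in a fixed order (heated cohorts,
reference cohorts, catch thinning, auxiliary generators), so the same seed
yields byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

AREAS = ("heated", "reference")


@dataclass(frozen=True)
class AreaParams:
    """Generative life-history parameters for one area."""

    mu_linf: float  # cm, hyper-mean asymptotic length
    mu_k: float  # 1/yr, hyper-mean growth coefficient
    t0: float  # yr, age at zero length (fixed per area)
    sigma_linf: float  # cm, between-cohort SD of L_inf
    sigma_k: float  # 1/yr, between-cohort SD of K
    z: float  # 1/yr, instantaneous total mortality
    alpha: float  # %/yr at unit length, allometric growth coefficient
    theta: float  # dimensionless allometric exponent

    def __post_init__(self) -> None:
        if self.mu_linf <= 0 or self.mu_k <= 0:
            raise ValueError("VBGE hyper-means must be positive")
        if self.z <= 0:
            raise ValueError("mortality Z must be positive")
        if self.sigma_linf < 0 or self.sigma_k < 0:
            raise ValueError("between-cohort SDs must be nonnegative")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic heated/reference populations."""

    heated: AreaParams = AreaParams(
        mu_linf=45.7, mu_k=0.19, t0=-0.5, sigma_linf=2.0, sigma_k=0.015,
        z=0.73, alpha=512.0, theta=-1.13,
    )
    reference: AreaParams = AreaParams(
        mu_linf=39.4, mu_k=0.15, t0=-0.5, sigma_linf=2.0, sigma_k=0.015,
        z=0.62, alpha=433.0, theta=-1.18,
    )
    # Student-t observation noise on log length
    nu: float = 5.0
    sigma_obs: float = 0.08
    # back-calculation constants (L = kappa * R**s)
    kappa: float = 20.0
    s: float = 0.861
    # dome selectivity: mode length (cm) and log-length spread; None = fully selective
    sel_mode: float | None = 15.0
    sel_spread: float = 0.6
    # allometric growth generator noise structure
    growth_sigma_cohort: float = 30.0
    growth_sigma_id: float = 40.0
    growth_sigma_obs: float = 4.0
    # sampling design
    cohort_first: int = 1981
    cohort_last: int = 1997
    catch_first: int = 1987
    catch_last: int = 2003
    one_cm_years: tuple[int, ...] = (2001, 2002, 2003)
    nets_per_year: int = 10
    recruits_per_cohort: int = 500
    radius_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort_last < self.cohort_first:
            raise ValueError("empty cohort range")
        if self.catch_last < self.catch_first:
            raise ValueError("empty catch-year range")
        if self.cohort_first + 1 > self.catch_last:
            raise ValueError(
                "cohort window incompatible with catch window: no cohort can "
                "reach age 1 before the last catch year"
            )
        if self.sigma_obs < 0 or self.nu <= 0:
            raise ValueError("invalid observation-noise parameters")
        if self.s <= 0 or self.kappa <= 0:
            raise ValueError("back-calculation constants must be positive")

    def area_params(self, area: str) -> AreaParams:
        if area == "heated":
            return self.heated
        if area == "reference":
            return self.reference
        raise ValueError(f"unknown area {area!r}")

    @property
    def cohorts(self) -> range:
        return range(self.cohort_first, self.cohort_last + 1)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FishRecord:
    """One aged individual; radii are per-annulus operculum radii."""

    id: int
    area: str
    cohort: int
    catch_year: int
    age: int
    length_at_catch: float
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        if self.area not in AREAS:
            raise ValueError(f"unknown area {self.area!r}")
        if self.catch_year - self.age != self.cohort:
            raise ValueError("catch_year - age must equal cohort")
        if self.radii.size != self.age:
            raise ValueError("need one radius per annulus (length(radii) = age)")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if self.length_at_catch <= 0:
            raise ValueError("length_at_catch must be positive")


@dataclass
class CatchRecord:
    """Count of fish in one (area, year, net, length class) cell."""

    area: str
    year: int
    net_id: int
    length_class_lower: float
    length_class_width: float
    count: int
    disturbed: bool = False

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be nonnegative")
        if self.length_class_width not in (1.0, 2.5):
            raise ValueError("class width must be 1.0 or 2.5 cm")
        k = self.length_class_lower / self.length_class_width
        if abs(k - round(k)) > 1e-9:
            raise ValueError("class lower edge not aligned to the width grid")


def vbge_length(age, linf, k, t0):
    """von Bertalanffy mean length ``L_inf * (1 - exp(-K (t - t0)))``."""
    return linf * (1.0 - np.exp(-k * (np.asarray(age, dtype=float) - t0)))


def selectivity(length, mode: float | None, spread: float) -> np.ndarray:
    """Dome-shaped (lognormal) gillnet selectivity, peak 1 at the mode length."""
    length = np.asarray(length, dtype=float)
    if mode is None:
        return np.ones_like(length)
    return np.exp(-((np.log(length) - np.log(mode)) ** 2) / (2.0 * spread**2))


def _positive_normal(rng: np.random.Generator, mu: float, sd: float) -> float:
    """Normal draw rejected until positive (generative counterpart of the
    positivity constraint on L_inf and K)."""
    while True:
        x = rng.normal(mu, sd)
        if x > 0:
            return x


def simulate_cohorts(config: SimConfig) -> list[FishRecord]:
    """Simulate aged individuals from cohort-varying VBGE growth and
    exponential survival.

    Each recruit draws a lifespan from an exponential at the area mortality
    rate; deaths occur between birthdays, and the fish is sampled at its last
    attained integer age (so the age composition within a catch year declines
    exactly as exp(-Z age)).  Fish whose sampling year falls outside the
    catch-year window are not observed.  Radii are the exact power-law
    inversion of the true lengths at each birthday; observation noise enters
    only the recorded length at catch.
    """
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(4)
    records: list[FishRecord] = []
    fish_id = 0
    for area, stream in zip(AREAS, streams[:2]):
        rng = np.random.default_rng(stream)
        pars = config.area_params(area)
        for cohort in config.cohorts:
            linf_j = _positive_normal(rng, pars.mu_linf, pars.sigma_linf)
            k_j = _positive_normal(rng, pars.mu_k, pars.sigma_k)
            lifespans = rng.exponential(1.0 / pars.z, size=config.recruits_per_cohort)
            ages = np.floor(lifespans).astype(int)
            noises = rng.standard_t(config.nu, size=config.recruits_per_cohort)
            jit_rng = rng
            for age, tnoise in zip(ages, noises):
                year = cohort + age
                if age < 1 or not (config.catch_first <= year <= config.catch_last):
                    continue
                true_lengths = vbge_length(
                    np.arange(1, age + 1), linf_j, k_j, pars.t0
                )
                obs_length = float(
                    np.exp(np.log(true_lengths[-1]) + config.sigma_obs * tnoise)
                )
                radius_catch = (true_lengths[-1] / config.kappa) ** (1.0 / config.s)
                radii = radius_catch * (true_lengths / true_lengths[-1]) ** (
                    1.0 / config.s
                )
                if config.radius_jitter > 0 and age > 1:
                    radii[:-1] *= np.exp(
                        jit_rng.normal(0.0, config.radius_jitter, size=age - 1)
                    )
                    radii[:-1] = np.minimum(
                        np.sort(radii[:-1]), radii[-1] * (1 - 1e-9)
                    )
                records.append(
                    FishRecord(
                        id=fish_id,
                        area=area,
                        cohort=cohort,
                        catch_year=year,
                        age=int(age),
                        length_at_catch=obs_length,
                        radii=radii,
                    )
                )
                fish_id += 1
    return records


def simulate_catch(fish: list[FishRecord], config: SimConfig) -> list[CatchRecord]:
    """Thin fish through the gillnet dome, allocate to nets, bin to classes.

    Retention probability follows the lognormal dome at the fish's recorded
    length; retained fish are assigned uniformly to the year's net
    deployments and counted per length class (2.5 cm, or 1 cm in the
    configured late years).  Counts sum to the number of retained fish.
    """
    if not fish:
        raise ValueError("empty fish list")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[2])
    counts: dict[tuple, int] = {}
    lengths = np.array([f.length_at_catch for f in fish])
    keep = rng.uniform(size=len(fish)) < selectivity(
        lengths, config.sel_mode, config.sel_spread
    )
    nets = rng.integers(0, config.nets_per_year, size=len(fish))
    for f, kept, net in zip(fish, keep, nets):
        if not kept:
            continue
        width = 1.0 if f.catch_year in config.one_cm_years else 2.5
        lower = np.floor(f.length_at_catch / width) * width
        key = (f.area, f.catch_year, int(net), float(lower), width)
        counts[key] = counts.get(key, 0) + 1
    return [
        CatchRecord(
            area=a, year=y, net_id=n, length_class_lower=lo,
            length_class_width=w, count=c,
        )
        for (a, y, n, lo, w), c in sorted(counts.items())
    ]


def simulate_growth_data(
    config: SimConfig,
    n_individuals: int = 1200,
    min_age: int = 3,
    max_age: int = 8,
) -> pd.DataFrame:
    """Generate specific-growth observations directly from the allometric model.

    Per area, individual growth coefficients are nested normal draws
    ``alpha_id = alpha_area + u_cohort + v_id`` with SDs
    ``growth_sigma_cohort`` and ``growth_sigma_id``; lengths along each
    individual's trajectory come from the area's mean VBGE curve, and the
    observed growth is ``alpha_id * L_geo**theta`` plus Student-t noise of
    scale ``growth_sigma_obs``.  Output matches `backcalc.growth_observations`.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    cohorts = list(config.cohorts)
    rows = []
    fish_id = 0
    for area in AREAS:
        pars = config.area_params(area)
        u_cohort = rng.normal(0.0, config.growth_sigma_cohort, size=len(cohorts))
        for _ in range(n_individuals):
            ci = int(rng.integers(0, len(cohorts)))
            alpha_id = (
                pars.alpha + u_cohort[ci] + rng.normal(0.0, config.growth_sigma_id)
            )
            age = int(rng.integers(min_age, max_age + 1))
            lengths = vbge_length(np.arange(1, age + 1), pars.mu_linf, pars.mu_k, pars.t0)
            for t in range(age - 1):
                l_geo = float(np.sqrt(lengths[t] * lengths[t + 1]))
                g = alpha_id * l_geo**pars.theta + config.growth_sigma_obs * rng.standard_t(config.nu)
                rows.append(
                    {
                        "id": fish_id,
                        "area": area,
                        "cohort": cohorts[ci],
                        "age_start": t + 1,
                        "L_start": lengths[t],
                        "L_end": lengths[t + 1],
                        "G": g,
                        "L_geo": l_geo,
                    }
                )
            fish_id += 1
    return pd.DataFrame(rows)


def simulate_catch_curve_data(
    config: SimConfig,
    n_years: int = 15,
    ages: tuple[int, int] = (2, 8),
    log_cpue_at_age0: float = 7.0,
    sigma_year: float = 0.2,
    sigma_obs: float = 0.3,
) -> pd.DataFrame:
    """Generate catch-at-age CPUE that declines exponentially at the area Z.

    log CPUE = intercept + year deviation - Z * age + normal noise, i.e.
    lognormal CPUE noise around the catch-curve line.  Returns columns
    ``area, year, age, cpue``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    years = np.arange(config.catch_first, config.catch_first + n_years)
    age_grid = np.arange(ages[0], ages[1] + 1)
    rows = []
    for area in AREAS:
        z = config.area_params(area).z
        u_year = rng.normal(0.0, sigma_year, size=len(years))
        for yi, year in enumerate(years):
            eps = rng.normal(0.0, sigma_obs, size=len(age_grid))
            log_cpue = log_cpue_at_age0 + u_year[yi] - z * age_grid + eps
            for age, lc in zip(age_grid, log_cpue):
                rows.append(
                    {"area": area, "year": int(year), "age": int(age),
                     "cpue": float(np.exp(lc))}
                )
    return pd.DataFrame(rows)


def age_stratified_subsample(
    fish: list[FishRecord],
    n_per_area: int,
    seed: int = 0,
) -> list[FishRecord]:
    """Age-stratified aged subsample (the stratified field protocol).

    Fills the quota by drawing evenly across ages (randomly within an age),
    which enriches rare old fish — the observations that identify the
    asymptotic length — without selecting on length within an age, so
    length-at-age stays unbiased.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 20511)))
    out: list[FishRecord] = []
    for area in AREAS:
        group = [f for f in fish if f.area == area]
        if len(group) <= n_per_area:
            out.extend(group)
            continue
        strata: dict[int, list[FishRecord]] = {}
        for f in group:
            strata.setdefault(f.age, []).append(f)
        pools = [list(v) for _, v in sorted(strata.items())]
        for pool in pools:
            rng.shuffle(pool)
        chosen: list[FishRecord] = []
        while len(chosen) < n_per_area and any(pools):
            for pool in pools:
                if pool and len(chosen) < n_per_area:
                    chosen.append(pool.pop())
            pools = [p for p in pools if p]
        out.extend(sorted(chosen, key=lambda f: f.id))
    return out


def fish_to_frame(records: list[FishRecord]) -> pd.DataFrame:
    """Tabulate FishRecords; radii serialized as '|'-joined decimal strings."""
    return pd.DataFrame(
        {
            "id": [f.id for f in records],
            "area": [f.area for f in records],
            "cohort": [f.cohort for f in records],
            "catch_year": [f.catch_year for f in records],
            "age": [f.age for f in records],
            "length_at_catch": [f.length_at_catch for f in records],
            "radii": ["|".join(f"{r:.12g}" for r in f.radii) for f in records],
        }
    )


def frame_to_fish(df: pd.DataFrame) -> list[FishRecord]:
    return [
        FishRecord(
            id=int(row.id),
            area=row.area,
            cohort=int(row.cohort),
            catch_year=int(row.catch_year),
            age=int(row.age),
            length_at_catch=float(row.length_at_catch),
            radii=np.array([float(x) for x in row.radii.split("|")]),
        )
        for row in df.itertuples()
    ]


def catch_to_frame(records: list[CatchRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "area": [c.area for c in records],
            "year": [c.year for c in records],
            "net_id": [c.net_id for c in records],
            "length_class_lower": [c.length_class_lower for c in records],
            "length_class_width": [c.length_class_width for c in records],
            "count": [c.count for c in records],
            "disturbed": [c.disturbed for c in records],
        }
    )


def frame_to_catch(df: pd.DataFrame) -> list[CatchRecord]:
    return [
        CatchRecord(
            area=row.area,
            year=int(row.year),
            net_id=int(row.net_id),
            length_class_lower=float(row.length_class_lower),
            length_class_width=float(row.length_class_width),
            count=int(row.count),
            disturbed=bool(row.disturbed),
        )
        for row in df.itertuples()
    ]
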