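"""Catch-curve mortality estimation via age-length keys.

Under exponential decline ``N_t = N0 * exp(-Z t)`` and catch proportional to
abundance, log CPUE falls linearly in age with slope ``-Z``.  The chain is:

1. build an area-specific age-length key (ALK) from the aged subsample —
   a matrix of conditional age proportions per 2.5 cm length class;
2. expand the length-binned catch through the ALK to CPUE-at-age
   (fish per net per night), conserving total catch;
3. keep only ages on the descending right limb of the catch dome (the modal
   age and older, on year-pooled mean CPUE per area), where gillnet
   selectivity no longer truncates the age distribution from below;
4. regress log CPUE on age.  The Bayesian regression uses a Student-t
   likelihood with cohort-varying coefficients under a full-covariance MVN
   prior (flat priors on the regression coefficients, as in brms);
   ``Z_ref = -beta2`` and ``Z_heat = -(beta2 + beta3)``.  A classical OLS
   slope is provided as an independent cross-check; on exactly log-linear
   data it recovers the slope to machine precision.

Annual mortality (fraction of a cohort dying per year) is ``1 - exp(-Z)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from heatfish import bayes_engine as be
from heatfish.size_spectrum import rebin_1cm_to_2p5cm

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# age-length keys

@dataclass
class AgeLengthKey:
    """Conditional age proportions per length class for one area.

    ``proportions[i, j]`` is the probability that a fish in length class
    ``class_lowers[i]`` has age ``ages[j]``; rows sum to one.  Length classes
    with no aged fish are simply absent (imputed from the nearest populated
    class at expansion time).
    """

    area: str
    class_lowers: np.ndarray
    ages: np.ndarray
    proportions: np.ndarray
    class_width: float = 2.5
    n_aged: int = 0

    def __post_init__(self) -> None:
        self.class_lowers = np.asarray(self.class_lowers, dtype=float)
        self.ages = np.asarray(self.ages, dtype=int)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.shape != (self.class_lowers.size, self.ages.size):
            raise ValueError("proportion matrix shape mismatch")
        if np.any(self.proportions < 0) or np.any(self.proportions > 1):
            raise ValueError("proportions must lie in [0, 1]")
        rowsums = self.proportions.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError("ALK rows must sum to 1")

    def row_for(self, class_lower: float) -> np.ndarray:
        """ALK row for a class, imputing from the nearest populated class."""
        if self.class_lowers.size == 0:
            raise ValueError("empty age-length key")
        i = int(np.argmin(np.abs(self.class_lowers - class_lower)))
        return self.proportions[i]


def _fish_frame(aged_fish) -> pd.DataFrame:
    if isinstance(aged_fish, pd.DataFrame):
        return aged_fish
    return pd.DataFrame(
        {
            "area": [f.area for f in aged_fish],
            "age": [f.age for f in aged_fish],
            "length_at_catch": [f.length_at_catch for f in aged_fish],
        }
    )


def build_alk(aged_fish, area: str, class_width: float = 2.5) -> AgeLengthKey:
    """Row-normalized age proportions per length class from the aged subsample."""
    df = _fish_frame(aged_fish)
    df = df[df["area"] == area]
    if df.empty:
        raise ValueError(f"no aged fish in area {area!r}")
    lowers = np.floor(df["length_at_catch"].to_numpy() / class_width) * class_width
    ages = np.sort(df["age"].unique())
    classes = np.sort(np.unique(lowers))
    counts = np.zeros((classes.size, ages.size))
    ai = np.searchsorted(ages, df["age"].to_numpy())
    ci = np.searchsorted(classes, lowers)
    np.add.at(counts, (ci, ai), 1.0)
    props = counts / counts.sum(axis=1, keepdims=True)
    return AgeLengthKey(
        area=area, class_lowers=classes, ages=ages, proportions=props,
        class_width=class_width, n_aged=len(df),
    )


def _catch_frame(catch) -> pd.DataFrame:
    if isinstance(catch, pd.DataFrame):
        return catch
    from heatfish.synthetic_data import catch_to_frame

    return catch_to_frame(catch)


def filter_disturbed(catch) -> pd.DataFrame:
    """Drop catch records flagged as disturbed (seal damage, algal clogging)."""
    df = _catch_frame(catch)
    if "disturbed" not in df.columns:
        return df
    n_bad = int(df["disturbed"].sum())
    if n_bad:
        logger.info("dropping %d disturbed catch records", n_bad)
    return df[~df["disturbed"].astype(bool)].drop(columns=["disturbed"])


def standardize_catch(catch) -> pd.DataFrame:
    """Convert any 1 cm length classes to the common 2.5 cm grid.

    Counts in 1 cm classes are allocated to overlapping 2.5 cm classes in
    proportion to the overlap width (total conserved, counts may become
    fractional).  Returns columns ``area, year, net_id, length_class_lower,
    count`` on the 2.5 cm grid.
    """
    df = _catch_frame(catch).copy()
    if "length_class_width" not in df.columns:  # already standardized
        return df
    fine = df[df["length_class_width"] == 1.0]
    coarse = df[df["length_class_width"] == 2.5]
    out = [
        coarse[["area", "year", "net_id", "length_class_lower", "count"]]
    ]
    for (area, year, net), grp in fine.groupby(["area", "year", "net_id"]):
        lowers, counts = rebin_1cm_to_2p5cm(
            grp["length_class_lower"].to_numpy(), grp["count"].to_numpy()
        )
        out.append(
            pd.DataFrame(
                {"area": area, "year": year, "net_id": net,
                 "length_class_lower": lowers, "count": counts}
            )
        )
    res = pd.concat(out, ignore_index=True)
    return (
        res.groupby(["area", "year", "net_id", "length_class_lower"], as_index=False)
        ["count"].sum()
    )


def expand_catch(
    catch,
    alk: AgeLengthKey,
    effort: dict | None = None,
) -> pd.DataFrame:
    """Expand length-binned catch to CPUE-at-age through the ALK.

    ``effort`` maps year -> net-nights; by default it is the number of
    distinct net deployments observed that year.  Total fish are conserved:
    per (area, year), sum(cpue) * effort equals the summed counts.
    Returns columns ``area, year, age, cpue``.
    """
    df = standardize_catch(catch)
    df = df[df["area"] == alk.area]
    if df.empty:
        raise ValueError(f"no catch records for area {alk.area!r}")
    rows = []
    for year, grp in df.groupby("year"):
        eff = effort[year] if effort else grp["net_id"].nunique()
        cpue = np.zeros(alk.ages.size)
        for lower, cnt in (
            grp.groupby("length_class_lower")["count"].sum().items()
        ):
            cpue += cnt * alk.row_for(lower)
        cpue /= eff
        for age, v in zip(alk.ages, cpue):
            rows.append({"area": alk.area, "year": int(year), "age": int(age), "cpue": v})
    return pd.DataFrame(rows)


def select_descending_limb(catch_at_age: pd.DataFrame, area: str | None = None) -> pd.DataFrame:
    """Keep ages at and beyond the catch mode (per area, year-pooled CPUE).

    The modal age is computed on mean CPUE pooled across years within each
    area; retained are ages >= the mode.  The modal ages are recorded in
    ``result.attrs['modal_age']``.
    """
    df = catch_at_age if area is None else catch_at_age[catch_at_age["area"] == area]
    if df.empty or not np.any(df["cpue"] > 0):
        raise ValueError("no positive CPUE to select a descending limb from")
    keep = []
    modal = {}
    for a, grp in df.groupby("area"):
        mean_by_age = grp.groupby("age")["cpue"].mean()
        modal_age = int(mean_by_age.idxmax())
        modal[a] = modal_age
        keep.append(grp[grp["age"] >= modal_age])
    out = pd.concat(keep, ignore_index=True)
    out.attrs["modal_age"] = modal
    return out


# ---------------------------------------------------------------------------
# catch-curve regression

def annual_mortality(z) -> np.ndarray | float:
    """Annual mortality fraction ``1 - exp(-Z)``."""
    return 1.0 - np.exp(-np.asarray(z, dtype=float)) if np.ndim(z) else float(1.0 - np.exp(-z))


def catch_curve_slope_ols(catch_at_age: pd.DataFrame, area: str) -> float:
    """Classical catch-curve estimate: OLS slope of log CPUE on age.

    Returns Z (the negated slope).  Zero-CPUE rows are dropped.
    """
    df = catch_at_age[(catch_at_age["area"] == area) & (catch_at_age["cpue"] > 0)]
    if df["age"].nunique() < 2:
        raise ValueError("need >= 2 distinct ages for a slope")
    slope = np.polyfit(df["age"].to_numpy(dtype=float),
                       np.log(df["cpue"].to_numpy(dtype=float)), 1)[0]
    return float(-slope)


class CatchCurveModel(be.HierarchicalModel):
    """Student-t log-CPUE regression with cohort-varying coefficients.

    Mean structure (heat/ref dummy coded):
    ``mu = (b0 + u0_j) heat + (b1 + u1_j) ref + (b2 + u2_j) age
    + (b3 + u3_j) age*heat`` where the deviations u_j follow a zero-mean MVN
    with estimated SDs and full correlation matrix.  ``varying='intercepts'``
    restricts deviations to b0, b1 (slopes as fixed effects);
    ``interaction=False`` drops b3 (one shared age slope).
    """

    def __init__(
        self,
        catch_at_age: pd.DataFrame,
        interaction: bool = True,
        varying: str = "intercepts",
        group: str = "cohort",
    ):
        df = catch_at_age[catch_at_age["cpue"] > 0].reset_index(drop=True)
        n_dropped = len(catch_at_age) - len(df)
        if n_dropped:
            logger.info("dropped %d zero-CPUE rows before log", n_dropped)
        for area in df["area"].unique():
            if df.loc[df["area"] == area, "age"].nunique() < 3:
                raise ValueError(f"fewer than 3 distinct ages in area {area!r}")
        self.interaction = interaction
        self.varying = varying
        self.name = (
            f"catchcurve[{'with' if interaction else 'no'}-interaction,"
            f"varying-{varying}]"
        )
        self.y = np.log(df["cpue"].to_numpy(dtype=float))
        age = df["age"].to_numpy(dtype=float)
        heat = (df["area"] == "heated").to_numpy(dtype=float)
        ref = 1.0 - heat
        cols = [heat, ref, age]
        self.coef_names = ["b0", "b1", "b2"]
        if interaction:
            cols.append(age * heat)
            self.coef_names.append("b3")
        self.X = np.column_stack(cols)
        self.n_obs = len(df)

        gvals = (
            df["year"].to_numpy() - df["age"].to_numpy()
            if group == "cohort"
            else df["year"].to_numpy()
        )
        self.groups = np.sort(np.unique(gvals))
        self.g_idx = np.searchsorted(self.groups, gvals)
        self.n_groups = len(self.groups)
        self.vary_cols = (
            [0, 1] if varying == "intercepts" else list(range(len(self.coef_names)))
        )
        self.p = len(self.vary_cols)
        n_corr = self.p * (self.p - 1) // 2

        self.scalar_names = list(self.coef_names)
        self.scalar_names += [f"log_sd_u{c}" for c in self.vary_cols]
        self.scalar_names += [f"corr_y{i}" for i in range(n_corr)]
        self.scalar_names += ["log_sigma", "log_nu"]
        self.blocks = {"u": (self.n_groups, self.p)}
        self.step0 = {n: 0.1 for n in self.scalar_names}
        self.step0["u"] = 0.1
        self.n_corr = n_corr
        # interweaving moves against the group-SD funnel: rescale one
        # deviation column together with its SD
        self.joint_moves = [
            self._make_sd_rescale(k) for k in range(self.p)
        ]

    def _make_sd_rescale(self, col: int):
        def move(state, rng, scale):
            delta = scale * rng.normal()
            prop = dict(state)
            c = self.vary_cols[col]
            prop[f"log_sd_u{c}"] = state[f"log_sd_u{c}"] + delta
            u = state["u"].copy()
            u[:, col] *= np.exp(delta)
            prop["u"] = u
            return prop, self.n_groups * delta

        return move

    def _corr_chol(self, state):
        y = np.array([state[f"corr_y{i}"] for i in range(self.n_corr)])
        return be.chol_from_partial_correlations(np.tanh(y), self.p)

    def _mu(self, state):
        beta = np.array([state[c] for c in self.coef_names])
        mu = self.X @ beta
        u = state["u"]
        for k, c in enumerate(self.vary_cols):
            mu = mu + self.X[:, c] * u[self.g_idx, k]
        return mu

    def loglik_pointwise(self, state):
        nu, sigma = np.exp(state["log_nu"]), np.exp(state["log_sigma"])
        return be.student_t_logpdf(self.y, nu, self._mu(state), sigma)

    def _u_prior_units(self, state):
        sds = np.exp(np.array([state[f"log_sd_u{c}"] for c in self.vary_cols]))
        return be.mvn_zero_mean_logpdf(state["u"], sds, self._corr_chol(state))

    def block_logp_units(self, name, state):
        prior = self._u_prior_units(state)
        data = np.bincount(
            self.g_idx, weights=self.loglik_pointwise(state), minlength=self.n_groups
        )
        return prior + data

    def logp(self, state):
        lp = 0.0  # flat priors on regression coefficients
        for c in self.vary_cols:
            sd = np.exp(state[f"log_sd_u{c}"])
            lp += be.half_t_logpdf(sd, 3.0, 2.5) + state[f"log_sd_u{c}"]
        for i in range(self.n_corr):
            lp += be.partial_correlation_log_prior(np.array([state[f"corr_y{i}"]]))
        lp += float(np.sum(self._u_prior_units(state)))
        sigma, nu = np.exp(state["log_sigma"]), np.exp(state["log_nu"])
        lp += be.half_t_logpdf(sigma, 3.0, 2.5) + state["log_sigma"]
        lp += be.gamma_logpdf(nu, 2.0, 0.1) + state["log_nu"]
        if not np.isfinite(lp):
            return -np.inf
        return float(lp + np.sum(self.loglik_pointwise(state)))

    def init_state(self, rng):
        # least-squares start jittered per chain
        beta0, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        state = {
            c: float(beta0[i] + rng.normal(0, 0.2))
            for i, c in enumerate(self.coef_names)
        }
        for c in self.vary_cols:
            state[f"log_sd_u{c}"] = np.log(rng.uniform(0.05, 0.5))
        for i in range(self.n_corr):
            state[f"corr_y{i}"] = rng.normal(0, 0.3)
        state["u"] = rng.normal(0, 0.05, size=(self.n_groups, self.p))
        state["log_sigma"] = np.log(rng.uniform(0.1, 0.6))
        state["log_nu"] = np.log(rng.uniform(3, 30))
        return state

    def constrained(self, state):
        out = {c: state[c] for c in self.coef_names}
        out["Z_reference"] = -state["b2"]
        out["Z_heated"] = -(state["b2"] + state.get("b3", 0.0)) if self.interaction else -state["b2"]
        for c in self.vary_cols:
            out[f"sd_u{c}"] = np.exp(state[f"log_sd_u{c}"])
        if self.n_corr:
            L = self._corr_chol(state)
            corr = L @ L.T
            out["corr"] = corr[np.tril_indices(self.p, -1)]
        out["u"] = state["u"]
        out["sigma"] = np.exp(state["log_sigma"])
        out["nu"] = np.exp(state["log_nu"])
        return out


def fit_catch_curve(
    catch_at_age: pd.DataFrame,
    interaction: bool = True,
    varying: str = "intercepts",
    group: str = "cohort",
    config: be.SamplerConfig | None = None,
) -> be.PosteriorSummary:
    """Bayesian catch-curve regression; returns posterior with Z draws.

    ``interaction`` toggles the age-by-area slope difference (without it both
    areas share one Z); ``varying`` selects which coefficients get
    cohort-level deviations ('intercepts' or 'all'); ``group`` is 'cohort'
    (year - age) or 'year'.
    """
    model = CatchCurveModel(catch_at_age, interaction=interaction,
                            varying=varying, group=group)
    result = be.sample_posterior(model, config)
    result.meta["converged"] = result.converged
    result.meta["variant"] = model.name
    if not result.meta["converged"]:
        logger.warning("%s did not converge: worst R-hat %.3f", model.name,
                       max(result.rhat.values()))
    return result
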