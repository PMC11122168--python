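"""Synthetic two-sex obese-adult cohort generator (Gaussian copula).

Real patient-level data for severely obese inpatient cohorts are rarely
deposited; this module generates cohorts with the statistical structure the
downstream analysis assumes, so every stage is testable end to end:

* per-sex marginal means/SDs for eleven continuous variables (age, height,
  BMI, waist, hip, SBP, DBP, glucose, total cholesterol, HDL-C,
  triglycerides), defaulting to a severely obese adult cohort dominated by
  females (88.4%);
* right-skewed triglycerides and glucose (lognormal marginals, parameterized
  to hit the target mean/SD exactly);
* a configurable latent correlation matrix imposed by a Gaussian copula:
  a latent multivariate normal is drawn and each coordinate is mapped
  through its marginal's quantile function, which preserves the marginals
  exactly whatever the correlation;
* bounded variables (the BMI > 35 inclusion criterion, plausibility
  guardrails) use truncated-normal marginals whose *parent* parameters are
  moment-matched so the truncated distribution has the configured mean/SD —
  truncation neither shifts the realized moments nor leaks bias into
  correlated variables, and produces no boundary point mass;
* body weight is derived as BMI x height(m)^2 (exactly, per subject), and
  blood pressures are rounded to the nearest 5 mmHg as sphygmomanometer
  protocols do;
* treatment/diagnosis flags are independent Bernoulli draws (default
  probability 0, since comorbidity prevalences are typically unavailable;
  the flags exist so the classifier's override logic is exercisable).

Every draw is governed by an explicit seed; the same (config, seed) pair
reproduces the cohort byte for byte.
"""
from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .cohort import FEMALE, MALE, CohortTable, FLAG_FIELDS
from .mets import classify_cohort

logger = logging.getLogger(__name__)

#: Continuous variables, in latent-coordinate order.
VARIABLES: tuple[str, ...] = (
    "age", "height", "bmi", "waist", "hip", "sbp", "dbp",
    "glucose", "total_chol", "hdl", "triglycerides",
)

NORMAL = "normal"
LOGNORMAL = "lognormal"

#: Variables feeding each MetS criterion, used by prevalence calibration.
CRITERION_GROUP: dict[str, int] = {
    "waist": 0, "sbp": 1, "dbp": 1, "glucose": 2, "hdl": 3, "triglycerides": 4,
}


@dataclass(frozen=True)
class Marginal:
    """Target mean/SD and distribution family for one variable in one sex."""

    mean: float
    sd: float
    family: str = NORMAL


# Default per-sex marginals: a severely obese adult inpatient cohort.
_DEFAULT_MARGINALS: dict[str, dict[str, Marginal]] = {
    MALE: {
        "age": Marginal(47.5, 14.7),
        "height": Marginal(172.0, 7.9),
        "bmi": Marginal(42.8, 6.2),
        "waist": Marginal(131.5, 12.6),
        "hip": Marginal(130.1, 13.9),
        "sbp": Marginal(131.6, 15.1),
        "dbp": Marginal(78.2, 9.5),
        "glucose": Marginal(100.8, 35.7, LOGNORMAL),
        "total_chol": Marginal(191.0, 35.0),
        "hdl": Marginal(41.6, 10.0),
        "triglycerides": Marginal(164.7, 87.0, LOGNORMAL),
    },
    FEMALE: {
        "age": Marginal(51.1, 14.0),
        "height": Marginal(157.4, 6.8),
        "bmi": Marginal(43.4, 6.2),
        "waist": Marginal(120.1, 12.4),
        "hip": Marginal(132.1, 12.7),
        "sbp": Marginal(128.2, 13.7),
        "dbp": Marginal(76.9, 7.6),
        "glucose": Marginal(98.5, 31.8, LOGNORMAL),
        "total_chol": Marginal(196.2, 37.5),
        "hdl": Marginal(50.7, 12.7),
        "triglycerides": Marginal(133.4, 61.4, LOGNORMAL),
    },
}

#: Truncation bounds in measurement units (None = unbounded on that side).
#: The BMI lower bound encodes the severe-obesity inclusion criterion.
_DEFAULT_BOUNDS: dict[str, tuple[float | None, float | None]] = {
    "age": (18.0, 90.0),
    "height": (130.0, 210.0),
    "bmi": (35.0, 80.0),
    "waist": (80.0, 220.0),
    "hip": (80.0, 220.0),
    "sbp": (80.0, 230.0),
    "dbp": (45.0, 130.0),
    "glucose": (None, None),
    "total_chol": (60.0, 450.0),
    "hdl": (15.0, 120.0),
    "triglycerides": (None, None),
}

# Latent correlations: moderate positives among adiposity measures, weak
# metabolic couplings, near-zero elsewhere; shared by both sexes.  These are
# declared assumptions (cohort summary tables publish no covariances), and
# every entry is user-overridable through the config file.
_DEFAULT_CORR_PAIRS: dict[tuple[str, str], float] = {
    ("bmi", "waist"): 0.65,
    ("bmi", "hip"): 0.65,
    ("waist", "hip"): 0.55,
    ("sbp", "dbp"): 0.60,
    ("age", "sbp"): 0.30,
    ("age", "glucose"): 0.20,
    ("age", "triglycerides"): 0.10,
    ("age", "hdl"): 0.10,
    ("bmi", "sbp"): 0.15,
    ("waist", "sbp"): 0.15,
    ("waist", "glucose"): 0.15,
    ("waist", "triglycerides"): 0.20,
    ("waist", "hdl"): -0.15,
    ("glucose", "triglycerides"): 0.20,
    ("glucose", "hdl"): -0.10,
    ("triglycerides", "hdl"): -0.30,
    ("triglycerides", "total_chol"): 0.30,
    ("total_chol", "hdl"): 0.15,
}


def _corr_from_pairs(pairs: Mapping[tuple[str, str], float]) -> np.ndarray:
    k = len(VARIABLES)
    idx = {v: i for i, v in enumerate(VARIABLES)}
    corr = np.eye(k)
    for (u, v), rho in pairs.items():
        corr[idx[u], idx[v]] = corr[idx[v], idx[u]] = rho
    return corr


@dataclass
class SimConfig:
    """Everything needed to draw a cohort: size, sex mix, per-sex marginals,
    latent correlation matrix, truncation bounds, flag probabilities, seed."""

    n: int = 1912
    male_fraction: float = 0.116
    marginals: dict[str, dict[str, Marginal]] = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_MARGINALS))
    corr: np.ndarray = field(
        default_factory=lambda: _corr_from_pairs(_DEFAULT_CORR_PAIRS))
    bounds: dict[str, tuple[float | None, float | None]] = field(
        default_factory=lambda: dict(_DEFAULT_BOUNDS))
    treatment_probs: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0, 1]")
        corr = np.asarray(self.corr, dtype=float)
        k = len(VARIABLES)
        if corr.shape != (k, k):
            raise ValueError(f"correlation matrix must be {k}x{k}")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ValueError("correlation matrix must be positive definite")
        for sex in (MALE, FEMALE):
            for var in VARIABLES:
                m = self.marginals[sex][var]
                if m.sd <= 0:
                    raise ValueError(f"{sex}/{var}: sd must be positive")
                if m.family not in (NORMAL, LOGNORMAL):
                    raise ValueError(f"{sex}/{var}: unknown family {m.family!r}")
                if m.family == LOGNORMAL and m.mean <= 0:
                    raise ValueError(f"{sex}/{var}: lognormal mean must be positive")
        for p in self.treatment_probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError("treatment probabilities must be in [0, 1]")

    # ---- config file round trip ------------------------------------------
    def to_file(self, path: str | Path) -> None:
        data = {
            "n": self.n,
            "male_fraction": self.male_fraction,
            "seed": self.seed,
            "treatment_probs": {"lipid": self.treatment_probs[0],
                                "htn": self.treatment_probs[1],
                                "t2dm": self.treatment_probs[2]},
            "marginals": {
                sex: {var: {"mean": m.mean, "sd": m.sd, "family": m.family}
                      for var, m in self.marginals[sex].items()}
                for sex in (MALE, FEMALE)
            },
            "bounds": {var: list(self.bounds.get(var, (None, None)))
                       for var in VARIABLES},
            "variables": list(VARIABLES),
            "corr": [[float(x) for x in row] for row in np.asarray(self.corr)],
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if data.get("variables", list(VARIABLES)) != list(VARIABLES):
            raise ValueError("config variable list does not match this version")
        tp = data.get("treatment_probs", {})
        cfg = cls(
            n=int(data.get("n", 1912)),
            male_fraction=float(data.get("male_fraction", 0.116)),
            marginals={
                sex: {var: Marginal(float(d["mean"]), float(d["sd"]),
                                    d.get("family", NORMAL))
                      for var, d in data["marginals"][sex].items()}
                for sex in (MALE, FEMALE)
            } if "marginals" in data else copy.deepcopy(_DEFAULT_MARGINALS),
            corr=np.asarray(data["corr"], dtype=float) if "corr" in data
                 else _corr_from_pairs(_DEFAULT_CORR_PAIRS),
            bounds={var: tuple(None if x is None else float(x) for x in lim)
                    for var, lim in data["bounds"].items()} if "bounds" in data
                   else dict(_DEFAULT_BOUNDS),
            treatment_probs=(float(tp.get("lipid", 0.0)), float(tp.get("htn", 0.0)),
                             float(tp.get("t2dm", 0.0))),
            seed=int(data.get("seed", 0)),
        )
        cfg.validate()
        return cfg


@dataclass
class SimReport:
    """Realized summary of an emitted cohort (recomputable from it)."""

    n: int
    seed: int
    realized: dict
    prevalence_pct: float


def default_config() -> SimConfig:
    """The default study conditions: n = 1912, 11.6% male, severe obesity."""
    cfg = SimConfig()
    cfg.validate()
    return cfg


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of ln X such that X has the given mean and SD."""
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _match_truncnorm(mean: float, sd: float, lo: float | None,
                     hi: float | None) -> tuple[float, float]:
    """Parent (mu, sigma) whose [lo, hi]-truncation has the target mean/SD.

    When the bounds lie far in the tails the parent parameters coincide with
    the targets; a binding bound (e.g. BMI > 35) pushes the parent mean down
    and sigma up so the truncated moments still match.
    """
    lo_f = -math.inf if lo is None else lo
    hi_f = math.inf if hi is None else hi
    if lo_f == -math.inf and hi_f == math.inf:
        return mean, sd
    # non-binding shortcut: both bounds beyond 8 parent SDs
    if (mean - lo_f) / sd > 8.0 and (hi_f - mean) / sd > 8.0:
        return mean, sd

    def residual(params: np.ndarray) -> np.ndarray:
        mu, log_s = params
        s = math.exp(log_s)
        a, b = (lo_f - mu) / s, (hi_f - mu) / s
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        return np.array([m - mean, math.sqrt(v) - sd])

    sol = optimize.root(residual, np.array([mean, math.log(sd)]), tol=1e-12)
    if not sol.success or np.abs(sol.fun).max() > 1e-6:
        raise ValueError(f"could not moment-match truncation bounds "
                         f"[{lo_f:g}, {hi_f:g}] to mean {mean:g}, sd {sd:g}")
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def _marginal_transform(z: np.ndarray, marg: Marginal,
                        bounds: tuple[float | None, float | None],
                        cache: dict, key: tuple) -> np.ndarray:
    """Map standard-normal latents through one marginal's quantile function."""
    if marg.family == LOGNORMAL:
        mu, sigma = _lognormal_params(marg.mean, marg.sd)
        return np.exp(mu + sigma * z)
    if key not in cache:
        cache[key] = _match_truncnorm(marg.mean, marg.sd, *bounds)
    mu, s = cache[key]
    lo, hi = bounds
    lo_f = -math.inf if lo is None else lo
    hi_f = math.inf if hi is None else hi
    if lo_f == -math.inf and hi_f == math.inf:
        return mu + s * z
    a, b = (lo_f - mu) / s, (hi_f - mu) / s
    return stats.truncnorm.ppf(stats.norm.cdf(z), a, b, loc=mu, scale=s)


def simulate_cohort(config: SimConfig, seed: int | None = None
                    ) -> tuple[CohortTable, SimReport]:
    """Draw a cohort from the configured joint distribution.

    Fully reproducible: the same (config, seed) yields an identical cohort.
    ``seed`` overrides ``config.seed`` when given.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    used_seed = config.seed if seed is None else seed
    n = config.n
    try:
        chol = np.linalg.cholesky(np.asarray(config.corr, dtype=float))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - validate() guards
        raise ValueError("correlation matrix is not positive definite") from exc

    male_mask = rng.random(n) < config.male_fraction
    columns = {var: np.empty(n) for var in VARIABLES}
    matched_cache: dict = {}
    for sex, mask in ((MALE, male_mask), (FEMALE, ~male_mask)):
        n_sex = int(mask.sum())
        z = rng.standard_normal((n_sex, len(VARIABLES))) @ chol.T
        for j, var in enumerate(VARIABLES):
            marg = config.marginals[sex][var]
            bounds = config.bounds.get(var, (None, None))
            columns[var][mask] = _marginal_transform(
                z[:, j], marg, bounds, matched_cache, (sex, var))

    sbp = np.round(columns["sbp"] / 5.0) * 5.0
    dbp = np.round(columns["dbp"] / 5.0) * 5.0
    height_m = columns["height"] / 100.0
    body_weight = columns["bmi"] * height_m**2

    p_lipid, p_htn, p_t2dm = config.treatment_probs
    flags = {
        "lipid_treated": rng.random(n) < p_lipid,
        "htn_treated": rng.random(n) < p_htn,
        "t2dm_diagnosed": rng.random(n) < p_t2dm,
    }

    width = len(str(n))
    df = pd.DataFrame({
        "id": [f"S{i + 1:0{width}d}" for i in range(n)],
        "sex": np.where(male_mask, MALE, FEMALE),
        "age": columns["age"],
        "body_weight": body_weight,
        "height": columns["height"],
        "waist": columns["waist"],
        "hip": columns["hip"],
        "sbp": sbp,
        "dbp": dbp,
        "glucose": columns["glucose"],
        "total_chol": columns["total_chol"],
        "hdl": columns["hdl"],
        "triglycerides": columns["triglycerides"],
        **flags,
    })
    cohort = CohortTable.from_frame(df)
    report = _sim_report(df, used_seed)
    return cohort, report


def _sim_report(df: pd.DataFrame, seed: int) -> SimReport:
    realized: dict = {}
    for sex in (MALE, FEMALE):
        sub = df[df["sex"] == sex]
        realized[sex] = {"n": int(len(sub))}
        for var in VARIABLES:
            if var == "bmi":
                values = sub["body_weight"].to_numpy() / (sub["height"].to_numpy() / 100.0) ** 2
            else:
                values = sub[var].to_numpy(float)
            if len(sub) >= 2:
                realized[sex][var] = {"mean": float(values.mean()),
                                      "sd": float(values.std(ddof=1))}
    _, summary = classify_cohort(df)
    return SimReport(n=len(df), seed=seed, realized=realized,
                     prevalence_pct=summary["prevalence_pct"])


def scale_intercriterion_corr(config: SimConfig, multiplier: float) -> SimConfig:
    """Scale the latent correlations *between* distinct MetS criteria.

    Entries within a criterion (SBP-DBP) and entries involving non-criterion
    variables are untouched.
    """
    cfg = copy.deepcopy(config)
    corr = np.asarray(cfg.corr, dtype=float).copy()
    idx = {v: i for i, v in enumerate(VARIABLES)}
    for u in CRITERION_GROUP:
        for v in CRITERION_GROUP:
            if CRITERION_GROUP[u] != CRITERION_GROUP[v]:
                corr[idx[u], idx[v]] *= multiplier
    cfg.corr = corr
    return cfg


def calibrate_prevalence(config: SimConfig, target_prevalence: float,
                         seed: int, n_sim: int = 20000, tol: float = 0.02,
                         max_iter: int = 30) -> SimConfig:
    """Tune the inter-criterion correlation strength to hit a target MetS
    prevalence.

    A single multiplier in [0, 1] scales every latent correlation between
    variables of distinct criteria; bisection on the simulated prevalence at
    ``n_sim`` subjects (common random numbers across evaluations) stops once
    the realized prevalence is within ``tol`` of ``target_prevalence``.
    Raises ``ValueError`` if the target is unattainable within the
    multiplier bounds.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target prevalence must be in (0, 1)")
    config.validate()
    sim_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))

    def realized(multiplier: float) -> float:
        cfg = scale_intercriterion_corr(config, multiplier)
        cfg.n = n_sim
        cohort, report = simulate_cohort(cfg, seed=sim_seed)
        return report.prevalence_pct / 100.0

    p_hi = realized(1.0)
    if abs(p_hi - target_prevalence) <= tol:
        return copy.deepcopy(config)
    p_lo = realized(0.0)
    if abs(p_lo - target_prevalence) <= tol:
        return scale_intercriterion_corr(config, 0.0)
    lo_p, hi_p = sorted((p_lo, p_hi))
    if not lo_p - tol <= target_prevalence <= hi_p + tol:
        raise ValueError(
            f"target prevalence {target_prevalence:.3f} unattainable: "
            f"multiplier range [0, 1] spans [{lo_p:.3f}, {hi_p:.3f}]")
    lo_m, hi_m = 0.0, 1.0
    best_m, best_gap = 1.0, abs(p_hi - target_prevalence)
    for _ in range(max_iter):
        mid = (lo_m + hi_m) / 2.0
        p_mid = realized(mid)
        gap = abs(p_mid - target_prevalence)
        if gap < best_gap:
            best_m, best_gap = mid, gap
        if gap <= tol:
            return scale_intercriterion_corr(config, mid)
        # keep the half-interval whose endpoint prevalences bracket the target
        if (p_lo - target_prevalence) * (p_mid - target_prevalence) <= 0:
            hi_m, p_hi = mid, p_mid
        else:
            lo_m, p_lo = mid, p_mid
    if best_gap <= tol:
        return scale_intercriterion_corr(config, best_m)
    raise ValueError("prevalence calibration did not converge within "
                     f"{max_iter} iterations (best gap {best_gap:.4f})")


def calibrated_default_config(target_prevalence: float = 0.623,
                              seed: int = 0, n_sim: int = 20000) -> SimConfig:
    """The default config calibrated toward the default target prevalence.

    Under the default marginals (no treated comorbidities) the realizable
    prevalence spans roughly 59-61% over the correlation multiplier, so the
    62.3% target sits at the edge of the calibration tolerance.  When strict
    calibration reports the target unattainable for a particular seed, this
    helper falls back to the multiplier endpoint whose realized prevalence is
    closest to the target, with a logged notice.
    """
    config = default_config()
    try:
        return calibrate_prevalence(config, target_prevalence, seed=seed,
                                    n_sim=n_sim)
    except ValueError:
        sim_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
        best_cfg, best_gap = None, math.inf
        for multiplier in (0.0, 1.0):
            cfg = scale_intercriterion_corr(config, multiplier)
            probe = copy.deepcopy(cfg)
            probe.n = n_sim
            _, report = simulate_cohort(probe, seed=sim_seed)
            gap = abs(report.prevalence_pct / 100.0 - target_prevalence)
            if gap < best_gap:
                best_cfg, best_gap = cfg, gap
        logger.warning(
            "prevalence target %.3f not attainable by correlation scaling; "
            "using the closest endpoint (gap %.3f)", target_prevalence, best_gap)
        return best_cfg
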