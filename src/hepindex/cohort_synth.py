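"""Seeded synthetic MASLD-style cohorts via a Gaussian copula.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised without patient data:

* published marginal distributions for demographics, anthropometrics
  and fasting labs (normal for most, log-normal for the right-skewed
  triglycerides and the tightly distributed fasting glucose);
* fixed steatosis (S0–S3) and fibrosis (F0/F1–F4) prevalence strata,
  realised exactly as multinomial draws through a quantile map on the
  latent CAP and stiffness variables;
* rank correlations between the computed metabolic indices and
  CAP/TE-derived severity, induced by a single latent "metabolic
  severity" factor whose per-variable loadings were calibrated
  numerically once against the target Spearman correlations and are
  shipped as defaults.

Dependence is a Gaussian copula: a latent multivariate normal vector
with unit variances is transformed through each variable's inverse CDF.
Only pairwise rank targets are modelled — no tail dependence.  Because
the indices (TyG, VAI, LAP, NFS, FIB-4) are computed from the generated
raw measurements rather than drawn directly, the formula modules are
exercised end to end, and the severity strata inherit higher index
means automatically from the factor structure.

Determinism: identical spec and seed give byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .indices import compute_panel_table
from .staging import grade_steatosis_array, stage_fibrosis_array

__all__ = [
    "MarginalSpec",
    "CohortSpec",
    "SyntheticCohort",
    "spearman_to_pearson",
    "default_spec",
    "generate_cohort",
    "calibration_report",
]


class MarginalSpec(BaseModel):
    """One variable's marginal distribution in the copula.

    ``normal`` uses mean/sd with optional clipping bounds; ``lognormal``
    uses the log-scale mu/sigma.  ``quantile_strata`` maps the latent
    percentile through prevalence strata onto fixed value bins (used for
    CAP and stiffness so the severity distribution is exact).
    """

    family: Literal["normal", "lognormal", "quantile_strata"]
    mean: Optional[float] = None
    sd: Optional[float] = None
    mu: Optional[float] = None
    sigma: Optional[float] = None
    clip: Optional[Tuple[float, float]] = None
    bins: Optional[List[Tuple[float, float]]] = None  # per-stratum value range
    prevalence: Optional[List[float]] = None

    @model_validator(mode="after")
    def _check(self) -> "MarginalSpec":
        if self.family == "normal" and (self.mean is None or self.sd is None):
            raise ValueError("normal marginal needs mean and sd")
        if self.family == "lognormal" and (self.mu is None or self.sigma is None):
            raise ValueError("lognormal marginal needs mu and sigma")
        if self.family == "quantile_strata":
            if not self.bins or not self.prevalence:
                raise ValueError("quantile_strata needs bins and prevalence")
            if len(self.bins) != len(self.prevalence):
                raise ValueError("bins and prevalence must align")
            if abs(sum(self.prevalence) - 1.0) > 1e-9:
                raise ValueError("prevalence must sum to 1")
        return self


def _lognormal_from_mean_sd(mean: float, sd: float) -> Tuple[float, float]:
    """Log-scale (mu, sigma) matching an arithmetic mean and SD."""
    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _lognormal_from_median_iqr(median: float, q1: float, q3: float) -> Tuple[float, float]:
    """Log-scale (mu, sigma) matching a median and interquartile range."""
    z75 = 0.6744897501960817
    return math.log(median), (math.log(q3) - math.log(q1)) / (2 * z75)


#: Steatosis prevalence over S0–S3 in the emulated cohort.
STEATOSIS_PREVALENCE = (0.31, 0.05, 0.213, 0.427)
#: Fibrosis prevalence over F0/F1–F4.
FIBROSIS_PREVALENCE = (0.455, 0.27, 0.174, 0.101)

# CAP value range (dB/m) of each steatosis stratum; the latent percentile
# is mapped linearly across the active bin, keeping the map monotone.
_CAP_BINS = [(150.0, 294.0), (294.0, 310.0), (310.0, 331.0), (331.0, 400.0)]
# stiffness (kPa) range per fibrosis stratum
_TE_BINS = [(3.0, 8.2), (8.2, 9.7), (9.7, 13.6), (13.6, 35.0)]

_TG_MU, _TG_SIGMA = _lognormal_from_mean_sd(198.2, 148.9)
_FBG_MU, _FBG_SIGMA = _lognormal_from_median_iqr(114.5, 110.0, 120.0)

#: Loadings of each variable on the latent metabolic-severity factor.
#: tg / waist / hdl / cap / te were calibrated numerically against the
#: target index–severity Spearman correlations (see docs/methods.md);
#: the remainder encode mild, physiologically signed associations.
DEFAULT_FACTOR_LOADINGS: Dict[str, float] = {
    "age": 0.0,
    "bmi": 0.50,
    "waist_circumference": 0.1235,
    "tg": 0.7177,
    "hdl": -0.9122,
    "ldl": 0.15,
    "total_cholesterol": 0.12,
    "fbg": 0.45,
    "ast": 0.30,
    "alt": 0.30,
    "ggt": 0.25,
    "albumin": -0.10,
    "platelets": -0.15,
    "hgb_like": 0.0,
    "systolic_bp": 0.30,
    "diastolic_bp": 0.25,
    "hba1c": 0.40,
    "cap": 0.997,
    "te": 0.8181,
}

#: Extra pairwise Spearman targets between raw variables, layered on top
#: of the factor structure (converted to latent Pearson via the sine rule).
#: The tg–hdl entry relaxes the factor-implied coupling toward the
#: physiologic marginal association and is part of the calibration.
DEFAULT_EXTRA_RANK_CORR: Dict[Tuple[str, str], float] = {
    ("waist_circumference", "bmi"): 0.75,
    ("ast", "alt"): 0.65,
    ("total_cholesterol", "ldl"): 0.85,
    ("tg", "hdl"): -0.3623,
}

#: Index–severity Spearman targets the calibrated defaults aim for.
DEFAULT_RANK_CORR_TARGETS: Dict[Tuple[str, str], float] = {
    ("tyg", "steatosis"): 0.66,
    ("vai", "steatosis"): 0.76,
    ("lap", "steatosis"): 0.61,
    ("tyg", "fibrosis"): 0.53,
    ("vai", "fibrosis"): 0.63,
    ("lap", "fibrosis"): 0.51,
}


def _default_marginals() -> Dict[str, MarginalSpec]:
    n = MarginalSpec
    return {
        "age": n(family="normal", mean=52.79, sd=12.56, clip=(18.0, 90.0)),
        "bmi": n(family="normal", mean=31.4, sd=5.3, clip=(16.0, 55.0)),
        "waist_circumference": n(family="normal", mean=109.1, sd=11.4, clip=(60.0, 160.0)),
        "tg": n(family="lognormal", mu=_TG_MU, sigma=_TG_SIGMA, clip=(30.0, 1500.0)),
        "hdl": n(family="normal", mean=44.3, sd=10.6, clip=(15.0, 110.0)),
        "ldl": n(family="normal", mean=149.0, sd=32.8, clip=(30.0, 300.0)),
        "total_cholesterol": n(family="normal", mean=203.2, sd=46.6, clip=(80.0, 400.0)),
        "fbg": n(family="lognormal", mu=_FBG_MU, sigma=_FBG_SIGMA, clip=(60.0, 300.0)),
        "ast": n(family="normal", mean=42.3, sd=23.7, clip=(8.0, 199.0)),
        "alt": n(family="normal", mean=53.1, sd=39.6, clip=(8.0, 199.0)),
        "ggt": n(family="normal", mean=48.0, sd=35.0, clip=(8.0, 300.0)),
        "albumin": n(family="normal", mean=3.3, sd=1.23, clip=(1.5, 5.5)),
        "platelets": n(family="normal", mean=225.0, sd=38.7, clip=(50.0, 450.0)),
        # haemoglobin-like CBC variable; kept out of every correlation target
        "hgb_like": n(family="normal", mean=11.1, sd=3.76, clip=(4.0, 20.0)),
        "systolic_bp": n(family="normal", mean=131.0, sd=15.0, clip=(90.0, 200.0)),
        "diastolic_bp": n(family="normal", mean=82.0, sd=10.0, clip=(50.0, 120.0)),
        "hba1c": n(family="normal", mean=5.9, sd=0.9, clip=(4.0, 12.0)),
        "cap": n(
            family="quantile_strata",
            bins=[list(b) for b in _CAP_BINS],
            prevalence=list(STEATOSIS_PREVALENCE),
        ),
        "te": n(
            family="quantile_strata",
            bins=[list(b) for b in _TE_BINS],
            prevalence=list(FIBROSIS_PREVALENCE),
        ),
    }


class CohortSpec(BaseModel):
    """Full generator configuration.

    The shipped defaults emulate a 178-subject tertiary-care MASLD
    screening cohort; ``rank_corr_targets`` documents the index–severity
    Spearman correlations the calibrated factor loadings aim for and is
    what :func:`calibration_report` checks against.
    """

    n: int = 178
    male_fraction: float = 0.551
    seed: int = 0
    marginals: Dict[str, MarginalSpec] = Field(default_factory=_default_marginals)
    factor_loadings: Dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_FACTOR_LOADINGS)
    )
    extra_rank_corr: Dict[str, float] = Field(
        default_factory=lambda: {
            f"{a}|{b}": v for (a, b), v in DEFAULT_EXTRA_RANK_CORR.items()
        }
    )
    rank_corr_targets: Dict[str, float] = Field(
        default_factory=lambda: {
            f"{a}|{b}": v for (a, b), v in DEFAULT_RANK_CORR_TARGETS.items()
        }
    )

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")
        for name, rho in {**self.extra_rank_corr, **self.rank_corr_targets}.items():
            if not -1.0 < rho < 1.0:
                raise ValueError(f"rank correlation target {name} outside (−1, 1)")
        for name in self.factor_loadings.values():
            if not -1.0 <= name <= 1.0:
                raise ValueError("factor loadings must lie in [−1, 1]")
        return self


@dataclass
class SyntheticCohort:
    """A generated cohort plus the provenance needed to regenerate it."""

    records: pd.DataFrame
    spec: CohortSpec
    seed: int
    generator_version: str
    n_clipped: Dict[str, int]


def spearman_to_pearson(rho_s: float) -> float:
    """Latent Pearson correlation inducing a given Spearman under a
    Gaussian copula: 2·sin(π·ρₛ/6)."""
    if not -1.0 < rho_s < 1.0:
        raise ValueError(f"|rho_s| must be < 1, got {rho_s}")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def default_spec(n: int = 178, seed: int = 0) -> CohortSpec:
    """The shipped, calibrated default cohort specification."""
    return CohortSpec(n=n, seed=seed)


def _build_correlation(spec: CohortSpec, names: List[str]) -> np.ndarray:
    lam = np.array([spec.factor_loadings.get(v, 0.0) for v in names])
    corr = np.outer(lam, lam)
    np.fill_diagonal(corr, 1.0)
    idx = {v: i for i, v in enumerate(names)}
    for key, rho_s in spec.extra_rank_corr.items():
        a, b = key.split("|")
        if a in idx and b in idx:
            r = spearman_to_pearson(rho_s)
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    return _repair_correlation(corr, names)


def _repair_correlation(
    corr: np.ndarray, names: List[str], max_shift: float = 0.05
) -> np.ndarray:
    """Clip negative eigenvalues and renormalise; error if the repair
    moves any entry beyond ``max_shift``."""
    w, v = np.linalg.eigh(corr)
    if w.min() >= 1e-10:
        return corr
    w = np.clip(w, 1e-8, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    delta = np.abs(fixed - corr)
    if delta.max() > max_shift:
        i, j = np.unravel_index(np.argmax(delta), delta.shape)
        raise ValueError(
            "correlation targets not jointly attainable; worst pair "
            f"({names[i]}, {names[j]}) shifted by {delta.max():.3f}"
        )
    return fixed


def _quantile_strata_map(u: np.ndarray, marg: MarginalSpec) -> np.ndarray:
    prev = np.asarray(marg.prevalence, float)
    edges = np.concatenate([[0.0], np.cumsum(prev)])
    edges[-1] = 1.0
    stratum = np.clip(np.searchsorted(edges, u, side="right") - 1, 0, len(prev) - 1)
    lo_p, hi_p = edges[stratum], edges[stratum + 1]
    frac = (u - lo_p) / np.maximum(hi_p - lo_p, 1e-12)
    bins = np.asarray(marg.bins, float)
    lo_v, hi_v = bins[stratum, 0], bins[stratum, 1]
    return lo_v + frac * (hi_v - lo_v)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a cohort from the Gaussian copula defined by ``spec``.

    The latent vector is mapped through each marginal's inverse CDF;
    CAP and stiffness go through the prevalence-preserving stratum
    quantile map, so realised severity counts are exact multinomial
    draws of the prevalence vectors.  Physiologic clipping is counted
    per variable in the returned ``n_clipped``.
    """
    from scipy import stats as sps

    names = list(spec.marginals)
    corr = _build_correlation(spec, names)
    rng = np.random.default_rng(spec.seed)

    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((spec.n, len(names))) @ chol.T
    u = sps.norm.cdf(z)

    data: Dict[str, np.ndarray] = {}
    n_clipped: Dict[str, int] = {}
    for k, name in enumerate(names):
        marg = spec.marginals[name]
        if marg.family == "normal":
            x = marg.mean + marg.sd * z[:, k]
        elif marg.family == "lognormal":
            x = np.exp(marg.mu + marg.sigma * z[:, k])
        else:
            x = _quantile_strata_map(u[:, k], marg)
        if marg.clip is not None:
            lo, hi = marg.clip
            clipped = int(((x < lo) | (x > hi)).sum())
            if clipped:
                n_clipped[name] = clipped
            x = np.clip(x, lo, hi)
        data[name] = x

    sex = np.where(rng.random(spec.n) < spec.male_fraction, "male", "female")
    iqr_ratio = np.round(rng.uniform(0.05, 0.32, spec.n), 3)

    df = pd.DataFrame(data)
    width = len(str(spec.n))
    df.insert(0, "subject_id", [f"S{i + 1:0{width}d}" for i in range(spec.n)])
    df.insert(1, "sex", sex)
    df["diabetes_or_ifg"] = df["fbg"] >= 100.0
    df["on_antihypertensives"] = False
    df["on_tg_treatment"] = False
    df["alcohol_g_week"] = np.round(rng.gamma(1.2, 25.0, spec.n), 1)
    df["te_iqr_over_median"] = iqr_ratio
    df["te_valid_count"] = 10
    df["ultrasound_steatosis"] = df["cap"] > 248.0
    for col in ("age", "bmi", "waist_circumference", "hdl", "ldl",
                "total_cholesterol", "tg", "fbg", "ast", "alt", "ggt",
                "platelets", "hgb_like", "systolic_bp", "diastolic_bp",
                "cap", "te"):
        df[col] = np.round(df[col], 4)
    df["albumin"] = np.round(df["albumin"], 4)
    df["hba1c"] = np.round(df["hba1c"], 4)

    return SyntheticCohort(
        records=df,
        spec=spec,
        seed=spec.seed,
        generator_version=__version__,
        n_clipped=n_clipped,
    )


def _censored_normal_moments(
    mean: float, sd: float, clip: Optional[Tuple[float, float]]
) -> Tuple[float, float]:
    """Mean and SD of clip(mean + sd·Z, a, b) for standard normal Z."""
    if clip is None:
        return mean, sd
    from scipy import stats as sps

    a, b = clip
    alpha, beta = (a - mean) / sd, (b - mean) / sd
    Fa, Fb = sps.norm.cdf(alpha), sps.norm.cdf(beta)
    fa, fb = sps.norm.pdf(alpha), sps.norm.pdf(beta)
    mid = Fb - Fa
    ez = fa - fb                      # ∫ z φ over (alpha, beta)
    ez2 = mid + alpha * fa - beta * fb  # ∫ z² φ over (alpha, beta)
    m1 = a * Fa + b * (1.0 - Fb) + mean * mid + sd * ez
    m2 = (
        a**2 * Fa
        + b**2 * (1.0 - Fb)
        + mean**2 * mid
        + 2 * mean * sd * ez
        + sd**2 * ez2
    )
    return m1, math.sqrt(max(m2 - m1**2, 0.0))


def calibration_report(
    cohort: SyntheticCohort,
    spec: Optional[CohortSpec] = None,
    corr_tolerance: float = 0.05,
    moment_rel_tolerance: float = 0.10,
) -> pd.DataFrame:
    """Target-versus-realised check for a generated cohort.

    Rank-correlation rows compare realised Spearman correlations of the
    computed indices with CAP/TE severity against the spec targets
    (tolerance ±``corr_tolerance``; requires n ≥ 100).  Marginal rows
    compare realised means and SDs with the spec parameters at
    ±``moment_rel_tolerance`` relative, evaluated only at n ≥ 5000
    (below that ``passed`` is left NA — sampling noise dominates).
    """
    from scipy import stats as sps

    spec = spec or cohort.spec
    df = cohort.records
    n = len(df)
    rows: List[dict] = []

    panel = compute_panel_table(df)
    severity = {
        "steatosis": grade_steatosis_array(df["cap"].to_numpy()),
        "fibrosis": stage_fibrosis_array(df["te"].to_numpy()),
    }
    for key, target in spec.rank_corr_targets.items():
        score, axis = key.split("|")
        if n < 100:
            continue
        realized = float(sps.spearmanr(panel[score], severity[axis]).statistic)
        rows.append(
            dict(
                target=f"spearman({score}, {axis})",
                kind="rank_correlation",
                expected=target,
                realized=realized,
                deviation=abs(realized - target),
                tolerance=corr_tolerance,
                passed=abs(realized - target) <= corr_tolerance,
            )
        )

    for name, marg in spec.marginals.items():
        if marg.family == "normal":
            # clipping censors the tails; compare against the censored moments
            exp_mean, exp_sd = _censored_normal_moments(
                marg.mean, marg.sd, marg.clip
            )
        elif marg.family == "lognormal":
            exp_mean = math.exp(marg.mu + marg.sigma**2 / 2.0)
            exp_sd = exp_mean * math.sqrt(math.expm1(marg.sigma**2))
        else:
            continue
        x = df[name].to_numpy(float)
        for stat_name, expected, realized in (
            ("mean", exp_mean, float(x.mean())),
            ("sd", exp_sd, float(x.std(ddof=1))),
        ):
            rel = abs(realized - expected) / abs(expected)
            rows.append(
                dict(
                    target=f"{stat_name}({name})",
                    kind="marginal_moment",
                    expected=expected,
                    realized=realized,
                    deviation=rel,
                    tolerance=moment_rel_tolerance,
                    passed=(rel <= moment_rel_tolerance) if n >= 5000 else None,
                )
            )
    return pd.DataFrame(rows)
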