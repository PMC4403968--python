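"""Reproducibility statistics: group CV, mixed-model variance components,
inter-/intra-scanner CV and intraclass correlations.

Phantom data are summarised with the plain group coefficient of variation
CV = 100 * sigma / mu over the per-scanner ROI means (sample SD, n-1).

Volunteer data are analysed with the mixed-effect model

    y_ijk = mu + scanner_i + volunteer_j + eps_ijk

with the scanner a fixed effect and the volunteer a random effect, fitted
by REML. Three standard deviations come out of the model:

* sigma_inter  -- sample SD of the estimated scanner means (the spread a
  volunteer would see moving between scanners);
* sigma_volunteer -- SD of the volunteer random effect (the spread seen
  scanning different volunteers on one scanner);
* sigma_intra  -- residual SD (repeat sessions of one volunteer on one
  scanner).

Each is converted to a CV against the model grand mean (the unweighted
mean of the scanner means, so scanners are treated symmetrically under
unbalanced volunteer counts). The intraclass correlations partition the
inter- plus intra-scanner variance:

    ICC_inter = sigma_inter^2 / (sigma_inter^2 + sigma_intra^2)
    ICC_intra = sigma_intra^2 / (sigma_inter^2 + sigma_intra^2)

A volunteer variance that collapses to the zero boundary is reported as
not estimable ("NE"), matching standard mixed-model reporting practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GroupCV",
    "VarianceComponents",
    "ReproResult",
    "group_cv",
    "fit_variance_components",
    "cv_from_components",
    "icc_pair",
    "subgroup_analysis",
    "summarize_report",
]


class StatsError(ValueError):
    """Invalid statistical input."""


@dataclass(frozen=True)
class GroupCV:
    mean: float
    sd: float
    cv: float  # percent
    defined: bool = True
    n: int = 0


def group_cv(values) -> GroupCV:
    """Group mean, sample SD (n-1) and CV% of per-scanner means."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise StatsError("group CV needs at least two values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if mean == 0.0:
        return GroupCV(mean=mean, sd=sd, cv=np.nan, defined=False, n=x.size)
    return GroupCV(mean=mean, sd=sd, cv=100.0 * sd / mean, n=x.size)


def cv_from_components(mu: float, sigma: float) -> float:
    """CV% = 100 * sigma / mu against the model grand mean.

    Report tables round to one decimal; the returned value is unrounded.
    """
    if sigma < 0:
        raise StatsError("sigma must be >= 0")
    if mu == 0:
        return float("nan")
    return 100.0 * sigma / mu


def icc_pair(sigma_inter: float, sigma_intra: float) -> tuple[float, float]:
    """(ICC_inter, ICC_intra): variance shares of inter vs intra scanner.

    The two always sum to one; both SDs zero is undefined and raises.
    """
    vi, ve = sigma_inter**2, sigma_intra**2
    tot = vi + ve
    if tot == 0:
        raise StatsError("ICC undefined when both SDs are zero")
    return vi / tot, ve / tot


@dataclass(frozen=True)
class VarianceComponents:
    """REML components for one metric/region."""

    mu: float
    sigma_inter: float
    sigma_volunteer: float
    sigma_intra: float
    volunteer_estimable: bool = True
    converged: bool = True
    scanner_means: dict = field(default_factory=dict)
    n_obs: int = 0


#: Boundary rule: a volunteer SD below this fraction of the residual SD is
#: reported as not estimable ("NE"). Boundary (singular) REML fits are
#: resolved by the optimiser only to about 1e-4 on this ratio, while
#: genuinely supported components sit near or above 1, so 1e-3 separates
#: the two regimes cleanly (cf. lme4's singular-fit tolerance of 1e-4 on
#: the same SD ratio).
NE_RATIO = 1e-3


def fit_variance_components(
    table: pd.DataFrame, metric: str, region: str
) -> VarianceComponents:
    """Fit the scanner-fixed / volunteer-random model for one metric/region.

    Uses REML (statsmodels ``MixedLM``; Powell optimiser, which converges
    to the balanced-ANOVA solution to ~1e-7 relative on balanced designs).
    Degenerate noiseless tables (zero residual after scanner effects) are
    resolved in closed form instead of invoking the optimiser.
    """
    sub = table[(table["metric"] == metric) & (table["region"] == region)]
    if sub.empty:
        raise StatsError(f"no rows for metric={metric!r} region={region!r}")
    scanners = sorted(sub["scanner"].unique())
    if len(scanners) < 2:
        raise StatsError("variance-component fit needs >= 2 scanners")
    if sub["volunteer"].nunique() < 2:
        raise StatsError("variance-component fit needs >= 2 volunteers")

    y = sub["value"].to_numpy(dtype=float)
    scanner_mean_obs = sub.groupby("scanner")["value"].mean()
    resid_fixed = y - sub["scanner"].map(scanner_mean_obs).to_numpy()
    scale = max(float(np.abs(y).max()), 1e-300)
    if float(resid_fixed @ resid_fixed) <= (1e-12 * scale) ** 2 * y.size:
        # noiseless limit: scanner means are exact, nothing left for the
        # volunteer or residual terms
        means = {s: float(m) for s, m in scanner_mean_obs.items()}
        mvals = np.array(list(means.values()))
        return VarianceComponents(
            mu=float(mvals.mean()),
            sigma_inter=float(mvals.std(ddof=1)),
            sigma_volunteer=0.0,
            sigma_intra=0.0,
            volunteer_estimable=False,
            scanner_means=means,
            n_obs=y.size,
        )

    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("value ~ C(scanner)", sub, groups=sub["volunteer"])
        try:
            # Tight tolerances: on balanced designs the REML optimum
            # coincides with the ANOVA estimators and is checked to 1e-6.
            res = model.fit(reml=True, method="powell", maxiter=5000,
                            xtol=1e-12, ftol=1e-14)
        except Exception:
            res = model.fit(reml=True, method="lbfgs", maxiter=5000)
        converged = bool(getattr(res, "converged", True))

    params = res.fe_params
    intercept = params["Intercept"]
    means = {}
    for s in scanners:
        key = f"C(scanner)[T.{s}]"
        means[s] = float(intercept + (params[key] if key in params else 0.0))
    mvals = np.array(list(means.values()))

    sigma_intra = float(np.sqrt(res.scale))
    sigma_vol = float(np.sqrt(max(res.cov_re.iloc[0, 0], 0.0)))
    estimable = sigma_vol >= NE_RATIO * max(sigma_intra, 1e-300)
    return VarianceComponents(
        mu=float(mvals.mean()),
        sigma_inter=float(mvals.std(ddof=1)),
        sigma_volunteer=sigma_vol if estimable else 0.0,
        sigma_intra=sigma_intra,
        volunteer_estimable=estimable,
        converged=converged,
        scanner_means=means,
        n_obs=y.size,
    )


@dataclass(frozen=True)
class ReproResult:
    """CV/ICC summary for one metric/region (and optional subgroup)."""

    metric: str
    region: str
    subgroup: str
    mean: float
    sigma_inter: float
    sigma_volunteer: float
    sigma_intra: float
    volunteer_estimable: bool
    cv_inter: float
    cv_volunteer: float
    cv_intra: float
    icc_inter: float
    icc_intra: float
    valid: bool = True
    note: str = ""

    @classmethod
    def flagged(cls, metric, region, subgroup, note) -> "ReproResult":
        nan = float("nan")
        return cls(metric=metric, region=region, subgroup=subgroup,
                   mean=nan, sigma_inter=nan, sigma_volunteer=nan,
                   sigma_intra=nan, volunteer_estimable=False, cv_inter=nan,
                   cv_volunteer=nan, cv_intra=nan, icc_inter=nan,
                   icc_intra=nan, valid=False, note=note)


def repro_result(vc: VarianceComponents, metric: str, region: str,
                 subgroup: str = "all") -> ReproResult:
    """Convert variance components into the CV/ICC summary."""
    icc_i, icc_e = icc_pair(vc.sigma_inter, vc.sigma_intra)
    return ReproResult(
        metric=metric, region=region, subgroup=subgroup, mean=vc.mu,
        sigma_inter=vc.sigma_inter, sigma_volunteer=vc.sigma_volunteer,
        sigma_intra=vc.sigma_intra,
        volunteer_estimable=vc.volunteer_estimable,
        cv_inter=cv_from_components(vc.mu, vc.sigma_inter),
        cv_volunteer=(cv_from_components(vc.mu, vc.sigma_volunteer)
                      if vc.volunteer_estimable else float("nan")),
        cv_intra=cv_from_components(vc.mu, vc.sigma_intra),
        icc_inter=icc_i, icc_intra=icc_e,
    )


def analyse_metric_region(table: pd.DataFrame, metric: str, region: str,
                          subgroup: str = "all") -> ReproResult:
    """Fit the variance components and summarise in one step."""
    vc = fit_variance_components(table, metric, region)
    return repro_result(vc, metric, region, subgroup)


def subgroup_analysis(
    table: pd.DataFrame,
    field_strength: dict,
    metric: str,
    region: str,
) -> dict:
    """Run the CV/ICC pipeline per field strength and combined.

    ``field_strength`` maps scanner id -> 1.5 or 3. Subgroups that cannot
    support the model (fewer than two scanners) are flagged in the result
    rather than aborting the others.
    """
    groups = {"all": sorted(set(table["scanner"]))}
    for sid, fs in field_strength.items():
        groups.setdefault(f"{fs:g}T", []).append(sid)
    out = {}
    for name, sids in groups.items():
        sub = table[table["scanner"].isin(sids)]
        try:
            out[name] = analyse_metric_region(sub, metric, region, name)
        except StatsError as exc:
            out[name] = ReproResult.flagged(metric, region, name, str(exc))
    return out


def summarize_report(results) -> pd.DataFrame:
    """Tabulate CV/ICC results the way reproducibility tables are printed.

    One row per result: mean, the three SDs, the three CVs (one decimal),
    the ICC pair (two decimals) and the minimum detectable change
    (2 x inter-scanner CV -- a change must exceed two standard deviations
    to be distinguishable from scanner variation). Non-estimable volunteer
    components are rendered "NE". Internal values are never rounded;
    rounding happens only here.
    """
    rows = []
    for r in results:
        if not r.valid:
            rows.append({"metric": r.metric, "region": r.region,
                         "subgroup": r.subgroup, "note": r.note})
            continue
        ne = not r.volunteer_estimable
        rows.append({
            "metric": r.metric,
            "region": r.region,
            "subgroup": r.subgroup,
            "mean": r.mean,
            "sd_inter": r.sigma_inter,
            "sd_volunteer": "NE" if ne else r.sigma_volunteer,
            "sd_intra": r.sigma_intra,
            "cv_inter_pct": round(r.cv_inter, 1),
            "cv_volunteer_pct": "NE" if ne else round(r.cv_volunteer, 1),
            "cv_intra_pct": round(r.cv_intra, 1),
            "icc_inter": round(r.icc_inter, 2),
            "icc_intra": round(r.icc_intra, 2),
            "mdc_pct": round(2.0 * r.cv_inter, 1),
            "note": r.note,
        })
    columns = ["metric", "region", "subgroup", "mean", "sd_inter",
               "sd_volunteer", "sd_intra", "cv_inter_pct",
               "cv_volunteer_pct", "cv_intra_pct", "icc_inter",
               "icc_intra", "mdc_pct", "note"]
    return pd.DataFrame(rows, columns=columns)
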