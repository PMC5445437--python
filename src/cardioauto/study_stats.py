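"""Delta-from-baseline tables and the study-level inference layer.

Endpoint values are summarized per animal per day; each exposure-day value
minus the same animal's baseline value forms a "delta".  Group effects on
deltas are estimated with linear mixed models (random structure chosen by
AIC); arrhythmia counts with a Poisson GEE under an exchangeable working
correlation, the baseline count entering as a per-animal covariate (or
offset); associations with simple Pearson or group-adjusted partial
correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

BASELINE_LABEL = "baseline"

#: Candidate random-effect structures for the mixed model.  A random
#: intercept induces a compound-symmetric marginal covariance, so the
#: classic CS candidate coincides with "intercept".
RANDOM_STRUCTURES = ("intercept", "intercept_day")


@dataclass
class EffectEstimate:
    endpoint: str
    contrast: str          # "overall" | "day:<label>"
    estimate: float
    se: float
    p_value: float
    model: str = ""
    aic: float = np.nan
    warnings: list = field(default_factory=list)


def make_deltas(values: pd.DataFrame, endpoints: list[str] | None = None,
                baseline_label: str = BASELINE_LABEL) -> pd.DataFrame:
    """Long delta table from per-animal-day endpoint values.

    ``values`` needs columns ``animal_id``, ``group``, ``day_label`` plus one
    column per endpoint (multiple rows per animal-day are averaged first).
    Animals without a baseline row are excluded with an audit column absent;
    missing endpoint values yield missing deltas, never zero.
    """
    if endpoints is None:
        endpoints = [c for c in values.columns
                     if c not in ("animal_id", "group", "day_label", "segment_id")]
    daily = (values.groupby(["animal_id", "group", "day_label"], sort=False, as_index=False)[endpoints]
             .mean())
    base = daily[daily["day_label"].astype(str) == baseline_label]
    rows = []
    for _, r in daily[daily["day_label"].astype(str) != baseline_label].iterrows():
        b = base[base["animal_id"] == r["animal_id"]]
        if len(b) == 0:
            continue  # no baseline for this animal
        for ep in endpoints:
            delta = r[ep] - b[ep].iloc[0]
            if pd.isna(delta):
                continue
            rows.append({
                "animal_id": r["animal_id"], "group": r["group"],
                "day_label": str(r["day_label"]), "endpoint": ep,
                "delta": float(delta),
            })
    return pd.DataFrame(rows, columns=["animal_id", "group", "day_label", "endpoint", "delta"])


def _fit_one_lmm(df: pd.DataFrame, formula: str, structure: str, reml: bool):
    kwargs = {"groups": df["animal_id"]}
    if structure == "intercept_day":
        kwargs["re_formula"] = "~day_num"
    model = smf.mixedlm(formula, df, **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=reml)
        except np.linalg.LinAlgError:
            fit = model.fit(reml=reml, method="powell")
    return fit


def fit_lmm(
    deltas: pd.DataFrame,
    endpoint: str,
    exposed_group: str | None = None,
    contrast: str = "overall",
    structures: tuple[str, ...] = RANDOM_STRUCTURES,
) -> list[EffectEstimate]:
    """Exposure-group effect on an endpoint's deltas, controlling for day.

    ``contrast="overall"`` fits ``delta ~ day + exposed`` and reports the
    exposed coefficient; ``"daily"`` fits a group × day interaction and
    reports one contrast per day.  Candidate random structures are compared
    by (ML) AIC; non-convergence falls back to the simplest structure with a
    warning recorded on the estimate.
    """
    df = deltas[deltas["endpoint"] == endpoint].copy()
    if df.empty:
        raise ValueError(f"no rows for endpoint {endpoint!r}")
    groups = sorted(df["group"].unique())
    if exposed_group is None:
        exposed_group = groups[-1]
    df["exposed"] = (df["group"] == exposed_group).astype(float)
    day_order = list(dict.fromkeys(df["day_label"]))
    df["day_num"] = df["day_label"].map({d: i for i, d in enumerate(day_order)}).astype(float)

    if contrast == "overall":
        formula = "delta ~ C(day_label) + exposed"
    elif contrast == "daily":
        formula = "delta ~ C(day_label) + C(day_label):exposed"
    else:
        raise ValueError(f"unknown contrast {contrast!r}")

    # candidate selection by (ML) AIC, inference from a REML refit of the
    # winner; group contrasts use between-within t degrees of freedom
    # (animals minus the two group-level parameters), mirroring the
    # conventions of the mixed-model software the design targets
    best_struct, best_aic, notes = None, np.inf, []
    if len(structures) == 1:
        best_struct = structures[0]
        best_aic = np.nan
    else:
        for struct in structures:
            try:
                fit = _fit_one_lmm(df, formula, struct, reml=False)
            except Exception as exc:  # noqa: BLE001 - any optimizer failure
                notes.append(f"{struct}: failed ({exc})")
                continue
            if fit.aic < best_aic:
                best_struct, best_aic = struct, float(fit.aic)
    if best_struct is None:
        raise RuntimeError(f"no random structure converged for {endpoint}: {notes}")
    try:
        best = _fit_one_lmm(df, formula, best_struct, reml=True)
    except Exception as exc:  # noqa: BLE001
        notes.append(f"REML refit failed ({exc}); falling back to intercept")
        best_struct = structures[0]
        best = _fit_one_lmm(df, formula, best_struct, reml=True)

    df_bw = max(int(df["animal_id"].nunique()) - 2, 1)

    def wald_t(name: str) -> tuple[float, float, float]:
        est, se = float(best.params[name]), float(best.bse[name])
        p = 2.0 * stats.t.sf(abs(est / se), df_bw) if se > 0 else np.nan
        return est, se, p

    out = []
    if contrast == "overall":
        est, se, p = wald_t("exposed")
        out.append(EffectEstimate(
            endpoint=endpoint, contrast="overall", estimate=est, se=se,
            p_value=p, model=best_struct, aic=best_aic, warnings=notes,
        ))
    else:
        for d in day_order:
            name = f"C(day_label)[{d}]:exposed"
            if name not in best.params.index:
                continue
            est, se, p = wald_t(name)
            out.append(EffectEstimate(
                endpoint=endpoint, contrast=f"day:{d}", estimate=est, se=se,
                p_value=p, model=best_struct, aic=best_aic, warnings=notes,
            ))
    return out


def fit_count_gee(
    counts: pd.DataFrame,
    endpoint: str,
    exposed_group: str | None = None,
    contrast: str = "overall",
    baseline_label: str = BASELINE_LABEL,
    baseline_as: str = "covariate",
) -> list[EffectEstimate]:
    """Poisson GEE for daily event counts (exchangeable working correlation).

    ``counts`` columns: ``animal_id``, ``group``, ``day_label`` and the
    endpoint column of non-negative integers, one row per animal-day
    including a baseline day.  Each animal's baseline count enters as
    ``log(baseline + 0.5)`` — covariate by default, offset with
    ``baseline_as="offset"``.  Estimates are reported as log rate ratios.
    """
    df = counts.copy()
    df["day_label"] = df["day_label"].astype(str)
    base = (df[df["day_label"] == baseline_label]
            .set_index("animal_id")[endpoint])
    df = df[df["day_label"] != baseline_label].copy()
    df["log_base"] = np.log(df["animal_id"].map(base).astype(float) + 0.5)
    df = df.dropna(subset=[endpoint, "log_base"])
    if df[endpoint].sum() == 0:
        raise ValueError(f"endpoint {endpoint!r} is all zero: rate ratio inestimable")
    groups = sorted(df["group"].unique())
    if exposed_group is None:
        exposed_group = groups[-1]
    df["exposed"] = (df["group"] == exposed_group).astype(float)

    if contrast == "overall":
        formula = f"{endpoint} ~ C(day_label) + exposed + log_base"
    elif contrast == "daily":
        formula = f"{endpoint} ~ C(day_label) + C(day_label):exposed + log_base"
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    offset = None
    if baseline_as == "offset":
        formula = formula.replace(" + log_base", "")
        offset = df["log_base"]

    model = smf.gee(formula, groups="animal_id", data=df, offset=offset,
                    family=sm.families.Poisson(),
                    cov_struct=sm.cov_struct.Exchangeable())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit()
    notes = []
    if df.groupby("group")["animal_id"].nunique().min() < 2:
        notes.append("robust SE unreliable: fewer than 2 animals in a group")

    out = []
    if contrast == "overall":
        out.append(EffectEstimate(
            endpoint=endpoint, contrast="overall",
            estimate=float(fit.params["exposed"]), se=float(fit.bse["exposed"]),
            p_value=float(fit.pvalues["exposed"]), model="gee_poisson_exch",
            warnings=notes,
        ))
    else:
        for d in sorted(df["day_label"].unique()):
            name = f"C(day_label)[{d}]:exposed"
            if name not in fit.params.index:
                continue
            out.append(EffectEstimate(
                endpoint=endpoint, contrast=f"day:{d}",
                estimate=float(fit.params[name]), se=float(fit.bse[name]),
                p_value=float(fit.pvalues[name]), model="gee_poisson_exch",
                warnings=notes,
            ))
    return out


def correlate(x, y, groups=None) -> tuple[float, float]:
    """Pearson r and p between paired endpoint vectors.

    With ``groups`` given, both variables are first residualized on group
    indicators (partial correlation adjusting for group).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    if groups is not None:
        g = pd.get_dummies(pd.Series(np.asarray(groups)[ok]), drop_first=False).to_numpy(float)
        x = x - g @ np.linalg.lstsq(g, x, rcond=None)[0]
        y = y - g @ np.linalg.lstsq(g, y, rcond=None)[0]
        if np.std(x) == 0 or np.std(y) == 0:
            return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
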