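"""Statistical battery: normality screen, nonparametric tests, FDR, logistic models.

The comparison layer is deliberately nonparametric: HRV features and
transition probabilities are bounded, skewed quantities whose normality is
screened (and routinely rejected) by a Monte-Carlo Lilliefors test.
Between-group contrasts use the unpaired Mann-Whitney U test, within-group
stage contrasts the Wilcoxon signed-rank test (the paired analogue),
three-group screening the Kruskal-Wallis test, and every test family is
adjusted by Benjamini-Hochberg FDR at alpha = 0.05.  Group membership is
finally modelled per sleep stage by the logistic regression

    logit(y) ~ 1 + X + A + S + C   [+ AHI + PLMI]

with X one HRV feature, A age, S sex (male 0 / female 1) and C the
recording center (0/1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

ALPHA = 0.05

HRV_PARAMS = ("mu", "sigma2", "lf", "hf", "lfn", "hfn", "lfhf")
SLEEP_STAGES = ("N1", "N2", "N3", "REM")
NREM_STAGES = ("N1", "N2", "N3")


class SeparationError(RuntimeError):
    """Logistic outcome perfectly predicted; coefficients are unbounded."""


class DesignError(ValueError):
    """Rank-deficient regression design (names the collinear columns)."""


@dataclass
class TestResult:
    statistic: float
    p_raw: float
    n: tuple[int, ...]
    method: str
    p_fdr: float | None = None
    flag: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_raw}")


@dataclass
class RegressionSpec:
    """One logistic model: a single HRV feature for a single stage."""

    parameter: str
    stage: str
    contrast: tuple[str, str]  # (reference group -> y=0, case group -> y=1)
    extra_covariates: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Lilliefors normality test (Monte-Carlo null)

_LILLIEFORS_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _lilliefors_stat(x: np.ndarray) -> float:
    """KS distance of the sample against N(mean, sd) with estimated moments."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: Lilliefors statistic undefined")
    z = sps.norm.cdf((x - x.mean()) / sd)
    up = np.arange(1, n + 1) / n - z
    lo = z - np.arange(0, n) / n
    return float(max(up.max(), lo.max()))


def _lilliefors_null(n: int, n_mc: int, seed: int) -> np.ndarray:
    key = (n, n_mc, seed)
    if key not in _LILLIEFORS_NULL_CACHE:
        rng = np.random.default_rng(seed)
        samples = rng.standard_normal((n_mc, n))
        samples.sort(axis=1)
        mean = samples.mean(axis=1, keepdims=True)
        sd = samples.std(axis=1, ddof=1, keepdims=True)
        z = sps.norm.cdf((samples - mean) / sd)
        grid_hi = np.arange(1, n + 1) / n
        grid_lo = np.arange(0, n) / n
        d = np.maximum((grid_hi - z).max(axis=1), (z - grid_lo).max(axis=1))
        _LILLIEFORS_NULL_CACHE[key] = np.sort(d)
    return _LILLIEFORS_NULL_CACHE[key]


def lilliefors(sample, n_mc: int = 10000, seed: int = 12345) -> TestResult:
    """Lilliefors normality test with a seeded Monte-Carlo null.

    The statistic is the KS distance against the normal with estimated mean
    and SD; the p-value is the (add-one) exceedance fraction of the same
    statistic over ``n_mc`` seeded standard-normal samples of equal size.
    The null table is distribution-free and cached per sample size.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError("Lilliefors test requires n >= 4")
    d = _lilliefors_stat(x)
    null = _lilliefors_null(x.size, n_mc, seed)
    p = (1 + int(null.size - np.searchsorted(null, d, side="left"))) / (n_mc + 1)
    return TestResult(statistic=d, p_raw=min(p, 1.0), n=(x.size,), method="lilliefors-mc")


# ---------------------------------------------------------------------------
# Rank tests

def mann_whitney_u(x, y, paired: bool = False) -> TestResult:
    """Two-sided Mann-Whitney U test (or its paired analogue).

    Unpaired: exact enumeration when n_x + n_y <= 16 and the pooled data
    are tie-free, tie-corrected normal approximation (no continuity
    correction) otherwise.  Paired: Wilcoxon signed-rank on the
    differences, exact for n <= 15 without ties/zeros; all-tied pairs give
    p = 1 with a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired test requires equal-length samples")
        d = x - y
        nz = d[d != 0]
        if nz.size == 0:
            return TestResult(0.0, 1.0, (x.size,), "wilcoxon", flag="all-tied")
        exact = nz.size <= 15 and np.unique(np.abs(nz)).size == nz.size
        stat, p = sps.wilcoxon(x, y, zero_method="wilcox",
                               method="exact" if exact else "approx")
        return TestResult(float(stat), float(min(p, 1.0)), (x.size,), "wilcoxon")
    if x.size < 2 or y.size < 2:
        raise ValueError("unpaired test requires n >= 2 per group")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:  # degenerate: everything tied
        return TestResult(x.size * y.size / 2.0, 1.0, (x.size, y.size),
                          "mwu-degenerate", flag="all-tied")
    ties = np.unique(pooled).size < pooled.size
    small = x.size + y.size <= 16
    method = "exact" if (small and not ties) else "asymptotic"
    stat, p = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                               use_continuity=False)
    return TestResult(float(stat), float(min(p, 1.0)), (x.size, y.size),
                      f"mwu-{method}")


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H across k groups (tie-corrected, chi-square p).

    Degenerate all-equal data are reported as H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:
        return TestResult(0.0, 1.0, tuple(g.size for g in groups), "kruskal",
                          flag="all-equal")
    stat, p = sps.kruskal(*groups)
    return TestResult(float(stat), float(p), tuple(g.size for g in groups), "kruskal")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Logistic regression

def logistic_fit(y, X: pd.DataFrame) -> pd.DataFrame:
    """Maximum-likelihood logistic fit (IRLS/Newton) with Wald p-values.

    ``X`` must not include the constant; it is added as ``const``.  Raises
    :class:`DesignError` on rank-deficient designs (naming the collinear
    columns) and :class:`SeparationError` on complete separation — no
    silent, runaway coefficients are returned.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 20:
        raise ValueError("logistic fit requires n >= 20")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    design = sm.add_constant(X.astype(float), has_constant="add")
    mat = design.to_numpy()
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify columns that do not increase the rank
        bad, r = [], 0
        for k, col in enumerate(design.columns):
            if np.linalg.matrix_rank(mat[:, : k + 1]) == r:
                bad.append(col)
            else:
                r += 1
        raise DesignError(f"rank-deficient design; collinear columns: {bad}")
    try:
        res = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(str(exc)) from exc
    fitted = res.predict(design)
    if np.all((fitted > 1 - 1e-8) == (y > 0.5)) and np.all(
        np.minimum(fitted, 1 - fitted) < 1e-8
    ):
        raise SeparationError("outcome perfectly predicted by the design")
    return pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "z": res.tvalues,
            "p": res.pvalues,
            "ci_lo": res.conf_int()[0],
            "ci_hi": res.conf_int()[1],
        }
    )


# ---------------------------------------------------------------------------
# Full battery

def _feature_pivot(features: pd.DataFrame) -> pd.DataFrame:
    """Long (subject_id, group, stage, parameter, value) -> wide per row."""
    return features.pivot_table(
        index=["subject_id", "group", "stage"], columns="parameter",
        values="value", aggfunc="first",
    ).reset_index()


def run_battery(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    deltas: pd.DataFrame | None = None,
    alpha: float = ALPHA,
    seed: int = 12345,
) -> dict:
    """Run the full comparison battery on a stage-level feature table.

    ``features`` is long-format with columns (subject_id, group, stage,
    parameter, value); ``metadata`` has one row per subject with columns
    (subject_id, group, age, sex, center, ahi, plmi); ``deltas`` optionally
    holds REM-NREM difference rows in the same long format with a
    ``contrast`` column.

    Returns a dict of tidy DataFrames: normality screen, Kruskal-Wallis,
    pairwise between-group tests (FDR within each contrast over the
    parameters x stages family), within-group REM-vs-NREM paired tests
    (FDR per group), delta-value between-group tests, and logistic models
    per contrast x stage x parameter (with and without AHI/PLMI), plus a
    manifest recording family definitions and counts.
    """
    groups = [g for g in ("CG", "iRBD", "PD_RBD") if g in set(features["group"])]
    wide = _feature_pivot(features)
    params = [p for p in HRV_PARAMS if p in wide.columns]

    def sample(group: str, stage: str, param: str) -> np.ndarray:
        v = wide.loc[(wide["group"] == group) & (wide["stage"] == stage), param]
        return v.dropna().to_numpy()

    # --- normality screen + Kruskal-Wallis
    norm_rows, kw_rows = [], []
    for param in params:
        for stage in SLEEP_STAGES:
            samples = {g: sample(g, stage, param) for g in groups}
            for g, v in samples.items():
                if v.size >= 4 and np.unique(v).size > 1:
                    r = lilliefors(v, seed=seed)
                    norm_rows.append(
                        {"group": g, "stage": stage, "parameter": param,
                         "n": v.size, "statistic": r.statistic, "p": r.p_raw}
                    )
            usable = [v for v in samples.values() if v.size >= 2]
            if len(usable) >= 2:
                try:
                    r = kruskal_wallis(usable)
                    kw_rows.append(
                        {"stage": stage, "parameter": param, "H": r.statistic,
                         "p": r.p_raw, "n": r.n, "flag": r.flag}
                    )
                except ValueError:
                    pass

    # --- pairwise between-group (FDR family: params x stages per contrast)
    between_rows = []
    for ga, gb in itertools.combinations(groups, 2):
        fam = []
        for param in params:
            for stage in SLEEP_STAGES:
                xa, xb = sample(ga, stage, param), sample(gb, stage, param)
                row = {"contrast": f"{ga}_vs_{gb}", "parameter": param,
                       "stage": stage, "n_a": xa.size, "n_b": xb.size,
                       "median_a": float(np.median(xa)) if xa.size else np.nan,
                       "median_b": float(np.median(xb)) if xb.size else np.nan,
                       "p_raw": np.nan, "testable": xa.size >= 2 and xb.size >= 2}
                if row["testable"]:
                    row["p_raw"] = mann_whitney_u(xa, xb).p_raw
                fam.append(row)
        ps = [r["p_raw"] for r in fam if r["testable"]]
        if ps:
            adj = iter(bh_fdr(ps))
            for r in fam:
                r["p_fdr"] = next(adj) if r["testable"] else np.nan
        between_rows.extend(fam)

    # --- within-group paired REM vs NREM (FDR family: params x pairs per group)
    within_rows = []
    for g in groups:
        sub = wide[wide["group"] == g]
        fam = []
        for param in params:
            rem = sub[sub["stage"] == "REM"].set_index("subject_id")[param]
            for nrem in NREM_STAGES:
                other = sub[sub["stage"] == nrem].set_index("subject_id")[param]
                joined = pd.concat([rem, other], axis=1, join="inner").dropna()
                row = {"group": g, "parameter": param, "pair": f"REM_vs_{nrem}",
                       "n": len(joined), "p_raw": np.nan,
                       "testable": len(joined) >= 4}
                if row["testable"]:
                    r = mann_whitney_u(joined.iloc[:, 0], joined.iloc[:, 1],
                                       paired=True)
                    row["p_raw"] = r.p_raw
                    row["flag"] = r.flag
                fam.append(row)
        ps = [r["p_raw"] for r in fam if r["testable"]]
        if ps:
            adj = iter(bh_fdr(ps))
            for r in fam:
                r["p_fdr"] = next(adj) if r["testable"] else np.nan
        within_rows.extend(fam)

    # --- delta-value between-group tests
    delta_rows = []
    if deltas is not None and len(deltas):
        dwide = deltas.pivot_table(
            index=["subject_id", "group", "contrast"], columns="parameter",
            values="value", aggfunc="first").reset_index()
        for ga, gb in itertools.combinations(groups, 2):
            fam = []
            for param in params:
                for dc in sorted(set(dwide["contrast"])):
                    xa = dwide.loc[(dwide["group"] == ga) & (dwide["contrast"] == dc),
                                   param].dropna().to_numpy()
                    xb = dwide.loc[(dwide["group"] == gb) & (dwide["contrast"] == dc),
                                   param].dropna().to_numpy()
                    row = {"contrast": f"{ga}_vs_{gb}", "parameter": param,
                           "delta": dc, "n_a": xa.size, "n_b": xb.size,
                           "p_raw": np.nan,
                           "testable": xa.size >= 2 and xb.size >= 2}
                    if row["testable"]:
                        row["p_raw"] = mann_whitney_u(xa, xb).p_raw
                    fam.append(row)
            ps = [r["p_raw"] for r in fam if r["testable"]]
            if ps:
                adj = iter(bh_fdr(ps))
                for r in fam:
                    r["p_fdr"] = next(adj) if r["testable"] else np.nan
            delta_rows.extend(fam)

    # --- logistic models per contrast x stage x parameter
    meta = metadata.set_index("subject_id")
    logit_rows = []
    for ga, gb in itertools.combinations(groups, 2):
        for param in params:
            for stage in SLEEP_STAGES:
                sub = wide[(wide["stage"] == stage)
                           & (wide["group"].isin((ga, gb)))].dropna(subset=[param])
                sub = sub[sub["subject_id"].isin(meta.index)]
                for extra in ((), ("ahi", "plmi")):
                    row = {"contrast": f"{ga}_vs_{gb}", "parameter": param,
                           "stage": stage, "covariates": "+".join(extra) or "base",
                           "n": len(sub), "flag": ""}
                    try:
                        m = meta.loc[sub["subject_id"]]
                        X = pd.DataFrame(
                            {"X": sub[param].to_numpy(),
                             "A": m["age"].to_numpy(),
                             "S": m["sex"].to_numpy(),
                             "C": m["center"].to_numpy()})
                        for e in extra:
                            X[e.upper()] = m[e].to_numpy()
                        y = (sub["group"] == gb).astype(float).to_numpy()
                        coefs = logistic_fit(y, X)
                        for name, c in coefs.iterrows():
                            row[f"coef_{name}"] = c["coef"]
                            row[f"p_{name}"] = c["p"]
                    except (ValueError, SeparationError, DesignError) as exc:
                        row["flag"] = f"not-testable: {exc}"
                    logit_rows.append(row)

    manifest = {
        "alpha": alpha,
        "groups": groups,
        "n_subjects": {g: int((metadata["group"] == g).sum()) for g in groups},
        "fdr_families": {
            "between": "per pairwise contrast: parameters x 4 stages",
            "within": "per group: parameters x 3 REM-NREM pairs",
            "delta": "per pairwise contrast: parameters x delta contrasts",
        },
        "seed": seed,
    }
    return {
        "normality": pd.DataFrame(norm_rows),
        "kruskal": pd.DataFrame(kw_rows),
        "between": pd.DataFrame(between_rows),
        "within": pd.DataFrame(within_rows),
        "delta": pd.DataFrame(delta_rows),
        "logistic": pd.DataFrame(logit_rows),
        "manifest": manifest,
    }
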