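"""Numerical and statistical quantification: copies-per-cell, ddCt
fold-change with a 2xSD outlier rule, qPCR standard curves, Welch's t,
Cohen's d, Dunnett and Steel-Dwass multiple comparisons, and OLS
regression with pointwise confidence bands.

The qPCR conventions follow routine relative quantification: Ct values
are normalised to a reference gene (18S rRNA), dCt to the mean dCt of
the control group within the same (target, compartment) stratum, and
log2 fold-change = -ddCt.  Samples whose log2 FC deviates from their
group mean by more than twice the group SD are flagged as outliers in a
single pass and excluded from reported group statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

AVOGADRO = 6.02214076e23

#: required columns of a Ct table
CT_COLUMNS = ("sample_id", "group", "compartment", "target",
              "ct_target", "ct_reference")


# ---------------------------------------------------------------------------
# copies per cell


@dataclass(frozen=True)
class CpcEstimate:
    """Absolute copy number from a molar concentration and a cell volume."""

    concentration_molar: float
    cell_volume_um3: float
    copies_per_cell: float


def copies_per_cell(concentration_molar: float, volume_um3: float) -> CpcEstimate:
    """copies = c * N_A * V, with V converted from um^3 to litres (1e-15 L)."""
    if concentration_molar < 0 or volume_um3 < 0:
        raise ValueError("concentration and volume must be non-negative")
    copies = concentration_molar * AVOGADRO * (volume_um3 * 1e-15)
    return CpcEstimate(concentration_molar, volume_um3, copies)


def excess_ratio(copies: float, endogenous_upper_cpc: float) -> float:
    """Fold excess of an introduced species over an endogenous upper bound."""
    if endogenous_upper_cpc <= 0:
        raise ValueError("endogenous upper bound must be positive")
    return copies / endogenous_upper_cpc


# ---------------------------------------------------------------------------
# ddCt


@dataclass
class FoldChangeResult:
    """Per-sample log2 fold-changes and per-group summaries.

    ``per_sample`` columns: the Ct table columns plus ``delta_ct``,
    ``delta_delta_ct``, ``log2_fc`` and ``outlier``;
    ``group_summary`` has mean/SD/n per (target, compartment, group)
    computed after outlier exclusion, plus the excluded sample ids.
    """

    per_sample: pd.DataFrame
    group_summary: pd.DataFrame
    control_group: str
    outlier_rule: str = ""


def delta_delta_ct(records: pd.DataFrame, control_group: str,
                   outlier_policy: str = "robust") -> FoldChangeResult:
    """Relative quantification with reference normalisation and outliers.

    Within each (target, compartment) stratum: dCt = ct_target -
    ct_reference, ddCt = dCt - mean(control-group dCt), log2 FC = -ddCt.
    Requires at least one control sample per stratum and a finite
    reference Ct for every record.

    Outlier policies (single pass, per (target, compartment, group)):

    ``robust`` (default)
        Flag samples with |log2FC - group median| > 2 x SD_robust, where
        SD_robust = 1.4826 * MAD.  Tracks the plain 2xSD rule on clean
        Gaussian groups but still has power at small n: the centred
        sample-SD form can never fire for n <= 6 because
        max |x - mean| / SD = (n-1)/sqrt(n) < 2.
    ``group``
        The literal centred form, |log2FC - group mean| > 2 x group SD.
    """
    df = pd.DataFrame(records).copy()
    missing_cols = [c for c in CT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"Ct table lacks columns: {missing_cols}")
    bad = df[~np.isfinite(df["ct_reference"]) | ~np.isfinite(df["ct_target"])]
    if len(bad):
        raise ValueError(
            "missing/non-finite Ct for samples: "
            + ", ".join(str(s) for s in bad["sample_id"])
        )
    if (df[["ct_target", "ct_reference"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")

    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    out = []
    for (target, compartment), stratum in df.groupby(["target", "compartment"],
                                                     sort=False):
        ctrl = stratum[stratum["group"] == control_group]
        if len(ctrl) == 0:
            raise ValueError(
                f"no control-group sample in stratum ({target}, {compartment})"
            )
        baseline = float(ctrl["delta_ct"].mean())
        stratum = stratum.copy()
        stratum["delta_delta_ct"] = stratum["delta_ct"] - baseline
        stratum["log2_fc"] = -stratum["delta_delta_ct"]
        out.append(stratum)
    per_sample = pd.concat(out, ignore_index=True)

    # single-pass 2xSD rule, per (target, compartment, group)
    if outlier_policy not in ("robust", "group"):
        raise ValueError(f"unknown outlier policy: {outlier_policy!r}")
    per_sample["outlier"] = False
    for _, idx in per_sample.groupby(["target", "compartment", "group"],
                                     sort=False).groups.items():
        vals = per_sample.loc[idx, "log2_fc"]
        if len(vals) < 2:
            continue
        if outlier_policy == "group":
            center = float(vals.mean())
            sd = float(vals.std(ddof=1))
        else:
            center = float(vals.median())
            sd = 1.4826 * float((vals - vals.median()).abs().median())
            if sd == 0:  # degenerate MAD (e.g. duplicated values)
                sd = float(vals.std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            continue
        per_sample.loc[idx, "outlier"] = (vals - center).abs() > 2.0 * sd
    rule = ("|log2FC - group median| > 2 x 1.4826*MAD, single pass"
            if outlier_policy == "robust"
            else "|log2FC - group mean| > 2 x group SD, single pass")

    rows = []
    for (target, compartment, group), sub in per_sample.groupby(
            ["target", "compartment", "group"], sort=False):
        kept = sub[~sub["outlier"]]
        rows.append({
            "target": target, "compartment": compartment, "group": group,
            "mean_log2_fc": float(kept["log2_fc"].mean()) if len(kept) else np.nan,
            "sd_log2_fc": float(kept["log2_fc"].std(ddof=1)) if len(kept) > 1 else np.nan,
            "n": int(len(kept)),
            "outlier_sample_ids": ";".join(
                str(s) for s in sub.loc[sub["outlier"], "sample_id"]),
        })
    summary = pd.DataFrame(rows, columns=["target", "compartment", "group",
                                          "mean_log2_fc", "sd_log2_fc", "n",
                                          "outlier_sample_ids"])
    return FoldChangeResult(per_sample=per_sample, group_summary=summary,
                            control_group=control_group, outlier_rule=rule)


# ---------------------------------------------------------------------------
# standard curve


@dataclass
class StandardCurveResult:
    slope: float
    intercept: float
    efficiency: float  # 10^(-1/slope) - 1; 1.0 == 100 %
    amounts: np.ndarray

    def predict_ct(self, amount: float) -> float:
        return self.slope * math.log10(amount) + self.intercept


def standard_curve_quantify(standards: Sequence[tuple[float, float]],
                            unknown_cts: Sequence[float]) -> StandardCurveResult:
    """Absolute quantification against a dilution series.

    Fits ``ct = m * log10(amount) + b`` by least squares over the
    standards and inverts it for the unknowns; the amplification
    efficiency ``10^(-1/m) - 1`` is reported (1.0 for a perfect
    doubling slope of -1/log10(2) ~ -3.32 cycles/decade).
    """
    amounts = np.asarray([s[0] for s in standards], dtype=np.float64)
    cts = np.asarray([s[1] for s in standards], dtype=np.float64)
    if amounts.size < 2 or np.unique(amounts).size < 2:
        raise ValueError("need >= 2 distinct standard amounts")
    if (amounts <= 0).any():
        raise ValueError("standard amounts must be positive")
    slope, intercept = np.polyfit(np.log10(amounts), cts, 1)
    if abs(slope) < 1e-12:
        raise ValueError("degenerate standard curve (zero slope)")
    unknowns = np.asarray(unknown_cts, dtype=np.float64)
    est = np.power(10.0, (unknowns - intercept) / slope)
    return StandardCurveResult(slope=float(slope), intercept=float(intercept),
                               efficiency=float(10.0 ** (-1.0 / slope) - 1.0),
                               amounts=est)


# ---------------------------------------------------------------------------
# two-sample tests and effect size


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (statistic, df, two-sided p)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def cohens_d(x, y) -> float:
    """Cohen's d with the SD pooled by degrees of freedom."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled SD: effect size undefined")
    return float((x.mean() - y.mean()) / math.sqrt(pooled_var))


# ---------------------------------------------------------------------------
# multiple comparisons


def dunnett(groups: Mapping[str, Sequence[float]], control_label: str,
            alpha: float = 0.05, seed: int | None = None) -> pd.DataFrame:
    """Many-to-one comparisons against a control.

    Multiplicity adjustment by the multivariate-t distribution of the
    Dunnett statistics (scipy); the quantile integration is seeded for
    reproducibility.  Returns one row per non-control group with the t
    statistic, adjusted p, and significance at ``alpha``.
    """
    if control_label not in groups:
        raise ValueError(f"missing control label: {control_label!r}")
    labels = [k for k in groups if k != control_label]
    if not labels:
        raise ValueError("need at least one non-control group")
    samples = [np.asarray(groups[k], dtype=np.float64) for k in labels]
    control = np.asarray(groups[control_label], dtype=np.float64)
    if any(s.size < 2 for s in samples) or control.size < 2:
        raise ValueError("each group needs n >= 2")
    rng = np.random.default_rng(seed)
    res = sps.dunnett(*samples, control=control, random_state=rng)
    df = pd.DataFrame({
        "comparison": [f"{k} vs {control_label}" for k in labels],
        "statistic": np.asarray(res.statistic, dtype=float),
        "p_adjusted": np.asarray(res.pvalue, dtype=float),
    })
    df["significant"] = df["p_adjusted"] < alpha
    df.attrs["method"] = "Dunnett (multivariate-t adjustment, scipy)"
    return df


def _range_sf(q: float, k: int) -> float:
    """P(range of k iid standard normals >= q).

    CDF(q) = k * Integral phi(z) * [Phi(z) - Phi(z - q)]^(k-1) dz, the
    df = infinity limit of the studentized range; evaluated by fixed-grid
    quadrature (the integrand is smooth and compactly concentrated).
    """
    if q <= 0:
        return 1.0
    z = np.linspace(-8.0, 8.0 + q, 4001)
    integrand = sps.norm.pdf(z) * np.power(
        np.clip(sps.norm.cdf(z) - sps.norm.cdf(z - q), 0.0, 1.0), k - 1)
    cdf = k * np.trapezoid(integrand, z)
    return float(min(max(1.0 - cdf, 0.0), 1.0))


def steel_dwass(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Nonparametric all-pairs comparison (Steel-Dwass).

    For each pair of groups, the Wilcoxon rank-sum statistic is computed
    on the two groups' pooled midranks with tie-corrected variance; the
    standardised statistic is referred to the studentized-range
    distribution with k groups (df = infinity):
    ``p = P(Q_k >= sqrt(2) * |z|)``.  Heavy ties proceed with midranks.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {k: np.asarray(groups[k], dtype=np.float64) for k in labels}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("each group needs n >= 2")
    k = len(labels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[labels[i]], arrays[labels[j]]
            na, nb = a.size, b.size
            pooled = np.concatenate([a, b])
            ranks = sps.rankdata(pooled)  # midranks for ties
            n = na + nb
            w = float(ranks[:na].sum())
            expect = na * (n + 1) / 2.0
            var = na * nb / (n * (n - 1.0)) * float(
                np.sum((ranks - (n + 1) / 2.0) ** 2))
            if var == 0:
                z = 0.0
            else:
                z = (w - expect) / math.sqrt(var)
            p = _range_sf(math.sqrt(2.0) * abs(z), k)
            rows.append({"group_a": labels[i], "group_b": labels[j],
                         "statistic": z, "p_adjusted": p})
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic",
                                     "p_adjusted"])
    df.attrs["method"] = "Steel-Dwass (pairwise midrank Wilcoxon, studentized-range adjustment)"
    return df


# ---------------------------------------------------------------------------
# regression with CI band


@dataclass
class LinearFitResult:
    slope: float
    intercept: float
    level: float
    _model: object

    def predict(self, x_new) -> np.ndarray:
        x_new = np.asarray(x_new, dtype=np.float64)
        return self.intercept + self.slope * x_new

    def confidence_band(self, x_new) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise CI for the mean response at each x (t distribution)."""
        import statsmodels.api as sm

        x_new = np.asarray(x_new, dtype=np.float64)
        exog = sm.add_constant(x_new, has_constant="add")
        pred = self._model.get_prediction(exog)
        ci = pred.conf_int(alpha=1.0 - self.level)
        return ci[:, 0], ci[:, 1]


def linear_fit_ci(x, y, level: float = 0.95) -> LinearFitResult:
    """OLS fit with pointwise confidence band for the regression mean.

    This is the scatter-plot-with-translucent-band summary used for
    per-cell object counts (e.g. MVEs vs co-localized objects).
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("constant x: regression undefined")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return LinearFitResult(slope=float(model.params[1]),
                           intercept=float(model.params[0]),
                           level=level, _model=model)
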