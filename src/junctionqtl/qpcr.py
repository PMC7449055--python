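"""Mini-gene qPCR analysis by the standard-curve method.

Each assay's serial-dilution wells define a standard curve (Cq regressed on
log10 concentration); experimental Cq values are converted to relative
quantities from that curve, averaged over replicate wells, and normalised to
the geometric mean of the sample's reference assays (endogenous control and
transfection control).  Per-sample splicing ratios (spliced : unspliced
quantity per junction) are contrasted between plasmid alleles with a
two-sample t-test and a Bonferroni-adjusted significance flag.

Input plate tables are long-format CSV with columns: sample_id, allele,
assay_id, assay_role {spliced, unspliced, reference}, junction, well, cq,
dilution (set only for standard-curve wells).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StandardCurve:
    """Fitted dilution curve of one assay: ``cq = intercept + slope x log10(q)``.

    ``efficiency`` is the per-cycle amplification gain, ``10**(-1/slope) - 1``
    (1.0 = perfect doubling ... wait, 100% efficiency doubles per cycle and
    gives slope -1/log10(2) = -3.32).  Valid assays have negative slopes and
    efficiency roughly in (0.7, 1.2); anything else is flagged.
    """

    assay_id: str
    slope: float
    intercept: float
    r_squared: float
    n_dilutions: int

    @property
    def efficiency(self) -> float:
        if self.slope >= 0:
            return math.nan
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def valid(self) -> bool:
        return self.slope < 0 and 0.7 < self.efficiency < 1.2

    def quantity(self, cq) -> np.ndarray:
        """Relative concentration(s) back-calculated from Cq."""
        return 10.0 ** ((np.asarray(cq, dtype=float) - self.intercept) / self.slope)


def fit_standard_curve(curve_wells: pd.DataFrame, assay_id: str | None = None) -> StandardCurve:
    """Least-squares standard curve from dilution wells of one assay.

    ``curve_wells`` needs columns ``cq`` and ``dilution`` (> 0); at least 3
    distinct dilutions are required.  A non-negative slope is flagged
    invalid (logged), not raised.
    """
    wells = curve_wells.dropna(subset=["cq", "dilution"])
    dilutions = wells["dilution"].astype(float)
    if (dilutions <= 0).any():
        raise ValueError("dilutions must be positive")
    if dilutions.nunique() < 3:
        raise ValueError(
            f"standard curve needs >= 3 distinct dilutions, got {dilutions.nunique()}"
        )
    x = np.log10(dilutions.to_numpy())
    y = wells["cq"].to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    curve = StandardCurve(
        assay_id=assay_id or str(wells.get("assay_id", pd.Series(["?"])).iloc[0]),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n_dilutions=int(dilutions.nunique()),
    )
    if not curve.valid:
        logger.warning(
            "assay %s: standard curve flagged invalid (slope %.3f, efficiency %.3f)",
            curve.assay_id, curve.slope, curve.efficiency,
        )
    return curve


def fit_all_curves(plate: pd.DataFrame) -> dict[str, StandardCurve]:
    """Standard curves for every assay with dilution wells on the plate."""
    curves = {}
    curve_wells = plate[plate["dilution"].notna()]
    for assay_id, wells in curve_wells.groupby("assay_id"):
        curves[assay_id] = fit_standard_curve(wells, assay_id)
    return curves


def relative_expression(
    plate: pd.DataFrame,
    curves: dict[str, StandardCurve],
    reference_assays: list[str] | None = None,
) -> pd.DataFrame:
    """Per sample x assay normalised quantities from experimental wells.

    Quantities are back-calculated from each assay's curve, averaged over
    replicate wells, and divided by the geometric mean of the sample's
    reference-assay quantities.  Samples missing any reference assay are
    dropped with a log entry.  Returns a tidy frame: sample_id, allele,
    assay_id, assay_role, junction, quantity, norm_quantity.
    """
    wells = plate[plate["dilution"].isna()].copy()
    missing_curves = set(wells["assay_id"]) - set(curves)
    if missing_curves:
        raise ValueError(f"no standard curve for assays: {sorted(missing_curves)}")
    if reference_assays is None:
        reference_assays = sorted(wells.loc[wells["assay_role"] == "reference", "assay_id"].unique())
    wells["quantity"] = [
        float(curves[a].quantity(c)) for a, c in zip(wells["assay_id"], wells["cq"])
    ]
    agg = (
        wells.groupby(["sample_id", "allele", "assay_id", "assay_role", "junction"], dropna=False)[
            "quantity"
        ]
        .mean()
        .reset_index()
    )
    norm = {}
    for sample, sub in agg.groupby("sample_id"):
        refs = sub[sub["assay_id"].isin(reference_assays)]["quantity"]
        if len(refs) < len(reference_assays):
            logger.warning("sample %s dropped: missing reference assay(s)", sample)
            continue
        norm[sample] = math.exp(np.log(refs.to_numpy()).mean())
    agg = agg[agg["sample_id"].isin(norm)].copy()
    agg["norm_quantity"] = agg["quantity"] / agg["sample_id"].map(norm)
    return agg


def splicing_ratio_per_sample(expr: pd.DataFrame) -> pd.DataFrame:
    """Per sample x junction splicing ratio: spliced / unspliced quantity.

    ``expr`` is the output of :func:`relative_expression`.  Samples with
    zero unspliced quantity get a missing ratio (logged).  Returns columns
    sample_id, allele, junction, spliced, unspliced, ratio.
    """
    target = expr[expr["assay_role"].isin(["spliced", "unspliced"])]
    wide = target.pivot_table(
        index=["sample_id", "allele", "junction"],
        columns="assay_role",
        values="norm_quantity",
        aggfunc="mean",
    ).reset_index()
    ratios = []
    for _, row in wide.iterrows():
        if row.get("unspliced", 0) and row["unspliced"] > 0:
            ratios.append(row["spliced"] / row["unspliced"])
        else:
            logger.warning(
                "sample %s junction %s: zero unspliced expression, ratio missing",
                row["sample_id"], row["junction"],
            )
            ratios.append(math.nan)
    wide = wide.rename(columns={"spliced": "spliced", "unspliced": "unspliced"})
    wide["ratio"] = ratios
    return wide


def allele_contrast(
    values_a,
    values_b,
    test: str = "student",
    n_tests: int = 1,
    alpha: float = 0.05,
) -> dict:
    """Two-sided two-sample t-test between allele groups.

    ``test`` is "student" (pooled variance) or "welch".  Returns t, df, p,
    the Bonferroni-adjusted threshold ``alpha / n_tests`` and a significance
    flag at that threshold.  Requires >= 2 values per group.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("allele contrast needs >= 2 values per group")
    if test not in ("student", "welch"):
        raise ValueError(f"unknown test {test!r}")
    equal_var = test == "student"
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = a.size + b.size - 2
    else:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    if np.allclose(a.mean(), b.mean()) and float(res.statistic) == 0:
        p = 1.0
    else:
        p = float(res.pvalue)
    threshold = alpha / n_tests
    return {
        "t": float(res.statistic),
        "df": float(df),
        "p": p,
        "threshold": threshold,
        "significant": p < threshold,
    }


def summarize_plate(
    plate: pd.DataFrame,
    n_tests: int | None = None,
    test: str = "student",
    alpha: float = 0.05,
    reference_assays: list[str] | None = None,
) -> pd.DataFrame:
    """Per-junction allele comparison of splicing ratio and spliced /
    unspliced expression (three measurement blocks per junction).

    ``n_tests`` defaults to 3 measurement types x number of junctions.
    Group summaries are mean +/- SD across samples; p-values are two-sided
    t-tests between alleles.
    """
    curves = fit_all_curves(plate)
    expr = relative_expression(plate, curves, reference_assays)
    ratios = splicing_ratio_per_sample(expr)
    junctions = sorted(j for j in ratios["junction"].dropna().unique())
    if n_tests is None:
        n_tests = 3 * len(junctions)
    alleles = sorted(ratios["allele"].unique(), reverse=True)  # K before A
    rows = []
    for measure, col in [
        ("splicing_ratio", "ratio"),
        ("spliced_expression", "spliced"),
        ("unspliced_expression", "unspliced"),
    ]:
        for j in junctions:
            sub = ratios[ratios["junction"] == j]
            groups = {al: sub.loc[sub["allele"] == al, col].to_numpy() for al in alleles}
            contrast = allele_contrast(
                groups[alleles[0]], groups[alleles[1]], test=test, n_tests=n_tests, alpha=alpha
            )
            row = {"measurement": measure, "junction": j}
            for al in alleles:
                vals = groups[al][~np.isnan(groups[al])]
                row[f"mean_{al}"] = vals.mean()
                row[f"sd_{al}"] = vals.std(ddof=1)
            row.update({k: contrast[k] for k in ("t", "df", "p", "threshold", "significant")})
            rows.append(row)
    return pd.DataFrame(rows)
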