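"""Group-level statistics over per-specimen apparent moduli.

Specimens are partitioned four ways — age (threshold 50 years), BMI
(threshold 25 kg/m^2), menopausal status, and breast side — and the
apparent Young's moduli of the two linear strain regions are compared
between subgroups.  The pipeline screens normality (Shapiro–Wilk), applies
rank-based two-group tests, computes Spearman correlations between group
memberships, and adjusts p-values for multiple testing with the
Benjamini–Hochberg step-up procedure; significance is declared on adjusted
p <= 0.05.

Test routing: subgroups defined by patient-level factors (age, BMI,
menopause) are independent samples and default to the Wilcoxon rank-sum
test.  Breast side is the one factor with true within-patient pairing, and
uses the Wilcoxon signed-rank test on per-patient side means when enough
patients provide both sides.  A configuration switch can instead force
signed-rank tests on per-patient means for every factor.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "GroupPartition",
    "ComparisonRecord",
    "partition_cohort",
    "normality_p",
    "rank_test",
    "spearman",
    "bh_adjust",
    "group_report",
    "group_correlations",
    "FACTORS",
]

#: factor name -> (label if predicate true, label otherwise, predicate column)
FACTORS = ("age", "bmi", "menopause", "side")

ALPHA = 0.05


@dataclass
class GroupPartition:
    """One two-level partition of the cohort with per-specimen E values."""

    factor: str
    labels: tuple[str, str]
    members: dict[str, list[str]]  # label -> specimen ids
    values: dict[tuple[str, str], np.ndarray]  # (label, region) -> moduli

    @property
    def testable(self) -> bool:
        return all(len(v) >= 2 for v in self.members.values())


def _subgroup_of(row: pd.Series, factor: str) -> str:
    # threshold cases land on the ">=" side
    if factor == "age":
        return "age_gt50" if row["age_years"] >= 50.0 else "age_lt50"
    if factor == "bmi":
        return "bmi_gt25" if row["bmi_kg_m2"] >= 25.0 else "bmi_lt25"
    if factor == "menopause":
        return "post_m" if row["menopause"] == "post" else "pre_m"
    if factor == "side":
        return str(row["side"])
    raise ValueError(f"unknown factor {factor!r}")


def partition_cohort(metadata: pd.DataFrame, moduli: pd.DataFrame) -> list[GroupPartition]:
    """Build the four standard partitions.

    ``metadata`` columns: specimen_id, patient_id, age_years, bmi_kg_m2,
    menopause (pre|post), side (left|right).  ``moduli`` columns:
    specimen_id, E_first, E_second (N/mm^2).  Missing metadata raises an
    error naming the specimen.
    """
    need = ["specimen_id", "patient_id", "age_years", "bmi_kg_m2", "menopause", "side"]
    for col in need:
        if col not in metadata.columns:
            raise ValueError(f"metadata lacks column {col!r}")
    bad = metadata[metadata[need].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"incomplete metadata for specimen {bad['specimen_id'].iloc[0]!r}")
    df = metadata.merge(moduli, on="specimen_id", validate="one_to_one")

    labels = {
        "age": ("age_gt50", "age_lt50"),
        "bmi": ("bmi_gt25", "bmi_lt25"),
        "menopause": ("post_m", "pre_m"),
        "side": ("right", "left"),
    }
    out = []
    for factor in FACTORS:
        sub = df.apply(lambda r: _subgroup_of(r, factor), axis=1)
        members = {lab: df.loc[sub == lab, "specimen_id"].tolist() for lab in labels[factor]}
        values = {}
        for lab in labels[factor]:
            for region, col in (("first", "E_first"), ("second", "E_second")):
                values[(lab, region)] = df.loc[sub == lab, col].to_numpy(dtype=float)
        boundary = df.loc[(factor == "age") & (df["age_years"] == 50.0), "specimen_id"]
        if factor == "age" and len(boundary):
            log.info("specimens at the age threshold assigned to the older side: %s",
                     list(boundary))
        out.append(GroupPartition(factor, labels[factor], members, values))
    return out


def normality_p(values: np.ndarray) -> float:
    """Shapiro–Wilk normality p-value (requires 3 <= n <= 5000)."""
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(values) == 0.0:
        raise ValueError("constant sample: normality test undefined")
    return float(sps.shapiro(values).pvalue)


def rank_test(x, y, paired: bool = False) -> tuple[float, float]:
    """Two-sided Wilcoxon test: signed-rank (paired) or rank-sum (unpaired).

    Paired: zero differences are dropped (Wilcoxon convention); the
    statistic is the smaller signed-rank sum; exact null distribution for
    n <= 25 without ties, normal approximation with correction otherwise.
    All-zero differences are degenerate and return (0, 1).

    Unpaired: the statistic is the rank sum of ``x``; the p-value is exact
    for small tie-free samples, otherwise normal-approximated with tie
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.size != y.size or x.size < 1:
            raise ValueError("paired test needs equal-length nonempty samples")
        d = x - y
        if np.all(d == 0.0):
            return 0.0, 1.0
        res = sps.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided", method="auto")
        return float(res.statistic), float(res.pvalue)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test needs two nonempty samples")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    W = float(res.statistic) + x.size * (x.size + 1) / 2.0  # U -> rank sum of x
    return W, float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with exact permutation p for n <= 8.

    rho is the Pearson correlation of mid-ranks.  For n <= 8 the two-sided
    p-value is computed by enumerating all permutations of one sample
    (counting |rho_perm| >= |rho|); beyond that the usual t-approximation
    applies.  Constant input raises (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("constant input: correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= 8:
        perms = np.array(list(itertools.permutations(range(n))))
        ryp = ry[perms]  # (n!, n)
        rxc = rx - rx.mean()
        ryc = ryp - ryp.mean(axis=1, keepdims=True)
        rhos = (ryc @ rxc) / np.sqrt((rxc**2).sum() * (ryc**2).sum(axis=1))
        p = float(np.mean(np.abs(rhos) >= np.abs(rho) - 1e-12))
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return rho, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ComparisonRecord:
    """One subgroup comparison (factor x linear region)."""

    factor: str
    region: str
    labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    stds: tuple[float, float]
    test: str  # "rank-sum" | "signed-rank" | "untestable"
    statistic: float | None
    p_raw: float | None
    p_adjusted: float | None = None
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p_adjusted is not None and self.p_adjusted <= ALPHA


def group_report(
    metadata: pd.DataFrame,
    moduli: pd.DataFrame,
    force_signed_rank: bool = False,
) -> list[ComparisonRecord]:
    """Full comparison table: 4 factors x 2 regions, BH-adjusted jointly.

    ``force_signed_rank=True`` replaces every unpaired comparison by a
    signed-rank test on per-patient mean moduli, truncating the subgroups
    to equal size (a statistically irregular but historically used routing;
    the default routes independent factors through the rank-sum test).
    """
    parts = partition_cohort(metadata, moduli)
    df = metadata.merge(moduli, on="specimen_id", validate="one_to_one")
    records: list[ComparisonRecord] = []
    for part in parts:
        la, lb = part.labels
        for region in ("first", "second"):
            va = part.values[(la, region)]
            vb = part.values[(lb, region)]
            rec = ComparisonRecord(
                part.factor,
                region,
                part.labels,
                (va.size, vb.size),
                (float(va.mean()) if va.size else np.nan,
                 float(vb.mean()) if vb.size else np.nan),
                (float(va.std(ddof=1)) if va.size > 1 else 0.0,
                 float(vb.std(ddof=1)) if vb.size > 1 else 0.0),
                "untestable",
                None,
                None,
            )
            if va.size < 2 or vb.size < 2:
                rec.note = "subgroup with fewer than 2 specimens"
                records.append(rec)
                continue
            try:
                if part.factor == "side":
                    stat, p, n_pairs = _paired_side_test(df, region)
                    if n_pairs >= 2:
                        rec.test, rec.statistic, rec.p_raw = "signed-rank", stat, p
                        rec.note = f"{n_pairs} patient pairs"
                    else:
                        stat, p = rank_test(va, vb, paired=False)
                        rec.test, rec.statistic, rec.p_raw = "rank-sum", stat, p
                        rec.note = "too few both-side patients; unpaired fallback"
                elif force_signed_rank:
                    stat, p = _forced_signed_rank(df, part.factor, region)
                    rec.test, rec.statistic, rec.p_raw = "signed-rank", stat, p
                    rec.note = "per-patient means, truncated pairing"
                else:
                    stat, p = rank_test(va, vb, paired=False)
                    rec.test, rec.statistic, rec.p_raw = "rank-sum", stat, p
            except ValueError as exc:
                rec.note = str(exc)
            records.append(rec)

    tested = [r for r in records if r.p_raw is not None]
    if tested:
        adj = bh_adjust([r.p_raw for r in tested])
        for r, q in zip(tested, adj):
            r.p_adjusted = float(q)
    return records


def _paired_side_test(df: pd.DataFrame, region: str) -> tuple[float, float, int]:
    col = "E_first" if region == "first" else "E_second"
    per = df.groupby(["patient_id", "side"])[col].mean().unstack()
    if "right" not in per.columns or "left" not in per.columns:
        return 0.0, 1.0, 0
    both = per.dropna(subset=["right", "left"])
    n = len(both)
    if n < 2:
        return 0.0, 1.0, n
    stat, p = rank_test(both["right"].to_numpy(), both["left"].to_numpy(), paired=True)
    return stat, p, n


def _forced_signed_rank(df: pd.DataFrame, factor: str, region: str) -> tuple[float, float]:
    col = "E_first" if region == "first" else "E_second"
    sub = df.apply(lambda r: _subgroup_of(r, factor), axis=1)
    means = df.assign(sub=sub).groupby(["patient_id", "sub"])[col].mean()
    groups = [g.sort_index().to_numpy() for _, g in means.groupby(level="sub")]
    if len(groups) != 2:
        raise ValueError("factor does not split the cohort in two")
    m = min(len(g) for g in groups)
    if m < 2:
        raise ValueError("fewer than 2 patients per subgroup")
    return rank_test(groups[0][:m], groups[1][:m], paired=True)


def group_correlations(metadata: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlations between subgroup-membership indicators.

    Returns a tidy frame (factor_a, factor_b, rho, p_raw, p_adjusted); a
    correlation of 1.0 flags two factors whose subgroups contain exactly
    the same specimens.
    """
    ind = {}
    for factor in FACTORS:
        first_label = {"age": "age_gt50", "bmi": "bmi_gt25",
                       "menopause": "post_m", "side": "right"}[factor]
        ind[factor] = metadata.apply(
            lambda r: 1.0 if _subgroup_of(r, factor) == first_label else 0.0, axis=1
        ).to_numpy()
    rows = []
    for fa, fb in itertools.combinations(FACTORS, 2):
        try:
            rho, p = spearman(ind[fa], ind[fb]) if len(metadata) <= 8 else (
                float(sps.spearmanr(ind[fa], ind[fb]).correlation),
                float(sps.spearmanr(ind[fa], ind[fb]).pvalue),
            )
        except ValueError:
            rho, p = np.nan, np.nan
        rows.append({"factor_a": fa, "factor_b": fb, "rho": rho, "p_raw": p})
    out = pd.DataFrame(rows)
    ok = out["p_raw"].notna()
    out["p_adjusted"] = np.nan
    if ok.any():
        out.loc[ok, "p_adjusted"] = bh_adjust(out.loc[ok, "p_raw"].to_numpy())
    return out
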