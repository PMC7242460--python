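"""Cohort descriptive statistics: per-subgroup means +/- SD and Dunnett ANOVA.

Includes the study cohort itself — 9 control endometrium donors (atrophic,
secretory-phase and proliferative-phase, 3 each), 9 type 1 endometrial
carcinoma patients (endometrioid grades 1-3, 3 each) and 6 type 2 patients
(serous and carcinosarcoma, 3 each) with their published ages and BMIs — so
the descriptive table can be reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

AGE_RANGE = (18.0, 110.0)
BMI_RANGE = (10.0, 80.0)

# (subgroup, group, [(age, bmi) x 3])
_STUDY_ROWS = [
    ("atrophic", "control", [(65, 34), (65, 22), (57, 24)]),
    ("secretory", "control", [(44, 25), (51, 27), (43, 26)]),
    ("proliferative", "control", [(47, 27), (48, 27), (47, 24)]),
    ("grade1", "EC1", [(63, 33), (88, 24), (83, 37)]),
    ("grade2", "EC1", [(78, 29), (69, 32), (56, 31)]),
    ("grade3", "EC1", [(74, 42), (60, 30), (84, 34)]),
    ("serous", "EC2", [(61, 40), (55, 35), (61, 38)]),
    ("carcinosarcoma", "EC2", [(50, 34), (45, 44), (55, 32)]),
]


def study_cohort() -> pd.DataFrame:
    """The published patient characteristics as a tidy record table."""
    rows = []
    for subgroup, group, patients in _STUDY_ROWS:
        for i, (age, bmi) in enumerate(patients, start=1):
            rows.append(
                {
                    "sample_id": f"{subgroup}_{i}",
                    "group": group,
                    "subgroup": subgroup,
                    "age": float(age),
                    "bmi": float(bmi),
                }
            )
    return pd.DataFrame(rows)


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    records = pd.DataFrame(records)
    if records.empty:
        raise ValueError("cohort record table is empty")
    for col, (lo, hi) in (("age", AGE_RANGE), ("bmi", BMI_RANGE)):
        if col in records.columns:
            vals = records[col].dropna()
            bad = vals[(vals <= lo) | (vals >= hi)]
            if len(bad):
                raise ValueError(f"{col} values outside ({lo}, {hi}): {sorted(bad)}")
    return records


@dataclass
class GroupSummary:
    """Mean +/- SD of one variable in one labelled group of patients."""

    label: str
    n: int
    mean: float
    sd: float
    degenerate: bool = False  # single-member group: SD reported as 0 with this flag

    def display(self, decimals: int = 2) -> str:
        return f"{self.mean:.{decimals}f} ± {self.sd:.{decimals}f} (n={self.n})"


def group_summary(
    records: pd.DataFrame,
    by: str = "subgroup",
    variable: str = "age",
) -> list[GroupSummary]:
    """Per-label arithmetic mean and sample SD (n-1) of ``variable``.

    Values are kept at full precision; use :meth:`GroupSummary.display` for
    the conventional 2-decimal presentation.
    """
    records = validate_records(records)
    if variable not in records.columns:
        raise ValueError(f"unknown variable {variable!r}")
    if by not in records.columns:
        raise ValueError(f"unknown grouping column {by!r}")
    out = []
    for label, chunk in records.groupby(by, sort=False):
        vals = chunk[variable].to_numpy(dtype=float)
        degenerate = len(vals) == 1
        out.append(
            GroupSummary(
                label=str(label),
                n=len(vals),
                mean=float(vals.mean()),
                sd=0.0 if degenerate else float(vals.std(ddof=1)),
                degenerate=degenerate,
            )
        )
    return out


def pooled_summary(records: pd.DataFrame, label_value: str, by: str = "group",
                   variable: str = "age") -> GroupSummary:
    """Summary of all records whose ``by`` column equals ``label_value``."""
    subset = pd.DataFrame(records)[lambda df: df[by] == label_value]
    if subset.empty:
        raise ValueError(f"no records with {by} == {label_value!r}")
    return group_summary(subset, by=by, variable=variable)[0]


@dataclass
class DunnettResult:
    """One-way ANOVA with Dunnett many-to-one comparisons against a reference."""

    f_statistic: float
    df_between: int
    df_within: int
    reference: str
    p_values: dict[str, float]
    degenerate: bool = False  # zero pooled within-group variance


def dunnett_anova(
    records: pd.DataFrame,
    variable: str,
    reference: str,
    comparisons: list[str] | None = None,
    by: str = "subgroup",
) -> DunnettResult:
    """One-way ANOVA F plus Dunnett two-sided adjusted p-values vs a reference.

    The Dunnett adjustment uses the multivariate-t distribution with the
    pooled within-group variance over the included groups (reference +
    comparisons).  Every included group needs n >= 2.
    """
    records = validate_records(records)
    if variable not in records.columns:
        raise ValueError(f"unknown variable {variable!r}")
    labels = list(records[by].unique())
    if reference not in labels:
        raise ValueError(f"reference group {reference!r} not found")
    if comparisons is None:
        comparisons = [l for l in labels if l != reference]
    unknown = [l for l in comparisons if l not in labels]
    if unknown:
        raise ValueError(f"comparison group(s) not found: {unknown}")

    def values(label):
        return records.loc[records[by] == label, variable].to_numpy(dtype=float)

    ref_vals = values(reference)
    comp_vals = [values(l) for l in comparisons]
    for label, vals in zip([reference, *comparisons], [ref_vals, *comp_vals]):
        if len(vals) < 2:
            raise ValueError(f"group {label!r} has n < 2")

    all_groups = [ref_vals, *comp_vals]
    df_between = len(all_groups) - 1
    df_within = sum(len(v) for v in all_groups) - len(all_groups)
    pooled_ss = sum(((v - v.mean()) ** 2).sum() for v in all_groups)
    if pooled_ss == 0.0:
        return DunnettResult(
            f_statistic=float("nan"),
            df_between=df_between,
            df_within=df_within,
            reference=reference,
            p_values={l: float("nan") for l in comparisons},
            degenerate=True,
        )
    f_stat = float(stats.f_oneway(*all_groups).statistic)
    # fixed QMC seed: the multivariate-t quadrature is otherwise randomised
    dunnett = stats.dunnett(
        *comp_vals, control=ref_vals, alternative="two-sided", rng=np.random.default_rng(0)
    )
    p_values = {l: float(p) for l, p in zip(comparisons, dunnett.pvalue)}
    return DunnettResult(
        f_statistic=f_stat,
        df_between=df_between,
        df_within=df_within,
        reference=reference,
        p_values=p_values,
    )


def cohort_table(records: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table: subgroup and pooled-group mean +/- SD for age and BMI."""
    records = validate_records(records)
    rows = []
    for variable in ("age", "bmi"):
        for summary in group_summary(records, by="subgroup", variable=variable):
            grp = records.loc[records["subgroup"] == summary.label, "group"].iloc[0]
            rows.append(
                {
                    "variable": variable,
                    "level": "subgroup",
                    "label": summary.label,
                    "group": grp,
                    "n": summary.n,
                    "mean": summary.mean,
                    "sd": summary.sd,
                }
            )
        for summary in group_summary(records, by="group", variable=variable):
            rows.append(
                {
                    "variable": variable,
                    "level": "group",
                    "label": summary.label,
                    "group": summary.label,
                    "n": summary.n,
                    "mean": summary.mean,
                    "sd": summary.sd,
                }
            )
    return pd.DataFrame(rows)
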