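"""Allele-level HLA expression: normalization and group comparisons.

Read counts are divided by allele length and rescaled per sample so the
abundances sum to one million; each non-reference allele is compared to the
reference (DQB1*06:02 by default) with a Wilcoxon rank-sum test, and
sample-level aggregates (non-reference sum, or a DQB1 sublineage sum) are
compared case vs control with a t-test.

Unit of analysis: group tests aggregate to one value per sample before
testing, to avoid pseudo-replication from samples carrying two alleles of
the selected class.  This choice is recorded in output metadata.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .io_formats import SampleInfo

REFERENCE_ALLELE = "DQB1*06:02"

SUBLINEAGE_03_04 = "dqb1_03_04"
SUBLINEAGE_05_06 = "dqb1_05_06"
SELECTOR_NON_REFERENCE = "non_reference"
SELECTORS = (SELECTOR_NON_REFERENCE, SUBLINEAGE_03_04, SUBLINEAGE_05_06)

PER_MILLION = 1_000_000.0


@dataclass(frozen=True)
class AlleleCount:
    """Raw per-sample per-allele RNA read count with the allele's length."""

    sample_id: str
    gene: str
    allele: str
    read_count: float
    allele_length: int

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError(f"read_count must be >= 0, got {self.read_count}")
        if self.allele_length <= 0:
            raise ValueError(f"allele_length must be > 0, got {self.allele_length}")


@dataclass(frozen=True)
class AlleleAbundance:
    """Length-normalized, per-million-scaled abundance for one (sample, allele)."""

    sample_id: str
    gene: str
    allele: str
    abundance: float


def counts_to_frame(counts: Iterable[AlleleCount] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(counts, pd.DataFrame):
        return counts.copy()
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "gene": c.gene,
                "allele": c.allele,
                "read_count": c.read_count,
                "allele_length": c.allele_length,
            }
            for c in counts
        ]
    )


def allele_gene(allele: str) -> str:
    """The gene label encoded in an allele name, e.g. ``DQB1*06:02`` -> ``DQB1``."""
    return allele.partition("*")[0]


def sublineage_of(allele: str) -> str | None:
    """Map a DQB1 allele name to its sublineage group.

    Returns ``dqb1_03_04`` for *03/*04 alleles, ``dqb1_05_06`` for *05/*06,
    ``"other"`` for any other DQB1 allele, and None for non-DQB1 alleles —
    so every DQB1 allele maps to exactly one group.
    """
    gene, star, rest = allele.partition("*")
    if gene != "DQB1" or not star:
        return None
    prefix = rest.split(":")[0]
    if prefix in ("03", "04"):
        return SUBLINEAGE_03_04
    if prefix in ("05", "06"):
        return SUBLINEAGE_05_06
    return "other"


def normalize_abundance(
    counts: Iterable[AlleleCount] | pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Convert read counts into per-million, length-normalized abundances.

    Per sample: ``rate_i = count_i / length_i`` and
    ``abundance_i = 1e6 * rate_i / sum_j rate_j``, so each sample's
    abundances sum to one million.  Samples whose counts are all zero are
    flagged and excluded (their abundances would be undefined).
    """
    df = counts_to_frame(counts)
    if df.empty:
        raise DataError("no allele counts supplied")
    df = df.sort_values(["sample_id", "gene", "allele"], kind="mergesort").reset_index(
        drop=True
    )
    df["rate"] = df["read_count"] / df["allele_length"]
    totals = df.groupby("sample_id")["rate"].transform("sum")
    zero_samples = sorted(df.loc[totals == 0, "sample_id"].unique())
    kept = df[totals > 0].copy()
    kept["abundance"] = PER_MILLION * kept["rate"] / totals[totals > 0]
    return (
        kept[["sample_id", "gene", "allele", "abundance"]].reset_index(drop=True),
        zero_samples,
    )


def per_allele_vs_reference(
    abundances: pd.DataFrame,
    reference_allele: str = REFERENCE_ALLELE,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Compare each same-gene allele to the reference by Wilcoxon rank-sum.

    Observations are pooled across the samples carrying each allele.  Ties
    are handled by the normal approximation with tie correction and no
    continuity correction (so identical distributions give P = 1); an exact
    test is used for small samples without ties (scipy's ``method="auto"``).
    Alleles observed in fewer than ``min_samples`` samples are flagged
    untested.
    """
    gene = allele_gene(reference_allele)
    sub = abundances[abundances["gene"] == gene]
    ref = sub.loc[sub["allele"] == reference_allele, "abundance"].to_numpy()
    if ref.size < 2:
        raise DataError(
            f"reference allele {reference_allele!r} observed in {ref.size} "
            f"sample(s); need >= 2"
        )
    rows = []
    for allele, grp in sub[sub["allele"] != reference_allele].groupby("allele"):
        vals = grp["abundance"].to_numpy()
        row = {
            "allele": allele,
            "n_samples": int(vals.size),
            "n_reference": int(ref.size),
            "mean_abundance": float(vals.mean()),
            "mean_reference": float(ref.mean()),
        }
        if vals.size < min_samples:
            row.update(p_value=np.nan, tested=False)
        else:
            res = stats.mannwhitneyu(
                vals, ref, alternative="two-sided", method="auto",
                use_continuity=False,
            )
            row.update(p_value=float(res.pvalue), tested=True)
        rows.append(row)
    columns = [
        "allele", "n_samples", "n_reference", "mean_abundance",
        "mean_reference", "p_value", "tested",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    return (
        pd.DataFrame(rows)[columns]
        .sort_values("allele", kind="mergesort")
        .reset_index(drop=True)
    )


@dataclass
class GroupedComparison:
    """Case-vs-control t-test of a per-sample abundance aggregate."""

    selector: str
    n_case: int
    n_control: int
    mean_case: float
    mean_control: float
    difference: float  # case - control
    p_value: float


def grouped_comparison(
    abundances: pd.DataFrame,
    samples: Sequence[SampleInfo],
    selector: str,
    reference_allele: str = REFERENCE_ALLELE,
    equal_var: bool = True,
) -> GroupedComparison:
    """Aggregate selected alleles per sample, then t-test case vs control.

    ``selector`` is one of ``non_reference`` (all same-gene alleles other
    than the reference), ``dqb1_03_04`` or ``dqb1_05_06`` (sublineage sums,
    reference always excluded).  Samples carrying no selected allele are
    excluded; an empty group is an error naming the selector.
    """
    if selector not in SELECTORS:
        raise DataError(f"unknown selector {selector!r}; expected one of {SELECTORS}")
    gene = allele_gene(reference_allele)
    sub = abundances[
        (abundances["gene"] == gene) & (abundances["allele"] != reference_allele)
    ]
    if selector != SELECTOR_NON_REFERENCE:
        sub = sub[sub["allele"].map(sublineage_of) == selector]
    per_sample = sub.groupby("sample_id")["abundance"].sum()

    by_id = {s.sample_id: s for s in samples}
    unknown = [sid for sid in per_sample.index if sid not in by_id]
    if unknown:
        raise DataError(f"sample sheet does not cover sample {unknown[0]!r}")
    case_vals = np.array(
        [v for sid, v in per_sample.items() if by_id[sid].group == "case"]
    )
    ctrl_vals = np.array(
        [v for sid, v in per_sample.items() if by_id[sid].group == "control"]
    )
    if case_vals.size == 0 or ctrl_vals.size == 0:
        raise DataError(
            f"selector {selector!r}: empty {'case' if case_vals.size == 0 else 'control'} "
            f"group after selection"
        )
    res = stats.ttest_ind(case_vals, ctrl_vals, equal_var=equal_var)
    return GroupedComparison(
        selector=selector,
        n_case=int(case_vals.size),
        n_control=int(ctrl_vals.size),
        mean_case=float(case_vals.mean()),
        mean_control=float(ctrl_vals.mean()),
        difference=float(case_vals.mean() - ctrl_vals.mean()),
        p_value=float(res.pvalue),
    )


def grouped_comparisons_frame(
    abundances: pd.DataFrame,
    samples: Sequence[SampleInfo],
    reference_allele: str = REFERENCE_ALLELE,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Run every selector that yields two non-empty groups; tabulate results."""
    rows = []
    for selector in SELECTORS:
        try:
            g = grouped_comparison(
                abundances, samples, selector, reference_allele, equal_var
            )
        except DataError:
            continue
        rows.append(
            {
                "selector": g.selector,
                "n_case": g.n_case,
                "n_control": g.n_control,
                "mean_case": g.mean_case,
                "mean_control": g.mean_control,
                "difference": g.difference,
                "p_value": g.p_value,
            }
        )
    return pd.DataFrame(rows)
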