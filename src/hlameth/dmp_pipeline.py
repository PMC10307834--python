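"""Region-restricted case-control DMP association on beta-value matrices.

Fixed pipeline order: detection-P filter -> blocklist -> region subset ->
tests.  Tests run on the beta scale: a two-sample t-test per probe, and an
ordinary-least-squares regression of beta on case status with the
DQB1*06:02 carrier flag (and optional extra covariates) adjusted for.
Family-wise significance uses Bonferroni with ``n_tests`` recomputed from
the number of probes actually tested, never hard-coded.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .io_formats import BetaMatrix, ProbeRecord, RegionDefinition, SampleInfo
from .probe_reliability import ProbeAudit

log = logging.getLogger(__name__)

_VAR_TINY = 1e-24  # below this a within-group variance counts as zero


@dataclass
class AssociationConfig:
    """Knobs for one association run."""

    alpha_family: float = 0.05
    region: RegionDefinition | None = None
    detection_p_cut: float = 0.01
    detection_sample_frac: float = 0.10
    covariates: tuple[str, ...] = ("dqb1_0602_carrier",)
    equal_var: bool = True  # Student by default; Welch via flag

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_family < 1.0:
            raise ValueError(f"alpha_family must be in (0,1), got {self.alpha_family}")


# ---------------------------------------------------------------------------
# Filtering stages
# ---------------------------------------------------------------------------

def filter_detection_p(
    betas: BetaMatrix,
    detp: BetaMatrix,
    cut: float = 0.01,
    frac: float = 0.10,
) -> tuple[BetaMatrix, list[str]]:
    """Drop probes whose detection P is >= ``cut`` in more than ``frac`` of samples.

    "More than" is strict: with 10 samples, exactly one failure (10%) keeps
    the probe, two failures (20%) drop it.  Missing detection-P cells count
    as failures.
    """
    if betas.probe_ids != detp.probe_ids or betas.sample_ids != detp.sample_ids:
        raise DataError("beta and detection-P matrices must share both axes")
    d = detp.data.to_numpy()
    failed = np.isnan(d) | (d >= cut)
    fail_frac = failed.mean(axis=1)
    dropped = [p for p, f in zip(betas.probe_ids, fail_frac) if f > frac]
    log.info("detection-P filter: dropped %d of %d probes", len(dropped), len(fail_frac))
    return betas.drop_probes(dropped), dropped


def apply_blocklist(
    betas: BetaMatrix, blocklist: Iterable[str]
) -> tuple[BetaMatrix, int]:
    """Remove blocklisted probes; ids absent from the matrix are a no-op."""
    block = set(blocklist)
    present = block & set(betas.probe_ids)
    absent = block - present
    if absent:
        log.warning("blocklist: %d id(s) not present in the matrix", len(absent))
    log.info("blocklist: removed %d probes", len(present))
    return betas.drop_probes(present), len(present)


def subset_region(
    betas: BetaMatrix,
    manifest: Sequence[ProbeRecord] | Mapping[str, ProbeRecord],
    region: RegionDefinition,
) -> BetaMatrix:
    """Keep probes whose binding position lies inside ``region`` (inclusive)."""
    if not isinstance(manifest, Mapping):
        manifest = {p.probe_id: p for p in manifest}
    missing = [p for p in betas.probe_ids if p not in manifest]
    if missing:
        raise DataError(
            f"manifest does not cover {len(missing)} matrix probe(s), "
            f"e.g. {missing[0]!r}"
        )
    keep = [
        pid
        for pid in betas.probe_ids
        if region.contains(manifest[pid].chromosome, manifest[pid].binding_pos)
    ]
    log.info("region %s: kept %d of %d probes", region.name, len(keep), len(betas.probe_ids))
    return betas.select_probes(keep)


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def _split_groups(
    betas: BetaMatrix, samples: Sequence[SampleInfo]
) -> tuple[list[str], list[str]]:
    by_id = {s.sample_id: s for s in samples}
    missing = [sid for sid in betas.sample_ids if sid not in by_id]
    if missing:
        raise DataError(f"sample sheet does not cover matrix sample {missing[0]!r}")
    case_ids = [sid for sid in betas.sample_ids if by_id[sid].group == "case"]
    ctrl_ids = [sid for sid in betas.sample_ids if by_id[sid].group == "control"]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise DataError(
            f"need >= 2 samples per group, got {len(case_ids)} case / "
            f"{len(ctrl_ids)} control"
        )
    return case_ids, ctrl_ids


def dmp_ttest(
    betas: BetaMatrix,
    samples: Sequence[SampleInfo],
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-probe two-sample t-test, case vs control, on the beta scale.

    Missing values are excluded pairwise per probe.  Probes with fewer than
    two non-missing values in either group, or with zero variance in both,
    get a missing P and a non-"ok" flag rather than propagating NaN silently.
    Difference is always case mean minus control mean (negative =
    hypomethylated in cases).
    """
    case_ids, ctrl_ids = _split_groups(betas, samples)
    case = betas.data[case_ids].to_numpy(float)
    ctrl = betas.data[ctrl_ids].to_numpy(float)
    n_case = (~np.isnan(case)).sum(axis=1)
    n_ctrl = (~np.isnan(ctrl)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_case = np.nanmean(case, axis=1)
        mean_ctrl = np.nanmean(ctrl, axis=1)
        var_case = np.nanvar(case, axis=1, ddof=1)
        var_ctrl = np.nanvar(ctrl, axis=1, ddof=1)
        res = stats.ttest_ind(
            case, ctrl, axis=1, equal_var=equal_var, nan_policy="omit"
        )
    p = np.asarray(res.pvalue, float)
    t = np.asarray(res.statistic, float)

    insufficient = (n_case < 2) | (n_ctrl < 2)
    zero_var = ~insufficient & (var_case < _VAR_TINY) & (var_ctrl < _VAR_TINY)
    flags = np.where(insufficient, "insufficient", np.where(zero_var, "zero_variance", "ok"))
    p = np.where(flags == "ok", p, np.nan)
    t = np.where(flags == "ok", t, np.nan)

    return pd.DataFrame(
        {
            "n_control": n_ctrl,
            "n_case": n_case,
            "mean_beta_control": mean_ctrl,
            "mean_beta_case": mean_case,
            "difference": mean_case - mean_ctrl,
            "t_statistic": t,
            "p_ttest": p,
            "ttest_flag": flags,
        },
        index=pd.Index(betas.probe_ids, name="probe_id"),
    )


def _design_matrix(
    sample_ids: Sequence[str],
    samples: Sequence[SampleInfo],
    covariates: Sequence[str],
) -> np.ndarray:
    by_id = {s.sample_id: s for s in samples}
    cols = [np.ones(len(sample_ids))]
    cols.append(
        np.array([1.0 if by_id[sid].group == "case" else 0.0 for sid in sample_ids])
    )
    for cov in covariates:
        vals = []
        for sid in sample_ids:
            v = getattr(by_id[sid], cov, None)
            if v is None:
                raise DataError(f"covariate {cov!r} missing for sample {sid!r}")
            vals.append(float(v))
        cols.append(np.array(vals))
    return np.column_stack(cols)


def _ols_block(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS of each row of Y on the shared design matrix X.

    Returns (coefficients, standard errors, two-sided P) with shape
    (n_rows, n_params).  Rows with (near-)zero residual variance get NaN P.
    """
    n, k = X.shape
    dof = n - k
    xtx_inv = np.linalg.inv(X.T @ X)
    hat = xtx_inv @ X.T  # k x n
    coefs = Y @ hat.T  # rows x k
    resid = Y - coefs @ X.T
    ss_res = (resid**2).sum(axis=1)
    sigma2 = ss_res / dof
    se = np.sqrt(np.maximum(sigma2, 0.0)[:, None] * np.diag(xtx_inv)[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = coefs / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    degenerate = sigma2 < _VAR_TINY
    pvals[degenerate, :] = np.nan
    return coefs, se, pvals


def dmp_regression(
    betas: BetaMatrix,
    samples: Sequence[SampleInfo],
    covariates: Sequence[str] = ("dqb1_0602_carrier",),
) -> pd.DataFrame:
    """Per-probe OLS of beta on case status adjusting for the given covariates.

    Columns: ``coef_regression`` (case-status effect on the beta scale), its
    ``p_regression``, ``p_covariate`` (first covariate, the carrier term),
    and ``regression_flag``.  A rank-deficient design (e.g. carrier status
    collinear with case status) flags every probe ``collinear`` instead of
    crashing; probes with missing cells are refit on their complete samples.
    """
    sample_ids = betas.sample_ids
    X = _design_matrix(sample_ids, samples, covariates)
    k = X.shape[1]
    n_probes = betas.shape[0]
    coef = np.full(n_probes, np.nan)
    p_case = np.full(n_probes, np.nan)
    p_cov = np.full(n_probes, np.nan)
    flags = np.full(n_probes, "ok", dtype=object)

    if np.linalg.matrix_rank(X) < k:
        flags[:] = "collinear"
        return _regression_frame(betas, coef, p_case, p_cov, flags)

    Y = betas.data.to_numpy(float)
    complete = ~np.isnan(Y).any(axis=1)
    if complete.any():
        coefs, _, pvals = _ols_block(Y[complete], X)
        coef[complete] = coefs[:, 1]
        p_case[complete] = pvals[:, 1]
        if covariates:
            p_cov[complete] = pvals[:, 2]
        flags[complete] = np.where(np.isnan(pvals[:, 1]), "zero_residual", "ok")

    for i in np.flatnonzero(~complete):
        mask = ~np.isnan(Y[i])
        Xi = X[mask]
        if Xi.shape[0] <= k or np.linalg.matrix_rank(Xi) < k:
            flags[i] = "insufficient"
            continue
        coefs, _, pvals = _ols_block(Y[i : i + 1, mask], Xi)
        coef[i] = coefs[0, 1]
        p_case[i] = pvals[0, 1]
        if covariates:
            p_cov[i] = pvals[0, 2]
        flags[i] = "zero_residual" if np.isnan(pvals[0, 1]) else "ok"

    return _regression_frame(betas, coef, p_case, p_cov, flags)


def _regression_frame(betas, coef, p_case, p_cov, flags) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "coef_regression": coef,
            "p_regression": p_case,
            "p_covariate": p_cov,
            "regression_flag": flags,
        },
        index=pd.Index(betas.probe_ids, name="probe_id"),
    )


def bonferroni(
    p_values: Sequence[float] | np.ndarray | pd.Series,
    alpha_family: float = 0.05,
    n_tests: int | None = None,
) -> tuple[np.ndarray, float]:
    """Family-wise significance flags under Bonferroni correction.

    ``threshold = alpha_family / n_tests``; a P value is significant iff it
    is strictly below the threshold.  ``n_tests`` defaults to the number of
    P values supplied (missing ones included — they were still tests).
    """
    p = np.asarray(p_values, float)
    if n_tests is None:
        n_tests = p.size
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    threshold = alpha_family / n_tests
    with np.errstate(invalid="ignore"):
        flags = p < threshold
    flags = np.where(np.isnan(p), False, flags)
    return flags, threshold


@dataclass
class CellTypeOverlap:
    """Overlap of nominally significant probes between two analyses."""

    n_significant_a: int
    n_significant_b: int
    n_common: int
    hypo_fraction_a: float
    hypo_fraction_b: float

    @property
    def hyper_fraction_a(self) -> float:
        return 1.0 - self.hypo_fraction_a if self.n_significant_a else float("nan")

    @property
    def hyper_fraction_b(self) -> float:
        return 1.0 - self.hypo_fraction_b if self.n_significant_b else float("nan")


def compare_cell_types(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    p_cut: float = 0.05,
    p_column: str = "p_ttest",
) -> CellTypeOverlap:
    """Count nominally significant probes per analysis and their intersection.

    Both result tables must cover the same probe universe.  The hypo
    fraction is the share of significant probes with a negative case-minus-
    control difference.
    """
    if set(results_a.index) != set(results_b.index):
        raise DataError("cell-type comparison requires the same probe universe")

    def _sig(df: pd.DataFrame) -> pd.Index:
        p = df[p_column]
        return df.index[(p < p_cut).fillna(False)]

    sig_a, sig_b = _sig(results_a), _sig(results_b)

    def _hypo_frac(df: pd.DataFrame, sig: pd.Index) -> float:
        if len(sig) == 0:
            return float("nan")
        return float((df.loc[sig, "difference"] < 0).mean())

    return CellTypeOverlap(
        n_significant_a=len(sig_a),
        n_significant_b=len(sig_b),
        n_common=len(set(sig_a) & set(sig_b)),
        hypo_fraction_a=_hypo_frac(results_a, sig_a),
        hypo_fraction_b=_hypo_frac(results_b, sig_b),
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_dmp(
    betas: BetaMatrix,
    detp: BetaMatrix | None,
    manifest: Sequence[ProbeRecord] | Mapping[str, ProbeRecord],
    samples: Sequence[SampleInfo],
    region: RegionDefinition,
    blocklist: Iterable[str] | None = None,
    audits: Sequence[ProbeAudit] | None = None,
    config: AssociationConfig | None = None,
    adjust: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Run the full association pipeline in its fixed order.

    Returns the per-probe result table (t-test, and regression when
    ``adjust``) annotated from the manifest, plus a metadata dict with the
    stage counts and the alpha threshold actually used.
    """
    cfg = config or AssociationConfig()
    if not isinstance(manifest, Mapping):
        manifest = {p.probe_id: p for p in manifest}

    meta: dict = {"pipeline_order": ["detection_p", "blocklist", "region", "tests"]}
    meta["probes_in"] = len(betas.probe_ids)

    if detp is not None:
        betas, dropped_detp = filter_detection_p(
            betas, detp, cut=cfg.detection_p_cut, frac=cfg.detection_sample_frac
        )
        meta["dropped_detection_p"] = len(dropped_detp)
    else:
        meta["dropped_detection_p"] = 0

    if blocklist is not None:
        betas, n_blocked = apply_blocklist(betas, blocklist)
        meta["dropped_blocklist"] = n_blocked
    else:
        meta["dropped_blocklist"] = 0

    betas = subset_region(betas, manifest, region)
    meta["probes_in_region"] = len(betas.probe_ids)
    if not betas.probe_ids:
        raise DataError(f"no probes remain inside region {region.name}")

    result = dmp_ttest(betas, samples, equal_var=cfg.equal_var)
    if adjust:
        result = result.join(dmp_regression(betas, samples, cfg.covariates))

    n_tests = len(result)
    meta["probes_tested"] = n_tests
    sig, threshold = bonferroni(result["p_ttest"], cfg.alpha_family, n_tests)
    result["significant_bonferroni"] = sig
    if adjust:
        sig_adj, _ = bonferroni(result["p_regression"], cfg.alpha_family, n_tests)
        result["significant_bonferroni_adjusted"] = sig_adj
    meta["alpha_family"] = cfg.alpha_family
    meta["alpha_threshold"] = threshold
    meta["t_test"] = "student" if cfg.equal_var else "welch"

    result.insert(0, "position", [manifest[p].binding_pos for p in result.index])
    result.insert(1, "gene", [manifest[p].gene or "" for p in result.index])
    result.insert(2, "feature", [manifest[p].feature or "" for p in result.index])
    if audits is not None:
        unreliable = {a.probe_id for a in audits if any(a.unreliable_at.values())}
        result["reliable"] = [p not in unreliable for p in result.index]
    return result, meta
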