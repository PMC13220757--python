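"""Per-genus linear mixed models with subject random intercepts.

Each taxon's relative abundance is modelled as

    y_ij = b0 + b_time * post_ij + b_sdd * sdd_i + b_ileo * ileostomy_i
           + u_i + e_ij,      u_i ~ N(0, s_u^2),  e_ij ~ N(0, s_e^2)

fitted by REML with Wald p-values per fixed effect. Effect sizes are
reported both raw (proportion units) and scaled by the taxon's mean
relative abundance (dimensionless); p-values are Benjamini-Hochberg
adjusted across taxa within each factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_formats import CountTable

FIXED_FACTORS = ("timepoint", "sdd", "ileostomy")
DEFAULT_PREVALENCE_MIN = 0.10
TRANSFORMS = ("none", "log", "arcsinsqrt")


def to_relative(table: CountTable) -> pd.DataFrame:
    """Sample-wise proportions; errors on an all-zero sample."""
    totals = table.sample_totals()
    if np.any(totals == 0):
        bad = table.sample_ids[int(np.argmin(totals))]
        raise ValueError(f"sample {bad!r} has zero total count; cannot form proportions")
    rel = table.counts / totals[:, None]
    return pd.DataFrame(rel, index=table.sample_ids, columns=table.taxon_ids)


@dataclass
class GenusFit:
    """Fixed-effect estimates and Wald p-values for one taxon's model."""

    effects: dict[str, float]
    p_values: dict[str, float]
    converged: bool
    method: str  # "lmm" or "ols" (fallback when the random intercept is unidentifiable)
    flagged: bool = False
    reason: str | None = None


def _design_matrix(design: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(
        {
            "const": 1.0,
            "timepoint": (design["timepoint"] == "post").astype(float),
            "sdd": (design["sdd"] == "yes").astype(float),
            "ileostomy": (design["ileostomy"] == "yes").astype(float),
        },
        index=design.index,
    )
    return X


def fit_genus_lmm(y: pd.Series | np.ndarray, design: pd.DataFrame) -> GenusFit:
    """Fit one taxon's mixed model on an observed design.

    ``design`` needs columns subject_id, timepoint, sdd, ileostomy, one row
    per sample aligned with ``y``. A zero-variance response, or an
    unidentifiable/non-converging fit, yields a flagged result rather than
    an exception; when fewer than two subjects contribute both samples the
    random intercept is unidentifiable and a plain OLS fit is used instead
    (``method='ols'``).
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(design):
        raise ValueError("response and design lengths differ")
    null = {f: np.nan for f in FIXED_FACTORS}
    if np.ptp(y) == 0.0:
        return GenusFit(null, dict(null), False, "none", flagged=True, reason="zero-variance response")
    X = _design_matrix(design)
    varying = [f for f in FIXED_FACTORS if X[f].nunique() > 1]
    if not varying:
        return GenusFit(null, dict(null), False, "none", flagged=True, reason="no varying factor")
    n_paired = int((design.groupby("subject_id")["timepoint"].nunique() == 2).sum())
    Xv = X[["const", *varying]]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if n_paired >= 2:
                model = sm.MixedLM(y, Xv, groups=design["subject_id"].to_numpy())
                fit = model.fit(reml=True)
                if not fit.converged:
                    # lbfgs stalls on near-boundary variance components;
                    # Powell is slower but more robust there
                    fit = model.fit(reml=True, method="powell", maxiter=1000)
                converged = bool(fit.converged)
                method = "lmm"
            else:
                fit = sm.OLS(y, Xv).fit()
                converged = True
                method = "ols"
    except (np.linalg.LinAlgError, ValueError) as exc:
        return GenusFit(null, dict(null), False, "none", flagged=True, reason=f"fit failed: {exc}")
    if not converged:
        return GenusFit(null, dict(null), False, method, flagged=True, reason="non-convergence")
    effects = dict(null)
    p_values = dict(null)
    for f in varying:
        effects[f] = float(fit.params[f] if hasattr(fit.params, "index") else fit.params[Xv.columns.get_loc(f)])
        p_values[f] = float(fit.pvalues[f] if hasattr(fit.pvalues, "index") else fit.pvalues[Xv.columns.get_loc(f)])
    return GenusFit(effects, p_values, True, method)


def scale_effect(raw_effect: float, mean_relabund: float) -> float:
    """Scale a raw (proportion-units) effect by the taxon's mean abundance."""
    if mean_relabund <= 0:
        raise ValueError("mean relative abundance must be positive")
    return raw_effect / mean_relabund


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _transform(y: np.ndarray, transform: str) -> np.ndarray:
    if transform == "none":
        return y
    if transform == "log":
        positive = y[y > 0]
        pseudo = positive.min() / 2 if positive.size else 1e-6
        return np.log(y + pseudo)
    if transform == "arcsinsqrt":
        return np.arcsin(np.sqrt(np.clip(y, 0.0, 1.0)))
    raise ValueError(f"transform must be one of {TRANSFORMS}, got {transform!r}")


def differential_abundance(
    table: CountTable,
    metadata: pd.DataFrame,
    prevalence_min: float = DEFAULT_PREVALENCE_MIN,
    transform: str = "none",
) -> pd.DataFrame:
    """Fit every taxon's mixed model and BH-adjust within each factor.

    Taxa present in fewer than ``prevalence_min`` of samples, with zero
    variance, or with failed fits are excluded from the result (the model
    response defaults to untransformed relative abundance). Returns one row
    per (taxon, factor) with raw and mean-abundance-scaled effects, p and q.
    """
    rel = to_relative(table)
    design = metadata.set_index("sample_id").loc[rel.index].reset_index()
    prevalence = (rel > 0).mean(axis=0)
    kept = [t for t in rel.columns if prevalence[t] >= prevalence_min]
    rows = []
    for taxon in kept:
        y_raw = rel[taxon].to_numpy()
        fit = fit_genus_lmm(_transform(y_raw, transform), design)
        if fit.flagged:
            continue
        mean_ab = float(y_raw.mean())
        for factor in FIXED_FACTORS:
            if np.isnan(fit.p_values[factor]):
                continue
            rows.append(
                {
                    "taxon": taxon,
                    "factor": factor,
                    "raw_effect": fit.effects[factor],
                    "mean_relabund": mean_ab,
                    "scaled_effect": scale_effect(fit.effects[factor], mean_ab),
                    "p_value": fit.p_values[factor],
                    "method": fit.method,
                }
            )
    result = pd.DataFrame(
        rows,
        columns=["taxon", "factor", "raw_effect", "mean_relabund", "scaled_effect", "p_value", "method"],
    )
    if result.empty:
        result["q_value"] = pd.Series(dtype=float)
        return result
    # p-values of exactly 0 can only arise from numerical underflow; clamp
    # them to the smallest positive float so BH's (0, 1] precondition holds.
    result["p_value"] = result["p_value"].clip(lower=np.nextafter(0.0, 1.0))
    result["q_value"] = np.nan
    for factor, grp in result.groupby("factor"):
        result.loc[grp.index, "q_value"] = bh_adjust(grp["p_value"].to_numpy())
    return result


def volcano_table(results: pd.DataFrame, comparison: str) -> pd.DataFrame:
    """Volcano-plot table (taxon, scaled effect, -log10 q) for one factor.

    Sorted by q ascending with taxon id as a stable tie-break.
    """
    if comparison not in FIXED_FACTORS:
        raise ValueError(f"comparison must be one of {FIXED_FACTORS}")
    sub = results[results["factor"] == comparison].copy() if not results.empty else results
    if sub.empty:
        return pd.DataFrame(columns=["taxon", "scaled_effect", "neg_log10_q"])
    sub["neg_log10_q"] = -np.log10(sub["q_value"])
    sub = sub.sort_values(["q_value", "taxon"], kind="stable")
    return sub[["taxon", "scaled_effect", "neg_log10_q"]].reset_index(drop=True)


def composition_summary(rel: pd.DataFrame, metadata: pd.DataFrame, k: int = 21) -> pd.DataFrame:
    """Per-stratum mean relative abundance of the top-k taxa overall.

    Taxa are ranked by overall mean relative abundance; strata are the
    timepoint x sdd x source cells present in the metadata; taxa beyond the
    top k are aggregated into an ``other`` row. Within each stratum the
    reported means (top-k plus other) sum to 1.
    """
    if k > rel.shape[1]:
        raise ValueError(f"k={k} exceeds the {rel.shape[1]} available taxa")
    design = metadata.set_index("sample_id").loc[rel.index]
    top = list(rel.mean(axis=0).sort_values(ascending=False, kind="stable").index[:k])
    strata = design.groupby(["timepoint", "sdd", "source"], observed=True, sort=False)
    rows = []
    for (tp, sdd, source), idx in strata.groups.items():
        block = rel.loc[idx]
        means = block.mean(axis=0)
        for taxon in top:
            rows.append(
                {
                    "timepoint": tp,
                    "sdd": sdd,
                    "source": source,
                    "taxon": taxon,
                    "mean_relabund": float(means[taxon]),
                }
            )
        if k < rel.shape[1]:
            rows.append(
                {
                    "timepoint": tp,
                    "sdd": sdd,
                    "source": source,
                    "taxon": "other",
                    "mean_relabund": float(means.drop(top).sum()),
                }
            )
    return pd.DataFrame(rows)
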