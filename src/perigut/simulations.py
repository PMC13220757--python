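"""Simulation studies exercising the pipeline end to end.

These drivers are used by the numbered analysis scripts and the acceptance
checks: a full-cohort run of the default study design, type-I-error
calibration of the stratified PERMANOVA on null cohorts, mixed-model
effect-recovery and false-discovery-rate studies, and sample-count fidelity
of the cohort generator. All randomness derives from a single integer seed
through ``numpy.random.SeedSequence`` spawning, so every study is exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_stats import alpha_group_tests
from .differential_abundance import bh_adjust, differential_abundance, fit_genus_lmm
from .diversity import alpha_diversity_table, pairwise_weighted_unifrac, rarefy
from .stratified_permanova import PermanovaResult, build_full_design, permanova_test
from .synthetic_cohort import CohortConfig, SyntheticCohort, generate_cohort

_SEED_MOD = 2**31


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % _SEED_MOD


@dataclass
class PipelineRun:
    cohort: SyntheticCohort
    excluded_samples: list[str]
    alpha: pd.DataFrame
    alpha_tests: pd.DataFrame
    permanova: PermanovaResult
    diffabund: pd.DataFrame


def run_default_pipeline(
    seed: int,
    n_subjects: int = 214,
    n_taxa: int = 60,
    depth: int = 20_000,
    rarefaction_depth: int = 10_000,
    n_permutations: int = 9_999,
) -> PipelineRun:
    """Full analysis of one default synthetic cohort.

    Generate the cohort, rarefy to the working depth, compute alpha
    diversity with stratified group tests, weighted UniFrac distances with
    the stratified PERMANOVA, and per-genus mixed-model differential
    abundance.
    """
    s = _child_seeds(seed, 4)
    cohort = generate_cohort(CohortConfig(n_subjects=n_subjects, n_taxa=n_taxa, depth=depth, seed=int(s[0])))
    rare, excluded = rarefy(cohort.counts, depth=rarefaction_depth, seed=int(s[1]))
    meta = cohort.metadata[cohort.metadata["sample_id"].isin(rare.sample_ids)].reset_index(drop=True)
    alpha = alpha_diversity_table(rare, cohort.tree)
    alpha_tests = alpha_group_tests(alpha, meta)
    dm = pairwise_weighted_unifrac(rare, cohort.tree)
    perm = permanova_test(
        dm, build_full_design(meta), n_permutations=n_permutations, seed=int(s[2]), mode="monte_carlo"
    )
    da = differential_abundance(rare, meta)
    return PipelineRun(cohort, excluded, alpha, alpha_tests, perm, da)


def permanova_type_i_error(
    n_datasets: int = 200,
    n_subjects: int = 40,
    n_taxa: int = 40,
    depth: int = 1_000,
    p_missing_post: float = 0.2,
    n_permutations: int = 499,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Empirical rejection rate of each PERMANOVA term on null cohorts.

    Cohorts carry no injected effects (subject-level correlation remains),
    so each term's rejection rate should sit at the nominal level.
    """
    seeds = _child_seeds(seed, 2 * n_datasets)
    rejections = {"timepoint": 0, "ileostomy": 0, "sdd": 0}
    for r in range(n_datasets):
        cfg = CohortConfig(
            n_subjects=n_subjects,
            n_taxa=n_taxa,
            depth=depth,
            seed=int(seeds[2 * r]),
            effect_table=[],
            p_missing_pre=0.0,
            p_missing_post=p_missing_post,
        )
        cohort = generate_cohort(cfg)
        dm = pairwise_weighted_unifrac(cohort.counts, cohort.tree)
        res = permanova_test(
            dm,
            build_full_design(cohort.metadata),
            n_permutations=n_permutations,
            seed=int(seeds[2 * r + 1]),
            mode="monte_carlo",
        )
        for t in res.terms:
            # strict inequality: significance is declared at p < alpha
            rejections[t.name] += t.p_value < alpha
    return {k: v / n_datasets for k, v in rejections.items()}


def _paired_design(n_subjects: int, rng: np.random.Generator, p_sdd: float = 0.4, p_ileo: float = 0.35) -> pd.DataFrame:
    sdd = rng.random(n_subjects) < p_sdd
    ileo = rng.random(n_subjects) < p_ileo
    rows = []
    for s in range(n_subjects):
        for tp in ("pre", "post"):
            rows.append(
                {
                    "sample_id": f"s{s}_{tp}",
                    "subject_id": f"subj{s}",
                    "timepoint": tp,
                    "sdd": "yes" if sdd[s] else "no",
                    "ileostomy": "yes" if ileo[s] else "no",
                }
            )
    return pd.DataFrame(rows)


def _lmm_response(
    design: pd.DataFrame,
    rng: np.random.Generator,
    beta_time: float,
    intercept: float = 0.1,
    subject_sd: float = 0.02,
    noise_sd: float = 0.03,
) -> np.ndarray:
    """Gaussian response with the mixed model's own covariance structure.

    Used for recovery and FDR studies where taxa must be independently and
    exactly null or non-null; in a compositional (softmax) cohort a shift in
    one taxon necessarily moves every other taxon's relative abundance, so
    'null taxon' is only well defined outside the simplex.
    """
    subjects = design["subject_id"].unique()
    u = dict(zip(subjects, rng.normal(0.0, subject_sd, len(subjects))))
    return (
        intercept
        + beta_time * (design["timepoint"] == "post").to_numpy()
        + np.array([u[s] for s in design["subject_id"]])
        + rng.normal(0.0, noise_sd, len(design))
    )


def lmm_recovery(
    n_replicates: int = 50,
    n_subjects: int = 200,
    beta_time: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Mean estimate and relative bias of the time effect over replicates."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    estimates = []
    for _ in range(n_replicates):
        design = _paired_design(n_subjects, rng)
        y = _lmm_response(design, rng, beta_time)
        fit = fit_genus_lmm(y, design)
        if not fit.flagged:
            estimates.append(fit.effects["timepoint"])
    mean_est = float(np.mean(estimates))
    return {
        "mean_estimate": mean_est,
        "true_effect": beta_time,
        "relative_bias": (mean_est - beta_time) / beta_time if beta_time else np.nan,
        "n_fits": len(estimates),
    }


def lmm_fdr(
    n_replicates: int = 50,
    n_taxa: int = 40,
    frac_nonnull: float = 0.10,
    beta_time: float = 0.02,
    n_subjects: int = 60,
    q_threshold: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Empirical FDR of the per-taxon LMM + BH pipeline at a q threshold.

    Each replicate simulates ``n_taxa`` independent responses of which
    ``frac_nonnull`` carry a true time effect; discoveries are pooled
    across replicates.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_nonnull = int(round(frac_nonnull * n_taxa))
    false = true = 0
    for _ in range(n_replicates):
        design = _paired_design(n_subjects, rng)
        pvals, is_nonnull = [], []
        for taxon in range(n_taxa):
            beta = beta_time if taxon < n_nonnull else 0.0
            fit = fit_genus_lmm(_lmm_response(design, rng, beta), design)
            if fit.flagged:
                continue
            pvals.append(max(fit.p_values["timepoint"], 1e-300))
            is_nonnull.append(beta != 0.0)
        q = bh_adjust(np.array(pvals))
        disc = q < q_threshold
        nn = np.array(is_nonnull)
        false += int((disc & ~nn).sum())
        true += int((disc & nn).sum())
    total = false + true
    return {
        "fdr": false / total if total else 0.0,
        "n_discoveries": total,
        "n_false_discoveries": false,
    }


def sample_count_fidelity(
    n_replicates: int = 1_000,
    n_subjects: int = 214,
    seed: int = 0,
) -> dict[str, float]:
    """Mean realised pre/post sample counts under the default missingness.

    With the default configuration the expectations are 191 preoperative
    and 163 postoperative samples out of 214 subjects.
    """
    seeds = _child_seeds(seed, n_replicates)
    pre = np.empty(n_replicates)
    post = np.empty(n_replicates)
    for r in range(n_replicates):
        cohort = generate_cohort(
            CohortConfig(n_subjects=n_subjects, n_taxa=12, depth=50, seed=int(seeds[r]))
        )
        tp = cohort.metadata["timepoint"]
        pre[r] = (tp == "pre").sum()
        post[r] = (tp == "post").sum()
    return {
        "mean_pre": float(pre.mean()),
        "mean_post": float(post.mean()),
        "se_pre": float(pre.std(ddof=1) / np.sqrt(n_replicates)),
        "se_post": float(post.std(ddof=1) / np.sqrt(n_replicates)),
    }
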