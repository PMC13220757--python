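"""PERMANOVA with a complete-design permutation scheme and subject strata.

Standard PERMANOVA permutes observed sample labels freely, which is invalid
for paired designs with missing samples: it breaks the subject pairing and
implicitly conditions on the missingness pattern. Here the null distribution
is generated by permuting the COMPLETE subject-by-timepoint design grid —
every subject has a pre and a post cell whether observed or not:

* within each subject, the two timepoint labels are flipped by an
  independent fair coin (subject-specific strata), and
* whole subject-level covariate vectors (ileostomy, SDD) are permuted
  uniformly across subjects,

after which labels landing on unobserved cells are simply dropped and the
term F statistics are recomputed on the same distance matrix. Sums of
squares are the McArdle-Anderson partition of the Gower-centred squared
distance matrix, sequential (type-I) in the user-given term order.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

DEFAULT_TERMS = ("timepoint", "ileostomy", "sdd")
DEFAULT_N_PERMUTATIONS = 10_000
#: Exhaustive enumeration is auto-selected when the scheme space S! * 2^S
#: does not exceed this.
EXHAUSTIVE_LIMIT = 100_000

_RANK_TOL = 1e-9
#: Slack used when comparing permuted to observed F, so permutations that
#: are exactly tied with the observed labelling (e.g. symmetry-equivalent
#: schemes) count toward the null despite floating-point noise.
_TIE_EPS = 1e-12


class DegenerateTermError(ValueError):
    """A model term is constant (zero df) on the observed design."""


@dataclass(frozen=True)
class PermutationScheme:
    """Joint permutation of a complete paired design.

    ``flips[s]`` swaps subject ``s``'s pre/post labels; ``subject_perm``
    reassigns subject-level covariate vectors (subject ``s`` receives the
    covariates of subject ``subject_perm[s]``).
    """

    flips: np.ndarray
    subject_perm: np.ndarray

    @classmethod
    def draw(cls, n_subjects: int, rng: np.random.Generator) -> "PermutationScheme":
        return cls(
            flips=rng.integers(0, 2, n_subjects).astype(bool),
            subject_perm=rng.permutation(n_subjects),
        )

    @classmethod
    def identity(cls, n_subjects: int) -> "PermutationScheme":
        return cls(flips=np.zeros(n_subjects, dtype=bool), subject_perm=np.arange(n_subjects))


@dataclass
class PermanovaTerm:
    name: str
    ss: float
    df: int
    r_squared: float
    pseudo_f: float
    p_value: float | None = None


@dataclass
class PermanovaResult:
    terms: list[PermanovaTerm]
    residual_ss: float
    residual_df: int
    total_ss: float
    n_permutations: int | None = None
    method: str | None = None
    n_degenerate_permutations: int = 0

    def term(self, name: str) -> PermanovaTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "term": t.name,
                "sum_of_squares": t.ss,
                "df": t.df,
                "r_squared": t.r_squared,
                "pseudo_f": t.pseudo_f,
                "p_value": t.p_value,
            }
            for t in self.terms
        ]
        rows.append(
            {
                "term": "residual",
                "sum_of_squares": self.residual_ss,
                "df": self.residual_df,
                "r_squared": self.residual_ss / self.total_ss if self.total_ss else np.nan,
                "pseudo_f": np.nan,
                "p_value": np.nan,
            }
        )
        rows.append(
            {
                "term": "total",
                "sum_of_squares": self.total_ss,
                "df": sum(t.df for t in self.terms) + self.residual_df,
                "r_squared": 1.0,
                "pseudo_f": np.nan,
                "p_value": np.nan,
            }
        )
        return pd.DataFrame(rows)


def gower_center(d: np.ndarray | DistanceMatrix) -> np.ndarray:
    """Gower-centred matrix G = -1/2 * J * D^2 * J (J the centring projector).

    Rows and columns of G sum to zero; trace(G) is the total sum of squares
    of the distance partition.
    """
    if isinstance(d, DistanceMatrix):
        d = d.data
    d = np.asarray(d, dtype=float)
    a = -0.5 * d**2
    row_mean = a.mean(axis=1, keepdims=True)
    col_mean = a.mean(axis=0, keepdims=True)
    return a - row_mean - col_mean + a.mean()


def build_full_design(metadata: pd.DataFrame) -> pd.DataFrame:
    """Expand sample metadata to the complete subject-by-timepoint grid.

    One row per (subject, timepoint) cell, observed or not; unobserved cells
    carry ``observed=False`` and a null ``sample_id``. Subject-level
    covariates fill both cells.
    """
    subjects = metadata.drop_duplicates("subject_id")[["subject_id", "ileostomy", "sdd"]]
    cells = []
    lookup = {(r.subject_id, r.timepoint): r.sample_id for r in metadata.itertuples()}
    for r in subjects.itertuples():
        for tp in ("pre", "post"):
            sid = lookup.get((r.subject_id, tp))
            cells.append(
                {
                    "subject_id": r.subject_id,
                    "timepoint": tp,
                    "ileostomy": r.ileostomy,
                    "sdd": r.sdd,
                    "observed": sid is not None,
                    "sample_id": sid,
                }
            )
    return pd.DataFrame(cells)


def permute_complete_design(full: pd.DataFrame, scheme: PermutationScheme) -> pd.DataFrame:
    """Apply a joint within/between-subject permutation to a complete design.

    Observed flags and sample ids stay attached to their original
    (subject, slot) cells; timepoint labels flip within subjects and
    subject-level covariates move between subjects, so restricting the
    permuted design to observed cells drops exactly the labels that landed
    on missing data.
    """
    full = full.sort_values(["subject_id", "timepoint"], ascending=[True, False], kind="stable")
    subjects = full["subject_id"].unique()
    n = len(subjects)
    if len(scheme.flips) != n or len(scheme.subject_perm) != n:
        raise ValueError("scheme size does not match number of subjects")
    sub_idx = {s: i for i, s in enumerate(subjects)}
    cov = full.drop_duplicates("subject_id").set_index("subject_id")[["ileostomy", "sdd"]]
    out = full.copy()
    idx = out["subject_id"].map(sub_idx).to_numpy()
    flip = scheme.flips[idx]
    tp = out["timepoint"].to_numpy()
    out["timepoint"] = np.where(flip, np.where(tp == "pre", "post", "pre"), tp)
    donor = subjects[scheme.subject_perm[idx]]
    out["ileostomy"] = cov.loc[donor, "ileostomy"].to_numpy()
    out["sdd"] = cov.loc[donor, "sdd"].to_numpy()
    return out.reset_index(drop=True)


def _encode_columns(design: pd.DataFrame, terms: tuple[str, ...]) -> list[np.ndarray]:
    cols = []
    for term in terms:
        v = design[term].to_numpy()
        if term == "timepoint":
            cols.append((v == "post").astype(float))
        else:
            cols.append((v == "yes").astype(float))
    return cols


def _sequential_ss(G: np.ndarray, cols: list[np.ndarray], trace: float):
    """Sequential (type-I) SS via Gram-Schmidt projection of centred columns.

    Returns per-term (ss, df), residual ss/df. A column that is (numerically)
    constant or collinear with earlier terms contributes zero df.
    """
    n = G.shape[0]
    qs: list[np.ndarray] = []
    ss = np.zeros(len(cols))
    dfs = np.zeros(len(cols), dtype=int)
    for j, c in enumerate(cols):
        v = c - c.mean()
        for q in qs:
            v = v - q * (q @ v)
        nrm2 = float(v @ v)
        if nrm2 < _RANK_TOL * n:
            continue
        q = v / math.sqrt(nrm2)
        qs.append(q)
        ss[j] = float(q @ (G @ q))
        dfs[j] = 1
    resid_ss = trace - ss.sum()
    resid_df = n - 1 - int(dfs.sum())
    return ss, dfs, resid_ss, resid_df


def _f_stats(ss, dfs, resid_ss, resid_df):
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = resid_ss / resid_df if resid_df > 0 else np.nan
        f = np.where(dfs > 0, (ss / np.maximum(dfs, 1)) / denom, np.nan)
    return f


def pseudo_f(
    dm: DistanceMatrix,
    design: pd.DataFrame,
    terms: tuple[str, ...] = DEFAULT_TERMS,
) -> PermanovaResult:
    """Term-wise pseudo-F partition of a distance matrix (no p-values).

    ``design`` has one row per sample with a ``sample_id`` column aligned to
    the distance matrix and the term columns; sums of squares are sequential
    in the order of ``terms``. Raises :class:`DegenerateTermError` for a
    term with zero df on the design.
    """
    design = design.set_index("sample_id").loc[list(dm.ids)].reset_index()
    G = gower_center(dm)
    trace = float(np.trace(G))
    cols = _encode_columns(design, terms)
    ss, dfs, resid_ss, resid_df = _sequential_ss(G, cols, trace)
    if (dfs == 0).any():
        bad = terms[int(np.argmin(dfs))]
        raise DegenerateTermError(f"term {bad!r} has zero degrees of freedom on this design")
    f = _f_stats(ss, dfs, resid_ss, resid_df)
    result_terms = [
        PermanovaTerm(
            name=t,
            ss=float(ss[j]),
            df=int(dfs[j]),
            r_squared=float(ss[j] / trace) if trace else np.nan,
            pseudo_f=float(f[j]),
        )
        for j, t in enumerate(terms)
    ]
    return PermanovaResult(result_terms, float(resid_ss), int(resid_df), float(trace))


def _design_arrays(full: pd.DataFrame, dm_ids: list[str]):
    """Vectorised view of the observed design used by the permutation loop."""
    full = full.sort_values(["subject_id", "timepoint"], ascending=[True, False], kind="stable")
    subjects = list(full["subject_id"].unique())
    sub_idx = {s: i for i, s in enumerate(subjects)}
    obs = full[full["observed"]]
    by_sample = obs.set_index("sample_id")
    missing = set(dm_ids) - set(by_sample.index)
    extra = set(by_sample.index) - set(dm_ids)
    if missing or extra:
        raise ValueError(
            f"observed design cells and distance-matrix samples differ "
            f"(missing from design: {sorted(missing)[:5]}, absent from distances: {sorted(extra)[:5]})"
        )
    by_sample = by_sample.loc[list(dm_ids)]
    subj = by_sample["subject_id"].map(sub_idx).to_numpy()
    slot = (by_sample["timepoint"] == "post").to_numpy().astype(np.int8)
    cov = full.drop_duplicates("subject_id").set_index("subject_id")[["ileostomy", "sdd"]]
    ileo = (cov.loc[subjects, "ileostomy"] == "yes").to_numpy().astype(float)
    sdd = (cov.loc[subjects, "sdd"] == "yes").to_numpy().astype(float)
    return subj, slot, ileo, sdd, len(subjects)


def _perm_columns(subj, slot, ileo, sdd, terms, flips, perm):
    cols = []
    for term in terms:
        if term == "timepoint":
            cols.append((slot ^ flips[subj]).astype(float))
        elif term == "ileostomy":
            cols.append(ileo[perm[subj]])
        elif term == "sdd":
            cols.append(sdd[perm[subj]])
        else:
            raise ValueError(f"unknown term {term!r}")
    return cols


def scheme_space_size(n_subjects: int) -> int:
    """Size of the joint permutation space: n! * 2^n."""
    return math.factorial(n_subjects) * 2**n_subjects


def permanova_test(
    dm: DistanceMatrix,
    full: pd.DataFrame,
    terms: tuple[str, ...] = DEFAULT_TERMS,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    mode: str = "auto",
) -> PermanovaResult:
    """Complete-design stratified PERMANOVA.

    The observed F statistics come from the unpermuted observed design; each
    permutation replicate jointly flips timepoints within subjects and
    permutes subject-level covariates across subjects on the COMPLETE
    design, restricts to observed cells and recomputes all term Fs on the
    same distance matrix. Monte-Carlo p = (#{F_perm >= F_obs} + 1) / (B + 1);
    in exhaustive mode (``mode='exhaustive'``, or ``'auto'`` when
    n! * 2^n <= 100 000) the whole scheme space is enumerated and
    p = #{F_perm >= F_obs} / N.

    Ties count toward the null (>=). A permutation in which some term loses
    all its degrees of freedom is counted as an exceedance for that term
    (conservative); a warning is issued if this affects > 1% of replicates.
    """
    if mode not in ("auto", "exhaustive", "monte_carlo"):
        raise ValueError(f"mode must be auto/exhaustive/monte_carlo, got {mode!r}")
    subj, slot, ileo, sdd, S = _design_arrays(full, list(dm.ids))
    G = gower_center(dm)
    trace = float(np.trace(G))

    obs_cols = _perm_columns(subj, slot, ileo, sdd, terms, np.zeros(S, dtype=np.int8), np.arange(S))
    ss, dfs, resid_ss, resid_df = _sequential_ss(G, obs_cols, trace)
    if (dfs == 0).any():
        bad = terms[int(np.argmin(dfs))]
        raise DegenerateTermError(f"term {bad!r} has zero degrees of freedom on the observed design")
    f_obs = _f_stats(ss, dfs, resid_ss, resid_df)

    if S < 63:
        space = scheme_space_size(S)
    else:
        space = None  # astronomically large
    exhaustive = mode == "exhaustive" or (mode == "auto" and space is not None and space <= EXHAUSTIVE_LIMIT)
    if exhaustive and (space is None or space > 10 * EXHAUSTIVE_LIMIT):
        raise ValueError(f"scheme space too large to enumerate for {S} subjects")

    exceed = np.zeros(len(terms))
    n_degenerate = 0
    if exhaustive:
        total = 0
        for perm in itertools.permutations(range(S)):
            perm = np.array(perm)
            for mask in range(2**S):
                flips = np.array([(mask >> b) & 1 for b in range(S)], dtype=np.int8)
                cols = _perm_columns(subj, slot, ileo, sdd, terms, flips, perm)
                pss, pdfs, prss, prdf = _sequential_ss(G, cols, trace)
                f_perm = _f_stats(pss, pdfs, prss, prdf)
                degenerate = pdfs == 0
                n_degenerate += int(degenerate.any())
                exceed += np.where(degenerate, 1.0, f_perm >= f_obs - _TIE_EPS)
                total += 1
        p = exceed / total
        n_perm_done = total
        method = "exhaustive"
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_permutations):
            scheme = PermutationScheme.draw(S, rng)
            flips = scheme.flips.astype(np.int8)
            cols = _perm_columns(subj, slot, ileo, sdd, terms, flips, scheme.subject_perm)
            pss, pdfs, prss, prdf = _sequential_ss(G, cols, trace)
            f_perm = _f_stats(pss, pdfs, prss, prdf)
            degenerate = pdfs == 0
            n_degenerate += int(degenerate.any())
            exceed += np.where(degenerate, 1.0, f_perm >= f_obs - _TIE_EPS)
        p = (exceed + 1.0) / (n_permutations + 1.0)
        n_perm_done = n_permutations
        method = "monte_carlo"

    if n_degenerate > 0.01 * n_perm_done:
        warnings.warn(
            f"{n_degenerate} of {n_perm_done} permutations had a zero-df term "
            "(counted as exceedances)",
            stacklevel=2,
        )

    result_terms = [
        PermanovaTerm(
            name=t,
            ss=float(ss[j]),
            df=int(dfs[j]),
            r_squared=float(ss[j] / trace) if trace else np.nan,
            pseudo_f=float(f_obs[j]),
            p_value=float(p[j]),
        )
        for j, t in enumerate(terms)
    ]
    return PermanovaResult(
        result_terms,
        float(resid_ss),
        int(resid_df),
        float(trace),
        n_permutations=n_perm_done,
        method=method,
        n_degenerate_permutations=n_degenerate,
    )
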