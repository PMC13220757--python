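"""Paired pre/post microbiome cohort simulator.

Emulates the design of a perioperative rectal-surgery cohort: ~214 subjects,
each contributing at most one preoperative faecal sample and one
postoperative sample (faecal, or ileostomy effluent when a diverting
ileostomy was formed), with subject-level antibiotic-decontamination (SDD)
and ileostomy factors and independent sample missingness.

Counts follow a compositional generative model: per-taxon log baselines plus
a subject scalar intercept, optional per-taxon subject deviations and the
injected design effects are pushed through a softmax to per-sample taxon
proportions, from which a fixed sequencing depth is drawn multinomially
(optionally Dirichlet-multinomial when an overdispersion concentration is
given). The scalar subject intercept shifts all taxa equally and therefore
cancels in the softmax; it is retained for fidelity of the absolute-scale
model, while the per-taxon deviations are what induce within-subject
correlation of relative abundances.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_formats import CountTable, validate_metadata, write_count_table, write_metadata, write_newick

FACTORS = ("time", "ileostomy", "sdd")

#: Cohort margins of the emulated study: 214 subjects, 85 on SDD, 78 with an
#: ileostomy, 191 of 214 preoperative and 163 of 214 postoperative samples
#: recovered.
N_SUBJECTS = 214
P_SDD = 85 / 214
P_ILEOSTOMY = 78 / 214
P_MISSING_PRE = 23 / 214
P_MISSING_POST = 51 / 214


@dataclass(frozen=True)
class Effect:
    """One injected design effect: a log-fold-change on a taxon's logit."""

    taxon: int
    factor: str
    lfc: float

    def __post_init__(self) -> None:
        if self.factor not in FACTORS:
            raise ValueError(f"effect factor must be one of {FACTORS}, got {self.factor!r}")


#: Roles of the first taxa under the default baseline and effect table:
#: 0 Enterococcus-like and 1 Klebsiella-like (rare preoperatively, bloom
#: after surgery), 10 Escherichia-like (rare, blooms in effluent), 2-8
#: abundant strict-anaerobe Firmicutes-like genera (7-8 Parabacteroides/
#: Lachnoclostridium-like, depleted in effluent), 9 Bacteroides-like
#: (abundant, increased under SDD).
RARE_BLOOMER_TAXA = (0, 1, 10)
RARE_BLOOMER_PROPORTION = 0.004


def default_baseline_log(n_taxa: int) -> np.ndarray:
    """Deterministic preoperative log-abundance baseline.

    A geometric rank-abundance decay over the bulk taxa, with the designated
    bloom taxa pinned at ~0.4% so that their postoperative logit shifts
    produce the double-digit relative abundances seen in perturbed guts.
    """
    decay = np.exp(-0.10 * np.arange(n_taxa, dtype=float))
    p = decay / decay.sum()
    for t in RARE_BLOOMER_TAXA:
        if t < n_taxa:
            p[t] = RARE_BLOOMER_PROPORTION
    return np.log(p / p.sum())


def default_effect_table(n_taxa: int = 120) -> list[Effect]:
    """Post-surgery blooms of facultative anaerobes, losses of
    strict-anaerobe Firmicutes-like taxa, a broad postoperative depletion of
    the rare tail (richness loss), large additional shifts in ileostomy
    effluent and a modest SDD-associated Bacteroides-like increase.

    Magnitudes are sized so that, through weighted UniFrac, the surgery
    (time) contrast dominates community variance, ileostomy is second and
    SDD smallest: ileostomy shifts act only on the few effluent samples but
    are individually large (effluent is an ecologically distinct community),
    while the modest SDD shift acts on every sample of an SDD subject.
    A bloom from 0.4% to >10% is a logit shift of ~3.5. The tail depletion
    (last ~40% of taxa, already near the detection limit) is what pulls
    postoperative richness -- and with it Faith PD -- down, mirroring the
    loss of rare obligate anaerobes after surgery. Requires n_taxa >= 11.
    """
    effects = [
        Effect(0, "time", 3.5),
        Effect(1, "time", 3.0),
        Effect(2, "time", -1.0),
        Effect(3, "time", -1.0),
        Effect(4, "time", -1.0),
        Effect(5, "time", -1.0),
        Effect(6, "time", -1.0),
        Effect(0, "ileostomy", 1.0),
        Effect(10, "ileostomy", 2.5),
        Effect(7, "ileostomy", -2.0),
        Effect(8, "ileostomy", -2.0),
        Effect(2, "ileostomy", -1.5),
        Effect(3, "ileostomy", -1.5),
        Effect(9, "sdd", 0.7),
    ]
    tail_start = max(11, int(np.ceil(0.6 * n_taxa)))
    effects.extend(Effect(t, "time", -1.5) for t in range(tail_start, n_taxa))
    return effects


@dataclass
class CohortConfig:
    """Generator configuration; defaults reproduce the emulated study design."""

    n_subjects: int = N_SUBJECTS
    p_sdd: float = P_SDD
    p_ileostomy: float = P_ILEOSTOMY
    p_missing_pre: float = P_MISSING_PRE
    p_missing_post: float = P_MISSING_POST
    n_taxa: int = 120
    depth: int = 10_000
    effect_table: list[Effect] | None = None
    subject_sd: float = 0.5
    subject_taxon_sd: float = 0.3
    overdispersion: float | None = None
    #: SD of random jitter added to the deterministic default baseline
    #: (ignored when baseline_log is given).
    baseline_sd: float = 0.3
    #: Optional fixed per-taxon log baseline; when given it replaces the
    #: default rank-abundance baseline + jitter, making per-cell proportions
    #: analytically known.
    baseline_log: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_table is None:
            self.effect_table = default_effect_table(self.n_taxa)
        for name in ("p_sdd", "p_ileostomy", "p_missing_pre", "p_missing_post"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be positive")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValueError("overdispersion concentration must be positive")
        if self.baseline_log is not None and len(self.baseline_log) != self.n_taxa:
            raise ValueError("baseline_log length must equal n_taxa")
        bad = [e for e in self.effect_table if not 0 <= e.taxon < self.n_taxa]
        if bad:
            raise ValueError(
                f"effect taxa out of range for n_taxa={self.n_taxa}: "
                f"{sorted({e.taxon for e in bad})}"
            )


@dataclass
class SyntheticCohort:
    counts: CountTable
    metadata: pd.DataFrame
    tree: TreeNode
    truth: pd.DataFrame  # the effect table actually injected

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_count_table(self.counts, directory / "counts.tsv")
        write_metadata(self.metadata, directory / "metadata.tsv")
        write_newick(self.tree, directory / "tree.nwk")
        self.truth.to_csv(directory / "truth.tsv", sep="\t", index=False)


def taxon_names(n_taxa: int) -> list[str]:
    return [f"g{i:03d}" for i in range(n_taxa)]


def generate_random_tree(n_taxa: int, seed: int, taxon_ids: list[str] | None = None) -> TreeNode:
    """Random rooted binary tree over ``n_taxa`` leaves.

    Built by coalescent-style random pairwise joins with exponential branch
    lengths (mean 0.1, a typical 16S genus-level substitution scale).
    Deterministic under ``seed``.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa to build a tree")
    if taxon_ids is None:
        taxon_ids = taxon_names(n_taxa)
    if len(taxon_ids) != n_taxa:
        raise ValueError("taxon_ids length must equal n_taxa")
    rng = np.random.default_rng(seed)
    nodes = []
    for name in taxon_ids:
        leaf = TreeNode(name=name)
        leaf.length = float(rng.exponential(0.1))
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.exponential(0.1))
        nodes = [n for k, n in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return root


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def expected_proportions(
    baseline: np.ndarray, effect_table: list[Effect], *, post: bool, ileostomy: bool, sdd: bool
) -> np.ndarray:
    """Noise-free taxon proportions for a design cell.

    With zero per-taxon subject deviation and no overdispersion this is the
    exact per-sample proportion vector, which makes it a closed-form oracle
    for effect-recovery checks.
    """
    logits = baseline.astype(float).copy()
    for e in effect_table:
        active = (
            (e.factor == "time" and post)
            or (e.factor == "ileostomy" and post and ileostomy)
            or (e.factor == "sdd" and sdd)
        )
        if active:
            logits[e.taxon] += e.lfc
    return _softmax(logits)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort (counts, metadata, tree, injected truth).

    Subject factors are independent Bernoulli draws; effects are active as
    follows: ``time`` effects on postoperative samples, ``ileostomy`` effects
    on postoperative samples of ileostomy subjects (preoperative samples are
    all faecal), ``sdd`` effects on every sample of an SDD subject. Samples
    are deleted independently with the configured missingness probabilities.
    Identical seeds give bit-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    tree_seed = int(rng.integers(2**31))
    n, S = config.n_taxa, config.n_subjects
    taxa = taxon_names(n)
    tree = generate_random_tree(n, tree_seed, taxa) if n >= 2 else TreeNode(name=taxa[0])

    baseline = default_baseline_log(n) + rng.normal(0.0, config.baseline_sd, n)
    if config.baseline_log is not None:
        baseline = np.asarray(config.baseline_log, dtype=float)
    sdd = rng.random(S) < config.p_sdd
    ileo = rng.random(S) < config.p_ileostomy
    intercept = rng.normal(0.0, config.subject_sd, S)
    taxon_dev = (
        rng.normal(0.0, config.subject_taxon_sd, (S, n))
        if config.subject_taxon_sd > 0
        else np.zeros((S, n))
    )
    miss_pre = rng.random(S) < config.p_missing_pre
    miss_post = rng.random(S) < config.p_missing_post

    rows, meta_rows = [], []
    for s in range(S):
        subject_id = f"subj{s:04d}"
        for tp, missing in (("pre", miss_pre[s]), ("post", miss_post[s])):
            if missing:
                continue
            logits = (
                baseline
                + intercept[s]
                + taxon_dev[s]
                + _logit_shift(config.effect_table, n, post=tp == "post", ileostomy=bool(ileo[s]), sdd=bool(sdd[s]))
            )
            p = _softmax(logits)
            if config.overdispersion is not None:
                p = rng.dirichlet(p * config.overdispersion)
            counts = rng.multinomial(config.depth, p)
            source = "ileostomy_effluent" if (tp == "post" and ileo[s]) else "faeces"
            rows.append(counts)
            meta_rows.append(
                {
                    "sample_id": f"s{s:04d}_{tp}",
                    "subject_id": subject_id,
                    "timepoint": tp,
                    "ileostomy": "yes" if ileo[s] else "no",
                    "sdd": "yes" if sdd[s] else "no",
                    "source": source,
                }
            )

    metadata = validate_metadata(pd.DataFrame(meta_rows, columns=METADATA_COLUMNS_ORDER))
    counts = CountTable(
        [r["sample_id"] for r in meta_rows],
        taxa,
        np.array(rows, dtype=np.int64).reshape(len(rows), n),
    )
    truth = pd.DataFrame(
        [{"taxon": taxa[e.taxon], "factor": e.factor, "lfc": e.lfc} for e in config.effect_table],
        columns=["taxon", "factor", "lfc"],
    )
    return SyntheticCohort(counts=counts, metadata=metadata, tree=tree, truth=truth)


METADATA_COLUMNS_ORDER = ["sample_id", "subject_id", "timepoint", "ileostomy", "sdd", "source"]


def _logit_shift(effect_table: list[Effect], n_taxa: int, *, post: bool, ileostomy: bool, sdd: bool) -> np.ndarray:
    shift = np.zeros(n_taxa)
    for e in effect_table:
        active = (
            (e.factor == "time" and post)
            or (e.factor == "ileostomy" and post and ileostomy)
            or (e.factor == "sdd" and sdd)
        )
        if active:
            shift[e.taxon] += e.lfc
    return shift
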