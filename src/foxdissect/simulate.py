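"""Seeded synthetic data with planted ground truth.

The count simulator emulates the statistical structure of the motivating
transduction study: a bimodal log2-FPKM baseline (a low-expression and a
high-expression Gaussian mode plus a non-expressed class), two replicates
per condition, a planted set of factor-regulated genes with up/down
directions, and mutant conditions that revert a chosen subset of those
effects back toward the control baseline.  Counts are negative binomial
around length- and library-size-scaled means, so the generator exactly
inverts the FPKM formula used downstream.

The MSA simulator plants conserved blocks (high within-column identity)
on a low-identity background, prolines at chosen reference positions, and
an accompanying per-codon Bayes-factor table elevated inside the blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from foxdissect.io import CountMatrix

_AMINO = np.array(list("ACDEFGHIKLMNQRSTVWY"))  # 19 letters, no proline
_AMINO_ALL = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimulationConfig:
    """Parameters of a synthetic transduction study.

    The defaults encode the emulated study design: two replicates per
    condition, a half/half split between the two expression modes centred
    at -2 and +6 log2 FPKM (sd 1 each), 10% never-expressed genes, and a
    mean-dispersion trend alpha(mu) = a + b/mu.  ``mutant_dysregulation``
    maps a mutant condition name to either a fraction of the regulated
    genes or an explicit list of gene ids whose planted effect is reverted
    toward control (fully by default; ``reversion`` < 1 leaves a partial
    effect).
    """

    n_genes: int = 10_000
    conditions: list[str] = field(default_factory=lambda: ["control", "foxp3"])
    n_replicates: int = 2
    pi_LE: float = 0.5
    mu_LE: float = -2.0
    sigma_LE: float = 1.0
    mu_HE: float = 6.0
    sigma_HE: float = 1.0
    frac_zero: float = 0.1
    n_regulated: int = 0
    frac_up: float = 0.5
    effect_log2fc_range: tuple[float, float] = (2.0, 4.0)
    mutant_dysregulation: dict = field(default_factory=dict)
    reversion: float = 1.0
    nb_dispersion: float | tuple[float, float] = (0.05, 5.0)
    library_size_range: tuple[float, float] = (1e7, 3e7)
    gene_length_range: tuple[int, int] = (500, 5000)
    seed: int = 0

    # conditions whose true means carry the planted factor effect
    effect_conditions: tuple[str, ...] = ("foxp3", "treg")
    # conditions at the control baseline
    baseline_conditions: tuple[str, ...] = ("control", "naive_th")

    def validate(self) -> None:
        for name, v in (("pi_LE", self.pi_LE), ("frac_zero", self.frac_zero),
                        ("frac_up", self.frac_up)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_regulated > self.n_genes * (1.0 - self.frac_zero):
            raise ValueError("n_regulated exceeds the number of expressed genes")
        lo, hi = self.effect_log2fc_range
        if lo <= 0 or hi < lo:
            raise ValueError("effect range must be strictly positive")
        known = set(self.effect_conditions) | set(self.baseline_conditions)
        for m in self.mutant_dysregulation:
            if m in known:
                raise ValueError(f"mutant condition {m!r} clashes with a baseline/effect condition")
            if m not in self.conditions:
                raise ValueError(f"mutant condition {m!r} not in conditions list")
        for c in self.conditions:
            if c not in known and c not in self.mutant_dysregulation:
                raise ValueError(f"condition {c!r} has no defined expression model")


@dataclass
class GroundTruth:
    """Planted truth of one simulated study."""

    regulated: pd.Series            # direction ('up'/'down') indexed by regulated gene id
    dysregulated: dict[str, list[str]]  # mutant condition -> gene ids reverted
    true_fpkm: pd.DataFrame         # genes x conditions, linear FPKM (0 = never expressed)
    component: pd.Series = None     # baseline mixture component per gene: NE/LE/HE

    @property
    def regulated_genes(self) -> set[str]:
        return set(self.regulated.index)

    def to_json(self, path: str) -> None:
        payload = {
            "regulated": {g: d for g, d in self.regulated.items()},
            "dysregulated": {m: sorted(v) for m, v in self.dysregulated.items()},
            "true_fpkm": {c: self.true_fpkm[c].round(6).to_dict() for c in self.true_fpkm},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _alpha_of_mean(nb_dispersion, mu: np.ndarray) -> np.ndarray:
    if isinstance(nb_dispersion, (int, float)):
        return np.full_like(mu, float(nb_dispersion))
    a, b = nb_dispersion
    return a + b / np.maximum(mu, 1e-8)


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw a seeded count matrix and its planted ground truth.

    Identical config and seed give bit-identical output.  Regulated genes
    are drawn from the high-expression mode so that planted effects are
    observable through the downstream INT/HE expression filter.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_structure, rng_library, rng_counts = [np.random.default_rng(s) for s in ss.spawn(3)]

    n = config.n_genes
    genes = [f"gene{i:05d}" for i in range(n)]

    # never-expressed genes: exact count, planted deterministically
    n_zero = int(round(config.frac_zero * n))
    perm = rng_structure.permutation(n)
    zero_idx = np.sort(perm[:n_zero])
    expressed_idx = np.sort(perm[n_zero:])

    # baseline log2 FPKM from the two-mode mixture
    base = np.full(n, -np.inf)
    is_le = rng_structure.random(len(expressed_idx)) < config.pi_LE
    draw = np.where(
        is_le,
        rng_structure.normal(config.mu_LE, config.sigma_LE, len(expressed_idx)),
        rng_structure.normal(config.mu_HE, config.sigma_HE, len(expressed_idx)),
    )
    base[expressed_idx] = draw

    # regulated genes come from the HE mode
    he_pool = expressed_idx[~is_le]
    if config.n_regulated > len(he_pool):
        raise ValueError("not enough high-mode genes to plant the regulated set")
    reg_idx = np.sort(rng_structure.choice(he_pool, size=config.n_regulated, replace=False))
    n_up = int(round(config.frac_up * config.n_regulated))
    up_mask = np.zeros(config.n_regulated, dtype=bool)
    up_order = rng_structure.permutation(config.n_regulated)
    up_mask[up_order[:n_up]] = True
    effects = rng_structure.uniform(*config.effect_log2fc_range, size=config.n_regulated)
    signed = np.where(up_mask, effects, -effects)

    # per-condition true log2 FPKM
    cond_log2 = {}
    shift = np.zeros(n)
    shift[reg_idx] = signed
    for c in config.conditions:
        if c in config.baseline_conditions:
            cond_log2[c] = base.copy()
        elif c in config.effect_conditions:
            cond_log2[c] = base + shift
        # mutants handled below
    dysregulated: dict[str, list[str]] = {}
    taken = np.zeros(config.n_regulated, dtype=bool)  # for disjoint integer draws
    for m, entry in config.mutant_dysregulation.items():
        if isinstance(entry, bool):
            raise ValueError("dysregulation entry must be a fraction, count or gene list")
        if isinstance(entry, int):
            # integer counts are drawn disjointly across mutants, in config order
            free = np.flatnonzero(~taken)
            if entry > len(free):
                raise ValueError(f"not enough unassigned regulated genes for {m!r}")
            pick = np.sort(rng_structure.choice(free, size=entry, replace=False))
            taken[pick] = True
        elif isinstance(entry, float):
            if not 0.0 <= entry <= 1.0:
                raise ValueError("dysregulation fraction must be in [0, 1]")
            k = int(round(entry * config.n_regulated))
            pick = np.sort(rng_structure.choice(config.n_regulated, size=k, replace=False))
        else:
            wanted = set(entry)
            unknown = wanted - {genes[i] for i in reg_idx}
            if unknown:
                raise ValueError(f"dysregulated genes not in the regulated set: {sorted(unknown)}")
            pick = np.array([j for j, i in enumerate(reg_idx) if genes[i] in wanted], dtype=int)
        mut_shift = shift.copy()
        mut_shift[reg_idx[pick]] = signed[pick] * (1.0 - config.reversion)
        cond_log2[m] = base + mut_shift
        dysregulated[m] = [genes[i] for i in reg_idx[pick]]

    true_fpkm = pd.DataFrame(
        {c: np.where(np.isfinite(v), 2.0 ** np.where(np.isfinite(v), v, 0.0), 0.0)
         for c, v in cond_log2.items()},
        index=genes,
    )

    # samples, lengths, library sizes
    lengths = rng_library.integers(config.gene_length_range[0],
                                   config.gene_length_range[1] + 1, size=n)
    sample_ids, cond_of = [], []
    for c in config.conditions:
        for r in range(1, config.n_replicates + 1):
            sample_ids.append(f"{c}_r{r}")
            cond_of.append(c)
    libsizes = rng_library.uniform(*config.library_size_range, size=len(sample_ids))

    counts = np.zeros((n, len(sample_ids)), dtype=np.int64)
    kb = lengths / 1e3
    for j, (s, c) in enumerate(zip(sample_ids, cond_of)):
        mu = true_fpkm[c].to_numpy() * kb * (libsizes[j] / 1e6)
        pos = mu > 0
        alpha = _alpha_of_mean(config.nb_dispersion, mu[pos])
        r_param = 1.0 / np.maximum(alpha, 1e-12)
        p_param = r_param / (r_param + mu[pos])
        counts[pos, j] = rng_counts.negative_binomial(r_param, p_param)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
        gene_lengths=pd.Series(lengths, index=genes, dtype=float),
        metadata=pd.DataFrame(
            {"condition": cond_of,
             "replicate": [int(s.rsplit("_r", 1)[1]) for s in sample_ids]},
            index=pd.Index(sample_ids, name="sample"),
        ),
    )
    component = np.full(n, "NE", dtype=object)
    component[expressed_idx[is_le]] = "LE"
    component[expressed_idx[~is_le]] = "HE"
    truth = GroundTruth(
        regulated=pd.Series(np.where(up_mask, "up", "down"),
                            index=[genes[i] for i in reg_idx], name="direction"),
        dysregulated=dysregulated,
        true_fpkm=true_fpkm,
        component=pd.Series(component, index=genes, name="component"),
    )
    return cm, truth


def simulate_msa(n_sequences: int, length: int,
                 conserved_blocks: list[tuple[tuple[int, int], float]],
                 proline_positions: list[int], seed: int = 0,
                 background_identity: float = 0.4,
                 bf_high_range: tuple[float, float] = (60.0, 120.0),
                 bf_low_range: tuple[float, float] = (0.0, 20.0)):
    """Simulate a gapless protein MSA and matching per-codon Bayes factors.

    Each non-reference sequence keeps the reference residue with
    probability equal to the local identity level (block level inside
    conserved blocks, ``background_identity`` outside) and otherwise
    substitutes a uniformly random different residue.  The reference
    carries prolines exactly at ``proline_positions``.  Bayes factors are
    drawn from ``bf_high_range`` inside the conserved blocks and
    ``bf_low_range`` outside.

    Returns ``(ProteinMSA, pd.Series)``.
    """
    from foxdissect.conservation import ProteinMSA

    if n_sequences < 2 or length < 1:
        raise ValueError("need >= 2 sequences of positive length")
    level = np.full(length, float(background_identity))
    assigned = np.full(length, np.nan)
    for (start, end), ident in conserved_blocks:
        if not (1 <= start <= end <= length):
            raise ValueError(f"block [{start},{end}] outside [1,{length}]")
        sl = slice(start - 1, end)
        prev = assigned[sl]
        clash = np.isfinite(prev) & (prev != ident)
        if clash.any():
            raise ValueError("overlapping blocks with conflicting identity levels")
        assigned[sl] = ident
        level[sl] = ident
    for p in proline_positions:
        if not 1 <= p <= length:
            raise ValueError("proline position outside sequence")

    rng = np.random.default_rng(seed)
    ref = rng.choice(_AMINO, size=length)  # proline-free background
    for p in proline_positions:
        ref[p - 1] = "P"

    rows = [ref.copy()]
    for _ in range(n_sequences - 1):
        keep = rng.random(length) < level
        seq = ref.copy()
        subs = np.flatnonzero(~keep)
        for i in subs:
            choices = _AMINO_ALL[_AMINO_ALL != ref[i]]
            seq[i] = rng.choice(choices)
        rows.append(seq)

    ids = ["ref"] + [f"sp{i}" for i in range(1, n_sequences)]
    msa = ProteinMSA(ids=ids, rows=["".join(r) for r in rows], reference_id="ref")

    in_block = np.isfinite(assigned)
    bf = np.where(in_block,
                  rng.uniform(*bf_high_range, size=length),
                  rng.uniform(*bf_low_range, size=length))
    bf_table = pd.Series(bf, index=pd.RangeIndex(1, length + 1, name="codon"), name="bf")
    return msa, bf_table


def write_bf_table(bf: pd.Series, path: str) -> None:
    bf.rename("bayes_factor").to_csv(path, sep="\t", index_label="codon")
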