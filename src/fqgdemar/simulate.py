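"""Seeded generators for ground-truth-annotated pipeline inputs.

The expression generator emulates a 2x2 (age x sex) post-mortem hippocampus
cohort measured on a high-density oligonucleotide array: a Gaussian core of
null probes plus a minority of probes carrying pure-age, pure-sex or
interaction effects injected on the +/-1-coded linear scale of the bi-linear
factorial model (log2 units). Genes carry several probes, and a small
discordance probability gives probes of one gene opposite effect signs, which
is what the downstream intersection QC is designed to catch.

Companion generators produce a typed interactome (genetic and metabolic edges
directed, protein-protein undirected) and GMT-style gene-set collections over
the simulated gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, StudyDesign, code_design

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_interactome",
    "simulate_genesets",
]

EFFECT_CLASSES = (
    "null",
    "age+",
    "age-",
    "sex+",
    "sex-",
    "interaction+",
    "interaction-",
)


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    ``group_sizes`` is ordered (A-B-, A-B+, A+B-, A+B+) =
    (Younger Men, Younger Women, Older Men, Older Women); the default
    (9, 9, 15, 14) mirrors the stratification of the analyzed cohort.
    ``frac_*`` are fractions of probes carrying each effect;
    ``effect_size_mean``/``sd`` parameterize the injected coefficient
    magnitude in log2 units. ``up_down_asymmetry_age`` is the up:down odds of
    a positive age coefficient (Older-up), ``up_down_asymmetry_sex`` the
    women:men odds of a positive sex coefficient. ``p_discordant`` is the
    per-probe probability that a probe of an affected gene flips sign
    relative to its gene.
    """

    n_probes: int = 20000
    n_genes: int = 12000
    probes_per_gene: tuple[int, int] = (1, 4)
    group_sizes: tuple[int, int, int, int] = (9, 9, 15, 14)
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.5
    frac_age: float = 0.05
    frac_sex: float = 0.05
    frac_interaction: float = 0.05
    effect_size_mean: float = 2.0
    effect_size_sd: float = 0.25
    up_down_asymmetry_age: float = 1.75
    up_down_asymmetry_sex: float = 2.0
    p_discordant: float = 0.05
    age_cutoff: float = 64.0
    seed: int = 0

    def validate(self) -> None:
        fracs = (self.frac_age, self.frac_sex, self.frac_interaction)
        if any(f < 0 for f in fracs) or sum(fracs) > 1:
            raise ConfigurationError("effect fractions must be >= 0 and sum to <= 1")
        if self.n_probes <= 0 or self.n_genes <= 0:
            raise ConfigurationError("counts must be positive")
        lo, hi = self.probes_per_gene
        if not (1 <= lo <= hi):
            raise ConfigurationError("probes_per_gene must satisfy 1 <= min <= max")
        if any(g <= 0 for g in self.group_sizes):
            raise ConfigurationError("every design cell needs at least one sample")
        if self.noise_sd <= 0 or self.baseline_sd < 0:
            raise ConfigurationError("noise_sd must be > 0 and baseline_sd >= 0")
        if not (0 <= self.p_discordant <= 1):
            raise ConfigurationError("p_discordant must be in [0, 1]")
        if self.n_genes * hi < self.n_probes:
            raise ConfigurationError(
                "n_genes x max(probes_per_gene) cannot cover n_probes"
            )

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Per-probe truth labels plus the class counts recorded at generation."""

    table: pd.DataFrame  # probe_id (index), gene_id, true_class, true_effect
    class_counts: dict[str, int] = field(default_factory=dict)

    def probes_of_class(self, cls: str) -> pd.Index:
        return self.table.index[self.table["true_class"] == cls]


def _assign_genes(cfg: SimulationConfig, rng: np.random.Generator):
    lo, hi = cfg.probes_per_gene
    mult = rng.integers(lo, hi + 1, size=cfg.n_genes)
    total = int(mult.sum())
    if total < cfg.n_probes:
        raise ConfigurationError(
            f"drawn probe multiplicities cover only {total} of {cfg.n_probes} probes; "
            "increase n_genes or probes_per_gene"
        )
    gene_ids = np.repeat(np.arange(cfg.n_genes), mult)[: cfg.n_probes]
    return gene_ids, mult


def _design_from_config(cfg: SimulationConfig, rng: np.random.Generator) -> StudyDesign:
    cells = [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    rows = []
    k = 0
    for (i, j), size in zip(cells, cfg.group_sizes):
        for _ in range(size):
            if i < 0:
                age = int(rng.integers(20, int(cfg.age_cutoff) + 1))
            else:
                age = int(rng.integers(int(cfg.age_cutoff) + 2, 100))
            rows.append(
                {
                    "sample_id": f"S{k:03d}",
                    "age_years": age,
                    "sex": "female" if j > 0 else "male",
                }
            )
            k += 1
    return code_design(pd.DataFrame(rows), age_cutoff=cfg.age_cutoff)


def simulate_expression(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, StudyDesign, GroundTruth]:
    """Draw a log2 expression matrix with known per-probe effect classes.

    Each probe value is ``baseline + alpha*i + beta*j + gamma*i*j + noise``
    with exactly one of (alpha, beta, gamma) nonzero according to the probe's
    true class; intensities are clipped to stay positive. Identical
    configurations (including seed) give bit-identical outputs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    design = _design_from_config(cfg, rng)
    i = design.table["age_code"].to_numpy()
    j = design.table["sex_code"].to_numpy()
    n_samples = len(i)

    gene_idx, _ = _assign_genes(cfg, rng)
    n_used_genes = int(gene_idx.max()) + 1

    # factor assignment at the gene level so probes of one gene share a factor
    probs = [cfg.frac_age, cfg.frac_sex, cfg.frac_interaction]
    probs.append(1.0 - sum(probs))
    gene_factor = rng.choice(4, size=n_used_genes, p=probs)  # 0 age, 1 sex, 2 inter, 3 null

    def sign_probs(odds: float) -> float:
        return odds / (1.0 + odds)

    p_pos = {0: sign_probs(cfg.up_down_asymmetry_age), 1: sign_probs(cfg.up_down_asymmetry_sex), 2: 0.5}
    gene_sign = np.zeros(n_used_genes, dtype=int)
    for f, p in p_pos.items():
        sel = gene_factor == f
        gene_sign[sel] = np.where(rng.random(sel.sum()) < p, 1, -1)

    probe_factor = gene_factor[gene_idx]
    probe_sign = gene_sign[gene_idx].astype(float)
    affected = probe_factor != 3
    flip = rng.random(cfg.n_probes) < cfg.p_discordant
    probe_sign[affected & flip] *= -1

    magnitude = np.abs(rng.normal(cfg.effect_size_mean, cfg.effect_size_sd, cfg.n_probes))
    effect = np.where(affected, probe_sign * magnitude, 0.0)

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_probes)
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_probes, n_samples))

    code = np.empty((cfg.n_probes, n_samples))
    code[probe_factor == 0] = i
    code[probe_factor == 1] = j
    code[probe_factor == 2] = i * j
    code[probe_factor == 3] = 0.0

    values = baseline[:, None] + effect[:, None] * code + noise
    values = np.clip(values, 1e-3, None)

    probe_ids = [f"P{k:06d}_at" for k in range(cfg.n_probes)]
    gene_symbols = np.array([f"G{g:05d}" for g in range(n_used_genes)])[gene_idx]
    factor_name = np.array(["age", "sex", "interaction", "null"])[probe_factor]
    sign_name = np.where(probe_sign > 0, "+", "-")
    true_class = np.where(affected, np.char.add(factor_name, sign_name), "null")

    truth_table = pd.DataFrame(
        {
            "gene_id": gene_symbols,
            "true_class": true_class,
            "true_effect": effect,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    counts = truth_table["true_class"].value_counts().to_dict()

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=design.table["sample_id"].tolist()),
        annotation=pd.Series(gene_symbols, index=probe_ids, dtype=object),
    )
    return matrix, design, GroundTruth(table=truth_table, class_counts=counts)


def simulate_interactome(
    n_nodes: int,
    edge_density: float,
    seed: int,
    nodes: list[str] | None = None,
    type_probs: tuple[float, float, float] = (0.3, 0.4, 0.3),
) -> pd.DataFrame:
    """Erdos-Renyi typed interactome over ``n_nodes`` gene symbols.

    Each unordered pair carries an edge with probability ``edge_density``;
    the edge type is drawn from ``type_probs`` over (genetic, pp, metabolic).
    Genetic and metabolic edges get a random direction; pp edges are
    undirected (stored once, source < target).
    """
    if n_nodes < 2:
        raise ConfigurationError("an interactome needs at least 2 nodes")
    if not (0 < edge_density <= 1):
        raise ConfigurationError("edge_density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if nodes is None:
        nodes = [f"G{k:05d}" for k in range(n_nodes)]
    elif len(nodes) != n_nodes:
        raise ConfigurationError("len(nodes) must equal n_nodes")
    iu, ju = np.triu_indices(n_nodes, k=1)
    keep = rng.random(iu.size) < edge_density
    iu, ju = iu[keep], ju[keep]
    etypes = rng.choice(["genetic", "pp", "metabolic"], size=iu.size, p=list(type_probs))
    flip = rng.random(iu.size) < 0.5
    rows = []
    for a, b, t, fl in zip(iu, ju, etypes, flip):
        u, v = nodes[a], nodes[b]
        if t == "pp":
            rows.append((min(u, v), t, max(u, v)))
        else:
            rows.append((v, t, u) if fl else (u, t, v))
    return pd.DataFrame(rows, columns=["source", "edge_type", "target"])


def simulate_genesets(
    genes: list[str],
    n_terms: int,
    term_size: tuple[int, int],
    seed: int,
) -> dict[str, set[str]]:
    """Random distinct gene subsets over the given universe, GMT-style."""
    if not genes:
        raise ConfigurationError("gene universe is empty")
    lo, hi = term_size
    if not (1 <= lo <= hi):
        raise ConfigurationError("term_size must satisfy 1 <= min <= max")
    if hi > len(genes):
        raise ConfigurationError("term_size max exceeds the gene universe")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    terms: dict[str, set[str]] = {}
    seen: set[frozenset[str]] = set()
    attempts = 0
    k = 0
    while len(terms) < n_terms:
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(genes, size=size, replace=False))
        attempts += 1
        if members in seen:
            if attempts > 50 * n_terms + 100:
                raise ConfigurationError(
                    "cannot draw the requested number of distinct terms"
                )
            continue
        seen.add(members)
        terms[f"T{k:04d}"] = set(members)
        k += 1
    return terms
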