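"""Synthetic families of differential-expression result tables.

The generator emulates the statistical structure that the comparison
methods probe, not RNA-seq counts: a gene universe in which a *shared
pool* of genes responds to the target factor in every experiment, plus
optional *batch pools* — disjoint gene sets that respond only in the
experiments of one batch, mimicking non-target (batch) factors.  Each
eligible gene becomes a DEG in an experiment independently with its
pool's inclusion probability; DEGs receive a signed log2 fold change
around ``effect_size`` and an adjusted p placed strictly below the
calling threshold, non-DEGs a near-zero logFC and an adjusted p strictly
above it.  Ground truth is therefore exact by construction: calling DEGs
at ``alpha`` recovers the planted assignments gene for gene.

Defaults describe a mid-sized bulk-transcriptomics compendium: a
10,000-gene universe, seven experiments, a 1,000-gene responsive pool
and a 30 % per-experiment inclusion probability (so any two experiments
share roughly a third of their DEGs), |logFC| centred on 2 with 0.25 SD
noise around 0 for unresponsive genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .profile_io import ExperimentProfile

__all__ = [
    "BatchConfig",
    "SimulationConfig",
    "SimulationResult",
    "simulate_profiles",
    "write_simulation",
    "load_config",
]


@dataclass
class BatchConfig:
    """One batch: ``n_experiments`` experiments sharing a private pool of
    ``pool_size`` genes, each included per experiment with ``deg_prob``."""

    n_experiments: int
    pool_size: int
    deg_prob: float

    def validate(self) -> None:
        if self.n_experiments < 1:
            raise ValueError("batch n_experiments must be >= 1")
        if self.pool_size < 0:
            raise ValueError("batch pool_size must be >= 0")
        if not 0.0 <= self.deg_prob <= 1.0:
            raise ValueError("batch deg_prob must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Parameters of one simulated family of DE result tables.

    Without ``batches``, ``m`` experiments all draw from the shared pool
    only (a homogeneous family).  With ``batches``, the experiments are
    partitioned into the listed batches (m becomes the sum of their
    sizes) and each batch adds its own disjoint pool on top of the
    shared one; set ``shared_pool_size=0`` for fully disjoint batches.
    """

    n_genes: int = 10_000
    m: int = 7
    shared_pool_size: int = 1_000
    deg_prob: float = 0.3
    batches: list[BatchConfig] | None = None
    effect_size: float = 2.0
    noise_sd: float = 0.25
    alpha: float = 0.05
    seed: int | None = None

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 <= self.deg_prob <= 1.0:
            raise ValueError("deg_prob must be in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ValueError("effect_size and noise_sd must be >= 0")
        if self.shared_pool_size < 0:
            raise ValueError("shared_pool_size must be >= 0")
        total_pool = self.shared_pool_size
        if self.batches is not None:
            for b in self.batches:
                b.validate()
            total_pool += sum(b.pool_size for b in self.batches)
        if total_pool > self.n_genes:
            raise ValueError(
                f"pools need {total_pool} genes but universe has {self.n_genes}"
            )
        if self.n_experiments < 2:
            raise ValueError("need at least 2 experiments")

    @property
    def n_experiments(self) -> int:
        if self.batches is not None:
            return sum(b.n_experiments for b in self.batches)
        return self.m


@dataclass
class SimulationResult:
    """Profiles plus the exact planted truth."""

    profiles: list[ExperimentProfile]
    truth: dict[str, frozenset[str]]  # experiment_id -> planted DEG set
    batch_of: dict[str, int]  # experiment_id -> batch index (0 = no batches)
    pools: dict[str, list[str]]  # pool name -> gene ids
    config: SimulationConfig


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def simulate_profiles(config: SimulationConfig) -> SimulationResult:
    """Generate one family of profiles; deterministic under ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    gene_index = pd.Index(genes, name="gene_id")

    # pools occupy consecutive blocks of the universe: shared first, then
    # one block per batch — disjoint by construction
    cursor = 0
    shared_pos = np.arange(cursor, cursor + config.shared_pool_size)
    cursor += config.shared_pool_size
    pools: dict[str, list[str]] = {"shared": [genes[i] for i in shared_pos]}

    batch_specs: list[tuple[int, np.ndarray, float]] = []  # (n_exp, pool_pos, prob)
    if config.batches is not None:
        for bi, b in enumerate(config.batches, start=1):
            pool_pos = np.arange(cursor, cursor + b.pool_size)
            cursor += b.pool_size
            pools[f"batch{bi}"] = [genes[i] for i in pool_pos]
            batch_specs.append((b.n_experiments, pool_pos, b.deg_prob))
    else:
        batch_specs.append((config.m, np.arange(0), 0.0))

    # response direction is a property of the gene, drawn once: a regulated
    # gene moves the same way in every experiment where it responds, so
    # families are coherent in fold-change space while both directions occur
    gene_sign = rng.choice([-1.0, 1.0], size=config.n_genes)

    profiles: list[ExperimentProfile] = []
    truth: dict[str, frozenset[str]] = {}
    batch_of: dict[str, int] = {}
    exp_no = 0
    for bi, (n_exp, pool_pos, prob) in enumerate(batch_specs, start=1):
        for _ in range(n_exp):
            exp_no += 1
            exp_id = f"exp{exp_no:02d}"
            is_deg = np.zeros(config.n_genes, dtype=bool)
            if len(shared_pos):
                is_deg[shared_pos] = rng.random(len(shared_pos)) < config.deg_prob
            if len(pool_pos):
                is_deg[pool_pos] = rng.random(len(pool_pos)) < prob

            logfc = rng.normal(0.0, config.noise_sd, size=config.n_genes)
            n_deg = int(is_deg.sum())
            logfc[is_deg] = gene_sign[is_deg] * rng.normal(
                config.effect_size, config.noise_sd, size=n_deg
            )
            # padj placed on the correct side of alpha by construction, with
            # margin so both strict and inclusive calling recover the truth
            padj = rng.uniform(1.02 * config.alpha, 1.0, size=config.n_genes)
            padj[is_deg] = rng.uniform(0.0, 0.98 * config.alpha, size=n_deg)

            df = pd.DataFrame({"logfc": logfc, "padj": padj}, index=gene_index)
            profiles.append(
                ExperimentProfile(exp_id, df, {"batch": bi if config.batches else 0})
            )
            truth[exp_id] = frozenset(np.array(genes)[is_deg])
            batch_of[exp_id] = bi if config.batches else 0

    return SimulationResult(profiles, truth, batch_of, pools, config)


def write_simulation(result: SimulationResult, outdir: str | Path) -> dict[str, str]:
    """Write per-experiment TSVs in the format ``read_result_table`` reads,
    the config as YAML, and the planted truth as ``truth.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inventory: dict[str, str] = {}
    for p in result.profiles:
        path = outdir / f"{p.experiment_id}.tsv"
        out = p.data.rename(columns={"logfc": "logFC", "padj": "padj"})
        out.to_csv(path, sep="\t", index_label="gene_id")
        inventory[p.experiment_id] = str(path)

    cfg = result.config
    cfg_dict = {
        "n_genes": cfg.n_genes,
        "m": cfg.m,
        "shared_pool_size": cfg.shared_pool_size,
        "deg_prob": cfg.deg_prob,
        "effect_size": cfg.effect_size,
        "noise_sd": cfg.noise_sd,
        "alpha": cfg.alpha,
        "seed": cfg.seed,
        "batches": None
        if cfg.batches is None
        else [
            {
                "n_experiments": b.n_experiments,
                "pool_size": b.pool_size,
                "deg_prob": b.deg_prob,
            }
            for b in cfg.batches
        ],
    }
    cfg_path = outdir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)
    inventory["config"] = str(cfg_path)

    rows = []
    for exp_id, degs in result.truth.items():
        for g in sorted(degs):
            rows.append({"experiment_id": exp_id, "gene_id": g})
    truth_path = outdir / "truth.tsv"
    pd.DataFrame(rows, columns=["experiment_id", "gene_id"]).to_csv(
        truth_path, sep="\t", index=False
    )
    inventory["truth"] = str(truth_path)
    return inventory


def load_config(path: str | Path) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from YAML (or JSON, a YAML subset)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    batches = raw.pop("batches", None)
    if batches is not None:
        batches = [BatchConfig(**b) for b in batches]
    cfg = SimulationConfig(batches=batches, **raw)
    cfg.validate()
    return cfg
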