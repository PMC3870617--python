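"""Synthetic pipeline inputs with known ground truth.

The study design being emulated is a serum miRNA microarray comparison of
three TCM syndrome groups of hepatocellular carcinoma patients (LGDHS,
LDSDS, LKYDS — 3 patients each) against 7 healthy controls. No raw arrays
are publicly deposited, so every downstream stage is validated on simulated
inputs where the truth is known:

* an expression matrix on the log2 scale with planted differentially
  expressed miRNAs and heteroscedastic per-miRNA noise whose variance is
  drawn from the same inverse-gamma law the RVM test assumes (so calibration
  tests of the test are meaningful);
* nine binary-hit target-prediction tables plus one score-valued table
  (miRDB-style scores in [0, 100]) with a tunable probability that a true
  miRNA-target pair satisfies the consensus rule (>=2 binary programs AND
  score > 60);
* a TarBase-style validated-interaction table;
* a GMT gene-set collection with optional sets planted to be enriched among
  the targets of planted up-regulated miRNAs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix, write_expression

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_prediction_tables",
    "simulate_gene_sets",
    "simulate_all",
    "write_simulation",
]

NORMAL = "Normal"
SYNDROMES = ("LGDHS", "LDSDS", "LKYDS")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults mirror the study design.

    ``inv_gamma_shape``/``inv_gamma_scale`` are (a, b) of the precision law
    1/sigma^2 ~ Gamma(shape a, scale b); see the rvm module. ``de_log2fc``
    is the planted shift in log2 units. ``program_agreement`` is the
    probability a true target pair is emitted so that the consensus rule
    recovers it.
    """

    n_mirnas: int = 400
    n_genes: int = 2000
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {NORMAL: 7, "LGDHS": 3, "LDSDS": 3, "LKYDS": 3}
    )
    n_de_per_group: int = 40
    de_log2fc: float = 2.0
    frac_up: float = 0.5
    inv_gamma_shape: float = 3.0
    inv_gamma_scale: float = 1.0
    prediction_programs: int = 10
    program_agreement: float = 0.9
    targets_per_mirna: int = 8
    n_decoy_pairs: int | None = None
    validated_fraction: float = 0.05
    n_gene_sets: int = 50
    gene_set_size: tuple[int, int] = (20, 80)
    planted_enriched_sets: int = 5
    planted_set_signal_frac: float = 0.6
    score_threshold: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        if NORMAL not in self.group_sizes:
            raise ValueError(f"group_sizes must contain the {NORMAL!r} group")
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("all group sizes must be positive")
        if self.n_mirnas <= 0 or self.n_genes <= 0:
            raise ValueError("n_mirnas and n_genes must be positive")
        if not (0 <= self.n_de_per_group <= self.n_mirnas):
            raise ValueError("n_de_per_group must be in [0, n_mirnas]")
        if not np.isfinite(self.de_log2fc):
            raise ValueError("de_log2fc must be finite")
        if self.inv_gamma_shape <= 1 or self.inv_gamma_scale <= 0:
            raise ValueError("require inverse-gamma shape > 1 and scale > 0")
        if not (0.0 <= self.program_agreement <= 1.0):
            raise ValueError("program_agreement must be in [0, 1]")
        if self.planted_enriched_sets > self.n_gene_sets:
            raise ValueError("planted_enriched_sets must be <= n_gene_sets")

    @property
    def syndrome_groups(self) -> list[str]:
        return [g for g in self.group_sizes if g != NORMAL]


@dataclass
class GroundTruth:
    """What was planted: DE miRNAs per group (with direction), the true
    miRNA->target map, and the ids of planted-enriched gene sets."""

    de_mirnas: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    true_targets: dict[str, set[str]] = field(default_factory=dict)
    enriched_set_ids: set[str] = field(default_factory=set)

    def de_ids(self, group: str) -> set[str]:
        return {m for m, _ in self.de_mirnas.get(group, set())}

    def up_ids(self, group: str) -> set[str]:
        return {m for m, d in self.de_mirnas.get(group, set()) if d == "up"}

    def to_json(self) -> str:
        payload = {
            "de_mirnas": {g: sorted(list(v)) for g, v in self.de_mirnas.items()},
            "true_targets": {m: sorted(v) for m, v in self.true_targets.items()},
            "enriched_set_ids": sorted(self.enriched_set_ids),
        }
        return json.dumps(payload, indent=1)


def _mirna_ids(n: int) -> list[str]:
    return [f"miR-{i:04d}" for i in range(1, n + 1)]


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i:05d}" for i in range(1, n + 1)]


def simulate_expression(config: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the log2 expression matrix and its planted ground truth.

    Per-miRNA baseline levels are Uniform(6, 12) on the log2 scale (typical
    microarray intensities); noise is Gaussian with per-miRNA variance drawn
    as 1/sigma^2 ~ Gamma(a, scale b). Each syndrome group gets its own draw
    of ``n_de_per_group`` DE miRNAs (so groups can share DE miRNAs, as the
    real syndromes do), shifted by +/- ``de_log2fc`` in that group only;
    directions are half up / half down by default.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    mirnas = _mirna_ids(config.n_mirnas)
    sample_ids: list[str] = []
    group_of: dict[str, str] = {}
    for g, n in config.group_sizes.items():
        for i in range(1, n + 1):
            sid = f"{g}_{i}"
            sample_ids.append(sid)
            group_of[sid] = g

    baseline = rng.uniform(6.0, 12.0, size=config.n_mirnas)
    precision = rng.gamma(shape=config.inv_gamma_shape,
                          scale=config.inv_gamma_scale,
                          size=config.n_mirnas)
    sigma = 1.0 / np.sqrt(precision)

    n_total = len(sample_ids)
    noise = rng.standard_normal((config.n_mirnas, n_total)) * sigma[:, None]
    values = baseline[:, None] + noise

    truth = GroundTruth()
    col_idx = {s: j for j, s in enumerate(sample_ids)}
    for g in config.syndrome_groups:
        chosen = rng.choice(config.n_mirnas, size=config.n_de_per_group, replace=False)
        n_up = int(round(config.frac_up * config.n_de_per_group))
        planted: set[tuple[str, str]] = set()
        cols = [col_idx[s] for s in sample_ids if group_of[s] == g]
        for rank, i in enumerate(chosen):
            direction = "up" if rank < n_up else "down"
            shift = config.de_log2fc if direction == "up" else -config.de_log2fc
            values[i, cols] += shift
            planted.add((mirnas[i], direction))
        truth.de_mirnas[g] = planted

    df = pd.DataFrame(values, index=pd.Index(mirnas, name="mirna_id"), columns=sample_ids)
    groups = pd.Series({s: group_of[s] for s in sample_ids})
    return ExpressionMatrix(values=df, groups=groups), truth


def simulate_prediction_tables(
    mirna_ids: list[str],
    gene_ids: list[str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, dict[str, set[str]]], dict[tuple[str, str], float],
           set[tuple[str, str]], dict[str, set[str]]]:
    """Simulate 9 binary prediction programs, one scored program and a
    validated-interaction table.

    Returns ``(binary_programs, scores, validated, true_targets)``. A true
    pair is made consensus-recoverable (>=2 binary hits AND score > 60) with
    probability ``program_agreement``; otherwise, and for all decoy pairs,
    the construction guarantees at least one consensus condition fails.
    """
    if not mirna_ids or not gene_ids:
        raise ValueError("mirna_ids and gene_ids must be non-empty")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)

    n_binary = config.prediction_programs - 1
    program_names = [f"prog{i+1}" for i in range(n_binary)]
    binary: dict[str, dict[str, set[str]]] = {p: {} for p in program_names}
    scores: dict[tuple[str, str], float] = {}
    thr = config.score_threshold

    true_targets: dict[str, set[str]] = {}
    all_true_pairs: set[tuple[str, str]] = set()
    for m in mirna_ids:
        k = min(config.targets_per_mirna, len(gene_ids))
        tg = rng.choice(len(gene_ids), size=k, replace=False)
        true_targets[m] = {gene_ids[i] for i in tg}
        all_true_pairs.update((m, gene_ids[i]) for i in tg)

    def add_hit(program: str, m: str, g: str) -> None:
        binary[program].setdefault(m, set()).add(g)

    def emit_recoverable(m: str, g: str) -> None:
        # guaranteed >=2 binary programs; extra programs join with prob 0.3
        progs = rng.choice(n_binary, size=2, replace=False).tolist()
        extras = np.nonzero(rng.random(n_binary) < 0.3)[0]
        for j in set(progs) | set(extras.tolist()):
            add_hit(program_names[j], m, g)
        scores[(m, g)] = float(rng.uniform(thr + 1.0, 100.0))

    def emit_failing(m: str, g: str) -> None:
        # guarantee at least one consensus condition fails
        mode = rng.integers(3)
        if mode == 0:      # <=1 binary hit, low score
            if rng.random() < 0.5:
                add_hit(program_names[int(rng.integers(n_binary))], m, g)
            scores[(m, g)] = float(rng.uniform(0.0, thr))
        elif mode == 1:    # >=2 binary hits but score <= threshold
            for j in rng.choice(n_binary, size=2, replace=False):
                add_hit(program_names[int(j)], m, g)
            scores[(m, g)] = float(rng.uniform(0.0, thr))
        else:              # high score but <=1 binary hit
            if rng.random() < 0.5:
                add_hit(program_names[int(rng.integers(n_binary))], m, g)
            scores[(m, g)] = float(rng.uniform(thr + 1.0, 100.0))

    for (m, g) in sorted(all_true_pairs):
        if rng.random() < config.program_agreement:
            emit_recoverable(m, g)
        else:
            emit_failing(m, g)

    n_decoys = config.n_decoy_pairs
    if n_decoys is None:
        n_decoys = len(all_true_pairs)
    emitted = 0
    while emitted < n_decoys:
        m = mirna_ids[int(rng.integers(len(mirna_ids)))]
        g = gene_ids[int(rng.integers(len(gene_ids)))]
        if (m, g) in all_true_pairs or (m, g) in scores:
            continue
        emit_failing(m, g)
        emitted += 1

    validated: set[tuple[str, str]] = set()
    for (m, g) in sorted(all_true_pairs):
        if rng.random() < config.validated_fraction:
            validated.add((m, g))

    return binary, scores, validated, true_targets


def simulate_gene_sets(
    gene_ids: list[str],
    config: SimulationConfig,
    enriched_pool: set[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, tuple[str, str, set[str]]], set[str]]:
    """Simulate a GMT-style collection with optional planted enrichment.

    ``enriched_pool`` is the gene pool the planted sets over-sample (in the
    pipeline: targets of planted up-regulated miRNAs). Planted sets draw
    ``planted_set_signal_frac`` of their members from the pool, the rest at
    random — at the default sizes that is an overlap odds ratio well above
    10. All sets get >= 5 members. Returns (sets, planted ids) where each
    set maps id -> (name, category, genes).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    lo, hi = config.gene_set_size
    if hi > len(gene_ids):
        raise ValueError("gene universe smaller than requested set sizes")
    if lo < 5:
        raise ValueError("gene sets must allow at least 5 members")

    pool = sorted(enriched_pool) if enriched_pool else []
    categories = ["GO", "KEGG", "BIOCARTA"]
    sets: dict[str, tuple[str, str, set[str]]] = {}
    planted_ids: set[str] = set()

    n_planted = config.planted_enriched_sets if pool else 0
    for i in range(config.n_gene_sets):
        sid = f"SET{i+1:04d}"
        size = int(rng.integers(lo, hi + 1))
        category = categories[i % len(categories)]
        if i < n_planted:
            n_sig = min(int(round(config.planted_set_signal_frac * size)), len(pool))
            sig = set(rng.choice(pool, size=n_sig, replace=False)) if n_sig else set()
            rest_pool = [g for g in gene_ids if g not in sig]
            rest = rng.choice(rest_pool, size=size - len(sig), replace=False)
            members = sig | set(rest.tolist())
            planted_ids.add(sid)
            name = f"planted_{category.lower()}_set_{i+1}"
        else:
            members = set(rng.choice(gene_ids, size=size, replace=False).tolist())
            name = f"random_{category.lower()}_set_{i+1}"
        sets[sid] = (name, category, members)

    return sets, planted_ids


def simulate_all(config: SimulationConfig) -> dict:
    """Generate every pipeline input from one config/seed.

    A single seed fans out to independent per-generator streams so each
    generator is individually reproducible. Returns a dict with keys
    ``expression``, ``truth``, ``binary_programs``, ``scores``,
    ``validated``, ``gene_sets``, ``gene_ids``.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng_expr, rng_pred, rng_sets = (np.random.default_rng(s) for s in root.spawn(3))

    expr, truth = simulate_expression(config, rng=rng_expr)
    genes = _gene_ids(config.n_genes)
    binary, scores, validated, true_targets = simulate_prediction_tables(
        expr.mirna_ids, genes, config, rng=rng_pred
    )
    truth.true_targets = true_targets

    pool: set[str] = set()
    for g in config.syndrome_groups:
        for m in truth.up_ids(g):
            pool |= true_targets.get(m, set())
    sets, planted = simulate_gene_sets(genes, config, enriched_pool=pool, rng=rng_sets)
    truth.enriched_set_ids = planted

    return {
        "expression": expr,
        "truth": truth,
        "binary_programs": binary,
        "scores": scores,
        "validated": validated,
        "gene_sets": sets,
        "gene_ids": genes,
    }


def write_simulation(sim: dict, out_dir: str | Path) -> None:
    """Write all simulated inputs in their on-disk dialects (TSV/GMT/JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(sim["expression"], out / "expression.tsv", out / "groups.tsv")

    rows = []
    for prog, hits in sim["binary_programs"].items():
        for m, gs in sorted(hits.items()):
            for g in sorted(gs):
                rows.append((prog, m, g, ""))
    for (m, g), s in sorted(sim["scores"].items()):
        rows.append(("miRDB", m, g, f"{s:.3f}"))
    pd.DataFrame(rows, columns=["program", "mirna_id", "gene_id", "score"]).to_csv(
        out / "predictions.tsv", sep="\t", index=False
    )
    pd.DataFrame(sorted(sim["validated"]), columns=["mirna_id", "gene_id"]).assign(
        evidence="synthetic"
    ).to_csv(out / "validated.tsv", sep="\t", index=False)

    with open(out / "gene_sets.gmt", "w") as fh:
        for sid, (name, category, members) in sim["gene_sets"].items():
            fh.write("\t".join([sid, f"{category}|{name}", *sorted(members)]) + "\n")

    (out / "ground_truth.json").write_text(sim["truth"].to_json())
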