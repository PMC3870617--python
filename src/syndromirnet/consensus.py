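"""Data A / Data B consensus rule for miRNA target selection.

Targets predicted computationally are noisy, so the pipeline keeps only
genes supported by two independent lines of evidence:

* **Data A** — genes predicted by at least 2 of the 9 binary-hit programs
  (DIANAmT, miRanda, miRWalk, RNAhybrid, PicTar4/5, PITA, RNA22, TargetScan
  style). Operationally this is the union, over all unordered program
  pairs, of the pairwise intersections — provably the same set as the
  ">=2 votes" rule, and tested against an independent vote-counting oracle.
* **Data B** — genes whose score in the score-valued program (miRDB style)
  strictly exceeds 60.

The consensus per miRNA is Data A ∩ Data B. Experimentally validated
interactions (TarBase-style input) bypass the filter and are union-ed into
the final edge set with a ``validated`` source flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd

__all__ = [
    "PredictionEnsemble",
    "ConsensusTargetSet",
    "data_a",
    "data_b",
    "consensus_targets",
    "read_prediction_tables",
    "write_consensus",
]

SCORED_PROGRAM = "miRDB"


@dataclass
class PredictionEnsemble:
    """Nine binary-hit program tables, one scored table, one validated set."""

    binary_programs: dict[str, dict[str, set[str]]]
    scored_program: dict[tuple[str, str], float]
    validated: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for (m, g), s in self.scored_program.items():
            if not (0.0 <= s <= 100.0):
                warnings.warn(
                    f"score {s} for ({m},{g}) outside [0,100]; kept as-is",
                    RuntimeWarning,
                )

    @property
    def mirnas(self) -> set[str]:
        out: set[str] = set()
        for hits in self.binary_programs.values():
            out |= set(hits)
        out |= {m for m, _ in self.scored_program}
        return out


@dataclass
class ConsensusTargetSet:
    """Per-miRNA Data A, Data B, their intersection, and validated add-ons."""

    data_a: dict[str, set[str]]
    data_b: dict[str, set[str]]
    consensus: dict[str, set[str]]
    validated_added: dict[str, set[str]]

    def final_edges(self) -> set[tuple[str, str, str]]:
        """(mirna, gene, source) with source in {consensus, validated, both}."""
        edges: set[tuple[str, str, str]] = set()
        for m, genes in self.consensus.items():
            val = self.validated_added.get(m, set())
            for g in genes:
                edges.add((m, g, "both" if g in val else "consensus"))
        for m, genes in self.validated_added.items():
            for g in genes - self.consensus.get(m, set()):
                edges.add((m, g, "validated"))
        return edges

    def targets_of(self, mirna: str) -> set[str]:
        return self.consensus.get(mirna, set()) | self.validated_added.get(mirna, set())


def data_a(binary_programs: dict[str, dict[str, set[str]]], mirna: str) -> set[str]:
    """Union over all unordered program pairs of pairwise intersections.

    Equivalent to keeping genes predicted by at least two programs; the
    exhaustive pairing is kept as the implementation because it is the
    operation the rule describes, and the equivalence is enforced by tests.
    """
    hit_sets = [hits.get(mirna, set()) for hits in binary_programs.values()]
    out: set[str] = set()
    for s1, s2 in combinations(hit_sets, 2):
        out |= s1 & s2
    return out


def data_b(scored_program: dict[tuple[str, str], float], mirna: str,
           threshold: float = 60.0) -> set[str]:
    """Genes whose score strictly exceeds ``threshold`` (score == 60 excluded)."""
    return {g for (m, g), s in scored_program.items() if m == mirna and s > threshold}


def per_program_significance_filter(ensemble: PredictionEnsemble) -> PredictionEnsemble:
    """Hook for a per-program significance screen; currently a no-op.

    Standard exports of the prediction programs carry no per-program
    p-values, so no defensible test exists here; the hook is kept so the
    pipeline structure matches the published analysis stages and warns that
    it passes everything through.
    """
    warnings.warn(
        "per-program significance filtering is a no-op: prediction exports "
        "carry no per-program p-values", RuntimeWarning)
    return ensemble


def consensus_targets(ensemble: PredictionEnsemble,
                      mirnas: list[str] | None = None,
                      threshold: float = 60.0) -> ConsensusTargetSet:
    """Apply the consensus rule per miRNA and merge validated interactions."""
    if mirnas is None:
        mirnas = sorted(ensemble.mirnas | {m for m, _ in ensemble.validated})
    A: dict[str, set[str]] = {}
    B: dict[str, set[str]] = {}
    C: dict[str, set[str]] = {}
    V: dict[str, set[str]] = {}
    # index scored table once per call
    scores_by_mirna: dict[str, dict[str, float]] = {}
    for (m, g), s in ensemble.scored_program.items():
        scores_by_mirna.setdefault(m, {})[g] = s

    for m in mirnas:
        a = data_a(ensemble.binary_programs, m)
        b = {g for g, s in scores_by_mirna.get(m, {}).items() if s > threshold}
        A[m] = a
        B[m] = b
        C[m] = a & b
        V[m] = {g for (mm, g) in ensemble.validated if mm == m}
        if not a and not b and not V[m]:
            warnings.warn(f"miRNA {m} absent from all programs; empty consensus",
                          RuntimeWarning)
    return ConsensusTargetSet(data_a=A, data_b=B, consensus=C, validated_added=V)


def read_prediction_tables(predictions_path: str | Path,
                           validated_path: str | Path | None = None,
                           scored_program: str = SCORED_PROGRAM) -> PredictionEnsemble:
    """Read the TSV dialect (program, mirna_id, gene_id[, score])."""
    df = pd.read_csv(predictions_path, sep="\t")
    binary: dict[str, dict[str, set[str]]] = {}
    scores: dict[tuple[str, str], float] = {}
    for row in df.itertuples(index=False):
        prog, m, g = str(row.program), str(row.mirna_id), str(row.gene_id)
        if prog == scored_program:
            scores[(m, g)] = float(row.score)
        else:
            binary.setdefault(prog, {}).setdefault(m, set()).add(g)
    validated: set[tuple[str, str]] = set()
    if validated_path is not None:
        vdf = pd.read_csv(validated_path, sep="\t")
        validated = {(str(r.mirna_id), str(r.gene_id)) for r in vdf.itertuples(index=False)}
    return PredictionEnsemble(binary_programs=binary, scored_program=scores,
                              validated=validated)


def write_consensus(cts: ConsensusTargetSet, path: str | Path) -> None:
    rows = sorted(cts.final_edges())
    pd.DataFrame(rows, columns=["mirna_id", "gene_id", "source"]).to_csv(
        path, sep="\t", index=False
    )
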