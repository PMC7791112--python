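"""Synthetic study generator.

Emulates a 3-vs-3 bulk RNA-seq comparison (wild type vs knockout
gastrocnemius-style design) at the FPKM level, together with every ancillary
input the downstream stages consume: TF->target maps, gene-set collections,
promoter sequences with planted motif sites, and interaction edge lists.
Every generator plants ground truth so recovery can be measured.

Expression model: per expressed gene a baseline log2 mean is drawn uniformly
on ``baseline_log2_range``; sample values are Normal(mean, sigma_log2) on the
log2 scale and exponentiated to FPKM. Differential genes shift the two group
means by +/- effect_log2 / 2 so the planted group difference equals
``effect_log2`` exactly. Silent genes are background noise drawn uniformly on
(0, 0.5) FPKM, strictly below the expressed-gene detection cutoff of 1.

All generators draw from per-generator child streams of a single seed
(``numpy.random.SeedSequence(seed, spawn_key=(stream,))``) so each module can
be re-run independently with reproducible output.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import SCALE_FPKM, ExpressionMatrix, GroupDesign
from .enrichment import GeneSetCollection
from .errors import ParameterError
from .motifs import PositionFrequencyMatrix, reverse_complement

#: fixed child-stream indices of the master seed, one per generator
STREAMS = {
    "expression": 0,
    "tf_map": 1,
    "gene_sets": 2,
    "promoters": 3,
    "interactions": 4,
    "permutation": 5,
}

LABEL_UP = "up"
LABEL_DOWN = "down"
LABEL_NULL = "null"
LABEL_SILENT = "silent"


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """The documented per-generator random stream of a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(STREAMS[name],))
    )


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the expression generator.

    Defaults emulate the target design: ~1.2e4 genes x 3+3 samples, a 5%
    planted differential fraction at a 4-fold (2 on log2) effect, within-group
    SD of 0.35 on the log2 scale, and a 20% silent (sub-detection) fraction.
    """

    n_genes: int = 12000
    n_per_group: int = 3
    frac_de: float = 0.05
    frac_silent: float = 0.20
    effect_log2: float = 2.0
    sigma_log2: float = 0.35
    baseline_log2_range: tuple[float, float] = (0.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        if self.n_per_group < 2:
            raise ParameterError("n_per_group must be >= 2")
        if not (0.0 <= self.frac_de <= 1.0 and 0.0 <= self.frac_silent <= 1.0):
            raise ParameterError("fractions must lie in [0, 1]")
        if self.frac_de + self.frac_silent > 1.0:
            raise ParameterError("frac_de + frac_silent must be <= 1")
        if self.sigma_log2 <= 0:
            raise ParameterError("sigma_log2 must be > 0")
        if self.effect_log2 <= 0:
            raise ParameterError("effect_log2 must be > 0")
        lo, hi = self.baseline_log2_range
        if not hi >= lo:
            raise ParameterError("baseline_log2_range must be a valid interval")


@dataclass
class SimulatedStudy:
    """An FPKM matrix with its design and per-gene planted truth."""

    matrix: ExpressionMatrix
    design: GroupDesign
    truth_de: pd.Series  # gene -> {up, down, null, silent}
    truth_log2_effect: pd.Series  # gene -> signed planted log2 shift
    params: SimulationParams
    seed: int

    @property
    def de_genes(self) -> list[str]:
        mask = self.truth_de.isin([LABEL_UP, LABEL_DOWN])
        return list(self.truth_de.index[mask])


def simulate_expression(params: SimulationParams) -> SimulatedStudy:
    """Draw an FPKM matrix with planted up/down/null/silent genes.

    The same params (including seed) give byte-identical output.
    """
    rng = stream_rng(params.seed, "expression")
    n = params.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]
    k = params.n_per_group
    sample_ids = [f"WT_{j + 1}" for j in range(k)] + [
        f"KO_{j + 1}" for j in range(k)
    ]
    design = GroupDesign(
        groups={
            s: ("wildtype" if s.startswith("WT") else "knockout")
            for s in sample_ids
        },
        reference="wildtype",
    )

    n_silent = math.floor(params.frac_silent * n)
    n_de = math.floor(params.frac_de * n)
    n_down = n_de // 2
    n_up = n_de - n_down  # odd remainder goes to "up"

    order = rng.permutation(n)
    labels = np.full(n, LABEL_NULL, dtype=object)
    labels[order[:n_silent]] = LABEL_SILENT
    labels[order[n_silent : n_silent + n_up]] = LABEL_UP
    labels[order[n_silent + n_up : n_silent + n_de]] = LABEL_DOWN

    effects = np.zeros(n)
    effects[labels == LABEL_UP] = params.effect_log2
    effects[labels == LABEL_DOWN] = -params.effect_log2

    lo, hi = params.baseline_log2_range
    baseline = rng.uniform(lo, hi, size=n)
    # group means on log2 scale; "up" means higher in the knockout group
    mean_wt = baseline - effects / 2.0
    mean_ko = baseline + effects / 2.0
    log2_vals = np.empty((n, 2 * k))
    log2_vals[:, :k] = rng.normal(
        mean_wt[:, None], params.sigma_log2, size=(n, k)
    )
    log2_vals[:, k:] = rng.normal(
        mean_ko[:, None], params.sigma_log2, size=(n, k)
    )
    fpkm = np.exp2(log2_vals)
    silent_mask = labels == LABEL_SILENT
    if silent_mask.any():
        fpkm[silent_mask] = rng.uniform(
            0.0, 0.5, size=(int(silent_mask.sum()), 2 * k)
        )

    matrix = ExpressionMatrix(
        pd.DataFrame(fpkm, index=gene_ids, columns=sample_ids), SCALE_FPKM
    )
    return SimulatedStudy(
        matrix=matrix,
        design=design,
        truth_de=pd.Series(labels, index=gene_ids, name="truth_de"),
        truth_log2_effect=pd.Series(
            effects, index=gene_ids, name="truth_log2_effect"
        ),
        params=params,
        seed=params.seed,
    )


def simulate_tf_map(
    n_tfs: int,
    targets_per_tf: int,
    planted_tf_count: int,
    truth_de: pd.Series,
    seed: int,
    min_de_targets: int = 5,
) -> tuple[dict[str, list[str]], list[str]]:
    """TF -> target map with ``planted_tf_count`` TFs enriched for DE genes.

    Planted TFs draw ``max(min_de_targets, targets_per_tf // 2)`` (capped at
    ``targets_per_tf``) of their targets from the planted DE genes; the rest,
    and all background TFs, draw uniformly from the expressed universe.
    """
    if planted_tf_count > n_tfs:
        raise ParameterError("planted_tf_count cannot exceed n_tfs")
    if targets_per_tf < 1:
        raise ParameterError("targets_per_tf must be >= 1")
    universe = np.array(truth_de.index[truth_de != LABEL_SILENT])
    de_genes = np.array(truth_de.index[truth_de.isin([LABEL_UP, LABEL_DOWN])])
    if targets_per_tf > len(universe):
        raise ParameterError("targets_per_tf exceeds the expressed universe")
    n_from_de = min(targets_per_tf, max(min_de_targets, targets_per_tf // 2))
    if planted_tf_count > 0 and len(de_genes) < n_from_de:
        raise ParameterError(
            f"need >= {n_from_de} DE genes to plant TFs; have {len(de_genes)}"
        )
    rng = stream_rng(seed, "tf_map")
    tf_ids = [f"TF{i + 1:03d}" for i in range(n_tfs)]
    planted = sorted(
        rng.choice(tf_ids, size=planted_tf_count, replace=False).tolist()
    )
    planted_set = set(planted)
    tf_map: dict[str, list[str]] = {}
    for tf in tf_ids:
        if tf in planted_set:
            de_part = rng.choice(de_genes, size=n_from_de, replace=False)
            pool = np.setdiff1d(universe, de_part, assume_unique=False)
            bg_part = rng.choice(
                pool, size=targets_per_tf - n_from_de, replace=False
            )
            targets = np.concatenate([de_part, bg_part])
        else:
            targets = rng.choice(universe, size=targets_per_tf, replace=False)
        tf_map[tf] = sorted(targets.tolist())
    return tf_map, planted


def simulate_gene_sets(
    n_sets: int,
    set_size_range: tuple[int, int],
    truth_de: pd.Series,
    planted_set_count: int,
    seed: int,
    frac_de_members: float = 0.75,
) -> tuple[GeneSetCollection, pd.DataFrame]:
    """Gene-set collection with ``planted_set_count`` DE-enriched sets.

    Planted sets draw ``round(frac_de_members * size)`` members from the DE
    genes. Returns the collection and a truth table (set_id, planted,
    n_de_members).
    """
    if planted_set_count > n_sets:
        raise ParameterError("planted_set_count cannot exceed n_sets")
    lo, hi = set_size_range
    if not 1 <= lo <= hi:
        raise ParameterError("invalid set_size_range")
    universe = np.array(truth_de.index[truth_de != LABEL_SILENT])
    de_genes = np.array(truth_de.index[truth_de.isin([LABEL_UP, LABEL_DOWN])])
    if hi > len(universe):
        raise ParameterError("set sizes exceed the expressed universe")
    rng = stream_rng(seed, "gene_sets")
    set_ids = [f"SET{i + 1:03d}" for i in range(n_sets)]
    planted = set(
        rng.choice(set_ids, size=planted_set_count, replace=False).tolist()
    )
    sets: dict[str, list[str]] = {}
    records = []
    for set_id in set_ids:
        size = int(rng.integers(lo, hi + 1))
        if set_id in planted:
            n_de = min(round(frac_de_members * size), len(de_genes), size)
            if planted_set_count > 0 and n_de == 0:
                raise ParameterError("no DE genes available to plant sets")
            de_part = rng.choice(de_genes, size=n_de, replace=False)
            pool = np.setdiff1d(universe, de_part)
            bg_part = rng.choice(pool, size=size - n_de, replace=False)
            members = np.concatenate([de_part, bg_part])
        else:
            n_de = 0
            members = rng.choice(universe, size=size, replace=False)
        sets[set_id] = sorted(members.tolist())
        records.append(
            {
                "set_id": set_id,
                "planted": set_id in planted,
                "n_de_members": int(n_de) if set_id in planted else None,
            }
        )
    truth = pd.DataFrame(records, columns=["set_id", "planted", "n_de_members"])
    descriptions = {
        s: ("planted DE-enriched set" if s in planted else "background set")
        for s in set_ids
    }
    return GeneSetCollection(sets, descriptions), truth


def simulate_promoters(
    pfm: PositionFrequencyMatrix,
    n_seq: int,
    length: int,
    planted: Sequence[tuple[int, int, str]],
    seed: int,
) -> tuple[dict[str, str], list[tuple[str, int, str]]]:
    """Random promoter sequences with consensus motif sites planted.

    ``planted`` is a list of ``(sequence_index, position, strand)``; the
    motif consensus (reverse-complemented for '-') replaces the background
    bases at that plus-strand position. Planted sites must fit and must not
    overlap within a sequence.
    """
    L = pfm.length
    per_seq: dict[int, list[tuple[int, str]]] = {}
    for idx, pos, strand in planted:
        if not 0 <= idx < n_seq:
            raise ParameterError(f"planted sequence index {idx} out of range")
        if strand not in "+-":
            raise ParameterError(f"invalid strand {strand!r}")
        if pos < 0 or pos + L > length:
            raise ParameterError(
                f"planted site at {pos} does not fit in length {length}"
            )
        per_seq.setdefault(idx, []).append((pos, strand))
    for idx, sites in per_seq.items():
        sites.sort()
        for (p1, _), (p2, _) in itertools.pairwise(sites):
            if p2 < p1 + L:
                raise ParameterError(
                    f"overlapping planted sites at {p1} and {p2} in sequence {idx}"
                )
    rng = stream_rng(seed, "promoters")
    consensus = pfm.consensus()
    bases = np.array(list("ACGT"))
    sequences: dict[str, str] = {}
    truth: list[tuple[str, int, str]] = []
    for i in range(n_seq):
        seq_id = f"seq_{i + 1:03d}"
        seq = rng.choice(bases, size=length)
        for pos, strand in per_seq.get(i, []):
            word = consensus if strand == "+" else reverse_complement(consensus)
            seq[pos : pos + L] = list(word)
            truth.append((seq_id, pos, strand))
        sequences[seq_id] = "".join(seq)
    return sequences, truth


def simulate_interactions(
    genes: Sequence[str], n_edges: int, seed: int
) -> list[tuple[str, str]]:
    """Undirected simple random edges over the gene universe.

    No self-loops, no duplicate edges (regardless of orientation).
    """
    gene_list = list(dict.fromkeys(genes))
    n = len(gene_list)
    max_edges = n * (n - 1) // 2
    if n_edges < 0:
        raise ParameterError("n_edges must be >= 0")
    if n_edges > max_edges:
        raise ParameterError(
            f"n_edges {n_edges} exceeds the {max_edges} possible simple edges"
        )
    rng = stream_rng(seed, "interactions")
    if max_edges <= 2_000_000:
        chosen = rng.choice(max_edges, size=n_edges, replace=False)
        edges = []
        cum = lambda i: (i * (2 * n - i - 1)) // 2  # noqa: E731
        for code in sorted(int(c) for c in chosen):
            # decode the linear index of an (i < j) pair
            i = int((2 * n - 1 - math.sqrt((2 * n - 1) ** 2 - 8 * code)) // 2)
            while i + 1 < n and cum(i + 1) <= code:  # guard sqrt rounding
                i += 1
            while i > 0 and cum(i) > code:
                i -= 1
            j = i + 1 + (code - cum(i))
            edges.append((gene_list[i], gene_list[j]))
        return edges
    seen: set[tuple[int, int]] = set()
    edges = []
    while len(edges) < n_edges:
        i, j = (int(x) for x in rng.integers(0, n, size=2))
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        edges.append((gene_list[key[0]], gene_list[key[1]]))
    return edges
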