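"""Breakpoints-per-gene contrast between ovary- and testis-specific genes.

Stage 2 of the pipeline: the statistic is (No/O)/(Nt/T) — the mean number
of gene-order-disrupting rearrangement breakpoints flanking ovary-specific
genes divided by the same mean for testis-specific genes.  The null
rearranges the gonadal expression tags uniformly at random among the OL
genes of each chromosome arm, preserving every arm's tag counts, and
recomputes the ratio.  A ratio above one with small P_upper indicates that
gene-order disruption concentrates around female-germline-accessible genes.

By default tags are reassigned over ALL OL genes on the arm, testing the
tag-breakpoint association against the arm-matched genomic background;
``universe="tagged-only"`` restricts the shuffle to the tagged genes as a
sensitivity analysis.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .genome_model import GeneRecord, PermutationResult, UndefinedStatisticError
from .resampling import count_invalid, empirical_p_values

logger = logging.getLogger("armshuffle")

_TAG_CODE = {"untagged": 0, "ovary_specific": 1, "testis_specific": 2}
_CODE_TAG = {v: k for k, v in _TAG_CODE.items()}

UNIVERSES = ("all-genes", "tagged-only")


def breakpoints_per_gene(gene: GeneRecord, definition: str) -> int:
    """Total breakpoints flanking a gene: left + right for ``definition``."""
    return gene.breakpoints_total(definition)


def ovary_testis_ratio(genes: Sequence[GeneRecord], definition: str) -> float:
    """(No/O)/(Nt/T) over the tagged genes; errors if either class is empty."""
    No = Nt = 0
    O = T = 0
    for g in genes:
        if g.tag == "ovary_specific":
            O += 1
            No += g.breakpoints_total(definition)
        elif g.tag == "testis_specific":
            T += 1
            Nt += g.breakpoints_total(definition)
    if O == 0 or T == 0:
        raise ValueError(f"need >= 1 gene of each class (O={O}, T={T})")
    if Nt == 0:
        raise UndefinedStatisticError("testis-specific genes have zero breakpoints: ratio undefined")
    return (No / O) / (Nt / T)


def _tag_codes(genes: Sequence[GeneRecord]) -> np.ndarray:
    return np.array([_TAG_CODE[g.tag] for g in genes], dtype=np.int8)


def _arm_groups(genes: Sequence[GeneRecord]) -> list[np.ndarray]:
    groups: dict[str, list[int]] = {}
    for i, g in enumerate(genes):
        groups.setdefault(g.arm, []).append(i)
    return [np.asarray(v, dtype=np.int64) for v in groups.values()]


def permute_tag_matrix(
    tags: np.ndarray,
    arm_groups: list[np.ndarray],
    replicates: int,
    rng: np.random.Generator,
    universe: str = "all-genes",
) -> np.ndarray:
    """(replicates, n_genes) matrix of arm-stratified tag shuffles.

    Within each arm the tag multiset is preserved exactly; each replicate
    row is an independent uniform shuffle.  Under ``tagged-only`` untagged
    genes keep their (un)tag and only tagged genes exchange labels.
    """
    if universe not in UNIVERSES:
        raise ValueError(f"universe must be one of {UNIVERSES}")
    out = np.empty((replicates, tags.size), dtype=np.int8)
    out[:] = tags[None, :]
    for idx in arm_groups:
        if universe == "tagged-only":
            idx = idx[tags[idx] != 0]
        if idx.size <= 1:
            continue
        perm = np.argsort(rng.random((replicates, idx.size)), axis=1)
        out[:, idx] = tags[idx][perm]
    return out


def permute_tags_within_arms(
    genes: Sequence[GeneRecord],
    rng: np.random.Generator,
    universe: str = "all-genes",
) -> list[str]:
    """One replicate of the arm-respecting tag shuffle; returns new tags."""
    tags = _tag_codes(genes)
    row = permute_tag_matrix(tags, _arm_groups(genes), 1, rng, universe)[0]
    return [_CODE_TAG[int(c)] for c in row]


def _annotated(genes: Sequence[GeneRecord], definition: str) -> list[GeneRecord]:
    kept = [g for g in genes if definition in g.left_breakpoints and definition in g.right_breakpoints]
    dropped = len(genes) - len(kept)
    if dropped:
        logger.warning(
            "%d genes lack breakpoint annotation for %s and are excluded", dropped, definition
        )
    return kept


def breakpoint_permutation_test(
    genes: Sequence[GeneRecord],
    definition: str,
    replicates: int = 10_000,
    seed: int | None = 0,
    universe: str = "all-genes",
) -> dict[str, PermutationResult]:
    """Arm-respecting tag-permutation test of the breakpoint ratio.

    Returns three results sharing one null sample: ``"ratio"`` for
    (No/O)/(Nt/T), plus ``"ovary_mean"`` (No/O) and ``"testis_mean"``
    (Nt/T), whose own tails show which class drives a significant ratio.
    """
    kept = _annotated(genes, definition)
    tags = _tag_codes(kept)
    bp = np.array([g.breakpoints_total(definition) for g in kept], dtype=float)
    O = int(np.count_nonzero(tags == 1))
    T = int(np.count_nonzero(tags == 2))
    if O == 0 or T == 0:
        raise ValueError(f"need >= 1 gene of each class (O={O}, T={T})")
    rng = np.random.default_rng(seed)
    mat = permute_tag_matrix(tags, _arm_groups(kept), replicates, rng, universe)
    No_null = (mat == 1) @ bp
    Nt_null = (mat == 2) @ bp
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_null = (No_null / O) / (Nt_null / T)
    ratio_null[Nt_null == 0] = np.nan

    No = float(bp[tags == 1].sum())
    Nt = float(bp[tags == 2].sum())
    if Nt == 0:
        raise UndefinedStatisticError("observed testis breakpoint total is zero: ratio undefined")
    observed = (No / O) / (Nt / T)

    def _result(label: str, obs: float, nulls: np.ndarray) -> PermutationResult:
        p_upper, p_lower = empirical_p_values(obs, nulls)
        return PermutationResult(
            label=label,
            observed=obs,
            null_values=nulls,
            p_upper=p_upper,
            p_lower=p_lower,
            replicates=replicates,
            n_invalid=count_invalid(nulls),
            seed=seed,
        )

    return {
        "ratio": _result(f"breakpoint_ratio[{definition}]", observed, ratio_null),
        "ovary_mean": _result(f"breakpoints_per_ovary_gene[{definition}]", No / O, No_null / O),
        "testis_mean": _result(f"breakpoints_per_testis_gene[{definition}]", Nt / T, Nt_null / T),
    }
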