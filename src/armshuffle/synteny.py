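"""Flanking-gene conservation classes and their gonadal-expression bias.

Stage 3 of the pipeline.  Every OL gene falls in exactly one class by the
fate of its two flanking genes across the genus:

* ``singleton``   — both flanking genes changed at least once;
* ``unisyntenic`` — exactly one flanking gene changed;
* ``bisyntenic``  — neither flanking gene ever changed.

Nested genes are always bisyntenic; a gene hosting nested genes whose both
flanks changed is unisyntenic (the nested gene shields one side).  The
class x tag table is tested for trend (Cochran-Armitage, scores 0,1,2 on
singleton < unisyntenic < bisyntenic), and each class's expression ratio
(no/No)/(nt/Nt) is evaluated against the same arm-stratified tag shuffle
used by the breakpoint analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genome_model import (
    GeneRecord,
    PermutationResult,
    TrendTestResult,
    UndefinedStatisticError,
)
from .breakpoints import _arm_groups, _tag_codes, permute_tag_matrix
from .resampling import count_invalid, empirical_p_values

CLASSES = ("singleton", "unisyntenic", "bisyntenic")


@dataclass
class ClassTagTable:
    """3x2 counts: rows (singleton, unisyntenic, bisyntenic) x (ovary, testis)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 2):
            raise ValueError("ClassTagTable must be 3x2 (classes x ovary/testis)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def No(self) -> int:
        """Total ovary-specific genes over the three classes."""
        return int(self.counts[:, 0].sum())

    @property
    def Nt(self) -> int:
        """Total testis-specific genes over the three classes."""
        return int(self.counts[:, 1].sum())


def classify_synteny(gene: GeneRecord, definition: str) -> str:
    """Assign the gene's synteny class for one stability definition.

    Precedence: nested -> bisyntenic; host with both flanks changed ->
    unisyntenic; then the plain flank rules.  Only direct nesting links are
    consulted.
    """
    try:
        left = gene.left_changed[definition]
        right = gene.right_changed[definition]
    except KeyError:
        raise KeyError(
            f"gene {gene.id!r}: no flank-change annotation for definition {definition!r}"
        ) from None
    if gene.nested_in is not None:
        return "bisyntenic"
    if gene.hosts and left and right:
        return "unisyntenic"
    if left and right:
        return "singleton"
    if left or right:
        return "unisyntenic"
    return "bisyntenic"


def build_class_tag_table(
    genes: Sequence[GeneRecord],
    definition: str,
    tags: Mapping[str, str] | None = None,
) -> ClassTagTable:
    """Cross-tabulate synteny class against gonadal tag (untagged excluded)."""
    counts = np.zeros((3, 2), dtype=np.int64)
    cls_index = {c: i for i, c in enumerate(CLASSES)}
    for g in genes:
        if definition not in g.left_changed or definition not in g.right_changed:
            continue  # gene not annotated under this definition
        tag = tags.get(g.id, g.tag) if tags is not None else g.tag
        if tag == "ovary_specific":
            col = 0
        elif tag == "testis_specific":
            col = 1
        else:
            continue
        counts[cls_index[classify_synteny(g, definition)], col] += 1
    return ClassTagTable(counts)


def trend_chi_square(
    table: ClassTagTable | np.ndarray,
    scores: Sequence[float] = (0.0, 1.0, 2.0),
) -> TrendTestResult:
    """Cochran-Armitage chi-square test for trend (df = 1).

    With row totals n_i, ovary counts o_i, scores s_i, N = sum n_i and
    O = sum o_i:

        chi2 = N (N*T1 - O*T2)^2 / [ O (N - O) (N*T3 - T2^2) ]

    where T1 = sum o_i s_i, T2 = sum n_i s_i, T3 = sum n_i s_i^2.  No
    continuity correction.  The statistic is invariant under affine score
    changes and equals the Pearson chi-square when only two rows are
    non-empty.
    """
    counts = table.counts if isinstance(table, ClassTagTable) else np.asarray(table, dtype=np.int64)
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise ValueError("trend table must be k x 2")
    s = np.asarray(scores, dtype=float)
    if s.size != counts.shape[0]:
        raise ValueError("one score per row required")
    n = counts.sum(axis=1).astype(float)
    o = counts[:, 0].astype(float)
    N = n.sum()
    O = o.sum()
    if N < 1:
        raise ValueError("empty table")
    T1 = float(o @ s)
    T2 = float(n @ s)
    T3 = float(n @ (s * s))
    denom = O * (N - O) * (N * T3 - T2 * T2)
    if denom == 0:
        raise UndefinedStatisticError(
            "degenerate table: all mass in one row or one column; trend undefined"
        )
    chi2 = N * (N * T1 - O * T2) ** 2 / denom
    return TrendTestResult(
        chi_square=float(chi2),
        degrees_of_freedom=1,
        p_value=float(stats.chi2.sf(chi2, 1)),
    )


def class_expression_ratio(table: ClassTagTable, synteny_class: str) -> float:
    """(no/No)/(nt/Nt) for one class; undefined when the class has nt = 0."""
    if synteny_class not in CLASSES:
        raise ValueError(f"unknown class {synteny_class!r}")
    if table.No == 0 or table.Nt == 0:
        raise ValueError("need >= 1 ovary- and >= 1 testis-specific gene overall")
    i = CLASSES.index(synteny_class)
    no, nt = int(table.counts[i, 0]), int(table.counts[i, 1])
    if nt == 0:
        raise UndefinedStatisticError(f"class {synteny_class!r} has no testis-specific genes")
    return (no / table.No) / (nt / table.Nt)


def class_ratio_permutation_test(
    genes: Sequence[GeneRecord],
    definition: str,
    replicates: int = 10_000,
    seed: int | None = 0,
    universe: str = "all-genes",
) -> dict[str, PermutationResult]:
    """Per-class expression-ratio test under the arm-stratified tag shuffle.

    Returns one PermutationResult per synteny class.  Replicates where a
    class draws zero testis-specific genes have an undefined ratio for that
    class and are excluded from its tails (``n_invalid``).  A class whose
    *observed* ratio is undefined (nt = 0 in the real tags) is omitted from
    the result with a logged warning.
    """
    genes = [g for g in genes if definition in g.left_changed and definition in g.right_changed]
    tags = _tag_codes(genes)
    cls = np.array([CLASSES.index(classify_synteny(g, definition)) for g in genes], dtype=np.int8)
    table = build_class_tag_table(genes, definition)
    No, Nt = table.No, table.Nt
    if No == 0 or Nt == 0:
        raise ValueError("need >= 1 ovary- and >= 1 testis-specific gene overall")
    rng = np.random.default_rng(seed)
    mat = permute_tag_matrix(tags, _arm_groups(genes), replicates, rng, universe)
    ind = np.zeros((len(genes), 3))
    ind[np.arange(len(genes)), cls] = 1.0
    no_null = (mat == 1) @ ind  # (R, 3)
    nt_null = (mat == 2) @ ind
    out: dict[str, PermutationResult] = {}
    for i, c in enumerate(CLASSES):
        with np.errstate(divide="ignore", invalid="ignore"):
            nulls = (no_null[:, i] / No) / (nt_null[:, i] / Nt)
        nulls[nt_null[:, i] == 0] = np.nan
        try:
            observed = class_expression_ratio(table, c)
        except UndefinedStatisticError as exc:
            logging.getLogger("armshuffle").warning("class %s skipped: %s", c, exc)
            continue
        p_upper, p_lower = empirical_p_values(observed, nulls)
        out[c] = PermutationResult(
            label=f"class_ratio[{definition}:{c}]",
            observed=observed,
            null_values=nulls,
            p_upper=p_upper,
            p_lower=p_lower,
            replicates=replicates,
            n_invalid=count_invalid(nulls),
            seed=seed,
        )
    return out
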